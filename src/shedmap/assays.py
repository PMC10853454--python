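"""Shedding-ratio, FRET-trace and concentration-response quantification.

Ectodomain shedding is read out as fluorescence released into the culture
supernatant versus fluorescence retained on the cells: after subtracting
the medium blank from both compartments, Ratio = F_supernatant / F_cell,
normalized to the control condition. FRET time series are
background-corrected per channel, the acceptor channel corrected for donor
bleed-through, ratioed, and affine-mapped so the pre-ligand baseline is 0 %
and the saturating-stimulus plateau is 100 %. Concentration-response curves
use a three-parameter logistic (bottom, top, logEC50; Hill slope fixed at
1) and nested fits are compared with the extra-sum-of-squares F test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


# --- shedding ratio ---------------------------------------------------------

@dataclass(frozen=True)
class Well:
    condition: str
    compartment: str  # "supernatant" | "cell"
    fluorescence: float

    def __post_init__(self):
        if self.compartment not in ("supernatant", "cell"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.fluorescence < 0:
            raise ValueError("fluorescence must be non-negative")


@dataclass
class PlateMeasurement:
    """Fluorescence wells plus per-compartment blank (background) values."""

    wells: list[Well]
    background: dict[str, float]  # compartment -> blank fluorescence

    def conditions(self) -> list[str]:
        seen = []
        for w in self.wells:
            if w.condition not in seen:
                seen.append(w.condition)
        return seen

    def corrected_mean(self, condition: str, compartment: str) -> float:
        vals = [
            w.fluorescence - self.background.get(compartment, 0.0)
            for w in self.wells
            if w.condition == condition and w.compartment == compartment
        ]
        if not vals:
            raise ValueError(f"no {compartment} wells for condition {condition!r}")
        return float(np.mean(vals))


@dataclass(frozen=True)
class SheddingResult:
    condition: str
    ratio: float
    normalized_ratio: float


def shedding_ratio(
    plate: PlateMeasurement,
    control_condition: str,
    floor: float = 0.0,
) -> list[SheddingResult]:
    """Background-corrected supernatant/cell ratio per condition.

    Negative background-corrected supernatant means are clipped to
    ``floor`` (0 by default); a non-positive corrected cell-compartment mean
    makes the ratio undefined and raises. Ratios are normalized by the
    control condition's ratio, so the control reports exactly 1.
    """
    if control_condition not in plate.conditions():
        raise ValueError(f"control condition {control_condition!r} not on plate")

    raw: dict[str, float] = {}
    for cond in plate.conditions():
        sup = max(plate.corrected_mean(cond, "supernatant"), floor)
        cell = plate.corrected_mean(cond, "cell")
        if cell <= 0:
            raise ValueError(
                f"corrected cell fluorescence for {cond!r} is non-positive; "
                "ratio undefined"
            )
        raw[cond] = sup / cell

    control = raw[control_condition]
    if control <= 0:
        raise ValueError("control ratio is non-positive; cannot normalize")
    return [
        SheddingResult(cond, r, 1.0 if cond == control_condition else r / control)
        for cond, r in raw.items()
    ]


# --- FRET traces ------------------------------------------------------------

@dataclass
class FretTrace:
    """A two-channel FRET time series with correction metadata.

    ``donor``/``acceptor`` are raw emission intensities; ``background`` maps
    each channel to the cell-free-region intensity to subtract;
    ``bleed_through_factor`` is the fraction of donor emission leaking into
    the acceptor channel; ``ligand_index`` marks the frame of ligand
    addition and ``stimulus_index`` the frame of the saturating stimulus.
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    background: dict[str, float]
    bleed_through_factor: float
    ligand_index: int
    stimulus_index: int

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.donor = np.asarray(self.donor, float)
        self.acceptor = np.asarray(self.acceptor, float)
        n = len(self.time)
        if len(self.donor) != n or len(self.acceptor) != n:
            raise ValueError("channel lengths must match the time axis")
        if not (0 <= self.bleed_through_factor < 1):
            raise ValueError("bleed-through factor must be in [0, 1)")
        if not (0 < self.ligand_index < self.stimulus_index < n):
            raise ValueError("event markers out of order or out of range")


def fret_ratio(trace: FretTrace) -> np.ndarray:
    """Corrected donor/acceptor ratio per time point.

    Channels are background-subtracted, the acceptor is corrected for donor
    bleed-through, and the ratio donor/acceptor is returned (an increase
    reports loss of FRET, i.e. rising cAMP for an Epac-type sensor).
    """
    donor = trace.donor - trace.background.get("donor", 0.0)
    acceptor = trace.acceptor - trace.background.get("acceptor", 0.0)
    acceptor = acceptor - trace.bleed_through_factor * donor
    if np.any(acceptor <= 0):
        raise ValueError("corrected acceptor channel non-positive; check background")
    return donor / acceptor


def fret_normalize(
    trace: FretTrace,
    baseline_n: int = 10,
    plateau_n: int = 10,
) -> np.ndarray:
    """Normalized delta-FRET series in percent.

    The mean of the ``baseline_n`` points immediately before ligand
    addition maps to 0 % and the mean of the last ``plateau_n`` points
    after the saturating stimulus maps to 100 %.
    """
    if trace.ligand_index < baseline_n:
        raise ValueError(
            f"need {baseline_n} baseline points before ligand addition, "
            f"have {trace.ligand_index}"
        )
    ratio = fret_ratio(trace)
    baseline = ratio[trace.ligand_index - baseline_n : trace.ligand_index].mean()
    plateau = ratio[-plateau_n:].mean()
    if plateau <= baseline:
        raise ValueError("saturating plateau does not exceed baseline")
    return (ratio - baseline) / (plateau - baseline) * 100.0


# --- concentration-response fitting -----------------------------------------

def three_param_logistic(conc, bottom, top, log_ec50):
    """Response at molar concentration ``conc`` (Hill slope fixed at 1)."""
    conc = np.asarray(conc, float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (log_ec50 - np.log10(conc)))


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ec50: float
    residual_ss: float
    n_points: int
    n_parameters: int = 3
    converged: bool = True
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n_points - self.n_parameters

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, conc):
        return three_param_logistic(conc, self.bottom, self.top, self.log_ec50)


def fit_dose_response(
    concentration,
    response,
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares three-parameter logistic fit.

    Initial values come from data quantiles (bottom/top from the response
    extremes, logEC50 from a small grid over the sampled concentration
    range); the best of the multi-start fits is kept. ``fix_bottom`` pins
    the bottom parameter (e.g. 0) and fits only top and logEC50.
    """
    conc = np.asarray(concentration, float)
    resp = np.asarray(response, float)
    if conc.shape != resp.shape:
        raise ValueError("concentration and response must have equal length")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (molar)")

    if np.ptp(resp) == 0:
        ss = 0.0
        return DoseResponseFit(
            float(resp[0]), float(resp[0]), float(np.median(np.log10(conc))),
            ss, len(resp), converged=True, degenerate=True,
        )

    lo, hi = float(resp.min()), float(resp.max())
    log_c = np.log10(conc)
    starts = np.quantile(log_c, [0.25, 0.5, 0.75])

    best = None
    for lec50_0 in starts:
        try:
            if fix_bottom is None:
                popt, _ = optimize.curve_fit(
                    three_param_logistic, conc, resp,
                    p0=[lo, hi, lec50_0], maxfev=10000,
                )
                bottom, top, lec50 = popt
            else:
                popt, _ = optimize.curve_fit(
                    lambda c, t, l: three_param_logistic(c, fix_bottom, t, l),
                    conc, resp, p0=[hi, lec50_0], maxfev=10000,
                )
                bottom, (top, lec50) = fix_bottom, popt
        except RuntimeError:
            continue
        ss = float(np.sum((resp - three_param_logistic(conc, bottom, top, lec50)) ** 2))
        if best is None or ss < best.residual_ss:
            best = DoseResponseFit(
                float(bottom), float(top), float(lec50), ss, len(resp),
                n_parameters=2 if fix_bottom is not None else 3,
            )
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from any start")
    return best


@dataclass(frozen=True)
class ESSFTestResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float


def ess_f_test(
    ss_shared: float,
    df_shared: int,
    ss_separate: float,
    df_separate: int,
) -> ESSFTestResult:
    """Extra-sum-of-squares F test between nested curve fits.

    The shared (pooled-parameter) model must be nested in the separate
    (per-curve) model: fewer parameters, hence more residual degrees of
    freedom and residual SS at least as large.
    """
    if df_shared <= df_separate:
        raise ValueError("shared model must have more residual df than separate")
    if ss_shared < ss_separate - 1e-9 * max(1.0, ss_separate):
        raise ValueError("shared model fits better than separate; models not nested")
    df1 = df_shared - df_separate
    df2 = df_separate
    if ss_separate == 0:
        warnings.warn("separate-model residual SS is zero; p set to 0")
        return ESSFTestResult(math.inf, df1, df2, 0.0)
    f = max(0.0, (ss_shared - ss_separate) / df1) / (ss_separate / df2)
    p = float(stats.f.sf(f, df1, df2))
    return ESSFTestResult(float(f), df1, df2, p)


def compare_dose_response(
    conc1, resp1, conc2, resp2, share: str = "top"
) -> tuple[DoseResponseFit, DoseResponseFit, ESSFTestResult]:
    """Fit two curves separately and with one parameter shared; F test.

    ``share`` names the parameter constrained equal across curves ("top",
    "bottom" or "log_ec50"); the remaining parameters stay per-curve. Used
    to ask whether, e.g., the maximal efficacy of two receptor variants
    differs.
    """
    conc1, resp1 = np.asarray(conc1, float), np.asarray(resp1, float)
    conc2, resp2 = np.asarray(conc2, float), np.asarray(resp2, float)
    fit1 = fit_dose_response(conc1, resp1)
    fit2 = fit_dose_response(conc2, resp2)
    ss_sep = fit1.residual_ss + fit2.residual_ss
    df_sep = fit1.df + fit2.df

    names = ("bottom", "top", "log_ec50")
    if share not in names:
        raise ValueError(f"share must be one of {names}")
    si = names.index(share)

    def packed_residuals(params):
        shared = params[0]
        p1 = list(params[1:3])
        p2 = list(params[3:5])
        p1.insert(si, shared)
        p2.insert(si, shared)
        r1 = resp1 - three_param_logistic(conc1, *p1)
        r2 = resp2 - three_param_logistic(conc2, *p2)
        return np.concatenate([r1, r2])

    full1 = [fit1.bottom, fit1.top, fit1.log_ec50]
    full2 = [fit2.bottom, fit2.top, fit2.log_ec50]
    shared0 = 0.5 * (full1[si] + full2[si])
    x0 = [shared0] + [v for i, v in enumerate(full1) if i != si] + [
        v for i, v in enumerate(full2) if i != si
    ]
    sol = optimize.least_squares(packed_residuals, x0)
    ss_shared = float(np.sum(sol.fun ** 2))
    df_shared = len(resp1) + len(resp2) - 5
    # numerical guard: the shared model can never beat the separate fits
    ss_shared = max(ss_shared, ss_sep)
    test = ess_f_test(ss_shared, df_shared, ss_sep, df_sep)
    return fit1, fit2, test


# --- qPCR -------------------------------------------------------------------

def qpcr_efficiency(slope: float) -> float:
    """Amplification efficiency (percent) from a standard-curve slope.

    E = (10^(-1/slope) - 1) * 100; a perfect doubling per cycle
    (slope = -1/log10(2) = -3.3219) gives 100 %.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0
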