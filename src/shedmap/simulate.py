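"""Synthetic data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and returns
its ground truth alongside the data so recovery tests never re-derive it.
The generators emulate the statistical structure of the real inputs:

* shedding identifications — a protein cleaved at planted sites, each
  product digested fully by several proteases, with per-peptide detection
  dropout and decoy peptides carrying spurious non-canonical termini;
* spectrum pairs — a noiseless "predicted" fragment spectrum from a simple
  positional intensity heuristic (an intentionally non-physical stand-in
  for a learned fragment-intensity predictor) and an "acquired" copy with
  log-normal intensity noise, peak dropout, m/z jitter and background
  peaks;
* LFQ proteome — per-protein normal log2 intensities, a labelled subset
  shifted between groups, and intensity-dependent (MNAR) missingness via a
  decreasing logistic;
* plate and FRET traces — known shed fractions / known 0-100 anchors with
  additive background, the oracles for the assay-quantification round
  trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import FretTrace, PlateMeasurement, Well
from .fragments import Peak, Spectrum, theoretical_fragments
from .proteolysis import (
    PeptideMatch,
    ProteaseSpec,
    ProteinRecord,
    classify_termini,
    digest,
    TerminusLabel,
)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def generate_protein(length: int, seed: int, protein_id: str = "SIM") -> ProteinRecord:
    """Uniform-random protein sequence of the given length."""
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_RESIDUES), size=length))
    return ProteinRecord(protein_id, seq, "simulated protein")


def simulate_shedding_identifications(
    protein: ProteinRecord,
    planted_sites: list[int],
    proteases: list[ProteaseSpec],
    decoy_rate: float = 0.0,
    detection_probability: float = 1.0,
    seed: int = 0,
    length_range: tuple[int, int] = (1, 1_000_000),
) -> tuple[list[PeptideMatch], dict]:
    """Peptide table from a protein cleaved at planted sites.

    For each planted site the protein is split into its two products; each
    product is digested fully (0 missed cleavages) by each protease, and
    every resulting peptide is mapped back to whole-protein coordinates and
    retained with ``detection_probability``. The default length range is
    unbounded so the noise-free table always contains the two peptides
    flanking each planted site (the generator's contract); narrow it to
    emulate instrument-detectable peptide lengths. Decoy peptides are
    random substrings whose termini are non-canonical at non-planted
    positions, added at ``decoy_rate`` of the signal-peptide count.

    Returns the table and the ground truth
    ``{"planted_sites": [...], "decoys": [...]}``.
    """
    if not (0 <= decoy_rate <= 1) or not (0 <= detection_probability <= 1):
        raise ValueError("rates must be fractions in [0, 1]")
    for s in planted_sites:
        if not (1 <= s <= len(protein) - 1):
            raise ValueError(f"planted site {s} outside protein")
    rng = np.random.default_rng(seed)
    table: list[PeptideMatch] = []

    for site in planted_sites:
        products = [
            (1, ProteinRecord(protein.id, protein.subsequence(1, site))),
            (site + 1, ProteinRecord(protein.id, protein.subsequence(site + 1, len(protein)))),
        ]
        for offset, product in products:
            for protease in proteases:
                for pm in digest(
                    product, protease, "full", 0, length_range
                ):
                    if rng.random() > detection_probability:
                        continue
                    table.append(
                        PeptideMatch(
                            protein.id,
                            pm.start + offset - 1,
                            pm.end + offset - 1,
                            pm.peptide,
                            protease.name,
                        )
                    )

    decoys: list[PeptideMatch] = []
    n_decoys = rng.binomial(max(len(table), 1), decoy_rate) if decoy_rate else 0
    lo, hi = length_range
    planted = set(planted_sites)
    attempts = 0
    while len(decoys) < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        length = int(rng.integers(lo, min(hi, len(protein)) + 1))
        start = int(rng.integers(1, len(protein) - length + 2))
        end = start + length - 1
        protease = proteases[int(rng.integers(len(proteases)))]
        pm = PeptideMatch(
            protein.id, start, end, protein.subsequence(start, end), protease.name
        )
        n_lab, c_lab = classify_termini(pm, protein, protease)
        # a useful decoy carries a spurious non-canonical terminus at a
        # position that is NOT a planted site
        sites = []
        if n_lab is TerminusLabel.NON_CANONICAL:
            sites.append(start - 1)
        if c_lab is TerminusLabel.NON_CANONICAL:
            sites.append(end)
        if sites and not any(s in planted for s in sites):
            decoys.append(pm)
    table = table + decoys
    order = rng.permutation(len(table))
    table = [table[i] for i in order]
    truth = {"planted_sites": sorted(planted_sites), "decoys": decoys}
    return table, truth


def predicted_intensity(series: str, index: int, peptide_length: int) -> float:
    """Positional intensity heuristic for "predicted" spectra.

    Mid-sequence y-ions are most intense, b-ions weaker; purely a smooth,
    deterministic stand-in for a learned predictor (non-physical).
    """
    frac = index / peptide_length
    base = math.sin(math.pi * frac) + 0.1
    return (1.0 if series == "y" else 0.55) * base * 1000.0


def simulate_spectrum_pair(
    peptide: str,
    noise_sd: float = 0.0,
    dropout: float = 0.0,
    charges: int = 2,
    mz_jitter: float = 0.0,
    n_background_peaks: int = 0,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum]:
    """An (acquired, predicted) spectrum pair for one peptide.

    The predicted spectrum is the noiseless heuristic intensity at the
    theoretical m/z of every b/y ion up to ``charges``. The acquired
    spectrum multiplies each intensity by exp(N(0, noise_sd)), drops each
    peak with probability ``dropout``, jitters m/z uniformly within
    ``±mz_jitter`` (Th) and appends ``n_background_peaks`` uniform noise
    peaks.
    """
    if not (0 <= dropout <= 1):
        raise ValueError("dropout must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ions = theoretical_fragments(peptide, charges)
    n = len(peptide)

    pred_peaks = []
    acq_peaks = []
    for ion in ions:
        inten = predicted_intensity(ion.series, ion.index, n) / ion.charge
        pred_peaks.append(Peak(ion.mz, inten))
        if rng.random() < dropout:
            continue
        noisy = inten * math.exp(rng.normal(0.0, noise_sd)) if noise_sd else inten
        mz = ion.mz + (rng.uniform(-mz_jitter, mz_jitter) if mz_jitter else 0.0)
        acq_peaks.append(Peak(mz, noisy))
    if n_background_peaks:
        lo = min(p.mz for p in pred_peaks)
        hi = max(p.mz for p in pred_peaks)
        for _ in range(n_background_peaks):
            acq_peaks.append(
                Peak(rng.uniform(lo, hi), rng.uniform(1.0, 100.0))
            )

    predicted = Spectrum(pred_peaks, charges, peptide, "predicted")
    acquired = Spectrum(acq_peaks, charges, peptide, "acquired")
    return acquired, predicted


@dataclass
class ProteomeTruth:
    shifted_proteins: list[str]
    effect_size: float


def simulate_proteome(
    n_proteins: int = 1000,
    n_per_group: int = 3,
    effect_size: float = 0.0,
    n_shifted: int = 0,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    within_sd: float = 0.3,
    mnar_midpoint: float = 22.0,
    mnar_steepness: float = 1.2,
    missing: bool = True,
    seed: int = 0,
):
    """Two-group LFQ matrix with MNAR missingness and a shifted subset.

    Per-protein true log2 abundance ~ N(base_mean, base_sd^2); replicate
    noise N(0, within_sd^2). The first ``n_shifted`` proteins are raised by
    ``effect_size`` log2 units in group A. Each cell goes missing with
    probability sigmoid(-(value - mnar_midpoint) * mnar_steepness), i.e.
    low-intensity cells vanish preferentially.

    Returns (IntensityMatrix, ProteomeTruth).
    """
    from .proteome import IntensityMatrix

    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    samples = [f"A{j+1}" for j in range(n_per_group)] + [
        f"B{j+1}" for j in range(n_per_group)
    ]
    groups = {s: s[0] for s in samples}

    base = rng.normal(base_mean, base_sd, n_proteins)
    values = np.empty((n_proteins, 2 * n_per_group))
    for j in range(2 * n_per_group):
        mu = base.copy()
        if j < n_per_group and n_shifted:
            mu[:n_shifted] += effect_size
        values[:, j] = mu + rng.normal(0.0, within_sd, n_proteins)

    if missing:
        p_missing = 1.0 / (1.0 + np.exp((values - mnar_midpoint) * mnar_steepness))
        mask = rng.random(values.shape) < p_missing
        values = np.where(mask, np.nan, values)

    frame = pd.DataFrame(values, index=proteins, columns=samples)
    truth = ProteomeTruth(proteins[:n_shifted], effect_size)
    return IntensityMatrix(frame, groups), truth


def simulate_plate(
    shed_fractions: dict[str, float],
    control_condition: str,
    n_wells: int = 4,
    total_fluorescence: float = 10000.0,
    background: float = 500.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PlateMeasurement, dict]:
    """Shedding plate with known true shed fraction per condition.

    A condition with shed fraction f places f of the total signal in the
    supernatant and 1-f on the cells, so its true corrected ratio is
    f/(1-f). Background is added to every well and recorded for the blank;
    ``gain`` scales everything (ratios must be invariant to it).
    """
    rng = np.random.default_rng(seed)
    wells = []
    truth = {}
    for cond, f in shed_fractions.items():
        if not (0 <= f < 1):
            raise ValueError("shed fraction must be in [0, 1)")
        truth[cond] = f / (1 - f)
        for compartment, signal in (
            ("supernatant", f * total_fluorescence),
            ("cell", (1 - f) * total_fluorescence),
        ):
            for _ in range(n_wells):
                value = signal + background
                if noise_sd:
                    value += rng.normal(0.0, noise_sd)
                wells.append(Well(cond, compartment, max(gain * value, 0.0)))
    plate = PlateMeasurement(
        wells,
        {"supernatant": gain * background, "cell": gain * background},
    )
    ctrl = truth[control_condition]
    normalized_truth = {c: (r / ctrl if ctrl else np.nan) for c, r in truth.items()}
    return plate, {"ratio": truth, "normalized_ratio": normalized_truth}


def simulate_fret_trace(
    n_points: int = 120,
    ligand_index: int = 30,
    stimulus_index: int = 90,
    bleed_through: float = 0.3,
    background: float = 50.0,
    baseline_ratio: float = 1.0,
    plateau_ratio: float = 2.0,
    response_fraction: float = 0.7,
    donor_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FretTrace, dict]:
    """FRET trace with known 0 % / 100 % anchors and bleed-through.

    The underlying corrected donor/acceptor ratio is ``baseline_ratio``
    before ligand addition, steps to an intermediate level covering
    ``response_fraction`` of the dynamic range after the ligand, and to
    ``plateau_ratio`` after the saturating stimulus. Channels are then
    re-encoded with the stated bleed-through and additive background so the
    correction has real work to undo.

    Ground truth is the normalized percent series.
    """
    rng = np.random.default_rng(seed)
    true_ratio = np.full(n_points, baseline_ratio, float)
    mid = baseline_ratio + response_fraction * (plateau_ratio - baseline_ratio)
    true_ratio[ligand_index:stimulus_index] = mid
    true_ratio[stimulus_index:] = plateau_ratio
    if noise_sd:
        true_ratio = true_ratio + rng.normal(0.0, noise_sd, n_points)

    donor = np.full(n_points, donor_level, float)
    acceptor_clean = donor / true_ratio
    # re-encode: add donor bleed-through into the acceptor channel, then
    # additive background on both raw channels
    acceptor_raw = acceptor_clean + bleed_through * donor + background
    donor_raw = donor + background

    trace = FretTrace(
        np.arange(n_points, dtype=float),
        donor_raw,
        acceptor_raw,
        {"donor": background, "acceptor": background},
        bleed_through,
        ligand_index,
        stimulus_index,
    )
    span = plateau_ratio - baseline_ratio
    normalized_truth = (
        (true_ratio - baseline_ratio) / span * 100.0
        if span != 0
        else np.full(n_points, np.nan)
    )
    return trace, {"normalized_percent": normalized_truth, "ratio": true_ratio}


def simulate_dose_response(
    bottom: float,
    top: float,
    log_ec50: float,
    concentrations=None,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Responses from a three-parameter logistic with additive noise.

    ``n_replicates`` repeats every concentration (independent noise per
    replicate), emulating pooled wells/experiments fitted jointly.
    """
    from .assays import three_param_logistic

    if concentrations is None:
        concentrations = np.logspace(-11, -5, 8)
    conc = np.repeat(np.asarray(concentrations, float), n_replicates)
    rng = np.random.default_rng(seed)
    resp = three_param_logistic(conc, bottom, top, log_ec50)
    if noise_sd:
        resp = resp + rng.normal(0.0, noise_sd, conc.shape)
    return conc, resp
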