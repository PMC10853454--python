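"""Theoretical b/y fragment ions, peak matching and charge deconvolution.

Fragment m/z values are monoisotopic: a b-ion is the sum of its residue
masses plus ``z`` protons over ``z``; a y-ion additionally carries one water.
Acquired and predicted peak lists are matched ion-by-ion within a Da or ppm
tolerance (closest peak wins, each peak assigned at most once), then the
intensities of the same fragment observed at different charge states are
summed into a single per-fragment value ("charge deconvolution") before any
similarity scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .proteolysis import InvalidResidueError

PROTON = 1.007276
WATER = 18.010565

# Monoisotopic residue (amino-acid minus water) masses.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class Spectrum:
    """A peak list, kept sorted by m/z."""

    peaks: list[Peak]
    precursor_charge: int = 1
    peptide: str | None = None
    label: str = ""

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")

    @classmethod
    def from_arrays(
        cls,
        mz: Iterable[float],
        intensity: Iterable[float],
        **kwargs,
    ) -> "Spectrum":
        return cls([Peak(m, i) for m, i in zip(mz, intensity)], **kwargs)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment (b or y series)."""

    series: str  # "b" | "y"
    index: int
    charge: int
    mz: float

    @property
    def label(self) -> str:
        """Charge-independent fragment label, e.g. ``y3``."""
        return f"{self.series}{self.index}"


def peptide_neutral_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of an unmodified peptide."""
    total = WATER
    for i, aa in enumerate(peptide, start=1):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise InvalidResidueError(aa, i) from None
    return total


def theoretical_fragments(peptide: str, max_charge: int = 1) -> list[FragmentIon]:
    """All b_i / y_i ions for i in [1, len-1] at charges 1..max_charge."""
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have at least 2 residues")
    for i, aa in enumerate(peptide, start=1):
        if aa not in RESIDUE_MASS:
            raise InvalidResidueError(aa, i)

    prefix = [0.0]
    for aa in peptide:
        prefix.append(prefix[-1] + RESIDUE_MASS[aa])
    total = prefix[-1]

    ions = []
    for i in range(1, n):
        b_neutral = prefix[i]
        y_neutral = total - prefix[n - i] + WATER
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", i, z, (y_neutral + z * PROTON) / z))
    return ions


def _tolerance_da(mz: float, tolerance: float, unit: str) -> float:
    if unit == "Da":
        return tolerance
    if unit == "ppm":
        return mz * tolerance * 1e-6
    raise ValueError(f"unknown tolerance unit {unit!r}")


def match_peaks(
    spectrum: Spectrum,
    ions: list[FragmentIon],
    tolerance: float = 20.0,
    unit: str = "ppm",
) -> dict[FragmentIon, float]:
    """Greedy nearest assignment of peaks to theoretical ions.

    Ion–peak candidate pairs within tolerance are assigned globally closest
    first (ties broken toward lower peak m/z), each peak and each ion used at
    most once. Unmatched ions get intensity 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    candidates = []
    for ion_idx, ion in enumerate(ions):
        tol = _tolerance_da(ion.mz, tolerance, unit)
        for peak_idx, peak in enumerate(spectrum.peaks):
            delta = abs(peak.mz - ion.mz)
            if delta <= tol:
                candidates.append((delta, peak.mz, ion_idx, peak_idx))
    candidates.sort()

    matched: dict[FragmentIon, float] = {ion: 0.0 for ion in ions}
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    for _, _, ion_idx, peak_idx in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        matched[ions[ion_idx]] = spectrum.peaks[peak_idx].intensity
    return matched


def charge_deconvolute(per_ion: Mapping[FragmentIon, float]) -> dict[str, float]:
    """Sum intensities of the same fragment label over charge states."""
    out: dict[str, float] = {}
    for ion, intensity in per_ion.items():
        if intensity < 0:
            raise ValueError("intensities must be non-negative")
        out[ion.label] = out.get(ion.label, 0.0) + intensity
    return out


@dataclass
class MatchedFragmentSet:
    """Charge-deconvoluted acquired/predicted intensities per fragment label.

    Only labels with positive intensity in *both* spectra are retained —
    these are the "matching fragment peaks" a similarity score is computed
    from. ``mz_z1`` (the singly-charged m/z of each label) is kept for
    deterministic tie-breaking when ranking.
    """

    acquired: dict[str, float]
    predicted: dict[str, float]
    mz_z1: dict[str, float]
    tolerance: float = 20.0
    unit: str = "ppm"
    labels: list[str] = field(init=False)

    def __post_init__(self):
        common = [
            lab
            for lab in self.predicted
            if self.acquired.get(lab, 0.0) > 0 and self.predicted[lab] > 0
        ]
        common.sort(key=lambda lab: self.mz_z1[lab])
        self.labels = common

    def vectors(self, labels: list[str] | None = None):
        labs = self.labels if labels is None else labels
        a = [self.acquired[lab] for lab in labs]
        p = [self.predicted[lab] for lab in labs]
        return a, p

    def __len__(self) -> int:
        return len(self.labels)


def match_fragments(
    acquired: Spectrum,
    predicted: Spectrum,
    peptide: str,
    max_charge: int = 2,
    tolerance: float = 20.0,
    unit: str = "ppm",
) -> MatchedFragmentSet:
    """Full matching pipeline for one acquired/predicted spectrum pair.

    Both spectra are matched per charge state against the same theoretical
    ion ladder, then charge-deconvoluted symmetrically.
    """
    ions = theoretical_fragments(peptide, max_charge)
    acq = charge_deconvolute(match_peaks(acquired, ions, tolerance, unit))
    pred = charge_deconvolute(match_peaks(predicted, ions, tolerance, unit))
    mz_z1 = {ion.label: ion.mz for ion in ions if ion.charge == 1}
    return MatchedFragmentSet(acq, pred, mz_z1, tolerance, unit)
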