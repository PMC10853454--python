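"""Spectrum contrast angle (SCA) and its bootstrap stability.

The SCA treats two fragment-intensity vectors as directions in the positive
orthant and scores the angle between them, rescaled to [0, 1]:

    SCA = 1 - 2*theta/pi,   theta = arccos( a.b / (|a| |b|) )

so identical (parallel) spectra score 1 and spectra with no shared signal
(orthogonal vectors) score 0. The score is computed from the K most intense
matching fragments (ranked by predicted intensity; K = 8 by default), and
its stability is assessed by bootstrap resampling of those fragment pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fragments import MatchedFragmentSet

DEFAULT_TOP_K = 8
DEFAULT_N_BOOT = 20


class NoMatchedFragmentsError(ValueError):
    """Acquired and predicted spectra share no fragment labels."""


def spectrum_contrast_angle(a, b) -> float:
    """Normalized spectral contrast angle between two intensity vectors.

    Both vectors must be non-negative, equal-length and not all-zero.
    Returns a value in [0, 1]; symmetric and invariant to positive scaling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("intensities must be non-negative")
    na = math.sqrt(float(a @ a))
    nb = math.sqrt(float(b @ b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("SCA undefined for an all-zero intensity vector")
    if float(a @ b) == 0.0:
        # non-negative vectors are orthogonal iff their supports are
        # disjoint: absolute disagreement, exactly 0
        return 0.0
    # angle from the chord between unit vectors: theta = 2*asin(|u - v|/2).
    # Non-negative inputs keep theta <= pi/2, where this form is
    # well-conditioned and hits the 0 and pi/2 endpoints exactly.
    chord = float(np.linalg.norm(a / na - b / nb))
    theta = 2.0 * math.asin(min(1.0, chord / 2.0))
    return min(1.0, max(0.0, 1.0 - 2.0 * theta / math.pi))


def select_top_k(matched: MatchedFragmentSet, k: int = DEFAULT_TOP_K) -> list[str]:
    """Labels of the k most intense matched fragments (predicted spectrum).

    Ties in predicted intensity are broken toward the lower singly-charged
    m/z, making the selection deterministic. Fewer than k matches simply
    returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(matched) == 0:
        raise NoMatchedFragmentsError(
            "no fragment label is present in both acquired and predicted spectra"
        )
    ranked = sorted(
        matched.labels, key=lambda lab: (-matched.predicted[lab], matched.mz_z1[lab])
    )
    return ranked[:k]


@dataclass
class SCAResult:
    """Point SCA on the top-k fragments plus a bootstrap distribution."""

    sca: float
    k_used: int
    bootstrap_values: list[float]
    n_boot: int
    seed: int
    labels: list[str] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.bootstrap_values))

    @property
    def q1(self) -> float:
        return float(np.percentile(self.bootstrap_values, 25))

    @property
    def q3(self) -> float:
        return float(np.percentile(self.bootstrap_values, 75))

    def to_dict(self) -> dict:
        return {
            "sca": self.sca,
            "k_used": self.k_used,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "values": list(self.bootstrap_values),
            "labels": list(self.labels),
        }


def bootstrap_sca(
    matched: MatchedFragmentSet,
    k: int = DEFAULT_TOP_K,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    max_retries: int = 100,
) -> SCAResult:
    """SCA on the top-k matched fragments with bootstrap resampling.

    Each replicate resamples the k (acquired, predicted) fragment pairs with
    replacement and recomputes the SCA; a degenerate resample (an all-zero
    vector, impossible here since retained pairs are positive in both
    spectra, but guarded anyway) is redrawn up to ``max_retries`` times.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = select_top_k(matched, k)
    acq, pred = matched.vectors(labels)
    acq = np.asarray(acq)
    pred = np.asarray(pred)
    point = spectrum_contrast_angle(acq, pred)

    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        for _attempt in range(max_retries):
            idx = rng.integers(0, len(labels), size=len(labels))
            ra, rp = acq[idx], pred[idx]
            if ra.any() and rp.any():
                values.append(spectrum_contrast_angle(ra, rp))
                break
        else:
            raise RuntimeError("bootstrap resample degenerate after retries")
    return SCAResult(point, len(labels), values, n_boot, seed, labels)
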