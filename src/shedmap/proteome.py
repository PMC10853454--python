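"""Label-free proteome comparison statistics.

The stages mirror the standard LFQ workflow for DIA report tables: filter
identifications on q-values / mass evidence / charge, log2-transform,
impute missing values from a down-shifted normal distribution (missingness
in LFQ is intensity-dependent, so missing cells are drawn from a narrow
distribution centred below the observed intensities), test per protein with
a two-sample t test, control FDR with Benjamini-Hochberg, classify a volcano
plot, and z-score per-protein median profiles for a heatmap.

The volcano significance cut defaults to log2FC >= 2 with adjusted P < 0.5.
An adjusted-P threshold of 0.5 is far more permissive than the conventional
0.05; it is kept as the default deliberately (see docs) and is a plain
parameter to override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_REPORT_COLUMNS = (
    "q_value",
    "protein_q_value",
    "mass_evidence",
    "precursor_charge",
)


def filter_report(records: pd.DataFrame) -> pd.DataFrame:
    """Filter a DIA report table on identification confidence.

    Keeps rows with q_value <= 0.01, protein_q_value <= 0.01,
    mass_evidence > 0.5 and precursor_charge > 1 (all four must hold);
    row order is preserved.
    """
    for col in REQUIRED_REPORT_COLUMNS:
        if col not in records.columns:
            raise KeyError(f"missing required column {col!r}")
    keep = (
        (records["q_value"] <= 0.01)
        & (records["protein_q_value"] <= 0.01)
        & (records["mass_evidence"] > 0.5)
        & (records["precursor_charge"] > 1)
    )
    return records.loc[keep]


@dataclass
class IntensityMatrix:
    """Protein x sample log2 intensities with an explicit missingness mask.

    ``values`` is a DataFrame (proteins as rows, samples as columns) with
    NaN for missing cells; ``groups`` maps each sample id to its group
    label.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self):
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask (True = measured)."""
        return self.values.notna()

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


def impute_missing(
    matrix: IntensityMatrix,
    width_factor: float = 0.25,
    shift_sd: float = 1.8,
    seed: int = 0,
    per_column: bool = True,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Down-shifted-normal imputation of missing log2 intensities.

    Each missing cell is drawn from Normal(mu - shift_sd*sigma,
    (width_factor*sigma)^2) where mu and sigma are the mean and SD of the
    observed values — per sample column by default (the Perseus
    convention), or globally with ``per_column=False``. Observed cells are
    never altered. Returns the completed matrix and the imputation mask
    (True where a value was drawn).
    """
    values = matrix.values.copy()
    rng = np.random.default_rng(seed)
    imputed_mask = values.isna()
    if not imputed_mask.to_numpy().any():
        return IntensityMatrix(values, dict(matrix.groups)), imputed_mask

    def fill(col: pd.Series, mu: float, sigma: float) -> pd.Series:
        miss = col.isna()
        draws = rng.normal(mu - shift_sd * sigma, width_factor * sigma, miss.sum())
        col = col.copy()
        col[miss] = draws
        return col

    if per_column:
        for c in values.columns:
            obs = values[c].dropna()
            if len(obs) < 2:
                raise ValueError(
                    f"column {c!r} has fewer than 2 observed values; "
                    "cannot define an imputation distribution"
                )
            values[c] = fill(values[c], obs.mean(), obs.std(ddof=1))
    else:
        obs = values.to_numpy().ravel()
        obs = obs[~np.isnan(obs)]
        if obs.size < 2:
            raise ValueError("fewer than 2 observed values in the whole matrix")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        for c in values.columns:
            values[c] = fill(values[c], mu, sigma)

    return IntensityMatrix(values, dict(matrix.groups)), imputed_mask


class VolcanoClass(str, Enum):
    UP_A = "up_A"
    UP_B = "up_B"
    NOT_SIGNIFICANT = "not_significant"


@dataclass
class DifferentialResult:
    protein_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    flat: bool = False  # zero variance in both groups with equal means
    volcano_class: VolcanoClass = VolcanoClass.NOT_SIGNIFICANT


def differential_test(
    matrix: IntensityMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Per-protein two-sample t test between two groups, BH-corrected.

    Welch's unequal-variance t test by default (``equal_var=True`` for
    Student's). log2 fold change is mean(A) - mean(B). Proteins with zero
    variance and equal means in both groups get p = 1 by convention and are
    flagged.
    """
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix.values[cols_a].to_numpy()
    b = matrix.values[cols_b].to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix must be complete (impute first)")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    flat = np.isnan(pvals)
    pvals = np.where(flat, 1.0, pvals)

    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        DifferentialResult(pid, float(l), float(p), float(q), bool(f))
        for pid, l, p, q, f in zip(matrix.values.index, lfc, pvals, adj, flat)
    ]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (exposed for direct use on raw p lists)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def classify_volcano(
    results: list[DifferentialResult],
    lfc_cut: float = 2.0,
    p_cut: float = 0.5,
) -> list[DifferentialResult]:
    """Assign volcano classes in place and return the list.

    up_A: log2FC >= lfc_cut and adjusted p < p_cut; up_B mirrored at
    -lfc_cut; everything else not_significant.
    """
    for r in results:
        if r.adjusted_p < p_cut and r.log2_fold_change >= lfc_cut:
            r.volcano_class = VolcanoClass.UP_A
        elif r.adjusted_p < p_cut and r.log2_fold_change <= -lfc_cut:
            r.volcano_class = VolcanoClass.UP_B
        else:
            r.volcano_class = VolcanoClass.NOT_SIGNIFICANT
    return results


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein_id for r in results],
            "log2fc": [r.log2_fold_change for r in results],
            "p": [r.p_value for r in results],
            "adj_p": [r.adjusted_p for r in results],
            "class": [r.volcano_class.value for r in results],
        }
    )


def zscore_profiles(
    matrix: IntensityMatrix,
    ddof: int = 0,
    proteins: list[str] | None = None,
) -> pd.DataFrame:
    """Median-per-condition profile of each protein, row z-scored.

    Replicate columns are collapsed to their median per group/condition,
    then each protein row is centred and scaled to unit SD across
    conditions (population SD by default; ``ddof=1`` for sample SD).
    Constant rows are returned as all zeros.
    """
    conditions = sorted(set(matrix.groups.values()))
    med = pd.DataFrame(
        {
            cond: matrix.values[matrix.samples_in(cond)].median(axis=1)
            for cond in conditions
        }
    )
    if proteins is not None:
        med = med.loc[proteins]
    arr = med.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mean) / sd, 0.0)
    return pd.DataFrame(z, index=med.index, columns=med.columns)
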