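"""Report filtering, imputation, differential testing and profiles."""

import numpy as np
import pandas as pd
import pytest

import shedmap as sm
from shedmap.proteome import IntensityMatrix, results_frame
from shedmap.simulate import simulate_proteome


def small_matrix(values, groups=None):
    frame = pd.DataFrame(
        values,
        index=[f"P{i}" for i in range(len(values))],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"][: len(values[0])],
    )
    groups = groups or {c: c[0] for c in frame.columns}
    return IntensityMatrix(frame, groups)


class TestFilterReport:
    @pytest.mark.parametrize(
        "q,pq,ev,z,kept",
        [
            (0.02, 0.001, 0.9, 2, False),  # q-value too high
            (0.01, 0.01, 0.51, 2, True),   # boundary semantics: <= and >
            (0.001, 0.001, 0.9, 1, False),  # charge must exceed 1
            (0.001, 0.001, 0.5, 2, False),  # mass evidence must exceed 0.5
        ],
    )
    def test_boundary_semantics(self, q, pq, ev, z, kept):
        frame = pd.DataFrame(
            {"q_value": [q], "protein_q_value": [pq], "mass_evidence": [ev],
             "precursor_charge": [z]}
        )
        assert (len(sm.filter_report(frame)) == 1) is kept

    def test_order_preserved_and_missing_column(self):
        frame = pd.DataFrame(
            {"q_value": [0.001, 0.5, 0.002], "protein_q_value": [0.001] * 3,
             "mass_evidence": [0.9] * 3, "precursor_charge": [2] * 3}
        )
        assert list(sm.filter_report(frame).index) == [0, 2]
        with pytest.raises(KeyError, match="mass_evidence"):
            sm.filter_report(frame.drop(columns="mass_evidence"))


class TestImputation:
    def test_complete_matrix_unchanged(self):
        matrix = small_matrix(np.arange(12.0).reshape(2, 6) + 20)
        completed, mask = sm.impute_missing(matrix, seed=0)
        pd.testing.assert_frame_equal(completed.values, matrix.values)
        assert not mask.to_numpy().any()

    def test_observed_cells_never_touched(self, rng):
        matrix, _ = simulate_proteome(n_proteins=200, seed=5)
        completed, mask = sm.impute_missing(matrix, seed=1)
        observed = matrix.mask
        assert completed.values.where(observed).equals(matrix.values.where(observed))
        assert (mask == ~observed).all().all()

    def test_distributional_recovery(self, rng):
        """Imputed draws recover mean - 1.8 SD and 0.25 SD within 3 SE."""
        n_obs, n_missing = 4000, 10000
        observed = rng.normal(25.0, 2.0, n_obs)
        column = np.concatenate([observed, np.full(n_missing, np.nan)])
        frame = pd.DataFrame({"S1": column, "S2": np.full_like(column, 24.0)})
        matrix = IntensityMatrix(frame, {"S1": "A", "S2": "B"})
        completed, _ = sm.impute_missing(matrix, seed=7)
        draws = completed.values["S1"].to_numpy()[n_obs:]
        mu, sigma = observed.mean(), observed.std(ddof=1)
        target_mean, target_sd = mu - 1.8 * sigma, 0.25 * sigma
        se_mean = target_sd / np.sqrt(n_missing)
        se_sd = target_sd / np.sqrt(2 * (n_missing - 1))
        assert abs(draws.mean() - target_mean) < 3 * se_mean
        assert abs(draws.std(ddof=1) - target_sd) < 3 * se_sd

    def test_seeded_determinism(self):
        matrix, _ = simulate_proteome(n_proteins=100, seed=2)
        c1, _ = sm.impute_missing(matrix, seed=9)
        c2, _ = sm.impute_missing(matrix, seed=9)
        pd.testing.assert_frame_equal(c1.values, c2.values)

    def test_all_missing_rejected(self):
        frame = pd.DataFrame({"S1": [np.nan, np.nan], "S2": [np.nan, np.nan]})
        matrix = IntensityMatrix(frame, {"S1": "A", "S2": "B"})
        with pytest.raises(ValueError):
            sm.impute_missing(matrix, seed=0)


def bh_step_up(pvalues):
    """Closed-form BH: min over j >= i of p_(j) * m / j, capped at 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


class TestDifferentialTest:
    def test_identical_groups_null_result(self):
        matrix = small_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        (res,) = sm.differential_test(matrix, "A", "B")
        assert res.p_value == pytest.approx(1.0)
        assert res.log2_fold_change == 0.0

    def test_flat_protein_flagged(self):
        matrix = small_matrix(
            [[5.0, 5.0, 5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]
        )
        flat, other = sm.differential_test(matrix, "A", "B")
        assert flat.flat and flat.p_value == 1.0
        assert not other.flat

    def test_bh_against_closed_form(self):
        """BH adjustment equals the step-up formula on enumerated vectors."""
        cases = [
            [0.01, 0.02, 0.03, 0.04],
            [0.5],
            [0.04, 0.04, 0.04],
            [0.9, 0.001, 0.5, 0.02, 0.02, 0.3],
            [1.0, 0.0, 0.5],
        ]
        for p in cases:
            np.testing.assert_allclose(sm.benjamini_hochberg(p), bh_step_up(p))
        # worked example: all four adjust to 0.04
        np.testing.assert_allclose(
            sm.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_bh_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        adj = sm.benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)

    def test_null_type_i_calibration(self):
        """Student t on equal-variance null data rejects at ~5%."""
        total, hits = 0, 0
        for seed in range(5):
            matrix, _ = simulate_proteome(
                n_proteins=1000, missing=False, seed=seed
            )
            results = sm.differential_test(matrix, "A", "B", equal_var=True)
            hits += sum(r.p_value < 0.05 for r in results)
            total += len(results)
        rate = hits / total
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < half_width


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,adj_p,expected",
        [
            (2.5, 0.01, "up_A"),
            (1.9, 0.001, "not_significant"),
            (-3.0, 0.4, "up_B"),
            (3.0, 0.6, "not_significant"),
            (2.0, 0.499, "up_A"),  # boundary: >= lfc cut, < p cut
        ],
    )
    def test_classes(self, lfc, adj_p, expected):
        res = sm.DifferentialResult("P", lfc, 0.01, adj_p)
        sm.classify_volcano([res])
        assert res.volcano_class.value == expected

    def test_row_order_invariance(self, rng):
        results = [
            sm.DifferentialResult(f"P{i}", float(l), 0.01, float(q))
            for i, (l, q) in enumerate(
                zip(rng.normal(0, 3, 40), rng.uniform(0, 1, 40))
            )
        ]
        sm.classify_volcano(results)
        by_id = {r.protein_id: r.volcano_class for r in results}
        shuffled = [results[i] for i in rng.permutation(40)]
        sm.classify_volcano(shuffled)
        assert all(by_id[r.protein_id] == r.volcano_class for r in shuffled)


class TestZScoreProfiles:
    def test_arithmetic_sequence_closed_form(self):
        matrix = small_matrix([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]],
                              groups={"A1": "c1", "A2": "c1", "A3": "c2",
                                      "B1": "c2", "B2": "c3", "B3": "c3"})
        z = sm.zscore_profiles(matrix)
        np.testing.assert_allclose(
            z.iloc[0].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_row_all_zero(self):
        matrix = small_matrix([[4.0] * 6])
        assert (sm.zscore_profiles(matrix).iloc[0] == 0).all()

    def test_rows_standardized(self, rng):
        matrix, _ = simulate_proteome(n_proteins=30, missing=False, seed=3)
        z = sm.zscore_profiles(matrix).to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)
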