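import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunodyn.errors import ValidationError
from immunodyn.expression_scoring import (
    ExpressionMatrix,
    GeneSignature,
    RAW_COUNTS,
    TPM,
    compare_groups,
    load_signatures,
    longitudinal_signature_model,
    normalize_panel_counts,
    ssgsea_scores,
    zscore_genes,
)
from immunodyn.reference import ssgsea_naive
from immunodyn.synthetic_data import simulate_expression_cohort


def matrix_from(arr, genes=None, samples=None, kind=TPM):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), kind)


SIG = GeneSignature("toy", ("G0", "G2"))


class TestSsgsea:
    def test_identical_profiles_identical_scores(self):
        m = matrix_from(np.tile([[5.0], [1.0], [3.0], [2.0], [4.0]], (1, 3)))
        res = ssgsea_scores(m, SIG, normalize=False)
        assert res.scores.nunique() == 1

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2, 20, (30, 4))
        a = ssgsea_scores(matrix_from(x), SIG, normalize=False).scores
        b = ssgsea_scores(matrix_from(np.log1p(x) ** 2), SIG,
                          normalize=False).scores
        assert np.allclose(a, b)

    def test_matches_naive_reference_small_instance(self):
        m = matrix_from([[10.0], [8.0], [6.0], [4.0], [2.0]])
        res = ssgsea_scores(m, SIG, normalize=False)
        ref = ssgsea_naive(m.values.iloc[:, 0].to_numpy(),
                           m.values.index.isin(SIG.gene_symbols))
        assert res.scores.iloc[0] == pytest.approx(ref, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_matches_naive_reference_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        ng, ns = int(rng.integers(5, 50)), int(rng.integers(1, 5))
        vals = rng.gamma(2.0, 30.0, (ng, ns)).round(int(rng.integers(0, 3)))
        vals += 0.01  # keep strictly positive after rounding
        k = int(rng.integers(2, max(3, ng // 2)))
        genes = [f"G{i}" for i in range(ng)]
        sig = GeneSignature("r", tuple(rng.choice(genes, size=k, replace=False)))
        m = matrix_from(vals, genes=genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ssgsea_scores(m, sig, normalize=False)
        in_set = m.values.index.isin(sig.gene_symbols)
        for j, s in enumerate(m.sample_ids):
            ref = ssgsea_naive(vals[:, j], in_set)
            assert res.scores[s] == pytest.approx(ref, abs=1e-10)

    def test_normalization_divides_by_score_range(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.gamma(2, 30, (20, 5)))
        raw = ssgsea_scores(m, SIG, normalize=False).scores
        norm = ssgsea_scores(m, SIG, normalize=True).scores
        assert np.allclose(norm, raw / (raw.max() - raw.min()))

    def test_missing_signature_genes_error_lists_symbols(self):
        m = matrix_from(np.ones((4, 2)) + np.arange(4)[:, None])
        sig = GeneSignature("x", ("G0", "NOPE1", "NOPE2"))
        with pytest.raises(ValidationError, match="NOPE1"):
            ssgsea_scores(m, sig)

    def test_case_insensitive_gene_matching(self):
        m = matrix_from([[5.0], [1.0], [3.0]], genes=["TIGIT", "Cd27", "STAT1"])
        sig = GeneSignature("s", ("tigit", "CD27"))
        res = ssgsea_scores(m, sig, normalize=False)
        assert res.fraction_genes_found == 1.0

    def test_bundled_signature_has_18_genes(self):
        sigs = load_signatures()
        assert len(sigs["TIS"].gene_symbols) == 18


class TestZscoreGenes:
    def test_population_sd_convention(self):
        z = zscore_genes(matrix_from([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        assert z.values.iloc[0].to_numpy() == pytest.approx(
            [-1.224745, 0.0, 1.224745], abs=1e-6
        )

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_genes(matrix_from([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        assert (z.values.iloc[1] == 0).all()

    def test_row_means_zero(self):
        rng = np.random.default_rng(1)
        z = zscore_genes(matrix_from(rng.gamma(2, 10, (10, 6))))
        assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            zscore_genes(matrix_from([[1.0], [2.0]]))


class TestCompareGroups:
    def test_identical_multisets_give_p_one(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        labels = pd.Series(list("AAABBB"), index=list("abcdef"))
        assert compare_groups(scores, labels).p_value == pytest.approx(1.0)

    def test_exact_rank_sum_example(self):
        # (1,2,3) vs (4,5,6): 2/C(6,3) = 0.1 two-sided
        scores = pd.Series([1, 2, 3, 4, 5, 6.0], index=list("abcdef"))
        labels = pd.Series(list("AAABBB"), index=list("abcdef"))
        res = compare_groups(scores, labels)
        assert res.p_value == pytest.approx(0.1)
        assert res.median_group_a == 2.0 and res.median_group_b == 5.0

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(0, 1, 12),
                           index=[f"s{i}" for i in range(12)])
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=scores.index)
        swapped = labels.map({"A": "B", "B": "A"})
        assert compare_groups(scores, labels).p_value == pytest.approx(
            compare_groups(scores, swapped).p_value
        )

    def test_empty_group_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            compare_groups(scores, pd.Series(["A", "A"], index=["a", "b"]))

    def test_power_and_null_calibration_on_synthetic_cohorts(self):
        sig = GeneSignature("s", tuple(f"SG{i}" for i in range(18)))
        rejections_null, rejections_strong = 0, 0
        n_reps = 60
        for rep in range(n_reps):
            for effect, counter in ((0.0, "null"), (2.0, "strong")):
                m, labels, _ = simulate_expression_cohort(
                    20, sig, effect_size=effect, seed=1000 + rep
                )
                scores = ssgsea_scores(m, sig)
                p = compare_groups(scores, labels).p_value
                if counter == "null":
                    rejections_null += p < 0.05
                else:
                    rejections_strong += p < 0.05
        # nominal 5% null rate within generous binomial bounds; near-full power
        assert rejections_null <= 9
        assert rejections_strong / n_reps > 0.9


class TestNormalizePanelCounts:
    def _raw(self):
        vals = pd.DataFrame(
            {
                "s1": [0.0, 0.0, 60.0, 40.0, 10.0],
                "s2": [0.0, 0.0, 250.0, 150.0, 80.0],
            },
            index=["NEG1", "NEG2", "HK1", "HK2", "G1"],
        )
        return ExpressionMatrix(vals, RAW_COUNTS)

    def test_zero_negatives_leave_counts_unchanged_before_scaling(self):
        out, excluded = normalize_panel_counts(
            self._raw(), ["NEG1", "NEG2"], ["HK1", "HK2"]
        )
        assert excluded == []
        # housekeeping sums equalized at the geometric mean of (100, 400) = 200
        hk = out.values.loc[["HK1", "HK2"]].sum(axis=0)
        assert np.allclose(hk, 200.0)
        # scale factors in ratio 4:1
        assert out.values.loc["G1", "s1"] / 10.0 == pytest.approx(
            4 * out.values.loc["G1", "s2"] / 80.0
        )

    def test_background_subtraction_floors_at_zero(self):
        vals = pd.DataFrame(
            {"s1": [50.0, 30.0, 100.0, 10.0]},
            index=["NEG1", "NEG2", "HK1", "G1"],
        )
        out, _ = normalize_panel_counts(
            ExpressionMatrix(vals, RAW_COUNTS), ["NEG1", "NEG2"], ["HK1"]
        )
        assert out.values.loc["G1", "s1"] == 0.0

    def test_zero_housekeeping_sample_excluded(self):
        vals = pd.DataFrame(
            {"good": [0.0, 100.0, 5.0], "bad": [10.0, 8.0, 5.0]},
            index=["NEG1", "HK1", "G1"],
        )
        with pytest.warns(UserWarning, match="bad"):
            out, excluded = normalize_panel_counts(
                ExpressionMatrix(vals, RAW_COUNTS), ["NEG1"], ["HK1"]
            )
        assert excluded == ["bad"]
        assert list(out.sample_ids) == ["good"]

    def test_wrong_value_kind_rejected(self):
        with pytest.raises(ValidationError):
            normalize_panel_counts(matrix_from(np.ones((3, 2))), ["G0"], ["G1"])


class TestLongitudinalModel:
    @staticmethod
    def _cohort(n_patients, shift, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_patients):
            base = rng.normal(0, 1)
            for visit, delta in (("C0D1", 0.0), ("C1D1", shift), ("C1D22", 0.0)):
                rows.append(
                    {
                        "patient_id": f"P{p}",
                        "visit": visit,
                        "score": base + delta + rng.normal(0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_visit_effect_calibrated(self):
        n_reps, rejections = 100, 0
        for rep in range(n_reps):
            res = longitudinal_signature_model(self._cohort(30, 0.0, rep))
            assert res.method == "lmm"
            rejections += res.lrt_p_value < 0.05
        # binomial(100, 0.05): P(X > 11) < 0.005
        assert rejections <= 11

    def test_shift_recovered_within_two_standard_errors(self):
        hits = 0
        n_reps = 30
        for rep in range(n_reps):
            res = longitudinal_signature_model(self._cohort(40, 1.0, 500 + rep))
            eff = res.effects.loc["C1D1"]
            hits += abs(eff["estimate"] - 1.0) <= 2 * eff["se"]
        assert hits / n_reps >= 0.9

    def test_single_patient_rejected(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1"] * 2,
                "visit": ["C0D1", "C1D1"],
                "score": [0.0, 1.0],
            }
        )
        with pytest.raises(ValidationError):
            longitudinal_signature_model(df)
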