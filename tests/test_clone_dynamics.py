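import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from immunodyn.clone_dynamics import (
    EXPANDED,
    CONTRACTED,
    bh_adjust,
    classify_dynamics,
    cohort_visit_comparison,
    fisher_clone_test,
    paired_signed_rank,
)
from immunodyn.errors import EmptySampleError, ValidationError
from immunodyn.reference import fisher_two_sided_exact
from immunodyn.repertoire_io import RepertoireSample, filter_productive
from immunodyn.synthetic_data import (
    ExpansionEvent,
    RepertoireSimSpec,
    simulate_longitudinal_repertoires,
)
from tests.conftest import make_sample


class TestFisherCloneTest:
    def test_identical_margins_give_p_one(self):
        assert fisher_clone_test(5, 100, 5, 100) == 1.0

    def test_small_table_matches_enumeration(self):
        # hypergeometric enumeration of [[3,7],[0,10]] gives 0.2105...
        p = fisher_clone_test(3, 10, 0, 10)
        assert p == pytest.approx(0.210526, abs=1e-6)
        assert p == pytest.approx(fisher_two_sided_exact(3, 10, 0, 10), abs=1e-12)

    def test_extreme_expansion_rejects_null(self):
        assert fisher_clone_test(0, 10_000, 500, 10_000) < 1e-50

    def test_enumeration_oracle_small_margins(self):
        """Exhaustive agreement with exact integer enumeration, margins <= 12."""
        for ta in range(1, 13):
            for tb in range(1, 13):
                for ka in range(ta + 1):
                    for kb in range(tb + 1):
                        assert fisher_clone_test(ka, ta, kb, tb) == pytest.approx(
                            fisher_two_sided_exact(ka, ta, kb, tb), abs=1e-10
                        )

    @given(st.data())
    @settings(max_examples=100)
    def test_agrees_with_scipy_cross_check(self, data):
        ta = data.draw(st.integers(1, 200))
        tb = data.draw(st.integers(1, 200))
        ka = data.draw(st.integers(0, ta))
        kb = data.draw(st.integers(0, tb))
        mine = fisher_clone_test(ka, ta, kb, tb)
        ref = fisher_exact([[ka, ta - ka], [kb, tb - kb]]).pvalue
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_count_above_total_rejected(self):
        with pytest.raises(ValidationError):
            fisher_clone_test(11, 10, 0, 10)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        # ranks 1..4, m=4: min over j>=i of p_j * 4/j, all 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty_input_empty_output(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100)
    def test_matches_hand_step_up_rule(self, ps):
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = running
        assert q == pytest.approx(expected, abs=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-15)


def _sim_pair(seed, expansions=(), n_clones=400, depth=5000):
    spec = RepertoireSimSpec(
        seed=seed, n_clones=n_clones, depth=depth,
        visits=("C0D1", "C1D1"), expansion_events=tuple(expansions),
        nonproductive_fraction=0.0,
    )
    cohort, truth = simulate_longitudinal_repertoires(spec, 1)
    rec = cohort["P001"]
    return (filter_productive(rec.samples["C0D1"]),
            filter_productive(rec.samples["C1D1"]), truth)


class TestClassifyDynamics:
    def test_identical_samples_yield_no_calls(self, sample_factory):
        a = sample_factory({"A": 50, "B": 30, "C": 20})
        b = sample_factory({"A": 50, "B": 30, "C": 20}, visit="C1D1")
        records, summary = classify_dynamics(a, b)
        assert summary.n_expanded == summary.n_contracted == 0
        assert all(r.p_value == 1.0 for r in records)

    def test_injected_expansion_detected_and_newly_flagged(self):
        a, b, _ = _sim_pair(
            5,
            expansions=[ExpansionEvent(clone="novel", visit="C1D1",
                                       target_frequency=0.05)],
            depth=10_000,
        )
        records, summary = classify_dynamics(a, b)
        novel = [r for r in records if r.count_a == 0 and r.count_b > 100]
        assert len(novel) == 1
        assert novel[0].direction == EXPANDED
        assert novel[0].newly_detected
        # all background clones obey the null
        assert summary.n_expanded <= 2

    def test_swap_exchanges_expansion_and_contraction_labels(self):
        a, b, _ = _sim_pair(
            6,
            expansions=[ExpansionEvent(clone=3, visit="C1D1", fold_change=8.0)],
        )
        fwd, _ = classify_dynamics(a, b)
        rev, _ = classify_dynamics(b, a)
        fwd_exp = {r.rearrangement_id for r in fwd if r.direction == EXPANDED}
        fwd_con = {r.rearrangement_id for r in fwd if r.direction == CONTRACTED}
        rev_exp = {r.rearrangement_id for r in rev if r.direction == EXPANDED}
        rev_con = {r.rearrangement_id for r in rev if r.direction == CONTRACTED}
        assert fwd_exp == rev_con and fwd_con == rev_exp

    def test_newly_detected_never_exceeds_expanded(self):
        for seed in range(4):
            a, b, _ = _sim_pair(
                seed,
                expansions=[
                    ExpansionEvent(clone="novel", visit="C1D1",
                                   target_frequency=0.01),
                    ExpansionEvent(clone=0, visit="C1D1", fold_change=4.0),
                ],
            )
            _, s = classify_dynamics(a, b)
            assert s.n_newly_detected_expanded <= s.n_expanded <= s.n_tested

    def test_loose_novel_rule_skips_significance(self, sample_factory):
        a = sample_factory({"A": 5000})
        b = sample_factory({"A": 4994, "B": 6}, visit="C1D1")
        strict, _ = classify_dynamics(a, b)
        loose, _ = classify_dynamics(a, b, require_significance=False)
        b_strict = next(r for r in strict if r.count_b == 6)
        b_loose = next(r for r in loose if r.count_b == 6)
        assert not b_strict.newly_detected  # not Fisher-significant
        assert b_loose.newly_detected

    def test_patient_mismatch_and_empty_sample_errors(self, sample_factory):
        a = sample_factory({"A": 5})
        other = sample_factory({"A": 5}, patient_id="P2", visit="C1D1")
        with pytest.raises(ValidationError, match="patient"):
            classify_dynamics(a, other)
        with pytest.raises(EmptySampleError):
            classify_dynamics(a, RepertoireSample("P1", "C1D1"))


class TestCohortVisitComparison:
    def test_exact_paired_signed_rank_example(self):
        # all five deltas positive: two-sided exact p = 2/2^5
        assert paired_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(0.0625)

    def test_all_zero_deltas_skipped_with_warning(self):
        values = {"C0D1": {"P1": 1.0, "P2": 2.0}, "C1D1": {"P1": 1.0, "P2": 2.0}}
        with pytest.warns(UserWarning, match="skipped"):
            out = cohort_visit_comparison(values, [("C0D1", "C1D1")])
        assert len(out) == 0

    def test_swapping_visits_keeps_two_sided_p(self):
        rng = np.random.default_rng(0)
        vals = {
            "C0D1": dict(zip("abcdefgh", rng.normal(0, 1, 8))),
            "C1D1": dict(zip("abcdefgh", rng.normal(0.5, 1, 8))),
        }
        fwd = cohort_visit_comparison(vals, [("C0D1", "C1D1")])
        rev = cohort_visit_comparison(vals, [("C1D1", "C0D1")])
        assert fwd["p_value"][0] == pytest.approx(rev["p_value"][0])
        assert fwd["median_delta"][0] == pytest.approx(-rev["median_delta"][0])

    def test_bh_applied_across_comparisons_and_deltas_returned(self):
        rng = np.random.default_rng(1)
        vals = {
            "C0D1": dict(zip(range(10), rng.normal(0, 1, 10))),
            "C1D1": dict(zip(range(10), rng.normal(2, 1, 10))),
            "C1D22": dict(zip(range(10), rng.normal(0, 1, 10))),
        }
        out = cohort_visit_comparison(
            vals, [("C0D1", "C1D1"), ("C1D1", "C1D22"), ("C0D1", "C1D22")]
        )
        assert len(out) == 3
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        assert len(out["deltas"][0]) == 10
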