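"""Enrichment analysis: counting, normalization, dispersion, exact test,
hit calling and representation QC."""

import numpy as np
import pandas as pd
import pytest

from metavenom import enrich
from metavenom.enrich import (
    CountMatrix,
    HitCallCriteria,
    call_hits,
    count_reads,
    estimate_dispersion,
    exact_test,
    normalize,
    representation_qc,
    score_enrichment,
)
from metavenom.simulate import ScreenSimConfig, simulate_screen

from _oracles import conditional_binomial_tail


def _samples(n_target=3, n_control=3):
    rows = [
        {"sample": f"control_{i+1}", "group": "control", "replicate": i + 1}
        for i in range(n_control)
    ] + [
        {"sample": f"target_{i+1}", "group": "target", "replicate": i + 1}
        for i in range(n_target)
    ]
    return pd.DataFrame(rows).set_index("sample")


def _matrix(control_rows, target_rows, clones=None):
    control = np.asarray(control_rows)
    target = np.asarray(target_rows)
    data = {}
    for i in range(control.shape[1]):
        data[f"control_{i+1}"] = control[:, i]
    for i in range(target.shape[1]):
        data[f"target_{i+1}"] = target[:, i]
    counts = pd.DataFrame(data, index=clones or [f"c{i}" for i in range(len(control))], dtype=np.int64)
    return CountMatrix(counts=counts, samples=_samples(target.shape[1], control.shape[1]))


class TestCountReads:
    def test_exact_multiplicities(self):
        ref = {"a": "AAAT", "b": "CCCT", "c": "GGGT"}
        reads = {"s1": ["AAAT"] * 5 + ["GGGT"] * 2}
        samples = pd.DataFrame({"group": ["target"], "replicate": [1]}, index=["s1"])
        m, unmapped = count_reads(reads, ref, samples)
        assert m.counts["s1"].tolist() == [5, 0, 2]
        assert unmapped["s1"] == 0

    def test_single_mismatch_is_unmapped(self):
        ref = {"a": "AAAT"}
        samples = pd.DataFrame({"group": ["target"], "replicate": [1]}, index=["s1"])
        m, unmapped = count_reads({"s1": ["AAAA"]}, ref, samples)
        assert m.counts["s1"].tolist() == [0]
        assert unmapped["s1"] == 1

    def test_prefix_matching(self):
        ref = {"a": "AAATGGG"}
        samples = pd.DataFrame({"group": ["target"], "replicate": [1]}, index=["s1"])
        m, _ = count_reads({"s1": ["AAAT"]}, ref, samples, prefix_len=4)
        assert m.counts["s1"].tolist() == [1]

    def test_duplicate_reference_rejected(self):
        samples = pd.DataFrame({"group": ["target"], "replicate": [1]}, index=["s1"])
        with pytest.raises(ValueError, match="ambiguous"):
            count_reads({"s1": []}, {"a": "AAAT", "b": "AAAT"}, samples)


class TestNormalize:
    def test_total_scaling_closed_form(self):
        m = _matrix([[500, 1000]], [[10, 10]])
        # totals (510, 1010, 10, 10): factor = mean/total
        f = normalize(m)
        totals = m.counts.sum(axis=0)
        assert np.allclose(f.values, totals.mean() / totals.values)
        scaled = (m.counts * f).sum(axis=0)
        assert np.allclose(scaled, scaled.iloc[0])

    def test_identical_columns_unit_factors(self):
        col = [[10, 10], [20, 20], [5, 5]]
        m = _matrix(col, col)
        assert np.allclose(normalize(m).values, 1.0)

    def test_trimmed_insensitive_to_outlier_clone(self, rng):
        base = rng.integers(50, 150, size=(40, 6))
        base[0, 0] = 100_000  # one huge clone in one sample
        m = _matrix(base[:, :3], base[:, 3:])
        trimmed = normalize(m, method="trimmed")
        total = normalize(m, method="total")
        assert abs(trimmed.iloc[0] - 1.0) < 0.05
        assert abs(total.iloc[0] - 1.0) > 0.3

    def test_all_zero_sample_rejected(self):
        m = _matrix([[0, 5]], [[3, 3]])
        with pytest.raises(ValueError, match="control_1"):
            normalize(m)


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        m, _ = simulate_screen(ScreenSimConfig(n_clones=5000, phi=0.0, seed=31))
        model = estimate_dispersion(m)
        assert model.common == pytest.approx(0.0, abs=0.02)

    def test_nb_dispersion_recovered(self):
        m, _ = simulate_screen(ScreenSimConfig(n_clones=5000, phi=0.2, seed=32))
        model = estimate_dispersion(m)
        assert 0.15 <= model.common <= 0.25

    def test_shrinkage_formula(self):
        m, _ = simulate_screen(ScreenSimConfig(n_clones=200, phi=0.1, seed=33))
        model = estimate_dispersion(m)
        clone = m.counts.index[0]
        raw = float(model.per_clone[clone])
        assert model.phi(clone) == pytest.approx(0.2 * raw + 0.8 * model.common)

    def test_no_replicates_falls_back_to_prior(self):
        counts = pd.DataFrame({"t": [5, 9], "c": [4, 8]}, index=["a", "b"], dtype=np.int64)
        samples = pd.DataFrame(
            {"group": ["target", "control"], "replicate": [1, 1]}, index=["t", "c"]
        )
        model = estimate_dispersion(CountMatrix(counts=counts, samples=samples), prior=0.1)
        assert model.common == 0.1


class TestExactTest:
    def test_symmetric_counts_uninformative(self):
        p, fc = exact_test(60.0, 60.0, 3, 3, 0.2)
        assert fc == pytest.approx(1.0)
        assert p >= 0.5

    def test_poisson_case_matches_binomial_oracle(self):
        """With zero dispersion the test equals the one-sided conditional
        binomial tail computed by exhaustive summation."""
        p, fc = exact_test(60.0, 6.0, 3, 3, 0.0)
        assert p == pytest.approx(conditional_binomial_tail(60, 6, 0.5), rel=1e-9)
        assert fc == pytest.approx(60.5 / 6.5)

    def test_unequal_replicate_numbers(self):
        p, _ = exact_test(40.0, 20.0, 2, 1, 0.0)
        assert p == pytest.approx(conditional_binomial_tail(40, 20, 2 / 3), rel=1e-9)

    def test_both_groups_zero(self):
        assert exact_test(0.0, 0.0, 3, 3, 0.2) == (1.0, 1.0)

    def test_p_decreases_with_enrichment(self):
        ps = [exact_test(float(t), 30.0, 3, 3, 0.2)[0] for t in (30, 60, 120, 240)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_dispersion_widens_the_null(self):
        p_pois, _ = exact_test(90.0, 30.0, 3, 3, 0.0)
        p_nb, _ = exact_test(90.0, 30.0, 3, 3, 0.3)
        assert p_nb > p_pois

    def test_fold_change_equivariance(self):
        _, fc1 = exact_test(100.0, 50.0, 3, 3, 0.1)
        _, fc3 = exact_test(300.0, 50.0, 3, 3, 0.1)
        assert fc3 / fc1 == pytest.approx(3.0, rel=0.01)


class TestHitCalling:
    def _results(self, m, p, fc):
        return pd.DataFrame(
            {
                "mean_target": m.counts[m.group_columns("target")].mean(axis=1),
                "mean_control": m.counts[m.group_columns("control")].mean(axis=1),
                "ml_fold_change": fc,
                "p_value": p,
            },
            index=m.counts.index,
        )

    def test_support_count_boundary(self):
        m = _matrix([[1, 1, 1]], [[14, 14, 14]])
        res = call_hits(self._results(m, [1e-9], [100.0]), m)
        assert not res["is_hit"].iloc[0]
        assert res["support_reps"].iloc[0] == 0

    def test_two_of_three_support_suffices(self):
        m = _matrix([[1, 1, 1]], [[15, 15, 0]])
        res = call_hits(self._results(m, [1e-9], [10.0]), m)
        assert res["is_hit"].iloc[0]
        assert res["support_reps"].iloc[0] == 2

    def test_fold_change_threshold_strict(self):
        m = _matrix([[20, 20, 20]], [[100, 100, 100]])
        res = call_hits(self._results(m, [1e-9], [4.9]), m)
        assert not res["is_hit"].iloc[0]

    def test_p_threshold_strict(self):
        m = _matrix([[1, 1, 1]], [[100, 100, 100]])
        res = call_hits(self._results(m, [0.001], [50.0]), m)
        assert not res["is_hit"].iloc[0]  # p must be < 0.001, not <=

    def test_order_invariance(self):
        m, truth = simulate_screen(
            ScreenSimConfig(n_clones=300, phi=0.2, depth=30_000, spiked=((5, 10.0), (17, 10.0)), seed=34)
        )
        res1 = call_hits(score_enrichment(m), m)
        perm = np.random.default_rng(0).permutation(len(m.counts))
        cols = list(m.counts.columns)[::-1]
        m2 = CountMatrix(counts=m.counts.iloc[perm][cols], samples=m.samples)
        res2 = call_hits(score_enrichment(m2), m2)
        assert res1["is_hit"].sort_index().equals(res2["is_hit"].sort_index())


class TestRepresentationQC:
    def test_identical_libraries(self):
        a = pd.Series([10, 20, 30], index=list("abc"))
        ratio, summary = representation_qc(a, a.copy())
        assert np.allclose(ratio.values, 1.0)
        assert summary["median_ratio"] == pytest.approx(1.0)
        assert summary["pct_within_one_log"] == 100.0

    def test_dropout_detection_rate(self, rng):
        b = pd.Series(rng.integers(50, 200, size=1000))
        a = b.copy()
        dropped = rng.choice(1000, size=100, replace=False)
        a.iloc[dropped] = 0
        _, summary = representation_qc(a, b)
        assert summary["pct_detected"] == pytest.approx(90.0, abs=1.0)

    def test_single_depleted_member(self):
        b = pd.Series([100] * 101, index=range(101))
        a = b.copy()
        a.iloc[0] = 10
        ratio, summary = representation_qc(a, b)
        assert ratio.iloc[0] == pytest.approx(0.1, rel=0.1)  # pseudocount shifts slightly
        assert summary["median_ratio"] == pytest.approx(1.0, rel=0.02)


def test_bh_column_emitted_but_hit_rule_uses_raw_p():
    m, _ = simulate_screen(ScreenSimConfig(n_clones=200, phi=0.2, depth=20_000, seed=35))
    res = score_enrichment(m)
    assert "bh_q" in res.columns
    assert (res["bh_q"] >= res["p_value"] - 1e-12).all()
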