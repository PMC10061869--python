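import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evarseq as ev
from evarseq.metrics import exclusive_intersections, kendall_tau, variability_metrics


def tau_b_oracle(x, y):
    """O(n^2) pair-counting Kendall tau-b with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    c = d = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            c += 1
        else:
            d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


class TestVariabilityMetrics:
    def test_hand_example(self):
        stratum = pd.DataFrame([[1, 2, 3, 4, 5]], index=["g"], columns=list("abcde"))
        row = variability_metrics(stratum).iloc[0]
        assert row["mean"] == 3.0
        assert row["sd"] == pytest.approx(1.5811, abs=1e-4)
        assert row["cv"] == pytest.approx(0.5270, abs=1e-4)
        assert row["median_expr"] == 3.0
        assert row["mad"] == pytest.approx(1.4826)
        assert row["d"] == pytest.approx(0.4942, abs=1e-4)

    def test_constant_gene(self):
        stratum = pd.DataFrame([[4.0, 4.0, 4.0]], index=["g"], columns=list("abc"))
        row = variability_metrics(stratum).iloc[0]
        assert row["cv"] == 0.0
        assert row["d"] == 0.0

    def test_scale_invariance_of_cv_and_d(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, 20)
        m1 = variability_metrics(pd.DataFrame([vals], index=["g"])).iloc[0]
        m2 = variability_metrics(pd.DataFrame([vals * 7.3], index=["g"])).iloc[0]
        assert m1["cv"] == pytest.approx(m2["cv"], rel=1e-12)
        assert m1["d"] == pytest.approx(m2["d"], rel=1e-12)

    def test_zero_mean_flagged_nan(self):
        stratum = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g"], columns=list("abc"))
        row = variability_metrics(stratum).iloc[0]
        assert np.isnan(row["cv"]) and np.isnan(row["d"])


class TestKendallTau:
    def test_perfect_agreement(self):
        x = [3.0, 1.0, 2.0, 5.0]
        assert kendall_tau(x, x) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x[::-1]) == pytest.approx(-1.0)

    def test_one_third_example(self):
        assert kendall_tau([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=4, max_value=30))
    def test_matches_pair_counting_oracle_with_ties(self, rng_seed, n):
        rng = np.random.default_rng(rng_seed)
        x = rng.integers(0, 5, n).astype(float)  # heavy ties
        y = rng.integers(0, 5, n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert kendall_tau(x, y) == pytest.approx(tau_b_oracle(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])


class TestMetricVsExpression:
    def test_identical_metric_and_expression(self):
        rng = np.random.default_rng(1)
        med = rng.uniform(1, 100, 50)
        table = pd.DataFrame(
            {"group": "N0", "dose": "0", "median_expr": med, "cv": med, "d": med, "ev": med}
        )
        out = ev.metric_vs_expression(table)
        stratum = out[out["group"] == "N0"].iloc[0]
        assert stratum["tau_cv"] == pytest.approx(1.0)

    def test_permuted_metric_near_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        med = rng.uniform(1, 100, n)
        table = pd.DataFrame(
            {"group": "N0", "dose": "0", "median_expr": med,
             "cv": rng.permutation(med), "d": rng.permutation(med), "ev": rng.permutation(med)}
        )
        out = ev.metric_vs_expression(table)
        se2 = 2 * np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(out.iloc[0]["tau_cv"]) < se2

    def test_pooled_row_emitted(self):
        rng = np.random.default_rng(3)
        frames = []
        for grp in ("N0", "N1"):
            med = rng.uniform(1, 100, 30)
            frames.append(pd.DataFrame(
                {"group": grp, "dose": "0", "median_expr": med, "cv": med, "d": med, "ev": med}
            ))
        out = ev.metric_vs_expression(pd.concat(frames, ignore_index=True))
        assert "pooled" in set(out["group"])


class TestExclusiveIntersections:
    def test_identical_sets_share_one_cell(self):
        report = exclusive_intersections({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert len(report) == 1
        row = report.iloc[0]
        assert row["A"] and row["B"] and row["count"] == 2

    def test_disjoint_sets(self):
        report = exclusive_intersections({"A": {"g1"}, "B": {"g2"}})
        assert len(report) == 2
        assert report["count"].sum() == 2

    def test_nested_sets_enumeration(self):
        report = exclusive_intersections(
            {"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g3"}}
        )
        cells = {
            (bool(r["A"]), bool(r["B"]), bool(r["C"])): r["gene_ids"]
            for _, r in report.iterrows()
        }
        assert cells[(True, False, False)] == "g1"
        assert cells[(True, True, False)] == "g2"
        assert cells[(True, True, True)] == "g3"

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_counts_sum_to_union(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        universe = [f"g{i}" for i in range(30)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            for name in ("A", "B", "C", "D")
        }
        report = exclusive_intersections(sets)
        union = set().union(*sets.values())
        assert report["count"].sum() == len(union)
        # every gene appears in exactly one cell
        seen = [g for ids in report["gene_ids"] for g in ids.split(",") if g]
        assert sorted(seen) == sorted(union)
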