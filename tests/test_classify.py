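import numpy as np
import pandas as pd
import pytest

import evarseq as ev
from evarseq.classify import (
    ClassificationThresholds,
    bh_adjust,
    binomial_concordance_p,
    classify_ev,
    classify_whole,
    crossvalidate,
    reference_interval,
)
from evarseq.ev import EVConfig


class TestReferenceInterval:
    def test_symmetric_values_give_plus_minus_three(self):
        # exact median 0; |x| = {0, a1, a1, ..., a50, a50} with a25 = 1,
        # so the plug-in MAD (constant 1) is exactly 1
        a = 0.04 * np.arange(1, 51)
        x = np.concatenate([-a, [0.0], a])
        thr = reference_interval(x, B=2000, constant=1.0, k=3.0, seed=0)
        assert thr.ref_median_ev == pytest.approx(0.0, abs=1e-12)
        lo, hi = thr.interval
        assert hi == pytest.approx(3.0, rel=0.1)
        assert lo == pytest.approx(-3.0, rel=0.1)

    def test_degenerate_equal_values(self):
        thr = reference_interval(np.zeros(20), B=100, seed=1)
        assert thr.interval == (0.0, 0.0)
        assert classify_ev(0.5, thr) == "hyper"
        assert classify_ev(-0.5, thr) == "hypo"
        assert classify_ev(0.0, thr) == "non"

    def test_k_zero_collapses_to_median(self):
        x = np.arange(20.0)
        thr = reference_interval(x, B=500, k=0.0, seed=2)
        assert thr.interval[0] == thr.interval[1] == thr.ref_median_ev

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="10"):
            reference_interval(np.arange(5.0))


class TestClassifyEV:
    thr = ClassificationThresholds(dose="0", ref_median_ev=10.0, ref_mad_ev=50.0, k=3.0)

    def test_interval_bounds(self):
        assert self.thr.interval == (-140.0, 160.0)

    @pytest.mark.parametrize(
        "value,label",
        [(200.0, "hyper"), (-200.0, "hypo"), (10.0, "non"), (160.0, "non"), (-140.0, "non")],
    )
    def test_labels_with_closed_interval(self, value, label):
        assert classify_ev(value, self.thr) == label

    def test_vectorized(self):
        out = classify_ev(np.array([-200.0, 0.0, 200.0]), self.thr)
        assert list(out) == ["hypo", "non", "hyper"]

    def test_widening_k_shrinks_variable_sets(self):
        rng = np.random.default_rng(0)
        evs = rng.normal(0, 1, 500)
        sets = {}
        for k in (1.0, 2.0, 3.0):
            thr = ClassificationThresholds(dose="0", ref_median_ev=0.0, ref_mad_ev=1.0, k=k)
            lab = classify_ev(evs, thr)
            sets[k] = set(np.flatnonzero(lab != "non"))
        assert sets[3.0] <= sets[2.0] <= sets[1.0]

    def test_reference_group_mostly_non_on_trend_only_data(self):
        # study-scale stratum with a homogeneous noise scale: the robust
        # 3-MAD interval captures the bulk of the reference group's EVs
        cfg = ev.SimConfig(
            n_genes=500, samples_per_group=52, groups=("N0",), doses=("0",),
            mean_log_mu_range=(np.log(50), np.log(800)),
            frac_hyper=0, frac_hypo=0, frac_bimodal=0, frac_de=0, seed=17,
        )
        counts, metadata, _ = ev.simulate_counts(cfg)
        s = ev.compute_size_factors(counts)
        table = ev.compute_ev(counts, metadata, s, list(counts.index), EVConfig(B=300, seed=17))
        labelled, _ = classify_whole(table, "N0", B=300, seed=17)
        assert (labelled["label"] == "non").mean() >= 0.9


class TestBinomialAndBH:
    def test_ten_of_ten(self):
        assert binomial_concordance_p(10, 10) == pytest.approx(1 / 1024)

    def test_eight_of_ten(self):
        # P(X >= 8) = (45 + 10 + 1) / 1024
        assert binomial_concordance_p(8, 10) == pytest.approx(56 / 1024)

    def test_zero_successes(self):
        assert binomial_concordance_p(0, 10) == pytest.approx(1.0)

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_bh_single_and_ties(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_bh_matches_min_over_ranks_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        m = p.size
        order = np.argsort(p)
        sorted_p = p[order]
        oracle_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def cv_result():
    cfg = ev.SimConfig(
        n_genes=300, samples_per_group=12, doses=("0",),
        frac_hyper=0.1, frac_hypo=0, frac_bimodal=0, frac_de=0,
        effect_hyper=10.0, seed=23,
    )
    counts, metadata, truth = ev.simulate_counts(cfg)
    s = ev.compute_size_factors(counts)
    ecfg = EVConfig(B=60, seed=23)
    cls = crossvalidate(counts, metadata, s, list(counts.index), ecfg,
                        reference_group="N0", R=3, seed=23)
    return counts, metadata, s, ecfg, cls


class TestCrossvalidate:
    def test_labels_partition_genes(self, cv_result):
        *_, cls = cv_result
        per = cls.groupby(["group", "dose"]).size()
        assert (per == 300).all()
        assert set(cls["label_whole"]) <= {"hypo", "non", "hyper"}

    def test_confirmed_subset_of_whole(self, cv_result):
        *_, cls = cv_result
        changed = cls["label_confirmed"] != cls["label_whole"]
        assert (cls.loc[changed, "label_confirmed"] == "non").all()
        for lab in ("hypo", "hyper"):
            conf = set(cls.loc[cls["label_confirmed"] == lab, "gene_id"])
            whole = set(cls.loc[cls["label_whole"] == lab, "gene_id"])
            assert conf <= whole

    def test_adjusted_p_not_below_raw(self, cv_result):
        *_, cls = cv_result
        assert (cls["p_adjusted"] >= cls["p_binomial"] - 1e-12).all()

    def test_successes_in_range(self, cv_result):
        *_, cls = cv_result
        assert cls["successes"].between(0, 3).all()

    def test_deterministic(self, cv_result):
        counts, metadata, s, ecfg, cls = cv_result
        again = crossvalidate(counts, metadata, s, list(counts.index), ecfg,
                              reference_group="N0", R=3, seed=23)
        pd.testing.assert_frame_equal(cls, again)

    def test_identical_samples_give_full_concordance(self):
        """Identical columns within each group: every half reproduces the
        whole-data labels, so successes = R for every gene."""
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(60)]
        base = {grp: rng.poisson(100, size=60) + 1 for grp in ("N0", "N1")}
        cols, meta_rows = {}, []
        for grp in ("N0", "N1"):
            for j in range(8):
                sid = f"{grp}_{j}"
                cols[sid] = base[grp]
                meta_rows.append((sid, grp, "0", f"t{j}", "F", 0, 0))
        counts = pd.DataFrame(cols, index=genes)
        metadata = pd.DataFrame(
            meta_rows,
            columns=["sample_id", "donor_group", "dose", "triplet_id", "sex",
                     "smoking_pack_years", "alcohol_per_day"],
        ).set_index("sample_id")
        s = pd.Series(1.0, index=counts.columns)
        cls = crossvalidate(counts, metadata, s, genes, EVConfig(B=30, seed=1),
                            reference_group="N0", R=4, seed=1, by_triplet=False)
        assert (cls["successes"] == 4).all()

    def test_stratum_too_small_to_split(self, small_sim, small_size_factors):
        _, counts, metadata, _ = small_sim
        few = metadata.groupby(["donor_group", "dose"]).head(3)
        with pytest.raises(ValueError, match="fewer than 4|too small"):
            crossvalidate(counts[few.index], few, small_size_factors,
                          list(counts.index)[:50], EVConfig(B=10, seed=0), R=2, seed=0)
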