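import numpy as np
import pytest

import hdtcardio as hc
from hdtcardio.errors import DesignError, DomainError


def hochberg_bruteforce_rejections(p, alpha):
    """Literal step-up rule: order descending, find the largest k (counting
    from the most significant end) such that p_(k) <= alpha / (m - k + 1),
    reject all smaller p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    rejected = np.zeros(m, dtype=bool)
    k_star = 0
    for k in range(1, m + 1):  # k-th smallest
        if p[order[k - 1]] <= alpha / (m - k + 1):
            k_star = k
    rejected[order[:k_star]] = True
    return rejected


class TestHochberg:
    def test_worked_example(self):
        adj = hc.hochberg_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert hc.hochberg_adjust([0.0321])[0] == pytest.approx(0.0321)

    def test_ties_all_equal(self):
        adj = hc.hochberg_adjust([0.04, 0.04, 0.04])
        assert np.allclose(adj, 0.04)

    def test_domain_validation(self):
        with pytest.raises(DomainError):
            hc.hochberg_adjust([0.5, 1.2])

    def test_matches_bruteforce_step_up_on_fuzzed_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = int(rng.integers(1, 12))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            adj = hc.hochberg_adjust(p)
            for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
                assert np.array_equal(adj <= alpha,
                                      hochberg_bruteforce_rejections(p, alpha))

    def test_matches_statsmodels_simes_hochberg(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(2, 10)))
            ref = mt.multipletests(p, method="simes-hochberg")[1]
            assert np.allclose(hc.hochberg_adjust(p), ref, atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(0, 1, 8)
            adj = hc.hochberg_adjust(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_superset_of_holm(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(21)
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(2, 10))) ** 2
            hoch = hc.hochberg_adjust(p) <= 0.05
            holm = mt.multipletests(p, alpha=0.05, method="holm")[0]
            assert np.all(hoch | ~holm)


class TestFitMixedModel:
    def test_empty_cell_raises_design_error(self):
        df = hc.simulate_timecourse_table(rng=np.random.default_rng(1))
        df = df[~((df["group"] == "TRAIN") & (df["timepoint"] == "HDT56"))]
        with pytest.raises(DesignError, match="TRAIN.*HDT56"):
            hc.fit_mixed_model(df, hc.ModelSpec("HR", "timecourse"))

    def test_single_subject_group_rejected(self):
        df = hc.simulate_timecourse_table(n_ctrl=1, rng=np.random.default_rng(1))
        with pytest.raises(DesignError):
            hc.fit_mixed_model(df, hc.ModelSpec("HR", "timecourse"))

    def test_baseline_null_depends_on_index_scale(self):
        assert hc.ModelSpec("HR", "timecourse").baseline_null == 100.0
        assert hc.ModelSpec("HF", "timecourse").baseline_null == 0.0
        assert hc.ModelSpec("TPR", "postural").baseline_null == 0.0


class TestTimecourseContrasts:
    def test_ctrl_only_rise_found_with_high_power(self):
        hits = {tp: 0 for tp in ("HDT28", "HDT56", "R+10")}
        train_false = 0
        reps = 40
        root = np.random.default_rng(31)
        for _ in range(reps):
            df = hc.simulate_timecourse_table(
                sigma_subject=5.0, sigma_resid=5.0,
                effects={("CTRL", "HDT28"): 15.0, ("CTRL", "HDT56"): 15.0,
                         ("CTRL", "R+10"): 15.0},
                rng=np.random.default_rng(int(root.integers(2**31))),
            )
            m = hc.fit_mixed_model(df, hc.ModelSpec("HR", "timecourse"))
            res = {r.name: r for r in hc.timecourse_contrasts(m)}
            for tp in hits:
                r = res[f"CTRL {tp} vs baseline"]
                if not r.gated and r.p_adj < 0.05:
                    hits[tp] += 1
            for tp in ("HDT2", "HDT28", "HDT56", "R+10"):
                r = res[f"TRAIN {tp} vs baseline"]
                if not r.gated and r.p_adj < 0.05:
                    train_false += 1
        for tp, k in hits.items():
            assert k / reps >= 0.9, tp
        assert train_false / (4 * reps) <= 0.05

    def test_null_data_gates_all_contrasts(self):
        # average over a few seeds: with no effects most runs gate everything
        gated_runs = 0
        root = np.random.default_rng(17)
        for _ in range(20):
            df = hc.simulate_timecourse_table(
                rng=np.random.default_rng(int(root.integers(2**31)))
            )
            m = hc.fit_mixed_model(df, hc.ModelSpec("HR", "timecourse"))
            res = hc.timecourse_contrasts(m)
            if all(r.gated for r in res):
                gated_runs += 1
                assert all(np.isnan(r.p_adj) for r in res)
        assert gated_runs >= 14

    def test_pooled_contrasts_when_only_time_significant(self):
        df = hc.simulate_timecourse_table(
            effects={("CTRL", "HDT56"): 8.0, ("TRAIN", "HDT56"): 8.0},
            rng=np.random.default_rng(23),
        )
        m = hc.fit_mixed_model(df, hc.ModelSpec("HR", "timecourse"))
        om = m.omnibus
        res = hc.timecourse_contrasts(m)
        if om["Timepoint"].p < 0.05 and om["Group"].p >= 0.05 \
                and om["GroupxTimepoint"].p >= 0.05:
            assert all(r.name.startswith("pooled") for r in res)
            assert len(res) == 4


class TestDeltaContrasts:
    def test_deterministic_deltas_equal_cell_means(self):
        df = hc.simulate_delta_table(
            sigma_subject=0.0, sigma_resid=0.0,
            effects={("CTRL", "supine"): -120.0, ("CTRL", "sitting"): 30.0},
            rng=np.random.default_rng(0),
        )
        m = hc.fit_mixed_model(df, hc.ModelSpec("TPR", "postural"))
        res = {r.name: r for r in hc.delta_contrasts(m)}
        assert res["CTRL supine delta vs 0"].estimate == pytest.approx(-120.0)
        assert res["CTRL sitting delta vs 0"].estimate == pytest.approx(30.0)
        assert res["TRAIN supine delta vs 0"].estimate == pytest.approx(0.0)

    def test_injected_supine_decline_detected(self):
        found_nonzero = found_posture = 0
        reps = 40
        root = np.random.default_rng(41)
        for _ in range(reps):
            df = hc.simulate_delta_table(
                sigma_subject=50.0, sigma_resid=50.0,
                effects={("CTRL", "supine"): -100.0},
                rng=np.random.default_rng(int(root.integers(2**31))),
            )
            m = hc.fit_mixed_model(df, hc.ModelSpec("TPR", "postural"))
            res = {r.name: r for r in hc.delta_contrasts(m)}
            r1 = res["CTRL supine delta vs 0"]
            r2 = res["CTRL supine vs sitting"]
            if not r1.gated and r1.p_adj < 0.05:
                found_nonzero += 1
            if not r2.gated and r2.p_adj < 0.05:
                found_posture += 1
        assert found_nonzero / reps >= 0.8
        assert found_posture / reps >= 0.8

    def test_contrast_family_size_and_membership(self):
        df = hc.simulate_delta_table(
            effects={("CTRL", "supine"): -40.0}, rng=np.random.default_rng(2)
        )
        m = hc.fit_mixed_model(df, hc.ModelSpec("TPR", "postural"))
        res = hc.delta_contrasts(m)
        assert len(res) == 8  # 4 non-zero + 2 posture + 2 group comparisons
        assert len({r.family for r in res}) == 1
        live = [r for r in res if not r.gated]
        if live:
            assert all(r.p_adj >= r.p - 1e-15 for r in live)


class TestSummaries:
    def test_output_frames(self):
        df = hc.simulate_delta_table(
            effects={("CTRL", "supine"): -60.0}, rng=np.random.default_rng(3)
        )
        m = hc.fit_mixed_model(df, hc.ModelSpec("TPR", "postural"))
        cf = hc.contrasts_to_frame(hc.delta_contrasts(m))
        assert {"contrast", "estimate", "se", "df", "t", "p", "p_adj"} <= set(cf.columns)
        of = hc.omnibus_to_frame([m])
        assert of.loc[0, "outcome"] == "TPR"
        assert {"p_Group", "p_Posture", "p_GroupxPosture"} <= set(of.columns)
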