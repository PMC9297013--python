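"""Randomization nulls: tail quantiles, flags, pairing and determinism."""

import numpy as np
import pytest

import phyloshift as ps
from phyloshift.tree import mpd_over_masks

CFG = ps.NullConfig(n_reps=200, seed=42)


class TestTailQuantile:
    def test_half_below(self):
        assert ps.tail_quantile(np.arange(1, 11), 5.5) == 0.5

    def test_all_ties_midrank(self):
        assert ps.tail_quantile(np.full(100, 3.0), 3.0) == 0.5

    def test_below_all(self):
        assert ps.tail_quantile(np.arange(1, 11), 0.0) == 0.0

    def test_above_all(self):
        assert ps.tail_quantile(np.arange(1, 11), 11.0) == 1.0

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(size=500)
        qs = [ps.tail_quantile(reps, o) for o in np.linspace(-3, 3, 25)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_no_defined_replicates(self):
        with pytest.raises(ValueError):
            ps.tail_quantile(np.array([np.nan]), 0.0)


class TestFlags:
    @pytest.mark.parametrize(
        "q,flag", [(0.01, "sig_low"), (0.97, "sig_high"), (0.5, "ns"), (0.05, "ns"), (0.95, "ns")]
    )
    def test_thresholds(self, q, flag):
        assert ps.flag_significance(q, ps.NullConfig()) == flag


def _scenario_transition(sc, i):
    return ps.AssemblageTransition.from_sets(
        sc.grid.cell_ids[i], sc.current.species_at(i), sc.future.species_at(i)
    )


class TestLossNull:
    def test_no_loss_untestable(self, toy_tree, toy_dist):
        tr = ps.AssemblageTransition.from_sets("c", {"A", "B"}, {"A", "B", "C"})
        out = ps.random_loss_null(toy_tree, toy_dist, tr, CFG)
        assert all(nd.flag == "untestable" and nd.reason == "no loss" for nd in out.values())

    def test_complete_loss_degenerate(self, toy_tree, toy_dist):
        tr = ps.AssemblageTransition.from_sets("c", {"A", "B", "C"}, set())
        out = ps.random_loss_null(toy_tree, toy_dist, tr, CFG)
        nd = out["FaithPD"]
        assert np.allclose(nd.replicates, nd.observed)
        assert nd.q == 0.5 and nd.flag == "ns"
        # all three species removed leaves < 2 survivors in every replicate
        assert out["MPD"].flag == "untestable"
        assert out["MPD"].reason == "MPD undefined in replicates"

    def test_observed_matches_decomposition(self, yule64, yule64_dist):
        labels = list(yule64.tip_labels)
        tr = ps.AssemblageTransition.from_sets("c", set(labels[:20]), set(labels[5:20]))
        out = ps.random_loss_null(yule64, yule64_dist, tr, CFG)
        rec = ps.decompose_metric_change(yule64, yule64_dist, tr)
        assert out["FaithPD"].observed == pytest.approx(rec.loss_delta_pd.value)
        assert out["MPD"].observed == pytest.approx(rec.loss_delta_mpd.value)
        assert out["FaithPD"].q is not None and 0 <= out["FaithPD"].q <= 1

    def test_pd_and_mpd_paired_draws(self, yule64, yule64_dist):
        """Each replicate's PD and MPD deltas must come from the same draw:
        with 2 of 5 species removed there are only 10 possible survivor
        sets, so each PD delta identifies the set and must map to the MPD
        delta of that same set."""
        labels = sorted(yule64.tip_labels)[:5]
        tr = ps.AssemblageTransition.from_sets("c", set(labels), set(labels[:3]))
        out = ps.random_loss_null(yule64, yule64_dist, tr, ps.NullConfig(n_reps=300, seed=9))
        from itertools import combinations

        pd_cur = ps.faith_pd(yule64, labels).value
        mpd_cur = ps.mpd(yule64_dist, labels).value
        mapping = {}
        for survivors in combinations(labels, 3):
            key = round(ps.faith_pd(yule64, survivors).value - pd_cur, 9)
            mapping[key] = ps.mpd(yule64_dist, survivors).value - mpd_cur
        for pd_delta, mpd_delta in zip(out["FaithPD"].replicates, out["MPD"].replicates):
            assert mapping[round(pd_delta, 9)] == pytest.approx(mpd_delta, abs=1e-9)

    def test_mpd_untestable_when_survivors_below_two(self, toy_tree, toy_dist):
        tr = ps.AssemblageTransition.from_sets("c", {"A", "B", "C"}, {"A"})
        out = ps.random_loss_null(toy_tree, toy_dist, tr, CFG)
        assert out["MPD"].reason == "MPD undefined in replicates"
        assert out["FaithPD"].flag != "untestable"


class TestGainNull:
    def test_no_gain_untestable(self, toy_tree, toy_dist):
        tr = ps.AssemblageTransition.from_sets("c", {"A", "B", "C"}, {"A", "B"})
        pool = ps.DispersalPool("c", 100.0, frozenset({"D"}))
        out = ps.random_gain_null(toy_tree, toy_dist, tr, pool, CFG)
        assert all(nd.reason == "no gain" for nd in out.values())

    def test_pool_too_small(self, yule64, yule64_dist):
        labels = list(yule64.tip_labels)
        tr = ps.AssemblageTransition.from_sets(
            "c", set(labels[:5]), set(labels[:5]) | set(labels[5:8])
        )
        pool = ps.DispersalPool("c", 100.0, frozenset(labels[5:7]))  # 2 < 3 gained
        out = ps.random_gain_null(yule64, yule64_dist, tr, pool, CFG)
        assert all(nd.reason == "pool too small" for nd in out.values())

    def test_degenerate_pool_equals_gain(self, yule64, yule64_dist):
        labels = list(yule64.tip_labels)
        gained = set(labels[10:12])
        tr = ps.AssemblageTransition.from_sets(
            "c", set(labels[:10]), set(labels[:10]) | gained
        )
        pool = ps.DispersalPool("c", 10.0, frozenset(gained))
        out = ps.random_gain_null(yule64, yule64_dist, tr, pool, CFG)
        for nd in out.values():
            assert np.allclose(nd.replicates, nd.observed)
            assert nd.q == 0.5 and nd.flag == "ns"

    def test_observed_matches_decomposition(self, yule64, yule64_dist):
        labels = list(yule64.tip_labels)
        tr = ps.AssemblageTransition.from_sets(
            "c", set(labels[:15]), set(labels[:12]) | set(labels[20:25])
        )
        pool = ps.DispersalPool("c", 500.0, frozenset(labels[18:40]))
        out = ps.random_gain_null(yule64, yule64_dist, tr, pool, CFG)
        rec = ps.decompose_metric_change(yule64, yule64_dist, tr)
        assert out["FaithPD"].observed == pytest.approx(rec.gain_delta_pd.value)
        assert out["MPD"].observed == pytest.approx(rec.gain_delta_mpd.value)


class TestDeterminism:
    def test_substreams_order_invariant(self, yule64, yule64_dist):
        labels = list(yule64.tip_labels)
        trs = [
            ps.AssemblageTransition.from_sets(
                f"cell{i}", set(labels[i : i + 12]), set(labels[i + 3 : i + 12])
            )
            for i in range(4)
        ]
        cfg = ps.NullConfig(n_reps=100, seed=123)
        forward = {tr.cell_id: ps.random_loss_null(yule64, yule64_dist, tr, cfg) for tr in trs}
        backward = {
            tr.cell_id: ps.random_loss_null(yule64, yule64_dist, tr, cfg)
            for tr in reversed(trs)
        }
        for cell, out in forward.items():
            for metric, nd in out.items():
                assert np.array_equal(nd.replicates, backward[cell][metric].replicates)
                assert nd.q == backward[cell][metric].q

    def test_different_components_different_streams(self):
        cfg = ps.NullConfig(seed=1)
        r_loss = ps.nullmodels.cell_rng(cfg, "cell1", "loss").random(5)
        r_gain = ps.nullmodels.cell_rng(cfg, "cell1", "gain").random(5)
        assert not np.allclose(r_loss, r_gain)


class TestCalibrationSmoke:
    def test_dropout_quantiles_roughly_uniform(self):
        """Per-presence dropout makes each cell's lost set an exactly
        uniform draw, so loss-null quantiles should look uniform."""
        cfg = ps.ScenarioConfig(
            n_species=48, lat_min=40, lat_max=50, lon_min=0, lon_max=10,
            shift_mode="random_dropout", seed=3,
        )
        sc = ps.simulate_scenario(cfg)
        ch, nulls, _ = ps.analyze_assemblages(
            sc.tree, sc.current, sc.future, ps.NullConfig(n_reps=200, seed=3),
            cell_indices=np.arange(0, sc.grid.n_cells, 4),
        )
        q = nulls[(nulls.metric == "FaithPD") & (nulls.component == "loss")]["q"].dropna()
        assert len(q) > 50
        assert 0.35 < q.mean() < 0.65
        assert ((q < 0.05) | (q > 0.95)).mean() < 0.25
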