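"""Tile building, the two-proportion logistic LRT, BH adjustment and DMR
calling."""

import numpy as np
import pandas as pd
import pytest

from methgwas.core import GenomicInterval, ValidationError
from methgwas.dmr import TileTable, adjust_q, binomial_lrt, build_tiles, call_dmrs
from methgwas.dmr import test_tiles as run_tile_test
from methgwas.simulate import (
    PlantedDmrTile,
    SimulationDesign,
    default_layout,
    simulate_methylomes,
)


class TestBuildTiles:
    def test_tile_grid_assignment(self, layout, make_sample_factory):
        s = make_sample_factory(layout, [("chr1", 600, 3, 10)])
        table = build_tiles([s], layout)
        assert table.units.iloc[0][["start", "end"]].tolist() == [500, 1000]

    def test_grid_boundary_splits_tiles(self, layout, make_sample_factory):
        s = make_sample_factory(layout, [("chr1", 499, 3, 10), ("chr1", 500, 3, 10)])
        table = build_tiles([s], layout)
        assert table.units["start"].tolist() == [0, 500]

    def test_cpg_unit_one_row_per_locus(self, layout, make_sample_factory):
        s = make_sample_factory(layout, [("chr1", 499, 3, 10), ("chr1", 500, 3, 10)])
        table = build_tiles([s], layout, unit="cpg")
        assert table.n_units == 2
        assert (table.units["end"] - table.units["start"]).tolist() == [1, 1]

    def test_unknown_chromosome_rejected(self, layout, make_sample_factory):
        s = make_sample_factory(layout, [("chr2", 600, 3, 10)])
        other = default_layout(1, 100_000)  # only has chr1
        with pytest.raises(ValidationError):
            build_tiles([s], other)


def two_sample_table(m1, t1, m2, t2, layout):
    units = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
    return TileTable(
        "tile500",
        units,
        ["a", "b"],
        np.array([[m1], [m2]]),
        np.array([[t1], [t2]]),
    )


class TestLikelihoodRatioTest:
    def test_worked_example_80_vs_20(self, layout):
        # closed-form oracle: G = 2[ll(80,20) + ll(20,80) - ll(100,100)]
        def ll(m, u):
            t = m + u
            return (m * np.log(m / t) if m else 0.0) + (u * np.log(u / t) if u else 0.0)

        expected = 2 * (ll(80, 20) + ll(20, 80) - ll(100, 100))
        assert binomial_lrt(80, 100, 20, 100) == pytest.approx(expected, abs=1e-9)
        assert binomial_lrt(80, 100, 20, 100) == pytest.approx(77.0979028, abs=1e-6)
        res = run_tile_test(two_sample_table(80, 100, 20, 100, layout), ["a"], ["b"])
        assert res.loc[0, "lrt"] == pytest.approx(expected, abs=1e-9)
        assert res.loc[0, "diff"] == pytest.approx(60.0)

    def test_identical_groups_null(self, layout):
        res = run_tile_test(two_sample_table(30, 100, 30, 100, layout), ["a"], ["b"])
        assert res.loc[0, "lrt"] == 0.0
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "diff"] == 0.0

    def test_complete_separation(self, layout):
        # 100/100 vs 0/100: G = 2 * 200 * ln 2
        assert binomial_lrt(100, 100, 0, 100) == pytest.approx(
            400 * np.log(2), abs=1e-9
        )
        res = run_tile_test(two_sample_table(100, 100, 0, 100, layout), ["a"], ["b"])
        assert res.loc[0, "diff"] == pytest.approx(100.0)
        assert res.loc[0, "p"] < 1e-20

    def test_matches_statsmodels_binomial_glm(self, layout):
        # independent route: logistic GLM with a binary group covariate,
        # LRT from the deviance difference against the intercept model
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = rng.integers(10, 80, size=4)
            m = rng.binomial(t, [0.3, 0.35, 0.6, 0.55])
            endog = np.column_stack([m, t - m]).astype(float)
            g = np.array([0, 0, 1, 1])
            full = sm.GLM(endog, sm.add_constant(g), family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((4, 1)), family=sm.families.Binomial()).fit()
            lrt_glm = null.deviance - full.deviance
            ours = binomial_lrt(m[:2].sum(), t[:2].sum(), m[2:].sum(), t[2:].sum())
            assert ours == pytest.approx(lrt_glm, abs=1e-6)

    def test_swapping_groups_negates_diff_preserves_p(self, layout):
        table = two_sample_table(70, 90, 25, 80, layout)
        ab = run_tile_test(table, ["a"], ["b"])
        ba = run_tile_test(table, ["b"], ["a"])
        assert ab.loc[0, "p"] == ba.loc[0, "p"]
        assert ab.loc[0, "diff"] == pytest.approx(-ba.loc[0, "diff"])

    def test_coverage_gate_excludes_uncovered_sample(self, layout, make_sample_factory):
        a = make_sample_factory(layout, [("chr1", 100, 5, 20), ("chr1", 600, 5, 20)], "a")
        b = make_sample_factory(layout, [("chr1", 600, 5, 20)], "b")
        table = build_tiles([a, b], layout)
        res = run_tile_test(table, ["a"], ["b"])
        assert res["start"].tolist() == [500]

    def test_empty_group_rejected(self, layout):
        with pytest.raises(ValidationError):
            run_tile_test(two_sample_table(1, 10, 1, 10, layout), [], ["b"])


class TestAdjustQ:
    def test_single_p(self):
        assert adjust_q([0.04]).tolist() == [0.04]

    def test_bh_by_hand(self):
        # p = {.01,.02,.03,.04}: q_i = min over j>=i of p_j * 4 / j = .04
        q = adjust_q([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert adjust_q([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_q_monotone_in_p_rank_and_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = adjust_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_pi0_variant_never_larger_than_bh(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(size=50), rng.uniform(0, 1e-4, size=10)])
        assert (adjust_q(p, method="bh_pi0") <= adjust_q(p) + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_q([0.0, 0.5])


class TestCallDmrs:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "p", "q", "diff"]
        )

    def test_gain_and_loss_partition_whole(self):
        res = self.frame(
            [
                ("chr1", 0, 500, 1e-4, 0.005, 6.0),
                ("chr1", 500, 1000, 1e-4, 0.005, -8.0),
                ("chr1", 1000, 1500, 0.5, 0.9, 30.0),
            ]
        )
        calls = call_dmrs(res, q_cutoff=0.01)
        assert len(calls["whole"]) == 2
        assert len(calls["gain"]) == 1 and len(calls["loss"]) == 1
        merged = pd.concat([calls["gain"], calls["loss"]]).sort_index()
        assert merged.equals(calls["whole"])

    def test_exact_cutoffs_are_strict(self):
        res = self.frame(
            [
                ("chr1", 0, 500, 1e-4, 0.005, 5.0),   # |diff| not > 5
                ("chr1", 500, 1000, 1e-4, 0.01, 8.0),  # q not < 0.01
            ]
        )
        calls = call_dmrs(res, q_cutoff=0.01)
        assert len(calls["whole"]) == 0

    def test_null_simulation_rare_false_calls(self):
        # ~100 null tiles, 3 vs 3 at coverage 10: expect 0-1 DMRs at q<0.01
        layout = default_layout(1, 50_000)
        false_calls = []
        for seed in range(3):
            design = SimulationDesign(layout=layout, n_samples_per_group=3, seed=seed)
            samples, _ = simulate_methylomes(design)
            table = build_tiles(samples, layout)
            ids = [s.sample_id for s in samples]
            res = run_tile_test(table, ids[:3], ids[3:])
            false_calls.append(len(call_dmrs(res, q_cutoff=0.01)["whole"]))
        assert max(false_calls) <= 1


def test_planted_difference_recovery():
    layout = default_layout(1, 500_000)
    tiles = [
        PlantedDmrTile(GenomicInterval("chr1", 50_000 + 5_000 * i, 50_500 + 5_000 * i), 0.75, 0.45)
        for i in range(30)
    ]
    design = SimulationDesign(
        layout=layout, coverage_mean=20, planted_dmr_tiles=tiles,
        n_samples_per_group=3, seed=8,
    )
    samples, truth = simulate_methylomes(design)
    table = build_tiles(samples, layout)
    ids = [s.sample_id for s in samples]
    res = run_tile_test(table, ids[:3], ids[3:])
    calls = call_dmrs(res, q_cutoff=0.01)
    called = set(zip(calls["whole"]["chrom"], calls["whole"]["start"]))
    planted = {(t.interval.chrom, t.interval.start) for t in truth.dmr_tiles}
    recall = len(called & planted) / len(planted)
    assert recall >= 0.8
    # planted gains must be called as gains
    gains = set(zip(calls["gain"]["chrom"], calls["gain"]["start"]))
    assert called & planted == gains & planted
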