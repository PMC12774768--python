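"""Zipcode-correlation mapping, smoothing and the version-2 rules."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scst.geometry import PositionalAddress
from scst.mapping import (
    MappingParams,
    map_cell_v2,
    map_cells,
    smooth_position,
    srcc_profile,
    weighted_geometric_median,
)
from scst import synthetic


def _addr(name, coord, layer="ectoderm", stage="S"):
    section = int("".join(ch for ch in name if ch.isdigit()) or 0)
    sector = "".join(ch for ch in name if not ch.isdigit())
    return PositionalAddress(stage, section, sector, layer, tuple(map(float, coord)))


def grid_search_median(anchors, weights, rounds=6, pts=21):
    """Multi-resolution dense grid minimizer of the weighted sum of
    distances; independent oracle for the smoothing consensus point."""
    anchors = np.asarray(anchors, float)
    weights = np.asarray(weights, float)
    lo = anchors.min(axis=0) - 0.5
    hi = anchors.max(axis=0) + 0.5
    center = (lo + hi) / 2
    width = (hi - lo).max() + 1e-6
    best = None
    for _ in range(rounds):
        axes = [np.linspace(center[d] - width / 2, center[d] + width / 2, pts) for d in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts_xyz = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        d = np.linalg.norm(pts_xyz[:, None, :] - anchors[None, :, :], axis=2)
        f = (d * weights).sum(axis=1)
        i = int(f.argmin())
        best = pts_xyz[i]
        center = best
        width = 4.0 * width / (pts - 1)
    return best


class TestSrccProfile:
    def test_copy_of_reference_row_gives_one(self, small_atlas):
        atlas, _ = small_atlas
        cell = atlas.expression.iloc[5].rename("q")
        profile = srcc_profile(cell, atlas)
        assert profile.iloc[5] == pytest.approx(1.0)
        assert profile.idxmax() == atlas.position_names[5]

    def test_reversed_ranks_give_minus_one(self, small_atlas):
        atlas, _ = small_atlas
        row = atlas.expression.iloc[3]
        reversed_cell = pd.Series(-row.to_numpy(), index=row.index, name="q")
        assert srcc_profile(reversed_cell, atlas).iloc[3] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, small_atlas):
        atlas, _ = small_atlas
        rng = np.random.default_rng(0)
        cell = pd.Series(rng.normal(2, 1, atlas.expression.shape[1]),
                         index=atlas.genes, name="q")
        profile = srcc_profile(cell, atlas)
        zc = atlas.zipcodes
        for i in [0, 7, 19]:
            rho, _ = scipy.stats.spearmanr(cell[zc], atlas.expression.iloc[i][zc])
            assert profile.iloc[i] == pytest.approx(rho)

    def test_constant_position_recorded_missing(self, small_atlas):
        atlas, _ = small_atlas
        broken = atlas.expression.copy()
        broken.iloc[2] = 1.0
        atlas2 = type(atlas)(expression=broken, addresses=atlas.addresses,
                             zipcodes=atlas.zipcodes)
        cell = broken.iloc[5].rename("q")
        profile = srcc_profile(cell, atlas2)
        assert np.isnan(profile.iloc[2])

    def test_too_few_shared_genes_rejected(self, small_atlas):
        atlas, _ = small_atlas
        cell = pd.Series([1.0, 2.0], index=["g0000", "g0001"], name="q")
        with pytest.raises(ValueError, match="zipcode genes shared"):
            srcc_profile(cell, atlas)


class TestSmoothing:
    def test_identical_anchor_coordinates(self):
        coord = (1.0, 2.0, 3.0)
        top = [(_addr(f"{i}P", coord), 0.5) for i in range(3)]
        p0, assigned, _, _ = smooth_position(top, gate_threshold=0.1)
        assert p0 == pytest.approx(coord)
        assert assigned.coordinate == coord

    def test_consensus_matches_grid_search(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            anchors = rng.uniform(-3, 3, (3, 3))
            weights = rng.uniform(0.2, 1.0, 3)
            top = [(_addr(f"{i}P", a), w) for i, (a, w) in enumerate(zip(anchors, weights))]
            p0, _, _, trace = smooth_position(top, gate_threshold=np.inf)
            assert trace == ["smoothed"]
            oracle = grid_search_median(anchors, weights)
            assert np.linalg.norm(np.array(p0) - oracle) < 1e-3

    def test_wide_gap_skips_smoothing(self):
        top = [
            (_addr("1P", (0, 0, 1)), 0.9),
            (_addr("5P", (0, 0, 5)), 0.7),
            (_addr("9P", (0, 0, 9)), 0.6),
        ]
        p0, assigned, delta, trace = smooth_position(top, gate_threshold=0.1)
        assert delta == pytest.approx((0.9 - 0.7) / 0.9)
        assert trace == ["high_confidence"]
        assert assigned.name == "1P"

    def test_all_nonpositive_falls_back_to_top1(self):
        top = [(_addr(f"{i}P", (i, 0, i)), s) for i, s in enumerate([-0.1, -0.2, -0.5], 1)]
        with pytest.warns(UserWarning, match="no positive SRCC"):
            _, assigned, delta, trace = smooth_position(top, gate_threshold=0.1)
        assert assigned.name == "1P"
        assert delta is None

    def test_median_pulled_toward_heavier_anchor(self):
        anchors = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        near = weighted_geometric_median(anchors, np.array([10.0, 1.0, 1.0]))
        assert np.linalg.norm(near - anchors[0]) < 1e-6  # dominant weight wins


class TestV2Rules:
    def test_noiseless_cells_map_perfectly(self, small_atlas):
        atlas, truth = small_atlas
        cells, ct = synthetic.make_cells(atlas, truth, 1, noise_sigma=0.0, seed=1)
        results = map_cells(cells, atlas)
        assert all(r.assigned.name == ct.cell_addresses[r.cell_id] for r in results)

    def test_layer_rule_restricts_top_positions(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=1.5, seed=2)
        results = map_cells(cells, atlas)
        for r in results:
            top_layer = r.top_positions[0][0].layer
            assert all(a.layer == top_layer for a, _ in r.top_positions)
            assert f"layer:{top_layer}" in r.rule_trace

    def test_dispersed_top3_and_section_override(self):
        """A cell torn between section 1 and sections 5-6 triggers the
        top-5 dispersion fallback; when the smoothed point then lands far
        from the best-correlated section, the argmax position wins."""
        from scst.geometry import EmbryoModelConfig, enumerate_addresses
        from scst.zipcodes import ReferenceAtlas

        cfg = EmbryoModelConfig(
            stage="S", proximal_distal_length=6.0, n_sections=6,
            layer_diameters={"ectoderm": 2.0},
            sector_schemes={"ectoderm": [("P", 0.0)]},
            ectoderm_inner_radius=0.0,
        )
        addrs = enumerate_addresses(cfg)
        rng = np.random.default_rng(0)
        g = 30
        base_a, base_b = rng.normal(0, 1, g), rng.normal(0, 1, g)
        rows = []
        for a in addrs:
            if a.section == 1:
                rows.append(base_a)
            elif a.section in (5, 6):
                rows.append(base_b + rng.normal(0, 0.05, g))
            else:
                rows.append(rng.normal(0, 1, g))
        genes = [f"g{i}" for i in range(g)]
        atlas = ReferenceAtlas(
            expression=pd.DataFrame(rows, index=[a.name for a in addrs], columns=genes),
            addresses=addrs, zipcodes=genes,
        )
        cell = pd.Series(0.53 * base_a + 0.47 * base_b, index=genes, name="q")
        result = map_cell_v2(cell, atlas)
        assert "top5_fallback" in result.rule_trace
        assert "section_override" in result.rule_trace
        assert result.assigned.name == "1P"  # the argmax-SRCC position
        assert result.top_positions[0][0].name == "1P"
        # the smoothed point itself sits in the far group that was rejected
        assert result.smoothed_point[2] > 4.0

    def test_dispersion_never_fires_for_adjacent_top3(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=1.0, seed=3)
        for r in map_cells(cells, atlas):
            sections = [a.section for a, _ in r.top_positions[:3]]
            if max(sections) - min(sections) <= 1:
                assert "top5_fallback" not in r.rule_trace

    def test_monotone_transform_invariance(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=0.8, seed=4)
        cell = cells.iloc[:, 0]
        transformed = (np.exp(0.5 * cell) + 3.0).rename(cell.name)
        r1 = map_cell_v2(cell, atlas)
        r2 = map_cell_v2(transformed, atlas)
        assert r1.assigned == r2.assigned
        assert np.allclose(r1.srcc, r2.srcc)

    def test_v2_at_least_as_accurate_as_v1_under_noise(self, small_config):
        accs = {1: [], 2: []}
        for rep in range(20):
            atlas, truth = synthetic.make_reference(
                small_config, n_genes=120, n_domains=4, markers_per_domain=10,
                seed=400 + rep,
            )
            cells, ct = synthetic.make_cells(atlas, truth, 1, noise_sigma=1.2,
                                             seed=500 + rep)
            for v in (1, 2):
                results = map_cells(cells, atlas, MappingParams(version=v))
                accs[v].append(
                    np.mean([r.assigned.name == ct.cell_addresses[r.cell_id]
                             for r in results])
                )
        assert np.mean(accs[2]) >= np.mean(accs[1])


class TestBatch:
    def test_empty_input_empty_output(self, small_atlas):
        atlas, _ = small_atlas
        assert map_cells(pd.DataFrame(index=atlas.genes), atlas) == []

    def test_batch_equals_per_cell(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=0.5, seed=5)
        sub = cells.iloc[:, :6]
        batch = map_cells(sub, atlas)
        singles = [map_cell_v2(sub[c], atlas) for c in sub.columns]
        assert [r.assigned for r in batch] == [r.assigned for r in singles]

    def test_results_invariant_to_cell_order(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=0.5, seed=6)
        sub = cells.iloc[:, :8]
        forward = {r.cell_id: r.assigned for r in map_cells(sub, atlas)}
        backward = {r.cell_id: r.assigned for r in map_cells(sub.iloc[:, ::-1], atlas)}
        assert forward == backward

    def test_per_cell_failures_collected_not_fatal(self, small_atlas):
        atlas, truth = small_atlas
        cells, _ = synthetic.make_cells(atlas, truth, 1, noise_sigma=0.5, seed=7)
        sub = cells.iloc[:, :3].copy()
        sub.iloc[:, 1] = 2.0  # constant cell: SRCC undefined everywhere
        results = map_cells(sub, atlas)
        assert len(results) == 3
        assert results[1].error is not None and results[1].assigned is None
        assert results[0].error is None and results[2].error is None
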