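"""Branch filtering, zigzag index, per-image aggregation, full pipeline."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from tjmorph import (
    BinaryMask,
    LoopBranch,
    SkeletonGraph,
    ZigzagConfig,
    build_skeleton_graph,
    filter_branches,
    generate_junction_scene,
    image_mean_zigzag,
    run_zigzag_pipeline,
    skeletonize,
    zigzag_index,
)
from tjmorph.skeleton import Branch
from tjmorph.validation import SYNTHETIC_ZIGZAG_CONFIG


def mk_branch(bid, alpha, beta, is_loop=False, endpointish=False):
    b = Branch(
        branch_id=bid,
        path_pixels=((0, 0), (0, 1)),
        end_node_a=0,
        end_node_b=0 if is_loop else 1,
        alpha_um=alpha,
        beta_um=beta,
        is_loop=is_loop,
    )
    object.__setattr__(b, "_endpointish", endpointish)
    return b


def mk_graph(branches):
    return SkeletonGraph(nodes=[], branches=branches, pixel_size_um=1.0)


class TestFilterBranches:
    def test_strict_elimination_below_2um(self):
        g = mk_graph([mk_branch(i, a, a) for i, a in enumerate([1.5, 2.0, 3.7])])
        kept = filter_branches(g, 2.0)
        assert [b.alpha_um for b in kept] == [2.0, 3.7]

    def test_zero_threshold_removes_only_loops(self):
        g = mk_graph([mk_branch(0, 1.0, 1.0), mk_branch(1, 2.0, 0.0, is_loop=True)])
        kept = filter_branches(g, 0.0)
        assert [b.branch_id for b in kept] == [0]

    def test_endpoint_terminal_exclusion(self):
        g = mk_graph(
            [mk_branch(0, 5.0, 4.0), mk_branch(1, 5.0, 4.0, endpointish=True)]
        )
        assert len(filter_branches(g, 2.0, require_junction_ends=False)) == 2
        assert len(filter_branches(g, 2.0, require_junction_ends=True)) == 1

    def test_matches_predicate_comprehension(self, rng):
        branches = [
            mk_branch(i, a, a * 0.9, is_loop=bool(l), endpointish=bool(e))
            for i, (a, l, e) in enumerate(
                zip(rng.uniform(0, 5, 50), rng.random(50) < 0.2, rng.random(50) < 0.3)
            )
        ]
        g = mk_graph(branches)
        expected = [
            b for b in branches if not b.is_loop and b.alpha_um >= 2.0 and not b._endpointish
        ]
        assert filter_branches(g, 2.0, require_junction_ends=True) == expected


class TestZigzagIndex:
    def test_straight(self):
        assert zigzag_index(mk_branch(0, 3.0, 3.0)) == 1.0

    def test_loop_raises(self):
        with pytest.raises(LoopBranch):
            zigzag_index(mk_branch(0, 3.0, 0.0, is_loop=True))

    @staticmethod
    def _index_of_curve(mask_px):
        g = build_skeleton_graph(
            skeletonize(BinaryMask(mask_px, 1.0))
        )
        contacts = filter_branches(g, 0.0, require_junction_ends=False)
        assert len(contacts) == 1
        return zigzag_index(contacts[0])

    def test_semicircle_analytic_branch(self):
        """Contract level: α = πr over β = 2r gives exactly π/2."""
        r = 80.0
        assert zigzag_index(mk_branch(0, np.pi * r, 2 * r)) == pytest.approx(
            np.pi / 2, rel=1e-12
        )

    def test_semicircle_rasterized_digital_length(self):
        """Rasterized arc: the 8-connected step metric measures the digital
        perimeter, 4(√2−1) ≈ 1.657 per chord — π/2 inflated by the known
        ≈5.5% digital-arc-length bias (thinning corner-cuts part of it)."""
        r = 80
        yy, xx = np.mgrid[0:110, 0:180]
        d = np.hypot(yy - 100.0, xx - 90.0)
        band = (np.abs(d - r) <= 1.5) & (yy <= 100)
        idx = self._index_of_curve(band)
        assert np.pi / 2 < idx <= 4 * (np.sqrt(2) - 1) * 1.005

    def test_right_angle_l_analytic(self):
        a = 120
        m = np.zeros((a + 6, a + 6), bool)
        m[3, 3 : 3 + a] = True  # horizontal leg
        m[3 : 3 + a, 3] = True  # vertical leg
        idx = self._index_of_curve(m)
        assert idx == pytest.approx(np.sqrt(2), rel=0.02)


class TestImageMean:
    def test_simple_mean(self):
        contacts = [mk_branch(i, a, 1.0) for i, a in enumerate([1.0, 1.5, 2.0])]
        rep = image_mean_zigzag(contacts)
        assert rep.image_mean_zigzag == pytest.approx(1.5)
        assert rep.n_contacts == 3

    def test_single_contact(self):
        rep = image_mean_zigzag([mk_branch(0, 2.2, 2.0)])
        assert rep.image_mean_zigzag == pytest.approx(1.1)

    def test_empty_flagged(self):
        with pytest.warns(UserWarning):
            rep = image_mean_zigzag([])
        assert rep.n_contacts == 0
        assert np.isnan(rep.image_mean_zigzag)


class TestPipeline:
    def test_straight_scene_near_unity(self, small_scene_params):
        params = dataclasses.replace(
            small_scene_params, ruffle_amplitude_um=0.0, noise_model="none"
        )
        scene = generate_junction_scene(params)
        rep = run_zigzag_pipeline(scene.image, SYNTHETIC_ZIGZAG_CONFIG)
        assert rep.n_contacts > 0
        assert 1.0 <= rep.image_mean_zigzag <= 1.08

    def test_scale_invariance_of_index(self):
        """Rescaling pixel size leaves every zigzag index unchanged."""
        rng = np.random.default_rng(3)
        blob = ndi.gaussian_filter(rng.normal(size=(64, 64)), 2.5)
        mask = blob > np.quantile(blob, 0.6)
        idx = {}
        for px in (1.0, 3.0):
            g = build_skeleton_graph(skeletonize(BinaryMask(mask, px)))
            contacts = filter_branches(g, 0.0)
            idx[px] = sorted(zigzag_index(b) for b in contacts)
        assert idx[1.0] == pytest.approx(idx[3.0])

    def test_report_csv_roundtrip(self, tmp_path, small_scene):
        rep = run_zigzag_pipeline(small_scene.image, SYNTHETIC_ZIGZAG_CONFIG)
        out = tmp_path / "report.csv"
        rep.to_csv(out)
        import pandas as pd

        table = pd.read_csv(out)
        assert table.iloc[-1]["branch_id"] == "image_mean"
        assert len(table) == rep.n_contacts + 1
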