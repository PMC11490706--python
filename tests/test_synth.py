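"""Synthetic junction scenes: geometry, ground truth, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.integrate import quad

from tjmorph import (
    DegenerateEdge,
    SceneParams,
    amplitude_for_tortuosity,
    generate_coloc_pair,
    generate_junction_scene,
    pearson,
    ruffle_edge,
    scene_ground_truth,
)
from tjmorph.synth import _rasterize_polylines


class TestRuffleEdge:
    def test_zero_amplitude_is_straight(self):
        poly, tort = ruffle_edge((0, 0), (10, 0), 0.0, 2.0, n_points=512)
        assert tort == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(poly[:, 1], 0.0)

    def test_endpoints_pinned(self):
        poly, _ = ruffle_edge((1, 2), (7, -3), 0.5, 2.0, n_points=777, phase_seed=4)
        assert np.allclose(poly[0], [1, 2])
        assert np.allclose(poly[-1], [7, -3])

    def test_tortuosity_increases_with_amplitude(self):
        torts = [
            ruffle_edge((0, 0), (10, 0), a, 2.0, n_points=4096, phase_seed=7)[1]
            for a in (0.1, 0.3, 0.6)
        ]
        assert torts[0] < torts[1] < torts[2]
        assert all(t >= 1.0 for t in torts)

    def test_arc_mode_is_semicircle(self):
        _, tort = ruffle_edge((0, 0), (10, 0), 0.0, 2.0, n_points=4096, mode="arc")
        assert tort == pytest.approx(np.pi / 2, rel=1e-5)

    def test_quadrature_against_independent_integral(self):
        """Polyline arc length vs adaptive quadrature of the analytic speed."""
        A, lam, L = 0.4, 1.7, 9.0
        poly, tort = ruffle_edge((0, 0), (L, 0), A, lam, n_points=4096, phase_seed=5)
        phase = float(np.random.default_rng(5).uniform(0, 2 * np.pi))

        def dprime(s):
            w = np.sin(np.pi * s / L) ** 2
            wp = 2 * np.sin(np.pi * s / L) * np.cos(np.pi * s / L) * np.pi / L
            g = np.sin(2 * np.pi * s / lam + phase)
            gp = np.cos(2 * np.pi * s / lam + phase) * 2 * np.pi / lam
            return A * (gp * w + g * wp)

        arc, _ = quad(lambda s: np.hypot(1.0, dprime(s)), 0, L, limit=200)
        assert tort == pytest.approx(arc / L, rel=1e-3)

    def test_coincident_endpoints_raise(self):
        with pytest.raises(DegenerateEdge):
            ruffle_edge((3, 3), (3, 3), 0.1, 2.0)


class TestAmplitudeInversion:
    def test_round_trip(self):
        a = amplitude_for_tortuosity(1.25, 2.0, chord_um=8.0)
        poly, tort = ruffle_edge((0, 0), (8, 0), a, 2.0, n_points=4096, phase_seed=0)
        # the inversion runs at phase 0; re-derive with the same phase
        phase0 = 0.0
        from tjmorph.synth import _arc_length, _ruffle_polyline

        p = _ruffle_polyline(
            np.array([0.0, 0.0]), np.array([8.0, 0.0]), a, 2.0, 4096, phase0, "sine"
        )
        assert _arc_length(p) / 8.0 == pytest.approx(1.25, rel=1e-4)

    def test_zero_target(self):
        assert amplitude_for_tortuosity(1.0, 2.0) == 0.0


class TestGenerateScene:
    def test_seeded_determinism(self, small_scene_params):
        s1 = generate_junction_scene(small_scene_params)
        s2 = generate_junction_scene(small_scene_params)
        assert np.array_equal(s1.image.pixels, s2.image.pixels)
        assert s1.truth.to_json() == s2.truth.to_json()

    def test_straight_scene_truth_is_unity(self, small_scene_params):
        params = dataclasses.replace(small_scene_params, ruffle_amplitude_um=0.0)
        truth = scene_ground_truth(params)
        assert truth.edges
        assert all(e.tortuosity == pytest.approx(1.0, abs=1e-9) for e in truth.edges)

    def test_truth_invariants(self, small_scene):
        for e in small_scene.truth.edges:
            assert e.tortuosity >= 1.0 - 1e-12
            assert e.tortuosity == pytest.approx(
                e.path_length_um / e.chord_um, rel=1e-12
            )

    def test_tricellular_nodes_have_degree_three(self, small_scene):
        degrees = [n.degree for n in small_scene.truth.nodes]
        assert degrees and all(d == 3 for d in degrees)

    def test_signal_confined_to_polylines(self, small_scene_params):
        params = dataclasses.replace(
            small_scene_params, noise_model="none", background_intensity=0.0
        )
        scene = generate_junction_scene(params)
        line = _rasterize_polylines(
            scene.truth.polylines_px, scene.image.pixels.shape
        )
        dist = ndi.distance_transform_edt(~line)
        limit = params.line_width_px / 2 + 4 * params.psf_sigma_px + 1
        nz = scene.image.pixels > 1e-9
        assert dist[nz].max() <= limit

    def test_image_shape_and_zstack(self, small_scene_params):
        params = dataclasses.replace(small_scene_params, n_slices=4)
        scene = generate_junction_scene(params)
        assert scene.image.pixels.shape == (4, 512, 512)
        assert (scene.image.pixels >= 0).all()

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            SceneParams(n_cells=1)


class TestColocPair:
    def test_full_sharing_is_identity(self, small_scene):
        pair = generate_coloc_pair(small_scene, 1.0, 0.0, (0, 0), seed=0)
        assert np.array_equal(pair.channel_a.pixels, pair.channel_b.pixels)
        assert pair.expected_r_regime == "high"

    def test_zero_sharing_decorrelates(self, small_scene):
        pair = generate_coloc_pair(small_scene, 0.0, 5.0, (0, 0), seed=0)
        assert pair.expected_r_regime == "low"
        assert abs(pearson(pair.channel_a, pair.channel_b)) < 0.05

    def test_shift_reduces_correlation(self, small_scene):
        pair0 = generate_coloc_pair(small_scene, 1.0, 2.0, (0, 0), seed=4)
        pair_shift = generate_coloc_pair(small_scene, 1.0, 2.0, (20, 0), seed=4)
        r0 = pearson(pair0.channel_a, pair0.channel_b)
        r_shift = pearson(pair_shift.channel_a, pair_shift.channel_b)
        assert r0 > r_shift

    def test_oversized_shift_raises(self, small_scene):
        with pytest.raises(ValueError):
            generate_coloc_pair(small_scene, 1.0, 0.0, (600, 0), seed=0)
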