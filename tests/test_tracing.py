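"""Cylinder-template correlation and greedy fibre tracing.

Template parameters are scaled to the small test volumes (the defaults
target full-size tomograms); thresholds keep the 0.8 continuation/start
ratio of the defaults.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fibredvc.fibres import FibrePolyline
from fibredvc.phantom import PhantomConfig, generate_volume, lamella_boundaries
from fibredvc.tracing import (
    CylinderTemplateParams,
    TraceParams,
    _cylinder_template,
    cylinder_correlate,
    hemisphere_directions,
    label_lamellae,
    trace_fibres,
)
from fibredvc.volume import Volume

SMALL_CYL = CylinderTemplateParams(length_vox=15, angular_sampling_deg=15.0, mask_radius_vox=4.0, outer_radius_vox=2.0, erosion_vox=4)
SMALL_TRACE = TraceParams(min_start_score=0.5, min_continuation_score=0.4, step_vox=1.0, max_turn_deg=30.0, min_length_vox=10.0)


def make_tube(shape, p0, d, sigma=1.5, amp=1.0):
    d = np.asarray(d, dtype=float)
    d /= np.linalg.norm(d)
    X, Y, Z = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    rel = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
    ax = rel @ d
    rad2 = (rel**2).sum(-1) - ax**2
    return amp * np.exp(-rad2 / (2 * sigma**2))


class TestParamValidation:
    def test_template_geometry_constraints(self):
        with pytest.raises(ValueError, match="outer_radius"):
            CylinderTemplateParams(outer_radius_vox=6.0, mask_radius_vox=5.0).validate()
        with pytest.raises(ValueError, match="length_vox"):
            CylinderTemplateParams(length_vox=10, mask_radius_vox=5.0).validate()
        with pytest.raises(ValueError, match="erosion"):
            CylinderTemplateParams(erosion_vox=3, mask_radius_vox=5.0).validate()

    def test_trace_threshold_ordering(self):
        with pytest.raises(ValueError, match="min_continuation"):
            TraceParams(min_start_score=0.4, min_continuation_score=0.5).validate()

    def test_template_larger_than_volume_rejected(self):
        with pytest.raises(ValueError, match="not larger"):
            cylinder_correlate(Volume(np.zeros((12, 12, 12))), SMALL_CYL)


@pytest.fixture(scope="module")
def tube_response():
    data = make_tube((48, 48, 48), (24, 24, 24), (1, 0, 0))
    return cylinder_correlate(Volume(data, 1.0), SMALL_CYL)


class TestCylinderCorrelate:

    def test_score_peaks_on_tube_axis(self, tube_response):
        score, _ = tube_response
        on_axis = score[24, 24, 24]
        off = max(score[24, 32, 24], score[24, 24, 32], score[24, 33, 33])
        assert on_axis > 0.5
        assert on_axis > off  # >= 2x mask radius away

    def test_direction_recovered_within_one_angular_bin(self, tube_response):
        _, dirs = tube_response
        d = dirs[:, 24, 24, 24]
        angle = np.degrees(np.arccos(min(1.0, abs(d[0]))))
        assert angle <= SMALL_CYL.angular_sampling_deg

    def test_uniform_volume_scores_zero(self):
        score, _ = cylinder_correlate(Volume(np.full((40, 40, 40), 7.0), 1.0), SMALL_CYL)
        assert np.abs(score).max() == 0.0

    def test_boundary_shell_eroded(self, tube_response):
        score, _ = tube_response
        e = SMALL_CYL.erosion_vox
        assert np.abs(score[:e]).max() == 0.0
        assert np.abs(score[:, :, -e:]).max() == 0.0

    def test_tilted_tube_direction_matches_fine_angle_oracle(self):
        th = np.radians(30.0)
        true_d = np.array([np.cos(th), 0.0, np.sin(th)])
        data = make_tube((48, 48, 48), (24, 24, 24), true_d)
        _, dirs = cylinder_correlate(Volume(data, 1.0), SMALL_CYL)
        found = dirs[:, 24, 24, 24]
        # oracle: exhaustive fine-angle (2°) template correlation at the
        # centre voxel over a cone around the found direction
        data_n = (data - data.mean()) / data.std()
        best, best_d = -np.inf, None
        for dth in np.arange(-20.0, 20.01, 2.0):
            a = th + np.radians(dth)
            cand = np.array([np.cos(a), 0.0, np.sin(a)])
            tmpl, support = _cylinder_template(cand, SMALL_CYL)
            he = [e // 2 for e in tmpl.shape]
            patch = data_n[24 - he[0] : 24 + he[0] + 1, 24 - he[1] : 24 + he[1] + 1, 24 - he[2] : 24 + he[2] + 1]
            sup = support.astype(bool)
            local = patch[sup] - patch[sup].mean()
            denom = np.sqrt((local**2).sum())
            if denom > 0:
                c = float((tmpl[sup] * local).sum() / denom)
                if c > best:
                    best, best_d = c, cand
        oracle_angle = np.degrees(np.arccos(min(1.0, abs(best_d @ true_d))))
        found_angle = np.degrees(np.arccos(min(1.0, abs(found @ true_d))))
        assert oracle_angle <= 2.0
        assert found_angle <= SMALL_CYL.angular_sampling_deg

    def test_gain_and_offset_invariance(self):
        data = make_tube((40, 40, 40), (20, 20, 20), (1, 0, 0))
        s1, _ = cylinder_correlate(Volume(data, 1.0), SMALL_CYL)
        s2, _ = cylinder_correlate(Volume(3.5 * data + 120.0, 1.0), SMALL_CYL)
        np.testing.assert_allclose(s1, s2, atol=1e-5)  # FFT round-off only

    def test_hemisphere_covers_orientations_once(self):
        dirs = hemisphere_directions(15.0)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0)
        # no antipodal duplicates: all pairwise dot products > -1 + eps
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, 0.0)
        assert dots.min() > -0.999


class TestTraceFibres:
    def test_two_separated_tubes_give_two_full_traces(self):
        shape = (48, 48, 48)
        data = make_tube(shape, (24, 16, 24), (1, 0, 0)) + make_tube(shape, (24, 32, 24), (1, 0, 0))
        score, dirs = cylinder_correlate(Volume(data, 1.0), SMALL_CYL)
        fibres = trace_fibres(score, dirs, SMALL_TRACE, voxel_size=1.0)
        assert len(fibres) == 2
        usable = 48 - 2 * SMALL_CYL.erosion_vox  # eroded shell cannot be traced
        for fb in fibres:
            assert fb.length >= 0.9 * usable
            assert fb.vertices[:, 1].std() < 1.0  # stays on its own tube

    def test_impossible_start_threshold_gives_zero_traces(self):
        rng = np.random.default_rng(0)
        data = make_tube((40, 40, 40), (20, 20, 20), (1, 0, 0)) + 0.1 * rng.normal(size=(40, 40, 40))
        score, dirs = cylinder_correlate(Volume(data, 1.0), SMALL_CYL)
        hard = TraceParams(min_start_score=1.0, min_continuation_score=0.4, step_vox=1.0, max_turn_deg=30.0, min_length_vox=10.0)
        assert trace_fibres(np.minimum(score, 0.999), dirs, hard, voxel_size=1.0) == []

    def test_empty_score_volume_gives_empty_list(self):
        assert trace_fibres(np.zeros((0, 0, 0)), np.zeros((3, 0, 0, 0)), SMALL_TRACE) == []

    def test_traces_disjoint(self):
        shape = (48, 48, 48)
        data = make_tube(shape, (24, 16, 24), (1, 0, 0)) + make_tube(shape, (24, 32, 24), (1, 0, 0))
        score, dirs = cylinder_correlate(Volume(data, 1.0), SMALL_CYL)
        fibres = trace_fibres(score, dirs, SMALL_TRACE, voxel_size=1.0)
        seen = set()
        for fb in fibres:
            for v in np.round(fb.vertices).astype(int):
                assert tuple(v) not in seen
                seen.add(tuple(v))


@pytest.fixture(scope="module")
def traced_phantom():
    cfg = PhantomConfig(
        grid_shape=(64, 64, 64), n_lamellae=2, lamella_thickness=30.0, fibre_spacing=10.0,
        noise_sd=3000.0, depth_margin=8, rng_seed=7,
    )
    vol, truth = generate_volume(cfg)
    score, dirs = cylinder_correlate(vol, SMALL_CYL)
    traces = trace_fibres(score, dirs, SMALL_TRACE, voxel_size=cfg.voxel_size)
    return cfg, truth, traces


class TestPhantomRecall:

    def test_recall_of_true_fibres_at_default_noise(self, traced_phantom):
        """>= 90% of interior true centrelines matched within the mask radius
        (nearest-centreline assignment oracle on the ground-truth table)."""
        cfg, truth, traces = traced_phantom
        assert truth.fibre_table.fibre.nunique() >= 50
        all_pts = np.vstack([fb.vertices for fb in traces])
        tree = cKDTree(all_pts)
        matched = total = 0
        for fb_true in truth.polylines:
            v = fb_true.vertices / cfg.voxel_size
            interior = np.all((v >= 10) & (v <= 54), axis=1)
            if interior.sum() < 3:
                continue
            total += 1
            d, _ = tree.query(fb_true.vertices[interior])
            if (d <= SMALL_CYL.mask_radius_vox * cfg.voxel_size).mean() >= 0.5:
                matched += 1
        assert total >= 30
        assert matched / total >= 0.9

    def test_traced_chord_angles_match_lamella_angles(self, traced_phantom):
        """Coarse chord orientation of each trace within 5° of its lamella's
        fibre angle (±30° from the transverse plane here)."""
        cfg, truth, traces = traced_phantom
        errs = []
        for fb in traces:
            if fb.length < 40.0:
                continue
            chord = fb.vertices[-1] - fb.vertices[0]
            chord /= np.linalg.norm(chord)
            elev = np.degrees(np.arcsin(abs(chord[2])))
            errs.append(abs(elev - 30.0))
        assert len(errs) >= 10
        assert np.median(errs) < 5.0

    def test_lamella_labels_match_ground_truth(self, traced_phantom):
        cfg, truth, traces = traced_phantom
        bounds = lamella_boundaries(truth.config)
        labelled = label_lamellae(traces, bounds)
        # assign each trace to the true lamella of its nearest centreline
        correct = total = 0
        for fb in labelled:
            mid_y = np.median(fb.vertices[:, 1])
            true_lam = 1 + int(np.searchsorted(bounds, mid_y))
            total += 1
            correct += fb.lamella == true_lam
        assert correct == total


class TestLabelLamellae:
    def _fb(self, ys):
        verts = np.stack([np.arange(len(ys), dtype=float), np.asarray(ys, dtype=float), np.zeros(len(ys))], axis=1)
        return FibrePolyline(0, 0, verts)

    def test_no_boundaries_puts_everything_in_lamella_one(self):
        fibres = label_lamellae([self._fb([5.0] * 4)], [])
        assert fibres[0].lamella == 1

    def test_majority_rule_for_straddling_fibre(self):
        # 6 of 10 vertices below the boundary at y=10 -> lamella 1
        fb = self._fb([8, 8, 9, 9, 9, 9, 11, 11, 12, 12])
        assert label_lamellae([fb], [10.0])[0].lamella == 1
        fb2 = self._fb([8, 8, 9, 9, 11, 11, 11, 12, 12, 12])
        assert label_lamellae([fb2], [10.0])[0].lamella == 2

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            label_lamellae([self._fb([1.0] * 4)], [10.0, 5.0])
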