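"""Template alignment: objective, global/local optimization, TPS, edits."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import RBFInterpolator

from arrayquant.blob_detection import Blob
from arrayquant.errors import AlignmentError, ConfigError
from arrayquant.blob_detection import detect
from arrayquant.grid_processing import build_grid
from arrayquant.synthetic_array import SyntheticArraySpec, render_array
from arrayquant.template_alignment import (
    AlignmentResult,
    SimilarityTransform,
    alignment_objective,
    align,
    edit_template,
    fit_tps,
    global_align,
    local_refine,
    match_pairs,
)
from conftest import truth_order


def _blobs_at(points):
    return [Blob(x=float(x), y=float(y), sigma=4.0, response=1.0) for x, y in points]


IDENT = SimilarityTransform()


class TestObjective:
    def test_perfect_overlap_is_zero(self, clean_template):
        blobs = _blobs_at(clean_template.positions())
        assert alignment_objective(clean_template, IDENT, blobs) == 0.0

    def test_missing_wells_not_penalized(self, clean_template):
        pos = clean_template.positions()
        blobs = _blobs_at(pos[: int(0.7 * len(pos))])  # 30% of wells undetected
        assert alignment_objective(clean_template, IDENT, blobs) == 0.0

    def test_half_displaced_gives_half(self, clean_template):
        pos = clean_template.positions().copy()
        n = len(pos)
        pos[: n // 2] += 500.0  # far beyond any match radius
        blobs = _blobs_at(pos)
        assert alignment_objective(clean_template, IDENT, blobs) == pytest.approx(0.5)

    def test_no_blobs_scores_one(self, clean_template):
        assert alignment_objective(clean_template, IDENT, []) == 1.0


class TestGlobalAlign:
    def test_self_alignment_recovers_identity(self, clean_template):
        blobs = _blobs_at(clean_template.positions())
        res = global_align(clean_template, blobs, seed=0)
        assert res.objective <= 0.05
        assert abs(res.transform.theta) <= 0.5
        assert np.hypot(res.transform.tx, res.transform.ty) <= 2.0
        assert res.transform.scale == pytest.approx(1.0, abs=0.01)

    def test_known_transform_recovered(self, clean_template):
        rng = np.random.default_rng(5)
        truth = SimilarityTransform(
            theta=5.0, tx=20.0, ty=-10.0, scale=1.05,
            center=tuple(clean_template.positions().mean(axis=0)),
        )
        pts = truth.apply(clean_template.positions()) + rng.normal(0, 0.5, (80, 2))
        res = global_align(clean_template, _blobs_at(pts), seed=1)
        assert res.transform.theta == pytest.approx(5.0, abs=0.5)
        assert res.transform.tx == pytest.approx(20.0, abs=2.0)
        assert res.transform.ty == pytest.approx(-10.0, abs=2.0)
        assert res.transform.scale == pytest.approx(1.05, abs=0.01)

    def test_recovery_with_20pct_missing(self, clean_template):
        rng = np.random.default_rng(6)
        truth = SimilarityTransform(
            theta=-8.0, tx=-15.0, ty=25.0, scale=0.95,
            center=tuple(clean_template.positions().mean(axis=0)),
        )
        pts = truth.apply(clean_template.positions())
        keep = rng.choice(len(pts), int(0.8 * len(pts)), replace=False)
        res = global_align(clean_template, _blobs_at(pts[keep]), seed=2)
        assert res.transform.theta == pytest.approx(-8.0, abs=0.5)
        assert res.transform.tx == pytest.approx(-15.0, abs=2.0)
        assert res.transform.scale == pytest.approx(0.95, abs=0.01)

    def test_seeded_determinism(self, clean_template):
        blobs = _blobs_at(clean_template.positions() + 3.0)
        r1 = global_align(clean_template, blobs, seed=9)
        r2 = global_align(clean_template, blobs, seed=9)
        assert np.array_equal(r1.transform.params(), r2.transform.params())
        assert r1.objective == r2.objective

    def test_wrong_template_flags_failure(self, clean_template):
        rng = np.random.default_rng(10)
        junk = _blobs_at(rng.uniform(-3000, -2000, (40, 2)))
        res = global_align(clean_template, junk, seed=0)
        assert res.failed and res.objective >= 0.9


class TestLocalRefine:
    def test_gate_passes_through_bad_global(self, clean_template):
        bad = AlignmentResult(transform=IDENT, objective=0.7)
        out = local_refine(bad, clean_template, _blobs_at(clean_template.positions()))
        assert not out.refined and out.transform is bad.transform

    def test_subpixel_translation_polish(self, clean_template):
        center = tuple(clean_template.positions().mean(axis=0))
        blobs = _blobs_at(clean_template.positions())
        off = AlignmentResult(
            transform=SimilarityTransform(tx=1.5, ty=-1.2, center=center),
            objective=alignment_objective(
                clean_template, SimilarityTransform(tx=1.5, ty=-1.2, center=center), blobs
            ),
        )
        out = local_refine(off, clean_template, blobs)
        assert out.refined
        assert abs(out.transform.tx) <= 0.25 and abs(out.transform.ty) <= 0.25

    def test_never_worsens_objective(self, clean_template):
        rng = np.random.default_rng(3)
        blobs = _blobs_at(clean_template.positions() + rng.normal(0, 1.5, (80, 2)))
        start = global_align(clean_template, blobs, seed=4)
        out = local_refine(start, clean_template, blobs)
        assert out.objective <= start.objective


class TestMatchPairs:
    def test_perfect_overlap_all_paired(self, clean_template):
        blobs = _blobs_at(clean_template.positions())
        pairs = match_pairs(clean_template, IDENT, blobs)
        assert len(pairs) == len(blobs)
        assert pairs["residual"].max() == pytest.approx(0.0, abs=1e-9)

    def test_mutual_nearest_only(self, clean_template):
        # two blobs straddling one well: only the closer is paired with it
        pos = clean_template.positions()
        blobs = _blobs_at(np.vstack([pos[0] + [1.0, 0.0], pos[0] + [2.0, 0.0]]))
        pairs = match_pairs(clean_template, IDENT, blobs)
        assert len(pairs) == 1
        assert pairs["blob_id"].iloc[0] == 0

    def test_far_blob_unpaired(self, clean_template):
        blobs = _blobs_at(np.vstack([clean_template.positions(), [[5000.0, 5000.0]]]))
        pairs = match_pairs(clean_template, IDENT, blobs)
        assert len(pairs) == len(clean_template.wells)
        assert 5000.0 not in pairs["blob_x"].values


class TestTps:
    def test_identity_pairs_give_identity_warp(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 300, (15, 2))
        warp = fit_tps(src, src)
        assert np.allclose(warp.weights, 0.0, atol=1e-8)
        assert np.allclose(warp.affine, [[0, 0], [1, 0], [0, 1]], atol=1e-8)
        probe = rng.uniform(0, 300, (20, 2))
        assert np.allclose(warp.apply(probe), probe, atol=1e-6)

    def test_interpolates_sinusoidal_deformation(self):
        xs, ys = np.meshgrid(np.arange(0, 300, 30), np.arange(0, 240, 30))
        src = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        tgt = src + 2.0 * np.sin(src[:, ::-1] * 2 * np.pi / 200.0)
        warp = fit_tps(src, tgt)
        assert np.abs(warp.apply(src) - tgt).max() < 1e-6
        # off-lattice probes inside the control-point hull (no extrapolation)
        hx, hy = np.meshgrid(np.arange(45, 230, 30), np.arange(45, 190, 30))
        held = np.column_stack([hx.ravel(), hy.ravel()]).astype(float)
        held_tgt = held + 2.0 * np.sin(held[:, ::-1] * 2 * np.pi / 200.0)
        assert np.abs(warp.apply(held) - held_tgt).max() < 0.5

    def test_matches_scipy_rbf_thin_plate_oracle(self):
        rng = np.random.default_rng(7)
        src = rng.uniform(0, 200, (24, 2))
        tgt = src + rng.normal(0, 3, src.shape)
        warp = fit_tps(src, tgt)
        oracle = RBFInterpolator(src, tgt, kernel="thin_plate_spline", smoothing=0)
        probe = rng.uniform(20, 180, (40, 2))
        assert np.abs(warp.apply(probe) - oracle(probe)).max() < 1e-6

    def test_too_few_pairs_raises(self):
        src = np.random.default_rng(1).uniform(0, 100, (9, 2))
        with pytest.raises(AlignmentError):
            fit_tps(src, src)

    def test_collinear_sources_degenerate(self):
        src = np.column_stack([np.arange(12.0), np.arange(12.0) * 2 + 1])
        with pytest.raises(AlignmentError):
            fit_tps(src, src + 1.0)


class TestEndToEnd:
    def test_full_alignment_on_rendered_fixture(self, wide_margin_template):
        spec = SyntheticArraySpec(
            n_rows=8, n_cols=10, seed=21, margin=140,
            theta=6.0, tx=18.0, ty=-22.0, scale=1.04, warp_amplitude=1.5,
        )
        image, truth = render_array(spec)
        blobs = detect(image)
        res = align(wide_margin_template, blobs, seed=5)
        assert res.warp is not None and res.refined
        pred = res.predict(wide_margin_template.positions())
        err = np.linalg.norm(pred - truth.positions[truth_order(truth)], axis=1)
        assert (err < 1.0).mean() >= 0.99

    def test_objective_stays_in_unit_interval(self, wide_margin_template):
        spec = SyntheticArraySpec(n_rows=8, n_cols=10, seed=22, margin=140, theta=-4.0)
        image, _ = render_array(spec)
        res = align(wide_margin_template, detect(image), seed=6)
        assert 0.0 <= res.objective <= 1.0


class TestEditTemplate:
    def test_invert_is_involution(self, clean_template):
        twice = edit_template(edit_template(clean_template, "invert_orientation"),
                              "invert_orientation")
        assert twice.wells.reset_index(drop=True).equals(
            clean_template.wells.reset_index(drop=True)
        )

    def test_invert_relabels_corners(self, clean_blobs):
        template, _ = build_grid(clean_blobs, control_spec={"A1": "pos"})
        flipped = edit_template(template, "invert_orientation")
        # the physical well once called A1 is now the last label
        assert flipped.control_wells("pos") == ["H10"]
        orig_a1 = template.wells.set_index("label").loc["A1", ["x", "y"]].astype(float)
        new_h10 = flipped.wells.set_index("label").loc["H10", ["x", "y"]].astype(float)
        assert np.allclose(orig_a1.values, new_h10.values)

    def test_add_well_extends_lattice_consistently(self, clean_template):
        grown = edit_template(clean_template, "add_well", label="I1")
        assert grown.n_rows == 9
        i1 = grown.wells.set_index("label").loc["I1"]
        h1 = clean_template.wells.set_index("label").loc["H1"]
        g1 = clean_template.wells.set_index("label").loc["G1"]
        pitch_y = h1["y"] - g1["y"]
        assert i1["y"] - h1["y"] == pytest.approx(pitch_y, abs=0.2)

    def test_add_duplicate_and_remove_missing_rejected(self, clean_template):
        with pytest.raises(ConfigError):
            edit_template(clean_template, "add_well", label="A1")
        with pytest.raises(ConfigError):
            edit_template(clean_template, "remove_well", label="Q40")

    def test_remove_well(self, clean_template):
        out = edit_template(clean_template, "remove_well", label="B2")
        assert "B2" not in set(out.wells["label"])
        assert len(out.wells) == len(clean_template.wells) - 1
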