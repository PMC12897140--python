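"""Grid reconstruction: rotation search, axis clustering, lines, template."""

import numpy as np
import pytest

from arrayquant.blob_detection import Blob, detect
from arrayquant.errors import ConfigError, GriddingError
from arrayquant.grid_processing import (
    GridTemplate,
    build_grid,
    build_template,
    cluster_axes,
    estimate_rotation,
    fit_grid_lines,
    intersect_lines,
    parse_label,
    well_label,
)
from arrayquant.synthetic_array import SyntheticArraySpec, render_array


def _blob(x, y, radius=6.0):
    return Blob(x=x, y=y, sigma=radius / np.sqrt(2), response=1.0)


def _lattice_blobs(n_rows=6, n_cols=8, pitch=30.0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            dx, dy = (rng.normal(0, jitter, 2) if jitter else (0.0, 0.0))
            out.append(_blob(100 + c * pitch + dx, 80 + r * pitch + dy))
    return out


class TestWellLabels:
    @pytest.mark.parametrize(
        "rc,label", [((0, 0), "A1"), ((1, 1), "B2"), ((9, 22), "J23"), ((25, 0), "Z1"), ((26, 5), "AA6")]
    )
    def test_label_round_trip(self, rc, label):
        assert well_label(*rc) == label
        assert parse_label(label) == rc


class TestRotation:
    def test_axis_aligned_grid_zero_angle_not_applied(self):
        est = estimate_rotation(_lattice_blobs())
        assert est.angle == pytest.approx(0.0, abs=0.1)
        assert not est.applied and est.confidence < 0.3

    @pytest.mark.parametrize("theta", [7.3, -12.0, 24.5])
    def test_rendered_rotation_recovered_within_grid_step(self, theta):
        spec = SyntheticArraySpec(n_rows=6, n_cols=8, theta=theta, seed=3, margin=120)
        image, _ = render_array(spec)
        est = estimate_rotation(detect(image))
        assert est.applied
        assert est.angle == pytest.approx(-theta, abs=0.1)

    def test_rotation_recovery_with_jitter(self):
        for theta in (-18.0, 9.0):
            spec = SyntheticArraySpec(
                n_rows=6, n_cols=8, theta=theta, jitter_sd=1.0, seed=4, margin=120
            )
            image, _ = render_array(spec)
            est = estimate_rotation(detect(image))
            assert est.angle == pytest.approx(-theta, abs=0.3)

    def test_out_of_range_angle_cannot_be_recovered(self):
        # 45 degrees is outside the +/-30 search window by construction
        spec = SyntheticArraySpec(n_rows=6, n_cols=8, theta=45.0, seed=5, margin=160)
        image, _ = render_array(spec)
        est = estimate_rotation(detect(image))
        assert abs(est.angle - (-45.0)) > 1.0

    def test_too_few_blobs_skips_estimation(self):
        est = estimate_rotation([_blob(i * 30.0, 0) for i in range(5)])
        assert est.angle == 0.0 and est.confidence == 0.0 and not est.applied


class TestClusterAxes:
    def test_perfect_grid_fully_assigned(self):
        blobs = _lattice_blobs(8, 10)
        rows, cols = cluster_axes(blobs)
        assert rows.max() + 1 == 8 and cols.max() + 1 == 10
        assert (rows >= 0).all() and (cols >= 0).all()
        # index equals lattice order
        expect = np.repeat(np.arange(8), 10)
        assert np.array_equal(rows, expect)

    def test_jittered_grid_same_structure(self):
        blobs = _lattice_blobs(8, 10, jitter=1.0, seed=2)
        rows, cols = cluster_axes(blobs, eps_row=10, eps_col=10)
        assert rows.max() + 1 == 8 and cols.max() + 1 == 10

    def test_stray_blob_between_rows_dropped(self):
        # a stray 12 px off a row is density-unreachable at eps 10
        blobs = _lattice_blobs(6, 8) + [_blob(115.0, 80 + 2.4 * 30)]
        rows, cols = cluster_axes(blobs, eps_row=10.0, eps_col=10.0)
        assert rows[-1] == -1  # noise on the row axis
        assert rows[:-1].max() + 1 == 6  # existing rows untouched

    def test_single_row_is_gridding_error(self):
        with pytest.raises(GriddingError):
            cluster_axes([_blob(i * 30.0, 50.0) for i in range(8)])


class TestGridLines:
    def test_collinear_row_exact_fit(self):
        blobs = [_blob(x, 100.0) for x in (0, 50, 100, 150)]
        rows, cols = np.zeros(4, int), np.arange(4)
        row_lines, _ = fit_grid_lines(blobs, rows, cols)
        assert row_lines[0].slope == pytest.approx(0.0, abs=1e-12)
        assert row_lines[0].intercept == pytest.approx(100.0)

    def test_jittered_row_slope_within_ols_bound(self):
        rng = np.random.default_rng(8)
        xs = np.linspace(0, 600, 20)
        blobs = [_blob(x, 200 + rng.normal(0, 1)) for x in xs]
        lines, _ = fit_grid_lines(blobs, np.zeros(20, int), np.arange(20))
        # sd(slope) = sigma / sqrt(sum (x - xbar)^2) ~ 0.0013; 4 sd << 0.01
        assert abs(lines[0].slope) < 0.01

    def test_vertical_column_no_singularity(self):
        blobs = [_blob(250.0, y) for y in (0, 40, 80, 120)]
        _, col_lines = fit_grid_lines(blobs, np.arange(4), np.zeros(4, int))
        assert col_lines[0].slope == pytest.approx(0.0, abs=1e-12)
        assert col_lines[0].intercept == pytest.approx(250.0)


class TestIntersections:
    def test_hand_intersection(self):
        from arrayquant.grid_processing import GridLine

        row = [GridLine("row", 0, 0.0, 100.0)]
        col = [GridLine("column", 0, 0.0, 250.0)]
        pos = intersect_lines(row, col)
        assert pos[(0, 0)] == pytest.approx((250.0, 100.0))

    def test_count_is_rows_times_cols(self):
        blobs = _lattice_blobs(8, 10)
        rows, cols = cluster_axes(blobs)
        rl, cl = fit_grid_lines(blobs, rows, cols)
        assert len(intersect_lines(rl, cl)) == 80

    def test_jittered_fixture_intersections_near_true_lattice(self):
        spec = SyntheticArraySpec(n_rows=8, n_cols=10, jitter_sd=1.0, seed=9)
        image, truth = render_array(spec)
        template, _ = build_grid(detect(image))
        order = np.lexsort((truth.cols, truth.rows))
        # jitter-free lattice: reconstruct from truth minus jitter is not
        # available, so compare to the jittered truth with a loose RMS
        err = np.linalg.norm(template.positions() - truth.positions[order], axis=1)
        assert np.sqrt((err**2).mean()) < 1.5


class TestTemplate:
    def test_labels_and_shape(self, clean_template):
        assert clean_template.n_rows == 8 and clean_template.n_cols == 10
        assert clean_template.wells["label"].iloc[0] == "A1"
        assert clean_template.wells["label"].iloc[-1] == "H10"
        assert clean_template.wells[["row", "col"]].duplicated().sum() == 0

    def test_median_radius_is_median_of_member_radii(self):
        radii = [4.0, 5.0, 6.0, 7.0, 100.0]
        blobs = [_blob(100 + 40 * i, 100 + 30 * (i % 2), r) for i, r in enumerate(radii)]
        # force a trivial 2x5 assignment
        rows = np.array([i % 2 for i in range(5)])
        cols = np.arange(5)
        rl, cl = fit_grid_lines(blobs, rows, cols)
        template = build_template(blobs, rows, cols, rl, cl)
        assert template.median_radius == pytest.approx(6.0)

    def test_save_load_round_trip_bit_identical(self, clean_template, tmp_path):
        path = tmp_path / "template.txt"
        clean_template.save(path)
        back = GridTemplate.load(path)
        assert back.n_rows == clean_template.n_rows
        assert back.median_radius == clean_template.median_radius
        assert np.array_equal(back.positions(), clean_template.positions())
        assert back.wells["label"].tolist() == clean_template.wells["label"].tolist()

    def test_control_spec_applied_and_validated(self, clean_blobs):
        template, _ = build_grid(clean_blobs, control_spec={"A1": "pos", "H10": "neg"})
        assert template.control_wells("pos") == ["A1"]
        assert template.control_wells("neg") == ["H10"]
        with pytest.raises(ConfigError):
            build_grid(clean_blobs, control_spec={"Z99": "pos"})

    def test_missing_spots_still_get_positions(self):
        # 20% of amplitudes zero: absent analytes must still be measurable
        rng = np.random.default_rng(14)
        amp = np.full((8, 10), 3000.0)
        off = rng.choice(80, 16, replace=False)
        amp.flat[off] = 0.0
        spec = SyntheticArraySpec(n_rows=8, n_cols=10, amplitudes=amp, seed=14)
        image, truth = render_array(spec)
        template, _ = build_grid(detect(image))
        assert len(template.wells) == 80
        order = np.lexsort((truth.cols, truth.rows))
        err = np.linalg.norm(template.positions() - truth.positions[order], axis=1)
        assert err.max() < 1.0

    def test_template_determinism(self, clean_blobs):
        t1, _ = build_grid(clean_blobs)
        t2, _ = build_grid(clean_blobs)
        assert t1.wells.equals(t2.wells)
        assert t1.median_radius == t2.median_radius
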