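"""Stage 3 — registering a stored grid template onto a new scan.

Three phases:

1. **Global**: differential evolution over a bounded similarity transform
   (rotation +/-15 degrees, translation +/-50 px, uniform scale +/-10%)
   maximizing centroid overlap.  The reported objective is the fraction of
   detected blobs with *no* template well within the match radius (the
   template's median spot radius), so template wells without a detection
   (absent analytes) are never penalized.
2. **Local**: bounded L-BFGS-B on a smoothed (soft-min) residual objective,
   run only when the global objective is below 0.5; gives sub-pixel
   accuracy.  Reverts if it would worsen the counting objective.
3. **Non-rigid**: a thin-plate-spline warp fitted to mutual-nearest-neighbour
   correspondences (at least 10 required) absorbs membrane distortion.

The global optimizer internally minimizes a graded version of the overlap
objective (per-blob credit 1 - d/r clipped to [0, 1]): the counting
objective is piecewise constant below the match radius, which would leave
the optimum on a plateau.  Both objectives agree at 0 (perfect overlap)
and on fully unmatched blobs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .blob_detection import Blob, blobs_xy
from .errors import AlignmentError, ConfigError
from .grid_processing import GridTemplate, parse_label, well_label

#: similarity-transform search bounds: theta (deg), tx, ty (px), scale
TRANSFORM_BOUNDS = ((-15.0, 15.0), (-50.0, 50.0), (-50.0, 50.0), (0.90, 1.10))
#: local refinement runs only below this global objective
REFINE_GATE = 0.5
#: global objective at/above this flags the template as wrong for the image
FAILURE_OBJECTIVE = 0.9
#: minimum matched pairs for a thin-plate-spline warp
MIN_TPS_PAIRS = 10


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + translation + uniform scale about a fixed center.

    Maps p -> scale * R(theta) @ (p - center) + center + (tx, ty).  The
    center is the template's well centroid, which decouples rotation from
    translation; this is a re-parameterization of a rotation about any
    other fixed point.
    """

    theta: float = 0.0  # degrees
    tx: float = 0.0
    ty: float = 0.0
    scale: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = np.deg2rad(self.theta)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        c = np.asarray(self.center)
        return self.scale * (pts - c) @ rot.T + c + np.array([self.tx, self.ty])

    def params(self) -> np.ndarray:
        return np.array([self.theta, self.tx, self.ty, self.scale])


@dataclass
class TpsWarp:
    """Thin-plate-spline map R^2 -> R^2 with kernel U(r) = r^2 log r.

    ``affine`` is 3x2 ([[a0x, a0y], [axx, axy], [ayx, ayy]]); ``weights``
    is n x 2, one weight pair per source point.  With ``lam = 0`` the warp
    interpolates the fitted correspondences exactly.
    """

    source_points: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    lam: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = _tps_kernel(_pairwise_dist(pts, self.source_points))
        return (
            self.affine[0]
            + pts @ self.affine[1:]
            + u @ self.weights
        )


@dataclass
class AlignmentResult:
    transform: SimilarityTransform
    warp: TpsWarp | None = None
    objective: float = 1.0
    matched_pairs: pd.DataFrame | None = None
    refined: bool = False
    failed: bool = False
    tps_skipped_reason: str | None = None

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Template coordinates -> image coordinates (similarity, then warp)."""
        out = self.transform.apply(points)
        if self.warp is not None:
            out = self.warp.apply(out)
        return out

    def to_json(self, path: str | Path) -> None:
        d = {
            "theta": self.transform.theta,
            "tx": self.transform.tx,
            "ty": self.transform.ty,
            "scale": self.transform.scale,
            "center": list(self.transform.center),
            "objective": self.objective,
            "refined": self.refined,
            "failed": self.failed,
            "tps_skipped_reason": self.tps_skipped_reason,
            "n_matched": 0 if self.matched_pairs is None else len(self.matched_pairs),
            "mean_residual": (
                None
                if self.matched_pairs is None or len(self.matched_pairs) == 0
                else float(self.matched_pairs["residual"].mean())
            ),
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


# ---------------------------------------------------------------------------
# objectives


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def alignment_objective(
    template: GridTemplate,
    transform: SimilarityTransform,
    blobs: list[Blob],
    match_radius: float | None = None,
) -> float:
    """Fraction of detected blobs with no transformed well within radius.

    Normalizing by the number of *detected blobs* (not template wells)
    means wells with no detection — absent analytes — cost nothing.
    Returns 1.0 when there are no blobs.
    """
    if not blobs:
        return 1.0
    r = match_radius if match_radius is not None else template.median_radius
    pos = transform.apply(template.positions())
    d, _ = cKDTree(pos).query(blobs_xy(blobs))
    return float(np.mean(d > r))


def _graded_energy(well_pos: np.ndarray, blob_xy: np.ndarray, r: float) -> float:
    d, _ = cKDTree(well_pos).query(blob_xy)
    credit = np.clip(1.0 - d / r, 0.0, 1.0)
    return float(1.0 - credit.mean())


def _softmin_energy(well_pos: np.ndarray, blob_xy: np.ndarray, temperature: float) -> float:
    k = min(4, len(well_pos))
    d, _ = cKDTree(well_pos).query(blob_xy, k=k)
    d = np.atleast_2d(d)
    soft = -temperature * logsumexp(-d / temperature, axis=1)
    return float(soft.mean())


# ---------------------------------------------------------------------------
# global + local optimization


def _make_transform(params: np.ndarray, center: tuple[float, float]) -> SimilarityTransform:
    return SimilarityTransform(
        theta=float(params[0]),
        tx=float(params[1]),
        ty=float(params[2]),
        scale=float(params[3]),
        center=center,
    )


def global_align(
    template: GridTemplate,
    blobs: list[Blob],
    seed: int = 0,
    popsize: int = 10,
    maxiter: int = 200,
    match_radius: float | None = None,
    n_starts: int = 3,
) -> AlignmentResult:
    """Differential-evolution search over the bounded similarity transform.

    Seed-controlled and reproducible.  Because a periodic grid has deep
    local minima one lattice pitch apart, up to ``n_starts`` independent
    DE runs (seeds derived from ``seed``) are taken and the best kept;
    later starts are skipped once a run ends with near-perfect overlap.
    An objective >= 0.9 after the budget flags the alignment as failed
    (wrong template for this image).
    """
    if len(blobs) < 4:
        raise AlignmentError("need at least 4 detected blobs to align")
    r = match_radius if match_radius is not None else template.median_radius
    base = template.positions()
    center = tuple(base.mean(axis=0))
    blob_pts = blobs_xy(blobs)
    # grade the search energy over half the grid pitch: a wider credit
    # slope smooths the landscape and enlarges the true basin relative to
    # one-pitch-shifted lattice optima, without changing the optimum itself
    d_nn, _ = cKDTree(base).query(base, k=2)
    pitch = float(np.median(d_nn[:, 1])) if len(base) > 1 else r
    r_search = max(r, 0.5 * pitch)

    def energy(params: np.ndarray) -> float:
        return _graded_energy(
            _make_transform(params, center).apply(base), blob_pts, r_search
        )

    best_x, best_energy = None, np.inf
    for start in range(n_starts):
        res = differential_evolution(
            energy,
            bounds=TRANSFORM_BOUNDS,
            seed=(seed + 1000003 * start) % 2**31,
            popsize=popsize,
            maxiter=maxiter,
            tol=1e-3,
            polish=False,
            init="sobol",
        )
        if res.fun < best_energy:
            best_x, best_energy = res.x, res.fun
        if best_energy <= 0.02:
            break
    transform = _make_transform(best_x, center)
    obj = alignment_objective(template, transform, blobs, r)
    return AlignmentResult(transform=transform, objective=obj, failed=obj >= FAILURE_OBJECTIVE)


def local_refine(
    result: AlignmentResult,
    template: GridTemplate,
    blobs: list[Blob],
    match_radius: float | None = None,
) -> AlignmentResult:
    """Bounded quasi-Newton polish of the global solution.

    Runs only when the global objective is below 0.5 (otherwise the input
    is passed through with ``refined=False``).  Minimizes the soft-min
    residual objective with temperature = match radius / 3; reverts if the
    counting objective would get worse.
    """
    if result.objective >= REFINE_GATE:
        return replace(result, refined=False)
    r = match_radius if match_radius is not None else template.median_radius
    base = template.positions()
    center = result.transform.center
    blob_pts = blobs_xy(blobs)
    temperature = r / 3.0

    def energy(params: np.ndarray) -> float:
        return _softmin_energy(
            _make_transform(params, center).apply(base), blob_pts, temperature
        )

    res = minimize(
        energy,
        x0=result.transform.params(),
        method="L-BFGS-B",
        bounds=TRANSFORM_BOUNDS,
    )
    refined_tf = _make_transform(res.x, center)
    new_obj = alignment_objective(template, refined_tf, blobs, r)
    if new_obj > result.objective:
        return replace(result, refined=True)  # keep the better transform
    return replace(result, transform=refined_tf, objective=new_obj, refined=True)


# ---------------------------------------------------------------------------
# correspondences and thin-plate spline


def match_pairs(
    template: GridTemplate,
    transform: SimilarityTransform,
    blobs: list[Blob],
    match_radius: float | None = None,
) -> pd.DataFrame:
    """Mutual-nearest-neighbour well/blob correspondences within radius.

    Columns: label, well_x, well_y (transformed template position),
    blob_id, blob_x, blob_y, residual.  Each well and each blob appears at
    most once.
    """
    r = match_radius if match_radius is not None else template.median_radius
    pos = transform.apply(template.positions())
    bxy = blobs_xy(blobs)
    cols = ["label", "well_x", "well_y", "blob_id", "blob_x", "blob_y", "residual"]
    if len(bxy) == 0:
        return pd.DataFrame(columns=cols)
    well_tree = cKDTree(pos)
    blob_tree = cKDTree(bxy)
    d_b2w, nearest_well = well_tree.query(bxy)
    _, nearest_blob = blob_tree.query(pos)
    rows = []
    for bi, (wi, d) in enumerate(zip(nearest_well, d_b2w)):
        if d <= r and nearest_blob[wi] == bi:
            rows.append(
                dict(
                    label=template.wells["label"].iloc[wi],
                    well_x=pos[wi, 0],
                    well_y=pos[wi, 1],
                    blob_id=bi,
                    blob_x=bxy[bi, 0],
                    blob_y=bxy[bi, 1],
                    residual=float(d),
                )
            )
    return pd.DataFrame(rows, columns=cols)


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, with U(0) = 0 by continuity
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(r > 0, r * r * np.log(r), 0.0)
    return u


def fit_tps(
    source_points: np.ndarray, target_points: np.ndarray, lam: float = 0.0
) -> TpsWarp:
    """Solve the standard thin-plate-spline system.

    [[K + lam*I, P], [P^T, 0]] [w; a] = [v; 0] with P = [1, x, y].  With
    ``lam = 0`` the warp interpolates the correspondences exactly.  Raises
    on fewer than 10 pairs or on collinear (rank-deficient) sources.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    n = len(src)
    if n < MIN_TPS_PAIRS:
        raise AlignmentError(f"thin-plate spline needs >= {MIN_TPS_PAIRS} pairs, got {n}")
    if src.shape != tgt.shape or src.shape[1] != 2:
        raise ConfigError("source/target must both be (n, 2)")
    p = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(p) < 3:
        raise AlignmentError("thin-plate spline sources are collinear (degenerate)")
    k = _tps_kernel(_pairwise_dist(src, src)) + lam * np.eye(n)
    lhs = np.zeros((n + 3, n + 3))
    lhs[:n, :n] = k
    lhs[:n, n:] = p
    lhs[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    sol = np.linalg.solve(lhs, rhs)
    return TpsWarp(source_points=src, affine=sol[n:], weights=sol[:n], lam=lam)


def align(
    template: GridTemplate,
    blobs: list[Blob],
    seed: int = 0,
    tps_lambda: float = 0.0,
    match_radius: float | None = None,
    popsize: int = 10,
    maxiter: int = 200,
) -> AlignmentResult:
    """Full stage: global DE -> gated local refinement -> TPS warp."""
    result = global_align(
        template, blobs, seed=seed, popsize=popsize, maxiter=maxiter, match_radius=match_radius
    )
    if result.failed:
        warnings.warn(
            f"alignment failed (objective {result.objective:.2f} >= {FAILURE_OBJECTIVE}); "
            "is the template right for this image?"
        )
        return result
    result = local_refine(result, template, blobs, match_radius=match_radius)
    pairs = match_pairs(template, result.transform, blobs, match_radius=match_radius)
    result.matched_pairs = pairs
    if len(pairs) < MIN_TPS_PAIRS:
        result.tps_skipped_reason = f"only {len(pairs)} matched pairs (< {MIN_TPS_PAIRS})"
        return result
    src = pairs[["well_x", "well_y"]].to_numpy()
    tgt = pairs[["blob_x", "blob_y"]].to_numpy()
    try:
        result.warp = fit_tps(src, tgt, lam=tps_lambda)
    except AlignmentError as exc:
        result.tps_skipped_reason = str(exc)
        return result
    warped = result.warp.apply(src)
    pairs = pairs.assign(residual=np.linalg.norm(warped - tgt, axis=1))
    result.matched_pairs = pairs
    return result


# ---------------------------------------------------------------------------
# template editing


def edit_template(template: GridTemplate, action: str, **args) -> GridTemplate:
    """Structured template edits that preserve geometric consistency.

    Actions: ``invert_orientation`` (180-degree relabelling, A1 <-> last
    well, controls follow their physical wells), ``remap_controls``
    (positive=[...], negative=[...]), ``add_well`` (label=...; position
    extrapolated from the affine lattice fit), ``remove_well`` (label=...).
    """
    wells = template.wells.copy()
    if action == "invert_orientation":
        wells["row"] = template.n_rows - 1 - wells["row"]
        wells["col"] = template.n_cols - 1 - wells["col"]
        wells["label"] = [well_label(r, c) for r, c in zip(wells["row"], wells["col"])]
        wells = wells.sort_values(["row", "col"], ignore_index=True)
        row_lines = [
            replace(gl, index=template.n_rows - 1 - gl.index) for gl in template.row_lines
        ]
        col_lines = [
            replace(gl, index=template.n_cols - 1 - gl.index) for gl in template.col_lines
        ]
        return GridTemplate(
            wells=wells,
            row_lines=sorted(row_lines, key=lambda g: g.index),
            col_lines=sorted(col_lines, key=lambda g: g.index),
            median_radius=template.median_radius,
            n_rows=template.n_rows,
            n_cols=template.n_cols,
        )
    if action == "remap_controls":
        wells["control"] = ""
        for sign, key in (("pos", "positive"), ("neg", "negative")):
            for lab in args.get(key, []):
                if lab not in set(wells["label"]):
                    raise ConfigError(f"control label {lab!r} not in template")
                wells.loc[wells["label"] == lab, "control"] = sign
        return replace_wells(template, wells)
    if action == "add_well":
        label = args["label"]
        if label in set(wells["label"]):
            raise ConfigError(f"duplicate well label {label!r}")
        r, c = parse_label(label)
        # affine lattice fit: position ~ base + row_vec*r + col_vec*c
        design = np.column_stack(
            [np.ones(len(wells)), wells["row"].to_numpy(), wells["col"].to_numpy()]
        )
        coef, *_ = np.linalg.lstsq(design, wells[["x", "y"]].to_numpy(), rcond=None)
        x, y = np.array([1.0, r, c]) @ coef
        wells = pd.concat(
            [wells, pd.DataFrame([dict(label=label, row=r, col=c, x=x, y=y, control="")])],
            ignore_index=True,
        ).sort_values(["row", "col"], ignore_index=True)
        tpl = replace_wells(template, wells)
        tpl.n_rows = max(tpl.n_rows, r + 1)
        tpl.n_cols = max(tpl.n_cols, c + 1)
        return tpl
    if action == "remove_well":
        label = args["label"]
        if label not in set(wells["label"]):
            raise ConfigError(f"no such well: {label!r}")
        wells = wells[wells["label"] != label].reset_index(drop=True)
        return replace_wells(template, wells)
    raise ConfigError(f"unknown template edit action: {action!r}")


def replace_wells(template: GridTemplate, wells: pd.DataFrame) -> GridTemplate:
    return GridTemplate(
        wells=wells,
        row_lines=list(template.row_lines),
        col_lines=list(template.col_lines),
        median_radius=template.median_radius,
        n_rows=template.n_rows,
        n_cols=template.n_cols,
    )
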