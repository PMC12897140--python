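"""Stage 2 — grid reconstruction.

From a cloud of detected spot centroids this stage (i) estimates and
corrects a global rotation by variance minimization over a +/-30 degree
grid search in 0.1 degree steps, (ii) groups centroids into rows and
columns by 1-D density clustering, (iii) fits a least-squares line through
every row and column, and (iv) intersects the lines into a full lattice of
well positions stored as a reusable :class:`GridTemplate`.

Well positions come from line intersections rather than from the blobs
directly, so wells whose analyte is absent (no detectable spot) still get a
measurable position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .blob_detection import Blob, blobs_xy, median_nn_distance
from .errors import ConfigError, GriddingError

#: rotation grid search half-range (degrees) and step
ROTATION_RANGE = 30.0
ROTATION_STEP = 0.1
#: a rotation is applied only when its confidence exceeds this
ROTATION_CONFIDENCE_GATE = 0.3
#: minimum blobs for a meaningful rotation estimate (>= 2 rows x 2 cols + slack)
MIN_BLOBS_FOR_ROTATION = 9


@dataclass(frozen=True)
class RotationEstimate:
    angle: float  # degrees; the correction to APPLY to the centroids
    confidence: float  # relative variance reduction vs 0 degrees, in [0, 1]
    applied: bool
    center: tuple[float, float] = (0.0, 0.0)  # rotation center (centroid cloud mean)


@dataclass(frozen=True)
class GridLine:
    """A fitted row or column line.

    Rows regress y on x (y = slope*x + intercept); columns regress x on y
    (x = slope*y + intercept), which keeps vertical columns non-singular.
    """

    kind: str  # "row" | "column"
    index: int
    slope: float
    intercept: float
    member_ids: tuple[int, ...] = ()


@dataclass
class GridTemplate:
    """Reusable geometric model of an array.

    ``wells`` has columns label, row, col, x, y, control ("pos", "neg" or "").
    Labels follow microplate convention: row letter (A..Z, AA..) + 1-based
    column number, e.g. A1, B2, J23.
    """

    wells: pd.DataFrame
    row_lines: list[GridLine]
    col_lines: list[GridLine]
    median_radius: float
    n_rows: int
    n_cols: int

    def positions(self) -> np.ndarray:
        return self.wells[["x", "y"]].to_numpy(dtype=float)

    @property
    def labels(self) -> list[str]:
        return self.wells["label"].tolist()

    def control_wells(self, sign: str) -> list[str]:
        return self.wells.loc[self.wells["control"] == sign, "label"].tolist()

    # --- plain-text serialization -------------------------------------
    def save(self, path: str | Path) -> None:
        lines = ["# arrayquant grid template v1"]
        lines.append(f"n_rows\t{self.n_rows}")
        lines.append(f"n_cols\t{self.n_cols}")
        lines.append(f"median_radius\t{self.median_radius!r}")
        for gl in self.row_lines + self.col_lines:
            lines.append(f"line\t{gl.kind}\t{gl.index}\t{gl.slope!r}\t{gl.intercept!r}")
        lines.append("wells\tlabel\trow\tcol\tx\ty\tcontrol")
        for _, w in self.wells.iterrows():
            lines.append(
                f"well\t{w['label']}\t{int(w['row'])}\t{int(w['col'])}"
                f"\t{w['x']!r}\t{w['y']!r}\t{w['control']}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GridTemplate":
        text = Path(path).read_text().splitlines()
        if not text or not text[0].startswith("# arrayquant grid template"):
            raise ConfigError(f"not a grid template file: {path}")
        meta: dict[str, str] = {}
        row_lines: list[GridLine] = []
        col_lines: list[GridLine] = []
        wells: list[dict] = []
        for ln in text[1:]:
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if parts[0] in ("n_rows", "n_cols", "median_radius"):
                meta[parts[0]] = parts[1]
            elif parts[0] == "line":
                gl = GridLine(parts[1], int(parts[2]), float(parts[3]), float(parts[4]))
                (row_lines if gl.kind == "row" else col_lines).append(gl)
            elif parts[0] == "well":
                wells.append(
                    dict(
                        label=parts[1],
                        row=int(parts[2]),
                        col=int(parts[3]),
                        x=float(parts[4]),
                        y=float(parts[5]),
                        control=parts[6] if len(parts) > 6 else "",
                    )
                )
        return cls(
            wells=pd.DataFrame(wells),
            row_lines=row_lines,
            col_lines=col_lines,
            median_radius=float(meta["median_radius"]),
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
        )


# ---------------------------------------------------------------------------
# labels


def well_label(row: int, col: int) -> str:
    """Microplate label: 0-based (row, col) -> e.g. (0, 0) -> 'A1'.

    Rows beyond Z continue AA, AB, ... (standard plate convention).
    """
    if row < 0 or col < 0:
        raise ValueError("negative grid index")
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


def parse_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`well_label`."""
    m = re.fullmatch(r"([A-Z]+)([0-9]+)", label)
    if not m:
        raise ValueError(f"malformed well label: {label!r}")
    row = 0
    for ch in m.group(1):
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(m.group(2)) - 1


# ---------------------------------------------------------------------------
# rotation


def _within_group_ss(values: np.ndarray, gap: float) -> float:
    """Sum of within-group squared deviations, groups split at sorted gaps > gap."""
    s = np.sort(values)
    if len(s) < 2:
        return 0.0
    breaks = np.nonzero(np.diff(s) > gap)[0] + 1
    total = 0.0
    for g in np.split(s, breaks):
        if len(g) > 1:
            total += float(((g - g.mean()) ** 2).sum())
    return total


def _rotate_xy(xy: np.ndarray, angle_deg: float, center: np.ndarray) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return (xy - center) @ rot.T + center


def estimate_rotation(blobs: list[Blob]) -> RotationEstimate:
    """Grid search the rotation that minimizes within-row/column variance.

    Scans angles in [-30, +30] degrees in 0.1 degree steps; at each
    candidate the centroids are rotated about their mean and the total
    within-row Y scatter plus within-column X scatter is evaluated (groups
    formed by sorted-gap splitting at 0.75x the median nearest-neighbour
    distance — above pitch/sqrt(2), so the spurious 45-degree diagonal
    sublattice of a square grid merges into high-scatter groups instead of
    mimicking rows).  Confidence is the relative variance reduction against the
    unrotated cloud, clipped to [0, 1]; the rotation is flagged ``applied``
    only when confidence exceeds 0.3.
    """
    if len(blobs) < MIN_BLOBS_FOR_ROTATION:
        return RotationEstimate(0.0, 0.0, False)
    xy = blobs_xy(blobs)
    center = xy.mean(axis=0)
    gap = 0.75 * median_nn_distance(blobs)
    if gap <= 0:
        return RotationEstimate(0.0, 0.0, False, tuple(center))
    n_steps = int(round(ROTATION_RANGE / ROTATION_STEP))
    angles = np.round(np.arange(-n_steps, n_steps + 1) * ROTATION_STEP, 10)
    scores = np.empty(len(angles))
    for i, a in enumerate(angles):
        r = _rotate_xy(xy, a, center)
        scores[i] = _within_group_ss(r[:, 1], gap) + _within_group_ss(r[:, 0], gap)
    # prefer the smallest |angle| among ties (exact zero for aligned grids)
    best = np.lexsort((np.abs(angles), scores))[0]
    var0 = scores[np.argmin(np.abs(angles))]
    vmin = scores[best]
    confidence = 0.0 if var0 <= 0 else float(np.clip((var0 - vmin) / var0, 0.0, 1.0))
    angle = float(angles[best])
    return RotationEstimate(
        angle=angle,
        confidence=confidence,
        applied=confidence > ROTATION_CONFIDENCE_GATE,
        center=(float(center[0]), float(center[1])),
    )


def apply_rotation(blobs: list[Blob], angle: float, center: tuple[float, float]) -> list[Blob]:
    """Rotate blob centroids by ``angle`` degrees about ``center``."""
    xy = _rotate_xy(blobs_xy(blobs), angle, np.asarray(center, dtype=float))
    return [
        Blob(x=float(p[0]), y=float(p[1]), sigma=b.sigma, response=b.response)
        for b, p in zip(blobs, xy)
    ]


def correct_rotation(blobs: list[Blob]) -> tuple[list[Blob], RotationEstimate]:
    """Estimate and, if confident, apply the rotation correction."""
    est = estimate_rotation(blobs)
    if est.applied:
        return apply_rotation(blobs, est.angle, est.center), est
    return list(blobs), est


# ---------------------------------------------------------------------------
# axis clustering, line fitting, intersections


def cluster_axes(
    blobs: list[Blob],
    eps_row: float | None = None,
    eps_col: float | None = None,
    min_samples: int = 3,
    min_occupancy_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign rotation-corrected blobs to rows and columns.

    1-D DBSCAN on Y yields row groups, on X column groups; groups are
    ordered by mean coordinate and indexed 0..n-1.  Blobs that are noise on
    either axis get index -1 on that axis (and are dropped downstream).

    Groups holding fewer than ``min_occupancy_frac`` of the median group
    size are discarded as spurious: on noisy scans, false detections along
    the membrane margin can otherwise masquerade as an extra sparse row or
    column and shift every well label by one.
    """
    if not blobs:
        raise GriddingError("no blobs to grid")
    xy = blobs_xy(blobs)
    default_eps = 0.5 * median_nn_distance(blobs)
    eps_row = eps_row if eps_row is not None else default_eps
    eps_col = eps_col if eps_col is not None else default_eps
    if eps_row <= 0 or eps_col <= 0:
        raise GriddingError("cannot infer clustering eps from blob geometry")

    def one_axis(vals: np.ndarray, eps: float) -> np.ndarray:
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(vals.reshape(-1, 1))
        out = np.full(len(vals), -1, dtype=int)
        uniq = [lab for lab in np.unique(labels) if lab != -1]
        counts = {lab: int((labels == lab).sum()) for lab in uniq}
        if counts:
            cutoff = min_occupancy_frac * float(np.median(list(counts.values())))
            uniq = [lab for lab in uniq if counts[lab] >= cutoff]
        means = {lab: vals[labels == lab].mean() for lab in uniq}
        for rank, lab in enumerate(sorted(uniq, key=means.get)):
            out[labels == lab] = rank
        return out

    rows = one_axis(xy[:, 1], eps_row)
    cols = one_axis(xy[:, 0], eps_col)
    if rows.max(initial=-1) < 1 or cols.max(initial=-1) < 1:
        raise GriddingError("fewer than 2 row or column groups detected")
    return rows, cols


def fit_grid_lines(
    blobs: list[Blob], row_assign: np.ndarray, col_assign: np.ndarray
) -> tuple[list[GridLine], list[GridLine]]:
    """OLS line through each row (y on x) and column (x on y) group."""
    xy = blobs_xy(blobs)
    keep = (row_assign >= 0) & (col_assign >= 0)

    def fit(kind: str, groups: np.ndarray, dep: int, indep: int) -> list[GridLine]:
        out = []
        for g in range(groups[keep].max() + 1):
            ids = np.nonzero(keep & (groups == g))[0]
            pts = xy[ids]
            if len(pts) == 0:
                continue
            if len(pts) == 1:
                warnings.warn(f"{kind} group {g} has a single member; slope forced to 0")
                slope, intercept = 0.0, float(pts[0, dep])
            else:
                slope, intercept = np.polyfit(pts[:, indep], pts[:, dep], 1)
            out.append(GridLine(kind, g, float(slope), float(intercept), tuple(ids)))
        return out

    return fit("row", row_assign, dep=1, indep=0), fit("column", col_assign, dep=0, indep=1)


def intersect_lines(
    row_lines: list[GridLine], col_lines: list[GridLine]
) -> dict[tuple[int, int], tuple[float, float]]:
    """Exact intersection of every (row, column) line pair.

    Row: y = a_r x + b_r; column: x = a_c y + b_c.  Near-parallel pairs
    (|1 - a_r a_c| ~ 0) indicate a broken grid fit.
    """
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for rl in row_lines:
        for cl in col_lines:
            denom = 1.0 - rl.slope * cl.slope
            if abs(denom) < 1e-9:
                raise GriddingError(
                    f"near-parallel row {rl.index} / column {cl.index} lines"
                )
            x = (cl.slope * rl.intercept + cl.intercept) / denom
            y = rl.slope * x + rl.intercept
            out[(rl.index, cl.index)] = (float(x), float(y))
    return out


def fill_missing_lines(lines: list[GridLine]) -> list[GridLine]:
    """Interpolate grid lines for rows/columns with no detectable spots.

    A membrane can carry a whole row or column of analytes too faint to
    detect; its line is still needed so the wells get measured and the
    labels of later rows/columns do not shift.  Gaps are found by
    comparing adjacent intercept spacings to the median spacing; a gap of
    ~m pitches gets m-1 evenly spaced lines with interpolated slope.
    Edge rows/columns outside the detected span cannot be recovered.
    """
    if len(lines) < 3:
        return lines
    ordered = sorted(lines, key=lambda g: g.intercept)
    diffs = np.diff([g.intercept for g in ordered])
    med = float(np.median(diffs))
    if med <= 0:
        return lines
    out: list[GridLine] = [ordered[0]]
    for prev, nxt, d in zip(ordered, ordered[1:], diffs):
        m = int(round(d / med))
        for j in range(1, min(m, 4)):
            frac = j / m
            out.append(
                GridLine(
                    kind=prev.kind,
                    index=-1,
                    slope=prev.slope + frac * (nxt.slope - prev.slope),
                    intercept=prev.intercept + frac * d,
                    member_ids=(),
                )
            )
        out.append(nxt)
    return [replace(g, index=i) for i, g in enumerate(out)]


def build_template(
    blobs: list[Blob],
    row_assign: np.ndarray,
    col_assign: np.ndarray,
    row_lines: list[GridLine],
    col_lines: list[GridLine],
    control_spec: dict[str, str] | None = None,
) -> GridTemplate:
    """Assemble a :class:`GridTemplate` from the fitted grid.

    ``control_spec`` maps well labels to "pos"/"neg"; labels outside the
    grid raise a config error.  ``median_radius`` is the median radius of
    the blobs that were assigned to the grid.
    """
    keep = (row_assign >= 0) & (col_assign >= 0)
    radii = [b.radius for b, k in zip(blobs, keep) if k]
    if not radii:
        raise GriddingError("no gridded blobs")
    positions = intersect_lines(row_lines, col_lines)
    n_rows = max(r for r, _ in positions) + 1
    n_cols = max(c for _, c in positions) + 1
    rows = []
    for (r, c), (x, y) in sorted(positions.items()):
        rows.append(dict(label=well_label(r, c), row=r, col=c, x=x, y=y, control=""))
    wells = pd.DataFrame(rows)
    if control_spec:
        known = set(wells["label"])
        bad = set(control_spec) - known
        if bad:
            raise ConfigError(f"control labels outside grid: {sorted(bad)}")
        for lab, sign in control_spec.items():
            if sign not in ("pos", "neg"):
                raise ConfigError(f"control sign must be pos/neg, got {sign!r}")
            wells.loc[wells["label"] == lab, "control"] = sign
    return GridTemplate(
        wells=wells,
        row_lines=row_lines,
        col_lines=col_lines,
        median_radius=float(np.median(radii)),
        n_rows=n_rows,
        n_cols=n_cols,
    )


def build_grid(
    blobs: list[Blob],
    control_spec: dict[str, str] | None = None,
    eps_row: float | None = None,
    eps_col: float | None = None,
) -> tuple[GridTemplate, RotationEstimate]:
    """Full stage: rotation correction -> axis clustering -> lines -> template.

    The returned template's well coordinates live in the rotation-corrected
    frame; the accompanying :class:`RotationEstimate` maps back to the
    original image frame.
    """
    corrected, est = correct_rotation(blobs)
    rows, cols = cluster_axes(corrected, eps_row, eps_col)
    row_lines, col_lines = fit_grid_lines(corrected, rows, cols)
    row_lines = fill_missing_lines(row_lines)
    col_lines = fill_missing_lines(col_lines)
    template = build_template(corrected, rows, cols, row_lines, col_lines, control_spec)
    return template, est
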