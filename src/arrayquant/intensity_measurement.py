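"""Stage 4 — per-well intensity extraction and control normalization.

Measurements are taken at the aligned template well positions only, never
at raw detections, so spurious blobs (dust, scratches) contribute nothing
and faint analytes without a detectable spot are still measured.  Each
well value is the mean pixel intensity over a flat disk of the template's
median spot radius (optionally a truncated-Gaussian-weighted mean to
mirror a Gaussian spot profile).

Normalization is a two-point linear anchor on the control spots shared by
every membrane: normalized = (raw - mu_neg) / (mu_pos - mu_neg), so the
negative-control mean maps to 0 and the positive-control mean to 1.  This
makes the values exactly invariant to any gain/offset change of the whole
scan.  Duplicate spots of the same analyte are averaged *after*
normalization, yielding one value per analyte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, MeasurementError
from .grid_processing import GridTemplate
from .image_io import ArrayImage
from .template_alignment import AlignmentResult

#: log floor, expressed on the normalized (positive-control = 1) scale
DEFAULT_EPSILON = 1e-4


@dataclass
class AnalyteMap:
    """Well -> analyte assignment with duplicate groups and control wells.

    ``entries`` columns: well, analyte, dup_group, control ("pos", "neg"
    or "").  Wells absent from the map are blanks.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "analyte", "dup_group", "control"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ConfigError(f"analyte map missing columns: {sorted(missing)}")
        self.entries = self.entries.fillna({"control": "", "dup_group": "", "analyte": ""})
        if self.entries["well"].duplicated().any():
            dups = self.entries.loc[self.entries["well"].duplicated(), "well"].tolist()
            raise ConfigError(f"duplicate wells in analyte map: {dups}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnalyteMap":
        return cls(pd.read_csv(path, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)

    @property
    def positive_controls(self) -> list[str]:
        return self.entries.loc[self.entries["control"] == "pos", "well"].tolist()

    @property
    def negative_controls(self) -> list[str]:
        return self.entries.loc[self.entries["control"] == "neg", "well"].tolist()

    @property
    def analyte_wells(self) -> pd.DataFrame:
        e = self.entries
        return e[(e["control"] == "") & (e["analyte"] != "")]

    @property
    def analytes(self) -> list[str]:
        return sorted(self.analyte_wells["analyte"].unique())

    def control_spec(self) -> dict[str, str]:
        e = self.entries
        return dict(zip(e.loc[e["control"] != "", "well"], e.loc[e["control"] != "", "control"]))


def human_xl_map() -> AnalyteMap:
    """The packaged 105-analyte membrane-array map (10 x 24 grid).

    A synthetic-but-consistent reconstruction of a Proteome Profiler Human
    XL-style layout: 105 analytes spotted in horizontal duplicate pairs,
    3 positive-control (reference) wells and 1 negative-control well at
    the array corners.  The analyte placement is this package's own; the
    vendor does not publish machine-readable coordinates.
    """
    with resources.files("arrayquant.data").joinpath("human_xl_map.csv").open() as fh:
        return AnalyteMap(pd.read_csv(fh, keep_default_na=False))


# ---------------------------------------------------------------------------
# measurement


def measure_spot(
    image: ArrayImage,
    center: tuple[float, float],
    radius: float,
    weighting: str = "flat",
) -> float:
    """Mean intensity in a disk around ``center``.

    ``flat``: unweighted mean over pixels with distance <= radius.
    ``gaussian``: mean weighted by a 2-D Gaussian of sigma = radius / 2,
    truncated at 2 sigma.  The mask is clipped at image borders and the
    mean taken over valid pixels only.
    """
    cx, cy = center
    if not (0 <= cx < image.width and 0 <= cy < image.height):
        raise MeasurementError(f"spot center {center} outside image")
    if radius <= 0:
        raise MeasurementError("spot radius must be > 0")
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)) + 1, image.width)
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)) + 1, image.height)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = d2 <= radius**2
    if not mask.any():
        raise MeasurementError(f"no valid pixels for spot at {center}")
    patch = image.pixels[y0:y1, x0:x1]
    if weighting == "flat":
        return float(patch[mask].mean())
    if weighting == "gaussian":
        sigma = radius / 2.0
        w = np.exp(-d2 / (2 * sigma**2)) * mask
        return float((patch * w).sum() / w.sum())
    raise ConfigError(f"unknown weighting {weighting!r} (flat or gaussian)")


def measure_wells(
    image: ArrayImage,
    template: GridTemplate,
    alignment: AlignmentResult | None = None,
    weighting: str = "flat",
    radius: float | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw intensity table: one row per template well, always n_rows x n_cols.

    Positions are the template wells mapped through the alignment
    (similarity + optional warp); with ``alignment=None`` the template's
    own coordinates are used (the image the template was built from).
    ``positions`` overrides both (already-localized well centers, e.g.
    mapped back through a rotation correction).  Wells that fall outside
    the image get NaN with a warning.
    """
    r = radius if radius is not None else template.median_radius
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
    else:
        pos = template.positions()
        if alignment is not None:
            pos = alignment.predict(pos)
    rows = []
    n_outside = 0
    for (_, well), (x, y) in zip(template.wells.iterrows(), pos):
        try:
            raw = measure_spot(image, (float(x), float(y)), r, weighting)
        except MeasurementError:
            raw = np.nan
            n_outside += 1
        rows.append(dict(well=well["label"], x=float(x), y=float(y), raw_mean=raw))
    if n_outside:
        warnings.warn(f"{n_outside} wells fell outside the image; recorded as NaN")
    return pd.DataFrame(rows)


def normalize_controls(
    table: pd.DataFrame, amap: AnalyteMap, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Two-point control normalization of a raw intensity table.

    normalized = (raw - mu_neg) / (mu_pos - mu_neg), with mu_pos the mean
    of the positive-control raw means and mu_neg the negative-control
    mean.  Values below the negative control floor at 0; ``log_norm`` is
    log2(max(normalized, epsilon)).
    """
    pos_wells = amap.positive_controls
    neg_wells = amap.negative_controls
    if not pos_wells or not neg_wells:
        raise ConfigError("analyte map must declare positive and negative controls")
    by_well = table.set_index("well")["raw_mean"]
    missing = [w for w in pos_wells + neg_wells if w not in by_well.index or pd.isna(by_well[w])]
    if missing:
        raise MeasurementError(f"control wells not measured: {missing}")
    mu_pos = float(by_well[pos_wells].mean())
    mu_neg = float(by_well[neg_wells].mean())
    if mu_pos <= mu_neg:
        raise MeasurementError(
            f"failed array: positive-control mean ({mu_pos:.3g}) <= "
            f"negative-control mean ({mu_neg:.3g})"
        )
    out = table.copy()
    norm = (out["raw_mean"] - mu_neg) / (mu_pos - mu_neg)
    out["normalized"] = np.maximum(norm, 0.0)
    out["log_norm"] = np.log2(np.maximum(out["normalized"], epsilon))
    return out


def collapse_duplicates(table: pd.DataFrame, amap: AnalyteMap) -> pd.DataFrame:
    """Average duplicate spots into one normalized value per analyte.

    Controls and blank wells are excluded.  An analyte whose member spots
    are all unmeasured gets NaN and is flagged in the ``flagged`` column.
    """
    if "normalized" not in table.columns:
        raise ConfigError("table must be normalized before collapsing duplicates")
    merged = table.merge(amap.analyte_wells, on="well", how="inner")
    if merged.empty:
        raise ConfigError("no analyte wells found in table")
    rows = []
    for (group, analyte), sub in merged.groupby(["dup_group", "analyte"], sort=True):
        vals = sub["normalized"].dropna()
        rows.append(
            dict(
                analyte=analyte,
                dup_group=group,
                value=float(vals.mean()) if len(vals) else np.nan,
                n_spots=int(len(vals)),
                flagged=len(vals) == 0,
            )
        )
    out = pd.DataFrame(rows).sort_values("analyte", ignore_index=True)
    if out["flagged"].any():
        warnings.warn(f"{int(out['flagged'].sum())} analytes had no measurable spot")
    return out


def render_overlay(
    image: ArrayImage,
    template: GridTemplate,
    alignment: AlignmentResult | None,
    path: str | Path,
    labels: bool = True,
) -> None:
    """QC figure: scan with well circles (positive controls green, negative
    red, analytes yellow) and well labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    pos = template.positions()
    if alignment is not None:
        pos = alignment.predict(pos)
    r = template.median_radius
    fig, ax = plt.subplots(figsize=(image.width / 80, image.height / 80))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest")
    colors = {"pos": "lime", "neg": "red", "": "yellow"}
    for (_, w), (x, y) in zip(template.wells.iterrows(), pos):
        ax.add_patch(Circle((x, y), r, fill=False, color=colors[w["control"]], lw=0.8))
        if labels:
            ax.text(x, y - r - 1, w["label"], color="cyan", fontsize=3, ha="center")
    ax.set_axis_off()
    fig.savefig(path, dpi=160, bbox_inches="tight")
    plt.close(fig)
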