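"""Ground-truthed synthetic array scans and replicate experiments.

Every pipeline stage is testable without external data: this module
renders membrane-array images from a fully specified geometric and
photometric model and returns the exact quantities the pipeline is
supposed to recover (spot centroids, amplitudes, transform parameters,
injected fold-changes).

The image model: a rectilinear lattice of 2-D Gaussian spots
(amplitude * exp(-d^2 / 2 sigma^2)), mapped through a similarity
transform (rotation about the image center, translation, uniform scale)
and a smooth sinusoidal warp emulating membrane distortion, on top of a
linear background ramp, with optional per-spot placement jitter and
seeded Gaussian pixel noise, clipped to the bit depth.  Replicate
experiments add per-spot multiplicative lognormal intensity noise of a
given coefficient of variation — chemiluminescent/fluorescent spot
intensities vary multiplicatively — while control spots stay fixed
across conditions.

Not modelled: optical blooming, membrane texture, saturation streaks;
conclusions from these fixtures are about the geometry/statistics
pipeline, not about scanner physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .grid_processing import parse_label
from .image_io import ArrayImage
from .intensity_measurement import AnalyteMap


@dataclass
class SyntheticArraySpec:
    """Full description of one rendered array image."""

    n_rows: int = 8
    n_cols: int = 10
    pitch: float = 30.0
    spot_sigma: float = 4.5
    amplitudes: np.ndarray | None = None  # (n_rows, n_cols); None -> all 3000
    theta: float = 0.0  # degrees, about the image center
    tx: float = 0.0
    ty: float = 0.0
    scale: float = 1.0
    warp_amplitude: float = 0.0  # px
    warp_period: float = 200.0  # px
    background: tuple[float, float] = (500.0, 0.0)  # (offset, gradient per px along x)
    noise_sd: float = 0.0
    jitter_sd: float = 0.0  # per-spot placement jitter
    seed: int = 0
    bit_depth: int = 16
    margin: float | None = None  # None -> 3*spot_sigma + 12

    def amplitude_grid(self) -> np.ndarray:
        if self.amplitudes is None:
            return np.full((self.n_rows, self.n_cols), 3000.0)
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.shape != (self.n_rows, self.n_cols):
            raise ConfigError(
                f"amplitudes shape {amp.shape} != grid ({self.n_rows}, {self.n_cols})"
            )
        if amp.min() < 0:
            raise ConfigError("amplitudes must be >= 0")
        return amp


@dataclass
class GroundTruth:
    """Everything a test may assert about a rendered image."""

    positions: np.ndarray  # (n_wells, 2) final (x, y), post-transform/warp/jitter
    amplitudes: np.ndarray  # (n_wells,)
    rows: np.ndarray  # (n_wells,) 0-based row index
    cols: np.ndarray
    theta: float
    tx: float
    ty: float
    scale: float
    image_center: tuple[float, float]

    def position_of(self, row: int, col: int) -> np.ndarray:
        i = np.nonzero((self.rows == row) & (self.cols == col))[0][0]
        return self.positions[i]


def _warp_displacement(xy: np.ndarray, amplitude: float, period: float) -> np.ndarray:
    if amplitude == 0:
        return np.zeros_like(xy)
    dx = amplitude * np.sin(2 * np.pi * xy[:, 1] / period)
    dy = amplitude * np.sin(2 * np.pi * xy[:, 0] / period)
    return np.column_stack([dx, dy])


def render_array(spec: SyntheticArraySpec) -> tuple[ArrayImage, GroundTruth]:
    """Render one array image and its ground truth.

    The image size is fixed by the *base* lattice plus the margin, so the
    same spec with different transforms yields comparable coordinate
    frames (a template built at identity can be aligned onto a
    transformed render).  Raises if transformed spots leave the canvas or
    if spots would overlap (pitch < 4 sigma).
    """
    if spec.pitch * spec.scale < 4 * spec.spot_sigma:
        raise ConfigError(
            f"overlapping spots: pitch*scale {spec.pitch * spec.scale:.1f} "
            f"< 4*sigma {4 * spec.spot_sigma:.1f}"
        )
    margin = spec.margin if spec.margin is not None else 3 * spec.spot_sigma + 12
    width = int(np.ceil((spec.n_cols - 1) * spec.pitch + 2 * margin)) + 1
    height = int(np.ceil((spec.n_rows - 1) * spec.pitch + 2 * margin)) + 1
    center = np.array([(width - 1) / 2.0, (height - 1) / 2.0])

    rows, cols = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
    rows, cols = rows.ravel(), cols.ravel()
    lattice = np.column_stack(
        [
            cols * spec.pitch + center[0] - (spec.n_cols - 1) * spec.pitch / 2.0,
            rows * spec.pitch + center[1] - (spec.n_rows - 1) * spec.pitch / 2.0,
        ]
    )
    t = np.deg2rad(spec.theta)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    pos = spec.scale * (lattice - center) @ rot.T + center + np.array([spec.tx, spec.ty])
    pos = pos + _warp_displacement(pos, spec.warp_amplitude, spec.warp_period)

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sd > 0:
        pos = pos + rng.normal(0.0, spec.jitter_sd, pos.shape)

    amp = spec.amplitude_grid().ravel()
    lim = 3 * spec.spot_sigma
    rendered = amp > 0
    if rendered.any():
        p = pos[rendered]
        if (
            p[:, 0].min() < lim
            or p[:, 1].min() < lim
            or p[:, 0].max() > width - 1 - lim
            or p[:, 1].max() > height - 1 - lim
        ):
            raise ConfigError(
                "transformed grid does not fit the canvas; increase spec.margin"
            )

    img = np.full((height, width), float(spec.background[0]))
    if spec.background[1]:
        img += spec.background[1] * np.arange(width)[None, :]
    win = int(np.ceil(4 * spec.spot_sigma))
    for (x, y), a in zip(pos, amp):
        if a <= 0:
            continue
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(xi - win, 0), min(xi + win + 1, width)
        y0, y1 = max(yi - win, 0), min(yi + win + 1, height)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * spec.spot_sigma**2)
        )
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 2**spec.bit_depth - 1)

    truth = GroundTruth(
        positions=pos,
        amplitudes=amp,
        rows=rows,
        cols=cols,
        theta=spec.theta,
        tx=spec.tx,
        ty=spec.ty,
        scale=spec.scale,
        image_center=(float(center[0]), float(center[1])),
    )
    return ArrayImage(img, bit_depth=spec.bit_depth), truth


# ---------------------------------------------------------------------------
# replicate experiments


def amplitudes_from_map(
    amap: AnalyteMap,
    analyte_amplitudes: dict[str, float],
    n_rows: int,
    n_cols: int,
    pos_amplitude: float = 50000.0,
) -> np.ndarray:
    """Amplitude grid for an analyte map: controls fixed, blanks zero."""
    grid = np.zeros((n_rows, n_cols))
    for _, e in amap.entries.iterrows():
        r, c = parse_label(e["well"])
        if r >= n_rows or c >= n_cols:
            raise ConfigError(f"well {e['well']} outside the {n_rows}x{n_cols} grid")
        if e["control"] == "pos":
            grid[r, c] = pos_amplitude
        elif e["control"] == "neg":
            grid[r, c] = 0.0
        elif e["analyte"]:
            grid[r, c] = analyte_amplitudes.get(e["analyte"], 0.0)
    return grid


def render_experiment(
    base_spec: SyntheticArraySpec,
    amap: AnalyteMap,
    effects: dict[str, float],
    n_replicates: int = 4,
    cv: float = 0.10,
    seed: int = 0,
    ref_amplitudes: dict[str, float] | None = None,
    amp_range: tuple[float, float] = (1500.0, 12000.0),
    pos_amplitude: float = 50000.0,
    vary_geometry: bool = True,
) -> tuple[dict[str, list[tuple[ArrayImage, GroundTruth]]], pd.DataFrame]:
    """Render a 2-condition replicate experiment with injected fold-changes.

    ``effects`` maps analyte -> true log2 fold-change (treated vs
    reference); analytes not listed get 0.  Reference amplitudes default
    to a seeded log-uniform draw over ``amp_range``.  Treated amplitudes
    are reference * 2**log2FC.  Every analyte spot (each duplicate
    independently) is multiplied by mean-one lognormal noise of the given
    coefficient of variation; positive controls stay at a fixed high
    amplitude and the negative control at background, in every image.
    With ``vary_geometry`` each membrane also gets a small random
    rotation/translation/scale, as separate physical membranes would.

    Returns ``({"treated": [(image, truth), ...], "reference": [...]},
    truth_table)`` where the truth table has one row per analyte with its
    reference amplitude and true log2FC.
    """
    rng = np.random.default_rng(seed)
    analytes = amap.analytes
    unknown = set(effects) - set(analytes)
    if unknown:
        raise ConfigError(f"effects for analytes not on the array: {sorted(unknown)}")
    if ref_amplitudes is None:
        lo, hi = amp_range
        draws = np.exp(rng.uniform(np.log(lo), np.log(hi), len(analytes)))
        ref_amplitudes = dict(zip(analytes, draws))
    sigma_ln = float(np.sqrt(np.log(1 + cv**2)))

    # map wells once
    well_info = []
    for _, e in amap.analyte_wells.iterrows():
        well_info.append((parse_label(e["well"]), e["analyte"]))

    out: dict[str, list[tuple[ArrayImage, GroundTruth]]] = {}
    for cond in ("treated", "reference"):
        images = []
        for rep in range(n_replicates):
            grid = amplitudes_from_map(
                amap, {}, base_spec.n_rows, base_spec.n_cols, pos_amplitude
            )
            for (r, c), analyte in well_info:
                amp = ref_amplitudes[analyte]
                if cond == "treated":
                    amp = amp * 2.0 ** effects.get(analyte, 0.0)
                noise = np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)) if cv > 0 else 1.0
                grid[r, c] = amp * noise
            spec = replace(
                base_spec,
                amplitudes=grid,
                seed=int(rng.integers(2**31)),
            )
            if vary_geometry:
                spec = replace(
                    spec,
                    theta=float(rng.uniform(-2, 2)),
                    tx=float(rng.uniform(-8, 8)),
                    ty=float(rng.uniform(-8, 8)),
                    scale=float(rng.uniform(0.99, 1.01)),
                )
            images.append(render_array(spec))
        out[cond] = images

    truth = pd.DataFrame(
        dict(
            analyte=analytes,
            ref_amplitude=[ref_amplitudes[a] for a in analytes],
            log2FC=[effects.get(a, 0.0) for a in analytes],
        )
    )
    return out, truth
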