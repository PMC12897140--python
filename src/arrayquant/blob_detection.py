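"""Stage 1 — spot candidate detection.

Four steps, in order:

1. percentile-based contrast enhancement (``contrast_lower``/``contrast_upper``);
2. multi-scale Laplacian-of-Gaussian filtering over ``num_sigma`` scales
   log-spaced in [``min_sigma``, ``max_sigma``], keeping scale-space maxima
   above ``threshold`` with sub-pixel centroid refinement;
3. radius-based de-duplication: within ``radius_filter`` pixels only the
   blob with the largest radius survives;
4. DBSCAN outlier removal on (x, y): isolated detections (dust, scratches)
   are dropped, leaving the grid-like cloud of true spots.

The LoG response is scale-normalized (multiplied by sigma^2) so that spots
of different sizes compete on an equal footing, and negated so that bright
spots give positive maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from sklearn.cluster import DBSCAN

from .errors import ConfigError
from .image_io import ArrayImage


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detection stage.

    Defaults are sized for membrane-array scans with a 10-30 px spot pitch.
    """

    contrast_lower: float = 1.0
    contrast_upper: float = 99.0
    min_sigma: float = 4.0
    max_sigma: float = 12.0
    num_sigma: int = 9
    threshold: float = 0.02
    radius_filter: float = 15.0
    cluster_eps: float | None = None  # None -> 2x median nearest-neighbour distance
    cluster_min_pts: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.contrast_lower < self.contrast_upper <= 100):
            raise ConfigError("need 0 <= contrast_lower < contrast_upper <= 100")
        if self.min_sigma > self.max_sigma:
            raise ConfigError("min_sigma must be <= max_sigma")
        if self.num_sigma < 1:
            raise ConfigError("num_sigma must be >= 1")
        if self.threshold < 0:
            raise ConfigError("threshold must be >= 0")
        if self.radius_filter <= 0:
            raise ConfigError("radius_filter must be > 0")
        if self.cluster_eps is not None and self.cluster_eps <= 0:
            raise ConfigError("cluster_eps must be > 0")
        if self.cluster_min_pts < 1:
            raise ConfigError("cluster_min_pts must be >= 1")


@dataclass(frozen=True)
class Blob:
    """A detected spot candidate with sub-pixel centroid."""

    x: float
    y: float
    sigma: float
    response: float

    @property
    def radius(self) -> float:
        # a LoG filter of scale sigma responds maximally to a disk of
        # radius sigma * sqrt(2)
        return self.sigma * np.sqrt(2.0)


def blobs_xy(blobs: list[Blob]) -> np.ndarray:
    """Centroids of a blob list as an (n, 2) array of (x, y)."""
    if not blobs:
        return np.empty((0, 2))
    return np.array([[b.x, b.y] for b in blobs], dtype=float)


def median_nn_distance(blobs: list[Blob]) -> float:
    """Median nearest-neighbour distance of blob centroids (grid-pitch proxy)."""
    xy = blobs_xy(blobs)
    if len(xy) < 2:
        return 0.0
    d, _ = cKDTree(xy).query(xy, k=2)
    return float(np.median(d[:, 1]))


def enhance_contrast(
    image: ArrayImage, contrast_lower: float = 1.0, contrast_upper: float = 99.0
) -> ArrayImage:
    """Linearly rescale intensities so the given percentiles map to [0, 1].

    Values outside the percentile window are clipped.  A zero-dynamic-range
    image is returned unchanged with a warning.
    """
    if not (0 <= contrast_lower < contrast_upper <= 100):
        raise ConfigError("need 0 <= contrast_lower < contrast_upper <= 100")
    lo, hi = np.percentile(image.pixels, [contrast_lower, contrast_upper])
    if hi <= lo:
        warnings.warn("zero dynamic range between contrast percentiles; image unchanged")
        return ArrayImage(image.pixels.copy(), image.bit_depth, image.polarity)
    scaled = np.clip((image.pixels - lo) / (hi - lo), 0.0, 1.0)
    return ArrayImage(scaled, image.bit_depth, image.polarity)


def _subpixel_offset(plane: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """2-D quadratic (Taylor) refinement of a response maximum.

    Fits the local quadratic from finite differences and returns the
    (dx, dy) of its apex; falls back to (0, 0) at borders or when the
    Hessian is degenerate / the apex escapes the pixel.
    """
    h, w = plane.shape
    if not (1 <= y < h - 1 and 1 <= x < w - 1):
        return 0.0, 0.0
    gx = (plane[y, x + 1] - plane[y, x - 1]) / 2.0
    gy = (plane[y + 1, x] - plane[y - 1, x]) / 2.0
    hxx = plane[y, x + 1] - 2 * plane[y, x] + plane[y, x - 1]
    hyy = plane[y + 1, x] - 2 * plane[y, x] + plane[y - 1, x]
    hxy = (
        plane[y + 1, x + 1] - plane[y + 1, x - 1] - plane[y - 1, x + 1] + plane[y - 1, x - 1]
    ) / 4.0
    det = hxx * hyy - hxy * hxy
    if abs(det) < 1e-12:
        return 0.0, 0.0
    dx = -(hyy * gx - hxy * gy) / det
    dy = -(hxx * gy - hxy * gx) / det
    if abs(dx) > 1.0 or abs(dy) > 1.0:
        return 0.0, 0.0
    return float(dx), float(dy)


#: multiple of the estimated response noise sd used as an automatic floor
NOISE_FLOOR_K = 5.0
#: 3x3 discrete biharmonic kernel for high-frequency noise estimation
_HF_KERNEL = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


def estimate_pixel_noise(pixels: np.ndarray) -> float:
    """Robust white-noise sd estimate from the 3x3 biharmonic response.

    Smooth image structure (Gaussian spots several pixels wide) barely
    excites this kernel, while white noise passes with gain
    sqrt(sum k^2) = 6; the median of |response| over the image therefore
    tracks the noise level even when spots cover most pixels.
    """
    hf = ndimage.convolve(pixels, _HF_KERNEL, mode="reflect")
    # median |N(0, 6 sd)| = 6 * 0.6745 * sd
    return float(np.median(np.abs(hf)) / (6.0 * 0.6745))


def detect_blobs(image: ArrayImage, params: DetectionParams = DetectionParams()) -> list[Blob]:
    """Multi-scale LoG detection with sub-pixel centroids.

    One blob per scale-space response maximum above the detection floor.
    The floor is the configured ``params.threshold`` or, on noisy scans,
    an automatic noise-adaptive level: NOISE_FLOOR_K times the standard
    deviation that white pixel noise of the estimated level induces in
    the finest-scale normalized LoG response (analytically
    sd_noise * sqrt(3/8pi) / sigma; the finest scale passes noise
    strongest, so this bounds spurious maxima at every scale).  On clean
    images the estimate is ~0 and the configured threshold rules.
    Returns an empty list on blank images.
    """
    sigmas = np.geomspace(params.min_sigma, params.max_sigma, params.num_sigma)
    px = image.pixels
    stack = np.stack(
        [-(s**2) * ndimage.gaussian_laplace(px, s) for s in sigmas], axis=0
    )
    noise_sd = estimate_pixel_noise(px)
    response_noise_sd = noise_sd * np.sqrt(3.0 / (8.0 * np.pi)) / sigmas[0]
    floor = max(params.threshold, NOISE_FLOOR_K * float(response_noise_sd))
    peaks = peak_local_max(
        stack,
        threshold_abs=floor,
        footprint=np.ones((3, 3, 3), dtype=bool),
        # keep every scale but drop maxima hugging the image border, where
        # filter boundary artifacts pile up on noisy scans
        exclude_border=(0, 2, 2),
    )
    h, w = px.shape
    blobs: list[Blob] = []
    for si, yi, xi in peaks:
        dx, dy = _subpixel_offset(stack[si], yi, xi)
        x = min(max(xi + dx, 0.0), w - 1e-9)
        y = min(max(yi + dy, 0.0), h - 1e-9)
        blobs.append(Blob(x=x, y=y, sigma=float(sigmas[si]), response=float(stack[si, yi, xi])))
    return blobs


def dedupe_by_radius(blobs: list[Blob], radius_filter: float) -> list[Blob]:
    """Suppress overlapping detections, keeping the largest blob.

    Greedy suppression in priority order (largest radius, then strongest
    response, then smaller (y, x)): a kept blob removes every other blob
    within ``radius_filter`` pixels of its centroid.  Output is a subset of
    the input, in input order.
    """
    if radius_filter <= 0:
        raise ConfigError("radius_filter must be > 0")
    if len(blobs) <= 1:
        return list(blobs)
    xy = blobs_xy(blobs)
    tree = cKDTree(xy)
    order = sorted(
        range(len(blobs)),
        key=lambda i: (-blobs[i].radius, -blobs[i].response, blobs[i].y, blobs[i].x),
    )
    alive = np.ones(len(blobs), dtype=bool)
    kept = np.zeros(len(blobs), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        kept[i] = True
        for j in tree.query_ball_point(xy[i], radius_filter):
            if j != i:
                alive[j] = False
    return [b for i, b in enumerate(blobs) if kept[i]]


def remove_outliers(
    blobs: list[Blob],
    cluster_eps: float | None = None,
    cluster_min_pts: int = 4,
) -> list[Blob]:
    """Drop isolated detections via DBSCAN on centroid coordinates.

    ``cluster_eps=None`` defaults to twice the median nearest-neighbour
    distance, i.e. roughly twice the grid pitch.  Points labelled noise are
    removed; if everything is noise an empty list is returned with a warning.
    """
    if len(blobs) < cluster_min_pts:
        warnings.warn("fewer blobs than cluster_min_pts; all removed as noise")
        return []
    if cluster_eps is None:
        cluster_eps = 2.0 * median_nn_distance(blobs)
        if cluster_eps <= 0:
            cluster_eps = 1.0
    labels = DBSCAN(eps=cluster_eps, min_samples=cluster_min_pts).fit_predict(blobs_xy(blobs))
    kept = [b for b, lab in zip(blobs, labels) if lab != -1]
    if not kept:
        warnings.warn("all blobs labelled noise by DBSCAN")
    return kept


def detect(image: ArrayImage, params: DetectionParams = DetectionParams()) -> list[Blob]:
    """Full detection stage: enhance -> LoG -> de-duplicate -> de-outlier."""
    enhanced = enhance_contrast(image, params.contrast_lower, params.contrast_upper)
    blobs = detect_blobs(enhanced, params)
    blobs = dedupe_by_radius(blobs, params.radius_filter)
    return remove_outliers(blobs, params.cluster_eps, params.cluster_min_pts)
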