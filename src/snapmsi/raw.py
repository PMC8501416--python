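"""Restoration of raw snapshot-mosaic fiberscope frames into 9-band image cubes.

Raw frames from the spectrally resolved detector array (SRDA) carry two
artifacts: a 3x3 mosaic pattern, because each sensor pixel sits behind one of
nine spectral filters, and a honeycomb "comb" pattern imprinted by the cores
of the imaging fiber bundle.  This module removes both: saturation masking,
dark subtraction, per-band demosaicing, fiber-core detection on a white
frame, and decombing by per-core sampling and interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

# Mask codes shared across the pipeline.  Higher stages may only add flags,
# never clear them (mask monotonicity).
MASK_VALID = 0
MASK_SATURATED = 1
MASK_LOW_SIGNAL = 2
MASK_OUT_OF_BUNDLE = 3

#: Saturation threshold on the 8-bit scale: pixels strictly above are flagged.
SATURATION_THRESHOLD = 250

#: Center wavelengths (nm) of the eight narrow bands; band 9 is broadband.
NARROW_BAND_CENTERS_NM = (553.0, 587.0, 629.0, 665.0, 714.0, 749.0, 791.0, 829.0)
BROADBAND_RANGE_NM = (500.0, 850.0)
N_BANDS = 9


@dataclass
class RawFrame:
    """One 8-bit sensor frame.

    ``pixels`` is a (H, W) uint8 array; the physical sensor is 1280x1024
    (W x H), i.e. arrays are (1024, 1280) row-major.
    """

    pixels: np.ndarray
    role: str = "sample"  # dark | white | sample
    exposure_ms: float = 200.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("RawFrame.pixels must be 2-D")
        if self.role not in ("dark", "white", "sample"):
            raise ValueError(f"unknown frame role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MosaicLayout:
    """3x3 assignment of mosaic positions to spectral bands.

    ``band_of_position[i, j]`` gives the 0-based band index recorded by the
    sensor pixel at mosaic position (i, j); the assignment must be a bijection
    onto the nine bands.  ``phase`` shifts the convention that frame pixel
    (0, 0) sits at mosaic position (0, 0), for sensor dialects whose readout
    window starts mid-superpixel.
    """

    band_of_position: np.ndarray = None
    phase: tuple[int, int] = (0, 0)
    band_centers_nm: tuple = NARROW_BAND_CENTERS_NM
    fwhm_nm: float = 30.0

    def __post_init__(self) -> None:
        if self.band_of_position is None:
            self.band_of_position = np.arange(9).reshape(3, 3)
        self.band_of_position = np.asarray(self.band_of_position)
        if self.band_of_position.shape != (3, 3):
            raise ValueError("band_of_position must be 3x3")
        if sorted(self.band_of_position.ravel().tolist()) != list(range(9)):
            raise ValueError("band_of_position must be a bijection onto bands 0..8")

    def band_index_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Band index recorded at every pixel of a frame of the given shape."""
        rows = (np.arange(shape[0])[:, None] + self.phase[0]) % 3
        cols = (np.arange(shape[1])[None, :] + self.phase[1]) % 3
        return self.band_of_position[rows, cols]


@dataclass
class FiberMap:
    """Detected (or simulated) fiber-core geometry for one bundle.

    ``centers`` are (n, 2) sub-pixel (row, col) coordinates; ``core_radius``
    is a representative core radius in pixels; the bundle footprint is the
    disc of ``bundle_radius`` around ``bundle_center``.
    """

    centers: np.ndarray
    core_radius: float
    bundle_center: tuple[float, float]
    bundle_radius: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            raise ValueError("FiberMap requires at least one core")
        if self.bundle_radius <= 0:
            raise ValueError("bundle radius must be positive")

    @property
    def n_cores(self) -> int:
        return len(self.centers)


@dataclass
class ImageCube:
    """H x W x 9 band stack with a per-pixel validity mask and labels.

    ``mask`` holds one code per pixel (see MASK_* constants); any nonzero
    code excludes the pixel from all downstream statistics.  ``stages``
    records the processing history so the pipeline order is auditable.
    """

    values: np.ndarray
    mask: np.ndarray
    labels: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.values.ndim != 3 or self.values.shape[2] != N_BANDS:
            raise ValueError("ImageCube values must be H x W x 9")
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask and values must share spatial dimensions")

    @property
    def valid(self) -> np.ndarray:
        return self.mask == MASK_VALID

    def copy(self) -> "ImageCube":
        return ImageCube(
            self.values.copy(), self.mask.copy(), dict(self.labels), list(self.stages)
        )


def check_saturation_mask(frame: RawFrame) -> np.ndarray:
    """Flag saturated pixels: 8-bit values strictly greater than 250.

    Saturated pixels (typically specular reflections) propagate into the
    cube mask and are excluded from classification.
    """
    return np.asarray(frame.pixels) > SATURATION_THRESHOLD


def dark_subtract(frame: RawFrame, dark: RawFrame) -> np.ndarray:
    """Subtract the dark frame, clamping the difference at zero.

    Returns a real-valued (H, W) array on the raw intensity scale.
    """
    if frame.shape != dark.shape:
        raise ValueError(f"frame shape {frame.shape} != dark shape {dark.shape}")
    out = frame.pixels.astype(float) - dark.pixels.astype(float)
    np.maximum(out, 0.0, out=out)
    return out


def demosaic(frame: np.ndarray, mosaic: MosaicLayout) -> np.ndarray:
    """Separate the nine spectral bands of a corrected frame.

    For each band, the pixels at that band's mosaic positions are retained
    and the band plane is filled to full resolution by bilinear
    interpolation (exact on affine images, and exact at the sample points
    themselves).  Output is (H, W, 9).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("demosaic expects a 2-D corrected frame")
    h, w = frame.shape
    out = np.empty((h, w, N_BANDS), dtype=float)
    rows_full = np.arange(h, dtype=float)
    cols_full = np.arange(w, dtype=float)
    for i in range(3):
        for j in range(3):
            band = int(mosaic.band_of_position[i, j])
            r0 = (i - mosaic.phase[0]) % 3
            c0 = (j - mosaic.phase[1]) % 3
            sub = frame[r0::3, c0::3]
            samp_rows = np.arange(r0, h, 3, dtype=float)
            samp_cols = np.arange(c0, w, 3, dtype=float)
            # fractional index of every output pixel in the coarse sample grid,
            # clipped so the border extrapolates with the nearest sample
            fr = np.clip((rows_full - r0) / 3.0, 0.0, len(samp_rows) - 1.0)
            fc = np.clip((cols_full - c0) / 3.0, 0.0, len(samp_cols) - 1.0)
            coords = np.meshgrid(fr, fc, indexing="ij")
            out[:, :, band] = ndimage.map_coordinates(
                sub, coords, order=1, mode="nearest"
            )
    return out


def detect_fiber_cores(
    white_frame: np.ndarray,
    min_distance: int = 5,
    rel_threshold: float = 0.25,
) -> FiberMap:
    """Locate fiber-core centers on a (dark-subtracted) white frame.

    Cores appear as bright local maxima of the comb pattern.  The frame is
    lightly smoothed, local maxima above ``rel_threshold`` of the frame
    maximum and at least ``min_distance`` apart are kept, and centers are
    refined to sub-pixel precision with an intensity centroid over a small
    neighborhood.  The bundle footprint is estimated from the detected
    cores.  Raises ValueError on a featureless frame.
    """
    from skimage.feature import peak_local_max

    img = np.asarray(white_frame, dtype=float)
    if np.ptp(img) <= 0:
        raise ValueError("featureless frame: no fiber cores found")
    smooth = ndimage.gaussian_filter(img, 1.0)
    peaks = peak_local_max(
        smooth,
        min_distance=min_distance,
        threshold_abs=rel_threshold * smooth.max(),
        exclude_border=False,
    )
    if len(peaks) == 0:
        raise ValueError("featureless frame: no fiber cores found")

    # sub-pixel refinement: centroid over a 5x5 patch around each peak
    h, w = img.shape
    centers = np.empty((len(peaks), 2), dtype=float)
    for k, (pr, pc) in enumerate(peaks):
        r0, r1 = max(pr - 2, 0), min(pr + 3, h)
        c0, c1 = max(pc - 2, 0), min(pc + 3, w)
        patch = smooth[r0:r1, c0:c1]
        tot = patch.sum()
        if tot <= 0:
            centers[k] = (pr, pc)
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers[k] = ((rr * patch).sum() / tot, (cc * patch).sum() / tot)

    # spacing -> core radius estimate; cores fill ~0.8 of the lattice pitch
    if len(centers) >= 2:
        tree = cKDTree(centers)
        dists, _ = tree.query(centers, k=2)
        pitch = float(np.median(dists[:, 1]))
    else:
        pitch = 2.0 * min_distance
    core_radius = 0.4 * pitch

    bundle_center = tuple(centers.mean(axis=0))
    d = np.hypot(centers[:, 0] - bundle_center[0], centers[:, 1] - bundle_center[1])
    bundle_radius = float(d.max() + pitch)
    return FiberMap(centers, core_radius, bundle_center, bundle_radius)


def decomb(
    stack: np.ndarray,
    fibers: FiberMap,
    sampling_radius: float | None = None,
    n_neighbors: int = 4,
    idw_power: float = 2.0,
) -> ImageCube:
    """Remove the fiber-bundle comb pattern from a demosaiced band stack.

    Per band, the value carried by each fiber core is taken as the mean of
    the band's pixels within ``sampling_radius`` of the core center (default
    a conservative fraction of the core radius, so only the flat-topped part
    of the core transmission profile is sampled).  Every pixel inside the
    bundle footprint is then filled by inverse-distance-weighted
    interpolation from the ``n_neighbors`` nearest core values (the nearest
    core alone at zero distance); pixels outside the footprint are masked
    out-of-bundle.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != N_BANDS:
        raise ValueError("decomb expects an H x W x 9 stack")
    if fibers.n_cores == 0:
        raise ValueError("empty FiberMap")
    h, w = stack.shape[:2]
    if sampling_radius is None:
        # stay well inside the flat core top: demosaicing pulls samples from
        # up to 3 px away, which must remain within the core
        sampling_radius = max(1.0, 0.35 * fibers.core_radius)

    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    tree = cKDTree(fibers.centers)
    k = min(n_neighbors, fibers.n_cores)
    dists, idx = tree.query(pix, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]

    # per-core sample values: mean of pixels within sampling_radius of the
    # center (sampling_radius < half the pitch, so a pixel in range of any
    # core is in range of its nearest core)
    flat = stack.reshape(-1, N_BANDS)
    core_sums = np.zeros((fibers.n_cores, N_BANDS))
    core_counts = np.zeros(fibers.n_cores)
    sel = dists[:, 0] <= sampling_radius
    np.add.at(core_sums, idx[sel, 0], flat[sel])
    np.add.at(core_counts, idx[sel, 0], 1)
    # cores with no in-radius pixel fall back to the nearest pixel's value
    empty = core_counts == 0
    if empty.any():
        nearest_pix = np.round(fibers.centers[empty]).astype(int)
        nearest_pix[:, 0] = np.clip(nearest_pix[:, 0], 0, h - 1)
        nearest_pix[:, 1] = np.clip(nearest_pix[:, 1], 0, w - 1)
        core_sums[empty] = stack[nearest_pix[:, 0], nearest_pix[:, 1]]
        core_counts[empty] = 1
    core_values = core_sums / core_counts[:, None]
    exact = dists[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        weights = 1.0 / dists**idw_power
    weights[exact] = 0.0
    weights[exact, 0] = 1.0
    weights /= weights.sum(axis=1, keepdims=True)
    values = np.einsum("pk,pkb->pb", weights, core_values[idx]).reshape(h, w, N_BANDS)

    mask = np.zeros((h, w), dtype=np.uint8)
    in_bundle = (
        np.hypot(rr - fibers.bundle_center[0], cc - fibers.bundle_center[1])
        <= fibers.bundle_radius
    )
    mask[~in_bundle] = MASK_OUT_OF_BUNDLE
    return ImageCube(values, mask, stages=["decomb"])


def restore_frame(
    frame: RawFrame,
    dark: RawFrame,
    mosaic: MosaicLayout,
    fibers: FiberMap,
    labels: dict | None = None,
    decomb_enabled: bool = True,
) -> ImageCube:
    """Full raw-frame restoration: saturation mask, dark subtraction,
    demosaicing, decombing.  Returns an ImageCube on the raw intensity
    scale with the saturation mask applied and the stage ledger filled in.
    """
    saturated = check_saturation_mask(frame)
    corrected = dark_subtract(frame, dark)
    stack = demosaic(corrected, mosaic)
    if decomb_enabled:
        cube = decomb(stack, fibers)
        stages = ["saturation", "dark_subtract", "demosaic", "decomb"]
    else:
        cube = ImageCube(stack, np.zeros(stack.shape[:2], dtype=np.uint8))
        stages = ["saturation", "dark_subtract", "demosaic"]
    cube.mask[saturated & (cube.mask == MASK_VALID)] = MASK_SATURATED
    cube.labels = dict(labels or {})
    cube.stages = stages
    return cube
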