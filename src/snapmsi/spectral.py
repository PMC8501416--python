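"""Spectral processing of restored image cubes.

Implements the chain that turns a restored 9-band cube into classifiable
spectra: low-signal masking on the raw intensity scale, division by the
per-procedure white reference spectrum, 32x32 spatial binning (1280x1024
frames become 40x32x9 cubes, i.e. 1280 "per-pixel" spectra per cube),
max-normalization, and the image- and patient-level mean spectra.

Order matters and is audited through each cube's stage ledger:
saturation -> dark subtraction -> demosaic/decomb -> low-signal mask ->
white reference -> binning -> max-normalization.  The mean image spectrum
is taken over un-normalized spectra (so brighter pixels weigh more) and
only then max-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raw import (
    ImageCube,
    MASK_LOW_SIGNAL,
    MASK_VALID,
    N_BANDS,
)

#: low-signal threshold on the raw (pre-reference) intensity scale: pixels
#: whose 9-band maximum is strictly below this are removed
LOW_SIGNAL_THRESHOLD = 50.0

#: canonical pipeline stage order, asserted by tests via the stage ledger
STAGE_ORDER = (
    "saturation",
    "dark_subtract",
    "demosaic",
    "decomb",
    "low_signal",
    "white_reference",
    "bin_spatial",
    "max_normalize",
)


@dataclass
class Spectrum:
    """One 9-band spectrum at a stated aggregation level."""

    y: np.ndarray
    level: str = "pixel"  # pixel | image | patient
    labels: dict = field(default_factory=dict)
    normalized: bool = False
    n_pixels: int = 1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_BANDS,):
            raise ValueError("Spectrum must have exactly 9 bands")
        if np.any(self.y < 0):
            raise ValueError("Spectrum values must be nonnegative")


@dataclass
class WhiteReference:
    """Averaged white-standard spectrum for one procedure (strictly
    positive in every band)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (N_BANDS,):
            raise ValueError("WhiteReference must have exactly 9 bands")
        if np.any(self.w <= 0):
            raise ValueError("WhiteReference must be strictly positive in every band")


def mask_low_signal(cube: ImageCube, threshold: float = LOW_SIGNAL_THRESHOLD) -> ImageCube:
    """Flag pixels whose 9-band maximum is strictly below ``threshold``.

    Operates on the pre-reference intensity scale; already-invalid pixels
    keep their existing mask code.
    """
    out = cube.copy()
    low = (out.values.max(axis=2) < threshold) & (out.mask == MASK_VALID)
    out.mask[low] = MASK_LOW_SIGNAL
    out.stages = list(cube.stages) + ["low_signal"]
    return out


def apply_white_reference(cube: ImageCube, ref: WhiteReference) -> ImageCube:
    """Band-wise division by the white reference spectrum."""
    out = cube.copy()
    out.values = out.values / ref.w[None, None, :]
    out.stages = list(cube.stages) + ["white_reference"]
    return out


def max_normalize(spectrum: Spectrum) -> Spectrum:
    """Normalize a spectrum to its maximum, which becomes exactly 1."""
    m = spectrum.y.max()
    if m <= 0:
        raise ValueError("cannot max-normalize an all-zero spectrum")
    return Spectrum(
        y=spectrum.y / m,
        level=spectrum.level,
        labels=dict(spectrum.labels),
        normalized=True,
        n_pixels=spectrum.n_pixels,
    )


def max_normalize_cube(cube: ImageCube) -> ImageCube:
    """Max-normalize every valid per-pixel spectrum of a cube in place
    semantics (returns a new cube); all-zero valid spectra gain the
    low-signal mask flag."""
    out = cube.copy()
    m = out.values.max(axis=2)
    zero = (m <= 0) & (out.mask == MASK_VALID)
    out.mask[zero] = MASK_LOW_SIGNAL
    safe = np.where(m > 0, m, 1.0)
    out.values = out.values / safe[:, :, None]
    out.stages = list(cube.stages) + ["max_normalize"]
    return out


def bin_spatial(cube: ImageCube, block: int = 32) -> ImageCube:
    """Bin the spatial dimensions into ``block`` x ``block`` cells.

    Each output pixel is the per-band mean over the *valid* input pixels of
    its block; blocks with no valid pixel are masked (low-signal code, the
    same exclusion downstream sees).  A 1280x1024 frame yields a 40x32
    (W x H) cube, i.e. a (32, 40, 9) array.
    """
    if block < 1:
        raise ValueError("block size must be positive")
    h, w = cube.values.shape[:2]
    if block > h or block > w:
        raise ValueError("block larger than frame")
    nh, nw = h // block, w // block
    vals = cube.values[: nh * block, : nw * block]
    valid = (cube.mask[: nh * block, : nw * block] == MASK_VALID).astype(float)
    v = vals.reshape(nh, block, nw, block, N_BANDS)
    m = valid.reshape(nh, block, nw, block)
    counts = m.sum(axis=(1, 3))
    sums = (v * m[:, :, :, :, None]).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, :, None]
    out_mask = np.where(counts > 0, MASK_VALID, MASK_LOW_SIGNAL).astype(np.uint8)
    means[counts == 0] = 0.0
    return ImageCube(
        means,
        out_mask,
        labels=dict(cube.labels),
        stages=list(cube.stages) + ["bin_spatial"],
    )


def mean_image_spectrum(
    cube: ImageCube,
    roi_radius_frac: float = 0.5,
    center: tuple[float, float] | None = None,
    bundle_radius: float | None = None,
) -> Spectrum:
    """Mean spectrum of one cube over a central circular region of interest.

    The mean is taken over the *un-normalized* (post-reference-division)
    spectra of valid ROI pixels and only then max-normalized, so brighter
    pixels contribute more.  The ROI is a disc of ``roi_radius_frac`` times
    the bundle radius around the bundle center (defaults: image center,
    radius half the smaller image dimension).
    """
    h, w = cube.values.shape[:2]
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if bundle_radius is None:
        bundle_radius = min(h, w) / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    roi = (
        np.hypot(rr - center[0], cc - center[1]) <= roi_radius_frac * bundle_radius
    ) & (cube.mask == MASK_VALID)
    if not roi.any():
        raise ValueError("ROI contains no valid pixels")
    mean = cube.values[roi].mean(axis=0)
    spec = Spectrum(
        y=mean, level="image", labels=dict(cube.labels), n_pixels=int(roi.sum())
    )
    return max_normalize(spec)


def patient_spectrum(images: list) -> Spectrum:
    """Mean of image spectra of one tissue class within one patient,
    max-normalized.  All inputs must share class and patient labels."""
    if not images:
        raise ValueError("patient_spectrum requires at least one image spectrum")
    keys = {(s.labels.get("class"), s.labels.get("patient")) for s in images}
    if len(keys) > 1:
        raise ValueError(f"mixed class/patient labels: {sorted(keys)}")
    mean = np.mean([s.y for s in images], axis=0)
    spec = Spectrum(
        y=mean,
        level="patient",
        labels=dict(images[0].labels),
        n_pixels=sum(s.n_pixels for s in images),
    )
    return max_normalize(spec)


def compute_white_reference(
    white_cubes: list,
    roi_radius_frac: float = 0.5,
) -> WhiteReference:
    """Average restored white-standard cubes into the 9-band reference.

    Each white cube is averaged over the central ROI (valid pixels only);
    the per-cube spectra are then averaged across acquisitions.
    """
    if not white_cubes:
        raise ValueError("no white frames supplied")
    spectra = []
    for cube in white_cubes:
        h, w = cube.values.shape[:2]
        rr, cc = np.mgrid[0:h, 0:w]
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
        roi = (
            np.hypot(rr - center[0], cc - center[1])
            <= roi_radius_frac * min(h, w) / 2.0
        ) & (cube.mask == MASK_VALID)
        if not roi.any():
            raise ValueError("white cube has no valid ROI pixels")
        spectra.append(cube.values[roi].mean(axis=0))
    return WhiteReference(w=np.mean(spectra, axis=0))
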