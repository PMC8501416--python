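"""Synthetic raw-frame generator for snapshot mosaic multispectral endoscopy.

No public dataset of in-vivo esophageal frames exists for this instrument
class, so every downstream stage is exercised against synthetic acquisitions
that reproduce the statistical structure the analysis assumes:

* nine spectral bands (eight narrow + one broadband) interleaved as a 3x3
  mosaic on the sensor;
* a honeycomb comb pattern from a ~10,000-core imaging fiber bundle, with
  near-dark inter-core gaps;
* three tissue classes (squamous / NDBE / neoplasia) with a hierarchical
  patient -> image -> pixel variance structure on reflectance;
* specular (saturated) regions and radial illumination falloff;
* a 24-patch Macbeth-style color chart mode (18 chromatic + 6 achromatic
  patches) for controlled validation.

All randomness is driven by explicit seeds; identical configuration and seed
give bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .raw import FiberMap, MosaicLayout, RawFrame, N_BANDS

CLASS_NAMES = ("squamous", "ndbe", "neoplasia")

#: relative spectral throughput of source x filters, divided out later by the
#: white reference; a fixed smooth non-flat profile so that the white
#: referencing step is actually exercised
BAND_THROUGHPUT = np.array([0.85, 0.95, 1.00, 0.98, 0.92, 0.86, 0.79, 0.72, 0.90])


@dataclass
class SpectralModel:
    """Three-class tissue reflectance model with hierarchical variance.

    ``class_means`` holds one 9-band mean reflectance vector per class, in
    [0, 1].  Band-wise Gaussian perturbations are added at three levels —
    per patient (``sigma_patient``), per image cube (``sigma_image``) and
    per classification pixel (``sigma_pixel``) — and the result is clipped
    to [0, 1].  A "classification pixel" is one 32x32 cell of the raw frame,
    the unit on which per-pixel spectra are computed downstream.

    Default counts approximate the scale of the source study cohort
    (15 patients, ~727 cubes); tests and demos pass smaller counts.
    """

    class_means: np.ndarray
    sigma_patient: float = 0.04
    sigma_image: float = 0.03
    sigma_pixel: float = 0.10
    n_patients: int = 15
    regions_per_patient: int = 2
    cubes_per_region: int = 24
    noise_cell: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        if self.class_means.shape != (3, N_BANDS):
            raise ValueError("class_means must be 3 x 9")
        if np.any(self.class_means < 0) or np.any(self.class_means > 1):
            raise ValueError("class mean reflectances must lie in [0, 1]")
        for name in ("sigma_patient", "sigma_image", "sigma_pixel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("n_patients", "regions_per_patient", "cubes_per_region"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChartModel:
    """24-patch color chart: 18 chromatic patches + 6 achromatic grays.

    ``patch_reflectances`` is (24, 9); the first 18 rows are chromatic
    (non-flat across the eight narrow bands), the last 6 are neutral grays
    (flat across the narrow bands).  ``layout`` is the physical 4x6 grid.
    """

    patch_reflectances: np.ndarray
    layout: tuple[int, int] = (4, 6)
    frames_per_patch: int = 24
    sigma_pixel: float = 0.03
    noise_cell: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        self.patch_reflectances = np.asarray(self.patch_reflectances, dtype=float)
        if self.patch_reflectances.shape != (24, N_BANDS):
            raise ValueError("chart needs exactly 24 patch reflectances of 9 bands")
        if self.layout[0] * self.layout[1] != 24:
            raise ValueError("layout must cover 24 patches")


@dataclass
class SceneGroundTruth:
    """Per-pixel ground truth for one simulated frame."""

    class_grid: np.ndarray  # (H, W) int class / patch index
    patient: int = 0
    region: int = 0
    cube_id: int = 0
    label: str = ""
    specular_mask: np.ndarray | None = None
    band_offset: np.ndarray = field(default_factory=lambda: np.zeros(N_BANDS))

    def __post_init__(self) -> None:
        self.class_grid = np.asarray(self.class_grid)
        if self.specular_mask is not None:
            self.specular_mask = np.asarray(self.specular_mask, dtype=bool)
            if self.specular_mask.shape != self.class_grid.shape:
                raise ValueError("specular mask must match the label grid")
        self.band_offset = np.asarray(self.band_offset, dtype=float)


# ---------------------------------------------------------------------------
# spectra


def _smooth_bumps(centers, widths, amps) -> np.ndarray:
    """Sum of Gaussian bumps over band index 0..8, used to build smooth
    synthetic reflectance curves."""
    x = np.arange(N_BANDS, dtype=float)
    out = np.zeros(N_BANDS)
    for c, w, a in zip(centers, widths, amps):
        out += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return out


def generate_class_spectra(seed: int, separation: float, **model_kw) -> SpectralModel:
    """Build a three-class SpectralModel with controllable class separation.

    Class means are a shared smooth base curve plus ``separation`` times a
    fixed, class-specific smooth unit direction (two Gaussian bumps over
    band index), so pairwise L2 distances scale linearly with
    ``separation`` and ``separation=0`` yields identical means.  The curves
    are synthetic: amplitudes are arbitrary-but-fixed, not digitized tissue
    reflectances.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    base = 0.45 + _smooth_bumps([2.0, 6.5], [1.8, 1.5], [0.18, 0.12])
    base += 0.02 * rng.standard_normal()  # small seed-dependent overall level
    directions = np.stack(
        [
            _smooth_bumps([1.0, 5.0], [1.2, 2.0], [1.0, -0.6]),
            _smooth_bumps([3.5, 7.5], [1.5, 1.2], [-0.8, 0.9]),
            _smooth_bumps([0.5, 4.5], [1.0, 2.5], [-0.5, 0.8]),
        ]
    )
    directions -= directions.mean(axis=1, keepdims=True)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = np.clip(base[None, :] + separation * directions, 0.0, 1.0)
    return SpectralModel(class_means=means, seed=seed, **model_kw)


def make_chart_model(seed: int = 0, **chart_kw) -> ChartModel:
    """Construct the 24-patch chart: 18 chromatic + 6 achromatic patches.

    Chromatic patches are smooth single- or double-bump reflectance curves
    with peak positions spread over the eight narrow bands; the broadband
    value is the mean narrow-band reflectance.  Achromatic patches are a
    six-step neutral gray lightness scale (flat narrow-band spectrum).
    The gray floor is chosen so that even the darkest patch stays above the
    low-signal cutoff at nominal exposure — every patch of the physical
    chart is classifiable.
    """
    rng = np.random.default_rng(seed)
    patches = np.empty((24, N_BANDS))
    x = np.arange(8, dtype=float)
    for k in range(18):
        mu = 7.0 * (k % 9) / 8.0 + rng.uniform(-0.3, 0.3)
        width = rng.uniform(1.0, 2.2)
        amp = rng.uniform(0.35, 0.6)
        level = rng.uniform(0.08, 0.25)
        curve = level + amp * np.exp(-0.5 * ((x - mu) / width) ** 2)
        if k >= 9:  # second set: add a secondary bump for two-lobed hues
            mu2 = (mu + 4.0) % 8.0
            curve += 0.5 * amp * np.exp(-0.5 * ((x - mu2) / width) ** 2)
        patches[k, :8] = np.clip(curve, 0.0, 1.0)
        patches[k, 8] = patches[k, :8].mean()
    gray_levels = np.linspace(0.9, 0.35, 6)
    for k, g in enumerate(gray_levels):
        patches[18 + k, :] = g
    return ChartModel(patch_reflectances=patches, seed=seed, **chart_kw)


# ---------------------------------------------------------------------------
# geometry: fiber bundle, transmission, illumination


def make_fiber_map(
    frame_shape: tuple[int, int] = (1024, 1280),
    n_cores: int = 10000,
    seed: int = 0,
    jitter: float = 0.35,
    bundle_radius_frac: float = 0.47,
) -> FiberMap:
    """Lay fiber cores on a jittered hexagonal lattice.

    ``n_cores`` sets the lattice density as cores per full-frame area; only
    cores inside the circular bundle footprint are kept.  The default
    density gives a lattice pitch of ~12 px on a 1280x1024 frame,
    consistent with a 10,000-fiberlet bundle.
    """
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    pitch = np.sqrt(2.0 * h * w / (np.sqrt(3.0) * n_cores))
    row_step = pitch * np.sqrt(3.0) / 2.0
    rows = np.arange(0.0, h, row_step)
    centers = []
    for i, r in enumerate(rows):
        offset = 0.5 * pitch if i % 2 else 0.0
        cols = np.arange(offset, w, pitch)
        centers.append(np.column_stack([np.full_like(cols, r), cols]))
    centers = np.concatenate(centers)
    centers += rng.normal(0.0, jitter, size=centers.shape)

    bundle_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    bundle_radius = bundle_radius_frac * min(h, w)
    d = np.hypot(centers[:, 0] - bundle_center[0], centers[:, 1] - bundle_center[1])
    inside = d <= bundle_radius - 0.6 * pitch
    centers = centers[inside]
    centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    return FiberMap(
        centers=centers,
        core_radius=0.4 * pitch,
        bundle_center=bundle_center,
        bundle_radius=bundle_radius,
    )


def fiber_transmission(
    fibers: FiberMap,
    frame_shape: tuple[int, int],
    flat_radius_frac: float = 1.15,
    edge_width_frac: float = 0.09,
) -> np.ndarray:
    """Per-pixel transmission of the fiber bundle comb.

    Each core transmits fully (T = 1) inside a flat top of radius
    ``flat_radius_frac * core_radius`` and falls off as a Gaussian of width
    ``edge_width_frac * pitch`` beyond it, so inter-core gaps are near dark
    and everything outside the bundle footprint goes to zero.  The flat top
    is wide enough that demosaicing near a core center only ever draws on
    fully transmitting pixels.
    """
    h, w = frame_shape
    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(fibers.centers)
    d, _ = tree.query(pix)
    pitch = fibers.core_radius / 0.4
    flat_radius = flat_radius_frac * fibers.core_radius
    width = max(edge_width_frac * pitch, 0.3)
    t = np.where(
        d <= flat_radius, 1.0, np.exp(-(((d - flat_radius) / width) ** 2))
    )
    return t.reshape(h, w)


def illumination_field(
    frame_shape: tuple[int, int],
    fibers: FiberMap,
    falloff: float = 0.35,
) -> np.ndarray:
    """Radial illumination: bright at the bundle center, darker at the edge.

    ``falloff`` is the fractional drop at the bundle radius; 0 gives flat
    illumination.
    """
    h, w = frame_shape
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.hypot(rr - fibers.bundle_center[0], cc - fibers.bundle_center[1])
    return np.clip(1.0 - falloff * (d / fibers.bundle_radius) ** 2, 0.05, 1.0)


# ---------------------------------------------------------------------------
# frame rendering


def _quantize_8bit(values: np.ndarray) -> np.ndarray:
    """8-bit quantization by rounding half away from zero, clamped at 255."""
    return np.clip(np.floor(values + 0.5), 0, 255).astype(np.uint8)


def _cell_noise(
    rng: np.random.Generator, frame_shape: tuple[int, int], cell: int, sigma: float
) -> np.ndarray:
    """Band-wise Gaussian pixel-level noise, drawn once per classification
    cell (``cell`` x ``cell`` block) and upsampled to frame resolution."""
    h, w = frame_shape
    nh = -(-h // cell)
    nw = -(-w // cell)
    grid = rng.normal(0.0, sigma, size=(nh, nw, N_BANDS)) if sigma > 0 else np.zeros(
        (nh, nw, N_BANDS)
    )
    up = np.repeat(np.repeat(grid, cell, axis=0), cell, axis=1)
    return up[:h, :w]


def simulate_raw_frame(
    reflectances: np.ndarray,
    truth: SceneGroundTruth,
    fibers: FiberMap,
    mosaic: MosaicLayout | None = None,
    dark_level: float = 8.0,
    seed: int = 0,
    sigma_pixel: float = 0.0,
    noise_cell: int = 32,
    white_level: float = 220.0,
    transmission: np.ndarray | None = None,
    illumination: np.ndarray | None = None,
) -> RawFrame:
    """Render one raw 8-bit mosaic+comb frame from a labeled scene.

    ``reflectances`` is an (n_classes, 9) table indexed by ``truth.class_grid``.
    Each pixel records, in the single band selected by its mosaic position::

        value = quantize8(dark_level
                          + white_level * illumination * throughput[band]
                            * transmission * clip(R + offsets + noise, 0, 1))

    where ``R`` is the class reflectance in that band, ``offsets`` is the
    per-frame patient+image perturbation carried by the truth record, and
    ``noise`` is band-wise Gaussian pixel noise drawn per classification
    cell.  Specular pixels are set to 255.
    """
    if not 0 <= dark_level < 255:
        raise ValueError("dark_level must lie in [0, 255)")
    shape = truth.class_grid.shape
    if mosaic is None:
        mosaic = MosaicLayout()
    if transmission is None:
        transmission = fiber_transmission(fibers, shape)
    if illumination is None:
        illumination = illumination_field(shape, fibers)
    if transmission.shape != shape or illumination.shape != shape:
        raise ValueError("truth/frame size mismatch")

    reflectances = np.asarray(reflectances, dtype=float)
    rng = np.random.default_rng(seed)
    band_map = mosaic.band_index_map(shape)

    refl = reflectances[truth.class_grid] + truth.band_offset[None, None, :]
    if sigma_pixel > 0:
        refl = refl + _cell_noise(rng, shape, noise_cell, sigma_pixel)
    refl = np.clip(refl, 0.0, 1.0)
    refl_at_band = np.take_along_axis(refl, band_map[..., None], axis=2)[..., 0]

    signal = (
        dark_level
        + white_level
        * illumination
        * BAND_THROUGHPUT[band_map]
        * transmission
        * refl_at_band
    )
    pixels = _quantize_8bit(signal)
    if truth.specular_mask is not None:
        pixels[truth.specular_mask] = 255
    return RawFrame(
        pixels=pixels,
        role="sample",
        meta={
            "patient": truth.patient,
            "region": truth.region,
            "cube_id": truth.cube_id,
            "label": truth.label,
        },
    )


def _specular_mask(
    rng: np.random.Generator, shape: tuple[int, int], fibers: FiberMap
) -> np.ndarray | None:
    """With 30% probability, one or two saturated glare discs inside the
    bundle footprint."""
    if rng.random() > 0.3:
        return None
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, 3)):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.6) * fibers.bundle_radius
        cy = fibers.bundle_center[0] + rad * np.sin(ang)
        cx = fibers.bundle_center[1] + rad * np.cos(ang)
        r = rng.uniform(0.02, 0.05) * min(h, w)
        mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
    return mask


@dataclass
class SimulatedDataset:
    """Output of a dataset simulation: sample frames with ground truth plus
    per-patient dark and white reference frames."""

    frames: list
    truths: list
    references: dict  # patient -> {"dark": RawFrame, "white": [RawFrame, ...]}
    fibers: FiberMap
    mosaic: MosaicLayout


def simulate_procedure_dataset(
    model: SpectralModel,
    frame_shape: tuple[int, int] = (1024, 1280),
    n_cores: int = 10000,
    n_white_frames: int = 10,
    dark_level: float = 8.0,
    white_level: float = 220.0,
    illumination_falloff: float = 0.35,
    specular: bool = True,
    mosaic: MosaicLayout | None = None,
) -> SimulatedDataset:
    """Simulate a full multi-patient acquisition campaign.

    Emits ``n_patients x regions_per_patient x cubes_per_region`` sample
    frames.  Each region carries one tissue class (regions alternate
    through the three classes so every class appears); each patient gets a
    dark frame and ``n_white_frames`` white-standard frames taken under the
    same bundle and illumination.  The number of white frames per procedure
    is a free parameter of the generator (the acquisition protocol it
    emulates does not pin it down).
    """
    rng = np.random.default_rng(model.seed)
    if mosaic is None:
        mosaic = MosaicLayout()
    fibers = make_fiber_map(frame_shape, n_cores=n_cores, seed=model.seed)
    transmission = fiber_transmission(fibers, frame_shape)
    illum = illumination_field(frame_shape, fibers, falloff=illumination_falloff)

    white_refl = np.ones((1, N_BANDS))
    frames: list[RawFrame] = []
    truths: list[SceneGroundTruth] = []
    references: dict[int, dict] = {}
    cube_id = 0
    for p in range(model.n_patients):
        patient_offset = rng.normal(0.0, model.sigma_patient, size=N_BANDS)
        dark = RawFrame(
            pixels=_quantize_8bit(np.full(frame_shape, dark_level)),
            role="dark",
            meta={"patient": p},
        )
        whites = []
        for wi in range(n_white_frames):
            wtruth = SceneGroundTruth(
                class_grid=np.zeros(frame_shape, dtype=np.int8), patient=p
            )
            wf = simulate_raw_frame(
                white_refl,
                wtruth,
                fibers,
                mosaic,
                dark_level=dark_level,
                seed=int(rng.integers(2**31)),
                sigma_pixel=0.0,
                white_level=white_level,
                transmission=transmission,
                illumination=illum,
            )
            wf.role = "white"
            wf.meta = {"patient": p, "white_index": wi}
            whites.append(wf)
        references[p] = {"dark": dark, "white": whites}

        for r in range(model.regions_per_patient):
            cls = (p * model.regions_per_patient + r) % 3
            for _c in range(model.cubes_per_region):
                image_offset = rng.normal(0.0, model.sigma_image, size=N_BANDS)
                truth = SceneGroundTruth(
                    class_grid=np.full(frame_shape, cls, dtype=np.int8),
                    patient=p,
                    region=r,
                    cube_id=cube_id,
                    label=CLASS_NAMES[cls],
                    specular_mask=_specular_mask(rng, frame_shape, fibers)
                    if specular
                    else None,
                    band_offset=patient_offset + image_offset,
                )
                frame = simulate_raw_frame(
                    model.class_means,
                    truth,
                    fibers,
                    mosaic,
                    dark_level=dark_level,
                    seed=int(rng.integers(2**31)),
                    sigma_pixel=model.sigma_pixel,
                    noise_cell=model.noise_cell,
                    white_level=white_level,
                    transmission=transmission,
                    illumination=illum,
                )
                frames.append(frame)
                truths.append(truth)
                cube_id += 1
    return SimulatedDataset(frames, truths, references, fibers, mosaic)


def simulate_color_chart_dataset(
    chart: ChartModel,
    frame_shape: tuple[int, int] = (1024, 1280),
    n_cores: int = 10000,
    n_white_frames: int = 10,
    dark_level: float = 8.0,
    white_level: float = 220.0,
    illumination_falloff: float = 0.35,
    mosaic: MosaicLayout | None = None,
) -> SimulatedDataset:
    """Simulate handheld imaging of the 24-patch chart.

    The field of view covers a single patch per frame (plus illumination
    falloff at the edges); labels are the patch identities 1..24.  All
    frames share one reference set (one simulated procedure).
    """
    rng = np.random.default_rng(chart.seed)
    if mosaic is None:
        mosaic = MosaicLayout()
    fibers = make_fiber_map(frame_shape, n_cores=n_cores, seed=chart.seed)
    transmission = fiber_transmission(fibers, frame_shape)
    illum = illumination_field(frame_shape, fibers, falloff=illumination_falloff)

    dark = RawFrame(
        pixels=_quantize_8bit(np.full(frame_shape, dark_level)),
        role="dark",
        meta={"patient": 0},
    )
    whites = []
    for wi in range(n_white_frames):
        wf = simulate_raw_frame(
            np.ones((1, N_BANDS)),
            SceneGroundTruth(class_grid=np.zeros(frame_shape, dtype=np.int8)),
            fibers,
            mosaic,
            dark_level=dark_level,
            seed=int(rng.integers(2**31)),
            white_level=white_level,
            transmission=transmission,
            illumination=illum,
        )
        wf.role = "white"
        wf.meta = {"patient": 0, "white_index": wi}
        whites.append(wf)

    frames: list[RawFrame] = []
    truths: list[SceneGroundTruth] = []
    cube_id = 0
    for patch in range(24):
        for _f in range(chart.frames_per_patch):
            truth = SceneGroundTruth(
                class_grid=np.full(frame_shape, patch, dtype=np.int8),
                patient=0,
                region=patch,
                cube_id=cube_id,
                label=f"patch_{patch + 1:02d}",
            )
            frame = simulate_raw_frame(
                chart.patch_reflectances,
                truth,
                fibers,
                mosaic,
                dark_level=dark_level,
                seed=int(rng.integers(2**31)),
                sigma_pixel=chart.sigma_pixel,
                noise_cell=chart.noise_cell,
                white_level=white_level,
                transmission=transmission,
                illumination=illum,
            )
            frame.meta["label"] = truth.label
            frames.append(frame)
            truths.append(truth)
            cube_id += 1
    return SimulatedDataset(frames, truths, {0: {"dark": dark, "white": whites}}, fibers, mosaic)


def sample_labeled_spectra(
    model: SpectralModel,
    n_cubes: int,
    spectra_per_cube: int = 80,
    seed: int = 0,
):
    """Sample labeled per-pixel spectra directly at the classification level.

    Fast path for studying classifiers in isolation: draws reflectance
    spectra with the same patient -> image -> pixel variance hierarchy the
    frame renderer uses, but skips the optics (comb, mosaic, illumination,
    quantization).  Cubes cycle through patients/regions exactly as
    ``simulate_procedure_dataset`` does.

    Returns ``(X, y, cube_id, patient)`` with X of shape
    (n_cubes * spectra_per_cube, 9), un-normalized.
    """
    rng = np.random.default_rng(seed)
    n = n_cubes * spectra_per_cube
    X = np.empty((n, N_BANDS))
    y = np.empty(n, dtype=int)
    cube_ids = np.empty(n, dtype=int)
    patients = np.empty(n, dtype=int)
    cubes_per_patient = max(1, n_cubes // model.n_patients)
    patient_offsets = rng.normal(
        0.0, model.sigma_patient, size=(model.n_patients, N_BANDS)
    )
    for c in range(n_cubes):
        p = min(c // cubes_per_patient, model.n_patients - 1)
        cls = c % 3
        image_offset = rng.normal(0.0, model.sigma_image, size=N_BANDS)
        base = model.class_means[cls] + patient_offsets[p] + image_offset
        sl = slice(c * spectra_per_cube, (c + 1) * spectra_per_cube)
        X[sl] = np.clip(
            base[None, :]
            + rng.normal(0.0, model.sigma_pixel, size=(spectra_per_cube, N_BANDS)),
            0.0,
            1.0,
        )
        y[sl] = cls
        cube_ids[sl] = c
        patients[sl] = p
    return X, y, cube_ids, patients
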