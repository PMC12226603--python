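"""Synthetic speed-of-sound phantoms and noisy measurement simulation.

Ground-truth maps contain a single randomly shaped inclusion obtained by
deforming a random ellipse with a smooth random radial field; half of the
inclusions get low-pass-filtered (smooth) edges and a small fraction of the
samples is inclusion-free.  Measurements are simulated on an ``hr_factor``
finer grid with an independent high-resolution operator plus i.i.d. Gaussian
noise, then block-averaged down to the coarse measurement grid, so the
reconstruction operator is never the one that generated the data (inverse
crime guard).

Multi-frame "lesion cases" emulate repeated acquisitions of one lesion where
a subset of frames is corrupted (inflated noise plus a low-frequency
displacement offset as a hand/body-motion surrogate); these exercise the
uncertainty-based frame selection.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.ndimage

from .geometry import (
    AcquisitionSpec,
    DisplacementMeasurements,
    ForwardModel,
    ImagingGrid,
    build_forward_model,
)
from .maps import SoSMap, sos_to_slowness

#: Default measurement-noise std (s) at the high-resolution simulation stage.
#: Chosen so that the displacement SNR on a 40 m/s contrast phantom on the
#: default scaled grid is roughly 20 dB after downsampling.
DEFAULT_NOISE_STD = 3.4e-9


def default_grid() -> ImagingGrid:
    """Paper-scale 84 x 64 (axial x lateral) reconstruction grid."""
    return ImagingGrid(n_ax=84, n_lat=64, pitch_ax=0.5, pitch_lat=0.6)


def scaled_down_grid() -> ImagingGrid:
    """Small grid used by the scaled-down presets (28 x 20, ~42 x 40 mm)."""
    return ImagingGrid(n_ax=28, n_lat=20, pitch_ax=1.5, pitch_lat=2.0)


def scaled_down_spec() -> AcquisitionSpec:
    """Reduced transmit sequence (9 transmits -> 7 pairs) for desk-scale runs."""
    return AcquisitionSpec(n_transmits=9, pair_offset=2)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the study conditions.

    ``background_sos_range`` and ``contrast_range`` are in m/s (contrast is a
    magnitude; its sign is drawn at random), ``noise_std`` is the Gaussian
    measurement noise std in seconds applied on the high-resolution grid.
    """

    grid: ImagingGrid = dataclasses.field(default_factory=scaled_down_grid)
    spec: AcquisitionSpec = dataclasses.field(default_factory=scaled_down_spec)
    n_train: int = 500
    n_test: int = 32
    p_no_inclusion: float = 0.05
    p_smooth: float = 0.5
    background_sos_range: tuple[float, float] = (1490.0, 1540.0)
    contrast_range: tuple[float, float] = (10.0, 60.0)
    hr_factor: int = 2
    noise_std: float = DEFAULT_NOISE_STD
    sos_bounds: tuple[float, float] = (1300.0, 1700.0)
    edge_sigma_px: float = 1.2
    ca_contrast_threshold: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_no_inclusion, self.p_smooth):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.hr_factor < 2:
            raise ValueError("hr_factor must be >= 2 (inverse-crime guard)")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")


@dataclasses.dataclass
class Phantom:
    """One ground-truth sample: SoS map plus inclusion metadata."""

    sos_map: SoSMap
    inclusion_mask: np.ndarray
    smooth_edge: bool
    background_sos: float
    contrast: float

    @property
    def has_inclusion(self) -> bool:
        return bool(self.inclusion_mask.any())


def _deformed_ellipse_mask(
    grid: ImagingGrid,
    rng: np.random.Generator,
    depth_frac: tuple[float, float] = (0.25, 0.75),
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean inclusion mask plus a continuous inside-ness field.

    The ellipse boundary radius is modulated by a periodic Gaussian-filtered
    random field, giving smoothly irregular shapes.  ``depth_frac`` bounds
    the center depth as a fraction of the axial extent.
    """
    width, depth = grid.width, grid.depth
    scale = min(width, depth)
    for _ in range(100):
        cx = rng.uniform(-0.25 * width, 0.25 * width)
        cz = grid.depth_offset + rng.uniform(depth_frac[0] * depth, depth_frac[1] * depth)
        a = rng.uniform(0.10, 0.28) * scale
        b = rng.uniform(0.10, 0.28) * scale
        rot = rng.uniform(0.0, np.pi)
        n_ang = 128
        field = rng.standard_normal(n_ang)
        field = scipy.ndimage.gaussian_filter1d(field, sigma=10.0, mode="wrap")
        std = field.std()
        if std > 0:
            field = 0.15 * field / std
        rho = np.clip(1.0 + field, 0.5, 1.5)

        X, Z = np.meshgrid(grid.lateral_centers, grid.axial_centers)
        dx, dz = X - cx, Z - cz
        ur = np.cos(rot) * dx + np.sin(rot) * dz
        vr = -np.sin(rot) * dx + np.cos(rot) * dz
        r = np.hypot(ur / a, vr / b)
        ang = np.mod(np.arctan2(vr / b, ur / a), 2 * np.pi)
        ang_grid = np.linspace(0.0, 2 * np.pi, n_ang, endpoint=False)
        rho_at = np.interp(ang.ravel(), ang_grid, rho, period=2 * np.pi).reshape(r.shape)
        inside_field = rho_at - r  # > 0 inside the deformed boundary
        mask = inside_field > 0
        if 4 <= mask.sum() <= 0.5 * grid.n_pixels:
            return mask, inside_field
    raise RuntimeError("failed to draw a non-degenerate inclusion")


def sample_phantom(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    contrast: float | None = None,
    force_inclusion: bool = False,
    depth_frac: tuple[float, float] = (0.25, 0.75),
) -> Phantom:
    """Draw one phantom; reproducible from the generator state.

    ``contrast`` overrides the random signed contrast draw (m/s); with
    ``force_inclusion`` the inclusion-free branch is skipped and
    ``depth_frac`` bounds the lesion center depth (used when building
    lesion cohorts, which must place lesions inside the depth window the
    limited-angle geometry is actually sensitive to).
    """
    grid = cfg.grid
    background = rng.uniform(*cfg.background_sos_range)
    no_inclusion = (rng.random() < cfg.p_no_inclusion) and not force_inclusion
    if no_inclusion:
        sos = np.full(grid.shape, background)
        return Phantom(
            sos_map=SoSMap(values=sos, grid=grid),
            inclusion_mask=np.zeros(grid.shape, dtype=bool),
            smooth_edge=False,
            background_sos=background,
            contrast=0.0,
        )
    mask, _field = _deformed_ellipse_mask(grid, rng, depth_frac=depth_frac)
    if contrast is None:
        magnitude = rng.uniform(*cfg.contrast_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        contrast = sign * magnitude
    smooth = rng.random() < cfg.p_smooth
    profile = mask.astype(float)
    if smooth:
        profile = scipy.ndimage.gaussian_filter(profile, sigma=cfg.edge_sigma_px)
    sos = np.clip(background + contrast * profile, *cfg.sos_bounds)
    return Phantom(
        sos_map=SoSMap(values=sos, grid=grid),
        inclusion_mask=mask,
        smooth_edge=smooth,
        background_sos=background,
        contrast=float(contrast),
    )


def build_hr_model(cfg: SimulationConfig) -> ForwardModel:
    """High-resolution operator used only for simulating measurements."""
    hr_grid = cfg.grid.upsample(cfg.hr_factor)
    return build_forward_model(cfg.spec, hr_grid, hr_grid)


def _block_average(a: np.ndarray, f: int) -> np.ndarray:
    p, nz, nx = a.shape
    return a.reshape(p, nz // f, f, nx // f, f).mean(axis=(2, 4))


def simulate_measurements(
    phantom: Phantom,
    model_hr: ForwardModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> DisplacementMeasurements:
    """Noisy displacements: ``d_hr = L_hr x_hr + eps`` averaged to the coarse grid.

    The coarse slowness deviation is replicated to the fine grid, pushed
    through the high-resolution operator, perturbed with Gaussian noise of
    std ``cfg.noise_std``, and block-averaged back per pair.
    """
    f = cfg.hr_factor
    if model_hr.recon_grid.shape != (cfg.grid.n_ax * f, cfg.grid.n_lat * f):
        raise ValueError("model_hr is not built on the hr_factor-upsampled grid")
    x_coarse = sos_to_slowness(phantom.sos_map, cfg.spec.c0).values
    x_hr = np.kron(x_coarse, np.ones((f, f)))
    d_hr = model_hr.L @ x_hr.ravel()
    d_hr = d_hr + rng.normal(0.0, cfg.noise_std, size=d_hr.shape)
    d_hr = d_hr.reshape(model_hr.meas_shape)
    d = _block_average(d_hr, f)
    return DisplacementMeasurements(values=d, grid=cfg.grid, pairs=model_hr.pairs)


@dataclasses.dataclass
class SimDataset:
    """In-memory dataset of (displacements, ground-truth SoS, mask) triples."""

    d: np.ndarray  # (n, n_pairs, n_ax', n_lat')
    sos_gt: np.ndarray  # (n, n_ax, n_lat)
    mask: np.ndarray  # (n, n_ax, n_lat) bool
    grid: ImagingGrid
    spec: AcquisitionSpec
    seed: int

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def record(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.d[i], self.sos_gt[i], self.mask[i]


def generate_samples(
    cfg: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    model_hr: ForwardModel | None = None,
) -> SimDataset:
    """Draw ``n`` phantoms and simulate their measurements."""
    if model_hr is None:
        model_hr = build_hr_model(cfg)
    n_pairs = len(model_hr.pairs)
    d = np.zeros((n, n_pairs, cfg.grid.n_ax, cfg.grid.n_lat))
    sos = np.zeros((n, cfg.grid.n_ax, cfg.grid.n_lat))
    mask = np.zeros((n, cfg.grid.n_ax, cfg.grid.n_lat), dtype=bool)
    for i in range(n):
        ph = sample_phantom(cfg, rng)
        meas = simulate_measurements(ph, model_hr, cfg, rng)
        d[i] = meas.values
        sos[i] = ph.sos_map.values
        mask[i] = ph.inclusion_mask
    return SimDataset(d=d, sos_gt=sos, mask=mask, grid=cfg.grid, spec=cfg.spec, seed=cfg.seed)


def make_dataset(
    cfg: SimulationConfig, path=None
) -> tuple[SimDataset, SimDataset]:
    """Training and test archives; optionally written to an HDF5 container."""
    rng = np.random.default_rng(cfg.seed)
    model_hr = build_hr_model(cfg)
    train = generate_samples(cfg, cfg.n_train, rng, model_hr)
    test = generate_samples(cfg, cfg.n_test, rng, model_hr)
    if path is not None:
        from . import io as sio

        sio.save_dataset(path, train, test, cfg)
    return train, test


@dataclasses.dataclass
class LesionCase:
    """One lesion imaged ``n_frames`` times; some frames may be corrupted."""

    frames: list[DisplacementMeasurements]
    masks: list[np.ndarray]
    phantom: Phantom
    label: str  # "CA" (malignant surrogate) or "FA" (benign surrogate)
    corrupted_frames: frozenset[int]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _lowfreq_offset(shape: tuple[int, int, int], std: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random per-pair displacement offset field with the given std."""
    field = rng.standard_normal(shape)
    field = scipy.ndimage.gaussian_filter(field, sigma=(0.0, 3.0, 3.0))
    s = field.std()
    if s > 0:
        field *= std / s
    return field


def make_lesion_case(
    cfg: SimulationConfig,
    n_frames: int,
    n_corrupted: int,
    corruption_scale: float,
    rng: np.random.Generator,
    model_hr: ForwardModel | None = None,
    contrast: float | None = None,
    depth_frac: tuple[float, float] = (0.25, 0.75),
) -> LesionCase:
    """Simulate repeated acquisitions of a single lesion.

    Corrupted frames get their noise std multiplied by ``corruption_scale``
    plus a smooth offset field of std ``(corruption_scale - 1) * noise_std``
    (a motion surrogate), so ``corruption_scale = 1`` is exactly the null
    case of statistically exchangeable frames.
    """
    if not 0 <= n_corrupted < n_frames:
        raise ValueError("need 0 <= n_corrupted < n_frames")
    if model_hr is None:
        model_hr = build_hr_model(cfg)
    phantom = sample_phantom(cfg, rng, contrast=contrast, force_inclusion=True,
                             depth_frac=depth_frac)
    corrupted = frozenset(rng.choice(n_frames, size=n_corrupted, replace=False).tolist())
    frames: list[DisplacementMeasurements] = []
    for fidx in range(n_frames):
        if fidx in corrupted:
            frame_cfg = dataclasses.replace(cfg, noise_std=cfg.noise_std * corruption_scale)
            meas = simulate_measurements(phantom, model_hr, frame_cfg, rng)
            offset = _lowfreq_offset(
                meas.values.shape, (corruption_scale - 1.0) * cfg.noise_std, rng
            )
            meas = DisplacementMeasurements(
                values=meas.values + offset, grid=meas.grid, pairs=meas.pairs
            )
        else:
            meas = simulate_measurements(phantom, model_hr, cfg, rng)
        frames.append(meas)
    label = "CA" if abs(phantom.contrast) >= cfg.ca_contrast_threshold else "FA"
    return LesionCase(
        frames=frames,
        masks=[phantom.inclusion_mask.copy() for _ in range(n_frames)],
        phantom=phantom,
        label=label,
        corrupted_frames=corrupted,
    )


def make_cohort(
    cfg: SimulationConfig,
    n_ca: int,
    n_fa: int,
    rng: np.random.Generator,
    n_frames: int = 4,
    n_corrupted: int = 3,
    corruption_scale: float = 5.0,
    ca_contrast: tuple[float, float] = (40.0, 60.0),
    fa_contrast: tuple[float, float] = (10.0, 25.0),
    model_hr: ForwardModel | None = None,
    depth_frac: tuple[float, float] = (0.2, 0.55),
) -> list[LesionCase]:
    """Contrast-separable synthetic cohort of lesion cases (CA high, FA low).

    Lesion centers are confined to the shallow-to-mid depth window where the
    limited-angle transmit geometry retains contrast sensitivity; deeper
    lesions are essentially unreconstructable and would make the cohort
    non-separable regardless of the true contrast gap.
    """
    if model_hr is None:
        model_hr = build_hr_model(cfg)
    cases = []
    specs = [ca_contrast] * n_ca + [fa_contrast] * n_fa
    for rng_range in specs:
        contrast = rng.uniform(*rng_range)
        cases.append(
            make_lesion_case(
                cfg,
                n_frames,
                n_corrupted,
                corruption_scale,
                rng,
                model_hr=model_hr,
                contrast=contrast,
                depth_frac=depth_frac,
            )
        )
    return cases
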