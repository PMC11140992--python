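"""Synthetic OCT B-scan phantoms with exact ground truth.

The generator renders a layered mouse retina as seen in a 16-bit
log-scaled OCT B-scan: reflectivity slabs for the inner retina
(NFL+GCL, IPL, INL+OPL, ONL), Gaussian hyperreflective bands for the
ELM, the ellipsoid zone (EZ, the band immediately posterior to the ELM)
and the RPE, mild parabolic retinal curvature, per-frame rigid jitter
and multiplicative speckle.  Every rendered stack carries its exact
noise-free boundary geometry, so each downstream stage (registration,
segmentation, thickness and band-shape measurement, statistics) can be
validated against known truth.

Coordinate convention: rows = axial depth, increasing posteriorly;
columns = lateral position.  Depths are 0-based, subpixel positions are
real numbers, and thickness in micrometers is (row difference) x
``axial_px_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "LayerSpec",
    "PhantomConfig",
    "GroundTruth",
    "BScanStack",
    "GroupSpec",
    "CohortSpec",
    "SimulatedMouse",
    "make_retina_layers",
    "synth_profile",
    "synth_bscan_stack",
    "simulate_cohort",
]

#: layer labels in fixed anterior -> posterior order
LAYER_ORDER = (
    "ILM",
    "GCL/IPL",
    "IPL/INL",
    "INL+OPL",
    "OPL/ONL",
    "ELM",
    "EZ",
    "RPE",
    "BrM",
)

#: thin bright bands modelled as Gaussians rather than slabs
BAND_LAYERS = frozenset({"ELM", "EZ", "RPE"})

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # half-maximum offset in units of sigma
MAX_COUNTS = 65535.0


class PhantomSizingError(ValueError):
    """Raised when the layer stack does not fit in the axial field of view."""


@dataclass(frozen=True)
class LayerSpec:
    """One retinal layer.

    A slab layer is named after the boundary at its anterior edge (e.g.
    the slab named ``"OPL/ONL"`` is the ONL, extending from the OPL/ONL
    boundary to the ELM).  Band layers (ELM, EZ, RPE) occupy a slab of
    ``thickness_um`` with background ``base_reflectivity`` and add a
    Gaussian of the given amplitude and axial sigma centred in the slab.
    """

    name: str
    thickness_um: float
    base_reflectivity: float = 0.0
    amplitude: float | None = None
    width_sigma_um: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if self.is_band:
            if self.amplitude is None or self.width_sigma_um is None:
                raise ValueError(
                    f"band layer {self.name!r} needs amplitude and width_sigma_um"
                )
            if not (0 <= self.amplitude <= MAX_COUNTS):
                raise ValueError(f"band amplitude must be in [0, {MAX_COUNTS:.0f}]")
            if self.width_sigma_um <= 0:
                raise ValueError("band width_sigma_um must be > 0")

    @property
    def is_band(self) -> bool:
        return self.name in BAND_LAYERS


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition geometry and noise/jitter settings for one stack."""

    axial_px_um: float = 1.6
    lateral_px_um: float = 1.4
    rows: int = 512
    cols: int = 1000
    onh_col: int | None = None          # default: image centre
    curvature_um: float = 20.0          # peak-to-edge posterior sag
    speckle_sigma: float = 0.0          # multiplicative speckle scale (unitless)
    max_jitter_rot_deg: float = 0.0
    max_jitter_shift_px: float = 0.0
    n_frames: int = 1
    seed: int = 0
    ilm_offset_um: float = 120.0        # depth of the ILM at the lateral centre
    vitreous_reflectivity: float = 1200.0
    edge_sigma_um: float = 1.2          # axial softness of slab interfaces (PSF)
    log_slope: float = MAX_COUNTS / 8.0  # counts per natural-log unit of linear signal
    n_vessels: int = 5                  # retinal vessel shadows (lateral landmarks)
    vessel_depth: float = 0.35          # peak fractional attenuation under a vessel
    vessel_sigma_px: float = 4.0        # lateral half-width of a shadow

    def __post_init__(self) -> None:
        if self.rows < 64 or self.cols < 64:
            raise ValueError("rows and cols must be >= 64")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.axial_px_um <= 0 or self.lateral_px_um <= 0:
            raise ValueError("pixel sizes must be > 0")

    @property
    def centre_col(self) -> int:
        return self.cols // 2 if self.onh_col is None else self.onh_col


@dataclass
class GroundTruth:
    """Exact noise-free geometry of a rendered stack (frame-1 coordinates).

    ``frame_transforms`` holds, per frame, the rigid transform
    (rotation deg, dy px, dx px) that ALIGNS the frame back onto frame 1
    — i.e. what a registration stage should estimate.  Frame 1 is the
    identity.
    """

    boundaries: dict[str, np.ndarray]
    elm_rpe_um: float
    ez_elongation: float
    frame_transforms: list[tuple[float, float, float]]
    config: PhantomConfig | None = None

    def check_ordering(self) -> None:
        order = [n for n in LAYER_ORDER if n in self.boundaries]
        stackd = np.stack([self.boundaries[n] for n in order])
        if not np.all(np.diff(stackd, axis=0) > 0):
            raise AssertionError("ground-truth boundaries are not strictly ordered")


@dataclass
class BScanStack:
    """A set of co-located B-scan frames plus pixel-size metadata."""

    frames: np.ndarray                  # (n_frames, rows, cols) uint16
    axial_px_um: float
    lateral_px_um: float
    onh_col: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def make_retina_layers(
    elm_rpe_um: float = 50.0,
    ez_elongation: float = 1.0,
    *,
    nfl_gcl_um: float = 25.0,
    ipl_um: float = 55.0,
    inl_opl_um: float = 50.0,
    onl_um: float = 60.0,
    elm_span_um: float = 14.0,
    ez_span_um: float = 16.0,
    elm_sigma_um: float = 2.0,
    ez_sigma_um: float = 4.0,
    rpe_sigma_um: float = 5.0,
    band_background: float = 13000.0,
    elm_amplitude: float = 20000.0,
    ez_amplitude: float = 30000.0,
    rpe_amplitude: float = 28000.0,
) -> list[LayerSpec]:
    """Build the default layer stack with a prescribed ELM-RPE distance.

    ELM-RPE is measured from the ELM band centre to the basal RPE at
    Bruch's membrane, operationally the posterior half-maximum crossing
    of the RPE band (centre + sqrt(2 ln 2) * sigma).  The RPE slab span
    is solved so that distance equals ``elm_rpe_um`` exactly.
    ``ez_elongation`` scales the axial sigma of the EZ band at fixed
    amplitude (the band-shape effect the MCP/AR descriptor tracks).
    """

    ez_sigma = ez_sigma_um * ez_elongation
    rpe_half = elm_rpe_um - elm_span_um / 2.0 - ez_span_um - _HALF_MAX * rpe_sigma_um
    if rpe_half <= _HALF_MAX * rpe_sigma_um:
        raise ValueError(
            f"elm_rpe_um={elm_rpe_um} too small for the requested band geometry"
        )
    return [
        LayerSpec("ILM", nfl_gcl_um, 30000.0),
        LayerSpec("GCL/IPL", ipl_um, 25000.0),
        LayerSpec("IPL/INL", inl_opl_um, 20000.0),
        LayerSpec("OPL/ONL", onl_um, 11000.0),
        LayerSpec("ELM", elm_span_um, band_background, elm_amplitude, elm_sigma_um),
        LayerSpec("EZ", ez_span_um, band_background, ez_amplitude, ez_sigma),
        LayerSpec("RPE", 2.0 * rpe_half, band_background, rpe_amplitude, rpe_sigma_um),
        # sub-RPE slab at the band background so the RPE half-max crossing is exact
        LayerSpec("BrM", 80.0, band_background),
    ]


def _profile_terms(
    layers: list[LayerSpec],
    offset_um: float,
    vitreous: float,
    edge_sigma_um: float,
):
    """Decompose the continuous axial profile into erf steps + Gaussians.

    Returns (step list [(depth_um, delta_refl)], band list
    [(centre_um, amplitude, sigma_um)], boundary dict name -> depth_um).
    """

    names = [ly.name for ly in layers]
    order_idx = [LAYER_ORDER.index(n) if n in LAYER_ORDER else -1 for n in names]
    if -1 in order_idx or order_idx != sorted(order_idx) or len(set(names)) != len(names):
        raise ValueError(
            f"layers must be unique and in anterior->posterior order {LAYER_ORDER}"
        )

    steps: list[tuple[float, float]] = []
    bands: list[tuple[float, float, float]] = []
    boundaries: dict[str, float] = {}
    depth = offset_um
    prev_refl = vitreous
    for ly in layers:
        steps.append((depth, ly.base_reflectivity - prev_refl))
        if ly.is_band:
            centre = depth + ly.thickness_um / 2.0
            bands.append((centre, float(ly.amplitude), float(ly.width_sigma_um)))
            boundaries[ly.name] = centre
        else:
            boundaries[ly.name] = depth
        prev_refl = ly.base_reflectivity
        depth += ly.thickness_um
    return steps, bands, boundaries, depth


def _bands_by_name(layers: list[LayerSpec], bands) -> dict:
    it = iter(bands)
    return {ly.name: next(it) for ly in layers if ly.is_band}


def _continuous_profile(z_um, steps, bands, edge_sigma_um, vitreous):
    """Evaluate the continuous reflectivity model at depths ``z_um``."""

    out = np.full_like(np.asarray(z_um, dtype=float), vitreous)
    for depth, delta in steps:
        out = out + delta * 0.5 * (1.0 + special.erf((z_um - depth) / (np.sqrt(2.0) * edge_sigma_um)))
    for centre, amp, sigma in bands:
        out = out + amp * np.exp(-0.5 * ((z_um - centre) / sigma) ** 2)
    return out


def synth_profile(
    layers: list[LayerSpec],
    axial_px_um: float,
    n_px: int = 512,
    *,
    offset_um: float = 120.0,
    vitreous_reflectivity: float = 1200.0,
    edge_sigma_um: float = 1.2,
) -> tuple[np.ndarray, dict[str, float]]:
    """Render a noise-free 1-D axial reflectivity profile.

    Returns the profile sampled at row centres (``z = row * axial_px_um``)
    and the exact boundary depths in (subpixel) rows: anterior slab edges
    for slab layers, band centres for ELM/EZ/RPE, plus ``"BrM"`` at the
    posterior half-maximum crossing of the RPE band when one is present.

    Raises :class:`PhantomSizingError` if the layer stack extends past
    the axial field of view.
    """

    steps, bands, boundaries_um, total_um = _profile_terms(
        layers, offset_um, vitreous_reflectivity, edge_sigma_um
    )
    fov_um = n_px * axial_px_um
    if total_um > fov_um:
        raise PhantomSizingError(
            f"layer stack ends at {total_um:.1f} um but field of view is {fov_um:.1f} um"
        )
    band_by_name = _bands_by_name(layers, bands)
    if "RPE" in band_by_name:
        centre, _amp, sigma = band_by_name["RPE"]
        boundaries_um["BrM"] = centre + _HALF_MAX * sigma

    z = np.arange(n_px, dtype=float) * axial_px_um
    profile = _continuous_profile(z, steps, bands, edge_sigma_um, vitreous_reflectivity)
    boundaries_px = {k: v / axial_px_um for k, v in boundaries_um.items()}
    return profile, boundaries_px


def _sag_px(config: PhantomConfig) -> np.ndarray:
    """Per-column posterior sag in rows: 0 at the lateral centre,
    ``curvature_um`` at the image edge."""
    c = np.arange(config.cols, dtype=float)
    cc = (config.cols - 1) / 2.0
    half = max(cc, config.cols - 1 - cc)
    return (config.curvature_um / config.axial_px_um) * ((c - cc) / half) ** 2


def _rot_shift_matrix(rot_deg: float, dy: float, dx: float, shape) -> np.ndarray:
    """3x3 homogeneous matrix for: rotate by rot_deg about the image
    centre (row/col coordinates), then translate by (dy, dx)."""
    th = np.deg2rad(rot_deg)
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = np.array([cy + dy, cx + dx]) - R @ np.array([cy, cx])
    M = np.eye(3)
    M[:2, :2] = R
    M[:2, 2] = t
    return M


def invert_rigid(t: tuple[float, float, float]) -> tuple[float, float, float]:
    """Invert a (rotation deg, dy, dx) transform about the image centre."""
    rot, dy, dx = t
    th = np.deg2rad(-rot)
    c, s = np.cos(th), np.sin(th)
    return (-rot, -(c * dy - s * dx), -(s * dy + c * dx))


def apply_rigid(img: np.ndarray, rot_deg: float, dy: float, dx: float, order: int = 1) -> np.ndarray:
    """Rotate ``img`` about its centre then shift by (dy, dx) rows/cols,
    with bilinear interpolation and edge replication."""
    from scipy import ndimage

    if rot_deg == 0.0 and dy == 0.0 and dx == 0.0:
        return img.astype(float, copy=True)
    M = _rot_shift_matrix(rot_deg, dy, dx, img.shape)
    Minv = np.linalg.inv(M)
    return ndimage.affine_transform(
        img.astype(float), Minv[:2, :2], offset=Minv[:2, 2], order=order, mode="nearest"
    )


def synth_bscan_stack(
    config: PhantomConfig,
    layers: list[LayerSpec] | None = None,
    elm_rpe_um: float = 50.0,
    ez_elongation: float = 1.0,
) -> tuple[BScanStack, GroundTruth]:
    """Render a jittered, speckled B-scan stack with exact ground truth.

    Each frame is the curved lateral extrusion of :func:`synth_profile`,
    moved by a per-frame rigid jitter (frame 1 is untouched) and
    corrupted by multiplicative speckle — log-normal on the linear
    signal, hence additive Gaussian with standard deviation
    ``log_slope * speckle_sigma`` counts on the stored log-scaled image.
    """

    if layers is None:
        layers = make_retina_layers(elm_rpe_um=elm_rpe_um, ez_elongation=ez_elongation)

    steps, bands, boundaries_um, total_um = _profile_terms(
        layers, config.ilm_offset_um, config.vitreous_reflectivity, config.edge_sigma_um
    )
    max_sag_um = config.curvature_um
    if total_um + max_sag_um > config.rows * config.axial_px_um:
        raise PhantomSizingError("layer stack + curvature exceeds the axial field of view")
    band_by_name = _bands_by_name(layers, bands)
    if "RPE" in band_by_name:
        centre, _amp, sigma = band_by_name["RPE"]
        boundaries_um["BrM"] = centre + _HALF_MAX * sigma

    sag = _sag_px(config)                              # (cols,)
    rows = np.arange(config.rows, dtype=float)
    z_um = (rows[:, None] - sag[None, :]) * config.axial_px_um
    base = _continuous_profile(
        z_um, steps, bands, config.edge_sigma_um, config.vitreous_reflectivity
    )

    rng = np.random.default_rng(config.seed)
    if config.n_vessels > 0:
        # vessel shadows: fixed multiplicative attenuation of the retinal
        # signal under a few lateral positions; they give the frames the
        # lateral texture real B-scans have (and registration needs)
        c = np.arange(config.cols, dtype=float)
        pos = rng.uniform(0.08 * config.cols, 0.92 * config.cols, size=config.n_vessels)
        depths = rng.uniform(0.5, 1.0, size=config.n_vessels) * config.vessel_depth
        shade = np.zeros(config.cols)
        for p, d in zip(pos, depths):
            shade += d * np.exp(-0.5 * ((c - p) / config.vessel_sigma_px) ** 2)
        factor = np.clip(1.0 - shade, 0.0, 1.0)
        base = config.vitreous_reflectivity + (base - config.vitreous_reflectivity) * factor[None, :]
    align: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    frames = np.empty((config.n_frames, config.rows, config.cols), dtype=np.uint16)
    noise_sd = config.log_slope * config.speckle_sigma
    for i in range(config.n_frames):
        if i == 0 or (config.max_jitter_rot_deg == 0 and config.max_jitter_shift_px == 0):
            t = (0.0, 0.0, 0.0)
            frame = base.copy()
        else:
            t = (
                float(rng.uniform(-config.max_jitter_rot_deg, config.max_jitter_rot_deg)),
                float(rng.uniform(-config.max_jitter_shift_px, config.max_jitter_shift_px)),
                float(rng.uniform(-config.max_jitter_shift_px, config.max_jitter_shift_px)),
            )
            frame = apply_rigid(base, *invert_rigid(t))
        if i > 0:
            align.append(t)
        if noise_sd > 0:
            frame = frame + noise_sd * rng.standard_normal(frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, MAX_COUNTS).astype(np.uint16)

    boundaries = {
        name: depth_um / config.axial_px_um + sag
        for name, depth_um in boundaries_um.items()
    }
    truth = GroundTruth(
        boundaries=boundaries,
        elm_rpe_um=(boundaries_um["BrM"] - boundaries_um["ELM"]) if "BrM" in boundaries_um and "ELM" in boundaries_um else float("nan"),
        ez_elongation=ez_elongation,
        frame_transforms=align,
        config=config,
    )
    stack = BScanStack(
        frames=frames,
        axial_px_um=config.axial_px_um,
        lateral_px_um=config.lateral_px_um,
        onh_col=config.centre_col,
        metadata={"seed": config.seed, "speckle_sigma": config.speckle_sigma},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the simulated cross-sectional study."""

    label: str
    condition: str                      # "light" or "dark"
    n_mice: int
    elm_rpe_um: float = 50.0
    ez_elongation: float = 1.0
    cs_mean: float = 15.0               # inverse Michelson contrast, unitless
    cs_shape: float = 30.0              # gamma shape (between-mouse)
    acuity_mean: float = 0.39           # cycles/degree
    acuity_sd: float = 0.015
    elm_rpe_sd: float = 0.8             # between-mouse SD, um

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2 per group")
        if self.cs_mean <= 0 or self.cs_shape <= 0:
            raise ValueError("cs_mean and cs_shape must be > 0")
        if self.condition not in ("light", "dark"):
            raise ValueError("condition must be 'light' or 'dark'")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("at least one group required")


@dataclass
class SimulatedMouse:
    mouse_id: str
    group: str
    condition: str
    stack: BScanStack
    truth: GroundTruth
    cs: float
    acuity: float


def simulate_cohort(spec: CohortSpec) -> tuple[list[SimulatedMouse], pd.DataFrame]:
    """Draw a cohort of simulated mice: per-mouse ELM-RPE (normal around
    the group mean), CS (gamma with the group mean), acuity (normal), and
    a rendered B-scan stack per mouse.  Fully reproducible from the seed.

    Returns the mice and a tidy truth table (one row per mouse).
    """

    ss = np.random.SeedSequence(spec.seed)
    mice: list[SimulatedMouse] = []
    rows = []
    child_seeds = ss.spawn(len(spec.groups))
    for g, gseed in zip(spec.groups, child_seeds):
        rng = np.random.default_rng(gseed)
        stack_seeds = rng.integers(0, 2**31 - 1, size=g.n_mice)
        for j in range(g.n_mice):
            elm_rpe = float(g.elm_rpe_um + g.elm_rpe_sd * rng.standard_normal())
            cs = float(rng.gamma(shape=g.cs_shape, scale=g.cs_mean / g.cs_shape))
            acuity = float(g.acuity_mean + g.acuity_sd * rng.standard_normal())
            cfg = replace(spec.phantom, seed=int(stack_seeds[j]))
            stack, truth = synth_bscan_stack(
                cfg, elm_rpe_um=elm_rpe, ez_elongation=g.ez_elongation
            )
            mid = f"{g.label}_{g.condition}_{j:02d}"
            mice.append(SimulatedMouse(mid, g.label, g.condition, stack, truth, cs, acuity))
            rows.append(
                dict(
                    mouse=mid,
                    group=g.label,
                    condition=g.condition,
                    elm_rpe_um=elm_rpe,
                    ez_elongation=g.ez_elongation,
                    cs=cs,
                    acuity=acuity,
                )
            )
    return mice, pd.DataFrame(rows)
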