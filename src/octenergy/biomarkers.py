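"""Outer-retina biomarkers from a segmented, averaged B-scan.

Two energy-linked outcome measures are computed in an analysis region
350-624 um from the optic nerve head on each side (inferior/superior):

* **ELM-RPE thickness** — mean axial distance from the external
  limiting membrane to the basal RPE at Bruch's membrane, a proxy for
  pH-triggered subretinal water removal (it contracts when rod energy
  demand is high).
* **MCP/AR** — the minor-to-major aspect ratio of an ellipse
  moment-matched to the region of the mean A-line reflectivity profile
  bounded below by a chord baseline between the local minima flanking
  the hyperreflective band immediately posterior to the ELM (the
  ellipsoid zone).  It tracks the axial spread of the band, attributed
  to the configuration of photoreceptor mitochondria.

Laminar thicknesses (IPL, INL+OPL, ONL) come from the same traces.  All
shape analysis runs on the 16-bit log-scaled image; the profile region
is made two-dimensional by mapping intensity counts to pixels with a
fixed study-wide ``intensity_scale`` (counts per pixel), because aspect
ratios are only comparable at a fixed scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import BScanStack
from .registration import register_and_average
from .segmentation import SegmentationResult, segment

__all__ = [
    "RoiSpec",
    "ReflectivityProfile",
    "BandRegion",
    "EllipseFit",
    "BiomarkerRecord",
    "FlattenedImage",
    "roi_columns",
    "layer_thickness",
    "flatten_to_brm",
    "mean_profile",
    "ez_band_region",
    "fit_ellipse_moments",
    "mcp_ar",
    "measure_eye",
]

log = logging.getLogger(__name__)

#: default intensity-to-distance mapping: full 16-bit range -> 256 px
DEFAULT_INTENSITY_SCALE = 65535.0 / 256.0

#: thickness outcome -> (upper trace, lower trace)
THICKNESS_PAIRS = {
    "elm_rpe_um": ("ELM", "BrM"),
    "ipl_um": ("GCL/IPL", "IPL/INL"),
    "inl_opl_um": ("IPL/INL", "OPL/ONL"),
    "onl_um": ("OPL/ONL", "ELM"),
}


class BandNotFoundError(RuntimeError):
    """The reflectivity profile has no usable band posterior to the ELM."""


class DegenerateRegionError(ValueError):
    pass


@dataclass(frozen=True)
class RoiSpec:
    """Analysis region on one side of the optic nerve head."""

    onh_col: int
    lateral_px_um: float
    side: str                       # "inferior" (columns < onh) or "superior"
    inner_um: float = 350.0
    outer_um: float = 624.0

    def __post_init__(self) -> None:
        if self.inner_um >= self.outer_um:
            raise ValueError("inner_um must be < outer_um")
        if self.side not in ("inferior", "superior"):
            raise ValueError("side must be 'inferior' or 'superior'")


def roi_columns(spec: RoiSpec, width: int) -> np.ndarray:
    """Column indices whose lateral offset from the optic nerve head lies
    in [inner_um, outer_um] (inclusive).  Inferior = columns before the
    nerve head, superior = after.  A region partly outside the image is
    truncated with a warning; an empty region is an error."""

    c = np.arange(width)
    offset_um = (c - spec.onh_col) * spec.lateral_px_um
    if spec.side == "inferior":
        offset_um = -offset_um
    eps = 1e-9
    inside = (offset_um >= spec.inner_um - eps) & (offset_um <= spec.outer_um + eps)
    cols = c[inside]
    # how many columns the full region would need, were the image unbounded
    full = int(np.floor(spec.outer_um / spec.lateral_px_um + eps)
               - np.ceil(spec.inner_um / spec.lateral_px_um - eps)) + 1
    if cols.size == 0:
        raise ValueError(
            f"{spec.side} region [{spec.inner_um}, {spec.outer_um}] um lies outside the image"
        )
    if cols.size < full:
        warnings.warn(
            f"{spec.side} region truncated to {cols.size}/{full} columns by the image edge",
            stacklevel=2,
        )
    return cols


def layer_thickness(
    seg: SegmentationResult,
    roi: np.ndarray,
    upper: str,
    lower: str,
    axial_px_um: float,
    *,
    max_undefined_frac: float = 0.10,
) -> float:
    """Mean thickness over the region: mean of (lower - upper) rows times
    the axial pixel size, in micrometers."""

    du = seg[upper].depth[roi]
    dl = seg[lower].depth[roi]
    diff = dl - du
    bad = ~np.isfinite(diff)
    if bad.mean() > max_undefined_frac:
        raise ValueError(
            f"{upper}->{lower}: undefined on {bad.mean():.0%} of region columns"
        )
    return float(np.nanmean(diff) * axial_px_um)


@dataclass
class FlattenedImage:
    """B-scan with Bruch's membrane shifted to a fixed row by per-column
    integer shifts (no stretching); vacated pixels are masked."""

    data: np.ndarray
    mask: np.ndarray                 # True where valid
    target_row: int
    shifts: np.ndarray               # integer rows each column moved by


def flatten_to_brm(
    image: np.ndarray,
    brm_depth: np.ndarray,
    target_row: int | None = None,
) -> FlattenedImage:
    """Hold the basal RPE at a fixed row using integer per-column axial
    shifts only (the image is never interpolated or stretched)."""

    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    brm = np.asarray(brm_depth, dtype=float)
    if brm.size != cols or not np.isfinite(brm).all():
        raise ValueError("BrM trace must be finite and defined at every column")
    if target_row is None:
        target_row = int(np.rint(np.median(brm)))
    shifts = np.rint(target_row - brm).astype(int)

    out = np.zeros_like(img)
    mask = np.zeros(img.shape, dtype=bool)
    for c in range(cols):
        s = shifts[c]
        src_lo, src_hi = max(0, -s), min(rows, rows - s)
        dst_lo, dst_hi = max(0, s), min(rows, rows + s)
        out[dst_lo:dst_hi, c] = img[src_lo:src_hi, c]
        mask[dst_lo:dst_hi, c] = True
    return FlattenedImage(out, mask, target_row, shifts)


@dataclass
class ReflectivityProfile:
    """Mean axial intensity profile of a flattened region; depth is in
    pixels relative to the fixed Bruch's membrane row (negative =
    anterior)."""

    depth: np.ndarray
    intensity: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth must be strictly increasing")


def mean_profile(flat: FlattenedImage, roi: np.ndarray) -> ReflectivityProfile:
    """Per-depth mean over region columns, masked pixels excluded;
    all-masked depth rows are dropped."""

    if len(roi) == 0:
        raise ValueError("empty region")
    sub = flat.data[:, roi]
    msk = flat.mask[:, roi]
    counts = msk.sum(axis=1)
    keep = counts > 0
    with np.errstate(invalid="ignore"):
        mean = np.where(keep, (sub * msk).sum(axis=1) / np.maximum(counts, 1), np.nan)
    rows = np.arange(flat.data.shape[0])
    return ReflectivityProfile(
        depth=(rows[keep] - flat.target_row).astype(float),
        intensity=mean[keep],
        provenance={"n_columns": int(len(roi)), "target_row": flat.target_row},
    )


@dataclass
class BandRegion:
    """Baseline-bounded band of a reflectivity profile.

    ``x`` is depth (px); the region is the area between the profile
    segment and the straight chord joining the flanking local minima.
    """

    x_left: float
    x_right: float
    x: np.ndarray
    curve: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        if self.x_left >= self.x_right:
            raise ValueError("x_left must be < x_right")
        if not np.any(self.curve > self.baseline):
            raise ValueError("curve never exceeds the baseline")


def _local_extrema(y: np.ndarray):
    i = np.arange(1, y.size - 1)
    maxima = i[(y[i] >= y[i - 1]) & (y[i] >= y[i + 1]) & ((y[i] > y[i - 1]) | (y[i] > y[i + 1]))]
    minima = i[(y[i] <= y[i - 1]) & (y[i] <= y[i + 1]) & ((y[i] < y[i - 1]) | (y[i] < y[i + 1]))]
    return maxima, minima


def ez_band_region(
    profile: ReflectivityProfile,
    elm_depth: float,
    *,
    baseline_mode: str = "chord",
) -> BandRegion:
    """Delimit the hyperreflective band immediately posterior to the ELM.

    The band peak is the first local maximum posterior to the ELM peak;
    its flanking local minima set the interval, and the baseline is the
    straight chord joining the profile values at those minima
    (``baseline_mode="horizontal"`` instead uses a flat line at the
    higher minimum).
    """

    y = profile.intensity
    x = profile.depth
    maxima, minima = _local_extrema(y)
    if maxima.size == 0:
        raise BandNotFoundError("profile has no local maxima")
    # ELM peak: local maximum nearest the stated ELM depth
    i_elm = maxima[np.argmin(np.abs(x[maxima] - elm_depth))]
    post = maxima[maxima > i_elm]
    if post.size == 0:
        raise BandNotFoundError("no local maximum posterior to the ELM")
    i_band = post[0]

    left_min = minima[(minima > i_elm) & (minima < i_band)]
    right_min = minima[minima > i_band]
    if left_min.size == 0 or right_min.size == 0:
        raise BandNotFoundError("band is not flanked by local minima")
    il = left_min[np.argmin(y[left_min])]
    ir = right_min[0]

    xs = x[il : ir + 1]
    ys = y[il : ir + 1]
    if baseline_mode == "chord":
        base = y[il] + (y[ir] - y[il]) * (xs - x[il]) / (x[ir] - x[il])
    elif baseline_mode == "horizontal":
        base = np.full_like(ys, max(y[il], y[ir]))
    else:
        raise ValueError("baseline_mode must be 'chord' or 'horizontal'")
    return BandRegion(float(x[il]), float(x[ir]), xs, ys, base)


@dataclass
class EllipseFit:
    """Moment-matched ellipse of a planar region."""

    centroid: tuple[float, float]    # (x = depth px, y = scaled-intensity px)
    semi_major: float
    semi_minor: float
    orientation_deg: float
    area: float

    @property
    def aspect_ratio(self) -> float:
        return self.semi_minor / self.semi_major


def fit_ellipse_moments(
    region: BandRegion,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
    *,
    oversample: int = 16,
) -> EllipseFit:
    """Fit an ellipse by matching area, centroid and second central
    moments of the planar region between baseline and curve.

    The region is ``{(x, y): x in [x_left, x_right],
    baseline(x)/s <= y <= curve(x)/s}`` with ``s = intensity_scale`` in
    counts per pixel.  The curve and baseline are treated as piecewise
    linear on an oversampled grid; every moment integrand is then a
    polynomial of degree <= 3 per strip, so 2-point Gauss-Legendre
    integration per strip is exact for that polygonal region.  The
    returned ellipse has the same centroid, the moment-derived
    orientation and axis ratio, and the same area.
    """

    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be > 0")
    s = intensity_scale
    n = max(int((region.x_right - region.x_left) * oversample), 8)
    xf = np.linspace(region.x_left, region.x_right, n + 1)
    a = np.interp(xf, region.x, region.baseline) / s    # lower edge
    b = np.interp(xf, region.x, region.curve) / s       # upper edge
    b = np.maximum(b, a)                                # clip where curve dips below
    dx = xf[1] - xf[0]

    # Gauss-Legendre nodes on each strip (exact through cubic integrands)
    tg = 0.5 + np.array([-1.0, 1.0]) / (2.0 * np.sqrt(3.0))
    X = xf[:-1, None] + dx * tg[None, :]
    A = a[:-1, None] + (a[1:] - a[:-1])[:, None] * tg[None, :]
    B = b[:-1, None] + (b[1:] - b[:-1])[:, None] * tg[None, :]
    H = B - A

    def integ(v):
        return float(v.sum() * dx * 0.5)

    m00 = integ(H)
    if m00 <= 0:
        raise DegenerateRegionError("region has zero area")
    m10 = integ(X * H)
    m01 = integ((B**2 - A**2) / 2.0)
    cx, cy = m10 / m00, m01 / m00
    mu20 = integ((X - cx) ** 2 * H)
    mu02 = integ(((B - cy) ** 3 - (A - cy) ** 3) / 3.0)
    mu11 = integ((X - cx) * ((B - cy) ** 2 - (A - cy) ** 2) / 2.0)

    cov = np.array([[mu20, mu11], [mu11, mu02]]) / m00
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 1e-300)
    ratio = float(np.sqrt(lam_minor / lam_major)) if lam_major > 0 else 0.0
    if ratio <= 0:
        raise DegenerateRegionError("region is degenerate (zero minor axis)")
    v = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(v[1], v[0])))
    semi_major = float(np.sqrt(m00 / (np.pi * ratio)))
    semi_minor = ratio * semi_major
    return EllipseFit(
        centroid=(cx, cy),
        semi_major=semi_major,
        semi_minor=semi_minor,
        orientation_deg=orientation,
        area=m00,
    )


def mcp_ar(
    flat: FlattenedImage,
    seg: SegmentationResult,
    roi: np.ndarray,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
    *,
    baseline_mode: str = "chord",
) -> float:
    """Aspect-ratio descriptor of the band posterior to the ELM: mean
    profile -> band region -> moment-matched ellipse -> minor/major."""

    profile = mean_profile(flat, roi)
    elm_rel = float(np.nanmean(seg["ELM"].depth[roi] - seg["BrM"].depth[roi]))
    region = ez_band_region(profile, elm_rel, baseline_mode=baseline_mode)
    return fit_ellipse_moments(region, intensity_scale).aspect_ratio


@dataclass
class BiomarkerRecord:
    """One eye-side worth of outcomes."""

    mouse: str
    group: str
    condition: str
    side: str
    elm_rpe_um: float
    mcp_ar: float
    ipl_um: float
    inl_opl_um: float
    onl_um: float
    cs: float = float("nan")
    acuity_cd: float = float("nan")

    def as_dict(self) -> dict:
        return dict(
            mouse=self.mouse, group=self.group, condition=self.condition,
            side=self.side, elm_rpe_um=self.elm_rpe_um, mcp_ar=self.mcp_ar,
            ipl_um=self.ipl_um, inl_opl_um=self.inl_opl_um, onl_um=self.onl_um,
            cs=self.cs, acuity_cd=self.acuity_cd,
        )


def measure_eye(
    stack: BScanStack,
    metadata: dict | None = None,
    *,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
    inner_um: float = 350.0,
    outer_um: float = 624.0,
    baseline_mode: str = "chord",
    registration_kwargs: dict | None = None,
    segmentation_kwargs: dict | None = None,
) -> list[BiomarkerRecord]:
    """End-to-end per-eye measurement: register and average the frames,
    segment, then per side compute layer thicknesses and MCP/AR.

    Returns one record per side (inferior, superior).  Stage failures
    are re-raised with the stage name and eye id attached.
    """

    meta = dict(metadata or {})
    eye = meta.get("mouse", meta.get("eye", "?"))

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"[{name}] eye {eye}: {exc}") from exc

    reg = _stage("register", register_and_average, stack, **(registration_kwargs or {}))
    seg = _stage("segment", segment, reg.average, **(segmentation_kwargs or {}))

    records = []
    for side in ("inferior", "superior"):
        spec = RoiSpec(stack.onh_col, stack.lateral_px_um, side,
                       inner_um=inner_um, outer_um=outer_um)
        roi = _stage("roi", roi_columns, spec, reg.average.shape[1])
        thick = {
            out: _stage("thickness", layer_thickness, seg, roi, up, lo, stack.axial_px_um)
            for out, (up, lo) in THICKNESS_PAIRS.items()
        }
        flat = _stage("flatten", flatten_to_brm, reg.average, seg["BrM"].depth)
        # flattening moves the traces with the columns
        ar = _stage("mcp_ar", mcp_ar, flat, _shifted_seg(seg, flat), roi,
                    intensity_scale, baseline_mode=baseline_mode)
        records.append(
            BiomarkerRecord(
                mouse=str(eye),
                group=str(meta.get("group", "")),
                condition=str(meta.get("condition", "")),
                side=side,
                mcp_ar=ar,
                cs=float(meta.get("cs", float("nan"))),
                acuity_cd=float(meta.get("acuity", float("nan"))),
                **thick,
            )
        )
    return records


def _shifted_seg(seg: SegmentationResult, flat: FlattenedImage) -> SegmentationResult:
    from .segmentation import BoundaryTrace

    out = SegmentationResult()
    for name, tr in seg.traces.items():
        out.traces[name] = BoundaryTrace(name, tr.depth + flat.shifts, tr.confidence)
    return out
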