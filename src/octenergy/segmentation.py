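"""Retinal layer segmentation of an averaged B-scan.

Boundary estimation proceeds in three stages.  A classical per-column
detector provides draft ("seed") boundaries: the ILM as the strongest
anterior dark-to-bright edge, the three inner slab boundaries (GCL/IPL,
IPL/INL, OPL/ONL) as the most prominent bright-to-dark gradient peaks
between ILM and the outer bands, and the outer hyperreflective bands
(ELM, EZ, RPE) as the most posterior prominent local maxima of the
axial profile.  Slab seeds are then refined with a dynamic-programming
shortest path through a per-layer cost image, constrained to a band
around the seed with a bounded column-to-column jump.  Finally the ELM
and RPE are re-localized as subpixel local maxima (3-point parabolic
interpolation) and Bruch's membrane as the posterior half-maximum
crossing of the RPE band.

A truth-perturbation seed mode (`seeds_from_truth`) lets the
shortest-path refinement be exercised in isolation against phantom
ground truth, standing in for an external learned boundary estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .phantom import GroundTruth

__all__ = [
    "BoundaryTrace",
    "CostImage",
    "SegmentationResult",
    "SegmentationError",
    "seed_boundaries",
    "seeds_from_truth",
    "shortest_path_refine",
    "detect_elm_rpe",
    "segment",
]

log = logging.getLogger(__name__)

#: traces a full segmentation must provide, anterior -> posterior
TRACE_ORDER = ("ILM", "GCL/IPL", "IPL/INL", "OPL/ONL", "ELM", "EZ", "RPE", "BrM")
SLAB_TRACES = ("ILM", "GCL/IPL", "IPL/INL", "OPL/ONL")
_HALF_MAX = np.sqrt(2.0 * np.log(2.0))


class SegmentationError(RuntimeError):
    pass


class InfeasiblePathError(SegmentationError):
    pass


@dataclass
class BoundaryTrace:
    """Per-column subpixel row position of one boundary."""

    layer: str
    depth: np.ndarray                   # (cols,) float
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)


@dataclass
class CostImage:
    """Non-negative per-pixel cost for one boundary's shortest path."""

    cost: np.ndarray
    transition: str = "ridge"           # dark->bright | bright->dark | ridge

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        if (self.cost < 0).any():
            raise ValueError("costs must be >= 0")


@dataclass
class SegmentationResult:
    traces: dict[str, BoundaryTrace] = field(default_factory=dict)

    def __getitem__(self, layer: str) -> BoundaryTrace:
        return self.traces[layer]

    def depth_matrix(self) -> np.ndarray:
        return np.stack([self.traces[n].depth for n in TRACE_ORDER if n in self.traces])

    def validate_ordering(self) -> None:
        d = self.depth_matrix()
        bad = ~np.all(np.diff(d, axis=0) > 0, axis=0)
        if bad.any():
            cols = np.where(bad)[0]
            raise SegmentationError(
                f"anatomical ordering violated at columns {cols.min()}..{cols.max()}"
            )


# ---------------------------------------------------------------------------
# seed detection

def _fill_gaps(depth: np.ndarray, layer: str, max_nan_frac: float = 0.5) -> np.ndarray:
    bad = ~np.isfinite(depth)
    if bad.mean() > max_nan_frac:
        raise SegmentationError(f"layer {layer}: detected in too few columns")
    if bad.any():
        x = np.arange(depth.size)
        depth = depth.copy()
        depth[bad] = np.interp(x[bad], x[~bad], depth[~bad])
    return ndimage.median_filter(depth, size=9, mode="nearest")


def seed_boundaries(
    image: np.ndarray,
    *,
    smooth_sigma_ax: float = 1.5,
    smooth_sigma_lat: float = 2.0,
    peak_prominence_frac: float = 0.08,
) -> SegmentationResult:
    """Classical draft segmentation of an averaged B-scan.

    Raises :class:`SegmentationError` when a required layer is missing
    in more than half of the columns (e.g. structureless input).
    """

    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise SegmentationError("image has no structure (constant intensity)")
    sm = ndimage.gaussian_filter(img, (smooth_sigma_ax, smooth_sigma_lat))
    rows, cols = sm.shape
    out = {name: np.full(cols, np.nan) for name in ("ILM", "GCL/IPL", "IPL/INL", "OPL/ONL", "ELM", "EZ", "RPE")}

    for c in range(cols):
        p = sm[:, c]
        span = np.percentile(p, 99) - np.percentile(p, 1)
        if span <= 0:
            continue
        peaks, props = signal.find_peaks(p, prominence=peak_prominence_frac * span)
        if peaks.size < 3:
            continue
        elm, ez, rpe = peaks[-3:]
        out["ELM"][c], out["EZ"][c], out["RPE"][c] = elm, ez, rpe

        g = np.gradient(p)
        # ILM: most anterior strong rising edge before the outer bands
        head = g[: max(elm - 10, 1)]
        gpeaks, _ = signal.find_peaks(head, height=0.4 * head.max()) if head.size > 2 else (np.array([]), None)
        if gpeaks.size == 0:
            continue
        ilm = int(gpeaks[0])
        out["ILM"][c] = ilm
        # inner slab boundaries: three strongest falling edges between ILM and ELM
        lo, hi = ilm + 3, max(elm - 6, ilm + 4)
        seg = -g[lo:hi]
        npeaks, nprops = signal.find_peaks(seg, height=0.0)
        if npeaks.size >= 3:
            top3 = npeaks[np.argsort(nprops["peak_heights"])[-3:]]
            b1, b2, b3 = np.sort(top3) + lo
            out["GCL/IPL"][c], out["IPL/INL"][c], out["OPL/ONL"][c] = b1, b2, b3

    traces = {}
    for name, depth in out.items():
        traces[name] = BoundaryTrace(name, _fill_gaps(depth, name))
    return SegmentationResult(traces=traces)


def seeds_from_truth(
    truth: GroundTruth,
    *,
    bias_px: float = 0.0,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SegmentationResult:
    """Seed provider from phantom ground truth with optional perturbation
    (constant bias and per-column Gaussian jitter), for testing the
    refinement stages in isolation."""

    rng = rng or np.random.default_rng(0)
    traces = {}
    for name in TRACE_ORDER:
        if name == "BrM" or name not in truth.boundaries:
            continue
        d = truth.boundaries[name].astype(float) + bias_px
        if jitter_px > 0:
            d = d + jitter_px * rng.standard_normal(d.size)
        traces[name] = BoundaryTrace(name, d)
    return SegmentationResult(traces=traces)


# ---------------------------------------------------------------------------
# shortest-path refinement

def shortest_path_refine(
    cost: CostImage,
    seed: BoundaryTrace,
    band: int = 12,
    max_jump: int = 2,
) -> BoundaryTrace:
    """Minimum-total-cost left-to-right path through ``(column, row)``
    nodes with ``|row - seed(column)| <= band`` and
    ``|row(c+1) - row(c)| <= max_jump``, by dynamic programming.

    Ties are broken toward the seed row, then toward the smaller row.
    Raises :class:`InfeasiblePathError` when the band leaves no feasible
    row in some column.
    """

    if band < 1 or max_jump < 1:
        raise ValueError("band and max_jump must be >= 1")
    C = np.asarray(cost.cost, dtype=float)
    rows, cols = C.shape
    seed_r = np.rint(np.asarray(seed.depth, dtype=float)).astype(int)
    if seed_r.size != cols:
        raise ValueError("seed trace length must match cost image width")

    lo = np.maximum(seed_r - band, 0)
    hi = np.minimum(seed_r + band, rows - 1)
    if (lo > hi).any():
        bad = int(np.where(lo > hi)[0][0])
        raise InfeasiblePathError(f"no feasible rows at column {bad}")

    INF = np.inf
    # backward DP: D[c][r] = min cost of path from column c (at row r) to the end
    D = np.full((cols, rows), INF)
    D[-1, lo[-1] : hi[-1] + 1] = C[lo[-1] : hi[-1] + 1, -1]
    for c in range(cols - 2, -1, -1):
        nxt = D[c + 1]
        best = np.full(rows, INF)
        for j in range(-max_jump, max_jump + 1):
            shifted = np.full(rows, INF)
            if j >= 0:
                shifted[: rows - j] = nxt[j:]
            else:
                shifted[-j:] = nxt[: rows + j]
            best = np.minimum(best, shifted)
        sl = slice(lo[c], hi[c] + 1)
        D[c, sl] = C[sl, c] + best[sl]

    feas0 = np.arange(lo[0], hi[0] + 1)
    d0 = D[0, feas0]
    if not np.isfinite(d0).any():
        raise InfeasiblePathError("no feasible path (jump constraint disconnects bands)")

    def _pick(cands: np.ndarray, values: np.ndarray, seed_row: int) -> int:
        m = values.min()
        opts = cands[values <= m + 1e-12]
        dist = np.abs(opts - seed_row)
        opts = opts[dist == dist.min()]
        return int(opts.min())

    path = np.empty(cols, dtype=int)
    path[0] = _pick(feas0, d0, seed_r[0])
    for c in range(1, cols):
        r_prev = path[c - 1]
        cands = np.arange(max(lo[c], r_prev - max_jump), min(hi[c], r_prev + max_jump) + 1)
        if cands.size == 0:
            raise InfeasiblePathError(f"jump constraint leaves no row at column {c}")
        path[c] = _pick(cands, D[c, cands], seed_r[c])

    conf = C[path, np.arange(cols)]
    return BoundaryTrace(seed.layer, path.astype(float), confidence=conf)


# ---------------------------------------------------------------------------
# cost images and subpixel band localization

def gradient_cost(image: np.ndarray, transition: str, smooth_sigma: float = 1.5) -> CostImage:
    """Per-column min-max-scaled signed axial gradient cost: low cost at
    the strongest edge of the requested polarity."""

    sm = ndimage.gaussian_filter(np.asarray(image, dtype=float), (smooth_sigma, smooth_sigma))
    g = np.gradient(sm, axis=0)
    if transition == "dark->bright":
        g = -g
    elif transition != "bright->dark":
        raise ValueError("transition must be 'dark->bright' or 'bright->dark'")
    gmin = g.min(axis=0, keepdims=True)
    gmax = g.max(axis=0, keepdims=True)
    span = np.where(gmax > gmin, gmax - gmin, 1.0)
    return CostImage((g - gmin) / span, transition)


def intensity_cost(image: np.ndarray, smooth_sigma: float = 1.0) -> CostImage:
    """Inverted, per-column min-max-scaled intensity: low cost on ridges."""

    sm = ndimage.gaussian_filter(np.asarray(image, dtype=float), (smooth_sigma, smooth_sigma))
    mn = sm.min(axis=0, keepdims=True)
    mx = sm.max(axis=0, keepdims=True)
    span = np.where(mx > mn, mx - mn, 1.0)
    return CostImage((mx - sm) / span, "ridge")


def _parabolic_peak(p: np.ndarray, r: int) -> tuple[float, float]:
    """Subpixel peak location/height from the 3-point neighbourhood."""
    if r <= 0 or r >= p.size - 1:
        return float(r), float(p[r])
    y0, y1, y2 = p[r - 1], p[r], p[r + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(r), float(p[r])
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return r + d, float(y1 - 0.25 * (y0 - y2) * d)


def _band_peak_trace(
    sm: np.ndarray, seed: BoundaryTrace, band: int, layer: str
) -> tuple[BoundaryTrace, np.ndarray]:
    """Subpixel local maximum within ``seed +- band`` per column.

    Non-unique maxima: the highest wins; exact ties go to the most
    anterior (smallest row), which is what argmax returns.
    """

    rows, cols = sm.shape
    depth = np.empty(cols)
    height = np.empty(cols)
    seed_r = np.rint(seed.depth).astype(int)
    for c in range(cols):
        a = max(seed_r[c] - band, 1)
        b = min(seed_r[c] + band, rows - 2)
        p = sm[:, c]
        win = np.arange(a, b + 1)
        is_max = (p[win] >= p[win - 1]) & (p[win] >= p[win + 1])
        cands = win[is_max]
        if cands.size == 0:
            # no interior maximum in the band: fall back to the windowed argmax
            r = int(a + np.argmax(p[a : b + 1]))
        else:
            # highest local maximum wins; exact ties go to the most anterior
            heights = p[cands]
            best = heights.max()
            r = int(cands[heights >= best - 1e-12].min())
        d, h = _parabolic_peak(p, r)
        depth[c] = d
        height[c] = h
    return BoundaryTrace(layer, depth, confidence=height), height


def detect_elm_rpe(
    image: np.ndarray,
    seeds: SegmentationResult,
    *,
    band: int = 6,
    smooth_sigma: float = 1.0,
    brm_search_px: int = 20,
) -> tuple[BoundaryTrace, BoundaryTrace, BoundaryTrace]:
    """Localize the ELM and RPE peaks (subpixel) and Bruch's membrane.

    ELM and RPE are the parabolic-interpolated local signal maxima
    within a band around their seeds.  Bruch's membrane is the posterior
    half-maximum crossing of the RPE band: the first depth posterior to
    the RPE peak where the profile falls below
    ``background + (peak - background)/2`` (linear interpolation between
    samples), with the background taken as the minimum over the
    posterior search window.
    """

    img = np.asarray(image, dtype=float)
    sm = ndimage.gaussian_filter(img, (smooth_sigma, 0.0))
    elm, _ = _band_peak_trace(sm, seeds["ELM"], band, "ELM")
    rpe, rpe_height = _band_peak_trace(sm, seeds["RPE"], band, "RPE")

    rows, cols = sm.shape
    brm = np.empty(cols)
    for c in range(cols):
        r0 = int(np.rint(rpe.depth[c]))
        r1 = min(r0 + brm_search_px, rows - 1)
        tail = sm[r0 : r1 + 1, c]
        background = tail.min()
        half = background + 0.5 * (rpe_height[c] - background)
        below = np.where(tail < half)[0]
        if below.size == 0 or below[0] == 0:
            brm[c] = np.nan
            continue
        i = below[0]
        y0, y1 = tail[i - 1], tail[i]
        frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.5
        brm[c] = r0 + i - 1 + frac
    brm_trace = BoundaryTrace("BrM", _fill_gaps(brm, "BrM"))
    return elm, rpe, brm_trace


def segment(
    image: np.ndarray,
    *,
    seeds: SegmentationResult | None = None,
    band: int = 12,
    max_jump: int = 2,
    smooth_sigma: float = 1.5,
    peak_band: int = 6,
) -> SegmentationResult:
    """Full segmentation: seeds -> shortest-path slab refinement ->
    subpixel band localization -> ordering check.

    Slab boundaries (all bright-to-dark except the dark-to-bright ILM)
    are refined on min-max-scaled gradient costs and then given a
    subpixel parabolic correction at the gradient extremum; ELM/EZ/RPE
    and Bruch's membrane come from :func:`detect_elm_rpe`.
    """

    img = np.asarray(image, dtype=float)
    if seeds is None:
        seeds = seed_boundaries(img, smooth_sigma_ax=smooth_sigma)

    traces: dict[str, BoundaryTrace] = {}
    grad_sm = {}
    for name in SLAB_TRACES:
        polarity = "dark->bright" if name == "ILM" else "bright->dark"
        cimg = gradient_cost(img, polarity, smooth_sigma)
        refined = shortest_path_refine(cimg, seeds[name], band=band, max_jump=max_jump)
        # subpixel: parabolic interpolation of the gradient extremum
        sm = ndimage.gaussian_filter(img, (smooth_sigma, smooth_sigma))
        g = np.gradient(sm, axis=0)
        if name != "ILM":
            g = -g
        depth = refined.depth.copy()
        for c in range(depth.size):
            d, _ = _parabolic_peak(g[:, c], int(depth[c]))
            depth[c] = d
        traces[name] = BoundaryTrace(name, depth, confidence=refined.confidence)

    sm_band = ndimage.gaussian_filter(img, (1.0, 0.0))
    ez, _ = _band_peak_trace(sm_band, seeds["EZ"], peak_band, "EZ")
    elm, rpe, brm = detect_elm_rpe(img, seeds, band=peak_band)
    traces["ELM"], traces["EZ"], traces["RPE"], traces["BrM"] = elm, ez, rpe, brm

    result = SegmentationResult(traces=traces)
    result.validate_ordering()
    return result
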