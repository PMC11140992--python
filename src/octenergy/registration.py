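"""Rigid registration and averaging of B-scan frames.

The procedure mirrors a two-stage OCT frame-averaging workflow: the
central frames of a volume are selected, each frame gets a first-pass
rigid-body alignment (rotation about the image centre + subpixel
translation, scored by normalized cross-correlation), followed by an
iterated non-rotational refinement that shifts individual pixel columns
(axially) and rows (laterally) — three iterations by default — before
the aligned frames are averaged pixel-wise.  A numeric NCC floor stands
in for the visual quality check: frames whose post-alignment NCC falls
below it are excluded from the average and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .phantom import BScanStack, apply_rigid

__all__ = [
    "RigidTransform",
    "ShiftField",
    "RegistrationResult",
    "select_central_frames",
    "estimate_rigid",
    "refine_nonrotational",
    "register_and_average",
]

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when a frame has no intensity variance to align on."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about the image centre) then (dy, dx) shift in
    pixels; subpixel values allowed."""

    rotation_deg: float = 0.0
    dy: float = 0.0
    dx: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rotation_deg, self.dy, self.dx)


@dataclass
class ShiftField:
    """Accumulated per-column axial and per-row lateral shifts (pixels)."""

    col_axial: np.ndarray      # (cols,) shift applied to each column
    row_lateral: np.ndarray    # (rows,)


@dataclass
class RegistrationResult:
    average: np.ndarray
    transforms: list[RigidTransform]
    shift_fields: list[ShiftField]
    ncc: list[float]
    included: list[bool]
    reference_index: int = 0

    @property
    def qc(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "ncc": [float(v) for v in self.ncc],
            "included": [bool(v) for v in self.included],
            "n_excluded": int(sum(not v for v in self.included)),
        }


def select_central_frames(stack: BScanStack, lo: int, hi: int) -> BScanStack:
    """Return the frames numbered ``lo``..``hi`` (1-based, inclusive —
    e.g. 450..549 of a 1000-frame volume gives 100 frames)."""

    if not (1 <= lo <= hi <= stack.n_frames):
        raise IndexError(
            f"frame range [{lo}, {hi}] outside stack with {stack.n_frames} frames"
        )
    return BScanStack(
        frames=stack.frames[lo - 1 : hi],
        axial_px_um=stack.axial_px_um,
        lateral_px_um=stack.lateral_px_um,
        onh_col=stack.onh_col,
        metadata={**stack.metadata, "frame_range": (lo, hi)},
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _central(img: np.ndarray, margin: int) -> np.ndarray:
    m = min(margin, (min(img.shape) - 8) // 2)
    return img[m:-m, m:-m] if m > 0 else img


def _score_rotation(frame, reference, rot, shift_max, margin, upsample):
    rotated = apply_rigid(frame, rot, 0.0, 0.0)
    shift, _err, _ = phase_cross_correlation(
        reference, rotated, upsample_factor=upsample, normalization=None
    )
    dy = float(np.clip(shift[0], -shift_max, shift_max))
    dx = float(np.clip(shift[1], -shift_max, shift_max))
    moved = ndimage.shift(rotated, (dy, dx), order=1, mode="nearest")
    return _ncc(_central(moved, margin), _central(reference, margin)), dy, dx


def estimate_rigid(
    frame: np.ndarray,
    reference: np.ndarray,
    *,
    rot_max_deg: float = 3.0,
    rot_step_deg: float = 0.1,
    shift_max_px: float = 10.0,
    upsample: int = 50,
) -> RigidTransform:
    """First-pass rigid alignment of ``frame`` onto ``reference``.

    Searches a rotation grid (coarse 5x step, then ``rot_step_deg``
    around the best, then a parabolic fit of NCC over the final three
    points) and at each rotation estimates the subpixel translation by
    cross-correlation; the transform with the highest NCC wins.
    """

    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if frame.std() == 0 or reference.std() == 0:
        raise DegenerateInputError("constant image cannot be registered")

    margin = int(np.ceil(shift_max_px)) + 4
    coarse_step = max(rot_step_deg * 5, rot_step_deg)
    coarse = np.arange(-rot_max_deg, rot_max_deg + 1e-9, coarse_step)
    if 0.0 not in coarse:
        coarse = np.sort(np.append(coarse, 0.0))

    def best_over(grid):
        results = {}
        for r in grid:
            results[round(float(r), 6)] = _score_rotation(
                frame, reference, float(r), shift_max_px, margin, upsample
            )
        best = max(results, key=lambda r: results[r][0])
        return best, results

    best, scores = best_over(coarse)
    fine = np.arange(best - coarse_step, best + coarse_step + 1e-9, rot_step_deg)
    fine = fine[(fine >= -rot_max_deg - 1e-9) & (fine <= rot_max_deg + 1e-9)]
    best, fine_scores = best_over(fine)
    scores.update(fine_scores)

    # parabolic sub-step refinement of rotation when bracketed
    lo, hi = round(best - rot_step_deg, 6), round(best + rot_step_deg, 6)
    rot = best
    if lo in scores and hi in scores:
        y0, y1, y2 = scores[lo][0], scores[best][0], scores[hi][0]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            rot = best + 0.5 * (y0 - y2) / denom * rot_step_deg
            rot = float(np.clip(rot, -rot_max_deg, rot_max_deg))
    ncc, dy, dx = _score_rotation(frame, reference, rot, shift_max_px, margin, upsample)
    # keep the grid optimum if the parabolic step did not help
    if ncc < scores[best][0]:
        rot, (ncc, dy, dx) = best, scores[best]
    return RigidTransform(rotation_deg=float(rot), dy=dy, dx=dx)


def _line_shifts(moving: np.ndarray, reference: np.ndarray, window: int, axis: int):
    """Integer + parabolic-subpixel shift per line maximizing NCC.

    ``axis=0``: shift each column axially; ``axis=1``: shift each row
    laterally.  Lines with zero variance get shift 0.
    """

    if axis == 1:
        moving = moving.T
        reference = reference.T
    n, m = moving.shape  # n = samples per line after transpose handling
    w = window
    lo, hi = w, n - w
    if hi - lo < 8:
        raise ValueError("window too large for image size")
    ref = reference[lo:hi]
    ref_c = ref - ref.mean(axis=0)
    ref_sd = ref.std(axis=0)
    shifts = np.arange(-w, w + 1)
    scores = np.empty((len(shifts), m))
    for i, k in enumerate(shifts):
        # content moved down by k means new[r] = old[r-k]
        seg = moving[lo - k : hi - k]
        seg_c = seg - seg.mean(axis=0)
        seg_sd = seg.std(axis=0)
        denom = ref_sd * seg_sd
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[i] = np.where(denom > 0, (ref_c * seg_c).mean(axis=0) / denom, -np.inf)
    ibest = np.argmax(scores, axis=0)
    best = shifts[ibest].astype(float)
    # parabolic refinement where the peak is interior
    interior = (ibest > 0) & (ibest < len(shifts) - 1)
    idx = np.where(interior)[0]
    if idx.size:
        y0 = scores[ibest[idx] - 1, idx]
        y1 = scores[ibest[idx], idx]
        y2 = scores[ibest[idx] + 1, idx]
        denom = y0 - 2 * y1 + y2
        # a perfect-correlation peak cannot be improved by interpolation
        ok = (denom < 0) & (y1 < 1.0 - 1e-9)
        frac = np.zeros_like(y1)
        frac[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
        best[idx] += np.clip(frac, -0.5, 0.5)
    dead = ~np.isfinite(scores).any(axis=0)
    if dead.any():
        best[dead] = 0.0
        log.debug("zero-variance lines along axis %d: %d", axis, int(dead.sum()))
    return np.clip(best, -w, w)


def _shift_lines(img: np.ndarray, shifts: np.ndarray, axis: int) -> np.ndarray:
    """Apply per-line subpixel shifts (content moves by +shift along the
    line) with linear interpolation and edge replication."""

    work = img if axis == 0 else img.T
    n, m = work.shape
    rows = np.arange(n, dtype=float)[:, None] - shifts[None, :]
    rows = np.clip(rows, 0, n - 1)
    r0 = np.floor(rows).astype(int)
    r1 = np.minimum(r0 + 1, n - 1)
    frac = rows - r0
    cols = np.broadcast_to(np.arange(m), (n, m))
    out = work[r0, cols] * (1 - frac) + work[r1, cols] * frac
    return out if axis == 0 else out.T


def refine_nonrotational(
    frame: np.ndarray,
    reference: np.ndarray,
    *,
    window: int = 10,
    n_iter: int = 3,
) -> tuple[ShiftField, np.ndarray]:
    """Iterated per-column (axial) then per-row (lateral) shift
    refinement against a fixed reference; ``n_iter`` full passes."""

    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if window < 1:
        raise ValueError("window must be >= 1")
    rows, cols = frame.shape
    total_col = np.zeros(cols)
    total_row = np.zeros(rows)
    current = frame
    for _ in range(int(n_iter)):
        s_col = _line_shifts(current, reference, window, axis=0)
        current = _shift_lines(current, s_col, axis=0)
        total_col += s_col
        s_row = _line_shifts(current, reference, window, axis=1)
        current = _shift_lines(current, s_row, axis=1)
        total_row += s_row
    return ShiftField(col_axial=total_col, row_lateral=total_row), current


def register_and_average(
    stack: BScanStack,
    *,
    reference_index: int = 0,
    rot_max_deg: float = 3.0,
    rot_step_deg: float = 0.1,
    shift_max_px: float = 10.0,
    window: int = 10,
    n_iter: int = 3,
    ncc_floor: float = 0.6,
) -> RegistrationResult:
    """Align every frame to the reference frame and average.

    Each non-reference frame goes through :func:`estimate_rigid` and
    :func:`refine_nonrotational`; frames whose final NCC against the
    reference is below ``ncc_floor`` are excluded from the pixel-wise
    mean (and logged).  Single-frame stacks are returned unchanged.
    """

    if stack.n_frames < 1:
        raise ValueError("empty stack")
    frames = stack.frames.astype(float)
    ref = frames[reference_index]
    if ref.std() == 0:
        raise DegenerateInputError(f"reference frame {reference_index} is constant")

    rows, cols = ref.shape
    aligned = [ref]
    transforms = [RigidTransform()]
    shift_fields = [ShiftField(np.zeros(cols), np.zeros(rows))]
    nccs = [1.0]
    margin = int(np.ceil(shift_max_px)) + 4
    for i in range(stack.n_frames):
        if i == reference_index:
            continue
        frame = frames[i]
        try:
            t = estimate_rigid(
                frame, ref,
                rot_max_deg=rot_max_deg, rot_step_deg=rot_step_deg,
                shift_max_px=shift_max_px,
            )
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"frame {i}: {exc}") from exc
        moved = apply_rigid(frame, *t.as_tuple())
        sf, refined = refine_nonrotational(moved, ref, window=window, n_iter=n_iter)
        ncc = _ncc(_central(refined, margin), _central(ref, margin))
        transforms.append(t)
        shift_fields.append(sf)
        nccs.append(ncc)
        aligned.append(refined)

    # restore stack order (reference first in our accumulators)
    order = [reference_index] + [i for i in range(stack.n_frames) if i != reference_index]
    perm = np.argsort(order)
    transforms = [transforms[j] for j in perm]
    shift_fields = [shift_fields[j] for j in perm]
    nccs = [nccs[j] for j in perm]
    aligned = [aligned[j] for j in perm]

    included = [v >= ncc_floor for v in nccs]
    if not any(included):
        included[reference_index] = True
    for i, ok in enumerate(included):
        if not ok:
            log.warning("frame %d excluded from average (NCC %.3f < floor %.3f)",
                        i, nccs[i], ncc_floor)
    avg = np.mean([a for a, ok in zip(aligned, included) if ok], axis=0)
    return RegistrationResult(
        average=avg,
        transforms=transforms,
        shift_fields=shift_fields,
        ncc=nccs,
        included=included,
        reference_index=reference_index,
    )
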