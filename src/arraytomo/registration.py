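"""Rigid alignment of serial-section stacks.

Physical sections land on the slide with small independent translations and
rotations.  Alignment estimates a rigid transform between each pair of
consecutive sections on a reference channel (phase correlation for the
translation, a bounded small-angle search for the rotation) and composes the
pairwise transforms into the frame of the first section.  The identical
transform is applied to every channel of a section, so inter-channel spatial
relations are preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp

from .stacks import MultiChannelStack

__all__ = ["RigidTransform", "estimate_rigid", "align_stack", "apply_rigid"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotate by ``theta`` (deg, CCW) about the image
    centre, then translate by ``(dx, dy)`` pixels (x = columns, y = rows)."""

    dx: float
    dy: float
    theta: float = 0.0
    section: int | None = None
    reference_channel: str | None = None

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous matrix in (x, y) coordinates, rotation about centre."""
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        th = np.deg2rad(self.theta)
        c, s = np.cos(th), np.sin(th)
        m = np.array(
            [
                [c, -s, self.dx + cx - c * cx + s * cy],
                [s, c, self.dy + cy - s * cx - c * cy],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def inverse(self, shape: tuple[int, int]) -> "RigidTransform":
        return transform_from_matrix(np.linalg.inv(self.matrix(shape)), shape)


def transform_from_matrix(m: np.ndarray, shape: tuple[int, int]) -> RigidTransform:
    """Recover the centred (dx, dy, theta) parameterization from a matrix."""
    theta = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    centre = np.array([cx, cy, 1.0])
    moved = m @ centre
    return RigidTransform(dx=float(moved[0] - cx), dy=float(moved[1] - cy), theta=theta)


def apply_rigid(image: np.ndarray, t: RigidTransform, order: int = 1) -> np.ndarray:
    """Warp an image by a rigid transform (moves content by ``t``).

    ``order=1`` is bilinear (default for intensity data); ``order=0`` is
    nearest-neighbour, exact for integer-pixel translations.
    """
    m = t.matrix(image.shape)
    tform = AffineTransform(matrix=np.linalg.inv(m))
    return warp(
        np.asarray(image, dtype=float), tform, order=order, mode="constant",
        cval=0.0, preserve_range=True,
    )


def _shift_and_error(fixed: np.ndarray, moving: np.ndarray, upsample: int) -> tuple[np.ndarray, float]:
    shift, error, _ = phase_cross_correlation(
        fixed, moving, upsample_factor=upsample, normalization=None
    )
    return shift, float(error)


def estimate_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 5.0,
    coarse_step: float = 0.5,
    upsample: int = 100,
    smooth_sigma: float = 1.5,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Translation comes from phase cross-correlation resolved to sub-pixel by
    Fourier upsampling; rotation from a coarse grid over ``±max_rotation``
    degrees followed by bounded scalar refinement of the phase-correlation
    residual.  Array tomography sections are near-aligned by acquisition, so
    the small-angle search is adequate.

    Both images are low-pass filtered (``smooth_sigma`` px) before
    estimation: consecutive physical sections image different slices of the
    same structures, and suppressing the slice-specific high frequencies
    reduces the rotation bias that difference induces.  Filtering is
    shift-equivariant, so translation accuracy is unaffected.

    Raises a ``ValueError`` on constant (featureless) input.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        raise ValueError("degenerate input: constant image cannot be registered")
    if smooth_sigma > 0:
        from scipy import ndimage

        fixed = ndimage.gaussian_filter(fixed, smooth_sigma)
        moving = ndimage.gaussian_filter(moving, smooth_sigma)

    def residual(theta: float) -> float:
        rotated = apply_rigid(moving, RigidTransform(0.0, 0.0, theta)) if theta else moving
        _, err = _shift_and_error(fixed, rotated, upsample=10)
        return err

    best_theta = 0.0
    if max_rotation > 0:
        grid = np.arange(-max_rotation, max_rotation + coarse_step / 2, coarse_step)
        errs = [residual(t) for t in grid]
        best_theta = float(grid[int(np.argmin(errs))])
        lo = max(best_theta - coarse_step, -max_rotation)
        hi = min(best_theta + coarse_step, max_rotation)
        res = optimize.minimize_scalar(
            residual, bounds=(lo, hi), method="bounded", options={"xatol": 5e-3}
        )
        if res.fun <= residual(best_theta):
            best_theta = float(res.x)

    rotated = apply_rigid(moving, RigidTransform(0.0, 0.0, best_theta)) if best_theta else moving
    shift, _ = _shift_and_error(fixed, rotated, upsample=upsample)
    return RigidTransform(dx=float(shift[1]), dy=float(shift[0]), theta=best_theta)


def align_stack(
    stack: MultiChannelStack,
    reference_channel: str | None = None,
    max_rotation: float = 5.0,
    order: int = 1,
) -> tuple[MultiChannelStack, pd.DataFrame]:
    """Align all sections of a stack into the frame of the first section.

    Pairwise transforms are estimated between consecutive sections of the
    reference channel and composed into a global per-section transform that is
    applied identically to every channel.  Voxels warped in from outside the
    frame are marked invalid and excluded from analyzed volume downstream.
    A section whose estimate fails gets the identity and a logged warning.

    Returns the aligned stack and a table ``(section, dx, dy, theta, ok)`` of
    the applied global transforms.
    """
    if reference_channel is None:
        reference_channel = stack.channel_names[0]
    if reference_channel not in stack.channels:
        raise KeyError(f"reference channel {reference_channel!r} not in stack")
    ref = stack.channels[reference_channel]
    n_sections = ref.shape[0]
    shape2d = ref.shape[1:]

    matrices = [np.eye(3)]
    ok = [True]
    for s in range(1, n_sections):
        try:
            t = estimate_rigid(ref[s - 1], ref[s], max_rotation=max_rotation)
            matrices.append(matrices[-1] @ t.matrix(shape2d))
            ok.append(True)
        except ValueError as exc:
            logger.warning("section %d: registration failed (%s); using identity", s, exc)
            matrices.append(matrices[-1].copy())
            ok.append(False)

    aligned = {name: np.empty_like(arr, dtype=float) for name, arr in stack.channels.items()}
    valid = np.empty(ref.shape, dtype=bool)
    ones = np.ones(shape2d)
    rows = []
    for s in range(n_sections):
        t = transform_from_matrix(matrices[s], shape2d)
        for name, arr in stack.channels.items():
            aligned[name][s] = np.clip(apply_rigid(arr[s], t, order=order), 0.0, None)
        valid[s] = apply_rigid(ones, t, order=order) > 0.999
        rows.append(
            {"section": s, "dx": t.dx, "dy": t.dy, "theta": t.theta, "ok": ok[s]}
        )

    prev_valid = stack.valid()
    out = MultiChannelStack(
        channels=aligned,
        geometry=stack.geometry,
        aligned=True,
        valid_mask=valid & prev_valid,
    )
    return out, pd.DataFrame(rows)
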