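"""Shared resampling helpers.

All affine transforms in this package are expressed in millimetre
coordinates about the volume centre and used as pull-back sampling maps:
the output image evaluates the input at ``A·x`` for each output-grid
offset ``x`` (see :class:`trialprep.core_io.AffineParams`).  An optional
pre-translation in voxels (the within-trial phase-axis shift) is folded
into the same map so each volume is interpolated exactly once.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def grid_center(shape) -> np.ndarray:
    return (np.asarray(shape[:3], float) - 1.0) / 2.0


def voxel_matrix_offset(
    M_mm: np.ndarray,
    voxel_size: np.ndarray,
    shape,
    pre_translation_vox: np.ndarray | None = None,
    post_translation_vox: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a centre-anchored mm map into ndimage matrix/offset form.

    The composed sampling map is
    ``in = c + V⁻¹ M₃ V (out − c − p) + V⁻¹ t + q`` where ``V`` holds the
    voxel sizes, ``c`` the grid centre, ``p``/``q`` the optional pre/post
    translations (voxels) and ``(M₃, t)`` the linear and translation parts
    of ``M_mm``.  The pre-translation shifts the output frame before the
    affine acts (used when injecting corruption); the post-translation
    adds to the sampling coordinate after it (used when composing the
    within-trial shift correction with the trial affine).
    """
    M_mm = np.asarray(M_mm, float)
    V = np.asarray(voxel_size, float).reshape(3)
    c = grid_center(shape)
    A = (M_mm[:3, :3] * V[np.newaxis, :]) / V[:, np.newaxis]  # V^-1 M3 V
    t_vox = M_mm[:3, 3] / V
    anchor = c.copy()
    if pre_translation_vox is not None:
        anchor = anchor + np.asarray(pre_translation_vox, float)
    offset = c + t_vox - A @ anchor
    if post_translation_vox is not None:
        offset = offset + np.asarray(post_translation_vox, float)
    return A, offset


def resample(
    volume: np.ndarray,
    M_mm: np.ndarray,
    voxel_size: np.ndarray,
    pre_translation_vox: np.ndarray | None = None,
    post_translation_vox: np.ndarray | None = None,
    order: int = 3,
    prefiltered: bool = False,
) -> np.ndarray:
    """Resample ``volume`` through a centre-anchored mm affine map.

    With ``M_mm`` the identity and no pre/post translation this is exact
    (no interpolation is performed).
    """
    pre = np.zeros(3) if pre_translation_vox is None else \
        np.asarray(pre_translation_vox, float).reshape(3)
    post = np.zeros(3) if post_translation_vox is None else \
        np.asarray(post_translation_vox, float).reshape(3)
    if (np.allclose(M_mm, np.eye(4), atol=1e-14)
            and np.all(np.abs(pre) < 1e-14) and np.all(np.abs(post) < 1e-14)):
        return volume.copy()
    A, offset = voxel_matrix_offset(M_mm, voxel_size, volume.shape, pre, post)
    return ndimage.affine_transform(
        volume, A, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=not prefiltered,
    )


def shift_volume(
    volume: np.ndarray,
    shift_vox: float,
    axis: int,
    order: int = 3,
    prefiltered: bool = False,
) -> np.ndarray:
    """Translate by ``shift_vox`` voxels along one axis (object moves in
    the positive index direction for positive shifts)."""
    if abs(shift_vox) < 1e-14:
        return volume.copy()
    vec = np.zeros(3)
    vec[axis] = shift_vox
    return ndimage.shift(volume, vec, order=order, mode="constant", cval=0.0,
                         prefilter=not prefiltered)
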