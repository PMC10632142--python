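"""Depth stratification and co-fasciculation contact statistics.

Dendritic stratification depth is expressed as a percentage across the inner
plexiform layer (0% = INL border, 100% = GCL border): a z-axis intensity
profile is background-subtracted, normalised to its maximum, negatives
clipped to zero, and mapped linearly between the two border z-positions.

Co-fasciculation between a filled cell and a partner channel (e.g. ChAT-
labelled starburst dendrites) is the per-slice overlap area of the two
binary masks summed over the stack, expressed as a percentage of the
reference-mask area. The control statistic repeats the measurement after
rotating the partner channel 90° in-plane about the volume centre, which
destroys genuine co-fasciculation while preserving the partner's area and
depth profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DepthProfile:
    depth_pct: np.ndarray  # 0 (INL border) .. 100 (GCL border), monotone
    intensity: np.ndarray  # (Z,) or (Z, n_channels), normalised to [0, 1]
    peak_depth_pct: np.ndarray  # per channel; NaN when profile is empty


def depth_profile(
    intensity_z,
    inl_z: float,
    gcl_z: float,
    background: float | np.ndarray = 0.0,
) -> DepthProfile:
    """Normalised IPL depth profile of one or more channels.

    ``intensity_z`` is a (Z,) or (Z, n_channels) z-axis intensity profile;
    ``inl_z``/``gcl_z`` are the border frame positions (either acquisition
    direction — the linear map flips as needed). The mean background is
    subtracted per channel, profiles are normalised to their maximum, and
    negative values are set to 0. A channel that is non-positive everywhere
    after subtraction has an undefined (NaN) peak.
    """
    if inl_z == gcl_z:
        raise ValueError("INL and GCL border positions must differ")
    prof = np.asarray(intensity_z, dtype=float)
    squeeze = prof.ndim == 1
    if squeeze:
        prof = prof[:, None]
    bg = np.broadcast_to(np.asarray(background, dtype=float), (prof.shape[1],))
    prof = prof - bg[None, :]
    z = np.arange(prof.shape[0])
    depth = (z - inl_z) / (gcl_z - inl_z) * 100.0
    if depth[0] > depth[-1]:  # re-order so the depth axis is increasing
        depth = depth[::-1]
        prof = prof[::-1]
    norm = np.zeros_like(prof)
    peaks = np.full(prof.shape[1], np.nan)
    for c in range(prof.shape[1]):
        peak = prof[:, c].max()
        if peak <= 0:
            continue
        norm[:, c] = np.clip(prof[:, c] / peak, 0.0, None)
        peaks[c] = depth[int(np.argmax(prof[:, c]))]
    return DepthProfile(
        depth_pct=depth,
        intensity=norm[:, 0] if squeeze else norm,
        peak_depth_pct=peaks,
    )


@dataclass
class ContactResult:
    overlap_area_per_slice: np.ndarray  # voxels of overlap per z-slice
    total_overlap_pct: float  # overlap as % of reference-mask area
    rotated_overlap_pct: float | None  # same after 90° in-plane rotation
    rotated_area_loss_pct: float | None  # partner voxels lost to the frame edge


def _rotate90_inplane(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate a Z×Y×X binary mask 90° about the z-axis through the centre.

    Exact (lossless) when the in-plane shape is square; otherwise nearest-
    neighbour resampling about the centre, dropping voxels rotated out of
    frame. Returns (rotated mask, % of partner area lost).
    """
    _, ny, nx = mask.shape
    before = int(mask.sum())
    if ny == nx:
        rot = np.rot90(mask, k=1, axes=(1, 2))
        return rot, 0.0
    rot = (
        ndimage.rotate(
            mask.astype(np.uint8), 90.0, axes=(2, 1), reshape=False, order=0, mode="constant"
        )
        > 0
    )
    after = int(rot.sum())
    loss = 0.0 if before == 0 else 100.0 * (before - after) / before
    return rot, loss


def contact_fraction(
    mask_ref: np.ndarray,
    mask_partner: np.ndarray,
    rotate_control: bool = True,
) -> ContactResult:
    """Per-slice overlap of two binary volumes as % of the reference area.

    ``mask_ref`` is the filled-cell mask, ``mask_partner`` the thresholded
    partner channel. With ``rotate_control``, the measurement is repeated
    with the partner rotated 90° in-plane as a chance-overlap control.
    """
    ref = np.asarray(mask_ref, dtype=bool)
    par = np.asarray(mask_partner, dtype=bool)
    if ref.shape != par.shape:
        raise ValueError(f"volume shapes differ: {ref.shape} vs {par.shape}")
    ref_area = int(ref.sum())
    if ref_area == 0:
        raise ValueError("reference mask is empty")
    per_slice = (ref & par).sum(axis=(1, 2))
    total_pct = 100.0 * per_slice.sum() / ref_area
    rot_pct = rot_loss = None
    if rotate_control:
        rot, rot_loss = _rotate90_inplane(par)
        rot_pct = 100.0 * (ref & rot).sum() / ref_area
    return ContactResult(
        overlap_area_per_slice=per_slice,
        total_overlap_pct=float(total_pct),
        rotated_overlap_pct=None if rot_pct is None else float(rot_pct),
        rotated_area_loss_pct=rot_loss,
    )
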