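"""Compartment intensity ratios: nuclear/cytoplasmic YAP and
apical/basolateral pERM.

Both ratios are means of raw voxel intensities over compartment masks and
are therefore invariant to any positive rescaling of the channel. The
cytoplasm is the whole cell minus the nucleus (membrane shells included);
no background subtraction is applied by default (synthetic volumes are
background-free), but a constant offset can be passed for real data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .embryo import LabelledEmbryo

#: Default membrane-shell thickness in µm (one z-step of typical stacks).
DEFAULT_SHELL_THICKNESS = 1.0


@dataclass
class CompartmentMasks:
    """Flat voxel indices of one cell's compartments.

    ``apical`` collects cell voxels within ``shell_thickness`` of the
    exposed (outside-facing) surface, ``basolateral`` those near surface
    apposed to other cells. ``nucleus`` and ``cytoplasm`` are disjoint and
    the shells are subsets of the cell by construction.
    """

    cell_id: int
    nucleus: np.ndarray
    cytoplasm: np.ndarray
    apical: np.ndarray
    basolateral: np.ndarray
    shell_thickness: float


def membrane_shells(
    cell_labels: np.ndarray,
    cell_id: int,
    spacing,
    thickness: float = DEFAULT_SHELL_THICKNESS,
    contact_distance: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean apical / basolateral shell masks for one cell.

    The shell is the set of cell voxels within ``thickness`` of the cell
    boundary. A shell voxel is basolateral when a voxel of a different cell
    lies within ``thickness + contact_distance`` of it, apical otherwise
    (mirroring the surface-domain proximity rule at voxel resolution).
    """
    spacing = np.asarray(spacing, float)
    mask = cell_labels == cell_id
    if not mask.any():
        raise ValueError(f"no voxels labelled {cell_id}")
    pad = tuple(int(np.ceil((thickness + contact_distance) / s)) + 2 for s in spacing)
    obj = ndimage.find_objects(mask.astype(np.uint8))[0]
    sl = tuple(
        slice(max(s.start - p, 0), min(s.stop + p, n))
        for s, p, n in zip(obj, pad, mask.shape)
    )
    sub = cell_labels[sl]
    cell = sub == cell_id
    inner = ndimage.distance_transform_edt(cell, sampling=spacing)
    shell = cell & (inner <= thickness)
    other = (sub > 0) & ~cell
    if other.any():
        d_other = ndimage.distance_transform_edt(~other, sampling=spacing)
        baso_sub = shell & (d_other <= thickness + contact_distance)
    else:
        baso_sub = np.zeros_like(shell)
    api_sub = shell & ~baso_sub
    apical = np.zeros_like(mask)
    basolateral = np.zeros_like(mask)
    apical[sl] = api_sub
    basolateral[sl] = baso_sub
    return apical, basolateral


def compartment_masks(
    embryo: LabelledEmbryo,
    cell_id: int,
    shell_thickness: float = DEFAULT_SHELL_THICKNESS,
    contact_distance: float = 1.0,
) -> CompartmentMasks:
    """Build nucleus/cytoplasm/apical/basolateral masks for one cell."""
    cell = embryo.cell_labels == cell_id
    if not cell.any():
        raise ValueError(f"embryo {embryo.embryo_id!r} has no cell {cell_id}")
    nucleus = embryo.nucleus_labels == cell_id
    apical, baso = membrane_shells(
        embryo.cell_labels,
        cell_id,
        embryo.voxel_spacing,
        thickness=shell_thickness,
        contact_distance=contact_distance,
    )
    return CompartmentMasks(
        cell_id=int(cell_id),
        nucleus=np.flatnonzero(nucleus),
        cytoplasm=np.flatnonzero(cell & ~nucleus),
        apical=np.flatnonzero(apical),
        basolateral=np.flatnonzero(baso),
        shell_thickness=shell_thickness,
    )


def _mean(channel: np.ndarray, idx: np.ndarray, offset: float) -> float:
    return float(channel.ravel()[idx].mean() - offset)


def nc_ratio(
    channel: np.ndarray, masks: CompartmentMasks, background: float = 0.0
) -> float:
    """Nuclear / cytoplasmic mean-intensity ratio for one cell.

    NaN (with no exception) when the nucleus mask is empty - a missed
    nucleus segmentation is a per-cell QC failure, not a pipeline error.
    """
    if masks.nucleus.size == 0 or masks.cytoplasm.size == 0:
        return float("nan")
    cyto = _mean(channel, masks.cytoplasm, background)
    if cyto <= 0:
        return float("nan")
    return _mean(channel, masks.nucleus, background) / cyto


def ab_ratio(
    channel: np.ndarray, masks: CompartmentMasks, background: float = 0.0
) -> float:
    """Apical / basolateral shell mean-intensity ratio for one cell.

    NaN for fully internal cells (no exposed surface, hence no apical
    shell) and for isolated cells with no contacts.
    """
    if masks.apical.size == 0 or masks.basolateral.size == 0:
        return float("nan")
    baso = _mean(channel, masks.basolateral, background)
    if baso <= 0:
        return float("nan")
    return _mean(channel, masks.apical, background) / baso
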