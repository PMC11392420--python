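"""Disconnectome maps and voxelwise permutation inference.

A disconnectome map estimates, per voxel, the probability that a lesion
disconnects the white matter passing there.  Tractography is emulated by
intersection against precomputed control streamline sets: for each control,
the *visitation map* marks every voxel traversed by a streamline of that
control that also passes through the lesion.  The N binarised visitation
maps are summed and scaled to 0-100%, so map values are exact multiples of
100/N.

Group differences (impaired > unimpaired) are tested with a voxelwise
linear model (grey-matter lesion volume as covariate), enhanced with
threshold-free cluster enhancement (TFCE: E = 0.5, H = 2, 6-connectivity,
100 integration steps with dh = max(t)/100), and corrected for family-wise
error with the permutation distribution of the image-wide maximum TFCE
statistic under Freedman-Lane residual permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .volumes import StreamlineSet, VolumeGrid, rasterize_streamline, require_compatible

__all__ = [
    "visitation_map",
    "disconnectome_map",
    "DisconnectomeBuilder",
    "tfce",
    "group_difference_tfce",
    "TfceGroupResult",
]

_STRUCTURE_6 = ndi.generate_binary_structure(3, 1)


class DisconnectomeBuilder:
    """Precomputes streamline rasterisations for fast per-lesion maps.

    Rasterising the control bundles is the dominant cost and does not depend
    on the lesion, so it is done once per (controls, grid) pair; each lesion
    then only needs set-membership tests.
    """

    def __init__(self, controls: Sequence[StreamlineSet], grid: VolumeGrid):
        if len(controls) < 2:
            raise ValueError("disconnectome maps need at least 2 controls")
        self.grid = grid
        self.controls = list(controls)
        self._flat: list[tuple[np.ndarray, np.ndarray, int]] = []
        shape = grid.shape
        for control in self.controls:
            vox_idx: list[np.ndarray] = []
            line_ids: list[np.ndarray] = []
            for j, line in enumerate(control.streamlines):
                vox = rasterize_streamline(line, grid)
                if not vox:
                    continue
                arr = np.array(sorted(vox), dtype=np.intp)
                flat = np.ravel_multi_index((arr[:, 0], arr[:, 1], arr[:, 2]), shape)
                vox_idx.append(flat)
                line_ids.append(np.full(len(flat), j, dtype=np.intp))
            if vox_idx:
                self._flat.append(
                    (
                        np.concatenate(vox_idx),
                        np.concatenate(line_ids),
                        len(control.streamlines),
                    )
                )
            else:
                self._flat.append(
                    (np.empty(0, np.intp), np.empty(0, np.intp), len(control.streamlines))
                )

    def visitation(self, lesion: VolumeGrid, control_index: int) -> VolumeGrid:
        """Binary map of voxels on this control's lesion-intersecting lines."""
        require_compatible(lesion, self.grid)
        lesion_flat = lesion.as_mask().ravel()
        vox, lines, n_lines = self._flat[control_index]
        out = np.zeros(self.grid.shape, dtype=np.uint8).ravel()
        if len(vox):
            hit = np.zeros(n_lines, dtype=bool)
            hit[lines[lesion_flat[vox]]] = True
            sel = hit[lines]
            out[vox[sel]] = 1
        return self.grid.like(out.reshape(self.grid.shape))

    def map(self, lesion: VolumeGrid) -> VolumeGrid:
        """Disconnection probability map, % of controls (multiples of 100/N)."""
        require_compatible(lesion, self.grid)
        lesion_flat = lesion.as_mask().ravel()
        count = np.zeros(np.prod(self.grid.shape), dtype=np.int32)
        for vox, lines, n_lines in self._flat:
            if not len(vox):
                continue
            hit = np.zeros(n_lines, dtype=bool)
            hit[lines[lesion_flat[vox]]] = True
            sel = hit[lines]
            visited = np.zeros_like(count, dtype=bool)
            visited[vox[sel]] = True
            count += visited
        values = 100.0 * count.reshape(self.grid.shape) / len(self.controls)
        return self.grid.like(values)


def visitation_map(
    lesion: VolumeGrid, control: StreamlineSet, grid: VolumeGrid
) -> VolumeGrid:
    """Voxels traversed by this control's streamlines that cross the lesion."""
    require_compatible(lesion, grid)
    lesion_mask = lesion.as_mask()
    out = np.zeros(grid.shape, dtype=np.uint8)
    for line in control.streamlines:
        vox = rasterize_streamline(line, grid)
        if any(lesion_mask[v] for v in vox):
            for v in vox:
                out[v] = 1
    return grid.like(out)


def disconnectome_map(
    lesion: VolumeGrid, controls: Sequence[StreamlineSet], grid: VolumeGrid
) -> VolumeGrid:
    """Per-voxel disconnection probability: 100 x (controls visiting) / N."""
    return DisconnectomeBuilder(controls, grid).map(lesion)


# ---------------------------------------------------------------------------
# TFCE


def tfce(
    stat: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive-tail) statistic map.

    ``TFCE(v) = sum_h extent(v, h)^E * h^H * dh`` over midpoint thresholds
    ``h = (k - 0.5) * dh``, ``k = 1..n_steps``, ``dh = max(stat)/n_steps``
    unless given.  Clusters use 6-connectivity.  Non-positive maps return
    zeros (the one-sided contrast carries no signal).
    """
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    peak = float(stat.max(initial=0.0))
    if peak <= 0:
        return out
    if dh is None:
        dh = peak / n_steps
    steps = int(np.ceil(peak / dh - 0.5 + 1e-9)) if dh > 0 else 0
    for k in range(1, steps + 1):
        h = (k - 0.5) * dh
        sup = stat >= h
        lab, nlab = ndi.label(sup, structure=_STRUCTURE_6)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        out += (sizes[lab] ** E) * (h**H) * dh
    return out


# ---------------------------------------------------------------------------
# Permutation GLM


@dataclass
class TfceGroupResult:
    """Voxelwise group contrast with TFCE + max-statistic FWE correction."""

    t_map: VolumeGrid
    tfce_map: VolumeGrid
    p_fwe: VolumeGrid  # corrected p, 1.0 outside the analysis mask
    sig_mask_05: VolumeGrid
    sig_mask_001: VolumeGrid
    analysis_mask: VolumeGrid
    max_null: np.ndarray  # permutation distribution of the max TFCE
    n_perm: int


def _t_for_first_column(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """One-sided t for the first design column, vectorised over map columns."""
    n, p = D.shape
    gram_inv = np.linalg.inv(D.T @ D)
    M = gram_inv @ D.T
    beta = M @ Y
    resid = Y - D @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * gram_inv[0, 0], 1e-300))
    return beta[0] / se


def group_difference_tfce(
    maps: Sequence[VolumeGrid],
    impaired: Sequence[bool],
    covariate: Sequence[float] | None = None,
    n_perm: int = 4000,
    seed: int | None = None,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    permute: str = "freedman-lane",
) -> TfceGroupResult:
    """Voxelwise impaired > unimpaired contrast on disconnectome maps.

    Per voxel a linear model ``value ~ group + covariate`` is fitted; the
    one-sided group t-map is TFCE-enhanced, and family-wise corrected
    p-values come from the permutation distribution of the image-wide
    maximum TFCE under Freedman-Lane residual permutation (add-one rule, so
    p in {1/(n_perm+1), ..., 1}).  ``permute="labels"`` swaps in plain
    group-label permutation (for the no-covariate case).

    Voxels that are constant across participants carry no information and
    are excluded from the analysis mask (p = 1 there).
    """
    impaired = np.asarray(impaired, dtype=bool)
    n = len(impaired)
    if len(maps) != n:
        raise ValueError("one map per participant required")
    if impaired.all() or not impaired.any():
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for FWE control", stacklevel=2)
    require_compatible(*maps)
    grid = maps[0]
    rng = np.random.default_rng(seed)

    data = np.stack([np.asarray(m.values, dtype=float) for m in maps])  # (n, X, Y, Z)
    mask3d = data.std(axis=0) > 0
    if not mask3d.any():
        raise ValueError("all voxels are constant across participants")
    # crop to the informative bounding box: TFCE cost scales with array size
    bbox = tuple(
        slice(idx.min(), idx.max() + 1) for idx in np.nonzero(mask3d)
    )
    cmask = mask3d[bbox]
    Y = data[(slice(None),) + bbox].reshape(n, -1)[:, cmask.ravel()]

    g = impaired.astype(float)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (n,):
            raise ValueError("covariate must have one value per participant")
        if np.ptp(cov) == 0:
            raise ValueError("constant covariate makes the design singular")
        Z = np.column_stack([np.ones(n), cov])
    else:
        Z = np.ones((n, 1))
    D = np.column_stack([g, Z])
    df = n - D.shape[1]
    if df < 2:
        raise ValueError("not enough participants for the model")

    def tfce_of(tvals: np.ndarray) -> np.ndarray:
        field = np.zeros(cmask.shape)
        field[cmask] = tvals
        return tfce(field, E=E, H=H, n_steps=n_steps)

    t_obs = _t_for_first_column(D, Y)
    tfce_obs = tfce_of(t_obs)

    if permute == "freedman-lane":
        Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        fitted = Hz @ Y
        resid = Y - fitted
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            t_b = _t_for_first_column(D, fitted + resid[perm])
            max_null[b] = tfce_of(t_b).max()
    elif permute == "labels":
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            Db = np.column_stack([g[perm], Z])
            t_b = _t_for_first_column(Db, Y)
            max_null[b] = tfce_of(t_b).max()
    else:
        raise ValueError(f"unknown permutation scheme {permute!r}")

    sorted_null = np.sort(max_null)
    exceed = len(sorted_null) - np.searchsorted(
        sorted_null, tfce_obs[cmask], side="left"
    )
    p_in_mask = (1.0 + exceed) / (n_perm + 1.0)

    def expand(values_in_mask, fill, dtype=float):
        full = np.full(grid.shape, fill, dtype=dtype)
        box = np.full(cmask.shape, fill, dtype=dtype)
        box[cmask] = values_in_mask
        full[bbox] = box
        return grid.like(full)

    p_map = expand(p_in_mask, 1.0)
    return TfceGroupResult(
        t_map=expand(t_obs, 0.0),
        tfce_map=expand(tfce_obs[cmask], 0.0),
        p_fwe=p_map,
        sig_mask_05=grid.like((p_map.values < 0.05).astype(np.uint8)),
        sig_mask_001=grid.like((p_map.values < 0.001).astype(np.uint8)),
        analysis_mask=grid.like(mask3d.astype(np.uint8)),
        max_null=max_null,
        n_perm=n_perm,
    )
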