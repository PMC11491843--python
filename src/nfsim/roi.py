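"""Automated target-region selection on a contrast t-map.

Within an anatomical pre-mask (in practice a box around the expected
supplementary-motor-area location), the selector grows a single
26-connected cluster of the most significant voxels: it seeds at the
pre-mask voxel with maximal t and repeatedly adds the neighbouring
pre-mask voxel with the highest t whose inclusion keeps the cluster
within the slice-span budget, stopping at the requested size (30 voxels,
at most six contiguous slices, by default).

The growth rule is greedy and deterministic; ties on t are broken by the
lowest linearised (z, y, x) index so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ROIMask", "ROISelectionError", "select_target_region", "neighbors_26"]


class ROISelectionError(RuntimeError):
    """Raised when cluster growth stalls before reaching the target size."""

    def __init__(self, achieved: int, requested: int):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"cluster growth stalled at {achieved} voxels "
            f"(requested {requested}): no admissible 26-neighbour left"
        )


@dataclass
class ROIMask:
    """Selected target region: voxel coordinates plus audit fields."""

    voxels: np.ndarray  # (n, 3) int array of (x, y, z)
    grid_dims: tuple[int, int, int]
    contrast: str = ""
    seed_voxel: tuple[int, int, int] | None = None
    t_min: float = float("nan")
    t_max: float = float("nan")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def slice_span(self) -> int:
        """Number of slices covered: max z - min z + 1."""
        z = self.voxels[:, 2]
        return int(z.max() - z.min() + 1)

    def to_array(self) -> np.ndarray:
        mask = np.zeros(self.grid_dims, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask

    def save(self, path: str | Path, voxel_size_mm: float = 1.0) -> None:
        import nibabel as nib

        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(
            nib.Nifti1Image(self.to_array().astype(np.uint8), affine), str(path)
        )

    def report(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "slice_span": self.slice_span,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "seed_voxel": list(self.seed_voxel) if self.seed_voxel else None,
            "contrast": self.contrast,
        }

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=1))


def neighbors_26(voxel: tuple[int, int, int], dims) -> list[tuple[int, int, int]]:
    """All in-grid voxels sharing a face, edge or corner with ``voxel``."""
    x, y, z = voxel
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < dims[0] and 0 <= ny < dims[1] and 0 <= nz < dims[2]:
                    out.append((nx, ny, nz))
    return out


def _tie_key(t: float, voxel: tuple[int, int, int], dims) -> tuple[float, int]:
    x, y, z = voxel
    return (-t, (z * dims[1] + y) * dims[0] + x)


def select_target_region(
    tmap: np.ndarray,
    premask: np.ndarray,
    n_target: int = 30,
    connectivity: int = 26,
    max_slices: int = 6,
    *,
    contrast: str = "",
) -> ROIMask:
    """Grow the target cluster greedily from the pre-mask t-maximum.

    Parameters
    ----------
    tmap
        3D t-statistic array; must be finite on the pre-mask.
    premask
        Boolean 3D array of anatomically admissible voxels.
    n_target
        Cluster size to reach (default 30 voxels).
    connectivity
        Only the 26-neighbour criterion is supported.
    max_slices
        Maximum z-extent of the cluster, as contiguous slices
        (max z - min z + 1 <= max_slices).

    Raises
    ------
    ROISelectionError
        If no admissible neighbour remains before ``n_target`` is reached.
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is implemented")
    if n_target < 1:
        raise ValueError("n_target must be positive")
    if max_slices < 1:
        raise ValueError("max_slices must be positive")
    tmap = np.asarray(tmap, dtype=float)
    premask = np.asarray(premask, dtype=bool)
    if tmap.shape != premask.shape:
        raise ValueError("tmap and premask shapes differ")
    if not premask.any():
        raise ValueError("empty pre-mask")
    if not np.isfinite(tmap[premask]).all():
        raise ValueError("t-map must be finite on the pre-mask")
    dims = tmap.shape

    coords = np.argwhere(premask)
    ts = tmap[premask]
    best = min(
        (tuple(int(c) for c in coords[i]) for i in range(len(coords))),
        key=lambda v: _tie_key(tmap[v], v, dims),
    )
    del ts

    selected: list[tuple[int, int, int]] = [best]
    selected_set = {best}
    z_min = z_max = best[2]
    frontier: set[tuple[int, int, int]] = {
        v for v in neighbors_26(best, dims) if premask[v]
    }
    while len(selected) < n_target:
        admissible = [
            v
            for v in frontier
            if max(z_max, v[2]) - min(z_min, v[2]) + 1 <= max_slices
        ]
        if not admissible:
            raise ROISelectionError(len(selected), n_target)
        nxt = min(admissible, key=lambda v: _tie_key(tmap[v], v, dims))
        frontier.discard(nxt)
        selected.append(nxt)
        selected_set.add(nxt)
        z_min, z_max = min(z_min, nxt[2]), max(z_max, nxt[2])
        for v in neighbors_26(nxt, dims):
            if premask[v] and v not in selected_set:
                frontier.add(v)
        frontier -= selected_set

    arr = np.array(selected, dtype=int)
    tvals = tmap[tuple(arr.T)]
    return ROIMask(
        voxels=arr,
        grid_dims=dims,
        contrast=contrast,
        seed_voxel=best,
        t_min=float(tvals.min()),
        t_max=float(tvals.max()),
    )
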