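"""In-memory container for a segmented embryo."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np


@dataclass
class LabelledEmbryo:
    """Co-registered label and intensity volumes for one embryo.

    All volumes share the same (z, y, x) shape; ``voxel_spacing`` gives the
    physical step per axis in µm. ``cell_labels`` uses 0 for background and
    positive integers for blastomeres; ``nucleus_labels`` uses the id of the
    owning cell, so nucleus ids are a subset of cell ids by construction.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    voxel_spacing: Tuple[float, float, float]
    channels: Dict[str, np.ndarray] = field(default_factory=dict)
    embryo_id: str = "embryo"

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        shape = self.cell_labels.shape
        if self.cell_labels.ndim != 3:
            raise ValueError("cell_labels must be a 3-D (z, y, x) volume")
        if self.nucleus_labels.shape != shape:
            raise ValueError("nucleus_labels shape differs from cell_labels")
        for name, vol in self.channels.items():
            if np.asarray(vol).shape != shape:
                raise ValueError(f"channel {name!r} shape differs from cell_labels")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive lengths (z, y, x)")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        nuc_ids = set(np.unique(self.nucleus_labels[self.nucleus_labels > 0]).tolist())
        cell_ids = set(np.unique(self.cell_labels[self.cell_labels > 0]).tolist())
        if not nuc_ids <= cell_ids:
            raise ValueError(f"nucleus ids {sorted(nuc_ids - cell_ids)} have no matching cell")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.cell_labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"embryo {self.embryo_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None
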