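"""End-to-end quantification: embryo volumes -> per-blastomere record table.

One record row per cell carries the full descriptor panel: volume, surface
areas and domain proportions, sphericity/oblateness/prolateness, the A/J
ratio, the N/C YAP ratio and (when a pERM channel is present) the A/B pERM
ratio, plus annotation fields (manual TE/ICM label, dividing flag,
compaction class).
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DomainParams
from .embryo import LabelledEmbryo
from . import geometry, intensity

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "embryo_id",
    "cell_id",
    "stage",
    "volume",
    "total_area",
    "exposed_area",
    "junctional_area",
    "contact_area",
    "prop_exposed",
    "prop_junctional",
    "prop_contact",
    "sphericity",
    "oblateness",
    "prolateness",
    "aj_ratio",
    "nc_yap",
    "ab_perm",
    "manual_label",
    "dividing",
    "compaction_class",
    "qc_flags",
]


def quantify_embryo(
    embryo: LabelledEmbryo,
    domain_params: DomainParams = DomainParams(),
    shell_thickness: float = intensity.DEFAULT_SHELL_THICKNESS,
    yap_channel: str = "yap",
    perm_channel: Optional[str] = "perm",
    stage: Optional[int] = None,
    background: float = 0.0,
) -> pd.DataFrame:
    """Quantify every cell of one embryo.

    Runs surface extraction, domain classification, shape and position
    descriptors and compartment intensity ratios; returns one row per cell.
    ``stage`` defaults to the number of cells in the embryo. Cells flagged
    by QC (empty nucleus, no exposed surface, degenerate moments) keep their
    row with NaN ratios and a ``qc_flags`` note.
    """
    surfaces = geometry.extract_surfaces(embryo)
    domains = geometry.classify_domains(surfaces, embryo, domain_params)
    n_cells = len(embryo.cell_ids)
    stage = stage if stage is not None else n_cells
    has_perm = perm_channel is not None and perm_channel in embryo.channels
    yap = embryo.channel(yap_channel) if yap_channel in embryo.channels else None

    rows = []
    for cid, cell in domains:
        flags = []
        mask = embryo.cell_labels == cid
        shape = geometry.shape_descriptors(mask, embryo.voxel_spacing, cell.total_area)
        if shape.pop("degenerate"):
            flags.append("degenerate_moments")
        pos = geometry.position_descriptors(cell)
        row = {"embryo_id": embryo.embryo_id, "cell_id": cid, "stage": stage}
        row.update(shape)
        row.update(pos)
        nc = ab = float("nan")
        if yap is not None:
            masks = intensity.compartment_masks(
                embryo, cid, shell_thickness, domain_params.contact_distance
            )
            nc = intensity.nc_ratio(yap, masks, background)
            if masks.nucleus.size == 0 or not np.isfinite(nc):
                flags.append("empty_or_invalid_nucleus")
            if has_perm:
                ab = intensity.ab_ratio(embryo.channel(perm_channel), masks, background)
                if not np.isfinite(ab):
                    flags.append("no_apical_or_basal_shell")
        row["nc_yap"] = nc
        row["ab_perm"] = ab
        row["manual_label"] = "none"
        row["dividing"] = False
        row["compaction_class"] = "none"
        row["qc_flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def build_records(
    embryo_records: Iterable[pd.DataFrame],
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Pool per-embryo records and apply the per-cell annotation table.

    ``annotations`` rows are keyed by (embryo_id, cell_id) and may carry
    ``manual_label`` (TE/ICM/none), ``dividing`` and ``compaction_class``
    columns. Dividing cells are dropped (their geometry is not comparable
    and their nuclear envelope is disassembled); the number removed is
    logged. Annotations referencing unknown cells raise with the offending
    keys listed.
    """
    table = pd.concat(list(embryo_records), ignore_index=True)
    if annotations is not None and len(annotations):
        ann = annotations.copy()
        required = {"embryo_id", "cell_id"}
        if not required <= set(ann.columns):
            raise ValueError(f"annotations must have columns {sorted(required)}")
        keys = set(map(tuple, table[["embryo_id", "cell_id"]].itertuples(index=False)))
        offenders = [
            t for t in map(tuple, ann[["embryo_id", "cell_id"]].itertuples(index=False))
            if t not in keys
        ]
        if offenders:
            raise ValueError(f"annotations reference unknown cells: {offenders}")
        for col in ("manual_label", "dividing", "compaction_class"):
            if col in ann.columns:
                merged = table.merge(
                    ann[["embryo_id", "cell_id", col]],
                    on=["embryo_id", "cell_id"],
                    how="left",
                    suffixes=("", "_ann"),
                )
                update = merged[f"{col}_ann"].notna()
                table.loc[update, col] = merged.loc[update, f"{col}_ann"]
    table["dividing"] = table["dividing"].astype(bool)
    n_dividing = int(table["dividing"].sum())
    if n_dividing:
        log.info("excluding %d dividing cell(s) from the record table", n_dividing)
    return table[~table["dividing"]].reset_index(drop=True)


def quantify_cohort(
    embryos: Sequence[LabelledEmbryo],
    domain_params: DomainParams = DomainParams(),
    annotations: Optional[pd.DataFrame] = None,
    **kwargs,
) -> pd.DataFrame:
    """Quantify a list of embryos and pool the records."""
    frames = [quantify_embryo(e, domain_params, **kwargs) for e in embryos]
    return build_records(frames, annotations)
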