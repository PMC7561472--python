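"""File formats: TIFF / NRRD volumes, PLY meshes, record CSVs and config JSON.

Conventions (also echoed in every volume's sidecar JSON): arrays are
(z, y, x); multi-page TIFF pages are z-slices in increasing z; NRRD files
are raw-encoded little-endian with sizes in fast-to-slow (x, y, z) order,
which matches the C layout of a (z, y, x) array. Label volumes are written
as 16-bit unsigned integers, intensity channels as 16-bit after rounding.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .config import SyntheticConfig
from .embryo import LabelledEmbryo
from .geometry import DOMAIN_NAMES, CellDomains

log = logging.getLogger(__name__)

RECORD_SCHEMA_VERSION = 1
_SCHEMA_COMMENT = f"# blastomorph-records schema={RECORD_SCHEMA_VERSION}"

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------
def write_volume(
    path: PathLike,
    volume: np.ndarray,
    spacing: Tuple[float, float, float],
    sidecar: bool = True,
) -> None:
    """Write a (z, y, x) volume as multi-page TIFF or raw NRRD (by suffix)."""
    path = Path(path)
    vol = np.asarray(volume)
    if np.issubdtype(vol.dtype, np.floating):
        vol = np.clip(np.rint(vol), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif vol.dtype != np.uint16:
        vol = vol.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, vol)
    elif path.suffix.lower() == ".nrrd":
        _write_nrrd(path, vol, spacing)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r} (use .tif or .nrrd)")
    if sidecar:
        meta = {
            "axis_order": "zyx",
            "voxel_spacing_um": list(spacing),
            "shape": list(vol.shape),
            "dtype": str(vol.dtype),
            "tiff_page_axis": "z (increasing)",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_volume(path: PathLike) -> Tuple[np.ndarray, Optional[Tuple[float, float, float]]]:
    """Read a TIFF or NRRD volume; returns (array, spacing-or-None)."""
    path = Path(path)
    spacing = None
    if path.suffix.lower() in (".tif", ".tiff"):
        vol = tifffile.imread(path)
    elif path.suffix.lower() == ".nrrd":
        vol, spacing = _read_nrrd(path)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if spacing is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = tuple(meta["voxel_spacing_um"])
    return vol, spacing


def _write_nrrd(path: Path, vol: np.ndarray, spacing) -> None:
    """Minimal raw-encoded NRRD writer (header + little-endian buffer)."""
    type_name = {np.dtype(np.uint16): "uint16", np.dtype(np.float32): "float"}[vol.dtype]
    sz, sy, sx = spacing
    header = [
        "NRRD0004",
        "# produced by blastomorph",
        f"type: {type_name}",
        "dimension: 3",
        f"sizes: {vol.shape[2]} {vol.shape[1]} {vol.shape[0]}",
        "encoding: raw",
        "endian: little",
        "space dimension: 3",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode())
        fh.write(np.ascontiguousarray(vol).astype(vol.dtype.newbyteorder("<")).tobytes())


def _read_nrrd(path: Path) -> Tuple[np.ndarray, Optional[Tuple[float, float, float]]]:
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, body = raw.partition(b"\n\n")
    fields: Dict[str, str] = {}
    for line in head.decode().splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError(f"only raw-encoded NRRD supported, got {fields.get('encoding')!r}")
    dtype = {"uint16": np.uint16, "unsigned short": np.uint16, "float": np.float32}[
        fields["type"]
    ]
    sx, sy, sz = (int(s) for s in fields["sizes"].split())
    vol = np.frombuffer(body, dtype=np.dtype(dtype).newbyteorder("<")).reshape(sz, sy, sx)
    spacing = None
    if "space directions" in fields:
        vecs = [
            [float(x) for x in v.strip("()").split(",")]
            for v in fields["space directions"].split(") (")
        ]
        # directions are per fast-to-slow axis (x, y, z): diagonal entries
        spacing = (abs(vecs[2][2]), abs(vecs[1][1]), abs(vecs[0][0]))
    return vol.copy(), spacing


# ---------------------------------------------------------------------------
# embryo bundles
# ---------------------------------------------------------------------------
VOLUME_FILES = ("cell_labels", "nucleus_labels", "yap", "perm")


def write_embryo(
    outdir: PathLike,
    embryo: LabelledEmbryo,
    fmt: str = "tif",
    config: Optional[SyntheticConfig] = None,
    ground_truth: Optional[pd.DataFrame] = None,
) -> Path:
    """Write an embryo as a directory of volumes (+ optional truth/config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "cell_labels": embryo.cell_labels,
        "nucleus_labels": embryo.nucleus_labels,
        **embryo.channels,
    }
    for name, arr in arrays.items():
        write_volume(outdir / f"{name}.{fmt}", arr, embryo.voxel_spacing)
    if ground_truth is not None:
        ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    if config is not None:
        (outdir / "config.json").write_text(config.to_json(indent=2))
    return outdir


def read_embryo(indir: PathLike, fmt: str = "tif", embryo_id: Optional[str] = None) -> LabelledEmbryo:
    """Read an embryo bundle written by :func:`write_embryo`."""
    indir = Path(indir)
    vols = {}
    spacing = None
    for f in sorted(indir.glob(f"*.{fmt}")):
        vol, sp = read_volume(f)
        vols[f.stem] = vol
        spacing = spacing or sp
    if "cell_labels" not in vols or "nucleus_labels" not in vols:
        raise FileNotFoundError(f"{indir} lacks cell_labels/nucleus_labels volumes")
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
        log.warning("no voxel spacing found for %s; assuming 1 µm isotropic", indir)
    channels = {
        k: v.astype(np.float32)
        for k, v in vols.items()
        if k not in ("cell_labels", "nucleus_labels")
    }
    return LabelledEmbryo(
        cell_labels=vols["cell_labels"].astype(np.int32),
        nucleus_labels=vols["nucleus_labels"].astype(np.int32),
        channels=channels,
        voxel_spacing=spacing,
        embryo_id=embryo_id or indir.name,
    )


# ---------------------------------------------------------------------------
# record tables
# ---------------------------------------------------------------------------
def write_records(path: PathLike, records: pd.DataFrame) -> None:
    """Write the record table as CSV with a schema-version header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_SCHEMA_COMMENT + "\n")
        records.to_csv(fh, index=False)


def read_records(path: PathLike) -> pd.DataFrame:
    """Read a record CSV, checking the schema-version header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# blastomorph-records"):
            raise ValueError(f"{path} is not a blastomorph record CSV (missing schema header)")
        version = int(first.split("schema=")[1])
        if version != RECORD_SCHEMA_VERSION:
            raise ValueError(
                f"{path} has schema version {version}; this build reads "
                f"version {RECORD_SCHEMA_VERSION}"
            )
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------
def write_mesh_ply(path: PathLike, cell: CellDomains) -> None:
    """ASCII PLY of one cell surface with a per-face integer domain tag.

    Face property ``domain``: 0 = exposed, 1 = junctional, 2 = contact
    (names recorded in the header comment).
    """
    mesh = cell.mesh
    v = mesh.vertices
    f = mesh.faces
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment domain codes: {DOMAIN_NAMES}",
        f"element vertex {len(v)}",
        "property float z",
        "property float y",
        "property float x",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "property int domain",
        "end_header",
    ]
    for p in v:
        lines.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}")
    for tri, dom in zip(f, cell.face_domain):
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]} {int(dom)}")
    Path(path).write_text("\n".join(lines) + "\n")
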