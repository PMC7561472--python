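"""Synthetic preimplantation embryos with known ground truth.

The generator emulates the kind of data produced by confocal imaging of
2- to 64-cell embryos: co-registered cell and nucleus label volumes plus a
YAP channel whose nuclear/cytoplasmic ratio is a monotone function of each
cell's exposed-surface proportion, and a pERM channel enriched on the
apically exposed membrane.

Geometry model
--------------
Cell shapes come from a voxel-native packing model rather than a physics
simulation: seed points are packed inside the embryo envelope by iterated
repulsion, and each cell is the intersection of

* the envelope interior,
* the Voronoi region of its seed, and
* a ball of radius ``r_g`` around its seed.

``r_g`` interpolates with the compaction parameter gamma from "balls just
touching" (gamma = 0, loosely apposed blastomeres with point-like contacts)
to "envelope-filling" (gamma = 1, a packed partition with flat interfaces),
reproducing the morphology of compaction without simulating its dynamics.

Envelopes
---------
``sphere``
    Free embryo of radius ``reference_radius``.
``cylinder``
    Hydrogel channel. Soft gels stretch around blastomeres wider than the
    nominal bore, so the effective channel radius is
    ``max(envelope_radius, channel_dilation * cell_radius)`` and the length
    conserves embryo volume. The resulting deep axial overlap (cells
    stacked and flattened against each other like a roll of coins) is what
    lowers the exposed-surface proportion under cylindrical confinement;
    confinement pressure also forces near-complete compaction.
``slab``
    Planar confinement under a hydrogel sheet: a single cell layer of
    half-thickness ``0.8 * cell_radius`` (or ``envelope_radius`` when
    given), lateral extent conserving embryo volume.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import SyntheticConfig
from .embryo import LabelledEmbryo
from .geometry import MIN_CELL_VOXELS, voxel_face_domains
from .intensity import membrane_shells

log = logging.getLogger(__name__)

VALID_STAGES = (2, 4, 8, 16, 32, 64)

#: Intensity model constants (arbitrary units; ratios are what matter).
CYTOPLASM_LEVEL = 100.0
PERM_MEMBRANE_LEVEL = 100.0
PERM_CYTOPLASM_LEVEL = 50.0
PERM_NUCLEUS_LEVEL = 30.0
#: Apical pERM enrichment slope: apical/basolateral = 1 + k * perm_polarity.
PERM_ENRICHMENT_K = 3.0
#: Ground-truth proximity gap (µm) matching DomainParams.contact_distance.
TRUTH_CONTACT_DISTANCE = 1.0
#: Confinement pressure in the channel forces compaction at least this high.
CYLINDER_MIN_COMPACTION = 0.9


class PackingError(ValueError):
    """Raised when the requested cells cannot be packed into the envelope."""


# ---------------------------------------------------------------------------
# seed packing
# ---------------------------------------------------------------------------
def _pack_seeds(rng, n, sample, inside, iters=80, step=0.25):
    """Deterministic repulsion-based packing of n points in a region."""
    pts = np.array([sample(rng) for _ in range(n)], dtype=float)
    if n == 1:
        return pts
    for _ in range(iters):
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        target = 2.0 * (np.median(nn) + 1e-6)
        overlap = np.where(np.isfinite(dist), np.clip(target - dist, 0.0, None), 0.0)
        push = (diff * (overlap / (dist + 1e-9))[..., None]).sum(axis=1)
        pts = pts + step * push
        for i in range(n):
            if not inside(pts[i]):
                pts[i] = _pull_inside(pts[i], inside, sample, rng)
    return pts


def _pull_inside(p, inside, sample, rng, shrink=0.95, steps=60):
    q = p.copy()
    for _ in range(steps):
        q = q * shrink
        if inside(q):
            return q
    return sample(rng)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------
def _envelope(config: SyntheticConfig):
    """Envelope predicate, seed-domain sampler and bounding half-extents."""
    r_cell = config.cell_radius
    V = config.embryo_volume
    margin = 2.0
    if config.envelope == "sphere":
        R = config.envelope_radius or config.reference_radius
        core = 0.75 * R

        def env(Z, Y, X):
            return Z**2 + Y**2 + X**2 <= R**2

        def inside(p):
            return float(p @ p) < core**2

        def sample(rng):
            return rng.uniform(-0.7 * R, 0.7 * R, 3)

        half = np.array([R + margin] * 3)
        meta = {"radius": R}
    elif config.envelope == "cylinder":
        r_nom = config.envelope_radius or 12.5
        r_eff = max(r_nom, config.channel_dilation * r_cell)
        L = V / (np.pi * r_eff**2)
        r_seed = max(r_eff - 0.8 * r_cell, 0.05 * r_eff)
        half_l = 0.95 * L / 2.0

        def env(Z, Y, X):
            return (Y**2 + X**2 <= r_eff**2) & (np.abs(Z) <= L / 2.0)

        def inside(p):
            return (p[1] ** 2 + p[2] ** 2 < r_seed**2) and abs(p[0]) < half_l

        def sample(rng):
            return np.array(
                [
                    rng.uniform(-0.9 * L / 2.0, 0.9 * L / 2.0),
                    rng.uniform(-r_seed, r_seed),
                    rng.uniform(-r_seed, r_seed),
                ]
            )

        half = np.array([L / 2.0 + margin, r_eff + margin, r_eff + margin])
        meta = {"radius": r_eff, "nominal_radius": r_nom, "length": L}
    elif config.envelope == "slab":
        h = config.envelope_radius or 0.8 * r_cell
        Rd = np.sqrt(V / (2.0 * h * np.pi))

        def env(Z, Y, X):
            return (np.abs(Z) <= h) & (Y**2 + X**2 <= Rd**2)

        def inside(p):
            return abs(p[0]) < 0.3 * h and p[1] ** 2 + p[2] ** 2 < (0.85 * Rd) ** 2

        def sample(rng):
            return np.array(
                [
                    rng.uniform(-0.2 * h, 0.2 * h),
                    rng.uniform(-0.8 * Rd, 0.8 * Rd),
                    rng.uniform(-0.8 * Rd, 0.8 * Rd),
                ]
            )

        half = np.array([h + margin, Rd + margin, Rd + margin])
        meta = {"half_thickness": h, "disk_radius": Rd}
    else:  # pragma: no cover - guarded by SyntheticConfig
        raise ValueError(config.envelope)
    return env, inside, sample, half, meta


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def generate_embryo(
    config: SyntheticConfig, embryo_id: Optional[str] = None
) -> Tuple[LabelledEmbryo, pd.DataFrame]:
    """Generate one synthetic embryo and its ground-truth table.

    Returns the embryo (cell labels, nucleus labels, ``yap`` and ``perm``
    channels) and a DataFrame with one row per cell: seed position, true
    exposed-surface proportion (voxel-face oracle on the generated labels),
    the expected N/C YAP ratio ``coupling(p)``, the expected A/B pERM
    enrichment and the stage label. Fully reproducible from the config.
    """
    spacing = np.asarray(config.voxel_spacing, float)
    if config.cell_radius < 2.0 * spacing.max():
        raise PackingError(
            f"cells of radius {config.cell_radius:.2f} µm are unresolvable at "
            f"voxel spacing {tuple(spacing)} µm: n_cells={config.n_cells} is too "
            f"large for an embryo of reference radius {config.reference_radius} µm"
        )
    rng = np.random.default_rng(config.seed)
    env_fn, inside, sample, half, meta = _envelope(config)
    gamma = config.effective_compaction
    if config.envelope == "cylinder":
        gamma = max(gamma, CYLINDER_MIN_COMPACTION)

    seeds = _pack_seeds(rng, config.n_cells, sample, inside)

    axes = [np.arange(-np.ceil(h / s), np.ceil(h / s) + 1) * s for h, s in zip(half, spacing)]
    shape = tuple(len(a) for a in axes)
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    env_mask = env_fn(Z, Y, X)
    pts = np.c_[Z[env_mask], Y[env_mask], X[env_mask]]
    dist, idx = cKDTree(seeds).query(pts)

    if config.n_cells > 1:
        nn = cKDTree(seeds).query(seeds, k=2)[0][:, 1]
        r_touch = 0.55 * float(np.median(nn))
    else:
        r_touch = 0.0
    r_fill = float(dist.max()) * 1.001
    r_g = r_fill if gamma >= 1.0 else r_touch + gamma**2 * (max(r_fill, r_touch) - r_touch)

    labels = np.zeros(shape, dtype=np.int16)
    keep = dist <= r_g
    flat = np.flatnonzero(env_mask.ravel())
    labels.ravel()[flat[keep]] = idx[keep].astype(np.int16) + 1

    counts = np.bincount(labels.ravel(), minlength=config.n_cells + 1)[1:]
    if (counts < MIN_CELL_VOXELS).any():
        bad = np.flatnonzero(counts < MIN_CELL_VOXELS) + 1
        raise PackingError(
            f"packing infeasible: cells {bad.tolist()} have fewer than "
            f"{MIN_CELL_VOXELS} voxels (n_cells={config.n_cells}, "
            f"envelope={config.envelope!r}, spacing={tuple(spacing)})"
        )

    nuclei = _place_nuclei(labels, spacing, config)

    truth = voxel_face_domains(labels, spacing, contact_distance=TRUTH_CONTACT_DISTANCE)
    p_true = truth["prop_exposed"].to_numpy()
    # immature stages sense only a fraction of their exposure signal
    nc_expected = np.asarray(config.coupling(config.maturity * p_true), dtype=float)
    cell_factor = (
        np.exp(rng.normal(0.0, config.noise_sd, config.n_cells))
        if config.noise_sd > 0
        else np.ones(config.n_cells)
    )

    yap = np.zeros(shape, dtype=np.float32)
    yap[labels > 0] = CYTOPLASM_LEVEL
    for i, cid in enumerate(range(1, config.n_cells + 1)):
        yap[nuclei == cid] = CYTOPLASM_LEVEL * nc_expected[i] * cell_factor[i]

    perm = np.zeros(shape, dtype=np.float32)
    perm[labels > 0] = PERM_CYTOPLASM_LEVEL
    apical_level = PERM_MEMBRANE_LEVEL * (1.0 + PERM_ENRICHMENT_K * config.perm_polarity)
    for cid in range(1, config.n_cells + 1):
        apical, baso = membrane_shells(
            labels, cid, spacing, thickness=1.0, contact_distance=TRUTH_CONTACT_DISTANCE
        )
        perm[baso] = PERM_MEMBRANE_LEVEL
        perm[apical] = apical_level
    perm[nuclei > 0] = PERM_NUCLEUS_LEVEL

    if config.noise_sd > 0:
        yap *= np.exp(rng.normal(0.0, config.noise_sd, shape)).astype(np.float32)
        perm *= np.exp(rng.normal(0.0, config.noise_sd, shape)).astype(np.float32)

    eid = embryo_id or f"synthetic_seed{config.seed}"
    embryo = LabelledEmbryo(
        cell_labels=labels,
        nucleus_labels=nuclei,
        channels={"yap": yap, "perm": perm},
        voxel_spacing=tuple(spacing),
        embryo_id=eid,
    )
    truth_df = pd.DataFrame(
        {
            "embryo_id": eid,
            "cell_id": np.arange(1, config.n_cells + 1),
            "stage": config.n_cells,
            "seed_z": seeds[:, 0],
            "seed_y": seeds[:, 1],
            "seed_x": seeds[:, 2],
            "true_prop_exposed": p_true,
            "true_nc_yap": nc_expected,
            "true_ab_perm": 1.0 + PERM_ENRICHMENT_K * config.perm_polarity,
            "dividing": False,
        }
    )
    return embryo, truth_df


def _place_nuclei(labels: np.ndarray, spacing: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """One spherical nucleus per cell, centred at the cell's inner-most voxel.

    The radius is ``nucleus_radius_fraction`` of the cell's volume-equivalent
    radius, capped at 90% of the maximal inscribed distance so the nucleus
    always lies strictly inside its cell.
    """
    nuclei = np.zeros_like(labels)
    voxvol = float(np.prod(spacing))
    for cid in range(1, config.n_cells + 1):
        mask = labels == cid
        obj = ndimage.find_objects(mask.astype(np.uint8))[0]
        sub = mask[obj]
        inner = ndimage.distance_transform_edt(sub, sampling=spacing)
        centre = np.unravel_index(int(np.argmax(inner)), sub.shape)
        r_eq = (3.0 * sub.sum() * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_nuc = min(config.nucleus_radius_fraction * r_eq, 0.9 * float(inner.max()))
        r_nuc = max(r_nuc, 0.51 * float(spacing.min()))
        zz, yy, xx = np.indices(sub.shape)
        d2 = (
            ((zz - centre[0]) * spacing[0]) ** 2
            + ((yy - centre[1]) * spacing[1]) ** 2
            + ((xx - centre[2]) * spacing[2]) ** 2
        )
        nuc = sub & (d2 <= r_nuc**2)
        nuclei[obj][nuc] = cid
    return nuclei


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------
def generate_cohort(
    stages: Sequence[int],
    per_stage_n: Union[int, Dict[int, int]],
    template: Optional[SyntheticConfig] = None,
) -> Tuple[List[LabelledEmbryo], pd.DataFrame]:
    """Generate replicate embryos per stage and pool their ground truth.

    ``stages`` must be drawn from {2, 4, 8, 16, 32, 64}; the stage label is
    the literal cell count (dividing cells are not simulated). Per-embryo
    seeds are spawned deterministically from the template seed, so distinct
    replicates differ while the whole cohort is reproducible.
    """
    stages = list(dict.fromkeys(stages))  # dedupe, keep order
    if not stages:
        raise ValueError("stage list must not be empty")
    bad = sorted(set(stages) - set(VALID_STAGES))
    if bad:
        raise ValueError(f"invalid stages {bad}; valid stages are {VALID_STAGES}")
    template = template or SyntheticConfig()
    if isinstance(per_stage_n, int):
        per_stage = {s: per_stage_n for s in stages}
    else:
        per_stage = dict(per_stage_n)

    n_embryos = sum(per_stage[s] for s in stages)
    children = np.random.SeedSequence(template.seed).spawn(n_embryos)
    child_seeds = [int(c.generate_state(1)[0] % np.uint32(2**31)) for c in children]

    embryos: List[LabelledEmbryo] = []
    tables = []
    k = 0
    for stage in stages:
        for rep in range(per_stage[stage]):
            cfg = template.replace(n_cells=stage, seed=child_seeds[k])
            eid = f"stage{stage:02d}_rep{rep:02d}"
            emb, truth = generate_embryo(cfg, embryo_id=eid)
            embryos.append(emb)
            tables.append(truth)
            k += 1
    pooled = pd.concat(tables, ignore_index=True)
    return embryos, pooled
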