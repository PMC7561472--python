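"""Configuration objects shared across the pipeline.

All parameters are in physical units: lengths in micrometres (µm), areas in
µm², volumes in µm³. Volumes are indexed (z, y, x) and ``voxel_spacing``
follows the same order.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

ENVELOPES = ("sphere", "cylinder", "slab")

#: Default compaction per cleavage stage. Compaction is essentially complete
#: by the 16-cell stage; 2- and 4-cell blastomeres are loosely apposed balls.
STAGE_COMPACTION = {2: 0.25, 4: 0.35, 8: 0.6, 16: 0.85, 32: 1.0, 64: 1.0}

#: Stage-dependent maturity of position sensing: the fraction of a cell's
#: exposed-surface signal that actually reaches the YAP coupling. Position
#: sensing emerges during compaction (8-cell stage) and is complete from the
#: 16-cell stage, so early blastomeres show intermediate N/C YAP despite
#: their large exposed surface.
DEVELOPMENTAL_MATURITY = {2: 0.2, 4: 0.25, 8: 0.5, 16: 1.0, 32: 1.0, 64: 1.0}


@dataclass(frozen=True)
class AffineCoupling:
    """Monotone map from exposed-surface proportion p to expected N/C YAP ratio.

    ``ratio(p) = base + slope * p``. With the defaults, a fully internal cell
    (p=0) sits at N/C = 1 (YAP evenly distributed) and a fully exposed cell at
    N/C = 2, bracketing the empirical high/low split around ~1.6.
    """

    base: float = 1.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.base <= 0:
            raise ValueError("coupling base must be > 0")
        if self.slope < 0:
            raise ValueError("coupling must be non-decreasing in p (slope >= 0)")

    def __call__(self, p):
        return self.base + self.slope * p

    def to_dict(self) -> dict:
        return {"kind": "affine", "base": self.base, "slope": self.slope}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineCoupling":
        if d.get("kind", "affine") != "affine":
            raise ValueError(f"unknown coupling kind {d.get('kind')!r}")
        return cls(base=float(d["base"]), slope=float(d["slope"]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic embryo.

    Parameters
    ----------
    n_cells:
        Number of blastomeres (1-64 supported; stages are 2, 4, ..., 64).
    envelope:
        Embryo outline: free ``sphere``, ``cylinder`` (hydrogel channel) or
        ``slab`` (planar confinement under a hydrogel sheet).
    envelope_radius:
        Sphere radius / nominal channel radius / slab half-thickness, µm.
        ``None`` selects the envelope-specific default: the reference radius
        for spheres, 12.5 µm (25 µm channel) for cylinders and 0.8x the
        nominal cell radius for slabs.
    reference_radius:
        Radius of the volume-equivalent unconfined embryo, µm. Cleavage
        conserves embryo volume, so this is stage independent.
    compaction:
        0 = loosely apposed balls, 1 = fully packed partition of the
        envelope. ``None`` picks the stage-appropriate default
        (:data:`STAGE_COMPACTION`).
    nucleus_radius_fraction:
        Nucleus radius as a fraction of the equivalent cell radius.
    coupling:
        Map from true exposed proportion to expected N/C YAP ratio.
    coupling_maturity:
        Optional stage -> maturity map in [0, 1] scaling the *sensed*
        exposure before it enters the coupling
        (``nc = coupling(maturity * p)``). ``None`` means fully mature at
        every stage; the string ``"developmental"`` selects
        :data:`DEVELOPMENTAL_MATURITY`, under which position sensing
        emerges at compaction.
    noise_sd:
        Sigma of the multiplicative log-normal intensity noise. The same
        sigma also jitters the per-cell nuclear YAP level, so realised N/C
        ratios scatter around the coupling curve the way per-cell biological
        variability would.
    perm_polarity:
        Apical pERM enrichment in [0, 1]; 0 emulates loss of apical pERM
        under ROCK inhibition. Apical/basolateral shell intensity ratio is
        ``1 + 3 * perm_polarity``.
    channel_dilation:
        Wall compliance of the hydrogel channel: the effective channel
        radius is ``max(envelope_radius, channel_dilation * cell_radius)``.
        Soft gels stretch around blastomeres larger than the nominal bore.
    voxel_spacing:
        (z, y, x) spacing in µm.
    seed:
        Integer seed; the generator is bit-reproducible given the config.
    """

    n_cells: int = 8
    envelope: str = "sphere"
    envelope_radius: Optional[float] = None
    reference_radius: float = 25.0
    compaction: Optional[float] = None
    nucleus_radius_fraction: float = 0.5
    coupling: AffineCoupling = field(default_factory=AffineCoupling)
    coupling_maturity: Union[None, str, Mapping[int, float]] = None
    noise_sd: float = 0.0
    perm_polarity: float = 0.8
    channel_dilation: float = 1.4
    voxel_spacing: Sequence[float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.envelope not in ENVELOPES:
            raise ValueError(f"envelope must be one of {ENVELOPES}, got {self.envelope!r}")
        if self.envelope_radius is not None and self.envelope_radius <= 0:
            raise ValueError("envelope_radius must be > 0")
        if self.reference_radius <= 0:
            raise ValueError("reference_radius must be > 0")
        if self.compaction is not None and not 0.0 <= self.compaction <= 1.0:
            raise ValueError("compaction must lie in [0, 1]")
        if not 0.0 < self.nucleus_radius_fraction < 0.9:
            raise ValueError("nucleus_radius_fraction must lie in (0, 0.9)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.coupling_maturity, str) and self.coupling_maturity != "developmental":
            raise ValueError(
                'coupling_maturity must be None, "developmental" or a stage->maturity map'
            )
        if not 0.0 <= self.perm_polarity <= 1.0:
            raise ValueError("perm_polarity must lie in [0, 1]")
        if self.channel_dilation < 1.0:
            raise ValueError("channel_dilation must be >= 1")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive lengths (z, y, x)")

    # -- derived quantities -------------------------------------------------
    @property
    def embryo_volume(self) -> float:
        """Total embryo volume in µm³ (stage independent)."""
        import math

        return 4.0 / 3.0 * math.pi * self.reference_radius**3

    @property
    def cell_radius(self) -> float:
        """Nominal (volume-equivalent) blastomere radius in µm."""
        return self.reference_radius / self.n_cells ** (1.0 / 3.0)

    @property
    def effective_compaction(self) -> float:
        if self.compaction is not None:
            return self.compaction
        return STAGE_COMPACTION.get(self.n_cells, 1.0)

    @property
    def maturity(self) -> float:
        """Fraction of the exposure signal sensed at this stage."""
        if self.coupling_maturity is None:
            return 1.0
        table = (
            DEVELOPMENTAL_MATURITY
            if self.coupling_maturity == "developmental"
            else self.coupling_maturity
        )
        return float(table.get(self.n_cells, 1.0))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling"] = self.coupling.to_dict()
        d["voxel_spacing"] = list(self.voxel_spacing)
        if isinstance(self.coupling_maturity, Mapping):
            d["coupling_maturity"] = {str(k): v for k, v in self.coupling_maturity.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "coupling" in d and isinstance(d["coupling"], dict):
            d["coupling"] = AffineCoupling.from_dict(d["coupling"])
        if "voxel_spacing" in d:
            d["voxel_spacing"] = tuple(d["voxel_spacing"])
        if isinstance(d.get("coupling_maturity"), dict):
            d["coupling_maturity"] = {int(k): float(v) for k, v in d["coupling_maturity"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "SyntheticConfig":
        return cls.from_dict(json.loads(s))

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DomainParams:
    """Proximity parameters of the surface-domain classifier.

    ``contact_distance`` is the largest surface-to-surface gap still counted
    as cell-cell contact; ``junction_width`` is the half-width of the
    junctional band straddling the exposed/contact boundary. Both default to
    1 µm, one z-step at typical confocal sampling of whole embryos.
    """

    contact_distance: float = 1.0
    junction_width: float = 1.0

    def __post_init__(self) -> None:
        if self.contact_distance < 0:
            raise ValueError("contact_distance must be >= 0")
        if self.junction_width < 0:
            raise ValueError("junction_width must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DomainParams":
        return cls(**d)
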