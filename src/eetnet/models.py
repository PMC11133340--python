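"""Core domain types: atoms, residues, structure models, pigment sites and censuses.

Coordinates are orthogonal angstroms throughout.  A :class:`StructureModel` is a
light, format-agnostic view of one model of a structure file; pigment-specific
content lives in :class:`PigmentSite` / :class:`PigmentInventory`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional

import numpy as np


class PigmentKind(str, enum.Enum):
    """Cofactor classes recognised by the census and downstream analyses."""

    CHL_A = "CHL_A"
    CHL_C = "CHL_C"
    ALX = "ALX"      # alloxanthin
    ACAR = "ACAR"    # alpha-carotene
    CRO = "CRO"      # crocoxanthin
    MON = "MON"      # monadoxanthin
    LMG = "LMG"      # monogalactosyl diglyceride lipid
    SQD = "SQD"      # sulfoquinovosyl diacylglycerol lipid
    LHG = "LHG"      # phosphatidyl glycerol lipid
    OTHER = "OTHER"


CHLOROPHYLL_KINDS = frozenset({PigmentKind.CHL_A, PigmentKind.CHL_C})
CAROTENOID_KINDS = frozenset(
    {PigmentKind.ALX, PigmentKind.ACAR, PigmentKind.CRO, PigmentKind.MON}
)
PIGMENT_KINDS = CHLOROPHYLL_KINDS | CAROTENOID_KINDS
LIPID_KINDS = frozenset({PigmentKind.LMG, PigmentKind.SQD, PigmentKind.LHG})

#: Prefix used to build human-readable pigment labels ("a603", "Alx615", ...)
LABEL_PREFIX: Mapping[PigmentKind, str] = {
    PigmentKind.CHL_A: "a",
    PigmentKind.CHL_C: "c",
    PigmentKind.ALX: "Alx",
    PigmentKind.ACAR: "Car",
    PigmentKind.CRO: "Cro",
    PigmentKind.MON: "Mon",
    PigmentKind.LMG: "Lmg",
    PigmentKind.SQD: "Sqd",
    PigmentKind.LHG: "Lhg",
    PigmentKind.OTHER: "x",
}


@dataclass
class AtomRecord:
    """One atom with resolved alternate location."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), angstrom
    chain_id: str
    residue_name: str
    residue_number: int
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    residue_name: str
    atoms: List[AtomRecord]
    hetero: bool = False

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> str:
        return f"{self.chain_id}/{self.residue_number}"


@dataclass
class StructureModel:
    """Chains of residues plus file-level metadata."""

    chains: Dict[str, List[Residue]] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def get_residue(self, chain_id: str, residue_number: int) -> Optional[Residue]:
        for res in self.chains.get(chain_id, ()):
            if res.residue_number == residue_number:
                return res
        return None


@dataclass
class PigmentSite:
    """One extracted cofactor.

    ``mg_position`` is present iff the site is a chlorophyll (and was extracted
    with a central Mg atom).
    """

    kind: PigmentKind
    chain_id: str
    subunit_label: str
    pigment_label: str
    residue_number: int
    atoms: List[AtomRecord]
    mg_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mg_position is not None:
            self.mg_position = np.asarray(self.mg_position, dtype=float)

    @property
    def site_id(self) -> str:
        return f"{self.chain_id}/{self.residue_number}"

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``a608_ACPII-1``."""
        return f"{self.pigment_label}_{self.subunit_label}"

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_chlorophyll(self) -> bool:
        return self.kind in CHLOROPHYLL_KINDS


@dataclass
class PigmentInventory:
    """All pigment/lipid sites of a model plus the chain naming scheme."""

    sites: List[PigmentSite] = field(default_factory=list)
    naming_map: Dict[str, str] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)  # warnings for skipped sites

    def __len__(self) -> int:
        return len(self.sites)

    def by_kind(self, *kinds: PigmentKind) -> List[PigmentSite]:
        wanted = set(kinds)
        return [s for s in self.sites if s.kind in wanted]

    def chlorophylls(self) -> List[PigmentSite]:
        return [s for s in self.sites if s.is_chlorophyll]

    def get(self, site_id: str) -> Optional[PigmentSite]:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        return None

    def find_label(self, label: str) -> Optional[PigmentSite]:
        """Look a site up by its full ``pigment_label_subunit`` label."""
        for s in self.sites:
            if s.label == label:
                return s
        return None


@dataclass
class CensusTable:
    """Per-kind cofactor counts with pigment/lipid totals."""

    counts: Dict[PigmentKind, int]
    total_pigments: int
    total_lipids: int

    @classmethod
    def from_sites(cls, sites: List[PigmentSite]) -> "CensusTable":
        counts: Dict[PigmentKind, int] = {k: 0 for k in PigmentKind}
        for s in sites:
            counts[s.kind] += 1
        return cls(
            counts=counts,
            total_pigments=sum(counts[k] for k in PIGMENT_KINDS),
            total_lipids=sum(counts[k] for k in LIPID_KINDS),
        )

    def as_dict(self) -> Dict[str, int]:
        out = {k.value: v for k, v in self.counts.items()}
        out["total_pigments"] = self.total_pigments
        out["total_lipids"] = self.total_lipids
        return out
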