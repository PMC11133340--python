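"""Synthetic structure fixtures with analytic ground truth.

Every pipeline stage is testable without any deposited structure: a
:class:`FixtureSpec` places chlorophyll-like residues (central Mg plus NB/ND
ring nitrogens realizing a requested dipole direction), carotenoid-like atom
chains and lipid markers; :func:`make_fixture` writes a minimal legal
mmCIF/PDB file and returns a :class:`GroundTruth` computed in closed form from
the spec itself — never through the file-reading path it is meant to check.

Positional noise (seeded Gaussian, per coordinate) is applied to the written
file only after the ground truth is computed; it is intended for layer
fixtures, whose ground truth is noise-robust, and must be left at zero when
exact edge oracles are wanted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

from .errors import FixtureValidationError, GeometryError
from .fret import FretEdge, FretParameters
from .models import (
    CHLOROPHYLL_KINDS,
    CensusTable,
    PigmentKind,
    LABEL_PREFIX,
)

#: Component codes written into fixture files.  Chlorophylls reuse the real
#: codes so the default code_map applies unchanged; the carotenoid/lipid codes
#: are fixture-local and carried by :data:`FIXTURE_CODE_MAP`.
FIXTURE_CODES: Dict[PigmentKind, str] = {
    PigmentKind.CHL_A: "CLA",
    PigmentKind.CHL_C: "KC2",
    PigmentKind.ALX: "XAL",
    PigmentKind.ACAR: "XAC",
    PigmentKind.CRO: "XCR",
    PigmentKind.MON: "XMO",
    PigmentKind.LMG: "LMG",
    PigmentKind.SQD: "SQD",
    PigmentKind.LHG: "LHG",
}
FIXTURE_CODE_MAP: Dict[str, PigmentKind] = {v: k for k, v in FIXTURE_CODES.items()}

#: NB/ND are set this far on either side of the Mg along the dipole direction;
#: any nonzero value realizes the direction exactly, and 2 A total is within a
#: real chlorin's N-N scale.
NB_ND_HALF_SPAN = 1.0


@dataclass
class Placement:
    """One residue to synthesize."""

    kind: PigmentKind
    chain_id: str
    residue_number: int
    mg_position: np.ndarray  # anchor position for non-chlorophylls
    dipole_direction: Optional[np.ndarray] = None  # chlorophylls only
    extra_atoms: Sequence[Tuple[str, str, np.ndarray]] = ()  # (name, element, pos)

    def __post_init__(self) -> None:
        self.mg_position = np.asarray(self.mg_position, dtype=float)
        if self.dipole_direction is not None:
            self.dipole_direction = np.asarray(self.dipole_direction, dtype=float)

    @property
    def site_id(self) -> str:
        return f"{self.chain_id}/{self.residue_number}"

    @property
    def label(self) -> str:
        return f"{LABEL_PREFIX[self.kind]}{self.residue_number}_{self.chain_id}"


@dataclass
class TwoLayerSpec:
    z_low: float
    z_high: float
    n_low: int
    n_high: int


@dataclass
class FixtureSpec:
    placements: List[Placement] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0
    two_layer: Optional[TwoLayerSpec] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FixtureSpec":
        """Load a declarative spec (see docs/fixture-spec.md for the schema)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        placements = [
            Placement(
                kind=PigmentKind(p["kind"]),
                chain_id=str(p["chain"]),
                residue_number=int(p["resnum"]),
                mg_position=np.asarray(p["position"], dtype=float),
                dipole_direction=(
                    np.asarray(p["dipole"], dtype=float) if "dipole" in p else None
                ),
                extra_atoms=[
                    (a["name"], a["element"], np.asarray(a["position"], dtype=float))
                    for a in p.get("extra_atoms", [])
                ],
            )
            for p in raw.get("placements", [])
        ]
        tl = raw.get("two_layer")
        spec = cls(
            placements=placements,
            noise_sigma=float(raw.get("noise_sigma", 0.0)),
            seed=int(raw.get("seed", 0)),
            two_layer=TwoLayerSpec(**tl) if tl else None,
        )
        spec.validate()
        return spec

    def validate(self) -> None:
        violations = []
        seen = set()
        for p in self.placements:
            if p.site_id in seen:
                violations.append(f"duplicate residue identity {p.site_id}")
            seen.add(p.site_id)
            if p.kind in CHLOROPHYLL_KINDS:
                if p.dipole_direction is None:
                    violations.append(f"{p.site_id}: chlorophyll needs a dipole direction")
                elif not math.isclose(
                    float(np.linalg.norm(p.dipole_direction)), 1.0, abs_tol=1e-9
                ):
                    violations.append(f"{p.site_id}: dipole direction not unit-norm")
        if self.noise_sigma < 0:
            violations.append("noise_sigma must be >= 0")
        if violations:
            raise FixtureValidationError(violations)


@dataclass
class GroundTruth:
    """Analytic expectations paired with a written fixture."""

    expected_census: CensusTable
    expected_edges: List[FretEdge]
    expected_layers: Dict[str, str]  # site id -> "layer1"/"layer2" (planted)
    mg_positions: Dict[str, np.ndarray]

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "census": self.expected_census.as_dict(),
            "edges": [
                {
                    "donor": e.donor,
                    "acceptor": e.acceptor,
                    "r_angstrom": e.r_angstrom,
                    "kappa_sq": e.kappa_sq,
                    "rate_per_ps": e.rate,
                    "lifetime_ps": e.lifetime,
                }
                for e in self.expected_edges
            ],
            "layers": self.expected_layers,
            "mg_positions": {k: list(v) for k, v in self.mg_positions.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def analytic_rate(
    placement_d: Placement,
    placement_a: Placement,
    params: Optional[FretParameters] = None,
) -> FretEdge:
    """Closed-form edge straight from spec vectors (no file or atom step).

    This is the independent oracle for the full pipeline: it re-derives
    kappa^2 and the rate from the placement positions/directions alone.
    """
    params = params or FretParameters()
    rvec = placement_a.mg_position - placement_d.mg_position
    r = float(np.linalg.norm(rvec))
    if r == 0:
        raise GeometryError("coincident placements")
    r_hat = rvec / r
    ud = placement_d.dipole_direction
    ua = placement_a.dipole_direction
    kappa = float(ud @ ua - 3.0 * ((ud @ r_hat) * (ua @ r_hat)))
    ksq = kappa * kappa
    r_in_unit = r / 10.0 if params.distance_unit_in_rate == "nm" else r
    rate = params.C * ksq / (params.n ** 4 * r_in_unit ** 6)
    return FretEdge(
        donor=placement_d.site_id,
        acceptor=placement_a.site_id,
        r_angstrom=r,
        kappa_sq=ksq,
        rate=rate,
        donor_label=placement_d.label,
        acceptor_label=placement_a.label,
    )


def _placement_atoms(p: Placement) -> List[Tuple[str, str, np.ndarray]]:
    atoms: List[Tuple[str, str, np.ndarray]] = []
    if p.kind in CHLOROPHYLL_KINDS:
        u = p.dipole_direction
        atoms.append(("MG", "MG", p.mg_position))
        atoms.append(("NB", "N", p.mg_position - NB_ND_HALF_SPAN * u))
        atoms.append(("ND", "N", p.mg_position + NB_ND_HALF_SPAN * u))
    elif not p.extra_atoms:
        # default carotenoid/lipid body: short carbon chain along +x
        for i in range(5):
            atoms.append((f"C{i + 1}", "C", p.mg_position + np.array([1.4 * i, 0, 0])))
    atoms.extend((n, el, np.asarray(pos, dtype=float)) for n, el, pos in p.extra_atoms)
    return atoms


def ground_truth_for(
    spec: FixtureSpec, params: Optional[FretParameters] = None
) -> GroundTruth:
    """Analytic census, edge list and planted layers for a spec."""
    params = params or FretParameters()
    census = CensusTable.from_sites(
        [  # census only needs kinds; synthesize the minimal fields
            _census_stub(p) for p in spec.placements
        ]
    )
    chl_a = [p for p in spec.placements if p.kind == PigmentKind.CHL_A]
    edges = []
    for i in range(len(chl_a)):
        for j in range(i + 1, len(chl_a)):
            r = float(np.linalg.norm(chl_a[j].mg_position - chl_a[i].mg_position))
            if 0 < r < params.cutoff:
                edges.append(analytic_rate(chl_a[i], chl_a[j], params))
    layers: Dict[str, str] = {}
    if spec.two_layer is not None:
        mid = 0.5 * (spec.two_layer.z_low + spec.two_layer.z_high)
        for p in spec.placements:
            if p.kind in CHLOROPHYLL_KINDS:
                layers[p.site_id] = "layer2" if p.mg_position[2] > mid else "layer1"
    return GroundTruth(
        expected_census=census,
        expected_edges=edges,
        expected_layers=layers,
        mg_positions={p.site_id: p.mg_position.copy() for p in spec.placements},
    )


def _census_stub(p: Placement):
    from .models import PigmentSite, AtomRecord

    return PigmentSite(
        kind=p.kind,
        chain_id=p.chain_id,
        subunit_label=p.chain_id,
        pigment_label=f"{LABEL_PREFIX[p.kind]}{p.residue_number}",
        residue_number=p.residue_number,
        atoms=[
            AtomRecord("X", "C", p.mg_position, p.chain_id,
                       FIXTURE_CODES[p.kind], p.residue_number)
        ],
        mg_position=p.mg_position if p.kind in CHLOROPHYLL_KINDS else None,
    )


def make_fixture(
    spec: FixtureSpec,
    path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
    params: Optional[FretParameters] = None,
) -> GroundTruth:
    """Write the fixture file and return (saving optionally) its ground truth.

    Deterministic: the same spec and seed produce byte-identical output.
    """
    spec.validate()
    path = Path(path)
    truth = ground_truth_for(spec, params)

    names: List[str] = []
    elements: List[str] = []
    coords: List[np.ndarray] = []
    chain_ids: List[str] = []
    res_ids: List[int] = []
    res_names: List[str] = []
    for p in spec.placements:
        for name, element, pos in _placement_atoms(p):
            names.append(name)
            elements.append(element)
            coords.append(pos)
            chain_ids.append(p.chain_id)
            res_ids.append(p.residue_number)
            res_names.append(FIXTURE_CODES[p.kind])

    n = len(names)
    arr = struc.AtomArray(n)
    if n:
        coord = np.array(coords, dtype=np.float64)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(spec.seed)
            coord = coord + rng.normal(0.0, spec.noise_sigma, size=coord.shape)
        arr.coord = coord.astype(np.float32)
        arr.chain_id = np.array(chain_ids)
        arr.res_id = np.array(res_ids)
        arr.res_name = np.array(res_names)
        arr.atom_name = np.array(names)
        arr.element = np.array(elements)
        arr.hetero = np.ones(n, dtype=bool)
        arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))

    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        if n == 0:  # biotite refuses empty structures; write a bare block
            path.write_text("data_fixture\n#\n")
        else:
            cif = pdbx_io.CIFFile()
            pdbx_io.set_structure(cif, arr)
            cif.write(str(path))
    elif suffix in (".pdb", ".ent"):
        if n == 0:
            path.write_text("END\n")
        else:
            pdbf = pdb_io.PDBFile()
            pdbf.set_structure(arr)
            pdbf.write(str(path))
    else:
        raise ValueError(f"unsupported fixture suffix {suffix!r}")

    if truth_path is not None:
        truth.save(truth_path)
    return truth


#: Unit vectors that are exactly representable in binary floating point.
_AXIS_DIPOLES = [
    np.array(v, dtype=float)
    for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
]


def random_fixture_spec(
    seed: int,
    n_sites: int = 8,
    box: float = 40.0,
    grid: float = 1.0 / 64.0,
) -> FixtureSpec:
    """Seeded random chlorophyll-a spec with exactly round-trippable geometry.

    Mg positions snap to a binary-exact grid and dipoles are axis-aligned unit
    vectors, so writing to mmCIF (float32 text) and reading back reproduces
    every coordinate bit-for-bit and pipeline rates can be compared to the
    analytic oracle at machine precision.
    """
    rng = np.random.default_rng(seed)
    placements: List[Placement] = []
    used = set()
    while len(placements) < n_sites:
        pos = np.round(rng.uniform(0, box, size=3) / grid) * grid
        key = tuple(pos)
        if key in used:
            continue
        used.add(key)
        placements.append(
            Placement(
                kind=PigmentKind.CHL_A,
                chain_id="A",
                residue_number=601 + len(placements),
                mg_position=pos,
                dipole_direction=_AXIS_DIPOLES[rng.integers(len(_AXIS_DIPOLES))].copy(),
            )
        )
    return FixtureSpec(placements=placements, seed=seed)


def make_two_layer_spec(
    z_low: float = 0.0,
    z_high: float = 18.0,
    n_low: int = 10,
    n_high: int = 7,
    noise_sigma: float = 1.0,
    seed: int = 17,
) -> FixtureSpec:
    """Two flat chlorophyll-a sheets along z, laid out on xy grids.

    Each layer is a two-row grid, laterally centered on the origin so the
    layers share a lateral centroid (no x/z or y/z cross-covariance), with
    pitches scaled to the layer separation so the lateral variances always
    dominate the inter-layer variance: the covariance-smallest axis is then
    the z normal for any separation and any noise well below it.
    """
    sep = abs(z_high - z_low)
    lateral_pitch = max(12.0, 1.5 * sep)
    row_pitch = max(40.0, 2.5 * sep)
    placements: List[Placement] = []
    counts = [(z_low, n_low, "L"), (z_high, n_high, "U")]
    for z, n, chain in counts:
        cols = max(2, int(math.ceil(n / 2)))
        grid = [
            np.array([(i % cols) * lateral_pitch, (i // cols) * row_pitch])
            for i in range(n)
        ]
        center = np.mean(grid, axis=0)
        for i, xy in enumerate(grid):
            placements.append(
                Placement(
                    kind=PigmentKind.CHL_A,
                    chain_id=chain,
                    residue_number=601 + i,
                    mg_position=np.array([xy[0] - center[0], xy[1] - center[1], z]),
                    dipole_direction=np.array([1.0, 0.0, 0.0]),
                )
            )
    return FixtureSpec(
        placements=placements,
        noise_sigma=noise_sigma,
        seed=seed,
        two_layer=TwoLayerSpec(z_low=z_low, z_high=z_high, n_low=n_low, n_high=n_high),
    )
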