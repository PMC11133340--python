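"""Reading structure files and extracting pigment cofactors.

Parsing is delegated to :mod:`biotite` (mmCIF/PDBx and PDB dialects); this
module resolves alternate locations deterministically, reshapes atoms into
:class:`~eetnet.models.StructureModel` and pulls pigment hetero-residues into a
typed :class:`~eetnet.models.PigmentInventory`.

Chemical-component codes are entry specific for the exotic carotenoids, so the
kind mapping is profile-driven: a profile bundles a ``code_map`` (component
code -> :class:`~eetnet.models.PigmentKind`) and a ``naming_map``
(chain id -> subunit label).  Profiles are YAML files; two ship with the
package (``default``, ``8wb4``).  For mmCIF inputs the carotenoid codes can
also be inferred from the file's own ``chem_comp`` names.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

from .errors import StructureFormatError, StructureParseError
from .models import (
    AtomRecord,
    CensusTable,
    PigmentInventory,
    PigmentKind,
    PigmentSite,
    Residue,
    StructureModel,
    LABEL_PREFIX,
)

#: Component codes that are stable across entries: chlorophyll a (CLA),
#: the chlorophyll c species (KC1/KC2) and the standard thylakoid lipids.
DEFAULT_CODE_MAP: Dict[str, PigmentKind] = {
    "CLA": PigmentKind.CHL_A,
    "KC1": PigmentKind.CHL_C,
    "KC2": PigmentKind.CHL_C,
    "LMG": PigmentKind.LMG,
    "SQD": PigmentKind.SQD,
    "LHG": PigmentKind.LHG,
}

#: Substring -> kind rules used to infer entry-specific carotenoid codes from
#: mmCIF ``chem_comp.name`` strings (checked in order; first match wins).
_CHEM_COMP_NAME_RULES: Tuple[Tuple[str, PigmentKind], ...] = (
    ("ALLOXANTHIN", PigmentKind.ALX),
    ("CROCOXANTHIN", PigmentKind.CRO),
    ("MONADOXANTHIN", PigmentKind.MON),
    ("CAROTENE", PigmentKind.ACAR),
    ("CHLOROPHYLL A", PigmentKind.CHL_A),
    ("CHLOROPHYLL C", PigmentKind.CHL_C),
)

_MMCIF_SUFFIXES = {".cif", ".mmcif", ".pdbx"}
_PDB_SUFFIXES = {".pdb", ".ent"}


@dataclass
class Profile:
    """Entry profile: component-code mapping plus chain naming."""

    code_map: Dict[str, PigmentKind] = field(default_factory=lambda: dict(DEFAULT_CODE_MAP))
    naming_map: Dict[str, str] = field(default_factory=dict)
    infer_carotenoids: bool = False  # scan chem_comp names of mmCIF inputs
    #: optional monomer name -> chain-id list (for per-monomer analyses)
    monomers: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Profile":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        code_map = dict(DEFAULT_CODE_MAP)
        for code, kind in (raw.get("code_map") or {}).items():
            code_map[str(code).upper()] = PigmentKind(kind)
        return cls(
            code_map=code_map,
            naming_map={str(k): str(v) for k, v in (raw.get("naming_map") or {}).items()},
            infer_carotenoids=bool(raw.get("infer_carotenoids", False)),
            monomers={
                str(k): [str(c) for c in v]
                for k, v in (raw.get("monomers") or {}).items()
            },
        )


def load_profile(name_or_path: Union[str, Path]) -> Profile:
    """Load a profile by bundled name (``default``, ``8wb4``) or file path."""
    p = Path(name_or_path)
    if p.exists():
        return Profile.from_yaml(p)
    ref = resources.files("eetnet.profiles").joinpath(f"{name_or_path}.yaml")
    if ref.is_file():
        with resources.as_file(ref) as fp:
            return Profile.from_yaml(fp)
    raise FileNotFoundError(f"no such profile: {name_or_path!r}")


def _detect_format(path: Path, fmt: str) -> str:
    if fmt not in {"auto", "mmcif", "pdb"}:
        raise StructureFormatError(f"unknown format {fmt!r} (expected mmcif/pdb/auto)")
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in _MMCIF_SUFFIXES:
        return "mmcif"
    if suffix in _PDB_SUFFIXES:
        return "pdb"
    raise StructureFormatError(
        f"cannot infer format from suffix {suffix!r} of {path.name}; pass format explicitly"
    )


def _resolve_altlocs(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep, per (chain, residue, atom name), the highest-occupancy conformer.

    Ties break toward the lexicographically smallest altloc id, which makes
    re-reads byte-reproducible.
    """
    if "altloc_id" not in atoms.get_annotation_categories():
        return atoms
    alt = np.char.replace(atoms.altloc_id.astype("U4"), ".", "")
    occ = (
        atoms.occupancy
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    best: Dict[tuple, int] = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], int(atoms.res_id[i]), atoms.ins_code[i],
               atoms.res_name[i], atoms.atom_name[i])
        j = best.get(key)
        if j is None:
            best[key] = i
        elif (occ[i], _neg_alt(alt[i])) > (occ[j], _neg_alt(alt[j])):
            best[key] = i
    keep = np.zeros(atoms.array_length(), dtype=bool)
    keep[list(best.values())] = True
    return atoms[keep]


class _neg_alt(str):
    """Reverses lexicographic order so max() prefers the smallest altloc id."""

    def __lt__(self, other):  # noqa: D105
        return str(self) > str(other)

    def __gt__(self, other):  # noqa: D105
        return str(self) < str(other)


def read_structure(
    path: Union[str, Path], format: str = "auto"
) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    All atoms with coordinates are loaded (waters and ions included); altloc
    duplicates are resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: no such file")
    fmt = _detect_format(path, format)
    if path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file")
    metadata: Dict[str, str] = {"path": str(path), "format": fmt}
    try:
        if fmt == "mmcif":
            cif = pdbx_io.CIFFile.read(str(path))
            block_name = next(iter(cif), None)
            if block_name is None:
                raise StructureParseError(f"{path}: no data block found")
            metadata["block"] = block_name
            atoms = pdbx_io.get_structure(
                cif, model=1, altloc="all", extra_fields=["occupancy"]
            )
        else:
            pdbf = pdb_io.PDBFile.read(str(path))
            atoms = pdbf.get_structure(
                model=1, altloc="all", extra_fields=["occupancy"]
            )
    except StructureParseError:
        raise
    except Exception as exc:  # biotite raises format-specific exceptions
        raise StructureParseError(f"{path}: parse failed: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: no atom records")
    atoms = _resolve_altlocs(atoms)
    return _to_model(atoms, metadata)


def _to_model(atoms: struc.AtomArray, metadata: Dict[str, str]) -> StructureModel:
    model = StructureModel(metadata=metadata)
    categories = atoms.get_annotation_categories()
    occ = atoms.occupancy if "occupancy" in categories else np.ones(atoms.array_length())
    alt = (
        np.char.replace(atoms.altloc_id.astype("U4"), ".", "")
        if "altloc_id" in categories
        else np.full(atoms.array_length(), "", dtype="U4")
    )
    hetero = atoms.hetero
    current: Optional[Residue] = None
    for i in range(atoms.array_length()):
        chain_id = str(atoms.chain_id[i])
        res_num = int(atoms.res_id[i])
        res_name = str(atoms.res_name[i])
        if (
            current is None
            or current.chain_id != chain_id
            or current.residue_number != res_num
            or current.residue_name != res_name
        ):
            current = Residue(chain_id, res_num, res_name, [], hetero=bool(hetero[i]))
            model.chains.setdefault(chain_id, []).append(current)
        current.atoms.append(
            AtomRecord(
                name=str(atoms.atom_name[i]),
                element=str(atoms.element[i]),
                position=np.array(atoms.coord[i], dtype=float),
                chain_id=chain_id,
                residue_name=res_name,
                residue_number=res_num,
                altloc=str(alt[i]),
                occupancy=float(min(max(occ[i], 0.0), 1.0)),
            )
        )
    return model


def infer_code_map(path: Union[str, Path]) -> Dict[str, PigmentKind]:
    """Derive component-code -> kind entries from an mmCIF ``chem_comp`` table.

    Returns only the inferred entries; merge over :data:`DEFAULT_CODE_MAP`.
    """
    cif = pdbx_io.CIFFile.read(str(path))
    block = cif[next(iter(cif))]
    if "chem_comp" not in block:
        return {}
    cat = block["chem_comp"]
    ids = np.atleast_1d(cat["id"].as_array(str))
    names = (
        np.atleast_1d(cat["name"].as_array(str))
        if "name" in cat
        else np.full(len(ids), "")
    )
    inferred: Dict[str, PigmentKind] = {}
    for code, name in zip(ids, names):
        upper = name.upper()
        for needle, kind in _CHEM_COMP_NAME_RULES:
            if needle in upper:
                inferred[str(code)] = kind
                break
    return inferred


def extract_pigments(
    model: StructureModel,
    code_map: Optional[Mapping[str, PigmentKind]] = None,
    naming_map: Optional[Mapping[str, str]] = None,
) -> PigmentInventory:
    """Pull every residue whose component code is in ``code_map`` into a site.

    Chlorophyll sites must carry MG, NB and ND atoms; those that do not are
    skipped with a warning entry rather than raising.
    """
    code_map = dict(DEFAULT_CODE_MAP) if code_map is None else dict(code_map)
    if not code_map:
        raise ValueError("code_map must be non-empty")
    naming_map = dict(naming_map or {})
    inv = PigmentInventory(naming_map=naming_map)
    for res in model.residues():
        kind = code_map.get(res.residue_name)
        if kind is None:
            continue
        subunit = naming_map.get(res.chain_id, res.chain_id)
        label = f"{LABEL_PREFIX[kind]}{res.residue_number}"
        mg = None
        if kind in (PigmentKind.CHL_A, PigmentKind.CHL_C):
            mg_atom = res.atom("MG")
            missing = [n for n in ("MG", "NB", "ND") if res.atom(n) is None]
            if missing:
                inv.skipped.append(
                    f"{res.key} ({res.residue_name}): chlorophyll missing {','.join(missing)}"
                )
                continue
            mg = mg_atom.position
        inv.sites.append(
            PigmentSite(
                kind=kind,
                chain_id=res.chain_id,
                subunit_label=subunit,
                pigment_label=label,
                residue_number=res.residue_number,
                atoms=list(res.atoms),
                mg_position=mg,
            )
        )
    return inv


def pigment_census(inventory: PigmentInventory) -> CensusTable:
    """Count sites per kind; totals split pigments from lipids."""
    return CensusTable.from_sites(inventory.sites)


def census_to_csv(table: CensusTable, path: Union[str, Path]) -> None:
    rows = [(k.value, v) for k, v in table.counts.items()]
    pd.DataFrame(rows, columns=["kind", "count"]).to_csv(path, index=False)


def census_to_json(table: CensusTable, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(table.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
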