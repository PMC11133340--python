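"""Contact geometry beyond the rate network.

Shortest inter-pigment distances (phytol tails excluded by default, as the
published figures omit them), carotenoid-chlorophyll contact maps, Mg axial
ligand detection, polar-contact (hydrogen-bond proxy) search, and
stromal/lumenal layer classification of chlorophylls.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .errors import ClassificationError, GeometryError, SelectionError
from .models import (
    CAROTENOID_KINDS,
    CHLOROPHYLL_KINDS,
    AtomRecord,
    PigmentInventory,
    PigmentKind,
    PigmentSite,
    StructureModel,
)

#: Chlorophyll phytol-tail atoms are plain numbered carbons (C1..C20) in the
#: standard component nomenclature; chlorin-ring carbons carry letter suffixes.
_PHYTOL_ATOM = re.compile(r"^C\d{1,2}$")


@dataclass
class ContactPair:
    site_a: str
    site_b: str
    min_distance: float
    atom_a: str
    atom_b: str
    label_a: str = ""
    label_b: str = ""


@dataclass
class LigandAssignment:
    chl_site: str
    ligand: str  # "chain/resnum resname atom" or "unassigned"
    distance: Optional[float]
    chl_label: str = ""

    @property
    def assigned(self) -> bool:
        return self.ligand != "unassigned"


@dataclass
class LayerAssignment:
    labels: Dict[str, str]        # site id -> layer name
    axis: np.ndarray              # unit membrane normal
    split_point: float            # threshold on the axis projection
    layer_names: Tuple[str, str] = ("layer1", "layer2")

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for name in self.labels.values():
            out[name] = out.get(name, 0) + 1
        return out


def _site_positions(site: PigmentSite, exclude_phytol: bool) -> List[AtomRecord]:
    atoms = site.atoms
    if exclude_phytol and site.kind in CHLOROPHYLL_KINDS:
        atoms = [a for a in atoms if not _PHYTOL_ATOM.match(a.name)]
    atoms = [a for a in atoms if a.element.upper() != "H"]
    if not atoms:
        raise SelectionError(f"{site.label}: no atoms left after filtering")
    return atoms


def min_distance(
    site_a: PigmentSite, site_b: PigmentSite, exclude_phytol: bool = True
) -> ContactPair:
    """Minimum heavy-atom distance between two sites."""
    atoms_a = _site_positions(site_a, exclude_phytol)
    atoms_b = _site_positions(site_b, exclude_phytol)
    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([b.position for b in atoms_b])
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return ContactPair(
        site_a=site_a.site_id,
        site_b=site_b.site_id,
        min_distance=float(d[i, j]),
        atom_a=atoms_a[i].name,
        atom_b=atoms_b[j].name,
        label_a=site_a.label,
        label_b=site_b.label,
    )


def contact_map(
    inventory: PigmentInventory,
    kinds_a: Iterable[PigmentKind],
    kinds_b: Iterable[PigmentKind],
    threshold: float,
    exclude_phytol: bool = True,
) -> List[ContactPair]:
    """All cross-kind pairs closer than ``threshold``, ascending by distance."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    set_a, set_b = set(kinds_a), set(kinds_b)
    sites_a = [s for s in inventory.sites if s.kind in set_a]
    sites_b = [s for s in inventory.sites if s.kind in set_b]
    seen: Set[frozenset] = set()
    hits: List[ContactPair] = []
    for sa in sites_a:
        for sb in sites_b:
            if sa.site_id == sb.site_id:
                continue
            key = frozenset((sa.site_id, sb.site_id))
            if key in seen:
                continue
            seen.add(key)
            pair = min_distance(sa, sb, exclude_phytol=exclude_phytol)
            if pair.min_distance < threshold:
                hits.append(pair)
    hits.sort(key=lambda p: p.min_distance)
    return hits


def axial_ligand(
    chl_site: PigmentSite,
    model: StructureModel,
    cutoff: float = 3.5,
    excluded_residues: Optional[Set[str]] = None,
) -> LigandAssignment:
    """Nearest non-pigment heavy atom to the central Mg within ``cutoff`` A.

    Protein side chains/backbone, waters and lipid head groups all qualify;
    chromophore residues (chlorophylls and carotenoids) are excluded via
    ``excluded_residues`` (site ``chain/resnum`` keys), as is the chlorophyll
    itself.  With nothing in range the assignment is ``"unassigned"``.
    """
    if chl_site.mg_position is None:
        raise GeometryError(f"{chl_site.label}: no Mg position")
    excluded = set(excluded_residues or ())
    excluded.add(chl_site.site_id)
    mg = chl_site.mg_position
    best: Optional[Tuple[float, AtomRecord]] = None
    for res in model.residues():
        if res.key in excluded:
            continue
        for atom in res.atoms:
            if atom.element.upper() in ("H", "MG"):
                continue
            d = float(np.linalg.norm(atom.position - mg))
            if d <= cutoff and (best is None or d < best[0]):
                best = (d, atom)
    if best is None:
        return LigandAssignment(chl_site.site_id, "unassigned", None, chl_site.label)
    d, atom = best
    ligand = f"{atom.chain_id}/{atom.residue_number} {atom.residue_name} {atom.name}"
    return LigandAssignment(chl_site.site_id, ligand, d, chl_site.label)


def chromophore_residue_keys(inventory: PigmentInventory) -> Set[str]:
    """Residue keys of chlorophylls and carotenoids (axial-ligand exclusions)."""
    return {
        s.site_id
        for s in inventory.sites
        if s.kind in CHLOROPHYLL_KINDS | CAROTENOID_KINDS
    }


@dataclass
class ResidueSelection:
    """``chain:resnum[:atom]`` selector; several may be comma-joined."""

    chain_id: str
    residue_number: int
    atom_name: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> List["ResidueSelection"]:
        out = []
        for token in text.split(","):
            parts = token.strip().split(":")
            if len(parts) not in (2, 3) or not parts[0]:
                raise SelectionError(f"bad selection {token!r}; expected chain:resnum[:atom]")
            try:
                num = int(parts[1])
            except ValueError as exc:
                raise SelectionError(f"bad residue number in {token!r}") from exc
            out.append(cls(parts[0], num, parts[2] if len(parts) == 3 else None))
        return out

    def resolve(self, model: StructureModel) -> List[AtomRecord]:
        res = model.get_residue(self.chain_id, self.residue_number)
        if res is None:
            return []
        atoms = res.atoms
        if self.atom_name is not None:
            atoms = [a for a in atoms if a.name == self.atom_name]
        return atoms


def polar_contacts(
    model: StructureModel,
    selection_a: Union[str, Sequence[ResidueSelection]],
    selection_b: Union[str, Sequence[ResidueSelection]],
    d_max: float = 3.5,
) -> List[ContactPair]:
    """N/O atom pairs across two selections within ``d_max`` A.

    A distance-only hydrogen-bond proxy: no angular term, heavy atoms only.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if isinstance(selection_a, str):
        selection_a = ResidueSelection.parse(selection_a)
    if isinstance(selection_b, str):
        selection_b = ResidueSelection.parse(selection_b)
    atoms_a = [a for sel in selection_a for a in sel.resolve(model)]
    atoms_b = [a for sel in selection_b for a in sel.resolve(model)]
    if not atoms_a or not atoms_b:
        raise SelectionError("selection resolved to zero residues")
    polar_a = [a for a in atoms_a if a.element.upper() in ("N", "O")]
    polar_b = [b for b in atoms_b if b.element.upper() in ("N", "O")]
    hits: List[ContactPair] = []
    for a in polar_a:
        for b in polar_b:
            if a is b:
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if d <= d_max:
                hits.append(
                    ContactPair(
                        site_a=f"{a.chain_id}/{a.residue_number}",
                        site_b=f"{b.chain_id}/{b.residue_number}",
                        min_distance=d,
                        atom_a=a.name,
                        atom_b=b.name,
                        label_a=a.residue_name,
                        label_b=b.residue_name,
                    )
                )
    hits.sort(key=lambda p: p.min_distance)
    return hits


def _two_means_1d(x: np.ndarray) -> Tuple[np.ndarray, float]:
    """Exact 1-D two-class k-means: best split of the sorted projections."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    best_cost, best_k = np.inf, 1
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])
    for k in range(1, n):
        left = csq[k] - csum[k] ** 2 / k
        right = (csq[n] - csq[k]) - (csum[n] - csum[k]) ** 2 / (n - k)
        cost = left + right
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    split = 0.5 * (xs[best_k - 1] + xs[best_k])
    labels = (x > split).astype(int)
    return labels, float(split)


def classify_layers(
    inventory: PigmentInventory,
    axis: Optional[np.ndarray] = None,
    stromal_reference: Optional[np.ndarray] = None,
    min_spread: float = 1e-6,
) -> LayerAssignment:
    """Split chlorophylls into two layers along the membrane normal.

    The normal defaults to the smallest-eigenvalue eigenvector of the Mg
    coordinate covariance (the slab-thickness axis of a membrane complex);
    Mg projections are split by exact two-class 1-D k-means.  Sidedness
    cannot be derived from geometry alone: with ``stromal_reference`` (a point
    on the stromal side) or an explicitly oriented ``axis`` the layers are
    named stromal/lumenal, otherwise layer1/layer2 with a warning.
    """
    chls = inventory.chlorophylls()
    if len(chls) < 2:
        raise ClassificationError("need at least two chlorophylls")
    mg = np.array([s.mg_position for s in chls])
    oriented = axis is not None
    if axis is None:
        centered = mg - mg.mean(axis=0)
        cov = centered.T @ centered / len(mg)
        eigvals, eigvecs = np.linalg.eigh(cov)
        axis = eigvecs[:, 0]  # smallest eigenvalue
        # deterministic sign: largest-magnitude component positive
        lead = np.argmax(np.abs(axis))
        if axis[lead] < 0:
            axis = -axis
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = mg @ axis
    if proj.max() - proj.min() < min_spread:
        raise ClassificationError("degenerate split: all Mg collinear along the normal")
    side, split = _two_means_1d(proj)
    if stromal_reference is not None or oriented:
        if stromal_reference is not None:
            ref_proj = float(np.asarray(stromal_reference, dtype=float) @ axis)
            stromal_side = 1 if ref_proj > split else 0
        else:
            stromal_side = 1  # oriented axis points stromal-ward by convention
        names = ("lumenal", "stromal") if stromal_side == 1 else ("stromal", "lumenal")
    else:
        warnings.warn(
            "no orientation hint: labeling layers 'layer1'/'layer2' "
            "(pass stromal_reference or an oriented axis for sidedness)",
            stacklevel=2,
        )
        names = ("layer1", "layer2")
    labels = {s.site_id: names[side[i]] for i, s in enumerate(chls)}
    return LayerAssignment(labels=labels, axis=axis, split_point=split, layer_names=names)
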