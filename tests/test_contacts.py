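import numpy as np
import pytest

from eetnet import (
    PigmentKind,
    ResidueSelection,
    axial_ligand,
    classify_layers,
    contact_map,
    min_distance,
    polar_contacts,
)
from eetnet.contacts import chromophore_residue_keys
from eetnet.errors import ClassificationError, SelectionError
from eetnet.models import (
    AtomRecord,
    PigmentInventory,
    PigmentSite,
    Residue,
    StructureModel,
)


def site_of(kind, chain, resnum, atoms):
    records = [
        AtomRecord(name, element, np.asarray(pos, dtype=float), chain, "XXX", resnum)
        for name, element, pos in atoms
    ]
    mg = next((a.position for a in records if a.name == "MG"), None)
    return PigmentSite(kind, chain, chain, f"p{resnum}", resnum, records, mg)


def chl_at(mg, chain="A", resnum=601, direction=(0, 0, 1.0)):
    mg = np.asarray(mg, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return site_of(
        PigmentKind.CHL_A,
        chain,
        resnum,
        [("MG", "MG", mg), ("NB", "N", mg - u), ("ND", "N", mg + u)],
    )


class TestMinDistance:
    def test_site_with_itself_is_zero(self):
        s = site_of(PigmentKind.ALX, "A", 615, [("C1", "C", [0, 0, 0])])
        assert min_distance(s, s).min_distance == 0.0

    def test_3_4_5_triangle(self):
        a = site_of(PigmentKind.ALX, "A", 615, [("C1", "C", [0, 0, 0])])
        b = site_of(PigmentKind.ALX, "A", 616, [("C1", "C", [3, 4, 0])])
        pair = min_distance(a, b)
        assert pair.min_distance == pytest.approx(5.0)
        assert pair.atom_a == "C1" and pair.atom_b == "C1"

    def test_minimum_over_atom_pairs(self):
        a = site_of(
            PigmentKind.ALX, "A", 615,
            [("C1", "C", [0, 0, 0]), ("C2", "C", [1, 0, 0])],
        )
        b = site_of(
            PigmentKind.ALX, "A", 616,
            [("C1", "C", [9, 0, 0]), ("C2", "C", [4, 0, 0])],
        )
        pair = min_distance(a, b)
        assert pair.min_distance == pytest.approx(3.0)
        assert (pair.atom_a, pair.atom_b) == ("C2", "C2")

    def test_phytol_tail_excluded_for_chlorophylls_by_default(self):
        # C5 is a phytol-tail name; ring carbons carry letter suffixes
        chl = site_of(
            PigmentKind.CHL_A, "A", 601,
            [
                ("MG", "MG", [0, 0, 0]),
                ("NB", "N", [0, -1, 0]),
                ("ND", "N", [0, 1, 0]),
                ("C5", "C", [4.0, 0, 0]),
            ],
        )
        car = site_of(PigmentKind.ALX, "B", 615, [("C1", "C", [6.0, 0, 0])])
        assert min_distance(chl, car).min_distance == pytest.approx(6.0)
        assert min_distance(chl, car, exclude_phytol=False).min_distance == pytest.approx(2.0)

    def test_hydrogens_ignored(self):
        a = site_of(PigmentKind.ALX, "A", 615, [("C1", "C", [0, 0, 0]), ("H1", "H", [2.9, 0, 0])])
        b = site_of(PigmentKind.ALX, "A", 616, [("C1", "C", [3, 0, 0])])
        assert min_distance(a, b).min_distance == pytest.approx(3.0)

    def test_empty_selection_after_filtering(self):
        chl = site_of(PigmentKind.CHL_A, "A", 601, [("C5", "C", [0, 0, 0])])
        other = site_of(PigmentKind.ALX, "B", 615, [("C1", "C", [1, 0, 0])])
        with pytest.raises(SelectionError):
            min_distance(chl, other)

    def test_symmetry(self):
        a = chl_at([0, 0, 0])
        b = site_of(PigmentKind.ALX, "B", 615, [("C1", "C", [3, 4, 0])])
        assert min_distance(a, b).min_distance == min_distance(b, a).min_distance


class TestContactMap:
    def test_empty_inventory(self):
        assert contact_map(PigmentInventory(), {PigmentKind.ALX}, {PigmentKind.CHL_A}, 5.0) == []

    def test_single_forced_pair(self):
        inv = PigmentInventory(
            sites=[
                chl_at([0, 0, 0], direction=(0, 1.0, 0)),
                site_of(PigmentKind.ALX, "B", 615, [("C1", "C", [0, 4.0, 0])]),
                site_of(PigmentKind.ALX, "B", 616, [("C1", "C", [0, 40.0, 0])]),
            ]
        )
        pairs = contact_map(inv, {PigmentKind.ALX}, {PigmentKind.CHL_A}, 5.0)
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(3.0)  # to the ND at (0,1,0)

    def test_sorted_ascending_no_duplicates(self):
        rng = np.random.default_rng(0)
        sites = [chl_at(rng.uniform(0, 30, 3), resnum=601 + i) for i in range(10)]
        sites += [
            site_of(PigmentKind.ALX, "B", 700 + i, [("C1", "C", rng.uniform(0, 30, 3))])
            for i in range(10)
        ]
        inv = PigmentInventory(sites=sites)
        pairs = contact_map(inv, {PigmentKind.ALX}, {PigmentKind.CHL_A}, 15.0)
        dists = [p.min_distance for p in pairs]
        assert dists == sorted(dists)
        keys = {frozenset((p.site_a, p.site_b)) for p in pairs}
        assert len(keys) == len(pairs)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        chls = [chl_at(rng.uniform(0, 50, 3), resnum=601 + i) for i in range(25)]
        cars = [
            site_of(PigmentKind.ALX, "B", 700 + i, [("C1", "C", rng.uniform(0, 50, 3))])
            for i in range(25)
        ]
        inv = PigmentInventory(sites=chls + cars)
        threshold = 12.0
        got = {
            frozenset((p.site_a, p.site_b))
            for p in contact_map(inv, {PigmentKind.ALX}, {PigmentKind.CHL_A}, threshold)
        }
        expected = set()
        for c in cars:
            for h in chls:
                if min_distance(c, h).min_distance < threshold:
                    expected.add(frozenset((c.site_id, h.site_id)))
        assert got == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            contact_map(PigmentInventory(), {PigmentKind.ALX}, {PigmentKind.CHL_A}, 0.0)


def protein_residue(chain, resnum, resname, atoms):
    return Residue(
        chain,
        resnum,
        resname,
        [
            AtomRecord(name, element, np.asarray(pos, dtype=float), chain, resname, resnum)
            for name, element, pos in atoms
        ],
    )


class TestAxialLigand:
    def _model(self, residues):
        model = StructureModel()
        for r in residues:
            model.chains.setdefault(r.chain_id, []).append(r)
        return model

    def test_isolated_mg_unassigned(self):
        chl = chl_at([0, 0, 0])
        model = self._model([protein_residue("P", 1, "GLY", [("CA", "C", [50, 0, 0])])])
        lg = axial_ligand(chl, model)
        assert not lg.assigned
        assert lg.ligand == "unassigned" and lg.distance is None

    def test_nearest_atom_wins(self):
        chl = chl_at([0, 0, 0])
        model = self._model(
            [
                protein_residue("P", 93, "HIS", [("NE2", "N", [0, 0, 2.2])]),
                protein_residue("W", 1, "HOH", [("O", "O", [0, 3.0, 0])]),
            ]
        )
        lg = axial_ligand(chl, model)
        assert lg.assigned
        assert lg.distance == pytest.approx(2.2)
        assert "HIS" in lg.ligand and "NE2" in lg.ligand

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        chl = chl_at([10, 10, 10])
        residues = [
            protein_residue("P", i, "ALA", [("CB", "C", rng.uniform(5, 15, 3))])
            for i in range(1, 40)
        ]
        model = self._model(residues)
        lg = axial_ligand(chl, model, cutoff=3.5)
        # oracle: exhaustive nearest neighbour over all heavy atoms
        dists = [
            (float(np.linalg.norm(a.position - chl.mg_position)), a)
            for r in residues
            for a in r.atoms
        ]
        d_min, a_min = min(dists, key=lambda t: t[0])
        if d_min <= 3.5:
            assert lg.distance == pytest.approx(d_min)
            assert str(a_min.residue_number) in lg.ligand
        else:
            assert not lg.assigned

    def test_own_atoms_and_chromophores_excluded(self):
        chl = chl_at([0, 0, 0], chain="A", resnum=601)
        neighbour = chl_at([0, 0, 3.0], chain="A", resnum=602)
        model = self._model(
            [
                Residue("A", 601, "CLA", chl.atoms, hetero=True),
                Residue("A", 602, "CLA", neighbour.atoms, hetero=True),
            ]
        )
        inv = PigmentInventory(sites=[chl, neighbour])
        lg = axial_ligand(chl, model, excluded_residues=chromophore_residue_keys(inv))
        assert not lg.assigned

    def test_lipid_head_group_qualifies(self):
        chl = chl_at([0, 0, 0])
        model = self._model([protein_residue("L", 621, "LHG", [("O1", "O", [0, 0, 2.8])])])
        lg = axial_ligand(chl, model)
        assert lg.assigned and "LHG" in lg.ligand


class TestPolarContacts:
    def _model(self):
        model = StructureModel()
        res_a = protein_residue(
            "S", 250, "SER", [("OG", "O", [0, 0, 0]), ("CB", "C", [1.0, 0, 0])]
        )
        res_b = protein_residue(
            "D", 231, "GLU", [("OE1", "O", [2.5, 0, 0]), ("CD", "C", [3.2, 0, 0])]
        )
        res_c = protein_residue("D", 300, "ALA", [("CB", "C", [0, 2.0, 0])])
        for r in (res_a, res_b, res_c):
            model.chains.setdefault(r.chain_id, []).append(r)
        return model

    def test_forced_geometry(self):
        model = StructureModel()
        for r in (
            protein_residue("A", 1, "ASP", [("OD1", "O", [0, 0, 0])]),
            protein_residue("B", 2, "LYS", [("NZ", "N", [2.8, 0, 0])]),
        ):
            model.chains.setdefault(r.chain_id, []).append(r)
        pairs = polar_contacts(model, "A:1", "B:2", d_max=3.5)
        assert len(pairs) == 1
        assert pairs[0].min_distance == pytest.approx(2.8)

    def test_distance_only_proxy(self):
        pairs = polar_contacts(self._model(), "S:250", "D:231", d_max=3.5)
        assert len(pairs) == 1  # only the O-O pair at 2.5; carbons ignored
        assert pairs[0].min_distance == pytest.approx(2.5)
        assert {pairs[0].atom_a, pairs[0].atom_b} == {"OG", "OE1"}

    def test_no_polar_atoms_empty(self):
        pairs = polar_contacts(self._model(), "S:250:CB", "D:300", d_max=5.0)
        assert pairs == []

    def test_atom_scoped_selection(self):
        pairs = polar_contacts(self._model(), "S:250:OG", "D:231:OE1", d_max=3.0)
        assert len(pairs) == 1

    def test_empty_selection_is_an_error(self):
        with pytest.raises(SelectionError):
            polar_contacts(self._model(), "Z:999", "D:231", d_max=3.5)

    def test_selection_parse_errors(self):
        with pytest.raises(SelectionError):
            ResidueSelection.parse("justachain")
        with pytest.raises(SelectionError):
            ResidueSelection.parse("A:notanumber")

    def test_comma_joined_selections(self):
        sels = ResidueSelection.parse("S:250, D:231:OE1")
        assert len(sels) == 2
        assert sels[1].atom_name == "OE1"


class TestClassifyLayers:
    def _two_sheets(self, n_low=8, n_high=8, z_high=20.0, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sites = []
        num = 601
        for z, n in ((0.0, n_low), (z_high, n_high)):
            for i in range(n):
                pos = np.array(
                    [18.0 * (i % 4), 45.0 * (i // 4), z]
                ) + rng.normal(0, sigma, 3)
                sites.append(chl_at(pos, resnum=num))
                num += 1
        return PigmentInventory(sites=sites)

    def test_perfect_sheets(self):
        inv = self._two_sheets()
        with pytest.warns(UserWarning):
            assignment = classify_layers(inv)
        assert abs(assignment.axis @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-6)
        assert assignment.split_point == pytest.approx(10.0, abs=1e-6)
        counts = assignment.counts()
        assert sorted(counts.values()) == [8, 8]

    def test_noisy_10_7_split(self):
        inv = self._two_sheets(n_low=10, n_high=7, z_high=18.0, sigma=1.0, seed=17)
        with pytest.warns(UserWarning):
            assignment = classify_layers(inv)
        assert sorted(assignment.counts().values()) == [7, 10]
        # planted membership (z midpoint oracle) must match the recovered
        # partition exactly, whatever the layers were named
        groups = {}
        for site in inv.sites:
            groups.setdefault(assignment.labels[site.site_id], set()).add(
                site.mg_position[2] < 9.0
            )
        assert all(len(v) == 1 for v in groups.values())

    def test_stromal_reference_orients_names(self):
        inv = self._two_sheets()
        assignment = classify_layers(inv, stromal_reference=np.array([0, 0, 100.0]))
        stromal = [
            s for s in inv.sites if assignment.labels[s.site_id] == "stromal"
        ]
        assert all(s.mg_position[2] > 10 for s in stromal)
        flipped = classify_layers(inv, stromal_reference=np.array([0, 0, -100.0]))
        stromal2 = [s for s in inv.sites if flipped.labels[s.site_id] == "stromal"]
        assert all(s.mg_position[2] < 10 for s in stromal2)

    def test_rotation_translation_invariance(self):
        inv = self._two_sheets(n_low=9, n_high=6, sigma=0.5, seed=5)
        with pytest.warns(UserWarning):
            base = classify_layers(inv)
        # random rotation + translation
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = rng.uniform(-50, 50, 3)
        moved = PigmentInventory(
            sites=[
                chl_at(q @ s.mg_position + shift, resnum=s.residue_number)
                for s in inv.sites
            ]
        )
        with pytest.warns(UserWarning):
            rotated = classify_layers(moved)
        # same partition (possibly with swapped names)
        def partition(assignment, inv):
            groups = {}
            for s in inv.sites:
                groups.setdefault(assignment.labels[s.site_id], frozenset())
            out = {}
            for s in inv.sites:
                out.setdefault(assignment.labels[s.site_id], set()).add(s.residue_number)
            return {frozenset(v) for v in out.values()}

        assert partition(base, inv) == partition(rotated, moved)

    def test_too_few_chlorophylls(self):
        inv = PigmentInventory(sites=[chl_at([0, 0, 0])])
        with pytest.raises(ClassificationError):
            classify_layers(inv)

    def test_degenerate_spread(self):
        # all Mg in one flat z=0 plane and an explicit z axis: no split possible
        sites = [chl_at([5.0 * i, 3.0 * (i % 3), 0.0], resnum=601 + i) for i in range(8)]
        inv = PigmentInventory(sites=sites)
        with pytest.raises(ClassificationError):
            classify_layers(inv, axis=np.array([0, 0, 1.0]))
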