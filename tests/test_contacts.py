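"""Contact detection, filtering, state partition and interface matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allodecoder.contacts import (
    atom_contacts,
    interface_matrix,
    interface_residues,
    partition_by_state,
    residue_contacts,
)
from allodecoder.structures import DEFAULT_VDW_RADII, ResidueAnnotation, StructureModel

from conftest import make_atoms


def brute_force_contacts(model, gap_cutoff=0.5):
    """O(n^2) all-pairs oracle for the vdW-gap contact rule."""
    atoms = model.receptor
    out = set()
    for i in range(atoms.array_length()):
        for j in range(i + 1, atoms.array_length()):
            key_i = f"{atoms.chain_id[i]}:{atoms.res_id[i]}"
            key_j = f"{atoms.chain_id[j]}:{atoms.res_id[j]}"
            if key_i == key_j:
                continue
            if atoms.chain_id[i] == atoms.chain_id[j]:
                d_res = int(atoms.res_id[j]) - int(atoms.res_id[i])
                names = (str(atoms.atom_name[i]), str(atoms.atom_name[j]))
                if (d_res == 1 and names == ("C", "N")) or (
                    d_res == -1 and names == ("N", "C")
                ):
                    continue
            d = np.linalg.norm(
                atoms.coord[i].astype(float) - atoms.coord[j].astype(float)
            )
            gap = (
                d
                - DEFAULT_VDW_RADII[str(atoms.element[i]).upper()]
                - DEFAULT_VDW_RADII[str(atoms.element[j]).upper()]
            )
            if gap <= gap_cutoff:
                pair = tuple(
                    sorted(
                        [
                            (key_i, str(atoms.atom_name[i])),
                            (key_j, str(atoms.atom_name[j])),
                        ]
                    )
                )
                out.add(pair)
    return out


def random_model(rng, n_atoms, box=25.0):
    """Random scattering of C/N/O/S atoms over a handful of residues."""
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
    specs = []
    for i in range(n_atoms):
        res = int(rng.integers(1, max(2, n_atoms // 3)))
        name = f"X{i}"
        specs.append(
            ("A", res, "UNK", name, elements[i], rng.uniform(0, box, size=3))
        )
    return StructureModel(make_atoms(specs))


class TestAtomContacts:
    def test_gap_arithmetic_at_the_cutoff(self):
        """Two carbons at 3.90 A touch (gap 0.50); at 3.95 A they do not."""
        near = StructureModel(
            make_atoms(
                [
                    ("A", 1, "UNK", "C1", "C", [0, 0, 0]),
                    ("A", 2, "UNK", "C1", "C", [3.90, 0, 0]),
                ]
            )
        )
        far = StructureModel(
            make_atoms(
                [
                    ("A", 1, "UNK", "C1", "C", [0, 0, 0]),
                    ("A", 2, "UNK", "C1", "C", [3.95, 0, 0]),
                ]
            )
        )
        assert len(atom_contacts(near)) == 1
        assert atom_contacts(near)[0].gap == pytest.approx(0.50, abs=1e-5)
        assert atom_contacts(far) == []

    def test_empty_model(self):
        import biotite.structure as struc

        assert atom_contacts(StructureModel(struc.AtomArray(0))) == []

    def test_peptide_bond_excluded(self):
        m = StructureModel(
            make_atoms(
                [
                    ("A", 1, "ALA", "C", "C", [0, 0, 0]),
                    ("A", 2, "ALA", "N", "N", [1.33, 0, 0]),
                ]
            )
        )
        assert atom_contacts(m) == []

    def test_unknown_element_named_in_error(self):
        m = StructureModel(make_atoms([("A", 1, "UNK", "Q1", "QQ", [0, 0, 0])]))
        with pytest.raises(KeyError, match="QQ"):
            atom_contacts(m)

    @given(seed=st.integers(0, 1000), n=st.integers(2, 60))
    @settings(max_examples=30, deadline=None)
    def test_equals_brute_force_oracle(self, seed, n):
        """Tree-accelerated detection equals the O(n^2) all-pairs oracle."""
        model = random_model(np.random.default_rng(seed), n)
        got = {
            ((c.res_i, c.atom_i), (c.res_j, c.atom_j))
            for c in atom_contacts(model)
        }
        assert got == brute_force_contacts(model)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=15, deadline=None)
    def test_atom_order_shuffle_invariance(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, 40)
        perm = rng.permutation(model.receptor.array_length())
        shuffled = StructureModel(model.receptor[perm])
        as_set = lambda m: {
            (c.res_i, c.res_j, c.atom_i, c.atom_j) for c in atom_contacts(m)
        }
        assert as_set(model) == as_set(shuffled)


def ann(sse_map):
    return ResidueAnnotation(gpcrdb={}, sse=sse_map)


class TestResidueContacts:
    def base_contacts(self):
        m = StructureModel(
            make_atoms(
                [
                    ("A", 1, "UNK", "CB", "C", [0, 0, 0]),
                    ("A", 1, "UNK", "CA", "C", [1.5, 0, 0]),
                    ("A", 5, "UNK", "CB", "C", [3.5, 0, 0]),
                ]
            )
        )
        return atom_contacts(m)

    def test_aggregation_counts_atom_contacts(self):
        rc = residue_contacts(
            self.base_contacts(), ann({"A:1": "TM3", "A:5": "TM5"})
        )
        assert rc[("A:1", "A:5")].n_atom_contacts == 2

    def test_backbone_only_pairs_dropped(self):
        m = StructureModel(
            make_atoms(
                [
                    ("A", 1, "UNK", "O", "O", [0, 0, 0]),
                    ("A", 5, "UNK", "N", "N", [2.9, 0, 0]),
                ]
            )
        )
        cs = atom_contacts(m)
        assert len(cs) == 1 and cs[0].kind == "mainchain-mainchain"
        assert residue_contacts(cs, ann({"A:1": "TM1", "A:5": "TM2"})) == {}
        kept = residue_contacts(
            cs, ann({"A:1": "TM1", "A:5": "TM2"}), drop_mainchain_only=False
        )
        assert kept[("A:1", "A:5")].backbone_only

    def test_same_sse_pairs_dropped(self):
        rc = residue_contacts(self.base_contacts(), ann({"A:1": "TM3", "A:5": "TM3"}))
        assert rc == {}

    def test_unannotated_residues_kept_with_na_label(self):
        rc = residue_contacts(self.base_contacts(), ann({}))
        assert ("A:1", "A:5") in rc

    def test_restriction_to_resolved_residues(self):
        rc = residue_contacts(
            self.base_contacts(),
            ann({"A:1": "TM3", "A:5": "TM5"}),
            restrict_to={"A:1"},
        )
        assert rc == {}


class TestPartition:
    def test_identical_inputs_all_shared(self):
        rc = residue_contacts(
            TestResidueContacts().base_contacts(), ann({"A:1": "TM3", "A:5": "TM5"})
        )
        part = partition_by_state(rc, rc)
        assert part.counts() == {"active_only": 0, "inactive_only": 0, "shared": 1}

    def test_partition_set_identities(self, bundle):
        """|active_only| + |shared| equals the filtered active contact count."""
        active, inactive, annotation = bundle
        common = active.resolved_residues & inactive.resolved_residues
        rca = residue_contacts(atom_contacts(active), annotation, restrict_to=common)
        rci = residue_contacts(atom_contacts(inactive), annotation, restrict_to=common)
        part = partition_by_state(rca, rci)
        c = part.counts()
        assert c["active_only"] + c["shared"] == len(rca)
        assert c["inactive_only"] + c["shared"] == len(rci)
        assert (
            set(part.active_only) | set(part.inactive_only) | set(part.shared)
            == set(rca) | set(rci)
        )
        assert set(part.active_only) & set(part.shared) == set()

    def test_programmed_rewiring_recovered_exactly(self, bundle, study):
        _, rewiring, _ = study
        active, inactive, annotation = bundle
        common = active.resolved_residues & inactive.resolved_residues
        rca = residue_contacts(atom_contacts(active), annotation, restrict_to=common)
        rci = residue_contacts(atom_contacts(inactive), annotation, restrict_to=common)
        part = partition_by_state(rca, rci)
        assert set(part.active_only) == rewiring.by_state("active_only")
        assert set(part.inactive_only) == rewiring.by_state("inactive_only")
        assert set(part.shared) == rewiring.by_state("shared")


def interface_fixture():
    rec = make_atoms(
        [
            ("A", 1, "ALA", "CB", "C", [0, 0, 0]),
            ("A", 2, "ALA", "CB", "C", [8, 0, 0]),
            ("A", 3, "ALA", "N", "N", [16, 0, 0]),
        ]
    )
    lig = make_atoms(
        [
            ("L", 1, "ADR", "O1", "O", [3.5, 0, 0]),
            ("L", 1, "ADR", "C7", "C", [11.0, 0, 0]),
            ("L", 1, "ADR", "C8", "C", [16.0, 3.2, 0]),
        ]
    )
    return StructureModel(rec, partners={"ligand": lig})


class TestInterfaces:
    def test_site_membership_at_4A(self):
        m = interface_fixture()
        # A:1 at 3.5 A of O1; A:2 at 3.0 A of C7; A:3 at 3.2 A of C8
        assert interface_residues(m, "ligand") == {"A:1", "A:2", "A:3"}
        assert interface_residues(m, "ligand", cutoff=3.1) == {"A:2"}

    def test_distant_partner_is_empty(self):
        rec = make_atoms([("A", 1, "ALA", "CB", "C", [0, 0, 0])])
        lig = make_atoms([("L", 1, "ADR", "O1", "O", [10, 0, 0])])
        m = StructureModel(rec, partners={"ligand": lig})
        assert interface_residues(m, "ligand") == set()

    def test_empty_partner_is_error(self):
        import biotite.structure as struc

        m = StructureModel(
            make_atoms([("A", 1, "ALA", "CB", "C", [0, 0, 0])]),
            partners={"ligand": struc.AtomArray(0)},
        )
        with pytest.raises(ValueError, match="empty"):
            interface_residues(m, "ligand")

    def test_matrix_marginals_conserve_totals(self):
        m = interface_fixture()
        im = interface_matrix(m, "ligand", mode="ligand_atoms")
        total = im.counts.to_numpy().sum()
        assert im.row_totals.sum() == total
        assert im.col_totals.sum() == total

    def test_block_structure_matches_construction(self):
        """Each programmed receptor-ligand pair lands in its own cell."""
        m = interface_fixture()
        im = interface_matrix(m, "ligand", mode="ligand_atoms")
        assert im.counts.loc["A:1", "O1"] == 1
        assert im.counts.loc["A:2", "C7"] == 1
        assert im.counts.to_numpy().sum() == 3
        # A:3 touches the ligand only through its backbone nitrogen
        assert im.mainchain_only_rows == {"A:3"}

    def test_partner_residue_mode(self):
        m = interface_fixture()
        im = interface_matrix(m, "ligand", mode="partner_residues")
        assert list(im.counts.columns) == ["L:1"]
        assert im.counts["L:1"].sum() == 3
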