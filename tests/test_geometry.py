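"""Edge-to-edge distances and interface salt-bridge census."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nifcompat.geometry import (
    DEFAULT_HOTSPOTS,
    edge_to_edge_distance,
    find_salt_bridges,
    hotspot_contacts,
    nearest_ligand_cofactor,
)
from nifcompat.structure_io import AtomRecord, DockedComplexModel, RedoxCofactor
from nifcompat.synthetic import ComplexSpec, make_toy_complex

from conftest import build_model


def _point_cofactor(points, kind="FE4S4", chain="X", resnum=1):
    atoms = [
        AtomRecord(i, f"FE{i}", "SF4", chain, resnum, tuple(map(float, p)), "FE")
        for i, p in enumerate(points, 1)
    ]
    return RedoxCofactor(kind, "SF4", atoms, atoms, chain, resnum)


class TestEdgeToEdge:
    def test_single_atom_pair(self):
        a = _point_cofactor([(0, 0, 0)])
        b = _point_cofactor([(10, 0, 0)], chain="Y", resnum=2)
        assert edge_to_edge_distance(a, b).R == 10.0

    def test_minimum_over_cross_pairs(self):
        a = _point_cofactor([(0, 0, 0), (2, 0, 0)])
        b = _point_cofactor([(9, 0, 0), (20, 0, 0)], chain="Y", resnum=2)
        meas = edge_to_edge_distance(a, b)
        assert meas.R == 7.0
        assert meas.receptor_atom.xyz == (2.0, 0.0, 0.0)
        assert meas.ligand_atom.xyz == (9.0, 0.0, 0.0)

    def test_symmetric_in_arguments(self):
        a = _point_cofactor([(0, 1, 2), (3, -1, 0.5)])
        b = _point_cofactor([(8, 2, -1), (12, 0, 3)], chain="Y", resnum=2)
        assert edge_to_edge_distance(a, b).R == edge_to_edge_distance(b, a).R

    def test_empty_edge_set_is_an_error(self):
        a = _point_cofactor([(0, 0, 0)])
        b = RedoxCofactor("FE4S4", "SF4", [], [], "Y", 2)
        with pytest.raises(ValueError):
            edge_to_edge_distance(a, b)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.tuples(*[st.floats(-50, 50) for _ in range(3)]), min_size=1, max_size=10),
        st.lists(st.tuples(*[st.floats(-50, 50) for _ in range(3)]), min_size=1, max_size=10),
    )
    def test_minimum_property_vs_brute_force(self, pa, pb):
        a = _point_cofactor(pa)
        b = _point_cofactor(pb, chain="Y", resnum=2)
        brute = min(
            math.dist(x, y) for x, y in itertools.product(pa, pb)
        )
        assert edge_to_edge_distance(a, b).R == pytest.approx(brute, abs=1e-12)


class TestNearestLigandCofactor:
    def _model(self, ligand_cofactors):
        receptor = _point_cofactor([(0, 0, 0)], chain="A", resnum=300)
        return DockedComplexModel(
            model_index=1,
            receptor_chains=("A", "B"),
            ligand_chains=("C",),
            receptor_atoms=receptor.atoms,
            ligand_atoms=[a for c in ligand_cofactors for a in c.atoms],
            receptor_cofactors=[receptor],
            ligand_cofactors=ligand_cofactors,
            chain_labels={"A": "a", "B": "b"},
        )

    def test_closer_cluster_selected(self):
        near = _point_cofactor([(8, 0, 0)], chain="C", resnum=201)
        far = _point_cofactor([(15, 0, 0)], chain="C", resnum=202)
        model = self._model([far, near])
        cof, meas = nearest_ligand_cofactor(model)
        assert cof.parent_residue == 201 and meas.R == 8.0

    def test_single_cofactor_identity(self):
        only = _point_cofactor([(12, 0, 0)], chain="C", resnum=201)
        cof, _ = nearest_ligand_cofactor(self._model([only]))
        assert cof is only

    def test_tie_breaks_to_lower_residue_number(self):
        c1 = _point_cofactor([(10, 0, 0)], chain="C", resnum=205)
        c2 = _point_cofactor([(0, 10, 0)], chain="C", resnum=202)
        cof, meas = nearest_ligand_cofactor(self._model([c1, c2]))
        assert meas.R == 10.0 and cof.parent_residue == 202


def _bridge_model(separation, carrier_positive=True):
    """Minimal complex: one charged residue on each side, `separation` apart."""
    if carrier_positive:
        lig = [AtomRecord(1, "NZ", "LYS", "C", 50, (separation, 0.0, 0.0), "N")]
        rec = [AtomRecord(2, "OE1", "GLU", "A", 112, (0.0, 0.0, 0.0), "O")]
    else:
        lig = [AtomRecord(1, "OE1", "GLU", "C", 50, (separation, 0.0, 0.0), "O")]
        rec = [AtomRecord(2, "NH1", "ARG", "A", 101, (0.0, 0.0, 0.0), "N")]
    return DockedComplexModel(
        model_index=1,
        receptor_chains=("A", "B"),
        ligand_chains=("C",),
        receptor_atoms=rec,
        ligand_atoms=lig,
        receptor_cofactors=[],
        ligand_cofactors=[],
        chain_labels={"A": "a", "B": "b"},
    )


class TestSaltBridges:
    def test_close_pair_reported_with_polarity(self):
        bridges = find_salt_bridges(_bridge_model(3.5), cutoff=4.0)
        assert len(bridges) == 1
        b = bridges[0]
        assert b.pair_distance == pytest.approx(3.5)
        assert b.polarity == "carrier_positive"
        assert b.fe_protein_residue == ("a", 112, "GLU")

    def test_pair_beyond_cutoff_excluded(self):
        assert find_salt_bridges(_bridge_model(4.5), cutoff=4.0) == []

    def test_generator_bridge_count_recovered(self, toy_model, toy_complex):
        bridges = find_salt_bridges(toy_model, cutoff=4.0)
        assert len(bridges) == toy_complex[1]["n_bridges"] == 3
        assert all(b.pair_distance == pytest.approx(3.5, abs=2e-3) for b in bridges)

    def test_census_sorted_by_distance(self, toy_model):
        d = [b.pair_distance for b in find_salt_bridges(toy_model, cutoff=6.0)]
        assert d == sorted(d)

    def test_enlarging_cutoff_never_removes_bridges(self, toy_model):
        previous: set = set()
        for cutoff in (3.0, 3.6, 4.0, 5.0, 6.5):
            now = {
                (b.carrier_residue, b.fe_protein_residue)
                for b in find_salt_bridges(toy_model, cutoff=cutoff)
            }
            assert previous <= now
            previous = now

    def test_invariant_under_homodimer_chain_swap(self, toy_complex):
        model = build_model(toy_complex[0])
        swapped_atoms = []
        for a in model.receptor_atoms + model.ligand_atoms:
            chain = {"A": "B", "B": "A"}.get(a.chain_id, a.chain_id)
            swapped_atoms.append(
                AtomRecord(a.serial, a.name, a.residue_name, chain, a.residue_number, a.xyz, a.element)
            )
        from nifcompat.structure_io import split_receptor_ligand

        swapped = split_receptor_ligand(swapped_atoms, {"A", "B"})
        orig = find_salt_bridges(model)
        new = find_salt_bridges(swapped)
        assert len(orig) == len(new)
        flip = {"a": "b", "b": "a"}
        assert {
            (b.carrier_residue, (flip[b.fe_protein_residue[0]],) + b.fe_protein_residue[1:])
            for b in orig
        } == {(b.carrier_residue, b.fe_protein_residue) for b in new}

    def test_nonpositive_cutoff_rejected(self, toy_model):
        with pytest.raises(ValueError):
            find_salt_bridges(toy_model, cutoff=0.0)


class TestHotspotContacts:
    def test_bridge_to_hotspot_grouped(self):
        model = _bridge_model(3.5)
        bridges = find_salt_bridges(model)
        report = hotspot_contacts(bridges, model)
        assert len(report.contacts[("E112", "a")]) == 1
        assert all(not v for k, v in report.contacts.items() if k != ("E112", "a"))

    def test_no_bridges_all_keys_empty(self, toy_model):
        report = hotspot_contacts([], toy_model)
        assert set(report.contacts) == {(h, lab) for h in DEFAULT_HOTSPOTS for lab in ("a", "b")}
        assert all(v == [] for v in report.contacts.values())

    def test_non_hotspot_bridge_stays_in_census_only(self):
        lig = [AtomRecord(1, "NZ", "LYS", "C", 50, (3.5, 0.0, 0.0), "N")]
        rec = [AtomRecord(2, "OE1", "GLU", "A", 55, (0.0, 0.0, 0.0), "O")]
        model = DockedComplexModel(
            1, ("A", "B"), ("C",), rec, lig, [], [], {"A": "a", "B": "b"}
        )
        bridges = find_salt_bridges(model)
        assert len(bridges) == 1
        report = hotspot_contacts(bridges, model)
        assert all(v == [] for v in report.contacts.values())

    def test_absent_hotspot_flagged(self):
        model = _bridge_model(3.5)  # receptor holds only E112
        report = hotspot_contacts([], model)
        assert "R101" in report.not_present and "E112" not in report.not_present

    def test_full_toy_complex_hotspots(self, toy_model):
        bridges = find_salt_bridges(toy_model)
        report = hotspot_contacts(bridges, toy_model)
        touched = {k for k, v in report.contacts.items() if v}
        assert touched == {("R101", "a"), ("E112", "b"), ("R140", "a")}
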