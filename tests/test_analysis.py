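"""Geometry and renumbering analyses against closed forms and brute-force oracles."""

import dataclasses
import itertools

import numpy as np
import pytest

from pdbkit import (
    Chain,
    FixtureSpec,
    Model,
    Residue,
    Structure,
    TraversalKind,
    WeightingScheme,
    canonical_axes,
    center_of_mass,
    chain_sequence,
    count,
    iter_nodes,
    radius_of_gyration,
    recenter,
    renumber_atoms,
    renumber_residues,
    structure_equal,
    synthetic_structure,
    write_structure,
)
from pdbkit.analysis import UnknownElementError
from conftest import make_atom


def coords_of(root):
    return np.array([a.coord for a in iter_nodes(root, TraversalKind.ATOM)])


def pairwise_distances(coords):
    return np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)


@pytest.fixture
def random_cloud():
    rng = np.random.default_rng(99)
    atoms = [
        make_atom(serial=i + 1, coord=rng.uniform(-30, 30, size=3)) for i in range(100)
    ]
    return Chain("A", residues=[Residue("GLY", 1, atoms=atoms)])


class TestCenterOfMass:
    def test_midpoint(self):
        chain = Chain("A", residues=[Residue("GLY", 1, atoms=[
            make_atom(serial=1, coord=(0, 0, 0)), make_atom(serial=2, coord=(2, 0, 0))])])
        np.testing.assert_allclose(center_of_mass(chain), [1.0, 0.0, 0.0])

    def test_singleton(self):
        atom = make_atom(coord=(3.0, -4.0, 5.5))
        np.testing.assert_allclose(center_of_mass(atom), [3.0, -4.0, 5.5])

    def test_uniform_matches_mean_oracle(self, random_cloud):
        np.testing.assert_allclose(
            center_of_mass(random_cloud), coords_of(random_cloud).mean(axis=0), atol=1e-9
        )

    def test_mass_weighted_matches_direct_formula(self):
        from pdbkit.analysis import ATOMIC_MASSES

        atoms = [
            make_atom(serial=1, coord=(0, 0, 0), element="C"),
            make_atom(serial=2, coord=(1, 0, 0), element="O", name="O"),
        ]
        chain = Chain("A", residues=[Residue("GLY", 1, atoms=atoms)])
        expected = ATOMIC_MASSES["O"] / (ATOMIC_MASSES["C"] + ATOMIC_MASSES["O"])
        np.testing.assert_allclose(
            center_of_mass(chain, WeightingScheme.ELEMENT_MASS), [expected, 0, 0]
        )

    def test_unknown_element_raises_under_mass_weighting(self):
        atom = make_atom(element="XX")
        with pytest.raises(UnknownElementError):
            center_of_mass(atom, WeightingScheme.ELEMENT_MASS)

    def test_zero_atoms_is_error(self):
        with pytest.raises(ValueError, match="at least one atom"):
            center_of_mass(Structure())


class TestRecenter:
    def test_center_lands_at_origin(self, rich_structure):
        centered = recenter(rich_structure)
        assert np.linalg.norm(center_of_mass(centered)) < 1e-9

    def test_idempotent_within_tolerance(self, random_cloud):
        once = recenter(random_cloud)
        twice = recenter(once)
        assert np.abs(coords_of(once) - coords_of(twice)).max() < 1e-9

    def test_pairwise_distances_unchanged(self, random_cloud):
        before = pairwise_distances(coords_of(random_cloud))
        after = pairwise_distances(coords_of(recenter(random_cloud)))
        np.testing.assert_allclose(before, after, atol=1e-9)


class TestRenumberResidues:
    def test_consecutive_with_cleared_insertion_codes(self):
        chain = Chain("A", residues=[
            Residue("MET", 5, atoms=[make_atom(serial=1)]),
            Residue("GLY", 7, atoms=[make_atom(serial=2)]),
            Residue("ALA", 7, ins_code="A", atoms=[make_atom(serial=3)]),
            Residue("SER", 8, atoms=[make_atom(serial=4)]),
        ])
        renumbered = renumber_residues(chain, start=1)
        assert [r.res_seq for r in renumbered.residues] == [1, 2, 3, 4]
        assert all(r.ins_code == " " for r in renumbered.residues)

    def test_empty_chain(self):
        assert renumber_residues(Chain("A")).residues == []

    def test_begins_anew_per_chain(self):
        model = synthetic_structure(
            FixtureSpec(n_models=1, chains_per_model=2, residues_per_chain=3, seed=1)
        ).models[0]
        chains = [renumber_residues(c, start=1) for c in model.chains]
        assert all(c.residues[0].res_seq == 1 for c in chains)

    def test_idempotent(self, rich_structure):
        chain = rich_structure.models[0].chains[0]
        once = renumber_residues(chain)
        assert structure_equal(
            Structure(models=[Model(1, [once])]),
            Structure(models=[Model(1, [renumber_residues(once)])]),
            0.0,
        )


class TestRenumberAtoms:
    def model_3_plus_2(self):
        def chain(cid, n, base):
            return Chain(cid, residues=[Residue("GLY", 1, atoms=[
                make_atom(serial=base + i) for i in range(n)])])

        return Model(1, chains=[chain("A", 3, 10), chain("B", 2, 40)])

    def test_ter_consumes_a_serial(self):
        renumbered = renumber_atoms(self.model_3_plus_2())
        serials = [a.serial for a in iter_nodes(renumbered, TraversalKind.ATOM)]
        assert serials == [1, 2, 3, 5, 6]  # TER takes 4 and 7

    def test_written_ter_serials_match_hand_simulation(self):
        text = write_structure(Structure(models=[renumber_atoms(self.model_3_plus_2())]))
        ter_serials = [
            int(line[6:11]) for line in text.splitlines() if line.startswith("TER")
        ]
        assert ter_serials == [4, 7]

    def test_single_atom_chain(self, two_atom_chain):
        structure = Structure(models=[Model(1, [two_atom_chain])])
        renumbered = renumber_atoms(structure)
        serials = [a.serial for a in iter_nodes(renumbered, TraversalKind.ATOM)]
        assert serials == [1, 2]
        assert "TER   " + f"{3:5d}" in write_structure(renumbered)

    def test_counter_restarts_per_model(self):
        structure = synthetic_structure(FixtureSpec(n_models=2, seed=5))
        renumbered = renumber_atoms(structure)
        for model in renumbered.models:
            first = next(iter_nodes(model, TraversalKind.ATOM))
            assert first.serial == 1

    def test_idempotent_and_shape_preserving(self, rich_structure):
        once = renumber_atoms(rich_structure)
        twice = renumber_atoms(once)
        assert structure_equal(once, twice, 0.0)
        assert count(once, TraversalKind.ATOM) == count(rich_structure, TraversalKind.ATOM)

    def test_hetatm_only_chain_consumes_no_ter_serial(self):
        model = Model(1, chains=[
            Chain("W", residues=[Residue("HOH", 1, atoms=[
                make_atom(name="O", element="O", is_hetatm=True)])]),
            Chain("A", residues=[Residue("GLY", 1, atoms=[make_atom()])]),
        ])
        serials = [a.serial for a in iter_nodes(renumber_atoms(model), TraversalKind.ATOM)]
        assert serials == [1, 2]  # no TER after the water chain


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(make_atom(coord=(5, 5, 5))) == 0.0

    def test_unit_pair_closed_form(self, two_atom_chain):
        assert radius_of_gyration(two_atom_chain) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, random_cloud):
        coords = coords_of(random_cloud)
        centered = coords - coords.mean(axis=0)
        expected = np.sqrt((centered**2).sum(axis=1).mean())
        assert radius_of_gyration(random_cloud) == pytest.approx(expected, abs=1e-9)

    def test_translation_and_rotation_invariant(self, random_cloud):
        base = radius_of_gyration(random_cloud)
        shifted = recenter(random_cloud)
        assert radius_of_gyration(shifted) == pytest.approx(base, abs=1e-9)
        structure = Structure(models=[Model(1, [random_cloud])])
        rotated, _ = canonical_axes(structure)
        assert radius_of_gyration(rotated) == pytest.approx(base, abs=1e-9)


class TestCanonicalAxes:
    def test_two_atom_pair_lands_on_y_axis(self, two_atom_chain):
        structure = Structure(models=[Model(1, [two_atom_chain])])
        oriented, transform = canonical_axes(structure)
        coords = coords_of(oriented)
        np.testing.assert_allclose(np.abs(coords[:, 1]), [1.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(coords[:, [0, 2]], 0.0, atol=1e-9)
        assert abs(np.linalg.det(transform.rotation) - 1.0) < 1e-9

    def test_already_canonical_is_near_identity(self):
        atoms = [
            make_atom(serial=1, coord=(0.0, -10.0, 0.0)),
            make_atom(serial=2, coord=(0.0, 10.0, 0.0)),
            make_atom(serial=3, coord=(3.0, 0.0, 0.0)),
            make_atom(serial=4, coord=(-3.0, 0.0, 0.0)),
        ]
        structure = Structure(models=[Model(1, [Chain("A", [Residue("GLY", 1, atoms=atoms)])])])
        oriented, transform = canonical_axes(structure)
        np.testing.assert_allclose(np.abs(transform.rotation), np.eye(3), atol=1e-9)
        np.testing.assert_allclose(coords_of(oriented), coords_of(structure), atol=1e-9)

    def test_rigid_and_max_pair_along_y(self, rich_structure):
        oriented, _ = canonical_axes(rich_structure)
        before, after = coords_of(rich_structure), coords_of(oriented)
        np.testing.assert_allclose(
            pairwise_distances(before), pairwise_distances(after), atol=1e-6
        )
        # brute-force max-distance pair of the output differs only in y
        d = pairwise_distances(after)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert abs(after[i, 0] - after[j, 0]) < 1e-6
        assert abs(after[i, 2] - after[j, 2]) < 1e-6

    def test_cross_section_principal_direction_on_x(self):
        rng = np.random.default_rng(7)
        # elongated along a random direction, wide along a second one
        n = 60
        axis1 = np.array([1.0, 2.0, 2.0]) / 3.0
        axis2 = np.array([2.0, -2.0, 1.0]) / 3.0
        axis3 = np.cross(axis1, axis2)
        t = rng.normal(size=(n, 3)) * np.array([20.0, 6.0, 1.0])
        coords = t[:, [0]] * axis1 + t[:, [1]] * axis2 + t[:, [2]] * axis3
        atoms = [make_atom(serial=i + 1, coord=c) for i, c in enumerate(coords)]
        structure = Structure(models=[Model(1, [Chain("A", [Residue("GLY", 1, atoms=atoms)])])])
        oriented, _ = canonical_axes(structure)
        after = coords_of(oriented)
        projected = after[:, [0, 2]]
        moment = projected.T @ projected
        eigvals, eigvecs = np.linalg.eigh(moment)
        principal = eigvecs[:, np.argmax(eigvals)]
        # principal direction of the XZ projection is the X axis
        assert abs(abs(principal[0]) - 1.0) < 1e-9

    def test_fewer_than_two_atoms_is_error(self):
        structure = Structure(models=[Model(1, [Chain("A", [Residue("GLY", 1, [make_atom()])])])])
        with pytest.raises(ValueError, match="two atoms"):
            canonical_axes(structure)


class TestChainSequence:
    def test_standard_translation(self):
        chain = Chain("A", residues=[
            Residue(name, i + 1, atoms=[make_atom(serial=i + 1)])
            for i, name in enumerate(["ALA", "GLY", "MET"])
        ])
        assert chain_sequence(chain) == "AGM"

    def test_unknown_residue_is_x_and_water_skipped(self):
        chain = Chain("A", residues=[
            Residue("XYZ", 1, atoms=[make_atom(serial=1)]),
            Residue("HOH", 2, atoms=[make_atom(serial=2, name="O", is_hetatm=True)]),
            Residue("TRP", 3, atoms=[make_atom(serial=3)]),
        ])
        assert chain_sequence(chain) == "XW"

    def test_nucleotides(self):
        chain = Chain("B", residues=[
            Residue(name, i + 1, atoms=[make_atom(serial=i + 1)])
            for i, name in enumerate(["DA", "DC", "DG", "DT", "U"])
        ])
        assert chain_sequence(chain) == "ACGTU"

    def test_empty_chain(self):
        assert chain_sequence(Chain("A")) == ""
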