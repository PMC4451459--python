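"""Structure metrics: H-bonds, helix assignment, ASA, contacts, RCO,
circular permutation, superposition RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldperm as fp
from foldperm.structure import hbond_energy_from_distances, place_amide_hydrogen
from foldperm.synthetic import (
    ToyStructureSpec,
    build_death_domain_mimic,
    build_toy_structure,
    bundle_contact_map,
    long_range_contact_map,
)


# ------------------------------------------------------------- hydrogen bonds

class TestHbondEnergy:
    def test_direct_arithmetic(self):
        # 27.888 * (1/3 + 1/4 - 1/2 - 1/5)
        e = hbond_energy_from_distances(3.0, 4.0, 2.0, 5.0)
        assert e == pytest.approx(27.888 * (1 / 3 + 1 / 4 - 1 / 2 - 1 / 5), rel=1e-12)
        assert e == pytest.approx(-3.254, abs=1e-3)

    def test_equal_distances_cancel(self):
        assert hbond_energy_from_distances(2.9, 2.9, 2.9, 2.9) == 0.0

    def test_distant_pair_below_bond_threshold(self):
        # donor and acceptor ~20 A apart: all four reciprocals are ~1/20
        e = hbond_energy_from_distances(20.0, 20.5, 19.0, 21.5)
        assert abs(e) < 0.5

    def test_proline_donor_unassignable(self):
        h = build_toy_structure(ToyStructureSpec(12, "ideal_helix"))
        pro = fp.Residue(99, "PRO", dict(h.residues[5].atoms))
        assert fp.hbond_energy(pro, h.residues[1]) is None

    def test_ideal_helix_i_to_i_plus_4_bond_is_strong(self):
        h = build_toy_structure(ToyStructureSpec(12, "ideal_helix"))
        res = h.residues
        hcoord = place_amide_hydrogen(res[4], res[5])
        e = fp.hbond_energy(res[5], res[1], h_coord=hcoord)
        assert e is not None and e < -0.5


class TestAssignHelices:
    def test_missing_backbone_oxygen_reported_unassignable(self):
        h = build_toy_structure(ToyStructureSpec(12, "ideal_helix"))
        k = 5
        broken = fp.ProteinStructure([
            fp.Residue(r.index, r.name,
                       {n: c for n, c in r.atoms.items()
                        if not (r.index == k + 1 and n == "O")})
            for r in h.residues
        ])
        labels, count = fp.assign_helices(broken)
        assert labels[k] == "?"
        assert count < 10  # the break removes turns through residue k

    def test_short_chain_warns_and_returns_zero(self):
        s = build_toy_structure(ToyStructureSpec(4, "ideal_helix"))
        with pytest.warns(UserWarning, match="shorter than 5"):
            labels, count = fp.assign_helices(s)
        assert count == 0

    def test_death_domain_mimic_has_73_helical_residues(self):
        """Six ideal helices sized like the death-domain fold (16, 13,
        12, 16, 14, 14 residues) carry exactly 73 assignable helical
        residues: each helix of length n contributes n - 2."""
        mimic = build_death_domain_mimic()
        labels, count = fp.assign_helices(mimic)
        assert count == 73

    def test_round_trip_through_pdb_preserves_assignment(self, tmp_path):
        mimic = build_death_domain_mimic()
        path = tmp_path / "mimic.pdb"
        fp.write_structure(mimic, path)
        reread = fp.read_structure(path)
        assert fp.assign_helices(reread)[1] == fp.assign_helices(mimic)[1]


# ------------------------------------------------------------------ PDB I/O

class TestReadStructure:
    def test_round_trip_coordinates(self, tmp_path):
        s = build_toy_structure(ToyStructureSpec(8, "random_coil", seed=3))
        path = tmp_path / "coil.pdb"
        fp.write_structure(s, path)
        r = fp.read_structure(path)
        assert len(r) == 8
        for a, b in zip(s.residues, r.residues):
            for name in a.atoms:
                np.testing.assert_allclose(a.atoms[name], b.atoms[name],
                                           atol=1e-2)  # PDB has 3 decimals

    def test_missing_model_rejected(self, tmp_path):
        s = build_toy_structure(ToyStructureSpec(8, "ideal_helix"))
        path = tmp_path / "one_model.pdb"
        fp.write_structure(s, path)
        with pytest.raises(ValueError, match="model 2"):
            fp.read_structure(path, model=2)

    def test_insertion_codes_rejected(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  N   ALA A   1A      3.000   1.000   0.000  1.00  0.00           N\n"
            "END\n")
        path = tmp_path / "icode.pdb"
        path.write_text(pdb)
        with pytest.raises(ValueError, match="insertion code"):
            fp.read_structure(path)


# --------------------------------------------------------------------- ASA

class TestAccessibleSurfaceArea:
    def test_isolated_carbon_matches_sphere_area_within_1_percent(self):
        s = fp.ProteinStructure(
            [fp.Residue(1, "GLY", {"CA": [0.0, 0.0, 0.0]}, {"CA": "C"})])
        asa = fp.accessible_surface_area(s, n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert asa[1] == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_has_zero_area(self):
        from foldperm.structure import _fibonacci_sphere

        # dense shell of occluders 2 A from a central carbon
        shell = _fibonacci_sphere(60) * 2.0
        s = fp.ProteinStructure([
            fp.Residue(1, "GLY", {"CA": np.zeros(3)}, {"CA": "C"}),
            fp.Residue(2, "XXX", {f"S{i}": c for i, c in enumerate(shell)},
                       {f"S{i}": "C" for i in range(len(shell))}),
        ])
        asa = fp.accessible_surface_area(s, residue_selection=[1],
                                         n_sphere_points=480)
        assert asa[1] == 0.0

    def test_symmetric_pair_loses_equal_spherical_caps(self):
        # analytic oracle: each sphere loses a cap of area 2 pi R h,
        # h = R - d/2, when two equal spheres overlap at distance d < 2R
        r_ext = 1.7 + 1.4
        d = 2 * r_ext - 0.4
        s = fp.ProteinStructure([
            fp.Residue(1, "GLY", {"CA": [0.0, 0.0, 0.0]}, {"CA": "C"}),
            fp.Residue(2, "GLY", {"CA": [d, 0.0, 0.0]}, {"CA": "C"}),
        ])
        asa = fp.accessible_surface_area(s, n_sphere_points=3000)
        h = r_ext - d / 2
        exact = 4 * np.pi * r_ext**2 - 2 * np.pi * r_ext * h
        assert asa[1] == pytest.approx(exact, rel=0.01)
        # point-lattice discretisation breaks exact mirror symmetry
        assert asa[1] == pytest.approx(asa[2], rel=0.01)

    def test_occlusion_monotone_under_added_atoms(self):
        base = build_toy_structure(ToyStructureSpec(6, "ideal_helix"))
        asa_before = fp.accessible_surface_area(base, n_sphere_points=240)
        extra = fp.Residue(7, "GLY", {"CA": base.residues[3].atoms["CA"]
                                      + np.array([4.0, 0, 0])}, {"CA": "C"})
        grown = fp.ProteinStructure(base.residues + [extra])
        asa_after = fp.accessible_surface_area(grown, n_sphere_points=240)
        for idx in asa_before:
            assert asa_after[idx] <= asa_before[idx] + 1e-9

    def test_agrees_with_independent_implementation(self):
        # cross-check against biotite's Shrake-Rupley on a toy helix
        import biotite.structure as struc

        helix = build_toy_structure(ToyStructureSpec(12, "ideal_helix"))
        n_atoms = sum(len(r.atoms) for r in helix.residues)
        arr = struc.AtomArray(n_atoms)
        i = 0
        for r in helix.residues:
            for name, coord in r.atoms.items():
                arr.coord[i] = coord
                arr.res_id[i] = r.index
                arr.res_name[i] = r.name
                arr.atom_name[i] = name
                arr.element[i] = r.elements[name]
                arr.chain_id[i] = "A"
                i += 1
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii="Single").sum()
        ours = sum(fp.accessible_surface_area(helix, n_sphere_points=960).values())
        assert ours == pytest.approx(ref, rel=0.01)


# ------------------------------------------------------- contacts & topology

def brute_force_rco(cmap, weighting="atom_pairs"):
    """Independent enumeration of RCO: explicit loop over contacts."""
    total = 0.0
    n = 0
    for i, j, pairs in cmap.contacts:
        w = pairs if weighting == "atom_pairs" else 1
        total += w * abs(i - j)
        n += w
    return total / (cmap.chain_length * n)


class TestContactMap:
    def test_cutoff_boundary(self):
        mk = lambda d: fp.ProteinStructure([
            fp.Residue(1, "GLY", {"CA": [0.0, 0.0, 0.0]}),
            fp.Residue(2, "GLY", {"CA": [0.0, 0.0, 100.0]}),
            fp.Residue(3, "GLY", {"CA": [d, 0.0, 0.0]}),
        ])
        assert fp.contact_map(mk(5.9), cutoff=6.0, min_seq_sep=2).contacts == \
            [(1, 3, 1)]
        assert fp.contact_map(mk(6.1), cutoff=6.0, min_seq_sep=2).contacts == []

    def test_extended_chain_map_is_near_empty(self):
        s = build_toy_structure(ToyStructureSpec(12, "extended"))
        cm = fp.contact_map(s, cutoff=6.0, min_seq_sep=2)
        # a strand has no contacts beyond nearest non-adjacent neighbours
        assert all(j - i == 2 for i, j, _ in cm.contacts)

    def test_hydrogens_excluded_from_heavy_atom_contacts(self):
        s = fp.ProteinStructure([
            fp.Residue(1, "GLY", {"CA": [0.0, 0.0, 0.0], "HA": [3.0, 0, 0]},
                       {"CA": "C", "HA": "H"}),
            fp.Residue(3, "GLY", {"CA": [12.0, 0.0, 0.0], "HA": [5.0, 0, 0]},
                       {"CA": "C", "HA": "H"}),
        ])
        assert fp.contact_map(s, cutoff=6.0, min_seq_sep=1).contacts == []


class TestRelativeContactOrder:
    def test_single_contact_closed_form(self):
        cm = fp.ContactMap(4, [(1, 4, 1)], 6.0)
        assert fp.relative_contact_order(cm) == pytest.approx(0.75)

    def test_two_contact_enumeration(self):
        cm = fp.ContactMap(5, [(1, 5, 1), (2, 4, 1)], 6.0)
        assert fp.relative_contact_order(cm) == pytest.approx(0.6)

    def test_all_local_map_closed_form(self):
        sep = 3
        L = 15
        cm = fp.ContactMap(L, [(i, i + sep, 2) for i in range(1, L - sep + 1)], 6.0)
        assert fp.relative_contact_order(cm) == pytest.approx(sep / L)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fp.relative_contact_order(fp.ContactMap(5, [], 6.0))

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_on_small_maps(self, data):
        L = data.draw(st.integers(4, 20))
        pairs = data.draw(st.sets(
            st.tuples(st.integers(1, L), st.integers(1, L)).map(
                lambda t: (min(t), max(t))).filter(lambda t: t[0] < t[1]),
            min_size=1, max_size=25))
        contacts = [(i, j, data.draw(st.integers(1, 9))) for i, j in sorted(pairs)]
        cm = fp.ContactMap(L, contacts, 6.0)
        for w in ("atom_pairs", "residue_pairs"):
            assert fp.relative_contact_order(cm, w) == \
                pytest.approx(brute_force_rco(cm, w), rel=1e-12)

    def test_sequence_reversal_leaves_rco_unchanged(self):
        cm, _ = bundle_contact_map()
        L = cm.chain_length
        rev = fp.ContactMap(
            L, sorted((min(L + 1 - i, L + 1 - j), max(L + 1 - i, L + 1 - j), n)
                      for i, j, n in cm.contacts), cm.cutoff)
        assert fp.relative_contact_order(rev) == \
            pytest.approx(fp.relative_contact_order(cm), rel=1e-12)


class TestCircularPermute:
    def test_identity_permutation(self):
        cm = fp.ContactMap(5, [(1, 5, 2), (2, 4, 1)], 6.0)
        out = fp.circular_permute(cm, fp.PermutationSpec(1))
        assert out.contacts == cm.contacts
        assert out.chain_length == 5

    def test_terminal_contact_becomes_local(self):
        cm = fp.ContactMap(5, [(1, 5, 1)], 6.0)
        out = fp.circular_permute(cm, fp.PermutationSpec(3))
        assert out.contacts == [(3, 4, 1)]

    @pytest.mark.parametrize("p", range(1, 8))
    def test_inverse_permutation_restores_map_at_L7(self, p):
        cm = fp.ContactMap(7, [(1, 7, 3), (2, 5, 1), (3, 7, 2), (1, 4, 1)], 6.0)
        once = fp.circular_permute(cm, fp.PermutationSpec(p))
        # permuting by p then by L - p + 2 is the identity
        inv = 7 - p + 2 if p > 1 else 1
        back = fp.circular_permute(once, fp.PermutationSpec(inv))
        assert sorted(back.contacts) == sorted(cm.contacts)

    @pytest.mark.parametrize("p", range(1, 8))
    def test_preserves_length_count_and_weights_at_L7(self, p):
        cm = fp.ContactMap(7, [(1, 7, 3), (2, 5, 1), (3, 7, 2), (1, 4, 1)], 6.0)
        out = fp.circular_permute(cm, fp.PermutationSpec(p))
        assert out.chain_length == cm.chain_length
        assert len(out) == len(cm)
        assert sorted(n for _, _, n in out.contacts) == \
            sorted(n for _, _, n in cm.contacts)

    def test_linker_extends_chain_without_adding_contacts(self):
        cm = fp.ContactMap(10, [(1, 10, 1), (4, 8, 2)], 6.0)
        out = fp.circular_permute(cm, fp.PermutationSpec(4, linker_length=5))
        assert out.chain_length == 15
        assert len(out) == 2
        # linker positions (11..15 after the wrapped block shift) are empty
        touched = {i for c in out.contacts for i in c[:2]}
        assert touched <= set(range(1, 16))

    def test_helix_bundle_rco_insensitive_to_loop_permutation(self):
        """Permuting a helix-dominated bundle map at any inter-helix loop
        changes RCO by < 10%; a long-range-only (sandwich-like) map
        changes by > 50% at its central cut."""
        cmap, loop_cuts = bundle_contact_map()
        base = fp.relative_contact_order(cmap)
        for p in loop_cuts:
            permuted = fp.circular_permute(cmap, fp.PermutationSpec(p))
            rco = fp.relative_contact_order(permuted)
            assert abs(rco - base) / base < 0.10
        lr = long_range_contact_map()
        base_lr = fp.relative_contact_order(lr)
        cut = lr.chain_length // 2
        rco_lr = fp.relative_contact_order(
            fp.circular_permute(lr, fp.PermutationSpec(cut)))
        assert abs(rco_lr - base_lr) / base_lr > 0.50


# -------------------------------------------------------------------- RMSD

def brute_force_rmsd(a, b, seeds=27):
    """Rotation-search oracle: Nelder-Mead over Euler angles from a grid
    of starting orientations; independent of the SVD solution."""
    from scipy.optimize import minimize

    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def objective(angles):
        ax, ay, az = angles
        rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        rz = np.array([[np.cos(az), -np.sin(az), 0],
                       [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        r = rz @ ry @ rx
        return np.sqrt(((a0 @ r.T - b0) ** 2).sum() / len(a0))

    starts = [np.array([i, j, k]) for i in (0.0, 2.1, 4.2)
              for j in (0.0, 2.1, 4.2) for k in (0.0, 2.1, 4.2)]
    return min(minimize(objective, s, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12}).fun
               for s in starts)


class TestKabschRmsd:
    def test_identical_sets(self):
        a = np.random.default_rng(1).normal(size=(8, 3))
        assert fp.kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        b = a @ rot.T + np.array([3.0, -2.0, 7.0])
        assert fp.kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-8)

    def test_displaced_square_corner_matches_rotation_search_oracle(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        b = a.copy()
        b[2, 2] = 1.0
        assert fp.kabsch_rmsd(a, b) == pytest.approx(
            brute_force_rmsd(a, b), abs=1e-3)

    def test_reflection_not_allowed(self):
        # mirror image of a chiral set cannot superpose to zero
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        b = a.copy()
        b[:, 2] *= -1
        assert fp.kabsch_rmsd(a, b) > 0.1
        assert fp.kabsch_rmsd(a, b) == pytest.approx(
            brute_force_rmsd(a, b), abs=1e-3)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            fp.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
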