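"""Molecule model, encoding round-trips, bond inference and graph features."""

import numpy as np
import pytest

from diffmcgen.chem_io import (ChemIOError, Molecule, QM9_ALPHABET,
                               check_validity, compute_global_features,
                               decode_graph, encode_graph,
                               infer_bonds_from_distances, parse_smiles,
                               read_sdf, read_smiles_file, read_xyz, write_sdf,
                               write_smiles_file, write_xyz)


class TestParseSmiles:
    def test_single_carbon(self):
        m = parse_smiles("C")
        assert m.atoms == ["C"] and not m.bonds

    def test_benzene_aromatic(self):
        m = parse_smiles("c1ccccc1")
        assert len(m.atoms) == 6
        assert len(m.bonds) == 6
        assert all(order == "aromatic" for _, _, order in m.bonds)

    def test_cyclopropane_graph(self):
        # hand enumeration: 3 atoms, 3 single bonds forming one 3-cycle
        m = parse_smiles("C1CC1")
        assert len(m.atoms) == 3 and len(m.bonds) == 3
        assert all(order == "single" for _, _, order in m.bonds)
        degree = [0, 0, 0]
        for i, j, _ in m.bonds:
            degree[i] += 1
            degree[j] += 1
        assert degree == [2, 2, 2]

    def test_unparsable_raises_with_input(self):
        with pytest.raises(ChemIOError, match="xx\\("):
            parse_smiles("xx(")
        with pytest.raises(ChemIOError):
            parse_smiles("")


class TestEncodeDecode:
    def test_methane_heavy_atom_encoding(self):
        g = encode_graph(parse_smiles("C"), n_max=4)
        assert g.X[0, QM9_ALPHABET.atom_index("C")] == 1.0
        assert g.E[0, 0, 0] == 1.0            # self-loop is "none"
        assert g.mask.tolist() == [True, False, False, False]

    def test_ethane_single_bond_symmetric(self):
        g = encode_graph(parse_smiles("CC"), n_max=4)
        k = QM9_ALPHABET.bond_index("single")
        assert g.E[0, 1, k] == 1.0 and g.E[1, 0, k] == 1.0

    def test_roundtrip_canonical_smiles(self, fixture20):
        for m in fixture20.molecules:
            g = encode_graph(m, n_max=16)
            assert decode_graph(g).to_smiles() == m.to_smiles()

    def test_invariants_after_encode(self, fixture20):
        for m in fixture20.molecules[:10]:
            g = encode_graph(m, n_max=16)
            assert np.allclose(g.X[g.mask].sum(-1), 1.0)
            assert np.array_equal(g.E, g.E.transpose(1, 0, 2))
            assert np.all(g.X[~g.mask] == 0.0)

    def test_soft_argmax_decode(self):
        g = encode_graph(parse_smiles("CC"), n_max=2)
        soft = g.copy()
        soft.E[0, 1] = soft.E[1, 0] = [0.1, 0.2, 0.6, 0.05, 0.05]
        m = decode_graph(soft)
        assert m.bonds == {(0, 1, "double")}

    def test_disconnected_decode(self):
        g = encode_graph(parse_smiles("C"), n_max=2)
        g.mask[:] = True
        g.X[1, 0] = 1.0
        g.E[1, 1, 0] = g.E[0, 1, 0] = g.E[1, 0, 0] = 1.0
        m = decode_graph(g)
        assert m.n_atoms == 2 and not m.bonds

    def test_size_and_alphabet_errors(self):
        with pytest.raises(ChemIOError):
            encode_graph(parse_smiles("CCCCC"), n_max=3)
        with pytest.raises(ChemIOError):
            encode_graph(parse_smiles("CS"), n_max=8)  # S not in alphabet


class TestInferBonds:
    def test_two_carbons_bond_length(self):
        coords = np.array([[0.0, 0, 0], [1.54, 0, 0]])
        bonds = infer_bonds_from_distances(coords, ["C", "C"])
        assert bonds == {(0, 1, "single")}

    def test_two_carbons_too_far(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert infer_bonds_from_distances(coords, ["C", "C"]) == set()

    def test_water_geometry(self):
        ang = np.deg2rad(104.5)
        coords = np.array([[0.0, 0, 0],
                           [0.96, 0, 0],
                           [0.96 * np.cos(ang), 0.96 * np.sin(ang), 0]])
        bonds = infer_bonds_from_distances(coords, ["O", "H", "H"])
        assert {(i, j) for i, j, _ in bonds} == {(0, 1), (0, 2)}

    def test_nan_coordinates_rejected(self):
        with pytest.raises(ChemIOError):
            infer_bonds_from_distances(np.array([[np.nan, 0, 0]]), ["C"])

    def test_conformer_bond_recovery(self, fixture20):
        """>= 95% of declared bonds recovered from the relaxed conformer."""
        declared = recovered = 0
        for m in fixture20.molecules:
            inferred = {(i, j) for i, j, _ in
                        infer_bonds_from_distances(m.coords, m.atoms, tau=0.4)}
            for i, j, _ in m.bonds:
                declared += 1
                if (i, j) in inferred:
                    recovered += 1
        assert recovered / declared >= 0.95


class TestValidity:
    def test_benzene_valid(self):
        ok, reason = check_validity(parse_smiles("c1ccccc1"))
        assert ok and reason == ""

    def test_pentavalent_carbon_invalid(self):
        m = Molecule(atoms=["C", "C", "C", "C", "C", "C"],
                     bonds={(0, k, "single") for k in range(1, 6)})
        ok, reason = check_validity(m)
        assert not ok and "valence" in reason.lower()

    def test_charged_nitrogen_four_bonds_valid(self):
        m = Molecule(atoms=["N", "C", "C", "C", "C"], charges=[1, 0, 0, 0, 0],
                     bonds={(0, k, "single") for k in range(1, 5)})
        ok, _ = check_validity(m)
        assert ok


class TestFileFormats:
    def test_sdf_roundtrip(self, fixture20, tmp_path):
        path = tmp_path / "set.sdf"
        write_sdf(fixture20.molecules, path)
        back = read_sdf(path)
        assert [m.to_smiles() for m in back] == \
            [m.to_smiles() for m in fixture20.molecules]
        for a, b in zip(back, fixture20.molecules):
            assert np.allclose(a.coords, b.coords - b.coords.mean(0), atol=1e-3)

    def test_sdf_empty_file(self, tmp_path):
        path = tmp_path / "empty.sdf"
        path.write_text("")
        assert read_sdf(path) == []

    def test_sdf_bad_record_skipped(self, fixture20, tmp_path):
        path = tmp_path / "mixed.sdf"
        write_sdf(fixture20.molecules[:3], path)
        text = path.read_text().split("$$$$\n")
        # corrupt the middle record's counts line
        rec = text[1].splitlines()
        rec[3] = " 99 99  0  0  0  0  0  0  0  0999 V2000"
        text[1] = "\n".join(rec) + "\n"
        path.write_text("$$$$\n".join(text))
        with pytest.warns(UserWarning, match="record 1"):
            back = read_sdf(path)
        assert len(back) == 2

    def test_xyz_roundtrip(self, fixture20, tmp_path):
        path = tmp_path / "set.xyz"
        write_xyz(fixture20.molecules[:5], path)
        back = read_xyz(path)
        assert len(back) == 5
        for a, b in zip(back, fixture20.molecules):
            assert a.atoms == b.atoms
            assert np.allclose(a.coords, b.coords, atol=1e-3)
            assert not a.bonds

    def test_smiles_file_roundtrip(self, fixture20, tmp_path):
        path = tmp_path / "set.smi"
        write_smiles_file(fixture20.molecules[:5], path)
        back = read_smiles_file(path)
        assert [m.to_smiles() for m in back] == \
            [m.to_smiles() for m in fixture20.molecules[:5]]


class TestGlobalFeatures:
    def test_benzene_cycles_and_components(self):
        y = compute_global_features(encode_graph(parse_smiles("c1ccccc1"),
                                                 n_max=8))
        cycles = y[:4]                     # lengths 3..6
        assert cycles.tolist() == [0, 0, 0, 1]
        assert y[9] == 1.0                 # one connected component

    def test_path_graph_laplacian(self):
        # P3 Laplacian spectrum is {0, 1, 3}
        y = compute_global_features(encode_graph(parse_smiles("CCC"), n_max=4))
        eigs = y[4:9]
        assert np.allclose(eigs[:2], [1.0, 3.0], atol=1e-9)

    def test_disconnected_atoms(self):
        g = encode_graph(parse_smiles("C"), n_max=2)
        g.mask[:] = True
        g.X[1, 0] = 1.0
        g.E[1, 1, 0] = g.E[0, 1, 0] = g.E[1, 0, 0] = 1.0
        y = compute_global_features(g)
        assert y[:4].tolist() == [0, 0, 0, 0]
        assert y[9] == 2.0

    def test_permutation_invariance(self, fixture20):
        rng = np.random.default_rng(4)
        for m in fixture20.molecules[:5]:
            g = encode_graph(m, n_max=10)
            y0 = compute_global_features(g)
            perm = rng.permutation(10)
            gp = g.copy()
            gp.X = g.X[perm]
            gp.E = g.E[perm][:, perm]
            gp.mask = g.mask[perm]
            yp = compute_global_features(gp)
            assert np.allclose(y0, yp, atol=1e-9)
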