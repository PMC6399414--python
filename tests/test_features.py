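"""Descriptor correctness: composition, physicochemistry, geometry, triads,
Zernike invariants and feature-vector assembly."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from epibind import structure_io as sio
from epibind import features as ft
from epibind.structure_io import Patch, ResidueId

from conftest import mini_pdb, single_atom_residue


def _prepared_chain(residue_letters, spacing=5.0):
    """A straight chain of single-CA residues with chosen identities."""
    aa3 = {v: k for k, v in sio.RESIDUE_3TO1.items()}
    rows = [single_atom_residue("A", i + 1, aa3[l], (spacing * i, 0.0, 0.0))
            for i, l in enumerate(residue_letters)]
    rows.append(single_atom_residue("B", 1, "GLY", (0.0, 40.0, 0.0)))
    model = sio.parse_structure(mini_pdb(rows), {"A"}, {"B"})
    sio.compute_accessibility(model)
    graph = sio.surface_neighbor_graph(model)
    patch = Patch("antigen", tuple(ResidueId("A", i + 1, "")
                                   for i in range(len(residue_letters))))
    return model, graph, patch


class TestComposition:
    def test_counting_and_normalization(self):
        model, _, patch = _prepared_chain("AAGV")
        comp = ft.aa_composition(patch, model)
        assert comp[ft.AA_ORDER.index("A")] == pytest.approx(0.5)
        assert comp[ft.AA_ORDER.index("G")] == pytest.approx(0.25)
        assert comp[ft.AA_ORDER.index("V")] == pytest.approx(0.25)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(comp) == 3

    def test_single_residue_patch(self):
        model, _, patch = _prepared_chain("W")
        comp = ft.aa_composition(patch, model)
        assert comp[ft.AA_ORDER.index("W")] == 1.0


class TestPhysicochemistry:
    def test_residue_class_counts(self):
        model, _, patch = _prepared_chain("KDFH")
        _, _, _, aromatic, positive, negative = ft.physicochemical_counts(patch, model)
        assert aromatic == 2  # F, H
        assert positive == 2  # K, H
        assert negative == 1  # D

    def test_lone_lysine_is_positive_not_negative(self):
        model, _, patch = _prepared_chain("K")
        _, _, _, _, positive, negative = ft.physicochemical_counts(patch, model)
        assert (positive, negative) == (1.0, 0.0)

    def test_hydrophobic_carbon_excluded_near_exposed_acceptor(self):
        # a bare carbon 2.4 A from an exposed backbone O is not hydrophobic;
        # at 2.6 A it is (strict > 2.5 A rule)
        for dist, expected in ((2.4, 0.0), (2.6, 1.0)):
            rows = [
                ("A", 1, "GLY", [("CA", "C", (0.0, 0.0, 0.0)),
                                 ("O", "O", (dist, 0.0, 0.0))]),
                single_atom_residue("B", 1, "GLY", (0.0, 40.0, 0.0)),
            ]
            model = sio.parse_structure(mini_pdb(rows), {"A"}, {"B"})
            sio.compute_accessibility(model)
            patch = Patch("antigen", (ResidueId("A", 1, ""),))
            _, _, hydrophobic, _, _, _ = ft.physicochemical_counts(patch, model)
            assert hydrophobic == expected

    def test_phenylalanine_with_no_polar_atoms_nearby(self):
        # side-chain-only Phe: all carbons count, aromatic = 1
        rows = [
            ("A", 1, "PHE", [("CB", "C", (0.0, 0.0, 0.0)),
                             ("CG", "C", (1.5, 0.0, 0.0)),
                             ("CD1", "C", (2.3, 1.2, 0.0))]),
            single_atom_residue("B", 1, "GLY", (0.0, 40.0, 0.0)),
        ]
        model = sio.parse_structure(mini_pdb(rows), {"A"}, {"B"})
        sio.compute_accessibility(model)
        patch = Patch("antigen", (ResidueId("A", 1, ""),))
        donors, acceptors, hydrophobic, aromatic, _, _ = ft.physicochemical_counts(patch, model)
        assert (donors, acceptors) == (0.0, 0.0)
        assert hydrophobic == 3.0
        assert aromatic == 1.0


class TestGeometry:
    def test_collinear_patch_has_rank_one_spread(self):
        model, graph, patch = _prepared_chain("G" * 10)
        pc1, pc2, pc3, size, _ = ft.geometry_features(patch, model, graph)
        assert size == 10
        assert pc1 > 0
        assert pc2 == pytest.approx(0.0, abs=1e-9)
        assert pc3 == pytest.approx(0.0, abs=1e-9)

    def test_two_adjacent_residues_have_unit_density(self):
        model, graph, patch = _prepared_chain("GG")
        *_, density = ft.geometry_features(patch, model, graph)
        assert density == 1.0

    def test_pc_magnitudes_match_eigensolver(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3)) * np.array([3.0, 2.0, 0.5])
        expected = np.sqrt(np.sort(np.linalg.eig(np.cov(pts.T, bias=True))[0].real)[::-1])
        assert np.allclose(ft.pc_magnitudes(pts), expected, atol=1e-9)

    def test_translation_leaves_pcs_unchanged(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(9, 3))
        assert np.allclose(ft.pc_magnitudes(pts),
                           ft.pc_magnitudes(pts + np.array([100.0, -50.0, 7.0])),
                           atol=1e-9)


class TestRSA:
    def test_single_residue_stats_coincide(self, model, graph, interface):
        patch = Patch("antigen", interface.epitope.residues[:1])
        mx, mn, mean = ft.rsa_stats(patch, model)
        assert mx == mn == mean

    def test_mean_matches_hand_recomputation(self, model, interface):
        patch = interface.epitope
        by_hand = np.mean([
            min(model.residue_sasa(rid) / ft.MAX_ASA[model.residue_name(rid)], 1.2)
            for rid in patch.residues])
        *_, mean = ft.rsa_stats(patch, model)
        assert mean == pytest.approx(by_hand)

    def test_buried_residue_gives_zero_minimum(self, complex_bundle):
        model = sio.parse_structure(complex_bundle["pdb_text"], {"A"}, {"H"})
        sio.compute_accessibility(model)
        patch = Patch("antigen", tuple(model.residues[:3]))
        model.sasa[model.atoms_of_residue(patch.residues[0])] = 0.0
        _, mn, _ = ft.rsa_stats(patch, model)
        assert mn == 0.0


def _brute_force_triads(patch, model, graph):
    """Independent exhaustive triad enumeration."""
    counts = np.zeros(196)
    members = set(patch.residues)
    combos = [(a, b) for a in range(7) for b in range(a, 7)]
    for x in patch.residues:
        nbrs = [n for n in graph.neighbors(x) if n in members]
        for n1, n2 in itertools.combinations(sorted(nbrs), 2):
            c = ft.CONJOINT_CLASSES[model.residue_letter(x)]
            f = tuple(sorted((ft.CONJOINT_CLASSES[model.residue_letter(n1)],
                              ft.CONJOINT_CLASSES[model.residue_letter(n2)])))
            counts[c * 28 + combos.index(f)] += 1
    return counts / counts.sum() if counts.sum() else counts


class TestConjointTriads:
    def test_type_space_is_196(self):
        assert ft.N_TRIAD_TYPES == 7 * (7 * 8 // 2) == 196

    def test_linear_three_residue_patch_single_triad(self):
        # A-G-V: classes all 0; only the middle residue has two neighbors
        model, graph, patch = _prepared_chain("AGV")
        vec = ft.conjoint_triads(patch, model, graph)
        assert vec[0] == 1.0  # triad [0,0,0]
        assert vec.sum() == 1.0

    def test_star_patch_matches_brute_force(self):
        # center with 3 neighbors at 5 A; neighbors 8+ A apart pairwise
        rows = [
            single_atom_residue("A", 1, "TRP", (0.0, 0.0, 0.0)),
            single_atom_residue("A", 2, "ALA", (5.0, 0.0, 0.0)),
            single_atom_residue("A", 3, "ASP", (-2.5, 4.33, 0.0)),
            single_atom_residue("A", 4, "LYS", (-2.5, -4.33, 0.0)),
            single_atom_residue("B", 1, "GLY", (0.0, 40.0, 0.0)),
        ]
        model = sio.parse_structure(mini_pdb(rows), {"A"}, {"B"})
        sio.compute_accessibility(model)
        graph = sio.surface_neighbor_graph(model)
        patch = Patch("antigen", tuple(ResidueId("A", i, "") for i in (1, 2, 3, 4)))
        vec = ft.conjoint_triads(patch, model, graph)
        assert vec.sum() == pytest.approx(1.0)
        assert np.count_nonzero(vec) == 3  # three unordered flank pairs
        assert np.allclose(vec, _brute_force_triads(patch, model, graph))

    def test_fixture_patch_matches_brute_force(self, model, graph, interface):
        vec = ft.conjoint_triads(interface.epitope, model, graph)
        assert np.allclose(vec, _brute_force_triads(interface.epitope, model, graph))

    def test_no_two_neighbor_residue_gives_all_zero(self):
        model, graph, patch = _prepared_chain("GG")
        assert not ft.conjoint_triads(patch, model, graph).any()


class TestZernike:
    def test_descriptor_count_and_nonnegativity(self, model, interface):
        z = ft.zernike_descriptors(interface.epitope, model)
        assert z.shape == (7,)
        assert np.all(z >= 0)

    def test_rotation_and_translation_invariance(self, complex_bundle):
        model = sio.parse_structure(complex_bundle["pdb_text"], {"A"}, {"H"})
        sio.compute_accessibility(model)
        patch = complex_bundle["prep"].interface.epitope
        z0 = ft.zernike_descriptors(patch, model)
        coords = model.coords.copy()
        rot = Rotation.random(random_state=4).as_matrix()
        model.coords = coords @ rot.T + np.array([11.0, -3.0, 8.0])
        z1 = ft.zernike_descriptors(patch, model)
        # invariance to voxelization accuracy, relative to descriptor scale
        assert np.max(np.abs(z1 - z0)) <= 1e-3 * z0.max()

    def test_scale_invariance(self, complex_bundle):
        model = sio.parse_structure(complex_bundle["pdb_text"], {"A"}, {"H"})
        sio.compute_accessibility(model)
        patch = complex_bundle["prep"].interface.epitope
        z0 = ft.zernike_descriptors(patch, model)
        model.coords = model.coords * 2.0
        z2 = ft.zernike_descriptors(patch, model)
        assert np.max(np.abs(z2 - z0)) <= 1e-3 * z0.max()

    def test_degenerate_geometry_raises(self):
        rows = [single_atom_residue("A", i + 1, "GLY", (3.0 * i, 2.0 * i, 0.0))
                for i in range(4)]  # collinear
        rows.append(single_atom_residue("B", 1, "GLY", (0.0, 40.0, 0.0)))
        model = sio.parse_structure(mini_pdb(rows), {"A"}, {"B"})
        sio.compute_accessibility(model)
        patch = Patch("antigen", tuple(ResidueId("A", i + 1, "") for i in range(4)))
        with pytest.raises(ValueError, match="degenerate patch geometry"):
            ft.zernike_descriptors(patch, model)

    def test_uniform_ball_moments_match_quadrature(self):
        """Independent oracle: 1D radial quadrature for a centered ball.

        For occupancy = ball of radius a, all l > 0 descriptors vanish by
        spherical symmetry and the l = 0 ones reduce to
        (3/4pi) * Y00 * 4pi * int_0^a R_n0(r) r^2 dr.
        """
        grid = 64
        h = 2.0 / grid
        axis = (np.arange(grid) + 0.5) * h - 1.0
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        vox = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        a = 0.7
        inside = (vox ** 2).sum(axis=1) <= a * a
        z = ft.zernike_from_points(vox[inside], np.full(inside.sum(), h ** 3))

        from scipy.special import eval_jacobi

        y00 = 1.0 / math.sqrt(4.0 * math.pi)
        for i, (n, l) in enumerate(ft.ZERNIKE_ORDERS):
            if l > 0:
                assert z[i] < 5e-3
            else:
                val = quad(lambda r, n=n: math.sqrt(2 * n + 3)
                           * eval_jacobi(n // 2, 0, 0.5, 2 * r * r - 1) * r * r,
                           0, a)[0]
                expected = 3.0 * y00 * val
                assert z[i] == pytest.approx(abs(expected), rel=0.02, abs=1e-4)

    def test_centrosymmetric_shape_kills_odd_orders(self):
        # filled ball sampled on a symmetric lattice (exactly centrosymmetric):
        # odd-n descriptors vanish by parity
        grid = 32
        h = 2.0 / grid
        axis = (np.arange(grid) + 0.5) * h - 1.0
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[(pts ** 2).sum(axis=1) <= 0.8 ** 2]
        z = ft.zernike_from_points(pts, np.full(len(pts), h ** 3))
        idx31 = ft.ZERNIKE_ORDERS.index((3, 1))
        idx33 = ft.ZERNIKE_ORDERS.index((3, 3))
        assert z[idx31] < 0.01 * z.max()
        assert z[idx33] < 0.01 * z.max()


class TestAssembly:
    def test_layout_lengths(self):
        assert len(ft.feature_names("full")) == 471
        assert len(ft.feature_names("antigen")) == 237
        assert len(ft.feature_names("minimal")) == 62
        assert len(ft.feature_names("full")) - len(ft.feature_names("antigen")) == 234

    def test_assembled_vectors(self, complex_bundle):
        prep = complex_bundle["prep"]
        epi, para = prep.epitope_desc, prep.paratope_desc
        full = ft.assemble_feature_vector(epi, para, "full")
        antigen = ft.assemble_feature_vector(epi, None, "antigen")
        minimal = ft.assemble_feature_vector(epi, para, "minimal")
        assert full.shape == (471,)
        assert antigen.shape == (237,)
        assert minimal.shape == (62,)
        # antigen layout is exactly the antigen block of the full layout
        assert np.array_equal(full[:237], antigen)

    def test_full_layout_requires_paratope(self, complex_bundle):
        epi = complex_bundle["prep"].epitope_desc
        with pytest.raises(ValueError, match="paratope"):
            ft.assemble_feature_vector(epi, None, "full")

    def test_frequency_blocks_sum_to_one_or_zero(self, complex_bundle, graph, model):
        prep = complex_bundle["prep"]
        rng = np.random.default_rng(2)
        antigen_nodes = [r for r in graph.nodes if r.chain == "A"]
        for _ in range(10):
            k = int(rng.integers(1, 8))
            rids = tuple(sorted(rng.choice(len(antigen_nodes), size=k, replace=False)))
            patch = Patch("antigen", tuple(antigen_nodes[i] for i in rids))
            desc = ft.describe_patch(patch, model, graph)
            assert desc.aa_composition.sum() == pytest.approx(1.0, abs=1e-9)
            assert (desc.triads.sum() == pytest.approx(1.0, abs=1e-9)
                    or not desc.triads.any())
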