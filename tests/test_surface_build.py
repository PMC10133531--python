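"""Structure parsing, surface meshing, featurization and region masks."""

import numpy as np
import pytest

from surfaceid.atoms import AtomSet, parse_structure
from surfaceid.features import (compute_chemical_features,
                                compute_geometric_features,
                                standardize_features)
from surfaceid.mesh import (FEATURE_CHANNELS, compute_surface_mesh,
                            define_region)
from surfaceid.synthetic import make_icosphere

SINGLE_CA = (
    "ATOM      1  CA  ALA A   1      11.104   6.134   2.100  1.00  0.00"
    "           C\n"
)


def _atomset(coords, radii=None, charges=None, res="ALA", names=None):
    k = len(coords)
    coords = np.asarray(coords, dtype=float)
    return AtomSet(
        atom_id=np.arange(k),
        atom_name=np.asarray(names or ["CA"] * k, dtype=object),
        element=np.asarray(["C"] * k, dtype=object),
        coords=coords,
        residue_name=np.asarray([res] * k, dtype=object),
        residue_seq=np.arange(1, k + 1),
        insertion_code=np.asarray([""] * k, dtype=object),
        chain_id=np.asarray(["A"] * k, dtype=object),
        radius=np.asarray(radii if radii is not None else [1.7] * k, dtype=float),
        partial_charge=np.asarray(charges if charges is not None else [0.0] * k,
                                  dtype=float),
        hydropathy=np.full(k, 1.8),
        hbond_class=np.zeros(k, dtype=int),
    )


class TestParseStructure:
    def test_single_atom_record(self):
        atoms = parse_structure(SINGLE_CA)
        assert len(atoms) == 1
        assert atoms.residue_name[0] == "ALA"
        assert atoms.atom_name[0] == "CA"
        np.testing.assert_allclose(atoms.coords[0], [11.104, 6.134, 2.100])

    def test_toy_peptide_round_trip(self, toy_peptide, peptide_atoms):
        _, n_reported = toy_peptide
        assert len(peptide_atoms) == n_reported

    def test_malformed_coordinate_field_names_line(self):
        bad = SINGLE_CA.replace("11.104", "xx.104")
        with pytest.raises(ValueError, match="line 1"):
            parse_structure(bad)

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError, match="no atoms"):
            parse_structure(SINGLE_CA, chains=["Z"])

    def test_waters_excluded_by_default(self):
        text = SINGLE_CA + (
            "HETATM    2  O   HOH A   2      50.000  50.000  50.000  1.00"
            "  0.00           O\n")
        assert len(parse_structure(text)) == 1

    def test_kyte_doolittle_assignment(self, peptide_atoms):
        # residue 3 of the toy peptide is LEU (KD 3.8)
        leu = peptide_atoms.residue_seq == 3
        assert np.all(peptide_atoms.hydropathy[leu] == 3.8)


class TestComputeSurfaceMesh:
    def test_single_atom_sphere_area(self):
        atoms = _atomset([[0.0, 0.0, 0.0]], radii=[1.7])
        mesh = compute_surface_mesh(atoms, probe_radius=1.4,
                                    target_edge_len=0.5)
        analytic = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert abs(mesh.trimesh().area - analytic) / analytic < 0.10
        assert mesh.is_watertight()

    def test_far_apart_atoms_keep_largest_component(self):
        atoms = _atomset([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]],
                         radii=[1.7, 3.0])
        mesh = compute_surface_mesh(atoms, probe_radius=1.4,
                                    target_edge_len=0.8)
        assert mesh.is_watertight()
        # the surviving component encloses only the larger atom
        assert np.linalg.norm(mesh.vertices.mean(axis=0)
                              - [100.0, 0.0, 0.0]) < 1.0
        assert np.all(np.linalg.norm(mesh.vertices - [100.0, 0, 0],
                                     axis=1) < 10.0)

    def test_deterministic_rebuild(self, peptide_atoms):
        m1 = compute_surface_mesh(peptide_atoms, 1.4, 1.0)
        m2 = compute_surface_mesh(peptide_atoms, 1.4, 1.0)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.faces, m2.faces)

    def test_coincident_atoms_still_mesh(self):
        atoms = _atomset([[0.0, 0.0, 0.0]] * 3)
        mesh = compute_surface_mesh(atoms, 1.4, 0.8)
        assert mesh.is_watertight()

    def test_normals_unit_length(self, peptide_mesh):
        norms = np.linalg.norm(peptide_mesh.normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)


def _flat_square_mesh(n=9, spacing=1.0):
    """Regular triangulated square in the z=0 plane."""
    xs = np.arange(n) * spacing
    vv = np.array([[x, y, 0.0] for y in xs for x in xs])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    from surfaceid.mesh import SurfaceMesh
    return SurfaceMesh(vertices=vv, faces=np.asarray(faces),
                       normals=np.tile([0.0, 0.0, 1.0], (len(vv), 1)))


class TestGeometricFeatures:
    def test_flat_square_interior_mean_curvature_zero(self):
        mesh = _flat_square_mesh()
        compute_geometric_features(mesh)
        center = len(mesh.vertices) // 2   # interior vertex
        assert abs(mesh.channel("mean_curvature")[center]) < 0.05

    def test_icosphere_shape_index_is_convex_cap(self, icosphere):
        mesh = icosphere.copy()
        compute_geometric_features(mesh)
        si = mesh.channel("shape_index")
        assert si.mean() > 0.9
        assert np.all(si >= -1.0) and np.all(si <= 1.0)

    def test_dent_has_negative_shape_index(self):
        mesh = make_icosphere(subdivisions=3, radius=9.0)
        u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1,
                                           keepdims=True)
        ang = np.arccos(np.clip(u @ np.array([0.0, 0.0, 1.0]), -1, 1))
        dent = 2.0 * np.exp(-((ang * 9.0) ** 2) / (2 * 2.5 ** 2))
        mesh.vertices = (9.0 - dent)[:, None] * u
        mesh.normals = mesh.trimesh().vertex_normals.copy()
        compute_geometric_features(mesh)
        bottom = int(np.argmax(dent))
        assert mesh.channel("shape_index")[bottom] < 0

    def test_shape_index_bounded_on_rough_surface(self, feature_mesh):
        mesh = feature_mesh.copy()
        compute_geometric_features(mesh)
        si = mesh.channel("shape_index")
        assert np.all(si >= -1.0) and np.all(si <= 1.0)
        assert np.all(np.isfinite(si))


class TestChemicalFeatures:
    def test_zero_charges_give_zero_field(self):
        atoms = _atomset([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        mesh = compute_surface_mesh(atoms, 1.4, 0.8)
        compute_chemical_features(mesh, atoms)
        np.testing.assert_array_equal(mesh.channel("charge"), 0.0)

    def test_hydropathy_is_nearest_residue_lookup(self):
        atoms = _atomset([[0.0, 0.0, 0.0]], res="ILE")
        atoms.hydropathy[:] = 4.5
        mesh = compute_surface_mesh(atoms, 1.4, 0.8)
        compute_chemical_features(mesh, atoms)
        np.testing.assert_array_equal(mesh.channel("hydropathy"), 4.5)

    def test_charge_field_sign_follows_source(self):
        atoms = _atomset([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]],
                         charges=[1.0, -1.0])
        mesh = compute_surface_mesh(atoms, 1.4, 0.8)
        compute_chemical_features(mesh, atoms)
        charge = mesh.channel("charge")
        over_pos = mesh.vertices[:, 0] < 5.0
        over_neg = mesh.vertices[:, 0] > 15.0
        assert np.all(charge[over_pos] > 0)
        assert np.all(charge[over_neg] < 0)

    def test_standardization_contract(self, peptide_mesh):
        for i, name in enumerate(FEATURE_CHANNELS):
            x = peptide_mesh.features[:, i]
            if x.std() > 0:   # non-constant channels
                assert abs(x.mean()) < 1e-8
                assert abs(x.std() - 1.0) < 1e-6
        assert "standardization" in peptide_mesh.meta


class TestDefineRegion:
    def test_distant_reference_gives_empty_mask(self, peptide_mesh,
                                                peptide_atoms):
        far = peptide_atoms.transformed(np.eye(3), [500.0, 0.0, 0.0])
        mask = define_region(peptide_mesh, far, cutoff=3.5)
        assert len(mask) == 0

    def test_huge_cutoff_saturates(self, peptide_mesh, peptide_atoms):
        mask = define_region(peptide_mesh, peptide_atoms, cutoff=1e6)
        assert len(mask) == peptide_mesh.n_vertices

    def test_matches_exhaustive_distance_oracle(self, peptide_mesh):
        rng = np.random.default_rng(4)
        atoms = _atomset(rng.uniform(-2, 12, size=(6, 3)))
        mask = define_region(peptide_mesh, atoms, cutoff=3.5)
        # brute-force all-pairs oracle
        d = np.linalg.norm(peptide_mesh.vertices[:, None, :]
                           - atoms.coords[None, :, :], axis=2)
        np.testing.assert_array_equal(mask.vertex_flags, d.min(axis=1) <= 3.5)

    def test_empty_reference_is_an_error(self, peptide_mesh, peptide_atoms):
        empty = peptide_atoms.subset(np.zeros(len(peptide_atoms), dtype=bool))
        with pytest.raises(ValueError):
            define_region(peptide_mesh, empty, cutoff=3.5)


class TestRigidMotionEquivariance:
    """The features must follow the atoms under rigid motion.  The
    density grid is axis-aligned, so the invariant is exact for motions
    the grid supports (whole-voxel translations) and holds up to
    remeshing jitter for general rotations."""

    def test_exact_under_voxel_translation(self, peptide_atoms):
        from surfaceid.features import featurize
        mesh0 = featurize(compute_surface_mesh(peptide_atoms, 1.4, 1.0),
                          peptide_atoms)
        t = np.array([3.0, -2.0, 7.0])    # integer multiples of the pitch
        moved = peptide_atoms.transformed(np.eye(3), t)
        mesh1 = featurize(compute_surface_mesh(moved, 1.4, 1.0), moved)
        np.testing.assert_allclose(mesh1.vertices - t, mesh0.vertices,
                                   atol=1e-9)
        np.testing.assert_allclose(mesh1.features, mesh0.features, atol=1e-3)

    def test_surface_and_feature_statistics_under_rotation(self,
                                                           peptide_atoms):
        from scipy.spatial import cKDTree
        from surfaceid.features import featurize
        mesh0 = featurize(compute_surface_mesh(peptide_atoms, 1.4, 1.0),
                          peptide_atoms)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([3.0, -2.0, 7.0])
        moved = peptide_atoms.transformed(R, t)
        mesh1 = featurize(compute_surface_mesh(moved, 1.4, 1.0), moved)

        back = (mesh1.vertices - t) @ R   # map back onto mesh0's frame
        d, _ = cKDTree(back).query(mesh0.vertices)
        assert d.max() < 0.8              # same surface up to re-meshing
        for i in range(len(FEATURE_CHANNELS)):
            q0 = np.percentile(mesh0.features[:, i], [10, 50, 90])
            q1 = np.percentile(mesh1.features[:, i], [10, 50, 90])
            np.testing.assert_allclose(q1, q0, atol=0.2)
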