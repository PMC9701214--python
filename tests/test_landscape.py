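import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from confdyn.exceptions import (
    ChainBreakError,
    ClusteringError,
    DegenerateExtentError,
    MissingAtomError,
    ScalingError,
    SchemaError,
)
from confdyn.landscape import (
    DihedralMatrix,
    LandscapeModel,
    fit_landscape,
    free_energy_surface,
    kmeans_states,
    phi_psi_matrix,
    torsion,
)
from confdyn.structure_io import Ensemble, write_multimodel_pdb
from confdyn.synthetic import SyntheticSpec, ground_truth, simulate_ensemble

from .conftest import backbone_ensemble
from .oracles import gaussian_radial_profile_error, pca_by_eigendecomposition


class TestTorsion:
    def test_planar_anti_is_180(self):
        assert torsion([0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]) == pytest.approx(180.0)

    def test_reference_quadruplet_is_minus_90(self):
        p = ([1, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 1])
        assert torsion(*p) == pytest.approx(-90.0)
        mirrored = [np.array(q) * [1, 1, -1] for q in p]
        assert torsion(*mirrored) == pytest.approx(90.0)

    def test_batched_matches_scalar(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 4, 3))
        batched = torsion(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        for i in range(5):
            assert batched[i] == pytest.approx(
                float(torsion(pts[i, 0], pts[i, 1], pts[i, 2], pts[i, 3]))
            )


class TestPhiPsi:
    def test_build_measure_round_trip(self):
        ens = backbone_ensemble(np.full((2, 10), -60.0), np.full((2, 10), -45.0))
        mat = phi_psi_matrix(ens, "A")
        assert mat.values.shape == (2, 18)  # 2R - 2 columns
        for col, (num, kind) in zip(mat.values.T, mat.column_labels):
            expected = -60.0 if kind == "phi" else -45.0
            np.testing.assert_allclose(col, expected, atol=1e-6)

    def test_column_labels_cover_non_terminal_angles(self):
        ens = backbone_ensemble(np.full((1, 5), -135.0), np.full((1, 5), 135.0))
        labels = phi_psi_matrix(ens, "A").column_labels
        assert (1, "phi") not in labels and (5, "psi") not in labels
        assert (2, "phi") in labels and (1, "psi") in labels

    def test_cross_check_against_mdtraj(self, tmp_path):
        import mdtraj

        rng = np.random.default_rng(8)
        phi = rng.uniform(-150, -30, size=(4, 8))
        psi = rng.uniform(30, 150, size=(4, 8))
        ens = backbone_ensemble(phi, psi)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(ens, path)
        mat = phi_psi_matrix(ens, "A")
        traj = mdtraj.load(str(path))
        _, md_phi = mdtraj.compute_phi(traj)
        _, md_psi = mdtraj.compute_psi(traj)
        ours_phi = mat.values[:, [k == "phi" for _, k in mat.column_labels]]
        ours_psi = mat.values[:, [k == "psi" for _, k in mat.column_labels]]
        # 0.1 degree agreement: the PDB file quantizes coordinates to 3 decimals
        np.testing.assert_allclose(ours_phi, np.degrees(md_phi), atol=0.1)
        np.testing.assert_allclose(ours_psi, np.degrees(md_psi), atol=0.1)

    def test_missing_atom_and_chain_break_errors(self, reference_20):
        topo = [a for a in reference_20.topology if not (a.residue_number == 7 and a.atom_name == "CA")]
        idx = [i for i, a in enumerate(reference_20.topology) if a in topo]
        broken = Ensemble(topology=topo, coordinates=reference_20.coordinates[:, idx])
        with pytest.raises(MissingAtomError, match="residue 7"):
            phi_psi_matrix(broken, "A")

        topo2 = [a for a in reference_20.topology if a.residue_number != 7 or a.record_class == "hetero"]
        idx2 = [i for i, a in enumerate(reference_20.topology) if a in topo2]
        gapped = Ensemble(topology=topo2, coordinates=reference_20.coordinates[:, idx2])
        with pytest.raises(ChainBreakError, match="missing \\[7\\]"):
            phi_psi_matrix(gapped, "A")


def _matrix(values, label="c"):
    d = values.shape[1]
    labels = tuple((i // 2 + 1, "phi" if i % 2 else "psi") for i in range(d))
    return DihedralMatrix(values=values, column_labels=labels, condition_label=label)


class TestFitLandscape:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(13)
        pooled = rng.normal(size=(50, 6)) * rng.uniform(0.5, 3.0, 6)
        model = fit_landscape([_matrix(pooled)])
        w, comps = pca_by_eigendecomposition(pooled, k=2)
        np.testing.assert_allclose(model.explained_variance, w[:2], atol=1e-8)
        np.testing.assert_allclose(model.components, comps, atol=1e-8)
        np.testing.assert_allclose(model.all_eigenvalues, w, atol=1e-8)

    def test_line_embedded_in_high_dim_is_one_component(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=80)
        direction = rng.normal(size=7)
        pooled = np.outer(t, direction) + 5.0
        model = fit_landscape([_matrix(pooled)])
        assert model.explained_variance_ratio()[0] == pytest.approx(1.0, abs=1e-10)
        # projections collinear: PC2 scores vanish
        np.testing.assert_allclose(model.projections["c"][:, 1], 0.0, atol=1e-8)

    def test_shared_scaling_and_basis_over_conditions(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(30, 6))
        b = rng.normal(size=(20, 6)) + 2.0
        model = fit_landscape([_matrix(a, "a"), _matrix(b, "b")])
        pooled = np.vstack([a, b])
        np.testing.assert_allclose(model.scaling_mean, pooled.mean(axis=0))
        np.testing.assert_allclose(model.scaling_std, pooled.std(axis=0))
        assert model.projections["a"].shape == (30, 2)
        assert model.projections["b"].shape == (20, 2)
        # orthonormal rows
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(2), atol=1e-10
        )

    def test_total_variance_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(5)
        model = fit_landscape([_matrix(rng.normal(size=(40, 8)))])
        assert model.total_variance == pytest.approx(
            float(model.all_eigenvalues.sum()), rel=1e-8
        )

    def test_refit_is_bit_identical(self):
        rng = np.random.default_rng(19)
        vals = rng.normal(size=(25, 6))
        m1 = fit_landscape([_matrix(vals)])
        m2 = fit_landscape([_matrix(vals.copy())])
        np.testing.assert_array_equal(m1.components, m2.components)
        np.testing.assert_array_equal(m1.projections["c"], m2.projections["c"])

    def test_schema_and_scaling_errors(self):
        rng = np.random.default_rng(6)
        a = _matrix(rng.normal(size=(10, 6)), "a")
        bad = DihedralMatrix(
            values=rng.normal(size=(10, 6)),
            column_labels=tuple((i + 2, "phi") for i in range(6)),
            condition_label="b",
        )
        with pytest.raises(SchemaError):
            fit_landscape([a, bad])
        flat = rng.normal(size=(10, 6))
        flat[:, 2] = 7.0
        with pytest.raises(ScalingError, match="phi|psi"):
            fit_landscape([_matrix(flat)])

    def test_two_basin_projection_separates_states(self):
        """PC1 of a two-basin ensemble recovers the planted state labels."""
        spec = SyntheticSpec(
            n_residues=8, n_frames=2000, seed=21,
            basins=((-110.0, 110.0), (10.0, -10.0)),
            transition_matrix=((0.9, 0.1), (0.1, 0.9)),
            dihedral_noise_deg=10.0,
        )
        ens, real = simulate_ensemble(spec)
        truth = ground_truth(spec, real)
        mat = phi_psi_matrix(ens, "A", condition_label="x")
        model = fit_landscape([mat])
        pc1 = model.projections["x"][:, 0]
        split = (pc1 > np.mean([pc1[truth.state_sequence == 0].mean(),
                                pc1[truth.state_sequence == 1].mean()]))
        predicted = split.astype(int)
        acc = max(
            np.mean(predicted == truth.state_sequence),
            np.mean(1 - predicted == truth.state_sequence),
        )
        assert acc >= 0.99

    def test_sincos_mode_doubles_columns(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-170, 170, size=(30, 6))
        model = fit_landscape([_matrix(vals)], dihedral_mode="sincos")
        assert len(model.column_labels) == 12
        assert model.components.shape == (2, 12)


class TestFreeEnergySurface:
    def test_uniform_density_is_flat_zero(self):
        centers = np.array([[x, y] for x in (0.25, 0.75) for y in (0.25, 0.75)])
        projection = np.repeat(centers, 25, axis=0)
        fes = free_energy_surface(projection, bins=2)
        assert fes.grid.count() == 4
        np.testing.assert_allclose(fes.grid.compressed(), 0.0, atol=1e-12)

    def test_75_25_split_closed_form(self):
        projection = np.vstack(
            [np.tile([0.0, 0.0], (75, 1)), np.tile([1.0, 1.0], (25, 1))]
        )
        fes = free_energy_surface(projection, bins=2)
        occupied = np.sort(fes.grid.compressed())
        np.testing.assert_allclose(occupied, [0.0, np.log(3.0)], atol=1e-12)

    def test_gaussian_density_gives_quadratic_profile(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100_000, 2))
        fes = free_energy_surface(pts, bins=60)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=60)
        assert gaussian_radial_profile_error(fes, counts) <= 0.15

    def test_normalization_identity(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5000, 2))
        fes = free_energy_surface(pts, bins=20)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=20)
        p_max = counts.max() / counts.sum()
        assert float(np.exp(-fes.grid).sum() * p_max) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(DegenerateExtentError):
            free_energy_surface(np.tile([1.0, 2.0], (50, 1)))


def _model_with_projection(projections: dict) -> LandscapeModel:
    d = 4
    return LandscapeModel(
        column_labels=tuple((i + 1, "phi") for i in range(d)),
        scaling_mean=np.zeros(d),
        scaling_std=np.ones(d),
        components=np.eye(2, d),
        explained_variance=np.array([1.0, 0.5]),
        all_eigenvalues=np.array([1.0, 0.5, 0.1, 0.05]),
        total_variance=1.65,
        projections=projections,
    )


class TestKMeansStates:
    def test_three_point_masses_recovered_exactly(self):
        pts = np.vstack(
            [np.tile([-10.0, 0.0], (30, 1)), np.tile([0.0, 0.0], (30, 1)),
             np.tile([10.0, 0.0], (30, 1))]
        )
        model = _model_with_projection({"c": pts})
        centers, labels, occ = kmeans_states(model, k=3, seed=0)
        np.testing.assert_allclose(centers[:, 0], [-10.0, 0.0, 10.0], atol=1e-12)
        assert occ["c"] == {"A": pytest.approx(1 / 3), "B": pytest.approx(1 / 3),
                            "C": pytest.approx(1 / 3)}
        assert sum(occ["c"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_separated_gaussians_match_ground_truth_partition(self):
        rng = np.random.default_rng(14)
        truth = np.repeat([0, 1, 2], 200)
        centers = np.array([[-10.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        pts = centers[truth] + rng.normal(scale=0.5, size=(600, 2))
        model = _model_with_projection({"c": pts})
        _, labels, _ = kmeans_states(model, k=3, seed=1)
        assert adjusted_rand_score(truth, [ord(l) for l in labels["c"]]) == 1.0

    def test_labels_stable_under_frame_permutation(self):
        rng = np.random.default_rng(15)
        pts = np.vstack([rng.normal(-5, 0.3, (100, 2)), rng.normal(5, 0.3, (100, 2))])
        perm = rng.permutation(len(pts))
        _, labels_a, occ_a = kmeans_states(_model_with_projection({"c": pts}), k=2, seed=0)
        _, labels_b, occ_b = kmeans_states(_model_with_projection({"c": pts[perm]}), k=2, seed=0)
        assert occ_a == occ_b
        np.testing.assert_array_equal(labels_a["c"][perm], labels_b["c"])

    def test_too_few_distinct_points_rejected(self):
        pts = np.tile([1.0, 1.0], (50, 1))
        with pytest.raises(ClusteringError):
            kmeans_states(_model_with_projection({"c": pts}), k=3, seed=0)
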