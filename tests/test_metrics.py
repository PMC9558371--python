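"""Structural metrics: dihedral conventions, descriptor wiring, distances,
PCA fitting/projection and even subsampling."""

import numpy as np
import pandas as pd
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kitddg.ensemble import ATOM_COLUMNS, Ensemble, backbone_mask
from kitddg.metrics import (
    ZeroCovarianceError,
    dfg_descriptor,
    dihedral_angle,
    fit_pca,
    hdr_descriptor,
    project,
    residue_phi,
    residue_psi,
    salt_bridge_distance,
    spine_pca,
    subsample_evenly,
)
from kitddg.workgen import (
    DihedralSpec,
    EnsembleGenSpec,
    generate_gaussian_ensemble,
    generate_peptide_frames,
    generate_salt_bridge_ensemble,
    rigid_body_modes,
)

finite3 = st.tuples(
    st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)
)


class TestDihedralAngle:
    def test_cis_is_zero_and_trans_is_180(self):
        assert dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == (
            pytest.approx(0.0, abs=1e-12)
        )
        assert dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == (
            pytest.approx(180.0, abs=1e-12)
        )

    def test_sign_convention_and_reference_formula(self):
        # right-handed convention: this arrangement is +90
        assert dihedral_angle([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]) == (
            pytest.approx(90.0)
        )
        rng = np.random.default_rng(0)
        for _ in range(25):
            pts = rng.normal(size=(4, 3))
            mine = dihedral_angle(*pts)
            ref = np.degrees(calc_dihedral(*[Vector(*p) for p in pts]))
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            dihedral_angle([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(ValueError, match="collinear"):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p1=finite3, p2=finite3, p3=finite3, p4=finite3, seed=st.integers(0, 999))
    def test_rigid_transform_invariance(self, p1, p2, p3, p4, seed):
        pts = np.array([p1, p2, p3, p4])
        try:
            before = dihedral_angle(*pts)
        except ValueError:
            return  # degenerate draw
        rot = Rotation.random(rng=np.random.default_rng(seed))
        shift = np.random.default_rng(seed + 1).normal(size=3)
        after = dihedral_angle(*(rot.apply(pts) + shift))
        assert after == pytest.approx(before, abs=1e-8)


class TestBackboneDihedralSeries:
    def test_round_trip_against_generator(self):
        ens = generate_peptide_frames(
            DihedralSpec(n_residues=4, phi={2: -60.0}, psi={3: 25.0})
        )
        assert residue_phi(ens, 2).values[0] == pytest.approx(-60.0, abs=1e-6)
        assert residue_psi(ens, 3).values[0] == pytest.approx(25.0, abs=1e-6)

    def test_psi_conventions_differ_by_180(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=3, psi={1: 60.0}))
        carbonyl = residue_psi(ens, 1, convention="carbonyl").values[0]
        amide = residue_psi(ens, 1, convention="amide").values[0]
        assert carbonyl == pytest.approx(60.0, abs=1e-6)
        assert (amide - carbonyl) % 360.0 == pytest.approx(180.0, abs=1e-6)

    def test_first_residue_phi_unavailable(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=2))
        with pytest.raises(KeyError):
            residue_phi(ens, 1)

    def test_missing_residue_reported(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=3))
        with pytest.raises(KeyError, match="99"):
            residue_psi(ens, 99)


class TestDfgHdrDescriptors:
    def test_dfg_on_renumbered_chain(self):
        ens = generate_peptide_frames(
            DihedralSpec(
                n_residues=4,
                first_resnum=809,
                phi={810: -65.0, 811: 55.0},
                psi={810: -45.0, 811: 30.0},
            )
        )
        series = dfg_descriptor(ens)
        assert set(series) == {"phi_810", "psi_810", "phi_811", "psi_811"}
        assert series["phi_810"].values[0] == pytest.approx(-65.0, abs=1e-6)
        assert series["psi_811"].values[0] == pytest.approx(30.0, abs=1e-6)

    def test_hdr_is_phi_of_the_arginine(self):
        ens = generate_peptide_frames(
            DihedralSpec(n_residues=3, first_resnum=790, phi={791: -100.0})
        )
        assert hdr_descriptor(ens).values[0] == pytest.approx(-100.0, abs=1e-6)

    def test_missing_dfg_residues_reported(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=3))
        with pytest.raises(KeyError):
            dfg_descriptor(ens)


class TestSaltBridgeDistance:
    def _fixture(self):
        atoms = pd.DataFrame(
            [
                ("A", 623, "LYS", "NZ"),
                ("A", 640, "GLU", "OE1"),
                ("A", 640, "GLU", "OE2"),
            ],
            columns=ATOM_COLUMNS,
        )
        coords = np.array([[[0, 0, 0], [0.30, 0, 0], [0.50, 0, 0]]])
        return Ensemble(coords, atoms)

    def test_minimum_over_oxygen_pairs(self):
        assert salt_bridge_distance(self._fixture(), 623, 640).values[0] == (
            pytest.approx(0.30)
        )

    def test_invariant_to_oxygen_label_swap(self):
        ens = self._fixture()
        swapped_atoms = ens.atoms.copy()
        swapped_atoms.loc[1, "name"], swapped_atoms.loc[2, "name"] = "OE2", "OE1"
        swapped = Ensemble(ens.coords.copy(), swapped_atoms)
        assert (
            salt_bridge_distance(swapped, 623, 640).values[0]
            == salt_bridge_distance(ens, 623, 640).values[0]
        )

    def test_prescribed_series_recovered(self):
        series = np.linspace(0.28, 0.60, 9)
        ens = generate_salt_bridge_ensemble(series, acidic_resnum=810,
                                            acidic_resname="ASP")
        np.testing.assert_allclose(
            salt_bridge_distance(ens, 623, 810).values, series
        )

    def test_missing_side_chain_atoms_reported(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=3))
        with pytest.raises(KeyError, match="amine"):
            salt_bridge_distance(ens, 1, 2)


def _planted_ensemble(n_modes, variances, n_frames, seed=0, n_atoms=15):
    rng = np.random.default_rng(seed)
    mean = rng.normal(size=(n_atoms, 3))
    raw = rng.normal(size=(n_modes, mean.size))
    rigid = rigid_body_modes(mean)
    raw -= (raw @ rigid.T) @ rigid
    q, _ = np.linalg.qr(raw.T)
    spec = EnsembleGenSpec(
        mean=mean,
        modes=q.T[:n_modes],
        variances=variances,
        n_frames=n_frames,
        seed=seed + 1,
    )
    return generate_gaussian_ensemble(spec)


class TestPca:
    def test_rank_one_ensemble(self):
        model = fit_pca(_planted_ensemble(1, [0.02], 2000))
        assert model.explained_fraction[0] >= 0.99

    def test_modes_orthonormal_variances_sorted(self):
        model = fit_pca(_planted_ensemble(3, [0.05, 0.02, 0.01], 300))
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-8)

    def test_variances_invariant_under_rigid_transform(self):
        ens = _planted_ensemble(2, [0.03, 0.01], 200, seed=3)
        rot = Rotation.random(rng=np.random.default_rng(7))
        moved = Ensemble(rot.apply(ens.coords.reshape(-1, 3)).reshape(ens.coords.shape)
                         + np.array([1.0, -2.0, 0.5]), ens.atoms)
        a = fit_pca(ens).variances[:2]
        b = fit_pca(moved).variances[:2]
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_identical_frames_flagged(self):
        coords = np.zeros((5, 4, 3)) + np.arange(12).reshape(4, 3)
        atoms = pd.DataFrame(
            [("A", i + 1, "GLY", "CA") for i in range(4)], columns=ATOM_COLUMNS
        )
        with pytest.raises(ZeroCovarianceError):
            fit_pca(Ensemble(coords, atoms), superpose=False)

    def test_selection_restricts_the_model(self):
        ens = _planted_ensemble(1, [0.02], 100, n_atoms=20)
        model = fit_pca(ens, lambda df: df["resnum"] <= 5)
        assert len(model.atoms) == 5
        assert model.modes.shape[1] == 15


class TestProjection:
    def test_mean_maps_to_origin(self):
        model = fit_pca(_planted_ensemble(2, [0.03, 0.01], 400, seed=5))
        out = project(model, model.mean[None, :, :])
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_eigen_direction_maps_to_single_coordinate(self):
        model = fit_pca(_planted_ensemble(2, [0.03, 0.01], 400, seed=6))
        c = 0.07
        frame = model.mean.ravel() + c * model.modes[0]
        out = project(model, frame.reshape(model.mean.shape)[None])
        assert out[0, 0] == pytest.approx(c, abs=1e-6)
        np.testing.assert_allclose(out[0, 1:], 0.0, atol=1e-6)

    def test_projecting_fit_ensemble_reproduces_variances(self):
        ens = _planted_ensemble(2, [0.03, 0.01], 800, seed=7)
        model = fit_pca(ens)
        proj = project(model, ens)
        got = np.var(proj, axis=0, ddof=1)
        # compare the modes carrying signal; trailing ones are numerical zero
        np.testing.assert_allclose(got[:2], model.variances[:2], rtol=1e-6)
        assert model.variances[2:].max() < 1e-9

    def test_atom_mismatch_reported(self):
        model = fit_pca(_planted_ensemble(1, [0.02], 50, n_atoms=10))
        other = generate_peptide_frames(DihedralSpec(n_residues=3))
        with pytest.raises(KeyError, match="selection"):
            project(model, other)


class TestSpinePca:
    def _spine_ensemble(self, n_frames=60):
        rng = np.random.default_rng(11)
        residues = [621, 603, 678, 798, 799, 800, 656, 644, 811, 790, 500]
        atoms = pd.DataFrame(
            [("A", r, "LEU", "CA") for r in residues], columns=ATOM_COLUMNS
        )
        mean = rng.normal(size=(len(residues), 3))
        coords = mean + 0.05 * rng.standard_normal((n_frames, len(residues), 3))
        return Ensemble(coords, atoms)

    def test_restricts_to_spine_residues(self):
        model = spine_pca(self._spine_ensemble())
        assert set(model.atoms["resnum"]) == {
            621, 603, 678, 798, 799, 800, 656, 644, 811, 790,
        }
        assert model.meta["spine_residues"]

    def test_missing_spine_residue_named(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=3))
        with pytest.raises(KeyError, match="621"):
            spine_pca(ens)


class TestSubsampleEvenly:
    @staticmethod
    def _ens(n):
        atoms = pd.DataFrame([("A", 1, "GLY", "CA")], columns=ATOM_COLUMNS)
        coords = np.arange(n, dtype=float)[:, None, None] * np.ones((n, 1, 3))
        return Ensemble(coords, atoms)

    def test_full_request_is_identity(self):
        out = subsample_evenly(self._ens(10), 10)
        np.testing.assert_array_equal(out.coords[:, 0, 0], np.arange(10))

    def test_formula_indices(self):
        out = subsample_evenly(self._ens(9), 3)
        np.testing.assert_array_equal(out.coords[:, 0, 0], [0, 4, 8])

    def test_single_snapshot_is_first_frame(self):
        out = subsample_evenly(self._ens(5), 1)
        assert out.n_frames == 1 and out.coords[0, 0, 0] == 0

    def test_endpoints_always_kept(self):
        out = subsample_evenly(self._ens(101), 7)
        assert out.coords[0, 0, 0] == 0 and out.coords[-1, 0, 0] == 100

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_evenly(self._ens(5), 6)


class TestBackboneMask:
    def test_range_restriction(self):
        ens = generate_peptide_frames(DihedralSpec(n_residues=6, first_resnum=570))
        mask = backbone_mask(ens.atoms, [(571, 573)])
        assert set(ens.atoms.loc[mask, "resnum"]) == {571, 572, 573}
        assert set(ens.atoms.loc[mask, "name"]) == {"N", "CA", "C", "O"}
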