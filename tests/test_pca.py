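"""PCA eigenmodes, vibrational weights, softness and projections."""

import numpy as np
import pytest

from aquaflux import (
    BeadNetworkSpec,
    BeadTrajectory,
    DomainSoftnessModel,
    ProjectionVector,
    Topology,
    Trajectory,
    four_bead_reduction,
    harmonic_mode_covariance,
    pca,
    projected_softness,
    rocking_bundle_vectors,
    sample_bead_network,
    vibrational_weights,
)
from aquaflux.constants import DEFAULT_TEMPERATURE, KB_KCAL, OMEGA_TO_INV_PS
from aquaflux.synthetic import default_bead_reference
from oracles import eq5_vibrational_weight

KBT = KB_KCAL * DEFAULT_TEMPERATURE


def fitted(spec_cov, n_samples=50_000, seed=0, mass_weighted=False, masses=None):
    spec = BeadNetworkSpec(
        target_covariance=spec_cov, n_samples=n_samples, seed=seed, masses=masses
    )
    traj = sample_bead_network(spec)
    beads = BeadTrajectory.from_trajectory(traj)
    return DomainSoftnessModel(beads, mass_weighted=mass_weighted).fit(), beads


def stretch_mode():
    v = np.array([[1, 0, 0], [1, 0, 0], [-1, 0, 0], [-1, 0, 0]], float).ravel()
    return v / np.linalg.norm(v)


def z_mode():
    v = np.array([[0, 0, 1], [0, 0, -1], [0, 0, 1], [0, 0, -1]], float).ravel()
    return v / np.linalg.norm(v)


class TestFourBeadReduction:
    def _traj(self, coords, masses, labels):
        n = coords.shape[1]
        top = Topology.from_arrays(
            names=[f"A{i}" for i in range(n)],
            segments=["protein"] * n,
            masses=masses,
            domain_labels=labels,
        )
        return Trajectory(
            coordinates=coords,
            box=np.tile([100.0, 100.0, 100.0], (coords.shape[0], 1)),
            dt_frame=1.0,
            topology=top,
        )

    def test_two_atom_domain_beads_at_atom_positions(self):
        coords = np.array(
            [[[0, 0, -3], [0, 0, 3], [5, 0, -2], [5, 0, 2]]], float
        )
        traj = self._traj(coords, [10.0] * 4, ["bundle", "bundle", "hash", "hash"])
        beads = four_bead_reduction(traj)
        # beads coincide with the atoms (after CoM removal, which is zero here)
        ref = coords[0] - coords[0].mean(axis=0)
        got = beads.positions[0]
        order = {lab: k for k, lab in enumerate(beads.labels)}
        np.testing.assert_allclose(got[order["bundle_lower"]], ref[0], atol=1e-12)
        np.testing.assert_allclose(got[order["bundle_upper"]], ref[1], atol=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 1, (5, 8, 3)) + default_bead_reference().repeat(2, axis=0)
        masses = rng.uniform(5, 20, 8)
        labels = ["bundle"] * 4 + ["hash"] * 4
        traj = self._traj(coords, masses, labels)
        beads = four_bead_reduction(traj)
        assert beads.masses.sum() == pytest.approx(masses.sum())

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 1, (6, 8, 3)) + default_bead_reference().repeat(2, axis=0)
        labels = ["bundle"] * 4 + ["hash"] * 4
        traj = self._traj(coords, [10.0] * 8, labels)
        shifted = self._traj(coords + np.array([3.0, -2.0, 7.0]), [10.0] * 8, labels)
        a = four_bead_reduction(traj)
        b = four_bead_reduction(shifted)
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-9)


class TestPCA:
    def test_isotropic_covariance_flat_spectrum(self):
        c = 0.4
        res, _ = fitted(c * np.eye(12), n_samples=60_000, seed=3)
        # CoM removal projects out 3 translations: 9 modes at c, 3 null
        np.testing.assert_allclose(res.eigenvalues[:9], c, rtol=0.06)
        np.testing.assert_allclose(res.eigenvalues[9:], 0.0, atol=1e-9)

    def test_harmonic_mode_equipartition_and_frequency(self):
        k = 1.5  # kcal/mol/Å²
        m = 1000.0
        cov = harmonic_mode_covariance(stretch_mode(), k)
        res, beads = fitted(cov, seed=4)
        lam = res.eigenvalues[0]
        assert lam == pytest.approx(KBT / k, rel=0.05)
        assert res.stiffness[0] == pytest.approx(k, rel=0.05)
        res_mw = DomainSoftnessModel(beads, mass_weighted=True).fit()
        omega = res_mw.quasi_frequencies[0]
        assert omega == pytest.approx(OMEGA_TO_INV_PS * np.sqrt(k / m), rel=0.05)

    def test_known_anisotropic_spectrum(self):
        ks = np.array([0.5, 1.0, 4.0])
        modes = np.stack([stretch_mode(), z_mode(), _rock_mode()])
        cov = harmonic_mode_covariance(modes, ks)
        res, _ = fitted(cov, seed=5)
        np.testing.assert_allclose(np.sort(res.eigenvalues[:3]), np.sort(KBT / ks), rtol=0.05)

    def test_trace_identity_and_orthonormality(self):
        cov = harmonic_mode_covariance(
            np.stack([stretch_mode(), z_mode()]), [1.0, 2.0]
        )
        res, _ = fitted(cov, n_samples=5_000, seed=6)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(res.covariance), rel=1e-10)
        gram = res.eigenvectors.T @ res.eigenvectors
        np.testing.assert_allclose(gram, np.eye(12), atol=1e-9)

    def test_mass_weighted_reduces_to_scaled_unweighted_for_equal_masses(self):
        cov = harmonic_mode_covariance(stretch_mode(), 2.0)
        m = 500.0
        res_u, beads = fitted(cov, n_samples=20_000, seed=7, masses=np.full(4, m))
        res_m = DomainSoftnessModel(beads, mass_weighted=True).fit()
        np.testing.assert_allclose(
            res_m.eigenvalues, m * res_u.eigenvalues, rtol=1e-8, atol=1e-10
        )

    def test_few_frames_warns(self):
        traj = sample_bead_network(
            BeadNetworkSpec(target_covariance=0.1 * np.eye(12), n_samples=30, seed=0)
        )
        with pytest.warns(UserWarning):
            pca(BeadTrajectory.from_trajectory(traj))


def _rock_mode():
    v = np.array([[1, 0, 0], [-1, 0, 0], [-1, 0, 0], [1, 0, 0]], float).ravel()
    return v / np.linalg.norm(v)


def _exact_result(modes, lams, masses=None, reference=None):
    """SoftnessResults with exactly prescribed eigenvectors (no sampling)."""
    from aquaflux.pca import SoftnessResults

    modes = np.atleast_2d(modes)
    n = modes.shape[1] // 3
    full = np.linalg.qr(
        np.concatenate([modes.T, np.random.default_rng(0).normal(size=(3 * n, 3 * n))], axis=1)
    )[0][:, : 3 * n]
    # ensure leading columns equal the prescribed modes (QR keeps span/order)
    full[:, : len(modes)] = modes.T
    lam_full = np.concatenate([lams, np.zeros(3 * n - len(modes))])
    cov = (full * lam_full) @ full.T
    ref = reference if reference is not None else default_bead_reference()
    masses = masses if masses is not None else np.full(n, 1000.0)
    ref = ref - (masses[:, None] * ref).sum(axis=0) / masses.sum()
    return SoftnessResults(
        covariance=cov,
        eigenvalues=lam_full,
        eigenvectors=full,
        kbt=KBT,
        mass_weighted=False,
        masses=np.asarray(masses, float),
        reference=ref,
        zero_modes=lam_full <= 0,
    )


class TestVibrationalWeights:
    def test_pure_stretch_two_beads(self):
        ref = np.array([[-3.0, 0, 0], [3.0, 0, 0]])
        mode = np.array([[-1.0, 0, 0], [1.0, 0, 0]]) / np.sqrt(2)
        res = _exact_result(mode.ravel()[None], [0.5], masses=np.full(2, 10.0), reference=ref)
        res = vibrational_weights(res)
        assert res.vib_weights[0] == 1.0  # exactly, r × e = 0

    def test_pure_rotation_mode(self):
        ref = default_bead_reference()
        masses = np.full(4, 10.0)
        com = ref.mean(axis=0)
        axis = np.array([0.0, 0.0, 1.0])
        disp = np.cross(axis, ref - com)
        disp /= np.linalg.norm(disp)
        res = _exact_result(disp.ravel()[None], [0.3], masses=masses, reference=ref)
        res = vibrational_weights(res)
        assert res.vib_weights[0] <= 1e-10

    def test_sampled_rigid_rotation_has_tiny_weight(self):
        spec = BeadNetworkSpec(
            rigid_rotation_amplitude=0.1, n_samples=20_000, seed=9
        )
        traj = sample_bead_network(spec)
        res = DomainSoftnessModel(BeadTrajectory.from_trajectory(traj)).fit()
        top = np.argmax(res.eigenvalues)
        assert res.vib_weights[top] <= 0.02

    def test_random_mode_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(21)
        ref = default_bead_reference() + rng.normal(0, 0.5, (4, 3))
        masses = rng.uniform(100, 2000, 4)
        mode = rng.normal(size=12)
        mode /= np.linalg.norm(mode)
        res = _exact_result(mode[None], [0.7], masses=masses, reference=ref)
        res = vibrational_weights(res)
        com = (masses[:, None] * ref).sum(axis=0) / masses.sum()
        expected = eq5_vibrational_weight(masses, ref, (mode.reshape(4, 3)))
        assert res.vib_weights[0] == pytest.approx(expected, rel=1e-10)

    def test_weights_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        cov = rng.normal(size=(12, 12))
        cov = cov @ cov.T / 10
        res, beads = fitted(cov, n_samples=3_000, seed=10)
        assert ((res.vib_weights >= 0) & (res.vib_weights <= 1)).all()


class TestSoftness:
    def test_zero_weights_zero_softness(self):
        res = _exact_result(stretch_mode()[None], [0.5])
        res.vib_weights = np.zeros(12)
        assert res.softness == 0.0

    def test_single_mode(self):
        res = _exact_result(stretch_mode()[None], [0.5])
        res = vibrational_weights(res)
        assert res.vib_weights[0] == pytest.approx(1.0, abs=1e-12)
        assert res.softness == pytest.approx(0.5, rel=1e-12)
        assert res.softness_over_kbt == pytest.approx(0.5 / KBT, rel=1e-12)

    def test_all_vibrational_network_softness_is_total_variance(self):
        ks = [0.8, 1.6]
        cov = harmonic_mode_covariance(np.stack([stretch_mode(), z_mode()]), ks)
        res, _ = fitted(cov, seed=11)
        expected = (KBT / np.asarray(ks)).sum()
        assert res.softness == pytest.approx(expected, rel=0.05)


class TestProjections:
    def _result(self):
        res = _exact_result(
            np.stack([stretch_mode(), z_mode()]), [0.5, 0.2]
        )
        return vibrational_weights(res)

    def test_projection_on_eigenvector(self):
        res = self._result()
        p = ProjectionVector(res.eigenvectors[:, 0])
        assert res.project(p) == pytest.approx(
            res.eigenvalues[0] * res.vib_weights[0], abs=1e-10
        )

    def test_orthogonal_projection_zero(self):
        res = self._result()
        p = res.eigenvectors[:, -1]  # null mode, orthogonal to populated ones
        assert res.project(p) == pytest.approx(0.0, abs=1e-10)

    def test_parseval_sum_over_basis(self):
        res = self._result()
        rng = np.random.default_rng(14)
        basis = np.linalg.qr(rng.normal(size=(12, 12)))[0]
        total = sum(res.project(basis[:, j]) for j in range(12))
        assert total == pytest.approx(res.softness, abs=1e-10)

    def test_sigma_p_bounded_by_sigma(self):
        res = self._result()
        rng = np.random.default_rng(15)
        for _ in range(5):
            p = rng.normal(size=12)
            p /= np.linalg.norm(p)
            assert res.project(p) <= res.softness + 1e-12

    def test_unnormalised_vector_warns(self):
        res = self._result()
        with pytest.warns(UserWarning):
            projected_softness(res, 2.0 * res.eigenvectors[:, 0])


class TestRockingVectors:
    def _beads(self):
        spec = BeadNetworkSpec(target_covariance=0.01 * np.eye(12), n_samples=100, seed=0)
        traj = sample_bead_network(spec)
        return four_bead_reduction(traj)

    def test_translation_free_and_orthonormal(self):
        vs = rocking_bundle_vectors(self._beads())
        assert len(vs) == 2
        for v in vs:
            comp = v.components.reshape(4, 3)
            np.testing.assert_allclose(comp.sum(axis=0), 0.0, atol=1e-9)
            assert np.linalg.norm(v.components) == pytest.approx(1.0)
        assert vs[0].components @ vs[1].components == pytest.approx(0.0, abs=1e-9)

    def test_separation_vector_increases_domain_distance(self):
        beads = self._beads()
        vs = rocking_bundle_vectors(beads)
        ref = beads.reference
        order = {lab: k for k, lab in enumerate(beads.labels)}
        disp = vs[0].components.reshape(4, 3)
        moved = ref + 0.5 * disp
        def dom_dist(r):
            b = (r[order["bundle_lower"]] + r[order["bundle_upper"]]) / 2
            h = (r[order["hash_lower"]] + r[order["hash_upper"]]) / 2
            return np.linalg.norm(b - h)
        assert dom_dist(moved) > dom_dist(ref)
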