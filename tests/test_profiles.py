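"""Density profiles, dmin, 2D layers, transit profiles and pair energies."""

import numpy as np
import pytest

from aquaflux import (
    DensityProfile,
    EnergyModel,
    ProteinBlob,
    channel_opening,
    coulomb_energy,
    density_profile,
    detect_permeation_events,
    layered_density_2d,
    lj_energy,
    make_profile_fixture,
    select,
    transit_profiles,
)
from aquaflux.profiles import LayeredDensity2D
from conftest import make_water_trajectory


class TestDensityProfile:
    def test_uniform_slab_density(self):
        traj = make_profile_fixture(600, seed=1, n_frames=60, box=(30, 30, 60))
        waters = select(traj.topology, "segment:water")
        prof = density_profile(traj, waters, bins=2.0)
        expected = 600 / (30 * 30 * 60)
        # mean matches exactly by conservation; per-bin within sampling error
        assert prof.density.mean() == pytest.approx(expected, rel=1e-9)
        se = np.sqrt(expected / (60 * 30 * 30 * 2.0))  # Poisson per bin
        assert np.all(np.abs(prof.density - expected) < 4 * se)

    def test_counts_conserved_per_frame(self):
        traj = make_profile_fixture(200, seed=2, n_frames=10)
        waters = select(traj.topology, "segment:water")
        prof = density_profile(traj, waters, bins=1.0)
        area = traj.box[0, 0] * traj.box[0, 1]
        total = (prof.density * np.diff(prof.bin_edges)).sum() * area
        assert total == pytest.approx(200, rel=1e-9)

    def test_empty_window_rejected(self):
        traj = make_profile_fixture(10, seed=0, n_frames=5)
        waters = select(traj.topology, "segment:water")
        with pytest.raises(ValueError):
            density_profile(traj, waters, window=(1.0, 1.0))

    def test_depletion_fixture_locates_dmin(self):
        traj = make_profile_fixture(
            1200, seed=3, n_frames=80, depletion=(-6.0, 2.0, 0.97)
        )
        waters = select(traj.topology, "segment:water")
        prof = density_profile(traj, waters, bins=1.0)
        dmin, z_at = channel_opening(prof)
        assert abs(z_at - (-6.0)) <= 1.0
        assert dmin < 0.3 * prof.density.max()


class TestChannelOpening:
    def _profile(self, density, edges=None):
        density = np.asarray(density, float)
        if edges is None:
            edges = np.linspace(-16, 16, len(density) + 1)
        return DensityProfile(bin_edges=edges, density=density)

    def test_flat_profile(self):
        prof = self._profile(np.full(32, 0.033))
        dmin, _ = channel_opening(prof)
        assert dmin == pytest.approx(0.033)

    def test_tie_broken_toward_zero(self):
        density = np.full(32, 1.0)
        centers = 0.5 * (prof_edges := np.linspace(-16, 16, 33))[:-1] + 0.5
        prof = self._profile(density, prof_edges)
        c = prof.bin_centers
        density[np.argmin(np.abs(c - (-5.0)))] = 0.2
        density[np.argmin(np.abs(c - 3.0))] = 0.2
        dmin, z_at = channel_opening(self._profile(density, prof_edges))
        assert dmin == 0.2 and z_at == pytest.approx(3.0, abs=0.5)

    def test_all_zero_flagged(self):
        prof = self._profile(np.zeros(32))
        assert prof.all_zero
        assert channel_opening(prof) == (0.0, 0.0)


class TestLayered2D:
    def test_absent_species_map_zero(self):
        blob = ProteinBlob(
            positions=np.array([[0.0, 0.0, 40.0]]),  # outside every layer
            charges=np.array([0.5]),
            lj_epsilon=np.array([0.1]),
            lj_rmin_half=np.array([2.0]),
        )
        traj = make_profile_fixture(50, blob, seed=4, n_frames=5, box=(30, 30, 90))
        sels = {
            "water": select(traj.topology, "segment:water"),
            "protein": select(traj.topology, "segment:protein"),
        }
        out = layered_density_2d(traj, sels)
        assert isinstance(out, LayeredDensity2D)
        for li in range(len(out.z_layers)):
            assert np.all(out.maps[("protein", li)] == 0.0)

    def test_layer_partition_conserves_counts(self):
        traj = make_profile_fixture(300, seed=5, n_frames=8, box=(30, 30, 60))
        waters = select(traj.topology, "segment:water")
        out = layered_density_2d(traj, {"water": waters})
        bin_area = np.outer(np.diff(out.x_edges), np.diff(out.y_edges))
        total = sum(
            (out.maps[("water", li)] * bin_area * (hi - lo)).sum()
            for li, (lo, hi) in enumerate(out.z_layers)
        )
        z = traj.z(waters)
        in_slab = ((z >= -15) & (z < 15)).sum() / traj.n_frames
        assert total * traj.n_frames == pytest.approx(in_slab * traj.n_frames, rel=1e-9)

    def test_cylindrical_column_pattern(self):
        rng = np.random.default_rng(6)
        n, frames = 400, 10
        theta = rng.uniform(0, 2 * np.pi, (frames, n))
        rad = 5.0 * np.sqrt(rng.uniform(0, 1, (frames, n)))
        coords = np.stack(
            [rad * np.cos(theta), rad * np.sin(theta), rng.uniform(-14, 14, (frames, n))],
            axis=2,
        )
        traj = make_water_trajectory(np.zeros((frames, n)), box=(40, 40, 40))
        traj.coordinates = coords
        waters = select(traj.topology, "segment:water")
        out = layered_density_2d(traj, {"water": waters}, bin_width=2.0)
        xc = 0.5 * (out.x_edges[:-1] + out.x_edges[1:])
        yc = 0.5 * (out.y_edges[:-1] + out.y_edges[1:])
        rr = np.sqrt(xc[:, None] ** 2 + yc[None, :] ** 2)
        disc = out.maps[("water", 2)]
        assert disc[rr < 4].mean() > 10 * max(disc[rr > 7].mean(), 1e-12)


class TestPairEnergies:
    def test_coulomb_closed_form(self):
        assert coulomb_energy(1.0, -1.0, 10.0) == pytest.approx(-33.20636, abs=1e-6)

    def test_lj_minimum(self):
        eps, rmin = 0.2, 3.5
        assert lj_energy(eps, rmin, rmin) == pytest.approx(-eps, abs=1e-12)
        # force ~ 0 at the minimum (finite difference)
        du = (lj_energy(eps, rmin, rmin + 1e-5) - lj_energy(eps, rmin, rmin - 1e-5)) / 2e-5
        assert abs(du) < 1e-6

    def test_pair_energy_cutoff_and_shift(self):
        model = EnergyModel(cutoff=12.0)
        assert model.pair_energy(1, -1, 0, 0, 0, 0, 15.0) == 0.0
        unshifted = model.pair_energy(1, -1, 0, 0, 0, 0, 10.0)
        assert unshifted == pytest.approx(-33.20636, abs=1e-6)
        shifted_model = EnergyModel(cutoff=12.0, shift=True)
        shifted = shifted_model.pair_energy(1, -1, 0, 0, 0, 0, 10.0)
        assert shifted == pytest.approx(unshifted - coulomb_energy(1, -1, 12.0), abs=1e-9)


class TestTransitProfiles:
    def _transit_traj(self, n_steps=26):
        # one molecule at constant speed from the lower to the upper compartment
        z = np.linspace(-13.0, 13.0, n_steps)[:, None]
        return make_water_trajectory(z, box=(20, 20, 60))

    def test_constant_velocity_flat_dtau_dz(self):
        traj = self._transit_traj()
        waters = select(traj.topology, "segment:water")
        events = detect_permeation_events(traj, waters)
        assert len(events) == 1
        profs = transit_profiles(traj, events, bin_width=1.0)
        prof = profs["up"]
        tau = events[0].tau
        assert prof.residence_integral() == pytest.approx(tau, rel=1e-9)
        occupied = prof.residence_time_density[prof.residence_time_density > 0]
        # uniform speed: all occupied interior bins carry the same dτ/dz
        assert occupied.std() / occupied.mean() < 0.35

    def test_integral_equals_mean_tau_many_events(self, channel_traj):
        waters = select(channel_traj.topology, "segment:water")
        events = [
            e for e in detect_permeation_events(channel_traj, waters) if e.confined
        ]
        assert len(events) > 10
        profs = transit_profiles(channel_traj, events, bin_width=1.0)
        for direction, prof in profs.items():
            evs = [e for e in events if e.direction == direction]
            mean_tau = np.mean([e.tau for e in evs])
            assert prof.residence_integral() == pytest.approx(mean_tau, rel=0.02)

    def test_up_down_symmetry(self, channel_traj):
        waters = select(channel_traj.topology, "segment:water")
        events = detect_permeation_events(channel_traj, waters)
        profs = transit_profiles(channel_traj, events, bin_width=2.0)
        up, down = profs["up"], profs["down"]
        # same pathways in both directions: integrals agree within sampling
        assert up.residence_integral() == pytest.approx(
            down.residence_integral(), rel=0.5
        )

    def test_chargeless_system_skips_energetics_with_warning(self):
        traj = self._transit_traj()
        waters = select(traj.topology, "segment:water")
        events = detect_permeation_events(traj, waters)
        with pytest.warns(UserWarning):
            profs = transit_profiles(traj, events, model=EnergyModel())
        assert profs["up"].u_protein is None

    def test_energetics_against_direct_pair_sum(self):
        traj = self._transit_traj(n_steps=27)  # integer z steps: z=0 sampled
        # one static protein atom with charge; water gets a charge too
        blob_pos = np.array([[0.0, 3.0, 0.0]])
        top = traj.topology.atoms
        import pandas as pd

        prot = pd.DataFrame(
            {
                "atom_index": [1],
                "name": ["P0"],
                "residue_id": [1],
                "residue_name": ["BLB"],
                "segment": ["protein"],
                "mass": [12.0],
                "charge": [1.0],
                "lj_epsilon": [0.0],
                "lj_rmin_half": [0.0],
            }
        )
        top = pd.concat([top, prot], ignore_index=True)
        from aquaflux import Topology, Trajectory

        top.loc[0, "charge"] = -1.0
        coords = np.concatenate(
            [traj.coordinates, np.tile(blob_pos, (traj.n_frames, 1, 1))], axis=1
        )
        traj2 = Trajectory(
            coordinates=coords,
            box=traj.box,
            dt_frame=traj.dt_frame,
            topology=Topology(top),
        )
        waters = select(traj2.topology, "segment:water")
        events = detect_permeation_events(traj2, waters)
        model = EnergyModel(cutoff=12.0)
        profs = transit_profiles(traj2, events, model=model, bin_width=1.0)
        prof = profs["up"]
        # bin where the water passes closest to the protein atom (z≈0, r=3):
        i0 = np.argmin(np.abs(prof.bin_centers - 0.0))
        assert np.isfinite(prof.u_protein[i0])
        z_mid = prof.bin_centers[i0]
        r = np.hypot(3.0, z_mid)
        assert prof.u_protein[i0] == pytest.approx(
            coulomb_energy(-1.0, 1.0, r), rel=0.05
        )
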