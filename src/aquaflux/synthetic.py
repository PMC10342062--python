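"""Synthetic trajectories with known ground truth.

Two families of generators make every downstream stage testable without any
external dataset:

* **Channel waters** — overdamped (position) Langevin dynamics of point waters
  in a box with a membrane slab pierced by a cylindrical channel, bulk
  reservoirs on both sides, an optional tabulated axial potential U(z), and an
  optional *single-file* regime in which the in-channel file holds exactly N
  non-passing waters exchanged at the mouths.
* **Bead networks** — a small set of beads fluctuating harmonically about a
  reference structure with a prescribed 3n×3n covariance, optionally with a
  superposed rigid-body rotation, so PCA output is recoverable analytically.

All randomness flows from the explicit ``seed`` carried by each spec; the same
seed yields a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, MEMBRANE_SPAN
from .errors import SpecificationError, StabilityError
from .trajectory import Topology, Trajectory

WATER_MASS = 18.0153  # amu, whole molecule carried by its tracked site


# ---------------------------------------------------------------------------
# channel waters
# ---------------------------------------------------------------------------


@dataclass
class ChannelSpec:
    """Parameters of the Brownian channel-water generator.

    The membrane occupies ``|z| < membrane_span/2`` and is impenetrable except
    through a cylinder of ``channel_radius`` around the z axis.  ``potential``
    is an optional tabulated axial potential ``(z_grid, U)`` in Å/kcal/mol felt
    inside the channel.  ``dt`` is the integration step; every
    ``sample_every``-th step is stored as a frame.
    """

    box: tuple = (30.0, 30.0, 70.0)
    membrane_span: float = MEMBRANE_SPAN
    channel_radius: float = 4.0
    potential: tuple | None = None  # (z_grid, U_kcal_per_mol)
    mobility_profile: tuple | None = None  # (z_grid, relative mobility in (0, 1])
    diffusion_coefficient: float = 0.23  # Å^2/ps, bulk-water-like
    n_waters: int = 60
    single_file: bool = False
    single_file_occupancy: int = 4
    temperature: float = DEFAULT_TEMPERATURE
    dt: float = 0.1  # ps
    n_steps: int = 100_000
    sample_every: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.channel_radius <= 0:
            raise SpecificationError("channel_radius must be positive")
        if self.diffusion_coefficient < 0:
            raise SpecificationError("diffusion_coefficient must be non-negative")
        if self.dt <= 0:
            raise SpecificationError("dt must be positive")
        if self.single_file and self.single_file_occupancy < 1:
            raise SpecificationError("single_file_occupancy must be >= 1")
        if self.membrane_span >= self.box[2]:
            raise SpecificationError("membrane_span must fit inside the box")
        if self.single_file and self.n_waters <= self.single_file_occupancy:
            raise SpecificationError("need reservoir waters beyond the file occupancy")
        if self.mobility_profile is not None:
            mg = np.asarray(self.mobility_profile[1], float)
            if (mg <= 0).any() or (mg > 1 + 1e-9).any():
                raise SpecificationError("relative mobility must lie in (0, 1]")
        if self.potential is not None and self.diffusion_coefficient > 0:
            zg, ug = map(np.asarray, self.potential)
            grad = np.abs(np.gradient(ug, zg)).max()
            kbt = KB_KCAL * self.temperature
            if grad * self.dt * self.diffusion_coefficient / kbt > 0.5:
                raise StabilityError(
                    "potential gradient moves a water more than 0.5 Å per step; "
                    "reduce dt or the barrier"
                )


def _water_topology(n: int) -> Topology:
    return Topology.from_arrays(
        names=["O"] * n,
        segments=["water"] * n,
        masses=np.full(n, WATER_MASS),
        residue_ids=np.arange(n),
        residue_names=["TIP3"] * n,
    )


def _wrap(x: np.ndarray, length: float) -> np.ndarray:
    return x - length * np.round(x / length)


def simulate_channel_water(spec: ChannelSpec) -> Trajectory:
    """Propagate the channel-water system and return the stored frames.

    Dynamics: ``z <- z - (D/kBT) U'(z) dt + sqrt(2 D dt) xi`` with free lateral
    diffusion in the reservoirs, radial confinement inside the channel and
    reflecting membrane walls; z is periodic through the bulk.  In single-file
    mode the in-channel file keeps exactly N non-passing waters; when the
    extreme water leaves through a mouth, a reservoir water is inserted at the
    opposite mouth at the vacated file slot (depth L/(N+1)).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    hs = spec.membrane_span / 2.0
    n = spec.n_waters
    d0, dt = spec.diffusion_coefficient, spec.dt
    sigma = np.sqrt(2.0 * d0 * dt)
    kbt = KB_KCAL * spec.temperature

    if spec.potential is not None:
        z_grid = np.asarray(spec.potential[0], float)
        u_grid = np.asarray(spec.potential[1], float)
        f_grid = -np.gradient(u_grid, z_grid)  # force, kcal/mol/Å
    else:
        z_grid = f_grid = None

    pos = _initial_positions(spec, rng)
    n_frames = spec.n_steps // spec.sample_every
    frames = np.empty((n_frames, n, 3))

    if spec.single_file:
        _propagate_single_file(spec, pos, rng, sigma, frames)
    else:
        _propagate_open_channel(spec, pos, rng, sigma, kbt, z_grid, f_grid, frames)

    box = np.array([lx, ly, lz])
    return Trajectory(
        coordinates=frames,
        box=np.tile(box, (n_frames, 1)),
        dt_frame=spec.dt * spec.sample_every,
        topology=_water_topology(n),
    )


def _initial_positions(spec: ChannelSpec, rng) -> np.ndarray:
    lx, ly, lz = spec.box
    hs = spec.membrane_span / 2.0
    n = spec.n_waters
    pos = np.empty((n, 3))
    if spec.single_file:
        nf = spec.single_file_occupancy
        a = spec.membrane_span / (nf + 1)
        pos[:nf, 0] = pos[:nf, 1] = 0.0
        pos[:nf, 2] = -hs + a * np.arange(1, nf + 1)  # file slots, bottom→top
        n_res = n - nf
        pos[nf:, 0] = rng.uniform(-lx / 2, lx / 2, n_res)
        pos[nf:, 1] = rng.uniform(-ly / 2, ly / 2, n_res)
        half = n_res // 2
        pos[nf : nf + half, 2] = rng.uniform(hs, lz / 2, half)
        pos[nf + half : n, 2] = rng.uniform(-lz / 2, -hs, n_res - half)
    else:
        # spread waters through reservoirs and channel proportionally to volume
        r, vol_ch = spec.channel_radius, np.pi * spec.channel_radius**2 * 2 * hs
        vol_res = lx * ly * (lz - 2 * hs)
        n_ch = min(n, int(round(n * vol_ch / (vol_ch + vol_res))))
        theta = rng.uniform(0, 2 * np.pi, n_ch)
        rad = r * np.sqrt(rng.uniform(0, 1, n_ch)) * 0.98
        pos[:n_ch, 0] = rad * np.cos(theta)
        pos[:n_ch, 1] = rad * np.sin(theta)
        pos[:n_ch, 2] = rng.uniform(-hs, hs, n_ch)
        n_res = n - n_ch
        pos[n_ch:, 0] = rng.uniform(-lx / 2, lx / 2, n_res)
        pos[n_ch:, 1] = rng.uniform(-ly / 2, ly / 2, n_res)
        signs = np.where(rng.uniform(size=n_res) < 0.5, 1.0, -1.0)
        pos[n_ch:, 2] = signs * rng.uniform(hs, lz / 2, n_res)
    return pos


def _propagate_open_channel(spec, pos, rng, sigma, kbt, z_grid, f_grid, frames):
    lx, ly, lz = spec.box
    hs = spec.membrane_span / 2.0
    r_ch = spec.channel_radius
    d0, dt = spec.diffusion_coefficient, spec.dt
    store = spec.sample_every
    if spec.mobility_profile is not None:
        mz_grid = np.asarray(spec.mobility_profile[0], float)
        m_grid = np.asarray(spec.mobility_profile[1], float)
        # Itô spurious-drift correction dD/dz keeps Boltzmann statistics exact
        dgrad_grid = np.gradient(d0 * m_grid, mz_grid)
    else:
        mz_grid = m_grid = dgrad_grid = None
    chunk = 20_000
    step = 0
    while step < spec.n_steps:
        m = min(chunk, spec.n_steps - step)
        noise = rng.standard_normal(size=(m, spec.n_waters, 3)) if sigma else None
        for k in range(m):
            old = pos
            r_old = np.hypot(old[:, 0], old[:, 1])
            in_ch = (np.abs(old[:, 2]) < hs) & (r_old < r_ch)
            d_loc = np.full(spec.n_waters, d0)
            if m_grid is not None and in_ch.any():
                d_loc[in_ch] = d0 * np.interp(old[in_ch, 2], mz_grid, m_grid)
            if noise is not None:
                new = old + noise[k] * np.sqrt(2.0 * d_loc * dt)[:, None]
            else:
                new = old.copy()
            if m_grid is not None and in_ch.any():
                new[in_ch, 2] += np.interp(old[in_ch, 2], mz_grid, dgrad_grid) * dt
            if f_grid is not None and in_ch.any():
                force = np.interp(old[in_ch, 2], z_grid, f_grid)
                new[in_ch, 2] += (d_loc[in_ch] * dt / kbt) * force
            # periodic wrap
            new[:, 0] = _wrap(new[:, 0], lx)
            new[:, 1] = _wrap(new[:, 1], ly)
            new[:, 2] = _wrap(new[:, 2], lz)
            # membrane walls
            r_new = np.hypot(new[:, 0], new[:, 1])
            in_mem = np.abs(new[:, 2]) < hs
            was_res = np.abs(old[:, 2]) >= hs
            # reservoir particle hit the membrane face outside the channel
            hit_face = in_mem & was_res & (r_new >= r_ch)
            if hit_face.any():
                s = np.sign(old[hit_face, 2])
                refl = 2.0 * s * hs - new[hit_face, 2]
                refl = np.where(np.abs(refl) < hs, s * (hs + 1e-6), refl)
                new[hit_face, 2] = refl
            # channel particle hit the cylindrical wall
            r_new = np.hypot(new[:, 0], new[:, 1])
            hit_wall = (np.abs(new[:, 2]) < hs) & (~was_res) & (r_new >= r_ch)
            if hit_wall.any():
                r_val = r_new[hit_wall]
                r_ref = np.clip(2.0 * r_ch - r_val, 1e-6, r_ch * 0.999)
                scale = r_ref / r_val
                new[hit_wall, 0] *= scale
                new[hit_wall, 1] *= scale
            pos = new
            g = step + k + 1
            if g % store == 0:
                frames[g // store - 1] = pos
        step += m


def _propagate_single_file(spec, pos, rng, sigma, frames):
    """Single-file regime: the in-channel column of N waters moves as a
    concerted (incompressible) file.

    The file's collective offset u performs overdamped Brownian motion with
    D_file = D0/N (common noise, summed mobility); waters sit at slots
    -L/2 + a·(i+1) + u with spacing a = L/(N+1), so they never pass each
    other.  One *standby* water tracks the trailing mouth continuously (at
    -L/2+u for u>0, at +L/2+u for u<0), entering the channel as the file
    advances; when u accumulates ±a a full hop has completed — the leading
    water is released into its reservoir exactly at the mouth and the standby
    becomes a file member — keeping the in-channel occupancy at exactly N.
    The standby role exchanges freely with the reservoir water nearest the
    mouth (a flux-neutral identity swap), mimicking fast mouth equilibration.
    This is the continuum limit of the hopping single-file channel, for which
    pf/pd = N + 1 holds exactly; the collective coordinate advances as
    (N+1)·u/L, diffusive at every lag.
    """
    lx, ly, lz = spec.box
    hs = spec.membrane_span / 2.0
    nf = spec.single_file_occupancy
    a = spec.membrane_span / (nf + 1)
    store = spec.sample_every
    n = spec.n_waters
    sigma_file = np.sqrt(2.0 * spec.diffusion_coefficient * spec.dt / nf)
    slots = -hs + a * np.arange(1, nf + 1)

    # identity bookkeeping: file_ids ordered bottom→top; standby tracks the
    # trailing mouth; everything else is reservoir
    file_ids = list(range(nf))
    res_ids = [i for i in range(n) if i not in file_ids]
    standby = -1  # atom id of the current standby (-1: none, u == 0)
    u = 0.0
    eps = 1e-3

    def _release(atom, mouth_z):
        pos[atom] = (0.0, 0.0, mouth_z + eps * np.sign(mouth_z))
        res_ids.append(atom)

    def _recruit(mouth_z):
        zs = pos[res_ids, 2]
        j = int(np.argmin(np.abs(zs - mouth_z)))
        return res_ids.pop(j)

    chunk = 20_000
    step = 0
    while step < spec.n_steps:
        m = min(chunk, spec.n_steps - step)
        noise = rng.normal(0.0, sigma, size=(m, n, 3)) if sigma else np.zeros((m, n, 3))
        u_noise = rng.normal(0.0, sigma_file, size=m) if sigma_file else np.zeros(m)
        for k in range(m):
            u_old = u
            u += u_noise[k]
            # standby switches sides when u changes sign
            if standby >= 0 and u * u_old <= 0:
                _release(standby, -hs if u_old > 0 else hs)
                standby = -1
            # --- completed hops: leader released at its mouth, standby joins ---
            while u >= a or u <= -a:
                if u >= a:  # file moved up
                    leaver = file_ids.pop()
                    _release(leaver, hs)
                    if standby < 0:
                        standby = _recruit(-hs)
                    file_ids.insert(0, standby)
                    standby = -1
                    u -= a
                else:  # file moved down
                    leaver = file_ids.pop(0)
                    _release(leaver, -hs)
                    if standby < 0:
                        standby = _recruit(hs)
                    file_ids.append(standby)
                    standby = -1
                    u += a
            mouth = -hs if u > 0 else hs
            if standby < 0 and u != 0.0:
                standby = _recruit(mouth)
            # --- reservoir: free 3D with reflecting membrane faces ---
            ridx = np.asarray(res_ids)
            old_z = pos[ridx, 2]
            new = pos[ridx] + noise[k][ridx]
            new[:, 0] = _wrap(new[:, 0], lx)
            new[:, 1] = _wrap(new[:, 1], ly)
            new[:, 2] = _wrap(new[:, 2], lz)
            entered = np.abs(new[:, 2]) < hs
            if entered.any():
                s = np.sign(old_z[entered])
                refl = 2.0 * s * hs - new[entered, 2]
                refl = np.where(np.abs(refl) < hs, s * (hs + 1e-6), refl)
                new[entered, 2] = refl
            pos[ridx] = new
            # --- place file and standby; churn standby with nearest reservoir ---
            pos[file_ids, 0] = 0.0
            pos[file_ids, 1] = 0.0
            pos[file_ids, 2] = slots + u
            if standby >= 0:
                zs = pos[ridx, 2]
                j = int(np.argmin(np.abs(zs - mouth)))
                if np.abs(zs[j] - mouth) < np.abs(u):
                    _release(standby, mouth)
                    standby = res_ids.pop(j)
                pos[standby] = (0.0, 0.0, mouth + u)
            g = step + k + 1
            if g % store == 0:
                frames[g // store - 1] = pos
        step += m


def simulate_free_water(
    n_waters: int,
    box: tuple,
    diffusion_coefficient: float,
    dt_frame: float,
    n_frames: int,
    seed: int,
    wrap: bool = True,
) -> Trajectory:
    """Unconfined Brownian waters (no membrane): exact free diffusion at any
    frame spacing.  Used as ground truth for MSD-based estimators."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    start = rng.uniform(-box / 2, box / 2, size=(n_waters, 3))
    steps = rng.normal(
        0.0,
        np.sqrt(2.0 * diffusion_coefficient * dt_frame),
        size=(n_frames - 1, n_waters, 3),
    )
    coords = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    if wrap:
        coords = coords - box * np.round(coords / box)
    return Trajectory(
        coordinates=coords,
        box=np.tile(box, (n_frames, 1)),
        dt_frame=dt_frame,
        topology=_water_topology(n_waters),
    )


# ---------------------------------------------------------------------------
# bead networks
# ---------------------------------------------------------------------------


def default_bead_reference(separation: float = 6.0, height: float = 10.0) -> np.ndarray:
    """Reference geometry of the four-bead domain model: two bundle beads at
    x=+separation/2 and two hash beads at x=-separation/2, each pair split
    along z by *height*.  Order: bundle-lower, bundle-upper, hash-lower,
    hash-upper."""
    s, h = separation / 2.0, height / 2.0
    return np.array([[s, 0, -h], [s, 0, h], [-s, 0, -h], [-s, 0, h]])


@dataclass
class BeadNetworkSpec:
    """Harmonic bead network with known covariance.

    ``target_covariance`` is the 3n×3n displacement covariance (Å²) about the
    reference; sampled frames optionally carry a rigid rotation about
    ``rotation_axis`` through the CoM with per-frame angles drawn from
    N(0, rigid_rotation_amplitude²)."""

    n_beads: int = 4
    masses: np.ndarray | None = None
    reference: np.ndarray | None = None
    target_covariance: np.ndarray | None = None
    rigid_rotation_amplitude: float = 0.0  # radians (std of per-frame angle)
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.full(self.n_beads, 1000.0)
        self.masses = np.asarray(self.masses, float)
        if self.reference is None:
            if self.n_beads == 4:
                self.reference = default_bead_reference()
            else:
                raise SpecificationError("reference required when n_beads != 4")
        self.reference = np.asarray(self.reference, float)
        if self.target_covariance is None:
            self.target_covariance = np.zeros((3 * self.n_beads, 3 * self.n_beads))
        self.target_covariance = np.asarray(self.target_covariance, float)

    def validate(self) -> None:
        if (self.masses <= 0).any():
            raise SpecificationError("bead masses must be positive")
        c = self.target_covariance
        if c.shape != (3 * self.n_beads, 3 * self.n_beads):
            raise SpecificationError("target_covariance must be 3n x 3n")
        if not np.allclose(c, c.T, atol=1e-10):
            raise SpecificationError("target_covariance must be symmetric")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise SpecificationError("target_covariance must be positive semi-definite")


def sample_bead_network(spec: BeadNetworkSpec) -> Trajectory:
    """Draw frames from the harmonic network; CoM translation is removed from
    every frame.  Bead topology labels the first half of the beads ``bundle``
    and the second half ``hash`` (the four-bead convention)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, nt = spec.n_beads, spec.n_samples
    w, v = np.linalg.eigh(spec.target_covariance)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    disp = rng.standard_normal(size=(nt, 3 * n)) @ factor.T
    coords = spec.reference[None] + disp.reshape(nt, n, 3)

    if spec.rigid_rotation_amplitude > 0:
        axis = np.asarray(spec.rotation_axis, float)
        axis = axis / np.linalg.norm(axis)
        angles = rng.normal(0.0, spec.rigid_rotation_amplitude, size=nt)
        com_ref = spec.masses @ spec.reference / spec.masses.sum()
        rel = coords - com_ref
        cos, sin = np.cos(angles), np.sin(angles)
        # Rodrigues rotation, vectorised over frames
        cross = np.cross(np.broadcast_to(axis, rel.shape), rel)
        dot = rel @ axis
        coords = com_ref + (
            rel * cos[:, None, None]
            - cross * sin[:, None, None]
            + axis[None, None, :] * dot[..., None] * (1 - cos)[:, None, None]
        )

    com = np.einsum("k,tkd->td", spec.masses, coords) / spec.masses.sum()
    coords = coords - com[:, None, :]

    half = n // 2
    labels = ["bundle"] * half + ["hash"] * (n - half)
    topology = Topology.from_arrays(
        names=[f"B{i}" for i in range(n)],
        segments=["protein"] * n,
        masses=spec.masses,
        residue_ids=np.arange(n),
        residue_names=["BEA"] * n,
        domain_labels=labels,
    )
    side = max(200.0, 4 * np.abs(spec.reference).max())
    return Trajectory(
        coordinates=coords,
        box=np.tile([side, side, side], (nt, 1)),
        dt_frame=1.0,
        topology=topology,
    )


def harmonic_mode_covariance(
    modes: np.ndarray, spring_constants, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Covariance of a harmonic network with orthonormal mode vectors (rows of
    *modes*, length 3n) and per-mode spring constants k_i (kcal/mol/Å²):
    C = Σ_i (kBT/k_i) v_i v_iᵀ, i.e. equipartition ⟨q_i²⟩ = kBT/k_i."""
    modes = np.atleast_2d(np.asarray(modes, float))
    ks = np.atleast_1d(np.asarray(spring_constants, float))
    kbt = KB_KCAL * temperature
    return (modes.T * (kbt / ks)) @ modes


# ---------------------------------------------------------------------------
# profile fixture
# ---------------------------------------------------------------------------


@dataclass
class ProteinBlob:
    """A static pseudo-protein: fixed atom positions with charges and LJ
    parameters so interaction-energy profiles are computable."""

    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj_epsilon: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lj_rmin_half: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def make_profile_fixture(
    n_waters: int,
    protein_blob: ProteinBlob | None = None,
    seed: int = 0,
    *,
    box: tuple = (30.0, 30.0, 60.0),
    n_frames: int = 50,
    depletion: tuple | None = None,  # (z0, width, amplitude in [0,1])
    n_membrane: int = 0,
) -> Trajectory:
    """Water slab plus optional pseudo-protein and membrane segments.

    Waters are redrawn independently each frame, uniform in the box except for
    an optional Gaussian depletion zone ``amplitude*exp(-(z-z0)²/2w²)`` removed
    by rejection — a construction whose density minimum location is known.
    """
    if n_waters <= 0 or n_frames <= 0:
        raise SpecificationError("counts must be positive")
    rng = np.random.default_rng(seed)
    lx, ly, lz = box
    blob = protein_blob or ProteinBlob()

    water = np.empty((n_frames, n_waters, 3))
    for f in range(n_frames):
        water[f, :, 0] = rng.uniform(-lx / 2, lx / 2, n_waters)
        water[f, :, 1] = rng.uniform(-ly / 2, ly / 2, n_waters)
        if depletion is None:
            water[f, :, 2] = rng.uniform(-lz / 2, lz / 2, n_waters)
        else:
            z0, width, amp = depletion
            zs = np.empty(n_waters)
            have = 0
            while have < n_waters:
                cand = rng.uniform(-lz / 2, lz / 2, 2 * (n_waters - have))
                keep_p = 1.0 - amp * np.exp(-((cand - z0) ** 2) / (2 * width**2))
                cand = cand[rng.uniform(size=len(cand)) < keep_p]
                take = min(len(cand), n_waters - have)
                zs[have : have + take] = cand[:take]
                have += take
            water[f, :, 2] = zs

    mem = np.zeros((0, 3))
    if n_membrane:
        theta = rng.uniform(0, 2 * np.pi, n_membrane)
        rad = rng.uniform(8.0, min(lx, ly) / 2 - 1.0, n_membrane)
        mem = np.column_stack(
            [rad * np.cos(theta), rad * np.sin(theta), rng.uniform(-12, 12, n_membrane)]
        )

    n_p, n_m = blob.n_atoms, len(mem)
    static = np.concatenate([blob.positions.reshape(-1, 3), mem]) if (n_p + n_m) else np.zeros((0, 3))
    coords = np.concatenate(
        [water, np.tile(static, (n_frames, 1, 1))], axis=1
    ) if len(static) else water

    names = ["O"] * n_waters + [f"P{i}" for i in range(n_p)] + ["C"] * n_m
    segments = ["water"] * n_waters + ["protein"] * n_p + ["membrane"] * n_m
    masses = np.concatenate(
        [np.full(n_waters, WATER_MASS), np.full(n_p, 12.011), np.full(n_m, 12.011)]
    )
    charges = np.concatenate(
        [np.full(n_waters, -0.834), blob.charges, np.zeros(n_m)]
    )
    eps = np.concatenate([np.full(n_waters, 0.1521), blob.lj_epsilon, np.zeros(n_m)])
    rmin = np.concatenate([np.full(n_waters, 1.7682), blob.lj_rmin_half, np.zeros(n_m)])
    topology = Topology.from_arrays(
        names=names,
        segments=segments,
        masses=masses,
        charges=charges,
        lj_epsilon=eps,
        lj_rmin_half=rmin,
        residue_ids=np.arange(n_waters + n_p + n_m),
        residue_names=["TIP3"] * n_waters + ["BLB"] * n_p + ["MEM"] * n_m,
    )
    return Trajectory(
        coordinates=coords,
        box=np.tile([lx, ly, lz], (n_frames, 1)),
        dt_frame=2.0,
        topology=topology,
    )


# ---------------------------------------------------------------------------
# windowed correlation fixture
# ---------------------------------------------------------------------------


def make_windowed_fixture(
    n_windows: int,
    steps_per_window: int,
    *,
    barrier_heights=None,
    diffusions=None,
    bead_scales=None,
    base_barrier: float = 1.5,
    base_diffusion: float = 0.23,
    base_bead_sigma2: float = 0.05,
    n_waters: int = 100,
    channel_radius: float = 5.0,
    dt: float = 0.1,
    sample_every: int = 5,
    seed: int = 0,
) -> tuple[Trajectory, float]:
    """A long trajectory whose generator parameters vary window by window.

    Four protein beads (two ``bundle``, two ``hash``) ride along with the
    waters; per window the water channel is simulated with barrier height
    ``barrier_heights[w]`` and diffusion ``diffusions[w]``, and the beads are
    drawn from a stretch-mode harmonic network whose eigenvalue is scaled by
    ``bead_scales[w]``.  Returns ``(trajectory, window_ps)``.
    """
    rng = np.random.default_rng(seed)
    ones = np.ones(n_windows)
    barrier_heights = np.asarray(barrier_heights if barrier_heights is not None else ones * base_barrier, float)
    diffusions = np.asarray(diffusions if diffusions is not None else ones * base_diffusion, float)
    bead_scales = np.asarray(bead_scales if bead_scales is not None else ones, float)

    z_grid = np.linspace(-20, 20, 161)
    ref = default_bead_reference()
    # in-line bundle–hash stretch mode (translation-free, unit norm)
    stretch = np.array(
        [[1, 0, 0], [1, 0, 0], [-1, 0, 0], [-1, 0, 0]], float
    ).ravel()
    stretch /= np.linalg.norm(stretch)

    water_parts, bead_parts = [], []
    n_frames_w = steps_per_window // sample_every
    for w in range(n_windows):
        u = barrier_heights[w] * np.exp(-(z_grid**2) / (2 * 3.0**2))
        cspec = ChannelSpec(
            box=(30.0, 30.0, 70.0),
            channel_radius=channel_radius,
            potential=(z_grid, u),
            diffusion_coefficient=diffusions[w],
            n_waters=n_waters,
            dt=dt,
            n_steps=steps_per_window,
            sample_every=sample_every,
            seed=int(rng.integers(2**31 - 1)),
        )
        water_parts.append(simulate_channel_water(cspec).coordinates)
        cov = harmonic_mode_covariance(stretch, KB_KCAL * DEFAULT_TEMPERATURE / (base_bead_sigma2 * bead_scales[w]))
        bspec = BeadNetworkSpec(
            target_covariance=cov,
            n_samples=n_frames_w,
            seed=int(rng.integers(2**31 - 1)),
        )
        bead_parts.append(sample_bead_network(bspec).coordinates + np.array([0.0, 10.0, 0.0]))

    water = np.concatenate(water_parts)
    beads = np.concatenate(bead_parts)
    coords = np.concatenate([water, beads], axis=1)

    bead_top = Topology.from_arrays(
        names=["B0", "B1", "B2", "B3"],
        segments=["protein"] * 4,
        masses=np.full(4, 1000.0),
        domain_labels=["bundle", "bundle", "hash", "hash"],
        residue_ids=np.arange(4),
        residue_names=["BEA"] * 4,
    )
    import pandas as pd

    water_top = _water_topology(n_waters).atoms
    bt = bead_top.atoms.copy()
    bt["atom_index"] += n_waters
    bt["residue_id"] += n_waters
    topology = Topology(pd.concat([water_top, bt], ignore_index=True))
    dt_frame = dt * sample_every
    traj = Trajectory(
        coordinates=coords,
        box=np.tile([30.0, 30.0, 70.0], (len(coords), 1)),
        dt_frame=dt_frame,
        topology=topology,
    )
    return traj, steps_per_window * dt
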