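"""Density profiles, channel opening, layered 2D densities and transit profiles.

The channel-opening measure ``dmin`` is the minimum of the water number
density along the membrane normal within the membrane span — a small dmin
means a tight constriction.  Transit profiles characterise only waters taking
part in full permeation events: residence time per unit length dτ/dz (whose
integral over the span equals the mean event duration τ), short-time mobility
(mean displacement over 2 ps), interaction energy with the protein and with
the total environment, and the magnitude of the energy gradient |ΔU/Δs| along
each molecule's own path.

Interaction energies are pairwise Lennard-Jones (CHARMM ``ε, rmin/2``
convention, Lorentz–Berthelot combining) plus Coulomb, truncated at a cutoff;
an optional shift removes the cutoff discontinuity for smoother force
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT
from .permeation import PermeationEvent
from .trajectory import FrameSelection, Trajectory

__all__ = [
    "DensityProfile",
    "density_profile",
    "channel_opening",
    "layered_density_2d",
    "EnergyModel",
    "coulomb_energy",
    "lj_energy",
    "TransitProfile",
    "transit_profiles",
]


# ---------------------------------------------------------------------------
# 1D density profile and channel opening
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Time-averaged number density along z for one species."""

    bin_edges: np.ndarray  # Å
    density: np.ndarray  # Å⁻³
    species: str = ""
    window: tuple | None = None  # (t0, t1) ns
    span: float = 30.0  # membrane span used for dmin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def all_zero(self) -> bool:
        return not np.any(self.density > 0)

    @property
    def dmin(self) -> float:
        return channel_opening(self)[0]

    @property
    def z_at_dmin(self) -> float:
        return channel_opening(self)[1]

    def scaled(self) -> np.ndarray:
        """Profile rescaled to a maximum of 1 (presentation only)."""
        peak = self.density.max()
        return self.density / peak if peak > 0 else self.density


def density_profile(
    traj: Trajectory,
    selection: FrameSelection,
    bins: np.ndarray | float = 1.0,
    window: tuple | None = None,
    span: float = 30.0,
) -> DensityProfile:
    """Number density of a species along z, averaged over a time window.

    ``bins`` is either an explicit edge array or a bin width in Å (edges then
    cover the smallest box); ``window`` is (t0, t1) in ns.  Density is
    normalised by frame count and bin volume (bin width × lateral box area),
    so a uniform slab of n waters gives n/V per bin.
    """
    f0, f1 = 0, traj.n_frames
    if window is not None:
        t0, t1 = window
        f0 = int(round(t0 * 1000.0 / traj.dt_frame))
        f1 = int(round(t1 * 1000.0 / traj.dt_frame))
        f0, f1 = max(f0, 0), min(f1, traj.n_frames)
    if f1 <= f0:
        raise ValueError("empty analysis window")
    z = traj.z(selection)[f0:f1]
    if np.isscalar(bins):
        lz = traj.box[f0:f1, 2].min()
        half = lz / 2.0
        n_bins = max(1, int(np.floor(lz / float(bins))))
        edges = np.linspace(-half, half, n_bins + 1)
    else:
        edges = np.asarray(bins, float)
    counts, _ = np.histogram(z.ravel(), bins=edges)
    n_frames = f1 - f0
    area = float(np.mean(traj.box[f0:f1, 0] * traj.box[f0:f1, 1]))
    widths = np.diff(edges)
    density = counts / (n_frames * area * widths)
    return DensityProfile(
        bin_edges=edges,
        density=density,
        species=selection.label,
        window=(f0 * traj.dt_frame / 1000.0, f1 * traj.dt_frame / 1000.0),
        span=span,
    )


def channel_opening(profile: DensityProfile) -> tuple[float, float]:
    """(dmin, z_at_dmin): minimum density within |z| ≤ span/2.

    Ties are broken toward the z closest to 0.  An all-zero profile returns
    (0.0, 0.0) — flagged by ``profile.all_zero``.
    """
    centers = profile.bin_centers
    mask = np.abs(centers) <= profile.span / 2.0 + 1e-9
    if not mask.any():
        raise ValueError("profile does not cover the membrane span")
    if profile.all_zero:
        return 0.0, 0.0
    vals = profile.density[mask]
    zs = centers[mask]
    dmin = vals.min()
    candidates = zs[np.isclose(vals, dmin, rtol=0.0, atol=1e-300)]
    z_at = candidates[np.argmin(np.abs(candidates))]
    return float(dmin), float(z_at)


# ---------------------------------------------------------------------------
# layered 2D densities
# ---------------------------------------------------------------------------


@dataclass
class LayeredDensity2D:
    """Per-layer, per-species (x, y) number-density maps."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    z_layers: list  # [(lo, hi), ...] Å
    maps: dict  # {(species, layer_index): 2D array, Å⁻³}


def layered_density_2d(
    traj: Trajectory,
    selections: dict,
    z_layers: list | None = None,
    bin_width: float = 1.0,
) -> LayeredDensity2D:
    """2D (x, y) density maps in consecutive z layers for several species.

    ``selections`` maps species label → :class:`FrameSelection`; ``z_layers``
    defaults to six 5 Å layers covering [−15, 15].
    """
    if z_layers is None:
        z_layers = [(lo, lo + 5.0) for lo in range(-15, 15, 5)]
    lx, ly = traj.box[:, 0].min(), traj.box[:, 1].min()
    nx, ny = max(1, int(lx / bin_width)), max(1, int(ly / bin_width))
    x_edges = np.linspace(-lx / 2, lx / 2, nx + 1)
    y_edges = np.linspace(-ly / 2, ly / 2, ny + 1)
    maps = {}
    bin_area = np.outer(np.diff(x_edges), np.diff(y_edges))
    for label, sel in selections.items():
        coords = traj.coordinates[:, sel.indices, :]
        flat = coords.reshape(-1, 3)
        for li, (lo, hi) in enumerate(z_layers):
            in_layer = (flat[:, 2] >= lo) & (flat[:, 2] < hi)
            hist, _, _ = np.histogram2d(
                flat[in_layer, 0], flat[in_layer, 1], bins=[x_edges, y_edges]
            )
            maps[(label, li)] = hist / (traj.n_frames * bin_area * (hi - lo))
    return LayeredDensity2D(x_edges=x_edges, y_edges=y_edges, z_layers=z_layers, maps=maps)


# ---------------------------------------------------------------------------
# pairwise interaction energies
# ---------------------------------------------------------------------------


def coulomb_energy(q1: float, q2: float, r, k: float = COULOMB_CONSTANT):
    """Coulomb pair energy k q1 q2 / r in kcal/mol (r in Å, q in e)."""
    return k * q1 * q2 / np.asarray(r, float)


def lj_energy(epsilon, rmin, r):
    """Lennard-Jones pair energy ε[(rmin/r)¹² − 2(rmin/r)⁶] (CHARMM form):
    minimum −ε at r = rmin."""
    x = np.asarray(rmin, float) / np.asarray(r, float)
    x6 = x**6
    return np.asarray(epsilon, float) * (x6 * x6 - 2.0 * x6)


@dataclass
class EnergyModel:
    """Nonbonded interaction model: truncated LJ + Coulomb.

    ``cutoff`` in Å; with ``shift=True`` each pair term is shifted so it
    vanishes continuously at the cutoff (smoother finite-difference forces, at
    the price of shifted absolute levels).  Lorentz–Berthelot combining:
    ε_ij = sqrt(ε_i ε_j), rmin_ij = rmin_half_i + rmin_half_j.
    """

    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float = 12.0
    shift: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def pair_energy(self, q1, q2, eps1, eps2, rmin_half1, rmin_half2, r):
        """Combined LJ + Coulomb pair energy at separation r (scalar or array),
        zero beyond the cutoff."""
        r = np.asarray(r, float)
        eps = np.sqrt(np.asarray(eps1, float) * np.asarray(eps2, float))
        rmin = np.asarray(rmin_half1, float) + np.asarray(rmin_half2, float)
        u = coulomb_energy(q1, q2, r, self.coulomb_constant) + lj_energy(eps, rmin, r)
        if self.shift:
            u = u - (
                coulomb_energy(q1, q2, self.cutoff, self.coulomb_constant)
                + lj_energy(eps, rmin, self.cutoff)
            )
        return np.where(r < self.cutoff, u, 0.0)

    def site_energy(self, traj: Trajectory, frame: int, atom: int, others: np.ndarray) -> float:
        """Interaction energy of one atom with a group, minimum-image, one frame."""
        if len(others) == 0:
            return 0.0
        top = traj.topology.atoms
        pos = traj.coordinates[frame]
        box = traj.box[frame]
        d = pos[others] - pos[atom]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=1))
        near = r < self.cutoff
        if not near.any():
            return 0.0
        q = top["charge"].to_numpy(float)
        eps = top["lj_epsilon"].to_numpy(float)
        rmh = top["lj_rmin_half"].to_numpy(float)
        sel = others[near]
        u = self.pair_energy(
            q[atom], q[sel], eps[atom], eps[sel], rmh[atom], rmh[sel], r[near]
        )
        return float(np.sum(u))


# ---------------------------------------------------------------------------
# transit profiles
# ---------------------------------------------------------------------------


@dataclass
class TransitProfile:
    """Per-direction profiles of fully-transiting waters."""

    bin_centers: np.ndarray  # Å
    residence_time_density: np.ndarray  # dτ/dz, ps/Å
    mobility: np.ndarray  # Å per mobility_lag ps (NaN where unsampled)
    direction: str
    n_events: int
    u_protein: np.ndarray | None = None  # kcal/mol
    u_total: np.ndarray | None = None  # kcal/mol
    force_protein: np.ndarray | None = None  # |ΔU/Δs|, kcal/mol/Å
    force_total: np.ndarray | None = None

    def residence_integral(self) -> float:
        """∫(dτ/dz) dz — equals the mean event τ up to binning."""
        widths = np.diff(self.bin_centers).mean() if len(self.bin_centers) > 1 else 1.0
        return float(self.residence_time_density.sum() * widths)


def transit_profiles(
    traj: Trajectory,
    events: list[PermeationEvent],
    model: EnergyModel | None = None,
    bin_width: float = 1.0,
    z_extent: float = 17.5,
    mobility_lag: float = 2.0,
) -> dict[str, TransitProfile]:
    """Profiles along z of the waters performing full (confined) transits.

    For each event, every frame in (t*, t*+τ] deposits the frame spacing into
    the z bin occupied by the molecule; dividing by event count and bin width
    gives dτ/dz whose integral is the mean τ exactly.  Mobility is the mean
    3D displacement over ``mobility_lag`` ps per bin.  When charges or LJ
    parameters are present, per-bin water–protein and total interaction
    energies plus the force magnitudes |ΔU/Δs| along the molecule's own path
    are added; otherwise energetics are skipped with a warning.
    """
    confined = [e for e in events if e.confined]
    if not confined:
        raise ValueError("no confined events to profile")
    dt = traj.dt_frame
    edges = np.arange(-z_extent, z_extent + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    lag = max(1, int(round(mobility_lag / dt)))

    top = traj.topology.atoms
    seg = traj.topology.segments
    protein_idx = np.flatnonzero(seg == "protein")
    has_params = bool(
        np.any(top["charge"].to_numpy(float) != 0)
        or np.any(top["lj_epsilon"].to_numpy(float) != 0)
    )
    do_energy = has_params and model is not None
    if model is not None and not has_params:
        warnings.warn("topology carries no charges/LJ parameters; energetics skipped")

    out = {}
    for direction in ("up", "down"):
        evs = [e for e in confined if e.direction == direction]
        if not evs:
            continue
        res = np.zeros(nb)
        mob_sum, mob_cnt = np.zeros(nb), np.zeros(nb)
        up_sum, ut_sum, u_cnt = np.zeros(nb), np.zeros(nb), np.zeros(nb)
        fp_sum, ft_sum, f_cnt = np.zeros(nb), np.zeros(nb), np.zeros(nb)
        for ev in evs:
            mol = ev.molecule_id
            f0 = ev.t_star_frame
            n_tau = int(round(ev.tau / dt))
            frames = np.arange(f0 + 1, f0 + n_tau + 1)
            frames = frames[frames < traj.n_frames]
            zs = traj.coordinates[frames, mol, 2]
            bins_idx = np.clip(np.digitize(zs, edges) - 1, 0, nb - 1)
            np.add.at(res, bins_idx, dt)
            # mobility
            ok = frames + lag < traj.n_frames
            if ok.any():
                d = traj.coordinates[frames[ok] + lag, mol, :] - traj.coordinates[frames[ok], mol, :]
                box = traj.box[frames[ok]]
                d -= box * np.round(d / box)
                disp = np.sqrt((d**2).sum(axis=1))
                np.add.at(mob_sum, bins_idx[ok], disp)
                np.add.at(mob_cnt, bins_idx[ok], 1)
            if do_energy:
                not_self = np.setdiff1d(np.arange(traj.n_atoms), [mol])
                u_p = np.array(
                    [model.site_energy(traj, f, mol, protein_idx) for f in frames]
                )
                u_t = np.array(
                    [model.site_energy(traj, f, mol, not_self) for f in frames]
                )
                np.add.at(up_sum, bins_idx, u_p)
                np.add.at(ut_sum, bins_idx, u_t)
                np.add.at(u_cnt, bins_idx, 1)
                # |ΔU/Δs| along the molecule's own 3D path, centred differences
                dpath = traj.coordinates[frames[1:], mol, :] - traj.coordinates[frames[:-1], mol, :]
                bx = traj.box[frames[1:]]
                dpath -= bx * np.round(dpath / bx)
                ds = np.sqrt((dpath**2).sum(axis=1))
                s = np.concatenate([[0.0], np.cumsum(ds)])
                if len(frames) >= 3:
                    denom = s[2:] - s[:-2]
                    good = denom > 1e-12
                    fp = np.abs(u_p[2:] - u_p[:-2])[good] / denom[good]
                    ft = np.abs(u_t[2:] - u_t[:-2])[good] / denom[good]
                    mid = bins_idx[1:-1][good]
                    np.add.at(fp_sum, mid, fp)
                    np.add.at(ft_sum, mid, ft)
                    np.add.at(f_cnt, mid, 1)
        n_ev = len(evs)
        with np.errstate(invalid="ignore", divide="ignore"):
            profile = TransitProfile(
                bin_centers=centers,
                residence_time_density=res / (n_ev * bin_width),
                mobility=np.where(mob_cnt > 0, mob_sum / mob_cnt, np.nan),
                direction=direction,
                n_events=n_ev,
                u_protein=np.where(u_cnt > 0, up_sum / u_cnt, np.nan) if do_energy else None,
                u_total=np.where(u_cnt > 0, ut_sum / u_cnt, np.nan) if do_energy else None,
                force_protein=np.where(f_cnt > 0, fp_sum / f_cnt, np.nan) if do_energy else None,
                force_total=np.where(f_cnt > 0, ft_sum / f_cnt, np.nan) if do_energy else None,
            )
        out[direction] = profile
    return out
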