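"""Principal component analysis of domain motion and protein softness.

The covariance matrix of centred (optionally mass-weighted) bead coordinates
is diagonalised into modes e_i with eigenvalues λ_i (Å², the mean-square
fluctuation along the mode).  Each mode gets

* a stiffness κ_i = kBT/λ_i and a mode softness σ_i = λ_i (Å²),
* a vibrational weight wv_i ∈ [0, 1] — the fraction of the mode's kinetic
  energy not attributable to rigid rotation about the CoM, computed from the
  displacement field's angular momentum Γ = Σ_k m_k r_k × e_k and the moment
  of inertia J about the Γ axis:
  ``wv = (W_tot − |Γ|²/2J) / W_tot`` with ``W_tot = ½ Σ_k m_k |e_k|²``,
* in the mass-weighted branch, a quasi-harmonic frequency
  ω_i = sqrt(kBT/λ̃_i).

The overall softness is σ = Σ_i λ_i wv_i (Å²; σ/kBT is reported alongside),
and the intensity of a predefined motion P (|P| = 1) is the projected
softness σ_P = Σ_i λ_i wv_i (P·e_i)².  The squared projection is used because
eigenvector signs are arbitrary: a linear dot product would make σ_P
sign-indeterminate, while the squared form is an intensity satisfying
Σ_basis σ_P = σ over any orthonormal basis and σ_P = λ_j wv_j when P = e_j.

Rigid-body translation is removed exactly (per-frame CoM subtraction); rigid
rotation is deliberately *not* removed — its residue is measured by wv.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, OMEGA_TO_INV_PS
from .errors import SelectionError
from .trajectory import FrameSelection, Trajectory

__all__ = [
    "BeadTrajectory",
    "four_bead_reduction",
    "pca",
    "vibrational_weights",
    "softness",
    "projected_softness",
    "rocking_bundle_vectors",
    "ProjectionVector",
    "DomainSoftnessModel",
    "SoftnessResults",
]

FOUR_BEAD_LABELS = ("bundle_lower", "bundle_upper", "hash_lower", "hash_upper")


@dataclass
class BeadTrajectory:
    """Bead positions with per-frame mass-weighted CoM translation removed."""

    masses: np.ndarray
    positions: np.ndarray  # (n_frames, n_beads, 3), Å
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, float)
        self.positions = np.asarray(self.positions, float)
        com = np.einsum("k,tkd->td", self.masses, self.positions) / self.masses.sum()
        self.positions = self.positions - com[:, None, :]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def reference(self) -> np.ndarray:
        """Mean (reference) bead positions."""
        return self.positions.mean(axis=0)

    @classmethod
    def from_trajectory(
        cls, traj: Trajectory, selection: FrameSelection | None = None, labels=()
    ) -> "BeadTrajectory":
        idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
        return cls(
            masses=traj.topology.masses[idx],
            positions=traj.coordinates[:, idx, :],
            labels=tuple(labels),
        )


def four_bead_reduction(traj: Trajectory, domains: dict | None = None) -> BeadTrajectory:
    """Reduce bundle and hash domains to four beads.

    Each domain contributes two beads: the mass-weighted CoM of its lower and
    upper halves, split at the domain's own CoM z in the reference (time-mean)
    structure, so the atom assignment is fixed across frames.  Bead masses are
    the summed atom masses; the four-bead CoM translation is removed.

    ``domains`` optionally maps ``{"bundle": indices, "hash": indices}``;
    by default the topology's ``domain_label`` column is used.
    """
    top = traj.topology.atoms
    if domains is None:
        domains = {}
        for name in ("bundle", "hash"):
            idx = top.loc[top["domain_label"] == name, "atom_index"].to_numpy(int)
            domains[name] = idx
    for name in ("bundle", "hash"):
        if name not in domains or len(domains[name]) == 0:
            raise SelectionError(f"domain '{name}' is missing or empty")

    mean_coords = traj.coordinates.mean(axis=0)
    masses_all = traj.topology.masses
    bead_pos, bead_mass, labels = [], [], []
    for name in ("bundle", "hash"):
        idx = np.asarray(domains[name], int)
        m = masses_all[idx]
        split_z = (mean_coords[idx, 2] * m).sum() / m.sum()
        lower = idx[mean_coords[idx, 2] < split_z]
        upper = idx[mean_coords[idx, 2] >= split_z]
        if len(lower) == 0 or len(upper) == 0:
            # degenerate flat domain: split evenly by z order instead
            order = idx[np.argsort(mean_coords[idx, 2], kind="stable")]
            lower, upper = order[: len(idx) // 2], order[len(idx) // 2 :]
        for half_idx, suffix in ((lower, "lower"), (upper, "upper")):
            mh = masses_all[half_idx]
            com = np.einsum(
                "k,tkd->td", mh, traj.coordinates[:, half_idx, :]
            ) / mh.sum()
            bead_pos.append(com)
            bead_mass.append(mh.sum())
            labels.append(f"{name}_{suffix}")
    positions = np.stack(bead_pos, axis=1)
    return BeadTrajectory(
        masses=np.asarray(bead_mass), positions=positions, labels=tuple(labels)
    )


@dataclass
class ProjectionVector:
    """A unit-norm 3n reference-mode vector P."""

    components: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.components, float).ravel()
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("projection vector must be nonzero")
        if abs(norm - 1.0) > 1e-8:
            warnings.warn("projection vector was not unit norm; normalising")
            v = v / norm
        self.components = v


@dataclass
class SoftnessResults:
    """Eigenmodes, vibrational weights and softness of one bead trajectory."""

    covariance: np.ndarray  # (3n, 3n), Å² (amu Å² when mass-weighted)
    eigenvalues: np.ndarray  # λ_i, descending
    eigenvectors: np.ndarray  # columns e_i, orthonormal
    kbt: float  # kcal/mol
    mass_weighted: bool
    masses: np.ndarray
    reference: np.ndarray  # (n, 3) reference bead positions (CoM at origin)
    labels: tuple = ()
    vib_weights: np.ndarray | None = None  # wv_i ∈ [0, 1]
    zero_modes: np.ndarray | None = None  # flags for numerically null modes

    # -- derived ----------------------------------------------------------
    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def stiffness(self) -> np.ndarray:
        """κ_i = kBT/λ_i (kcal/mol/Å² on the unweighted branch)."""
        with np.errstate(divide="ignore"):
            return np.where(self.eigenvalues > 0, self.kbt / self.eigenvalues, np.inf)

    @property
    def quasi_frequencies(self) -> np.ndarray:
        """ω_i = sqrt(kBT/λ̃_i) in ps⁻¹ (mass-weighted branch only)."""
        if not self.mass_weighted:
            raise ValueError("quasi-harmonic frequencies require mass_weighted=True")
        with np.errstate(divide="ignore"):
            lam = np.where(self.eigenvalues > 0, self.eigenvalues, np.inf)
            return OMEGA_TO_INV_PS * np.sqrt(self.kbt / lam)

    @property
    def mode_softness(self) -> np.ndarray:
        """λ_i wv_i (Å² on the unweighted branch)."""
        self._require_wv()
        return self.eigenvalues * self.vib_weights

    @property
    def softness(self) -> float:
        """σ = Σ_i λ_i wv_i, Å²."""
        return float(self.mode_softness.sum())

    @property
    def softness_over_kbt(self) -> float:
        """σ/kBT in Å² mol/kcal — the same sum carrying the 1/kBT factor."""
        return self.softness / self.kbt

    def _require_wv(self) -> None:
        if self.vib_weights is None:
            raise ValueError("vibrational weights not computed; call vibrational_weights")

    def project(self, p: ProjectionVector | np.ndarray) -> float:
        """Projected softness σ_P = Σ_i λ_i wv_i (P·e_i)²."""
        return projected_softness(self, p)

    def mode_table(self) -> pd.DataFrame:
        data = {
            "eigenvalue": self.eigenvalues,
            "stiffness": self.stiffness,
        }
        if self.vib_weights is not None:
            data["vib_weight"] = self.vib_weights
            data["mode_softness"] = self.mode_softness
        if self.mass_weighted:
            data["omega_per_ps"] = self.quasi_frequencies
        return pd.DataFrame(data)

    def summary(self) -> str:
        branch = "mass-weighted" if self.mass_weighted else "unweighted"
        lines = [
            f"Domain softness analysis ({branch}, kBT = {self.kbt:.5f} kcal/mol)",
            "-" * 60,
            self.mode_table().to_string(float_format=lambda x: f"{x:.5g}"),
        ]
        if self.vib_weights is not None:
            lines += [
                "-" * 60,
                f"softness sigma        {self.softness:.6g} A^2",
                f"sigma / kBT           {self.softness_over_kbt:.6g} A^2 mol/kcal",
            ]
        return "\n".join(lines)


def pca(
    beads: BeadTrajectory,
    temperature: float = DEFAULT_TEMPERATURE,
    mass_weighted: bool = False,
) -> SoftnessResults:
    """Covariance eigendecomposition of the bead trajectory.

    Coordinates are centred (the per-frame CoM translation was already removed
    when the :class:`BeadTrajectory` was built); in the mass-weighted branch
    q_k = sqrt(m_k) r_k.  Eigenvalues are returned descending and each
    eigenvector's sign is fixed so its largest-magnitude component is
    positive.  A warning is emitted with fewer than 10 frames per degree of
    freedom, and trailing numerically-null modes are flagged.
    """
    x = beads.positions.reshape(beads.n_frames, -1)
    dof = x.shape[1]
    if beads.n_frames < 10 * dof:
        warnings.warn(
            f"{beads.n_frames} frames for {dof} degrees of freedom "
            "(fewer than 10 per DoF); eigenvalues will be noisy"
        )
    if mass_weighted:
        x = x * np.sqrt(np.repeat(beads.masses, 3))
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / max(beads.n_frames - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    peak = np.abs(evecs).argmax(axis=0)
    signs = np.sign(evecs[peak, np.arange(dof)])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    tol = max(evals.max(), 1.0) * 1e-12
    zero_modes = evals <= tol
    if beads.n_frames - 1 < dof:
        warnings.warn("fewer frames than degrees of freedom; trailing modes are null")
    return SoftnessResults(
        covariance=cov,
        eigenvalues=evals,
        eigenvectors=evecs,
        kbt=KB_KCAL * temperature,
        mass_weighted=mass_weighted,
        masses=beads.masses.copy(),
        reference=beads.reference,
        labels=beads.labels,
        zero_modes=zero_modes,
    )


def vibrational_weights(result: SoftnessResults, beads: BeadTrajectory | None = None) -> SoftnessResults:
    """Attach wv_i to every mode (in place; also returned).

    For each mode the eigenvector is read as a bead displacement field (in the
    mass-weighted branch e is first un-weighted by 1/sqrt(m_k)); then
    ``W_tot = ½ Σ m_k |e_k|²``, ``Γ = Σ m_k r_k × e_k``,
    ``W_R = |Γ|² / 2J`` with J the moment of inertia about the Γ axis through
    the CoM, and ``wv = (W_tot − W_R)/W_tot`` clamped to [0, 1].  Null modes
    get wv = 0.
    """
    ref = beads.reference if beads is not None else result.reference
    masses = result.masses
    n = len(masses)
    wv = np.zeros(result.n_modes)
    for i in range(result.n_modes):
        e = result.eigenvectors[:, i].reshape(n, 3)
        if result.mass_weighted:
            e = e / np.sqrt(masses)[:, None]
        w_tot = 0.5 * float((masses * (e**2).sum(axis=1)).sum())
        if w_tot <= 0 or (result.zero_modes is not None and result.zero_modes[i]):
            wv[i] = 0.0
            continue
        gamma = (masses[:, None] * np.cross(ref, e)).sum(axis=0)
        g2 = float(gamma @ gamma)
        if g2 <= 1e-300:
            wv[i] = 1.0
            continue
        axis = gamma / np.sqrt(g2)
        perp = ref - np.outer(ref @ axis, axis)
        j_axis = float((masses * (perp**2).sum(axis=1)).sum())
        w_rot = g2 / (2.0 * j_axis) if j_axis > 0 else 0.0
        wv[i] = np.clip((w_tot - w_rot) / w_tot, 0.0, 1.0)
    result.vib_weights = wv
    return result


def softness(result: SoftnessResults) -> float:
    """σ = Σ_i λ_i wv_i (Å²)."""
    return result.softness


def projected_softness(result: SoftnessResults, p) -> float:
    """σ_P = Σ_i λ_i wv_i (P·e_i)² for a unit reference mode P."""
    if not isinstance(p, ProjectionVector):
        p = ProjectionVector(np.asarray(p, float))
    result._require_wv()
    overlaps = p.components @ result.eigenvectors
    return float((result.eigenvalues * result.vib_weights * overlaps**2).sum())


def rocking_bundle_vectors(beads: BeadTrajectory) -> list[ProjectionVector]:
    """Reference modes of bundle–hash domain motion for the four-bead model.

    Returns two unit, mutually orthogonal, translation-free vectors:

    1. *separation* — both bundle beads move opposite to both hash beads along
       the inter-domain axis (modulates the bundle–hash distance);
    2. *rocking* — the upper beads converge while the lower beads diverge
       along the same axis.
    """
    if beads.n_beads != 4:
        raise SelectionError("rocking-bundle vectors require the four-bead model")
    labels = beads.labels or FOUR_BEAD_LABELS
    order = {lab: k for k, lab in enumerate(labels)}
    missing = [lab for lab in FOUR_BEAD_LABELS if lab not in order]
    if missing:
        raise SelectionError(f"four-bead labels missing: {missing}")
    ref = beads.reference
    m = beads.masses
    bl, bu = order["bundle_lower"], order["bundle_upper"]
    hl, hu = order["hash_lower"], order["hash_upper"]
    bundle_com = (m[bl] * ref[bl] + m[bu] * ref[bu]) / (m[bl] + m[bu])
    hash_com = (m[hl] * ref[hl] + m[hu] * ref[hu]) / (m[hl] + m[hu])
    axis = bundle_com - hash_com
    norm = np.linalg.norm(axis)
    if norm < 1e-8 or np.linalg.norm(ref[bu] - ref[bl]) < 1e-8:
        raise SelectionError("degenerate four-bead geometry (coincident beads)")
    axis = axis / norm

    def _build(signs, label):
        disp = np.zeros((4, 3))
        for bead, s in signs.items():
            disp[order[bead]] = s * axis
        disp -= (m[:, None] * disp).sum(axis=0) / m.sum()  # translation-free
        return disp.ravel()

    v1 = _build(
        {"bundle_lower": 1, "bundle_upper": 1, "hash_lower": -1, "hash_upper": -1},
        "separation",
    )
    v2 = _build(
        {"bundle_lower": 1, "bundle_upper": -1, "hash_lower": -1, "hash_upper": 1},
        "rocking",
    )
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 - (v2 @ v1) * v1  # Gram–Schmidt
    v2 = v2 / np.linalg.norm(v2)
    return [ProjectionVector(v1, "separation"), ProjectionVector(v2, "rocking")]


class DomainSoftnessModel:
    """PCA-softness analysis of domain motion.

    Accepts either a :class:`BeadTrajectory` or an atomistic
    :class:`~aquaflux.trajectory.Trajectory` carrying ``bundle``/``hash``
    domain labels (reduced to four beads automatically).

    Examples
    --------
    >>> res = DomainSoftnessModel(beads).fit()            # doctest: +SKIP
    >>> res.softness, res.project(rocking)                # doctest: +SKIP
    """

    def __init__(
        self,
        data,
        temperature: float = DEFAULT_TEMPERATURE,
        mass_weighted: bool = False,
    ):
        if isinstance(data, Trajectory):
            data = four_bead_reduction(data)
        self.beads: BeadTrajectory = data
        self.temperature = temperature
        self.mass_weighted = mass_weighted

    def fit(self) -> SoftnessResults:
        result = pca(self.beads, self.temperature, self.mass_weighted)
        return vibrational_weights(result, self.beads)
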