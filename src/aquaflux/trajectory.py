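"""In-memory trajectory/topology model, file I/O, selections, centering, unwrapping.

Conventions
-----------
* The membrane normal is the z axis; after :func:`center_on_group` the origin is
  the per-frame mass-weighted centre of mass (CoM) of the centering group
  (typically the protein).
* Internal units: Å, ps, amu, kcal/mol, elementary charges.
* Boxes are orthorhombic; only the three box lengths are kept.
* A water molecule is tracked by a single particle (its oxygen), standing in for
  the molecule CoM.

File formats are delegated to MDAnalysis (PDB/PSF topologies, DCD/XTC
coordinates, DCD output).  Force-field parameters and domain labels, which no
coordinate format carries, live in a plain-CSV topology table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    SelectionError,
    TopologyMismatchError,
    TrajectoryFormatError,
    UndersamplingError,
)

TOPOLOGY_COLUMNS = [
    "atom_index",
    "name",
    "residue_id",
    "residue_name",
    "segment",
    "mass",
    "charge",
    "lj_epsilon",
    "lj_rmin_half",
    "domain_label",
]


@dataclass
class Topology:
    """Per-atom metadata table.

    Parameters
    ----------
    atoms : pandas.DataFrame
        One row per atom with the columns of :data:`TOPOLOGY_COLUMNS`.
        ``segment`` is a coarse group label (``protein``/``water``/``membrane``
        or similar); ``domain_label`` is one of ``bundle``/``hash``/``gate``/
        ``none`` and may be non-``none`` only for protein atoms.
    """

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.atoms
        missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
        if missing:
            raise TrajectoryFormatError(f"topology table missing columns: {missing}")
        if len(df) and not (df["mass"].to_numpy(float) > 0).all():
            raise TrajectoryFormatError("all atom masses must be positive")
        bad = df[(df["domain_label"] != "none") & (df["segment"] != "protein")]
        if len(bad):
            raise TrajectoryFormatError(
                "domain_label set on non-protein atoms: rows "
                f"{bad['atom_index'].tolist()[:5]}"
            )
        self.atoms = df.reset_index(drop=True)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        *,
        names,
        segments,
        masses,
        charges=None,
        lj_epsilon=None,
        lj_rmin_half=None,
        residue_ids=None,
        residue_names=None,
        domain_labels=None,
    ) -> "Topology":
        n = len(names)
        zeros = np.zeros(n)
        df = pd.DataFrame(
            {
                "atom_index": np.arange(n),
                "name": list(names),
                "residue_id": residue_ids if residue_ids is not None else np.arange(n),
                "residue_name": (
                    residue_names if residue_names is not None else list(names)
                ),
                "segment": list(segments),
                "mass": np.asarray(masses, float),
                "charge": np.asarray(charges, float) if charges is not None else zeros,
                "lj_epsilon": (
                    np.asarray(lj_epsilon, float) if lj_epsilon is not None else zeros
                ),
                "lj_rmin_half": (
                    np.asarray(lj_rmin_half, float)
                    if lj_rmin_half is not None
                    else zeros
                ),
                "domain_label": (
                    list(domain_labels) if domain_labels is not None else ["none"] * n
                ),
            }
        )
        return cls(df)

    @classmethod
    def from_universe(cls, universe) -> "Topology":
        """Build a table from an ``MDAnalysis.Universe`` (PSF carries masses and
        charges; for PDB-only input MDAnalysis-guessed masses are used)."""
        ag = universe.atoms
        n = len(ag)

        def _get(attr, default):
            try:
                return np.asarray(getattr(ag, attr))
            except Exception:
                return default

        masses = _get("masses", np.full(n, 1.0))
        masses = np.where(np.asarray(masses, float) > 0, masses, 1.0)
        segments = []
        for a in ag:
            seg = ""
            for attr in ("segid", "chainID"):
                seg = getattr(a, attr, "") or seg
            segments.append(str(seg) if seg else "all")
        return cls.from_arrays(
            names=[a.name for a in ag],
            segments=segments,
            masses=masses,
            charges=_get("charges", np.zeros(n)),
            residue_ids=_get("resids", np.arange(n)),
            residue_names=[getattr(a, "resname", "UNK") for a in ag],
        )

    @classmethod
    def from_csv(cls, path) -> "Topology":
        return cls(pd.read_csv(path, keep_default_na=False))

    def to_csv(self, path) -> None:
        self.atoms.to_csv(path, index=False)

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy(float)

    @property
    def charges(self) -> np.ndarray:
        return self.atoms["charge"].to_numpy(float)

    @property
    def segments(self) -> np.ndarray:
        return self.atoms["segment"].to_numpy()

    def with_parameters(self, mapping: dict) -> "Topology":
        """Return a copy with LJ parameters (and optionally charges) applied by
        atom name: ``{name: {"lj_epsilon": ..., "lj_rmin_half": ..., "charge": ...}}``.
        """
        df = self.atoms.copy()
        for name, params in mapping.items():
            mask = df["name"] == name
            for key, val in params.items():
                df.loc[mask, key] = val
        return Topology(df)

    def with_domains(self, assignments: dict) -> "Topology":
        """Return a copy with ``domain_label`` set from ``{label: selection}``
        where *selection* is a mini selection string (see :func:`select`)."""
        df = self.atoms.copy()
        for label, sel_str in assignments.items():
            idx = select(self, sel_str).indices
            df.loc[df["atom_index"].isin(idx), "domain_label"] = label
        return Topology(df)


@dataclass
class FrameSelection:
    """An ordered, duplicate-free list of atom indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise SelectionError(f"duplicate indices in selection '{self.label}'")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Coordinates for every frame plus topology metadata.

    Attributes
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3), Å
    box : ndarray, shape (n_frames, 3), Å — orthorhombic box lengths
    dt_frame : float, ps between stored frames
    topology : Topology
    """

    coordinates: np.ndarray
    box: np.ndarray
    dt_frame: float
    topology: Topology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryFormatError("coordinates must have shape (frames, atoms, 3)")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise TrajectoryFormatError("box must have shape (frames, 3)")
        if not (self.box > 0).all():
            raise TrajectoryFormatError("box lengths must be positive")
        if self.dt_frame <= 0:
            raise TrajectoryFormatError("dt_frame must be positive")
        if self.coordinates.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                f"{self.coordinates.shape[1]} coordinate atoms vs "
                f"{len(self.topology)} topology atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.dt_frame

    def z(self, selection: FrameSelection | None = None) -> np.ndarray:
        """z coordinates, shape (n_frames, n_selected)."""
        if selection is None:
            return self.coordinates[:, :, 2]
        return self.coordinates[:, selection.indices, 2]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return replace(
            self,
            coordinates=self.coordinates[start:stop],
            box=self.box[start:stop],
        )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_SELECTION_KEYS = {
    "segment": "segment",
    "name": "name",
    "resname": "residue_name",
    "resid": "residue_id",
    "domain": "domain_label",
    "index": "atom_index",
}


def select(topology: Topology, expression: str, label: str | None = None) -> FrameSelection:
    """Select atoms with a mini expression of space-separated ``key:value`` clauses.

    Clauses are AND-combined; comma-separated values within a clause are
    OR-combined.  Keys: ``segment``, ``name``, ``resname``, ``resid``,
    ``domain``, ``index`` (``index`` and ``resid`` accept ``lo-hi`` ranges).

    >>> select(top, "segment:water name:O")        # doctest: +SKIP
    >>> select(top, "domain:bundle,hash")          # doctest: +SKIP
    """
    df = topology.atoms
    mask = np.ones(len(df), dtype=bool)
    for clause in expression.split():
        if ":" not in clause:
            raise SelectionError(f"malformed clause '{clause}' (expected key:value)")
        key, _, value = clause.partition(":")
        if key not in _SELECTION_KEYS:
            raise SelectionError(f"unknown selection key '{key}'")
        col = df[_SELECTION_KEYS[key]]
        clause_mask = np.zeros(len(df), dtype=bool)
        for val in value.split(","):
            if key in ("resid", "index"):
                ivals = col.to_numpy(int)
                if "-" in val:
                    lo, _, hi = val.partition("-")
                    clause_mask |= (ivals >= int(lo)) & (ivals <= int(hi))
                else:
                    clause_mask |= ivals == int(val)
            else:
                clause_mask |= (col == val).to_numpy()
        mask &= clause_mask
    indices = df.loc[mask, "atom_index"].to_numpy(int)
    if len(indices) == 0:
        raise SelectionError(f"selection '{expression}' matches no atoms")
    return FrameSelection(indices=indices, label=label or expression)


# ---------------------------------------------------------------------------
# file I/O (via MDAnalysis)
# ---------------------------------------------------------------------------


def load_trajectory(topology_path, coords_path, dt_frame: float | None = None) -> Trajectory:
    """Read a topology (PDB/PSF or the package's topology CSV) plus a
    coordinate file (DCD/XTC/PDB) into an in-memory :class:`Trajectory`.

    ``dt_frame`` overrides the time step recorded in the coordinate file
    (many writers store a bogus default).
    """
    import MDAnalysis as mda

    topology_path, coords_path = str(topology_path), str(coords_path)
    if topology_path.endswith(".csv"):
        topology = Topology.from_csv(topology_path)
        try:
            universe = mda.Universe.empty(len(topology), trajectory=True)
            universe.load_new(coords_path)
        except ValueError as exc:
            raise TopologyMismatchError(str(exc)) from exc
        except Exception as exc:  # pragma: no cover - format dependent
            raise TrajectoryFormatError(str(exc)) from exc
    else:
        try:
            universe = mda.Universe(topology_path, coords_path)
        except ValueError as exc:
            raise TopologyMismatchError(str(exc)) from exc
        except Exception as exc:
            raise TrajectoryFormatError(str(exc)) from exc
        topology = Topology.from_universe(universe)
    if universe.atoms.n_atoms != len(topology):
        raise TopologyMismatchError(
            f"{universe.atoms.n_atoms} atoms in coordinates vs {len(topology)} in topology"
        )
    frames, boxes = [], []
    for ts in universe.trajectory:
        frames.append(ts.positions.astype(float).copy())
        dims = ts.dimensions
        boxes.append(dims[:3].astype(float) if dims is not None else np.full(3, np.nan))
    boxes = np.asarray(boxes)
    if np.isnan(boxes).any():
        raise TrajectoryFormatError("coordinate file carries no box dimensions")
    if dt_frame is None:
        dt_frame = float(getattr(universe.trajectory, "dt", 1.0) or 1.0)
    return Trajectory(
        coordinates=np.asarray(frames), box=boxes, dt_frame=dt_frame, topology=topology
    )


def write_trajectory(traj: Trajectory, coords_path, topology_path=None) -> None:
    """Write coordinates to DCD (via MDAnalysis) and, optionally, the topology
    table to CSV (``.csv``) or a minimal PDB."""
    import MDAnalysis as mda

    universe = mda.Universe.empty(traj.n_atoms, trajectory=True)
    coords_path = str(coords_path)
    with mda.Writer(coords_path, traj.n_atoms) as writer:
        for f in range(traj.n_frames):
            universe.atoms.positions = traj.coordinates[f].astype(np.float32)
            universe.dimensions = np.array(
                [*traj.box[f], 90.0, 90.0, 90.0], dtype=np.float32
            )
            writer.write(universe.atoms)
    if topology_path is not None:
        topology_path = str(topology_path)
        if topology_path.endswith(".csv"):
            traj.topology.to_csv(topology_path)
        else:
            _write_minimal_pdb(traj, topology_path)


def _write_minimal_pdb(traj: Trajectory, path: str) -> None:
    df = traj.topology.atoms
    xyz = traj.coordinates[0]
    with open(path, "w") as fh:
        lx, ly, lz = traj.box[0]
        fh.write(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for i, row in df.iterrows():
            name = str(row["name"])[:4]
            resname = str(row["residue_name"])[:3]
            seg = str(row["segment"])[:1].upper() or "A"
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} {resname:<3s} {seg}{int(row['residue_id']) % 10000:4d}    "
                f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# coordinate operations
# ---------------------------------------------------------------------------


def center_on_group(traj: Trajectory, group: FrameSelection) -> Trajectory:
    """Shift every frame along z so the mass-weighted CoM of *group* sits at z=0.

    Only the z axis is recentred (the membrane-normal convention); relative
    geometry is untouched.  Idempotent.
    """
    if len(group) == 0:
        raise SelectionError("cannot center on an empty group")
    masses = traj.topology.masses[group.indices]
    com_z = (
        traj.coordinates[:, group.indices, 2] * masses
    ).sum(axis=1) / masses.sum()
    coords = traj.coordinates.copy()
    coords[:, :, 2] -= com_z[:, None]
    return replace(traj, coordinates=coords)


def unwrap_z(traj: Trajectory, molecules: FrameSelection) -> Trajectory:
    """Remove periodic z-wrapping from the tracked molecules' coordinates.

    Each tracked particle's z series becomes continuous; the output differs
    from the input by integer multiples of the per-frame box z length.  Raises
    :class:`UndersamplingError` when a corrected frame-to-frame displacement
    still reaches half the box (the stride is too coarse to disambiguate).
    """
    coords = traj.coordinates.copy()
    z = coords[:, molecules.indices, 2]
    box_z = traj.box[:, 2]
    dz = np.diff(z, axis=0)
    shift = -np.round(dz / box_z[1:, None]) * box_z[1:, None]
    dz_corr = dz + shift
    if (np.abs(dz_corr) > 0.5 * box_z[1:, None] - 1e-9).any():
        raise UndersamplingError(
            "a frame-to-frame z displacement reaches half the box; "
            "the frame stride is too coarse to unwrap"
        )
    z_unwrapped = np.concatenate([z[:1], z[:1] + np.cumsum(dz_corr, axis=0)], axis=0)
    coords[:, molecules.indices, 2] = z_unwrapped
    return replace(traj, coordinates=coords)


def minimum_image_dz(z: np.ndarray, box_z: np.ndarray) -> np.ndarray:
    """Per-frame-pair z displacements folded to the minimum image.

    Parameters
    ----------
    z : (n_frames, n_molecules) wrapped z coordinates
    box_z : (n_frames,) box z lengths
    """
    dz = np.diff(z, axis=0)
    bz = box_z[1:, None]
    return dz - np.round(dz / bz) * bz
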