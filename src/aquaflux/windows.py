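"""Per-window statistics and the flux–opening–softness correlation analysis.

The trajectory is cut into equal analysis windows (100 ns in production use;
the remainder is dropped).  Each window yields one record: permeation rate
nw, channel opening dmin, four-bead domain softness σ_dmn, selected-atom
softness σ_sel, rocking-bundle projected softness σ_rb, and the local water
diffusion in the 5 Å constriction slab divided by the channel length, D/L.
Pearson correlations (with least-squares lines) across windows then link
instantaneous water flux to channel opening and domain motion:

* nw vs dmin,
* nw/dmin vs σ_dmn and vs σ_sel (flux per unit opening scales as D/L),
* D/L vs σ_rb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError
from .pca import DomainSoftnessModel, BeadTrajectory, four_bead_reduction, rocking_bundle_vectors
from .permeation import SlabGeometry, detect_permeation_events, permeation_rate
from .profiles import density_profile, channel_opening
from .trajectory import FrameSelection, Trajectory, select

__all__ = [
    "WindowConfig",
    "WindowStats",
    "window_stats",
    "local_diffusion",
    "correlate",
    "CorrelationResult",
    "flux_opening_report",
    "FluxOpeningReport",
    "WindowCorrelationModel",
    "WindowCorrelationResults",
]


@dataclass
class WindowConfig:
    """Configuration of the per-window analysis."""

    window_ns: float = 100.0
    slab: SlabGeometry = field(default_factory=SlabGeometry)
    constriction_width: float = 5.0
    water_selection: str = "segment:water"
    softness_selection: str | None = "segment:protein"
    temperature: float = 303.15
    msd_lags: tuple = (2.0, 10.0)  # ps
    bin_width: float = 1.0


@dataclass
class WindowStats:
    """One analysis window's record."""

    t0: float  # ns
    t1: float  # ns
    nw: float  # events / 100 ns
    dmin: float  # Å⁻³
    sigma_dmn: float = np.nan  # Å², four-bead softness
    sigma_sel: float = np.nan  # Å², selected-atom softness
    sigma_rb: float = np.nan  # Å², rocking-bundle projected softness
    d_over_l: float = np.nan  # ps⁻¹

    @property
    def nw_over_dmin(self) -> float:
        return self.nw / self.dmin if self.dmin > 0 else np.nan


def window_stats(traj: Trajectory, config: WindowConfig | None = None) -> list[WindowStats]:
    """Compute one :class:`WindowStats` per full window (remainder dropped).

    Each window is analysed independently: events, density minimum and
    softness are computed on that window's frames only.
    """
    config = config or WindowConfig()
    frames_per_window = int(round(config.window_ns * 1000.0 / traj.dt_frame))
    if frames_per_window < 10:
        raise InsufficientDataError(
            "analysis window shorter than 10 frame strides; refine the stride"
        )
    n_windows = traj.n_frames // frames_per_window
    if n_windows == 0:
        raise InsufficientDataError("trajectory shorter than one analysis window")
    waters_all = select(traj.topology, config.water_selection)
    has_beads = (traj.topology.atoms["domain_label"] != "none").any()

    records = []
    for w in range(n_windows):
        f0, f1 = w * frames_per_window, (w + 1) * frames_per_window
        sub = traj.slice_frames(f0, f1)
        duration_ns = (sub.n_frames - 1) * sub.dt_frame / 1000.0
        events = detect_permeation_events(sub, waters_all, config.slab)
        nw = permeation_rate(events, duration_ns)
        profile = density_profile(
            sub, waters_all, bins=config.bin_width, span=config.slab.span
        )
        dmin, z_at = channel_opening(profile)
        rec = WindowStats(
            t0=f0 * traj.dt_frame / 1000.0,
            t1=f1 * traj.dt_frame / 1000.0,
            nw=nw,
            dmin=dmin,
        )
        if has_beads:
            beads = four_bead_reduction(sub)
            res = DomainSoftnessModel(beads, config.temperature).fit()
            rec.sigma_dmn = res.softness
            rec.sigma_rb = sum(res.project(p) for p in rocking_bundle_vectors(beads))
        if config.softness_selection is not None:
            try:
                sel = select(traj.topology, config.softness_selection)
                bt = BeadTrajectory.from_trajectory(sub, sel)
                rec.sigma_sel = DomainSoftnessModel(bt, config.temperature).fit().softness
            except Exception:
                rec.sigma_sel = np.nan
        half_w = config.constriction_width / 2.0
        d_local = local_diffusion(
            sub, waters_all, (z_at - half_w, z_at + half_w), lag_range=config.msd_lags
        )
        rec.d_over_l = d_local / config.slab.span if np.isfinite(d_local) else np.nan
        records.append(rec)
    return records


def local_diffusion(
    traj: Trajectory,
    waters: FrameSelection,
    constriction: tuple,
    lag_range: tuple = (2.0, 10.0),
) -> float:
    """Local diffusion coefficient (Å²/ps) in a z slab from the 3D MSD.

    Only contiguous segments during which a molecule stays inside
    ``constriction = (z_lo, z_hi)`` contribute; D is the least-squares slope/6
    of the MSD over lag times in ``lag_range`` ps.  Returns NaN when no water
    ever samples the region long enough.
    """
    z_lo, z_hi = constriction
    dt = traj.dt_frame
    coords = traj.coordinates[:, waters.indices, :]
    box = traj.box
    # locally unwrap so displacements are physical
    d = np.diff(coords, axis=0)
    d -= box[1:, None, :] * np.round(d / box[1:, None, :])
    unwrapped = np.concatenate([coords[:1], coords[:1] + np.cumsum(d, axis=0)])
    inside = (coords[:, :, 2] > z_lo) & (coords[:, :, 2] < z_hi)
    prefix = np.zeros((inside.shape[0] + 1, inside.shape[1]), dtype=np.int64)
    np.cumsum(inside, axis=0, out=prefix[1:])

    l_lo = max(1, int(np.ceil(lag_range[0] / dt)))
    l_hi = int(np.floor(lag_range[1] / dt))
    if l_hi < l_lo:
        return np.nan
    lags, msds = [], []
    for lag in range(l_lo, l_hi + 1):
        # stay[t, j]: inside for every frame t..t+lag
        stay = (prefix[lag + 1 :] - prefix[: -(lag + 1)]) == lag + 1
        if not stay.any():
            continue
        disp = unwrapped[lag:] - unwrapped[:-lag]
        sq = (disp**2).sum(axis=2)
        msds.append(sq[stay].mean())
        lags.append(lag * dt)
    if len(lags) < 2:
        return np.nan
    slope = np.polyfit(lags, msds, 1)[0]
    return max(slope / 6.0, 0.0)


@dataclass
class CorrelationResult:
    """Pearson (or Spearman) correlation with a least-squares line."""

    x_label: str
    y_label: str
    r: float
    n: int
    slope: float
    intercept: float
    p_value: float = np.nan
    method: str = "pearson"


def correlate(xs, ys, x_label: str = "x", y_label: str = "y", method: str = "pearson") -> CorrelationResult:
    """Correlation of paired values; non-finite pairs are dropped listwise."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.shape != ys.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if len(xs) < 3:
        raise InsufficientDataError("need at least 3 finite pairs to correlate")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {'x' if np.ptp(xs) == 0 else 'y'}; correlation undefined"
        )
    if method == "pearson":
        r, p = sps.pearsonr(xs, ys)
    elif method == "spearman":
        r, p = sps.spearmanr(xs, ys)
    else:
        raise ValueError(f"unknown method '{method}'")
    slope, intercept = np.polyfit(xs, ys, 1)
    return CorrelationResult(
        x_label=x_label,
        y_label=y_label,
        r=float(r),
        n=len(xs),
        slope=float(slope),
        intercept=float(intercept),
        p_value=float(p),
        method=method,
    )


@dataclass
class FluxOpeningReport:
    """The four flux/opening/softness correlations across windows."""

    stats: pd.DataFrame
    correlations: dict  # name -> CorrelationResult
    errors: dict = field(default_factory=dict)  # name -> error message

    def summary(self) -> str:
        lines = ["Windowed correlation report", "-" * 52]
        for name, c in self.correlations.items():
            lines.append(
                f"{name:28s} r = {c.r:+.3f}  (n = {c.n}, slope = {c.slope:.3g})"
            )
        for name, msg in self.errors.items():
            lines.append(f"{name:28s} undefined: {msg}")
        return "\n".join(lines)


_PANELS = [
    ("nw_vs_dmin", "dmin", "nw"),
    ("nw_over_dmin_vs_sigma_dmn", "sigma_dmn", "nw_over_dmin"),
    ("nw_over_dmin_vs_sigma_sel", "sigma_sel", "nw_over_dmin"),
    ("d_over_l_vs_sigma_rb", "sigma_rb", "d_over_l"),
]


def stats_to_frame(stats: list[WindowStats]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "t0": s.t0,
                "t1": s.t1,
                "nw": s.nw,
                "dmin": s.dmin,
                "sigma_dmn": s.sigma_dmn,
                "sigma_sel": s.sigma_sel,
                "sigma_rb": s.sigma_rb,
                "d_over_l": s.d_over_l,
            }
            for s in stats
        ]
    )
    df["nw_over_dmin"] = np.where(df["dmin"] > 0, df["nw"] / df["dmin"], np.nan)
    return df


def flux_opening_report(stats: list[WindowStats], method: str = "pearson") -> FluxOpeningReport:
    """Correlate flux against opening and softness across windows.

    Emits the four panel correlations; windows with dmin = 0 are flagged
    missing and dropped listwise; undefined correlations are surfaced in
    ``errors`` rather than silently omitted.
    """
    if len(stats) < 3:
        raise InsufficientDataError("need at least 3 windows")
    df = stats_to_frame(stats)
    correlations, errors = {}, {}
    for name, xcol, ycol in _PANELS:
        try:
            correlations[name] = correlate(
                df[xcol], df[ycol], x_label=xcol, y_label=ycol, method=method
            )
        except (UndefinedCorrelationError, InsufficientDataError) as exc:
            errors[name] = str(exc)
    return FluxOpeningReport(stats=df, correlations=correlations, errors=errors)


def plot_report(report: FluxOpeningReport, path: str) -> None:
    """Scatter plots with fitted lines for the four panels (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, (name, xcol, ycol) in zip(axes.ravel(), _PANELS):
        df = report.stats
        ax.scatter(df[xcol], df[ycol], s=20)
        if name in report.correlations:
            c = report.correlations[name]
            xs = np.linspace(df[xcol].min(), df[xcol].max(), 20)
            ax.plot(xs, c.slope * xs + c.intercept, "r-", lw=1)
            ax.set_title(f"{name}  r={c.r:+.2f}")
        else:
            ax.set_title(f"{name} (undefined)")
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


class WindowCorrelationModel:
    """Windowed flux–opening–softness analysis of one trajectory.

    Examples
    --------
    >>> res = WindowCorrelationModel(traj, WindowConfig(window_ns=5e-3)).fit()  # doctest: +SKIP
    >>> print(res.summary())                                                    # doctest: +SKIP
    """

    def __init__(self, traj: Trajectory, config: WindowConfig | None = None):
        self.traj = traj
        self.config = config or WindowConfig()

    def fit(self, method: str = "pearson") -> "WindowCorrelationResults":
        stats = window_stats(self.traj, self.config)
        report = flux_opening_report(stats, method=method)
        return WindowCorrelationResults(stats=stats, report=report)


@dataclass
class WindowCorrelationResults:
    stats: list
    report: FluxOpeningReport

    def summary(self) -> str:
        return self.report.summary()

    def to_frame(self) -> pd.DataFrame:
        return self.report.stats
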