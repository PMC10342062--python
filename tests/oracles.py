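"""Independent brute-force oracles used by the test-suite only.

These re-derive expected results with the plainest possible mechanics (per
frame, per molecule, explicit loops) and stay independent of the vectorised
implementation paths they check.
"""

import numpy as np


def brute_force_events(z, box_z, dt, delta_big=25.0, delta_small=5.0):
    """Per-molecule, per-frame state machine for permeation events.

    Walks every frame of every molecule: remembers the last compartment
    visited (the arming side and its time t*), forgets it after a periodic
    jump, and emits an event whenever the molecule is observed in the
    opposite compartment.  Returns tuples
    ``(column, t_star, tau, direction, confined)``.
    """
    half = delta_big / 2.0
    outer = half + delta_small
    n_frames, n_mol = z.shape
    events = []
    for j in range(n_mol):
        col = z[:, j]
        col_list = col.tolist()
        armed = 0
        t_star = -1
        z_prev = None
        for f in range(n_frames):
            zi = col_list[f]
            if f > 0 and abs(zi - z_prev) > 0.5 * box_z[f]:
                armed = 0
            if -outer < zi < -half:
                side = -1
            elif half < zi < outer:
                side = 1
            else:
                side = 0
            if side != 0:
                if armed != 0 and side == -armed:
                    seg = col[t_star + 1 : f]
                    confined = bool((np.abs(seg) < half).all()) if len(seg) else True
                    events.append(
                        (
                            j,
                            t_star * dt,
                            (f - t_star) * dt,
                            "up" if armed == -1 else "down",
                            confined,
                        )
                    )
                armed = side
                t_star = f
            z_prev = zi
    return events


def eq5_vibrational_weight(masses, reference, mode):
    """Term-by-term evaluation of the vibrational weight of one mode.

    ``mode`` is a (n, 3) bead displacement field; computes
    W_tot = ½ Σ m |e|², Γ = Σ m r × e, W_R = |Γ|²/(2J) with J the moment of
    inertia about Γ̂ through the CoM, and returns (W_tot − W_R)/W_tot.
    """
    masses = np.asarray(masses, float)
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    r = reference - com
    w_tot = 0.0
    gamma = np.zeros(3)
    for k in range(len(masses)):
        w_tot += 0.5 * masses[k] * float(mode[k] @ mode[k])
        gamma += masses[k] * np.cross(r[k], mode[k])
    g2 = float(gamma @ gamma)
    if g2 == 0.0:
        return 1.0
    axis = gamma / np.sqrt(g2)
    j_axis = 0.0
    for k in range(len(masses)):
        perp = r[k] - (r[k] @ axis) * axis
        j_axis += masses[k] * float(perp @ perp)
    w_rot = g2 / (2.0 * j_axis) if j_axis > 0 else 0.0
    return min(max((w_tot - w_rot) / w_tot, 0.0), 1.0)


def pearson_by_hand(xs, ys):
    """Pearson r from explicit covariance / standard deviations."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    mx, my = xs.mean(), ys.mean()
    cov = ((xs - mx) * (ys - my)).sum()
    return cov / np.sqrt(((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum())
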