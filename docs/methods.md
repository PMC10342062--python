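# Methods

This note records the models implemented in `aquaflux`, the choices made where
the methodology is genuinely open, and what the synthetic generators do and do
not emulate. Internal units throughout: Å, ps, amu, kcal/mol, elementary
charges; k_B = 0.0019872041 kcal/(mol K); Coulomb constant 332.0636
kcal·Å/(mol·e²); default temperature 303.15 K.

## Coordinate conventions

The membrane normal is z; profiles and detection geometry assume the
trajectory has been centred so the protein's mass-weighted CoM sits at z = 0
in every frame (`center_on_group` shifts only z). Water molecules are tracked
by a single site (the oxygen), standing in for the molecule CoM. Boxes are
orthorhombic; triclinic cells are out of scope. The frame stride is a free
parameter; 2 ps is the default production value (it is also the mobility
timestep), and all estimators state their stride requirements explicitly.

## Permeation events

Two planes at ±Δ/2 (Δ = 25 Å) with compartments of thickness δ = 5 Å outside
them (Δ + δ = 30 Å spans the membrane). The detector is a per-molecule state
machine on wrapped coordinates: each compartment visit arms the molecule (and
refreshes t\*); observing it in the opposite compartment emits one event with
τ = t − t\*, after which that visit seeds the next passage — so no event is
double-counted and a molecule must fully exit into a compartment before a new
event can start. A frame-to-frame |Δz| exceeding half the box is a
periodic-boundary jump and disarms the molecule, which excludes wrap
crossings. Events whose intermediate frames all satisfy |z| < Δ/2 are flagged
`confined`; coarse-stride passages that skip intermediate frames keep the
event but drop the flag (τ is then an upper bound). The detector is verified
*exactly* (count, t\*, τ, direction, confined) against an independent
brute-force per-frame oracle on hundreds of random-walk fixtures.

## Permeabilities

* p_d = (N_w / 2T) · v_w, with N_w the bidirectional event count: the factor 2
  converts to the unidirectional exchange rate. The single-water volume
  defaults to v_w = 3.018×10⁻²³ cm³, the value consistent with the published
  per-count permeabilities; it is configurable.
* The collective coordinate n(t) accumulates dn = Σ_i dz_i / L per frame pair
  over the channel window [−Δ/2, Δ/2] with L = Δ; displacements are
  minimum-image and clipped to the window, so one full transit contributes
  exactly ±1 and same-side excursions cancel. p_f = v_w · D_n with D_n half
  the least-squares slope of the time-origin-averaged MSD of n(t).
* MSD fit protocol (not prescribed by the method's sources): lags in
  [W/5, W] with W = min(total/10, 50 ps). n(t) is diffusive from picosecond
  lags, and short lags provide thousands of independent time origins; fits at
  lags comparable to a tenth of the run length had run-to-run scatter of tens
  of percent for this scalar series.
* p_f/p_d = N + 1 for a single-file channel holding N waters; ratios below ~2
  flag non-single-file transport in the results object.

## Synthetic channel waters

Overdamped (position) Langevin dynamics,
z ← z − (D/k_BT)·U′(z)·dt + √(2D·dt)·ξ, with free lateral diffusion in the
reservoirs, a reflecting membrane slab pierced by a reflecting cylindrical
channel, and periodic boundaries through the bulk. The axial potential U(z) is
tabulated; the integrator refuses steps where |U′|·dt·D/k_BT > 0.5 Å. An
optional relative mobility profile m(z) ∈ (0,1] makes D spatially varying
inside the channel with the Itô drift correction dD/dz, so the stationary
density remains Boltzmann. This matters because a *potential* barrier at
constant friction does not reduce the stay-conditioned local MSD — drift
inflates it — whereas physical constriction slow-down is frictional; the
mobility dip is therefore the construction used for "reduced mobility at the
constriction" fixtures. Defaults: D = 0.23 Å²/ps (bulk water), dt = 0.1 ps,
2 ps analysis stride via `sample_every`.

**Single-file mode.** The in-channel column of exactly N waters moves as a
concerted (incompressible) file: a collective offset u performs Brownian
motion with D_file = D₀/N, waters sit at slots −L/2 + a(i+1) + u with spacing
a = L/(N+1), and one *standby* water tracks the trailing mouth continuously,
entering as the file advances. When u accumulates ±a a hop has completed: the
leading water is released into its reservoir at the mouth and the standby
becomes a file member. The standby role exchanges freely with the reservoir
water nearest the mouth (a flux-neutral identity swap emulating fast mouth
equilibration). This realises the continuum hopping single-file channel, for
which p_f/p_d = N + 1 holds exactly: n(t) advances as (N+1)u/L (diffusive at
every lag), and a tracer entering at the first slot passes with probability
1/(N+1) by the gambler's-ruin argument. A *compressible* file (independent
non-passing Brownian waters with mouth exchange) was implemented first and
rejected: its end waters exit by individual fluctuation, inflating the tracer
rate ~30% above the hopping value and pushing the measured ratio to ≈4 at
N = 4. Single-file fixtures use membrane_span = 25 Å so the file length
equals the detection plane separation Δ (the law presumes both measurements
see the same channel) and D₀ = 0.4 Å²/ps (TIP3P-like water at 303 K), which
yields ~330 events per 200 ns run.

The generators are fully deterministic given the spec's mandatory seed.

## Profiles and energetics

Densities are time-averaged histograms normalised to number density (counts /
frames / bin volume); d_min is the minimum within |z| ≤ span/2, ties broken
toward z = 0; an all-zero profile reports (0, 0) with a flag. Default bins:
1 Å (z), 1 Å × 1 Å (layered 2D maps, six 5 Å layers covering [−15, 15]).

Transit profiles use confined events only. Each frame in (t\*, t\*+τ] deposits
the frame spacing into the molecule's z bin; dividing by event count and bin
width makes ∫(dτ/dz)dz equal the mean τ exactly (the test suite asserts 2%).
Mobility is the mean 3D displacement over 2 ps per bin. Interaction energies
are pairwise CHARMM-form LJ (ε, r_min/2, Lorentz–Berthelot) plus Coulomb,
truncated at 12 Å. Truncation is *unshifted* by default so that pair energies
match the closed forms (−ε at r_min; k·q₁q₂/r); `shift=True` subtracts the
cutoff value for smoother finite-difference forces. Force magnitudes |ΔU/Δs|
use centred differences of the per-molecule energy along its own 3D path
length — Δs is read as a path increment since no other definition is
workable. The "total" energy sums over all non-self atoms carrying
parameters; per-segment terms can be recovered by selection.

## PCA softness

Covariance of centred bead coordinates (per-frame mass-weighted CoM
translation removed exactly; rotation deliberately *not* removed — its
residue is measured by w_v, since Kabsch-style alignment is out of scope).
Eigenvalues descend; each eigenvector's sign makes its largest-magnitude
component positive. κ_i = k_BT/λ_i; the mass-weighted branch (q = √m·r) gives
ω_i = √(k_BT/λ̃_i), converted to ps⁻¹ via √(kcal/mol/(amu Å²)) = 20.4548 ps⁻¹.

Vibrational weight of mode e (read as a bead displacement field; un-weighted
by 1/√m in the mass-weighted branch):
W_tot = ½ Σ_k m_k|e_k|², Γ = Σ_k m_k r_k × e_k, W_R = |Γ|²/(2J) with J the
moment of inertia about the Γ axis through the CoM, and
w_v = (W_tot − W_R)/W_tot clamped to [0, 1]. Γ is the angular momentum of the
displacement field — the square of the vector sum, which is the standard
rigid-rotation kinetic energy (summing squared per-bead terms instead has no
such interpretation). An in-line stretch gives w_v = 1 identically; a rigid
rotation about a principal axis gives w_v = 0.

Softness is reported as σ = Σ λ_i w_vi in Å², with σ/k_BT (Å²·mol/kcal)
alongside, so both unit readings are available. Projected softness uses the
*squared* overlap, σ_P = Σ λ_i w_vi (P·e_i)²: eigenvector signs are
arbitrary, so a linear dot product is sign-indeterminate, while the squared
form is an intensity with σ_P = λ_j w_vj at P = e_j and Σ_basis σ_P = σ over
any orthonormal basis (both asserted to 1e-10).

The four-bead reduction takes the bundle and hash domains, splits each at its
own reference (time-mean) CoM z — a fixed atom assignment, so bead identity
is stable across frames — and builds per-frame half-domain CoMs with summed
masses. The rocking-bundle reference modes are the symmetric bundle–hash
separation and the upper-converge/lower-diverge rocking pattern, both
translation-free, orthogonalised and normalised. The per-window "rocking
bundle" softness sums the two projections, since the domain-distance motion
is carried by both. The residue selection for σ_sel is a configuration input
(a selection expression), not hard-coded.

## Windows and correlations

The trajectory is cut into equal windows (default 100 ns; synthetic fixtures
use milli-scale windows), the remainder dropped; each window is analysed
independently (events, d_min, softness, local diffusion computed on its
frames only). Local diffusion D uses the 3D MSD over lags 2–10 ps restricted
to segments that stay inside the 5 Å constriction slab centred at the
window's own z(d_min); D/L uses L = 30 Å. The 1D-z variant is available via
the same machinery. Note the stay-inside conditioning biases D downward in
narrow slabs — harmless for correlations, which only need monotonicity.
Pearson correlation with a least-squares line is the default (the observable
relationships are modelled as linear); Spearman is an option. Windows with
d_min = 0 make n_w/d_min undefined and are dropped listwise; zero-variance
inputs raise an explicit undefined-correlation error that the report surfaces
rather than hiding.

## Synthetic fixtures: what they do and do not show

The generators reproduce the *statistical mechanics* the estimators rely on —
Boltzmann densities, free and single-file diffusion, harmonic fluctuations
with prescribed covariance and rigid rotations — with known ground truth, so
passing tests demonstrate estimator correctness, determinism and the
advertised identities/limits. They do not emulate explicit 3-site water,
electrostatics during generation (charges are static labels for the energy
stage), lipid dynamics, inertial motion, or correlated protein–water coupling
beyond the windowed parameter schedules; agreement on fixtures therefore
validates the analysis pipeline, not any biological claim about a particular
transporter. Problem sizes in the test suite (10⁵–2×10⁶ Brownian steps,
2–5×10⁴ PCA frames, 6–8 analysis windows) were chosen as the smallest runs
whose sampling error sits comfortably inside the asserted tolerances.

## Numerical details and edge cases

* Degenerate inputs: empty selections, uncentred trajectories, undersampled
  unwrapping, non-PSD covariances, too-short series and zero-variance
  correlations all raise typed errors (`aquaflux.errors`).
* Rank-deficient PCA (fewer frames than DoF) warns and flags null modes;
  zero-norm modes get w_v = 0.
* The event detector and unwrapping require frame-to-frame displacements
  below half the box; the generators' default strides satisfy this by an
  order of magnitude.
* DCD output stores float32; round-trips are exact at that precision.
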