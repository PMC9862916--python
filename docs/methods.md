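# Methods

## The synthetic single-file channel

The generator (`poreflux.synthetic`) emulates the *statistical* structure
of an MD trajectory of a tetrameric water channel, not its physics. Each
chain is an independent 1-D column: waters move along z by overdamped
Euler–Maruyama dynamics on an imposed profile U(z) in kT,

    Δz = −D·U′(z)·Δt + sqrt(2·D·Δt)·ξ,   ξ ~ N(0,1),

with a 30 Å channel section flanked by reservoir segments and reflecting
walls at the outer ends. U(z) is a sum of Gaussian bumps; the main
barrier sits at the ar/R position, and a scheduled ligand adds a bump of
chosen height to its chain while "bound". Lateral coordinates are jitter
within the pore cylinder — they exist only so that per-chain cylinder
gating and selections work; all physical observables live on z.

Parameters (defaults) and why:

* `diffusion_const` = 50 Å²/ns — single-file water mobility of the right
  order for a narrow pore (bulk water is ~230 Å²/ns; pore confinement
  slows it severalfold).
* `n_waters_per_chain` = 10 in a 30 Å section — one water per 3 Å, the
  occupancy of a single-file chain.
* `n_reservoir_waters` = 10 over two 15 Å reservoirs — matches the
  channel's linear density, so the flat-profile equilibrium occupancy of
  the section stays at `n_waters_per_chain` (this is what makes the
  closed form below exact).
* `dt` = 0.01 ns per frame; for runs with PMF features validation enforces
  sqrt(2·D·dt) ≤ 0.2 × the narrowest feature width (0.0015 ns for the
  standard 2 Å-wide barrier), so the discretised dynamics resolves the
  barrier; validation rejects coarser steps.
* `temperature` = 310.15 K throughout (energies are in kT; the
  temperature only enters unit conversions).
* One RNG stream per chain, split from the master seed: chains are
  reproducible independently of evaluation order, and a seed fully
  determines the trajectory bitwise.

Ground truth emitted with every run: the imposed U(z) per chain, the true
permeation-event list (computed from the float32 coordinates actually
written, so estimator comparisons are exact), ligand-bound intervals, and
— for flat profiles — the analytic collective diffusion coefficient

    D_n = N·D/L²     and     p_f = v_w·D_n,  v_w = 3.0×10⁻²³ cm³.

What the generator does **not** emulate: excluded-volume ordering of the
water file (collective transport of independent walkers has the same
D_n; only tracer properties would differ), hydrogen-bond networks, real
protein flexibility (the scaffold residues are static positions plus
0.2 Å Gaussian jitter), electrostatics in the dynamics, and ligand
diffusion (binding is schedule-driven). Passing tests therefore validate
the *estimators* — counting, inversion, normalisation, statistics — not
force-field realism.

The protein scaffold places the residues the interaction metrics name
(ar/R R187 and H177; C-loop A117/V118/N119; K197/F198/D199; surface
carboxylates E106/D111/D115/D199/D200 with OE/OD atoms; backbone N, CA,
C, O per residue with the carbonyl O offset toward +z) on plausible
ring positions, plus six-atom pore-lining rings (resname `POR`) for the
diameter profile, compartmentalised Na⁺/K⁺/Cl⁻ ions, and an optional
five-atom ligand (resname `COR`).

## Permeation counting

A water's compartment per frame is below / inside / above the section;
"inside" additionally requires the lateral pore cylinder (default radius
6 Å). An event is a maximal inside-run flanked by opposite sides; runs
touching the lateral exclusion zone are voided. Both total and net
(directed) counts are reported — equilibrium trajectories have no net
direction, so the total is the permeability-relevant number while the
net is a sanity check.

A useful identity: because the collective coordinate uses clamped
endpoint differences, its per-water contribution telescopes to the
endpoint difference, so n(T) − (net directed events) equals the sum of
fractional endpoint positions of waters inside the section at t = 0 and
t = T. It is therefore bounded by the endpoint occupancies — but not by
±1; the test suite checks the exact bound.

## Collective-coordinate p_f

Per frame pair, each water contributes (clamp(z₂) − clamp(z₁))/L with
clamping to the section — a water crossing the boundary mid-step counts
only its in-section fraction, which removes boundary shot noise. D_n is
the WLS slope (through the origin) of MSD(τ) over lag times, divided
by 2.

Fit window: lags between 0.01% and 0.2% of the trajectory length
(≥ 1 frame), with inverse-variance weights ∝ 1/τ³ (the MSD variance of a
Brownian path grows ~τ³/T). The short-lag window is deliberate: in any
finite box the collective coordinate is weakly mean-reverting at lags
beyond the channel/reservoir relaxation time (~(2H)²/π²D ≈ 7 ns for the
default geometry), and a fit reaching into that regime systematically
under-estimates D_n — so the default upper lag (1 ns on a 500 ns run)
stays well below it. The residual mean-reversion within the window
leaves a few-percent low bias on the closed synthetic geometry; the
validation band for closed-form recovery is 20%. The window is an
exposed argument for trajectories with different relaxation scales.

## Free-energy profiles and the Dk correction

ρ(z) is the per-0.5 Å-slice mean occupancy (cylinder-gated at all z so
channel and reservoir slices are commensurable). ρ_bulk defaults to the
mean over 5 Å of reservoir beyond each section end, averaged over both
ends; per-chain and pooled-chain densities are both possible since the
profile is computed per section. Bins with mean occupancy < 10⁻³ per
frame are masked (NaN), never silently zero — −ln of rare counts is
sampling-noise dominated. G is kept in kT internally and converted to
kcal/mol (R·T at the run temperature) for reports.

Barrier summary: E₀ = max unmasked G over the section, E_arR = max G
within ±1.5 Å of the ar/R position (window configurable). The correction
constant is read as the dimensionless parse

    Dk = (2·E₀ − E_arR)/E₀,

the only reading under which Dk is unit-free (the alternative grouping
2·E₀ − E_arR/E₀ would carry units of energy); E₀ ≤ 0 (no barrier) is an
error rather than Dk = anything. `p_f,corrected = p_f·Dk`.

## Pore geometry and electrostatics

Diameter: at each z the largest free sphere restricted to the plane —
centre optimised by a coarse grid (0.5 Å, 5 Å search disc around the
axis) plus Nelder–Mead refinement from the three best seeds, constrained
to the disc; radius = min over atoms of (distance − vdW radius), with a
Bondi-style element table (unknown elements 1.7 Å with a warning).
In-plane optimisation (rather than strictly on-axis probes) avoids
under-estimating curved pores. Planes whose free radius exceeds 10 Å are
masked as open. Snapshot and frame-averaged modes are both provided,
since either convention is defensible for reporting.

Potential: direct Coulomb sum over partial charges at on-axis probes,
uniform relative dielectric (default 10), contributions softened at 1 Å.
This yields *comparative* profiles (condition A vs B along the same
pore), not absolute potentials — no reaction field, no screening by
explicit solvent.

## Interaction metrics

Hydrogen bonds are purely geometric: donor–acceptor distance ≤ 3.5 Å and
D–H···A deviation from linearity ≤ 30°, the common defaults of standard
MD analysis tools; a heavy-atom distance-only fallback exists for
hydrogen-free topologies. Loop distances default to Cα atoms and the
pairwise mean over all inter-group pairs (the convention is embedded in
the series name); a centroid mode is provided because "mean loop
distance" is ambiguous between the two. The backbone C→O angle is
θ = arcsin(v_z/|v|) ∈ [−90°, 90°], positive when the carbonyl oxygen
points extracellular. RDFs superpose all reference atoms and normalise
by the ideal-gas expectation at the ions' mean number density with
minimum-image distances; the closure ∫g·4πr²ρ dr = mean count within
r_max is tested.

## Binding score and K_D

Contacts between ligand and protein within 10.5 Å are bucketed by
element pair (C–C, C–N, C–O, N–N, N–O, O–O, X–polar, X–apolar; hydrogens
and exotic elements bucket by their partner's polarity). The score is
linear in the bucket counts. The shipped coefficient set is a synthetic
default — favourable polar contacts, mildly favourable apolar ones —
so the machinery runs out of the box; published empirical coefficient
sets are drop-in data (dict or JSON), not code. Sampling cadence is one
frame per nanosecond.

K_D = exp(ΔG/(R·T)) in mol/L at the 1 M reference state, with
R = 8.314 J·mol⁻¹·K⁻¹ expressed in kcal (8.314/4184). Two deliberate
choices live here. First, the sign: the convention that a favourable
(negative) ΔG gives K_D < 1 M — the form sometimes written
exp(−ΔG/RT) only matches nanomolar results if its ΔG is implicitly
positive; this implementation follows the numbers, and a binding free
energy of −9.39 kcal/mol at 310.15 K maps to ≈ 241.6 nM. Second, R: the
conversion is sensitive at the third decimal to how the calorie is
defined; the standard SI value of R expressed through the thermochemical
calorie is used and is an explicit argument for users who need another
convention.

## Windowing and test selection

Windows are fixed [0,w), [w,2w), … partitions (default 10 ns), trailing
remainder dropped and reported. Per-window statistics are computed
independently per window — not by differencing cumulative curves — so
windows are exchangeable units. Pooling the four chains' windows into
one condition versus keeping chains separate is the caller's choice
(`mode="pooled"` / `"per-chain"`): whether tetramer coupling breaks
exchangeability is a modelling judgement the package does not make.

Comparisons record Shapiro normality per group and a homoscedasticity
check (two-sided variance-ratio F for two groups; Bartlett for more) at
α = 0.05, then branch deterministically: t-test or Mann–Whitney for two
groups; ANOVA+Tukey or Kruskal–Wallis omnibus with pairwise rank-sum
tests under Bonferroni for more. Mann–Whitney uses the exact null for
n ≤ 8 per group without ties and the tie-corrected normal approximation
otherwise; fully tied samples report p = 1 directly (no evidence of a
shift); zero-variance groups are treated as failing normality so the
branch is always defined. The empirical size of the full two-group
selection-then-test path is checked at 0.05 ± 0.01 over 2000 null
simulations.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate on: 50 random-walk
waters × 10⁴ steps (exact oracle equivalence of event counting); three
flat-profile runs of 5×10⁴ frames (closed-form p_f recovery within 20%);
one 3 kT-barrier run of 1.2×10⁵ frames at dt = 0.0015 ns (barrier
recovery within 0.3 kT); one four-chain run of 8×10⁴ frames with a +3 kT
scheduled ligand on one chain (bound-vs-free comparison); 2000 null
simulations at n = 40 per group (type-I calibration). These sizes give
each check comfortable statistical margin at desktop runtimes.

## Known limitations

* The generator's reservoirs are closed; real periodic MD systems
  recycle water, so the long-lag behaviour of n(t) differs (see the fit
  window discussion above).
* Windowed statistics inherit the autocorrelation of the underlying
  trajectory; no effective-sample-size correction is applied (the
  windowing scheme itself assumes 10 ns decorrelates the observables).
* The electrostatic profile is comparative only.
* The shipped binding coefficients are placeholders by design; absolute
  ΔG / K_D values are only as good as the coefficient set supplied.
* Only orthorhombic boxes are supported.
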