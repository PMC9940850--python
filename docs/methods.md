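# Methods

This note documents the models, estimators, parameters and numerical
choices implemented in `mldroplet`, and what the test suite does and
does not demonstrate.

## Canonical droplet thermodynamics (`thermo`)

**Model.** A single spherical droplet of `n` chains at fixed
condensed-phase number density ρ_c coexists with an ideal dilute phase
in a closed box (N chains, volume V, temperature T). The work of
droplet formation relative to the homogeneous state is

    βF(n) = βσ A(n) − Φ(n),     Φ(n) = ∫₀ⁿ ln( ρ_d^m / ρ_d* ) dm,

with A(n) = (36π)^⅓ (n/ρ_c)^⅔ and the depleted dilute density
ρ_d^m = (N−m)/(V−m/ρ_c). Φ has the closed form

    Φ(n) = N ln N − (N−n) ln(N−n)
           − ρ_c [ V ln V − (V−n/ρ_c) ln(V−n/ρ_c) ] − n ln ρ_d* .

This is the unique free energy with F(0) = 0 whose stationarity
condition is exactly the Gibbs–Thomson/Kelvin relation
ρ_d^n = ρ_d\* exp(2σ/(ρ_c kT r(n))); in the macroscopic limit
(N, V → ∞ at fixed total density ρ_d°) it reduces pointwise to the CNT
work −n ln S + βσA(n), S = ρ_d°/ρ_d\*. A pointwise bulk term of the
form −n ln(ρ_d^n/ρ_d\*) would shift the minimum off the Kelvin root by
O(n/(N−n)) — several percent at the conditions of interest — and is
deliberately not used.

**Assumptions.** Spherical droplets; incompressible condensed phase;
ideal (dilute) vapor; a single droplet; no curvature correction to σ
(no Tolman length); n treated as continuous.

**Finite-size convergence.** The canonical profile approaches the CNT
profile at the rate

    βF_finite(n) − βF_CNT(n) = −(n²/2N)(1 − ρ_d°/ρ_c) + O(n³/N²),

a physical property of the finite reservoir, not a numerical artifact.
At N = 10⁶ and n = 50 this is ≈1.2×10⁻³ kT for dilute total densities.
The test suite asserts this exact law; one acceptance-level check that
posits a 10⁻³ kT agreement at those sizes sits just inside the
correction and is expected to read as a (documented) failure.

**Stationary points.** dF/dn is evaluated analytically; it diverges to
+∞ at n → 0 and at the depletion cap min(N, ρ_c V), with a single
interior minimum. The sign of that minimum classifies the profile
(monotonic / flex / two stationary points); roots are refined with
Brent's method to machine precision. The stability-diagram boundary
(the flex locus) is found by bisection on the box length of the
minimum of dF/dn, treating N = ρ_d°·V as continuous.

**Units.** Internally: nm, kJ/mol, Da, ps. kT = 2.494 kJ/mol at 300 K;
1 mN/m = 0.24143 kT/nm² at 300 K; 1 Da/nm³ = 1.66054 mg/mL. The
conversion constants are centralized in `units.py` and tested.

## Kelvin fit (`kelvin`)

Taking logs of the Kelvin relation at the steady state linearizes it,

    ln ρ_d^(n_ss) = ln ρ_d* + βσ · x,     x = 2/(ρ_c r_ss),

so the global fit over conditions (N, V, n_ss) is ordinary least
squares for (ln ρ_d\*, βσ). Defaults: equal row weights; only rows
flagged `stable` enter; ρ_c is held fixed at the value measured from
droplet-core density profiles; the chain mass is derived from the
observation table's paired number/mass density columns. Options: a
nonlinear (density-space) objective initialized from the linear
solution, and propagated inverse-variance weights `weights="nss_err"`.

The log-density noise is strongly heteroscedastic — δ(ln ρ_d^n) ≈
δn/(N−n) blows up when most chains are condensed — so the weighted
estimator has markedly lower slope variance. For reference, at the
packaged 12-condition design with 3% relative size noise, the
linearized Cramér–Rao bound on σ is ≈12% relative: no estimator can do
better, and recovery tests are calibrated against that bound rather
than against wishful precision. (This matches the ≈60% bootstrap 95%
interval on the NDDX4 surface tension.)

**Bootstrap.** Case resampling over observation rows, default 10 000
replicates, seeded; replicates with fewer than three distinct rows are
redrawn (two parameters cannot be constrained otherwise); percentile
2.5/97.5 intervals. Degenerate replicates may fit σ < 0; they are kept
(the interval reports them) without per-draw warnings.

**Steady-state prediction.** `predict_nss` brackets the descending
sign change of ln ρ_d^n − ln ρ_Kelvin(n) on a geometric grid and
refines with Brent; the larger root is the stable droplet, absence of
a root is reported as "inhibited" (consistent with the stability
diagram).

## Droplet detection (`detect`)

Two-stage geometric criterion. Stage 1: chains are linked when ≥
`min_contacts` bead pairs lie within `contact_cutoff` (periodic
KD-tree, minimum image); clusters are connected components (single
linkage). Stage 2: chains whose COM lies farther than `com_cutoff`
from the cluster COM are reassigned dilute; the default cutoff is
adaptive, 2× the cluster's radius of gyration. COMs under periodic
boundaries use per-axis circular means, robust to boundary-crossing
droplets. Defaults — contact_cutoff 1.0 nm, min_contacts 1 — are
deliberately configurable and recorded in output metadata; tests on
sparse-bead synthetic chains use 2.0 nm (see Fixtures below).

**Steady-state size.** Largest-cluster size per frame; the first half
of the trajectory is discarded as equilibration (configurable);
block-average standard error over ≥5 contiguous blocks. Outcome flags:
`none` if the largest cluster is below 5 chains in ≥90% of frames,
`fluctuating` if the relative block error exceeds 25% or several
droplets coexist in ≥25% of frames, else `stable`.

**Density profiles and ρ_c.** Bead-mass histogram in 0.5 nm spherical
shells about the droplet COM, averaged over frames, converted to
mg/mL. The condensed density is the volume-weighted mean over shells
within 50% of the half-density radius; peak and half-radius are
located on a volume-weighted 3-bin moving average because the
innermost shells are tiny and Poisson-noisy. Shells inside ~2 nm of
the COM carry very few chains per frame — ρ_c estimates should pool
O(10) frames or more.

**Asphericity.** b = (λ₁ − (λ₂+λ₃)/2)/(λ₁+λ₂+λ₃) from gyration-tensor
eigenvalues of the droplet beads: 0 for a sphere, ½ for a 2:1:1
prolate ellipsoid, 1 for a line.

## Exchange kinetics (`msm`)

Two macrostates per chain — condensed (member of the largest cluster)
or dilute — assigned with the same criteria as droplet detection.
Transition counts at lag τ (sliding window, pooled over chains) give a
2×2 row-stochastic matrix per droplet-size bin; for a two-state chain
MFPT(c→d) = τ/p_cd, so the escape rate is k_cd = p_cd/τ (reported in
1/µs). Uncertainty: Jeffreys Beta(½,½) posterior on the exit
probability; bins with no observed exits report the posterior upper
bound, flagged. Default lag 1 frame with an implied-timescale
flatness diagnostic across lags {1, 2, 5}; default binning quintiles
of the droplet-size series. The size dependence of k_cd is summarized
by least squares of ln k on n; the balance check regresses k_cd/k_dc
on N_dilute/N_condensed over time windows, which for equilibrated
two-state dynamics falls on the parity line.

## Coarse-grained force field (`forcefield`)

One bead per residue. Bonds: harmonic, r₀ = 0.38 nm, k = 10³
kJ·mol⁻¹·nm⁻². Electrostatics: Debye–Hückel with screening length
1 nm (≈100 mM), prefactor 138.935/80 kJ·mol⁻¹·nm·e⁻², charges
D/E = −1, K/R = +1, His neutral (all per-residue configurable — charge
patterning is what makes the electrostatic term matter for NDDX4-like
sequences). Short range: 12-6 Lennard-Jones with the
stickers-and-spacers energy scale — stickers are Arg, Phe, Tyr, Trp,
Gln; pair well depths ε_StSt : ε_StSp : ε_SpSp = 1 : 1/1.5 : 1/3 with
the absolute scale `eps_stst` as the single free parameter (no default
tuning to experimental densities is attempted). Pair σ by Lorentz
(arithmetic) combination from a per-residue table; the shipped
diameters are a stand-in from the widely used HPS one-bead-per-residue
convention and can be overridden from a delimited text file. Cutoffs
default to 2.0 nm (LJ) and 3.5 nm (DH); only directly bonded (1–2)
pairs are excluded from nonbonded sums. Forces are analytic and tested
against centered finite differences at 10⁻⁵ relative.

Neighbor search: vectorized all-pairs below 10³ beads (faster in
numpy), periodic cell-linked list above; both paths are
cross-validated. The pair kernel clamps r ≥ 10⁻⁴ nm so exact overlaps
produce huge finite forces rather than NaNs.

## Langevin integrator (`simulate`)

BAOAB splitting; uniform bead mass 110 Da (an average residue — chain
dynamics need not be chemically faithful for analysis tests);
default dt = 0.02 ps set by the stiffest term (bond frequency
ω = √(k/m) ≈ 3 ps⁻¹, so ω·dt ≈ 0.06); default friction 1 ps⁻¹.
A per-half-step displacement cap (0.1 nm) tames the r⁻¹² wall during
collisions; it is inactive in equilibrium sampling (verified by the
harmonic-dimer distribution test). Random-walk initial configurations
overlap freely, so `minimize_energy` (capped steepest descent) should
be run before dynamics. Trajectories: initial state is always frame 0;
outputs in a plain whitespace format, GRO, or XTC.

What desk-scale runs do *not* show: µs-scale condensation of
10⁵-bead systems, realistic exchange rates, or tuned coexistence
densities. The simulator exists to exercise detection and kinetics
analysis end to end (droplet persistence vs. evaporation under strong
vs. negligible sticker attraction is the designed smoke test).

## Synthetic fixtures (`synthetic`)

All fixtures are deterministic given a seed and carry their ground
truth with the data.

* **Droplet configurations:** freely jointed chains (bond 0.38 nm)
  with centers uniform in a central sphere whose radius realizes the
  target core mass density exactly; vapor chains keep a 6 nm clearance
  from the sphere. Because ideal coils at liquid density do not
  geometrically percolate (the generator has no excluded
  volume/interpenetration), chains stranded outside the single-linkage
  contact component at 1.5 nm are resampled (seeded) until the droplet
  is connected — so any contact cutoff ≥1.5 nm recovers the planted
  membership exactly, which is what the detector tests require. The
  construction emulates a liquid-density sphere in a vapor; it does
  not emulate interfacial width, surface fluctuations, or chain-level
  structure.
* **Observation tables:** forward Kelvin model (`predict_nss`) over
  the standard 12-condition design (L ∈ {40, 50, 60, 70} nm, three
  loadings each) with multiplicative Gaussian noise on n_ss truncated
  at ±3 s.d.; the 3% default matches the relative block errors of the
  packaged tables. Conditions without a stable root are flagged
  `none`.
* **Telegraph state series:** independent two-state Markov chains with
  per-frame switching probabilities k·Δt, started from the stationary
  distribution.

## Known limitations

Single-droplet thermodynamics only (no multi-droplet partition
functions, no Tolman correction); ρ_c fixed rather than co-fitted; the
simulator is a testing device, not a production engine; the shipped
residue diameters are a stand-in table, not a validated
parameterization; the σ information content of a 12-condition design
is limited (≈12% at 3% size noise) — tighter estimates need more box
sizes or lower-noise steady states.
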