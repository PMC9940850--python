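# mldroplet

Macroscopic condensation thermodynamics from finite-size droplet
simulations of phase-separating proteins.

## The problem

Biomolecular condensates — the droplets formed by liquid–liquid phase
separation (LLPS) of disordered proteins such as NDDX4 and FUS-LC —
nucleate from supersaturated solution. Molecular simulations of this
process necessarily run in a closed box (canonical, *NVT*): as a
droplet of *n* chains grows it depletes the surrounding dilute phase,
so the free energy of droplet formation depends on the box size and
chain count, not only on the thermodynamics of the protein. Naively
reading coexistence densities or barriers off such simulations gives
box-dependent answers.

`mldroplet` turns this finite-size effect into a measurement device.
The canonical (liquid-droplet) free energy of an *n*-chain droplet is

```
βF(n) = βσ A(n) − ∫₀ⁿ ln( ρ_d^m / ρ_d* ) dm ,     A(n) = (36π)^⅓ (n/ρ_c)^⅔
```

where σ is the planar surface tension, ρ_c the condensed-phase
density, ρ_d\* the macroscopic coexistence (dilute-phase) density, and
ρ_d^m = (N−m)/(V−m/ρ_c) the depleted dilute-phase density with an
*m*-chain droplet present. Setting dF/dn = 0 gives the
Gibbs–Thomson/Kelvin relation for the self-limiting steady-state
droplet of radius r_ss = (3 n_ss / 4πρ_c)^⅓:

```
ρ_d^(n_ss) = ρ_d* · exp( 2σ / (ρ_c kT r_ss) )
```

Each simulated condition (N, V, n_ss) therefore constrains (σ, ρ_d\*),
and a *global fit* over several box sizes recovers both — the
macroscopic surface tension and solubility — from modest closed-box
runs. With those in hand the package evaluates the macroscopic
classical-nucleation-theory (CNT) limit βF(n) = −n ln(ρ_d°/ρ_d\*) +
βσA(n), nucleation barriers 16π(βσ)³/(3ρ_c² ln²S), critical nuclei,
barrier crossovers between proteins, and the finite-size stability
diagram (unstable / confinement-inhibited / stable droplet regions
over density × box size).

Supporting modules make the pipeline end-to-end testable:

| module | what it does |
|---|---|
| `thermo` | canonical & CNT free-energy profiles, stationary points, crossovers, stability diagrams |
| `kelvin` | Kelvin-relation forward model, steady-state size prediction, global fit + bootstrap CIs |
| `detect` | droplet detection (contact graph + COM refinement), block-averaged steady-state sizes, radial density profiles, ρ_c, asphericity |
| `msm` | two-state (condensed/dilute) Markov-state exchange kinetics: per-size escape rates, exponential size dependence, rate-ratio balance |
| `forcefield` | one-bead-per-residue stickers-and-spacers potential (harmonic bonds, Debye–Hückel, class-mixed Lennard-Jones) |
| `simulate` | desk-scale BAOAB Langevin integrator in a periodic box |
| `synthetic` | planted-ground-truth fixtures: droplet configurations, observation tables, telegraph state series |
| `io` / `cli` | CSV/JSON/GRO/XTC plumbing and the `mldroplet` command line |

The package ships the finite-size observation tables for NDDX4 (8
stable conditions) and FUS-LC (9 stable conditions) as CSV data.

## Worked example

Fit the packaged NDDX4 observations (ρ_c = 359 mg/mL from the droplet
core density profiles; the chain mass is derived from the table's
paired nm⁻³ / mg·mL⁻¹ density columns):

```sh
$ mldroplet fit --protein NDDX4 --rho-c 359 --n-boot 2000 --seed 7 --out fit_nddx4.json
sigma = 0.1005 mN/m (95% CI 0.0534..0.1751), rho_d* = 4.899 mg/mL (95% CI 3.414..5.907)
```

The surface tension of the NDDX4 condensate comes out at 0.10 mN/m —
an order of magnitude below a water–oil interface, typical of these
highly hydrated protein condensates — and its equilibrium dilute-phase
density at ≈4.9 mg/mL. The 95% intervals are case-resampling bootstrap
over observation rows.

Predict steady-state droplet sizes at new conditions from those
parameters:

```sh
$ mldroplet predict --sigma 0.101 --rho-d-star 4.87 --rho-c 359 \
    --chain-mass 25427 -L 70 -N 187 -L 50 -N 69 -L 40 -N 25 --out pred.csv
 L_nm   N  rho0_mgml   nss_pred   outcome
 70.0 187  23.019279 132.303520    stable
 50.0  69  23.306835  45.597538    stable
 40.0  25  16.493175        NaN inhibited
```

The first two conditions reproduce the observed steady-state sizes
(130 ± 3 and 45 ± 2 chains); in the third the box is so small that the
free-energy profile is monotonically increasing — condensation is
inhibited by confinement, exactly as observed in that simulation.

Other subcommands: `profile` (F(n) curves), `diagram` (stability
diagram + flex boundary), `detect` (trajectory → observation row +
density profile), `msm` (exchange-rate tables), `simulate` (toy
Langevin runs), `synth` (planted fixtures). All accept `--help`.

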