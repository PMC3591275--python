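# Model and methods

## The model

`epimotion` simulates a confluent epithelial monolayer (MDCK-like) as point
particles. Each cell `i` carries a velocity `v_i` obeying a continuous-time
Langevin equation,

    dv_i/dt = −α v_i + β Σ_{j∈N(i)} (v_j − v_i) + Σ_{j∈N(i)} f(x_j − x_i) + σ_i η_i,
    dx_i/dt = v_i,

with

- `α` (h⁻¹): effective damping from adhesion rupture and substrate/cell
  friction;
- `β` (h⁻¹ per neighbor): velocity-alignment coupling toward each neighbor;
  the sum runs over the sector neighbors (below), *not* divided by the
  neighbor count (a `align_mean` switch enables the mean variant);
- `f`: central pair force, gaussian repulsive core
  `A_rep (r/r_rep²) e^{−r²/(2 r_rep²)}` plus a Heaviside-gated linear
  attraction `−A_att (r − r_att)/(r_cut − r_att)` on `r_att < r ≤ r_cut`,
  zero beyond the cutoff. The gate makes the force drop discontinuously from
  `−A_att` to 0 at `r_cut` (a kink of the potential); the magnitude is
  capped below `r_cap = 0.5 µm` so coincident daughters after division do
  not blow up;
- `η_i`: per-cell, per-component Ornstein–Uhlenbeck noise with correlation
  time `τ` (h) and unit stationary variance; `σ_i` (µm·h⁻²) is constant
  (`sigma0`) or grows linearly as the local density `d_i` falls below the
  reference `d0`: `σ_i = σ0 [1 + κ max(0, 1 − d_i/d0)]` (the published form
  of the density dependence is not available; this linear stand-in is
  configurable). The default κ = 1 doubles the drive of a fully isolated
  cell; larger values make the unrestrained border race far beyond the
  bulk cell speed it should stay comparable to.

Neighbors: the plane around each cell is split into six 60° sectors with
the +x axis as one boundary; the closest particle within 100 µm in each
sector is a neighbor (the relation may be asymmetric). The local density is
`d_i = 2/(√3 r̄_i²)` with `r̄_i` the mean sector distance, empty sectors
counting the cutoff; the constant is fixed so a hexagonal lattice reports
its true number density.

Reference bulk parameters: `(α, β, τ) = (1.42 h⁻¹, 38 h⁻¹, 1.40 h)`, the
fitted triple for MDCK monolayers; `d0 = 4×10⁻³ µm⁻²` (N = 4000 cells per
mm², mean spacing ≈ 17 µm); `σ0 = 490 µm·h⁻²`, calibrated with the
frozen-lattice closed form so the bulk mean speed is ≈ 15 µm/h. Potential
defaults (`A_rep = 150 µm·h⁻², r_rep = 5 µm, A_att = 2 µm·h⁻²,
r_att = 25 µm, r_cut = 50 µm`) give a relaxed sheet spacing of ≈ 16–17 µm,
consistent with 15–25 µm cells.

## Frontier: leaders, free surface, division

Border-progression runs use a band periodic in y: cells tile
`x ∈ [−W, 0]` at density `d0`, and the unexplored surface `x > 0` carries a
10 µm grid of static surface particles. Non-leader cells are repelled by
alive surface particles (gaussian kernel, width 10 µm, amplitude
300 µm·h⁻²). The amplitude must be comparable to the propulsive force scale
σ0 ≈ 490 µm·h⁻², otherwise ordinary noise excursions walk cells straight
through intact surface. Each surface particle carries a damage variable
`dw/dt = −w/τ_w + Σ |f(cell on s)|` summed over cells within 30 µm and is
removed permanently at `w ≥ w_thr = 2 τ_w A_surf` (`τ_w = 1 h`; `τ_w = ∞`
recovers pure accumulation); a stalled cell presses with roughly its
driving-force scale, so this threshold requires a couple of cells pressing
simultaneously — lone contacts do not erode the surface. Leaders damage the
surface with a 50× larger amplitude over a wider kernel (25 µm), clearing a
follower-passable corridor within minutes, and feel no surface force.

Leaders appear along the border as a Poisson process, 0.3 mm⁻¹h⁻¹ before
20 h and 0.1 mm⁻¹h⁻¹ after, choosing a random bulk cell within 30 µm of the
border whose y-distance to every existing leader is ≥ 150 µm. A new leader
moves in +x with speed drawn from a gaussian of mean 18 µm/h (sd 4 µm/h,
truncated at 0). While a leader has ≥ 4 neighbors it keeps that velocity;
with 1–3 it takes the mean neighbor velocity capped at its initial modulus;
with none it keeps its previous direction at the capped speed. Leaders
never divide. Bulk cells divide with doubling time 20 h; the daughter is
placed 2 µm away with the parent's velocity and OU state, and the division
is rolled back unless both parent and daughter local densities stay at or
below `d0` (contact inhibition as a hard density cap). Note that a fresh
parent–daughter pair separates slowly: the alignment coupling locks their
velocities together, so only the (weak at 2 µm) repulsive core drives them
apart. The density cap is therefore a statement about division acceptance,
not about densities at later times, when sheet compression can transiently
raise the local density of such pairs above `d0`.

Several frontier constants (leader rates, creation depth, exclusion
distance, speed sd, damage parameters, doubling time) are not legible in
the available source and are package defaults chosen at biologically
sensible scales; all are configurable and none should be quoted as
published values.

## Numerics

Integration is explicit Euler for velocities and positions with an exact
(stationarity-preserving) OU substep,
`η' = η e^{−dt/τ} + √(1−e^{−2dt/τ}) ζ`. The stiffest velocity mode relaxes
at `α + 9β ≈ 343 h⁻¹` (the triangular-lattice Laplacian spectrum reaches 9),
so stability requires `dt < 2/(α+9β) ≈ 0.006 h`. Defaults: `dt = 0.002 h`
for bulk runs and `0.004–0.005 h` for band runs (stiff modes carry a
vanishing share of the velocity variance, ∝ 1/λ², so their larger
discretization error is immaterial; the per-mode discrete-chain variance
agrees with the continuous one to < 0.2% at these steps). The neighbor
graph is refreshed every step by default; long runs refresh every 5–10
steps (per-interval displacements ≲ 0.2 µm, far below the 17 µm spacing).
Neighbor search is a two-stage KD-tree pass (short radius first, full
100 µm cutoff for particles with empty sectors) that reproduces the
brute-force all-pairs sector scan exactly; periodic boundaries are handled
by ghost-image augmentation, which also covers the band geometry (periodic
in y only).

## Estimators

All correlation estimators remove the per-snapshot component mean before
correlating and normalize at lag 0. Defaults: velocity histograms 1 µm/h
bins; center pair correlation dr = 2 µm; spatial velocity correlation
dr = 10 µm; temporal lags at the 0.1 h snapshot cadence; velocity profiles
in 50 µm bins after translating the mean border position to 0. The
correlation length/time is the linearly interpolated first 1/e crossing.
Border kinetics: least-squares quadratic fit through the initial border
position for `t < t_crossover` and a linear fit after, plus log–log slopes
of the border advance. Finger density profiles bin the local density of
cells beyond the mean border position by distance from the border (model
fingers grow normal to the initial border, so this distance is the
arclength coordinate).

## Frozen-lattice closed forms

With positions pinned to a periodic triangular lattice and pair forces
dropped, the dynamics diagonalize over lattice modes q with relaxation
rates `λ_q = α + β Σ_e (1 − cos q·e)`. Driven by unit-variance OU noise
(rate μ = 1/τ), each mode's stationary autocovariance is

    C_q(T) = e^{−λT}/(2λ(λ+μ)) + [e^{−λT}/(2λ) − e^{−μT}/(λ+μ)]/(μ−λ),

with the analytic limit `e^{−λT}(1/(2λ²) + T/(2λ))` at λ = μ; equal-time
mode variances are `1/(λ_q(λ_q+μ))`. The temporal autocorrelation is the
normalized mode sum and the spatial correlation the inverse discrete
Fourier sum of mode variances. Two conventions matter and are defaults
here: (i) the uniform q = 0 mode is excluded, because the empirical
estimators subtract the instantaneous spatial mean, which removes exactly
that mode — and it carries a large weight (its rate is the bare α); (ii)
the lattice extent is matched to the simulation box, because the low-q
mode cutoff noticeably shapes the normalized curves (convergence with
lattice size is slow: 48 vs 96 cells differ by up to 0.1 in C(r)).

The approximation is qualitatively faithful but not exact for moving
cells: at the reference parameters the full model's spatial correlation
reaches 1/e at ≈ 155 µm versus ≈ 120 µm for the lattice, and its temporal
decay is slightly faster. Lattice curves are therefore used for fit
initialization, σ calibration and as oracles for the frozen-position
simulation — never as ground truth for moving-cell curves.

## Parameter fitting and identifiability

The mismatch `E = Σ_{r≤R_max}[C_N − C_N^t]² + Σ_{t≤T_max}[A_N − A_N^t]²`
(R_max = 300 µm, T_max = 4 h by default) is minimized over (α, β, τ) with
Nelder–Mead in log-parameter space. The lattice objective is deterministic
and fast (precomputed mode tables); because the landscape can hold several
basins, it is minimized from a deterministic multi-start over rescalings of
a moment-based initial guess, each start restarted until stagnation. The
simulation objective re-simulates a bulk sheet per evaluation with one
fixed seed (common random numbers) in the same box as the target — matching
boxes matters because the finite-size mode cutoff shapes the curves. σ0 is
calibrated after the triple from the exact linearity of the velocity scale
in σ, and the fit/calibration loop repeats until the triple changes < 1%.

A caution established by the package's own experiments: the triple is only
weakly identified from one run's normalized curves. A near-degenerate
valley runs through (α, β, τ) — noisy targets generated at a fixed truth
are fit almost equally well by triples whose α differs by factors of ~2–4,
with the lattice objective as well as within the exact lattice family.
Recovering the damping rate to ~10% requires the simulation objective
(whose family curvature across the valley is much stronger), a matched box,
and averaged x/y curves; even then the recovered α carries a noticeable
sampling spread. Fitted triples should be read as curve descriptors, not as
independently measured rates.

## Synthetic data

`io.make_synthetic_piv` emulates PIV output: a bulk run binned to a 30 or
60 µm square grid (per-cell mean velocities) plus isotropic gaussian
measurement noise, with a truth record of the generating parameters. It
reproduces the gridded, time-resolved character of PIV velocity fields but
none of the imaging artifacts (interrogation-window correlation, edge
effects, tracking loss), so passing recovery tests demonstrate estimator
and fit correctness on model data, not robustness to microscopy noise.

## Problem sizes used in tests and the acceptance script

Bulk reference runs use N = 4000 in a 1 mm × 1 mm periodic box, 10 h with
the first 5 h discarded. Parameter-recovery experiments use N = 1024 in a
506 µm box (target and refit at the same scale). Leader-speed sampling uses
thin bands (80 µm deep, 12 mm border) with surface and division disabled —
leader creation statistics depend only on the border geometry and the
creation rule. Border-kinetics runs use ≈ 2000 cells on a 1.5 mm border for
32 h. These sizes are the package's desk-scale defaults; all scale up by
configuration.

## Mesoscale swirls and single-run variability

At the reference triple the bulk sheet does not behave as a collection of
independently relaxing linear modes: coherent swirls of ~150 µm extent
persist for hours, well beyond the slowest linear relaxation time
(1/α ≈ 0.7 h after mean removal), presumably stabilized by the advection of
the velocity pattern with the cells that carry it. Practical consequences:
single-run correlation measures scatter strongly between seeds (1/e
correlation lengths of 117–152 µm were observed across three seeds, and one
velocity component's autocorrelation can stay above 1/e beyond a 4 h
window); a single snapshot holds only a few dozen statistically independent
velocity samples, so distribution tests must subsample in space and time;
and curve standard errors computed from snapshot-to-snapshot scatter must
be inflated by the ratio of snapshots to effectively independent snapshots.
The headline correlation length is therefore reported from curves averaged
over both components and three independent runs.

## Emergent border kinetics at desk scale

The closed-form leader-entrainment estimate (`border_estimate`) predicts a
border advance `v0 t + ½ λ_L (ℓ/1000) (V_L − v0) t²` that grows quadratically
under a constant creation rate and linearly after the rate drops; it is
verified against an explicit discrete-event model. The emergent band
simulations reproduce the ingredients (slow restrained baseline, ~18 µm/h
finger tips, base-to-tip density decrease) but at desk scale (1.5 mm border,
~8 leaders, one realization) the measured mean border position fluctuates by
±30 µm, which masks the early quadratic signal, and corridors take a few
hours to mobilize followers, delaying the advance. The log–log slopes of the
leader-induced advance measured on such runs are therefore noisy and do not
cleanly resolve the 2 → 1 sequence; resolving it requires longer borders or
averaging over many runs.
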