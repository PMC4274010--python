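# Methods

## The individual-based model

Two sessile species occupy a periodic L × L square lattice (torus), at most
one individual per site; site spacing is one lattice unit and coordinates
are 0-based with wrap-around. Three event types act per individual of
species *i*:

| event | rate | range | outcome |
|---|---|---|---|
| birth attempt | *b<sub>i</sub>* | disc of radius *R<sup>b</sup><sub>i</sub>* | offspring placed on a uniformly drawn site; fails silently if occupied |
| intrinsic death | *d<sub>i</sub>* | — | individual removed |
| kill attempt on species *k* | *c<sub>k,i</sub>* | disc of radius *R<sup>c</sup><sub>k,i</sub>* | uniformly drawn site; an individual of species *k* found there dies, anything else is a no-op |

Competition is *active*: the rate belongs to the killer (the individual
acquiring resources), and the *attempt* rate — not the success rate —
equals *c*. The interaction disc is the set of integer offsets with
0 < dx² + dy² ≤ R²; the focal site is excluded (no self-placement, no
self-kill), which also makes intra- and inter-specific target selection
symmetric.

**Scheduler.** Random sequential updating with rejection: draw one
individual uniformly among the N present, then draw an event against the
global maximum per-capita total rate
Λ<sub>max</sub> = max<sub>i</sub>(b<sub>i</sub>+d<sub>i</sub>+c<sub>1,i</sub>+c<sub>2,i</sub>),
leaving the residual probability mass as a no-op. Simulated time advances
by 1/(N Λ<sub>max</sub>) per elementary update, so the per-capita frequency
of each realised event per unit time equals its nominal rate and the scheme
is distributionally equivalent to an exact event-driven simulation. A *time
step* elapses when on average every individual has been updated once
(tracked by accumulating 1/N per update); densities are recorded once per
step. A *generation* is one unit of simulated time times the smallest
positive birth rate. The hot loop is numba-compiled; a pure-Python
reference implementation of the elementary update (`elementary_update`)
implements the identical scheme and backs the bookkeeping and contract
tests.

**Initial condition.** Every site is independently assigned species 1 with
probability ρ₁(0), species 2 with ρ₂(0) (complete spatial randomness).

**Stopping.** A run ends when (a) the net change of total density across
`stop_window` (default 20) consecutive time steps stays below
`stop_tolerance` (default 10⁻⁵) for a further `stop_window` consecutive
steps, (b) both species are extinct, or (c) a hard cap of
`max_generations` is reached. The persistence requirement in (a) exists
because a windowed net change alone crosses any small threshold by chance
(~1% per step on a 50 × 50 lattice) during slow exclusion transients, which
would mislabel them stationary; with it, genuinely frozen or absorbing
states stop early while fluctuating quasi-stationary communities run to
the cap that each experiment sets explicitly. Extinction is absorbing per
species.

**Defaults.** b = 1, d = 0.1, all c = 0.2, all radii 1, L = 150,
ρ(0) = 0.4 per species. These are the package defaults used across tests
and docs; all are configurable through the YAML spec files
(`model_params`).

## Mean-field analysis

With every individual experiencing average density the model reduces to a
Lotka–Volterra system with logistic birth crowding by *total* density
(births fail into any occupied site):

dρ<sub>i</sub>/dt = b<sub>i</sub>ρ<sub>i</sub>(1−ρ₁−ρ₂) − d<sub>i</sub>ρ<sub>i</sub> − Σ<sub>j</sub> c<sub>i,j</sub>ρ<sub>i</sub>ρ<sub>j</sub>.

Closed forms implemented in `meanfield`: boundary equilibria
ρ<sub>i</sub>\* = (b<sub>i</sub>−d<sub>i</sub>)/(b<sub>i</sub>+c<sub>i,i</sub>);
the interior point solves a 2 × 2 linear system whose determinant is
exactly (b₁+c₁₁)(b₂+c₂₂) − (b₁+c₁₂)(b₂+c₂₁) — positive: stable
coexistence (when the point is interior); negative: the interior point is a
saddle and both boundary points attract (founder control); zero with
coincident null-lines: ecological drift (a line of equilibria). All
stability labels come from the analytic Jacobian; an ODE-integration oracle
cross-checks classification in the tests. The ODE form is kept behind a
single function (`mf_rhs`) so it can be swapped in one place. The spatial
variant (`spatial_mf_rhs`) weights each pairwise density product by a
neighbourhood factor g and reduces to the mean-field form exactly at g ≡ 1.

## Point-pattern statistics

All second-order statistics use exact torus (minimum-image) distances, so
no edge correction is applied anywhere. Patterns live on integer lattice
sites; ordered pair counts are obtained exactly by circular
cross-correlation of occupancy indicator grids (FFT, O(L² log L)), with
self pairs removed for univariate statistics.

* Ripley's K: K(r) = (ordered pairs with d ≤ r) / (λ̂<sub>partner</sub> ·
  n<sub>focal</sub>).
* Pair correlation: per annulus (r<sub>k</sub>, r<sub>k+1</sub>],
  g = (pairs in annulus) / (n<sub>focal</sub> λ̂<sub>partner</sub> ×
  annulus *site count*). Annuli are left-open so that g is exactly the
  discrete derivative of K (which uses d ≤ r); the zero-distance offset
  then never falls in a bin, which removes self pairs automatically.
  Annulus areas are counted in lattice sites, not continuum ring areas:
  on a grid the site count is the exact normaliser and continuum areas
  bias g at small r. Empty annuli (no lattice offset in the ring) are
  flagged NaN.
* Neighbourhood factor g<sub>a,b</sub>(R): K(R) divided by the number of
  lattice sites within distance R of the origin (origin excluded — the
  same disc the simulator uses). It equals the site-count-weighted mean of
  the PCF annuli tiling (0, R], is 1 under independence, and is the weight
  entering the spatial Lotka–Volterra equations.

Default bins are unit-width annuli from 0 to L/4: L/2 is the largest
unambiguous torus distance and L/4 keeps annuli well populated; the bin
width is exposed as a parameter because short-range structure is what the
mechanism diagnostics read. Ensemble PCFs are averaged pointwise with
standard errors.

A note on estimator calibration: on a duplicate-free lattice pattern of
n points the naive estimator carries an O(1/n) deflation relative to 1
under CSR (the focal individual cannot be its own neighbour); at the
densities used in the tests this is ≤ 0.2% and well inside the Monte-Carlo
3-standard-error bands.

## Ecological pressure

P<sub>i</sub> is defined per capita, dρ<sub>i</sub>/dt =
−ρ<sub>i</sub>P<sub>i</sub>, which makes it independent of abundance and
interpretable as the net force the environment exerts on the species:

P<sub>i</sub> = d<sub>i</sub> + Σ<sub>j</sub> c<sub>i,j</sub>
g<sup>c</sup><sub>i,j</sub> ρ<sub>j</sub> − b<sub>i</sub>(1 − Σ<sub>j</sub>
g<sup>b</sup><sub>i,j</sub> ρ<sub>j</sub>),

with g measured from the snapshot at the model's own radii (birth crowding
at R<sup>b</sup><sub>i</sub>, each kill term at R<sup>c</sup><sub>i,j</sub>).
−ρ<sub>i</sub>P<sub>i</sub> reproduces `spatial_mf_rhs` exactly (tested as
an algebraic identity). Pressure on an extinct species is undefined (NaN);
a zero-density *partner* simply contributes nothing. `pressure_from_series`
estimates the same quantity from a density time series alone
(−(Δρ/Δt)/ρ, centred differences plus a moving average), which is how it
would be inferred from field census data; the two estimators agree on
stationary ensembles within Monte-Carlo error.

`delta_pressure_first_order` re-measures only the g factors tied to one
changed radius, holding the pattern and densities frozen — the
instantaneous (first-order) pressure response. On aggregated conspecific
patterns (g > 1 at short range) shrinking the intra-specific competition
radius raises self-pressure; against a segregated competitor (cross g < 1)
shrinking the inter-specific radius relieves the victim. Changes whose
first-order response is zero but that still alter outcomes (the triadic
route) are detected empirically, from simulation and PCF contrasts, not
from analytic third-moment equations, which are out of scope here.

## Mechanism classification

`classify_mechanism` compares a long-range ("mean-field-like") baseline
PCF set with a short-range focal set, for pairs (1,1), (2,2), (1,2), plus
the stationary densities. Summaries: *cluster extent* = first distance at
which the conspecific g falls back through 1; *peak height* = max g;
*short-range g* = mean over the first three defined bins. Rules, in order:

1. **heteromyopia** — dominant species' cluster extent drops by ≥ 25%
   versus baseline while the rare species is aggregated (short-range
   g > 1.1) in both sets;
2. **triadic** — rare species' conspecific peak exceeds 1.5 at baseline
   and its excess over 1 drops by ≥ 25% in the focal set, while the
   dominant's peak changes by ≤ 10%;
3. **spatial segregation** — both conspecific short-range g > 1.1, cross
   g < 0.9, and near-equivalent species, proxied by a density ratio < 3
   (the operation sees only patterns and densities, not parameters);
4. otherwise **none**.

The thresholds are deliberately coarse, monotone summaries of the
qualitative contrasts; the 1.5-peak requirement keeps estimator noise on
unstructured (CSR-like) patterns from triggering a triadic call.

## Experiments and problem sizes

Ensembles use seeds derived as
`SeedSequence([base_seed, point_index, realisation_index])`, so every grid
point re-runs independently and results are order-independent. Outcome
classification thresholds persistence at one individual per lattice
(ensemble-mean density > 1/L²): on a finite lattice "never falls to zero"
is exact zero per realisation, but ensembles near phase boundaries mix
outcomes, so the documented rule operates on the ensemble mean.

The package's own test and acceptance runs are scaled to a 50 × 50 lattice:
ensembles of 5–10 realisations, 200–300 generations for stationary-state
measurements, and 600 generations for sweep classification — long enough
that near-boundary exclusion transients resolve (a remnant of a dying
species otherwise gets misread as coexistence at the grid scale). The
full-resolution design (L = 150; c₁,₂ and d₂ swept in 0.01 increments,
1,404 combinations × 20 realisations = 28,080 runs per composite diagram)
is exposed as `full_scale_manifest()` for cluster-scale reproduction; its
grid endpoints (c₁,₂ ∈ [0.05, 0.40], d₂ ∈ [0.02, 0.40]) are package
choices consistent with the published totals.

## What the synthetic fixtures do and do not show

`make_fixture` provides deterministic patterns with known statistics
(full lattice: g ≡ 1; two tight clusters: aggregation then segregation;
seeded CSR) and *synthetic* mechanism contrasts (`fig4-*-like`): PCF
curves constructed from smooth parametric shapes exhibiting each
mechanism's canonical signature, with densities naming the dominant
species. They validate the classifier's decision logic, not the emergence
of the mechanisms — that is exercised separately by simulation (e.g. the
test showing that lengthening the dominant's intra-specific competition
radius restores coexistence at a point where both the mean-field model and
the short-range simulation give exclusion). Simulated patterns differ from
the fixtures in having estimator noise and partially mixed signatures;
near a boundary between mechanisms the classifier's coarse thresholds may
return `none` rather than guess.

## Known limitations

* Two species only; homogeneous environment; no facilitation, age
  structure or movement of established individuals (continuous space is
  approximated by the lattice, which is equivalent to a finer lattice in
  the limit).
* The stationarity detector is conservative by design; noisy stationary
  runs usually terminate at the generation cap, so the cap is part of the
  experimental design and is reported with results.
* `mf_phase_boundary` extracts boundaries as midpoint segments between
  differently-classified cells — adequate for overlays at sweep
  resolution, not a root-finder for the analytic boundary.
* The triadic mechanism is detected through its pattern signature and
  simulated outcomes; no third-order moment hierarchy is computed.
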