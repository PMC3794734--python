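# Methods

## Lattice models and conventions

Proteins sit on the sites of a lattice that grows along the x axis.  A
*column* is the set of `Ly * Lz` proteins at one x position: `Ly`
filaments per protofibril layer, `Lz` layers (1 for filaments and
strips; the "cube" fibril is two in-register `Ly = 2` strips, `Lz = 2`).
Each protein carries a conformational label: coil (the reference state,
weight 1) and sheet for the two-state models; coil, helix and sheet for
the three-state Potts model.

All interactions are nearest-neighbour Boltzmann weights, free energies
in RT units:

* **Propagation** `s = exp(P)` — carried once per ordered site.
* **Interfaces** — in the two-state model each sheet-coil interface
  along the growth axis costs `exp(-R)`, so one ordered segment
  (two interfaces) pays the classic Zimm-Bragg initiation weight
  `sigma = exp(-2R)`.  With this convention the two-state aggregation
  matrix `[[1, sqrt(sigma)], [s*sqrt(sigma), s]]` has characteristic
  polynomial `lambda^2 - (1+s) lambda + s(1-sigma)` — identical to the
  one-directional helix-coil (folding) matrix — and the textbook closed
  forms (`lambda_1 = (1+s+sqrt((s-1)^2+4 s sigma))/2`, the helicity and
  segment-length formulas) hold with `sigma` appearing once.  The
  three-state Potts model instead carries the full `sigma(r, r')`
  on every interface, as its Hamiltonian is conventionally written;
  its segments pay `sigma^2`.  Both conventions are locked in by the
  enumeration oracle (below).
* **Polymerization** `k = exp(K)` — once per nearest-neighbour protein
  pair (bond) on the lattice: `Ly*Lz*(Lx-1)` x-bonds plus
  `(Ly-1)*Lz*Lx` y-bonds plus `(Lz-1)*Ly*Lx` z-bonds.  The bond count is
  the single normative rule for the `k` exponent in every partition
  function; it is validated site-by-site by the oracle.
* **Lateral binding** `b = exp(B)` — per sheet-sheet pair of y-adjacent
  proteins within a layer; the cube model adds one further `b` for a
  column whose four proteins are all sheet (the inter-protofibril bond).

Open-chain partition functions are `Z = k^bonds <f| T^(Lx-1) |i>` with
`T[new, old] = intra(new) * prod_rows sigma(new_site, old_site)`: the
initial vector carries the first column's intrinsic weight (propagation
plus lateral bonds), the final vector selects allowed final columns.
Boundary kinds: `free` (any conformations at the ends), `coil_only`
(all-coil end columns), `sheet_or_coil` (no helix at the ends; identical
to `free` for two-state models), and `periodic`
(`Z = k^bonds trace(T^Lx)`).

### The enumeration oracle

`fibrilstat.oracle` recomputes every partition function by brute force:
it enumerates all `q^(sites)` (or `(q+1)^(sites)` grand-canonical)
configurations and multiplies the Hamiltonian's weights term by term,
per site and per bond, accumulating with `math.fsum` in fixed order
(bit-reproducible).  It shares no code with the transfer-matrix path and
is the ground truth for every convention above; the certified agreement
is ~1e-14 relative across seeded parameter draws for all geometries,
boundaries and both ensembles.

## Dilute aggregate ensembles and mass balance

In dilute solution each species occurs with number density
`rho(L) = Z(L) z^L` (ideal mixing; `z = exp(mu)` the protein fugacity,
`L` the protein count).  Summing the density and the mass over sizes in
the spectral basis gives geometric and arithmetic-geometric series in
`x_i = k^a z^ell lambda_i`, where `a` is bonds-per-column and `ell`
proteins-per-column; they converge for `x_1 < 1`, i.e. below the
saturation fugacity `z_max = (k^a lambda_1)^(-1/ell)`.  Two numerical
points:

* The closed forms are written as `c_i y x_i^(m-1) / (1-x_i)` (with
  `y = k^a z^ell` and `m` the minimum column count) rather than
  `c_i/lambda_i * x_i^m/(1-x_i)`, so singular transfer matrices — e.g.
  the `sigma = 1` filament, whose second eigenvalue is exactly zero —
  stay finite.
* Near saturation `1 - x_1` suffers catastrophic cancellation; for real
  positive eigenvalues it is evaluated through `expm1` of
  `log(k^a lambda) + ell*log(z)`.

The mass balance `phi(z) = phi_target` is solved by 40 bisection steps
in `ln z` followed by 12 safeguarded Newton steps using the exact slope
`d phi / d ln z` of the closed forms; `phi` is strictly increasing and
diverges at `z_max`, so the root is unique.  Round-trip accuracy is at
machine-precision-limited ~1e-11..1e-10 over four decades of
concentration (the residual floor near saturation comes from
representing `z` itself in double precision: one ulp of `z` moves `phi`
by `~ 2 ell/(1-x_1)` ulps).

The closed-form species sums are continuously certified against an
adaptive direct sum over sizes (`ensemble_sums` evaluates both routes
and requires 1e-8 agreement) — a deliberate dual-evaluation design,
since the published closed forms for these sums contain typographical
inconsistencies and the direct sum is normative.

Observables: the mass-weighted sheet fraction is
`<theta2> = s (d rho_total / d s) / phi` at fixed fugacity (each
aggregate's sheet count is the `ln s` derivative of its `ln Z`),
computed by a centered difference in `ln s` (step 1e-5).  Mean lengths
are ratios of the mass and number series: the ensemble-wide mean
proteins per aggregate, and per-species mean columns along the growth
axis (fibril length is quoted in columns, i.e. proteins divided by
`Ly*Lz`).  `eta` is the mass fraction beyond each species' smallest
aggregate.

**Standard state.** All concentrations and the fugacity are activities
relative to a declared standard state, default 1 uM, carried on every
ensemble and result object.  The published two-state parameter sets for
alpha-synuclein (`P = K = 2.7`, `B = 1.95`, `R = -1.64`, strips
`Ly = 1..4`) and A-beta(1-40) (`P = 7.41`, `B = 1.4`, `R = -2.47`,
`K = 0.45`, filament + strip + cube) produce, under this convention,
fibril take-off (half-rise of the fibril species' mass fraction) at
~6.3e-3 uM and ~0.68 uM respectively.  The source literature quotes
take-offs of ~15 uM and ~100 uM for these parameter sets; no choice of
standard state reconciles both (the model is linear in the standard
state, so the ratio of the two take-offs is convention-free: ~107 here
vs ~6.7 quoted), and the printed closed-form species sums those numbers
were presumably produced with are internally inconsistent (their cube
`k` exponents disagree between their own terms).  The package therefore
reports the take-offs its own certified model actually predicts and
makes the standard state an explicit knob rather than a hidden
calibration.

In the two-state models the single propagation/interface pair is stored
in the `P1`/`R1` fields (`EnergyParams.two_state`); published fits
quote the same two numbers variously as `P1`/`P2` and `R2`, but a
two-state model has only one such pair.

## Single-chain helix-coil models

The zipper model (at most one helical stretch) uses the derived closed
form `1 + sigma (s^(N+2) - (N+1) s^2 + N s)/(s-1)^2`; within `1e-4` of
`s = 1` the closed form cancels catastrophically and the exact direct
sum is used instead (at `s = 1` it reduces to `1 + sigma N(N+1)/2`).
The finite Zimm-Bragg chain uses the one-directional pair weights
(cc:1, hc:1, ch:`sigma s`, hh:`s`); helicity and segment counts are
log-derivatives of `ln Z` (centered differences with one Richardson
step, initial step 1e-4 in `ln x`, relative accuracy ~1e-7).  The
maximum helical residue count `N_H` defaults to `N` (whether chain ends
are excluded is not specified in the source conventions; the default is
documented rather than guessed).  Finite-chain helicity converges to
the closed form like `1/N` at small `sigma` — at `N = 200`,
`sigma = 1e-3`, `s = 1.2` it is still ~5% below the limit, which is the
physically correct finite-size effect, not an error.

## Oosawa-Kasai mass action

`n_k = sigma s^(k-1) n1^k` for `k >= 2`; the monomer is the reference
species (`n_1 = n1` — extending the k-mer formula to `k = 1` would give
`sigma n1`, inconsistent with the mass series, so the convention is
explicit).  `m_tot(n1)` uses the closed form
`n1 (1 - sigma + sigma/(1 - s n1)^2)`; inversion is bracketed Brent on
`(0, min(m_tot, (1-1e-14)/s))` to machine tolerance.

## Grand-canonical lattice gas

Sites hold a solvent cluster (weight 1) or a protein (weight `z` per
protein) with a conformation.  Per protein-protein bond along a
filament: `k`, plus `s1` when the left protein is sheet, plus
`exp(-R1)` when the two conformations differ; each sheet protein facing
solvent also pays `exp(-R1)`; each solvent-aggregate nucleation
boundary pays `exp(-A)` (so one aggregate pays `alpha = exp(-2A)`).
Variant A runs the nucleation window (`nc` columns, fully occupied
interior) along the growth axis independently in each row and couples
rows only by `f = exp(F)` between lateral sheet pairs; variant B makes
the column the nucleus (penalty when a uniformly occupied column meets
its complete opposite) and gives the y direction full bond interactions
with `F` as the lateral sheet propagation.

For `nc > 1` the transfer-matrix state is augmented with the occupancy
pattern of the previous `nc - 1` columns (dimension
`3^Ly * 2^(Ly(nc-1))`, capped at `nc*Ly <= 8` composite sites — the
published fits use `nc = 2`, `Ly <= 2`, well inside the cap).  The
strip is periodic along x; `ln Q / (Ly N) -> ln(lambda_1)/Ly`.

Because every matrix entry is a monomial in `(z, s1, k, alpha)`, the
thermodynamic averages are computed *exactly* through entrywise
exponent matrices: `d ln trace(T^N) / d ln x = N trace((T*E) T^(N-1)) /
trace(T^N)` on finite rings and `u (T*E) v / (lambda_1 u.v)` in the
thermodynamic limit (`u, v` the leading left/right eigenvectors).
Occupancy is the `z` derivative, sheet segments the `s1` derivative,
filament count the `ln alpha` derivative (half the expected number of
aggregate boundaries — the source's `(1/2) d/dA` form, made
sign-definite for a penalty `A > 0`), and proteins-in-filaments the `k`
derivative plus the filament count.  These match the enumeration oracle
to ~1e-15.

The solution link uses `mu_soln = mu_ST + mu_SR + RT ln c` with the
literature constant `mu_ST + mu_SR = -29 kcal/mol` and the
three-quarters rule `mu_PV = 0.75 (mu_ST + mu_SR)` by default;
`R = 1.9872e-3 kcal/(mol K)`, `T = 298.15 K` (RT = 0.5925 kcal/mol),
concentration standard state 1 M — all overridable on `SolutionLink`.

## Fitting

Model objects (`FibrilCurveModel`, `GrandCurveModel`) hold a dataset
(concentrations in uM, observed sheet fractions or mean lengths,
optional per-point SEs) and a model configuration; free parameters are
named free-energy fields, optionally tied (e.g. `K = P1`) and bounded
(default (-8, 12) RT — wide enough to be uninformative, narrow enough
to keep the weights representable).  The loss is (optionally
SE-weighted) squared residuals, minimized with bounded trust-region
least squares (`scipy.optimize.least_squares`, finite-difference
Jacobian, `diff_step = 1e-5`); `fit(n_restarts=...)` restarts from
seeded multiplicative jitters of the start vector and keeps the best
optimum.  Standard errors come from the Gauss-Newton covariance
`(J'J)^-1 * RSS/(n-p)` at the optimum; a parameter whose Jacobian
column is numerically null is flagged *flat* (the data do not constrain
it — the situation the source describes as fitted values "~0 within
modeling uncertainty") instead of being given a meaningless SE.
Duplicating every data point leaves the optimum unchanged (unweighted
loss), and a noise-free synthetic dataset is recovered to ~1e-4 from
20%-perturbed starts.

### Synthetic data

`generate_synthetic_curve` evaluates the exact model observable at each
concentration and adds independent Gaussian noise (seeded,
bit-reproducible), clipping sheet fractions to [0, 1] and lengths to
>= 1.  It emulates steady-state CD sheet-fraction titrations and AFM
mean-length titrations with homoscedastic Gaussian error.  It does
*not* emulate: raw-ellipticity-to-fraction conversion error,
length-dependent AFM detection bias, heteroscedastic or correlated
noise, kinetic trapping, or off-pathway species — so parameter-recovery
results certify the estimator under the model's own assumptions, not
robustness to real-data pathologies.

The recovery study (acceptance suite) uses the alpha-synuclein-style
four-strip model: 30 log-spaced concentrations spanning the length
take-off (5e-4..5e-2 in standard-state units), additive noise SD 0.02
on the mean length, truth `P = K = 2.7`, `B = 1.95`, `R = -1.64` with
`P = K` tied (three free parameters, as in the published fit), starts
jittered ±20%, one start per replicate, 100 replicates; success is all
parameters within 3 SE of truth.

## Known limitations

* Quasi-1D only: transfer matrices are finite (`q^(Ly Lz)` canonical,
  `3^Ly`-based grand-canonical); no 2D/3D bulk limits.
* Canonical two-state observables treat the ordered state as "sheet";
  helix-specific observables need the three-state model.
* The grand-canonical module is two-state (`q = 2`) only.
* Equilibrium only — no kinetics, no secondary nucleation, no
  off-pathway oligomers.
* The published take-off concentrations are not reproduced under any
  self-consistent reading of the published equations (see Standard
  state above); the package's predictions are internally certified but
  differ from those printed values.
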