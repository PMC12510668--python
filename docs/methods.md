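# Methods

This note documents the model implemented by `placeremap`, the choices made
where the design was genuinely open, and what the synthetic scenarios do and
do not show about real data.

## Latent code

Each environmental variable `x ∈ [-1, 1]` is encoded on a circle:
`α = π(x + 1)`, `z = (cos α, sin α)`. The circle reflects two modelling
commitments: energy-normalized population activity (direction, not
magnitude, carries the message) and localized tuning (a curved trajectory
aligns with each neuron's tuning vector only locally, producing fields
rather than monotonic ramps). Decoding uses `atan2(sin, cos)` mapped into
`[0, 2π)` (negative branch shifted by `2π`), which makes
`decode ∘ encode` the exact identity on `[-1, 1)`; the seam `x = +1` is
identified with `-1`, so position grids are half-open. Grid-module codes
scale the angle by `(3/2)^{f_j}` per module with `f_1 = 0` enforced; the
first module is then a bijection and position is decoded from it alone. The
default exponents are `(0, 1, -1, 2, -2, …)`. The square-lattice geometry is
deliberate; hexagonal (twisted-torus) modules are out of scope.

With both positional and cognitive blocks present, each block is normalized
to `1/√2` so the latent vector is unit length, matching the unit-norm
decoder columns. When the embedding dimension `Y` exceeds a cutoff
(default 4) the embedding vector is additionally multiplied by `Y`. This
factor matters: it keeps the drive `Dᵀy` strong relative to the fixed
thresholds as `Y` grows, and it is what makes autoencoding accurate — with
it, the reference multi-chart configuration decodes with ≈ 8% median
relative error; with a weaker `√Y` factor the error triples and the model
leaves its intended accurate-autoencoding regime.

## Environments

A scenario holds `K` environments over one position grid (default 100
points in 1-d, 32×32 in 2-d, equally spaced, half-open).

*Cognitive trajectories.* `c^A(p) = wrap(k^A + g^A(p))` per component, with
offset `k^A ~ N(0, σ²)` for `σ < 1` and `Uniform[-1, 1]` at `σ = 1`, and
`g^A ~ GP(0, K)` with squared-exponential kernel of marginal variance `σ²`
and length scale `v` (default 0.3 in normalized position units; Euclidean
distance over the flattened grid, jitter `1e-8`, Cholesky sampling).
A single parameter `σ` thus scales both the across-environment offsets and
the within-environment fluctuations; we read the printed `N(0, σ)` as
standard deviation `σ`, coherent with the kernel amplitude `σ_v² = σ²`.
Components are i.i.d. across the `C` cognitive dimensions. The wrap to
`[-1, 1)` matches the circular latent geometry and may create seams; that is
accepted. The reward task replaces the GP by the deterministic profile
`c(p) = exp(-(p-μ)²/(2σ_r²)) - 1` with one reward location `μ` per
environment.

*Embedding maps.* Multi-chart environments draw `R^A` Haar-uniformly from
the orthonormal-column matrices (QR of a Gaussian matrix, columns
sign-corrected by the R-factor diagonal). Grid realignment draws one
2×2 rotation per (position variable, module) with phase `Uniform[0, 2π)`.
Mixed-selective scenarios use the identity map. All maps are isometries on
their column space.

## Network

Decoder weights `D ∈ R^{Y×N}` are Gaussian, normalized per code scheme:
mixed (unit columns), conjunctive (each circle pair at `1/√(Y/2)`),
conjunctive-mixed (positional pairs conjunctive, cognitive rows mixed, block
norms `1/√2` each), and the hand-designed pure-and-mixed code. For
pure-and-mixed, pure cells' preferred angles are evenly spaced on their
circle (starting at 0) rather than random: the code exists to demonstrate
dedicated pure-selective cells, and even spacing guarantees coverage of the
variable range with a handful of cells — with four pure-cognitive cells one
sits exactly at the reward angle π. The full-dimensional variant sets
`D = Id_N` with `Y = N`. Thresholds default to `T = ½ diag(DᵀD)`.

Steady-state rates solve `min_{r≥0} ‖y − Dr‖² + 2Tᵀr`. The solver is an
active-set (Lawson–Hanson style) iteration adapted to the linear cost, with
two safeguards for degenerate instances (near-parallel decoder columns make
the restricted normal equations numerically singular): a descent-ray step
along the null-space residual when the restricted system is inconsistent,
and a FISTA fallback with support polishing when the active-set iteration
stalls. Every returned solution satisfies the KKT certificate
(`g = 2Dᵀ(Dr−y) + 2T ≥ −10⁻⁶`, `r·g ≤ 10⁻⁶`); residues below `10⁻⁹` are
clamped to zero. On random instances small enough for exhaustive support
enumeration the solver matches the global optimum to `10⁻⁸` in objective.
When the active set is degenerate (duplicated columns) the solution is not
unique; the solver reports one KKT point.

*Participation modulation.* `spar ∈ [0, 1]` is the fraction of neurons left
at normal excitability; `round(N(1−spar))` uniformly chosen neurons get the
suppression threshold. The printed convention ("choose N·spar and
suppress") conflicts with the same source's reading of `spar > 50%` as cell
birth; we adopt the active-fraction convention. The suppression threshold
is specified as 10 at unit input scale and is multiplied by the embedding
rescale factor, so suppression always means silencing (~10× the effective
drive); without this scaling, large-`Y` inputs can exceed a fixed threshold
of 10 and "suppressed" neurons keep firing where drive is extreme.

## Analysis

Rate maps are thresholded at `10⁻³` before analysis. Overlap is the cosine
similarity of environment-mean population vectors; its shuffle permutes
neuron identities of both vectors (20 realizations, independent RNG stream
per environment pair). Spatial correlation averages per-neuron rate-map
cosine similarity over neurons active (any post-threshold rate > 0) in both
environments; its shuffle pairs each co-active neuron with a random
different co-active partner. Significance is a two-sided one-sample t-test
of the per-pair means against the grand shuffle mean, with threshold
`0.05/n_tests` (`n_tests = 1` for a single configuration; set it to the
sweep size when sweeping). Pairs whose statistics are undefined — an empty
rate map (full suppression), or no co-active neurons — are excluded and
reported as skipped rather than silently dropped or NaN'd.

The remapping-norm decomposition reports, per environment pair,
root-mean-square over grid positions (configurable to sum) of: the full rate
difference; its spatially decodable part `D_p Δr`; its cognitively decodable
part `D_c Δr`; and the null-space residual `Δr − E D Δr`. For
encoder-decoder scenarios the whole embedding carries position, so the
spatial block is all of `D` and the cognitive norm is 0. With orthonormal
encoder columns the per-position Pythagorean identity
`‖Δr‖² = ‖EDΔr‖² + ‖Δr − EDΔr‖²` holds and is tested.

Place-field statistics: a neuron is active if any post-threshold rate is
positive; field size is the fraction of grid positions above 10% of the
neuron's peak (configurable), contiguity not required, averaged over active
neurons.

*Null-space dominance* is the median over grid positions of
`‖D Δr(p)‖ / ‖Δr(p)‖` between the default and a modulated map — small values
certify that participation modulation moved activity without moving the
decoded estimate. Comparisons against a fully silenced map are excluded
(they measure the default map, not a remapping).

*Reward-zone analysis* (1-d reward task): the reward zone is
`|p − μ| ≤ 2σ_r`, the region where the reward signal varies appreciably;
winner density is the count of distinct argmax neurons per unit position.
Cross-location comparisons use two sets: neurons *winning* inside the reward
core (`|p − μ| ≤ σ_r`) of every environment (expected empty for a
conjunctive code, whose reward responses remap with position), and neurons
*active* somewhere in the zone of every environment (where a pure-reward
cell appears under the pure-and-mixed code).

## Reference configurations

Desk-scale versions of the main remapping experiments, runnable in seconds
to tens of seconds each on one CPU (sizes chosen to preserve the redundancy
regimes that carry the qualitative results):

| scenario         | N   | Y  | P | C | K  | grid  | code | notes |
|------------------|-----|----|---|---|----|-------|------|-------|
| multi_chart      | 256 | 16 | 2 | 0 | 10 | 32×32 | M    | redundancy 16 |
| full_d           | 64  | 64 | 2 | 0 | 10 | 32×32 | Id   | truly random |
| grid_realign     | 96  | 12 | 2 | 0 | 10 | 32×32 | C    | m = 3, f = (0,1,−1) |
| space_feature    | 256 | 16 | 2 | 6 | 10 | 32×32 | CM   | σ = 0.3 |
| implicit_space   | 256 | 12 | 0 | 6 | 10 | 32×32 | C    | no encoded position |
| null_space       | 256 | 16 | 2 | 0 | 1  | 32×32 | M    | spar ∈ {0,…,1}, 5 draws each |
| reward / pure-mixed | 16 | 4 | 1 | 1 | 2  | 200   | C / pM | μ = ∓0.5, σ_r = 0.2 |

The null-space scenario deliberately reuses the multi-chart network: with
fewer neurons (e.g. N = 48) the population left after 50% suppression has
too little redundancy and the decoded estimate shifts along with the rates,
destroying the null-space confinement that defines this remapping family.
The implicit-space code scheme is conjunctive so every neuron is tuned to
all cognitive angles (localized fields); with a mixed code many neurons
would be dominated by a single variable.

Seeding is hierarchical and counter-based (`SeedSequence([master, tag,
index])`): per-environment draws, the network, threshold modulations, and
each pair's shuffle stream are independent, so adding environments does not
perturb earlier ones and every run is bit-reproducible.

## What the synthetic scenarios do and do not show

The generator emulates steady-state, noise-free, trial-averaged rate maps
under fully specified remapping mechanisms. Passing the signature tests
shows that the statistics *separate the mechanisms in the model*: overlap
above shuffle with chance-level spatial correlation for low-dimensional
encoder-decoder remapping; both above shuffle for mixed selectivity at
moderate variance; both high with null-space-confined changes for
participation modulation; neither for full-dimensional random remapping.
The scenarios contain no spiking noise, no behavioral sampling, no drift
within an environment, no learning, and no time-resolved dynamics, so the
tests say nothing about estimating these statistics from finite, noisy
recordings. Deep suppression (spar = 0.25) already shows the limit of the
idealization: with the surviving redundancy down to 4, decoding degrades
and a measurable spatial component leaks into the remapping vector.

At the reward task's reference size (N = 16) the conjunctive-code checks
carry residual seed-to-seed variability (roughly one seed in ten shares a
core winner by chance); the package's tests pin the reference seed, and the
20-seed behaviour is documented here rather than hidden.

## Numerical choices

KKT tolerance `10⁻⁶`, objective comparisons `10⁻⁸`, rate clamp `10⁻⁹`,
analysis threshold `10⁻³`, GP jitter `10⁻⁸`, orthonormality checked at
`10⁻¹⁰`. Argmax ties in mosaics break to the lowest neuron index; mesh
points where no neuron is positively excited render as background. The
feedforward excitation `Dᵀy` is a visualization-only approximation and
never feeds the statistics.
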