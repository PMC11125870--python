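# Methods

`markergp` models the kinetics of cancer-stem-cell (CSC) marker expression in
polystyrene-nanoparticle (PSNP)-treated cancer cell lines. Flow cytometry
yields, per marker system, the percentage of gated cells positive for a
marker (or double-positive for a marker pair) at 24, 33, 43 and 52 h after
treatment, with a further measurement at 76 h held out for blind validation
and a 96-h forecast requested beyond all data. Three independent experiments
provide three replicates per timepoint. The package (1) simulates such data
for the nine marker model systems of the study design, (2) fits each treated
time course with a genetic-programming (GP) symbolic regressor, and
(3) validates the fitted expression blind at 76 h and forecasts 96 h.

## Synthetic data generator

The generator emulates the study design; it is parameterized from the
published percentage ranges and qualitative trend descriptions per system,
not from raw measurements (which are not publicly deposited as numbers).
What it produces is therefore an *emulation* of the study's statistical
structure, not a reconstruction of the real data.

Each system is a `GeneratorSpec`: a trend family, a percentage range
`[range_low, range_high]`, optional control-arm anchors, a noise level and
the design grid (timepoints, replicates). The five trend families are
minimal smooth curves consistent with the described kinetics, anchored so
the trend attains the printed extremes over the 24–76 h span:

| family | form | anchors |
|---|---|---|
| `monotone_increase` | linear | low at 24 h → high at 76 h |
| `monotone_decrease` | linear | high at 24 h → low at 76 h |
| `dip_then_rise` | quadratic, vertex at 33 h | low at 33 h, high at 76 h |
| `rise_then_plateau` | saturating exponential | low at 24 h, plateau 0.95·high, 95% saturated by 43 h |
| `acute_peak_then_decline` | exponential decay (~10× over span) | high at 24 h, low at 76 h |

All trend values are clamped to [0, 100]. The nine default systems:
HCT-116 ABCG2⁺ (6.71–13.39%, dip then rise), HCT-116 ALDH1⁺ (6.13–26.8%,
steady increase, 2.5-fold over control at 52 h), HCT-116 CD24⁺ABCG2⁺
(0.31–2.94%, steady increase), HCT-116 CD24⁺ALDH1⁺ (0.34–2.09%, rise then
plateau), MDA-MB-231 CD24⁺ABCG2⁺ (6.56–15.69%, acute 24-h peak then
decline), and declining MDA-MB-231 systems CD24⁺ALDH1⁺ (2.16–5.71%),
ABCG2⁺CD24⁺ (2.09–3.11%) and ALDH1⁺CD24⁺ (1.59–2.89%). MDA-MB-231 CD44⁺ has
no published range anywhere; its default (80–95%, rise then plateau) is an
assumption — CD44 is near-ubiquitously expressed in this line — flagged with
`assumed_range=True` and overridable in configuration.

**Noise model.** Replicates are the trend plus independent Gaussian noise on
the percentage scale, clamped to [0, 100]. The default standard deviation is
5% of the system's dynamic range (`range_high − range_low`). The rationale:
the nine systems span percentages from 0.3% to 95%, yet the study reports
comparably tight replicate scatter and uniformly near-unity prediction
scores for all of them. That pattern is only consistent with measurement
error that scales with the signal span. A fixed absolute noise (say 0.5
percentage points) would be negligible for the CD44 system but larger than
the entire dynamic range of the narrow double-positive systems — under it,
even the *true generating trend* would have an expected blind-window R² of
about 0.4–0.6 on those systems, contradicting the uniform near-unity scores
the generator is supposed to emulate. An explicit `noise_sd` (including 0)
overrides the default.

**Control arms** are flat: at the midpoint of the treated range by default,
at `control_level` when the published comparison direction pins it (the
declining MDA-MB-231 systems stay below control), or at
`treated(52 h)/fold_change_at_52h` when a fold change is stated (HCT-116
ALDH1⁺, 2.5-fold). Whether real control arms drift over time is not
quantified in the source; flat is an assumption.

**Seeding.** One master seed; each system draws from a substream whose seed
is `CRC32(labels) XOR (master · golden-ratio constant) mod 2³¹`. Adding or
removing systems therefore never shifts another system's draws, and every
stage is bit-reproducible.

## GP symbolic regressor

The regressor is a tree-based genetic program over a single predictor,
scaled time `t = hours/24` (training inputs 1.0–2.17, commensurate with the
default constant range [−10, 10]). Internal nodes come from the function set
{add, sub, mult, div, sqrt, log, abs, neg, inv, max, min, sin, cos, tan};
leaves are `t` or a constant. Protected primitives make evaluation total:
div and inv return 1 when the denominator magnitude is ≤ ε (default 10⁻⁶),
log acts on |x| and returns 0 below ε, sqrt acts on |x|, tan is clamped to
±10⁶. With the default depth bound this guarantees finite output for finite
input (verified against an independently written naive evaluator).

Evolution is a standard generational loop: ramped half-and-half
initialization at depths 2–4, tournament selection (size 5) on fitness
penalized by tree size, subtree crossover (p=0.70, bounded retry on depth
violations), subtree mutation (0.15), point mutation (0.10, with constants
refined half the time by a local Gaussian perturbation rather than a fresh
draw), reproduction (0.05), one elite, maximum depth 6, population 500, at
most 100 generations, early stop when the training R² reaches 0.9999. Raw
fitness is R² of the tree's predictions against the fitting target;
penalized fitness subtracts 0.001 per node (parsimony pressure). All
randomness flows from a single integer seed; runs are bit-reproducible.

Two additions beyond the plain loop:

* **Hall of fame.** The best individual of every distinct tree *shape*
  (preorder symbol signature) encountered during the run is retained (up to
  24 shapes, ranked by penalized fitness).
* **Constant polish.** At the end of a run the constants of each hall
  member are refined by Nelder–Mead least squares (shape fixed, constants
  clipped to the configured range, deterministic). Evolution explores
  shapes well but tunes numeric coefficients only by random perturbation;
  a short local optimization closes that gap.

## Fit → blind-validate → forecast protocol

For each treated time course the protocol computes per-timepoint replicate
means, fits the four training means (24–52 h), and only afterwards scores
the result against all five means including the blind 76-h mean. Isolation
is structural: the evolutionary search and the model selection receive
exactly four timepoints. Reported scores are

* `r2_train` — R² over the four training means,
* `r2_overall` — R² over the five means including the blind point (the
  headline "score of the prediction"): with a single blind observation an
  R² of the blind point alone is undefined (zero total sum of squares), so
  the five-point score is the self-consistent choice, with the absolute
  blind error reported alongside,
* `abs_error_blind` — |prediction − observed mean| at 76 h, in percentage
  points,
* predictions at 76 h and 96 h, clamped to [0, 100] for reporting, with raw
  unclamped values retained for diagnostics.

R² follows the standard definition 1 − SSR/SST with SSR the residual sum of
squares and SST the total sum of squares about the observed mean. Degenerate
case: when all observed values are equal (SST = 0) the score is 1.0 if the
worst residual is below 10⁻⁹ and 0.0 otherwise.

**Restarts and model selection.** The protocol runs five independent
searches (seeds derived from the protocol seed) and pools their polished
halls of fame, collapsing candidates with numerically identical predicted
trajectories. The reported model is chosen by three data-side criteria, none
of which touches the blind point:

1. *Adequacy*: a candidate's training residual sum of squares must not
   exceed twice the summed squared standard errors of the training means —
   a lack-of-fit allowance of about twice the expected noise contribution,
   estimated from the replicate scatter. This removes both underfits and
   noise-chasing interpolants (fitting closer than the noise floor earns no
   credit).
2. *Plausibility*: the trajectory must stay within [0, 100] over the whole
   24–96 h window — predictions are percentages.
3. *Smoothness*: among the remaining candidates, the trajectory with the
   smallest integrated squared second difference wins (ties → fewer nodes,
   then higher training R²). Marker kinetics are slowly varying; among
   models equally consistent with the data, the smoothest is preferred.

If nothing is adequate (e.g. a deliberately tiny search budget), the best
raw fit within [0, 100] is reported instead.

**A known, fundamental limitation.** Four training points cannot identify
extrapolation behavior within a function space this rich. In internal
experiments the pooled candidate set essentially always contains an
expression whose blind-window score exceeds 0.94, but candidates that fit
the training means equally well (within replicate noise) routinely disagree
beyond 52 h, and no training-side criterion — parsimony, adequacy,
smoothness, consensus across restarts, or leave-one-out refitting of
constants — reliably singles out the one that extrapolates best.
Model selection as described makes the choice deterministic, physically
plausible and often good, but the worst-of-nine blind score varies
substantially across data realizations and seeds. Suite-level summaries
(minimum/mean across the nine systems) should therefore be read as
realizations of a volatile statistic, not as stable properties of the
method. This volatility is intrinsic to blind extrapolation from four
points, not an implementation artifact.

## Treated-vs-control comparison

Per shared timepoint, a two-sided Mann–Whitney test on the replicate
values. U is computed from mid-rank sums (ties receive averaged ranks). For
pooled sizes up to 12 the p-value is exact: all C(n_a+n_b, n_a) assignments
of the pooled values are enumerated and those with |U − n_a·n_b/2| at least
as large as observed are counted — correct under ties, unlike the usual
distribution-table shortcut. Larger samples use the tie-corrected normal
approximation (scipy). Note that with three replicates per arm the smallest
attainable exact two-sided p is 2/20 = 0.1: significance at the 5% level is
mathematically impossible, which is worth remembering when reading per-
timepoint tables. No multiple-testing adjustment is applied across
timepoints or systems; the report notes this.

## Problem sizes and runtime

Default suite: 9 systems × (5 restarts × 500 individuals × ≤100
generations), four training points per fit. A full simulate-and-fit run
takes a few minutes on one CPU core; unit tests use reduced budgets
(population 60–80, ≤12 generations, 1–2 restarts) chosen to exercise the
same code paths quickly.

## Degenerate inputs and conventions

* Fewer than two distinct timepoints: rejected (R² undefined).
* Constant observations: handled by the SST = 0 convention above; an
  interpolating constant is recoverable exactly only if the level lies
  within the configured constant range.
* Generated percentages and reported predictions are clamped to [0, 100];
  clamping of noise makes extreme noise levels slightly sub-Gaussian near
  the scale edges.
* Expression text round-trips exactly (`repr` of IEEE doubles); parsing
  errors carry character positions.
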