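# Methods

This note documents the statistical procedures phagepst implements, the
conventions and defaults it fixes, what the synthetic-data generator does and
does not emulate, and the design choices made where the underlying protocol
left room for interpretation.

## Planktonic killing assay (PKA)

A strain's susceptibility in liquid culture is read from 24 h OD600 curves
sampled every 15 min (the default grid; irregular grids are accepted). The
statistic is the normalised area under the curve,

    AUC_norm = AUC[0,24h](infected) / AUC[0,24h](uninfected control),

with trapezoidal integration. The call is **lysis** when `AUC_norm < 0.8`,
strictly — 0.80 itself is **no lysis**. The cutoff is a configuration value
(`cutoff_auc`, default 0.8).

Conventions fixed here:

* **No blank or pathlength correction.** Ratios are taken on raw OD. A shared
  blank offset inflates both integrals and compresses the ratio toward 1;
  users who blank their reader exports should do so before import.
* **Replicates are averaged as curves** (pointwise mean OD on a shared grid)
  before any integral is taken, mirroring how pooled triplicates are handled
  in the MOI assay; per-replicate ratios can still be computed by calling
  `auc_norm` per well for dispersion diagnostics.
* **Time of lysis** is the first *sampled* time `t > 0` at which the
  expanding-window ratio `AUC[0,t](infected)/AUC[0,t](control)` is below the
  cutoff. It is reported only for pairs whose full-window call is lysis, so
  `time_of_lysis is None ⇔ call == no_lysis` always holds. At the first
  sample the ratio is defined by the first trapezoid; a control whose
  integral prefix is zero raises a degenerate-control error rather than
  producing 0/0 (protocol cultures start at OD 0.1, so this only occurs for
  failed wells).
* **Short runs**: if either curve ends before 24 h the ratio is computed over
  the common window, and the call refers to that window.

Integration endpoints that fall between samples are linearly interpolated;
for piecewise-linear curves the integral is exact and invariant under grid
refinement, which the test suite asserts as a property.

## Virulence indices (vi, vp)

The local virulence index at one MOI is

    vi = 1 − AUC[0,t_s](infected) / AUC[0,t_s](control),

integrated to the **control's** stationary-phase onset `t_s` (both curves use
the same bound). vi is clamped to [0, 1]: regrowth exceeding the control
(raw vi < 0) carries no additional virulence information and would corrupt
the second integration. The clamp is this package's choice and is visible in
`local_virulence`.

**Stationary-phase onset** is the first local maximum of the control: the
first sample whose OD is not exceeded (beyond a tolerance `tol`, default
0 OD) by any of the next `window` samples. The window defaults to 5 samples
(75 min at the 15-min cadence). The "first local maximum with a threshold of
5" rule admits several readings (samples, minutes, slope units); the
5-sample forward-looking window is the simplest one consistent with "first
local maximum" and is isolated in `detect_stationary_onset` so alternatives
can be plugged in. A strictly increasing control has no interior maximum and
falls back to the final time point — this is the correct bound for a culture
still growing at 24 h, and it is also what makes the noise-free logistic
control analytically tractable in the tests.

The global index integrates vi over the MOI ladder (default
1, 0.1, …, 10⁻⁴):

    A_p  = trapezoidal area under vi versus log10(MOI),
    A_max = log10(MOI_max) − log10(MOI_min)   (= 4 for the default ladder),
    vp   = A_p / A_max ∈ [0, 1].

vp requires at least two distinct MOIs; entry order is irrelevant. Base-10
logarithms are used throughout.

## Host-range coverage and DPA/PKA concordance

Coverage counts per phage are taken over non-missing cells only (`NA` cells
are excluded from numerator and denominator alike). Display percentages are
rounded **half-up to integers**; machine outputs keep full precision and no
intermediate is ever rounded, so a displayed `5% + 13% = 18%` may coexist
with an exact `17.4%` total.

Pairs tested with both assays fall into six groups (DPA call × PKA call):

| group | DPA | PKA |
|---|---|---|
| 1 | no lysis | no lysis |
| 2 | reduced growth | no lysis |
| 3 | lysis | no lysis |
| 4 | no lysis | lysis |
| 5 | reduced growth | lysis |
| 6 | lysis | lysis |

**Concordance is the fraction in groups 1 and 6 only.** Reduced growth is
not an agreement with either PKA outcome; group 2 is ambiguous, not
concordant. Per-genus breakdowns (when phage metadata is supplied) recompose
exactly to the global fractions when weighted by pair counts — a property
the tests assert.

## MRGN classification

Zone diameters are interpreted as S (`diameter ≥ s_min`), R
(`diameter < r_max`) or I (in between). Breakpoints are **data** — a
versioned TSV, never constants — because they are revised annually.
The RKI multidrug-resistance classes count resistant *lead substances* of
four antibiotic classes (defaults: piperacillin, ceftazidime, meropenem,
ciprofloxacin): three ⇒ 3MRGN, four ⇒ 4MRGN. "I" counts as non-resistant by
default (`--i-as-resistant` flips this for sensitivity analysis).
Combination agents and non-lead antibiotics are carried through but never
decide the class. `phagepst.synthetic.example_breakpoints()` ships
plausible, clearly-labelled placeholder values for simulation; real analyses
must supply the current EUCAST table.

## Ranking rubric

Points: DPA lysed strains `[42,∞) → 3, [21,42) → 2, [0,21) → 1`; PKA lysed
strains `[63,∞) → 3, [31,63) → 2, [0,31) → 1`; vp
`[0.6,1] → 3, [0.3,0.6) → 2, [0,0.3) → 1`; safety 1 point for a strictly
lytic phage free of virulence factors, resistance genes and
lysogeny-associated genes (safety is consumed as a boolean input; genome
screening is out of scope). All bins are half-open with inclusive lower
edges: the explicit "≥" on the top bins forces the middle bins' upper edges
to be exclusive. The count thresholds correspond to ~15/30% (DPA) and
~22/45% (PKA) of a 141-strain panel and are exposed as configuration so the
rubric scales to other panels. Ranking ties break deterministically by
(PKA points, DPA points, vp points, name).

## Cocktail optimization

Coverage of a phage set is the number of strains with a lysis call for at
least one member; reduced growth never counts unless `include_reduced` is
set. The exhaustive solver enumerates all C(n, k) subsets with bitmask
unions and returns *every* co-optimal set (capped at 10,000 with a
truncation flag); `auto` uses it whenever C(n, k) ≤ 10⁶, which covers
realistic panels (18 safe phages at k = 6 is 18,564 subsets). The greedy
solver adds the best-marginal-gain phage per step, breaking ties
lexicographically, and inherits the classical (1 − 1/e) max-coverage
guarantee — asserted empirically against brute force in the tests. There is
no randomness anywhere in the solvers.

## Synthetic-data generator

The generator is phenomenological: the pipeline consumes only OD curves, so
a piecewise logistic/exponential model with closed-form means is preferred
over a mechanistic phage–bacteria ODE — it gives analytic AUC oracles for
the tests. Components:

* **Control**: logistic `OD(t) = K·od0 / (od0 + (K − od0)·e^{−rt})` with
  defaults od0 = 0.1 (the protocol's adjusted inoculum), r = 0.6 h⁻¹,
  K = 1.2 OD — plateau well before 24 h, as plate cultures do.
* **Infected**: follows the control until the onset
  `t_L = max(0, t0 − τ·log10(MOI))` (default t0 = 4 h, τ = 1 h/decade:
  higher MOI lyses earlier), then decays exponentially (λ = 2 h⁻¹) toward a
  debris floor (0.05 OD). With probability `regrow_frac` a resistant
  subpopulation regrows logistically (rate r2) from a seeded time — modelled
  on the second-lysis-after-regrowth behaviour real panels show. `λ = 0`
  with no regrowth is the null phage and reproduces the control exactly.
* **Noise**: additive Gaussian on OD, truncated at 0. Multiplicative noise
  was rejected to keep the AUC oracles linear. The default study noise is
  sd = 0.02 OD.
* **Host-range matrices**: per-genus blocks share a susceptible strain
  group; inside it phages lyse with `p_within` (default 0.7), elsewhere
  `p_between` (0.05); a fraction of non-lysed DPA cells (0.15) is scored
  reduced growth. With a `planted_set`, each planted phage receives a
  private strain group sized so that any k-set omitting a planted member
  covers strictly fewer strains — the planted set is the provably unique
  optimum by construction, no post-verification needed.
* **Antibiograms**: per-class Bernoulli resistance states with zones drawn
  uniformly inside the R or S band, so MRGN class fractions follow binomial
  arithmetic.

Determinism: one global seed fans out to per-well substreams by SHA-256
hashing of (strain, phage, MOI, replicate), so adding wells never perturbs
existing ones, and identical seeds give bitwise-identical outputs.

What the generator does **not** emulate: lag-phase variability, plate edge
effects, condensation artefacts, OD non-linearity at high density,
phage–phage interference in co-infections, and correlations between
antibiotic resistance and phage susceptibility. Passing recovery tests
therefore demonstrates the correctness of the statistics on curves shaped
like real ones, not robustness to every instrument artefact.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data at
desk scale: plates up to 10 phages × 40 strains (≈ 440 wells × 97 time
points), 200 random cocktail instances with ≤ 12 phages for the brute-force
cross-check, 141-strain antibiogram panels, and 20-seed noise ensembles for
vp recovery — sizes chosen to mirror a realistic single-study screen while
keeping a full run in well under a minute. Floating-point conventions:
closed-form comparisons are asserted to 1e−9; vp recovery to 1e−6 without
noise and 0.05 in the mean with noise; group fractions sum to 1 within one
ulp. Degenerate inputs (zero-area controls, empty matrices, single-MOI
ladders, inverted breakpoints, k exceeding the candidate pool) raise typed
errors rather than producing numbers.

## Known limitations

* The stationary-onset rule is one reading of an ambiguous protocol phrase;
  onset-sensitive quantities (vi, vp) can shift under alternative rules,
  which is why the rule is a single replaceable function.
* vi clamping discards information about regrowth beyond the control.
* Concordance is a raw fraction; no chance-corrected agreement statistic
  (e.g. Cohen's κ) is computed.
* MIC-based interpretation, ECOFFs and resistance-mechanism inference are
  out of scope; so are phage–phage synergy and receptor-overlap constraints
  in cocktail design.
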