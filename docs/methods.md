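# Methods

## Data model

A census is long-format: one row per individual × year with plot id,
individual id, calendar year, sex code and optional covariates (DBH in cm,
relative PPFD in the leafless and leafy seasons as fractions of open-site
flux).  Valid sex codes are the six expressed categories `F, M, H, HF, HM,
HFM`, the pooled hermaphrodite code `HALL` (for censuses recorded directly
on the 3-state space, e.g. pooled-mode synthetic data), and the unexpressed
codes `NF` (non-flowering) and `NA` (not observed).  `(individual, year)`
keys are unique; rPPFD values must lie in [0, 1].  Internally all matrices
are row-stochastic with rows = origin state; the transposed layout used in
printed transition tables (columns = previous year) is supported at I/O only
(`orientation="paper"`).

## Transition counting

A pair of observations contributes one transition iff the years are
consecutive calendar years and both states are expressed.  `NF`/`NA` break
the pair they touch but not later pairs, and a missing calendar year
likewise yields no transition.  Pooling (`H, HF, HM, HFM → HALL`) is applied
to states before counting; this commutes with aggregating the unpooled
matrix (property-tested).  Probabilities are the row-normalized counts; a
row with no observed origin events is flagged undefined (NaN), not an error.
No smoothing or pseudocounts are applied anywhere.

## Stationary distribution and bootstrap

The stationary distribution solves `(Pᵀ − I)π = 0` with `Σπ = 1`, by
replacing one equation of the singular system with the normalization
constraint and solving densely.  The solve is accepted only if
`max|πP − π| ≤ 1e-10`; irreducibility is checked beforehand on the
positive-support graph (strongly connected components), and reducible or
undefined chains raise an error naming the states outside the closed class.
The test suite cross-validates the solver against an independent power
iteration oracle on random 3×3 and 6×6 chains at 1e-8.

Sampling uncertainty: the observed `n` transition events are treated as an
exchangeable multiset and resampled by a single multinomial per replicate
(`scheme="pooled"`, default, 5000 replicates); `scheme="row-stratified"`
instead resamples each origin row at its observed total.  Each replicate is
row-normalized and its stationary vector computed; replicates with an empty
row or a reducible support graph have no stationary distribution and are
rejected and redrawn (cap: 1000 consecutive rejections, then an error; the
redraw count is reported in the result metadata).  Intervals are equal-tail
percentile intervals; significance against the uniform null (1/3 per pooled
state by default) is interval exclusion — no p-value is computed, by design.
BCa or basic intervals were considered and not adopted; percentile intervals
are the transparent default for a plug-in functional like π.

**Known limitation — interval width.**  Event-level resampling treats all
transitions as independent.  In real censuses the events are clustered
within individuals, and bidirectional reversals (`A→B→A`) make within-
individual transitions negatively correlated, which event-level resampling
cannot see; its intervals are therefore conservative (too wide) for such
populations.  Concretely, on the shipped 937-event tally the male state's
95% upper bound lands just above 1/3 (≈0.344), so only the female call
(interval entirely above 1/3) is significant under this scheme; a
sequence-level bootstrap of the underlying individuals could tighten the
male interval, but requires the raw multi-year trajectories, which the
fixtures deliberately do not encode.  The bootstrap means are insensitive
to the scheme (both schemes agree within 0.002 here).

## Pattern taxonomy

The expressed-state sequence of an individual (non-flowering years skipped
by default) is collapsed over consecutive repeats and relabelled `A, B, C…`
in order of first appearance: `[F, F, M, F]` → `A→B→A`.  `n_changes` is the
number of arrows; direction is *constant* (no change), *bidirectional* (some
letter reappears after a different letter intervened — equivalently, any
repeated letter in the collapsed pattern), else *unidirectional*.  With
`collapse_gaps=False`, gaps instead split the trajectory into segments
joined by `|`; only within-segment steps count as changes, and cross-gap
differences count neither as changes nor as reappearances.  The default is
the right choice for yearly censuses where five-symbol patterns require five
uninterrupted flowering years; the strict mode is exposed for sensitivity
analysis.  Pattern classification is invariant to permuting the concrete
state identities (property-tested).  Change *events* (for cross-tabulation
against the transition matrix) always use the strict consecutive-year rule,
so aggregated events equal the off-diagonal transition counts on the same
data.

## Tests and models of change

* **G-test**: `G = 2ΣO·ln(O/E)` over cells with `O > 0`, `df = (R−1)(C−1)`,
  upper-tail χ² p-value; no continuity or Williams correction.  Zero margins
  are an error (the year-comparison pipeline drops categories absent from
  both compared years first).  For the first-vs-last-year sex-ratio
  comparison the six expressed categories are used (2 × 6 table, df = 5).
* **Kruskal–Wallis**: tie-corrected rank statistic with χ²(k−1) reference
  (delegated to `scipy.stats.kruskal`); all-identical data return H = 0 with
  a warning.  Post-hoc pairwise comparisons are out of scope.
* **Mixed logistic model**: response is whether an individual's (pooled) sex
  changed between consecutive expressed years; focal-pattern models restrict
  to the at-risk subset (origin state matches) and mark the focal change.
  Covariates — DBH (cm), rPPFD-winter, rPPFD-summer, yearly absolute DBH
  growth (mm) — are standardized to mean 0, SD 1 (constants stored with the
  data); rows lacking any covariate or the previous-year DBH are dropped,
  which excludes the first census year.  The marginal likelihood integrates
  a single Gaussian random intercept per plot by *adaptive* Gauss–Hermite
  quadrature (15 nodes by default): per plot, a Newton search finds the
  conditional mode of the integrand and the Hermite nodes are recentred and
  rescaled by its curvature.  Optimization is BFGS on (β, log σ), with a
  Nelder–Mead polish on the rare non-converged path; standard errors come
  from the numerical observed information.  With σ² fixed at 0 the fit
  reproduces plain logistic regression to ~1e-6 (tested against
  `statsmodels.Logit`); the quadrature matches an adaptive QUADPACK
  integration oracle to <1e-4 log-likelihood and a `lme4::glmer(nAGQ=15)`
  fit to ~1e-3 on all parameters.  AIC = −2·logLik + 2·(#β + 1 for σ when
  free); backward selection repeatedly drops the term whose removal lowers
  AIC most (ties: the term latest in the declared order), stops when no
  removal lowers AIC, and reports the full trace.  Non-converged candidate
  fits are excluded with a warning; coefficients carry no p-values.

## Synthetic censuses

Defaults are the study conditions of a five-year, four-plot shrub census:
74/81/102/52 individuals per plot, years 2010–2014, initial state
distribution at the observed mean category proportions, non-flowering
probability 0.06 per individual-year (the gap between the ~1000 yearly
observations and the 937 expressed transition events), plot random-intercept
SD 0.5, and the pooled field transition matrix as the default chain.
Covariate generators: DBH ~ lognormal(0.9, 0.5) cm (a shrub understory size
distribution, median ≈ 2.5 cm), rPPFD-winter ~ Beta(2, 5) (leafless canopy,
mean 0.29), rPPFD-summer ~ Beta(1.5, 8) (leafy canopy, mean 0.16), yearly
growth ~ Gamma(1.5, 1.0) mm.  DBH and light are drawn once per individual
(near-static over five years); growth is redrawn yearly and accumulates onto
DBH.  In covariate mode the change probability is
`logit⁻¹(β₀ + β·z + u_plot)` with default β echoing the selected occurrence
model (winter light 0.34, summer light 0.03, growth 0.16, size 0) and
β₀ = −1.8 matching the observed ~14% yearly change rate; destinations on
change follow the origin's conditional off-diagonal distribution.
Non-flowering years mask the latent state without advancing the chain.
Everything is driven by one `numpy` generator seeded from the config, so a
config determines its census bit-for-bit; output files embed the config
hash.

What the generator does *not* emulate: mortality, recruitment, spatial or
climate structure, covariate-dependent non-flowering, and within-individual
correlation beyond the first-order chain.  Passing recovery tests on this
generator therefore shows the estimators are correct under the model's own
assumptions, not that real censuses satisfy them.

The two fixture builders are exact reconstructions of printed summaries,
not simulations: `table2_pairs.csv` encodes each of the 937 tallied
transition events as an independent two-year pseudo-individual (the tally's
H-origin column prints a total of 57 but its cells sum to 58; the cells are
taken as authoritative), and `table1_trajectories.csv` realizes the nine
published pattern counts as 309 five-year trajectories whose concrete states
use only transitions actually observed in the tally.  The two fixtures are
intentionally independent and not individual-level consistent with each
other.

## Problem sizes and numerical choices

Default bootstrap size is 5000 replicates (seconds at 3 states).  The test
suite exercises recovery at ~15k–100k simulated transition pairs, CI
coverage over 200 resimulated tallies at the field sample size, mixed-model
recovery over 100 replicates of ~4000 individual-years in 4 plots, and test
calibration over 2000 null replicates — chosen so the full suite runs in a
few minutes on one core.  Probabilities are never rounded internally;
4-decimal figures are display-only.  Writers emit fixed column orders and
`%.6f` floats so all outputs are byte-reproducible.
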