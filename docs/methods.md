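# Methods

This note records the models implemented, the defaults chosen where the
method leaves a choice open, and what the synthetic data do and do not
demonstrate.

## Data screening and aggregation

Acute endpoints are LC₅₀ or EC₅₀ in mg/L; concentrations are converted to
mg/L once at ingestion. Conversions between ng/L, µg/L, mg/L and g/L are
computed in exact rational arithmetic and rounded once to the nearest
double, so each conversion is correctly rounded; a round trip returns the
input to within one ulp (bit-exact identity is impossible for decimal
factors in binary floating point, and tests assert the 1-ulp bound).

Per (chemical, species), records at the class-preferred exposure duration
are kept: 48 h for invertebrates, 96 h for fish, algae and others. When no
record sits at the preferred duration, the nearest duration is used, ties
resolving to the shorter exposure — the preference durations are standard;
the nearest/shorter fallback is this package's rule. Replicate values per
(species, endpoint) collapse to their geometric mean, computed in
natural-log space (base-independent). Species names match exactly after
case-folding and whitespace normalization; no taxonomic fuzzy matching is
attempted, so joins are deterministic.

## QSAR stage

Stepwise multiple linear regression of log₁₀ toxicity on descriptors:
forward selection adds the candidate with the smallest partial-F p-value
when ≤ p_enter, then backward elimination drops any included term with
p ≥ p_remove, iterating to a fixed point. Defaults p_enter = 0.05,
p_remove = 0.10 are the classic SPSS stepwise defaults. Every descriptor
competes both raw and log₁₀-transformed (when strictly positive) but can
hold at most one term. Ties on p-value resolve by larger |t| then
lexicographic symbol, making the selection invariant to candidate order.
Forward selection stops early once the model fits to machine precision
(≤ 10⁻¹² of TSS), because p-values computed on a zero residual are
numerical noise.

Validation: r² is the squared Pearson correlation of fitted vs observed
(distinct from the regression R²); Q² = 1 − PRESS/TSS with PRESS the sum of
squared leave-one-out prediction errors, the term set held fixed and
coefficients re-estimated per fold. For OLS the LOO residual equals
e_i/(1 − h_ii), so the hat matrix gives the exact loop result; tests verify
this against a literal row-deletion loop. The conventional predictive-
ability screen is r² > 0.6 and Q² > 0.5.

The four shipped per-species equations are evaluated literally as printed —
including the log-transformed terms and the raw (untransformed) K_ow where
printed — with no rescaling of descriptor inputs. Their original descriptor
tables were never published machine-readably, so the per-chemical toxicity
predictions printed alongside them are embedded for reference only and are
not reproducible from the equations; tests therefore check the evaluator
against independent term-by-term arithmetic, not against those printed
predictions. Published models carry no training min–max box; for models
fitted here, predictions outside the per-descriptor training range are
flagged out-of-domain but still computed.

## ICE stage

An ICE model is OLS of log₁₀(predicted species toxicity) on
log₁₀(surrogate species toxicity), with the training surrogate min–max as
applicability domain. Model parameters may also be supplied as a CSV (the
large published ICE batteries print no equations, so they are user inputs).
Before use, models pass a quality gate (R² ≥ 0.6, p < 0.05, n ≥ 3) that can
be relaxed. The species pool for the SSD is the union of measured values,
QSAR predictions and ICE extrapolations with per-species precedence
measured > QSAR > ICE, so observations always dominate extrapolations.
Several ICE routes to one predicted species combine by geometric mean,
mirroring the replicate-aggregation rule. By default each model consumes the
pooled value of its own surrogate species; an explicit predicted→surrogate
map can override this. Out-of-domain extrapolations are excluded unless
requested.

## SSD stage

μ is the mean and σ the maximum-likelihood (divide-by-n) standard deviation
of the natural-log species values; the unbiased (n−1) variant is available
behind a flag and yields a slightly larger σ, hence a lower HC₅. The
fraction-affected curve is the log-normal CDF; HC₅ = exp(μ + σ·z₀.₀₅) is its
exact inverse at 5 % (verified to 10⁻¹⁰), and PNEC = HC₅/AF with AF = 5 by
default. HC₅ is a point estimate, matching single-value reporting
conventions; a parametric-bootstrap percentile CI is available with an
explicit seed. Fits below 6 species are refused; fits below 15 species
succeed with a warning, reflecting the usual minimum-dataset guidance of at
least 15 species across three trophic levels.

Goodness of fit tests the ln-values against a normal with estimated
parameters. The Anderson–Darling and Cramér–von Mises statistics carry the
Stephens small-sample modifications and are compared with the
estimated-parameter critical values (at α = 0.05: A* = 0.752, W* = 0.126;
α ∈ {0.10, 0.05, 0.025, 0.01} are tabulated); Kolmogorov–Smirnov uses the
Lilliefors test and decides via its p-value at any α. Inside the GOF
computation the ln-values are standardized with the sample mean and n−1
standard deviation — the estimator pair those critical values are
calibrated for — rather than the fit's MLE σ, which would mildly inflate
the statistics at small n. Monte Carlo checks put each test's null
rejection rate near 5.5 % at n = 100, and the probability that a null
sample passes all three tests jointly near 92 %. Both the statistic and the
pass/fail decision are reported so either can be audited.

## Risk stage

RQ = MEC/PNEC with MEC in ng/L and PNEC in mg/L, i.e. a fixed 10⁶ unit
bridge. Grades: high (RQ ≥ 1), medium (1 > RQ ≥ 0.1), low (0.1 > RQ ≥ 0.01),
none (RQ < 0.01); boundaries belong to the higher grade. Per chemical the
report carries the per-site range and the arithmetic mean of per-site RQs
(a geometric-mean option exists), scaled by 10⁶ and rounded to 3
significant figures; per site, the summed MEC. Non-detects enter at zero by
default, with a substitution value (e.g. LOD/2) available. Report output is
rounded to 3 significant figures; raw full-precision values are emitted
alongside.

## Synthetic data

The generators are pure functions of (config, seed); each draws from its
own named substream so adding a generator never perturbs another's output.

* **QSAR**: 13 descriptors for 50 chemicals (defaults) of a homologous
  fluorinated series: a latent chain length (uniform 2–15) drives the
  size-related descriptors (MW, TE, EE, E_CCR, COSMO area/volume, heat of
  formation, K_ow) with idiosyncratic Gaussian noise, so they are strongly
  mutually collinear — as AM1 descriptors of a homologous series are —
  while orbital/gradient descriptors are essentially size-independent.
  log₁₀ toxicity = 2.0 − 0.5·K_ow + 0.8·E_LUMO + N(0, 0.1): toxicity
  increases with lipophilicity and decreases with E_LUMO, matching the
  signs of the shipped equations, with the 0.1 log-unit noise used by the
  recovery analyses.
* **ICE**: surrogate log₁₀ values uniform on [−1, 3] (0.1–1000 mg/L);
  predicted = 0.5 + 0.8·log₁₀(surrogate) + N(0, 0.05), n = 100.
* **SSD**: species values from LogNormal(μ = 4.0, σ = 1.5) on the ln-mg/L
  scale — a median near 55 mg/L with the multi-decade spread typical of
  acute SSDs — with 17 species by default (a 4-QSAR + 13-ICE sized pool).

What passing tests show: the estimators recover their generating parameters
at the stated noise levels and the derivation chain is internally exact.
What they do not show: real descriptor–toxicity relations are not linear
with Gaussian noise, real interspecies correlations are messier than one
log-log line, and real SSD pools mix endpoints, qualities and taxa; the
synthetic results bound estimation error, not biological validity.

Problem sizes in the recovery analyses (50–100 replicates; pools of 10–500
species; 200-chemical regressions) were chosen so each analysis completes in
seconds while keeping Monte Carlo error well below the tolerances examined.

## Known limitations and observed behaviour

* Exact-support recovery of stepwise selection is bounded by spurious
  entries: with entry at p ≤ 0.05 and k effectively independent null
  candidates the expected exact-recovery rate is ≈ 0.95^k. At the default
  13-descriptor generator it measures ~68 % over 100 replicates (both true
  descriptors are recovered in 100 %; failures are single extra terms).
  A stricter p_enter raises exact recovery at the cost of power; the
  default stays at the conventional 0.05.
* A battery of three GOF tests at α = 0.05 passes jointly on null data
  ~92 % of the time; short seed sequences will fluctuate around that value.
* Report values rounded to 3 significant figures can disagree in the last
  digit with numbers derived from already-rounded inputs (e.g. a PNEC
  computed from a 3-figure HC₅).
* Chronic PNECs, acute-to-chronic ratios, non-log-normal SSD families,
  model averaging and probabilistic (joint exposure-effect) risk are out of
  scope.
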