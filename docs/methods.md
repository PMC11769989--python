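# Methods

## Rhythm model and detection

Expression of each gene is modelled as a fixed-period (24 h) sinusoid
on the log₂ scale, `y = M + A·cos(2π(t − φ)/24) + ε`, fitted per gene by
OLS on the harmonic linearization. All genes in a group share the
design matrix, so the whole gene × sample matrix is fitted in one
linear solve. Derived quantities:

* **amplitude** `A = √(β_c² + β_s²)` — half peak-to-trough distance of
  the fitted curve, log₂ units;
* **acrophase / peak time** `φ = (24/2π)·atan2(β_s, β_c) mod 24` —
  hours after the group's circadian reference (lights-on/ZT0 for mouse,
  sunrise for human);
* **R²**, the **F statistic** of the harmonic pair vs the
  intercept-only model with df (2, n − 3), its p-value, and
  Benjamini–Hochberg q-values over the group's gene list.

Rhythmicity calls use unadjusted p < 0.05 (strict) by default — the
exploratory convention for brain diurnal transcriptomes, where modest
cohorts and time-of-death noise depress power; every function that
takes an alpha also accepts a stricter one (0.01 is wired into the
pipeline summary), and q-values are always emitted for FDR-based calls.
Constant input is reported as amplitude 0, F = 0, p = 1, R² = 0; a
perfect (zero-residual, non-constant) fit gets the p floor 1e-300 so p
stays in (0, 1]. A rank-deficient design (fewer than 3 distinct times)
is a hard error. Period scans, multi-harmonic fits and covariate
adjustment are out of scope; optional covariates can be regressed out
upstream if needed.

## Preprocessing

The detection filter keeps genes with log₂CPM > 1 in more than half of
the samples of at least one species × sex × region group and drops
Y-flagged genes; grouping is configurable. Both the CPM transform and
the post-normalization log use pseudocount 1, declared so tests are
exact; with that convention log₂CPM > 1 means CPM > 1. Size factors are
the median-of-ratios estimator over reference genes with positive
counts in every sample (geometric means computed over those genes
only). Each species is filtered and normalized within its own cohort.
Note the estimator's actual invariance: scaling one sample by c scales
its factor *relative to the others* by c; absolute factors move
together because the scaled sample shifts every geometric mean.

## Cross-species phase comparison

Per-gene differences are **raw** acrophase differences
`Δ = φ_human − φ_mouse` in (−24, 24), not wrapped into (−12, 12]: shifts
near the half period are exactly the regime of interest (an anti-phase
nocturnal/diurnal pair), and a circular wrap would fold −12.4 into
+11.6. A `wrapped_difference` variant exists for callers who want
circular semantics. Raw differences are only meaningful when the true
shift stays away from the ±12 fold — see the generator notes below.

Effect variances are delta-method acrophase variances,
`Var(φ) = (24/2π)²·[β_s, −β_c]Σ[β_s, −β_c]ᵀ/A⁴` with Σ the 2×2
coefficient covariance; they are validated against a parametric
bootstrap in the test suite. Within-sex pooling is DerSimonian–Laird
random effects; the sex contrast is a mixed-effects meta-regression
with sex as moderator (method-of-moments τ², GLS coefficients, Wald z),
numerically equivalent to `rma(yi, vi, mods=~sex, method="DL")` in
metafor, which the tests use as an independent oracle. If every effect
variance is zero while effects disagree, pooling falls back to equal
weights with a warning.

Peak-time distributions are summarized as percentage histograms over
left-closed two-hour bins and as the fraction of rhythmic peaks inside
the species' behaviorally active window: mouse [12, 24) (dark phase
under 12:12 LD), human [0, 12) after sunrise. The human window is a
declared 12-h convention; real photoperiods vary.

## Overlap and RRHO

Thresholded overlap reports the intersection of two rhythmic sets
within their shared expressed universe, both directional percentages
(|A∩B|/|A| and |A∩B|/|B|), and the upper hypergeometric tail as an
enrichment p. The RRHO map ranks the shared universe by −log₁₀(p) on
each axis (ties broken by gene id for reproducibility), then scores
every pair of rank cutoffs on a grid of `steps` cutoffs (stride
⌈N/steps⌉, default 100 steps) with −log₁₀ of the hypergeometric upper
tail. Rhythmicity p-values are unsigned, so only the single
over-enrichment quadrant is computed (no four-quadrant signed variant).
Cell-wise significance is annotated with Benjamini–Yekutieli q-values,
which remain valid under the strong positive dependence between nested
cells. Tails are evaluated through scipy's log-space survival function
and verified against exact enumeration for all universes up to N = 60.

## Enrichment

Over-representation is the one-sided hypergeometric (Fisher right-tail)
test of a query against a GMT pathway restricted to a declared
background (all filter-passing transcripts of that group). Pathways
with fewer than 15 background members are excluded; the size rule is
applied after background restriction. The cross-group rule takes each
group's top 10 pathways (ties broken by name) and marks them shared in
the opposing group when its −log₁₀ p exceeds 1.3 (p < 0.05), "not
tested" when absent. This is a transparent stand-in for
knowledge-base-driven pathway scoring: selection rules are preserved,
but no equivalence to any proprietary scorer is claimed.

## Synthetic data generator

The generator emulates the two designs the pipeline targets:

* **mouse** — 6 zeitgeber timepoints (ZT 2, 6, 10, 14, 18, 22), 5
  animals/sex/timepoint, one region (mPFC);
* **human** — two subregions (DLPFC: 42/sex, ACC: 38/sex) with
  continuous time of death, uniform on [0, 24) by default since the
  real distribution is unknowable.

Counts are negative binomial with mean
`μ = L_s·2^(m + A·cos(2π(t−φ)/24)) / Σ_g 2^(...)` and a single
dispersion α (Var = μ + αμ²). Defaults, chosen as realistic bulk
RNA-seq values and fixed once: dispersion 0.1, mesor log₂ ~ U(3, 8),
amplitude log₂ ~ U(0.5, 2), library size ~ U(4e6, 6e6), 12% of genes
rhythmic. A conserved clock block (PER1–3, DBP, CIART, NR1D1, CHRM4,
KANSL3; amplitude 1.5) is rhythmic in every group, with human peaks at
the mouse peak plus a per-sex species offset (−12 h male, −9 h female).
Mouse clock-block peaks are drawn from U(14, 18): clock-output genes
peak in the late light/early dark phase, and this also keeps the true
raw differences away from the ±12 fold, which is a precondition for
unwrapped pooling (see above). Low-expressed genes (5%) are pinned to a
target CPM of 0.1–0.5 so they fail the expression filter at any
simulated transcriptome size, and 0.5% of genes carry a Y-chromosome
flag. Rhythmic identity is drawn as one pool of exactly
round(n·frac_rhythmic) genes; beyond the clock block, 25% of the pool
is rhythmic in both species and the rest is split evenly into
species-exclusive sets, giving partial, asymmetric cross-species
overlap.

What the generator does **not** emulate: batch effects, RNA-integrity
or postmortem-interval covariates, gene–gene correlation, cell-type
composition, varying photoperiod, or realistic time-of-death
distributions. Passing recovery tests therefore demonstrates
correctness of the estimators under the declared sampling model, not
robustness to those real-data complications.

One interaction worth knowing: because rhythmic genes oscillate the
per-sample count total, raw log-CPM profiles of *every* gene carry a
shared time-dependent composition distortion (~1 h of apparent phase
at 50% rhythmic genes). Median-of-ratios normalization removes it;
fits should always run on normalized values, as the pipeline does.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the designs: the
type-I calibration fits 10,000 null genes on the full 60-sample mouse
design; phase recovery/power uses 60-gene studies (clock block + filler)
over 100–200 seeded replicates at dispersion 0.05 ("low noise") and 0.3
("moderate noise"); the cross-species preset uses 2,000 genes with a
bimodal (peaks 4 and 16) mouse phase distribution and a unimodal
(mode 6, SD 2) human one. RRHO oracle checks run at N = 50 with a
full-resolution grid; hypergeometric tails are enumerated exhaustively
to N = 60. Seeds are fixed in tests and derived from the single
`--seed` argument in the acceptance script. p-values are clamped to
[1e-300, 1]; RRHO tail probabilities to ≥1e-320 before logs; amplitude
below 1e-10 is treated as zero when an acrophase SE is requested.

## Known limitations

* Gene identifiers are opaque strings; cross-species matching (e.g.
  ortholog mapping to upper-cased symbols) is the caller's
  responsibility, as is any ID translation.
* Raw phase differences assume the true shift is bounded away from
  ±12 h; use the wrapped variant otherwise and interpret pooling with
  care.
* The F-test's calibration on log-transformed counts relies on
  approximate normality; it is verified in simulation at moderate
  expression but can drift for very low counts.
* The enrichment stand-in shares only selection rules, not scores,
  with knowledge-base pathway tools, so named-pathway results are not
  comparable across tools.
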