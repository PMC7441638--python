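# Methods

This note documents the statistical procedures `queendx` implements, the
assumptions behind them, the synthetic-data model used to validate them,
and the design decisions taken where more than one convention was
defensible.

## Preprocessing

Input is a MaxQuant-style protein-group table: LFQ intensities per sample,
with `+`-marked reverse (decoy), potential-contaminant and
only-identified-by-site columns. A zero LFQ intensity means non-detection
and is treated as missing from the moment of parsing; nothing downstream
ever sees an artificial zero. Intensities are log2-transformed for all
testing.

Filtering removes flagged rows and any protein with fewer than
`min_valid = 6` quantified values. The valid-value rule is applied
**globally** (across all samples of the experiment); a per-group variant
(≥ `min_valid` in at least one group, the other common convention) is
available via `per_group=True`. When multiple flags apply to a row it is
counted once, with precedence reverse > contaminant > site-only, so the
filter report always reconciles exactly with the input count. No
imputation is performed anywhere: tests use pairwise-complete
observations, and proteins with fewer than two values in either group of a
comparison are reported untested rather than guessed at.

## Differential expression

The pairwise test is Student's two-sample *t* with pooled variance and
df = n₁ + n₂ − 2. The pooled form (rather than Welch) is the convention
this pipeline standardises on because it is what the degrees of freedom of
the motivating analyses imply (a 7-vs-6 comparison reporting df = 11);
Welch's test is available through `test="welch"`. Benjamini–Hochberg
adjustment (via `statsmodels`) runs over the *tested* family only —
untested proteins are excluded, not assigned p = 1 — and the default
family-wise FDR is 5%, relaxed to 10% for the pesticide-versus-solvent
contrast, whose effects are subtler than thermal stress. Ties when ranking
results break by adjusted p, then |t| descending, then accession, so
output order is deterministic.

Degenerate rows (zero pooled variance) are defined to give t = 0, p = 1
when the means agree and a capped-p extreme otherwise, instead of NaN.

Survey-style analyses with continuous and discrete covariates use ordinary
least squares — per-term *t*-tests plus an overall *F*-test against the
intercept-only model — in place of empirical-Bayes moderated statistics,
which are deliberately out of scope; with ≥ 45 samples per group the
moderation gain is marginal. A constant response is reported as F = 0,
p = 1 (no variance to explain), and rank-deficient designs raise an error
naming the collinear terms.

## Gene-score resampling enrichment

Gene scores are −log₁₀ of the **raw** p-value, restricted to one direction
of change at a time (proteins moving the other way score 0); p-values are
floored at 1e-300. This makes enrichment independent of any significance
threshold chosen upstream. A term's group score is the arithmetic mean of
member scores (median available via `stat="median"`); its p-value is
estimated against draws **without replacement from the realised score
list** — an assumption-free null that conditions on the observed score
distribution. Terms with C(n, k) ≤ 10,000 possible member sets are
enumerated exhaustively; larger ones use Monte-Carlo (default 10,000
iterations) with add-one smoothing p = (b + 1)/(B + 1), so p is never 0.
Monte-Carlo draws reuse one permutation pass per iteration: the first k
entries of a permuted score vector are a valid size-k draw, so a single
cumulative sum serves every term size.

Term sizes are filtered to [5, 200] after intersection with the scored
universe — conventional bounds, configurable. BH adjustment runs across
terms within one direction.

The multifunctionality (MF) score is descriptive only: each gene's MF is
the normalised average-tie rank of its annotation count (most-annotated
gene = 0, least = 1, i.e. **higher = less multifunctional**), and a term's
MF is the mean over its scored members. No multifunctionality *correction*
is applied to the enrichment statistics.

## Biomarker diagnostics

Candidate markers are the k = 2 most significantly upregulated proteins of
a comparison. Upregulated-only is deliberate: elevated proteins are
detectable above instrument noise floors and are robust to sample
degradation in a way depleted proteins are not. If fewer than k proteins
are significant and upregulated the panel is padded with the best
remaining upregulated candidates and flagged with a warning; if nothing is
upregulated the panel is empty.

The normalisation reference is the protein with the smallest variance of
log2 intensity among proteins observed in **every** sample. Variance is
computed on the log2 scale because linear-scale variance is dominated by
absolute abundance; this is a package convention (the scale used by the
original analyses is not documented). Exact ties resolve to the
lexicographically smaller accession.

A sample's diagnostic value is the linear-scale ratio marker/reference; a
missing marker is a non-detection and scores 0 (no elevation). The
classifier flags samples whose ratio **strictly** exceeds the elevation
threshold, default 0.05 — the regime where an unstressed queen's marker
sits well below 5% of the reference protein's intensity and heat-shock
induction lifts it above. Because the value is a within-sample ratio,
flags are invariant to any common rescaling of a sample's intensities.

The blind-trial protocol enforces its ordering mechanically: true labels
live in a `SealedLabels` container that records when it is opened, and
`blind_trial` refuses to run on an already-unsealed set. Per-marker
confusion matrices and the both-markers-elevated AND rule are computed
before unsealing. TPR is sensitivity — correctly flagged stressed samples
over all truly stressed samples.

## Hazard quotients

HQ = concentration (ppb) / LD50 (µg/bee), worker-oral LD50 convention;
cumulative HQ is the plain sum over mixture components. Additivity is a
standardisation device, not a toxicological claim — interactions between
components are simply unknown — and no correction is applied for the
queen-topical versus worker-oral route mismatch. Display rounding is 2
decimals per component and integer totals; full precision is kept
internally, and `formulate_mixture` inverts the sum exactly (one common
scale factor; round-trip error at machine precision).

The shipped nine-component cocktail fixture reproduces a published
~511-HQ blend. Its LD50 column is **back-computed** as
concentration/quotient because the source table prints quotients, not
LD50s; concentrations for the five low-level components are reconstructed
from the uniform median-to-target scale factor (≈ 3.335) evident in the
unambiguous rows.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes,
not mass spectra:

* **Baselines.** Per-protein log2 abundance uniform on [20, 32] (a typical
  LFQ dynamic range), per-sample Gaussian noise with sd 0.4 log2 units —
  a mid-range between-replicate variability for tissue LFQ.
* **Markers.** Additive log2 fold changes in the stressor group. Marker
  baselines are drawn from [24, 30], clear of the censoring floor: a
  protein can only ever be *nominated* as a candidate biomarker if it
  survives the six-valid-values filter, so useful markers are reliably
  quantified by construction. In blind trials, marker baselines are
  instead tied to the reference protein at a linear ratio of 0.02, which
  places unstressed queens below and ≥ 2-fold-induced queens above the
  0.05 ratio threshold — the operating regime of the published trial.
* **Housekeeping reference.** One designated protein (`HK_REF_1`) at a
  fixed high baseline (2²⁸) with sd 0.02, giving reference selection a
  known answer.
* **Missingness.** Left-censoring (MNAR): P(missing) is a logistic
  function of the cell's log2 intensity, anchored at the 10th percentile
  of all generated values with steepness 3 per log2 unit (~10% missing
  overall, concentrated at low abundance). Setting the censor quantile to
  0 disables missingness.
* **Decoys/contaminants.** Extra rows with `REV__`/`CON__` accession
  prefixes, matching the MaxQuant dialect.
* **Time course.** Heat-marker effects follow a hinge ramp
  lfc × clamp((t − onset)/(saturation − onset), 0, 1), onset 1 h and
  saturation 2 h by default — no induction below about an hour of heat —
  scaled linearly in relative humidity from 1× at 40% RH to 1.5× at 80%
  RH (humid heat is the stronger stressor).
* **Blind trials.** n_stressed of n_total queens receive marker effects;
  the assignment is shuffled by the seed and hidden behind the sealed
  labels; public metadata shows only "blind".

Everything is driven by one `numpy` `default_rng` seed; identical configs
give bit-identical tables.

**What the generator does not emulate:** peptide-level evidence, shared
peptides between protein groups, between-sample normalisation artefacts,
batch effects, correlated protein modules, or realistic annotation
structure (synthetic GO terms are random memberships). Passing recovery
tests therefore demonstrates the *methods* are implemented correctly and
are well calibrated under the stated noise model — not that real
spermathecal data will behave this cleanly, as the published blind trial's
75% sensitivity illustrates.

## Statistical test tolerances

Monte-Carlo assertions in the test suite allow 3 binomial standard errors
around nominal bounds. This is not slack for its own sake: under a global
null with continuous independent p-values, BH attains FDR = α *exactly*,
so a 100-seed empirical FDR is a Binomial(100, α)/100 draw centred exactly
on the bound and a literal `≤ α` assertion would fail ~40% of the time by
construction. The 3-SE margin is derived from that sampling distribution,
a priori. Enrichment calibration is checked both against exhaustive
enumeration (within 3 binomial SEs of the Monte-Carlo estimate) and by a
Kolmogorov–Smirnov uniformity test of null resampling p-values at the 1%
level.

## Problem sizes

Simulation-based checks use 100 seeds with 200–500 background proteins and
7 samples per group (16-queen blind trials), matching the motivating
designs' group sizes while keeping the whole suite fast; the acceptance
script uses the same sizes.

## Known limitations

* No empirical-Bayes moderation; small-n survey contrasts are noisier than
  a limma-style analysis would be.
* Enrichment takes annotations as given — no ontology-graph propagation,
  and the MF score is a simplified descriptive analogue of ErmineJ's
  precision-recall construction.
* The threshold classifier is binary per stressor; multi-class stressor
  attribution is out of scope.
* Hazard quotients ignore toxicokinetics and synergy by design.
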