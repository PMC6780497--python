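# Methods

This note documents the statistical model, the defaults and the design
choices behind `nglyco`, including what the synthetic-study generator
does and does not emulate.

## Glycosite model

SPEG-style enrichment captures glycopeptides on hydrazide resin and
releases them with PNGase F, converting the glycosylated Asn to Asp. In
the search output this appears as a deamidation (+0.984 Da) on N, so a
deamidated N is the observable proxy for an occupied N-glycosite. Two
filters separate signal from chemistry noise:

* **Sequon filter.** N-linked glycans occur at N-X-S/T with X ≠ P. The
  sequon is evaluated against the *protein* sequence, not the peptide:
  a tryptic peptide ending in ...N can have its S/T in the next peptide,
  and peptide-local validation would silently discard such true sites.
  Deamidated N outside sequons (spontaneous deamidation) are logged as
  artifacts and dropped; Q deamidation is ignored for site calling.
* **Mapping policy.** Peptides shared between proteins produce site
  records for every claimed accession that contains them, and a peptide
  occurring several times within one protein yields all occurrences,
  flagged ambiguous. No razor-protein parsimony is applied: MS evidence
  cannot resolve the assignment, so the pipeline does not pretend to.
  L and I are treated as distinct residues, matching search-engine
  output semantics.

Unique glycopeptides are keyed by (sequence, set of sites), so replicate
multiplicity and modification-order differences never inflate counts.

## FDR estimation

The search engine's own rescoring (posterior error probabilities) is not
reproducible from a generic export, so q-values are re-estimated by
plain target–decoy counting: at each score threshold s,
FDR̂(s) = #decoys(≥ s) / max(1, #targets(≥ s)), capped at 1, with the
q-value of a PSM the minimum FDR̂ over all thresholds at or below its
score. Tied scores share a threshold and decoys inherit the q of their
stratum. The convention is #decoys/#targets (concatenated-search
estimator) rather than 2D/(T+D). The default filter keeps targets at
q ≤ 0.01.

## Quantitation model

* PSMs are aggregated to (peptide, modifications, replicate) by summing
  reporter intensities — TMT reporter counts are additive.
* Intensities are log2-transformed; zeros (missing reporter ions) become
  missing values and are excluded from all log-space statistics rather
  than imputed.
* Columns (channel × replicate) are median-centred by default, the
  equal-loading assumption of TMT. `normalization="none"` disables it.
  Median centring shifts each column by a constant, so within-row
  contrasts are affected only through those constants; under strongly
  asymmetric regulation the column medians absorb part of the planted
  signal, which slightly biases null rows. The noiseless-recovery test
  therefore runs with normalization off.
* Fold change = difference of log2 means over all (channel, replicate)
  observations, i.e. the ratio of geometric means. Observations are
  treated as independent: up to 3 channels × R replicates per side. The
  four replicates of the emulated design are most plausibly repeated
  injections of one labelled pool, so this treats technical replicates
  as exchangeable observations; the run summary flags the assumption
  (`replicates_treated_as_independent`).
* Protein rollup (global aliquot) sums peptide intensities per protein
  before the log transform; proteins with no surviving peptides are
  absent, which downstream becomes the "NI" (not identified) state.

## Differential testing

Welch's two-sample t-test (unequal variances, Welch–Satterthwaite df,
two-sided p from the t distribution) on the per-column log2 values.
Conventions:

* Groups with n < 2 are *untestable* (p missing), never silently p = 1.
* Two zero-variance groups with different means give |t| = ∞, reported
  with p = 0 (documented cap); equal means give t = 0, p = 1.
* Direction uses the fold change alone, inclusive at 1.5-fold, with the
  decreased threshold the reciprocal (symmetric in log2). Comparisons
  are made in log2 space with a 1e-9 guard so that exact boundary values
  survive float round-trips.
* The signature is selected on *raw* p ≤ 0.05; Benjamini–Hochberg
  q-values are computed across testable rows and reported alongside
  (an optional switch selects on q instead).
* A label-permutation p-value (permuting the group assignment of the
  channel × replicate columns, seeded, p = (1 + #exceedances)/(B + 1))
  is available for a non-parametric reading of the test; the parametric
  Welch p is the default.

Because the per-replicate shifts in real (and simulated) TMT data are
shared by the two contrast groups within a replicate, they cancel from
the mean difference but inflate the variance estimate, making the Welch
test on generated data slightly conservative. The type-I calibration
test therefore draws i.i.d. null rows, which isolates the test's own
calibration (rejection rate 0.05 ± 0.02 at α = 0.05 over 1000 rows).

## Occupancy quadrants

A glycopeptide's fold change confounds site occupancy with protein
abundance. Each (glycopeptide, protein) pair is classified from the two
fold changes, with "changed" meaning fc ≥ t or fc ≤ 1/t (inclusive):

| quadrant | glyco | protein |
|---|---|---|
| `occupancy_strong` | changed at 2.0 | unchanged at 1.5 |
| `glyco_changed` | changed at 1.5 | unchanged at 1.5 |
| `concordant` | changed at 1.5 | changed at 1.5, same direction |
| `discordant` | changed at 1.5 | changed at 1.5, opposite direction |
| `unchanged` | otherwise | |
| `protein_NI` | — | not identified globally |

The `discordant` class is this package's addition: opposite-direction
changes fit neither "concordant dysregulation" nor "occupancy with flat
protein", and folding them into `concordant` would break the invariant
that concordant calls share a direction. They are rare and reported
separately.

Quadrant membership is defined by fold change alone (no significance
requirement), matching the fold-change-defined quadrant colouring; since
"without significant changes" is ambiguous, the summary also reports an
alternative occupancy-only count restricted to statistically significant
glycopeptides. The occupancy-only protein set = accessions with at least
one `occupancy_strong`/`glyco_changed` call and no
`concordant`/`discordant` call. Thresholds are applied to unrounded fold
changes; published tables that print 1-decimal roundings (e.g. a protein
fc of 0.7 described as 1.5-fold down, where 1/1.5 = 0.667) can disagree
with the strict bands for exactly that reason, and the tests document
the two affected cases (CTSD, ICAM1).

## Enrichment

Upper hypergeometric tail per gene set (via the survival function of the
hypergeometric distribution, exact and computed stably), BH-corrected
across tested sets. The universe defaults to the quantified
glycoproteins — conditioning on detectability — rather than a whole
annotation space; this is deliberately narrower than web enrichment
tools and is configurable. Symbols match case-insensitively after
trimming. The test suite checks the tail against exhaustive enumeration
of every draw for all universes N ≤ 12.

## Clustering

Supervised in the heatmap sense: columns are never clustered but fixed
in the design order (non-type channel block, then luminal/basal, each
channel's replicates together). Rows are z-scored (sample sd, ddof = 1;
constant rows set to 0 and flagged) for display; distances use
1 − Pearson on the raw rows (Pearson is shift/scale invariant, so the
z-scoring is purely cosmetic), average linkage. Leaf order is a
deterministic recursive traversal, smaller subtree first, ties broken by
lower node id, so results are reproducible across runs and row orders.
Rows sharing fewer than two finite columns with a partner are an error
naming the offending pair.

## Synthetic-study generator

The generator emulates the study conditions: six TMT channels carrying
T24/J82/RT112/VMCUB-1/UMUC3/SW780 on 126–131, four replicates, a glyco
aliquot and a global aliquot, search scores for targets and reversed
decoys, planted sequons and artifact deamidation.

Model and defaults:

* Proteins are concatenations of unique random tryptic units (6–20
  residues, K/R terminus, no internal K/R, P down-weighted and never
  following a cleavage site), so in-silico digestion recovers exactly
  the emitted peptides and every planted site has a known coordinate.
  The emitted PSM tables contain the fully cleaved forms; missed
  cleavage handling is exercised through `digest_tryptic` directly.
* 500 proteins, 460 carrying 1–4 glycosites each (~1200 glycopeptides),
  matching the scale of the emulated study (1299 glycopeptides on 460
  proteins).
* Effect classes per glycoprotein: concordant_up 0.10, concordant_down
  0.05, occupancy_only_up 0.10, occupancy_only_down 0.05, null 0.70 —
  roughly a quarter of glycopeptides dysregulated, as in the emulated
  data; effect size 2.0-fold.
* Reporter model per peptide: base log2 abundance ~ N(20, 1.5); per
  channel value = base + planted log2 fc (non-type channels only) +
  replicate shift ~ N(0, 0.1) shared by the six channels of a replicate
  + noise ~ N(0, 0.25); intensity = 2^value with 2% missing-at-random
  dropout. Effects are planted on the channel-group mean, which makes
  the sampling variance of the recovered log2 fold change available in
  closed form (σ·√(1/12 + 1/12) for 4 replicates) and is asserted in
  the tests.
* Scores: targets ~ N(8, 1), decoys ~ N(4, 1); decoy rows at 0.2 of the
  target rows. Artifact deamidation (planted as N-P-A, which no protein
  context can validate) at 0.05 of the true glycopeptides. An optional
  NI rate removes glycoproteins from the global aliquot to exercise the
  `protein_NI` path (default 0: the real NI frequency is unknown).

What it does **not** emulate: spectra and search-engine behaviour
(scores are drawn, not computed), ratio compression from co-isolation,
isotope-impurity cross-talk, peptide-level variation in digestion or
ionisation efficiency, missed-cleavage PSMs, shared peptides between
target proteins, and intensity-dependent missingness. Passing the
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own observation model, not that real TMT data meet
that model.

## Problem sizes used in the automated checks

The test suite and the acceptance script are sized to run comfortably on
one CPU: the sequon-oracle and recovery checks use 500–900 proteins
(~1200–2000 glycopeptides), the type-I calibration 1000 null rows, and
the exhaustive hypergeometric sweep all universes up to N = 12. These
sizes give binomial/simulation noise well inside the asserted bands.

## Known limitations

* q-value estimation assumes a reasonably populated decoy score
  distribution; with very few decoys the estimate is coarse.
* The occupancy classification is threshold-based, not a stoichiometric
  occupancy model (no ratio-of-ratios with enrichment-efficiency terms).
* Protein rollup uses summed intensities; no peptide-level outlier
  handling or shared-peptide reapportionment.
* The enrichment step is a generic ORA over user-supplied GMT sets; it
  does not bundle or reproduce any hosted annotation database.
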