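# Methods

## Windowed PS scoring

Every protein is decomposed into all length-15 windows at step 1; a
protein shorter than 15 residues is scored as a single full-length
window rather than skipped, so no mutation is silently dropped. Window
coordinates are 1-based inclusive at every interface. A scorer is a pure
function of window content returning a score in [0, 1]; purity is what
makes the delta computation local (windows that do not contain the
mutated residue are bit-identical between wild type and mutant, and the
mutant score track is the wild-type track with only the containment
windows rescored).

The reference scorer, `prone_fraction`, is the fraction of window
residues in {G, S, Q, N, Y, F, P, R}: glycine/serine spacers, the polar
Q/N pair, aromatics, proline and arginine — the residue classes that
dominate low-complexity condensate-forming sequence. It is a
deliberately simple composition statistic, not a re-implementation of
any structure- or disorder-feature-based predictor, and its scores are
not comparable to such predictors' numeric outputs. Its value is that it
is exactly analyzable: a single substitution changes any window score by
0 or ±1/15, so the delta-PS score of any mutation is bounded by 1/15 in
magnitude and is exactly antisymmetric under reversal. Those two facts
anchor the oracle tests.

The trainable scorer is a random forest (scikit-learn, 200 trees,
deterministic for a fixed seed) over 23 features per window: the 20
residue frequencies plus prone-set, charged ({D, E, K, R}) and aromatic
({F, W, Y}) fractions. Training peptides longer than the window are
split into all their windows, each inheriting the peptide label. The
window/cutoff contract is identical to the reference scorer's, so a
trained model can be dropped into every downstream stage. Models persist
through a versioned joblib payload carrying the spec and the feature
list; loading verifies both.

### Region calling

PS regions are maximal runs of consecutive windows with score ≥ 0.5208;
a run from window *i* to *j* covers residues `start_i .. start_j + 14`
(clipped to the sequence end). Equality at the cutoff counts as inside
the region — the positive class is closed. Runs separated by any
sub-cutoff window yield separate regions even when their residue spans
overlap; this is a deterministic convention chosen because it is
checkable against a trivial run-scanning oracle. A protein with at least
one region is a phase-separating protein.

## Delta-PS and classification

For a mutation at position *p* the containment windows start at
`max(1, p−14) .. min(p, L−14)`; their count is
`min(p, 15, L−14, L−p+1)` (1 when L < 15). `wt_avg` and `mut_avg` are
plain float means over exactly those windows and
`delta = mut_avg − wt_avg`. The sign convention — positive delta means
PS-promoting — is the one under which "positively affecting" mutations
have delta > +0.05.

Labels:

* `affect_label`: positive if delta > 0.05, negative if delta < −0.05,
  else neutral. The inequalities are strict, so a change of exactly 0.05
  is neutral.
* `aberrant_label`: by default judged on the containment-window averages
  (`gain` iff wt_avg < 0.5208 ≤ mut_avg, `loss` for the reverse). The
  alternative rule — whole-protein phase-separating status flipping —
  is available as `EffectConfig(aberrant_rule="protein_flip")`. The
  local rule was preferred as deterministic and locally attributable.
* `region_change`: residues covered by called regions overlapping the
  span `p−14 .. p+14`, compared between wild type and mutant
  (0→>0 created, >0→0 lost, increase extended, decrease contracted).
  By locality, the local coverage difference equals the whole-protein
  coverage difference; restricting the comparison neighbourhood only
  refines created/lost attribution when distant regions exist.
* `on_ps_region`: the mutated position lies inside a wild-type region.

Numerical note: because score means are IEEE-754 floats, |delta| can
exceed the real-arithmetic bound 1/15 by a few ulps; tests allow 1e−12
of rounding slack on that bound while holding `delta == mut_avg −
wt_avg` and antisymmetry exactly.

## Cohort aggregation

Per-cancer summaries count effect classes exactly and report two
affecting-percentage denominators (all scored mutations, and mutations
on phase-separating proteins) because cohort reports are read both ways.
Per-gene summaries carry the burden, affecting fraction and the
phase-separating flag of the gene's protein. Top-mutation ranking is by
|delta| descending with a lexicographic (accession, position, alt)
tie-break so output is stable across runs. All counts are partitions of
the input effects; rounding to two decimals happens only at
serialization. The pathogenic-fraction comparison divides pathogenic by
labelled mutations separately among positive- and negative-labelled
effects; classes with no labelled member report an undefined (None)
fraction rather than zero.

## Enrichment

For each annotation set the 2×2 table is (target ∩ set, target \ set,
background ∩ set, background \ set) with set membership intersected with
the universe first; the p-value is one-sided Fisher ("greater":
enrichment, not depletion; two-sided available), computed by
`scipy.stats.fisher_exact` and verified in tests against a closed-form
hypergeometric tail sum. Benjamini–Hochberg adjustment runs over exactly
the tested sets (those with ≥ 1 universe member). The recommended
universe is all genes with at least one scored mutation — conservative
relative to a whole-genome background — and the odds ratio reports +inf
when b·c = 0 with a·d > 0.

## Survival

Per patient: `mut_num` (count of |delta| > 0.05 mutations), `score_all`
(sum of delta over those), `percent_mut` (fraction of scored mutations
with delta strictly > 0; the cutoff is configurable because "positive"
could defensibly mean "> 0.05"). Patients with no scored mutation are
excluded and logged. Cox proportional-hazards fits use lifelines with
Efron tie handling; stage is ordinal 1–4 with missing stages dropped
listwise (logged); zero-variance covariates and non-convergence raise
rather than returning silently degenerate fits. Backward stepwise
selection drops the worst Wald p until all retained candidates are below
the threshold (default 0.05); at least one candidate is always retained
because a zero-covariate partial-likelihood fit is undefined — the final
fit is reported even if its p is above threshold. Median splits assign
median-valued subjects to the low group; Kaplan–Meier curves and the
two-group log-rank test come from lifelines.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) — reruns are
byte-identical — and every dataset ships with its planted truth, so all
recovery metrics are computable without reading generator internals.

* **Proteome**: each protein (default 200 proteins, 80–250 residues)
  carries at most one planted segment (30–60 residues, rate 0.7) whose
  residues are prone with probability 0.9 against a 0.1 background;
  outside the prone set the background is uniform over the 12 non-prone
  letters. This is the simplest composition model under which the
  default 0.5208 cutoff separates segment from background windows with
  high margin (segment windows score ≈ Binomial(15, 0.9)/15).
* **Mutations** (default 2,000): planted positive mutations substitute
  non-prone → prone (delta = +1/15 over every containment window),
  negative the reverse, neutral preserve prone status; each planted
  class is verified by actually scoring the mutation at generation
  time. The default class mix (4% positive, 6% negative, 90% neutral)
  reproduces the regime of a pan-cancer missense cohort: roughly a
  tenth of mutations PS-affecting, with suppressing mutations
  outnumbering promoting ones. Samples (default 240 across 4 cancer
  types) are uniform; cancer-type labels are strata with no
  type-specific signal unless configured.
* **Annotations** (default 50 sets, 3 planted, relative risk 5, base
  inclusion 0.1): planted sets include target-class genes at 5× the
  base rate; with relative risk 1 the generator is an exact null.
* **Clinical outcomes**: exponential event times with hazard
  `h0 · exp(β·percent_mut + 0.01·(age−60) + 0.1·sex + 0.2·(stage−2))`
  (h0 = 0.001 per day; age ~ N(62, 10²) clipped to 30–90; sex
  Bernoulli(½); stage categorical 1–4; TMB = the patient's scored
  mutation count) and independent exponential censoring calibrated to
  the requested censoring fraction (default 0.3). When run standalone
  (without a mutation table) the per-patient profile is sparse and
  polarized — 1 + Poisson(1) scored mutations, positivity probability
  Beta(0.5, 0.5) — giving percent_mut a spread (sd ≈ 0.45) under which
  a planted coefficient of 1.0 is recoverable to ±0.3 at n = 500 with
  ~30% censoring; a more concentrated percent_mut distribution would
  leave the coefficient weakly identified at that cohort size.

None of this emulates real mutational signatures, codon structure,
per-gene mutation-rate heterogeneity, linkage between mutations, or the
actual score distribution of structure-aware LLPS predictors. Passing
recovery tests on these cohorts demonstrates that the *pipeline's
arithmetic and inference are correct under a known model*, not that the
composition scorer predicts experimental phase separation.

## Problem sizes and other numerical choices

Tests and the acceptance script run at sizes chosen to make the
statistical assertions stable on one CPU in seconds-to-minutes: 500
protein/mutation pairs for oracle equivalence, 10,000 mutations for the
bound check, 200 proteins for segment recovery, 1,000 tables/replicates
for Fisher calibration, 100 planted-enrichment replicates, 20/100/20
replicates for Cox recovery, Cox null calibration and log-rank power.
The permutation-null AUC of the trainable scorer is asserted only at a
fixed seed: on strongly cluster-structured peptides the shuffled-label
AUC has wide replicate-to-replicate spread (the forest's held-out
ordering collapses to a cluster-level coin flip), so it is a sanity
check, not a calibrated null distribution.

Known limitations: only single-residue missense effects are modelled
(no indels, nonsense, splice or multi-residue haplotypes); accession and
position must already refer to the supplied sequence (no isoform
mapping); enrichment is set-membership only (no topology-aware GO
methods); survival modelling assumes proportional hazards and offers no
competing-risk or time-varying extensions.
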