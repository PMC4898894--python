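# Methods

## Pair classification model

The unit of prediction is the unordered gene pair. For a pair *(a, b)* the
default feature schema holds eight values, all symmetric in the pair by
construction:

| feature | definition | missing when |
|---|---|---|
| `go_bp_shared`, `go_mf_shared`, `go_cc_shared` | number of GO terms of the aspect annotated to both genes after propagating every annotation to all of its is_a ancestors, excluding the aspect root | never (unannotated gene → 0, mask set) |
| `coexpression` | Pearson correlation of the two expression profiles over shared finite conditions | gene absent, <2 shared conditions, or zero-variance profile |
| `domain_logodds` | max over (d₁ ∈ domains(a), d₂ ∈ domains(b)) of log[(#(d₁,d₂) among training positives + α)/(#(d₁,d₂) among training randoms + α)], pseudocount α = 1 | either gene has no domains |
| `same_chrom` | indicator that both loci are on one chromosome | either locus unknown |
| `chrom_log_dist` | log₁₀(midpoint distance + 1), capped at 9 (≈ chromosome length scale) | different chromosomes or locus unknown |
| `tissue_jaccard` | \|Tₐ ∩ T_b\| / \|Tₐ ∪ T_b\| | either tissue set empty |

Missing values are encoded as sentinel 0 plus an explicit boolean mask; the
forest trains on values only, with a config switch (`FeatureSchema.append_mask`)
to append the mask as extra columns. GO propagation uses is_a edges only —
part_of handling varies between annotation pipelines, and a minimal DAG keeps
the closure deterministic. The domain-pair counts are fitted exclusively on
the labelled training pairs, never on held-out data (a leakage guard enforced
by the `PairFeaturizer.fit`/`transform` split).

The classifier is a random forest with 30 trees, information-gain (entropy)
splits over 4 randomly drawn candidate features per node (clipped to the
number of enabled features when fewer), minimum 10 samples per leaf, and
bootstrap resampling per tree. "4 random features per split" is read as the
candidate-subset size (mtry), the standard reading. The pair score is the
unweighted fraction of trees voting positive, so every score lies exactly on
the grid k/30; thresholding is strict (positive iff score > t), and the
interactome threshold is 0.5. Models persist to a versioned archive
(schema + hyperparameters + fitted trees + domain-pair counts) and reload to
bit-identical scores.

## Training and evaluation protocol

Training mixes known-interaction positives with uniformly random non-self
pairs at a 1:4 ratio, random pairs drawn to exclude every known PPI. No
degree matching is applied — the construction knowingly admits undiscovered
true interactions among the "negatives", which bounds measurable precision
from above. Held-out positives are a disjoint 80/20 random split of the
known edges (split protocol is this package's choice; disjointness of train
and test positives is enforced). Test sets fix the positive count at
round(total × prevalence) (round half to even), default 0.3% of 160,000 =
480 at protocol scale.

Two evaluation protocols are provided. The precision/recall sweep varies the
threshold from 1 down to 0 over every distinct score; precision at zero
predictions is reported as 1.0 with an explicit flag. The hub protocol takes
every gene with more than 50 known PPIs (strictly greater; desk-scale runs
use a lower cutoff), ranks its catalog-wide predictions above a score floor
(default 0.5, ties broken by partner symbol for determinism) and counts
cumulative true positives (held-out known partners) against false positives
(all other retained pairs — an evaluation convention, since unlabeled pairs
may be undiscovered interactions). The cross-hub average curve is the mean
cumulative TP at each FP count, hubs with shorter lists contributing their
final value. The recall denominator for hubs is the held-out partner set;
`hub_ranked_eval` takes the held-out edges explicitly so callers can pass
all known partners instead.

## Interactome construction and network statistics

A genome scan pairs each seed gene with every other catalog gene, scores all
pairs once (seed–seed pairs are not double-counted) and retains novel pairs
with score > 0.5. Scores in (0.4, 0.5] are reported in a side channel but
never enter the graph. The interactome is the union of the seeds' known PPIs
and their retained predictions; node roles rank seed > known-interactor >
novel-interactor and an edge that is both known and predicted keeps source
"known", so novel ∩ known = ∅ holds structurally.

Distance statistics run on the full known network as background (optionally
augmented with predicted edges), not on the seed-star interactome, because
meaningful seed–seed distances require paths through non-seed genes.
Averages are over connected unordered pairs only; disconnected pairs are
counted and reported, never imputed (a cap-at-K alternative would introduce
an arbitrary constant). Consequently the "with" and "without" averages may
cover different pair sets when predictions connect previously unreachable
genes — the per-report connected/disconnected counts make this visible.

The permutation test compares the seed panel's drop in average distance
(without → with its predicted edges) against the drops of `n_trials` random
gene sets of equal size. The catalog-wide prediction set is computed once;
the predicted edges of any gene set are then exactly the cached edges
touching it, which is identical to scanning that set with the model. The
empirical P uses the add-one estimator P = (1 + #{null ≥ observed})/(N + 1),
so P ∈ (0, 1] and is never zero. The statistic compared is the rank of the
observed drop in the null (the alternative — testing the difference of mean
drops — is directly computable from the returned null sample). P values are
uniform on the grid {1/(N+1), …, 1} under the null provided the drop
statistic is effectively continuous; for very small gene sets on a sparse
background the drop ties at exactly 0 and the estimator becomes
conservative, which is why calibration checks use study-sized panels.

Overlap significance is the upper-tail hypergeometric probability of at
least the observed intersection, with the universe size M defaulting to the
catalog size (the appropriate M for real data depends on the annotation
coverage and is left to the caller). GO-term enrichment applies the same
test per term over propagated annotations with Benjamini–Hochberg correction
by default (Bonferroni and uncorrected available). Drug summaries map each
ATC code to its anatomic category (first letter; malformed codes are binned
as "unknown" with a warning), count a drug once per category it belongs to,
and classify drugs by whether their interactome targets are known
interactors, novel interactors, or both.

## Synthetic universe

The generator emulates every input the pipeline touches, with one planted
mechanism: genes belong to functional clusters (default 16 clusters over 300
genes), and cluster membership drives all annotation sources simultaneously —
shared GO terms sampled from per-cluster term modules inside random is_a
DAGs (depth 4, 60 terms per aspect), expression correlation through a
one-factor-per-cluster latent model (gene noise sd 0.5 around the cluster
factor over 40 conditions), signature protein domains (two per cluster,
~10% of genes domain-free), and shared tissue labels (three per cluster,
~5% of genes tissue-free). Loci are uniform over 10 chromosomes and carry no
planted signal.

True interactions are the top `edge_density` (default 2%) of all pairs by a
weighted rule score over GO overlap, co-expression and domain compatibility
plus Gaussian noise (sd 0.05); at noise 0 the rule is exact — every true
edge's rule score strictly exceeds every non-edge's. A further 8% of the
true-edge count is added as uniform cross-module edges carrying no
annotation signal: real interactomes form a giant connected component
rather than isolated pathways, and without this backbone distance analyses
have no connected pairs to average. The observed known-PPI list is an exact
round(observed_fraction × |truth|) subsample (default 85%), drawn with
study bias: 25% of genes are "under-studied" and their true edges enter the
known list with relative weight 0.3. This mirrors the literature bias of
interaction databases and is what makes disease-gene analyses well-posed at
desk scale: seed panels (default 77 + 25 genes with 1 shared, i.e. 101
genes) are sampled preferentially by unobserved true degree, the synthetic
analog of disease genes whose interactions are disproportionately
unreported.

Default parameters were fixed once so that, at the default scale, the
planted signal supports the pipeline's calibration checks — forest precision
among score > 0.5 pairs on a 0.3%-prevalence test set of roughly 0.19–0.25
(60–80× prevalence) at 86–93% recall, and a seed-panel distance-drop
permutation P of ~0.005 at 200 trials — while a full synth → split → train →
eval → scan → stats run stays under a minute on one CPU.

What the generator does **not** emulate: scale-free degree distributions
(cluster components are dense and homogeneous), realistic GO DAG topology
(trees, no multiple inheritance), part_of relations, expression batch
structure, sequence-level features, and any drug-target pharmacology (drug
tables are random assignments biased toward high-degree genes). Passing
tests therefore demonstrate correctness of the machinery and recoverability
of an annotation-driven planted signal — not expected performance on real
interactome data, where feature informativeness and database bias are far
less favourable.

## Numerical and design choices

- Gene identity is the upper-cased symbol string; aliases resolve through an
  explicit map at the reader boundary, before any deduplication.
- Locus coordinates are stored 0-based half-open; 1-based inputs must be
  converted by the reader of that format.
- Duplicate GO (gene, term) rows collapse; NOT-qualified GAF rows are
  excluded; annotations to terms absent from the DAG are an error.
- Unresolvable symbols and self-pairs are dropped with logged counts, never
  silently.
- Test-set positive counts round half to even (Python's `round`).
- All stochastic steps take explicit integer seeds; `hippip run` derives
  per-stage seeds from the master seed and records them in `manifest.yaml`.
- Desk-scale defaults: 300-gene catalog, 30,000-pair test set (0.3%
  prevalence keeps 90 positives), 200 permutation trials, hub cutoff at
  degree > 8. The full-protocol constants (20,000/80,000/160,000, hub
  degree > 50) remain the library defaults where no feature computation is
  required.

## Known limitations

- Exact feature definitions of published annotation-based predictors vary;
  this package fixes one explicit, auditable 8-feature schema rather than
  reverse-engineering any particular one.
- Hypergeometric P values can underflow to 0 in double precision for
  extreme overlaps; reported values are floored at the smallest positive
  double only where the (0, 1] invariant is asserted.
- The permutation null draws gene sets uniformly from the catalog; no
  degree-matched null is provided.
- `interactome_overlap` compares node sets; it does not attempt to
  distinguish overlap driven by shared seeds from overlap driven by shared
  interactors (callers can subtract the seed sets).
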