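# Methods

## Ontology model and closure

The ontology is an acyclic directed graph of GO terms with child→parent
edges typed `is_a` or `part_of`. Annotation propagation (the true-path
rule) takes the **reflexive** transitive closure over those two relations
only: `regulates`-family relationships are parsed and ignored, matching the
GO Consortium's annotation-propagation convention. Reflexivity means a
gene's "all terms, both inferred and direct" is a single set, which is what
the congruence score consumes.

Obsolete terms stay in the term map (so lookups can report a
`replaced_by` hint) but carry no edges; annotations resolving to them are
dropped with a logged count. An `alt_id` claimed by two primary terms is a
hard error — silently picking one would corrupt closures. Cycle detection
runs at parse time and reports one offending cycle.

`term_depth` is the shortest directed path to the aspect root (root = 0);
it exists to drive the simulator's specificity-truncation step.

## Annotation semantics

GAF 2.1/2.2 rows are read with the qualifier column split on `|`; a `NOT`
entry marks the record negated. Negated records never enter the positive
direct/closed sets and are never propagated to ancestors: a gene shown to
lack a *specific* activity may still have the general one, so negation
propagates (logically) downward, not upward, and here it is simply not
propagated at all — it is reported exactly as asserted. Positive and
negative sets are built independently; a positive child and a NOT parent
coexist without cancellation.

Closed sets exclude the three aspect roots by default: every annotated gene
reaches its root, so keeping it adds a constant shared term that inflates
every congruence score (published per-gene annotation listings likewise
omit the roots). A flag restores them.

Duplicate (gene, term) records collapse to one set member for scoring;
record-level multiplicity is preserved for the bias module's `records`
counting unit.

The default evidence filter is the six experimental codes EXP, IPI, IDA,
IMP, IGI, IEP. Species tags normalize NCBI taxon ids through a small
extendable table (9606→human, 10090→mouse).

## Congruence score

For closed sets A, B of the same aspect: jaccard `|A∩B|/|A∪B|` (default),
`min` `|A∩B|/min(|A|,|B|)`, `max` `|A∩B|/max(|A|,|B|)`. The normalization
used is recorded on every result because published set-overlap scores are
often ambiguous about the denominator. The score is NA when either set is
empty — under the open-world assumption an unannotated gene is unknown,
not dissimilar — and NA results are excluded from class means/medians and
counted separately. Scores are computed per aspect, never pooled: the
biological-process and molecular-function corpora have very different
annotation cultures. Class summaries add a within-species vs
between-species aggregate with a descriptive two-sided Mann-Whitney U
(rank-based, no multiplicity correction), and medians use the midpoint of
the central order statistics.

The divergence screen emits a row when one gene's positive closed set
contains a term t and its partner carries a NOT annotation to t or to a
descendant of t — the only annotation pattern accepted as evidence of
functional divergence. Matching runs through the ontology: a NOT term's
ancestor set is intersected with the partner's closed set, with the aspect
root excluded so unrelated annotations cannot "contradict" through it.

## Overrepresentation

Per term, counts in the two corpora are compared with the upper cumulative
hypergeometric tail: for species A, `P(X ≥ count_a)` with population
`N = total_a + total_b`, successes `K = count_a + count_b` and draws
`n = total_a`. The tail is computed through scipy's survival function
(log-space internally); a `log10` variant keeps extreme biases rankable
below the float underflow limit (~1e-300), and rows are ranked by it.

The default counting unit is **distinct gene-term pairs after closure** —
record-level counts double-count findings reported in multiple papers. The
`records` unit (closure-propagated record counts) is retained because
published cross-species comparisons of this kind have used corpus
magnitudes consistent with record counting, and the choice is not always
documented; the unit is stored on the counts and checked for consistency.
Corpus totals are emitted alongside every p-value so the urn is auditable.
No correction is applied by default; Bonferroni and Benjamini-Hochberg are
available. Closure makes counts monotone along edges (parent ≥ child), so
parent-term p-values are not independent of their children's — the module
ranks and flags, it does not control any error rate.

## The simulator

The generator emulates two species annotating the *same* conserved biology
through different experimental lenses.

**Ontology.** A single biological_process tree: root, `n_themes` depth-1
"theme" terms, then `branching`-ary subtrees to `depth`. Defaults
`branching=3, depth=4, n_themes=2` give 81 terms and 54 leaves — deep
enough for truncation to matter, small enough that closures are instant. A
tree (not a multi-parent DAG) suffices because the bias mechanism lives in
*which* subtree gets probed, not in diamond structure. Emission is
deterministic OBO text, re-parsed through the package's own parser.

**Families.** `n_families=500` families each contribute an ortholog pair;
with probability `p_dup=0.3` the family carries a duplication,
pre-speciation with `p_pre=0.5` (yielding a second ortholog pair, two
within-species outparalog pairs and two between-species outparalog pairs)
or post-speciation (an inparalog pair in one species plus the co-ortholog
pair). Each family draws `m_terms=5` true leaf functions uniformly;
duplicates independently resample a fraction `delta` of them
(`delta=0` ⇒ perfect conservation family-wide). 500 families give a few
hundred pairs per side of the within/between split — enough that the null
gap's Monte-Carlo noise is well under the 0.1 effect size probed.

**Sampling.** A gene of species *s* gets its true leaf *t* annotated with
probability `q·w_s[theme(t)]`, `q=0.8` (most known functions of a studied
gene end up annotated) and `w` max-normalized so equal vectors reduce
exactly to unbiased sampling. With probability `r=0.3` the record lands on
a strict ancestor at uniform distance 1..`u=2` (capped at the theme level,
never the root) — annotation-specificity truncation, the mechanism behind
specificity-driven congruence loss. All records carry evidence code IDA;
evidence diversity is not part of the model. The biased condition used in
the experiments, `w_a=(1,0.2)` / `w_b=(0.2,1)`, is illustrative of strong
complementarity; no published calibration of human-vs-mouse propensity
magnitudes exists to fit against.

**Determinism.** Each run seeds one `numpy` generator per stage, the stage
seeds derived from the run seed via `SeedSequence.spawn`, so stages are
independently replayable and identical configs give identical corpora,
scores and summaries.

**What passing shows — and does not.** The simulation demonstrates the
*mechanism*: complementary experiment propensities alone open a
within-vs-between congruence gap (> 0.1 under the strong-bias condition)
and flag each species' favored theme as overrepresented, with zero true
divergence. Real corpora differ in ways the model omits: multi-parent DAG
topology, evidence-code mixtures, curation-date and curator-group effects,
gene-specific study intensity, and annotation errors. Results on synthetic
data bound what the statistics can distinguish; they do not estimate the
size of the bias in any real database.

## Fixtures

The two packaged case-study files transcribe experimental annotation
snapshots (AMIGO retrievals, late 2011) for MAP4K2/MAP4K3/Map4k2
(biological process) and Thra/THRA/Esr1 (molecular function), preserving
the direct-vs-inferred distinction. Closed sets are stored verbatim rather
than recomputed because the ontology edges of that era are not part of the
package; this keeps the case studies self-contained and immutable
(sha256-guarded). On these fixtures the jaccard scores are exactly
10/17 ≈ 0.588 (Thra-Esr1) vs 11/24 ≈ 0.458 (Thra-THRA), and the
MAP4K2-Map4k2 ortholog intersection is the single broad term GO:0009987.

## Numerical and edge-case choices

* Hypergeometric tails: `P(X ≥ 0)` is forced to exactly 1; parameters are
  validated (`0 ≤ k ≤ min(K, n)`, `K, n ≤ N`); tests check the tail against
  exact integer enumeration (1e-12) over all urns with N ≤ 60.
* Closure: breadth-first over child→parent edges; tested against an
  independent depth-first reachability oracle on random DAGs.
* Empty corpora, header-only GAFs, all-filtered corpora and genes absent
  from a corpus all produce well-defined empty/NA outputs, never errors.
* Malformed GAF rows fail fast with a line number by default; a
  skip-and-count mode is available.
* Tabular outputs are single-header TSV with fixed column orders.
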