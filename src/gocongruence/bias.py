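"""Cross-species annotation-bias profiling by term overrepresentation.

Different model organisms attract different kinds of experiments (mouse
genetics probes organism-level processes; human work leans on isolated
cells and proteins), so the experimental GO annotation corpora of two
species can be systematically skewed toward different parts of the
ontology even when the underlying gene functions are conserved. This
module quantifies that skew: per GO term, how unequally do annotations
distribute between the two corpora, under a hypergeometric null?

For a term with count k in species A, pooled count K = count_a + count_b,
corpus total n = total_a and pooled total N = total_a + total_b, the
overrepresentation p-value in A is the upper cumulative tail P(X ≥ k) of
Hypergeometric(N, K, n). No multiple-testing correction is applied by
default; Bonferroni and Benjamini-Hochberg are available.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph, ObsoleteTermError, UnknownTermError

COUNT_UNITS = ("gene_term_pairs", "records")
CORRECTIONS = ("none", "bonferroni", "bh")


@dataclass
class TermCounts:
    """Closure-propagated per-term counts for one corpus and aspect."""

    counts: dict[str, int]
    total: int
    unit: str
    aspect: str
    species: str


@dataclass(frozen=True)
class EnrichmentRow:
    """Per-term cross-species counts and hypergeometric p-values."""

    term: str
    name: str
    aspect: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    p_over_a: float
    p_over_b: float
    direction: str
    adjusted_p: float = math.nan
    log10_min_p: float = math.nan

    @property
    def min_p(self) -> float:
        return min(self.p_over_a, self.p_over_b)


def term_counts(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str,
    unit: str = "gene_term_pairs",
    *,
    exclude_root: bool = True,
) -> TermCounts:
    """Count closure-propagated annotations per term.

    ``gene_term_pairs``: number of distinct genes whose closed set contains
    the term (multi-record findings counted once). ``records``: number of
    annotation records whose closure reaches the term (duplicates kept).
    Only non-negated annotations of the requested aspect count; the aspect
    root is excluded by default.
    """
    if unit not in COUNT_UNITS:
        raise ValueError(f"unit must be one of {COUNT_UNITS}")
    root = graph.root_of_aspect(aspect) if exclude_root else None
    counter: Counter[str] = Counter()
    if unit == "records":
        for a in corpus.positives():
            if a.aspect != aspect:
                continue
            try:
                primary = graph.resolve(a.term)
            except (UnknownTermError, ObsoleteTermError):
                continue
            if graph.terms[primary].aspect != aspect:
                continue
            for anc in graph.ancestors(primary):
                if anc != root:
                    counter[anc] += 1
    else:
        per_gene: dict[str, set[str]] = {}
        for a in corpus.positives():
            if a.aspect != aspect:
                continue
            try:
                primary = graph.resolve(a.term)
            except (UnknownTermError, ObsoleteTermError):
                continue
            if graph.terms[primary].aspect != aspect:
                continue
            per_gene.setdefault(a.gene_id, set()).update(graph.ancestors(primary))
        for terms in per_gene.values():
            terms.discard(root)
            counter.update(terms)
    return TermCounts(
        counts=dict(counter),
        total=sum(counter.values()),
        unit=unit,
        aspect=aspect,
        species=corpus.species,
    )


def hypergeom_upper_tail(k, K: int, n: int, N: int):
    """Upper cumulative hypergeometric tail P(X ≥ k).

    X counts successes among ``n`` draws without replacement from a
    population of ``N`` containing ``K`` successes. ``k`` may be a scalar
    or an array of tail cutoffs. Computed via the survival function (which
    works in log space internally), so extreme tails keep precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got k={k}, K={K}, n={n}, N={N}")
    k_arr = np.asarray(k)
    if k_arr.min() < 0 or k_arr.max() > min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X > k-1) = P(X >= k); force the k=0 tail to exactly 1
    p = np.where(k_arr == 0, 1.0, stats.hypergeom.sf(k_arr - 1, N, K, n))
    return float(p) if np.isscalar(k) else p


def hypergeom_upper_tail_log10(k: int, K: int, n: int, N: int) -> float:
    """log10 of P(X ≥ k); stays finite where the plain tail underflows."""
    if k == 0:
        return 0.0
    return float(stats.hypergeom.logsf(k - 1, N, K, n)) / math.log(10)


def overrepresentation(
    counts_a: TermCounts,
    counts_b: TermCounts,
    correction: str = "none",
    min_count: int = 1,
    graph: OntologyGraph | None = None,
) -> list[EnrichmentRow]:
    """Score every term for unequal representation between two corpora.

    One row per term with ``count_a + count_b >= min_count``. ``p_over_a``
    asks whether the term is overrepresented among species A's annotations
    given the pooled counts (and symmetrically for B). ``direction`` names
    the species with the smaller p-value (``tied`` on exact equality).
    Correction, when requested, is applied to the per-term min p. Rows come
    back sorted by min p.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if counts_a.unit != counts_b.unit:
        raise ValueError(
            f"count unit mismatch: {counts_a.unit} vs {counts_b.unit}"
        )
    if counts_a.aspect != counts_b.aspect:
        raise ValueError(
            f"aspect mismatch: {counts_a.aspect} vs {counts_b.aspect}"
        )
    total_a, total_b = counts_a.total, counts_b.total
    N = total_a + total_b
    rows: list[EnrichmentRow] = []
    for term in sorted(set(counts_a.counts) | set(counts_b.counts)):
        ka = counts_a.counts.get(term, 0)
        kb = counts_b.counts.get(term, 0)
        K = ka + kb
        if K < min_count:
            continue
        p_a = hypergeom_upper_tail(ka, K, total_a, N)
        p_b = hypergeom_upper_tail(kb, K, total_b, N)
        # keep extreme biases rankable: log10 of the smaller tail, from logsf
        log10_min = min(
            hypergeom_upper_tail_log10(ka, K, total_a, N),
            hypergeom_upper_tail_log10(kb, K, total_b, N),
        )
        if p_a < p_b:
            direction = counts_a.species or "a"
        elif p_b < p_a:
            direction = counts_b.species or "b"
        else:
            direction = "tied"
        name = term
        if graph is not None and term in graph.terms:
            name = graph.terms[term].name
        rows.append(
            EnrichmentRow(
                term=term,
                name=name,
                aspect=counts_a.aspect,
                count_a=ka,
                count_b=kb,
                total_a=total_a,
                total_b=total_b,
                p_over_a=p_a,
                p_over_b=p_b,
                direction=direction,
                log10_min_p=log10_min,
            )
        )
    rows.sort(key=lambda r: (r.log10_min_p, r.term))
    if correction != "none" and rows:
        min_ps = np.array([r.min_p for r in rows])
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        adjusted = multipletests(min_ps, method=method)[1]
        rows = [
            EnrichmentRow(**{**r.__dict__, "adjusted_p": float(q)})
            for r, q in zip(rows, adjusted)
        ]
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows in the report column order."""
    df = pd.DataFrame(
        {
            "aspect": [r.aspect for r in rows],
            "term_id": [r.term for r in rows],
            "term_name": [r.name for r in rows],
            "count_a": [r.count_a for r in rows],
            "count_b": [r.count_b for r in rows],
            "total_a": [r.total_a for r in rows],
            "total_b": [r.total_b for r in rows],
            "p_over_a": [r.p_over_a for r in rows],
            "p_over_b": [r.p_over_b for r in rows],
            "direction": [r.direction for r in rows],
            "adjusted_p": [r.adjusted_p for r in rows],
            "log10_min_p": [r.log10_min_p for r in rows],
        }
    )
    return df
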