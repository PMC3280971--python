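"""Annotation-congruence scoring for homolog pairs.

The score S compares two genes' ontology-closed experimental annotation
sets A and B within one GO aspect:

    jaccard   S = |A ∩ B| / |A ∪ B|        (default)
    min       S = |A ∩ B| / min(|A|, |B|)
    max       S = |A ∩ B| / max(|A|, |B|)

S measures agreement in what has been *annotated so far*, not similarity of
actual biological function — under the open-world assumption an unannotated
function is simply unknown. Accordingly S is NA (not 0) when either closed
set is empty, and NA results are excluded from class summaries rather than
treated as dissimilar.

The only annotation pattern accepted here as positive evidence of
functional *divergence* is an explicit contradiction: one gene annotated to
a term whose partner carries a NOT annotation to that term or a descendant
(:func:`divergence_screen`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from scipy import stats

from .annotations import AnnotationCorpus, ClosedAnnotationSet, closed_sets
from .ontology import OntologyGraph

PAIR_CLASSES = (
    "ortholog",
    "inparalog",
    "within_species_outparalog",
    "between_species_outparalog",
)
WITHIN_SPECIES_CLASSES = frozenset({"inparalog", "within_species_outparalog"})
BETWEEN_SPECIES_CLASSES = frozenset({"ortholog", "between_species_outparalog"})

NORMALIZATIONS = ("jaccard", "min", "max")


class AspectMismatchError(ValueError):
    """The two closed sets belong to different GO aspects."""


@dataclass(frozen=True)
class HomologPair:
    """A pair of homologous genes with its evolutionary class label.

    Orthologs and between-species outparalogs relate genes of different
    species; inparalogs and within-species outparalogs are same-species.
    """

    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    pair_class: str

    def __post_init__(self) -> None:
        if self.pair_class not in PAIR_CLASSES:
            raise ValueError(f"unknown pair class {self.pair_class!r}")
        cross = self.species_a != self.species_b
        if self.pair_class in BETWEEN_SPECIES_CLASSES and not cross:
            raise ValueError(
                f"{self.pair_class} pair {self.gene_a}/{self.gene_b} must span species"
            )
        if self.pair_class in WITHIN_SPECIES_CLASSES and cross:
            raise ValueError(
                f"{self.pair_class} pair {self.gene_a}/{self.gene_b} must be same-species"
            )


@dataclass(frozen=True)
class CongruenceResult:
    """A scored pair; ``score`` is NaN when either closed set is empty."""

    pair: HomologPair
    aspect: str
    score: float
    n_terms_a: int
    n_terms_b: int
    n_shared: int
    normalization: str
    na_reason: str = ""

    @property
    def is_na(self) -> bool:
        return math.isnan(self.score)


def congruence_score(
    set_a: ClosedAnnotationSet,
    set_b: ClosedAnnotationSet,
    normalization: str = "jaccard",
    pair: HomologPair | None = None,
) -> CongruenceResult:
    """Score the overlap of two genes' closed term sets within one aspect."""
    if set_a.aspect != set_b.aspect:
        raise AspectMismatchError(
            f"aspect mismatch: {set_a.gene_id}={set_a.aspect}, {set_b.gene_id}={set_b.aspect}"
        )
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    a, b = set_a.closed_terms, set_b.closed_terms
    shared = len(a & b)
    na_reason = ""
    if not a or not b:
        score = math.nan
        na_reason = "empty_set"
    elif normalization == "jaccard":
        score = shared / len(a | b)
    elif normalization == "min":
        score = shared / min(len(a), len(b))
    else:
        score = shared / max(len(a), len(b))
    if pair is None:
        pair = HomologPair(set_a.gene_id, "x", set_b.gene_id, "y", "ortholog")
    return CongruenceResult(
        pair=pair,
        aspect=set_a.aspect,
        score=score,
        n_terms_a=len(a),
        n_terms_b=len(b),
        n_shared=shared,
        normalization=normalization,
        na_reason=na_reason,
    )


def score_pairs(
    pairs: Iterable[HomologPair],
    corpora: Mapping[str, AnnotationCorpus],
    graph: OntologyGraph,
    aspect: str,
    normalization: str = "jaccard",
    *,
    exclude_root: bool = True,
) -> list[CongruenceResult]:
    """Score every homolog pair against per-species closed annotation sets.

    Genes absent from their species' corpus yield an NA result flagged
    ``unannotated`` — absence of annotation is not evidence of anything.
    """
    pairs = list(pairs)
    needed = {p.species_a for p in pairs} | {p.species_b for p in pairs}
    missing = needed - set(corpora)
    if missing:
        raise KeyError(f"no corpus for species {sorted(missing)}")
    sets_by_species = {
        sp: closed_sets(corpora[sp], graph, aspect, exclude_root=exclude_root)
        for sp in sorted(needed)
    }
    results = []
    for p in pairs:
        sa = sets_by_species[p.species_a].get(p.gene_a)
        sb = sets_by_species[p.species_b].get(p.gene_b)
        if sa is None or sb is None:
            results.append(
                CongruenceResult(
                    pair=p,
                    aspect=aspect,
                    score=math.nan,
                    n_terms_a=len(sa.closed_terms) if sa else 0,
                    n_terms_b=len(sb.closed_terms) if sb else 0,
                    n_shared=0,
                    normalization=normalization,
                    na_reason="unannotated",
                )
            )
        else:
            results.append(congruence_score(sa, sb, normalization, pair=p))
    return results


def results_frame(results: Sequence[CongruenceResult]) -> pd.DataFrame:
    """Tabulate results: one row per scored pair."""
    return pd.DataFrame(
        {
            "gene_a": [r.pair.gene_a for r in results],
            "species_a": [r.pair.species_a for r in results],
            "gene_b": [r.pair.gene_b for r in results],
            "species_b": [r.pair.species_b for r in results],
            "pair_class": [r.pair.pair_class for r in results],
            "aspect": [r.aspect for r in results],
            "score": [r.score for r in results],
            "n_terms_a": [r.n_terms_a for r in results],
            "n_terms_b": [r.n_terms_b for r in results],
            "n_shared": [r.n_shared for r in results],
            "normalization": [r.normalization for r in results],
            "na_reason": [r.na_reason for r in results],
        }
    )


def class_summary(results: Sequence[CongruenceResult]) -> pd.DataFrame:
    """Summarize scores per pair class and aspect, plus a within-vs-between row.

    NA scores are excluded from means/medians and counted in ``n_na``. The
    within-species vs between-species aggregate carries a rank-based
    two-sample comparison (Mann-Whitney U, descriptive, uncorrected).
    """
    df = results_frame(results)
    rows = []
    for (cls, aspect), grp in df.groupby(["pair_class", "aspect"], sort=True):
        ok = grp["score"].dropna()
        rows.append(
            {
                "group": cls,
                "aspect": aspect,
                "n": len(grp),
                "n_na": int(grp["score"].isna().sum()),
                "mean": ok.mean() if len(ok) else math.nan,
                "median": ok.median() if len(ok) else math.nan,
            }
        )
    for aspect, grp in df.groupby("aspect", sort=True):
        within = grp.loc[grp["pair_class"].isin(WITHIN_SPECIES_CLASSES), "score"].dropna()
        between = grp.loc[grp["pair_class"].isin(BETWEEN_SPECIES_CLASSES), "score"].dropna()
        if len(within) and len(between):
            u, pval = stats.mannwhitneyu(within, between, alternative="two-sided")
        else:
            u, pval = math.nan, math.nan
        for label, s in (("within_species", within), ("between_species", between)):
            rows.append(
                {
                    "group": label,
                    "aspect": aspect,
                    "n": len(s),
                    "n_na": int(
                        grp.loc[
                            grp["pair_class"].isin(
                                WITHIN_SPECIES_CLASSES
                                if label == "within_species"
                                else BETWEEN_SPECIES_CLASSES
                            ),
                            "score",
                        ]
                        .isna()
                        .sum()
                    ),
                    "mean": s.mean() if len(s) else math.nan,
                    "median": s.median() if len(s) else math.nan,
                }
            )
        rows.append(
            {
                "group": "within_minus_between",
                "aspect": aspect,
                "n": len(within) + len(between),
                "n_na": 0,
                "mean": (within.mean() - between.mean())
                if len(within) and len(between)
                else math.nan,
                "median": (within.median() - between.median())
                if len(within) and len(between)
                else math.nan,
                "mannwhitney_u": u,
                "mannwhitney_p": pval,
            }
        )
    return pd.DataFrame(rows)


def divergence_screen(
    pairs: Iterable[HomologPair],
    corpora: Mapping[str, AnnotationCorpus],
    graph: OntologyGraph,
    aspect: str,
) -> pd.DataFrame:
    """Screen pairs for documented functional divergence via NOT annotations.

    A row is emitted when one gene's positive closed set contains a term t
    and the partner carries a NOT annotation to t or to a descendant of t:
    the partner has been shown to lack a function (or a specific form of it)
    the first gene has. One row per (pair direction, NOT term); the matched
    positive terms are joined into ``positive_terms``. This explicit
    contradiction is the only annotation pattern treated as evidence of
    divergence; mere absence never is. The aspect root is excluded from the
    positive sets so unrelated annotations cannot "contradict" through it.
    """
    pairs = list(pairs)
    needed = sorted({p.species_a for p in pairs} | {p.species_b for p in pairs})
    sets_by_species = {
        sp: closed_sets(corpora[sp], graph, aspect, exclude_root=True) for sp in needed
    }
    root = graph.root_of_aspect(aspect)
    rows = []
    for p in pairs:
        for (gpos, spos), (gneg, sneg) in (
            ((p.gene_a, p.species_a), (p.gene_b, p.species_b)),
            ((p.gene_b, p.species_b), (p.gene_a, p.species_a)),
        ):
            pos = sets_by_species[spos].get(gpos)
            neg = sets_by_species[sneg].get(gneg)
            if pos is None or neg is None:
                continue
            for not_term in sorted(neg.negated_terms):
                # terms the NOT assertion contradicts: the NOT term itself
                # or any of its ancestors present in the positive closed set
                hits = (graph.ancestors(not_term) - {root}) & pos.closed_terms
                if hits:
                    rows.append(
                        {
                            "gene_positive": gpos,
                            "species_positive": spos,
                            "gene_negative": gneg,
                            "species_negative": sneg,
                            "pair_class": p.pair_class,
                            "aspect": aspect,
                            "not_term": not_term,
                            "positive_terms": "|".join(sorted(hits)),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_positive",
            "species_positive",
            "gene_negative",
            "species_negative",
            "pair_class",
            "aspect",
            "not_term",
            "positive_terms",
        ],
    )


# -- pairs TSV ------------------------------------------------------------


def read_pairs_tsv(stream: TextIO | str) -> list[HomologPair]:
    """Read the homolog-pairs table: gene_a, species_a, gene_b, species_b, pair_class."""
    if isinstance(stream, str):
        stream = StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = ["gene_a", "species_a", "gene_b", "species_b", "pair_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pairs TSV missing columns {missing}")
    return [HomologPair(*row) for row in df[required].itertuples(index=False)]


def write_pairs_tsv(pairs: Iterable[HomologPair], handle: TextIO) -> None:
    handle.write("gene_a\tspecies_a\tgene_b\tspecies_b\tpair_class\n")
    for p in pairs:
        handle.write(
            f"{p.gene_a}\t{p.species_a}\t{p.gene_b}\t{p.species_b}\t{p.pair_class}\n"
        )
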