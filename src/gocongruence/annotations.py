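"""GAF annotation corpora: parsing, evidence filtering, and ontology closure.

A Gene Association File (GAF 2.1/2.2) row associates a gene product with a
GO term, an evidence code and optional qualifiers. Two semantic points drive
the design here:

* **Open world.** Absence of an annotation is not evidence of absent
  function, and a ``NOT``-qualified annotation is a distinct, explicit
  assertion that a function is *lacking*. Negated annotations therefore
  never enter the positive term sets, and are never propagated to ancestors
  (a gene lacking a specific activity may well have the general one).

* **True path rule.** A positive annotation to a term implies every
  is_a/part_of ancestor. :func:`closed_sets` materializes this as
  ``closed_terms`` — the "all terms, both inferred and direct" set that the
  congruence score compares. The three aspect roots are excluded by default:
  every annotated gene reaches them, so they only add a shared constant.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, TextIO

from .ontology import (
    OntologyGraph,
    UnknownTermError,
    ObsoleteTermError,
)

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17

#: Evidence codes denoting direct experimental support (the default filter).
EXPERIMENTAL_EVIDENCE_CODES = frozenset({"EXP", "IPI", "IDA", "IMP", "IGI", "IEP"})

#: All recognized GO evidence codes.
KNOWN_EVIDENCE_CODES = EXPERIMENTAL_EVIDENCE_CODES | frozenset(
    {
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD", "IKR", "IRD",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)

VALID_ASPECTS = frozenset({"P", "F", "C"})

#: NCBI taxon id → species label; extendable via parse_gaf(taxon_labels=...).
DEFAULT_TAXON_LABELS = {"9606": "human", "10090": "mouse"}


class GafFormatError(ValueError):
    """A GAF row violates the format (wrong column count, bad aspect...)."""


@dataclass(frozen=True)
class Annotation:
    """One GAF record."""

    gene_id: str
    gene_symbol: str
    species: str
    term: str
    aspect: str
    evidence: str
    negated: bool = False
    reference: str = ""
    qualifier: str = ""
    db: str = "GOC"
    taxon: str = ""
    date: str = ""
    assigned_by: str = ""
    object_type: str = "protein"

    def __post_init__(self) -> None:
        if self.aspect not in VALID_ASPECTS:
            raise GafFormatError(f"invalid aspect {self.aspect!r} for {self.gene_id}")
        if self.evidence not in KNOWN_EVIDENCE_CODES:
            raise GafFormatError(
                f"unrecognized evidence code {self.evidence!r} for {self.gene_id}"
            )


@dataclass
class AnnotationCorpus:
    """A species' annotation records plus provenance."""

    annotations: list[Annotation]
    species: str
    source_label: str = ""
    gaf_version: str = "2.1"

    def __post_init__(self) -> None:
        bad = {a.species for a in self.annotations if a.species != self.species}
        if bad:
            raise ValueError(
                f"corpus tagged {self.species!r} contains records for {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def positives(self) -> Iterable[Annotation]:
        return (a for a in self.annotations if not a.negated)

    def negatives(self) -> Iterable[Annotation]:
        return (a for a in self.annotations if a.negated)


@dataclass
class ClosedAnnotationSet:
    """Per-gene, per-aspect term sets: direct, ontology-closed, and negated.

    ``closed_terms`` ⊇ ``direct_terms``; ``negated_terms`` is kept entirely
    separate (NOT annotations are not propagated and never cancel positives).
    """

    gene_id: str
    aspect: str
    direct_terms: frozenset[str]
    closed_terms: frozenset[str]
    negated_terms: frozenset[str] = frozenset()
    species: str = ""


def _taxon_to_species(taxon_field: str, taxon_labels: Mapping[str, str]) -> str:
    first = taxon_field.split("|")[0].strip()
    numeric = first.removeprefix("taxon:")
    return taxon_labels.get(numeric, numeric or "unknown")


def parse_gaf(
    stream: TextIO | str,
    *,
    species: str | None = None,
    taxon_labels: Mapping[str, str] | None = None,
    on_bad_row: str = "error",
    source_label: str = "",
) -> AnnotationCorpus:
    """Read a GAF 2.1/2.2 stream into an :class:`AnnotationCorpus`.

    Parameters
    ----------
    species:
        Override the corpus species tag; by default it is taken from the
        records' taxon column, which must then be homogeneous.
    on_bad_row:
        ``"error"`` (fail fast, with line number) or ``"skip"`` (drop the
        row and log a count at the end).
    """
    if isinstance(stream, str):
        stream = StringIO(stream)
    labels = dict(DEFAULT_TAXON_LABELS)
    if taxon_labels:
        labels.update(taxon_labels)
    if on_bad_row not in ("error", "skip"):
        raise ValueError("on_bad_row must be 'error' or 'skip'")

    gaf_version = "2.1"
    records: list[Annotation] = []
    n_skipped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("!"):
            if line.lower().startswith("!gaf-version:"):
                gaf_version = line.split(":", 1)[1].strip()
            continue
        cols = line.split("\t")
        try:
            if len(cols) != GAF_COLUMNS:
                raise GafFormatError(
                    f"line {lineno}: expected {GAF_COLUMNS} columns, got {len(cols)}"
                )
            qualifier = cols[3]
            rec_species = species or _taxon_to_species(cols[12], labels)
            records.append(
                Annotation(
                    gene_id=cols[1],
                    gene_symbol=cols[2],
                    species=rec_species,
                    term=cols[4],
                    aspect=cols[8],
                    evidence=cols[6],
                    negated="NOT" in qualifier.split("|"),
                    reference=cols[5],
                    qualifier=qualifier,
                    db=cols[0],
                    taxon=cols[12],
                    date=cols[13],
                    assigned_by=cols[14],
                    object_type=cols[11],
                )
            )
        except GafFormatError as exc:
            if on_bad_row == "error":
                raise GafFormatError(f"line {lineno}: {exc}") from exc
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d malformed GAF rows", n_skipped)

    if species is None:
        found = sorted({a.species for a in records})
        if len(found) > 1:
            raise GafFormatError(
                f"GAF mixes species {found}; pass species= to override"
            )
        species = found[0] if found else "unknown"
    return AnnotationCorpus(
        annotations=records,
        species=species,
        source_label=source_label,
        gaf_version=gaf_version,
    )


def write_gaf(corpus: AnnotationCorpus, handle: TextIO) -> None:
    """Write a corpus back out as GAF, preserving the version header."""
    handle.write(f"!gaf-version: {corpus.gaf_version}\n")
    for a in corpus.annotations:
        cols = [
            a.db,
            a.gene_id,
            a.gene_symbol,
            a.qualifier if a.qualifier else ("NOT" if a.negated else ""),
            a.term,
            a.reference,
            a.evidence,
            "",  # with/from
            a.aspect,
            "",  # object name
            "",  # synonyms
            a.object_type,
            a.taxon,
            a.date,
            a.assigned_by,
            "",  # annotation extension
            "",  # gene product form id
        ]
        handle.write("\t".join(cols) + "\n")


def filter_experimental(
    corpus: AnnotationCorpus,
    codes: Iterable[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> AnnotationCorpus:
    """Keep only records with experimental evidence codes.

    Default codes are EXP, IPI, IDA, IMP, IGI, IEP — the codes denoting
    direct experimental support. Removed counts are logged per code.
    """
    codes = frozenset(codes)
    if not codes:
        raise ValueError("evidence code set must be non-empty")
    kept = [a for a in corpus.annotations if a.evidence in codes]
    removed = Counter(a.evidence for a in corpus.annotations if a.evidence not in codes)
    for code, n in sorted(removed.items()):
        logger.info("evidence filter removed %d %s records", n, code)
    return AnnotationCorpus(
        annotations=kept,
        species=corpus.species,
        source_label=corpus.source_label,
        gaf_version=corpus.gaf_version,
    )


def closed_sets(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str,
    *,
    exclude_root: bool = True,
) -> dict[str, ClosedAnnotationSet]:
    """Build per-gene ontology-closed annotation sets for one aspect.

    ``direct_terms`` are the curator-assigned (non-negated) terms;
    ``closed_terms`` add every is_a/part_of ancestor — the inferred
    annotations of the true path rule. Annotations to unknown or obsolete
    terms, or whose term namespace does not match ``aspect``, are dropped
    with a warning count. NOT-qualified terms go to ``negated_terms``
    untouched by closure.
    """
    if aspect not in VALID_ASPECTS:
        raise ValueError(f"aspect must be one of {sorted(VALID_ASPECTS)}")
    direct: dict[str, set[str]] = defaultdict(set)
    negated: dict[str, set[str]] = defaultdict(set)
    n_unknown = n_mismatch = 0
    for a in corpus.annotations:
        if a.aspect != aspect:  # other aspects are simply out of scope here
            continue
        try:
            primary = graph.resolve(a.term)
        except (UnknownTermError, ObsoleteTermError):
            n_unknown += 1
            continue
        if graph.terms[primary].aspect != aspect:
            n_mismatch += 1
            continue
        if a.negated:
            negated[a.gene_id].add(primary)
        else:
            direct[a.gene_id].add(primary)
    if n_unknown:
        logger.warning("dropped %d annotations to unknown/obsolete terms", n_unknown)
    if n_mismatch:
        logger.warning("dropped %d annotations with aspect/namespace mismatch", n_mismatch)

    root = graph.root_of_aspect(aspect)
    out: dict[str, ClosedAnnotationSet] = {}
    for gene in sorted(set(direct) | set(negated)):
        closed: set[str] = set()
        for t in direct.get(gene, ()):
            closed |= graph.ancestors(t)
        if exclude_root and root is not None:
            closed.discard(root)
        out[gene] = ClosedAnnotationSet(
            gene_id=gene,
            aspect=aspect,
            direct_terms=frozenset(direct.get(gene, ())),
            closed_terms=frozenset(closed),
            negated_terms=frozenset(negated.get(gene, ())),
            species=corpus.species,
        )
    return out


def negative_annotations(corpus: AnnotationCorpus) -> dict[str, frozenset[str]]:
    """Map gene → its NOT-qualified terms, exactly as asserted (no closure)."""
    out: dict[str, set[str]] = defaultdict(set)
    for a in corpus.negatives():
        out[a.gene_id].add(a.term)
    return {g: frozenset(ts) for g, ts in out.items()}


# -- closed-set TSV dialect (gene_id, aspect, term_id, origin) ------------


def write_closed_sets_tsv(
    sets: Iterable[ClosedAnnotationSet], handle: TextIO, *, with_species: bool = False
) -> None:
    """Export closed sets as TSV, mirroring the direct/inferred distinction."""
    cols = ["gene_id", "aspect", "term_id", "origin"]
    if with_species:
        cols.append("species")
    handle.write("\t".join(cols) + "\n")
    for s in sets:
        for term in sorted(s.closed_terms):
            origin = "direct" if term in s.direct_terms else "inferred"
            row = [s.gene_id, s.aspect, term, origin]
            if with_species:
                row.append(s.species)
            handle.write("\t".join(row) + "\n")


def read_closed_sets_tsv(stream: TextIO | str) -> dict[str, ClosedAnnotationSet]:
    """Re-import the closed-set TSV dialect (direct_terms ⊆ closed_terms)."""
    if isinstance(stream, str):
        stream = StringIO(stream)
    header = stream.readline().rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for required in ("gene_id", "aspect", "term_id", "origin"):
        if required not in idx:
            raise ValueError(f"closed-set TSV missing column {required!r}")
    direct: dict[tuple[str, str, str], set[str]] = defaultdict(set)
    closed: dict[tuple[str, str, str], set[str]] = defaultdict(set)
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        species = cols[idx["species"]] if "species" in idx else ""
        key = (cols[idx["gene_id"]], cols[idx["aspect"]], species)
        closed[key].add(cols[idx["term_id"]])
        if cols[idx["origin"]] == "direct":
            direct[key].add(cols[idx["term_id"]])
    return {
        gene: ClosedAnnotationSet(
            gene_id=gene,
            aspect=aspect,
            direct_terms=frozenset(direct[(gene, aspect, species)]),
            closed_terms=frozenset(terms),
            species=species,
        )
        for (gene, aspect, species), terms in closed.items()
    }
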