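"""Synthetic two-species annotation corpora with ascertainment bias.

The generator realizes a deliberately simple world in which the ortholog
functional-conservation question has a known ground truth: gene families
whose *true* functions (sets of leaf terms in a synthetic ontology) are
perfectly conserved across species unless explicitly diverged. What differs
between species is only *which* of those true functions get experimentally
annotated:

* **Theme propensity.** The ontology's depth-1 subtrees are labeled
  "themes" (stand-ins for broad experimental domains such as
  organism-level development vs. cellular biochemistry). Species ``s``
  annotates a true leaf in theme ``j`` with probability ``q * w_s[j]``,
  where ``w_s`` is a max-normalized per-theme propensity vector. Equal
  vectors mean unbiased discovery; orthogonal vectors mean the two
  species' literatures probe disjoint biology.

* **Specificity truncation.** With probability ``r`` an annotation is
  recorded at a strict ancestor of the true leaf (uniform distance
  ``1..u``, never the root) instead of the leaf itself — annotation
  incompleteness in depth rather than in breadth.

With divergence ``delta = 0`` every within-family gene has identical true
function, so any within-species vs between-species congruence gap produced
by unequal ``w`` vectors is pure ascertainment bias, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations import Annotation, AnnotationCorpus
from .bias import overrepresentation, term_counts
from .congruence import HomologPair, class_summary, results_frame, score_pairs
from .ontology import OntologyGraph, parse_obo

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"
SIM_TAXA = {SPECIES_A: "taxon:9601", SPECIES_B: "taxon:9602"}
#: taxon-id → label table for re-parsing simulated GAF output
SIM_TAXON_LABELS = {"9601": SPECIES_A, "9602": SPECIES_B}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-species annotation-sampling model.

    Ontology shape: a rooted tree of depth ``depth`` whose ``n_themes``
    depth-1 subtrees branch by ``branching`` at every level; annotations
    target its leaves. ``w_a``/``w_b`` give each species' relative
    propensity to probe each theme (max-normalized on construction).
    """

    branching: int = 3
    depth: int = 4
    n_themes: int = 2
    n_families: int = 500
    p_dup: float = 0.3
    p_pre: float = 0.5
    m_terms: int = 5
    delta: float = 0.0
    q: float = 0.8
    w_a: tuple[float, ...] = (1.0, 1.0)
    w_b: tuple[float, ...] = (1.0, 1.0)
    r: float = 0.3
    u: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.m_terms < 1:
            raise ValueError("m_terms must be >= 1")
        for name in ("p_dup", "p_pre", "delta", "q", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.q <= 1.0):
            raise ValueError("q must be in (0, 1]")
        if self.u < 1:
            raise ValueError("u must be >= 1")
        for name in ("w_a", "w_b"):
            w = getattr(self, name)
            if len(w) != self.n_themes:
                raise ValueError(f"{name} must have one entry per theme")
            if min(w) < 0 or max(w) <= 0:
                raise ValueError(f"{name} must be nonnegative with a positive max")
            object.__setattr__(self, name, tuple(v / max(w) for v in w))

    def to_flat(self) -> dict[str, str]:
        """Flat key=value form for the config file dialect."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = ",".join(str(x) for x in v) if isinstance(v, tuple) else str(v)
        return out

    @classmethod
    def from_flat(cls, items: Mapping[str, str]) -> "SimulationConfig":
        kwargs: dict = {}
        for k, v in items.items():
            if k in ("w_a", "w_b"):
                kwargs[k] = tuple(float(x) for x in v.split(","))
            elif k in ("branching", "depth", "n_themes", "n_families", "m_terms", "u", "seed"):
                kwargs[k] = int(v)
            else:
                kwargs[k] = float(v)
        return cls(**kwargs)


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    species: str
    family: int
    true_terms: frozenset[str]


@dataclass
class FamilySet:
    """Generated genes with ground-truth term sets, plus homolog pairs."""

    genes: list[SimGene]
    pairs: list[HomologPair]

    def gene_map(self) -> dict[str, SimGene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class BiasExperimentSummary:
    """End-to-end outcome of one simulated two-species study."""

    mean_within: float
    mean_between: float
    gap: float
    n_within: int
    n_between: int
    n_themes_over_a: int
    n_themes_over_b: int
    p_threshold: float
    config: SimulationConfig


# -- ontology generation --------------------------------------------------


def generate_ontology_obo(config: SimulationConfig) -> str:
    """Emit the synthetic ontology as OBO 1.2 text (deterministic per config).

    A single biological_process tree: one root, ``n_themes`` theme terms at
    depth 1, then ``branching``-ary subtrees down to ``depth``.
    """
    counter = 1

    def next_id() -> str:
        nonlocal counter
        tid = f"GO:{counter:07d}"
        counter += 1
        return tid

    root = next_id()
    stanzas = [
        "format-version: 1.2",
        "ontology: simulated-go",
        "",
        "[Term]",
        f"id: {root}",
        "name: simulated process root",
        "namespace: biological_process",
    ]
    # breadth-first so ids are level-ordered; theme index rides on the name
    frontier: list[tuple[str, int]] = []
    for j in range(config.n_themes):
        tid = next_id()
        stanzas += [
            "",
            "[Term]",
            f"id: {tid}",
            f"name: theme_{j:02d}",
            "namespace: biological_process",
            f"is_a: {root} ! simulated process root",
        ]
        frontier.append((tid, j))
    for level in range(2, config.depth + 1):
        nxt: list[tuple[str, int]] = []
        for parent, theme in frontier:
            for c in range(config.branching):
                tid = next_id()
                stanzas += [
                    "",
                    "[Term]",
                    f"id: {tid}",
                    f"name: theme_{theme:02d} level_{level} term_{tid[3:]}",
                    "namespace: biological_process",
                    f"is_a: {parent}",
                ]
                nxt.append((tid, theme))
        frontier = nxt
    return "\n".join(stanzas) + "\n"


def generate_ontology(config: SimulationConfig) -> OntologyGraph:
    """Parse the emitted OBO through the standard parser (self-consistency)."""
    return parse_obo(generate_ontology_obo(config))


def theme_index(graph: OntologyGraph, term: str) -> int:
    """Theme (depth-1 subtree) a term belongs to, read off the term name."""
    name = graph.terms[graph.resolve(term)].name
    if not name.startswith("theme_"):
        raise ValueError(f"term {term} ({name!r}) has no theme")
    return int(name.split("_")[1].split()[0])


def theme_terms(graph: OntologyGraph) -> dict[int, str]:
    """Map theme index → the depth-1 theme term id."""
    out = {}
    for tid, term in graph.terms.items():
        if term.name.startswith("theme_") and " " not in term.name:
            out[int(term.name.split("_")[1])] = tid
    return out


def leaf_terms(graph: OntologyGraph) -> list[str]:
    """Terms with no children — the annotation targets."""
    has_child = {p for parents in graph.edges.values() for p, _rel in parents}
    return sorted(t for t in graph.terms if t not in has_child)


# -- family generation ----------------------------------------------------


def _resample(
    true_terms: tuple[str, ...],
    delta: float,
    leaves: Sequence[str],
    rng: np.random.Generator,
) -> frozenset[str]:
    """Independently replace a fraction delta of a duplicate's true terms."""
    n_swap = int(round(delta * len(true_terms)))
    if n_swap == 0:
        return frozenset(true_terms)
    keep = list(true_terms)
    swap_idx = rng.choice(len(keep), size=n_swap, replace=False)
    pool = [t for t in leaves if t not in true_terms]
    new_terms = rng.choice(len(pool), size=min(n_swap, len(pool)), replace=False)
    for i, j in zip(swap_idx, new_terms):
        keep[i] = pool[j]
    return frozenset(keep)


def generate_families(
    config: SimulationConfig, graph: OntologyGraph, seed: int
) -> FamilySet:
    """Draw gene families with known homology classes and true term sets.

    Every family has one gene per species (an ortholog pair). With
    probability ``p_dup`` the family carries a duplication: pre-speciation
    (probability ``p_pre``) yields a second ortholog pair plus within- and
    between-species outparalogs; post-speciation yields an inparalog in one
    species (itself an ortholog of the other species' gene). Duplicate
    genes resample a fraction ``delta`` of the family's true terms; at
    ``delta = 0`` true function is identical across the family.
    """
    rng = np.random.default_rng(seed)
    leaves = leaf_terms(graph)
    genes: list[SimGene] = []
    pairs: list[HomologPair] = []
    for fam in range(config.n_families):
        base = tuple(
            leaves[i]
            for i in rng.choice(len(leaves), size=config.m_terms, replace=False)
        )
        a0 = SimGene(f"F{fam:04d}_A0", SPECIES_A, fam, frozenset(base))
        b0 = SimGene(f"F{fam:04d}_B0", SPECIES_B, fam, frozenset(base))
        genes += [a0, b0]
        pairs.append(
            HomologPair(a0.gene_id, SPECIES_A, b0.gene_id, SPECIES_B, "ortholog")
        )
        if rng.random() >= config.p_dup:
            continue
        if rng.random() < config.p_pre:
            # pre-speciation duplication: both species carry both copies
            a1 = SimGene(
                f"F{fam:04d}_A1",
                SPECIES_A,
                fam,
                _resample(base, config.delta, leaves, rng),
            )
            b1 = SimGene(
                f"F{fam:04d}_B1",
                SPECIES_B,
                fam,
                _resample(base, config.delta, leaves, rng),
            )
            genes += [a1, b1]
            pairs += [
                HomologPair(a1.gene_id, SPECIES_A, b1.gene_id, SPECIES_B, "ortholog"),
                HomologPair(
                    a0.gene_id, SPECIES_A, a1.gene_id, SPECIES_A,
                    "within_species_outparalog",
                ),
                HomologPair(
                    b0.gene_id, SPECIES_B, b1.gene_id, SPECIES_B,
                    "within_species_outparalog",
                ),
                HomologPair(
                    a0.gene_id, SPECIES_A, b1.gene_id, SPECIES_B,
                    "between_species_outparalog",
                ),
                HomologPair(
                    a1.gene_id, SPECIES_A, b0.gene_id, SPECIES_B,
                    "between_species_outparalog",
                ),
            ]
        else:
            # post-speciation duplication in one species, chosen at random
            sp = SPECIES_A if rng.random() < 0.5 else SPECIES_B
            original = a0 if sp == SPECIES_A else b0
            partner = b0 if sp == SPECIES_A else a0
            dup = SimGene(
                f"F{fam:04d}_{'A' if sp == SPECIES_A else 'B'}1",
                sp,
                fam,
                _resample(base, config.delta, leaves, rng),
            )
            genes.append(dup)
            pairs += [
                HomologPair(original.gene_id, sp, dup.gene_id, sp, "inparalog"),
                HomologPair(
                    dup.gene_id, sp, partner.gene_id, partner.species, "ortholog"
                ),
            ]
    return FamilySet(genes=genes, pairs=pairs)


# -- annotation sampling --------------------------------------------------


def sample_annotations(
    families: FamilySet,
    graph: OntologyGraph,
    config: SimulationConfig,
    seed: int,
) -> dict[str, AnnotationCorpus]:
    """Sample each species' annotation corpus under biased discovery.

    Each true leaf ``t`` of a gene in species ``s`` is annotated with
    probability ``q * w_s[theme(t)]``; a recorded annotation lands on a
    strict ancestor at uniform distance ``1..u`` (capped above the theme
    level, never the root) with probability ``r``, else on the leaf. All
    records carry evidence code IDA.
    """
    rng = np.random.default_rng(seed)
    w_by_species = {SPECIES_A: config.w_a, SPECIES_B: config.w_b}
    # unique root-ward path per term (the ontology is a tree)
    parent_of = {c: ps[0][0] for c, ps in graph.edges.items()}
    records: dict[str, list[Annotation]] = {SPECIES_A: [], SPECIES_B: []}
    for gene in families.genes:
        w = w_by_species[gene.species]
        for t in sorted(gene.true_terms):
            if rng.random() >= config.q * w[theme_index(graph, t)]:
                continue
            term = t
            if config.r > 0 and rng.random() < config.r:
                depth = graph.term_depth(t)
                max_dist = depth - 1  # stop at theme level, never the root
                dist = min(int(rng.integers(1, config.u + 1)), max_dist)
                for _ in range(dist):
                    term = parent_of[term]
            records[gene.species].append(
                Annotation(
                    gene_id=gene.gene_id,
                    gene_symbol=gene.gene_id,
                    species=gene.species,
                    term=term,
                    aspect="P",
                    evidence="IDA",
                    reference="SIM_REF:0000001",
                    db="SIM",
                    taxon=SIM_TAXA[gene.species],
                    date="20110910",
                    assigned_by="SIM",
                )
            )
    return {
        sp: AnnotationCorpus(
            annotations=recs, species=sp, source_label="simulated", gaf_version="2.1"
        )
        for sp, recs in records.items()
    }


# -- end-to-end experiment ------------------------------------------------


def run_bias_experiment(
    config: SimulationConfig,
    p_threshold: float = 1e-3,
    *,
    return_tables: bool = False,
):
    """Generate, sample, score and profile one simulated two-species study.

    Returns a :class:`BiasExperimentSummary`: mean jaccard congruence of
    within-species pairs (inparalogs + within-species outparalogs) vs
    between-species pairs (orthologs + between-species outparalogs), their
    gap, and how many themes each species' corpus overrepresents at
    ``p_threshold``. With ``return_tables=True`` also returns the scored
    pairs, class summary and enrichment tables.
    """
    ss = np.random.SeedSequence(config.seed)
    fam_seed, ann_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    graph = generate_ontology(config)
    families = generate_families(config, graph, fam_seed)
    corpora = sample_annotations(families, graph, config, ann_seed)
    results = score_pairs(families.pairs, corpora, graph, "P", "jaccard")
    df = results_frame(results)
    within = df.loc[
        df["pair_class"].isin(("inparalog", "within_species_outparalog")), "score"
    ].dropna()
    between = df.loc[
        df["pair_class"].isin(("ortholog", "between_species_outparalog")), "score"
    ].dropna()
    mean_within = float(within.mean()) if len(within) else math.nan
    mean_between = float(between.mean()) if len(between) else math.nan

    counts_a = term_counts(corpora[SPECIES_A], graph, "P")
    counts_b = term_counts(corpora[SPECIES_B], graph, "P")
    rows = overrepresentation(counts_a, counts_b, graph=graph)
    themes = set(theme_terms(graph).values())
    n_over_a = sum(1 for r in rows if r.term in themes and r.p_over_a < p_threshold)
    n_over_b = sum(1 for r in rows if r.term in themes and r.p_over_b < p_threshold)

    summary = BiasExperimentSummary(
        mean_within=mean_within,
        mean_between=mean_between,
        gap=mean_within - mean_between,
        n_within=int(len(within)),
        n_between=int(len(between)),
        n_themes_over_a=n_over_a,
        n_themes_over_b=n_over_b,
        p_threshold=p_threshold,
        config=config,
    )
    if return_tables:
        return summary, df, class_summary(results), rows
    return summary
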