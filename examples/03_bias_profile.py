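"""Cross-species term overrepresentation on a simulated pair of corpora.

Samples two species' annotations from the same ground-truth gene functions
but with complementary per-theme experiment propensities, then asks which
terms are overrepresented in each corpus under the hypergeometric null —
the same computation one would run on real human vs mouse experimental
annotation sets.
"""

from gocongruence import (
    SimulationConfig,
    enrichment_frame,
    generate_families,
    generate_ontology,
    overrepresentation,
    sample_annotations,
    term_counts,
)
from gocongruence.synthetic_data import SPECIES_A, SPECIES_B

cfg = SimulationConfig(
    n_families=300, w_a=(1.0, 0.25), w_b=(0.25, 1.0), seed=5
)
graph = generate_ontology(cfg)
families = generate_families(cfg, graph, seed=50)
corpora = sample_annotations(families, graph, cfg, seed=51)

counts_a = term_counts(corpora[SPECIES_A], graph, "P", "gene_term_pairs")
counts_b = term_counts(corpora[SPECIES_B], graph, "P", "gene_term_pairs")
rows = overrepresentation(counts_a, counts_b, correction="none", min_count=5, graph=graph)

df = enrichment_frame(rows)
print(df.head(8).to_string(index=False))
print()
print(
    "count_a/count_b are distinct gene-term pairs after closure; p_over_a\n"
    "is the upper hypergeometric tail for overrepresentation in species A.\n"
    "The theme terms (depth-1) top the ranking in opposite directions —\n"
    "a pure ascertainment artifact, since every family's true function is\n"
    "identical across species here."
)
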