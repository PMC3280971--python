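"""End-to-end ascertainment-bias experiment: null vs biased annotation sampling.

Runs the full pipeline (generate ontology and families, sample biased
annotations, score homolog pairs, profile theme overrepresentation) under
two conditions with *identical, perfectly conserved* true gene functions:

* null — both species probe the ontology's themes equally;
* biased — species A's experiments favor theme 0, species B's theme 1.

Only the biased condition opens a within-species vs between-species
congruence gap, reproducing how species-specific experimental bias can
masquerade as functional divergence between orthologs.
"""

from gocongruence import SimulationConfig, run_bias_experiment

for label, w_a, w_b in (
    ("null  ", (1.0, 1.0), (1.0, 1.0)),
    ("biased", (1.0, 0.2), (0.2, 1.0)),
):
    cfg = SimulationConfig(n_families=500, delta=0.0, w_a=w_a, w_b=w_b, seed=1)
    s = run_bias_experiment(cfg, p_threshold=1e-3)
    print(
        f"{label}  within={s.mean_within:.3f}  between={s.mean_between:.3f}  "
        f"gap={s.gap:+.3f}  themes flagged: A={s.n_themes_over_a} B={s.n_themes_over_b}"
    )

print()
print(
    "'within'/'between' are mean jaccard congruences for same-species vs\n"
    "cross-species homolog pairs; 'themes flagged' counts depth-1 themes\n"
    "overrepresented in each species' corpus at p < 1e-3. delta=0 means no\n"
    "gene diverged in true function: the biased-condition gap is entirely\n"
    "annotation ascertainment."
)
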