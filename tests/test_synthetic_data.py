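"""The ascertainment-bias generator: ontology, families, sampling, experiment."""

import io

import numpy as np
import pytest

from gocongruence import (
    SimulationConfig,
    closed_sets,
    generate_families,
    generate_ontology,
    generate_ontology_obo,
    parse_gaf,
    run_bias_experiment,
    sample_annotations,
    write_gaf,
)
from gocongruence.synthetic_data import (
    SIM_TAXON_LABELS,
    SPECIES_A,
    SPECIES_B,
    leaf_terms,
    theme_index,
    theme_terms,
)


def small_config(**kwargs) -> SimulationConfig:
    defaults = dict(branching=2, depth=3, n_themes=2, n_families=40, seed=11)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateOntology:
    def test_term_count_for_tiny_tree(self):
        cfg = SimulationConfig(branching=2, depth=2, n_themes=2)
        graph = generate_ontology(cfg)
        # 1 root + 2 themes + 4 leaves
        assert len(graph.terms) == 7
        assert len(graph.roots) == 1
        assert len(leaf_terms(graph)) == 4

    def test_emitted_obo_is_deterministic(self):
        cfg = small_config()
        assert generate_ontology_obo(cfg) == generate_ontology_obo(cfg)

    def test_every_term_reaches_root(self):
        graph = generate_ontology(small_config())
        root = graph.roots[0]
        for tid in graph.terms:
            assert root in graph.ancestors(tid)

    def test_theme_partition(self):
        graph = generate_ontology(small_config())
        themes = theme_terms(graph)
        assert set(themes) == {0, 1}
        for leaf in leaf_terms(graph):
            j = theme_index(graph, leaf)
            assert themes[j] in graph.ancestors(leaf)


class TestGenerateFamilies:
    def test_conservation_null_all_sets_identical(self):
        cfg = small_config(delta=0.0, p_dup=1.0)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=3)
        by_family = {}
        for g in fams.genes:
            by_family.setdefault(g.family, set()).add(g.true_terms)
        assert all(len(s) == 1 for s in by_family.values())

    def test_no_duplication_gives_only_orthologs(self):
        cfg = small_config(p_dup=0.0)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=3)
        assert {p.pair_class for p in fams.pairs} == {"ortholog"}
        assert len(fams.pairs) == cfg.n_families

    def test_delta_resamples_duplicates(self):
        cfg = small_config(delta=1.0, p_dup=1.0, m_terms=3)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=3)
        originals = {g.gene_id: g for g in fams.genes}
        diverged = [
            g for g in fams.genes
            if g.gene_id.endswith("1")
            and g.true_terms != originals[g.gene_id[:-1] + "0"].true_terms
        ]
        assert diverged  # with delta=1 duplicates must differ

    def test_pair_species_constraints_hold(self):
        cfg = small_config(p_dup=1.0, p_pre=0.5)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=5)
        # HomologPair's validator enforces the constraints at construction;
        # here we check all four classes actually occur
        classes = {p.pair_class for p in fams.pairs}
        assert classes == {
            "ortholog",
            "inparalog",
            "within_species_outparalog",
            "between_species_outparalog",
        }


class TestSampleAnnotations:
    def test_no_noise_limit_recovers_true_sets(self):
        cfg = small_config(q=1.0, r=0.0)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=2)
        corpora = sample_annotations(fams, graph, cfg, seed=4)
        for sp in (SPECIES_A, SPECIES_B):
            sets = closed_sets(corpora[sp], graph, "P")
            for gene in fams.genes:
                if gene.species != sp:
                    continue
                assert sets[gene.gene_id].direct_terms == gene.true_terms

    def test_full_truncation_leaves_no_leaf_annotations(self):
        cfg = small_config(q=1.0, r=1.0, u=1)
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=2)
        corpora = sample_annotations(fams, graph, cfg, seed=4)
        leaves = set(leaf_terms(graph))
        for corpus in corpora.values():
            assert all(a.term not in leaves for a in corpus)

    def test_truncation_never_hits_root(self):
        cfg = small_config(q=1.0, r=1.0, u=10)  # u far beyond the depth
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=2)
        corpora = sample_annotations(fams, graph, cfg, seed=4)
        root = graph.roots[0]
        for corpus in corpora.values():
            assert all(a.term != root for a in corpus)

    def test_extreme_bias_partitions_themes(self):
        cfg = small_config(q=1.0, r=0.0, w_a=(1.0, 0.0), w_b=(0.0, 1.0))
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=2)
        corpora = sample_annotations(fams, graph, cfg, seed=4)
        for a in corpora[SPECIES_A]:
            assert theme_index(graph, a.term) == 0
        for b in corpora[SPECIES_B]:
            assert theme_index(graph, b.term) == 1

    def test_corpora_round_trip_through_gaf(self):
        cfg = small_config()
        graph = generate_ontology(cfg)
        fams = generate_families(cfg, graph, seed=2)
        corpora = sample_annotations(fams, graph, cfg, seed=4)
        corpus = corpora[SPECIES_A]
        buf = io.StringIO()
        write_gaf(corpus, buf)
        back = parse_gaf(buf.getvalue(), taxon_labels=SIM_TAXON_LABELS)
        assert back.species == SPECIES_A
        assert [(a.gene_id, a.term) for a in back] == [
            (a.gene_id, a.term) for a in corpus
        ]


class TestConfig:
    def test_w_vectors_max_normalized(self):
        cfg = SimulationConfig(w_a=(2.0, 1.0), w_b=(0.5, 0.1))
        assert cfg.w_a == (1.0, 0.5)
        assert max(cfg.w_b) == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(q=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(delta=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(depth=1)
        with pytest.raises(ValueError):
            SimulationConfig(w_a=(1.0,), n_themes=2)

    def test_flat_round_trip(self):
        cfg = SimulationConfig(seed=9, w_a=(1.0, 0.2), w_b=(0.2, 1.0), delta=0.25)
        assert SimulationConfig.from_flat(cfg.to_flat()) == cfg


class TestRunBiasExperiment:
    def test_determinism(self):
        cfg = small_config(n_families=60)
        s1 = run_bias_experiment(cfg)
        s2 = run_bias_experiment(cfg)
        assert s1 == s2

    def test_seed_changes_outcome(self):
        a = run_bias_experiment(small_config(seed=1, n_families=60))
        b = run_bias_experiment(small_config(seed=2, n_families=60))
        assert (a.mean_within, a.mean_between) != (b.mean_within, b.mean_between)

    def test_bias_direction_monotone_in_w_divergence(self):
        """More divergent propensity vectors never shrink the expected
        within-vs-between gap (3-point grid, averaged over seeds)."""
        grid = [0.0, 0.5, 0.9]
        mean_gaps = []
        for eps in grid:
            gaps = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_families=120,
                    w_a=(1.0, 1.0 - eps),
                    w_b=(1.0 - eps, 1.0),
                    seed=seed,
                )
                gaps.append(run_bias_experiment(cfg).gap)
            mean_gaps.append(float(np.mean(gaps)))
        assert mean_gaps[0] <= mean_gaps[1] + 0.02
        assert mean_gaps[1] <= mean_gaps[2] + 0.02
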