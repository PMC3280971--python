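"""Congruence scoring, class summaries, and the divergence screen."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from gocongruence import (
    AspectMismatchError,
    ClosedAnnotationSet,
    HomologPair,
    class_summary,
    congruence_score,
    divergence_screen,
    load_fixture,
    parse_gaf,
    read_pairs_tsv,
    score_pairs,
    write_pairs_tsv,
)

from conftest import GAF_HEADER, gaf_row, gid


def make_set(gene, terms, aspect="P", direct=None, negated=(), species="x"):
    return ClosedAnnotationSet(
        gene_id=gene,
        aspect=aspect,
        direct_terms=frozenset(direct if direct is not None else terms),
        closed_terms=frozenset(terms),
        negated_terms=frozenset(negated),
        species=species,
    )


class TestCongruenceScore:
    @pytest.mark.parametrize("norm", ["jaccard", "min", "max"])
    def test_identical_sets_score_one(self, norm):
        a = make_set("A", {"x", "y", "z"})
        b = make_set("B", {"x", "y", "z"})
        assert congruence_score(a, b, norm).score == 1.0

    @pytest.mark.parametrize("norm", ["jaccard", "min", "max"])
    def test_disjoint_sets_score_zero(self, norm):
        res = congruence_score(make_set("A", {"x", "y"}), make_set("B", {"u", "v"}), norm)
        assert res.score == 0.0
        assert res.n_shared == 0

    def test_normalization_denominators(self):
        a, b = make_set("A", {"x", "y", "z"}), make_set("B", {"x", "u"})
        assert congruence_score(a, b, "jaccard").score == pytest.approx(1 / 4)
        assert congruence_score(a, b, "min").score == pytest.approx(1 / 2)
        assert congruence_score(a, b, "max").score == pytest.approx(1 / 3)

    def test_empty_set_gives_na_not_zero(self):
        res = congruence_score(make_set("A", set()), make_set("B", {"x"}))
        assert res.is_na
        assert res.na_reason == "empty_set"

    def test_aspect_mismatch_rejected(self):
        with pytest.raises(AspectMismatchError):
            congruence_score(make_set("A", {"x"}, aspect="P"), make_set("B", {"x"}, aspect="F"))

    @pytest.mark.parametrize("norm", ["jaccard", "min", "max"])
    def test_symmetry(self, norm):
        a, b = make_set("A", {"x", "y", "z"}), make_set("B", {"y", "u"})
        assert congruence_score(a, b, norm).score == congruence_score(b, a, norm).score

    def test_jaccard_monotonicity(self):
        base_a, base_b = {"x", "y"}, {"y", "z"}
        s0 = congruence_score(make_set("A", base_a), make_set("B", base_b)).score
        # shared term never decreases the score
        s_shared = congruence_score(
            make_set("A", base_a | {"w"}), make_set("B", base_b | {"w"})
        ).score
        assert s_shared >= s0
        # one-sided term never increases it
        s_onesided = congruence_score(
            make_set("A", base_a | {"q"}), make_set("B", base_b)
        ).score
        assert s_onesided <= s0

    def test_nuclear_receptor_fixture_scores(self):
        """Mouse Thra scores higher with its paralog Esr1 than its ortholog THRA."""
        fx = load_fixture("table2")
        s_paralog = congruence_score(fx["Thra"], fx["Esr1"])
        s_ortholog = congruence_score(fx["Thra"], fx["THRA"])
        assert s_paralog.score == pytest.approx(Fraction(10, 17))
        assert s_ortholog.score == pytest.approx(Fraction(11, 24))
        assert s_paralog.score > s_ortholog.score

    def test_map4k_fixture_ortholog_overlap_is_one_broad_term(self):
        fx = load_fixture("table1")
        res = congruence_score(fx["MAP4K2"], fx["Map4k2"])
        assert res.n_shared == 1
        assert fx["MAP4K2"].closed_terms & fx["Map4k2"].closed_terms == {"GO:0009987"}


term_sets = st.sets(st.sampled_from([f"GO:{i:07d}" for i in range(2, 14)]))


@given(a=term_sets, b=term_sets)
@settings(max_examples=200, deadline=None, derandomize=True)
@pytest.mark.parametrize("norm", ["jaccard", "min", "max"])
def test_score_range_symmetry_and_equality(norm, a, b):
    """S ∈ [0,1] or NA; symmetric; jaccard S=1 exactly for equal non-empty sets."""
    res_ab = congruence_score(make_set("A", a), make_set("B", b), norm)
    res_ba = congruence_score(make_set("B", b), make_set("A", a), norm)
    if not a or not b:
        assert res_ab.is_na and res_ba.is_na
    else:
        assert 0.0 <= res_ab.score <= 1.0
        assert res_ab.score == res_ba.score
        if norm == "jaccard":
            assert (res_ab.score == 1.0) == (a == b)


class TestScorePairs:
    def test_identical_annotations_across_species(self, chain_graph):
        corpora = {
            "human": parse_gaf(GAF_HEADER + gaf_row("G1", gid(3))),
            "mouse": parse_gaf(GAF_HEADER + gaf_row("g1", gid(3), taxon="taxon:10090")),
        }
        pairs = [HomologPair("G1", "human", "g1", "mouse", "ortholog")]
        (res,) = score_pairs(pairs, corpora, chain_graph, "P")
        assert res.score == 1.0

    def test_unannotated_partner_is_na(self, chain_graph):
        corpora = {
            "human": parse_gaf(GAF_HEADER + gaf_row("G1", gid(3))),
            "mouse": parse_gaf(GAF_HEADER, species="mouse"),
        }
        pairs = [HomologPair("G1", "human", "absent", "mouse", "ortholog")]
        (res,) = score_pairs(pairs, corpora, chain_graph, "P")
        assert res.is_na
        assert res.na_reason == "unannotated"

    def test_unknown_species_named_in_error(self, chain_graph):
        pairs = [HomologPair("G1", "human", "g1", "marmoset", "ortholog")]
        with pytest.raises(KeyError, match="marmoset"):
            score_pairs(pairs, {"human": parse_gaf(GAF_HEADER, species="human")},
                        chain_graph, "P")

    def test_pair_class_species_constraints(self):
        with pytest.raises(ValueError):
            HomologPair("a", "human", "b", "human", "ortholog")
        with pytest.raises(ValueError):
            HomologPair("a", "human", "b", "mouse", "inparalog")
        with pytest.raises(ValueError):
            HomologPair("a", "human", "b", "mouse", "within_species_outparalog")
        with pytest.raises(ValueError):
            HomologPair("a", "human", "b", "human", "between_species_outparalog")


class TestClassSummary:
    def test_means_and_gap_arithmetic(self):
        from gocongruence.congruence import CongruenceResult

        def res(cls, score, cross):
            pair = HomologPair("A", "h", "B", "m" if cross else "h", cls)
            return CongruenceResult(pair, "P", score, 2, 2, 1, "jaccard")

        results = [
            res("ortholog", 0.2, True),
            res("ortholog", 0.4, True),
            res("inparalog", 0.8, False),
            res("inparalog", 1.0, False),
        ]
        df = class_summary(results).set_index("group")
        assert df.loc["ortholog", "mean"] == pytest.approx(0.3)
        assert df.loc["inparalog", "mean"] == pytest.approx(0.9)
        assert df.loc["within_minus_between", "mean"] == pytest.approx(0.6)

    def test_na_excluded_and_counted(self):
        from gocongruence.congruence import CongruenceResult

        pair = HomologPair("A", "h", "B", "m", "ortholog")
        results = [
            CongruenceResult(pair, "P", 0.5, 2, 2, 1, "jaccard"),
            CongruenceResult(pair, "P", math.nan, 0, 2, 0, "jaccard", "unannotated"),
        ]
        df = class_summary(results).set_index("group")
        assert df.loc["ortholog", "n"] == 2
        assert df.loc["ortholog", "n_na"] == 1
        assert df.loc["ortholog", "mean"] == pytest.approx(0.5)


class TestDivergenceScreen:
    def _corpora(self, rows_human, rows_mouse):
        return {
            "human": parse_gaf(GAF_HEADER + "".join(rows_human), species="human"),
            "mouse": parse_gaf(GAF_HEADER + "".join(rows_mouse), species="mouse"),
        }

    def test_direct_contradiction_yields_one_row(self, chain_graph):
        corpora = self._corpora(
            [gaf_row("G1", gid(2))],
            [gaf_row("g1", gid(2), qualifier="NOT", taxon="taxon:10090")],
        )
        pairs = [HomologPair("G1", "human", "g1", "mouse", "ortholog")]
        df = divergence_screen(pairs, corpora, chain_graph, "P")
        assert len(df) == 1
        assert df.iloc[0]["not_term"] == gid(2)
        assert df.iloc[0]["gene_negative"] == "g1"

    def test_descendant_rule(self, chain_graph):
        # human positive for parent gid(2); mouse NOT child gid(3)
        corpora = self._corpora(
            [gaf_row("G1", gid(2))],
            [gaf_row("g1", gid(3), qualifier="NOT", taxon="taxon:10090")],
        )
        pairs = [HomologPair("G1", "human", "g1", "mouse", "ortholog")]
        df = divergence_screen(pairs, corpora, chain_graph, "P")
        assert len(df) == 1
        assert df.iloc[0]["not_term"] == gid(3)
        assert gid(2) in df.iloc[0]["positive_terms"]

    def test_no_not_rows_empty_table(self, chain_graph):
        corpora = self._corpora(
            [gaf_row("G1", gid(2))],
            [gaf_row("g1", gid(3), taxon="taxon:10090")],
        )
        pairs = [HomologPair("G1", "human", "g1", "mouse", "ortholog")]
        assert divergence_screen(pairs, corpora, chain_graph, "P").empty

    def test_unrelated_not_does_not_fire(self, diamond_graph):
        # human positive only under branch b (gid 2); mouse NOT on branch c
        corpora = self._corpora(
            [gaf_row("G1", gid(2))],
            [gaf_row("g1", gid(3), qualifier="NOT", taxon="taxon:10090")],
        )
        pairs = [HomologPair("G1", "human", "g1", "mouse", "ortholog")]
        assert divergence_screen(pairs, corpora, diamond_graph, "P").empty


class TestPairsTsv:
    def test_round_trip(self, tmp_path):
        pairs = [
            HomologPair("G1", "human", "g1", "mouse", "ortholog"),
            HomologPair("G1", "human", "G2", "human", "within_species_outparalog"),
        ]
        path = tmp_path / "pairs.tsv"
        with open(path, "w") as fh:
            write_pairs_tsv(pairs, fh)
        with open(path) as fh:
            assert read_pairs_tsv(fh) == pairs
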