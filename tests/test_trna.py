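import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolfit.trna import (
    UNKNOWN,
    TgcnVector,
    TrnaGene,
    build_tgcn,
    combine_pools,
    merge_predictions,
    normalize_anticodon,
    parse_aragorn,
    parse_trna_tsv,
    parse_trnascan,
    write_trna_tsv,
)


def P(start, anticodon="GAA", isotype="Phe", strand="+", pseudo=False):
    return TrnaGene("g1", start, start + 75, strand, anticodon, isotype, "tRNAscan-SE", pseudo)


def Q(start, anticodon="GAA", isotype="Phe", strand="+"):
    return TrnaGene("g1", start, start + 75, strand, anticodon, isotype, "Aragorn")


def undet(start):
    return TrnaGene("g1", start, start + 75, "+", UNKNOWN, "Undet", "tRNAscan-SE")


class TestMergeRules:
    def test_same_anticodon_within_window_keeps_aragorn_location(self):
        merged = merge_predictions([P(100)], [Q(103)], window=10)
        assert len(merged) == 1
        assert merged[0].start == 103 and merged[0].source == "Aragorn"

    def test_cat_anticodon_keeps_scan_call(self):
        p = P(200, anticodon="CAT", isotype="Met")
        merged = merge_predictions([p], [Q(205, anticodon="CAT", isotype="Met")], window=10)
        assert merged == [p]

    def test_undetermined_scan_replaced_by_aragorn(self):
        merged = merge_predictions([undet(50)], [Q(52, anticodon="TGC", isotype="Ala")], window=10)
        assert len(merged) == 1
        assert merged[0].anticodon == "TGC" and merged[0].source == "Aragorn"

    def test_undetermined_outranks_cat_rule(self):
        # an undetermined structure-aware call carries no isotype worth keeping
        merged = merge_predictions([undet(50)], [Q(52, anticodon="CAT", isotype="Met")], window=10)
        assert merged[0].source == "Aragorn" and merged[0].anticodon == "CAT"

    def test_empty_scan_side_returns_aragorn_unchanged(self):
        qs = [Q(10), Q(200, "TGC", "Ala"), Q(400, "CAT", "Met")]
        assert merge_predictions([], qs) == sorted(qs, key=lambda g: g.start)

    def test_outside_window_both_kept(self):
        merged = merge_predictions([P(100)], [Q(115)], window=10)
        assert len(merged) == 2

    def test_different_strand_not_matched(self):
        merged = merge_predictions([P(100)], [Q(103, strand="-")], window=10)
        assert len(merged) == 2

    def test_greedy_prefers_smallest_offset(self):
        # two scan calls compete for one aragorn call: the closer one wins
        merged = merge_predictions([P(100), P(105)], [Q(103)], window=10)
        starts = sorted(g.start for g in merged)
        assert starts == [100, 103]  # P(105) collapsed into Q(103); P(100) kept

    def test_mixed_seq_ids_error(self):
        other = TrnaGene("g2", 5, 80, "+", "GAA", "Phe", "Aragorn")
        with pytest.raises(ValueError, match="seq_id"):
            merge_predictions([P(1)], [other])

    def test_negative_window_error(self):
        with pytest.raises(ValueError):
            merge_predictions([P(1)], [Q(1)], window=-1)


anticodons = st.sampled_from(["GAA", "TGC", "CAT", "TTC", "GGG"])
gene_sets = st.lists(
    st.builds(
        lambda s, ac, und: undet(s) if und else P(s, ac, "Met" if ac == "CAT" else "Xxx"),
        st.integers(1, 400),
        anticodons,
        st.booleans(),
    ),
    max_size=8,
)
q_sets = st.lists(
    st.builds(lambda s, ac: Q(s, ac, "Met" if ac == "CAT" else "Xxx"),
              st.integers(1, 400), anticodons),
    max_size=8,
)


class TestMergeProperties:
    @given(gene_sets, q_sets)
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_bounded(self, ps, qs):
        merged = merge_predictions(ps, qs, window=10)
        assert max(len(ps), 0) <= len(ps) + len(qs)
        assert len(merged) <= len(ps) + len(qs)
        again_q = merge_predictions(merged, qs, window=10)
        assert again_q == merged
        again_p = merge_predictions(ps, merged, window=10)
        assert again_p == merged

    @given(gene_sets, q_sets)
    @settings(max_examples=100, deadline=None)
    def test_never_invents_anticodons(self, ps, qs):
        seen = {g.anticodon for g in ps} | {g.anticodon for g in qs}
        assert all(g.anticodon in seen for g in merge_predictions(ps, qs))


class TestBuildTgcn:
    def test_counts_per_anticodon(self):
        v = build_tgcn([P(1), P(100), P(200, "TGC", "Ala")])
        assert v.copies == {"GAA": 2, "TGC": 1}

    def test_empty_input_gives_zero_vector(self):
        assert build_tgcn([]).copies == {}

    def test_unknown_and_pseudo_accounting(self):
        genes = [P(1), undet(100), P(200, pseudo=True), P(300, "TGC", "Ala")]
        v = build_tgcn(genes)
        assert v.total == 2  # 1 unknown + 1 pseudo excluded
        assert build_tgcn(genes, include_pseudo=True).total == 3

    @given(st.lists(st.tuples(anticodons, st.booleans(), st.booleans()), max_size=30))
    def test_total_accounting_property(self, gene_specs):
        genes = [
            TrnaGene("g1", 10 * i + 1, 10 * i + 76, "+",
                     UNKNOWN if unk else ac, "Undet" if unk else "Xxx",
                     "tRNAscan-SE", pseudo)
            for i, (ac, unk, pseudo) in enumerate(gene_specs)
        ]
        v = build_tgcn(genes)
        n_pseudo = sum(1 for _, _, p in gene_specs if p)
        n_unknown = sum(1 for _, u, p in gene_specs if u and not p)
        assert v.total + n_unknown + n_pseudo == len(genes)


class TestCombinePools:
    def test_elementwise_sum(self):
        out = combine_pools(TgcnVector({"GAA": 1}), TgcnVector({"GAA": 2, "TGC": 1}))
        assert out.copies == {"GAA": 3, "TGC": 1}

    @given(st.dictionaries(anticodons, st.integers(0, 9)),
           st.dictionaries(anticodons, st.integers(0, 9)))
    def test_commutative_with_zero_identity(self, a, b):
        va, vb = TgcnVector(dict(a)), TgcnVector(dict(b))
        ab, ba = combine_pools(va, vb), combine_pools(vb, va)
        assert {k: v for k, v in ab.copies.items() if v} == {k: v for k, v in ba.copies.items() if v}
        assert combine_pools(va, TgcnVector({})).copies == va.copies


SCAN_OUT = """\
Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf
Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore
--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----
phageA\t1\t100\t175\tPhe\tGAA\t0\t0\t75.2
phageA\t2\t300\t225\tMet\tCAT\t0\t0\t60.1
phageA\t3\t500\t572\tUndet\t???\t0\t0\t30.0
phageA\t4\t700\t772\tAla\tTGC\t0\t0\t22.1\tpseudo
"""

ARAGORN_OUT = """\
>phageA
4 genes found
1   tRNA-Phe               [103,178]      35      (gaa)
2   tRNA-Met              c[225,300]      35      (cat)
3   tRNA-Ala               [502,574]      35      (ugc)
4   tmRNA                  [900,1200]     90,123  ANDNRVSA*
"""


class TestParsers:
    def test_trnascan_fields(self, tmp_path):
        p = tmp_path / "scan.out"
        p.write_text(SCAN_OUT)
        genes = parse_trnascan(p)
        assert len(genes) == 4
        phe, met, und, ala = genes
        assert (phe.start, phe.end, phe.strand, phe.anticodon) == (100, 175, "+", "GAA")
        assert met.strand == "-" and met.start == 225 and met.anticodon == "CAT"
        assert und.isotype == "Undet" and und.anticodon == UNKNOWN
        assert ala.pseudo

    def test_aragorn_fields_and_tmrna_excluded(self, tmp_path):
        p = tmp_path / "aragorn.out"
        p.write_text(ARAGORN_OUT)
        genes = parse_aragorn(p)
        assert len(genes) == 3  # tmRNA dropped: not part of the translational pool
        assert genes[0].seq_id == "phageA"
        assert (genes[0].start, genes[0].anticodon) == (103, "GAA")
        assert genes[1].strand == "-"
        assert genes[2].anticodon == "TGC"  # RNA alphabet normalized to DNA

    def test_parsed_outputs_merge(self, tmp_path):
        (tmp_path / "s").write_text(SCAN_OUT)
        (tmp_path / "a").write_text(ARAGORN_OUT)
        merged = merge_predictions(parse_trnascan(tmp_path / "s"),
                                   parse_aragorn(tmp_path / "a"), window=10)
        v = build_tgcn(merged)
        # Phe collapses to Aragorn, Met keeps the scan call (CAT), Undet
        # becomes Aragorn's Ala; the pseudo scan call is excluded from pools
        assert v.copies == {"GAA": 1, "CAT": 1, "TGC": 1}

    def test_tsv_round_trip(self, tmp_path):
        genes = [P(100), Q(300, "TGC", "Ala"), undet(500), P(700, pseudo=True)]
        path = tmp_path / "genes.tsv"
        write_trna_tsv(genes, path)
        assert parse_trna_tsv(path) == genes

    def test_tsv_missing_column_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("seq_id\tstart\tend\n")
        with pytest.raises(ValueError, match="source"):
            parse_trna_tsv(p)


@pytest.mark.parametrize(
    "raw,expected",
    [("gaa", "GAA"), ("UGC", "TGC"), ("???", UNKNOWN), ("", UNKNOWN), (None, UNKNOWN)],
)
def test_normalize_anticodon(raw, expected):
    assert normalize_anticodon(raw) == expected
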