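"""QC rules: TMR prediction, lipobox detection, and type classifiers."""

import itertools

import numpy as np
import pytest

from lysismine.lysclass import (
    KYTE_DOOLITTLE,
    DomainHit,
    SpaninComplex,
    SpaninComponent,
    classify_endolysin,
    classify_holin,
    classify_spanin,
    detect_lipobox,
    predict_tmrs,
    summarize_lysis_systems,
)

from oracles import tmr_scan_oracle


def dom(category, family=None, start=0, end=18):
    return DomainHit(family=family or category, category=category, start=start, end=end)


class TestTMR:
    def test_single_leucine_block(self):
        protein = "M" + "L" * 25 + "E" * 20
        segs = predict_tmrs(protein)
        assert len(segs) == 1
        assert segs[0].start <= 1 and segs[0].end >= 24

    def test_all_glutamate_cold(self):
        assert predict_tmrs("E" * 60) == []

    def test_two_blocks_with_serine_linker(self):
        protein = "L" * 21 + "S" * 15 + "L" * 21
        assert len(predict_tmrs(protein)) == 2

    def test_short_protein_no_segments(self):
        assert predict_tmrs("LLLLL") == []

    def test_agrees_with_window_scan_oracle_on_random_proteins(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            protein = "".join(rng.choice(aa, size=int(rng.integers(19, 200))))
            ours = [(s.start, s.end) for s in predict_tmrs(protein)]
            assert ours == tmr_scan_oracle(protein, KYTE_DOOLITTLE)


class TestLipobox:
    def test_canonical_lipobox(self):
        assert detect_lipobox("MKKLLAGCDDEEDDEE") == 7

    def test_no_cysteine_in_window(self):
        assert detect_lipobox("MKK" + "D" * 50 + "C") is None

    def test_cys_too_early_for_pattern(self):
        assert detect_lipobox("MCCDDDEEE") is None

    def test_cys_beyond_scan_window(self):
        protein = "M" + "D" * 45 + "LAGC" + "D" * 10
        assert detect_lipobox(protein) is None


class TestEndolysin:
    @pytest.mark.parametrize(
        "cats,subclass",
        [
            (["amidase"], "amidase"),
            (["muramidase"], "muramidase"),
            (["amidase", "endopeptidase"], "m-EAD"),
            (["amidase", "amidase"], "amidase"),  # repeat category collapses
            (["CBD"], "s-CBD"),
            (["other"], "unclassified"),
        ],
    )
    def test_subclass_assignment(self, cats, subclass):
        rec = classify_endolysin("p", [dom(c, family=f"f{i}") for i, c in enumerate(cats)], [])
        assert rec.verdict == "pass" and rec.subclass == subclass

    def test_val_hit_rejected(self):
        rec = classify_endolysin("p", [dom("amidase"), dom("VAL-structural")], [])
        assert rec.verdict == "reject:VAL"

    def test_tmr_rejected(self):
        from lysismine.lysclass import TMRSegment

        rec = classify_endolysin("p", [dom("amidase")], [TMRSegment(5, 26, 3.0)])
        assert rec.verdict == "reject:TMR"

    def test_no_domain_rejected(self):
        assert classify_endolysin("p", [], []).verdict == "reject:no-domain"

    def test_order_invariance(self):
        domains = [dom("amidase", "f1"), dom("endopeptidase", "f2"), dom("CBD", "f3")]
        results = {
            (classify_endolysin("p", list(perm), []).subclass,
             classify_endolysin("p", list(perm), []).verdict)
            for perm in itertools.permutations(domains)
        }
        assert results == {("m-EAD", "pass")}


class TestHolin:
    @pytest.mark.parametrize("k,subclass", [(1, "TMRs-1"), (2, "TMRs-2"), (4, "TMRs-4"), (5, "TMRs-4+"), (7, "TMRs-4+")])
    def test_tmr_count_classes(self, k, subclass):
        from lysismine.lysclass import TMRSegment

        tmrs = [TMRSegment(i * 40, i * 40 + 21, 3.0) for i in range(k)]
        rec = classify_holin("p", tmrs)
        assert rec.verdict == "pass" and rec.subclass == subclass

    def test_no_tmr_rejected(self):
        assert classify_holin("p", []).verdict == "reject:no-TMR"


def comp(pid, start, end, protein):
    return SpaninComponent(pid, start, end, "+", protein)


INNER = "M" + "DDDD" + "L" * 21 + "E" * 60  # one TMR, no lipobox
OUTER = "M" + "D" * 14 + "LAGC" + "E" * 40  # lipobox at 18, no TMR
PLAIN = "M" + "D" * 80  # neither feature


class TestSpanin:
    def test_separated_pair(self):
        cx = SpaninComplex([comp("i", 0, 300, INNER), comp("o", 400, 600, OUTER)])
        assert cx.arrangement == "separated"
        labels = {r.protein_id: r.subclass for r in classify_spanin(cx)}
        assert labels == {"i": "SIS", "o": "SOS"}

    def test_embedded_pair(self):
        cx = SpaninComplex([comp("i", 0, 600, INNER), comp("o", 200, 400, OUTER)])
        assert cx.arrangement == "embedded"
        labels = {r.protein_id: r.subclass for r in classify_spanin(cx)}
        assert labels == {"i": "EIS", "o": "EOS"}

    def test_overlapping_pair(self):
        cx = SpaninComplex([comp("i", 0, 400, INNER), comp("o", 300, 700, OUTER)])
        assert cx.arrangement == "overlapping"
        labels = {r.protein_id: r.subclass for r in classify_spanin(cx)}
        assert labels == {"i": "OIS", "o": "OOS"}

    def test_unimolecular(self):
        usp = "M" + "D" * 14 + "LAGC" + "D" * 30 + "L" * 21 + "D" * 10
        cx = SpaninComplex([comp("u", 0, 300, usp)])
        recs = classify_spanin(cx)
        assert recs[0].subclass == "USP" and recs[0].verdict == "pass"

    def test_unimolecular_lipobox_after_tmr_rejected(self):
        bad = "M" + "D" * 4 + "L" * 21 + "D" * 10 + "LAGC" + "D" * 30
        cx = SpaninComplex([comp("u", 0, 300, bad)])
        assert classify_spanin(cx)[0].verdict == "reject:no-lipobox"

    def test_pair_with_neither_tmr_rejected(self):
        cx = SpaninComplex([comp("a", 0, 250, PLAIN), comp("b", 400, 600, PLAIN)])
        verdicts = sorted(r.verdict for r in classify_spanin(cx))
        assert verdicts == ["reject:no-TMR", "reject:no-lipobox"]

    def test_mirrored_coordinates_keep_labels(self):
        """Reverse-complementing the genome mirrors intervals; labels hold."""
        L = 10_000
        fwd = SpaninComplex([comp("i", 100, 400, INNER), comp("o", 500, 700, OUTER)])
        rev = SpaninComplex(
            [
                SpaninComponent("i", L - 400, L - 100, "-", INNER),
                SpaninComponent("o", L - 700, L - 500, "-", OUTER),
            ]
        )
        fwd_labels = {r.protein_id: r.subclass for r in classify_spanin(fwd)}
        rev_labels = {r.protein_id: r.subclass for r in classify_spanin(rev)}
        assert fwd_labels == rev_labels


class TestSummary:
    def test_combinations(self):
        from lysismine.lysclass import LypRecord

        records = [
            LypRecord("g1_a", "endolysin", "amidase", "pass"),
            LypRecord("g1_b", "holin", "TMRs-2", "pass"),
            LypRecord("g2_a", "endolysin", "amidase", "pass"),
            LypRecord("g2_b", "holin", "TMRs-1", "pass"),
            LypRecord("g2_c", "spanin", "SIS", "pass"),
            LypRecord("g3_a", "endolysin", None, "reject:TMR"),
        ]
        mapping = {r.protein_id: r.protein_id.split("_")[0] for r in records}
        df = summarize_lysis_systems(records, mapping)
        combos = dict(zip(df["genome_id"], df["combination"]))
        assert combos == {
            "g1": "endolysin & holin",
            "g2": "endolysin & holin & spanin",
            "g3": "none",
        }

    def test_proportions_sum_to_one(self):
        from lysismine.lysclass import LypRecord, summarize_lysis_systems
        from lysismine.lysclass import combination_proportions

        records = [LypRecord(f"g{i}_a", "endolysin", "amidase", "pass") for i in range(5)]
        df = summarize_lysis_systems(records, {f"g{i}_a": f"g{i}" for i in range(5)})
        assert combination_proportions(df).sum() == pytest.approx(1.0)
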