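"""Splice-event extraction, the seven-kind taxonomy and ISE detection."""

import numpy as np
import pytest

from isopept import events as ev
from isopept.annotation import Exon, GeneSet, Isoform
from isopept.mapping import map_peptides

from conftest import make_gene, make_isoform


def iso_from_exons(iso_id, gene_id, exon_list, segs):
    """Isoform from pre-built shared Exon objects plus per-exon segments."""
    return Isoform(iso_id, gene_id, list(exon_list), "".join(segs))


@pytest.fixture()
def skip_gene():
    """Three-exon main isoform; alt skips the middle exon (30 codons)."""
    segs = ["M" + "A" * 11, "W" * 30, "G" * 12]
    e1 = Exon("e1", "c1", 1000, 1000 + 36, "+", 0)
    e2 = Exon("e2", "c1", 2000, 2000 + 90, "+", 0)
    e3 = Exon("e3", "c1", 3000, 3000 + 36, "+", 0)
    main = iso_from_exons("t1", "g", [e1, e2, e3], segs)
    alt = iso_from_exons("t2", "g", [e1, e3], [segs[0], segs[2]])
    return main, alt


class TestProjection:
    def test_exon_skip_matches_flanks_only(self, skip_gene):
        main, alt = skip_gene
        aln = ev.project_isoform_pair(main, alt)
        assert len(aln.pairs) == 24
        assert aln.pairs[:2] == [(0, 0), (1, 1)]
        assert aln.pairs[-1] == (53, 23)

    def test_identical_isoforms_fully_matched(self, skip_gene):
        main, _ = skip_gene
        twin = iso_from_exons("t3", "g", main.exons, [main.protein])
        aln = ev.project_isoform_pair(main, twin)
        assert aln.pairs == [(i, i) for i in range(len(main.protein))]

    def test_shared_exon_in_different_frame_unmatched(self):
        # alt reads the same genomic bases shifted by one: no codon matches
        e_main = Exon("em", "c1", 999, 999 + 36, "+", 0)
        e_alt = Exon("ea", "c1", 1000, 1000 + 36, "+", 0)
        main = iso_from_exons("t1", "g", [e_main], ["M" + "A" * 11])
        alt = iso_from_exons("t2", "g", [e_alt], ["C" * 12])
        aln = ev.project_isoform_pair(main, alt)
        assert aln.pairs == []

    def test_different_genes_rejected(self, skip_gene):
        main, _ = skip_gene
        other = make_isoform("x1", "other", [("z", "MAAA")])
        with pytest.raises(ValueError):
            ev.project_isoform_pair(main, other)

    def test_fallback_alignment_without_cds(self):
        main = Isoform("t1", "g", [], "MAAAWWWWGGG")
        alt = Isoform("t2", "g", [], "MAAAGGG")
        aln = ev.project_isoform_pair(main, alt)
        assert (0, 0) in aln.pairs and (len(main.protein) - 1, len(alt.protein) - 1) in aln.pairs


class TestExtraction:
    def test_internal_skip_yields_one_deletion_event(self, skip_gene):
        main, alt = skip_gene
        events = ev.extract_events(ev.project_isoform_pair(main, alt))
        assert len(events) == 1
        assert events[0].main_segment == (12, 42)
        assert events[0].alt_segment == (12, 12)

    def test_pure_truncation_yields_no_events(self, skip_gene):
        main, _ = skip_gene
        segs = [main.protein[:12], main.protein[12:42]]
        trunc = iso_from_exons("t4", "g", main.exons[:2], segs)
        assert ev.extract_events(ev.project_isoform_pair(main, trunc)) == []

    def test_identical_isoforms_yield_no_events(self, skip_gene):
        main, _ = skip_gene
        twin = iso_from_exons("t5", "g", main.exons, [main.protein])
        assert ev.extract_events(ev.project_isoform_pair(main, twin)) == []

    def test_exon_swap_yields_substitution_with_both_segments(self, skip_gene):
        main, _ = skip_gene
        e2b = Exon("e2b", "c1", 2200, 2200 + 90, "+", 0)
        alt = iso_from_exons(
            "t6", "g", [main.exons[0], e2b, main.exons[2]],
            [main.protein[:12], "Y" * 30, main.protein[42:]],
        )
        events = ev.extract_events(ev.project_isoform_pair(main, alt))
        assert len(events) == 1
        assert events[0].main_segment == (12, 42)
        assert events[0].alt_segment == (12, 42)


class TestClassification:
    def _substitution_event(self, main_mid, alt_mid, flank=12):
        m_f1 = "M" + "A" * (flank - 1)
        m_f2 = "G" * flank
        e1 = Exon("e1", "c1", 1000, 1000 + 3 * flank, "+", 0)
        e2 = Exon("e2", "c1", 2000, 2000 + 3 * len(main_mid), "+", 0)
        e2b = Exon("e2b", "c1", 2500, 2500 + 3 * len(alt_mid), "+", 0)
        e3 = Exon("e3", "c1", 3000, 3000 + 3 * flank, "+", 0)
        main = iso_from_exons("t1", "g", [e1, e2, e3], [m_f1, main_mid, m_f2])
        alt = iso_from_exons("t2", "g", [e1, e2b, e3], [m_f1, alt_mid, m_f2])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        return event

    def _indel_event(self, n_removed, flank=12):
        mid = "W" * n_removed
        e1 = Exon("e1", "c1", 1000, 1000 + 3 * flank, "+", 0)
        e2 = Exon("e2", "c1", 2000, 2000 + 3 * n_removed, "+", 0)
        e3 = Exon("e3", "c1", 3000, 3000 + 3 * flank, "+", 0)
        main = iso_from_exons("t1", "g", [e1, e2, e3],
                              ["M" + "A" * (flank - 1), mid, "G" * flank])
        alt = iso_from_exons("t2", "g", [e1, e3],
                             ["M" + "A" * (flank - 1), "G" * flank])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        return event

    @pytest.mark.parametrize("n,expected", [(1, "nagnag"), (4, "nagnag"),
                                            (5, "indel"), (13, "indel")])
    def test_nagnag_indel_boundary(self, n, expected):
        assert ev.classify_event(self._indel_event(n)) == expected

    def test_homologous_substitution_identical_segments(self):
        seg = "MWNDYACQPLTSVHEWKRFGDNSTYMLQAV"
        event = self._substitution_event(seg, seg)
        assert ev.classify_event(event) == "homologous_substitution"
        assert event.homology["empirical_p"] <= 0.005

    def test_internal_substitution_non_homologous(self):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHKLMNPQSTVWY"
        big = "".join(rng.choice(list(aa), size=100))
        small = "".join(rng.choice(list(aa), size=6))
        event = self._substitution_event(big, small)
        assert ev.classify_event(event) == "internal_substitution"

    def test_terminal_substitutions(self):
        flank = "G" * 14
        e_last = Exon("el", "c1", 3000, 3000 + 60, "+", 0)
        e_lastb = Exon("elb", "c1", 3500, 3500 + 36, "+", 0)
        e1 = Exon("e1", "c1", 1000, 1000 + 42, "+", 0)
        main = iso_from_exons("t1", "g", [e1, e_last], ["M" + flank[1:], "W" * 20])
        alt = iso_from_exons("t2", "g", [e1, e_lastb], ["M" + flank[1:], "DSTNQYHCEVPL"])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        assert ev.classify_event(event) == "cterm_substitution"

        e_first = Exon("ef", "c1", 100, 100 + 60, "+", 0)
        e_firstb = Exon("efb", "c1", 400, 400 + 36, "+", 0)
        main2 = iso_from_exons("t1", "g", [e_first, e1], ["W" * 20, "M" + flank[1:]])
        alt2 = iso_from_exons("t2", "g", [e_firstb, e1], ["DSTNQYHCEVPL", "M" + flank[1:]])
        (event2,) = ev.extract_events(ev.project_isoform_pair(main2, alt2))
        assert ev.classify_event(event2) == "nterm_substitution"

    def test_frame_shifted_pair_is_two_proteins(self):
        e_main = Exon("em", "c1", 999, 999 + 60, "+", 0)
        e_alt = Exon("ea", "c1", 1000, 1000 + 60, "+", 0)
        main = iso_from_exons("t1", "g", [e_main], ["M" + "A" * 19])
        alt = iso_from_exons("t2", "g", [e_alt], ["C" * 20])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        assert ev.classify_event(event) == "two_proteins"

    def test_classification_total_and_swap_invariant(self, synth):
        """Every event gets exactly one kind; substitution kinds survive
        exchanging main and alt."""
        # order-independent homology call so the swap is exactly symmetric
        def sym_homology(a, b):
            x, y = sorted((a, b))
            return ev.test_segment_homology(x, y)

        n_checked = 0
        for gene in list(synth.merged)[:40]:
            if len(gene.isoforms) < 2:
                continue
            main_id = gene.principal_isoform().isoform_id
            for event in ev.gene_events(gene, main_id):
                assert event.kind in ev.EVENT_KINDS
                n_checked += 1
            for alt_id in gene.isoforms:
                if alt_id == main_id:
                    continue
                fwd = ev.extract_events(
                    ev.project_isoform_pair(
                        gene.isoforms[main_id], gene.isoforms[alt_id]
                    )
                )
                rev = ev.extract_events(
                    ev.project_isoform_pair(
                        gene.isoforms[alt_id], gene.isoforms[main_id]
                    )
                )
                for f, r in zip(fwd, rev):
                    kf = ev.classify_event(f, homology_test=sym_homology)
                    kr = ev.classify_event(r, homology_test=sym_homology)
                    if kf not in ("nterm_substitution", "cterm_substitution"):
                        assert kf == kr
        assert n_checked > 0


class TestSegmentHomology:
    def test_identical_segments_at_p_floor(self):
        seg = "MWNDYACQPLTSVHEWKRFGDNSTYMLQAV"
        res = ev.test_segment_homology(seg, seg, n_shuffles=200)
        assert res["homologous"] and res["empirical_p"] == pytest.approx(1 / 201)

    def test_reversed_random_sequence_not_homologous(self):
        rng = np.random.default_rng(11)
        seg = "".join(rng.choice(list("ACDEFGHKLMNPQSTVWY"), size=50))
        res = ev.test_segment_homology(seg, seg[::-1], seed=42, n_shuffles=200)
        assert not res["homologous"]

    def test_diverged_domain_still_homologous(self):
        """~33% identity over a domain-sized segment is detectable."""
        rng = np.random.default_rng(7)
        aa = list("ACDEFGHKLMNPQSTVWY")
        base = "".join(rng.choice(aa, size=120))
        mutated = list(base)
        for pos in rng.choice(120, size=80, replace=False):
            mutated[pos] = rng.choice([c for c in aa if c != base[pos]])
        res = ev.test_segment_homology(base, "".join(mutated))
        assert res["homologous"]

    def test_too_short_segments_never_homologous(self):
        assert not ev.test_segment_homology("A", "A")["homologous"]


class TestIseDetection:
    def _deletion_setup(self):
        segs = ["M" + "A" * 11 + "K", "W" * 8 + "K" + "W" * 6, "G" * 6 + "R" + "G" * 5]
        e1 = Exon("e1", "c1", 1000, 1000 + 3 * len(segs[0]), "+", 0)
        e2 = Exon("e2", "c1", 2000, 2000 + 3 * len(segs[1]), "+", 0)
        e3 = Exon("e3", "c1", 3000, 3000 + 3 * len(segs[2]), "+", 0)
        main = iso_from_exons("t1", "g", [e1, e2, e3], segs)
        alt = iso_from_exons("t2", "g", [e1, e3], [segs[0], segs[2]])
        gene = make_gene("g", [main, alt])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        return gene, event, main, alt

    def test_deletion_without_junction_peptide_is_not_ise(self):
        gene, event, main, alt = self._deletion_setup()
        # peptides in shared flanks only
        matches, _ = map_peptides(["MAAAAAAAAAAAK"], GeneSet({"g": gene}))
        assert ev.detect_ise(event, matches) is None

    def test_deletion_with_junction_and_insertion_peptides_is_ise(self):
        gene, event, main, alt = self._deletion_setup()
        junction = alt.protein[7:20]  # crosses the e1/e3 junction on alt
        inside = main.protein[13:22]  # inside the skipped exon on main
        matches, _ = map_peptides([junction, inside], GeneSet({"g": gene}))
        ise = ev.detect_ise(event, matches)
        assert ise is not None
        assert ise.main_side_peptides and ise.alt_side_peptides

    def test_substitution_two_peptides_each_side(self):
        seg_m = "W" * 10 + "K" + "W" * 9
        seg_a = "Y" * 10 + "K" + "Y" * 9
        flank1, flank2 = "M" + "A" * 11, "G" * 12
        e1 = Exon("e1", "c1", 1000, 1036, "+", 0)
        e2 = Exon("e2", "c1", 2000, 2060, "+", 0)
        e2b = Exon("e2b", "c1", 2500, 2560, "+", 0)
        e3 = Exon("e3", "c1", 3000, 3036, "+", 0)
        main = iso_from_exons("t1", "g", [e1, e2, e3], [flank1, seg_m, flank2])
        alt = iso_from_exons("t2", "g", [e1, e2b, e3], [flank1, seg_a, flank2])
        gene = make_gene("g", [main, alt])
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        matches, _ = map_peptides(
            [main.protein[12:20], main.protein[20:30], alt.protein[12:20],
             alt.protein[20:30]],
            GeneSet({"g": gene}),
        )
        ise = ev.detect_ise(event, matches)
        assert ise is not None
        assert len(ise.main_side_peptides) == 2 and len(ise.alt_side_peptides) == 2

    def test_ise_requires_both_sides_by_construction(self):
        gene, event, main, alt = self._deletion_setup()
        with pytest.raises(ValueError):
            ev.ISE(event, set(), {"SOMEPEP"})


class TestDedupe:
    def test_same_skip_in_multiple_pairs_collapses(self, skip_gene):
        main, alt = skip_gene
        alt_copy = iso_from_exons("t3", "g", alt.exons, [alt.protein])
        events = []
        for a in (alt, alt_copy):
            for e in ev.extract_events(ev.project_isoform_pair(main, a)):
                e.kind = "indel"
                events.append(e)
        assert len(ev.dedupe_events(events)) == 1

    def test_distinct_skips_stay_distinct(self):
        segs = ["M" + "A" * 11, "W" * 12, "Y" * 12, "G" * 12]
        exons = [
            Exon(f"e{i}", "c1", 1000 * (i + 1), 1000 * (i + 1) + 36, "+", 0)
            for i in range(4)
        ]
        main = iso_from_exons("t1", "g", exons, segs)
        alt1 = iso_from_exons("t2", "g", [exons[0], exons[2], exons[3]],
                              [segs[0], segs[2], segs[3]])
        alt2 = iso_from_exons("t3", "g", [exons[0], exons[1], exons[3]],
                              [segs[0], segs[1], segs[3]])
        events = []
        for a in (alt1, alt2):
            for e in ev.extract_events(ev.project_isoform_pair(main, a)):
                e.kind = "indel"
                events.append(e)
        assert len(ev.dedupe_events(events)) == 2

    def test_unique_count_matches_brute_force_key_grouping(self, synth):
        events = []
        for gene in list(synth.merged)[:30]:
            if len(gene.isoforms) < 2:
                continue
            main_id = gene.principal_isoform().isoform_id
            events.extend(ev.gene_events(gene, main_id, classify=True))
        unique = ev.dedupe_events(events)
        oracle = {(e.gene_id, e.kind, e.genomic_key) for e in events}
        assert len(unique) == len(oracle)
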