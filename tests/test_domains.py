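"""Domain-impact classification: broken / lost / swap / none."""

import pytest

from isopept import domains as dom
from isopept import events as ev
from isopept.annotation import Exon, Isoform
from isopept.domains import DomainAnnotation


def _deletion_event(n_removed=10, flank=20):
    e1 = Exon("e1", "c1", 1000, 1000 + 3 * flank, "+", 0)
    e2 = Exon("e2", "c1", 2000, 2000 + 3 * n_removed, "+", 0)
    e3 = Exon("e3", "c1", 3000, 3000 + 3 * flank, "+", 0)
    main = Isoform("t1", "g", [e1, e2, e3],
                   "M" + "A" * (flank - 1) + "W" * n_removed + "G" * flank)
    alt = Isoform("t2", "g", [e1, e3], "M" + "A" * (flank - 1) + "G" * flank)
    (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
    event.kind = "indel" if n_removed > 4 else "nagnag"
    return event


def _insertion_event(n_inserted, flank=20):
    e1 = Exon("e1", "c1", 1000, 1000 + 3 * flank, "+", 0)
    e2 = Exon("e2", "c1", 2000, 2000 + 3 * n_inserted, "+", 0)
    e3 = Exon("e3", "c1", 3000, 3000 + 3 * flank, "+", 0)
    main = Isoform("t1", "g", [e1, e3], "M" + "A" * (flank - 1) + "G" * flank)
    alt = Isoform("t1b", "g", [e1, e2, e3],
                  "M" + "A" * (flank - 1) + "W" * n_inserted + "G" * flank)
    (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
    event.kind = "indel" if n_inserted > 4 else "nagnag"
    return event


class TestEventDomainEffect:
    def test_deletion_inside_domain_breaks_it(self):
        event = _deletion_event(10)  # main segment (20, 30)
        main_doms = [DomainAnnotation("t1", "PF1", 16, 40)]
        alt_doms = [DomainAnnotation("t2", "PF1", 16, 30)]
        out = dom.event_domain_effect(event, main_doms, alt_doms)
        assert out.verdict == "broken"

    @pytest.mark.parametrize("n,verdict", [(4, "none"), (5, "broken")])
    def test_broken_boundary_at_five_residues_deleted(self, n, verdict):
        event = _deletion_event(n)
        main_doms = [DomainAnnotation("t1", "PF1", 11, 20 + n + 10)]
        out = dom.event_domain_effect(event, main_doms, [])
        assert out.verdict == verdict

    @pytest.mark.parametrize("n,verdict", [(4, "none"), (5, "broken")])
    def test_broken_boundary_at_five_residues_gained(self, n, verdict):
        event = _insertion_event(n)
        main_doms = [DomainAnnotation("t1", "PF1", 11, 30)]  # spans the junction
        alt_doms = [DomainAnnotation("t1b", "PF1", 11, 30 + n)]
        out = dom.event_domain_effect(event, main_doms, alt_doms)
        assert out.verdict == verdict

    def test_whole_domain_deleted_is_lost(self):
        event = _deletion_event(10)
        main_doms = [
            DomainAnnotation("t1", "PF1", 21, 30),  # exactly the skipped exon
            DomainAnnotation("t1", "PF2", 2, 10),  # intact elsewhere
        ]
        alt_doms = [DomainAnnotation("t2", "PF2", 2, 10)]
        out = dom.event_domain_effect(event, main_doms, alt_doms)
        assert out.verdict == "lost" and out.lost_accs == ("PF1",)

    def test_hes_event_spanning_domain_is_unbroken(self):
        event = _deletion_event(10)
        event.kind = "homologous_substitution"
        main_doms = [DomainAnnotation("t1", "PF1", 21, 30)]
        out = dom.event_domain_effect(event, main_doms, [])
        assert out.verdict == "none"

    def test_hes_override_restores_normal_rules(self):
        event = _deletion_event(10)
        event.kind = "homologous_substitution"
        main_doms = [DomainAnnotation("t1", "PF1", 21, 30)]
        out = dom.event_domain_effect(event, main_doms, [], override_accs={"PF1"})
        assert out.verdict == "lost"

    def test_domain_swap(self):
        """One domain set replaced by a different one (nebulin-repeats ->
        LIM style)."""
        flank = 20
        e1 = Exon("e1", "c1", 1000, 1000 + 3 * flank, "+", 0)
        ea = Exon("ea", "c1", 2000, 2000 + 90, "+", 0)
        eb = Exon("eb", "c1", 2500, 2500 + 60, "+", 0)
        main = Isoform("t1", "g", [e1, ea], "M" + "A" * (flank - 1) + "W" * 30)
        alt = Isoform("t2", "g", [e1, eb], "M" + "A" * (flank - 1) + "Y" * 20)
        (event,) = ev.extract_events(ev.project_isoform_pair(main, alt))
        event.kind = "cterm_substitution"
        main_doms = [DomainAnnotation("t1", "PF_repeat", 22, 48)]
        alt_doms = [DomainAnnotation("t2", "PF_LIM", 22, 38)]
        out = dom.event_domain_effect(event, main_doms, alt_doms)
        assert out.verdict == "swap"
        assert out.gained_accs == ("PF_LIM",)

    def test_no_domains_means_none(self):
        assert dom.event_domain_effect(_deletion_event(10), [], []).verdict == "none"

    def test_verdict_invariant_to_domain_order(self):
        event = _deletion_event(10)
        doms = [
            DomainAnnotation("t1", "PF2", 2, 10),
            DomainAnnotation("t1", "PF1", 21, 30),
        ]
        a = dom.event_domain_effect(event, doms, [])
        b = dom.event_domain_effect(event, list(reversed(doms)), [])
        assert a.verdict == b.verdict


class TestTally:
    def test_counts_sum_to_event_total(self, synth):
        dmap = {}
        for d in synth.truth.domain_rows:
            dmap.setdefault(d.isoform_id, []).append(d)
        events = []
        for gene in synth.merged:
            if len(gene.isoforms) < 2:
                continue
            main_id = gene.principal_isoform().isoform_id
            events.extend(ev.gene_events(gene, main_id))
        tally = dom.tally_domain_effects(events, dmap)
        assert (
            tally["broken_n"] + tally["lost_n"] + tally["swap_n"] + tally["none_n"]
            == tally["n_events"]
            == len(events)
        )
        assert sum(tally["percentages"].values()) == pytest.approx(100.0)

    def test_planted_split_recovered_exactly(self):
        """A constructed event set with a known 30/30/10/30 verdict split."""
        events, dmap = [], {}
        for i in range(100):
            event = _deletion_event(10)
            event.gene_id = f"g{i}"
            if i < 30:  # broken
                dmap.setdefault(f"b{i}", []).append(
                    DomainAnnotation(f"b{i}", "PF", 16, 40)
                )
                event.main_isoform_id = f"b{i}"
            elif i < 60:  # lost
                dmap.setdefault(f"l{i}", []).append(
                    DomainAnnotation(f"l{i}", "PF", 21, 30)
                )
                event.main_isoform_id = f"l{i}"
            elif i < 70:  # swap: lost + gained accession
                dmap.setdefault(f"s{i}", []).append(
                    DomainAnnotation(f"s{i}", "PF", 21, 30)
                )
                dmap.setdefault(f"sa{i}", []).append(
                    DomainAnnotation(f"sa{i}", "PF_other", 15, 25)
                )
                event.main_isoform_id = f"s{i}"
                event.alt_isoform_id = f"sa{i}"
                event.alt_segment = (20, 30)  # substitution, not pure deletion
            # else: no domains -> none
            events.append(event)
        tally = dom.tally_domain_effects(events, dmap)
        assert (tally["broken_n"], tally["lost_n"], tally["swap_n"],
                tally["none_n"]) == (30, 30, 10, 30)

    def test_removing_all_domains_forces_none(self, synth):
        events = []
        for gene in list(synth.merged)[:20]:
            if len(gene.isoforms) < 2:
                continue
            main_id = gene.principal_isoform().isoform_id
            events.extend(ev.gene_events(gene, main_id, classify=False))
        tally = dom.tally_domain_effects(events, {})
        assert tally["none_n"] == tally["n_events"]

    def test_planted_verdicts_recovered_on_fixture(self, synth):
        dmap = {}
        for d in synth.truth.domain_rows:
            dmap.setdefault(d.isoform_id, []).append(d)
        checked = 0
        for planted in synth.truth.events:
            if planted.domain_verdict is None:
                continue
            gene = synth.merged.genes[planted.gene_id]
            aln = ev.project_isoform_pair(
                gene.isoforms[planted.main_isoform_id],
                gene.isoforms[planted.alt_isoform_id],
            )
            match = [
                e
                for e in ev.extract_events(aln)
                if (e.main_segment, e.alt_segment)
                == (tuple(planted.main_segment), tuple(planted.alt_segment))
            ]
            assert len(match) == 1
            event = match[0]
            ev.classify_event(event)
            if planted.ambiguous:
                continue  # homology call not guaranteed at low identity
            out = dom.event_domain_effect(
                event,
                dmap.get(planted.main_isoform_id, ()),
                dmap.get(planted.alt_isoform_id, ()),
            )
            assert out.verdict == planted.domain_verdict, planted
            checked += 1
        assert checked > 100
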