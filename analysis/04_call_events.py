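#!/usr/bin/env python
"""Extract, classify and peptide-validate splice events.

For every gene the main isoform is the one with the most discriminating
peptides; events against each alternative are classified into the seven
kinds and kept as identified splicing events (ISEs) when peptides map to
both sides.  Grades the ISE set against the planted truth.
"""

import importlib.util
import json
from collections import Counter
from pathlib import Path

from isopept import events as ev
from isopept import filtering as fl
from isopept import mapping as mp

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

_spec = importlib.util.spec_from_file_location(
    "step03", Path(__file__).with_name("03_map_peptides.py")
)
step03 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(step03)


def main() -> None:
    merged = step03.load_annotation()
    kept = fl.read_peptide_tsv(OUT / "filtered_peptides.tsv")
    matches, _ = mp.map_peptides(kept, merged)
    by_gene = mp.matches_by_gene(matches)

    all_events, ises = [], []
    for gene in merged:
        gene_matches = by_gene.get(gene.gene_id, [])
        main_id = mp.pick_main_isoform(gene, gene_matches)
        events = ev.dedupe_events(ev.gene_events(gene, main_id))
        all_events.extend(events)
        for event in events:
            ise = ev.detect_ise(event, gene_matches)
            if ise:
                ises.append(ise)

    kind_counts = Counter(e.kind for e in all_events)
    ise_counts = Counter(i.event.kind for i in ises)
    summary = {
        "n_unique_events": len(all_events),
        "n_ises": len(ises),
        "events_by_kind": dict(kind_counts),
        "ises_by_kind": dict(ise_counts),
        "ise_genes": sorted({i.event.gene_id for i in ises}),
    }
    (OUT / "events_summary.json").write_text(json.dumps(summary, indent=1))

    rows = []
    for i in ises:
        e = i.event
        rows.append(
            f"{e.gene_id}\t{e.main_isoform_id}\t{e.alt_isoform_id}\t{e.kind}\t"
            f"{e.main_segment}\t{e.alt_segment}\t"
            f"{';'.join(sorted(i.main_side_peptides))}\t"
            f"{';'.join(sorted(i.alt_side_peptides))}"
        )
    (OUT / "ises.tsv").write_text(
        "gene\tmain\talt\tkind\tmain_segment\talt_segment\t"
        "main_side_peptides\talt_side_peptides\n" + "\n".join(rows) + "\n"
    )

    truth = json.loads((OUT / "truth.json").read_text())
    expected = {
        (e["gene_id"], frozenset((e["main_isoform_id"], e["alt_isoform_id"])))
        for e in truth["events"]
        if e["detectable"]
    }
    got = {
        (i.event.gene_id,
         frozenset((i.event.main_isoform_id, i.event.alt_isoform_id)))
        for i in ises
    }
    print(f"{len(all_events)} unique annotated events; {len(ises)} ISEs "
          f"with both-sides peptide evidence")
    print(f"  events by kind: {dict(kind_counts)}")
    print(f"  ISE recovery vs truth: {len(got & expected)}/{len(expected)} "
          f"(false positives: {len(got - expected)})")


if __name__ == "__main__":
    main()
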