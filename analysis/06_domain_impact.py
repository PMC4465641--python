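#!/usr/bin/env python
"""Score the effect of every splice event on domain annotations.

Tallies broken / lost / swap / none over (a) all annotated events and
(b) the peptide-validated ISEs, mirroring the contrast between the
annotated event universe and what is actually expressed.
"""

import importlib.util
import json
from pathlib import Path

from isopept import domains as dom
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
    dmap = dom.read_domain_tsv(OUT / "domains.tsv")
    kept = fl.read_peptide_tsv(OUT / "filtered_peptides.tsv")
    matches, _ = mp.map_peptides(kept, merged)
    by_gene = mp.matches_by_gene(matches)

    all_events, ise_events = [], []
    for gene in merged:
        gene_matches = by_gene.get(gene.gene_id, [])
        main_id = mp.pick_main_isoform(gene, gene_matches)
        events = ev.dedupe_events(ev.gene_events(gene, main_id))
        all_events.extend(events)
        ise_events.extend(
            e for e in events if ev.detect_ise(e, gene_matches)
        )

    tallies = {
        "all_annotated_events": dom.tally_domain_effects(all_events, dmap),
        "ises": dom.tally_domain_effects(ise_events, dmap),
    }
    impacts = dom.classify_all(all_events, dmap)
    dom.write_impact_tsv(impacts, OUT / "domain_impacts.tsv")
    (OUT / "domain_tallies.json").write_text(json.dumps(tallies, indent=1))
    for name, tally in tallies.items():
        pct = {k: round(v, 1) for k, v in tally["percentages"].items()}
        print(f"{name}: n={tally['n_events']}  {pct}")


if __name__ == "__main__":
    main()
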