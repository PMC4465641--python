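#!/usr/bin/env python
"""Scan the annotation for mutually exclusive homologous exons (HES).

Annotation-only: no peptide data.  Validated pairs are exported as TSV
and BED, recovery is graded against the planted pairs, and detection
enrichment of HES genes among peptide-detected genes is Fisher-tested.
"""

import importlib.util
import json
from pathlib import Path

from isopept import hes
from isopept.evostats import ContingencyTable, fisher_exact

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

_spec = importlib.util.spec_from_file_location(
    "step03", Path(__file__).with_name("03_map_peptides.py")
)
step03 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(step03)


def main() -> None:
    merged = step03.load_annotation()
    cands = hes.scan_gene_set(merged)
    hes.write_hes_tsv(cands, OUT / "hes_candidates.tsv")
    hes.write_hes_bed(cands, OUT / "hes_pairs.bed")

    truth = json.loads((OUT / "truth.json").read_text())
    planted = {
        (d["gene_id"], frozenset((tuple(d["exon_a"]), tuple(d["exon_b"]))))
        for d in truth["hes_pairs"]
    }
    got = {
        (c.gene_id, frozenset((c.exon_a.key, c.exon_b.key)))
        for c in cands
        if c.verdict
    }
    print(f"{len(cands)} mutually exclusive candidate pairs, "
          f"{len(got)} validated as homologous")
    print(f"  planted recovered: {len(got & planted)}/{len(planted)}, "
          f"false positives: {len(got - planted)}")

    # enrichment of HES genes among genes with protein-level AS evidence
    # (every synthetic gene clears the 2-peptide bar, so the informative
    # outcome is ISE detection, not bare peptide detection)
    ise_genes = set(
        json.loads((OUT / "events_summary.json").read_text())["ise_genes"]
    )
    hes_genes = {c.gene_id for c in cands if c.verdict}
    background = set(merged.genes) - hes_genes
    table = ContingencyTable(
        a=len(hes_genes & ise_genes),
        b=len(hes_genes - ise_genes),
        c=len(background & ise_genes),
        d=len(background - ise_genes),
    )
    result = fisher_exact(table)
    (OUT / "hes_enrichment.json").write_text(json.dumps(
        {"table": table.__dict__, **result}, indent=1))
    print(f"  AS-evidence enrichment: a={table.a} b={table.b} c={table.c} "
          f"d={table.d} -> p={result['p_value']:.3g}, "
          f"odds={result['odds_ratio']:.2f}")


if __name__ == "__main__":
    main()
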