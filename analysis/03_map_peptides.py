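#!/usr/bin/env python
"""Map the high-confidence peptides onto the isoform annotation.

Loads the GTF/FASTA written by step 01 (read-through and pseudoautosomal
entries are filtered on load, gene clusters merged), maps peptides
I/L-insensitively, and reports per-gene evidence.
"""

import json
from pathlib import Path

from isopept import annotation as ann
from isopept import filtering as fl
from isopept import mapping as mp

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def load_annotation():
    gene_set = ann.load_gene_set(
        OUT / "annotation.gtf",
        OUT / "proteins.fa",
        pseudoautosomal_regions=ann.read_region_bed(OUT / "pseudoautosomal.bed"),
    )
    merged = ann.merge_gene_clusters(
        gene_set, ann.read_cluster_yaml(OUT / "clusters.yaml")
    )
    ann.select_all_principals(merged)
    return merged


def main() -> None:
    merged = load_annotation()
    kept = fl.read_peptide_tsv(OUT / "filtered_peptides.tsv")
    # re-merge provenance rows of the filtered table
    by_canon = {}
    for r in kept:
        tgt = by_canon.setdefault(r.canon_seq, r)
        if tgt is not r:
            tgt.datasets |= r.datasets
    records = list(by_canon.values())
    matches, audit = mp.map_peptides(records, merged)
    mp.write_matches_tsv(matches, OUT / "peptide_matches.tsv")
    evidence = mp.count_gene_evidence(matches)
    summary = {
        "n_peptides_mapped": len(matches),
        "n_multi_gene_dropped": audit["multi_gene"],
        "n_unmatched": audit["unmatched"],
        "genes_detected": sum(1 for v in evidence.values() if v["detected"]),
        "genes_with_any_peptide": len(evidence),
    }
    (OUT / "mapping_summary.json").write_text(json.dumps(summary, indent=1))
    n_disc = sum(
        1
        for m in matches
        if m.is_discriminating(merged.genes[m.gene_id])
    )
    print(f"mapped {len(matches)} peptides "
          f"({audit['multi_gene']} multi-gene dropped, {audit['unmatched']} unmatched)")
    print(f"  genes with >= 2 peptides: {summary['genes_detected']}")
    print(f"  isoform-discriminating peptides: {n_disc} "
          f"({100 * n_disc / max(len(matches), 1):.1f}%)")


if __name__ == "__main__":
    main()
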