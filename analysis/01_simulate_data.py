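#!/usr/bin/env python
"""Generate the synthetic proteogenomic study.

Writes the annotation (GTF + protein FASTA, including read-through and
pseudoautosomal decoys), the gene-cluster definition, the domain table,
eight per-experiment peptide tables with injected artifacts, and the
cross-species fixtures under results/synthetic/.  The ground truth
(planted events, peptide origins, abundances) is stored as JSON so the
later steps can grade themselves.
"""

import json
from dataclasses import asdict
from pathlib import Path

from isopept import annotation as ann
from isopept import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SynthConfig(seed=SEED)
    gene_set, truth = sd.generate_gene_set(cfg)
    merged = ann.merge_gene_clusters(gene_set, truth.clusters)
    ann.select_all_principals(merged)
    per_ds = sd.simulate_detections(merged, truth, cfg)

    sd.write_annotation(gene_set, truth, OUT / "annotation.gtf", OUT / "proteins.fa")
    sd.write_par_bed(OUT / "pseudoautosomal.bed")
    sd.write_cluster_yaml(truth.clusters, OUT / "clusters.yaml")
    sd.write_domain_tsv(truth, OUT / "domains.tsv")
    sd.write_experiment_tsvs(per_ds, OUT / "experiments")
    fix = sd.generate_species_fixtures(n_features=50, seed=SEED + 29)
    sd.write_species_fixtures(fix, OUT / "species")

    truth_json = {
        "events": [asdict(e) for e in truth.events],
        "hes_pairs": [
            {**d, "exon_a": list(d["exon_a"]), "exon_b": list(d["exon_b"])}
            for d in truth.hes_pairs
        ],
        "peptide_origin": truth.peptide_origin,
        "per_gene_detected": truth.per_gene_detected,
        "readthrough_ids": truth.readthrough_ids,
        "par_gene_ids": truth.par_gene_ids,
        "dollo_origins": fix.origins,
    }
    (OUT / "truth.json").write_text(json.dumps(truth_json, indent=1))

    n_events = len(truth.events)
    n_detectable = sum(1 for e in truth.events if e.detectable)
    n_peps = sum(len(v) for v in per_ds.values())
    print(f"wrote synthetic study to {OUT}")
    print(f"  genes: {len(gene_set)} (merged: {len(merged)}), "
          f"planted events: {n_events} ({n_detectable} detectable)")
    print(f"  peptide observations: {n_peps} over {len(per_ds)} experiments, "
          f"clean peptides: {len(truth.clean_peptides)}")


if __name__ == "__main__":
    main()
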