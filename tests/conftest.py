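"""Shared fixtures: the default synthetic study and small hand-built genes."""

from __future__ import annotations

import pytest

from isopept import annotation as ann
from isopept import synthetic_data as sd
from isopept.annotation import Exon, Gene, Isoform


@pytest.fixture(scope="session")
def synth():
    """The default 200-gene synthetic study, generated once per session.

    Returns a namespace with the unmerged gene set, truth tables, merged
    gene set (principals selected) and per-dataset peptide records.
    """
    cfg = sd.SynthConfig(seed=1)
    gene_set, truth = sd.generate_gene_set(cfg)
    merged = ann.merge_gene_clusters(gene_set, truth.clusters)
    ann.select_all_principals(merged)
    per_ds = sd.simulate_detections(merged, truth, cfg)

    class Synth:
        pass

    out = Synth()
    out.config = cfg
    out.gene_set = gene_set
    out.truth = truth
    out.merged = merged
    out.per_ds = per_ds
    return out


def make_isoform(iso_id, gene_id, exon_segments, chrom="chr1", strand="+", start=1000,
                 intron=100):
    """Build an isoform from (exon_id, protein_segment, genomic_start|None)
    triples; None genomic_start lays exons out left to right."""
    exons, protein, cursor = [], "", start
    for item in exon_segments:
        exon_id, seg = item[0], item[1]
        g_start = item[2] if len(item) > 2 and item[2] is not None else cursor
        exons.append(Exon(exon_id, chrom, g_start, g_start + 3 * len(seg), strand, 0))
        cursor = max(cursor, g_start + 3 * len(seg)) + intron
        protein += seg
    return Isoform(iso_id, gene_id, exons, protein)


def make_gene(gene_id, isoforms):
    return Gene(gene_id, {iso.isoform_id: iso for iso in isoforms},
                source_gene_ids=[gene_id])
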