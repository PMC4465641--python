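"""Annotation-driven detection of mutually exclusive homologous exons.

Independent of any peptide data: for each multi-isoform gene, find pairs
of CDS exons that never co-occur in a transcript, translate them in
their host transcripts, and call the pair a homologous exon substitution
(HES) candidate when the translations are sequence-homologous and the
exons occupy equivalent relative positions in their proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import pandas as pd

from .annotation import Exon, Gene, GeneSet, Isoform
from .events import test_segment_homology

MIN_EXON_BP = 30  # exons must be strictly longer than this


@dataclass
class HesCandidate:
    gene_id: str
    exon_a: Exon
    exon_b: Exon
    host_a: str  # isoform ids the translations were taken from
    host_b: str
    segment_a: str = ""
    segment_b: str = ""
    similarity: dict | None = None
    positionally_equivalent: bool = False
    in_locus: bool = True
    verdict: bool = False


def exon_protein_segment(iso: Isoform, exon: Exon) -> tuple[str, int, int]:
    """The protein segment encoded by an exon within a transcript.

    Returns (sequence, start, end) with a 0-based half-open residue
    interval covering every residue whose codon overlaps the exon.
    """
    codons = iso.codon_coordinates()
    lo, hi = None, None
    for k, codon in enumerate(codons):
        if any(c == exon.chrom and exon.start <= p < exon.end for c, p in codon):
            if lo is None:
                lo = k
            hi = k + 1
    if lo is None:
        return ("", 0, 0)
    return (iso.protein[lo:hi], lo, hi)


def find_mutually_exclusive_pairs(
    gene: Gene, min_exon_bp: int = MIN_EXON_BP
) -> list[HesCandidate]:
    """Candidate exon pairs that never co-occur in any transcript.

    Both CDS portions must be longer than ``min_exon_bp``.  Genomically
    overlapping exons are excluded: those are splice-site variants of one
    exon (e.g. NAGNAG acceptors), not distinct homologous exons.  For
    each exon the transcript with the longest protein serves as the
    reference in which the exon is translated.
    """
    if len(gene.isoforms) < 2:
        return []
    exon_hosts: dict[tuple, list[str]] = {}
    exon_by_key: dict[tuple, Exon] = {}
    for iso in gene.isoforms.values():
        for exon in iso.exons:
            exon_hosts.setdefault(exon.key, []).append(iso.isoform_id)
            exon_by_key.setdefault(exon.key, exon)
    candidates = []
    keys = [k for k in exon_hosts if exon_by_key[k].length > min_exon_bp]
    for key_a, key_b in combinations(sorted(keys), 2):
        hosts_a, hosts_b = set(exon_hosts[key_a]), set(exon_hosts[key_b])
        if hosts_a & hosts_b:
            continue  # co-occur in a transcript
        ex_a, ex_b = exon_by_key[key_a], exon_by_key[key_b]
        if ex_a.chrom == ex_b.chrom and ex_a.start < ex_b.end and ex_b.start < ex_a.end:
            continue  # overlapping splice-site variants of one exon
        host_a = max(hosts_a, key=lambda i: (len(gene.isoforms[i].protein), i))
        host_b = max(hosts_b, key=lambda i: (len(gene.isoforms[i].protein), i))
        candidates.append(
            HesCandidate(gene.gene_id, ex_a, ex_b, host_a, host_b)
        )
    return candidates


def validate_hes(
    gene: Gene,
    candidate: HesCandidate,
    homology_test: Callable[[str, str], dict] | None = None,
    position_tolerance: float = 0.10,
    seed: int | None = None,
    locus_margin: int = 100_000,
) -> HesCandidate:
    """Fill in homology, positional equivalence and the locus guard.

    verdict = homologous (permutation p <= 0.005 analog) AND the exons'
    protein-coordinate midpoints differ by at most ``position_tolerance``
    as a fraction of protein length AND both exons lie within
    ``locus_margin`` of the span of the gene's remaining exons (guards
    against candidates that really belong to a paralogous neighbour gene
    or pseudogene).
    """
    iso_a = gene.isoforms[candidate.host_a]
    iso_b = gene.isoforms[candidate.host_b]
    seg_a, lo_a, hi_a = exon_protein_segment(iso_a, candidate.exon_a)
    seg_b, lo_b, hi_b = exon_protein_segment(iso_b, candidate.exon_b)
    candidate.segment_a, candidate.segment_b = seg_a, seg_b
    test = homology_test or (lambda a, b: test_segment_homology(a, b, seed=seed))
    candidate.similarity = test(seg_a, seg_b)
    mid_a = (lo_a + hi_a) / 2 / max(len(iso_a.protein), 1)
    mid_b = (lo_b + hi_b) / 2 / max(len(iso_b.protein), 1)
    candidate.positionally_equivalent = abs(mid_a - mid_b) <= position_tolerance
    pair_keys = {candidate.exon_a.key, candidate.exon_b.key}
    rest = [
        e
        for iso in gene.isoforms.values()
        for e in iso.exons
        if e.key not in pair_keys
    ]
    if rest:
        chrom = rest[0].chrom
        g_start = min(e.start for e in rest) - locus_margin
        g_end = max(e.end for e in rest) + locus_margin
        candidate.in_locus = all(
            e.chrom == chrom and e.start >= g_start and e.end <= g_end
            for e in (candidate.exon_a, candidate.exon_b)
        )
    else:
        candidate.in_locus = True
    candidate.verdict = (
        bool(candidate.similarity["homologous"])
        and candidate.positionally_equivalent
        and candidate.in_locus
    )
    return candidate


def scan_gene_set(
    gene_set: GeneSet,
    homology_test: Callable[[str, str], dict] | None = None,
    position_tolerance: float = 0.10,
    seed: int | None = None,
) -> list[HesCandidate]:
    out = []
    for gene in gene_set:
        for cand in find_mutually_exclusive_pairs(gene):
            out.append(
                validate_hes(
                    gene, cand, homology_test, position_tolerance, seed=seed
                )
            )
    return out


def write_hes_tsv(candidates: Sequence[HesCandidate], path) -> None:
    rows = [
        {
            "gene": c.gene_id,
            "exon_a": c.exon_a.exon_id,
            "exon_b": c.exon_b.exon_id,
            "coords_a": f"{c.exon_a.chrom}:{c.exon_a.start}-{c.exon_a.end}",
            "coords_b": f"{c.exon_b.chrom}:{c.exon_b.start}-{c.exon_b.end}",
            "score": c.similarity["score"] if c.similarity else None,
            "empirical_p": c.similarity["empirical_p"] if c.similarity else None,
            "positionally_equivalent": c.positionally_equivalent,
            "in_locus": c.in_locus,
            "verdict": c.verdict,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hes_bed(candidates: Sequence[HesCandidate], path) -> None:
    """BED export of verdict-true homologous exon pairs."""
    with open(path, "w") as fh:
        for c in candidates:
            if not c.verdict:
                continue
            for exon, host in ((c.exon_a, c.host_a), (c.exon_b, c.host_b)):
                fh.write(
                    f"{exon.chrom}\t{exon.start}\t{exon.end}\t"
                    f"{c.gene_id}|{exon.exon_id}|{host}\t0\t{exon.strand}\n"
                )
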