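"""Map filtered peptides onto isoform proteins (I/L-insensitive).

Matching is exact substring search over canonicalized protein sequences.
Peptides hitting more than one gene are discarded (they cannot attribute
evidence); peptides hitting a proper subset of a gene's isoforms are the
isoform-discriminating peptides that drive everything downstream.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotation import Gene, GeneSet, Isoform
from .filtering import PeptideRecord
from .peptides import canonical_il


@dataclass
class PeptideMatch:
    canon_seq: str
    gene_id: str
    isoform_ids: set[str] = field(default_factory=set)
    positions: dict[str, list[int]] = field(default_factory=dict)  # iso -> 1-based starts
    datasets: set[str] = field(default_factory=set)

    def is_discriminating(self, gene: Gene) -> bool:
        """True when the peptide maps to a proper, non-empty subset of the
        gene's isoforms (and can therefore tell isoforms apart)."""
        return 0 < len(self.isoform_ids) < len(gene.isoforms)


class ProteinIndex:
    """Concatenated canonical proteome with '#' separators for fast
    multi-isoform substring lookup via str.find."""

    def __init__(self, gene_set: GeneSet) -> None:
        parts: list[str] = []
        self.offsets: list[int] = []
        self.isoforms: list[Isoform] = []
        pos = 0
        for iso in gene_set.isoforms():
            canon = canonical_il(iso.protein)
            self.offsets.append(pos)
            self.isoforms.append(iso)
            parts.append(canon)
            pos += len(canon) + 1
        self.text = "#".join(parts)

    def occurrences(self, canon_pep: str) -> list[tuple[Isoform, int]]:
        """All (isoform, 1-based start) occurrences of a canonical peptide."""
        hits = []
        start = self.text.find(canon_pep)
        while start != -1:
            idx = bisect.bisect_right(self.offsets, start) - 1
            iso = self.isoforms[idx]
            hits.append((iso, start - self.offsets[idx] + 1))
            start = self.text.find(canon_pep, start + 1)
        return hits


def map_peptides(
    peptides: Sequence[PeptideRecord] | Iterable[str],
    gene_set: GeneSet,
    index: ProteinIndex | None = None,
) -> tuple[list[PeptideMatch], dict[str, int]]:
    """Match peptides against the canonical proteome.

    Accepts PeptideRecords or bare sequences.  Returns gene-unique matches
    and an audit of peptides dropped for matching no gene or >1 gene.
    """
    index = index or ProteinIndex(gene_set)
    audit = {"unmatched": 0, "multi_gene": 0}
    matches: list[PeptideMatch] = []
    for item in peptides:
        if isinstance(item, PeptideRecord):
            canon, datasets = item.canon_seq, set(item.datasets)
        else:
            canon, datasets = canonical_il(item), set()
        occ = index.occurrences(canon)
        if not occ:
            audit["unmatched"] += 1
            continue
        genes = {iso.gene_id for iso, _ in occ}
        if len(genes) > 1:
            audit["multi_gene"] += 1
            continue
        match = PeptideMatch(canon, genes.pop(), datasets=datasets)
        for iso, start in occ:
            match.isoform_ids.add(iso.isoform_id)
            match.positions.setdefault(iso.isoform_id, []).append(start)
        matches.append(match)
    return matches, audit


def matches_by_gene(matches: Sequence[PeptideMatch]) -> dict[str, list[PeptideMatch]]:
    out: dict[str, list[PeptideMatch]] = {}
    for m in matches:
        out.setdefault(m.gene_id, []).append(m)
    return out


def pick_main_isoform(gene: Gene, matches: Sequence[PeptideMatch]) -> str:
    """The gene's main isoform: most isoform-discriminating peptides, ties
    broken by principal flag, then longest protein, then smallest id.
    Falls back to the principal isoform when no peptide discriminates."""
    counts = {iso_id: 0 for iso_id in gene.isoforms}
    for m in matches:
        if m.gene_id == gene.gene_id and m.is_discriminating(gene):
            for iso_id in m.isoform_ids:
                counts[iso_id] += 1
    if not matches or all(c == 0 for c in counts.values()):
        return gene.principal_isoform().isoform_id
    return min(
        counts,
        key=lambda i: (
            -counts[i],
            not gene.isoforms[i].principal,
            -len(gene.isoforms[i].protein),
            i,
        ),
    )


def count_gene_evidence(
    matches: Sequence[PeptideMatch], detection_threshold: int = 2
) -> dict[str, dict]:
    """Per-gene unique-peptide counts; a gene counts as detected with
    at least ``detection_threshold`` distinct peptides."""
    peps: dict[str, set[str]] = {}
    for m in matches:
        peps.setdefault(m.gene_id, set()).add(m.canon_seq)
    return {
        g: {"n_peptides": len(s), "detected": len(s) >= detection_threshold}
        for g, s in peps.items()
    }


def write_matches_tsv(matches: Sequence[PeptideMatch], path) -> None:
    rows = [
        {
            "peptide": m.canon_seq,
            "gene": m.gene_id,
            "isoforms": ";".join(sorted(m.isoform_ids)),
            "positions": ";".join(
                f"{iso}:{','.join(map(str, sorted(pos)))}"
                for iso, pos in sorted(m.positions.items())
            ),
        }
        for m in matches
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
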