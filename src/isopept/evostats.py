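"""Enrichment testing, exon-origin dating and conservation tallies.

Works from precomputed cross-species similarity hit tables (BLAST-style
tabular output), a species presence/absence table and a rooted Newick
species tree; no sequence searching happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = in-set / background, columns = detected / not."""

    a: int  # in-set, detected
    b: int  # in-set, not detected
    c: int  # background, detected
    d: int  # background, not detected

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def fisher_exact(table: ContingencyTable, sided: str = "two-sided") -> dict:
    """Exact hypergeometric test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) whose probability does not exceed that of the observed
    table (minimum-likelihood method).  The odds ratio is (a*d)/(b*c),
    with a 0.5 continuity correction applied to every cell when any of
    b*c's factors is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if 0 in (row1, c + d, col1, b + d):
        raise ValueError("Fisher test undefined: a margin is zero")
    dist = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    if sided == "two-sided":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif sided == "greater":
        p = float(pmf[support >= a].sum())
    elif sided == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    if b * c == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {"p_value": min(p, 1.0), "odds_ratio": float(odds)}


@dataclass(frozen=True)
class HitRecord:
    """One cross-species similarity hit for a query exon."""

    query_exon_id: str
    species: str
    chrom: str
    start: int
    end: int
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start > end")


def read_hit_tsv(path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            str(r.query_exon_id),
            str(r.species),
            str(r.chrom),
            int(r.start),
            int(r.end),
            float(getattr(r, "evalue", 0.0)),
        )
        for r in df.itertuples(index=False)
    ]


def assign_hits_to_genes(
    hits: Sequence[HitRecord],
    target_genes: Mapping[str, Sequence[tuple[str, str, int, int]]],
    gene_lengths: Mapping[str, Sequence[int]],
    window_quantile: float = 0.95,
) -> dict[HitRecord, str]:
    """Assign each hit to an annotated gene or a de-novo locus.

    The grouping window per species is the ``window_quantile`` quantile
    of that species' gene-length distribution.  Hits within the window
    of an annotated gene interval take that gene (nearest wins);
    remaining hits are single-linkage clustered into new loci with the
    same window.
    """
    windows = {
        sp: float(np.quantile(np.asarray(lengths, dtype=float), window_quantile))
        for sp, lengths in gene_lengths.items()
    }
    assignment: dict[HitRecord, str] = {}
    leftovers: dict[str, list[HitRecord]] = {}
    for hit in hits:
        window = windows[hit.species]
        best: tuple[float, str] | None = None
        for gene_id, chrom, g_start, g_end in target_genes.get(hit.species, ()):
            if chrom != hit.chrom:
                continue
            dist = max(0, max(g_start - hit.end, hit.start - g_end))
            if dist <= window and (best is None or dist < best[0]):
                best = (dist, gene_id)
        if best is not None:
            assignment[hit] = best[1]
        else:
            leftovers.setdefault(hit.species, []).append(hit)
    for sp, sp_hits in leftovers.items():
        window = windows[sp]
        sp_hits.sort(key=lambda h: (h.chrom, h.start))
        locus_n = 0
        prev: HitRecord | None = None
        for hit in sp_hits:
            if (
                prev is None
                or hit.chrom != prev.chrom
                or hit.start - prev.end > window
            ):
                locus_n += 1
            assignment[hit] = f"{sp}:novel_locus_{locus_n}"
            prev = hit
    return assignment


@dataclass
class SpeciesPresence:
    feature_id: str
    presence: dict[str, bool]


def read_presence_tsv(path) -> list[SpeciesPresence]:
    """Presence TSV: feature_id column plus one 0/1 column per species."""
    df = pd.read_csv(path, sep="\t").set_index("feature_id")
    return [
        SpeciesPresence(str(fid), {sp: bool(v) for sp, v in row.items()})
        for fid, row in df.iterrows()
    ]


def load_tree(newick_path_or_string: str) -> dendropy.Tree:
    """Read a rooted species tree from a Newick string or file path."""
    src = str(newick_path_or_string)
    kwargs = {"schema": "newick", "rooting": "force-rooted"}
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, **kwargs)
    return dendropy.Tree.get(path=src, **kwargs)


def dollo_origin(presence: SpeciesPresence, tree: dendropy.Tree) -> dendropy.Node:
    """Origin of a presence/absence character under Dollo parsimony.

    A single gain and any number of losses: the origin is the most
    recent common ancestor of all taxa possessing the character.
    """
    present = sorted(sp for sp, p in presence.presence.items() if p)
    if not present:
        raise ValueError(f"feature {presence.feature_id}: present in no species")
    labels = {t.label for t in tree.taxon_namespace}
    unknown = [sp for sp in present if sp not in labels]
    if unknown:
        raise KeyError(f"species not in tree: {unknown}")
    if len(present) == 1:
        leaf = tree.find_node_with_taxon_label(present[0])
        return leaf
    return tree.mrca(taxon_labels=present)


def node_label(node: dendropy.Node) -> str:
    """Stable name for a tree node: its own label, its taxon, or the
    sorted tuple of leaf taxa below it."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def conservation_fraction(exon_hit_calls: Mapping[str, bool]) -> float:
    """Fraction of exons called conserved (hit in/near an orthologous gene)."""
    if not exon_hit_calls:
        raise ValueError("no conservation calls supplied")
    return sum(bool(v) for v in exon_hit_calls.values()) / len(exon_hit_calls)
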