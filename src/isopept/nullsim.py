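"""Null abundance models for expected alternative-splicing detection.

How many genes with protein-level splice evidence would we expect to see
if isoform expression followed a simple null model?  Peptides are drawn
per gene from the unique fully-tryptic peptide database — as many as
were observed for that gene — and a gene counts as an AS gene when the
drawn peptides satisfy the same both-sides evidence rule used on the
real data.  Two abundance models are provided:

  uniform   every isoform of a gene expressed equally (each unique
            peptide weight 1)
  dominant  the principal isoform produced ``dominance_ratio`` times
            (default 50) more than each other isoform; a peptide's
            weight aggregates the abundances of the isoforms carrying it

The observed counts sit far below both models when most genes express a
single dominant protein isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotation import Gene, GeneSet
from .events import SpliceEvent, extract_events, project_isoform_pair
from .peptides import PeptideDB

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModelConfig:
    model: str = "uniform"  # "uniform" | "dominant"
    dominance_ratio: float = 50.0
    replicates: int = 100
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("uniform", "dominant"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.dominance_ratio < 1 or self.replicates < 1:
            raise ValueError("dominance_ratio >= 1 and replicates >= 1 required")


@dataclass
class SimulationSummary:
    per_replicate: list[dict] = field(default_factory=list)

    @property
    def mean_as_genes(self) -> float:
        return float(np.mean([r["as_genes"] for r in self.per_replicate]))

    @property
    def mean_three_plus_genes(self) -> float:
        return float(np.mean([r["three_plus_genes"] for r in self.per_replicate]))

    @property
    def sem_as_genes(self) -> float:
        vals = [r["as_genes"] for r in self.per_replicate]
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0


def assign_peptide_weights(
    db: PeptideDB, gene: Gene, model: str = "uniform", dominance_ratio: float = 50.0
) -> dict[str, float]:
    """Sampling weight for each unique peptide of a gene.

    Uniform: weight 1.  Dominant: ``dominance_ratio`` for occurrence in
    the principal isoform plus 1 per non-principal isoform carrying the
    peptide, so shared peptides aggregate isoform abundances.
    """
    gene_peps = {
        canon
        for canon, locs in db.entries.items()
        if any(g == gene.gene_id for g, _i, _p in locs)
    }
    if not gene_peps:
        raise KeyError(f"gene {gene.gene_id} has no peptides in the database")
    if model == "uniform":
        return {p: 1.0 for p in gene_peps}
    principal = gene.principal_isoform().isoform_id
    weights = {}
    for p in gene_peps:
        isos = {i for g, i, _pos in db.entries[p] if g == gene.gene_id}
        weights[p] = dominance_ratio * (principal in isos) + sum(
            1 for i in isos if i != principal
        )
    return weights


@dataclass
class _GeneSim:
    """Precomputed sampling machinery for one gene."""

    peptides: list[str]
    weights: np.ndarray
    # per event: (main-support indices, alt-support indices, alt isoform id)
    events: list[tuple[set[int], set[int], str]]


def _event_support_indices(
    event: SpliceEvent,
    pep_index: dict[str, int],
    positions: Mapping[str, dict[str, list[int]]],
) -> tuple[set[int], set[int]]:
    """Indices of database peptides able to support each side of an event.

    Mirrors the evidence rule of the events module: segment overlap for
    inserted/substituted sequence, junction crossing for deletions, with
    the peptide absent from the partner isoform in both cases.
    """
    main_id, alt_id = event.main_isoform_id, event.alt_isoform_id

    def collect(iso_id: str, other_id: str, segment: tuple[int, int], junction: bool):
        out = set()
        for canon, idx in pep_index.items():
            pos_self = positions.get(iso_id, {}).get(canon)
            if not pos_self or positions.get(other_id, {}).get(canon):
                continue
            n = len(canon)
            for start in pos_self:
                s0 = start - 1
                if junction:
                    ok = s0 < segment[0] and s0 + n > segment[0]
                else:
                    ok = s0 < segment[1] and s0 + n > segment[0]
                if ok:
                    out.add(idx)
                    break
        return out

    main_sup = collect(
        main_id, alt_id, event.main_segment, junction=event.main_len == 0
    )
    alt_sup = collect(alt_id, main_id, event.alt_segment, junction=event.alt_len == 0)
    return main_sup, alt_sup


def _prepare_gene(
    gene: Gene, db: PeptideDB, config: NullModelConfig
) -> _GeneSim | None:
    weights = assign_peptide_weights(db, gene, config.model, config.dominance_ratio)
    peptides = sorted(weights)
    pep_index = {p: i for i, p in enumerate(peptides)}
    # per-isoform positions of each gene peptide
    positions: dict[str, dict[str, list[int]]] = {}
    for p in peptides:
        for g, iso, start in db.entries[p]:
            if g == gene.gene_id:
                positions.setdefault(iso, {}).setdefault(p, []).append(start)
    main = gene.principal_isoform()
    ev_support = []
    for iso_id in sorted(gene.isoforms):
        if iso_id == main.isoform_id:
            continue
        aln = project_isoform_pair(main, gene.isoforms[iso_id])
        for ev in extract_events(aln):
            main_sup, alt_sup = _event_support_indices(ev, pep_index, positions)
            if main_sup and alt_sup:
                ev_support.append((main_sup, alt_sup, iso_id))
    w = np.array([weights[p] for p in peptides], dtype=float)
    return _GeneSim(peptides, w / w.sum(), ev_support)


def simulate_draws(
    gene_set: GeneSet,
    db: PeptideDB,
    per_gene_counts: Mapping[str, int],
    config: NullModelConfig = NullModelConfig(),
) -> SimulationSummary:
    """Monte-Carlo replicate draws of per-gene peptides.

    For each replicate and gene, draw ``per_gene_counts[gene]`` distinct
    peptides (without replacement by default) with probability
    proportional to their model weight; the gene is an AS gene when the
    drawn set covers both sides of at least one event between the main
    isoform and any alternative, and a three-plus gene when events
    against two or more distinct alternatives are covered (peptides
    jointly distinguish >= 3 isoforms).  Fixed seed => identical output.
    """
    sims: dict[str, _GeneSim] = {}
    for gene_id, count in per_gene_counts.items():
        if count <= 0 or gene_id not in gene_set.genes:
            continue
        sims[gene_id] = _prepare_gene(gene_set.genes[gene_id], db, config)

    rng = np.random.default_rng(config.seed)
    summary = SimulationSummary()
    order = sorted(sims)
    for _rep in range(config.replicates):
        as_genes = 0
        three_plus = 0
        for gene_id in order:
            sim = sims[gene_id]
            k = per_gene_counts[gene_id]
            n = len(sim.peptides)
            if k > n and not config.with_replacement:
                log.warning(
                    "gene %s: requested %d draws of %d peptides; drawing all",
                    gene_id,
                    k,
                    n,
                )
                k = n
            drawn = set(
                rng.choice(n, size=k, replace=config.with_replacement, p=sim.weights)
            )
            alts = {
                alt_id
                for main_sup, alt_sup, alt_id in sim.events
                if drawn & main_sup and drawn & alt_sup
            }
            if alts:
                as_genes += 1
            if len(alts) >= 2:
                three_plus += 1
        summary.per_replicate.append(
            {"as_genes": as_genes, "three_plus_genes": three_plus}
        )
    return summary


def compare_to_observed(
    summary: SimulationSummary, observed: Mapping[str, float]
) -> dict:
    """Fold ratios mean_simulated / observed for both statistics."""
    out = {}
    for key, mean in (
        ("as_genes", summary.mean_as_genes),
        ("three_plus_genes", summary.mean_three_plus_genes),
    ):
        obs = observed.get(key, 0)
        if obs == 0:
            out[key] = {"ratio": float("inf"), "flagged_zero_observed": True}
        else:
            out[key] = {"ratio": mean / obs, "flagged_zero_observed": False}
    return out
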