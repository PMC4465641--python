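"""Per-dataset quality filters and the cross-experiment requirement.

Each large-scale proteomics dataset carries its own reliability profile
(search engines, score scales, digestion enzymes), so filtering is
configured per dataset: enzymatic specificity, a minimum search-engine
score, and a minimum number of agreeing engines.  Missed-cleavage
peptides are only trusted when one of their fully cleaved sub-peptides
was also observed, and a peptide must be seen in at least two independent
datasets to enter the mapping stage at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peptides import ENZYME_RULES, canonical_il, cleavage_sites, count_missed


@dataclass
class PeptideRecord:
    """One observed peptide with its provenance.

    ``prev_aa``/``next_aa`` are the flanking protein residues reported by
    the search pipeline ('-' at a protein terminus); they determine
    enzymatic specificity.  ``datasets`` and the per-dataset engine/score
    maps accumulate as records are merged across experiments.
    """

    raw_seq: str
    enzyme: str = "trypsin"
    datasets: set[str] = field(default_factory=set)
    engines: dict[str, frozenset[str]] = field(default_factory=dict)
    scores: dict[str, float | None] = field(default_factory=dict)
    prev_aa: str = "-"
    next_aa: str = "-"
    n_missed: int | None = None

    def __post_init__(self) -> None:
        if self.n_missed is None:
            self.n_missed = count_missed(self.raw_seq, self.enzyme)

    @property
    def canon_seq(self) -> str:
        return canonical_il(self.raw_seq)

    def n_conforming_termini(self) -> int:
        """How many peptide termini are consistent with the declared enzyme.

        A terminus conforms if it is a protein terminus or an enzymatic
        cleavage site (not followed by proline, matching the digestion
        rule).  2 = fully specific, 1 = semi-specific, 0 = non-specific.
        """
        residues = ENZYME_RULES[self.enzyme]
        n = 0
        if self.prev_aa == "-" or (
            self.prev_aa in residues and self.raw_seq[0] != "P"
        ):
            n += 1
        if self.next_aa == "-" or (
            self.raw_seq[-1] in residues and self.next_aa != "P"
        ):
            n += 1
        return n


@dataclass(frozen=True)
class DatasetFilterConfig:
    dataset_id: str
    min_score: float | None = None
    min_engines: int = 1
    allowed_enzymes: frozenset[str] = frozenset(ENZYME_RULES)
    require_fully_specific: bool = True

    def __post_init__(self) -> None:
        if self.min_engines < 1:
            raise ValueError("min_engines must be >= 1")


@dataclass
class FilteredPeptideSet:
    peptides: list[PeptideRecord]
    audit: dict[str, int] = field(default_factory=dict)


def read_peptide_tsv(path) -> list[PeptideRecord]:
    """Read a peptide table: sequence, dataset, engines (';'-joined), score,
    enzyme, prev_aa, next_aa and optionally n_missed (recomputed if absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    records = []
    for row in df.itertuples(index=False):
        ds = str(row.dataset)
        score = getattr(row, "score", None)
        score = None if pd.isna(score) else float(score)
        n_missed = getattr(row, "n_missed", None)
        n_missed = None if n_missed is None or pd.isna(n_missed) else int(n_missed)
        records.append(
            PeptideRecord(
                raw_seq=row.sequence,
                enzyme=getattr(row, "enzyme", "trypsin") or "trypsin",
                datasets={ds},
                engines={ds: frozenset(str(row.engines).split(";"))},
                scores={ds: score},
                prev_aa=getattr(row, "prev_aa", "-") or "-",
                next_aa=getattr(row, "next_aa", "-") or "-",
                n_missed=n_missed,
            )
        )
    return records


def write_peptide_tsv(records: Iterable[PeptideRecord], path) -> None:
    rows = []
    for r in records:
        for ds in sorted(r.datasets):
            rows.append(
                {
                    "sequence": r.raw_seq,
                    "dataset": ds,
                    "engines": ";".join(sorted(r.engines.get(ds, ()))),
                    "score": r.scores.get(ds),
                    "enzyme": r.enzyme,
                    "prev_aa": r.prev_aa,
                    "next_aa": r.next_aa,
                    "n_missed": r.n_missed,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_dataset_filters(
    peptides: Sequence[PeptideRecord], config: DatasetFilterConfig
) -> FilteredPeptideSet:
    """Specificity, enzyme, score and engine-agreement filters for one dataset."""
    kept: list[PeptideRecord] = []
    audit = {"non_specific": 0, "enzyme": 0, "score": 0, "engines": 0}
    ds = config.dataset_id
    for rec in peptides:
        if rec.enzyme not in config.allowed_enzymes:
            audit["enzyme"] += 1
            continue
        if config.require_fully_specific and rec.n_conforming_termini() < 2:
            audit["non_specific"] += 1
            continue
        if config.min_score is not None:
            score = rec.scores.get(ds)
            if score is None:
                raise ValueError(
                    f"dataset {ds}: record {rec.raw_seq} lacks a score but "
                    "min_score is configured"
                )
            if score < config.min_score:
                audit["score"] += 1
                continue
        if len(rec.engines.get(ds, ())) < config.min_engines:
            audit["engines"] += 1
            continue
        kept.append(rec)
    return FilteredPeptideSet(kept, audit)


def enforce_missed_cleavage_support(
    peptides: Sequence[PeptideRecord], min_len: int = 1
) -> FilteredPeptideSet:
    """Keep missed-cleavage peptides only when a fully cleaved sub-peptide
    of the same enzyme is present in the same set (canonical comparison).

    Runs after the specificity/score filters; support is assessed within
    one dataset's filtered set.  Multi-enzyme datasets are handled
    per enzyme, since a sub-peptide only supports a missed cleavage under
    the enzyme that produced it.
    """
    observed_zero: dict[str, set[str]] = {}
    for rec in peptides:
        if rec.n_missed == 0:
            observed_zero.setdefault(rec.enzyme, set()).add(rec.canon_seq)

    kept, removed = [], 0
    for rec in peptides:
        if rec.n_missed == 0:
            kept.append(rec)
            continue
        sites = cleavage_sites(rec.raw_seq, rec.enzyme)
        bounds = [0] + [s + 1 for s in sites] + [len(rec.raw_seq)]
        subs = {
            canonical_il(rec.raw_seq[bounds[i] : bounds[i + 1]])
            for i in range(len(bounds) - 1)
            if bounds[i + 1] - bounds[i] >= min_len
        }
        if subs & observed_zero.get(rec.enzyme, set()):
            kept.append(rec)
        else:
            removed += 1
    return FilteredPeptideSet(kept, {"unsupported_missed_cleavage": removed})


def cross_experiment_filter(
    per_dataset_sets: Mapping[str, FilteredPeptideSet], min_datasets: int = 2
) -> list[PeptideRecord]:
    """Retain canonical peptides observed in >= min_datasets datasets,
    merging provenance into a single record per peptide."""
    if min_datasets > len(per_dataset_sets):
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {len(per_dataset_sets)} "
            "datasets provided"
        )
    merged: dict[str, PeptideRecord] = {}
    for ds in sorted(per_dataset_sets):
        for rec in per_dataset_sets[ds].peptides:
            canon = rec.canon_seq
            if canon not in merged:
                merged[canon] = PeptideRecord(
                    raw_seq=rec.raw_seq,
                    enzyme=rec.enzyme,
                    datasets=set(rec.datasets),
                    engines=dict(rec.engines),
                    scores=dict(rec.scores),
                    prev_aa=rec.prev_aa,
                    next_aa=rec.next_aa,
                    n_missed=rec.n_missed,
                )
            else:
                tgt = merged[canon]
                tgt.datasets |= rec.datasets
                tgt.engines.update(rec.engines)
                tgt.scores.update(rec.scores)
    return [
        rec for rec in merged.values() if len(rec.datasets) >= min_datasets
    ]


def run_filter_pipeline(
    per_dataset_records: Mapping[str, Sequence[PeptideRecord]],
    configs: Mapping[str, DatasetFilterConfig],
    min_datasets: int = 2,
    support_min_len: int = 1,
) -> tuple[list[PeptideRecord], dict[str, dict[str, int]]]:
    """Per-dataset filters, then missed-cleavage support, then the
    cross-experiment requirement.  Returns the high-confidence peptide
    list and a per-dataset audit of removals."""
    filtered: dict[str, FilteredPeptideSet] = {}
    audits: dict[str, dict[str, int]] = {}
    for ds, records in per_dataset_records.items():
        cfg = configs.get(ds, DatasetFilterConfig(dataset_id=ds))
        stage1 = apply_dataset_filters(records, cfg)
        stage2 = enforce_missed_cleavage_support(stage1.peptides, support_min_len)
        filtered[ds] = stage2
        audits[ds] = {**stage1.audit, **stage2.audit}
    return cross_experiment_filter(filtered, min_datasets), audits
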