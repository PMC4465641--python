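"""Effect of splice events on protein functional-domain annotations.

Domain annotations (e.g. Pfam-A intervals from a domain scanner) are an
input, given per isoform in that isoform's own protein coordinates.  A
splice event is judged against the domains it touches:

  broken  an overlapping domain loses or gains >= 5 residues without
          disappearing entirely
  lost    at least one whole domain is absent from the alternative,
          remaining domains intact
  swap    the alternative replaces one set of domain accessions over the
          event region with a different set
  none    otherwise

Special rule: a homologous-exon substitution coinciding with a domain
leaves the domain intact ('unbroken') — the swapped exons are homologous,
so the domain is preserved — unless the accession is explicitly listed
as an override (poorly delimited domain families).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import SpliceEvent

log = logging.getLogger(__name__)

BROKEN_MIN_RESIDUES = 5  # change of >= 5 residues damages a domain

VERDICTS = ("broken", "lost", "swap", "none")


@dataclass(frozen=True)
class DomainAnnotation:
    isoform_id: str
    domain_acc: str
    start: int  # 1-based inclusive protein coordinates
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.isoform_id}/{self.domain_acc}: bad interval "
                f"{self.start}-{self.end}"
            )

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open residue interval."""
        return (self.start - 1, self.end)


@dataclass
class DomainImpact:
    event: SpliceEvent
    verdict: str
    broken_accs: tuple[str, ...] = ()
    lost_accs: tuple[str, ...] = ()
    gained_accs: tuple[str, ...] = ()


def read_domain_tsv(path) -> dict[str, list[DomainAnnotation]]:
    """Domain TSV: isoform, accession, start, end (1-based)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DomainAnnotation]] = {}
    for row in df.itertuples(index=False):
        ann = DomainAnnotation(str(row.isoform), str(row.accession), int(row.start), int(row.end))
        out.setdefault(ann.isoform_id, []).append(ann)
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def event_domain_effect(
    event: SpliceEvent,
    main_domains: Sequence[DomainAnnotation],
    alt_domains: Sequence[DomainAnnotation],
    override_accs: Iterable[str] = (),
) -> DomainImpact:
    """Classify one event's effect on the domain architecture.

    For every main-isoform domain overlapping the event: residues deleted
    from the domain plus residues inserted into its interior give the
    size of the change; a wholly deleted domain is a loss candidate.
    Alternative-side domains overlapping the replacement segment with
    accessions that do not mirror the main side mark a swap.
    """
    override = set(override_accs)
    ms, me = event.main_segment
    as_, ae = event.alt_segment
    main_domains = sorted(
        main_domains, key=lambda d: d.end - d.start, reverse=True
    )  # longer domain wins on conflicting overlaps
    seen_spans: list[tuple[int, int]] = []

    broken: list[str] = []
    lost: list[str] = []
    main_region_accs: Counter = Counter()
    for dom in main_domains:
        s, e = dom.interval0
        deleted = _overlap((s, e), (ms, me))
        interior_insert = ae - as_ if (ae > as_ and s < ms and me < e) else 0
        if deleted == 0 and interior_insert == 0:
            continue
        if any(_overlap((s, e), sp) > 0 for sp in seen_spans):
            log.warning(
                "overlapping domain calls on %s near %s; longer domain kept",
                dom.isoform_id,
                dom.domain_acc,
            )
            continue
        seen_spans.append((s, e))
        main_region_accs[dom.domain_acc] += 1
        if deleted == e - s:
            lost.append(dom.domain_acc)
        elif deleted + interior_insert >= BROKEN_MIN_RESIDUES:
            broken.append(dom.domain_acc)

    alt_region_accs: Counter = Counter()
    for dom in alt_domains:
        if _overlap(dom.interval0, (as_, ae)) > 0:
            alt_region_accs[dom.domain_acc] += 1
    gained = sorted((alt_region_accs - main_region_accs).elements())

    if event.kind == "homologous_substitution" and not (
        (set(main_region_accs) | set(alt_region_accs)) & override
    ):
        verdict = "none"
    elif lost and gained:
        verdict = "swap"
    elif broken:
        verdict = "broken"
    elif lost:
        verdict = "lost"
    else:
        verdict = "none"
    return DomainImpact(event, verdict, tuple(broken), tuple(lost), tuple(gained))


def classify_all(
    events: Sequence[SpliceEvent],
    domain_annotations: Mapping[str, Sequence[DomainAnnotation]],
    override_accs: Iterable[str] = (),
) -> list[DomainImpact]:
    return [
        event_domain_effect(
            ev,
            domain_annotations.get(ev.main_isoform_id, ()),
            domain_annotations.get(ev.alt_isoform_id, ()),
            override_accs,
        )
        for ev in events
    ]


def tally_domain_effects(
    events: Sequence[SpliceEvent],
    domain_annotations: Mapping[str, Sequence[DomainAnnotation]],
    override_accs: Iterable[str] = (),
) -> dict:
    """Counts and percentages of broken/lost/swap/none over an event set."""
    impacts = classify_all(events, domain_annotations, override_accs)
    counts = Counter(imp.verdict for imp in impacts)
    n = len(impacts)
    summary = {f"{v}_n": counts.get(v, 0) for v in VERDICTS}
    summary["n_events"] = n
    summary["percentages"] = {
        v: (100.0 * counts.get(v, 0) / n if n else 0.0) for v in VERDICTS
    }
    return summary


def write_impact_tsv(impacts: Sequence[DomainImpact], path) -> None:
    rows = [
        {
            "gene": imp.event.gene_id,
            "main_isoform": imp.event.main_isoform_id,
            "alt_isoform": imp.event.alt_isoform_id,
            "kind": imp.event.kind,
            "verdict": imp.verdict,
            "broken": ";".join(imp.broken_accs),
            "lost": ";".join(imp.lost_accs),
            "gained": ";".join(imp.gained_accs),
        }
        for imp in impacts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
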