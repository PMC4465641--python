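"""Summary arithmetic over pipeline tallies.

Small, deliberately boring functions that turn category counts into the
percentages, rates and fold ratios a study report quotes.  Keeping them
in one place means every reported number is reproducible from the raw
counts, and the same code serves both the synthetic pipeline outputs and
externally supplied count tables.
"""

from __future__ import annotations

from typing import Mapping

from .evostats import ContingencyTable, fisher_exact


def percentage(part: float, total: float, ndigits: int | None = 1) -> float:
    """100 * part / total, optionally rounded."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    value = 100.0 * part / total
    return round(value, ndigits) if ndigits is not None else value


def category_percentages(
    counts: Mapping[str, int], ndigits: int | None = 1
) -> dict[str, float]:
    """Per-category percentages of the total; unrounded values sum to 100."""
    total = sum(counts.values())
    return {k: percentage(v, total, ndigits) for k, v in counts.items()}


def fold_ratio(simulated: float, observed: float, ndigits: int | None = 1) -> float:
    """How many times larger a simulated count is than the observed one."""
    if observed == 0:
        return float("inf")
    value = simulated / observed
    return round(value, ndigits) if ndigits is not None else value


def rate_per_gene(n_events: float, n_genes: float, ndigits: int | None = 2) -> float:
    if n_genes == 0:
        raise ZeroDivisionError("rate over zero genes")
    value = n_events / n_genes
    return round(value, ndigits) if ndigits is not None else value


def enrichment_test(
    set_detected: int,
    set_total: int,
    background_detected: int,
    background_total: int,
    sided: str = "two-sided",
) -> dict:
    """Fisher exact test of detection enrichment for a gene set against a
    background, from the four raw counts."""
    table = ContingencyTable(
        a=set_detected,
        b=set_total - set_detected,
        c=background_detected,
        d=background_total - background_detected,
    )
    return fisher_exact(table, sided=sided)
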