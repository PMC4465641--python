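"""Synthetic annotation, peptide-detection and cross-species fixtures.

Every pipeline stage is testable without external downloads: this module
generates multi-isoform gene models realizing each splice-event kind
(including mutually exclusive homologous exon pairs, NAGNAG indels and
frame-disjoint two-protein pairs), a variable-first-exon gene cluster,
read-through and pseudoautosomal decoys, per-isoform domain placements
with known impact verdicts, noisy multi-experiment peptide detections
driven by a dominant-isoform abundance model, injected filter-target
artifacts, and species presence/absence fixtures with known origin
nodes.  Everything is deterministic under the configured seed, and every
emitted object traces to a truth record.

Peptide detection emulates the real situation this pipeline probes: each
gene expresses its main isoform at some abundance and every alternative
isoform at ``dominance_ratio`` times less, and the peptides observed for
a gene are drawn with probability proportional to the total abundance of
the isoforms carrying them.  With the default ratio (250:1) alternative-
specific peptides are rare, so observed splice-event yields sit far
below what equal-expression or moderate-dominance null models predict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import ClusterDef, Exon, Gene, GeneSet, Isoform
from .domains import DomainAnnotation
from .events import project_isoform_pair
from .filtering import DatasetFilterConfig, PeptideRecord
from .peptides import DigestConfig, canonical_il, digest

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NON_KR = "ACDEFGHILMNPQSTVWY"

CHROM = "chr1"
PAR_CHROM = "chrXY"
#: configurable pseudoautosomal-like region used by the generated decoys
PAR_REGIONS = [(PAR_CHROM, 0, 50_000)]

EVENT_KIND_DEFAULTS = {
    "indel": 0.25,
    "nagnag": 0.10,
    "homologous_substitution": 0.15,
    "cterm_substitution": 0.12,
    "nterm_substitution": 0.08,
    "internal_substitution": 0.05,
    "two_proteins": 0.05,
    "none": 0.20,
}

#: reliability profile of each emulated proteomics dataset
DATASET_PROFILES: dict[str, dict] = {
    "geiger": {"engines": ("Andromeda",), "min_score": 100.0, "min_engines": 1},
    "nagaraj": {"engines": ("Andromeda",), "min_score": 100.0, "min_engines": 1},
    "wilhelm": {"engines": ("Andromeda",), "min_score": 100.0, "min_engines": 1},
    "kim": {"engines": ("Mascot", "Sequest"), "min_score": None, "min_engines": 2},
    "nist": {
        "engines": ("Sequest", "Andromeda", "Mascot", "X!Tandem", "OMSSA"),
        "min_score": None,
        "min_engines": 2,
    },
    "peptideatlas": {"engines": ("SpectraST",), "min_score": None, "min_engines": 1},
    "ezkurdia": {"engines": ("X!Tandem",), "min_score": None, "min_engines": 1},
    "munoz": {"engines": ("Mascot",), "min_score": None, "min_engines": 1},
}

SCORED_DATASETS = ("geiger", "nagaraj", "wilhelm")


def default_filter_configs() -> dict[str, DatasetFilterConfig]:
    return {
        ds: DatasetFilterConfig(
            dataset_id=ds,
            min_score=prof["min_score"],
            min_engines=prof["min_engines"],
        )
        for ds, prof in DATASET_PROFILES.items()
    }


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 200
    event_type_proportions: tuple[tuple[str, float], ...] = tuple(
        EVENT_KIND_DEFAULTS.items()
    )
    second_event_fraction: float = 0.15  # of indel genes gain a second alternative
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_codons: tuple[int, int] = (18, 45)
    tryptic_site_rate: float = 0.11
    hes_identity_range: tuple[float, float] = (0.40, 0.95)
    hes_unambiguous_identity: float = 0.70
    n_experiments: int = 8
    abundance_mu: float = 2.7  # log-scale of detected peptides per gene
    abundance_sigma: float = 0.6
    max_coverage: float = 0.6  # proteomics never sees every peptide of a gene
    dominance_ratio: float = 250.0  # main:alternative isoform abundance
    expressed_alt_fraction: float = 0.10  # genes whose alternative is really expressed
    expressed_alt_ratio: float = 2.0  # main:alt ratio for those genes
    clean_missed_rate: float = 0.05  # genes with a supported missed cleavage
    artifact_rates: tuple[tuple[str, float], ...] = (
        ("non_tryptic", 0.02),
        ("unsupported_missed", 0.02),
        ("single_experiment", 0.03),
        ("sub_score", 0.02),
    )
    n_readthrough: int = 4
    n_par_genes: int = 2
    with_cluster: bool = True
    seed: int = 0

    def proportions(self) -> dict[str, float]:
        props = dict(self.event_type_proportions)
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_type_proportions sum to {total}, not 1")
        if any(v < 0 or v > 1 for v in props.values()):
            raise ValueError("proportions must lie in [0, 1]")
        return props


@dataclass
class PlantedEvent:
    gene_id: str
    main_isoform_id: str
    alt_isoform_id: str
    kind: str
    main_segment: tuple[int, int]  # 0-based half-open protein interval
    alt_segment: tuple[int, int]
    identity: float | None = None  # for homologous pairs
    ambiguous: bool = False  # identity too low to guarantee the homology call
    domain_verdict: str | None = None
    detectable: bool | None = None  # set by simulate_detections


@dataclass
class TruthTables:
    events: list[PlantedEvent] = field(default_factory=list)
    hes_pairs: list[dict] = field(default_factory=list)
    domain_rows: list[DomainAnnotation] = field(default_factory=list)
    clusters: list[ClusterDef] = field(default_factory=list)
    readthrough_ids: list[str] = field(default_factory=list)
    par_gene_ids: list[str] = field(default_factory=list)
    decoy_isoforms: list[Isoform] = field(default_factory=list)
    peptide_origin: dict[str, str] = field(default_factory=dict)
    clean_peptides: set[str] = field(default_factory=set)
    per_gene_detected: dict[str, int] = field(default_factory=dict)
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)


def allocate_exact(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n items to categories (exact totals)."""
    floors = {k: int(np.floor(p * n)) for k, p in proportions.items()}
    remainder = n - sum(floors.values())
    order = sorted(
        proportions,
        key=lambda k: (-(proportions[k] * n - floors[k]), k),
    )
    for k in order[:remainder]:
        floors[k] += 1
    return floors


def _sample_protein(rng: np.random.Generator, n: int, kr_rate: float) -> str:
    out = []
    for _ in range(n):
        if rng.random() < kr_rate:
            out.append("K" if rng.random() < 0.5 else "R")
        else:
            out.append(AA_NON_KR[rng.integers(len(AA_NON_KR))])
    return "".join(out)


def _sample_dissimilar_segment(
    rng: np.random.Generator,
    length: int,
    kr_rate: float,
    against: Sequence[str],
    margin_p: float = 0.05,
    max_tries: int = 20,
) -> str:
    """Sample a random segment guaranteed non-homologous to the given ones.

    Non-homologous substitutions are planted with a generous margin: the
    permutation homology test must stay clearly insignificant (p >=
    ``margin_p``, an order of magnitude above the 0.005 call threshold)
    against every segment the new one will be mutually exclusive with.
    Without this, ~0.5% of random pairs would sit exactly at the test's
    significance floor and the planted kind would be ill-defined.
    """
    from .events import test_segment_homology

    seg = _sample_protein(rng, length, kr_rate)
    for _ in range(max_tries):
        if all(
            test_segment_homology(a, seg)["empirical_p"] >= margin_p
            for a in against
        ):
            break
        seg = _sample_protein(rng, length, kr_rate)
    return seg


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float
) -> tuple[str, float]:
    n_mut = int(round((1.0 - identity) * len(seq)))
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    chars = list(seq)
    for p in positions:
        choices = [c for c in AA20 if c != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    realized = sum(a == b for a, b in zip(seq, chars)) / len(seq)
    return "".join(chars), realized


class _GeneBuilder:
    """Lays out one gene's exons in a transcription-coordinate cursor, then
    mirrors them onto the genome for minus-strand genes."""

    def __init__(self, gene_id: str, chrom: str, base: int, strand: str) -> None:
        self.gene_id = gene_id
        self.chrom = chrom
        self.base = base
        self.strand = strand
        self.cursor = 0
        self._exons: list[tuple[str, int, int, str]] = []  # id, t_start, t_end, seg

    def add_exon(self, exon_id: str, seg: str, gap_after: int = 400) -> str:
        t_start = self.cursor
        t_end = t_start + 3 * len(seg)
        self._exons.append((exon_id, t_start, t_end, seg))
        self.cursor = t_end + gap_after
        return exon_id

    def add_exon_at(self, exon_id: str, t_start: int, seg: str) -> str:
        self._exons.append((exon_id, t_start, t_start + 3 * len(seg), seg))
        return exon_id

    def finish(self) -> dict[str, tuple[Exon, str]]:
        span = max(t_end for _, _, t_end, _ in self._exons) + 100
        out = {}
        for exon_id, t_start, t_end, seg in self._exons:
            if self.strand == "+":
                g_start, g_end = self.base + t_start, self.base + t_end
            else:
                g_start = self.base + (span - t_end)
                g_end = self.base + (span - t_start)
            out[exon_id] = (
                Exon(exon_id, self.chrom, g_start, g_end, self.strand, 0),
                seg,
            )
        return out


def _make_isoform(
    iso_id: str, gene_id: str, exon_map: dict, exon_ids: Sequence[str]
) -> Isoform:
    exons = [exon_map[e][0] for e in exon_ids]
    protein = "".join(exon_map[e][1] for e in exon_ids)
    return Isoform(iso_id, gene_id, exons, protein)


def _offsets(exon_map: dict, exon_ids: Sequence[str]) -> dict[str, int]:
    off, pos = {}, 0
    for e in exon_ids:
        off[e] = pos
        pos += len(exon_map[e][1])
    return off


def generate_gene_set(config: SynthConfig = SynthConfig()) -> tuple[GeneSet, TruthTables]:
    """Build the annotation and its ground truth.

    Returns the analysis-ready gene set (decoys excluded, cluster members
    still separate genes — merge with ``truth.clusters``) plus the truth
    tables.  Deterministic: the same config yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    props = config.proportions()
    counts = allocate_exact(props, config.n_genes)
    kinds: list[str] = []
    for kind in sorted(counts):
        kinds.extend([kind] * counts[kind])
    rng.shuffle(kinds)

    truth = TruthTables()
    genes: dict[str, Gene] = {}
    locus_spacing = 20_000
    lo_ex, hi_ex = config.exons_per_gene
    lo_c, hi_c = config.exon_codons
    indel_genes: list[str] = []

    for gi, kind in enumerate(kinds):
        gene_id = f"G{gi:04d}"
        strand = "-" if gi % 5 == 4 else "+"
        builder = _GeneBuilder(gene_id, CHROM, 1000 + gi * locus_spacing, strand)
        n_ex = int(rng.integers(lo_ex, hi_ex + 1))
        segs = []
        for k in range(n_ex):
            n_codons = int(rng.integers(lo_c, hi_c + 1))
            seg = _sample_protein(rng, n_codons, config.tryptic_site_rate)
            if k == 0:
                seg = "M" + seg[1:]
            segs.append(seg)
        main_exon_ids = [
            builder.add_exon(f"{gene_id}.e{k}", seg) for k, seg in enumerate(segs)
        ]
        internal = list(range(1, n_ex - 1))
        k_ev = int(rng.choice(internal))
        alt_exon_ids: list[str] | None = None
        identity = None
        ambiguous = False

        if kind == "none":
            alt_exon_ids = None
        elif kind == "indel":
            alt_exon_ids = [e for i, e in enumerate(main_exon_ids) if i != k_ev]
            indel_genes.append(gene_id)
        elif kind == "nagnag":
            d = int(rng.integers(1, 5))
            var_seg = segs[k_ev][d:]
            # the variant shares the 3' part of the exon: same genomic bases
            orig_t_start = builder._exons[k_ev][1]
            var_id = builder.add_exon_at(
                f"{gene_id}.e{k_ev}v", orig_t_start + 3 * d, var_seg
            )
            alt_exon_ids = list(main_exon_ids)
            alt_exon_ids[k_ev] = var_id
        elif kind == "homologous_substitution":
            lo_i, hi_i = config.hes_identity_range
            identity = float(rng.uniform(lo_i, hi_i))
            partner_seg, identity = _mutate_to_identity(rng, segs[k_ev], identity)
            ambiguous = identity < config.hes_unambiguous_identity
            src_t_end = builder._exons[k_ev][2]
            var_id = builder.add_exon_at(
                f"{gene_id}.e{k_ev}h", src_t_end + 120, partner_seg
            )
            alt_exon_ids = list(main_exon_ids)
            alt_exon_ids[k_ev] = var_id
        elif kind in ("cterm_substitution", "nterm_substitution", "internal_substitution"):
            target = {"cterm_substitution": n_ex - 1, "nterm_substitution": 0}.get(
                kind, k_ev
            )
            new_len = max(10, len(segs[target]) - int(rng.integers(4, 9)))
            new_seg = _sample_dissimilar_segment(
                rng, new_len, config.tryptic_site_rate, [segs[target]]
            )
            src_t_end = builder._exons[target][2]
            var_id = builder.add_exon_at(
                f"{gene_id}.e{target}s", src_t_end + 120, new_seg
            )
            alt_exon_ids = list(main_exon_ids)
            alt_exon_ids[target] = var_id
            k_ev = target
        elif kind == "two_proteins":
            # a disjoint exon chain in the same locus: no shared codons.
            # kept shorter than the main protein so the main isoform stays
            # the longest
            alt_exon_ids = []
            t_base = builder.cursor + 500
            for k in range(3):
                seg = _sample_dissimilar_segment(
                    rng, int(rng.integers(12, 21)), config.tryptic_site_rate, segs
                )
                alt_exon_ids.append(
                    builder.add_exon_at(
                        f"{gene_id}.x{k}", t_base + k * 400, seg
                    )
                )
                t_base += 3 * len(seg)
        else:  # pragma: no cover
            raise ValueError(kind)

        exon_map = builder.finish()
        main_iso = _make_isoform(f"{gene_id}.t1", gene_id, exon_map, main_exon_ids)
        gene = Gene(gene_id, {main_iso.isoform_id: main_iso}, source_gene_ids=[gene_id])
        genes[gene_id] = gene
        if alt_exon_ids is None:
            _plant_domains(truth, gene_id, None, exon_map, main_exon_ids, None, None, rng)
            continue
        alt_iso = _make_isoform(f"{gene_id}.t2", gene_id, exon_map, alt_exon_ids)
        gene.isoforms[alt_iso.isoform_id] = alt_iso
        m_off = _offsets(exon_map, main_exon_ids)
        a_off = _offsets(exon_map, alt_exon_ids)
        ev = _planted_event_for(
            gene_id, main_iso, alt_iso, kind, k_ev, main_exon_ids, alt_exon_ids,
            exon_map, m_off, a_off, identity, ambiguous,
        )
        truth.events.append(ev)
        if kind == "homologous_substitution":
            truth.hes_pairs.append(
                {
                    "gene_id": gene_id,
                    "exon_a": exon_map[main_exon_ids[k_ev]][0].key,
                    "exon_b": exon_map[alt_exon_ids[k_ev]][0].key,
                    "identity": identity,
                    "ambiguous": ambiguous,
                    "from_cluster": False,
                }
            )
        _plant_domains(
            truth, gene_id, ev, exon_map, main_exon_ids, alt_exon_ids, k_ev, rng
        )

    # second alternative (another exon skip) for a fraction of indel genes
    n_second = int(round(config.second_event_fraction * len(indel_genes)))
    for gene_id in indel_genes[:n_second]:
        gene = genes[gene_id]
        main_iso = gene.isoforms[f"{gene_id}.t1"]
        first_ev = next(e for e in truth.events if e.gene_id == gene_id)
        skipped_len = first_ev.main_segment[1] - first_ev.main_segment[0]
        # find which exon the first event skipped, pick a different internal one
        exon_ids = [e.exon_id for e in main_iso.exons]
        seg_lens = [e.length // 3 for e in main_iso.exons]
        offs = np.cumsum([0] + seg_lens)
        k1 = int(np.searchsorted(offs, first_ev.main_segment[0]))
        # avoid k1 (first event) and k1+1 (a planted 'broken' domain can
        # extend into the following exon)
        choices = [k for k in range(1, len(exon_ids) - 1) if k not in (k1, k1 + 1)]
        if not choices:
            continue
        k2 = choices[0]
        alt2_exons = [e for i, e in enumerate(main_iso.exons) if i != k2]
        alt2 = Isoform(
            f"{gene_id}.t3",
            gene_id,
            alt2_exons,
            "".join(
                main_iso.protein[offs[i] : offs[i + 1]]
                for i in range(len(exon_ids))
                if i != k2
            ),
        )
        gene.isoforms[alt2.isoform_id] = alt2
        truth.events.append(
            PlantedEvent(
                gene_id,
                main_iso.isoform_id,
                alt2.isoform_id,
                "indel",
                (int(offs[k2]), int(offs[k2 + 1])),
                (int(offs[k2]), int(offs[k2])),
                domain_verdict="none",
            )
        )

    if config.with_cluster:
        _build_cluster(genes, truth, rng, config, base=1000 + len(kinds) * locus_spacing)
    _build_decoys(genes, truth, rng, config)

    gene_set = GeneSet(genes={g: genes[g] for g in sorted(genes)})
    return gene_set, truth


def _planted_event_for(
    gene_id, main_iso, alt_iso, kind, k_ev, main_exon_ids, alt_exon_ids,
    exon_map, m_off, a_off, identity, ambiguous,
) -> PlantedEvent:
    main_len = len(main_iso.protein)
    alt_len = len(alt_iso.protein)
    if kind == "two_proteins":
        return PlantedEvent(
            gene_id, main_iso.isoform_id, alt_iso.isoform_id, kind,
            (0, main_len), (0, alt_len),
        )
    m_ex = main_exon_ids[k_ev]
    m_start = m_off[m_ex]
    m_seg_len = len(exon_map[m_ex][1])
    if kind == "indel":
        return PlantedEvent(
            gene_id, main_iso.isoform_id, alt_iso.isoform_id, kind,
            (m_start, m_start + m_seg_len), (m_start, m_start),
        )
    if kind == "nagnag":
        a_ex = alt_exon_ids[k_ev]
        d = m_seg_len - len(exon_map[a_ex][1])
        return PlantedEvent(
            gene_id, main_iso.isoform_id, alt_iso.isoform_id, kind,
            (m_start, m_start + d), (a_off[a_ex], a_off[a_ex]),
        )
    a_ex = alt_exon_ids[k_ev]
    a_start = a_off[a_ex]
    a_seg_len = len(exon_map[a_ex][1])
    return PlantedEvent(
        gene_id, main_iso.isoform_id, alt_iso.isoform_id, kind,
        (m_start, m_start + m_seg_len), (a_start, a_start + a_seg_len),
        identity=identity, ambiguous=ambiguous,
    )


def _map_domain_to_alt(
    main_iso: Isoform, alt_iso: Isoform, start0: int, end0: int
) -> tuple[int, int] | None:
    """Project a main-isoform domain interval into alt coordinates via the
    shared-codon correspondence; None when no residue survives."""
    aln = project_isoform_pair(main_iso, alt_iso)
    js = [j for i, j in aln.pairs if start0 <= i < end0]
    if not js:
        return None
    return (min(js), max(js) + 1)


def _plant_domains(
    truth, gene_id, ev, exon_map, main_exon_ids, alt_exon_ids, k_ev, rng
) -> None:
    """Place domain annotations realizing a known impact verdict per event."""
    main_id = f"{gene_id}.t1"
    m_off = _offsets(exon_map, main_exon_ids)
    segs = [exon_map[e][1] for e in main_exon_ids]
    first_len = len(segs[0])

    def add(iso_id, acc, start0, end0):
        truth.domain_rows.append(DomainAnnotation(iso_id, acc, start0 + 1, end0))

    if ev is None:  # single-isoform gene: one decorative domain
        add(main_id, f"PF_{gene_id}_bg", 2, min(first_len, 12))
        return
    alt_id = ev.alt_isoform_id
    kind = ev.kind
    acc = f"PF_{gene_id}"
    m_start, m_end = ev.main_segment
    main_iso = None
    alt_iso = None

    def project(start0, end0):
        return _map_domain_to_alt(main_iso, alt_iso, start0, end0)

    # late import of the concrete isoforms via truth-independent closure:
    # callers pass exon maps, so rebuild the two isoforms locally
    main_iso = _make_isoform(main_id, gene_id, exon_map, main_exon_ids)
    alt_iso = _make_isoform(alt_id, gene_id, exon_map, alt_exon_ids)

    if kind == "indel":
        plan = ["broken", "lost", "none"][int(rng.integers(3))]
        if plan == "broken":
            s0, e0 = m_end - 6, m_end + 10
            add(main_id, acc, s0, e0)
        elif plan == "lost":
            s0, e0 = m_start + 2, m_end - 2
            add(main_id, acc, s0, e0)
            add(main_id, acc + "_keep", 2, min(first_len, 12))
        else:
            s0, e0 = 2, min(first_len, 12)
            add(main_id, acc, s0, e0)
        for dom in [d for d in truth.domain_rows if d.isoform_id == main_id]:
            mapped = project(dom.start - 1, dom.end)
            if mapped:
                add(alt_id, dom.domain_acc, mapped[0], mapped[1])
        ev.domain_verdict = plan
    elif kind == "nagnag":
        add(main_id, acc, m_start, m_end + 10)
        mapped = project(m_start, m_end + 10)
        if mapped:
            add(alt_id, acc, mapped[0], mapped[1])
        ev.domain_verdict = "none"  # change of <= 4 residues
    elif kind == "homologous_substitution":
        add(main_id, acc, m_start, m_end)
        a_start, a_end = ev.alt_segment
        add(alt_id, acc, a_start, a_end)
        ev.domain_verdict = "none"  # homologous exons leave the domain intact
    elif kind == "nterm_substitution":
        add(main_id, acc + "_a", m_start + 1, m_end - 1)
        a_start, a_end = ev.alt_segment
        add(alt_id, acc + "_b", a_start + 1, a_end - 1)
        ev.domain_verdict = "swap"
    elif kind == "cterm_substitution":
        plan = ["lost", "none"][int(rng.integers(2))]
        if plan == "lost":
            add(main_id, acc, m_start + 1, m_end - 1)
            add(main_id, acc + "_keep", 2, min(first_len, 12))
            add(alt_id, acc + "_keep", 2, min(first_len, 12))
        else:
            add(main_id, acc, 2, min(first_len, 12))
            add(alt_id, acc, 2, min(first_len, 12))
        ev.domain_verdict = plan
    elif kind == "internal_substitution":
        add(main_id, acc, 2, min(first_len, 12))
        add(alt_id, acc, 2, min(first_len, 12))
        ev.domain_verdict = "none"
    elif kind == "two_proteins":
        add(main_id, acc, m_start + 4, m_start + 20)
        ev.domain_verdict = "lost"


def _build_cluster(genes, truth, rng, config, base) -> None:
    """A variable-first-exon gene cluster: members share a common block of
    3' exons and differ in homologous first exons, annotated as separate
    genes but really splice variants of one gene."""
    shared_segs = [
        _sample_protein(rng, int(rng.integers(20, 36)), config.tryptic_site_rate)
        for _ in range(3)
    ]
    first_len = 28
    first_a = "M" + _sample_protein(rng, first_len - 1, config.tryptic_site_rate)
    first_b, id_b = _mutate_to_identity(rng, first_a, 0.85)
    first_c, id_c = _mutate_to_identity(rng, first_a, 0.85)
    first_a = first_a + _sample_protein(rng, 4, config.tryptic_site_rate)  # longest

    builder = _GeneBuilder("CL", CHROM, base, "+")
    t = 0
    firsts = {}
    for name, seg in (("a", first_a), ("b", first_b), ("c", first_c)):
        firsts[name] = builder.add_exon_at(f"CL.f{name}", t, seg)
        t += 3 * len(seg) + 300
    shared_ids = []
    for k, seg in enumerate(shared_segs):
        shared_ids.append(builder.add_exon_at(f"CL.s{k}", t, seg))
        t += 3 * len(seg) + 300
    exon_map = builder.finish()

    member_ids = []
    for name in ("a", "b", "c"):
        gid = f"CLG_{name}"
        iso = _make_isoform(f"{gid}.t1", gid, exon_map, [firsts[name]] + shared_ids)
        genes[gid] = Gene(gid, {iso.isoform_id: iso}, source_gene_ids=[gid])
        member_ids.append(gid)
    truth.clusters.append(ClusterDef("CL1", tuple(member_ids)))

    len_a, len_b, len_c = len(first_a), len(first_b), len(first_c)
    for name, other_len, ident in (("b", len_b, id_b), ("c", len_c, id_c)):
        truth.events.append(
            PlantedEvent(
                "CL1",
                "CLG_a.t1",
                f"CLG_{name}.t1",
                "homologous_substitution",
                (0, len_a),
                (0, other_len),
                identity=ident,
                ambiguous=ident < config.hes_unambiguous_identity,
                domain_verdict="none",
            )
        )
    for pair, ident in (
        (("a", "b"), id_b),
        (("a", "c"), id_c),
        (("b", "c"), None),
    ):
        truth.hes_pairs.append(
            {
                "gene_id": "CL1",
                "exon_a": exon_map[firsts[pair[0]]][0].key,
                "exon_b": exon_map[firsts[pair[1]]][0].key,
                "identity": ident,
                "ambiguous": False,
                "from_cluster": True,
            }
        )


def _build_decoys(genes, truth, rng, config) -> None:
    plus_genes = sorted(
        g
        for g in genes
        if g.startswith("G")
        and next(iter(genes[g].isoforms.values())).exons[0].strand == "+"
    )
    for i in range(config.n_readthrough):
        g1, g2 = genes[plus_genes[2 * i]], genes[plus_genes[2 * i + 1]]
        iso1 = g1.isoforms[f"{g1.gene_id}.t1"]
        iso2 = g2.isoforms[f"{g2.gene_id}.t1"]
        rt = Isoform(
            f"{g1.gene_id}.rt",
            g1.gene_id,
            list(iso1.exons) + [iso2.exons[0]],
            iso1.protein + iso2.protein[: iso2.exons[0].length // 3],
            read_through=True,
        )
        truth.decoy_isoforms.append(rt)
        truth.readthrough_ids.append(rt.isoform_id)
    for i in range(config.n_par_genes):
        gid = f"PARG{i}"
        builder = _GeneBuilder(gid, PAR_CHROM, 2000 + i * 5000, "+")
        seg = "M" + _sample_protein(rng, 40, config.tryptic_site_rate)
        builder.add_exon(f"{gid}.e0", seg)
        exon_map = builder.finish()
        iso = _make_isoform(f"{gid}.t1", gid, exon_map, [f"{gid}.e0"])
        truth.decoy_isoforms.append(iso)
        truth.par_gene_ids.append(gid)


# ---------------------------------------------------------------------------
# annotation writers


def write_annotation(gene_set: GeneSet, truth: TruthTables, gtf_path, fasta_path) -> None:
    """Write GTF + protein FASTA including the read-through and
    pseudoautosomal decoys, so loading exercises the filters."""
    all_isoforms = list(gene_set.isoforms()) + list(truth.decoy_isoforms)
    with open(gtf_path, "w") as gtf:
        for iso in all_isoforms:
            chrom, start, end = iso.genomic_span()
            tag = ' tag "readthrough_transcript";' if iso.read_through else ""
            attrs = f'gene_id "{iso.gene_id}"; transcript_id "{iso.isoform_id}";'
            gtf.write(
                f"{chrom}\tsynth\ttranscript\t{start + 1}\t{end}\t.\t"
                f"{iso.exons[0].strand}\t.\t{attrs}{tag}\n"
            )
            for exon in iso.exons:
                gtf.write(
                    f"{exon.chrom}\tsynth\tCDS\t{exon.start + 1}\t{exon.end}\t.\t"
                    f'{exon.strand}\t0\t{attrs} exon_id "{exon.exon_id}";{tag}\n'
                )
    with open(fasta_path, "w") as fa:
        for iso in all_isoforms:
            fa.write(f">{iso.isoform_id}\n{iso.protein}\n")


def write_cluster_yaml(clusters: Sequence[ClusterDef], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "cluster_name": c.cluster_name,
                    "member_gene_ids": list(c.member_gene_ids),
                }
                for c in clusters
            ],
            fh,
        )


def write_par_bed(path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in PAR_REGIONS:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_domain_tsv(truth: TruthTables, path) -> None:
    pd.DataFrame(
        [
            {
                "isoform": d.isoform_id,
                "accession": d.domain_acc,
                "start": d.start,
                "end": d.end,
            }
            for d in truth.domain_rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide detection


def _side_supporters(
    iso_digest: Mapping[str, list[tuple[str, int]]],
    iso_canon: Mapping[str, set[str]],
    iso_id: str,
    other_id: str,
    segment: tuple[int, int],
    junction: bool,
) -> set[str]:
    """Canonical peptides of one isoform able to evidence one event side."""
    out = set()
    for pep, start in iso_digest[iso_id]:
        canon = canonical_il(pep)
        if canon in iso_canon[other_id]:
            continue
        s0, n = start - 1, len(pep)
        if junction:
            ok = s0 < segment[0] and s0 + n > segment[0]
        else:
            ok = s0 < segment[1] and s0 + n > segment[0]
        if ok:
            out.add(canon)
    return out


def simulate_detections(
    merged_gene_set: GeneSet,
    truth: TruthTables,
    config: SynthConfig = SynthConfig(),
) -> dict[str, list[PeptideRecord]]:
    """Sample per-experiment peptide observations with known provenance.

    Detection is abundance-driven: the main isoform at relative abundance
    1, each alternative at 1/dominance_ratio, and each gene contributes a
    log-normally distributed number of distinct tryptic peptides drawn
    with probability proportional to summed isoform abundance.  Clean
    peptides appear in >= 2 experiments; artifacts (non-tryptic,
    unsupported missed cleavage, single-experiment, sub-threshold score)
    are injected at the configured rates and labelled in the truth
    tables.  Sets ``detectable`` on every planted event.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    datasets = sorted(DATASET_PROFILES)[: config.n_experiments]
    per_ds: dict[str, list[PeptideRecord]] = {ds: [] for ds in datasets}
    dig = DigestConfig()

    # canon -> (raw, iso_id, start) for flank lookup; canon -> gene
    occurrence: dict[str, tuple[str, str, int]] = {}
    canon_gene: dict[str, str] = {}
    gene_digests: dict[str, dict[str, list[tuple[str, int]]]] = {}
    iso_by_id: dict[str, Isoform] = {}

    for gene in merged_gene_set:
        iso_digest = {}
        for iso in gene.isoforms.values():
            iso_digest[iso.isoform_id] = [
                (p, s) for p, s, _m in digest(iso.protein, dig)
            ]
            iso_by_id[iso.isoform_id] = iso
        gene_digests[gene.gene_id] = iso_digest

    detected: dict[str, set[str]] = {}
    for gene in merged_gene_set:
        gene_id = gene.gene_id
        iso_digest = gene_digests[gene_id]
        main_id = min(
            gene.isoforms, key=lambda i: (-len(gene.isoforms[i].protein), i)
        )
        ratio = (
            config.expressed_alt_ratio
            if rng.random() < config.expressed_alt_fraction
            else config.dominance_ratio
        )
        abund = {
            iso_id: (1.0 if iso_id == main_id else 1.0 / ratio)
            for iso_id in gene.isoforms
        }
        truth.abundances[gene_id] = abund
        weights: dict[str, float] = {}
        for iso_id, prods in iso_digest.items():
            for pep, start in prods:
                canon = canonical_il(pep)
                other = canon_gene.get(canon)
                if other is not None and other != gene_id:
                    continue  # cross-gene collision: skip entirely
                canon_gene[canon] = gene_id
                occurrence.setdefault(canon, (pep, iso_id, start))
                weights[canon] = weights.get(canon, 0.0) + abund[iso_id]
        peps = sorted(weights)
        if not peps:
            detected[gene_id] = set()
            continue
        w = np.array([weights[p] for p in peps])
        cap = max(2, int(config.max_coverage * len(peps)))
        n_det = int(
            np.clip(round(rng.lognormal(config.abundance_mu, config.abundance_sigma)),
                    2, cap)
        )
        drawn_idx = rng.choice(len(peps), size=n_det, replace=False, p=w / w.sum())
        detected[gene_id] = {peps[i] for i in sorted(drawn_idx)}

    # supported missed cleavages for a fraction of genes
    for gene in merged_gene_set:
        if rng.random() >= config.clean_missed_rate:
            continue
        gene_id = gene.gene_id
        iso = gene.isoforms[
            min(gene.isoforms, key=lambda i: (-len(gene.isoforms[i].protein), i))
        ]
        frags = [(p, s) for p, s, m in digest(iso.protein, DigestConfig(min_len=1))
                 if m == 0]
        for (p1, s1), (p2, s2) in zip(frags, frags[1:]):
            if len(p1) >= 7 and s2 == s1 + len(p1) and len(p1) + len(p2) >= 8:
                joined = p1 + p2
                cj = canonical_il(joined)
                if cj in canon_gene and canon_gene[cj] != gene_id:
                    continue
                canon_gene[cj] = gene_id
                occurrence.setdefault(cj, (joined, iso.isoform_id, s1))
                detected[gene_id].add(canonical_il(p1))
                detected[gene_id].add(cj)
                break

    # event detectability from what was actually drawn
    iso_canon = {
        iso_id: {canonical_il(p) for p, _s in prods}
        for g, dig_map in gene_digests.items()
        for iso_id, prods in dig_map.items()
    }
    for ev in truth.events:
        if ev.gene_id not in gene_digests:
            ev.detectable = False
            continue
        iso_digest = gene_digests[ev.gene_id]
        main_sup = _side_supporters(
            iso_digest, iso_canon, ev.main_isoform_id, ev.alt_isoform_id,
            ev.main_segment, junction=ev.main_segment[0] == ev.main_segment[1],
        )
        alt_sup = _side_supporters(
            iso_digest, iso_canon, ev.alt_isoform_id, ev.main_isoform_id,
            ev.alt_segment, junction=ev.alt_segment[0] == ev.alt_segment[1],
        )
        got = detected[ev.gene_id]
        ev.detectable = bool(main_sup & got) and bool(alt_sup & got)

    # experiment assignment for clean peptides
    def emit(canon: str, ds_list: Sequence[str], low_score: bool = False) -> None:
        raw, iso_id, start = occurrence[canon]
        protein = iso_by_id[iso_id].protein
        prev_aa = protein[start - 2] if start > 1 else "-"
        next_pos = start - 1 + len(raw)
        next_aa = protein[next_pos] if next_pos < len(protein) else "-"
        for ds in ds_list:
            prof = DATASET_PROFILES[ds]
            if ds == "nist":
                k = int(rng.integers(2, len(prof["engines"]) + 1))
                engines = frozenset(
                    map(str, rng.choice(prof["engines"], size=k, replace=False))
                )
            else:
                engines = frozenset(prof["engines"])
            if prof["min_score"] is not None:
                score = (
                    float(rng.uniform(20, 90))
                    if low_score
                    else float(rng.uniform(120, 280))
                )
            else:
                score = float(rng.uniform(1, 100))
            per_ds[ds].append(
                PeptideRecord(
                    raw_seq=raw,
                    enzyme="trypsin",
                    datasets={ds},
                    engines={ds: engines},
                    scores={ds: score},
                    prev_aa=prev_aa,
                    next_aa=next_aa,
                )
            )

    def pick_datasets(n: int) -> list[str]:
        return sorted(rng.choice(datasets, size=n, replace=False))

    all_clean: list[str] = []
    for gene_id in sorted(detected):
        truth.per_gene_detected[gene_id] = len(detected[gene_id])
        for canon in sorted(detected[gene_id]):
            all_clean.append(canon)
    # emit supported-missed pairs into identical dataset sets
    missed_partner: dict[str, str] = {}
    for canon in all_clean:
        raw = occurrence[canon][0]
        if _n_internal_tryptic_sites(raw) >= 1:
            # find its first fully cleaved sub-peptide among clean peptides
            for other in sorted(detected[canon_gene[canon]]):
                if other != canon and other in canon and _n_internal_tryptic_sites(
                    occurrence[other][0]
                ) == 0:
                    missed_partner[canon] = other
                    break
    for canon in all_clean:
        truth.peptide_origin[canon] = (
            "clean_missed" if canon in missed_partner else "clean"
        )
        truth.clean_peptides.add(canon)
    for canon in all_clean:
        n_ds = 2 + int(rng.binomial(len(datasets) - 2, 0.25))
        ds_list = pick_datasets(n_ds)
        if canon in missed_partner:
            # same datasets as the supporting sub-peptide
            emit(canon, ds_list)
            emit(missed_partner[canon], ds_list)
        elif canon in missed_partner.values():
            continue  # emitted alongside its missed partner
        else:
            emit(canon, ds_list)

    _inject_artifacts(
        merged_gene_set, truth, config, rng, canon_gene, occurrence, iso_by_id,
        detected, emit, pick_datasets, datasets, len(all_clean),
    )
    return per_ds


def _n_internal_tryptic_sites(pep: str) -> int:
    return sum(
        1
        for i in range(len(pep) - 1)
        if pep[i] in "KR" and pep[i + 1] != "P"
    )


def _inject_artifacts(
    gene_set, truth, config, rng, canon_gene, occurrence, iso_by_id,
    detected, emit, pick_datasets, datasets, n_clean,
) -> None:
    rates = dict(config.artifact_rates)
    gene_ids = sorted(g for g in detected if detected[g])
    all_isoforms = [iso for g in gene_set for iso in g.isoforms.values()]

    def register(canon, raw, iso_id, start, label) -> bool:
        if canon in truth.peptide_origin or canon in canon_gene and canon_gene[
            canon
        ] != iso_by_id[iso_id].gene_id:
            return False
        occurrence.setdefault(canon, (raw, iso_id, start))
        canon_gene.setdefault(canon, iso_by_id[iso_id].gene_id)
        truth.peptide_origin[canon] = label
        return True

    # non-tryptic: random window with non-conforming termini
    n = int(round(rates.get("non_tryptic", 0) * n_clean))
    made = 0
    while made < n:
        iso = all_isoforms[int(rng.integers(len(all_isoforms)))]
        if len(iso.protein) < 30:
            continue
        start = int(rng.integers(5, len(iso.protein) - 15))
        raw = iso.protein[start : start + int(rng.integers(8, 13))]
        prev_aa = iso.protein[start - 1]
        next_aa = iso.protein[start + len(raw)]
        if prev_aa in "KR" or raw[-1] in "KR":
            continue
        canon = canonical_il(raw)
        if register(canon, raw, iso.isoform_id, start + 1, "artifact:non_tryptic"):
            emit(canon, pick_datasets(2))
            made += 1

    # unsupported missed cleavage: joined fragments, neither sub-peptide seen
    n = int(round(rates.get("unsupported_missed", 0) * n_clean))
    made = 0
    attempts = 0
    while made < n and attempts < 50 * n + 50:
        attempts += 1
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = gene_set.genes[gene_id]
        iso = next(iter(gene.isoforms.values()))
        frags = [
            (p, s) for p, s, m in digest(iso.protein, DigestConfig(min_len=1))
            if m == 0
        ]
        idx = int(rng.integers(max(1, len(frags) - 1)))
        if idx + 1 >= len(frags):
            continue
        (p1, s1), (p2, _s2) = frags[idx], frags[idx + 1]
        joined = p1 + p2
        if len(joined) < 8:
            continue
        c1, c2, cj = canonical_il(p1), canonical_il(p2), canonical_il(joined)
        if c1 in truth.clean_peptides or c2 in truth.clean_peptides:
            continue
        if register(cj, joined, iso.isoform_id, s1, "artifact:unsupported_missed"):
            emit(cj, pick_datasets(2))
            made += 1

    # single-experiment: valid peptides seen in exactly one dataset
    n = int(round(rates.get("single_experiment", 0) * n_clean))
    made = 0
    attempts = 0
    while made < n and attempts < 50 * n + 50:
        attempts += 1
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = gene_set.genes[gene_id]
        iso = next(iter(gene.isoforms.values()))
        prods = [(p, s) for p, s, _m in digest(iso.protein, DigestConfig())]
        if not prods:
            continue
        p, s = prods[int(rng.integers(len(prods)))]
        canon = canonical_il(p)
        if canon in truth.peptide_origin:
            continue
        if register(canon, p, iso.isoform_id, s, "artifact:single_experiment"):
            emit(canon, pick_datasets(1))
            made += 1

    # sub-threshold score: only in score-filtered datasets, scores below cut
    n = int(round(rates.get("sub_score", 0) * n_clean))
    made = 0
    attempts = 0
    while made < n and attempts < 50 * n + 50:
        attempts += 1
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = gene_set.genes[gene_id]
        iso = next(iter(gene.isoforms.values()))
        prods = [(p, s) for p, s, _m in digest(iso.protein, DigestConfig())]
        if not prods:
            continue
        p, s = prods[int(rng.integers(len(prods)))]
        canon = canonical_il(p)
        if canon in truth.peptide_origin:
            continue
        if register(canon, p, iso.isoform_id, s, "artifact:sub_score"):
            ds_list = sorted(rng.choice(SCORED_DATASETS, size=2, replace=False))
            emit(canon, ds_list, low_score=True)
            made += 1


def write_experiment_tsvs(per_ds: Mapping[str, list[PeptideRecord]], out_dir) -> None:
    from pathlib import Path

    from .filtering import write_peptide_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds, records in per_ds.items():
        write_peptide_tsv(records, out / f"{ds}.tsv")


# ---------------------------------------------------------------------------
# cross-species fixtures

SPECIES_TREE = "(lamprey,(coelacanth,(spotted_gar,(zebrafish,(fugu,human)))));"


@dataclass
class SpeciesFixtures:
    tree_newick: str
    presence: pd.DataFrame  # feature_id x species, 0/1
    origins: dict[str, str]  # feature_id -> planted origin node label
    hits: pd.DataFrame
    species_genes: dict[str, pd.DataFrame]
    hit_truth: dict[tuple, str]  # (feature, species, start) -> expected gene/locus


def generate_species_fixtures(
    n_features: int = 50, seed: int = 0, tree_newick: str = SPECIES_TREE
) -> SpeciesFixtures:
    """Presence/absence fixtures with known Dollo origins plus hit tables
    whose correct gene assignment is recorded."""
    from .evostats import load_tree, node_label

    rng = np.random.default_rng(seed)
    tree = load_tree(tree_newick)
    human = tree.find_node_with_taxon_label("human")
    path = [human]
    node = human.parent_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    leaves = sorted(t.label for t in tree.taxon_namespace)

    presence_rows = []
    origins: dict[str, str] = {}
    for i in range(n_features):
        fid = f"hes_exon_{i:03d}"
        origin = path[int(rng.integers(len(path)))]
        present = {sp: False for sp in leaves}
        present["human"] = True
        if origin is not human:
            # pin the MRCA: one leaf from the child subtree away from human
            for child in origin.child_nodes():
                child_leaves = {l.taxon.label for l in child.leaf_iter()}
                if "human" not in child_leaves:
                    present[sorted(child_leaves)[0]] = True
                    below = sorted(
                        l.taxon.label for l in origin.leaf_iter()
                    )
                    for sp in below:
                        if not present[sp] and rng.random() < 0.3:
                            present[sp] = True
                    break
        presence_rows.append({"feature_id": fid, **{sp: int(present[sp]) for sp in leaves}})
        origins[fid] = node_label(origin)

    presence = pd.DataFrame(presence_rows)

    species_genes: dict[str, pd.DataFrame] = {}
    gene_rows: dict[str, list] = {}
    for sp in leaves:
        if sp == "human":
            continue
        lengths = np.round(rng.lognormal(9.2, 0.5, size=60)).astype(int)
        starts = np.cumsum(lengths + 200_000) + 10_000
        rows = [
            {
                "gene_id": f"{sp}_g{j:02d}",
                "chrom": "c1",
                "start": int(starts[j] - lengths[j]),
                "end": int(starts[j]),
                "length": int(lengths[j]),
            }
            for j in range(60)
        ]
        gene_rows[sp] = rows
        species_genes[sp] = pd.DataFrame(rows)

    hit_rows = []
    hit_truth: dict[tuple, str] = {}
    for row in presence_rows:
        fid = row["feature_id"]
        for sp in leaves:
            if sp == "human" or not row[sp]:
                continue
            g = gene_rows[sp][int(rng.integers(60))]
            h_start = int(rng.integers(g["start"], g["end"] - 50))
            hit_rows.append(
                {
                    "query_exon_id": fid,
                    "species": sp,
                    "chrom": "c1",
                    "start": h_start,
                    "end": h_start + 60,
                    "evalue": float(10 ** -rng.uniform(3, 30)),
                }
            )
            hit_truth[(fid, sp, h_start)] = g["gene_id"]
    # far-away decoys that must become novel loci
    for sp in [l for l in leaves if l != "human"][:3]:
        far = gene_rows[sp][-1]["end"] + 5_000_000
        hit_rows.append(
            {
                "query_exon_id": "decoy",
                "species": sp,
                "chrom": "c1",
                "start": far,
                "end": far + 60,
                "evalue": 0.05,
            }
        )
        hit_truth[("decoy", sp, far)] = "novel"

    return SpeciesFixtures(
        tree_newick=tree_newick,
        presence=presence,
        origins=origins,
        hits=pd.DataFrame(hit_rows),
        species_genes=species_genes,
        hit_truth=hit_truth,
    )


def write_species_fixtures(fix: SpeciesFixtures, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "species_tree.nwk").write_text(fix.tree_newick + "\n")
    fix.presence.to_csv(out / "presence.tsv", sep="\t", index=False)
    fix.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    for sp, df in fix.species_genes.items():
        df.to_csv(out / f"genes_{sp}.tsv", sep="\t", index=False)
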