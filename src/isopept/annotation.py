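"""Gene-model layer: GTF + protein FASTA loading, cluster merging, principal isoforms.

The internal representation keeps only the coding structure of each
transcript: an ordered list of CDS exons (in transcription direction) and
the protein sequence.  Genomic coordinates are stored 0-based half-open;
GTF input/output is 1-based inclusive; protein coordinates are 1-based
where exposed to users.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Exon:
    """A CDS exon. ``start``/``end`` are 0-based half-open genomic coordinates."""

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_phase: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon {self.exon_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Genomic identity of the exon, independent of its id."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class Isoform:
    isoform_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)  # transcription order
    protein: str = ""
    read_through: bool = False
    principal: bool = False

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.exons)

    def codon_coordinates(self) -> list[tuple[tuple[str, int], ...]]:
        """Genomic coordinates of each codon, in transcription direction.

        Returns one tuple of three (chrom, position) pairs per protein
        residue.  Positions follow the strand, so two isoforms share a
        codon entry exactly when they read the same genomic bases in the
        same frame.
        """
        bases: list[tuple[str, int]] = []
        for exon in self.exons:
            if exon.strand == "+":
                bases.extend((exon.chrom, p) for p in range(exon.start, exon.end))
            else:
                bases.extend(
                    (exon.chrom, p) for p in range(exon.end - 1, exon.start - 1, -1)
                )
        n_codons = len(bases) // 3
        return [tuple(bases[3 * k : 3 * k + 3]) for k in range(n_codons)]

    def genomic_span(self) -> tuple[str, int, int]:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return (self.exons[0].chrom, min(starts), max(ends))


@dataclass
class Gene:
    gene_id: str
    isoforms: dict[str, Isoform] = field(default_factory=dict)
    cluster_id: str | None = None
    source_gene_ids: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        iso = next(iter(self.isoforms.values()))
        return iso.exons[0].chrom

    def genomic_span(self) -> tuple[str, int, int]:
        spans = [iso.genomic_span() for iso in self.isoforms.values() if iso.exons]
        chrom = spans[0][0]
        return (chrom, min(s[1] for s in spans), max(s[2] for s in spans))

    def principal_isoform(self) -> Isoform:
        for iso in self.isoforms.values():
            if iso.principal:
                return iso
        return self.isoforms[select_principal(self)]


@dataclass
class GeneSet:
    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self) -> Iterable[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def isoforms(self) -> Iterable[Isoform]:
        for gene in self.genes.values():
            yield from gene.isoforms.values()


@dataclass(frozen=True)
class ClusterDef:
    """A named group of annotated 'genes' to be treated as one gene.

    Models loci like UGT1A, where variable first exons joined to a shared
    set of exons are annotated as separate genes but behave as splice
    variants of a single gene.
    """

    cluster_name: str
    member_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("a cluster needs at least two member genes")


def read_cluster_yaml(path) -> list[ClusterDef]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [
        ClusterDef(d["cluster_name"], tuple(d["member_gene_ids"])) for d in raw
    ]


def read_region_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file of regions (e.g. pseudoautosomal) as 0-based half-open."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


def _overlaps_regions(span: tuple[str, int, int], regions) -> bool:
    chrom, start, end = span
    return any(c == chrom and start < e and s < end for c, s, e in regions)


class GtfParseError(ValueError):
    pass


def _parse_gtf_attributes(raw: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs.setdefault(key, []).append(value.strip().strip('"'))
    return attrs


def load_gene_set(
    gtf_path,
    protein_fasta_path,
    drop_read_through: bool = True,
    drop_pseudoautosomal: bool = True,
    pseudoautosomal_regions: Sequence[tuple[str, int, int]] | None = None,
    readthrough_tag: str = "readthrough_transcript",
    genome_fasta_path=None,
) -> GeneSet:
    """Load a GTF annotation and per-transcript protein FASTA into a GeneSet.

    Only CDS features are used.  Transcripts tagged as read-through (via
    ``readthrough_tag`` in the GTF ``tag`` attribute) are dropped when
    ``drop_read_through`` is set; genes overlapping any of the configured
    pseudoautosomal regions are dropped when ``drop_pseudoautosomal`` is
    set.  A coding transcript with no protein sequence (and no genome to
    translate from) is dropped with a warning.

    When ``genome_fasta_path`` is given, proteins missing from the FASTA
    are derived by translating the concatenated CDS, and provided
    proteins are checked against the translation.
    """
    from Bio import SeqIO

    proteins = {
        rec.id: str(rec.seq).rstrip("*")
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }
    genome = None
    if genome_fasta_path is not None:
        genome = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome_fasta_path), "fasta")
        }

    # transcript_id -> (gene_id, [(exon fields)], tags)
    tx_exons: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    tx_tags: dict[str, set[str]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{gtf_path}:{lineno}: expected 9 fields")
            chrom, _source, ftype, start, end, _score, strand, frame, attr_raw = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"{gtf_path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attributes(attr_raw)
            try:
                tid = attrs["transcript_id"][0]
                gid = attrs["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: missing transcript_id/gene_id"
                ) from exc
            phase = None if frame == "." else int(frame)
            exon_id = attrs.get("exon_id", [f"{tid}.cds{len(tx_exons.get(tid, []))}"])[0]
            tx_exons.setdefault(tid, []).append(
                Exon(exon_id, chrom, start_i - 1, end_i, strand, phase)
            )
            tx_gene[tid] = gid
            tx_tags.setdefault(tid, set()).update(attrs.get("tag", []))

    genes: dict[str, Gene] = {}
    for tid, exons in tx_exons.items():
        strand = exons[0].strand
        exons = sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
        read_through = readthrough_tag in tx_tags.get(tid, set())
        if drop_read_through and read_through:
            continue
        protein = proteins.get(tid, "")
        translated = ""
        if genome is not None:
            cds = "".join(
                genome[e.chrom][e.start : e.end] if e.strand == "+"
                else str(Seq(genome[e.chrom][e.start : e.end]).reverse_complement())
                for e in exons
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                translated = str(Seq(cds).translate()).rstrip("*")
        if not protein:
            protein = translated
        elif translated and protein != translated:
            log.warning("transcript %s: protein FASTA disagrees with CDS translation", tid)
        if not protein:
            log.warning("coding transcript %s has no protein sequence; dropped", tid)
            continue
        gid = tx_gene[tid]
        gene = genes.setdefault(gid, Gene(gid, source_gene_ids=[gid]))
        gene.isoforms[tid] = Isoform(tid, gid, exons, protein, read_through=read_through)

    if drop_pseudoautosomal and pseudoautosomal_regions:
        keep = {
            gid: g
            for gid, g in genes.items()
            if not _overlaps_regions(g.genomic_span(), pseudoautosomal_regions)
        }
        genes = keep

    return GeneSet(genes={gid: genes[gid] for gid in sorted(genes)})


def merge_gene_clusters(gene_set: GeneSet, clusters: Sequence[ClusterDef]) -> GeneSet:
    """Replace each cluster's member genes by a single merged gene.

    Idempotent: re-applying a ClusterDef whose members were already merged
    into the named cluster gene is a no-op.
    """
    genes = dict(gene_set.genes)
    for cluster in clusters:
        present = [m for m in cluster.member_gene_ids if m in genes]
        merged_already = (
            cluster.cluster_name in genes
            and set(cluster.member_gene_ids)
            <= set(genes[cluster.cluster_name].source_gene_ids)
        )
        if not present and merged_already:
            continue
        missing = [m for m in cluster.member_gene_ids if m not in genes]
        if missing:
            raise KeyError(
                f"cluster {cluster.cluster_name}: member gene(s) not found: "
                + ", ".join(missing)
            )
        merged = Gene(
            cluster.cluster_name,
            cluster_id=cluster.cluster_name,
            source_gene_ids=list(cluster.member_gene_ids),
        )
        for member in cluster.member_gene_ids:
            for iso in genes.pop(member).isoforms.values():
                moved = replace(iso, gene_id=cluster.cluster_name)
                merged.isoforms[moved.isoform_id] = moved
        genes[cluster.cluster_name] = merged
    return GeneSet(genes={gid: genes[gid] for gid in sorted(genes)})


def select_principal(
    gene: Gene, principal_table: Mapping[str, str] | None = None
) -> str:
    """Pick the gene's principal isoform and set its flag.

    Uses the externally supplied table (gene_id -> isoform_id, e.g. from
    APPRIS) when available; otherwise falls back to the longest protein,
    ties broken by lexicographically smallest isoform id.  The fallback
    is an approximation of feature-based principal-isoform selection.
    """
    if not gene.isoforms:
        raise ValueError(f"gene {gene.gene_id} has no isoforms")
    if principal_table and gene.gene_id in principal_table:
        iso_id = principal_table[gene.gene_id]
        if iso_id not in gene.isoforms:
            raise KeyError(
                f"principal table names unknown isoform {iso_id} for gene {gene.gene_id}"
            )
    else:
        iso_id = min(
            gene.isoforms, key=lambda i: (-len(gene.isoforms[i].protein), i)
        )
    for iso in gene.isoforms.values():
        iso.principal = iso.isoform_id == iso_id
    return iso_id


def select_all_principals(
    gene_set: GeneSet, principal_table: Mapping[str, str] | None = None
) -> dict[str, str]:
    return {g.gene_id: select_principal(g, principal_table) for g in gene_set}
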