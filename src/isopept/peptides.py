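"""In-silico digestion and the unique-peptide database.

Peptide identity throughout the pipeline is I/L-insensitive: mass
spectrometry cannot distinguish leucine from isoleucine, so sequences are
canonicalized by mapping I to L before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import GeneSet

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

#: residues after which each enzyme cleaves
ENZYME_RULES: dict[str, frozenset[str]] = {
    "trypsin": frozenset("KR"),
    "lysc": frozenset("K"),
    "chymotrypsin": frozenset("FWY"),
    "gluc": frozenset("ED"),
}


def canonical_il(seq: str) -> str:
    """Collapse isoleucine onto leucine so I/L-ambiguous matches compare equal."""
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"non-amino-acid character(s) in sequence: {sorted(bad)}")
    return seq.replace("I", "L")


@dataclass(frozen=True)
class DigestConfig:
    enzyme: str = "trypsin"
    max_missed: int = 0
    min_len: int = 7
    max_len: int | None = None
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_RULES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.min_len < 1 or self.max_missed < 0:
            raise ValueError("min_len must be >= 1 and max_missed >= 0")


def cleavage_sites(protein: str, enzyme: str = "trypsin", proline_rule: bool = True) -> list[int]:
    """0-based indices i such that the enzyme cleaves between i and i+1.

    The protein C-terminus is not a site.  With the proline rule, cleavage
    is suppressed when the following residue is proline.
    """
    residues = ENZYME_RULES[enzyme]
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in residues and not (proline_rule and protein[i + 1] == "P")
    ]


def count_missed(peptide: str, enzyme: str = "trypsin", proline_rule: bool = True) -> int:
    """Number of internal uncleaved sites a peptide retains."""
    return len(cleavage_sites(peptide, enzyme, proline_rule))


def digest(protein: str, config: DigestConfig = DigestConfig()) -> list[tuple[str, int, int]]:
    """Enumerate proteolytic products as (peptide, 1-based start, n_missed).

    Products with 0..max_missed missed cleavages are emitted, filtered to
    lengths within [min_len, max_len].  Concatenating the 0-missed
    products (before the length filter) reconstructs the protein.
    """
    if not protein:
        raise ValueError("empty protein")
    sites = cleavage_sites(protein, config.enzyme, config.proline_rule)
    boundaries = [0] + [s + 1 for s in sites] + [len(protein)]
    out: list[tuple[str, int, int]] = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for m in range(config.max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start, end = boundaries[i], boundaries[j]
            length = end - start
            if length < config.min_len:
                continue
            if config.max_len is not None and length > config.max_len:
                continue
            out.append((protein[start:end], start + 1, m))
    return out


@dataclass
class PeptideDB:
    """Unique canonical peptides mapped to every place they occur.

    ``entries``: canon_seq -> set of (gene_id, isoform_id, 1-based start).
    Each peptide is represented exactly once regardless of how many
    isoforms produce it.
    """

    entries: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def genes_of(self, canon_seq: str) -> set[str]:
        return {g for g, _i, _p in self.entries.get(canon_seq, ())}

    def isoforms_of(self, canon_seq: str) -> set[str]:
        return {i for _g, i, _p in self.entries.get(canon_seq, ())}

    def gene_peptides(self) -> dict[str, set[str]]:
        """gene_id -> set of canonical peptides occurring in that gene."""
        out: dict[str, set[str]] = {}
        for canon, locs in self.entries.items():
            for g, _i, _p in locs:
                out.setdefault(g, set()).add(canon)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("canon_seq\tgene_id\tisoform_id\tstart\n")
            for canon in sorted(self.entries):
                for g, i, p in sorted(self.entries[canon]):
                    fh.write(f"{canon}\t{g}\t{i}\t{p}\n")


def build_unique_peptide_db(
    gene_set: GeneSet, config: DigestConfig = DigestConfig()
) -> PeptideDB:
    """Digest every isoform and pool the canonicalized products.

    Used both for mapping sanity checks and as the peptide universe of
    the null abundance models (which, like the reference analysis, use
    fully cleaved products only: max_missed=0 by default).
    """
    db = PeptideDB()
    for iso in gene_set.isoforms():
        for pep, start, _m in digest(iso.protein, config):
            canon = canonical_il(pep)
            db.entries.setdefault(canon, set()).add((iso.gene_id, iso.isoform_id, start))
    return db
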