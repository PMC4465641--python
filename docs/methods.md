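# Methods

`isopept` asks how much alternative splicing is visible at the protein
level.  Transcript annotations describe tens of thousands of alternative
isoforms, but tandem-MS proteomics recovers peptide evidence for only a
small fraction of them.  The package implements the full chain of
reasoning needed to quantify that gap rigorously: conservative peptide
filtering, isoform-aware mapping, a splice-event taxonomy with explicit
evidence rules, a scan for mutually exclusive homologous exons, domain-
impact scoring, null abundance models, and Dollo-parsimony dating of
exon origins.  A first-class synthetic-data generator supplies study
conditions with complete ground truth, so every stage is tested without
external downloads.

## Gene model

Only coding structure is kept: each isoform is an ordered list of CDS
exons (transcription direction) plus its protein sequence.  Genomic
coordinates are 0-based half-open internally, 1-based inclusive at the
GTF boundary; protein coordinates are 1-based where user-facing.  On
load, transcripts tagged `readthrough_transcript` are dropped (they
overlap neighbouring coding genes and would make peptides ambiguous),
as are genes inside a configurable pseudoautosomal region list.
Annotated gene clusters whose members are really splice variants of one
locus (UGT1A-style variable first exons joined to shared exons) are
merged into single genes via a YAML cluster definition; the merge is
idempotent and keeps member-gene provenance.

Each gene gets a principal (reference) isoform: an externally supplied
designation when available, otherwise the longest protein with a
lexicographic tie-break.  The fallback is an approximation of
feature-based principal-isoform selection and is documented as such.

## Peptides

All peptide comparisons are I/L-insensitive (isoleucine and leucine are
isobaric), implemented by canonicalizing I→L on both peptides and
proteins.  In-silico digestion enumerates products for trypsin, LysC,
chymotrypsin and GluC with configurable missed cleavages, a 7-residue
minimum length by default, and the proline rule (no cleavage before P)
on by default — standard trypsin specificity; it is configurable because
whole-proteome digest counts depend on it.  The unique-peptide database
holds each canonical peptide once, mapped to every (gene, isoform,
position) where it occurs; the null models use fully cleaved tryptic
products only, because admitting all missed-cleavage combinations would
explode the peptide universe.

## Filtering

Each proteomics dataset carries its own reliability profile, so filters
are per dataset: enzymatic specificity (both termini must conform to the
declared enzyme, protein termini counting as conforming; "semi-specific"
means exactly one terminus conforms), a minimum search-engine score
where the dataset's engine provides a comparable scale (e.g. 100 for
Andromeda-scored sets), and a minimum number of agreeing engines where
multiple engines were run.  Score scales are never compared across
datasets.  A missed-cleavage peptide is kept only when one of its fully
cleaved sub-peptides is observed in the same dataset's filtered set
(checked per enzyme).  Finally, only peptides observed in two or more
datasets are mapped; single-experiment identifications are too likely to
be false positives.  All filters are contractive and audited — removal
counts per rule always reconcile with the input/output difference.

## Mapping and events

Peptides are exact-substring-matched against the canonical proteome via
a concatenated index; peptides hitting more than one gene are discarded,
and a peptide hitting a proper subset of a gene's isoforms is
isoform-discriminating.  Each gene's *main* isoform is the one with the
most discriminating peptides (ties: principal flag, longest protein,
smallest id).

Two isoforms are compared in genomic space: residues match iff their
codons read identical genomic bases in the same frame.  This makes exon
substitutions, NAGNAG acceptor shifts and frame-shifted overlaps fall
out of coordinate arithmetic with no sequence alignment; a global
protein alignment is the fallback when CDS coordinates are absent.
Maximal unmatched runs become events; alternatives that are pure
prefix/suffix truncations of the main isoform emit none (they are
indistinguishable from annotation fragments).  Kinds, in decision
order: no shared in-frame region → `two_proteins`; pure indel of ≤ 4
residues → `nagnag`, > 4 → `indel`; substitutions whose segments pass
the homology test → `homologous_substitution` (this outranks terminal
labels because homologous exon swaps also occur at first/last exons);
otherwise N-terminal, C-terminal or internal substitution by position.

Segment homology is a permutation test: the local alignment score
(BLOSUM62, gap open −11, extend −1) of the observed pair against 200
composition-preserving shuffles, homologous iff the empirical p ≤ 0.005.
The threshold mirrors a BLAST e-value cut-off of 0.005 without needing a
sequence database; the shuffle seed is derived from the sequences
themselves, so a given pair always receives one deterministic verdict
regardless of which module asks.  Note the test has an irreducible
false-positive rate of ~1/201 under the null — the price of an
empirical-p design — which the synthetic generator sidesteps by planting
non-homologous segments with a clear margin (below).

An identified splicing event (ISE) is an event with peptide evidence on
*both* sides: any isoform-specific peptide overlapping an inserted or
substituted segment by ≥ 1 residue, and, for the side where sequence was
deleted, a peptide on the shorter isoform crossing the junction with at
least one residue on each flank.  Pure terminal extensions are therefore
undetectable by construction, as they should be.  Events are
deduplicated by (gene, kind, set of genomic bases unique to the event).

## Homologous exon pairs (HES)

Independent of peptides, each multi-isoform gene is scanned for pairs of
CDS exons that never co-occur in a transcript, are each longer than
30 bp, and do not overlap genomically (overlapping "pairs" are splice-
site variants of one exon).  A pair is validated when its translations
(in the host transcript with the longest protein) pass the homology
test, the exons' midpoint positions agree within 10% of protein length
(a deterministic stand-in for manual positional inspection), and both
exons lie within 100 kb of the rest of the gene's exons — a guard
against candidates that belong to a paralogous neighbour or pseudogene.
Every validated pair, run through the events module on its host
transcripts, yields a homologous-substitution event (tested).

## Domain impact

Domain annotations (scanner output: isoform, accession, 1-based
interval) are inputs.  Per event: a domain that loses or gains five or
more residues without disappearing is *broken*; a domain wholly absent
from the alternative while the rest stay intact is *lost*; a lost
domain set accompanied by a different accession gained over the
replacement region is a *swap*; otherwise *none*.  A homologous-exon
substitution coinciding with a domain counts as `none` — homologous
exons preserve the fold — unless the accession is in a per-domain
override list (for poorly delimited families).  Insertion gains count
toward "broken" only when the insertion point is interior to the
domain.  On conflicting overlapping calls the longer domain wins, with
a warning.

## Null abundance models

How many AS genes would the same per-gene peptide yields produce under
null expression models?  For each gene, as many distinct tryptic
peptides as were observed are drawn from the unique-peptide database,
without replacement, with probability proportional to the model weight:
uniform (every peptide 1 — all isoforms equally expressed) or dominant
(ratio·[in principal] + 1 per other isoform carrying it; default ratio
50).  A gene counts as an AS gene when the drawn set satisfies the same
both-sides rule for at least one event between its main isoform and any
alternative, and as a three-plus gene when events against ≥ 2 distinct
alternatives are covered.  100 replicates are averaged; a fixed seed
gives bit-identical output.  Support sets per event are precomputed, so
replicates are cheap.

## Synthetic data generator

The generator is the package's study-conditions definition, not a test
convenience.  Defaults: 200 genes on one chromosome (one in five on the
minus strand), 5–8 CDS exons of 18–45 codons, residues uniform except
K/R at a combined 0.11 rate so tryptic fragments average ~9 residues.
Event kinds are allocated exactly by largest remainder: 25% exon-skip
indels, 10% NAGNAG (1–4 codon acceptor shifts sharing the exon's 3'
bases), 15% homologous exon pairs (a duplicated exon mutated to a
40–95% identity recorded per pair; pairs below 70% are flagged
*ambiguous* and exempt from exact-recovery claims), 12%/8%/5% C-/N-
terminal/internal substitutions (replacement exons rejection-sampled
until the homology test is comfortably insignificant, p ≥ 0.05, so the
planted "non-homologous" label is well-defined), 5% frame-disjoint
two-protein pairs, 20% single-isoform genes.  One UGT1A-style
three-member cluster with homologous variable first exons, four
read-through decoy transcripts and two pseudoautosomal decoy genes
exercise the loading filters.  Domains are planted per event with a
known verdict (broken/lost/swap/none), propagated to alternative
isoforms through the shared-codon correspondence.

Detection emulates dominant-isoform expression: each gene's main
isoform has relative abundance 1 and alternatives 1/250 — reflecting
the conclusion that most alternatives are produced well below 2% of the
main isoform — except for a 10% subpopulation whose alternative is
genuinely expressed at 1:2, which is what yields a small, realistic set
of detectable events (~5–10 per run).  Per gene, a log-normal(2.7, 0.6)
number of distinct peptides is drawn (capped at 60% of the gene's
peptide universe: proteomics coverage is never complete) with
probability proportional to summed isoform abundance.  Clean peptides
are emitted into ≥ 2 of the eight emulated experiments with
profile-appropriate engines and scores; artifacts are injected at ~2–3%
each: non-tryptic windows, missed-cleavage peptides whose sub-peptides
were never observed, single-experiment peptides, and sub-threshold
scores confined to score-filtered datasets.  Every emitted peptide
traces to exactly one truth label.  Because the model weights of the
dominant(R) null are proportional to the generator's summed abundances
for every R, the matching null model reproduces the generator's own
detection count (parameter-recovery test at R ∈ {1, 10, 50}).

Species fixtures: a rooted six-taxon tree (lamprey, coelacanth, spotted
gar, zebrafish, fugu, human); each feature's origin node is planted on
the root-to-human path and presence is pinned with one leaf from the
sibling subtree, so the Dollo reconstruction (MRCA of present leaves —
single gain, any number of losses) has a unique correct answer.  Hit
tables carry coordinates inside known target genes plus far decoys that
must cluster into novel loci under the 95th-percentile gene-length
window.

What the generator does not emulate: spectra, retention times, mass
accuracy, peptide detectability physics, PTMs, paralogy across genes,
and incomplete/erroneous gene models.  Passing tests therefore certify
the pipeline's logic and bookkeeping under controlled conditions, not
its robustness to annotation error or instrument bias.

## Numerical choices and degenerate inputs

Fisher's exact test sums hypergeometric probabilities ≤ that of the
observed table (minimum-likelihood two-sided; enrichment here is so
extreme that sidedness is immaterial), with a 0.5 continuity correction
on the odds ratio only when a denominator cell is zero; zero margins are
errors.  Draws larger than a gene's peptide universe fall back to
drawing everything, with a warning.  Empty segments never test as
homologous; segments shorter than two residues are never homologous.
Ties in principal selection, main-isoform choice and event
deduplication are broken deterministically (documented in each
docstring), so every pipeline output is reproducible bit-for-bit from
(config, seed).

## Known limitations

The permutation homology test is not a database e-value: scores are
compared only against shuffles of the partner segment, so very short or
low-complexity segments have little power, and the 0.005 threshold sits
at the resolution limit of 200 shuffles.  The HES positional-equivalence
threshold (10% of protein length) and the paralogy guard margin
(100 kb) replace manual curation with fixed cut-offs.  The main-isoform
rule can, with sparse evidence, select an alternative isoform and
re-express the same events from the other side; all event comparisons
are therefore symmetric in the isoform pair.
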