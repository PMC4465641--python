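# isopept

Peptide-level evidence for alternative splice isoforms.

Transcript annotations describe alternative isoforms for nearly every
multi-exon gene, but how many of those isoforms exist as protein?
`isopept` implements a conservative proteogenomic pipeline for that
question: filter large-scale peptide identifications to a
high-confidence set, map them I/L-insensitively onto an isoform
annotation, extract and classify splice events between each gene's main
and alternative isoforms, keep only events with peptide evidence on
both sides, scan the annotation for mutually exclusive homologous
exons, score the impact of events on functional domains, compare the
observed yield with null abundance models, and date exon origins by
Dollo parsimony.

## The core ideas

**Both-sides evidence.** A splice event between a main isoform *M* and
an alternative *A* is *identified* (an ISE) only when isoform-specific
peptides support both sides: any peptide overlapping an inserted or
substituted segment, but for a deletion a peptide on the shorter
isoform must cross the junction with ≥ 1 residue on each flank.

**Event taxonomy.** Residues of two isoforms are matched iff their
codons occupy the same genomic bases in the same frame; maximal
unmatched runs are events, classified as indel (> 4 residues), NAGNAG
(≤ 4), homologous substitution (segments pass a permutation homology
test: local BLOSUM62 score vs 200 shuffles, p ≤ 0.005), N-/C-terminal
or internal substitution, or two-proteins (no shared in-frame region).

**Null models.** For each gene, draw as many unique tryptic peptides as
were observed, with probability proportional to isoform abundance under
a null: uniform (all isoforms equal) or dominant (main isoform
*r*-fold, default 50:1).  A gene is an expected AS gene when the drawn
peptides satisfy the same both-sides rule.  The observed yield sits far
below both models when most genes express one dominant protein isoform.

**Dollo dating.** A homologous exon present in human and any subset of
distant vertebrates originated at the most recent common ancestor of
the species carrying it (single gain, any number of losses).

## Worked example

The analysis chain regenerates and analyses a fully synthetic
200-gene study with known ground truth:

```bash
python analysis/01_simulate_data.py
python analysis/02_filter_peptides.py
python analysis/03_map_peptides.py
python analysis/04_call_events.py
python analysis/05_scan_homologous_exons.py
python analysis/06_domain_impact.py
python analysis/07_null_models.py
python analysis/08_date_exon_origins.py
python analysis/09_headline_numbers.py
```

Step 01 writes the annotation (203 genes including a UGT1A-style
cluster and decoys), 5,196 peptide observations over eight emulated
experiments, and prints:

```
  genes: 203 (merged: 201), planted events: 170 (5 detectable)
  peptide observations: 5196 over 8 experiments, clean peptides: 1401
```

Step 02 removes every injected artifact and no clean peptide; step 04
recovers exactly the detectable planted events:

```
170 unique annotated events; 5 ISEs with both-sides peptide evidence
  events by kind: {'homologous_substitution': 32, 'indel': 58, 'nagnag': 20,
                   'internal_substitution': 10, 'cterm_substitution': 24,
                   'nterm_substitution': 16, 'two_proteins': 10}
  ISE recovery vs truth: 5/5 (false positives: 0)
```

Step 07 shows the expected-vs-observed gap — the observed AS-gene count
(5) sits far below the equal-expression null (≈ 80) because the
generator expresses alternatives at a small fraction of the main
isoform:

```
uniform (ratio -): mean AS genes 79.9 (+-0.55), three-plus 0.8
dominant (ratio 50.0): mean AS genes 3.9 (+-0.18), three-plus 0.0
observed AS genes: 5
```

Step 08 recovers all 50 planted exon-origin nodes by Dollo parsimony,
and step 09 prints the headline percentages and ratios derived from the
reference category counts (e.g. 21.3% of identified events are
homologous exon substitutions; Fisher enrichment p ≈ 2.4 × 10⁻³¹).

## Layout

```
src/isopept/       the library: annotation, peptides, filtering, mapping,
                   events, hes, domains, nullsim, evostats, report,
                   synthetic_data
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit + property + acceptance)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameters, limitations
```
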