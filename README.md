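# multiguide

A design-and-analysis toolkit for multiplexed CRISPR-Cas9 knockout screens
in zebrafish. It covers the desk side of a founder screen end to end:

1. **Guide selection** — scan exon sequences (both strands) for 23-nt
   protospacer+PAM sites of the form `GG N18 NGG`: the leading `GG` lets T7
   polymerase initiate transcription on the guide's own 5' end, the trailing
   `NGG` is the SpCas9 PAM. Candidates are ranked by proximity to the CDS
   start (where indels most reliably truncate the protein) and can be
   filtered against known SNP positions.
2. **Cloning-free template assembly** — build the ~125-bp in-vitro
   transcription template (T7 promoter + target 23-mer + 81-nt sgRNA
   scaffold) and decompose it into three sticky-ended duplex fragments made
   of six 38–46-nt oligos. The two junction overhangs sit in constant
   sequence and are chosen to be mutually incompatible, so the one-pot
   ligation has a unique outcome and switching genes replaces only the two
   fragment-1 oligos. A ligation simulator verifies both claims
   exhaustively for every design.
3. **Indel calling** — globally align Sanger-resolved mutant alleles to
   wild type (affine gaps: match +1, mismatch −2, open −5, extend −1;
   indels left-aligned), call deletions/insertions, and label each allele
   founder-table style: net change first, component breakdown for complex
   alleles (`-8`, `+1`, `+2 (-5, +7)`), with frameshift = net not divisible
   by 3.
4. **Cohort summaries** — per-gene mutation efficiency (% of fish mutated),
   cohort positive rate, the deletion/insertion/complex split over mutation
   *events*, and the frameshift fraction over distinct mutation *types* —
   both denominators reported explicitly.
5. **Phenotype statistics** — C-start startle scoring with a 25-ms latency
   gate (inclusive), per-fish response rates, Welch/Student/permutation/
   pooled-χ² group comparisons, staining intensity as percent of control,
   and hair-cell count summaries.

A seeded synthetic-data layer (`multiguide.simulate`) generates exons with
planted targets, mutant alleles with known ground-truth events, Bernoulli
C-start trial tables, and Gaussian intensity/count data, so the whole
pipeline is testable without any external data.

## Worked example

```python
from multiguide import (GuideTarget, build_template, split_template,
                        simulate_ligation, call_event)

target = GuideTarget(gene="gabbr1a", seq="GGATGTCCCTTGAGAACGGGAGG",
                     strand="+", start=0, end=23)
template = build_template(target)
print(len(template.seq))          # 125
print(template.seq[:53])          # AATTTAATACGACTCACTATAGGATGTCCCTTGAGAACGGGAGGGTTTTAGAG

oligos, fragments = split_template(template)
for o in oligos:
    print(o.name, len(o.seq), o.variable_per_target)
# F1-top 42 True
# F1-bottom 46 True
# F2-top 40 False
# F2-bottom 40 False
# F3-top 43 False
# F3-bottom 39 False

products = simulate_ligation(fragments)
print(len(products), products[0].circular, len(products[0].top_sequence))
# 1 False 125      <- exactly one product: the full-length linear template

ev = call_event("GGATGTCCCTTGAGAACGGGAGGGTGTCGCTG",
                "GGATGTCCCTTGAGGGTGTCGCTG", gene="gabbr1a")
print(ev.label, ev.mutation_class, ev.frameshift)
# -8 deletion True
```

Only `F1-top`/`F1-bottom` carry target-dependent bases, so a five-gene
screen needs 10 gene-specific oligos plus one shared set of four.

The same workflow is available from the shell:

```bash
multiguide design --fasta exons.fa --cds-start 0 --out targets.tsv
multiguide assemble --targets targets.tsv --out oligos.tsv --report ligation.txt
multiguide call --wt wt.fa --alleles alleles.tsv --out events.tsv
multiguide summarize --events events.tsv --n-fish 6 --out summary.json
multiguide simulate-cstart --n-fish 48 --n-trials 10 --seed 1 --out trials.tsv
multiguide cstart --trials trials.tsv --out cstart.json
```

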