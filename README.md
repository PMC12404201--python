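# circflow

Analysis toolkit for circular RNA (circRNA) biogenesis studies in which an
RNA-binding protein — the motivating case is the pan-neuronal ELAV/Hu family
— promotes back-splicing by binding the introns that flank circRNAs on the
nascent transcript. The package implements the quantitative side of such a
study as a tested, reusable pipeline:

- **Back-splice junction (BSJ) quantification** — calling BSJs from split
  reads with canonical GT/AG splice-signal filtering, forward-splice
  junction (FSJ) counting, the circular-to-linear junction ratio
  `2·bsj / (2·bsj + fsj)`, a ≥5-BSJ-per-population reference filter, and a
  read-subsampling saturation analysis.
- **Intron database** — protein-coding intron extraction with alternative
  TSS/TES exon exclusion, collapse of circRNAs whose ends lie within 10 nt,
  and classification of introns as flanking / nonflanking / other-gene
  relative to circRNA back-splice sites.
- **Differential circRNA expression** — a conditional binomial exact test
  on pooled BSJ counts with the threshold presets used for circRNA classes
  (e.g. neuronal: logCPM > −5, *P* < 0.1, log₂FC > 0).
- **Exon–intron split analysis (EISA)** — exon–exon-junction (EEJ) vs
  exon–intron-boundary (EIB) read classification to separate pre-mRNA from
  mature-transcript binding in IP/input comparisons.
- **Splicing efficiency** — per-intron cotranscriptional efficiency from
  nascent signal, `1 − (intron density / exon density)` over the last 30 %
  of the intron vs the first 30 % of the downstream exon.
- **Reverse complementary matches (RCMs)** — exact (oracle-verified) and
  mismatch-tolerant detection of complementary spans between the two
  flanking introns of each circRNA, with density/GC summaries and a
  length-preserving permutation test of repeat overlap.
- **Cross-link enrichment** — χ² tests of iCLIP-style cross-link counts
  across intron classes against a length-proportional expectation, plus
  metaprofiles over normalized introns and around RCMs.
- **BSJ motif statistics** — PWM scanning of the ±25 nt window reading
  across the back-splice junction, Fisher set enrichment, and a binomial
  test of central positional enrichment.

A first-class synthetic-data module generates genomes, annotations, reads,
cross-link tracks and nascent signal with *planted, recoverable truth*
(circRNA coordinates, RCM pairs, motif sites, enrichments, spliced
fractions), so the whole pipeline is testable end to end without external
data.

Intended users: computational biologists analysing total RNA-seq, iCLIP /
xRIP-seq and nascent RNA-seq data around circRNA biogenesis, and anyone who
needs a transparent, deterministic re-implementation of these statistics.

## Worked example

Simulate a study (20 genes, 10 circRNA hosts, ~50 BSJ reads per circle per
sample), then run the stages over the written files:

```bash
circflow simulate --out sim --seed 3 --samples 1
circflow build-introns --gtf sim/annotation.gtf --circs sim/circs_truth.bed --out sim/introns.tsv
circflow quantify --reads sim/reads_A0.tsv --genome sim/genome.fa --out sim/quant
circflow rcm --genome sim/genome.fa --introns sim/introns.tsv --out sim/rcms.tsv
circflow clip --track sim/crosslinks.bed --introns sim/introns.tsv --out sim/clip
```

which prints:

```
wrote synthetic data for 10 circRNAs to sim
wrote 75 introns (10 circRNA clusters)
10 circRNAs called; 10 at >= 5 BSJ reads
10 RCM pairs across 10 circRNAs
chi2=720.454 p=3.59e-157 (df=2)
```

Reading the output: all 10 planted circRNAs are recovered at exact
coordinates and pass the ≥5-BSJ filter; the RCM detector finds the planted
complementary pair in every circle's flanking introns; and the cross-link
χ² test detects the planted 3× flanking-intron enrichment (the χ² compares
cross-link counts in flanking vs nonflanking vs other-gene introns against
their length shares). The same functionality is available as a library —
see `circflow.quantify`, `circflow.rcm`, `circflow.clip`, etc.

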