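# Methods

This note documents the models, statistics and design choices behind
`circflow`, and what the synthetic-data generator does and does not
emulate.

## Back-splice calling and quantification

A split read is a back-splice candidate when its two segments map to the
same chromosome and strand but out of transcriptional order: on the plus
strand the second segment lies genomically upstream of the first; on the
minus strand the relation mirrors. The candidate junction spans from the
acceptor-side boundary (genomic start) to the donor-side boundary (genomic
end, half-open). Candidates are kept only if the transcribed-strand
intronic dinucleotides are canonical — GT immediately past the donor and AG
immediately before the acceptor; on the minus strand the genomic
complements (AC before the start, CT past the end) are checked. Counting is
at exact coordinates; fuzzy merging is deliberately deferred to the
annotation layer (10-nt collapse), keeping raw counts auditable.

The circular-to-linear **junction ratio** is `2·bsj / (2·bsj + fsj)`: a
back-spliced molecule presents two junction-crossing opportunities per
circle passage while a linear molecule presents one per boundary. FSJ reads
are defined as reads colinearly spanning either circle boundary — a
contiguous alignment crossing the boundary position, or a spliced alignment
whose junction coincides with the boundary's linear junction — deduplicated
per read per circRNA. This is an explicit operational definition; the
upstream tools this replaces do not publish their exact read-admission
rules, so the definition is kept simple and testable.

The reference filter retains a circRNA when its pooled BSJ count reaches 5
in at least one population (pooling replicates within population first);
the qualifying populations are recorded. The saturation analysis subsamples
the accepted back-splice reads without replacement at each requested
fraction (default 3 replicates; 12 in the calibration runs), recomputes
detection at the ≥5-read threshold, and reports recovery against the
full-set detections.

## Intron database and circRNA-relative classes

From protein-coding gene models, each transcript's first/last exon is
dropped when its outer boundary differs from the gene-level outermost
boundary (the minimal operational reading of an "alternative TSS/TES"
exon); optionally, exons absent from a caller-supplied expressed-exon
whitelist are dropped (no expression estimation happens inside the module).
The union of retained exons is subtracted from the gene span; gaps shorter
than 10 nt are discarded. Using the union across transcripts means an
intron must be intronic in every retained isoform.

circRNAs collapse by single linkage when both the 5′ and the 3′ ends lie
within 10 nt (inclusive — "within" is read inclusively) on the same
chromosome and strand. An intron whose 3′ boundary abuts (≤ 10 nt) a
cluster's 5′ back-splice boundary is `flank_up`; the mirror case is
`flank_down`; labels follow transcription direction, so minus-strand genes
swap the genomic relations. Remaining introns of circRNA-hosting genes are
`nonflanking`, all others `other_gene`. The degenerate single-intron-circle
geometry (one intron abutting both boundaries) keeps both links and is
flagged rather than erroring. Host genes are resolved from the circRNAs'
own gene assignment when present, else by containment of the cluster in a
gene's intron hull; disambiguating overlapping multi-gene loci is out of
scope.

## Differential circRNA expression

Replicates are pooled within group and each circRNA tested with a
conditional binomial exact test: given `n = countA + countB`, `countA` is
`Binomial(n, libA/(libA+libB))` under the null of equal rates; the
two-sided p-value sums outcome probabilities no larger than the observed
one. Fold changes use 0.5 prior counts,
`log2FC = log2(((countA+0.5)/libA) / ((countB+0.5)/libB))`, and
`logCPM = log2((count+0.5)/(lib+1)·10⁶)` averaged over the two groups.
This replaces a negative-binomial GLM stack on purpose: at BSJ-scale counts
the exact test is self-contained and oracle-verifiable. The cost is that
between-replicate dispersion is ignored — pooling treats replicates as one
library — so p-values on overdispersed real data will be anticonservative;
this is a documented limitation, not a target of the calibration tests
(which use Poisson counts, where the test is exact).

Classification presets mirror the printed thresholds for circRNA classes:
population contrast — logCPM > −5, *P* < 0.1, log₂FC > 0 (neuronal) or
< 0 (nonneuronal), else "other"; a stricter display preset (*P* < 0.05,
logCPM > −5.4, |log₂FC| ≥ 1) is exposed separately rather than reconciled
with the former, because both threshold sets are in use for different
purposes. Mutant contrasts call a circRNA affected when |log₂FC| ≥ 0.3
(double mutant) or ≥ 0.5 (single mutant) with logCPM > −5.4, signed into
up/down. No multiple-testing correction is applied, matching the raw-P
criteria the classes are defined by.

## Exon–intron split analysis

Reads are classified per gene as EEJ (spliced alignment whose gap equals an
annotated intron; mature + premature evidence) or EIB (contiguous alignment
with an all-M CIGAR overlapping ≥ 1 nt of exon and ≥ 1 nt of intron of one
gene; pre-mRNA evidence). The two classes are mutually exclusive by
construction (gapped vs contiguous). Per gene,
`enrichment = log2(((ip+0.5)/(input+0.5)) · (lib_input/lib_ip))` is
computed separately from EEJ (total transcript) and EIB (pre-mRNA) counts;
genes averaging < 10 EEJ reads across samples are filtered. A gene is
called pre-mRNA-enriched when the boundary enrichment exceeds a log₂
threshold (default 1) with a conditional binomial p < α (default 0.05)
— both config-exposed, since the quasi-likelihood framework this replaces
does not print an equivalent cutoff.

## Splicing efficiency

Per intron, the measurement windows are the transcribed-strand last 30 % of
the intron and first 30 % of the downstream exon (genomically mirrored on
the minus strand); window lengths round half-up with a 1-nt minimum, and a
feature whose window would round to zero raises. Efficiency is
`1 − (intron per-nt density / exon per-nt density)`, clamped to [0, 1]
because sampling noise can push the raw ratio outside the interpretable
range. Library scaling cancels in the ratio; the heavier normalization used
upstream in the original analyses is intentionally replaced by per-window
densities. Group comparisons bin introns by length (log-spaced by default)
and use a one-tailed Welch t-test per bin; empty bins report NA.

## RCMs and repeat overlap

RCM detection works on genomic forward-strand sequence: RNA-level pairing
between two introns of one gene reduces to
`up_forward == revcomp(down_forward)` regardless of gene strand. The
default (exact) mode reports all maximal exact matches ≥ 21 nt ("longer
than 20"), found by 7-mer seeding — the minus-strand BLAST word size — and
bidirectional extension, deduplicated per diagonal; N never matches. An
O(n·m) brute-force enumeration serves as the test oracle, and exact mode is
required to agree with it identically. The optional greedy mode
approximates BLAST behaviour with X-drop extension (+1 match, −2 mismatch,
drop 6) and suppresses hits contained in longer ones. Downstream spans are
reported in forward-strand coordinates for BED compatibility. GC content is
(G+C)/(A+C+G+T) with N excluded from both sides.

RCM density per circRNA class counts circRNAs with ≥ 1 RCM per
pairing-length bin (multiple RCMs of one circle in one bin count once),
normalized per kb of flanking-intron sequence. Repeat overlap uses a
permutation test: the observed statistic is the number of RCM regions
overlapping ≥ 1 repeat; the null re-places each region, length preserved,
uniformly over the placement space (an interval is chosen with probability
proportional to its number of valid start positions; overlaps among placed
regions are allowed, matching the default behaviour of the randomization
tool this emulates); `p = (1 + #{null ≥ obs})/(ntimes + 1)` with a z-score
against the null, default `ntimes = 500`. Conservation scoring of RCMs is
excluded: it requires an external per-base score track; the interface
computes span means if such a track is supplied.

## Cross-link enrichment and profiles

Cross-link tracks are strand-aware position-count tables (1-nt BED with
count in score, as produced by standard iCLIP peak callers; cross-link
calling itself is out of scope). Enrichment across intron classes is a χ²
goodness-of-fit of raw per-group counts against a length-proportional
expectation with k−1 degrees of freedom. This keeps counts integral — a χ²
on rescaled non-integer "length-normalized counts" would be ill-defined —
while expressing the same comparison of per-kb densities. Metaprofiles map
positions to length-normalized bins in transcription orientation (integer
arithmetic, `bin = pos_offset·n_bins // length`, so introns shorter than
the bin count share bins deterministically); RCM-centered profiles keep
±1 kb nucleotide-resolution flanks around a length-normalized interior,
accumulated separately for upstream- and downstream-intron RCMs.

## BSJ motif statistics

The BSJ window is the 2·25 nt sequence reading across the junction, built
on the spliced (exonic) circle sequence in transcript orientation — the RNA
that actually spans a multi-exon circle's junction is exonic — with modular
wrap-around for circles shorter than the window and a genomic fallback for
single-exon circles. Motifs are PWMs (MEME-format reader/writer included)
scored as log-odds against a background; the default hit threshold is 0
log-odds and is config-exposed, since the scanning tools this replaces keep
their thresholds internal. Set enrichment is a Fisher exact test on
windows-with-hit counts (odds ratio reported with Haldane 0.5 correction);
positional enrichment is an upper-tail binomial test of hit centers (motif
midpoint, rounded down) falling in a 20-nt central region, with null
probability `central_width / (window_len − motif_len + 1)`.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of the study designs the analyses
serve: multi-exon protein-coding genes on both strands with canonical GT/AG
intron boundaries; a subset of genes hosting one circRNA over internal
exons; one exact RCM pair per circle planted in the flanking introns, with
a U-rich consensus (default `TTTTTTT`, the ELAV-class binding preference)
embedded on the transcribed strand; junction reads at configurable
circular:linear ratios and group fold changes; cross-link tracks with a
configurable flanking-intron density multiplier; and nascent position
counts with per-intron spliced fractions.

Default study conditions (chosen once as realistic desk-scale conditions):
20 genes, 4–6 exons of 80–200 nt, introns 150–600 nt, 10 circRNA hosts,
mean 50 BSJ reads per circle per sample, circular fraction 0.5, group fold
change 4, RCMs 25–40 nt, cross-link base density 0.05 sites/nt with 3×
flanking enrichment, spliced fraction 0.5, nascent depth 5000 reads per
intron, read segments 30 nt. Read-depth model: BSJ counts are Poisson with
mean `bsj_depth` (times the fold change in group B) and FSJ counts Poisson
with mean scaled so the back-spliced fraction of junction reads equals the
configured circular fraction; the degenerate fractions 0 and 1 produce
all-linear and all-circular samples. One top-level seed drives everything;
each generator derives an independent child stream by a fixed offset, so
outputs are byte-identical at fixed config.

The read model is idealized: no mismatches or indels, fixed 30-nt segments,
all-M CIGARs, no fragment-length or paired-end structure, no sequencing
error, single transcript per gene (an option adds alternative terminal
exons to exercise the TSS/TES exclusion). Nascent counts are uniform over
features rather than 3′-biased. Passing tests therefore demonstrate the
correctness and calibration of the *statistics* on clean evidence — they do
not validate aligner behaviour, chimeric-read heuristics, or robustness to
real-data artefacts such as overdispersion between replicates, mapping
bias, or repeat-driven multi-mapping.

## Numerical choices and degenerate inputs

- Window rounding: half-up everywhere a fraction of a length is taken.
- Efficiency and junction ratios return NaN (not errors) when their
  denominators are empty; zero-depth simulation warns and returns an empty
  sample; an empty cross-link track warns and returns an NA χ² result.
- Ties in the exact tests follow `scipy.stats.binomtest` (outcomes with
  probability ≤ observed, to float tolerance).
- The empirical permutation p uses add-one smoothing and is therefore
  never 0; with a discrete overlap statistic it is slightly conservative,
  which the calibration check accounts for by using query sets large and
  varied enough to spread the null support.
- Chromosome-bound violations in read segments raise; BSJ windows and RCM
  flank profiles truncate at chromosome ends when sizes are known.

## Verification problem sizes

The acceptance script and test suite run each check at fixed sizes chosen
to make the statistical assertions sharp on a single CPU: 200 random intron
pairs (≤ 400 nt) for the RCM oracle audit; 500 circRNAs for null
calibration and power of the exact test; 1000 null simulations and 100
power runs for the χ² enrichment (50 introns of 1 kb per group, density
0.05 sites/nt); 40 genes (15 boundary-enriched at 8×, 5 low-count) for
EISA; 200 seeded runs at ntimes = 100 for permutation-p uniformity; and 50
planted circles for the motif positional test.
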