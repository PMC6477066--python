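# Methods

This note documents the models behind `causalmap`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions that matter when interpreting results.

## The screen being modelled

The package re-creates, on synthetic data, the identification of a
monogenic recessive lesion in a crop forward-genetics screen: a mutant
line isolated after mutagenesis is crossed to wild type; F2 progeny
segregate 3:1; mutant-phenotype F2 plants are genotyped on a SNP array to
find the chromosomal region that cosegregates with the phenotype; a bulk
of mutant-phenotype plants is pooled and sequenced, and variants with a
high mutant-allele read fraction inside the region are candidate lesions;
predicted protein effects prioritise the candidates; an independent
population confirms perfect cosegregation; and ovary RNA-seq characterises
the downstream transcriptome. Each stage is a library module; the
`pipeline` module chains them and reports whether the planted causal gene
was ranked first.

## Simulator

### Genome and gene models

The default genome is two 12 Mbp chromosomes — a deliberately scaled-down
stand-in chosen so that a full simulated screen completes in about a
second while the candidate interval (typically 1–3 Mbp, see below) remains
much smaller than a chromosome. Gene density defaults to 102.7 genes/Mbp,
the euchromatic density implied by 267 protein-coding genes in a 2.6 Mbp
mapped region of tomato chromosome 4. Genes are non-overlapping and
UTR-less (CDS intervals equal exon intervals), with 1–3 exons, log-normal
CDS lengths (median 400 codons, σ = 0.5, clipped to 60–1500), an ATG
start, no in-frame internal stop, and the genomic stop triplet written
immediately downstream of the CDS. The CDS convention **excludes the stop
codon**, so a 2871 bp CDS encodes exactly 957 residues; GFF3 files in the
wild vary on this point, so imported annotations should be checked.

### Meiosis and phenotype

Gametes recombine under the Haldane model: crossover count is Poisson with
mean equal to the chromosome's map length in Morgans, positions uniform,
no interference. The genetic map is uniform at 1 cM per 750 kb
(tomato-like); `map_kb_per_cm = inf` disables recombination. An F2
individual is two independent F1 gametes; its phenotype is mutant iff both
haplotypes carry mutant-parent origin at the causal position (fully
penetrant recessive model — no phenocopies or misclassification).

### Variants

Exactly one causal variant is planted: by default a 2 bp deletion in the
transcription-order first exon of a gene near the middle of the last
chromosome, VCF-anchored (3 bp REF, 1 bp ALT). Mutagen-induced background
variants (default 2×10⁻⁵/bp ≈ 480 genome-wide, 90% SNPs / 10% 1–2 bp
indels) are homozygous in the mutant parent and therefore segregate with
the cross; intra-cultivar polymorphisms (default 3×10⁻⁵/bp, SNPs) carry a
population allele frequency drawn uniform on (0.1, 0.9) and segregate
independently of the cross, emulating a not-fully-inbred parental
cultivar. The mutagen density is not reported for the original screen; the
default reproduces its observed scale of a few dozen bulk-homozygous
variants within a ~2 Mbp candidate region.

### Marker array

The array holds 7600 markers (uniform positions), of which exactly 1956
are informative — distinct homozygous calls in the two parents — matching
the informative fraction of the SolCAP array between the two cultivars of
the original cross. Non-informative markers are monomorphic, heterozygous
in one parent, or missing. Note the markers are therefore ~25× denser per
bp than on the real 760 Mbp genome; interval lengths in Mbp are
nevertheless comparable because marker *count* per interval, not spacing,
drives the mapping resolution at these population sizes.

### Pooled sequencing

Every bulk plant contributes equally (equal DNA amounts). Per variant:
depth ~ Poisson(30); mutant-allele reads ~ Binomial(depth, p′) where p is
the bulk mutant-allele frequency and p′ = p(1−e) + (1−p)e applies a
symmetric per-read allele flip at e = 0.5% — the simplest error model
under which the depth filter matters. Zero-depth records are emitted and
flagged rather than dropped. Read-level simulation (FASTQ, alignment,
base quality) is out of scope.

### RNA-seq counts

Counts are negative binomial (no distribution is stated for the original
experiment; NB is the field standard). Baseline means are log-normal
(log-mean 4.5, σ = 1.6 → median ≈ 90 reads, library ≈ 0.8 M reads over the
~2400-gene panel). Dispersion defaults to 0.002: each replicate pools
15–17 ovaries, which averages away most plant-to-plant biological
variance, leaving near-technical replicate noise. Thirteen planted genes
are up-regulated in the mutant group (one at 12-fold — the >10-fold
GA-biosynthesis analogue — twelve at 4-fold) and twelve down at 4-fold.
Planted genes are drawn among genes with baseline mean in [300, 3000]:
the lower bound makes them well-expressed (the real marker gene is a
highly expressed developmental enzyme), and the upper bound prevents a
single extreme gene from dominating the small panel's library size, which
would otherwise depress every other gene's RPKM in one group — a
composition artifact that a genome-sized panel would not show.

### What passing tests do and do not show

The simulator reproduces the *logical structure* of the screen —
recessive inheritance, linkage, pooled allele frequencies, background
subtraction, coding-effect prioritisation — under idealised conditions:
fully penetrant phenotype, clean genotype calls (error/missing rates
default to 0 and are configurable), equal pool contributions, symmetric
sequencing error, and a uniform genetic map. Passing the recovery tests
shows the pipeline's inference is correct under its stated model; it does
not certify performance against alignment artifacts, segregation
distortion, phenotyping error, structural variants, or the mutation
spectrum of any particular mutagen, none of which are modelled.

## Analysis stages: conventions and tunables

**Segregation** (`segregation`): plain Pearson χ², df = 1, α = 0.05. No
Yates correction — the uncorrected statistic is the one conventionally
printed for segregation tables (and reproduces 1.62 / 0.35 for the 109-
and 186-plant reference counts; the corrected values would differ).
Statistics are rounded to two decimals only for display.

**Interval mapping** (`intervals`): flanks are the first
*non*-cosegregating markers (outer bound) because published flanking
positions delimit the region guaranteed to contain the gene; users wanting
the inner bound can read it off `run_markers`. Missing calls are
uninformative, never imputed. A heterozygous call in a mutant-phenotype
plant breaks cosegregation at that marker and is surfaced in the
`noncoseg` diagnostics (possible phenotyping error) rather than dropped.
Runs separated by a gap whose every broken marker is attributable to one
single individual are merged: a lone recombinant consistent with a double
crossover (or one bad call) must not exclude a region — without this rule
roughly 2% of error-free default simulations map the wrong fragment.
Ties between runs: most cosegregating markers, then longest physical
span, then lowest chromosome/position. Gene–interval overlap is
closed-interval and any-overlap (conservative; never drops the causal
gene). Narrowing with an extra internal marker decides which flank to
replace by majority vote of the recombinant plants' calls at the current
flanks; conflicting votes raise an error rather than guessing.

**SNP/Indel index** (`snpindex`): defaults min_depth = 10 (the reported
reliable-read cutoff) and min_index = 0.9. The index cutoff is not stated
numerically in the original analysis ("high index", mutant homozygous);
0.9 tolerates 0.5% sequencing error at depth ≥ 10 while excluding
heterozygous-frequency variants, and is exposed as a flag. Subtraction
matches background variants on exact (chrom, pos, ref, alt) after
left-normalisation; same-position different-allele records are kept with a
warning so distinct overlapping indels are never silently discarded.
Alignment and variant calling are out of scope — the module consumes VCFs
with AD-style allele depths.

**Variant effects** (`effects`): stop positions are 1-based codon indices
in the mutated reading frame (stop at 494 ⇒ 493 aa truncated protein).
Frameshift re-translation scans past the annotated CDS end into downstream
sequence (default 30 kb cap) so that stop-lost extensions are called
faithfully. Indels spanning an exon–intron junction are lifted
coordinate-wise without splice re-modelling; splice-site effect prediction
is a non-goal. Protein domains are user-supplied intervals (the module
reports which are lost or truncated, it does not predict them). The
`codon_index` reported for indels is the first codon whose content
changes in transcription order — on minus-strand genes this differs from
the codon of the genomic anchor base.

**Differential expression** (`rnaseq`): RPKM with library size = column
totals; expressed = mean RPKM ≥ 1 in *at least one* group (the source
protocol does not specify the group rule; the either-group rule keeps
genes switched on in only one genotype, which is the interesting class);
filter-first, then test. Tests are Student's pooled t on log2(RPKM + 1)
(pseudocount 1; the transformation is unstated in the source and exposed
as a parameter). Welch's test is available via `equal_var=False` but is
not the default: with three replicates per group the Welch–Satterthwaite
degrees of freedom collapse toward 2 whenever one group's variance
estimate is small, so even very large t statistics cannot reach q < 0.05
and true ≥4-fold changes go uncalled. Multiple testing uses
Benjamini–Hochberg q values across expressed genes ("Bonferroni ... with
false discovery rate analysis" in the source protocol is contradictory;
q values indicate FDR adjustment, and Bonferroni is offered as an
option). Calls: up if log2FC ≥ 1 and q < 0.05; down if ≤ −1; genes where
both groups have zero variance are flagged `degenerate` and left
unchanged. Count-model DE methods (NB GLMs) are deliberately out of
scope — the stage mirrors an RPKM/t-test protocol.

**Pipeline** (`pipeline`): candidate genes are ranked by perfect
cosegregation in an independent simulated population (83 mutant + 80 WT
plants; a candidate passes iff all mutants are homozygous and no WT plant
is), then effect severity (frameshift/nonsense > stop-lost > missense >
in-frame > other), then highest index, then position. Severity-first
ranking mirrors prioritising the truncating mutation; expression-weighted
ranking would be an alternative mode. The bulk cross (109 plants) is
extended in batches when it yields fewer than 20 mutant-phenotype plants
(probability ≈ 5% at 3:1). All stages consume one seeded
`numpy.random.Generator`, so a run is byte-reproducible from its seed.

## Problem sizes used by the test suite

Unit tests run on a miniature design (2 × 1.5 Mbp, 40 genes, 160
informative markers). The behavioural guarantees use the default
configuration: 50 seeded end-to-end runs (causal gene top-ranked in
≥ 90%), 100 interval-mapping replicates (planted locus always contained,
error-free), 1000 pooled-bulk replicates (causal index exactly 1.0 at
zero error; unlinked mean within 3 standard errors of 0.5), 1000 random
variant×gene classifications against a brute-force re-translation oracle,
and 100 RNA-seq seeds (sensitivity ≥ 0.9 for planted ≥4-fold genes,
empirical false-discovery proportion ≤ 0.05). The whole suite runs in
about a minute on one CPU.

## Known limitations

- One causal locus; no epistasis, no segregation distortion, no
  incomplete penetrance.
- The uniform genetic map ignores centromeric crossover suppression, which
  in real chromosomes widens pericentromeric intervals considerably.
- Intra-cultivar variants are modelled as independent per-site
  frequencies, not haplotypes, so linkage disequilibrium among background
  polymorphisms is absent.
- The RPKM/t-test DE stage inherits the limitations of that protocol
  (library-composition sensitivity, no count-model shrinkage); it is
  faithful to the workflow it reproduces, not a recommendation.
- Marker density per bp is much higher than on the real genome (see
  above); physical interval lengths are comparable, recombination counts
  per interval are not.
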