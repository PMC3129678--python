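# Methods

This note records the models, conventions, parameter choices and known
limitations behind `snpsieve`, in the order the pipeline runs.

## Coordinate and format conventions

SNP positions are 1-based (VCF convention); every interval — exons, CDS
segments, repeat masks, coverage runs, cluster spans — is 0-based
half-open (BED/BedGraph convention). Conversions are centralised in
`snpsieve.models`. Call tables are tab-separated with a `#`-prefixed
header (`schema_id, genome_id, chrom, pos, ref, alt, coverage, score,
zygosity`); heterozygous calls carry the IUPAC two-base code in `alt`.
Partition results export as plain VCF 4.2 with `CLASS`, `CONSENSUS_COV`
and `CONSENSUS_SCORE` INFO fields.

## Synthetic genome and mutant line

The generator's defaults define the study conditions; they are not tuning
knobs.

* **Genome**: 5 chromosomes × 200 kb. Genes are two-exon models (5′UTR 30
  bp | CDS part | intron 80–220 bp | CDS part | 3′UTR 30 bp) with
  ATG…stop CDS of 62–242 codons, split off-frame so CDS phase is
  exercised; density 0.05 genes/kb; 10% of genes overlap a neighbour's
  UTR tail so that apparent > actual counting is exercised; ~10% of each
  chromosome is low-complexity repeat, confined to intergenic gaps.
* **Accession divergence**: 1.2 SNP/kb (the genome-scale value), uniform
  over the 12 substitution types — natural variation is not EMS-shaped.
* **EMS load**: 0.1 mutations/kb. The genome-scale rate is ~1/100 kb; at
  a 1 Mb desk genome that would leave ~10 mutations and no statistics, so
  the rate is scaled 10× (a config default, documented here). Each
  chromosome draws a strand of origin uniformly; mutations occur only at
  C sites of that strand, so they appear on the reference plus strand as
  all-C→T or all-G→A per chromosome — the pure single-alkylated-strand
  limit.
* **Backcrossing**: 4 generations, recombination 4 cM/Mb with the Haldane
  map r = (1 − e^(−2d))/2. Each generation the causal-carrying gamete is
  selected (the experimenter re-selects the phenotype); a mutation at
  recombination fraction r from the causal locus survives each generation
  with probability 1 − r (1/2 if unlinked). The final selfing fixes a
  surviving mutation homozygous with probability 1 − r: 1/2 for unlinked
  loci — one more halving — and certainty in the fully linked limit,
  where the mutation cannot separate from the homozygosed causal allele.
  This interpolation is deliberately simple; a full Mendelian treatment
  conditioning on a causal-homozygous selfed offspring would give
  (1 − r)² and slightly lower unlinked retention (1/4 at the selfing
  step). The chosen model keeps the two anchor behaviours — unlinked
  retention (1/2)^(n+1) and certain retention at d = 0 — and reproduces
  the ~10× reduction of the mutation load and the hitchhiking cluster.
  The causal mutation is implanted as a strand-consistent non-synonymous
  CDS transition on chr5 and is always retained homozygous.
* **Call noise**: coverage is a windowed (200 bp) Poisson track per
  (genome, schema); mean depths 16/18/20/22/24 for schemas
  25_2/25_3/35_2/35_3/35_4 (strictest first — stricter matching maps
  fewer reads). True variants are homozygous calls with Beta-distributed
  scores whose mean falls from 0.95 to 0.88 with schema permissiveness
  (concentration 60). False positives are drawn per schema independently
  at 0.3/kb inside the repeat mask, heterozygous with probability 0.7,
  scores Beta(mean 0.45, concentration 10). Because FP loci are
  independent across schemas, cross-schema intersection removes
  essentially all of them — which is exactly why the real strategy used
  it. `coverage_noise=False, score_noise=False, fp_rate=0` give the
  noiseless limit in which pipeline output equals ground truth exactly.
* **Expression**: three datasets (two constant-light, one constant-dark),
  12 timepoints at 4-h spacing over 48 h (a common diurnal design),
  baseline 5, amplitude 2, Gaussian noise σ = 0.25. Gene classes:
  rhythmic-in-all (30%), rhythmic-in-dark-only (6%), arrhythmic. The
  pipeline forces the causal gene to rhythmic-in-dark-only and one decoy
  to rhythmic-in-all, reproducing the tier-1-decoy/tier-2-causal
  situation the screen cannot resolve alone.

What the generator does **not** emulate: read-level/color-space error,
indels and structural variation, hyper-variable regions, transcript
isoform diversity, UTR annotation (intragenic non-CDS positions all count
as "intronic"), and correlated coverage between schemas. Passing tests
therefore show the pipeline's logic is correct under the stated
statistical structure, not that it is robust to every artifact of real
sequencing data.

## Filtering semantics

Keep a call iff: homozygous (when `require_homozygous`), score ≥ 0.7, and
depth ≥ 6 in **both** genomes ("exceeded 5×" and "5 or less" agree on
keep-iff-depth ≥ 6). The score applies only to the calling genome — a
score is a property of a call, not of a locus. The score filter is
applied per schema *before* intersection. A chromosome absent from a
coverage track is depth 0 (logged, not an error). Cross-schema consensus
keeps a (chrom, pos, alt) present in every configured schema and carries
the minimum coverage/score across schemas. Schema ids are opaque strings;
the default set is `25_2, 25_3, 35_2, 35_3, 35_4`.

Uniqueness partition: same key in both genomes → shared; in one genome
only → unique to it **iff** the other genome has depth ≥ 6 under every
schema at that locus, else excluded-low-coverage (a shared SNP would
masquerade as unique when the other genome is under-covered).
Same-locus, different-alt conflicts make both calls unique to their
genome (each differs from the reference independently) and are logged.

Callable fractions classify every base: *no reads* = depth 0 in **any**
(genome, schema) pairing (configurable to "all pairings"; the default
reflects that calling needed both genomes), *interrogated* = depth ≥ 6
everywhere, remainder = had reads but failed the criteria. Implemented as
a breakpoint sweep; a per-base brute force reproduces it exactly in
tests.

## Effect classification

Standard nuclear genetic code throughout (organellar chromosomes would
use the same table unless overridden). Precedence per gene model:
pseudogene → `pseudogene`; CDS position → codon comparison
(`stop_created` if the new amino acid is a stop and the old is not,
`stop_deleted` for the reverse, `synonymous`/`non_synonymous` otherwise,
judged per codon including the annotated terminal stop); any other
position inside the model span → `intronic`; degenerate model (CDS length
not ÷ 3, bad phase) or ambiguity base → `unclassifiable`. A SNP
overlapping several genes produces one record per gene (multiple
transcripts of one gene collapse to the most severe consequence), giving
the *apparent* count; *actual* counts distinct loci, so apparent ≥ actual
with equality iff no locus overlaps two genes.

The neutral expectation enumerates every possible substitution at every
CDS position of every non-degenerate model, weights by a substitution
spectrum given on the reference plus strand, classifies with the same
codon logic, and normalises over the four coding categories. A
Monte-Carlo sampler over the same weighted site space serves as its
cross-check; a whole-protein translation of mutated vs reference CDS
serves as the independent oracle for the codon-local classifier.

## Spectrum statistics

Strand bias: among EMS-consistent SNPs in a region, the C→T fraction is
tested against a 50/50 null with an exact two-sided binomial
(`scipy.stats.binomtest`); non-EMS substitutions are reported as a
contamination fraction (expected 0 for a true EMS set). Mutation rate is
reported both per kb and as "1 per N kb" with N = round(interval_kb /
count). Clusters: max-gap single linkage (desk-scale default gap 50 kb,
i.e. the 500 kb genome-scale choice ÷ 10), minimum size 2; genome-wide
homogeneity is a chi-square dispersion test of per-window counts (50
windows allocated by chromosome length) against a uniform Poisson rate.
The clustering algorithm and both parameters are exposed because nothing
in the underlying method fixes them.

## Rhythmicity screen

Waveforms: sine/cosine are unit waves at period 24 h with phase scanned
over integer hours; a *spike* is a unit pulse at the gridpoint(s) nearest
the phase within each cycle (ties mark all tied points; note that on a
shared grid sine at phase φ equals cosine at phase φ+6, so best-model
identity is defined up to that equivalence). Scoring is plain Pearson
correlation on raw values — no detrending by default (a linear-detrend
flag exists); a zero-variance series scores 0 by convention. Rhythmic in
a dataset iff best r > 0.85, strictly; the boundary value 0.85 is not
rhythmic. Candidates are genes with a mutant-only protein-altering SNP,
tier 1 = rhythmic in all datasets, tier 2 = in at least one, tier 3 =
rest, sorted within tier by best r. With 12 points and a 72-waveform
bank the null false-positive rate at 0.85 is below 5% (checked on 1,000
arrhythmic simulated genes).

## Numerical and degenerate-input choices

Fixed seed ⇒ byte-identical outputs (NumPy `default_rng`; derived stage
seeds are fixed offsets of the run seed). Empty chromosome, negative
rates/generations, empty schema list, unknown schema, score outside
[0, 1], ref-mismatching SNP, concordance of an empty set, strand-bias
region with no EMS-consistent SNPs, and neutral expectation without CDS
all raise explicit errors. Chromosomes with no C/G sites yield zero EMS
mutations with a warning. Problem sizes in the test suite (1 Mb default
genome, 10⁴ backcross replicates, 10⁵ neutral-expectation draws, 10³
null-calibration genes) were chosen so every statistical check has
adequate power while the whole suite runs in well under a minute.

## Known limitations

The backcross model treats mutations independently given the causal locus
(no interference, no mutation–mutation linkage in the selfing step); the
false-positive model is deliberately minimal (repeat-confined, no
systematic cross-schema artifacts, so cross-schema intersection is more
effective here than on real data); strand-bias "purity" is exact by
construction rather than the ~96% a real line shows once late-arising
mutations accumulate; and the rhythmicity screen shares the limits of
correlation screening — it cannot distinguish a causal gene from a
rhythmic bystander, which is why candidate tiers carry provenance rather
than a verdict.
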