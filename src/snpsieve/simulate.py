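"""Synthetic-data generator for the re-sequencing pipeline.

Emulates, at desk scale, the genetic structure of a mutagenesis/backcross
experiment in a selfing plant:

* a Col-0-like reference genome with protein-coding gene models and a
  repeat mask;
* a divergent wild-type accession (~1.2 SNP/kb of natural variation,
  uniform substitution spectrum);
* an EMS-mutagenised line on that accession background: G/C→A/T
  transitions only, with a per-chromosome single-strand bias (every
  mutation on a chromosome is C→T or every one is G→A on the reference
  plus strand, depending on which alkylated strand the founder cell
  inherited);
* four backcrosses to the parent with selection at a causal locus,
  producing a hitchhiking cluster of retained mutations around it;
* per-schema SNP-call tables with schema-dependent coverage/score
  trade-offs and repeat-confined false positives;
* rhythmic / arrhythmic expression time courses over three datasets
  (two constant-light, one constant-dark).

Default scale is 5 chromosomes x 200 kb with the EMS rate scaled up 10x
(1/10 kb) so that per-run counts are statistically testable; the accession
rate keeps its genome-scale value.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    AccessionSnp,
    EmsMutation,
    GeneModel,
    GenomeBundle,
    IUPAC_HET,
    MutantGroundTruth,
    SnpCall,
    revcomp,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

MUTANT_GENOME = "mutant"
WILDTYPE_GENOME = "wildtype"


class PackingError(ValueError):
    """Raised when the requested gene density cannot be placed."""


@dataclass(frozen=True)
class SchemaParams:
    """Coverage/score behaviour of one matching schema.

    Strict schemas (fewer mismatches allowed) map fewer reads, hence lower
    mean coverage; permissive schemas admit error-prone distal bases, hence
    lower mean scores for the calls they add.
    """

    mean_coverage: float
    score_mean: float
    score_concentration: float = 60.0


@dataclass(frozen=True)
class ExpressionParams:
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 48, 4))
    rhythmic_fraction: float = 0.30
    dd_only_fraction: float = 0.06
    noise_sd: float = 0.25
    amplitude: float = 2.0
    baseline: float = 5.0
    period: float = 24.0
    datasets: tuple[str, ...] = ("LL1", "LL2", "DD")

    def __post_init__(self):
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


#: Default schema set, listed strictest-matching first.
DEFAULT_SCHEMAS: dict[str, SchemaParams] = {
    "25_2": SchemaParams(mean_coverage=16.0, score_mean=0.95),
    "25_3": SchemaParams(mean_coverage=18.0, score_mean=0.93),
    "35_2": SchemaParams(mean_coverage=20.0, score_mean=0.92),
    "35_3": SchemaParams(mean_coverage=22.0, score_mean=0.90),
    "35_4": SchemaParams(mean_coverage=24.0, score_mean=0.88),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: tuple[int, ...] = (200_000,) * 5
    gene_density: float = 0.05  # genes per kb
    overlap_fraction: float = 0.10
    repeat_fraction: float = 0.10
    accession_rate: float = 1.2  # SNPs per kb (natural variation)
    ems_rate: float = 0.1  # mutations per kb (10x genome-scale 1/100 kb)
    n_backcrosses: int = 4
    recomb_rate: float = 4.0  # cM per Mb
    causal_chrom_index: int = 4  # emulate a causal locus on the last chromosome
    schema_params: dict[str, SchemaParams] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMAS)
    )
    fp_rate: float = 0.3  # false calls per kb inside the repeat mask
    het_artifact_prob: float = 0.7
    fp_score_mean: float = 0.45
    fp_score_concentration: float = 10.0
    coverage_window: int = 200  # bp per coverage run
    coverage_noise: bool = True
    score_noise: bool = True
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self):
        for name in ("gene_density", "overlap_fraction", "repeat_fraction",
                     "accession_rate", "ems_rate", "recomb_rate", "fp_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_backcrosses < 0:
            raise ValueError("n_backcrosses must be >= 0")
        if not self.schema_params:
            raise ValueError("schema_params must be non-empty")
        covs = [p.mean_coverage for p in self.schema_params.values()]
        if any(b <= a for a, b in zip(covs, covs[1:])) and len(covs) > 1:
            raise ValueError(
                "schema_params must be listed strictest first with strictly "
                "increasing mean coverage"
            )

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _build_gene(rng: np.random.Generator, gid: str, chrom: str, start: int,
                strand: str) -> tuple[GeneModel, str]:
    """Construct a two-exon gene model plus its plus-strand sequence block.

    Transcript layout: 5'UTR(30) | CDS part 1 | intron | CDS part 2 | 3'UTR(30).
    The CDS is ATG + sense codons + stop; the split point is not a codon
    boundary, so downstream consumers must honour CDS phase.
    """
    n_codons = int(rng.integers(60, 240))
    cds_len = 3 * (n_codons + 2)  # + start and stop codons
    cds = "ATG" + _random_codons(rng, n_codons) + str(rng.choice(sorted(STOP_CODONS)))
    split = int(rng.integers(30, cds_len - 30))
    if split % 3 == 0:
        split += 1  # force a phase-carrying second segment
    intron_len = int(rng.integers(80, 220))
    intron = "GT" + "".join(rng.choice(list(BASES), size=intron_len - 4)) + "AG"
    utr5 = "".join(rng.choice(list(BASES), size=30))
    utr3 = "".join(rng.choice(list(BASES), size=30))
    tx_premrna = utr5 + cds[:split] + intron + cds[split:] + utr3
    c1, c2 = split, cds_len - split

    if strand == "+":
        block = tx_premrna
        exon1 = (start, start + 30 + c1)
        intron_iv = (exon1[1], exon1[1] + intron_len)
        exon2 = (intron_iv[1], intron_iv[1] + c2 + 30)
        cds_ivs = ((start + 30, start + 30 + c1), (intron_iv[1], intron_iv[1] + c2))
    else:
        block = revcomp(tx_premrna)
        # genomic left-to-right mirrors the transcript: 3'UTR first
        exon1 = (start, start + 30 + c2)
        intron_iv = (exon1[1], exon1[1] + intron_len)
        exon2 = (intron_iv[1], intron_iv[1] + c1 + 30)
        cds_ivs = ((start + 30, start + 30 + c2), (intron_iv[1], intron_iv[1] + c1))

    model = GeneModel(
        id=f"{gid}.1", gene_id=gid, chrom=chrom, strand=strand,
        feature_type="protein_coding", exons=(exon1, exon2), cds=cds_ivs,
    )
    return model, block


def generate_reference(config: SimulationConfig) -> GenomeBundle:
    """Generate the reference genome bundle. Deterministic for a fixed seed."""
    if not config.chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    if any(length <= 0 for length in config.chrom_lengths):
        raise ValueError("empty chromosome rejected: lengths must be positive")
    rng = np.random.default_rng(config.seed)
    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    repeats: list[tuple[str, int, int]] = []
    gene_counter = 0

    for name, length in zip(config.chrom_names, config.chrom_lengths):
        seq = rng.choice(list(BASES), size=length)
        seq = "".join(seq)
        n_genes = int(rng.poisson(config.gene_density * length / 1000.0))
        # spread genes over the whole chromosome: mean intergenic gap from
        # the expected footprint (~2.5 kb per gene)
        mean_gap = max(300.0, (length - 2500.0 * n_genes) / (n_genes + 1))
        placed: list[tuple[GeneModel, str, int]] = []
        cursor = int(rng.integers(100, 400))
        prev: GeneModel | None = None
        for _ in range(n_genes):
            gene_counter += 1
            gid = f"G{gene_counter:04d}"
            strand = str(rng.choice(["+", "-"]))
            if prev is not None and rng.random() < config.overlap_fraction:
                # overlap the previous gene's 3' UTR tail (never its CDS)
                start = prev.span[1] - int(rng.integers(10, 28))
            else:
                start = cursor + int(rng.integers(int(0.4 * mean_gap),
                                                  int(1.6 * mean_gap)))
            model, block = _build_gene(rng, gid, name, start, strand)
            if model.span[1] > length - 100:
                if 2500.0 * n_genes > 0.7 * length:
                    raise PackingError(
                        f"gene density {config.gene_density}/kb cannot be packed "
                        f"into {name} ({length} bp)"
                    )
                gene_counter -= 1
                break  # stochastic overflow at a feasible density: stop placing
            placed.append((model, block, start))
            prev = model
            cursor = model.span[1]
        for model, block, start in placed:
            seq = seq[:start] + block + seq[start + len(block):]
            models.append(model)

        # repeat mask: low-complexity runs in intergenic gaps
        target = config.repeat_fraction * length
        covered = 0
        gaps = _intergenic_gaps(length, [m.span for m in (p[0] for p in placed)])
        for gs, ge in gaps:
            rs = gs + 100
            while covered < target and ge - rs >= 700:
                rep_len = min(int(rng.integers(400, 1200)), ge - rs - 100,
                              int(target - covered))
                if rep_len < 200:
                    break
                unit = "".join(rng.choice(list(BASES), size=int(rng.integers(2, 5))))
                rep_seq = (unit * (rep_len // len(unit) + 1))[:rep_len]
                seq = seq[:rs] + rep_seq + seq[rs + rep_len:]
                repeats.append((name, rs, rs + rep_len))
                covered += rep_len
                rs += rep_len + int(rng.integers(200, 600))
            if covered >= target:
                break
        chromosomes[name] = seq

    return GenomeBundle(chromosomes=chromosomes, gene_models=models, repeat_mask=repeats)


def _intergenic_gaps(length: int, spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    gaps, cursor = [], 0
    for s, e in sorted(spans):
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    return gaps


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_accession_snps(genome: GenomeBundle, rate: float, seed: int
                            ) -> set[AccessionSnp]:
    """Natural-variation SNPs at ``rate`` per kb, uniform over the 12
    substitution types (the ref base at a uniform position is ~uniform)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    snps: set[AccessionSnp] = set()
    for chrom, seq in genome.chromosomes.items():
        n = int(rng.poisson(rate * len(seq) / 1000.0))
        n = min(n, len(seq))
        positions = rng.choice(len(seq), size=n, replace=False)
        for p0 in sorted(int(p) for p in positions):
            ref = seq[p0]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snps.add((chrom, p0 + 1, ref, alt))
    return snps


def simulate_ems_mutations(genome: GenomeBundle, rate: float, seed: int,
                           exclude_positions: set[tuple[str, int]] | None = None
                           ) -> tuple[set[EmsMutation], dict[str, str]]:
    """EMS G/C→A/T transitions with a per-chromosome strand of origin.

    A chromosome whose alkylated strand is '+' mutates only C sites of the
    plus strand (seen as C→T); '-' mutates C sites of the minus strand
    (seen as G→A on the reference plus strand).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    exclude = exclude_positions or set()
    rng = np.random.default_rng(seed)
    mutations: set[EmsMutation] = set()
    strand_choice: dict[str, str] = {}
    for chrom, seq in genome.chromosomes.items():
        strand = str(rng.choice(["+", "-"]))
        strand_choice[chrom] = strand
        target = "C" if strand == "+" else "G"
        arr = np.frombuffer(seq.encode(), dtype="S1")
        sites = np.flatnonzero(arr == target.encode())
        if sites.size == 0:
            warnings.warn(f"{chrom} has no {target} sites; no EMS mutations placed")
            continue
        n = min(int(rng.poisson(rate * len(seq) / 1000.0)), sites.size)
        chosen = rng.choice(sites, size=n, replace=False)
        for p0 in sorted(int(p) for p in chosen):
            if (chrom, p0 + 1) in exclude:
                continue  # rejection keeps EMS disjoint from accession SNPs
            ref, alt = (("C", "T") if strand == "+" else ("G", "A"))
            mutations.add(EmsMutation(chrom, p0 + 1, ref, alt, strand))
    return mutations, strand_choice


def haldane_recombination(d_morgans: float) -> float:
    """Haldane map function r = (1 - e^(-2d)) / 2."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


def _transmission_r(mut: EmsMutation, causal: tuple[str, int, str],
                    recomb_rate: float) -> float:
    """Recombination fraction between a mutation and the causal locus."""
    chrom, pos, _ = causal
    if mut.chrom != chrom:
        return 0.5
    d = abs(mut.pos - pos) / 1e6 * recomb_rate / 100.0  # Morgans
    return haldane_recombination(d)


def simulate_backcross(truth: MutantGroundTruth, genome: GenomeBundle,
                       n_generations: int, recomb_rate: float, seed: int
                       ) -> set[EmsMutation]:
    """Transmit EMS mutations through repeated backcrossing with selection.

    Each generation the causal-carrying gamete is selected; a mutation at
    recombination fraction r from the causal locus rides along with
    probability (1-r) (1/2 if unlinked). A final selfing fixes each
    surviving mutation homozygous with probability (1-r) — again 1/2 for
    unlinked loci, and certainty in the fully linked limit where the
    mutation cannot separate from the selected, homozygosed causal allele.
    Output is the homozygous fixed set; the causal mutation is always in it.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    retained: set[EmsMutation] = set()
    causal_chrom, causal_pos, _ = truth.causal
    for mut in sorted(truth.ems_mutations):
        if mut.chrom == causal_chrom and mut.pos == causal_pos:
            retained.add(mut)
            continue
        r = _transmission_r(mut, truth.causal, recomb_rate)
        alive = all(rng.random() < (1.0 - r) for _ in range(n_generations))
        if alive and rng.random() < (1.0 - r):  # selfing fixation
            retained.add(mut)
    return retained


def _pick_causal(genome: GenomeBundle, strand_choice: dict[str, str],
                 config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[EmsMutation, str]:
    """Choose a causal EMS mutation: a non-synonymous strand-consistent
    transition inside a CDS on the designated chromosome."""
    from .effects import classify_position_in_model  # local import, no cycle

    chrom = config.chrom_names[min(config.causal_chrom_index,
                                   len(config.chrom_lengths) - 1)]
    strand = strand_choice[chrom]
    ref, alt = (("C", "T") if strand == "+" else ("G", "A"))
    candidates = [m for m in genome.models_on(chrom)
                  if m.feature_type == "protein_coding" and not m.degenerate]
    for model in rng.permutation(len(candidates)):
        model = candidates[int(model)]
        for (s, e) in model.cds:
            for p0 in range(s, e):
                if genome.chromosomes[chrom][p0] != ref:
                    continue
                cat, _ = classify_position_in_model(genome, model, p0 + 1, alt)
                if cat == "non_synonymous":
                    return EmsMutation(chrom, p0 + 1, ref, alt, strand), model.gene_id
    raise PackingError(f"no non-synonymous {ref}>{alt} site available on {chrom}")


def simulate_mutant_line(genome: GenomeBundle, config: SimulationConfig
                         ) -> MutantGroundTruth:
    """Full ground truth: accession SNPs, EMS load with causal, backcrossed
    retained set."""
    rng = np.random.default_rng(config.seed + 1)
    accession = simulate_accession_snps(genome, config.accession_rate,
                                        seed=int(rng.integers(2**31)))
    ems, strand_choice = simulate_ems_mutations(
        genome, config.ems_rate, seed=int(rng.integers(2**31)),
        exclude_positions={(c, p) for c, p, _, _ in accession})
    causal_mut, causal_gene = _pick_causal(genome, strand_choice, config, rng)
    accession = {s for s in accession if (s[0], s[1]) != (causal_mut.chrom, causal_mut.pos)}
    ems = {m for m in ems if (m.chrom, m.pos) != (causal_mut.chrom, causal_mut.pos)}
    ems.add(causal_mut)
    truth = MutantGroundTruth(
        accession_snps=accession,
        ems_mutations=ems,
        causal=(causal_mut.chrom, causal_mut.pos, causal_gene),
        retained_after_backcross={causal_mut},
        chromosome_strand_choice=strand_choice,
    )
    truth.retained_after_backcross = simulate_backcross(
        truth, genome, config.n_backcrosses, config.recomb_rate,
        seed=int(rng.integers(2**31)))
    return truth


# ---------------------------------------------------------------------------
# call tables and coverage tracks
# ---------------------------------------------------------------------------

def _window_depths(length: int, window: int, mean: float,
                   rng: np.random.Generator, noisy: bool) -> np.ndarray:
    n = (length + window - 1) // window
    if noisy:
        return rng.poisson(mean, size=n)
    return np.full(n, int(round(mean)), dtype=int)


def simulate_call_tables(genome: GenomeBundle,
                         line_variants: dict[str, set[AccessionSnp]],
                         config: SimulationConfig, seed: int,
                         schemas: list[str] | None = None,
                         ) -> tuple[dict[tuple[str, str], list[SnpCall]],
                                    dict[tuple[str, str], "object"]]:
    """Per-(genome, schema) SNP-call tables and coverage tracks.

    True variants are emitted as homozygous calls with high scores (mean
    decreasing for permissive schemas); false positives are confined to the
    repeat mask, mostly heterozygous, and low-scoring. Coverage is a
    windowed Poisson track whose mean is schema-specific: strict schemas
    map fewer reads.
    """
    from .filtering import CoverageTrack

    if schemas is None:
        schemas = list(config.schema_params)
    unknown = [s for s in schemas if s not in config.schema_params]
    if unknown:
        raise KeyError(f"unknown schema id(s): {unknown}")
    for genome_id, variants in line_variants.items():
        for chrom, pos, _, _ in variants:
            if chrom not in genome.chromosomes or not (
                    1 <= pos <= len(genome.chromosomes[chrom])):
                raise ValueError(f"variant {chrom}:{pos} outside genome ({genome_id})")
    rng = np.random.default_rng(seed)
    calls: dict[tuple[str, str], list[SnpCall]] = {}
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for genome_id in sorted(line_variants):
        variants = sorted(line_variants[genome_id], key=lambda v: (v[0], v[1]))
        for schema_id in schemas:
            params = config.schema_params[schema_id]
            runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for chrom, seq in genome.chromosomes.items():
                depths = _window_depths(len(seq), config.coverage_window,
                                        params.mean_coverage, rng,
                                        config.coverage_noise)
                starts = np.arange(depths.size) * config.coverage_window
                ends = np.minimum(starts + config.coverage_window, len(seq))
                runs[chrom] = (starts, ends, depths)
            track = CoverageTrack({c: (s, e, d) for c, (s, e, d) in runs.items()})
            table: list[SnpCall] = []
            for chrom, pos, ref, alt in variants:
                cov = track.depth_at(chrom, pos)
                if config.score_noise:
                    a = params.score_mean * params.score_concentration
                    b = (1 - params.score_mean) * params.score_concentration
                    score = float(rng.beta(a, b))
                else:
                    score = params.score_mean
                table.append(SnpCall(schema_id, genome_id, chrom, pos, ref, alt,
                                     coverage=int(cov), score=score, zygosity="hom"))
            # schema-specific false positives inside the repeat mask; one
            # call per locus, so true-variant positions are skipped
            true_pos = {(c, p) for c, p, _, _ in variants}
            for chrom, rs, re_ in genome.repeat_mask:
                n_fp = int(rng.poisson(config.fp_rate * (re_ - rs) / 1000.0))
                for p0 in sorted(int(p) for p in rng.integers(rs, re_, size=n_fp)):
                    if (chrom, p0 + 1) in true_pos:
                        continue
                    ref = genome.chromosomes[chrom][p0]
                    alt = str(rng.choice([b for b in BASES if b != ref]))
                    het = bool(rng.random() < config.het_artifact_prob)
                    if het:
                        alt = IUPAC_HET[frozenset((ref, alt))]
                    a = config.fp_score_mean * config.fp_score_concentration
                    b = (1 - config.fp_score_mean) * config.fp_score_concentration
                    table.append(SnpCall(
                        schema_id, genome_id, chrom, p0 + 1, ref, alt,
                        coverage=int(track.depth_at(chrom, p0 + 1)),
                        score=float(rng.beta(a, b)),
                        zygosity="het" if het else "hom"))
            table.sort(key=lambda c: (c.chrom, c.pos, c.alt))
            calls[(genome_id, schema_id)] = table
            tracks[(genome_id, schema_id)] = track
    return calls, tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

WAVE_SHAPES = ("spike", "sine", "cosine")


def _waveform_values(shape: str, phase: float, timepoints: np.ndarray,
                     period: float) -> np.ndarray:
    from .rhythm import waveform_values
    return waveform_values(shape, phase, timepoints, period)


def assign_expression_classes(gene_ids: list[str], params: ExpressionParams,
                              rng: np.random.Generator,
                              forced: dict[str, str] | None = None
                              ) -> dict[str, str]:
    classes: dict[str, str] = {}
    for gid in gene_ids:
        if forced and gid in forced:
            classes[gid] = forced[gid]
            continue
        u = rng.random()
        if u < params.rhythmic_fraction:
            classes[gid] = "rhythmic_all"
        elif u < params.rhythmic_fraction + params.dd_only_fraction:
            classes[gid] = "rhythmic_dd_only"
        else:
            classes[gid] = "arrhythmic"
    return classes


def simulate_expression_matrix(gene_ids: list[str], config: SimulationConfig,
                               truth_assignment: dict[str, str] | None,
                               seed: int
                               ) -> tuple[dict[str, pd.DataFrame],
                                          dict[str, str],
                                          dict[str, tuple[str, float]]]:
    """Three expression datasets (two LL, one DD) as genes-x-timepoints frames.

    Returns (dataset -> DataFrame, gene -> class, gene -> (shape, phase)).
    Rhythmic genes are a 24-h waveform (spike/sine/cosine, integer phase)
    plus Gaussian noise; arrhythmic genes are noise around a constant.
    ``rhythmic_dd_only`` genes oscillate only in the DD dataset.
    """
    params = config.expression
    rng = np.random.default_rng(seed)
    t = np.asarray(params.timepoints, dtype=float)
    classes = assign_expression_classes(gene_ids, params, rng, truth_assignment)
    shapes: dict[str, tuple[str, float]] = {}
    data = {ds: {} for ds in params.datasets}
    for gid in gene_ids:
        shape = str(rng.choice(WAVE_SHAPES))
        phase = float(rng.integers(0, int(params.period)))
        shapes[gid] = (shape, phase)
        for ds in params.datasets:
            rhythmic_here = (
                classes[gid] == "rhythmic_all"
                or (classes[gid] == "rhythmic_dd_only" and ds.startswith("DD"))
            )
            noise = rng.normal(0.0, params.noise_sd, size=t.size)
            if rhythmic_here:
                wave = _waveform_values(shape, phase, t, params.period)
                values = params.baseline + params.amplitude * wave + noise
            else:
                values = params.baseline + noise
            data[ds][gid] = values
    frames = {
        ds: pd.DataFrame.from_dict(cols, orient="index", columns=[f"{h:g}" for h in t])
              .rename_axis("gene_id")
        for ds, cols in data.items()
    }
    return frames, classes, shapes
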