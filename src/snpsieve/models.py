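"""Shared domain types for the re-sequencing pipeline.

Coordinate conventions (used consistently package-wide):

* SNP positions are **1-based** (VCF convention).
* All intervals — exons, CDS segments, repeat masks, coverage runs,
  cluster spans — are **0-based half-open** (BED/BedGraph convention).

Helpers :func:`pos_to_interval` / :func:`interval_contains_pos` centralise
the conversion so no call site does its own arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: IUPAC two-base ambiguity codes, used for heterozygous call alleles.
IUPAC_HET = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def interval_contains_pos(start: int, end: int, pos: int) -> bool:
    """Does the 0-based half-open interval contain the 1-based position?"""
    return start <= pos - 1 < end


@dataclass(frozen=True)
class GeneModel:
    """One transcript-level gene model.

    ``exons`` and ``cds`` are ordered, non-overlapping 0-based half-open
    intervals in genomic (plus-strand) coordinates; CDS segments are a
    subset of the exonic footprint. Protein-coding models whose CDS length
    is not a multiple of 3 (or that are otherwise broken) carry
    ``degenerate=True`` and are classified "unclassifiable" downstream.
    """

    id: str
    chrom: str
    strand: str  # '+' or '-'
    feature_type: str  # 'protein_coding' or 'pseudogene'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    gene_id: str | None = None
    degenerate: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.id}")
        for ivs in (self.exons, self.cds):
            for (s, e) in ivs:
                if not (0 <= s < e):
                    raise ValueError(f"bad interval ({s},{e}) in {self.id}")
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"unsorted/overlapping intervals in {self.id}")
        if self.gene_id is None:
            object.__setattr__(self, "gene_id", self.id)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return interval_contains_pos(s, e, pos)


@dataclass
class GenomeBundle:
    """Reference sequences + gene models + repeat mask."""

    chromosomes: dict[str, str]  # name -> sequence, insertion-ordered
    gene_models: list[GeneModel] = field(default_factory=list)
    repeat_mask: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        names = list(self.chromosomes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for m in self.gene_models:
            if m.chrom not in self.chromosomes:
                raise ValueError(f"model {m.id} on unknown chromosome {m.chrom}")
            if m.span[1] > len(self.chromosomes[m.chrom]):
                raise ValueError(f"model {m.id} extends past end of {m.chrom}")

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def models_on(self, chrom: str) -> list[GeneModel]:
        return [m for m in self.gene_models if m.chrom == chrom]


# Variant keys used throughout: accession SNPs as (chrom, pos, ref, alt);
# EMS mutations additionally carry the strand of the alkylated C.
AccessionSnp = tuple[str, int, str, str]


@dataclass(frozen=True, order=True)
class EmsMutation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    strand_of_origin: str  # '+' or '-'

    def __post_init__(self):
        if (self.ref, self.alt) not in (("C", "T"), ("G", "A")):
            raise ValueError(
                f"EMS mutation must be C>T or G>A on the plus strand, got "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> AccessionSnp:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutantGroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    accession_snps: set[AccessionSnp]
    ems_mutations: set[EmsMutation]
    causal: tuple[str, int, str]  # (chrom, pos, gene_id)
    retained_after_backcross: set[EmsMutation]
    chromosome_strand_choice: dict[str, str]
    expression_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.retained_after_backcross <= self.ems_mutations:
            raise ValueError("retained set must be a subset of the EMS set")
        chrom, pos, _ = self.causal
        if not any(m.chrom == chrom and m.pos == pos for m in self.retained_after_backcross):
            raise ValueError("causal mutation must be in the retained set")
        for m in self.ems_mutations:
            want = self.chromosome_strand_choice.get(m.chrom)
            if want is not None and m.strand_of_origin != want:
                raise ValueError(f"strand of {m} contradicts chromosome choice {want}")
        overlap = {(m.chrom, m.pos) for m in self.ems_mutations} & {
            (c, p) for c, p, _, _ in self.accession_snps
        }
        if overlap:
            raise ValueError(f"EMS mutations collide with accession SNPs at {sorted(overlap)[:3]}")

    @property
    def retained_keys(self) -> set[AccessionSnp]:
        return {m.key for m in self.retained_after_backcross}


@dataclass(frozen=True)
class SnpCall:
    """One putative variant call at a locus for one genome under one schema."""

    schema_id: str
    genome_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # base, or IUPAC ambiguity code for heterozygous calls
    coverage: int
    score: float
    zygosity: str  # 'hom' or 'het'

    def __post_init__(self):
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"bad zygosity {self.zygosity!r} at {self.chrom}:{self.pos}")
        if self.coverage < 0:
            raise ValueError(f"negative coverage at {self.chrom}:{self.pos}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0,1] at {self.chrom}:{self.pos}")
        if self.zygosity == "hom" and self.alt == self.ref:
            raise ValueError(f"hom call with alt == ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Locus identity used for cross-schema and cross-genome matching."""
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class ConsensusSnp:
    """A SNP reported by every matching schema, with the most conservative
    coverage/score seen across schemas."""

    chrom: str
    pos: int
    ref: str
    alt: str
    min_coverage: int
    min_score: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


def sorted_variants(variants: Iterable) -> list:
    """Deterministic ordering for any (chrom, pos, ...)-keyed records."""
    return sorted(variants, key=lambda v: (v[0], v[1]) if isinstance(v, tuple) else (v.chrom, v.pos))
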