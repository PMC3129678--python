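"""SNP-confidence pipeline: per-genome filtering, cross-schema intersection,
two-genome uniqueness partition, callable-fraction accounting, concordance.

The filtering model is the one that makes a backcrossed-mutant experiment
work: every real locus in both the mutant and its parent line must be
homozygous, so heterozygous calls are a priori low-confidence; a call must
be well covered in *both* genomes (a SNP shared by both lines can masquerade
as line-specific when the other genome is under-covered); and only calls
reported by every matching schema survive, exploiting the complementary
failure modes of strict (low-coverage) and permissive (low-score) schemas.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .models import ConsensusSnp, SnpCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the confidence filter.

    ``min_coverage=6`` encodes "coverage must exceed 5x": a locus is kept
    iff depth >= 6 in both genomes. ``min_score`` applies to the calling
    genome only (a score is a property of a call, not of a locus).
    """

    min_coverage: int = 6
    min_score: float = 0.7
    require_homozygous: bool = True
    schemas: tuple[str, ...] = ("25_2", "25_3", "35_2", "35_3", "35_4")
    #: 'any' = a base is "no reads" when depth 0 in any (genome, schema)
    #: pairing; 'all' requires depth 0 everywhere.
    no_reads_rule: str = "any"

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must be in [0,1]")
        if not self.schemas:
            raise ValueError("schemas must be non-empty")
        if self.no_reads_rule not in ("any", "all"):
            raise ValueError("no_reads_rule must be 'any' or 'all'")


class CoverageTrack:
    """Run-length coverage per chromosome (0-based half-open runs)."""

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.runs = {}
        for chrom, (starts, ends, depths) in runs.items():
            starts = np.asarray(starts, dtype=int)
            ends = np.asarray(ends, dtype=int)
            depths = np.asarray(depths, dtype=int)
            if np.any(depths < 0):
                raise ValueError(f"negative depth on {chrom}")
            if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"runs on {chrom} must be sorted and non-overlapping")
            self.runs[chrom] = (starts, ends, depths)

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a 1-based position; absent run or chromosome -> 0."""
        if chrom not in self.runs:
            return 0
        starts, ends, depths = self.runs[chrom]
        i = bisect_right(starts, pos - 1) - 1
        if i >= 0 and pos - 1 < ends[i]:
            return int(depths[i])
        return 0

    def chrom_end(self, chrom: str) -> int:
        if chrom not in self.runs:
            return 0
        return int(self.runs[chrom][1][-1])

    def chromosomes(self) -> list[str]:
        return list(self.runs)


def filter_calls(calls: list[SnpCall], own_coverage: CoverageTrack,
                 other_coverage: CoverageTrack, config: FilterConfig
                 ) -> list[SnpCall]:
    """Keep calls that are homozygous (when required), score >= min_score,
    and covered at >= min_coverage depth in *both* genomes. Order preserved."""
    kept: list[SnpCall] = []
    dropped = {"het": 0, "score": 0, "own_cov": 0, "other_cov": 0}
    for call in calls:
        if call.chrom not in own_coverage.runs or call.chrom not in other_coverage.runs:
            logger.info("chromosome %s absent from a coverage track; depth treated as 0",
                        call.chrom)
        if config.require_homozygous and call.zygosity != "hom":
            dropped["het"] += 1
            continue
        if call.score < config.min_score:
            dropped["score"] += 1
            continue
        if own_coverage.depth_at(call.chrom, call.pos) < config.min_coverage:
            dropped["own_cov"] += 1
            continue
        if other_coverage.depth_at(call.chrom, call.pos) < config.min_coverage:
            dropped["other_cov"] += 1
            continue
        kept.append(call)
    logger.info("filter_calls: kept %d of %d (dropped %s)", len(kept), len(calls), dropped)
    return kept


def intersect_schemas(per_schema_filtered: dict[str, list[SnpCall]],
                      config: FilterConfig) -> list[ConsensusSnp]:
    """Emit (chrom, pos, alt) loci present post-filter in *every* schema.

    The consensus record carries the minimum coverage and score observed
    across schemas (the most conservative supporting evidence).
    """
    missing = [s for s in config.schemas if s not in per_schema_filtered]
    if missing:
        raise KeyError(f"schema(s) {missing} listed in config but absent from input")
    indexed: list[dict[tuple, SnpCall]] = []
    for schema in config.schemas:
        indexed.append({c.key: c for c in per_schema_filtered[schema]})
    common = set(indexed[0])
    for idx in indexed[1:]:
        common &= set(idx)
    out = []
    for key in sorted(common):
        supports = [idx[key] for idx in indexed]
        first = supports[0]
        out.append(ConsensusSnp(
            chrom=first.chrom, pos=first.pos, ref=first.ref, alt=first.alt,
            min_coverage=min(c.coverage for c in supports),
            min_score=min(c.score for c in supports)))
    return out


@dataclass
class UniquenessPartition:
    """Disjoint classification of two genomes' consensus SNPs."""

    shared: list[ConsensusSnp] = field(default_factory=list)
    mutant_only: list[ConsensusSnp] = field(default_factory=list)
    wildtype_only: list[ConsensusSnp] = field(default_factory=list)
    excluded_low_coverage: list[ConsensusSnp] = field(default_factory=list)

    def __post_init__(self):
        sets = [
            {c.key for c in self.shared},
            {c.key for c in self.mutant_only},
            {c.key for c in self.wildtype_only},
            {c.key for c in self.excluded_low_coverage},
        ]
        # pairwise disjoint, except that a locus excluded in one genome may
        # still be keyed differently; keys include alt so identical keys clash
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("partition sets must be pairwise disjoint")

    @property
    def mutant_only_keys(self) -> set[tuple[str, int, str]]:
        return {c.key for c in self.mutant_only}


def _covered_under_all_schemas(tracks: dict[str, CoverageTrack], chrom: str,
                               pos: int, min_coverage: int) -> bool:
    return all(t.depth_at(chrom, pos) >= min_coverage for t in tracks.values())


def partition_uniqueness(mutant_consensus: list[ConsensusSnp],
                         wildtype_consensus: list[ConsensusSnp],
                         mutant_tracks: dict[str, CoverageTrack],
                         wildtype_tracks: dict[str, CoverageTrack],
                         config: FilterConfig) -> UniquenessPartition:
    """Split consensus SNPs into shared / mutant-only / wildtype-only, with a
    low-coverage guard: a SNP seen in one genome only is called unique only
    if the *other* genome was deep enough, under every schema, to have seen
    it."""
    mut = {c.key: c for c in mutant_consensus}
    wt = {c.key: c for c in wildtype_consensus}
    part = UniquenessPartition()
    mut_loci = {(c.chrom, c.pos): c for c in mutant_consensus}
    wt_loci = {(c.chrom, c.pos): c for c in wildtype_consensus}
    for key in sorted(set(mut) | set(wt)):
        chrom, pos, _alt = key
        if key in mut and key in wt:
            part.shared.append(mut[key])
            continue
        if key in mut:
            other_has_conflicting = (chrom, pos) in wt_loci
            if other_has_conflicting:
                logger.info("conflicting alt alleles at %s:%d; both treated as unique",
                            chrom, pos)
                part.mutant_only.append(mut[key])
            elif _covered_under_all_schemas(wildtype_tracks, chrom, pos,
                                            config.min_coverage):
                part.mutant_only.append(mut[key])
            else:
                part.excluded_low_coverage.append(mut[key])
        else:
            if (chrom, pos) in mut_loci:
                logger.info("conflicting alt alleles at %s:%d; both treated as unique",
                            chrom, pos)
                part.wildtype_only.append(wt[key])
            elif _covered_under_all_schemas(mutant_tracks, chrom, pos,
                                            config.min_coverage):
                part.wildtype_only.append(wt[key])
            else:
                part.excluded_low_coverage.append(wt[key])
    return part


def callable_fraction(tracks: dict[tuple[str, str], CoverageTrack],
                      chrom_lengths: dict[str, int],
                      config: FilterConfig) -> tuple[float, float, float]:
    """Per-base accounting of the genome's callability.

    Returns (no_reads, reads_but_uninterrogated, interrogated) fractions,
    summing to 1. A base is *interrogated* iff depth >= min_coverage in
    every (genome, schema) pairing; *no reads* iff depth 0 in any pairing
    (``no_reads_rule='any'``, the default, since SNP calling needed both
    genomes) or in all pairings (``'all'``); the remainder had reads but
    failed the criteria.
    """
    total = sum(chrom_lengths.values())
    if total == 0:
        raise ValueError("empty chromosome universe")
    no_reads = 0
    interrogated = 0
    track_list = list(tracks.values())
    for chrom, length in chrom_lengths.items():
        # sweep over union breakpoints of all tracks on this chromosome
        cuts = {0, length}
        for t in track_list:
            if chrom in t.runs:
                starts, ends, _ = t.runs[chrom]
                cuts.update(int(x) for x in starts if x < length)
                cuts.update(int(x) for x in ends if x < length)
        cuts = sorted(cuts)
        for a, b in zip(cuts, cuts[1:]):
            depths = [t.depth_at(chrom, a + 1) for t in track_list]
            span = b - a
            zero = (any(d == 0 for d in depths) if config.no_reads_rule == "any"
                    else all(d == 0 for d in depths))
            if zero:
                no_reads += span
            elif all(d >= config.min_coverage for d in depths):
                interrogated += span
    uninterrogated = total - no_reads - interrogated
    return no_reads / total, uninterrogated / total, interrogated / total


def set_concordance(called_a: set, called_b: set
                    ) -> tuple[int, int, int, float]:
    """(|a|, |b|, |a∩b|, percent of a found in b, one decimal).

    Sets are keyed on (chrom, pos, alt). An empty first set has no defined
    percentage and is an error.
    """
    if len(called_a) == 0:
        raise ValueError("concordance undefined for an empty first set")
    inter = len(set(called_a) & set(called_b))
    pct = round(100.0 * inter / len(called_a), 1)
    return len(called_a), len(called_b), inter, pct
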