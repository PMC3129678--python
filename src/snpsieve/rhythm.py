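"""Rhythmic-expression screening and candidate-gene ranking.

A gene's time course is scored against a bank of circadian model
waveforms — spikes, sines and cosines with a 24-h period and scanned
phase — by Pearson correlation; a profile is called rhythmic in a dataset
when its best correlation strictly exceeds a threshold (default 0.85).
Candidate genes (those carrying a mutant-specific protein-altering SNP)
are then tiered: rhythmic in all datasets, rhythmic in at least one, or
arrhythmic — following the logic that core clock components are
themselves rhythmically expressed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelWaveform:
    shape: str  # 'spike', 'sine' or 'cosine'
    period: float
    phase: float
    timepoints: tuple[float, ...]
    values: tuple[float, ...]


def waveform_values(shape: str, phase: float, timepoints: np.ndarray,
                    period: float = 24.0) -> np.ndarray:
    """Sample one model waveform on a timepoint grid.

    A spike is a unit pulse at the gridpoint(s) closest to ``phase`` within
    each cycle (ties mark every tied gridpoint); sine/cosine are phase-
    shifted unit waves.
    """
    t = np.asarray(timepoints, dtype=float)
    if shape == "sine":
        return np.sin(2 * np.pi * (t - phase) / period)
    if shape == "cosine":
        return np.cos(2 * np.pi * (t - phase) / period)
    if shape == "spike":
        values = np.zeros_like(t)
        n_cycles = int(np.floor(t.max() / period)) + 1
        for c in range(n_cycles):
            target = c * period + (phase % period)
            dist = np.abs(t - target)
            values[dist == dist.min()] = 1.0
        return values
    raise ValueError(f"unknown waveform shape {shape!r}")


def build_model_waveforms(timepoints, period: float = 24.0,
                          phases=None, shapes=("spike", "sine", "cosine")
                          ) -> list[ModelWaveform]:
    """One waveform per (shape, phase); phases default to integer hours
    0..period-1. Warns when the grid is too coarse to resolve the period."""
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(timepoints, dtype=float)
    if phases is None:
        phases = list(range(int(period)))
    for phi in phases:
        if not 0 <= phi < period:
            raise ValueError(f"phase {phi} outside [0, {period})")
    spacing = np.diff(t)
    if spacing.size and np.median(spacing) > period / 2:
        warnings.warn("timepoint grid coarser than half the period; waveform "
                      "fits will alias")
    bank = []
    for shape in shapes:
        for phi in phases:
            vals = waveform_values(shape, float(phi), t, period)
            bank.append(ModelWaveform(shape=shape, period=period, phase=float(phi),
                                      timepoints=tuple(t), values=tuple(vals)))
    return bank


def score_rhythmicity(timepoints, values, bank: list[ModelWaveform],
                      detrend: bool = False
                      ) -> tuple[float, str | None, float | None]:
    """Best Pearson correlation of a series against the waveform bank.

    Returns (best_r, best_shape, best_phase). A constant (zero-variance)
    series scores 0 by convention. ``detrend=True`` removes a linear
    trend from the series first (raw values are the default convention).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if detrend and np.std(y) > 0:
        slope, intercept = np.polyfit(t, y, 1)
        y = y - (slope * t + intercept)
    best = (0.0, None, None)
    if np.std(y) == 0:
        return best
    yc = y - y.mean()
    ynorm = np.sqrt((yc ** 2).sum())
    best_r = -np.inf
    for wf in bank:
        if not np.allclose(np.asarray(wf.timepoints), t):
            raise ValueError("series and waveform bank sampled on different grids")
        x = np.asarray(wf.values)
        xc = x - x.mean()
        xnorm = np.sqrt((xc ** 2).sum())
        if xnorm == 0:
            continue
        r = float((xc * yc).sum() / (xnorm * ynorm))
        if r > best_r:
            best_r = r
            best = (r, wf.shape, wf.phase)
    return best


@dataclass
class RhythmicityResult:
    gene_id: str
    per_dataset: dict[str, tuple[float, str | None, float | None]]
    rhythmic_all: bool
    rhythmic_any: bool

    @property
    def max_r(self) -> float:
        return max((r for r, _, _ in self.per_dataset.values()), default=0.0)


def classify_rhythmic(results_per_dataset: dict[str, dict[str, tuple]],
                      threshold: float = 0.85, mode: str = "all"
                      ) -> dict[str, RhythmicityResult]:
    """Aggregate per-dataset scores into rhythmic_all / rhythmic_any flags.

    Rhythmic in a dataset iff best_r > threshold (strictly). A gene missing
    from a dataset is counted non-rhythmic there.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    genes = sorted({g for scores in results_per_dataset.values() for g in scores})
    out = {}
    for gene in genes:
        per = {}
        flags = []
        for ds, scores in results_per_dataset.items():
            if gene in scores:
                per[ds] = scores[gene]
                flags.append(scores[gene][0] > threshold)
            else:
                logger.info("gene %s missing from dataset %s; counted non-rhythmic",
                            gene, ds)
                per[ds] = (0.0, None, None)
                flags.append(False)
        out[gene] = RhythmicityResult(
            gene_id=gene, per_dataset=per,
            rhythmic_all=all(flags), rhythmic_any=any(flags))
    return out


@dataclass(frozen=True)
class Candidate:
    gene_id: str
    tier: int  # 1 = rhythmic in all datasets, 2 = in some, 3 = in none
    max_r: float
    snps: tuple[tuple[str, int, str, str, str], ...]  # (chrom,pos,ref,alt,category)
    per_dataset: tuple[tuple[str, float, str | None, float | None], ...]


PROTEIN_ALTERING = ("non_synonymous", "stop_created", "stop_deleted")


def rank_candidates(mutant_only_keys: set, effect_records,
                    rhythmicity: dict[str, RhythmicityResult],
                    interval: tuple[str, int, int] | None = None
                    ) -> list[Candidate]:
    """Rank genes carrying a mutant-specific protein-altering SNP.

    Tier 1: rhythmic in all datasets; tier 2: rhythmic in at least one;
    tier 3: the rest. Within a tier genes sort by best correlation,
    descending. ``interval`` (chrom, start, end; 0-based half-open)
    optionally restricts to a mapping interval.
    """
    per_gene: dict[str, list] = {}
    for rec in effect_records:
        if rec.category not in PROTEIN_ALTERING or rec.feature_id is None:
            continue
        if (rec.chrom, rec.pos, rec.alt) not in mutant_only_keys:
            continue
        if interval is not None:
            chrom, start, end = interval
            if rec.chrom != chrom or not (start <= rec.pos - 1 < end):
                continue
        per_gene.setdefault(rec.feature_id, []).append(
            (rec.chrom, rec.pos, rec.ref, rec.alt, rec.category))
    candidates = []
    for gene_id, snps in per_gene.items():
        res = rhythmicity.get(gene_id)
        if res is None:
            tier, max_r, per = 3, 0.0, ()
        else:
            tier = 1 if res.rhythmic_all else (2 if res.rhythmic_any else 3)
            max_r = res.max_r
            per = tuple((ds, r, shape, phase)
                        for ds, (r, shape, phase) in sorted(res.per_dataset.items()))
        candidates.append(Candidate(gene_id=gene_id, tier=tier, max_r=max_r,
                                    snps=tuple(sorted(snps)), per_dataset=per))
    candidates.sort(key=lambda c: (c.tier, -c.max_r, c.gene_id))
    return candidates
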