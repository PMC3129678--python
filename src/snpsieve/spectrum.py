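"""EMS mutation-spectrum characterisation.

EMS alkylates guanine, so induced point mutations are G/C→A/T transitions
almost exclusively. A line descended from a cell that inherited a single
alkylated strand per chromosome shows *strand bias*: every mutation on a
chromosome appears as C→T, or every one as G→A, on the reference plus
strand. Backcrossing with selection leaves retained mutations clustered
around the causal locus (hitchhiking). This module quantifies all three
signatures: substitution classification, exact-binomial strand-bias tests,
mutation-rate estimation, and max-gap cluster detection with a Poisson
dispersion test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import interval_contains_pos

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class SubstitutionClass:
    from_base: str
    to_base: str
    kind: str  # 'transition' or 'transversion'
    ems_consistent: bool


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Transition/transversion kind and EMS consistency of a substitution.

    EMS-consistent means C→T or G→A as seen on the reference plus strand.
    """
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"ambiguity code or invalid base {b!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    transition = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return SubstitutionClass(
        from_base=ref, to_base=alt,
        kind="transition" if transition else "transversion",
        ems_consistent=(ref, alt) in (("C", "T"), ("G", "A")))


@dataclass(frozen=True)
class StrandBiasResult:
    region: tuple[str, int, int]
    n_c_to_t: int
    n_g_to_a: int
    n_other: int
    fraction_c_to_t: float  # percent, over the EMS-consistent subset
    p_value: float  # two-sided exact binomial against 0.5

    @property
    def fraction_g_to_a(self) -> float:
        return 100.0 - self.fraction_c_to_t

    @property
    def contamination_fraction(self) -> float:
        """Fraction of SNPs in the region that are not EMS-consistent."""
        n = self.n_c_to_t + self.n_g_to_a + self.n_other
        return self.n_other / n if n else 0.0


def strand_bias(snps, region: tuple[str, int, int]) -> StrandBiasResult:
    """Tally EMS-consistent SNPs by direction inside a region and test the
    50/50 C→T vs G→A null with an exact two-sided binomial.

    ``snps`` yields (chrom, pos, ref, alt); ``region`` is (chrom, start,
    end), 0-based half-open. Non-EMS substitutions are counted separately
    as contamination and excluded from the fraction.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    n_ct = n_ga = n_other = 0
    for c, pos, ref, alt in snps:
        if c != chrom or not interval_contains_pos(start, end, pos):
            continue
        sub = classify_substitution(ref, alt)
        if (ref, alt) == ("C", "T"):
            n_ct += 1
        elif (ref, alt) == ("G", "A"):
            n_ga += 1
        else:
            n_other += 1
    n = n_ct + n_ga
    if n == 0:
        raise ValueError(f"no EMS-consistent SNPs in {chrom}:{start}-{end}; "
                         "strand-bias fraction undefined")
    p = stats.binomtest(n_ct, n, 0.5, alternative="two-sided").pvalue
    return StrandBiasResult(region=region, n_c_to_t=n_ct, n_g_to_a=n_ga,
                            n_other=n_other,
                            fraction_c_to_t=round(100.0 * n_ct / n, 1),
                            p_value=float(p))


@dataclass(frozen=True)
class MutationRate:
    rate_per_kb: float
    one_per_kb: int | None  # "1 mutation per N kb"; None when count is 0
    count: int
    interval_bp: int


def mutation_rate(snps, interval_bp: int) -> MutationRate:
    """Point-mutation rate over an interval, also expressed "1 per N kb"
    with N = round(interval_kb / count)."""
    if interval_bp <= 0:
        raise ValueError("interval must be positive")
    count = snps if isinstance(snps, int) else len(list(snps))
    kb = interval_bp / 1000.0
    if count == 0:
        return MutationRate(0.0, None, 0, interval_bp)
    return MutationRate(count / kb, int(round(kb / count)), count, interval_bp)


@dataclass(frozen=True)
class ClusterReport:
    clusters: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, n)
    homogeneity_p: float


def detect_clusters(snps, chrom_lengths: dict[str, int], max_gap_bp: int,
                    min_size: int = 2, n_windows: int = 50) -> ClusterReport:
    """Max-gap single-linkage clustering plus a genome-wide dispersion test.

    SNPs closer than ``max_gap_bp`` on the same chromosome join one
    cluster; clusters of >= ``min_size`` are reported with 0-based
    half-open spans. The homogeneity p-value is a chi-square dispersion
    test of per-window SNP counts (``n_windows`` windows allocated over the
    genome proportionally to chromosome length) against a uniform Poisson
    rate: small p means the SNPs are significantly clustered.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, *_ in snps:
        by_chrom.setdefault(chrom, []).append(pos)
    clusters = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run = [positions[0]]
        for pos in positions[1:]:
            if pos - run[-1] <= max_gap_bp:
                run.append(pos)
            else:
                if len(run) >= min_size:
                    clusters.append((chrom, run[0] - 1, run[-1], len(run)))
                run = [pos]
        if len(run) >= min_size:
            clusters.append((chrom, run[0] - 1, run[-1], len(run)))

    total_len = sum(chrom_lengths.values())
    counts = []
    for chrom, length in chrom_lengths.items():
        k = max(1, round(n_windows * length / total_len))
        edges = np.linspace(0, length, k + 1)
        pos = np.asarray(by_chrom.get(chrom, []), dtype=float)
        hist, _ = np.histogram(pos, bins=edges)
        counts.extend(hist.tolist())
    counts = np.asarray(counts, dtype=float)
    lam = counts.mean()
    if lam == 0:
        p = 1.0
    else:
        statistic = float(((counts - lam) ** 2 / lam).sum())
        p = float(stats.chi2.sf(statistic, df=counts.size - 1))
    return ClusterReport(clusters=tuple(clusters), homogeneity_p=p)


def plot_snp_positions(snps, tracks, chrom_lengths: dict[str, int], path):
    """Per-chromosome scatter of SNP positions over a coverage background.

    Optional visual aid; requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(chrom_lengths)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.6 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        for track in (tracks or {}).values():
            if chrom in track.runs:
                starts, _, depths = track.runs[chrom]
                ax.plot(starts, depths, color="0.8", lw=0.5, zorder=0)
        xs = [pos for c, pos, *_ in snps if c == chrom]
        ax.scatter(xs, [1] * len(xs), s=12, color="tab:blue", zorder=1)
        ax.set_ylabel(chrom, rotation=0, ha="right")
        ax.set_xlim(0, chrom_lengths[chrom])
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
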