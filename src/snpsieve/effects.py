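"""Codon-aware SNP consequence classification and tabulation.

Categories: synonymous, non_synonymous, stop_created, stop_deleted,
unclassifiable, pseudogene, intronic, intergenic.

Precedence within one gene model: pseudogene overlap -> pseudogene; CDS
overlap -> codon comparison under the standard nuclear genetic code
(stop_created / stop_deleted / synonymous / non_synonymous); any other
position inside the model span (introns and UTRs alike) -> intronic; a
degenerate model (CDS length not divisible by 3, bad phase) or an
ambiguity base -> unclassifiable. A SNP overlapping several gene models
yields one record per gene — the "apparent" count — while the "actual"
count is the number of distinct loci.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

from .models import COMPLEMENT, GeneModel, GenomeBundle, revcomp

logger = logging.getLogger(__name__)

CATEGORIES = (
    "synonymous", "non_synonymous", "stop_created", "stop_deleted",
    "unclassifiable", "pseudogene", "intronic", "intergenic",
)

CODING_CATEGORIES = ("synonymous", "non_synonymous", "stop_created", "stop_deleted")

#: severity used to deduplicate multiple transcripts of one gene
_SEVERITY = {c: i for i, c in enumerate(
    ("intronic", "unclassifiable", "synonymous", "non_synonymous",
     "stop_deleted", "stop_created"))}


@dataclass(frozen=True)
class EffectRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    feature_id: str | None
    category: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        coding = self.category in CODING_CATEGORIES
        have = self.codon_ref is not None
        if coding != have:
            raise ValueError("codon fields present iff the category is coding")


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(fasta_path, gff3_path) -> GenomeBundle:
    """Assemble a :class:`GenomeBundle` from FASTA + GFF3.

    Gene models are built per transcript (mRNA) from exon/CDS children;
    ``pseudogene`` features become CDS-less models. A protein-coding model
    whose CDS length is not a multiple of 3 is flagged degenerate rather
    than rejected.
    """
    chromosomes = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type(("gene", "pseudogene")):
        if gene.seqid not in chromosomes:
            raise ValueError(f"feature {gene.id} references missing chromosome "
                             f"{gene.seqid}")
        if gene.featuretype == "pseudogene":
            exons = tuple(sorted((f.start - 1, f.end)
                                 for f in db.children(gene, featuretype="exon")))
            if not exons:
                exons = ((gene.start - 1, gene.end),)
            models.append(GeneModel(
                id=gene.id, gene_id=gene.id, chrom=gene.seqid,
                strand=gene.strand, feature_type="pseudogene", exons=exons))
            continue
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            transcripts = [gene]  # allow flat gene records with direct CDS
        for tx in transcripts:
            exons = tuple(sorted((f.start - 1, f.end)
                                 for f in db.children(tx, featuretype="exon")))
            cds_feats = sorted(db.children(tx, featuretype="CDS"),
                               key=lambda f: f.start)
            cds = tuple((f.start - 1, f.end) for f in cds_feats)
            if not exons:
                exons = cds if cds else ((gene.start - 1, gene.end),)
            degenerate = False
            if sum(e - s for s, e in cds) % 3 != 0:
                degenerate = True
                logger.info("model %s flagged degenerate (CDS length %% 3 != 0)",
                            tx.id)
            if cds and not _phase_consistent(cds_feats, tx.strand):
                degenerate = True
                logger.info("model %s flagged degenerate (inconsistent phase)", tx.id)
            models.append(GeneModel(
                id=tx.id, gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                feature_type="protein_coding", exons=exons, cds=cds,
                degenerate=degenerate))
    return GenomeBundle(chromosomes=chromosomes, gene_models=models)


def _phase_consistent(cds_feats, strand: str) -> bool:
    """Check declared GFF3 CDS phases against cumulative segment lengths."""
    ordered = cds_feats if strand == "+" else list(reversed(cds_feats))
    consumed = 0
    for f in ordered:
        declared = f.frame
        if declared in (".", None, ""):
            return False
        if int(declared) != (-consumed) % 3:
            return False
        consumed += f.end - f.start + 1
    return True


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _cds_sequence(genome: GenomeBundle, model: GeneModel) -> str:
    """Spliced CDS in translation (5'->3') order."""
    seq = genome.chromosomes[model.chrom]
    parts = [seq[s:e] for s, e in model.cds]
    joined = "".join(parts)
    return revcomp(joined) if model.strand == "-" else joined


def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """0-based offset of a 1-based genomic position within the spliced CDS,
    in translation order; None if the position is not in the CDS."""
    p0 = pos - 1
    lengths = [e - s for s, e in model.cds]
    total = sum(lengths)
    acc = 0
    for (s, e), ln in zip(model.cds, lengths):
        if s <= p0 < e:
            plus_offset = acc + (p0 - s)
            return plus_offset if model.strand == "+" else total - 1 - plus_offset
        acc += ln
    return None


def classify_position_in_model(genome: GenomeBundle, model: GeneModel,
                               pos: int, alt: str
                               ) -> tuple[str, dict | None]:
    """Category of substituting ``alt`` (plus-strand base) at ``pos`` within
    one gene model, plus codon detail for coding categories."""
    if model.feature_type == "pseudogene":
        return "pseudogene", None
    offset = _cds_offset(model, pos)
    if offset is None:
        return "intronic", None
    if model.degenerate:
        return "unclassifiable", None
    cds = _cds_sequence(genome, model)
    alt_tx = alt if model.strand == "+" else COMPLEMENT.get(alt, "N")
    codon_i = offset // 3
    within = offset % 3
    codon_ref = cds[3 * codon_i: 3 * codon_i + 3]
    if len(codon_ref) < 3:
        return "unclassifiable", None
    if any(b not in "ACGT" for b in codon_ref) or alt_tx not in "ACGT":
        return "unclassifiable", None
    codon_alt = codon_ref[:within] + alt_tx + codon_ref[within + 1:]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    detail = {"codon_ref": codon_ref, "codon_alt": codon_alt,
              "aa_ref": aa_ref, "aa_alt": aa_alt}
    if aa_alt == "*" and aa_ref != "*":
        return "stop_created", detail
    if aa_ref == "*" and aa_alt != "*":
        return "stop_deleted", detail
    if aa_ref == aa_alt:
        return "synonymous", detail
    return "non_synonymous", detail


def classify_snp(snp: tuple[str, int, str, str], bundle: GenomeBundle
                 ) -> list[EffectRecord]:
    """Classify one SNP against every overlapping gene model.

    Returns one record per overlapping *gene* (transcripts of the same gene
    are collapsed to the most severe consequence), or a single intergenic
    record when no model overlaps. The reference allele must match the
    genome.
    """
    chrom, pos, ref, alt = snp
    if chrom not in bundle.chromosomes:
        raise ValueError(f"SNP on unknown chromosome {chrom}:{pos}")
    genome_base = bundle.base(chrom, pos)
    if ref != genome_base:
        raise ValueError(
            f"ref mismatch at {chrom}:{pos}: call says {ref}, genome has {genome_base}")
    per_gene: dict[str, tuple[str, dict | None, str]] = {}
    for model in bundle.models_on(chrom):
        if not model.contains(pos):
            continue
        category, detail = classify_position_in_model(bundle, model, pos, alt)
        prev = per_gene.get(model.gene_id)
        if prev is None or _SEVERITY.get(category, -1) > _SEVERITY.get(prev[0], -1):
            per_gene[model.gene_id] = (category, detail, model.gene_id)
    if not per_gene:
        return [EffectRecord(chrom, pos, ref, alt, None, "intergenic")]
    records = []
    for gene_id in sorted(per_gene):
        category, detail, _ = per_gene[gene_id]
        detail = detail or {}
        records.append(EffectRecord(
            chrom, pos, ref, alt, gene_id, category,
            codon_ref=detail.get("codon_ref"), codon_alt=detail.get("codon_alt"),
            aa_ref=detail.get("aa_ref"), aa_alt=detail.get("aa_alt")))
    return records


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    counts: pd.DataFrame  # chromosomes x categories
    apparent_per_chrom: pd.Series
    actual_per_chrom: pd.Series

    @property
    def apparent_total(self) -> int:
        return int(self.apparent_per_chrom.sum())

    @property
    def actual_total(self) -> int:
        return int(self.actual_per_chrom.sum())


def tabulate_effects(records: list[EffectRecord]) -> EffectTable:
    """Per-chromosome category counts with apparent (per gene context) and
    actual (distinct loci) totals."""
    chroms = sorted({r.chrom for r in records})
    counts = pd.DataFrame(0, index=chroms, columns=list(CATEGORIES), dtype=int)
    loci = defaultdict(set)
    for r in records:
        counts.loc[r.chrom, r.category] += 1
        loci[r.chrom].add(r.pos)
    apparent = counts.sum(axis=1)
    actual = pd.Series({c: len(loci[c]) for c in chroms}, dtype=int)
    if not (actual <= apparent).all():
        raise AssertionError("actual count exceeded apparent count")
    return EffectTable(counts=counts, apparent_per_chrom=apparent,
                       actual_per_chrom=actual)


# ---------------------------------------------------------------------------
# neutral expectation
# ---------------------------------------------------------------------------

def neutral_expectation(bundle: GenomeBundle,
                        spectrum: dict[tuple[str, str], float]
                        ) -> dict[str, float]:
    """Expected coding-category fractions under no selection.

    Exhaustively enumerates every possible substitution at every CDS
    position of every non-degenerate model, weights each by the spectrum's
    (plus-strand ref -> alt) weight, classifies it, and returns normalised
    fractions of the four coding categories.
    """
    if any(w < 0 for w in spectrum.values()) or not any(spectrum.values()):
        raise ValueError("spectrum weights must be >= 0 and not all zero")
    totals = {c: 0.0 for c in CODING_CATEGORIES}
    grand = 0.0
    models = [m for m in bundle.gene_models
              if m.feature_type == "protein_coding" and not m.degenerate and m.cds]
    if not models:
        raise ValueError("bundle has no usable CDS")
    for model in models:
        seq = bundle.chromosomes[model.chrom]
        for (s, e) in model.cds:
            for p0 in range(s, e):
                ref = seq[p0]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    w = spectrum.get((ref, alt), 0.0)
                    if w == 0.0:
                        continue
                    category, _ = classify_position_in_model(
                        bundle, model, p0 + 1, alt)
                    if category in totals:
                        totals[category] += w
                        grand += w
    if grand == 0.0:
        raise ValueError("spectrum assigns no weight to any CDS substitution")
    return {c: totals[c] / grand for c in CODING_CATEGORIES}


def sample_neutral_substitutions(bundle: GenomeBundle,
                                 spectrum: dict[tuple[str, str], float],
                                 n: int, seed: int) -> dict[str, float]:
    """Monte-Carlo companion to :func:`neutral_expectation`: draw ``n``
    weighted substitutions and return observed category fractions."""
    import numpy as np

    sites = []
    weights = []
    models = [m for m in bundle.gene_models
              if m.feature_type == "protein_coding" and not m.degenerate and m.cds]
    for mi, model in enumerate(models):
        seq = bundle.chromosomes[model.chrom]
        for (s, e) in model.cds:
            for p0 in range(s, e):
                ref = seq[p0]
                for alt in "ACGT":
                    w = spectrum.get((ref, alt), 0.0)
                    if w > 0:
                        sites.append((mi, p0 + 1, alt))
                        weights.append(w)
    if not sites:
        raise ValueError("spectrum assigns no weight to any CDS substitution")
    rng = np.random.default_rng(seed)
    w = np.asarray(weights) / sum(weights)
    draws = rng.choice(len(sites), size=n, p=w)
    counts = {c: 0 for c in CODING_CATEGORIES}
    cache: dict[tuple[int, int, str], str] = {}
    for i in draws:
        mi, pos, alt = sites[int(i)]
        key = (mi, pos, alt)
        if key not in cache:
            cache[key], _ = classify_position_in_model(bundle, models[mi], pos, alt)
        counts[cache[key]] += 1
    return {c: counts[c] / n for c in CODING_CATEGORIES}
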