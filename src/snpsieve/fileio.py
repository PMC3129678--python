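"""Readers/writers for the pipeline's on-disk formats.

Formats: FASTA + GFF3 (reference and annotation), the tab-separated
call-table dialect (``#``-prefixed header: schema_id, genome_id, chrom,
pos, ref, alt, coverage, score, zygosity), BedGraph coverage (0-based
half-open), expression TSV (gene id + one column per hour), VCF 4.2
exports of consensus/partition sets, and a JSON ground-truth manifest
used as the test oracle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .models import (
    ConsensusSnp,
    EmsMutation,
    GenomeBundle,
    MutantGroundTruth,
    SnpCall,
)

CALL_TABLE_COLUMNS = ("schema_id", "genome_id", "chrom", "pos", "ref", "alt",
                      "coverage", "score", "zygosity")


class CallTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def write_fasta(bundle: GenomeBundle, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in bundle.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(bundle: GenomeBundle, path) -> None:
    """GFF3 with gene/mRNA/exon/CDS features; CDS rows carry phase."""
    lines = ["##gff-version 3"]
    for name, seq in bundle.chromosomes.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for model in sorted(bundle.gene_models, key=lambda m: (m.chrom, m.span[0], m.id)):
        s, e = model.span
        src = "snpsieve"
        if model.feature_type == "pseudogene":
            lines.append("\t".join([model.chrom, src, "pseudogene", str(s + 1),
                                    str(e), ".", model.strand, ".",
                                    f"ID={model.id}"]))
            for i, (xs, xe) in enumerate(model.exons, 1):
                lines.append("\t".join([model.chrom, src, "exon", str(xs + 1),
                                        str(xe), ".", model.strand, ".",
                                        f"ID={model.id}.exon{i};Parent={model.id}"]))
            continue
        lines.append("\t".join([model.chrom, src, "gene", str(s + 1), str(e),
                                ".", model.strand, ".", f"ID={model.gene_id}"]))
        lines.append("\t".join([model.chrom, src, "mRNA", str(s + 1), str(e),
                                ".", model.strand, ".",
                                f"ID={model.id};Parent={model.gene_id}"]))
        for i, (xs, xe) in enumerate(model.exons, 1):
            lines.append("\t".join([model.chrom, src, "exon", str(xs + 1),
                                    str(xe), ".", model.strand, ".",
                                    f"ID={model.id}.exon{i};Parent={model.id}"]))
        # phase: bases to skip before the first full codon of each segment,
        # accumulated in translation order
        segs = list(model.cds) if model.strand == "+" else list(reversed(model.cds))
        consumed = 0
        phases = {}
        for (cs, ce) in segs:
            phases[(cs, ce)] = (-consumed) % 3
            consumed += ce - cs
        for i, (cs, ce) in enumerate(model.cds, 1):
            lines.append("\t".join([model.chrom, src, "CDS", str(cs + 1),
                                    str(ce), ".", model.strand,
                                    str(phases[(cs, ce)]),
                                    f"ID={model.id}.cds{i};Parent={model.id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

def write_call_table(calls: list[SnpCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join([c.schema_id, c.genome_id, c.chrom, str(c.pos),
                                c.ref, c.alt, str(c.coverage),
                                repr(c.score), c.zygosity]) + "\n")


def read_call_table(path) -> list[SnpCall]:
    """Parse a call table; malformed rows raise with their line number."""
    calls: list[SnpCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.lstrip("#").split("\t") != list(CALL_TABLE_COLUMNS):
            raise CallTableError(f"{path}: line 1: header does not match "
                                 f"expected columns {CALL_TABLE_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(CALL_TABLE_COLUMNS):
                raise CallTableError(f"{path}: line {lineno}: expected "
                                     f"{len(CALL_TABLE_COLUMNS)} columns, got "
                                     f"{len(fields)}")
            try:
                call = SnpCall(
                    schema_id=fields[0], genome_id=fields[1], chrom=fields[2],
                    pos=int(fields[3]), ref=fields[4], alt=fields[5],
                    coverage=int(fields[6]), score=float(fields[7]),
                    zygosity=fields[8])
            except ValueError as exc:
                raise CallTableError(f"{path}: line {lineno}: {exc}") from exc
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# BedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track, path) -> None:
    with open(path, "w") as fh:
        for chrom, (starts, ends, depths) in track.runs.items():
            for s, e, d in zip(starts, ends, depths):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{int(d)}\n")


def read_bedgraph(path):
    from .filtering import CoverageTrack

    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, d = line.split()
            runs.setdefault(chrom, []).append((int(s), int(e), int(float(d))))
    arrays = {}
    for chrom, rows in runs.items():
        rows.sort()
        starts, ends, depths = (np.array(x) for x in zip(*rows))
        arrays[chrom] = (starts, ends, depths)
    return CoverageTrack(arrays)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(frame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(records: list[tuple[ConsensusSnp, str]], bundle_lengths: dict[str, int],
              path) -> None:
    """Write consensus SNPs as VCF 4.2 with CLASS/CONSENSUS_* INFO fields.

    ``records`` pairs each SNP with its partition class
    (shared|mutant_only|wildtype_only|excluded_low_coverage).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CONSENSUS_COV,Number=1,Type=Integer,Description='
        '"Minimum coverage across matching schemas">',
        '##INFO=<ID=CONSENSUS_SCORE,Number=1,Type=Float,Description='
        '"Minimum call score across matching schemas">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description='
        '"Uniqueness partition class">',
    ]
    for chrom, length in bundle_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for snp, klass in sorted(records, key=lambda rc: (rc[0].chrom, rc[0].pos)):
        info = (f"CONSENSUS_COV={snp.min_coverage};"
                f"CONSENSUS_SCORE={snp.min_score:.4f};CLASS={klass}")
        lines.append("\t".join([snp.chrom, str(snp.pos), ".", snp.ref, snp.alt,
                                ".", "PASS", info]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ground-truth manifest
# ---------------------------------------------------------------------------

def write_truth_manifest(truth: MutantGroundTruth, path) -> None:
    payload = {
        "accession_snps": sorted(list(s) for s in truth.accession_snps),
        "ems_mutations": sorted(
            [m.chrom, m.pos, m.ref, m.alt, m.strand_of_origin]
            for m in truth.ems_mutations),
        "causal": list(truth.causal),
        "retained_after_backcross": sorted(
            [m.chrom, m.pos, m.ref, m.alt, m.strand_of_origin]
            for m in truth.retained_after_backcross),
        "chromosome_strand_choice": truth.chromosome_strand_choice,
        "expression_classes": truth.expression_classes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth_manifest(path) -> MutantGroundTruth:
    payload = json.loads(Path(path).read_text())
    return MutantGroundTruth(
        accession_snps={tuple(s) for s in payload["accession_snps"]},
        ems_mutations={EmsMutation(*m) for m in payload["ems_mutations"]},
        causal=tuple(payload["causal"]),
        retained_after_backcross={EmsMutation(*m)
                                  for m in payload["retained_after_backcross"]},
        chromosome_strand_choice=payload["chromosome_strand_choice"],
        expression_classes=payload.get("expression_classes", {}),
    )
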