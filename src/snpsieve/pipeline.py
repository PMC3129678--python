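"""End-to-end orchestration: simulate -> filter -> annotate -> spectrum ->
rhythm -> report.

The run writes every stage's inputs and outputs in their declared on-disk
formats (FASTA/GFF3, call-table TSVs, BedGraph, expression TSVs, VCF) and
re-reads them between stages, so a run also exercises the format
round-trips. The final report mirrors the study design: accession-variation
and mutant-specific effect tables with apparent/actual counts, uniqueness
and callable-fraction accounting, spectrum/cluster summaries, tiered
candidates, and — because the inputs are simulated — a ground-truth
scorecard (precision/recall of mutant-specific SNP recovery, causal rank).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fileio
from .effects import EffectRecord, classify_snp, load_annotation, tabulate_effects
from .filtering import (
    FilterConfig,
    callable_fraction,
    filter_calls,
    intersect_schemas,
    partition_uniqueness,
)
from .rhythm import (
    build_model_waveforms,
    classify_rhythmic,
    rank_candidates,
    score_rhythmicity,
)
from .simulate import (
    MUTANT_GENOME,
    WILDTYPE_GENOME,
    SimulationConfig,
    generate_reference,
    simulate_call_tables,
    simulate_expression_matrix,
    simulate_mutant_line,
)
from .spectrum import detect_clusters, mutation_rate, strand_bias

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    rhythm_threshold: float = 0.85
    rhythm_mode: str = "all"
    cluster_max_gap_bp: int = 50_000  # 500 kb at genome scale, /10 at desk scale
    cluster_min_size: int = 2
    mapping_interval: tuple[str, int, int] | None = None

    def validate(self) -> None:
        if not self.filter.schemas:
            raise ValueError("schema list must be non-empty")
        missing = [s for s in self.filter.schemas
                   if s not in self.simulation.schema_params]
        if missing:
            raise ValueError(f"filter schemas {missing} not simulated")
        if not 0 < self.rhythm_threshold < 1:
            raise ValueError("rhythm_threshold must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_kw = raw.get("simulation", {})
        if "schema_params" in sim_kw:
            from .simulate import SchemaParams
            sim_kw["schema_params"] = {
                k: SchemaParams(**v) for k, v in sim_kw["schema_params"].items()}
        if "expression" in sim_kw:
            from .simulate import ExpressionParams
            expr = dict(sim_kw["expression"])
            if "timepoints" in expr:
                expr["timepoints"] = tuple(expr["timepoints"])
            sim_kw["expression"] = ExpressionParams(**expr)
        if "chrom_lengths" in sim_kw:
            sim_kw["chrom_lengths"] = tuple(sim_kw["chrom_lengths"])
        filt_kw = raw.get("filter", {})
        if "schemas" in filt_kw:
            filt_kw["schemas"] = tuple(filt_kw["schemas"])
        top = {k: v for k, v in raw.items() if k not in ("simulation", "filter")}
        if "mapping_interval" in top and top["mapping_interval"] is not None:
            top["mapping_interval"] = tuple(top["mapping_interval"])
        return cls(simulation=SimulationConfig(**sim_kw),
                   filter=FilterConfig(**filt_kw), **top)


@dataclass
class RunReport:
    seed: int
    uniqueness_counts: dict
    callable_fractions: dict
    accession_effect_table: dict
    mutant_effect_table: dict
    spectrum: dict
    clusters: dict
    candidates: list
    scorecard: dict

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _effect_table_payload(table) -> dict:
    return {
        "per_chromosome": {c: {cat: int(table.counts.loc[c, cat])
                               for cat in table.counts.columns}
                           for c in table.counts.index},
        "apparent_per_chrom": {c: int(v) for c, v in table.apparent_per_chrom.items()},
        "actual_per_chrom": {c: int(v) for c, v in table.actual_per_chrom.items()},
        "apparent_total": table.apparent_total,
        "actual_total": table.actual_total,
    }


def run_pipeline(config: PipelineConfig, seed: int, outdir) -> RunReport:
    """Run every stage on a fresh simulation; returns the rendered report.

    Deterministic for a fixed (config, seed): rerunning yields a
    hash-identical report.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation.replace(seed=seed)

    # ---- stage: simulate -------------------------------------------------
    logger.info("stage simulate: generating reference and mutant line")
    genome = generate_reference(sim)
    truth = simulate_mutant_line(genome, sim)
    fileio.write_fasta(genome, outdir / "reference.fasta")
    fileio.write_gff3(genome, outdir / "annotation.gff3")
    line_variants = {
        WILDTYPE_GENOME: set(truth.accession_snps),
        MUTANT_GENOME: set(truth.accession_snps) | {m.key for m in
                                                    truth.retained_after_backcross},
    }
    calls, tracks = simulate_call_tables(genome, line_variants, sim,
                                         seed=seed + 10_000)
    for (genome_id, schema_id), table in calls.items():
        fileio.write_call_table(table, outdir / f"calls_{genome_id}_{schema_id}.tsv")
    for (genome_id, schema_id), track in tracks.items():
        fileio.write_bedgraph(track, outdir / f"coverage_{genome_id}_{schema_id}.bedgraph")

    gene_ids = sorted({m.gene_id for m in genome.gene_models})
    causal_gene = truth.causal[2]
    forced = {causal_gene: "rhythmic_dd_only"}
    decoys = [g for g in gene_ids if g != causal_gene]
    if decoys:
        forced[decoys[0]] = "rhythmic_all"
    frames, classes, _shapes = simulate_expression_matrix(
        gene_ids, sim, truth_assignment=forced, seed=seed + 20_000)
    truth.expression_classes = classes
    for ds, frame in frames.items():
        fileio.write_expression_tsv(frame, outdir / f"expression_{ds}.tsv")
    fileio.write_truth_manifest(truth, outdir / "truth.json")

    # ---- stage: filter ---------------------------------------------------
    logger.info("stage filter: per-schema filtering and intersection")
    loaded_calls = {key: fileio.read_call_table(outdir / f"calls_{key[0]}_{key[1]}.tsv")
                    for key in calls}
    loaded_tracks = {key: fileio.read_bedgraph(
        outdir / f"coverage_{key[0]}_{key[1]}.bedgraph") for key in tracks}
    consensus = {}
    for genome_id, other_id in ((MUTANT_GENOME, WILDTYPE_GENOME),
                                (WILDTYPE_GENOME, MUTANT_GENOME)):
        per_schema = {}
        for schema in config.filter.schemas:
            per_schema[schema] = filter_calls(
                loaded_calls[(genome_id, schema)],
                loaded_tracks[(genome_id, schema)],
                loaded_tracks[(other_id, schema)],
                config.filter)
        consensus[genome_id] = intersect_schemas(per_schema, config.filter)
    mut_tracks = {s: loaded_tracks[(MUTANT_GENOME, s)] for s in config.filter.schemas}
    wt_tracks = {s: loaded_tracks[(WILDTYPE_GENOME, s)] for s in config.filter.schemas}
    partition = partition_uniqueness(consensus[MUTANT_GENOME],
                                     consensus[WILDTYPE_GENOME],
                                     mut_tracks, wt_tracks, config.filter)
    chrom_lengths = {c: len(s) for c, s in genome.chromosomes.items()}
    fractions = callable_fraction(loaded_tracks, chrom_lengths, config.filter)
    vcf_records = ([(c, "shared") for c in partition.shared]
                   + [(c, "mutant_only") for c in partition.mutant_only]
                   + [(c, "wildtype_only") for c in partition.wildtype_only]
                   + [(c, "excluded_low_coverage")
                      for c in partition.excluded_low_coverage])
    fileio.write_vcf(vcf_records, chrom_lengths, outdir / "partition.vcf")

    # ---- stage: annotate -------------------------------------------------
    logger.info("stage annotate: consequence classification")
    bundle = load_annotation(outdir / "reference.fasta", outdir / "annotation.gff3")
    accession_records: list[EffectRecord] = []
    for snp in partition.shared + partition.wildtype_only:
        accession_records.extend(
            classify_snp((snp.chrom, snp.pos, snp.ref, snp.alt), bundle))
    mutant_records: list[EffectRecord] = []
    for snp in partition.mutant_only:
        mutant_records.extend(
            classify_snp((snp.chrom, snp.pos, snp.ref, snp.alt), bundle))
    accession_table = tabulate_effects(accession_records) if accession_records else None
    mutant_table = tabulate_effects(mutant_records) if mutant_records else None

    # ---- stage: spectrum -------------------------------------------------
    logger.info("stage spectrum: EMS signature statistics")
    mutant_snps = [(c.chrom, c.pos, c.ref, c.alt) for c in partition.mutant_only]
    per_chrom_bias = {}
    for chrom, length in chrom_lengths.items():
        try:
            res = strand_bias(mutant_snps, (chrom, 0, length))
        except ValueError:
            continue
        per_chrom_bias[chrom] = {
            "n_c_to_t": res.n_c_to_t, "n_g_to_a": res.n_g_to_a,
            "n_other": res.n_other, "fraction_c_to_t": res.fraction_c_to_t,
            "p_value": res.p_value}
    cluster_report = detect_clusters(
        mutant_snps, chrom_lengths, config.cluster_max_gap_bp,
        config.cluster_min_size) if mutant_snps else None
    causal_chrom = truth.causal[0]
    causal_chrom_snps = [s for s in mutant_snps if s[0] == causal_chrom]
    rate = mutation_rate(len(causal_chrom_snps), chrom_lengths[causal_chrom])

    # ---- stage: rhythm ---------------------------------------------------
    logger.info("stage rhythm: expression screening and candidate ranking")
    expr = {ds: fileio.read_expression_tsv(outdir / f"expression_{ds}.tsv")
            for ds in sim.expression.datasets}
    scores_per_ds = {}
    for ds, frame in expr.items():
        t = [float(c) for c in frame.columns]
        bank = build_model_waveforms(t, period=sim.expression.period)
        scores_per_ds[ds] = {gid: score_rhythmicity(t, row.values, bank)
                             for gid, row in frame.iterrows()}
    rhythmicity = classify_rhythmic(scores_per_ds, config.rhythm_threshold,
                                    config.rhythm_mode)
    candidates = rank_candidates(partition.mutant_only_keys, mutant_records,
                                 rhythmicity, config.mapping_interval)

    # ---- scorecard -------------------------------------------------------
    found = partition.mutant_only_keys
    true_keys = {(m.chrom, m.pos, m.alt) for m in truth.retained_after_backcross}
    tp = len(found & true_keys)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(true_keys) if true_keys else 0.0
    causal_key = (truth.causal[0], truth.causal[1])
    causal_recovered = any((k[0], k[1]) == causal_key for k in found)
    causal_rank = next((i + 1 for i, c in enumerate(candidates)
                        if c.gene_id == causal_gene), None)

    report = RunReport(
        seed=seed,
        uniqueness_counts={
            "shared": len(partition.shared),
            "mutant_only": len(partition.mutant_only),
            "wildtype_only": len(partition.wildtype_only),
            "excluded_low_coverage": len(partition.excluded_low_coverage)},
        callable_fractions={
            "no_reads": round(fractions[0], 6),
            "reads_but_uninterrogated": round(fractions[1], 6),
            "interrogated": round(fractions[2], 6)},
        accession_effect_table=(_effect_table_payload(accession_table)
                                if accession_table else {}),
        mutant_effect_table=(_effect_table_payload(mutant_table)
                             if mutant_table else {}),
        spectrum={
            "per_chromosome_strand_bias": per_chrom_bias,
            "causal_chromosome": causal_chrom,
            "causal_chromosome_rate_per_kb": round(rate.rate_per_kb, 6),
            "causal_chromosome_one_per_kb": rate.one_per_kb},
        clusters={
            "clusters": [list(c) for c in cluster_report.clusters],
            "homogeneity_p": cluster_report.homogeneity_p} if cluster_report else {},
        candidates=[{
            "gene_id": c.gene_id, "tier": c.tier, "max_r": round(c.max_r, 4),
            "snps": [list(s) for s in c.snps],
            "per_dataset": [[ds, round(r, 4), shape, phase]
                            for ds, r, shape, phase in c.per_dataset]}
            for c in candidates],
        scorecard={
            "precision": round(precision, 4),
            "recall": round(recall, 4),
            "n_true_retained": len(true_keys),
            "n_reported": len(found),
            "causal_gene": causal_gene,
            "causal_recovered": causal_recovered,
            "causal_candidate_rank": causal_rank},
    )
    render_report(report, outdir)
    return report


def render_report(report: RunReport, outdir) -> None:
    """Write the report as JSON plus TSV effect tables."""
    outdir = Path(outdir)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    for name, payload in (("accession", report.accession_effect_table),
                          ("mutant", report.mutant_effect_table)):
        if not payload:
            continue
        lines = ["chromosome\t" + "\t".join(
            sorted(next(iter(payload["per_chromosome"].values()))))
            + "\tapparent\tactual"]
        for chrom in sorted(payload["per_chromosome"]):
            cats = payload["per_chromosome"][chrom]
            apparent = payload["apparent_per_chrom"][chrom]
            actual = payload["actual_per_chrom"][chrom]
            if actual > apparent:
                raise AssertionError("actual > apparent in report rendering")
            lines.append(chrom + "\t" + "\t".join(
                str(cats[c]) for c in sorted(cats)) + f"\t{apparent}\t{actual}")
        lines.append("total\t" + "\t".join(
            str(sum(payload["per_chromosome"][ch][c]
                    for ch in payload["per_chromosome"]))
            for c in sorted(next(iter(payload["per_chromosome"].values()))))
            + f"\t{payload['apparent_total']}\t{payload['actual_total']}")
        (outdir / f"effect_table_{name}.tsv").write_text("\n".join(lines) + "\n")
    cand_lines = ["gene_id\ttier\tmax_r\tsnps\tper_dataset"]
    for c in report.candidates:
        snps = ";".join(f"{s[0]}:{s[1]}{s[2]}>{s[3]}({s[4]})" for s in c["snps"])
        per = ";".join(f"{ds}:r={r},{shape},{phase}" for ds, r, shape, phase
                       in c["per_dataset"])
        cand_lines.append(f"{c['gene_id']}\t{c['tier']}\t{c['max_r']}\t{snps}\t{per}")
    (outdir / "candidates.tsv").write_text("\n".join(cand_lines) + "\n")
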