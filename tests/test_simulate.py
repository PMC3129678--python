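"""Generator behaviour: determinism, configured rates, EMS constraints,
backcross genetics and expression ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from snpsieve import fileio
from snpsieve.models import EmsMutation, MutantGroundTruth
from snpsieve.simulate import (
    PackingError,
    SimulationConfig,
    generate_reference,
    haldane_recombination,
    simulate_accession_snps,
    simulate_backcross,
    simulate_call_tables,
    simulate_ems_mutations,
    simulate_expression_matrix,
    simulate_mutant_line,
)


class TestGenerateReference:
    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(SimulationConfig(chrom_lengths=(0,)))
        with pytest.raises(ValueError):
            generate_reference(SimulationConfig(chrom_lengths=()))

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_reference(SimulationConfig(chrom_lengths=(5_000,),
                                                gene_density=5.0))

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=4, chrom_lengths=(50_000, 50_000))
        paths = []
        for run in ("a", "b"):
            bundle = generate_reference(cfg)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            fileio.write_fasta(bundle, fa)
            fileio.write_gff3(bundle, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_gene_count_in_poisson_interval(self):
        # density 0.05/kb on 200 kb -> Poisson(10); 99% interval from scipy
        cfg = SimulationConfig(seed=2, chrom_lengths=(200_000,), gene_density=0.05)
        bundle = generate_reference(cfg)
        lo, hi = stats.poisson.interval(0.99, 10)
        assert lo <= len(bundle.gene_models) <= hi

    def test_cds_is_atg_to_stop_multiple_of_three(self, genome):
        from snpsieve.effects import _cds_sequence

        for model in genome.gene_models:
            if model.feature_type != "protein_coding":
                continue
            cds = _cds_sequence(genome, model)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in {"TAA", "TAG", "TGA"}

    def test_repeat_mask_emitted_and_disjoint_from_cds(self, genome):
        assert genome.repeat_mask
        covered = sum(e - s for _, s, e in genome.repeat_mask)
        assert covered > 0.02 * genome.total_length
        for chrom, rs, re_ in genome.repeat_mask:
            for model in genome.models_on(chrom):
                for cs, ce in model.cds:
                    assert re_ <= cs or ce <= rs

    def test_some_genes_overlap(self, genome):
        overlapping = 0
        for chrom in genome.chromosomes:
            spans = sorted(m.span for m in genome.models_on(chrom))
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    overlapping += 1
        assert overlapping > 0


class TestAccessionSnps:
    def test_rate_zero_empty(self, genome):
        assert simulate_accession_snps(genome, 0.0, seed=1) == set()

    def test_ref_matches_genome_and_alt_differs(self, genome):
        snps = simulate_accession_snps(genome, 0.5, seed=3)
        for chrom, pos, ref, alt in snps:
            assert genome.base(chrom, pos) == ref
            assert alt != ref

    def test_mean_count_matches_rate(self):
        # 1.2/kb on 500 kb -> mean 600; check the empirical mean over many
        # seeds against 3 SE of the Poisson expectation
        cfg = SimulationConfig(seed=9, chrom_lengths=(500_000,), gene_density=0.01)
        bundle = generate_reference(cfg)
        n_rep = 60
        counts = [len(simulate_accession_snps(bundle, 1.2, seed=s))
                  for s in range(n_rep)]
        se = np.sqrt(600 / n_rep)
        assert abs(np.mean(counts) - 600) < 3 * se

    def test_spectrum_covers_all_twelve_substitutions(self, genome):
        snps = simulate_accession_snps(genome, 1.2, seed=5)
        kinds = {(r, a) for _, _, r, a in snps}
        assert len(kinds) == 12


class TestEmsMutations:
    def test_rate_zero_empty(self, genome):
        muts, _ = simulate_ems_mutations(genome, 0.0, seed=1)
        assert muts == set()

    def test_pure_strand_limit_per_chromosome(self, genome):
        muts, strand_choice = simulate_ems_mutations(genome, 0.2, seed=7)
        for m in muts:
            if strand_choice[m.chrom] == "+":
                assert (m.ref, m.alt) == ("C", "T")
            else:
                assert (m.ref, m.alt) == ("G", "A")
            assert genome.base(m.chrom, m.pos) == m.ref

    def test_count_in_poisson_interval(self):
        # 1/100 kb on 1 Mb -> Poisson(10)
        cfg = SimulationConfig(seed=13, chrom_lengths=(1_000_000,),
                               gene_density=0.005)
        bundle = generate_reference(cfg)
        muts, _ = simulate_ems_mutations(bundle, 0.01, seed=21)
        lo, hi = stats.poisson.interval(0.99, 10)
        assert lo <= len(muts) <= hi

    def test_disjoint_from_excluded_positions(self, genome):
        snps = simulate_accession_snps(genome, 1.2, seed=31)
        exclude = {(c, p) for c, p, _, _ in snps}
        muts, _ = simulate_ems_mutations(genome, 0.2, seed=32,
                                         exclude_positions=exclude)
        assert not ({(m.chrom, m.pos) for m in muts} & exclude)


def _toy_truth(genome, mutations, causal):
    return MutantGroundTruth(
        accession_snps=set(),
        ems_mutations=set(mutations),
        causal=causal,
        retained_after_backcross={m for m in mutations
                                  if (m.chrom, m.pos) == causal[:2]},
        chromosome_strand_choice={})


class TestBackcross:
    def test_negative_generations_rejected(self, genome):
        causal_mut = EmsMutation("chr1", 100, "C", "T", "+")
        truth = _toy_truth(genome, [causal_mut], ("chr1", 100, "G1"))
        with pytest.raises(ValueError):
            simulate_backcross(truth, genome, -1, 4.0, seed=1)

    def test_causal_always_retained(self, genome):
        causal_mut = EmsMutation("chr1", 100, "C", "T", "+")
        truth = _toy_truth(genome, [causal_mut], ("chr1", 100, "G1"))
        for seed in range(20):
            assert causal_mut in simulate_backcross(truth, genome, 4, 4.0, seed)

    def test_unlinked_retention_matches_closed_form(self, genome):
        # unlinked locus through 4 backcrosses + selfing: (1/2)^5 = 0.03125
        causal_mut = EmsMutation("chr1", 100, "C", "T", "+")
        other = EmsMutation("chr2", 5_000, "C", "T", "+")
        truth = _toy_truth(genome, [causal_mut, other], ("chr1", 100, "G1"))
        n_rep = 10_000
        kept = sum(other in simulate_backcross(truth, genome, 4, 4.0, seed)
                   for seed in range(n_rep))
        p = 0.5 ** 5
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(kept / n_rep - p) < 3 * se

    def test_fully_linked_retention_is_one(self, genome):
        causal_mut = EmsMutation("chr1", 100, "C", "T", "+")
        linked = EmsMutation("chr1", 101, "C", "T", "+")  # d ~ 0
        truth = _toy_truth(genome, [causal_mut, linked], ("chr1", 100, "G1"))
        for seed in range(50):
            assert linked in simulate_backcross(truth, genome, 4, 4.0, seed)

    def test_haldane_limits(self):
        assert haldane_recombination(0.0) == 0.0
        assert haldane_recombination(50.0) == pytest.approx(0.5)

    def test_hitchhiking_cluster_near_causal(self, genome, truth):
        # retained mutations sit closer (in concatenated-genome coordinates)
        # to the causal locus than the full EMS set: rank-sum at alpha=0.01
        offsets = {}
        acc = 0
        for chrom, seq in genome.chromosomes.items():
            offsets[chrom] = acc
            acc += len(seq)
        causal_gpos = offsets[truth.causal[0]] + truth.causal[1]

        def dist(m):
            return abs(offsets[m.chrom] + m.pos - causal_gpos)

        retained = [dist(m) for m in truth.retained_after_backcross]
        full = [dist(m) for m in truth.ems_mutations]
        stat = stats.mannwhitneyu(retained, full, alternative="less")
        assert stat.pvalue < 0.01


class TestCallTables:
    def test_unknown_schema_rejected(self, genome, default_config):
        with pytest.raises(KeyError):
            simulate_call_tables(genome, {"mutant": set()}, default_config,
                                 seed=1, schemas=["99_9"])

    def test_variant_outside_genome_rejected(self, genome, default_config):
        bad = {("chr1", 10**9, "C", "T")}
        with pytest.raises(ValueError):
            simulate_call_tables(genome, {"mutant": bad}, default_config, seed=1)

    def test_noiseless_limit_calls_equal_truth(self, genome, default_config):
        cfg = default_config.replace(fp_rate=0.0, coverage_noise=False,
                                     score_noise=False)
        variants = {"mutant": {("chr1", 500, genome.base("chr1", 500),
                                "A" if genome.base("chr1", 500) != "A" else "G"),
                               ("chr2", 900, genome.base("chr2", 900),
                                "A" if genome.base("chr2", 900) != "A" else "G")}}
        calls, _ = simulate_call_tables(genome, variants, cfg, seed=1)
        for (gid, sid), table in calls.items():
            got = {(c.chrom, c.pos, c.ref, c.alt) for c in table}
            assert got == variants["mutant"]
            assert all(c.zygosity == "hom" for c in table)

    def test_mean_coverage_ordering_across_schemas(self, genome, default_config):
        calls, tracks = simulate_call_tables(
            genome, {"mutant": set()}, default_config, seed=3)
        means = []
        for sid, params in default_config.schema_params.items():
            track = tracks[("mutant", sid)]
            depths = np.concatenate([d for _, _, d in track.runs.values()])
            means.append(depths.mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_false_calls_mostly_heterozygous_true_calls_homozygous(
            self, genome, truth, default_config):
        variants = {"mutant": set(truth.accession_snps)}
        calls, _ = simulate_call_tables(genome, variants, default_config, seed=5)
        true_pos = {(c, p) for c, p, _, _ in truth.accession_snps}
        n_fp = n_fp_het = 0
        for table in calls.values():
            for c in table:
                if (c.chrom, c.pos) in true_pos:
                    assert c.zygosity == "hom"
                else:
                    n_fp += 1
                    n_fp_het += c.zygosity == "het"
        assert n_fp > 0
        assert n_fp_het / n_fp > 0.5

    def test_false_calls_confined_to_repeat_mask(self, genome, truth,
                                                 default_config):
        calls, _ = simulate_call_tables(
            genome, {"mutant": set(truth.accession_snps)}, default_config, seed=5)
        true_pos = {(c, p) for c, p, _, _ in truth.accession_snps}
        repeats = {c: [(s, e) for cc, s, e in genome.repeat_mask if cc == c]
                   for c in genome.chromosomes}
        for table in calls.values():
            for c in table:
                if (c.chrom, c.pos) not in true_pos:
                    assert any(s <= c.pos - 1 < e for s, e in repeats[c.chrom])


class TestExpression:
    def test_noiseless_rhythmic_gene_is_its_waveform(self, default_config):
        from snpsieve.rhythm import waveform_values

        cfg = default_config.replace(expression=dataclasses.replace(
            default_config.expression, noise_sd=0.0))
        frames, classes, shapes = simulate_expression_matrix(
            ["g1", "g2"], cfg, {"g1": "rhythmic_all", "g2": "arrhythmic"}, seed=2)
        t = np.asarray(cfg.expression.timepoints)
        shape, phase = shapes["g1"]
        expected = (cfg.expression.baseline + cfg.expression.amplitude
                    * waveform_values(shape, phase, t, cfg.expression.period))
        for ds, frame in frames.items():
            np.testing.assert_allclose(frame.loc["g1"].values, expected)
            np.testing.assert_allclose(frame.loc["g2"].values,
                                       cfg.expression.baseline)

    def test_dd_only_gene_flat_in_light_datasets(self, default_config):
        cfg = default_config.replace(expression=dataclasses.replace(
            default_config.expression, noise_sd=0.0))
        frames, _, _ = simulate_expression_matrix(
            ["g"], cfg, {"g": "rhythmic_dd_only"}, seed=3)
        assert frames["LL1"].loc["g"].std() == 0.0
        assert frames["DD"].loc["g"].std() > 0.0

    def test_class_assignment_recorded_for_oracles(self, default_config):
        genes = [f"g{i}" for i in range(200)]
        _, classes, _ = simulate_expression_matrix(genes, default_config, None,
                                                   seed=4)
        assert set(classes) == set(genes)
        assert set(classes.values()) <= {"rhythmic_all", "rhythmic_dd_only",
                                         "arrhythmic"}


class TestGroundTruthInvariants:
    def test_full_truth_invariants(self, genome, truth):
        assert truth.retained_after_backcross <= truth.ems_mutations
        causal_chrom, causal_pos, _ = truth.causal
        assert any(m.chrom == causal_chrom and m.pos == causal_pos
                   for m in truth.retained_after_backcross)
        acc_pos = {(c, p) for c, p, _, _ in truth.accession_snps}
        assert not ({(m.chrom, m.pos) for m in truth.ems_mutations} & acc_pos)
        for m in truth.ems_mutations:
            assert m.strand_of_origin == truth.chromosome_strand_choice[m.chrom]

    def test_truth_manifest_round_trip(self, truth, tmp_path):
        path = tmp_path / "truth.json"
        fileio.write_truth_manifest(truth, path)
        loaded = fileio.read_truth_manifest(path)
        assert loaded.accession_snps == truth.accession_snps
        assert loaded.ems_mutations == truth.ems_mutations
        assert loaded.retained_after_backcross == truth.retained_after_backcross
        assert loaded.causal == truth.causal
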