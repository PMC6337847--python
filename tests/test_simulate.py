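import json
import math

import numpy as np
import pytest

from snipchip import (
    ExactIndex,
    SimConfig,
    assign_reads,
    build_hybrid_reference,
    call_peaks_naive,
    derive_snp_map,
    expected_values,
    pileup_from_assignment,
    simulate_binding_profile,
    simulate_genome_pair,
    simulate_reads,
    write_fixture,
)
from snipchip.normalize import CHIP, INPUT, SampleCounts, compute_Nf, compute_Q
from snipchip.snpmap import SPIKE, TEST


class TestGenomePair:
    def test_zero_divergence_identical(self):
        config = SimConfig(seed=2, n_chromosomes=1, chrom_length=5000, divergence=0.0)
        test, spike, snpmap = simulate_genome_pair(config)
        assert test.chromosomes[0][1] == spike.chromosomes[0][1]
        assert len(snpmap) == 0

    def test_divergence_cap_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(divergence=0.2)

    def test_truth_matches_positionwise_derivation(self):
        config = SimConfig(seed=2, n_chromosomes=2, chrom_length=5000, divergence=0.01)
        test, spike, truth = simulate_genome_pair(config)
        derived = derive_snp_map(test, spike)
        assert derived.records == truth.records

    def test_binomial_snp_count(self):
        # L=1 Mb, d=0.007: counts within 4 binomial SD over 10 seeds
        length, d = 1_000_000, 0.007
        sd = math.sqrt(length * d * (1 - d))
        for seed in range(10):
            config = SimConfig(
                seed=seed, n_chromosomes=1, chrom_length=length, divergence=d
            )
            _t, _s, snpmap = simulate_genome_pair(config)
            assert abs(len(snpmap) - length * d) <= 4 * sd

    def test_determinism(self):
        config = SimConfig(seed=6, n_chromosomes=1, chrom_length=2000, divergence=0.01)
        a = simulate_genome_pair(config)
        b = simulate_genome_pair(config)
        assert a[0].chromosomes == b[0].chromosomes
        assert a[1].chromosomes == b[1].chromosomes


class TestBindingProfile:
    def _genome(self, length=1000):
        config = SimConfig(seed=3, n_chromosomes=1, chrom_length=length, divergence=0.0)
        return simulate_genome_pair(config)[0]

    def test_no_peaks_uniform(self):
        profile, peaks = simulate_binding_profile(self._genome(), 0, 100, 10.0, seed=1)
        assert profile.total_weight == 1000
        assert len(peaks) == 0

    def test_single_peak_weight_arithmetic(self):
        profile, peaks = simulate_binding_profile(self._genome(), 1, 100, 10.0, seed=1)
        # 900 background + 100 * 10 inside the peak
        assert profile.total_weight == 900 + 1000
        assert peaks.total_span == 100

    def test_background_fraction_rescaling(self):
        profile, _ = simulate_binding_profile(
            self._genome(), 1, 100, 10.0, background_fraction=0.5, seed=1
        )
        w = profile.per_chromosome["chrI"]
        assert w[w == 1].sum() == pytest.approx(0.5 * profile.total_weight)

    def test_nonoverlapping_peaks(self):
        profile, peaks = simulate_binding_profile(self._genome(5000), 12, 300, 5.0, seed=4)
        ivals = sorted((s, e) for _c, s, e, _n, _sc in peaks.intervals)
        assert all(e1 <= s2 for (_s1, e1), (s2, _e2) in zip(ivals, ivals[1:]))

    def test_infeasible_placement_errors(self):
        with pytest.raises((RuntimeError, ValueError)):
            simulate_binding_profile(self._genome(), 9, 100, 5.0, seed=1, max_tries=30)

    def test_peaks_recovered_by_naive_caller(self):
        # higher divergence keeps SNP-free coverage gaps from fragmenting
        # the called peaks
        config = SimConfig(
            seed=13, n_chromosomes=2, chrom_length=10_000, divergence=0.03,
            n_peaks=2, peak_width=500, enrichment_fold=10.0, n_reads=60_000,
        )
        test, spike, _snpmap = simulate_genome_pair(config)
        index = ExactIndex(build_hybrid_reference(test, spike), 100)
        chip_reads, truth = simulate_reads(config, "wt", "ChIP")
        input_reads, _ = simulate_reads(config, "wt", "Input")
        chip = pileup_from_assignment(assign_reads(chip_reads, index), 100, TEST)
        inp = pileup_from_assignment(assign_reads(input_reads, index), 100, TEST)
        called = call_peaks_naive(chip, inp, fold=4, min_width=100)
        # every true peak reciprocally overlaps a called peak by >= 80%
        for chrom, start, end, _n, _s in truth.peaks.intervals:
            overlaps = [
                (min(end, ce) - max(start, cs))
                for cc, cs, ce, _cn, _csc in called.intervals
                if cc == chrom and min(end, ce) > max(start, cs)
            ]
            assert overlaps, f"true peak {chrom}:{start}-{end} missed"
            best = max(overlaps)
            assert best >= 0.8 * (end - start)


class TestSimulateReads:
    def test_input_symmetry_at_half(self, small_index):
        config = SimConfig(
            seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01,
            spike_fraction=0.5, n_reads=20_000,
        )
        reads, _ = simulate_reads(config, "wt", "Input")
        spike_frac = sum(r.truth_origin == SPIKE for r in reads) / len(reads)
        se = math.sqrt(0.25 / len(reads))
        assert abs(spike_frac - 0.5) <= 4 * se

    def test_equal_abundance_nf_one(self, small_index):
        config = SimConfig(
            seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01, n_reads=30_000
        )
        qs = {}
        for role in (INPUT, CHIP):
            reads, _ = simulate_reads(config, "wt", "ChIP" if role == CHIP else "Input")
            res = assign_reads(reads, small_index)
            qs[role] = compute_Q(SampleCounts(role, res.C_endo, res.C_spike))
        nf = compute_Nf(qs[INPUT], qs[CHIP])
        assert nf.value == pytest.approx(1.0, rel=0.05)

    def test_closed_form_quarter_abundance(self):
        config = SimConfig(
            seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01,
            abundance=(("mut", 0.25),), n_reads=1,
        )
        expect = expected_values(config, "mut")
        assert expect == {"Q_input": 0.25, "Q_chip": 1.0, "Nf": 0.25}

    def test_expected_values_trivial_cases(self):
        config = SimConfig(seed=1, abundance=(("wt", 1.0), ("half", 0.5)), n_reads=1)
        assert expected_values(config, "wt") == {"Q_input": 0.25, "Q_chip": 0.25, "Nf": 1.0}
        assert expected_values(config, "half")["Nf"] == pytest.approx(0.5)

    def test_unknown_condition_errors(self):
        config = SimConfig(seed=1, n_reads=1)
        with pytest.raises(KeyError):
            simulate_reads(config, "nope", "ChIP")

    def test_error_rate_reduces_assignable(self, small_index):
        base = SimConfig(
            seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01, n_reads=5000
        )
        clean, _ = simulate_reads(base, "wt", "Input")
        noisy, _ = simulate_reads(base.with_(error_rate=0.02), "wt", "Input")
        res_clean = assign_reads(clean, small_index)
        res_noisy = assign_reads(noisy, small_index)
        assert res_noisy.n_unmapped > res_clean.n_unmapped
        # an error converting a read's only SNP base to the other allele can
        # legitimately cross genomes, but it should stay rare
        assigned = [
            (read, call)
            for read, call in zip(noisy, res_noisy.calls)
            if call in (TEST, SPIKE)
        ]
        mis = sum(1 for read, call in assigned if call != read.truth_origin)
        assert mis / max(len(assigned), 1) < 0.02

    def test_stream_independence_across_conditions(self):
        base = SimConfig(
            seed=11, n_chromosomes=1, chrom_length=5000, divergence=0.01,
            abundance=(("wt", 1.0),), n_reads=500,
        )
        more = base.with_(abundance=(("wt", 1.0), ("mut", 0.25)))
        a, _ = simulate_reads(base, "wt", "ChIP")
        b, _ = simulate_reads(more, "wt", "ChIP")
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestEndToEndRecovery:
    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0])
    def test_parameter_recovery_small(self, ratio, small_index):
        config = SimConfig(
            seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01,
            n_reads=30_000, abundance=(("wt", 1.0), ("mut", ratio)),
        )
        nf = {}
        for cond in ("wt", "mut"):
            qv = {}
            for role in (INPUT, CHIP):
                reads, _ = simulate_reads(config, cond, "ChIP" if role == CHIP else "Input")
                res = assign_reads(reads, small_index)
                qv[role] = compute_Q(SampleCounts(role, res.C_endo, res.C_spike))
            nf[cond] = compute_Nf(qv[INPUT], qv[CHIP], cond).value
        assert nf["mut"] / nf["wt"] == pytest.approx(ratio, rel=0.10)

    def test_low_divergence_stability(self):
        # ~0.01% divergence over a 12 Mb pair (~1200 SNPs) still recovers a
        # 4-fold abundance difference
        config = SimConfig(
            seed=19, n_chromosomes=2, chrom_length=6_000_000, divergence=1e-4,
            n_reads=1_000_000, abundance=(("wt", 1.0), ("mut", 0.25)),
        )
        from snipchip.simulate import _experiment_parts

        test, spike, *_ = _experiment_parts(config)
        index = ExactIndex(build_hybrid_reference(test, spike), config.read_length)
        nf = {}
        for cond in ("wt", "mut"):
            qv = {}
            for role in (INPUT, CHIP):
                reads, _ = simulate_reads(config, cond, "ChIP" if role == CHIP else "Input")
                res = assign_reads(reads, index)
                qv[role] = compute_Q(SampleCounts(role, float(res.C_endo), float(res.C_spike)))
                del reads, res
            nf[cond] = compute_Nf(qv[INPUT], qv[CHIP], cond).value
        assert nf["mut"] / nf["wt"] == pytest.approx(0.25, rel=0.15)


class TestWriteFixture:
    def _config(self):
        return SimConfig(
            seed=8, n_chromosomes=1, chrom_length=3000, divergence=0.01,
            n_reads=200, abundance=(("wt", 1.0),),
        )

    def test_fixture_complete(self, tmp_path):
        manifest = write_fixture(self._config(), str(tmp_path / "fix"))
        files = manifest["files"]
        for key in ("test_fasta", "spike_fasta", "hybrid_fasta", "truth_json"):
            assert (tmp_path / "fix").joinpath(files[key].split("/")[-1]).exists()
        truth = json.loads((tmp_path / "fix" / "truth.json").read_text())
        assert truth["spike_fraction"] == 0.2
        assert truth["expected"]["wt"]["Nf"] == 1.0

    def test_regeneration_byte_identical(self, tmp_path):
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_fixture(self._config(), str(dir_a))
        write_fixture(self._config(), str(dir_b))
        for path_a in sorted(dir_a.iterdir()):
            path_b = dir_b / path_a.name
            if path_a.suffix == ".json":
                a = json.loads(path_a.read_text())
                b = json.loads(path_b.read_text())
                a.pop("files", None), b.pop("files", None)  # manifest holds paths
                assert a == b
            else:
                assert path_a.read_bytes() == path_b.read_bytes()

    def test_fastq_reads_classify_cleanly(self, tmp_path):
        from snipchip.classify import read_fastq
        from snipchip.snpmap import genome_from_fasta

        out = tmp_path / "fix"
        manifest = write_fixture(self._config(), str(out))
        test = genome_from_fasta(str(out / "test.fa"), "testg")
        spike = genome_from_fasta(str(out / "spike.fa"), "spikeg")
        index = ExactIndex(build_hybrid_reference(test, spike), 100)
        reads = read_fastq(manifest["files"]["fastq"]["wt_Input"])
        result = assign_reads(reads, index)
        assert result.n_unmapped == 0
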