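"""Synthetic spike-in ChIP experiments with known ground truth.

Generates colinear genome pairs differing only by point substitutions,
peaked binding profiles, and error-free (optionally errored) single-end
read sets for ChIP and input samples of mixed test/spike-in cell
populations.  Every sampling step has a closed-form expectation
(:func:`expected_values`) so each estimator in the pipeline can be tested
against analytic truth.

Sampling model
--------------
A cell fraction ``s`` of the mixture is spike-in.  For the input sample a
read originates from the spike-in genome with probability
``s*L_spike / (s*L_spike + (1-s)*L_test)`` and its position is uniform.
For the ChIP sample the genome probability also weighs each population's
per-cell target abundance ``A`` and bound-chromatin weight ``W``:
``P(spike) = s*A_spike*W_spike / (s*A_spike*W_spike + (1-s)*A_cond*W_test)``
with read positions drawn proportional to the binding-profile weight.
The spike-in abundance ``A_spike`` is fixed at 1 and defines the unit.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .classify import Read, write_fastq
from .snpmap import (
    SPIKE,
    TEST,
    SnpMap,
    SnpRecord,
    StrainGenome,
    build_hybrid_reference,
    hybrid_to_fasta,
    write_fasta,
)
from .tracks import PeakSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def chrom_name(i: int) -> str:
    """chrI..chrXVI then chr17, chr18, ..."""
    return f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic spike-in experiment."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    divergence: float = 0.007
    n_peaks: int = 0
    peak_width: int = 1_000
    enrichment_fold: float = 5.0
    background_fraction: float | None = None
    spike_fraction: float = 0.2
    abundance: tuple[tuple[str, float], ...] = (("wt", 1.0),)
    read_length: int = 100
    n_reads: int = 200_000
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.1:
            raise ValueError("divergence must be in [0, 0.1]")
        if not 0.0 < self.spike_fraction < 1.0:
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.read_length > self.chrom_length:
            raise ValueError("read_length exceeds chromosome length")
        if self.n_peaks < 0 or self.peak_width < 1 or self.enrichment_fold < 1:
            raise ValueError("invalid peak parameters")
        if self.n_peaks * self.peak_width >= self.n_chromosomes * self.chrom_length:
            raise ValueError("peaks do not fit in the genome")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if isinstance(self.abundance, dict):
            object.__setattr__(self, "abundance", tuple(sorted(self.abundance.items())))
        for _cond, a in self.abundance:
            if a <= 0:
                raise ValueError("abundances must be > 0")

    @property
    def abundance_map(self) -> dict[str, float]:
        return dict(self.abundance)

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["abundance"] = dict(self.abundance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "abundance" in d:
            d["abundance"] = tuple(sorted(dict(d["abundance"]).items()))
        return cls(**d)


@dataclass
class BindingProfile:
    """Per-position sampling weights for ChIP read starts."""

    per_chromosome: dict[str, np.ndarray]

    @property
    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.per_chromosome.values()))


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    snpmap: SnpMap
    peaks: PeakSet
    spike_fraction: float
    abundance: dict[str, float]
    expected: dict[str, dict[str, float]]  # condition -> {Q_input, Q_chip, Nf}

    def to_dict(self) -> dict:
        return {
            "n_snps": len(self.snpmap),
            "n_peaks": len(self.peaks),
            "spike_fraction": self.spike_fraction,
            "abundance": self.abundance,
            "expected": self.expected,
        }


def _stream(seed: int, *labels) -> np.random.Generator:
    """Independent RNG stream derived from the master seed and string labels."""
    key = [zlib.crc32(str(label).encode()) for label in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome_pair(
    config: SimConfig,
) -> tuple[StrainGenome, StrainGenome, SnpMap]:
    """Random test genome plus a spike-in copy with point substitutions.

    Each base of the spike-in copy is substituted independently with
    probability ``config.divergence`` to a uniformly chosen different base;
    every substitution is recorded in the returned truth SnpMap.
    """
    rng = _stream(config.seed, "genome")
    test_chroms: list[tuple[str, str]] = []
    spike_chroms: list[tuple[str, str]] = []
    records: list[SnpRecord] = []
    for i in range(config.n_chromosomes):
        name = chrom_name(i)
        codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        sub_mask = rng.random(config.chrom_length) < config.divergence
        sub_pos = np.nonzero(sub_mask)[0]
        spike_codes = codes.copy()
        if len(sub_pos):
            # shift by 1..3 mod 4 => always a different base, uniform over the rest
            offsets = rng.integers(1, 4, size=len(sub_pos), dtype=np.uint8)
            spike_codes[sub_pos] = (codes[sub_pos] + offsets) % 4
        seq_t = _codes_to_str(codes)
        seq_s = _codes_to_str(spike_codes)
        test_chroms.append((name, seq_t))
        spike_chroms.append((name, seq_s))
        for pos in sub_pos.tolist():
            records.append(SnpRecord(name, pos, seq_t[pos], seq_s[pos]))
    test = StrainGenome("testg", test_chroms)
    spike = StrainGenome("spikeg", spike_chroms)
    return test, spike, SnpMap(records, genome_length=config.genome_length)


def simulate_binding_profile(
    genome: StrainGenome,
    n_peaks: int,
    peak_width: int,
    enrichment_fold: float,
    background_fraction: float | None = None,
    seed: int = 0,
    max_tries: int = 1_000,
) -> tuple[BindingProfile, PeakSet]:
    """Uniform background with non-overlapping rectangular enrichment peaks.

    Weight is ``enrichment_fold`` inside peaks and 1 outside; when
    ``background_fraction`` is given, peak weights are rescaled so the
    background contributes exactly that fraction of the total weight.
    """
    rng = _stream(seed, "profile")
    lengths = genome.chrom_lengths
    names = genome.chrom_names
    sizes = np.asarray([lengths[c] for c in names], dtype=float)
    weights = {c: np.ones(lengths[c]) for c in names}
    placed: dict[str, list[int]] = {c: [] for c in names}
    intervals = []
    for pi in range(n_peaks):
        for attempt in range(max_tries):
            ci = int(rng.choice(len(names), p=sizes / sizes.sum()))
            chrom = names[ci]
            if lengths[chrom] < peak_width:
                continue
            start = int(rng.integers(0, lengths[chrom] - peak_width + 1))
            if all(
                start + peak_width <= other or other + peak_width <= start
                for other in placed[chrom]
            ):
                placed[chrom].append(start)
                intervals.append((chrom, start, start + peak_width, f"true_peak_{pi + 1}", enrichment_fold))
                break
        else:
            raise RuntimeError(
                f"could not place peak {pi + 1} without overlap after {max_tries} tries"
            )
    for chrom, start, end, _n, _s in intervals:
        weights[chrom][start:end] = enrichment_fold
    if background_fraction is not None and n_peaks > 0:
        if not 0.0 < background_fraction < 1.0:
            raise ValueError("background_fraction must be in (0, 1)")
        bg = float(sum((w == 1).sum() for w in weights.values()))
        peak_mass = float(sum(w[w > 1].sum() for w in weights.values()))
        target_peak_mass = bg * (1 - background_fraction) / background_fraction
        scale = target_peak_mass / peak_mass
        for w in weights.values():
            w[w > 1] *= scale
    return BindingProfile(weights), PeakSet(intervals)


def _experiment_parts(config: SimConfig):
    """Genomes, truth SNPs, and the binding profile for a config (cached).

    Genome and profile generation depend only on the structural fields, so
    samples drawn for different conditions/roles share identical genomes.
    """
    key = (
        config.seed, config.n_chromosomes, config.chrom_length, config.divergence,
        config.n_peaks, config.peak_width, config.enrichment_fold,
        config.background_fraction,
    )
    cached = _experiment_parts._cache.get(key)
    if cached is None:
        test, spike, snpmap = simulate_genome_pair(config)
        profile, peaks = simulate_binding_profile(
            test, config.n_peaks, config.peak_width, config.enrichment_fold,
            config.background_fraction, seed=config.seed,
        )
        cached = (test, spike, snpmap, profile, peaks)
        _experiment_parts._cache.clear()  # keep at most one experiment resident
        _experiment_parts._cache[key] = cached
    return cached


_experiment_parts._cache = {}


def expected_values(config: SimConfig, condition_id: str) -> dict[str, float]:
    """Closed-form Q_input, Q_chip, and Nf for a condition.

    With colinear genomes the two sides have equal lengths and (mirrored)
    profiles, so Nf reduces to A_cond / A_spike = A_cond.
    """
    abundance = config.abundance_map
    if condition_id not in abundance:
        raise KeyError(f"condition {condition_id!r} has no abundance entry")
    s = config.spike_fraction
    l_test = l_spike = float(config.genome_length)
    *_parts, profile, _peaks = _experiment_parts(config)
    w_test = w_spike = profile.total_weight  # mirrored profile on both genomes
    a_cond = abundance[condition_id]
    a_spike = 1.0
    q_input = (s * l_spike) / ((1 - s) * l_test)
    q_chip = (s * a_spike * w_spike) / ((1 - s) * a_cond * w_test)
    return {"Q_input": q_input, "Q_chip": q_chip, "Nf": q_input / q_chip}


def _sample_positions(
    rng: np.random.Generator,
    genome: StrainGenome,
    profile: BindingProfile | None,
    read_length: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(chromosome index, start) per read; uniform or profile-weighted."""
    names = genome.chrom_names
    if profile is None:
        n_starts = np.asarray(
            [len(seq) - read_length + 1 for _c, seq in genome.chromosomes], dtype=float
        )
        chrom_idx = rng.choice(len(names), size=n, p=n_starts / n_starts.sum())
        starts = np.empty(n, dtype=np.int64)
        for ci in range(len(names)):
            mask = chrom_idx == ci
            starts[mask] = rng.integers(0, int(n_starts[ci]), size=int(mask.sum()))
        return chrom_idx, starts
    cum_by_chrom = []
    totals = []
    for name, seq in genome.chromosomes:
        w = profile.per_chromosome[name][: len(seq) - read_length + 1]
        cum = np.cumsum(w)
        cum_by_chrom.append(cum)
        totals.append(cum[-1])
    totals = np.asarray(totals)
    chrom_idx = rng.choice(len(names), size=n, p=totals / totals.sum())
    starts = np.empty(n, dtype=np.int64)
    for ci, cum in enumerate(cum_by_chrom):
        mask = chrom_idx == ci
        k = int(mask.sum())
        if k:
            u = rng.random(k) * cum[-1]
            starts[mask] = np.searchsorted(cum, u, side="right")
    return chrom_idx, starts


_RC_CODES = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    config: SimConfig, condition_id: str, sample_role: str
) -> tuple[list[Read], SimTruth]:
    """Draw one sample's reads (with truth labels) plus the experiment truth.

    ``sample_role`` is "ChIP" or "Input".  The RNG stream is derived from
    (seed, condition, role), so adding conditions never perturbs existing
    samples.
    """
    if sample_role not in ("ChIP", "Input"):
        raise ValueError("sample_role must be 'ChIP' or 'Input'")
    abundance = config.abundance_map
    if condition_id not in abundance:
        raise KeyError(f"condition {condition_id!r} has no abundance entry")
    test, spike, snpmap, profile, peaks = _experiment_parts(config)

    s = config.spike_fraction
    if sample_role == "Input":
        p_spike = s  # equal genome lengths
        use_profile = None
    else:
        a_cond = abundance[condition_id]
        w = profile.total_weight  # mirrored, cancels
        p_spike = (s * 1.0 * w) / (s * 1.0 * w + (1 - s) * a_cond * w)
        use_profile = profile

    rng = _stream(config.seed, "reads", condition_id, sample_role)
    n = config.n_reads
    rl = config.read_length
    is_spike = rng.random(n) < p_spike
    strands = rng.integers(0, 2, size=n)
    reads: list[Read] = [None] * n  # type: ignore[list-item]
    for origin, genome, mask in ((TEST, test, ~is_spike), (SPIKE, spike, is_spike)):
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        chrom_idx, starts = _sample_positions(rng, genome, use_profile, rl, len(idx))
        seqs = [seq for _name, seq in genome.chromosomes]
        for j, ci, start in zip(idx.tolist(), chrom_idx.tolist(), starts.tolist()):
            seq = seqs[ci][start : start + rl]
            if strands[j]:
                seq = seq.translate(_RC_CODES)[::-1]
            reads[j] = Read(f"{condition_id}:{sample_role}:{j}", seq, origin)
    if config.error_rate > 0:
        _inject_errors(reads, config.error_rate, rng)

    expected = {
        cond: expected_values(config, cond) for cond in abundance
    }
    truth = SimTruth(snpmap, peaks, s, abundance, expected)
    return reads, truth


def _inject_errors(reads: list[Read], rate: float, rng: np.random.Generator) -> None:
    """Independent substitution errors at the given per-base rate."""
    bases = "ACGT"
    for read in reads:
        n_err = rng.binomial(len(read.sequence), rate)
        if n_err == 0:
            continue
        seq = list(read.sequence)
        for pos in rng.choice(len(seq), size=n_err, replace=False):
            seq[pos] = bases[(bases.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
        read.sequence = "".join(seq)


def write_fixture(config: SimConfig, out_dir: str) -> dict:
    """Emit FASTA/FASTQ/JSON fixture files; regeneration is byte-identical."""
    os.makedirs(out_dir, exist_ok=True)
    test, spike, snpmap, _profile, peaks = _experiment_parts(config)
    hybrid = build_hybrid_reference(test, spike)
    paths = {
        "test_fasta": os.path.join(out_dir, "test.fa"),
        "spike_fasta": os.path.join(out_dir, "spike.fa"),
        "hybrid_fasta": os.path.join(out_dir, "hybrid.fa"),
        "truth_json": os.path.join(out_dir, "truth.json"),
        "manifest_json": os.path.join(out_dir, "manifest.json"),
    }
    write_fasta(paths["test_fasta"], test.chromosomes)
    write_fasta(paths["spike_fasta"], spike.chromosomes)
    hybrid_to_fasta(hybrid, paths["hybrid_fasta"])
    truth: SimTruth | None = None
    fastqs = {}
    for cond in config.abundance_map:
        for role in ("ChIP", "Input"):
            reads, truth = simulate_reads(config, cond, role)
            fq = os.path.join(out_dir, f"{cond}_{role.lower()}.fq")
            write_fastq(fq, reads)
            fastqs[f"{cond}_{role}"] = fq
    paths["fastq"] = fastqs
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
    manifest = {"config": config.to_dict(), "files": paths}
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
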