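"""Spike-in quotients, normalization factors, and the end-to-end pipeline.

For each sequenced sample the quotient ``Q = C_spike / C_endo`` compares
signal attributed to the spike-in genome against the test genome.  The
input sample's quotient measures the spike-in cell fraction; the ChIP
sample's quotient additionally reflects target abundance.  Their ratio
``Nf = Q_input / Q_chip`` scales each condition onto a common spike-in
anchored scale, and dividing a condition's Nf by the reference condition's
Nf yields its relative target level.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .classify import AssignmentResult, ExactIndex, Read, assign_reads, counts_from_contig_table
from .snpmap import HybridReference, SnpMap, TEST, SPIKE
from .tracks import (
    PeakSet,
    PileupTrack,
    apply_norm_factor,
    mean_pileup,
    pileup_from_assignment,
    spmr_scale,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

CHIP = "ChIP"
INPUT = "Input"

MIN_RECOMMENDED_SPIKE_PERCENT = 15.0


class EstimatorMethod(str, Enum):
    """How C_endo / C_spike are measured for a sample."""

    read_count = "read_count"
    pileup_all = "pileup_all"
    pileup_snp = "pileup_snp"
    pileup_snp_peaks = "pileup_snp_peaks"


@dataclass(frozen=True)
class SampleCounts:
    sample_role: str  # CHIP or INPUT
    C_endo: float
    C_spike: float
    method: EstimatorMethod = EstimatorMethod.read_count

    def __post_init__(self) -> None:
        if self.sample_role not in (CHIP, INPUT):
            raise ValueError(f"sample_role must be {CHIP!r} or {INPUT!r}")
        if self.C_endo < 0 or self.C_spike < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class QValue:
    value: float
    sample_role: str
    method: EstimatorMethod


@dataclass(frozen=True)
class NormFactor:
    value: float
    condition_id: str
    method: EstimatorMethod
    q_input: QValue
    q_chip: QValue


@dataclass
class ConditionLevel:
    """Target level of a condition as a fraction of the reference."""

    condition_id: str
    level: float
    replicate_values: list[float] = field(default_factory=list)

    @property
    def sd(self) -> float:
        if len(self.replicate_values) < 2:
            return float("nan")
        return float(np.std(self.replicate_values, ddof=1))


def compute_Q(counts: SampleCounts) -> QValue:
    """Q = C_spike / C_endo for one sample."""
    if counts.C_endo == 0:
        raise ValueError("C_endo is zero; Q undefined")
    if counts.C_spike == 0:
        warnings.warn(
            f"{counts.sample_role} sample has no spike-in signal; Q = 0", stacklevel=2
        )
    return QValue(counts.C_spike / counts.C_endo, counts.sample_role, counts.method)


def spike_in_percentage(q_input: QValue) -> float:
    """Estimated spike-in cell percentage, 100*Q/(1+Q), from an input sample."""
    if q_input.sample_role != INPUT:
        raise ValueError("spike-in percentage is defined on the Input sample's Q")
    return 100.0 * q_input.value / (1.0 + q_input.value)


def compute_Nf(q_input: QValue, q_chip: QValue, condition_id: str = "") -> NormFactor:
    """Nf = Q_input / Q_chip for one condition."""
    if q_input.method != q_chip.method:
        raise ValueError(
            f"method mismatch: {q_input.method.value} vs {q_chip.method.value}"
        )
    if q_input.sample_role != INPUT or q_chip.sample_role != CHIP:
        raise ValueError("compute_Nf expects (input Q, ChIP Q)")
    if q_chip.value == 0:
        raise ValueError("Q_chip is zero (no spike-in reads in ChIP); Nf undefined")
    if q_input.value == 0:
        raise ValueError("Q_input is zero (no spike-in reads in input); Nf undefined")
    pct = spike_in_percentage(q_input)
    if pct < MIN_RECOMMENDED_SPIKE_PERCENT:
        warnings.warn(
            f"estimated spike-in percentage {pct:.1f}% is below the recommended "
            f"{MIN_RECOMMENDED_SPIKE_PERCENT:.0f}%; Nf may be noisy",
            stacklevel=2,
        )
    return NormFactor(q_input.value / q_chip.value, condition_id, q_input.method, q_input, q_chip)


def relative_level(nf_cond: NormFactor, nf_wt: NormFactor) -> ConditionLevel:
    """Condition Nf divided by the reference (wild-type) Nf."""
    if nf_cond.method != nf_wt.method:
        raise ValueError("cannot compare Nf values from different estimator methods")
    if nf_wt.value <= 0:
        raise ValueError("reference Nf must be > 0")
    return ConditionLevel(nf_cond.condition_id, nf_cond.value / nf_wt.value)


def aggregate_replicates(levels: list[ConditionLevel]) -> ConditionLevel:
    """Mean of replicate levels with the individual values retained."""
    if not levels:
        raise ValueError("no replicate levels to aggregate")
    values = [lv.level for lv in levels]
    return ConditionLevel(levels[0].condition_id, float(np.mean(values)), values)


def estimate_counts(
    method: EstimatorMethod,
    assignment: AssignmentResult,
    snpmap: SnpMap | None = None,
    peaks: PeakSet | None = None,
    read_length: int = 100,
    sample_role: str = CHIP,
) -> SampleCounts:
    """Measure C_endo / C_spike for one sample under the chosen estimator.

    ``read_count`` uses the assignment's read tallies directly; the pileup
    variants replace them with mean coverage of each genome's track over
    all positions, SNP positions, or SNP positions inside peaks.  SNP and
    peak coordinates are shared between the colinear genomes, so the same
    position set applies to both tracks.
    """
    method = EstimatorMethod(method)
    if method == EstimatorMethod.read_count:
        return SampleCounts(sample_role, float(assignment.C_endo), float(assignment.C_spike), method)
    if method in (EstimatorMethod.pileup_snp, EstimatorMethod.pileup_snp_peaks) and snpmap is None:
        raise ValueError(f"{method.value} requires a SnpMap")
    if method == EstimatorMethod.pileup_snp_peaks and peaks is None:
        raise ValueError("pileup_snp_peaks requires a PeakSet")
    test_track = pileup_from_assignment(assignment, read_length, TEST)
    spike_track = pileup_from_assignment(assignment, read_length, SPIKE)
    if method == EstimatorMethod.pileup_all:
        c_endo = mean_pileup(test_track)
        c_spike = mean_pileup(spike_track)
    elif method == EstimatorMethod.pileup_snp:
        c_endo = mean_pileup(test_track, snpmap=snpmap)
        c_spike = mean_pileup(spike_track, snpmap=snpmap)
    else:
        c_endo = mean_pileup(test_track, snpmap=snpmap, peaks=peaks)
        c_spike = mean_pileup(spike_track, snpmap=snpmap, peaks=peaks)
    return SampleCounts(sample_role, c_endo, c_spike, method)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ConditionInput:
    """Per-condition sample sources: in-memory reads or count-table paths."""

    condition_id: str
    chip_reads: list[Read] | None = None
    input_reads: list[Read] | None = None
    chip_table: str | None = None
    input_table: str | None = None

    def __post_init__(self) -> None:
        if (self.chip_reads is None) == (self.chip_table is None):
            raise ValueError(
                f"{self.condition_id}: provide exactly one of chip_reads/chip_table"
            )
        if (self.input_reads is None) == (self.input_table is None):
            raise ValueError(
                f"{self.condition_id}: provide exactly one of input_reads/input_table "
                "(Nf requires the input sample)"
            )


def normalize_experiment(
    conditions: list[ConditionInput],
    reference: str,
    hybrid: HybridReference | None = None,
    snpmap: SnpMap | None = None,
    peaks: PeakSet | None = None,
    method: EstimatorMethod = EstimatorMethod.read_count,
    read_length: int = 100,
    out_dir: str | None = None,
) -> dict:
    """Run classify -> estimate -> Q -> Nf -> levels -> scaled tracks.

    Returns a machine-readable report; when ``out_dir`` is given, writes
    the report as JSON plus spike-in-scaled SPMR bedGraph tracks for every
    read-backed condition.
    """
    method = EstimatorMethod(method)
    ids = [c.condition_id for c in conditions]
    if reference not in ids:
        raise ValueError(f"reference condition {reference!r} not among {ids}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate condition ids")

    index: ExactIndex | None = None
    if any(c.chip_reads is not None or c.input_reads is not None for c in conditions):
        if hybrid is None:
            raise ValueError("read-backed conditions require the hybrid reference")
        index = ExactIndex(hybrid, read_length_hint=read_length)

    per_condition: dict[str, dict] = {}
    nf_by_condition: dict[str, NormFactor] = {}
    assignments: dict[str, AssignmentResult] = {}
    for cond in conditions:
        sample_counts = {}
        report_warnings: list[str] = []
        for role, reads, table in (
            (CHIP, cond.chip_reads, cond.chip_table),
            (INPUT, cond.input_reads, cond.input_table),
        ):
            if reads is not None:
                assignment = assign_reads(reads, index)
                if role == CHIP:
                    assignments[cond.condition_id] = assignment
                sample_counts[role] = estimate_counts(
                    method, assignment, snpmap=snpmap, peaks=peaks,
                    read_length=read_length, sample_role=role,
                )
            else:
                if method != EstimatorMethod.read_count:
                    raise ValueError(
                        f"{cond.condition_id}/{role}: count tables only support the "
                        "read_count estimator; pileup variants need the reads"
                    )
                if hybrid is None:
                    raise ValueError("count-table mode requires the hybrid (for contig origins)")
                c_endo, c_spike = counts_from_contig_table(table, hybrid.origin_of)
                sample_counts[role] = SampleCounts(role, float(c_endo), float(c_spike), method)
        q_chip = compute_Q(sample_counts[CHIP])
        q_input = compute_Q(sample_counts[INPUT])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            nf = compute_Nf(q_input, q_chip, condition_id=cond.condition_id)
        report_warnings.extend(str(w.message) for w in caught)
        nf_by_condition[cond.condition_id] = nf
        per_condition[cond.condition_id] = {
            "condition": cond.condition_id,
            "method": method.value,
            "C_endo_chip": sample_counts[CHIP].C_endo,
            "C_spike_chip": sample_counts[CHIP].C_spike,
            "C_endo_input": sample_counts[INPUT].C_endo,
            "C_spike_input": sample_counts[INPUT].C_spike,
            "Q_input": q_input.value,
            "Q_chip": q_chip.value,
            "spike_in_percent": spike_in_percentage(q_input),
            "Nf": nf.value,
            "warnings": report_warnings,
        }

    nf_ref = nf_by_condition[reference]
    for cond_id, nf in nf_by_condition.items():
        per_condition[cond_id]["level_vs_reference"] = relative_level(nf, nf_ref).level

    report = {
        "reference": reference,
        "method": method.value,
        "conditions": per_condition,
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        for cond_id, assignment in assignments.items():
            nf = nf_by_condition[cond_id]
            for genome_id in (TEST, SPIKE):
                track = pileup_from_assignment(assignment, read_length, genome_id)
                scaled = apply_norm_factor(
                    spmr_scale(track, assignment.C_endo + assignment.C_spike), nf
                )
                write_bedgraph(
                    scaled,
                    os.path.join(out_dir, f"{cond_id}_{genome_id}_chip_scaled.bedgraph"),
                )
    return report


def scaled_track(
    assignment: AssignmentResult,
    nf: NormFactor,
    read_length: int = 100,
    genome_id: str = TEST,
) -> PileupTrack:
    """Convenience: SPMR-scaled, spike-in-normalized ChIP track."""
    track = pileup_from_assignment(assignment, read_length, genome_id)
    depth = assignment.C_endo + assignment.C_spike
    return apply_norm_factor(spmr_scale(track, depth), nf)
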