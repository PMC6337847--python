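"""Robustness analyses: read-subsampling grids and spike-in titrations.

The subsampling grid checks that the normalization factor is insensitive
to sequencing depth by recomputing the mutant's wild type-normalized level
for every cross-sample combination of subsample sizes.  The titration
series checks that the spike-in read proportion of the ChIP sample scales
linearly with that of the input sample across spike-in cell fractions.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import ExactIndex, Read, assign_reads
from .normalize import (
    CHIP,
    INPUT,
    EstimatorMethod,
    SampleCounts,
    compute_Nf,
    compute_Q,
)
from .snpmap import SPIKE, TEST, build_hybrid_reference
from .simulate import SimConfig, _experiment_parts, simulate_reads

logger = logging.getLogger(__name__)

SAMPLE_KEYS = ("wt_chip", "wt_input", "mut_chip", "mut_input")


@dataclass
class SubsampleGrid:
    sizes: list[int]
    nf_values: np.ndarray  # levels (mutant vs wild type), one per size combination
    aligned_counts: dict[str, list[tuple[int, int]]]  # sample -> [(size, n_assigned)]
    mean: float
    sd: float
    cv: float


@dataclass
class TitrationResult:
    points: list[tuple[float, float]]  # (input spike fraction, chip spike fraction)
    slope: float
    intercept: float
    r_squared: float
    per_point_Nf: list[float]
    warnings: list[str] = field(default_factory=list)


def subsample_reads(reads: list[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample of n reads without replacement; deterministic per seed."""
    if n > len(reads):
        raise ValueError(f"cannot subsample {n} from {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def linear_fit(points) -> tuple[float, float, float]:
    """Ordinary least squares through (x, y) points.

    R^2 = 1 - SS_res/SS_tot; when SS_tot = 0 (all y equal) R^2 is defined
    as 1 for a perfect horizontal fit.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("linear_fit needs at least two points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values identical")
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r_squared


def _call_array(reads: list[Read], index: ExactIndex) -> np.ndarray:
    """Per-read call codes: 0=test, 1=spike, 2=other (ambiguous/unmapped)."""
    result = assign_reads(reads, index)
    codes = {TEST: 0, SPIKE: 1}
    return np.asarray([codes.get(c, 2) for c in result.calls], dtype=np.int8)


def nf_subsample_grid(
    samples: dict[str, list[Read]],
    sizes: list[int],
    seed: int,
    index: ExactIndex,
    method: EstimatorMethod = EstimatorMethod.read_count,
) -> SubsampleGrid:
    """Mutant level across every cross-sample combination of subsample sizes.

    Each of the four samples (wild-type ChIP/input, mutant ChIP/input) is
    subsampled once per size with an independent stream derived from the
    master seed; the wild type-normalized mutant level is computed for all
    ``len(sizes)**4`` size combinations.  Only the read_count estimator is
    supported (pileup variants would need per-subset pileups).
    """
    if EstimatorMethod(method) != EstimatorMethod.read_count:
        raise ValueError("nf_subsample_grid supports the read_count estimator only")
    if not sizes:
        raise ValueError("sizes must be non-empty")
    missing = [k for k in SAMPLE_KEYS if k not in samples]
    if missing:
        raise ValueError(f"missing samples: {missing}")
    for key in SAMPLE_KEYS:
        if max(sizes) > len(samples[key]):
            raise ValueError(
                f"size {max(sizes)} infeasible for sample {key} ({len(samples[key])} reads)"
            )

    q_by_sample: dict[str, np.ndarray] = {}
    aligned_counts: dict[str, list[tuple[int, int]]] = {}
    master = np.random.SeedSequence(seed)
    for si, key in enumerate(SAMPLE_KEYS):
        calls = _call_array(samples[key], index)
        qs = []
        aligned_counts[key] = []
        for zi, size in enumerate(sizes):
            sub_seed = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(si, zi)
            ).generate_state(1)[0]
            rng = np.random.default_rng(sub_seed)
            idx = rng.choice(len(calls), size=size, replace=False)
            sub = calls[idx]
            c_endo = int(np.sum(sub == 0))
            c_spike = int(np.sum(sub == 1))
            aligned_counts[key].append((size, c_endo + c_spike))
            if c_endo == 0:
                raise ValueError(f"subsample of {key} at size {size} has no test reads")
            qs.append(c_spike / c_endo)
        q_by_sample[key] = np.asarray(qs)

    # level = Nf_mut / Nf_wt = (Q_mut_in/Q_mut_chip) / (Q_wt_in/Q_wt_chip)
    q_wt_chip = q_by_sample["wt_chip"][:, None, None, None]
    q_wt_in = q_by_sample["wt_input"][None, :, None, None]
    q_mut_chip = q_by_sample["mut_chip"][None, None, :, None]
    q_mut_in = q_by_sample["mut_input"][None, None, None, :]
    levels = ((q_mut_in / q_mut_chip) / (q_wt_in / q_wt_chip)).ravel()
    mean = float(levels.mean())
    sd = float(levels.std(ddof=1)) if len(levels) > 1 else 0.0
    return SubsampleGrid(
        sizes=list(sizes),
        nf_values=levels,
        aligned_counts=aligned_counts,
        mean=mean,
        sd=sd,
        cv=sd / mean if mean else float("nan"),
    )


def titration_series(
    base_config: SimConfig,
    fractions: list[float],
    seed: int,
    condition_id: str | None = None,
) -> TitrationResult:
    """Simulate input+ChIP pairs across spike-in cell fractions.

    Records the spike read proportion (among assigned reads) of the input
    and ChIP samples per fraction, fits them by least squares, and reports
    the per-fraction Nf.
    """
    if len(fractions) < 3:
        raise ValueError("titration needs at least 3 fractions")
    if not all(0.0 < f < 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")
    if condition_id is None:
        condition_id = base_config.abundance[0][0]
    points = []
    nfs = []
    warnings_out: list[str] = []
    seeded = base_config.with_(seed=base_config.seed + int(seed))
    test, spike, _snpmap, _profile, _peaks = _experiment_parts(seeded)
    index = ExactIndex(
        build_hybrid_reference(test, spike), read_length_hint=seeded.read_length
    )
    for f in fractions:
        config = seeded.with_(spike_fraction=f)
        q_vals = {}
        fracs = {}
        for role in (INPUT, CHIP):
            reads, _truth = simulate_reads(config, condition_id, role)
            result = assign_reads(reads, index)
            assigned = result.C_endo + result.C_spike
            fracs[role] = result.C_spike / assigned if assigned else float("nan")
            q_vals[role] = compute_Q(
                SampleCounts(role, float(result.C_endo), float(result.C_spike))
            )
        points.append((fracs[INPUT], fracs[CHIP]))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # low-spike advisory handled by caller
            nfs.append(compute_Nf(q_vals[INPUT], q_vals[CHIP], condition_id).value)
    slope, intercept, r_squared = linear_fit(points)
    expected_slope_scale = max(abs(p[1]) for p in points)
    if abs(slope) < 1e-3 * max(expected_slope_scale, 1e-12):
        warnings_out.append(
            "pathological titration: ChIP spike fraction does not respond to "
            "input spike fraction"
        )
    return TitrationResult(points, slope, intercept, r_squared, nfs, warnings_out)
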