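"""Coverage pileups, mean scores, track scaling, and interval I/O.

Pileups use raw read-length coverage (no fragment-size extension); any
constant extension factor would cancel in the spike-in quotient, so the
simpler model is used for the estimators.  bedGraph is the text track
format so round-trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import AssignmentResult
from .snpmap import SnpMap, snps_in_intervals, split_contig_name, TEST, SPIKE

logger = logging.getLogger(__name__)


@dataclass
class PileupTrack:
    """Per-base read coverage for one side of the hybrid."""

    genome_id: str  # TEST or SPIKE
    per_chromosome: dict[str, np.ndarray]
    n_reads_used: int = 0
    # scaling bookkeeping: scaled values are always base * factor, computed
    # in one multiplication, so successive scalings commute exactly
    _base: dict[str, np.ndarray] | None = None
    _factor: float = 1.0

    @property
    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.per_chromosome.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(len(v) for v in self.per_chromosome.values()))

    def copy_scaled(self, factor: float) -> "PileupTrack":
        base = self._base if self._base is not None else self.per_chromosome
        combined = self._factor * float(factor)
        return PileupTrack(
            self.genome_id,
            {c: v.astype(float) * combined for c, v in base.items()},
            self.n_reads_used,
            _base=base,
            _factor=combined,
        )


@dataclass
class PeakSet:
    """Sorted, merged 0-based half-open intervals."""

    intervals: list[tuple[str, int, int, str, float]]

    def __post_init__(self) -> None:
        normalized = []
        for iv in self.intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            name = iv[3] if len(iv) > 3 else "."
            score = float(iv[4]) if len(iv) > 4 else 0.0
            if start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            normalized.append((chrom, start, end, name, score))
        normalized.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
        merged: list[tuple[str, int, int, str, float]] = []
        for iv in normalized:
            if merged and merged[-1][0] == iv[0] and iv[1] < merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (
                    prev[0],
                    prev[1],
                    max(prev[2], iv[2]),
                    prev[3],
                    max(prev[4], iv[4]),
                )
            else:
                merged.append(iv)
        self.intervals = merged

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_span(self) -> int:
        return sum(end - start for _c, start, end, _n, _s in self.intervals)


def pileup_from_assignment(
    result: AssignmentResult, read_length: int, genome_id: str
) -> PileupTrack:
    """Stack assigned reads of one genome into per-base coverage.

    Each uniquely assigned read adds +1 over ``[start, start+read_length)``
    on its chromosome (hybrid strain prefix stripped); ambiguous and
    unmapped reads contribute nothing.
    """
    if genome_id not in (TEST, SPIKE):
        raise ValueError(f"genome_id must be {TEST!r} or {SPIKE!r}")
    chrom_of: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for contig, length in result.contig_lengths.items():
        if result.origin_of.get(contig) == genome_id:
            chrom = split_contig_name(contig)[1]
            chrom_of[contig] = chrom
            lengths[chrom] = length
    # +1 slot so the closing decrement of a read ending at L lands in-array
    delta = {c: np.zeros(l + 1, dtype=np.int64) for c, l in lengths.items()}
    n_used = 0
    for _rid, pl, origin in result.assigned():
        if origin != genome_id:
            continue
        chrom = chrom_of[pl.contig]
        end = pl.start + read_length
        if pl.start < 0 or end > lengths[chrom]:
            raise ValueError(
                f"placement {pl} (+{read_length} bp) out of bounds on {chrom}"
            )
        delta[chrom][pl.start] += 1
        delta[chrom][end] -= 1
        n_used += 1
    coverage = {c: np.cumsum(d[:-1]) for c, d in delta.items()}
    return PileupTrack(genome_id, coverage, n_used)


def mean_pileup(
    track: PileupTrack,
    snpmap: SnpMap | None = None,
    peaks: PeakSet | None = None,
) -> float:
    """Mean coverage over all bases, SNP positions, or SNPs within peaks.

    With no ``snpmap`` the mean runs over every base of the genome; with a
    ``snpmap`` it is restricted to SNP positions; adding ``peaks`` further
    restricts to SNP positions inside peak intervals.
    """
    if snpmap is None:
        if peaks is not None:
            raise ValueError("peaks restriction requires a SnpMap")
        total = track.genome_length
        if total == 0:
            raise ValueError("mode 'all': track has no positions")
        return track.total_mass / total
    mode = "snp" if peaks is None else "snp_in_peaks"
    subset = snpmap if peaks is None else snps_in_intervals(snpmap, peaks)
    values: list[np.ndarray] = []
    for chrom, positions in subset.positions_by_chrom().items():
        cov = track.per_chromosome.get(chrom)
        if cov is None:
            raise ValueError(f"SNP chromosome {chrom!r} absent from track")
        values.append(cov[positions])
    if not values:
        raise ValueError(f"mode {mode!r}: empty position subset")
    return float(np.mean(np.concatenate(values)))


def per_chromosome_mean(track: PileupTrack) -> dict[str, float]:
    if not track.per_chromosome:
        raise ValueError("empty track")
    return {c: float(v.mean()) for c, v in track.per_chromosome.items()}


def spmr_scale(track: PileupTrack, total_assigned_reads: int) -> PileupTrack:
    """Scale to coverage per million assigned reads."""
    if total_assigned_reads <= 0:
        raise ValueError("total_assigned_reads must be > 0")
    return track.copy_scaled(1e6 / total_assigned_reads)


def apply_norm_factor(track: PileupTrack, nf) -> PileupTrack:
    """Multiply every value by the spike-in normalization factor."""
    value = getattr(nf, "value", nf)
    if value <= 0:
        raise ValueError("normalization factor must be > 0")
    return track.copy_scaled(float(value))


def call_peaks_naive(
    chip: PileupTrack,
    input_track: PileupTrack,
    fold: float,
    min_width: int,
) -> PeakSet:
    """Threshold caller for fixtures: runs where ChIP >= fold x scaled input.

    The input track is mean-scaled to the ChIP track's depth; maximal runs
    of positions with positive ChIP coverage at or above ``fold`` times the
    scaled input, of at least ``min_width`` bases, become peaks.  This is a
    deliberately simple substitute for a model-based external caller.
    """
    if set(chip.per_chromosome) != set(input_track.per_chromosome):
        raise ValueError("ChIP and input tracks cover different chromosomes")
    input_mean = input_track.total_mass / max(input_track.genome_length, 1)
    if input_mean <= 0:
        raise ValueError("input track is flat zero; cannot scale")
    chip_mean = chip.total_mass / max(chip.genome_length, 1)
    scale = chip_mean / input_mean
    intervals = []
    n = 0
    for chrom, cov in chip.per_chromosome.items():
        ref = input_track.per_chromosome[chrom].astype(float) * scale
        enriched = (cov >= fold * ref) & (cov > 0)
        padded = np.diff(np.concatenate(([0], enriched.view(np.int8), [0])))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        for start, end in zip(starts, ends):
            if end - start >= min_width:
                n += 1
                score = float(cov[start:end].mean())
                intervals.append((chrom, int(start), int(end), f"peak_{n}", score))
    return PeakSet(intervals)


# ---------------------------------------------------------------------------
# bedGraph / BED I/O


def write_bedgraph(track: PileupTrack, path: str) -> None:
    """Write the track with equal-value runs merged into single lines."""
    with open(path, "w") as fh:
        for chrom, cov in track.per_chromosome.items():
            if len(cov) == 0:
                continue
            change = np.nonzero(np.diff(cov))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(cov)]))
            for start, end in zip(starts, ends):
                value = cov[start]
                text = str(int(value)) if float(value).is_integer() else repr(float(value))
                fh.write(f"{chrom}\t{start}\t{end}\t{text}\n")


def read_bedgraph(path: str, genome_id: str = TEST) -> PileupTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line {line!r}")
            chrom, start, end, value = parts
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
    coverage = {}
    for chrom, runs in per_chrom.items():
        runs.sort()
        length = runs[-1][1]
        vec = np.zeros(length, dtype=float)
        for start, end, value in runs:
            vec[start:end] = value
        coverage[chrom] = vec
    return PileupTrack(genome_id, coverage)


def read_bed(path: str) -> PeakSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            intervals.append((chrom, start, end, name, score))
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\n")
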