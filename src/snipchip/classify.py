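"""Read classification against the hybrid reference.

Reads are placed under a strict perfect-match rule: a read is assigned to
the test or spike-in genome only when its sequence (on either strand)
occurs at exactly one location in the whole hybrid reference.  Reads with
no exact occurrence are unmapped; reads occurring at two or more locations
(typically because they span no SNP and therefore exist in both genomes)
are ambiguous and discarded.  The resulting counts C_endo and C_spike feed
the normalization quotients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .snpmap import HybridReference, SnpMap, TEST, SPIKE

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class Read:
    read_id: str
    sequence: str
    truth_origin: str | None = None  # simulation ground truth, if any


@dataclass(frozen=True)
class Placement:
    """A unique exact occurrence of a read in the hybrid reference."""

    contig: str
    start: int  # 0-based
    strand: str  # "+" or "-"


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i


class ExactIndex:
    """Seed-and-verify exact-occurrence index over the hybrid reference.

    Every window of length k = min(read_length_hint, 32) is packed into a
    2-bit-per-base integer code; the codes are kept sorted so all candidate
    positions for a query come from one binary search.  Candidates are
    verified by direct string comparison, so results are exact for queries
    of length >= k.  Shorter queries fall back to a full scan.  ``locate``
    returns ALL occurrences on both strands, ordered by (contig order,
    position, '+' before '-').
    """

    def __init__(self, hybrid: HybridReference, read_length_hint: int = 100):
        if not hybrid.contigs:
            raise ValueError("cannot index an empty hybrid reference")
        if read_length_hint < 1:
            raise ValueError("read_length_hint must be >= 1")
        self.hybrid = hybrid
        self.k = min(read_length_hint, 32)
        self._names = [c.name for c in hybrid.contigs]
        self._seqs = [c.sequence for c in hybrid.contigs]
        self.origin_of = hybrid.origin_of
        self._cat = "".join(self._seqs)
        lengths = [len(s) for s in self._seqs]
        self._offsets = np.cumsum([0] + lengths)

        k = self.k
        codes8 = _CODE_LUT[np.frombuffer(self._cat.encode("ascii"), dtype=np.uint8)]
        packed = np.zeros(len(codes8) - k + 1, dtype=np.uint64)
        nfree = np.ones(len(packed), dtype=bool)
        for shift in range(k):
            window = codes8[shift : shift + len(packed)]
            packed = (packed << np.uint64(2)) | window.astype(np.uint64)
            nfree &= window != 255  # no N anywhere in the window
        # seed windows must not cross contig boundaries
        starts = np.arange(len(packed), dtype=np.int64)
        contig_idx = np.searchsorted(self._offsets, starts, side="right") - 1
        valid = nfree & (starts + k <= self._offsets[contig_idx + 1])
        # unsorted per-position codes + N-free mask serve the batch
        # verification path in assign_reads
        self._packed_all = packed
        self._nfree = nfree
        order = np.argsort(packed[valid], kind="stable")
        self._codes = packed[valid][order]
        self._positions = starts[valid][order]

    def _encode(self, kmer: str) -> int | None:
        """2-bit pack a k-mer; None when it contains a non-ACGT base."""
        value = 0
        for ch in kmer:
            c = _CODE_LUT[ord(ch)]
            if c == 255:
                return None
            value = (value << 2) | int(c)
        return value

    def _scan(self, query: str) -> list[tuple[int, int, str]]:
        """Naive fallback for queries shorter than the seed length."""
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for ci, seq in enumerate(self._seqs):
                start = seq.find(q)
                while start != -1:
                    hits.append((ci, start, strand))
                    start = seq.find(q, start + 1)
        hits.sort()
        return hits

    def locate(self, query: str) -> list[Placement]:
        """All exact occurrences of ``query`` on both strands."""
        query = query.upper()
        if not query or "N" in query:
            return []
        if len(query) < self.k:
            raw = self._scan(query)
        else:
            raw = []
            n = len(query)
            cat = self._cat
            offsets = self._offsets
            codes = self._codes
            for strand, q in (("+", query), ("-", revcomp(query))):
                code = self._encode(q[: self.k])
                if code is None:
                    continue
                code = np.uint64(code)  # keep searchsorted on the fast scalar path
                lo = int(np.searchsorted(codes, code, side="left"))
                hi = int(np.searchsorted(codes, code, side="right"))
                for gpos in self._positions[lo:hi].tolist():
                    ci = int(np.searchsorted(offsets, gpos, side="right")) - 1
                    if gpos + n > offsets[ci + 1]:
                        continue
                    if cat[gpos : gpos + n] == q:
                        raw.append((ci, int(gpos - offsets[ci]), strand))
            raw.sort()
        return [Placement(self._names[ci], pos, strand) for ci, pos, strand in raw]


@dataclass
class AssignmentResult:
    """Per-read genome-of-origin calls plus the aggregate counts."""

    read_ids: list[str]
    calls: list[str]  # TEST / SPIKE / AMBIGUOUS / UNMAPPED, aligned to read_ids
    placements: list[Placement | None]
    C_endo: int
    C_spike: int
    n_ambiguous: int
    n_unmapped: int
    contig_lengths: dict[str, int] = field(default_factory=dict)
    origin_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.C_endo + self.C_spike + self.n_ambiguous + self.n_unmapped
        if total != len(self.read_ids):
            raise ValueError(
                f"count conservation violated: {total} != {len(self.read_ids)}"
            )

    @property
    def per_read(self) -> dict[str, str]:
        return dict(zip(self.read_ids, self.calls))

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def assigned(self) -> Iterable[tuple[str, Placement, str]]:
        """(read_id, placement, origin) for uniquely assigned reads."""
        for rid, call, pl in zip(self.read_ids, self.calls, self.placements):
            if call in (TEST, SPIKE):
                yield rid, pl, call


def _pack_read_chunks(
    codes2: np.ndarray, chunk_offsets: list[int], k: int
) -> np.ndarray:
    """Pack k-base windows of a (n_reads, read_len) 2-bit code matrix."""
    out = np.empty((len(chunk_offsets), codes2.shape[0]), dtype=np.uint64)
    for oi, off in enumerate(chunk_offsets):
        value = np.zeros(codes2.shape[0], dtype=np.uint64)
        for j in range(off, off + k):
            value = (value << np.uint64(2)) | codes2[:, j].astype(np.uint64)
        out[oi] = value
    return out


def _batch_placements(
    index: ExactIndex, sequences: list[str], read_length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized placement search for N-free, equal-length reads.

    Returns (hit counts per read, and for reads with exactly one placement:
    read indices, global genome positions, strand codes 0='+'/1='-').
    Exactly equivalent to calling ``locate`` per read: seeds come from the
    sorted code table; candidates are verified by comparing packed codes of
    covering k-windows of the genome, which together tile the full read.
    """
    k = index.k
    n = len(sequences)
    mat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes2 = _CODE_LUT[mat.reshape(n, read_length)]
    # complement in 2-bit space is XOR 3 (A<->T, C<->G)
    rev2 = codes2[:, ::-1] ^ 3
    chunk_offsets = list(range(0, read_length - k + 1, k))
    if chunk_offsets[-1] != read_length - k:
        chunk_offsets.append(read_length - k)

    all_read_idx = []
    all_gpos = []
    all_strand = []
    offsets = index._offsets
    for strand_code, chunk_codes in (
        (0, _pack_read_chunks(codes2, chunk_offsets, k)),
        (1, _pack_read_chunks(rev2, chunk_offsets, k)),
    ):
        seed = chunk_codes[0]
        lo = np.searchsorted(index._codes, seed, side="left")
        hi = np.searchsorted(index._codes, seed, side="right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total == 0:
            continue
        # gather positions[lo_i : hi_i] for every read in one shot
        flat = np.arange(total)
        base = np.repeat(np.cumsum(cnt) - cnt, cnt)
        read_idx = np.repeat(np.arange(n), cnt)
        gpos = index._positions[np.repeat(lo, cnt) + (flat - base)]
        # full read must stay inside one contig
        ci = np.searchsorted(offsets, gpos, side="right") - 1
        keep = gpos + read_length <= offsets[ci + 1]
        read_idx, gpos = read_idx[keep], gpos[keep]
        ok = np.ones(len(gpos), dtype=bool)
        for oi, off in enumerate(chunk_offsets):
            at = gpos + off
            ok &= index._nfree[at] & (index._packed_all[at] == chunk_codes[oi][read_idx])
        all_read_idx.append(read_idx[ok])
        all_gpos.append(gpos[ok])
        all_strand.append(np.full(int(ok.sum()), strand_code, dtype=np.int8))

    if not all_read_idx:
        empty = np.empty(0, dtype=np.int64)
        return np.zeros(n, dtype=np.int64), empty, empty, empty.astype(np.int8)
    read_idx = np.concatenate(all_read_idx)
    gpos = np.concatenate(all_gpos)
    strand = np.concatenate(all_strand)
    counts = np.bincount(read_idx, minlength=n)
    unique = counts[read_idx] == 1
    return counts, read_idx[unique], gpos[unique], strand[unique]


def assign_reads(
    reads: Sequence[Read], index: ExactIndex, origin_of: dict[str, str] | None = None
) -> AssignmentResult:
    """Classify reads by unique exact placement on the hybrid reference."""
    if origin_of is None:
        origin_of = index.origin_of
    if len(reads) == 0:
        raise ValueError("assign_reads requires at least one read")
    read_ids = [read.read_id for read in reads]
    calls: list[str] = [UNMAPPED] * len(reads)
    placements: list[Placement | None] = [None] * len(reads)

    clean = [i for i, read in enumerate(reads) if "N" not in read.sequence]
    lengths = {len(reads[i].sequence) for i in clean}
    if clean and len(lengths) == 1 and (length := lengths.pop()) >= index.k:
        counts, uniq_idx, gpos, strand = _batch_placements(
            index, [reads[i].sequence for i in clean], length
        )
        offsets = index._offsets
        ci = np.searchsorted(offsets, gpos, side="right") - 1
        local = gpos - offsets[ci]
        for i, cnt in zip(clean, counts.tolist()):
            if cnt > 1:
                calls[i] = AMBIGUOUS
        strands = "+-"
        for j, c, pos, st in zip(
            uniq_idx.tolist(), ci.tolist(), local.tolist(), strand.tolist()
        ):
            i = clean[j]
            contig = index._names[c]
            calls[i] = origin_of[contig]
            placements[i] = Placement(contig, pos, strands[st])
    else:
        for i in clean:
            hits = index.locate(reads[i].sequence)
            if len(hits) == 1:
                calls[i] = origin_of[hits[0].contig]
                placements[i] = hits[0]
            elif len(hits) > 1:
                calls[i] = AMBIGUOUS

    c_endo = calls.count(TEST)
    c_spike = calls.count(SPIKE)
    n_amb = calls.count(AMBIGUOUS)
    return AssignmentResult(
        read_ids=read_ids,
        calls=calls,
        placements=placements,
        C_endo=c_endo,
        C_spike=c_spike,
        n_ambiguous=n_amb,
        n_unmapped=len(reads) - c_endo - c_spike - n_amb,
        contig_lengths=index.hybrid.contig_lengths,
        origin_of=dict(origin_of),
    )


def counts_from_contig_table(path: str, origin_of: dict[str, str]) -> tuple[int, int]:
    """C_endo, C_spike from a per-contig mapped-read summary table.

    Expects the 4-column layout emitted by ``samtools idxstats``:
    contig, contig_length, n_mapped, n_unmapped (tab-separated, no header).
    Contigs absent from ``origin_of`` (e.g. ``*``) are ignored with a log.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "contig_length", "n_mapped", "n_unmapped"],
        dtype={"contig": str},
    )
    c_endo = c_spike = 0
    n_known = 0
    for contig, n_mapped in zip(table["contig"], table["n_mapped"]):
        origin = origin_of.get(contig)
        if origin is None:
            logger.info("ignoring unrecognized contig %r in %s", contig, path)
            continue
        n_known += 1
        if origin == TEST:
            c_endo += int(n_mapped)
        else:
            c_spike += int(n_mapped)
    if n_known == 0:
        raise ValueError(f"no recognizable contigs in count table {path}")
    if c_spike == 0:
        logger.warning("count table %s has zero spike-in reads; Q will be 0", path)
    return c_endo, c_spike


def write_contig_table(result: AssignmentResult, path: str) -> None:
    """Write an idxstats-style per-contig summary of an assignment."""
    mapped = {name: 0 for name in result.contig_lengths}
    for _rid, pl, _origin in result.assigned():
        mapped[pl.contig] += 1
    with open(path, "w") as fh:
        for name, length in result.contig_lengths.items():
            fh.write(f"{name}\t{length}\t{mapped[name]}\t0\n")
        fh.write(f"*\t0\t0\t{result.n_ambiguous + result.n_unmapped}\n")


def assignable_fraction(
    hybrid: HybridReference,
    snpmap: SnpMap,
    read_length: int,
    max_enumerate: int = 500_000,
    n_samples: int = 20_000,
    seed: int = 0,
) -> float:
    """Fraction of read-length windows that are SNP-informative and unique.

    Enumerates every window start on every contig (both genomes) when the
    total is small; otherwise samples windows with a fixed seed.  A window
    counts when it contains at least one SNP position and its sequence has
    exactly one exact occurrence in the hybrid.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    for contig in hybrid.contigs:
        if read_length > len(contig.sequence):
            raise ValueError(
                f"read_length {read_length} exceeds contig {contig.name!r} length"
            )
    index = ExactIndex(hybrid, read_length_hint=read_length)
    positions = snpmap.positions_by_chrom()

    windows: list[tuple[int, str, np.ndarray, int]] = []
    total_windows = 0
    from .snpmap import split_contig_name

    per_contig = []
    for ci, contig in enumerate(hybrid.contigs):
        _strain, chrom = split_contig_name(contig.name)
        snp_pos = positions.get(chrom, np.empty(0, dtype=np.int64))
        n_starts = len(contig.sequence) - read_length + 1
        per_contig.append((ci, contig.sequence, snp_pos, n_starts))
        total_windows += n_starts

    rng = np.random.default_rng(seed)
    if total_windows <= max_enumerate:
        starts_iter = (
            (ci, seq, snp_pos, start)
            for ci, seq, snp_pos, n_starts in per_contig
            for start in range(n_starts)
        )
        n_total = total_windows
    else:
        offsets = np.cumsum([0] + [n for *_x, n in per_contig])
        draws = rng.integers(0, total_windows, size=n_samples)
        chosen = []
        for d in draws:
            ci = int(np.searchsorted(offsets, d, side="right")) - 1
            _i, seq, snp_pos, _n = per_contig[ci]
            chosen.append((ci, seq, snp_pos, int(d - offsets[ci])))
        starts_iter = iter(chosen)
        n_total = n_samples

    n_good = 0
    for _ci, seq, snp_pos, start in starts_iter:
        i = np.searchsorted(snp_pos, start, side="left")
        has_snp = i < len(snp_pos) and snp_pos[i] < start + read_length
        if not has_snp:
            continue
        if len(index.locate(seq[start : start + read_length])) == 1:
            n_good += 1
    return n_good / n_total


# ---------------------------------------------------------------------------
# FASTQ I/O (single-end; qualities ignored)


def read_fastq(path: str) -> list[Read]:
    from Bio import SeqIO

    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_fastq(path: str, reads: Sequence[Read]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
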