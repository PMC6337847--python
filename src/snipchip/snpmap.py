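"""Hybrid two-strain references and SNP maps.

The spike-in strategy implemented here distinguishes reads from two
same-species strains purely through single-nucleotide differences.  This
module builds the concatenated hybrid reference both strains are mapped
against, derives or loads the SNP map that tells the strains apart, and
provides SNP-density diagnostics.

Coordinates are 0-based half-open everywhere in memory; VCF input is
converted from its 1-based convention on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .tracks import PeakSet

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
SNP_BASES = frozenset("ACGT")

TEST = "test"
SPIKE = "spike"


@dataclass
class StrainGenome:
    """A strain assembly: ordered (chromosome name, sequence) pairs."""

    strain_id: str
    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if "_" in self.strain_id:
            raise ValueError(
                "strain_id must not contain '_' (reserved for hybrid contig naming)"
            )
        if not self.chromosomes:
            raise ValueError(f"genome {self.strain_id!r} has no chromosomes")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in {self.strain_id!r}")
        normalized = []
        for name, seq in self.chromosomes:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"chromosome {name!r} has invalid bases: {bad}")
            if set(seq) == {"N"}:
                raise ValueError(f"chromosome {name!r} is all-N")
            normalized.append((name, seq))
        self.chromosomes = normalized

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def sequence_of(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)


@dataclass(frozen=True)
class HybridContig:
    name: str
    sequence: str
    origin: str  # TEST or SPIKE


@dataclass
class HybridReference:
    """Concatenation of the test and spike-in assemblies.

    Contigs are named ``<strain_id>_<chrom>`` so per-contig count tables
    produced by external aligners remain self-describing; the genome of
    origin of each contig is also carried explicitly.
    """

    contigs: list[HybridContig]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("hybrid contig names must be globally unique")
        for c in self.contigs:
            if c.origin not in (TEST, SPIKE):
                raise ValueError(f"bad origin {c.origin!r} for contig {c.name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(c.sequence) for c in self.contigs)

    @property
    def origin_of(self) -> dict[str, str]:
        return {c.name: c.origin for c in self.contigs}

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.name: len(c.sequence) for c in self.contigs}

    def chrom_lengths(self, genome_id: str) -> dict[str, int]:
        """Chromosome name -> length for one side of the hybrid."""
        out = {}
        for c in self.contigs:
            if c.origin == genome_id:
                out[split_contig_name(c.name)[1]] = len(c.sequence)
        return out


def split_contig_name(contig: str) -> tuple[str, str]:
    """Split ``<strain_id>_<chrom>`` into its parts."""
    if "_" not in contig:
        raise ValueError(f"contig name {contig!r} lacks a strain prefix")
    strain, chrom = contig.split("_", 1)
    return strain, chrom


@dataclass(frozen=True)
class SnpRecord:
    """One position distinguishing the colinear strain pair."""

    chrom: str
    pos: int  # 0-based
    allele_test: str
    allele_spike: str

    def __post_init__(self) -> None:
        if self.allele_test not in SNP_BASES or self.allele_spike not in SNP_BASES:
            raise ValueError(f"alleles must be in ACGT: {self}")
        if self.allele_test == self.allele_spike:
            raise ValueError(f"alleles must differ: {self}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self}")


@dataclass
class SnpMap:
    """Sorted collection of strain-distinguishing SNPs."""

    records: list[SnpRecord]
    genome_length: int | None = None
    _by_chrom: dict[str, np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        seen = set()
        for r in self.records:
            key = (r.chrom, r.pos)
            if key in seen:
                raise ValueError(f"duplicate SNP at {key}")
            seen.add(key)
        self._by_chrom = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def divergence(self) -> float:
        if not self.genome_length:
            raise ValueError("genome_length unknown; divergence undefined")
        return len(self.records) / self.genome_length

    @property
    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.records})

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted SNP position array per chromosome (cached)."""
        if self._by_chrom is None:
            by: dict[str, list[int]] = {}
            for r in self.records:
                by.setdefault(r.chrom, []).append(r.pos)
            self._by_chrom = {c: np.asarray(p, dtype=np.int64) for c, p in by.items()}
        return self._by_chrom


# ---------------------------------------------------------------------------
# operations


def build_hybrid_reference(test: StrainGenome, spike: StrainGenome) -> HybridReference:
    """Concatenate the two assemblies; test contigs first."""
    if test.strain_id == spike.strain_id:
        raise ValueError("test and spike-in strain_ids must differ")
    contigs = [
        HybridContig(f"{test.strain_id}_{name}", seq, TEST)
        for name, seq in test.chromosomes
    ]
    contigs += [
        HybridContig(f"{spike.strain_id}_{name}", seq, SPIKE)
        for name, seq in spike.chromosomes
    ]
    return HybridReference(contigs)


def derive_snp_map(test: StrainGenome, spike: StrainGenome) -> SnpMap:
    """Positionwise SNPs between a colinear, indel-free genome pair.

    Only valid when both genomes share chromosome names and lengths; real
    divergent assemblies need an externally produced VCF
    (see :func:`load_snp_map_vcf`).
    """
    if test.chrom_names != spike.chrom_names:
        raise ValueError(
            "chromosome names differ between genomes; for non-colinear pairs "
            "supply a SNP VCF via load_snp_map_vcf"
        )
    records: list[SnpRecord] = []
    total = 0
    n_code = ord("N")
    for (name, seq_t), (_, seq_s) in zip(test.chromosomes, spike.chromosomes):
        if len(seq_t) != len(seq_s):
            raise ValueError(
                f"length mismatch on {name!r} ({len(seq_t)} vs {len(seq_s)}); "
                "for non-colinear pairs supply a SNP VCF via load_snp_map_vcf"
            )
        total += len(seq_t)
        a = np.frombuffer(seq_t.encode("ascii"), dtype=np.uint8)
        b = np.frombuffer(seq_s.encode("ascii"), dtype=np.uint8)
        diff = np.nonzero((a != b) & (a != n_code) & (b != n_code))[0]
        for pos in diff.tolist():
            records.append(SnpRecord(name, pos, seq_t[pos], seq_s[pos]))
    return SnpMap(records, genome_length=total)


def load_snp_map_vcf(path: str, genome_length: int | None = None) -> SnpMap:
    """Load a SNP map from a VCF (REF = test allele, single ALT = spike allele).

    Indels and multiallelic records are skipped with a logged count.
    Positions are converted from VCF's 1-based to 0-based.
    """
    import pysam

    records: list[SnpRecord] = []
    n_skipped = 0
    last: tuple[str, int] | None = None
    with pysam.VariantFile(path) as vcf:
        if genome_length is None and vcf.header.contigs:
            lengths = [c.length for c in vcf.header.contigs.values()]
            if all(l is not None for l in lengths):
                genome_length = int(sum(lengths))
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in SNP_BASES
                or alts[0] not in SNP_BASES
            ):
                n_skipped += 1
                continue
            if last is not None and (rec.chrom, rec.start) < last and rec.chrom == last[0]:
                raise ValueError(
                    f"unsorted VCF: {rec.chrom}:{rec.pos} after {last[0]}:{last[1] + 1}"
                )
            last = (rec.chrom, rec.start)
            records.append(SnpRecord(rec.chrom, rec.start, rec.ref, alts[0]))
    if n_skipped:
        logger.info("skipped %d non-SNP (indel/multiallelic) VCF records", n_skipped)
    if not records:
        logger.warning("VCF %s contained no usable SNP records", path)
    return SnpMap(records, genome_length=genome_length)


def spacing_stats(snpmap: SnpMap) -> dict:
    """Median distance between consecutive SNPs, globally and per chromosome.

    Distances are only taken within a chromosome; a chromosome with a single
    SNP contributes no distances and reports NaN.
    """
    if not snpmap.records:
        raise ValueError("spacing_stats requires a non-empty SnpMap")
    per_chrom: dict[str, float] = {}
    all_dists: list[np.ndarray] = []
    for chrom, positions in snpmap.positions_by_chrom().items():
        if len(positions) < 2:
            logger.warning("chromosome %s has a single SNP; no spacing", chrom)
            per_chrom[chrom] = float("nan")
            continue
        d = np.diff(positions)
        all_dists.append(d)
        per_chrom[chrom] = float(np.median(d))
    if not all_dists:
        raise ValueError("no chromosome has >= 2 SNPs; spacing undefined")
    global_median = float(np.median(np.concatenate(all_dists)))
    return {
        "global_median": global_median,
        "per_chromosome": per_chrom,
        "count": len(snpmap.records),
    }


def snps_in_intervals(snpmap: SnpMap, peaks: "PeakSet") -> SnpMap:
    """Subset of the map falling inside peak intervals (test coordinates)."""
    known = set(snpmap.chroms)
    for chrom, *_ in peaks.intervals:
        if chrom not in known:
            raise ValueError(f"peak references unknown chromosome {chrom!r}")
    starts_by: dict[str, np.ndarray] = {}
    ends_by: dict[str, np.ndarray] = {}
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _name, _score in peaks.intervals:
        by.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by.items():
        ivals.sort()
        starts_by[chrom] = np.asarray([s for s, _ in ivals], dtype=np.int64)
        ends_by[chrom] = np.asarray([e for _, e in ivals], dtype=np.int64)
    selected = []
    for r in snpmap.records:
        if r.chrom not in starts_by:
            continue
        starts = starts_by[r.chrom]
        i = int(np.searchsorted(starts, r.pos, side="right")) - 1
        if i >= 0 and r.pos < ends_by[r.chrom][i]:
            selected.append(r)
    return SnpMap(selected, genome_length=snpmap.genome_length)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def read_fasta(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, path, "fasta")


def genome_from_fasta(path: str, strain_id: str) -> StrainGenome:
    return StrainGenome(strain_id, read_fasta(path))


def hybrid_to_fasta(hybrid: HybridReference, path: str) -> None:
    write_fasta(path, [(c.name, c.sequence) for c in hybrid.contigs])


def write_snp_tsv(snpmap: SnpMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tallele_test\tallele_spike\n")
        for r in snpmap.records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.allele_test}\t{r.allele_spike}\n")


def read_snp_tsv(path: str, genome_length: int | None = None) -> SnpMap:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"unexpected SNP TSV header: {header!r}")
        for line in fh:
            chrom, pos, a_t, a_s = line.rstrip("\n").split("\t")
            records.append(SnpRecord(chrom, int(pos), a_t, a_s))
    return SnpMap(records, genome_length=genome_length)
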