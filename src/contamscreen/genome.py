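"""Assembly containers, FASTA I/O, size filters, pseudo-reads and segments.

Coordinates are 0-based half-open throughout.  Pseudo-reads are the
250-nt non-overlapping windows fed to the read classifiers; segments are the
10-kb windows used for composition binning and genome maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID = set("ACGTN")
_IUPAC = re.compile(r"[RYSWKMBDHVU]")

# assemblies outside this total-length window are atypical for the focal group
MIN_TYPICAL_LENGTH = 500_000
MAX_TYPICAL_LENGTH = 15_000_000


class FastaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Scaffold:
    scaffold_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    assembly_id: str
    scaffolds: list[Scaffold]

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise FastaFormatError(f"assembly {self.assembly_id!r} has no scaffolds")
        ids = [s.scaffold_id for s in self.scaffolds]
        if len(set(ids)) != len(ids):
            raise FastaFormatError(f"duplicate scaffold id in {self.assembly_id!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def scaffold(self, scaffold_id: str) -> Scaffold:
        for s in self.scaffolds:
            if s.scaffold_id == scaffold_id:
                return s
        raise KeyError(scaffold_id)


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds_ge_1000: int
    total_length_ge_1000: int
    gc_percent: float
    n_fraction: float
    too_small: bool
    too_large: bool


@dataclass(frozen=True)
class PseudoRead:
    read_id: str
    scaffold_id: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class Segment:
    segment_id: str
    scaffold_id: str
    start: int
    end: int
    sequence: str


def clean_sequence(seq: str, where: str = "") -> str:
    """Upper-case and collapse IUPAC ambiguity codes to N; reject junk."""
    seq = seq.upper()
    seq = _IUPAC.sub("N", seq)
    if not set(seq) <= VALID:
        bad = sorted(set(seq) - VALID)
        raise FastaFormatError(f"illegal characters {bad} in {where or 'sequence'}")
    return seq


def read_fasta(path, assembly_id: Optional[str] = None) -> Assembly:
    scaffolds = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = clean_sequence(str(rec.seq), where=rec.id)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        scaffolds.append(Scaffold(rec.id, seq))
    if not scaffolds:
        raise FastaFormatError(f"{path}: no FASTA records")
    if assembly_id is None:
        assembly_id = str(path)
    return Assembly(assembly_id, scaffolds)


def write_fasta(assembly: Assembly, path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.scaffold_id, description="")
        for s in assembly.scaffolds
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def gc_content(sequence: str) -> Optional[float]:
    """GC percentage over non-N bases; None for an all-N/empty sequence."""
    gc = sequence.count("G") + sequence.count("C")
    denom = gc + sequence.count("A") + sequence.count("T")
    if denom == 0:
        return None
    return 100.0 * gc / denom


def compute_stats(assembly: Assembly, min_scaffold: int = 1000) -> AssemblyStats:
    """Assembly statistics over scaffolds >= ``min_scaffold`` nt.

    The too-small / too-large flags implement the typical-assembly size
    filter (>=500 kbp and <=15,000 kbp of sequence in scaffolds >=1 kb).
    """
    big = [s for s in assembly.scaffolds if len(s) >= min_scaffold]
    total = sum(len(s) for s in big)
    seq = "".join(s.sequence for s in big)
    gc = gc_content(seq)
    n_count = seq.count("N")
    return AssemblyStats(
        n_scaffolds_ge_1000=len(big),
        total_length_ge_1000=total,
        gc_percent=gc if gc is not None else float("nan"),
        n_fraction=100.0 * n_count / total if total else float("nan"),
        too_small=total < MIN_TYPICAL_LENGTH,
        too_large=total > MAX_TYPICAL_LENGTH,
    )


def make_pseudoreads(
    assembly: Assembly, read_len: int = 250, min_keep: int = 21
) -> list[PseudoRead]:
    """Tile each scaffold into consecutive ``read_len``-nt windows.

    A trailing partial window is kept only when it is at least ``min_keep``
    nt (the classifier kmer size): shorter tails contain no classifiable
    kmer.
    """
    if not (read_len >= min_keep >= 1):
        raise ValueError("need read_len >= min_keep >= 1")
    reads = []
    for scaf in assembly.scaffolds:
        for i, start in enumerate(range(0, len(scaf), read_len)):
            end = min(start + read_len, len(scaf))
            if end - start < min_keep:
                continue
            reads.append(
                PseudoRead(
                    read_id=f"{scaf.scaffold_id}|{i}",
                    scaffold_id=scaf.scaffold_id,
                    start=start,
                    end=end,
                    sequence=scaf.sequence[start:end],
                )
            )
    return reads


def make_segments(
    assembly: Assembly, seg_len: int = 10_000, min_len: int = 1000
) -> list[Segment]:
    """Cut scaffolds into non-overlapping ``seg_len``-nt segments.

    A trailing remainder shorter than ``seg_len`` is merged into the
    preceding segment of the same scaffold, so only scaffolds shorter than
    ``seg_len`` yield a single sub-length segment; segments shorter than
    ``min_len`` are discarded.
    """
    if seg_len <= min_len:
        raise ValueError("need seg_len > min_len")
    segments = []
    for scaf in assembly.scaffolds:
        n = len(scaf)
        starts = list(range(0, n, seg_len))
        # merge a trailing remainder into the previous full segment
        if len(starts) > 1 and n - starts[-1] < seg_len:
            starts.pop()
        for i, start in enumerate(starts):
            end = starts[i + 1] if i + 1 < len(starts) else n
            if end - start < min_len:
                continue
            segments.append(
                Segment(
                    segment_id=f"{scaf.scaffold_id}:{start}-{end}",
                    scaffold_id=scaf.scaffold_id,
                    start=start,
                    end=end,
                    sequence=scaf.sequence[start:end],
                )
            )
    return segments


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_stats_tsv(stats_by_assembly: dict[str, AssemblyStats], path) -> None:
    """One row per assembly: scaffold/length counts, GC, N fraction, size flags."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#assembly_id\tn_scaffolds_ge_1000\ttotal_length_ge_1000\t"
            "gc_percent\tn_fraction\ttoo_small\ttoo_large\n"
        )
        for aid, st in stats_by_assembly.items():
            fh.write(
                f"{aid}\t{st.n_scaffolds_ge_1000}\t{st.total_length_ge_1000}\t"
                f"{st.gc_percent:.2f}\t{st.n_fraction:.2f}\t"
                f"{int(st.too_small)}\t{int(st.too_large)}\n"
            )
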