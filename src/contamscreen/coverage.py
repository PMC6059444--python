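"""Genome maps, coverage validation, and decontaminated output.

Per-segment records combine classification fractions, GC content, marker
loci and sequencing coverage into the table behind the genome-map
figures; per-class coverage statistics test whether putative contaminant
scaffolds are sequenced at a different depth than genuine ones (foreign
DNA is rarely present in equal proportion); masking or dropping
contaminant-classified regions yields the decontaminated assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import Assembly, PseudoRead, Scaffold, Segment, gc_content, make_segments, revcomp
from .markers import MarkerHit, SsuLocus
from .taxonomy import Label, ReadLabel


class BedGraphError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Stepwise-constant per-scaffold depth intervals (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def mean_depth(self, scaffold_id: str, start: int, end: int) -> float:
        total = 0.0
        for s, e, d in self.intervals.get(scaffold_id, []):
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                total += d * (hi - lo)
        return total / max(end - start, 1)


@dataclass
class SegmentRecord:
    scaffold_id: str
    start: int
    end: int
    gc: Optional[float]
    focal: float
    contaminant: float
    unknown: float
    unclassified: float
    coverage: Optional[float] = None
    markers: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageStats:
    focal_median: float
    focal_iqr: float
    contaminant_median: float
    contaminant_iqr: float
    qcd: float  # assembly-wide quartile coefficient of dispersion


@dataclass(frozen=True)
class DecontamConfig:
    mode: str = "mask"  # "mask" | "drop"
    scaffold_drop_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("mask", "drop"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not 0.0 < self.scaffold_drop_threshold <= 1.0:
            raise ValueError("scaffold_drop_threshold must be in (0, 1]")


def segment_report(
    assembly: Assembly,
    labelled_reads: Sequence[tuple[PseudoRead, ReadLabel]],
    marker_hits: Sequence[MarkerHit | SsuLocus] = (),
    coverage: Optional[CoverageTrack] = None,
    seg_len: int = 10_000,
    min_len: int = 1000,
) -> list[SegmentRecord]:
    """Per-segment classification/GC/coverage records, ordered for plotting.

    Segments are grouped by scaffold and scaffolds ordered by ascending
    mean GC.  A pseudo-read spanning a segment boundary contributes to
    each segment proportionally to its overlap.
    """
    segments = make_segments(assembly, seg_len=seg_len, min_len=min_len)
    by_scaffold: dict[str, list[Segment]] = {}
    for seg in segments:
        by_scaffold.setdefault(seg.scaffold_id, []).append(seg)
    records: dict[str, SegmentRecord] = {}
    weights: dict[str, dict[Label, float]] = {}
    for seg in segments:
        rec = SegmentRecord(
            scaffold_id=seg.scaffold_id,
            start=seg.start,
            end=seg.end,
            gc=gc_content(seg.sequence),
            focal=0.0,
            contaminant=0.0,
            unknown=0.0,
            unclassified=0.0,
            coverage=(
                coverage.mean_depth(seg.scaffold_id, seg.start, seg.end)
                if coverage is not None
                else None
            ),
        )
        records[seg.segment_id] = rec
        weights[seg.segment_id] = {lab: 0.0 for lab in Label}
    for read, rl in labelled_reads:
        for seg in by_scaffold.get(read.scaffold_id, []):
            lo, hi = max(seg.start, read.start), min(seg.end, read.end)
            if hi > lo:
                weights[seg.segment_id][rl.label] += hi - lo
    for seg in segments:
        w = weights[seg.segment_id]
        total = sum(w.values())
        rec = records[seg.segment_id]
        if total > 0:
            rec.focal = 100.0 * w[Label.FOCAL] / total
            rec.contaminant = 100.0 * w[Label.CONTAMINANT] / total
            rec.unknown = 100.0 * w[Label.UNKNOWN] / total
            rec.unclassified = 100.0 * w[Label.UNCLASSIFIED] / total
        else:
            rec.unclassified = 100.0
    for mh in marker_hits:
        for seg in by_scaffold.get(mh.scaffold_id, []):
            if mh.start < seg.end and mh.end > seg.start:
                records[seg.segment_id].markers.append(mh)
    # scaffolds sorted by ascending mean GC, segments in genome order
    def scaffold_gc(sid: str) -> float:
        segs = by_scaffold[sid]
        vals = [(records[s.segment_id].gc, s.end - s.start) for s in segs]
        num = sum((g or 0.0) * w for g, w in vals)
        den = sum(w for g, w in vals if g is not None)
        return num / den if den else 0.0

    ordered_scaffolds = sorted(by_scaffold, key=lambda sid: (scaffold_gc(sid), sid))
    out = []
    for sid in ordered_scaffolds:
        for seg in sorted(by_scaffold[sid], key=lambda s: s.start):
            out.append(records[seg.segment_id])
    return out


def scaffold_label(records: Sequence[SegmentRecord]) -> str:
    """FOCAL / CONTAMINANT / UNDETERMINED from length-weighted classified
    fractions of one scaffold's segment records."""
    focal = sum(r.focal * r.length for r in records)
    contaminant = sum(r.contaminant * r.length for r in records)
    if contaminant > focal:
        return "CONTAMINANT"
    if focal > contaminant:
        return "FOCAL"
    return "UNDETERMINED"


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    return float(q1), float(q3)


def coverage_stats(
    records: Sequence[SegmentRecord],
    scaffold_labels: dict[str, str],
) -> CoverageStats:
    """Per-class median/IQR of segment coverages plus assembly-wide QCD."""
    cov = [r.coverage for r in records]
    if any(c is None for c in cov) or not cov:
        raise ValueError("coverage required for coverage_stats")
    all_cov = np.asarray(cov, dtype=float)
    by_class: dict[str, list[float]] = {"FOCAL": [], "CONTAMINANT": []}
    for r in records:
        cls = scaffold_labels.get(r.scaffold_id)
        if cls in by_class:
            by_class[cls].append(float(r.coverage))  # type: ignore[arg-type]

    def med_iqr(values: list[float]) -> tuple[float, float]:
        if not values:
            return float("nan"), float("nan")
        arr = np.asarray(values)
        q1, q3 = _quartiles(arr)
        return float(np.median(arr)), q3 - q1

    f_med, f_iqr = med_iqr(by_class["FOCAL"])
    c_med, c_iqr = med_iqr(by_class["CONTAMINANT"])
    q1, q3 = _quartiles(all_cov)
    qcd = (q3 - q1) / (q3 + q1) if (q3 + q1) > 0 else float("nan")
    return CoverageStats(f_med, f_iqr, c_med, c_iqr, qcd)


# -- bedGraph I/O and the naive exact mapper -----------------------------


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(track.intervals):
            for start, end, depth in track.intervals[sid]:
                fh.write(f"{sid}\t{start}\t{end}\t{depth:g}\n")


def read_bedgraph(path, assembly: Optional[Assembly] = None) -> CoverageTrack:
    """Read 4-column bedGraph (0-based half-open), validating against the
    assembly's scaffold bounds when given."""
    lengths = (
        {s.scaffold_id: len(s) for s in assembly.scaffolds} if assembly else None
    )
    track = CoverageTrack()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            sid, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start or depth < 0:
                raise BedGraphError(f"{path}:{lineno}: bad interval")
            if lengths is not None:
                if sid not in lengths:
                    raise BedGraphError(f"{path}:{lineno}: unknown scaffold {sid!r}")
                if end > lengths[sid]:
                    raise BedGraphError(
                        f"{path}:{lineno}: interval end {end} beyond scaffold length {lengths[sid]}"
                    )
            track.intervals.setdefault(sid, []).append((start, end, depth))
    for sid in track.intervals:
        track.intervals[sid].sort()
    return track


def depth_array_to_track(depths: dict[str, np.ndarray]) -> CoverageTrack:
    """Collapse per-base depth arrays into stepwise intervals."""
    track = CoverageTrack()
    for sid, arr in depths.items():
        arr = np.asarray(arr, dtype=float)
        if len(arr) == 0:
            continue
        change = np.flatnonzero(np.diff(arr) != 0) + 1
        starts = np.r_[0, change]
        ends = np.r_[change, len(arr)]
        track.intervals[sid] = [
            (int(s), int(e), float(arr[s])) for s, e in zip(starts, ends)
        ]
    return track


def coverage_from_reads(
    assembly: Assembly,
    reads: Iterable[tuple[str, str]],
    index_k: int = 16,
) -> CoverageTrack:
    """Naive exact mapper: each read is placed at its unique exact match
    (either strand); multi-mapping and non-matching reads are discarded.

    Intended for the simulator's error-free reads; reads with errors in
    the seed prefix simply fail to map.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for scaf in assembly.scaffolds:
        seq = scaf.sequence
        for i in range(0, max(len(seq) - index_k + 1, 0)):
            index.setdefault(seq[i : i + index_k], []).append((scaf.scaffold_id, i))
    depths = {s.scaffold_id: np.zeros(len(s), dtype=np.int32) for s in assembly.scaffolds}
    seqs = {s.scaffold_id: s.sequence for s in assembly.scaffolds}
    for _read_id, seq in reads:
        placements = []
        for oriented in (seq, revcomp(seq)):
            if len(oriented) < index_k:
                continue
            for sid, pos in index.get(oriented[:index_k], []):
                if seqs[sid][pos : pos + len(oriented)] == oriented:
                    placements.append((sid, pos, len(oriented)))
        if len(placements) != 1:
            continue
        sid, pos, ln = placements[0]
        depths[sid][pos : pos + ln] += 1
    return depth_array_to_track({k: v for k, v in depths.items()})


# -- decontamination -----------------------------------------------------


def decontaminate(
    assembly: Assembly,
    labelled_reads: Sequence[tuple[PseudoRead, ReadLabel]],
    config: DecontamConfig = DecontamConfig(),
    marker_hits: Optional[Sequence[MarkerHit | SsuLocus]] = None,
) -> Assembly:
    """Mask contaminant-classified pseudo-read intervals with N, or drop
    majority-contaminant scaffolds entirely (masking the survivors).

    ``marker_hits`` may supply the pipeline's foreign-classified marker
    loci (SSU rRNA, ribosomal proteins), which are masked as well: rRNA
    regions carry no protein-level signal, so without this the
    pseudo-read labels systematically spare foreign rRNA.  UNKNOWN
    reads are never masked: genuinely transferred genes tend to land in
    the classified-yet-uninformative fraction and masking them would
    destroy real signal.  Mask mode conserves scaffold count and every
    scaffold's length.
    """
    by_scaffold: dict[str, list[tuple[PseudoRead, ReadLabel]]] = {}
    for read, rl in labelled_reads:
        by_scaffold.setdefault(read.scaffold_id, []).append((read, rl))
    foreign_markers: dict[str, list[tuple[int, int]]] = {}
    for mh in marker_hits or ():
        label = getattr(mh, "label", None)
        if label is not None and label.label is Label.CONTAMINANT:
            foreign_markers.setdefault(mh.scaffold_id, []).append((mh.start, mh.end))
    out: list[Scaffold] = []
    for scaf in assembly.scaffolds:
        pairs = by_scaffold.get(scaf.scaffold_id, [])
        if config.mode == "drop":
            focal = sum(r.end - r.start for r, rl in pairs if rl.label is Label.FOCAL)
            contam = sum(r.end - r.start for r, rl in pairs if rl.label is Label.CONTAMINANT)
            classified = focal + contam
            if classified > 0 and contam / classified >= config.scaffold_drop_threshold:
                continue
        intervals = [
            (r.start, r.end) for r, rl in pairs if rl.label is Label.CONTAMINANT
        ] + foreign_markers.get(scaf.scaffold_id, [])
        if not intervals:
            out.append(scaf)
            continue
        chars = list(scaf.sequence)
        for s, e in intervals:
            chars[s:e] = "N" * (min(e, len(chars)) - s)
        out.append(Scaffold(scaf.scaffold_id, "".join(chars)))
    return Assembly(assembly.assembly_id + ".decontam", out)


def write_segment_report(records: Sequence[SegmentRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#scaffold_id\tstart\tend\tgc\tfocal\tcontaminant\tunknown\t"
            "unclassified\tcoverage\tn_markers\n"
        )
        for r in records:
            gc = f"{r.gc:.2f}" if r.gc is not None else "NA"
            cov = f"{r.coverage:.2f}" if r.coverage is not None else "NA"
            fh.write(
                f"{r.scaffold_id}\t{r.start}\t{r.end}\t{gc}\t{r.focal:.2f}\t"
                f"{r.contaminant:.2f}\t{r.unknown:.2f}\t{r.unclassified:.2f}\t"
                f"{cov}\t{len(r.markers)}\n"
            )


def plot_genome_map(records: Sequence[SegmentRecord], path, title: str = "") -> None:
    """Genome map: classification band, GC curve, marker symbols, and the
    coverage curve when present (one panel per track)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"focal": "#2ca02c", "contaminant": "#d62728", "unknown": "#999999"}
    n = len(records)
    has_cov = any(r.coverage is not None for r in records)
    fig, axes = plt.subplots(
        2 if has_cov else 1, 1, figsize=(max(6, n * 0.12), 4.5), sharex=True,
        squeeze=False,
    )
    ax = axes[0][0]
    xs = np.arange(n)
    bottoms = np.zeros(n)
    for key, color in colors.items():
        vals = np.array([getattr(r, key if key != "unknown" else "unknown") for r in records])
        ax.bar(xs, vals, bottom=bottoms, width=1.0, color=color, label=key)
        bottoms += vals
    gc_vals = [r.gc if r.gc is not None else np.nan for r in records]
    ax2 = ax.twinx()
    ax2.plot(xs, gc_vals, color="#1f77b4", lw=1.2, label="GC %")
    ax2.set_ylabel("GC %")
    for i, r in enumerate(records):
        for m in r.markers:
            marker = "o" if isinstance(m, SsuLocus) else "s"
            lab = getattr(m, "label", None)
            col = colors["contaminant"] if lab and lab.label is Label.CONTAMINANT else colors["focal"]
            ax.plot(i, 105, marker, color=col, ms=4, clip_on=False)
    boundaries = [i for i in range(1, n) if records[i].scaffold_id != records[i - 1].scaffold_id]
    for b in boundaries:
        ax.axvline(b - 0.5, color="k", lw=0.3)
    ax.set_ylim(0, 100)
    ax.set_ylabel("classified fraction (%)")
    ax.legend(loc="lower left", fontsize=7)
    if title:
        ax.set_title(title)
    if has_cov:
        axc = axes[1][0]
        axc.plot(xs, [r.coverage for r in records], color="#e07070", lw=1.2)
        axc.set_ylabel("coverage")
        for b in boundaries:
            axc.axvline(b - 0.5, color="k", lw=0.3)
    axes[-1][0].set_xlabel("segments (scaffolds by ascending GC)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
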