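"""Marker-gene contamination estimators.

Three estimators interrogate a small number of universal loci instead of
the whole genome:

* SSU rRNA: SSU-like loci are located by approximate nucleotide matching
  against a reference panel, each locus is labelled by its best-hit
  reference taxon, and contamination is foreign loci / predicted loci;
* ribosomal proteins: candidate orthologues are found by six-frame
  translated search against per-family reference panels and labelled by
  the LCA of their three most similar references (identity >= 70%,
  alignment >= 30 aa); contamination is foreign / classified, pooled over
  families;
* single-copy redundancy: with every marker family expected exactly once
  per genome, completeness is the fraction of families seen at least once
  and contamination the summed surplus copies per family (which exceeds
  100% when more than one complete foreign marker set is present).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .alignment import (
    AlignmentParams,
    ProteinDatabase,
    ProteinRecord,
    make_aligner,
    six_frame_translate,
)
from .genome import Assembly, revcomp
from .taxonomy import Label, ReadLabel, TaxonomyTree, UNCLASSIFIED_READ, label_of, lca


@dataclass(frozen=True)
class MarkerReference:
    ref_id: str
    genome_id: str
    taxon_id: str
    sequence: str


@dataclass
class MarkerFamily:
    family_id: str
    kind: str  # "nucleotide" | "protein"
    references: list[MarkerReference]

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"bad family kind {self.kind!r}")


@dataclass
class SsuLocus:
    scaffold_id: str
    start: int
    end: int
    strand: str
    best_ref: Optional[MarkerReference]
    identity: float
    label: ReadLabel = UNCLASSIFIED_READ


@dataclass
class MarkerHit:
    scaffold_id: str
    start: int
    end: int
    strand: str
    family_id: str
    bit_score: float
    # (reference, identity %, alignment length in aa), identity-descending
    neighbours: list[tuple[MarkerReference, float, int]] = field(default_factory=list)
    label: ReadLabel = UNCLASSIFIED_READ


@dataclass(frozen=True)
class MarkerEstimates:
    ssu_total_predicted: int
    ssu_foreign: int
    ssu_contamination: Optional[float]
    rprot_classified: int
    rprot_foreign: int
    rprot_contamination: Optional[float]
    redundancy_completeness: float
    redundancy_contamination: float


# -- SSU rRNA ------------------------------------------------------------


def _edlib_identity(dist: int, ref_len: int, span: int) -> float:
    return 100.0 * (1.0 - dist / max(ref_len, span))


def detect_ssu(
    assembly: Assembly,
    ssu_family: MarkerFamily,
    min_len: int = 300,
    min_identity: float = 70.0,
    max_copies_per_scaffold: int = 8,
) -> list[SsuLocus]:
    """Locate SSU-like loci by infix alignment of references on both strands.

    Each reference is aligned against each scaffold repeatedly, masking
    previous finds, until the identity drops below threshold; overlapping
    calls from different references are merged keeping the best.
    """
    if ssu_family.kind != "nucleotide":
        raise ValueError("SSU family must be nucleotide-kind")
    max_dist_frac = 1.0 - min_identity / 100.0
    calls: list[SsuLocus] = []
    for scaf in assembly.scaffolds:
        for ref in ssu_family.references:
            for strand, query in (("+", ref.sequence), ("-", revcomp(ref.sequence))):
                target = scaf.sequence
                for _ in range(max_copies_per_scaffold):
                    res = edlib.align(
                        query, target, mode="HW", task="locations",
                        k=int(len(query) * max_dist_frac),
                    )
                    if res["editDistance"] < 0 or not res["locations"]:
                        break
                    start, end = res["locations"][0]
                    end += 1  # edlib end is inclusive
                    span = end - start
                    ident = _edlib_identity(res["editDistance"], len(query), span)
                    if span < min_len or ident < min_identity:
                        break
                    calls.append(SsuLocus(scaf.scaffold_id, start, end, strand, ref, ident))
                    target = target[:start] + "#" * span + target[end:]
    return _merge_ssu_calls(calls)


def _merge_ssu_calls(calls: list[SsuLocus]) -> list[SsuLocus]:
    calls = sorted(calls, key=lambda c: (c.scaffold_id, c.start, -c.identity))
    merged: list[SsuLocus] = []
    for call in calls:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.scaffold_id == call.scaffold_id
            and call.start < last.end
        ):
            if call.identity > last.identity:
                call.start = min(call.start, last.start)
                call.end = max(call.end, last.end)
                merged[-1] = call
            else:
                last.end = max(last.end, call.end)
            continue
        merged.append(call)
    return merged


def classify_ssu_loci(
    loci: Sequence[SsuLocus],
    taxonomy: TaxonomyTree,
    min_identity: float = 70.0,
) -> list[SsuLocus]:
    """Label each locus by its best-hit reference taxon (top-1)."""
    for locus in loci:
        if locus.best_ref is None or locus.identity < min_identity:
            locus.label = UNCLASSIFIED_READ
        else:
            locus.label = label_of(taxonomy, locus.best_ref.taxon_id)
    return list(loci)


def ssu_contamination(loci: Sequence[SsuLocus]) -> Optional[float]:
    """Foreign SSU loci / predicted SSU loci, in %; None when none predicted."""
    total = len(loci)
    if total == 0:
        return None
    foreign = sum(1 for l in loci if l.label.label is Label.CONTAMINANT)
    return 100.0 * foreign / total


# -- ribosomal proteins --------------------------------------------------

_STOP_SPLIT = re.compile(r"\*")


def _orf_windows(sequence: str, min_aa: int = 30):
    """Maximal stop-free stretches >= min_aa in all six frames.

    Yields (frame, aa_offset, peptide); aa_offset is the offset of the
    stretch within the frame's translation.
    """
    for frame, pep in six_frame_translate(sequence).items():
        pos = 0
        for part in _STOP_SPLIT.split(pep):
            if len(part) >= min_aa:
                yield frame, pos, part
            pos += len(part) + 1


def _window_nt_coords(frame: int, aa_offset: int, aa_len: int, scaffold_len: int):
    nt_len = 3 * aa_len
    if frame > 0:
        start = (frame - 1) + 3 * aa_offset
        return start, start + nt_len, "+"
    rc_start = (-frame - 1) + 3 * aa_offset
    end = scaffold_len - rc_start
    return end - nt_len, end, "-"


def detect_rprot_orthologues(
    assembly: Assembly,
    families: Sequence[MarkerFamily],
    params: Optional[AlignmentParams] = None,
    min_aa: int = 30,
    min_bit: float = 50.0,
    seed_k: int = 5,
) -> list[MarkerHit]:
    """Find candidate marker orthologues by translated search.

    All six-frame stop-free windows >= ``min_aa`` are searched against the
    pooled family references; a candidate belongs to the family of its
    single best hit (a mutual-best screen against paralogue capture), its
    neighbour list holds its identity to every reference of that family,
    and overlapping candidates on a scaffold are deduplicated keeping the
    best bit score.
    """
    params = params or AlignmentParams()
    prot_families = [f for f in families if f.kind == "protein"]
    pooled = [
        ProteinRecord(f"{fam.family_id}|{ref.ref_id}", ref.genome_id, ref.taxon_id, ref.sequence)
        for fam in prot_families
        for ref in fam.references
    ]
    owner = {}
    for fam in prot_families:
        for ref in fam.references:
            owner[f"{fam.family_id}|{ref.ref_id}"] = (fam, ref)
    db = ProteinDatabase(pooled, seed_k=seed_k)
    aligner = make_aligner(params)
    min_raw = params.raw_for_bits(min_bit)
    hits: list[MarkerHit] = []
    for scaf in assembly.scaffolds:
        for frame, aa_offset, pep in _orf_windows(scaf.sequence, min_aa=min_aa):
            # one stop-free window may span several adjacent genes, so
            # keep searching the remainder around each aligned span
            pending = [(aa_offset, pep)]
            while pending:
                off, piece = pending.pop()
                cand = db.candidates(piece)
                if not cand:
                    continue
                best_idx, best_raw = -1, 0.0
                for idx in cand:
                    raw = aligner.score(piece, db.proteins[idx].sequence)
                    if raw > best_raw or (
                        raw == best_raw
                        and best_idx >= 0
                        and db.proteins[idx].protein_id < db.proteins[best_idx].protein_id
                    ):
                        best_idx, best_raw = idx, raw
                if best_idx < 0 or best_raw < min_raw:
                    continue
                family, _ = owner[db.proteins[best_idx].protein_id]
                best_aln = aligner.align(piece, db.proteins[best_idx].sequence)[0]
                q_blocks = best_aln.aligned[0]
                q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
                aligned_pep = piece[q0:q1]
                neighbours = []
                for ref in family.references:
                    res = _pep_identity(aligned_pep, ref.sequence)
                    if res is not None:
                        neighbours.append((ref, res[0], res[1]))
                neighbours.sort(key=lambda t: (-t[1], -t[2], t[0].ref_id))
                start, end, strand = _window_nt_coords(
                    frame, off + q0, q1 - q0, len(scaf)
                )
                hits.append(
                    MarkerHit(
                        scaffold_id=scaf.scaffold_id,
                        start=start,
                        end=end,
                        strand=strand,
                        family_id=family.family_id,
                        bit_score=params.bit_score(best_raw),
                        neighbours=neighbours,
                    )
                )
                if q0 >= min_aa:
                    pending.append((off, piece[:q0]))
                if len(piece) - q1 >= min_aa:
                    pending.append((off + q1, piece[q1:]))
    return _dedup_marker_hits(hits)


def _pep_identity(query: str, ref: str) -> Optional[tuple[float, int]]:
    """Percent identity and alignment length via fast edit-distance
    alignment of the reference within the query window (or vice versa)."""
    a, b = (query, ref) if len(query) >= len(ref) else (ref, query)
    res = edlib.align(b, a, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return None
    aln_len = len(b)
    identity = 100.0 * (1.0 - res["editDistance"] / aln_len)
    return identity, aln_len


def _dedup_marker_hits(hits: list[MarkerHit], min_overlap: float = 0.5) -> list[MarkerHit]:
    """Collapse candidates whose aligned spans substantially overlap
    (the same locus seen in several frames), keeping the best bit score."""
    hits = sorted(hits, key=lambda h: (-h.bit_score, h.scaffold_id, h.start))
    kept: list[MarkerHit] = []
    for hit in hits:
        duplicate = False
        for other in kept:
            if other.scaffold_id != hit.scaffold_id:
                continue
            ov = min(other.end, hit.end) - max(other.start, hit.start)
            shorter = min(other.end - other.start, hit.end - hit.start)
            if shorter > 0 and ov / shorter >= min_overlap:
                duplicate = True
                break
        if not duplicate:
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.scaffold_id, h.start))


def classify_marker(
    candidate: MarkerHit,
    taxonomy: TaxonomyTree,
    min_identity: float = 70.0,
    min_alnlen: int = 30,
    n_neighbours: int = 3,
) -> ReadLabel:
    """LCA of the candidate's ``n_neighbours`` most similar references.

    Neighbours must reach ``min_identity`` percent identity over at least
    ``min_alnlen`` aligned residues; with none passing, the candidate
    stays unclassified.
    """
    passing = [
        (ref, ident, alen)
        for ref, ident, alen in candidate.neighbours
        if ident >= min_identity and alen >= min_alnlen
    ]
    if not passing:
        return UNCLASSIFIED_READ
    top = passing[:n_neighbours]
    return label_of(taxonomy, lca(taxonomy, {ref.taxon_id for ref, _, _ in top}))


def classify_marker_hits(
    hits: Sequence[MarkerHit],
    taxonomy: TaxonomyTree,
    min_identity: float = 70.0,
    min_alnlen: int = 30,
    n_neighbours: int = 3,
) -> list[MarkerHit]:
    for hit in hits:
        hit.label = classify_marker(hit, taxonomy, min_identity, min_alnlen, n_neighbours)
    return list(hits)


def rprot_contamination(hits: Sequence[MarkerHit]) -> Optional[float]:
    """Foreign / classified marker hits in %, pooled over all families."""
    classified = [h for h in hits if h.label.label is not Label.UNCLASSIFIED]
    if not classified:
        return None
    foreign = sum(1 for h in classified if h.label.label is Label.CONTAMINANT)
    return 100.0 * foreign / len(classified)


# -- single-copy redundancy ----------------------------------------------


def redundancy_estimate(
    hits: Sequence[MarkerHit],
    panel_family_ids: Sequence[str],
    collocation_window: Optional[int] = None,
) -> tuple[float, float]:
    """Completeness and contamination from single-copy marker counts.

    With c_m detected copies of marker m over M panel markers:
    completeness = 100 * |{m : c_m >= 1}| / M and contamination =
    100 * sum(max(0, c_m - 1)) / M.  With ``collocation_window`` set,
    hits of different families within that many nt on one scaffold merge
    into one countable unit (emulating collocated marker sets), which
    lowers the contamination estimate.
    """
    if not panel_family_ids:
        raise ValueError("empty single-copy marker panel")
    panel = set(panel_family_ids)
    used = [h for h in hits if h.family_id in panel]
    if collocation_window is not None:
        used = _collapse_collocated(used, collocation_window)
    counts = {fid: 0 for fid in panel}
    for h in used:
        counts[h.family_id] += 1
    m = len(panel)
    completeness = 100.0 * sum(1 for c in counts.values() if c >= 1) / m
    contamination = 100.0 * sum(max(0, c - 1) for c in counts.values()) / m
    return completeness, contamination


def _collapse_collocated(hits: Sequence[MarkerHit], window: int) -> list[MarkerHit]:
    """Keep one representative per (family, collocated cluster)."""
    out: list[MarkerHit] = []
    by_family: dict[str, list[MarkerHit]] = {}
    for h in sorted(hits, key=lambda h: (h.family_id, h.scaffold_id, h.start)):
        by_family.setdefault(h.family_id, []).append(h)
    for fam_hits in by_family.values():
        last: Optional[MarkerHit] = None
        for h in fam_hits:
            if (
                last is not None
                and h.scaffold_id == last.scaffold_id
                and h.start - last.end <= window
            ):
                last = h
                continue
            out.append(h)
            last = h
    return out


def marker_estimates(
    ssu_loci: Sequence[SsuLocus],
    rprot_hits: Sequence[MarkerHit],
    panel_family_ids: Sequence[str],
    collocation_window: Optional[int] = None,
) -> MarkerEstimates:
    ssu_c = ssu_contamination(ssu_loci)
    rprot_c = rprot_contamination(rprot_hits)
    classified = [h for h in rprot_hits if h.label.label is not Label.UNCLASSIFIED]
    completeness, redundancy = redundancy_estimate(
        rprot_hits, panel_family_ids, collocation_window
    )
    return MarkerEstimates(
        ssu_total_predicted=len(ssu_loci),
        ssu_foreign=sum(1 for l in ssu_loci if l.label.label is Label.CONTAMINANT),
        ssu_contamination=ssu_c,
        rprot_classified=len(classified),
        rprot_foreign=sum(1 for h in classified if h.label.label is Label.CONTAMINANT),
        rprot_contamination=rprot_c,
        redundancy_completeness=completeness,
        redundancy_contamination=redundancy,
    )


# -- marker panel I/O ----------------------------------------------------


def write_marker_panel(families: Sequence[MarkerFamily], path) -> None:
    """Multi-FASTA with ``>ref_id|genome_id|taxon_id`` headers, one file,
    families separated by '#family' comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for fam in families:
            fh.write(f"#family\t{fam.family_id}\t{fam.kind}\n")
            for ref in fam.references:
                fh.write(f">{ref.ref_id}|{ref.genome_id}|{ref.taxon_id}\n{ref.sequence}\n")


def read_marker_panel(path) -> list[MarkerFamily]:
    families: list[MarkerFamily] = []
    current: Optional[MarkerFamily] = None
    header: Optional[tuple[str, str, str]] = None
    seq_parts: list[str] = []

    def flush_ref():
        nonlocal header, seq_parts
        if header is not None:
            assert current is not None
            ref_id, genome_id, taxon_id = header
            current.references.append(
                MarkerReference(ref_id, genome_id, taxon_id, "".join(seq_parts))
            )
        header, seq_parts = None, []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#family\t"):
                flush_ref()
                _, fam_id, kind = line.split("\t")
                current = MarkerFamily(fam_id, kind, [])
                families.append(current)
            elif line.startswith(">"):
                flush_ref()
                parts = line[1:].rsplit("|", 2)  # ref_id may itself contain '|'
                if len(parts) != 3:
                    raise ValueError(f"bad marker header {line!r}")
                header = (parts[0], parts[1], parts[2])
            elif line:
                seq_parts.append(line)
    flush_ref()
    return families
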