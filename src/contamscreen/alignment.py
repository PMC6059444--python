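"""Search substrates for the read classifiers.

Two engines:

* an exact signature-kmer index over reference genomes, mapping every
  canonical kmer to the LCA of all reference taxa whose genomes contain it
  (numpy-backed: sorted integer-encoded kmers, bitmask LCA reduction);
* a six-frame translated local-alignment search against reference
  proteomes (Smith-Waterman with affine gaps, BLOSUM62, bit scores via the
  Karlin-Altschul transform), accelerated by an exact amino-acid seed
  prefilter.

External search output can be substituted through the 12+2-column tabular
hit format, so neither engine is load-bearing for the downstream logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .genome import PseudoRead
from .taxonomy import TaxonomyTree, lca

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class HitsFormatError(ValueError):
    pass


def encode_bases(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all ACGT-only kmers of ``seq`` (in order).

    The canonical form of a kmer is the smaller of its own code and its
    reverse complement's, so an index built from reverse-complemented
    genomes is identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b = encode_bases(seq).astype(np.int64)
    m = len(b) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        window = b[j : j + m]
        fwd += np.where(window < 4, window, 0) << (2 * (k - 1 - j))
        rev += np.where(window < 4, 3 - window, 0) << (2 * j)
        valid &= window < 4
    return np.minimum(fwd, rev)[valid]


def decode_kmer(code: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


class KmerIndex:
    """Sorted canonical-kmer -> taxon map over a reference genome set."""

    def __init__(
        self,
        k: int,
        kmers: np.ndarray,
        taxa: np.ndarray,
        taxon_ids: list[str],
        source_genomes: set[str],
    ) -> None:
        self.k = k
        self.kmers = kmers  # sorted int64 canonical codes
        self.taxa = taxa  # int32 indices into taxon_ids
        self.taxon_ids = taxon_ids
        self.source_genomes = source_genomes

    def __len__(self) -> int:
        return len(self.kmers)

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Taxon index per code, -1 for absent kmers."""
        pos = np.searchsorted(self.kmers, codes)
        pos = np.clip(pos, 0, len(self.kmers) - 1) if len(self.kmers) else pos
        out = np.full(len(codes), -1, dtype=np.int64)
        if len(self.kmers):
            hit = self.kmers[pos] == codes
            out[hit] = self.taxa[pos[hit]]
        return out

    def lookup(self, kmer: str) -> Optional[str]:
        codes = kmer_codes(kmer, self.k)
        if len(codes) != 1:
            return None
        idx = self.lookup_codes(codes)[0]
        return None if idx < 0 else self.taxon_ids[idx]


def build_kmer_index(
    reference_genomes: Sequence[tuple[str, str, str]],
    taxonomy: TaxonomyTree,
    k: int = 21,
) -> KmerIndex:
    """Index canonical kmers of reference genomes by the LCA of their taxa.

    ``reference_genomes`` is a sequence of ``(genome_id, taxon_id,
    sequence)``; a genome split over several scaffolds may appear as
    several entries with the same ids.  Kmers containing N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_genome: dict[str, tuple[str, list[str]]] = {}
    for genome_id, taxon_id, seq in reference_genomes:
        if taxon_id not in taxonomy:
            raise ValueError(f"genome {genome_id!r} has unknown taxon {taxon_id!r}")
        entry = by_genome.setdefault(genome_id, (taxon_id, []))
        if entry[0] != taxon_id:
            raise ValueError(f"genome {genome_id!r} listed with two taxa")
        entry[1].append(seq)
    genome_ids = sorted(by_genome)
    if len(genome_ids) > 64:
        raise ValueError("kmer index supports at most 64 reference genomes")
    all_kmers = []
    all_masks = []
    for gi, genome_id in enumerate(genome_ids):
        _, seqs = by_genome[genome_id]
        codes = np.unique(np.concatenate([kmer_codes(s, k) for s in seqs] or [np.empty(0, np.int64)]))
        all_kmers.append(codes)
        all_masks.append(np.full(len(codes), np.uint64(1) << np.uint64(gi), dtype=np.uint64))
    kmers = np.concatenate(all_kmers)
    masks = np.concatenate(all_masks)
    order = np.argsort(kmers, kind="stable")
    kmers = kmers[order]
    masks = masks[order]
    if len(kmers):
        boundaries = np.flatnonzero(np.r_[True, np.diff(kmers) != 0])
        uniq_kmers = kmers[boundaries]
        group_masks = np.bitwise_or.reduceat(masks, boundaries)
    else:
        uniq_kmers = kmers
        group_masks = masks
    # one LCA computation per distinct genome-set bitmask
    uniq_masks, inverse = np.unique(group_masks, return_inverse=True)
    taxon_ids: list[str] = []
    taxon_pos: dict[str, int] = {}
    mask_taxon = np.empty(len(uniq_masks), dtype=np.int32)
    for i, mask in enumerate(uniq_masks):
        members = [
            by_genome[genome_ids[g]][0]
            for g in range(len(genome_ids))
            if int(mask) >> g & 1
        ]
        tid = lca(taxonomy, members)
        if tid not in taxon_pos:
            taxon_pos[tid] = len(taxon_ids)
            taxon_ids.append(tid)
        mask_taxon[i] = taxon_pos[tid]
    return KmerIndex(
        k=k,
        kmers=uniq_kmers,
        taxa=mask_taxon[inverse].astype(np.int32),
        taxon_ids=taxon_ids,
        source_genomes=set(genome_ids),
    )


def write_kmer_index(index: KmerIndex, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#k\t{index.k}\n")
        fh.write(f"#sources\t{','.join(sorted(index.source_genomes))}\n")
        for code, ti in zip(index.kmers, index.taxa):
            fh.write(f"{decode_kmer(int(code), index.k)}\t{index.taxon_ids[ti]}\n")


def read_kmer_index(path) -> KmerIndex:
    k = None
    sources: set[str] = set()
    kmers: list[int] = []
    taxon_ids: list[str] = []
    taxon_pos: dict[str, int] = {}
    taxa: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#k\t"):
                k = int(line.split("\t")[1])
                continue
            if line.startswith("#sources\t"):
                field_ = line.split("\t")[1]
                sources = set(field_.split(",")) if field_ else set()
                continue
            kmer, tid = line.split("\t")
            assert k is not None
            kmers.append(int(kmer_codes(kmer, k)[0]))
            if tid not in taxon_pos:
                taxon_pos[tid] = len(taxon_ids)
                taxon_ids.append(tid)
            taxa.append(taxon_pos[tid])
    if k is None:
        raise ValueError(f"{path}: missing '#k' header")
    arr = np.asarray(kmers, dtype=np.int64)
    order = np.argsort(arr)
    return KmerIndex(k, arr[order], np.asarray(taxa, dtype=np.int32)[order], taxon_ids, sources)


# -- translated protein search ------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    taxon_id: str
    sequence: str


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    subject_genome_id: str
    subject_taxon_id: str
    identity: float
    aln_len: int
    bit_score: float
    e_value: float


@dataclass
class AlignmentParams:
    """Local-alignment scoring: BLOSUM62, affine gaps, ungapped-default
    Karlin-Altschul constants for the bit-score transform."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # cost of a length-1 gap is gap_open + gap_extend
    gap_extend: int = 1
    ka_lambda: float = 0.3176
    ka_k: float = 0.134

    def bit_score(self, raw: float) -> float:
        return (self.ka_lambda * raw - math.log(self.ka_k)) / math.log(2.0)

    def raw_for_bits(self, bits: float) -> float:
        return (bits * math.log(2.0) + math.log(self.ka_k)) / self.ka_lambda


_ALIGNER_CACHE: dict[tuple, PairwiseAligner] = {}


def make_aligner(params: AlignmentParams) -> PairwiseAligner:
    key = (params.matrix_name, params.gap_open, params.gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
        aligner.open_gap_score = -(params.gap_open + params.gap_extend)
        aligner.extend_gap_score = -params.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    raw_score: float
    bit_score: float
    identity: float
    aln_len: int


def local_align(
    query_pep: str, subject_pep: str, params: Optional[AlignmentParams] = None
) -> Optional[LocalAlignment]:
    """Best Smith-Waterman local alignment; None when no positive-scoring
    alignment exists."""
    if not query_pep or not subject_pep:
        raise ValueError("empty peptide")
    params = params or AlignmentParams()
    aligner = make_aligner(params)
    raw = aligner.score(query_pep, subject_pep)
    if raw <= 0:
        return None
    aln = aligner.align(query_pep, subject_pep)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    return LocalAlignment(raw, params.bit_score(raw), identity, aln_len)


_FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(sequence: str) -> dict[int, str]:
    """Standard-code translations of frames +1..+3 and -1..-3.

    Stops are emitted as ``*``; trailing partial codons are dropped.
    """
    seq = Seq(sequence.upper())
    rc = seq.reverse_complement()
    out = {}
    for frame in _FRAMES:
        src = seq if frame > 0 else rc
        sub = src[abs(frame) - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        out[frame] = str(sub.translate())
    return out


class ProteinDatabase:
    """Reference proteome with an exact amino-acid seed prefilter.

    Candidate subjects for a query peptide are proteins sharing at least
    one exact ``seed_k``-mer with it; only candidates are aligned.  At the
    bit-score thresholds the pipeline uses (>=80 bits needs a well-matched
    run of ~35 residues) a seed is essentially always present, so the
    prefilter changes no retained hit.  ``seed_k=0`` disables seeding
    (exhaustive search, for small oracle tests).
    """

    def __init__(self, proteins: Iterable[ProteinRecord], seed_k: int = 5) -> None:
        self.proteins = list(proteins)
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein_id in database")
        self.seed_k = seed_k
        self._seeds: dict[str, list[int]] = {}
        if seed_k:
            for idx, prot in enumerate(self.proteins):
                s = prot.sequence
                prev = None
                for j in range(len(s) - seed_k + 1):
                    word = s[j : j + seed_k]
                    if word == prev:
                        continue
                    bucket = self._seeds.setdefault(word, [])
                    if not bucket or bucket[-1] != idx:
                        bucket.append(idx)
                    prev = word

    def candidates(self, peptide: str, min_seeds: int = 2) -> list[int]:
        """Subjects sharing at least ``min_seeds`` exact seed words with
        the query (single shared words are overwhelmingly chance at this
        database size)."""
        if not self.seed_k:
            return list(range(len(self.proteins)))
        counts: dict[int, int] = {}
        for j in range(len(peptide) - self.seed_k + 1):
            bucket = self._seeds.get(peptide[j : j + self.seed_k])
            if bucket:
                for idx in bucket:
                    counts[idx] = counts.get(idx, 0) + 1
        return sorted(i for i, c in counts.items() if c >= min_seeds)


def search_read(
    read: PseudoRead,
    db: ProteinDatabase,
    params: Optional[AlignmentParams] = None,
    min_bit: float = 0.0,
    with_alignment: bool = True,
) -> list[HitRecord]:
    """Translated search of a pseudo-read against a reference proteome.

    Returns the best local alignment per subject protein (maximised over
    the six reading frames), filtered at ``min_bit`` bits, sorted by
    descending bit score then subject id.  With ``with_alignment=False``
    only scores are computed (identity/aln_len reported as NaN/0), which
    is all the LCA classifier needs.
    """
    params = params or AlignmentParams()
    aligner = make_aligner(params)
    min_raw = params.raw_for_bits(min_bit) if min_bit > 0 else 0.0
    best_raw: dict[int, float] = {}
    best_frame: dict[int, str] = {}
    for frame, pep in six_frame_translate(read.sequence).items():
        if len(pep) < max(db.seed_k, 1):
            continue
        for idx in db.candidates(pep):
            raw = aligner.score(pep, db.proteins[idx].sequence)
            if raw > best_raw.get(idx, 0.0):
                best_raw[idx] = raw
                best_frame[idx] = pep
    hits = []
    for idx, raw in best_raw.items():
        if raw <= 0 or raw < min_raw:
            continue
        prot = db.proteins[idx]
        if with_alignment:
            aln = local_align(best_frame[idx], prot.sequence, params)
            assert aln is not None
        else:
            aln = LocalAlignment(raw, params.bit_score(raw), float("nan"), 0)
        # crude database-scale E-value; informational only
        space = max(len(read.sequence) // 3, 1) * max(len(prot.sequence), 1)
        e_value = space * math.exp(-params.ka_lambda * raw) * params.ka_k
        hits.append(
            HitRecord(
                query_id=read.read_id,
                subject_id=prot.protein_id,
                subject_genome_id=prot.genome_id,
                subject_taxon_id=prot.taxon_id,
                identity=aln.identity,
                aln_len=aln.aln_len,
                bit_score=aln.bit_score,
                e_value=e_value,
            )
        )
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


# -- tabular hit I/O -----------------------------------------------------

_HIT_COLUMNS = 14  # 12-column blast tabular + subject_genome_id, subject_taxon_id


def write_hits_tsv(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            mismatch = max(round(h.aln_len * (1.0 - h.identity / 100.0)), 0)
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.2f}",
                        str(h.aln_len),
                        str(mismatch),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                        h.subject_genome_id,
                        h.subject_taxon_id,
                    ]
                )
                + "\n"
            )


def read_hits_tsv(
    path, subject_map: Optional[dict[str, tuple[str, str]]] = None
) -> list[HitRecord]:
    """Read 14-column hits, or 12-column BLAST tabular plus a
    ``subject_id -> (genome_id, taxon_id)`` side mapping."""
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == _HIT_COLUMNS:
                genome_id, taxon_id = parts[12], parts[13]
            elif len(parts) == 12 and subject_map is not None:
                if parts[1] not in subject_map:
                    raise HitsFormatError(
                        f"{path}:{lineno}: subject {parts[1]!r} missing from mapping"
                    )
                genome_id, taxon_id = subject_map[parts[1]]
            else:
                raise HitsFormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} (or 12 + mapping) "
                    f"columns, got {len(parts)}"
                )
            hits.append(
                HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                    subject_genome_id=genome_id,
                    subject_taxon_id=taxon_id,
                )
            )
    return hits
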