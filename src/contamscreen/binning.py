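"""Reference-free contamination estimate from kmer-composition clustering.

Each 10-kb segment is summarised by its canonical short-kmer frequency
vector (tetramers by default: 136 strand-symmetric classes), vectors are
centre-scaled and projected onto the leading principal components, and a
Gaussian mixture whose component count is selected by a BIC sweep
hard-assigns segments to groups.  The contamination estimate is one minus
the share of segments in the largest group: a clean assembly concentrates
nearly all segments in one composition cluster, while foreign sequence of
distinct composition populates additional groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .alignment import kmer_codes
from .genome import Segment


@dataclass(frozen=True)
class BinningConfig:
    kappa: int = 4
    max_clusters: int = 400
    min_segment: int = 1000
    pca_variance: float = 0.90
    seed: int = 0
    max_sweep: int = 12  # cap on mixture sizes tried in the BIC sweep
    max_pca_dims: int = 2  # leading components carry the composition signal
    reg_factor: float = 0.3  # reg_covar as a fraction of mean projected variance

    def __post_init__(self) -> None:
        if self.kappa < 2:
            raise ValueError("kappa must be >= 2")
        if self.max_clusters < 2:
            raise ValueError("max_clusters must be >= 2")


def n_canonical_kmers(kappa: int) -> int:
    """Number of reverse-complement-collapsed kmer classes of size kappa."""
    total = 4**kappa
    palindromes = 4 ** (kappa // 2) if kappa % 2 == 0 else 0
    return (total + palindromes) // 2


def _canonical_class_index(kappa: int) -> dict[int, int]:
    """Map canonical kmer codes to dense vector positions."""
    from .alignment import decode_kmer  # local import to avoid cycle noise

    classes = sorted({int(kmer_codes(decode_kmer(c, kappa), kappa)[0]) for c in range(4**kappa)})
    return {code: i for i, code in enumerate(classes)}


_CLASS_CACHE: dict[int, dict[int, int]] = {}


def kmer_vector(segment: Segment | str, kappa: int = 4) -> np.ndarray:
    """Log-transformed canonical kmer frequency vector with pseudocount 1.

    The vector is invariant under reverse complement of the segment;
    palindromic kmers are counted once per occurrence.
    """
    seq = segment if isinstance(segment, str) else segment.sequence
    if len(seq) < kappa:
        raise ValueError("segment shorter than kmer size")
    if kappa not in _CLASS_CACHE:
        _CLASS_CACHE[kappa] = _canonical_class_index(kappa)
    index = _CLASS_CACHE[kappa]
    counts = np.ones(len(index), dtype=float)  # pseudocount 1
    codes = kmer_codes(seq, kappa)
    if len(codes):
        uniq, n = np.unique(codes, return_counts=True)
        for code, c in zip(uniq, n):
            counts[index[int(code)]] += c
    return np.log(counts / counts.sum())


@dataclass
class BinAssignment:
    segment_ids: list[str]
    group_ids: np.ndarray  # int group per segment

    def group_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.group_ids, return_counts=True)
        return {int(g): int(c) for g, c in zip(uniq, counts)}


def cluster_segments(
    segments: Sequence[Segment],
    config: BinningConfig = BinningConfig(),
    vectors: Optional[np.ndarray] = None,
    coverage: Optional[Sequence[float]] = None,
) -> BinAssignment:
    """Cluster segment composition vectors into groups.

    Centre-scaled vectors are projected onto the leading principal
    components (at most ``max_pca_dims``, within the ``pca_variance``
    budget: with strand-symmetric tetramer vectors the genuine
    between-genome signal concentrates in the first components while the
    trailing ones are segment-level sampling noise), diagonal Gaussian
    mixtures with 1..min(max_clusters, max_sweep, n) components are
    fitted, the component count minimising BIC is selected, and segments
    are hard-assigned by maximum responsibility.  The covariance
    regulariser is a fraction of the mean projected variance, so
    components cannot collapse onto near-duplicate segments and splitting
    only pays off for composition differences well above sampling noise.
    Optional per-segment coverage values are appended as an extra
    (scaled) feature column.  Deterministic under a fixed seed.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to cluster")
    if vectors is None:
        vectors = np.vstack([kmer_vector(s, config.kappa) for s in segments])
    x = np.asarray(vectors, dtype=float)
    if coverage is not None:
        cov = np.log1p(np.asarray(coverage, dtype=float))[:, None]
        x = np.hstack([x, cov])
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    x = (x - mean) / std
    if not x.any():  # all segments identical: one trivial group
        return BinAssignment(
            [s.segment_id for s in segments], np.zeros(len(segments), dtype=int)
        )
    n_comp_pca = min(x.shape[0] - 1, x.shape[1])
    if n_comp_pca >= 1:
        pca = PCA(n_components=n_comp_pca, random_state=config.seed)
        proj = pca.fit_transform(x)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(ratio, config.pca_variance) + 1)
        proj = proj[:, : min(keep, config.max_pca_dims)]
    else:
        proj = x
    reg = config.reg_factor * float(proj.var(axis=0).mean())
    k_max = min(config.max_clusters, config.max_sweep, len(segments))
    best: tuple[float, int, np.ndarray] | None = None
    with warnings.catch_warnings():
        # the sweep deliberately tries k beyond the number of distinct
        # points; sklearn's convergence warnings for those fits are noise
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(1, k_max + 1):
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                reg_covar=max(reg, 1e-6),
                n_init=10,
                max_iter=500,
                random_state=config.seed,
            )
            labels = gmm.fit_predict(proj)
            bic = gmm.bic(proj)
            if best is None or bic < best[0]:
                best = (bic, k, np.asarray(labels))
    assert best is not None
    return BinAssignment([s.segment_id for s in segments], best[2])


def largest_group_contamination(assignment: BinAssignment) -> float:
    """100 x (1 - share of segments in the largest group)."""
    sizes = assignment.group_sizes()
    if not sizes:
        raise ValueError("no assigned segments")
    n_total = sum(sizes.values())
    n_largest = max(sizes.values())
    return 100.0 * (1.0 - n_largest / n_total)


def write_assignment(assignment: BinAssignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#segment_id\tgroup_id\n")
        for sid, gid in zip(assignment.segment_ids, assignment.group_ids):
            fh.write(f"{sid}\t{int(gid)}\n")
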