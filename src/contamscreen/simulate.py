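"""Synthetic universe generator: taxonomy, genomes, markers, chimeras, reads.

The generator produces everything the screening pipeline consumes, with
exact ground truth:

* a small taxonomy (root -> domain -> phyla -> genera -> species) with
  one focal phylum;
* reference genomes with phylum-graded composition: protein-coding gene
  families shared across the whole taxonomy are evolved along the tree
  (substitution-only) and reverse-translated with GC-targeted,
  genus-level codon usage, so within-genus genomes share long exact
  nucleotide stretches while phyla are well separated in both GC and
  short-kmer space; intergenic spacers come from per-genome order-3
  Markov chains inheriting phylum-level transition parameters;
* marker implants: a panel of single-copy ribosomal-protein-like
  families laid out as one operon-like cluster per genome (mirroring real
  r-protein operons) and 1-4 identical SSU-like rRNA copies per genome
  with a conserved core;
* chimeric query assemblies: a fragmented host plus contaminant blocks
  drawn from other organisms (optionally concatenated onto host scaffolds),
  with the realized contaminant base fraction recorded exactly;
* error-prone reads at organism-specific depths plus the exact depth track.

All outputs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .alignment import ProteinRecord
from .genome import Assembly, Scaffold
from .markers import MarkerFamily, MarkerReference
from .taxonomy import TaxonNode, TaxonomyTree

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
# typical proteome residue background
_BG_AA = np.array(
    [0.082, 0.015, 0.052, 0.062, 0.040, 0.071, 0.021, 0.060, 0.058, 0.098,
     0.022, 0.042, 0.045, 0.039, 0.051, 0.070, 0.056, 0.069, 0.012, 0.031]
)
_BG_AA = _BG_AA / _BG_AA.sum()

_TABLE = unambiguous_dna_by_id[11]  # bacterial code
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    if _aa in _AA_INDEX:
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()

_BASES = "ACGT"

# per-branch substitution probabilities by taxonomic level
_AA_BRANCH = {"phylum": 0.18, "genus": 0.10, "species": 0.03}
_NT_BRANCH = {"phylum": 0.10, "genus": 0.04, "species": 0.015}
_SSU_CORE_FRACTION = 0.60
_SYNONYMOUS_RATE = 0.04


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_phyla: int = 5
    genera_per_phylum: int = 2
    species_per_genus: int = 2
    genome_length: int = 300_000
    markov_order: int = 3
    gc_min: float = 0.35
    gc_max: float = 0.65
    n_rprot_families: int = 20
    max_ssu_copies: int = 4
    contaminant_fraction: float = 0.10
    n_contaminant_organisms: int = 1
    chimeric_scaffold_rate: float = 0.10
    scaffold_log_mean: float = math.log(20_000.0)
    scaffold_log_sigma: float = 0.55
    min_scaffold: int = 1000
    host_depth: float = 68.0
    contaminant_depth: float = 26.0
    read_length: int = 100
    read_error_rate: float = 0.005
    cover_markers: bool = True
    ordinary_gene_aa: tuple[int, int] = (250, 350)
    rprot_aa: tuple[int, int] = (120, 200)
    ssu_length: int = 1500
    spacer_nt: tuple[int, int] = (25, 36)
    coding_density: float = 0.96  # gene-dense, as in compact prokaryotic genomes

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.host_depth <= 0 or self.contaminant_depth <= 0:
            raise ValueError("depths must be positive")
        if not 0.2 < self.gc_min < self.gc_max < 0.8:
            raise ValueError("GC targets must lie in (0.2, 0.8)")
        if self.n_phyla < 2:
            raise ValueError("need at least 2 phyla")


@dataclass(frozen=True)
class GeneLocus:
    family_id: str
    kind: str  # "gene" | "rprot" | "ssu"
    start: int
    end: int
    strand: str = "+"


@dataclass
class SimGenome:
    genome_id: str
    taxon_id: str
    phylum_id: str
    gc_target: float
    sequence: str = ""
    proteins: list[ProteinRecord] = field(default_factory=list)
    loci: list[GeneLocus] = field(default_factory=list)


@dataclass
class Universe:
    """A complete reference world: taxonomy, genomes, marker panels."""

    config: SimConfig
    taxonomy: TaxonomyTree
    genomes: dict[str, SimGenome]
    rprot_families: list[MarkerFamily]
    ssu_family: MarkerFamily
    phylum_gc: dict[str, float]

    def reference_genomes(self, exclude: frozenset[str] | set[str] = frozenset()):
        out = [
            (g.genome_id, g.taxon_id, g.sequence)
            for g in self.genomes.values()
            if g.genome_id not in exclude
        ]
        if not out:
            raise SimulationError("reference set would be empty")
        return out

    def proteome(self, exclude: frozenset[str] | set[str] = frozenset()) -> list[ProteinRecord]:
        out = [
            p
            for g in self.genomes.values()
            if g.genome_id not in exclude
            for p in g.proteins
        ]
        if not out:
            raise SimulationError("proteome would be empty")
        return out

    def marker_families(self, exclude: frozenset[str] | set[str] = frozenset()) -> list[MarkerFamily]:
        fams = []
        for fam in self.rprot_families:
            refs = [r for r in fam.references if r.genome_id not in exclude]
            fams.append(MarkerFamily(fam.family_id, fam.kind, refs))
        return fams

    def ssu_references(self, exclude: frozenset[str] | set[str] = frozenset()) -> MarkerFamily:
        refs = [r for r in self.ssu_family.references if r.genome_id not in exclude]
        return MarkerFamily(self.ssu_family.family_id, "nucleotide", refs)

    def focal_genomes(self) -> list[str]:
        return [
            g.genome_id
            for g in self.genomes.values()
            if self.taxonomy.is_ancestor(self.taxonomy.focal_id, g.taxon_id)
        ]

    def pick_contaminants(
        self, host_id: str, n: int, min_delta_gc: float, rng: np.random.Generator
    ) -> list[str]:
        host_gc = self.genomes[host_id].gc_target
        eligible = [
            g.genome_id
            for g in self.genomes.values()
            if g.phylum_id != self.genomes[host_id].phylum_id
            and abs(g.gc_target - host_gc) * 100.0 >= min_delta_gc
        ]
        if len(eligible) < n:
            raise SimulationError("not enough compositionally distant contaminants")
        picks = rng.choice(len(eligible), size=n, replace=False)
        return [eligible[i] for i in sorted(picks)]


@dataclass
class TruthInterval:
    start: int
    end: int
    organism_id: str


@dataclass
class TruthMarkerLocus:
    family_id: str
    kind: str
    scaffold_id: str
    start: int
    end: int
    organism_id: str


@dataclass
class GroundTruth:
    assembly_id: str
    host_id: str
    contaminant_ids: list[str]
    intervals: dict[str, list[TruthInterval]]
    contaminant_fraction: float  # exact, by base count
    marker_loci: list[TruthMarkerLocus] = field(default_factory=list)

    def source_of_base(self, scaffold_id: str, pos: int) -> Optional[str]:
        for iv in self.intervals.get(scaffold_id, []):
            if iv.start <= pos < iv.end:
                return iv.organism_id
        return None

    def contaminant_mask(self, scaffold_len: dict[str, int]) -> dict[str, np.ndarray]:
        out = {}
        for sid, n in scaffold_len.items():
            mask = np.zeros(n, dtype=bool)
            for iv in self.intervals.get(sid, []):
                if iv.organism_id != self.host_id:
                    mask[iv.start : iv.end] = True
            out[sid] = mask
        return out


# -- taxonomy ------------------------------------------------------------


def simulate_taxonomy(config: SimConfig) -> TaxonomyTree:
    """Root -> domain -> phyla -> genera -> species; phylum 1 is focal."""
    nodes = [
        TaxonNode("root", None, "root", "Root"),
        TaxonNode("dom", "root", "domain", "Domain"),
    ]
    for p in range(1, config.n_phyla + 1):
        pid = f"p{p}"
        nodes.append(TaxonNode(pid, "dom", "phylum", f"Phylum{p}"))
        for g in range(1, config.genera_per_phylum + 1):
            gid = f"{pid}.g{g}"
            nodes.append(TaxonNode(gid, pid, "genus", f"Genus{p}_{g}"))
            for s in range(1, config.species_per_genus + 1):
                sid = f"{gid}.s{s}"
                nodes.append(TaxonNode(sid, gid, "species", f"Species{p}_{g}_{s}"))
    return TaxonomyTree(nodes, focal_id="p1")


# -- sequence evolution helpers -----------------------------------------


def _mutate(seq: np.ndarray, p: float, n_states: int, rng: np.random.Generator,
            mutable: Optional[np.ndarray] = None) -> np.ndarray:
    """Substitute positions independently with probability ``p`` to a
    uniformly chosen different state."""
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    if mutable is not None:
        hit &= mutable
    idx = np.flatnonzero(hit)
    if len(idx):
        out[idx] = (out[idx] + rng.integers(1, n_states, size=len(idx))) % n_states
    return out


def _gc_of_codon(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def _codon_weights(beta: float) -> dict[str, np.ndarray]:
    out = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.exp([beta * _gc_of_codon(c) for c in codons])
        out[aa] = w / w.sum()
    return out


def _expected_gc(beta: float) -> float:
    w = _codon_weights(beta)
    total = 0.0
    for i, aa in enumerate(AA20):
        codons = _CODONS_BY_AA[aa]
        gcs = np.array([_gc_of_codon(c) / 3.0 for c in codons])
        total += _BG_AA[i] * float(w[aa] @ gcs)
    return total


def _solve_beta(target_gc: float) -> float:
    lo, hi = -8.0, 8.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _expected_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class _MarkovSampler:
    """Order-``m`` Markov chain over ACGT with per-context transitions."""

    def __init__(self, probs: np.ndarray, order: int, rng: np.random.Generator) -> None:
        self.cum = np.cumsum(probs, axis=1)
        self.order = order
        self.rng = rng
        self.context = int(rng.integers(0, 4**order))

    def sample(self, n: int) -> str:
        mask = 4**self.order
        us = self.rng.random(n)
        out = np.empty(n, dtype=np.uint8)
        ctx = self.context
        cum = self.cum
        for i in range(n):
            row = cum[ctx]
            b = int(np.searchsorted(row, us[i], side="right"))
            b = min(b, 3)
            out[i] = b
            ctx = (ctx * 4 + b) % mask
        self.context = ctx
        return "".join(_BASES[b] for b in out)


def _markov_probs(base_dist: np.ndarray, order: int, conc: float,
                  rng: np.random.Generator) -> np.ndarray:
    alpha = np.maximum(base_dist * conc, 1e-3)
    return rng.dirichlet(alpha, size=4**order)


def _perturb_probs(probs: np.ndarray, conc: float, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(probs)
    for i in range(probs.shape[0]):
        out[i] = rng.dirichlet(np.maximum(probs[i] * conc, 1e-3))
    return out


# -- genome construction -------------------------------------------------


@dataclass
class _FamilySpec:
    family_id: str
    kind: str  # "gene" | "rprot"
    length_aa: int
    # node_id -> amino-acid index array
    node_seqs: dict[str, np.ndarray] = field(default_factory=dict)
    # genus_id -> codon-choice index array (index within each aa's codon list)
    genus_codons: dict[str, np.ndarray] = field(default_factory=dict)


def _evolve_protein_family(
    fam: _FamilySpec, tree: TaxonomyTree, rng: np.random.Generator
) -> None:
    anc = rng.choice(len(AA20), size=fam.length_aa, p=_BG_AA).astype(np.int16)
    fam.node_seqs["dom"] = anc
    for pid in tree.children("dom"):
        pseq = _mutate(anc, _AA_BRANCH["phylum"], 20, rng)
        fam.node_seqs[pid] = pseq
        for gid in tree.children(pid):
            gseq = _mutate(pseq, _AA_BRANCH["genus"], 20, rng)
            fam.node_seqs[gid] = gseq
            for sid in tree.children(gid):
                fam.node_seqs[sid] = _mutate(gseq, _AA_BRANCH["species"], 20, rng)


def _aa_string(idx: np.ndarray) -> str:
    return "".join(AA20[i] for i in idx)


def _choose_codons(aa_idx: np.ndarray, weights: dict[str, np.ndarray],
                   rng: np.random.Generator) -> np.ndarray:
    """Codon-choice index per position, sampled by genus codon usage."""
    out = np.zeros(len(aa_idx), dtype=np.int8)
    for i, aa in enumerate(AA20):
        pos = np.flatnonzero(aa_idx == i)
        if len(pos):
            w = weights[aa]
            out[pos] = rng.choice(len(w), size=len(pos), p=w)
    return out


def _codon_string(aa_idx: np.ndarray, codon_idx: np.ndarray) -> str:
    return "".join(
        _CODONS_BY_AA[AA20[a]][c] for a, c in zip(aa_idx, codon_idx)
    )


def _species_gene_nt(
    fam: _FamilySpec,
    genus_id: str,
    species_id: str,
    weights: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> str:
    """Species gene: genus codon choices, re-drawn at amino-acid changes
    and at a low synonymous-substitution rate."""
    g_aa = fam.node_seqs[genus_id]
    s_aa = fam.node_seqs[species_id]
    codons = fam.genus_codons[genus_id].copy()
    diff = np.flatnonzero(g_aa != s_aa)
    syn = np.flatnonzero(rng.random(len(s_aa)) < _SYNONYMOUS_RATE)
    redo = np.union1d(diff, syn)
    for p in redo:
        aa = AA20[s_aa[p]]
        w = weights[aa]
        codons[p] = rng.choice(len(w), p=w)
    return _codon_string(s_aa, codons)


def simulate_genomes(tree: TaxonomyTree, config: SimConfig) -> Universe:
    """Generate the reference universe for a taxonomy.

    See the module docstring for the generative model.  Deterministic for
    a fixed ``config.seed``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    rng_fam, rng_layout, rng_comp, rng_markov = [
        np.random.default_rng(s) for s in root_ss.spawn(4)
    ]
    phyla = tree.children("dom")
    gc_targets = np.linspace(config.gc_min, config.gc_max, len(phyla))
    phylum_gc = {pid: float(g) for pid, g in zip(phyla, gc_targets)}

    # family inventory: ordinary genes to reach the coding-density target
    avg_ord_nt = 3 * sum(config.ordinary_gene_aa) // 2
    avg_rprot_nt = 3 * sum(config.rprot_aa) // 2
    spacer_mid = sum(config.spacer_nt) // 2
    cluster_nt = config.n_rprot_families * (avg_rprot_nt + spacer_mid)
    ssu_budget = config.max_ssu_copies * (config.ssu_length + spacer_mid)
    n_ordinary = max(
        1,
        int(
            (config.genome_length * config.coding_density - cluster_nt - ssu_budget)
            / (avg_ord_nt + spacer_mid)
        ),
    )

    families: list[_FamilySpec] = []
    for i in range(n_ordinary):
        length = int(rng_fam.integers(*config.ordinary_gene_aa))
        families.append(_FamilySpec(f"gene{i+1:04d}", "gene", length))
    for i in range(config.n_rprot_families):
        length = int(rng_fam.integers(*config.rprot_aa))
        families.append(_FamilySpec(f"rp{i+1:02d}", "rprot", length))
    for fam in families:
        _evolve_protein_family(fam, tree, rng_fam)

    # SSU-like nucleotide family with an immutable conserved core
    ssu_anc = rng_fam.choice(4, size=config.ssu_length).astype(np.int16)
    core = rng_fam.random(config.ssu_length) < _SSU_CORE_FRACTION
    mutable = ~core
    ssu_nodes: dict[str, np.ndarray] = {"dom": ssu_anc}
    for pid in phyla:
        pseq = _mutate(ssu_anc, _NT_BRANCH["phylum"], 4, rng_fam, mutable)
        ssu_nodes[pid] = pseq
        for gid in tree.children(pid):
            gseq = _mutate(pseq, _NT_BRANCH["genus"], 4, rng_fam, mutable)
            ssu_nodes[gid] = gseq
            for sid in tree.children(gid):
                ssu_nodes[sid] = _mutate(gseq, _NT_BRANCH["species"], 4, rng_fam, mutable)

    # codon usage solved per genus from the phylum GC target
    genus_weights: dict[str, dict[str, np.ndarray]] = {}
    genus_beta: dict[str, float] = {}
    for pid in phyla:
        for gid in tree.children(pid):
            target = phylum_gc[pid] + float(rng_comp.normal(0.0, 0.004))
            beta = _solve_beta(target)
            genus_beta[gid] = beta
            genus_weights[gid] = _codon_weights(beta)

    for fam in families:
        for pid in phyla:
            for gid in tree.children(pid):
                fam.genus_codons[gid] = _choose_codons(
                    fam.node_seqs[gid], genus_weights[gid], rng_comp
                )

    # per-phylum Markov transition parameters, perturbed per genome
    phylum_markov: dict[str, np.ndarray] = {}
    for pid in phyla:
        g = phylum_gc[pid]
        base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        phylum_markov[pid] = _markov_probs(base, config.markov_order, 60.0, rng_markov)

    genomes: dict[str, SimGenome] = {}
    rprot_refs: dict[str, list[MarkerReference]] = {
        f.family_id: [] for f in families if f.kind == "rprot"
    }
    ssu_refs: list[MarkerReference] = []

    for pid in phyla:
        for gid in tree.children(pid):
            weights = genus_weights[gid]
            for sid in tree.children(gid):
                genome_id = sid
                probs = _perturb_probs(phylum_markov[pid], 400.0, rng_markov)
                sampler = _MarkovSampler(
                    probs, config.markov_order,
                    np.random.default_rng(root_ss.spawn(1)[0]),
                )
                genome = SimGenome(genome_id, sid, pid, phylum_gc[pid])
                # items: ordinary genes, one r-protein cluster, SSU copies
                items: list[tuple[str, str, str]] = []  # (kind, family_id, nt)
                for fam in families:
                    nt = _species_gene_nt(fam, gid, sid, weights, rng_comp)
                    if fam.kind == "gene":
                        items.append(("gene", fam.family_id, nt))
                    else:
                        items.append(("rprot", fam.family_id, nt))
                    aa = _aa_string(fam.node_seqs[sid])
                    genome.proteins.append(
                        ProteinRecord(f"{genome_id}|{fam.family_id}", genome_id, sid, aa)
                    )
                    if fam.kind == "rprot":
                        rprot_refs[fam.family_id].append(
                            MarkerReference(f"{genome_id}|{fam.family_id}", genome_id, sid, aa)
                        )
                ssu_nt = "".join(_BASES[b] for b in ssu_nodes[sid])
                ssu_refs.append(MarkerReference(f"{genome_id}|SSU", genome_id, sid, ssu_nt))
                n_copies = int(rng_layout.integers(1, config.max_ssu_copies + 1))

                genome.sequence = _compose_genome(
                    genome, items, ssu_nt, n_copies, sampler, config, rng_layout
                )
                genomes[genome_id] = genome

    rprot_families = [
        MarkerFamily(fid, "protein", refs) for fid, refs in sorted(rprot_refs.items())
    ]
    ssu_family = MarkerFamily("SSU", "nucleotide", ssu_refs)
    return Universe(config, tree, genomes, rprot_families, ssu_family, phylum_gc)


def _compose_genome(
    genome: SimGenome,
    items: Sequence[tuple[str, str, str]],
    ssu_nt: str,
    n_ssu_copies: int,
    sampler: _MarkovSampler,
    config: SimConfig,
    rng: np.random.Generator,
) -> str:
    """Lay out genes, the r-protein cluster and SSU copies in random order
    with Markov spacers; loci are recorded in genome coordinates."""
    ordinary = [(k, f, nt) for k, f, nt in items if k == "gene"]
    rprots = [(k, f, nt) for k, f, nt in items if k == "rprot"]

    def spacer() -> str:
        return sampler.sample(int(rng.integers(*config.spacer_nt)))

    # the cluster is one placeable unit of all r-proteins in panel order
    cluster_parts: list[str] = []
    cluster_loci: list[tuple[str, int, int]] = []
    pos = 0
    for _, fam_id, nt in rprots:
        sp = spacer()
        cluster_parts.append(sp)
        pos += len(sp)
        cluster_loci.append((fam_id, pos, pos + len(nt)))
        cluster_parts.append(nt)
        pos += len(nt)
    cluster_nt = "".join(cluster_parts)

    units: list[tuple[str, str, str]] = list(ordinary)
    units.append(("cluster", "rprot_cluster", cluster_nt))
    for _ in range(n_ssu_copies):
        units.append(("ssu", "SSU", ssu_nt))
    order = rng.permutation(len(units))

    # leftover length is spread over all intergenic gaps (no monolithic
    # filler block, which would look like a foreign composition island)
    units_nt = sum(len(nt) for _, _, nt in units)
    n_gaps = len(units) + 1
    leftover = max(config.genome_length - units_nt, n_gaps * (sum(config.spacer_nt) // 2))
    gap_mean = leftover / n_gaps
    gap_lens = np.maximum(
        rng.uniform(0.6 * gap_mean, 1.4 * gap_mean, size=n_gaps).astype(int), 12
    )

    parts: list[str] = []
    pos = 0
    for gi, ui in enumerate(order):
        kind, fam_id, nt = units[ui]
        sp = sampler.sample(int(gap_lens[gi]))
        parts.append(sp)
        pos += len(sp)
        if kind == "cluster":
            for fid, s, e in cluster_loci:
                genome.loci.append(GeneLocus(fid, "rprot", pos + s, pos + e))
        else:
            genome.loci.append(GeneLocus(fam_id, kind, pos, pos + len(nt)))
        parts.append(nt)
        pos += len(nt)
    parts.append(sampler.sample(int(gap_lens[-1])))
    return "".join(parts)


def simulate_universe(config: SimConfig) -> Universe:
    return simulate_genomes(simulate_taxonomy(config), config)


# -- chimeric assemblies -------------------------------------------------


def _fragment_lengths(total: int, config: SimConfig, rng: np.random.Generator) -> list[int]:
    lengths: list[int] = []
    covered = 0
    while covered < total:
        ln = int(rng.lognormal(config.scaffold_log_mean, config.scaffold_log_sigma))
        ln = max(ln, config.min_scaffold)
        if total - covered - ln < config.min_scaffold:
            ln = total - covered
        lengths.append(ln)
        covered += ln
    if len(lengths) > 1 and lengths[-1] < config.min_scaffold:
        lengths[-2] += lengths.pop()
    return lengths


def _contaminant_blocks(
    genome: SimGenome,
    budget: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Intervals of the contaminant genome to carry over, prioritising the
    marker cluster and one SSU copy when ``cover_markers`` is set."""
    n = len(genome.sequence)
    blocks: list[tuple[int, int]] = []
    marker_ivs = [(l.start, l.end) for l in genome.loci if l.kind != "gene"]

    def overlaps(s: int, e: int) -> bool:
        return any(s < be and e > bs for bs, be in blocks)

    def cuts_marker(s: int, e: int) -> bool:
        # a block edge inside a marker locus would carry over a partial
        # marker the registry cannot account for
        return any(ms < s < me or ms < e < me for ms, me in marker_ivs)

    # blocks at the analysis segment scale, so the binning statistic's
    # segment-count share tracks the base-count share
    min_block = 11_000
    if config.cover_markers:
        rp = [l for l in genome.loci if l.kind == "rprot"]
        if rp:
            s = max(min(l.start for l in rp) - 200, 0)
            e = min(max(l.end for l in rp) + 200, n)
            blocks.append((s, e))
        ssu = [l for l in genome.loci if l.kind == "ssu"]
        if ssu:
            pick = ssu[int(rng.integers(0, len(ssu)))]
            used_so_far = sum(e - s for s, e in blocks)
            want = min(min_block, max(budget - used_so_far, 2000))
            s = max(pick.start - 250, 0)
            e = min(s + want, n)
            while any(ms < e < me for ms, me in marker_ivs):
                e = min(next(me for ms, me in marker_ivs if ms < e < me), n)
            if e - s >= pick.end - pick.start and not overlaps(s, e):
                blocks.append((s, e))
    used = sum(e - s for s, e in blocks)
    tries = 0
    while budget - used >= min_block // 2 and tries < 200:
        tries += 1
        ln = int(rng.lognormal(math.log(12_000.0), 0.25))
        ln = max(min_block, min(ln, budget - used))
        if budget - used - ln < min_block // 2:
            ln = budget - used
        if ln >= n:
            break
        s = int(rng.integers(0, n - ln))
        if overlaps(s, s + ln) or cuts_marker(s, s + ln):
            continue
        blocks.append((s, s + ln))
        used += ln
    # small leftover: extend the last marker block instead of emitting a
    # sliver scaffold, snapping the new edge off marker loci
    remaining = budget - used
    if remaining > 0 and blocks:
        blocks.sort()
        for bi in range(len(blocks) - 1, -1, -1):
            s, e = blocks[bi]
            new_e = min(e + remaining, n)
            while any(ms < new_e < me for ms, me in marker_ivs):
                new_e = min(next(me for ms, me in marker_ivs if ms < new_e < me), n)
            nxt = blocks[bi + 1][0] if bi + 1 < len(blocks) else n
            if new_e <= nxt:
                blocks[bi] = (s, new_e)
                break
    if not blocks:
        raise SimulationError("could not draw contaminant blocks")
    return sorted(blocks)


def build_chimera(
    universe: Universe,
    host_id: str,
    contaminant_ids: Sequence[str],
    assembly_id: str,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Assembly, GroundTruth]:
    """Fragment the host and splice in contaminant blocks.

    Contaminant bases total f/(1-f) x host length (f the configured
    contaminant fraction); each block becomes its own scaffold or, at the
    chimeric-scaffold rate, is concatenated onto a host scaffold.  The
    realized contaminant fraction and all carried marker loci are
    recorded exactly.
    """
    config = config or universe.config
    rng = rng or np.random.default_rng(0)
    if host_id in contaminant_ids:
        raise SimulationError("contaminant equals host")
    host = universe.genomes[host_id]
    scaffolds: list[tuple[str, str, list[TruthInterval]]] = []
    host_len = len(host.sequence)
    # fragment boundaries are snapped off marker loci so every implanted
    # marker survives fragmentation intact (keeps the registry exact)
    marker_ivs = [(l.start, l.end) for l in host.loci if l.kind != "gene"]
    cuts = []
    pos = 0
    for ln in _fragment_lengths(host_len, config, rng):
        pos += ln
        cut = pos
        moved = True
        while moved:
            moved = False
            for s, e in marker_ivs:
                if s < cut < e:
                    cut = e
                    moved = True
        cuts.append(min(cut, host_len))
    cuts = sorted(set(cuts) | {host_len})
    prev = 0
    for i, cut in enumerate(cuts):
        if cut <= prev:
            continue
        seq = host.sequence[prev:cut]
        scaffolds.append(
            (f"s{i+1:03d}", seq, [TruthInterval(0, cut - prev, host_id)])
        )
        prev = cut

    marker_origin: list[tuple[int, GeneLocus, str, int]] = []
    # (scaffold index, locus, organism, offset of block within scaffold)
    # host markers land wherever fragmentation put them
    offset = 0
    cum = 0
    frag_bounds = []
    for sid, seq, _ in scaffolds:
        frag_bounds.append((cum, cum + len(seq)))
        cum += len(seq)
    for locus in host.loci:
        if locus.kind == "gene":
            continue
        for si, (s, e) in enumerate(frag_bounds):
            if locus.start >= s and locus.end <= e:
                marker_origin.append((si, locus, host_id, -s))
                break

    if contaminant_ids and config.contaminant_fraction > 0:
        total_budget = int(
            round(config.contaminant_fraction / (1 - config.contaminant_fraction) * host_len)
        )
        per_org = total_budget // len(contaminant_ids)
        ci = 0
        for org_id in contaminant_ids:
            org = universe.genomes[org_id]
            if per_org > len(org.sequence):
                raise SimulationError("contaminant fraction too large for genome size")
            for bs, be in _contaminant_blocks(org, per_org, config, rng):
                ci += 1
                block = org.sequence[bs:be]
                contained = [
                    l for l in org.loci
                    if l.kind != "gene" and l.start >= bs and l.end <= be
                ]
                if rng.random() < config.chimeric_scaffold_rate and scaffolds:
                    target = int(rng.integers(0, len(scaffolds)))
                    sid, seq, ivs = scaffolds[target]
                    joint = len(seq)
                    ivs.append(TruthInterval(joint, joint + len(block), org_id))
                    scaffolds[target] = (sid, seq + block, ivs)
                    for l in contained:
                        marker_origin.append((target, l, org_id, joint - bs))
                else:
                    scaffolds.append(
                        (f"c{ci:03d}", block, [TruthInterval(0, len(block), org_id)])
                    )
                    for l in contained:
                        marker_origin.append((len(scaffolds) - 1, l, org_id, -bs))

    asm = Assembly(assembly_id, [Scaffold(sid, seq) for sid, seq, _ in scaffolds])
    total = sum(len(s) for _, s, _ in scaffolds)
    contam = sum(
        iv.end - iv.start
        for _, _, ivs in scaffolds
        for iv in ivs
        if iv.organism_id != host_id
    )
    truth = GroundTruth(
        assembly_id=assembly_id,
        host_id=host_id,
        contaminant_ids=list(contaminant_ids),
        intervals={sid: ivs for sid, _, ivs in scaffolds},
        contaminant_fraction=contam / total if total else 0.0,
    )
    for si, locus, org_id, shift in marker_origin:
        sid = scaffolds[si][0]
        truth.marker_loci.append(
            TruthMarkerLocus(
                locus.family_id, locus.kind, sid,
                locus.start + shift, locus.end + shift, org_id,
            )
        )
    return asm, truth


def build_clean_assembly(
    universe: Universe,
    host_id: str,
    assembly_id: str,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Assembly, GroundTruth]:
    cfg = replace(config or universe.config, contaminant_fraction=0.0)
    return build_chimera(universe, host_id, [], assembly_id, cfg, rng)


# -- reads ---------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    assembly: Assembly,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], dict[str, np.ndarray]]:
    """Uniform reads per source organism at its configured depth.

    Reads are sampled within single-source intervals (they do not cross
    chimeric junctions), on either strand, with substitution errors at
    the configured rate.  Returns the reads and the exact per-base depth
    arrays implied by the sampled intervals.
    """
    rl = config.read_length
    reads: list[tuple[str, str]] = []
    depth = {s.scaffold_id: np.zeros(len(s), dtype=np.int32) for s in assembly.scaffolds}
    counter = 0
    for scaf in assembly.scaffolds:
        for iv in truth.intervals.get(scaf.scaffold_id, []):
            span = iv.end - iv.start
            if span < rl:
                continue
            d = config.host_depth if iv.organism_id == truth.host_id else config.contaminant_depth
            n = int(round(d * span / rl))
            starts = rng.integers(iv.start, iv.end - rl + 1, size=n)
            strands = rng.random(n) < 0.5
            n_err = rng.binomial(rl, config.read_error_rate, size=n)
            for j in range(n):
                s = int(starts[j])
                seq = scaf.sequence[s : s + rl]
                if strands[j]:
                    seq = seq.translate(_COMP)[::-1]
                if n_err[j]:
                    chars = list(seq)
                    for p in rng.integers(0, rl, size=int(n_err[j])):
                        cur = chars[p]
                        choices = [b for b in _BASES if b != cur]
                        chars[p] = choices[int(rng.integers(0, 3))]
                    seq = "".join(chars)
                counter += 1
                reads.append((f"r{counter:07d}", seq))
                depth[scaf.scaffold_id][s : s + rl] += 1
    return reads, depth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h.strip().lstrip("@"), seq))
    return out


def write_truth_manifest(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#assembly\t{truth.assembly_id}\n")
        fh.write(f"#host\t{truth.host_id}\n")
        fh.write(f"#contaminants\t{','.join(truth.contaminant_ids)}\n")
        fh.write(f"#contaminant_fraction\t{truth.contaminant_fraction:.6f}\n")
        fh.write("#scaffold\tstart\tend\torganism\n")
        for sid in sorted(truth.intervals):
            for iv in truth.intervals[sid]:
                fh.write(f"{sid}\t{iv.start}\t{iv.end}\t{iv.organism_id}\n")
        fh.write("#marker\tfamily\tkind\tscaffold\tstart\tend\torganism\n")
        for m in truth.marker_loci:
            fh.write(
                f"marker\t{m.family_id}\t{m.kind}\t{m.scaffold_id}\t{m.start}\t"
                f"{m.end}\t{m.organism_id}\n"
            )
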