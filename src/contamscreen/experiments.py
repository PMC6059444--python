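"""Seeded study designs: chimera batteries, dose-response grids, coverage runs.

These functions define the standard experiments the analysis scripts and
the acceptance checks execute: paired chimera/clean batteries screened by
all six methods, a contaminant-fraction dose-response grid for the
genome-wide estimators, and a coverage-validation run with
organism-specific sequencing depths.  Problem sizes (300-kb genomes for
the main battery and the dose-response grid, smaller universes for the
narrower checks) are chosen so a full battery runs in minutes on one
CPU while every stage still has enough signal; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import KmerClassifierConfig
from .coverage import (
    CoverageStats,
    coverage_from_reads,
    coverage_stats,
    segment_report,
)
from .genome import Assembly
from .pipeline import ReferencePack, ScreenResult, build_reference_pack, screen_assembly, score_table
from .simulate import (
    GroundTruth,
    SimConfig,
    build_chimera,
    build_clean_assembly,
    simulate_reads,
    simulate_universe,
    Universe,
)

BATTERY_GENOME_LENGTH = 300_000
GRID_GENOME_LENGTH = 300_000
MIN_DELTA_GC = 15.0


@dataclass
class ChimeraCase:
    host_id: str
    chimera: Assembly
    chimera_truth: GroundTruth
    clean: Assembly
    clean_truth: GroundTruth
    chimera_result: Optional[ScreenResult] = None
    clean_result: Optional[ScreenResult] = None


@dataclass
class Battery:
    universe: Universe
    pack: ReferencePack
    cases: list[ChimeraCase] = field(default_factory=list)

    def scores(self) -> pd.DataFrame:
        results = [c.chimera_result for c in self.cases] + [
            c.clean_result for c in self.cases
        ]
        return score_table([r for r in results if r is not None])


def make_battery_universe(
    seed: int, genome_length: int = BATTERY_GENOME_LENGTH, **overrides
) -> tuple[Universe, ReferencePack]:
    cfg = SimConfig(seed=seed, genome_length=genome_length, **overrides)
    universe = simulate_universe(cfg)
    return universe, build_reference_pack(universe)


def build_cases(
    universe: Universe,
    seed: int,
    n_pairs: int = 10,
    contaminant_fraction: float = 0.10,
    n_contaminants: int = 1,
    min_delta_gc: float = MIN_DELTA_GC,
) -> list[ChimeraCase]:
    """Paired chimera/clean assemblies over the focal genomes (cycled)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_003]))
    hosts = universe.focal_genomes()
    cfg = replace(universe.config, contaminant_fraction=contaminant_fraction)
    cases = []
    for i in range(n_pairs):
        host = hosts[i % len(hosts)]
        contams = universe.pick_contaminants(host, n_contaminants, min_delta_gc, rng)
        chim, chim_truth = build_chimera(
            universe, host, contams, f"chim{i+1:02d}", cfg, rng
        )
        clean, clean_truth = build_clean_assembly(
            universe, host, f"clean{i+1:02d}", cfg, rng
        )
        cases.append(ChimeraCase(host, chim, chim_truth, clean, clean_truth))
    return cases


def run_battery(
    seed: int,
    n_pairs: int = 10,
    genome_length: int = BATTERY_GENOME_LENGTH,
    contaminant_fraction: float = 0.10,
    n_contaminants: int = 1,
    methods: Optional[Sequence[str]] = None,
    screen_clean: bool = True,
) -> Battery:
    """Simulate a universe, build paired chimera/clean assemblies, and
    screen each with the six methods."""
    universe, pack = make_battery_universe(seed, genome_length)
    cases = build_cases(
        universe, seed, n_pairs, contaminant_fraction, n_contaminants
    )
    battery = Battery(universe, pack, cases)
    kwargs = {} if methods is None else {"methods": tuple(methods)}
    for case in cases:
        case.chimera_result = screen_assembly(
            case.chimera, pack, self_genome_id=case.host_id, **kwargs
        )
        if screen_clean:
            case.clean_result = screen_assembly(
                case.clean, pack, self_genome_id=case.host_id, **kwargs
            )
    return battery


def dose_response(
    seed: int,
    fractions: Sequence[float] = (0.05, 0.10, 0.20, 0.30),
    genome_length: int = GRID_GENOME_LENGTH,
    methods: Sequence[str] = ("kmer", "binning"),
) -> pd.DataFrame:
    """Contamination estimates over a grid of true contaminant fractions.

    Host, contaminant and block layout are matched across the grid (same
    derived rng per fraction), isolating the effect of f.
    """
    universe, pack = make_battery_universe(seed, genome_length)
    hosts = universe.focal_genomes()
    host = hosts[seed % len(hosts)]
    pick_rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    contams = universe.pick_contaminants(host, 1, MIN_DELTA_GC, pick_rng)
    rows = []
    for f in fractions:
        cfg = replace(universe.config, contaminant_fraction=f)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        asm, truth = build_chimera(universe, host, contams, f"f{int(f*100):02d}", cfg, rng)
        res = screen_assembly(asm, pack, self_genome_id=host, methods=tuple(methods))
        row = {"fraction": f, "true_percent": 100.0 * truth.contaminant_fraction}
        for m in methods:
            row[m] = res.scores[m]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CoverageRun:
    stats: CoverageStats
    clean_qcd: float
    host_depth: float
    contaminant_depth: float


def coverage_validation(
    seed: int,
    genome_length: int = BATTERY_GENOME_LENGTH,
    host_depth: float = 68.0,
    contaminant_depth: float = 26.0,
    use_true_depth: bool = False,
) -> CoverageRun:
    """Depth-difference validation on one chimera plus one clean assembly.

    Reads are simulated at organism-specific depths, mapped back with the
    naive exact mapper, and per-class (ground-truth scaffold source)
    segment-coverage medians compared; the clean assembly yields the
    quartile coefficient of dispersion under uniform depth.
    """
    cfg = SimConfig(
        seed=seed,
        genome_length=genome_length,
        host_depth=host_depth,
        contaminant_depth=contaminant_depth,
        # two clean scaffold populations: the depth contrast is a
        # per-scaffold comparison, so no chimeric joins here
        chimeric_scaffold_rate=0.0,
    )
    universe = simulate_universe(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 555]))
    hosts = universe.focal_genomes()
    host = hosts[seed % len(hosts)]
    contams = universe.pick_contaminants(host, 1, MIN_DELTA_GC, rng)
    asm, truth = build_chimera(universe, host, contams, "cov_chimera", cfg, rng)

    reads, depth = simulate_reads(asm, truth, cfg, rng)
    if use_true_depth:
        from .coverage import depth_array_to_track

        track = depth_array_to_track(depth)
    else:
        track = coverage_from_reads(asm, reads)
    records = segment_report(asm, [], coverage=track)
    # scaffold class from ground truth; chimeric (mixed-source) scaffolds
    # are excluded — their segments would blur the per-class depth contrast
    labels = {}
    for sid, ivs in truth.intervals.items():
        orgs = {iv.organism_id for iv in ivs}
        if len(orgs) == 1:
            labels[sid] = "FOCAL" if orgs == {truth.host_id} else "CONTAMINANT"
    stats = coverage_stats(records, labels)

    clean, clean_truth = build_clean_assembly(universe, host, "cov_clean", cfg, rng)
    c_reads, c_depth = simulate_reads(clean, clean_truth, cfg, rng)
    if use_true_depth:
        from .coverage import depth_array_to_track

        c_track = depth_array_to_track(c_depth)
    else:
        c_track = coverage_from_reads(clean, c_reads)
    c_records = segment_report(clean, [], coverage=c_track)
    c_labels = {sid: "FOCAL" for sid in clean_truth.intervals}
    c_stats = coverage_stats(c_records, c_labels)
    return CoverageRun(stats, c_stats.qcd, host_depth, contaminant_depth)


def masking_performance(case: ChimeraCase) -> tuple[float, float]:
    """(recall, false-positive rate) of contaminant-base masking with the
    protein-LCA labels, against ground truth."""
    from .coverage import decontaminate, DecontamConfig
    from .taxonomy import Label

    assert case.chimera_result is not None
    res = case.chimera_result
    masked = decontaminate(
        case.chimera,
        res.protein_labels,
        DecontamConfig(mode="mask"),
        marker_hits=[*res.ssu_loci, *res.rprot_hits],
    )
    truth = case.chimera_truth
    scaffold_len = {s.scaffold_id: len(s) for s in case.chimera.scaffolds}
    contam_mask = truth.contaminant_mask(scaffold_len)
    masked_contam = masked_host = total_contam = total_host = 0
    for scaf in masked.scaffolds:
        orig = case.chimera.scaffold(scaf.scaffold_id)
        is_n = np.frombuffer(scaf.sequence.encode(), dtype=np.uint8) == ord("N")
        was_n = np.frombuffer(orig.sequence.encode(), dtype=np.uint8) == ord("N")
        newly = is_n & ~was_n
        cm = contam_mask[scaf.scaffold_id]
        total_contam += int(cm.sum())
        total_host += int((~cm).sum())
        masked_contam += int((newly & cm).sum())
        masked_host += int((newly & ~cm).sum())
    recall = masked_contam / total_contam if total_contam else float("nan")
    fpr = masked_host / total_host if total_host else float("nan")
    return recall, fpr
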