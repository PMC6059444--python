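"""Build the synthetic reference universe and the query assemblies.

Generates the taxonomy, 20 reference genomes in 5 compositionally
distinct phyla (with proteomes, a 20-family single-copy ribosomal-protein
panel and 1-4 SSU rRNA copies per genome), and 10 paired chimera/clean
query assemblies (f = 10%, contaminants from phyla at least 15 GC points
away, carrying their full marker panel).  Writes the reference files and
per-assembly ground truth under results/universe/.

Run:  python analysis/01_simulate_universe.py [--seed 1] [--out results/universe]
"""

import argparse
import pathlib

from contamscreen.experiments import BATTERY_GENOME_LENGTH, build_cases, make_battery_universe
from contamscreen.genome import write_fasta
from contamscreen.markers import write_marker_panel
from contamscreen.simulate import write_truth_manifest
from contamscreen.taxonomy import write_taxonomy


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-pairs", type=int, default=10)
    ap.add_argument("--out", default="results/universe")
    args = ap.parse_args()

    out = pathlib.Path(args.out)
    (out / "references").mkdir(parents=True, exist_ok=True)
    (out / "queries").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    universe, _ = make_battery_universe(args.seed, BATTERY_GENOME_LENGTH)
    write_taxonomy(universe.taxonomy, out / "taxonomy.tsv")
    write_marker_panel(universe.rprot_families, out / "references" / "rprot_panel.fa")
    write_marker_panel([universe.ssu_family], out / "references" / "ssu_panel.fa")
    print(f"universe: {len(universe.genomes)} genomes, "
          f"{len(universe.rprot_families)} marker families, "
          f"{len(universe.ssu_family.references)} SSU references")

    cases = build_cases(universe, args.seed, n_pairs=args.n_pairs)
    for case in cases:
        for asm, truth in (
            (case.chimera, case.chimera_truth),
            (case.clean, case.clean_truth),
        ):
            write_fasta(asm, out / "queries" / f"{asm.assembly_id}.fa")
            write_truth_manifest(truth, out / "truth" / f"{asm.assembly_id}.tsv")
        print(
            f"{case.chimera.assembly_id}: host {case.host_id}, "
            f"contaminants {case.chimera_truth.contaminant_ids}, "
            f"true fraction {100 * case.chimera_truth.contaminant_fraction:.2f}%"
        )
    print(f"wrote {2 * len(cases)} query assemblies under {out}/queries")


if __name__ == "__main__":
    main()
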