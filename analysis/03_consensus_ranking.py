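"""Aggregate the six method scores into the consensus global ranking.

Reads results/method_scores.tsv (written by 02_screen_assemblies.py),
computes per-method ranks, the NA-aware rank average, the global
ranking, per-assembly contamination categories and the Spearman
correlation matrix between methods and the global ranking.

Run:  python analysis/03_consensus_ranking.py
"""

import argparse
import pathlib

import pandas as pd

from contamscreen.consensus import categorize, consensus_report, correlation_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scores", default="results/method_scores.tsv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    scores = pd.read_csv(args.scores, sep="\t", index_col=0)
    report = consensus_report(scores)
    report.to_csv(out / "consensus_ranking.tsv", sep="\t")
    print("consensus ranking (most contaminated first):")
    print(report.round(2).to_string())

    cats = pd.DataFrame(
        {
            a: vars(categorize(scores.loc[a].to_dict()))
            for a in scores.index
        }
    ).T
    cats.to_csv(out / "categories.tsv", sep="\t")
    print("\ncontamination categories:")
    print(cats.to_string())

    corr = correlation_matrix(scores.dropna(axis=1, how="any"))
    corr.to_csv(out / "method_correlations.tsv", sep="\t")
    print("\nSpearman correlations (methods + global ranking):")
    print(corr.round(2).to_string())


if __name__ == "__main__":
    main()
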