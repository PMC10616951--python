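"""Binding landscape of the variant panel: delta-rank maps and promiscuity.

For the mutation-region 15-mers of each deimmunized analog versus the
immunogenic reference, computes the positional percentile-rank change per
allele (positive = loss of predicted affinity) and the allele-frequency-
weighted promiscuity score per peptide, with a paired Wilcoxon signed-rank
comparison of each analog against the reference.

Requires results/simulated/ (run 01 first).
"""

import argparse
from pathlib import Path

import pandas as pd

from mappskit import io, synthetic
from mappskit.binding import compare_promiscuity, delta_rank, promiscuity_score
from mappskit.constructs import generate_kmers, mutation_window

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    sim = RESULTS / "simulated"
    out = RESULTS / "binding"
    cfg = synthetic.default_config(seed)
    constructs = io.read_constructs_fasta(sim / "constructs.fasta")
    freqs = io.read_allele_frequencies_tsv(sim / "allele_frequencies.tsv")
    matrices = {cid: io.read_rank_matrix_tsv(sim / f"ranks_{cid}.tsv") for cid in constructs}
    subs = io.read_substitutions_tsv(sim / "substitutions.tsv")

    region = mutation_window(subs["VA"], constructs["VA"], cfg.k)
    region_starts = [
        s for s, _ in generate_kmers(constructs["VA"], cfg.k)
        if region.start <= s <= region.end - cfg.k + 1
    ]

    def region_scores(cid: str) -> list[float]:
        m = matrices[cid]
        return [
            promiscuity_score(m.peptides[s - 1], m.ranks_for(m.peptides[s - 1]), freqs).score
            for s in region_starts
        ]

    with io.OutputSession(out):
        rows = []
        for variant in ("DI-1", "DI-2"):
            d = delta_rank(matrices["VA"], matrices[variant])
            d.loc[region_starts].to_csv(out / f"delta_rank_VA_vs_{variant}.tsv", sep="\t")
            res = compare_promiscuity(region_scores("VA"), region_scores(variant))
            rows.append({"comparison": f"VA vs {variant}", "test": res.test,
                         "statistic": res.statistic, "p_value": res.pvalue,
                         "n_peptides": res.n})
            print(f"VA vs {variant}: {res.test} p = {res.pvalue:.4f} "
                  f"over {res.n} mutation-region 15-mers")
        pd.DataFrame(rows).to_csv(out / "promiscuity_comparison.tsv", sep="\t", index=False)
        scores = pd.DataFrame({cid: region_scores(cid) for cid in ("VA", "DI-1", "DI-2")},
                              index=region_starts)
        scores.rename_axis("position").to_csv(out / "promiscuity_scores.tsv", sep="\t")
    print(f"wrote delta-rank maps and promiscuity tables to {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
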