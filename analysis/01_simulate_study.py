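"""Simulate the study inputs: cohort, constructs, rank matrices, eluates, cpm.

Generates an 11-donor MAPPs cohort against the four-construct panel (WT, the
immunogenic analog VA, and two deimmunized analogs DI-1/DI-2) plus a
50-donor proliferation cohort, and writes every table in the pipeline's
interchange dialects under results/simulated/.

Run from the repository root:  python analysis/01_simulate_study.py [--seed N]
"""

import argparse
from pathlib import Path

from mappskit import io, synthetic
from mappskit.reference_tables import TCELL_COHORT_SIZE, TCELL_RESPONDER_COUNTS
from mappskit.tcell import ProliferationRecord

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> Path:
    out = RESULTS / "simulated"
    cfg = synthetic.default_config(seed)
    study = synthetic.simulate_study(cfg)
    with io.OutputSession(out):
        io.write_constructs_fasta(cfg.constructs, out / "constructs.fasta")
        io.write_substitutions_tsv(synthetic.default_substitutions(), out / "substitutions.tsv")
        io.write_genotypes_tsv(study.genotypes, out / "genotypes.tsv")
        io.write_allele_frequencies_tsv(cfg.allele_freqs, out / "allele_frequencies.tsv")
        for cid, matrix in study.matrices.items():
            io.write_rank_matrix_tsv(matrix, out / f"ranks_{cid}.tsv")
        records = [r for recs in study.eluates.values() for r in recs]
        io.write_eluates_tsv(records, out / "eluates.tsv")

        # 50-donor proliferation cohort: planted responder counts per construct
        # (VA elicits a response in nearly every donor; WT and the deimmunized
        # analogs in almost none)
        responder_counts = dict(TCELL_RESPONDER_COUNTS, VA=TCELL_COHORT_SIZE - 2)
        cpm_rows = []
        for stim_idx, (cid, n_resp) in enumerate(sorted(responder_counts.items())):
            for d in range(TCELL_COHORT_SIZE):
                test, control = synthetic.simulate_cpm(
                    cfg, d < n_resp, donor_key=d, stimulus_key=stim_idx
                )
                cpm_rows.append(ProliferationRecord(f"T{d + 1}", cid, 8, tuple(test)))
                if stim_idx == 0:  # one medium control per donor x day
                    cpm_rows.append(ProliferationRecord(f"T{d + 1}", "medium", 8, tuple(control)))
        io.write_cpm_tsv(cpm_rows, out / "cpm.tsv")

    n_eluate = sum(len(r) for r in study.eluates.values())
    print(f"wrote simulated study to {out}")
    print(f"  {cfg.n_donors} MAPPs donors, {len(cfg.constructs)} constructs, "
          f"{n_eluate} eluted peptides")
    print(f"  {TCELL_COHORT_SIZE} proliferation donors, "
          f"{len(responder_counts)} stimuli + medium control")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
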