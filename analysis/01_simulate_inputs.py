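#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Emulated study conditions: two C2C12 batches' day-4/day-7 patterned-vs-
unpatterned LFC tables with a 198-gene sarcomere set (planted shift 0.1 log2
at day 7) and an 87-gene in-vivo-upregulated set; a developmental DE table
with 143 up / 78 down significant genes; a TPM matrix in which 87 of the 143
upregulated genes are expressed; striation profiles at the ~2.4 um plateau
sarcomere length; and SYPRO-stained gel lanes with a 3:1 MyHC:actin planted
ratio on patterned substrates.

Writes results/synthetic/.  Run from the repository root:
    python analysis/01_simulate_inputs.py [--seed 1]
"""

import argparse
from pathlib import Path

from sarcoquant import io
from sarcoquant.geneset import derive_invivo_sets
from sarcoquant.synthetic import (LaneSimConfig, LfcSimConfig,
                                  StriationSimConfig, simulate_invivo_de_table,
                                  simulate_lane, simulate_lfc_table,
                                  simulate_striation_profile,
                                  simulate_tpm_matrix)

COMPARISONS = {
    # label -> (sarcomere delta, invivo_up delta); day-7 patterned contrasts
    # plant the headline shifts, earlier/weaker contrasts plant smaller ones
    "batch1_day7_patterned_vs_unpatterned": (0.10, 0.30),
    "batch2_day7_patterned_vs_unpatterned": (0.08, 0.25),
    "batch1_day4_patterned_vs_unpatterned": (0.05, 0.15),
    "batch1_day7_patterned_vs_plastic": (0.12, 0.35),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # LFC tables with planted set shifts
    for i, (label, (d_sarc, d_vivo)) in enumerate(COMPARISONS.items()):
        table, sets = simulate_lfc_table(LfcSimConfig(
            n_background_genes=12000,
            set_sizes={"sarcomere": 198, "invivo_up": 87},
            delta={"sarcomere": d_sarc, "invivo_up": d_vivo},
            sigma=0.3, seed=args.seed + i, comparison_label=label))
        io.write_lfc_table(table, out / f"{label}.lfc.tsv")
        if i == 0:
            io.write_gmt(sets, out / "gene_sets.gmt")
    print(f"wrote {len(COMPARISONS)} LFC tables (12,285 genes each) and "
          f"gene_sets.gmt (sarcomere n=198, invivo_up n=87)")

    # developmental DE table (P2-vs-E18-like) and C2C12 TPM matrix
    de = simulate_invivo_de_table(143, 78, 8000, q_threshold=0.05,
                                  seed=args.seed + 50)
    io.write_lfc_table(de, out / "invivo_P2_vs_E18.de.tsv")
    up, down = derive_invivo_sets(de)
    expressed = frozenset(sorted(up.gene_ids)[:87])
    tpm = simulate_tpm_matrix(list(de.data["gene_id"]), n_samples=6,
                              expressed_ids=expressed, seed=args.seed + 51)
    io.write_tpm_matrix(tpm, out / "c2c12_tpm.tsv")
    print(f"wrote DE table ({len(up)} up / {len(down)} down significant) and "
          f"TPM matrix ({tpm.shape[0]} genes x {tpm.shape[1]} samples, "
          f"87 of the upregulated genes expressed)")

    # striation profiles per substrate (n=8 myotubes each); patterned
    # myotubes sit at the 2.4 um plateau with cleaner striations
    substrates = {"patterned": (2.40, 15.0), "unpatterned": (2.30, 35.0),
                  "glass": (2.20, 50.0)}
    n_per_group = 8
    for s_idx, (sub, (period, noise)) in enumerate(substrates.items()):
        for k in range(n_per_group):
            prof = simulate_striation_profile(StriationSimConfig(
                period_um=period, pixel_size_um=0.1, n_samples=512,
                amplitude=100.0, noise_sd=noise,
                seed=args.seed + 100 + 10 * k + s_idx))
            io.write_profile_csv(prof, out / f"{sub}_{k + 1}.profile.csv")
    print(f"wrote {n_per_group} striation profiles per substrate "
          f"({', '.join(substrates)})")

    # gel lanes: MyHC (~220 kDa, early migration) and actin (~42 kDa);
    # patterned lanes carry 3x MyHC relative to actin
    lanes = {"patterned_d7": (3.0, 1.0), "unpatterned_d7": (1.2, 1.0),
             "plastic_d7": (1.0, 1.0)}
    for j, (lane_id, (myhc, actin)) in enumerate(lanes.items()):
        lane = simulate_lane(LaneSimConfig(
            band_centers=(0.25, 0.75), band_amounts=(myhc, actin),
            band_width=4.0, baseline_level=5.0, noise_sd=0.005,
            n_samples=512, seed=args.seed + 200 + j), lane_id)
        io.write_lane_csv(lane, out / f"{lane_id}.lane.csv")
    print(f"wrote {len(lanes)} gel lanes (planted MyHC:actin ratios "
          f"{[v[0] / v[1] for v in lanes.values()]})")


if __name__ == "__main__":
    main()
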