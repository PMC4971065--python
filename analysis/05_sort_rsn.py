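#!/usr/bin/env python
"""Temporal sorting of RSN time courses against the EEG microstates.

Builds HRF-convolved regressors from each subject's backfitted
segmentation, regresses every RSN component time course on the K
regressors jointly, averages the slopes per group, standardizes them to
Z-scores across components within each microstate x group cell, and
flags pairings with Z >= 1 — then checks the flags against the
generator's known coupling matrix.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from microstate_rsn import (
    RSNTimecourseSet,
    aggregate_z,
    build_regressors,
    read_subject_table,
    sort_components,
)
from microstate_rsn.backfit import Segmentation
from microstate_rsn.rsn_sorting import z_map_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--heatmap", action="store_true",
                    help="also render the Z heat map as PNG")
    args = ap.parse_args()

    data = args.out / "data"
    with open(data / "sim_params.json") as fh:
        params = json.load(fh)
    subjects = read_subject_table(data / "subjects.tsv")
    templates = pd.read_csv(args.out / "templates.tsv", sep="\t")
    state_labels = tuple(templates.columns)
    K = len(state_labels)

    slopes, groups, ids = [], [], []
    for _, row in subjects.table.iterrows():
        sid = row["subject_id"]
        seg_df = pd.read_csv(args.out / "segmentations" / f"{sid}.tsv", sep="\t")
        seg = Segmentation(seg_df["label"].to_numpy(),
                           seg_df["corr"].to_numpy(), params["fs"])
        regs = build_regressors(seg, params["tr_s"], params["n_volumes"],
                                n_states=K)
        tc = np.loadtxt(data / "rsn" / f"{sid}.tsv", delimiter="\t")
        rsn = RSNTimecourseSet(tc, tr_s=params["tr_s"], subject_id=sid)
        slopes.append(sort_components(regs, rsn))
        groups.append(row["group"])
        ids.append(sid)

    result = aggregate_z(np.asarray(slopes), groups, ids)
    table = z_map_table(result, state_labels)
    table.to_csv(args.out / "z_map.tsv", sep="\t", index=False)
    flagged = table[table["flagged"]]
    flagged.to_csv(args.out / "flagged_pairs.tsv", sep="\t", index=False)

    coupling = np.loadtxt(data / "ground_truth_coupling.tsv", delimiter="\t")
    truth_pairs = {(k, c) for k, c in zip(*np.nonzero(coupling))}
    print("flagged microstate-RSN pairings (Z >= 1):")
    for grp in result.flagged:
        got = set(result.flagged[grp])
        pretty = sorted((state_labels[k], c) for k, c in got)
        hits = len(got & truth_pairs)
        print(f"  {grp:>8}: {pretty} — {hits}/{len(truth_pairs)} true "
              f"couplings recovered, {len(got - truth_pairs)} spurious")

    if args.heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(result.z_map), figsize=(11, 3.2),
                                 sharey=True)
        for ax, (grp, z) in zip(np.atleast_1d(axes), result.z_map.items()):
            im = ax.imshow(z, cmap="RdBu_r", vmin=-3, vmax=3, aspect="auto")
            ax.set_title(grp)
            ax.set_xlabel("RSN component")
            ax.set_yticks(range(K), state_labels)
        fig.colorbar(im, ax=axes, label="Z")
        fig.savefig(args.out / "z_heatmap.png", dpi=150)
        print(f"heat map -> {args.out}/z_heatmap.png")
    print(f"wrote z_map.tsv and flagged_pairs.tsv -> {args.out}")


if __name__ == "__main__":
    main()
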