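#!/usr/bin/env python
"""Microstate segmentation: GFP peaks, clustering, backfitting.

Reads the cohort EEG, band-passes 1-40 Hz at 125 Hz, pools the GFP-peak
topographies of all subjects (patients and controls together, so group
comparisons share one template set), chooses the number of microstate
classes by the cross-validation criterion, clusters with the
polarity-invariant modified K-means, labels templates A-D against the
canonical reference patterns, checks group topographic consistency with
a TANOVA, and backfits the templates to every subject's continuous EEG.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from microstate_rsn import (
    backfit,
    builtin_montage,
    canonical_labeling,
    canonical_reference_maps,
    compute_gfp,
    extract_topographies,
    find_gfp_peaks,
    modified_kmeans,
    preprocess,
    read_eeg,
    read_subject_table,
    select_k,
    tanova,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--k-range", type=int, nargs=2, default=(2, 6))
    ap.add_argument("--k", type=int, default=None,
                    help="fix the number of microstate classes instead of "
                         "using the cross-validation choice")
    args = ap.parse_args()

    data = args.out / "data"
    montage = builtin_montage("standard-10-20-64")
    subjects = read_subject_table(data / "subjects.tsv")

    recs, peak_sets, row_groups = {}, {}, []
    for _, row in subjects.table.iterrows():
        sid = row["subject_id"]
        rec = read_eeg(data / "eeg" / f"{sid}.edf", montage,
                       subject_id=sid, group=row["group"])
        rec = preprocess(rec, band=(1.0, 40.0), target_fs=125.0)
        g = find_gfp_peaks(compute_gfp(rec))
        tops = extract_topographies(rec, g)
        recs[sid], peak_sets[sid] = rec, (g, tops)
        row_groups.extend([row["group"]] * tops.n_peaks)

    row_groups = np.asarray(row_groups)
    pooled = np.vstack([t.maps for _, t in peak_sets.values()])
    print(f"pooled {pooled.shape[0]} GFP-peak topographies from "
          f"{len(recs)} subjects")

    lo, hi = args.k_range
    chosen, cvs, _ = select_k(pooled, range(lo, hi + 1), n_restarts=10,
                              seed=args.seed)
    pd.DataFrame({"K": list(cvs), "cv_criterion": list(cvs.values())}).to_csv(
        args.out / "k_selection.tsv", sep="\t", index=False)
    print("cross-validation criterion:",
          {k: round(v, 4) for k, v in cvs.items()}, f"-> K = {chosen}")
    K = args.k if args.k is not None else chosen
    if args.k is not None and args.k != chosen:
        print(f"overriding cross-validation choice {chosen} with K = {K}")

    res = modified_kmeans(pooled, K, n_restarts=50, seed=args.seed)
    if K == 4:
        res = canonical_labeling(res, canonical_reference_maps(montage))
    labels = res.templates.labels
    print(f"clustering: GEV = {res.gev_total:.3f} "
          f"(per template {np.round(res.gev_per_template, 3)})")

    tpl = pd.DataFrame(res.templates.templates.T, columns=list(labels))
    tpl.to_csv(args.out / "templates.tsv", sep="\t", index=False)

    # topographic consistency per class: peak maps carry arbitrary alpha
    # polarity, so align each to its template before group averaging
    aligned = pooled * res.polarity[:, None]
    print("TANOVA per microstate class (patients vs controls):")
    for k, lab in enumerate(labels):
        sel = res.assignments == k
        diss, p = tanova(aligned[sel & (row_groups == "patient")],
                         aligned[sel & (row_groups == "control")],
                         n_perm=499, seed=args.seed + k)
        verdict = "consistent" if p > 0.05 else "different"
        print(f"  {lab}: DISS = {diss:.4f}, p = {p:.3f} ({verdict})")

    seg_dir = args.out / "segmentations"
    seg_dir.mkdir(parents=True, exist_ok=True)
    for sid, rec in recs.items():
        seg = backfit(rec, res.templates)
        g, _ = peak_sets[sid]
        pd.DataFrame({
            "label": seg.labels,
            "corr": np.round(seg.corr, 6),
            "gfp": np.round(g.values, 6),
        }).to_csv(seg_dir / f"{sid}.tsv", sep="\t", index=False)
    print(f"wrote templates, K selection and {len(recs)} segmentations "
          f"-> {args.out}")


if __name__ == "__main__":
    main()
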