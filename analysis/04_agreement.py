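#!/usr/bin/env python
"""Method comparison and repeatability. Pairs the base-reading B-line
score with gravimetric EVLWI (Pearson r), and compares repeat readings
(intra- and inter-observer) by Bland–Altman limits (bias ± 2 SD) and
Lin's concordance correlation. Writes agreement.json and, optionally,
scatter/Bland–Altman figures."""

import argparse
import json
from pathlib import Path

import pandas as pd

from lungwater.agreement import (
    PairedSeries,
    bland_altman,
    concordance,
    pearson,
    plot_agreement,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    scores = pd.read_csv(args.cohort / "scores.csv")
    evlw = pd.read_csv(args.cohort / "evlw.csv")
    truth = pd.read_csv(args.cohort / "truth.csv")

    base = scores[(scores.session_id == "S1")].set_index("animal_id")["total"]
    evlwi = evlw.set_index("animal_id")["evlw_index"]
    ids = sorted(set(base.index) & set(evlwi.index))
    series = PairedSeries.from_arrays(ids, base[ids], evlwi[ids])
    r, p = pearson(series)
    report = {"correlation": {"pearson_r": r, "pearson_p": p, "n": len(ids)}}
    print(f"B-line score vs gravimetric EVLWI: r = {r:.3f} (p = {p:.2e}, n = {len(ids)})")

    oa_ids = sorted(truth.loc[truth.group == "oa", "animal_id"])
    for label, observer in (("intra_observer", "OBS1"), ("inter_observer", "OBS2")):
        rep = scores[(scores.session_id == "S2")
                     & (scores.observer_id == observer)].set_index("animal_id")["total"]
        ids2 = [a for a in oa_ids if a in rep.index and a in base.index]
        pair = PairedSeries.from_arrays(ids2, base[ids2], rep[ids2])
        bias, sd, limits, n_out = bland_altman(pair.x, pair.y)
        ccc, lo, hi = concordance(pair)
        report[label] = {"n": len(ids2), "ba_bias": bias, "ba_sd": sd,
                         "ba_limits": list(limits), "ba_n_outside": n_out,
                         "concordance": ccc, "concordance_ci": [lo, hi]}
        print(f"{label}: bias = {bias:+.2f}, limits = [{limits[0]:.2f}, "
              f"{limits[1]:.2f}], {n_out}/{len(ids2)} beyond 2 SD, "
              f"CCC = {ccc:.3f} (95% CI {lo:.2f}–{hi:.2f})")
        if args.plots:
            figdir = args.cohort / "figures"
            figdir.mkdir(exist_ok=True)
            plot_agreement(pair, figdir / f"{label}_scatter.png",
                           figdir / f"{label}_bland_altman.png",
                           xlabel="reading 1", ylabel="reading 2")

    if args.plots:
        figdir = args.cohort / "figures"
        figdir.mkdir(exist_ok=True)
        plot_agreement(series, figdir / "score_vs_evlwi_scatter.png",
                       figdir / "score_vs_evlwi_bland_altman.png",
                       xlabel="B-line score", ylabel="EVLWI")

    with open(args.cohort / "agreement.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    print(f"report written to {args.cohort / 'agreement.json'}")


if __name__ == "__main__":
    main()
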