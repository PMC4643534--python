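#!/usr/bin/env python
"""Derive extravascular lung water from the gravimetric measurements:
water fractions of the dried aliquots, total lung water, the
hemoglobin-dilution residual-blood correction, EVLW = total −
intravascular water, and EVLWI (per 100 g body mass by default).
Writes evlw.csv and prints group summaries plus the Welch test between
arms."""

import argparse
from pathlib import Path

import pandas as pd

from lungwater.agreement import welch_t
from lungwater.pipeline import gravimetry_command


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--normalization", default="per_100g_body")
    args = ap.parse_args()

    gravimetry_command(args.cohort / "gravimetry.csv", args.cohort / "evlw.csv",
                       normalization=args.normalization)
    evlw = pd.read_csv(args.cohort / "evlw.csv")
    truth = pd.read_csv(args.cohort / "truth.csv")
    merged = evlw.merge(truth[["animal_id", "group"]], on="animal_id")

    print(f"EVLWI ({args.normalization}) by group:")
    print(merged.groupby("group")["evlw_index"].agg(["count", "mean", "std"]).round(3))
    ctrl = merged.loc[merged.group == "control", "evlw_index"]
    oa = merged.loc[merged.group == "oa", "evlw_index"]
    t, df, p = welch_t(ctrl, oa)
    print(f"Welch t = {t:.2f} (df = {df:.1f}), p = {p:.2e}")
    print("wet/dry ratio by group:")
    print(merged.groupby("group")["wet_dry_ratio"].agg(["mean", "std"]).round(2))


if __name__ == "__main__":
    main()
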