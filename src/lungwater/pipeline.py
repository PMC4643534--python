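"""End-to-end orchestration: generate → score → gravimetry → agreement.

``run_all`` produces, under one output directory:

* observations.csv — base reading plus intra- and inter-observer repeat
  readings for every animal,
* gravimetry.csv, truth.csv — measurement inputs and simulator ground truth,
* scores.csv, evlw.csv — per-reading B-line scores and per-animal EVLW,
* report.json — group summaries, score-vs-EVLWI correlation, Welch group
  test, and Bland–Altman + concordance repeatability blocks, with the
  full configuration echoed for provenance.

The file-level subcommand functions (``score_command`` etc.) are the
same operations lifted to CSV paths, so composing them reproduces
``run_all`` on identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np

from . import io as lio
from .agreement import (
    PairedSeries,
    bland_altman,
    concordance,
    pearson,
    plot_agreement,
    welch_t,
)
from .gravimetry import Normalization, compute_evlw
from .scoring import score_animal
from .synth import CohortConfig, ReadingMode, generate_cohort, replicate_reading

__all__ = ["RunConfig", "run_all", "generate_command", "score_command",
           "gravimetry_command", "agree_command"]

logger = logging.getLogger(__name__)

BASE_SESSION = ("S1", "OBS1")
INTRA_SESSION = ("S2", "OBS1")
INTER_SESSION = ("S2", "OBS2")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = None  # type: ignore[assignment]
    normalization: Normalization = Normalization.PER_100G_BODY
    ba_multiplier: float = 2.0
    concordance_method: str = "lin"
    outdir: Union[str, Path] = "results/run"
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort is None:
            object.__setattr__(self, "cohort", CohortConfig.calibrated())
        object.__setattr__(self, "normalization", Normalization(self.normalization))
        if self.concordance_method not in ("lin", "icc"):
            raise ValueError("concordance_method must be 'lin' or 'icc'")
        if self.ba_multiplier <= 0:
            raise ValueError("Bland–Altman multiplier must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        if cohort is not None and not isinstance(cohort, CohortConfig):
            cohort = CohortConfig.calibrated(**cohort)
        return cls(cohort=cohort, **d)

    def echo(self) -> dict:
        d = asdict(self)
        d["normalization"] = self.normalization.value
        d["outdir"] = str(self.outdir)
        return d


def _repeatability_block(series: PairedSeries, k: float, method: str) -> dict:
    bias, sd, limits, n_outside = bland_altman(series.x, series.y, k=k)
    ccc, lo, hi = concordance(series, method=method)
    return {
        "n": len(series),
        "ba_bias": bias,
        "ba_sd": sd,
        "ba_limits": list(limits),
        "ba_n_outside": n_outside,
        "concordance": ccc,
        "concordance_ci": [lo, hi],
        "concordance_method": method,
    }


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the report dict (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags: list[str] = []

    animals = generate_cohort(config.cohort)
    # repeat-reading seeds derived from the cohort seed, one stream per animal/mode
    rep_root = np.random.SeedSequence(entropy=(config.cohort.seed, 1))
    rep_seeds = rep_root.generate_state(2 * max(len(animals), 1)) % (2**31)

    obs_rows: list[dict] = []
    for i, a in enumerate(animals):
        obs_rows += lio.observation_rows(a.animal_id, *BASE_SESSION, a.observations)
        intra = replicate_reading(a, ReadingMode.INTRA, int(rep_seeds[2 * i]),
                                  config.cohort.observer)
        obs_rows += lio.observation_rows(a.animal_id, *INTRA_SESSION, intra)
        inter = replicate_reading(a, ReadingMode.INTER, int(rep_seeds[2 * i + 1]),
                                  config.cohort.observer)
        obs_rows += lio.observation_rows(a.animal_id, *INTER_SESSION, inter)

    obs_path = outdir / "observations.csv"
    grav_path = outdir / "gravimetry.csv"
    lio.write_observations_csv(obs_rows, obs_path)
    lio.write_gravimetry_csv({a.animal_id: a.gravimetry for a in animals}, grav_path)
    lio.write_truth_csv(animals, outdir / "truth.csv")

    scores = score_command(obs_path, outdir / "scores.csv")
    evlw = gravimetry_command(grav_path, outdir / "evlw.csv",
                              normalization=config.normalization)
    for animal_id, res in evlw.items():
        for f in res.flags:
            flags.append(f"{animal_id}:{f}")

    group_of = {a.animal_id: a.group for a in animals}
    base_totals = {
        aid: res.total for (aid, sess, obs_id), res in scores.items()
        if (sess, obs_id) == BASE_SESSION
    }
    report: dict = {
        "config": config.echo(),
        "n_animals": len(animals),
        "group_summaries": {},
        "flags": flags,
    }
    for grp in ("control", "oa"):
        totals = [t for aid, t in base_totals.items() if group_of[aid] == grp]
        idx = [evlw[aid].evlw_index for aid in base_totals if group_of[aid] == grp]
        if totals:
            report["group_summaries"][grp] = {
                "n": len(totals),
                "score_mean": float(np.mean(totals)),
                "score_sd": float(np.std(totals, ddof=1)) if len(totals) > 1 else 0.0,
                "evlwi_mean": float(np.mean(idx)),
                "evlwi_sd": float(np.std(idx, ddof=1)) if len(idx) > 1 else 0.0,
            }

    paired_ids = sorted(set(base_totals) & set(evlw))
    if len(paired_ids) < 3:
        logger.warning("fewer than 3 paired animals; agreement statistics skipped")
        report["agreement_skipped"] = True
    else:
        series = PairedSeries.from_arrays(
            paired_ids,
            [base_totals[a] for a in paired_ids],
            [evlw[a].evlw_index for a in paired_ids],
        )
        r, p = pearson(series)
        report["correlation"] = {"pearson_r": r, "pearson_p": p, "n": len(series)}

        ctrl = [base_totals[a] for a in paired_ids if group_of[a] == "control"]
        oa = [base_totals[a] for a in paired_ids if group_of[a] == "oa"]
        if len(ctrl) >= 2 and len(oa) >= 2:
            t, df, tp = welch_t(ctrl, oa)
            report["group_test"] = {"welch_t": t, "df": df, "p": tp}

        for label, sess in (("intra_observer", INTRA_SESSION),
                            ("inter_observer", INTER_SESSION)):
            rep_totals = {
                aid: res.total for (aid, s, o), res in scores.items()
                if (s, o) == sess
            }
            ids = [a for a in paired_ids if a in rep_totals]
            if len(ids) >= 3:
                rep_series = PairedSeries.from_arrays(
                    ids, [base_totals[a] for a in ids], [rep_totals[a] for a in ids]
                )
                report[label] = _repeatability_block(
                    rep_series, config.ba_multiplier, config.concordance_method
                )
                if config.make_plots:
                    plot_agreement(
                        rep_series,
                        outdir / f"{label}_scatter.png",
                        outdir / f"{label}_bland_altman.png",
                        k=config.ba_multiplier,
                        xlabel="reading 1 (score)",
                        ylabel="reading 2 (score)",
                    )
        if config.make_plots:
            plot_agreement(
                series,
                outdir / "score_vs_evlwi_scatter.png",
                outdir / "score_vs_evlwi_bland_altman.png",
                k=config.ba_multiplier,
                xlabel="B-line score",
                ylabel=f"EVLWI ({config.normalization.value})",
            )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def generate_command(cohort: CohortConfig, outdir: Union[str, Path]) -> None:
    """Write a cohort's observation/gravimetry/truth CSVs without analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    animals = generate_cohort(cohort)
    rows: list[dict] = []
    for a in animals:
        rows += lio.observation_rows(a.animal_id, *BASE_SESSION, a.observations)
    lio.write_observations_csv(rows, outdir / "observations.csv")
    lio.write_gravimetry_csv({a.animal_id: a.gravimetry for a in animals},
                             outdir / "gravimetry.csv")
    lio.write_truth_csv(animals, outdir / "truth.csv")


def score_command(observations_csv, scores_csv) -> dict:
    """Score every (animal, session, observer) reading in a CSV."""
    readings = lio.read_observations_csv(observations_csv)
    if not readings:
        logger.warning("%s: no observation rows; writing empty scores file",
                       observations_csv)
    results = {key: score_animal(obs) for key, obs in sorted(readings.items())}
    lio.write_scores_csv(results, scores_csv)
    return results


def gravimetry_command(gravimetry_csv, evlw_csv,
                       normalization=Normalization.PER_100G_BODY) -> dict:
    """Compute EVLW for every animal in a gravimetry CSV."""
    samples = lio.read_gravimetry_csv(gravimetry_csv)
    if not samples:
        logger.warning("%s: no gravimetry rows; writing empty EVLW file",
                       gravimetry_csv)
    results = {aid: compute_evlw(s, normalization=normalization)
               for aid, s in sorted(samples.items())}
    lio.write_evlw_csv(results, evlw_csv)
    return results


def agree_command(scores_csv, evlw_csv, report_json,
                  ba_multiplier: float = 2.0,
                  concordance_method: str = "lin") -> dict:
    """Correlation + agreement between scored readings and EVLW files.

    Pairs the base reading (first session/observer per animal) with
    EVLWI; if a second reading exists per animal, adds a repeatability
    block between the two readings.
    """
    import pandas as pd

    scores = pd.read_csv(scores_csv, dtype={"animal_id": str, "session_id": str,
                                            "observer_id": str})
    evlw = pd.read_csv(evlw_csv, dtype={"animal_id": str})
    if scores.empty or evlw.empty:
        raise lio.CsvSchemaError("agree: empty scores or EVLW input")

    scores = scores.sort_values(["animal_id", "session_id", "observer_id"])
    base = scores.groupby("animal_id", sort=True).first().reset_index()
    shared = sorted(set(base["animal_id"]) & set(evlw["animal_id"]))
    if not shared:
        raise lio.CsvSchemaError("agree: scores and EVLW files share no animal ids")
    if len(shared) < 3:
        raise lio.CsvSchemaError("agree: fewer than 3 paired animals")

    base_map = dict(zip(base["animal_id"], base["total"]))
    evlw_map = dict(zip(evlw["animal_id"], evlw["evlw_index"]))
    series = PairedSeries.from_arrays(shared,
                                      [base_map[a] for a in shared],
                                      [evlw_map[a] for a in shared])
    r, p = pearson(series)
    report = {"correlation": {"pearson_r": r, "pearson_p": p, "n": len(series)}}

    second = (
        scores.groupby("animal_id", sort=True)
        .nth(1)
        .reset_index()
        if scores.groupby("animal_id").size().max() > 1
        else None
    )
    if second is not None and not second.empty:
        sec_map = dict(zip(second["animal_id"], second["total"]))
        ids = [a for a in shared if a in sec_map]
        if len(ids) >= 3:
            rep_series = PairedSeries.from_arrays(
                ids, [base_map[a] for a in ids], [sec_map[a] for a in ids]
            )
            report["repeatability"] = _repeatability_block(
                rep_series, ba_multiplier, concordance_method
            )

    with open(report_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
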