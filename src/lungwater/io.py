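"""CSV schemas shared by the simulator and the real-data entry points.

Observations:  animal_id, session_id, observer_id, site (Z<zone>S<space>),
               mode, count, segments (semicolon-separated cm), space_width_cm
Gravimetry:    animal_id, lung_wet_mass_g, added_water_mass_g,
               homogenate_wet_g, homogenate_dry_g, supernatant_wet_g,
               supernatant_dry_g, blood_wet_g, blood_dry_g, blood_hb_gdl,
               supernatant_hb_gdl, hematocrit, body_mass_g
Scores:        animal_id, session_id, observer_id, zone1..zone4,
               total_raw, total, n_missing_sites
EVLW results:  animal_id, f_hom, f_sup, f_blood, total_lung_water_g,
               residual_blood_g, evlw_g, evlw_index, wet_dry_ratio,
               normalization, flags
Ground truth:  animal_id, group, body_mass_g, severity, true_evlwi,
               true_evlw_g, expected_score

Schema violations raise ``CsvSchemaError`` with the offending row index.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .gravimetry import EVLWResult, GravimetrySample
from .layout import parse_site
from .scoring import BLineScoreResult, Mode, SpaceObservation
from .synth import SyntheticAnimal

__all__ = [
    "CsvSchemaError",
    "OBSERVATION_COLUMNS",
    "GRAVIMETRY_COLUMNS",
    "write_observations_csv",
    "read_observations_csv",
    "write_gravimetry_csv",
    "read_gravimetry_csv",
    "write_scores_csv",
    "write_evlw_csv",
    "write_truth_csv",
]

OBSERVATION_COLUMNS = [
    "animal_id", "session_id", "observer_id", "site",
    "mode", "count", "segments", "space_width_cm",
]
GRAVIMETRY_COLUMNS = [
    "animal_id", "lung_wet_mass_g", "added_water_mass_g",
    "homogenate_wet_g", "homogenate_dry_g",
    "supernatant_wet_g", "supernatant_dry_g",
    "blood_wet_g", "blood_dry_g",
    "blood_hb_gdl", "supernatant_hb_gdl", "hematocrit", "body_mass_g",
]


class CsvSchemaError(ValueError):
    """A CSV file violated its schema; the message addresses the row."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvSchemaError(f"{path}: missing required columns {missing}")


def observation_rows(
    animal_id: str,
    session_id: str,
    observer_id: str,
    observations: Iterable[SpaceObservation],
) -> list[dict]:
    rows = []
    for obs in observations:
        rows.append(
            {
                "animal_id": animal_id,
                "session_id": session_id,
                "observer_id": observer_id,
                "site": obs.site.serialize(),
                "mode": obs.mode.value,
                "count": "" if obs.count is None else obs.count,
                "segments": ";".join(f"{s:.6g}" for s in obs.segments),
                "space_width_cm": "" if obs.space_width is None else f"{obs.space_width:.6g}",
            }
        )
    return rows


def write_observations_csv(rows: Sequence[dict], path: Union[str, Path]) -> None:
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def _parse_observation(row: pd.Series, path, idx: int) -> SpaceObservation:
    try:
        site = parse_site(str(row["site"]))
        mode = Mode(str(row["mode"]))
        count = None
        if mode is Mode.DISCRETE:
            raw = row["count"]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                raise ValueError("discrete row lacks a count")
            count = int(float(raw))
        segments: tuple[float, ...] = ()
        width = None
        if mode is Mode.CONFLUENT:
            raw_seg = row.get("segments", "")
            if not isinstance(raw_seg, str) or not raw_seg:
                raise ValueError("confluent row lacks segments")
            segments = tuple(float(tok) for tok in raw_seg.split(";") if tok)
            raw_w = row.get("space_width_cm")
            if raw_w is None or raw_w == "" or (isinstance(raw_w, float) and math.isnan(raw_w)):
                raise ValueError("confluent row lacks space_width_cm")
            width = float(raw_w)
        return SpaceObservation(site=site, mode=mode, count=count,
                                segments=segments, space_width=width)
    except (ValueError, KeyError) as exc:
        raise CsvSchemaError(f"{path}, row {idx + 2}: {exc}") from exc


def read_observations_csv(
    path: Union[str, Path],
) -> dict[tuple[str, str, str], list[SpaceObservation]]:
    """Observations grouped by (animal_id, session_id, observer_id)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "session_id": str,
                                  "observer_id": str, "site": str,
                                  "segments": str}, keep_default_na=False)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    readings: dict[tuple[str, str, str], list[SpaceObservation]] = {}
    for idx, row in df.iterrows():
        key = (row["animal_id"], row["session_id"], row["observer_id"])
        readings.setdefault(key, []).append(_parse_observation(row, path, idx))
    return readings


def write_gravimetry_csv(
    samples: Mapping[str, GravimetrySample], path: Union[str, Path]
) -> None:
    rows = []
    for animal_id, s in samples.items():
        rows.append(
            {
                "animal_id": animal_id,
                "lung_wet_mass_g": s.lung_wet_mass,
                "added_water_mass_g": s.added_water_mass,
                "homogenate_wet_g": s.homogenate_wet_mass,
                "homogenate_dry_g": s.homogenate_dry_mass,
                "supernatant_wet_g": s.supernatant_wet_mass,
                "supernatant_dry_g": s.supernatant_dry_mass,
                "blood_wet_g": s.blood_wet_mass,
                "blood_dry_g": s.blood_dry_mass,
                "blood_hb_gdl": s.blood_hb,
                "supernatant_hb_gdl": s.supernatant_hb,
                "hematocrit": s.hematocrit,
                "body_mass_g": s.body_mass,
            }
        )
    pd.DataFrame(rows, columns=GRAVIMETRY_COLUMNS).to_csv(path, index=False)


def read_gravimetry_csv(path: Union[str, Path]) -> dict[str, GravimetrySample]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, GRAVIMETRY_COLUMNS, path)
    samples: dict[str, GravimetrySample] = {}
    for idx, row in df.iterrows():
        try:
            samples[row["animal_id"]] = GravimetrySample(
                lung_wet_mass=float(row["lung_wet_mass_g"]),
                added_water_mass=float(row["added_water_mass_g"]),
                homogenate_wet_mass=float(row["homogenate_wet_g"]),
                homogenate_dry_mass=float(row["homogenate_dry_g"]),
                supernatant_wet_mass=float(row["supernatant_wet_g"]),
                supernatant_dry_mass=float(row["supernatant_dry_g"]),
                blood_wet_mass=float(row["blood_wet_g"]),
                blood_dry_mass=float(row["blood_dry_g"]),
                blood_hb=float(row["blood_hb_gdl"]),
                supernatant_hb=float(row["supernatant_hb_gdl"]),
                hematocrit=float(row["hematocrit"]),
                body_mass=float(row["body_mass_g"]),
            )
        except ValueError as exc:
            raise CsvSchemaError(f"{path}, row {idx + 2}: {exc}") from exc
    return samples


def write_scores_csv(
    results: Mapping[tuple[str, str, str], BLineScoreResult], path: Union[str, Path]
) -> None:
    rows = []
    for (animal_id, session_id, observer_id), res in results.items():
        row = {
            "animal_id": animal_id,
            "session_id": session_id,
            "observer_id": observer_id,
        }
        for z in range(1, 5):
            row[f"zone{z}"] = res.per_zone.get(z, 0.0)
        row["total_raw"] = res.total_raw
        row["total"] = res.total
        row["n_missing_sites"] = len(res.missing_sites)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_evlw_csv(results: Mapping[str, EVLWResult], path: Union[str, Path]) -> None:
    rows = []
    for animal_id, r in results.items():
        rows.append(
            {
                "animal_id": animal_id,
                "f_hom": r.f_hom,
                "f_sup": r.f_sup,
                "f_blood": r.f_blood,
                "total_lung_water_g": r.total_lung_water,
                "residual_blood_g": r.residual_blood_mass,
                "evlw_g": r.evlw,
                "evlw_index": r.evlw_index,
                "wet_dry_ratio": r.wet_dry_ratio,
                "normalization": r.normalization.value,
                "flags": ";".join(r.flags),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth_csv(animals: Sequence[SyntheticAnimal], path: Union[str, Path]) -> None:
    rows = [
        {
            "animal_id": a.animal_id,
            "group": a.group,
            "body_mass_g": a.body_mass,
            "severity": a.severity,
            "true_evlwi": a.evlwi_true,
            "true_evlw_g": a.evlw_true_g,
            "expected_score": a.expected_score,
        }
        for a in animals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
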