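"""Score a single-dose combination screen from well-level apoptosis readouts.

The screen measures percent cleaved caspase 3 per tumor line under four
conditions: vehicle (DMSO) alone, compound alone, vehicle + effector T
cells, and compound + effector T cells.  Each compound's interaction score
is the effector-attributable apoptosis under compound treatment divided by
the apoptosis induced by effectors alone::

    score = (caspase_combo - caspase_compound) / caspase_til

Scores above the enhancer threshold (default 1) flag compounds that
sensitize tumor cells to T-cell-mediated killing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    MissingConditionError,
    UnscorableError,
    ValidationError,
)

VEHICLE_ID = "DMSO"
WITH_TILS = "with_tils"
WITHOUT_TILS = "without_tils"

#: canonical column order for well tables
WELL_COLUMNS = [
    "plate_id",
    "well_id",
    "tumor_line_id",
    "compound_id",
    "dose",
    "til_status",
    "replicate_index",
    "pct_caspase3",
]

#: column order of the results table / CSV
RESULT_COLUMNS = [
    "tumor_line_id",
    "compound_id",
    "caspase_compound",
    "caspase_til",
    "caspase_combo",
    "caspase_vehicle",
    "comboscore",
    "rank",
    "is_enhancer",
    "flag",
]

_TIL_LITERALS = {"TIL": WITH_TILS, "NOTIL": WITHOUT_TILS,
                 WITH_TILS: WITH_TILS, WITHOUT_TILS: WITHOUT_TILS}


@dataclass(frozen=True)
class WellMeasurement:
    """One well's readout with its experimental annotations."""

    plate_id: str
    well_id: str
    tumor_line_id: str
    compound_id: str
    dose: float
    til_status: str
    replicate_index: int
    pct_caspase3: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_caspase3 <= 100.0:
            raise ValidationError(
                f"well {self.well_id!r}: pct_caspase3 {self.pct_caspase3} "
                "outside [0, 100]"
            )
        if self.dose < 0:
            raise ValidationError(f"well {self.well_id!r}: negative dose")
        if (self.dose == 0) != (self.compound_id == VEHICLE_ID):
            raise ValidationError(
                f"well {self.well_id!r}: dose must be 0 iff compound is "
                f"{VEHICLE_ID!r} (got dose={self.dose}, "
                f"compound={self.compound_id!r})"
            )
        if self.til_status not in (WITH_TILS, WITHOUT_TILS):
            raise ValidationError(
                f"well {self.well_id!r}: bad til_status {self.til_status!r}"
            )
        if self.replicate_index < 1:
            raise ValidationError(
                f"well {self.well_id!r}: replicate_index must be >= 1"
            )


WellsLike = Union[pd.DataFrame, Iterable[WellMeasurement]]


def wells_to_frame(wells: WellsLike) -> pd.DataFrame:
    """Normalize wells to a validated DataFrame with :data:`WELL_COLUMNS`."""
    if isinstance(wells, pd.DataFrame):
        df = wells.copy()
    else:
        df = pd.DataFrame([w.__dict__ for w in wells])
    if df.empty:
        raise EmptyInputError("no wells provided")
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"wells table missing columns: {sorted(missing)}")
    df = df[WELL_COLUMNS]
    bad = df[(df["pct_caspase3"] < 0) | (df["pct_caspase3"] > 100)]
    if not bad.empty:
        w = bad.iloc[0]
        raise ValidationError(
            f"well {w['well_id']!r}: pct_caspase3 {w['pct_caspase3']} "
            "outside [0, 100]"
        )
    df["til_status"] = df["til_status"].map(_TIL_LITERALS)
    if df["til_status"].isna().any():
        raise ValidationError("unrecognized til_status literal in wells table")
    return df


def read_wells_csv(path: str | Path) -> pd.DataFrame:
    """Read a wells CSV (header uses ``dose_nM``/``replicate`` and
    ``TIL``/``NOTIL`` literals) into the canonical frame."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well_id": str,
                                  "tumor_line_id": str, "compound_id": str})
    df = df.rename(columns={"dose_nM": "dose", "replicate": "replicate_index"})
    return wells_to_frame(df)


def write_wells_csv(wells: pd.DataFrame, path: str | Path) -> None:
    out = wells.rename(columns={"dose": "dose_nM",
                                "replicate_index": "replicate"})
    out = out.copy()
    out["til_status"] = out["til_status"].map(
        {WITH_TILS: "TIL", WITHOUT_TILS: "NOTIL"})
    out.to_csv(path, index=False)


def summarize_conditions(wells: WellsLike) -> pd.DataFrame:
    """Aggregate replicate wells into per-condition means and sample SDs.

    Returns one row per distinct ``(tumor_line_id, compound_id,
    til_status)`` with columns ``n_replicates``, ``mean_pct`` and
    ``sd_pct`` (0 for a single replicate), sorted by tumor line, compound
    and TIL status.
    """
    df = wells_to_frame(wells)
    grouped = df.groupby(
        ["tumor_line_id", "compound_id", "til_status"], sort=True
    )["pct_caspase3"]
    out = grouped.agg(
        n_replicates="size", mean_pct="mean", sd_pct=lambda s: s.std(ddof=1)
    ).reset_index()
    out["sd_pct"] = out["sd_pct"].fillna(0.0)
    return out


def comboscore(
    caspase_combo: float,
    caspase_compound: float,
    caspase_til: float,
    squared: bool = False,
) -> float:
    """Interaction score ``(combo - compound) / til``.

    ``squared=True`` returns the square of the ratio — an alternative
    reading of the published formula.  It is not the default because
    squaring lets strong antagonists (ratio < -1) exceed the enhancer
    threshold.
    """
    for name, v in (("caspase_combo", caspase_combo),
                    ("caspase_compound", caspase_compound),
                    ("caspase_til", caspase_til)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name} = {v} outside [0, 100]")
    if caspase_til == 0:
        raise UnscorableError("caspase_til is 0: score undefined")
    ratio = (caspase_combo - caspase_compound) / caspase_til
    return ratio * ratio if squared else ratio


def score_screen(
    summaries: pd.DataFrame,
    enhancer_threshold: float = 1.0,
    squared: bool = False,
    background_subtract: bool = False,
) -> pd.DataFrame:
    """Compute per-compound scores, ranks and enhancer calls from
    condition summaries.

    Every non-vehicle compound on a tumor line yields one row.  Compounds
    missing a required condition are flagged ``incomplete:*`` and excluded
    from ranking; a zero effector-alone mean flags ``unscorable:til_zero``.
    A tumor line with no vehicle+TILs condition is a hard error.

    With ``background_subtract`` the vehicle-alone mean is subtracted from
    all three terms before scoring (the vehicle-alone condition is then
    required).
    """
    required = {"tumor_line_id", "compound_id", "til_status", "mean_pct"}
    if not required <= set(summaries.columns):
        raise ValidationError(
            f"summaries missing columns: {sorted(required - set(summaries.columns))}"
        )
    rows = []
    for line_id, grp in summaries.groupby("tumor_line_id", sort=True):
        means = grp.set_index(["compound_id", "til_status"])["mean_pct"]

        if (VEHICLE_ID, WITH_TILS) not in means.index:
            raise MissingConditionError(
                f"tumor line {line_id!r}: no vehicle+TILs condition"
            )
        til_mean = float(means[(VEHICLE_ID, WITH_TILS)])
        vehicle_mean = (
            float(means[(VEHICLE_ID, WITHOUT_TILS)])
            if (VEHICLE_ID, WITHOUT_TILS) in means.index
            else np.nan
        )
        if background_subtract and np.isnan(vehicle_mean):
            raise MissingConditionError(
                f"tumor line {line_id!r}: background_subtract requires the "
                "vehicle-alone condition"
            )
        bg = vehicle_mean if background_subtract else 0.0

        compounds = sorted(set(grp["compound_id"]) - {VEHICLE_ID})
        for cid in compounds:
            rec = {
                "tumor_line_id": line_id,
                "compound_id": cid,
                "caspase_compound": np.nan,
                "caspase_til": til_mean,
                "caspase_combo": np.nan,
                "caspase_vehicle": vehicle_mean,
                "comboscore": np.nan,
                "is_enhancer": False,
                "flag": "ok",
            }
            missing = [
                label
                for label, key in (
                    ("compound_alone", (cid, WITHOUT_TILS)),
                    ("compound_plus_tils", (cid, WITH_TILS)),
                )
                if key not in means.index
            ]
            if missing:
                rec["flag"] = "incomplete:" + "+".join(missing)
            else:
                rec["caspase_compound"] = float(means[(cid, WITHOUT_TILS)])
                rec["caspase_combo"] = float(means[(cid, WITH_TILS)])
                til_term = til_mean - bg
                if til_term == 0:
                    rec["flag"] = "unscorable:til_zero"
                else:
                    ratio = (
                        (rec["caspase_combo"] - bg)
                        - (rec["caspase_compound"] - bg)
                    ) / til_term
                    score = ratio * ratio if squared else ratio
                    rec["comboscore"] = score
                    rec["is_enhancer"] = bool(score > enhancer_threshold)
            rows.append(rec)

    out = pd.DataFrame(rows)
    if out.empty:
        raise EmptyInputError("no non-vehicle compounds to score")

    # rank scored compounds per line, descending score, compound_id tiebreak
    out["rank"] = pd.NA
    for line_id, grp in out.groupby("tumor_line_id"):
        ok = grp[grp["flag"] == "ok"]
        order = ok.sort_values(
            ["comboscore", "compound_id"], ascending=[False, True]
        ).index
        out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    out["rank"] = out["rank"].astype("Int64")
    return out[RESULT_COLUMNS].sort_values(
        ["tumor_line_id", "rank"], na_position="last"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ComboResult:
    """One scored compound, as a typed record (mirrors a results-table row)."""

    tumor_line_id: str
    compound_id: str
    caspase_compound: float
    caspase_til: float
    caspase_combo: float
    caspase_vehicle: float
    comboscore: float
    rank: int | None
    is_enhancer: bool
    flag: str = "ok"

    @classmethod
    def from_row(cls, row: pd.Series) -> "ComboResult":
        rank = None if pd.isna(row["rank"]) else int(row["rank"])
        return cls(
            tumor_line_id=row["tumor_line_id"],
            compound_id=row["compound_id"],
            caspase_compound=float(row["caspase_compound"]),
            caspase_til=float(row["caspase_til"]),
            caspase_combo=float(row["caspase_combo"]),
            caspase_vehicle=float(row["caspase_vehicle"]),
            comboscore=float(row["comboscore"]),
            rank=rank,
            is_enhancer=bool(row["is_enhancer"]),
            flag=str(row["flag"]),
        )


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    summary_path: str | Path | None = None,
    enhancer_threshold: float = 1.0,
    squared: bool = False,
    background_subtract: bool = False,
) -> None:
    """Write the results CSV and (optionally) a JSON run summary."""
    results.to_csv(path, index=False)
    if summary_path is not None:
        summary = {
            "enhancer_threshold": enhancer_threshold,
            "squared": squared,
            "background_subtract": background_subtract,
            "n_results": int(len(results)),
            "n_scored": int((results["flag"] == "ok").sum()),
            "n_enhancers": int(results["is_enhancer"].sum()),
            "n_flagged": int((results["flag"] != "ok").sum()),
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))
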