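"""Median-effect dose-response fitting and Loewe combination-index analysis.

Single-agent curves follow the median-effect equation

    fa / (1 - fa) = (d / Dm) ** m

which is linear in log-log coordinates: log10(fa/fu) = m*log10(d) -
m*log10(Dm).  Each agent is fit by ordinary least squares on that line.
For a combination measured at fraction-affected ``fa`` the combination
index is

    CI = d1/Dx1 + d2/Dx2        (mutually exclusive, default)

with ``Dxi`` the single-agent dose producing ``fa``; the non-exclusive
form adds ``(d1*d2)/(Dx1*Dx2)``.  CI < 1 indicates synergy, = 1
additivity, > 1 antagonism.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    NonMonotoneResponseError,
    ValidationError,
)

#: pre-clamp epsilon for the optional fa clamp utility
CLAMP_EPS = 0.005

#: decades beyond the fitted dose range before an extrapolation flag is set
EXTRAPOLATION_DECADES = 2.0


@dataclass(frozen=True)
class DoseResponsePoint:
    """A single (dose, fraction affected) observation for one agent."""

    agent_id: str
    dose: float
    fa: float

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"dose must be > 0, got {self.dose}")
        if not 0.0 < self.fa < 1.0:
            raise ValidationError(
                f"fa must be in the open interval (0, 1), got {self.fa}; "
                "use clamp_fa() explicitly if boundary values must be kept"
            )


@dataclass(frozen=True)
class MedianEffectModel:
    """Fitted median-effect parameters of one agent.

    ``dm`` is the dose producing fa = 0.5, ``m`` the sigmoidicity (slope
    of the linearized plot) and ``r`` the Pearson correlation of the
    linearized fit.  ``log_dose_min``/``log_dose_max`` record the fitted
    dose range (log10) for extrapolation warnings.
    """

    agent_id: str
    dm: float
    m: float
    r: float
    n_points: int
    log_dose_min: float = float("nan")
    log_dose_max: float = float("nan")

    def __post_init__(self) -> None:
        if not self.dm > 0:
            raise ValidationError(f"Dm must be > 0, got {self.dm}")
        if not self.m > 0:
            raise ValidationError(f"m must be > 0, got {self.m}")


@dataclass(frozen=True)
class CombinationMeasurement:
    """Fraction affected observed at a (d1, d2) dose pair."""

    d1: float
    d2: float
    fa: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValidationError("doses must be >= 0")
        if self.d1 + self.d2 <= 0:
            raise ValidationError("at least one dose must be positive")
        if not 0.0 < self.fa < 1.0:
            raise ValidationError(f"fa must be in (0, 1), got {self.fa}")


@dataclass(frozen=True)
class CombinationIndexResult:
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    classification: str
    extrapolated: bool = False


def clamp_fa(fa, eps: float = CLAMP_EPS):
    """Clamp fa into [eps, 1-eps].  Off by default everywhere; callers must
    opt in — silent clamping distorts median-effect fits."""
    return np.clip(fa, eps, 1.0 - eps)


def median_effect_transform(dose, fa):
    """Map (dose, fa) to linearized coordinates (log10 d, log10(fa/fu))."""
    dose = np.asarray(dose, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if np.any(dose <= 0):
        raise ValidationError("dose must be > 0")
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValidationError("fa must be in the open interval (0, 1)")
    x = np.log10(dose)
    y = np.log10(fa / (1.0 - fa))
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


PointsLike = Union[pd.DataFrame, Iterable[DoseResponsePoint]]


def _points_frame(points: PointsLike) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
        missing = {"agent_id", "dose", "fa"} - set(df.columns)
        if missing:
            raise ValidationError(f"dose-response table missing {sorted(missing)}")
    else:
        df = pd.DataFrame([p.__dict__ for p in points])
        if df.empty:
            raise ValidationError("no dose-response points provided")
    if (df["dose"] <= 0).any():
        raise ValidationError("dose must be > 0")
    if ((df["fa"] <= 0) | (df["fa"] >= 1)).any():
        raise ValidationError("fa must be in (0, 1)")
    return df


def fit_median_effect(points: PointsLike) -> MedianEffectModel:
    """Fit (Dm, m, r) for one agent by OLS on the linearized plot."""
    df = _points_frame(points)
    agents = df["agent_id"].unique()
    if len(agents) != 1:
        raise ValidationError(
            f"fit_median_effect expects exactly one agent, got {list(agents)}"
        )
    if df["dose"].nunique() < 2:
        raise DegenerateDesignError(
            f"agent {agents[0]!r}: need >= 2 distinct doses"
        )
    x, y = median_effect_transform(df["dose"].to_numpy(), df["fa"].to_numpy())
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise NonMonotoneResponseError(
            f"agent {agents[0]!r}: non-positive slope {m:.4g} "
            f"(intercept {res.intercept:.4g}, r {res.rvalue:.4g})"
        )
    dm = 10.0 ** (-res.intercept / m)
    return MedianEffectModel(
        agent_id=str(agents[0]),
        dm=dm,
        m=m,
        r=float(res.rvalue),
        n_points=len(df),
        log_dose_min=float(np.min(x)),
        log_dose_max=float(np.max(x)),
    )


def fit_all(points: PointsLike) -> dict[str, MedianEffectModel]:
    """Fit one model per agent present in the table."""
    df = _points_frame(points)
    return {
        str(aid): fit_median_effect(sub)
        for aid, sub in df.groupby("agent_id", sort=True)
    }


def effect_at_dose(model: MedianEffectModel, dose) -> float:
    """Forward median-effect equation: fa = 1 / (1 + (Dm/d)^m)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValidationError("dose must be > 0")
    fa = 1.0 / (1.0 + (model.dm / dose) ** model.m)
    return float(fa) if fa.ndim == 0 else fa


def dose_for_effect(model: MedianEffectModel, fa) -> float:
    """Invert the median-effect equation: Dx = Dm * (fa/fu)^(1/m)."""
    fa = np.asarray(fa, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValidationError("fa must be in the open interval (0, 1)")
    dx = model.dm * (fa / (1.0 - fa)) ** (1.0 / model.m)
    return float(dx) if dx.ndim == 0 else dx


def _is_extrapolated(model: MedianEffectModel, dx: float) -> bool:
    if math.isnan(model.log_dose_min) or math.isnan(model.log_dose_max):
        return False
    lo = model.log_dose_min - EXTRAPOLATION_DECADES
    hi = model.log_dose_max + EXTRAPOLATION_DECADES
    return not (lo <= math.log10(dx) <= hi)


def classify_ci(ci: float, tol: float = 0.05) -> str:
    if ci < 1.0 - tol:
        return "synergy"
    if ci > 1.0 + tol:
        return "antagonism"
    return "additivity"


def combination_index(
    model1: MedianEffectModel,
    model2: MedianEffectModel,
    meas: CombinationMeasurement,
    form: str = "exclusive",
    tol: float = 0.05,
) -> CombinationIndexResult:
    """Combination index of one measurement against two fitted agents.

    ``form`` selects the mutually exclusive (two-term) or non-exclusive
    (three-term) equation.  ``extrapolated`` is set when either required
    single-agent dose lies more than two decades outside that agent's
    fitted dose range.
    """
    if form not in ("exclusive", "nonexclusive"):
        raise ValidationError(f"unknown CI form {form!r}")
    dx1 = dose_for_effect(model1, meas.fa)
    dx2 = dose_for_effect(model2, meas.fa)
    ci = meas.d1 / dx1 + meas.d2 / dx2
    if form == "nonexclusive":
        ci += (meas.d1 * meas.d2) / (dx1 * dx2)
    flagged = _is_extrapolated(model1, dx1) or _is_extrapolated(model2, dx2)
    return CombinationIndexResult(
        fa=meas.fa,
        d1=meas.d1,
        d2=meas.d2,
        dx1=dx1,
        dx2=dx2,
        ci=float(ci),
        classification=classify_ci(float(ci), tol),
        extrapolated=flagged,
    )


CombosLike = Union[pd.DataFrame, Iterable[CombinationMeasurement]]


def _combos(combos: CombosLike) -> list[CombinationMeasurement]:
    if isinstance(combos, pd.DataFrame):
        missing = {"d1", "d2", "fa"} - set(combos.columns)
        if missing:
            raise ValidationError(f"combination table missing {sorted(missing)}")
        return [
            CombinationMeasurement(float(r.d1), float(r.d2), float(r.fa))
            for r in combos.itertuples()
        ]
    return list(combos)


def combination_index_table(
    model1: MedianEffectModel,
    model2: MedianEffectModel,
    combos: CombosLike,
    form: str = "exclusive",
    tol: float = 0.05,
) -> pd.DataFrame:
    rows = [
        asdict(combination_index(model1, model2, m, form=form, tol=tol))
        for m in _combos(combos)
    ]
    return pd.DataFrame(rows)


def isobologram(
    model1: MedianEffectModel,
    model2: MedianEffectModel,
    combos: CombosLike,
) -> pd.DataFrame:
    """Plot-ready normalized dose pairs, one row per measurement.

    Columns ``x = d1/Dx1`` and ``y = d2/Dx2`` satisfy ``x + y = ci``
    (exclusive form); points below the unit diagonal indicate synergy.
    """
    rows = []
    for m in _combos(combos):
        res = combination_index(model1, model2, m, form="exclusive")
        rows.append(
            {
                "fa": m.fa,
                "d1": m.d1,
                "d2": m.d2,
                "x": m.d1 / res.dx1,
                "y": m.d2 / res.dx2,
                "ci": res.ci,
            }
        )
    return pd.DataFrame(rows).sort_values(["fa", "x"]).reset_index(drop=True)


# --- serialization -------------------------------------------------------

def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"agent_id": str})
    return _points_frame(df)


def read_combos_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"d1", "d2", "fa"} - set(df.columns)
    if missing:
        raise ValidationError(f"combination CSV missing {sorted(missing)}")
    return df


def models_to_json(models: dict[str, MedianEffectModel], path: str | Path) -> None:
    payload = {aid: asdict(m) for aid, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def models_from_json(path: str | Path) -> dict[str, MedianEffectModel]:
    payload = json.loads(Path(path).read_text())
    return {aid: MedianEffectModel(**rec) for aid, rec in payload.items()}
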