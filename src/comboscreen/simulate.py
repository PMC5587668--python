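"""Seeded simulators with known ground truth for every pipeline stage.

Each simulator is a deterministic function of (config, seed) and emits a
:class:`SimulationTruth` holding exactly the parameters downstream
analyses are expected to recover:

* screen — compound-alone apoptosis ``b + c_i``, effector-alone ``b + t``,
  combination ``b + c_i + gamma_i * t``; the interaction ``gamma_i``
  multiplies the effector increment, so the screen score identifies it
  exactly when the baseline ``b`` is zero (or background subtraction is on).
* dose-response — forward median-effect curve, noise on the linearized
  scale so the fitting model is correctly specified (an ``fa``-scale
  noise option exists for robustness checks).
* combination — Loewe construction ``d1 = lam*Dx1(fa)/alpha``,
  ``d2 = (1-lam)*Dx2(fa)/alpha`` whose true combination index is
  ``1/alpha`` at every (fa, lam).
* expression — probe baseline + ``delta`` added to planted probes in
  treated samples; the expected rank score of planted probes is ``delta``.
* qPCR — CT = base - log2(expression), so noise-free ddCT analysis
  recovers the configured fold changes exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synergy
from .enrichment import CONTROL, TREATED, ExpressionMatrix, GeneSet
from .errors import ValidationError
from .screen import VEHICLE_ID, WELL_COLUMNS, WITH_TILS, WITHOUT_TILS
from .synergy import MedianEffectModel


@dataclass
class SimulationTruth:
    """Ground-truth parameters emitted alongside a synthetic dataset.

    Only the sections relevant to the generating simulator are populated.
    """

    compounds: dict | None = None          # compound_id -> {c, gamma, true_comboscore}
    n_clamped: int | None = None
    agents: dict | None = None             # agent_id -> {dm, m}
    alpha: float | None = None
    true_ci: float | None = None
    planted_set: tuple[str, ...] | None = None
    delta: float | None = None
    true_folds: dict | None = None         # gene -> fold
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items() if v is not None}
        if "planted_set" in payload:
            payload["planted_set"] = list(payload["planted_set"])
        Path(path).write_text(json.dumps(payload, indent=2))


# --- screen --------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Generative parameters for a synthetic single-dose screen."""

    n_compounds: int
    n_replicates: int = 3
    baseline_pct: float = 0.0
    til_pct: float = 30.0
    compound_effect_range: tuple[float, float] = (5.0, 20.0)
    gamma_null: float = 1.0
    gamma_enhancers: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    dose_nm: float = 1000.0
    tumor_line_id: str = "L1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if self.til_pct <= 0:
            raise ValidationError("til_pct must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.compound_effect_range
        if lo > hi or lo < 0:
            raise ValidationError("bad compound_effect_range")


def compound_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"C{i:0{width}d}" for i in range(1, n + 1)]


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate well-level readouts for a full screen plus ground truth.

    Percentages are clamped to [0, 100] after noise; the number of
    clamping events is reported in the truth so acceptance runs can
    require configs with zero clamping.
    """
    rng = np.random.default_rng(config.seed)
    cids = compound_ids(config.n_compounds)
    lo, hi = config.compound_effect_range
    c = rng.uniform(lo, hi, size=config.n_compounds)
    gamma = np.full(config.n_compounds, config.gamma_null, dtype=float)
    unknown = set(config.gamma_enhancers) - set(cids)
    if unknown:
        raise ValidationError(f"gamma_enhancers reference unknown compounds: {sorted(unknown)}")
    for i, cid in enumerate(cids):
        if cid in config.gamma_enhancers:
            gamma[i] = float(config.gamma_enhancers[cid])

    b, t = config.baseline_pct, config.til_pct
    conditions: list[tuple[str, float, str, float]] = [
        (VEHICLE_ID, 0.0, WITHOUT_TILS, b),
        (VEHICLE_ID, 0.0, WITH_TILS, b + t),
    ]
    for i, cid in enumerate(cids):
        conditions.append((cid, config.dose_nm, WITHOUT_TILS, b + c[i]))
        conditions.append((cid, config.dose_nm, WITH_TILS, b + c[i] + gamma[i] * t))

    reps = np.arange(1, config.n_replicates + 1)
    n_rows = len(conditions) * config.n_replicates
    noise = (
        rng.normal(0.0, config.noise_sd, size=n_rows)
        if config.noise_sd > 0
        else np.zeros(n_rows)
    )

    records = []
    idx = 0
    for cid, dose, til, true_pct in conditions:
        for rep in reps:
            records.append(
                (
                    "plate1",
                    f"{cid}_{'T' if til == WITH_TILS else 'N'}_{rep}",
                    config.tumor_line_id,
                    cid,
                    dose,
                    til,
                    int(rep),
                    true_pct + noise[idx],
                )
            )
            idx += 1
    wells = pd.DataFrame(records, columns=WELL_COLUMNS)
    clipped = wells["pct_caspase3"].clip(0.0, 100.0)
    n_clamped = int((clipped != wells["pct_caspase3"]).sum())
    wells["pct_caspase3"] = clipped

    truth = SimulationTruth(
        compounds={
            cid: {"c": float(c[i]), "gamma": float(gamma[i]),
                  "true_comboscore": float(gamma[i])}
            for i, cid in enumerate(cids)
        },
        n_clamped=n_clamped,
        seed=config.seed,
    )
    return wells, truth


def enhancer_gamma_map(
    n_compounds: int,
    n_enhancers: int,
    gamma_range: tuple[float, float],
    seed: int = 0,
) -> dict[str, float]:
    """Pick a seeded random subset of compounds as enhancers with gamma
    drawn uniformly from ``gamma_range``."""
    if n_enhancers > n_compounds:
        raise ValidationError("n_enhancers exceeds n_compounds")
    rng = np.random.default_rng(seed)
    cids = compound_ids(n_compounds)
    chosen = rng.choice(n_compounds, size=n_enhancers, replace=False)
    gammas = rng.uniform(*gamma_range, size=n_enhancers)
    return {cids[i]: float(g) for i, g in zip(sorted(chosen), gammas)}


# --- dose-response -------------------------------------------------------

def simulate_dose_response(
    dm: float,
    m: float,
    doses: Sequence[float],
    y_noise_sd: float = 0.0,
    seed: int = 0,
    agent_id: str = "agent",
    noise_scale: str = "linearized",
) -> pd.DataFrame:
    """Points on a median-effect curve with optional noise.

    ``noise_scale='linearized'`` perturbs log10(fa/fu) (the correctly
    specified model for the OLS fit); ``'fa'`` perturbs fa directly and
    clips into (0, 1), deliberately misspecified for robustness tests.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValidationError("doses must be > 0")
    if dm <= 0 or m <= 0:
        raise ValidationError("Dm and m must be > 0")
    if noise_scale not in ("linearized", "fa"):
        raise ValidationError(f"unknown noise_scale {noise_scale!r}")
    rng = np.random.default_rng(seed)
    y = m * (np.log10(doses) - math.log10(dm))
    if noise_scale == "linearized":
        if y_noise_sd > 0:
            y = y + rng.normal(0.0, y_noise_sd, size=doses.size)
        fa = 10.0 ** y / (1.0 + 10.0 ** y)
    else:
        fa = 10.0 ** y / (1.0 + 10.0 ** y)
        if y_noise_sd > 0:
            fa = fa + rng.normal(0.0, y_noise_sd, size=doses.size)
        fa = np.clip(fa, 1e-6, 1.0 - 1e-6)
    return pd.DataFrame({"agent_id": agent_id, "dose": doses, "fa": fa})


# --- combination ---------------------------------------------------------

def simulate_combination(
    model1: MedianEffectModel,
    model2: MedianEffectModel,
    alpha: float,
    fa_levels: Sequence[float],
    lambdas: Sequence[float],
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Loewe-constructed combination measurements with true CI = 1/alpha.

    Doses sit on the additivity line for each effect level, scaled by
    1/alpha; alpha > 1 produces synergy, alpha < 1 antagonism.  The
    construction is noise-free (seed recorded for provenance only).
    """
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")
    rows = []
    for fa in fa_levels:
        dx1 = synergy.dose_for_effect(model1, fa)
        dx2 = synergy.dose_for_effect(model2, fa)
        for lam in lambdas:
            if not 0.0 < lam < 1.0:
                raise ValidationError("lambdas must be in (0, 1)")
            rows.append(
                {"d1": lam * dx1 / alpha, "d2": (1.0 - lam) * dx2 / alpha,
                 "fa": fa}
            )
    truth = SimulationTruth(
        agents={
            model1.agent_id: {"dm": model1.dm, "m": model1.m},
            model2.agent_id: {"dm": model2.dm, "m": model2.m},
        },
        alpha=float(alpha),
        true_ci=1.0 / float(alpha),
        seed=seed,
    )
    return pd.DataFrame(rows), truth


# --- expression ----------------------------------------------------------

def probe_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    n_probes: int,
    planted_set_size: int,
    delta: float,
    noise_sd: float,
    seed: int = 0,
    n_lines: int = 4,
    duplicates: int = 2,
    baseline_range: tuple[float, float] = (6.0, 10.0),
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Log2 expression matrix with a planted treated-up-regulated set.

    Each value is probe baseline + ``delta`` (planted probes, treated
    samples only) + Gaussian noise.  The planted probes are a seeded
    random subset, reported in the truth.
    """
    if planted_set_size >= n_probes:
        raise ValidationError("planted_set_size must be < n_probes")
    rng = np.random.default_rng(seed)
    probes = probe_ids(n_probes)
    planted_idx = rng.choice(n_probes, size=planted_set_size, replace=False)
    planted = sorted(probes[i] for i in planted_idx)
    baseline = rng.uniform(*baseline_range, size=n_probes)

    columns, ann_rows = [], []
    values = {}
    for li in range(1, n_lines + 1):
        line = f"line{li}"
        for treatment in (CONTROL, TREATED):
            for rep in range(1, duplicates + 1):
                sid = f"{line}_{treatment}_{rep}"
                col = baseline + rng.normal(0.0, noise_sd, size=n_probes)
                if treatment == TREATED:
                    col = col.copy()
                    col[planted_idx] += delta
                values[sid] = col
                ann_rows.append(
                    {"sample_id": sid, "cell_line_id": line,
                     "treatment": treatment, "replicate_index": rep}
                )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probes, name="probe_id")),
        annotations=pd.DataFrame(ann_rows).set_index("sample_id"),
    )
    truth = SimulationTruth(
        planted_set=tuple(planted), delta=float(delta), seed=seed
    )
    return matrix, truth


def planted_gene_set(truth: SimulationTruth, name: str = "planted") -> GeneSet:
    if truth.planted_set is None:
        raise ValidationError("truth carries no planted set")
    return GeneSet(name=name, members=frozenset(truth.planted_set))


# --- qPCR ----------------------------------------------------------------

def simulate_ct(
    true_folds: Mapping[str, float],
    ref_gene: str = "GAPDH",
    calibrator: str = "DMSO",
    sample_id: str = "treated",
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    base_ct_range: tuple[float, float] = (20.0, 28.0),
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Long CT table (sample_id, gene, replicate, ct) with known folds.

    Relative expression is ``fold`` for target genes in the test sample
    and 1 everywhere else (reference gene, calibrator sample), so
    CT = base - log2(expression) makes the ddCT round trip exact at zero
    noise.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValidationError("fold changes must be > 0")
    if ref_gene in true_folds:
        raise ValidationError("reference gene cannot carry a fold change")
    rng = np.random.default_rng(seed)
    genes = [ref_gene] + sorted(true_folds)
    base = dict(zip(genes, rng.uniform(*base_ct_range, size=len(genes))))
    rows = []
    for sample in (calibrator, sample_id):
        for gene in genes:
            expr = (
                true_folds[gene]
                if (sample == sample_id and gene != ref_gene)
                else 1.0
            )
            ct0 = base[gene] - math.log2(expr)
            noise = (
                rng.normal(0.0, ct_noise_sd, size=n_replicates)
                if ct_noise_sd > 0
                else np.zeros(n_replicates)
            )
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {"sample_id": sample, "gene": gene, "replicate": rep,
                     "ct": ct0 + noise[rep - 1]}
                )
    truth = SimulationTruth(true_folds=dict(true_folds), seed=seed)
    return pd.DataFrame(rows), truth
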