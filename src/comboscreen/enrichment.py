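"""Cross-cell-line expression ranking, KS-type gene-set enrichment, and
2^-ddCT qPCR quantification.

The rank is built exactly as the screening follow-up prescribes: per cell
line, average the treated replicates' log2 values and subtract the
averaged control log2 values; the per-probe mean of those differences
across lines orders the list (descending, probe id as tiebreak).

Enrichment uses the classic unweighted Kolmogorov-Smirnov running sum:
walking the rank from top to bottom, add 1/k at each of the k in-set
probes and subtract 1/(N-k) at each out-of-set probe; the enrichment
score is the signed running-sum value of maximal absolute magnitude.
Significance comes from a gene-label permutation null (random same-size
sets), two-sided on |ES| with the add-one correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    MissingConditionError,
    NoOverlapError,
    ValidationError,
)

TREATED = "treated"
CONTROL = "control"


# --- expression matrix ---------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities (probes x samples) with annotations.

    ``values`` is indexed by probe_id with one column per sample;
    ``annotations`` is indexed by sample_id with columns ``cell_line_id``,
    ``treatment`` (``control``/``treated``) and ``replicate_index``.
    Probes containing any missing value are dropped at construction and
    counted in ``n_probes_dropped``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    n_probes_dropped: int = 0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        extra = set(self.values.columns) - set(self.annotations.index)
        if extra:
            raise ValidationError(f"samples without annotation: {sorted(extra)}")
        bad = set(self.annotations["treatment"]) - {TREATED, CONTROL}
        if bad:
            raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
        n_before = len(self.values)
        self.values = self.values.dropna(axis=0)
        self.n_probes_dropped += n_before - len(self.values)
        self.annotations = self.annotations.loc[list(self.values.columns)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.annotations["cell_line_id"].unique())

    def samples_for(self, cell_line: str, treatment: str) -> list[str]:
        ann = self.annotations
        mask = (ann["cell_line_id"] == cell_line) & (ann["treatment"] == treatment)
        return list(ann.index[mask])

    @classmethod
    def from_files(
        cls,
        expr_tsv: str | Path,
        annot_csv: str | Path,
        treated_label: str = TREATED,
        control_label: str = CONTROL,
    ) -> "ExpressionMatrix":
        """Load an expression TSV (first column = probe_id) and an
        annotation CSV ``sample_id,cell_line_id,treatment,replicate``.

        ``treated_label``/``control_label`` map the annotation file's
        treatment literals (e.g. drug name / ``DMSO``) onto the canonical
        ``treated``/``control`` labels.
        """
        values = pd.read_csv(expr_tsv, sep="\t", index_col=0)
        ann = pd.read_csv(annot_csv, dtype=str).set_index("sample_id")
        ann = ann.rename(columns={"replicate": "replicate_index"})
        mapping = {treated_label: TREATED, control_label: CONTROL,
                   TREATED: TREATED, CONTROL: CONTROL}
        unknown = set(ann["treatment"]) - set(mapping)
        if unknown:
            raise ValidationError(
                f"treatment labels {sorted(unknown)} match neither "
                f"{treated_label!r} nor {control_label!r}"
            )
        ann["treatment"] = ann["treatment"].map(mapping)
        return cls(values=values, annotations=ann)

    def to_files(self, expr_tsv: str | Path, annot_csv: str | Path) -> None:
        self.values.to_csv(expr_tsv, sep="\t", index_label="probe_id")
        out = self.annotations.rename(columns={"replicate_index": "replicate"})
        out.to_csv(annot_csv, index_label="sample_id")


def delta_log2(matrix: ExpressionMatrix, cell_line: str) -> pd.Series:
    """Per-probe mean(treated) - mean(control) log2 difference for one line."""
    treated = matrix.samples_for(cell_line, TREATED)
    control = matrix.samples_for(cell_line, CONTROL)
    for label, cols in ((TREATED, treated), (CONTROL, control)):
        if not cols:
            raise MissingConditionError(
                f"cell line {cell_line!r}: no {label} samples"
            )
    return matrix.values[treated].mean(axis=1) - matrix.values[control].mean(axis=1)


# --- gene rank -----------------------------------------------------------

@dataclass(frozen=True)
class GeneRank:
    """Probes ordered by descending score (ties broken by probe id)."""

    probe_ids: tuple[str, ...]
    scores: tuple[float, ...]
    n_lines_used: int = 1

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.scores):
            raise ValidationError("probe_ids and scores length mismatch")
        if len(self.probe_ids) == 0:
            raise EmptyInputError("empty rank")
        if any(a > b for a, b in zip(self.scores[1:], self.scores[:-1])):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "score": self.scores,
                "rank": np.arange(1, len(self) + 1),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_scores(cls, scores: pd.Series, n_lines_used: int = 1) -> "GeneRank":
        df = scores.rename("score").rename_axis("probe_id").reset_index()
        df = df.sort_values(["score", "probe_id"], ascending=[False, True])
        return cls(
            probe_ids=tuple(df["probe_id"].astype(str)),
            scores=tuple(float(s) for s in df["score"]),
            n_lines_used=n_lines_used,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneRank":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
        df = df.sort_values("rank") if "rank" in df.columns else df
        return cls(
            probe_ids=tuple(df["probe_id"]),
            scores=tuple(df["score"].astype(float)),
        )


def cross_line_rank(matrix: ExpressionMatrix) -> GeneRank:
    """Average the per-line treated-minus-control differences across all
    cell lines and sort descending into a gene rank."""
    lines = matrix.cell_lines
    if not lines:
        raise EmptyInputError("matrix has no cell lines")
    deltas = pd.concat(
        {line: delta_log2(matrix, line) for line in lines}, axis=1
    )
    if deltas.isna().any().any():
        raise ValidationError("probe universes differ across cell lines")
    return GeneRank.from_scores(deltas.mean(axis=1), n_lines_used=len(lines))


# --- gene sets -----------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} empty")
        sets.append(GeneSet(name=name, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- enrichment ----------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    n_permutations: int
    seed: int
    leading_edge: tuple[str, ...]
    n_members_in_rank: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["leading_edge"] = list(self.leading_edge)
        return d


def _hit_mask(rank: GeneRank, gene_set: GeneSet) -> np.ndarray:
    probe_arr = np.asarray(rank.probe_ids)
    mask = np.isin(probe_arr, list(gene_set.members))
    if not mask.any():
        raise NoOverlapError(
            f"gene set {gene_set.name!r} has no members in the rank"
        )
    if mask.all():
        raise ValidationError(
            f"gene set {gene_set.name!r} covers the entire rank"
        )
    return mask


def _running_sum(mask: np.ndarray) -> np.ndarray:
    n = mask.size
    k = int(mask.sum())
    steps = np.where(mask, 1.0 / k, -1.0 / (n - k))
    return np.cumsum(steps)


def enrichment_score(rank: GeneRank, gene_set: GeneSet) -> float:
    """Signed KS enrichment score: running-sum value of maximal |.|."""
    rs = _running_sum(_hit_mask(rank, gene_set))
    # clip guards |ES| <= 1 against cumsum rounding drift
    return float(np.clip(rs[np.argmax(np.abs(rs))], -1.0, 1.0))


def _abs_es_from_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """|ES| for many null sets at once, from sorted 0-based hit positions.

    ``pos`` has shape (n_sets, k).  The running sum only attains its
    extrema immediately after a hit (maxima) or immediately before one
    (minima), so |ES| is computable in O(k) per set without materializing
    the length-n walk.
    """
    n_sets, k = pos.shape
    i = np.arange(1, k + 1, dtype=float)
    miss_step = 1.0 / (n - k)
    after = i / k - (pos + 1 - i) * miss_step
    before = (i - 1) / k - (pos - (i - 1)) * miss_step
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.maximum(hi, -lo)


def permutation_pvalue(
    rank: GeneRank,
    gene_set: GeneSet,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Two-sided permutation p-value for the enrichment score.

    The null is gene-label permutation: ``n_permutations`` random sets of
    the same size drawn uniformly without replacement from the rank.
    p = (1 + #{|ES_null| >= |ES_obs|}) / (n_permutations + 1).  The
    leading edge collects in-set members at or before the peak of the
    running sum (at or after it, for negative ES).
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    mask = _hit_mask(rank, gene_set)
    rs = _running_sum(mask)
    peak = int(np.argmax(np.abs(rs)))
    es = float(np.clip(rs[peak], -1.0, 1.0))

    probe_arr = np.asarray(rank.probe_ids)
    if es >= 0:
        lead = probe_arr[: peak + 1][mask[: peak + 1]]
    else:
        lead = probe_arr[peak:][mask[peak:]]

    n = mask.size
    k = int(mask.sum())
    rng = np.random.default_rng(seed)
    # sample n_permutations sets of size k without replacement
    null_pos = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :k]
    null_pos.sort(axis=1)
    null_abs = _abs_es_from_positions(null_pos.astype(float), n)
    p = (1.0 + np.count_nonzero(null_abs >= abs(es) - 1e-12)) / (
        n_permutations + 1.0
    )
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        leading_edge=tuple(lead),
        n_members_in_rank=k,
    )


def enrich_all(
    rank: GeneRank,
    gene_sets: Sequence[GeneSet],
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every set against the rank; each set gets a derived substream
    seed so results are independent of set order."""
    seeds = np.random.SeedSequence(seed).generate_state(len(gene_sets))
    return [
        permutation_pvalue(rank, gs, n_permutations, seed=int(s))
        for gs, s in zip(gene_sets, seeds)
    ]


def write_enrichment_json(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in results], indent=2)
    )


# --- qPCR 2^-ddCT --------------------------------------------------------

def ddct_fold_change(
    ct_target_sample: Sequence[float],
    ct_ref_sample: Sequence[float],
    ct_target_calibrator: Sequence[float],
    ct_ref_calibrator: Sequence[float],
) -> float:
    """Relative quantification by the 2^-ddCT method.

    Replicate CTs are averaged first; dCT = mean(target) - mean(reference)
    per condition; ddCT = dCT_sample - dCT_calibrator; fold = 2^-ddCT.
    """
    means = []
    for name, cts in (
        ("ct_target_sample", ct_target_sample),
        ("ct_ref_sample", ct_ref_sample),
        ("ct_target_calibrator", ct_target_calibrator),
        ("ct_ref_calibrator", ct_ref_calibrator),
    ):
        arr = np.asarray(cts, dtype=float)
        if arr.size == 0 or not np.all(np.isfinite(arr)):
            raise ValidationError(f"{name}: CT values must be finite and non-empty")
        means.append(arr.mean())
    dct_sample = means[0] - means[1]
    dct_cal = means[2] - means[3]
    return float(2.0 ** (-(dct_sample - dct_cal)))


def ddct_table(
    ct: pd.DataFrame, ref_gene: str, calibrator: str
) -> pd.DataFrame:
    """Fold changes for every (sample, gene) in a long CT table.

    ``ct`` has columns ``sample_id, gene, replicate, ct``; the reference
    gene normalizes within each sample and the calibrator sample anchors
    fold = 1.
    """
    required = {"sample_id", "gene", "replicate", "ct"}
    if not required <= set(ct.columns):
        raise ValidationError(f"CT table missing {sorted(required - set(ct.columns))}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValidationError("CT table contains non-finite values")
    means = ct.groupby(["sample_id", "gene"])["ct"].mean()
    samples = sorted(ct["sample_id"].unique())
    genes = sorted(g for g in ct["gene"].unique() if g != ref_gene)
    if calibrator not in samples:
        raise ValidationError(f"calibrator sample {calibrator!r} not in table")
    if ref_gene not in set(ct["gene"]):
        raise ValidationError(f"reference gene {ref_gene!r} not in table")
    rows = []
    for sample in samples:
        for gene in genes:
            fold = ddct_fold_change(
                [means[(sample, gene)]],
                [means[(sample, ref_gene)]],
                [means[(calibrator, gene)]],
                [means[(calibrator, ref_gene)]],
            )
            rows.append({"sample_id": sample, "gene": gene, "fold_change": fold})
    return pd.DataFrame(rows)
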