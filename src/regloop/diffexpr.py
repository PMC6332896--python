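"""Two-group differential expression with fold-change / p-value thresholding.

The study design this supports compares a disease cohort against normal
controls twice per modality (two independent case cohorts against the same
kind of control), then keeps the features that pass cutoffs in *both*
comparisons with the same direction of change.  Intensity-type data
(microarray, already on a log2 scale) are tested as-is; count-type data
(small-RNA sequencing) are normalised to counts per million and tested on
log2(CPM + 0.5).

The test statistic is a Welch two-sample t per feature.  This is a
deliberate, documented simplification of moderated linear models /
negative-binomial GLMs: it keeps the module self-contained while preserving
the two-group location-test semantics the downstream thresholding assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ThresholdPolicy",
    "GENE_POLICY",
    "MIRNA_POLICY",
    "bh_adjust",
    "de_two_group",
    "count_filter",
    "apply_thresholds",
    "intersect_consistent",
    "consistency_filter",
]

#: variance floor used when group means differ but sample variances are zero
_VAR_FLOOR = 1e-12
#: pseudo-count added to CPM before taking log2
CPM_PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """A features x samples expression grid with two-group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        Log2 intensities for ``modality="intensity"``; raw non-negative
        integer counts for ``modality="count"``.
    groups
        Mapping ``sample_id -> "case" | "control"``.
    modality
        ``"intensity"`` or ``"count"``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    modality: str = "intensity"

    def __post_init__(self) -> None:
        if self.modality not in ("intensity", "count"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        unknown = set(self.groups.values()) - {"case", "control"}
        if unknown:
            raise ValueError(f"group labels must be case/control, got {sorted(unknown)}")
        if self.modality == "count":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("count matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    def log2_values(self) -> pd.DataFrame:
        """Values on the log2 scale used for testing.

        Intensity data are assumed log2 already; counts are library-size
        normalised to CPM and transformed with log2(CPM + 0.5).
        """
        if self.modality == "intensity":
            return self.values
        libsize = self.values.sum(axis=0)
        libsize = libsize.replace(0, 1.0)  # empty library -> all-zero CPM column
        cpm = self.values / libsize * 1e6
        return np.log2(cpm + CPM_PSEUDOCOUNT)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Significance cutoffs for one modality.

    ``fc_min`` is a linear fold change; a feature passes when
    ``|log2fc| > log2(fc_min)`` and the chosen p-value is ``< p_max``
    (both strict).  ``min_count``/``min_samples`` apply only to count
    data, keeping features whose raw count exceeds ``min_count`` in at
    least ``min_samples`` samples.
    """

    fc_min: float = 4.0
    p_max: float = 1e-5
    use_adjusted: bool = True
    min_count: int = 0
    min_samples: int = 1

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")


#: gene-level cutoffs: fold change > 4 and BH-adjusted p < 1e-5
GENE_POLICY = ThresholdPolicy(fc_min=4.0, p_max=1e-5, use_adjusted=True)
#: miRNA-level cutoffs: fold change > 2, raw p < 0.05, count > 100 in >= 1 sample
MIRNA_POLICY = ThresholdPolicy(fc_min=2.0, p_max=0.05, use_adjusted=False,
                               min_count=100, min_samples=1)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min over ranks j >= rank(i) of p_(j) * n / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def de_two_group(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature Welch t-test of case vs control.

    Returns a DataFrame with columns ``feature_id, log2fc, p_raw, p_adj,
    direction, passed``; ``direction`` is ``"none"`` and ``passed`` False
    until :func:`apply_thresholds` is applied.  ``log2fc`` is
    mean(case) - mean(control) on the log2 scale.  Features with zero
    variance in both groups and equal means get p = 1 by convention; a
    variance floor prevents division by zero when means differ.
    """
    case = matrix.samples_in_group("case")
    ctrl = matrix.samples_in_group("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(case)} case / {len(ctrl)} control"
        )
    log2 = matrix.log2_values()
    x = log2[case].to_numpy(dtype=float)
    y = log2[ctrl].to_numpy(dtype=float)
    log2fc = x.mean(axis=1) - y.mean(axis=1)

    vx = np.maximum(x.var(axis=1, ddof=1), _VAR_FLOOR)
    vy = np.maximum(y.var(axis=1, ddof=1), _VAR_FLOOR)
    nx, ny = x.shape[1], y.shape[1]
    se2 = vx / nx + vy / ny
    t = log2fc / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    p_raw = np.where(log2fc == 0.0, 1.0, p_raw)
    p_raw = np.clip(p_raw, 0.0, 1.0)

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": "none",
            "passed": False,
        }
    )


def count_filter(matrix: ExpressionMatrix, policy: ThresholdPolicy) -> ExpressionMatrix:
    """Drop low-abundance count features before testing.

    Keeps features with raw count strictly greater than ``policy.min_count``
    in at least ``policy.min_samples`` samples; feature order is preserved.
    """
    if matrix.modality != "count":
        raise ValueError("count_filter requires a count-modality matrix")
    hits = (matrix.values > policy.min_count).sum(axis=1)
    keep = hits >= policy.min_samples
    return ExpressionMatrix(matrix.values.loc[keep], dict(matrix.groups), "count")


def apply_thresholds(results: pd.DataFrame, policy: ThresholdPolicy) -> pd.DataFrame:
    """Set ``passed`` and ``direction`` from the policy's strict cutoffs.

    Idempotent: flags are recomputed from log2fc and p, never accumulated.
    """
    out = results.copy()
    p = out["p_adj"] if policy.use_adjusted else out["p_raw"]
    lfc_min = np.log2(policy.fc_min)
    passed = (out["log2fc"].abs() > lfc_min) & (p < policy.p_max)
    out["passed"] = passed.to_numpy()
    direction = np.where(~passed, "none", np.where(out["log2fc"] > 0, "up", "down"))
    out["direction"] = direction
    return out


def intersect_consistent(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Features passing in both comparisons with the same direction.

    Returns ``(concordant, discordant)`` where concordant is a DataFrame
    with columns ``feature_id, direction`` (sorted by feature id) and
    discordant lists features passing both comparisons with opposite
    directions.
    """
    da = dict(zip(a.loc[a["passed"], "feature_id"], a.loc[a["passed"], "direction"]))
    db = dict(zip(b.loc[b["passed"], "feature_id"], b.loc[b["passed"], "direction"]))
    shared = sorted(set(da) & set(db))
    concordant = [(f, da[f]) for f in shared if da[f] == db[f]]
    discordant = [f for f in shared if da[f] != db[f]]
    return (
        pd.DataFrame(concordant, columns=["feature_id", "direction"]),
        discordant,
    )


def consistency_filter(
    matrix: ExpressionMatrix,
    candidates: pd.DataFrame,
    min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Expression-consistency robustness filter for unbalanced designs.

    A candidate feature (with a claimed direction) is retained iff at least
    ``min_fraction`` of the case samples lie on the claimed side of the
    feature's pooled across-group median (log2 scale).  This guards against
    calls driven by a handful of extreme case samples when the group sizes
    are very unequal.
    """
    case = matrix.samples_in_group("case")
    if not case:
        raise ValueError("empty case group")
    missing = set(candidates["feature_id"]) - set(matrix.feature_ids)
    if missing:
        raise ValueError(f"candidates absent from matrix: {sorted(missing)}")
    log2 = matrix.log2_values()
    keep = []
    for fid, direction in zip(candidates["feature_id"], candidates["direction"]):
        row = log2.loc[fid]
        med = row.median()
        vals = row[case]
        frac = float((vals > med).mean() if direction == "up" else (vals < med).mean())
        if frac >= min_fraction:
            keep.append((fid, direction))
    return pd.DataFrame(keep, columns=["feature_id", "direction"])
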