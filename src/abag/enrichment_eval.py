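"""Benchmark analytics for docking rescoring: AUC, success rates, separations.

Positives are models of at least Acceptable CAPRI quality versus the crystal
structure; negatives are Incorrect models.  Because the confidence-based
rescoring structurally rebuilds each pose, every model carries two quality
labels — one for the docking-generated coordinates and one for the rebuilt
coordinates — and evaluation uses the rebuilt-model label under the composite
scheme and the docking-model label under the docking scheme.

Provided analytics: per-system ROC AUC (rank-based, ties half-credit), top-N
success curves (a system succeeds at N when any of its N best-ranked models is
a positive), positive/negative median separation in pooled-SD units,
smoothed-density precision curves as a function of a score cutoff, and
decoy-set composition summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .capri_eval import QualityClass
from .rescoring import rank_models

logger = logging.getLogger("abag")

Scheme = Literal["docking", "af2_composite"]

#: which score / quality-label columns each ranking scheme uses
SCHEME_COLUMNS: dict[str, tuple[str, str]] = {
    "docking": ("docking_score", "class_docking"),
    "af2_composite": ("composite", "class_af2"),
}


# ---------------------------------------------------------------------------
# domain types

@dataclass
class LabeledDecoySet:
    """All decoys of one system with scores and both quality labels.

    ``models`` columns: ``model_id``, ``method``, ``docking_score`` (oriented,
    higher = better), ``composite``, ``class_docking`` and ``class_af2``
    (:class:`QualityClass` values).
    """

    system_id: str
    models: pd.DataFrame

    REQUIRED = ("model_id", "method", "docking_score", "composite",
                "class_docking", "class_af2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.models.columns]
        if missing:
            raise ValueError(f"decoy set {self.system_id}: missing columns {missing}")

    def positives_mask(self, scheme: Scheme,
                       floor: QualityClass = QualityClass.ACCEPTABLE) -> np.ndarray:
        _, label_col = SCHEME_COLUMNS[scheme]
        return np.array([int(c) >= int(floor) for c in self.models[label_col]])

    def ranked(self, scheme: Scheme) -> pd.DataFrame:
        score_col, _ = SCHEME_COLUMNS[scheme]
        return rank_models(self.models, scheme, score_col=score_col)


@dataclass
class SuccessCurve:
    """Fraction of systems with ≥1 positive among the top N, for N = 1..max."""

    n_values: np.ndarray
    success: np.ndarray

    def at(self, n: int) -> float:
        n_eff = min(n, int(self.n_values[-1]))
        return float(self.success[n_eff - 1])


@dataclass
class PrecisionCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    stderr: np.ndarray
    n_effective: np.ndarray

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.clip(self.precision - self.stderr, 0.0, 1.0)
        hi = np.clip(self.precision + self.stderr, 0.0, 1.0)
        return lo, hi


# ---------------------------------------------------------------------------
# ROC AUC

def roc_auc(positive_scores, negative_scores) -> float:
    """Rank-based (Mann-Whitney) AUC of positives over negatives, ties half-credit.

    Returns NaN when either class is empty — the "system excluded" signal used
    by per-system sweeps — rather than raising.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        return math.nan
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def per_system_auc(
    sets: Iterable[LabeledDecoySet],
    scheme: Scheme,
    floor: QualityClass = QualityClass.ACCEPTABLE,
) -> pd.Series:
    """AUC per system; systems lacking a positive or a negative are NaN."""
    score_col, _ = SCHEME_COLUMNS[scheme]
    out = {}
    for ds in sets:
        pos_mask = ds.positives_mask(scheme, floor)
        scores = np.asarray(ds.models[score_col], dtype=float)
        out[ds.system_id] = roc_auc(scores[pos_mask], scores[~pos_mask])
    return pd.Series(out, name=f"auc_{scheme}")


# ---------------------------------------------------------------------------
# success rates

def success_at_n(
    ranked: pd.DataFrame,
    positive: dict | pd.Series,
    n: int,
) -> bool:
    """True iff any of the top-N ranked models is labelled positive.

    ``positive`` maps model_id -> bool.  N beyond the list length evaluates at
    full length.
    """
    if n < 1:
        raise ValueError("N must be at least 1")
    top = ranked.head(n)["model_id"]
    return bool(any(positive[m] for m in top))


def success_curve(
    sets: Sequence[LabeledDecoySet],
    scheme: Scheme,
    floor: QualityClass = QualityClass.ACCEPTABLE,
) -> SuccessCurve:
    """Per-N fraction of systems with ≥1 positive in the top N.

    Systems with no positives at all are included (they simply never
    succeed) — the curve deliberately captures systems where docking failed.
    """
    if not sets:
        raise ValueError("need at least one system")
    max_n = max(len(ds.models) for ds in sets)
    counts = np.zeros(max_n, dtype=float)
    for ds in sets:
        ranked = ds.ranked(scheme)
        _, label_col = SCHEME_COLUMNS[scheme]
        pos = np.array([int(c) >= int(floor) for c in ranked[label_col]])
        if pos.any():
            first = int(np.argmax(pos))  # 0-based rank of first positive
            counts[first:] += 1.0
    return SuccessCurve(
        n_values=np.arange(1, max_n + 1),
        success=counts / len(sets),
    )


# ---------------------------------------------------------------------------
# separation and precision

def separation_sd(
    positive_scores, negative_scores,
    sd_mode: Literal["pooled", "negatives"] = "pooled",
) -> float:
    """|median(pos) − median(neg)| in units of the pooled score SD.

    ``sd_mode="negatives"`` uses the negative-class SD instead of the SD of
    all scores pooled.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    sd = (np.concatenate([pos, neg]).std(ddof=1) if sd_mode == "pooled"
          else neg.std(ddof=1))
    if sd == 0:
        raise ValueError("zero score spread: separation undefined")
    return float(abs(np.median(pos) - np.median(neg)) / sd)


def precision_curve(
    positive_scores,
    negative_scores,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> PrecisionCurve:
    """Precision vs score cutoff from smoothed (Gaussian-KDE) class densities.

    For each threshold t, precision(t) = w⁺S⁺(t) / (w⁺S⁺(t) + w⁻S⁻(t)) where
    S is a class's smoothed survival mass above t and w its model count;
    smoothing avoids outlier bias in the raw counts.  The uncertainty band is
    the binomial standard error at the effective (smoothed) count above t.
    Bandwidths follow Silverman's rule; the default grid spans the pooled data
    range extended by 3 bandwidths.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size < 5 or neg.size < 5:
        raise ValueError("need at least 5 scores per class")
    if np.ptp(pos) == 0 or np.ptp(neg) == 0:
        raise ValueError("degenerate (all-equal) scores in a class")
    kde_pos = stats.gaussian_kde(pos, bw_method="silverman")
    kde_neg = stats.gaussian_kde(neg, bw_method="silverman")
    if grid is None:
        h = max(kde_pos.factor * pos.std(ddof=1), kde_neg.factor * neg.std(ddof=1))
        lo = min(pos.min(), neg.min()) - 3 * h
        hi = max(pos.max(), neg.max()) + 3 * h
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)

    s_pos = np.array([kde_pos.integrate_box_1d(t, np.inf) for t in grid])
    s_neg = np.array([kde_neg.integrate_box_1d(t, np.inf) for t in grid])
    w_pos, w_neg = float(pos.size), float(neg.size)
    above = w_pos * s_pos + w_neg * s_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(above > 0, w_pos * s_pos / above, np.nan)
        stderr = np.where(
            above > 0,
            np.sqrt(np.clip(precision * (1 - precision), 0, None) / np.maximum(above, 1e-12)),
            np.nan,
        )
    return PrecisionCurve(
        thresholds=grid, precision=precision, stderr=stderr, n_effective=above
    )


# ---------------------------------------------------------------------------
# decoy-set composition summaries

def summarize_counts(
    method: str, variant: str, n_systems: int, n_models: int, n_positives: int
) -> dict:
    """Composition arithmetic for one method/variant from raw counts.

    Returns percentages to 1 decimal and the positives-per-system mean to
    1 decimal, as benchmark composition tables print them.
    """
    if n_positives > n_models:
        raise ValueError("more positives than models")
    pct = 100.0 * n_positives / n_models if n_models else 0.0
    return {
        "method": method,
        "variant": variant,
        "n_systems": n_systems,
        "n_models": n_models,
        "n_positives": n_positives,
        "positive_pct": round(pct, 1),
        "n_negatives": n_models - n_positives,
        "positives_per_system_mean": round(n_positives / n_systems, 1) if n_systems else 0.0,
    }


def summarize_decoy_sets(sets: Sequence[LabeledDecoySet]) -> pd.DataFrame:
    """Composition table per (method, label variant) plus cross-method totals.

    For each docking method and each model variant (docking-generated vs
    rebuilt) reports systems, models, positives with percentage, negatives,
    and the positives-per-system mean ± SD.
    """
    if not sets:
        raise ValueError("need at least one system")
    rows = []
    frames = []
    for ds in sets:
        df = ds.models.copy()
        df["system_id"] = ds.system_id
        frames.append(df)
    all_models = pd.concat(frames, ignore_index=True)

    for variant, label_col in (("docking", "class_docking"), ("af2", "class_af2")):
        for method, grp in all_models.groupby("method", sort=False):
            per_sys = grp.groupby("system_id")[label_col].apply(
                lambda c: sum(int(q) >= int(QualityClass.ACCEPTABLE) for q in c)
            )
            n_pos = int(per_sys.sum())
            row = summarize_counts(
                method, variant, per_sys.size, len(grp), n_pos
            )
            row["positives_per_system_sd"] = round(float(per_sys.std(ddof=1)), 1) \
                if per_sys.size > 1 else 0.0
            rows.append(row)
        # cross-method totals
        per_sys_all = all_models.groupby("system_id")[label_col].apply(
            lambda c: sum(int(q) >= int(QualityClass.ACCEPTABLE) for q in c)
        )
        row = summarize_counts(
            "All", variant,
            all_models["system_id"].nunique(), len(all_models),
            int(per_sys_all.sum()),
        )
        row["positives_per_system_sd"] = round(float(per_sys_all.std(ddof=1)), 1) \
            if per_sys_all.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
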