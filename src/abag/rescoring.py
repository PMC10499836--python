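"""Composite confidence rescoring and ranked-list construction.

Raw AF2 confidence metrics (mean pLDDT and pTMscore of a rebuilt model) are
not comparable across systems or docking methods, so each metric is
standardized to a z-score within the ensemble of docked models of one system,
and the two z-scores are summed, unweighted, into the composite score

    composite = z_pLDDT + z_pTMscore

Higher composite means higher confidence relative to the ensemble.  The same
within-(system, method) standardization is applied to docking energies when
pooling models across methods.  Sign conventions: energy-like scores (ProPOSE,
PIPER) are flipped so that higher is always better; ZDOCK scores and ClusPro
cluster sizes are kept as-is; ClusPro ties resolve in original output order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("abag")

#: docking-score orientation: multiply raw by this so that higher = better
SIGN_CONVENTION = {
    "ProPOSE": -1.0,   # energies, more negative = better
    "PIPER": -1.0,     # energies
    "ZDOCK": +1.0,     # shape-complementarity score, higher = better
    "ClusPro": +1.0,   # cluster size, larger = better
}

#: below this ensemble size, z-scores are noisy (composite error above ~1 unit)
SMALL_ENSEMBLE = 25


@dataclass(frozen=True)
class CompositeScore:
    z_plddt: float
    z_ptmscore: float

    @property
    def composite(self) -> float:
        return self.z_plddt + self.z_ptmscore


def zscores(values, ddof: int = 1) -> np.ndarray:
    """Standardize an ensemble of values to mean 0, sample SD 1.

    A constant ensemble maps to all zeros (with a warning) instead of
    dividing by zero, so degenerate systems never crash pooling.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("ensemble too small: need at least 2 values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("constant ensemble: z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def normalize_plddt(plddt) -> np.ndarray:
    """Accept pLDDT on the 0-1 or 0-100 convention; return 0-1.

    Standardization is affine-invariant so this is cosmetic, but it keeps
    reports readable.
    """
    x = np.asarray(plddt, dtype=float)
    if np.nanmax(x) > 1.5:
        x = x / 100.0
    return x


def composite_scores(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Composite scores for one (system, method) ensemble of confidence records.

    ``records`` needs columns ``plddt`` and ``ptmscore`` (plus optionally
    ``system_id``/``method``, which must each be single-valued).  Returns a
    copy with ``z_plddt``, ``z_ptmscore`` and ``composite`` columns; the
    composite is the unweighted sum of the two z-scores and sums to zero over
    the ensemble by construction.
    """
    for col in ("system_id", "method"):
        if col in records.columns and records[col].nunique() > 1:
            raise ValueError(f"records mix multiple values of {col}; "
                             "standardize within one ensemble at a time")
    n = len(records)
    if n < 2:
        raise ValueError("ensemble too small: need at least 2 models")
    if n < SMALL_ENSEMBLE:
        logger.warning(
            "ensemble of %d models: composite scores from fewer than %d poses "
            "carry errors above ~1 unit", n, SMALL_ENSEMBLE,
        )
    out = records.copy()
    out["z_plddt"] = zscores(normalize_plddt(records["plddt"]), ddof=ddof)
    out["z_ptmscore"] = zscores(np.asarray(records["ptmscore"], float), ddof=ddof)
    out["composite"] = out["z_plddt"] + out["z_ptmscore"]
    return out


def composite_scores_by_system(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Apply :func:`composite_scores` within every (system, method) group."""
    group_cols = [c for c in ("system_id", "method") if c in records.columns]
    if not group_cols:
        return composite_scores(records, ddof=ddof)
    parts = [
        composite_scores(grp, ddof=ddof)
        for _, grp in records.groupby(group_cols, sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def orient_docking_scores(
    scores: pd.DataFrame, conventions: dict[str, float] | None = None
) -> pd.DataFrame:
    """Populate an ``oriented`` column where higher always means better.

    ``scores`` needs ``method`` and ``raw`` columns.  Unknown methods raise
    unless an orientation is supplied through ``conventions``.
    """
    conv = dict(SIGN_CONVENTION)
    if conventions:
        conv.update(conventions)
    out = scores.copy()
    unknown = sorted(set(out["method"]) - set(conv))
    if unknown:
        raise ValueError(
            f"unknown docking method(s) {unknown}: supply an orientation"
        )
    out["oriented"] = [
        conv[m] * float(r) for m, r in zip(out["method"], out["raw"])
    ]
    return out


def rank_models(scores: pd.DataFrame, scheme: str,
                score_col: str = "score") -> pd.DataFrame:
    """Rank models by descending score; stable ties (original input order).

    Returns a new frame ordered by rank with a 1-based ``rank`` column and the
    scheme tag in ``.attrs["scheme"]``.  NaN scores are an error.
    """
    s = np.asarray(scores[score_col], dtype=float)
    if np.any(np.isnan(s)):
        raise ValueError("NaN score in ranking input")
    order = np.argsort(-s, kind="stable")
    ranked = scores.iloc[order].reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked.attrs["scheme"] = scheme
    return ranked


def pool_methods(standardized: pd.DataFrame, scheme: str = "pooled",
                 score_col: str = "score", atol: float = 1e-8) -> pd.DataFrame:
    """Merge per-method standardized scores of one system into one ranked list.

    Every (method) group must already be standardized (mean 0; sample SD 1 or
    the all-zero degenerate case) — pooling raw method-native units would be
    meaningless.  Pooling a single method reduces to :func:`rank_models`.
    """
    for method, grp in standardized.groupby("method", sort=False):
        x = np.asarray(grp[score_col], dtype=float)
        if x.size >= 2:
            sd = x.std(ddof=1)
            if abs(x.mean()) > atol or not (
                np.isclose(sd, 1.0, atol=1e-6) or sd <= atol
            ):
                raise ValueError(
                    f"method {method!r} scores are not standardized "
                    "(standardize within (system, method) before pooling)"
                )
    return rank_models(standardized, scheme, score_col=score_col)
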