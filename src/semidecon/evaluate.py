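"""Score inferred profiles and fractions against ground truth.

Four metrics: the Pearson correlation of the flattened matched
profile matrices (reported both as r and r^2, with r^2 the headline
profile score), the entrywise L1 loss ||Chat - C||_1 / ||C||_1, the
Pearson correlation of the flattened fraction matrices, and the mean
squared error of the fractions.  Unknown inferred types carry no
labels, so they are matched to the remaining truth types by
maximum-total-correlation bipartite assignment before scoring; known
types are matched by position.  Metrics can be restricted to the
known types (the convention when comparing against reference-only
methods) or pooled over all types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .matrix import ExpressionMatrix, FractionMatrix, ValidationError

__all__ = ["EvaluationReport", "match_cell_types", "score"]

SCOPES = ("known_only", "all_types")


def _columns(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, ExpressionMatrix):
        return x.values, list(x.column_ids)
    if isinstance(x, FractionMatrix):
        # fractions are types x samples: types are rows
        return x.values.T, list(x.cell_type_ids)
    arr = np.asarray(x, dtype=float)
    return arr, [f"col_{i + 1}" for i in range(arr.shape[1])]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class EvaluationReport:
    """Metric bundle for one (inferred, truth) comparison."""

    rc2: float           # headline profile score: squared Pearson r
    rc: float            # raw Pearson r of the profiles
    l1_loss_C: float
    rf2: float           # headline fraction score: squared Pearson r
    rf: float            # raw Pearson r of the fractions
    mse_F: float
    matching: dict[str, str]
    scope: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "scope": self.scope,
                "rc2": self.rc2,
                "rc": self.rc,
                "l1_loss_C": self.l1_loss_C,
                "rf2": self.rf2,
                "rf": self.rf,
                "mse_F": self.mse_F,
            }]
        )


def match_cell_types(C_hat, C_true, n_known: int) -> dict[str, str]:
    """Assign inferred profile columns to truth columns.

    The first ``n_known`` inferred columns correspond positionally to
    the reference types.  Remaining inferred columns are assigned to
    remaining truth columns by maximizing total Pearson correlation
    (optimal bipartite assignment; undefined correlations, e.g. a
    zero-variance column, rank below every defined one, so degenerate
    columns are matched last).  When there are more inferred than
    truth columns the surplus stays unmatched and is excluded from
    scoring.  Returns an injective inferred-id -> truth-id mapping.
    """
    Vh, ids_h = _columns(C_hat)
    Vt, ids_t = _columns(C_true)
    if Vh.shape[0] != Vt.shape[0]:
        raise ValidationError("matrices must be gene-aligned before matching")
    if n_known > min(len(ids_h), len(ids_t)):
        raise ValidationError("n_known exceeds the number of columns")
    matching = {ids_h[i]: ids_t[i] for i in range(n_known)}
    free_h = list(range(n_known, len(ids_h)))
    free_t = list(range(n_known, len(ids_t)))
    if not free_h or not free_t:
        return matching
    corr = np.full((len(free_h), len(free_t)), -2.0)
    for a, i in enumerate(free_h):
        for b, j in enumerate(free_t):
            r = _pearson(Vh[:, i], Vt[:, j])
            if np.isfinite(r):
                corr[a, b] = r
    rows, cols = linear_sum_assignment(corr, maximize=True)
    for a, b in zip(rows, cols):
        matching[ids_h[free_h[a]]] = ids_t[free_t[b]]
    return matching


def score(
    C_hat,
    F_hat,
    C_true,
    F_true,
    matching: dict[str, str] | None = None,
    scope: str = "all_types",
    n_known: int | None = None,
) -> EvaluationReport:
    """Compute the four metrics on matched, scope-filtered columns.

    ``matching`` defaults to :func:`match_cell_types` (which then
    requires ``n_known``).  ``scope='known_only'`` keeps only the
    first ``n_known`` inferred types, mirroring comparisons against
    methods that cannot infer unreferenced types; with no unknown
    types the two scopes coincide.  Undefined correlations are
    reported as NaN, never as 0.
    """
    if scope not in SCOPES:
        raise ValidationError(f"scope must be one of {SCOPES}")
    Ch, ids_h = _columns(C_hat)
    Ct, ids_t = _columns(C_true)
    Fh, fids_h = _columns(F_hat)
    Ft, fids_t = _columns(F_true)
    if matching is None:
        if n_known is None:
            raise ValidationError("score needs either a matching or n_known")
        matching = match_cell_types(C_hat, C_true, n_known)
    if n_known is None:
        n_known = len(matching)
    if len(set(matching.values())) != len(matching):
        raise ValidationError("matching must be injective")
    pairs = [(h, matching[h]) for h in ids_h if h in matching]
    if scope == "known_only":
        pairs = pairs[:n_known]
    if not pairs:
        raise ValidationError("no matched cell types to score")
    hi = {c: i for i, c in enumerate(ids_h)}
    ti = {c: i for i, c in enumerate(ids_t)}
    h_cols = [hi[h] for h, _ in pairs]
    t_cols = [ti[t] for _, t in pairs]
    Chm, Ctm = Ch[:, h_cols], Ct[:, t_cols]
    # fractions: same type mapping applied to rows (columns of _columns output)
    fhi = {c: i for i, c in enumerate(fids_h)}
    fti = {c: i for i, c in enumerate(fids_t)}
    Fhm = Fh[:, [fhi[h] for h, _ in pairs]]
    Ftm = Ft[:, [fti[t] for _, t in pairs]]
    denom = np.abs(Ctm).sum()
    l1 = float(np.abs(Chm - Ctm).sum() / denom) if denom > 0 else float("nan")
    mse = float(np.mean((Fhm - Ftm) ** 2))
    rc = _pearson(Chm, Ctm)
    rf = _pearson(Fhm, Ftm)
    return EvaluationReport(
        rc2=rc ** 2 if np.isfinite(rc) else float("nan"),
        rc=rc,
        l1_loss_C=l1,
        rf2=rf ** 2 if np.isfinite(rf) else float("nan"),
        rf=rf,
        mse_F=mse,
        matching=dict(matching),
        scope=scope,
    )
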