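"""Build a cell-type reference profile matrix S from annotated single cells.

Pipeline: counts-per-million normalization of the cell matrix,
per-cell-type averaging, a second CPM pass on the aggregated profiles,
and correction for single-cell dropout.  Dropout is modeled with a
Michaelis-Menten curve: the probability that a transcript with mean
expression mu escapes detection is

    P_dropout = 1 - mu / (K_M + mu)

where the Michaelis constant K_M is the mean expression at which half
the cells detect the gene.  Given an observed (mean, dropout-fraction)
pair per gene, K_M inverts exactly to mu * P / (1 - P), and the
dropout-free profile is recovered as S = Cs / (1 - P_dropout), which
collapses algebraically to S = Cs + K_M wherever Cs > 0.

Marker genes are selected by a per-gene, per-type two-sided Wilcoxon
rank-sum test of each type's cells against all others, with
Benjamini-Hochberg correction over the full gene x type family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .matrix import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "cpm_normalize",
    "aggregate_by_cell_type",
    "DropoutModel",
    "fit_dropout_model",
    "predict_dropout",
    "correct_dropout",
    "select_marker_genes",
    "build_reference",
]

FIT_MODES = ("per_gene_closed_form", "global_curve_fit")


def cpm_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every column to sum to one million (counts per million)."""
    sums = mat.values.sum(axis=0)
    if np.any(sums <= 0):
        j = int(np.argmax(sums <= 0))
        raise ValidationError(
            f"column {mat.column_ids[j]!r} has zero total expression; "
            "cannot normalize to CPM"
        )
    return mat.with_values(mat.values * (1e6 / sums), unit_tag="cpm")


def _annotation_series(ann) -> pd.Series:
    """Coerce cell annotations (Series / mapping / pair sequence / DataFrame)."""
    if isinstance(ann, pd.Series):
        out = ann.astype(str)
    elif isinstance(ann, pd.DataFrame):
        out = pd.Series(
            ann.iloc[:, 1].astype(str).to_numpy(),
            index=ann.iloc[:, 0].astype(str).to_numpy(),
        )
    elif isinstance(ann, Mapping):
        out = pd.Series({str(k): str(v) for k, v in ann.items()})
    else:
        pairs = list(ann)
        out = pd.Series(
            [str(t) for _, t in pairs], index=[str(c) for c, _ in pairs]
        )
    if out.index.duplicated().any():
        dup = out.index[out.index.duplicated()][0]
        raise ValidationError(f"cell {dup!r} annotated more than once")
    return out


def aggregate_by_cell_type(sc: ExpressionMatrix, ann) -> ExpressionMatrix:
    """Average cell columns per cell type: the pre-correction profile Cs.

    Column order follows the first appearance of each type in the
    annotation.  Every cell column must be annotated and every
    annotated cell must be present.
    """
    ann = _annotation_series(ann)
    absent = [c for c in ann.index if c not in set(sc.column_ids)]
    if absent:
        raise ValidationError(f"annotation references absent cells: {absent[:5]}")
    missing = [c for c in sc.column_ids if c not in ann.index]
    if missing:
        raise ValidationError(f"cells without annotation: {missing[:5]}")
    types: list[str] = []
    for c in ann.index:
        t = ann[c]
        if t not in types:
            types.append(t)
    col_index = {c: i for i, c in enumerate(sc.column_ids)}
    profile = np.empty((sc.n_genes, len(types)))
    for l, t in enumerate(types):
        cols = [col_index[c] for c in ann.index[ann == t]]
        profile[:, l] = sc.values[:, cols].mean(axis=1)
    return ExpressionMatrix(profile, list(sc.gene_ids), types, unit_tag=sc.unit_tag)


@dataclass
class DropoutModel:
    """Per-gene Michaelis-Menten dropout curves fitted from single cells.

    ``km`` holds the Michaelis constant in CPM units, ``mean_expr`` the
    all-cell mean used in fitting, ``dropout_fraction`` the observed
    zero fraction, and ``flagged`` marks genes never detected (dropout
    fraction 1), for which no correction is possible and K_M is stored
    as 0.
    """

    gene_ids: list[str]
    km: np.ndarray
    mean_expr: np.ndarray
    dropout_fraction: np.ndarray
    flagged: np.ndarray
    fit_mode: str = "per_gene_closed_form"

    def __post_init__(self) -> None:
        self.km = np.asarray(self.km, dtype=float)
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        self.dropout_fraction = np.asarray(self.dropout_fraction, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not (len(self.gene_ids) == self.km.size == self.mean_expr.size
                == self.dropout_fraction.size == self.flagged.size):
            raise ValidationError("dropout model field lengths disagree")
        if np.any(self.km < 0) or np.any(~np.isfinite(self.km)):
            raise ValidationError("K_M must be finite and non-negative")
        if self.fit_mode not in FIT_MODES:
            raise ValidationError(f"fit_mode must be one of {FIT_MODES}")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def predict(self, gene: str, mean_expr: float) -> float:
        """Dropout probability 1 - x / (K_M + x) at mean expression x."""
        if gene not in self._index:
            raise ValidationError(f"unknown gene {gene!r}")
        if mean_expr < 0:
            raise ValidationError("mean expression must be non-negative")
        km = self.km[self._index[gene]]
        if km == 0.0:
            return 0.0
        if mean_expr == 0.0:
            return 1.0
        return 1.0 - mean_expr / (km + mean_expr)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "km": self.km,
                "mean_expr": self.mean_expr,
                "dropout_fraction": self.dropout_fraction,
                "flagged": self.flagged.astype(int),
            },
            index=self.gene_ids,
        )
        df.index.name = "gene_id"
        return df


def fit_dropout_model(
    sc_cpm: ExpressionMatrix, fit_mode: str = "per_gene_closed_form"
) -> DropoutModel:
    """Fit dropout curves from a CPM-normalized single-cell matrix.

    For each gene, the all-cell mean expression mu_j (zeros included)
    and the observed dropout fraction P_j (share of cells with value
    exactly zero) are computed.  ``per_gene_closed_form`` inverts the
    Michaelis-Menten curve at that single point, K_M = mu_j P_j /
    (1 - P_j); ``global_curve_fit`` fits one shared K_M to all
    (mu_j, P_j) pairs by least squares.  Genes with P_j = 1 carry no
    information and are flagged (K_M stored as 0, correction skipped).
    """
    if fit_mode not in FIT_MODES:
        raise ValidationError(f"fit_mode must be one of {FIT_MODES}")
    if sc_cpm.n_columns < 2:
        raise ValidationError("dropout fitting needs at least 2 cells")
    X = sc_cpm.values
    mean_expr = X.mean(axis=1)
    p_drop = (X == 0.0).mean(axis=1)
    flagged = p_drop >= 1.0
    if flagged.any():
        logger.warning(
            "%d genes were never detected; their dropout correction is skipped",
            int(flagged.sum()),
        )
    if fit_mode == "per_gene_closed_form":
        km = np.zeros_like(mean_expr)
        ok = ~flagged
        km[ok] = mean_expr[ok] * p_drop[ok] / (1.0 - p_drop[ok])
    else:
        ok = ~flagged
        mu, p = mean_expr[ok], p_drop[ok]

        def sse(km_val: float) -> float:
            pred = km_val / (km_val + mu)
            return float(np.sum((pred - p) ** 2))

        upper = max(float(mu.max()), 1.0) * 10.0
        res = minimize_scalar(sse, bounds=(0.0, upper), method="bounded",
                              options={"xatol": 1e-8})
        km = np.full_like(mean_expr, max(float(res.x), 0.0))
        km[flagged] = 0.0
    return DropoutModel(
        gene_ids=list(sc_cpm.gene_ids),
        km=km,
        mean_expr=mean_expr,
        dropout_fraction=p_drop,
        flagged=flagged,
        fit_mode=fit_mode,
    )


def predict_dropout(model: DropoutModel, gene: str, mean_expr: float) -> float:
    """Dropout probability for ``gene`` at the given mean expression."""
    return model.predict(gene, mean_expr)


def correct_dropout(cs: ExpressionMatrix, model: DropoutModel) -> ExpressionMatrix:
    """Undo expected dropout: S = Cs / (1 - P_dropout(Cs)) = Cs + K_M.

    The dropout probability is evaluated at each entry's own value, so
    the correction adds exactly K_M to every positive entry; zeros stay
    zero (a zero profile entry gives P = 1 and carries no signal).
    Flagged genes are passed through unchanged.
    """
    missing = [g for g in cs.gene_ids if g not in model._index]
    if missing:
        raise ValidationError(f"dropout model does not cover genes: {missing[:5]}")
    rows = np.array([model._index[g] for g in cs.gene_ids])
    km = model.km[rows]
    n_zero_with_km = int(np.sum((cs.values == 0) & (km[:, None] > 0)))
    if n_zero_with_km:
        logger.warning(
            "%d zero profile entries have K_M > 0 (predicted dropout 1); "
            "left at zero", n_zero_with_km,
        )
    corrected = np.where(cs.values > 0, cs.values + km[:, None], 0.0)
    return cs.with_values(corrected, unit_tag="model")


def select_marker_genes(sc_cpm: ExpressionMatrix, ann, alpha: float = 0.001) -> list[str]:
    """Genes differentially expressed in at least one cell type.

    For every gene and cell type, a two-sided Wilcoxon rank-sum test
    compares the log2(CPM + 1) values of that type's cells against all
    other cells.  Benjamini-Hochberg correction is applied jointly over
    the full gene x type family, and a gene is kept when any corrected
    p-value is <= ``alpha`` (default 0.001).  Types with fewer than two
    cells are skipped with a warning.  The result preserves input gene
    order and is invariant to cell-column permutations.
    """
    ann = _annotation_series(ann)
    missing = [c for c in sc_cpm.column_ids if c not in ann.index]
    if missing:
        raise ValidationError(f"cells without annotation: {missing[:5]}")
    if alpha <= 0:
        return []
    labels = np.array([ann[c] for c in sc_cpm.column_ids])
    types = [t for t in dict.fromkeys(labels)]
    if len(types) < 2:
        raise ValidationError("marker selection needs at least 2 cell types")
    logx = np.log2(sc_cpm.values + 1.0)
    pvals = []
    for t in types:
        in_type = labels == t
        if in_type.sum() < 2:
            logger.warning("cell type %r has < 2 cells; skipped in marker selection", t)
            continue
        res = stats.mannwhitneyu(
            logx[:, in_type], logx[:, ~in_type],
            alternative="two-sided", axis=1, method="auto",
        )
        pvals.append(np.asarray(res.pvalue, dtype=float))
    if not pvals:
        raise ValidationError("no cell type had >= 2 cells")
    P = np.vstack(pvals)  # types x genes
    adj = stats.false_discovery_control(P.ravel(), method="bh").reshape(P.shape)
    keep = (adj <= alpha).any(axis=0)
    return [g for g, kp in zip(sc_cpm.gene_ids, keep) if kp]


def build_reference(
    sc_counts: ExpressionMatrix, ann, fit_mode: str = "per_gene_closed_form"
) -> ExpressionMatrix:
    """End-to-end reference construction from annotated single-cell counts.

    CPM-normalize the cells, average per cell type, CPM-normalize the
    aggregated profiles again, fit the dropout model on the cell-level
    CPM matrix, and correct the profiles.  Returns S (genes x types).
    """
    sc_cpm = cpm_normalize(sc_counts)
    cs = aggregate_by_cell_type(sc_cpm, ann)
    cs = cpm_normalize(cs)
    model = fit_dropout_model(sc_cpm, fit_mode=fit_mode)
    return correct_dropout(cs, model)
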