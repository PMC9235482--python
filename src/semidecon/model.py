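"""Semi-deconvolution of bulk expression with a single-cell reference.

The model explains a non-negative bulk matrix B (genes x samples) as a
product C F of cell-type expression profiles C (genes x K) and simplex
cell-type fractions F (K x samples), while shrinking the first k
columns of C toward a reference profile matrix S built from
single-cell data:

    min_{C,F,mu}  ||B - C F||_Fr^2 + lam * ||C1 - mu S||_Fr^2
    s.t.          C >= 0,  F >= 0,  each column of F sums to 1

C = [C1 | C2] splits into k "known" cell types matched to the columns
of S and y extra "unknown" types allowed only in the bulk samples
(populations absent from the single-cell reference).  ``mu`` is a free
scale that reconciles reference and bulk units; ``lam`` balances the
complete-deconvolution data term against the reference penalty.

The objective is minimized by coordinate descent.  Each block update
is an exactly-solved convex subproblem, so the per-sweep objective
trace is non-increasing:

* fractions F        - one simplex-constrained QP per sample;
* known profiles C1  - one non-negative ridge-style least squares per
  gene row (design [F1' ; sqrt(lam) I]);
* unknown profiles C2 - one non-negative least squares per gene row;
* scale mu           - closed-form no-intercept regression of C1 on S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    FractionMatrix,
    ValidationError,
    align_genes,
    read_expression_matrix,
    write_expression_matrix,
)
from .qp import nonneg_lstsq_rows, simplex_lsq
from .reference import cpm_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "objective",
    "solve_fractions",
    "solve_known_profiles",
    "solve_unknown_profiles",
    "solve_scale",
    "SemiDeconvolution",
    "DeconvolutionResults",
]


def _values(x) -> np.ndarray:
    if isinstance(x, (ExpressionMatrix, FractionMatrix)):
        return x.values
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def objective(B, C, F, S, mu: float, lam: float) -> float:
    """Penalized reconstruction loss ||B - CF||_Fr^2 + lam ||C1 - mu S||_Fr^2.

    C1 is the first k columns of C, where k is the number of columns
    of the reference S.  With ``lam = 0`` this is the plain complete-
    deconvolution loss and S does not affect the value.
    """
    B, C, F, S = _values(B), _values(C), _values(F), _values(S)
    m, n = B.shape
    K = C.shape[1]
    k = S.shape[1]
    if C.shape[0] != m or F.shape != (K, n) or S.shape[0] != m or k > K:
        raise ValidationError(
            f"inconsistent shapes: B{B.shape}, C{C.shape}, F{F.shape}, S{S.shape}"
        )
    resid = B - C @ F
    val = float(np.sum(resid * resid))
    if lam != 0.0:
        pen = C[:, :k] - mu * S
        val += float(lam) * float(np.sum(pen * pen))
    return val


def solve_fractions(B, C) -> np.ndarray:
    """Optimal fractions given profiles: per-sample simplex-constrained QP.

    For every bulk column b solves  min_f 1/2 f'C'Cf - b'Cf  subject to
    f >= 0 and sum(f) = 1; the sample problems are independent.  Tiny
    solver negatives are clamped and each column renormalized to sum
    exactly to one.
    """
    B, C = _values(B), _values(C)
    m, n = B.shape
    K = C.shape[1]
    if C.shape[0] != m:
        raise ValidationError(f"B has {m} genes but C has {C.shape[0]}")
    F = np.empty((K, n))
    if K == 1:
        F[:] = 1.0
        return F
    H = C.T @ C
    G = C.T @ B
    from .qp import solve_simplex_qp

    for j in range(n):
        F[:, j] = solve_simplex_qp(H, G[:, j])
    return F


def solve_known_profiles(B, C2, F, S, mu: float, lam: float) -> np.ndarray:
    """Optimal known-type profiles C1 given everything else.

    With F partitioned vertically into F1 (top k rows) and F2 (bottom
    y rows) and Bbar = B - C2 F2, each gene row i solves

        min_{c1 >= 0} 1/2 c1'(F1 F1' + lam I)c1 - (F1 bbar_i + lam mu s_i)'c1

    which is the non-negative least-squares problem with stacked design
    [F1' ; sqrt(lam) I] and target [bbar_i ; sqrt(lam) mu s_i].  Rows
    are independent and share the design matrix.
    """
    B, F, S = _values(B), _values(F), _values(S)
    C2 = _values(C2) if C2 is not None else np.zeros((B.shape[0], 0))
    if C2.size == 0:
        C2 = C2.reshape(B.shape[0], 0)
    m, n = B.shape
    k = S.shape[1]
    y = F.shape[0] - k
    if y != C2.shape[1]:
        raise ValidationError(
            f"F has {F.shape[0]} rows for k={k} known types but C2 has "
            f"{C2.shape[1]} columns"
        )
    F1, F2 = F[:k, :], F[k:, :]
    Bbar = B - C2 @ F2 if y else B
    if lam > 0.0:
        root = np.sqrt(lam)
        A = np.vstack([F1.T, root * np.eye(k)])
        D = np.vstack([Bbar.T, root * mu * S.T])
    else:
        A = F1.T
        D = Bbar.T
    return nonneg_lstsq_rows(A, D).T


def solve_unknown_profiles(B, C1, F) -> np.ndarray:
    """Optimal unknown-type profiles C2 given C1 and F.

    Each gene row solves min_{c2>=0} ||bbar_i - c2'F2||^2 with
    Bbar = B - C1 F1.  Returns an (m, 0) array when there are no
    unknown types.
    """
    B, C1, F = _values(B), _values(C1), _values(F)
    m, n = B.shape
    k = C1.shape[1]
    y = F.shape[0] - k
    if y < 0:
        raise ValidationError("F has fewer rows than C1 has columns")
    if y == 0:
        return np.zeros((m, 0))
    F1, F2 = F[:k, :], F[k:, :]
    Bbar = B - C1 @ F1
    return nonneg_lstsq_rows(F2.T, Bbar.T).T


def solve_scale(C1, S) -> float:
    """Closed-form scale mu* = <C1, S> / <S, S> (no-intercept regression).

    Minimizes the residual sum of squares ||C1 - mu S||_Fr^2 over mu.
    """
    C1, S = _values(C1), _values(S)
    if C1.shape != S.shape:
        raise ValidationError(f"C1 shape {C1.shape} differs from S shape {S.shape}")
    denom = float(np.sum(S * S))
    if denom == 0.0:
        raise ValidationError("reference matrix S is all zero; scale is undefined")
    return float(np.sum(C1 * S)) / denom


@dataclass
class DeconvolutionResults:
    """Fitted profiles, fractions and diagnostics from a deconvolution run."""

    model: "SemiDeconvolution"
    C: ExpressionMatrix
    F: FractionMatrix
    mu: float
    lam: float
    objective_trace: np.ndarray
    converged: bool
    n_sweeps: int
    known_types: list[str]
    unknown_types: list[str]
    seed: int
    init: str

    @property
    def C1(self) -> np.ndarray:
        """Known-type profile columns (matched to the reference)."""
        return self.C.values[:, : len(self.known_types)]

    @property
    def C2(self) -> np.ndarray:
        """Unknown-type profile columns."""
        return self.C.values[:, len(self.known_types):]

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def summary(self) -> str:
        """Human-readable fit report: dimensions, convergence, fractions."""
        m, K = self.C.shape
        n = self.F.shape[1]
        lines = [
            "             Semi-deconvolution results",
            "=" * 56,
            f"No. genes:           {m:>8}    No. bulk samples:  {n:>4}",
            f"Known cell types:    {len(self.known_types):>8}    Unknown types:     {len(self.unknown_types):>4}",
            f"lambda (penalty):    {self.lam:>8g}    mu (scale):      {self.mu:>8.4g}",
            f"Sweeps:              {self.n_sweeps:>8}    Converged:         {str(self.converged):>5}",
            f"Final objective:     {self.final_objective:>12.6e}",
            "-" * 56,
            "Cell-type fractions (rows = cell types, columns = samples)",
            self.F.to_frame().round(4).to_string(),
            "=" * 56,
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write C.tsv, F.tsv, mu.txt, trace.tsv and convergence.txt."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        from .matrix import write_fraction_matrix

        write_expression_matrix(self.C, os.path.join(out_dir, "C.tsv"))
        write_fraction_matrix(self.F, os.path.join(out_dir, "F.tsv"))
        with open(os.path.join(out_dir, "mu.txt"), "w") as fh:
            fh.write(f"{self.mu!r}\n")
        trace = pd.DataFrame(
            {"sweep": np.arange(1, len(self.objective_trace) + 1),
             "objective": self.objective_trace}
        )
        trace.to_csv(os.path.join(out_dir, "trace.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "convergence.txt"), "w") as fh:
            fh.write(f"converged = {self.converged}\n")
            fh.write(f"n_sweeps = {self.n_sweeps}\n")
            fh.write(f"final_objective = {self.final_objective!r}\n")
            fh.write(f"mu = {self.mu!r}\n")
            fh.write(f"lam = {self.lam!r}\n")
            fh.write(f"seed = {self.seed}\n")
            fh.write(f"init = {self.init}\n")


class SemiDeconvolution:
    """Reference-penalized deconvolution model for bulk expression.

    Parameters
    ----------
    bulk : ExpressionMatrix or DataFrame
        Bulk expression B, genes x samples, non-negative.
    reference : ExpressionMatrix or DataFrame
        Reference profiles S, genes x known cell types, built from
        annotated single-cell data (see :func:`semidecon.build_reference`).
    lam : float, default 0.1
        Weight of the reference penalty.  ``lam = 0`` disables the
        penalty (complete deconvolution with an informed start).
    n_unknown : int, default 1
        Number y of extra cell types allowed only in the bulk samples.
    normalize : bool, default True
        Rescale every column of B and S to counts-per-million before
        fitting; ``mu`` absorbs any residual scale difference.

    Genes are aligned by exact identifier intersection in the order of
    the bulk matrix; dropped genes are logged.

    Examples
    --------
    >>> model = SemiDeconvolution(bulk, reference, lam=0.1, n_unknown=1)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, bulk, reference, *, lam: float = 0.1, n_unknown: int = 1,
                 normalize: bool = True):
        if lam < 0:
            raise ValidationError("lam must be non-negative")
        if n_unknown < 0:
            raise ValidationError("n_unknown must be non-negative")
        bulk = self._coerce(bulk, "bulk")
        reference = self._coerce(reference, "reference")
        if reference.n_columns < 1:
            raise ValidationError("reference must contain at least one cell type")
        n_dropped = len(set(bulk.gene_ids) ^ set(reference.gene_ids))
        bulk, reference = align_genes(bulk, reference)
        if n_dropped:
            logger.warning(
                "gene alignment dropped %d identifiers not shared by both matrices",
                n_dropped,
            )
        if normalize:
            bulk = cpm_normalize(bulk)
            reference = cpm_normalize(reference)
        self.bulk = bulk
        self.reference = reference
        self.lam = float(lam)
        self.n_unknown = int(n_unknown)
        self.normalize = normalize
        if self.n_unknown > bulk.n_columns:
            logger.warning(
                "y=%d unknown types with only n=%d bulk samples: the problem "
                "is ill-posed (more unknown types than samples)",
                self.n_unknown, bulk.n_columns,
            )

    @staticmethod
    def _coerce(x, what: str) -> ExpressionMatrix:
        if isinstance(x, ExpressionMatrix):
            return x
        if isinstance(x, pd.DataFrame):
            return ExpressionMatrix.from_frame(x)
        raise TypeError(f"{what} must be an ExpressionMatrix or DataFrame")

    @classmethod
    def from_files(cls, bulk_path, reference_path, **kwargs) -> "SemiDeconvolution":
        """Build a model from two delimited-text matrices on disk."""
        bulk = read_expression_matrix(bulk_path)
        reference = read_expression_matrix(reference_path)
        return cls(bulk, reference, **kwargs)

    @property
    def n_known(self) -> int:
        return self.reference.n_columns

    def fit(
        self,
        *,
        init: str = "reference",
        seed: int = 0,
        max_sweeps: int = 100,
        tol: float = 1e-6,
        start: dict | None = None,
    ) -> DeconvolutionResults:
        """Run coordinate descent until the objective stabilizes.

        Parameters
        ----------
        init : {"reference", "random"}
            ``reference`` starts C1 at S (mu = 1); ``random`` draws C1
            uniformly on [0, max(B)] (the no-prior condition).  C2 is
            always drawn uniformly on [0, max(B)] from ``seed``.
        seed : int
            Seed for the randomized parts of the initialization.
        max_sweeps : int
            Upper bound on full F -> C1 -> C2 -> mu sweeps.
        tol : float
            Relative objective-change convergence threshold.
        start : dict, optional
            Explicit warm start overriding ``init``; any of the keys
            ``"C1"``, ``"C2"``, ``"mu"``.

        Returns
        -------
        DeconvolutionResults
            With a non-increasing per-sweep objective trace.
        """
        if init not in ("reference", "random"):
            raise ValidationError("init must be 'reference' or 'random'")
        if max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")
        if tol <= 0:
            raise ValidationError("tol must be positive")
        B = self.bulk.values
        S = self.reference.values
        m, n = B.shape
        k = self.n_known
        y = self.n_unknown
        rng = np.random.default_rng(seed)
        hi = float(B.max())
        if init == "reference":
            C1 = S.copy()
        else:
            C1 = rng.uniform(0.0, hi, size=(m, k))
        C2 = rng.uniform(0.0, hi, size=(m, y))
        mu = 1.0
        if start:
            if "C1" in start:
                C1 = np.array(_values(start["C1"]), dtype=float)
            if "C2" in start:
                C2 = np.array(_values(start["C2"]), dtype=float)
            if "mu" in start:
                mu = float(start["mu"])
        trace: list[float] = []
        converged = False
        F = None
        prev = np.inf
        for sweep in range(1, max_sweeps + 1):
            C = np.hstack([C1, C2])
            F = solve_fractions(B, C)
            C1 = solve_known_profiles(B, C2, F, S, mu, self.lam)
            if y:
                C2 = solve_unknown_profiles(B, C1, F)
            mu = solve_scale(C1, S)
            obj = objective(B, np.hstack([C1, C2]), F, S, mu, self.lam)
            if not np.isfinite(obj):
                raise ValidationError(f"non-finite objective at sweep {sweep}")
            trace.append(obj)
            logger.info("sweep %3d  objective %.10e", sweep, obj)
            if np.isfinite(prev) and abs(prev - obj) / max(prev, 1e-12) < tol:
                converged = True
                break
            prev = obj
        unknown_ids = [f"unknown_{i + 1}" for i in range(y)]
        C_full = ExpressionMatrix(
            np.hstack([C1, C2]),
            gene_ids=list(self.bulk.gene_ids),
            column_ids=list(self.reference.column_ids) + unknown_ids,
            unit_tag="model",
        )
        F_full = FractionMatrix(
            F,
            cell_type_ids=list(self.reference.column_ids) + unknown_ids,
            sample_ids=list(self.bulk.column_ids),
        )
        return DeconvolutionResults(
            model=self,
            C=C_full,
            F=F_full,
            mu=float(mu),
            lam=self.lam,
            objective_trace=np.asarray(trace),
            converged=converged,
            n_sweeps=len(trace),
            known_types=list(self.reference.column_ids),
            unknown_types=unknown_ids,
            seed=seed,
            init=init,
        )
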