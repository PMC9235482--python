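"""Ground-truthed synthetic bulk mixtures from cell-type profiles.

The generator emulates pseudo-bulk construction from a cell-type
profile matrix: the base profile is log2-transformed (pseudocount 1),
replicated once per sample, and perturbed gene-wise with Gaussian
noise of standard deviation sigma_j / 5, where sigma_j is the standard
deviation of gene j's log2 values across cell types.  Noisy component
matrices are mapped back to linear space.  Base cell-type fractions
are perturbed once in the same transformed space with sd sigma_f / 2
(sigma_f: across-type sd of the transformed frequencies) to form the
tissue-level fraction vector, replicated per sample, perturbed again
with the inter-sample rule (sd sigma_f / 5), mapped back, clamped at
zero and renormalized to the simplex.  Each bulk column is the exact
convolution of its own component matrix with its fraction vector, so
B - component @ fraction == 0 holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, FractionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "make_base_profile",
    "default_fractions",
    "log2_sd_across_types",
    "perturb_log2",
    "simulate_components",
    "simulate_fractions",
    "simulate_bulk",
    "simulate_dropout_cells",
    "perturb_reference",
]

# independent, reproducible RNG streams derived from the one user seed
_STREAM_PROFILE = 11
_STREAM_SUBSAMPLE = 12
_STREAM_COMPONENTS = 13
_STREAM_FRACTIONS = 14
_STREAM_REFERENCE = 15

#: coarse tumor-microenvironment labels used for generated profiles
DEFAULT_TYPE_NAMES = (
    "epithelial", "fibroblast", "lymphocyte", "myeloid", "endothelial",
    "osteoclast",
)

_PSEUDOCOUNT = 1.0


def _to_log2(x: np.ndarray) -> np.ndarray:
    return np.log2(x + _PSEUDOCOUNT)


def _from_log2(v: np.ndarray) -> np.ndarray:
    return np.clip(np.exp2(v) - _PSEUDOCOUNT, 0.0, None)


def perturb_log2(values: np.ndarray, sd, rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian noise (per-entry sd, broadcastable) in log2(1+x) space.

    Returns the perturbed *transformed* values; callers map back to
    linear space with the clamped inverse transform.
    """
    values = np.asarray(values, dtype=float)
    noise = rng.standard_normal(values.shape) * np.asarray(sd, dtype=float)
    return values + noise


def log2_sd_across_types(profile: np.ndarray) -> np.ndarray:
    """Per-gene sd of log2(1+x) values across cell-type columns (ddof=1)."""
    L = _to_log2(np.asarray(profile, dtype=float))
    if L.shape[1] < 2:
        return np.zeros(L.shape[0])
    return L.std(axis=1, ddof=1)


def default_fractions(n_types: int) -> np.ndarray:
    """A fixed, realistically uneven simplex vector (geometric decay)."""
    w = 0.7 ** np.arange(n_types)
    return w / w.sum()


def make_base_profile(
    n_genes: int, n_types: int, seed=0, marker_fold: tuple[float, float] = (8.0, 32.0)
) -> ExpressionMatrix:
    """Generate a CPM-normalized ground-truth cell-type profile matrix.

    Genes share a log-normal baseline; each type receives a dedicated
    block of strongly up-regulated marker genes (fold change drawn from
    ``marker_fold``) on top of mild log-normal type-to-type variation,
    mimicking the marker structure of an annotated single-cell atlas.
    """
    if n_genes < n_types:
        raise ValidationError("need at least one gene per cell type")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=4.0, sigma=1.5, size=n_genes)
    fold = rng.lognormal(mean=0.0, sigma=0.4, size=(n_genes, n_types))
    n_mark = max(1, n_genes // (4 * n_types))
    order = rng.permutation(n_genes)
    for t in range(n_types):
        idx = order[t * n_mark:(t + 1) * n_mark]
        fold[idx, t] *= rng.uniform(*marker_fold, size=idx.size)
    values = baseline[:, None] * fold
    values *= 1e6 / values.sum(axis=0)
    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    type_ids = [
        DEFAULT_TYPE_NAMES[t] if t < len(DEFAULT_TYPE_NAMES) else f"type_{t + 1}"
        for t in range(n_types)
    ]
    return ExpressionMatrix(values, gene_ids, type_ids, unit_tag="cpm")


@dataclass
class SimulationConfig:
    """Study conditions for the bulk-mixture generator.

    Defaults reproduce the main benchmark setting: 5000 genes, five
    known cell types plus one unknown, a single bulk sample, and noise
    multipliers of 1 (0 turns the corresponding noise off).
    """

    n_genes: int = 5000
    n_samples: int = 1
    n_known: int = 5
    n_unknown: int = 1
    base_profile: ExpressionMatrix | None = None
    base_fractions: np.ndarray | None = None
    component_noise_scale: float = 1.0
    fraction_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_known < 0 or self.n_unknown < 0 or self.n_total < 1:
            raise ValidationError("need a non-negative type split with >= 1 type")
        if self.component_noise_scale < 0 or self.fraction_noise_scale < 0:
            raise ValidationError("noise scales must be non-negative")
        if self.base_fractions is not None:
            f = np.asarray(self.base_fractions, dtype=float)
            if f.ndim != 1 or f.size != self.n_total:
                raise ValidationError("base_fractions length must equal K")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
                raise ValidationError("base_fractions must be a simplex vector")
        if self.base_profile is not None and self.base_profile.n_columns != self.n_total:
            raise ValidationError(
                f"base_profile has {self.base_profile.n_columns} columns "
                f"but K = {self.n_total}"
            )

    @property
    def n_total(self) -> int:
        return self.n_known + self.n_unknown


@dataclass
class SimulatedDataset:
    """A simulated bulk cohort together with its ground truth."""

    B: ExpressionMatrix
    component_matrices: list[np.ndarray]
    F_true: FractionMatrix
    ground_truth_C: ExpressionMatrix
    n_known: int

    @property
    def reference(self) -> ExpressionMatrix:
        """The known-type columns of the true profile (the oracle S)."""
        em = self.ground_truth_C
        return ExpressionMatrix(
            em.values[:, : self.n_known],
            list(em.gene_ids),
            list(em.column_ids[: self.n_known]),
            em.unit_tag,
        )

    def save(self, out_dir) -> None:
        import os

        from .matrix import write_expression_matrix, write_fraction_matrix

        os.makedirs(out_dir, exist_ok=True)
        write_expression_matrix(self.B, os.path.join(out_dir, "B.tsv"))
        write_expression_matrix(self.ground_truth_C, os.path.join(out_dir, "C_true.tsv"))
        write_expression_matrix(self.reference, os.path.join(out_dir, "S_true.tsv"))
        write_fraction_matrix(self.F_true, os.path.join(out_dir, "F_true.tsv"))
        comp_dir = os.path.join(out_dir, "components")
        os.makedirs(comp_dir, exist_ok=True)
        em = self.ground_truth_C
        for j, comp in enumerate(self.component_matrices):
            write_expression_matrix(
                ExpressionMatrix(comp, list(em.gene_ids), list(em.column_ids), "model"),
                os.path.join(comp_dir, f"component_{j + 1}.tsv"),
            )


def _resolve(config: SimulationConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Materialize the base profile and fractions for a config (deterministic)."""
    K = config.n_total
    if config.base_profile is not None:
        profile = config.base_profile
        if config.n_genes < profile.n_genes:
            rng = np.random.default_rng([_STREAM_SUBSAMPLE, config.seed])
            rows = np.sort(rng.choice(profile.n_genes, config.n_genes, replace=False))
            profile = ExpressionMatrix(
                profile.values[rows, :],
                [profile.gene_ids[i] for i in rows],
                list(profile.column_ids),
                profile.unit_tag,
            )
    else:
        profile = make_base_profile(config.n_genes, K, seed=[_STREAM_PROFILE, config.seed])
    if config.base_fractions is not None:
        f0 = np.asarray(config.base_fractions, dtype=float)
    else:
        f0 = default_fractions(K)
    return profile, f0


def simulate_components(config: SimulationConfig) -> list[np.ndarray]:
    """Per-sample noisy copies of the base profile (linear space, m x K).

    Gene-wise noise sd is sigma_j / 5 * component_noise_scale in
    log2(1+x) space; genes identical across types (sigma_j = 0) are
    never perturbed, and with a single cell type all components equal
    the base profile.
    """
    profile, _ = _resolve(config)
    K = profile.n_columns
    if K == 1:
        logger.warning("single cell type: sigma_j = 0, components equal the base profile")
    L = _to_log2(profile.values)
    sigma = log2_sd_across_types(profile.values)
    sd = sigma[:, None] / 5.0 * config.component_noise_scale
    rng = np.random.default_rng([_STREAM_COMPONENTS, config.seed])
    out = []
    for _ in range(config.n_samples):
        if config.component_noise_scale == 0.0:
            out.append(profile.values.copy())
        else:
            comp = _from_log2(perturb_log2(L, sd, rng))
            # sd 0 means "drawn from N(x, 0)": keep those genes bit-exact
            zero = sigma == 0.0
            comp[zero, :] = profile.values[zero, :]
            out.append(comp)
    return out


def simulate_fractions(config: SimulationConfig) -> FractionMatrix:
    """Ground-truth fraction matrix (K x n), every column on the simplex.

    The base fraction vector is perturbed once (sd sigma_f / 2 *
    fraction_noise_scale) to form the tissue-level vector, replicated,
    perturbed per sample with the inter-sample rule (sd sigma_f / 5 *
    component_noise_scale), inverse-transformed, clamped and
    renormalized.  A degenerate all-zero column triggers a seeded
    resample (at most 100 attempts).
    """
    profile, f0 = _resolve(config)
    K = f0.size
    type_ids = list(profile.column_ids)
    sample_ids = [f"sample_{j + 1}" for j in range(config.n_samples)]
    if K == 1:
        return FractionMatrix(np.ones((1, config.n_samples)), type_ids, sample_ids)
    lf = _to_log2(f0)
    sigma_f = float(np.std(lf, ddof=1))
    rng = np.random.default_rng([_STREAM_FRACTIONS, config.seed])
    for _ in range(100):
        primary = perturb_log2(lf, sigma_f / 2.0 * config.fraction_noise_scale, rng)
        cols = np.empty((K, config.n_samples))
        ok = True
        for j in range(config.n_samples):
            col = perturb_log2(primary, sigma_f / 5.0 * config.component_noise_scale, rng)
            lin = _from_log2(col)
            total = lin.sum()
            if total <= 0.0:
                ok = False
                break
            cols[:, j] = lin / total
        if ok:
            return FractionMatrix(cols, type_ids, sample_ids)
    raise ValidationError("fraction simulation degenerated to all-zero columns")


def simulate_bulk(config: SimulationConfig) -> SimulatedDataset:
    """Convolve per-sample component matrices with their fraction vectors.

    Deterministic given ``config.seed``; B[:, j] equals
    component_matrices[j] @ F_true[:, j] exactly.
    """
    profile, _ = _resolve(config)
    comps = simulate_components(config)
    F = simulate_fractions(config)
    n = config.n_samples
    B = np.empty((profile.n_genes, n))
    for j in range(n):
        B[:, j] = comps[j] @ F.values[:, j]
    sample_ids = list(F.sample_ids)
    Bm = ExpressionMatrix(B, list(profile.gene_ids), sample_ids, unit_tag="model")
    return SimulatedDataset(
        B=Bm,
        component_matrices=comps,
        F_true=F,
        ground_truth_C=profile,
        n_known=config.n_known,
    )


def simulate_dropout_cells(
    profile: ExpressionMatrix,
    n_cells: int,
    km: np.ndarray,
    seed: int = 0,
    cell_jitter: float = 0.1,
):
    """Synthetic annotated single cells with Michaelis-Menten dropout.

    Each cell is drawn from one cell type (types cycle so every type is
    populated), its expression is the type's profile column with mild
    log-normal cell-to-cell jitter, and every entry is then zeroed
    independently with probability 1 - x / (K_M + x) for that gene's
    Michaelis constant.  Returns the cell matrix and a cell -> type
    annotation Series, the fixture for validating dropout correction.
    """
    import pandas as pd

    km = np.asarray(km, dtype=float)
    if km.size != profile.n_genes or np.any(km < 0):
        raise ValidationError("km must be non-negative with one value per gene")
    if n_cells < profile.n_columns:
        raise ValidationError("need at least one cell per type")
    rng = np.random.default_rng(seed)
    k = profile.n_columns
    labels = [profile.column_ids[i % k] for i in range(n_cells)]
    X = np.empty((profile.n_genes, n_cells))
    for j, lab in enumerate(labels):
        col = profile.values[:, profile.column_ids.index(lab)]
        x = col * rng.lognormal(mean=0.0, sigma=cell_jitter, size=col.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_drop = np.where(x > 0, 1.0 - x / (km + x), 1.0)
        X[:, j] = np.where(rng.random(x.size) < p_drop, 0.0, x)
    cell_ids = [f"cell_{j + 1}" for j in range(n_cells)]
    cells = ExpressionMatrix(X, list(profile.gene_ids), cell_ids, unit_tag="counts")
    ann = pd.Series(labels, index=cell_ids, name="cell_type")
    ann.index.name = "cell_id"
    return cells, ann


def perturb_reference(S: ExpressionMatrix, s_noise: float, seed: int = 0) -> ExpressionMatrix:
    """Reference-side noise: log2-Gaussian perturbation with sd s_noise * sigma_j.

    A reconstruction of degraded reference quality (a reference built
    from cells that imperfectly represent the bulk tissue), using the
    same log2(1+x) Gaussian scheme as the component matrices but with
    the full across-type sd scaled by ``s_noise``.
    """
    if s_noise < 0:
        raise ValidationError("s_noise must be non-negative")
    if s_noise == 0:
        return S.copy()
    sigma = log2_sd_across_types(S.values)
    rng = np.random.default_rng([_STREAM_REFERENCE, seed])
    V = perturb_log2(_to_log2(S.values), s_noise * sigma[:, None], rng)
    return S.with_values(_from_log2(V), unit_tag="model")
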