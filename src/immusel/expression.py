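"""Expression normalization and per-gene covariates.

Implements TMM (trimmed mean of M-values) library-size normalization, the
TMM-FPKM expression measure (CPM on TMM-adjusted library sizes divided by
per-sample effective gene length in kb), and the tissue-specificity index

    tau = sum_i (1 - x_i / x_max) / (N - 1)

computed on per-tissue mean TMM-FPKM values (0 = uniformly expressed,
1 = single-tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Expected counts with per-gene-per-sample effective lengths and a
    sample -> tissue map. ``true_profiles`` carries simulation truth when
    the matrix comes from the generator."""

    counts: pd.DataFrame  # genes x samples
    effective_lengths: pd.DataFrame  # genes x samples
    sample_tissue: dict[str, str]
    sample_sex: dict[str, str] = field(default_factory=dict)
    true_profiles: pd.DataFrame | None = None

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.sample_tissue)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ----------------------------------------------------------------- TMM
def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean one).

    Published procedure: the reference sample is the one whose
    upper-quartile (of counts scaled by library size) is closest to the
    mean upper-quartile; each sample's factor is the weighted mean of
    gene-wise log2 fold changes (M) after trimming the most extreme 30% of
    M and 5% of A values, with inverse-asymptotic-variance weights.
    All-zero samples get a missing factor and a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    ok = lib > 0
    if not ok.all():
        log.warning("all-zero samples excluded from TMM: %s",
                    list(lib.index[~ok]))
    x = counts.loc[:, ok].values.astype(float)
    libv = lib[ok].values
    # reference selection by upper quartile of scaled counts
    uq = np.array([
        np.quantile(x[:, j][x[:, j] > 0] / libv[j], 0.75) if (x[:, j] > 0).any()
        else 0.0
        for j in range(x.shape[1])
    ])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_j]
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_j:
            factors[j] = 1.0
            continue
        obs = x[:, j]
        use = (obs > 0) & (ref > 0)
        if use.sum() < 10:
            factors[j] = 1.0
            continue
        p_o = obs[use] / libv[j]
        p_r = ref[use] / libv[ref_j]
        M = np.log2(p_o / p_r)
        A = 0.5 * np.log2(p_o * p_r)
        w = (libv[j] - obs[use]) / (libv[j] * obs[use]) + (
            libv[ref_j] - ref[use]
        ) / (libv[ref_j] * ref[use])
        n = len(M)
        rank_m = M.argsort().argsort()
        rank_a = A.argsort().argsort()
        keep = (
            (rank_m >= np.floor(n * trim_m))
            & (rank_m < np.ceil(n * (1 - trim_m)))
            & (rank_a >= np.floor(n * trim_a))
            & (rank_a < np.ceil(n * (1 - trim_a)))
        )
        if not keep.any() or w[keep].sum() == 0:
            factors[j] = 1.0
            continue
        f = (M[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = pd.Series(np.nan, index=counts.columns, dtype=float)
    out[lib.index[ok]] = factors
    return out


def tmm_fpkm(
    counts: pd.DataFrame,
    factors: pd.Series,
    effective_lengths: pd.DataFrame,
) -> pd.DataFrame:
    """CPM on TMM-adjusted library sizes divided by effective length in kb.

    Effective lengths of zero are remapped to 0.01 before division."""
    lib = counts.sum(axis=0).astype(float)
    eff_lib = lib * factors
    cpm = counts / eff_lib * 1e6
    lengths = effective_lengths.reindex(
        index=counts.index, columns=counts.columns
    ).astype(float)
    lengths = lengths.mask(lengths <= 0, 0.01)
    return cpm / (lengths / 1e3)


# ----------------------------------------------------------------- tau
def tau(per_tissue_means) -> float:
    """Tissue-specificity index on nonnegative per-tissue mean expression;
    NaN when all tissue means are zero."""
    x = np.asarray(per_tissue_means, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression means must be nonnegative")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def summarize_expression(
    matrix: ExpressionMatrix,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene per-tissue mean TMM-FPKM, mean expression across tissues,
    and tau. Genes with zero expression across all tissues get NaN tau
    (and are excluded from covariate analyses downstream)."""
    if factors is None:
        factors = tmm_factors(matrix.counts)
    fpkm = tmm_fpkm(matrix.counts, factors, matrix.effective_lengths)
    tissues = sorted(set(matrix.sample_tissue.values()))
    tissue_means = pd.DataFrame(index=fpkm.index, columns=tissues, dtype=float)
    for t in tissues:
        cols = [s for s, tt in matrix.sample_tissue.items() if tt == t and s in fpkm]
        tissue_means[t] = fpkm[cols].mean(axis=1)
    out = tissue_means.copy()
    out["mean_expression"] = tissue_means.mean(axis=1)
    out["tau"] = [tau(row) for row in tissue_means.values]
    return out


# ------------------------------------------------------------- orthologs
def ortholog_filter(intersection_table: pd.DataFrame) -> pd.DataFrame:
    """One-to-one ortholog pairs: keep rows where both genes appear exactly
    once in the table and, if an ``orthology_class`` column is present, it
    is 'one2one'."""
    df = intersection_table
    a_counts = df["geneA"].value_counts()
    b_counts = df["geneB"].value_counts()
    keep = df["geneA"].map(a_counts).eq(1) & df["geneB"].map(b_counts).eq(1)
    if "orthology_class" in df.columns:
        keep &= df["orthology_class"].eq("one2one")
    return df.loc[keep].copy()


# ------------------------------------------------------------------ PCA QC
def expression_pca_qc(
    counts: pd.DataFrame,
    min_reads: int = 4,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-component sample embedding of log2(CPM + 1) for QC.

    Low-expression genes (fewer than ``min_reads`` reads in fewer than
    ``min_samples`` samples) are removed first. Returns the (n_samples, 2)
    embedding and the variance-explained ratios of all components."""
    if counts.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    expressed = (counts >= min_reads).sum(axis=1) >= min_samples
    sub = counts.loc[expressed]
    if sub.shape[0] < 2:
        raise ValueError("degenerate matrix after expression filter")
    lib = sub.sum(axis=0).astype(float)
    logcpm = np.log2(sub / lib * 1e6 + 1.0)
    X = logcpm.values.T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(1, X.shape[0] - 1)
    ratios = var / var.sum() if var.sum() > 0 else var
    emb = pd.DataFrame(
        (U * s)[:, :2], index=counts.columns, columns=["PC1", "PC2"]
    )
    return emb, ratios
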