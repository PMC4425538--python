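"""Cohort-level expression preprocessing.

The interaction model is fit on heavily preprocessed expression: quantile
normalization to the per-rank median distribution, log2 transform, double
centering of probe and sample means, residualization on external covariates
(e.g. genotype MDS components), removal of deviating arrays via the first
principal component of the sample correlation matrix, and finally removal of
the strongest expression principal components — skipping any component that is
itself under detectable genetic control, so that the correction does not eat
the eQTL signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "PcCorrectionReport",
    "quantile_normalize_median",
    "log2_center",
    "remove_covariates",
    "sample_qc_pc1",
    "pc_correct_skip_genetic",
]


@dataclass
class PcCorrectionReport:
    """Audit trail of the PC-correction step.

    ``removed_component_indices`` and ``skipped_genetic_indices`` partition the
    first ``n_components_requested`` components (0-based, strongest first).
    """

    n_components_requested: int
    removed_component_indices: list[int]
    skipped_genetic_indices: list[int]
    per_component_top_association_p: list[float]
    genetic_p_threshold: float

    def __post_init__(self) -> None:
        removed, skipped = set(self.removed_component_indices), set(self.skipped_genetic_indices)
        if removed & skipped:
            raise ValueError("a component cannot be both removed and skipped")
        if removed | skipped != set(range(self.n_components_requested)):
            raise ValueError("removed and skipped components must partition the requested set")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def quantile_normalize_median(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize every sample column to the per-rank median distribution.

    After the transform every column has the same sorted value vector: the
    median, across samples, of each column's k-th order statistic.  Within-
    column rank order is preserved; ties receive the average of the reference
    values at the tied ranks (so the map is exactly idempotent on tie-free
    input, and moves tied values by at most their within-tie spread on a
    second application).
    """
    x = raw.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values are not supported by quantile normalization")
    n_probes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.median(np.sort(x, axis=0), axis=1)  # per-rank median
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        ranks = stats.rankdata(col, method="average")  # 1-based, ties averaged
        # linear interpolation between reference order statistics handles
        # half-integer average ranks from ties
        out[:, j] = np.interp(ranks, np.arange(1, n_probes + 1), reference)
    values = pd.DataFrame(out, index=raw.values.index, columns=raw.values.columns)
    return raw.with_values(values, "quantile_normalize_median")


def log2_center(x: ExpressionMatrix, tol: float = 1e-8, max_iter: int = 100) -> ExpressionMatrix:
    """log2-transform, then center probe and sample means to zero.

    Centering alternates row- and column-mean subtraction until both maxima of
    absolute means fall below ``tol`` (double centering converges in one sweep
    for exact arithmetic; the loop guards floating-point drift).
    """
    vals = x.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive expression value for probe {x.probe_ids[i]!r}, "
            f"sample {x.sample_ids[j]!r}; log2 requires positive values"
        )
    vals = np.log2(vals)
    for _ in range(max_iter):
        vals = vals - vals.mean(axis=1, keepdims=True)
        vals = vals - vals.mean(axis=0, keepdims=True)
        if (
            np.abs(vals.mean(axis=1)).max() < tol
            and np.abs(vals.mean(axis=0)).max() < tol
        ):
            break
    values = pd.DataFrame(vals, index=x.values.index, columns=x.values.columns)
    return x.with_values(values, "log2_center")


def center_only(x: ExpressionMatrix, tol: float = 1e-8, max_iter: int = 100) -> ExpressionMatrix:
    """Double-center probe and sample means without the log2 transform.

    Used for data already on a log-like scale (e.g. simulated expression).
    """
    vals = x.values.to_numpy(dtype=float).copy()
    for _ in range(max_iter):
        vals = vals - vals.mean(axis=1, keepdims=True)
        vals = vals - vals.mean(axis=0, keepdims=True)
        if np.abs(vals.mean(axis=1)).max() < tol and np.abs(vals.mean(axis=0)).max() < tol:
            break
    values = pd.DataFrame(vals, index=x.values.index, columns=x.values.columns)
    return x.with_values(values, "center")


def remove_covariates(x: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Residualize every probe on an intercept plus the covariate columns.

    ``covariates`` is samples x k, indexed by sample identifier and aligned to
    the expression columns.  Raises on rank-deficient designs.
    """
    cov = covariates.loc[x.sample_ids].to_numpy(dtype=float)
    n, k = cov.shape
    if k >= n:
        raise ValueError("need fewer covariates than samples")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "covariate matrix is rank-deficient; remove collinear or constant columns"
        )
    y = x.values.to_numpy(dtype=float).T  # samples x probes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = (y - design @ beta).T
    values = pd.DataFrame(resid, index=x.values.index, columns=x.values.columns)
    return x.with_values(values, f"remove_covariates[k={k}]")


def _sample_correlation_pcs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the sample x sample Pearson correlation matrix.

    Returns (eigenvalues, eigenvectors) sorted by decreasing eigenvalue;
    eigenvector k holds the per-sample coordinates of component k.
    """
    corr = np.corrcoef(x.T)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def sample_qc_pc1(
    x: ExpressionMatrix, threshold: float = 0.9
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove deviating arrays using PC1 of the sample correlation matrix.

    The first eigenvector of the sample correlation matrix defines a reference
    expression profile (the expression matrix projected onto it); samples whose
    Pearson correlation with that profile falls below ``threshold`` are
    dropped.  The eigenvector sign is oriented so the median correlation is
    positive.  Arrays of poor quality deviate from the shared profile and fall
    below the cut.
    """
    if x.n_samples < 3:
        raise ValueError("sample QC needs at least 3 samples")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    vals = x.values.to_numpy(dtype=float)
    _, eigvecs = _sample_correlation_pcs(vals)
    pc1 = eigvecs[:, 0]
    reference = vals @ pc1  # probe-space reference profile
    # Pearson correlation of each sample column with the reference profile
    ref_c = reference - reference.mean()
    cols = vals - vals.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(cols, axis=0) * np.linalg.norm(ref_c)
    corr = (cols.T @ ref_c) / denom
    if np.median(corr) < 0:
        corr = -corr
    keep = corr >= threshold
    removed = [s for s, k in zip(x.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError("sample QC removed every sample; check the input matrix")
    kept = x.subset_samples([s for s, k in zip(x.sample_ids, keep) if k])
    kept.transform_log.append(f"sample_qc_pc1[threshold={threshold},removed={len(removed)}]")
    return kept, removed


def _orient_components(vals: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pin eigenvector signs: loading correlation with mean profile >= 0."""
    mean_profile = vals.mean(axis=1)
    mean_c = mean_profile - mean_profile.mean()
    for k in range(scores.shape[1]):
        loading = vals @ scores[:, k]
        if np.dot(loading - loading.mean(), mean_c) < 0:
            scores[:, k] = -scores[:, k]
    return scores


def pc_correct_skip_genetic(
    x: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    n_components: int = 40,
    genetic_p_threshold: float = 5e-8,
) -> tuple[ExpressionMatrix, PcCorrectionReport]:
    """Remove the strongest expression PCs, keeping genetically driven ones.

    The first ``n_components`` components of the sample correlation matrix are
    tested for genetic control: each component's per-sample score is regressed
    on every SNP dosage, and a component whose minimum association p-value
    falls below ``genetic_p_threshold`` is flagged genetic and *not* removed.
    The remaining components are removed jointly by residualizing every probe
    on their scores.
    """
    vals = x.values.to_numpy(dtype=float)
    max_rank = min(x.n_probes, x.n_samples) - 1
    if n_components >= max_rank:
        raise ValueError(
            f"n_components={n_components} must be below the matrix rank bound {max_rank}"
        )
    eigvals, eigvecs = _sample_correlation_pcs(vals)
    scores = eigvecs[:, :n_components].copy()
    scores = scores / scores.std(axis=0, ddof=0, keepdims=True)  # unit-variance scores
    scores = _orient_components(vals, scores)

    geno = genotypes.subset_samples(x.sample_ids).values.to_numpy(dtype=float)
    n = x.n_samples
    # simple-regression p-value via the correlation -> t transform, all SNPs at once
    g_c = geno - np.nanmean(geno, axis=1, keepdims=True)
    g_c = np.nan_to_num(g_c)  # missing dosages contribute zero (mean imputation)
    g_norm = np.linalg.norm(g_c, axis=1)
    top_p: list[float] = []
    for k in range(n_components):
        s = scores[:, k]
        s_c = s - s.mean()
        denom = g_norm * np.linalg.norm(s_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (g_c @ s_c) / denom, 0.0)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        top_p.append(float(p.min()))

    skipped = [k for k, p in enumerate(top_p) if p < genetic_p_threshold]
    removed = [k for k in range(n_components) if k not in skipped]

    if removed:
        design = np.column_stack([np.ones(n), scores[:, removed]])
        beta, *_ = np.linalg.lstsq(design, vals.T, rcond=None)
        resid = (vals.T - design @ beta).T
    else:
        resid = vals - vals.mean(axis=1, keepdims=True)
    values = pd.DataFrame(resid, index=x.values.index, columns=x.values.columns)
    report = PcCorrectionReport(
        n_components_requested=n_components,
        removed_component_indices=removed,
        skipped_genetic_indices=skipped,
        per_component_top_association_p=top_p,
        genetic_p_threshold=genetic_p_threshold,
    )
    corrected = x.with_values(
        values, f"pc_correct[removed={len(removed)},skipped={len(skipped)}]"
    )
    return corrected, report
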