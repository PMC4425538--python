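"""Per-cohort genotype-by-proxy interaction models for candidate cis-eQTLs.

For each candidate SNP-probe pair the model

    Y ~ I + b1*G + b2*P + b3*(G x P) + e

is fit by ordinary least squares, where Y is PC-corrected expression, G the
additive genotype dosage, and P the standardized cell-type proxy.  The
interaction coefficient b3 captures how the eQTL effect scales with the
proxied cell-type proportion; its Z-score (b3 / SE) is the per-cohort
statistic that enters the meta-analysis.  Classical OLS standard errors are
the default; heteroscedasticity-consistent (sandwich) standard errors are
available as a sensitivity option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix
from .proxy import ProxyPhenotype

logger = logging.getLogger("ctqtl")

__all__ = [
    "InteractionResult",
    "SkipRecord",
    "fit_interaction",
    "fit_main_effect",
    "robust_se3",
    "cohort_scan",
]

_N_PARAMS = 4  # intercept, genotype, proxy, interaction


@dataclass
class InteractionResult:
    """OLS fit of the interaction model for one (SNP, probe, cohort)."""

    snp_id: str
    probe_id: str
    cohort_id: str
    n_samples: int
    beta1: float
    beta2: float
    beta3: float
    se3_classical: float
    se3_robust: float | None
    z3: float
    se_mode: str  # "classical" | "robust"


@dataclass
class SkipRecord:
    """Why a candidate pair was untestable in a cohort."""

    snp_id: str
    probe_id: str
    cohort_id: str
    reason: str  # machine-readable reason code


def _design(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(g)), g, p, g * p])


def fit_interaction(
    y: np.ndarray,
    g: np.ndarray,
    p: np.ndarray,
    snp_id: str = "",
    probe_id: str = "",
    cohort_id: str = "",
) -> InteractionResult:
    """OLS fit of Y ~ 1 + G + P + G:P with classical standard errors.

    Samples with a missing dosage must already be excluded (``cohort_scan``
    does this pairwise).  Raises on constant genotype or proxy, or on an
    otherwise collinear design.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(y)
    if not (len(g) == len(p) == n):
        raise ValueError("y, g and p must have equal lengths")
    if n < _N_PARAMS + 2:
        raise ValueError(f"need at least {_N_PARAMS + 2} samples, got {n}")
    if np.ptp(g) == 0:
        raise ValueError("genotype vector is constant")
    if np.ptp(p) == 0:
        raise ValueError("proxy vector is constant")

    x = _design(g, p)
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"collinear design for pair ({snp_id!r}, {probe_id!r}): {exc}"
        ) from exc
    cond = np.linalg.cond(xtx)
    if cond > 1e12:
        raise ValueError(
            f"collinear design for pair ({snp_id!r}, {probe_id!r}): condition number {cond:.3g}"
        )
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - _N_PARAMS)
    se3 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    z3 = float(beta[3] / se3) if se3 > 0 else 0.0
    return InteractionResult(
        snp_id=snp_id,
        probe_id=probe_id,
        cohort_id=cohort_id,
        n_samples=n,
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta3=float(beta[3]),
        se3_classical=se3,
        se3_robust=None,
        z3=z3,
        se_mode="classical",
    )


def fit_main_effect(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of the reduced single-marker model Y ~ I + b1*G + e.

    Returns (beta1, se1, z1).  This is the generic-eQTL model under which
    candidate pairs are discovered before any interaction testing.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(g) == 0:
        raise ValueError("genotype vector is constant")
    x = np.column_stack([np.ones(n), g])
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    se1 = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return float(beta[1]), se1, float(beta[1] / se1)


def robust_se3(
    y: np.ndarray,
    g: np.ndarray,
    p: np.ndarray,
    fitted: InteractionResult,
    estimator: str = "HC0",
) -> float:
    """Sandwich (heteroscedasticity-consistent) SE of the interaction term.

    Computes (X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1 with w_i = 1 for HC0 or
    w_i = 1/(1 - h_ii)^2 for HC3, and updates ``fitted.se3_robust``.
    """
    if estimator not in ("HC0", "HC3"):
        raise ValueError("estimator must be 'HC0' or 'HC3'")
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    x = _design(g, p)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    leverage = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
    if estimator == "HC3":
        if np.any(leverage >= 1 - 1e-12):
            raise ValueError("leverage of 1 encountered (saturated observation)")
        w = resid**2 / (1 - leverage) ** 2
    else:
        w = resid**2
    meat = (x * w[:, None]).T @ x
    cov = xtx_inv @ meat @ xtx_inv
    se = float(np.sqrt(cov[3, 3]))
    fitted.se3_robust = se
    return se


def cohort_scan(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    proxy: ProxyPhenotype,
    pairs: list[tuple[str, str]],
    cohort_id: str = "",
    min_samples: int = 30,
    min_minor_group: int = 3,
    se_mode: str = "classical",
) -> tuple[list[InteractionResult], list[SkipRecord]]:
    """Fit the interaction model for every testable candidate pair.

    ``expression`` must already be PC-corrected.  Pairs are processed in list
    order; untestable pairs are recorded in the skip log with a reason code
    (missing_snp, missing_probe, monomorphic_snp, minor_group, low_n,
    constant_proxy, collinear).  When ``se_mode`` is "robust", HC3 sandwich
    standard errors replace the classical ones in z3.
    """
    if not pairs:
        raise ValueError("empty candidate pair list")
    if se_mode not in ("classical", "robust"):
        raise ValueError("se_mode must be 'classical' or 'robust'")
    samples = [s for s in expression.sample_ids if s in set(genotypes.sample_ids)]
    samples = [s for s in samples if s in proxy.sample_scores.index]
    expr_vals = expression.values.loc[:, samples]
    geno_vals = genotypes.values.loc[:, samples]
    p_all = proxy.sample_scores.loc[samples].to_numpy(dtype=float)

    probe_index = {pid: i for i, pid in enumerate(expr_vals.index)}
    snp_index = {sid: i for i, sid in enumerate(geno_vals.index)}
    expr_np = expr_vals.to_numpy(dtype=float)
    geno_np = geno_vals.to_numpy(dtype=float)

    results: list[InteractionResult] = []
    skips: list[SkipRecord] = []
    for snp_id, probe_id in pairs:
        if snp_id not in snp_index:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "missing_snp"))
            continue
        if probe_id not in probe_index:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "missing_probe"))
            continue
        g = geno_np[snp_index[snp_id]]
        y = expr_np[probe_index[probe_id]]
        mask = ~np.isnan(g)
        g_use, y_use, p_use = g[mask], y[mask], p_all[mask]
        n = int(mask.sum())
        if n < max(min_samples, _N_PARAMS + 2):
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "low_n"))
            continue
        if np.ptp(g_use) == 0:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "monomorphic_snp"))
            continue
        hard = np.round(g_use).astype(int)
        counts = np.bincount(np.clip(hard, 0, 2), minlength=3)
        present = counts[counts > 0]
        if len(present) > 1 and sorted(present)[:-1][-1] < min_minor_group:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "minor_group"))
            continue
        if np.ptp(p_use) == 0:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "constant_proxy"))
            continue
        try:
            res = fit_interaction(y_use, g_use, p_use, snp_id, probe_id, cohort_id)
        except ValueError:
            skips.append(SkipRecord(snp_id, probe_id, cohort_id, "collinear"))
            continue
        if se_mode == "robust":
            se = robust_se3(y_use, g_use, p_use, res, estimator="HC3")
            res.z3 = res.beta3 / se
            res.se_mode = "robust"
        results.append(res)
    if skips:
        logger.info(
            "cohort %s: %d pairs tested, %d skipped", cohort_id, len(results), len(skips)
        )
    return results, skips


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    """Tabulate interaction results in the interchange column order."""
    return pd.DataFrame(
        [
            {
                "cohort_id": r.cohort_id,
                "snp_id": r.snp_id,
                "probe_id": r.probe_id,
                "n": r.n_samples,
                "beta1": r.beta1,
                "beta2": r.beta2,
                "beta3": r.beta3,
                "se3": r.se3_robust if r.se_mode == "robust" else r.se3_classical,
                "z3": r.z3,
                "se_mode": r.se_mode,
            }
            for r in results
        ]
    )
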