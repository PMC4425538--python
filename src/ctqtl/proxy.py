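"""Proxy phenotype for an unmeasured cell-type percentage.

A training cohort with measured cell counts is used once, to pick marker
probes whose expression correlates positively with the measured percentage
(Spearman).  In every cohort — including those without counts — the proxy is
then the first principal component of the marker-probe correlation matrix,
oriented so that it tracks mean marker expression, and standardized.  Because
the markers were chosen for positive correlation with the cell type, the
oriented PC1 is an increasing stand-in for its percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "MarkerRule",
    "MarkerSet",
    "ProxyPhenotype",
    "select_markers",
    "build_proxy",
    "proxy_stability",
]


@dataclass(frozen=True)
class MarkerRule:
    """Marker selection rule: a correlation threshold or a top-N cut.

    Exactly one of ``threshold`` (keep probes with Spearman R strictly above
    it) and ``top_n`` (keep the N best-correlated probes) must be set.
    """

    threshold: float | None = None
    top_n: int | None = None

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.top_n is None):
            raise ValueError("set exactly one of threshold and top_n")
        if self.top_n is not None and self.top_n <= 0:
            raise ValueError("top_n must be positive")

    def describe(self) -> str:
        if self.threshold is not None:
            return f"spearman>{self.threshold}"
        return f"top{self.top_n}"


@dataclass
class MarkerSet:
    """Marker probes with their training-cohort Spearman correlations.

    Probes are ordered by descending correlation (ties broken by identifier).
    """

    probe_ids: list[str]
    training_correlations: pd.Series
    selection_rule: str

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("marker set is empty")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "training_correlation": self.training_correlations.loc[self.probe_ids].to_numpy(),
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t")
        corr = pd.Series(df["training_correlation"].to_numpy(), index=df["probe_id"])
        return cls(list(df["probe_id"]), corr, selection_rule="loaded")


@dataclass
class ProxyPhenotype:
    """Standardized per-sample proxy scores for a cell-type percentage."""

    sample_scores: pd.Series
    marker_set: MarkerSet
    orientation_sign: int
    explained_variance_fraction: float

    def to_tsv(self, path: str | Path) -> None:
        self.sample_scores.rename("score").rename_axis("sample_id").to_csv(
            path, sep="\t", float_format="%.10g"
        )


def _spearman_probes_vs_counts(expr: ExpressionMatrix, counts: pd.Series) -> pd.Series:
    """Spearman correlation of every probe with the count vector (vectorized)."""
    x = expr.values.to_numpy(dtype=float)
    probe_ranks = np.apply_along_axis(stats.rankdata, 1, x)
    count_ranks = stats.rankdata(counts.to_numpy(dtype=float))
    pr = probe_ranks - probe_ranks.mean(axis=1, keepdims=True)
    cr = count_ranks - count_ranks.mean()
    denom = np.linalg.norm(pr, axis=1) * np.linalg.norm(cr)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (pr @ cr) / denom, np.nan)
    return pd.Series(rho, index=expr.values.index)


def select_markers(
    training_expr: ExpressionMatrix,
    counts: pd.Series,
    rule: MarkerRule,
    min_samples: int = 30,
) -> MarkerSet:
    """Pick marker probes by Spearman correlation with measured percentages.

    ``training_expr`` must be quantile-normalized / log-scale expression that
    has *not* been PC-corrected (PC correction strips the very correlation
    structure being exploited).  ``counts`` is a per-sample percentage series;
    samples are intersected with the expression columns.
    """
    shared = [s for s in training_expr.sample_ids if s in counts.index]
    if len(shared) < min_samples:
        raise ValueError(
            f"only {len(shared)} samples with cell counts; need >= {min_samples}"
        )
    expr = training_expr.subset_samples(shared)
    rho = _spearman_probes_vs_counts(expr, counts.loc[shared]).dropna()
    ordered = rho.sort_index().sort_values(ascending=False, kind="stable")
    if rule.threshold is not None:
        chosen = ordered[ordered > rule.threshold]
        if chosen.empty:
            raise ValueError(
                f"no probe exceeds Spearman threshold {rule.threshold}; "
                "lower the threshold or use a top-N rule"
            )
    else:
        chosen = ordered.iloc[: rule.top_n]
    return MarkerSet(
        probe_ids=list(chosen.index),
        training_correlations=chosen,
        selection_rule=rule.describe(),
    )


def build_proxy(cohort_expr: ExpressionMatrix, markers: MarkerSet) -> ProxyPhenotype:
    """PC1 of the marker-probe correlation matrix as a proxy phenotype.

    Marker probes are standardized across samples; the leading eigenvector of
    their Pearson correlation matrix provides probe loadings, and each
    sample's score is its standardized marker expression projected onto those
    loadings.  The sign is oriented so scores correlate positively with mean
    marker expression, and scores are standardized to mean 0, variance 1.
    """
    present = [p for p in markers.probe_ids if p in set(cohort_expr.probe_ids)]
    absent = sorted(set(markers.probe_ids) - set(present))
    if absent:
        warnings.warn(
            f"{len(absent)} marker probes absent from cohort and dropped: {absent[:5]}...",
            stacklevel=2,
        )
    x = cohort_expr.values.loc[present].to_numpy(dtype=float)
    sds = x.std(axis=1, ddof=0)
    if (sds == 0).any():
        dropped = [p for p, s in zip(present, sds) if s == 0]
        warnings.warn(f"dropping zero-variance marker probes: {dropped}", stacklevel=2)
        present = [p for p, s in zip(present, sds) if s > 0]
        x = cohort_expr.values.loc[present].to_numpy(dtype=float)
    if len(present) < 2:
        raise ValueError("fewer than 2 usable marker probes present in cohort")

    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    corr = np.corrcoef(z)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    leading = eigvals[-1]
    scores = loadings @ z

    mean_marker = x.mean(axis=0)
    sign = 1
    if np.corrcoef(scores, mean_marker)[0, 1] < 0:
        sign = -1
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    return ProxyPhenotype(
        sample_scores=pd.Series(scores, index=cohort_expr.sample_ids, name="score"),
        marker_set=MarkerSet(
            probe_ids=present,
            training_correlations=markers.training_correlations.reindex(present),
            selection_rule=markers.selection_rule,
        ),
        orientation_sign=sign,
        explained_variance_fraction=float(leading / len(present)),
    )


def proxy_stability(
    training_expr: ExpressionMatrix,
    counts: pd.Series,
    candidate_pool_size: int,
    subset_sizes: list[int],
    n_repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of the proxy under random marker subsets.

    From the ``candidate_pool_size`` probes best correlated with the measured
    percentage, repeatedly draw subsets of each requested size, rebuild the
    proxy, and record its Spearman correlation with the measured counts.
    Returns one row per subset size with the mean and SD across repeats.
    """
    pool = select_markers(
        training_expr, counts, MarkerRule(top_n=candidate_pool_size)
    )
    if any(size > candidate_pool_size for size in subset_sizes):
        raise ValueError("subset size exceeds the candidate pool")
    shared = [s for s in training_expr.sample_ids if s in counts.index]
    truth = counts.loc[shared].to_numpy(dtype=float)
    rng = np.random.default_rng([seed, 101])
    rows = []
    for size in subset_sizes:
        rhos = []
        for _ in range(n_repeats):
            chosen = sorted(rng.choice(pool.probe_ids, size=size, replace=False))
            subset = MarkerSet(
                probe_ids=chosen,
                training_correlations=pool.training_correlations.reindex(chosen),
                selection_rule=f"stability_subset[{size}]",
            )
            phenotype = build_proxy(training_expr, subset)
            rho = stats.spearmanr(
                phenotype.sample_scores.loc[shared].to_numpy(), truth
            ).statistic
            rhos.append(rho)
        rows.append(
            {
                "subset_size": size,
                "mean_correlation": float(np.mean(rhos)),
                "sd_correlation": float(np.std(rhos, ddof=0)),
                "n_repeats": n_repeats,
            }
        )
    return pd.DataFrame(rows)
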