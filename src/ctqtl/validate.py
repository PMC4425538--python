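"""Replication of mediation calls in purified-cell-type expression data.

If an eQTL is truly mediated by a lineage, its effect should be strongest in
expression measured on purified cells of that lineage.  The per-pair effect
size in a purified dataset is the Pearson correlation between dosage and
expression; mediated and generic groups are compared on absolute effect sizes
with a one-tailed rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ReplicationEffect", "effect_size", "group_compare"]


@dataclass
class ReplicationEffect:
    """Dosage-expression correlation for one pair in one purified dataset."""

    snp_id: str
    probe_id: str
    dataset_id: str
    r: float
    n: int


def effect_size(
    g: np.ndarray,
    y: np.ndarray,
    snp_id: str = "",
    probe_id: str = "",
    dataset_id: str = "",
) -> ReplicationEffect:
    """Pearson correlation between genotype dosage and expression."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(g) != len(y):
        raise ValueError("dosage and expression vectors must have equal lengths")
    if len(g) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector; correlation undefined")
    r = float(np.corrcoef(g, y)[0, 1])
    return ReplicationEffect(snp_id=snp_id, probe_id=probe_id, dataset_id=dataset_id, r=r, n=len(g))


def group_compare(
    effects_group_a: list[float],
    effects_group_b: list[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Rank-sum comparison of two groups of absolute effect sizes.

    Tests whether group A's |r| values are stochastically larger than group
    B's (one-tailed by default).  Uses exact enumeration when both groups have
    at most 10 values and the pooled values are tie-free; otherwise the normal
    approximation with tie correction.  Returns (U statistic, p-value).
    """
    a = np.abs(np.asarray(effects_group_a, dtype=float))
    b = np.abs(np.asarray(effects_group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)
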