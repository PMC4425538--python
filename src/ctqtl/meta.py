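"""Sample-size-weighted Z-score meta-analysis of interaction statistics.

Per-cohort interaction Z-scores are combined as

    Z_meta = sum_i w_i * z_i / sqrt(sum_i w_i^2),   w_i = sqrt(n_i)

which preserves the direction of effect.  A significant positive Z_meta means
the eQTL strengthens with the proxied (myeloid) proportion; a significant
negative Z_meta means it strengthens as the complementary lymphoid proportion
rises, because the two fractions are anti-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import InteractionResult

__all__ = [
    "MetaResult",
    "weighted_z",
    "z_to_p_two_tailed",
    "p_to_z_two_tailed",
    "classify_direction",
    "meta_analyze",
    "meta_to_frame",
]

MYELOID = "myeloid-mediated"
LYMPHOID = "lymphoid-mediated"
GENERIC = "generic"


@dataclass
class MetaResult:
    """Combined interaction statistic for one SNP-probe pair."""

    snp_id: str
    probe_id: str
    cohort_ids: list[str]
    cohort_z3: list[float]
    cohort_n: list[int]
    z_meta: float
    p_meta: float
    n_total: int
    significant: bool = False
    direction: str = GENERIC


def weighted_z(z: list[float], n: list[int]) -> float:
    """Combine Z-scores with sqrt(sample size) weights."""
    if len(z) == 0:
        raise ValueError("cannot meta-analyze an empty set of Z-scores")
    if len(z) != len(n):
        raise ValueError("z and n must have equal lengths")
    n_arr = np.asarray(n, dtype=float)
    if (n_arr <= 0).any():
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n_arr)
    return float((w * np.asarray(z, dtype=float)).sum() / np.sqrt((w**2).sum()))


def z_to_p_two_tailed(z: float) -> float:
    """Two-tailed p-value of a standard-normal Z: p = 2 * Phi(-|z|)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * stats.norm.sf(abs(z)))


def p_to_z_two_tailed(p: float) -> float:
    """|Z| whose two-tailed p equals ``p`` (inverse of ``z_to_p_two_tailed``)."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return float(abs(stats.norm.isf(p / 2.0)))


def classify_direction(z_meta: float, significant: bool) -> str:
    """Label a pair by the sign of its significant interaction, else generic."""
    if significant and z_meta > 0:
        return MYELOID
    if significant and z_meta < 0:
        return LYMPHOID
    return GENERIC


def meta_analyze(
    results: list[InteractionResult], min_cohorts: int = 2
) -> list[MetaResult]:
    """Group per-cohort results by pair and combine their interaction Z-scores.

    Pairs testable in fewer than ``min_cohorts`` cohorts are dropped.  Output
    order follows first appearance in the input, so a scan in pair-list order
    yields meta results in pair-list order.
    """
    if min_cohorts < 1:
        raise ValueError("min_cohorts must be >= 1")
    grouped: dict[tuple[str, str], list[InteractionResult]] = {}
    for r in results:
        grouped.setdefault((r.snp_id, r.probe_id), []).append(r)
    out: list[MetaResult] = []
    for (snp_id, probe_id), group in grouped.items():
        if len(group) < min_cohorts:
            continue
        z = [r.z3 for r in group]
        n = [r.n_samples for r in group]
        zm = weighted_z(z, n)
        out.append(
            MetaResult(
                snp_id=snp_id,
                probe_id=probe_id,
                cohort_ids=[r.cohort_id for r in group],
                cohort_z3=z,
                cohort_n=n,
                z_meta=zm,
                p_meta=z_to_p_two_tailed(zm),
                n_total=int(sum(n)),
            )
        )
    return out


def meta_to_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Tabulate meta results (per-cohort Z-scores semicolon-joined)."""
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "probe_id": r.probe_id,
                "z_meta": r.z_meta,
                "p_meta": r.p_meta,
                "direction": r.direction,
                "significant": r.significant,
                "n_total": r.n_total,
                "cohort_z3": ";".join(f"{z:.6g}" for z in r.cohort_z3),
            }
            for r in results
        ]
    )
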