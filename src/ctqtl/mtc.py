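"""Permutation-calibrated multiple-testing correction.

Because both expression (co-expression) and genotypes (LD) are internally
correlated, a Bonferroni correction over the nominal number of candidate
pairs is too strict.  The effective number of independent tests is instead
estimated from permutations: genotype sample labels are shuffled within each
cohort (breaking genotype-expression and genotype-proxy linkage while
preserving the expression-proxy structure), the full interaction scan and
meta-analysis is re-run, and the minimum meta p-value per permutation is
recorded.  The estimator is

    n_effective = 0.5 / mean(min p over permutations)

implemented exactly as printed in the source method.  (For M truly
independent uniform p-values the mean minimum is 1/(M+1), so the estimator
returns roughly M/2 — about half the nominal count — which matches the
original report's observation.)  The FDR is then the expected number of
uniform p-values below a threshold, t * n_effective, divided by the observed
count, maximized over observed thresholds subject to FDR <= the level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, GenotypeMatrix
from .interaction import cohort_scan
from .meta import meta_analyze, p_to_z_two_tailed
from .proxy import ProxyPhenotype

__all__ = [
    "EffectiveTests",
    "FdrCall",
    "effective_tests",
    "permutation_min_p",
    "fdr_calls",
]


@dataclass
class EffectiveTests:
    """Permutation-based effective number of independent tests."""

    mean_min_p: float
    n_effective: float
    n_nominal_tests: int


@dataclass
class FdrCall:
    """The nominal threshold realizing the requested FDR level."""

    nominal_p_threshold: float
    z_threshold: float
    fdr_level: float
    n_significant: int


def effective_tests(
    min_p_per_permutation: list[float], n_nominal_tests: int = 0
) -> EffectiveTests:
    """n_effective = 0.5 / mean(minimum p per permutation)."""
    arr = np.asarray(min_p_per_permutation, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one permutation minimum p-value")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("permutation p-values must lie in (0, 1]")
    mean_min_p = float(arr.mean())
    n_eff = 0.5 / mean_min_p
    if n_nominal_tests and n_eff > n_nominal_tests:
        import warnings

        warnings.warn(
            f"effective tests ({n_eff:.1f}) exceeds nominal tests ({n_nominal_tests})",
            stacklevel=2,
        )
    return EffectiveTests(
        mean_min_p=mean_min_p, n_effective=n_eff, n_nominal_tests=n_nominal_tests
    )


def permutation_min_p(
    cohorts: list[tuple[ExpressionMatrix, GenotypeMatrix, ProxyPhenotype, str]],
    pairs: list[tuple[str, str]],
    n_permutations: int = 100,
    seed: int = 0,
    min_cohorts: int = 2,
    **scan_kwargs,
) -> list[float]:
    """Minimum meta p-value under within-cohort genotype label permutation.

    Each permutation shuffles the genotype matrix's sample assignment within
    every cohort, reruns ``cohort_scan`` and ``meta_analyze`` on the permuted
    data, and records the smallest meta p across pairs.
    """
    if n_permutations < 10:
        raise ValueError("use at least 10 permutations")
    rng = np.random.default_rng([seed, 997])
    minima: list[float] = []
    for _ in range(n_permutations):
        all_results = []
        for expression, genotypes, proxy, cohort_id in cohorts:
            perm = rng.permutation(genotypes.n_samples)
            shuffled = genotypes.values.iloc[:, perm].copy()
            shuffled.columns = genotypes.values.columns
            geno_perm = GenotypeMatrix(values=shuffled, snp_info=genotypes.snp_info)
            results, _ = cohort_scan(
                expression, geno_perm, proxy, pairs, cohort_id=cohort_id, **scan_kwargs
            )
            all_results.extend(results)
        metas = meta_analyze(all_results, min_cohorts=min_cohorts)
        if not metas:
            raise ValueError("no testable pairs in permutation scan")
        minima.append(min(m.p_meta for m in metas))
    return minima


def fdr_calls(
    p_meta: list[float], eff: EffectiveTests, fdr_level: float = 0.05
) -> tuple[FdrCall, np.ndarray]:
    """Flag significant pairs at the permutation-calibrated FDR level.

    Candidate thresholds are the observed p-values; at threshold t the
    expected (uniform-null) count is t * n_effective and FDR(t) = expected /
    observed.  The call threshold is the largest observed t with FDR(t) <=
    ``fdr_level``; if none qualifies the threshold is 0 and nothing is called.
    Returns the call summary and a per-pair boolean flag array in input order.
    """
    p = np.asarray(p_meta, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must be in (0, 1)")
    order = np.sort(p)
    observed = np.arange(1, p.size + 1)
    expected = order * eff.n_effective
    fdr = expected / observed
    ok = fdr <= fdr_level
    if not ok.any():
        import warnings

        warnings.warn("no threshold achieves the requested FDR level", stacklevel=2)
        call = FdrCall(
            nominal_p_threshold=0.0,
            z_threshold=float("inf"),
            fdr_level=fdr_level,
            n_significant=0,
        )
        return call, np.zeros(p.size, dtype=bool)
    threshold = float(order[ok][-1])
    flags = p <= threshold
    call = FdrCall(
        nominal_p_threshold=threshold,
        z_threshold=p_to_z_two_tailed(threshold),
        fdr_level=fdr_level,
        n_significant=int(flags.sum()),
    )
    return call, flags
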