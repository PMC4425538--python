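"""GWAS-trait enrichment of cell-type-mediated cis-eQTLs.

For each trait, genome-wide-significant SNPs are LD-pruned (greedy, most
significant first, discarding SNPs in r² >= threshold with a kept SNP), the
pruned list is intersected with the tested eQTL SNPs, and the fraction of
those that are cell-type-mediated is compared with the background fraction by
a one-tailed exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger("ctqtl")

__all__ = [
    "EnrichmentResult",
    "ld_prune",
    "trait_enrichment",
    "r2_from_genotypes",
    "gwas_enrichment",
]

R2Lookup = Callable[[str, str], float] | Mapping[frozenset, float]


@dataclass
class EnrichmentResult:
    """One trait's enrichment of mediated eQTLs among its pruned SNPs."""

    trait: str
    n_pruned_eqtl_snps: int
    n_mediated: int
    background_proportion: float
    binomial_p_one_tailed: float

    @property
    def mediated_percent(self) -> float:
        return 100.0 * self.n_mediated / self.n_pruned_eqtl_snps


def _lookup_r2(r2: R2Lookup, a: str, b: str, missing: list[int]) -> float:
    if callable(r2):
        value = r2(a, b)
    else:
        value = r2.get(frozenset((a, b)))
    if value is None:
        missing[0] += 1
        return 0.0
    return float(value)


def ld_prune(
    snp_p: Mapping[str, float] | pd.Series,
    r2: R2Lookup,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Greedy LD pruning of an association-ranked SNP list.

    Restrict to SNPs with p < ``p_threshold``; repeatedly keep the most
    significant remaining SNP (ties broken by identifier) and discard every
    remaining SNP with r² >= ``r2_threshold`` to it.  Missing r² entries are
    treated as 0 (independent) and counted in the log.
    """
    if isinstance(snp_p, pd.Series):
        snp_p = snp_p.to_dict()
    candidates = sorted(
        (snp for snp, p in snp_p.items() if p < p_threshold),
        key=lambda snp: (snp_p[snp], snp),
    )
    kept: list[str] = []
    missing = [0]
    remaining = candidates
    while remaining:
        lead = remaining[0]
        kept.append(lead)
        remaining = [
            snp
            for snp in remaining[1:]
            if _lookup_r2(r2, lead, snp, missing) < r2_threshold
        ]
    if missing[0]:
        logger.info("ld_prune: %d missing r2 entries treated as 0", missing[0])
    return kept


def trait_enrichment(
    trait: str,
    trait_snps: list[str],
    mediated_flags: Mapping[str, bool],
    background_proportion: float,
    min_snps: int = 20,
) -> EnrichmentResult | None:
    """One-tailed binomial enrichment test for one trait.

    ``trait_snps`` is the pruned list of trait-associated SNPs;
    ``mediated_flags`` maps each *tested eQTL SNP* to whether it is
    cell-type-mediated (SNPs absent from the mapping are not eQTL SNPs and do
    not count).  Traits with <= ``min_snps`` eQTL SNPs are skipped (None).
    The p-value is the exact upper binomial tail P(X >= k) under the
    background proportion.
    """
    if not 0 < background_proportion < 1:
        raise ValueError("background_proportion must be strictly inside (0, 1)")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    eqtl_snps = [s for s in trait_snps if s in mediated_flags]
    n = len(eqtl_snps)
    if n <= min_snps:
        logger.info("trait %s skipped: %d eQTL SNPs (need > %d)", trait, n, min_snps)
        return None
    k = sum(bool(mediated_flags[s]) for s in eqtl_snps)
    # exact upper tail: P(X >= k) = sf(k - 1)
    p = float(stats.binom.sf(k - 1, n, background_proportion))
    return EnrichmentResult(
        trait=trait,
        n_pruned_eqtl_snps=n,
        n_mediated=k,
        background_proportion=background_proportion,
        binomial_p_one_tailed=p,
    )


def r2_from_genotypes(genotypes: GenotypeMatrix) -> Callable[[str, str], float]:
    """r² lookup computed as squared dosage correlation in a reference cohort."""
    values = genotypes.values
    index = {snp: i for i, snp in enumerate(values.index)}
    arr = values.to_numpy(dtype=float)

    def lookup(a: str, b: str) -> float | None:
        if a not in index or b not in index:
            return None
        x, y = arr[index[a]], arr[index[b]]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
            return None
        r = np.corrcoef(x[mask], y[mask])[0, 1]
        return float(r * r)

    return lookup


def gwas_enrichment(
    gwas: pd.DataFrame,
    mediated_flags: Mapping[str, bool],
    r2: R2Lookup,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.2,
    min_snps: int = 20,
    background_proportion: float | None = None,
) -> pd.DataFrame:
    """Run LD pruning plus the binomial test for every trait in a GWAS table.

    ``gwas`` has columns snp_id, trait, p.  The background proportion defaults
    to the trait-agnostic fraction of mediated SNPs among all tested eQTL
    SNPs after the same pruning (pruning over all tested eQTL SNPs at p-rank
    order is not available here, so the unpruned tested set is used).
    """
    empty = pd.DataFrame(
        columns=[
            "trait", "n_pruned_eqtl_snps", "n_mediated", "mediated_percent",
            "background_proportion", "binomial_p_one_tailed",
        ]
    )
    if background_proportion is None:
        flags = list(mediated_flags.values())
        if not flags:
            raise ValueError("mediated_flags is empty")
        background_proportion = sum(map(bool, flags)) / len(flags)
        if background_proportion in (0.0, 1.0):
            logger.warning(
                "degenerate background proportion %.0f: no trait is testable",
                background_proportion,
            )
            return empty
    rows = []
    for trait, sub in gwas.groupby("trait"):
        snp_p = pd.Series(sub["p"].to_numpy(), index=sub["snp_id"])
        pruned = ld_prune(snp_p, r2, p_threshold=p_threshold, r2_threshold=r2_threshold)
        result = trait_enrichment(
            trait, pruned, mediated_flags, background_proportion, min_snps=min_snps
        )
        if result is not None:
            rows.append(
                {
                    "trait": result.trait,
                    "n_pruned_eqtl_snps": result.n_pruned_eqtl_snps,
                    "n_mediated": result.n_mediated,
                    "mediated_percent": result.mediated_percent,
                    "background_proportion": result.background_proportion,
                    "binomial_p_one_tailed": result.binomial_p_one_tailed,
                }
            )
    return pd.DataFrame(rows, columns=empty.columns) if rows else empty
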