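"""Core in-memory containers shared by every pipeline stage.

Both matrices are thin wrappers around a :class:`pandas.DataFrame` with
features (probes or SNPs) on the rows and samples on the columns, which is the
orientation the tab-separated interchange files use.  The wrappers exist to
carry provenance (the ordered list of normalization steps applied to an
expression matrix, per-SNP metadata for genotypes) and to centralize the
identifier-alignment checks every stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GenotypeMatrix", "align_samples"]


@dataclass
class ExpressionMatrix:
    """Probes x samples real-valued expression.

    Parameters
    ----------
    values
        DataFrame indexed by probe identifier with sample identifiers as
        columns.  No missing values are allowed once normalization starts.
    transform_log
        Append-only record of the normalization steps applied, in order.
    """

    values: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, step: str) -> "ExpressionMatrix":
        """Return a new matrix with ``step`` appended to the transform log."""
        return ExpressionMatrix(values=values, transform_log=[*self.transform_log, step])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, sample_ids],
            transform_log=list(self.transform_log),
        )


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive dosage matrix (values in [0, 2], NaN = missing).

    ``snp_info`` holds per-SNP metadata (chromosome, 1-based position, alleles,
    allele frequency, LD-block label when simulated), indexed like ``values``.
    """

    values: pd.DataFrame
    snp_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate SNP identifiers in genotype matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in genotype matrix")
        if self.snp_info is not None and not self.snp_info.index.equals(self.values.index):
            raise ValueError("snp_info index does not match dosage matrix rows")
        bad = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(bad, initial=0.0) < -1e-9 or np.nanmax(bad, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(values=self.values.loc[:, sample_ids], snp_info=self.snp_info)


def align_samples(
    expression: ExpressionMatrix, genotypes: GenotypeMatrix
) -> tuple[ExpressionMatrix, GenotypeMatrix, int]:
    """Intersect the sample sets of an expression and a genotype matrix.

    Returns the two matrices restricted to the shared samples (in expression
    order) together with the number of samples dropped from either side.
    """
    shared = [s for s in expression.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise ValueError("expression and genotype matrices share no samples")
    dropped = (expression.n_samples - len(shared)) + (genotypes.n_samples - len(shared))
    return expression.subset_samples(shared), genotypes.subset_samples(shared), dropped
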