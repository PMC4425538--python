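"""Synthetic multi-cohort fixtures with the structure the method assumes.

Whole-blood expression is modelled as a two-lineage mixture: each sample has a
myeloid (neutrophil-like) fraction ``f`` drawn from a truncated normal, and the
lymphoid fraction is ``1 - f`` (the two are perfectly anti-correlated, as they
are to a good approximation in blood).  A cis-eQTL acting within one lineage
contributes to the bulk measurement in proportion to that lineage's abundance,
which is exactly the signal the genotype-by-proportion interaction model is
designed to detect.

Expression is generated directly on a log-intensity-like scale (the scale on
which the linear interaction model operates); marker probes are noisy copies of
``f`` so that the proxy stage only requires a monotone association.  Genotypes
are Hardy-Weinberg dosages organised into LD blocks via a shared latent allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "EqtlEffectSpec",
    "SimulationConfig",
    "CohortFixture",
    "simulate_fractions",
    "simulate_genotypes",
    "simulate_cohort",
    "write_fixture",
]

# Substream labels: every stage draws from default_rng([seed, STREAM, cohort])
# so that adding draws to one stage never perturbs another.
_STREAM_GENOTYPES = 11
_STREAM_FRACTIONS = 23
_STREAM_EXPRESSION = 37
_STREAM_BASELINES = 53  # cohort-independent: probes share baselines across cohorts


@dataclass(frozen=True)
class EqtlEffectSpec:
    """Per-lineage allelic effect of one SNP on one probe.

    ``beta_myeloid`` / ``beta_lymphoid`` are the additive effects of one allele
    copy on within-lineage expression; the bulk effect observed in a sample
    with myeloid fraction f is ``f*beta_myeloid + (1-f)*beta_lymphoid``.
    """

    snp_id: str
    probe_id: str
    beta_myeloid: float = 0.0
    beta_lymphoid: float = 0.0
    baseline_myeloid: float = 0.0
    baseline_lymphoid: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of the multi-cohort generator.

    Defaults describe the study conditions this package is tested under:
    three microarray cohorts of a few hundred samples, a myeloid fraction of
    0.60 +/- 0.08 (neutrophils are ~60% of white blood cells), and cell counts
    measured in the first cohort only (the training cohort).
    """

    n_cohorts: int = 3
    samples_per_cohort: list[int] = field(default_factory=lambda: [300, 300, 300])
    n_snps: int = 100
    n_probes: int = 150
    maf_range: tuple[float, float] = (0.05, 0.5)
    neutrophil_mean: float = 0.60
    neutrophil_sd: float = 0.08
    n_marker_probes: int = 20
    marker_noise_sd: float = 0.02
    ld_block_size: int = 5
    within_block_r: float = 0.8
    eqtl_effects: list[EqtlEffectSpec] = field(default_factory=list)
    noise_sd: float = 0.30
    baseline_sd: float = 2.0
    composition_sd: float = 2.0
    cohorts_with_counts: tuple[int, ...] = (0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts <= 0 or self.n_snps <= 0 or self.n_probes <= 0:
            raise ValueError("n_cohorts, n_snps and n_probes must be positive")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort must have n_cohorts entries")
        if any(n <= 0 for n in self.samples_per_cohort):
            raise ValueError("samples_per_cohort entries must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 < self.neutrophil_mean < 1):
            raise ValueError("neutrophil_mean must be in (0, 1)")
        if not (0 < self.neutrophil_sd < 1):
            raise ValueError("neutrophil_sd must be in (0, 1)")
        if self.n_marker_probes <= 0:
            raise ValueError("n_marker_probes must be positive")
        if min(self.marker_noise_sd, self.noise_sd, self.baseline_sd, self.composition_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if not (0 <= self.within_block_r <= 1):
            raise ValueError("within_block_r must be in [0, 1]")
        snps = set(self.snp_ids())
        probes = set(self.probe_ids())
        for eff in self.eqtl_effects:
            if eff.snp_id not in snps:
                raise ValueError(f"effect spec references unknown SNP {eff.snp_id!r}")
            if eff.probe_id not in probes:
                raise ValueError(f"effect spec references unknown probe {eff.probe_id!r}")

    def snp_ids(self) -> list[str]:
        return [f"rs{i + 1:06d}" for i in range(self.n_snps)]

    def probe_ids(self) -> list[str]:
        return [f"probe_{i + 1:05d}" for i in range(self.n_probes)]

    def marker_probe_ids(self) -> list[str]:
        """The first ``n_marker_probes`` probes that carry no eQTL effect."""
        with_effects = {e.probe_id for e in self.eqtl_effects}
        markers = [p for p in self.probe_ids() if p not in with_effects]
        if len(markers) < self.n_marker_probes:
            raise ValueError("not enough effect-free probes to serve as markers")
        return markers[: self.n_marker_probes]


@dataclass
class CohortFixture:
    """One cohort's simulated data plus the ground truth used by tests."""

    cohort_id: str
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    cell_counts: pd.DataFrame | None
    true_fractions: pd.Series
    marker_probes: list[str]

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.genotypes.sample_ids:
            raise ValueError("expression and genotype sample identifiers disagree")
        if list(self.true_fractions.index) != self.expression.sample_ids:
            raise ValueError("true_fractions index disagrees with sample identifiers")


def _rng(seed: int, stream: int, cohort_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, cohort_index])


def _sample_ids(config: SimulationConfig, cohort_index: int) -> list[str]:
    n = config.samples_per_cohort[cohort_index]
    return [f"C{cohort_index}_S{i + 1:04d}" for i in range(n)]


def simulate_fractions(config: SimulationConfig, cohort_index: int) -> pd.Series:
    """Draw per-sample myeloid fractions from a normal truncated to (0, 1)."""
    rng = _rng(config.seed, _STREAM_FRACTIONS, cohort_index)
    a = (0.0 - config.neutrophil_mean) / config.neutrophil_sd
    b = (1.0 - config.neutrophil_mean) / config.neutrophil_sd
    f = stats.truncnorm.rvs(
        a, b, loc=config.neutrophil_mean, scale=config.neutrophil_sd,
        size=config.samples_per_cohort[cohort_index], random_state=rng,
    )
    return pd.Series(f, index=_sample_ids(config, cohort_index), name="myeloid_fraction")


def simulate_genotypes(config: SimulationConfig, cohort_index: int) -> GenotypeMatrix:
    """Hardy-Weinberg dosages in LD blocks.

    Each block shares a latent allele pair; every SNP copies each latent allele
    with probability sqrt(within_block_r), otherwise draws a fresh allele with
    the block's frequency.  Pairwise dosage correlation within a block is then
    within_block_r in expectation and zero across blocks.  The minor-allele
    frequency is drawn uniformly from ``maf_range`` once per block (a shared
    latent allele requires a shared frequency).
    """
    if cohort_index >= config.n_cohorts:
        raise ValueError("cohort_index out of range")
    rng = _rng(config.seed, _STREAM_GENOTYPES, cohort_index)
    n = config.samples_per_cohort[cohort_index]
    samples = _sample_ids(config, cohort_index)
    copy_p = float(np.sqrt(config.within_block_r))

    dosages = np.empty((config.n_snps, n), dtype=float)
    mafs = np.empty(config.n_snps)
    blocks = np.empty(config.n_snps, dtype=int)
    lo, hi = config.maf_range
    n_blocks = -(-config.n_snps // config.ld_block_size)
    snp = 0
    for block in range(n_blocks):
        maf = rng.uniform(lo, hi)
        latent = rng.random((2, n)) < maf  # one latent allele pair per block
        block_len = min(config.ld_block_size, config.n_snps - snp)
        for _ in range(block_len):
            copied = rng.random((2, n)) < copy_p
            fresh = rng.random((2, n)) < maf
            alleles = np.where(copied, latent, fresh)
            dosages[snp] = alleles.sum(axis=0)
            mafs[snp] = maf
            blocks[snp] = block
            snp += 1

    snp_ids = config.snp_ids()
    info = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, config.n_snps + 1) * 1000,  # 1-based, metadata only
            "ref": "A",
            "alt": "G",
            "maf": mafs,
            "ld_block": blocks,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    values = pd.DataFrame(dosages, index=info.index, columns=samples)
    return GenotypeMatrix(values=values, snp_info=info)


def simulate_cohort(config: SimulationConfig, cohort_index: int) -> CohortFixture:
    """Generate one cohort: genotypes, mixture expression, optional cell counts.

    For a probe g with an effect spec and sample i with myeloid fraction f_i:

        Y_gi = f_i * (baseline_myeloid + beta_myeloid * G_i)
             + (1 - f_i) * (baseline_lymphoid + beta_lymphoid * G_i)
             + Normal(0, noise_sd^2)

    Marker probes (the first ``n_marker_probes`` effect-free probes) are
    Y_gi = f_i + Normal(0, marker_noise_sd^2).  Each remaining background
    probe g is baseline_g + lambda_g * f_i + Normal(0, noise_sd^2), with a
    per-probe baseline ~ Normal(0, baseline_sd^2) and composition loading
    lambda_g ~ Normal(0, composition_sd^2), both drawn once and shared by
    every cohort (a common array platform and a common biology).  The
    baseline spread gives arrays the shared expression profile the PC1
    sample-QC step relies on; the composition loadings make cell composition
    a dominant transcriptome-wide factor, which is what lets the strongest
    expression PCs absorb it during correction — as in real whole blood.
    Cell counts (100 * f_i, cell_type "neutrophil") are emitted only for
    cohorts listed in ``cohorts_with_counts``.
    """
    genotypes = simulate_genotypes(config, cohort_index)
    fractions = simulate_fractions(config, cohort_index)
    rng = _rng(config.seed, _STREAM_EXPRESSION, cohort_index)
    probe_rng = np.random.default_rng([config.seed, _STREAM_BASELINES])
    baselines = probe_rng.normal(0.0, config.baseline_sd, config.n_probes)
    composition = probe_rng.normal(0.0, config.composition_sd, config.n_probes)
    samples = list(fractions.index)
    f = fractions.to_numpy()

    probe_ids = config.probe_ids()
    markers = config.marker_probe_ids()
    marker_set = set(markers)
    effects = {e.probe_id: e for e in config.eqtl_effects}

    values = np.empty((config.n_probes, len(samples)))
    for row, probe in enumerate(probe_ids):
        if probe in effects:
            eff = effects[probe]
            g = genotypes.values.loc[eff.snp_id].to_numpy()
            signal = f * (eff.baseline_myeloid + eff.beta_myeloid * g) + (1 - f) * (
                eff.baseline_lymphoid + eff.beta_lymphoid * g
            )
            values[row] = signal + rng.normal(0.0, config.noise_sd, len(samples))
        elif probe in marker_set:
            values[row] = f + rng.normal(0.0, config.marker_noise_sd, len(samples))
        else:
            values[row] = (
                baselines[row]
                + composition[row] * f
                + rng.normal(0.0, config.noise_sd, len(samples))
            )

    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        transform_log=["simulated"],
    )

    cell_counts = None
    if cohort_index in config.cohorts_with_counts:
        cell_counts = pd.DataFrame(
            {"sample_id": samples, "cell_type": "neutrophil", "percentage": 100.0 * f}
        )

    return CohortFixture(
        cohort_id=f"cohort{cohort_index}",
        expression=expression,
        genotypes=genotypes,
        cell_counts=cell_counts,
        true_fractions=fractions,
        marker_probes=markers,
    )


def write_fixture(fixture: CohortFixture, directory: str | Path) -> dict[str, Path]:
    """Write one cohort to TSV/VCF files round-trippable by :mod:`ctqtl.io`.

    Emits expression TSV, dosage TSV, a VCFv4.2 file with a DS FORMAT field,
    the cell-count TSV when counts exist, and a JSON sidecar with the true
    myeloid fractions and marker probes for recovery tests.
    """
    from . import io as ctio  # local import to avoid a cycle

    if fixture.expression.n_probes == 0:
        raise ValueError("refusing to write a fixture with an empty probe set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "dosages": directory / "dosages.tsv",
        "vcf": directory / "genotypes.vcf",
        "truth": directory / "truth.json",
    }
    ctio.write_expression(fixture.expression, paths["expression"])
    ctio.write_dosages(fixture.genotypes, paths["dosages"])
    ctio.write_vcf(fixture.genotypes, paths["vcf"])
    if fixture.cell_counts is not None:
        paths["cell_counts"] = directory / "cell_counts.tsv"
        ctio.write_cell_counts(fixture.cell_counts, paths["cell_counts"])
    truth = {
        "cohort_id": fixture.cohort_id,
        "true_fractions": {s: float(v) for s, v in fixture.true_fractions.items()},
        "marker_probes": list(fixture.marker_probes),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
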