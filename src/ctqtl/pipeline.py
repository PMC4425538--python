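"""End-to-end pipeline driver: configuration, orchestration, run manifest.

The stages run in the order the method prescribes: normalization, marker
selection in the training cohort, per-cohort proxy construction, PC correction
(skipping genetically driven components), per-cohort interaction scans, the
weighted-Z meta-analysis, permutation-calibrated FDR calls, and (optionally)
GWAS trait enrichment.  All randomness flows from the single config seed via
named substreams, and a JSON manifest records the config hash, seed and a
checksum per output so that equal manifests imply equal outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .containers import ExpressionMatrix, GenotypeMatrix
from .enrich import gwas_enrichment, r2_from_genotypes
from .interaction import cohort_scan, results_to_frame
from .meta import classify_direction, meta_analyze, meta_to_frame, MYELOID
from .mtc import effective_tests, fdr_calls, permutation_min_p
from .normalize import (
    center_only,
    log2_center,
    pc_correct_skip_genetic,
    quantile_normalize_median,
    remove_covariates,
    sample_qc_pc1,
)
from .proxy import MarkerRule, build_proxy, select_markers

logger = logging.getLogger("ctqtl")

__all__ = ["CohortPaths", "PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class CohortPaths:
    """File locations for one cohort."""

    id: str
    expression: str
    genotypes: str
    genotype_format: str = "dosage"
    cell_counts: str | None = None
    covariates: str | None = None


_COHORT_KEYS = {"id", "expression", "genotypes", "genotype_format", "cell_counts", "covariates"}
_CONFIG_KEYS = {
    "cohorts", "pairs", "gwas", "training_cohort", "output_dir", "marker_rule",
    "log2_transform", "n_pcs", "genetic_p_threshold", "sample_qc_threshold",
    "min_cohorts", "fdr_level", "n_permutations", "min_samples",
    "min_minor_group", "se_mode", "enrichment_p_threshold",
    "enrichment_r2_threshold", "enrichment_min_snps", "seed",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (defaults follow the method)."""

    cohorts: list[CohortPaths]
    pairs: str
    training_cohort: str
    output_dir: str
    gwas: str | None = None
    marker_rule: MarkerRule = field(default_factory=lambda: MarkerRule(threshold=0.57))
    log2_transform: bool = True
    n_pcs: int = 40
    genetic_p_threshold: float = 5e-8
    sample_qc_threshold: float = 0.9
    min_cohorts: int = 2
    fdr_level: float = 0.05
    n_permutations: int = 100
    min_samples: int = 30
    min_minor_group: int = 3
    se_mode: str = "classical"
    enrichment_p_threshold: float = 5e-8
    enrichment_r2_threshold: float = 0.2
    enrichment_min_snps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config lists no cohorts")
        ids = [c.id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cohort ids")
        if self.training_cohort not in ids:
            raise ValueError(f"training cohort {self.training_cohort!r} not among cohorts")
        if not 0 < self.sample_qc_threshold <= 1:
            raise ValueError("sample_qc_threshold must be in (0, 1]")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be non-negative")
        for path_attr in ("pairs", "gwas"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr} file not found: {p}")
        for cohort in self.cohorts:
            for attr in ("expression", "genotypes", "cell_counts", "covariates"):
                p = getattr(cohort, attr)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"cohort {cohort.id}: {attr} file not found: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cohorts = []
    for entry in raw.pop("cohorts", []):
        extra = set(entry) - _COHORT_KEYS
        if extra:
            raise ValueError(f"{path}: unknown cohort keys {sorted(extra)}")
        cohorts.append(CohortPaths(**entry))
    rule_raw = raw.pop("marker_rule", None)
    rule = MarkerRule(**rule_raw) if rule_raw else MarkerRule(threshold=0.57)
    base = str(Path(path).parent)

    def _resolve(p):
        return p if p is None or Path(p).is_absolute() else str(Path(base) / p)

    for c in cohorts:
        c.expression = _resolve(c.expression)
        c.genotypes = _resolve(c.genotypes)
        c.cell_counts = _resolve(c.cell_counts)
        c.covariates = _resolve(c.covariates)
    for key in ("pairs", "gwas", "output_dir"):
        if key in raw and raw[key] is not None:
            raw[key] = _resolve(raw[key])
    return PipelineConfig(cohorts=cohorts, marker_rule=rule, **raw)


@dataclass
class PipelineResult:
    """Everything a run produces, plus where it was written."""

    per_cohort_results: pd.DataFrame
    skip_log: pd.DataFrame
    meta_results: pd.DataFrame
    effective_tests: float
    fdr_threshold: float
    fdr_z_threshold: float
    n_significant: int
    enrichment: pd.DataFrame | None
    manifest_path: Path


def _normalize_cohort(
    expression: ExpressionMatrix,
    covariates: pd.DataFrame | None,
    log2_transform: bool,
    qc_threshold: float,
) -> tuple[ExpressionMatrix, list[str]]:
    """Quantile normalize, sample-QC, (log2-)center, residualize covariates.

    The PC1 quality filter runs on the quantile-normalized but still
    uncentered matrix: there the shared probe-mean profile dominates, every
    good array correlates highly with the PC1 reference profile, and the 0.9
    cut has its intended meaning.  Centering afterwards removes that shared
    profile before modelling.
    """
    x = quantile_normalize_median(expression)
    x, removed = sample_qc_pc1(x, threshold=qc_threshold)
    x = log2_center(x) if log2_transform else center_only(x)
    if covariates is not None:
        x = remove_covariates(x, covariates)
    return x, removed


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all outputs plus a run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs_df = pd.read_csv(config.pairs, sep="\t")
    if not {"snp_id", "probe_id"}.issubset(pairs_df.columns):
        raise ValueError(f"{config.pairs}: expected columns snp_id, probe_id")
    pairs = list(pairs_df[["snp_id", "probe_id"]].itertuples(index=False, name=None))
    if not pairs:
        raise ValueError("empty candidate pair list")

    normalized: dict[str, ExpressionMatrix] = {}
    genotypes: dict[str, GenotypeMatrix] = {}
    counts: dict[str, pd.Series] = {}
    qc_removed: dict[str, list[str]] = {}
    for cohort in config.cohorts:
        stage = f"normalize[{cohort.id}]"
        try:
            expr = ctio.read_expression(cohort.expression)
            geno = ctio.read_genotypes(cohort.genotypes, format=cohort.genotype_format)
            cov = None
            if cohort.covariates:
                cov_df = pd.read_csv(cohort.covariates, sep="\t", index_col=0)
                cov = cov_df.apply(pd.to_numeric)
            norm, removed = _normalize_cohort(
                expr, cov, config.log2_transform, config.sample_qc_threshold
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        normalized[cohort.id] = norm
        genotypes[cohort.id] = geno
        qc_removed[cohort.id] = removed
        if cohort.cell_counts:
            table = ctio.read_cell_counts(cohort.cell_counts)
            counts[cohort.id] = table.set_index("sample_id")["percentage"]

    if config.training_cohort not in counts:
        raise RuntimeError(
            f"stage select_markers failed: training cohort {config.training_cohort!r} "
            "has no cell-count table"
        )
    markers = select_markers(
        normalized[config.training_cohort], counts[config.training_cohort], config.marker_rule
    )
    markers.to_tsv(out_dir / "markers.tsv")

    proxies = {}
    corrected = {}
    reports = {}
    for cohort in config.cohorts:
        cid = cohort.id
        try:
            proxies[cid] = build_proxy(normalized[cid], markers)
            proxies[cid].to_tsv(out_dir / f"proxy_{cid}.tsv")
            n_pcs = min(
                config.n_pcs,
                min(normalized[cid].n_probes, normalized[cid].n_samples) - 2,
            )
            corrected[cid], reports[cid] = pc_correct_skip_genetic(
                normalized[cid],
                genotypes[cid],
                n_components=n_pcs,
                genetic_p_threshold=config.genetic_p_threshold,
            )
            reports[cid].to_json(out_dir / f"pc_report_{cid}.json")
        except Exception as exc:
            raise RuntimeError(f"stage proxy_and_correct[{cid}] failed: {exc}") from exc

    all_results = []
    all_skips = []
    for cohort in config.cohorts:
        cid = cohort.id
        results, skips = cohort_scan(
            corrected[cid],
            genotypes[cid],
            proxies[cid],
            pairs,
            cohort_id=cid,
            min_samples=config.min_samples,
            min_minor_group=config.min_minor_group,
            se_mode=config.se_mode,
        )
        all_results.extend(results)
        all_skips.extend(skips)

    metas = meta_analyze(all_results, min_cohorts=config.min_cohorts)
    if not metas:
        raise RuntimeError("stage meta failed: no pair testable in enough cohorts")

    perm_cohorts = [
        (corrected[c.id], genotypes[c.id], proxies[c.id], c.id) for c in config.cohorts
    ]
    min_ps = permutation_min_p(
        perm_cohorts,
        pairs,
        n_permutations=config.n_permutations,
        seed=config.seed,
        min_cohorts=config.min_cohorts,
        min_samples=config.min_samples,
        min_minor_group=config.min_minor_group,
        se_mode=config.se_mode,
    )
    eff = effective_tests(min_ps, n_nominal_tests=len(metas))
    call, flags = fdr_calls([m.p_meta for m in metas], eff, fdr_level=config.fdr_level)
    for m, flag in zip(metas, flags):
        m.significant = bool(flag)
        m.direction = classify_direction(m.z_meta, m.significant)

    results_frame = results_to_frame(all_results)
    skip_frame = pd.DataFrame(
        [
            {"cohort_id": s.cohort_id, "snp_id": s.snp_id, "probe_id": s.probe_id, "reason": s.reason}
            for s in all_skips
        ],
        columns=["cohort_id", "snp_id", "probe_id", "reason"],
    )
    meta_frame = meta_to_frame(metas)
    results_frame.to_csv(out_dir / "interaction_results.tsv", sep="\t", index=False, float_format="%.10g")
    skip_frame.to_csv(out_dir / "skip_log.tsv", sep="\t", index=False)
    meta_frame.to_csv(out_dir / "meta_results.tsv", sep="\t", index=False, float_format="%.10g")
    pd.Series(min_ps, name="min_p").rename_axis("permutation").to_csv(
        out_dir / "permutation_min_p.tsv", sep="\t", float_format="%.10g"
    )
    fdr_report = {
        "mean_min_p": eff.mean_min_p,
        "n_effective_tests": eff.n_effective,
        "n_nominal_tests": eff.n_nominal_tests,
        "nominal_p_threshold": call.nominal_p_threshold,
        "z_threshold": call.z_threshold,
        "fdr_level": call.fdr_level,
        "n_significant": call.n_significant,
    }
    (out_dir / "fdr_report.json").write_text(json.dumps(fdr_report, indent=1))

    enrichment = None
    if config.gwas:
        gwas = ctio.read_gwas(config.gwas)
        mediated = {m.snp_id: m.direction == MYELOID for m in metas}
        reference = genotypes[config.training_cohort]
        enrichment = gwas_enrichment(
            gwas,
            mediated,
            r2_from_genotypes(reference),
            p_threshold=config.enrichment_p_threshold,
            r2_threshold=config.enrichment_r2_threshold,
            min_snps=config.enrichment_min_snps,
        )
        enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")

    manifest_path = out_dir / "manifest.json"
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "qc_removed_samples": qc_removed,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))

    return PipelineResult(
        per_cohort_results=results_frame,
        skip_log=skip_frame,
        meta_results=meta_frame,
        effective_tests=eff.n_effective,
        fdr_threshold=call.nominal_p_threshold,
        fdr_z_threshold=call.z_threshold,
        n_significant=call.n_significant,
        enrichment=enrichment,
        manifest_path=manifest_path,
    )


def _config_hash(config: PipelineConfig) -> str:
    def _default(obj):
        if isinstance(obj, (CohortPaths, MarkerRule)):
            return obj.__dict__
        raise TypeError(type(obj))

    payload = json.dumps(config.__dict__, default=_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
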