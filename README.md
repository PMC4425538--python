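# ctqtl — cell-type-mediated cis-eQTL mapping without sorting cells

Bulk tissue is a mixture: a cis-eQTL measured in whole blood is a weighted
average of its effects in the constituent cell types, with weights equal to
each donor's cell-type proportions. `ctqtl` detects eQTLs whose effect size
*scales* with the abundance of one lineage — e.g. neutrophil-mediated eQTLs in
whole blood — without physically purifying cells. It is aimed at
statistical-genetics practitioners who have multi-cohort expression + genotype
data and, for at least one cohort, measured cell counts.

## The method

1. **Proxy phenotype.** In a training cohort with measured cell percentages,
   select marker probes whose expression correlates positively with the
   percentage (Spearman *R* above a threshold, or top-N). In every cohort —
   including those without counts — compute the probe×probe correlation matrix
   of the markers, take the first principal component, orient it so it tracks
   mean marker expression, and standardize the per-sample scores. This PC1 is
   the proxy *P* for the cell-type proportion.
2. **Interaction model.** For each candidate SNP–probe pair, per cohort, fit

   ```
   Y ≈ I + β₁·G + β₂·P + β₃·(P:G) + e
   ```

   with *Y* the PC-corrected expression, *G* the additive dosage and *P* the
   proxy. β₃ measures how the eQTL scales with the proxied proportion;
   heteroscedasticity-robust (HC0/HC3 sandwich) standard errors are available
   as a sensitivity option. Candidates are pairs with a known *generic* eQTL
   effect, i.e. discovered with the reduced model `Y ≈ I + β₁·G + e`.
3. **Meta-analysis.** Per-cohort interaction Z-scores combine as
   `Z = Σ√nᵢ·Zᵢ / √(Σnᵢ)`. A significant positive Z means the effect grows
   with the (myeloid) proxy; a significant negative Z means it grows with the
   complementary lymphoid fraction.
4. **Multiple testing.** The effective number of independent tests is
   `0.5 / mean(min p over permutations)`, with permutations that shuffle
   genotype sample labels within each cohort. The FDR at threshold *t* is
   `t·n_effective / #{p ≤ t}`, maximized over observed p-values subject to
   FDR ≤ 0.05.
5. **Disease enrichment.** GWAS hits per trait are LD-pruned (greedy,
   p < 5×10⁻⁸, r² ≥ 0.2 collapsed); the fraction of pruned eQTL SNPs that are
   mediated is compared with the background fraction by a one-tailed exact
   binomial test (traits with > 20 pruned eQTL SNPs only).
6. **Replication.** In purified-cell-type datasets, per-pair effect sizes
   (dosage–expression Pearson *r*) of mediated vs generic eQTLs are compared
   with a one-tailed rank-sum test.

A full synthetic-data generator (`ctqtl.synthdata`) produces multi-cohort
fixtures with the structure the method assumes — two-lineage mixture
expression, marker probes, LD-blocked Hardy–Weinberg genotypes, cell counts in
a training cohort — so the whole pipeline is testable end to end.

## Worked example

Simulate three cohorts of 150 samples with two planted cell-type-mediated
eQTLs (a myeloid one at `rs000001` and a lymphoid one at `rs000004`), write
them to disk, and run the full pipeline from a YAML config:

```python
import pandas as pd, yaml, pathlib
from ctqtl import (EqtlEffectSpec, SimulationConfig, simulate_cohort,
                   write_fixture, load_config, run_pipeline)

root = pathlib.Path("demo")
effects = [
    EqtlEffectSpec("rs000001", "probe_00041", beta_myeloid=2.0, beta_lymphoid=0.0),
    EqtlEffectSpec("rs000004", "probe_00042", beta_myeloid=0.0, beta_lymphoid=2.0),
]
config = SimulationConfig(n_cohorts=3, samples_per_cohort=[150]*3, n_snps=30,
                          n_probes=300, n_marker_probes=15,
                          eqtl_effects=effects, seed=42)
cohorts = []
for i in range(3):
    fx = simulate_cohort(config, i)
    paths = write_fixture(fx, root / fx.cohort_id)
    entry = {"id": fx.cohort_id, "expression": str(paths["expression"]),
             "genotypes": str(paths["dosages"])}
    if "cell_counts" in paths:                      # training cohort only
        entry["cell_counts"] = str(paths["cell_counts"])
    cohorts.append(entry)

pairs = [{"snp_id": "rs000001", "probe_id": "probe_00041"},
         {"snp_id": "rs000004", "probe_id": "probe_00042"}]
pairs += [{"snp_id": f"rs{i+1:06d}", "probe_id": f"probe_{31 + i % 8:05d}"}
          for i in range(6, 28)]                    # null pairs
pd.DataFrame(pairs).to_csv(root / "pairs.tsv", sep="\t", index=False)

(root / "config.yaml").write_text(yaml.safe_dump({
    "seed": 42, "output_dir": str(root / "out"), "training_cohort": "cohort0",
    "pairs": str(root / "pairs.tsv"), "log2_transform": False,
    "marker_rule": {"top_n": 15}, "n_pcs": 15, "n_permutations": 20,
    "cohorts": cohorts}))

result = run_pipeline(load_config(root / "config.yaml"))
print("effective tests:", round(result.effective_tests, 1))
print("nominal p threshold:", f"{result.fdr_threshold:.3g}",
      "-> |Z| >=", round(result.fdr_z_threshold, 2))
print(result.meta_results[result.meta_results.significant][
    ["snp_id", "probe_id", "z_meta", "p_meta", "direction"]].to_string(index=False))
```

Output:

```
effective tests: 16.0
nominal p threshold: 3.64e-08 -> |Z| >= 5.51
  snp_id    probe_id    z_meta       p_meta         direction
rs000004 probe_00042 -5.507301 3.643772e-08 lymphoid-mediated
```

The planted lymphoid eQTL is called with the correct direction: its
interaction Z is negative because the effect strengthens as the myeloid proxy
*falls*. The myeloid pair at `rs000001` comes out positive in every cohort
(per-cohort Z ≈ 1.9, 0.2, 1.9) but at 450 total samples stays below the
permutation-calibrated threshold — detecting proportion-scaling effects needs
large sample sizes, which is exactly why the method meta-analyzes cohorts.
The 22 null pairs produce no calls. All stage outputs (marker list, per-cohort
proxies, interaction and meta tables, skip log, permutation minima, FDR report,
run manifest) land under `demo/out/`.

The same pipeline is scriptable from the shell via the `ctqtl` CLI
(`ctqtl simulate`, `select-markers`, `build-proxy`, `normalize`, `scan`,
`meta`, `fdr`, `enrich`, `validate`, `run-all`).

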