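# xte — cross-tissue enrichment toolkit

`xte` is a statistical pipeline for multi-tissue differential-expression
studies in which the interesting biology is *subtle and distributed*:
many genes shift expression by a few percent, coherently within
pathways and consistently across tissues, and no single gene clears a
genome-wide significance threshold. The motivating setting is the
comparison of breeding and non-breeding cooperatively breeding
mammals, whose reproductive status roughly halves or doubles remaining
life expectancy, but the machinery applies to any per-tissue DE
summary tables.

It is aimed at computational biologists who have per-tissue DE results
(gene, p-value, log2 fold-change, mean expression) and want
threshold-free, resampling-calibrated answers to four questions:

1. **Which pathways are enriched for DE signal in a tissue?**
   Fisher-combination statistic F_X = -2 Σ ln p over the set members,
   tested against an *empirical* null built by redrawing matched-size
   gene sets from the tissue background (1,000 → 10,000 → 100,000
   draws as precision demands), because gene-level p-values are
   correlated and the chi-square(2m) reference cannot be trusted. The
   ratio F_up/F_down indicates the set's net regulation direction, and
   L_X = Σ |log2FC| provides a p-value-free cross-check.
2. **Which genes are consistently regulated across tissues, where they
   are actually expressed?** The expression-weighted statistic
   f_g = |2 Σ_t ln(p_gt) · w_gt| with signed weights
   w_gt = expr_gt · sgn(log2FC_gt) / Σ_t expr_gt, which rewards
   direction-consistent regulation and lets a tissue-specific gene be
   judged by its own tissue. Pathway enrichment is then run on the
   gene-level cross-tissue p-values.
3. **Are two pathways co-regulated at the network level?**
   Signed biweight-midcorrelation adjacency, topological overlap
   matrix, and set-pair connectivity k_XY = Σ tom over the non-shared
   members, with a one-sided empirical null of matched-size random
   index pairs.
4. **Do two cohorts age at different rates?** Status-specific annual
   mortality rates per 6-month age interval with exact person-years
   exposure accounting, plus paired comparisons across intervals.

A synthetic-data module generates every input with known ground truth
(planted pathway effects, planted co-expression modules, cohorts with
known hazards), so the whole pipeline is validated by parameter
recovery rather than by fixtures.

## Worked example

```python
import numpy as np
from xte import (SimulationConfig, PlantedEffect, simulate_de_summaries,
                 enrich_tissue, tissue_weights, gene_crosstissue_p,
                 enrich_crosstissue)

cfg = SimulationConfig(
    n_genes=4000, n_tissues=4, n_sets=40, seed=11,
    planted=[PlantedEffect(name="STEROID_UP", size=20, beta_a=0.1,
                           direction=+1)])
panel, sets, truth = simulate_de_summaries(cfg)

run = enrich_tissue(panel, sets, "T01", method="F", seed=1)
top = min(run.results, key=lambda r: r.empirical_p)
print(f"{top.set_name}: F={top.statistic:.1f} p={top.empirical_p:.2e} "
      f"FDR={top.fdr:.2e} ratio={top.direction_ratio} "
      f"draws={top.n_draws_used}")

w = tissue_weights(panel)
gene_stats = gene_crosstissue_p(panel, w, seed=2)
cross = enrich_crosstissue(gene_stats, sets, seed=3)
hit = min(cross.results, key=lambda r: r.empirical_p)
print(f"cross-tissue {hit.set_name}: p={hit.empirical_p:.2e} "
      f"FDR={hit.fdr:.2e}")
```

prints

```
STEROID_UP: F=308.1 p=1.00e-05 FDR=4.00e-04 ratio=inf draws=100000
cross-tissue STEROID_UP: p=1.00e-05 FDR=4.00e-04
```

The planted set is recovered in a single tissue with the smallest
representable empirical p (1/100,001 after escalating to 100,000 null
draws), its direction ratio is flagged +inf because every member is
up-regulated, and the cross-tissue combination recovers it as well;
the BH-FDR of 4e-4 reflects correction across the 40 sets tested.

The same stages are available from the shell via the `xte` CLI
(`xte simulate | enrich | cross | connectivity | compare | mortality |
run`); `xte run --config config.yaml --seed 7 --outdir out/` executes
the configured stages end to end and writes a manifest with per-stage
seeds and output checksums. Identical config and seed reproduce
byte-identical tables.

See `docs/methods.md` for the statistical details and design
decisions.

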