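# sca1vol

Longitudinal volumetric biomarkers for spinocerebellar ataxia type 1
(SCA1), as a tested, reusable pipeline. SCA1 is a dominantly inherited
polyglutamine movement disorder; with therapies on the horizon, candidate
trial biomarkers must (i) separate affected from unaffected individuals,
(ii) change measurably within affected individuals alone, (iii) do so
within a monitorable timeframe, and (iv) track clinical disease burden
(the SARA ataxia score, 0–40). This package implements the full analysis
chain that evaluates regional brain volumes against those criteria, plus
the multi-atlas labelling core that produces the volumes, and a synthetic
cohort generator with known ground truth so every stage is verifiable.

The pipeline, stage by stage:

1. **ICV adjustment** — per region, fit the allometric model
   `VOI = α·ICV^β`, adjust as `VOI/ICV^β`, and rescale to natural units by
   moment matching. After adjustment essentially no VOI–ICV correlation
   remains.
2. **Mixed-effects screens** — for each of 34 regions, model change from
   baseline with subject random intercepts: the group screen tests the
   group×time interaction (differential atrophy), the within-affected
   screen tests elapsed time alone; Satterthwaite df, Bonferroni over the
   34-region family. A standardized baseline group comparison accompanies
   them.
3. **Detectability horizon** — the earliest time `t` at which the 99% CI of
   the predicted cumulative change `β₀ + β_t·t` excludes zero.
4. **Penalized selection** — an L1-penalized linear mixed model
   (`max loglik − λ·Σ|β|`, coordinate descent, integer λ grid 1..100, BIC
   and subject-grouped cross-validation) picks which regional changes and
   change×time interactions predict SARA change.
5. **MAGMA-style labelling core** — candidate atlases ranked by Pearson
   correlation of Jacobian-determinant maps with the target's, the top-k
   exemplars' label sets fused by locally intensity-weighted majority vote,
   and regional volumes extracted from the fused labels.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a simulated
cohort and write tables under `results/analysis/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_adjust_icv.py
python analysis/03_screen_volumes.py
python analysis/04_detectability.py
python analysis/05_select_predictors.py
python analysis/06_fuse_atlas.py
```

Output of the first three stages (seed 2026):

```
simulated 92 subject-visits for 33 subjects (seed 2026)
  affected: 13 subjects, 11 third visits, ICV mean 1,471,723 mm^3 (SD 93,953)
  unaffected: 20 subjects, 15 third visits, ICV mean 1,499,952 mm^3 (SD 119,300)

fitted scaling exponents for 34 regions (beta range 0.125 to 1.180)
raw VOI-ICV correlation: r = 0.085 to 0.824
after adjustment:        r = -0.0245 to 0.0277

group-by-time screen: 7 regions with differential change:
  pons                   beta    -405.4 mm^3/yr  t(60.7) = -8.27  p_bonf = 5.22e-10
  pallidum               beta    -112.5 mm^3/yr  t(60.0) = -5.49  p_bonf = 2.96e-05
  putamen                beta    -194.4 mm^3/yr  t(60.9) = -4.96  p_bonf = 2.00e-04
  ...
within-affected screen: 7 regions change (cerebellum, cereb_lobule_6,
cereb_wm_deep_nuclei, caudate, putamen, pallidum, pons)
```

Reading this: 92 rows (not 99) because some subjects miss the third visit;
adjustment shrinks VOI–ICV correlations from up to 0.82 down to |r| < 0.03;
the screen then flags the regions whose simulated atrophy rates were set
nonzero — pons steepest, exactly as configured — with ~60 denominator df
from 33 subjects. Stage 05 reports which terms survive the penalized
selection of SARA-change predictors (on a 33-subject cohort the collinear
pons main/interaction pair is typically represented by a single term), and
stage 06 demonstrates exemplar ranking, vote fusion and exact volume
conservation on a 32³ atlas stack.

The same functionality is scriptable via a single CLI
(`sca1vol simulate|adjust|screen|detect|select|fuse|volumes|run`), e.g.
`sca1vol run --config pipeline.yaml` for the whole chain with provenance
logging.

## Layout

```
src/sca1vol/        library: synthetic, atlas, fusion, icv, mixedlm,
                    screen, detect, lasso, io, pipeline, cli
analysis/           numbered narrative drivers (worked example above)
scripts/            acceptance.py
tests/              pytest suite incl. statistical acceptance tests
docs/methods.md     models, defaults, calibration, design choices
```
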