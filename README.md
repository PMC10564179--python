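# circust

Reconstruction of 24-hour gene-expression rhythms from cohorts sampled at a
single, unknown (or unreliable) time point per subject — the situation of
postmortem tissue banks such as GTEx, where each donor contributes one
sample and annotated times of death are imprecise relative to internal
biological time.

The package solves two coupled problems:

1. **Temporal order estimation.** Given a genes × samples expression matrix,
   recover the circular order of the samples around the 24-h day.  Two
   *eigengenes* (the leading right-singular vectors of the row-centered
   submatrix of rhythmic genes) span the plane in which rhythmic samples
   trace an ellipse; whitening the two scores and taking the two-argument
   arctangent projects every sample onto the unit circle (circular PCA).
   The remaining 2*m*-fold ambiguity (starting point and clockwise /
   counterclockwise direction) is resolved from canonical clock-gene peak
   precedences — in the base model a single comparison, *DBP* peaking before
   *ARNTL* — optionally refined by user-supplied precedence chains such as
   `{DBP} <= {CRY1,CRY2} <= {ARNTL}`.

2. **Rhythm characterization.** Each gene is screened with a fast circular
   unimodal ("up–down–up") order-restricted fit (R²_ORI), and survivors are
   fitted with the five-parameter Frequency Modulated Möbius (FMM) wave

   μ(t) = M + A·cos(β + 2·arctan(ω·tan((t − α)/2))),

   where M is the midline, A ≥ 0 the amplitude, α a translation, β a shape
   (skewness) angle and ω ∈ (0, 1] the sharpness (ω = 1 is a pure sinusoid,
   small ω a sharp asymmetric pulse).  The peak phase (acrophase) has the
   closed form t_U = α + 2·arctan(tan(−β/2)/ω).

The pipeline (12 seed clock genes → preliminary order → outlier removal →
quality gate → ORI screen → TOP gene selection with ω > 0.1, R²_FMM > 0.5
and quarter coverage → K = 5 re-orderings from random 2/3 gene subsets →
per-gene medians, circular for t_U) yields a per-tissue **atlas table** of
robust rhythmicity parameters and an estimated time for every sample.

## Worked example

Everything is testable without downloads via the ground-truthed synthetic
generator, which emulates FMM-shaped rhythmic genes (including the 12 seed
genes with biologically ordered phases), non-rhythmic confounds (flat noise,
index drift, batch shifts, sharp spikes) and uneven sampling:

```python
import numpy as np
from circust import (SimulationSpec, simulate, PipelineConfig, run_circust)

spec = SimulationSpec(m=100, n_rhythmic=40, n_confound=60, noise_sd=0.1,
                      rng_seed=11)
expr, truth = simulate(spec)

result = run_circust(expr, PipelineConfig(rng_seed=1),
                     known_times=dict(zip(expr.sample_ids, truth.true_times)))

rep = result.report
print(f"gate: {rep['gate_status']} (median seed R2 = "
      f"{rep['gate_median_seed_r2']:.3f})")
print(f"TOP genes: {rep['n_top']}; accepted orderings: "
      f"{rep['n_orderings_accepted']}")
print(f"circular correlation with true times: "
      f"{rep['validation']['circular_correlation']:.3f}")
print(f"median angular error (MAD): "
      f"{rep['validation']['angular_mad_rad']:.3f} rad")
print(result.atlas.table.head(5).to_string(index=False))
```

prints

```
gate: passed (median seed R2 = 0.981)
TOP genes: 40; accepted orderings: 5
circular correlation with true times: 0.993
median angular error (MAD): 0.053 rad
  gene   r2_med       tU_med  omega_med    A_med     M_med phase_class  n_valid_orderings
 NR1D1 0.985570 3.437481e-10   0.842209 0.933839 -0.001665      active                  5
RHY002 0.985155 6.195127e+00   0.940761 0.922715 -0.012034    inactive                  5
RHY025 0.984995 4.672790e+00   0.889683 0.881783  0.015217    inactive                  5
   DBP 0.984014 5.570725e-01   0.749684 0.917386 -0.003489      active                  5
RHY020 0.983495 3.656147e+00   0.860079 0.917759  0.025478    inactive                  5
```

The quality gate passed (median seed-gene R²_FMM 0.98 ≥ 0.3), the
reconstructed sample angles track the hidden true times (circular
correlation 0.993; median angular error 0.053 rad ≈ 12 minutes of clock
time), and the atlas ranks the 40 TOP genes by median rhythmicity with
their peak phases (`tU_med`, radians; 0 = lights-on, π = lights-off),
sharpness (`omega_med`) and active/inactive classification.

A command-line interface wraps the same functionality:

```bash
circust simulate --out sim/ --rng-seed 11
circust run --input sim/expr.tsv --output-dir out/ \
            --known-times sim/truth.tsv --rng-seed 1
circust validate --estimated out/sample_times.tsv --truth sim/truth.tsv
```

writing `atlas.tsv`, `sample_times.tsv` and `report.json`.

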