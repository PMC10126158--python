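# acqcost

Toolkit for quantifying the **plasmid acquisition cost** — the transient
growth burden a bacterial cell pays immediately after receiving a
conjugative plasmid — from single-colony time-lapse growth curves, and for
exploring its population-level consequences.

It is written for microbiologists and quantitative biologists who track
colonies (flatbed-scanner or plate-reader kinetics) of *de novo*
transconjugants (plasmid received within the last ~1 h) against *adapted*
transconjugants (lineage carrying the plasmid ≥ 24 h), and who want to ask:
how costly is acquisition, is the cost carried by lag time or by growth
rate, and what does that mean for competing plasmids?

## The model

Each colony's normalized log-density curve is fit with the modified
logistic growth model

```
N(t) = A / (1 + exp((4 μm / A) (λ − t) + 2))
```

where `A` is the asymptotic density, `μm` the maximum growth rate (h⁻¹)
and `λ` the lag time (h): the steepest tangent crosses N = 0 at t = λ.
The **time-to-threshold** TTT is the time the curve first reaches a fixed
density (default 0.8 on the normalized scale), and the **acquisition
cost** of a plasmid is

```
cost = mean TTT(de novo) / mean TTT(adapted)
```

compared across populations with two-sided t-tests (Bonferroni-corrected
across plasmids). On top of this quantification the package provides:

* **QC filters** for raw scanner curves: per-plate final-density 2 SD
  outlier removal, closing of 1–2-point spikes by flanking averages,
  rejection of wider spikes and of curves that never plateau.
* A **constrained lognormal bootstrap** testing whether the within-colony
  lag/growth tradeoff (longer-lagged clones growing faster) is needed to
  reproduce the observed growth-vs-TTT relationship: clone pairs are
  resampled with growth either independent of lag (unconstrained) or tied
  to it through the observed regression (constrained), each round's
  growth-vs-TTT slope is recorded via the closed-form inverse of the
  model, and 95% CIs are compared with the observed slope CI.
* A **heterogeneous-clone ODE competition model**,
  `dNj/dt = μj Nj 1[t ≥ λj] (1 − (ΣNi + P)/K)`, with per-clone lognormal
  lags, optional lag→growth tradeoff, shared carrying capacity `K`
  (default 2×10⁹ cells) and non-growing residual parents `P`; used for
  single-population density sweeps and calibrated pairwise competitions.
* A **synthetic data generator** (also the test-fixture factory) that
  renders phenotypes into noisy sampled curves with a detection floor and
  plantable artifacts, plus three illustrative presets spanning low /
  intermediate / high acquisition cost.

## Worked example

```python
import numpy as np
from acqcost import SynthConfig, qc_filter, quantify_curves, acquisition_cost, regress
from acqcost.synth import gen_phenotypes, render_curves, inject_artifacts

cfg = SynthConfig(n_colonies=60, target_cost=1.5, tradeoff=(0.04, 0.28, 0.03), seed=42)
r1, r2, r3 = (np.random.default_rng(s) for s in np.random.SeedSequence(42).spawn(3))
truth = gen_phenotypes(cfg, rng=r1)
curves = render_curves(truth, cfg, rng=r2)
curves, manifest = inject_artifacts(curves, {"spike1": 2, "size_outlier": 1}, rng=r3)

passed, report = qc_filter(curves)
print(f"QC: {len(passed)}/{len(curves)} curves passed")

phen = quantify_curves(passed, threshold=0.8)
ok = phen[phen.qc_pass]
res = acquisition_cost(ok.loc[ok.population == 'de_novo', 'ttt_h'],
                       ok.loc[ok.population == 'adapted', 'ttt_h'])
print(f"acquisition cost = {res.cost:.3f} (p = {res.p_value:.2e})")

dn = ok[ok.population == 'de_novo']
fit = regress(dn['lag_h'], dn['growth_rate_per_h'])
print(f"tradeoff slope = {fit.slope:.4f} 1/h per h (rho = {fit.pearson_rho:.2f})")
```

prints

```
QC: 117/120 curves passed
acquisition cost = 1.477 (p = 2.33e-25)
tradeoff slope = 0.0414 1/h per h (rho = 0.88)
```

The generator was asked for a cost of 1.5 and a lag→growth slope of 0.04;
the pipeline recovers 1.477 and 0.0414 from the rendered noisy curves. The
QC step removed the planted oversized colony (and two borderline clean
finals — a 2 SD rule clips ~5% of honest tails). The tiny p-value says the
de novo and adapted TTT distributions are clearly distinct; rho = 0.88 is
the within-population lag/growth correlation that motivates the
constrained bootstrap.

The same stages are scriptable from the shell:

```
acqcost synth --seed 2 --out out/        # curves.csv + truth.csv + manifest
acqcost cost --input out/curves.csv --out out/
acqcost bootstrap --config run.yaml --out out/
acqcost sweep|calibrate|compete|run ...
```

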