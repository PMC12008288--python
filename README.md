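# ctrlenergy

Time-resolved network control energy analysis of pharmacologically
altered brain dynamics.

## What this package is for

Serotonergic drugs with rapid kinetics (an intravenous bolus acting
within a minute and fading within half an hour) change how easily the
brain moves between activity states. `ctrlenergy` quantifies that with
network control theory: each fMRI volume is a brain state — the vector
of regional BOLD amplitudes — and the transition between adjacent
volumes is modelled as a steered trajectory of the linear system

```
dx/dt = A x(t) + B u(t)
```

where `A` is the (stabilized) weighted structural connectome, `B =
diag(v)` assigns each region its input authority, and `u(t)` is the
exogenous input. The **minimum control energy** of a transition from
`x0` to `xf` over a horizon `T` is

```
E_min = min ∫₀ᵀ u(t)ᵀu(t) dt  subject to the dynamics,  x(0)=x0, x(T)=xf
      = dᵀ W_T⁻¹ d,     d = xf − e^{AT} x0,
W_T   = ∫₀ᵀ e^{As} B Bᵀ e^{Aᵀs} ds   (controllability Gramian)
```

with regional energies `E_i = ∫₀ᵀ u_i*(t)² dt` summing to `E_min`.
Computing this for every adjacent-volume pair yields an energy
time-series per subject and condition (drug vs. placebo), which the
package then relates to:

- **EEG signal diversity** — Lempel–Ziv (LZ76) dictionary size of
  mean-binarized 2-s epochs, channel-averaged and HRF-convolved onto the
  volume grid;
- **subjective intensity ratings** (0–10 per minute), via per-minute
  windowed energies;
- **PET receptor density maps** (serotonin 2a and other 5-HT
  receptors/transporter), via Spearman correlations tested against
  spatial-autocorrelation-preserving spin permutations, plus dominance
  analysis across maps;
- a **pharmacokinetically informed simulation**: an effect-compartment
  concentration curve `c(t)` and the 2a receptor map `ρ` define a
  time-varying control strategy `v(t) = 1 + α·(c̃(t) + ρ̃)` applied to
  post-injection transitions of the *placebo* scans, predicting the
  drug condition's energy trajectory; `α` is calibrated by grid search.

It is aimed at researchers analysing pharmaco-fMRI/EEG designs with an
in-scanner drug challenge, and ships a synthetic-data generator that
emulates the full study structure so every stage runs and is testable
without any data download.

## Worked example

```python
import numpy as np
from ctrlenergy import ControlConfig, ControlEnergyModel, PharmacoControlModel
from ctrlenergy.pksim import PkParams, ScheduleSpec, simulate_concentration
from ctrlenergy.synth import SynthConfig, gen_bold, gen_connectome, gen_receptor_map

cfg = SynthConfig(n_regions=48, n_cortical=40, n_subjects=8, n_volumes=300,
                  injection_volume=91, seed=1)
sc = gen_connectome(cfg)                  # modular weighted connectome
rmap, coords = gen_receptor_map(cfg)      # smooth receptor map on the sphere
drug, placebo = gen_bold(cfg, sc, rmap)   # paired BOLD state series

model = ControlEnergyModel(drug, placebo, sc,
                           config=ControlConfig(integration_steps=101))
res = model.fit(n_perm=2000, seed=1)
print(res.summary())
```

```
Control energy condition contrast
================================================
subjects: 8    transitions: 299    state norm: none
time horizon T = 1.0
mean global energy  drug: 91.98    placebo: 111.4
mean post-injection delta (drug - placebo): -27.85
significant clusters (p <= 0.05): 1
fraction of post-injection time-points significant: 99.5%
```

The generator plants a receptor-weighted, concentration-gated damping of
post-injection BOLD amplitude in the drug condition; because energy
scales quadratically with state magnitude, drug energy drops below
placebo after the injection, and the cluster-based permutation test
marks essentially the whole post-injection period as significant.
`res` also exposes `delta_global()`, `correlate_diversity()`,
`correlate_intensity()`, `regional_metrics()`, `receptor_association()`
and `dominance()` for the downstream analyses.

The pharmacological simulation predicts the drug energy series from the
placebo scans alone:

```python
conc = simulate_concentration(PkParams(), np.arange(0.0, 602.0, 2.0))
pm = PharmacoControlModel(placebo, res.group_global["drug"], sc, conc, rmap,
                          spec=ScheduleSpec(injection_volume=cfg.injection_volume),
                          config=model.config)
print(pm.fit(grid=(1, 10, 20, 30, 40)).summary())
```

```
Pharmacologically informed control simulation
================================================
schedule mode: additive    fitted alpha: 1
alpha grid distances (Euclidean, group-level):
  alpha =     1: 948.224  <-- minimum
  alpha =    10: 1215.02
  alpha =    20: 1220.79
  alpha =    30: 1221.96
  alpha =    40: 1222.38
```

Each distance is the Euclidean norm between the group-mean simulated and
empirical global energy series; the fitted `α` is the grid argmin (here
the synthetic drug effect is mild, so a small `α` fits best;
`pm.compare_variants()` contrasts effect-site vs. plasma concentration
and receptor-weighted vs. uniform spatial maps).

## Command line

```
ctrlenergy synth --out data/ --seed 0            # write a synthetic study
ctrlenergy run-all --data data/ --out results/   # energy → stats → regional
                                                 # → dominance → pksim
```

Individual stages (`energy`, `diversity`, `global-stats`, `regional`,
`dominance`, `pksim`) run standalone; all outputs are TSV + JSON with a
manifest recording seeds and a config hash.

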