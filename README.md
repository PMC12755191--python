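# pulsediv

Response diversity and community stability under pulse disturbances.

Ecological communities can buffer environmental change when their species
respond differently — *response diversity*. This package asks whether that
buffering holds for **pulse** disturbances (an abrupt, temporary temperature
drop) by combining two arms that community ecologists can run end to end:

- **Simulation arm** — multi-species discrete-time Lotka–Volterra
  communities with temperature-dependent growth,
  `N_i(t+1) = N_i(t) exp(r_i(T)(1 − Σ_j α_ij N_j / K_i(T)))`, run as paired
  control (22 °C throughout) and pulse (15 °C for 50 of 750 steps)
  simulations over a factorial design crossing interaction strength
  (`α_ij` sd) with the mean and range of species temperature optima
  (14,175 communities at default settings).
- **Empirical-style arm** — a synthetic generator for meta-analysis-shaped
  experiments (paired control/disturbed series, ≥ 3 sampling times
  normalized to [0, 1]) with exactly known ground truth, feeding the same
  metrics pipeline a real database export would.

Both arms share the core metrics:

- per-species responses: *fundamental* (change in intrinsic growth rate,
  `IGR_disturbed − IGR_control`) and *realised* (AUC over normalized time of
  the response ratio `RR = (treat − con)/(treat + con)` ∈ [−1, 1]);
- community response summaries: mean response, response **dissimilarity**
  (Leinster–Cobbold similarity-sensitive diversity at q = 0, in [1, 2]) and
  response **divergence** (`((max−min) − ||max|−|min||)/(max−min)`,
  in [0, 1]);
- community instability: signed **OEV** (AUC of the total-biomass response
  ratio) with a resistance / resilience / temporal-stability / recovery
  decomposition;
- an unweighted mixed-effects meta-regression
  (`OEV ~ mean + dissimilarity + divergence`, random intercept per
  experiment, unit sampling variances, REML) plus Spearman rank-correlation
  utilities.

See `docs/methods.md` for the model, the metric definitions and their
assumptions, and known limitations.

## Worked example

```python
import numpy as np
from pulsediv import (assemble_community, run_pair, filter_rare_species,
                      realised_responses, fundamental_response,
                      summarise_responses, stability_record)

community = assemble_community(S=10, bopt_mean=21.0, bopt_range=6.0,
                               alpha_sd=0.25, seed=42)
traj = run_pair(community)  # paired 750-step control/pulse simulation

fund = np.array([fundamental_response(sp) for sp in community.species])
mask = filter_rare_species(traj)          # drop very rare species
real = realised_responses(traj)[mask]

print(summarise_responses(fund, "fundamental"))
print(summarise_responses(real, "realised"))
print(stability_record(traj))
```

prints

```
ResponseSummary(basis='fundamental', mean=-0.5070732664317676, dissimilarity=1.7320300591789173, divergence=0.0, n_species=10)
ResponseSummary(basis='realised', mean=-0.04694210307347782, dissimilarity=1.6222410895026216, divergence=0.18025757056135497, n_species=8)
StabilityRecord(oev=-0.0128078119103303, oev_abs=0.013027021340892028, resistance=0.0, resilience=0.0028552638749511196, temporal_stability=20.055820074698076, recovery=1.4850730012221174e-06)
```

A warm-adapted community (optima around 21 °C): every species' intrinsic
growth rate drops under the cold pulse (mean fundamental response −0.51,
divergence 0 — all responses share one sign). Within the community the
damage is milder and more varied (mean realised response −0.05, divergence
0.18: competitive release lets a few species gain), two species were too
rare to score, and total biomass dips below control (OEV −0.013) before
recovering almost completely (recovery ≈ 0 deviation at the final step).

## Command line

```sh
pulsediv simulate --bopt-mean 19 --alpha-sd 0.25 --seed 1 --out series.csv
pulsediv grid     --config design.yaml --out records.csv
pulsediv metrics  --in series.csv --out-prefix measured
pulsediv synth    --out-prefix synthetic --experiments 134 --seed 1
pulsediv meta     --in measured_communities.csv --out fit.json
```

`grid` reads a YAML config (design levels, temperature profile, species
parameters); every output CSV carries a schema-version header and the seeds
used, so runs are reproducible byte for byte.

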