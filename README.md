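# mcdock

Multicanonical dynamic-docking analysis at desk scale: flat-histogram bias
learning, canonical reweighting, PCA free-energy landscapes with
cluster-free-energy ranking, native-contact (R-value) stability statistics,
SASA/RASA burial metrics, restraint-free validation simulations and
binding-pathway extraction — exercised on analytic toy potentials and a
coarse-grained gated-pocket receptor–ligand model instead of all-atom MD.

## The problem

Ligands that bind *cryptic* (hidden) sites — pockets occluded by a gateway
that must transiently open — are invisible to rigid docking.  Dynamic
docking samples the full binding process, but unbiased simulations cannot
cross the gateway's barriers on an accessible timescale.  Multicanonical
sampling (McMD) fixes this by adding an energy-dependent bias b(E) so the
sampled density

    ρ_mc(x) ∝ exp(−[E(x) + b(E(x))] / kB·T_ref)

is approximately **flat in potential energy** across the canonical mean
energies of a target temperature range (here 300–700 K): the walker then
diffuses freely in energy and crosses barriers at will.  Thermodynamics at
any temperature T inside the range is recovered by reweighting each
snapshot with

    w_i ∝ exp(−E_i/kB·T + [E_i + b(E_i)]/kB·T_ref).

From the reweighted ensemble the pipeline builds a free-energy landscape
F(PC1, PC2) = −kB·T·ln(ρ/ρ_max) over the first two principal components of
the ligand coordinates, finds its basins by steepest descent, and ranks
them by cluster free energy CFE = −kB·T·ln(p/p_max).  Each basin's
representative pose is then *validated*: restraint-free canonical replicas
at room and elevated temperature score the fraction of the pose's native
receptor–ligand contacts that survive (the R-value, a Q-value-family
statistic in [0, 1]).  Finally the binding pathway is reconstructed by
chaining nearest-neighbour structures through windows of a dissociation
coordinate λ (λ = 0 is bound), which exposes the gateway mechanism:
encounter at the gate, opening, passage, closure.

The package implements this entire pipeline as a tested library plus a
`mcdock` CLI, with a synthetic-data module (planted clusters,
bias-consistent energy samples, planted unbinding traces with decoys) that
provides exact ground truth for every stage.

## Worked example

Free-energy recovery on a tilted double well (barrier 3 kcal/mol, minima at
±2 Å, tilt 0.4 kcal/mol/Å), entirely from multicanonical sampling:

```python
import numpy as np
from mcdock import KB, make_double_well
from mcdock.engine import SamplingSchedule, learn_bias, run_mcmd
from mcdock.reweighting import canonical_weights, flatness_ratio
from mcdock.utils import count_round_trips

system = make_double_well(barrier=3.0, well_sep=2.0, tilt=0.4)
schedule = SamplingSchedule(n_trajectories=2, prerun_steps=200_000,
                            production_steps=1_000_000,
                            bias_update_iterations=8, snapshot_stride=50,
                            seed=42)
bias = learn_bias(system, schedule)
ensemble = run_mcmd(system, bias, schedule)
print(f"multicanonical frames: {len(ensemble)}")
print(f"flatness ratio (300-700 K range): "
      f"{flatness_ratio(ensemble, bias, n_bins=20):.2f}")
x = np.array([s.coords[0, 0] for s in ensemble])
print(f"barrier round trips: {count_round_trips(x, -1.0, 1.0)}")
for T in (300.0, 500.0, 700.0):
    we = canonical_weights(ensemble, bias, T)
    p_left = float(np.sum(we.weights[x < 0]))
    dF = -KB * T * np.log((1 - p_left) / p_left)
    print(f"T={T:.0f} K: P(left well)={p_left:.3f}  "
          f"ΔF(left→right)={dF:.3f} kcal/mol")
```

prints

```
multicanonical frames: 40000
flatness ratio (300-700 K range): 0.72
barrier round trips: 3313
T=300 K: P(left well)=0.924  ΔF(left→right)=1.492 kcal/mol
T=500 K: P(left well)=0.806  ΔF(left→right)=1.415 kcal/mol
T=700 K: P(left well)=0.726  ΔF(left→right)=1.357 kcal/mol
```

The energy histogram is flat (ratio 0.72 ≥ 0.5) across the target range,
the walker crosses the barrier thousands of times, and a *single* biased
run yields the well free-energy difference at three temperatures at once —
direct 1D quadrature of the Boltzmann integrals gives 1.517 / 1.449 /
1.398 kcal/mol at the same temperatures (the two-trajectory estimates above
sit within their sampling error; the six-trajectory run in
`scripts/acceptance.py` lands within 0.01 kcal/mol).  ΔF shrinks with T because the
tilt-induced population imbalance washes out as kB·T grows.

The full docking pipeline on the gated-pocket model runs from the shell:

```bash
mcdock pipeline --outdir run1 --seed 7
```

which learns the bias, samples, reweights to 300 K, writes the FEL
(`fel.csv`), the CFE-ranked cluster table (`clusters.csv`), per-pose
metrics (RASA, R-value, gateway distance), the validation report
(`validation.csv`) and the binding path (`path.csv`, `path.pdb`).

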