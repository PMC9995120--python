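# pocketensemble

Quantifying **cryptic-pocket opening** in protein conformational ensembles
and predicting **ligand binding affinity** by Boltzmann-weighted ensemble
docking over a Markov state model (MSM).

Many drug binding sites — such as the blebbistatin pocket of myosin-II
motors — are closed in every ligand-free experimental structure and only
open transiently in solution. `pocketensemble` is for computational
structural biologists who have (or can simulate) a conformational ensemble
of such a protein and want to answer two questions:

1. **How often is the pocket open at equilibrium?**
   Per-frame pocket volumes are measured with a grid-based
   (LIGSITE-style) detector at the site of a reference holo ligand, and
   reweighted to equilibrium with an MSM. The opening probability is

   *p*<sub>open</sub> = Σ<sub>f : v<sub>f</sub> ≥ v<sub>holo</sub></sub> π<sub>s(f)</sub>/N<sub>s(f)</sub>,

   the total equilibrium weight of frames whose ligand-site pocket volume
   v<sub>f</sub> reaches the volume v<sub>holo</sub> of the ligand-bound
   crystal structure (π<sub>s</sub> is the stationary probability of the
   MSM state the frame belongs to, N<sub>s</sub> the number of frames in
   that state).

2. **How strongly does the ligand bind the ensemble?**
   Docking scores g<sub>f</sub> (kcal/mol) computed against individual
   conformations are aggregated into one ensemble binding free energy

   ΔG<sub>total</sub> = −RT ln Σ<sub>f</sub> (π<sub>s(f)</sub>/N<sub>s(f)</sub>) e<sup>−g<sub>f</sub>/RT</sup>,

   which directly prices the configurational entropy of pocket opening:
   rarely-open ensembles pay their small π in the sum. The result converts
   to a standard-state K<sub>d</sub> = e<sup>ΔG/RT</sup> · 1 M and can be
   compared (R², RMSE) against experimental IC50/K<sub>i</sub> data
   converted to free energies under a mixed-inhibition scheme.

The MSM itself is built the standard way: sin/cos-encoded binding-site
dihedrals → tICA with commute mapping (90 % kinetic variance) → k-means
microstates (k selected by trajectory-split cross-validation with the
rank-10 VAMP-2 score) → reversible maximum-likelihood transition matrix,
with implied-timescale lag selection and a 250-trial trajectory bootstrap
for error bars.

A first-class synthetic module generates cage structures with known
cavities and hidden-Markov reference ensembles whose stationary
distribution, p_open and aggregate ΔG are available in closed form, so the
entire pipeline is testable without molecular dynamics or a docking engine.

## Worked example

Recover known ground truth from a synthetic three-state pocket ensemble
(20 trajectories × 10 000 frames, saved every 20 ps):

```python
import io
from pocketensemble.synthetic import (EnsembleSpec, simulate_reference_ensemble,
                                      make_docking_table)
from pocketensemble.kinetics import fit_tica, cluster_assign, fit_msm, frame_weights
from pocketensemble.pocket_stats import p_open
from pocketensemble.msm_dock import (sample_docking_structures,
                                     ingest_docking_scores,
                                     aggregate_binding_free_energy)

spec = EnsembleSpec(seed=1)
features, volumes, hidden, truth = simulate_reference_ensemble(spec)

tica = fit_tica(features, lag=5)               # 100 ps at the 20 ps save rate
model, dtrajs = cluster_assign(tica.transform(features), k=10, seed=1,
                               frame_interval_ps=spec.frame_interval_ps)
msm = fit_msm(dtrajs, lag=5)
weights = frame_weights(msm, dtrajs)

opening = p_open(volumes, weights, truth.threshold)
print(f"p_open      = {opening.p_open:.3f}   (ground truth {truth.p_open_true:.3f})")

samples = sample_docking_structures(msm, dtrajs, seed=1)
scores, dG_true = make_docking_table(spec, hidden, samples)
buf = io.StringIO(); scores.to_csv(buf, index=False); buf.seek(0)
records = ingest_docking_scores(buf, dtrajs, msm)
estimate = aggregate_binding_free_energy(records, msm, samples)
print(f"dG_total    = {estimate.dG_total:.2f} kcal/mol   (ground truth {dG_true:.2f})")
print(f"K_d         = {estimate.K_d * 1e6:.2f} uM")
```

Output:

```
p_open      = 0.183   (ground truth 0.188)
dG_total    = -7.20 kcal/mol   (ground truth -7.23)
K_d         = 8.35 uM
```

The estimated opening probability is within 0.005 of the closed-form truth
and the aggregated free energy within 0.03 kcal/mol — the pipeline's
statistical error at this ensemble size, not a bias.

On real data the same stages run from the command line against PDB/XTC/DCD
inputs and external docking-score tables:

```sh
pocketensemble contacts --structure holo.pdb --ligand-resname BIT \
    --cutoff 5.0 --out contacts.csv
pocketensemble run --config run.yaml --stages volumes,msm,popen,sample,aggregate
```

`run.yaml` holds the input paths, grid parameters, tICA/MSM lags, the
cluster count, temperature (default 310 K) and a mandatory seed; every run
writes a checksummed `manifest.json`, and reruns with unchanged inputs
reproduce identical checksums.

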