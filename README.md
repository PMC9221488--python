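# vinecmc

Corticomuscular functional coupling networks from multichannel EEG and
surface-EMG recordings, modelled with GARCH-filtered R-vine copulas.

## The problem

During voluntary movement, oscillations in the sensorimotor cortex (EEG) and
the electrical activity of the contracting muscles (sEMG) are statistically
coupled. Linear tools — coherence, Granger causality — capture only part of
this dependence, which is nonlinear and non-Gaussian. `vinecmc` implements a
copula-based alternative for researchers who want a *functional network* view
of corticomuscular coupling: nodes are channels (e.g. Cz, C3, …, FDS, BR, …),
edges are rank-dependence strengths, and graph metrics summarize how the
network reorganizes across motor tasks.

## The model

For each channel the series is filtered by an AR(1) mean equation with
GJR-GARCH(1,1) conditional variance and Student-t innovations:

    x_t     = c0 + c1 x_{t-1} + a_t,          a_t = sigma_t * xi_t
    sigma_t^2 = omega + alpha a_{t-1}^2 + beta sigma_{t-1}^2
                + gamma a_{t-1}^2 1{a_{t-1} < 0},
    xi_t    ~ t_d  (standardized to unit variance)

The probability-integral transform u_t = F_d(xi_t) of the standardized
residuals gives uniform margins. Cross-channel dependence is then a p-variate
copula, factorized as a regular vine (pair-copula construction): tree 1 is
the maximum spanning tree on |Kendall tau| weights (Prim's algorithm); each
edge carries a bivariate copula (Gaussian, Student-t, Clayton, Gumbel, Frank,
rotations, or independence) selected by AIC/BIC; conditional
pseudo-observations from the h-functions h(u|v) = ∂C(u,v)/∂v feed the next
tree, under the proximity condition, until one edge remains.

The network is built from the pairwise Kendall-tau matrix: |tau| is min–max
normalized separately within the EEG–EEG, EMG–EMG and EEG–EMG blocks,
binarized at the largest threshold t ∈ {0, 0.05, …, 1} whose average node
degree still satisfies K ≥ 2 ln N, and summarized by characteristic path
length L, clustering coefficient C = mean_i 2E_i/(K_i(K_i−1)), and core
(maximum-degree) nodes. A bivariate spectral Granger-causality baseline
(Geweke measure from an AIC-selected VAR) is included for comparison.

Because matched EEG/sEMG recordings cannot be redistributed, the package
ships a first-class synthetic-data generator with a known chain+bridge vine
truth and GARCH margins, so every stage is testable end to end.

## Worked example

```python
from vinecmc import make_scenario, simulate, RunConfig, run_pipeline

conds = {}
for k, name in enumerate(("HO", "HC")):          # two task conditions
    sc = make_scenario(n_eeg=4, n_emg=3, tau_within=0.5, tau_cross=0.15,
                       n_samples=3000, seed=10 + k)
    conds[name] = simulate(sc)[0]

res = run_pipeline(RunConfig(conditions=conds, apply_preproc=False,
                             run_gc=False))
print(f"shared threshold: {res['threshold']:.2f}")
for name, d in res["conditions"].items():
    m = d["metrics"]
    print(f"{name}: L={m['L']:.3f}  C={m['C']:.3f}  "
          f"core={d['network'].core_nodes}  bridge={d['tree1']['bridge_edges']}")
for e in res["conditions"]["HO"]["tree1"]["edges"]:
    print(f"  {e['pair'][0]:>5s} -- {e['pair'][1]:<5s} "
          f"{e['family']:<10s} tau={e['tau']:+.2f}")
```

prints

```
shared threshold: 0.25
HO: L=1.286  C=0.843  core=['EEG3']  bridge=[('EEG3', 'EMG1')]
HC: L=1.381  C=0.714  core=['EEG2', 'EEG3', 'EMG1', 'EMG2']  bridge=[('EEG3', 'EMG1')]
   EEG1 -- EEG2  gaussian   tau=+0.51
   EEG2 -- EEG3  gaussian   tau=+0.50
   EEG3 -- EEG4  gaussian   tau=+0.49
   EEG3 -- EMG1  gaussian   tau=+0.14
   EMG1 -- EMG2  gaussian   tau=+0.50
   EMG2 -- EMG3  gaussian   tau=+0.51
```

The fitted first vine tree recovers the planted truth exactly: Gaussian
chains within each modality (tau ≈ 0.5), one weaker EEG–EMG bridge
(tau ≈ 0.15) at the C3-like position, which is also the core node. L and C
describe the thresholded network; the shared threshold is the densest one
satisfying the average-degree rule across both conditions.

A CLI mirrors the library: `vinecmc simulate`, `vinecmc preprocess`,
`vinecmc granger`, and `vinecmc run --config run.yaml`.

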