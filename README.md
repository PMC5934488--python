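# restnet

Resting-state functional brain network analysis for source-space EEG:
band-limited **lagged-coherence** connectivity over an 84-node Brodmann-area
parcellation, **weighted small-world analysis** (Small-World Propensity),
**minimum-spanning-tree** topology metrics, and **two-group permutation
inference** with FDR correction.

The package is aimed at clinical EEG studies that compare resting-state
functional networks between a patient group and matched controls (the
built-in study design is 19 cases vs 52 controls, e.g. adults who stutter
vs fluent speakers), working downstream of source localization: the inputs
are per-subject ROI time series or precomputed coherence matrices.

## The analysis

**Connectivity.** For each subject, cross-spectra are estimated as the
mean Hann-tapered periodogram over ≥ 4 s artifact-free epochs (250 Hz,
1024-point transforms). Lagged coherence between ROIs x and y at frequency
f,

```
LagC_xy(f) = Im(S_xy)² / (S_xx S_yy − Re(S_xy)²),
```

keeps only the non-instantaneous part of the cross-spectrum, so zero-lag
volume-conduction leakage cancels. Band values (theta 4–8, alpha 8–12,
beta1 12–20, beta2 20–30 Hz) are means over the bins in each band, giving
one symmetric 84×84 weighted matrix per subject and band.

**Small-world analysis (weighted, no thresholding).** With Onnela
clustering C and inverse-weight characteristic path L, the Small-World
Propensity compares the observed graph with a weight-matched ring lattice
and the mean of 50 weight-permuted random surrogates:

```
ΔC = (C_latt − C_obs) / (C_latt − C_rand)      (clamped to [0, 1])
ΔL = (L_obs − L_rand) / (L_latt − L_rand)      (clamped to [0, 1])
φ  = 1 − sqrt((ΔC² + ΔL²) / 2)
```

φ > 0.6 classifies a network as small-world.

**MST metrics.** The minimum spanning tree of the distance graph d = 1/w
(the backbone of strongest coherences) is summarized by maximum
betweenness centrality (ordered-pair convention, ceiling (n−1)(n−2) =
6806), nodal degree, leaf fraction, diameter, and eccentricity.

**Group statistics.** Each of the 7 global indices (SWP, L, C, max BC,
leaf fraction, diameter, average eccentricity) × 4 bands = 28 cells is
tested with a label-permutation Welch-t test (5000 shuffles by default,
add-one p-values), with Benjamini–Hochberg FDR across the 28 cells. Nodal
BC / eccentricity follow-ups run only in bands flagged globally, FDR
across the 84 ROIs per family.

Because resting EEG recordings of this kind are not publicly deposited,
the package ships a synthetic-cohort generator (ring-lattice coherence
backbone with rewired shortcuts and controllable group effects on
clustering, path length, diameter and hub betweenness) so the entire
pipeline is testable end-to-end.

## Worked example

Inject a strong theta-band clustering deficit into the case group of a
synthetic 19 + 52 cohort and run the full analysis:

```python
from restnet.pipeline import PipelineConfig, run_pipeline
from restnet.stats import results_to_frame

cfg = PipelineConfig(
    mode="synthetic", seed=42, n_perm=2000, n_null=10,
    effects=[{"band": "theta", "target": "clustering",
              "magnitude": 0.5, "direction": -1}],
)
report = run_pipeline(cfg)
frame = results_to_frame(report.global_results)
cols = ["index", "band", "t_obs", "p", "q", "mean_x", "mean_y"]
print(frame.loc[frame.q < 0.05, cols].round(4).to_string(index=False))
```

prints

```
     index  band    t_obs      p     q  mean_x  mean_y
       swp theta   3.8071 0.0005 0.007  0.7021  0.6836
clustering theta -96.1293 0.0005 0.007  0.0287  0.0394
```

The injected deficit is recovered: case subjects (`mean_x`) have lower
theta clustering than controls (`mean_y`), significant after FDR
(q = 0.007); the same weight change makes the case networks slightly
*more* small-world (higher φ), because weakening the diffuse background
sharpens the lattice-vs-random contrast. The other 26 cells stay null.

The same run from the shell:

```
$ restnet run-all --config theta_deficit.yaml
28 global tests (2 significant at q < 0.05); 0 nodal tests; report in report/
```

CLI verbs: `simulate` (write a synthetic cohort), `connect` (epoch CSVs →
band adjacency matrices), `metrics` (graph indices of one matrix),
`compare` (group tests on a metrics table), `run-all` (everything, from a
YAML config).

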