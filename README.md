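# traitconn

Graph-theoretical analysis of resting-state functional connectomes and their
association with dimensional autistic traits in neurotypical adults.

Autistic traits vary continuously in the general population, and several
models of the autistic brain predict reduced long-range functional
connectivity that should leave a signature on network topology even in
people without a diagnosis. `traitconn` implements the full analysis chain
needed to test that prediction on resting-state fMRI: per-subject wavelet
correlation networks, threshold-free (cost-integrated) topological metrics,
population-level statistical parametric networks, probability-weighted
regional diffusion anisotropy, and GLM association of all of these with
trait questionnaires (ASSQ, SRS) under FDR control. A first-class synthetic
cohort generator reproduces the statistical structure of such a study
(127 subjects, 149 regions, 260 BOLD volumes at TR = 2.5 s), so every stage
is testable without any imaging download.

## Method

For each subject with regional BOLD series, connectivity between regions
*i* and *j* is the Pearson correlation r_ij of their level-3 maximum-overlap
discrete wavelet transform (MODWT, LA(8) filter) coefficients — the
0.025–0.05 Hz band at TR = 2.5 s — soft-thresholded into edge weights
w_ij = |r_ij|². Graph topology is computed on binary graphs G^k obtained by
keeping the m = round(k·M_C) heaviest edges at wiring cost k, where
M_C = N(N−1)/2:

- degree k_i = Σ_j a_ij
- nodal efficiency e_i = (N−1)⁻¹ Σ_{j≠i} 1/l_ij (1/∞ = 0 for unreachable pairs)
- global efficiency E_g = mean_i e_i
- local efficiency E_l = mean_i E_g(G_i), G_i the neighbour subgraph of *i*

Because any single cost threshold is arbitrary, each metric X is
cost-integrated: X* = E[X(G^k)] with k uniform on [0.05, 0.95], estimated by
Monte Carlo (200 draws). Population-level edge structure is summarised by
the mean statistical parametric network, z^e = (r̄^e − r̄)/sd(r) with grand
statistics pooled over subjects and edges. Associations with the trait
scores use per-region OLS (design 1: intercept + ASSQ + SRS + age + gender;
design 2: + verbal IQ), a joint F-contrast on the trait terms, effect sizes
η_p² = F·dfh/(F·dfh + dfe), and Benjamini–Hochberg FDR at α = 0.05 across
the region family.

## Worked example

Simulate a reduced cohort (60 subjects, 40 regions) with the default
injected trait effects, run the full pipeline, and inspect the hub region's
degree association:

```python
from traitconn import PipelineConfig, SyntheticCohortConfig, run_pipeline

config = PipelineConfig(
    cohort=SyntheticCohortConfig(n_subjects=60, n_regions=40, seed=0),
    mc_samples=200,
    metric_set=frozenset({"degree", "nodal_efficiency", "global_efficiency"}),
    seed=7,
)
result = run_pipeline(config)
table = result.associations["degree"]
row = table.iloc[config.cohort.hub_region]
```

Output:

```
hub region:        l-R001
joint trait F:     9.28  (p = 3.38e-04)
partial eta^2:     0.252
B_ASSQ:            -0.153
FDR significant:   True
regions FDR-hit:   1 of 40
cohort E_g*:       0.705 +/- 0.015
```

The generator weakens the designated hub's band-limited coupling in
high-trait subjects; the pipeline recovers exactly that region (1 of 40
FDR-significant) with a negative ASSQ slope on cost-integrated degree —
the joint 2-df trait contrast is significant well past the BH threshold.
Cohort-mean cost-integrated global efficiency sits at 0.705, in the
small-world regime expected for modular networks with long-range shortcuts.

A command-line interface mirrors the stages (`traitconn simulate |
connectivity | topology | spn | associate | run-all`); note that `run-all`
at the full default scale (127 subjects, 149 regions, all four metrics
including local efficiency) is a compute-heavy job best reduced via a JSON
config for interactive use.

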