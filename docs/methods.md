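# Methods

This note records the models, numerical choices and known limitations of
`traitconn`, in the spirit of a statistical software vignette. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Wavelet connectivity

Regional BOLD series are decomposed with a four-level maximum-overlap
discrete wavelet transform (MODWT) using the Daubechies least-asymmetric
length-8 filter (LA(8); PyWavelets' `sym4` taps rescaled by 1/√2). The
MODWT is implemented directly as the standard circular-filtering pyramid:
PyWavelets' undecimated `swt` requires the series length to be divisible by
2^J, which a 260-volume acquisition is not, and the circular MODWT is the
variant with the exact energy identity Σ_j‖W_j‖² + ‖V_J‖² = ‖X‖² and exact
shift covariance — both are enforced as tests in lieu of a second
implementation.

Level k of the transform covers [1/(2^(k+1)·TR), 1/(2^k·TR)] Hz; at
TR = 2.5 s the four levels are 0.1–0.2, 0.05–0.1, 0.025–0.05 and
0.0125–0.025 Hz, and level 3 is the conventional resting-state band.
Connectivity is the Pearson correlation of level-3 coefficients. Boundary
(circularly wrapped) coefficients are *retained* by default; an
`exclude_boundary` flag drops the standard count (2^k−1)(L−1) per level.
Retention is the default because the wrapped coefficients still carry
band-limited signal and excluding them discards ~40% of a 260-sample series
at level 3; both behaviours are exposed since the choice is not canonical.

Soft thresholding maps correlations to weights w = |r|² (the squaring makes
the absolute value redundant; it is kept for clarity). A region with a
constant signal has no defined correlation and raises an error naming the
region, rather than propagating NaN.

Regional series extraction from 4-D volumes uses probabilistic labels
thresholded at p > 0.25; voxels claimed by several regions go to the
highest-probability region, ties to the lower region index. The surviving
probabilities act as weights both for BOLD averaging and for regional
fractional-anisotropy extraction (weighting uses the *post*-threshold
probabilities; sub-threshold voxels contribute nothing).

## Graph model and topology

All metrics operate on undirected binary graphs. Wiring cost is the mean
off-diagonal adjacency (edge count over M_C = N(N−1)/2; mean weight for
weighted matrices). Efficiencies follow Latora–Marchiori: unreachable pairs
contribute 1/∞ = 0, so every metric is defined on the disconnected graphs
that sparse thresholding produces; nodes with fewer than two neighbours
contribute local efficiency 0 (their neighbour subgraph has no pairs).
Shortest paths are computed with scipy's csgraph BFS; on graphs of ≤7 nodes
every metric is verified against a naive enumeration oracle.

Thresholding a weighted network at cost k keeps the m = round(k·M_C)
heaviest edges (round-half-to-even), ties broken deterministically by
ascending (i, j) index through a stable sort; with real-valued wavelet
correlations, ties have measure zero, and a seeded random tie-break is
available by flag.

Cost integration draws edge counts m uniformly (with replacement by
default) from [⌈0.05·M_C⌉, ⌊0.95·M_C⌋] and averages each requested metric
over the corresponding G^k, with one shared cost sample sequence per call
so nodal and global integrands see identical graph realisations. 200 draws
give a Monte-Carlo standard error of roughly 0.01 on E_g* for the fixture
networks used in the tests; the test suite checks the estimate against the
exhaustive cost-grid average within its analytic MC error rather than
asserting a fixed sub-SE reproducibility between independent runs, which
plain Monte Carlo cannot provide.

Reference networks for small-world validation: uniform random graphs with
exactly round(k·M_C) edges, and ring lattices filled ring-by-ring with a
deterministic residual ring (the "regularly distributed edges"
construction is underspecified in the literature; the ring lattice is this
package's documented choice). One saturation effect matters when comparing
efficiency-by-cost curves: whenever two graphs have equal edge count and
diameter ≤ 2 (dense regime, roughly cost ≥ 0.5), E_g = (1 + k)/2 for both
*identically* — the curves merge exactly, so ordering claims are only
meaningful in the sparse regime and are tested strictly there.

## Statistical parametric network

The mean SPN standardises each edge's subject-mean correlation by the grand
mean and grand SD pooled over subjects × upper-triangle edges (each
undirected edge counted once); by construction the edge z-scores average to
zero. Nominal p-value thresholds map to one-sided upper-tail
standard-normal quantiles by default (z > 2.576 at p = 0.005), with a
two-sided option. Connection profiles list a seed region's supra-threshold
neighbours in descending strength; percentile thresholds use linear
interpolation between order statistics. Profiles stored at printed
precision (e.g. two decimals) are thresholded at that precision with an
inclusive comparison — applying a three-decimal cut-off to two-decimal data
would silently drop boundary entries.

## GLM association

Each response (per-region cost-integrated metric, global efficiency, or
regional FA; one observation per subject) is fit by OLS. A subject-level
random effect is unidentifiable with a single observation per subject and
region, and is absorbed into the residual. Design 1 uses intercept + ASSQ +
SRS + age + gender (0 = female, 1 = male); design 2 adds verbal IQ. The
trait effect is a joint 2-df F-contrast on (ASSQ, SRS) by default — the
reported tables' two-slope structure supports this reading — with a 1-df
combined-standardised-score contrast available by flag. Effect sizes use
η_p² = F·dfh/(F·dfh + dfe), which equals SS_effect/(SS_effect + SS_error)
for single-df contrasts (tested numerically). Region families are corrected
with the hand-implemented Benjamini–Hochberg step-up rule at α = 0.05,
cross-checked against statsmodels. `fit_glm` (statsmodels) and the
vectorised family fit are kept as two routes and tested to agree.

## Synthetic cohort generator

The generator emulates the study conditions: n = 127 subjects, 149 regions,
260 timepoints at TR = 2.5 s.

**Phenotypes** come from a latent Gaussian copula over (verbal IQ,
performance IQ, ASSQ, SRS) followed by marginal transforms: Gaussian IQ
marginals (verbal 106.9 ± 13), a rounded lognormal clipped to 0–39 for ASSQ
(mean 5.2, SD 7.9; strongly right-skewed) and a rounded Gaussian clipped to
0–195 for SRS (27.2 ± 19.4). Target observed correlations are
corr(VIQ, PIQ) = 0.55, corr(VIQ, ASSQ) = −0.393, corr(VIQ, SRS) = −0.343;
the ASSQ/SRS correlation is not pinned by any published value and defaults
to 0.6. Latent correlations involving ASSQ are divided by an attenuation
factor of 0.82, calibrated once by large-sample simulation of the marginal
transform, so the *observed* correlations hit their targets (verified at
n = 5000 in the tests). Age is truncated-normal 35.8 ± 12.8 on 18–65 and
gender Bernoulli with p(male) = 78/127, both independent of the traits.

**BOLD** series are mixtures of band-limited (0.025–0.05 Hz) unit-variance
latent signals: one per community (8 communities by default, regions split
evenly), one weak global signal (amplitude 0.3), and "long-range" pair
signals (1.2% of M_C random inter-community pairs, amplitudes 0.6–1.0)
plus white noise (SD 1). Community amplitudes are heterogeneous
(0.4–1.3), which — together with the pair shortcuts — makes the
cost-thresholded graphs connected and small-world even at 5% cost instead
of decomposing into isolated modules.

Trait effects act on *coupling*: a subject's shared-signal loadings are
scaled and the lost variance is replaced by private band-limited noise, so
signal power is preserved and only inter-regional correlations move. This
matters because cost-thresholded metrics depend solely on the *ranking* of
edge weights; a uniform amplitude change would be invisible to them. The
designated hub region (index 0) belongs to community 1 and additionally
couples to two other communities; its loadings shrink by
`effect_sizes["hub_coupling"]` (default −0.4) per SD of the combined trait
score (mean of standardised ASSQ and SRS, restandardised). All loadings
shrink by `effect_sizes["local_efficiency"]` (default −0.1), degrading the
rank structure toward noise and hence whole-network E_l*. Regional FA is
region-baseline (0.30–0.60) plus N(0, 0.04) subject noise; in the
designated effect regions the standardised FA has correlation
`effect_sizes["fa"]` (default −0.4) with the trait score by construction,
giving clean parameter-recovery semantics. Defaults were chosen once to
mirror the magnitude of the motivating study's detected effects (η_p² ≈
0.11 for the hub, i.e. |r| ≈ 0.3–0.5 on the metric scale).

**Label volumes** place region centres on a 3-D lattice two voxels apart
with Gaussian probability bumps (p = 1 at the centre), producing genuine
partial overlaps for the p > 0.25 / highest-probability-wins logic to
resolve. Helper functions synthesise 4-D BOLD and 3-D FA volumes from the
resolved assignment to exercise the extraction path.

What the generator does **not** emulate: hemodynamic response shape, head
motion, physiological noise, spatial autocorrelation of real voxel data,
anatomically realistic atlas geometry, or scanner drift. Passing tests
therefore demonstrate the correctness and statistical calibration of the
*analysis*, not robustness to real-data artefacts.

## Problem sizes and determinism

The default configuration reproduces the study scale; at that scale
cost-integrating local efficiency over 200 draws for 127 subjects is a
cluster-sized job. The test suite and the acceptance script therefore run
the statistically demanding checks at reduced scale (20–50 regions,
5–10-subject curve cohorts, 50 power replicates), sizes chosen so each
check's Monte-Carlo error is well below its decision margin. Every stage
takes an explicit seed; a single pipeline seed fans out to per-stage child
seeds via `SeedSequence`, so identical configurations reproduce identical
outputs byte for byte (tested).

Monte-Carlo acceptance checks that verify a *bound* (e.g. BH keeping the
false-discovery proportion at or below α under a full null, where the
per-family FDP is Bernoulli(α)) are tested by exact one-sided binomial
tests on the replicate counts rather than by comparing a noisy sample mean
to the bound directly; the test is calibrated at level 0.01.

## Known limitations

- OLS ignores any within-subject dependence structure across regions; the
  family-wise correction treats regions as independent, which is
  conservative in the intended direction but not exact.
- The regular-network construction and the boundary-coefficient policy are
  documented choices, not canonical definitions.
- The mean SPN is descriptive; no inferential SPN variants (edge-wise
  permutation tests, subgroup difference SPNs) are provided.
- The generator's trait effects are linear in the standardised trait score;
  threshold or interaction effects are out of scope.
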