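"""Synthetic cohort generator: phenotypes, BOLD, label volumes and FA.

Emulates the statistical structure the downstream analysis assumes for a
resting-state cohort of neurotypical adults: ~127 subjects, 149 brain
regions, 260 BOLD timepoints at TR = 2.5 s, modular band-limited
inter-regional covariance, a phenotype battery (age, gender, WASI verbal and
performance IQ, ASSQ and SRS trait scores) with the observed correlation
structure, and configurable trait effects injected into the network
(hub-coupling reduction), the whole-brain local efficiency, and regional
diffusion anisotropy.

Phenotypes come from a latent Gaussian copula followed by marginal
transforms: IQ scores and SRS are (truncated/rounded) Gaussian, ASSQ is a
rounded, clipped lognormal, reproducing its right-skewed distribution.  The
latent correlations involving ASSQ are pre-compensated for the attenuation
the skewed marginal induces on the observed Pearson correlation (factor
~0.82, calibrated by large-sample simulation of the marginal transform), so
the generated cohort hits the target observed correlations.

Regional BOLD series are mixtures of band-limited (0.025-0.05 Hz) latent
signals: one shared signal per community, one weak global signal, and a set
of "long-range" pair signals connecting random region pairs across
communities.  The heterogeneous community amplitudes and the long-range
pairs give the thresholded networks brain-like small-world structure (high
clustering from the communities, short paths from the cross links) at every
wiring cost.  Trait effects scale coupling *amplitudes* — not correlations
directly — so the wavelet stage is genuinely exercised.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortConfig",
    "LabelVolumeSet",
    "generate_phenotypes",
    "combined_trait_score",
    "generate_bold",
    "generate_label_volumes",
    "generate_fa",
    "default_region_names",
    "bold_to_volume",
    "fa_to_volume",
]

#: Attenuation of a Pearson correlation against the rounded, clipped
#: lognormal ASSQ marginal relative to the latent Gaussian correlation
#: (calibrated once by large-sample simulation of the marginal transform).
_ASSQ_ATTENUATION = 0.82

# Cohort marginals (mean, sd) on the questionnaire / WASI scales.
_VIQ_MEAN, _VIQ_SD = 106.9, 13.0
_PIQ_MEAN, _PIQ_SD = 109.7, 13.5
_ASSQ_MEAN, _ASSQ_SD = 5.2, 7.9
_SRS_MEAN, _SRS_SD = 27.2, 19.4
_AGE_MEAN, _AGE_SD = 35.8, 12.8
_P_MALE = 78 / 127


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_sizes`` holds the injected standardized trait effects:

    - ``hub_coupling``: multiplicative slope of the designated hub region's
      coupling amplitudes per SD of the combined trait score (negative
      values weaken the hub's connectivity in high-trait subjects);
    - ``local_efficiency``: multiplicative slope applied to *all* signal
      amplitudes, producing a small whole-network effect;
    - ``fa``: correlation between the combined trait score and FA in the
      designated effect regions.
    """

    n_subjects: int = 127
    n_regions: int = 149
    n_timepoints: int = 260
    tr: float = 2.5
    n_communities: int = 8
    module_partition: list[np.ndarray] | None = None
    hub_region: int = 0
    fa_effect_regions: tuple[int, ...] | None = None
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "hub_coupling": -0.4,
            "local_efficiency": -0.1,
            "fa": -0.4,
        }
    )
    noise_sd: float = 1.0
    assq_srs_corr: float = 0.6
    long_range_fraction: float = 0.012
    grid_shape: tuple[int, int, int] | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_regions", "n_timepoints", "n_communities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if self.tr <= 0 or self.noise_sd < 0:
            raise ValueError("tr must be positive and noise_sd non-negative")
        if not 0 <= self.hub_region < self.n_regions:
            raise ValueError("hub_region outside region range")
        if self.fa_effect_regions is not None:
            bad = [r for r in self.fa_effect_regions if not 0 <= r < self.n_regions]
            if bad:
                raise ValueError(f"fa_effect_regions outside region range: {bad}")
        if self.module_partition is not None:
            flat = np.sort(np.concatenate([np.asarray(m) for m in self.module_partition]))
            if not np.array_equal(flat, np.arange(self.n_regions)):
                raise ValueError("module_partition must cover every region exactly once")

    @property
    def fa_effect_indices(self) -> tuple[int, ...]:
        """Regions carrying the trait->FA effect (two bilateral pairs by default)."""
        if self.fa_effect_regions is not None:
            return tuple(self.fa_effect_regions)
        r = self.n_regions
        cand = [int(0.27 * r), int(0.27 * r) + 1, int(0.40 * r), int(0.40 * r) + 1]
        keep = sorted({c for c in cand if 0 <= c < r and c != self.hub_region})
        return tuple(keep) or ((r - 1,) if r - 1 != self.hub_region else (0,))

    @property
    def partition(self) -> list[np.ndarray]:
        if self.module_partition is not None:
            return [np.asarray(m) for m in self.module_partition]
        return np.array_split(np.arange(self.n_regions), self.n_communities)

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator fanned out from the global seed."""
        root = 0 if self.seed is None else int(self.seed)
        key = zlib.crc32(stage.encode("ascii"))
        child = np.random.SeedSequence(root, spawn_key=(key,))
        return np.random.default_rng(child)

    def with_seed(self, seed: int) -> "SyntheticCohortConfig":
        return replace(self, seed=seed)


def default_region_names(n_regions: int = 149) -> list[str]:
    """Generic hemisphere-plus-index region labels (l-R001, r-R001, ...)."""
    return [
        f"{'l' if i % 2 == 0 else 'r'}-R{i // 2 + 1:03d}" for i in range(n_regions)
    ]


# --------------------------------------------------------------------------
# phenotypes


def _latent_correlation(assq_srs_corr: float) -> np.ndarray:
    """Latent copula correlation for (viq, piq, assq, srs)."""
    va = -0.393 / _ASSQ_ATTENUATION
    vs = -0.343
    as_ = np.clip(assq_srs_corr / _ASSQ_ATTENUATION, -0.97, 0.97)
    c = np.array(
        [
            [1.0, 0.55, va, vs],
            [0.55, 1.0, 0.55 * va, 0.55 * vs],
            [va, 0.55 * va, 1.0, as_],
            [vs, 0.55 * vs, as_, 1.0],
        ]
    )
    # clip tiny negative eigenvalues if an extreme assq_srs_corr breaks PSD
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < 1e-9:
        vals = np.clip(vals, 1e-9, None)
        c = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def generate_phenotypes(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Phenotype table with the cohort's trait correlation structure.

    Columns: subject_id, age, gender ("female"/"male"), verbal_iq,
    performance_iq, full_iq, assq, srs.
    """
    rng = config.stage_rng("phenotypes")
    n = config.n_subjects
    corr = _latent_correlation(config.assq_srs_corr)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")

    viq = np.round(_VIQ_MEAN + _VIQ_SD * z[:, 0])
    piq = np.round(_PIQ_MEAN + _PIQ_SD * z[:, 1])
    sigma2 = np.log(1.0 + (_ASSQ_SD / _ASSQ_MEAN) ** 2)
    mu = np.log(_ASSQ_MEAN) - sigma2 / 2.0
    assq = np.clip(np.round(np.exp(mu + np.sqrt(sigma2) * z[:, 2])), 0, 39)
    srs = np.clip(np.round(_SRS_MEAN + _SRS_SD * z[:, 3]), 0, 195)
    age = np.clip(np.round(rng.normal(_AGE_MEAN, _AGE_SD, size=n)), 18, 65)
    gender = np.where(rng.random(n) < _P_MALE, "male", "female")

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age.astype(int),
            "gender": gender,
            "verbal_iq": viq.astype(int),
            "performance_iq": piq.astype(int),
            "full_iq": np.round((viq + piq) / 2).astype(int),
            "assq": assq.astype(int),
            "srs": srs.astype(int),
        }
    )


def combined_trait_score(phenotypes: pd.DataFrame) -> np.ndarray:
    """Standardized mean of within-cohort standardized ASSQ and SRS scores."""
    z_a = (phenotypes["assq"] - phenotypes["assq"].mean()) / phenotypes["assq"].std()
    z_s = (phenotypes["srs"] - phenotypes["srs"].mean()) / phenotypes["srs"].std()
    combo = (z_a + z_s) / 2.0
    return ((combo - combo.mean()) / combo.std()).to_numpy()


# --------------------------------------------------------------------------
# network architecture and BOLD


@dataclass
class _Architecture:
    """Cohort-level signal architecture shared by all subjects."""

    community_of: np.ndarray        # region -> community index
    community_amp: np.ndarray       # per-region within-community amplitude
    global_amp: float
    hub_cross: np.ndarray           # communities the hub additionally joins
    hub_cross_amp: float
    pair_index: np.ndarray          # (n_pairs, 2) region pairs
    pair_amp: np.ndarray            # per-pair amplitude


def _build_architecture(config: SyntheticCohortConfig) -> _Architecture:
    rng = config.stage_rng("architecture")
    r = config.n_regions
    community_of = np.empty(r, dtype=int)
    for c, members in enumerate(config.partition):
        community_of[members] = c
    n_comm = len(config.partition)
    amp = rng.uniform(0.4, 1.3, size=r)
    amp[config.hub_region] = 1.2
    hub_comm = community_of[config.hub_region]
    hub_cross = np.array(
        [(hub_comm + 1) % n_comm, (hub_comm + 2) % n_comm]
    ) if n_comm > 1 else np.empty(0, int)

    mc = r * (r - 1) // 2
    n_pairs = int(round(config.long_range_fraction * mc))
    iu, ju = np.triu_indices(r, k=1)
    inter = np.flatnonzero(
        (community_of[iu] != community_of[ju])
        & (iu != config.hub_region)
        & (ju != config.hub_region)
    )
    n_pairs = min(n_pairs, inter.size)
    chosen = rng.choice(inter, size=n_pairs, replace=False) if n_pairs else np.empty(0, int)
    pair_index = np.column_stack([iu[chosen], ju[chosen]]) if n_pairs else np.empty((0, 2), int)
    pair_amp = rng.uniform(0.6, 1.0, size=n_pairs)
    return _Architecture(
        community_of=community_of,
        community_amp=amp,
        global_amp=0.3,
        hub_cross=np.unique(hub_cross[hub_cross != hub_comm]),
        hub_cross_amp=0.6,
        pair_index=pair_index,
        pair_amp=pair_amp,
    )


def _band_limited_signals(rng, n_signals: int, n_t: int, tr: float,
                          low: float = 0.025, high: float = 0.05) -> np.ndarray:
    """Unit-variance signals with power restricted to [low, high] Hz."""
    white = rng.standard_normal((n_signals, n_t))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise ValueError("no Fourier bins inside the requested band; series too short")
    spec[:, ~keep] = 0.0
    sig = np.fft.irfft(spec, n=n_t, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    return sig / np.where(sd == 0, 1.0, sd)


def generate_bold(config: SyntheticCohortConfig, phenotypes: pd.DataFrame) -> np.ndarray:
    """Per-subject regional BOLD matrices, shape (n_subjects, regions, time).

    Inter-regional coupling is carried by shared band-limited (0.025-0.05 Hz)
    community, global and long-range pair signals plus white noise.  The hub
    region's coupling amplitudes shrink linearly in the subject's combined
    trait score (``effect_sizes["hub_coupling"]``); all amplitudes shrink
    with ``effect_sizes["local_efficiency"]``.
    """
    if len(phenotypes) != config.n_subjects:
        raise ValueError(
            f"phenotype count {len(phenotypes)} does not match n_subjects {config.n_subjects}"
        )
    arch = _build_architecture(config)
    trait = combined_trait_score(phenotypes)
    rng = config.stage_rng("bold")
    r, t = config.n_regions, config.n_timepoints
    n_comm = len(config.partition)
    beta_hub = config.effect_sizes.get("hub_coupling", 0.0)
    beta_el = config.effect_sizes.get("local_efficiency", 0.0)

    out = np.empty((config.n_subjects, r, t))
    hub = config.hub_region
    # per-region shared-signal variance (coupling scaling preserves it by
    # swapping shared variance for private band-limited variance, so trait
    # effects move correlations, not signal power)
    shared_var = arch.community_amp**2 + arch.global_amp**2
    np.add.at(shared_var, arch.pair_index.ravel(),
              np.repeat(arch.pair_amp**2, 2))
    shared_var[hub] = (
        arch.community_amp[hub] ** 2
        + arch.global_amp**2
        + arch.hub_cross.size * arch.hub_cross_amp**2
    )
    shared_sd = np.sqrt(shared_var)

    for s in range(config.n_subjects):
        n_fac = n_comm + 1 + len(arch.pair_amp) + r
        fac = _band_limited_signals(rng, n_fac, t, config.tr)
        comm_sig = fac[:n_comm]
        glob_sig = fac[n_comm]
        pair_sig = fac[n_comm + 1:n_comm + 1 + len(arch.pair_amp)]
        private_sig = fac[n_comm + 1 + len(arch.pair_amp):]

        scale = np.full(r, np.clip(1.0 + beta_el * trait[s], 0.05, 2.0))
        scale[hub] *= np.clip(1.0 + beta_hub * trait[s], 0.05, 2.0)

        shared = arch.community_amp[:, None] * comm_sig[arch.community_of]
        shared += arch.global_amp * glob_sig
        for (i, j), u, ps in zip(arch.pair_index, arch.pair_amp, pair_sig):
            shared[i] += u * ps
            shared[j] += u * ps
        shared[hub] = (
            arch.community_amp[hub] * comm_sig[arch.community_of[hub]]
            + arch.hub_cross_amp * comm_sig[arch.hub_cross].sum(axis=0)
            + arch.global_amp * glob_sig
        )
        private_amp = shared_sd * np.sqrt(np.clip(1.0 - scale**2, 0.0, None))
        x = scale[:, None] * shared + private_amp[:, None] * private_sig
        x += config.noise_sd * rng.standard_normal((r, t))
        out[s] = x
    return out


# --------------------------------------------------------------------------
# label volumes and FA


@dataclass
class LabelVolumeSet:
    """Per-region voxelwise probability maps on a common 3-D grid.

    ``probabilities`` has shape (n_regions, x, y, z) with values in [0, 1].
    Region delineation thresholds at p > ``threshold`` and resolves
    overlapping voxels by assigning each to the region with the highest
    probability (ties go to the lower region index).
    """

    probabilities: np.ndarray
    region_names: list[str]
    threshold: float = 0.25

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 4:
            raise ValueError("probabilities must have shape (regions, x, y, z)")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.region_names) != p.shape[0]:
            raise ValueError("region_names length must match probability maps")
        self.probabilities = p

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape[1:]

    def assignment(self) -> np.ndarray:
        """Voxelwise region index after thresholding and overlap resolution.

        Returns -1 for voxels where no region exceeds the threshold.
        """
        p = np.where(self.probabilities > self.threshold, self.probabilities, 0.0)
        idx = np.argmax(p, axis=0)
        idx[p.max(axis=0) == 0.0] = -1
        return idx

    def effective_weights(self) -> np.ndarray:
        """Post-threshold, overlap-resolved probability weights per region."""
        p = np.where(self.probabilities > self.threshold, self.probabilities, 0.0)
        assigned = self.assignment()
        region_ids = np.arange(p.shape[0]).reshape(-1, 1, 1, 1)
        return np.where(assigned[None] == region_ids, p, 0.0)

    def to_nifti(self):
        """4-D NIfTI image (x, y, z, region) of the probability maps."""
        import nibabel as nib

        data = np.moveaxis(self.probabilities, 0, -1)
        return nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))


def generate_label_volumes(config: SyntheticCohortConfig) -> LabelVolumeSet:
    """Synthetic probabilistic label maps with deliberate partial overlaps.

    Region centres sit on a 3-D lattice two voxels apart; each region's
    probability is a Gaussian bump (p = 1 at its own centre), so neighbours
    overlap at intermediate voxels and the p > 0.25 threshold plus
    highest-probability assignment is genuinely exercised.
    """
    r = config.n_regions
    per_axis = int(np.ceil(r ** (1 / 3)))
    nx = per_axis
    ny = int(np.ceil(np.sqrt(r / nx)))
    nz = int(np.ceil(r / (nx * ny)))
    grid = config.grid_shape or (2 * nx + 1, 2 * ny + 1, 2 * nz + 1)
    centres = np.array(
        [(1 + 2 * i, 1 + 2 * j, 1 + 2 * k)
         for i in range(nx) for j in range(ny) for k in range(nz)][:r]
    )
    if len(centres) < r or any(c >= g for c, g in zip(centres.max(axis=0), grid)):
        raise ValueError(
            f"grid {grid} too small to give each of {r} regions its own voxel"
        )
    xs, ys, zs = np.indices(grid)
    coords = np.stack([xs, ys, zs], axis=-1)
    d2 = ((coords[None] - centres[:, None, None, None, :]) ** 2).sum(axis=-1)
    p = np.exp(-d2 / (2 * 1.1**2))
    p[p < 0.05] = 0.0
    return LabelVolumeSet(
        probabilities=p, region_names=default_region_names(r), threshold=0.25
    )


def generate_fa(
    config: SyntheticCohortConfig, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject regional fractional anisotropy, shape subjects x regions.

    In the designated effect regions the standardized FA has correlation
    ``effect_sizes["fa"]`` with the combined trait score; all other regions
    are trait-independent.  Values are clipped into (0, 1).
    """
    if len(phenotypes) != config.n_subjects:
        raise ValueError(
            f"phenotype count {len(phenotypes)} does not match n_subjects {config.n_subjects}"
        )
    rng = config.stage_rng("fa")
    trait = combined_trait_score(phenotypes)
    r = config.n_regions
    base = rng.uniform(0.30, 0.60, size=r)
    sd_fa = 0.04
    beta = float(np.clip(config.effect_sizes.get("fa", 0.0), -1.0, 1.0))
    eps = rng.standard_normal((config.n_subjects, r))
    fa = base[None, :] + sd_fa * eps
    if beta != 0.0:
        idx = list(config.fa_effect_indices)
        fa[:, idx] = base[None, idx] + sd_fa * (
            beta * trait[:, None] + np.sqrt(1 - beta**2) * eps[:, idx]
        )
    fa = np.clip(fa, 0.01, 0.99)
    return pd.DataFrame(
        fa, index=phenotypes["subject_id"], columns=default_region_names(r)
    )


def bold_to_volume(bold_subject: np.ndarray, labels: LabelVolumeSet) -> np.ndarray:
    """4-D volume whose voxels carry their resolved region's BOLD series."""
    assigned = labels.assignment()
    t = bold_subject.shape[1]
    vol = np.zeros(labels.grid_shape + (t,))
    mask = assigned >= 0
    vol[mask] = bold_subject[assigned[mask]]
    return vol


def fa_to_volume(fa_by_region: np.ndarray, labels: LabelVolumeSet) -> np.ndarray:
    """3-D FA volume whose voxels carry their resolved region's FA value."""
    assigned = labels.assignment()
    vol = np.zeros(labels.grid_shape)
    mask = assigned >= 0
    vol[mask] = np.asarray(fa_by_region)[assigned[mask]]
    return vol
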