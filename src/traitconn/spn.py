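"""Population-level mean statistical parametric network (SPN).

Because per-subject networks differ in their average correlation, raw
correlation thresholds are not comparable across subjects or groups.  The
mean SPN standardises each edge: its z-score is the deviation of the edge's
subject-mean correlation from the grand mean of all edges, in units of the
grand standard deviation (both pooled over subjects and upper-triangle
edges).  Subgraphs thresholded on z (or on a nominal p-value mapped to a
standard-normal quantile) can then be compared between groups, e.g. the
first-degree connection profile of a seed region in low- versus high-trait
subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MeanSPN",
    "ConnectionProfile",
    "mean_spn",
    "first_degree_connections",
    "percentile_threshold",
]


@dataclass
class MeanSPN:
    """Edge-wise z-scores of mean wavelet correlations in a population."""

    z: np.ndarray
    mean_edge_corr: np.ndarray
    grand_mean: float
    grand_sd: float
    n_subjects: int
    region_names: list[str] | None = field(default=None)


@dataclass
class ConnectionProfile:
    """Supra-threshold first-degree connections of a seed region."""

    seed_region: str | int
    connected_regions: list[tuple[str, float]]
    threshold_used: float
    threshold_kind: str

    def __len__(self) -> int:
        return len(self.connected_regions)

    @property
    def region_labels(self) -> list[str]:
        return [name for name, _ in self.connected_regions]


def _corr_stack(corr_stack) -> tuple[np.ndarray, list[str] | None]:
    mats, names = [], None
    for c in corr_stack:
        if hasattr(c, "r"):
            mats.append(np.asarray(c.r, dtype=float))
            names = names or getattr(c, "region_names", None)
        else:
            mats.append(np.asarray(c, dtype=float))
    arr = np.stack(mats)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("correlation stack must be subjects x regions x regions")
    return arr, names


def mean_spn(corr_stack) -> MeanSPN:
    """Mean SPN of a stack of per-subject correlation matrices.

    The grand mean and SD pool every subject's upper-triangle edges (each
    undirected edge counted once); z^e = (mean_e - grand_mean) / grand_sd.
    """
    arr, names = _corr_stack(corr_stack)
    n_sub, n = arr.shape[0], arr.shape[1]
    if n_sub < 2:
        raise ValueError("mean SPN needs at least 2 subjects")
    iu, ju = np.triu_indices(n, k=1)
    pooled = arr[:, iu, ju]
    grand_mean = float(pooled.mean())
    grand_sd = float(pooled.std(ddof=1))
    if grand_sd == 0:
        raise ValueError("degenerate input: zero grand standard deviation")
    mean_edge = arr.mean(axis=0)
    np.fill_diagonal(mean_edge, 0.0)
    z = (mean_edge - grand_mean) / grand_sd
    np.fill_diagonal(z, 0.0)
    return MeanSPN(
        z=z,
        mean_edge_corr=mean_edge,
        grand_mean=grand_mean,
        grand_sd=grand_sd,
        n_subjects=n_sub,
        region_names=names,
    )


def _seed_index(seed, region_names, n) -> int:
    if isinstance(seed, (int, np.integer)):
        if not 0 <= seed < n:
            raise ValueError(f"seed region index {seed} outside 0..{n - 1}")
        return int(seed)
    if region_names is None or seed not in region_names:
        raise ValueError(f"seed region {seed!r} not found in region list")
    return region_names.index(seed)


def first_degree_connections(
    matrix,
    seed,
    threshold: float,
    kind: str = "correlation",
    region_names: list[str] | None = None,
    sided: str = "one",
    inclusive: bool = False,
    precision: int | None = None,
) -> ConnectionProfile:
    """Regions whose edge to the seed exceeds a threshold, strongest first.

    ``kind="correlation"`` compares edge strengths to ``threshold``
    directly; ``kind="z_p_value"`` treats ``threshold`` as a nominal
    p-value and compares z-scores to the standard-normal quantile
    (one-sided upper tail by default, ``sided="two"`` for two-sided).
    ``precision`` rounds the threshold to a fixed number of decimals before
    comparison, for profiles stored at printed precision (with
    ``inclusive=True`` values equal to the rounded threshold are kept).
    """
    if hasattr(matrix, "z") and kind == "z_p_value":
        values, names = matrix.z, matrix.region_names
    elif hasattr(matrix, "mean_edge_corr") and kind == "correlation":
        values, names = matrix.mean_edge_corr, matrix.region_names
    else:
        values, names = np.asarray(matrix, dtype=float), region_names
    names = region_names or names
    n = values.shape[0]
    i = _seed_index(seed, names, n)
    strengths = values[i].astype(float).copy()
    strengths[i] = -np.inf

    if kind == "correlation":
        cut = threshold
    elif kind == "z_p_value":
        p = threshold / 2.0 if sided == "two" else threshold
        cut = float(stats.norm.isf(p))
    else:
        raise ValueError(f"unknown threshold kind {kind!r}")
    if precision is not None:
        cut = round(cut, precision)
    keep = strengths >= cut if inclusive else strengths > cut
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(-strengths[idx], kind="stable")]
    labels = names if names is not None else [str(j) for j in range(n)]
    return ConnectionProfile(
        seed_region=labels[i] if names is not None else i,
        connected_regions=[(labels[j], float(strengths[j])) for j in order],
        threshold_used=float(cut),
        threshold_kind=kind,
    )


def percentile_threshold(matrix, seed, percentile: float,
                         region_names: list[str] | None = None) -> float:
    """Given percentile of the seed region's edge strengths.

    Uses linear interpolation between order statistics (numpy's default
    quantile definition).
    """
    if hasattr(matrix, "mean_edge_corr"):
        values, names = matrix.mean_edge_corr, matrix.region_names
    else:
        values, names = np.asarray(matrix, dtype=float), region_names
    names = region_names or names
    i = _seed_index(seed, names, values.shape[0])
    edges = np.delete(values[i], i)
    return float(np.percentile(edges, percentile))
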