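"""Probability-weighted regional fractional anisotropy extraction.

Given a scalar FA volume and a probabilistic label system, each region's
mean FA is the probability-weighted average of its voxels' FA values,
using the post-threshold (p > 0.25), overlap-resolved probabilities as
weights — voxels below the threshold or won by another region contribute
nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["regional_fa"]


def regional_fa(fa_volume, labels, subject_id: str | None = None) -> pd.Series:
    """Per-region probability-weighted mean FA.

    ``fa_volume`` is a 3-D array or NIfTI-style image on the label grid.
    Returns a Series indexed by region name (named after ``subject_id``
    when given).  Raises if any region retains no voxels after the
    threshold and overlap resolution.
    """
    if hasattr(fa_volume, "get_fdata"):
        fa_volume = fa_volume.get_fdata()
    vol = np.asarray(fa_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("fa_volume must be 3-D")
    weights = labels.effective_weights()
    if weights.shape[1:] != vol.shape:
        raise ValueError(
            f"label grid {weights.shape[1:]} does not match FA grid {vol.shape}"
        )
    flat_w = weights.reshape(weights.shape[0], -1)
    totals = flat_w.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        bad = ", ".join(labels.region_names[i] for i in empty[:5])
        raise ValueError(
            f"no voxels survive the p > {labels.threshold} threshold for region(s): {bad}"
        )
    means = (flat_w @ vol.ravel()) / totals
    return pd.Series(means, index=labels.region_names, name=subject_id)
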