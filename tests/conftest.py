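import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from traitconn import (
    SyntheticCohortConfig,
    build_connectivity,
    generate_bold,
    generate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-subject, 30-region cohort with default effect sizes."""
    cfg = SyntheticCohortConfig(n_subjects=16, n_regions=30, seed=11)
    pheno = generate_phenotypes(cfg)
    bold = generate_bold(cfg, pheno)
    return cfg, pheno, bold


@pytest.fixture(scope="session")
def small_networks(small_cohort):
    """Correlation matrices and weighted networks of the small cohort."""
    cfg, pheno, bold = small_cohort
    pairs = [build_connectivity(bold[s], tr=cfg.tr, level=3)
             for s in range(cfg.n_subjects)]
    return [c for c, _ in pairs], [n for _, n in pairs]


@pytest.fixture(scope="session")
def toy_weights():
    """A reproducible 20-node weighted network with community structure."""
    rng = np.random.default_rng(5)
    n = 20
    base = rng.uniform(0, 0.3, size=(n, n))
    for block in (slice(0, 7), slice(7, 14), slice(14, 20)):
        base[block, block] += 0.5
    w = np.clip((base + base.T) / 2, 0, 1)
    np.fill_diagonal(w, 0)
    return w
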