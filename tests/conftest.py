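import numpy as np
import pytest

from gsikit.popgen import GenotypeMatrix, LocusInfo
from gsikit.simulate import GeneratorConfig, gen_baselines


def make_gm(dosage, lg=None, pos=None, ids=None):
    """Build a GenotypeMatrix from a nested list/array of dosages."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    loci = [
        LocusInfo(
            f"L{j}",
            linkage_group=(lg[j] if lg else "LG1"),
            map_pos=(pos[j] if pos else float(j)),
        )
        for j in range(L)
    ]
    inds = ids if ids else [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(inds, loci, dosage)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_baselines():
    """Desk-scale generator output shared across tests (cheap, seeded)."""
    cfg = GeneratorConfig(n_candidate_loci=400, baseline_n=100, seed=11)
    return cfg, gen_baselines(cfg)


@pytest.fixture(scope="session")
def default_baselines():
    """Full-default generator output (1200 loci, 150+150)."""
    cfg = GeneratorConfig(seed=42)
    return cfg, gen_baselines(cfg)
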