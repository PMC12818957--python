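import numpy as np
import pandas as pd
import pytest

from invgwas.data_model import GenotypePanel, KaryotypeTable
from invgwas.synthetic_data import (
    InversionSimSpec,
    SimConfig,
    TraitSimConfig,
    simulate_panel,
    simulate_traits,
)


def make_panel(dosage, positions=None, arm="2L", line_ids=None):
    """Construct a panel from a dosage array (lines x variants)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    line_ids = line_ids or [f"L{i}" for i in range(n)]
    arms = [arm] * m if isinstance(arm, str) else list(arm)
    meta = pd.DataFrame(
        {
            "id": [f"{a}:{p}" for a, p in zip(arms, positions)],
            "arm": arms,
            "pos": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypePanel(line_ids, meta, dosage)


def make_karyotypes(calls, line_ids=None, inversion="In(2L)t"):
    calls = list(calls)
    line_ids = line_ids or [f"L{i}" for i in range(len(calls))]
    return KaryotypeTable(pd.DataFrame({inversion: calls}, index=line_ids))


@pytest.fixture(scope="session")
def sim_small():
    """A small but non-degenerate simulated scenario shared across tests."""
    cfg = SimConfig(
        n_lines=120,
        genome={"2L": 23_500_000, "3R": 28_000_000},
        n_variants_per_arm=220,
        seed=7,
    )
    panel, kary, invs, cov = simulate_panel(cfg)
    traits = simulate_traits(
        panel, kary, cov, TraitSimConfig(n_traits=6, seed=7), inversion_defs=invs
    )
    return {"cfg": cfg, "panel": panel, "karyotypes": kary, "inversions": invs,
            "covariates": cov, "traits": traits}
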