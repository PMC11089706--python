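import numpy as np
import pandas as pd
import pytest

import uroev


@pytest.fixture(scope="session")
def small_sim():
    """Default-shape synthetic dataset on a miniature genome (shared)."""
    cfg = uroev.SimulationConfig(seed=42, n_contigs=2, contig_length=50_000)
    return uroev.simulate_all(cfg)


@pytest.fixture(scope="session")
def discovery_sim():
    """Clean 47/16 cohort (no contamination), ~1000 regions."""
    cfg = uroev.SimulationConfig(seed=11, n_case=47, n_control=16,
                                 n_contaminated=0, n_contigs=2,
                                 contig_length=50_000)
    return uroev.simulate_all(cfg)


def make_sheet(n_case, n_control, seed=0, **overrides):
    """Simple deterministic sample sheet for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in (("case", n_case), ("control", n_control)):
        for i in range(n):
            rows.append({
                "sample_id": f"{grp}{i:02d}", "group": grp,
                "gender": "male" if rng.random() < 0.7 else "female",
                "age": float(rng.integers(40, 81)),
                "dna_rna_ratio": 0.0,
                "obesity": bool(rng.random() < 0.3),
                "hypertension": bool(rng.random() < 0.5),
            })
    df = pd.DataFrame(rows)
    for col, vals in overrides.items():
        df[col] = vals
    return uroev.SampleSheet(rows=df)
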