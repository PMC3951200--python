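import numpy as np
import pandas as pd
import pytest

from divquail.io_align import BLAST_COLUMNS
from divquail.synth import SyntheticAlignmentSpec, make_alignment_table


def random_hit_table(rng, n_queries=20, max_hits_per_query=5):
    """Random HSP table with duplicated E-values/bitscores to exercise ties."""
    rows = []
    for q in range(n_queries):
        for _ in range(int(rng.integers(1, max_hits_per_query + 1))):
            length = int(rng.integers(25, 5000))
            qs = int(rng.integers(1, 1000))
            ss = int(rng.integers(1, 10**7))
            rows.append(
                {
                    "query_id": f"q{q:03d}",
                    "subject_id": f"chr{rng.integers(1, 4)}",
                    "percent_identity": float(np.round(rng.uniform(60, 100), 2)),
                    "alignment_length": length,
                    "mismatches": 0,
                    "gap_opens": 0,
                    "q_start": qs,
                    "q_end": qs + length - 1,
                    "s_start": ss,
                    "s_end": ss + length - 1,
                    # coarse grid so exact ties happen often
                    "e_value": float(rng.choice([0.0, 1e-50, 1e-30, 1e-10, 1e-4])),
                    "bit_score": float(rng.choice([50.0, 100.0, 200.0, 500.0])),
                }
            )
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240312)


@pytest.fixture(scope="session")
def planted_dataset():
    """One mid-size synthetic table with two planted outliers per tail."""
    spec = SyntheticAlignmentSpec(
        n_background=9998, n_planted_diverged=2, n_planted_conserved=2, seed=7
    )
    hits, meta, truth = make_alignment_table(spec)
    return spec, hits, meta, truth
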