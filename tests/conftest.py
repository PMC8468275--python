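from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernapipe.diffexpr import ExpressionMatrix

BASES = np.array(list("ACGU"))

#: a let-7-family-like 22-nt miRNA used by deterministic examples
EXAMPLE_MIR_SEQ = "UGAGGUAGUAGGUUGUAUAGUU"


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def de_frame(rows: list[tuple[float, float]]) -> pd.DataFrame:
    """Minimal DE result table from (FC, p) pairs, for call_de tests."""
    return pd.DataFrame(
        {
            "feature": [f"f{i}" for i in range(len(rows))],
            "mean_WT": 1.0,
            "mean_KO": [fc for fc, _ in rows],
            "FC": [fc for fc, _ in rows],
            "log2FC": np.log2([fc for fc, _ in rows]),
            "p": [p for _, p in rows],
            "FDR": [p for _, p in rows],
            "call": "none",
        }
    )


def intensity_matrix(values: np.ndarray, flags=None) -> ExpressionMatrix:
    """3 + 3 sample intensity matrix from a (features x 6) array."""
    n = values.shape[1] // 2
    cols = [f"WT_{i+1}" for i in range(n)] + [f"KO_{i+1}" for i in range(n)]
    vals = pd.DataFrame(values, columns=cols,
                        index=[f"f{i}" for i in range(len(values))])
    fl = None
    if flags is not None:
        fl = pd.DataFrame(flags, columns=cols, index=vals.index)
    groups = pd.Series(["WT"] * n + ["KO"] * n, index=cols)
    return ExpressionMatrix(vals, groups, platform="intensity", flags=fl)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)
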