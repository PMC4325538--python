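import numpy as np
import pandas as pd
import pytest

from orthoset.diffexpr import ActivationMatrix, GeneSetScoreMatrix
from orthoset.noise import NoiseCurve, ReplicateExpressionSet


def flat_noise_curve(sd: float = 1.0, lo: float = 0.0, hi: float = 100.0, n_bins: int = 14) -> NoiseCurve:
    """A constant noise curve spanning [lo, hi]; every bin populated."""
    edges = np.linspace(lo, hi, n_bins + 1)
    means = 0.5 * (edges[:-1] + edges[1:])
    return NoiseCurve(edges, means, np.full(n_bins, sd), np.ones(n_bins, dtype=int))


@pytest.fixture
def flat_curve():
    return flat_noise_curve()


@pytest.fixture
def small_expression():
    """3 genes x 2 stimuli x 3 replicates, 4 control replicates, no noise structure."""
    rng = np.random.default_rng(42)
    values = 50.0 + rng.normal(0, 1.0, size=(3, 2, 3))
    control = 50.0 + rng.normal(0, 1.0, size=(3, 4))
    return ReplicateExpressionSet(values, control, ["g0", "g1", "g2"], ["s0", "s1"])


def make_scores(fdr: np.ndarray, nes: np.ndarray | None = None, species: str = "rat") -> GeneSetScoreMatrix:
    fdr = np.atleast_2d(np.asarray(fdr, dtype=float))
    if nes is None:
        nes = np.zeros_like(fdr)
    idx = [f"GS{i}" for i in range(fdr.shape[0])]
    cols = [f"st{j}" for j in range(fdr.shape[1])]
    return GeneSetScoreMatrix(
        nes=pd.DataFrame(nes, index=idx, columns=cols),
        fdr=pd.DataFrame(fdr, index=idx, columns=cols),
        species=species,
    )


def make_activation(on: np.ndarray, ids=None, cols=None) -> ActivationMatrix:
    on = np.atleast_2d(np.asarray(on, dtype=bool))
    ids = ids or [f"GS{i}" for i in range(on.shape[0])]
    cols = cols or [f"st{j}" for j in range(on.shape[1])]
    return ActivationMatrix(
        on=pd.DataFrame(on, index=ids, columns=cols), source="gene set", threshold=0.25
    )
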