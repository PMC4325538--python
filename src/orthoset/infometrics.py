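"""Entropy and mutual information over binary activation profiles.

All quantities are in bits (log base 2) with the convention 0*log(0) = 0.
The MI of a pair of on/off profiles over stimuli quantifies cross-species
predictability regardless of correlation sign; significance comes from
permuting the stimulus order of the second profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orthoset.diffexpr import ActivationMatrix

__all__ = [
    "BinaryProfilePair",
    "MIResult",
    "OrthologMap",
    "state_probabilities",
    "shannon_entropy",
    "joint_entropy",
    "mutual_information",
    "permutation_pvalue",
    "pairwise_mi_screen",
]


def _as_bool_vector(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("profile must be a non-empty 1-d vector")
    if arr.dtype != bool:
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("profile must be binary")
        arr = arr.astype(bool)
    return arr


@dataclass
class BinaryProfilePair:
    """Aligned on/off profiles of an item in two species over shared stimuli."""

    x: np.ndarray
    y: np.ndarray
    stimulus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = _as_bool_vector(self.x)
        self.y = _as_bool_vector(self.y)
        if self.x.shape != self.y.shape:
            raise ValueError("profiles must have equal length")
        if self.x.size < 2:
            raise ValueError("profiles must cover >= 2 stimuli")


@dataclass
class MIResult:
    id_a: str
    id_b: str
    h_x: float
    h_y: float
    h_joint: float
    mi: float
    pearson: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class OrthologMap:
    """Many-to-many id pairs between two species; duplicates permitted."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        if not self.pairs:
            raise ValueError("ortholog map is empty")


def state_probabilities(x) -> tuple[float, float]:
    """Empirical (p_off, p_on) of a binary profile."""
    arr = _as_bool_vector(x)
    p_on = float(arr.mean())
    return 1.0 - p_on, p_on


def _plogp(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def shannon_entropy(x) -> float:
    """H = -sum_c p(c) log2 p(c) over the empirical on/off distribution."""
    p = np.array(state_probabilities(x))
    return float(-_plogp(p).sum())


def joint_entropy(x, y=None) -> float:
    """Entropy of the empirical 2x2 joint on/off table, in bits."""
    pair = x if isinstance(x, BinaryProfilePair) else BinaryProfilePair(x, y)
    n = pair.x.size
    n11 = int(np.sum(pair.x & pair.y))
    n10 = int(pair.x.sum()) - n11
    n01 = int(pair.y.sum()) - n11
    n00 = n - n11 - n10 - n01
    p = np.array([n00, n01, n10, n11], dtype=float) / n
    # summing in sorted order makes the result exactly invariant under
    # transposition/complement of the table (cells permute, sum order not)
    p.sort()
    return float(-_plogp(p).sum())


def mutual_information(x, y=None) -> float:
    """I(x, y) = H(x) + H(y) - H(x, y), clipped at zero against roundoff."""
    pair = x if isinstance(x, BinaryProfilePair) else BinaryProfilePair(x, y)
    mi = shannon_entropy(pair.x) + shannon_entropy(pair.y) - joint_entropy(pair)
    return max(mi, 0.0)


def _mi_from_counts(n11: np.ndarray, nx: int, ny: int, n: int) -> np.ndarray:
    """Vectorized MI (bits) of 2x2 tables parameterized by the overlap count."""
    n11 = np.asarray(n11, dtype=float)
    n10 = nx - n11
    n01 = ny - n11
    n00 = n - nx - ny + n11
    cells = np.stack([n00, n01, n10, n11], axis=-1) / n
    h_joint = -_plogp(cells).sum(axis=-1)
    marg = np.array([nx / n, 1 - nx / n, ny / n, 1 - ny / n])
    h_marg = -_plogp(marg).sum()
    return np.maximum(h_marg - h_joint, 0.0)


def _binary_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x.astype(float), y.astype(float))[0, 1])


def permutation_pvalue(
    x,
    y=None,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    id_a: str = "x",
    id_b: str = "y",
) -> MIResult:
    """Observed MI with a permutation p-value from shuffling the stimuli of y.

    The p-value uses the add-one convention ``(1 + #{I_perm >= I_obs}) /
    (1 + n_perm)`` so it is always strictly positive and valid (it can be
    conservative where the discrete MI statistic ties).
    """
    pair = x if isinstance(x, BinaryProfilePair) else BinaryProfilePair(x, y)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = pair.x.size
    nx = int(pair.x.sum())
    ny = int(pair.y.sum())
    obs = mutual_information(pair)
    perms = rng.permuted(np.tile(pair.y.astype(np.int64), (n_perm, 1)), axis=1)
    n11 = perms @ pair.x.astype(np.int64)
    mi_perm = _mi_from_counts(n11, nx, ny, n)
    p = (1 + int(np.sum(mi_perm >= obs - 1e-12))) / (1 + n_perm)
    return MIResult(
        id_a=id_a,
        id_b=id_b,
        h_x=shannon_entropy(pair.x),
        h_y=shannon_entropy(pair.y),
        h_joint=joint_entropy(pair),
        mi=obs,
        pearson=_binary_pearson(pair.x, pair.y),
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_mi_screen(
    a: ActivationMatrix,
    b: ActivationMatrix,
    ortholog_map: OrthologMap,
    n_perm: int = 1000,
    seed: int | None = None,
    hist_bins: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MI with permutation significance for every mapped pair, ranked by MI.

    Pairs appear with the full multiplicity of the ortholog map.  Returns the
    ranked table (columns ``id_a, id_b, mi_bits, pearson, p_value``) and the
    null-MI histogram: per MI bin, the mean and SD across permutation rounds
    of the number of pairs falling in that bin.
    """
    shared = [s for s in a.stimulus_ids if s in set(b.stimulus_ids)]
    if len(shared) < 2:
        raise ValueError("activation matrices share fewer than 2 stimuli")
    amat = a.on[shared]
    bmat = b.on[shared]

    missing_a = sorted({p[0] for p in ortholog_map.pairs} - set(a.item_ids))
    missing_b = sorted({p[1] for p in ortholog_map.pairs} - set(b.item_ids))
    if missing_a or missing_b:
        raise KeyError(
            f"unmapped ids — species a: {missing_a[:10]}, species b: {missing_b[:10]}"
        )

    if hist_bins is None:
        hist_bins = np.linspace(0.0, 1.0, 21)
    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_perm, len(hist_bins) - 1))

    rows = []
    for id_a, id_b in ortholog_map.pairs:
        x = amat.loc[id_a].to_numpy(dtype=bool)
        y = bmat.loc[id_b].to_numpy(dtype=bool)
        pair = BinaryProfilePair(x, y, stimulus_ids=shared)
        n = x.size
        nx = int(x.sum())
        ny = int(y.sum())
        obs = mutual_information(pair)
        perms = rng.permuted(np.tile(y.astype(np.int64), (n_perm, 1)), axis=1)
        mi_perm = _mi_from_counts(perms @ x.astype(np.int64), nx, ny, n)
        p = (1 + int(np.sum(mi_perm >= obs - 1e-12))) / (1 + n_perm)
        which = np.clip(np.digitize(mi_perm, hist_bins) - 1, 0, len(hist_bins) - 2)
        np.add.at(null_counts, (np.arange(n_perm), which), 1)
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "mi_bits": obs,
                "pearson": _binary_pearson(x, y),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).sort_values("mi_bits", ascending=False, kind="mergesort")
    table = table.reset_index(drop=True)
    hist = pd.DataFrame(
        {
            "bin_left": hist_bins[:-1],
            "bin_right": hist_bins[1:],
            "null_mean_count": null_counts.mean(axis=0),
            "null_sd_count": null_counts.std(axis=0, ddof=1),
        }
    )
    return table, hist
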