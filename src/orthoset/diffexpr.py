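"""Differential calls against control and binarization of gene-set scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from orthoset.noise import NoiseCurve, ReplicateExpressionSet, _group_mean_sd, interpolate_sd

__all__ = [
    "DifferentialCallMatrix",
    "GeneSetScoreMatrix",
    "ActivationMatrix",
    "call_differential_genes",
    "binarize_genesets",
    "binarize_genes",
    "continuous_activation",
]


@dataclass
class DifferentialCallMatrix:
    """Per (gene, stimulus) p-values and binary calls versus control.

    Pairs discarded upstream carry NaN p-values and ``valid == False``; they
    are missing, never "not called".
    """

    p_values: np.ndarray  # (genes, stimuli), NaN where invalid
    calls: np.ndarray  # bool, False wherever invalid
    valid: np.ndarray  # bool
    effect: np.ndarray  # treated mean - control mean, linearized units
    threshold: float
    gene_ids: list[str]
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        good = self.valid & ~np.isnan(self.p_values)
        if not np.array_equal(self.calls & good, self.calls):
            raise ValueError("calls must be False wherever the pair is invalid")


@dataclass
class GeneSetScoreMatrix:
    """Gene-set enrichment signal (NES) with attached significance (FDR)."""

    nes: pd.DataFrame  # gene set x stimulus
    fdr: pd.DataFrame  # same shape, values in [0, 1]
    species: str = ""

    def __post_init__(self) -> None:
        if not self.nes.index.equals(self.fdr.index) or not self.nes.columns.equals(
            self.fdr.columns
        ):
            raise ValueError("nes and fdr must share row and column labels")
        if not np.isfinite(self.nes.to_numpy()).all():
            raise ValueError("nes values must be finite")
        f = self.fdr.to_numpy()
        if np.isnan(f).any() or (f < 0).any() or (f > 1).any():
            raise ValueError("fdr values must lie in [0, 1]")

    @property
    def set_ids(self) -> list[str]:
        return list(self.nes.index)

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.nes.columns)


@dataclass
class ActivationMatrix:
    """Binary item x stimulus on/off calls derived from a score matrix."""

    on: pd.DataFrame  # bool
    source: str  # "gene" or "gene set"
    threshold: float

    def __post_init__(self) -> None:
        if self.source not in ("gene", "gene set"):
            raise ValueError("source must be 'gene' or 'gene set'")
        if self.on.dtypes.map(lambda d: d != bool).any():
            self.on = self.on.astype(bool)

    @property
    def item_ids(self) -> list[str]:
        return list(self.on.index)

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.on.columns)

    def profile(self, item_id: str) -> np.ndarray:
        return self.on.loc[item_id].to_numpy(dtype=bool)


def call_differential_genes(
    cleaned: ReplicateExpressionSet,
    curve: NoiseCurve,
    alpha: float = 0.01,
    df_method: str = "normal",
) -> DifferentialCallMatrix:
    """Two-sample test of treated vs control means using curve-derived SDs.

    For each (gene, stimulus) the statistic is
    ``(mean_t - mean_c) / sqrt(sd_t^2/n_t + sd_c^2/n_c)`` where both group
    SDs are read off the universal noise curve at the respective group means
    (the curve is evaluated in the same, i.e. linearized, space as the data).

    ``df_method`` selects the reference distribution for the two-sided
    p-value:

    - ``"normal"`` (default): standard normal.  The curve SD pools thousands
      of replicate groups and is effectively known, so the statistic is a
      z-score; this choice is calibrated at the nominal level under the null.
    - ``"pooled"``: Student t with ``n_t + n_c - 2`` degrees of freedom, the
      conventional two-sample df.  Conservative with known SDs.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df_method not in ("normal", "pooled"):
        raise ValueError("df_method must be 'normal' or 'pooled'")

    mean_t, _, n_t = _group_mean_sd(cleaned.values)
    mean_c, _, n_c = _group_mean_sd(cleaned.control_values)

    valid = (n_t >= 2) & (n_c >= 2)[:, None]
    G, S = mean_t.shape
    p = np.full((G, S), np.nan)
    effect = np.full((G, S), np.nan)

    if valid.any():
        mt = mean_t[valid]
        mc = np.broadcast_to(mean_c[:, None], (G, S))[valid]
        nt = n_t[valid]
        nc = np.broadcast_to(n_c[:, None], (G, S))[valid]
        sd_t = interpolate_sd(curve, mt)
        sd_c = interpolate_sd(curve, mc)
        if np.any(sd_t <= 0) or np.any(sd_c <= 0):
            raise ValueError("noise curve returned a non-positive SD")
        se = np.sqrt(sd_t**2 / nt + sd_c**2 / nc)
        t = (mt - mc) / se
        if df_method == "normal":
            pv = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pv = 2.0 * stats.t.sf(np.abs(t), df=nt + nc - 2)
        p[valid] = pv
        effect[valid] = mt - mc

    calls = np.zeros((G, S), dtype=bool)
    calls[valid] = p[valid] < alpha
    return DifferentialCallMatrix(
        p_values=p,
        calls=calls,
        valid=valid,
        effect=effect,
        threshold=alpha,
        gene_ids=list(cleaned.gene_ids),
        stimulus_ids=list(cleaned.stimulus_ids),
    )


def binarize_genesets(scores: GeneSetScoreMatrix, fdr_cut: float = 0.25) -> ActivationMatrix:
    """Binarize a gene-set score matrix: on iff FDR strictly below the cut."""
    if not 0 < fdr_cut <= 1:
        raise ValueError("fdr_cut must be in (0, 1]")
    return ActivationMatrix(on=scores.fdr < fdr_cut, source="gene set", threshold=fdr_cut)


def binarize_genes(calls: DifferentialCallMatrix) -> ActivationMatrix:
    """Wrap gene-level differential calls as an activation matrix.

    Invalid (discarded) pairs come through as off; the ``valid`` mask on the
    call matrix remains the authority on missingness.
    """
    df = pd.DataFrame(calls.calls, index=calls.gene_ids, columns=calls.stimulus_ids)
    return ActivationMatrix(on=df, source="gene", threshold=calls.threshold)


def continuous_activation(scores: GeneSetScoreMatrix) -> pd.DataFrame:
    """Map FDR to a continuous activation scale, ``1 - FDR``."""
    return 1.0 - scores.fdr
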