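"""Plain-text I/O: TSV matrices, long-format expression tables, GMT gene sets."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from orthoset.diffexpr import ActivationMatrix, GeneSetScoreMatrix
from orthoset.infometrics import OrthologMap
from orthoset.noise import NoiseCurve, ReplicateExpressionSet, SaturationCurve

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_activation_tsv",
    "read_activation_tsv",
    "write_noise_curve_tsv",
    "read_noise_curve_tsv",
    "write_saturation_curve_tsv",
    "read_saturation_curve_tsv",
    "read_ortholog_map_tsv",
    "write_ortholog_map_tsv",
    "write_gmt",
    "read_gmt",
]


def write_expression_tsv(data: ReplicateExpressionSet, path, control_path) -> None:
    """Write treated values in long format (gene, stimulus, replicate, value)
    and control values in long format (gene, replicate, value).  Missing
    replicate values are omitted."""
    G, S, R = data.values.shape
    gi, si, ri = np.meshgrid(range(G), range(S), range(R), indexing="ij")
    v = data.values.ravel()
    keep = ~np.isnan(v)
    long = pd.DataFrame(
        {
            "gene": np.asarray(data.gene_ids)[gi.ravel()[keep]],
            "stimulus": np.asarray(data.stimulus_ids)[si.ravel()[keep]],
            "replicate": ri.ravel()[keep],
            "value": v[keep],
        }
    )
    long.to_csv(path, sep="\t", index=False)
    Gc, C = data.control_values.shape
    gi, ri = np.meshgrid(range(Gc), range(C), indexing="ij")
    v = data.control_values.ravel()
    keep = ~np.isnan(v)
    ctrl = pd.DataFrame(
        {
            "gene": np.asarray(data.gene_ids)[gi.ravel()[keep]],
            "replicate": ri.ravel()[keep],
            "value": v[keep],
        }
    )
    ctrl.to_csv(control_path, sep="\t", index=False)


def read_expression_tsv(path, control_path) -> ReplicateExpressionSet:
    long = pd.read_csv(path, sep="\t", dtype={"gene": str, "stimulus": str})
    ctrl = pd.read_csv(control_path, sep="\t", dtype={"gene": str})
    gene_ids = sorted(set(long["gene"]) | set(ctrl["gene"]))
    stimulus_ids = sorted(set(long["stimulus"]))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    spos = {s: i for i, s in enumerate(stimulus_ids)}
    R = int(long["replicate"].max()) + 1
    values = np.full((len(gene_ids), len(stimulus_ids), R), np.nan)
    values[
        long["gene"].map(gpos), long["stimulus"].map(spos), long["replicate"]
    ] = long["value"].to_numpy()
    C = int(ctrl["replicate"].max()) + 1
    control = np.full((len(gene_ids), C), np.nan)
    control[ctrl["gene"].map(gpos), ctrl["replicate"]] = ctrl["value"].to_numpy()
    return ReplicateExpressionSet(values, control, gene_ids, stimulus_ids)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_scores_tsv(scores: GeneSetScoreMatrix, nes_path, fdr_path) -> None:
    write_matrix_tsv(scores.nes, nes_path, index_label="gene_set")
    write_matrix_tsv(scores.fdr, fdr_path, index_label="gene_set")


def read_scores_tsv(nes_path, fdr_path, species: str = "") -> GeneSetScoreMatrix:
    return GeneSetScoreMatrix(
        nes=read_matrix_tsv(nes_path), fdr=read_matrix_tsv(fdr_path), species=species
    )


def write_activation_tsv(act: ActivationMatrix, path) -> None:
    write_matrix_tsv(act.on.astype(int), path, index_label="id")


def read_activation_tsv(path, source: str = "gene set", threshold: float = 0.25) -> ActivationMatrix:
    df = read_matrix_tsv(path)
    return ActivationMatrix(on=df.astype(bool), source=source, threshold=threshold)


def write_noise_curve_tsv(curve: NoiseCurve, path) -> None:
    pd.DataFrame(
        {
            "bin_mean_expression": curve.bin_mean_expression,
            "bin_sd": curve.bin_sd,
            "n_pairs": curve.n_pairs_per_bin,
            "bin_left_edge": curve.bin_edges[:-1],
            "bin_right_edge": curve.bin_edges[1:],
        }
    ).to_csv(path, sep="\t", index=False)


def read_noise_curve_tsv(path) -> NoiseCurve:
    df = pd.read_csv(path, sep="\t")
    edges = np.append(df["bin_left_edge"].to_numpy(), df["bin_right_edge"].iloc[-1])
    return NoiseCurve(
        bin_edges=edges,
        bin_mean_expression=df["bin_mean_expression"].to_numpy(),
        bin_sd=df["bin_sd"].to_numpy(),
        n_pairs_per_bin=df["n_pairs"].to_numpy(),
    )


def write_saturation_curve_tsv(sat: SaturationCurve, path) -> None:
    pd.DataFrame({"g": sat.g_grid, "F": sat.F_values}).to_csv(path, sep="\t", index=False)


def read_saturation_curve_tsv(path) -> SaturationCurve:
    df = pd.read_csv(path, sep="\t")
    return SaturationCurve(g_grid=df["g"].to_numpy(), F_values=df["F"].to_numpy())


def read_ortholog_map_tsv(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns")
    return OrthologMap(pairs=list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_ortholog_map_tsv(omap: OrthologMap, path) -> None:
    pd.DataFrame(omap.pairs, columns=["id_a", "id_b"]).to_csv(path, sep="\t", index=False)


def write_gmt(gene_sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name, description, tab-separated members."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
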