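"""End-to-end orchestration: generate -> noise -> calls -> mi -> translate -> score.

A run is driven by a flat ``key: value`` config (mirrored by CLI flags;
flags win).  Stages whose inputs are supplied precomputed are skipped — in
particular, providing NES/FDR matrices skips the expression stages entirely.
Every run writes a manifest with the config snapshot, package version and
per-output checksums, so deterministic stages can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from orthoset import __version__, diffexpr, evaluation, infometrics, io, noise, translator
from orthoset.synthetic import (
    SyntheticExpressionConfig,
    SyntheticTranslationConfig,
    generate_replicate_expression,
    generate_translation_dataset,
)

log = logging.getLogger("orthoset")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "orthoset_run"
    seed: int = 0
    # module parameters (defaults follow the pipeline's reference settings)
    n_bins: int = 14
    k_sd: float = 3.0
    alpha: float = 0.01
    fdr_cut: float = 0.25
    n_components: int = 8
    n_perm: int = 1000
    covariance: str = "diagonal"
    df_method: str = "normal"
    # optional precomputed inputs; empty string means "generate synthetically"
    expression_tsv: str = ""
    control_tsv: str = ""
    rat_nes_tsv: str = ""
    rat_fdr_tsv: str = ""
    human_fdr_tsv: str = ""
    gold_tsv: str = ""
    ortholog_map_tsv: str = ""
    # stage toggles
    run_noise: bool = True
    run_calls: bool = True
    run_mi: bool = True
    run_translate: bool = True
    run_score: bool = True
    # synthetic generation knobs (used when inputs are not supplied)
    synth_n_genes: int = 500
    synth_n_genesets: int = 200
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("expression_tsv", "control_tsv", "rat_nes_tsv", "rat_fdr_tsv",
                     "human_fdr_tsv", "gold_tsv", "ortholog_map_tsv"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} points at a missing file: {p}")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_cut <= 1:
            raise ValueError("alpha and fdr_cut must be valid thresholds")
        if self.n_components < 1 or self.n_bins < 2 or self.n_perm < 100:
            raise ValueError("invalid module parameter")


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timestamps: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "outputs": self.outputs,
                "timestamps": self.timestamps,
                "stages_run": self.stages_run,
            },
            indent=2,
            sort_keys=True,
        )


_BOOL_KEYS = {"run_noise", "run_calls", "run_mi", "run_translate", "run_score"}
_INT_KEYS = {"seed", "n_bins", "n_components", "n_perm", "synth_n_genes", "synth_n_genesets"}
_FLOAT_KEYS = {"k_sd", "alpha", "fdr_cut"}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key: value`` config file (one pair per line, # comments)."""
    cfg = PipelineConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, value = (s.strip() for s in line.split(":", 1))
        if not hasattr(cfg, key):
            raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _BOOL_KEYS:
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        else:
            setattr(cfg, key, value)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the stages in dependency order and write a run manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)

    def record(stage: str, *paths: Path) -> None:
        manifest.stages_run.append(stage)
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        for p in paths:
            manifest.outputs[str(p)] = _sha256(p)

    try:
        # --- expression branch -------------------------------------------
        expr = None
        if config.run_noise or config.run_calls:
            if config.expression_tsv:
                expr = io.read_expression_tsv(config.expression_tsv, config.control_tsv)
            else:
                log.info("no expression input supplied; generating synthetic replicates")
                expr, _ = generate_replicate_expression(
                    SyntheticExpressionConfig(
                        n_genes=config.synth_n_genes, seed=config.seed, outlier_rate=0.01
                    )
                )
                p_e = out / "expression.tsv"
                p_c = out / "controls.tsv"
                io.write_expression_tsv(expr, p_e, p_c)
                record("generate_expression", p_e, p_c)

        if config.run_noise and expr is not None:
            curve = noise.build_noise_curve(expr, n_bins=config.n_bins)
            cleaned, report = noise.remove_outliers(expr, curve, k_sd=config.k_sd)
            sat = noise.build_saturation_curve(curve)
            linear = noise.linearize(cleaned, sat)
            p_nc = out / "noise_curve.tsv"
            p_sc = out / "saturation_curve.tsv"
            io.write_noise_curve_tsv(curve, p_nc)
            io.write_saturation_curve_tsv(sat, p_sc)
            record("noise", p_nc, p_sc)
            log.info("noise stage: %d replicate values flagged", report.n_flagged)

            if config.run_calls:
                lin_curve = noise.build_noise_curve(linear, n_bins=config.n_bins)
                calls = diffexpr.call_differential_genes(
                    linear, lin_curve, alpha=config.alpha, df_method=config.df_method
                )
                p_calls = out / "gene_calls.tsv"
                io.write_activation_tsv(diffexpr.binarize_genes(calls), p_calls)
                record("calls", p_calls)

        # --- gene-set branch ---------------------------------------------
        rat = human_fdr = gold = None
        dataset = None
        if config.rat_nes_tsv:
            if config.rat_fdr_tsv:
                rat = io.read_scores_tsv(config.rat_nes_tsv, config.rat_fdr_tsv, species="rat")
            else:
                nes = io.read_matrix_tsv(config.rat_nes_tsv)
                # no significance supplied: all-off placeholder FDR (mi stage
                # then sees an empty rat activation pattern)
                rat = diffexpr.GeneSetScoreMatrix(nes=nes, fdr=1.0 + 0.0 * nes, species="rat")
            if config.human_fdr_tsv:
                human_fdr = io.read_matrix_tsv(config.human_fdr_tsv)
            if config.gold_tsv:
                gold = io.read_activation_tsv(config.gold_tsv)
        elif config.run_translate or config.run_mi or config.run_score:
            log.info("no NES input supplied; generating a synthetic translation dataset")
            dataset = generate_translation_dataset(
                SyntheticTranslationConfig(n_genesets=config.synth_n_genesets, seed=config.seed)
            )
            rat = dataset.rat
            human_fdr = dataset.human_train.fdr
            gold = dataset.human_labels_test
            p_nes = out / "rat_nes.tsv"
            p_fdr = out / "rat_fdr.tsv"
            p_hfdr = out / "human_fdr_train.tsv"
            p_gold = out / "human_gold.tsv"
            io.write_scores_tsv(rat, p_nes, p_fdr)
            io.write_matrix_tsv(human_fdr, p_hfdr, index_label="gene_set")
            io.write_activation_tsv(gold, p_gold)
            record("generate_translation", p_nes, p_fdr, p_hfdr, p_gold)

        train_labels = None
        if human_fdr is not None:
            hf = diffexpr.GeneSetScoreMatrix(nes=0.0 * human_fdr, fdr=human_fdr, species="human")
            train_labels = diffexpr.binarize_genesets(hf, fdr_cut=config.fdr_cut)

        if config.run_mi and rat is not None and train_labels is not None:
            omap = (
                io.read_ortholog_map_tsv(config.ortholog_map_tsv)
                if config.ortholog_map_tsv
                else (dataset.ortholog_map if dataset is not None else None)
            )
            if omap is None:
                log.info("mi stage skipped: no ortholog map available")
            else:
                rat_act = diffexpr.binarize_genesets(rat, fdr_cut=config.fdr_cut)
                train_cols = list(train_labels.stimulus_ids)
                rat_act_train = diffexpr.ActivationMatrix(
                    on=rat_act.on[train_cols], source="gene set", threshold=config.fdr_cut
                )
                table, hist = infometrics.pairwise_mi_screen(
                    rat_act_train, train_labels, omap, n_perm=config.n_perm, seed=config.seed
                )
                p_mi = out / "mi_ranked.tsv"
                p_hist = out / "mi_null_histogram.tsv"
                table.to_csv(p_mi, sep="\t", index=False)
                hist.to_csv(p_hist, sep="\t", index=False)
                record("mi", p_mi, p_hist)

        predictions = None
        if config.run_translate and rat is not None and train_labels is not None:
            test_ids = [s for s in rat.stimulus_ids if s not in set(train_labels.stimulus_ids)]
            if not test_ids:
                raise ValueError("translate stage: no test stimuli beyond the labelled set")
            pca = translator.fit_pca(rat, config.n_components)
            predictions = translator.predict_loo_ensemble(
                pca, train_labels, test_ids, config.n_components, covariance=config.covariance
            )
            p_pred = out / "predictions.tsv"
            io.write_matrix_tsv(predictions.p_on, p_pred, index_label="gene_set")
            record("translate", p_pred)

        if config.run_score and predictions is not None and gold is not None:
            report = evaluation.score(predictions, gold)
            p_score = out / "score.json"
            p_score.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
            record("score", p_score)
    except Exception as exc:
        stage = manifest.stages_run[-1] if manifest.stages_run else "startup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
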