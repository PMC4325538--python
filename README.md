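# orthoset

Cross-species gene-set activation prediction toolkit. Given replicate
microarray expression data and per-species gene-set enrichment scores
(NES + FDR), the pipeline:

1. **models replicate noise** — pools all (gene, stimulus) replicate groups
   into a single "universal" curve of replicate SD versus mean expression
   (14 equal-count bins by default), under the assumption that measurement
   noise depends only on the mean level (`orthoset.noise`);
2. **removes outliers** — iteratively flags replicates deviating more than
   3 curve-SDs from their group mean (worst-first), discarding groups left
   with fewer than two survivors;
3. **corrects saturation** — when true noise is constant, the observed
   noise curve equals dF/dg of the saturation map F, so integrating its
   reciprocal recovers F up to an affine transform; applying F⁻¹
   linearizes the signal;
4. **calls activation** — curve-SD two-sample tests of treated versus
   control means (P < 0.01) for genes, and FDR < 0.25 binarization for
   gene sets (`orthoset.diffexpr`);
5. **screens cross-species mutual information** — Shannon/joint entropy and
   MI in bits over binary on/off profiles for every ortholog pair (with
   multiplicity), with an add-one permutation p-value and a null-MI
   histogram (`orthoset.infometrics`);
6. **translates** — PCA of the combined train+test NES matrix (stimuli as
   samples), then per gene set a two-class pooled-diagonal-Gaussian
   classifier with empirical priors on the N leading components (default
   N = 8, selectable by internal leave-one-out), ensembled by averaging the
   posteriors of all leave-one-training-stimulus-out fits
   (`orthoset.translator`);
7. **evaluates** — AUPR, AUROC, Pearson (binary and 1−FDR), balanced
   accuracy and Matthews correlation, plus a stratified 10%-resampling
   robustness ranking of competing prediction sets (`orthoset.evaluation`).

`orthoset.synthetic` generates all fixtures with the statistical structure
the pipeline assumes — constant true-space noise through a monotone concave
saturation with injected outliers, and paired-species matrices with
low-rank latent structure (including anticorrelated gene sets) — so every
stage is testable without any external download.

## CLI

All tabular I/O is TSV with a header row; gene sets use GMT. Logs go to
stderr.

```sh
# synthetic fixtures
orthoset generate --kind expression --out-dir data/ --seed 1 --outlier-rate 0.01
orthoset generate --kind translation --out-dir data/ --seed 1

# noise curve, outlier removal, saturation correction
orthoset noise --expression data/expression.tsv --controls data/controls.tsv \
    --out-dir out/ --n-bins 14 --k-sd 3

# differential calls (genes) or FDR binarization (gene sets)
orthoset calls --expression out/linearized.tsv --controls out/linearized_controls.tsv \
    --out out/gene_calls.tsv --alpha 0.01

# cross-species MI screen
orthoset mi --activation-a rat_act.tsv --activation-b human_act.tsv \
    --ortholog-map data/ortholog_map.tsv --out out/mi.tsv --n-perm 1000 --seed 1

# prediction and scoring
orthoset translate --rat-nes data/rat_nes.tsv --train-labels human_train_labels.tsv \
    --out out/predictions.tsv --n-components 8
orthoset score --predictions out/predictions.tsv --gold data/human_gold.tsv
orthoset robustness --predictions mine out/predictions.tsv --predictions base base.tsv \
    --gold data/human_gold.tsv --fraction 0.1 --n-resamples 1000 --seed 1

# everything end to end from a flat key:value config (flags win)
orthoset run --config run.cfg --out-dir run_out --seed 7
```

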