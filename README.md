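# smokesig

Tobacco exposure leaves a reproducible imprint on the DNA methylome, and in
lung adenocarcinoma (LUAD) that imprint separates current- from
never-smokers well enough to classify exposure from 450K β-values alone.
`smokesig` is a Python toolkit for the full analysis: find a compact set of
smoking-signature CpG probes in an epigenome-wide matrix, then trace what
those probes plausibly regulate — first at the gene level through
differential methylation–expression correlation, then at the protein level
through shortest-path tracing on a weighted interaction network.

The pipeline, stage by stage:

1. **Preprocess** — drop all-missing features, samples with incomplete
   clinical records, and chrX/chrY probes/genes; audit per-probe normality
   with the Jarque–Bera test (β-values are bimodal, which is why the next
   stage is rank-based).
2. **Prescreen** — per-probe two-sided Wilcoxon rank-sum test of current vs
   never-smokers with Benjamini–Hochberg FDR control (q = 0.05).
3. **Deep select** — iterative PLS-DA: fit a partial-least-squares
   discriminant model on the surviving probes, rank probes by VIP
   (VIP_j = √(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)), drop the bottom
   10 %, refit; stop when stratified 5-fold CV accuracy stops improving and
   keep the probe set of the best iteration. Signatures are evaluated on
   held-out cohorts by sensitivity / specificity / accuracy.
4. **Differential correlation (DCS)** — for every (signature probe, gene)
   pair compute within-group biweight midcorrelation (bicor) and Spearman
   correlation; keep pairs with |r| ≥ TS2 = 0.6 in one smoking group and
   |r| ≤ TS1 = 0.3 in the other, and intersect the gene sets from the two
   methods. Linked genes form a soft-threshold co-expression weight network
   (a_ij = |cor|⁶) whose high-connectivity nodes are hub genes.
5. **PPI tracing** — map genes onto a STRING-style weighted graph
   (distance = 1001 − combined score), trace one Dijkstra shortest path per
   seed pair with deterministic lexicographic tie-breaking, rank non-seed
   intermediates by how many paths cross them, and remove promiscuous
   universal hubs flagged by a 100-round random-seed permutation test.

A synthetic-study generator (`smokesig.simulate`) plants known signature
probes, probe–gene couplings and PPI bridge proteins, so every stage has a
ground-truth recovery benchmark that runs offline in seconds.

## Worked example

```python
import numpy as np
from smokesig import SimulationConfig, generate_study, prescreen_probes, DeepSelectPLS

cfg = SimulationConfig(n_current=70, n_never=30, rng_seed=7)
study = generate_study(cfg)                      # 2000 probes, 50 planted

pres = prescreen_probes(study.methylation, study.metadata, q=0.05)
print(f"{int(pres.table['selected'].sum())} / {len(pres.table)} probes pass the prescreen")

res = DeepSelectPLS.from_dataframes(
    study.methylation.loc[pres.selected_probes], study.metadata
).fit()
print(res.summary())

truth = study.truth_signature_probes
print(f"planted-probe recall: {len(set(res.signature) & truth) / len(truth):.2f}")

X_val = study.validation_methylation.T
y_val = np.where(study.validation_metadata["smoking_status"] == "current", 1, -1)
print(f"held-out cohort accuracy: {res.evaluate(X_val, y_val).acc:.4f}")
```

Output:

```
50 / 2000 probes pass the prescreen
Deep-selecting PLS-DA signature
======================================
iterations run        : 6
stopping reason       : patience
best iteration        : 0
signature size        : 50
PLS components        : 1
CV sensitivity (SN)   : 1.0000
CV specificity (SP)   : 1.0000
CV accuracy (ACC)     : 1.0000
planted-probe recall: 1.00
held-out cohort accuracy: 1.0000
```

At Δβ = 0.25 the planted effect is strong: the FDR-controlled prescreen
isolates exactly the 50 planted probes (no false positives among 1950 null
probes), the elimination loop keeps them (cross-validated accuracy is
already perfect at the first iteration, and the best-iteration rule is
conservative on ties), and the signature classifies an independently drawn
cohort without error. Shrink `delta_beta` to watch each stage degrade.

The package also ships the published 105-probe LUAD smoking signature with
its annotations (`smokesig.load_signature_annotation()`); summarising it
with `smokesig.summarize_annotations` reproduces the signature's zone
distribution (45.7 % open sea, 25.7 % island), its 20 gene-less probes, and
its 85-probe → 77-gene first-symbol mapping.

## Command line

Every stage is a subcommand of `smokesig`:

```sh
smokesig simulate --config sim.yaml --out data/ --seed 5
smokesig preprocess --methylation data/methylation.tsv --metadata data/metadata.tsv --out prep/
smokesig prescreen --methylation data/methylation.tsv --metadata data/metadata.tsv --out prescreen.tsv
smokesig select --methylation data/methylation.tsv --metadata data/metadata.tsv \
    --prescreen prescreen.tsv --out select/
smokesig correlate --signature select/signature.tsv --methylation data/methylation.tsv \
    --expression data/expression.tsv --metadata data/metadata.tsv --method bicor --out corr/
smokesig ppi --edges data/ppi_edges.tsv --idmap data/id_map.tsv --genes corr/genes_bicor.txt \
    --floor 100 --rounds 100 --out ppi/
smokesig summarize            # packaged 105-probe signature annotation
```

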