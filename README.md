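# dopavuln

Lesion-vulnerability analysis for two-condition single-nucleus RNA-seq.

Midbrain dopamine (mDA) neurons differ sharply in how they respond to
toxic stress: in Parkinson's disease and in 6-OHDA lesion models, neurons
of the substantia nigra die while many ventral-tegmental neurons survive.
Given snRNA-seq of nuclei sorted from an intact and a lesioned hemisphere,
`dopavuln` answers three questions:

1. **How much of each transcriptomic population was lost?** For every
   subcluster with intact count `s_i` and lesioned count `s_l`,

       L = 1 − (β·s_l) / s_i,    β = N_intact_QC / N_lesioned_QC

   where β is a *yield normalization coefficient* computed over all
   QC-passing nuclei — it corrects for asymmetric sorting capture between
   hemispheres. `L = 1` is total loss, `L = 0` none; negative values are
   set to NA. Cluster loss `A` is the mean of non-NA subcluster losses,
   and territory/neighborhood losses aggregate the same subcluster values.
   Group differences are tested with a Kruskal-Wallis/Welch-ANOVA omnibus
   and Conover–Iman pairwise post hocs (BH-adjusted, rejection at
   adjusted p ≤ α/2).

2. **Which genes mark vulnerable and resilient populations?** Wilcoxon
   rank-sum DE on *intact* nuclei only (cluster vs all other intact
   dopaminergic nuclei), keeping genes significantly upregulated
   (Bonferroni p < 0.05, log2FC > 0.5) in *every* cluster with loss > 0.9
   (vulnerability) or < 0.5 (resilience); ranked by mean log2FC, top 20 / 8.

3. **Do those modules predict loss?** Each nucleus is scored against
   expression-matched control genes (24 bins, 100 controls per gene), and
   per-cluster loss is regressed on the square root of the mean module
   score, excluding the clusters that defined the module.

Everything runs on synthetic data with known ground truth: the bundled
generator plants territories, survival fractions, a sorting-yield
asymmetry, stress-shifted surviving nuclei, and graded vulnerability
programs, so every estimator can be checked against the planted truth.

## Worked example

```python
from dopavuln import RunConfig, run_pipeline
from dopavuln.simulate import module_config

# six territories, 900 nuclei each, planted losses 0.95 … 0.05
report = run_pipeline(RunConfig(sim=module_config(seed=1), seed=1))
print(report["headline"])
```

prints (abridged):

```
beta: 1.097
unit_loss: {"territory_0": 0.949, "territory_1": 0.654, "territory_2": 0.478,
            "territory_3": 0.325, "territory_4": 0.153, "territory_5": 0.153}
vulnerability genes: ['Slc6a3', 'Gene00016', 'Gene00009', 'Gene00005',
                      'Gene00029', 'Gene00003', 'Gene00021']
regression: {"slope": 0.858, "r_squared": 0.7746, "model_p": 0.00035,
             "transform": "sqrt(shift 0.19)", "n_clusters": 11}
```

Reading it: the estimated yield coefficient (1.097) matches the planted
capture asymmetry (0.9/0.82 ≈ 1.098); the six territory losses recover the
planted 0.95/0.65/0.45/0.30/0.15/0.05 — the lowest-loss territory is
slightly over-estimated because the NA rule truncates negative subcluster
values (see `docs/methods.md`); the recovered vulnerability module consists
entirely of planted program genes (including the `Slc6a3` transporter
analogue); and the module score still predicts loss with R² ≈ 0.77 after
the input clusters are excluded.

The same stages are available from the shell:

```sh
dopavuln simulate --out sim/ --seed 1
dopavuln qc --in sim/ --out qc/ --select-da
dopavuln cluster --in qc/ --out clusters/ --seed 1
dopavuln loss --labels clusters/labels.csv --beta 1.097 --out loss.csv
dopavuln run --out run/ --seed 1          # everything, with a JSON report
dopavuln show-config                       # effective defaults + provenance
```

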