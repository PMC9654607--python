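# urosig

Derivation and application of a urothelial IFNγ-response gene
signature for bladder cancer prognosis, as a tested, reusable Python
pipeline.

Bacillus Calmette–Guérin (BCG) immunotherapy for non-muscle-invasive
bladder cancer works by provoking an IFNγ-rich inflammatory response.
A gene signature capturing how normal urothelium responds to IFNγ
can be scored in tumour expression data to read out each tumour's
IFNγ signalling state: signature-low tumours recur and die more.
`urosig` implements that whole analysis for anyone who wants to
derive such a signature from a paired stimulation experiment and
apply it to tumour cohorts — plus synthetic-data generators with
planted ground truth, so every statistical claim the pipeline makes
is testable end to end without downloading any cohort.

## The method

1. **Differential expression.** From a paired control/IFNγ-treated
   design across independent donors, responsive genes are found with
   a donor-blocked likelihood-ratio test: per gene, nested OLS
   models on log₂(TPM+1) (full: treatment + donor; reduced: donor),
   LRT statistic N·ln(RSS₀/RSS₁), exact F calibration, and
   Benjamini–Hochberg q-values. Up-regulated candidates satisfy
   q < 0.05 and log₂FC > 1 (strictly more than two-fold).
2. **Consensus refinement.** Within each of ≥ 2 tumour cohorts, all
   pairwise Spearman correlations among the candidates are computed;
   each gene is summarised by its median correlation with the other
   candidates, and genes whose cross-cohort mean median rho exceeds
   0.5 form the signature — genes both induced in vitro and
   co-expressed in tumours.
3. **Scoring.** Each signature gene's log-expression vector is
   scaled to unit Euclidean length within the cohort, the scaled
   values are summed per patient, and the sums are rescaled to
   [0, 1]: a single IFNγ-signature score per tumour.
4. **Stratification.** Euclidean k-means (k = 2, k-means++, 50
   restarts) on the signature-gene expression splits each cohort
   into signature-high and -low groups.
5. **Survival.** Kaplan–Meier curves per group; Mantel-Cox and
   Gehan–Breslow–Wilcoxon tests; hazard ratios in Mantel-Haenszel
   exp((O−E)/V) and O/E-ratio forms; Cox proportional-hazards
   regression on the continuous score (Newton–Raphson partial
   likelihood, Efron ties).
6. **Mutational associations.** Mann–Whitney U tests of APOBEC
   signature exposures (SBS2/SBS13; SBS4/SBS5 as controls) and
   neoantigen load between groups, and OLS regression of neoantigen
   load on the score.

See `docs/methods.md` for assumptions, parameter defaults and what
the synthetic generators do and do not emulate.

## Worked example

A fully synthetic study: a 1000-gene paired screen across 6 donors
with a planted 33-gene IFNγ module, two 200-patient tumour cohorts
driven by a bimodal latent IFNγ activity, and survival times planted
with a low-vs-high hazard ratio of 3.

```python
import pandas as pd
from urosig import log2p1_transform, run_derivation, run_cohort_analysis
from urosig.core_io import ClinicalTable
from urosig.signature import compute_scores
from urosig.synthetic_data import generate_study, generate_survival

study = generate_study(seed=1, n_patients=200)
cohorts = {k: log2p1_transform(v) for k, v in study["cohorts"].items()}
deriv = run_derivation(log2p1_transform(study["invitro"]),
                       study["design"], cohorts)
print(f"screen: {len(deriv.up_genes)} up / {len(deriv.down_genes)} down")
print(f"signature: {len(deriv.signature)} genes")

frames = []
for i, name in enumerate(cohorts):
    st = compute_scores(cohorts[name], deriv.signature, name)
    frames.append(generate_survival(study["cohort_truths"][name], st,
                                    seed=100 + i).df)
clinical = ClinicalTable(pd.concat(frames), "RFS")
analysis = run_cohort_analysis(cohorts, deriv.signature, clinical,
                               pooling="separate", seed=1)
print(f"Mantel-Cox chi2 = {analysis.mantel_cox.chi_square:.2f}, "
      f"p = {analysis.mantel_cox.p_value:.3g}")
hr = analysis.hr_mantel_haenszel
print(f"HR (low vs high) = {hr.hr:.2f} [{hr.ci95[0]:.2f}, {hr.ci95[1]:.2f}]")
```

Output:

```
screen: 49 up / 36 down
signature: 33 genes
Mantel-Cox chi2 = 54.74, p = 1.37e-13
HR (low vs high) = 2.65 [2.05, 3.44]
```

The screen recovers the planted responsive genes (49 of 50 up), the
consensus filter returns exactly the planted 33-gene module, and the
signature-low group shows the planted excess hazard: the Kaplan–Meier
split is highly significant and the estimated low-vs-high hazard
ratio of 2.65 sits near the planted value of 3 (dichotomisation and
k-means misassignment attenuate it slightly).

The same flow is available from a shell:

```sh
urosig run-all --seed 1 --out-dir out/
urosig simulate --seed 1 --out-dir sim/
urosig diffexpr --expression sim/invitro_tpm.tsv --design sim/design.tsv --out-dir de/
```

with further subcommands `derive-signature`, `score`, `stratify`,
`heatmap-order`, `survival` and `associate` for running stages on
your own TSV tables (genes × samples expression matrices;
patient_id/time/event clinical tables; per-patient SBS exposure
tables).

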