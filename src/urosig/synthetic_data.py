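"""Synthetic cohorts with planted ground truth.

Four generators emulate the data shapes the pipeline consumes:

* ``generate_invitro`` — a paired control/treated expression
  experiment across independent donors with planted log2
  fold-changes, mimicking the in vitro IFNγ stimulation screen.
* ``generate_cohort`` — a tumour cohort in which a latent per-patient
  "IFNγ activity" factor drives correlated expression of a planted
  signature-gene module on top of background genes.
* ``generate_survival`` — follow-up times from an exponential
  proportional-hazards model in the (rescaled) signature score, with
  administrative censoring.  Hazard decreases with score: the planted
  hazard ratio expresses low-versus-high risk, matching the observed
  direction that signature-low tumours do worse.
* ``generate_mutation_table`` — APOBEC signature exposures (SBS2,
  SBS13) log-normally enriched with latent activity, non-APOBEC
  controls (SBS4, SBS5) independent of it, and a Poisson neoantigen
  load tied to total APOBEC exposure.

All generators are pure functions of their arguments including the
seed.  Expression is synthesised on the log2(TPM+1) scale as
baseline + effects + Gaussian noise and back-transformed via
TPM = max(0, 2^x - 1); the fraction of cells clipped at zero is
recorded on the truth object (it is 0 whenever baselines stay at
least 3 noise SDs above zero).

The default module gene symbols are a synthetic stand-in list of
well-known IFNγ-response genes (chemokines, GBPs, MHC machinery);
they name nothing about any real cohort's data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix, MutationTable, Scale
from .signature import ScoreTable

__all__ = [
    "IFNG_MODULE_GENES",
    "InVitroTruth",
    "CohortTruth",
    "generate_invitro",
    "generate_cohort",
    "generate_survival",
    "generate_mutation_table",
    "generate_study",
]

# Synthetic 33-gene IFNγ-response module used as default planted signature.
IFNG_MODULE_GENES: tuple[str, ...] = (
    "CXCL9", "CXCL10", "CXCL11", "GBP1", "GBP2", "GBP4", "GBP5", "STAT1",
    "IRF1", "TAP1", "TAP2", "B2M", "CD74", "CIITA", "HLA-A", "HLA-B",
    "HLA-C", "HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1", "HLA-DMA",
    "PSMB8", "PSMB9", "UBE2L6", "IDO1", "IL32", "IL18BP", "CD274", "VSIR",
    "SOCS1", "ICAM1", "IFNG",
)


@dataclass
class InVitroTruth:
    """Planted ground truth of a paired in vitro experiment."""

    up_genes: list[str]
    down_genes: list[str]
    null_genes: list[str]
    effects: pd.Series            # planted per-gene log2 effect
    noise_sd: float
    donor_effect_sd: float
    seed: int
    clip_fraction: float = 0.0


@dataclass
class CohortTruth:
    """Planted ground truth of a tumour cohort simulation."""

    latent_activity: pd.Series    # A_p per patient
    loadings: pd.Series           # lambda_g per gene (0 off-module)
    baseline: pd.Series           # alpha_g per gene
    noise_sd: float
    planted_hr: float             # low-vs-high hazard ratio per unit score
    censor_time: float
    seed: int
    clip_fraction: float = 0.0

    @property
    def module_genes(self) -> list[str]:
        return list(self.loadings.index[self.loadings > 0])

    def high_activity_labels(self) -> pd.Series:
        """Patients above the midpoint of the activity mixture means."""
        a = self.latent_activity
        return (a > a.mean()).map({True: "high", False: "low"})


def _back_transform(x: np.ndarray) -> tuple[np.ndarray, float]:
    """log2(TPM+1) -> TPM with clipping at zero; returns clip fraction."""
    tpm = np.power(2.0, x) - 1.0
    clipped = tpm < 0
    tpm[clipped] = 0.0
    return tpm, float(clipped.mean())


def generate_invitro(
    n_donors: int = 6,
    n_genes: int = 1000,
    n_up: int = 60,
    n_down: int = 40,
    effect_lo: float = 1.2,
    effect_hi: float = 4.0,
    noise_sd: float = 0.4,
    donor_effect_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, "PairedDesign", InVitroTruth]:
    """Paired control/treated TPM matrix with planted fold-changes.

    Log-scale expression is alpha_g + delta_donor + Delta_g * treated
    + eps with eps ~ N(0, noise_sd); Delta_g is uniform on
    [effect_lo, effect_hi] for up genes, the negated range for down
    genes, and 0 otherwise.  effect_lo must exceed 1 (log2 units) so
    planted genes genuinely pass a two-fold screen.
    """
    from .core_io import PairedDesign

    if n_donors < 2:
        raise ValueError("paired test undefined with fewer than 2 donors")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if n_up and effect_lo <= 1.0:
        raise ValueError("effect_lo must exceed 1 (log2 units)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    up = genes[:n_up]
    down = genes[n_up:n_up + n_down]
    null = genes[n_up + n_down:]
    effects = np.zeros(n_genes)
    effects[:n_up] = rng.uniform(effect_lo, effect_hi, n_up)
    effects[n_up:n_up + n_down] = -rng.uniform(effect_lo, effect_hi, n_down)

    donors = [f"D{d + 1}" for d in range(n_donors)]
    samples = [f"{d}_ctrl" for d in donors] + [f"{d}_ifng" for d in donors]
    treated = np.concatenate([np.zeros(n_donors), np.ones(n_donors)])
    donor_idx = np.concatenate([np.arange(n_donors)] * 2)

    alpha = rng.uniform(2.0, 9.0, n_genes)
    delta_donor = rng.normal(0.0, donor_effect_sd, n_donors)
    eps = rng.normal(0.0, noise_sd, (n_genes, 2 * n_donors))
    x = (alpha[:, None] + delta_donor[donor_idx][None, :]
         + effects[:, None] * treated[None, :] + eps)
    tpm, clip_fraction = _back_transform(x)

    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=samples), Scale.TPM)
    design = PairedDesign({d: (f"{d}_ctrl", f"{d}_ifng") for d in donors})
    truth = InVitroTruth(up, down, null, pd.Series(effects, index=genes),
                         noise_sd, donor_effect_sd, seed, clip_fraction)
    return matrix, design, truth


def generate_cohort(
    n_patients: int = 200,
    module_genes: Sequence[str] = IFNG_MODULE_GENES,
    n_background: int = 117,
    loading: float = 1.5,
    noise_sd: float = 0.5,
    activity_mix: tuple[float, float, float] = (0.5, 0.0, 2.0),
    seed: int = 0,
    planted_hr: float = 3.0,
    censor_time: float = 60.0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Tumour cohort driven by a latent bimodal activity factor.

    The latent activity A_p follows a two-component unit-variance
    Gaussian mixture (p_high, mu_low, mu_high); module genes load on
    it with coefficient ``loading``, background genes with 0, and
    log-expression is alpha_g + lambda_g * A_p + N(0, noise_sd).
    The bimodal mixture plants the high/low structure a two-group
    clustering is expected to recover.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("module_genes must be non-empty")
    p_high, mu_low, mu_high = activity_mix
    if not 0.0 <= p_high <= 1.0:
        raise ValueError("p_high must be in [0,1]")
    if loading < 0:
        raise ValueError("loading must be non-negative")
    rng = np.random.default_rng(seed)

    genes = module_genes + [f"BG{i:04d}" for i in range(n_background)]
    patients = [f"P{i:04d}" for i in range(n_patients)]
    lam = np.concatenate(
        [np.full(len(module_genes), loading), np.zeros(n_background)])

    component = rng.random(n_patients) < p_high
    activity = np.where(component,
                        rng.normal(mu_high, 1.0, n_patients),
                        rng.normal(mu_low, 1.0, n_patients))
    alpha = rng.uniform(3.0, 8.0, len(genes))
    eps = rng.normal(0.0, noise_sd, (len(genes), n_patients))
    x = alpha[:, None] + lam[:, None] * activity[None, :] + eps
    tpm, clip_fraction = _back_transform(x)

    matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=patients), Scale.TPM)
    truth = CohortTruth(
        pd.Series(activity, index=patients),
        pd.Series(lam, index=genes),
        pd.Series(alpha, index=genes),
        noise_sd, planted_hr, censor_time, seed, clip_fraction)
    return matrix, truth


def generate_survival(
    truth: CohortTruth,
    scores: ScoreTable,
    baseline_hazard: float = 0.03,
    seed: int = 0,
    contrast: str = "groups",
) -> ClinicalTable:
    """Exponential survival times under proportional hazards in the score.

    Each patient's hazard is baseline_hazard * planted_hr**(-z), so a
    LOW score implies a HIGHER hazard; times are administratively
    censored at ``truth.censor_time``.

    ``contrast`` fixes what the planted hazard ratio spans.  With
    ``"groups"`` (default) z is the score linearly rescaled so the
    planted low- and high-activity groups have mean 0 and 1:
    planted_hr is then the hazard ratio between the two planted
    groups, the contrast a dichotomised analysis estimates.  With
    ``"unit"`` z is the score itself, so planted_hr spans score 0 to
    1 and the true Cox coefficient of the score is exactly
    -ln(planted_hr).  If the group contrast is degenerate (a group
    empty, or group mean scores closer than 0.05), ``"groups"`` falls
    back to ``"unit"`` with a warning.
    """
    import logging

    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if contrast not in ("groups", "unit"):
        raise ValueError("contrast must be 'groups' or 'unit'")
    s = np.asarray(scores.score, float)
    if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
        raise ValueError("scores must be rescaled to [0,1]")
    z = s
    if contrast == "groups":
        labels = truth.high_activity_labels().reindex(scores.patient_ids)
        m_low = s[(labels == "low").to_numpy()].mean() if (labels == "low").any() else np.nan
        m_high = s[(labels == "high").to_numpy()].mean() if (labels == "high").any() else np.nan
        if np.isfinite(m_low) and np.isfinite(m_high) and m_high - m_low > 0.05:
            z = (s - m_low) / (m_high - m_low)
        else:
            logging.getLogger("urosig").warning(
                "generate_survival: degenerate group contrast; "
                "planted_hr spans score 0 to 1 instead")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.power(truth.planted_hr, -z)
    t = rng.exponential(1.0 / hazard)
    event = (t <= truth.censor_time).astype(int)
    time = np.minimum(t, truth.censor_time)
    df = pd.DataFrame({"time": time, "event": event},
                      index=pd.Index(scores.patient_ids, name="patient_id"))
    return ClinicalTable(df, "RFS")


def generate_mutation_table(
    truth: CohortTruth,
    enrich: float = 1.0,
    seed: int = 0,
    base_log_mean: float = 3.0,
    log_sd: float = 0.6,
) -> MutationTable:
    """Mutational-signature exposures coupled to latent activity.

    SBS2/SBS13 are log-normal with log-mean base + enrich * A_p;
    SBS4/SBS5 are log-normal and independent of activity; the
    neoantigen load is Poisson with log-mean affine in
    log1p(SBS2 + SBS13), tying predicted antigen counts to APOBEC
    mutagenesis.
    """
    if enrich < 0:
        raise ValueError("enrich must be non-negative")
    rng = np.random.default_rng(seed)
    a = truth.latent_activity.to_numpy(float)
    n = len(a)
    sbs2 = rng.lognormal(base_log_mean + enrich * a, log_sd, n)
    sbs13 = rng.lognormal(base_log_mean - 0.2 + enrich * a, log_sd, n)
    sbs4 = rng.lognormal(base_log_mean - 0.5, log_sd, n)
    sbs5 = rng.lognormal(base_log_mean + 0.5, log_sd, n)
    neo_rate = np.exp(0.5 + 0.6 * np.log1p(sbs2 + sbs13))
    neoantigens = rng.poisson(neo_rate)
    df = pd.DataFrame(
        {"SBS2": sbs2, "SBS13": sbs13, "SBS4": sbs4, "SBS5": sbs5,
         "neoantigen_load": neoantigens},
        index=pd.Index(list(truth.latent_activity.index), name="patient_id"))
    return MutationTable(df)


def generate_study(
    seed: int,
    n_patients: int = 200,
    n_genes: int = 1000,
    n_up: int = 50,
    n_down: int = 40,
    module_genes: Sequence[str] = IFNG_MODULE_GENES,
    loading: float = 1.5,
    cohort_noise_sd: float = 0.5,
    planted_hr: float = 3.0,
    enrich: float = 1.0,
    module_effect_lo: float = 2.5,
    module_effect_hi: float = 4.5,
) -> dict:
    """Full synthetic study linking the in vitro screen to tumour cohorts.

    Generates a paired in vitro experiment whose planted up-regulated
    genes include the signature module, plus two tumour cohorts in
    which exactly the module genes load on the latent activity factor
    while the remaining up-genes are present but uncorrelated.  Gene
    identifiers are shared across the two data types so signature
    derivation can run end to end: the first ``len(module_genes)``
    planted up-genes carry the module symbols, and the next
    ``n_up - len(module_genes)`` cohort background genes carry the
    remaining up-gene symbols.

    Module genes receive in vitro effects from the higher range
    [module_effect_lo, module_effect_hi]: the genes that survive the
    tumour-consensus filter are, in the system being emulated, among
    the most strongly induced responders (chemokines induced from
    near-zero), not borderline two-fold changes.

    Returns a dict with keys ``invitro``, ``design``,
    ``invitro_truth``, ``cohorts`` (name -> TPM matrix),
    ``cohort_truths``, ``module_genes`` and ``enrich``.
    """
    module_genes = list(module_genes)
    if n_up < len(module_genes):
        raise ValueError("n_up must cover the signature module")
    invitro, design, iv_truth = generate_invitro(
        n_genes=n_genes, n_up=n_up, n_down=n_down, seed=seed)

    rename_iv = dict(zip(iv_truth.up_genes[:len(module_genes)], module_genes))
    invitro.data.rename(index=rename_iv, inplace=True)
    iv_truth.up_genes = [rename_iv.get(g, g) for g in iv_truth.up_genes]
    iv_truth.effects.rename(index=rename_iv, inplace=True)

    # strengthen module-gene induction on the log scale (noise preserved)
    rng = np.random.default_rng(seed + 7)
    new_effects = rng.uniform(module_effect_lo, module_effect_hi,
                              len(module_genes))
    treated_cols = [t for _, t in design.pairs.values()]
    for g, eff in zip(module_genes, new_effects):
        boost = eff - iv_truth.effects[g]
        logvals = np.log2(invitro.data.loc[g, treated_cols] + 1.0) + boost
        invitro.data.loc[g, treated_cols] = np.maximum(
            np.power(2.0, logvals) - 1.0, 0.0)
        iv_truth.effects[g] = eff

    extra_up = iv_truth.up_genes[len(module_genes):]
    cohorts: dict[str, ExpressionMatrix] = {}
    truths: dict[str, CohortTruth] = {}
    for i, name in enumerate(("cohort_a", "cohort_b")):
        m, t = generate_cohort(
            n_patients=n_patients, module_genes=module_genes,
            loading=loading, noise_sd=cohort_noise_sd,
            seed=seed + 101 + i, planted_hr=planted_hr)
        rename_bg = {f"BG{j:04d}": g for j, g in enumerate(extra_up)}
        m.data.rename(index=rename_bg, inplace=True)
        for attr in ("loadings", "baseline"):
            getattr(t, attr).rename(index=rename_bg, inplace=True)
        # keep patient IDs disjoint across cohorts
        prefix = {p: f"{name}_{p}" for p in m.sample_ids}
        m.data.rename(columns=prefix, inplace=True)
        t.latent_activity.rename(index=prefix, inplace=True)
        cohorts[name] = m
        truths[name] = t
    return {
        "invitro": invitro, "design": design, "invitro_truth": iv_truth,
        "cohorts": cohorts, "cohort_truths": truths,
        "module_genes": module_genes, "enrich": enrich,
    }
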