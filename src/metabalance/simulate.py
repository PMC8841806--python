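"""Synthetic paired-cohort generator.

A single latent axis per patient drives (i) planted positive/negative
expression programs in the tumor-vs-normal log2 fold changes, (ii) the
log-scale tumor-to-liver uptake ratio, (iii) proportional-hazards survival
through the true balance score, and (iv) two antagonistic binary mutation
labels. Counts are negative-binomial around the implied means. All
randomness flows from one seed through named substreams, so regenerating a
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import (
    CountsTable,
    GeneSet,
    GeneSetCollection,
    MutationTable,
    write_clinical_tsv,
    write_counts_tsv,
    write_gmt,
    write_maf_lite,
    write_pairing_tsv,
)
from .normalize import gene_zscores
from .scoring import metabolic_balance_score

__all__ = ["SimulationParams", "SyntheticCohort", "simulate_cohort",
           "write_cohort", "fixture_params"]

_SUBSTREAMS = ("latent", "baseline", "fc", "counts", "tlr", "dfs", "os", "mut")


@dataclass
class SimulationParams:
    n_patients: int = 60
    n_genes: int = 1000
    n_glucose: int = 25
    n_lipid: int = 25
    beta_glu: float = 0.8      # log2-FC units per latent SD, positive coupling
    beta_lip: float = 0.8      # magnitude of the negative coupling
    gamma0: float = 1.0        # log2-TLR intercept
    gamma1: float = 0.8        # log2-TLR slope on the latent axis
    sigma_fc: float = 0.6
    sigma_tlr: float = 0.5
    nb_dispersion: float = 0.08
    baseline_logmean_mean: float = 4.5   # natural-log scale of expected counts
    baseline_logmean_sd: float = 1.2
    depth_sigma: float = 0.2             # per-sample lognormal depth variation
    suv_mean_liver: float = 2.2
    suv_mean_sd: float = 0.3
    surv_baseline_hazard: float = 0.015  # events per month
    surv_log_hr: float = 0.4             # log hazard ratio per true-MBS unit
    censor_window: float = 120.0         # months
    mut_intercept: float = -0.3
    mut_slope: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for f in ("n_patients", "n_genes", "n_glucose", "n_lipid"):
            if getattr(self, f) <= 0:
                bad.append(f)
        for f in ("sigma_fc", "sigma_tlr", "nb_dispersion", "depth_sigma",
                  "suv_mean_liver", "surv_baseline_hazard", "censor_window"):
            if getattr(self, f) <= 0:
                bad.append(f)
        if self.n_glucose + self.n_lipid > self.n_genes:
            bad.append("n_glucose+n_lipid")
        if self.n_patients < 3:
            bad.append("n_patients")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            bad.append("seed")
        if bad:
            raise ValidationError(f"invalid simulation parameters: {bad}")


@dataclass
class SyntheticCohort:
    counts: CountsTable
    clinical: pd.DataFrame
    mutations: MutationTable
    gene_sets: GeneSetCollection
    truth: dict

    @property
    def patients(self) -> pd.Index:
        return self.clinical.index


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Draw one cohort according to the generative model in the module docstring."""
    params.validate()
    rngs = _rngs(params.seed)
    npat, ngene = params.n_patients, params.n_genes

    patients = [f"P{i+1:04d}" for i in range(npat)]
    tumor_ids = [f"T_{p}" for p in patients]
    normal_ids = [f"N_{p}" for p in patients]
    genes = ([f"GLU{i+1:03d}" for i in range(params.n_glucose)]
             + [f"LIP{i+1:03d}" for i in range(params.n_lipid)]
             + [f"BG{i+1:04d}" for i in range(ngene - params.n_glucose - params.n_lipid)])
    glu_genes = genes[:params.n_glucose]
    lip_genes = genes[params.n_glucose:params.n_glucose + params.n_lipid]

    a = rngs["latent"].standard_normal(npat)

    baseline = np.exp(rngs["baseline"].normal(params.baseline_logmean_mean,
                                              params.baseline_logmean_sd, size=ngene))

    # true log2 fold changes: planted coupling + noise
    fc = rngs["fc"].normal(0.0, params.sigma_fc, size=(ngene, npat))
    fc[:params.n_glucose] += params.beta_glu * a
    fc[params.n_glucose:params.n_glucose + params.n_lipid] -= params.beta_lip * a
    true_fc = pd.DataFrame(fc, index=genes, columns=patients)

    depth = np.exp(rngs["counts"].normal(0.0, params.depth_sigma, size=2 * npat))
    normal_mean = baseline[:, None] * depth[:npat][None, :]
    tumor_mean = baseline[:, None] * (2.0 ** fc) * depth[npat:][None, :]
    normal_counts = _nb(rngs["counts"], normal_mean, params.nb_dispersion)
    tumor_counts = _nb(rngs["counts"], tumor_mean, params.nb_dispersion)
    values = pd.DataFrame(
        np.hstack([tumor_counts, normal_counts]).astype(np.int64),
        index=genes, columns=tumor_ids + normal_ids,
    )
    pairing = dict(zip(tumor_ids, normal_ids))
    counts = CountsTable(values=values, pairing=pairing)

    # imaging: log2 TLR linear in the latent axis, TLR floored at 1
    log2_tlr = (params.gamma0 + params.gamma1 * a
                + rngs["tlr"].normal(0.0, params.sigma_tlr, size=npat))
    tlr = np.maximum(2.0 ** log2_tlr, 1.0)
    suv_mean = np.clip(rngs["tlr"].normal(params.suv_mean_liver, params.suv_mean_sd,
                                          size=npat), 0.5, None)
    suv_max = tlr * suv_mean

    # true balance score from the planted fold changes (z-scored across patients)
    z_true = gene_zscores(true_fc)
    glu_set = GeneSet("GLUCOSE_PROGRAM", "planted positively coupled genes",
                      tuple(glu_genes))
    lip_set = GeneSet("LIPID_PROGRAM", "planted negatively coupled genes",
                      tuple(lip_genes))
    mbs_true = metabolic_balance_score(z_true, glu_set, lip_set).mbs

    clinical = pd.DataFrame({
        "suv_max": suv_max,
        "suv_mean_liver": suv_mean,
        "tlr": tlr,
    }, index=pd.Index(patients, name="sample"))
    mbs_arr = mbs_true.reindex(patients).to_numpy()
    for ep in ("dfs", "os"):
        rng = rngs[ep]
        rate = params.surv_baseline_hazard * np.exp(params.surv_log_hr * mbs_arr)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, params.censor_window, size=npat)
        time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
        clinical[f"{ep}_time"] = time
        clinical[f"{ep}_event"] = (t_event <= t_cens).astype(int)

    # antagonistic mutation labels on the same latent axis
    logistic = lambda z: 1.0 / (1.0 + np.exp(-z))
    p_tp53 = logistic(params.mut_intercept + params.mut_slope * a)
    p_ctnnb1 = logistic(params.mut_intercept - params.mut_slope * a)
    tp53 = rngs["mut"].random(npat) < p_tp53
    ctnnb1 = rngs["mut"].random(npat) < p_ctnnb1
    rows = [{"sample": p, "gene": "TP53"} for p, m in zip(patients, tp53) if m]
    rows += [{"sample": p, "gene": "CTNNB1"} for p, m in zip(patients, ctnnb1) if m]
    mutations = MutationTable(pairs=pd.DataFrame(rows, columns=["sample", "gene"]))

    gene_sets = GeneSetCollection()
    gene_sets.add(glu_set)
    gene_sets.add(lip_set)

    truth = {
        "latent": pd.Series(a, index=patients, name="latent"),
        "glucose_genes": list(glu_genes),
        "lipid_genes": list(lip_genes),
        "true_fc": true_fc,
        "mbs_true": mbs_true,
        "log2_tlr": pd.Series(log2_tlr, index=patients, name="log2_tlr"),
        "surv_log_hr": params.surv_log_hr,
    }
    return SyntheticCohort(counts=counts, clinical=clinical, mutations=mutations,
                           gene_sets=gene_sets, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 seed: int | None = None) -> dict[str, Path]:
    """Write the cohort in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "pairing": outdir / "pairing.tsv",
        "clinical": outdir / "clinical.tsv",
        "mutations": outdir / "mutations.maf.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_counts_tsv(cohort.counts, paths["counts"], seed=seed)
    write_pairing_tsv(cohort.counts.pairing, paths["pairing"], seed=seed)
    write_clinical_tsv(cohort.clinical, paths["clinical"], seed=seed)
    write_maf_lite(cohort.mutations, paths["mutations"], seed=seed)
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    truth_df = pd.DataFrame({
        "latent": cohort.truth["latent"],
        "mbs_true": cohort.truth["mbs_true"],
        "log2_tlr": cohort.truth["log2_tlr"],
    })
    write_clinical_tsv(truth_df, paths["truth"], seed=seed)
    return paths


def fixture_params(seed: int = 0) -> SimulationParams:
    """The small bundled cohort used by the test suite (60 patients, 1000 genes)."""
    return SimulationParams(n_patients=60, n_genes=1000, seed=seed)
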