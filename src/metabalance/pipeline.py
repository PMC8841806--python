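"""Orchestration of the discovery and validation runs.

``run_discovery`` goes counts -> TMM/CPM -> paired fold changes -> uptake
correlation screen -> derived gene programs -> signature scores (+ optional
over-representation tables). ``run_validation`` goes expression + survival ->
per-endpoint univariable Cox screen -> candidate intersection -> collinearity
filter -> multivariable fit -> prognostic index -> median-split risk groups ->
KM / log-rank -> per-gene t-tests -> balance-score stratification (+ optional
mutation chi-square). Every run writes a JSON manifest with input/output
digests so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import PipelineStageError, ValidationError
from .io_formats import (
    AnalysisConfig,
    GeneSet,
    comment_header,
    read_clinical_tsv,
    read_counts_tsv,
    read_expression_tsv,
    read_gmt,
    read_maf_lite,
    write_gmt,
)
from .normalize import cpm, gene_zscores, paired_log2_fc, tmm_factors
from .scoring import metabolic_balance_score, stratify_by_cutoff, tlr_phenotype
from .screen import ora_hypergeometric, screen_genes, sets_from_screen
from .survival_stats import (
    RiskGroups,
    SurvivalData,
    chisq_2x2,
    collinearity_filter,
    cox_fit,
    intersect_candidates,
    km_estimate,
    logrank_test,
    median_split,
    prognostic_index,
    ttest_by_group,
    univariable_screen,
)

__all__ = ["RunManifest", "run_discovery", "run_validation"]

log = logging.getLogger("metabalance")


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "version": __version__,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
            "notes": self.notes,
        }, indent=2, sort_keys=True)

    def write(self, path: Path) -> None:
        path.write_text(self.to_json() + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_inputs(manifest: RunManifest, paths: dict[str, str | None]) -> None:
    """Digest every declared input up front; a missing file aborts before any
    stage runs, so failures never leave partial outputs behind."""
    for name, p in paths.items():
        if p is None:
            continue
        if not Path(p).is_file():
            raise PipelineStageError("inputs", FileNotFoundError(f"{name}: {p}"))
        manifest.inputs[str(p)] = _sha256(p)


class _Stage:
    """Context manager adding stage names to errors and timings to the manifest."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest = manifest
        self.name = name

    def __enter__(self):
        self.t0 = _time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings[self.name] = _time.perf_counter() - self.t0
        if exc is not None and not isinstance(exc, PipelineStageError):
            raise PipelineStageError(self.name, exc) from exc
        return False


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(comment_header(seed))
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_discovery(config: AnalysisConfig) -> dict:
    """Execute the discovery arm; returns the in-memory results and manifest."""
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    outdir = Path(config.outdir)
    for key in ("counts", "pairing", "clinical", "candidates_gmt"):
        if getattr(config, key) is None:
            raise PipelineStageError("inputs", ValidationError(f"config.{key} is required"))
    _require_inputs(manifest, {
        "counts": config.counts, "pairing": config.pairing,
        "clinical": config.clinical, "candidates_gmt": config.candidates_gmt,
        "ora_gmt": config.ora_gmt,
    })
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage(manifest, "read"):
        counts = read_counts_tsv(config.counts, config.pairing)
        clinical = read_clinical_tsv(config.clinical, endpoints=())
        candidates_coll = read_gmt(config.candidates_gmt)
        candidates = candidates_coll.union()

    with _Stage(manifest, "normalize"):
        factors = tmm_factors(counts)
        mat = cpm(counts, factors)
        pairing = counts.pairing or {}
        if not pairing:
            raise ValidationError("discovery run requires tumor-normal pairing")
        fc = paired_log2_fc(mat, mat, pairing, pseudocount=config.pseudocount)
        log.info("normalize: %d genes, %d pairs, reference %s",
                 fc.shape[0], fc.shape[1], factors.reference)

    with _Stage(manifest, "uptake"):
        tlr = clinical["tlr"].reindex(fc.columns.str.replace("T_", "", regex=False))
        if tlr.isna().any():
            # clinical may be keyed by tumor sample id instead of patient id
            tlr = clinical["tlr"].reindex(fc.columns)
        if tlr.isna().any():
            bad = tlr.index[tlr.isna()][0]
            raise ValidationError(f"no TLR for patient {bad!r}")
        tlr.index = fc.columns
        uptake = np.log2(tlr) if config.use_log2_tlr else tlr
        phenotype, tlr_median = tlr_phenotype(tlr)

    with _Stage(manifest, "screen"):
        target = fc
        if config.correlate_on == "tumor":
            tum_cols = list(pairing.keys())
            target = np.log2(mat[tum_cols] + config.pseudocount)
            target.columns = fc.columns
        result = screen_genes(target, uptake, candidates,
                              alpha=config.screen_alpha, adjust=config.adjust_screen_p)
        log.info("screen: %d candidates in, %d tested, %d positive, %d negative, "
                 "%d missing, %d constant", len(candidates), len(result.records),
                 len(result.positive), len(result.negative),
                 len(result.missing), len(result.skipped))
        derived = sets_from_screen(result)

    with _Stage(manifest, "scoring"):
        z = gene_zscores(target)
        scores = None
        if result.positive and result.negative:
            scores = metabolic_balance_score(
                z, derived["GLUCOSE_PROGRAM"], derived["LIPID_PROGRAM"])
            groups = stratify_by_cutoff(scores.mbs, cutoff=config.mbs_cutoff)
            scores.frame["risk_group"] = groups
        else:
            manifest.notes.append("scoring skipped: an empty screen-derived program")

    ora_tables = {}
    if config.ora_gmt is not None:
        with _Stage(manifest, "ora"):
            coll = read_gmt(config.ora_gmt)
            universe = GeneSet("universe", "all tested genes",
                               tuple(result.records["gene"]))
            for name, genes in (("positive", result.positive),
                                ("negative", result.negative)):
                if genes:
                    query = GeneSet(name, "", tuple(genes))
                    ora_tables[name] = ora_hypergeometric(query, coll, universe)
    else:
        manifest.notes.append("ora skipped: no collection provided")

    with _Stage(manifest, "write"):
        out = {}
        out["correlations"] = outdir / "correlations.tsv"
        _write_tsv(result.records, out["correlations"], config.seed)
        out["derived_sets"] = outdir / "derived_sets.gmt"
        write_gmt(derived, out["derived_sets"])
        out["phenotype"] = outdir / "tlr_phenotype.tsv"
        _write_tsv(pd.DataFrame({"tlr": tlr, "phenotype": phenotype}),
                   out["phenotype"], config.seed, index_label="patient")
        if scores is not None:
            out["scores"] = outdir / "scores.tsv"
            _write_tsv(scores.frame, out["scores"], config.seed, index_label="sample")
        if result.missing or result.skipped:
            miss = pd.DataFrame(
                [(g, "absent from matrix") for g in result.missing]
                + [(g, "constant") for g in result.skipped],
                columns=["gene", "reason"])
            out["miss_log"] = outdir / "screen_miss_log.tsv"
            _write_tsv(miss, out["miss_log"], config.seed)
        for name, tab in ora_tables.items():
            out[f"ora_{name}"] = outdir / f"ora_{name}.tsv"
            _write_tsv(tab, out[f"ora_{name}"], config.seed)
        for name, p in out.items():
            manifest.outputs[str(p)] = _sha256(p)

    manifest.write(outdir / "manifest.json")
    return {"screen": result, "scores": scores, "ora": ora_tables,
            "factors": factors, "fold_changes": fc, "tlr_median": tlr_median,
            "manifest": manifest}


def _km_table(curves) -> pd.DataFrame:
    rows = []
    for label, c in curves.items():
        for t, n, s in zip(c.times, c.at_risk, c.survival):
            rows.append((label, t, n, s))
    return pd.DataFrame(rows, columns=["group", "time", "at_risk", "survival"])


def run_validation(config: AnalysisConfig) -> dict:
    """Execute the validation arm on an expression + survival cohort."""
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    outdir = Path(config.outdir)
    for key in ("expression", "clinical", "gene_sets_gmt"):
        if getattr(config, key) is None:
            raise PipelineStageError("inputs", ValidationError(f"config.{key} is required"))
    _require_inputs(manifest, {
        "expression": config.expression, "clinical": config.clinical,
        "gene_sets_gmt": config.gene_sets_gmt, "mutations": config.mutations,
    })
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage(manifest, "read"):
        expr_raw = read_expression_tsv(config.expression)
        clinical = read_clinical_tsv(config.clinical, endpoints=config.endpoints)
        sets = read_gmt(config.gene_sets_gmt)
        glucose = sets[config.glucose_set]
        lipid = sets[config.lipid_set]
        candidates = [g for g in sets.union() if g in expr_raw.index]
        if not candidates:
            raise ValidationError("no gene-set gene present in the expression matrix")
        mutations = read_maf_lite(config.mutations) if config.mutations else None

    with _Stage(manifest, "transform"):
        expr = (np.log2(expr_raw + 1.0) if config.expression_transform == "log2p1"
                else expr_raw)
        samples = [s for s in expr.columns if s in clinical.index]
        expr = expr[samples]

    surv: dict[str, SurvivalData] = {}
    with _Stage(manifest, "survival_data"):
        for ep in config.endpoints:
            sub = clinical.loc[samples, [f"{ep}_time", f"{ep}_event"]].dropna()
            surv[ep] = SurvivalData(sub[f"{ep}_time"], sub[f"{ep}_event"], endpoint=ep)
            log.info("endpoint %s: %d samples, %d events", ep, len(surv[ep]),
                     surv[ep].n_events)

    screens = {}
    with _Stage(manifest, "univariable"):
        for ep in config.endpoints:
            sub_expr = expr.loc[candidates, surv[ep].time.index]
            screens[ep] = univariable_screen(sub_expr, surv[ep],
                                             alpha=config.cox_alpha, ties=config.ties)
            log.info("univariable %s: %d tested, %d retained at p<%g", ep,
                     len(screens[ep].table), len(screens[ep].retained), config.cox_alpha)

    with _Stage(manifest, "intersect"):
        eps = list(config.endpoints)
        biomarkers = screens[eps[0]].retained
        for ep in eps[1:]:
            biomarkers = intersect_candidates(biomarkers, screens[ep].retained)
        log.info("biomarker set: %d genes (%s)", len(biomarkers), ", ".join(biomarkers))
        if not biomarkers:
            raise ValidationError("no gene passed the univariable screen on all endpoints")

    with _Stage(manifest, "collinearity"):
        kept, exclusions = collinearity_filter(expr, biomarkers,
                                               r_cutoff=config.collinearity_r)
        for ex in exclusions:
            log.info("collinearity: excluded %s (r=%.3f with %s)",
                     ex["gene"], ex["r"], ex["partner"])

    multi, risk, km, logrank = {}, {}, {}, {}
    with _Stage(manifest, "multivariable"):
        for ep in config.endpoints:
            X = expr.loc[kept, surv[ep].time.index].T
            multi[ep] = cox_fit(X, surv[ep], ties=config.ties)

    with _Stage(manifest, "prognostic_index"):
        for ep in config.endpoints:
            pi = prognostic_index(multi[ep], expr.loc[kept, surv[ep].time.index])
            risk[ep] = median_split(pi)
            km[ep] = km_estimate(surv[ep], risk[ep].labels)
            logrank[ep] = logrank_test(surv[ep], risk[ep].labels)
            log.info("PI %s: median %.4f, log-rank chi2=%.2f p=%.3g", ep,
                     risk[ep].threshold, *logrank[ep])

    with _Stage(manifest, "ttests"):
        ttest_ep = eps[-1]  # expression differences shown for the last endpoint (OS)
        ttests = {}
        for g in biomarkers:
            vals = expr.loc[g, surv[ttest_ep].time.index]
            ttests[g] = ttest_by_group(vals, risk[ttest_ep].labels, welch=config.welch)

    with _Stage(manifest, "balance_score"):
        z = gene_zscores(expr)
        scores = metabolic_balance_score(z, glucose, lipid)
        mbs_groups = stratify_by_cutoff(scores.mbs, cutoff=config.mbs_cutoff)
        mbs_results = {}
        for ep in config.endpoints:
            labels = mbs_groups.reindex(surv[ep].time.index)
            indicator = (labels == "high").astype(float).to_frame("mbs_high")
            fit = cox_fit(indicator, surv[ep], ties=config.ties)
            mbs_results[ep] = {
                "fit": fit,
                "hr": float(fit.hr["mbs_high"]),
                "logrank": logrank_test(surv[ep], labels),
                "km": km_estimate(surv[ep], labels),
            }

    chisq = {}
    if mutations is not None:
        with _Stage(manifest, "mutations"):
            for gene in ("TP53", "CTNNB1"):
                flags = mutations.flags_for(gene, list(mbs_groups.index))
                high = mbs_groups == "high"
                table = [[int(((flags == 1) & high).sum()), int(((flags == 1) & ~high).sum())],
                         [int(((flags == 0) & high).sum()), int(((flags == 0) & ~high).sum())]]
                chisq[gene] = {"table": table,
                               "test": chisq_2x2(table, yates=config.yates)}
    else:
        manifest.notes.append("mutation chi-square skipped: no mutation table provided")

    with _Stage(manifest, "write"):
        out = {}
        for ep in config.endpoints:
            tab = screens[ep].table.rename(columns={c: f"uni_{c}" for c in
                                                    ("coef", "se", "hr", "ci_lower",
                                                     "ci_upper", "p")})
            msum = multi[ep].summary().add_prefix("multi_")
            tab = tab.merge(msum, left_on="gene", right_index=True, how="left")
            excluded = {ex["gene"]: ex["partner"] for ex in exclusions}
            tab["excluded_collinear_with"] = tab["gene"].map(excluded).fillna("")
            out[f"cox_{ep}"] = outdir / f"cox_{ep}.tsv"
            _write_tsv(tab, out[f"cox_{ep}"], config.seed)
            out[f"km_{ep}"] = outdir / f"km_{ep}.tsv"
            _write_tsv(_km_table(km[ep]), out[f"km_{ep}"], config.seed)
            out[f"km_mbs_{ep}"] = outdir / f"km_mbs_{ep}.tsv"
            _write_tsv(_km_table(mbs_results[ep]["km"]), out[f"km_mbs_{ep}"], config.seed)
        out["risk_groups"] = outdir / "risk_groups.tsv"
        rg = pd.DataFrame({f"pi_{ep}": risk[ep].labels for ep in config.endpoints})
        rg["mbs_group"] = mbs_groups
        _write_tsv(rg, out["risk_groups"], config.seed, index_label="sample")
        out["scores"] = outdir / "scores.tsv"
        _write_tsv(scores.frame, out["scores"], config.seed, index_label="sample")
        summary = {
            "biomarkers": biomarkers,
            "kept_after_collinearity": kept,
            "exclusions": exclusions,
            "logrank_pi": {ep: logrank[ep] for ep in config.endpoints},
            "mbs": {ep: {"hr": mbs_results[ep]["hr"],
                         "logrank": mbs_results[ep]["logrank"]}
                    for ep in config.endpoints},
            "ttests": ttests,
            "mutation_chisq": {g: {"table": v["table"], "test": v["test"]}
                               for g, v in chisq.items()},
        }
        out["summary"] = outdir / "validation_summary.json"
        out["summary"].write_text(json.dumps(summary, indent=2, default=str) + "\n")
        for name, p in out.items():
            manifest.outputs[str(p)] = _sha256(p)

    manifest.write(outdir / "manifest.json")
    return {"screens": screens, "biomarkers": biomarkers, "kept": kept,
            "exclusions": exclusions, "multivariable": multi, "risk": risk,
            "km": km, "logrank": logrank, "ttests": ttests, "scores": scores,
            "mbs_groups": mbs_groups, "mbs_results": mbs_results,
            "mutation_chisq": chisq, "manifest": manifest}
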