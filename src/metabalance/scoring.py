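"""Imaging statistic (tumor-to-liver ratio), gene-set signature scores, the
glucose-minus-lipid balance score, and cutoff-based group assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import GeneSet
from .normalize import ZScoreMatrix

__all__ = [
    "TlrValue",
    "SignatureScores",
    "compute_tlr",
    "tlr_phenotype",
    "gess",
    "metabolic_balance_score",
    "stratify_by_cutoff",
]


@dataclass(frozen=True)
class TlrValue:
    tlr: float
    suv_max: float | None = None
    suv_mean: float | None = None


@dataclass
class SignatureScores:
    """Per-sample glucose/lipid signature scores and their difference."""

    frame: pd.DataFrame  # columns: gess_glucose, gess_lipid, mbs
    genes_used: dict[str, list[str]] = field(default_factory=dict)
    genes_missing: dict[str, list[str]] = field(default_factory=dict)

    @property
    def mbs(self) -> pd.Series:
        return self.frame["mbs"]


def compute_tlr(suv_max: float, suv_mean: float) -> TlrValue:
    """Tumor SUVmax divided by normal-liver SUVmean."""
    if suv_max <= 0 or suv_mean <= 0:
        raise ValidationError(f"SUV values must be positive, got ({suv_max}, {suv_mean})")
    return TlrValue(tlr=suv_max / suv_mean, suv_max=suv_max, suv_mean=suv_mean)


def tlr_phenotype(tlrs: pd.Series) -> tuple[pd.Series, float]:
    """Label each patient high/low uptake against the cohort median (high iff >=)."""
    if len(tlrs) < 2:
        raise ValidationError("phenotype split needs at least 2 patients")
    med = float(np.median(tlrs.to_numpy(dtype=float)))
    labels = pd.Series(np.where(tlrs.to_numpy(dtype=float) >= med, "high", "low"),
                       index=tlrs.index, name="tlr_phenotype")
    return labels, med


def _zframe(z) -> pd.DataFrame:
    return z.values if isinstance(z, ZScoreMatrix) else z


def gess(z, gene_set: GeneSet) -> tuple[pd.Series, list[str], list[str]]:
    """Per-sample mean z-score over the genes of ``gene_set`` present in ``z``.

    Returns (scores, genes_used, genes_missing); missing genes are skipped.
    """
    zf = _zframe(z)
    used = [g for g in gene_set if g in zf.index]
    missing = [g for g in gene_set if g not in zf.index]
    if not used:
        raise ValidationError(f"no gene of set {gene_set.name!r} is present in the matrix")
    scores = zf.loc[used].mean(axis=0)
    scores.name = f"gess_{gene_set.name}"
    return scores, used, missing


def metabolic_balance_score(z, glucose: GeneSet, lipid: GeneSet) -> SignatureScores:
    """GESS(glucose) - GESS(lipid) per sample."""
    g_scores, g_used, g_missing = gess(z, glucose)
    l_scores, l_used, l_missing = gess(z, lipid)
    frame = pd.DataFrame({
        "gess_glucose": g_scores,
        "gess_lipid": l_scores,
    })
    frame["mbs"] = frame["gess_glucose"] - frame["gess_lipid"]
    return SignatureScores(
        frame=frame,
        genes_used={glucose.name: g_used, lipid.name: l_used},
        genes_missing={glucose.name: g_missing, lipid.name: l_missing},
    )


def stratify_by_cutoff(scores: pd.Series, cutoff: float = 0.0) -> pd.Series:
    """Binary risk labels: high iff score >= cutoff (ties go high)."""
    if len(scores) < 1:
        raise ValidationError("need at least 1 sample to stratify")
    return pd.Series(np.where(scores.to_numpy(dtype=float) >= cutoff, "high", "low"),
                     index=scores.index, name="risk_group")
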