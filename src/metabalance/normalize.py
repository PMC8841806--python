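"""Count normalization: TMM scaling factors, CPM, paired log2 fold changes,
and per-gene z-scores.

The TMM factor for a sample is the precision-weighted mean of doubly trimmed
gene-wise log ratios (M values) against a reference sample, the reference
being the sample whose upper-quartile CPM is closest to the cohort mean
upper quartile. Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError
from .io_formats import CountsTable

__all__ = [
    "NormFactors",
    "ZScoreMatrix",
    "tmm_factors",
    "cpm",
    "paired_log2_fc",
    "gene_zscores",
]


@dataclass
class NormFactors:
    factors: pd.Series  # per-sample scaling factor, geometric mean 1
    reference: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors.to_numpy())))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"TMM factors have geometric mean {gm}, expected 1")


@dataclass
class ZScoreMatrix:
    """Row-standardized matrix; zero-variance genes are dropped, not kept."""

    values: pd.DataFrame
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (gene, reason)


def _pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                 trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (untrimmed scale)."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return np.nan
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    po = o / lib_obs
    pr = r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method weights: inverse binomial variances of M
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return f if np.isfinite(f) and f > 0 else 1.0


def tmm_factors(counts: CountsTable | pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample.

    Parameters
    ----------
    counts
        Gene x sample integer count matrix (or :class:`CountsTable`).
    trim_m, trim_a
        Per-tail trim fractions applied to the M (log ratio) and A (average
        log abundance) statistics.
    """
    df = counts.values if isinstance(counts, CountsTable) else counts
    if df.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = df.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[(lib == 0).to_numpy()][0]
        raise ValidationError(f"sample {bad!r} has no nonzero counts")
    cpm_raw = df.to_numpy(dtype=float) / lib.to_numpy() * 1e6
    uq = np.quantile(cpm_raw, 0.75, axis=0)
    dist = np.abs(uq - uq.mean())
    # deterministic tie break: lexicographically first sample id
    best = dist.min()
    tied = [s for s, d in zip(df.columns, dist) if d <= best + 1e-15]
    ref = sorted(tied)[0]
    ref_col = df[ref].to_numpy()
    lib_ref = float(lib[ref])
    raw: dict[str, float] = {}
    for s in df.columns:
        if s == ref:
            raw[s] = 1.0
            continue
        f = _pair_factor(df[s].to_numpy(), ref_col, float(lib[s]), lib_ref,
                         trim_m, trim_a)
        if np.isnan(f):
            raise ValidationError(
                f"sample {s!r} shares no co-nonzero genes with reference {ref!r}"
            )
        raw[s] = f
    fac = pd.Series(raw, dtype=float).reindex(df.columns)
    fac /= np.exp(np.mean(np.log(fac.to_numpy())))
    return NormFactors(factors=fac, reference=ref)


def cpm(counts: CountsTable | pd.DataFrame, factors: NormFactors) -> pd.DataFrame:
    """Counts per million on TMM-adjusted library sizes."""
    df = counts.values if isinstance(counts, CountsTable) else counts
    missing = set(df.columns) - set(factors.factors.index)
    if missing:
        raise ValidationError(f"factors missing for samples: {sorted(missing)}")
    lib = df.sum(axis=0).astype(float)
    eff = lib * factors.factors.reindex(df.columns)
    return df / eff * 1e6


def paired_log2_fc(tumor_cpm: pd.DataFrame, normal_cpm: pd.DataFrame,
                   pairing: dict[str, str], pseudocount: float = 0.5) -> pd.DataFrame:
    """log2((tumor + pc) / (normal + pc)) per gene, one column per tumor sample."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    cols = {}
    for tum, norm in pairing.items():
        if tum not in tumor_cpm.columns:
            raise ValidationError(f"tumor sample {tum!r} not in tumor matrix")
        if norm not in normal_cpm.columns:
            raise ValidationError(f"normal sample {norm!r} not in normal matrix")
        cols[tum] = np.log2((tumor_cpm[tum] + pseudocount)
                            / (normal_cpm[norm] + pseudocount))
    return pd.DataFrame(cols)


def gene_zscores(matrix: pd.DataFrame) -> ZScoreMatrix:
    """Standardize each gene row to mean 0 / sample SD 1 (ddof=1).

    Zero-variance genes are dropped and listed in ``rejected``.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("z-scoring needs at least 3 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    rejected = [(g, "zero variance") for g in matrix.index[~keep]]
    z = matrix.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ZScoreMatrix(values=z, rejected=rejected)
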