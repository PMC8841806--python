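"""Uptake-correlation gene screening and hypergeometric over-representation.

Each candidate gene's expression change is correlated (Pearson) with the
per-patient uptake variable; genes significant at ``alpha`` are split by
correlation sign into an up- and a down-regulated program. Over-representation
of a query gene list in a GMT collection uses the upper-tail hypergeometric
test with Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io_formats import GeneSet, GeneSetCollection

__all__ = [
    "ScreenResult",
    "pearson_with_p",
    "screen_genes",
    "ora_hypergeometric",
    "sets_from_screen",
]


@dataclass
class ScreenResult:
    records: pd.DataFrame          # gene, r, p, n (all tested genes)
    positive: list[str]            # r > 0, p < alpha
    negative: list[str]            # r < 0, p < alpha
    missing: list[str] = field(default_factory=list)   # candidates absent from matrix
    skipped: list[str] = field(default_factory=list)   # constant genes
    alpha: float = 0.05


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def screen_genes(fc: pd.DataFrame, log2_tlr: pd.Series, candidates: GeneSet,
                 alpha: float = 0.05, adjust: bool = False) -> ScreenResult:
    """Correlate candidate genes against uptake and sign-split the hits.

    Parameters
    ----------
    fc
        Gene x patient matrix (fold changes or expression).
    log2_tlr
        Per-patient uptake values aligned to ``fc`` columns.
    candidates
        Genes to test; members absent from ``fc`` go to the miss log.
    alpha
        Two-sided significance threshold on the (optionally BH-adjusted) p.
    """
    uptake = log2_tlr.reindex(fc.columns)
    if uptake.isna().any():
        bad = uptake.index[uptake.isna()][0]
        raise ValidationError(f"no uptake value for patient {bad!r}")
    present = [g for g in candidates if g in fc.index]
    missing = [g for g in candidates if g not in fc.index]
    if not present:
        raise ValidationError("no candidate gene is present in the matrix")
    y = uptake.to_numpy()
    rows, skipped = [], []
    for g in present:
        x = fc.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped.append(g)
            continue
        r, p = pearson_with_p(x, y)
        rows.append((g, r, p, x.size))
    records = pd.DataFrame(rows, columns=["gene", "r", "p", "n"])
    pvals = records["p"].to_numpy()
    if adjust and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    records["p_used"] = pvals
    sig = records["p_used"] < alpha
    positive = records.loc[sig & (records["r"] > 0), "gene"].tolist()
    negative = records.loc[sig & (records["r"] < 0), "gene"].tolist()
    return ScreenResult(records=records.drop(columns="p_used").assign(p_adj=pvals) if adjust
                        else records.drop(columns="p_used"),
                        positive=positive, negative=negative,
                        missing=missing, skipped=skipped, alpha=alpha)


def sets_from_screen(result: ScreenResult,
                     positive_name: str = "GLUCOSE_PROGRAM",
                     negative_name: str = "LIPID_PROGRAM") -> GeneSetCollection:
    """Package the sign-split screen hits as a two-set GMT-ready collection."""
    coll = GeneSetCollection()
    if result.positive:
        coll.add(GeneSet(positive_name, "positively uptake-correlated genes",
                         tuple(result.positive)))
    if result.negative:
        coll.add(GeneSet(negative_name, "negatively uptake-correlated genes",
                         tuple(result.negative)))
    return coll


def ora_hypergeometric(query: GeneSet, collection: GeneSetCollection,
                       universe: GeneSet) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Population = universe, successes = |set ∩ universe|, draws = |query|;
    p = P(X >= overlap). BH-adjusted q across the collection.
    """
    uni = set(universe.genes)
    if not uni:
        raise ValidationError("empty universe")
    q = [g for g in query if g in uni]
    rows = []
    for gs in collection:
        members = [g for g in gs.genes if g in uni]
        k = len(set(members) & set(q))
        if len(q) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        rows.append((gs.name, k, len(members), len(q), len(uni), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                      "universe_size", "p"])
    if len(out):
        out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    else:
        out["q"] = []
    return out.sort_values("p", kind="stable").reset_index(drop=True)
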