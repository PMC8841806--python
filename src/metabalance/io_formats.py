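"""Readers/writers for the tabular and gene-set formats the pipeline consumes.

Counts and expression matrices are gene x sample TSV files (first column =
gene identifier, header row = sample identifiers). Gene sets use the GMT
dialect (name TAB description TAB gene ...). Clinical and mutation tables are
plain TSV; mutation input additionally accepts standard MAF headers
(``Hugo_Symbol``, ``Tumor_Sample_Barcode``). Identifier matching everywhere is
exact and case-sensitive after whitespace stripping.

Output tables carry a ``#`` comment line recording the package version and
seed; all readers skip ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

__all__ = [
    "CountsTable",
    "GeneSet",
    "GeneSetCollection",
    "MutationTable",
    "AnalysisConfig",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_expression_tsv",
    "read_pairing_tsv",
    "write_pairing_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_maf_lite",
    "write_maf_lite",
    "comment_header",
]

_NA_VALUES = ["", "NA"]


def comment_header(seed: int | None = None) -> str:
    """Comment line stamped onto every output table."""
    from . import __version__

    tail = "" if seed is None else f" seed={seed}"
    return f"# metabalance v{__version__}{tail}\n"


# ---------------------------------------------------------------------------
# CountsTable
# ---------------------------------------------------------------------------


@dataclass
class CountsTable:
    """Gene x sample matrix of non-negative integer read counts.

    ``pairing`` optionally maps each tumor sample id to its matched normal
    sample id; both sides must be present among the columns.
    """

    values: pd.DataFrame
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            bad = ~np.isfinite(arr) | (arr != np.floor(arr))
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
            self.values = self.values.astype(np.int64)
            arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.pairing is not None:
            known = set(cols)
            seen_normals: dict[str, str] = {}
            for tum, norm in self.pairing.items():
                if tum not in known:
                    raise ValidationError(f"paired tumor sample {tum!r} not in counts")
                if norm not in known:
                    raise ValidationError(f"paired normal sample {norm!r} not in counts")
                if norm in seen_normals:
                    raise ValidationError(
                        f"normal sample {norm!r} paired with both "
                        f"{seen_normals[norm]!r} and {tum!r}"
                    )
                seen_normals[norm] = tum


def read_counts_tsv(path: str | Path, pairing_path: str | Path | None = None) -> CountsTable:
    """Read a gene x sample integer count matrix, preserving file order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse counts file {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[bad.isna().to_numpy().argmax()]
            raise FormatError(
                f"non-numeric count at gene {row!r}, sample {col!r} in {path}"
            )
    pairing = read_pairing_tsv(pairing_path) if pairing_path is not None else None
    return CountsTable(values=df, pairing=pairing)


def write_counts_tsv(table: CountsTable | pd.DataFrame, path: str | Path,
                     seed: int | None = None) -> None:
    df = table.values if isinstance(table, CountsTable) else table
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(comment_header(seed))
        df.to_csv(fh, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample matrix of non-negative expression values (floats OK)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier: {dup!r}")
    arr = df.to_numpy(dtype=float)
    if arr.size and ((arr < 0) | ~np.isfinite(arr)).any():
        g, s = np.argwhere((arr < 0) | ~np.isfinite(arr))[0]
        raise FormatError(
            f"negative or non-finite expression at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    return df.astype(float)


def read_pairing_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (tumor, normal) linking tumor samples to matched normals."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["tumor", "normal"]:
        raise FormatError(
            f"pairing file {path} must have columns 'tumor' and 'normal', got {cols}"
        )
    pairing: dict[str, str] = {}
    for i, (tum, norm) in enumerate(zip(df["tumor"], df["normal"]), start=2):
        tum, norm = str(tum).strip(), str(norm).strip()
        if tum in pairing:
            raise FormatError(f"tumor sample {tum!r} paired twice (line {i})")
        pairing[tum] = norm
    return pairing


def write_pairing_tsv(pairing: Mapping[str, str], path: str | Path,
                      seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(comment_header(seed))
        fh.write("tumor\tnormal\n")
        for tum, norm in pairing.items():
            fh.write(f"{tum}\t{norm}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        stripped = tuple(g.strip() for g in self.genes)
        object.__setattr__(self, "genes", stripped)
        if len(set(stripped)) != len(stripped):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene set name: {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> GeneSet:
        """All member genes as one set, first occurrence order."""
        seen: dict[str, None] = {}
        for gs in self:
            for g in gs.genes:
                seen.setdefault(g)
        return GeneSet("union", "union of all sets", tuple(seen))


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} in {path} has {len(fields)} fields (need >= 3)"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            genes = tuple(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"GMT line {lineno} in {path}: set {name!r} is empty")
            try:
                coll.add(GeneSet(name, desc, genes))
            except ValidationError as exc:
                raise FormatError(f"GMT line {lineno} in {path}: {exc}") from exc
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


@dataclass
class MutationTable:
    """Distinct (sample, gene) pairs observed mutated at least once."""

    pairs: pd.DataFrame  # columns: sample, gene

    def __post_init__(self) -> None:
        need = {"sample", "gene"}
        if not need.issubset(self.pairs.columns):
            raise ValidationError("MutationTable needs columns 'sample' and 'gene'")
        self.pairs = (
            self.pairs[["sample", "gene"]]
            .astype(str)
            .apply(lambda c: c.str.strip())
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.pairs.to_numpy()))

    def flags_for(self, gene: str, samples: Sequence[str]) -> pd.Series:
        """0/1 mutation indicator for one gene across ``samples``."""
        mutated = set(self.pairs.loc[self.pairs["gene"] == gene, "sample"])
        return pd.Series([1 if s in mutated else 0 for s in samples],
                         index=list(samples), name=gene)


def read_maf_lite(path: str | Path) -> MutationTable:
    """Read a MAF-style TSV; any listed variant flags its (sample, gene) pair."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise FormatError(f"MAF file {path} is missing required column {col!r}")
    pairs = df.rename(
        columns={"Tumor_Sample_Barcode": "sample", "Hugo_Symbol": "gene"}
    )[["sample", "gene"]]
    return MutationTable(pairs=pairs)


def write_maf_lite(table: MutationTable, path: str | Path,
                   seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(comment_header(seed))
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\n")
        for _, row in table.pairs.iterrows():
            fh.write(f"{row['gene']}\t{row['sample']}\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def read_clinical_tsv(path: str | Path,
                      endpoints: Sequence[str] = ("dfs", "os")) -> pd.DataFrame:
    """Per-sample clinical TSV indexed by the first column.

    Recognized columns: ``tlr``, ``suv_max``, ``suv_mean_liver`` and, per
    endpoint ``e``, ``{e}_time`` / ``{e}_event``. Empty strings and "NA" are
    missing. Each row must carry ``tlr`` or both SUV components or survival
    columns for at least one requested endpoint.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     na_values=_NA_VALUES, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate sample identifier in clinical table: {dup!r}")
    for col in ("tlr", "suv_max", "suv_mean_liver"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if ((vals <= 0) & df[col].notna()).any():
                bad = df.index[(vals <= 0).fillna(False)][0]
                raise FormatError(f"non-positive {col} for sample {bad!r}")
            df[col] = vals
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol in df.columns:
            df[tcol] = pd.to_numeric(df[tcol], errors="coerce")
            if ((df[tcol] <= 0) & df[tcol].notna()).any():
                bad = df.index[(df[tcol] <= 0).fillna(False)][0]
                raise FormatError(f"non-positive {tcol} for sample {bad!r}")
        if ecol in df.columns:
            ev = pd.to_numeric(df[ecol], errors="coerce")
            ok = ev.isin([0, 1]) | ev.isna()
            if not ok.all():
                bad = df.index[~ok][0]
                raise FormatError(f"{ecol} for sample {bad!r} is not 0/1")
            df[ecol] = ev
    has_tlr = "tlr" in df.columns
    has_suv = {"suv_max", "suv_mean_liver"}.issubset(df.columns)
    if (has_tlr or has_suv) and not has_tlr and has_suv:
        df["tlr"] = df["suv_max"] / df["suv_mean_liver"]
    return df


def write_clinical_tsv(df: pd.DataFrame, path: str | Path,
                       seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(comment_header(seed))
        df.to_csv(fh, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds, conventions and input paths for a pipeline run."""

    # thresholds / conventions
    screen_alpha: float = 0.05
    cox_alpha: float = 0.1
    collinearity_r: float = 0.8
    mbs_cutoff: float = 0.0
    pseudocount: float = 0.5
    seed: int = 0
    use_log2_tlr: bool = True
    correlate_on: str = "fold_change"  # or "tumor"
    adjust_screen_p: bool = False
    ties: str = "efron"
    welch: bool = True
    yates: bool = True
    expression_transform: str = "log2p1"  # or "raw"
    endpoints: tuple[str, ...] = ("dfs", "os")
    # input paths (discovery)
    counts: str | None = None
    pairing: str | None = None
    clinical: str | None = None
    candidates_gmt: str | None = None
    ora_gmt: str | None = None
    # input paths (validation)
    expression: str | None = None
    gene_sets_gmt: str | None = None
    glucose_set: str = "GLUCOSE_PROGRAM"
    lipid_set: str = "LIPID_PROGRAM"
    mutations: str | None = None
    # output
    outdir: str = "metabalance_out"

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "cox_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {a}")
        if self.pseudocount <= 0:
            raise ValidationError(f"pseudocount must be > 0, got {self.pseudocount}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError(f"seed must be a non-negative integer, got {self.seed}")
        if self.correlate_on not in ("fold_change", "tumor"):
            raise ValidationError(f"correlate_on must be fold_change|tumor")
        if self.ties not in ("efron", "breslow"):
            raise ValidationError("ties must be efron|breslow")
        if self.expression_transform not in ("log2p1", "raw"):
            raise ValidationError("expression_transform must be log2p1|raw")
        self.endpoints = tuple(self.endpoints)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["endpoints"] = list(d["endpoints"])
        return d
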