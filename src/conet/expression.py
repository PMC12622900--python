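"""Spot-level ingestion, duplicate-spot averaging, normalisation and
control-relative fold changes.

The raw observation is a per-spot fluorescence intensity on a two-line
per-genotype oligoarray design: each gene is printed as several duplicate
spots per array, each array (sample) belongs to a genotype line (``VC``
vector control, ``PhaC``, ``PhaBC``), and the two non-control genotypes
form the treatment group. Gene-level expression is the arithmetic mean of
the passing duplicate spots; the fold change of a gene is the mean, over
treatment arrays, of its expression divided by its mean control expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

log = logging.getLogger(__name__)

SPOT_COLUMNS = ("probe_id", "gene_id", "sample_id", "intensity", "flag")
DESIGN_COLUMNS = ("sample_id", "line", "replicate", "group")
LINES = ("VC", "PhaC", "PhaBC")

_TRUTHY = {"1", "true", "t", "pass", "p", "yes", "y"}
_FALSY = {"0", "false", "f", "fail", "absent", "no", "n"}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"unrecognised pass/fail flag value: {value!r}")


def read_spot_table(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a long-format spot intensity table.

    The table is a TSV with header ``probe_id gene_id sample_id intensity
    flag``; an empty ``gene_id`` field marks an unmapped probe. The pair
    (probe_id, sample_id) must be unique.
    """
    if fmt != "tsv":
        raise FormatError(f"unknown spot-table dialect: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spot table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"probe_id": str, "gene_id": str,
                            "sample_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spot table {path} missing required columns: "
                          + ", ".join(missing))
    if df.empty:
        raise FormatError(f"spot table {path} contains no records")
    dup = df.duplicated(subset=["probe_id", "sample_id"], keep=False)
    if dup.any():
        pairs = (df.loc[dup, ["probe_id", "sample_id"]]
                 .drop_duplicates().itertuples(index=False))
        listing = "; ".join(f"{p},{s}" for p, s in pairs)
        raise FormatError(f"duplicate (probe_id, sample_id) pairs: {listing}")
    out = df.loc[:, list(SPOT_COLUMNS)].copy()
    out["gene_id"] = out["gene_id"].where(out["gene_id"].notna() &
                                          (out["gene_id"] != ""), other=pd.NA)
    out["intensity"] = out["intensity"].astype(float)
    if (out["intensity"] < 0).any():
        bad = out.loc[out["intensity"] < 0, "probe_id"].head(5).tolist()
        raise FormatError(f"negative intensities (first probes: {bad})")
    out["flag"] = out["flag"].map(_parse_flag)
    return out


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    out = spots.copy()
    out["flag"] = out["flag"].map(lambda b: "1" if b else "0")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def validate_design(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError("sample design missing required columns: "
                          + ", ".join(missing))
    meta = meta.loc[:, list(DESIGN_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design")
    bad_line = set(meta["line"]) - set(LINES)
    if bad_line:
        raise FormatError(f"unknown genotype line(s): {sorted(bad_line)}")
    if not set(meta["group"]) <= {"control", "treatment"}:
        raise FormatError("group must be 'control' or 'treatment'")
    vc_mismatch = (meta["line"] == "VC") != (meta["group"] == "control")
    if vc_mismatch.any():
        raise ConfigError("design violates line VC <=> group control")
    if not (meta["group"] == "control").any():
        raise ConfigError("design has no control sample")
    if not (meta["group"] == "treatment").any():
        raise ConfigError("design has no treatment sample")
    return meta


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design TSV: ``sample_id line replicate group``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line": str,
                                            "group": str})
    return validate_design(df)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression levels plus the sample design.

    ``data`` is a DataFrame indexed by gene_id with one column per
    sample_id; ``meta`` rows are aligned with the column order.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = validate_design(self.meta.reset_index(drop=True))
        if list(self.data.columns) != list(self.meta["sample_id"]):
            raise ConfigError("matrix columns do not match design sample order")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate gene rows in expression matrix")
        if not np.isfinite(self.data.to_numpy()).all():
            raise FormatError("non-finite values in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def control_samples(self) -> list[str]:
        return list(self.meta.loc[self.meta["group"] == "control", "sample_id"])

    def treatment_samples(self, lines: Sequence[str] | None = None) -> list[str]:
        sel = self.meta["group"] == "treatment"
        if lines is not None:
            sel &= self.meta["line"].isin(list(lines))
        return list(self.meta.loc[sel, "sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 design_path: str | Path) -> "ExpressionMatrix":
        data = pd.read_csv(matrix_path, sep="\t", index_col="gene_id",
                           float_precision="round_trip")
        meta = read_design(design_path)
        data = data.loc[:, list(meta["sample_id"])]
        return cls(data=data, meta=meta)


def average_spots(spots: pd.DataFrame, meta: pd.DataFrame) -> ExpressionMatrix:
    """Average duplicate spot intensities per gene and sample.

    Failed spots (``flag`` false) and unmapped probes are excluded first.
    A gene lacking a passing spot in any design sample is dropped entirely
    (the count is logged).
    """
    meta = validate_design(meta)
    ok = spots.loc[spots["flag"] & spots["gene_id"].notna()]
    ok = ok.loc[ok["sample_id"].isin(set(meta["sample_id"]))]
    if ok.empty:
        raise FormatError("no passing, gene-mapped spots in any design sample")
    # explicit sum/count: bincount accumulates sequentially in table
    # order, so each cell is bit-for-bit the running sum of its spot
    # intensities divided by their count
    grouper = ok.groupby(["gene_id", "sample_id"], sort=True)
    codes = grouper.ngroup().to_numpy()
    sums = np.bincount(codes, weights=ok["intensity"].to_numpy())
    counts = np.bincount(codes)
    keys = pd.MultiIndex.from_tuples(list(grouper.groups),
                                     names=["gene_id", "sample_id"])
    cells = pd.Series(sums / counts, index=keys).unstack("sample_id")
    cells = cells.reindex(columns=list(meta["sample_id"]))
    complete = cells.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("average_spots: dropped %d gene(s) lacking a passing spot "
                 "in at least one sample", n_dropped)
    cells = cells.loc[complete].sort_index()
    cells.columns.name = None
    cells.index.name = "gene_id"
    return ExpressionMatrix(data=cells, meta=meta)


def normalize(matrix: ExpressionMatrix,
              method: str = "median-scale") -> ExpressionMatrix:
    """Normalise arrays. ``median-scale`` rescales every sample column so
    that its median equals the global median of the matrix; ``none`` is the
    identity."""
    if method == "none":
        return ExpressionMatrix(data=matrix.data.copy(), meta=matrix.meta.copy())
    if method != "median-scale":
        raise ConfigError(f"unknown normalization method: {method!r}")
    values = matrix.data.to_numpy()
    if (values <= 0).any():
        bad = matrix.data.index[(matrix.data <= 0).any(axis=1)]
        raise ConfigError("median-scale requires strictly positive values; "
                          f"offending genes: {list(bad[:10])}")
    global_median = float(np.median(values))
    col_medians = np.median(values, axis=0)
    scaled = values * (global_median / col_medians)
    data = pd.DataFrame(scaled, index=matrix.data.index,
                        columns=matrix.data.columns)
    return ExpressionMatrix(data=data, meta=matrix.meta.copy())


@dataclass
class FoldChangeTable:
    """Per-gene control-relative expression ratios and their mean.

    ``ratios`` holds one column per treatment sample (gene value divided by
    that gene's mean control expression); ``fold_change`` is the arithmetic
    mean of the per-sample ratios. Genes whose control mean is not positive
    are dropped before ratio computation and listed in ``dropped``.
    """

    ratios: pd.DataFrame
    fold_change: pd.Series
    dropped: tuple = field(default_factory=tuple)

    @property
    def n_treatment(self) -> int:
        return self.ratios.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.fold_change.index)

    @property
    def frame(self) -> pd.DataFrame:
        out = self.ratios.copy()
        out.columns = [f"ratio_{s}" for s in self.ratios.columns]
        out["fold_change"] = self.fold_change
        out["n_treatment"] = self.n_treatment
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FoldChangeTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     float_precision="round_trip")
        ratio_cols = [c for c in df.columns if c.startswith("ratio_")]
        ratios = df[ratio_cols].copy()
        ratios.columns = [c[len("ratio_"):] for c in ratio_cols]
        return cls(ratios=ratios, fold_change=df["fold_change"].copy())


def fold_change(matrix: ExpressionMatrix,
                treatment_lines: Sequence[str] | None = None) -> FoldChangeTable:
    """Compute control-relative fold changes.

    ratio(g, s) = value(g, s) / mean over control samples of value(g, .)
    for every treatment sample s; fold_change(g) is the arithmetic mean of
    the per-sample ratios. ``treatment_lines`` restricts the treatment
    group to specific genotype lines (default: all treatment samples, i.e.
    the PhaC and PhaBC arrays pooled as one dataset).
    """
    controls = matrix.control_samples()
    treatments = matrix.treatment_samples(treatment_lines)
    if not controls:
        raise ConfigError("no control samples in design")
    if not treatments:
        raise ConfigError("no treatment samples in design"
                          + (f" for lines {list(treatment_lines)}"
                             if treatment_lines else ""))
    control_mean = matrix.data[controls].mean(axis=1)
    keep = control_mean > 0
    dropped = tuple(matrix.data.index[~keep])
    if dropped:
        log.info("fold_change: dropped %d gene(s) with non-positive control "
                 "mean", len(dropped))
    ratios = matrix.data.loc[keep, treatments].div(control_mean[keep], axis=0)
    fc = ratios.mean(axis=1)
    fc.name = "fold_change"
    return FoldChangeTable(ratios=ratios, fold_change=fc, dropped=dropped)
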