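"""Regeneration-efficiency arithmetic for the transformation experiment.

Each record counts calli treated with one transgene construct, the plants
that regenerated and grew to the vegetative stage, and the total
regenerated including plants that died immediately. Efficiencies are
percentages rounded to three significant figures, the precision of the
published counts. Recomputed efficiencies are compared against any
printed-efficiency columns and disagreements are reported, never silently
corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigError, FormatError


@dataclass(frozen=True)
class RegenerationRecord:
    transgene: str
    n_calli: int
    n_regenerated: int
    n_regenerated_total: int

    def __post_init__(self) -> None:
        for name in ("n_calli", "n_regenerated", "n_regenerated_total"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (self.n_regenerated <= self.n_regenerated_total
                <= self.n_calli):
            raise ConfigError(
                f"{self.transgene}: counts must satisfy regenerated <= "
                f"regenerated_total <= calli "
                f"({self.n_regenerated}, {self.n_regenerated_total}, "
                f"{self.n_calli})")


def round_sig(x: float, figures: int = 3) -> float:
    """Round to a number of significant figures (half-even at binary
    representation boundaries, as ordinary float rounding)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, figures - 1 - exponent)


def regeneration_efficiency(rec: RegenerationRecord,
                            figures: int = 3) -> tuple[float, float]:
    """Percent regeneration (vegetative-stage and total), three
    significant figures."""
    if rec.n_calli == 0:
        raise ConfigError(f"{rec.transgene}: n_calli must be positive")
    percent = round_sig(100.0 * rec.n_regenerated / rec.n_calli, figures)
    percent_total = round_sig(100.0 * rec.n_regenerated_total / rec.n_calli,
                              figures)
    return percent, percent_total


# The published regeneration table: counts plus the efficiencies as
# printed. Used as input data and as the reference the recomputation is
# compared against.
TABLE1 = (
    ("35S-ABC", 409, 0, 6, 0.0, 1.47),
    ("RPP-ABC", 308, 2, 6, 0.649, 1.95),
    ("SPK-ABC", 129, 1, 3, 0.775, 2.33),
    ("35S-BC", 325, 2, 5, 0.615, 1.54),
    ("SPK-BC", 527, 2, 7, 0.379, 1.33),
    ("35S-AB", 33, 10, 10, 30.0, 30.3),
    ("35S-C", 65, 11, 11, 16.9, 16.9),
    ("VC", 50, 4, 4, 8.0, 8.0),
)


def table1_records() -> list[RegenerationRecord]:
    return [RegenerationRecord(t, c, r, rt) for t, c, r, rt, _e, _et in TABLE1]


def table1_frame() -> pd.DataFrame:
    return pd.DataFrame(TABLE1, columns=[
        "transgene", "n_calli", "n_regenerated", "n_regenerated_total",
        "efficiency_printed", "efficiency_total_printed"])


def recompute(frame: pd.DataFrame) -> pd.DataFrame:
    """Append recomputed efficiencies and printed-value discrepancy flags."""
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(RegenerationRecord(
                str(row["transgene"]), int(row["n_calli"]),
                int(row["n_regenerated"]), int(row["n_regenerated_total"])))
        except (ConfigError, ValueError) as exc:
            raise FormatError(f"row {i + 1}: {exc}") from exc
    out = frame.copy()
    eff = [regeneration_efficiency(r) for r in records]
    out["efficiency"] = [e for e, _ in eff]
    out["efficiency_total"] = [et for _, et in eff]
    if "efficiency_printed" in out.columns:
        out["discrepancy"] = out["efficiency"] != out["efficiency_printed"]
    if "efficiency_total_printed" in out.columns:
        out["discrepancy_total"] = (out["efficiency_total"]
                                    != out["efficiency_total_printed"])
    return out


def read_regeneration_table(path: str | Path) -> pd.DataFrame:
    """Read, validate and recompute a regeneration TSV.

    Requires columns transgene, n_calli, n_regenerated,
    n_regenerated_total; printed-efficiency columns, when present, are
    checked and flagged where they disagree with the recomputation.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"regeneration table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"regeneration table {path} is empty")
    required = ("transgene", "n_calli", "n_regenerated",
                "n_regenerated_total")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError("regeneration table missing columns: "
                          + ", ".join(missing))
    return recompute(df)


def write_table1_tsv(path: str | Path) -> Path:
    table1_frame().to_csv(path, sep="\t", index=False)
    return Path(path)
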