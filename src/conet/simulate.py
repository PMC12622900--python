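"""Synthetic stand-in for the study inputs.

Generates (a) an annotated gene universe with controlled GO-term overlap
and (b) a six-array spot-intensity experiment — two arrays each for the
vector control (VC) and the two phaC-expressing genotypes (PhaC, PhaBC) —
with duplicate spots per gene, log-normal intensity noise and a planted
differential-expression signature. The signature is shared between the
PhaC and PhaBC lines except for a small PhaBC-only component
(``shared_fraction``, default 0.95, mirrors the observation that fewer
than 5% of the changed genes were specific to PhaBC).

Intensities follow log2 intensity = baseline(g) + noise, multiplied on
the linear scale by the line's planted effect, so noise-free runs recover
planted multipliers exactly through the whole pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .go_scoring import ASPECTS, GoAnnotation

LINE_OF_SAMPLE = (("VC", 1), ("VC", 2), ("PhaC", 1), ("PhaC", 2),
                  ("PhaBC", 1), ("PhaBC", 2))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated design scaled to desk size: 2,000
    genes (the real arrays carry ~44k probes; the count is configurable),
    six arrays in three genotypes, two duplicate spots per gene, log2
    baseline ~ N(10, 1.5), spot noise 0.25 on the log2 scale, and a DE
    signature shared at 95% between the phaC-expressing lines.
    """

    seed: int = 0
    n_genes: int = 2000
    n_terms: Mapping[str, int] = field(
        default_factory=lambda: {"BP": 80, "MF": 40, "CC": 30})
    term_size_distribution: tuple[int, int, float] = (5, 60, 1.0)
    terms_per_gene_mean: float = 3.0
    n_spot_replicates: int = 2
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.25
    de_spec: tuple[tuple[str, float], ...] = ()
    shared_fraction: float = 0.95
    phaBC_only_terms: tuple[tuple[str, float], ...] = ()
    spot_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not set(self.n_terms) <= set(ASPECTS):
            raise ConfigError(f"n_terms keys must be among {ASPECTS}")
        lo, hi, shape = self.term_size_distribution
        if not (1 <= lo <= hi):
            raise ConfigError("term sizes must satisfy 1 <= min <= max")
        if shape <= 0:
            raise ConfigError("term size shape must be positive")
        if self.terms_per_gene_mean <= 0:
            raise ConfigError("terms_per_gene_mean must be positive")
        if not 0 <= self.shared_fraction <= 1:
            raise ConfigError("shared_fraction must lie in [0, 1]")
        if self.noise_sd_log2 < 0 or not 0 <= self.spot_fail_rate < 1:
            raise ConfigError("invalid noise or spot failure rate")
        for term, mult in tuple(self.de_spec) + tuple(self.phaBC_only_terms):
            if mult <= 0:
                raise ConfigError(f"multiplier for {term} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("de_spec", "phaBC_only_terms"):
            if key in raw:
                raw[key] = tuple((str(t), float(m)) for t, m in raw[key])
        if "term_size_distribution" in raw:
            raw["term_size_distribution"] = tuple(raw["term_size_distribution"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["n_terms"] = dict(raw["n_terms"])
        raw["term_size_distribution"] = list(raw["term_size_distribution"])
        raw["de_spec"] = [list(x) for x in raw["de_spec"]]
        raw["phaBC_only_terms"] = [list(x) for x in raw["phaBC_only_terms"]]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def study_default_config(seed: int = 0, n_genes: int = 2000) -> SimConfig:
    """The default emulated study: a few strongly up- and downregulated
    BP terms shared between the phaC-expressing lines."""
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        de_spec=(("GO:0000001", 4.0), ("GO:0000002", 3.0),
                 ("GO:0000003", 0.25), ("GO:0000004", 0.4)),
    )


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _term_ids(cfg: SimConfig) -> list[tuple[str, str]]:
    """Sequential GO-style identifiers, BP first, with their aspect."""
    out = []
    i = 1
    for aspect in ASPECTS:
        for _ in range(int(cfg.n_terms.get(aspect, 0))):
            out.append((f"GO:{i:07d}", aspect))
            i += 1
    return out


def simulate_annotation(cfg: SimConfig) -> GoAnnotation:
    """Draw a random gene->GO annotation.

    Term sizes follow the configured log-uniform-style distribution
    (shape > 1 skews small, < 1 skews large), rescaled so the total
    number of gene-term incidences hits n_genes * terms_per_gene_mean;
    members are drawn uniformly without replacement per term, which
    creates the term overlap the co-occurrence network feeds on. Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng([0, cfg.seed])
    terms = _term_ids(cfg)
    if not terms:
        raise ConfigError("no terms configured")
    target = cfg.terms_per_gene_mean * cfg.n_genes
    if target > len(terms) * cfg.n_genes:
        raise ConfigError("terms_per_gene_mean infeasible for the "
                          "configured number of terms")
    lo, hi, shape = cfg.term_size_distribution
    u = rng.random(len(terms)) ** shape
    raw = lo * (hi / lo) ** u
    sizes = raw * (target / raw.sum())
    sizes = np.clip(np.round(sizes).astype(int), 1, cfg.n_genes)
    genes = np.array(_gene_ids(cfg.n_genes))
    pairs = []
    aspects = {}
    names = {}
    for (term, aspect), size in zip(terms, sizes):
        members = rng.choice(cfg.n_genes, size=int(size), replace=False)
        pairs.extend((genes[g], term) for g in members)
        aspects[term] = aspect
        names[term] = f"synthetic {aspect} term {term[-7:].lstrip('0')}"
    return GoAnnotation(pairs, aspects=aspects, names=names)


@dataclass
class GroundTruth:
    """Planted per-gene expression multipliers per genotype line."""

    multipliers: pd.DataFrame  # genes x (VC, PhaC, PhaBC)

    def pooled(self, lines: Sequence[str] = ("PhaC", "PhaBC")) -> pd.Series:
        """Expected pooled fold change per gene: with equal numbers of
        arrays per line, the mean of per-array ratios equals the mean of
        the per-line multipliers."""
        return self.multipliers[list(lines)].mean(axis=1)

    def de_genes(self, line: str) -> frozenset[str]:
        m = self.multipliers[line]
        return frozenset(m.index[m != 1.0])


def expected_scores(truth: GroundTruth, ann: GoAnnotation,
                    lines: Sequence[str] = ("PhaC", "PhaBC")) -> pd.Series:
    """Reference GO-term scores implied by the planted multipliers."""
    pooled = truth.pooled(lines)
    out = {}
    for term in ann.term_ids:
        members = [g for g in sorted(ann.genes(term)) if g in pooled.index]
        if members:
            out[term] = float(pooled[members].mean())
    return pd.Series(out, name="expected_score")


def design_frame() -> pd.DataFrame:
    rows = [(f"{line}_{rep}", line, rep,
             "control" if line == "VC" else "treatment")
            for line, rep in LINE_OF_SAMPLE]
    return pd.DataFrame(rows, columns=["sample_id", "line", "replicate",
                                       "group"])


def simulate_experiment(cfg: SimConfig, ann: GoAnnotation,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the six-array spot table.

    Returns (spot table, sample design, ground truth). Every de_spec term
    must exist in the annotation; a gene annotated with several DE terms
    multiplies their effects. Each DE gene is shared between PhaC and
    PhaBC with probability ``shared_fraction`` and is otherwise
    PhaBC-only; ``phaBC_only_terms`` adds an explicit PhaBC-specific
    component.
    """
    rng = np.random.default_rng([1, cfg.seed])
    genes = _gene_ids(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for term, _m in tuple(cfg.de_spec) + tuple(cfg.phaBC_only_terms):
        if term not in ann:
            raise ConfigError(f"DE term {term} not present in annotation")

    log2_effect = np.zeros(cfg.n_genes)
    for term, mult in cfg.de_spec:
        for g in ann.genes(term):
            log2_effect[gene_index[g]] += np.log2(mult)
    de_mask = log2_effect != 0
    shared = rng.random(cfg.n_genes) < cfg.shared_fraction

    mult = pd.DataFrame(1.0, index=pd.Index(genes, name="gene_id"),
                        columns=["VC", "PhaC", "PhaBC"])
    mult.loc[de_mask & shared, "PhaC"] = 2.0 ** log2_effect[de_mask & shared]
    mult.loc[de_mask, "PhaBC"] = 2.0 ** log2_effect[de_mask]
    only = np.zeros(cfg.n_genes)
    for term, m in cfg.phaBC_only_terms:
        for g in ann.genes(term):
            only[gene_index[g]] += np.log2(m)
    mult.loc[only != 0, "PhaBC"] = (mult.loc[only != 0, "PhaBC"].to_numpy()
                                    * 2.0 ** only[only != 0])

    baseline = (cfg.baseline_log2_mean
                + cfg.baseline_log2_sd * rng.standard_normal(cfg.n_genes))
    meta = design_frame()
    n_spots = cfg.n_spot_replicates
    frames = []
    for sample_id, line in zip(meta["sample_id"], meta["line"]):
        line_mult = mult[line].to_numpy()
        # (gene, spot) noise drawn in one block per array for determinism
        noise = cfg.noise_sd_log2 * rng.standard_normal((cfg.n_genes, n_spots))
        intensity = np.exp2(baseline[:, None] + noise) * line_mult[:, None]
        if cfg.spot_fail_rate > 0:
            flag = rng.random((cfg.n_genes, n_spots)) >= cfg.spot_fail_rate
        else:
            flag = np.ones((cfg.n_genes, n_spots), dtype=bool)
        frames.append(pd.DataFrame({
            "probe_id": [f"P{i:05d}_{s + 1}" for i in range(cfg.n_genes)
                         for s in range(n_spots)],
            "gene_id": np.repeat(genes, n_spots),
            "sample_id": sample_id,
            "intensity": intensity.ravel(),
            "flag": flag.ravel(),
        }))
    spots = pd.concat(frames, ignore_index=True)
    return spots, meta, GroundTruth(multipliers=mult)
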