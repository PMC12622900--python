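"""Gene→GO annotation index and GO-term expression scoring.

A GO term's expression score is the arithmetic mean of the fold change of
the measured genes annotated with that term; a gene annotated with several
terms contributes independently to each of them. Terms are then classified
up- or downregulated by strict thresholds on the score (defaults > 2 up,
< 0.5 down). Annotations are flat labels — no ontology-hierarchy
propagation is performed.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .expression import FoldChangeTable

log = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
_TERM_RE = re.compile(r"^GO:\d{7}$")


class GoAnnotation:
    """Bidirectional gene <-> GO-term membership index with aspect labels."""

    def __init__(self, pairs: Iterable[tuple[str, str]],
                 aspects: Mapping[str, str] | None = None,
                 names: Mapping[str, str] | None = None,
                 strict: bool = False) -> None:
        aspects = dict(aspects or {})
        names = dict(names or {})
        gene_to_terms: dict[str, set[str]] = {}
        term_to_genes: dict[str, set[str]] = {}
        for gene, term in pairs:
            gene, term = str(gene), str(term)
            if strict and not _TERM_RE.match(term):
                raise FormatError(f"malformed GO term identifier: {term!r}")
            gene_to_terms.setdefault(gene, set()).add(term)
            term_to_genes.setdefault(term, set()).add(gene)
        self._gene_to_terms = {g: frozenset(ts) for g, ts in gene_to_terms.items()}
        self._term_to_genes = {t: frozenset(gs) for t, gs in term_to_genes.items()}
        self._meta: dict[str, tuple[str, str]] = {}
        n_defaulted = 0
        for term in self._term_to_genes:
            aspect = aspects.get(term)
            if aspect is None:
                aspect = "BP"
                n_defaulted += 1
            if aspect not in ASPECTS:
                raise FormatError(f"unknown GO aspect {aspect!r} for {term}")
            self._meta[term] = (aspect, names.get(term, ""))
        if n_defaulted:
            log.warning("GoAnnotation: %d term(s) without aspect defaulted "
                        "to BP", n_defaulted)

    # -- queries ---------------------------------------------------------
    @property
    def term_ids(self) -> list[str]:
        return sorted(self._term_to_genes)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._gene_to_terms)

    @property
    def n_terms(self) -> int:
        return len(self._term_to_genes)

    @property
    def n_genes(self) -> int:
        return len(self._gene_to_terms)

    def genes(self, term: str) -> frozenset[str]:
        return self._term_to_genes[term]

    def terms(self, gene: str) -> frozenset[str]:
        return self._gene_to_terms.get(gene, frozenset())

    def __contains__(self, term: str) -> bool:
        return term in self._term_to_genes

    def aspect(self, term: str) -> str:
        return self._meta[term][0]

    def name(self, term: str) -> str:
        return self._meta[term][1]

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((g, t) for g, ts in self._gene_to_terms.items()
                      for t in ts)

    def subset_aspect(self, aspect: str) -> "GoAnnotation":
        if aspect not in ASPECTS:
            raise ConfigError(f"unknown GO aspect: {aspect!r}")
        keep = {t for t in self._term_to_genes if self.aspect(t) == aspect}
        pairs = [(g, t) for g, t in self.pairs() if t in keep]
        return GoAnnotation(pairs,
                            aspects={t: self.aspect(t) for t in keep},
                            names={t: self.name(t) for t in keep})

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, strict: bool = False) -> "GoAnnotation":
        """Read a two-column (optionally three-column) annotation TSV:
        ``gene_id  term_id  [aspect]``."""
        path = Path(path)
        if not path.exists():
            raise FormatError(f"annotation file not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns)
        if len(cols) < 2:
            raise FormatError("annotation TSV needs at least two columns "
                              "(gene_id, term_id)")
        rename = {cols[0]: "gene_id", cols[1]: "term_id"}
        if len(cols) >= 3:
            rename[cols[2]] = "aspect"
        df = df.rename(columns=rename)
        aspects = None
        if "aspect" in df.columns:
            sub = df.loc[df["aspect"].notna(), ["term_id", "aspect"]]
            aspects = dict(sub.itertuples(index=False))
        names = None
        if "name" in df.columns:
            sub = df.loc[df["name"].notna(), ["term_id", "name"]]
            names = dict(sub.itertuples(index=False))
        pairs = df[["gene_id", "term_id"]].itertuples(index=False)
        return cls(pairs, aspects=aspects, names=names, strict=strict)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, t, self.aspect(t), self.name(t)) for g, t in self.pairs()]
        pd.DataFrame(rows, columns=["gene_id", "term_id", "aspect", "name"]) \
          .to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path, strict: bool = False) -> GoAnnotation:
    return GoAnnotation.from_tsv(path, strict=strict)


def score_terms(fc: FoldChangeTable | pd.Series,
                ann: GoAnnotation) -> pd.DataFrame:
    """Score every GO term as the mean fold change of its measured members.

    Returns a DataFrame indexed by term_id with columns ``aspect``,
    ``name``, ``score`` and ``n_measured``; terms with no measured member
    are omitted (their count is logged and stored in
    ``df.attrs["n_terms_unmeasured"]``).
    """
    values = fc.fold_change if isinstance(fc, FoldChangeTable) else fc
    if len(values) == 0:
        raise ConfigError("empty fold-change table")
    lookup = values.to_dict()
    rows = []
    n_unmeasured = 0
    for term in ann.term_ids:
        # sorted members: summation order fixed across processes
        member_fc = [lookup[g] for g in sorted(ann.genes(term)) if g in lookup]
        if not member_fc:
            n_unmeasured += 1
            continue
        rows.append((term, ann.aspect(term), ann.name(term),
                     float(np.mean(member_fc)), len(member_fc)))
    if n_unmeasured:
        log.info("score_terms: %d term(s) had no measured member gene",
                 n_unmeasured)
    out = pd.DataFrame(rows, columns=["term_id", "aspect", "name", "score",
                                      "n_measured"]).set_index("term_id")
    if out.empty:
        log.warning("score_terms: no term had any measured member")
    out.attrs["n_terms_unmeasured"] = n_unmeasured
    return out


def classify_terms(scores: pd.DataFrame, up: float = 2.0,
                   down: float = 0.5) -> pd.DataFrame:
    """Label terms up/down/none with strict thresholds (score > up is up,
    score < down is down)."""
    if not (up > down > 0):
        raise ConfigError(f"thresholds must satisfy up > down > 0, "
                          f"got up={up}, down={down}")
    out = scores.copy()
    label = np.where(out["score"] > up, "up",
                     np.where(out["score"] < down, "down", "none"))
    out["label"] = label
    return out


def permutation_pvalues(fc: FoldChangeTable | pd.Series, ann: GoAnnotation,
                        n_permutations: int = 1000,
                        seed: int = 0) -> pd.Series:
    """Optional per-term permutation p-value by gene-label shuffling.

    The observed score is compared against scores of random gene sets of
    the same size drawn from the measured genes; the two-sided p-value is
    the fraction of permuted |log score| at least as extreme as observed
    (with the +1 small-sample correction). Off by default everywhere in
    the pipeline; the method itself is descriptive scoring, not a test.
    """
    values = fc.fold_change if isinstance(fc, FoldChangeTable) else fc
    scores = score_terms(values, ann)
    rng = np.random.default_rng(seed)
    measured = values.to_numpy()
    pvals = {}
    for term, row in scores.iterrows():
        k = int(row["n_measured"])
        perm = np.array([
            measured[rng.choice(len(measured), size=k, replace=False)].mean()
            for _ in range(n_permutations)])
        obs = abs(np.log(row["score"]))
        p = (1 + np.sum(np.abs(np.log(perm)) >= obs)) / (n_permutations + 1)
        pvals[term] = p
    return pd.Series(pvals, name="p_value")


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="term_id")


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="term_id",
                     float_precision="round_trip")
    if "name" in df.columns:
        df["name"] = df["name"].fillna("")
    return df
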