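"""Spearman co-expression of genes and pseudogenes across tissues.

Expression values are TPM from bulk RNA-seq, organized genes x samples
with a tissue label per sample. Correlations are computed across
tissue-level means (one point per tissue) by default, matching the usual
per-tissue scatter presentation; a per-sample mode is available.

p-values: two-sided, exact by permutation enumeration for n < 10 and via
the t-approximation for n >= 10. Benjamini-Hochberg adjusted p-values are
reported alongside raw ones in screens.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_P_MAX_N = 9  # exhaustive n! enumeration kept below 10 points


class ConstantVectorError(ValueError):
    """Spearman rho is undefined when a vector has no variation."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of non-negative TPM values.

    ``values`` is a DataFrame (rows = genes, columns = sample ids);
    ``tissues`` labels each column with its tissue of origin.
    """

    values: pd.DataFrame
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tissues) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.tissues)} tissue labels for "
                f"{self.values.shape[1]} sample columns"
            )
        if any(not t for t in self.tissues):
            raise ValueError("tissue labels must be non-empty")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        """Two header rows: sample ids, then tissue labels."""
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(map(str, self.values.columns)) + "\n")
            fh.write("tissue\t" + "\t".join(self.tissues) + "\n")
            for gene, row in self.values.iterrows():
                fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            tissue_row = fh.readline().rstrip("\n").split("\t")
            if tissue_row[0] != "tissue":
                raise ValueError(f"{path}: second header row must start with 'tissue'")
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        df.columns = header[1:]
        df.index.name = "gene"
        return cls(values=df.astype(float), tissues=tuple(tissue_row[1:]))


def aggregate_by_tissue(
    m: ExpressionMatrix, exclude: Sequence[str] = ()
) -> ExpressionMatrix:
    """Mean expression per tissue; excluded tissues (e.g. cultured-cell
    pseudo-tissues) are dropped. Unknown exclude labels warn."""
    present = set(m.tissues)
    for label in exclude:
        if label not in present:
            warnings.warn(f"exclude label {label!r} not in matrix, ignored")
    keep = [t for t in m.tissues if t not in set(exclude)]
    if not keep:
        raise ValueError("all tissues excluded")
    grouped = m.values.T.groupby(pd.Index(m.tissues, name="tissue")).mean().T
    grouped = grouped.drop(columns=[t for t in exclude if t in grouped.columns])
    tissues = tuple(grouped.columns)
    return ExpressionMatrix(values=grouped, tissues=tissues)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, observed_r: float) -> float:
    """Two-sided exact p over all n! pairings of the rank vectors."""
    rx = stats.rankdata(x)
    n = len(x)
    perms = np.array(list(itertools.permutations(stats.rankdata(y))))
    rs = np.array([stats.spearmanr(rx, p).statistic for p in perms]) \
        if n <= 4 else _vector_spearman(rx, perms)
    count = np.sum(np.abs(rs) >= abs(observed_r) - 1e-12)
    return float(count / len(perms))


def _vector_spearman(rx: np.ndarray, rank_perms: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank vector rx against each row of rank_perms."""
    rx_c = rx - rx.mean()
    perms_c = rank_perms - rank_perms.mean(axis=1, keepdims=True)
    num = perms_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (perms_c**2).sum(axis=1))
    return num / den


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (mid-ranks) with a two-sided p-value.

    For n < 10 the p-value is exact over all n! permutations; for larger
    n the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantVectorError("constant vector: Spearman rho undefined")
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if n <= EXACT_P_MAX_N:
        p = _exact_permutation_p(x, y, r)
    else:
        p = float(res.pvalue)
    return r, min(max(p, np.nextafter(0, 1)), 1.0)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation of one gene pair across tissues."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int
    p_adjusted: Optional[float] = None
    flag: str = ""  # significant | trend | ""


def correlation_screen(
    m: ExpressionMatrix,
    gene_set: Optional[Sequence[str]] = None,
    significant_at: float = 0.05,
    trend_at: float = 0.1,
) -> list[CorrelationResult]:
    """Spearman screen over all unordered gene pairs.

    Flags pairs as ``significant`` (p < significant_at) or ``trend``
    (significant_at <= p < trend_at) on the raw p-value; BH-adjusted
    p-values are reported alongside, never substituted.
    """
    genes = list(gene_set) if gene_set is not None else m.genes
    missing = set(genes) - set(m.genes)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)}")
    pairs = list(itertools.combinations(genes, 2))
    raw = []
    for ga, gb in pairs:
        r, p = spearman(m.values.loc[ga], m.values.loc[gb])
        raw.append((ga, gb, r, p))
    if not raw:
        return []
    p_adj = multipletests([p for *_, p in raw], method="fdr_bh")[1]
    results = []
    for (ga, gb, r, p), pa in zip(raw, p_adj):
        flag = (
            "significant"
            if p < significant_at
            else ("trend" if p < trend_at else "")
        )
        results.append(
            CorrelationResult(
                gene_a=ga, gene_b=gb, r=r, p=p, n=m.values.shape[1],
                p_adjusted=float(pa), flag=flag,
            )
        )
    return results


def screen_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "r": r.r,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "n": r.n,
                "flag": r.flag,
            }
            for r in results
        ]
    )
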