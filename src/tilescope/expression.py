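"""Expression-based receptor-status classifiers and gene-set enrichment.

A ridge-penalized linear classifier is fitted on a gene-by-sample
expression matrix with the receptor genes themselves (ESR1/PGR by default)
excluded, so any predictive signal must come from correlated programs
rather than the receptor transcript.  Single-gene AUC baselines and
hypergeometric gene-set over-representation (with Benjamini-Hochberg
correction and an immune-related fraction summary) complete the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.linear_model import RidgeClassifierCV
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .aggregation import compute_auc

__all__ = [
    "RidgeResult",
    "fit_ridge_expression_classifier",
    "single_gene_auc",
    "enrich_gene_sets",
    "read_gmt",
    "DEFAULT_RECEPTOR_EXCLUSION",
]

DEFAULT_RECEPTOR_EXCLUSION = ("ESR1", "PGR")
DEFAULT_ALPHAS = tuple(float(a) for a in np.logspace(-2, 4, 13))


@dataclass
class RidgeResult:
    coefficients: pd.Series          # standardized coefficients, kept genes only
    penalty: float
    excluded_genes: list
    auc: float
    n_train: int
    n_test: int

    def top_genes(self, n: int = 100) -> list:
        """Top-ranked genes by |standardized coefficient|."""
        return list(self.coefficients.abs().sort_values(ascending=False).index[:n])


@dataclass
class EnrichmentTable:
    table: pd.DataFrame
    immune_fraction: float
    alpha: float = 0.05


def _prepare(matrix: pd.DataFrame, log2_transform: bool) -> pd.DataFrame:
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if not matrix.index.is_unique:
        raise ValueError("gene identifiers must be unique")
    if log2_transform:
        matrix = np.log2(matrix + 1.0)
    return matrix


def fit_ridge_expression_classifier(
    matrix: pd.DataFrame,
    labels,
    exclude_genes=DEFAULT_RECEPTOR_EXCLUSION,
    alphas=DEFAULT_ALPHAS,
    seed: int = 0,
    test_fraction: float = 0.25,
    log2_transform: bool = False,
) -> RidgeResult:
    """Ridge classifier on expression with explicit gene exclusion.

    Genes in ``exclude_genes`` are dropped BEFORE fitting, so they carry no
    coefficient.  Features are z-scored on the training split, the ridge
    penalty is chosen by internal cross-validation over ``alphas``, and the
    AUC is computed on a held-out sample split untouched by fitting.  Set
    ``log2_transform`` for raw count-scale input.
    """
    matrix = _prepare(matrix, log2_transform)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need two classes")
    keep = [g for g in matrix.index if g not in set(exclude_genes)]
    if not keep:
        raise ValueError("all genes excluded")
    x = matrix.loc[keep].to_numpy(dtype=float).T  # samples x genes
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    scaler = StandardScaler().fit(x_tr)
    clf = RidgeClassifierCV(alphas=list(alphas))
    clf.fit(scaler.transform(x_tr), y_tr)
    scores = clf.decision_function(scaler.transform(x_te))
    auc = compute_auc(scores, y_te)
    coefs = pd.Series(clf.coef_.ravel(), index=keep, name="coefficient")
    return RidgeResult(
        coefficients=coefs,
        penalty=float(clf.alpha_),
        excluded_genes=[g for g in exclude_genes if g in matrix.index],
        auc=auc,
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def single_gene_auc(matrix: pd.DataFrame, gene: str, labels) -> float:
    """AUC of one gene's raw expression as the classification score.

    Score orientation is chosen so the result is at least 0.5 (a gene
    predictive in either direction scores symmetrically).
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    auc = compute_auc(matrix.loc[gene].to_numpy(dtype=float), np.asarray(labels))
    return max(auc, 1.0 - auc)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a tab-delimited GMT file: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def enrich_gene_sets(
    query_genes,
    universe_genes,
    gene_sets: dict[str, list[str]],
    immune_tags=(),
    alpha: float = 0.05,
) -> EnrichmentTable:
    """One-sided hypergeometric over-representation of each gene set.

    Sets are intersected with the universe first.  P-values are BH-adjusted
    across sets, and ``immune_fraction`` is the share of significant sets
    (adjusted p < ``alpha``) whose name is in ``immune_tags`` — the summary
    used to quantify how immune-dominated the top-gene signal is.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    immune = set(immune_tags)

    m = len(universe)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        members_u = set(members) & universe
        k_set = len(members_u)
        overlap = len(members_u & query)
        # P(X >= overlap), X ~ Hypergeom(M=m, K=k_set, n=n_query)
        p = float(hypergeom.sf(overlap - 1, m, k_set, n_query)) if k_set else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": k_set,
                "universe_size": m,
                "query_size": n_query,
                "p_value": min(p, 1.0),
                "immune_tag": name in immune,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["p_adjusted"] = adj
    else:
        table["p_adjusted"] = []
    sig = table[table["p_adjusted"] < alpha]
    frac = float(sig["immune_tag"].mean()) if len(sig) else float("nan")
    table = table.sort_values("p_value", ignore_index=True)
    return EnrichmentTable(table=table, immune_fraction=frac, alpha=alpha)
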