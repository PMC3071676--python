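"""Binding x expression integration and term enrichment.

Bound-gene lists are tested for enrichment among expression-responsive
genes with a one-sided hypergeometric test; responsive genes are
clustered on their two expression contrasts (average linkage) with
binding indicators carried along as annotations; and gene sets are tested
for term enrichment per term (hypergeometric upper tail) with Bonferroni
correction, reporting a single top term when it clears corrected p <
0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import hypergeom

from .params import DEFAULT_PARAMS


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap
    n: int  # query set size
    m: int  # term (or responsive) set size
    N: int  # universe
    p: float
    p_bonferroni: float = 1.0

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.m):
            raise ValueError("overlap exceeds a set size")


def hypergeom_upper_tail(k: int, N: int, n: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n)."""
    return float(hypergeom.sf(k - 1, N, m, n))


def binding_expression_enrichment(
    bound_genes: set[str], responsive_genes: set[str], universe_size: int
) -> EnrichmentResult:
    """Is the bound set enriched among responsive genes?

    One-sided hypergeometric upper-tail p of the observed intersection,
    drawing |bound| genes from a universe of ``universe_size`` of which
    |responsive| are responsive.
    """
    k = len(bound_genes & responsive_genes)
    n, m = len(bound_genes), len(responsive_genes)
    if max(n, m) > universe_size:
        raise ValueError("a gene set is larger than the universe")
    p = hypergeom_upper_tail(k, universe_size, n, m)
    return EnrichmentResult(term="binding_x_expression", k=k, n=n, m=m, N=universe_size, p=p)


def cluster_expression(
    records: pd.DataFrame,
    contrast_cols: tuple[str, str] = ("log2_haltere_vs_wing", "log2_cbx1wing_vs_wing"),
    binding_cols: tuple[str, ...] = (),
    n_clusters: int = 5,
) -> pd.DataFrame:
    """Hierarchically cluster genes on the two expression contrasts.

    Average linkage on the Euclidean distance of the two log-ratio
    columns only; binding indicator columns ride along as annotations.
    Returns the input frame with ``cluster`` labels (1..n_clusters) and
    rows in dendrogram leaf order. A constant matrix collapses to one
    cluster with a warning.
    """
    if len(records) < 2:
        raise ValueError("need at least two genes to cluster")
    X = records.loc[:, list(contrast_cols)].to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("constant expression matrix; returning a single cluster")
        out = records.copy()
        out["cluster"] = 1
        return out
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    order = leaves_list(Z)
    out = records.copy()
    out["cluster"] = labels
    return out.iloc[order].reset_index(drop=True)


def term_enrichment(
    gene_set: set[str],
    term_annotation: pd.DataFrame,
    universe: set[str],
    alpha: float = DEFAULT_PARAMS.bonferroni_alpha,
) -> tuple[pd.DataFrame, str | None]:
    """Per-term hypergeometric enrichment with Bonferroni correction.

    ``term_annotation`` maps genes to terms (columns ``gene``, ``term``).
    Only universe genes count. Returns (results sorted by corrected then
    raw p, top term) where the top term is the most significant term iff
    its corrected p < alpha; None otherwise. An empty gene set yields an
    empty frame.
    """
    ann = term_annotation[term_annotation["gene"].isin(universe)]
    gene_set = gene_set & universe
    N = len(universe)
    n = len(gene_set)
    if n == 0:
        return pd.DataFrame(columns=["term", "k", "n", "m", "N", "p", "p_bonferroni"]), None
    terms = ann.groupby("term")["gene"].agg(set)
    n_tested = len(terms)
    rows = []
    for term, members in terms.items():
        m = len(members)
        k = len(gene_set & members)
        p = hypergeom_upper_tail(k, N, n, m)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "m": m,
                "N": N,
                "p": p,
                "p_bonferroni": min(1.0, p * n_tested),
            }
        )
    res = pd.DataFrame(rows).sort_values(["p_bonferroni", "p", "term"]).reset_index(drop=True)
    top = None
    if len(res) and res.loc[0, "p_bonferroni"] < alpha:
        top = str(res.loc[0, "term"])
    return res, top
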