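"""Term-enrichment statistics.

Single-list enrichment uses the hypergeometric upper tail (probability of
drawing at least the observed number of annotated genes when sampling the
list from the universe without replacement). Two-list comparison (low- vs
high-MI hit groups) uses a two-sided Fisher exact test on the per-term 2x2
table. Raw p-values are adjusted with Benjamini-Hochberg across the tested
terms. Annotations are flat (gene, term) pairs: any hierarchical propagation
must happen upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "n",
    "K",
    "N",
    "p_value",
    "adjusted_p",
]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated genes in the universe, n the
    list size and k the annotated genes in the list. The tail is summed in
    log space for stability at extreme counts.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValidationError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValidationError(f"k={k} outside [0, min(n={n}, K={K})]")
    support_min = max(0, n - (N - K))
    if k <= support_min:
        return 1.0
    ks = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def _prepare_annotations(annotations: pd.DataFrame, universe: set[str]) -> pd.DataFrame:
    ann = annotations.loc[annotations["gene_symbol"].isin(universe)]
    return ann


def enrich_list(
    genes,
    universe,
    annotations: pd.DataFrame,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list against a universe.

    Terms annotating fewer than ``min_term_size`` universe genes are not
    tested. Returns one row per tested term (columns
    :data:`RESULT_COLUMNS`), sorted by raw p.
    """
    gene_set = {str(g).upper() for g in genes}
    uni = {str(g).upper() for g in universe}
    offenders = sorted(gene_set - uni)
    if offenders:
        raise ValidationError(
            f"list genes absent from universe: {', '.join(offenders)}"
        )
    ann = _prepare_annotations(annotations, uni)
    N, n = len(uni), len(gene_set)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(grp["gene_symbol"])
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & gene_set)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_tail(k, n, K, N),
            }
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["adjusted_p"] = pd.Series(dtype=float)
    return out


def compare_lists(
    list_a,
    list_b,
    annotations: pd.DataFrame,
    min_annotated: int = 1,
) -> pd.DataFrame:
    """Per-term Fisher exact comparison of two disjoint gene lists.

    For each term annotating at least ``min_annotated`` genes of the union,
    the 2x2 table [annotated / not] x [list A / list B] is tested two-sided.
    ``direction`` names the list with the higher annotated fraction
    ("A", "B" or "tie"). Swapping the lists flips directions and leaves
    p-values unchanged.
    """
    a = {str(g).upper() for g in list_a}
    b = {str(g).upper() for g in list_b}
    overlap = sorted(a & b)
    if overlap:
        raise ValidationError(f"lists overlap: {', '.join(overlap)}")
    ann = _prepare_annotations(annotations, a | b)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(grp["gene_symbol"])
        ka, kb = len(term_genes & a), len(term_genes & b)
        if ka + kb < min_annotated:
            continue
        table = [[ka, len(a) - ka], [kb, len(b) - kb]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        fa, fb = ka / len(a), kb / len(b)
        direction = "tie" if fa == fb else ("A" if fa > fb else "B")
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k_a": ka,
                "n_a": len(a),
                "k_b": kb,
                "n_b": len(b),
                "p_value": p,
                "direction": direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k_a", "n_a", "k_b", "n_b", "p_value", "direction"],
    )
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["adjusted_p"] = pd.Series(dtype=float)
    return out
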