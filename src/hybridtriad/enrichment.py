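"""One-sided hypergeometric over-representation with Benjamini-Hochberg FDR.

Given a selected gene set, a term -> gene annotation map and a universe, each
term's p-value is the upper hypergeometric tail P(X >= k) for drawing k
annotated genes in a selection of n from a universe of N containing K
annotated genes; adjusted p-values come from the BH step-up across all tested
terms.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


class ParameterError(ValueError):
    pass


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, take ``adj_i = min_{j >= i} p_j * m / j`` clipped at 1,
    and restore the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeom_enrich(selection: Iterable[str],
                     annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Test each term for over-representation in ``selection``.

    ``annotation`` is either a term -> gene-set mapping or a two-column
    DataFrame (gene, term).  Annotated genes are intersected with the
    universe; the selection must be a subset of the universe.  Terms left
    with no annotated genes are skipped.  Returns a DataFrame indexed by term
    with columns N, K, n, k, fold, p, padj, sorted by p.
    """
    universe = set(universe)
    selection = set(selection)
    if not universe:
        raise ParameterError("empty universe")
    if not selection:
        raise ParameterError("empty selection")
    if not selection <= universe:
        raise ParameterError("selection must be a subset of the universe")
    if isinstance(annotation, pd.DataFrame):
        term_map = {t: set(g) for t, g in annotation.groupby("term")["gene"]}
    else:
        term_map = {t: set(g) for t, g in annotation.items()}

    N, n = len(universe), len(selection)
    rows = []
    for term, genes in term_map.items():
        members = genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selection)
        # one-sided upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term, N, K, n, k, fold, p))
    if not rows:
        return pd.DataFrame(columns=["N", "K", "n", "k", "fold", "p", "padj"])
    table = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "fold", "p"])
    table["padj"] = bh_adjust(table["p"].to_numpy())
    return table.set_index("term").sort_values("p")
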