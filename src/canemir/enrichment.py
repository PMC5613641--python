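"""Term enrichment of predicted target genes.

Per-term significance is the upper-tail hypergeometric probability
(identical to one-sided Fisher's exact on the 2x2 table): with N
background genes, K of them in the term, and n target genes of which k
are in the term, p = P(X >= k).  Multiple testing is controlled with
Storey q-values (pi0 estimated on a lambda grid with a cubic smoother),
falling back to Benjamini-Hochberg when there are fewer than 100 terms,
where the pi0 smoother is unstable.  Significance applies the dual
cutoff p < 0.05 and q < 0.05.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .diffexp import adjust_fdr

__all__ = ["enrich_terms", "estimate_qvalues", "estimate_pi0"]

_STOREY_MIN_TERMS = 100
_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Storey's null-proportion estimate, cubic-spline smoothed over lambda.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a
    cubic smoothing spline and evaluated at the largest lambda; the
    result is clipped to [1/m, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if lambdas.size >= 5:
        from scipy.interpolate import UnivariateSpline

        pi0 = float(UnivariateSpline(lambdas, pi0_l, k=3)(lambdas.max()))
    else:
        pi0 = float(pi0_l[-1])
    return float(min(1.0, max(pi0, 1.0 / m)))


def estimate_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Storey q-values (BH fallback below 100 tests).

    q-values are monotone non-decreasing in the sorted p-values and
    bounded by 1; with a single p-value the estimate reduces to
    q = pi0 * p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < _STOREY_MIN_TERMS:
        pi0 = 1.0 if p.size > 1 else estimate_pi0(p, np.array([0.5]))
        base = adjust_fdr(p) if p.size > 1 else p.copy()
        return np.minimum(1.0, pi0 * base)
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    m = p.size
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(1.0, q_sorted)
    return q


def enrich_terms(
    target_genes: Iterable[str],
    annotation: pd.DataFrame,
    background: Iterable[str] | None = None,
    max_p: float = RunConfig.enrich_max_p,
    max_q: float = RunConfig.enrich_max_q,
    term_blocklist: Iterable[str] = (),
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a target-gene set.

    ``annotation`` maps genes to terms (columns ``gene``, ``term`` and
    optionally ``name``/``namespace``).  The background defaults to all
    annotated genes; target genes absent from the background raise a
    validation error listing the offenders.  One row is emitted per term
    hit by at least one target gene; ``significant`` applies both the p
    and q cutoffs.  ``term_blocklist`` drops named terms before testing
    (e.g. organism-irrelevant pathways).
    """
    required = {"gene", "term"}
    if not required <= set(annotation.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    blocked = set(term_blocklist)
    ann = annotation[~annotation["term"].isin(blocked)]
    bg = set(background) if background is not None else set(ann["gene"])
    tg = set(target_genes)
    offenders = sorted(tg - bg)
    if offenders:
        raise ValueError(f"target gene(s) absent from background: {offenders}")
    N = len(bg)
    n = len(tg)
    rows = []
    names = (
        ann.drop_duplicates("term").set_index("term")["name"]
        if "name" in ann.columns
        else None
    )
    for term, members in ann.groupby("term")["gene"]:
        genes = set(members) & bg
        K = len(genes)
        k = len(genes & tg)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": names[term] if names is not None else term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": min(1.0, p),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "pvalue"]
    )
    if len(result):
        result = result.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
        result["qvalue"] = estimate_qvalues(result["pvalue"].to_numpy())
        result["significant"] = (result["pvalue"] < max_p) & (result["qvalue"] < max_q)
    else:
        result["qvalue"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
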