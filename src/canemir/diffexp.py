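"""Two-group differential expression on raw miRNA counts.

The test is a conditional negative-binomial exact test with a common
method-of-moments dispersion (an in-package replacement for the exact
test of count-based DE packages).  Counts are parameterised
NB(mean mu, variance mu + phi * mu^2); the per-group sums are again NB
with size n/phi, and conditioning on the pooled sum yields a
parameter-free distribution given phi, whose two-sided p-value is twice
the smaller tail.  At phi = 0 this reduces exactly to the conditional
binomial test with proportion equal to the library-size ratio.

Classification applies the four-way filter: normalised expression
> 5 TPM in at least one sample, |log2FC| > 1, p < 0.05 and FDR < 0.05.
A published DE table can be supplied as a fixture (its fold changes,
p-values and FDRs are used as-is) to exercise the classification rule
separately from the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import RunConfig

__all__ = [
    "estimate_dispersion",
    "nb_exact_test",
    "adjust_fdr",
    "classify_de",
    "de_from_counts",
    "load_table2",
    "mature_passenger_pairs",
]

_PHI_EPS = 1e-12


def _split_groups(
    samples: Sequence[str], groups: Mapping[str, str]
) -> tuple[str, str, list[str], list[str]]:
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"sample(s) missing from group map: {missing}")
    labels = sorted(set(groups[s] for s in samples))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a = [s for s in samples if groups[s] == labels[0]]
    b = [s for s in samples if groups[s] == labels[1]]
    return labels[0], labels[1], a, b


def estimate_dispersion(counts: pd.DataFrame, groups: Mapping[str, str]) -> float:
    """Common NB dispersion phi by pooled method of moments, floored at 0.

    Within each group g and gene i with sample mean m and unbiased
    variance v, E[v - m] = phi * mu^2, so the ratio estimator
    sum(v - m) / sum(m^2) over all gene/group cells is consistent.
    """
    _, _, ga, gb = _split_groups(list(counts.columns), groups)
    if min(len(ga), len(gb)) < 2:
        raise ValueError("each group needs at least 2 samples to estimate dispersion")
    num = 0.0
    den = 0.0
    for cols in (ga, gb):
        sub = counts[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den == 0.0:
        return 0.0
    return max(0.0, num / den)


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    phi: float,
    library_sizes: tuple[Sequence[float], Sequence[float]] | None = None,
) -> float:
    """Conditional NB exact test for a two-group count comparison.

    Two-sided by doubling the smaller tail (capped at 1); symmetric in
    group exchange; returns exactly 1 for all-zero counts.  With
    ``phi = 0`` the conditional law is Binomial(total, ratio of summed
    library sizes), matching the exact binomial test; with ``phi > 0``
    counts are first scaled to equal library sizes and the conditional
    distribution uses per-group sizes n_g / phi (independent of mu).
    """
    ya = np.asarray(counts_a, dtype=float)
    yb = np.asarray(counts_b, dtype=float)
    if (ya < 0).any() or (yb < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    na, nb = len(ya), len(yb)
    if phi < _PHI_EPS:
        sa, sb = int(round(ya.sum())), int(round(yb.sum()))
        t = sa + sb
        if t == 0:
            return 1.0
        if library_sizes is not None:
            la, lb = (float(np.sum(library_sizes[0])), float(np.sum(library_sizes[1])))
        else:
            la, lb = float(na), float(nb)
        prop = la / (la + lb)
        lower = stats.binom.cdf(sa, t, prop)
        upper = stats.binom.sf(sa - 1, t, prop)
        return float(min(1.0, 2.0 * min(lower, upper)))

    if library_sizes is not None:
        la = np.asarray(library_sizes[0], dtype=float)
        lb = np.asarray(library_sizes[1], dtype=float)
        ref = float(np.concatenate([la, lb]).mean())
        ya = np.round(ya * ref / la)
        yb = np.round(yb * ref / lb)
    sa, sb = int(ya.sum()), int(yb.sum())
    t = sa + sb
    if t == 0:
        return 1.0
    ra, rb = na / phi, nb / phi
    k = np.arange(t + 1)
    logw = (
        gammaln(k + ra)
        - gammaln(k + 1)
        + gammaln(t - k + rb)
        - gammaln(t - k + 1)
    )
    logw -= logsumexp(logw)
    w = np.exp(logw)
    lower = float(w[: sa + 1].sum())
    upper = float(w[sa:].sum())
    return float(min(1.0, 2.0 * min(lower, upper)))


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEThresholds:
    """The four-way DE classification filter (published defaults)."""

    min_tpm: float = RunConfig.de_min_tpm
    min_abs_log2fc: float = RunConfig.de_min_abs_log2fc
    max_p: float = RunConfig.de_max_p
    max_fdr: float = RunConfig.de_max_fdr


def classify_de(
    table: pd.DataFrame,
    sample_columns: Sequence[str],
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Label each row up / down / ns from the four criteria.

    ``table`` must carry per-sample TPM columns plus ``log2fc``,
    ``pvalue`` and ``fdr`` (externally supplied values are used as-is).
    A label other than ``ns`` requires ALL of: TPM strictly above
    ``min_tpm`` in at least one sample, |log2fc| strictly above
    ``min_abs_log2fc``, p strictly below ``max_p`` and FDR strictly
    below ``max_fdr``.
    """
    missing = [c for c in [*sample_columns, "log2fc", "pvalue", "fdr"] if c not in table]
    if missing:
        raise ValueError(f"DE table missing column(s): {missing}")
    out = table.copy()
    expressed = (out[list(sample_columns)] > thresholds.min_tpm).any(axis=1)
    passes = (
        expressed
        & (out["log2fc"].abs() > thresholds.min_abs_log2fc)
        & (out["pvalue"] < thresholds.max_p)
        & (out["fdr"] < thresholds.max_fdr)
    )
    out["label"] = "ns"
    out.loc[passes & (out["log2fc"] > 0), "label"] = "up"
    out.loc[passes & (out["log2fc"] < 0), "label"] = "down"
    return out


def de_from_counts(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    groups: Mapping[str, str],
    thresholds: DEThresholds = DEThresholds(),
    pseudocount: float = RunConfig.de_pseudocount_tpm,
    library_sizes: Mapping[str, float] | None = None,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Full DE analysis from raw counts: exact test, BH FDR, labels.

    log2FC is computed on group-mean TPM with a pseudocount, oriented as
    log2(treatment / reference); ``reference_group`` names the
    denominator group (default: the first label in sorted order).
    """
    la, lb, ga, gb = _split_groups(list(counts.columns), groups)
    if reference_group is not None:
        if reference_group not in (la, lb):
            raise ValueError(f"reference group {reference_group!r} not in ({la}, {lb})")
        if reference_group == lb:
            la, lb, ga, gb = lb, la, gb, ga
    phi = estimate_dispersion(counts, groups)
    libs = None
    if library_sizes is not None:
        libs = (
            [float(library_sizes[s]) for s in ga],
            [float(library_sizes[s]) for s in gb],
        )
    pvals = [
        nb_exact_test(counts.loc[i, ga], counts.loc[i, gb], phi, libs)
        for i in counts.index
    ]
    mean_a = tpm[ga].mean(axis=1)
    mean_b = tpm[gb].mean(axis=1)
    table = pd.DataFrame(
        {
            f"mean_tpm_{la}": mean_a,
            f"mean_tpm_{lb}": mean_b,
            "log2fc": np.log2((mean_b + pseudocount) / (mean_a + pseudocount)),
            "pvalue": pvals,
        },
        index=counts.index,
    )
    table["fdr"] = adjust_fdr(table["pvalue"].to_numpy())
    table = pd.concat([tpm, table], axis=1)
    table.attrs["dispersion"] = phi
    return classify_de(table, list(tpm.columns), thresholds)


def load_table2() -> pd.DataFrame:
    """The in-repo published DE table fixture (TPM per sample, log2FC, p, FDR)."""
    with resources.files("canemir.fixtures").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="mirna")


def mature_passenger_pairs(mirna_ids: Sequence[str]) -> list[str]:
    """Hairpin base names present with both a -5p and a -3p product."""
    arms: dict[str, set[str]] = {}
    for mid in mirna_ids:
        for suffix in ("-5p", "-3p"):
            if mid.endswith(suffix):
                arms.setdefault(mid[: -len(suffix)], set()).add(suffix)
    return sorted(base for base, seen in arms.items() if len(seen) == 2)
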