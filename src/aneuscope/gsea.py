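"""Preranked gene-set enrichment with the weighted Kolmogorov-Smirnov statistic.

Given a real-valued gene ranking (e.g. epistasis delta-LFC or association
coefficients) and named gene sets, the enrichment score is the maximum
deviation of a running sum that increments at set members in proportion to
|score|^p (p = 1 by default) and decrements 1/(N - Nh) at non-members.
Significance and the normalized enrichment score come from permuting gene
labels; FDR is Benjamini-Hochberg across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["enrichment_score", "preranked_gsea"]


def enrichment_score(
    ranked_scores: pd.Series, members: set, weight: float = 1.0
) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score of one gene set against a ranking.

    Parameters
    ----------
    ranked_scores
        Gene -> score, sorted in decreasing score order.
    members
        Gene set (only members present in the ranking count).

    Returns
    -------
    (es, leading_edge)
        ES in [-1, 1] and the leading-edge genes (members up to / from the
        running-sum extremum, by its sign).
    """
    genes = np.asarray(ranked_scores.index)
    scores = ranked_scores.to_numpy(dtype=float)
    hit = np.isin(genes, list(members))
    n = len(genes)
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranking")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member scores are exactly zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    running = np.cumsum(hit_w / denom - (~hit) / (n - nh))
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, leading


def preranked_gsea(
    scores: pd.Series,
    gene_sets: dict[str, set],
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of every gene set in a ranked list, with permutation p/NES.

    Parameters
    ----------
    scores
        Gene -> real score; duplicate gene labels are rejected.  Sorted
        internally in decreasing order.
    gene_sets
        Name -> member genes.  Sets whose overlap with the ranking falls
        outside [min_size, max_size], or that cover the whole ranking, are
        skipped with a warning.
    n_perm
        Gene-label permutations for the null ES distribution per set size.

    Returns
    -------
    DataFrame with set, es, nes, p, fdr, size, leading_edge.
    """
    scores = pd.Series(scores, dtype=float)
    if scores.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ranked = scores.sort_values(ascending=False)
    universe = set(ranked.index)
    n = len(ranked)

    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        overlap = universe & set(members)
        k = len(overlap)
        if k == 0:
            logger.warning("gene set %s shares no genes with the ranking; skipped", name)
            continue
        if k >= n:
            logger.warning("gene set %s covers the whole ranking; skipped", name)
            continue
        if not min_size <= k <= max_size:
            logger.warning("gene set %s overlap %d outside [%d, %d]; skipped", name, k, min_size, max_size)
            continue
        es, leading = enrichment_score(ranked, overlap, weight)
        if k not in null_cache:
            null = np.empty(n_perm)
            all_genes = np.asarray(ranked.index)
            for j in range(n_perm):
                rand_members = set(rng.choice(all_genes, size=k, replace=False))
                null[j], _ = enrichment_score(ranked, rand_members, weight)
            null_cache[k] = null
        null = null_cache[k]
        # signed p-value: compare against the same-sign side of the null
        if es >= 0:
            side = null[null >= 0]
            b = np.sum(side >= es)
            mean_side = side.mean() if len(side) else np.nan
        else:
            side = null[null < 0]
            b = np.sum(side <= es)
            mean_side = side.mean() if len(side) else np.nan
        p = float((b + 1) / (len(side) + 1))
        nes = float(es / abs(mean_side)) if mean_side and not np.isnan(mean_side) else np.nan
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p": p,
                "size": k,
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size", "leading_edge"])
    if len(out):
        out.insert(4, "fdr", multipletests(out["p"].to_numpy(), method="fdr_bh")[1])
    else:
        out.insert(4, "fdr", pd.Series(dtype=float))
    return out
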