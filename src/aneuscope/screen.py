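"""Paired-timepoint CRISPR screen analysis with copy-number bias correction.

Guide counts at PD0 (post-selection) and PD6 (six population doublings) are
library-size normalized and reduced to per-guide log2 fold changes.  Guides on
copy-number-altered arms show a positional dropout/enrichment bias unrelated
to gene function; the correction here subtracts, per altered arm, the arm's
median guide LFC offset from the genome-wide median.  Gene-level significance
comes from a permutation null of pseudo-genes assembled from randomly drawn
guide sets of matching size, and epistasis profiles contrast gene scores
between aneuploid and diploid clone screens.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_and_lfc",
    "correct_cn_bias",
    "gene_level_test",
    "epistasis_profile",
    "essential_gene_calls",
]

META_COLS = ("guide", "gene", "chrom", "pos")


def _count_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in META_COLS]


def _pairs(columns: list[str]) -> list[tuple[str, str, str]]:
    """(clone_replicate id, PD0 column, PD6 column) pairs from column names."""
    pd0 = {}
    pd6 = {}
    for c in columns:
        parts = c.split("_PD")
        if len(parts) != 2:
            continue
        clone, rest = parts
        tp, _, rep = rest.partition("_")
        key = (clone, rep or "r1")
        if tp == "0":
            pd0[key] = c
        elif tp == "6":
            pd6[key] = c
    shared = sorted(set(pd0) & set(pd6))
    if not shared:
        raise ValueError(
            "no PD0/PD6 column pairs found; expected names like 'clone1_PD0_r1' / 'clone1_PD6_r1'"
        )
    return [(f"{clone}_{rep}", pd0[(clone, rep)], pd6[(clone, rep)]) for clone, rep in shared]


def normalize_and_lfc(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    min_pd0_count: int = 30,
    median_center: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-guide log2 fold change PD6 vs PD0 for every clone/replicate.

    ``lfc = log2((c6 + pc) / N6) - log2((c0 + pc) / N0)`` with N the raw
    column totals.  Guides with PD0 count below ``min_pd0_count`` in a given
    clone/replicate are excluded from downstream testing for that column
    (LFC set to NaN) and reported.  Columns are optionally median-centered so
    the typical guide has LFC 0.

    Returns
    -------
    (lfc, excluded)
        ``lfc``: guide metadata plus one LFC column per clone/replicate.
        ``excluded``: long table (guide, column) of low-coverage exclusions.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    cols = _count_columns(counts)
    pairs = _pairs(cols)
    out = counts.loc[:, [c for c in META_COLS if c in counts.columns]].copy()
    dropped = []
    for name, c0, c6 in pairs:
        n0 = counts[c0].sum()
        n6 = counts[c6].sum()
        if n0 <= 0 or n6 <= 0:
            raise ValueError(f"zero library size in column pair {c0}/{c6}")
        lfc = np.log2((counts[c6] + pseudocount) / n6) - np.log2(
            (counts[c0] + pseudocount) / n0
        )
        low = counts[c0] < min_pd0_count
        if low.any():
            for g in counts.loc[low, "guide"]:
                dropped.append({"guide": g, "column": name, "reason": "low PD0 count"})
            lfc = lfc.mask(low)
        if median_center:
            lfc = lfc - lfc.median()
        out[name] = lfc
    excluded = pd.DataFrame(dropped, columns=["guide", "column", "reason"])
    if len(excluded):
        logger.warning("%d guide/column LFC values excluded for low PD0 coverage", len(excluded))
    return out, excluded


def correct_cn_bias(
    lfc: pd.DataFrame,
    genome: GenomeModel,
    karyotype: dict[str, dict[str, str]],
    min_guides: int = 20,
) -> pd.DataFrame:
    """Remove arm-positional LFC bias on copy-number-altered arms.

    For each clone and each arm its karyotype marks as gained or lost, the
    offset (arm median guide LFC - background median guide LFC) is subtracted
    from that arm's guides in that clone's LFC columns.  The background is
    the median over guides on copy-neutral arms, so the estimate is not
    contaminated by the biased arms themselves (falling back to the
    genome-wide median if no neutral guides exist).  Copy-neutral arms are
    untouched.  Arms with fewer than ``min_guides`` guides are skipped with a
    warning.

    Parameters
    ----------
    lfc
        Output of :func:`normalize_and_lfc` (guide metadata + LFC columns).
    karyotype
        ``{clone: {arm_id: "gain"|"loss"|"neutral"}}``; missing arms are
        treated as neutral.
    """
    out = lfc.copy()
    if "chrom" not in out.columns or "pos" not in out.columns:
        raise ValueError("lfc table needs chrom and pos columns to locate guides on arms")
    arm_ids = np.array(
        [genome.arm_of(c, p) for c, p in zip(out["chrom"], out["pos"])], dtype=object
    )
    lfc_cols = [c for c in out.columns if c not in META_COLS]
    for col in lfc_cols:
        clone = col.rsplit("_r", 1)[0]
        calls = karyotype.get(clone, {})
        altered = [a for a, call in calls.items() if call in ("gain", "loss")]
        if not altered:
            continue
        vals = out[col].to_numpy(dtype=float)
        on_altered = np.isin(arm_ids, altered)
        neutral_vals = vals[~on_altered]
        if np.sum(~np.isnan(neutral_vals)) > 0:
            background_median = np.nanmedian(neutral_vals)
        else:
            background_median = np.nanmedian(vals)
        for arm in altered:
            on_arm = arm_ids == arm
            n = int(np.sum(on_arm & ~np.isnan(vals)))
            if n < min_guides:
                logger.warning(
                    "clone %s arm %s: only %d guides (<%d); bias correction skipped",
                    clone, arm, n, min_guides,
                )
                continue
            offset = np.nanmedian(vals[on_arm]) - background_median
            vals = np.where(on_arm, vals - offset, vals)
        out[col] = vals
    return out


def gene_level_test(
    lfc: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    aggregate: str = "mean",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Gene-level scores and permutation p-values from guide LFCs.

    The gene score is the mean (or median) of its guides' LFCs averaged over
    the selected clone/replicate columns.  The null distribution for a gene
    with k guides is the score of pseudo-genes assembled from k guides drawn
    at random from the whole library; the two-sided p-value uses the
    (b + 1) / (n_perm + 1) correction and is BH-adjusted across genes.

    Returns a DataFrame with gene, lfc, p, fdr, n_guides.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    lfc_cols = columns or [c for c in lfc.columns if c not in META_COLS]
    if not lfc_cols:
        raise ValueError("no LFC columns found")
    guide_val = lfc[lfc_cols].mean(axis=1)
    keep = ~guide_val.isna()
    n_dropped_guides = int((~keep).sum())
    work = pd.DataFrame({"gene": lfc.loc[keep, "gene"], "val": guide_val[keep]})
    if work.empty:
        raise ValueError("no guides with finite LFC")

    agg = work.groupby("gene")["val"]
    score = agg.mean() if aggregate == "mean" else agg.median()
    sizes = agg.size()
    dropped_genes = set(lfc["gene"].unique()) - set(score.index)
    if n_dropped_guides or dropped_genes:
        logger.warning(
            "%d guides excluded; %d gene(s) dropped with no surviving guides",
            n_dropped_guides, len(dropped_genes),
        )

    rng = np.random.default_rng(seed)
    pool = work["val"].to_numpy()
    pvals = pd.Series(index=score.index, dtype=float)
    for k, genes_k in sizes.groupby(sizes).groups.items():
        draws = rng.choice(pool, size=(n_perm, int(k)), replace=True)
        null = draws.mean(axis=1) if aggregate == "mean" else np.median(draws, axis=1)
        null_abs = np.sort(np.abs(null))
        obs = np.abs(score.loc[genes_k].to_numpy())
        # b = number of null scores at least as extreme (two-sided)
        b = len(null_abs) - np.searchsorted(null_abs, obs, side="left")
        pvals.loc[genes_k] = (b + 1) / (n_perm + 1)
    fdr = multipletests(pvals.to_numpy(), method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": score.index,
            "lfc": score.to_numpy(),
            "p": pvals.to_numpy(),
            "fdr": fdr,
            "n_guides": sizes.to_numpy(),
        }
    ).reset_index(drop=True)


def essential_gene_calls(
    result: pd.DataFrame, fdr_cutoff: float = 0.05, lfc_cutoff: float = -2.0
) -> pd.DataFrame:
    """Dropout (essential) calls at the default FDR < 0.05 and LFC < -2."""
    hit = (result["fdr"] < fdr_cutoff) & (result["lfc"] < lfc_cutoff)
    out = result.copy()
    out["essential"] = hit
    return out


def epistasis_profile(
    aneuploid: pd.DataFrame,
    diploid: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene differential essentiality between aneuploid and diploid screens.

    Inputs are guide-LFC tables (one per group layout: guide metadata plus one
    LFC column per clone/replicate).  The profile is, per gene,
    ``delta_lfc = mean aneuploid gene score - mean diploid gene score``;
    negative values mean more essential in the aneuploid clones.  With at
    least two clones per group the p-value comes from permuting clone labels;
    otherwise guide-level LFC values are permuted between the two groups
    within each gene.  BH FDR across genes.
    """
    a_cols = [c for c in aneuploid.columns if c not in META_COLS]
    d_cols = [c for c in diploid.columns if c not in META_COLS]
    if not a_cols or not d_cols:
        raise ValueError("each group needs at least one LFC column")

    a_gene = aneuploid.groupby("gene")[a_cols].mean()
    d_gene = diploid.groupby("gene")[d_cols].mean()
    shared = a_gene.index.intersection(d_gene.index)
    if shared.empty:
        raise ValueError("aneuploid and diploid screens share no genes")
    a_gene = a_gene.loc[shared]
    d_gene = d_gene.loc[shared]
    delta = a_gene.mean(axis=1) - d_gene.mean(axis=1)

    rng = np.random.default_rng(seed)
    a_clones = sorted({c.rsplit("_r", 1)[0] for c in a_cols})
    d_clones = sorted({c.rsplit("_r", 1)[0] for c in d_cols})
    if len(a_clones) >= 2 and len(d_clones) >= 2:
        # permute clone labels across groups
        clone_scores = {}
        for clone in a_clones:
            cols = [c for c in a_cols if c.rsplit("_r", 1)[0] == clone]
            clone_scores[clone] = a_gene[cols].mean(axis=1)
        for clone in d_clones:
            cols = [c for c in d_cols if c.rsplit("_r", 1)[0] == clone]
            clone_scores[clone] = d_gene[cols].mean(axis=1)
        all_clones = a_clones + d_clones
        mat = np.column_stack([clone_scores[c].to_numpy() for c in all_clones])
        n_a = len(a_clones)
        b = np.zeros(len(shared))
        obs = np.abs(delta.to_numpy())
        for _ in range(n_perm):
            perm = rng.permutation(mat.shape[1])
            d_perm = mat[:, perm[:n_a]].mean(axis=1) - mat[:, perm[n_a:]].mean(axis=1)
            b += np.abs(d_perm) >= obs
        pvals = (b + 1) / (n_perm + 1)
    else:
        # guide-level permutation within each gene
        a_guides = aneuploid.assign(val=aneuploid[a_cols].mean(axis=1))[["gene", "val"]]
        d_guides = diploid.assign(val=diploid[d_cols].mean(axis=1))[["gene", "val"]]
        pvals = np.ones(len(shared))
        obs = delta.to_numpy()
        a_by_gene = {g: grp["val"].to_numpy() for g, grp in a_guides.groupby("gene")}
        d_by_gene = {g: grp["val"].to_numpy() for g, grp in d_guides.groupby("gene")}
        for i, g in enumerate(shared):
            av = a_by_gene.get(g, np.array([]))
            dv = d_by_gene.get(g, np.array([]))
            av = av[~np.isnan(av)]
            dv = dv[~np.isnan(dv)]
            if len(av) == 0 or len(dv) == 0:
                pvals[i] = np.nan
                continue
            pooled = np.concatenate([av, dv])
            n_a = len(av)
            idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
            perm_a = pooled[idx[:, :n_a]].mean(axis=1)
            perm_d = pooled[idx[:, n_a:]].mean(axis=1)
            b = np.sum(np.abs(perm_a - perm_d) >= abs(obs[i]))
            pvals[i] = (b + 1) / (n_perm + 1)

    ok = ~np.isnan(pvals)
    fdr = np.full(len(pvals), np.nan)
    if ok.any():
        fdr[ok] = multipletests(np.asarray(pvals)[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": shared, "delta_lfc": delta.to_numpy(), "p": pvals, "fdr": fdr}
    ).reset_index(drop=True)
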