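"""Feature normalization and association with aneuploidy burden.

Metabolite abundances (or DepMap-style gene-effect scores) are normalized —
per cell, or per ploidy relative to the 46-chromosome diploid baseline — and
regressed feature-by-feature on a per-sample burden score with ordinary least
squares.  Coefficients, two-sided p-values and BH FDR come back in a table
directly rankable for preranked GSEA.  Ratio metrics (labeled::unlabeled UTP,
GSH::GSSG, ATP::AMP) and the mitochondrial copy-number estimate from
coverage ratios live here too.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_abundance",
    "ratio_metrics",
    "associate_with_burden",
    "mito_copy_estimate",
    "DIPLOID_CHROMOSOME_COUNT",
]

DIPLOID_CHROMOSOME_COUNT = 46


def normalize_abundance(
    values,
    mode: str,
    chromosome_count=None,
    cell_count=None,
):
    """Normalize abundances per cell or per total chromosomal content.

    ``per_cell`` divides by ``cell_count``; ``per_ploidy`` divides by
    ``chromosome_count / 46`` so a 92-chromosome (4N) sample is halved
    relative to the diploid baseline.  Scalar or array input.
    """
    values = np.asarray(values, dtype=float)
    if mode == "per_cell":
        if cell_count is None:
            raise ValueError("per_cell normalization requires cell_count")
        cell_count = np.asarray(cell_count, dtype=float)
        if np.any(cell_count <= 0):
            raise ValueError("cell_count must be positive")
        out = values / cell_count
    elif mode == "per_ploidy":
        if chromosome_count is None:
            raise ValueError("per_ploidy normalization requires chromosome_count")
        chromosome_count = np.asarray(chromosome_count, dtype=float)
        if np.any(chromosome_count < 1):
            raise ValueError("chromosome_count must be >= 1")
        out = values / (chromosome_count / DIPLOID_CHROMOSOME_COUNT)
    else:
        raise ValueError("mode must be 'per_cell' or 'per_ploidy'")
    if out.ndim == 0:
        return float(out)
    return out


def ratio_metrics(numerator, denominator):
    """Simple abundance ratio (labeled::unlabeled, GSH::GSSG, ATP::AMP).

    Zero or negative denominators yield NaN with a warning rather than a
    fabricated value.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    bad = den <= 0
    if np.any(bad):
        logger.warning("%d ratio(s) undefined (nonpositive denominator); NaN reported", int(np.sum(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    if out.ndim == 0:
        return float(out)
    return out


def associate_with_burden(
    features: pd.DataFrame,
    burden: pd.Series,
    log_transform: bool = False,
    clamp_coef: float | None = None,
) -> pd.DataFrame:
    """OLS slope of every feature on the per-sample burden score.

    Parameters
    ----------
    features
        samples x features matrix; its index must match ``burden``'s.
    burden
        Per-sample burden (net gain - loss).  Must vary.
    log_transform
        Apply log2(x + 1) to features before fitting (off by default).
    clamp_coef
        Optional symmetric cap on the reported coefficient (display clamp
        only; p-values are computed on the unclamped fit).

    Returns
    -------
    DataFrame with feature, coefficient, p, fdr, n, sorted by input order.
    """
    burden = pd.Series(burden, dtype=float)
    common = features.index.intersection(burden.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples with both feature and burden values")
    X = burden.loc[common].to_numpy()
    if np.allclose(X, X[0]):
        raise ValueError("burden has zero variance; slope unidentifiable")
    mat = features.loc[common]
    if log_transform:
        mat = np.log2(mat + 1)

    rows = []
    for feat in mat.columns:
        y = mat[feat].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < 3:
            rows.append({"feature": feat, "coefficient": np.nan, "p": np.nan, "n": n})
            continue
        res = stats.linregress(X[ok], y[ok])
        slope, p = res.slope, res.pvalue
        if np.isnan(p):  # constant feature: slope 0, no evidence
            slope, p = 0.0, 1.0
        rows.append({"feature": feat, "coefficient": float(slope), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    ok = ~out["p"].isna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    if clamp_coef is not None:
        out["coefficient"] = out["coefficient"].clip(-abs(clamp_coef), abs(clamp_coef))
    return out


def mito_copy_estimate(
    mean_mt_coverage: float,
    mean_autosomal_coverage: float,
    nuclear_ploidy: float = 2.0,
) -> float:
    """Mitochondrial genome copies per cell from sequencing coverage.

    ``copies = nuclear_ploidy * mt_coverage / autosomal_coverage`` — an
    autosomal locus is present at ``nuclear_ploidy`` copies, so the coverage
    ratio scales directly to mtDNA copy number.
    """
    if mean_mt_coverage <= 0 or mean_autosomal_coverage <= 0:
        raise ValueError("coverages must be positive")
    if nuclear_ploidy <= 0:
        raise ValueError("nuclear_ploidy must be positive")
    return float(nuclear_ploidy * mean_mt_coverage / mean_autosomal_coverage)
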