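"""Aneuploidy burden scoring from segments, gene-level copy number, or expression.

The burden statistic is the genomic material gained minus lost per sample:
arm-level gain/loss calls are made from purity-corrected segment means
(gain above +0.32, loss below -0.41, with at least half the arm affected),
and the score is megabases affected by gains minus megabases affected by
losses.  A positive net value classifies the sample as net-gain, negative as
net-loss.  Gene-level copy-number matrices on the log2(ratio + 1) scale use
the 1.16 / 0.8 cutoffs and count genes instead of megabases.  Expression
matrices are converted to copy-number calls by reference normalization and
moving-average smoothing along the genome, with gain/loss cutoffs at
1.02 / 0.98 of baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "purity_correct",
    "call_arm_events",
    "aneuploidy_burden",
    "gene_level_burden",
    "infer_cna_from_expression",
]


@dataclass(frozen=True)
class Thresholds:
    """Gain/loss cutoffs for each input scheme.

    Defaults are the study's published values: purity-corrected segment-mean
    cutoffs +0.32 / -0.41 with >=50% of the arm affected; gene-level
    log2(copy ratio + 1) cutoffs 1.16 / 0.8; reference-normalized expression
    cutoffs 1.02 / 0.98.
    """

    arm_gain_log2: float = 0.32
    arm_loss_log2: float = -0.41
    min_arm_fraction: float = 0.5
    gene_gain_l2cn1: float = 1.16
    gene_loss_l2cn1: float = 0.8
    expr_gain: float = 1.02
    expr_loss: float = 0.98

    def __post_init__(self):
        if self.arm_gain_log2 <= self.arm_loss_log2:
            raise ValueError("arm gain cutoff must exceed loss cutoff")
        if self.gene_gain_l2cn1 <= self.gene_loss_l2cn1:
            raise ValueError("gene-level gain cutoff must exceed loss cutoff")
        if self.expr_gain <= self.expr_loss:
            raise ValueError("expression gain cutoff must exceed loss cutoff")
        if not 0 < self.min_arm_fraction <= 1:
            raise ValueError("min_arm_fraction must be in (0, 1]")


def purity_correct(log2_ratio, purity):
    """De-mix observed log2 copy ratios for tumor purity.

    The observed linear copy ratio is a mixture
    ``R = purity * R_tumor + (1 - purity) * 1``; solving for the tumor
    component gives ``R_tumor = (R - (1 - purity)) / purity`` and the
    corrected value is its log2.  Scalar or array input.  Segments whose
    implied tumor ratio is nonpositive cannot be corrected and come back as
    NaN with a warning.
    """
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must be in (0, 1]")
    mixed = np.power(2.0, log2_ratio)
    tumor = (mixed - (1.0 - purity)) / purity
    bad = tumor <= 0
    if np.any(bad):
        logger.warning(
            "%d segment(s) uncorrectable (implied tumor ratio <= 0); set to NaN",
            int(np.sum(bad)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(bad, np.nan, np.log2(np.where(bad, 1.0, tumor)))
    if corrected.ndim == 0:
        return float(corrected)
    return corrected


def _overlap_bp(seg_start, seg_end, arm_start, arm_end):
    """Overlap in bp between 1-based inclusive intervals (vectorized)."""
    lo = np.maximum(seg_start, arm_start)
    hi = np.minimum(seg_end, arm_end)
    return np.maximum(hi - lo + 1, 0)


def call_arm_events(
    segments: pd.DataFrame,
    arms: GenomeModel,
    th: Thresholds | None = None,
    apply_purity_correction: bool = True,
) -> pd.DataFrame:
    """Arm-level gain/loss/neutral calls per sample.

    An arm is called gained when the megabases of that arm covered by
    segments whose (purity-corrected) log2 ratio exceeds the gain cutoff
    reach at least ``min_arm_fraction`` of the arm's length; losses are
    symmetric.  If both directions qualify the larger affected span wins
    (exact tie -> neutral).  Segments outside every arm are skipped with a
    warning.

    Parameters
    ----------
    segments
        Columns sample, chrom, start_bp, end_bp, log2_ratio and optionally
        purity (default 1).
    apply_purity_correction
        When True (default) and a purity column is present, segment means are
        de-mixed with :func:`purity_correct` before thresholding.

    Returns
    -------
    DataFrame with columns sample, arm_id, call, gain_mb, loss_mb,
    affected_mb, arm_fraction, arm_length_mb.
    """
    if th is None:
        th = Thresholds()
    seg = segments.copy()
    seg["chrom"] = seg["chrom"].map(normalize_chrom)
    if "purity" not in seg.columns:
        seg["purity"] = 1.0
    seg["purity"] = seg["purity"].fillna(1.0)
    if apply_purity_correction:
        seg["corrected"] = purity_correct(seg["log2_ratio"].to_numpy(), seg["purity"].to_numpy())
    else:
        seg["corrected"] = seg["log2_ratio"].astype(float)
    n_nan = int(seg["corrected"].isna().sum())
    if n_nan:
        seg = seg.dropna(subset=["corrected"])

    arm_df = arms.arms
    rows = []
    for sample, sub in seg.groupby("sample", sort=True):
        sub = sub.reset_index(drop=True)
        chrom_arr = sub["chrom"].to_numpy()
        corr = sub["corrected"].to_numpy()
        overlapped = np.zeros(len(sub), dtype=bool)
        for _, arm_row in arm_df.iterrows():
            mask = chrom_arr == arm_row["chrom"]
            ov = np.zeros(len(sub))
            if mask.any():
                ov[mask] = _overlap_bp(
                    sub.loc[mask, "start_bp"].to_numpy(),
                    sub.loc[mask, "end_bp"].to_numpy(),
                    arm_row["start_bp"],
                    arm_row["end_bp"],
                )
            overlapped |= ov > 0
            arm_len_bp = arm_row["end_bp"] - arm_row["start_bp"] + 1
            gain_bp = float(np.sum(ov * (corr > th.arm_gain_log2)))
            loss_bp = float(np.sum(ov * (corr < th.arm_loss_log2)))
            gain_frac = gain_bp / arm_len_bp
            loss_frac = loss_bp / arm_len_bp
            call = "neutral"
            affected_bp = 0.0
            if gain_frac >= th.min_arm_fraction and loss_frac >= th.min_arm_fraction:
                if gain_bp > loss_bp:
                    call, affected_bp = "gain", gain_bp
                elif loss_bp > gain_bp:
                    call, affected_bp = "loss", loss_bp
            elif gain_frac >= th.min_arm_fraction:
                call, affected_bp = "gain", gain_bp
            elif loss_frac >= th.min_arm_fraction:
                call, affected_bp = "loss", loss_bp
            rows.append(
                {
                    "sample": sample,
                    "arm_id": arm_row["arm_id"],
                    "call": call,
                    "gain_mb": gain_bp / 1e6,
                    "loss_mb": loss_bp / 1e6,
                    "affected_mb": affected_bp / 1e6,
                    "arm_fraction": affected_bp / arm_len_bp,
                    "arm_length_mb": arm_len_bp / 1e6,
                }
            )
        n_out = int((~overlapped).sum())
        if n_out:
            logger.warning("sample %s: %d segment(s) outside every arm; skipped", sample, n_out)
    return pd.DataFrame(rows)


def aneuploidy_burden(
    calls: pd.DataFrame,
    weighting: str = "segment",
) -> pd.DataFrame:
    """Gain/loss/net megabases and net-gain class per sample from arm calls.

    ``weighting="segment"`` (default) sums the megabases actually affected on
    called arms; ``weighting="arm"`` counts each called arm's full length.
    net_mb > 0 -> net_gain, < 0 -> net_loss, == 0 -> balanced.
    """
    if weighting not in ("segment", "arm"):
        raise ValueError("weighting must be 'segment' or 'arm'")
    if calls.empty:
        logger.warning("empty call table; zero burden reported")
        return pd.DataFrame(columns=["sample", "gain_mb", "loss_mb", "net_mb", "class"])
    rows = []
    for sample, sub in calls.groupby("sample", sort=True):
        if weighting == "arm":
            gain = float(sub.loc[sub["call"] == "gain", "arm_length_mb"].sum())
            loss = float(sub.loc[sub["call"] == "loss", "arm_length_mb"].sum())
        else:
            gain = float(sub.loc[sub["call"] == "gain", "affected_mb"].sum())
            loss = float(sub.loc[sub["call"] == "loss", "affected_mb"].sum())
        net = gain - loss
        cls = "net_gain" if net > 0 else ("net_loss" if net < 0 else "balanced")
        rows.append({"sample": sample, "gain_mb": gain, "loss_mb": loss, "net_mb": net, "class": cls})
    return pd.DataFrame(rows)


def gene_level_burden(
    gene_cn: pd.DataFrame,
    th: Thresholds | None = None,
    gene_lengths_mb: pd.Series | None = None,
) -> pd.DataFrame:
    """Net gain - loss from a gene-level copy-number matrix.

    Input values are on the log2(copy ratio + 1) scale, where diploid neutral
    is exactly 1.0 (log2(1 + 1)).  Genes above the 1.16 cutoff count as
    gained, below 0.8 as lost; net is the gained-minus-lost gene count per
    sample (or megabases when ``gene_lengths_mb`` is provided).

    Parameters
    ----------
    gene_cn
        genes x samples matrix of log2(copy ratio + 1) values.
    """
    if th is None:
        th = Thresholds()
    med = float(np.nanmedian(gene_cn.to_numpy(dtype=float)))
    if not 0.5 <= med <= 1.5:
        logger.warning(
            "gene-level CN median %.3f outside [0.5, 1.5]; input may not be on the "
            "log2(copy ratio + 1) scale",
            med,
        )
    vals = gene_cn.to_numpy(dtype=float)
    gained = vals > th.gene_gain_l2cn1
    lost = vals < th.gene_loss_l2cn1
    if gene_lengths_mb is not None:
        w = pd.Series(gene_lengths_mb).reindex(gene_cn.index).to_numpy(dtype=float)[:, None]
        gain = np.nansum(gained * w, axis=0)
        loss = np.nansum(lost * w, axis=0)
        unit = "mb"
    else:
        gain = gained.sum(axis=0).astype(float)
        loss = lost.sum(axis=0).astype(float)
        unit = "genes"
    net = gain - loss
    cls = np.where(net > 0, "net_gain", np.where(net < 0, "net_loss", "balanced"))
    return pd.DataFrame(
        {
            "sample": gene_cn.columns,
            f"gain_{unit}": gain,
            f"loss_{unit}": loss,
            f"net_{unit}": net,
            "class": cls,
        }
    )


def infer_cna_from_expression(
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    reference: list[str],
    window: int = 101,
    th: Thresholds | None = None,
    gene_lengths_mb: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Copy-number calls and burden inferred from bulk expression.

    Per gene, expression is normalized to the reference-sample mean, smoothed
    by a centered moving average of ``window`` genes along each chromosome in
    genomic order, and re-centered so each sample's genome-wide median is 1
    ("modified expression").  Genes above/below the expression cutoffs are
    called gained/lost, and gain - loss is summed per tumor sample (gene
    count, or megabases when lengths are given).

    Parameters
    ----------
    expr
        genes x samples matrix of nonnegative expression values.
    genes
        Gene metadata with columns gene, chrom, pos giving genomic order.
    reference
        Names of normal reference samples (non-empty, disjoint from tumors).
    window
        Moving-average width in genes; forced odd; shrunk (with a warning)
        on chromosomes with fewer genes.

    Returns
    -------
    (modified_expr, calls, burden)
        modified expression matrix (genes x samples, tumors only), long-form
        call table, and per-sample burden table.
    """
    if th is None:
        th = Thresholds()
    if not reference:
        raise ValueError("reference sample set must be non-empty")
    missing = set(reference) - set(expr.columns)
    if missing:
        raise ValueError(f"reference samples not in matrix: {sorted(missing)}")
    tumors = [c for c in expr.columns if c not in set(reference)]
    if not tumors:
        raise ValueError("no tumor samples left after removing references")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1

    meta = genes.set_index("gene").loc[expr.index]
    order = meta.sort_values(["chrom", "pos"], key=lambda s: s.map(normalize_chrom) if s.name == "chrom" else s).index
    expr_o = expr.loc[order]
    meta_o = meta.loc[order]

    ref_mean = expr_o[list(reference)].mean(axis=1)
    zero_ref = ref_mean <= 0
    if zero_ref.any():
        logger.warning("%d gene(s) with nonpositive reference mean dropped", int(zero_ref.sum()))
        expr_o = expr_o.loc[~zero_ref]
        meta_o = meta_o.loc[~zero_ref]
        ref_mean = ref_mean.loc[~zero_ref]

    rel = expr_o[tumors].div(ref_mean, axis=0)

    smoothed = pd.DataFrame(index=rel.index, columns=tumors, dtype=float)
    for chrom, idx in meta_o.groupby("chrom", sort=False).groups.items():
        w = min(window, len(idx))
        if w % 2 == 0:
            w -= 1
        if w < window:
            logger.warning("chromosome %s has %d genes; window shrunk to %d", chrom, len(idx), w)
        block = rel.loc[idx]
        smoothed.loc[idx] = block.rolling(w, center=True, min_periods=1).mean()

    med = smoothed.median(axis=0)
    modified = smoothed.div(med, axis=1)

    vals = modified.to_numpy(dtype=float)
    gained = vals > th.expr_gain
    lost = vals < th.expr_loss
    calls = pd.DataFrame(
        {
            "gene": np.tile(modified.index, len(tumors)),
            "sample": np.repeat(tumors, len(modified)),
            "modified_expression": vals.T.ravel(),
            "call": np.where(gained.T.ravel(), "gain", np.where(lost.T.ravel(), "loss", "neutral")),
        }
    )
    if gene_lengths_mb is not None:
        w_mb = pd.Series(gene_lengths_mb).reindex(modified.index).to_numpy(dtype=float)[:, None]
        gain = np.nansum(gained * w_mb, axis=0)
        loss = np.nansum(lost * w_mb, axis=0)
        unit = "mb"
    else:
        gain = gained.sum(axis=0).astype(float)
        loss = lost.sum(axis=0).astype(float)
        unit = "genes"
    net = gain - loss
    burden = pd.DataFrame(
        {
            "sample": tumors,
            f"gain_{unit}": gain,
            f"loss_{unit}": loss,
            f"net_{unit}": net,
            "class": np.where(net > 0, "net_gain", np.where(net < 0, "net_loss", "balanced")),
        }
    )
    return modified, calls, burden
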