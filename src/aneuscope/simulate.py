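"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline (burden scoring, screen analysis,
burden association, survival stratification) is exercised on data produced
here.  Each generator plants a known signal — arm-level copy-number events
mixed with tumor purity, essential genes depleted in a guide screen with an
arm-positional dropout bias, features linearly coupled to burden, dosage
scaling of expression on gained arms, or a two-arm survival cohort with a
chosen hazard ratio — and returns the emitted table together with a
:class:`SimTruth` record that exactly parameterizes it.  Identical seed and
parameters give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import GenomeModel, toy_genome

__all__ = [
    "SimTruth",
    "simulate_segments",
    "simulate_screen",
    "simulate_feature_matrix",
    "simulate_survival_cohort",
    "simulate_expression_cna",
    "ExpressionSim",
]


@dataclass
class SimTruth:
    """Ground truth behind a simulated dataset.

    Only the fields relevant to the generator that produced it are filled.
    """

    seed: int
    arm_events: dict[str, list[tuple[str, str]]] | None = None
    essential_genes: list[str] | None = None
    feature_slopes: dict[str, float] | None = None
    true_hr: float | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _check_direction(direction: str) -> int:
    if direction == "gain":
        return 1
    if direction == "loss":
        return -1
    raise ValueError(f"event direction must be 'gain' or 'loss', got {direction!r}")


def simulate_segments(
    genome: GenomeModel | None = None,
    events: dict[str, list[tuple[str, str]]] | None = None,
    purity: float | dict[str, float] = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    segments_per_arm: int = 2,
    event_fraction: float = 1.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Emit a SEG-style segment table with planted arm-level events.

    Each planted event changes the tumor copy number on one arm by a single
    copy (gain: 2 -> 3, loss: 2 -> 1).  The observed segment mean is the log2
    of the purity-weighted mixture of tumor and normal copy ratio, plus
    Gaussian noise in log2 units.  Mixing is done on the linear copy-ratio
    scale before taking log2, matching physical DNA mixing.

    Parameters
    ----------
    genome
        Arm model; defaults to the built-in ten-arm toy genome.
    events
        Mapping sample -> list of ``(arm_id, "gain"|"loss")``.
    purity
        Tumor-cell fraction in (0, 1], scalar or per-sample mapping.
    noise_sd
        Standard deviation of Gaussian noise added to segment means (log2).
    segments_per_arm
        Number of equal segments each arm is split into.
    event_fraction
        Fraction of the arm (from its start) covered by the planted event.

    Returns
    -------
    (segments, truth)
        ``segments`` has columns sample, chrom, start_bp, end_bp,
        log2_ratio, purity.
    """
    if genome is None:
        genome = toy_genome()
    if events is None:
        events = {}
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < event_fraction <= 1:
        raise ValueError("event_fraction must be in (0, 1]")
    if segments_per_arm < 1:
        raise ValueError("segments_per_arm must be >= 1")

    samples = sorted(events) or ["sample1"]
    purities = {s: (purity[s] if isinstance(purity, dict) else purity) for s in samples}
    for s, p in purities.items():
        if not 0 < p <= 1:
            raise ValueError(f"purity for {s} must be in (0, 1], got {p}")
    known = set(genome.arm_ids)
    for s, evs in events.items():
        for arm, direction in evs:
            _check_direction(direction)
            if arm not in known:
                raise ValueError(f"event on arm {arm!r} (sample {s}) not in genome model")

    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        p = purities[s]
        delta = {}  # arm -> copy change in tumor
        for arm, direction in events.get(s, []):
            delta[arm] = delta.get(arm, 0) + _check_direction(direction)
        for _, arm_row in genome.arms.iterrows():
            arm_id = arm_row["arm_id"]
            bounds = np.linspace(arm_row["start_bp"] - 1, arm_row["end_bp"], segments_per_arm + 1)
            event_end = arm_row["start_bp"] - 1 + event_fraction * (
                arm_row["end_bp"] - arm_row["start_bp"] + 1
            )
            for i in range(segments_per_arm):
                start = int(bounds[i]) + 1
                end = int(bounds[i + 1])
                # segment carries the event iff its midpoint lies in the event span
                mid = (start + end) / 2
                d = delta.get(arm_id, 0) if mid <= event_end else 0
                tumor_ratio = (2 + d) / 2
                mixed = p * tumor_ratio + (1 - p) * 1.0
                log2r = float(np.log2(mixed))
                if noise_sd > 0:
                    log2r += float(rng.normal(0.0, noise_sd))
                rows.append((s, arm_row["chrom"], start, end, log2r, p))
    seg = pd.DataFrame(
        rows, columns=["sample", "chrom", "start_bp", "end_bp", "log2_ratio", "purity"]
    )
    truth = SimTruth(
        seed=seed,
        arm_events={s: [tuple(e) for e in evs] for s, evs in events.items()},
        params={
            "purity": purities,
            "noise_sd": noise_sd,
            "segments_per_arm": segments_per_arm,
            "event_fraction": event_fraction,
        },
    )
    return seg, truth


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2.

    dispersion == 0 reduces to Poisson.
    """
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen(
    n_genes: int = 2000,
    guides_per_gene: int = 5,
    depth: float = 500.0,
    essential_fraction: float = 0.05,
    essential_lfc: float = -2.0,
    cn_bias: dict[str, float] | dict[str, dict[str, float]] | None = None,
    clones: tuple[str, ...] = ("clone1",),
    replicates: int = 1,
    dispersion: float = 0.1,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate PD0/PD6 guide counts for one or more clone screens.

    Genes are laid out along the genome in contiguous blocks proportional to
    arm length; each gene gets ``guides_per_gene`` guides at its locus.  PD0
    counts are negative binomial around a common depth modulated by per-guide
    lognormal abundance.  A planted-essential gene's PD6 expectation is shifted
    by ``essential_lfc`` log2 units; guides on arms listed in ``cn_bias`` carry
    an additional additive log2 shift (the chromosomal-location dropout bias).

    Parameters
    ----------
    cn_bias
        Either ``{arm_id: lfc_shift}`` applied to every clone, or
        ``{clone: {arm_id: lfc_shift}}``.

    Returns
    -------
    (counts, truth)
        ``counts`` columns: guide, gene, chrom, pos, then one count column
        per ``(clone, timepoint, replicate)`` named ``{clone}_PD{0,6}_r{i}``.
    """
    if n_genes < 1 or guides_per_gene < 1:
        raise ValueError("n_genes and guides_per_gene must be >= 1")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if not 0 <= essential_fraction <= 1:
        raise ValueError("essential_fraction must be in [0, 1]")
    if genome is None:
        genome = toy_genome()

    rng = np.random.default_rng(seed)
    n_guides = n_genes * guides_per_gene

    # gene layout: contiguous blocks per arm, proportional to arm length
    arms = genome.arms
    lengths = (arms["end_bp"] - arms["start_bp"] + 1).to_numpy(dtype=float)
    quota = np.floor(lengths / lengths.sum() * n_genes).astype(int)
    while quota.sum() < n_genes:
        quota[np.argmax(lengths / (quota + 1))] += 1
    gene_arm, gene_chrom, gene_pos = [], [], []
    for (_, arm_row), k in zip(arms.iterrows(), quota):
        if k == 0:
            continue
        pos = np.linspace(arm_row["start_bp"], arm_row["end_bp"], k + 2)[1:-1]
        gene_arm.extend([arm_row["arm_id"]] * k)
        gene_chrom.extend([arm_row["chrom"]] * k)
        gene_pos.extend(pos.astype(np.int64))
    gene_names = [f"GENE{i:05d}" for i in range(n_genes)]

    n_ess = int(round(essential_fraction * n_genes))
    ess_idx = rng.choice(n_genes, size=n_ess, replace=False) if n_ess else np.array([], int)
    ess_mask = np.zeros(n_genes, bool)
    ess_mask[ess_idx] = True

    guide_gene_idx = np.repeat(np.arange(n_genes), guides_per_gene)
    base_abund = rng.lognormal(mean=0.0, sigma=0.25, size=n_guides)
    pd0_mean = depth * base_abund / base_abund.mean()

    if cn_bias is None:
        cn_bias = {}
    per_clone_bias: dict[str, dict[str, float]] = {}
    if cn_bias and all(isinstance(v, dict) for v in cn_bias.values()):
        per_clone_bias = {c: dict(cn_bias.get(c, {})) for c in clones}  # type: ignore[arg-type]
    else:
        per_clone_bias = {c: dict(cn_bias) for c in clones}  # type: ignore[arg-type]
    known = set(genome.arm_ids)
    for c, shifts in per_clone_bias.items():
        unknown = set(shifts) - known
        if unknown:
            raise ValueError(f"cn_bias arms not in genome model (clone {c}): {sorted(unknown)}")

    guide_arm = np.asarray(gene_arm)[guide_gene_idx]
    true_lfc = np.where(ess_mask[guide_gene_idx], essential_lfc, 0.0)

    counts = pd.DataFrame(
        {
            "guide": [f"{gene_names[g]}_g{i % guides_per_gene + 1}" for i, g in enumerate(guide_gene_idx)],
            "gene": np.asarray(gene_names)[guide_gene_idx],
            "chrom": np.asarray(gene_chrom)[guide_gene_idx],
            "pos": np.asarray(gene_pos)[guide_gene_idx],
        }
    )
    for clone in clones:
        shifts = per_clone_bias.get(clone, {})
        bias = np.array([shifts.get(a, 0.0) for a in guide_arm])
        pd6_mean = pd0_mean * np.power(2.0, true_lfc + bias)
        for r in range(1, replicates + 1):
            counts[f"{clone}_PD0_r{r}"] = _nb_counts(rng, pd0_mean, dispersion)
            counts[f"{clone}_PD6_r{r}"] = _nb_counts(rng, pd6_mean, dispersion)

    truth = SimTruth(
        seed=seed,
        essential_genes=[gene_names[i] for i in sorted(ess_idx)],
        params={
            "n_genes": n_genes,
            "guides_per_gene": guides_per_gene,
            "depth": depth,
            "essential_lfc": essential_lfc,
            "cn_bias": per_clone_bias,
            "clones": list(clones),
            "replicates": replicates,
            "dispersion": dispersion,
        },
    )
    return counts, truth


def simulate_feature_matrix(
    burden: pd.Series,
    slopes: dict[str, float] | pd.Series,
    noise_sd: float = 0.1,
    intercepts: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Features linearly coupled to a per-sample burden score.

    ``feature_j = intercept_j + slope_j * burden + N(0, noise_sd)``.

    Returns a samples x features DataFrame indexed like ``burden``.
    """
    burden = pd.Series(burden)
    if len(burden) < 3:
        raise ValueError("need at least 3 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    slopes = pd.Series(slopes, dtype=float)
    if intercepts is not None and set(intercepts) != set(slopes.index):
        raise ValueError("intercepts must cover exactly the features in slopes")
    rng = np.random.default_rng(seed)
    data = {}
    for feat, slope in slopes.items():
        b0 = intercepts[feat] if intercepts else 0.0
        vals = b0 + slope * burden.to_numpy(dtype=float)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(burden))
        data[feat] = vals
    mat = pd.DataFrame(data, index=burden.index)
    truth = SimTruth(
        seed=seed,
        feature_slopes={str(k): float(v) for k, v in slopes.items()},
        params={"noise_sd": noise_sd, "n_samples": len(burden)},
    )
    return mat, truth


def simulate_survival_cohort(
    n: int,
    true_hr: float = 1.0,
    baseline_5yr_survival: float = 0.95,
    censor_horizon_years: float = 5.0,
    random_censor_frac: float = 0.0,
    group_labels: tuple[str, str] = ("baseline", "exposed"),
    two_groups: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-arm survival cohort with exponential event times.

    The baseline hazard is calibrated so that true 5-year survival of the
    baseline group equals ``baseline_5yr_survival``; the second group's hazard
    is ``true_hr`` times the baseline.  Follow-up is administratively censored
    at ``censor_horizon_years``.  With ``random_censor_frac > 0`` that fraction
    of subjects additionally draws a uniform random censoring time before the
    horizon (applied whether or not it precedes the event).

    Returns a DataFrame with columns patient, group, time, event.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if true_hr <= 0:
        raise ValueError("true_hr must be > 0")
    if not 0 < baseline_5yr_survival < 1:
        raise ValueError("baseline_5yr_survival must be in (0, 1)")
    if censor_horizon_years <= 0:
        raise ValueError("censor_horizon_years must be > 0")
    if not 0 <= random_censor_frac < 1:
        raise ValueError("random_censor_frac must be in [0, 1)")

    rng = np.random.default_rng(seed)
    lam0 = -np.log(baseline_5yr_survival) / 5.0
    if two_groups:
        half = n // 2
        groups = np.array([group_labels[0]] * half + [group_labels[1]] * (n - half))
        lam = np.where(groups == group_labels[0], lam0, lam0 * true_hr)
    else:
        groups = np.array([group_labels[0]] * n)
        lam = np.full(n, lam0)
    t_event = rng.exponential(1.0 / lam)
    t_cens = np.full(n, censor_horizon_years)
    if random_censor_frac > 0:
        who = rng.random(n) < random_censor_frac
        t_cens = np.where(who, rng.uniform(0.0, censor_horizon_years, n), t_cens)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against zero times (lifelines requires time > 0)
    time = np.maximum(time, 1e-9)
    cohort = pd.DataFrame(
        {
            "patient": [f"P{i:05d}" for i in range(n)],
            "group": groups,
            "time": time,
            "event": event,
        }
    )
    truth = SimTruth(
        seed=seed,
        true_hr=float(true_hr),
        params={
            "baseline_5yr_survival": baseline_5yr_survival,
            "baseline_hazard": float(lam0),
            "censor_horizon_years": censor_horizon_years,
            "random_censor_frac": random_censor_frac,
            "n": n,
            "two_groups": two_groups,
        },
    )
    return cohort, truth


class ExpressionSim(NamedTuple):
    expr: pd.DataFrame  # genes x samples
    genes: pd.DataFrame  # gene, chrom, pos (genomic order)
    truth: SimTruth


def simulate_expression_cna(
    genome: GenomeModel | None = None,
    events: dict[str, list[tuple[str, str]]] | None = None,
    dosage_effect: float = 1.5,
    reference_n: int = 5,
    n_genes: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionSim:
    """Expression matrix whose gained arms carry a dosage signal.

    Reference (normal) samples express every gene at a lognormal baseline;
    tumor samples scale genes on gained arms by ``dosage_effect`` and genes on
    lost arms by ``2 - dosage_effect`` (single-copy dosage symmetry around the
    diploid baseline).  Multiplicative lognormal noise with log-sd
    ``noise_sd`` is applied per gene per sample.
    """
    if dosage_effect <= 0:
        raise ValueError("dosage_effect must be > 0")
    if reference_n < 2:
        raise ValueError("need reference_n >= 2 reference samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if genome is None:
        genome = toy_genome()
    if events is None:
        events = {}
    known = set(genome.arm_ids)
    for s, evs in events.items():
        for arm, direction in evs:
            _check_direction(direction)
            if arm not in known:
                raise ValueError(f"event on arm {arm!r} (sample {s}) not in genome model")

    rng = np.random.default_rng(seed)
    arms = genome.arms
    lengths = (arms["end_bp"] - arms["start_bp"] + 1).to_numpy(dtype=float)
    quota = np.floor(lengths / lengths.sum() * n_genes).astype(int)
    while quota.sum() < n_genes:
        quota[np.argmax(lengths / (quota + 1))] += 1
    recs = []
    for (_, arm_row), k in zip(arms.iterrows(), quota):
        pos = np.linspace(arm_row["start_bp"], arm_row["end_bp"], k + 2)[1:-1]
        for p in pos:
            recs.append((arm_row["chrom"], int(p), arm_row["arm_id"]))
    genes = pd.DataFrame(recs, columns=["chrom", "pos", "arm_id"])
    genes.insert(0, "gene", [f"G{i:05d}" for i in range(len(genes))])

    base = rng.lognormal(mean=2.0, sigma=0.5, size=len(genes))
    tumors = sorted(events)
    refs = [f"REF{i:02d}" for i in range(reference_n)]
    loss_scale = max(2.0 - dosage_effect, 1e-6)

    cols = {}
    for s in refs:
        noise = rng.lognormal(0.0, noise_sd, len(genes)) if noise_sd > 0 else 1.0
        cols[s] = base * noise
    for s in tumors:
        scale = np.ones(len(genes))
        for arm, direction in events[s]:
            on_arm = (genes["arm_id"] == arm).to_numpy()
            scale[on_arm] *= dosage_effect if direction == "gain" else loss_scale
        noise = rng.lognormal(0.0, noise_sd, len(genes)) if noise_sd > 0 else 1.0
        cols[s] = base * scale * noise
    expr = pd.DataFrame(cols, index=genes["gene"])

    truth = SimTruth(
        seed=seed,
        arm_events={s: [tuple(e) for e in evs] for s, evs in events.items()},
        params={
            "dosage_effect": dosage_effect,
            "reference_samples": refs,
            "n_genes": n_genes,
            "noise_sd": noise_sd,
        },
    )
    return ExpressionSim(expr=expr, genes=genes.drop(columns="arm_id"), truth=truth)
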