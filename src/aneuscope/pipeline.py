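"""End-to-end pipeline: simulate -> score -> screen -> associate -> survive.

``run_pipeline`` drives every stage in dependency order on a synthetic bundle
(or user-supplied files where config paths are given), writing each stage's
tables as CSV with a JSON provenance sidecar (config hash + seed) and a final
machine-readable summary.  Reruns with the same config are bit-identical for
the deterministic stages and seed-reproducible for the stochastic ones.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cn, gsea, io, screen, simulate, survival
from .genome import toy_genome

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "aneuscope_out",
    # burden scoring
    "arm_gain_log2": 0.32,
    "arm_loss_log2": -0.41,
    "min_arm_fraction": 0.5,
    "weighting": "segment",
    # simulation sizes
    "n_samples": 12,
    "purity": 0.8,
    "seg_noise_sd": 0.03,
    "screen_n_genes": 500,
    "guides_per_gene": 5,
    "screen_depth": 500.0,
    "essential_fraction": 0.05,
    "cn_bias_shift": 0.5,
    # testing
    "n_perm": 1000,
    "feature_noise_sd": 0.5,
    "n_features": 50,
    # survival
    "survival_n": 1000,
    "true_hr": 2.67,
    "baseline_5yr_survival": 0.95,
    # optional input files (override simulation for that stage)
    "seg_path": None,
    "purity_path": None,
    "chemo_keywords": list(survival.CHEMO_KEYWORDS),
}


def _validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    for path_key in ("seg_path", "purity_path"):
        p = merged[path_key]
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path_key}: {p} does not exist")
    return merged


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    cfg = _validate_config(config or {})
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = toy_genome()
    th = cn.Thresholds(
        arm_gain_log2=cfg["arm_gain_log2"],
        arm_loss_log2=cfg["arm_loss_log2"],
        min_arm_fraction=cfg["min_arm_fraction"],
    )
    summary: dict = {"seed": seed, "config_hash": io.config_hash(cfg), "stages": {}}

    # --- stage 1: segments + burden scoring -------------------------------
    logger.info("[simulate] segment table")
    if cfg["seg_path"]:
        seg = io.read_seg(cfg["seg_path"])
        if cfg["purity_path"]:
            pur = io.read_purity(cfg["purity_path"])
            seg["purity"] = seg["sample"].map(pur).fillna(1.0)
    else:
        arm_ids = genome.arm_ids
        events = {}
        for i in range(int(cfg["n_samples"])):
            n_ev = int(rng.integers(1, 4))
            arms_i = rng.choice(arm_ids, size=n_ev, replace=False)
            dirs = rng.choice(["gain", "loss"], size=n_ev)
            events[f"S{i:03d}"] = list(zip(arms_i.tolist(), dirs.tolist()))
        seg, seg_truth = simulate.simulate_segments(
            genome, events, purity=cfg["purity"], noise_sd=cfg["seg_noise_sd"],
            seed=int(rng.integers(2**31)),
        )
        seg_truth.to_json(out / "segments_truth.json")
    io.write_seg(seg, out / "segments.seg")

    logger.info("[score-cn] arm calls and burden")
    calls = cn.call_arm_events(seg, genome, th)
    burden = cn.aneuploidy_burden(calls, weighting=cfg["weighting"])
    calls.to_csv(out / "arm_calls.csv", index=False)
    burden.to_csv(out / "burden.csv", index=False)
    summary["stages"]["score_cn"] = {
        "n_samples": int(burden.shape[0]),
        "n_net_gain": int((burden["class"] == "net_gain").sum()),
        "n_net_loss": int((burden["class"] == "net_loss").sum()),
    }

    # --- stage 2: screen ---------------------------------------------------
    logger.info("[screen] guide counts, bias correction, gene test")
    bias_arm = genome.arm_ids[0]
    counts, screen_truth = simulate.simulate_screen(
        n_genes=int(cfg["screen_n_genes"]),
        guides_per_gene=int(cfg["guides_per_gene"]),
        depth=cfg["screen_depth"],
        essential_fraction=cfg["essential_fraction"],
        cn_bias={bias_arm: cfg["cn_bias_shift"]},
        genome=genome,
        seed=int(rng.integers(2**31)),
    )
    screen_truth.to_json(out / "screen_truth.json")
    lfc, _ = screen.normalize_and_lfc(counts)
    corrected = screen.correct_cn_bias(
        lfc, genome, {"clone1": {bias_arm: "gain"}}
    )
    result = screen.gene_level_test(
        corrected, n_perm=int(cfg["n_perm"]), seed=int(rng.integers(2**31))
    )
    result = screen.essential_gene_calls(result)
    result.to_csv(out / "screen_gene_results.csv", index=False)
    planted = set(screen_truth.essential_genes)
    called = set(result.loc[result["essential"], "gene"])
    summary["stages"]["screen"] = {
        "n_genes": int(result.shape[0]),
        "n_essential_called": len(called),
        "recall_planted_essentials": (
            len(called & planted) / len(planted) if planted else None
        ),
    }

    # --- stage 3: GSEA on the screen ranking --------------------------------
    logger.info("[gsea] enrichment of planted-essential set")
    ranking = result.set_index("gene")["lfc"]
    sets = {"PLANTED_ESSENTIAL": planted} if planted else {}
    if sets:
        enr = gsea.preranked_gsea(
            ranking, sets, n_perm=min(int(cfg["n_perm"]), 500),
            max_size=max(len(planted), 5), seed=int(rng.integers(2**31)),
        )
        enr.to_csv(out / "gsea.csv", index=False)
        summary["stages"]["gsea"] = {
            "n_sets": int(enr.shape[0]),
            "min_p": float(enr["p"].min()) if len(enr) else None,
        }

    # --- stage 4: burden association ---------------------------------------
    logger.info("[assoc] features vs burden")
    b = burden.set_index("sample")["net_mb"]
    slopes = {f"feat{j:02d}": (0.01 if j < cfg["n_features"] // 2 else 0.0)
              for j in range(int(cfg["n_features"]))}
    feats, feat_truth = simulate.simulate_feature_matrix(
        b, slopes, noise_sd=cfg["feature_noise_sd"], seed=int(rng.integers(2**31))
    )
    feat_truth.to_json(out / "features_truth.json")
    assoc_res = assoc.associate_with_burden(feats, b)
    assoc_res.to_csv(out / "associations.csv", index=False)
    summary["stages"]["assoc"] = {
        "n_features": int(assoc_res.shape[0]),
        "n_fdr05": int((assoc_res["fdr"] < 0.05).sum()),
    }

    # --- stage 5: survival ---------------------------------------------------
    logger.info("[survival] stratified KM/Cox")
    cohort, surv_truth = simulate.simulate_survival_cohort(
        n=int(cfg["survival_n"]),
        true_hr=cfg["true_hr"],
        baseline_5yr_survival=cfg["baseline_5yr_survival"],
        group_labels=("net_gain", "net_loss"),
        seed=int(rng.integers(2**31)),
    )
    surv_truth.to_json(out / "survival_truth.json")
    cohort["burden_class"] = cohort["group"]
    cohort["treatment_class"] = "chemo"
    # non-chemo stratum with no burden effect
    nc, _ = simulate.simulate_survival_cohort(
        n=int(cfg["survival_n"]),
        true_hr=1.0,
        baseline_5yr_survival=cfg["baseline_5yr_survival"],
        group_labels=("net_gain", "net_loss"),
        seed=int(rng.integers(2**31)),
    )
    nc["burden_class"] = nc["group"]
    nc["treatment_class"] = "non_chemo"
    full = pd.concat([cohort, nc], ignore_index=True)
    full.to_csv(out / "cohort.csv", index=False)
    strat = survival.stratified_survival_analysis(full)
    surv_summary = {
        t: {"hr": fit.hr, "p": fit.p, "diverged": fit.diverged}
        for t, fit in strat["cox"].items()
    }
    surv_summary["survival_at_5y"] = {
        f"{t}|{b_}": s for (t, b_), s in strat["survival_at_horizon"].items()
    }
    summary["stages"]["survival"] = surv_summary

    io.write_provenance(out / "provenance.json", cfg, seed=seed)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
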