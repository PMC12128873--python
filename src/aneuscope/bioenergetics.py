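"""Extracellular-flux summary metrics (mitochondrial stress and glycolytic rate tests).

The mitochondrial stress test reads oxygen consumption rate (OCR) in four
phases — basal, after oligomycin (ATP-synthase block), after FCCP (uncoupler),
and after rotenone/antimycin A (full ETC block) — and derives ATP-linked,
maximal, spare, and nonmitochondrial respiration by phase subtraction.  The
glycolytic rate test reads proton efflux rate (PER) at basal, after
rotenone/antimycin A, and after 2-deoxyglucose; compensatory glycolysis is the
post-rot/AA PER minus the post-2-DG PER.  All metrics are divided by a
per-well protein normalization factor.  Negative derived metrics are reported
with a QC flag, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InjectionTrace",
    "BioenergeticMetrics",
    "phase_means",
    "mito_stress_metrics",
    "glycolytic_rate_metrics",
]

OCR_PHASES = ("basal", "post_oligomycin", "post_FCCP", "post_rotAA")
PER_PHASES = ("basal", "post_rotAA", "post_2DG")


@dataclass(frozen=True)
class InjectionTrace:
    """Phase means of one well's instrument trace.

    ``assay`` is "OCR" (mitochondrial stress test) or "PER" (glycolytic rate
    test); ``phases`` maps phase name to its mean measurement; ``protein`` is
    the per-well normalization factor.
    """

    assay: str
    phases: dict[str, float] = field(default_factory=dict)
    protein: float = 1.0

    def __post_init__(self):
        if self.assay not in ("OCR", "PER"):
            raise ValueError("assay must be 'OCR' or 'PER'")
        required = OCR_PHASES if self.assay == "OCR" else PER_PHASES
        missing = [p for p in required if p not in self.phases]
        if missing:
            raise ValueError(f"{self.assay} trace missing phase(s): {missing}")
        if any(v < 0 for v in self.phases.values()):
            raise ValueError("phase means must be >= 0")
        if self.protein <= 0:
            raise ValueError("protein normalization factor must be > 0")


@dataclass(frozen=True)
class BioenergeticMetrics:
    assay: str
    metrics: dict[str, float]
    qc_flags: tuple[str, ...] = ()


def phase_means(
    trace: pd.DataFrame, assay: str, last_n: int = 3, protein: float = 1.0
) -> InjectionTrace:
    """Collapse a long-format (phase, measurement, value) trace to phase means.

    The phase summary is the mean of the last ``last_n`` measurement cycles in
    each phase (or all of them, if fewer).
    """
    if last_n < 1:
        raise ValueError("last_n must be >= 1")
    means = {}
    for phase, grp in trace.groupby("phase"):
        vals = grp.sort_values("measurement")["value"].to_numpy(dtype=float)
        means[str(phase)] = float(vals[-last_n:].mean())
    return InjectionTrace(assay=assay, phases=means, protein=protein)


def mito_stress_metrics(trace: InjectionTrace) -> BioenergeticMetrics:
    """Mitochondrial stress test metrics from OCR phase means.

    nonmito = post_rotAA; basal_mito = basal - nonmito;
    atp_linked = basal - post_oligomycin; maximal = post_FCCP - nonmito;
    spare = maximal - basal_mito.  All divided by the protein factor.
    """
    if trace.assay != "OCR":
        raise ValueError("mito stress metrics require an OCR trace")
    p = trace.phases
    nonmito = p["post_rotAA"]
    basal_mito = p["basal"] - nonmito
    atp_linked = p["basal"] - p["post_oligomycin"]
    maximal = p["post_FCCP"] - nonmito
    spare = maximal - basal_mito
    raw = {
        "basal": p["basal"],
        "basal_mito": basal_mito,
        "atp_linked": atp_linked,
        "maximal": maximal,
        "spare": spare,
        "nonmito": nonmito,
    }
    flags = tuple(sorted(k for k, v in raw.items() if v < 0))
    metrics = {k: v / trace.protein for k, v in raw.items()}
    return BioenergeticMetrics(assay="OCR", metrics=metrics, qc_flags=flags)


def glycolytic_rate_metrics(trace: InjectionTrace) -> BioenergeticMetrics:
    """Glycolytic rate test metrics from PER phase means.

    basal_glycolysis = basal; compensatory = post_rotAA - post_2DG;
    blocked = post_2DG.  Protein-normalized; negatives flagged, not clipped.
    """
    if trace.assay != "PER":
        raise ValueError("glycolytic rate metrics require a PER trace")
    p = trace.phases
    raw = {
        "basal_glycolysis": p["basal"],
        "compensatory": p["post_rotAA"] - p["post_2DG"],
        "blocked": p["post_2DG"],
    }
    flags = tuple(sorted(k for k, v in raw.items() if v < 0))
    metrics = {k: v / trace.protein for k, v in raw.items()}
    return BioenergeticMetrics(assay="PER", metrics=metrics, qc_flags=flags)
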