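"""Burden-stratified survival analysis: treatment classification, KM, Cox.

Patients are classed as chemotherapy-treated when any of their drug-name
strings matches a keyword list of DNA-damaging/antifolate/antinucleotide
agents, stratified into net-gain vs net-loss aneuploidy by the burden score,
and compared with Kaplan-Meier curves and Cox proportional-hazards ratios
(Efron tie handling) within each treatment class.  Estimation is delegated to
lifelines; this module owns the stratification design, the keyword matcher,
and the reporting contracts (divergence on monotone likelihood, Greenwood
variance, right-continuous step evaluation).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)

__all__ = [
    "CHEMO_KEYWORDS",
    "classify_treatment",
    "KMCurve",
    "km_curve",
    "CoxFit",
    "cox_hr",
    "stratified_survival_analysis",
]

# Search strings identifying DNA-damaging, antifolate, and antinucleotide
# chemotherapies in free-text clinical drug fields.
CHEMO_KEYWORDS = (
    "platin",
    "dox",
    "uracil",
    "rubicin",
    "mycin",
    "phosphamid",
    "citabine",
    "cytoxan",
    "trexate",
    "ac",
    "capecetabine",
    "5-fu",
    "metotreksat",
    "mitoxantrone",
    "cytoxen",
    "gemzar",
    "tc",
    "tch",
    "xeloda",
)

# Codes matched as whole tokens rather than substrings: "ac" would otherwise
# fire inside "paclitaxel", "tc" inside "mitchell", etc.
_TOKEN_CODES = frozenset({"ac", "tc", "tch", "5-fu"})


def _tokens(s: str) -> list[str]:
    return [t for t in re.split(r"[\s,;/+()]+", s.lower().strip()) if t]


def classify_treatment(
    drug_strings,
    keywords=CHEMO_KEYWORDS,
    match_mode: str = "token_short",
) -> tuple[str, str | None]:
    """Classify a patient's drug list as chemo or non_chemo.

    Drug strings are lowercased and trimmed.  In the default ``token_short``
    mode, short codes ("ac", "tc", "tch", "5-fu") match only as whole tokens
    while the remaining keywords match as substrings; ``substring`` mode
    matches every keyword as a substring (the raw published search-string
    behaviour, which can false-positive on e.g. "paclitaxel" via "ac").

    Returns
    -------
    (class, annotation)
        class is "chemo" or "non_chemo"; annotation is "untreated" for an
        empty drug list, else None.
    """
    if match_mode not in ("token_short", "substring"):
        raise ValueError("match_mode must be 'token_short' or 'substring'")
    if isinstance(drug_strings, str):
        drug_strings = [drug_strings]
    drugs = [d.strip().lower() for d in drug_strings if str(d).strip()]
    if not drugs:
        return "non_chemo", "untreated"
    for d in drugs:
        toks = _tokens(d)
        for kw in keywords:
            kw_l = kw.lower()
            if match_mode == "token_short" and kw_l in _TOKEN_CODES:
                if kw_l in toks:
                    return "chemo", None
            elif kw_l in d:
                return "chemo", None
    return "non_chemo", None


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with Greenwood variance.

    ``times`` are the distinct observed event times (prepended with 0);
    ``survival`` the step values at those times; ``variance`` Greenwood's
    estimate of Var[S(t)] at each step.
    """

    times: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)
    n: int = 0
    n_events: int = 0

    def survival_at(self, t: float) -> float:
        """S(t) under the right-continuous step convention."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    If every observation is censored the curve is identically 1 and a warning
    is emitted.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValueError("need at least one subject")
    if not event.any():
        logger.warning("no events observed; survival curve identically 1")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    at_risk = table["at_risk"].to_numpy(dtype=float)
    observed = table["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    times = table.index.to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            (observed > 0) & (at_risk > observed),
            observed / (at_risk * (at_risk - observed)),
            np.where(observed > 0, np.nan, 0.0),
        )
    var = surv**2 * np.cumsum(terms)
    if times[0] != 0:
        times = np.insert(times, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        var = np.insert(var, 0, 0.0)
    return KMCurve(
        times=times,
        survival=surv,
        variance=var,
        n=len(time),
        n_events=int(event.sum()),
    )


@dataclass(frozen=True)
class CoxFit:
    """Two-group Cox proportional-hazards fit (Efron ties)."""

    coef: float
    hr: float
    se: float
    p: float
    n: int
    n_events: int
    reference: str
    comparison: str
    diverged: bool = False


def cox_hr(
    cohort: pd.DataFrame,
    group_col: str = "group",
    reference: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Hazard ratio of the non-reference group vs the reference group.

    Maximum partial likelihood with Efron tie handling, Wald p-value.  A
    monotone likelihood (one group with zero events while the other has
    events) is reported as a divergence (``diverged=True``, NaN estimates)
    rather than a number.
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    other = groups[0] if groups[1] == reference else groups[1]
    if cohort[event_col].sum() == 0:
        raise ValueError("no events in cohort; hazard ratio unidentifiable")

    events_by_group = cohort.groupby(group_col)[event_col].sum()
    n = len(cohort)
    n_events = int(cohort[event_col].sum())
    if (events_by_group == 0).any():
        logger.warning(
            "monotone partial likelihood (a group has zero events); reporting divergence"
        )
        return CoxFit(
            coef=np.nan, hr=np.nan, se=np.nan, p=np.nan,
            n=n, n_events=n_events, reference=reference, comparison=other, diverged=True,
        )

    df = pd.DataFrame(
        {
            "time": cohort[time_col].to_numpy(dtype=float),
            "event": cohort[event_col].to_numpy(dtype=int),
            "x": (cohort[group_col] == other).astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    return CoxFit(
        coef=coef,
        hr=float(np.exp(coef)),
        se=se,
        p=p,
        n=n,
        n_events=n_events,
        reference=reference,
        comparison=other,
    )


def stratified_survival_analysis(
    cohort: pd.DataFrame,
    horizon_years: float = 5.0,
    burden_col: str = "burden_class",
    treatment_col: str = "treatment_class",
    time_col: str = "time",
    event_col: str = "event",
) -> dict:
    """KM curves per (treatment x burden) stratum and per-treatment Cox HRs.

    Follow-up is administratively truncated at ``horizon_years`` before
    fitting.  Within each treatment class the Cox model compares net_loss
    against net_gain (HR > 1 means net-loss patients fare worse).  Missing
    strata yield a partial table with a warning; a missing burden class
    within a treatment class skips that treatment's HR.

    Returns
    -------
    dict with keys ``km`` (``{(treatment, burden): KMCurve}``), ``cox``
    (``{treatment: CoxFit}``), and ``survival_at_horizon``
    (``{(treatment, burden): float}``).
    """
    for col in (burden_col, treatment_col, time_col, event_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort missing column {col!r}")
    burden_classes = set(cohort[burden_col].unique())
    if not burden_classes & {"net_gain", "net_loss"}:
        raise ValueError("cohort has neither net_gain nor net_loss patients")

    df = cohort.copy()
    over = df[time_col] > horizon_years
    df.loc[over, event_col] = 0
    df.loc[over, time_col] = horizon_years

    km: dict[tuple[str, str], KMCurve] = {}
    s_at: dict[tuple[str, str], float] = {}
    expected = [(t, b) for t in ("chemo", "non_chemo") for b in ("net_gain", "net_loss")]
    for (t, b) in expected:
        sub = df[(df[treatment_col] == t) & (df[burden_col] == b)]
        if sub.empty:
            logger.warning("stratum (%s, %s) empty; partial table returned", t, b)
            continue
        curve = km_curve(sub[time_col], sub[event_col])
        km[(t, b)] = curve
        s_at[(t, b)] = curve.survival_at(horizon_years)

    cox: dict[str, CoxFit] = {}
    for t in ("chemo", "non_chemo"):
        sub = df[df[treatment_col] == t]
        present = set(sub[burden_col].unique())
        if not {"net_gain", "net_loss"} <= present:
            logger.warning("treatment class %s lacks both burden classes; Cox skipped", t)
            continue
        sub2 = sub[sub[burden_col].isin(["net_gain", "net_loss"])]
        cox[t] = cox_hr(sub2, group_col=burden_col, reference="net_gain",
                        time_col=time_col, event_col=event_col)
    return {"km": km, "cox": cox, "survival_at_horizon": s_at}
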