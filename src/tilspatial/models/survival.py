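"""Survival analysis: Kaplan-Meier estimation and the multivariate Cox
proportional-hazards model with the slope-group predictor.

Subjects are dichotomized at the cohort-median spatial-coupling slope
(HigherSlope vs LowerSlope; the split itself lives in
:mod:`tilspatial.models.subject`).  The Cox model adjusts the group effect
for treatment, sex, the age category (AgeCat: age >= 70 years = upper),
grade and stage; with LowerSlope as the reference, a hazard ratio below 1
for the HigherSlope group reads as protection.  Ties are handled with the
Efron approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times

logger = logging.getLogger(__name__)

AGECAT_CUTOFF_YEARS = 70.0


def make_agecat(age, cutoff: float = AGECAT_CUTOFF_YEARS):
    """Categorize age at the cohort-median cutoff; ``upper`` iff age >= cutoff."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr <= 0):
        raise ValueError("age must be positive")
    cat = np.where(age_arr >= cutoff, "upper", "lower")
    return cat.item() if np.isscalar(age) or age_arr.ndim == 0 else cat


@dataclass
class GroupCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float  # nan = not reached
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalFit:
    """Product-limit curves, one per group (single 'all' group when ungrouped)."""

    curves: dict[str, GroupCurve]

    @property
    def median(self) -> float:
        if len(self.curves) != 1:
            raise ValueError("overall median undefined for grouped fit")
        return next(iter(self.curves.values())).median

    def risk_table(self, times) -> pd.DataFrame:
        rows = []
        for label, c in self.curves.items():
            kmf_times = np.asarray(times, dtype=float)
            for t in kmf_times:
                at_risk = int(c.at_risk[np.searchsorted(c.times, t, side="right") - 1]) \
                    if np.any(c.times <= t) else c.n
                rows.append({"group": label, "time": t, "at_risk": at_risk,
                             "survival": c.survival_at(t)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        frames = []
        for label, c in self.curves.items():
            frames.append(pd.DataFrame({
                "group": label, "time": c.times, "at_risk": c.at_risk,
                "events": c.events, "survival": c.survival,
                "ci_lower": c.ci_lower, "ci_upper": c.ci_upper,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                    float_format="%.6f")


def _fit_one_group(df: pd.DataFrame, label: str) -> GroupCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    med = kmf.median_survival_time_
    med = float(med) if np.isfinite(med) else np.nan
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    event_table = kmf.event_table
    times = event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    conf = kmf.confidence_interval_
    return GroupCurve(
        label=label,
        times=times,
        survival=surv,
        ci_lower=conf.iloc[:, 0].to_numpy(),
        ci_upper=conf.iloc[:, 1].to_numpy(),
        at_risk=event_table["at_risk"].to_numpy(),
        events=event_table["observed"].to_numpy(),
        median=med,
        median_ci=(lo, hi),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def km_fit(table: pd.DataFrame, group_by: str | None = None) -> SurvivalFit:
    """Kaplan-Meier product-limit estimate, optionally per group.

    ``table`` needs ``time`` (days, > 0) and ``event`` (1 = death).  The
    median survival time and its 95% CI use the log-log-transformed
    pointwise interval; a curve that never crosses 0.5 reports the median
    as not reached (NaN).
    """
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not table["event"].isin((0, 1)).all():
        raise ValueError("event must be 0/1")
    curves: dict[str, GroupCurve] = {}
    if group_by is None:
        curves["all"] = _fit_one_group(table, "all")
    else:
        for label, sub in table.groupby(group_by, observed=True):
            curves[str(label)] = _fit_one_group(sub, str(label))
    return SurvivalFit(curves=curves)


_COX_FACTORS = {
    "slope_group": ("LowerSlope", "slope_group"),
    "treatment": ("naive", "treatment"),
    "sex": (None, "sex"),
    "agecat": ("lower", "agecat"),
    "grade": ("G1", "grade"),
    "stage": ("I", "stage"),
}


@dataclass
class CoxResults:
    """Per-term hazard ratios with 95% CIs and Wald p-values."""

    table: pd.DataFrame  # term, hr, lo, hi, p, coef, se
    n: int
    n_events: int
    loglike: float
    converged: bool
    collapsed_levels: dict = field(default_factory=dict)

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["lo"]), float(row["hi"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    @property
    def slope_group_term(self) -> str:
        return next(t for t in self.table["term"] if t.startswith("slope_group"))

    def forest_csv(self, path) -> None:
        self.table[["term", "hr", "lo", "hi", "p"]].to_csv(
            path, index=False, float_format="%.6g"
        )

    def summary(self) -> str:
        lines = [f"Cox PH (Efron ties): {self.n} subjects, {self.n_events} events"]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['term']:28s} HR {r['hr']:.2f} "
                f"[{r['lo']:.2f}, {r['hi']:.2f}]  p={r['p']:.3g}"
            )
        return "\n".join(lines)


class CoxModel:
    """Multivariate Cox PH model of survival on the slope-group label and
    clinical covariates.

    Age enters as the binary AgeCat (>= 70 = upper) by default, matching
    the forest-plot presentation; ``age_as_category=False`` uses linear
    age in years instead.  Factor levels with fewer than 2 events can be
    collapsed into the adjacent level with ``collapse_sparse=True``
    (logged), which guards against monotone-likelihood blowups in sparse
    strata such as stage IV.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        age_as_category: bool = True,
        agecat_cutoff: float = AGECAT_CUTOFF_YEARS,
        collapse_sparse: bool = False,
        terms: tuple[str, ...] = ("slope_group", "treatment", "sex", "agecat",
                                  "grade", "stage"),
    ):
        self.raw = table.copy()
        self.age_as_category = age_as_category
        self.agecat_cutoff = agecat_cutoff
        self.collapse_sparse = collapse_sparse
        self.terms = terms
        self.collapsed: dict[str, str] = {}

    _ADJACENT = {"stage": ["I", "II", "III", "IV"], "grade": ["G1", "G2", "G3"]}

    def _design(self) -> pd.DataFrame:
        df = self.raw.copy()
        if "agecat" in self.terms:
            if self.age_as_category:
                df["agecat"] = make_agecat(df["age"].to_numpy(), self.agecat_cutoff)
            else:
                df["agecat"] = df["age"].astype(float)
        if self.collapse_sparse:
            for col, order in self._ADJACENT.items():
                if col not in self.terms or col not in df.columns:
                    continue
                for lev in order[::-1]:
                    sub = df[df[col] == lev]
                    if len(sub) and sub["event"].sum() < 2 and lev != order[0]:
                        target = order[order.index(lev) - 1]
                        logger.info("collapsing sparse %s level %s into %s",
                                    col, lev, target)
                        df.loc[df[col] == lev, col] = target
                        self.collapsed[f"{col}:{lev}"] = target
        cols = {"time": df["time"].astype(float), "event": df["event"].astype(int)}
        for term in self.terms:
            if term == "agecat" and not self.age_as_category:
                cols["age_years"] = df["agecat"]
                continue
            ref, col = _COX_FACTORS[term]
            vals = df[col].astype(str)
            levels = sorted(vals.unique())
            if ref is None:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{term}[{lev}]"] = (vals == lev).astype(float)
        return pd.DataFrame(cols)

    def fit(self, penalizer: float = 0.0) -> CoxResults:
        """Partial-likelihood ML with Efron ties.

        On a monotone-likelihood failure (separation: some level's events
        all precede or follow the rest) the fit is retried with a small
        ridge penalty, Firth-style in spirit, and the retry is logged.
        """
        design = self._design()
        if design["event"].sum() < 1:
            raise ValueError("Cox model needs at least one event")
        converged = True
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            cph.fit(design, duration_col="time", event_col="event")
        except Exception as exc:  # noqa: BLE001 - separation / singular designs
            logger.warning("Cox fit failed (%s); retrying with ridge penalty", exc)
            converged = False
            cph = CoxPHFitter(penalizer=max(penalizer, 0.1))
            cph.fit(design, duration_col="time", event_col="event")
        s = cph.summary
        table = pd.DataFrame({
            "term": s.index,
            "coef": s["coef"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "lo": s["exp(coef) lower 95%"].to_numpy(),
            "hi": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }).reset_index(drop=True)
        return CoxResults(
            table=table,
            n=len(design),
            n_events=int(design["event"].sum()),
            loglike=float(cph.log_likelihood_),
            converged=converged,
            collapsed_levels=dict(self.collapsed),
        )
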