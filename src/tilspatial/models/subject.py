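"""Per-subject spatial-coupling statistic.

For one subject, CD8+ quadrat counts are regressed on cancer quadrat
counts in a negative-binomial GLM with log link,

    cd8_i ~ NB(mean = exp(alpha + beta * cancer_i), theta),

over active quadrats only.  The slope ``beta`` is the subject's spatial
correlation between the two cell populations: through the log link, an
increase of n cancer cells per quadrat multiplies the expected CD8+ count
by exp(n * beta) — the fold-change reading used throughout the cohort
analyses.  Dispersion theta (NB size) is estimated by maximum likelihood
jointly with the coefficients; when the data are equidispersed and the ML
estimate of 1/theta collapses to zero, the fit falls back to a Poisson GLM
and is flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from ..spatial import QuadratGrid

logger = logging.getLogger(__name__)

#: below this ML estimate of 1/theta the NB fit is treated as Poisson
_ALPHA_POISSON_EPS = 1e-4


@dataclass
class SubjectSlopeResults:
    """Fitted per-subject NB GLM: intercept, slope, dispersion, diagnostics."""

    subject_id: str
    intercept: float
    beta: float
    beta_se: float
    intercept_se: float
    theta: float  # NB size; inf when Poisson fallback used
    n_quadrats: int
    converged: bool
    family_used: str  # "negbin" | "poisson"
    loglike: float

    def fold_change(self, n: float) -> float:
        return fold_change(self.beta, n)

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return self.beta - z * self.beta_se, self.beta + z * self.beta_se

    def summary(self) -> str:
        lines = [
            f"Subject {self.subject_id}: NB GLM of CD8+ on cancer quadrat counts",
            f"  quadrats used (active): {self.n_quadrats}",
            f"  intercept  {self.intercept:+.4f} (SE {self.intercept_se:.4f})",
            f"  slope beta {self.beta:+.4f} (SE {self.beta_se:.4f})",
            f"  dispersion theta {self.theta:.3g}  family {self.family_used}",
            f"  fold change per 10 cancer cells: {self.fold_change(10):.2f}",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)


class SubjectSlopeModel:
    """NB-GLM model of one subject's CD8+ vs cancer quadrat counts.

    Build from a :class:`~tilspatial.spatial.QuadratGrid` (active quadrats
    are selected automatically) or from raw paired count vectors.
    """

    def __init__(
        self,
        cancer_counts: np.ndarray,
        cd8_counts: np.ndarray,
        subject_id: str = "",
    ):
        self.cancer = np.asarray(cancer_counts, dtype=float).ravel()
        self.cd8 = np.asarray(cd8_counts, dtype=float).ravel()
        if self.cancer.shape != self.cd8.shape:
            raise ValueError("count vectors must have equal length")
        if len(self.cancer) < 2:
            raise ValueError("need at least 2 quadrats to fit a slope")
        if np.ptp(self.cancer) == 0:
            raise ValueError(
                f"degenerate design: constant cancer counts for subject {subject_id!r}"
            )
        self.subject_id = subject_id

    @classmethod
    def from_grid(cls, grid: QuadratGrid) -> "SubjectSlopeModel":
        cancer, cd8 = grid.active_counts()
        return cls(cancer, cd8, subject_id=grid.subject_id)

    def _design(self) -> np.ndarray:
        return np.column_stack([np.ones_like(self.cancer), self.cancer])

    def _fit_poisson(self) -> tuple[np.ndarray, np.ndarray, float, bool]:
        mod = sm.GLM(self.cd8, self._design(), family=sm.families.Poisson())
        res = mod.fit()
        return res.params, res.bse, float(res.llf), True

    def fit(self, maxiter: int = 200) -> SubjectSlopeResults:
        """Joint ML fit of (intercept, slope, dispersion).

        Uses an NB2 likelihood (variance = m + m^2/theta).  Falls back to a
        Poisson GLM when the estimated overdispersion is negligible or the
        NB optimizer fails; ``family_used`` records which likelihood
        produced the reported estimates.
        """
        family = "negbin"
        converged = True
        theta = np.inf
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = NegativeBinomial(self.cd8, self._design(), loglike_method="nb2")
                res = mod.fit(disp=0, maxiter=maxiter)
            alpha_hat = float(res.params[-1])
            if not res.mle_retvals.get("converged", False) or alpha_hat < _ALPHA_POISSON_EPS:
                raise RuntimeError("NB dispersion degenerate or not converged")
            params, bse = res.params[:2], res.bse[:2]
            llf = float(res.llf)
            theta = 1.0 / alpha_hat
            if not np.all(np.isfinite(bse)):
                raise RuntimeError("non-finite NB standard errors")
        except Exception as exc:  # noqa: BLE001 - any NB failure routes to Poisson
            logger.debug("subject %s: NB fit fell back to Poisson (%s)",
                         self.subject_id, exc)
            family = "poisson"
            try:
                params, bse, llf, converged = self._fit_poisson()
            except Exception:
                return SubjectSlopeResults(
                    subject_id=self.subject_id,
                    intercept=np.nan, beta=np.nan, beta_se=np.nan,
                    intercept_se=np.nan, theta=np.nan,
                    n_quadrats=len(self.cancer),
                    converged=False, family_used="none", loglike=np.nan,
                )
            theta = np.inf
        return SubjectSlopeResults(
            subject_id=self.subject_id,
            intercept=float(params[0]),
            beta=float(params[1]),
            beta_se=float(bse[1]),
            intercept_se=float(bse[0]),
            theta=float(theta),
            n_quadrats=len(self.cancer),
            converged=bool(converged),
            family_used=family,
            loglike=llf,
        )


def fold_change(beta: float, n: float) -> float:
    """Expected multiplicative change in CD8+ count per ``n``-cell increase
    in cancer count: exp(n * beta).  Rounding (2 decimals) is left to the
    presentation layer."""
    return float(np.exp(n * beta))


def cohort_slope_table(
    results: list[SubjectSlopeResults],
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-subject slope fits to clinical covariates.

    One row per converged subject with columns ``beta, beta_se, theta,
    n_quadrats, converged, family_used`` plus all clinical fields.
    Non-converged fits are dropped (and logged); a slope subject missing
    from the clinical table is an error.
    """
    rows = []
    for r in results:
        if not r.converged:
            logger.warning("subject %s: fit not converged, excluded from cohort table",
                           r.subject_id)
            continue
        rows.append(
            {
                "subject_id": r.subject_id,
                "beta": r.beta,
                "beta_se": r.beta_se,
                "theta": r.theta,
                "n_quadrats": r.n_quadrats,
                "converged": r.converged,
                "family_used": r.family_used,
            }
        )
    slopes = pd.DataFrame(rows)
    if slopes.empty:
        raise ValueError("no converged subject fits")
    clinical = clinical.copy()
    clinical["subject_id"] = clinical["subject_id"].astype(str)
    unmatched = set(slopes["subject_id"]) - set(clinical["subject_id"])
    if unmatched:
        raise ValueError(f"subjects missing from clinical table: {sorted(unmatched)}")
    return slopes.merge(clinical, on="subject_id", how="left")


def arm_medians(table: pd.DataFrame) -> dict[str, float]:
    """Median slope per treatment arm; empty arms are reported absent."""
    out: dict[str, float] = {}
    for arm in ("naive", "NAT"):
        betas = table.loc[table["treatment"] == arm, "beta"]
        if betas.empty:
            logger.warning("treatment arm %s is empty; no median reported", arm)
            continue
        out[arm] = float(betas.median())
    return out


def median_split(table: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize subjects at the whole-cohort median slope.

    Adds ``slope_group`` (``HigherSlope`` iff beta >= cohort median, else
    ``LowerSlope``) and ``cohort_median_beta`` columns.  With the >= rule,
    all-tied cohorts land entirely in HigherSlope.
    """
    if len(table) < 2:
        raise ValueError("median split needs at least 2 subjects")
    med = float(table["beta"].median())
    out = table.copy()
    out["cohort_median_beta"] = med
    out["slope_group"] = np.where(out["beta"] >= med, "HigherSlope", "LowerSlope")
    return out
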