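"""Cohort-level contrasts between neoadjuvant-treated (NAT) and
treatment-naive subjects.

Three models operate on cohort-level summaries or pooled quadrat data:

* :class:`LogSlopeModel` — ordinary least squares on log(beta) with
  treatment, sex, age, grade and stage; the treatment coefficient is the
  log-ratio of typical slopes between arms.
* :class:`HeterogeneityModel` — OLS of the subject's quadrat-wise SD of
  cancer counts (an intratumoral-heterogeneity proxy) on the same
  covariates.
* :class:`NegativeBinomialMixedModel` — a negative-binomial GLMM over all
  subjects' active quadrats, with fixed effects for cancer count,
  treatment and their interaction, and a subject-level random intercept:

      cd8_ij ~ NB(exp(b0 + bc*cancer_ij + bt*NAT_j + bx*cancer_ij*NAT_j + u_j), theta),
      u_j ~ N(0, sigma^2).

  The marginal likelihood integrates u_j out per subject; the integral is
  approximated by a Laplace approximation (default) or adaptive
  Gauss-Hermite quadrature (verification mode).  exp(100*bc) is the
  naive-arm fold change of CD8+ cells per 100 extra cancer cells,
  exp(100*(bc+bx)) the NAT-arm one, and exp(100*bx) their ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_FACTOR_REFERENCES = {
    "treatment": "naive",
    "sex": None,
    "grade": "G1",
    "stage": "I",
}


def _build_formula(dep: str, data: pd.DataFrame) -> tuple[str, list[str]]:
    """Assemble the covariate formula, dropping single-level factors.

    Reference levels (naive, G1, stage I) are used when present in the
    data; otherwise patsy's default (first level) applies.
    """
    terms, dropped = [], []
    for col, ref in _FACTOR_REFERENCES.items():
        if data[col].nunique() < 2:
            dropped.append(col)
            logger.warning("covariate %r has a single level; dropped from model", col)
            continue
        if ref is not None and ref in set(data[col].astype(str)):
            terms.append(f"C({col}, Treatment('{ref}'))")
        else:
            terms.append(f"C({col})")
    terms.append("age")
    return f"{dep} ~ " + " + ".join(terms), dropped


def _check_rank(res) -> None:
    X = res.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = res.model.exog_names
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); aliased terms among {names}"
        )


@dataclass
class LogSlopeResults:
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    n_used: int
    excluded_nonpositive: list[str]
    dropped_covariates: list[str]
    treatment_term: str

    @property
    def treatment_coef(self) -> float:
        return float(self.params[self.treatment_term])

    @property
    def treatment_pvalue(self) -> float:
        return float(self.pvalues[self.treatment_term])

    @property
    def slope_ratio(self) -> float:
        """Implied multiplicative NAT/naive ratio of slope coefficients."""
        return float(np.exp(self.treatment_coef))

    def summary(self) -> str:
        lines = ["OLS of log(slope) on treatment + covariates",
                 f"  n used: {self.n_used}"
                 + (f" (excluded beta<=0: {self.excluded_nonpositive})"
                    if self.excluded_nonpositive else "")]
        for name in self.params.index:
            lines.append(f"  {name:48s} {self.params[name]:+.4f}"
                         f"  p={self.pvalues[name]:.4g}")
        lines.append(f"  implied NAT/naive slope ratio: {self.slope_ratio:.2f}")
        return "\n".join(lines)


class LogSlopeModel:
    """OLS on log-transformed subject slopes.

    The slope distribution is right-skewed, so slopes are log-transformed
    before the linear model.  Slopes <= 0 have no log; the default policy
    excludes those subjects (their ids are reported on the results);
    ``policy="shift"`` instead uses log(beta + shift) for a sensitivity
    analysis.
    """

    def __init__(self, table: pd.DataFrame, policy: str = "exclude",
                 shift: float = 0.01):
        if policy not in ("exclude", "shift"):
            raise ValueError("policy must be 'exclude' or 'shift'")
        self.table = table
        self.policy = policy
        self.shift = shift

    def fit(self) -> LogSlopeResults:
        df = self.table.copy()
        if self.policy == "exclude":
            bad = df["beta"] <= 0
            excluded = sorted(df.loc[bad, "subject_id"].astype(str))
            if excluded:
                logger.info("log-slope model: excluded non-positive slopes for %s",
                            excluded)
            df = df[~bad].copy()
            df["log_beta"] = np.log(df["beta"])
        else:
            excluded = []
            df["log_beta"] = np.log(df["beta"] + self.shift)
        for arm in ("naive", "NAT"):
            if (df["treatment"] == arm).sum() < 2:
                raise ValueError(f"need >=2 subjects with positive slope in arm {arm}")
        formula, dropped = _build_formula("log_beta", df)
        res = smf.ols(formula, data=df).fit()
        _check_rank(res)
        treat_term = next(n for n in res.params.index if n.startswith("C(treatment"))
        return LogSlopeResults(
            params=res.params, pvalues=res.pvalues, bse=res.bse,
            n_used=int(res.nobs), excluded_nonpositive=excluded,
            dropped_covariates=dropped, treatment_term=treat_term,
        )


@dataclass
class HeterogeneityResults:
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    n_used: int
    dropped_covariates: list[str]
    treatment_term: str

    @property
    def treatment_effect(self) -> float:
        """Adjusted NAT-vs-naive difference in quadrat-wise cancer-count SD
        (counts per quadrat; negative = NAT less heterogeneous)."""
        return float(self.params[self.treatment_term])

    @property
    def treatment_pvalue(self) -> float:
        return float(self.pvalues[self.treatment_term])


class HeterogeneityModel:
    """OLS of per-subject quadrat-wise cancer-count SD on treatment and
    clinical covariates (sex, age, grade, stage)."""

    def __init__(self, table: pd.DataFrame):
        # table: one row per subject with quadrat_sd_cancer + covariates
        self.table = table

    @classmethod
    def from_summaries(cls, summaries, clinical: pd.DataFrame) -> "HeterogeneityModel":
        rows = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "quadrat_sd_cancer": s.quadrat_sd_cancer,
                    "quadrat_mean_cancer": s.quadrat_mean_cancer,
                    "quadrat_sd_cd8": s.quadrat_sd_cd8,
                    "quadrat_mean_cd8": s.quadrat_mean_cd8,
                }
                for s in summaries
            ]
        )
        clinical = clinical.copy()
        clinical["subject_id"] = clinical["subject_id"].astype(str)
        return cls(rows.merge(clinical, on="subject_id", how="inner"))

    def fit(self) -> HeterogeneityResults:
        df = self.table
        for arm in ("naive", "NAT"):
            if (df["treatment"] == arm).sum() < 2:
                raise ValueError(f"need >=2 subjects in arm {arm}")
        formula, dropped = _build_formula("quadrat_sd_cancer", df)
        res = smf.ols(formula, data=df).fit()
        _check_rank(res)
        treat_term = next(n for n in res.params.index if n.startswith("C(treatment"))
        return HeterogeneityResults(
            params=res.params, pvalues=res.pvalues, bse=res.bse,
            n_used=int(res.nobs), dropped_covariates=dropped,
            treatment_term=treat_term,
        )


# ---------------------------------------------------------------------------
# Negative-binomial GLMM with subject random intercepts
# ---------------------------------------------------------------------------

_FIXED_NAMES = ("intercept", "cancer", "treatment", "cancer_x_treatment")


def _nb_loglik_terms(y: np.ndarray, eta: np.ndarray, theta: float) -> np.ndarray:
    """Pointwise NB2 log-pmf with mean exp(eta) and size theta."""
    mu = np.exp(eta)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta)
        + y * eta
        - (y + theta) * np.log(theta + mu)
    )


@dataclass
class MixedModelResults:
    """Fitted NB GLMM: fixed effects, dispersion, random-intercept SD."""

    fe_params: pd.Series  # intercept, cancer, treatment, cancer_x_treatment
    fe_bse: pd.Series
    fe_pvalues: pd.Series
    theta: float
    sigma_u: float
    loglike: float
    converged: bool
    method: str
    n_obs: int
    n_subjects: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def beta_cancer(self) -> float:
        return float(self.fe_params["cancer"])

    @property
    def beta_interaction(self) -> float:
        return float(self.fe_params["cancer_x_treatment"])

    def fold_changes(self, n: float = 100.0) -> dict[str, float]:
        """Fold change of expected CD8+ count per n extra cancer cells,
        by arm, plus the NAT/naive ratio of fold changes."""
        fc_naive = float(np.exp(n * self.beta_cancer))
        fc_nat = float(np.exp(n * (self.beta_cancer + self.beta_interaction)))
        return {"naive": fc_naive, "NAT": fc_nat, "ratio": fc_nat / fc_naive}

    def summary(self) -> str:
        lines = [
            f"NB GLMM ({self.method}): CD8+ count ~ cancer * treatment + (1 | subject)",
            f"  n quadrats {self.n_obs}, subjects {self.n_subjects}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"  {name:20s} {self.fe_params[name]:+.5f}"
                f" (SE {self.fe_bse[name]:.5f}, p={self.fe_pvalues[name]:.3g})"
            )
        lines.append(f"  theta {self.theta:.3f}   random-intercept SD {self.sigma_u:.3f}")
        fc = self.fold_changes(100)
        lines.append(
            f"  fold change per 100 cancer cells: naive {fc['naive']:.2f},"
            f" NAT {fc['NAT']:.2f}, ratio {fc['ratio']:.2f}"
        )
        lines.append(f"  log-likelihood {self.loglike:.2f}  converged {self.converged}")
        return "\n".join(lines)


class NegativeBinomialMixedModel:
    """NB GLMM over pooled active quadrats with subject random intercepts.

    Parameters
    ----------
    data
        Long DataFrame with one row per active quadrat, columns
        ``subject_id``, ``cd8`` (response count), ``cancer`` (count),
        ``treatment`` (``naive``/``NAT``).
    """

    def __init__(self, data: pd.DataFrame):
        needed = {"subject_id", "cd8", "cancer", "treatment"}
        if not needed <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(needed)}")
        df = data.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        self.subjects = df["subject_id"].drop_duplicates().to_numpy()
        arms = df.groupby("subject_id")["treatment"].first()
        for arm in ("naive", "NAT"):
            if (arms == arm).sum() < 2:
                raise ValueError(f"need >=2 subjects in arm {arm}")
        self.y = df["cd8"].to_numpy(dtype=float)
        nat = (df["treatment"] == "NAT").to_numpy(dtype=float)
        cancer = df["cancer"].to_numpy(dtype=float)
        self.X = np.column_stack(
            [np.ones(len(df)), cancer, nat, cancer * nat]
        )
        if len(self.y) < 10 * (self.X.shape[1] + 2):
            raise ValueError("too few pooled quadrats for the number of parameters")
        codes = pd.Categorical(df["subject_id"], categories=self.subjects).codes
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.y = self.y[order]
        self.X = self.X[order]
        codes = codes[order]
        self._bounds = np.searchsorted(codes, np.arange(len(self.subjects) + 1))

    # -- per-subject inner optimisation ------------------------------------

    def _subject_slices(self):
        for j in range(len(self.subjects)):
            yield slice(self._bounds[j], self._bounds[j + 1])

    @staticmethod
    def _inner_mode(y, c, theta, sigma2, u0=0.0, tol=1e-10, maxiter=50):
        """Newton maximisation of the joint log-density over the random
        intercept u for one subject; c = X@beta is the fixed linear part.
        The objective is strictly concave in u."""
        u = u0
        for _ in range(maxiter):
            mu = np.exp(c + u)
            frac = (y + theta) * mu / (theta + mu)
            grad = np.sum(y - frac) - u / sigma2
            hess = -np.sum((y + theta) * theta * mu / (theta + mu) ** 2) - 1.0 / sigma2
            step = grad / hess
            u_new = u - step
            # safeguarded: halve until the joint density does not decrease
            f_old = np.sum(_nb_loglik_terms(y, c + u, theta)) - u**2 / (2 * sigma2)
            for _ in range(30):
                f_new = np.sum(_nb_loglik_terms(y, c + u_new, theta)) - u_new**2 / (2 * sigma2)
                if f_new >= f_old - 1e-12:
                    break
                u_new = (u + u_new) / 2
            if abs(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        mu = np.exp(c + u)
        neg_hess = np.sum((y + theta) * theta * mu / (theta + mu) ** 2) + 1.0 / sigma2
        return u, neg_hess

    def _marginal_loglike(self, params: np.ndarray, method: str, nodes: int) -> float:
        beta = params[:4]
        theta = np.exp(params[4])
        sigma = np.exp(params[5])
        sigma2 = sigma**2
        eta_fixed = self.X @ beta
        total = 0.0
        if method == "agq":
            z, w = np.polynomial.hermite.hermgauss(nodes)
        for sl in self._subject_slices():
            y, c = self.y[sl], eta_fixed[sl]
            u_hat, neg_hess = self._inner_mode(y, c, theta, sigma2)
            g_hat = (
                np.sum(_nb_loglik_terms(y, c + u_hat, theta))
                - u_hat**2 / (2 * sigma2)
                - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            )
            if method == "laplace":
                total += g_hat + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(neg_hess)
            else:
                s = 1.0 / np.sqrt(neg_hess)
                uk = u_hat + np.sqrt(2.0) * s * z
                gk = (
                    np.array([np.sum(_nb_loglik_terms(y, c + u, theta)) for u in uk])
                    - uk**2 / (2 * sigma2)
                    - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                )
                # log-sum-exp of sqrt(2)*s * sum_k w_k exp(g_k + z_k^2)
                lg = gk + z**2 + np.log(w)
                m = np.max(lg)
                total += m + np.log(np.sum(np.exp(lg - m))) + 0.5 * np.log(2.0) + np.log(s)
        return total

    def _start_values(self) -> np.ndarray:
        from statsmodels.discrete.discrete_model import NegativeBinomial

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = NegativeBinomial(self.y, self.X, loglike_method="nb2").fit(disp=0)
                beta0 = res.params[:4]
                alpha = max(float(res.params[-1]), 1e-3)
                ltheta = -np.log(alpha)
            except Exception:
                res = sm.GLM(self.y, self.X, family=sm.families.Poisson()).fit()
                beta0 = res.params
                ltheta = np.log(2.0)
        return np.concatenate([beta0, [ltheta, np.log(0.3)]])

    def fit(
        self,
        method: str = "laplace",
        agq_nodes: int = 7,
        maxiter: int = 300,
        n_restarts: int = 3,
        seed: int = 0,
        track_iterations: bool = False,
    ) -> MixedModelResults:
        """Maximise the marginal likelihood.

        ``method`` is ``"laplace"`` (default) or ``"agq"`` (adaptive
        Gauss-Hermite with ``agq_nodes`` nodes, used as a verification
        mode).  On failure the optimiser restarts from jittered start
        values (seeded).  Standard errors come from the numerically
        differentiated Hessian of the marginal log-likelihood.
        """
        if method not in ("laplace", "agq"):
            raise ValueError("method must be 'laplace' or 'agq'")
        if method == "agq" and agq_nodes < 5:
            raise ValueError("use >=5 quadrature nodes")
        nll_evals: list[float] = []

        def nll(p):
            val = -self._marginal_loglike(p, method, agq_nodes)
            if not np.isfinite(val):
                val = 1e12
            nll_evals.append(val)
            return val

        rng = np.random.default_rng(seed)
        x0 = self._start_values()
        bounds = [(None, None)] * 4 + [(np.log(1e-3), np.log(1e4)),
                                       (np.log(1e-4), np.log(10.0))]
        iter_logliks: list[float] = []
        callback = None
        if track_iterations:
            callback = lambda xk: iter_logliks.append(-nll(xk))  # noqa: E731
        best = None
        for attempt in range(n_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.2, size=6)
            if track_iterations:
                iter_logliks.append(-nll(start))
            res = optimize.minimize(
                nll, start, method="L-BFGS-B", bounds=bounds, callback=callback,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        converged = bool(best.success)
        p = best.x
        H = _numerical_hessian(nll, p)
        diagnostics = {
            "grad_norm": float(np.linalg.norm(best.jac)) if best.jac is not None else np.nan,
            "optimizer_message": str(best.message),
            "n_restarts_used": attempt,
        }
        if track_iterations:
            diagnostics["iteration_loglikes"] = iter_logliks
        try:
            cov = np.linalg.inv(H)
            diagnostics["hessian_condition"] = float(np.linalg.cond(H))
            se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            converged = False
            se_all = np.full(6, np.nan)
            diagnostics["hessian_condition"] = np.inf
        if not converged:
            logger.warning("NB GLMM did not fully converge: %s", diagnostics)
        fe = pd.Series(p[:4], index=_FIXED_NAMES)
        fe_se = pd.Series(se_all[:4], index=_FIXED_NAMES)
        zvals = fe / fe_se
        pvals = pd.Series(2 * stats.norm.sf(np.abs(zvals)), index=_FIXED_NAMES)
        return MixedModelResults(
            fe_params=fe, fe_bse=fe_se, fe_pvalues=pvals,
            theta=float(np.exp(p[4])), sigma_u=float(np.exp(p[5])),
            loglike=-float(best.fun), converged=converged, method=method,
            n_obs=len(self.y), n_subjects=len(self.subjects),
            diagnostics=diagnostics,
        )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; step scaled per coordinate."""
    n = len(x)
    H = np.empty((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def glmm_long_table(grids, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pool all subjects' active quadrats into GLMM long format."""
    clin = clinical.copy()
    clin["subject_id"] = clin["subject_id"].astype(str)
    arm = clin.set_index("subject_id")["treatment"]
    rows = []
    for g in grids:
        sid = str(g.subject_id)
        if sid not in arm.index:
            raise ValueError(f"subject {sid} missing from clinical table")
        cancer, cd8 = g.active_counts()
        rows.append(pd.DataFrame({
            "subject_id": sid,
            "cancer": cancer,
            "cd8": cd8,
            "treatment": arm[sid],
        }))
    return pd.concat(rows, ignore_index=True)
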