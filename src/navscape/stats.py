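"""Group-comparison models for proportion, count, and continuous outcomes.

Beta regression (probit/logit/cauchit link) for proportion measures such as
periphery preference; hurdle (zero-altered) negative-binomial models for
overdispersed error counts, splitting the zero/nonzero decision (logistic)
from positive-count magnitude (zero-truncated NB); a Poisson dispersion
check; and likelihood-ratio / information-criterion model comparison.

Estimation is delegated to statsmodels (BetaModel, Logit, zero-truncated
NegativeBinomialP, Poisson GLM); this module owns the hurdle assembly, the
tidy coefficient tables, Cragg-Uhler pseudo-R², and the comparison layer.
All fitters are deterministic given the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.discrete.discrete_model import Logit
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP
from statsmodels.genmod.families.links import Cauchy, Logit as LogitLink, Probit
from statsmodels.othermod.betareg import BetaModel

__all__ = ["ModelFit", "ModelComparison", "fit_beta_regression",
           "fit_hurdle_negbin", "dispersion_check", "compare_models",
           "design_matrix", "squeeze_proportions", "simulate_beta_data",
           "simulate_hurdle_data"]

_LINKS = {"probit": Probit, "logit": LogitLink, "cauchit": Cauchy}


@dataclass
class ModelFit:
    """A fitted group-comparison model with tidy coefficient tables."""

    family: str
    coefficients: pd.DataFrame        # est, se, z, p, ci_low, ci_high per term
    loglik: float
    aic: float
    bic: float
    nobs: int
    n_params: int
    precision: float | None = None    # beta Φ, or NB θ for count models
    pseudo_r2: float | None = None    # Cragg-Uhler, vs intercept-only model
    converged: bool = True
    submodels: dict = field(default_factory=dict)   # hurdle: zero/count tables

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "est"])

    def to_dict(self) -> dict:
        return {
            "family": self.family, "loglik": self.loglik, "aic": self.aic,
            "bic": self.bic, "nobs": self.nobs, "n_params": self.n_params,
            "precision": self.precision, "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
            "coefficients": self.coefficients.reset_index()
                                             .rename(columns={"index": "term"})
                                             .to_dict(orient="records"),
            "submodels": {k: v.reset_index().rename(columns={"index": "term"})
                           .to_dict(orient="records")
                          for k, v in self.submodels.items()},
        }


@dataclass(frozen=True)
class ModelComparison:
    """LRT (nested) and information-criterion deltas for a model pair.

    ``delta_aic``/``delta_bic`` are reduced − full: positive values favor
    the fuller model.
    """

    lrt_chi2: float
    df: int
    p: float
    delta_aic: float
    delta_bic: float


def design_matrix(sex, treatment=None, interaction: bool = True) -> pd.DataFrame:
    """Treatment-coded 2×2 design: intercept, Sex[M], Treat[E2V], interaction.

    The reference cell is F.PBO, matching the convention of regressing each
    outcome on sex, treatment, and their interaction in that order.
    """
    sex = np.asarray(sex)
    cols = {"const": np.ones(len(sex)), "sex_M": (sex == "M").astype(float)}
    if treatment is not None:
        treatment = np.asarray(treatment)
        cols["treat_E2V"] = (treatment == "E2V").astype(float)
        if interaction:
            cols["sex_M:treat_E2V"] = cols["sex_M"] * cols["treat_E2V"]
    return pd.DataFrame(cols)


def squeeze_proportions(y: np.ndarray) -> np.ndarray:
    """Pull boundary proportions off 0/1 via the (y(n−1)+0.5)/n transform."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def _coef_table(params, bse, names, alpha: float = 0.05) -> pd.DataFrame:
    params = np.asarray(params, dtype=float)
    bse = np.asarray(bse, dtype=float)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    z = params / bse
    return pd.DataFrame({
        "est": params, "se": bse, "z": z,
        "p": 2 * sps.norm.sf(np.abs(z)),
        "ci_low": params - zcrit * bse, "ci_high": params + zcrit * bse,
    }, index=list(names))


def _optimizer_ok(res, grad_tol: float = 1e-4) -> bool:
    """Accept a fit if the optimizer converged or the gradient is ~zero.

    BFGS sometimes flags precision loss on its final line search even when
    the score equations are satisfied to numerical accuracy.
    """
    rv = res.mle_retvals
    if rv.get("converged", True):
        return True
    g = rv.get("gopt")
    return g is not None and float(np.linalg.norm(g)) < grad_tol


def _cragg_uhler(llf: float, llf_null: float, n: int) -> float:
    num = 1.0 - math.exp(-2.0 * (llf - llf_null) / n)
    den = 1.0 - math.exp(2.0 * llf_null / n)
    return num / den if den != 0 else float("nan")


# ------------------------------------------------------- beta regression

def fit_beta_regression(y, design: pd.DataFrame, link: str = "probit") -> ModelFit:
    """ML beta regression of a proportion on a design matrix.

    The mean model uses the requested link; precision Φ is a single
    parameter on a log link.  Values on the open interval (0, 1) are
    required; apply :func:`squeeze_proportions` first if the data touch the
    boundary.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("proportions must lie strictly in (0, 1); "
                         "use squeeze_proportions for boundary values")
    if link not in _LINKS:
        raise ValueError(f"link must be one of {sorted(_LINKS)}")
    exog = np.asarray(design, dtype=float)
    model = BetaModel(y, exog, link=_LINKS[link]())
    res = model.fit(disp=False, maxiter=500, gtol=1e-8)
    if not _optimizer_ok(res):
        res = model.fit(disp=False, maxiter=5000, method="nm",
                        start_params=res.params)
    if not _optimizer_ok(res):
        raise RuntimeError(
            f"beta regression did not converge: {res.mle_retvals}")
    k_mean = exog.shape[1]
    names = list(design.columns) + ["log_precision"]
    table = _coef_table(res.params, res.bse, names)
    # standard beta-regression pseudo-R²: squared correlation between the
    # link-transformed response and the fitted linear predictor
    lk = _LINKS[link]()
    eta = exog @ res.params[:k_mean]
    r2 = float(np.corrcoef(lk(y), eta)[0, 1] ** 2) if k_mean > 1 else 0.0
    return ModelFit(
        family=f"beta_{link}", coefficients=table.iloc[:k_mean],
        loglik=float(res.llf), aic=float(res.aic), bic=float(res.bic),
        nobs=len(y), n_params=len(res.params),
        precision=float(np.exp(res.params[-1])),
        pseudo_r2=r2,
        submodels={"precision": table.iloc[k_mean:]},
    )


def simulate_beta_data(design: pd.DataFrame, beta, phi: float, link: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw proportions from the beta-regression data-generating process."""
    eta = np.asarray(design, dtype=float) @ np.asarray(beta, dtype=float)
    mu = _LINKS[link]().inverse(eta)
    return rng.beta(mu * phi, (1 - mu) * phi)


# --------------------------------------------------------- hurdle models

def fit_hurdle_negbin(y, design: pd.DataFrame) -> ModelFit:
    """Zero-altered (hurdle) negative-binomial regression.

    The hurdle is a logistic model of P(y > 0); positive counts follow a
    zero-truncated NB2 with log link.  The joint log-likelihood decomposes
    exactly into the two parts, each with its own coefficient table
    (``submodels['zero']`` and ``submodels['count']``).
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("counts must be non-negative")
    exog = np.asarray(design, dtype=float)
    pos = y > 0
    if not pos.any():
        raise ValueError("all counts are zero: the truncated count component "
                         "has no data")
    if pos.all():
        raise ValueError("no zero counts: the hurdle (zero) component is "
                         "degenerate; fit a plain truncated/NB model instead")

    zero_res = Logit(pos.astype(float), exog).fit(disp=False, maxiter=200)
    count_model = TruncatedLFNegativeBinomialP(y[pos], exog[pos], truncation=0)
    count_res = count_model.fit(disp=False, maxiter=500, method="bfgs")
    if not count_res.mle_retvals.get("converged", True):
        count_res = count_model.fit(disp=False, maxiter=2000, method="nm",
                                    start_params=count_res.params)

    names = list(design.columns)
    zero_tab = _coef_table(zero_res.params, zero_res.bse, names)
    count_tab = _coef_table(count_res.params, count_res.bse, names + ["alpha"])
    llf = float(zero_res.llf + count_res.llf)
    k = len(zero_res.params) + len(count_res.params)
    n = len(y)
    aic = 2 * k - 2 * llf
    bic = k * math.log(n) - 2 * llf

    # null: intercept-only in both components
    ones = np.ones((n, 1))
    llf_null = (Logit(pos.astype(float), ones).fit(disp=False).llf
                + TruncatedLFNegativeBinomialP(y[pos], ones[pos], truncation=0)
                .fit(disp=False, maxiter=500, method="bfgs").llf)
    alpha = float(count_res.params[-1])
    return ModelFit(
        family="hurdle_negbin", coefficients=count_tab.iloc[:-1],
        loglik=llf, aic=aic, bic=bic, nobs=n, n_params=k,
        precision=1.0 / alpha if alpha > 0 else float("inf"),
        pseudo_r2=_cragg_uhler(llf, llf_null, n),
        converged=bool(count_res.mle_retvals.get("converged", True)),
        submodels={"zero": zero_tab, "count": count_tab},
    )


def simulate_hurdle_data(design: pd.DataFrame, gamma, beta, theta: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw counts from the hurdle-NB data-generating process.

    ``gamma`` are logit coefficients of P(y > 0); ``beta`` are log-mean
    coefficients of the untruncated NB2 whose zero-truncation generates the
    positive counts; ``theta`` is the NB size (1/alpha).
    """
    X = np.asarray(design, dtype=float)
    p_pos = 1.0 / (1.0 + np.exp(-(X @ np.asarray(gamma, dtype=float))))
    mu = np.exp(X @ np.asarray(beta, dtype=float))
    nb_n = theta
    nb_p = theta / (theta + mu)
    y = np.zeros(len(X), dtype=int)
    crossed = rng.random(len(X)) < p_pos
    if crossed.any():
        # inverse-CDF sampling of the zero-truncated NB
        p0 = sps.nbinom.cdf(0, nb_n, nb_p[crossed])
        u = rng.uniform(p0, 1.0)
        y[crossed] = sps.nbinom.ppf(u, nb_n, nb_p[crossed]).astype(int)
    return y


# ------------------------------------------------- dispersion + comparison

def dispersion_check(y, design: pd.DataFrame) -> tuple[float, float]:
    """Pearson dispersion ratio of a Poisson model of y on the design.

    Returns ``(ratio, pearson_chi2)`` with ratio = χ²/df_resid; values well
    above 1 indicate overdispersion (motivating NB / hurdle-NB models).
    """
    y = np.asarray(y, dtype=float)
    res = sm.GLM(y, np.asarray(design, dtype=float),
                 family=sm.families.Poisson()).fit()
    chi2 = float(res.pearson_chi2)
    return chi2 / res.df_resid, chi2


def compare_models(fit_full: ModelFit, fit_reduced: ModelFit,
                   nested: bool = True) -> ModelComparison:
    """Likelihood-ratio test (for declared-nested pairs) and ΔAIC/ΔBIC."""
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("models were fitted to different numbers of observations")
    lrt = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    df = fit_full.n_params - fit_reduced.n_params
    if nested:
        p = float(sps.chi2.sf(lrt, df)) if df > 0 else float("nan")
    else:
        p = float("nan")
    return ModelComparison(lrt_chi2=lrt, df=df, p=p,
                           delta_aic=fit_reduced.aic - fit_full.aic,
                           delta_bic=fit_reduced.bic - fit_full.bic)
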