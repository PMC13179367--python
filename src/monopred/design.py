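"""A priori sample-size and power machinery for univariable logistic regression.

Implements the information-based approximation (Whittemore; Hsieh's corrected,
tabulated formulation) for a single standardized continuous covariate:

    N = (z_{1-alpha/2} + z_{power})^2 / (P (1-P) sigma^2),   sigma = ln(OR),

where ``P`` is the event probability at the covariate mean (X = 0 after
z-scoring) and the odds ratio is per 1-SD increase of the indicator.  The
inverse of the same approximation yields the analytic power of the two-sided
Wald test:

    power = Phi( sqrt(N P (1-P)) |sigma| - z_{1-alpha/2} ).

Validation fits (`LogisticIndicatorModel` / `fit_logistic`) estimate the same
single-covariate model by maximum likelihood on z-scored indicator values, and
`simulate_power` checks the analytic approximation by Monte Carlo.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DesignSpec",
    "hsieh_n",
    "hsieh_power",
    "LogisticIndicatorModel",
    "LogisticFitResults",
    "fit_logistic",
    "simulate_power",
]


@dataclass(frozen=True)
class DesignSpec:
    """Design inputs for the single-covariate logistic sample-size calculation.

    Parameters
    ----------
    odds_ratio : float
        Target odds ratio per 1-SD increase of the standardized indicator.
    event_prob : float
        Anticipated event (responder) probability at the covariate mean.
    alpha : float
        Two-sided type-I error rate.
    power : float
        Target power 1 - beta.
    correction : {"none", "multiple-correlation"}
        "none" is the base information formula.  "multiple-correlation"
        applies the published variance-inflation adjustment N / (1 - rho^2)
        for a covariate with squared multiple correlation ``rho_sq`` with
        other model covariates; with ``rho_sq=0`` it equals the base formula.
    rho_sq : float
        Squared multiple correlation used by the correction.
    """

    odds_ratio: float
    event_prob: float
    alpha: float = 0.05
    power: float = 0.80
    correction: str = "none"
    rho_sq: float = 0.0

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if not 0 < self.event_prob < 1:
            raise ValueError("event_prob must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.correction not in ("none", "multiple-correlation"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if not 0 <= self.rho_sq < 1:
            raise ValueError("rho_sq must be in [0, 1)")

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio)

    @property
    def intercept(self) -> float:
        """alpha_0 = logit(P), the intercept of the planned model."""
        return math.log(self.event_prob / (1 - self.event_prob))


def hsieh_n(spec: DesignSpec) -> int:
    """Minimum required total cohort size, rounded up to an integer.

    Raises ``ValueError`` for OR = 1 (zero effect implies unbounded N).
    """
    sigma = spec.log_or
    if sigma == 0.0:
        raise ValueError("odds_ratio = 1 gives an unbounded sample size")
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    p = spec.event_prob
    n = (z_a + z_b) ** 2 / (p * (1 - p) * sigma**2)
    if spec.correction == "multiple-correlation":
        n /= 1 - spec.rho_sq
    return math.ceil(n)


def hsieh_power(n: int, odds_ratio: float, event_prob: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided Wald test at total cohort size ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma = abs(math.log(odds_ratio))
    z_a = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(math.sqrt(n * event_prob * (1 - event_prob)) * sigma - z_a))


@dataclass
class LogisticFitResults:
    """Results of a univariable logistic fit on a z-scored indicator."""

    coef: float
    se: float
    odds_ratio: float
    conf_int: tuple[float, float]
    pvalue: float
    nobs: int
    converged: bool
    standardized: bool
    intercept: float = float("nan")
    message: str = ""

    def summary(self) -> str:
        lines = [
            "Univariable logistic regression (indicator z-scored)"
            if self.standardized
            else "Univariable logistic regression (raw scale)",
            f"  n obs          : {self.nobs}",
            f"  log-odds coef  : {self.coef:.4f} (SE {self.se:.4f})",
            f"  OR per 1-SD    : {self.odds_ratio:.3f} "
            f"(95% CI {self.conf_int[0]:.3f}-{self.conf_int[1]:.3f})",
            f"  two-sided p    : {self.pvalue:.4g}",
            f"  converged      : {self.converged}",
        ]
        if self.message:
            lines.append(f"  note           : {self.message}")
        return "\n".join(lines)


class LogisticIndicatorModel:
    """Single-indicator logistic model logit{Pr(Y=1|X)} = a0 + sigma*X.

    Parameters
    ----------
    x : array-like
        Indicator values (z-scored internally when ``standardize``).
    y : array-like
        Binary outcome, 1 = responder.
    standardize : bool
        Fit on z-scored x so the coefficient is per 1-SD increase.
    """

    def __init__(self, x, y, standardize: bool = True):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and aligned")
        if x.size < 10:
            raise ValueError("need at least 10 observations")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
            raise ValueError("y must contain both classes coded 0/1")
        self.standardize = standardize
        if standardize:
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError("constant indicator cannot be standardized")
            x = (x - x.mean()) / sd
        self.x = x
        self.y = y

    def fit(self, alpha: float = 0.05) -> LogisticFitResults:
        exog = sm.add_constant(self.x)
        model = sm.Logit(self.y, exog)
        message = ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = model.fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # separation or non-convergence
            converged = False
            message = f"fit failed: {exc}"
            res = None
        if res is None or not converged or not np.isfinite(res.bse).all():
            return LogisticFitResults(
                coef=float("nan"), se=float("nan"), odds_ratio=float("nan"),
                conf_int=(float("nan"), float("nan")), pvalue=float("nan"),
                nobs=self.y.size, converged=False,
                standardized=self.standardize,
                message=message or "non-converged (possible complete separation)",
            )
        coef = float(res.params[1])
        se = float(res.bse[1])
        z_a = stats.norm.ppf(1 - alpha / 2)
        ci = (math.exp(coef - z_a * se), math.exp(coef + z_a * se))
        return LogisticFitResults(
            coef=coef, se=se, odds_ratio=math.exp(coef), conf_int=ci,
            pvalue=float(res.pvalues[1]), nobs=self.y.size, converged=True,
            standardized=self.standardize, intercept=float(res.params[0]),
        )


def fit_logistic(x, y, standardize: bool = True) -> LogisticFitResults:
    """Fit the univariable logistic validation model; see LogisticIndicatorModel."""
    return LogisticIndicatorModel(x, y, standardize=standardize).fit()


@dataclass
class PowerSimResults:
    power: float
    reps: int
    rejections: int
    conf_int: tuple[float, float]

    def summary(self) -> str:
        return (
            f"Empirical power {self.power:.3f} "
            f"({self.rejections}/{self.reps} rejections, "
            f"95% CI {self.conf_int[0]:.3f}-{self.conf_int[1]:.3f})"
        )


def simulate_power(
    spec: DesignSpec, n: int, reps: int = 2000, seed: int = 0, alpha: float | None = None
) -> PowerSimResults:
    """Empirical power of the Wald test under the planned model, by simulation.

    Each replicate draws X ~ N(0,1), Y | X ~ Bernoulli(expit(a0 + sigma X)),
    refits the logistic model and tests the slope at ``alpha`` (two-sided).
    Replicates use independent counter-derived substreams of ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if alpha is None:
        alpha = spec.alpha
    sigma = spec.log_or
    a0 = spec.intercept
    rejections = 0
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        while True:
            x = rng.standard_normal(n)
            p = 1.0 / (1.0 + np.exp(-(a0 + sigma * x)))
            y = (rng.random(n) < p).astype(float)
            if 0 < y.sum() < n:
                break
        res = LogisticIndicatorModel(x, y, standardize=True).fit()
        if res.converged and res.pvalue < alpha:
            rejections += 1
    lo, hi = stats.binomtest(rejections, reps).proportion_ci(0.95, method="wilson")
    return PowerSimResults(
        power=rejections / reps, reps=reps, rejections=rejections,
        conf_int=(float(lo), float(hi)),
    )
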