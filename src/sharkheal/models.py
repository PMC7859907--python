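"""Healing-trajectory models and the factor screen.

Two nonlinear least-squares models summarise pooled healing trajectories:

* **Exponential closure** — percent healed y at day x follows
  ``y(x) = a·(1 − e^(−b·x))`` with horizontal asymptote ``a`` (%) and rate
  ``b`` (1/day). Inverting the fitted curve gives the day a closure
  threshold τ is reached: ``x = −ln(1 − τ/a)/b``, defined only for τ < a.

* **Quadratic plateau** — the inter-sighting rate y at day x follows
  ``y(x) = a + b·x·(1 − x/(2·x_cl))`` for x < x_cl and stays constant at
  ``a + b·x_cl/2`` beyond; ``x_cl`` is the critical day where the rate of
  change plateaus. The curve is continuous with zero slope at x_cl by
  construction.

Goodness of fit is a Nagelkerke pseudo-r² computed from Gaussian
log-likelihoods of the model and the intercept-only null.

Before fitting, the record exclusions applied to the published analysis are
available through :func:`apply_exclusions`: sightings past 150 days are
omitted from both curve fits (clearer temporal resolution; virtually healed
late records removed), negative rates are additionally dropped from the
plateau fit, and fully healed (100%) records are dropped from the
mixed-model table.

The factor screen fits a linear mixed model to the logit-transformed healed
proportion with random intercepts for shark and injury case, and removes
non-significant fixed factors (type, location, severity) stepwise by
likelihood-ratio test until a minimum adequate model remains.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import (
    FitFailureError,
    InsufficientDataError,
    UndefinedR2Error,
    UnreachableThresholdError,
)
from .stats import LOGIT_EPS, logit_proportion

log = logging.getLogger(__name__)

__all__ = [
    "apply_exclusions",
    "day_to_threshold",
    "nagelkerke_r2",
    "gaussian_loglik",
    "ExponentialHealingModel",
    "ExponentialHealingResults",
    "QuadraticPlateauModel",
    "QuadraticPlateauResults",
    "HealingFactorScreen",
    "FactorScreenResult",
    "FactorScreenResults",
    "lmm_factor_screen",
]

DEFAULT_MAX_DAY = 150

#: Numerical tolerance (percent points) below 100 at which a record counts
#: as fully healed for the mixed-model exclusion rule.
FULL_HEAL_TOL = 1e-3


# ---------------------------------------------------------------------------
# Record exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    table: pd.DataFrame,
    purpose: str,
    max_day: int = DEFAULT_MAX_DAY,
) -> pd.DataFrame:
    """Filter a tidy per-sighting table for one of the three analyses.

    purpose:
      ``mixed_model`` — drop fully healed (percent_healed >= 100) rows and
      day-0 rows (percent healed is identically 0 there by construction);
      ``curve_fit`` — drop rows with day_offset > max_day;
      ``rate_fit`` — drop rows past max_day, then rows with undefined or
      negative rate.
    """
    if purpose == "mixed_model":
        healed = table["percent_healed"] >= 100.0 - FULL_HEAL_TOL
        out = table[~healed & (table["day_offset"] > 0)]
    elif purpose == "curve_fit":
        out = table[table["day_offset"] <= max_day]
    elif purpose == "rate_fit":
        out = table[table["day_offset"] <= max_day]
        out = out[out["rate"].notna() & (out["rate"] >= 0.0)]
    else:
        raise ValueError(f"unknown purpose {purpose!r}")
    if out.empty:
        raise InsufficientDataError(f"no records left after {purpose} exclusions")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood of a regression with residual SS *rss*."""
    if n < 1 or rss < 0:
        raise ValueError("need n >= 1 and rss >= 0")
    if rss == 0.0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-r²: Cox–Snell r² rescaled to a [0, 1] maximum."""
    if n < 2:
        raise ValueError("need n >= 2")
    if loglik_model < loglik_null:
        raise ValueError("model log-likelihood below the null's")
    denom = 1.0 - math.exp(2.0 * loglik_null / n)
    if denom == 0.0:
        raise UndefinedR2Error("null likelihood degenerate; r² undefined")
    if math.isinf(loglik_model):
        return 1.0
    num = 1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n)
    return num / denom


def _pseudo_r2_from_rss(rss_model: float, rss_null: float, n: int) -> float:
    return nagelkerke_r2(gaussian_loglik(rss_model, n), gaussian_loglik(rss_null, n), n)


# ---------------------------------------------------------------------------
# Exponential closure model
# ---------------------------------------------------------------------------

def day_to_threshold(a: float, b: float, threshold: float = 90.0) -> float:
    """Day the exponential closure curve reaches *threshold* percent.

    Solves a·(1 − e^(−b·x)) = threshold; the asymptote never attains
    thresholds at or above *a*, so those raise UnreachableThresholdError.
    """
    if b <= 0:
        raise ValueError("rate b must be positive")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if threshold >= a:
        raise UnreachableThresholdError(
            f"threshold {threshold}% is not reachable under asymptote a={a}%"
        )
    return -math.log(1.0 - threshold / a) / b


def _exp_curve(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * (1.0 - np.exp(-b * x))


# Multi-start grids: the published analysis reports no initial values, so the
# fit takes the best of a coarse lattice of starts (final RSS decides).
_EXP_STARTS = [(a0, b0) for a0 in (80.0, 90.0, 100.0, 110.0)
               for b0 in (0.01, 0.05, 0.1, 0.3)]


class _NLSModelBase:
    """Shared multi-start nonlinear least-squares machinery."""

    _starts: list[tuple]
    _bounds: tuple

    def _curve(self, x, *params):  # pragma: no cover - overridden
        raise NotImplementedError

    def _solve(self, x: np.ndarray, y: np.ndarray):
        best = None
        for start in self._starts:
            try:
                res = optimize.least_squares(
                    lambda p: self._curve(x, *p) - y,
                    x0=np.asarray(start, dtype=float),
                    bounds=self._bounds,
                    method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(res.cost * 2.0)
            if best is None or rss < best[1]:
                best = (res, rss)
        if best is None:
            raise FitFailureError(
                f"no start in {self._starts} converged on {len(x)} points"
            )
        res, rss = best
        n, p = len(x), len(res.x)
        dof = max(n - p, 1)
        sigma2 = rss / dof
        # Asymptotic covariance via the Gauss-Newton approximation J'J.
        _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
        s = s[s > max(s) * np.finfo(float).eps * max(res.jac.shape)]
        vt = vt[: len(s)]
        cov = (vt.T / s**2) @ vt * sigma2
        return res.x, cov, rss


class ExponentialHealingModel(_NLSModelBase):
    """Pooled exponential closure model fitted to (day, percent healed) points.

    Parameters
    ----------
    days, percent_healed : array-like
        Pooled observations across injuries; at least 3 distinct days.
    """

    _starts = _EXP_STARTS
    _bounds = ([1e-9, 1e-9], [np.inf, np.inf])

    def __init__(self, days, percent_healed):
        self.days = np.asarray(days, dtype=float)
        self.endog = np.asarray(percent_healed, dtype=float)
        if self.days.shape != self.endog.shape:
            raise ValueError("days and percent_healed must align")
        if len(np.unique(self.days)) < 3:
            raise FitFailureError(
                "exponential fit is under-determined with <3 distinct days"
            )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        metric: str = "area",
        max_day: int = DEFAULT_MAX_DAY,
    ) -> "ExponentialHealingModel":
        """Build from a tidy rates table, applying the curve-fit exclusions."""
        sub = table[table["metric"] == metric] if "metric" in table else table
        sub = apply_exclusions(sub, "curve_fit", max_day=max_day)
        return cls(sub["day_offset"].to_numpy(), sub["percent_healed"].to_numpy())

    def _curve(self, x, a, b):
        return _exp_curve(x, a, b)

    def fit(self) -> "ExponentialHealingResults":
        params, cov, rss = self._solve(self.days, self.endog)
        n = len(self.days)
        rss_null = float(np.sum((self.endog - self.endog.mean()) ** 2))
        r2 = _pseudo_r2_from_rss(rss, rss_null, n) if rss_null > 0 else 1.0
        return ExponentialHealingResults(self, params, cov, rss, r2)


@dataclass
class ExponentialHealingResults:
    """Fitted exponential closure curve."""

    model: ExponentialHealingModel
    params: np.ndarray
    cov_params: np.ndarray
    rss: float
    rsquared: float

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def nobs(self) -> int:
        return len(self.model.days)

    def predict(self, days) -> np.ndarray:
        return _exp_curve(np.asarray(days, dtype=float), self.a, self.b)

    def day_to_threshold(self, threshold: float = 90.0) -> float:
        """Day the fitted curve reaches *threshold* percent closure."""
        return day_to_threshold(self.a, self.b, threshold)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Exponential closure model  y(x) = a(1 - exp(-bx))",
            f"  n obs            {self.nobs}",
            f"  a (asymptote %)  {self.a:10.3f}  (se {se[0]:.3f})",
            f"  b (1/day)        {self.b:10.4f}  (se {se[1]:.4f})",
            f"  Nagelkerke r2    {self.rsquared:10.3f}",
        ]
        try:
            lines.append(f"  day to 90%       {self.day_to_threshold(90.0):10.3f}")
        except UnreachableThresholdError:
            lines.append("  day to 90%            unreachable (a <= 90)")
        return "\n".join(lines)

    def plot(self, ax=None, threshold: float | None = 90.0):
        """Scatter the observations with the fitted curve (and threshold day)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.days, self.model.endog, s=12, alpha=0.6, label="observed")
        grid = np.linspace(0.0, float(self.model.days.max()), 200)
        ax.plot(grid, self.predict(grid), label="exponential fit")
        if threshold is not None and threshold < self.a:
            ax.axvline(self.day_to_threshold(threshold), ls=":", c="r",
                       label=f"{threshold:g}% closure")
        ax.set_xlabel("days since first sighting")
        ax.set_ylabel("percent healed")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Quadratic plateau model
# ---------------------------------------------------------------------------

def _plateau_curve(x: np.ndarray, a: float, b: float, x_cl: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    rising = a + b * x * (1.0 - x / (2.0 * x_cl))
    flat = a + b * x_cl / 2.0
    return np.where(x < x_cl, rising, flat)


class QuadraticPlateauModel(_NLSModelBase):
    """Quadratic-plateau model for inter-sighting rates vs day.

    Fits y = a + b·x(1 − x/(2·x_cl)) below the critical day x_cl and a
    constant plateau beyond it; needs at least 4 distinct days.
    """

    _starts = [(a0, b0, x0)
               for a0 in (5.0, 10.0, 15.0)
               for b0 in (-0.05, -0.3, -1.0, -3.0)
               for x0 in (10.0, 30.0, 60.0)]
    _bounds = ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf])

    def __init__(self, days, rates):
        self.days = np.asarray(days, dtype=float)
        self.endog = np.asarray(rates, dtype=float)
        if self.days.shape != self.endog.shape:
            raise ValueError("days and rates must align")
        if len(np.unique(self.days)) < 4:
            raise FitFailureError(
                "plateau fit is under-determined with <4 distinct days"
            )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        metric: str = "area",
        max_day: int = DEFAULT_MAX_DAY,
    ) -> "QuadraticPlateauModel":
        """Build from a tidy rates table, applying the rate-fit exclusions."""
        sub = table[table["metric"] == metric] if "metric" in table else table
        sub = apply_exclusions(sub, "rate_fit", max_day=max_day)
        return cls(sub["day_offset"].to_numpy(), sub["rate"].to_numpy())

    def _curve(self, x, a, b, x_cl):
        return _plateau_curve(x, a, b, x_cl)

    def fit(self) -> "QuadraticPlateauResults":
        params, cov, rss = self._solve(self.days, self.endog)
        n = len(self.days)
        rss_null = float(np.sum((self.endog - self.endog.mean()) ** 2))
        r2 = _pseudo_r2_from_rss(rss, rss_null, n) if rss_null > 0 else 1.0
        res = QuadraticPlateauResults(self, params, cov, rss, r2)
        if res.x_cl > self.days.max():
            res.beyond_data_range = True
            log.warning("fitted plateau day %.2f lies beyond the data range", res.x_cl)
        return res


@dataclass
class QuadraticPlateauResults:
    """Fitted quadratic-plateau rate curve."""

    model: QuadraticPlateauModel
    params: np.ndarray
    cov_params: np.ndarray
    rss: float
    rsquared: float
    beyond_data_range: bool = False

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def x_cl(self) -> float:
        return float(self.params[2])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def x_cl_se(self) -> float:
        return float(self.bse[2])

    @property
    def x_cl_t(self) -> float:
        return self.x_cl / self.x_cl_se

    @property
    def x_cl_p(self) -> float:
        dof = max(len(self.model.days) - 3, 1)
        return float(2.0 * sps.t.sf(abs(self.x_cl_t), dof))

    @property
    def plateau_value(self) -> float:
        """Constant rate beyond the critical day: a + b·x_cl/2."""
        return self.a + self.b * self.x_cl / 2.0

    @property
    def nobs(self) -> int:
        return len(self.model.days)

    def predict(self, days) -> np.ndarray:
        return _plateau_curve(np.asarray(days, dtype=float), self.a, self.b, self.x_cl)

    def summary(self) -> str:
        se = self.bse
        return "\n".join([
            "Quadratic plateau model  y(x) = a + bx(1 - x/(2 x_cl)), x < x_cl",
            f"  n obs              {self.nobs}",
            f"  a (%/day at d0)    {self.a:10.3f}  (se {se[0]:.3f})",
            f"  b (decay)          {self.b:10.4f}  (se {se[1]:.4f})",
            f"  x_cl (days)        {self.x_cl:10.3f}  (se {self.x_cl_se:.3f},"
            f" t {self.x_cl_t:.3f})",
            f"  plateau (%/day)    {self.plateau_value:10.3f}",
            f"  Nagelkerke r2      {self.rsquared:10.3f}",
        ])

    def plot(self, ax=None):
        """Scatter the rates with the fitted piecewise curve and x_cl marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.days, self.model.endog, s=12, alpha=0.6, label="rates")
        grid = np.linspace(0.0, float(self.model.days.max()), 200)
        ax.plot(grid, self.predict(grid), label="plateau fit")
        ax.axvline(self.x_cl, ls=":", c="r", label=f"x_cl = {self.x_cl:.1f} d")
        ax.set_xlabel("days since first sighting")
        ax.set_ylabel("healing rate (%/day)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Mixed-model factor screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorScreenResult:
    """Likelihood-ratio test of one fixed factor in the mixed model."""

    term: str
    chi2: float
    df: int
    p: float
    retained: bool


@dataclass
class FactorScreenResults:
    """Outcome of the stepwise factor screen."""

    results: list[FactorScreenResult]
    final_formula: str
    random_structure: str
    alpha: float

    @property
    def retained(self) -> list[str]:
        return [r.term for r in self.results if r.retained]

    def summary(self) -> str:
        lines = [
            f"Mixed-model factor screen (alpha={self.alpha}; "
            f"random: {self.random_structure})",
            f"  minimum adequate model: {self.final_formula}",
            f"  {'term':<10} {'chi2':>8} {'df':>3} {'p':>8}  retained",
        ]
        for r in self.results:
            lines.append(
                f"  {r.term:<10} {r.chi2:8.3f} {r.df:3d} {r.p:8.4f}  {r.retained}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": r.term, "chi2": r.chi2, "df": r.df, "p": r.p,
              "retained": r.retained} for r in self.results]
        )


class HealingFactorScreen:
    """Stepwise mixed-model screen of injury factors on logit healed proportion.

    The response is logit(percent_healed/100), clamped to stay finite. Time
    since first sighting enters the fixed part as log(day) and is never
    screened (the logit of an exponential-closure proportion is close to
    linear in log-day through the active-healing range). Each candidate
    factor contributes a block of terms — its main effect plus its
    interaction with log-day — and blocks are screened together by
    likelihood-ratio tests of ML fits, removing the least significant block
    above ``alpha`` and refitting until a minimum adequate model remains.

    Random structure: a shark random intercept plus an injury-case variance
    component. When that structure is degenerate — too few sharks, a failed
    fit, or variance estimates blowing past the response variance (shark and
    injury effects are unidentifiable when most sharks carry a single
    injury) — the screen falls back to an injury-only random intercept with
    a logged warning.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        factors: tuple[str, ...] = ("type", "location", "severity"),
        alpha: float = 0.05,
    ):
        self.table = table.copy()
        self.alpha = alpha
        if "logit_healed" not in self.table:
            self.table["logit_healed"] = [
                logit_proportion(p / 100.0, LOGIT_EPS)
                for p in self.table["percent_healed"]
            ]
        if (self.table["day_offset"] <= 0).any():
            raise ValueError("screen table must exclude day-0 rows")
        self.table["log_day"] = np.log(self.table["day_offset"].astype(float))
        self.factors = [
            f for f in factors
            if f in self.table and self.table[f].nunique() >= 2
        ]
        dropped = sorted(set(factors) - set(self.factors))
        if dropped:
            log.warning("factors %s have <2 levels; not screened", dropped)

    @classmethod
    def from_rates_frame(
        cls,
        table: pd.DataFrame,
        metric: str = "area",
        factors: tuple[str, ...] = ("type", "location", "severity"),
        alpha: float = 0.05,
    ) -> "HealingFactorScreen":
        """Build from a tidy rates table, applying the mixed-model exclusions."""
        sub = table[table["metric"] == metric] if "metric" in table else table
        sub = apply_exclusions(sub, "mixed_model")
        return cls(sub, factors=factors, alpha=alpha)

    def _formula(self, terms: list[str]) -> str:
        rhs = ["log_day"]
        for t in terms:
            rhs += [f"C({t})", f"log_day:C({t})"]
        return "logit_healed ~ " + " + ".join(rhs)

    def _block_df(self, term: str) -> int:
        # main effect + log-day interaction, each (levels - 1) columns
        return 2 * (self.table[term].nunique() - 1)

    def _fit_once(self, formula: str, mode: str):
        """One ML fit under a fixed random structure.

        mode: ``vc`` — shark intercept plus injury intercept/trend variance
        components; ``slope`` — injury random intercept + log-day slope (the
        slope keeps tests of factor x time interactions calibrated);
        ``intercept`` — injury random intercept only (last resort).
        """
        import statsmodels.formula.api as smf

        last_exc: Exception | None = None
        for method in (["lbfgs", "bfgs"], ["cg"]):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if mode == "vc":
                        md = smf.mixedlm(
                            formula,
                            self.table,
                            groups=self.table["shark_id"],
                            vc_formula={
                                "injury": "0 + C(injury_id)",
                                "injury_trend": "0 + C(injury_id):log_day",
                            },
                        )
                    elif mode == "slope":
                        md = smf.mixedlm(
                            formula,
                            self.table,
                            groups=self.table["injury_id"],
                            re_formula="1 + log_day",
                        )
                    else:
                        md = smf.mixedlm(
                            formula, self.table, groups=self.table["injury_id"]
                        )
                    fit = md.fit(reml=False, method=method, maxiter=400)
                if np.isfinite(fit.llf) and np.all(np.isfinite(fit.fe_params)):
                    return fit
            except Exception as exc:  # singular hessian, LinAlgError, ...
                last_exc = exc
        raise FitFailureError(f"mixed model failed to fit: {last_exc}")

    def _structure_is_degenerate(self, fit) -> bool:
        # a sane variance decomposition cannot put more variance into the
        # random effects than the marginal response carries in total
        resp_var = float(np.var(self.table["logit_healed"]))
        total_re = float(np.trace(np.atleast_2d(fit.cov_re))) + float(
            np.sum(fit.vcomp)
        )
        return not math.isfinite(total_re) or total_re > max(resp_var, 1e-12)

    #: Minimum number of sharks carrying >=2 injuries for the shark-level
    #: variance component to be identifiable separately from the injury one.
    MIN_MULTI_INJURY_SHARKS = 5

    def _choose_structure(self) -> str:
        """Pick the richest random structure the data can identify."""
        full = self._formula(self.factors)
        n_sharks = self.table["shark_id"].nunique() if "shark_id" in self.table else 0
        multi = (
            self.table.groupby("shark_id")["injury_id"].nunique() >= 2
        ).sum() if n_sharks else 0
        use_vc = n_sharks >= 2 and multi >= self.MIN_MULTI_INJURY_SHARKS
        if not use_vc:
            log.warning(
                "only %d sharks carry multiple injuries; shark variance not "
                "identifiable separately — using injury-level random structure",
                multi,
            )
        else:
            try:
                probe = self._fit_once(full, "vc")
                if not self._structure_is_degenerate(probe):
                    return "vc"
                log.warning("shark+injury variance components degenerate; falling back")
            except FitFailureError as exc:
                log.warning("shark+injury random structure failed (%s); falling back", exc)
        try:
            self._fit_once(full, "slope")
            return "slope"
        except FitFailureError as exc:
            log.warning(
                "random log-day slope not estimable (%s); intercept-only", exc
            )
            return "intercept"

    def fit(self) -> FactorScreenResults:
        mode = self._choose_structure()

        current = list(self.factors)
        removed: dict[str, FactorScreenResult] = {}
        while True:
            full = self._fit_once(self._formula(current), mode)
            tests = {}
            for term in current:
                reduced = self._fit_once(
                    self._formula([t for t in current if t != term]), mode
                )
                chi2 = max(2.0 * (full.llf - reduced.llf), 0.0)
                df = self._block_df(term)
                tests[term] = (chi2, df, float(sps.chi2.sf(chi2, df)))
            worst = max(tests, key=lambda t: tests[t][2], default=None)
            if worst is not None and tests[worst][2] > self.alpha:
                chi2, df, p = tests[worst]
                removed[worst] = FactorScreenResult(worst, chi2, df, p, False)
                current.remove(worst)
                continue
            results = [
                FactorScreenResult(t, *tests[t], True) for t in current
            ] + list(removed.values())
            results.sort(key=lambda r: self.factors.index(r.term))
            random_structure = {
                "vc": "shark intercept + injury variance components",
                "slope": "injury intercept + log-day slope (fallback)",
                "intercept": "injury intercept only (fallback)",
            }[mode]
            return FactorScreenResults(
                results=results,
                final_formula=self._formula(current),
                random_structure=random_structure,
                alpha=self.alpha,
            )


def lmm_factor_screen(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("type", "location", "severity"),
    alpha: float = 0.05,
) -> FactorScreenResults:
    """Functional front end to :class:`HealingFactorScreen` (exclusions applied)."""
    return HealingFactorScreen.from_rates_frame(
        table, factors=factors, alpha=alpha
    ).fit()
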