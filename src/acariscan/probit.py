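"""Probit dose-response analysis and diagnostic-dose derivation.

The model is the classical log-dose probit: the probability that a mite
dies in a vial coated at dose :math:`d` is

.. math:: P(d) = c + (1 - c)\\,\\Phi(\\alpha + \\beta \\log_{10} d)

where :math:`\\Phi` is the standard normal CDF, :math:`\\beta` the probit
slope (homogeneity of the population response), and :math:`c` the natural
(control) response. Parameters are estimated by maximum binomial
likelihood; lack of fit is assessed with a Pearson chi-square over the
distinct doses, and when it is significant at the 5% level the
variance-covariance matrix is inflated by the heterogeneity factor
chi2/df and confidence quantiles switch from the normal to t(df)
(Finney's convention, as implemented by the major commercial packages).

The lethal dose for probability p is
:math:`\\mathrm{LD}_p = 10^{(\\Phi^{-1}(p) - \\alpha)/\\beta}`, with 95%
confidence limits by the delta method on the log10 scale (default) or by
Fieller's theorem. The diagnostic dose used for single-dose resistance
monitoring is fixed at twice the LD90 of the susceptible reference
strain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .bioassay import BioassayDataset, BioassayObservation, pool_by_dose

__all__ = [
    "ProbitDoseResponse",
    "ProbitResults",
    "ProbitNotDetermined",
    "DiagnosticDose",
    "LdEstimate",
    "NonIdentifiableFitError",
    "fit_probit",
    "ld_p",
    "diagnostic_dose",
    "ppm_to_surface_dose",
    "mortality_at_dd",
]

_Z90 = float(stats.norm.ppf(0.9))  # 1.2816...


class NonIdentifiableFitError(ValueError):
    """Raised when the likelihood carries no dose-response information
    (all mites dead, or none, at every dose)."""


@dataclass(frozen=True)
class LdEstimate:
    """A lethal-dose quantile with its 95% confidence interval."""

    p: float
    dose: float
    ci_lower: float
    ci_upper: float
    ci_method: str
    unit: str = "ug/cm2"

    def __str__(self) -> str:
        return f"LD{100 * self.p:g} = {self.dose:.4g} ({self.ci_lower:.4g}-{self.ci_upper:.4g}) {self.unit}"


@dataclass(frozen=True)
class DiagnosticDose:
    """Discriminating dose for single-dose resistance monitoring.

    Fixed at ``factor`` (= 2) times the LD90 of the susceptible
    reference fit; the doubling is applied to the unrounded LD90.
    """

    value: float
    unit: str
    basis: float
    factor: float = 2.0

    def __post_init__(self) -> None:
        if not math.isclose(self.value, self.factor * self.basis, rel_tol=1e-12):
            raise ValueError("diagnostic dose must equal factor x basis exactly")


@dataclass(frozen=True)
class ProbitNotDetermined:
    """Structured placeholder for an assay whose probit line could not be
    determined (the 'ND' rows of a toxicity table). Never raised; returned
    by batch layers instead of a fit."""

    strain: str
    acaricide: str
    reason: str

    @property
    def determined(self) -> bool:
        return False


class ProbitDoseResponse:
    """Binomial probit dose-response model for one strain x acaricide assay.

    Parameters
    ----------
    dose, n_treated, n_dead : array_like
        Per-vial records. Dose-0 rows are controls: excluded from the
        probit design matrix, used only to estimate the natural response
        when ``fit(control_correction=True)``.
    dose_unit : str
        Unit tag carried through to results (``"ug/cm2"`` or ``"ppm"``).
    strain, acaricide : str
        Labels for reporting.

    Examples
    --------
    >>> model = ProbitDoseResponse([1, 10, 100], [100, 100, 100], [5, 50, 95])
    >>> res = model.fit()
    >>> round(res.ld50.dose, 1)
    10.0
    """

    def __init__(
        self,
        dose,
        n_treated,
        n_dead,
        dose_unit: str = "ug/cm2",
        strain: str = "",
        acaricide: str = "",
        exposure_h: float = 8.0,
    ) -> None:
        dose = np.asarray(dose, dtype=float)
        n = np.asarray(n_treated, dtype=int)
        y = np.asarray(n_dead, dtype=int)
        if not (dose.shape == n.shape == y.shape):
            raise ValueError("dose, n_treated and n_dead must have equal length")
        if np.any(~np.isfinite(dose)) or np.any(dose < 0):
            raise ValueError("doses must be finite and >= 0")
        if np.any(n <= 0) or np.any(y < 0) or np.any(y > n):
            raise ValueError("need 0 <= n_dead <= n_treated and n_treated > 0")
        treated = dose > 0
        self.dose = dose[treated]
        self.n = n[treated]
        self.y = y[treated]
        self.control_n = int(n[~treated].sum())
        self.control_y = int(y[~treated].sum())
        self.log_dose = np.log10(self.dose)
        self.dose_unit = dose_unit
        self.strain = strain
        self.acaricide = acaricide
        self.exposure_h = exposure_h
        if len(np.unique(self.dose)) < 3:
            raise ValueError("probit fitting needs >= 3 distinct positive doses")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataset(cls, data: BioassayDataset) -> "ProbitDoseResponse":
        data.validate_for_fit()
        obs = data.observations
        return cls(
            [o.dose for o in obs],
            [o.n_treated for o in obs],
            [o.n_dead for o in obs],
            dose_unit=data.dose_unit,
            strain=data.strain,
            acaricide=data.acaricide,
            exposure_h=obs[0].exposure_h if obs else 8.0,
        )

    @classmethod
    def from_dataframe(cls, df, dose="dose", n_treated="n_treated", n_dead="n_dead", **kw):
        return cls(df[dose].to_numpy(), df[n_treated].to_numpy(), df[n_dead].to_numpy(), **kw)

    # -- likelihood ------------------------------------------------------
    def _prob(self, alpha: float, beta: float, c: float) -> np.ndarray:
        p = c + (1.0 - c) * stats.norm.cdf(alpha + beta * self.log_dose)
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def loglike(self, params) -> float:
        """Binomial log-likelihood at ``params = (alpha, beta[, c])``."""
        alpha, beta = params[0], params[1]
        c = params[2] if len(params) > 2 else 0.0
        if not 0.0 <= c < 1.0:
            return -np.inf
        p = self._prob(alpha, beta, c)
        ll = float(np.sum(self.y * np.log(p) + (self.n - self.y) * np.log1p(-p)))
        if self.control_n and len(params) > 2:
            pc = min(max(c, 1e-12), 1 - 1e-12)
            ll += self.control_y * math.log(pc) + (self.control_n - self.control_y) * math.log1p(-pc)
        return ll

    def _start(self) -> tuple[float, float]:
        # least squares on empirical probits of non-degenerate doses
        pooled = pool_by_dose(
            [BioassayObservation(d, int(n), int(y)) for d, n, y in zip(self.dose, self.n, self.y)]
        )
        xs, zs = [], []
        for d, n, y in pooled:
            frac = (y + 0.5) / (n + 1.0)  # shrink away from 0/1
            xs.append(math.log10(d))
            zs.append(stats.norm.ppf(frac))
        xs, zs = np.asarray(xs), np.asarray(zs)
        if np.ptp(xs) == 0:
            return float(zs.mean()), 1.0
        beta, alpha = np.polyfit(xs, zs, 1)
        if not np.isfinite(beta) or beta == 0:
            beta = 1.0
        return float(alpha), float(beta)

    def fit(self, control_correction: bool = False, ci_method: str = "delta") -> "ProbitResults":
        """Maximum-likelihood fit.

        Parameters
        ----------
        control_correction : bool
            Estimate the natural response c from dose-0 control rows
            (Abbott-style, but through the likelihood). Default off: the
            diagnostic-dose tables this package mirrors report
            uncorrected fits.
        ci_method : {"delta", "fieller"}
            Default confidence-limit method carried onto the results.
        """
        if self.y.sum() == 0 or (self.n - self.y).sum() == 0:
            raise NonIdentifiableFitError(
                f"{self.strain}/{self.acaricide}: mortality is degenerate "
                "(all dead or all alive at every dose); the probit line is not identifiable"
            )
        a0, b0 = self._start()
        if control_correction and self.control_n:
            c0 = min(max(self.control_y / self.control_n, 1e-4), 0.5)
            x0 = np.array([a0, b0, c0])
            bounds = [(None, None), (None, None), (1e-9, 0.999)]
        else:
            x0 = np.array([a0, b0])
            bounds = None
        res = optimize.minimize(
            lambda th: -self.loglike(th), x0, method="L-BFGS-B", bounds=bounds
        )
        # polish with Nelder-Mead if line search stalled
        if not res.success:
            res = optimize.minimize(lambda th: -self.loglike(th), res.x, method="Nelder-Mead")
        params = res.x
        cov = _numerical_cov(lambda th: -self.loglike(th), params)
        return ProbitResults(self, params, cov, control_correction, ci_method)


def _numerical_cov(nll, params: np.ndarray) -> np.ndarray:
    """Inverse observed information by central-difference Hessian."""
    k = len(params)
    h = 1e-4 * np.maximum(np.abs(params), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(params + ei + ej) - nll(params + ei - ej)
                - nll(params - ei + ej) + nll(params - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov


class ProbitResults:
    """Fitted probit line: parameters, goodness of fit, LDp quantiles.

    Attributes
    ----------
    alpha : float
        Intercept on the probit scale at log10 dose 0.
    beta : float
        Probit slope per log10 dose.
    natural_response : float
        Fitted control response c (0 when correction is off).
    chi2, df_resid : float, int
        Pearson lack-of-fit statistic over distinct doses and its
        degrees of freedom (distinct doses minus fitted parameters).
    heterogeneity : float
        chi2/df variance inflation, applied only when the lack of fit is
        significant at the 5% level; 1 otherwise.
    """

    @classmethod
    def from_parameters(
        cls,
        ld50: float,
        slope: float,
        slope_se: float = 0.0,
        dose_unit: str = "ug/cm2",
        strain: str = "",
        acaricide: str = "",
    ) -> "ProbitResults":
        """Build a results object from published toxicity parameters
        (LD50 and probit slope) rather than raw data.

        Useful for closed-form work with printed toxicity tables: LDp
        quantiles and the diagnostic dose follow from
        ``alpha = -slope * log10(LD50)`` alone. Confidence limits are
        only meaningful if ``slope_se`` is supplied (intercept variance
        and covariance are taken as zero).
        """
        if ld50 <= 0 or slope <= 0:
            raise ValueError("need ld50 > 0 and slope > 0")
        stub = _StubModel(dose_unit=dose_unit, strain=strain, acaricide=acaricide)
        obj = cls.__new__(cls)
        obj.model = stub
        obj.params = np.array([-slope * math.log10(ld50), slope])
        obj.alpha, obj.beta = float(obj.params[0]), float(obj.params[1])
        obj.natural_response = 0.0
        obj.control_correction = False
        obj.ci_method = "delta"
        obj.negative_slope = False
        obj._raw_cov = np.array([[0.0, 0.0], [0.0, slope_se**2]])
        obj.chi2 = 0.0
        obj.df_resid = 0
        obj.heterogeneity = 1.0
        obj.heterogeneity_applied = False
        obj.cov_params = obj._raw_cov
        return obj

    def __init__(self, model, params, cov, control_correction, ci_method="delta"):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.alpha = float(params[0])
        self.beta = float(params[1])
        self.natural_response = float(params[2]) if len(params) > 2 else 0.0
        self.control_correction = control_correction
        self.ci_method = ci_method
        self.negative_slope = self.beta <= 0
        if self.negative_slope:
            warnings.warn(
                f"{model.strain}/{model.acaricide}: fitted probit slope is not positive; "
                "LD estimates are undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        self._raw_cov = np.asarray(cov, dtype=float)
        self._compute_gof()

    # -- goodness of fit -------------------------------------------------
    def _compute_gof(self) -> None:
        m = self.model
        pooled = pool_by_dose(
            [BioassayObservation(d, int(n), int(y)) for d, n, y in zip(m.dose, m.n, m.y)]
        )
        chi2 = 0.0
        for d, n, y in pooled:
            p = self.predict(d)
            chi2 += (y - n * p) ** 2 / (n * p * (1 - p))
        self.chi2 = float(chi2)
        self.df_resid = max(len(pooled) - len(self.params), 0)
        if self.df_resid > 0 and self.chi2 > stats.chi2.ppf(0.95, self.df_resid):
            self.heterogeneity = self.chi2 / self.df_resid
            self.heterogeneity_applied = True
        else:
            self.heterogeneity = 1.0
            self.heterogeneity_applied = False
        self.cov_params = self._raw_cov * self.heterogeneity

    def _quantile(self, level: float = 0.95) -> float:
        """Two-sided CI quantile: normal, or t(df) under heterogeneity."""
        q = 1 - (1 - level) / 2
        if self.heterogeneity_applied and self.df_resid > 0:
            return float(stats.t.ppf(q, self.df_resid))
        return float(stats.norm.ppf(q))

    # -- derived quantities ----------------------------------------------
    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov_params[1, 1]))

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.cov_params[0, 0]))

    @property
    def loglike(self) -> float:
        return self.model.loglike(self.params)

    def predict(self, dose) -> np.ndarray | float:
        """Expected mortality (incl. natural response) at ``dose``."""
        dose = np.asarray(dose, dtype=float)
        c = self.natural_response
        p = c + (1 - c) * stats.norm.cdf(self.alpha + self.beta * np.log10(dose))
        return float(p) if p.ndim == 0 else p

    def ld(self, p: float, ci_method: str | None = None, level: float = 0.95) -> LdEstimate:
        """Dose at which the fitted susceptibility distribution reaches
        mortality ``p`` (natural response excluded), with confidence limits.

        The point estimate is ``10 ** ((z_p - alpha) / beta)`` with
        ``z_p = Phi^{-1}(p)``. Limits are computed on the log10 scale by
        the delta method, or by Fieller's theorem on request.
        """
        if not 0 < p < 1:
            raise ValueError(f"p must lie strictly in (0, 1), got {p}")
        if self.beta <= 0:
            raise ValueError("LD quantiles are undefined for a non-positive slope")
        ci_method = ci_method or self.ci_method
        z = float(stats.norm.ppf(p))
        theta = (z - self.alpha) / self.beta  # log10 LDp
        V = self.cov_params[:2, :2]
        q = self._quantile(level)
        if ci_method == "delta":
            var = (V[0, 0] + 2 * theta * V[0, 1] + theta**2 * V[1, 1]) / self.beta**2
            half = q * math.sqrt(max(var, 0.0))
            lo, hi = theta - half, theta + half
        elif ci_method == "fieller":
            lo, hi = _fieller_log10(self.alpha, self.beta, V, z, q)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        return LdEstimate(p, 10.0**theta, 10.0**lo, 10.0**hi, ci_method, self.model.dose_unit)

    @property
    def ld50(self) -> LdEstimate:
        return self.ld(0.5)

    @property
    def ld90(self) -> LdEstimate:
        return self.ld(0.9)

    def diagnostic_dose(self) -> DiagnosticDose:
        """Two-fold the (unrounded) LD90, in the fit's dose unit."""
        basis = self.ld(0.9).dose
        return DiagnosticDose(value=2.0 * basis, unit=self.model.dose_unit, basis=basis)

    @property
    def determined(self) -> bool:
        return True

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        ld50, ld90 = self.ld(0.5), self.ld(0.9)
        dd = self.diagnostic_dose()
        lines = [
            "Probit dose-response fit",
            "=" * 60,
            f"strain: {m.strain or '-'}    acaricide: {m.acaricide or '-'}",
            f"N treated: {int(m.n.sum())}    distinct doses: {len(np.unique(m.dose))}"
            f"    unit: {m.dose_unit}",
            f"slope +/- SE: {self.beta:.2f} +/- {self.slope_se:.2f}",
            f"intercept:    {self.alpha:.3f}",
            f"natural response c: {self.natural_response:.4f}"
            + ("" if self.control_correction else " (not estimated)"),
            f"Pearson chi2: {self.chi2:.2f}  df: {self.df_resid}"
            + (
                f"  heterogeneity applied: {self.heterogeneity:.2f}"
                if self.heterogeneity_applied
                else ""
            ),
            f"LD50: {ld50.dose:.3g} ({ld50.ci_lower:.3g}-{ld50.ci_upper:.3g})",
            f"LD90: {ld90.dose:.3g} ({ld90.ci_lower:.3g}-{ld90.ci_upper:.3g})",
            f"D/D (2 x LD90): {dd.value:.3g} {dd.unit}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ld50, ld90 = self.ld(0.5), self.ld(0.9)
        return {
            "strain": self.model.strain,
            "acaricide": self.model.acaricide,
            "n": int(self.model.n.sum()),
            "slope": self.beta,
            "slope_se": self.slope_se,
            "intercept": self.alpha,
            "natural_response": self.natural_response,
            "chi2": self.chi2,
            "df": self.df_resid,
            "heterogeneity": self.heterogeneity,
            "ld50": ld50.dose,
            "ld50_ci": [ld50.ci_lower, ld50.ci_upper],
            "ld90": ld90.dose,
            "ld90_ci": [ld90.ci_lower, ld90.ci_upper],
            "diagnostic_dose": self.diagnostic_dose().value,
            "dose_unit": self.model.dose_unit,
        }


@dataclass
class _StubModel:
    """Minimal model stand-in behind parameter-only results."""

    dose_unit: str = "ug/cm2"
    strain: str = ""
    acaricide: str = ""


def _fieller_log10(alpha, beta, V, z, q):
    """Fieller interval for (z - alpha)/beta with covariance V."""
    A = beta**2 - q**2 * V[1, 1]
    B = 2 * (beta * (alpha - z) - q**2 * V[0, 1])
    C = (alpha - z) ** 2 - q**2 * V[0, 0]
    if A <= 0:
        # interval unbounded: slope not significantly different from 0
        return -np.inf, np.inf
    disc = B**2 - 4 * A * C
    if disc < 0:
        return -np.inf, np.inf
    r = math.sqrt(disc)
    # roots are for m where alpha + beta*m = z boundary; note sign of B
    lo = (-B - r) / (2 * A)
    hi = (-B + r) / (2 * A)
    return min(lo, hi), max(lo, hi)


# ---------------------------------------------------------------------------
# functional surface


def fit_probit(data: BioassayDataset, control_correction: bool = False) -> ProbitResults:
    """Fit the binomial probit model to one assay dataset."""
    return ProbitDoseResponse.from_dataset(data).fit(control_correction=control_correction)


def ld_p(fit: ProbitResults, p: float, ci_method: str | None = None) -> LdEstimate:
    """LDp quantile of a fitted probit line with 95% confidence limits."""
    return fit.ld(p, ci_method=ci_method)


def diagnostic_dose(fit: ProbitResults) -> DiagnosticDose:
    """Diagnostic dose = 2 x LD90 of the fit (doubling the unrounded value)."""
    return fit.diagnostic_dose()


def ppm_to_surface_dose(
    conc_ppm: float, volume_ul: float = 100.0, vial_area_cm2: float = 16.39
) -> float:
    """Convert a coating-solution concentration (ppm = ug/ml) to the
    residual surface dose (ug/cm2) it deposits on the vial wall.

    ``conc_ppm`` ug/ml applied in ``volume_ul`` ul leaves
    ``conc_ppm * volume_ul * 1e-3`` ug spread over ``vial_area_cm2`` cm2
    of inner glass surface. With the 100 ul / 16.39 cm2 defaults of the
    5-ml vial assay, 1 ppm deposits about 6.1e-3 ug/cm2.
    """
    if conc_ppm < 0:
        raise ValueError("concentration must be >= 0")
    if vial_area_cm2 <= 0:
        raise ValueError("vial area must be positive")
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    return conc_ppm * volume_ul * 1e-3 / vial_area_cm2


@dataclass(frozen=True)
class MortalityAtDiagnosticDose:
    """Observed single-dose mortality with a Wilson 95% interval."""

    mortality_pct: float
    ci_lower_pct: float
    ci_upper_pct: float
    n_treated: int
    n_dead: int
    resistant: bool | None = None


def mortality_at_dd(
    obs: BioassayObservation | None = None,
    *,
    n_dead: int | None = None,
    n_treated: int | None = None,
    threshold_pct: float | None = None,
) -> MortalityAtDiagnosticDose:
    """Percent mortality under the diagnostic dose, with a 95% Wilson
    score interval; optionally classify the population as resistant when
    mortality falls below ``threshold_pct``.
    """
    if obs is not None:
        n_dead, n_treated = obs.n_dead, obs.n_treated
    if n_treated is None or n_dead is None:
        raise ValueError("provide an observation or n_dead and n_treated")
    if n_treated <= 0:
        raise ValueError("n_treated must be positive")
    if not 0 <= n_dead <= n_treated:
        raise ValueError("need 0 <= n_dead <= n_treated")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(n_dead, n_treated, alpha=0.05, method="wilson")
    pct = 100.0 * n_dead / n_treated
    flag = None if threshold_pct is None else pct < threshold_pct
    return MortalityAtDiagnosticDose(pct, 100 * lo, 100 * hi, n_treated, n_dead, flag)
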