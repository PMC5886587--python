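"""Two-method agreement statistics for scalar imaging biomarkers.

The central tool is the variance-components intraclass correlation
coefficient (ICC) for ``n`` subjects each measured by two methods (two
scanners, two field strengths, two sessions, ...):

    m_ij = A + M_j + p_i + eps_ij,     i = 1..n subjects, j = 1, 2 methods

with the method effect M, subject effect p and residual eps all random.
Variance components are estimated by maximum likelihood (Gaussian, mean
profiled out by GLS), constrained non-negative, and

    ICC = sigma_p^2 / (sigma_p^2 + sigma_M^2 + sigma_eps^2).

ICC and R^2 values are graded on the conventional bands: poor 0.00-0.30,
weak 0.31-0.50, moderate 0.51-0.70, strong 0.71-0.90, very strong
0.91-1.00.

Bland-Altman bias statistics (absolute and percent of the pairwise mean)
and an ordinary least-squares regression of method 2 on method 1 complete
the agreement report.  The model API follows the familiar fit/results
pattern: ``MethodAgreement(data).fit()`` returns :class:`AgreementResults`
with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import linregress

__all__ = [
    "PairedMeasurements",
    "MethodAgreement",
    "AgreementResults",
    "icc_random_effects",
    "bland_altman",
    "regression_summary",
    "interpret_icc",
]

_BANDS = [
    (0.305, "poor"),
    (0.505, "weak"),
    (0.705, "moderate"),
    (0.905, "strong"),
    (np.inf, "very strong"),
]


def interpret_icc(value: float) -> str:
    """Agreement band for an ICC or R^2 value (poor ... very strong)."""
    for hi, name in _BANDS:
        if value < hi:
            return name
    return "very strong"


@dataclass
class PairedMeasurements:
    """n subjects x 2 methods of one scalar quantity.

    Rows with a non-finite entry are dropped (counted in
    ``n_dropped``) — subjects must have both measurements.
    """

    values: np.ndarray  # (n, 2)
    method_labels: tuple[str, str] = ("method 1", "method 2")
    n_dropped: int = 0

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != 2:
            raise ValueError("paired measurements need exactly 2 methods (columns)")
        keep = np.all(np.isfinite(v), axis=1)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            warnings.warn(
                f"dropped {self.n_dropped} incomplete pair(s)", RuntimeWarning
            )
        v = v[keep]
        if v.shape[0] < 3:
            raise ValueError("need at least 3 complete subject pairs")
        self.values = v

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject="subject", method="method", value="value"):
        """Build from a long-format table (subject, method, value)."""
        wide = df.pivot_table(index=subject, columns=method, values=value, aggfunc="first")
        if wide.shape[1] != 2:
            raise ValueError("long table must contain exactly 2 method levels")
        return cls(wide.to_numpy(), tuple(str(c) for c in wide.columns))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _profile_negloglik(variances: np.ndarray, m: np.ndarray) -> float:
    """-2 x profile Gaussian log-likelihood over (s2_p, s2_M, s2_eps).

    The 2n-dimensional covariance (s2_p per subject block + s2_M per
    method + s2_eps I, grand mean profiled by GLS) is evaluated in closed
    form through the orthogonal per-subject sum/difference transform:

    * differences d_i = (m_i1 - m_i2)/sqrt(2) have covariance
      s2_eps I + s2_M J (the method contrast is shared across subjects);
    * sums s_i = (m_i1 + m_i2)/sqrt(2) have covariance
      (2 s2_p + s2_eps) I + s2_M J and mean A sqrt(2), whose GLS estimate
      under an exchangeable covariance is the plain mean.

    Matrices a I + b J have log-determinant (n-1) log a + log(a + n b) and
    an explicit inverse, so the evaluation is O(n).
    """
    s2p, s2m, s2e = (max(float(v), 0.0) for v in variances)
    n = m.shape[0]
    eps = 1e-12
    d = (m[:, 0] - m[:, 1]) / np.sqrt(2.0)
    s = (m[:, 0] + m[:, 1]) / np.sqrt(2.0)
    a_d = s2e + eps
    a_s = 2.0 * s2p + s2e + eps
    b = s2m

    logdet_d = (n - 1) * np.log(a_d) + np.log(a_d + n * b)
    quad_d = (d @ d - (b / (a_d + n * b)) * d.sum() ** 2) / a_d

    r = s - s.mean()
    logdet_s = (n - 1) * np.log(a_s) + np.log(a_s + n * b)
    quad_s = (r @ r) / a_s

    out = logdet_d + quad_d + logdet_s + quad_s
    return float(out) if np.isfinite(out) else 1e12


@dataclass
class AgreementResults:
    """Agreement estimates between two measurement methods."""

    n: int
    method_labels: tuple[str, str]
    grand_mean: float
    var_subject: float
    var_method: float
    var_residual: float
    icc: float
    icc_band: str
    bias: float
    bias_sd: float
    bias_pct: float
    bias_pct_sd: float
    loa: tuple[float, float]
    slope: float
    intercept: float
    r_squared: float
    r_squared_band: str
    neg2loglik: float
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "methods": list(self.method_labels),
            "variance_components": {
                "subject": self.var_subject,
                "method": self.var_method,
                "residual": self.var_residual,
            },
            "icc": self.icc,
            "icc_band": self.icc_band,
            "bias": {"mean": self.bias, "sd": self.bias_sd,
                     "pct_mean": self.bias_pct, "pct_sd": self.bias_pct_sd,
                     "limits_of_agreement": list(self.loa)},
            "regression": {"slope": self.slope, "intercept": self.intercept,
                           "r_squared": self.r_squared, "band": self.r_squared_band},
            "n_dropped": self.n_dropped,
        }

    def summary(self) -> str:
        lab1, lab2 = self.method_labels
        lines = [
            "Two-method agreement (variance-components ICC)",
            "=" * 54,
            f"subjects: {self.n}   methods: {lab1} vs {lab2}",
            f"variance components  subject={self.var_subject:.4g}  "
            f"method={self.var_method:.4g}  residual={self.var_residual:.4g}",
            f"ICC = {self.icc:.3f}  ({self.icc_band})",
            f"bias ({lab2} - {lab1}) = {self.bias:.4g} ± {self.bias_sd:.4g}"
            f"  ({self.bias_pct:.1f} ± {self.bias_pct_sd:.1f} %)",
            f"limits of agreement: [{self.loa[0]:.4g}, {self.loa[1]:.4g}]",
            f"regression: y = {self.slope:.2f}x + {self.intercept:+.2f},"
            f" R^2 = {self.r_squared:.2f}  ({self.r_squared_band})",
        ]
        return "\n".join(lines)


class MethodAgreement:
    """Random-effects agreement model for paired two-method measurements."""

    def __init__(self, data: PairedMeasurements):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **cols) -> "MethodAgreement":
        return cls(PairedMeasurements.from_long(df, **cols))

    def loglike(self, variances) -> float:
        """Profile log-likelihood at (s2_subject, s2_method, s2_residual)."""
        n2 = _profile_negloglik(np.asarray(variances, dtype=float), self.data.values)
        return -0.5 * (n2 + 2 * self.data.n * np.log(2 * np.pi))

    def fit(self, method: str = "ml") -> AgreementResults:
        """Estimate variance components (ML; REML via ``method='reml'``).

        The three variance components are constrained non-negative; the
        optimiser starts from moment estimates and from two boundary
        points so the method component, weakly identified with only two
        levels, lands cleanly on zero when the data ask for it.
        """
        m = self.data.values
        n = self.data.n
        total_var = float(m.var(ddof=1))
        if total_var == 0:
            raise ValueError("all measurements identical: total variance is zero")
        obj = {"ml": self._neg2_ml, "reml": self._neg2_reml}[method]
        subj_var = float(m.mean(axis=1).var(ddof=1))
        starts = [
            np.array([max(subj_var, 0.1 * total_var), 0.1 * total_var, 0.5 * total_var]),
            np.array([total_var, 1e-6 * total_var, 1e-3 * total_var]),
            np.array([0.5 * total_var, 0.5 * total_var, 0.5 * total_var]),
        ]
        best = None
        for x0 in starts:
            res = minimize(
                obj, x0, method="L-BFGS-B",
                bounds=[(0.0, None)] * 3,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("variance-components likelihood failed to converge")
        s2p, s2m, s2e = np.maximum(best.x, 0.0)
        tot = s2p + s2m + s2e
        icc = float(s2p / tot) if tot > 0 else 0.0
        icc = min(max(icc, 0.0), 1.0)

        ba = bland_altman(self.data)
        reg = regression_summary(self.data)
        return AgreementResults(
            n=n,
            method_labels=self.data.method_labels,
            grand_mean=float(m.mean()),
            var_subject=float(s2p),
            var_method=float(s2m),
            var_residual=float(s2e),
            icc=icc,
            icc_band=interpret_icc(icc),
            neg2loglik=float(best.fun),
            n_dropped=self.data.n_dropped,
            **ba,
            **reg,
        )

    def _neg2_ml(self, v):
        return _profile_negloglik(v, self.data.values)

    def _neg2_reml(self, v):
        # REML correction: add log(1' Sigma^-1 1) for the profiled mean;
        # in the sum/difference transform 1'Sigma^-1 1 = 2n / (a_s + n b)
        s2p, s2m, s2e = (max(float(x), 0.0) for x in v)
        n = self.data.n
        n2 = _profile_negloglik(v, self.data.values)
        a_s = 2.0 * s2p + s2e + 1e-12
        return n2 + np.log(2.0 * n / (a_s + n * s2m))


def icc_random_effects(data: PairedMeasurements, method: str = "ml") -> AgreementResults:
    """Convenience wrapper: fit the agreement model and return the results."""
    return MethodAgreement(data).fit(method=method)


def bland_altman(data: PairedMeasurements) -> dict:
    """Bias statistics: differences (method 2 - method 1), absolute and percent.

    Percent differences use the pairwise mean as denominator; pairs whose
    mean is zero are excluded from the percent statistics with a warning.
    Limits of agreement are mean +/- 1.96 SD.
    """
    m = data.values
    d = m[:, 1] - m[:, 0]
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    pm = m.mean(axis=1)
    ok = pm != 0
    if not np.all(ok):
        warnings.warn(
            f"{(~ok).sum()} pair(s) with zero mean excluded from percent bias",
            RuntimeWarning,
        )
    if ok.sum() > 0:
        pct = 100.0 * d[ok] / pm[ok]
        pct_mean = float(pct.mean())
        pct_sd = float(pct.std(ddof=1)) if ok.sum() > 1 else 0.0
    else:
        pct_mean = pct_sd = float("nan")
    return {
        "bias": mean_d,
        "bias_sd": sd_d,
        "bias_pct": pct_mean,
        "bias_pct_sd": pct_sd,
        "loa": (mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d),
    }


def regression_summary(data: PairedMeasurements) -> dict:
    """OLS of method 2 on method 1; R^2 as squared Pearson correlation."""
    x, y = data.values[:, 0], data.values[:, 1]
    if x.var() == 0:
        raise ValueError("method-1 values are constant; regression undefined")
    res = linregress(x, y)
    r2 = float(res.rvalue**2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": r2,
        "r_squared_band": interpret_icc(r2),
    }
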