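"""Linear-quadratic (LQ) survival model and the D10 endpoint.

The LQ model SF(D) = exp(-alpha*D - beta*D^2) is the standard clonogenic
dose-response. Fitting is done on the log scale, where the model is linear
in (alpha, beta) with a zero intercept (SF(0) = 1 by normalization to the
control), so the non-negativity-constrained least-squares problem is solved
exactly by NNLS rather than by a local optimizer.

D10, the dose giving 10% survival, is the positive root of
beta*D^2 + alpha*D - ln 10 = 0, written as

    D10 = 2 ln 10 / (alpha + sqrt(alpha^2 + 4 beta ln 10))

which is algebraically identical to the quadratic formula but free of
cancellation as beta -> 0 (the limit is ln 10 / alpha exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .assay import SurvivalPoint

__all__ = [
    "LQParameters",
    "D10Estimate",
    "LQSurvivalModel",
    "fit_lq",
    "predict_sf",
    "dose_at_survival",
    "d10",
    "d10_uncertainty",
]

_LN10 = float(np.log(10.0))

#: Default seed of the D10 bootstrap, fixed for reproducible reports.
DEFAULT_BOOTSTRAP_SEED = 20230822


@dataclass(frozen=True)
class LQParameters:
    """Fitted LQ coefficients.

    Attributes
    ----------
    alpha : float
        Linear coefficient, Gy^-1, >= 0.
    beta : float
        Quadratic coefficient, Gy^-2, >= 0.
    covariance : ndarray
        2x2 covariance of (alpha, beta) from the linearized fit.
    loss : float
        Residual sum of squares on the fitting (log) scale.
    """

    alpha: float
    beta: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    loss: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("LQ coefficients must be non-negative")


@dataclass(frozen=True)
class D10Estimate:
    """Dose at 10% survival with its uncertainty.

    ``method`` records how ``sd`` was obtained: "analytic" propagates the
    fit covariance through the root formula; "bootstrap" resamples
    replicates within dose levels.
    """

    d10: float
    sd: float
    method: str = "analytic"

    def __post_init__(self) -> None:
        if not self.d10 > 0:
            raise ValueError("d10 must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


class LQSurvivalModel(BaseEstimator):
    """Linear-quadratic survival regressor, scikit-learn style.

    Fits SF(D) = exp(-alpha*D - beta*D^2) by least squares on ln SF with a
    zero intercept and alpha, beta >= 0 (the constrained problem is solved
    exactly by NNLS; boundary solutions such as beta = 0 are valid fits,
    not errors).

    Parameters
    ----------
    weighting : {"none", "inverse_variance"}
        "inverse_variance" weights each point by 1/sd^2 on the log scale;
        requires ``sample_weight`` (or SurvivalPoint sd via
        :func:`fit_lq`).
    nonneg : bool
        Enforce alpha, beta >= 0 (default). Disabling reverts to ordinary
        least squares, useful only for diagnostics.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted coefficients (Gy^-1, Gy^-2).
    covariance_ : ndarray of shape (2, 2)
        Covariance of (alpha_, beta_).
    loss_ : float
        Weighted residual sum of squares on the log scale.
    d10_ : float
        Dose at 10% survival on the fitted curve.
    """

    def __init__(self, weighting: str = "none", nonneg: bool = True):
        self.weighting = weighting
        self.nonneg = nonneg

    def fit(self, dose, sf, sample_weight=None) -> "LQSurvivalModel":
        d = np.asarray(dose, dtype=float).ravel()
        s = np.asarray(sf, dtype=float).ravel()
        if d.shape != s.shape:
            raise ValueError("dose and sf must have the same length")
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(s)):
            raise ValueError("non-finite dose or survival fraction")
        if np.any(d <= 0):
            raise ValueError("fitting requires positive doses (SF(0)=1 is fixed)")
        if np.any(s <= 0):
            raise ValueError("survival fractions must be positive for log-scale fitting")
        if len(np.unique(d)) < 2:
            raise ValueError("need at least 2 distinct doses to separate alpha and beta")

        if sample_weight is None:
            w = np.ones_like(d)
        else:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if w.shape != d.shape or np.any(w < 0):
                raise ValueError("sample_weight must be non-negative, one per point")
        sw = np.sqrt(w)

        y = -np.log(s)
        X = np.column_stack([d, d * d])
        A = X * sw[:, None]
        b = y * sw
        if self.nonneg:
            theta, _ = optimize.nnls(A, b)
        else:
            theta, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = b - A @ theta
        rss = float(resid @ resid)

        n, p = len(d), 2
        sigma2 = rss / (n - p) if n > p else 0.0
        self.covariance_ = sigma2 * np.linalg.pinv(A.T @ A)
        self.alpha_ = float(theta[0])
        self.beta_ = float(theta[1])
        self.loss_ = rss
        self.n_features_in_ = 1
        return self

    def predict(self, dose):
        check_is_fitted(self, "alpha_")
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValueError("dose must be non-negative")
        return np.exp(-self.alpha_ * d - self.beta_ * d * d)

    @property
    def d10_(self) -> float:
        check_is_fitted(self, "alpha_")
        return dose_at_survival(self.params_, 0.1)

    @property
    def params_(self) -> LQParameters:
        check_is_fitted(self, "alpha_")
        return LQParameters(self.alpha_, self.beta_, self.covariance_, self.loss_)


def _weights_from_points(points: Sequence[SurvivalPoint], weighting: str) -> np.ndarray | None:
    if weighting == "none":
        return None
    if weighting != "inverse_variance":
        raise ValueError(f"unknown weighting {weighting!r}")
    # log-scale SD of SF is approximately sd/sf; zero SDs (n=1) get unit weight
    w = np.empty(len(points))
    for i, pt in enumerate(points):
        sd_log = pt.sd / pt.sf
        w[i] = 1.0 / sd_log**2 if sd_log > 0 else 1.0
    return w


def fit_lq(
    points: Sequence[SurvivalPoint],
    weighting: str = "none",
) -> LQParameters:
    """Fit the LQ model to aggregated survival points.

    Minimizes sum_i w_i (ln sf_i + alpha d_i + beta d_i^2)^2 subject to
    alpha, beta >= 0; unweighted by default, optionally inverse-variance
    weighted on the log scale.
    """
    model = LQSurvivalModel(weighting=weighting)
    model.fit(
        [p.dose for p in points],
        [p.sf for p in points],
        sample_weight=_weights_from_points(points, weighting),
    )
    return model.params_


def predict_sf(params: LQParameters, dose) -> np.ndarray | float:
    """Survival fraction exp(-alpha*D - beta*D^2) at the given dose(s)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-params.alpha * d - params.beta * d * d)
    return float(out) if np.isscalar(dose) else out


def dose_at_survival(params: LQParameters, survival: float) -> float:
    """Dose at which the fitted curve crosses the given survival level.

    Solves beta*D^2 + alpha*D = -ln(survival) with the cancellation-free
    root formula D = 2L / (alpha + sqrt(alpha^2 + 4*beta*L)).
    """
    if not 0 < survival < 1:
        raise ValueError("survival level must be in (0, 1)")
    if params.alpha == 0 and params.beta == 0:
        raise ValueError("flat curve: alpha = beta = 0 has no finite dose endpoint")
    L = -float(np.log(survival))
    return float(2.0 * L / (params.alpha + np.sqrt(params.alpha**2 + 4.0 * params.beta * L)))


def d10(params: LQParameters) -> D10Estimate:
    """D10 with analytic (delta-method) SD from the fit covariance.

    The gradient of D10 follows from implicit differentiation of
    beta*D^2 + alpha*D = ln 10: dD/dalpha = -D/(alpha + 2 beta D),
    dD/dbeta = -D^2/(alpha + 2 beta D).
    """
    dd = dose_at_survival(params, 0.1)
    denom = params.alpha + 2.0 * params.beta * dd
    grad = np.array([-dd / denom, -dd * dd / denom])
    var = float(grad @ params.covariance @ grad)
    return D10Estimate(d10=dd, sd=float(np.sqrt(max(var, 0.0))), method="analytic")


def _aggregate(replicate_sfs: Mapping[float, np.ndarray]) -> list[SurvivalPoint]:
    pts = []
    for dose, sfs in sorted(replicate_sfs.items()):
        sfs = np.asarray(sfs, dtype=float)
        sd = float(np.std(sfs, ddof=1)) if len(sfs) > 1 else 0.0
        pts.append(SurvivalPoint(dose=float(dose), sf=float(np.mean(sfs)), sd=sd, n=len(sfs)))
    return pts


def _resample_inflated(
    rng: np.random.Generator, values: np.ndarray, correct: bool
) -> np.ndarray:
    """n-of-n resample with the plug-in variance correction.

    Resampling n values plugs in the population variance (n-1)/n * s^2;
    for the tiny replicate counts of clonogenic assays (n = 2-3) that
    understates the spread materially, so resampled deviations from the
    original mean are inflated by sqrt(n/(n-1)) to restore the unbiased
    variance.
    """
    n = len(values)
    draw = values[rng.integers(0, n, size=n)]
    if not correct or n < 2:
        return draw
    center = values.mean()
    return center + np.sqrt(n / (n - 1.0)) * (draw - center)


def d10_uncertainty(
    replicate_sfs: Mapping[float, Sequence[float]],
    weighting: str = "none",
    n_boot: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    control_pe_ratios: Sequence[float] | None = None,
    variance_correction: bool = True,
    return_samples: bool = False,
):
    """Bootstrap SD of D10 by resampling replicates within dose levels.

    Each resample draws replicate SFs with replacement independently at
    every dose level, re-aggregates, refits the LQ model and recomputes
    D10. The reported ``d10`` is the point estimate on the original data;
    ``sd`` is the SD over bootstrap replicates.

    Parameters
    ----------
    replicate_sfs : mapping dose -> array of replicate SFs
        As produced by :func:`nrbe.assay.replicate_survival_fractions`.
    n_boot : int
        Number of bootstrap resamples (>= 100).
    seed : int
        Seed of the resampling generator; same seed, same SD.
    control_pe_ratios : sequence of float, optional
        Per-replicate control ratios colonies/cells_seeded. When given,
        the control tubes are resampled too and each resample's SFs are
        rescaled by PE/PE*; the plating-efficiency uncertainty is part of
        the experiment and belongs in the interval.
    variance_correction : bool
        Apply the sqrt(n/(n-1)) plug-in variance correction (see
        :func:`_resample_inflated`); on by default.
    return_samples : bool
        Also return the array of bootstrap D10 values (for percentile
        intervals).

    Raises
    ------
    RuntimeError
        If more than 10% of bootstrap refits fail.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    data = {float(d): np.asarray(v, dtype=float) for d, v in replicate_sfs.items()}
    point = dose_at_survival(fit_lq(_aggregate(data), weighting=weighting), 0.1)

    ratios = None
    pe0 = 1.0
    if control_pe_ratios is not None:
        ratios = np.asarray(control_pe_ratios, dtype=float)
        pe0 = float(ratios.mean())

    rng = np.random.default_rng(seed)
    doses = sorted(data)
    samples = np.empty(n_boot)
    failures = 0
    for i in range(n_boot):
        scale = 1.0
        if ratios is not None:
            pe_star = float(np.mean(_resample_inflated(rng, ratios, variance_correction)))
            if pe_star <= 0:
                samples[i] = np.nan
                failures += 1
                continue
            scale = pe0 / pe_star
        resampled = {
            dose: scale * _resample_inflated(rng, data[dose], variance_correction)
            for dose in doses
        }
        try:
            params = fit_lq(_aggregate(resampled), weighting=weighting)
            samples[i] = dose_at_survival(params, 0.1)
        except (ValueError, RuntimeError):
            samples[i] = np.nan
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {failures / n_boot:.1%} exceeds 10%: "
            "data too degenerate for a resampling SD"
        )
    valid = samples[np.isfinite(samples)]
    est = D10Estimate(d10=point, sd=float(np.std(valid, ddof=1)), method="bootstrap")
    return (est, valid) if return_samples else est
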