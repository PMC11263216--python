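"""Two-sample Mendelian randomization estimators.

Each method regresses outcome betas on exposure betas across independent
instruments, so the estimators are exposed in scikit-learn style: construct
with hyperparameters, ``fit(X, y, sample_weight)`` where ``X`` holds per-SNP
exposure betas, ``y`` the outcome betas aligned to the same effect allele, and
``sample_weight`` the inverse outcome variances ``1/se_out**2``; fitted
attributes carry a trailing underscore (``beta_``, ``se_``, ``pval_``, ...).

Methods
-------
IVW
    Precision-weighted mean of per-SNP Wald ratios, equivalently weighted
    least squares through the origin.  The primary method; the default
    variance model is multiplicative random effects with the residual scale
    floored at 1.
MR-Egger
    Weighted regression with an unconstrained intercept; the intercept
    estimates average directional pleiotropy.  Instruments are oriented so
    every exposure beta is positive.
Weighted median
    Weighted 50% quantile of the Wald ratios; consistent when instruments
    carrying more than half the weight are valid.  SE by parametric
    bootstrap.
Simple / weighted mode
    Mode of a Gaussian kernel density over the Wald ratios (uniform or
    precision weights); SE by the same bootstrap.

Module-level functions (:func:`ivw`, :func:`egger`, :func:`weighted_median`,
:func:`mode_estimate`, :func:`run_all_methods`) are thin wrappers that accept
a harmonized-instrument table and return :class:`MRResult` records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .gwas_io import DataError

logger = logging.getLogger(__name__)

#: normal quantile used for all 95% Wald intervals (reported as OR [95% CI])
Z95 = 1.96

METHOD_IVW = "IVW"
METHOD_EGGER = "MR-Egger"
METHOD_WM = "weighted_median"
METHOD_SIMPLE_MODE = "simple_mode"
METHOD_WEIGHTED_MODE = "weighted_mode"
ALL_METHODS = (METHOD_IVW, METHOD_EGGER, METHOD_WM, METHOD_SIMPLE_MODE, METHOD_WEIGHTED_MODE)


class DegenerateInstrumentError(DataError):
    """An instrument with zero exposure beta cannot form a Wald ratio."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: theta = beta_out/beta_exp, first-order SE."""

    snp: str
    theta: float
    se: float

    @property
    def weight(self) -> float:
        return self.se ** -2


@dataclass
class MRResult:
    """One method's causal estimate on the log-odds-per-SD-exposure scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se
        self.or_ = float(np.exp(self.beta))
        self.or_low = float(np.exp(self.ci_low))
        self.or_high = float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "or": self.or_, "ci_low": self.or_low,
            "ci_high": self.or_high, "pval": self.pval,
        }
        d.update({f"extra_{k}": v for k, v in self.extra.items()})
        return d


# ---------------------------------------------------------------------------
# input handling


def _as_xyw(X, y, sample_weight):
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError("X must be a single column of exposure betas")
        x = x[:, 0]
    y = np.asarray(y, dtype=float)
    if y.shape != x.shape:
        raise ValueError("X and y length mismatch")
    if sample_weight is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != x.shape:
            raise ValueError("sample_weight length mismatch")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("sample_weight must be positive and finite")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    return x, y, w


def _ratio_arrays(x, y, w):
    """Wald ratios and first-order SEs from betas and outcome precisions."""
    if np.any(x == 0):
        raise DegenerateInstrumentError("exposure beta of 0: Wald ratio undefined")
    se_out = w ** -0.5
    theta = y / x
    se = se_out / np.abs(x)
    return theta, se


def wald_ratio(beta_exp: float, beta_out: float, se_out: float, snp: str = "") -> RatioEstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError(f"{snp or 'SNP'}: beta_exp = 0")
    if se_out <= 0:
        raise DataError(f"{snp or 'SNP'}: se_out must be positive")
    return RatioEstimate(snp, beta_out / beta_exp, se_out / abs(beta_exp))


def wald_ratios(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios from a harmonized-instrument table."""
    x = harmonized["beta_exp"].to_numpy(float)
    y = harmonized["beta_out"].to_numpy(float)
    w = harmonized["se_out"].to_numpy(float) ** -2.0
    theta, se = _ratio_arrays(x, y, w)
    return pd.DataFrame({
        "snp": harmonized["snp"].to_numpy(),
        "theta": theta,
        "se": se,
        "weight": se ** -2.0,
    })


# ---------------------------------------------------------------------------
# estimator classes


class _MRBase(BaseEstimator):
    """Shared fit plumbing: validation, CI/OR derivation, predict."""

    method: str = ""
    min_instruments: int = 1

    def fit(self, X, y, sample_weight=None):
        x, y, w = _as_xyw(X, y, sample_weight)
        if len(x) < self.min_instruments:
            raise DataError(
                f"{self.method} needs >= {self.min_instruments} instruments, got {len(x)}"
            )
        self._fit(x, y, w)
        self.n_snp_ = int(len(x))
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.or_ = float(np.exp(self.beta_))
        self.or_low_ = float(np.exp(self.ci_low_))
        self.or_high_ = float(np.exp(self.ci_high_))
        return self

    def _fit(self, x, y, w):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return getattr(self, "intercept_", 0.0) + self.beta_ * x

    def _result_extra(self) -> dict:
        return {}

    def result_(self) -> MRResult:
        return MRResult(
            method=self.method, beta=float(self.beta_), se=float(self.se_),
            pval=float(self.pval_), n_snp=self.n_snp_, extra=self._result_extra(),
        )


def _pval_from_z(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


class IVWEstimator(_MRBase):
    """Inverse-variance-weighted estimator (WLS through the origin).

    Parameters
    ----------
    variance_model : {"multiplicative_random", "fixed"}
        ``fixed`` uses SE = (sum w_j)**-1/2 on the ratio scale;
        ``multiplicative_random`` (default) scales that SE by
        ``sqrt(max(1, Q/(J-1)))`` where Q is Cochran's Q, so heterogeneity
        widens but never narrows the interval.
    """

    method = METHOD_IVW
    min_instruments = 1

    def __init__(self, variance_model: str = "multiplicative_random"):
        self.variance_model = variance_model

    def _fit(self, x, y, w):
        if self.variance_model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown variance_model {self.variance_model!r}")
        theta, se_r = _ratio_arrays(x, y, w)
        wr = se_r ** -2.0
        beta = float(np.sum(wr * theta) / np.sum(wr))
        se_fixed = float(np.sum(wr) ** -0.5)
        J = len(x)
        q = float(np.sum(wr * (theta - beta) ** 2))
        scale = 1.0
        if self.variance_model == "multiplicative_random" and J >= 2:
            scale = max(1.0, np.sqrt(q / (J - 1)))
        self.beta_ = beta
        self.se_ = se_fixed * scale
        self.q_ = q
        self.pval_ = _pval_from_z(self.beta_, self.se_)

    def _result_extra(self) -> dict:
        return {"variance_model": self.variance_model, "cochran_q": self.q_}


class EggerEstimator(_MRBase):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are oriented so beta_exp > 0 (both betas negated otherwise);
    the intercept then estimates average directional pleiotropy.  Standard
    errors use a residual scale floored at 1 and t tests with J-2 df.
    """

    method = METHOD_EGGER
    min_instruments = 3

    def _fit(self, x, y, w):
        flip = x < 0
        x = np.where(flip, -x, x)
        y = np.where(flip, -y, y)
        J = len(x)
        sw, swx = np.sum(w), np.sum(w * x)
        swxx, swy, swxy = np.sum(w * x * x), np.sum(w * y), np.sum(w * x * y)
        det = sw * swxx - swx ** 2
        if det <= 0 or np.isclose(det / (sw * swxx), 0.0):
            raise DataError("MR-Egger design singular: no spread in exposure betas")
        slope = (sw * swxy - swx * swy) / det
        intercept = (swy - slope * swx) / sw
        resid = y - intercept - slope * x
        rss = float(np.sum(w * resid ** 2))
        sigma2 = max(1.0, rss / (J - 2))
        self.beta_ = float(slope)
        self.se_ = float(np.sqrt(sigma2 * sw / det))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(np.sqrt(sigma2 * swxx / det))
        self.rss_ = rss
        tdist = stats.t(df=J - 2)
        self.pval_ = float(2.0 * tdist.sf(abs(self.beta_) / self.se_)) if self.se_ > 0 else 0.0
        if self.intercept_se_ > 0:
            self.intercept_pval_ = float(2.0 * tdist.sf(abs(self.intercept_) / self.intercept_se_))
        else:
            self.intercept_pval_ = 0.0 if self.intercept_ != 0 else 1.0

    def _result_extra(self) -> dict:
        return {
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "intercept_pval": self.intercept_pval_,
            "rss": self.rss_,
        }


def _weighted_median(theta: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted 50% quantile (standardized cumulative weights)."""
    order = np.argsort(theta, kind="mergesort")
    t, w = theta[order], weight[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, t))


class WeightedMedianEstimator(_MRBase):
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    ``n_boot=0`` skips the bootstrap (``se_``/``pval_`` become NaN), which is
    useful in simulation studies that only need point estimates.
    """

    method = METHOD_WM
    min_instruments = 3

    def __init__(self, n_boot: int = 1000, random_state=None):
        self.n_boot = n_boot
        self.random_state = random_state

    def _fit(self, x, y, w):
        theta, se_r = _ratio_arrays(x, y, w)
        wr = se_r ** -2.0
        self.beta_ = _weighted_median(theta, wr)
        self.se_, self.pval_ = self._bootstrap(theta, se_r, wr)

    def _bootstrap(self, theta, se_r, wr):
        if self.n_boot == 0:
            return float("nan"), float("nan")
        rng = np.random.default_rng(self.random_state)
        draws = rng.normal(theta, se_r, size=(self.n_boot, len(theta)))
        ests = np.array([_weighted_median(row, wr) for row in draws])
        se = float(np.std(ests, ddof=1))
        return se, _pval_from_z(self.beta_, se)


def _kde_mode(theta_rows: np.ndarray, weight: np.ndarray, phi: float,
              n_grid: int = 512) -> np.ndarray:
    """Argmax of a weighted Gaussian KDE per row of ``theta_rows``.

    Bandwidth per row: phi * 0.9 * min(sd, IQR/1.349) * J**(-1/5), falling
    back to whichever of sd and IQR is positive; rows with no spread return
    the common value.
    """
    theta_rows = np.atleast_2d(theta_rows)
    B, J = theta_rows.shape
    sd = np.std(theta_rows, axis=1, ddof=1)
    q75, q25 = np.percentile(theta_rows, [75, 25], axis=1)
    iqr = (q75 - q25) / 1.349
    both = np.stack([sd, iqr])
    with np.errstate(invalid="ignore"):
        scale = np.where(
            np.min(both, axis=0) > 0, np.min(both, axis=0), np.max(both, axis=0)
        )
    h = phi * 0.9 * scale * J ** (-0.2)
    out = np.empty(B)
    wn = weight / np.sum(weight)
    for i in range(B):  # rows are small; keep memory bounded
        t = theta_rows[i]
        if h[i] <= 0:
            out[i] = t[0]
            continue
        grid = np.linspace(t.min() - 3 * h[i], t.max() + 3 * h[i], n_grid)
        dens = wn @ np.exp(-0.5 * ((grid[None, :] - t[:, None]) / h[i]) ** 2)
        out[i] = grid[np.argmax(dens)]
    return out


class ModeEstimator(_MRBase):
    """Mode-based estimator (simple or weighted) over the Wald ratios.

    Parameters
    ----------
    weighted : bool
        Precision weights (1/se_ratio^2) when True, uniform otherwise.
    phi : float
        Bandwidth multiplier on the modified Silverman rule.
    n_boot, random_state :
        Parametric bootstrap for the SE, as in the weighted median.
    """

    min_instruments = 3

    def __init__(self, weighted: bool = False, phi: float = 1.0,
                 n_boot: int = 1000, random_state=None):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self) -> str:  # type: ignore[override]
        return METHOD_WEIGHTED_MODE if self.weighted else METHOD_SIMPLE_MODE

    def _fit(self, x, y, w):
        theta, se_r = _ratio_arrays(x, y, w)
        wr = se_r ** -2.0 if self.weighted else np.ones_like(theta)
        if np.all(theta == theta[0]):
            self.beta_, self.se_, self.pval_ = float(theta[0]), 0.0, _pval_from_z(theta[0], 0.0)
            return
        self.beta_ = float(_kde_mode(theta[None, :], wr, self.phi)[0])
        if self.n_boot == 0:
            self.se_, self.pval_ = float("nan"), float("nan")
            return
        rng = np.random.default_rng(self.random_state)
        chunk = 128
        ests = []
        for start in range(0, self.n_boot, chunk):
            b = min(chunk, self.n_boot - start)
            draws = rng.normal(theta, se_r, size=(b, len(theta)))
            ests.append(_kde_mode(draws, wr, self.phi))
        ests = np.concatenate(ests)
        self.se_ = float(np.std(ests, ddof=1))
        self.pval_ = _pval_from_z(self.beta_, self.se_)

    def _result_extra(self) -> dict:
        return {"phi": self.phi, "n_boot": self.n_boot}


# ---------------------------------------------------------------------------
# functional wrappers over harmonized-instrument tables


def _xyw_from_harmonized(harmonized: pd.DataFrame):
    x = harmonized["beta_exp"].to_numpy(float)
    y = harmonized["beta_out"].to_numpy(float)
    w = harmonized["se_out"].to_numpy(float) ** -2.0
    return x, y, w


def ivw(harmonized: pd.DataFrame, variance_model: str = "multiplicative_random") -> MRResult:
    x, y, w = _xyw_from_harmonized(harmonized)
    return IVWEstimator(variance_model=variance_model).fit(x, y, w).result_()


def egger(harmonized: pd.DataFrame) -> MRResult:
    x, y, w = _xyw_from_harmonized(harmonized)
    return EggerEstimator().fit(x, y, w).result_()


def weighted_median(harmonized: pd.DataFrame, n_boot: int = 1000, seed=None) -> MRResult:
    x, y, w = _xyw_from_harmonized(harmonized)
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(x, y, w).result_()


def mode_estimate(harmonized: pd.DataFrame, weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed=None) -> MRResult:
    x, y, w = _xyw_from_harmonized(harmonized)
    est = ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot, random_state=seed)
    return est.fit(x, y, w).result_()


def run_all_methods(
    harmonized: pd.DataFrame,
    variance_model: str = "multiplicative_random",
    n_boot: int = 1000,
    phi: float = 1.0,
    seed=None,
) -> list[MRResult]:
    """Run every applicable method on one harmonized-instrument table.

    Methods whose instrument minimum is not met are skipped with a logged
    notice.  Fully deterministic given ``seed`` (child seeds are spawned per
    stochastic method).
    """
    J = len(harmonized)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(3)
    results: list[MRResult] = []
    if J >= 1:
        results.append(ivw(harmonized, variance_model=variance_model))
    if J >= 3:
        results.append(egger(harmonized))
        results.append(weighted_median(harmonized, n_boot=n_boot, seed=children[0]))
        results.append(mode_estimate(harmonized, weighted=False, phi=phi,
                                     n_boot=n_boot, seed=children[1]))
        results.append(mode_estimate(harmonized, weighted=True, phi=phi,
                                     n_boot=n_boot, seed=children[2]))
    else:
        logger.info("only %d instruments: skipping Egger, median and mode methods", J)
    return results


def results_table(results: Sequence[MRResult], **labels) -> pd.DataFrame:
    """Flatten MRResults to a tidy table, prefixing optional label columns."""
    rows = [{**labels, **r.to_dict()} for r in results]
    return pd.DataFrame(rows)
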