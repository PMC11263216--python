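"""Sensitivity battery for two-sample MR.

Cochran's Q for heterogeneity, the Egger intercept test for directional
pleiotropy, MR-PRESSO (global residual test, per-SNP outlier flags, and a
distortion test with outlier-corrected re-estimation), leave-one-out IVW, and
the Steiger directionality test.

The conventional "pass" reading, applied by the pipeline verdict: Q p > 0.05
and Egger intercept p > 0.05 (no detectable heterogeneity or pleiotropy),
PRESSO global p > 0.05 (no outlying residual structure), Steiger p < 0.05
with the instruments explaining more variance in the exposure than in the
outcome (orientation supported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import METHOD_IVW, EggerEstimator, IVWEstimator, MRResult, _xyw_from_harmonized
from .gwas_io import ConfigurationError, DataError

logger = logging.getLogger(__name__)


def cochran_q(theta, se) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios.

    Q = sum w_j (theta_j - theta_fixed)^2 with w_j = 1/se_j^2; df = J-1;
    p from the upper tail of chi-square(df).
    """
    theta = np.asarray(theta, float)
    w = np.asarray(se, float) ** -2.0
    if len(theta) < 2:
        raise DataError("Cochran's Q needs at least 2 ratios")
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    return q, df, float(stats.chi2.sf(q, df))


def cochran_q_harmonized(harmonized: pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q from a harmonized-instrument table."""
    theta = harmonized["beta_out"].to_numpy(float) / harmonized["beta_exp"].to_numpy(float)
    se = harmonized["se_out"].to_numpy(float) / np.abs(harmonized["beta_exp"].to_numpy(float))
    return cochran_q(theta, se)


def egger_intercept_test(harmonized: pd.DataFrame) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p) from the MR-Egger regression.

    p > 0.05 is read downstream as no detectable directional pleiotropy.
    """
    x, y, w = _xyw_from_harmonized(harmonized)
    est = EggerEstimator().fit(x, y, w)
    return est.intercept_, est.intercept_se_, est.intercept_pval_


@dataclass
class PressoResult:
    """MR-PRESSO outcome: global empirical p, flagged outliers, distortion."""

    global_pval: float
    outliers: list  # [(snp, per-SNP empirical p), ...] for flagged SNPs
    distortion_pval: float | None
    corrected: MRResult | None
    n_sim: int

    @property
    def outlier_snps(self) -> list[str]:
        return [s for s, _ in self.outliers]


def _loo_ivw_slopes(x, y, w):
    """Leave-one-out IVW (fixed-effect WLS-through-origin) slopes, vectorized."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    harmonized: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed=None,
    variance_model: str = "multiplicative_random",
) -> PressoResult:
    """MR-PRESSO: Monte-Carlo residual-sum-of-squares pleiotropy test.

    Observed RSS sums squared outcome-beta residuals around leave-one-out IVW
    predictions; the null distribution re-runs the same computation on
    ``n_sim`` parametric draws (beta_exp* ~ N(beta_exp, se_exp), beta_out* ~
    N(loo_slope*beta_exp, se_out)).  Empirical p-values use the
    (1 + #exceed)/(n_sim + 1) convention, so the smallest attainable p is
    1/(n_sim+1).  Per-SNP outliers are flagged at ``outlier_alpha``
    Bonferroni-corrected by J; if any are flagged, the distortion test
    compares the IVW shift from removing them against removing equally many
    random SNPs, and ``corrected`` re-estimates IVW on the retained set.
    """
    J = len(harmonized)
    if J < 4:
        raise DataError(f"MR-PRESSO needs >= 4 instruments, got {J}")
    x = harmonized["beta_exp"].to_numpy(float)
    y = harmonized["beta_out"].to_numpy(float)
    se_x = harmonized["se_exp"].to_numpy(float)
    se_y = harmonized["se_out"].to_numpy(float)
    w = se_y ** -2.0
    rng = np.random.default_rng(seed)

    slopes_loo = _loo_ivw_slopes(x, y, w)
    resid_obs = y - slopes_loo * x
    rss_obs = float(np.sum(resid_obs ** 2))

    bx = rng.normal(x, se_x, size=(n_sim, J))
    by = rng.normal(slopes_loo * x, se_y, size=(n_sim, J))
    sxy = np.sum(w * bx * by, axis=1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=1, keepdims=True)
    loo_sim = (sxy - w * bx * by) / (sxx - w * bx * bx)
    resid_sim = by - loo_sim * bx
    rss_sim = np.sum(resid_sim ** 2, axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_snp = (1 + np.sum(resid_sim ** 2 >= resid_obs[None, :] ** 2, axis=0)) / (n_sim + 1)
    flagged = np.where(p_snp < outlier_alpha / J)[0]
    outliers = [(harmonized["snp"].iat[i], float(p_snp[i])) for i in flagged]

    distortion_pval = None
    corrected = None
    if len(flagged) and len(flagged) < J - 1:
        keep = np.setdiff1d(np.arange(J), flagged)
        ivw_all = IVWEstimator(variance_model=variance_model).fit(x, y, w)
        ivw_kept = IVWEstimator(variance_model=variance_model).fit(x[keep], y[keep], w[keep])
        d_obs = ivw_all.beta_ - ivw_kept.beta_
        n_rand = min(n_sim, 1000)
        d_null = np.empty(n_rand)
        for i in range(n_rand):
            drop = rng.choice(J, size=len(flagged), replace=False)
            k = np.setdiff1d(np.arange(J), drop)
            b = np.sum(w[k] * x[k] * y[k]) / np.sum(w[k] * x[k] * x[k])
            d_null[i] = ivw_all.beta_ - b
        distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_rand + 1))
        corrected = ivw_kept.result_()
        corrected.extra["removed_outliers"] = [s for s, _ in outliers]
    return PressoResult(global_pval, outliers, distortion_pval, corrected, n_sim)


def leave_one_out(
    harmonized: pd.DataFrame,
    variance_model: str = "multiplicative_random",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    Flags exclusions that change the sign of the estimate or move its p-value
    across ``alpha`` relative to the all-SNP fit.
    """
    J = len(harmonized)
    if J < 2:
        raise DataError("leave-one-out needs >= 2 instruments")
    x, y, w = _xyw_from_harmonized(harmonized)
    full = IVWEstimator(variance_model=variance_model).fit(x, y, w)
    rows = []
    idx = np.arange(J)
    for j in range(J):
        keep = idx != j
        est = IVWEstimator(variance_model=variance_model).fit(x[keep], y[keep], w[keep])
        rows.append({
            "excluded_snp": harmonized["snp"].iat[j],
            "beta": est.beta_, "se": est.se_, "pval": est.pval_,
            "sign_change": bool(np.sign(est.beta_) != np.sign(full.beta_)),
            "p_crosses_alpha": bool((est.pval_ < alpha) != (full.pval_ < alpha)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: instrument variance explained per trait."""

    direction: bool  # True when instruments explain more of the exposure
    pval: float
    r2_exposure: float
    r2_outcome: float
    n_exposure: float
    n_outcome: float


def steiger(harmonized: pd.DataFrame) -> SteigerResult:
    """Steiger test of causal orientation.

    Sums per-instrument R^2 = 2 beta^2 EAF (1-EAF) on each trait (the
    outcome's on its observed log-odds scale), converts to correlations, and
    compares them with a two-sample Fisher-z test using the respective sample
    sizes.  ``direction`` True with p < 0.05 supports exposure -> outcome.
    """
    for col in ("eaf_exp", "eaf_out", "n_exp", "n_out"):
        if col not in harmonized.columns or harmonized[col].isna().any():
            raise ConfigurationError(f"Steiger test requires complete {col}")
    r2x = float(np.sum(2 * harmonized["beta_exp"] ** 2
                       * harmonized["eaf_exp"] * (1 - harmonized["eaf_exp"])))
    r2y = float(np.sum(2 * harmonized["beta_out"] ** 2
                       * harmonized["eaf_out"] * (1 - harmonized["eaf_out"])))
    nx = float(harmonized["n_exp"].mean())
    ny = float(harmonized["n_out"].mean())
    rx, ry = min(np.sqrt(r2x), 1 - 1e-12), min(np.sqrt(r2y), 1 - 1e-12)
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(1 / (nx - 3) + 1 / (ny - 3))
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(r2x > r2y, pval, r2x, r2y, nx, ny)


@dataclass
class SensitivityReport:
    """Aggregated sensitivity battery for one exposure-outcome analysis.

    Components that could not run (too few instruments) stay ``None`` and are
    treated as vacuously passing by :meth:`passes`.
    """

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_pval: float | None = None
    presso_corrected: MRResult | None = None
    loo_table: pd.DataFrame | None = None
    steiger_direction: bool | None = None
    steiger_pval: float | None = None
    r2_exposure: float | None = None
    r2_outcome: float | None = None

    def passes(self, alpha: float = 0.05) -> bool:
        """The conventional all-clear reading of the battery."""
        checks = []
        if self.q_pval is not None:
            checks.append(self.q_pval > alpha)
        if self.egger_intercept_pval is not None:
            checks.append(self.egger_intercept_pval > alpha)
        if self.presso_global_pval is not None:
            checks.append(self.presso_global_pval > alpha)
        if self.steiger_pval is not None:
            checks.append(bool(self.steiger_direction) and self.steiger_pval < alpha)
        return all(checks)

    def to_row(self) -> dict:
        return {
            "intercept": self.egger_intercept,
            "intercept_p": self.egger_intercept_pval,
            "Q": self.q_stat, "Q_df": self.q_df, "Q_p": self.q_pval,
            "presso_global_p": self.presso_global_pval,
            "presso_n_outliers": len(self.presso_outliers),
            "presso_distortion_p": self.presso_distortion_pval,
            "steiger_direction": self.steiger_direction,
            "steiger_p": self.steiger_pval,
            "r2_exposure": self.r2_exposure, "r2_outcome": self.r2_outcome,
        }


def run_sensitivity(
    harmonized: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed=None,
    variance_model: str = "multiplicative_random",
) -> SensitivityReport:
    """Run every sensitivity component its instrument count allows."""
    rep = SensitivityReport()
    J = len(harmonized)
    if J >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q_harmonized(harmonized)
        rep.loo_table = leave_one_out(harmonized, variance_model=variance_model)
    if J >= 3:
        (rep.egger_intercept, rep.egger_intercept_se,
         rep.egger_intercept_pval) = egger_intercept_test(harmonized)
    if J >= 4:
        presso = mr_presso(harmonized, n_sim=n_sim, outlier_alpha=outlier_alpha,
                           seed=seed, variance_model=variance_model)
        rep.presso_global_pval = presso.global_pval
        rep.presso_outliers = presso.outliers
        rep.presso_distortion_pval = presso.distortion_pval
        rep.presso_corrected = presso.corrected
    try:
        st = steiger(harmonized)
        rep.steiger_direction = st.direction
        rep.steiger_pval = st.pval
        rep.r2_exposure = st.r2_exposure
        rep.r2_outcome = st.r2_outcome
    except ConfigurationError as exc:
        logger.warning("Steiger test skipped: %s", exc)
    return rep
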