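"""Evidence synthesis: replication meta-analysis, verdicts, pathway ORA.

Meta-analysis combines the primary and replication causal estimates with both
a common-effect (inverse-variance fixed) and a DerSimonian-Laird
random-effects model.  The verdict encodes the screening logic used for a
metabolite panel: an exposure is called only when the primary IVW is
significant, all five methods agree in direction, the sensitivity battery is
clean, and (when a replication study is supplied) the meta-analysis remains
significant.  Pathway over-representation is a hypergeometric upper-tail test
of the called metabolites against a compound universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import METHOD_IVW, Z95, MRResult
from .gwas_io import ConfigurationError, DataError, PathwaySet
from .sensitivity import SensitivityReport

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Fixed- and random-effects combination of per-study (beta, se)."""

    beta_fixed: float
    se_fixed: float
    pval_fixed: float
    beta_random: float
    se_random: float
    pval_random: float
    tau2: float
    i2: float
    q_between: float
    q_between_pval: float
    studies: list = field(default_factory=list)  # [(beta, se), ...]

    @property
    def pval_headline(self) -> float:
        """Random-effects p when tau2 > 0, else the identical fixed p."""
        return self.pval_random if self.tau2 > 0 else self.pval_fixed


def meta_combine(studies: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed and DerSimonian-Laird random-effects meta.

    tau^2 = max(0, (Q - df)/(sum w - sum w^2/sum w)); random-effects weights
    are 1/(se^2 + tau^2); both pooled estimates get two-sided normal p-values.
    """
    if len(studies) < 2:
        raise DataError("meta-analysis needs >= 2 studies")
    beta = np.array([b for b, _ in studies], float)
    se = np.array([s for _, s in studies], float)
    if np.any(se <= 0):
        raise DataError("non-positive study SE")
    w = se ** -2.0
    bf = float(np.sum(w * beta) / np.sum(w))
    sef = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (beta - bf) ** 2))
    df = len(studies) - 1
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = float(max(0.0, (q - df) / denom)) if denom > 0 else 0.0
    if tau2 == 0.0:
        br, ser = bf, sef  # exact: zero between-study variance
    else:
        wr = 1.0 / (se ** 2 + tau2)
        br = float(np.sum(wr * beta) / np.sum(wr))
        ser = float(np.sum(wr) ** -0.5)
    i2 = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
    pf = float(2 * stats.norm.sf(abs(bf) / sef))
    pr = float(2 * stats.norm.sf(abs(br) / ser))
    return MetaResult(bf, sef, pf, br, ser, pr, tau2, i2, q,
                      float(stats.chi2.sf(q, df)), list(map(tuple, studies)))


def or_ci_to_beta_se(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (beta, se) from a published OR with 95% CI.

    beta = ln(OR); se = (ln hi - ln lo)/(2*1.96).  Warns when the log-scale
    interval is asymmetric about beta by more than 5% of its half-width
    (a sign of rounding or a non-Wald interval).
    """
    if not (0 < ci_low <= or_ <= ci_high):
        raise DataError(f"require 0 < ci_low <= OR <= ci_high, got {or_}, [{ci_low}, {ci_high}]")
    beta = float(np.log(or_))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))
    hi_half = np.log(ci_high) - beta
    lo_half = beta - np.log(ci_low)
    half = max(hi_half, lo_half)
    if half > 0 and abs(hi_half - lo_half) > 0.05 * half:
        warnings.warn(
            f"OR CI asymmetric on the log scale (halves {lo_half:.4f}/{hi_half:.4f}); "
            "se from full width may be off", stacklevel=2,
        )
    return beta, se


def beta_se_to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Inverse of :func:`or_ci_to_beta_se` (95% Wald interval)."""
    return (float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


@dataclass(frozen=True)
class PathwayTestResult:
    """Hypergeometric over-representation outcome for one pathway."""

    pathway_id: str
    name: str
    universe_size: int  # M
    pathway_size: int   # K (after intersecting with the universe)
    selected_size: int  # s
    hits: int           # k
    pval: float
    significant: bool


def pathway_ora(
    selected: Iterable[str],
    universe: Iterable[str],
    pathways: Sequence[PathwaySet],
    alpha: float = 0.1,
) -> list[PathwayTestResult]:
    """Hypergeometric upper-tail enrichment of ``selected`` within pathways.

    Each pathway's member set is intersected with the universe first;
    p = P(X >= k | M, K, s).  Results are sorted by ascending p; the
    ``significant`` flag applies p < ``alpha`` (default 0.1, the relaxed
    threshold conventional for small metabolite panels).
    """
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise DataError(f"selected compounds not in universe: {sorted(stray)}")
    M, s = len(universe), len(selected)
    out = []
    for pw in pathways:
        members = set(pw.members) & universe
        K = len(members)
        k = len(members & selected)
        pval = float(stats.hypergeom.sf(k - 1, M, K, s)) if K else 1.0
        out.append(PathwayTestResult(pw.pathway_id, pw.name, M, K, s, k,
                                     pval, pval < alpha))
    return sorted(out, key=lambda r: (r.pval, r.pathway_id))


def pathway_table(results: Sequence[PathwayTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway": r.pathway_id, "name": r.name, "M": r.universe_size,
        "K": r.pathway_size, "s": r.selected_size, "k": r.hits,
        "p": r.pval, "significant": r.significant,
    } for r in results])


CLASSIFICATIONS = (
    "pathogenic", "protective", "false_positive_direction",
    "not_significant", "not_replicated",
)


@dataclass(frozen=True)
class Verdict:
    """Screening classification for one exposure.

    Gate order: IVW significance, direction agreement across all five
    methods, the sensitivity battery, then replication.  A sensitivity
    failure is classified ``not_significant`` (the evidence is judged
    unreliable); the individual booleans preserve the distinction.
    """

    exposure_id: str
    ivw_significant: bool
    directions_consistent: bool
    sensitivity_pass: bool
    replication_meta_significant: bool | None
    beta_ivw: float
    classification: str

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "ivw_significant": self.ivw_significant,
            "directions_consistent": self.directions_consistent,
            "sensitivity_pass": self.sensitivity_pass,
            "replication_meta_significant": self.replication_meta_significant,
            "beta_ivw": self.beta_ivw,
            "classification": self.classification,
        }


def verdict(
    primary: Sequence[MRResult],
    sensitivity: SensitivityReport | None,
    meta: MetaResult | None,
    alpha: float = 0.05,
    exposure_id: str = "",
) -> Verdict:
    """Classify one exposure from its primary results and follow-up evidence.

    ``meta=None`` (no replication study) skips the replication gate;
    ``sensitivity=None`` treats the battery as vacuously passing.
    """
    by_method = {r.method: r for r in primary}
    if METHOD_IVW not in by_method:
        raise ConfigurationError("verdict requires an IVW result")
    ivw_res = by_method[METHOD_IVW]
    ivw_significant = ivw_res.pval < alpha
    betas = np.array([r.beta for r in primary])
    directions_consistent = bool(len(primary) >= 1 and np.all(np.sign(betas) == np.sign(ivw_res.beta))
                                 and np.sign(ivw_res.beta) != 0)
    sensitivity_pass = True if sensitivity is None else sensitivity.passes(alpha)
    meta_sig = None if meta is None else bool(meta.pval_headline < alpha)

    if not ivw_significant:
        cls = "not_significant"
    elif not directions_consistent:
        cls = "false_positive_direction"
    elif not sensitivity_pass:
        cls = "not_significant"
    elif meta_sig is False:
        cls = "not_replicated"
    else:
        cls = "pathogenic" if ivw_res.beta > 0 else "protective"
    return Verdict(exposure_id, bool(ivw_significant), directions_consistent,
                   bool(sensitivity_pass), meta_sig, float(ivw_res.beta), cls)
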