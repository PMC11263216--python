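"""Synthetic GWAS summary statistics with known causal ground truth.

The generator works entirely at the summary level, mirroring the structure of
a metabolite GWAS (quantitative exposure, n ~ 7,800) paired with a large
case-control outcome GWAS (log-odds scale, n > 100,000): per SNP j it draws
an effect-allele frequency, a true per-allele exposure effect, and observed
betas around the truth with sampling noise se = 1/sqrt(2 n EAF (1-EAF)) — the
standard-error of a per-allele regression coefficient for a unit-variance
trait under Hardy-Weinberg genotype variance 2 EAF (1-EAF).  The outcome's
true effect is theta * beta_exp plus an optional pleiotropic shift alpha_j on
a configurable fraction of "invalid" instruments (balanced or directional).

Allele coding stress is generated on purpose: a configurable fraction of SNPs
is palindromic (A/T or C/G) and a fraction of outcome rows has its coding
swapped and/or strand-flipped, with beta and EAF adjusted so that correct
harmonization exactly undoes the scrambling.  Independent random streams are
used for structure, sampling noise, and scrambling, so two datasets differing
only in ``allele_scramble_frac`` are otherwise draw-for-draw identical twins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset
from .instruments import COMPLEMENT, LDTable

logger = logging.getLogger(__name__)

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generator parameters for one exposure/outcome pair.

    Defaults emulate a metabolite-on-disease analysis: a metabolite exposure
    GWAS of 7,824 individuals and a case-control outcome GWAS of 10,074
    cases / 103,164 controls, ~50 candidate instruments per metabolite, and
    EAFs spread over (0.05, 0.95).  ``n_out`` is the sample size plugged
    into the SE formula; for a binary outcome on the log-odds scale the
    faithful value is the effective (harmonic) case-control size
    1/(1/n_cases + 1/n_controls) ~ 9,146, since the per-allele log-OR
    variance is (1/n_cases + 1/n_controls) / (2 EAF (1-EAF)).  Exposure
    effect magnitudes default to |beta| ~ U(0.05, 0.25) SD with random sign,
    spanning weak-to-strong instruments (per-SNP F roughly 8 to 200) as in
    a relaxed-threshold metabolite screen.

    Directional pleiotropy is applied relative to the exposure-increasing
    allele (beta_Y = theta*beta_X + sign(beta_X)*alpha_j), the orientation
    in which a nonzero mean biases MR and is estimable by the Egger
    intercept; under random allele coding an unoriented shift would cancel.
    """

    n_snp: int = 50
    theta: float = 0.0
    n_exp: int = 7824
    n_out: int = 9146
    eaf_range: tuple = (0.05, 0.95)
    # ("uniform", lo, hi) magnitude with random sign | ("fixed", mag) | ("normal", sd)
    beta_exp_dist: tuple = ("uniform", 0.05, 0.25)
    pleiotropy: tuple = ("none",)  # | ("balanced", sd) | ("directional", mean, sd)
    prop_invalid: float = 0.0
    palindrome_frac: float = 0.1
    allele_scramble_frac: float = 0.0
    ld_blocks: list = field(default_factory=list)  # [(block_size, r2), ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1 or self.n_exp < 1 or self.n_out < 1:
            raise ValueError("n_snp and sample sizes must be positive")
        for frac in (self.prop_invalid, self.palindrome_frac, self.allele_scramble_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {frac}")
        lo, hi = self.eaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError(f"eaf_range must satisfy 0 < low < high < 1, got {self.eaf_range}")
        if sum(size for size, _ in self.ld_blocks) > self.n_snp:
            raise ValueError("ld_blocks cover more SNPs than n_snp")


@dataclass
class SimTruth:
    """Ground-truth ledger for recovery tests."""

    theta: float
    beta_x_true: pd.Series  # true per-allele exposure effects, by snp id
    beta_y_true: pd.Series  # theta*beta_x + alpha, by snp id
    alpha: pd.Series        # per-SNP pleiotropic effects, by snp id
    eaf: pd.Series
    invalid_ids: list
    palindromic_ids: list
    scrambled_ids: list


def _draw_beta_exp(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(0.0, dist[1], size)
    if kind == "fixed":
        return dist[1] * rng.choice([-1.0, 1.0], size)
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size) * rng.choice([-1.0, 1.0], size)
    raise ValueError(f"unknown beta_exp_dist {dist!r}")


def _draw_alpha(rng: np.random.Generator, pleiotropy: tuple, invalid: np.ndarray,
                size: int) -> np.ndarray:
    alpha = np.zeros(size)
    kind = pleiotropy[0]
    if kind == "none" or not invalid.any():
        return alpha
    if kind == "balanced":
        alpha[invalid] = rng.normal(0.0, pleiotropy[1], int(invalid.sum()))
    elif kind == "directional":
        alpha[invalid] = rng.normal(pleiotropy[1], pleiotropy[2], int(invalid.sum()))
    else:
        raise ValueError(f"unknown pleiotropy regime {pleiotropy!r}")
    return alpha


def _positions(config: SimConfig) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Chromosome/position layout: LD-block members adjacent, all else far apart."""
    J = config.n_snp
    chrom = np.empty(J, dtype=object)
    pos = np.empty(J, dtype=np.int64)
    spans: list[tuple[int, int]] = []  # [start, stop) index ranges of blocks
    i = 0
    slot = 0
    for size, _ in config.ld_blocks:
        spans.append((i, i + size))
        c = str(slot % 22 + 1)
        base = 1_000_000 + (slot // 22) * 5_000_000
        for j in range(size):
            chrom[i], pos[i] = c, base + j * 10_000
            i += 1
        slot += 1
    while i < J:
        chrom[i] = str(slot % 22 + 1)
        pos[i] = 1_000_000 + (slot // 22) * 5_000_000
        i += 1
        slot += 1
    return chrom, pos, spans


def simulate_pair(
    config: SimConfig,
    snp_prefix: str = "snp",
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> tuple[SummaryDataset, SummaryDataset, LDTable, SimTruth]:
    """Generate one exposure/outcome summary-statistic pair with ground truth.

    Returns ``(exposure, outcome, ld, truth)``.  Same config (including seed)
    gives byte-identical datasets.
    """
    J = config.n_snp
    s_struct, s_noise, s_scramble = np.random.SeedSequence(config.seed).spawn(3)
    rng_struct = np.random.default_rng(s_struct)
    rng_noise = np.random.default_rng(s_noise)
    rng_scramble = np.random.default_rng(s_scramble)

    snp = np.array([f"{snp_prefix}{j:05d}" for j in range(J)])
    chrom, pos, block_spans = _positions(config)
    eaf = rng_struct.uniform(*config.eaf_range, J)
    beta_x = _draw_beta_exp(rng_struct, config.beta_exp_dist, J)

    # LD blocks: correlated true effects with the declared pairwise r2
    ld = LDTable()
    for (start, stop), (_, r2) in zip(block_spans, config.ld_blocks):
        lead = beta_x[start]
        noise = _draw_beta_exp(rng_struct, config.beta_exp_dist, stop - start - 1)
        beta_x[start + 1:stop] = np.sqrt(r2) * lead + np.sqrt(1 - r2) * noise
        for a in range(start, stop):
            for b in range(a + 1, stop):
                ld.set(snp[a], snp[b], r2)

    n_invalid = int(round(config.prop_invalid * J))
    invalid = np.zeros(J, dtype=bool)
    invalid[rng_struct.choice(J, n_invalid, replace=False)] = True
    alpha = _draw_alpha(rng_struct, config.pleiotropy, invalid, J)
    # pleiotropy oriented to the exposure-increasing allele (see class docstring)
    beta_y = config.theta * beta_x + np.where(beta_x >= 0, 1.0, -1.0) * alpha

    n_pal = int(round(config.palindrome_frac * J))
    pal_idx = rng_struct.choice(J, n_pal, replace=False)
    is_pal = np.zeros(J, dtype=bool)
    is_pal[pal_idx] = True
    pair_choice = rng_struct.integers(0, 8, J)
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    for j in range(J):
        pairs = _PALINDROMIC_PAIRS if is_pal[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pairs[pair_choice[j] % len(pairs)]

    se_x = 1.0 / np.sqrt(2.0 * config.n_exp * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_out * eaf * (1.0 - eaf))
    bx_obs = rng_noise.normal(beta_x, se_x)
    by_obs = rng_noise.normal(beta_y, se_y)

    exposure = pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": bx_obs, "se": se_x,
        "pval": 2 * stats.norm.sf(np.abs(bx_obs) / se_x),
        "n": np.full(J, config.n_exp, dtype=np.int64),
    })
    outcome = exposure[["snp", "chr", "pos"]].copy()
    outcome["effect_allele"] = ea.copy()
    outcome["other_allele"] = oa.copy()
    outcome["eaf"] = eaf.copy()
    outcome["beta"] = by_obs
    outcome["se"] = se_y
    outcome["pval"] = 2 * stats.norm.sf(np.abs(by_obs) / se_y)
    outcome["n"] = np.full(J, config.n_out, dtype=np.int64)

    # scramble outcome allele coding; harmonization must exactly undo this
    n_scramble = int(round(config.allele_scramble_frac * J))
    scr_idx = rng_scramble.choice(J, n_scramble, replace=False)
    ops = rng_scramble.integers(0, 3, n_scramble)  # 0=swap, 1=flip, 2=both
    scrambled_ids = []
    for i, op in zip(scr_idx, ops):
        if is_pal[i]:
            op = 0  # flipping a palindrome's letters is a no-op; swap instead
        eai, oai = outcome.at[i, "effect_allele"], outcome.at[i, "other_allele"]
        if op in (0, 2):
            eai, oai = oai, eai
            outcome.at[i, "beta"] = -outcome.at[i, "beta"]
            outcome.at[i, "eaf"] = 1.0 - outcome.at[i, "eaf"]
        if op in (1, 2):
            eai, oai = COMPLEMENT[eai], COMPLEMENT[oai]
        outcome.at[i, "effect_allele"], outcome.at[i, "other_allele"] = eai, oai
        scrambled_ids.append(snp[i])

    truth = SimTruth(
        theta=config.theta,
        beta_x_true=pd.Series(beta_x, index=snp),
        beta_y_true=pd.Series(beta_y, index=snp),
        alpha=pd.Series(alpha, index=snp),
        eaf=pd.Series(eaf, index=snp),
        invalid_ids=list(snp[invalid]),
        palindromic_ids=list(snp[is_pal]),
        scrambled_ids=scrambled_ids,
    )
    return (
        SummaryDataset(exposure_id, "quantitative", exposure),
        SummaryDataset(outcome_id, "binary", outcome),
        ld,
        truth,
    )


@dataclass
class PanelSim:
    """A multi-exposure screen: per-metabolite exposures, a shared outcome."""

    exposures: list  # list[SummaryDataset]
    outcome: SummaryDataset
    replication: SummaryDataset | None
    ld: LDTable
    truths: dict  # exposure trait_id -> SimTruth
    causal_ids: list
    dropout_ids: list  # exposures with no SNP overlap in the outcome


def simulate_panel(
    n_exposures: int,
    n_causal: int,
    base: SimConfig,
    theta_causal: float = 0.3,
    include_dropout: bool = True,
    replication_n: int | None = 11_418,
) -> PanelSim:
    """Simulate a metabolite-panel screen against one shared outcome GWAS.

    ``n_causal`` exposures receive ``theta_causal``; the rest are null.  When
    ``include_dropout`` and there is at least one null exposure, the last
    exposure's SNPs are withheld from the outcome so the pipeline exercises
    its zero-overlap skip path.  ``replication_n`` adds an independent second
    outcome GWAS (new sampling noise around the same true effects) of that
    effective sample size; the default scales the primary outcome's
    effective size by 141,355/113,238, emulating a somewhat larger
    replication cohort with the same case fraction.  None disables it.
    """
    if n_causal > n_exposures:
        raise ValueError("n_causal must be <= n_exposures")
    seeds = np.random.SeedSequence(base.seed).spawn(n_exposures + 1)
    rng_rep = np.random.default_rng(seeds[-1])

    exposures, truths = [], {}
    ld = LDTable()
    outcome_frames, rep_frames = [], []
    causal_ids, dropout_ids = [], []
    dropout_index = n_exposures - 1 if include_dropout and n_exposures > n_causal else None

    for i in range(n_exposures):
        causal = i < n_causal
        cfg = replace(
            base,
            theta=theta_causal if causal else 0.0,
            seed=int(seeds[i].generate_state(1)[0] % (2 ** 31)),
        )
        trait = f"metabolite_{i:03d}"
        exp, out, ld_i, truth = simulate_pair(
            cfg, snp_prefix=f"e{i}_snp", exposure_id=trait, outcome_id="outcome",
        )
        exposures.append(exp)
        truths[trait] = truth
        for (a, b), r2 in ld_i._r2.items():
            ld.set(a, b, r2)
        if causal:
            causal_ids.append(trait)
        if i == dropout_index:
            dropout_ids.append(trait)
            continue  # withhold this exposure's SNPs from the outcome
        outcome_frames.append(out.records)
        if replication_n is not None:
            rep = out.records.copy()
            eaf = truth.eaf.to_numpy()
            se_rep = 1.0 / np.sqrt(2.0 * replication_n * eaf * (1.0 - eaf))
            b_rep = rng_rep.normal(truth.beta_y_true.to_numpy(), se_rep)
            rep["beta"] = b_rep
            rep["se"] = se_rep
            rep["pval"] = 2 * stats.norm.sf(np.abs(b_rep) / se_rep)
            rep["n"] = np.int64(replication_n)
            # replication uses the exposure's (unscrambled) allele coding
            exp_rec = exp.records
            rep["effect_allele"] = exp_rec["effect_allele"].to_numpy()
            rep["other_allele"] = exp_rec["other_allele"].to_numpy()
            rep["eaf"] = exp_rec["eaf"].to_numpy()
            rep_frames.append(rep)

    outcome = SummaryDataset(
        "outcome", "binary", pd.concat(outcome_frames, ignore_index=True),
    )
    replication = None
    if replication_n is not None:
        replication = SummaryDataset(
            "outcome_replication", "binary", pd.concat(rep_frames, ignore_index=True),
        )
    return PanelSim(exposures, outcome, replication, ld, truths,
                    causal_ids, dropout_ids)
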