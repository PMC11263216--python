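"""Instrumental-variable selection and allele harmonization.

Selection follows the standard summary-statistics workflow for metabolite
exposures: a relaxed genome-wide threshold (p < 1e-5), greedy LD clumping
(r2 > 0.01 within 500 kb removed), and an instrument-strength filter dropping
SNPs with F < 10, where F = (n - k - 1) R^2 / (k (1 - R^2)) and the per-SNP
variance explained is R^2 = 2 beta^2 EAF (1 - EAF) on a unit-variance trait
scale.

Harmonization aligns outcome betas to the exposure's effect allele, resolving
swapped and complementary-strand codings, and excludes palindromic SNPs (A/T
or C/G) whose effect-allele frequency is intermediate — inside (0.42, 0.58) —
because their strand cannot be inferred from frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import ConfigurationError, DataError, SummaryDataset

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of a harmonized-instrument table
HARMONIZED_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "eaf_out", "n_out",
    "harmonization_action",
]


class LDTable:
    """Sparse symmetric pairwise r-squared map between SNPs.

    Absent pairs default to ``default_r2`` (0: assumed independent); the
    diagonal is implicitly 1.
    """

    def __init__(self, pairs=None, default_r2: float = 0.0):
        self._r2: dict[tuple[str, str], float] = {}
        self.default_r2 = float(default_r2)
        if pairs is not None:
            for a, b, r2 in pairs:
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise DataError(f"r2 for ({a},{b}) out of [0,1]: {r2}")
        if a != b:
            self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), self.default_r2)

    def has(self, a: str, b: str) -> bool:
        return a == b or self._key(a, b) in self._r2

    def __len__(self) -> int:
        return len(self._r2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDTable":
        return cls(zip(df["snp_a"], df["snp_b"], df["r2"]))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "LDTable":
        df = pd.read_csv(Path(path), sep="\t")
        return cls.from_frame(df)


@dataclass(frozen=True)
class InstrumentStrength:
    """Instrument-strength summary for one SNP: variance explained and F."""

    snp: str
    r2: float
    f_stat: float
    n: int
    k: int


def select_by_pvalue(
    dataset: SummaryDataset, threshold: float = 1e-5
) -> SummaryDataset | None:
    """Keep records with p strictly below ``threshold`` (order preserved).

    Returns ``None`` (with a logged warning) when nothing passes, since a
    :class:`SummaryDataset` is non-empty by contract.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"p-value threshold must be in [0,1], got {threshold}")
    mask = dataset.records["pval"] < threshold
    n_kept = int(mask.sum())
    if n_kept == 0:
        logger.warning("%s: no SNPs pass p < %g", dataset.trait_id, threshold)
        return None  # type: ignore[return-value]
    return dataset.subset(mask)


def clump(
    dataset: SummaryDataset,
    ld: LDTable | None = None,
    r2_max: float = 0.01,
    window_bp: int = 500_000,
) -> SummaryDataset:
    """Greedy LD clumping: keep the most significant SNP, drop its neighbours.

    SNPs are visited by ascending p (ties: smaller se, then snp id); each kept
    SNP removes all remaining SNPs on the same chromosome within ``window_bp``
    whose pairwise r2 with it exceeds ``r2_max`` (strict >).  Pairs absent
    from the LD table are treated as r2 = ``ld.default_r2`` (0 by default)
    with a one-time warning.
    """
    df = dataset.records
    if df["pos"].isna().any() or df["chr"].isna().any():
        raise ConfigurationError("clumping requires chrom and pos on every record")
    ld = ld if ld is not None else LDTable()
    order = df.sort_values(["pval", "se", "snp"], kind="mergesort")
    chrom = df.set_index("snp")["chr"].astype(str).to_dict()
    pos = df.set_index("snp")["pos"].to_dict()

    remaining = list(order["snp"])
    kept: list[str] = []
    warned_missing = False
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for other in remaining:
            if chrom[other] == chrom[best] and abs(pos[other] - pos[best]) <= window_bp:
                if not ld.has(best, other) and not warned_missing:
                    logger.warning(
                        "LD table has no entry for some in-window pairs; "
                        "treating them as r2=%g", ld.default_r2,
                    )
                    warned_missing = True
                if ld.r2(best, other) > r2_max:
                    continue  # clumped away
            survivors.append(other)
        remaining = survivors
    keep_mask = df["snp"].isin(kept)
    logger.info("%s: clumping kept %d of %d SNPs", dataset.trait_id, len(kept), len(df))
    return dataset.subset(keep_mask)


def compute_f(
    dataset: SummaryDataset,
    k_mode: str = "per_snp",
    r2_method: str = "eaf",
) -> list[InstrumentStrength]:
    """Instrument strength per SNP.

    ``r2_method='eaf'`` uses R^2 = 2 beta^2 EAF (1-EAF); ``'tstat'`` uses
    t^2/(t^2 + n - 2) with t = beta/se.  ``k_mode='per_snp'`` evaluates
    F = (n-2) R^2/(1-R^2) per SNP (k=1); ``'joint'`` sums R^2 over the J
    instruments and uses k=J, giving one joint F shared by all SNPs.
    """
    df = dataset.records
    n = df["n"].to_numpy(float)
    if r2_method == "eaf":
        r2 = 2.0 * df["beta"].to_numpy(float) ** 2 * df["eaf"].to_numpy(float) * (
            1.0 - df["eaf"].to_numpy(float)
        )
    elif r2_method == "tstat":
        t2 = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
        r2 = t2 / (t2 + n - 2.0)
    else:
        raise ConfigurationError(f"unknown r2_method {r2_method!r}")
    if np.any(r2 >= 1.0):
        offenders = df.loc[r2 >= 1.0, "snp"].tolist()
        raise DataError(f"per-SNP R^2 >= 1 for {offenders}")

    out: list[InstrumentStrength] = []
    if k_mode == "per_snp":
        k = 1
        f = (n - k - 1) * r2 / (k * (1.0 - r2))
        for snp, r2_j, f_j, n_j in zip(df["snp"], r2, f, n):
            out.append(InstrumentStrength(snp, float(r2_j), float(f_j), int(n_j), k))
    elif k_mode == "joint":
        k = len(df)
        r2_tot = float(np.sum(r2))
        if r2_tot >= 1.0:
            raise DataError(f"joint R^2 >= 1 ({r2_tot:.3f})")
        for snp, r2_j, n_j in zip(df["snp"], r2, n):
            f_joint = (n_j - k - 1) * r2_tot / (k * (1.0 - r2_tot))
            out.append(InstrumentStrength(snp, float(r2_j), float(f_joint), int(n_j), k))
    else:
        raise ConfigurationError(f"unknown k_mode {k_mode!r}")
    return out


def filter_weak(
    dataset: SummaryDataset,
    strengths: list[InstrumentStrength],
    f_min: float = 10.0,
) -> SummaryDataset | None:
    """Drop SNPs with F strictly below ``f_min`` (weak instruments).

    Returns ``None`` (with a logged warning) when every instrument is weak.
    """
    keep = {s.snp for s in strengths if s.f_stat >= f_min}
    mask = dataset.records["snp"].isin(keep)
    if not mask.any():
        logger.warning("%s: all instruments weak (F < %g)", dataset.trait_id, f_min)
        return None  # type: ignore[return-value]
    return dataset.subset(mask)


def _is_palindromic(ea: np.ndarray, oa: np.ndarray) -> np.ndarray:
    comp = np.vectorize(COMPLEMENT.get)
    return comp(ea) == oa


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_low: float = 0.42,
    palindrome_eaf_high: float = 0.58,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome betas to the exposure's effect allele per shared SNP.

    Returns ``(harmonized, exclusions)``:

    * ``harmonized`` — :data:`HARMONIZED_COLUMNS`, one row per retained SNP,
      both betas referring to the exposure's effect allele.
    * ``exclusions`` — columns ``snp, stage, reason`` for every dropped SNP
      (reasons: ``palindromic_intermediate_eaf``, ``allele_mismatch``).

    Non-palindromic SNPs are matched directly, with swapped allele order
    (negate beta, flip EAF), with complementary-strand relabelling, or both.
    Palindromic SNPs carry no strand information in their letters: if either
    trait's EAF lies strictly inside the intermediate window they are
    excluded; otherwise EAF concordance decides (EAFs on opposite sides of
    0.5 imply a swap).
    """
    exp = exposure.records.add_suffix("_exp").rename(columns={"snp_exp": "snp"})
    out = outcome.records.add_suffix("_out").rename(columns={"snp_out": "snp"})
    m = exp.merge(out, on="snp", how="inner")
    if len(m) == 0:
        return (
            pd.DataFrame(columns=HARMONIZED_COLUMNS),
            pd.DataFrame(columns=["snp", "stage", "reason"]),
        )

    ea_x = m["effect_allele_exp"].to_numpy(str)
    oa_x = m["other_allele_exp"].to_numpy(str)
    ea_y = m["effect_allele_out"].to_numpy(str)
    oa_y = m["other_allele_out"].to_numpy(str)
    comp = np.vectorize(COMPLEMENT.get)

    pal = _is_palindromic(ea_x, oa_x)
    beta_out = m["beta_out"].to_numpy(float).copy()
    eaf_out = m["eaf_out"].to_numpy(float).copy()
    action = np.full(len(m), "", dtype=object)
    drop_reason = np.full(len(m), "", dtype=object)

    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    flip_same = (comp(ea_y) == ea_x) & (comp(oa_y) == oa_x)
    flip_swapped = (comp(ea_y) == oa_x) & (comp(oa_y) == ea_x)

    # non-palindromic resolution by allele letters
    np_mask = ~pal
    action[np_mask & same] = "unchanged"
    action[np_mask & ~same & swapped] = "swapped"
    action[np_mask & ~same & ~swapped & flip_same] = "strand_flipped"
    action[np_mask & ~same & ~swapped & ~flip_same & flip_swapped] = "swapped_and_flipped"
    drop_reason[np_mask & (action == "")] = "allele_mismatch"
    negate = np.isin(action, ("swapped", "swapped_and_flipped"))
    beta_out[negate] = -beta_out[negate]
    eaf_out[negate] = 1.0 - eaf_out[negate]

    # palindromic: letters are ambiguous (A/T == T/A == strand flip)
    pal_pair_ok = pal & (same | swapped)
    drop_reason[pal & ~pal_pair_ok] = "allele_mismatch"
    eaf_x = m["eaf_exp"].to_numpy(float)
    inter_x = (eaf_x > palindrome_eaf_low) & (eaf_x < palindrome_eaf_high)
    inter_y = (eaf_out > palindrome_eaf_low) & (eaf_out < palindrome_eaf_high)
    pal_inter = pal_pair_ok & (inter_x | inter_y)
    drop_reason[pal_inter] = "palindromic_intermediate_eaf"
    pal_keep = pal_pair_ok & ~pal_inter
    discordant = pal_keep & ((eaf_x - 0.5) * (eaf_out - 0.5) < 0)
    beta_out[discordant] = -beta_out[discordant]
    eaf_out[discordant] = 1.0 - eaf_out[discordant]
    action[pal_keep & discordant] = "swapped"
    action[pal_keep & ~discordant] = "unchanged"

    keep = drop_reason == ""
    harmonized = pd.DataFrame({
        "snp": m["snp"],
        "chr": m["chr_exp"].astype(str),
        "pos": m["pos_exp"],
        "effect_allele": ea_x,
        "other_allele": oa_x,
        "beta_exp": m["beta_exp"].to_numpy(float),
        "se_exp": m["se_exp"].to_numpy(float),
        "eaf_exp": eaf_x,
        "n_exp": m["n_exp"],
        "beta_out": beta_out,
        "se_out": m["se_out"].to_numpy(float),
        "eaf_out": eaf_out,
        "n_out": m["n_out"],
        "harmonization_action": action,
    }).loc[keep].reset_index(drop=True)

    exclusions = pd.DataFrame({
        "snp": m.loc[~keep, "snp"],
        "stage": "harmonize",
        "reason": drop_reason[~keep],
    }).reset_index(drop=True)
    if len(exclusions):
        logger.info(
            "harmonize(%s ~ %s): excluded %d SNPs (%s)",
            exposure.trait_id, outcome.trait_id, len(exclusions),
            exclusions["reason"].value_counts().to_dict(),
        )
    return harmonized, exclusions
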