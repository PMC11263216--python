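"""Read, validate and write GWAS summary statistics and pathway-set files.

The canonical in-memory container is :class:`SummaryDataset`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per SNP.  All betas and effect
allele frequencies are interpreted relative to ``effect_allele``; strand issues
are resolved later, during harmonization, never at read time.  External column
dialects are mapped onto the canonical schema via ``column_map``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics TSV dialect
CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VALID_ALLELES = frozenset({"A", "C", "G", "T"})


class ConfigurationError(ValueError):
    """A required column or configuration key is missing or invalid."""


class DataError(ValueError):
    """The data content violates a precondition (e.g. empty after filtering)."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with a trait.

    ``beta`` is the per-effect-allele effect: log-odds for a binary trait,
    SD units for a quantitative metabolite.
    """

    snp: str
    chr: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int


@dataclass
class SummaryDataset:
    """A validated set of per-SNP summary associations for one trait.

    ``records`` holds the canonical columns (:data:`CANONICAL_COLUMNS`); rows
    are unique by ``snp``.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"records missing canonical columns: {missing}")
        if len(self.records) == 0:
            raise DataError(f"dataset {self.trait_id!r} has no records")
        if self.records["snp"].duplicated().any():
            dups = self.records.loc[self.records["snp"].duplicated(), "snp"].tolist()
            raise DataError(f"duplicate snp ids in {self.trait_id!r}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def iter_records(self) -> Iterable[AssociationRecord]:
        for row in self.records.itertuples(index=False):
            yield AssociationRecord(
                snp=row.snp, chr=str(row.chr), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                pval=float(row.pval), n=int(row.n),
            )

    def subset(self, mask_or_index) -> "SummaryDataset":
        """Row-subset preserving trait metadata (raises if empty)."""
        sub = self.records.loc[mask_or_index].reset_index(drop=True)
        return SummaryDataset(self.trait_id, self.trait_type, sub)


@dataclass(frozen=True)
class PathwaySet:
    """A named pathway and its member compound IDs."""

    pathway_id: str
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"pathway {self.pathway_id!r} has no members")


def _row_validity_mask(df: pd.DataFrame) -> pd.Series:
    """True where a row satisfies every hard record invariant."""
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES) & (ea != oa)
    ok &= df["se"].gt(0) & np.isfinite(df["se"])
    ok &= df["eaf"].gt(0) & df["eaf"].lt(1)
    ok &= df["pval"].gt(0) & df["pval"].le(1)
    ok &= df["n"].gt(0)
    ok &= np.isfinite(df["beta"])
    ok &= df["pos"].notna()
    return ok.fillna(False)


def _warn_pz_inconsistency(df: pd.DataFrame, trait_id: str) -> None:
    """Warn when a published p disagrees with the |beta/se| z by >2x in -log10.

    Rounded published p-values routinely disagree a little; a factor-2 gap in
    -log10 flags likely unit or column mix-ups without rejecting the row.
    """
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"] / df["se"])
        p_expected = 2.0 * stats.norm.sf(z)
        lp_obs = -np.log10(np.clip(df["pval"].to_numpy(float), 1e-300, 1.0))
        lp_exp = -np.log10(np.clip(p_expected, 1e-300, 1.0))
    ratio = (lp_obs + 1e-12) / (lp_exp + 1e-12)
    bad = (ratio > 2.0) | (ratio < 0.5)
    n_bad = int(np.sum(bad & (np.maximum(lp_obs, lp_exp) > 1.0)))
    if n_bad:
        logger.warning(
            "%s: %d rows with p-value inconsistent with beta/se z-score "
            "(>2x in -log10); kept as published.", trait_id, n_bad,
        )


def validate_frame(df: pd.DataFrame, trait_id: str = "<unnamed>") -> pd.DataFrame:
    """Drop rows violating record invariants, logging the dropped count."""
    mask = _row_validity_mask(df)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.warning("%s: dropped %d invalid rows during validation", trait_id, n_drop)
    out = df.loc[mask].copy()
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()
    _warn_pz_inconsistency(out, trait_id)
    return out.reset_index(drop=True)


def read_summary(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = "\t",
    trait_id: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a validated dataset.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    column_map : mapping, optional
        ``{canonical_field: actual_column_name}`` for files in a foreign
        dialect; unmapped canonical names are looked up verbatim.
    sep : str
        Field delimiter (tab by default).
    trait_id, trait_type :
        Trait metadata; ``trait_id`` defaults to the file stem.

    Rows failing the record invariants are dropped with a logged count; an
    empty result raises :class:`DataError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory columns {missing} (have {list(raw.columns)})"
        )
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    df["chr"] = df["chr"].astype(str)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype("Int64")
    df = validate_frame(df, trait_id or path.stem)
    if len(df) == 0:
        raise DataError(f"{path}: no valid records after validation")
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return SummaryDataset(trait_id or path.stem, trait_type, df)


def write_summary(dataset: SummaryDataset, path) -> None:
    """Write a dataset as canonical tab-separated text (round-trip exact)."""
    if len(dataset) == 0:  # unreachable through the constructor; guard anyway
        raise DataError("refusing to write an empty dataset")
    df = dataset.records[CANONICAL_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_pathways(path) -> list[PathwaySet]:
    """Read GMT-style pathway sets: ``pathway_id<TAB>name<TAB>member...``.

    Members may be tab- or comma-separated; duplicates within a line are
    deduplicated.  A line with no members is a parse error naming the line.
    """
    path = Path(path)
    out: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected pathway_id, name, members")
            pathway_id, name = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            for tok in fields[2:]:
                members.extend(m.strip() for m in tok.split(",") if m.strip())
            if not members:
                raise DataError(f"{path}:{lineno}: pathway {pathway_id!r} has no members")
            out.append(PathwaySet(pathway_id, name, frozenset(members)))
    return out


def write_pathways(pathways: Sequence[PathwaySet], path) -> None:
    """Write pathway sets in the same GMT-style dialect read_pathways accepts."""
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")
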