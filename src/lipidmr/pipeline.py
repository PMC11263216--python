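"""End-to-end orchestration of the bidirectional MR screen.

``run_forward`` analyses each metabolite exposure against the outcome GWAS:
p-value selection, LD clumping, F-statistic filtering, harmonization, the
five MR methods, the sensitivity battery, optional replication plus
meta-analysis, and a verdict per exposure.  ``run_reverse`` swaps the roles
(the disease as exposure, each metabolite as outcome) with identical
instrument criteria and writes under a separate subdirectory so forward and
reverse runs never share an output path.

All stochastic components derive their streams from one run seed; reruns with
the same config produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, instruments, sensitivity, synthesis
from .gwas_io import ConfigurationError, SummaryDataset, read_pathways, read_summary
from .instruments import LDTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, method settings, and file locations for one run.

    Defaults are the conventional metabolite-MR settings: instrument p < 1e-5,
    clump r2 0.01 within 500 kb, drop F < 10, IVW significance at 0.05,
    pathway significance at 0.1, palindrome EAF window (0.42, 0.58).
    """

    exposure_paths: list = field(default_factory=list)
    outcome_path: str | None = None
    replication_outcome_path: str | None = None
    ld_path: str | None = None
    pathway_gmt: str | None = None
    compound_map: str | None = None  # TSV: trait_id <TAB> compound_id
    out_dir: str = "lipidmr_out"
    p_threshold: float = 1e-5
    clump_r2: float = 0.01
    clump_kb: float = 500.0
    f_min: float = 10.0
    f_k_mode: str = "per_snp"
    alpha: float = 0.05
    pathway_alpha: float = 0.1
    palindrome_window: tuple = (0.42, 0.58)
    variance_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ConfigurationError(f"p_threshold out of range: {self.p_threshold}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigurationError(f"clump_r2 out of range: {self.clump_r2}")
        lo, hi = self.palindrome_window
        if not 0.0 < lo < hi < 1.0:
            raise ConfigurationError(f"bad palindrome_window: {self.palindrome_window}")
        if self.seed is None and (self.n_boot > 0 or self.presso_n_sim > 0):
            raise ConfigurationError("a seed is required when stochastic components run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "palindrome_window" in raw:
            raw["palindrome_window"] = tuple(raw["palindrome_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palindrome_window"] = list(self.palindrome_window)
        return d


@dataclass
class ExposureAnalysis:
    """Everything computed for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    counts: dict  # stage -> SNP count (monotone non-increasing)
    skip_reason: str | None = None
    results: list = field(default_factory=list)          # list[MRResult]
    replication_results: list = field(default_factory=list)
    sensitivity: sensitivity.SensitivityReport | None = None
    meta: synthesis.MetaResult | None = None
    verdict: synthesis.Verdict | None = None
    harmonized: pd.DataFrame | None = None
    exclusions: pd.DataFrame | None = None


def analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: RunConfig,
    ld: LDTable | None = None,
    replication_outcome: SummaryDataset | None = None,
    seed=None,
) -> ExposureAnalysis:
    """Run the full per-exposure pipeline in memory.

    Stages: p-threshold selection -> LD clumping -> F filter -> harmonization
    -> five MR methods -> sensitivity battery -> (optional) replication IVW
    and meta-analysis -> verdict.  A stage that empties the instrument set
    records a skip reason and stops cleanly.
    """
    seed = config.seed if seed is None else seed
    out = ExposureAnalysis(exposure.trait_id, outcome.trait_id, {"input": len(exposure)})

    selected = instruments.select_by_pvalue(exposure, config.p_threshold)
    out.counts["p_threshold"] = 0 if selected is None else len(selected)
    if selected is None:
        out.skip_reason = "no_snp_passes_p_threshold"
        return out

    clumped = instruments.clump(selected, ld, r2_max=config.clump_r2,
                                window_bp=int(config.clump_kb * 1000))
    out.counts["clump"] = len(clumped)

    strengths = instruments.compute_f(clumped, k_mode=config.f_k_mode)
    strong = instruments.filter_weak(clumped, strengths, f_min=config.f_min)
    out.counts["f_filter"] = 0 if strong is None else len(strong)
    if strong is None:
        out.skip_reason = "all_instruments_weak"
        return out

    lo, hi = config.palindrome_window
    harmonized, exclusions = instruments.harmonize(strong, outcome, lo, hi)
    out.counts["harmonized"] = len(harmonized)
    out.harmonized, out.exclusions = harmonized, exclusions
    if len(harmonized) == 0:
        out.skip_reason = "no_snp_harmonized"
        return out

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(3)
    out.results = estimators.run_all_methods(
        harmonized, variance_model=config.variance_model,
        n_boot=config.n_boot, seed=children[0],
    )
    out.sensitivity = sensitivity.run_sensitivity(
        harmonized, n_sim=config.presso_n_sim, seed=children[1],
        variance_model=config.variance_model,
    )

    primary_ivw = next(r for r in out.results if r.method == estimators.METHOD_IVW)
    if replication_outcome is not None:
        rep_h, _ = instruments.harmonize(strong, replication_outcome, lo, hi)
        if len(rep_h) >= 1:
            rep_ivw = estimators.ivw(rep_h, variance_model=config.variance_model)
            out.replication_results = [rep_ivw]
            out.meta = synthesis.meta_combine(
                [(primary_ivw.beta, primary_ivw.se), (rep_ivw.beta, rep_ivw.se)]
            )
        else:
            logger.warning("%s: no instruments harmonized in replication outcome",
                           exposure.trait_id)
    out.verdict = synthesis.verdict(
        out.results, out.sensitivity, out.meta,
        alpha=config.alpha, exposure_id=exposure.trait_id,
    )
    return out


def _check_monotone(counts: dict) -> None:
    vals = list(counts.values())
    assert all(a >= b for a, b in zip(vals, vals[1:])), f"stage counts increased: {counts}"


def _collect_tables(analyses: list[ExposureAnalysis],
                    direction: str) -> dict[str, pd.DataFrame]:
    res_rows, sens_rows, loo_rows, meta_rows, verdict_rows, excl_rows = [], [], [], [], [], []
    for a in analyses:
        label = {"exposure": a.exposure_id, "outcome": a.outcome_id, "direction": direction}
        ivw_p = next((r.pval for r in a.results
                      if r.method == estimators.METHOD_IVW), np.nan)
        for r in a.results:
            res_rows.append({**label, **r.to_dict(), "analysis": "primary"})
        for r in a.replication_results:
            res_rows.append({**label, **r.to_dict(), "analysis": "replication"})
        if a.sensitivity is not None:
            sens_rows.append({**label, **a.sensitivity.to_row()})
            if a.sensitivity.loo_table is not None:
                loo = a.sensitivity.loo_table.copy()
                for k, v in label.items():
                    loo.insert(0, k, v)
                loo_rows.append(loo)
        if a.meta is not None:
            m = a.meta
            meta_rows.append({
                **label,
                "beta_fixed": m.beta_fixed, "se_fixed": m.se_fixed, "pval_fixed": m.pval_fixed,
                "beta_random": m.beta_random, "se_random": m.se_random,
                "pval_random": m.pval_random, "tau2": m.tau2, "i2": m.i2,
                "q_between": m.q_between, "q_between_pval": m.q_between_pval,
            })
        if a.verdict is not None:
            verdict_rows.append({**a.verdict.to_row(), "outcome": a.outcome_id,
                                 "direction": direction, "ivw_pval": ivw_p,
                                 "skip_reason": a.skip_reason})
        elif a.skip_reason:
            verdict_rows.append({"exposure": a.exposure_id, "outcome": a.outcome_id,
                                 "direction": direction, "classification": "skipped",
                                 "ivw_pval": np.nan, "skip_reason": a.skip_reason})
        if a.exclusions is not None and len(a.exclusions):
            ex = a.exclusions.copy()
            ex.insert(0, "exposure", a.exposure_id)
            excl_rows.append(ex)

    tables = {}
    tables["results"] = pd.DataFrame(res_rows)
    tables["sensitivity"] = pd.DataFrame(sens_rows)
    tables["loo"] = pd.concat(loo_rows, ignore_index=True) if loo_rows else pd.DataFrame()
    tables["meta"] = pd.DataFrame(meta_rows)
    verdicts = pd.DataFrame(verdict_rows)
    if len(verdicts):
        # honesty layer: multiplicity-adjusted columns, not used by the verdict
        mask = verdicts["ivw_pval"].notna()
        p = verdicts.loc[mask, "ivw_pval"].to_numpy(float)
        if len(p):
            order = np.argsort(p)
            m = len(p)
            bh = np.empty(m)
            bh[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            verdicts.loc[mask, "ivw_pval_bh"] = np.minimum(bh, 1.0)
            verdicts.loc[mask, "ivw_pval_bonferroni"] = np.minimum(p * m, 1.0)
    tables["verdict"] = verdicts
    tables["exclusions"] = (
        pd.concat(excl_rows, ignore_index=True) if excl_rows else pd.DataFrame()
    )
    return tables


def _run(
    pairs: list,
    config: RunConfig,
    direction: str,
    out_dir: Path | None,
    pathways=None,
    compound_map: dict | None = None,
) -> dict:
    """Shared engine: pairs is [(exposure, outcome, replication|None), ...]."""
    analyses = []
    timings = []
    seeds = np.random.SeedSequence(config.seed).spawn(max(len(pairs), 1))
    for (exp, outc, rep, ld_i), child in zip(pairs, seeds):
        t0 = time.perf_counter()
        a = analyze_pair(exp, outc, config, ld=ld_i, replication_outcome=rep, seed=child)
        _check_monotone(a.counts)
        timings.append({"exposure": exp.trait_id, "seconds": time.perf_counter() - t0})
        if a.skip_reason:
            logger.warning("%s skipped: %s", exp.trait_id, a.skip_reason)
        analyses.append(a)

    tables = _collect_tables(analyses, direction)

    if pathways is not None and compound_map is not None and direction == "forward":
        universe = [compound_map[a.exposure_id] for a in analyses
                    if a.exposure_id in compound_map]
        selected = [
            compound_map[a.exposure_id] for a in analyses
            if a.exposure_id in compound_map and a.verdict is not None
            and a.verdict.classification in ("pathogenic", "protective")
        ]
        ora = synthesis.pathway_ora(selected, universe, pathways, alpha=config.pathway_alpha)
        tables["pathway"] = synthesis.pathway_table(ora)

    manifest = {
        "direction": direction,
        "config": config.to_dict(),
        "stage_counts": {f"{a.exposure_id}~{a.outcome_id}": a.counts for a in analyses},
        "skips": {f"{a.exposure_id}~{a.outcome_id}": a.skip_reason
                  for a in analyses if a.skip_reason},
        "artifacts": [],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            manifest["artifacts"].append(path.name)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out_dir / "run.log", "w") as fh:  # timings kept out of the manifest
            for t in timings:
                fh.write(f"{t['exposure']}\t{t['seconds']:.3f}\n")
    return {"analyses": analyses, "tables": tables, "manifest": manifest}


def _load_inputs(config: RunConfig):
    if not config.exposure_paths or config.outcome_path is None:
        raise ConfigurationError("exposure_paths and outcome_path are required")
    exposures = [read_summary(p, trait_type="quantitative") for p in config.exposure_paths]
    outcome = read_summary(config.outcome_path, trait_type="binary")
    replication = (read_summary(config.replication_outcome_path, trait_type="binary")
                   if config.replication_outcome_path else None)
    ld = LDTable.read(config.ld_path) if config.ld_path else None
    pathways = read_pathways(config.pathway_gmt) if config.pathway_gmt else None
    compound_map = None
    if config.compound_map:
        cm = pd.read_csv(config.compound_map, sep="\t")
        compound_map = dict(zip(cm.iloc[:, 0], cm.iloc[:, 1]))
    return exposures, outcome, replication, ld, pathways, compound_map


def run_forward(config: RunConfig) -> dict:
    """Metabolites as exposures, the disease GWAS as outcome (file-based)."""
    exposures, outcome, replication, ld, pathways, compound_map = _load_inputs(config)
    return run_forward_datasets(exposures, outcome, config, ld=ld,
                                replication=replication, pathways=pathways,
                                compound_map=compound_map,
                                out_dir=Path(config.out_dir) / "forward")


def run_forward_datasets(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    config: RunConfig,
    ld: LDTable | None = None,
    replication: SummaryDataset | None = None,
    pathways=None,
    compound_map: dict | None = None,
    out_dir=None,
) -> dict:
    """In-memory forward screen (used by tests and simulation studies)."""
    pairs = [(e, outcome, replication, ld) for e in exposures]
    return _run(pairs, config, "forward", out_dir, pathways, compound_map)


def run_reverse(config: RunConfig) -> dict:
    """The disease as exposure, each metabolite as outcome (file-based)."""
    exposures, outcome, _, ld, _, _ = _load_inputs(config)
    return run_reverse_datasets(outcome, exposures, config, ld=ld,
                                out_dir=Path(config.out_dir) / "reverse")


def run_reverse_datasets(
    disease: SummaryDataset,
    metabolites: list[SummaryDataset],
    config: RunConfig,
    ld: LDTable | None = None,
    out_dir=None,
) -> dict:
    """In-memory reverse screen: identical IV criteria, roles swapped."""
    pairs = [(disease, m, None, ld) for m in metabolites]
    return _run(pairs, config, "reverse", out_dir)
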