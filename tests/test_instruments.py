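import numpy as np
import pandas as pd
import pytest

from lipidmr.gwas_io import DataError
from lipidmr.instruments import (
    LDTable,
    clump,
    compute_f,
    filter_weak,
    harmonize,
    select_by_pvalue,
)

from conftest import make_summary


# ---------------------------------------------------------------------------
# p-value selection


def test_select_by_pvalue_strict_threshold():
    ds = make_summary(["a", "b", "c"], [0.1] * 3, [0.01] * 3,
                      pvals=[1e-6, 1e-4, 1e-5])
    kept = select_by_pvalue(ds, 1e-5)
    # p == threshold is excluded (strict <)
    assert list(kept.records["snp"]) == ["a"]
    assert len(select_by_pvalue(ds, 1.0)) == 3
    assert select_by_pvalue(ds, 1e-8) is None


# ---------------------------------------------------------------------------
# LD clumping


def test_clump_independent_snps_all_kept():
    ds = make_summary(["a", "b", "c"], [0.1] * 3, [0.01] * 3)
    assert len(clump(ds, LDTable())) == 3


def test_clump_keeps_most_significant_of_linked_pair():
    ds = make_summary(["a", "b"], [0.1, 0.1], [0.01, 0.01],
                      pvals=[1e-8, 1e-6], positions=[100_000, 110_000])
    ld = LDTable([("a", "b", 0.5)])
    assert list(clump(ds, ld).records["snp"]) == ["a"]


def test_clump_window_limits_removal():
    # same r2 but 600 kb apart: both survive
    ds = make_summary(["a", "b"], [0.1, 0.1], [0.01, 0.01],
                      pvals=[1e-8, 1e-6], positions=[100_000, 700_000])
    ld = LDTable([("a", "b", 0.5)])
    assert len(clump(ds, ld)) == 2


def _brute_force_check(kept, df, ld, r2_max, window):
    """Every dropped SNP must conflict with a better-p kept SNP; kept set admissible."""
    info = df.set_index("snp")
    kept = list(kept)
    for s in info.index:
        if s in kept:
            continue
        conflicts = [
            k for k in kept
            if info.loc[k, "chr"] == info.loc[s, "chr"]
            and abs(int(info.loc[k, "pos"]) - int(info.loc[s, "pos"])) <= window
            and ld.r2(k, s) > r2_max
            and info.loc[k, "pval"] <= info.loc[s, "pval"]
        ]
        assert conflicts, f"dropped SNP {s} has no admissible reason"
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if info.loc[a, "chr"] == info.loc[b, "chr"] and \
               abs(int(info.loc[a, "pos"]) - int(info.loc[b, "pos"])) <= window:
                assert ld.r2(a, b) <= r2_max, f"kept pair {a},{b} in LD"


def test_clump_matches_brute_force_admissibility(rng):
    for _ in range(20):
        J = int(rng.integers(4, 11))
        snps = [f"s{i}" for i in range(J)]
        ds = make_summary(
            snps, [0.1] * J, rng.uniform(0.01, 0.02, J),
            pvals=rng.uniform(1e-10, 1e-4, J),
            positions=rng.integers(1, 2_000_000, J),
        )
        ld = LDTable()
        for i in range(J):
            for j in range(i + 1, J):
                if rng.random() < 0.4:
                    ld.set(snps[i], snps[j], rng.uniform(0, 1))
        kept = clump(ds, ld)
        _brute_force_check(kept.records["snp"], ds.records, ld, 0.01, 500_000)


# ---------------------------------------------------------------------------
# F statistic


def test_compute_f_printed_formula_hand_values():
    # n=1000, k=1, R2=0.01 -> F = 998*0.01/0.99
    # choose beta/eaf with 2*beta^2*eaf*(1-eaf) = 0.01
    beta = np.sqrt(0.01 / (2 * 0.25))
    ds = make_summary(["a"], [beta], [0.01], eafs=[0.5], n=1000)
    (s,) = compute_f(ds)
    assert s.f_stat == pytest.approx(998 * 0.01 / 0.99, rel=1e-9)
    assert s.k == 1

    ds2 = make_summary(["a"], [0.05], [0.01], eafs=[0.5], n=7824)
    (s2,) = compute_f(ds2)
    assert s2.r2 == pytest.approx(0.00125, abs=1e-12)
    assert s2.f_stat == pytest.approx(7822 * 0.00125 / 0.99875, rel=1e-9)
    assert s2.f_stat == pytest.approx(9.79, abs=0.01)


def test_compute_f_zero_beta_gives_zero_f():
    ds = make_summary(["a"], [0.0], [0.01])
    assert compute_f(ds)[0].f_stat == 0.0


def test_compute_f_joint_mode_uses_summed_r2():
    ds = make_summary(["a", "b"], [0.05, 0.05], [0.01, 0.01], eafs=[0.5, 0.5], n=1000)
    per = compute_f(ds, k_mode="per_snp")
    joint = compute_f(ds, k_mode="joint")
    r2_tot = sum(s.r2 for s in per)
    expected = (1000 - 2 - 1) * r2_tot / (2 * (1 - r2_tot))
    assert all(s.f_stat == pytest.approx(expected) for s in joint)
    assert all(s.k == 2 for s in joint)


def test_compute_f_monotone_in_r2_and_n():
    f = lambda beta, n: compute_f(make_summary(["a"], [beta], [0.01], n=n))[0].f_stat
    assert f(0.10, 1000) < f(0.12, 1000) < f(0.12, 2000)


def test_filter_weak_boundary():
    from lipidmr.instruments import InstrumentStrength

    # F = {9.99, 10.0, 12}: exactly the F<10 SNP is removed (strict <)
    ds = make_summary(["low", "ten", "high"], [0.1] * 3, [0.01] * 3, n=1000)
    strengths = [
        InstrumentStrength("low", 0.01, 9.99, 1000, 1),
        InstrumentStrength("ten", 0.01, 10.0, 1000, 1),
        InstrumentStrength("high", 0.01, 12.0, 1000, 1),
    ]
    kept = filter_weak(ds, strengths)
    assert set(kept.records["snp"]) == {"ten", "high"}


def test_filter_weak_all_weak_returns_none():
    ds = make_summary(["a"], [0.001], [0.01], n=1000)
    assert filter_weak(ds, compute_f(ds)) is None


# ---------------------------------------------------------------------------
# harmonization


def _pair(exp_alleles, out_alleles, beta_out=0.05, eaf_exp=0.3, eaf_out=None,
          beta_exp=0.1):
    exp = make_summary(["rs1"], [beta_exp], [0.01], eafs=[eaf_exp],
                       ea=[exp_alleles[0]], oa=[exp_alleles[1]])
    out = make_summary(["rs1"], [beta_out], [0.02],
                       eafs=[eaf_out if eaf_out is not None else eaf_exp],
                       ea=[out_alleles[0]], oa=[out_alleles[1]],
                       trait_type="binary")
    return harmonize(exp, out)


def test_harmonize_identical_alleles_unchanged():
    h, excl = _pair(("A", "G"), ("A", "G"))
    assert len(excl) == 0
    assert h["harmonization_action"].iloc[0] == "unchanged"
    assert h["beta_out"].iloc[0] == 0.05


def test_harmonize_swapped_alleles_negates_beta_and_flips_eaf():
    h, _ = _pair(("A", "G"), ("G", "A"), eaf_exp=0.3, eaf_out=0.7)
    assert h["harmonization_action"].iloc[0] == "swapped"
    assert h["beta_out"].iloc[0] == -0.05
    assert h["eaf_out"].iloc[0] == pytest.approx(0.3)


def test_harmonize_strand_flip_keeps_beta_sign():
    h, _ = _pair(("A", "G"), ("T", "C"))
    assert h["harmonization_action"].iloc[0] == "strand_flipped"
    assert h["beta_out"].iloc[0] == 0.05
    assert h["effect_allele"].iloc[0] == "A"


def test_harmonize_swapped_and_flipped():
    h, _ = _pair(("A", "G"), ("C", "T"), eaf_exp=0.3, eaf_out=0.7)
    assert h["harmonization_action"].iloc[0] == "swapped_and_flipped"
    assert h["beta_out"].iloc[0] == -0.05


def test_harmonize_palindrome_intermediate_eaf_excluded():
    h, excl = _pair(("A", "T"), ("A", "T"), eaf_exp=0.50)
    assert len(h) == 0
    assert excl["reason"].iloc[0] == "palindromic_intermediate_eaf"
    # boundary: exactly 0.42 is outside the open window, kept
    h2, excl2 = _pair(("A", "T"), ("A", "T"), eaf_exp=0.42, eaf_out=0.42)
    assert len(h2) == 1 and len(excl2) == 0


def test_harmonize_palindrome_eaf_discordance_implies_swap():
    h, _ = _pair(("A", "T"), ("T", "A"), eaf_exp=0.2, eaf_out=0.8)
    assert h["beta_out"].iloc[0] == -0.05
    assert h["eaf_out"].iloc[0] == pytest.approx(0.2)


def test_harmonize_irreconcilable_alleles_excluded():
    h, excl = _pair(("A", "G"), ("A", "C"))
    assert len(h) == 0
    assert excl["reason"].iloc[0] == "allele_mismatch"


def test_harmonize_idempotent(rng):
    from lipidmr.simdata import SimConfig, simulate_pair

    exp, out, _, _ = simulate_pair(SimConfig(n_snp=40, seed=11, allele_scramble_frac=0.5))
    h1, _ = harmonize(exp, out)
    # rebuild datasets from the harmonized table and harmonize again
    exp2 = exp.subset(exp.records["snp"].isin(h1["snp"]))
    out_rec = exp2.records.copy()
    merged = out_rec.merge(
        h1[["snp", "beta_out", "se_out", "eaf_out", "n_out"]], on="snp",
    )
    out_rec["beta"] = merged["beta_out"].to_numpy()
    out_rec["se"] = merged["se_out"].to_numpy()
    out_rec["eaf"] = merged["eaf_out"].to_numpy()
    out_rec["n"] = merged["n_out"].to_numpy()
    from lipidmr.gwas_io import SummaryDataset
    out2 = SummaryDataset("outcome", "binary", out_rec)
    h2, excl2 = harmonize(exp2, out2)
    assert len(excl2) == 0
    np.testing.assert_array_equal(h2["beta_out"].to_numpy(), h1["beta_out"].to_numpy())
    assert (h2["harmonization_action"] == "unchanged").all()


def test_harmonize_allele_coding_invariance(rng):
    """Relabelling outcome alleles (swap + sign flip) leaves the result unchanged."""
    from lipidmr.gwas_io import SummaryDataset
    from lipidmr.simdata import SimConfig, simulate_pair

    exp, out, _, _ = simulate_pair(SimConfig(n_snp=30, seed=3, palindrome_frac=0.0))
    flipped = out.records.copy()
    flipped[["effect_allele", "other_allele"]] = \
        flipped[["other_allele", "effect_allele"]].to_numpy()
    flipped["beta"] = -flipped["beta"]
    flipped["eaf"] = 1.0 - flipped["eaf"]
    out_flipped = SummaryDataset(out.trait_id, "binary", flipped)
    h1, _ = harmonize(exp, out)
    h2, _ = harmonize(exp, out_flipped)
    np.testing.assert_allclose(h1["beta_out"], h2["beta_out"], rtol=0, atol=0)
    np.testing.assert_array_equal(h1["effect_allele"], h2["effect_allele"])
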