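"""Genotype-likelihood model, EM allele frequency, calling and filtering."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.stats import binom, poisson

from conftest import build_callset
from snptitrate.caller import (
    FilterSpec,
    estimate_alt_frequency,
    genotype_log_likelihoods,
    hard_filter,
    joint_call,
    site_filter,
)
from snptitrate.errors import ConfigError, UndefinedMetricError
from snptitrate.simcore import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    PileupMatrix,
    SimConfig,
    simulate_genotypes,
    simulate_pileups,
    simulate_sites,
)


def make_pileup(ref, alt):
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    return PileupMatrix(ref, alt, np.zeros_like(ref))


def sites_for(n, p=0.1):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "ref": "A",
            "alt": "G",
            "alt_freq": p,
            "mut_class": "transition",
            "region": "intergenic",
            "effect": "none",
        }
    )


# ---------------------------------------------------------------------------
# likelihood model


def test_likelihoods_no_data_are_flat():
    assert np.allclose(genotype_log_likelihoods(0, 0, 0.01), 0.0)


def test_likelihoods_balanced_reads_favor_het():
    ll = genotype_log_likelihoods(5, 5, 0.01)
    assert ll.argmax() == 1
    assert ll[1] == pytest.approx(10 * np.log(0.5))
    # direct evaluation of the three product likelihoods
    assert ll[0] == pytest.approx(5 * np.log(0.99) + 5 * np.log(0.01))
    assert ll[2] == pytest.approx(ll[0])


@given(r=st_.integers(0, 60), a=st_.integers(0, 60), e=st_.floats(0.0, 0.49))
@settings(max_examples=60, deadline=None)
def test_likelihood_swap_symmetry(r, a, e):
    ll = genotype_log_likelihoods(r, a, e)
    ll_swapped = genotype_log_likelihoods(a, r, e)
    assert ll[1] == ll_swapped[1]
    assert ll[0] == ll_swapped[2] and ll[2] == ll_swapped[0]


def test_het_likelihood_depends_only_on_total_and_rr_decreases_in_alt():
    e = 0.02
    total = 12
    ra = [genotype_log_likelihoods(total - a, a, e)[1] for a in range(total + 1)]
    assert np.allclose(ra, ra[0])
    rr = [genotype_log_likelihoods(total - a, a, e)[0] for a in range(total + 1)]
    assert (np.diff(rr) < 0).all()


def test_zero_error_rate_contradicted_homozygote_is_minus_inf():
    ll = genotype_log_likelihoods(3, 2, 0.0)
    assert ll[0] == -np.inf and ll[2] == -np.inf and np.isfinite(ll[1])


# ---------------------------------------------------------------------------
# allele-frequency EM


def _em_reference(ref, alt, e, iters=500):
    """Independent scalar EM on the 3-cell model (plain Python loop)."""
    liks = [((1 - e) ** r * e**a, 0.5 ** (r + a), e**r * (1 - e) ** a) for r, a in zip(ref, alt)]
    p = 0.5
    for _ in range(iters):
        dose = 0.0
        for l_rr, l_ra, l_aa in liks:
            w = ((1 - p) ** 2 * l_rr, 2 * p * (1 - p) * l_ra, p**2 * l_aa)
            s = sum(w)
            dose += (0.5 * w[1] + w[2]) / s
        p = dose / len(liks)
    return p


def test_af_em_monomorphic_extremes():
    assert estimate_alt_frequency([10] * 8, [0] * 8, 0.01) < 0.01
    assert estimate_alt_frequency([0] * 8, [10] * 8, 0.01) > 0.99


def test_af_em_balanced_split_and_reference_oracle():
    ref = [10] * 5 + [0] * 5
    alt = [0] * 5 + [10] * 5
    p = estimate_alt_frequency(ref, alt, 0.01)
    assert p == pytest.approx(0.5, abs=0.01)
    assert p == pytest.approx(_em_reference(ref, alt, 0.01), abs=1e-4)

    rng = np.random.default_rng(17)
    for _ in range(5):
        ref = rng.integers(0, 12, 10).tolist()
        alt = rng.integers(0, 12, 10).tolist()
        p = estimate_alt_frequency(ref, alt, 0.02)
        assert p == pytest.approx(_em_reference(ref, alt, 0.02), abs=1e-4)


def test_af_em_no_reads_is_undefined():
    with pytest.raises(UndefinedMetricError):
        estimate_alt_frequency([0, 0], [0, 0], 0.01)


# ---------------------------------------------------------------------------
# calling


def test_single_individual_balanced_reads_called_het_with_confident_gq():
    pu = make_pileup([[5]], [[5]])
    cs = joint_call(pu, sites_for(1), error_rate=0.01, mode="ml")
    assert cs.n_sites == 1
    assert cs.gt[0, 0] == GT_HET
    assert cs.gq[0, 0] > 20


def test_no_reads_anywhere_emits_no_sites():
    pu = make_pileup(np.zeros((4, 3)), np.zeros((4, 3)))
    cs = joint_call(pu, sites_for(3), error_rate=0.01)
    assert cs.n_sites == 0


def test_zero_read_genotypes_are_missing():
    ref = np.array([[5, 0], [0, 0], [3, 4]])
    alt = np.array([[5, 0], [0, 0], [4, 0]])
    cs = joint_call(make_pileup(ref, alt), sites_for(2), error_rate=0.01, mode="ml")
    # first site emitted (het carriers); second site has one covered hom_ref
    # individual only -> not emitted
    assert cs.n_sites == 1
    assert cs.gt[1, 0] == GT_MISSING


def test_joint_prior_shrinks_singleton_alt_read_toward_hom_ref():
    # 31 individuals; one with a single alt read -> ml calls hom_alt,
    # joint (HWE prior at p-hat ~ 0) pulls it to hom_ref
    ref = np.full((31, 1), 10)
    alt = np.zeros((31, 1), dtype=np.int64)
    ref[0, 0], alt[0, 0] = 0, 1
    ml = joint_call(make_pileup(ref, alt), sites_for(1), 0.01, mode="ml")
    joint = joint_call(make_pileup(ref, alt), sites_for(1), 0.01, mode="joint")
    assert ml.n_sites == 1 and ml.gt[0, 0] == GT_HOM_ALT
    assert joint.n_sites == 0 or joint.gt[0, 0] == GT_HOM_REF


def test_joint_emits_no_more_false_sites_than_ml_at_monomorphic_sites():
    # prior shrinkage: >=1e4 truly monomorphic sites at modest depth
    n_sites = 10_000
    cfg = SimConfig(n_individuals=31, n_sites=n_sites, mean_depth=6.0, error_rate=0.01, seed=41)
    gt = np.zeros((31, n_sites), dtype=np.int8)
    pu = simulate_pileups(gt, cfg)
    sites = sites_for(n_sites)
    ml = joint_call(pu, sites, 0.01, mode="ml")
    joint = joint_call(pu, sites, 0.01, mode="joint")
    assert joint.n_sites <= ml.n_sites


def test_high_depth_calls_recover_truth_at_exact_enumerated_error_rate():
    """Genotype error at 20x/e=0.01 matches the Poisson-binomial enumeration.

    The oracle enumerates the ML decision over (depth, alt-read) outcomes;
    the observed error rate among covered genotypes must agree within Monte
    Carlo error and stay well below 0.2% (high depth recovers truth).
    """
    e, lam = 0.01, 20.0
    cfg = SimConfig(n_individuals=31, n_sites=20_000, mean_depth=lam, error_rate=e, seed=43)
    sites = simulate_sites(cfg)
    gt = simulate_genotypes(sites, cfg)
    pu = simulate_pileups(gt, cfg)
    ll = genotype_log_likelihoods(pu.ref, pu.alt, e)
    call = ll.argmax(axis=-1).astype(np.int8)
    covered = pu.total() > 0
    observed = (call[covered] != gt[covered]).mean()

    # exact oracle: enumerate ML calls over k ~ Poisson, a | k ~ Binomial
    def exact_error(p_read_alt):
        total = 0.0
        for k in range(1, 80):
            a = np.arange(k + 1)
            llk = np.stack(
                [
                    (k - a) * np.log(1 - e) + np.where(a > 0, a * np.log(e), 0.0),
                    np.full(k + 1, k * np.log(0.5)),
                    np.where(k - a > 0, (k - a) * np.log(e), 0.0) + a * np.log(1 - e),
                ]
            )
            calls = llk.argmax(axis=0)
            truth_code = {0.5: 1}.get(p_read_alt, 0 if p_read_alt < 0.5 else 2)
            wrong = binom.pmf(a, k, p_read_alt)[calls != truth_code].sum()
            total += poisson.pmf(k, lam) * wrong
        return total / (1 - poisson.pmf(0, lam))

    het_frac = (gt == GT_HET).mean()
    hom_alt_frac = (gt == GT_HOM_ALT).mean()
    expected = (
        het_frac * exact_error(0.5)
        + (1 - het_frac - hom_alt_frac) * exact_error(e)
        + hom_alt_frac * exact_error(1 - e)
    )
    n = int(covered.sum())
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 4 * sigma
    assert observed < 2e-3


def test_exact_ties_resolve_to_lowest_genotype_code():
    # balanced reads make l_RR == l_AA exactly; the argmax convention must
    # deterministically prefer hom_ref < het < hom_alt on ties
    ll = genotype_log_likelihoods(1, 1, 0.3)
    assert ll[0] == pytest.approx(ll[2])
    flat = np.zeros(3)
    assert flat.argmax() == 0  # convention the caller relies on


# ---------------------------------------------------------------------------
# site filter vs brute force


def brute_force_filter(gt, quals, alleles, spec):
    """Independent per-site rule evaluation with plain Python loops."""
    labels = []
    n_ind = len(gt)
    for j in range(len(quals)):
        col = [gt[i][j] for i in range(n_ind)]
        called = [g for g in col if g != -1]
        miss = 1 - len(called) / n_ind
        ac = sum(called)
        n_alleles = 2 * len(called)
        mac = min(ac, n_alleles - ac) if n_alleles else 0
        maf = mac / n_alleles if n_alleles else 0.0
        ref, alt = alleles[j]
        if miss > spec.max_missing + 1e-12:
            labels.append("max_missing")
        elif maf < spec.min_maf - 1e-12:
            labels.append("maf")
        elif mac < spec.min_mac:
            labels.append("mac")
        elif len(ref) != 1 or alt not in "ACGT" or len(alt) != 1:
            labels.append("not_biallelic")
        elif quals[j] < spec.min_qual:
            labels.append("minQ")
        else:
            labels.append("PASS")
    return labels


def test_site_filter_constructed_violations_match_brute_force():
    # 8 sites, one violation each (or none), 10 individuals
    n_ind = 10
    gt = np.zeros((n_ind, 8), dtype=np.int8)
    gt[:, 0] = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]  # clean PASS (mac 3, maf 0.15)
    gt[0, 1] = GT_MISSING  # 10% missing
    gt[:, 2] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]  # mac 1 -> maf 0.05? 1/20=0.05 fails mac
    gt[:, 3] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]  # mac 2 -> maf 0.10, fails mac
    gt[:, 4] = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    gt[:, 5] = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]  # low qual
    gt[:, 6] = [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]  # all hom_alt: mac 0 -> maf
    gt[:, 7] = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]  # symbolic alt
    quals = [100, 100, 100, 100, 100, 10, 100, 100]
    alleles = [("A", "G")] * 7 + [("A", "<DEL>")]
    cs = build_callset(gt, quals=quals, alleles=alleles)
    spec = FilterSpec()
    filtered = site_filter(cs, spec)
    expected = brute_force_filter(gt.tolist(), quals, alleles, spec)
    assert list(filtered.sites["filter"]) == expected
    # spot checks of the named rules
    assert expected[1] == "max_missing"
    assert expected[3] == "mac"
    assert expected[5] == "minQ"
    assert expected[6] == "maf"
    assert expected[7] == "not_biallelic"
    # genotypes unchanged
    assert (filtered.gt == cs.gt).all()


@pytest.mark.parametrize("seed", range(4))
def test_site_filter_random_toy_callsets_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_ind, n_sites = 31, 20
    gt = rng.choice([-1, 0, 1, 2], size=(n_ind, n_sites), p=[0.05, 0.55, 0.25, 0.15]).astype(np.int8)
    quals = rng.uniform(0, 120, n_sites).round(2).tolist()
    alleles = [("A", "G")] * n_sites
    spec = FilterSpec()
    cs = build_callset(gt, quals=quals, alleles=alleles)
    got = list(site_filter(cs, spec).sites["filter"])
    assert got == brute_force_filter(gt.tolist(), quals, alleles, spec)


def test_mac_two_of_31_individuals_fails():
    gt = np.zeros((31, 1), dtype=np.int8)
    gt[0, 0] = GT_HET
    gt[1, 0] = GT_HET  # 2 alt alleles total: MAC 2 < 3
    filtered = site_filter(build_callset(gt))
    assert filtered.sites["filter"].iloc[0] in ("mac", "maf")
    gt[2, 0] = GT_HOM_ALT  # MAC 4 of 62 -> maf 0.0645, passes everything
    assert site_filter(build_callset(gt)).sites["filter"].iloc[0] == "PASS"


def test_empty_callset_passes_through():
    cs = build_callset(np.zeros((3, 0), dtype=np.int8), quals=[], alleles=[])
    assert site_filter(cs).n_sites == 0


# ---------------------------------------------------------------------------
# hard filter


def test_hard_filter_bound_directions_and_parse_failures(caplog):
    info = {
        "QD": [1.9, 2.0, 25.0, 5.0, "oops"],
        "FS": [1.0, 60.0, 61.0, 1.0, 1.0],
        "MQ": [50.0, 50.0, 39.0, 50.0, 50.0],
    }
    cs = build_callset(np.zeros((2, 5), dtype=np.int8), info=info)
    out = hard_filter(cs)
    assert list(out.sites["filter"]) == ["hard:QD", "PASS", "hard:FS", "PASS", "hard:parse"]

    plain = build_callset(np.zeros((2, 2), dtype=np.int8))
    with caplog.at_level(logging.WARNING):
        out = hard_filter(plain)
    assert (out.sites["filter"] == "PASS").all()
    assert "skipped" in caplog.text or "vacuously" in caplog.text


def test_hard_filter_first_violated_rule_labels():
    # QD and MQ both violated -> labelled by QD (first in threshold order)
    info = {"QD": [1.0], "MQ": [10.0]}
    cs = build_callset(np.zeros((2, 1), dtype=np.int8), info=info)
    assert hard_filter(cs).sites["filter"].iloc[0] == "hard:QD"


def test_filterspec_validation():
    with pytest.raises(ConfigError, match="max_missing"):
        FilterSpec(max_missing=2.0)
    with pytest.raises(ConfigError, match="min_maf"):
        FilterSpec(min_maf=0.9)
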