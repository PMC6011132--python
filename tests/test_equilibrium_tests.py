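"""Exact Hardy-Weinberg tests and genotypic LD permutation tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from ssrkit.equilibrium_tests import (
    _enumerate_configurations, count_configurations, genotypic_ld_test,
    hwe_exact_test, hwe_test_locus, multiple_test_adjust,
)
from ssrkit.io_formats import GenotypeMatrix
from ssrkit.synthetic_data import GenotypeSimSpec, simulate_genotypes


def test_hand_enumerated_two_config_case():
    """Allele counts (8, 2) over n=5 admit exactly two configurations with
    conditional probabilities 1/9 and 8/9; the observed one is the rarer."""
    res = hwe_exact_test({(1, 1): 4, (2, 2): 1})
    assert res.method == "enumeration"
    assert res.n_configurations == 2
    assert res.p_probability == pytest.approx(1 / 9)
    assert res.p_deficit == pytest.approx(1 / 9)   # h=0 is the minimum
    assert res.p_excess == pytest.approx(1.0)


def test_singleton_allele_single_configuration():
    res = hwe_exact_test({(1, 1): 11, (1, 2): 1})
    assert res.n_configurations == 1
    assert res.p_probability == pytest.approx(1.0)


def test_monomorphic_not_applicable():
    res = hwe_exact_test({(1, 1): 12})
    assert res.method == "not_applicable"
    assert res.p_probability is None and res.p_deficit is None


def test_probabilities_sum_to_one_small_spaces():
    """Levene probabilities sum to 1 for all allele-count vectors with
    n <= 12 and up to 3 alleles (checked inside hwe_exact_test, which
    raises if the enumeration is inconsistent; spot totals here too)."""
    import math

    for counts in [(8, 2), (12, 12), (13, 7, 4), (6, 5, 1), (20, 3, 1)]:
        n = sum(counts) // 2
        m = {i + 1: c for i, c in enumerate(counts)}
        log_const = (
            math.lgamma(n + 1)
            + sum(math.lgamma(c + 1) for c in m.values())
            - math.lgamma(2 * n + 1)
        )
        total = 0.0
        for config in _enumerate_configurations(sorted(m), m):
            h = sum(c for (a, b), c in config if a != b)
            total += math.exp(
                log_const + h * math.log(2.0)
                - sum(math.lgamma(c + 1) for _, c in config)
            )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_enumeration_agrees_with_monte_carlo():
    """Force the MC path on the hand-enumerated example; agreement within
    3 MC standard errors."""
    exact = hwe_exact_test({(1, 1): 4, (2, 2): 1})
    mc = hwe_exact_test(
        {(1, 1): 4, (2, 2): 1},
        enumeration_limit=1, n_samples=20_000, seed=5,
    )
    assert mc.method == "monte_carlo"
    se = max(mc.mc_standard_error, 1e-6)
    assert abs(mc.p_probability - exact.p_probability) <= 3 * se
    assert abs(mc.p_deficit - exact.p_deficit) <= 3 * se


def test_type_one_error_conservative():
    """Rejection rate at alpha=0.05 under HWE stays at or below 0.05
    (exact conditional tests are conservative); 2000 simulated loci, n=12."""
    n_loci = 2000
    mats = [
        simulate_genotypes(
            GenotypeSimSpec(
                allele_freqs={"L1": [0.5, 0.3, 0.2]}, n_individuals=12,
                seed=100_000 + i,
            )
        )
        for i in range(n_loci)
    ]
    rejections = 0
    applicable = 0
    for mat in mats:
        res = hwe_test_locus(mat, "L1")
        if not res.applicable:
            continue
        applicable += 1
        if res.p_probability <= 0.05:
            rejections += 1
    assert applicable > n_loci * 0.9
    rate = rejections / applicable
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / applicable)


def test_power_under_inbreeding():
    """Strong inbreeding (F=0.8) must be rejected far more often than F=0."""
    def rejection_rate(f, seeds):
        hits = 0
        for seed in seeds:
            mat = simulate_genotypes(
                GenotypeSimSpec(
                    allele_freqs={"L1": [0.5, 0.5]}, n_individuals=50,
                    inbreeding_f=f, seed=seed,
                )
            )
            res = hwe_test_locus(mat, "L1")
            if res.applicable and res.p_probability <= 0.05:
                hits += 1
        return hits / len(seeds)

    seeds = range(200)
    assert rejection_rate(0.8, seeds) > rejection_rate(0.0, seeds)


def test_deficit_excess_tail_bounds():
    """Each one-sided p is at least the probability of the most extreme
    configuration and the two tails overlap at the observed class."""
    res = hwe_exact_test({(1, 1): 5, (1, 2): 2, (2, 2): 5})
    assert 0 < res.p_deficit <= 1 and 0 < res.p_excess <= 1
    assert res.p_deficit + res.p_excess >= 1.0  # both include h_obs


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test({})
    with pytest.raises(ValueError):
        hwe_exact_test({(1, 2): -1})


def test_count_configurations_limit():
    m = {1: 30, 2: 30, 3: 30, 4: 30}
    assert count_configurations(m, limit=50) == 51


# ---------------------------------------------------------------------------
# genotypic LD
# ---------------------------------------------------------------------------

def _two_locus_matrix(col_a, col_b, pop="P"):
    return GenotypeMatrix(
        population_name=pop,
        individual_ids=[f"i{k}" for k in range(len(col_a))],
        locus_names=["A", "B"],
        calls=[[a, b] for a, b in zip(col_a, col_b)],
    )


def test_ld_detects_duplicated_locus():
    col = [(1, 1)] * 4 + [(1, 2)] * 4 + [(2, 2)] * 4
    mat = _two_locus_matrix(col, list(col))
    res = genotypic_ld_test(mat, "A", "B", n_permutations=10_000, seed=1)
    assert res.applicable and res.statistic > 0
    assert res.p_value <= 0.05


def test_ld_monomorphic_not_applicable():
    col_a = [(1, 1)] * 12
    col_b = [(1, 2)] * 6 + [(1, 1)] * 6
    res = genotypic_ld_test(
        _two_locus_matrix(col_a, col_b), "A", "B", n_permutations=200, seed=0
    )
    assert not res.applicable and res.p_value is None
    assert res.reason == "monomorphic_locus"


def test_ld_requires_permutations():
    col = [(1, 2)] * 6 + [(1, 1)] * 6
    with pytest.raises(ValueError):
        genotypic_ld_test(_two_locus_matrix(col, col), "A", "B", n_permutations=50)


def test_ld_p_uniform_under_independence():
    """Independent loci give an approximately uniform p distribution
    (KS test at alpha=0.01 over replicated simulations)."""
    pvals = []
    for rep in range(400):
        mat = simulate_genotypes(
            GenotypeSimSpec(
                allele_freqs={
                    "A": [0.4, 0.35, 0.25], "B": [0.4, 0.35, 0.25],
                },
                n_individuals=60,
                seed=50_000 + rep,
            )
        )
        res = genotypic_ld_test(mat, "A", "B", n_permutations=199, seed=rep)
        if res.applicable:
            pvals.append(res.p_value)
    assert len(pvals) > 380
    _, ks_p = stats.kstest(pvals, "uniform")
    assert ks_p > 0.01


def test_ld_deterministic_under_seed():
    col = [(1, 1)] * 4 + [(1, 2)] * 5 + [(2, 2)] * 3
    col_b = [(2, 2)] * 3 + [(1, 2)] * 5 + [(1, 1)] * 4
    mat = _two_locus_matrix(col, col_b)
    r1 = genotypic_ld_test(mat, "A", "B", n_permutations=500, seed=9)
    r2 = genotypic_ld_test(mat, "A", "B", n_permutations=500, seed=9)
    assert r1.p_value == r2.p_value and r1.statistic == r2.statistic


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def test_bonferroni_definition():
    assert multiple_test_adjust([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
        [0.03, 0.06, 0.09]
    )


def test_single_p_unchanged():
    for method in ("bonferroni", "holm", "bh"):
        assert multiple_test_adjust([0.2], method) == pytest.approx([0.2])


def test_holm_dominates_bonferroni():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=8)
        holm = multiple_test_adjust(list(p), "holm")
        bonf = multiple_test_adjust(list(p), "bonferroni")
        assert all(h <= b + 1e-12 for h, b in zip(holm, bonf))


def test_invalid_p_rejected():
    with pytest.raises(ValueError):
        multiple_test_adjust([0.5, 1.5], "holm")
    with pytest.raises(ValueError):
        multiple_test_adjust([0.5], "sidak")
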