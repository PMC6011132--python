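"""Marker statistics: allele frequencies, NA/Ho/He/PIC, panel means,
and the genotype-configuration reconstruction oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrkit.datasets import marker_panel
from ssrkit.io_formats import GenotypeMatrix
from ssrkit.popgen_stats import (
    allele_frequencies, configuration_to_matrix, expected_heterozygosity,
    polymorphic_information_content, reconstruct_genotype_configuration,
    round3, summarize_locus, summarize_panel,
)
from ssrkit.synthetic_data import GenotypeSimSpec, simulate_genotypes


def _matrix(calls, locus="L1", pop="P"):
    return GenotypeMatrix(
        population_name=pop,
        individual_ids=[f"i{k}" for k in range(len(calls))],
        locus_names=[locus],
        calls=[[c] for c in calls],
    )


def test_allele_frequencies_counting():
    mat = _matrix([(1, 1)] * 11 + [(1, 2)])
    spec = allele_frequencies(mat, "L1")
    assert spec.counts == {1: 23, 2: 1} and spec.n == 12
    mat2 = _matrix([(1, 1)] * 6 + [(2, 2)] * 6)
    f = allele_frequencies(mat2, "L1").freqs
    assert f[1] == f[2] == 0.5


def test_allele_frequencies_monomorphic_and_missing():
    assert allele_frequencies(_matrix([(1, 1)] * 4), "L1").freqs == {1: 1.0}
    with pytest.raises(ValueError, match="no data"):
        allele_frequencies(_matrix([None, None]), "L1")
    # missing calls are dropped per locus, not per individual
    spec = allele_frequencies(_matrix([(1, 2), None, (2, 2)]), "L1")
    assert spec.n == 2 and spec.counts == {1: 1, 2: 3}


@pytest.mark.parametrize(
    "calls,expect",
    [
        # printed two-population marker table values, via the unique
        # reconstructed configurations
        ([(1, 1)] * 11 + [(1, 2)], (2, 0.083, 0.083, 0.077)),
        ([(1, 1)] * 10 + [(1, 2)] * 2, (2, 0.167, 0.159, 0.141)),
        ([(1, 1)] * 12, (1, 0.0, 0.0, 0.0)),
    ],
)
def test_summarize_locus_reference_values(calls, expect):
    s = summarize_locus(_matrix(calls), "L1")
    na, ho, he, pic = expect
    assert s.NA == na
    assert (round3(s.Ho), round3(s.He), round3(s.PIC)) == (ho, he, pic)


def test_summary_errors():
    with pytest.raises(ValueError):
        summarize_locus(_matrix([None]), "L1")
    with pytest.raises(KeyError):
        summarize_locus(_matrix([(1, 1)]), "nope")


@given(
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    st.integers(5, 60),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_pic_he_inequality(weights, n):
    """PIC <= 1 - sum p^2 <= unbiased He, for any spectrum."""
    p = np.asarray(weights) / np.sum(weights)
    gene_diversity = 1.0 - float(np.sum(p * p))
    pic = polymorphic_information_content(p)
    he = expected_heterozygosity(p, n)
    assert pic <= gene_diversity + 1e-9
    assert gene_diversity <= he + 1e-9


def test_he_estimator_unbiased():
    """Mean unbiased He over many small samples hits 1 - sum p^2."""
    freqs = [0.5, 0.3, 0.2]
    target = 1.0 - sum(f * f for f in freqs)
    vals = []
    for seed in range(4000):
        mat = simulate_genotypes(
            GenotypeSimSpec(
                allele_freqs={"L1": freqs}, n_individuals=12, seed=seed
            )
        )
        s = summarize_locus(mat, "L1")
        vals.append(s.He)
    vals = np.asarray(vals)
    sem = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - target) < 3 * sem + 1e-3


def test_equal_frequency_limit():
    """He approaches 1 - 1/k for k equifrequent alleles at large n."""
    k = 4
    mat = simulate_genotypes(
        GenotypeSimSpec(
            allele_freqs={"L1": [1 / k] * k}, n_individuals=10_000, seed=7
        )
    )
    assert abs(summarize_locus(mat, "L1").He - (1 - 1 / k)) < 1e-3


def test_recovers_generating_frequencies():
    freqs = [0.6, 0.3, 0.1]
    mat = simulate_genotypes(
        GenotypeSimSpec(allele_freqs={"L1": freqs}, n_individuals=5000, seed=3)
    )
    got = allele_frequencies(mat, "L1").freqs
    for code, f in zip([1, 2, 3], freqs):
        se = np.sqrt(f * (1 - f) / 10_000)
        assert abs(got[code] - f) < 4 * se + 1e-3


def test_panel_means_match_printed_table():
    """Printed per-locus columns give mean NA 2.56 and mean PIC 0.372/0.256."""
    panel = marker_panel()
    assert round(panel["NA"].mean(), 2) == 2.56
    assert round(panel["PIC_ZZ"].mean(), 3) == 0.372
    assert round(panel["PIC_FZ"].mean(), 3) == 0.256


def test_summarize_panel_shapes(two_population_matrices):
    per_locus, means = summarize_panel(two_population_matrices)
    assert len(per_locus) == 10  # 2 pops x 5 loci
    assert set(means["population"]) == {
        two_population_matrices[0].population_name,
        two_population_matrices[1].population_name,
        "pooled",
    }
    # pooled NA counts the union of alleles, never below either population
    pooled = means.loc[means["population"] == "pooled", "mean_NA"].item()
    per_pop = means.loc[means["population"] != "pooled", "mean_NA"]
    assert pooled >= per_pop.max() - 1e-12


def test_summarize_panel_single_locus():
    mat = _matrix([(1, 2)] * 4 + [(1, 1)] * 4)
    per_locus, means = summarize_panel([mat])
    s = summarize_locus(mat, "L1")
    assert per_locus["PIC"].iloc[0] == pytest.approx(s.PIC)
    assert means["mean_PIC"].iloc[0] == pytest.approx(s.PIC)


# ---------------------------------------------------------------------------
# reconstruction oracle
# ---------------------------------------------------------------------------

def test_reconstruction_unique_configurations():
    cfgs = reconstruct_genotype_configuration(12, 2, 0.083, 0.083, 0.0005)
    assert len(cfgs) == 1
    assert sorted(cfgs[0].hom_counts) == [0, 11]
    assert list(cfgs[0].het_counts.values()) == [1]
    assert round3(cfgs[0].PIC) == 0.077

    cfgs = reconstruct_genotype_configuration(12, 2, 0.167, 0.159, 0.0005)
    assert len(cfgs) == 1
    assert sorted(cfgs[0].hom_counts) == [0, 10]
    # the alternative split 9 hom / 2 het / 1 hom implies He ~ 0.290 and
    # must be excluded by the tolerance
    assert all(abs(c.He - 0.159) <= 0.0005 for c in cfgs)

    cfgs = reconstruct_genotype_configuration(12, 1, 0.0, 0.0)
    assert len(cfgs) == 1 and cfgs[0].hom_counts == (12,)


def test_reconstruction_matrix_roundtrip():
    (cfg,) = reconstruct_genotype_configuration(12, 2, 0.167, 0.159, 0.0005)
    mat = configuration_to_matrix(cfg)
    s = summarize_locus(mat, "locus")
    assert (round3(s.Ho), round3(s.He), round3(s.PIC)) == (0.167, 0.159, 0.141)


def test_reconstruction_bounds_and_empty_result():
    with pytest.raises(ValueError):
        reconstruct_genotype_configuration(60, 2, 0.1, 0.1)
    # impossible target: no configuration can have He near 0 with Ho 0.5
    assert reconstruct_genotype_configuration(12, 2, 0.5, 0.01, 1e-4) == []
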