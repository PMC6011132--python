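"""Hardy-Weinberg exact tests and genotypic linkage-disequilibrium tests.

Hardy-Weinberg testing conditions on the observed allele counts
(Levene's conditional distribution): for a locus with ``n`` diploid
individuals, allele copy counts ``m_i`` and genotype counts ``n_ij``,

    P(config) = n! * prod_i m_i! * 2^h / ((2n)! * prod_{i<=j} n_ij!)

with ``h`` the number of heterozygotes.  The probability test sums
P over all configurations no more probable than the observed one
(ties included); the one-sided heterozygote-deficit and -excess
p-values are the tail sums over configurations with h <= h_obs and
h >= h_obs respectively.  When the configuration space is small the
distribution is enumerated completely; otherwise configurations are
sampled by random pairing of the allele copies (Monte-Carlo), with
the seed and sample count recorded in the result.

Genotypic linkage disequilibrium between two loci is tested without
assuming phase: the log-likelihood-ratio statistic G is computed on the
genotype x genotype contingency table of complete cases and compared
with its permutation null distribution (one locus's genotype column
shuffled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenotypeMatrix

#: configuration-count ceiling below which the Levene distribution is enumerated
ENUMERATION_LIMIT = 100_000

GenotypeCounts = Mapping[tuple[int, int], int]


@dataclass(frozen=True)
class HWEResult:
    """Exact Hardy-Weinberg test result for one locus."""

    locus: str
    population: str
    p_probability: float | None
    p_deficit: float | None
    p_excess: float | None
    method: str  # "enumeration", "monte_carlo" or "not_applicable"
    n_configurations: int | None = None
    n_samples: int | None = None
    seed: int | None = None
    mc_standard_error: float | None = None

    @property
    def applicable(self) -> bool:
        return self.method != "not_applicable"


@dataclass(frozen=True)
class LDResult:
    """Genotypic linkage-disequilibrium permutation test for a locus pair."""

    locus_pair: tuple[str, str]
    population: str
    statistic: float | None  # log-likelihood ratio G
    p_value: float | None
    n_permutations: int
    seed: int
    applicable: bool = True
    reason: str | None = None


def _normalize_genotype_counts(
    genotype_counts: GenotypeCounts,
) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for (a, b), c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        if c == 0:
            continue
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + c
    if not counts:
        raise ValueError("no genotypes")
    return counts


def _allele_counts(counts: GenotypeCounts) -> dict[int, int]:
    m: dict[int, int] = {}
    for (a, b), c in counts.items():
        m[a] = m.get(a, 0) + c
        m[b] = m.get(b, 0) + c
    return m


def _log_config_probability(
    genotypes: Sequence[tuple[tuple[int, int], int]],
    log_const: float,
) -> float:
    """log P(config) given the precomputed log(n! prod m_i! / (2n)!)."""
    h = sum(c for (a, b), c in genotypes if a != b)
    return (
        log_const
        + h * math.log(2.0)
        - sum(math.lgamma(c + 1) for _, c in genotypes)
    )


def _enumerate_configurations(alleles: list[int], m: dict[int, int]):
    """Yield every genotype-count dict consistent with allele copy counts m."""
    k = len(alleles)
    pairs = [
        (alleles[i], alleles[j]) for i in range(k) for j in range(i, k)
    ]

    def rec(idx: int, remaining: dict[int, int], acc: list[tuple[tuple[int, int], int]]):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield list(acc)
            return
        a, b = pairs[idx]
        if a == b:
            cap = remaining[a] // 2
        else:
            cap = min(remaining[a], remaining[b])
        # alleles not used by any later pair must already be exhausted
        later = {x for p in pairs[idx + 1:] for x in p}
        for cnt in range(cap, -1, -1):
            rem = dict(remaining)
            if a == b:
                rem[a] -= 2 * cnt
            else:
                rem[a] -= cnt
                rem[b] -= cnt
            if any(v > 0 and x not in later for x, v in rem.items()):
                continue
            acc.append(((a, b), cnt))
            yield from rec(idx + 1, rem, acc)
            acc.pop()

    yield from rec(0, dict(m), [])


def count_configurations(m: dict[int, int], limit: int | None = None) -> int:
    """Number of genotype-count configurations with allele copy counts m.

    With ``limit`` the count stops at ``limit + 1`` so huge spaces are
    detected without paying for a full enumeration.
    """
    count = 0
    for _ in _enumerate_configurations(sorted(m), m):
        count += 1
        if limit is not None and count > limit:
            return count
    return count


def hwe_exact_test(
    genotype_counts: GenotypeCounts,
    locus: str = "locus",
    population: str = "pop",
    enumeration_limit: int = ENUMERATION_LIMIT,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> HWEResult:
    """Exact Hardy-Weinberg test from genotype counts at one locus.

    ``genotype_counts`` maps unordered allele pairs to counts, e.g.
    ``{(1, 1): 4, (2, 2): 1}``.  A monomorphic locus yields a
    not-applicable result.  Complete enumeration is used while the
    configuration count stays within ``enumeration_limit``; beyond that
    the conditional distribution is sampled ``n_samples`` times by
    random re-pairing of the allele copies.
    """
    counts = _normalize_genotype_counts(genotype_counts)
    m = _allele_counts(counts)
    n = sum(counts.values())
    if n < 1:
        raise ValueError("need at least one genotype")
    if len(m) < 2:
        return HWEResult(
            locus=locus, population=population,
            p_probability=None, p_deficit=None, p_excess=None,
            method="not_applicable",
        )

    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(c + 1) for c in m.values())
        - math.lgamma(2 * n + 1)
    )
    obs_items = list(counts.items())
    log_p_obs = _log_config_probability(obs_items, log_const)
    h_obs = sum(c for (a, b), c in obs_items if a != b)

    n_config = count_configurations(m, limit=enumeration_limit)
    if n_config <= enumeration_limit:
        p_prob = p_def = p_exc = 0.0
        total = 0.0
        for config in _enumerate_configurations(sorted(m), m):
            log_p = _log_config_probability(config, log_const)
            p = math.exp(log_p)
            total += p
            h = sum(c for (a, b), c in config if a != b)
            if log_p <= log_p_obs + 1e-12 * abs(log_p_obs) + 1e-12:
                p_prob += p
            if h <= h_obs:
                p_def += p
            if h >= h_obs:
                p_exc += p
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(
                f"Levene probabilities sum to {total}, not 1; "
                "enumeration is inconsistent"
            )
        return HWEResult(
            locus=locus, population=population,
            p_probability=min(p_prob, 1.0),
            p_deficit=min(p_def, 1.0),
            p_excess=min(p_exc, 1.0),
            method="enumeration", n_configurations=n_config,
        )

    # Monte-Carlo: re-pair the 2n allele copies uniformly at random
    rng = np.random.default_rng(seed)
    copies = np.repeat(
        np.fromiter(m.keys(), dtype=np.int64),
        np.fromiter(m.values(), dtype=np.int64),
    )
    hits_prob = hits_def = hits_exc = 0
    batch = 20_000
    remaining = n_samples
    while remaining > 0:
        b = min(batch, remaining)
        remaining -= b
        perms = np.tile(copies, (b, 1))
        perms = rng.permuted(perms, axis=1)
        left, right = perms[:, ::2], perms[:, 1::2]
        lo = np.minimum(left, right)
        hi = np.maximum(left, right)
        codes = lo * (copies.max() + 1) + hi
        h_vec = (left != right).sum(axis=1)
        for row_codes, h in zip(codes, h_vec):
            uniq, cnt = np.unique(row_codes, return_counts=True)
            log_p = (
                log_const
                + float(h) * math.log(2.0)
                - float(np.sum([math.lgamma(c + 1) for c in cnt]))
            )
            if log_p <= log_p_obs + 1e-12 * abs(log_p_obs) + 1e-12:
                hits_prob += 1
            if h <= h_obs:
                hits_def += 1
            if h >= h_obs:
                hits_exc += 1
    p_prob = hits_prob / n_samples
    se = math.sqrt(max(p_prob * (1 - p_prob), 1e-12) / n_samples)
    return HWEResult(
        locus=locus, population=population,
        p_probability=p_prob,
        p_deficit=hits_def / n_samples,
        p_excess=hits_exc / n_samples,
        method="monte_carlo", n_samples=n_samples, seed=seed,
        mc_standard_error=se,
    )


def genotype_counts_from_matrix(
    matrix: GenotypeMatrix, locus: str
) -> dict[tuple[int, int], int]:
    """Unordered genotype counts at one locus (missing calls dropped)."""
    counts: dict[tuple[int, int], int] = {}
    for call in matrix.calls_at(locus):
        if call is None:
            continue
        key = tuple(sorted(call))
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError(f"no data at locus {locus!r}")
    return counts


def hwe_test_locus(
    matrix: GenotypeMatrix, locus: str, **kwargs
) -> HWEResult:
    """Convenience wrapper: exact HWE test on one locus of a matrix."""
    return hwe_exact_test(
        genotype_counts_from_matrix(matrix, locus),
        locus=locus, population=matrix.population_name, **kwargs,
    )


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood ratio G = 2 sum O ln(O/E) over nonzero cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def genotypic_ld_test(
    matrix: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> LDResult:
    """Permutation test of genotypic association between two loci.

    Complete cases only; either locus monomorphic among them yields a
    not-applicable result.  p = (1 + #{G_perm >= G_obs}) / (1 + B).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    ja, jb = matrix.locus_index(locus_a), matrix.locus_index(locus_b)
    pairs = [
        (row[ja], row[jb]) for row in matrix.calls
        if row[ja] is not None and row[jb] is not None
    ]
    geno_a = [tuple(sorted(a)) for a, _ in pairs]
    geno_b = [tuple(sorted(b)) for _, b in pairs]

    def _mono(genos: list[tuple[int, int]]) -> bool:
        alleles = {x for g in genos for x in g}
        return len(alleles) < 2

    if not pairs or _mono(geno_a) or _mono(geno_b):
        return LDResult(
            locus_pair=(locus_a, locus_b), population=matrix.population_name,
            statistic=None, p_value=None, n_permutations=n_permutations,
            seed=seed, applicable=False, reason="monomorphic_locus",
        )

    cat_a = {g: i for i, g in enumerate(sorted(set(geno_a)))}
    cat_b = {g: i for i, g in enumerate(sorted(set(geno_b)))}
    ia = np.array([cat_a[g] for g in geno_a])
    ib = np.array([cat_b[g] for g in geno_b])
    ka, kb = len(cat_a), len(cat_b)

    def table(perm_b: np.ndarray) -> np.ndarray:
        flat = np.bincount(ia * kb + perm_b, minlength=ka * kb)
        return flat.reshape(ka, kb)

    g_obs = _g_statistic(table(ib))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        g_perm = _g_statistic(table(rng.permutation(ib)))
        if g_perm >= g_obs - 1e-12:
            hits += 1
    return LDResult(
        locus_pair=(locus_a, locus_b), population=matrix.population_name,
        statistic=g_obs, p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations, seed=seed,
    )


def multiple_test_adjust(
    p_values: Sequence[float], method: str = "bonferroni"
) -> list[float]:
    """Adjust p-values for multiple testing (bonferroni, holm or bh)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    codes = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}
    try:
        sm_method = codes[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(codes)}")
    return list(multipletests(p, method=sm_method)[1])
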