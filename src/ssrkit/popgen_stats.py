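"""Per-locus marker statistics: NA, Ho, He (unbiased), PIC.

For a locus with sample allele frequencies :math:`p_i` over ``n``
diploid individuals (missing calls dropped per locus):

* ``NA`` — number of distinct observed alleles;
* ``Ho`` — fraction of genotyped individuals that are heterozygous;
* ``He`` — Nei's unbiased expected heterozygosity
  :math:`\\frac{2n}{2n-1}\\left(1 - \\sum_i p_i^2\\right)`;
* ``PIC`` — polymorphic information content (Botstein et al. 1980)
  :math:`1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`.

Values are kept at full precision internally and rounded half-up to
three decimals only in reports.  A monomorphic locus has
Ho = He = PIC = 0 and no Hardy-Weinberg test.

The module also carries an exhaustive genotype-configuration
reconstruction oracle: given printed (n, NA, Ho, He) values it
enumerates every genotype-count vector consistent with them, which lets
published per-locus tables be validated even when the raw genotypes
were never deposited.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele counts and frequencies at one locus after dropping missing calls."""

    locus: str
    counts: Mapping[int, int]
    n: int  # diploid individuals with a call

    @property
    def freqs(self) -> dict[int, float]:
        total = 2 * self.n
        return {a: c / total for a, c in self.counts.items()}

    @property
    def n_alleles(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LocusSummary:
    """NA / Ho / He / PIC for one locus in one population.

    ``hwe_p`` and the one-sided ``hwe_deficit_p`` / ``hwe_excess_p`` are
    ``None`` until an equilibrium test is attached, and stay ``None``
    (not applicable) for monomorphic loci.
    """

    locus: str
    population: str
    n: int
    NA: int
    Ho: float
    He: float
    PIC: float
    hwe_p: float | None = None
    hwe_deficit_p: float | None = None
    hwe_excess_p: float | None = None


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, as used in printed marker tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def allele_frequencies(matrix: GenotypeMatrix, locus: str) -> AlleleFrequencySpectrum:
    """Observed allele counts at ``locus``; errors if every call is missing."""
    calls = [c for c in matrix.calls_at(locus) if c is not None]
    if not calls:
        raise ValueError(f"no data at locus {locus!r}")
    counts: dict[int, int] = {}
    for a1, a2 in calls:
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
    return AlleleFrequencySpectrum(
        locus=locus, counts=dict(sorted(counts.items())), n=len(calls)
    )


def expected_heterozygosity(freqs: Sequence[float], n: int) -> float:
    """Nei's unbiased He = (2n / (2n - 1)) * (1 - sum p_i^2)."""
    p = np.asarray(freqs, dtype=float)
    return float(2 * n / (2 * n - 1) * (1.0 - np.sum(p * p)))


def polymorphic_information_content(freqs: Sequence[float]) -> float:
    """PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(freqs, dtype=float)
    sum_p2 = float(np.sum(p * p))
    # sum_{i<j} p_i^2 p_j^2 = ((sum p^2)^2 - sum p^4) / 2
    cross = (sum_p2 ** 2 - float(np.sum(p ** 4))) / 2.0
    return 1.0 - sum_p2 - 2.0 * cross


def summarize_locus(matrix: GenotypeMatrix, locus: str) -> LocusSummary:
    """NA, Ho, He and PIC for one locus of one population."""
    spectrum = allele_frequencies(matrix, locus)
    calls = [c for c in matrix.calls_at(locus) if c is not None]
    n = spectrum.n
    if spectrum.n_alleles == 1:
        return LocusSummary(
            locus=locus, population=matrix.population_name, n=n,
            NA=1, Ho=0.0, He=0.0, PIC=0.0,
        )
    het = sum(1 for a1, a2 in calls if a1 != a2)
    freqs = list(spectrum.freqs.values())
    return LocusSummary(
        locus=locus,
        population=matrix.population_name,
        n=n,
        NA=spectrum.n_alleles,
        Ho=het / n,
        He=expected_heterozygosity(freqs, n),
        PIC=polymorphic_information_content(freqs),
    )


def summarize_panel(
    matrices: Sequence[GenotypeMatrix],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus summaries for every population, plus panel means.

    Returns ``(per_locus, means)``:

    * ``per_locus`` — one row per locus x population with n, NA, Ho, He,
      PIC (full precision);
    * ``means`` — per population the arithmetic means of NA and PIC
      across loci, plus one ``pooled`` row whose ``mean_NA`` counts the
      union of alleles observed across populations at each locus.
    """
    if not matrices:
        raise ValueError("no populations supplied")
    shared = [
        l for l in matrices[0].locus_names
        if all(l in m.locus_names for m in matrices)
    ]
    if not shared:
        raise ValueError("populations share no loci")

    rows = [
        summarize_locus(mat, locus).__dict__
        for mat in matrices
        for locus in shared
    ]
    per_locus = pd.DataFrame(rows).drop(
        columns=["hwe_p", "hwe_deficit_p", "hwe_excess_p"]
    )

    mean_rows = []
    for mat in matrices:
        sub = per_locus[per_locus["population"] == mat.population_name]
        mean_rows.append(
            {
                "population": mat.population_name,
                "mean_NA": float(sub["NA"].mean()),
                "mean_PIC": float(sub["PIC"].mean()),
            }
        )
    pooled_na = []
    for locus in shared:
        alleles: set[int] = set()
        for mat in matrices:
            for call in mat.calls_at(locus):
                if call is not None:
                    alleles.update(call)
        pooled_na.append(len(alleles))
    mean_rows.append(
        {
            "population": "pooled",
            "mean_NA": float(np.mean(pooled_na)),
            "mean_PIC": float("nan"),
        }
    )
    return per_locus, pd.DataFrame(mean_rows)


# ---------------------------------------------------------------------------
# Reconstruction oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeConfiguration:
    """One genotype-count vector over NA alleles, with implied statistics."""

    hom_counts: tuple[int, ...]            # per allele i: count of (i,i)
    het_counts: Mapping[tuple[int, int], int]  # per pair i<j
    n: int
    Ho: float
    He: float
    PIC: float

    def allele_counts(self) -> list[int]:
        k = len(self.hom_counts)
        counts = [2 * h for h in self.hom_counts]
        for (i, j), c in self.het_counts.items():
            counts[i] += c
            counts[j] += c
        return counts


def _compositions(total: int, parts: int) -> Iterable[tuple[int, ...]]:
    """All tuples of ``parts`` nonnegative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def reconstruct_genotype_configuration(
    n: int,
    NA: int,
    Ho: float,
    He: float,
    tolerance: float = 0.0005,
) -> list[GenotypeConfiguration]:
    """All genotype-count configurations matching printed (n, NA, Ho, He).

    Exhaustively enumerates genotype counts over ``NA`` alleles summing
    to ``n`` whose heterozygote count equals ``round(Ho * n)``, every
    allele is observed, and the unbiased He is within ``tolerance`` of
    the printed value.  Configurations differing only by a permutation
    of allele labels are reported once (labels in printed tables are
    arbitrary).  An empty result is allowed.  Bounded to n <= 50 and
    NA <= 4 to keep the enumeration exact and cheap.
    """
    if n > 50 or NA > 4:
        raise ValueError("reconstruction bounded to n <= 50, NA <= 4")
    het_total = round(Ho * n)
    hom_total = n - het_total
    pairs = list(itertools.combinations(range(NA), 2))
    seen: set[tuple] = set()
    results: list[GenotypeConfiguration] = []
    for homs in _compositions(hom_total, NA):
        for hets in _compositions(het_total, len(pairs)) if pairs else [()]:
            het_map = dict(zip(pairs, hets))
            counts = [2 * h for h in homs]
            for (i, j), c in het_map.items():
                counts[i] += c
                counts[j] += c
            if any(c == 0 for c in counts):
                continue  # every one of the NA alleles must be observed
            freqs = [c / (2 * n) for c in counts]
            he = expected_heterozygosity(freqs, n) if NA > 1 else 0.0
            if abs(he - He) > tolerance:
                continue
            pic = polymorphic_information_content(freqs) if NA > 1 else 0.0
            canon = min(
                (
                    tuple(homs[p] for p in perm),
                    tuple(sorted(
                        ((tuple(sorted((perm.index(i), perm.index(j)))), c)
                         for (i, j), c in het_map.items()),
                    )),
                )
                for perm in itertools.permutations(range(NA))
            )
            if canon in seen:
                continue
            seen.add(canon)
            results.append(
                GenotypeConfiguration(
                    hom_counts=homs,
                    het_counts=het_map,
                    n=n,
                    Ho=het_total / n,
                    He=he,
                    PIC=pic,
                )
            )
    return results


def configuration_to_matrix(
    config: GenotypeConfiguration,
    locus: str = "locus",
    population: str = "pop",
) -> GenotypeMatrix:
    """Materialise a configuration as a single-locus GenotypeMatrix."""
    calls: list[tuple[int, int]] = []
    for i, c in enumerate(config.hom_counts, start=1):
        calls.extend([(i, i)] * c)
    for (i, j), c in sorted(config.het_counts.items()):
        calls.extend([(i + 1, j + 1)] * c)
    return GenotypeMatrix(
        population_name=population,
        individual_ids=[f"ind{k + 1}" for k in range(len(calls))],
        locus_names=[locus],
        calls=[[c] for c in calls],
    )


def summaries_to_frame(summaries: Iterable[LocusSummary]) -> pd.DataFrame:
    """Report frame with the marker-table layout, rounded to 3 decimals."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "locus": s.locus,
                "population": s.population,
                "n": s.n,
                "NA": s.NA,
                "Ho": round3(s.Ho),
                "He": round3(s.He),
                "PIC": round3(s.PIC),
                "hwe_p": "" if s.hwe_p is None else round3(s.hwe_p),
                "hwe_deficit_p": "" if s.hwe_deficit_p is None else round3(s.hwe_deficit_p),
                "hwe_excess_p": "" if s.hwe_excess_p is None else round3(s.hwe_excess_p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "population", "n", "NA", "Ho", "He", "PIC",
            "hwe_p", "hwe_deficit_p", "hwe_excess_p",
        ],
    )
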