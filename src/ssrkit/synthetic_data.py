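"""Synthetic inputs for the whole pipeline, with ground truth attached.

Two generators cover the two input kinds the toolkit consumes:

* :func:`simulate_transcripts_with_ssrs` builds a transcript (unigene)
  set with perfect SSRs implanted at recorded coordinates.  Background
  sequence is drawn i.i.d. from a base-composition vector and
  rejection-sampled against the miner itself until it is repeat-free at
  the active thresholds, so the emitted truth table is exact: mining
  the FASTA must recover precisely the implanted loci.
* :func:`simulate_genotypes` draws diploid genotypes for one population
  under a mixture of random mating and autozygosity: with probability
  ``F`` (the inbreeding coefficient) an individual's two allele copies
  at a locus are one draw doubled, otherwise two independent draws from
  the locus's allele frequencies.  Expected heterozygosity under this
  model is ``(1 - F) * (1 - sum p_i^2)``.  Allele codes are assigned
  1..k in descending frequency order.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, SequenceRecord, write_fasta
from .ssr_mining import (
    MiningThresholds, SSRLocus, find_perfect_ssrs, loci_to_frame,
)

#: default background base composition; mildly A/T-rich like insect
#: transcriptomes, but far enough from homopolymer-prone extremes for
#: rejection sampling to converge quickly
DEFAULT_BASE_COMPOSITION: dict[str, float] = {
    "A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30,
}


@dataclass(frozen=True)
class ImplantSpec:
    """A batch of identical SSR implants: ``count`` loci of ``motif x repeats``."""

    motif: str
    repeats: int
    count: int = 1
    min_flank: int = 30

    def __post_init__(self) -> None:
        if self.repeats < 2 or self.count < 0 or self.min_flank < 0:
            raise ValueError("invalid implant specification")


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Design of one simulated population sample."""

    allele_freqs: Mapping[str, Sequence[float]]  # locus -> frequencies
    n_individuals: int
    inbreeding_f: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    population_name: str | None = None

    def __post_init__(self) -> None:
        for locus, freqs in self.allele_freqs.items():
            arr = np.asarray(list(freqs), dtype=float)
            if arr.size == 0 or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies at {locus!r} must be nonnegative "
                    "and sum to 1"
                )
        if not (0.0 <= self.inbreeding_f <= 1.0):
            raise ValueError("inbreeding F must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


def _random_repeat_free_segment(
    rng: np.random.Generator,
    length: int,
    bases: str,
    probs: np.ndarray,
    thresholds: MiningThresholds,
    max_attempts: int = 200,
) -> str:
    """Draw an i.i.d. segment containing no SSR at the given thresholds."""
    if length == 0:
        return ""
    for _ in range(max_attempts):
        seg = "".join(rng.choice(list(bases), size=length, p=probs))
        if not find_perfect_ssrs(seg, thresholds):
            return seg
    raise RuntimeError(
        "could not draw a repeat-free background segment after "
        f"{max_attempts} attempts; the base composition is too skewed "
        "(try something closer to uniform)"
    )


def simulate_transcripts_with_ssrs(
    n_seqs: int,
    length_bounds: tuple[int, int],
    implants: Sequence[ImplantSpec],
    base_composition: Mapping[str, float] | None = None,
    seed: int = 0,
    thresholds: MiningThresholds | None = None,
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate a transcript set with implanted SSRs and its truth table.

    At most one SSR is implanted per sequence (sequences are assigned in
    order, so the total implant count across all specs must not exceed
    ``n_seqs``); remaining sequences are pure repeat-free background.
    The truth table has the miner's TSV schema, and mining the emitted
    FASTA at the same thresholds returns exactly its rows.
    """
    thresholds = thresholds or MiningThresholds()
    comp = dict(base_composition or DEFAULT_BASE_COMPOSITION)
    bases = "".join(sorted(comp))
    probs = np.asarray([comp[b] for b in bases], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must be nonnegative and sum to 1")
    lo, hi = length_bounds
    if lo > hi or lo < 1:
        raise ValueError("bad length bounds")

    jobs: list[ImplantSpec | None] = []
    for spec in implants:
        jobs.extend([spec] * spec.count)
    if len(jobs) > n_seqs:
        raise ValueError(
            f"{len(jobs)} implants requested for only {n_seqs} sequences"
        )
    jobs.extend([None] * (n_seqs - len(jobs)))

    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truth: list[SSRLocus] = []
    for idx, job in enumerate(jobs, start=1):
        seq_id = f"tx{idx:05d}"
        length = int(rng.integers(lo, hi + 1))
        if job is None:
            seq = _random_repeat_free_segment(
                rng, length, bases, probs, thresholds
            )
            records.append(SequenceRecord(id=seq_id, seq=seq))
            continue
        insert = job.motif * job.repeats
        flank_total = max(length - len(insert), 2 * job.min_flank)
        for _ in range(200):
            left_len = int(
                rng.integers(job.min_flank, flank_total - job.min_flank + 1)
            )
            left = _random_repeat_free_segment(
                rng, left_len, bases, probs, thresholds
            )
            right = _random_repeat_free_segment(
                rng, flank_total - left_len, bases, probs, thresholds
            )
            seq = left + insert + right
            # junctions can extend or create runs; accept only if mining
            # recovers exactly the implant
            mined = find_perfect_ssrs(seq, thresholds)
            expected = SSRLocus(
                seq_id="seq", motif=job.motif, repeats=job.repeats,
                start=left_len + 1, end=left_len + len(insert),
            )
            if len(mined) == 1 and (
                mined[0].motif, mined[0].repeats, mined[0].start, mined[0].end
            ) == (expected.motif, expected.repeats, expected.start, expected.end):
                break
        else:
            raise RuntimeError(
                f"could not place implant {job.motif}x{job.repeats} cleanly; "
                "composition or flank bounds are too tight"
            )
        records.append(SequenceRecord(id=seq_id, seq=seq))
        truth.append(
            SSRLocus(
                seq_id=seq_id, motif=job.motif, repeats=job.repeats,
                start=left_len + 1, end=left_len + len(insert),
            )
        )

    truth_frame = loci_to_frame(truth)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if truth_path is not None:
        truth_frame.to_csv(truth_path, sep="\t", index=False)
    return records, truth_frame


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Draw one population of diploid genotypes under the inbreeding mixture."""
    rng = np.random.default_rng(spec.seed)
    loci = list(spec.allele_freqs)
    n = spec.n_individuals
    ind_ids = [f"sim{spec.seed}_{i + 1}" for i in range(n)]
    calls: list[list[tuple[int, int] | None]] = [[] for _ in range(n)]
    for locus in loci:
        freqs = np.asarray(list(spec.allele_freqs[locus]), dtype=float)
        order = np.argsort(-freqs, kind="stable")
        codes = np.empty_like(order)
        codes[order] = np.arange(1, freqs.size + 1)  # 1..k by descending freq
        sorted_freqs = freqs[order]
        for i in range(n):
            if rng.random() < spec.inbreeding_f:
                a = int(rng.choice(freqs.size, p=sorted_freqs)) + 1
                call: tuple[int, int] = (a, a)
            else:
                a1 = int(rng.choice(freqs.size, p=sorted_freqs)) + 1
                a2 = int(rng.choice(freqs.size, p=sorted_freqs)) + 1
                call = (min(a1, a2), max(a1, a2))
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                calls[i].append(None)
            else:
                calls[i].append(call)
    name = spec.population_name or ind_ids[-1]
    return GenotypeMatrix(
        population_name=name,
        individual_ids=ind_ids,
        locus_names=loci,
        calls=calls,
    )


def simulate_two_population_panel(
    n_individuals: int = 12,
    n_loci: int = 9,
    seed: int = 0,
    inbreeding_f: tuple[float, float] = (0.0, 0.3),
    missing_rate: float = 0.0,
) -> list[GenotypeMatrix]:
    """Convenience: a two-population marker-panel sample.

    Mirrors the design of a small validation study: two populations of
    ``n_individuals`` beetles genotyped at ``n_loci`` SSR loci with 2-3
    alleles each, the second population optionally showing homozygote
    excess through a nonzero inbreeding coefficient.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, list[float]] = {}
    for j in range(n_loci):
        k = int(rng.integers(2, 4))  # 2 or 3 alleles
        raw = rng.dirichlet(np.ones(k) * 3.0)
        freqs[f"L{j + 1}"] = [float(x) for x in raw]
    pops = []
    for p, f in enumerate(inbreeding_f):
        mat = simulate_genotypes(
            GenotypeSimSpec(
                allele_freqs=freqs,
                n_individuals=n_individuals,
                inbreeding_f=f,
                missing_rate=missing_rate,
                seed=seed + 1000 * (p + 1),
                population_name=f"pop{p + 1}",
            )
        )
        pops.append(mat)
    return pops
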