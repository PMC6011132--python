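"""Primer-candidate enumeration and scoring for SSR loci.

Candidates are primer pairs whose amplicon fully spans an SSR locus and
that satisfy hard constraints on product size (default 100-400 bp),
primer length (18-28 bp, optimum 23), GC fraction, melting temperature,
Tm balance, and a simple self/cross complementarity screen.  Surviving
pairs are ranked by an explicit additive penalty:

    penalty = |len_f - opt| + |len_r - opt|
            + w_tm * |Tm_f - Tm_r|
            + w_gc * (distance of each GC fraction outside [0.45, 0.55])

with w_tm = 1.0 per degree C and w_gc = 10.0.  This is a deliberately
transparent scorer, not an emulation of any commercial design suite's
unpublished penalty model; the hard constraints are the published
design parameters.

Melting temperatures come from the nearest-neighbor model (SantaLucia
1998 unified parameters via Biopython's ``Tm_NN``) at the fixed salt
and oligo concentrations recorded in :class:`PrimerConstraints`.

Mononucleotide-repeat loci are excluded from screening by default, as
is conventional when designing length-polymorphism assays.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .io_formats import SequenceRecord
from .motif_classification import reverse_complement
from .ssr_mining import SSRLocus

PRIMER_TSV_COLUMNS = [
    "seq_id", "locus", "forward_seq", "reverse_seq", "forward_start",
    "reverse_end", "product_size", "tm_forward", "tm_reverse",
    "gc_forward", "gc_reverse", "penalty",
]


@dataclass(frozen=True)
class PrimerConstraints:
    """Hard design constraints plus the fixed scoring/thermodynamic config."""

    product_min: int = 100
    product_max: int = 400
    primer_min: int = 18
    primer_max: int = 28
    primer_opt: int = 23
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 50.0
    tm_max: float = 65.0
    max_tm_diff: float = 5.0
    # soft-score weights
    w_tm: float = 1.0     # penalty units per degree C of Tm imbalance
    w_gc: float = 10.0    # penalty units per unit GC distance outside band
    gc_band: tuple[float, float] = (0.45, 0.55)
    # complementarity screen: reject if a contiguous complementary run
    # of at least this many bases exists (self- or cross-dimer)
    max_complementarity_run: int = 8
    # fixed thermodynamic conditions for Tm_NN (mM salts, nM oligos)
    salt_na_mM: float = 50.0
    oligo_nM: float = 250.0

    def __post_init__(self) -> None:
        if not (self.primer_min <= self.primer_opt <= self.primer_max):
            raise ValueError("need primer_min <= primer_opt <= primer_max")
        if self.product_min <= 2 * self.primer_min:
            raise ValueError("product_min must exceed twice primer_min")


@dataclass(frozen=True)
class PrimerCandidate:
    """One scored primer pair; reverse_seq is 5'->3' on the opposite strand."""

    forward_seq: str
    reverse_seq: str
    forward_start: int  # 1-based template coordinate of the forward 5' end
    reverse_end: int    # 1-based template coordinate of the reverse 5' end
    product_size: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    penalty: float


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of screening one locus: candidates, or a structured reason."""

    candidates: tuple[PrimerCandidate, ...]
    reason: str | None = None  # set when candidates is empty

    def __bool__(self) -> bool:
        return bool(self.candidates)


def melting_temperature(
    primer: str, constraints: PrimerConstraints | None = None
) -> float:
    """Nearest-neighbor duplex melting temperature in degrees C.

    Deterministic for fixed constraints; requires a pure-ACGT primer of
    at least 8 bases.
    """
    constraints = constraints or PrimerConstraints()
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 bases")
    if any(b not in "ACGT" for b in primer):
        raise ValueError(f"primer must be over ACGT, got {primer!r}")
    return float(
        MeltingTemp.Tm_NN(
            primer,
            nn_table=MeltingTemp.DNA_NN3,  # SantaLucia 1998 unified table
            Na=constraints.salt_na_mM,
            dnac1=constraints.oligo_nM,
            dnac2=constraints.oligo_nM,
            saltcorr=5,
        )
    )


def _has_complementary_run(a: str, b: str, k: int) -> bool:
    """True if ``a`` and ``b`` share a contiguous complementary stretch >= k.

    A run of length >= k exists iff some k-mer of ``a`` occurs in
    revcomp(b), so set containment replaces the quadratic
    common-substring scan.
    """
    rb = reverse_complement(b)
    if len(a) < k or len(rb) < k:
        return False
    kmers = {rb[i:i + k] for i in range(len(rb) - k + 1)}
    return any(a[i:i + k] in kmers for i in range(len(a) - k + 1))


def _passes_single(seq: str, c: PrimerConstraints) -> tuple[float, float] | None:
    """(tm, gc) if the single primer passes its hard constraints, else None."""
    gc = gc_fraction(seq)
    if not (c.gc_min <= gc <= c.gc_max):
        return None
    tm = melting_temperature(seq, c)
    if not (c.tm_min <= tm <= c.tm_max):
        return None
    if _has_complementary_run(seq, seq, c.max_complementarity_run):
        return None
    return tm, gc


def _gc_band_distance(gc: float, band: tuple[float, float]) -> float:
    lo, hi = band
    if gc < lo:
        return lo - gc
    if gc > hi:
        return gc - hi
    return 0.0


def screen_primer_pairs(
    record: SequenceRecord,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
    top_k: int = 3,
    exclude_mononucleotide: bool = True,
) -> ScreenOutcome:
    """Enumerate, filter and rank primer pairs flanking one SSR locus.

    Every returned candidate's amplicon contains the full repeat run and
    satisfies all hard constraints; candidates are ranked by ascending
    penalty with deterministic tie-breaking (leftmost forward start,
    then shortest product).
    """
    c = constraints or PrimerConstraints()
    seq = record.seq
    if locus.start < 1 or locus.end > len(seq):
        raise ValueError(
            f"locus [{locus.start},{locus.end}] outside record "
            f"{record.id!r} of length {len(seq)}"
        )
    if exclude_mononucleotide and len(locus.motif) == 1:
        return ScreenOutcome((), reason="mononucleotide_locus")

    # forward primers end strictly before the repeat, reverse primers
    # start strictly after it (0-based [s, e) template slices)
    left_limit = locus.start - 1   # length of the left flank
    right_start = locus.end        # 0-based start of the right flank
    candidates: list[PrimerCandidate] = []
    fwd: list[tuple[int, int, str, float, float]] = []  # (start0, len, seq, tm, gc)
    for flen in range(c.primer_min, c.primer_max + 1):
        for s in range(0, left_limit - flen + 1):
            sub = seq[s:s + flen]
            if "N" in sub or any(b not in "ACGT" for b in sub):
                continue
            tg = _passes_single(sub, c)
            if tg:
                fwd.append((s, flen, sub, tg[0], tg[1]))
    rev: list[tuple[int, int, str, float, float]] = []  # (end0_excl, len, seq, tm, gc)
    for rlen in range(c.primer_min, c.primer_max + 1):
        for e in range(right_start + rlen, len(seq) + 1):
            sub = seq[e - rlen:e]
            if any(b not in "ACGT" for b in sub):
                continue
            rseq = reverse_complement(sub)
            tg = _passes_single(rseq, c)
            if tg:
                rev.append((e, rlen, rseq, tg[0], tg[1]))

    if not fwd or not rev:
        return ScreenOutcome((), reason="no_candidates")

    rev.sort(key=lambda t: t[0])
    rev_ends = [t[0] for t in rev]
    scored: list[tuple[float, int, int, int, int]] = []
    for fi, (s, flen, fseq, ftm, fgc) in enumerate(fwd):
        lo = bisect_left(rev_ends, s + c.product_min)
        hi = bisect_right(rev_ends, s + c.product_max)
        fgc_pen = _gc_band_distance(fgc, c.gc_band)
        flen_pen = abs(flen - c.primer_opt)
        for ri in range(lo, hi):
            e, rlen, _, rtm, rgc = rev[ri]
            if abs(ftm - rtm) > c.max_tm_diff:
                continue
            penalty = (
                flen_pen + abs(rlen - c.primer_opt)
                + c.w_tm * abs(ftm - rtm)
                + c.w_gc * (fgc_pen + _gc_band_distance(rgc, c.gc_band))
            )
            scored.append((penalty, s + 1, e - s, fi, ri))
    # cross-dimer screening is the expensive hard constraint; walking the
    # ranking lazily applies it only until top_k survivors are found
    scored.sort()
    for penalty, start1, product, fi, ri in scored:
        if len(candidates) >= top_k:
            break
        s, flen, fseq, ftm, fgc = fwd[fi]
        e, rlen, rseq, rtm, rgc = rev[ri]
        if _has_complementary_run(fseq, rseq, c.max_complementarity_run):
            continue
        candidates.append(
            PrimerCandidate(
                forward_seq=fseq, reverse_seq=rseq,
                forward_start=start1, reverse_end=e,
                product_size=product,
                tm_forward=ftm, tm_reverse=rtm,
                gc_forward=fgc, gc_reverse=rgc,
                penalty=penalty,
            )
        )
    if not candidates:
        return ScreenOutcome((), reason="no_candidates")
    return ScreenOutcome(tuple(candidates))


def candidates_to_frame(
    results: Iterable[tuple[str, str, ScreenOutcome]],
) -> pd.DataFrame:
    """Flatten (seq_id, locus_label, outcome) triples into the report frame."""
    rows = []
    for seq_id, locus_label, outcome in results:
        for cand in outcome.candidates:
            rows.append(
                {
                    "seq_id": seq_id,
                    "locus": locus_label,
                    "forward_seq": cand.forward_seq,
                    "reverse_seq": cand.reverse_seq,
                    "forward_start": cand.forward_start,
                    "reverse_end": cand.reverse_end,
                    "product_size": cand.product_size,
                    "tm_forward": round(cand.tm_forward, 2),
                    "tm_reverse": round(cand.tm_reverse, 2),
                    "gc_forward": round(cand.gc_forward, 3),
                    "gc_reverse": round(cand.gc_reverse, 3),
                    "penalty": round(cand.penalty, 3),
                }
            )
    return pd.DataFrame(rows, columns=PRIMER_TSV_COLUMNS)
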