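"""Primer screening: hard constraints, penalty ranking, Tm model."""

from __future__ import annotations

import math
import random

import pytest

from ssrkit.io_formats import SequenceRecord
from ssrkit.motif_classification import reverse_complement
from ssrkit.primer_screening import (
    PrimerConstraints, _has_complementary_run, melting_temperature,
    screen_primer_pairs,
)
from ssrkit.ssr_mining import SSRLocus, find_perfect_ssrs
from ssrkit.synthetic_data import ImplantSpec, simulate_transcripts_with_ssrs

# SantaLucia (1998) unified nearest-neighbor stack parameters,
# (dH kcal/mol, dS cal/mol/K), keyed by the 5'->3' top-strand step.
_NN_STACKS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def oracle_tm(seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Independent reimplementation of the nearest-neighbor Tm: direct
    enthalpy/entropy sums with terminal initiation terms and the
    entropic monovalent-salt correction 0.368 (N-1) ln[Na+]."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh, ds = dh + 2.3, ds + 4.1
        else:
            dh, ds = dh + 0.1, ds - 2.8
    for i in range(len(seq) - 1):
        h, s = _NN_STACKS[seq[i:i + 2]]
        dh, ds = dh + h, ds + s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = (oligo_nM - oligo_nM / 2.0) * 1e-9
    return (1000.0 * dh) / (ds + 1.987 * math.log(k)) - 273.15


def test_tm_pinned_value():
    assert melting_temperature("ACGTACGTACGTACGTACGT") == pytest.approx(
        56.1458301607106, abs=1e-6
    )


def test_tm_matches_oracle_on_random_primers():
    rng = random.Random(3)
    for _ in range(100):
        p = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 28)))
        assert melting_temperature(p) == pytest.approx(oracle_tm(p), abs=1e-6)


def test_tm_reverse_complement_invariant():
    rng = random.Random(4)
    for _ in range(50):
        p = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 26)))
        assert melting_temperature(p) == pytest.approx(
            melting_temperature(reverse_complement(p)), abs=1e-9
        )


def test_tm_nondecreasing_appending_gc():
    rng = random.Random(5)
    for _ in range(50):
        p = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 26)))
        assert melting_temperature(p + "GC") >= melting_temperature(p) - 1e-9


def test_tm_input_validation():
    with pytest.raises(ValueError):
        melting_temperature("ACGT")  # too short
    with pytest.raises(ValueError):
        melting_temperature("ACGTACGTNACGT")


def test_complementary_run_detection():
    a = "AAAACCCCGGGG"
    assert _has_complementary_run(a, reverse_complement(a), 8)
    assert not _has_complementary_run("AAAAAAAAAAAA", "AAAAAAAAAAAA", 8)


@pytest.fixture(scope="module")
def screened_locus():
    records, truth = simulate_transcripts_with_ssrs(
        n_seqs=2, length_bounds=(320, 380),
        implants=[ImplantSpec("AT", 6, 2)], seed=21,
    )
    rec = records[0]
    (locus,) = find_perfect_ssrs(rec)
    outcome = screen_primer_pairs(rec, locus, top_k=5)
    return rec, locus, outcome


def test_candidates_satisfy_all_hard_constraints(screened_locus):
    rec, locus, outcome = screened_locus
    c = PrimerConstraints()
    assert outcome.candidates, "expected at least one candidate"
    for cand in outcome.candidates:
        assert c.primer_min <= len(cand.forward_seq) <= c.primer_max
        assert c.primer_min <= len(cand.reverse_seq) <= c.primer_max
        assert c.product_min <= cand.product_size <= c.product_max
        assert cand.product_size == cand.reverse_end - cand.forward_start + 1
        assert c.gc_min <= cand.gc_forward <= c.gc_max
        assert c.gc_min <= cand.gc_reverse <= c.gc_max
        assert c.tm_min <= cand.tm_forward <= c.tm_max
        assert c.tm_min <= cand.tm_reverse <= c.tm_max
        assert abs(cand.tm_forward - cand.tm_reverse) <= c.max_tm_diff
        # amplicon spans the repeat entirely
        assert cand.forward_start + len(cand.forward_seq) - 1 < locus.start
        assert cand.reverse_end - len(cand.reverse_seq) + 1 > locus.end
        # primer sequences match the template strands
        f0 = cand.forward_start - 1
        assert rec.seq[f0:f0 + len(cand.forward_seq)] == cand.forward_seq
        template = rec.seq[cand.reverse_end - len(cand.reverse_seq):cand.reverse_end]
        assert reverse_complement(template) == cand.reverse_seq


def test_ranking_deterministic_and_sorted(screened_locus):
    rec, locus, outcome = screened_locus
    pens = [c.penalty for c in outcome.candidates]
    assert pens == sorted(pens)
    again = screen_primer_pairs(rec, locus, top_k=5)
    assert again.candidates == outcome.candidates


def test_length_penalty_prefers_optimum():
    """23/23 beats 20/26 when all other terms are equal by construction."""
    c = PrimerConstraints()
    pen = lambda lf, lr: abs(lf - c.primer_opt) + abs(lr - c.primer_opt)
    assert pen(23, 23) == 0 < pen(20, 26) == 6


def test_mononucleotide_locus_excluded():
    flank = "GACTGCAGTCAGGTCACGGTATGCCTAGCTAGGATCCGTTAACGGCATGCAAGTCC"
    rec = SequenceRecord("m", flank * 3 + "A" * 12 + flank[::-1] * 3)
    (locus,) = find_perfect_ssrs(rec)
    assert locus.motif == "A"
    out = screen_primer_pairs(rec, locus)
    assert not out.candidates and out.reason == "mononucleotide_locus"
    # but it can be screened when the pre-filter is disabled
    out2 = screen_primer_pairs(rec, locus, exclude_mononucleotide=False)
    assert out2.reason != "mononucleotide_locus"


def test_short_flanks_give_structured_reason():
    rec = SequenceRecord("s", "ACGTT" + "AT" * 6 + "GGCCA")
    locus = find_perfect_ssrs(rec)[0]
    out = screen_primer_pairs(rec, locus)
    assert not out.candidates and out.reason == "no_candidates"


def test_locus_outside_record_rejected():
    rec = SequenceRecord("s", "ACGT" * 10)
    locus = SSRLocus(seq_id="s", motif="AT", repeats=6, start=100, end=111)
    with pytest.raises(ValueError):
        screen_primer_pairs(rec, locus)


def test_constraint_validation():
    with pytest.raises(ValueError):
        PrimerConstraints(primer_opt=30)
    with pytest.raises(ValueError):
        PrimerConstraints(product_min=30)
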