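import csv
from importlib import resources
from types import SimpleNamespace

import numpy as np
import pytest

from cernapipe.duplex import (
    BindingHit,
    DuplexAlignment,
    ScoringParams,
    align_duplex,
    duplex_energy,
    filter_hits,
    hit_passes,
    load_stack_table,
    scan_all,
    scan_circrna,
)
from cernapipe.records import CircSequence, MiRNA, revcomp

from conftest import EXAMPLE_MIR_SEQ, random_rna
from oracles import duplex_score_oracle

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _raw_stack_table() -> dict[tuple[str, str], float]:
    """Read the bundled stack table independently of the package loader."""
    path = resources.files("cernapipe.data").joinpath("nn_stacks.tsv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {(r["top"], r["bottom"]): float(r["dg_kcal_mol"]) for r in rows}


# ------------------------------------------------------------------ alignment


def test_perfect_duplex_score():
    # perfect complement: positions 2-8 score 5*4 each, the rest 5 each
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    window = revcomp(mir.sequence)
    aln = align_duplex(mir, window)
    expected = 7 * 5 * 4 + (len(mir.sequence) - 7) * 5
    assert aln.score == pytest.approx(expected) == pytest.approx(215.0)
    # every miRNA base paired WC, no gaps
    assert len(aln.pairs) == len(mir.sequence)
    assert all(cls == "WC" for *_, cls in aln.pairs)
    assert aln.target_span == (0, len(window))


def test_seed_wobble_costs_scaled_delta():
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    window = list(revcomp(mir.sequence))
    # position 6 of the miRNA is U; its partner sits at window index L-6.
    # A instead of the WC partner... the WC partner of U is A; change it
    # to G for a G:U wobble: delta = (5 - 2) * seed_scale = 12.
    pos = 6  # 1-based miRNA position, inside the scaled 2-8 region
    assert mir.sequence[pos - 1] == "U"
    widx = len(window) - pos
    assert window[widx] == "A"
    window[widx] = "G"
    aln = align_duplex(mir, "".join(window))
    assert aln.score == pytest.approx(215.0 - 12.0)


def test_window_overhangs_are_free():
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    window = "ACGU" + revcomp(mir.sequence) + "GGCC"
    aln = align_duplex(mir, window)
    assert aln.score == pytest.approx(215.0)
    assert aln.target_span == (4, 4 + len(mir.sequence))


def test_align_matches_exhaustive_enumeration_small(rng):
    params = ScoringParams()
    for _ in range(30):
        m = int(rng.integers(6, 9))
        n = int(rng.integers(m + 1, m + 5))
        mir_seq = random_rna(rng, m)
        # half the time give the window real complementarity
        if rng.random() < 0.5:
            window = random_rna(rng, n)
        else:
            w = list(random_rna(rng, n))
            off = int(rng.integers(0, n - m + 1))
            w[off : off + m] = revcomp(mir_seq)
            window = "".join(w)
        mir = SimpleNamespace(name="t", sequence=mir_seq)
        got = align_duplex(mir, window, params).score
        expected = duplex_score_oracle(mir_seq, window)
        assert got == pytest.approx(expected), (mir_seq, window)


def test_align_matches_exhaustive_enumeration_len10(rng):
    params = ScoringParams()
    for _ in range(2):
        mir_seq = random_rna(rng, 10)
        w = list(random_rna(rng, 11))
        w[1:11] = revcomp(mir_seq)[:10]
        window = "".join(w)
        mir = SimpleNamespace(name="t", sequence=mir_seq)
        got = align_duplex(mir, window, params).score
        assert got == pytest.approx(duplex_score_oracle(mir_seq, window))


# --------------------------------------------------------------------- energy


def test_stack_table_symmetry_and_sign():
    table = _raw_stack_table()
    assert len(table) == 36
    for (top, bottom), dg in table.items():
        assert dg < 0
        sym = (bottom[::-1], top[::-1])
        assert table[sym] == pytest.approx(dg), (top, bottom)
    # the package loader agrees with the raw file
    assert load_stack_table() == table


def test_perfect_duplex_energy_hand_sum():
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    window = revcomp(mir.sequence)
    aln = align_duplex(mir, window)
    table = _raw_stack_table()
    expected = sum(
        table[(window[j] + window[j + 1], _COMP[window[j]] + _COMP[window[j + 1]])]
        for j in range(len(window) - 1)
    )
    assert duplex_energy(aln) == pytest.approx(expected)
    assert duplex_energy(aln) < -20.0  # a perfect 22-mer duplex passes


def test_loop_penalty_per_helix_interruption():
    # fabricate an alignment: 3 WC pairs, mismatch column, 3 WC pairs
    mir_seq = "GGG" + "A" + "GGG" + "A" * 11  # length 18 for realism
    window = "CCC" + "C" + "CCC"  # C opposite A at column 3 = mismatch
    columns = [(i, i) for i in range(7)]
    aln = DuplexAlignment(mirna="t", mir_seq=mir_seq, window=window,
                          score=0.0, columns=columns)
    table = _raw_stack_table()
    stack_gc = table[("CC", "GG")]
    expected = 2 * stack_gc * 2 + ScoringParams().loop_penalty
    assert duplex_energy(aln) == pytest.approx(expected)


def test_unpaired_alignment_energy_zero():
    aln = DuplexAlignment(mirna="t", mir_seq="AAAA", window="CCCC",
                          score=0.0, columns=[(0, None), (1, None)])
    assert duplex_energy(aln) == 0.0


# ------------------------------------------------------------------ thresholds


def test_pass_thresholds_inclusive():
    assert hit_passes(150.0, -20.0)
    assert not hit_passes(149.9999, -20.0)
    assert not hit_passes(150.0, -19.9999)
    assert hit_passes(150.0001, -20.0001)


def test_filter_hits():
    mk = lambda s, e: BindingHit("c", "m", 0, 22, s, e, hit_passes(s, e))
    hits = [mk(150.0, -20.0), mk(149.0, -30.0), mk(200.0, -19.0)]
    kept = filter_hits(hits)
    assert [(h.score, h.energy) for h in kept] == [(150.0, -20.0)]


# ------------------------------------------------------------- circular scan


def _planted_circ(rng, mir: MiRNA, pos: int, L: int = 150) -> CircSequence:
    seq = list(random_rna(rng, L))
    mre = revcomp(mir.sequence)
    for k, b in enumerate(mre):
        seq[(pos + k) % L] = b
    return CircSequence("c", "gene", "".join(seq))


def test_scan_finds_planted_mre(rng):
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    circ = _planted_circ(rng, mir, pos=40)
    hits = scan_circrna(mir, circ)
    passing = [h for h in hits if h.passes]
    assert any(h.start == 40 for h in passing)
    best = max(passing, key=lambda h: h.score)
    assert best.score == pytest.approx(215.0)
    assert best.end - best.start == len(mir.sequence)


def test_scan_finds_junction_spanning_mre(rng):
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    L = 150
    circ = _planted_circ(rng, mir, pos=L - 10)  # spans the junction
    hits = [h for h in scan_circrna(mir, circ) if h.passes]
    assert any(h.start == L - 10 for h in hits)
    # the same sequence scanned linearly misses the split site
    linear = [h for h in scan_circrna(mir, circ, circular=False) if h.passes]
    assert not any(h.score == pytest.approx(215.0) for h in linear)


def test_scan_rotation_invariance(rng):
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    circ = _planted_circ(rng, mir, pos=40)
    L = len(circ.sequence)
    base = {((h.start) % L, round(h.score, 6), round(h.energy, 6))
            for h in scan_circrna(mir, circ)}
    for r in (1, 37, 100):
        rot = CircSequence("c", "gene", circ.sequence[r:] + circ.sequence[:r])
        got = {((h.start + r) % L, round(h.score, 6), round(h.energy, 6))
               for h in scan_circrna(mir, rot)}
        assert got == base, r


def test_anchored_equals_exhaustive_on_passing_hits(rng):
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    circ = _planted_circ(rng, mir, pos=17, L=90)
    key = lambda hits: {(h.start, round(h.score, 6), round(h.energy, 6))
                        for h in hits if h.passes}
    anchored = key(scan_circrna(mir, circ))
    exhaustive = key(scan_circrna(mir, circ, exhaustive=True))
    assert anchored == exhaustive
    assert anchored  # the planted site passes


def test_scan_short_circ_does_not_crash():
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    circ = CircSequence("tiny", "gene", "ACGUACGUACGU")  # shorter than the miRNA
    hits = scan_circrna(mir, circ)
    assert isinstance(hits, list)


def test_scan_all_table(rng):
    mir = MiRNA("let7-like", EXAMPLE_MIR_SEQ)
    c1 = _planted_circ(rng, mir, pos=10)
    c2 = CircSequence("c2", "gene2", random_rna(rng, 120))
    table = scan_all([mir], [c1, c2])
    assert list(table.columns) == ["circ", "mirna", "start", "end",
                                   "score", "energy", "passes"]
    assert table["passes"].any()
    # deterministically sorted
    assert table.equals(table.sort_values(["mirna", "circ", "start"],
                                          kind="mergesort").reset_index(drop=True))


def test_scoring_params_validation():
    with pytest.raises(ValueError):
        ScoringParams(seed_scale=0.5)
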