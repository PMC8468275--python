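"""Independent reference implementations used only by the tests.

Everything here is deliberately written from first principles (explicit
base-pair checks, exhaustive enumeration, textbook formulas) and shares
no code with the package modules it cross-checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

from scipy.stats import t as t_dist

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _wc(target: str, mir: str) -> bool:
    return _COMP[mir] == target


def _wobble(target: str, mir: str) -> bool:
    return (target, mir) in (("G", "U"), ("U", "G"))


# ------------------------------------------------------------------- sites


def canonical_sites_oracle(mir: str, utr: str) -> set[tuple[int, int, str]]:
    """Exhaustive scan for canonical seed sites via per-position pairing.

    Returns {(start, end, site_type)} with the strongest-wins priority:
    a 6-nt match to miRNA positions 2-7 anchors each locus; the m8 pair
    and the position-1 adenosine decide the type.
    """
    out = set()
    for i in range(len(utr) - 5):
        # utr[i + k] must pair miRNA position 7 - k (1-based), k = 0..5
        if not all(_wc(utr[i + k], mir[6 - k]) for k in range(6)):
            continue
        m8 = i > 0 and _wc(utr[i - 1], mir[7])
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if m8 and a1:
            out.add((i - 1, i + 7, "8mer"))
        elif m8:
            out.add((i - 1, i + 6, "7mer-m8"))
        elif a1:
            out.add((i, i + 7, "7mer-1A"))
        else:
            out.add((i, i + 6, "6mer"))
    return out


def noncanonical_sites_oracle(mir: str, utr: str) -> set[tuple[int, int, str]]:
    """Brute-force centered and 3'-compensatory sites (before canonical
    exclusion): every window is tested against the definitions."""
    out = set()
    # centered: 11 contiguous WC pairs to positions 4-14 or 5-15
    for lo in (3, 4):
        for i in range(len(utr) - 10):
            if all(_wc(utr[i + k], mir[lo + 10 - k]) for k in range(11)):
                out.add((i, i + 11, "centered"))
    # 3p-compensatory: seed (positions 2-7) with exactly one
    # wobble-or-mismatch, plus 4 contiguous WC pairs to positions 13-16
    # or 14-17 ending 0-8 nt 5' of the seed match
    for i in range(len(utr) - 5):
        bad = sum(0 if _wc(utr[i + k], mir[6 - k]) else 1 for k in range(6))
        if bad != 1:
            continue
        for lo in (12, 13):
            for end3 in range(max(0, i - 8 - 4) + 4, i + 1):
                s3 = end3 - 4
                if s3 < 0 or end3 > i:
                    continue
                if all(_wc(utr[s3 + k], mir[lo + 3 - k]) for k in range(4)):
                    out.add((s3, i + 6, "3p-compensatory"))
    return out


# ------------------------------------------------------------------- duplex


def duplex_score_oracle(
    mir: str,
    window: str,
    match: float = 5.0,
    gu: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -2.0,
    seed_scale: float = 4.0,
) -> float:
    """Exhaustive max over all non-crossing appositions of the miRNA
    against the window (window overhangs free, miRNA fully consumed).

    An alignment is a strictly increasing set of (miRNA index from the
    3' end, window index) appositions; unpaired miRNA stretches between
    (and flanking) the appositions are affine gaps, unpaired window
    stretches *between* appositions likewise, and window flanks are
    free.
    """
    q = mir[::-1]  # 3'->5'; q[i] is miRNA 1-based position len(mir) - i
    m, n = len(q), len(window)

    def pair_score(i: int, j: int) -> float:
        t, b = window[j], q[i]
        if _wc(t, b):
            s = match
        elif _wobble(t, b):
            s = gu
        else:
            s = mismatch
        if 2 <= (m - i) <= 8:
            s *= seed_scale
        return s

    def gap_cost(length: int) -> float:
        return gap_open + length * gap_extend if length > 0 else 0.0

    best = gap_cost(m)  # the empty alignment: the whole miRNA gapped
    for k in range(1, min(m, n) + 1):
        for mi in itertools.combinations(range(m), k):
            for wj in itertools.combinations(range(n), k):
                s = sum(pair_score(i, j) for i, j in zip(mi, wj))
                s += gap_cost(mi[0]) + gap_cost(m - 1 - mi[-1])
                for (i1, j1), (i2, j2) in zip(zip(mi, wj), zip(mi[1:], wj[1:])):
                    s += gap_cost(i2 - i1 - 1) + gap_cost(j2 - j1 - 1)
                if s > best:
                    best = s
    return best


# ------------------------------------------------------------------- triads


def triads_oracle(
    mrna_pairs: dict[str, set[tuple[str, str]]],
    circ_pairs: dict[str, set[tuple[str, str]]],
) -> set[tuple[str, str, str, str]]:
    """Brute-force triple loop over (miRNA, gene, circ) per class.

    Inputs: per class, the kept (mirna, gene) and (mirna, circ) pairs.
    """
    out = set()
    for cls in mrna_pairs:
        mirs = {m for m, _ in mrna_pairs[cls]} | {m for m, _ in circ_pairs[cls]}
        genes = {g for _, g in mrna_pairs[cls]}
        circs = {c for _, c in circ_pairs[cls]}
        for m in mirs:
            for g in genes:
                for c in circs:
                    if (m, g) in mrna_pairs[cls] and (m, c) in circ_pairs[cls]:
                        out.add((m, g, c, cls))
    return out


# ---------------------------------------------------------------- statistics


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value from the textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))
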