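"""MiRanda-style miRNA:target duplex alignment, free energy, circRNA scan.

The aligner runs a semi-global affine-gap dynamic program of the
reversed miRNA against a target window: the miRNA must be consumed in
full, window overhangs are free.  Per-position pair scores (Watson-Crick
+5, G:U wobble +2, mismatch -3) are multiplied by ``seed_scale`` (default
4) when the miRNA position lies in the seed-extended region 2-8; gap
penalties (open -8, extend -2 per base) are not scaled.

Duplex free energy is a simplified nearest-neighbor sum: consecutive
paired positions (WC or wobble) contribute the Turner-style stack
energies shipped in ``data/nn_stacks.tsv``, and every maximal
interruption (mismatch or gap run) between two helices adds one fixed
loop penalty.  An unpaired alignment has energy 0.

circRNAs are scanned circularly: the sequence is extended by its first
``window - 1`` nucleotides so that sites spanning the backsplice
junction are found exactly once, and hit coordinates are reported
modulo the circle length.  A hit passes when score >= ``score_min``
(default 150) and energy <= ``energy_max`` (default -20 kcal/mol),
both inclusive.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .records import MiRNA, CircSequence, normalize_rna, pair_class

NEG_INF = float("-inf")
_M, _X, _Y = 0, 1, 2  # pair column / gapped miRNA base / gapped window base


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    gu: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 4.0      # applied to paired positions at miRNA 2-8
    score_min: float = 150.0
    energy_max: float = -20.0    # kcal/mol; pass when dG <= energy_max
    loop_penalty: float = 4.0    # kcal/mol per helix interruption
    window_slack: int = 8        # window = miRNA length + slack
    min_hit_separation: int = 4  # nt between reported local maxima

    def __post_init__(self) -> None:
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")


@functools.lru_cache(maxsize=1)
def load_stack_table() -> dict[tuple[str, str], float]:
    """Stack energies keyed by (top, bottom): top = two adjacent target
    bases 5'->3', bottom = the two miRNA bases pairing them (read 3'->5',
    i.e. bottom[k] pairs top[k])."""
    with resources.files("cernapipe.data").joinpath("nn_stacks.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {(row.top, row.bottom): float(row.dg_kcal_mol) for row in df.itertuples()}


@dataclass
class DuplexAlignment:
    """Best non-crossing pairing of one miRNA against one target window.

    ``columns`` lists alignment columns 5'->3' along the target as
    (mir_index, window_index) with ``None`` marking a gap; ``mir_index``
    is 0-based from the miRNA 5' end.  ``pairs`` is the subset of
    columns where both sides are present, annotated with the pair class
    ('WC', 'GU' or 'mismatch').
    """

    mirna: str
    mir_seq: str
    window: str
    score: float
    columns: list[tuple[int | None, int | None]]

    @property
    def pairs(self) -> list[tuple[int, int, str]]:
        return [
            (mi, wj, pair_class(self.window[wj], self.mir_seq[mi]))
            for mi, wj in self.columns
            if mi is not None and wj is not None
        ]

    @property
    def target_span(self) -> tuple[int, int]:
        """[start, end) window interval covered by aligned miRNA columns."""
        js = [wj for mi, wj in self.columns if wj is not None and mi is not None]
        if not js:
            return (0, 0)
        return (min(js), max(js) + 1)


def _pair_score(t: str, m: str, seed: bool, params: ScoringParams) -> float:
    cls = pair_class(t, m)
    s = params.match if cls == "WC" else params.gu if cls == "GU" else params.mismatch
    return s * params.seed_scale if seed else s


def align_duplex(
    mir: MiRNA, window: str, params: ScoringParams | None = None
) -> DuplexAlignment:
    """Semi-global affine DP of the reversed miRNA against ``window``.

    The reversed miRNA (3'->5' left to right) aligns antiparallel to the
    window read 5'->3'.  Window overhangs on either side are free; every
    miRNA base is either apposed to a window base (scored, possibly as a
    mismatch) or gapped.
    """
    params = params or ScoringParams()
    w = normalize_rna(window)
    q = mir.sequence[::-1]
    m, n = len(q), len(w)
    if n == 0:
        raise ValueError("empty window")
    # q[i] corresponds to miRNA 1-based position m - i
    seed_row = [2 <= (m - i) <= 8 for i in range(m)]

    # dp[s][i][j]; backpointer bp[s][i][j] = (prev state, prev i, prev j)
    # or None for the virtual start (row 0, any j, score 0).
    dp = [[[NEG_INF] * (n + 1) for _ in range(m + 1)] for _ in range(3)]
    bp: list[list[list[tuple[int, int, int] | None]]] = [
        [[None] * (n + 1) for _ in range(m + 1)] for _ in range(3)
    ]
    for j in range(n + 1):
        dp[_M][0][j] = 0.0  # virtual start: leading window overhang is free

    go, ge = params.gap_open, params.gap_extend
    for i in range(1, m + 1):
        for j in range(n + 1):
            # X: miRNA base q[i-1] against a gap
            best, back = NEG_INF, None
            for s in (_M, _Y):
                v = dp[s][i - 1][j] + go + ge
                if v > best:
                    best, back = v, (s, i - 1, j)
            v = dp[_X][i - 1][j] + ge
            if v > best:
                best, back = v, (_X, i - 1, j)
            dp[_X][i][j], bp[_X][i][j] = best, back
            if j == 0:
                continue
            # M: q[i-1] apposed to w[j-1]
            sc = _pair_score(w[j - 1], q[i - 1], seed_row[i - 1], params)
            best, back = NEG_INF, None
            for s in (_M, _X, _Y):
                v = dp[s][i - 1][j - 1] + sc
                if v > best:
                    best, back = v, (s, i - 1, j - 1)
            dp[_M][i][j], bp[_M][i][j] = best, back
            # Y: window base w[j-1] against a gap in the miRNA (internal)
            best, back = NEG_INF, None
            for s in (_M, _X):
                v = dp[s][i][j - 1] + go + ge
                if v > best:
                    best, back = v, (s, i, j - 1)
            v = dp[_Y][i][j - 1] + ge
            if v > best:
                best, back = v, (_Y, i, j - 1)
            dp[_Y][i][j], bp[_Y][i][j] = best, back

    # trailing window overhang free: best over all j and states at i = m
    best, end = NEG_INF, (_M, m, n)
    for j in range(n + 1):
        for s in (_M, _X, _Y):
            if dp[s][m][j] > best:
                best, end = dp[s][m][j], (s, m, j)

    columns: list[tuple[int | None, int | None]] = []
    s, i, j = end
    while not (i == 0):
        prev = bp[s][i][j]
        if s == _M:
            if i == 0:
                break
            columns.append((m - i, j - 1))  # mir index from 5' end = m - i
        elif s == _X:
            columns.append((m - i, None))
        else:
            columns.append((None, j - 1))
        if prev is None:
            break
        s, i, j = prev
    columns.reverse()
    return DuplexAlignment(
        mirna=mir.name, mir_seq=mir.sequence, window=w, score=best, columns=columns
    )


def duplex_energy(
    alignment: DuplexAlignment, params: ScoringParams | None = None
) -> float:
    """Nearest-neighbor stack sum over the alignment's helices.

    Helices are maximal runs of consecutive alignment columns whose pair
    class is WC or GU; each adjacent pair of columns in a helix adds the
    stack keyed by its two target bases (5'->3') and the two apposed
    miRNA bases.  Every interruption between two helices adds one
    ``loop_penalty``; an alignment without paired positions has energy 0.
    """
    params = params or ScoringParams()
    table = load_stack_table()
    w, mseq = alignment.window, alignment.mir_seq
    dg, helices = 0.0, 0
    run: list[tuple[int, int]] = []

    def close() -> None:
        nonlocal dg, helices
        if run:
            helices += 1
            for (m1, j1), (m2, j2) in zip(run, run[1:]):
                key = (w[j1] + w[j2], mseq[m1] + mseq[m2])
                if key not in table:
                    raise KeyError(f"stack {key[0]}/{key[1]} absent from table")
                dg += table[key]
        run.clear()

    for mi, wj in alignment.columns:
        if mi is not None and wj is not None and pair_class(w[wj], mseq[mi]) in ("WC", "GU"):
            run.append((mi, wj))
        else:
            close()
    close()
    if helices > 1:
        dg += (helices - 1) * params.loop_penalty
    return dg


@dataclass(frozen=True)
class BindingHit:
    circ_id: str
    mirna: str
    start: int   # coordinate of the first paired target base (mod L on circles)
    end: int     # start + footprint length
    score: float
    energy: float
    passes: bool


def hit_passes(score: float, energy: float, params: ScoringParams | None = None) -> bool:
    params = params or ScoringParams()
    return score >= params.score_min and energy <= params.energy_max


def filter_hits(
    hits: Iterable[BindingHit], params: ScoringParams | None = None
) -> list[BindingHit]:
    """Keep hits with score >= score_min and energy <= energy_max (inclusive)."""
    params = params or ScoringParams()
    return [h for h in hits if hit_passes(h.score, h.energy, params)]


def scan_circrna(
    mir: MiRNA,
    circ: CircSequence,
    params: ScoringParams | None = None,
    circular: bool = True,
    exhaustive: bool = False,
) -> list[BindingHit]:
    """Scan a circRNA for miRNA binding windows.

    In circular mode the sequence is extended by its first ``window - 1``
    nucleotides so junction-spanning sites are evaluated, and hit
    coordinates are reported modulo the circle length.  By default only
    windows around an exact 6-nt seed match are aligned (a window with no
    WC seed pairing cannot reach the default score threshold; a rare
    wobble-paired seed could, so pass ``exhaustive=True`` to be complete);
    ``exhaustive=True`` aligns a window at every start.  Alignments of
    one locus from overlapping windows are deduplicated by footprint
    start; hits whose footprints overlap or whose starts are closer
    than ``min_hit_separation`` keep only the best-scoring
    representative.
    """
    params = params or ScoringParams()
    seq = circ.sequence
    L = len(seq)
    W = len(mir.sequence) + params.window_slack
    degenerate = L < len(mir.sequence)
    if circular:
        ext = seq + seq[: max(W - 1, 0)]
        all_starts: Sequence[int] = range(L) if not degenerate else range(1)
    else:
        ext = seq
        all_starts = range(max(1, L - W + 1))

    if exhaustive or degenerate:
        starts = list(all_starts)
    else:
        anchor = mir.seed_match()
        cand: set[int] = set()
        pos = ext.find(anchor)
        while pos != -1:
            # windows placed so the seed match sits near the window 3'
            # end, leaving room upstream for 3' pairing and bulge slack
            base = pos + 6 + 4 - W
            for shift in (-2, 0, 2):
                t = base + shift
                if circular:
                    cand.add(t % L)
                elif 0 <= t <= len(ext) - W:
                    cand.add(t)
            pos = ext.find(anchor, pos + 1)
        starts = sorted(cand)

    best_by_locus: dict[int, BindingHit] = {}
    for s in starts:
        window = ext[s : s + W]
        if not window:
            continue
        aln = align_duplex(mir, window, params)
        if not aln.pairs:
            continue
        span = aln.target_span
        footprint = span[1] - span[0]
        start = (s + span[0]) % L if circular else s + span[0]
        dg = duplex_energy(aln, params)
        hit = BindingHit(
            circ_id=circ.circ_id,
            mirna=mir.name,
            start=start,
            end=start + footprint,
            score=aln.score,
            energy=dg,
            passes=hit_passes(aln.score, dg, params),
        )
        prev = best_by_locus.get(start)
        if prev is None or (hit.score, -hit.energy) > (prev.score, -prev.energy):
            best_by_locus[start] = hit

    def same_locus(a: BindingHit, b: BindingHit) -> bool:
        return (_dist(a.start, b.start, L, circular) < params.min_hit_separation
                or _footprints_overlap(a, b, L, circular))

    hits = sorted(best_by_locus.values(), key=lambda h: (h.start, -h.score))
    merged: list[BindingHit] = []
    for hit in hits:
        if merged and same_locus(hit, merged[-1]):
            if (hit.score, -hit.energy) > (merged[-1].score, -merged[-1].energy):
                merged[-1] = hit
        else:
            merged.append(hit)
    if circular and len(merged) > 1:
        if same_locus(merged[0], merged[-1]):
            if (merged[-1].score, -merged[-1].energy) > (merged[0].score, -merged[0].energy):
                merged = merged[1:]
            else:
                merged = merged[:-1]
    return merged


def _dist(a: int, b: int, L: int, circular: bool) -> int:
    d = abs(a - b)
    return min(d, L - d) if circular else d


def _footprints_overlap(a: BindingHit, b: BindingHit, L: int, circular: bool) -> bool:
    """True when the [start, end) footprints intersect (modulo L on circles)."""
    if a.start < b.end and b.start < a.end:
        return True
    if circular:
        return any(a.start + off < b.end and b.start < a.end + off
                   for off in (L, -L))
    return False


def scan_all(
    mirnas: Sequence[MiRNA],
    circs: Sequence[CircSequence],
    params: ScoringParams | None = None,
    circular: bool = True,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Hit table over all miRNA x circRNA combinations, sorted
    deterministically by (mirna, circ, start)."""
    params = params or ScoringParams()
    rows = []
    for mir in mirnas:
        for circ in circs:
            for h in scan_circrna(mir, circ, params, circular=circular, exhaustive=exhaustive):
                rows.append(
                    {
                        "circ": h.circ_id,
                        "mirna": h.mirna,
                        "start": h.start,
                        "end": h.end,
                        "score": h.score,
                        "energy": h.energy,
                        "passes": h.passes,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["circ", "mirna", "start", "end", "score", "energy", "passes"]
    )
    return df.sort_values(["mirna", "circ", "start"], kind="mergesort").reset_index(
        drop=True
    )
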