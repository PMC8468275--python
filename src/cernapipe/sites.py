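"""Seed-match target site detection on 3'UTRs with conservation filtering.

Canonical site types follow the standard seed-match taxonomy.  Writing
the target 5'->3', a site is anchored at a 6-nt match to miRNA positions
2-7; the base 5' of the anchor may pair miRNA position 8 (the m8 pair)
and the base 3' of the anchor may be an A opposite miRNA position 1
(required to be an adenosine in the target regardless of the miRNA's
first base):

* 8mer      — m8 pair and the 1A        (footprint 8 nt)
* 7mer-m8   — m8 pair, no 1A            (footprint 7 nt)
* 7mer-1A   — 1A, no m8 pair            (footprint 7 nt)
* 6mer      — neither                   (footprint 6 nt)

Each seed-match locus receives exactly one type (strongest wins), so the
canonical classifier is a partition.

Non-canonical types (flag-gated, off in the conservative default mode):

* centered          — >= 11 contiguous Watson-Crick pairs to miRNA
                      positions 4-14 or 5-15.
* 3p-compensatory   — seed pairing with exactly one wobble/mismatch,
                      rescued by >= 4 contiguous WC pairs within miRNA
                      positions 13-17 located 0-8 nt 5' of the seed match.

Conservation: each site can carry a branch length (BL), aggregated from a
per-position track over the site footprint (mean by default); sites are
kept when BL >= the per-type threshold (defaults 8mer 0.6, 7mer-m8 1.8,
7mer-1A 2.5, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import MiRNA, UTRSequence, pair_class, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1A", "6mer", "centered", "3p-compensatory")
#: strongest-first ordering used for "best site" reporting
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

DEFAULT_BL_THRESHOLDS: dict[str, float] = {"8mer": 0.6, "7mer-m8": 1.8, "7mer-1A": 2.5}

# geometry of the 3p-compensatory search
_3P_MIN_CONTIG = 4
_3P_LOOP_MAX = 8


@dataclass(frozen=True)
class TargetSite:
    """One miRNA site on a UTR; [start, end) 0-based on the UTR."""

    gene_id: str
    mirna: str
    start: int
    end: int
    site_type: str
    branch_length: float | None = None


class ConservationTrack:
    """Per (gene, position) branch-length values."""

    def __init__(self, values: Mapping[str, Sequence[float]]):
        self._values = {g: np.asarray(v, dtype=float) for g, v in values.items()}
        for g, v in self._values.items():
            if (v < 0).any():
                raise ValueError(f"negative branch length for gene {g}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationTrack":
        """TSV with columns gene, position, branch_length."""
        df = pd.read_csv(path, sep="\t", comment="#")
        values: dict[str, np.ndarray] = {}
        for gene, grp in df.groupby("gene"):
            arr = np.zeros(int(grp["position"].max()) + 1)
            arr[grp["position"].to_numpy(dtype=int)] = grp["branch_length"].to_numpy()
            values[gene] = arr
        return cls(values)

    def site_bl(self, gene: str, start: int, end: int, aggregate: str = "mean") -> float:
        """Aggregate BL over a footprint; positions beyond the track count 0."""
        track = self._values.get(gene)
        if track is None:
            return 0.0
        window = np.zeros(end - start)
        hi = min(end, len(track))
        if hi > start:
            window[: hi - start] = track[start:hi]
        return float(window.max() if aggregate == "max" else window.mean())


def find_canonical_sites(mir: MiRNA, utr: UTRSequence) -> list[TargetSite]:
    """All canonical sites of ``mir`` on ``utr``, one type per seed locus."""
    seq = utr.sequence
    match6 = mir.seed_match()          # complements miRNA positions 2-7
    m8_target = revcomp(mir.sequence[7])  # base pairing miRNA position 8
    sites: list[TargetSite] = []
    pos = seq.find(match6)
    while pos != -1:
        has_m8 = pos > 0 and seq[pos - 1] == m8_target
        has_1a = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_1a:
            sites.append(TargetSite(utr.gene_id, mir.name, pos - 1, pos + 7, "8mer"))
        elif has_m8:
            sites.append(TargetSite(utr.gene_id, mir.name, pos - 1, pos + 6, "7mer-m8"))
        elif has_1a:
            sites.append(TargetSite(utr.gene_id, mir.name, pos, pos + 7, "7mer-1A"))
        else:
            sites.append(TargetSite(utr.gene_id, mir.name, pos, pos + 6, "6mer"))
        pos = seq.find(match6, pos + 1)
    return sites


def find_noncanonical_sites(
    mir: MiRNA, utr: UTRSequence, canonical: Iterable[TargetSite] | None = None
) -> list[TargetSite]:
    """Centered and 3'-compensatory sites, excluding canonical loci.

    ``canonical`` defaults to :func:`find_canonical_sites`; any
    non-canonical candidate whose footprint overlaps a canonical site of
    the same miRNA is dropped.
    """
    seq = utr.sequence
    if canonical is None:
        canonical = find_canonical_sites(mir, utr)
    occupied = [(s.start, s.end) for s in canonical]

    def overlaps(start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied)

    sites: list[TargetSite] = []

    # centered: 11 contiguous WC pairs to positions 4-14 or 5-15
    seen_centered: set[int] = set()
    for offset in (3, 4):  # 0-based starts of positions 4 and 5
        segment = mir.sequence[offset : offset + 11]
        pattern = revcomp(segment)
        pos = seq.find(pattern)
        while pos != -1:
            if pos not in seen_centered and not overlaps(pos, pos + 11):
                sites.append(
                    TargetSite(utr.gene_id, mir.name, pos, pos + 11, "centered")
                )
                seen_centered.add(pos)
            pos = seq.find(pattern, pos + 1)

    # 3p-compensatory: imperfect seed (exactly one wobble or mismatch)
    # plus >=4 contiguous WC pairs within miRNA positions 13-17,
    # 0-8 nt 5' of the seed match on the target.
    seed_rc = mir.seed_match()  # perfect 6-nt seed match
    three_p_patterns = [
        revcomp(mir.sequence[start : start + _3P_MIN_CONTIG])
        for start in (12, 13)  # positions 13-16 and 14-17
    ]
    for pos in range(len(seq) - 5):
        window = seq[pos : pos + 6]
        mismatches = sum(a != b for a, b in zip(window, seed_rc))
        if mismatches != 1:
            continue
        # the deviation must still leave 5 WC pairs; the deviant
        # apposition may be a wobble or a mismatch (both allowed)
        found = None
        for pat in three_p_patterns:
            lo = max(0, pos - _3P_LOOP_MAX - _3P_MIN_CONTIG)
            hi = pos - _3P_MIN_CONTIG
            for start3 in range(lo, hi + 1):
                if start3 < 0:
                    continue
                if seq[start3 : start3 + _3P_MIN_CONTIG] == pat:
                    found = start3
                    break
            if found is not None:
                break
        if found is None:
            continue
        start, end = found, pos + 6
        if not overlaps(start, end):
            sites.append(
                TargetSite(utr.gene_id, mir.name, start, end, "3p-compensatory")
            )
    return sites


def filter_conserved(
    sites: Iterable[TargetSite],
    track: ConservationTrack | None,
    thresholds: Mapping[str, float] | None = None,
    require_conserved_all: bool = False,
    aggregate: str = "mean",
) -> list[TargetSite]:
    """Keep sites whose branch length meets the per-type threshold.

    Site types without a threshold (6mer, non-canonical) pass untouched
    unless ``require_conserved_all`` is set, in which case they are
    dropped.  Thresholds are inclusive (BL >= cutoff keeps the site).
    """
    thresholds = DEFAULT_BL_THRESHOLDS if thresholds is None else dict(thresholds)
    sites = list(sites)
    if track is None:
        if sites:
            raise ValueError("conservation filtering requested without a track")
        return []
    kept = []
    for site in sites:
        bl = track.site_bl(site.gene_id, site.start, site.end, aggregate=aggregate)
        site = replace(site, branch_length=bl)
        cutoff = thresholds.get(site.site_type)
        if cutoff is None:
            if not require_conserved_all:
                kept.append(site)
        elif bl >= cutoff:
            kept.append(site)
    return kept


def find_sites(
    mir: MiRNA, utr: UTRSequence, include_noncanonical: bool = False
) -> list[TargetSite]:
    sites = find_canonical_sites(mir, utr)
    if include_noncanonical:
        sites = sites + find_noncanonical_sites(mir, utr, canonical=sites)
    return sites


def predict_targets(
    mirnas: Sequence[MiRNA],
    utrs: Sequence[UTRSequence],
    include_noncanonical: bool = False,
    conservation: ConservationTrack | None = None,
    bl_thresholds: Mapping[str, float] | None = None,
    require_conserved_all: bool = False,
) -> pd.DataFrame:
    """Gene-level target table: one row per (miRNA, gene) with >= 1
    surviving site; columns mirna, gene, n_sites, best_site_type.
    Sorted by (mirna, gene) for determinism."""
    rows = []
    for mir in mirnas:
        for utr in utrs:
            sites = find_sites(mir, utr, include_noncanonical=include_noncanonical)
            if conservation is not None:
                sites = filter_conserved(
                    sites,
                    conservation,
                    thresholds=bl_thresholds,
                    require_conserved_all=require_conserved_all,
                )
            if sites:
                best = min(sites, key=lambda s: SITE_RANK[s.site_type])
                rows.append(
                    {
                        "mirna": mir.name,
                        "gene": utr.gene_id,
                        "n_sites": len(sites),
                        "best_site_type": best.site_type,
                    }
                )
    df = pd.DataFrame(rows, columns=["mirna", "gene", "n_sites", "best_site_type"])
    return df.sort_values(["mirna", "gene"], kind="mergesort").reset_index(drop=True)


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene_id,
            "mirna": s.mirna,
            "start": s.start,
            "end": s.end,
            "site_type": s.site_type,
            "branch_length": s.branch_length,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["gene", "mirna", "start", "end", "site_type", "branch_length"]
    )
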