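"""Directional ceRNA triad integration, set statistics, network export.

A ceRNA triad couples one miRNA, one mRNA (gene level) and one circRNA
through shared miRNA response elements.  Two direction classes are
admitted, reflecting miRNA repression plus the observed co-regulation of
host mRNAs and circRNAs:

* class A: up-miRNA, down-mRNA, down-circRNA
* class B: down-miRNA, up-mRNA, up-circRNA

A triad requires at least one surviving target site on the mRNA and one
passing binding hit on the circRNA for the *same* miRNA.  Genes whose
transcripts appear in both the up and the down set are ambiguous and
excluded (reported, not silently dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_DIRECTIONS = {
    "A": {"mirna": "up", "mrna": "down", "circ": "down"},
    "B": {"mirna": "down", "mrna": "up", "circ": "up"},
}


@dataclass
class DESets:
    """Up/down feature-id sets per analyte, from DE calls."""

    mirna_up: set[str] = field(default_factory=set)
    mirna_down: set[str] = field(default_factory=set)
    mrna_up: set[str] = field(default_factory=set)
    mrna_down: set[str] = field(default_factory=set)
    circ_up: set[str] = field(default_factory=set)
    circ_down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("mirna", "mrna", "circ"):
            both = getattr(self, f"{name}_up") & getattr(self, f"{name}_down")
            if both:
                raise ValueError(f"{name} features in both directions: {sorted(both)}")

    @classmethod
    def from_calls(
        cls,
        mirna: pd.DataFrame | None = None,
        mrna: pd.DataFrame | None = None,
        circ: pd.DataFrame | None = None,
    ) -> "DESets":
        """Build from DE tables (columns ``feature`` and ``call``).

        mRNA features may be transcripts named ``gene|transcript``; they
        collapse to the gene, and genes with transcripts called in both
        directions are excluded as ambiguous (logged).
        """
        out = {}
        for name, table in (("mirna", mirna), ("circ", circ)):
            up, down = set(), set()
            if table is not None:
                up = set(table.loc[table["call"] == "up", "feature"])
                down = set(table.loc[table["call"] == "down", "feature"])
            out[f"{name}_up"], out[f"{name}_down"] = up, down
        up, down = set(), set()
        if mrna is not None:
            genes = mrna["feature"].astype(str).str.partition("|")[0]
            up = set(genes[mrna["call"] == "up"])
            down = set(genes[mrna["call"] == "down"])
            ambiguous = up & down
            if ambiguous:
                logger.info(
                    "excluding %d genes with transcripts in both directions: %s",
                    len(ambiguous), ", ".join(sorted(ambiguous)),
                )
            up -= ambiguous
            down -= ambiguous
        out["mrna_up"], out["mrna_down"] = up, down
        return cls(**out)

    def direction(self, analyte: str, feature: str) -> str:
        if feature in getattr(self, f"{analyte}_up"):
            return "up"
        if feature in getattr(self, f"{analyte}_down"):
            return "down"
        return "none"


@dataclass(frozen=True)
class CeRNATriad:
    mirna: str
    gene: str
    circ: str
    direction_class: str  # 'A' or 'B'


def select_directional_pairs(
    targets: pd.DataFrame,
    hits: pd.DataFrame,
    de: DESets,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Split interaction tables by direction class.

    ``targets`` needs columns (mirna, gene); ``hits`` needs (mirna,
    circ) and, when present, only rows with ``passes`` true are used.
    Features without a DE call are treated as no-call and discarded.
    Returns {class: (mir->mRNA pairs, mir->circ pairs)}.
    """
    if "passes" in hits.columns:
        # astype(bool) keeps this a boolean mask even for empty tables,
        # where the column dtype degrades to object
        hits = hits[hits["passes"].astype(bool)]
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for cls, want in CLASS_DIRECTIONS.items():
        t = targets[
            targets["mirna"].map(lambda m: de.direction("mirna", m) == want["mirna"])
            & targets["gene"].map(lambda g: de.direction("mrna", g) == want["mrna"])
        ]
        h = hits[
            hits["mirna"].map(lambda m: de.direction("mirna", m) == want["mirna"])
            & hits["circ"].map(lambda c: de.direction("circ", c) == want["circ"])
        ]
        out[cls] = (t.reset_index(drop=True), h.reset_index(drop=True))
    return out


def build_triads(
    pairs: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]]
) -> list[CeRNATriad]:
    """One triad per (miRNA, gene, circ) with both pair types in one class,
    sorted by (class, mirna, gene, circ)."""
    triads: list[CeRNATriad] = []
    for cls in sorted(pairs):
        t, h = pairs[cls]
        mrna_pairs = set(zip(t["mirna"], t["gene"]))
        circ_pairs = set(zip(h["mirna"], h["circ"]))
        by_mir: dict[str, set[str]] = {}
        for m, c in circ_pairs:
            by_mir.setdefault(m, set()).add(c)
        for m, g in sorted(mrna_pairs):
            for c in sorted(by_mir.get(m, ())):
                triads.append(CeRNATriad(m, g, c, cls))
    triads.sort(key=lambda x: (x.direction_class, x.mirna, x.gene, x.circ))
    return triads


def triads_to_frame(triads: Iterable[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"class": t.direction_class, "mirna": t.mirna, "gene": t.gene, "circ": t.circ}
            for t in triads
        ],
        columns=["class", "mirna", "gene", "circ"],
    )


def host_concordance(
    de: DESets, circ_to_gene: Mapping[str, str]
) -> dict[str, float | None]:
    """Fraction of DE circRNAs whose host mRNA moved the same way.

    Returns {'down': fraction or None, 'up': fraction or None}; a
    direction with zero DE circRNAs is undefined (None), not 0.
    """
    out: dict[str, float | None] = {}
    for d, circ_set in (("down", de.circ_down), ("up", de.circ_up)):
        known = [c for c in circ_set if c in circ_to_gene]
        missing = circ_set - set(known)
        if missing:
            logger.warning("%d circRNAs missing from the host map", len(missing))
        if not known:
            out[d] = None
            continue
        conc = sum(1 for c in known if de.direction("mrna", circ_to_gene[c]) == d)
        out[d] = conc / len(known)
    return out


@dataclass
class ListComparison:
    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: list[str]
    case_insensitive: bool = True

    @property
    def n_common(self) -> int:
        return len(self.intersection)


def compare_gene_lists(
    list_a: Sequence[str],
    list_b: Sequence[str],
    name_a: str = "A",
    name_b: str = "B",
    dedupe: bool = False,
) -> ListComparison:
    """Compare two gene-symbol lists.

    Sizes count entries as given (duplicates included) unless ``dedupe``;
    the intersection is computed on unique case-folded symbols and the
    members are reported in the capitalization of ``list_a``.
    """
    a = [x.strip() for x in list_a if x.strip()]
    b = [x.strip() for x in list_b if x.strip()]
    fold_b = {x.casefold() for x in b}
    seen: set[str] = set()
    common: list[str] = []
    for x in a:
        key = x.casefold()
        if key in fold_b and key not in seen:
            seen.add(key)
            common.append(x)
    size_a = len(set(x.casefold() for x in a)) if dedupe else len(a)
    size_b = len(set(x.casefold() for x in b)) if dedupe else len(b)
    return ListComparison(name_a, name_b, size_a, size_b, sorted(common, key=str.casefold))


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# -------------------------------------------------------------------- network


def build_network(
    triads: Sequence[CeRNATriad],
    mean_levels: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Typed ceRNA graph: miR->mRNA 'targets', miR->circ 'binds' and an
    mRNA<->circ 'competes' edge for each pair sharing >= 1 triad.
    ``mean_levels`` annotates nodes with their mean KO-group level."""
    g = nx.Graph()
    mean_levels = mean_levels or {}

    def add_node(name: str, kind: str) -> None:
        if not g.has_node(name):
            attrs = {"type": kind}
            if name in mean_levels:
                attrs["mean_KO"] = float(mean_levels[name])
            g.add_node(name, **attrs)

    for t in sorted(triads, key=lambda x: (x.direction_class, x.mirna, x.gene, x.circ)):
        add_node(t.mirna, "miRNA")
        add_node(t.gene, "mRNA")
        add_node(t.circ, "circRNA")
        g.add_edge(t.mirna, t.gene, relation="targets", direction_class=t.direction_class)
        g.add_edge(t.mirna, t.circ, relation="binds", direction_class=t.direction_class)
        g.add_edge(t.gene, t.circ, relation="competes", direction_class=t.direction_class)
    return g


def export_network(
    triads: Sequence[CeRNATriad],
    fmt: str,
    path: str | Path,
    mean_levels: Mapping[str, float] | None = None,
) -> None:
    """Write the triad network as 'sif', 'graphml' or 'tsv'.

    Output is byte-identical across runs for identical input: edges are
    emitted in sorted order and no timestamps are written.
    """
    g = build_network(triads, mean_levels)
    path = Path(path)
    if fmt == "sif":
        lines = sorted(
            f"{u}\t{d['relation']}\t{v}" for u, v, d in g.edges(data=True)
        )
        path.write_text("".join(line + "\n" for line in lines))
    elif fmt == "graphml":
        # rebuild with sorted nodes/edges so element order is canonical
        h = nx.Graph()
        for n in sorted(g.nodes):
            h.add_node(n, **g.nodes[n])
        for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
            h.add_edge(u, v, **g.edges[u, v])
        nx.write_graphml(h, path)
    elif fmt == "tsv":
        rows = sorted(
            (u, d["relation"], v, d["direction_class"])
            for u, v, d in g.edges(data=True)
        )
        pd.DataFrame(rows, columns=["source", "relation", "target", "direction_class"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Parse a SIF file back into a (source, relation, target) edge set."""
    edges = set()
    for line in Path(path).read_text().splitlines():
        if line.strip():
            src, rel, tgt = line.split("\t")
            edges.add((src, rel, tgt))
    return edges
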