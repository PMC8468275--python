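"""Synthetic two-group study generator with planted ceRNA structure.

The generator emulates the data types of a KO-vs-WT design with three
samples per genotype: log-normal array intensities with
Present/Marginal/Absent detection calls for mRNAs and circRNAs, and
negative-binomial sequencing counts for miRNAs.  Sequences are i.i.d.
background with configurable GC content into which miRNA response
elements are planted verbatim at recorded coordinates: an 8mer seed
site (by default) on the target gene's 3'UTR, and a full-length
complement on the partner circRNA so that the duplex-scoring route also
fires.  Planted miRNA seeds are screened out of all other sequences by
point mutation, so on a noise-free fixture the planted triads are the
*only* recoverable triads (truth for precision/recall = 1 checks).

Directional structure follows the two ceRNA direction classes:
class A = up-miRNA / down-mRNA / down-circRNA,
class B = down-miRNA / up-mRNA / up-circRNA.
Host-gene concordance (a down-circRNA whose host mRNA is also down, and
likewise for up) is plantable at configurable rates for the
concordance statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import MiRNA, UTRSequence, CircSequence, revcomp, write_fasta
from .diffexpr import ExpressionMatrix

DirectionClass = Literal["A", "B"]

_BASES = np.array(list("ACGU"))


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_mirnas: int = 8
    n_genes: int = 20
    n_circ: int = 12
    utr_len: int = 300
    circ_len: int = 150
    mirna_len: int = 22
    samples_per_group: int = 3
    #: (miRNA index, gene index, circ index, direction class 'A'|'B')
    planted_triads: list[tuple[int, int, int, str]] = field(default_factory=list)
    fc_mrna: float = 2.0
    fc_mirna: float = 3.0
    fc_circ: float = 2.0
    intensity_sigma: float = 0.25   # log2-scale s.d. of array noise
    nb_dispersion: float = 0.1
    libsize_mean: float = 1e6
    gc: float = 0.5
    site_type: Literal["8mer", "7mer-m8", "7mer-1A"] = "8mer"
    noise_free: bool = False
    # host-gene concordance planting (outside triads)
    n_extra_circ_de: int = 0        # per direction
    concordance_down: float = 0.6
    concordance_up: float = 0.7
    # detection-call model: background is log2-normal; Present above the
    # present_q quantile, Marginal in the band down to marginal_q
    bg_log2_mean: float = 4.0
    bg_log2_sd: float = 1.0
    present_q: float = 0.95
    marginal_q: float = 0.80
    fraction_undetected: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_circ", "utr_len", "circ_len",
                     "mirna_len", "samples_per_group"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("fc_mrna", "fc_mirna", "fc_circ"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not 0 < self.gc < 1:
            raise ConfigError("gc must lie in (0, 1)")
        if self.utr_len < 8:
            raise ConfigError("utr_len too short to host a planted site")
        if self.circ_len < self.mirna_len:
            raise ConfigError("circ_len too short to host a planted MRE")
        for mi, gi, ci, cls in self.planted_triads:
            if not (0 <= mi < self.n_mirnas and 0 <= gi < self.n_genes
                    and 0 <= ci < self.n_circ):
                raise ConfigError(f"triad index out of range: {(mi, gi, ci)}")
            if cls not in ("A", "B"):
                raise ConfigError(f"unknown direction class {cls!r}")


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating a fixture."""

    mirna_direction: dict[str, str]      # name -> up/down/none
    mrna_direction: dict[str, str]
    circ_direction: dict[str, str]
    mre_utr: list[tuple[str, str, int, int, str]]   # (mirna, gene, start, end, type)
    mre_circ: list[tuple[str, str, int, int]]       # (mirna, circ, start, end)
    triads: list[tuple[str, str, str, str]]         # (mirna, gene, circ, class)
    circ_to_gene: dict[str, str]


@dataclass
class SimOutput:
    mirnas: list[MiRNA]
    utrs: list[UTRSequence]
    circs: list[CircSequence]
    circ_to_gene: dict[str, str]
    truth: PlantedTruth
    mrna: ExpressionMatrix | None = None
    circ: ExpressionMatrix | None = None
    mirna_counts: ExpressionMatrix | None = None


# ------------------------------------------------------------------ sequences


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _site_string(mir: MiRNA, site_type: str) -> str:
    if site_type == "8mer":
        return mir.seed_match(extended=True) + "A"
    if site_type == "7mer-m8":
        # must not be followed by A; the screen leaves the next base as-is,
        # so append a non-A to pin the type
        return mir.seed_match(extended=True) + "C"
    if site_type == "7mer-1A":
        # seed match + A, preceded by a base failing the m8 pair
        m8 = revcomp(mir.sequence[7])
        bad = "A" if m8 != "A" else "C"
        return bad + mir.seed_match() + "A"
    raise ConfigError(f"unsupported planted site type: {site_type}")


def _plant(
    seq: str, inserts: list[str], rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Overwrite ``seq`` with insert strings at non-overlapping positions."""
    taken: list[tuple[int, int]] = []
    out = list(seq)
    for s in inserts:
        for _ in range(1000):
            start = int(rng.integers(0, len(seq) - len(s) + 1))
            end = start + len(s)
            if all(end <= a or start >= b for a, b in taken):
                break
        else:
            raise ConfigError("sequence too short to host all planted sites")
        out[start:end] = s
        taken.append((start, end))
    return "".join(out), taken


def _screen(
    seq: str,
    anchors: Sequence[str],
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> str:
    """Mutate stray anchor occurrences away.

    An occurrence fully inside a protected (planted) interval is a real
    MRE and stays; any other occurrence is mutated at one of its bases
    that lies outside every protected interval.
    """
    out = list(seq)

    def covered(idx: int) -> bool:
        return any(p0 <= idx < p1 for p0, p1 in protected)

    for _ in range(10_000):
        s = "".join(out)
        stray = None
        for a in anchors:
            pos = s.find(a)
            while pos != -1:
                span = (pos, pos + len(a))
                inside = any(span[0] >= p0 and span[1] <= p1 for p0, p1 in protected)
                if not inside:
                    stray = span
                    break
                pos = s.find(a, pos + 1)
            if stray:
                break
        if stray is None:
            return s
        free = [i for i in range(stray[0], stray[1]) if not covered(i)]
        if not free:  # fully covered by two adjoining planted sites: give up
            raise ConfigError("planted sites collide with a stray seed match")
        mid = free[len(free) // 2]
        choices = [b for b in "ACGU" if b != out[mid]]
        out[mid] = choices[int(rng.integers(0, 3))]
    raise ConfigError("could not screen planted seeds out of background")


def generate_sequences(config: SimConfig) -> SimOutput:
    """Draw miRNAs, UTRs and circRNAs with planted MREs and known truth."""
    rng = np.random.default_rng(config.seed)

    # miRNAs: 5' U (the usual bias), distinct seeds
    mirnas: list[MiRNA] = []
    seeds: set[str] = set()
    while len(mirnas) < config.n_mirnas:
        seq = "U" + _random_seq(rng, config.mirna_len - 1, config.gc)
        mir = MiRNA(f"miR-{len(mirnas)}", seq)
        if mir.seed in seeds:
            continue
        seeds.add(mir.seed)
        mirnas.append(mir)
    anchors = [m.seed_match() for m in mirnas]

    gene_ids = [f"gene{g}" for g in range(config.n_genes)]
    circ_ids = [f"circ{c}" for c in range(config.n_circ)]

    # circ -> host gene map; triad circs map to the triad's gene
    circ_to_gene = {circ_ids[c]: gene_ids[c % config.n_genes]
                    for c in range(config.n_circ)}
    for mi, gi, ci, _ in config.planted_triads:
        circ_to_gene[circ_ids[ci]] = gene_ids[gi]

    # planted inserts per sequence
    utr_inserts: dict[int, list[tuple[str, str]]] = {}   # gene idx -> (mir, site)
    circ_inserts: dict[int, list[tuple[str, str]]] = {}
    for mi, gi, ci, _ in config.planted_triads:
        mir = mirnas[mi]
        utr_inserts.setdefault(gi, []).append((mir.name, _site_string(mir, config.site_type)))
        circ_inserts.setdefault(ci, []).append((mir.name, revcomp(mir.sequence)))

    mre_utr: list[tuple[str, str, int, int, str]] = []
    utrs: list[UTRSequence] = []
    for g, gid in enumerate(gene_ids):
        seq = _random_seq(rng, config.utr_len, config.gc)
        protected: list[tuple[int, int]] = []
        if g in utr_inserts:
            seq, spans = _plant(seq, [s for _, s in utr_inserts[g]], rng)
            for (mname, sstr), (a, b) in zip(utr_inserts[g], spans):
                mre_utr.append((mname, gid, a, b, config.site_type))
            protected = spans
        seq = _screen(seq, anchors, protected, rng)
        utrs.append(UTRSequence(gid, seq))

    mre_circ: list[tuple[str, str, int, int]] = []
    circs: list[CircSequence] = []
    for c, cid in enumerate(circ_ids):
        seq = _random_seq(rng, config.circ_len, config.gc)
        protected = []
        if c in circ_inserts:
            seq, spans = _plant(seq, [s for _, s in circ_inserts[c]], rng)
            for (mname, _), (a, b) in zip(circ_inserts[c], spans):
                mre_circ.append((mname, cid, a, b))
            protected = spans
        # screening must also respect the circular junction: screen the
        # doubled sequence's junction region by checking the wrap
        seq = _screen(seq, anchors, protected, rng)
        seq = _screen_junction(seq, anchors, protected, rng)
        circs.append(CircSequence(cid, circ_to_gene[cid], seq))

    truth = _assign_directions(config, mirnas, gene_ids, circ_ids, circ_to_gene, rng)
    truth.mre_utr = mre_utr
    truth.mre_circ = mre_circ
    return SimOutput(mirnas, utrs, circs, circ_to_gene, truth)


def _screen_junction(
    seq: str,
    anchors: Sequence[str],
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> str:
    """Remove anchor occurrences spanning the backsplice junction."""
    k = max(len(a) for a in anchors)
    out = list(seq)
    L = len(out)

    def covered(idx: int) -> bool:
        return any(p0 <= idx < p1 for p0, p1 in protected)

    for _ in range(1000):
        wrap = "".join(out[-(k - 1):]) + "".join(out[: k - 1])
        stray = None
        for a in anchors:
            pos = wrap.find(a)
            if pos != -1:
                stray = (pos, len(a))
                break
        if stray is None:
            return "".join(out)
        pos, alen = stray
        circle_idx = [(L - (k - 1) + pos + off) % L for off in range(alen)]
        free = [i for i in circle_idx if not covered(i)]
        if not free:
            raise ConfigError("planted sites collide at the backsplice junction")
        mid = free[len(free) // 2]
        choices = [b for b in "ACGU" if b != out[mid]]
        out[mid] = choices[int(rng.integers(0, 3))]
    raise ConfigError("could not screen the backsplice junction")


def _assign_directions(
    config: SimConfig,
    mirnas: list[MiRNA],
    gene_ids: list[str],
    circ_ids: list[str],
    circ_to_gene: dict[str, str],
    rng: np.random.Generator,
) -> PlantedTruth:
    mdir = {m.name: "none" for m in mirnas}
    gdir = {g: "none" for g in gene_ids}
    cdir = {c: "none" for c in circ_ids}
    triads = []
    for mi, gi, ci, cls in config.planted_triads:
        m, g, c = mirnas[mi].name, gene_ids[gi], circ_ids[ci]
        want = ("up", "down", "down") if cls == "A" else ("down", "up", "up")
        for store, key, d in ((mdir, m, want[0]), (gdir, g, want[1]), (cdir, c, want[2])):
            if store[key] not in ("none", d):
                raise ConfigError(f"conflicting planted directions for {key}")
            store[key] = d
        triads.append((m, g, c, cls))

    # extra DE circRNAs with plantable host concordance
    free_circs = [c for c in circ_ids if cdir[c] == "none"
                  and gdir[circ_to_gene[c]] == "none"]
    # avoid two circs sharing one host among the extras
    seen_hosts: set[str] = set()
    free_circs = [c for c in free_circs
                  if not (circ_to_gene[c] in seen_hosts or seen_hosts.add(circ_to_gene[c]))]
    need = 2 * config.n_extra_circ_de
    if len(free_circs) < need:
        raise ConfigError("not enough spare circRNAs for concordance planting")
    picks = list(rng.permutation(free_circs))[:need] if need else []
    for k, c in enumerate(picks):
        d = "down" if k < config.n_extra_circ_de else "up"
        p = config.concordance_down if d == "down" else config.concordance_up
        cdir[c] = d
        if rng.random() < p:
            gdir[circ_to_gene[c]] = d
    return PlantedTruth(mdir, gdir, cdir, [], [], triads, dict(circ_to_gene))


# ----------------------------------------------------------------- expression


def _sample_names(n: int) -> list[str]:
    return [f"WT_{i+1}" for i in range(n)] + [f"KO_{i+1}" for i in range(n)]


def _groups(n: int) -> pd.Series:
    names = _sample_names(n)
    return pd.Series(["WT"] * n + ["KO"] * n, index=names)


def _intensity_matrix(
    features: list[str],
    direction: dict[str, str],
    fc: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    n = config.samples_per_group
    base = rng.uniform(6.0, 12.0, size=len(features))
    # keep DE features away from the extreme ranks: a fold change planted
    # at the global min/max rank cannot survive rank-based (quantile)
    # normalization, so both base and base+shift must stay inside the
    # background intensity range
    s = abs(np.log2(fc))
    de_idx = [i for i, f in enumerate(features) if direction[f] != "none"]
    if de_idx and 6.0 + s < 12.0 - s:
        base[de_idx] = rng.uniform(6.0 + s, 12.0 - s, size=len(de_idx))
    if config.fraction_undetected > 0:
        nulls = [i for i, f in enumerate(features) if direction[f] == "none"]
        k = int(round(config.fraction_undetected * len(features)))
        low = rng.permutation(nulls)[:k]
        base[low] = rng.uniform(2.0, 3.2, size=len(low))
    shift = np.array([
        {"up": np.log2(fc), "down": -np.log2(fc), "none": 0.0}[direction[f]]
        for f in features
    ])
    mu = np.column_stack([np.tile(base, (n, 1)).T,
                          np.tile(base + shift, (n, 1)).T])
    sigma = 0.0 if config.noise_free else config.intensity_sigma
    noise = rng.normal(0.0, 1.0, size=mu.shape) * sigma
    log2_vals = mu + noise
    values = pd.DataFrame(2.0 ** log2_vals, index=features, columns=_sample_names(n))
    present_cut = config.bg_log2_mean + sps.norm.ppf(config.present_q) * config.bg_log2_sd
    marginal_cut = config.bg_log2_mean + sps.norm.ppf(config.marginal_q) * config.bg_log2_sd
    flags = pd.DataFrame(
        np.where(log2_vals > present_cut, "P",
                 np.where(log2_vals > marginal_cut, "M", "A")),
        index=features, columns=values.columns,
    )
    return ExpressionMatrix(values, _groups(n), platform="intensity", flags=flags)


def _count_matrix(
    mirnas: list[str],
    direction: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    n = config.samples_per_group
    # DE miRNAs at modest abundance, null miRNAs dominating the library,
    # so compositional (CPM) distortion of the planted fold change is small
    w = np.array([
        2.0 ** rng.uniform(3, 7) if direction[m] != "none" else 2.0 ** rng.uniform(7, 12)
        for m in mirnas
    ])
    fc = np.array([
        {"up": config.fc_mirna, "down": 1.0 / config.fc_mirna, "none": 1.0}[direction[m]]
        for m in mirnas
    ])
    scale = config.libsize_mean / w.sum()
    mean_wt = w * scale
    mean_ko = w * fc * scale
    means = np.column_stack([np.tile(mean_wt, (n, 1)).T, np.tile(mean_ko, (n, 1)).T])
    if config.noise_free:
        counts = np.round(means)
    else:
        lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                        scale=means * config.nb_dispersion)
        counts = rng.poisson(lam).astype(float)
    values = pd.DataFrame(counts, index=mirnas, columns=_sample_names(n))
    return ExpressionMatrix(values, _groups(n), platform="counts")


def generate_expression(config: SimConfig, out: SimOutput) -> SimOutput:
    """Attach mRNA/circRNA intensity matrices and miRNA counts to ``out``.

    Uses an RNG stream derived from the config seed but distinct from
    the sequence stream, so sequence and expression draws do not
    interact."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    t = out.truth
    out.mrna = _intensity_matrix([u.gene_id for u in out.utrs],
                                 t.mrna_direction, config.fc_mrna, config, rng)
    out.circ = _intensity_matrix([c.circ_id for c in out.circs],
                                 t.circ_direction, config.fc_circ, config, rng)
    out.mirna_counts = _count_matrix([m.name for m in out.mirnas],
                                     t.mirna_direction, config, rng)
    return out


def simulate(config: SimConfig) -> SimOutput:
    """Sequences + expression in one call."""
    return generate_expression(config, generate_sequences(config))


def intensity_replicates(
    n_features: int,
    fc: float,
    direction: str = "up",
    config: SimConfig | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replicate array features with one planted direction.

    A calibration utility: ``n_features`` independent intensity features
    all carrying the same planted fold change (``direction='none'``
    plants the null, FC = 1), under the noise model of ``config``.
    """
    if direction not in ("up", "down", "none"):
        raise ConfigError(f"unknown direction {direction!r}")
    config = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    features = [f"f{i}" for i in range(n_features)]
    return _intensity_matrix(features, {f: direction for f in features}, fc, config, rng)


# -------------------------------------------------------------------- fixture


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(out: SimOutput, dir_path: str | Path, overwrite: bool = False) -> pd.DataFrame:
    """Write FASTA sequence sets, TSV matrices and truth tables plus a
    checksum manifest.  Refuses a non-empty directory unless
    ``overwrite`` is set.  Returns the manifest."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    if any(d.iterdir()) and not overwrite:
        raise FileExistsError(f"{d} is not empty (pass overwrite=True)")

    write_fasta([(m.name, m.sequence) for m in out.mirnas], d / "mirnas.fasta")
    write_fasta([(u.gene_id, u.sequence) for u in out.utrs], d / "utrs.fasta")
    write_fasta([(c.circ_id, c.sequence) for c in out.circs], d / "circs.fasta")
    pd.DataFrame(
        sorted(out.circ_to_gene.items()), columns=["circ", "gene"]
    ).to_csv(d / "circ_to_gene.tsv", sep="\t", index=False)

    matrices = [("mrna", out.mrna), ("circ", out.circ), ("mirna", out.mirna_counts)]
    for name, mat in matrices:
        if mat is None:
            continue
        mat.to_tsv(d / f"{name}_matrix.tsv")
        if mat.flags is not None:
            mat.flags.rename_axis("feature").to_csv(d / f"{name}_flags.tsv", sep="\t")

    t = out.truth
    for name, dd in (("mirna", t.mirna_direction), ("mrna", t.mrna_direction),
                     ("circ", t.circ_direction)):
        pd.DataFrame(sorted(dd.items()), columns=["feature", "direction"]).to_csv(
            d / f"truth_{name}_direction.tsv", sep="\t", index=False)
    pd.DataFrame(t.mre_utr, columns=["mirna", "gene", "start", "end", "site_type"]).to_csv(
        d / "truth_mre_utr.tsv", sep="\t", index=False)
    pd.DataFrame(t.mre_circ, columns=["mirna", "circ", "start", "end"]).to_csv(
        d / "truth_mre_circ.tsv", sep="\t", index=False)
    pd.DataFrame(t.triads, columns=["mirna", "gene", "circ", "class"]).to_csv(
        d / "truth_triads.tsv", sep="\t", index=False)

    files = sorted(p for p in d.iterdir() if p.name != "manifest.tsv")
    manifest = pd.DataFrame(
        [(p.name, _sha256(p)) for p in files], columns=["file", "sha256"]
    )
    manifest.to_csv(d / "manifest.tsv", sep="\t", index=False)
    return manifest
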