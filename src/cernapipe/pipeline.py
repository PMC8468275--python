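"""End-to-end orchestration: simulate/load -> DE -> targets -> bind -> network.

A run is driven by a :class:`PipelineConfig` (YAML on disk), executes the
stages in order, writes every intermediate as TSV under the output
directory, and returns a :class:`RunReport` of per-stage counts.  All
randomness flows from the single config seed, so a fixed config yields
byte-identical artifacts; stage timings go to ``run.log`` only, which is
excluded from determinism comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    DEFAULT_THRESHOLDS,
    DEThresholds,
    ExpressionMatrix,
    run_de,
    write_de_table,
)
from .duplex import ScoringParams, scan_all
from .network import (
    DESets,
    build_triads,
    export_network,
    host_concordance,
    select_directional_pairs,
    triads_to_frame,
)
from .records import read_circs, read_mirnas, read_utrs
from .simulate import SimConfig, simulate, write_fixture
from .sites import ConservationTrack, predict_targets

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; completed intermediates are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "cerna_run"
    seed: int = 0
    # either simulate...
    simulate: SimConfig | None = None
    # ...or load user inputs
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    circ_fasta: str | None = None
    circ_map: str | None = None
    mrna_matrix: str | None = None
    mrna_flags: str | None = None
    circ_matrix: str | None = None
    circ_flags: str | None = None
    mirna_counts: str | None = None
    # analysis options
    thresholds: dict[str, DEThresholds] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    scoring: ScoringParams = field(default_factory=ScoringParams)
    min_detected: int = 3
    var_equal: bool = True
    include_noncanonical: bool = False
    conservation: str | None = None
    require_conserved_all: bool = False
    exhaustive_scan: bool = False

    def __post_init__(self) -> None:
        if self.simulate is not None and isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)
        if isinstance(self.scoring, dict):
            self.scoring = ScoringParams(**self.scoring)
        self.thresholds = {
            k: (DEThresholds(**v) if isinstance(v, dict) else v)
            for k, v in self.thresholds.items()
        }
        if self.simulate is None:
            required = ("mirna_fasta", "utr_fasta", "circ_fasta", "circ_map",
                        "mrna_matrix", "circ_matrix", "mirna_counts")
            missing = [r for r in required if getattr(self, r) is None]
            if missing:
                raise ValueError(f"config needs simulate: or inputs {missing}")
        if self.simulate is not None:
            self.simulate.seed = self.seed

    # ------------------------------------------------------------- round trip

    def to_dict(self) -> dict[str, Any]:
        def conv(v: Any) -> Any:
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: conv(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    counts: dict[str, int]
    config_hash: str
    version: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"key": k, "value": v} for k, v in self.counts.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"cernapipe {__version__} config={config.config_hash}"
    counts: dict[str, int] = {}
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cernapipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                logger.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    config.to_yaml(out / "config.yaml")

    # ------------------------------------------------------------ inputs
    def load_inputs():
        if config.simulate is not None:
            sim = simulate(config.simulate)
            write_fixture(sim, out / "fixture", overwrite=True)
            return (sim.mirnas, sim.utrs, sim.circs, sim.circ_to_gene,
                    sim.mrna, sim.circ, sim.mirna_counts)
        circ_map = dict(
            pd.read_csv(config.circ_map, sep="\t")[["circ", "gene"]].itertuples(
                index=False, name=None
            )
        )
        return (
            read_mirnas(config.mirna_fasta),
            read_utrs(config.utr_fasta),
            read_circs(config.circ_fasta, circ_map),
            circ_map,
            ExpressionMatrix.from_tsv(config.mrna_matrix, "intensity",
                                      flags_path=config.mrna_flags),
            ExpressionMatrix.from_tsv(config.circ_matrix, "intensity",
                                      flags_path=config.circ_flags),
            ExpressionMatrix.from_tsv(config.mirna_counts, "counts"),
        )

    mirnas, utrs, circs, circ_map, mrna_mat, circ_mat, mir_mat = stage("inputs")(load_inputs)

    # ---------------------------------------------------------------- DE
    def de_stage():
        tables = {}
        for analyte, mat in (("mRNA", mrna_mat), ("circRNA", circ_mat),
                             ("miRNA", mir_mat)):
            res = run_de(mat, analyte, thresholds=config.thresholds[analyte],
                         min_detected=config.min_detected, var_equal=config.var_equal)
            tables[analyte] = res
            write_de_table(res, out / f"de_{analyte.lower()}.tsv", header_comment=header)
            counts[f"{analyte}_tested"] = len(res)
            counts[f"{analyte}_up"] = int((res["call"] == "up").sum())
            counts[f"{analyte}_down"] = int((res["call"] == "down").sum())
        return tables

    de_tables = stage("diffexpr")(de_stage)
    de_sets = DESets.from_calls(
        mirna=de_tables["miRNA"], mrna=de_tables["mRNA"], circ=de_tables["circRNA"]
    )
    de_mirs = [m for m in mirnas
               if de_sets.direction("mirna", m.name) != "none"]

    # ----------------------------------------------------------- targets
    def targets_stage():
        track = (ConservationTrack.from_tsv(config.conservation)
                 if config.conservation else None)
        table = predict_targets(
            de_mirs, utrs,
            include_noncanonical=config.include_noncanonical,
            conservation=track,
            require_conserved_all=config.require_conserved_all,
        )
        with open(out / "targets.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            table.to_csv(fh, sep="\t", index=False)
        counts["target_pairs"] = len(table)
        return table

    targets = stage("targets")(targets_stage)

    # ------------------------------------------------------------- bind
    def bind_stage():
        de_circs = [c for c in circs if de_sets.direction("circ", c.circ_id) != "none"]
        hits = scan_all(de_mirs, de_circs, config.scoring,
                        exhaustive=config.exhaustive_scan)
        with open(out / "hits.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            hits.to_csv(fh, sep="\t", index=False)
        counts["binding_hits"] = len(hits)
        counts["binding_hits_passing"] = int(hits["passes"].sum()) if len(hits) else 0
        return hits

    hits = stage("bind")(bind_stage)

    # ---------------------------------------------------------- network
    def network_stage():
        pairs = select_directional_pairs(targets, hits, de_sets)
        for cls, (t, h) in pairs.items():
            counts[f"class_{cls}_mrna_pairs"] = len(t)
            counts[f"class_{cls}_circ_pairs"] = len(h)
        triads = build_triads(pairs)
        frame = triads_to_frame(triads)
        with open(out / "triads.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            frame.to_csv(fh, sep="\t", index=False)
        for cls in ("A", "B"):
            counts[f"class_{cls}_triads"] = int((frame["class"] == cls).sum())
        mean_levels = {}
        for analyte, table in de_tables.items():
            mean_levels.update(dict(zip(table["feature"], table["mean_KO"])))
        export_network(triads, "sif", out / "network.sif")
        export_network(triads, "graphml", out / "network.graphml", mean_levels)
        export_network(triads, "tsv", out / "network_edges.tsv", mean_levels)
        conc = host_concordance(de_sets, circ_map)
        pd.DataFrame(
            [(d, "" if v is None else f"{v:.6f}") for d, v in sorted(conc.items())],
            columns=["direction", "host_concordance"],
        ).to_csv(out / "host_concordance.tsv", sep="\t", index=False)
        return triads

    stage("network")(network_stage)

    report = RunReport(counts=counts, config_hash=config.config_hash,
                       version=__version__)
    with open(out / "report.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        report.to_frame().to_csv(fh, sep="\t", index=False)
    lines = [f"cernapipe {__version__} run report (config {config.config_hash})", ""]
    lines += [f"{k:28s} {v}" for k, v in counts.items()]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    root.removeHandler(handler)
    handler.close()
    return report


def artifact_digest(dir_path: str | Path, exclude_logs: bool = True) -> dict[str, str]:
    """sha256 per artifact file (relative path -> digest), logs excluded."""
    base = Path(dir_path)
    out = {}
    for p in sorted(base.rglob("*")):
        if p.is_dir():
            continue
        if exclude_logs and p.suffix == ".log":
            continue
        out[str(p.relative_to(base))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
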