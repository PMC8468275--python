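"""Bundled annotation lists.

Small plain-text gene/miRNA symbol lists shipped with the package, taken
from a published HuD (ELAVL4) knockout mouse striatum study; they serve
as reference inputs for the list-comparison statistics:

* ``hud_targets_down_ko_up_oe`` - genes with mRNAs downregulated in HuD
  KO striatum that are HuD targets and upregulated in HuD-overexpressing
  mice.
* ``args_down_ko`` - addiction-related genes (ARGs) downregulated in
  HuD KO striatum.
* ``hud_target_arg_overlap`` - the published overlap of the ARG set with
  HuD targets, reproduced verbatim as printed (including one duplicated
  symbol and one misspelling present in the source table).
* ``cocaine_seeking_mirnas`` - miRNAs previously associated with
  cocaine-seeking behavior that changed in HuD KO striatum.
"""

from __future__ import annotations

from importlib import resources

AVAILABLE = (
    "hud_targets_down_ko_up_oe",
    "args_down_ko",
    "hud_target_arg_overlap",
    "cocaine_seeking_mirnas",
)


def load_annotation(name: str) -> list[str]:
    """Load a bundled symbol list by name (one symbol per line)."""
    if name not in AVAILABLE:
        raise KeyError(f"unknown annotation list {name!r}; have {AVAILABLE}")
    path = resources.files("cernapipe.data").joinpath(f"gene_lists/{name}.txt")
    return [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
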