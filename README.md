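# cernapipe

Competing-endogenous-RNA (ceRNA) network inference from differential
expression of mRNAs, circRNAs and miRNAs in a simple two-group design
(e.g. knockout vs wild-type, n = 3 per group).

The motivating setting is a published HuD (ELAVL4) knockout mouse
striatum study in which circRNAs and their host mRNAs were profiled by
microarray, miRNAs by small-RNA methods, and circRNA–miRNA–mRNA triads
were assembled from sequence-based target prediction plus directional
consistency of the expression changes. This package reimplements that
analysis style as a self-contained, deterministic pipeline with a
synthetic-data generator carrying planted ground truth, so every stage
can be validated end to end without any external data or network access.

## What it does

1. **Simulation** (`cernapipe.simulate`) — generates miRNA / 3'UTR /
   circRNA sequences with planted miRNA response elements, plus
   microarray-style intensity matrices and miRNA count matrices whose
   fold changes realize a chosen set of planted ceRNA triads. The truth
   (directions, site coordinates, triads) is written alongside.
2. **Differential expression** (`cernapipe.diffexpr`) — quantile
   normalization, present/marginal/absent detection filtering, CPM for
   count data, two-sample t-test on log2 intensities (pooled by default,
   Welch optional), Benjamini–Hochberg FDR, and strict threshold calling:
   fold change ≥ 1.25 or ≤ 0.75 for mRNA/circRNA, ≥ 1.75 or ≤ 0.55 for
   miRNA, each with p < 0.05. A 2^−ΔCt helper supports qPCR-style input.
3. **Target sites** (`cernapipe.sites`) — canonical seed-match classes
   (8mer, 7mer-m8, 7mer-1A, 6mer), flag-gated non-canonical classes
   (centered, 3'-compensatory), and branch-length conservation filtering
   (8mer ≥ 0.6, 7mer-m8 ≥ 1.8, 7mer-1A ≥ 2.5, inclusive).
4. **Duplex binding** (`cernapipe.duplex`) — a MiRanda-style semi-global
   alignment with affine gaps and 4× weighting of miRNA seed positions
   2–8, a simplified nearest-neighbor stack energy model, and a
   backsplice-aware circular scan so miRNA response elements spanning the
   circRNA junction are found. A hit passes with score ≥ 150 **and**
   ΔG ≤ −20 kcal/mol (both inclusive).
5. **Network integration** (`cernapipe.network`) — directional triads
   (class A: up-miRNA / down-mRNA / down-circRNA; class B the inverse),
   host-gene concordance, gene-list comparison against the bundled
   annotation lists, and export as SIF / GraphML / TSV with byte-identical
   output for identical input.
6. **CLI** (`cerna`) — `simulate`, `de`, `targets`, `bind`, `network`
   subcommands plus `run` for the whole pipeline from one YAML config.
   Exit codes: 0 success, 2 usage/config error, 3 stage failure.

## Worked example: Python API

```python
from cernapipe import MiRNA, UTRSequence, find_canonical_sites, \
    align_duplex, duplex_energy, revcomp

mir = MiRNA("miR-ex", "UGAGGUAGUAGGUUGUAUAGUU")          # let-7-like
utr = UTRSequence("Lsamp-like", "GGCAGCCUACCUCAGGUUUCCGCUACCUCAUU")
for s in find_canonical_sites(mir, utr):
    print(s)

aln = align_duplex(mir, revcomp(mir.sequence))            # perfect duplex
print("score:", aln.score, "energy:", round(duplex_energy(aln), 2))
```

Output:

```
TargetSite(gene_id='Lsamp-like', mirna='miR-ex', start=6, end=14, site_type='8mer', branch_length=None)
TargetSite(gene_id='Lsamp-like', mirna='miR-ex', start=22, end=30, site_type='8mer', branch_length=None)
score: 215.0 energy: -40.89
```

## Worked example: CLI

`demo.yaml`:

```yaml
out_dir: demo
seed: 11
simulate:
  n_mirnas: 6
  n_genes: 40
  n_circ: 24
  noise_free: true
  planted_triads:
    - [0, 0, 0, A]     # miR-0 up, gene0 down, circ0 down
    - [1, 1, 1, B]     # miR-1 down, gene1 up, circ1 up
```

```sh
cerna run --config demo.yaml
```

prints the run summary (also written to `demo/summary.tsv`):

```
mRNA_tested	40
mRNA_up	1
mRNA_down	1
circRNA_tested	24
circRNA_up	1
circRNA_down	1
miRNA_tested	6
miRNA_up	1
miRNA_down	1
target_pairs	2
binding_hits	2
binding_hits_passing	2
class_A_mrna_pairs	1
class_A_circ_pairs	1
class_B_mrna_pairs	1
class_B_circ_pairs	1
class_A_triads	1
class_B_triads	1
```

and recovers exactly the planted triads:

```
$ head -4 demo/triads.tsv
# cernapipe 0.1.0 config=bf65231f53fe
class	mirna	gene	circ
A	miR-0	gene0	circ0
B	miR-1	gene1	circ1

$ head -3 demo/network.sif
gene0	competes	circ0
gene1	competes	circ1
miR-0	binds	circ0
```

Running the same config twice produces byte-identical artifacts
(`run.log` aside); `cerna run` refuses to overwrite an existing output
directory unless `--overwrite` is given. The stages are also available
individually (`cerna simulate`, `cerna de`, `cerna targets`, `cerna
bind`, `cerna network`) for real, non-simulated inputs.

## Bundled annotation lists

Four gene/miRNA symbol lists from the motivating study are bundled under
`cernapipe.annotations` (`load_annotation(name)`):

| name | entries |
|---|---|
| `hud_targets_down_ko_up_oe` | 116 |
| `args_down_ko` | 67 |
| `hud_target_arg_overlap` | 32 |
| `cocaine_seeking_mirnas` | 15 |

Note: the source table's printed header for the first list says "(118)",
but only 116 symbols are actually enumerated there; the package bundles
and counts the enumerated symbols. The overlap list is a strict subset
of `args_down_ko`, as published.

## Repository layout

```
src/cernapipe/      package (records, diffexpr, sites, duplex, network,
                    simulate, pipeline, cli, annotations, data/)
tests/              pytest suite, including independent oracles
                    (tests/oracles.py) and tests/test_acceptance.py
scripts/acceptance.py   headline-metrics script (JSON output)
docs/methods.md     methods notes and limitations
```
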