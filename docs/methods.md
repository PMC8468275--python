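# Methods notes

Assumptions, parameter defaults and known limitations of each stage.
All defaults are inclusive unless noted, deterministic given a seed, and
exercised by the test suite against independent brute-force oracles in
`tests/oracles.py`.

## Differential expression (`cernapipe.diffexpr`)

**Pipeline per analyte.** Intensity data (mRNA and circRNA arrays):
detection filter → quantile normalization → two-sample t on log2 values
→ BH-FDR → threshold calling. Count data (miRNA): CPM → t on
log2(CPM + 0.5) → BH-FDR → calling.

**Quantile normalization** forces every sample column onto the per-rank
cross-sample means; ties within a column receive the mean of the rank
means they span, which makes the transform idempotent.

**Detection filter**: keep features flagged Present or Marginal in at
least `min_detected` (default 3) samples, mirroring array P/M/A calls.

**Test**: two-sided two-sample t. The default is the pooled-variance
(Student) form, `var_equal=True`; Welch is available with
`var_equal=False`. Rationale: at n = 3 per group, Welch's
Satterthwaite approximation is conservative — its empirical size on
exactly-normal null data is ≈ 0.034 at α = 0.05 (measured on 200 000
simulated null features), while the pooled test is exact when the two
groups share a noise scale, as they do under this package's generator
(measured size 0.0497). With equal group sizes and similar variances
the two tests give very similar statistics anyway. Rows with zero
variance in both groups get p = 1 when group means agree and p = 0 when
they differ.

**Fold change** is the ratio of *linear* group means (KO/WT), computed
after normalization; the test runs on log2 values. FDR is
Benjamini–Hochberg, reported but not used for calling.

**Calling** is strict on fold change and p: up when FC > up_fc and
p < 0.05; down when FC < down_fc and p < 0.05. Defaults: mRNA and
circRNA up_fc = 1.25, down_fc = 0.75; miRNA up_fc = 1.75,
down_fc = 0.55. A feature exactly at a fold-change cutoff is not
called; a p exactly at 0.05 is not significant.

**qPCR helper**: `relative_expression_ddct` implements 2^−(Ct_target −
Ct_reference) for a single sample.

**Caveat — quantile normalization distorts extreme-rank fold changes.**
Rank-based normalization maps every column onto the same value multiset,
so a feature planted at the global minimum (or maximum) intensity in
both groups is pinned to the same normalized value in both groups and
its fold change collapses toward 1.0 regardless of the planted effect.
The synthetic generator therefore draws the baseline of DE features from
the interior of the background intensity range (uniform(6 + |log2 FC|,
12 − |log2 FC|) on the log2 scale) so that both the shifted and the
unshifted value stay inside the background distribution. This is a
fixture-design constraint imposed by the normalization method itself,
not a tuning knob: without it the planted effect is destroyed before the
test sees it. Real data near the intensity extremes are subject to the
same distortion.

## Target sites (`cernapipe.sites`)

Canonical classes follow the standard seed taxonomy, scanning the 3'UTR
5'→3' against miRNA positions 2–7 (the seed):

* **6mer** — Watson–Crick (WC) pairing to miRNA positions 2–7;
* **7mer-m8** — 6mer plus a WC pair to miRNA position 8;
* **7mer-1A** — 6mer plus an adenosine opposite miRNA position 1
  (an A in the UTR, regardless of the miRNA base);
* **8mer** — both the m8 pair and the 1A.

Each seed-match locus is reported once with its best (most specific)
class; truncated UTR flanks simply lose the m8/1A upgrades. Two
non-canonical classes are gated behind `include_noncanonical`:

* **centered** — ≥ 11 contiguous WC pairs to miRNA positions 4–14 or
  5–15, no seed requirement;
* **3p-compensatory** — seed pairing with exactly one wobble or
  mismatch, rescued by ≥ 4 contiguous WC pairs to miRNA positions 13–16
  or 14–17, with an unpaired loop of 0–8 UTR nucleotides between the 3'
  helper helix and the seed region. The finder reports one footprint per
  imperfect-seed locus (the best helper placement); the test oracle
  enumerates all admissible placements and the finder's set is verified
  to be a subset with identical seed-end coverage.

Non-canonical sites overlapping a canonical locus are suppressed.

**Conservation**: a per-gene, per-position branch-length (BL) track; a
site's BL is the mean (or max) over its footprint, positions beyond the
track counting as 0. `filter_conserved` keeps sites with BL ≥ the
per-type threshold — 8mer 0.6, 7mer-m8 1.8, 7mer-1A 2.5, all inclusive.
Types without a threshold pass by default;
`require_conserved_all=True` subjects them to the 8mer threshold.

## Duplex binding (`cernapipe.duplex`)

**Alignment** is a MiRanda-style semi-global dynamic program of the
*reversed* miRNA against a target window read 5'→3': the miRNA must be
consumed in full, window overhangs on both sides are free, and gaps are
affine (open −8, extend −2). Per-position pair scores are WC +5, G:U
wobble +2, mismatch −3, and positions apposing miRNA nucleotides 2–8
(the seed) are multiplied by `seed_scale` = 4. The implementation is
verified against a truly exhaustive oracle that enumerates every
monotone apposition set (all `itertools.combinations` of miRNA and
window index subsets of equal size) for miRNAs up to length 10.

**Energy** uses a simplified nearest-neighbor model: a bundled table of
36 stack free energies for dinucleotide steps where both pairs are WC or
G:U (symmetric under reversing both strands, all values negative),
summed over contiguous helices; each helix interruption (internal
mismatch or gap run) adds a fixed `loop_penalty` of +4 kcal/mol; an
alignment with no paired positions has energy 0. The table is a
coarse, self-consistent surrogate for published nearest-neighbor
parameters, adequate for ranking and thresholding within this package
but not for quantitative thermodynamics.

**Pass criterion** (both inclusive): score ≥ 150 **and**
ΔG ≤ −20 kcal/mol.

**Circular scanning.** The circRNA sequence is extended by its first
`window − 1` nucleotides so windows spanning the backsplice junction are
scored; hit coordinates are reported modulo the circle length, and a
linear (non-circular) mode is available. The default scan is anchored:
windows are placed only around exact 6-nt WC seed matches. A window with
no WC pairing in the seed cannot pass (at most 7 G:U wobbles there score
7·2·4 + 15·5 = 131 < 150 for a 22-nt miRNA), so anchoring loses nothing
against seedless windows; a site pairing the seed partly through G:U
wobbles could in principle clear 150 without containing the exact 6-mer
anchor, so in that regime the anchored scan is a heuristic and
`exhaustive=True` aligns a window at every start instead. On fixtures
from the bundled generator — backgrounds screened of seed matches,
planted MREs perfect — the tests assert that anchored and exhaustive
scans agree on all *passing* hits. Overlapping windows re-align the same
locus, so hits whose [start, end) footprints intersect (modulo the
circle length) or whose starts are closer than `min_hit_separation` = 4
keep only the best-scoring representative.

## Network integration (`cernapipe.network`)

A ceRNA triad couples one miRNA, one gene and one circRNA and requires
(a) a surviving target site of the miRNA on the gene's 3'UTR, (b) a
passing binding hit of the same miRNA on the circRNA, and (c)
directional consistency: class A = miRNA up, mRNA down, circRNA down;
class B = the exact inverse. Genes whose transcripts
(`gene|transcript` ids) are called in both directions are excluded as
ambiguous and logged. Triad construction is verified against a
brute-force triple loop on fixtures of 10³ features.

**Host concordance** is the fraction of DE circRNAs whose host mRNA is
called in the same direction; a direction with no DE circRNAs is
undefined (None), not 0.

**Gene-list comparison** counts entries as given (duplicates included
unless `dedupe=True`); the intersection is case-insensitive, deduplicated
and reported in the capitalization of the first list.

**Export** (SIF, GraphML, TSV) emits nodes and edges in sorted order
with no timestamps, so identical input yields byte-identical files —
this underpins the pipeline's determinism guarantee (artifact digests
equal across re-runs of the same config and seed; only `run.log` is
excluded from the digest).

## Synthetic data (`cernapipe.simulate`)

Background sequences are i.i.d. with configurable GC content, then
*screened*: every 6-mer seed-match anchor of every generated miRNA is
removed from UTR and circRNA backgrounds (circRNAs checked across the
junction) by point mutation, so on a noise-free fixture the planted
triads are exactly the recoverable ones. Planting: each triad places an
8mer site on the gene's UTR and a full reverse-complement MRE on the
circRNA (optionally junction-spanning), and assigns fold changes per
class (defaults: miRNA 2.0, mRNA and circRNA 1/1.5 for class A, inverted
for class B). Host-gene concordance is planted per direction with
configurable rates.

Noise models: array intensities are log2-normal around the planted mean
(σ = 0.25) on a uniform(6, 12) log2 baseline — with the DE features'
baselines drawn from the interior as described above, and a configurable
fraction of low-intensity features carrying Absent flags; miRNA counts
are gamma–Poisson (negative binomial, dispersion 0.1). `noise_free=True`
zeroes both. `intensity_replicates` exposes the intensity model directly
for calibration studies.

## Limitations

* The energy model is a simplified surrogate; absolute ΔG values are not
  comparable to RNAhybrid/ViennaRNA outputs, only the ≤ −20 threshold
  semantics within this package.
* The DE module targets the small-n two-group array design it was built
  for; it is not a general count-model DE framework (no shrinkage, no
  covariates).
* Conservation tracks are user-supplied positional branch lengths; no
  alignment machinery is included.
* Quantile normalization's extreme-rank distortion (above) applies to
  real inputs as well as simulated ones.
* The bundled annotation lists reproduce their source table as
  enumerated; the first list's printed header count (118) disagrees with
  its enumerated content (116), and the package sides with the
  enumerated symbols.
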