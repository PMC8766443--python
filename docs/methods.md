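# Methods

This note documents the models, defaults, and design choices behind `qbc2`:
what the simulator emulates, how the demultiplexer makes its decisions, and
what the quantification layer computes. It is written for users who need to
judge whether results on simulated data transfer to their own experiments.

## Barcode architecture

A labeled antibody oligo carries, after the full protocol, an antibody
barcode, a UMI, and three well barcodes (two ligation rounds + one PCR
round). The default read layout is

- read 1 (100 nt): `[round-3 PCR barcode 8 nt][linker 4 nt][round-2 8 nt]
  [linker 4 nt][round-1 8 nt]`, later rounds proximal to the read start
  because ligation appends to the oligo 3′ end; the remainder of the read is
  inert padding.
- read 2 (50 nt): `[antibody barcode 15 nt][UMI 10 nt]`.

Barcode and UMI lengths are design choices of this package (the protocol
itself fixes only the read lengths and the three-round structure); all
lengths and the segment order are configurable through `BarcodeSchema`.

Whitelists (and antibody barcodes) are rejection-sampled to pairwise Hamming
distance ≥ 3. This makes the whitelist a radius-1 perfect code: any single
substitution corrects unambiguously, and the demultiplexer's default
correction radius of 1 can never map a read to the wrong source barcode.
`min_pairwise_hamming` exposes the check (`distance ≥ 2r + 1` for radius r).

Sample multiplexing uses subsets of hashtag antibodies. `build_hashtag_code`
assigns subsets deterministically — singletons in hashtag order, then pairs,
then triples, lexicographically — so ten samples over four hashtags get the
four singletons and the six pairs. Any bijective assignment would work; the
deterministic order makes runs reproducible and codes self-documenting.

## Simulator

**Antigen abundance.** Per cell type, each antibody has a mean molecule
count; a cell draws `Poisson(mean × exp(N(0, σ)))` with dispersion σ = 0.35
by default. The log-normal layer models cell-to-cell staining variability,
the Poisson layer molecule-count sampling; low-abundance antibodies thus
produce genuine zeros. Every antibody additionally receives ambient
background counts (`Poisson(0.3)`), so isotype and off-target channels are
nonzero and QC logic has something to measure. No published distribution
exists for bound-antibody counts in this assay; log-normal-Poisson is the
standard overdispersed choice for count data of this kind.

**Hashtags and controls.** Ordinary cells carry exactly their sample's
hashtag subset at mean 30 molecules per hashtag. HT2 controls (added before
round 1) and HT3 controls (added after round 1) carry only their control
hashtag at mean 120 — bright, as hashtags against ubiquitous antigens are —
and ambient background elsewhere. Spike sizes default to `round(0.05 × regular
pool)` each, the fractions used in the assay's validation design; absolute
overrides (`ht2_spike_n`) exist for controls-only scenarios.

**Split-pool.** Each cell draws a uniform well in each round; HT3 cells have
no round-1 well. Per molecule and round, ligation succeeds with probability
`ligation_success_prob` (default 1.0); a molecule missing any barcode never
amplifies and is dropped before sequencing. With probability
`blocking_failure_prob` (default 0) an HT3 molecule illegitimately acquires
a random round-1 barcode from the pooled mix — the failure mode the HT3
control exists to detect.

**Antibody swapping.** With probability `swap_rate` (default 0) a molecule
relocates to a uniformly random other cell *before* barcoding and follows
that cell's entire well path. This is deliberately the full-path model: a
swap confined to later rounds would mint brand-new triples, whereas the
HT2 control is designed to catch foreign marker signal appearing *on the
control cell's own barcode* — which only the full-path mechanism produces.
The rate is a free parameter; the assay's validation data constrain it only
to "small".

**PCR and sequencing.** PCR is modeled as per-molecule read multiplicity —
geometric with mean `mean_reads_per_molecule` — rather than cycle-by-cycle
amplification; the protocol's 14 cycles are carried as metadata only, since
after UMI collapse only the duplicate-count distribution matters.
Sequencing applies i.i.d. substitutions per base (no indels: ligation
products are fixed-length), and quality strings are constant because the
demultiplexer does not use them.

Identical config + seed gives byte-identical FASTQ and truth tables; each
stage draws from an independent deterministic stream derived from the seed.

## Demultiplexer

Reads are sliced at schema offsets (reads shorter than the required span are
rejected as truncated). Each barcode segment is corrected to the unique
whitelist entry within Hamming distance ≤ 1 (default); observations with no
entry in radius, or with two entries tied at the minimum, are rejected —
reproducibility over yield. `N` counts as a mismatch to every base.
Correction is vectorized over the distinct observed strings per segment, so
exact matches (the vast majority) cost a dictionary lookup.

Cells are called by grouping records on the corrected triple. UMIs are
collapsed per (cell, antibody) with the directional network rule (merge B
into A when Hamming(A,B) ≤ 1 and count(A) ≥ 2·count(B) − 1, then count
connected components) or by exact distinct strings. Directional collapse is
the default because it absorbs single-error PCR/sequencing satellites; note
that on data *without* PCR duplication it can merge two genuinely distinct
molecules whose random UMIs land within one mismatch, so exact counting is
the faithful inverse for duplication-free simulations and the round-trip
tests use it.

Cells with fewer than `min_umi = 10` collapsed UMIs are dropped. The floor
is an explicit, configurable threshold rather than a knee-point heuristic:
in this assay cells remain identifiable down to ~100 UMIs, so any small
floor mainly removes collision fragments and ambient triples, and an
explicit value keeps runs comparable. Every input read lands in exactly one
ledger category (truncated, one of four correction failures, low-UMI cell,
assigned), and the suite asserts the conservation identity.

Output is a Matrix Market triplet (matrix.mtx, barcodes.tsv = triple keys,
features.tsv = antibody name/class), readable by standard single-cell
tooling.

## Quantification

**CLR.** `clr_transform` computes `ln((xᵢ + c)/g(x + c))` with pseudocount
c = 1 and natural log by default (base configurable); rows sum to zero. The
log form is the standard centered log-ratio; a raw-ratio variant
(`log=False`) is provided for strict fidelity to formulations that display
the ratio without the logarithm.

**Collision mathematics.** `expected_collision_fraction(n, m)` returns
`1 − (1 − 1/m)^(n−1)` with a Poisson approximation `1 − e^(−(n−1)/m)`
(they agree to ~10⁻⁴ below 5% occupancy); `max_loading(m, f)` is the
dilution rule `⌊f·m⌋`. `monte_carlo_collision_fraction` estimates the same
quantity empirically by multinomial assignment and is used as an
independent cross-check.

**Hashtag decoding.** Per hashtag, cells split positive/negative by a
two-class 1-D k-means on that hashtag's CLR column; if the two centers are
closer than `min_separation = 1.0` CLR units the column is judged unimodal
and all cells are negative (this guards against hallucinating positives in
an unused channel). A cell's positive set is matched exactly against the
sample code; a set covering the union of ≥ 2 codes is labeled
`multi_sample` (the collision/doublet signature), anything else
`undetermined`. Decoding is threshold-free but not infallible: a cell whose
hashtag staining falls in the extreme log-normal tail can cross a
positivity boundary, so recovery on clean simulations is ≥ 99% rather than
exactly 100%.

**Control QC.** On simulated data control identity can come from the truth
table; on real data (and by default) controls are inferred from the data:
a cell is hashtag-only when ≥ 75% of its UMIs come from hashtag-class
antibodies, with the dominant hashtag naming the control. This signature
rule is robust where per-marker clustering is not (markers near-uniformly
expressed across the pool). The QC report counts HT2 and HT3 cells, compares
mean marker CLR on HT2 controls against ordinary cells (swap leakage), and
summarizes the isotype channel.

## Analysis

PCA is centered (full SVD) with component signs fixed so each component's
largest-magnitude loading is positive — determinism across runs and BLAS
builds. k-means uses best-of-10 restarts at a fixed seed. t-SNE is
initialized from the top-2 PCA scores (scaled to the 1e-4 early-variance
convention) with perplexity 30 by default; no perplexity is prescribed by
the assay, and the embedding is for visualization only — no test depends on
its geometry.

Gates are boolean masks nested under a parent (root = all cells); the
auto-threshold is the same 2-means split used for hashtags, computed within
the parent gate, with the convention that a unimodal marker has *no*
positive cells (threshold +∞) — so ">" gates come out empty and "<" gates
pass the parent through. When an entire parent population is positive for a
marker (e.g. CD45 on lymphocyte-only fixtures) an explicit threshold must
be supplied, exactly as a flow analyst would place that gate by eye.

`kappa_lambda_ratio` counts kappa-positive over lambda-positive cells in a
B-cell gate; 1–2 is normal, > 2 kappa-expanded, < 1 lambda-expanded, and a
gate with zero lambda-positives returns an infinite-ratio sentinel with a
warning. `flag_nonspecific` selects the principal component whose absolute
loading mass concentrates most on the control markers (isotype, stray
hashtags), orients it toward the controls, and flags cells above 2.5 robust
z-scores (MAD-scaled); if no component carries control loading it returns
an empty mask with a warning.

## Study fixtures and problem sizes

`two_lines` emulates a two-cell-line (Jurkat-like / HEK293T-like) 1:1
mixing experiment: 2,000 cells by default with a 7-antibody panel, 5% HT2
and 5% HT3 spikes, a 5% non-specifically stained subpopulation (dim uniform
markers, bright isotype, stray HT3), mean 1.2 reads per molecule and 0.5%
substitution error. `ten_patients` emulates ten pooled samples (150 cells
each by default) over a 29-antibody panel with four coding hashtags and
blood cell types including CLL-like (kappa-restricted, CD5+CD23+) and
ATLL-like (CD4+CD25+PD1+) clonal populations. `controls_only` carries only
the two spike-in populations (300 cells each). Mean antibody loads put
ordinary cells near 200 UMIs — deliberately modest so whole experiments
simulate and demultiplex in seconds; tests run the same scenarios at a few
hundred cells, and the acceptance script runs `two_lines` at its full
2,000-cell default.

## What the simulations do and do not show

The generator reproduces the *structural* features the pipeline's
guarantees rest on: combinatorial well assignment and its collision
statistics, per-round barcode acquisition and loss, spike-in control
semantics, UMI duplication, and substitution error. It does not model
ambient antibody background beyond a constant rate, cell-size–correlated
library depth, antibody cross-reactivity, doublet cells that physically
travel together, indels, or quality-score structure. Passing tests
therefore validate the decision logic and the mathematics; absolute
performance numbers (e.g. decoding accuracy) on real data will depend on
staining quality and background levels the simulator idealizes.

## Known limitations

- Threshold-free positivity fails by design on channels where a population
  is absent or universal; explicit thresholds are the escape hatch.
- Collision-merged cells are not deconvolved; they surface as
  `multi_sample` labels or mixed profiles, matching how the assay itself
  treats them (loading is chosen to make them rare).
- The swap model is a single between-cell relocation rate; it does not
  distinguish dissociation during split-pool from index hopping on the
  sequencer, which the real HT2 control also conflates.
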