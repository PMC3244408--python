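# Methods

## Problem and model

Small-RNA duplexes (siRNAs and miRNA duplexes) silence unintended
transcripts through their seed region: the heptamer at positions 2–8
(occasionally 1–7, as for miR-520f) from the 5′ end of a RISC-loaded
strand. A transcript is a candidate off-target whenever it contains the
exact Watson–Crick reverse complement of that heptamer ("target7"),
classically in the 3′UTR but demonstrably also in the CDS. This package
implements the complete computational workflow around that model:

1. **Site scanning** — enumerate every exact target7 occurrence per
   transcript, label it by region from a CDS annotation
   (5′UTR / CDS / 3′UTR), and name sites serially 5′→3′
   (`640a-1`, `640a-2`, …: duplex-name digits + strand letter + rank).
2. **Seed-duplex stability** — the melting temperature of the 7-bp
   seed:target duplex predicts silencing strength; strands are ranked
   by seed Tm.
3. **Promoter motif scanning** — E-box (CANNTG) occurrences in promoter
   sequences with signed TSS-relative coordinates, for reasoning about
   transcription-factor-mediated activation downstream of an off-target
   knockdown.
4. **Expression stratification** — split measured transcripts into
   seed-complementary targets vs a no-complementarity background and
   test whether targets are shifted down in log2 fold change.

## Seed matching

Matching is exact Watson–Crick only. G:U wobble pairs, mismatch
tolerance and context scores are deliberately out of scope: the
published seed heptamers and their complements (AAGUGCU → AGCACUU,
AGUGCUU → AAGCACU) are exact complements, and exact matching keeps every
count reproducible. Overlapping occurrences are all reported; nothing
is deduplicated. A site that straddles a region boundary is labeled by
the region of its 5′-most nucleotide. DNA transcript input is matched
after T→U normalization; reported sequences keep their input alphabet.

## Seed-duplex melting temperature

The seed duplex is modeled as the heptamer paired with its perfect
complement: six nearest-neighbor propagation stacks plus one helix
initiation term, no dangling ends, two-state melting:

    Tm(°C) = 1000·ΣΔH / (A + ΣΔS + R·ln(CT/4)) − 273.15 + 16.6·log10([Na+])

* ΔH, ΔS per stack: Freier et al. (1986) RNA/RNA parameters, shipped as
  editable plain text (`seedshift/data/rna_nn_freier1986.tsv`).
* A = −10.8 cal/(K·mol) (initiation), R = 1.987 cal/(K·mol).
* CT = 100 µM total strand, [Na+] = 100 mM (the standard conditions for
  seed-Tm ranking of siRNA strands).

With these defaults the family guide seed AAGUGCU melts at 29.6 °C,
matching its published 29.5 °C within the 0.5 °C calibration band. The
parameter table is data, not code, so an alternative table can be
swapped in without touching the implementation.

One quirk worth knowing: replacing an A:U pair by G:C raises Tm in
every interior stack context, but a terminal substitution that creates
a CG stack (the weakest G:C stack in the Freier table, e.g.
…CA → …CG) can lower Tm by up to ~0.12 °C. The property test asserts
strict monotonicity for interior positions and bounds the terminal
exception.

## One-sided K-S analysis

For a chosen seed and region (default 3′UTR), targets are transcripts
with ≥ `min_sites` sites in that region; the background is transcripts
with **no** site in any region — the conservative reading of "no seed
complementarity". Transcripts with sites that fail the target rule
belong to neither set. Probe-level duplicates are collapsed by median
log2FC before analysis.

The downward shift of targets is tested with the one-sided two-sample
Kolmogorov–Smirnov statistic

    D = sup_x [F_targets(x) − F_background(x)]

and the Smirnov asymptotic tail probability
`p = exp(−2·D²·m·n/(m+n))`, clipped to (0, 1]. This form is
deterministic, reproduces the very small p-value magnitudes a
genome-wide screen yields, and is calibrated: under the null the
rejection rate at α = 0.05 is 0.050 ± 0.02 (measured over 2000
simulations at m = n = 300 in the acceptance suite). For small samples
an exact permutation p-value (full enumeration of splits) is available
and cross-checks the asymptotic form on the worked example
{−3,−2,−1} vs {1,2,3}: D = 1, p = e⁻³ ≈ 0.0498 vs 1/20 exactly.

Correlations between conditions are Pearson r on log2FC vectors
restricted to a gene set (Spearman by flag); "commonly decreased /
increased" defaults to a sign criterion (log2FC < 0, resp. > 0, in all
conditions), configurable thresholds, because the published criterion
behind such counts is typically unstated.

## Synthetic data generator

The generator emulates the structure of a genome-wide array screen of
several transfections sharing one guide seed, with exact planted truth:

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` | 20 000 | array-scale transcript count |
| `utr5/cds/utr3_length` | 150 / 900 / 600 nt | typical mRNA proportions |
| `site_fraction` | 0.045 | ≈ 900 carriers per 20 k transcripts, the scale of a 7-mer 3′UTR census |
| `sites_per_carrier` | Poisson-truncated ≥1, λ = 1 (fixed count optional) | planted 3′UTR sites; variable counts give carriers heterogeneous true shifts, so target genes correlate between conditions |
| `effect_delta` | 0.3 | mean log2FC downshift per planted site |
| `noise_sigma` | 0.4 | log2FC noise SD |
| `n_conditions` | 6 | transfections sharing the guide seed |
| `shared_seed` | AAGUGCU | the family guide seed |

Design choices: the target7 is rejection-resampled out of every
non-planted position, so scanning recovers the carrier set *exactly* —
oracle tests are crisp, not probabilistic. The per-site effect is
additive (linear in site count), reflecting the observation that
mutating either of two sites removes part of the silencing and mutating
both removes it almost completely. Noise is Gaussian by default; a
Student-t (5 df, variance-matched) option exercises robustness.
All randomness flows from one integer seed through named
`numpy.random.default_rng` streams, so outputs are byte-identical across
runs and platforms.

What the generator does **not** emulate: probe-level intensity noise,
dye/normalization artifacts, 3′UTR length and composition biases,
wobble/mismatch near-sites, or correlated off-target effects of the
passenger strands. Passing tests therefore demonstrate correctness of
the pipeline's logic and calibration of its statistics under a clean
generative model — not performance on real array data.

## Numerical and interface choices

* Coordinates are 1-based inclusive for transcripts; promoter positions
  are signed TSS-relative with no 0; BED output (and only BED output)
  is 0-based half-open.
* Tm is reported to one decimal; ranking ties break by duplex name then
  strand role, so output order is deterministic.
* Empty UTRs are legal and scanning them simply returns no sites.
* Strand roles: "lower" is the guide (antisense) strand, "upper" the
  passenger; a duplex may lack an annotated passenger strand (several
  mature miRNAs do), and such strands are skipped wherever both strands
  would otherwise be scanned.
* Statistics refuse degenerate inputs loudly: empty target or
  background sets, zero-variance conditions and missing measurements
  are errors naming the offender, never silent NaNs.

## Problem sizes used in the shipped checks

The test suite and acceptance checks run the generator at 400–1500
transcripts and the K-S calibrations at 2000 null replicates
(m = n = 300) and 200 power replicates (300 vs 2700, δ = 0.5,
σ = 0.5) — sizes chosen so the full suite completes in seconds while
keeping Monte-Carlo error well inside the asserted bands. The
generator's own defaults (20 000 transcripts, six conditions) are what
`seedshift simulate` produces out of the box.

## Known limitations

* Seed-site scanning is exact-match 7-mer only; no 8-mer/6-mer site
  classes, no context scoring, no conservation.
* The Tm model has no mismatch, dangling-end or advanced salt terms;
  it is a ranking instrument for perfect seed duplexes, not a general
  hybridization calculator.
* The asymptotic one-sided K-S p-value is anti-conservative for very
  small samples; use the permutation option below ~20 per group.
* Strand sequences for several published siRNA duplexes exist only in
  figure form and are not shipped; the packaged duplex data cover the
  miRNA guide strands (miRBase) plus synthetic duplexes from the
  generator.
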