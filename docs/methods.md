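# Methods

## Statistical model

Site-level MS intensities are modeled as multiplicative: on the log2 scale
a replicate value is baseline + condition shift + Normal(0, σ) noise
(log-normal on the raw scale). All testing is done on
log2(x + pseudocount); the pseudocount (default 1) guards against zeros
from unquantified sites and is negligible relative to typical MS
intensities (~2^20), so the transform is effectively log2(x). Whether the
original analyses tested raw or log intensities beyond adding the
pseudocount is not documented anywhere we could find; log-scale testing is
the standard choice and is adopted here as an explicit assumption.

Each pairwise contrast uses the equal-variance two-sample Student t-test
(Welch is available behind a flag but is not the default, matching the
stated use of Student's test), with significance at unadjusted p < α. No
fold-change filter and no multiple-testing correction are applied in the
main path; a Benjamini–Hochberg mode (via statsmodels) exists for users
who want adjusted calls. Missing values are excluded per site, never
imputed; a site with fewer than two remaining replicates in either group
is untestable and is dropped with a logged count.

Degenerate inputs are resolved deterministically: when both groups have
zero variance the t statistic is undefined, so equal means give t = 0,
p = 1 and unequal means give p = 0 with an `exact_separation` flag. A
consequence of the t-test worth noting: a site cannot be significant with
log2FC exactly 0 (t = 0 implies p = 1), so direction never needs a tie
rule.

## Temporal classification

The three contrasts (6 h vs untreated, 24 h vs untreated, 24 h vs 6 h)
yield a direction triple in {up, down, none}³; the classifier is a total
function on those 27 triples (tested exhaustively against an independently
hand-enumerated table). Two design choices were genuinely open:

- The 24h-vs-6h contrast is consulted *only* when neither vs-untreated
  contrast is significant, which is exactly the observational definition
  of the pseudosilent category; a site significant vs untreated is
  classified from the vs-untreated pattern regardless of the 24-vs-6
  outcome.
- EARLY_UP_LATE_DOWN is included although only its mirror
  (early decrease, late increase) is described for real data; a taxonomy
  that partitions outcome space must contain it. It is expected (and
  planted) empty; calls of it on synthetic data are double false
  positives.

Protein rollup: per contrast a protein is up if ≥1 site is up and none
down (symmetrically down), mixed if both, none otherwise. The
protein-level temporal class is the class of its most significant site by
the 24 h-contrast p-value, ties broken by ascending residue position.
This tie rule is our invention — how multi-site proteins were summarized
on published protein-level heatmaps is not stated.

## Synthetic data generator

The generator emulates the 3×3 design (UnT, 6hAmAc, 24hAmAc × 3
replicates). Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| n_proteins / sites_per_protein | 400 / 1–3 | small acetylome-scale table |
| baseline log2 intensity | Normal(20, 2) | raw intensities ~10⁶, typical MS scale |
| effect_size (log2) | 2.0 | clearly powered at n = 3 |
| noise_sd (log2) | 0.3 | replicate CV ~20%, typical for enrichment MS |
| class proportions | 40% unchanged; persistent/late/early-transient up 10% each; their down mirrors and early-down-late-up 5%; pseudosilent 5%+5%; early-up-late-down 0 | most quantified sites unchanged; up-classes dominate, mirroring net hyperacetylation |
| compartments | mito .40 / nucleus .25 / cytosol .25 / membrane .10 | mitochondrial fraction largest |
| motif plant | E at −1, 40% of changed-site windows | glutamate N-terminal to acetyl-K, a reported acetylation context |
| background AA frequencies | uniform (1/20) | keeps binomial oracles exact |
| dropout | 0 | missing-data rule exercised explicitly in tests |

Class counts are realized exactly by largest-remainder apportionment, so
`round(proportion × n_sites)` is met and the total is exact. All outputs
are bit-reproducible for a given (design, seed).

**Pseudosilent planting.** The pseudosilent class is defined
observationally — 6 h and 24 h differ from each other while neither
differs from untreated — which no fixed pair of shifts realizes at high
power. Pseudosilent sites get shifts ∓effect/2 symmetric about untreated
(so the 24-vs-6 difference equals the full effect) with replicate noise
inflated ×2, de-powering the vs-untreated contrasts (Δ = effect/2) far
more than the 24-vs-6 contrast (Δ = effect). Recovery of this class is
therefore intrinsically partial. A pre-build Monte-Carlo calibration of
this design (direct scipy simulation, independent of the package code)
fixed the expected rates: ≈1.00 for persistent and sign-flip classes,
≈0.95 for late and early-transient (a vs-untreated false positive always
misclassifies them, so 0.95 × power is a hard ceiling at α = 0.05), ≈0.88
for unchanged (the joint probability that none of three correlated tests
is a false positive), and ≈0.30 for pseudosilent. Recovery is summarized
as the unweighted mean of per-class rates over the non-pseudosilent
classes (macro; ≈0.96 expected), with the site-weighted (micro, ≈0.93)
and pseudosilent rates reported alongside. These rates quantify the
classifier against its own planted model: real acetylomes have smaller
and heterogeneous effects, peptide-level missingness, and correlated
sites, so passing recovery here does not promise those rates on real
data — only that the machinery is correct and calibrated (type-I error
= α within Monte-Carlo tolerance).

What the generator does not emulate: raw spectra, peptide-to-site rollup,
batch effects, run-order drift, intensity-dependent variance, or
non-uniform flanking composition (overridable but uniform by default).

## Enrichment

Over-representation is the right-tailed Fisher exact test,
p = Σ_{i≥k} Hypergeom(i; N, K, n), via `scipy.stats.hypergeom.sf`. The
enrichment call applies the threshold in its printed log form,
−log10 p ≥ 1.3 (equivalent to p ≤ 10^−1.3 ≈ 0.0501, slightly looser than
p < 0.05; the equivalence is asserted in tests). The ORA universe
defaults to the proteins quantified in the input table rather than a
whole proteome — the detection-bias-correct background — and can be
overridden by a GMT-supplied universe. Identifier matching is
case-insensitive exact string matching; no ortholog mapping.

## Networks

Pearson correlations are computed with pairwise deletion of missing
values; p-values use the t transform with df = m − 2 shared samples.
Constant features are flagged degenerate and reported with r = 0, p = 1
rather than NaN. The stored matrix is exactly symmetric (symmetrized
after computation) with unit diagonal.

Edge concordance follows the circle-plot convention: both endpoints up →
`both_up`, both down → `both_down`, opposite directions → `discordant`.
Edges with exactly one unchanged endpoint are also `discordant` (they are
drawn gray in such plots); both endpoints unchanged → `unclassified`.
This one-unchanged-endpoint reading is an interpretive choice.

## Motif discovery

motif-x defaults: half-width 7 (15-mer windows), binomial p cutoff 1e−6,
minimum 20 foreground occurrences. Background frequencies are positional
(computed per offset from the background windows, re-computed after each
restriction) rather than a global composition, to respect positional bias
near the central lysine; a residue unseen in the restricted background is
floored at 1/(2·background size) rather than 0. Binomial tails are exact
(`scipy.stats.binom.sf`, verified against log-space summation to 1e−10),
not normal approximations. Candidate ties are broken lexicographically by
(offset, residue), making discovery deterministic and invariant to input
window order. Each emitted motif records per-step statistics; the
headline p-value is the seeding (most significant) constraint's. Known
limitation shared with motif-x: after restriction the background can
become small, so late extension steps have noisy background frequencies
and occasional spurious constraints — the emitted *first* constraint is
the robust signal.

PFM matching scores the best ungapped alignment by mean per-column
Pearson correlation (minimum overlap 4 columns); zero-variance columns
(e.g. uniform) contribute 0 by definition.

## Problem sizes in validation

The validation experiments use 2,000 sites × 20 seeds for class recovery
and type-I calibration, 500-window foregrounds × 20 seeds for motif
recovery, the full (K, n, k) grid for every universe size N ≤ 60 for the
hypergeometric oracle, and 1,000 random pairs for the correlation oracle.
These sizes give Monte-Carlo standard errors well below the asserted
tolerances while keeping the whole suite under half a minute.

## Interfaces

The command-line layer (`acetyltempo simulate|diff|classify|enrich|
network|motifs|report`) is a thin wrapper over the library; all logic is
importable. Configuration is TOML key/value, with CLI flags overriding
the file and the effective configuration echoed to the log. On-disk
formats are plain text throughout: TSV (intensities, sample sheets,
contrasts, classes, edges, PFMs), GMT (gene sets), FASTA (sequences).
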