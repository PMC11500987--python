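# Methods

## Scope and model

`csslkit` treats a CSSL panel as a set of mosaic genomes: each line is the
recurrent-parent genome with a small number of homozygous donor-origin
intervals fixed by backcrossing and selfing. Three assumptions drive the
design:

* both parents are inbred, so parental heterozygous or missing genotypes
  mark a site as non-diagnostic rather than something to impute;
* lines are near-fixed (>= 4 selfing generations), so a heterozygous call
  in a line is treated as ambiguous by default (`het_policy="ambiguous"`;
  `"donor_evidence"` optionally counts it as donor, since at a diagnostic
  site a het necessarily carries the donor-specific allele);
* segment origin is decidable only where the parents differ — regions
  where they are identical (natural introgression / shared haplotypes) are
  intrinsically ambiguous and are handled by the adjustment step, not by
  the classifier.

## Segment detection

The detector is windowed rather than site-wise so that genotyping error
(~1%) and missingness cannot fragment segments. Tunables, with defaults:

| parameter | default | meaning |
|---|---|---|
| `window_size_bp` | 200 000 | sliding-window width (bp) |
| `step_bp` | 50 000 | window stride (bp) |
| `min_informative_per_window` | 10 | informative sites needed for a defined LSP |
| `lsp_threshold` | 0.80 | strict (>) donor-fraction threshold |
| `ambiguous_frac_min` | 0.5 | ambiguous fraction that triggers adjustment |
| `donor_frac_min` | 0.8 | donor share of informative sites required to rescue |
| `merge_gap_windows` | 2 | non-seed windows bridgeable between seed runs |

The window default is calibrated to dense resequencing panels (thousands of
markers per Mb), where 10 informative sites per 200 kb is a trivial floor.
At sparser densities the window should be widened to keep the expected
informative count comfortably above the floor; the validation runs in this
repository genotype 50 markers/Mb and use 500 kb windows (expected ~25
sites per window) with the same 50 kb step.

Two rules are worth spelling out:

* **Updated substitution proportion is marker-wise.** After seed windows
  merge and boundaries are trimmed to the outermost donor-diagnostic
  markers, the donor fraction is recomputed over the trimmed interval's
  markers, not its windows, and compared strictly against the threshold.
  The marker-level recount is the stricter and more reproducible reading;
  it also makes reported proportions independent of window geometry.
* **Neutral windows.** A window dominated by ambiguous sites whose
  informative sites (if any) are donor-consistent carries no evidence
  against a substitution. Such windows do not count toward the merge gap.
  Without this, a parent-homologous tract of a few Mb — tens of
  consecutive windows with no informative sites — would split every
  segment it interrupts, which contradicts how such tracts behave in real
  panels (they are interior to true substitutions, flanked by donor
  evidence on both sides). A tract at a segment *edge* is still trimmed,
  because boundaries end at donor-diagnostic markers; its interior extent
  is genuinely undecidable from genotypes.

Boundary precision is limited by marker spacing: the reported boundary is
the outermost donor marker, so the expected inward bias is about one
marker interval per side (~20 kb at 50 markers/Mb).

## Pseudo-genome construction

Donor alleles are applied directly from the joint VCF (homozygous-ALT donor
sites inside each segment), in ascending order with cumulative offset
tracking. With fully genotyped inbred parents this is equivalent to
extracting the homologous donor-assembly sequence, and it keeps the
construction self-contained and exactly testable. Symbolic ALTs (`<DEL>`,
breakends) are rejected — only explicit REF/ALT sequence records have
deterministic semantics here. The liftover table maps coordinates exactly
everywhere except inside an indel's REF span (positions deleted from the
reference have no image; they map to the edit point). How genes straddling
a segment boundary should be quantified downstream is left to the caller —
the liftover is provided, but no single convention is imposed.

## Expression rules

Normalization is median-of-ratios (size factors from genes with no zero
count; all genes retained). The DEG test is Welch's unequal-variance t-test
on log2(NC + 1) replicate values — the rule being emulated specifies only
a p-value and fold-change cut, so the test choice is ours; raw P < 0.05 is
used deliberately, with no multiple-testing correction, to match that rule
rather than improve on it. Fold change is log2 with pseudocount 1. Two
"expressed" thresholds coexist on purpose: expression capacity counts
NC > 1, while the novel-gene DEG branch uses NC >= 1; both are separately
configurable because the source conventions differ and we preserve each as
stated. Degenerate inputs: identical replicate vectors yield P = 1 rather
than NaN.

## Module-flow equitability

Both definitions of `p_ij` are implemented because they genuinely differ.
The literal equation divides by the *target* module size `n_j`; its row
sums need not be 1, so `E_H` is not confined to [0, 1] and an even spread
into large modules can score near 0. The row-normalized form
(`p_ij = n_ij / sum_j n_ij`) satisfies the stated bounds — 0 exactly when
all genes flow to one module, 1 for a perfectly even spread — and is the
default; the `as_printed` mode is selectable for comparability. The
`0 ln 0 := 0` convention applies; `N_B = 1` is an error (maximum diversity
ln 1 = 0). Network inference itself (WGCNA-style) is out of scope: module
assignments, membership scores and trait correlations are inputs.

## Simulator

The generator reproduces the breeding design, not cotton biology: random
nucleotide genomes, diagnostic SNP/indel markers on a jittered grid
(uniform coverage, REF spans never overlapping), optional parent-shared
tracts (markers therein uninformative), meiosis with Poisson crossovers
(default mean 2/chromosome) and uniform breakpoints without interference,
rejection-sampled MAS retention, and per-tract fixation of residual
heterozygosity after selfing (a contiguous het tract fixes as a unit —
per-site independent fixation would shred tracts into impossible mosaics;
`het_residual=True` keeps the tracts het instead to exercise
`het_policy`). Expected donor fraction after `b` backcrosses plus selfing
is `0.5^(b+1)`, which the Monte-Carlo benchmark checks at 500 lines.

Default study conditions (20 lines, two 50-Mb chromosomes, 50 markers/Mb,
1% genotype error, 5% missingness, BC4 + 4 selfings, one 4-Mb MAS target
per line) are desk-scale: small enough to run in seconds, dense enough
that every window holds a meaningful marker count. Expression counts are
log-normal-Poisson (`lambda = 2^(mu + effect + N(0, sigma))`) with planted
cis effects for genes inside donor intervals and attenuated trans effects
for a random outside fraction — a convenience model for validating the
caller, not a claim about real RNA-seq dispersion.

What passing the simulation benchmarks does **not** show: robustness to
reference bias, structural variation, segmental duplication or polyploid
homoeology (all absent from the generator), performance at marker
densities far below ~10 informative sites per window, or correctness of
module assignments (which are never inferred here). Recovery statistics
use a fixed matching rule — a call is a true positive if it overlaps any
truth interval; a truth block >= 5 windows long is recovered if calls
cover >= 80% of it; breakpoint error is measured at the outermost call
boundaries of each recovered block.

## Numerical and degenerate-input choices

* Strict `>` at the 0.80 segment threshold; inclusive `>=` at the
  adjustment, key-gene and novel-gene thresholds — each as its rule states.
* Windows are clipped at chromosome ends; empty tracks yield empty window
  lists with a warning, not errors.
* Multiallelic VCF records are dropped by default (the detector needs
  parent-diagnostic biallelic contrasts); `split` re-codes each ALT as a
  biallelic record, marking genotypes that carry a different ALT missing.
  Split records share a position, so table ordering requires
  non-decreasing positions with distinct (pos, REF, ALT) keys.
* All randomness flows from a single integer seed; identical inputs and
  configuration produce byte-identical outputs.
* BED output is 0-based half-open; VCF positions are 1-based; a variant at
  position p with REF length L occupies [p-1, p-1+L).

## Known limitations

Ancestry is called deterministically from windowed proportions; an HMM
would propagate uncertainty and may localize breakpoints below marker
spacing, but is deliberately out of scope. Coverage-depth introgression
detection (useful for distant crosses) is not implemented. The observed
substitution proportion weights all lines equally, matching its use as a
panel-level sanity statistic rather than an estimator.
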