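# Methods

## Scope and model

`sigpep` covers the desk side of a genome-wide signal-peptide secretion
screen: sequence analytics of predicted Sec/SPI signal peptides, group
statistics contrasting secretion-positive and secretion-negative peptides,
cross-strain similarity of predicted signal-peptide repertoires,
fluorescence plate-screen shortlisting, and in-silico assembly of
signal-peptide::cargo expression cassettes. Signal-peptide *prediction*
itself (neural-network classifiers) and transmembrane-helix prediction are
deliberately out of scope: the package parses their tabular outputs and
treats the helix call as an externally supplied flag.

A signal peptide is recorded as the residues up to the cleavage site
(`sp_seq`, the cut lies after residue `len(sp_seq)`) plus up to two
downstream residues, because fusion constructs retain exactly two residues
of the native mature protein after the cleavage site.

## Sequence properties

* **N-domain.** Operationally, residues from the initial Met through the
  last positively charged residue (K or R). When a peptide contains no K/R
  the N-domain is defined as position 1 alone; this keeps
  `1 ≤ n_domain_end ≤ length` and contributes charge 0 for a Met start.
* **Net charge** over the N-domain with K/R = +1 and D/E = −1 (`signed`
  mode, the default). Histidine is not counted as positive and the
  N-terminal amino group contributes nothing. A `positive_count` mode counts
  K/R only; it exists because two rows of the reference table (PA_13510,
  PA_07000) print charges consistent only with that variant.
* **Hydrophobicity**: percent of residues in {G,A,V,L,I,M,F,W,P}, rounded
  half-up to an integer (reference tables print integers; Python's built-in
  banker's rounding would disagree on exact halves, so rounding is done
  exactly on rationals).
* **Ala-X-Ala motif**: alanine at −3 and −1 relative to the cleavage site;
  position −2 is unconstrained, and the downstream residues play no role.
* Ambiguity codes (X/U/B/Z) are rejected by default; in permissive mode they
  count as neither charged nor hydrophobic, since the property definitions
  enumerate standard residues only.

### Known discrepancies in the reference table

The packaged 29-row table reproduces the published per-peptide values with
the stated rules on every row except:

* six net charges (LP_23680, PA_18600, PA_13510, PA_10610, PA_14540,
  PA_07000). Four of them imply an N-domain ending at the last K/R *before*
  the hydrophobic core rather than the last K/R of the whole peptide — a
  boundary the stated last-K/R rule cannot express without a hydrophobic-core
  detector; the other two additionally omit the acidic subtraction and are
  matched by `positive_count` mode. The package implements the stated rule
  and documents the exceptions rather than chasing each row.
* PA_07000's printed length (38) exceeds its printed 37-residue sequence;
  the printed hydrophobicity (59 = 22/37) is consistent with the sequence,
  so the length is treated as a typesetting slip.

Group mean charges consequently differ from the published footer by ≤ 0.1
(computed 3.3/2.9 vs printed 3.4/2.8); lengths, hydrophobicities and
motif/helix percentages reproduce exactly.

## Group statistics

Group means are taken over the per-peptide values *as tabulated* — in
particular over the integer hydrophobicity percentages, since the reference
footer value 68.2 is exactly the mean of the printed integers (1363/20) —
and rounded half-up to one decimal. Motif and helix percentages round to
whole percent, the helix percentage only over peptides with a known flag.

`student_t` exposes both the pooled-variance Student's test
(`equal_var=True`, the default, df = n₁+n₂−2) and Welch's unequal-variance
test. On the reference table the published p-value row (0.34 / 0.25 / 0.99
for length / charge / hydrophobicity) is reproduced, within ±0.02, only by
the **Welch** variant (0.347 / 0.240 / 0.985 on computed properties); the
pooled test gives 0.49 for length. The regression tests and the acceptance
script therefore use `equal_var=False` for that row, while the qualitative
conclusion — no property separates the groups at α = 0.05 — holds in both
modes. Degenerate zero-variance comparisons use the conventions p = 1 for
equal means and p = 0 otherwise, logged loudly, so that constant triplicates
in screen confirmation behave predictably. No multiple-testing correction is
applied (three bare p-values, reported as such).

## Strain comparison

"Shared" means exact, case-insensitive amino-acid string equality between
predicted signal peptides; no identity threshold is applied by default
(an optional global-alignment identity mode supports near-match presence
queries). The percent-shared matrix is the Jaccard index × 100; an empty
strain set yields 0 off-diagonal and 100 on the diagonal, with a warning.
Summary statistics over a panel are the mean and sample SD (ddof = 1) of the
upper-triangle off-diagonal percents; a single pair has SD 0 by convention.

Heatmap ordering uses agglomerative average linkage on distance
100 − percent, written in-package rather than delegated to a linkage
library because the export contract demands deterministic output under
exact ties: equally distant cluster pairs merge in lexicographic order of
their sorted member labels, and the lexicographically smaller cluster goes
left. The exported matrix, not any particular rendering, is the contract.

## Plate screens

Relative improvement is `(mean(clone) − mean(control)) / mean(control)`.
Controls are averaged per plate by default (absorbing plate effects, e.g.
day-to-day intensity drift); a global-control mode exists because published
screens do not always state which normalization was used. Shortlist
thresholds are inclusive (≥ 20%, ≥ 50%), and raising the threshold can only
shrink the shortlist. Oversampling is picked colonies ÷ library size, with
a > 10-fold target so every library member is expected to be sampled.
Second-round confirmation requires ≥ 3 replicates per arm and declares a
candidate confirmed iff its mean exceeds the control's and the two-sided
t-test p-value is below 0.05.

## Construct design

Library fragments are `overlap_L + AGGAGG + spacer + [sp_cds + retained +
mature_cds] + overlap_R`. The spacer between the Shine–Dalgarno sequence and
the start codon defaults to 7 nt (a typical SD–start spacing; the source
screens state the RBS but not the spacing — configurable). Promoter and
terminator are modelled as vector-resident context, and the retained codons
fuse directly to the mature CDS (no linker). Signal-peptide DNA is sliced
from the source gene, never back-translated. `build_fusion` enforces that
the DNA parts translate exactly to the peptide record (the guard against
library cross-contamination), that the mature CDS ends in exactly one,
terminal, stop codon, and `assemble` verifies both 20 nt homology arms
base-by-base, reporting the first mismatch offset; landing sites must be
unique within the vector. Successful assembly conserves length:
`len(circle) = len(vector) + len(fragment) − 40`. GenBank output uses
1-based inclusive feature coordinates with parts labelled `overlap_L`,
`RBS`, `spacer`, `sp_cds`, `retained`, `mature_cds`, `overlap_R`.

## Synthetic data

Generators are pure functions of their parameters and a seed.

* **Peptides** follow the tripartite architecture: Met, then an N-domain of
  2–8 residues with K/R enrichment probability 0.4 whose final residue is
  forced to K/R (so the planted N-domain boundary is exact), a hydrophobic
  core of 10–18 residues from {G,A,V,L,I,M,F,W,P}, and a polar C-domain of
  4–8 residues; the −3/−1 positions are set to Ala with probability
  `p_axa` (default 0.5). Defaults bracket the length range (roughly 17–35
  residues) and motif frequency observed in lactobacilli repertoires.
  Confining K/R to the N-domain is a deliberate idealization: real C-regions
  occasionally carry a late K/R (several reference-table rows do), which is
  exactly the case where the operational N-domain rule and a structural
  N-region disagree. Passing tests on synthetic data therefore validate the
  bookkeeping, not that rule's biological adequacy.
* **Panels** plant pairwise Jaccard *constructively*: each strain holds a
  shared core of `c = 2sj/(1+j)` peptides plus `s − c` private ones, so the
  realized similarity equals the target exactly and similarity tests need no
  tolerance; infeasible integer combinations raise with the nearest feasible
  target. Optional blocks share nothing across blocks.
* **Plates** use multiplicative Gaussian noise truncated at zero
  (`reading = base · (1 + ε)`, ε ~ N(0, cv²)) — the simplest model
  consistent with nonnegative fluorescence units; no optical-density or
  growth structure is simulated.
* **Proteomes** append a random mature tail to each planted peptide and emit
  a matching prediction table, so parser → property pipeline must return the
  planted records identically.

None of the generators model codon usage, GC content, phylogenetic
structure, plate-position effects or heteroscedastic detector noise;
conclusions about those aspects of real data are outside what the test
suite demonstrates.

## Problem sizes and numerical choices

The test suite exercises panels up to 10 strains × 50 peptides against a
brute-force membership oracle (100 seeded trials), 200 seeded plate
simulations for shortlist power/false-positive behaviour, and a 155-member
synthetic fusion library for construct round trips — the scale of the
screened libraries themselves. Rounding of all reported one-decimal and
integer values is half-up, computed exactly on rationals. Property tests run
under a derandomized hypothesis profile so results are reproducible.
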