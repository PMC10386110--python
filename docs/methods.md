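# Methods

This note documents the models and procedures implemented in `oxymet`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the design choices made where more than one reasonable
option existed.

## Mass arithmetic and dereplication

**Monoisotopic masses.** Molecular formulas are parsed from Hill
notation and summed over a bundled element table
(`data/elements.csv`, CODATA/IUPAC monoisotopic values to ≥ 8 decimals;
¹²C exact by definition). Isotope labels, charges and parenthesised
groups are out of scope.

**Adducts.** Positive-mode ESI adduct m/z is
(M + shift)/z. Shifts carry the electron-mass correction — the +H shift
is the proton mass 1.00727646688 Da, and [M+Na]⁺ / [M+NH₄]⁺ / [M+K]⁺ are
the atom/group mass minus one electron (22.98922, 18.03383,
38.96316 Da). At a 0.001 Da matching tolerance the ~0.55 mDa electron
term is material, so it is never dropped. The default set
{[M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M+K]⁺} ships as an editable CSV; other
adducts can be added without code changes.

**The matching rule.** A feature (or aligned feature cluster) matches a
library record only when |Δ| < 0.001 Da **and** |Δ|/M·10⁶ < 10 ppm hold
simultaneously (strict inequalities) and the record's biological source
genus equals the producing strain's genus (case-insensitive exact
match; no taxonomy expansion). Both bounds are configurable
(`DerepParams`). The conjunction matters at the extremes: the Da bound
binds above ~100 Da, the ppm bound below. All passing records are
returned ranked by |ppm error| (rank 1 is the reported identity);
clusters with no passing record are reported as unknown. The ppm
denominator is the *library* mass — the tolerance is a property of the
assignment, and the alternative (observed-mass denominator) differs by
far less than rounding at these masses. When features carry neutral
(deconvoluted) masses, matching compares neutral masses directly;
adduct enumeration is applied only to raw-m/z input.

A note on printed reference values: published ppm errors for identified
metabolites (e.g. 0.534/0.703/0.541/0.814 ppm) imply library-stored
masses that differ from IUPAC-computed monoisotopic masses by ~10⁻⁴ Da.
Commercial databases' internal mass conventions are not reproducible
here; the package computes from formulas where they are known and
otherwise stores published masses verbatim, and reproduces the printed
ppm values to the precision the printed masses support (a mass printed
to 4 decimals quantizes the ppm error by ~0.2 ppm at 270 Da).

**The bundled library** (`data/compound_library_synthetic.csv`) is a
small open synthetic stand-in for a commercial natural-product database:
records named after published actinobacterial metabolites carry either a
literature formula or a published monoisotopic mass, and the
Decoyin/Baikalomycin entries are invented mass-decoys placed ≥ 0.05 Da
from every fixture feature so specificity is actually exercised.

## Feature alignment

Features from different samples are aligned by greedy centroid
clustering: sort by (mass, RT, sample), sweep once in ascending mass,
and attach each feature to the best open cluster within **5 ppm**
(consensus median mass) and **0.2 min** (consensus median RT) that does
not already hold a member from the same sample; ties break by smaller
mass gap, then smaller RT gap. The sort makes the result
permutation-invariant; greediness makes it deterministic and auditable,
which we preferred over density-based clustering for data of this size.
The defaults suit a high-resolution Q-TOF on an 18-min gradient and are
configurable; analyses in this package that mirror the study's 10-ppm
identification gate run the aligner at 10 ppm.

A single sweep can strand a fragment of one molecule as its own cluster:
an early outlier member opens a cluster whose consensus later members
avoid, even though the two final clusters sit within tolerance of each
other. A deterministic repair pass therefore merges mass-adjacent
cluster pairs whose consensus masses and RTs are mutually within both
tolerances and whose sample sets are disjoint, iterating to a fixed
point. Members that genuinely violate a tolerance against their
molecule's consensus (an RT draw ≳ 4 σ out) remain separate clusters —
correct behavior for the stated tolerances, and the reason a molecule
count can occasionally come out one high on noisy data. The
pairwise-agreement test quantifies the residual effect (≥ 99% Rand-type
agreement at 2 ppm noise); a split shows up as an extra presence-matrix
row, never as data loss.

## Presence analysis

The presence matrix is boolean: a cluster occupies a sample cell iff it
has a member from that sample with intensity above a floor (default 0 —
no intensity threshold is assumed; the floor exists for users who have
one). Design cells never observed in the data are all-false columns
with a warning, so silent design/data mismatches cannot occur.

`detect_only_experimental` returns clusters with zero presence across
control (C) columns and at least one presence elsewhere; it is undefined
(an error) for designs without both column groups. `induced_in_window`
returns clusters whose consensus RT lies in a closed window and whose
experimental presence count strictly exceeds the control count —
presence-count induction, not intensity fold-change, which is the
conservative reading when only detection events are trusted; an
intensity-based variant is deliberately not implemented.
`presence_activity_concordance` is the simple matching coefficient
(fraction of agreeing positions) between a presence row and a bioassay
call row over the same samples.

## Bioassays

The DPPH assay as performed is qualitative (pink → yellow). The package
operationalizes it as scavenging = 1 − A₅₁₇ˢᵃᵐᵖˡᵉ/A₅₁₇ᶜᵗʳˡ with a "+"
call at ≥ 20% scavenging. The 20% threshold is this package's own
operationalization (documented as such, configurable): well below any
clearly bleached well, well above plate-reader noise. Disk-diffusion
calls are "+" iff the inhibition zone exceeds the 6 mm disk diameter —
the disks themselves define the only defensible cutoff when none is
stated. Grids are (condition, fraction) × week with values {+, −, NA};
a missing measurement is NA, never "−".

## Mutation scanning

Weekly 16S consensus sequences are compared to the strain's **week-1
baseline** by pairwise Needleman–Wunsch global alignment (match +2,
mismatch −1, gap open −5, each further gap column −2, terminal gaps
free; delegated to Biopython's `PairwiseAligner` and verified against an
independent Gotoh dynamic program in the tests). For near-identical
amplicons of one gene this is equivalent to multiple alignment for
substitution calling and is far easier to verify. A column is called
only when both bases are unambiguous A/C/G/T, unequal, and trusted under
the optional per-position quality masks; gap and IUPAC-ambiguity columns
are never called.

Calls are re-expressed in the coordinates of an external reference
sequence (conventionally the *E. coli* 16S gene, GenBank NR_024570.1)
via a second alignment, and labelled with the containing hypervariable
region. The V1–V9 interval table (`data/variable_regions.csv`; V1 69–99
… V9 1295–1435 in *E. coli* numbering) is a conventional table, shipped
as an editable resource because published boundary sets differ by a few
bases. The reference itself is not bundled — it is an external database
record — so the synthetic generators produce their own coordinate
reference, and users supply the real one as FASTA.

## Distances and trees

**TN93.** The Tamura–Nei (1993) distance is computed in closed form
from the two transition proportions (A↔G, C↔T), the transversion
proportion, and empirical base frequencies averaged over both sequences;
no rate heterogeneity (no gamma), matching the bare model choice.
Columns with a gap or ambiguity in either sequence are deleted pairwise.
When any logarithm argument falls to or below zero the distance is
*undefined*, and the function raises `SaturationError` rather than
returning a number — saturated pairs should be visible, not silently
large. In the equal-frequency, equal-rate limit the formula collapses
onto Jukes–Cantor, which the tests assert to 1e-9.

**Neighbor joining.** Standard Saitou–Nei agglomeration with the
Q-criterion; joins tie-break on the smallest taxon indices, so output is
deterministic. Branch lengths use the usual update; a negative length
is clamped to zero with the residual moved to the sister edge,
preserving the pair's summed length. The final three lineages join at
an unresolved trifurcation (the tree is unrooted). On additive matrices
NJ is exact, and the tests verify that reconstructed tip-to-tip path
lengths reproduce the input matrix to 1e-8 and agree with scikit-bio's
independent implementation. Bootstrap support is out of scope.

## Synthetic data

The generators emulate the study design: conditions {C, O2, O3}, the
bi-weekly assay grid {1,3,5,7,9,11} (weekly 1–12 for sequence series),
fractions {biomass, cultural_liquid}. Defaults, chosen once as
realistic for this instrument class and organism group: mass error
multiplicative Gaussian with **sd 2 ppm** (how Q-TOF accuracy is
specified; leaves the 10 ppm gate comfortably wide, as in the sub-ppm
published identifications), RT jitter sd **0.05 min**, dropout
probability **0.1** per intended cell, GC content **0.70** (the
*Streptomyces*/*Rhodococcus* range is ~0.61–0.74), sequence length
1450 nt with 2% strain-vs-reference divergence. Feature classes:
constitutive (all cells), experimental-only (all non-control cells),
control-only, and induced (all experimental cells plus half the control
cells — enough control presence that dropout cannot plausibly erase the
class identity). Planted masses are kept ≥ 0.1 Da apart so the planted
clustering is recoverable.

Presets encode observed outcome patterns: `streptomyces_study` plants
the twelve named metabolites with their narrated presence (cells the
narrative does not mention are encoded absent — an editorial rule, not
data); `rhodococcus_study` plants 89 constitutive molecules of which
exactly one is library-identifiable; `rhodococcus_o3` plants a T→G
substitution inside V2 at week 10 and a C→T inside V9 at week 12, each
only in its own week's sequence; `streptomyces` plants none. Assay
generators draw absorbances/zones so the requested grid is reproduced
exactly under the default thresholds (positives at 45–75% scavenging or
8–18 mm zones; negatives at ≤ 8% or exactly 6 mm).

What the generators do **not** emulate — and what passing tests
therefore do not show about real data: chromatographic peak shapes and
co-elution, isotope envelopes and adduct redundancy within one run,
intensity drift and batch effects, chimeric or low-quality sequencing
reads, and real phylogenetic structure between strains. The pipeline's
behavior on those phenomena must be validated on instrument data.

## Numerical and degenerate-input conventions

Strict inequalities at both dereplication bounds; boundary-equal values
are rejected. Cluster consensus values are medians (robust to a single
outlier member). Empty feature lists align to empty cluster lists; an
empty composition has mass 0 and serves as the explicit unknown-formula
sentinel; zero-length or empty-overlap sequence comparisons are errors,
not zeros. All generator randomness flows from a single integer seed
through `numpy.random.default_rng`; identical configs produce
byte-identical CSV output.

## Problem sizes used in the checks

The bundled analyses run at the study's own scale: 12–89 molecules over
18–36 sample cells, 1000–1450 nt sequences over 12 weeks, and the
randomized suites use 30–200 instances (libraries ≤ 2000 records, trees
≤ 8 taxa, 100 seeded replicates for substitution recovery). These sizes
were chosen to exercise every code path at the scale the methods target;
all quantities reported by `scripts/acceptance.py` are recomputed from
scratch at run time.
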