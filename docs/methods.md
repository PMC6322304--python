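# Methods

This note documents the models, conventions and numerical choices behind
`pepdegradome`, and what the synthetic-data tests do and do not establish
about real data.

## Data model and conventions

All spans — peptide coordinates on precursors and topology segments — are
1-based and inclusive on both ends, the convention proteomics tables print;
conversion to 0-based half-open indexing happens only at the numpy boundary
(`_coords.py`). Protein identifiers are the FASTA header token before the
first whitespace, taken verbatim. Sequences may contain X and U; peptides
carrying them are retained for set algebra and PDP counting but excluded
from every AAindex-based computation (the flag travels with the record).
Missing intensities are explicit NaN, never zero, and no imputation is
performed anywhere.

A peptide is mapped by exact substring search against the proteome. A
peptide matching more than one site is flagged ambiguous: it contributes a
count to *every* matched site in the PDP matrices (each site is a distinct
start event) but appears *once* in peptide-level set algebra, because Venn
counts on sequences would otherwise be inflated by shared domains. Its
localisation and C-terminal calls use, respectively, the first match site
and the any-site rule (C-terminal if any site qualifies).

## Replicate filter and set algebra

Identification is heterogeneous between repeats, so a peptide counts as
present in a (compartment, condition) group only when its repeat evidence
covers at least `min_repeats` (default 2) of the biological repeats of that
group; duplicate identifications of one sequence are merged beforehand
(repeat sets unioned, per-repeat intensities averaged). "Shared between
conditions" is the intersection of the two *filtered* sets. The
shared-percentage dispersion is computed by restricting both sets to each
single repeat in turn and recomputing the shared fraction of the union; the
SD across repeats is reported.

A treatment-unique peptide counts as coming from a *new precursor* when none
of its matched proteins has any peptide in the control set. With an empty
unique set the fraction is undefined and reported as missing.

## Quantification

Fold change is log₂ of the ratio of mean intensities over observed repeats,
requiring at least `min_repeats` quantified values on both sides; otherwise
the peptide is flagged one-sided (`present_only_*`) or `not_quantified` and
excluded from correlations. The between-condition correlation is Pearson's r
on log₁₀ mean intensities of peptides quantified in both conditions (raw
scale available via a flag); the log transform is the package's choice —
XIC intensities are log-normally distributed and the correlation would
otherwise be dominated by the brightest peptides.

## Degradation patterns

Window i of an L-residue precursor covers residues
⌊(i−1)·L/n⌋+1 … ⌊i·L/n⌋ (n = 10 by default). Floor-based bounds make window
widths differ by at most one residue and tile 1…L exactly for every L and n,
including L < n (some windows are then empty; no special-casing). The 10 %
window is itself the device that tolerates peptide ladders, so no ladder
collapsing is applied before binning. Between-condition similarity is the
cosine of unit-sum-normalised rows with the median across shared precursors;
cosine is this package's own choice of statistic and is labelled as such in
reports (pattern comparisons in the source analyses were qualitative).

## Composition and the background set

Amino-acid frequencies are pooled over all residues of a set, non-standard
residues excluded from numerator and denominator. The composition null is a
background set sampled from precursor regions *not* covered by any observed
peptide: observed spans (all match sites) are masked, lengths are drawn with
replacement from the observed length distribution, and placements are
uniform over valid starts within contiguous unmasked runs — a sampled span
never touches a masked residue (checked exhaustively per run). The
between-set composition test is a per-residue 2×2 Fisher exact test
(residue vs. rest) with BH correction across the 20 residues; the source
analyses state a conclusion but not a test, so this choice is the package's
own and is labelled in output.

Terminal profiles take the first/last k = 5 residues (position 1 = terminal
residue, counting inward); peptides shorter than k are excluded and counted.
Information content is log₂20 − H(position) in bits.

## AAindex screen, clustering, enrichment

The per-peptide descriptor for an index is the arithmetic mean of
per-residue values — linear in composition, so it is computed as the
peptide's residue-fraction vector times the index matrix. Indexes with any
missing residue value are excluded before screening and the usable count is
reported, not hard-coded (published AAindex releases differ in how many
entries are complete).

The two-group test per index is a two-sided Mann–Whitney U. For groups of at
most 8 observations each the p-value is computed by exhaustive enumeration
of all C(n₁+n₂, n₁) labelings (correct under ties; the two-sided p is the
permutation probability of |U − n₁n₂/2| at least as large as observed).
Above that, the tie-corrected normal approximation
(`scipy.stats.mannwhitneyu`, asymptotic) is used — the screens that matter
run on hundreds to thousands of peptides per arm. Significance tiers follow
the raw p thresholds 10⁻⁵ / 10⁻¹⁵ / 10⁻²⁵ (nested by construction); BH
q-values are reported alongside everywhere.

Clustering: index profiles (vectors of per-peptide descriptors) are z-scored
across peptides, Ward linkage on Euclidean distance, tree cut to six
clusters. Columns are sorted lexically by index id first, which makes the
linkage independent of input column order; constant indexes carry no profile
and are excluded with a warning. The cluster containing the majority of the
canonical hydrophobicity scales (Kyte–Doolittle hydropathy, partition
coefficient, Jones hydrophobicity, Nozaki–Tanford transfer energy, Guy
partition energy) is labelled the hydrophobicity cluster. Cluster enrichment
among significant indexes is a per-cluster 2×2 Fisher test, BH-corrected
across clusters.

## Topology localisation

A peptide's location is the topology class covering a strict majority of its
residues (> half the peptide length, unannotated gaps counting against every
class); exact ties are `mixed`, precursors without records `unannotated`.
Mixed and unannotated peptides are excluded from the compartment × location
2×2 Fisher margins but their counts are reported. Odds ratios are oriented
so values > 1 mean cell-side over-representation and invert exactly when the
compartments are swapped.

## Antimicrobial triage

Predictor calls are score ≥ 0.5 for the CAMP and iAMPpred probabilities and
strictly > 0 for ADAM's real-valued score; consensus is the conjunction, and
peptides missing any score are reported as undetermined rather than negative.
Ranking is by consensus, then CAMP × iAMPpred probability product (ADAM's
score is not a probability and does not enter the product), then log₂FC;
log₂FC > 1 sets the up-regulated flag. The predictors' own
misclassification-probability filter has no reproducible definition, so it
is exposed only as an optional user-supplied exclusion list.

## The simulator

The generator emulates the study design the analyses assume: two
compartments × two conditions × three biological repeats. Defaults (all
overridable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| proteins | 1,000; length ~ LogNormal(μ=5.4, σ=0.45), min 60 aa | ≈ 250 aa mean, a typical proteome length scale |
| peptides per compartment | 2,000; length ~ round 𝒩(15, 4²), clipped 7–40 | endogenous peptides centre near 15 aa |
| C-terminal start bias | 2× within the last 50 aa | degradomes over-represent protein termini |
| hydrophobicity bias δ | secretome 0.5, cell 0 | start weights ∝ exp(δ·z) of the forward 15-residue mean Kyte–Doolittle hydropathy, read from the same aaindex file the analyser uses |
| topology bias β | cell 3, secretome 1 | inside-segment residues up-weighted in the cell compartment |
| membrane proteins | 30 % with alternating loop(≈40 aa)/helix(21 aa) architectures | architectures are assigned independently of sequence, so β and δ do not confound each other |
| treated extras | +5.5 % (cell), +2.3 % (secretome); 27 % of extras from a 5 % held-out new-precursor pool | held-out proteins have zero control sampling weight, making "new precursor" unambiguous in truth |
| effects | 20 % of shared peptides get log₂FC ~ 𝒩(1.0, 0.25²) | detectable but not dominant treatment response |
| ladders | probability 0.3; trim 1–3 residues from one end; child intensity × 0.75^trim | "non-identical but similar" peptide families |
| detection / intensity | Bernoulli(0.9) per repeat; base ~ LogNormal(13.8, 1.0); repeat noise e^𝒩(0, 0.25) | realistic dropout and XIC spread |

All randomness flows from one `numpy` Generator seeded by `rng_seed`;
identical seed and config give byte-identical output files. Synthetic AMP
scores are noisy readouts of a charge + hydropathy latent propensity
(the two axes sequence-based AMP predictors weight most), which puts the
consensus rate at a few percent of peptides. Synthetic AAindex collections
for clustering tests are built from latent residue factors per family, with
the hydrophobicity family anchored on the Kyte–Doolittle scale.

What the simulator does **not** emulate: identification error (all emitted
peptides are correct), intensity interference and missingness-not-at-random,
PTMs, isoforms and shared-domain ambiguity, protease specificity (cleavage
sites are positionally biased but sequence-independent apart from δ), and
correlated repeats. Passing the closed-loop tests therefore shows the
*analysis* is correct and well-calibrated under the stated generative
assumptions — not that those assumptions hold for any particular instrument
or organism.

## Test and acceptance problem sizes

The statistical primitives are verified against independent enumeration
oracles: Mann–Whitney against exhaustive label permutation for all group
sizes ≤ 6 (with and without ties), Fisher two-sided p against direct
hypergeometric tail enumeration over all 2×2 tables with cells ≤ 10
(margins ≤ 20), and PDP binning against a per-residue brute-force scan for
all L ≤ 200. Parameter recovery runs the full closed loop at the default
conditions over 20 seeds per scenario: the δ = 0.5 secretome shift must be
flagged (all reference hydrophobicity indexes at p < 10⁻⁵, secretome
direction) in ≥ 95 % of seeds, a matched δ = 0 null must yield zero sigAA
indexes in ≥ 95 % of seeds, the injected log₂FC is recovered with
|bias| ≤ 0.1, and the β = 3 inside bias must re-emerge as cell-side
over-representation in ≥ 95 % of seeds. Conservation and normalisation
invariants run on 100 randomized fixtures. These sizes keep the whole suite
at roughly two minutes on one CPU.

## Known limitations

* The bundled aaindex file is a miniature (two published scales plus
  clearly-labelled synthetic entries) sufficient for defaults and tests;
  full-scale screens need a user-supplied `aaindex1` file.
* `locate_peptides` is a straightforward per-protein substring scan —
  adequate for thousands of peptides, not for proteome-scale motif searches.
* PDP similarity has no canonical reference statistic; cosine on normalised
  rows is a reasonable but arbitrary choice, and values are near 1 whenever
  two conditions share most peptide events.
* The report bundle is TSV + JSON (+ optional PNG); there is no HTML report.
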