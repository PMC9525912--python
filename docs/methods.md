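# Methods

This note documents the models implemented in `msomics`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that matter.

## Mass chemistry (`msomics.chem`)

Formulas are element→count maps over an embedded monoisotopic mass table
(IUPAC/CODATA values for H, C, N, O, S, P, Cl, Na, K). Stable-isotope
labels are distinct symbols (`[13C]`, `[2H]`, `[15N]`) carrying the heavy
isotope's mass, because spiked internal standards are isotope-labeled
compounds (e.g. ¹³C₂,2,2-²H₂,¹⁵N-glycine = `[13C]2H3[2H]2[15N]O2`) whose
masses must reflect the label. The tests cross-check the table against a
hand-entered literal table and against pyteomics.

Derivatization shifts are per-site neutral deltas computed by formula
arithmetic: dansyl = dansyl chloride − HCl = C12H11NO2S (+233.051050 Da),
O-BHA = C7H9NO − H2O = C7H7N (+105.057849 Da). Both the amide (carboxyl)
and oxime (ketone/aldehyde) O-BHA products have the same net shift, so a
single site count suffices. Site counts live in the compound library
rather than being predicted from structure; this keeps the package free
of cheminformatics dependencies and reflects that multi-amine compounds
may derivatize partially — the matcher therefore tries every site count
from 1 up to the library value. Ions are positive-mode protonated species
([M+zH]z+, proton mass 1.00727646688 Da); small-molecule work here is
MH+ only.

## Metabolite identification and quantification (`msomics.metabolomics`)

Matching accepts the candidate with minimal |ppm| when |ppm| ≤ 5.0. The
bound is inclusive ("threshold" semantics), with an absolute epsilon of
1e-9 ppm so that a feature sitting exactly on the boundary is not
rejected by floating-point rounding. Ties break toward fewer
derivatization sites, then lexicographic compound id. Unmatched features
are returned with `accepted=False` rather than dropped. MS2 validation
is an input annotation (`validated` column) and is never computed.

Concentration is linear in the analyte/IS intensity ratio:
`(I_a / I_IS) × n_IS / m_protein`. A missing or zero IS intensity yields
NaN, not an exception. Protein mass per sample comes from the design file
(protein-assay value); when absent it defaults to 1.0 mg with a warning,
which preserves all relative comparisons. Because the core standards-manifest
columns (is_id, formula, amount, zone, scheme) cannot express the
exact-analogue link for the TCA track, the manifest accepts an optional
`target_compound_id` column; O-BHA compounds without an exact
labeled analogue fall back to the malate-targeted IS.

Differential testing is a per-compound two-sided pooled-variance Student
t-test (Welch by flag) with log2 fold change of group means; p-values are
raw by default, with Benjamini–Hochberg q-values behind a flag. Compounds
with a zero group mean get an infinite fold change and are flagged out of
plots; groups with fewer than two finite values yield missing statistics.

## Histone PTM quantification (`msomics.histone`)

The level of a modification is area(modified)/area(unmodified) — a ratio
that may exceed 1, reported as a "percentage" in the field's usage. A
bounded fraction-of-total mode (modified/(modified+unmodified)) is
available by flag for users who expect percentages ≤ 100%. With a
heavy-arginine SILAC histone standard present, the reported level is the
ratio of ratios r_light/r_heavy. Since the heavy standard is one
preparation shared by all samples, any multiplicative peptide-specific
factor (ionization efficiency, digestion yield) applies equally to both
channels and cancels exactly in cross-sample fold changes — this is an
algebraic identity, and the tests assert it at machine precision. Only
ratios enter computation; absolute heavy areas never do, because the
spiked amount differs between preparations. Co-eluting positional isomers
(e.g. H3K18/23ac) are treated as a single modification label. The
replicate unit for testing is the injection (technical replicate),
pooled-variance t-test as above.

## Isotope tracing (`msomics.tracing`)

The natural isotopologue envelope of a formula is the convolution of
per-element unit-mass-shift distributions. The default correction is
carbon-only (¹³C at 1.07%), the dominant term for CHNO metabolites and
peptides; a full CHNOS mode adds ²H, ¹⁵N, ¹⁷O/¹⁸O and ³³S/³⁴S/³⁶S.
Isotope-labeled atoms are fixed and contribute no spread.

Correction solves A·x = observed, where column j of A is the natural
envelope of the species with j tracer carbons fixed heavy, shifted up j
mass units; x (isotopologue fractions 0…n) is solved with non-negativity
(scipy NNLS) and normalized to sum 1. The non-negativity constraint is
the default because negative isotopologue fractions are unphysical; an
unconstrained least-squares mode exists for diagnostics. Near x = 0 the
constraint introduces a small downward bias on neighbouring components
under multiplicative noise (measured ≈ 0.004 absolute for a C40 species
at 5% per-peak noise); the acceptance script reports the mean absolute
bias across species and planted fractions, which stays well below 0.01.
A truncated envelope (K smaller than the label shift, or too small for a
stable solve) is rejected with advice to measure more isotopologues.

Two enrichment readouts are returned: the labeled/unlabeled intensity
ratio I(M+n)/I(M+0) — the literal "incorporation rate" — and the labeled
fraction, corrected by default (`--no-correct` reproduces the literal
uncorrected computation). When only M+0 and M+n are populated and
correction is off, fraction = ratio/(1+ratio) exactly. Histone tracing
uses no SILAC heavy standard. The mass shift for serine-derived methyl
marks (CD₂ vs CD₃ transfer) is deliberately input data (`label_shift`
column), not a constant, since it depends on the one-carbon chemistry of
the experiment.

## TMT proteomics and SAM (`msomics.proteomics`)

PSMs are accepted with posterior error probability strictly < 0.05;
protein groups are retained only with at least one accepted unique
peptide (shared peptides of retained groups still contribute intensity).
Aggregation is the channel-wise sum of reporter intensities per protein
group (a median-per-channel mode exists); channel totals are equalized by
default to remove labeling/loading imbalance, then log2-transformed.
All-zero rows are flagged non-quantifiable.

The SAM statistic is d = (mean_b − mean_a)/(s + s₀) on log2 data, with s
the pooled two-sample standard error and s₀ = 0.32 in log2-intensity
units — the value equals log2(1.25) to two decimals, i.e. a ~1.25×
fold-change cutoff. s₀ regularizes small-variance proteins (zero
within-group variance is handled, no division by zero). Permutations
draw from the distinct balanced group-label assignments: all of them when
there are no more than `n_perm` (a 3v3 design has 20), otherwise a
uniform sample without replacement under the given seed. The estimated
FDR at cutoff c is median over permutations of #{|d*| ≥ c} divided by
#{|d| ≥ c}; the decision cutoff is the smallest observed |d| whose
estimated FDR is at or below the target, and testing is two-sided with a
symmetric cutoff (asymmetric Tusher-style cutoffs are out of scope). The
exact numerical behaviour of other SAM implementations (e.g. their s₀
placement or q-value computation) is not claimed; this formulation is
documented here and fixed by the test suite. Calibration measured by the
tests: under a 1000-protein null (3v3, per-channel sd 0.2, FDR 0.01) the
false-positive proportion averages ≈ 0.0005 over 20 seeds, and
sensitivity for 50 planted 1-log2-unit effects averages ≈ 0.98.

## Synthetic data (`msomics.synthetic`)

The generators emulate the study design the analyses target: three
macrophage states (M0/M1/M2), eight injections per pooled sample,
TMT6 with channels 126/127 → M0, 128/129 → M1, 130/131 → M2, internal
standards spiked at 1 nmol (10 µl of 0.1 mM), lognormal multiplicative
intensity noise (CV 10% for peak areas, 5% for isotopologue peaks — unit
median, so planted values are medians), Gaussian m/z jitter of 1 ppm sd,
and planted 2-fold group effects. The metabolite library holds 112
compounds by default — a dozen real amino acids and TCA intermediates
plus randomly composed amine-bearing formulas, rejected if any
derivatized m/z falls within 30 ppm of an existing entry so that planted
±3 ppm features resolve unambiguously. Planted tracer enrichments follow
the magnitudes the tracing experiments are designed around: ~1.5% ¹³C₃
pyruvate and ¹³C₂ succinate, ~15% ¹³C₃ lactate, 15–25% ¹³C₂-acetyl on
H3K18/23 across states. `forward_envelope` is the brute-force forward
model (mixture of shifted natural envelopes) that the correction must
invert, and doubles as the oracle in the tests.

What the simulators do **not** emulate: chromatographic peak shapes and
integration error, retention-time drift, co-eluting isobaric
interference, TMT reporter isotope impurity, ratio compression from
co-isolation, missing values from low-abundance censoring beyond the
additive floor, and biological replicate variance (replicates are
technical, as in the pooled-sample design). Passing recovery tests on
these inputs therefore demonstrates the correctness of the quantification
arithmetic and statistics, not robustness to every artifact of real
acquisitions.

All generators draw from a single `numpy.random.default_rng(seed)` and
write TSVs with a fixed float format, so output is byte-identical under a
fixed seed. Stochastic tests either fix one seed or sweep seeds 1–20 and
assert a pass count (≥ 18/20) or a mean; every such test names its seeds.

## Problem sizes

The default test and acceptance runs use the study-scale inputs described
above (112 compounds × 16 injections; 15 modifications; 1000 proteins ×
6 channels with 20 permutations for 3v3 designs; envelopes to M+n+3).
The full suite runs in about half a minute; the acceptance script in a
few seconds.

## Known limitations

* Matching assumes charge 1 (MH+) unless the feature says otherwise, and
  ignores retention time except through the IS zone assignment.
* In-source fragments (e.g. the MH+−45 loss of dansylated arginine) are
  representable only as library annotations, never computed.
* The natural-abundance correction models the measured ion's formula as
  given; derivatized ions must be entered with the tag atoms included if
  the correction is to account for them.
* The SAM permutation null is limited by the number of distinct balanced
  assignments (20 for 3v3, 6 for 2v2); with so few permutations the FDR
  estimate is coarse, which makes the procedure conservative in practice.
* Absolute quantification is only as good as the IS manifest: compounds
  normalized against a zone surrogate (rather than an exact labeled
  analogue) inherit that surrogate's response, so their concentrations
  are estimates, not calibrated values.
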