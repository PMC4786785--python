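# Methods

`mutscape` implements the complete data-analysis chain of a plate-based
site-saturation mutagenesis screen of a small enzyme — here a 62-residue
tautomerase monomer with a catalytic N-terminal proline — whose outputs are
*mutability landscapes*: 20 x 61 matrices of one measured property (soluble
expression, relative specific activity, or enantiomeric ratio) for every
single amino-acid substitution at positions 2..62.  No screening raw data
are distributed with such studies, so a first-class synthetic-data module
emulates every instrument export with known ground truth; the analysis
modules never see that truth.

## The screen model

**Collection.** The mutant collection covers at least 15 of the 19 possible
substitutions at every position from Ile-2 to the C-terminal Arg-62
(Pro-1 is excluded: it is the catalytic residue and its mutants process
incorrectly).  The default collection size is 1,040, i.e. 90% of the
61 x 19 = 1,159 possible singles.  `synthdata.make_collection` draws the
guaranteed minimum per position first, then fills uniformly from the
leftovers; it is deterministic under its seed.

**Progress curves.**  Activity wells report substrate depletion as an
absorbance time series, `A(t) = eps * l * c(t)`.  The generator uses a
two-phase model — linear decrease at the true rate until the substrate is
exhausted, then flat at zero — rather than an integrated first-order form.
The analysis consumes only the initial linear section, and the piecewise
model makes ground-truth slopes exact, which lets recovery tests assert at
1e-9 rather than at a model-mismatch tolerance.  Default assay geometry:
500 μM substrate, 40 min at 60 s intervals (the acetaldehyde-addition
screen), a second preset with 650 μM / 80 min (butanal addition), and a
40 s / 0.26 s preset (tautomerase).  The extinction coefficient
(10 mM⁻¹cm⁻¹) and microplate path length (0.29 cm, the height of 100 μl in
a 96-well plate) are arbitrary configuration constants: relative activities
are provably invariant to them because the AU-to-concentration factor
cancels in the wild-type ratio (tested to 1e-12).

**Controls.**  Every plate carries its own wild-type (WT) wells, which share
one true specific activity, and empty-vector (EV) wells carrying only the
background depletion rate.  Controls are used exclusively within their own
plate; permuting plates cannot change any result.

**Rate extraction.**  The linear section is delimited by a depletion cap:
only the leading stretch where at most 20% of the initial signal has been
lost is eligible.  By default that whole stretch is fitted in a single OLS
pass.  A fixed-length sliding window with best-R²/earliest-tie selection is
available (`window_points`) for curves with early nonlinearity, but it is
not the default: on simulated plates at the default noise level, per-well
max-R² selection over short windows showed a selection bias of about +3%
and a seed-to-seed spread more than three times larger than the full-stretch
fit (worst seed 13% vs 5% error on a 3.5-fold variant).  Duplicate wells
are averaged pointwise at the trace level before fitting, mirroring how an
averaged depletion curve is analysed once.

**Specific and relative activity.**  The background rate (mean of the EV
wells' initial rates) is subtracted from every well on that plate; the
corrected rate converts to an activity U = μmol min⁻¹ through the well
volume, and to U mg⁻¹ through the enzyme mass delivered by the CFE aliquot
(gel-derived concentration x CFE volume fraction, default 40% of a 100 μl
well).  A corrected rate at or below zero becomes the `zero_activity`
state rather than a negative number.  Relative specific activity is
(U_mut x mg⁻¹)/(U_wt x mg⁻¹) with the reference being the arithmetic mean
of that plate's WT specific activities (median behind a switch).

**Densitometry.**  Each gel carries calibration lanes of 0.5/1/2.5/5 μg
purified WT protein.  An OLS line with free intercept (background staining
produces a nonzero blank) is fitted per gel and inverted for the sample
lanes of that gel only.  The lane load divided by the CFE volume equivalent
loaded (default 1 μl) gives mg ml⁻¹ in the extract.  Concentrations below
the 0.5 mg ml⁻¹ detection limit are flagged `below_lod`; negative
inversions clip to zero with the same flag.  In per-substitution averages
(the 20-bar summary of the expression landscape) `below_lod` cells count
as zero: they are a floor category, not missing data.

**Chiral HPLC.**  The four stereoisomers of the 2-ethyl γ-nitroaldehyde
product elute as four peaks.  The generator writes a sum of four Gaussians
(areas = total area x stereoisomer fractions) on a flat baseline at default
retention times 4.5/5.5/7.0/8.5 min with σ = 0.08 min.  Analysis estimates
the baseline as the 5th percentile of the signal, detects apexes by
prominence, bounds each peak at the minima separating it from its
neighbours (trace edges outside) and integrates by the trapezoid rule;
against adaptive quadrature of the analytic mixture the error is below
0.1%.  Peaks are labelled by disjoint retention-time windows.  The two syn
peaks carry absolute labels (2R3S, 2S3R) because reference material fixes
their elution order; the anti enantiomers keep elution-order labels
`anti-1`/`anti-2` and no configuration is ever invented for them.
d.r. = syn:anti over the total, e.r. = 2R3S:2S3R over the syn pool, both
summing to 100, stored at full precision and reported as integers.  A total
area under `min_total_area` yields the `insufficient_signal` state.
An enantio-inversion is a valued cell whose majority syn enantiomer differs
from the wild type's; exactly 50:50 has no majority.

**Landscapes.**  Matrices are amino-acid rows (alphabetical by default,
configurable) by positions 2..62, with exactly one `wild_type` cell per
position; for the relative-activity metric WT cells carry 1 by
construction.  Cells not in the collection manifest — and manifest cells
for which no record arrived — are `absent`.  State counts always sum to
20 x 61, and the long-form CSV export round-trips bit-exactly.  Hotspots
are valued cells above a fold threshold (default 5); the
neutral/beneficial/detrimental classification defaults to >2 / <0.5, a
package choice since "neutral" is conventionally left unquantified.

**Library design.**  Degenerate codons are expanded by enumerating all
concrete codons and translating with the standard genetic code; stops are
excluded from protein-variant counts but reported (NNK encodes the amber
stop).  The default focused library — {H,I,L,M,V} at 6, {A,D,E,Q} at 33,
NNK at 45, {F,V,L,A} at 50 — counts 5 x 4 x 20 x 4 = 1,600 protein members.
Collection coverage is 100 x |manifest| / (61 x 19), with the rounded
integer reported alongside full precision.  The multi-mutant predictor is
an explicit heuristic (fold-changes multiply; enantiomer preferences add on
log-odds relative to the WT baseline) and tags its output with the model
name; it is a prediction, not a measurement.

**Stoichiometry.**  Preparative bookkeeping uses IUPAC standard atomic
weights and formulas derived from the products' systematic names.
Catalyst loading is 100 x [catalyst μM] / (1000 x [substrate mM]); molar
yield divides the isolated (optionally contaminant-corrected, w/w) mass by
the molar mass and the theoretical mmol of the limiting substrate.

## Noise model and what the tests show

Noise is homoscedastic Gaussian on each raw signal: absorbance (default
0.005 AU), gel band intensity (default 1% of the gain), chromatogram
detector units.  This is the simplest model that exercises every estimator;
magnitudes are configuration because plate-reader and densitometry noise
levels are rarely published.  Real data additionally show drift, mixing
transients, heteroscedastic photometric error, gel smearing and tailing
peaks — none of which are emulated — so passing recovery tests demonstrate
correctness of the estimators under the stated model, not robustness to
every instrument artefact.  The two-phase kinetic model likewise idealises
enzyme progress curves; an exactly known linear section is what makes
1e-9-level slope assertions meaningful.

## Numerical choices and degenerate inputs

* Flat traces (zero signal variance in the fit span) return rate 0 with
  R² reported as 0.
* The depletion cap falls back to the first `min_points` samples (default
  8) when fewer points qualify.
* Calibration requires ≥3 distinct loads; identical loads are an error,
  not a silent zero-division.
* Sliding-window ties in R² (within 1e-12) resolve to the earliest window.
* Chromatograms with no peak above the prominence threshold yield an empty
  peak list; ratios then report `insufficient_signal`.
* All generators take explicit seeds and are bit-deterministic under them;
  orchestrated runs derive sub-seeds below 2^31 from one master seed.

## Problem sizes

The shipped defaults describe the full screen (1,040 variants, ~26 plates,
duplicate wells, 26-lane gels).  The test suite and the acceptance script
run the same code paths on one-to-few-plate problems (70–1,040 variants,
single plates for recovery checks), sizes chosen so the whole suite runs in
seconds while still exercising every stage end to end.

## Known limitations

* No statistical inference across replicates (the screen reports n=2/n=4
  means); duplicate spread is folded into the trace average, not propagated.
* Overlapping chromatographic peaks are split at the valley between apexes;
  no deconvolution is attempted.
* The additivity predictor ignores epistasis by construction.
* Michaelis–Menten parameters are out of scope: assays run at a fixed
  concentration near 2 x K_m, and only initial rates are used.
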