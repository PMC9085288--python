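# Methods

This note records the models, conventions and numerical choices behind
`halonet`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Mass arithmetic and the adduct convention

All masses derive from the static isotope table in
`halonet/elements.py` (NIST-style atomic masses and natural
abundances for C, H, N, O, S, Na, Cl, Br; overridable from a TSV via
`ElementMassTable.from_tsv`). Monoisotopic mass is the
lightest-isotope sum.

Adduct m/z uses **neutral-atom addition**:
m/z = (M + m(added) − m(removed)) / z with m(H) = 1.00783 and
m(Na) = 22.98977, no electron-mass correction. This is the convention
behind printed "calcd" values in the marine natural-products
literature: it reproduces, e.g., [C₂₀H₃₀O₃+H]⁺ = 319.2273 and
[C₂₂H₃₄O₄+Na]⁺ = 385.2355 exactly, whereas proton-mass arithmetic
gives 319.2268. The physically strict mode (subtract z electron
masses) is available via `electron_correction=True`. A handful of
published values differ from our table by 0.0001 Da (legacy atomic-mass
rounding in the source literature); the package's reproduction
tolerance of ±0.0005 Da absorbs this and no value is special-cased.

## Formula search

Bounded nested enumeration over per-element counts (heavy elements
outermost) with two-sided mass pruning, so the search is exhaustive
within bounds. Candidates must fall within the ppm tolerance
(default 5) and have RDBE ≥ 0, where RDBE counts halogens as
valence-1: RDBE = C − (H+Cl+Br)/2 + N/2 + 1. Ordering is
deterministic: |ppm error| ascending, ties by RDBE descending, then
Hill string. Default bounds are C ≤ 40, H ≤ 80, N ≤ 4, O ≤ 12,
Br ≤ 4, Cl ≤ 3; the annotation pipeline narrows Br/Cl to the counts
the isotope cluster supports, which is what makes 5-ppm assignment of
~400-Da halogenated ions essentially unambiguous.

## Isotopologue patterns

Patterns are computed by exact convolution of per-element multinomial
distributions (terms below 1e-12 probability dropped), then aggregated
into isotopologue lines in 0.3-Da bins (intensity-weighted mean m/z).
The 0.3-Da width merges lines that a QTof reads as one (e.g. ⁸¹Br at
+1.998 with ¹³C₂ at +2.007) while keeping the +1 ¹³C line (+1.003)
distinct from the +2 halogen line. `integer_ratio` divides intensities
by the smallest retained line and rounds half-to-even — the convention
that renders the Br₂Cl halogen pattern (3.30 : 7.48 : 5.18 : 1) as the
conventional 3 : 7 : 5 : 1.

## Halogen classification

An observed cluster is collapsed to its A/A+2/A+4… series: each peak's
offset from the anchor (first peak) is assigned to the nearest even-Da
index if it lies within 0.1 Da of it; peaks off the 2-Da grid — ¹³C
satellites at +1.0034 — are excluded from the series rather than
invalidating the cluster, because they carry carbon-count information,
not halogen-count information. Each (nBr, nCl) hypothesis on the grid
(defaults Br ≤ 4, Cl ≤ 3, covering all reference compounds) is scored
by the cosine between the observed series and the halogen-only
theoretical pattern, zero-padded to equal length; a chi-square variant
is available behind `metric="chi2"`. Ties break toward fewer total
halogens, so a single-line cluster classifies as halogen-free. The
literature gives no tolerance for calling a printed ratio; we treat a
top score ≥ 0.95 as a confident call (the `halogen_score_min` config
default), a free choice documented here. A sweep test shows the Br₂Cl
call is robust to the ¹³C envelope up to at least C₂₅.

## Modified cosine and network construction

Spectra are square-root transformed and unit-normalized. Candidate
peak pairs match directly (|Δm/z| ≤ 0.02 Da) or shifted by the
precursor difference; a one-to-one matching is selected greedily by
descending intensity product (ties to the smaller m/z deviation). An
optimal-assignment mode (`exact=True`, Hungarian algorithm) exists and
is held to agreement with an exhaustive brute-force enumeration in the
test suite; on realistic spectra the greedy and exact scores coincide,
and the greedy path also agrees peak-for-peak with an independent
implementation (matchms) in a cross-check test.

Network parameters mirror standard molecular-networking practice and
are all configurable: precursor merge tolerance 0.002 Da, fragment
tolerance 0.02 Da, minimum peak intensity 50 (non-strict: intensity
exactly 50 is kept), cosine threshold 0.7, minimum 4 matched peaks per
edge, mutual top-10 edges per node, components capped at 100 nodes by
discarding their weakest edges. The minimum-matched-peaks rule is
applied to network edges (no spectral-library search is bundled, so a
library-side interpretation does not arise). Before scoring, peaks
within ±17 Da of a spectrum's own precursor are removed — the standard
precursor-window filter; without it, the Br/Cl isotope clusters that
wide-isolation QTof acquisition co-transmits into MS/MS spectra make
any two dibrominated ions look alike under shift matching. Families
(components with ≥ 2 nodes) are labelled F1, F2, … by descending size,
ties by the smaller minimum precursor m/z.

Co-eluting nodes (RT within 0.2 min) whose precursor m/z differ by the
¹³C spacing (1.00336 Da) or the ⁸¹Br–⁷⁹Br spacing (1.99795 Da), or
small multiples, are grouped as isotopologues of one metabolite; the
lowest-m/z member represents the group and the group's precursor list
doubles as the observed isotope cluster.

## Neutral-loss chains

The loss table (packaged TSV, editable) carries exact masses computed
from the loss formulas: H₂O 18.0106, HBr 79.9262, HCl 35.9767, ketene
42.0106, NaOH 39.9925, Br 78.9183, C₂H₆ 30.0470,
1-bromopropa-1,2-diene 117.9418. Chain search is breadth-first over
loss sequences to depth 4 (the deepest chain the reference data needs:
NaOH, then two H₂O, then ketene). A step counts only if an observed
peak lies within the fragment tolerance of the expected m/z, so
expected m/z is strictly decreasing; when a precursor composition is
known, each loss must stay subformula-valid and NaOH is only offered to
sodium-containing ions. Among chains of equal (maximal) length the one
with the smallest summed |error| wins. A +42.0106-Da precursor
difference between two nodes additionally flags the heavier as a
putative acetylated derivative of the lighter.

Annotation confidence tiers are monotone in the evidence: removing
fragment peaks can demote A → B (chain lost) or leave B; removing the
isotope cluster caps the tier at C. Equal-formula reference hits are
always all reported.

## Synthetic data

The generator emulates the statistical structure the analysis relies
on, not chromatography or instrument physics. Each family derives from
one scaffold compound of the reference table; members are the base, an
acetylated analog (+C₂H₂O), a dehydro analog (−H₂O, one ladder step
shorter) and an alternative-adduct species — variations that preserve
most of the fragment ladder. All members share six family-specific
"skeleton" fragment peaks drawn deterministically from the base
composition (the common-substructure fragments real congeners share);
this, plus the ladder, is what makes intra-family modified cosine high
and cross-family similarity low.

Per spectrum: the precursor isotope cluster follows the exact
theoretical isotopologue pattern of the ionized composition (pruned at
1 % relative); one fragment sits at every loss-chain prefix with
intensity log-uniform in [0.05, 1] of the base peak; skeleton peaks are
log-uniform in [0.1, 0.6]. Noise defaults: Gaussian m/z jitter
σ = 0.001 Da (~2.5 ppm at m/z 400, a calibrated QTof), log-normal
intensity scatter σ = 0.3, five uniform contaminant peaks per spectrum
over the 100–1500 scan range at 10²–10⁴ counts, intensities clipped to
[10², 10⁶]. One integer seed drives every draw, and the MGF writer
uses fixed float formats, so output is byte-identical across runs.

What this does **not** emulate — and therefore what passing tests do
not show about real data: chromatographic peak shape and co-elution
artifacts, DDA duty-cycle effects (missed or chimeric MS/MS), detector
saturation, in-source fragmentation, and real fragmentation chemistry
beyond the loss ladder plus skeleton-peak abstraction. Family recovery
at ARI ≥ 0.9 on this generator demonstrates the correctness of the
networking machinery under the stated noise model, not a performance
claim for arbitrary extracts.

Problem sizes in the default test and acceptance runs — 3 families ×
4 members × 2 extracts, 20 seeds for the recovery sweep, 200 random
pairs for the cosine oracle — were chosen as the smallest
configurations that exercise every code path with non-trivial
statistics.

## Degenerate inputs and tie-breaks

Empty spectra score 0 and are excluded from networking; an
all-peaks-filtered spectrum is valid and empty; an empty loss chain and
an empty candidate list are valid annotation outcomes; an empty network
exports valid GraphML and headers-only tables. All orderings that the
underlying science leaves unspecified (candidate ranking ties, family
label ties, greedy matching ties) have documented deterministic
tie-breaks so identical inputs give identical outputs.

## Known limitations

* Formulas only — no structures, no stereochemistry: equal-formula
  isomers are indistinguishable by design.
* No bundled spectral library; reference matching is by elemental
  composition, not spectral similarity to authentic standards.
* The halogen classifier reads 2-Da-spaced clusters; it does not
  resolve fine isotope structure within a nominal bin, and sulfur
  (whose +2 isotope could mimic a weak Cl signal) gets no special
  treatment.
* mzML support reads centroided MS2 scans only; vendor raw formats and
  profile data are out of scope.
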