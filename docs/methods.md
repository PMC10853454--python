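# Methods

## Digestion model and terminus logic

A protease is a data-driven rule: a set of recognised residues, a side
(cut C-terminal or N-terminal to the recognised residue) and an optional
veto set for the residue following the bond. The bundled registry defines
Trypsin/P (after K/R, no proline veto), plain trypsin (after K/R, not
before P), LysC (after K), chymotrypsin (after F/W/Y/L) and AspN (before
D). Chymotrypsin's residue set and AspN's restriction to aspartate follow
the common search-engine definitions; both are plain configuration, not
hard-coded behaviour.

Coordinates are 1-based and inclusive; a cleavage *site* p denotes the
bond between residues p and p+1, so "site 64" means the bond 64|65. Full
digestion produces maximal runs between cut points merged across at most
`missed_cleavages` internal cuts; semi-specific digestion anchors one
terminus at a cut point or protein terminus and slides the other freely
(same missed-cleavage accounting). Sequences containing letters outside
the 20 standard residues are rejected at construction with the offending
position, because downstream fragment masses would be undefined.

Default search-style bounds where a caller gives none: 2 missed
cleavages, peptide length 6–40 — ordinary shotgun settings; both are
arguments everywhere they matter.

## Site calling

Each peptide is judged against its own digestion protease only (the
per-protease experiments are independent), yielding zero, one or two
non-canonical termini. Evidence is grouped by (protein, site); a call is
concordant when both product sides are represented, and by default only
concordant calls are reported (`min_products=2`), optionally also
requiring evidence from `min_proteases` distinct proteases. Peptides
mapping to more than one locus are excluded from calling by default —
an ambiguous locus cannot pin a bond — with an opt-in flag to keep them.
Output ordering is canonical (protein, then site), so calls are invariant
to the input row order.

## Fragment spectra and the contrast angle

Only b and y series are generated (the fragment types annotated in HCD
practice for this workflow), monoisotopically, with proton 1.007276 Da
and water 18.010565 Da; b = Σ residues + z·H⁺, y = Σ residues + water +
z·H⁺. Peak matching assigns globally-closest ion–peak pairs first within
the tolerance (default 20 ppm; Da available), ties broken toward lower
peak m/z, each peak and ion used at most once. Acquired and predicted
spectra are matched per charge state against the same ladder and then
charge-deconvoluted symmetrically — intensities of the same fragment
label at different charges are summed — because the order (match per
charge, then sum) is the only one that uses the per-charge m/z
information before collapsing it.

The spectrum contrast angle is normalized as SCA = 1 − 2θ/π so that
identical spectra score 1 and orthogonal (disjoint-support) spectra score
0. Numerically the angle is computed from the chord between the unit
vectors, θ = 2·arcsin(‖a/‖a‖ − b/‖b‖‖/2): for the ≤ 90° angles that
non-negative intensities allow this form is well-conditioned and returns
the endpoints exactly (a zero dot product short-circuits to 0). The score
is scale-invariant, so no intensity normalization is applied beforehand.
Scoring uses the K = 8 fragments with the highest *predicted* intensity
among those matched in both spectra (ties toward lower singly-charged
m/z); if fewer than K fragments match, all are used and `k_used` records
the count. Stability is assessed by resampling the K fragment pairs with
replacement (n_boot = 20 by default), the pair being the unit the angle
is computed from; the seed is mandatory and the result reproducible.

## Proteome comparison

Report filtering keeps rows with q_value ≤ 0.01, protein q_value ≤ 0.01,
mass evidence > 0.5 and precursor charge > 1, boundary semantics exactly
as stated. Imputation draws each missing log2 cell from
N(μ − 1.8σ, (0.25σ)²), with μ, σ the mean and SD of the observed values —
per sample column by default (the Perseus convention), globally on
request — and never touches observed cells. The per-protein test is
Welch's t by default, the robust choice for small-replicate LFQ data;
Student's equal-variance variant is available (`equal_var=True`) and is
what the calibration tests exercise, since Welch is intentionally
conservative at three replicates per group and a conservativeness check
would conflate the two effects. BH adjustment uses the standard step-up
with monotonicity enforcement. Volcano classes use log2FC ≥ 2 and
adjusted P < 0.5 by default; a 0.5 significance cut is far laxer than the
conventional 0.05 and is kept deliberately as the documented default of
this workflow — override `p_cut` for conventional use. Profile heatmaps
take the median over replicates per condition and z-score each protein
row with the population-SD convention (constant rows map to zeros).

## Assay quantification

Shedding: per condition, mean background-corrected supernatant
fluorescence over mean background-corrected cell fluorescence, then
normalization by the control condition's ratio (control ≡ 1). A negative
corrected supernatant mean is clipped to 0; a non-positive corrected cell
mean is an error, not a clip, because the ratio is then meaningless. The
ratio is invariant to any common gain applied to wells and blanks.

FRET: channels are background-subtracted, the acceptor corrected by
subtracting `bleed_through_factor` × donor (the factor is supplied, as
measured from donor-only controls; estimating it is out of scope), the
donor/acceptor ratio formed per frame and affine-mapped so the mean of
the 10 frames before ligand addition is 0 % and the mean of the last 10
frames after the saturating stimulus is 100 %. The 10-frame plateau
window mirrors the baseline window; a plateau not exceeding the baseline
is a degenerate normalization and raises.

Concentration–response: response = bottom + (top − bottom)/(1 +
10^(logEC50 − log10 c)) — the three-parameter logistic with Hill slope
fixed at 1; `fix_bottom` pins the bottom (e.g. 0) instead. Fitting is
least squares with deterministic multi-starts (logEC50 initialized at the
quartiles of the sampled log-concentration range; bottom/top at the
response extremes), keeping the best sum of squares. Two curves are
compared by refitting with one parameter shared (top by default — the
maximal-efficacy question) and the extra-sum-of-squares F test
F = ((SS_shared − SS_sep)/(df_shared − df_sep))/(SS_sep/df_sep); a shared
fit can never genuinely beat the separate fits, so SS_shared is floored
at SS_sep against numerical noise. qPCR efficiency is the exact formula
E = (10^(−1/slope) − 1) × 100.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (parameters, seed) and returns its
ground truth, so recovery tests never re-derive it.

* **Shedding identifications** split the protein at each planted site and
  fully digest both products with each protease, mapping peptides back to
  whole-protein coordinates. The default length range is unbounded so the
  noise-free table always contains the two peptides flanking each planted
  site — the generator's contract, and what makes noise-free recovery a
  sharp 100 % check; narrow the range to emulate instrument-detectable
  lengths. Decoys are random substrings carrying a spurious non-canonical
  terminus at a non-planted position. Detection dropout is Bernoulli per
  peptide. Not emulated: identification scores, modifications,
  chromatography.
* **Spectrum pairs** use a smooth positional intensity heuristic
  (mid-sequence y-ions most intense, b-ions weaker) as the "predicted"
  spectrum — an intentionally non-physical stand-in for a learned
  fragment-intensity predictor, which keeps the pipeline free of any
  external service. The acquired copy adds multiplicative log-normal
  intensity noise, per-peak dropout, m/z jitter and uniform background
  peaks. Passing tests therefore demonstrate the matching/scoring
  machinery, not the realism of fragmentation intensities.
* **Proteome matrices**: per-protein normal log2 abundances (mean 25,
  SD 2, within-group SD 0.3 — typical LFQ scales), a labelled subset
  shifted between groups, and missingness via a decreasing logistic of
  the true intensity (midpoint 22, steepness 1.2), i.e. MNAR as in real
  LFQ. Correlated proteins and batch effects are not modelled.
* **Plates and traces** embed known shed fractions / known 0–100 anchors
  and bleed-through, and serve as the oracles for the round-trip tests.

## Problem sizes in the checks

The recovery experiments use 150–200-residue proteins with four
proteases over 100 seeds; calibration checks use 1000-protein null
matrices over 20 seeds (t test), 500 null curve pairs (F test), and 10⁴
imputation draws; the digestion oracle compares 200 random proteins of at
most 60 residues against exhaustive substring enumeration. These sizes
give the binomial/standard-error tolerances quoted in the tests while
keeping the whole suite fast.

## Known limitations

* Fragment generation covers unmodified b/y ions only — no neutral
  losses, isotopes or modified residues.
* The bundled reference FASTA is a synthetic surrogate: it places the two
  identifying peptides at receptor-numbering coordinates 54–64 and 65–80
  within random flanking sequence, so coordinate arithmetic is faithful
  but the flanks are not the canonical receptor sequence.
* Site calling is evidence-counting only; no FDR is attached to a call.
* The F test for nested logistic fits is exact only asymptotically in
  nonlinear models; the type-I calibration test verifies it empirically
  at the simulated design.
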