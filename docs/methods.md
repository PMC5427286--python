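# Methods

`oligoxl` implements the quantitative core of an integrative
structural study of a double-disc protein oligomer — the kind of
analysis used to model and validate a dodecameric small heat-shock
protein (sHsp) such as chloroplast Hsp21.  This note records the
models, the parameters that matter, the synthetic-data conditions the
tests run under, and the numerical choices made where the design was
genuinely open.

## Assembly geometry (`structures`)

**Model.**  Twelve subunits form six domain-swapped dimers; three
dimers form a hexameric "trimer-of-dimers" disc; two discs stack along
the 3-fold axis.  The relation between the discs is a *screw
transform*: disc 1 equals disc 0 flipped by an in-plane 2-fold,
twisted by θ about the 3-fold axis and translated d along it.  In the
eclipsed crystallographic arrangement θ = 0; the staggered dodecamer
model has θ ≈ 30° with the discs ≈ 35 Å further apart.

**Conventions.**  After inertia alignment the 3-fold axis is z and
disc 0 is the disc with the lower centroid.  θ is reported in
[0°, 60°): the C3 symmetry of a disc makes the twist degenerate modulo
120°, and the eclipsed/staggered mirror folds that interval once more.
The separation d is the difference of the two disc Cα-centroid
projections on the axis.  Because the 2-fold flip axis is fixed to the
frame's x axis, the absolute θ of an arbitrarily oriented input depends
on its in-plane orientation; *differences* of twists measured in a
common frame, and all round-trip measurements on built assemblies, are
well defined.  The build/measure round trip recovers (θ, d) to 1e-6
over the whole admissible range (verified for 1,000 random parameter
pairs).

**Measurement.**  The twist is found in closed form: for matched point
sets P (flipped disc 0) and Q (disc 1), the optimal rotation about z is
atan2(Σ(p×q)_z, Σ p·q).  The chain correspondence is searched over the
3 cyclic dimer shifts × 2 cyclic directions (a 2-fold flip reverses the
cyclic order) × 2 within-dimer chain orders; the correspondence with
the lowest RMSD wins.  Dimers are inferred by maximizing the total
count of inter-chain Cα pairs within 8 Å over all perfect matchings of
the six chains of a disc — the domain-swap interface dominates every
other contact at the ~10 Å model resolutions this package targets.

**Degenerate inputs.**  A flat single-disc assembly has no unique
inertia axis; `measure_screw` accepts an `axis_hint` for such cases and
refuses single-disc maps.  Unmodelled residues are reported absent,
never imputed.

## Cross-linking mass spectrometry (`xlms`)

**Digestion.**  Trypsin cleaves after K/R except before proline; all
peptides with 0–2 missed cleavages are enumerated with 1-based spans.
The 0-missed-cleavage peptides tile the input sequence exactly.

**Masses.**  Monoisotopic throughout (the printed reporter-peptide
[M+H]+ of 1623.8 matches the monoisotopic sum, not the average).
Residue masses and elemental compositions come from pyteomics.  A
uniform ¹⁵N label shifts a peptide by 0.9970349 Da per nitrogen
(backbone plus side chains: R +3, K/N/Q/W +1, H +2 beyond the amide).
BS3 adds 138.06808 Da (C₈H₁₀O₂) when both ends react and 156.07864 Da
(C₈H₁₂O₃) as a hydrolysed dead-end.  Valid link sites are lysines and
the protein N terminus (the mature N-terminal peptide cross-links
avidly because its α-amine has the lower pKa).

**Isotope quartets.**  A 1:1 mix of unlabeled and ¹⁵N-labeled protein
makes an intersubunit cross-link visible as a *hybrid*: besides the
¹⁴N-¹⁴N and ¹⁵N-¹⁵N peaks, the ¹⁴N-¹⁵N and ¹⁵N-¹⁴N combinations appear,
offset by n_A·Δ and n_B·Δ from the light peak.  `classify_hybrid`
demands **both** mixed peaks (plus both outer peaks) within the m/z
tolerance — a single mixed peak is conservatively `not_detected`.  At
10 ppm and analyte masses below ~5 kDa, uniform decoys at 1 peak/Da do
not produce false hybrid calls in seeded trials.

**MS/MS acceptance.**  b/y ladders are generated for both peptides,
with the linker plus the entire partner peptide carried by fragments
containing the linked residue.  A species is accepted when ≥ 30% of
each peptide's ions match within 0.05 Da, the match score exceeds 25,
and the precursor intensity exceeds 1,000 (applied to the precursor
peak; the fragment-level reading of that threshold is ambiguous and
not used).  The score is −10·log₁₀ of the binomial tail probability of
the observed match count under random peak placement — an explicit
null model preserving the "score > 25" semantics of search-engine
scores whose exact definition is proprietary.

## Cross-link to structure mapping (`xl_mapping`)

For a residue pair the same cross-link can form in four geometric
contexts — within one subunit, across the dimer interface, between
non-dimer chains of one disc, or between discs.  Each context distance
is the **minimum** Cα–Cα distance over all ordered chain pairs in that
relation (the published per-context single values are consistent with
this reading; it is verified against a brute-force all-pairs oracle).

Evidence classes follow the standard 5-level scheme: hybrid detected →
intersubunit (class 2 with a monomer-band observation, else 4);
detected only non-hybrid → class 1; hybrid experiment inconclusive →
class 5 with a monomer band, class 3 with only a dimer band.  On the
bundled 22 unique residue pairs the decision table reproduces 20
published classes; the two deviations (89–126 and 121–173, both with
hybrid evidence only from the wild-type × V181A mixing experiment) are
carried as per-record overrides and *flagged*, not reclassified —
the published assignment appears to down-weight that experiment and we
do not guess the rule.

Constraint validation uses 30 Å (the upper end of the 26–30 Å range
appropriate for BS3/DSS Cα–Cα restraints).  A cross-link is satisfied
if **any** class-compatible context distance is within threshold
(class 1: intrasubunit; class 3: intrasubunit or within-dimer; classes
2/4: any; class 5: intrasubunit primary).  Links to the flexible
N-terminal arm (positions 1 and 27, unmodelled) are unevaluable, not
violations.  Lowering the threshold can only add violations.

## SAXS (`saxs`)

**Forward model.**  One dummy scatterer per residue at the Cα with a
uniform form factor, I(q) = Σᵢⱼ sin(qrᵢⱼ)/(qrᵢⱼ) — no hydration shell
or excluded-volume term.  This reduced model is validated against
closed forms (two-point interference, the analytic sphere factor to
< 2% for qR ≤ 5) rather than against full-physics predictors, since
the package's ensemble logic only needs relative curve shapes.  Above
2×10⁶ distance pairs the pair distances are binned at 0.1 Å, bounding
the phase error by q·Δr/2 (< 1% for q ≤ 10 nm⁻¹) while keeping large
particles tractable.  q is in nm⁻¹; Å⁻¹ input is converted on read.

**Guinier.**  ln I is fitted against q² with (I/σ)² weights, iterating
the range until q_max·Rg ≤ 1.3.  When enough points are available a
quadratic term in q² absorbs the leading departure from the Guinier
law and the linear coefficient gives the q → 0 slope; this removes the
~1–2% systematic bias a straight-line fit leaves on curved (e.g.
spherical) profiles and brings noiseless-curve Rg within 1% of the
coordinate-space value.

**P(r).**  From coordinates: a pair-distance histogram (Dmax = the
largest pair distance).  From a curve: non-negative least squares on
the sinc-kernel transform with a second-difference smoothness penalty
and pinned endpoints P(0) = P(Dmax) = 0; when Dmax is not supplied it
is scanned and the smallest support whose residual is within 10% of
the best is chosen (an unstable scan flags the result low-confidence).

**Porod.**  The invariant Q = ∫q²(I−c)dq with analytic extensions
below q_min (I ≈ I0) and above q_max (K/q⁴ tail) gives
Vp = 2π²I0/Q, MMp = Vp/1.6 in kDa for nm³ (and MMa = Va/2 for
bead-model volumes).  The constant background c and Porod constant K
are fitted jointly as the line q⁴I = K + c·q⁴ over the last 30% of
points: a 10%-tail constant-only fit spans less than one form-factor
oscillation on compact particles and is numerically degenerate (34%
volume error on the sphere oracle), while the 30% q⁴-space fit is
accurate to < 2% with or without a flat background.  Masses are
reported with half-up rounding, matching how printed tables round
ties (72.5 → 73).

**Flexible arms.**  Arms are self-avoiding Cα walks (3.8 Å steps,
3.5 Å non-bonded minimum against core, self and sibling arms) grown
from surface anchors, restricted to the core's exterior (`outside`) or
interior (`inside`).  Failed walks discard the conformer and are
counted.  Outside-mode pools have strictly larger mean Rg than the
core, and dodecamer outside pools are separably wider than inside
pools — the qualitative signature that discriminated the two arm
placements on real data.

**Ensemble optimization.**  The genetic algorithm selects subsets
(with repetition, size ≤ 20 by default) from the conformer pool;
fitness is χ² = 1/(N−1)·Σ[(c·I_ens − I_exp)/σ]² with the scale c
analytically optimal (hence scale-invariant); tournament selection
with 10% elitism guarantees χ² never increases across generations.
Defaults: population 50, 1,000 generations, mutation 0.1, crossover
0.5 (the published workflow ran its tool's unlisted defaults; these
are conventional values).  Weights are subset multiplicities;
per-state fractions sum weights by oligomer state.

## Density maps (`density`)

Maps are sums of per-atom isotropic Gaussians with FWHM equal to the
target resolution and amplitude proportional to atomic number — a
real-space stand-in for structure-factor map simulation, validated by
self-consistency (resampling correlation, linearity) rather than
bit-compatibility with crystallographic map generators.  The voxel
must satisfy spacing ≤ resolution/2.  Standardization scales to mean 0,
SD 1, so contour levels are in σ; difference maps subtract
standardized inputs element-wise.  Blobs are 26-connected components
above a threshold, size-sorted.  FSC uses one-Fourier-voxel shells up
to Nyquist with linear interpolation at the threshold crossing (0.143
for independent half-maps).  MRC/CCP4 mode-2 I/O goes through gemmi.

## Synthetic data (`synthetic`)

Every generator is a pure function of (parameters, seed) and emits a
`SyntheticTruth` sidecar that round-trips through a key=value text
format.  The default conditions are the study conditions: screw
θ = 30°, d = 35 Å; MS tolerances 10 ppm (MS1) and 0.05 Da (MS/MS) with
uniform decoys and bounded jitter; a 74:26 dodecamer:hexamer mixture
with σ(q) = 1%·I(q) Gaussian noise; maps at 10 Å with two independent
half-map noise realizations and optional inserted Gaussian blobs
(≥ 4.5σ_blob apart so they stay separable at half-peak contours).

What the generators do **not** emulate: real isotope envelopes and
charge-state distributions (MS peaks are single sticks), detector
geometry and inter-frame scaling in SAXS, structured (non-white) noise
and masking effects in cryo-EM maps, and conformational correlation
between arms.  Passing tests therefore demonstrate the correctness of
the arithmetic and the estimators under clean, known-truth conditions,
not robustness to every artifact of real data.

**Problem sizes.**  The test suite and the ensemble-recovery study run
on toy assemblies (20–30 residues per chain), pools of 60 conformers
per state with 20-residue arms, and 300 GA generations — sizes chosen
so the whole suite completes in a few minutes on one CPU while leaving
every statistical margin intact (fraction recovery lands within ±4
points of truth on 10 consecutive seeds, against the ±5 acceptance
band).  The deposited experimental models are not redistributed with
the package; the geometry checks that need them look under
`data/deposited/` and fail with a clear message when the files are
absent, while all algorithmic properties are covered by the synthetic
ground-truth fixtures.

## Known limitations

* The reduced SAXS forward model cannot reproduce absolute χ² values
  obtained with full-physics predictors on measured curves; χ²
  comparisons are meaningful only within one forward model.
* The screw twist of an arbitrarily oriented assembly is defined
  relative to the analysis frame (see above); compare twists, not
  absolute values, across structures.
* `infer_assembly_map` assumes 6 or 12 topologically equivalent
  chains; polydisperse or partial assemblies are out of scope.
* Isotope-envelope deconvolution, retention-time modelling and
  decoy-database FDR estimation are deliberately absent — the
  acceptance criteria mirror a manually validated workflow.
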