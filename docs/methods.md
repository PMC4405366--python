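# Methods

## Scope and data model

`tadens` analyses conformational ensembles of the intrinsically disordered
p53 transactivation domain (TAD, residues 1–61) and variants of it.  An
ensemble is a set of frames over a fixed topology — a `(frames, atoms, 3)`
coordinate array in Å with normalised frame weights — read from or written
to multi-model PDB files (one MODEL/ENDMDL pair per frame).  Frames are
treated as exchangeable, statistically independent draws from the
underlying conformational distribution; all uncertainty statements below
rest on that assumption.

Residue numbering is 1-based author numbering throughout (the p53-TAD
partial helices are residues 18–27, 40–44 and 48–52).  Frame indices are
0-based half-open internally; the command line accepts 1-based inclusive
ranges.  Alternate locations keep the first variant; insertion codes are
rejected outright, because simulated ensembles never carry them and their
silent acceptance would hide corrupt input.

## Helix assignment and helicity statistics

No single dihedral criterion for "helical" is canonical for Cα-trace
data, so the assignment is explicit and configurable:

* **phi–psi backend** (needs N, CA, C atoms): a residue is in the α basin
  when φ ∈ (−100°, −30°) and ψ ∈ (−67°, −7°).
* **ca-torsion backend** (Cα only): the virtual torsion over Cα atoms
  i..i+3 lying in (30°, 70°) marks residues i+1 and i+2.

Both backends then apply a minimum-run rule: only residues inside a run of
≥ 3 consecutively flagged residues count as helical.  This suppresses
spurious single-residue "helicity" from random coil torsions and matches
the definition used by the synthetic generator, so generator ground truth
and measurement share one definition.  Chain-terminal residues without a
defined dihedral are coil; in particular the first and last residues can
never be assigned helical, which slightly biases terminal segments (not an
issue for p53-TAD, whose helical segments are interior).

Helicity profiles are weighted column means of the binary state matrix.
The uncertainty convention is deliberately simple: when a system has been
sampled by two independent runs (the folding/control pattern of
enhanced-sampling studies), the per-residue uncertainty is the absolute
difference between the two run profiles, and the reported fraction is
their mean.  Helical substates — maximal runs within one frame — are
histogrammed by (start residue, end residue); the cell sum equals the mean
number of helical segments per frame and may exceed 1.

## Synthetic ensembles with known ground truth

Because the molecular-dynamics ensembles the analyses were designed for
are not deposited anywhere, the package carries a first-class synthetic
generator whose statistical structure mirrors them, so every downstream
stage can be validated by parameter recovery.

**States.**  Each frame draws per-residue helix/coil states independently
of every other frame (no Markov chain in the frame index — binomial error
bars are exact by construction).  Within a frame, residue r is helical
with probability given by its propensity p_r, with the odds multiplied by
exp(c) when residue r−1 is helical (nearest-neighbour cooperativity c ≥ 0;
c = 0 gives plain Bernoulli draws).  Runs shorter than 3 residues are then
relabeled coil.  The exact post-relabeling expectation for a short segment
is available by enumeration of all 2^L patterns
(`expected_helicity`), and `propensity_for_target` inverts it, so presets
are specified by their *realised* helicity: the wild-type-like preset
targets 10% over residues 18–27 and 8% over 40–44 and 48–52, the observed
levels for the simulated wild type; mutant-like presets halve individual
region targets (e.g. 18–27 to 5% for the K24N analogue, the distal turns
to 4% for the double-mutant analogue).

**Coordinates.**  Chains are grown atom by atom from internal coordinates
(virtual bond 3.8 Å, virtual bond angle 91°).  Steps whose two interior
residues are both helical take the ideal helix virtual torsion +50° with
uniform jitter ±5° (default); coil steps draw torsions uniformly on
(−180°, 180°] *excluding* the band (25°, 75°).  The exclusion is what
makes generator ground truth and torsion-based assignment agree exactly:
a coil torsion inside the helical window would otherwise extend helical
runs spuriously.  The price is a mild non-uniformity of the coil torsion
distribution (about 14% of the circle is excluded), which is irrelevant to
every statistic the package computes.  An optional N-CA-C backbone mode
grows real backbones (standard bond lengths/angles, ω = 180°) with helical
φ/ψ = (−62°, −41°) ± jitter and coil pairs sampled uniformly outside the
α basin, for exercising the phi–psi assignment backend.

**Excluded volume.**  Non-bonded Cα pairs must stay ≥ 3.8 Å apart
(configurable).  Whole-frame rejection is hopeless for a 61-mer (the
clash probability of an unconstrained random walk is essentially 1), so
clashing growth steps resample their torsion (up to a retry cap; frames
whose non-resamplable helical steps clash are regrown from scratch).
This is a chain-growth sampler, not an unbiased rejection sampler of the
torsion product measure — like all Rosenbluth-style growth it slightly
favours conformations that were easy to grow.  Crucially, the helix/coil
state row of a frame is never discarded during coordinate retries, so the
realised helicity equals the sampled states exactly and the enumeration
oracle remains valid regardless of the growth bias.

**Contact biases.**  Long-range pairs (|i−j| ≥ 4) can be tilted toward a
target contact probability (CA–CA ≤ 8 Å) by rejection sampling of
candidate *coordinate realisations*: a frame's coordinates are accepted
with probability exp(Σ s_k x_k − Σ max(s_k, 0)), where x_k indicates
contact k, and rejected frames rebuild their coordinates while keeping
their states.  The strength s_k that reaches a target p_t from a base
rate p_0 is the log-odds shift s = log[p_t(1−p_0)/(p_0(1−p_t))]; p_0 is
estimated from an unbiased pilot run and, because pilot noise on rare
contacts is large, refined once from the realised frequency of the full
ensemble when auto-calibration misses by more than 0.02.  Sustained
rejection above 99.9% is a hard error (the parameters are unrealisable).

Realistic defaults: 4000 frames per ensemble (the size of the
under-sampled simulation ensembles the analyses target), contact targets
in the 0.06–0.2 band where long-range contact maps of p53-TAD show
contours.

## Contact maps, distances, compaction

A residue pair is in contact when its distance is no greater than the
cutoff (boundary inclusive): 4.2 Å for the minimal heavy-atom criterion
on atomistic ensembles, 8.0 Å on Cα distances for Cα traces (the latter
is this package's convention, chosen so that Cα-trace contact rates for
helix-contact geometries resemble the heavy-atom rates of full chains).
Pairs with |i−j| < 4 are masked by default so the maps report long-range
structure; the mask and both cutoffs are parameters.  Map agreement
metrics (Pearson correlation, RMSD) are computed over unmasked
upper-triangle entries only, to avoid double-counting the symmetric half.
Distance distributions are weighted histograms of per-frame Cα–Cα
distances with mean and SD; the radius of gyration is mass-uniform.

## PRE back-calculation

For a spin label at residue ℓ, the transverse relaxation enhancement of
the amide proton of residue r at effective electron–proton distance
d (converted to cm) is

    R2sp = (K / d^6) · (4 τc + 3 τc / (1 + ωH² τc²))

with defaults K = 1.23×10⁻³² cm⁶ s⁻², τc = 3.3 ns, ωH = 2π × 600 MHz,
and the observable intensity ratio is

    I_ox / I_red = R2 · exp(−R2sp · t) / (R2 + R2sp)

with R2 = 16 s⁻¹ and INEPT delay t = 9.8 ms.  Two conventions are
exposed rather than silently chosen, because either reading is defensible
when a Larmor frequency is quoted in MHz:

* `omega_convention`: "angular" (default, ωH = 2πν — the standard
  spectral-density form; the dispersive term is then ~3 orders of
  magnitude smaller than the 4τc term) or "linear" (ωH = ν).
* `averaging_mode`: the effective distance is ⟨r⁻⁶⟩^(−1/6) by default
  (PRE is dominated by close approaches; this is the physically correct
  average for the observable) or the plain ⟨r⟩.  The r⁻⁶ average is never
  larger than the arithmetic one (power-mean inequality), so r6-mode
  ratios lower-bound arithmetic-mode ratios.

Cα–Cα distances proxy the electron–proton separation — no explicit
nitroxide label or rotamers are modeled.  The labeled residue's own ratio
is reported as 0 (its amide is fully broadened experimentally) and is
excluded from correlations with experimental tables.  Numerical note: the
ratio underflows to exactly 0 below ≈ 3.6 Å in double precision; it is
strictly increasing wherever representable.

## Fixed-radius clustering

The literature tools for fixed-radius conformational clustering name an
implementation, not an algorithm, so this package fixes its own
deterministic contract: a leader pass in frame order (assign each frame
to the nearest existing centroid with superposed Cα RMSD ≤ radius, else
found a new cluster on that frame), followed by `refine_passes` (default
3) rounds of centroid re-election (the member minimising its maximum RMSD
to the other members) and re-assignment.  Ties break toward the lower
cluster id; clusters are reported sorted by descending population.  No
equivalence with any external tool is claimed.  Superposition is Kabsch
via batched SVD with the reflection branch corrected to proper rotations;
the RMSD is evaluated on the explicitly rotated coordinates rather than
through the trace closed form, which keeps rigid-copy RMSDs at machine
precision (the closed form loses ~7 digits to cancellation).  The
refinement is quadratic in cluster size, which is why the bundled
acceptance script clusters a 500-frame subsample — ample to characterise
the heterogeneity (many small clusters at a 5 Å radius) of a disordered
ensemble.

## Mutant comparison and flagging

Helicity deltas are b − a per residue with combined uncertainty
√(u_a² + u_b²).  A residue window is flagged "modulated" when the
magnitude of its mean delta exceeds `flag_multiplier` × the combined
window uncertainty (window uncertainty = mean per-residue uncertainty of
each profile over the window, combined in quadrature).  The default
multiplier is 1.0 — the plain "difference exceeds its uncertainty" rule —
but because the uncertainty is itself a single noisy realisation (one
|run difference|), the 1× rule false-flags a null window roughly 15% of
the time; a multiplier of 2 brings the false-positive rate to the few-%
level and is what the bundled detection analyses use.  No
multiple-testing correction is applied across the three default windows;
this is reported transparently rather than dressed up as a test
statistic.  RDC profiles are compared after a single global scale
s = Σ(pred·exp)/Σ(pred²), the least-squares scalar through the origin.
Secondary chemical shifts are observed minus residue-type random-coil
reference values supplied by the user as a table (the reference
statistics themselves are not reproduced here).

## What the synthetic tests do and do not show

Passing parameter-recovery tests on synthetic ensembles demonstrates that
the analysis stages measure what they claim on data whose ground truth is
known, at realistic sample sizes, including the minimum-run subtleties
and the rare-contact calibration.  They do not validate any force field,
nor the physical realism of the generator: real disordered ensembles have
correlated frames (so binomial error bars are optimistic there),
sequence-dependent local geometry, side chains, and compaction physics
the generator does not attempt.  The generator is a statistical stand-in,
not a simulator of p53-TAD energetics.

## Problem sizes

Default study-scale conditions are 4000-member ensembles (two independent
runs where uncertainties are needed).  The acceptance script runs the
full pipeline at these sizes except for clustering (500-frame subsample,
see above); the test suite uses 4000-frame ensembles for recovery
criteria and smaller ensembles (hundreds of frames) for structural and
error-path checks.
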