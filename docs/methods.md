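# Methods

This note documents the models, conventions and numerical choices behind
assignkit, what the synthetic-data generator does and does not emulate, and
the limitations a user should know about.

## Data model and assignment semantics

A project exposes eleven top-level object kinds (Spectrum, SpectrumGroup,
Sample, Substance, Chain, Complex, NmrChain, ChemicalShiftList, DataSet,
StructureEnsemble, Note); seven of them carry child kinds.  Kinds outside
the assignment workflow (SampleComponent, RestraintList/Restraint, Data,
CalculationStep, Model, …) are deliberately skeletal — name plus parent
link — sufficient for hierarchy introspection and PID addressing but not
for restraint or ensemble science.

PIDs serialise as `TYPE:part1.part2...` with two-letter type codes.  Key
parts may not contain `.` or `:`; an NmrResidue's key includes its residue
type only when one is set, so `NR:@-.@13-1` and `NR:A.57.LYS` are both
valid.

Assignment is a *pure function of names*: an NmrResidue is assigned iff its
NmrChain name equals a Chain code and its sequence code and residue type
match a Residue there.  `assign` renames (and moves) the NmrResidue and its
offset children; `deassign` issues a fresh serial code from a single
project-wide counter and moves the spin system back to the default chain
`@-`.  Conflicts — a claimed target residue, an incompatible residue type,
a duplicate code — are errors, never silent renames.  Connected stretches
are NmrChains named `#n` with `isConnected` set; their residue order *is*
the hypothesised sequential order, and connecting tail-to-head concatenates
stretches.

Chemical shift values are the unweighted mean of all assigned peak
positions for an NmrAtom over the contributing dimensions, with the sample
standard deviation (0 for a single observation) and the contributing count.
Shifts are always recomputed from the current peaks, including for assigned
spin systems; freezing values at assignment time was considered and
rejected because it makes the shift list depend on operation order.

## Reference shift statistics

`refshifts.py` packages mean/sd chemical shifts for H, N, CA, CB, HA, HB
over the 20 standard amino acids, of the kind compiled in large public
shift databases (random-coil-centred, ~0.6 ppm sd for amide H, ~4 ppm for
N, 1.5–3 ppm for CA/CB).  Glycine carries no CB/HB entry and proline no
amide-proton entry.  The same table drives the synthetic-shift generator,
the atom-selector likelihood and the residue-type predictor, which makes
all recovery experiments self-consistent and offline.  Real proteins have
secondary-structure and neighbour effects these marginal statistics ignore;
see Limitations.

## Peak picking

A peak is a grid point strictly greater than all 3^ndim−1 neighbours with
intensity above threshold; under sign policy `both`/`negative`, strict
minima below −threshold are picked too (restricted picking defaults to
`both` because HNCACB-type spectra have negative CB correlations).  Points
tied with a neighbour (plateaus) and grid-edge points are never peaks —
deterministic, and safe for the synthetic grids where exact ties only arise
from perfectly symmetric peak placement.  Positions are refined per
dimension by a three-point parabola through the apex column, the offset
clamped to half a grid step; the reported height is the interpolated apex.
Restricted picking matches spectrum axes to a spin system's shifted
NmrAtoms by leading nucleus letter (axis `Hn` ↔ atom `H`); if several atoms
match one axis the alphabetically first defines the window — in the
intended workflow only the amide H and N have shifts at pick time.
Default tolerances: 0.05 ppm ¹H, 0.4 ppm ¹⁵N, 0.4 ppm ¹³C.

## Experiment types

A registry of eight common types (hsqc15N, hsqc13C, hnco, hncaco, hnca,
hncoca, hncacb, cbcaconh) records axis codes, the amide anchor atoms, and
the expected peak pattern as (atom, residue offset, sign) tuples — e.g.
hncacb: CA(i)+, CB(i)−, CA(i−1)+, CB(i−1)−.  Axis-code compatibility (for
overlaying spectra and routing regions) requires a pairing with equal
leading nucleus letters and, where both codes carry lowercase bonded-
partner suffixes, equal suffixes: `Hn` matches `H` but not `Hc`.

## Atom selector and strip matching

The atom selector scores an unassigned peak dimension against the (atom,
offset) candidates of the experiment's pattern: the likelihood of the mean
shift under the reference distributions of that atom pooled over the 20
residue types with equal weight, multiplied by 0.1 when the observed height
sign contradicts the pattern sign (a soft veto — sign information in real
data is occasionally wrong near noise level).  Scores are normalised over
candidates.

Strip matching ranks candidate spin systems by the tolerance-normalised RMS
deviation over shared atoms, `sqrt(mean_a (Δδ_a/tol_a)²)`.  Sharing is
literal: a glycine candidate without CB is scored on CA alone, and a
candidate sharing nothing is excluded rather than penalised.  CA and CB are
weighted equally (through their common ¹³C tolerance); ties break on PID.
For direction i−1 the query's inter-residue shifts are compared with
candidates' own shifts; for i+1 with candidates' `-1` offset children.

## Stretch-to-sequence mapping

Placement of a connected stretch on a chain uses the product-of-Gaussians
residue-type likelihood: log L(start p) = Σ_i log P(shifts_i | type at
p+i), with unobserved atoms contributing nothing (missing-at-random) and a
structurally impossible observation (CB at a glycine position) contributing
ε = 1e−6.  Posteriors over feasible starts are computed with a stable
log-sum-exp, so stretches of hundreds of residues stay finite.  Windows
overlapping residues already claimed by an assigned spin system are
excluded, preventing double assignment.  Mirroring the interactive
workflow, placements are only produced once a stretch has more than three
residues; `assignStretch` is all-or-nothing.  The likelihood/prior
construction is this package's own reconstruction of a Bayesian shift-
matching step; a uniform type prior is the default with an optional
composition prior.

## Referencing alignment

Stage 1 shifts the query peak set by the difference of the unweighted
centres of mass.  Stage 2 maximises Σ_q log(f(q+t)) where f is the
equal-weight Gaussian KDE of the match peaks, by steepest ascent with
central-difference gradients (step h/100), backtracking step halving
(initial step h), and convergence when every offset component moves less
than 1e−4 ppm.

Two choices were forced by measurement on synthetic HSQC sets:

* **Bandwidth.**  Scott's rule on the match set gives kernels as wide as
  the shift dispersion itself (h_N ≈ 2–3 ppm for ~50 amide peaks), which
  smooths away the peak-overlap structure: recovery of a planted
  (1.5, 4.0) ppm offset failed by (0.5, 1.9) ppm under 25% content
  mismatch.  The ascent is therefore *annealed*: repeated from Scott's-rule
  bandwidths halving down to the per-isotope matching tolerances
  (0.05/0.4 ppm), keeping the broad basin of attraction while ending sharp
  enough to lock the overlapping subset (recovery error < 0.01 ppm).
* **Outlier handling.**  During optimisation the KDE density is floored at
  a 5% uniform background over the (kernel-padded) match bounding box, so
  query peaks with no counterpart saturate at a constant penalty; with a
  bare numerical floor (1e−300) ten spurious peaks contribute ≈ −690 each
  to the log likelihood and drag the optimum to a wrong mode.

The reported `logLikTrace` is the ascent at the final bandwidth and is
non-decreasing by construction; `iterations` counts steps over all scales.
Offsets are corrections *added* to the query to land on the match;
`applyReferencing` moves peak positions or ppm axis limits, never
intensities.  Only translation is estimated — rotation/scale registration
and joint alignment of more than two spectra are out of scope.

## Synthetic data

`simulateShifts` draws one true shift per (residue, atom) from the
reference table — i.e. residues are independent, with no secondary-
structure correlation.  `simulatePeakList` renders one peak per expected-
pattern entry per residue (skipping prolines for HN-anchored experiments
and predecessor-dependent entries at the first residue), adds per-isotope
Gaussian position noise, drops peaks independently with a configurable
missing fraction, and adds spurious peaks uniform over the occupied ranges
with heights 0.5–1.5× the median magnitude and random sign.
`simulateSpectrumGrid` renders Gaussian lineshapes plus white noise;
`misreference` translates a deep copy.  `buildSpinSystems` reproduces the
state the pick-and-assign workflow leaves behind: serial spin systems with
own H/N/CA/CB shifts and `-1` children carrying the predecessor's CA/CB,
independently noised, in shuffled creation order.

Defaults reflect the study conditions exercised throughout: noiseless
positions unless stated; the strip-matching robustness checks use 0.1 ppm
¹³C noise on 30-residue chains, the mapping recovery checks 0.4 ppm ¹³C
noise with 5-residue stretches, and the referencing experiment ~50 amide
peaks with (1.5, 4.0) ppm offsets and (0.01, 0.05) ppm jitter.  Problem
sizes in the test suite (grids ≤ 64³ equivalents, chains ≤ 200 residues,
20–50 replicate simulations) were chosen as the smallest at which the
statistical checks are stable.

What passing these tests shows — and does not.  The generator draws from
the same distributions the predictors assume, so recovery rates here are
upper bounds: real spectra add correlated (secondary-structure) shift
deviations, overlap, lineshape distortions and artefacts the generator
does not model.  The tests validate the algorithms' correctness and their
behaviour under the stated noise models, not their field performance.

## I/O conventions

* **NEF dialect** — STAR-syntax saveframes `nef_nmr_meta_data`,
  `nef_molecular_system`, `nef_chemical_shift_list`, `nef_nmr_spectrum`
  (with `_nef_peak` rows; per-dimension chain/sequence/residue/atom
  columns, multiple assignments as repeated rows per peak id), plus a
  `ccpn_assignment`-style frame serialising the NMR-side hierarchy so
  assignment state round-trips by name.  Unknown `nef_`-category frames
  raise a named unsupported-block error; frames with other prefixes are
  preserved verbatim, and write→read→write is byte-stable on the supported
  subset.  The STAR parser is deliberately minimal (single data block,
  quoted and semicolon-delimited values, no nested loops).
* **`.sgrid`** — UTF-8 `key: value` header terminated by `end_header`,
  then a row-major little-endian float32 payload; ppm axes descend with
  increasing point index (point 0 at highest ppm); truncation is a format
  error.
* **CSV peak lists** — columns `serial`, `pos_<axisCode>`…, `height`,
  `assign_<axisCode>`… with semicolon-separated PIDs per cell.
* Recognised-but-unsupported formats (Bruker, Varian, NmrPipe, UCSF,
  Azara, XEASY, NmrView, PDB, Excel, CCPN projects) fail with a named
  routing error.

## Known limitations

No undo/notifier machinery or on-disk project layout; no side-chain
assignment workflow; the experiment-type registry covers eight types, not
the full catalogue of an interactive platform; no secondary-structure or
deuterium corrections to reference shifts; lineshape fitting beyond the
parabolic apex (volumes, full Gaussian/Lorentzian fits) is not attempted.
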