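# Methods

## Detection model

The detector formalises a near-attack-conformation (NAC) criterion for
water-mediated ester hydrolysis. A ground-state geometry is counted as
reactive when a water oxygen approaches the carbonyl carbon along the
canonical nucleophilic-attack trajectory: close (O···C < 3.5 Å), at the
Bürgi–Dunitz approach angle, and with the oxygen — not a hydrogen —
presented to the carbon. Frames satisfying this are a proxy for the
complex's ability to react; a second, donor-oriented water completes the
picture of a substrate-assisted mechanism in which the assistant activates
the nucleophile or relays its proton.

Definitions and conventions:

* **Bürgi–Dunitz angle** — the angle at the carbonyl carbon between the
  vector to the attacking water oxygen and the vector to the *carbonyl*
  (sp², double-bonded) oxygen. The angle could in principle be referred to
  the ester bridging oxygen instead; the carbonyl oxygen is the standard
  crystallographic choice and is what this package uses. The window is
  **closed**: [105°, 107°] inclusive at both bounds, both configurable.
* **Distances** — strict `<` for the W1 O–C test and the oxygen-first
  orientation comparison (an exact tie fails); `≤` for the W2 O–O and
  activator cutoffs. All cutoffs default to 3.5 Å, the conventional
  hydrogen-bond/contact distance.
* **Orientation of W1** — O–C distance strictly smaller than every H–C
  distance of that water. This requires an explicit-hydrogen water model;
  waters without hydrogens abort the scan by default
  (`on_missing_hydrogens="skip"` downgrades them to a silent skip).
* **Orientation of W2** — donor geometry: at least one W2 hydrogen
  strictly closer to O(W1) than O(W2) is. This mirrors the W1 oxygen-first
  logic on the donating side of the hydrogen bond. The test can be
  disabled (`require_w2_orientation=False`) to measure how much the
  orientation requirement filters, since a distance-only definition is
  also defensible.
* **Activators** — protein nitrogen/oxygen heavy atoms within 3.5 Å of
  O(W2). No separate literature cutoff exists for this contact, so the
  global 3.5 Å is reused and exposed. Only standard amino-acid residues
  are searched by default; the residue set is configurable, so nucleic
  acid atoms can be included by extending it.
* **Two-pass scan** — pass one collects waters whose oxygen is ever
  (in ≥ 1 frame) within the W1 cutoff of the carbonyl carbon; pass two
  tests only those waters per frame. This mirrors how site-extracted MD
  subsets are prepared and bounds the per-frame work. W2 candidates are
  *not* restricted to the pre-filter set: an assistant need never approach
  the carbonyl itself.
* **Frame-level semantics** — persistence statistics count frames, not
  hits: a frame with three attacking waters is one W1 frame. All W1 hits
  are still recorded individually in the per-frame reports.

Order of the three W1 tests does not affect the result set (they are
independent predicates); the implementation short-circuits
distance → angle → orientation.

## Persistence statistics

`summarize` reports total frames, W1 frames, W1+W2 frames, and the
percentage of W1 frames that carry an assistant. A zero-W1 trajectory
yields an *undefined* percentage (`None`), deliberately distinct from 0%.

Pair occupancy — the fraction of frames in which one specific (W1, W2)
water pair co-qualifies — needs a denominator, and either "all frames" or
"W1 frames only" is defensible. The library refuses to guess: the
denominator mode is a mandatory argument. The CLI defaults to `w1_frames`
and prints the mode it used.

Display rounding of percentages follows the convention of one decimal
place below 95% and two at or above it (61.3% but 95.37%); stored values
keep full precision.

## Synthetic trajectories

The generator emulates exactly what the detector consumes: a rigid
carbonyl fragment (C at the origin, O at 1.23 Å along +x, plus an inert
Cα and ester oxygen), a small protein shell ~14 Å away, and rigid 3-site
waters (O–H 0.96 Å, H–O–H 104.5°) placed by inverse geometry so that the
planted distance, Bürgi–Dunitz angle and orientation are hit exactly.
Multiple molecules in one frame are separated azimuthally by the golden
angle, which keeps unintended cross-contacts outside every cutoff.
Decoys violate exactly one criterion (4.2 Å for distance, 95° for angle,
or a flipped, hydrogen-first water), enabling per-criterion specificity
tests. Ground-truth labels are evaluated from the planted geometry against
the *default* site criteria — a "w1" spec placed outside the window is not
labelled — so labels are exact at zero jitter by construction.

Jitter is a per-molecule rigid Gaussian translation applied each frame
(default σ = 0.05 Å in the schedules used for validation, well inside the
~0.5 Å / 1° margins of the default planted geometries: 3.0 Å, 106°,
oxygen-first; W2 at 2.8 Å donor-oriented). Molecules not planted in a
frame are parked ≥ 40 Å from the site. The seed fixes all randomness;
regeneration is bit-identical.

What the generator does **not** emulate: realistic water dynamics,
hydrogen-bond networks, thermal libration of the carbonyl, periodic
solvent boxes, or correlated motion between frames. Passing the planted
suites therefore demonstrates that the geometric criteria are implemented
correctly and robustly near their boundaries — not that the criteria
themselves are a validated reactivity proxy for any particular enzyme.

## Trajectory I/O

Multi-model PDB is the required dialect (one `MODEL`/`ENDMDL` block per
frame; a file without `MODEL` records is a single frame); concatenated GRO
frames are read behind the same contract, converting nm to Å. The readers
are strict where it matters — malformed records fail with the line number,
frames disagreeing on atom count or (residue, atom-name) order raise a
topology error — and tolerant where it doesn't (trailing whitespace,
missing element columns; elements are then inferred from atom names, with
`CA` kept as carbon in amino-acid context). Coordinates are assumed
already imaged/whole, as site-extracted subsets are; an optional
minimum-image mode for orthorhombic boxes can be enabled in the site
definition. Binary formats (XTC/TRR/DCD) are out of scope. The test suite
cross-checks the PDB reader against MDAnalysis on the same files.

Frames are 0-indexed internally and 1-indexed in all human-readable
output.

## Michaelis–Menten fitting

`fit_mm` minimises squared residuals of v = kcat·[S]/(Km+[S]) with
scipy's bounded trust-region-reflective least squares (identical to
Levenberg–Marquardt away from the non-negativity bounds). The starting
point comes from a double-reciprocal (Lineweaver–Burk) linear fit,
falling back to (1.05·max v, median [S]) when the linearisation is
unusable. Standard errors are square roots of the covariance diagonal.
Non-convergence raises with diagnostics; non-positive estimates are
rejected as invalid fits.

Concentration units (mM or µM) travel with every series and parameter
set; efficiencies in different units refuse to combine. Noiseless
round-trip recovery is exact to < 10⁻⁶ relative error for all twelve
parameter sets used as truth; under 2%-of-Vmax Gaussian noise on an
8-point 0.07–14 Km design the median kcat bias over 500 replicates is
well under 1%.

Discrimination factors are reproduced from *printed* (rounded)
efficiencies, which is the convention that regenerates all published
values consistently (unrounded kcat/Km pairs do not, because printed
efficiency columns are themselves rounded). Factors are displayed as
nearest integers, with a thin-space thousands separator for large values.
Fold changes are displayed at the precision such statements are quoted:
nearest integer below 100, two significant figures above.

## Problem sizes in validation

Planted validation trajectories use 10–100 frames with ≤ ~20 waters;
oracle-equivalence checks run an independently written brute-force
all-pairs scan on the same trajectories. The noisy-fit bias study uses
500 seeded replicates. These sizes give exact, deterministic expectations
while keeping the full suite in seconds.

## Known limitations

* The detector treats frames independently; no residence-time or
  survival analysis of water occupancy is attempted.
* Water identity relies on (residue name, number, chain); trajectories
  that renumber solvent between frames violate the rigid-topology
  contract and are rejected rather than re-matched geometrically.
* The activator search reports contacts only; it does not score
  hydrogen-bond geometry or energetics.
* Minimum-image support is orthorhombic only.
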