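# Methods

## The observables

A single-pass TM helix in a bilayer has two orientational degrees of
freedom that matter for receptor signalling: how far it leans away from
the membrane normal (tilt) and how far it has rotated about that normal
relative to the rest of the protein (azimuth). This package measures
both, plus two hydration-based position measures, from classical MD
trajectories.

**Membrane frame.** The bilayer is represented per frame by a midplane
point, a unit normal oriented toward the extracellular side, and the two
signed leaflet offsets, all estimated from the lipid phosphorus atoms.
No time averaging is applied — membranes deform, and a per-frame frame
keeps the angle series honest about that. Two modes:

- `fixed-z` (default): normal = lab z-axis, midplane z = mean P z. This
  matches systems built with the bilayer normal along a box axis, which
  is the standard construction.
- `fitted`: plane fit to the P cloud. A naive smallest-principal-
  component fit of the pooled P coordinates is biased whenever the
  patch's lateral extent is comparable to the bilayer thickness, because
  the two leaflet planes (~38 Å apart) contribute large variance along
  the normal. We therefore refine in two iterations: split leaflets by
  the current normal, subtract each leaflet's centroid, and take the
  smallest principal component of the pooled *within-leaflet-centred*
  cloud. On noiseless data this is exactly rotation-equivariant; with
  1 Å P jitter it agrees with `fixed-z` to well under 1° on unrotated
  slabs.

The normal's sign is set by an extracellular reference point, by default
the Cα of the lowest-numbered TM residue (the TM span runs
extracellular → intracellular with increasing residue number).

**Helix axis and tilt.** The axis is the first right-singular vector of
the mean-centred TM Cα coordinates, sign-aligned from first to last
residue. The RMS perpendicular distance of the Cα atoms from the fitted
line (`rms_fit`) is always reported; an SVD will happily fit a line
through an unwound segment, so values above 3 Å trigger a warning. Tilt
is θ = arccos |â·n̂|, folded into [0°, 90°] by the absolute value so that
sign flips of the axis estimator cannot produce spurious 90°+ values.
Tilt is summarised with the linear mean and SD: it lives on a bounded
range far from any wrap point for realistic helices (θ ≲ 40°), where
linear statistics are appropriate and directly comparable to how such
tables are conventionally printed.

**Azimuth.** Measured as the IUPAC dihedral over four configurable Cα
atoms spanning the TM/intracellular junction, range (−180°, 180°]. The
choice of quadruple is a required configuration item because no
universal convention exists; the synthetic systems define it as their
four IC marker atoms. Azimuth wraps, so the summary is circular: the
circular mean (argument of the mean resultant vector), the mean
resultant length R̄, and the circular SD √(−2 ln R̄) (Mardia). Both
linear and circular means are emitted side by side, since published
averages for such angles rarely state which convention was used. When
R̄ < 0.2 — roughly what a uniform 360° spread produces at these sample
sizes — the summary sets a `weakly_concentrated` flag: a circular mean
of a near-uniform distribution is noise and must not be read as a
location estimate.

**Hydration RDF.** g(r) between one residue's Cβ and the water oxygens
(oxygen only; counting hydrogens would triple-count molecules),
minimum-image distances in orthorhombic boxes, uniform bins (default
0.1 Å up to 15 Å). Normalisation divides the mean per-frame shell count
by ρ_ref·V_shell with ρ_ref = N_waters/V_box (`box-density`). In a
membrane system water is excluded from the slab, so g plateaus below 1;
that is a property of the system, not an error, and cross-variant
comparisons are valid within a fixed normalisation. A `plateau` mode
rescales so the outer 20 % of bins average to 1, for readers who expect
bulk-normalised curves; the two modes must never be mixed in one
comparison. Coordination numbers integrate the raw pair counts, not the
normalised curve, so they are exact for the binning used.

**Intracellular region metrics.** For a labelled residue range: (i) the
minimum over its atoms of the distance to the nearer leaflet phosphorus
plane (|signed depth − leaflet offset|), and (ii) an exposure proxy, the
count of water oxygens within a cutoff (default 4.0 Å, a first hydration
shell) of any region atom. The exposure count is a deliberately simple
stand-in for solvent accessibility: an "open", JAK-accessible Box1 loop
is hydrated, a loop packed against the membrane or the protein body is
not. It is monotone in the cutoff and requires no SASA machinery.
Region numbering supports an integer offset because intracellular-local
and full-length residue numbering schemes both occur; the offset is a
config value the user must set deliberately — the resolved atom count of
every selection is logged as the guard against silent mismatches.

## Frame-window conventions

Windows are half-open `(start, end]`, anchored at the window end, with
frames kept when `end − t` is an integer multiple of the stride. This
makes "the last 100 ns sampled every 10 ps" exactly 10,000 frames and
"every 100 ps" exactly 1,000 — the counts standard practice quotes.
"last N ns" resolves against each trajectory's own final frame time, so
variants of different lengths can share a config. DCD headers store the
time step in internal units whose round-trip to ps carries ~1e-8
relative error; the reader snaps the step to a clean decimal and
regenerates uniform frame times so stride arithmetic stays exact.

Internal units are Å and ps; all angles are degrees.

## The synthetic generator

The generator emulates the *statistical structure* of a helix-in-bilayer
trajectory, not its physics: a rigid ideal α-helix (Cα radius 2.3 Å,
rise 1.5 Å/residue, 100°/residue twist, Cβ 1.5 Å radially outward;
default 23 residues numbered 490–512, placing residue 501 at the bilayer
centre), two phosphorus pseudo-planes at ±19 Å (a POPC-like phosphate
spacing; only relative comparisons depend on it) with ±0.5 Å per-frame
jitter, and water oxygens uniform at bulk density (0.0334 Å⁻³) in the
box region outside the slab. The default box is 75 × 75 × 110 Å.

Per frame, tilt and azimuth are drawn independently — von Mises with the
concentration solved from the requested SD via R = I₁(κ)/I₀(κ) and
SD = √(−2 ln R), or uniform for the azimuth — and applied as rigid
rotations R_x(θ)·R_z(φ) about the bilayer centre. Two constructions make
the ground truth exact rather than approximate:

- the helix template is pre-rotated so its *SVD-fitted* Cα axis is
  exactly the z-axis (the geometric axis of a finite, non-integer-turn
  helix deviates from the fitted axis by a fraction of a degree, which
  would otherwise bias tilt recovery);
- the four IC marker Cα atoms are placed with the two middle markers on
  the rotation axis; the first marker rides R_z(φ) while the last stays
  fixed in the lab frame (it represents the intracellular domain the
  rotation is measured against). The marker torsion then equals φ
  identically, and is 0° at the reference orientation, as is the tilt —
  matching how such simulation systems are initially placed.

Water-penetration events (a membrane defect hydrating a buried polar
side chain, S505-like) are emulated by `n_waters_per_event` reserved
water atoms that are placed uniformly in a 2.6–4.0 Å shell around the
target residue's Cβ on event frames (per-frame probability `p`) and in
the bulk otherwise — the atom count stays constant, as trajectory
formats require. The Box1 stand-in is a static 4-atom blob either in
solvent ~7 Å below the intracellular leaflet ("open") or tucked inside
the slab ("packed", where no water can reach it).

Waters are an ideal gas: uniform positions, no excluded volume, no
pair-separation enforcement (the 2.8 Å figure is used only for a
capacity sanity error). Everything derives from a single integer seed;
identical specs produce byte-identical PDB/DCD files.

**What passing tests do and do not show.** Recovery of generator
set-points validates the *estimators and conventions* — axis fitting,
angle arithmetic, circular statistics, RDF normalisation, frame
accounting — under known truth. It says nothing about force fields,
sampling convergence, helix flexibility (the generator's helix is rigid;
`rms_fit`-based unwinding detection is exercised by separate bent-helix
fixtures in the tests), lipid structure, or correlated water dynamics.
Published tilt tables from real simulations are used only as realistic
set-points for recovery, never as values this package claims to
reproduce from physics.

## Problem sizes used in validation

Recovery tests analyse 10,000-frame synthetic trajectories (the sample
size at which such angle statistics are conventionally quoted) with a
reduced water count, since tilt/azimuth recovery does not involve the
waters; hydration and exposure tests use 10–150 frames with 300–2,000
waters, which bounds the Monte-Carlo error at the 3-standard-error
tolerances the tests assert. The reference-construction script uses a
single frame with 500 waters. These sizes are the package's validation
choices; all scale linearly if users want tighter Monte-Carlo bounds.

## Numerical choices and degenerate inputs

- Torsion: atan2-based formula; an error is raised when three
  consecutive points are collinear (undefined plane) rather than
  returning an arbitrary value.
- Tilt at exactly 0° or 90° is handled by clipping |â·n̂| to 1 before
  arccos.
- Histograms cover the full wrap range including empty bins and
  normalise to ∫ = 1 exactly; a bin width that does not divide the range
  is an error, not a silent truncation.
- Leaflet split failure (all P on one side), sub-6-atom P selections,
  empty water selections, atom-count mismatches and non-commensurate
  strides are hard errors with messages naming the offending quantity;
  leaflet offsets outside 10–30 Å and `rms_fit` > 3 Å are warnings
  (physically suspicious, not invalid).
- Frames lacking box information fall back to non-periodic distances
  with a loud log message.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image, no molecule
  re-wrapping, no trajectory superposition.
- The exposure proxy is not SASA and its absolute values depend on the
  water model's density; only within-run comparisons are meaningful.
- `box-density` RDF normalisation depends on the box volume; comparing
  variants simulated in different box sizes requires `plateau` mode or
  explicit care.
- The azimuth definition depends on the chosen Cα quadruple; results
  from different quadruples are not comparable.
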