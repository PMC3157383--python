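# helixmetrics

Trajectory-geometry analysis for single-pass transmembrane (TM) helices in
membrane-protein MD simulations — built around the observables used to
characterise the thrombopoietin-receptor (MPL) TM domain and its
disease-associated mutants (S505N/A, W515L/K): helix **tilt**, azimuthal
**rotation**, residue **hydration**, and intracellular-domain
**membrane contact**. It ships a synthetic helix-in-bilayer trajectory
generator with exact ground truth, so every stage of the pipeline is
verifiable at desk scale without cluster-size MD runs.

## What it computes

For each variant trajectory (PDB topology + DCD or multi-model PDB
coordinates), windowed and strided by the standard conventions (last
100 ns, 10 ps sampling for angle series and RDFs, 100 ps for azimuth
histograms):

- **Membrane frame** — per-frame bilayer midplane, oriented unit normal
  **n̂**, and leaflet phosphorus-plane offsets, from lipid P atoms
  (`fixed-z` or plane-`fitted` mode).
- **Tilt angle** — θ = arccos |**â** · **n̂**| ∈ [0°, 90°], where **â** is
  the SVD-fitted axis through the TM Cα atoms (residues 490–512 by
  default). Reported as linear mean (SD) per variant.
- **Azimuthal angle** — rotation of the TM helix about the membrane
  normal relative to the intracellular (IC) domain, measured as the IUPAC
  dihedral over four chosen Cα atoms, in (−180°, 180°]. Summarised with
  circular statistics: circular mean, mean resultant length
  R̄ ∈ [0, 1], circular SD √(−2 ln R̄), plus an explicit
  "weakly concentrated" flag when R̄ < 0.2 (near-uniform rotation, as a
  charged W515K-like TM helix shows).
- **Hydration RDF** — g(r) between a residue's Cβ and the water oxygens
  under the minimum-image convention, a burial measure for key residues
  (491/505/515 by default), with first-shell coordination numbers.
- **IC region metrics** — minimum distance of labelled IC regions (e.g.
  the JAK-binding Box1 motif) to the nearer leaflet plane, and a
  solvent-exposure proxy (waters within 4 Å of the region).

## Worked example

Generate a two-variant synthetic panel (a concentrated "WT-like" system
and a uniform-azimuth, packed-Box1 "W515K-like" system), then analyse it:

```yaml
# panel.yaml
variants:
  - label: WT
    spec:
      n_frames: 1000
      dt: 10.0
      n_waters: 500
      seed: 1
      tilt_distribution: {mean_deg: 27.6, sd_deg: 7.0}
      azimuth_distribution: {mean_deg: 0.0, sd_deg: 15.0}
  - label: W515K
    spec:
      n_frames: 1000
      dt: 10.0
      n_waters: 500
      seed: 2
      tilt_distribution: {mean_deg: 25.1, sd_deg: 7.5}
      azimuth_distribution: {uniform: true}
      ic_domain: {mode: packed}
```

```yaml
# run.yaml
variants:
  - {label: WT,    topology: panel/WT.pdb,    trajectory: panel/WT.dcd}
  - {label: W515K, topology: panel/W515K.pdb, trajectory: panel/W515K.dcd}
key_residues: [491, 505]
azimuth_quad:
  - {residue_number: 521}
  - {residue_number: 522}
  - {residue_number: 523}
  - {residue_number: 524}
regions:
  - {label: Box1, residue_range: [525, 528], atom_scope: CA-only}
window: last 8 ns
strides: {angles: 10, azimuth_histogram: 100}
```

```bash
helixmetrics generate-panel --config panel.yaml --out panel
helixmetrics run --config run.yaml --out report
```

`report/tilt_table.tsv`:

```
variant	mean_deg	sd_deg	n
WT	27.9	6.7	800
W515K	24.7	7.3	800
```

The analysed tilt means recover the generator set-points (27.6° and
25.1°) within sampling error of the 800 frames in the 8-ns window.

`report/azimuth_table.tsv`:

```
variant	circular_mean_deg	linear_mean_deg	resultant_length	weakly_concentrated	n
WT	-0.3	-0.4	0.967	False	800
W515K	103.6	4.2	0.009	True	800
```

WT's rotation is tightly concentrated about its 0° set-point
(R̄ = 0.967); the W515K-like variant spreads over the full circle
(R̄ = 0.009), so its circular mean is flagged as unreliable — printing a
single average for such a distribution would be meaningless.

`report/region_metrics.tsv`:

```
variant	region	mean_min_membrane_distance_A	mean_exposure	n
WT	Box1	6.46	0.81	800
W515K	Box1	3.68	0.00	800
```

The "open" WT Box1 loop sits in solvent (0.81 waters in contact on
average); the packed variant's loop is buried against the membrane and
completely dehydrated.

Single analyses are also available directly
(`helixmetrics tilt|azimuth|rdf TOPOLOGY TRAJECTORY ...`), and the whole
pipeline can be driven from Python via
`helixmetrics.run_analysis(RunConfig(...))`.

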