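# Methods

## Scope and model

The package analyzes trajectories of a two-fold symmetric membrane-protein
dimer for asymmetric conformational switching at its two composite
nucleotide-binding sites. It does not produce trajectories: simulation
setup, force fields and integrators are out of scope. Input is a
multi-model PDB per run (coordinates in Å), a manifest with per-run
metadata (lipid, nucleotide, duration, frame interval), and a motif map
assigning the functional residues of each monomer (Q-loop Q422/D423,
Walker-B E503/D502, signature-adjacent K483, x-loop E473/R474, switch
H534, D-loop D509, coupling loops CL1/CL2, the TMD-interface residues
H204/Q200/Q208, the MgATP ligand and Mg²⁺) to chain + residue-number
selections.

Internally coordinates are Å, times ps; nanoseconds are converted at
interfaces. A trajectory is a shared atom topology plus an
`(n_frames, n_atoms, 3)` array, so per-frame geometry is vectorized.

## Geometric primitives

**Contacts.** The contact number of two disjoint atom groups is the
number of atom pairs strictly closer than the cutoff (default 4.0 Å).
The strict inequality is deliberate: a pair at exactly 4.000 Å is not a
contact. All atoms present in the model are counted (the source models
carry polar hydrogens only); a heavy-atoms-only switch exists. Groups up
to 10⁴ candidate pairs use an all-pairs distance matrix; larger problems
use a KD-tree neighbour query whose inclusive ball radius is re-tested
with the same strict inequality, so both paths agree bit-exactly on
integer counts. Contacts are computed on unwrapped coordinates with no
minimum-image convention — intra-protein distances here are far below
half of any realistic box edge, and a box-aware mode is out of scope.

**Hydrogen bonds.** (Donor, hydrogen, acceptor) triples with
d(D,A) ≤ 3.5 Å and an angle ≤ 30° between the D→A and D→H vectors,
measured at the donor. Both thresholds are inclusive (a "maximum" is
attainable), in contrast to the strict contact cutoff.

**Axis projections.** The z-position of a residue is the projection onto
the symmetry axis (a unit vector, +z by default) of the geometric centre
of its side-chain terminal atom group (guanidinium for Arg, imidazole for
His, …); selections without table entries fall back to all selected
atoms. Which direction along the axis points toward the TMDs is a motif-
map parameter (+z default).

**RMSD.** Per-frame least-squares rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) of the Cα subset onto
frame 0, then the root-mean-square deviation. By default the fitting set
equals the measured set; an optional `fit_spec` fits on a different
selection (e.g. the whole protein) before measuring a domain — both
readings of "per-domain RMSD" are available, per-domain fit being the
default. Frame 0 reports exactly 0. Fewer than three atoms or a collinear
reference raise errors (the rotation is degenerate there).

## Paired-site analysis

The interaction set is assembled from the motif map under the composite-
site rule: at the site owned by monomer X, the signature lysine, D-loop
aspartate and coupling loop CL2 come from the *other* monomer. Six
interactions are tracked: MgATP–Q422 and E503–H534 (intra-monomer),
H534–D-loop, D423–K483, D423–R474 and D423–CL2 (inter-monomer).

Contact series of one interaction at the two sites, sampled on a 50-ps
grid (a frame is used for a grid tick when it lies within half a frame
interval of it), form a paired series. From it:

- **Scatter density**: an integer-binned 2-D histogram (site A on one
  axis, site B on the other), Gaussian-smoothed with σ = 1 count-bin, and
  contour polylines at {0.8, 0.6, 0.4, 0.2, 0.1} of the density maximum
  (extracted with `skimage.measure.find_contours`; no figures are
  rendered, only data). A single reference frame — e.g. a crystal
  structure — can be evaluated to a reference point on the same axes.
  The smoothing bandwidth and contour ladder are package choices; only
  qualitative agreement with visual scatter inspection is claimed.
- **Asymmetry index**: over frames with c_A + c_B > 0, the mean of
  |c_A − c_B| / (c_A + c_B). Frames where both sites have zero contacts
  carry no information and are excluded (reported as
  `n_informative_frames`); an all-zero series scores 0. The index is the
  package's formalization of "off-diagonal scatter mass": bounded in
  [0, 1], zero exactly for identical series, one exactly for mutually
  exclusive engagement. Visual scatter inspection defines no number; this
  choice makes asymmetry comparable across interactions and runs.

## Switch timelines

Contact series are averaged over half-open 1-ns windows covering the
sampled range; a trailing window the trajectory does not fill is kept but
flagged partial (and excluded from recovery tests). Window means map to
states:

| switch | states | thresholds |
|---|---|---|
| MgATP–Q422 | LOW / MID / HIGH | < 5, 5–14, > 14 mean contacts |
| D423–R474, D423–K483 | OFF / ON | 1 |
| D423–CL2 | OFF / ON | 8 |
| R474 stacking | A-closer / B-closer / side-by-side | &#124;Δz&#124; > 2 Å |

Boundary handling must be total although the printed level definitions
use strict inequalities on both sides: a mean exactly at 5 or 14 falls to
MID, a mean exactly at a binary threshold falls to ON, and stacking keeps
the strict "> 2 Å" as printed. The stacking state compares the window
means of the two monomers' R474 z-positions; the monomer whose z lies
further toward the TMD direction is "closer".

## Synthetic-data generator

The generator is the package's ground-truth source. `build_toy_dimer`
constructs a two-chain dimer whose chains are exact mirror images (180°
rotation about z, chain labels swapped), so both composite sites are
perfectly equivalent before anything is planted. Each tracked interaction
occupies an isolated *station*: a grid (6 Å spacing) of slot-atom pairs
in which partner m sits directly above partner m at 6 Å vertical
separation (no contact) or 3 Å (contact). Stations are ≥ 10 Å apart and
cross-slot distances are ≥ 6 Å, so the realized contact count of a
station equals exactly the number of closed slots. Station capacities
(20 slots for MgATP–Q422, 18 for D423–CL2, 12 for the dyad, 6 for the
charge pairs) leave headroom above every planted level. Residues that
serve several interactions (D423, H534, R474) have atoms at several
stations; the geometry is kinematic bookkeeping, not a physical shape,
and no force field or energetics is involved.

`generate_trajectory` realizes a *switch schedule* — per switch and site,
segments of (start ns, end ns, target) covering the run. Targets are
state names mapped to counts placed ≥ 2 counts inside every
discretization bin (LOW→2, MID→9, HIGH→17 for Q422; ON→3/OFF→0 at
threshold 1; ON→12/OFF→4 at threshold 8) or raw integers. Per frame the
realized count is the target plus integer-rounded Gaussian noise
(`noise_sd`, default 0.5 contacts in the canned scenarios), clipped to
the station capacity; a target exceeding capacity raises an error naming
the switch. Stacking targets move the two arginine terminal groups by
±δ/2 (δ = 3 Å planted) along z; waters and stacked groups get small
positional jitter (0.1 Å). Frames run from 0 to the duration *inclusive*
at 50-ps intervals (a 40-ns run has 801 frames), so snapshot times like
"40 ns" exist; the final schedule segment is closed at its end to cover
the last frame.

All randomness descends from one seed through `numpy.random.SeedSequence`
spawning, one child stream per (switch, site) plus one each for stacking
and water jitter — sub-streams are independently reproducible, and
removing one switch from a schedule does not change any other switch's
counts.

What the generator emulates: per-window contact levels, their noise, site
exclusivity, stacking along the axis, and explicit waters for snapshot
export. What it does not: physical protein geometry, correlated
fluctuations, drift, periodic boundaries, or realistic water structure.
Passing the recovery suites therefore demonstrates correctness of the
*measurement machinery* under known dynamics — not that real trajectories
are this clean.

Canned scenarios: a fully symmetric schedule; an all-off schedule
(emulating the disengaged nucleotide-free/ADP behaviour of the tracked
contacts); an asymmetric-switching reference scenario (Q422 climbing
through its three levels at one site, the charge pair alternating between
sites at half-time, CL2 engaging late at one site, stacking flipping at
half-time); and an exclusivity schedule that makes each 1-ns window
exclusive with probability α for index-recovery studies.

## Ensemble pipeline

The pipeline loads every manifest run, computes all paired series,
asymmetry indices and timelines, and pools by nucleotide: MgATP repeats
are collated into one group (a lipid-control run is treated as an
additional repeat, matching the observation that the lipid change leaves
the cytosolic analysis unaffected), ADP controls are analyzed identically
but never pooled with MgATP. Total simulated time per group is the sum of
manifest durations. Outputs are tidy CSVs with fixed float formatting and
fixed ordering, so identical inputs give byte-identical files. Any stage
failure aborts with the run id and stage named.

The study conditions reproduced by the analysis drivers and the
acceptance script are six 40-ns DPPC runs plus one 30-ns POPC run with
MgATP (270 ns pooled) and two 30-ns ADP controls, frames every 50 ps.

## Snapshot export

`write_snapshots` exports selected times as a multi-model PDB containing
the protein, the ligand, and exactly the n water residues (residue names
HOH/SOL/WAT) closest to the ligand, ranked per snapshot by minimum
atom–atom distance with ties broken by ascending residue number. Atoms
are written in fixed-column PDB v3.3 (occupancy 1.00, B-factor 0.00) in
canonical chain-grouped order, which makes write∘read the identity on
coordinates at the format's 3-decimal precision. The synthetic waters are
placed at 1-Å radius increments so the ranking is stable under jitter.

## Numerical choices and edge cases

- Exact-cutoff ties: 4.0 Å is not a contact (strict); H-bond thresholds
  are inclusive; stacking is strict; discretization boundaries fall MID /
  ON as above.
- Stride sampling and snapshot lookup both use a half-frame-interval
  tolerance.
- Selections resolve deterministically in topology order; empty
  resolutions raise, as do models with mismatched atom identity (the
  error names the model).
- Multi-model PDB carries no time axis: an explicit per-model time list
  or a uniform stride (default 50 ps) supplies it.
- Degeneracy report: positions are flagged where a row differs from the
  reference row; column marks are `*` for identity and `:` / `.` from
  the standard Clustal strong/weak similarity classes (configurable).

## Known limitations

- PDB is the only trajectory format (no XTC/TRR/GRO); this keeps the
  artifact dependency-light and text-only, at the cost of file size.
- No periodic-boundary handling; inputs are assumed unwrapped.
- No kinetic or hidden-Markov modelling of switch transitions, and no
  significance testing of asymmetry — the analyses discretize and
  describe, they do not test.
- Published per-domain RMSD values from real transporter simulations
  cannot be reproduced here, since such trajectories are generally not
  deposited; only the RMSD methodology is provided and validated on
  constructed fixtures.
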