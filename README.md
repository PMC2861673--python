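# dimerswitch

Contact-based detection of **asymmetric conformational switching** in
molecular-dynamics trajectories of homodimeric ABC transporters.

## The problem

ABC exporters such as Sav1866 are homodimers: two identical halves form two
composite nucleotide-binding sites (NBSs) at the NBD–NBD interface, each
assembled from the Walker motifs and Q-loop of one monomer plus the
signature sequence and D-loop of the *other*. Yet ATP hydrolysis at the two
sites is sequential, not simultaneous — which requires the initially
symmetric dimer to break symmetry, at least transiently. This package
provides the trajectory-analysis machinery to resolve that symmetry
breaking from atomic coordinates:

- **Atomic contact counting.** The contact number of two residue groups in
  a frame is `|{(a, b) : d(a, b) < 4 Å}|` — a strict cutoff, counted over
  all atom pairs, so it measures both the existence and the strength of an
  interaction.
- **Hydrogen-bond detection** with the geometric criterion
  d(D,A) ≤ 3.5 Å and acceptor–donor–hydrogen angle ≤ 30°.
- **Paired-site asymmetry analysis.** Contact series of one interaction at
  the two NBSs, sampled every 50 ps, are plotted against each other as 2-D
  scatter densities with contour lines; off-diagonal mass is asymmetry.
  A normalized index condenses it: over frames with
  c_A + c_B > 0, the mean of |c_A − c_B| / (c_A + c_B) — 0 for identical
  series, 1 for strictly mutually exclusive ones.
- **Molecular-switch timelines.** Contact means over 1-ns windows are
  discretized: the MgATP-sensing glutamine (Q422) into three levels
  (< 5, 5–14, > 14 contacts), the Q-loop aspartate charge pairs
  (D423–R474, D423–K483, threshold 1; D423–CL2, threshold 8) into on/off,
  and the x-loop arginine pair (R474) into a stacking state along the
  membrane normal (stacked when the two z-positions differ by > 2 Å).
- **Cα RMSD** versus the starting structure after least-squares rigid
  superposition, per domain.
- **Ensemble orchestration** over a run manifest (lipid, nucleotide,
  duration per run), pooling MgATP repeats and keeping ADP controls
  separate, plus a degeneracy report that flags substitutions in aligned
  NBD motifs.

Because published trajectories of this kind are generally not deposited,
the package ships a first-class **synthetic-data generator**: a toy
homodimer with exact mirror symmetry about the z axis whose contact
dynamics follow a planted per-window switch schedule, realized
*geometrically* (atoms move across the 4 Å boundary), so every analysis
stage can be validated against ground truth.

## Worked example

```sh
python analysis/01_generate_ensemble.py   # 9 synthetic runs -> scratch/ensemble
python analysis/02_ensemble_analysis.py   # pipeline -> scratch/ + results/
python analysis/03_switch_timelines.py    # per-window timelines -> results/
python analysis/04_degeneracy.py          # motif degeneracy -> results/
```

Step 02 prints, for the seven pooled MgATP runs (six DPPC + one POPC
repeat, 270 ns total) and the two ADP controls:

```
== group accounting ==
  ADP: 2 runs, 60 ns total
  MgATP: 7 runs, 270 ns total

== pooled asymmetry indices (MgATP group) ==
  MgATP-Q422   intra_monomer  index = 0.591  (5407 informative frames)
  E503-H534    intra_monomer  index = 0.045  (5407 informative frames)
  H534-Dloop   inter_monomer  index = 0.920  (5407 informative frames)
  D423-K483    inter_monomer  index = 0.919  (5407 informative frames)
  D423-R474    inter_monomer  index = 0.696  (2514 informative frames)
  D423-CL2     inter_monomer  index = 0.339  (5407 informative frames)
```

The planted scenario engages the high-contact Q422 binding mode, the
inter-NBD D423–K483 charge pair and the D-loop contact at one site only,
so those interactions score high asymmetry; the catalytic dyad E503–H534
is engaged symmetrically and scores near zero (the 0.045 is residual count
noise). In the ADP controls every index is 0. Step 03 renders the
per-window timeline of each run, e.g. for `dppc_1`:

```
  D423-K483    NBS_A  ####################....................
  D423-K483    NBS_B  ....................####################
  MgATP-Q422   NBS_A  LLLLLLLLLLMMMMMMMMMMHHHHHHHHHHHHHHHHHHHH
  MgATP-Q422   NBS_B  LLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLL
  R474 stack   axis   ====================BBBBBBBBBBBBBBBBBBBB
```

— the charge pair alternates between the sites at 20 ns, Q422 climbs
through its three contact levels at site A only, and the R474 pair stacks
with monomer B toward the TMDs in the second half.

The same functionality is exposed as a CLI:
`dimerswitch generate|analyze|timeline|degeneracy --help`.

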