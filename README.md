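# hairpinpath

Trajectory analysis of the α-helix → β-hairpin conformational transition of
short peptides, built around the N-terminal 12 residues of human
α-synuclein (α-syn12, `MDVFMKGLSKAK`) — an amyloidogenic fragment whose
transition to β structure is an early event in aggregation. The package is
for structural-bioinformatics and molecular-simulation users who want to
ask, for a folding trajectory: *does the β-turn form before the
inter-strand hydrogen bonds (a turn-directed "zipper"), or do the bonds
come first?*

## What it computes

Given a backbone trajectory (or a synthetic one with a programmed
mechanism), the pipeline produces:

- **Conformational clustering** (Daura neighbor-count algorithm): frames
  are neighbors when their Cα RMSD after optimal rigid superposition
  (Kabsch) is below 0.1 nm; the center of the largest cluster is the *most
  clustered structure*.
- **Geometric annotation**: a backbone hydrogen bond `HB_d-a` (amide N–H
  of residue *d* donating to carbonyl O of residue *a*) is present when
  d(H···O) < 0.25 nm **and** ∠(N–H···O) > 135°; a β-turn `Turn_(i+3)-i`
  when d(Cαᵢ, Cαᵢ₊₃) < 0.7 nm with non-helical inner residues. Per-residue
  turn/strand propensities, and STRIDE/DSSP report import.
- **A discrete reaction coordinate**: per frame, X = RMSD_Cα from the most
  clustered structure; Y ∈ {−1, 0, 1…n} with −1 = turn absent, 0 = turn
  present but none of the *n* native bonds, k = turn plus k bonds.
- **Free-energy surface** F(X, Y) = −kT ln P(X, Y) at T = 300 K
  (kT = 2.494 kJ·mol⁻¹), with strict-local-minimum detection and
  rectangular basin labeling.
- **Mechanism statistics**: occurrence probabilities, the discriminating
  conditional P(H-bond | turn absent) — identically zero for a zipper
  mechanism — and basin-to-basin transition-path probabilities
  (U1→F, U2→F, U1→U2→F, …).

Two condition presets carry the native definitions: *physiological*
(Turn_9-6 with HB_9-6, HB_6-9, HB_11-4, HB_4-11) and *acidic* (Turn_8-5
with HB_8-5, HB_5-8, HB_10-3, HB_3-10, HB_12-1).

The `synthetic` module generates 12-residue backbone trajectories in which
turn formation, bond formation and basin visits happen in a *programmed*
order (modes `turn_first`, `hbond_first`, `two_path`) with Gaussian
coordinate noise — so every stage of the analysis can be validated against
known ground truth without any MD data.

## Worked example

Simulate a turn-first trajectory of 2000 frames and run the full analysis:

```bash
$ hairpinpath run --mode turn_first --n-frames 2000 --seed 1 --out demo
verdict: turn precedes H-bonds
artifacts in demo/ (report.json, CSVs, most_clustered.pdb)

$ hairpinpath annotate --mode turn_first --n-frames 2000 --seed 1 --out demo
Turn_9-6: occupancy 0.732; HB_9-6: 0.576, HB_6-9: 0.576, HB_11-4: 0.425, HB_4-11: 0.425

$ hairpinpath fes --mode turn_first --n-frames 2000 --seed 1 --out demo
minimum at (0.01 nm, +4): 0.0 kJ/mol
minimum at (0.65 nm, -1): 0.9 kJ/mol
minimum at (0.68 nm, +0): 2.2 kJ/mol
minimum at (0.15 nm, +2): 2.6 kJ/mol
```

Reading the output: the turn is present on 73% of frames and each native
bond on fewer — bonds only exist while the turn holds. The free-energy
surface has its global minimum at (0.01 nm, +4): the folded hairpin with
all four bonds, right at the most clustered structure. The basin at
(0.65 nm, −1) is the unfolded helix (turn absent), (0.68 nm, 0) the
turn-formed-but-unbonded intermediate, and (0.15 nm, +2) the partially
bonded intermediate. `demo/conditionals.csv` shows
P(HB | Turn_9-6 absent) = 0.0 for every bond over 537 turn-free frames —
the zipper signature behind the verdict.

The same stages are available as library calls (`run_pipeline`,
`cluster_daura`, `build_fes`, `conditional_hbond_given_no_turn`, …); the
CLI subcommands are thin wrappers that read and write a shared run
directory, and composing them reproduces `hairpinpath run` byte for byte.

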