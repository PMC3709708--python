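# Methods

## The analysis model

The pipeline treats a peptide trajectory as an ordered set of backbone
snapshots (N, H, Cα, C, O per residue; residue 1 carries no amide
hydrogen) and characterizes the helix→hairpin transition through five
stages, each a pure function of the coordinates:

1. **Superposition metric.** Conformational distance is the Cα RMSD after
   least-squares rigid superposition. The rotation is the Kabsch SVD
   solution with a determinant sign correction so reflections are never
   chosen. A fully independent Horn quaternion-eigenvalue implementation
   is kept in the package as a cross-check; the two agree to 1e-10 nm on
   random inputs. Pairwise matrices are computed in blocks with a
   batched SVD; the contract (tested) is bit-level agreement with the
   per-pair route. Note one numerical asymmetry: the per-pair route
   computes the RMSD from explicit coordinate differences (exactly 0 for
   identical frames), while the batched route uses the trace formula,
   whose cancellation error leaves residuals of order 1e-8 nm.

2. **Annotation.** A hydrogen bond `HB_d-a` is present iff
   d(H···O) < 0.25 nm and ∠(N–H···O) > 135°, both strict, matching the
   convention of GROMOS-family analysis tools. Secondary structure uses a
   transparent geometric assigner over {H, E, T, C} with precedence
   H > E > T > C: helix needs (φ, ψ) within ±30° of (−57°, −47°) across a
   three-residue window; strand needs β-region dihedrals
   (φ ∈ [−180°, −45°], ψ ∈ [90°, 180°] ∪ [−180°, −150°]) plus a non-local
   backbone H-bond within two residues; a turn window i..i+3 needs
   d(Cαᵢ, Cαᵢ₊₃) < 0.7 nm with non-helical inner residues. The 0.7 nm
   cutoff and the dihedral windows are standard β-turn/helix definitions;
   they are defaults, overridable per call. Knowledge-based assigners
   (STRIDE, DSSP) are not reimplemented — their per-residue reports are
   first-class inputs instead, reduced to the same alphabet (DSSP
   bend-like codes map to C and are tallied separately). A `Turn_j-i`
   track from external assignments requires all four window residues
   labeled T; the native criterion is the geometric window test.

3. **Clustering.** The Daura neighbor-count algorithm with a strict
   0.1 nm cutoff: the frame with the most neighbors becomes a center, it
   and its neighbors are removed, repeat. Ties break toward the lowest
   frame index, and clusters are relabeled so id 1 is the most populated.
   The algorithm is deliberately the same one the GROMOS/GROMACS
   toolchain defaults to, so "most clustered structure" means the same
   thing here as in that ecosystem. For large frame sets the pipeline
   subsamples evenly to `cluster_max_frames` (default 2000) before
   building the O(n²) matrix; the RMSD series against the chosen center
   is always computed on the full trajectory.

4. **Discrete landscape.** Frames are encoded as (X, Y) with X the RMSD
   to the most clustered structure and Y the turn/bond code (−1 turn
   absent; else the count of native bonds present, 0..n). F = −kT ln P
   over X bins (default width 0.01 nm, matching the 2-decimal precision
   at which minima are conventionally reported) × categorical Y levels;
   kT = R·T with R = 0.0083145 kJ·mol⁻¹·K⁻¹ and T = 300 K. Unsampled
   bins are flagged, not set to +∞, and exported as "NA". A local
   minimum is a sampled bin strictly below all sampled 8-neighbors —
   plateaus therefore contain no minima, a documented tie rule. Basins
   are axis-aligned rectangles; defaults are ±0.05 nm around minima at
   their exact Y level (the generator supplies tighter, template-derived
   rectangles for synthetic runs). Scale invariance (duplicating every
   frame leaves F unchanged) is the tested normalization property; note
   that *adding* a constant count to every bin is not a pure shift of F,
   since it changes probability ratios.

5. **Mechanism statistics.** Occurrence probabilities are per-track
   means, reported per trajectory and pooled. The discriminating
   statistic is P(H-bond | turn absent): a turn-directed (zipper)
   mechanism forces it to zero because bonds only exist while the turn
   holds; the verdict "turn precedes H-bonds" requires every defined
   conditional below 0.01. Conditioning sets of size zero are flagged
   undefined, never reported as 0. Transition paths are counted on
   basin labels: the label series is compressed (unassigned dropped,
   repeats collapsed) and each maximal segment from an unfolded basin to
   the folded one is one event, matched against a six-path catalog
   (U1→F, U2→F, U1→U2→F, U2→U1→F, and the two no-fold interconversions);
   non-folding inter-basin moves in the trailing stretch count as
   no-fold events, unmatched sequences as "other". This segmentation is
   a convention of this package — the catalog and a first-passage-only
   mode are configurable precisely because other conventions are
   defensible.

## The synthetic-data generator

Real microsecond MD of this system is not reproducible at desk scale, so
the generator stands in for it with trajectories whose mechanism is known
by construction. Conformations live in dihedral space: every frame is
rebuilt from ideal bond lengths/angles by natural-extension-reference-
frame construction, so all frames — including any dihedral-interpolated
ramp — are chemically sane backbones (bond lengths exact by
construction; tested within 5%).

Per condition, five templates are fit by constrained least squares over
(φ, ψ) with a deterministic multi-start fallback: an ideal α-helix
(−57°, −47°); the full hairpin (turn plus every native bond satisfied
with margin: d < 0.235 nm, angle > 150°); a turn-only intermediate
(distorted turn, strands splayed, every bond absent with margin); a
partially bonded intermediate (turn-closing pair formed, outer strand
ends held ≥ 0.8 nm apart so the conformation sits well off the folded
structure on the RMSD axis); and an open-loop state (outer-ladder bonds
formed, turn held ≥ 0.78 nm open) used by the hbond-first mode.
Construction fails loudly if any margin cannot be met, and the finished
templates are re-validated through the package's own annotators.

A `MechanismScript` is a schedule of template dwells. Presets:
`turn_first` cycles helix → turn-only → partial → folded (no bond
geometry exists on any turn-absent frame, so the zipper conditional is
exactly zero); `hbond_first` cycles helix → open-loop → folded (outer
bonds present while the turn is absent); `two_path` realizes a chosen
number of folding events (default 200 in 5000 frames) routed through the
turn-only basin U1 or the partial basin U2 with a programmed mixture.
Dwell lengths are drawn from the script seed; template switches are
instantaneous by default (`ramp_frames=0`), which makes every scheduled
onset exact — the optional linear dihedral ramp exists for visually
continuous trajectories and makes ground-truth labels approximate only
inside the ramp windows.

Isotropic Gaussian noise (default σ = 0.005 nm, per-atom norm truncated
at 3σ) is added in Cartesian space after the rebuild. The default was
chosen from the geometric margins: the closest non-bond contact in the
helix (O of residue i to amide H of residue i+3, 0.27 nm / 109°) must stay outside the detection
criteria, and template bonds must stay inside them. At σ = 0.005 every
detected track agrees with the programmed truth on ≥ 99% of frames; at
σ = 0.01 the backbone-dihedral jitter (±30–50°) starts to break the
±30° helix window on a few percent of helix frames, faking turns, and
the tightest bond angles flicker — agreement then degrades to ~95–99%
per track. This is a property of single-snapshot Cartesian noise against
hard geometric thresholds, not of the detectors.

What the generator does *not* emulate: force-field energetics, solvent,
kinetic realism (dwell times are scheduled, not thermodynamically
consistent with basin depths), side chains, and the conformational
heterogeneity of real unfolded states. Passing tests therefore show that
the analysis recovers a mechanism *when one is present in the geometry*;
they do not show that real MD data would be this clean.

## Problem sizes and defaults

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| H-bond distance / angle | 0.25 / 135 | nm / deg | GROMOS-style criterion, strict inequalities |
| Turn Cα cutoff | 0.7 | nm | standard i..i+3 turn compactness |
| Cluster cutoff | 0.1 | nm | mutual-RMSD cluster criterion |
| FES bin width (X) | 0.01 | nm | minima reported to 2 decimals |
| Temperature | 300 | K | simulated ensemble temperature |
| Frame spacing | 0.05 | ns | 50 000 conformations per 2 500 ns pair |
| Generator noise σ | 0.005 | nm | margin analysis above |
| Frames per synthetic trajectory | 5 000 | — | desk-scale stand-in for 25 000-frame production runs |
| Mechanism-recovery replicates | 20 seeds × 5 000 frames | — | keeps the full check under a minute |

Constructed-population clustering uses 1 500–2 000 frames so the O(n²)
pairwise stage stays in seconds; populations are programmed by frame
counts (e.g. 1780/2000 = 89%), and the noise (σ = 0.015 nm) keeps the
hairpin cloud within 0.05 nm of its reference, far inside the 0.1 nm
cutoff.

## Numerical and design choices

- All in-memory coordinates are nm; the PDB reader/writer is the only
  Å↔nm conversion site. Residue numbering is 1-based everywhere a user
  sees it; atom indices are internal and 0-based.
- Amide hydrogens missing from input PDBs are reconstructed 0.1 nm from
  N in the peptide plane (bisector rule, equivalent to anti-to-carbonyl
  for trans peptides) and flagged on their atom records.
- The frame-array text dialect stores floats at %.17g, so float64
  round-trips bit-exactly; PDB round-trips to 1e-3 nm (format
  precision).
- Daura clustering on arbitrary matrices is not permutation-equivariant
  when neighbor-count ties span clusters (ties break by frame index);
  on well-separated groups the partition is order-independent, which is
  the tested property.
- Template fitting is deterministic: fixed internal seed, staged least
  squares (the turn window is held during the first stage of the
  hairpin fit so strand alignment cannot trade away the closing bonds),
  wide multi-start only on failure.
- Two-path basin regions come from the generator (template RMSD ± 0.08
  nm at the programmed code level) rather than from FES minima, so path
  counting does not depend on histogram resolution.

## Known limitations

- The native secondary-structure assigner is a geometric approximation,
  not STRIDE: agreement is exact on ideal fixtures but will differ on
  borderline real conformations (as STRIDE and DSSP differ from each
  other). Externally computed assignments are the recommended route for
  real data.
- Transition-path probabilities depend on the event segmentation
  convention documented above.
- No periodic-boundary imaging: MD input must be whole-molecule.
- The acidic open-loop template satisfies detection geometry but places
  one H···O contact unphysically close (no energetics in the model);
  it is a labeling device, not a physical intermediate.
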