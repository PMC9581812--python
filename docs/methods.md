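# Methods

## The model

`cookesim` simulates implicit-solvent self-assembly of a 3-bead lipid and a
42-bead amphipathic peptide. Hydrophobicity is encoded pairwise: beads are
hydrophilic (H) or hydrophobic (T), and T–T pairs attract when at least one
partner belongs to a lipid. There are no water particles; the solvent's
effect is folded into that attraction.

All internal quantities are reduced: the bead diameter σ is the length
unit, the attraction depth ε the energy unit, and the (uniform) bead mass
m the mass unit. The physical mapping is σ = 0.6 nm, ε = 1 kcal/mol,
m = 100 amu, giving a time unit τ = σ√(m/ε) ≈ 2.933 ps and a thermal
energy kT/ε ≈ 0.616 at 310 K.

### Interactions

* **Excluded volume** — Weeks–Chandler–Andersen (truncated-shifted LJ):

  V_rep(r; b) = 4ε[(b/r)¹² − (b/r)⁶ + ¼] for r ≤ r_c = 2^{1/6} b, else 0,

  with b_HH = b_HT = 0.95 σ and b_TT = σ. The smaller head keeps the lipid
  cylindrical.

* **Hydrophobic attraction** — a plateau −ε for r < r_c ramped to zero by
  −ε cos²[π(r − r_c)/(2 w_c)] over r_c ≤ r ≤ r_c + w_c. w_c = σ for
  lipid–lipid and lipid–peptide T–T pairs and 0 otherwise; in particular
  peptide–peptide attraction is zero (the peptide alone must not
  aggregate). The minus sign on the ramp is forced by continuity with the
  −ε plateau and the zero tail.

* **Lipid bonds** — two FENE bonds,
  V = −½ k r∞² ln[1 − (r/r∞)²], k = 30 ε/σ², r∞ = 1.5 σ, acting together
  with the WCA term of the bonded pair (the usual FENE+WCA construction);
  plus a harmonic head–to–second-tail spring ½·10 ε/σ²·(r − 4σ)². Its 4σ
  rest length is unreachable (the chain is ~2σ long), so it acts purely as
  a straightening bias.

* **Peptide rigidity** — the 42 beads form 6 stacked, filled hexagons
  (1 center + 6 vertices per layer, ring radius and layer spacing 0.95 σ).
  A fully connected elastic network (½·30 ε/σ²·(r − r₀)², r₀ from the
  build geometry) joins all 21 intra-layer pairs per layer and all 49
  adjacent-layer pairs: 371 bonds, bead degree 13 on the end layers and 20
  in the middle. Eight beads are hydrophobic: a contiguous 2-vertex stripe
  on one face of the middle four layers (configurable), so the molecule is
  an amphipathic rod with hydrophilic caps — the coarse shape of a
  membrane-bound amphipathic helix.

### Nonbonded exclusions

All intra-peptide nonbonded pairs are excluded. At the reference geometry
every non-network intra-peptide pair is already beyond the WCA cutoff and
peptide–peptide attraction is zero, so the exclusion changes no physics; it
avoids WCA strain *across* the network (rest lengths 0.95 σ sit below the
WCA minimum 2^{1/6}·0.95 σ) and keeps the exclusion test O(1). Lipid
intramolecular WCA stays on.

### Overlap guard

Pair distances are clamped at 0.3 b inside the force kernels before the
r⁻¹² term is evaluated, so transient overlaps from random packing produce a
large finite push rather than an overflow. The scalar API
(`pair_energy_force`) instead raises `OverlapError` below the floor, which
is the right behaviour for configuration checking.

## Dynamics

* **Integrator** — BAOAB splitting of Langevin dynamics (half-kick,
  half-drift, Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick).
  With friction γ = 0 it reduces exactly to velocity Verlet, which is the
  basis of the thermostat-off energy-conservation oracle in the tests
  (drift < 10⁻⁴ ε over 10⁴ steps at dt = 0.1 fs). Production parameters:
  dt = 10 fs, γ = 1 ps⁻¹, NVT at 310 K.
* **Neighbor search** — Verlet list with a 0.5 σ skin over the largest
  interaction range (2^{1/6} σ + σ ≈ 2.12 σ), rebuilt when any bead has
  moved more than skin/2; the list is filled by a cell decomposition when
  the box is at least three list-cutoffs wide, otherwise by an all-pairs
  scan (with a warning). Positions are wrapped at rebuild time; all
  distances, bonded terms included, use the minimum image.
* **Determinism** — one seeded generator (numpy SFC64) drives thermostat
  noise; replica seeds are base_seed + replica index. Same seed, same
  single-threaded trajectory, bit for bit.
* **Preparation** — random packing (below), FIRE energy minimization with
  per-bead step caps of 0.05 σ (FENE bonds can never jump past r∞), then
  staged Langevin equilibration with the timestep ramped ×10 per stage,
  0.01 → 0.1 → 1 → 10 fs, 10⁴ steps per stage by default.
* **Masses** — uniform (100 amu). NVT equilibrium statistics are
  mass-independent; the value only calibrates the time axis.

## System construction

The cubic box edge follows from the lipid molarity alone,
L = (n_lipids/(N_A c))^{1/3}; peptides are added on top and do not count
toward the concentration. Molecules are placed by rejection sampling —
random position, uniform random orientation (Shoemake quaternions), accept
when no bead comes within 0.8 σ of another molecule under minimum image.
This replaces an external packing tool; packing is a convenience here, not
a method.

## Analysis

* **Clustering** — single linkage over *hydrophobic* beads at 0.9 nm
  (1.5 σ), connected components mapped up to molecules. Restricting to tail
  beads avoids spurious merges when aggregates merely graze each other.
* **Aggregates** — clusters of ≥ 5 molecules. Per aggregate: all-bead
  radius of gyration (label **disc** iff Rg ≥ 2.5 nm, else **micelle**) and
  a size metric = mean extent along the two leading principal axes of the
  member beads, which approximates the diameter of a sphere or a flat disc
  (Rg does not). Aggregate coordinates are first unwrapped: each molecule
  is made whole, then molecules are placed nearest-first by minimum image
  relative to already-placed centroids — valid because aggregates are
  compact relative to the box.
* **Free lipids / CMC** — lipids outside every ≥ 5-molecule aggregate count
  as free (sub-threshold clusters are free); this is the only closure in
  which every lipid is free or in exactly one aggregate. The free-lipid
  concentration is averaged over an equilibrated window (default: final
  third of the frames). The CMC is the plateau of that quantity — across
  system sizes at fixed total concentration (largest system wins; small
  systems are flagged artificially low) or across total concentrations at
  fixed size (mean over concentrations ≥ 2 mM where stable aggregates
  form).
* **Ergodic measure** — mean over replica pairs of [n_i(t) − n_j(t)]² for
  the aggregate count n(t); decay to a small plateau indicates replica
  convergence. An across-replica variance variant is also exposed.
* **Size distributions** — histogram of lipids per aggregate, Gaussian fit
  by sample mean/SD (no truncation correction, so small samples can imply
  negative counts — a known caveat), QQ pairs against the fitted normal,
  and an upper-tail deviation statistic (max excess of the upper-quartile
  order statistics over their Gaussian quantiles): disc formation shows up
  as a long upper tail.
* **Phase diagram** — per (n_lipids, P/L) grid point: *micelle* if every
  aggregate is a micelle, *disc* if all are discs, *mixture* otherwise.
  The finite-size flag marks points with n_lipids < 3 × the preferred
  aggregate size, where the preferred size is the mean lipids per aggregate
  of the largest system at the same P/L — the standard 3× heuristic for
  trusting self-assembly simulations.

## Synthetic fixtures

Self-assembly needs microseconds; the analysis stack is therefore tested on
deterministic idealized constructs with known ground truth: a spherical
micelle (tails inward, Fibonacci-sphere anchors), a flat circular bilayer
patch (disc) with peptides standing on the rim (hydrophobic stripe facing
inward — the "picket fence" arrangement), a planar bilayer, dispersed
monomers, and a planted micelle+disc mixture. The fixtures emulate the
*geometry* the analysis must classify, not the thermodynamics: passing
fixture tests validates clustering, labeling and size metrics, and says
nothing about whether the force field produces such structures — that is
what the self-assembly test is for. The mixture's planted disc needs
≥ ~140 lipids so its all-bead Rg genuinely exceeds the 2.5 nm threshold;
the generator refuses smaller requests rather than plant a mislabeled
truth.

## Problem sizes in the shipped tests

The statistical integrator checks use single beads and bonded pairs over
3×10⁵ steps, compared with closed forms (Maxwell–Boltzmann variance) or a
radial-distribution quadrature (bond-energy mean) at three standard
errors. The self-assembly experiment runs three replicas of 20 lipids +
10 peptides (P/L = 1/2, the fastest-converging composition) at 10 mM for
2×10⁶ steps (20 ns) each — mixed micelles form well within a few times
10⁵ steps, and this composition forms micelles only, so the assertions are
that every replica holds a mixed micelle in its final-third frames and
that no aggregate anywhere is labelled a disc. Mapping out the CMC
(≈ 0.5 mM for the lipid alone) or percent-disc plateaus at intermediate
P/L requires multi-microsecond trajectories of up to 1000 lipids and is
out of scope for the shipped test tier, though the scan and phase-diagram
machinery is implemented and exercised on synthetic inputs.

## Known limitations

* No electrostatics, explicit solvent, or pressure coupling; NVT only.
* The peptide is a rigid geometric proxy — no sequence specificity, no
  internal flexibility beyond the elastic network.
* The hydrophobic-stripe placement is a modelling choice (configurable);
  only its amphipathic character, not its exact pattern, is constrained.
* Kinetics are not physical: the implicit solvent removes hydrodynamics,
  and the Langevin friction sets an arbitrary diffusion scale. Equilibrium
  populations, not rates, are meaningful.
* The disc/micelle label is a single Rg threshold; aggregates near the
  threshold flip labels with thermal fluctuations.

## Checkpointing

`trajio.save_checkpoint` / `load_checkpoint` serialize the full dynamic
state (positions, velocities, box, clock) together with the noise
generator's internal state. A continuation from a checkpoint is exactly
reproducible and consumes the original noise stream where it left off. It
is not bit-identical to the corresponding unsegmented run — neighbor-list
rebuild points (which wrap coordinates at rounding level) differ across a
restart boundary and Langevin dynamics amplifies the difference — but
equilibrium statistics are unaffected.
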