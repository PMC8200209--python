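# Methods

This note documents the models behind `carbsorb`, the parameters that
matter, the synthetic-data generators and what they do and do not emulate,
and the numerical choices made where the design was genuinely open.

## 1. Geometry layer

All coordinates are Cartesian ångström; atom order is authoritative and
never silently changed. Bond perception is distance-based: pair (i, j) is
bonded iff `d ≤ f · (r_i + r_j)` with Cordero covalent radii
(C 0.76, H 0.31, O 0.66 Å) and tolerance factor `f = 1.15` (default;
valid range (1.0, 1.5]). Electron-count parity (sum of atomic numbers
minus net charge) stands in for spin multiplicity: an odd count marks a
radical/non-singlet species. XYZ is written at 6 decimals, PDB (via
biotite) at the format's fixed 3 decimals with occupancy 1.00 / B 0.00;
CRYST1 is emitted for periodic slabs.

## 2. Synthetic structures

### PAH flakes

`build_pah_flake(rows, cols)` lays peri-fused hexagons on a honeycomb
lattice (C–C 1.42 Å, planar, perimeter H at 1.09 Å): the central row holds
`cols` rings, each row outward one fewer. (1, 1) is benzene; the default
(3, 3-4-3 arrangement) yields the C32H14 flake used as the idealized
planar carbon surface — just large enough for an MCHM molecule to lie flat
with a ring of clearance.

### MCHM conformers

`build_mchm(isomer)` constructs an ideal chair cyclohexane (C–C 1.54 Å,
ring pucker ±0.25 Å) with the hydroxymethyl group at C1 and the methyl at
C4, placing substituent atoms by natural-extension (NeRF) placement with
explicit torsions. The 1,4-ring-face convention fixes the isomers: *trans*
is built di-equatorial (the low-strain arrangement), *cis* with the methyl
axial. `classify_mchm_isomer` inverts this robustly: it finds the
six-carbon ring, fits the mean plane by SVD, and compares the plane-side
of the two substituent carbons — same side ⇒ cis. The test is invariant
to puckering and mirror images, as cis/trans assignment must be.

`enumerate_mchm_conformers` scans the backbone torsions (C1–CH2OH and
O–H; optionally methyl) on a grid (default 120°), scores each rotamer
with a deliberately simple surrogate — full Lennard-Jones over atom pairs
separated by more than three bonds — and removes duplicates at heavy-atom
RMSD 0.05 Å after Kabsch superposition. Because O–H and methyl rotations
move no heavy atom, deduplication collapses them: the default grid yields
three distinct conformers per isomer, sorted by strain with the minimum
normalized to exactly zero. The surrogate ranks sterically crowded
rotamers; it is not a force field and its energies are never compared to
published values.

### Amorphous carbon slab

The tight-binding amorphous-carbon model used as the original surface is
not publicly available; `build_amorphous_slab` is an explicit procedural
surrogate matched in dimensions (5×5×3 nm default) and density
(2.0 g/cm³ default, validity range (1.0, 3.6)):

1. fill the periodic box with carbon on layered-graphite template layers,
   the layer count chosen so the carbon mass hits the target density;
2. perturb all positions (Gaussian, σ = 0.12 Å) and kick an `sp3_bias`
   fraction (default 0.3) of sites ±0.5 Å out of their layer — this is
   what produces amorphous-like roughness and mixed coordination;
3. relax with a deterministic push-apart sweep until no C–C pair is closer
   than 1.2 Å;
4. prune chemically impossible carbons (isolated or >4-coordinate in the
   periodic C–C network);
5. cap every carbon with fewer than three carbon neighbours with one H at
   1.09 Å along the mean missing-bond direction, rejecting cap positions
   that would bond to a foreign atom (a cone of fallback directions is
   tried for singly-coordinated carbons; an uncappable dangling carbon is
   deleted and the pass repeats).

The result contains only C and H, every carbon 2–4 coordinate, every
hydrogen exactly one bond, carbon density within 10% of target, and is
bitwise reproducible per seed. At the default spec it holds ~9000 atoms.
What it does **not** emulate: realistic sp²/sp³ bond-order statistics,
ring-size distributions, oxidized surface groups, or thermal equilibration
— a green test against this slab establishes that the *pipeline* behaves
correctly, not that the surface is a faithful GAC model.

## 3. Physisorption engine

The adsorbate:surface potential is vdW-only (electrostatics off, matching
the analysis this reproduces; MCHM carries no charges here). Two
functional forms, selectable per run:

* 12-6 Lennard-Jones with UFF parameters (ε_C 0.105, ε_H 0.044, ε_O
  0.060 kcal/mol; σ_C 3.431, σ_H 2.571, σ_O 3.118 Å), Lorentz–Berthelot
  combination;
* the published buffered 14-7 form. Note: that form gives exactly −ε at
  r = r*, but its true minimum sits at 0.99618 r* with depth 1.00056 ε —
  an accepted property of the published functional form.

Interactions use a hard 12 Å cutoff (no switching function; the
discontinuity is accepted and documented) with in-plane minimum image;
the cutoff must not exceed half the shortest cell length. Pairs closer
than 0.5 Å flag the pose as overlapping but the energy is still returned
(clamped at 10⁻³ Å to stay finite).

Pose sampling is uniform over the central patch (default 0.6 of each cell
vector — the central ~3×3 nm of a 5 nm cell), uniform over rotations, and
uniform in initial height 2.5–4.5 Å above the highest surface atom. The
lowest-strain conformers (up to three) are always included in the sample.

Minimization is a derivative-free pattern search over the six rigid-body
degrees of freedom, initial steps 0.4 Å / 0.15 rad halved whenever a sweep
yields no improvement; only downhill moves are accepted, so the energy
trace is non-increasing by construction. Tolerances: step 10⁻³ Å (and
rad), energy 10⁻⁶ kcal/mol, max 2000 sweeps. A pattern search was chosen
over gradient methods because the hard cutoff makes the energy surface
non-smooth and analytic gradients would buy little for 6 DOF.

Conformer filtering keeps complexes within 7.0 kcal/mol (default) of the
lowest-energy member. The conformer-referenced potential subtracts the
mean of the five lowest adsorbate conformer energies (all, if fewer than
five are supplied; ties broken by stable sort on energy then index).
Binding summaries report per-isomer mean, sample SD (n−1) and count of
the retained poses, and Δε = mean_trans − mean_cis. Sign convention
throughout: E_phys = −E_int, positive = stronger binding.

Cluster carving selects surface atoms within 12 Å (default) of the
adsorbate center of mass, using the nearest periodic images so the
cluster is contiguous; every broken C–C bond is capped with H at 1.09 Å
along the former bond vector. Clusters with odd electron count or nonzero
formal charge are flagged discarded (not raised). Exact cluster/slab
energy agreement holds when cap hydrogens are excluded and the carve
radius is at least the cutoff (plus the adsorbate extent for multi-atom
adsorbates); caps sit on the sphere boundary and would otherwise add tail
energy.

## 4. Desorption kinetics

Temperatures convert as T(K) = T(°C) + 273.15. The isomer rate ratio is
`exp(Δε / k_B T)` with Δε stored nonnegative (the binding-strength excess
of trans); the high-energy fraction is the regularized upper incomplete
gamma Q(3/2, E_a/k_B T), implemented in closed form
`erfc(√x) + (2/√π)√x·e^(−x)` and verified in the test suite against an
independent adaptive-quadrature oracle over the Maxwell–Boltzmann energy
density to ≤10⁻¹⁰ over x ∈ [0, 40].

The published reference table of relative rates is internally consistent
with an *effective* Boltzmann constant ≈5% below the standard value. The
package does not guess the cause; it ships both profiles. The
`paper_effective` profile is produced by `fit_effective_kB` — a
closed-form least-squares fit of 1/k_B to `ln r = Δε/(k_B T)` — calibrated
on the Δε = 8.0 kcal/mol row only (the row with the most leverage); the
fitted value is 1.8863×10⁻³ kcal mol⁻¹ K⁻¹. Held-out cells of the
reference table are then reproduced within 3% (the Δε = 1.3 row deviates
up to 3.4%; that row of the source table implies a slightly different
constant and is documented as such).

Partitioning assumes equal adsorbed cis/trans populations:
`n_cis = N·r/(1+r)`. Exact arithmetic conserves the total to machine
precision; nearest-integer rounding (the replica convention) conserves it
within one molecule. Isomer-specific EFs divide counts at the two
temperatures; in replica mode the *rounded* counts are divided — this
convention is required to reproduce the published 32.7 (= 294/9) and is
not the default outside replica mode. The published trans-specific EF of
3.65 at 10 °C is reproducible neither from rounded counts (33/9 = 3.67)
nor exact arithmetic (≈3.52); the replica reports the rounded-count value.

## 5. Statistics

t-tests and Cohen's d operate on summary statistics (mean, sample SD, n)
with pooled (n−1-weighted) variance; a Welch variant is provided. The
published effect size 2.006 for the cluster binding ensembles cannot be
reproduced exactly because the group sizes behind it are not disclosed;
with equal n the ensembles (18.6 ± 2.4 vs 23.2 ± 2.3) give d = 1.957,
within 3% of it, and p < 0.001 for every plausible n ≥ 10. Seasonal window
statistics pool all records whose month-day falls in an inclusive window
(wrapping the year boundary when needed) and report count, mean,
population SD and range separately for daily highs and lows; the
daily-variation statistic is the mean of (t_max − t_min).

## 6. Known limitations

* Absolute physisorption potentials are surrogate-level; only relative
  isomer differences are meaningful, and even those are qualitative
  against the published force-field values.
* The slab surrogate's hydrogen content (~15 atom-%) is higher than
  typical annealed amorphous carbon because capping is the only valence
  repair mechanism.
* The rigid-adsorbate, rigid-surface approximation ignores induced fit;
  conformational response is represented only through the discrete
  conformer set.
* Kinetics are relative rates and fractions only — no attempt frequencies,
  absolute rates, coverage dependence, or mass transfer in a filter bed.
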