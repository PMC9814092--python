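# Methods

This note documents the models, numerical choices and known limitations of
`cage_evolve`, module by module, in enough detail to reproduce or challenge
any of its behaviour.

## Cage assembly

A `Tri⁴Di⁶` cage is built by placing four copies of a tri-topic aldehyde
node on the vertices and six copies of a di-topic amine linker on the edges
of a regular tetrahedron, then condensing each aldehyde carbon with an
amine nitrogen into a C=N double bond. Per bond one aldehyde oxygen and two
amine hydrogens are deleted (a water equivalent; the aldehyde hydrogen is
retained as the imine hydrogen), so the atom count is
`4·n_node + 6·n_linker − 36` and the bond graph always contains exactly 12
imine bonds.

Precursor conformers come from RDKit's ETKDGv3 embedding (fixed seed,
default 61409) followed by a short MMFF94 clean-up. Placement is resolved
in two steps:

* **Orientation.** Each node is oriented by a proper-rotation Procrustes
  fit mapping its three reactive-site directions onto the in-plane
  projections of the three adjacent edge directions and its site-plane
  normal onto the inward radial direction; the best of the six
  site-to-edge assignments is kept, which fixes the mirror choice.
  Linkers map their N–N axis onto the edge and are rolled about it so
  their heavy-atom bulk points outward.
* **Scale and radial offset.** The three edges meeting at a vertex dip
  below the node plane by the tetrahedral angle, so a planar node tangent
  to the vertex sphere cannot reach them: the minimal aldehyde–amine
  distance of a tangent placement is ≈ 0.82× the site circumradius. Both
  the template circumradius and a per-node inward radial offset are
  therefore solved in closed form so that the prolongation of each node
  arm meets the edge exactly at the target C–N distance of 1.45 Å. This
  yields assembled imine bonds of 1.45 ± 0.05 Å without atom clashes for
  all tested precursors; clashes below 0.7 Å raise a warning but still
  return the structure, since optimisation is expected to relax it.

The C₆₀ guest is generated as an exact truncated icosahedron (60 atoms, 90
equal bonds, bond length 1.44 Å, diameter 7.14 Å nucleus-to-nucleus) and
placed at the template centre before the host, so complexes are built
around the guest.

## Energy backend

Backends satisfy a two-method contract (`total_energy`, `optimize`) and
register by name. The default surrogate is deliberately simple:

* **Potential.** 12-6 Lennard-Jones over all atom pairs except 1-2 and
  1-3 neighbours, with UFF van der Waals parameters (geometric mixing),
  plus harmonic bond terms referenced to scaled Cordero covalent radii
  (factors 1.0/0.87/0.78 for single/double/triple bonds, k = 2000
  kJ mol⁻¹ Å⁻²). No electrostatics, angles or torsions.
* **Optimisation.** L-BFGS with analytic gradients; convergence at a
  projected gradient of 0.05 kJ mol⁻¹ Å⁻¹ (the backend defines the units
  of this threshold). A restrained pass holds any requested bonds at
  their input lengths with k = 20 000 kJ mol⁻¹ Å⁻²; the standard protocol
  restrains every bond except the newly formed imines. `optimize` never
  returns a structure above its input energy (the input is returned if
  the minimiser fails to improve it).
* **Conformer search.** The molecular-dynamics stage of the original
  protocol (700 K, 1 fs, 10 ps equilibration, 200 ps production sampled
  every 10 ps) is abstracted to its sampling contract: N =
  production/sampling-interval seeded Gaussian coordinate perturbations
  (σ = 0.3 Å), each locally optimised, with the minimum-energy candidate
  selected. All fields of the schedule are kept in the configuration for
  provenance even though the surrogate only consumes the sample count.

A consequence worth knowing: without angle/torsion terms, empty cages are
floppy and often collapse onto themselves under pure dispersion — the
pore-analysis collapse filter then rightly discards them — while complexes
are propped open by the guest. This mirrors, in exaggerated form, the real
observation that a large fraction of candidate cages is not shape
persistent. Binding energies from the surrogate are dispersion-only and
not comparable to force-field values; only their ordering is meaningful.

## Pore metrics

The cavity diameter is `2·min_i(|r_i − centre| − vdW_i)`, floored at zero,
with the centre at the centre of mass (a `centroid` option exists). The
centre is *not* optimised, so the value is a lower bound on the
largest-included-sphere diameter; for near-symmetric tetrahedral cages the
difference is negligible.

Windows are found by ray casting on a subdivided-icosahedron direction
grid (default 5120 face directions). For each direction the bottleneck
clearance is the minimum over atoms ahead of the centre of (perpendicular
distance to the ray − vdW radius); directions with positive clearance
escape, adjacent escaping directions are clustered, and each cluster's
diameter is twice its best bottleneck. The angular spacing bounds the
diameter error at about `2·Δθ·R` (Δθ ≈ 0.044 rad at default resolution,
R the shell radius); analytic aperture fixtures confirm this bound.
Clusters narrower than 1 Å are discarded: sub-Ångström gaps between the
van der Waals spheres of bonded frameworks register as escape channels
depending on grid orientation but admit no guest. A cage is collapsed when
it has no cavity or fewer than two windows ≥ 1 Å. Asymmetry is the sum of
absolute pairwise window-diameter differences; with fewer than two windows
it is undefined and the cage is treated as collapsed.

## Fitness

Population normalisation subtracts the minimum and divides by the
post-shift mean, so the best member maps to exactly 0 and the mean to 1
(all-equal populations map to all-zero). The stated intent of the original
normalisation — "all values greater than zero" by *adding* the minimum —
cannot hold for negative minima, so the subtract-the-minimum reading is
implemented; the best member consequently contributes 0, not a small
positive value. Penalties are floored at 10⁻⁹ before inversion, so a
member that is simultaneously best in every component receives the capped
fitness 10⁹ rather than a division error. Invalid records (collapsed cage
or complex, repulsive binding, binding below the validity limit — default
−780 kJ/mol, with −404 kJ/mol mirroring the parameterisation study) are
excluded from the normalisation constants and receive fitness 0. Ranking
is by descending fitness (equivalently ascending penalty) with ties broken
by cage id.

The inverse-penalty form has a structural consequence: per-population mean
fitness is heavy-tailed. Whenever one member approaches the component-wise
minimum of its population, its penalty approaches the floor and its
fitness dwarfs the population; any statistic built on mean fitness should
therefore be aggregated robustly (the tests use cross-run medians).

## Parameter sweep

The normalised components do not depend on (a, b, c, d), so they are
computed once per table; each of the 5·5·21·21 = 11 025 grid cells ranks
by `a·Ẽᵇ + c·Ã^d` (ties by cage id) and rates its ten best cages. All 25
ordered (a, c) pairs are enumerated without deduplication by ratio, and
heat maps are keyed by the pair. The selected set attains the global
minimum R₁₀ and, among those, the smallest a+b+c+d, then lexicographic
(a, b, c, d). Heat maps export as a 21×21 CSV (b rows, d columns) and a
PNG with the minimum cell starred.

## Evolutionary engine

One generation: evaluate the population; produce 14 offspring by 7
crossovers (parent pairs drawn by roulette, fitness-proportional, with a
uniform option); produce 10 mutants — the fittest member first, the other
nine by drawing members uniformly and accepting when their min–max-scaled
fitness exceeds a fresh U(0,1) draw; pool all 44; select the next
population by roulette without replacement, elite guaranteed. Invalid
candidates carry fitness 0 and can only leave at selection. Every
stochastic step draws from a single `numpy` generator seeded from the
configuration, so runs are bit-reproducible.

Two choices here are deliberate departures from the most literal reading
of the procedure, made because the literal version demonstrably destroys
the search:

* **Initial populations are drawn without replacement** over the
  node × linker product (the initialisation is described as producing
  *diverse* cages; sampling with replacement seeds duplicate sentinels).
* **Selection runs over distinct compositions**: duplicates created by
  the operators collapse onto a single roulette slot (the shortfall, if a
  pool has fewer distinct compositions than slots, is filled from the
  leftovers). With duplicates kept as separate slots, measured populations
  degenerate into 20 copies of one cage within ~3 generations — the copies
  share every component minimum, all receive the capped fitness, and
  crossover and mutation then only ever resample one composition. The
  observed mean pairwise Dice similarity of real runs (rising to ~0.4–0.5,
  not 1.0) indicates populations of similar-but-distinct cages, which is
  exactly what distinct-composition selection produces.

Generation records (index 0 = the initial population) log min/mean/max
fitness, component means over valid members, mean pairwise Dice similarity
and the membership list. Combination across runs unions the final
populations, removes duplicate compositions, re-normalises every component
over the union, recomputes the final three-component fitness and assigns
code names C1, C2, … in descending order.

## Synthetic fixtures

The toy library is parametric and deterministic: node *i* carries three
arms of topological length *i*+1 with deliberately varied chemistry
(methylene, vinylene, alkynyl, ether, dienyl, diyne motifs) on a benzene
core; linker *j* is an α,ω-diamine of backbone length *j*+2 with a cycled
decoration (plain / methyl branch / central alkene). Varied motifs give
the fingerprint similarity real structure (mean pairwise Dice between
random pairs ≈ 0.45–0.55) while arm and backbone lengths stay strictly
increasing, so every combination maps to a distinct predicted cavity
diameter.

The analytic landscape predicts `D = 0.16 + 2.2·arm + 0.16·nn` Å (arm =
topological aldehyde-to-ring distance, nn = N-to-N path length) and scores
binding with an asymmetric Gaussian well of depth 300 kJ/mol centred at
guest diameter (10 Å) + 0.4 Å slack, widths 1.2 Å below and 1.5 Å above
the optimum (squeezing costs more than slack; the asymmetry also removes
exact energy ties between equidistant cages). Asymmetries are small and
flat within 1 Å of the optimal diameter and grow linearly beyond it.
These defaults were chosen so the landscape is an honest but solvable
testbed, and then frozen:

* the node dominates the cavity size (2.2 Å per arm bond) with the linker
  as fine tuning (0.16 Å per bond), so exactly one node row reaches the
  optimum — as in real `Tri⁴Di⁶` cages, where the vertex building block
  sets the size;
* with these coefficients the *only* composition that is simultaneously
  best-in-row and best-in-column is the global optimum (verified
  exhaustively), so single building-block swaps always admit an improving
  move and the search cannot be trapped;
* the flat asymmetry region makes the fitness ranking near the optimum
  purely binding-driven, keeping the exhaustive-oracle comparison exact.

The energy well's minimum coincides with a lattice point of the toy
library (node04+link07 in the 8×12 default), so the optimum is attained
exactly and uniquely (margin to the runner-up ≈ 1.7 kJ/mol). Optional
per-cage pseudo-noise and asymmetry jitter (hash-seeded, deterministic)
exist for robustness experiments and default to zero.

What the fixtures do *not* emulate: conformational flexibility,
force-field energetics, collapse of real assemblies, chemically diverse
ring systems, or any coupling between asymmetry and composition beyond
cavity mismatch. Passing the fixture-based tests validates the search
machinery and the equations — not the chemistry of any real cage.

## Physical evaluation route

`PhysicalEvaluator` chains assembly → restrained optimisation → conformer
search → binding energy → pore metrics, producing the same record type as
the landscape, so it can stand behind the EA or the enumeration
unmodified. At the default 20-sample schedule one evaluation of a small
cage costs on the order of a minute on one core; surveys should reduce the
sample count (the CLI default is 2). The C₆₀ reference energy is computed
once per evaluator.

## Numerical and testing notes

* All lengths are Å, energies kJ/mol, Cartesian coordinates with no
  periodicity.
* Dice similarity uses 2048-bit hashed circular substructure fingerprints
  of radius 2; two empty fingerprints define similarity 0. Similarity
  ties resolve to the lexicographically smallest id.
* Bond-character analytics count heavy-atom bonds only, on the Kekulé
  structure; rotatable bonds are acyclic single bonds between
  non-terminal heavy atoms (no amide exclusion — imine cages carry no
  amides). In an unsubstituted cage every framework bond is macrocyclic,
  so its rotatable fraction is 0 by this definition.
* Test problem sizes: the 8×12 library (96 combinations) for search and
  oracle tests, 30-generation runs, 20 seeds for recovery statistics,
  10⁴ draws for operator-frequency checks. These sizes keep the suite
  within a few minutes while leaving the statistics well-powered.
* Window-diameter assertions use the grid-resolution error bound; exact
  arithmetic (ratings, normalisation, stoichiometry) is asserted to
  machine precision.
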