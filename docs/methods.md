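# Methods

## The design problem

Intramolecular frustrated Lewis pairs (IFLPs) tether a Lewis-acidic
trivalent boron and a Lewis-basic nitrogen in one molecule. When sterics
or backbone geometry prevent the two centers from collapsing into a
dative B–N adduct, the pair can heterolytically split H2 (hydride to B,
proton to N) and transfer it to CO2, giving formate. Whether a given
IFLP is a good CO2-hydrogenation catalyst is governed by four largely
independent factors:

1. **Chemistry** — the cumulative acid–base strength. FEPA (free energy
   of proton attachment at N) and FEHA (free energy of hydride attachment
   at B), both in kcal/mol, must balance: predicted turnover frequency is
   maximal on the line FEPA + FEHA = −317.2 kcal/mol. The chemical merit
   of a candidate is the Euclidean distance of its (FEPA, FEHA) point
   from that line, `r_chem = |FEPA + FEHA + 317.2| / √2`.
2. **Geometry** — the B–N distance `d` and the orientation angle `Φ`
   between the open coordination sites, extracted from the H2-activated
   intermediate (Int2). High activity lives roughly at d ∈ [2.4, 3.2] Å
   and Φ ∈ [70, 140]°; the optimizer targets d = 2.7 Å, Φ = 100°.
3. **Synthetic complexity** — a score in [1, 5], minimized.
4. **Quenching** — a binary index Q: Q = 0 means the pair forms a
   classical adduct and is catalytically dead.

The package searches a combinatorial fragment space for candidates that
jointly optimize these with a genetic algorithm (GA) under a
hierarchical multi-objective scalarizer.

## Chromosome encoding and assembly

A candidate is an 8-gene chromosome: two acid substituents (on B), two
base substituents (on N), one backbone, and three optional backbone
decorations. Fragments are SMILES with attachment points written as
dummy atoms `[*:n]`. The backbone carries the Lewis B and N atoms
itself; its sockets use reserved map numbers (1–2 acid, 3–4 base, 5–7
decoration), which makes slot counting, conditional expression, and
welding fully deterministic. A ring-embedded ("endocyclic") B or N has
fewer free valences, so the backbone exposes fewer sockets and the
corresponding genes are *silenced*: kept in the tuple (crossover stays
positional) but excluded from assembly and fitness.

Assembly welds each expressed substituent onto its socket with a single
σ-bond, removes the dummies, sanitizes, and emits canonical SMILES
(RDKit's canonical writer, fixed for the whole package — the determinism
guarantee is writer-dependent). The Int2 form adds one H to B (formal
charge −1) and one H to N (+1); net charge stays zero and the heavy-atom
composition is unchanged.

Because welding is symmetric, ordered substituent assignments (A, B) and
(B, A) produce the same molecule. The chromosome-space count
`a²·b²·k·s` is therefore documented as a *full-expression upper bound*:
it ignores both silencing and swap symmetry. With the full pool sizes
(71 acids, 40 bases, 108 backbones, 2 decorations) it evaluates to
1 742 169 600 ≈ 1.7 × 10⁹.

## Geometry and steric descriptors

Int2 is embedded with seeded distance geometry (ETKDGv3) and refined by
a pluggable `optimize(structure) -> (structure, energy)` backend; the
shipped `IdentityBackend` is a no-op with a deterministic pseudo-energy,
and a semiempirical program can be adapted behind the same protocol.
Embedding retries up to 5 consecutive seeds; exhaustion is a
candidate-level failure (worst fitness, run continues).

`d` is the B–N distance. For `Φ` the package uses the B→H(hydride) and
N→H(proton) bond vectors as proxies for the empty p orbital and the lone
pair — in Int2 those hydrogens literally occupy the open sites. This
convention is a documented choice; the vectors are taken from designated
atom indices, so an alternative construction can be substituted.

Buried volume around a Lewis center is the fraction of a probe sphere
(radii 2.0, 2.5, 3.0, 3.5 Å) occupied by the van-der-Waals spheres of
the *other* atoms (Bondi radii, frozen in `geometry.VDW_RADII`;
hydrogens included, since H on B/N matters for frustration). The default
estimator is a deterministic cubic grid of 0.1 Å spacing; a seeded
Monte-Carlo estimator serves as an independent stochastic cross-check
(agreement within 0.02 absolute is enforced in tests).

## Fitness scores

* `CS = Q / max(r_chem, ε)` with ε = 10⁻³: the ε floor caps the
  singularity for candidates exactly on the maximum-TOF line.
* `GS = (C₁·f_d + C₂·f_Φ) · Q` with C₁ = C₂ = 0.5 and
  `f_p = exp(−(p − p_target)²/(2σ²))`, peak-normalized so both terms are
  1 on target and bounded by 1. σ_d = 0.60 (Å). σ_Φ = 0.75 is applied
  with Φ *in radians* (≈ 43°): a width of 0.75° would collapse the angle
  term to a numerical delta function and remove any gradient toward the
  target; the unit convention is a config switch (`phi_units`).
* `SCS` ∈ [1, 5], minimized. The default backend is a documented
  heuristic — a monotone saturating function of heavy atoms, rings, ring
  fusion, and stereocenters mapped to [1, 5] — chosen so the package has
  no trained-weights dependency. It preserves scale and direction but is
  *not* equivalent to the published neural-network scorer, which can be
  plugged in as an `external-model` callable.

Low-level FEPA/FEHA values are intended to pass through a per-descriptor
ordinary-least-squares linear correction (`fit_linear_correction`)
before scoring; coefficients ship as configuration, not constants.

## Quench classifier

Ground truth for frustration is a Boltzmann-weighted LA–LB distance
(BWDistance) over multi-start geometry optimizations
(Σ dᵢwᵢ/Σ wᵢ, wᵢ = exp(−ΔEᵢ/kT), T = 298.15 K by default). Pairs with
BWDistance ≤ 2.0 Å are labeled quenched — dative adducts settle near
1.6 Å — with the boundary itself assigned to quenched (a conservative
tie rule: rejecting a borderline catalyst is cheaper than accepting a
dead one). A random forest (200 trees, fixed seed) predicts the label
from the 8 buried-volume features. Cross-validation is stratified
k-fold (k = 20 default); when k exceeds the minority-class count (e.g.
leave-one-out) it falls back to plain k-fold.

## Scalarization and the GA

The hierarchy (default CS 25%, GS 10%, SCS 25% degradation tolerances)
is implemented by recursive region peeling: within the current candidate
set, those whose first objective is within `tol × (batch range)` of the
batch best form the accepted region and are ranked by the next
objective's rule; the rejected region is re-ranked by the same procedure
and placed strictly after. Terminal groups (all bands satisfied) are
ordered by the last objective. Ranks are the merit (smaller = better).
Consequences, enforced by tests: tolerance 0 everywhere is exact
lexicographic order; tolerance 1 makes an objective transparent; the
ranking is permutation-equivariant and invariant under positive affine
rescaling of any objective; the tolerance-0 best is always on the Pareto
front. Tolerances anchor to the *evaluation batch* best; because of this
relative anchoring a degenerate zero-width band (batch range 0) simply
accepts everything.

GA defaults: population 20, mutation rate 0.1 per gene, 50 generations
(≤ 1000 evaluations; exactly 1000 with the deduplication cache
disabled), elitism 2, tournament size 3, uniform per-gene crossover,
mutation to a uniformly drawn same-role fragment. Offspring that fail
assembly are resampled up to 5 times, then fall back to the first
parent. Candidates are cached by canonical Int2 SMILES. Early stopping
uses a 15-generation no-improvement patience window by default and can
be disabled (`patience=None`) for fixed-budget runs. A run is fully
determined by (seed, config, library, backend).

## Synthetic backend and what it does not show

Real descriptor evaluation requires semiempirical optimization per
candidate; the shipped synthetic backend instead assigns every fragment
fixed additive FEPA/FEHA/steric/geometry contributions. The
planted-optimum landscape (`make_planted_space`) plants one chromosome
exactly on the targets (FEPA + FEHA = −317.2, d = 2.7 Å, Φ = 100°) and
gives every other fragment strictly positive deviations per property, so
total deviation is additive over mismatched genes. This yields a smooth,
hill-climbable landscape with a unique optimum certified by exhaustive
enumeration — 4 acids × 3 bases × 2 backbones = 288 fully expressed
tuples, small enough to enumerate in seconds yet large enough that a
1000-evaluation GA budget is a real search. The quench fixture draws two
Gaussian clusters in feature space (centers 0.2/0.7, sd 0.03) with
BWDistance bimodal around 1.6 and 3.0 Å.

These generators emulate the *structure* of the problem (additive
composition, bimodal frustration, separable sterics), not its physics:
an early design that drew fully random contributions produced deceptive
near-line competitors and needle-like optima, which defeats the purpose
of a GA-validation surface, and was replaced by the monotone-deviation
construction. Passing tests therefore demonstrate the correctness of the
machinery (assembly, scoring, scalarization, evolution, classification),
not that the GA would recover specific catalysts under semiempirical
descriptors, and not that the heuristic SCS matches the published
complexity model.

## Numerical choices and limitations

- ε = 10⁻³ in CS; buried-volume grid spacing 0.1 Å; Monte-Carlo default
  200 000 proposal points; Φ degeneracy threshold 10⁻⁸ Å on direction
  vectors; chimera band comparisons use a 10⁻¹² slack to absorb float
  round-off.
- Ties in merit break by candidate insertion order (reproducibility).
- The Lewis pair is designated by the backbone's socket labels; backbones
  whose B or N carries no socket must contain exactly one atom of that
  element. Multi-boron decorations are allowed — designation is
  topology-driven, not element-scanning.
- Tautomers, stereoisomer enumeration, conformer ensembles, solvation and
  any DFT-level computation are out of scope; reported lead-candidate
  descriptor values are consumed as data (`flpga.reference`), not
  recomputed.
- Problem sizes used by the test suite and the reproduction script — the
  288-tuple planted space, 20 seeded recovery runs of 30 generations,
  one 50-generation budget run, n = 200 quench fixtures, 100-candidate
  Pareto oracles — were chosen as the smallest sizes at which each
  property is meaningfully exercised.
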