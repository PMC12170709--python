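# Methods

## The model

`nogmap` studies pathway design in the non-oxidative glycolysis (NOG)
reaction space: conversions of a hexose phosphate into three two-carbon
acetylphosphate units at 100% carbon efficiency, together with byproduct
routes to small acids.  The model has three layers:

1. **Molecules** are stereo-free labeled graphs over heavy atoms
   {C, O, P} with integer bond orders; hydrogens are implicit and
   recovered from fixed valences (C=4, O=2, P=5).  Stereoisomeric sugars
   (erythrose/threose, ribulose/xylulose, ...) are therefore one molecule.
   Phosphate groups are modeled in a fixed neutral protonation state
   (-OPO3H2) so elemental balance is exact.  Identity is decided by a
   canonical key computed with iterative neighborhood color refinement
   plus full backtracking over refinement ties, which makes key equality
   coincide with element- and bond-order-preserving graph isomorphism
   (property-tested against an exhaustive isomorphism oracle).
   Network species are linear-backbone molecules written in a compact
   code, one letter per carbon (`h` hydroxyl, `k` carbonyl,
   `p` phosphoester, `b` bare, `x` carboxyl, `a` acyl phosphate).

2. **Reactions** come from seven enzyme templates applied as rewrite
   rules on the linear code: aldolase (AL), aldose->ketose and
   ketose->aldose isomerases (AlKe/KeAl), phosphohydrolase (PHL),
   phosphoketolase (PK), transaldolase (TAL) and transketolase (TKL).
   Every emitted reaction is checked for exact elemental conservation
   (C, O, P and implicit H); an imbalance is an internal error, not a
   warning.  The network is the closure of a seed set
   {F6P, phosphoric acid, water} under the templates with a seven-carbon
   cap: reactions with any product above the cap are discarded entirely.
   Closure is a set-level fixed point, so seed order and rule order
   cannot influence the result (tested).

3. **Pathways** are integer hyperflows: nonnegative integer flows on
   reaction hyperedges satisfying per-molecule conservation, with the
   query fixing the source inflow (one F6P, which eliminates scaled
   duplicate solutions) and the sink outflow (e.g. three AcP), and
   leaving water and phosphate freely exchangeable.  By default every
   carbohydrate intermediate must carry a phosphate group; molecules
   that are not carbohydrates (water, phosphate, methanal, the free
   acids) are automatically exempt, as are query sources and sinks.

## Rule preconditions and their calibration

The template descriptions fix the chemistry of each rule but not every
structural precondition (how far a carbonyl may migrate, which bond
phosphoketolase cleaves, which alpha carbon an aldol donor attacks
through).  These are exposed on `RuleConfig` and the defaults were chosen
by sweeping the precondition space (~1500 configurations) against the
published results of this chemistry.  The selected defaults:

* **AlKe/KeAl** interconvert aldoses and 2-ketoses only (the carbonyl
  moves between C1 and C2).  Both directions are distinct hyperedges
  because flows are nonnegative.
* **AL** takes three-carbon ketose donors (dihydroxyacetone-like), which
  attack through the hydroxymethyl alpha carbon, onto aldose acceptors of
  at least two carbons.  A config switch lifts the donor-size
  restriction, admits acyl donors, or enables the retro direction.
* **TAL/TKL** transfer the C1-C3 dihydroxyacetone / C1-C2 glycolaldehyde
  unit of a ketose of at least four carbons onto an aldose acceptor.
* **PHL** hydrolyses one phosphoester (or acyl phosphate) per application
  with one water; no phosphorylation rule exists, so phosphate enters
  the space only through phosphoketolase and the seed.
* **PK** acts on 2-ketoses and cleaves a carbon-carbon bond at the
  C2-C3 enediol system, on either side.  Cleaving C2-C3 is the classic
  Xpk/Fpk/Spk chemistry (acetylphosphate + a two-carbon-shorter aldose +
  water); cleaving C3-C4 phosphorylates C3 instead and yields the
  3-hydroxypropionyl phosphate family (e.g. F6P + Pi -> HPA-P + G3P +
  H2O, which balances exactly).  The far-side variant is required by the
  byproduct chemistry: without it the shortest route to two
  3-hydroxypropionate molecules per F6P has nine steps rather than the
  observed seven.

With these defaults the package reproduces, reaction-by-reaction, both
seven-reaction NOG pathways (via SBP and via XBP), the count of twelve
eight-reaction/seven-distinct pathways none of which uses FBP, and the
five seven-step hydroxypropionate routes with six unique reactions.

**Known discrepancy (documented, not hidden).**  The reference network
for this chemistry is reported to contain 81 molecules and 414 reactions
(39 carbohydrate monophosphates, 14 biphosphates, 23 free carbohydrates,
5 small non-sugar species).  No configuration of the template
preconditions reaches that census: the default network has 37 molecules
and 185 reactions (17/4/11/5), and the configurations that come closest
in raw molecule count (about 83/448, via aldol attack through the
phosphorylated alpha carbon) change the pathway counts and are therefore
wrong on the better-validated evidence.  The exact rule encodings behind
the published census are not derivable from the template descriptions
alone; the default here is the configuration whose *pathway-level*
behavior is fully validated, and whose five small non-sugar species are
exactly the published five (water, phosphoric acid, methanal, ethanoic
acid, 3-hydroxypropionic acid).  Counts that depend on satellite regions
of the molecular space (the census itself; the ten-step acetate family,
which in this network reduces to the two NOG cores plus three acetyl
phosphate hydrolyses) inherit the discrepancy.

## The ILP and its enumeration

The hyperflow model is solved with HiGHS through `scipy.optimize.milp`.
Integer flows are encoded in unary ("thermometer") binaries
`y[e,k] = [f_e >= k]` with monotonicity constraints, so that excluding an
incumbent solution f* is a single linear no-good cut: some edge must
satisfy `f_e >= f*_e + 1` (i.e. `y[e, f*+1] = 1`) or `f_e <= f*_e - 1`
(`y[e, f*] = 0`).  Enumeration proceeds per total flow T (ascending from
the optimum), adding one cut per solution until infeasibility, which
yields the complete solution set up to the query bound; output is sorted
by (total flow, lexicographic flow vector), so it is deterministic
regardless of solver tie-breaking.  Completeness is certified by
flow-set equality against a brute-force enumeration of all bounded
integer flow vectors on seeded toy hypergraphs (100 instances in the
test suite).

Problem sizes: the default network model has a few hundred admissible
hyperedges after the phosphate restriction; at the bounds used in the
tests and the acceptance script (total flow up to 10) a full enumeration
takes seconds on one CPU.

## Free energies

Reaction free energies come from either a per-molecule potential table
(`DrG = sum G(products) - sum G(educts)`) or a per-reaction override
table; the shipped fixture holds the published standard values for the
three phosphoketolase reactions (-44.376, -49.666, -53.887 kJ/mol for
the 5-, 6- and 7-carbon substrates), the three biphosphate hydrolyses
(+7.386 XBP, +0.576 SBP, -0.0322 FBP) and two transaldolase steps
(+4.27, +2.72).  A full per-molecule table cannot be reconstructed from
those few printed numbers, so the fixture is deliberately a reaction
table; users with a quantum-chemistry toolchain can build a
`PotentialTable` through the adapter in `nogmap.qm` (Open Babel
embedding + xTB thermochemistry via subprocess; mocked in tests, never
required).

Profiles list per-step DrG in a user-chosen linearization; steps with
DrG > 0 are flagged as bottlenecks.  Because G is a state function the
net is independent of the ordering and identical across pathways with
the same overall reaction — asserted at 1e-9 kJ/mol in the profiler and
property-tested with random potential tables.

Two ratios are derived at T = 300 K (R = 8.314 J/mol/K; the standard
state of the potential model is 273.15 K and 1e5 Pa, but the published
ratios are quoted at 300 K, so that is the ratio default; both are
arguments): `boltzmann_ratio = exp(-DrG/RT)` (product-side likelihood)
and `equilibrium_ratio = exp(+DrG/RT)` (the educt/product concentration
ratio at which a mildly uphill hydrolysis equilibrates, with unit
activities for water and phosphate).  They are reciprocal by
construction.  `paper_product_preference(a, b) = exp(a/b)` reproduces a
published comparison of two net pathway energies; its exponent is a
ratio of free energies rather than an energy over RT, which is
dimensionally unconventional — the function reproduces the printed
definition and the documentation says so rather than guessing an
intended alternative.

## What the toy worlds do and do not show

Toy networks are abstract token hypergraphs with a planted
source-to-sink chain, used to certify ILP correctness (conservation,
completeness, cut safety) independently of the chemistry layer.  They
make no attempt at statistical realism: degree distributions, reaction
arities and flow magnitudes are arbitrary.  Passing the toy battery
shows the enumerator is exact on bounded instances; it says nothing
about whether the chemical rule set matches any particular published
network, which is exactly why the rule calibration above is reported
separately.

## Numerical choices and degenerate inputs

* Flows are bounded by the query's `max_total` (default cap per reaction
  = the total bound); HiGHS integrality tolerances are absorbed by
  rounding the binary solution before reconstructing flows, and every
  reconstructed pathway re-verifies conservation exactly in integers.
* An empty query (no inflow/outflow) admits the zero flow, which is
  returned as the single optimal solution.
* A query molecule missing from the network raises immediately; a fixed
  exchange on a molecule no admissible reaction touches yields a clean
  infeasibility (empty solution list).
* Expansion aborts with a diagnostic beyond a configurable molecule
  budget (default 20000) instead of running away.
* Seeds larger than the carbon cap are kept (the cap bounds what
  expansion may *add*).

## Limitations

* Open-chain sugars only; no ring/open-chain equilibria, tautomer
  enumeration, stereochemistry, charge states or pKa corrections.
* No kinetics, cofactors, or concentration-dependent free energies
  beyond the two-species equilibrium ratio.
* The rule-precondition calibration is inherently underdetermined by
  the template descriptions; the census discrepancy above is the honest
  residual of that underdetermination.
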