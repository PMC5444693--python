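# Methods

## Scope and model

`pathdyn` converts a deterministic kinetic model of a signaling network
into simulated, comparable, renderable dynamics. The model is a reaction
network — species with initial concentrations (nM), constant-volume
compartments, global/reaction-local parameters, and reactions with
arithmetic kinetic laws — read from SBML Level 2 V4 or Level 3 V1 core.
Only the core subset is accepted: events, rules, function definitions,
initial assignments, constraints, and piecewise/delay math are rejected
with an explicit unsupported-feature error. This is deliberate:
perturbations (drug doses, mutations) enter through the intervention layer,
not through SBML events, so a model file describes only the unperturbed
biochemistry. Amount-typed initial values are divided by compartment volume
on load so everything is a concentration; reaction-local parameters are
namespaced `<reaction>__<parameter>` and hoisted to the global table, which
is what lets an intervention address any kinetic constant uniformly.

Kinetic laws are sympy expression trees restricted to
{+, −, ×, ÷, power} over species ids, parameter ids and time. Rate-law
strings are parsed with an empty global namespace so identifiers like `I`
(a common drug-species name) or `E` are plain symbols, never sympy
constants. Compartment ids appearing in imported rate laws are substituted
by their constant volumes at load time.

## Interventions and regimes

An intervention is one of five discontinuity kinds applied at a time t ≥ 0
(minutes): `dose` (adds to the target concentration — a bolus), `set_` /
`scale_concentration`, and `set_` / `scale_parameter`. A dose *adds* rather
than sets so that sequential and repeated dosing compose naturally; for the
usual case of a drug species starting at 0 nM the two conventions coincide.
Simultaneous interventions apply in declared order (stable time sort), which
makes regimes deterministic by construction. Regime validation checks
target existence and that no intervention is scheduled after `t_end`.

## Integration

Velocities v(t, c, p) are compiled once per network (sympy → lambdify over
indexed state/parameter vectors) and the state derivative is the
stoichiometry matrix applied to the velocity vector, with boundary-species
rows zeroed. Integration uses SciPy's LSODA (stiff-capable, the sensible
default for signaling kinetics; method and tolerances are configurable).

The engine restarts the integrator at **every** output grid point, and
additionally at every intervention time (off-grid times split the
enclosing grid interval). This is the package's central numerical design
choice, made for exactness rather than speed: the state recorded at grid
point t is a function only of the state at the previous grid point, so two
regimes that agree up to time t produce *bit-identical* samples up to t,
and a dose at t appears as an exact `+dose` jump in the t column (the
sample at an intervention time is the post-discontinuity state, and
velocities are recomputed from that state, not integrated separately).
Restarting costs accuracy per restart, so default tolerances are tighter
than a single long integration would need: rtol 1e-10, atol 1e-12 nM. With
601 grid points over 10 min, the measured grid-sample error on the
analytic decay fixture is ~2e-8 relative, comfortably inside the 1e-6
contract; fixed-step RK4 cross-checks agree to ~1e-9.

Negative concentrations are not constrained during integration; reported
concentrations are clipped at 0 and a warning is emitted if any value falls
below −100·atol. The default grid is 601 points over t_end = 10 min (the
natural short-horizon window for receptor-proximal dynamics; longer runs
simply raise t_end).

`integrated_signal` is the trapezoidal integral of one species over a
window (nM·min), the scalar readout used to compare pathway activity
between regimes; window endpoints off the grid are linearly interpolated.

## Comparison encoding

`compare` requires identical species/reaction sets and identical grids
(resampling is deliberately the caller's job, keeping the diff exact) and
returns signed experiment-minus-control differences for every node and
edge, plus a (hue, intensity) encoding: hue is sign(diff) ∈ {low, neutral,
high}, rendered blue/white/red; intensity is |diff| / M(e) clipped to
[0, 1]. M(e) is per-entity by default — each entity's maximum |value|
across both regimes — so a low-abundance species' response is as visible
as an abundant one's; a single global scale per entity kind is available
when comparable magnitudes matter. M(e) = 0 (an entity at zero in both
runs) maps to intensity 0. These definitions make the algebraic
identities exact: self-comparison is everywhere neutral, and swapping the
regimes negates diffs and swaps red/blue at identical intensities.

## Layout

The drawn graph is bipartite: a hub node per reaction, spokes to every
participant. Positions come from a plain Fruchterman–Reingold iteration —
repulsion k²/d between all node pairs, attraction d²/k along edges, with
k = √(area/n) (area 1 for the unit box, 4πr² in sphere mode), displacement
capped by a temperature cooled linearly to zero over the iterations
(default 500), initial positions seeded uniform in the unit box (uniform on
the sphere in sphere mode). Sphere mode re-projects all positions to the
radius after every iteration, so the norm constraint holds to floating-
point precision. Layouts are bit-reproducible for a fixed (seed, mode,
iterations). Disconnected networks are laid out per component and tiled
along x (sharing the sphere in sphere mode). Edge-crossing minimization is
not an explicit objective — FR reduces crossings only incidentally.

## Rendering

Node radius and edge width scale linearly (optionally log) from a floor
(r_min/w_min, so empty entities stay visible) to a ceiling reached at the
entity's run maximum; edge width encodes |velocity| since thickness has no
sign. Single-run frames are white; with a comparison attached, nodes and
edges take the tri-color encoding. Frames are rasterized on a fixed canvas
(default 1200×900, nodes as translucent discs over a dark background, 3D
modes orthographically projected) and exported as a zero-padded PNG/JPEG
sequence at a configurable frames-per-simulated-minute; PNG export is
byte-deterministic for fixed inputs.

## Fixture motifs

The generated motifs are the package's test substrate and demo models, with
kinetics chosen once as generic mass action (rate constants 0.01–1 in
nM/min units, defaults fixed; optional seeded lognormal jitter, off by
default). They emulate mechanisms of receptor-driven kinase signaling
without reproducing any published parameterization:

- `decay` — closed form A(t) = A₀e^(−kt) (k = 0.1/min, A₀ = 10 nM).
- `reversible_pair` — A⇌B, total conserved.
- `linear_cascade(n)` — n activation/deactivation tiers, per-tier totals
  conserved.
- `receptor_inhibitor` — ligand/receptor binding, dimerization into an
  active dimer, and an antibody-like inhibitor sequestering the
  co-receptor; receptor, ligand and inhibitor totals conserved. Dosing the
  inhibitor suppresses the dimer dose-monotonically.
- `crosstalk_shared_phosphatase` — two cascades deactivated by one shared
  phosphatase plus an inhibitor of cascade X. Inhibiting X frees
  phosphatase, raising the Y-cascade's phosphatase complex — the
  crosstalk signature by which suppressing one pathway visibly shifts its
  neighbor.

What passing tests on these motifs shows is that the machinery —
compilation, event handling, conservation, comparison, rendering — is
correct on networks whose behavior is analytically known, and that the two
qualitative mechanisms arise from the stated topologies. It does not show
that any real pathway model is parameterized correctly; real models bring
their own kinetics through SBML.

## Verification script

`scripts/acceptance.py` recomputes, from scratch at run time: max relative
closed-form error (601 grid points), worst conservation drift, worst
deviation from fixed-step RK4 at h = 1e-4 min (fixtures ≤ 6 species),
dose-jump and pre-dose exactness (101-point grid), the comparison-algebra
residuals, dose-monotonicity violations across 10/30/100 nM and the dimer
inhibition percentage at 30 nM, the crosstalk complex increase percentage,
triangle edge-length coefficient of variation after 500 iterations, sphere
norm deviation, layout determinism, and SBML/CSV round-trip identity. The
`--seed` argument feeds every seeded component (layout initialization);
the simulation itself contains no randomness.

## Known limitations

No SSA/stochastic simulation, steady-state solving, or parameter fitting;
no SBML events/rules (by design, above); no pharmacokinetic clearance
beyond what the network's reactions encode; no continuous infusion dosing;
comparisons are pairwise only; frame export produces image sequences, not
video containers.
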