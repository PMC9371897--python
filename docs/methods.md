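# Methods

## Lattice model

A lattice design is declarative: motif type (J4/J3/DX), grid size,
connectivity, domain lengths, boundary policy and a phosphorylation
mask. The builder assembles an explicit graph of strands (ordered domain
runs, 5′→3′), duplexes (paired complementary domain instances, classed
intramotif/intermotif/boundary) and nicks (a 3′ terminus abutting a 5′
terminus on a continuous complementary template strand).

**Canonical strand layout.** Junction motifs place one strand per arm;
going 5′→3′ strand *s(M, d)* reads `stem(d) · root(d) · root(next(d))`
over a fixed cyclic arm order (N,E,S,W for J4). The root duplex of arm
*d* pairs the root(d) segments of *s(M, d)* and *s(M, prev(d))*; an
intermotif edge pairs the stems of the two facing arm strands and
carries exactly two nicks, one per motif side. Sealing the nick at
*A*'s side joins *s(A, prev(d))* to the neighbour's stem strand on the
continuous template *s(A, d)*, so the sealed segment length is
root + stem (21 bp for J4-I, 19 for J4-II, 26 for J4-III). Grid
coordinates are 0-based row-major; edges are identified by the
lower-coordinate motif and direction, giving stable ids for masks.

**J3 brick wall (6×7).** Each motif has east/west arms plus one
vertical arm alternating down/up with (row+col) parity; a vertical edge
forms wherever a down-arm meets an up-arm, i.e. at columns of matching
parity. This yields 36 horizontal + 18 vertical edges (4/3/4/3/4 over
the five row gaps) = 54 edges and 108 nicks, with 18 boundary arms left
unpaired. The exact vertical placement is config-visible; only the
totals are constrained by the published accounting.

**DX tiles.** The main text gives ligatable-nick totals (146 for DX-I,
110 for DX-II) but not the wiring, so the shipped DX configs are data
tuned to those totals: tiles connect brick-wall fashion through four
corner sticky-end ports (55 connections × 2 nicks for a 6×6), and the
DX-I tile (21-bp rigidity domains) additionally splits one strand
mid-rigidity, contributing one internal nick per tile with a continuous
21-bp template — the one-per-tile difference matches 146 − 110 = 36
exactly. A stricter transcription of the original tile schematics can
replace these configs without code changes.

**Boundary trimming.** With the strand-per-arm layout, each lattice
corner motif contains one strand whose two would-be terminal nicks both
sit on nonexistent boundary edges and which templates no nick. Such a
strand can never be locked in by any ligation event; the builder omits
it from the assembled design, as an addressable-lattice designer would
truncate it (motifs with no incident edges at all, e.g. a 1×1 build,
are standalone objects and keep all strands). Nick and edge counts are
unaffected; the 6×6 J4-I lattice has 140 strands after trimming.

Sequences are never modelled: no computation in scope depends on base
identity, so domains are typed lengths only.

## Ligation model

Each ligatable (mask-phosphorylated) nick seals independently with
probability *p* — a single-parameter Bernoulli model with no
cooperativity or steric term, the simplest model consistent with a
scalar "ligation efficiency". Sealed nicks merge strands along a
successor map; since each terminus joins at most one nick, products are
simple chains (linear) or closed cycles (circular), and nucleotide mass
is conserved exactly.

The exact product distribution sums over all 2^N sealed states
(capped at N ≤ 22; beyond that a capacity error points to Monte Carlo,
default 10 000 replicates). Species are keyed by composition; the gel
band table merges them by (length, circularity) — electrophoresis
separates by size, not identity — with a configurable detectability
floor (default mass fraction 0.005, mimicking detectability without
modelling staining chemistry).

Efficiency calibration uses the designed cycle of the 2×2 lattice: at
full ligation that lattice closes exactly one four-strand, four-nick
circle (the cycle is discovered from the config at run time, not
hard-coded), so an observed circular fraction *f* inverts as
*p̂* = *f*^(1/4). Any assembly-yield correction (circular products form
regardless of whether the full lattice assembled properly) must be
applied upstream; *f* is taken as given.

## Lock-in and intact-proportion simulation

Relative to a focal strand, a nick is X_I (joins its 3′ end), X_II
(joins its 5′ end) or Y (the strand is its continuous template).
Sealing X_I or X_II covalently extends the strand itself — full
lock-in. Sealing Y makes the strand's complementary side continuous
across root+stem — a partial anchoring effect.

Temperature enters only as a regime label (below the short-domain
melting range / between short-domain and ligated-segment melting /
above everything); no nearest-neighbour thermodynamics are computed,
because the stabilization argument is regime-based.

The default partial policy retains an unsealed strand only when it
templates at least one nick and *all* of its templated nicks are
sealed. The "at least one" clause is a deliberate design choice: a
strand that templates nothing has no ligation-extendable pairing and
always dissociates in the intermediate regime unless itself sealed;
without this clause such strands would be vacuously retained and the
p = 0 limit would not empty the lattice. `retain_never` and
`retain_always` (any sealed Y nick suffices) bracket the default, and
intact fractions are ordered accordingly.

The intermediate-regime survival cascade removes unlocked strands
simultaneously per sweep until a fixed point (≤ #strands sweeps); a
partial strand additionally requires the strands merged at its sealed Y
nicks to still be present. The condition is monotone in the surviving
set, so the fixed point is unique and order-independent.

Intact proportion is a Monte-Carlo mean of a per-replicate indicator
with binomial standard error. The default criterion,
`all_strands_retained`, is deliberately strict (a conservative
underestimate — transient dissociation events are counted as losses);
for that criterion the indicator reduces to "every strand is full or
partial against the intact lattice", which is computed vectorized and
verified against the explicit cascade in the tests. The alternative
`single_connected_component` criterion is far more forgiving: at
p = 0.7 the strict criterion on the 6×6 J4-I lattice is ≈0, while the
connected criterion is ≈0.99. Efficiency scans share one uniform draw
per nick per replicate across the grid (common random numbers), making
each replicate's indicator — and hence the scan — exactly monotone
nondecreasing in *p*.

## Melting analysis

Survival rate S(T) is the target-band intensity after incubation at T
normalized by the untreated 4 °C control band; values are not clipped
to [0, 1]. Yields use the linear intensity–mass correlation of a
standard band of known mass. Fits minimize unweighted least squares
over *raw replicate points* (means are for display only; no weighting
scheme is assumed).

Single model: S(T) = S_bot + (S_top − S_bot)/(1 + exp((T − T_half)/w)),
initialized at the extreme replicate means, T_half at the temperature
nearest the means' 0.5 crossing, w = span/10. Double model mixes two
transitions with fraction φ and enforces T1 < T2 by fitting the second
transition as a positive offset; T1/T2 are seeded at the two steepest
descent points of the smoothed mean curve. Tm is always the fitted
curve's S = 0.5 crossing located by bracketed root finding (reported Tm
satisfies |S(Tm) − 0.5| < 1e−6), *not* the inflection parameter; a
curve that never crosses 0.5 raises a Tm-undefined error rather than
extrapolating. Model selection between single and double is advisory
(AIC from the residual sum of squares); the caller chooses per dataset.

## Reconfiguration and topology

*Carving*: a mask makes only the edges of a target sub-shape ligatable;
at the intermediate regime the carved strands (all of whose terminal
nicks sit on unligatable edges) dissociate completely. A motif counts
as surviving when at least half its strands remain — with this strand
layout a carve boundary always costs interior motifs the single strand
whose two terminal nicks both lie on unligatable edges, and the ≥½ rule
reports the motif-level shape. At p = 1 the surviving motif set equals
the target exactly for all three shipped masks.

*Tubulation*: one wrapping boundary edge per row pairs the east
overhang of the last column with the west overhang of the first
(overhangs replace the boundary stems; two nicks per wrap edge, sealed
length overhang+root). A boundary duplex is permanent iff complementary
and (any of its nicks sealed, or length ≥ 10 bp — the positive-control
threshold, configurable); the sheet is tubular iff every row's wrap
duplex is permanent (a fractional closure threshold is available).
Non-complementary overhangs form no wrap duplexes and always classify
planar.

*Ring census and percolation*: circular species are rings; two rings
are declared catenated when they share at least one duplex in the
assembled lattice. True threading cannot be decided without a 3D
embedding; this surrogate is conservative for woven wireframe lattices
and is isolated in one predicate so a geometric test could replace it.
A catenation component spans when its rings touch all four grid sides
(site-percolation convention on motif coordinates — the percolation
threshold is not quantified in the source, so the spanning convention
is a declared choice). At full sealing the 6×6 J4-I lattice yields 25
plaquette rings whose shared edge duplexes link them into one spanning
chain-mail component. The exonuclease rule keys on covalent circularity
only: species with any free end are digested, circular species (and
hence interlocked components) survive. Whether nicked-but-hybridized
circular duplexes would also resist digestion is a biochemical detail
the rule ignores.

## Synthetic data

The generator emulates triplicate thermal-denaturation series: additive
Gaussian noise (default sd 0.05, the scale of triplicate scatter) on a
declared single/double Boltzmann truth, default grid 30–95 °C in 3 °C
steps with unligated (35–75 °C) and ligated (55–95 °C) window presets;
band tables are linear in mass with multiplicative lognormal noise
(default sd 0.1). Everything is seeded and the truth record travels
with the dataset, enabling closed-loop recovery tests: at zero noise
every analysis stage returns the truth to numerical precision; at
sd 0.05 the single-Boltzmann Tm is recovered within 1 °C in ≥95% of
200 seeds and both double-Boltzmann transitions within 2 °C.

What the generator does *not* emulate: baseline drift and smearing of
real gels, temperature-correlated noise, partial-assembly background
bands, and any coupling between ligation efficiency and survival noise.
Passing recovery tests therefore demonstrate correctness of the
estimators under the declared noise model, not robustness to every
artefact of real densitometry.

## Problem sizes and determinism

Exact enumerations run on the 2×2 lattice (2^8 states) and toy designs;
Monte-Carlo defaults are 10 000–50 000 replicates for intact fractions
and 20 000 for product distributions, with binomial standard errors
reported. All stochastic paths accept a seed (numpy Generator); equal
seeds give identical outcomes, and scan functions use common random
numbers for exact monotonicity.

## Known limitations

No 3D geometry, mechanics or curvature (tube formation is classified,
not simulated); no ligase kinetics or temperature dependence of
sealing; no intermolecular ligation between lattice copies; catenation
by shared duplex rather than geometric threading; the DX wiring is a
count-constrained reconstruction; AFM-scale mechanical fragility is out
of scope.
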