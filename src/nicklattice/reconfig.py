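"""Ligation-induced reconfiguration and topology analysis.

Two reconfiguration modes:

*Loss of function* — carving.  A phosphorylation mask makes only the
edges of a target sub-shape ligatable; after ligation, heating into the
intermediate regime dissociates the unligated segments and the lattice
reconfigures into the target shape.

*Gain of function* — sheet-to-tube closure.  Complementary 3-nt
overhangs on the east and west boundaries bind only transiently (OFF);
ligation locks the transient boundary duplexes in (ON) and the planar
sheet closes into a tube.  A boundary duplex counts as permanent when it
is complementary and either one of its nicks is sealed or its length
reaches the permanent-pairing threshold (default 10 bp, matching the
10-bp sticky-end positive control that tubulates without ligation).

Topology census: the circular products of an outcome form rings; two
rings are declared catenated when they share at least one duplex in the
assembled lattice.  True topological linkage (threading) would need a 3D
embedding; the shared-duplex surrogate is conservative for woven
wireframe lattices and is isolated in one predicate.  A catenation
component *spans* when its rings touch all four grid sides — at high
sealing density the interlocked rings percolate into a chain-mail
supermolecule, which also underlies the exonuclease toy rule: only
covalently circular species (and hence their interlocked components)
survive digestion, anything with a free end is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .lattice import LatticeGraph
from .ligation import LigationOutcome, ProductSpecies, enumerate_products, seal_nicks
from .stability import LockInRule, ThermalRegime, surviving_strands

__all__ = [
    "ReconfigSpec",
    "ReconfigResult",
    "TopologyReport",
    "RingCensus",
    "reconfigure",
    "classify_topology",
    "ring_census",
    "percolation_probability",
    "percolation_scan",
    "exonuclease_survival",
    "PERMANENT_LENGTH_BP",
]

PERMANENT_LENGTH_BP = 10  # unligated pairings >= this length never dissociate


@dataclass
class ReconfigSpec:
    """A reconfiguration experiment: base lattice + mask + expected shape."""

    lattice: LatticeGraph
    mask: frozenset[str]
    target_motifs: frozenset[tuple[int, int]]
    regime: ThermalRegime = ThermalRegime.INTERMEDIATE

    def __post_init__(self) -> None:
        grid = set(self.lattice.motifs)
        if not set(self.target_motifs) <= grid:
            raise ConfigurationError("target_shape contains motifs outside the grid")


@dataclass
class ReconfigResult:
    surviving_motifs: set[tuple[int, int]]
    exact_match: bool
    match_fraction: float
    n_reps: int
    retained_strands: set[str]


@dataclass
class TopologyReport:
    classification: str  # planar | tubular
    wrapping_cycle_found: bool
    boundary_states: dict[str, bool]  # boundary duplex id -> permanent?


@dataclass
class RingCensus:
    rings: list[ProductSpecies]
    catenation: nx.Graph
    spanning: bool


def _surviving_motifs(lattice: LatticeGraph, retained: set[str]) -> set[tuple[int, int]]:
    # A motif counts as surviving when at least half its strands remain;
    # a carve boundary always costs interior motifs the one strand whose
    # two terminal nicks both sit on unligatable edges.
    out = set()
    for coord, sids in lattice.motifs.items():
        kept = sum(1 for s in sids if s in retained)
        if kept * 2 >= len(sids):
            out.add(coord)
    return out


def reconfigure(
    spec: ReconfigSpec,
    p: float,
    seed: int | None = None,
    n_reps: int = 1,
    rule: LockInRule = LockInRule(),
) -> ReconfigResult:
    """Apply mask, seal nicks at ``p``, heat, and compare with the target.

    Reports the surviving motif coordinates of the first replicate, the
    exact-match flag against the target shape, and the exact-match
    fraction over ``n_reps`` replicates.
    """
    masked = spec.lattice.with_mask(spec.mask)
    rng = np.random.default_rng(seed)
    matches = 0
    first: tuple[set, set] | None = None
    for _ in range(max(n_reps, 1)):
        outcome = seal_nicks(masked, p, rng=rng)
        retained = surviving_strands(masked, outcome, spec.regime, rule)
        motifs = _surviving_motifs(masked, retained)
        if first is None:
            first = (motifs, retained)
        if motifs == set(spec.target_motifs):
            matches += 1
    motifs, retained = first  # type: ignore[misc]
    return ReconfigResult(
        surviving_motifs=motifs,
        exact_match=motifs == set(spec.target_motifs),
        match_fraction=matches / max(n_reps, 1),
        n_reps=max(n_reps, 1),
        retained_strands=retained,
    )


def classify_topology(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    permanent_length: int = PERMANENT_LENGTH_BP,
    closure_fraction: float = 1.0,
) -> TopologyReport:
    """Decide planar vs tubular from the boundary duplex states.

    Requires an overhang-boundary design.  The sheet closes into a tube
    when the permanent wrapping duplexes cover at least
    ``closure_fraction`` of the rows (default: every row).
    """
    design = lattice.design
    if design is None or design.boundary.policy != "overhang":
        raise ConfigurationError("topology classification needs an overhang boundary design")
    states: dict[str, bool] = {}
    nicks_by_duplex: dict[str, list[str]] = {}
    for n in lattice.nicks.values():
        for d in n.flank_duplexes:
            nicks_by_duplex.setdefault(d, []).append(n.id)
    for dup in lattice.boundary_duplexes:
        sealed = any(outcome.is_sealed(n) for n in nicks_by_duplex.get(dup.id, ()))
        states[dup.id] = sealed or dup.length >= permanent_length
    n_rows = design.rows
    n_permanent = sum(states.values())
    tubular = n_rows > 0 and n_permanent >= closure_fraction * n_rows and len(states) > 0
    return TopologyReport(
        classification="tubular" if tubular else "planar",
        wrapping_cycle_found=tubular,
        boundary_states=states,
    )


def _rings_linked(lattice: LatticeGraph, ring_a: frozenset[str], ring_b: frozenset[str]) -> bool:
    # Declared catenation criterion: the two rings share at least one
    # hybridized duplex in the assembled lattice.
    for dup in lattice.duplexes.values():
        if (dup.strand_a in ring_a and dup.strand_b in ring_b) or (
            dup.strand_a in ring_b and dup.strand_b in ring_a
        ):
            return True
    return False


def ring_census(lattice: LatticeGraph, outcome: LigationOutcome) -> RingCensus:
    """Circular species of an outcome and their catenation graph."""
    rings = [sp for sp in enumerate_products(lattice, outcome) if sp.circular]
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(len(rings)))
    members = [frozenset(r.member_strands) for r in rings]
    # Index rings by duplex membership instead of all-pairs strand scans.
    strand_ring: dict[str, int] = {}
    for i, m in enumerate(members):
        for s in m:
            strand_ring[s] = i
    for dup in lattice.duplexes.values():
        i = strand_ring.get(dup.strand_a)
        j = strand_ring.get(dup.strand_b)
        if i is not None and j is not None and i != j:
            g.add_edge(i, j)
    spanning = _has_spanning_component(lattice, rings, g)
    return RingCensus(rings, g, spanning)


def _has_spanning_component(
    lattice: LatticeGraph, rings: list[ProductSpecies], g: nx.Graph
) -> bool:
    if not rings or not lattice.motifs:
        return False
    rows = [c[0] for c in lattice.motifs]
    cols = [c[1] for c in lattice.motifs]
    r0, r1, c0, c1 = min(rows), max(rows), min(cols), max(cols)
    for comp in nx.connected_components(g):
        coords = {
            lattice.strands[s].motif for i in comp for s in rings[i].member_strands
        }
        touches = (
            any(r == r0 for r, _ in coords)
            and any(r == r1 for r, _ in coords)
            and any(c == c0 for _, c in coords)
            and any(c == c1 for _, c in coords)
        )
        if touches:
            return True
    return False


def percolation_probability(
    lattice: LatticeGraph,
    p: float,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo probability that the catenation graph spans the grid."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        outcome = seal_nicks(lattice, p, rng=rng)
        if ring_census(lattice, outcome).spanning:
            hits += 1
    frac = hits / n_reps
    se = float(np.sqrt(frac * (1 - frac) / n_reps))
    return frac, se


def percolation_scan(
    lattice: LatticeGraph,
    p_grid,
    n_reps: int = 500,
    seed: int | None = None,
):
    """Spanning probability across an efficiency grid with common random
    numbers, so the per-replicate spanning indicator is monotone in p."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    lig = lattice.ligatable_nicks
    u = rng.random((n_reps, len(lig)))
    rows = []
    for p in p_grid:
        hits = 0
        for i in range(n_reps):
            sealed = dict(zip(lig, (bool(b) for b in u[i] < p)))
            outcome = LigationOutcome(lattice, sealed, float(p))
            if ring_census(lattice, outcome).spanning:
                hits += 1
        frac = hits / n_reps
        rows.append(
            {
                "p": float(p),
                "spanning_probability": frac,
                "se": float(np.sqrt(frac * (1 - frac) / n_reps)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def exonuclease_survival(
    lattice: LatticeGraph, outcome: LigationOutcome
) -> list[ProductSpecies]:
    """Toy digestion rule: species with any free end are removed.

    Only covalently closed (circular) species survive; linked rings
    survive together as their catenation component, which by construction
    consists entirely of circular strands.
    """
    return [sp for sp in enumerate_products(lattice, outcome) if sp.circular]
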