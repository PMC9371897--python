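"""Lock-in classification and intact-lattice statistics after ligation.

The stabilization mechanism is kinetic interlocking: once a nick is
sealed, the short root/stem pairing domains on either side merge into one
continuous long paired segment (21 bp for J4-I) that cannot dissociate at
a temperature where the short domains alone would melt.  Temperature
enters only as a regime label:

``low``
    below the short-domain melting range — nothing dissociates;
``intermediate``
    above the short domains but below the combined ligated segment —
    only locked-in strands survive;
``high``
    above everything — no assembled lattice remains (covalent products
    persist as dissolved species).

Per-strand lock-in, relative to a focal strand (the study's X/Y nick
classes): sealing either of the strand's *own* terminal nicks (X_I at its
3' end, X_II at its 5' end) covalently extends the strand itself — full
lock-in.  Sealing the nick the strand *templates* (Y) makes its
complementary side continuous, anchoring the strand across one long
segment — a partial effect.  The default partial policy retains a strand
only when it templates at least one nick and all of them are sealed (a
strand that templates no nick has no ligation-extendable pairing and
always dissociates unless itself sealed); ``retain_never`` and
``retain_always`` (any sealed Y nick suffices) bracket this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lattice import LatticeGraph
from .ligation import LigationOutcome, seal_nicks

__all__ = [
    "ThermalRegime",
    "LockInRule",
    "IntactResult",
    "strand_lock_status",
    "surviving_strands",
    "surviving_structure",
    "intact_proportion",
    "efficiency_scan",
]


class ThermalRegime(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class LockInRule:
    """Retention rule for strands without a sealed terminal nick."""

    partial_policy: str = "retain_if_all_duplexes_templated"

    _POLICIES = (
        "retain_if_all_duplexes_templated",
        "retain_never",
        "retain_always",
    )

    def __post_init__(self) -> None:
        if self.partial_policy not in self._POLICIES:
            raise ValueError(f"unknown partial policy {self.partial_policy!r}")


@dataclass
class IntactResult:
    """Monte-Carlo intact-lattice proportion at one efficiency."""

    p: float
    intact_fraction: float
    se: float
    n_reps: int
    criterion: str
    flags: np.ndarray | None = None


def _is_full(lattice: LatticeGraph, outcome: LigationOutcome, strand_id: str) -> bool:
    five, three = lattice.terminal_nicks(strand_id)
    return any(n is not None and outcome.is_sealed(n) for n in (five, three))


def _partial_ok(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    strand_id: str,
    rule: LockInRule,
    retained: set[str] | None = None,
) -> bool:
    """Partial lock-in condition; if ``retained`` is given, the strands
    merged at the qualifying Y nicks must still be present."""
    if rule.partial_policy == "retain_never":
        return False
    y_nicks = lattice.templated_nicks(strand_id)
    if not y_nicks:
        return False

    def anchored(nick_id: str) -> bool:
        if not outcome.is_sealed(nick_id):
            return False
        if retained is None:
            return True
        nick = lattice.nicks[nick_id]
        return nick.upstream in retained and nick.downstream in retained

    if rule.partial_policy == "retain_always":
        return any(anchored(n) for n in y_nicks)
    return all(anchored(n) for n in y_nicks)


def strand_lock_status(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    strand_id: str,
    rule: LockInRule = LockInRule(),
) -> str:
    """Classify one strand as ``full``, ``partial`` or ``none``.

    Classification is against the intact lattice (no removal cascade):
    full if any of the strand's own terminal nicks (X_I/X_II) is sealed,
    else partial per the rule's Y-nick condition, else none.
    """
    if strand_id not in lattice.strands:
        raise KeyError(f"unknown strand id {strand_id!r}")
    if _is_full(lattice, outcome, strand_id):
        return "full"
    if _partial_ok(lattice, outcome, strand_id, rule):
        return "partial"
    return "none"


def surviving_strands(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    regime: ThermalRegime | str,
    rule: LockInRule = LockInRule(),
) -> set[str]:
    """Strand ids retained in the assembled structure at the given regime.

    The intermediate-regime removal cascades to a fixed point: dropping a
    strand deletes its duplexes, which can strip another partial strand's
    anchor.  Removal is simultaneous per sweep, so the result is the
    greatest fixed point and is independent of removal order.
    """
    regime = ThermalRegime(regime)
    if regime is ThermalRegime.LOW:
        return set(lattice.strands)
    if regime is ThermalRegime.HIGH:
        return set()
    retained = set(lattice.strands)
    full = {s for s in retained if _is_full(lattice, outcome, s)}
    while True:
        keep = full | {
            s
            for s in retained
            if s not in full and _partial_ok(lattice, outcome, s, rule, retained)
        }
        if keep == retained:
            return retained
        retained = keep


def surviving_structure(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    regime: ThermalRegime | str,
    rule: LockInRule = LockInRule(),
) -> LatticeGraph:
    """The assembled sub-lattice that survives an incubation regime."""
    return lattice.subgraph(surviving_strands(lattice, outcome, regime, rule))


def _intact_flag(
    lattice: LatticeGraph,
    outcome: LigationOutcome,
    regime: ThermalRegime,
    rule: LockInRule,
    criterion: str,
) -> bool:
    retained = surviving_strands(lattice, outcome, regime, rule)
    if criterion == "all_strands_retained":
        return len(retained) == len(lattice.strands)
    if criterion == "single_connected_component":
        if not retained:
            return False
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(retained)
        for d in lattice.duplexes.values():
            if d.strand_a in retained and d.strand_b in retained:
                g.add_edge(d.strand_a, d.strand_b)
        return nx.number_connected_components(g) == 1
    raise ValueError(f"unknown intact criterion {criterion!r}")


def _intact_flags_vectorized(
    lattice: LatticeGraph,
    sealed_matrix: np.ndarray,
    lig: Sequence[str],
    rule: LockInRule,
) -> np.ndarray:
    """all_strands_retained indicator per replicate, vectorized.

    The lattice is intact iff every strand is full or partial against the
    intact lattice: in that case the cascade removes nothing, and if any
    strand starts at ``none`` the all-strands criterion already fails.
    """
    idx = {n: i for i, n in enumerate(lig)}
    n_reps = sealed_matrix.shape[0]
    intact = np.ones(n_reps, dtype=bool)
    always = rule.partial_policy == "retain_always"
    never = rule.partial_policy == "retain_never"
    for sid in lattice.strands:
        five, three = lattice.terminal_nicks(sid)
        cols = [idx[n] for n in (five, three) if n is not None and n in idx]
        ok = (
            sealed_matrix[:, cols].any(axis=1)
            if cols
            else np.zeros(n_reps, dtype=bool)
        )
        if not never:
            y_cols = [idx[n] for n in lattice.templated_nicks(sid) if n in idx]
            if y_cols:
                y = (
                    sealed_matrix[:, y_cols].any(axis=1)
                    if always
                    else sealed_matrix[:, y_cols].all(axis=1)
                )
                ok = ok | y
        intact &= ok
        if not intact.any():
            break
    return intact


def intact_proportion(
    lattice: LatticeGraph,
    p: float,
    regime: ThermalRegime | str = ThermalRegime.INTERMEDIATE,
    rule: LockInRule = LockInRule(),
    criterion: str = "all_strands_retained",
    n_reps: int = 10_000,
    seed: int | None = None,
) -> IntactResult:
    """Monte-Carlo proportion of lattice copies that survive intact."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    regime = ThermalRegime(regime)
    rng = np.random.default_rng(seed)
    lig = lattice.ligatable_nicks
    if regime is ThermalRegime.INTERMEDIATE and criterion == "all_strands_retained":
        u = rng.random((n_reps, len(lig)))
        flags = _intact_flags_vectorized(lattice, u < p, lig, rule)
    else:
        flags = np.empty(n_reps, dtype=bool)
        for i in range(n_reps):
            outcome = seal_nicks(lattice, p, rng=rng)
            flags[i] = _intact_flag(lattice, outcome, regime, rule, criterion)
    frac = float(flags.mean())
    se = float(np.sqrt(frac * (1.0 - frac) / n_reps))
    return IntactResult(p, frac, se, n_reps, criterion, flags)


def efficiency_scan(
    lattice: LatticeGraph,
    p_grid: Iterable[float],
    regime: ThermalRegime | str = ThermalRegime.INTERMEDIATE,
    rule: LockInRule = LockInRule(),
    criterion: str = "all_strands_retained",
    n_reps: int = 10_000,
    seed: int | None = None,
    common_random_numbers: bool = True,
) -> pd.DataFrame:
    """Intact proportion across an efficiency grid.

    With common random numbers (one uniform draw per nick per replicate,
    shared across the grid, sealed where ``u < p``) each replicate's
    sealed set grows with ``p``, so the per-replicate intact indicator is
    monotone nondecreasing in ``p``.
    """
    p_grid = [float(p) for p in p_grid]
    if any(not 0.0 <= p <= 1.0 for p in p_grid):
        raise ValueError("p_grid values must lie in [0, 1]")
    regime = ThermalRegime(regime)
    lig = lattice.ligatable_nicks
    rng = np.random.default_rng(seed)
    rows = []
    if common_random_numbers:
        u = rng.random((n_reps, len(lig)))
        for p in p_grid:
            sealed = u < p
            if regime is ThermalRegime.INTERMEDIATE and criterion == "all_strands_retained":
                flags = _intact_flags_vectorized(lattice, sealed, lig, rule)
            else:
                flags = np.empty(n_reps, dtype=bool)
                for i in range(n_reps):
                    outcome = LigationOutcome(
                        lattice, dict(zip(lig, map(bool, sealed[i]))), p
                    )
                    flags[i] = _intact_flag(lattice, outcome, regime, rule, criterion)
            frac = float(flags.mean())
            rows.append(
                {
                    "p": p,
                    "intact_fraction": frac,
                    "se": float(np.sqrt(frac * (1 - frac) / n_reps)),
                    "n_reps": n_reps,
                    "criterion": criterion,
                }
            )
    else:
        for p in p_grid:
            res = intact_proportion(
                lattice, p, regime, rule, criterion, n_reps,
                seed=int(rng.integers(2**31)),
            )
            rows.append(
                {
                    "p": p,
                    "intact_fraction": res.intact_fraction,
                    "se": res.se,
                    "n_reps": n_reps,
                    "criterion": criterion,
                }
            )
    return pd.DataFrame(rows)
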