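"""Strand/domain/nick graph models of addressable DNA nanostructure lattices.

An addressable lattice is assembled from junction motifs (4-arm ``J4``,
3-arm ``J3``) or double-crossover tiles (``DX``) placed on a grid.  Each
arm of a junction motif carries a double-stranded *root* domain and a
single-stranded *stem* domain; two complementary stems from neighbouring
motifs hybridize into an intermotif edge.  Where a strand's terminus abuts
another strand's terminus on a continuous complementary template, the
backbone carries a *nick* that T4 ligase can seal into a phosphodiester
bond — provided the downstream 5' end is phosphorylated (the
``phosphorylation mask``).

The canonical strand layout used here assigns one component strand per
arm.  Going 5'→3', strand ``s(M, d)`` of motif ``M`` reads::

    stem(d)  root(d)  root(next(d))

with arms in a fixed cyclic order per motif type.  The root duplex of arm
``d`` pairs the ``root(d)`` segments of ``s(M, d)`` and ``s(M, prev(d))``.
An intermotif edge between ``A.armA`` and ``B.armB`` pairs the stems of
``s(A, armA)`` and ``s(B, armB)`` and carries exactly two nicks, one at
each motif's side; sealing the nick at ``A``'s side covalently joins the
3' end of ``s(A, prev(armA))`` to the 5' end of ``s(B, armB)`` on the
continuous template ``s(A, armA)``, creating a combined paired segment of
``root + stem`` base pairs (21 bp for the J4-I design).

DX tiles use the same cyclic construction over four corner ports with
*rigidity*/*sticky* domains in place of root/stem; the DX-I tile
additionally splits one strand mid-rigidity, contributing one internal
nick per tile.  Domains are abstract typed segments with lengths; base
identity is never modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ConfigurationError

__all__ = [
    "DomainSpec",
    "MotifSpec",
    "BoundarySpec",
    "LatticeDesign",
    "Strand",
    "Duplex",
    "Nick",
    "LatticeGraph",
    "build_lattice",
    "count_nicks",
    "ligated_segment_length",
    "apply_phosphorylation_mask",
    "expand_strand_mask",
    "export_graph",
    "load_graph",
    "design_from_dict",
    "load_design",
    "square_grid_edge_count",
]

# Cyclic arm orders.  J3 motifs alternate between an "up" variant (north
# vertical arm) and a "down" variant (south vertical arm) in a brick wall.
_J4_ARMS = ("N", "E", "S", "W")
_J3_ARMS_UP = ("E", "N", "W")
_J3_ARMS_DOWN = ("E", "W", "S")
_DX_ARMS = ("NW", "NE", "SE", "SW")

_CONNECTIVITY_FOR_MOTIF = {
    "J4": "square_grid",
    "J3": "brick_wall",
    "DX": "dx_rows",
}


@dataclass(frozen=True)
class DomainSpec:
    """A typed strand segment.

    role
        One of ``root``, ``stem``, ``rigidity``, ``sticky``, ``overhang``.
        Root/rigidity domains pair within a motif; stem/sticky/overhang
        domains pair between motifs (or across the lattice boundary).
    length
        Segment length in nucleotides (base pairs when paired).
    """

    role: str
    length: int

    _ROLES = frozenset({"root", "stem", "rigidity", "sticky", "overhang"})

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ConfigurationError(f"unknown domain role {self.role!r}")
        if self.length < 1:
            raise ConfigurationError("domain length must be >= 1")


@dataclass(frozen=True)
class MotifSpec:
    """Geometry-free description of a lattice building block.

    ``root_length``/``stem_length`` are the intramotif and intermotif
    pairing-domain lengths (named rigidity/sticky for DX tiles via
    ``root_role``/``stem_role``).  ``internal_nicks`` (DX only) adds one
    mid-rigidity nick per tile by splitting the first-arm strand.
    """

    motif_type: str
    root_length: int
    stem_length: int
    internal_nicks: int = 0
    root_role: str = "root"
    stem_role: str = "stem"

    def __post_init__(self) -> None:
        if self.motif_type not in ("J4", "J3", "DX"):
            raise ConfigurationError(f"unknown motif type {self.motif_type!r}")
        if self.internal_nicks not in (0, 1):
            raise ConfigurationError("internal_nicks must be 0 or 1")
        if self.internal_nicks and self.motif_type != "DX":
            raise ConfigurationError("internal nicks are a DX-tile feature")
        if self.root_length < 2 and self.internal_nicks:
            raise ConfigurationError("cannot split a 1-bp rigidity domain")

    def arms(self, row: int, col: int) -> tuple[str, ...]:
        if self.motif_type == "J4":
            return _J4_ARMS
        if self.motif_type == "DX":
            return _DX_ARMS
        # J3 brick wall: vertical arm points down when (row+col) is even.
        return _J3_ARMS_DOWN if (row + col) % 2 == 0 else _J3_ARMS_UP


@dataclass(frozen=True)
class BoundarySpec:
    """Lattice boundary policy.

    ``blunt`` leaves boundary arms unpaired.  ``overhang`` replaces the
    boundary stems on the listed sides with short overhang domains; when
    ``complementary`` is true the east overhang of each row pairs with the
    west overhang of the same row, wrapping the sheet into a potential
    tube (one boundary edge per row, two nicks each).
    """

    policy: str = "blunt"
    sides: tuple[str, ...] = ()
    overhang_length: int = 0
    complementary: bool = False

    def __post_init__(self) -> None:
        if self.policy not in ("blunt", "overhang"):
            raise ConfigurationError(f"unknown boundary policy {self.policy!r}")
        if self.policy == "overhang":
            if set(self.sides) - {"E", "W"}:
                raise ConfigurationError("overhang sides must be E and/or W")
            if self.overhang_length < 1:
                raise ConfigurationError("overhang_length must be >= 1")


@dataclass(frozen=True)
class LatticeDesign:
    """A declarative lattice design: motif, grid, boundary and mask."""

    name: str
    motif: MotifSpec
    rows: int
    cols: int
    connectivity: str
    boundary: BoundarySpec = BoundarySpec()
    mask: str | frozenset[str] = "all"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("rows and cols must be >= 1")
        expected = _CONNECTIVITY_FOR_MOTIF[self.motif.motif_type]
        if self.connectivity != expected:
            raise ConfigurationError(
                f"connectivity {self.connectivity!r} is incompatible with "
                f"motif type {self.motif.motif_type!r} (expected {expected!r})"
            )
        if not isinstance(self.mask, str):
            object.__setattr__(self, "mask", frozenset(self.mask))
        elif self.mask != "all":
            raise ConfigurationError("mask must be 'all' or a set of nick ids")


@dataclass(frozen=True)
class Strand:
    """One component strand: an ordered run of domains, 5'→3'."""

    id: str
    motif: tuple[int, int]
    arm: str
    domains: tuple[DomainSpec, ...]

    @property
    def length(self) -> int:
        return sum(d.length for d in self.domains)


@dataclass(frozen=True)
class Duplex:
    """A paired pair of complementary domain instances.

    ``cls`` is ``intramotif`` (root/rigidity), ``intermotif`` (edge) or
    ``boundary`` (wrapping overhang duplex).
    """

    id: str
    cls: str
    length: int
    strand_a: str
    strand_b: str


@dataclass(frozen=True)
class Nick:
    """A sealable backbone break.

    ``upstream`` contributes its 3'-hydroxyl, ``downstream`` its 5' end
    (ligatable only when phosphorylated, i.e. in the mask).
    ``template_strand`` is the continuous complementary strand spanning
    the break; ``flank_duplexes`` are the duplex instances on either side,
    whose combined length ``sealed_length`` becomes one continuous paired
    segment once the nick is sealed.
    """

    id: str
    upstream: str
    downstream: str
    template_strand: str
    flank_duplexes: tuple[str, ...]
    sealed_length: int
    ligatable: bool = True


def square_grid_edge_count(rows: int, cols: int) -> int:
    """Closed-form intermotif edge count of a square-grid junction lattice."""
    return rows * (cols - 1) + cols * (rows - 1)


class LatticeGraph:
    """An assembled lattice: strands, duplexes, nicks and grid coordinates.

    Instances are immutable in spirit: mutating operations (e.g. applying
    a phosphorylation mask) return new graphs.
    """

    def __init__(
        self,
        strands: Mapping[str, Strand],
        duplexes: Mapping[str, Duplex],
        nicks: Mapping[str, Nick],
        motifs: Mapping[tuple[int, int], tuple[str, ...]],
        design: LatticeDesign | None = None,
    ) -> None:
        self.strands = dict(strands)
        self.duplexes = dict(duplexes)
        self.nicks = dict(nicks)
        self.motifs = dict(motifs)
        self.design = design
        self._index()

    def _index(self) -> None:
        self._term3: dict[str, str] = {}
        self._term5: dict[str, str] = {}
        self._templated: dict[str, list[str]] = {s: [] for s in self.strands}
        for nick in self.nicks.values():
            if nick.upstream in self._term3 or nick.downstream in self._term5:
                raise ConfigurationError(
                    f"strand terminus participates in two nicks near {nick.id}"
                )
            self._term3[nick.upstream] = nick.id
            self._term5[nick.downstream] = nick.id
            self._templated[nick.template_strand].append(nick.id)
        self._strand_duplexes: dict[str, list[str]] = {s: [] for s in self.strands}
        for dup in self.duplexes.values():
            self._strand_duplexes[dup.strand_a].append(dup.id)
            self._strand_duplexes[dup.strand_b].append(dup.id)

    # -- structural accounting -------------------------------------------

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    @property
    def intermotif_edges(self) -> list[Duplex]:
        return [d for d in self.duplexes.values() if d.cls == "intermotif"]

    @property
    def boundary_duplexes(self) -> list[Duplex]:
        return [d for d in self.duplexes.values() if d.cls == "boundary"]

    def count_nicks(self, ligatable_only: bool = False) -> int:
        if ligatable_only:
            return sum(1 for n in self.nicks.values() if n.ligatable)
        return len(self.nicks)

    @property
    def ligatable_nicks(self) -> list[str]:
        return sorted(n.id for n in self.nicks.values() if n.ligatable)

    def total_nt(self) -> int:
        return sum(s.length for s in self.strands.values())

    def ligated_segment_length(self, nick_id: str) -> int:
        """Length (bp) of the continuous duplex formed by sealing this nick."""
        try:
            return self.nicks[nick_id].sealed_length
        except KeyError:
            raise KeyError(f"unknown nick id {nick_id!r}") from None

    # -- per-strand views ------------------------------------------------

    def terminal_nicks(self, strand_id: str) -> tuple[str | None, str | None]:
        """The nicks at a strand's (5', 3') termini, ``None`` for free ends."""
        if strand_id not in self.strands:
            raise KeyError(f"unknown strand id {strand_id!r}")
        return self._term5.get(strand_id), self._term3.get(strand_id)

    def templated_nicks(self, strand_id: str) -> tuple[str, ...]:
        """Nicks for which this strand is the continuous complementary template."""
        if strand_id not in self.strands:
            raise KeyError(f"unknown strand id {strand_id!r}")
        return tuple(self._templated[strand_id])

    def duplexes_of(self, strand_id: str) -> tuple[str, ...]:
        return tuple(self._strand_duplexes[strand_id])

    def nick_label(self, nick_id: str, strand_id: str) -> str | None:
        """Classify a nick relative to a focal strand.

        ``X_I``/``X_II``: the nick joins the strand's own 3'/5' terminus
        (full lock-in on sealing).  ``Y``: the strand templates the nick
        (partial lock-in).  ``None``: unrelated.
        """
        nick = self.nicks[nick_id]
        if nick.upstream == strand_id:
            return "X_I"
        if nick.downstream == strand_id:
            return "X_II"
        if nick.template_strand == strand_id:
            return "Y"
        return None

    # -- derived graphs --------------------------------------------------

    def with_mask(self, mask: Iterable[str]) -> "LatticeGraph":
        mask = frozenset(mask)
        unknown = mask - self.nicks.keys()
        if unknown:
            raise ConfigurationError(
                f"mask references nonexistent nicks: {sorted(unknown)[:5]}"
            )
        nicks = {
            nid: replace(n, ligatable=nid in mask) for nid, n in self.nicks.items()
        }
        return LatticeGraph(self.strands, self.duplexes, nicks, self.motifs, self.design)

    def subgraph(self, retained: Iterable[str]) -> "LatticeGraph":
        """Restrict to a strand subset, dropping dangling duplexes and nicks."""
        keep = set(retained)
        strands = {s: st for s, st in self.strands.items() if s in keep}
        duplexes = {
            d: dup
            for d, dup in self.duplexes.items()
            if dup.strand_a in keep and dup.strand_b in keep
        }
        nicks = {
            n: nk
            for n, nk in self.nicks.items()
            if nk.upstream in keep and nk.downstream in keep and nk.template_strand in keep
        }
        motifs = {
            coord: tuple(s for s in sids if s in keep)
            for coord, sids in self.motifs.items()
        }
        motifs = {c: s for c, s in motifs.items() if s}
        return LatticeGraph(strands, duplexes, nicks, motifs, self.design)

    def signature(self) -> tuple:
        """A canonical structural fingerprint (used for equality in tests)."""
        return (
            tuple(sorted((s.id, s.motif, s.arm, s.domains) for s in self.strands.values())),
            tuple(sorted((d.id, d.cls, d.length, d.strand_a, d.strand_b) for d in self.duplexes.values())),
            tuple(
                sorted(
                    (n.id, n.upstream, n.downstream, n.template_strand,
                     n.flank_duplexes, n.sealed_length, n.ligatable)
                    for n in self.nicks.values()
                )
            ),
        )


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------


def _edge_list(design: LatticeDesign) -> Iterator[tuple[tuple[int, int, str], tuple[int, int, str], str]]:
    """Yield ((rA, cA, armA), (rB, cB, armB), edge_id) intermotif edges."""
    rows, cols = design.rows, design.cols
    conn = design.connectivity
    if conn == "square_grid":
        for r in range(rows):
            for c in range(cols):
                if c + 1 < cols:
                    yield (r, c, "E"), (r, c + 1, "W"), f"e_h_r{r}c{c}"
                if r + 1 < rows:
                    yield (r, c, "S"), (r + 1, c, "N"), f"e_v_r{r}c{c}"
    elif conn == "brick_wall":
        for r in range(rows):
            for c in range(cols):
                if c + 1 < cols:
                    yield (r, c, "E"), (r, c + 1, "W"), f"e_h_r{r}c{c}"
                if r + 1 < rows and (r + c) % 2 == 0:
                    yield (r, c, "S"), (r + 1, c, "N"), f"e_v_r{r}c{c}"
    elif conn == "dx_rows":
        # Brick-wall of DX tiles: each tile connects through its SW/SE
        # corner ports to the NE/NW ports of two tiles in the next row.
        for r in range(rows - 1):
            for c in range(cols):
                if r % 2 == 0:
                    if c - 1 >= 0:
                        yield (r, c, "SW"), (r + 1, c - 1, "NE"), f"e_d_r{r}c{c}_sw"
                    yield (r, c, "SE"), (r + 1, c, "NW"), f"e_d_r{r}c{c}_se"
                else:
                    yield (r, c, "SW"), (r + 1, c, "NE"), f"e_d_r{r}c{c}_sw"
                    if c + 1 < cols:
                        yield (r, c, "SE"), (r + 1, c + 1, "NW"), f"e_d_r{r}c{c}_se"
    else:  # pragma: no cover - guarded by LatticeDesign validation
        raise ConfigurationError(f"unknown connectivity {conn!r}")


def _overhang_arm(design: LatticeDesign, r: int, c: int, arm: str) -> bool:
    b = design.boundary
    if b.policy != "overhang":
        return False
    return (arm == "E" and "E" in b.sides and c == design.cols - 1) or (
        arm == "W" and "W" in b.sides and c == 0
    )


def build_lattice(design: LatticeDesign) -> LatticeGraph:
    """Assemble the explicit strand/duplex/nick graph of a design.

    Deterministic: identical designs build graph-identical lattices,
    including all identifiers.
    """
    motif = design.motif
    root = DomainSpec(motif.root_role, motif.root_length)
    stem = DomainSpec(motif.stem_role, motif.stem_length)

    strands: dict[str, Strand] = {}
    duplexes: dict[str, Duplex] = {}
    nicks: dict[str, Nick] = {}
    motifs: dict[tuple[int, int], tuple[str, ...]] = {}

    def sid(r: int, c: int, arm: str) -> str:
        return f"s_r{r}c{c}_{arm}"

    # Strand holding each arm's 5'-leading (stem/overhang) segment, and the
    # strand whose 3' end abuts each arm's root outer end.  For split DX
    # strands these differ from the nominal per-arm strand.
    lead_strand: dict[tuple[int, int, str], str] = {}
    tail_strand: dict[tuple[int, int, str], str] = {}

    for r in range(design.rows):
        for c in range(design.cols):
            arms = motif.arms(r, c)
            motif_strands: list[str] = []
            for i, arm in enumerate(arms):
                nxt = arms[(i + 1) % len(arms)]
                if _overhang_arm(design, r, c, arm):
                    first = DomainSpec("overhang", design.boundary.overhang_length)
                else:
                    first = stem
                s = Strand(sid(r, c, arm), (r, c), arm, (first, root, root))
                strands[s.id] = s
                motif_strands.append(s.id)
                lead_strand[(r, c, arm)] = s.id
                tail_strand[(r, c, nxt)] = s.id
            # Intramotif root duplexes: root(d) of s(M,d) with root(d) of
            # s(M, prev(d)).
            for i, arm in enumerate(arms):
                prv = arms[(i - 1) % len(arms)]
                duplexes[f"d_root_r{r}c{c}_{arm}"] = Duplex(
                    f"d_root_r{r}c{c}_{arm}",
                    "intramotif",
                    motif.root_length,
                    sid(r, c, arm),
                    sid(r, c, prv),
                )
            # DX-I internal nick: split the first-arm strand mid-rigidity.
            if motif.internal_nicks:
                arm0 = arms[0]
                nxt0 = arms[1]
                old = strands.pop(sid(r, c, arm0))
                half_a = motif.root_length // 2
                half_b = motif.root_length - half_a
                first = old.domains[0]
                sa = Strand(old.id + "_a", (r, c), arm0, (first, DomainSpec(motif.root_role, half_a)))
                sb = Strand(old.id + "_b", (r, c), arm0, (DomainSpec(motif.root_role, half_b), root))
                strands[sa.id] = sa
                strands[sb.id] = sb
                motif_strands[motif_strands.index(old.id)] = sa.id
                motif_strands.insert(motif_strands.index(sa.id) + 1, sb.id)
                lead_strand[(r, c, arm0)] = sa.id
                tail_strand[(r, c, nxt0)] = sb.id
                # Fix duplexes referencing the split strand.
                rid = f"d_root_r{r}c{c}_{arm0}"
                # root(arm0) of the split strand spans both halves; keep one
                # duplex instance, anchored on sb (whose segment reaches the
                # arm's inner end), template continuity lives on the partner.
                dup = duplexes[rid]
                duplexes[rid] = replace(dup, strand_a=sb.id)
                nid = f"d_root_r{r}c{c}_{nxt0}"
                dupn = duplexes[nid]
                duplexes[nid] = replace(dupn, strand_a=dupn.strand_a if dupn.strand_a != old.id else sb.id,
                                        strand_b=dupn.strand_b if dupn.strand_b != old.id else sb.id)
                # Outer rigidity half pairs within the same root duplex; the
                # sticky segment of sa pairs in the arm0 edge duplex (below).
                nick_id = f"n_int_r{r}c{c}"
                nicks[nick_id] = Nick(
                    nick_id,
                    upstream=sa.id,
                    downstream=sb.id,
                    template_strand=sid(r, c, arms[-1]),  # prev(arm0) strand
                    flank_duplexes=(rid,),
                    sealed_length=motif.root_length,
                )
            motifs[(r, c)] = tuple(motif_strands)

    arm_lists = {coord: motif.arms(*coord) for coord in motifs}

    def prev_arm(r: int, c: int, arm: str) -> str:
        arms = arm_lists[(r, c)]
        return arms[(arms.index(arm) - 1) % len(arms)]

    def add_edge_nicks(a: tuple[int, int, str], b: tuple[int, int, str], dup: Duplex, edge_id: str) -> None:
        # One nick at each motif's side.  At A's side, the 3' end of A's
        # previous-arm strand abuts the 5' end of B's lead strand, on the
        # continuous template of A's own arm strand.
        for side, (near, far) in (("a", (a, b)), ("b", (b, a))):
            r, c, arm = near
            fr, fc, farm = far
            nick_id = f"{edge_id}:{side}"
            root_dup = f"d_root_r{r}c{c}_{arm}"
            nicks[nick_id] = Nick(
                nick_id,
                upstream=tail_strand[(r, c, arm)],
                downstream=lead_strand[(fr, fc, farm)],
                template_strand=lead_strand[(r, c, arm)],
                flank_duplexes=(root_dup, dup.id),
                sealed_length=design.motif.root_length + dup.length,
            )

    for a, b, edge_id in _edge_list(design):
        ra, ca, arma = a
        rb, cb, armb = b
        dup = Duplex(
            f"d_{edge_id}",
            "intermotif",
            motif.stem_length,
            lead_strand[(ra, ca, arma)],
            lead_strand[(rb, cb, armb)],
        )
        duplexes[dup.id] = dup
        add_edge_nicks(a, b, dup, edge_id)

    # Wrapping boundary edges (sheet-to-tube designs): the east overhang of
    # each row pairs with the west overhang of the same row.
    b = design.boundary
    if b.policy == "overhang" and b.complementary and {"E", "W"} <= set(b.sides) and design.cols >= 2:
        for r in range(design.rows):
            edge_id = f"e_w_r{r}"
            a = (r, design.cols - 1, "E")
            w = (r, 0, "W")
            dup = Duplex(
                f"d_{edge_id}",
                "boundary",
                b.overhang_length,
                lead_strand[a],
                lead_strand[w],
            )
            duplexes[dup.id] = dup
            add_edge_nicks(a, w, dup, edge_id)

    # Boundary trimming: a strand that participates in no nick anywhere —
    # neither as a terminus nor as a template — can never be locked in by
    # ligation; such ligation-inert strands arise at lattice corners,
    # where two cyclically adjacent arms both face the boundary, and are
    # omitted from the assembled design (as an addressable-lattice
    # designer would truncate them).  Motifs with no incident edges at
    # all (e.g. a 1×1 build) are standalone objects and keep all strands.
    involved: set[str] = set()
    for n in nicks.values():
        involved.update((n.upstream, n.downstream, n.template_strand))
    edged_motifs = {
        s.motif for d in duplexes.values() if d.cls != "intramotif"
        for s in (strands[d.strand_a], strands[d.strand_b])
    }
    trimmed = {
        sid
        for sid, s in strands.items()
        if sid not in involved and s.motif in edged_motifs
    }
    if trimmed:
        strands = {s: st for s, st in strands.items() if s not in trimmed}
        duplexes = {
            d: dup
            for d, dup in duplexes.items()
            if dup.strand_a not in trimmed and dup.strand_b not in trimmed
        }
        motifs = {
            coord: tuple(s for s in sids if s not in trimmed)
            for coord, sids in motifs.items()
        }

    lattice = LatticeGraph(strands, duplexes, nicks, motifs, design)
    if design.mask != "all":
        lattice = lattice.with_mask(design.mask)  # type: ignore[arg-type]
    return lattice


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------


def count_nicks(lattice: LatticeGraph, ligatable_only: bool = False) -> int:
    """Count nicks, optionally only the mask-phosphorylated (ligatable) ones."""
    return lattice.count_nicks(ligatable_only=ligatable_only)


def ligated_segment_length(lattice: LatticeGraph, nick_id: str) -> int:
    """Continuous duplex length (bp) formed if the given nick is sealed."""
    return lattice.ligated_segment_length(nick_id)


def apply_phosphorylation_mask(lattice: LatticeGraph, mask: Iterable[str]) -> LatticeGraph:
    """Return a lattice whose ligatable flags are set exactly to ``mask``."""
    return lattice.with_mask(mask)


def expand_strand_mask(lattice: LatticeGraph, strand_ids: Iterable[str]) -> set[str]:
    """Expand a strand-level phosphorylation mask to nick ids.

    A 5'-phosphorylated strand makes ligatable exactly the nicks whose
    downstream 5' end belongs to it.
    """
    sset = set(strand_ids)
    unknown = sset - lattice.strands.keys()
    if unknown:
        raise ConfigurationError(f"mask references unknown strands: {sorted(unknown)[:5]}")
    return {n.id for n in lattice.nicks.values() if n.downstream in sset}


# ---------------------------------------------------------------------------
# Plain-text graph export / import
# ---------------------------------------------------------------------------


def export_graph(lattice: LatticeGraph, path: str | Path) -> Path:
    """Write a typed edge-list text file, round-trippable by ``load_graph``."""
    path = Path(path)
    lines = ["# nicklattice graph v1"]
    for s in sorted(lattice.strands.values(), key=lambda s: s.id):
        doms = ",".join(f"{d.role}:{d.length}" for d in s.domains)
        lines.append(f"strand\t{s.id}\t{s.motif[0]}\t{s.motif[1]}\t{s.arm}\t{doms}")
    for d in sorted(lattice.duplexes.values(), key=lambda d: d.id):
        lines.append(f"duplex\t{d.id}\t{d.cls}\t{d.length}\t{d.strand_a}\t{d.strand_b}")
    for n in sorted(lattice.nicks.values(), key=lambda n: n.id):
        flanks = ",".join(n.flank_duplexes)
        lines.append(
            f"nick\t{n.id}\t{n.upstream}\t{n.downstream}\t{n.template_strand}"
            f"\t{flanks}\t{n.sealed_length}\t{int(n.ligatable)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_graph(path: str | Path) -> LatticeGraph:
    """Reload a graph written by ``export_graph``."""
    strands: dict[str, Strand] = {}
    duplexes: dict[str, Duplex] = {}
    nicks: dict[str, Nick] = {}
    motifs: dict[tuple[int, int], list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        kind, *f = line.split("\t")
        if kind == "strand":
            sid, r, c, arm, doms = f
            domains = tuple(
                DomainSpec(role, int(length))
                for role, length in (d.split(":") for d in doms.split(","))
            )
            strands[sid] = Strand(sid, (int(r), int(c)), arm, domains)
            motifs.setdefault((int(r), int(c)), []).append(sid)
        elif kind == "duplex":
            did, cls, length, sa, sb = f
            duplexes[did] = Duplex(did, cls, int(length), sa, sb)
        elif kind == "nick":
            nid, up, down, tmpl, flanks, sealed, lig = f
            nicks[nid] = Nick(
                nid, up, down, tmpl, tuple(flanks.split(",")), int(sealed), bool(int(lig))
            )
        else:
            raise ConfigurationError(f"unknown record kind {kind!r} in {path}")
    return LatticeGraph(
        strands, duplexes, nicks, {k: tuple(v) for k, v in motifs.items()}
    )


# ---------------------------------------------------------------------------
# Design config (JSON) loading
# ---------------------------------------------------------------------------


def design_from_dict(cfg: Mapping) -> LatticeDesign:
    """Build a ``LatticeDesign`` from a parsed design config dict."""
    try:
        m = cfg["motif"]
        motif = MotifSpec(
            motif_type=m["type"],
            root_length=m["root_length"],
            stem_length=m["stem_length"],
            internal_nicks=m.get("internal_nicks", 0),
            root_role=m.get("root_role", "root"),
            stem_role=m.get("stem_role", "stem"),
        )
        bnd = cfg.get("boundary", {"policy": "blunt"})
        boundary = BoundarySpec(
            policy=bnd.get("policy", "blunt"),
            sides=tuple(bnd.get("sides", ())),
            overhang_length=bnd.get("overhang_length", 0),
            complementary=bnd.get("complementary", False),
        )
        mask = cfg.get("mask", "all")
        return LatticeDesign(
            name=cfg.get("name", "design"),
            motif=motif,
            rows=cfg["rows"],
            cols=cfg["cols"],
            connectivity=cfg["connectivity"],
            boundary=boundary,
            mask=mask if isinstance(mask, str) else frozenset(mask),
        )
    except KeyError as exc:
        raise ConfigurationError(f"design config missing key {exc}") from exc


def load_design(source: str | Path) -> LatticeDesign:
    """Load a design from a JSON file path or a built-in design name."""
    p = Path(source)
    if p.suffix == ".json" or p.exists():
        return design_from_dict(json.loads(p.read_text()))
    from .builtin import get_design  # local import to avoid a cycle

    return get_design(str(source))
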