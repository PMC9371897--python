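"""Built-in design and mask configurations.

The shipped designs replicate the study's lattice series: three 6×6
4-arm-junction lattices (J4-I/II/III, differing in root/stem lengths), a
6×7 3-arm-junction brick-wall lattice (J3), two 6×6 DX-tile lattices
(DX-I/DX-II) and the small J4-I-derived 2×2 and 3×3 calibration lattices.
Reconfiguration fixtures cover three loss-of-function carving masks
(fig4a/b/c) and the gain-of-function sheet-to-tube design (fig4d) with
its non-complementary / unligatable / 10-bp sticky-end controls.

The J4/J3 wiring follows the printed nick accounting directly.  The DX
tile wiring is a package choice constrained by the printed ligatable-nick
totals (146 for DX-I, 110 for DX-II): tiles connect brick-wall fashion
through corner sticky ends (55 connections × 2 nicks for a 6×6) and the
DX-I tile carries one internal mid-rigidity nick (one per tile accounts
exactly for the 36-nick difference between the two DX designs).
"""

from __future__ import annotations

import copy
from typing import Mapping

from .errors import ConfigurationError
from .lattice import LatticeDesign, LatticeGraph, build_lattice, design_from_dict

__all__ = ["BUILTIN_DESIGNS", "BUILTIN_MASKS", "get_design", "build_design", "mask_nicks", "load_mask"]


def _j4(name: str, root: int, stem: int, rows: int = 6, cols: int = 6, **extra) -> dict:
    cfg = {
        "name": name,
        "motif": {"type": "J4", "root_length": root, "stem_length": stem},
        "rows": rows,
        "cols": cols,
        "connectivity": "square_grid",
        "boundary": {"policy": "blunt"},
        "mask": "all",
    }
    cfg.update(extra)
    return cfg


BUILTIN_DESIGNS: dict[str, dict] = {
    # 6×6 4-arm junction lattices: 36 motifs, 60 edges, 120 nicks.
    "J4-I": _j4("J4-I", root=11, stem=10),
    "J4-II": _j4("J4-II", root=13, stem=6),
    "J4-III": _j4("J4-III", root=16, stem=10),
    # Calibration lattices derived from J4-I.
    "J4-I_2x2": _j4("J4-I_2x2", root=11, stem=10, rows=2, cols=2),
    "J4-I_3x3": _j4("J4-I_3x3", root=11, stem=10, rows=3, cols=3),
    # 6×7 3-arm junction brick wall: 54 edges, 108 nicks.
    "J3": {
        "name": "J3",
        "motif": {"type": "J3", "root_length": 11, "stem_length": 10},
        "rows": 6,
        "cols": 7,
        "connectivity": "brick_wall",
        "boundary": {"policy": "blunt"},
        "mask": "all",
    },
    # 6×6 DX-tile lattices: 55 brick-wall connections (110 edge nicks);
    # DX-I adds one internal nick per tile (146 total).
    "DX-I": {
        "name": "DX-I",
        "motif": {
            "type": "DX",
            "root_length": 21,
            "stem_length": 10,
            "internal_nicks": 1,
            "root_role": "rigidity",
            "stem_role": "sticky",
        },
        "rows": 6,
        "cols": 6,
        "connectivity": "dx_rows",
        "boundary": {"policy": "blunt"},
        "mask": "all",
    },
    "DX-II": {
        "name": "DX-II",
        "motif": {
            "type": "DX",
            "root_length": 11,
            "stem_length": 11,
            "internal_nicks": 0,
            "root_role": "rigidity",
            "stem_role": "sticky",
        },
        "rows": 6,
        "cols": 6,
        "connectivity": "dx_rows",
        "boundary": {"policy": "blunt"},
        "mask": "all",
    },
    # Gain-of-function sheet-to-tube design: J4-I with complementary 3-nt
    # overhangs wrapping east↔west (one boundary edge per row).
    "fig4d_tube": _j4(
        "fig4d_tube",
        root=11,
        stem=10,
        boundary={
            "policy": "overhang",
            "sides": ["E", "W"],
            "overhang_length": 3,
            "complementary": True,
        },
    ),
    # Tube controls: non-complementary overhangs (no wrap duplexes form)
    # and the 10-bp sticky-end positive control (permanent by length).
    "fig4d_noncomp": _j4(
        "fig4d_noncomp",
        root=11,
        stem=10,
        boundary={
            "policy": "overhang",
            "sides": ["E", "W"],
            "overhang_length": 3,
            "complementary": False,
        },
    ),
    "fig4d_sticky10": _j4(
        "fig4d_sticky10",
        root=11,
        stem=10,
        boundary={
            "policy": "overhang",
            "sides": ["E", "W"],
            "overhang_length": 10,
            "complementary": True,
        },
    ),
}


def _block(r0: int, r1: int, c0: int, c1: int) -> list[list[int]]:
    return [[r, c] for r in range(r0, r1) for c in range(c0, c1)]


def _edges_incident(motifs: list[list[int]], rows: int = 6, cols: int = 6) -> list[str]:
    """All square-grid edge ids touching any motif of the set."""
    mset = {tuple(m) for m in motifs}
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols and ((r, c) in mset or (r, c + 1) in mset):
                edges.append(f"e_h_r{r}c{c}")
            if r + 1 < rows and ((r, c) in mset or (r + 1, c) in mset):
                edges.append(f"e_v_r{r}c{c}")
    return edges


def _carve_mask(name: str, carved: list[list[int]]) -> dict:
    target = [[r, c] for r in range(6) for c in range(6) if [r, c] not in carved]
    return {
        "name": name,
        "base": "J4-I",
        "mode": "edge_exclude",
        "edges": sorted(_edges_incident(carved)),
        "carved_motifs": sorted(map(tuple, carved)),
        "target_motifs": target,
    }


# Loss-of-function carving masks.  Every edge incident to a carved motif is
# unligatable, so the carved strands dissociate completely on heating:
#   fig4a: 2×3 corner block   → 12 edges unligatable → 96 ligatable nicks
#   fig4b: two corner L-trominoes → 12 edges         → 96 ligatable nicks
#   fig4c: one corner L-tromino   →  6 edges         → 108 ligatable nicks
BUILTIN_MASKS: dict[str, dict] = {
    "fig4a_mask": _carve_mask("fig4a_mask", _block(0, 2, 0, 3)),
    "fig4b_mask": _carve_mask(
        "fig4b_mask",
        [[0, 0], [0, 1], [1, 0], [5, 5], [5, 4], [4, 5]],
    ),
    "fig4c_mask": _carve_mask("fig4c_mask", [[0, 0], [0, 1], [1, 0]]),
}


def get_design(name: str) -> LatticeDesign:
    """Look up a built-in design by name."""
    try:
        return design_from_dict(copy.deepcopy(BUILTIN_DESIGNS[name]))
    except KeyError:
        raise ConfigurationError(
            f"unknown design {name!r}; built-ins: {sorted(BUILTIN_DESIGNS)}"
        ) from None


def build_design(name: str) -> LatticeGraph:
    """Build a built-in design by name."""
    return build_lattice(get_design(name))


def mask_nicks(lattice: LatticeGraph, mask_cfg: Mapping) -> set[str]:
    """Resolve a mask config to the set of ligatable nick ids.

    Supported modes: ``nicks`` (explicit nick ids), ``strands``
    (5'-phosphorylated strands; expands to nicks whose downstream end
    belongs to a masked strand) and ``edge_exclude`` (everything ligatable
    except the nicks of the listed edges).
    """
    mode = mask_cfg.get("mode", "nicks")
    if mode == "nicks":
        return set(mask_cfg["nicks"])
    if mode == "strands":
        from .lattice import expand_strand_mask

        return expand_strand_mask(lattice, mask_cfg["strands"])
    if mode == "edge_exclude":
        excluded = set(mask_cfg["edges"])
        out = set()
        for nick_id in lattice.nicks:
            edge = nick_id.rsplit(":", 1)[0]
            if edge not in excluded:
                out.add(nick_id)
        return out
    raise ConfigurationError(f"unknown mask mode {mode!r}")


def load_mask(source) -> dict:
    """Load a mask config from a JSON file path or a built-in mask name."""
    import json
    from pathlib import Path

    p = Path(str(source))
    if p.suffix == ".json" or p.exists():
        return json.loads(p.read_text())
    try:
        return copy.deepcopy(BUILTIN_MASKS[str(source)])
    except KeyError:
        raise ConfigurationError(
            f"unknown mask {source!r}; built-ins: {sorted(BUILTIN_MASKS)}"
        ) from None
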