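"""Quadtree local mesh refinement driven by vorticity / velocity-gradient
indicators.

A cell of size ``h`` is marked for refinement when ``|omega| h > eps_vort``
or ``|grad u| h > eps_gradu`` and for coarsening when the indicators fall
below one quarter of those tolerances.  The printed coarsening rule joins
the two indicators with "or", which would coarsen cells with a large
velocity gradient but small vorticity; the default here is the conservative
"and" reading (both indicators quiescent), switchable via
``AmrCriteria.coarsen_logic``.

Leaves are keyed ``(level, i, j)``; level-0 leaves tile the base grid, and
the children of ``(l, i, j)`` are ``(l+1, 2i+a, 2j+b)``.  A 2:1 balance
(adjacent leaves differ by at most one level — quadtree smoothing) is
restored after every edit by forced refinement.  Scalar fields ride along as
per-leaf dictionaries; refinement and coarsening transfers are mean
preserving, so the field integral over the domain is conserved to round-off.

The quadtree is a diagnostic/refinement-planning structure: the
Navier--Stokes fields of the valve runs live on the uniform base grid, and
the refinement maps plus the serial load report (the stand-in for dynamic
repartitioning) are emitted alongside each snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

Key = tuple[int, int, int]

REFINE, KEEP, COARSEN = "refine", "keep", "coarsen"


@dataclass
class AmrCriteria:
    """Refinement tolerances (velocity scale, m/s) and coarsening factor."""

    eps_vort: float
    eps_gradu: float
    coarsen_factor: float = 0.25
    coarsen_logic: str = "and"

    def __post_init__(self) -> None:
        if not (self.eps_vort > 0 and self.eps_gradu > 0):
            raise ValueError("refinement tolerances must be positive")
        if self.coarsen_logic not in ("and", "or"):
            raise ValueError("coarsen_logic must be 'and' or 'or'")


@dataclass
class AmrGrid:
    """Quadtree over an nx-by-ny base grid with spacing h0 (cm)."""

    nx: int
    ny: int
    h0: float
    max_level: int = 2
    x0: float = 0.0
    y0: float = 0.0
    leaves: set[Key] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.leaves:
            self.leaves = {(0, i, j) for i in range(self.nx) for j in range(self.ny)}

    # -- geometry ----------------------------------------------------------
    def h(self, level: int) -> float:
        return self.h0 / 2**level

    def centre(self, key: Key) -> tuple[float, float]:
        l, i, j = key
        h = self.h(l)
        return (self.x0 + (i + 0.5) * h, self.y0 + (j + 0.5) * h)

    def leaf_list(self) -> list[Key]:
        return sorted(self.leaves)

    def n_leaves(self) -> int:
        return len(self.leaves)

    def copy(self) -> "AmrGrid":
        return AmrGrid(self.nx, self.ny, self.h0, self.max_level,
                       self.x0, self.y0, set(self.leaves))

    # -- topology ----------------------------------------------------------
    @staticmethod
    def children(key: Key) -> list[Key]:
        l, i, j = key
        return [(l + 1, 2 * i + a, 2 * j + b) for a in (0, 1) for b in (0, 1)]

    @staticmethod
    def parent(key: Key) -> Key:
        l, i, j = key
        return (l - 1, i // 2, j // 2)

    def _in_domain(self, l: int, i: int, j: int) -> bool:
        return 0 <= i < self.nx * 2**l and 0 <= j < self.ny * 2**l

    def _max_depth_in(self, l: int, i: int, j: int, axis: int, side: int) -> int:
        """Deepest leaf level inside cell (l,i,j) along the face shared with
        its (axis, side) neighbour; -1 if the region is covered by an
        ancestor leaf."""
        if l > self.max_level:
            return -1
        if (l, i, j) in self.leaves:
            return l
        # ancestor?
        ll, ii, jj = l, i, j
        while ll > 0:
            ll, ii, jj = ll - 1, ii // 2, jj // 2
            if (ll, ii, jj) in self.leaves:
                return ll
        # descend into the two children adjacent to the shared face
        best = -1
        for c in self.children((l, i, j)):
            cl, ci, cj = c
            if axis == 0 and (ci % 2 == (0 if side > 0 else 1)):
                continue  # keep children on the 'side' face only
            if axis == 1 and (cj % 2 == (0 if side > 0 else 1)):
                continue
            best = max(best, self._max_depth_in(cl, ci, cj, axis, side))
        return best

    def neighbour_max_level(self, key: Key, axis: int, side: int) -> int:
        """Finest leaf level touching the given face of ``key``; -1 at the
        domain boundary."""
        l, i, j = key
        ni = i + (side if axis == 0 else 0)
        nj = j + (side if axis == 1 else 0)
        if not self._in_domain(l, ni, nj):
            return -1
        return self._max_depth_in(l, ni, nj, axis, -side)

    def check_balance(self) -> bool:
        for key in self.leaves:
            for axis in (0, 1):
                for side in (-1, 1):
                    if self.neighbour_max_level(key, axis, side) > key[0] + 1:
                        return False
        return True

    def covers_domain(self) -> bool:
        """Leaf areas sum to the domain area and no two leaves overlap."""
        L = max((k[0] for k in self.leaves), default=0)
        seen = np.zeros((self.nx * 2**L, self.ny * 2**L), dtype=np.uint8)
        for l, i, j in self.leaves:
            f = 2 ** (L - l)
            seen[i * f:(i + 1) * f, j * f:(j + 1) * f] += 1
        return bool(np.all(seen == 1))


def evaluate_indicators(grid: AmrGrid, velocity_fn):
    """Per-leaf |omega| and Frobenius |grad u| from a velocity callable.

    ``velocity_fn(pts) -> (N,2)`` in m/s with pts in cm; derivatives by
    centred differences at the leaf scale.
    """
    keys = grid.leaf_list()
    cx = np.array([grid.centre(k) for k in keys])
    out_w = np.empty(len(keys))
    out_g = np.empty(len(keys))
    for idx, k in enumerate(keys):
        h = grid.h(k[0])
        x, y = cx[idx]
        pts = np.array([[x + h / 2, y], [x - h / 2, y],
                        [x, y + h / 2], [x, y - h / 2]])
        uv = np.asarray(velocity_fn(pts), float)
        hm = h * 1e-2
        dudx = (uv[0, 0] - uv[1, 0]) / hm
        dvdx = (uv[0, 1] - uv[1, 1]) / hm
        dudy = (uv[2, 0] - uv[3, 0]) / hm
        dvdy = (uv[2, 1] - uv[3, 1]) / hm
        out_w[idx] = abs(dvdx - dudy)
        out_g[idx] = np.sqrt(dudx**2 + dudy**2 + dvdx**2 + dvdy**2)
    return dict(zip(keys, out_w)), dict(zip(keys, out_g))


def flag_cells(
    vort_mag: dict[Key, float],
    gradu_mag: dict[Key, float],
    grid: AmrGrid,
    criteria: AmrCriteria,
) -> dict[Key, str]:
    """Mark each leaf refine/keep/coarsen from the printed inequalities.

    Refinement: ``|omega| h > eps_vort`` or ``|grad u| h > eps_gradu``.
    Coarsening: both (default) indicators below ``coarsen_factor * eps``.
    Refinement wins when both trigger; leaves already at max_level keep.
    A pure function of its inputs.
    """
    actions: dict[Key, str] = {}
    cf = criteria.coarsen_factor
    for key in grid.leaf_list():
        h = grid.h(key[0]) * 1e-2  # indicators are SI velocity scales
        w = vort_mag[key] * h
        gu = gradu_mag[key] * h
        refine = (w > criteria.eps_vort) or (gu > criteria.eps_gradu)
        low_w = w < cf * criteria.eps_vort
        low_g = gu < cf * criteria.eps_gradu
        coarsen = (low_w and low_g) if criteria.coarsen_logic == "and" \
            else (low_w or low_g)
        if refine:
            if key[0] >= grid.max_level:
                log.warning("max_level reached at leaf %s; keeping", key)
                actions[key] = KEEP
            else:
                actions[key] = REFINE
        elif coarsen:
            actions[key] = COARSEN
        else:
            actions[key] = KEEP
    return actions


def apply_actions(
    grid: AmrGrid,
    actions: dict[Key, str],
    fields: dict[str, dict[Key, float]] | None = None,
):
    """Apply refine/coarsen actions, restore 2:1 balance, transfer fields.

    Returns ``(new_grid, new_fields)``.  Coarsening merges four siblings
    only when *all* are flagged coarsen (and the merge does not violate the
    balance, which is re-enforced afterwards by forced refinement anyway).
    Refinement copies the parent value to the children; coarsening averages
    the four children — both mean preserving, so any field's integral is
    conserved to round-off.
    """
    g = grid.copy()
    fields = {name: dict(vals) for name, vals in (fields or {}).items()}

    def refine_leaf(key):
        g.leaves.remove(key)
        kids = g.children(key)
        g.leaves.update(kids)
        for vals in fields.values():
            v = vals.pop(key)
            for c in kids:
                vals[c] = v

    # refinement pass
    for key, act in list(actions.items()):
        if act == REFINE and key in g.leaves and key[0] < g.max_level:
            refine_leaf(key)

    # coarsening pass: all four siblings flagged
    seen = set()
    for key, act in actions.items():
        if act != COARSEN or key[0] == 0 or key not in g.leaves:
            continue
        par = g.parent(key)
        if par in seen:
            continue
        seen.add(par)
        kids = g.children(par)
        if all(k in g.leaves and actions.get(k) == COARSEN for k in kids):
            for k in kids:
                g.leaves.remove(k)
            g.leaves.add(par)
            for vals in fields.values():
                vals[par] = float(np.mean([vals.pop(k) for k in kids]))

    # restore 2:1 balance by forced refinement of the coarser leaf
    changed = True
    while changed:
        changed = False
        for key in sorted(g.leaves):
            if key[0] >= g.max_level:
                continue
            for axis in (0, 1):
                for side in (-1, 1):
                    if g.neighbour_max_level(key, axis, side) > key[0] + 1:
                        refine_leaf(key)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    return g, fields


def integrate_field(grid: AmrGrid, vals: dict[Key, float]) -> float:
    """Area-weighted integral of a per-leaf field (cm^2 units)."""
    return sum(vals[k] * grid.h(k[0]) ** 2 for k in grid.leaves)


def load_report(grid: AmrGrid, blocks: tuple[int, int] = (2, 2)) -> dict:
    """Serial load estimate: leaf counts per spatial block and imbalance.

    The imbalance ratio (max over mean block load) is what a dynamic
    repartitioner would act on; partitioning itself is out of scope here.
    """
    if not grid.leaves:
        raise ValueError("empty grid")
    bx, by = blocks
    lx = grid.nx * grid.h0
    ly = grid.ny * grid.h0
    counts = np.zeros((bx, by), dtype=int)
    for key in grid.leaves:
        x, y = grid.centre(key)
        i = min(int((x - grid.x0) / lx * bx), bx - 1)
        j = min(int((y - grid.y0) / ly * by), by - 1)
        counts[i, j] += 1
    mean = counts.mean()
    return {
        "block_counts": counts,
        "imbalance_ratio": float(counts.max() / mean) if mean > 0 else np.inf,
        "n_leaves": grid.n_leaves(),
        "max_level": max(k[0] for k in grid.leaves),
    }
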