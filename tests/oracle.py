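"""Independent brute-force MSPA oracle.

Pure-Python reimplementation of the seven-type partition written directly
from the stated post-conditions: Chebyshev distances by exhaustive
pairwise search, connectivity by breadth-first search.  Deliberately free
of numpy/scipy so it shares nothing with the implementation under test.
"""

from __future__ import annotations

from collections import deque

INF = float("inf")


def _cells(mask):
    h, w = len(mask), len(mask[0])
    return [(i, j) for i in range(h) for j in range(w)]


def _cheb(a, b):
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _border_distance(p, h, w):
    i, j = p
    return min(i + 1, h - i, j + 1, w - j)


def _min_dist(p, targets):
    return min((_cheb(p, t) for t in targets), default=INF)


def _components(cells, connectivity):
    """BFS components of a cell set; returned in row-major first-cell order."""
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    remaining = set(cells)
    comps = []
    for seed in sorted(cells):
        if seed not in remaining:
            continue
        comp = {seed}
        remaining.discard(seed)
        queue = deque([seed])
        while queue:
            ci, cj = queue.popleft()
            for di, dj in nbrs:
                q = (ci + di, cj + dj)
                if q in remaining:
                    remaining.discard(q)
                    comp.add(q)
                    queue.append(q)
        comps.append(comp)
    return comps


def segment_oracle(mask, edge_width=1, border_condition="background"):
    """Return {type_name: set of cells} for a boolean 2-D list/array."""
    mask = [[bool(v) for v in row] for row in mask]
    h, w = len(mask), len(mask[0])
    fg = {(i, j) for i, j in _cells(mask) if mask[i][j]}
    bg = {(i, j) for i, j in _cells(mask) if not mask[i][j]}
    out = {k: set() for k in ("core", "islet", "perforation", "edge", "loop", "bridge", "branch")}
    if not fg:
        return out
    border_is_bg = border_condition == "background"

    def dist_to_bg(p):
        d = _min_dist(p, bg)
        if border_is_bg:
            d = min(d, _border_distance(p, h, w))
        return d

    core = {p for p in fg if dist_to_bg(p) > edge_width}
    out["core"] = core

    # holes: 4-connected background components with no cell on the lattice edge
    holes = set()
    for comp in _components(bg, 4):
        if not any(i in (0, h - 1) or j in (0, w - 1) for i, j in comp):
            holes |= comp
    outer = bg - holes

    def dist_to_outer(p):
        d = _min_dist(p, outer)
        if border_is_bg:
            d = min(d, _border_distance(p, h, w))
        return d

    boundary = set()
    if core:
        for p in fg - core:
            if _min_dist(p, core) <= edge_width:
                boundary.add(p)
                if _min_dist(p, holes) < dist_to_outer(p):
                    out["perforation"].add(p)
                else:
                    out["edge"].add(p)  # tie goes to edge

    core_comps = _components(core, 8)
    core_id = {}
    for k, comp in enumerate(core_comps, start=1):
        for p in comp:
            core_id[p] = k

    residual = fg - core - boundary
    for comp in _components(residual, 8):
        contact_labels = {}
        for p in comp:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    q = (p[0] + di, p[1] + dj)
                    if q in comp or q not in fg:
                        continue
                    if q in core:
                        contact_labels.setdefault(q, set()).add(core_id[q])
                    elif q in boundary:
                        near = {core_id[c] for c in core if _cheb(q, c) <= edge_width}
                        if near:
                            contact_labels.setdefault(q, set()).update(near)
        touched = set().union(*contact_labels.values()) if contact_labels else set()
        if not touched:
            out["islet"] |= comp
        elif len(touched) >= 2:
            out["bridge"] |= comp
        else:
            regions = _components(set(contact_labels), 8)
            out["loop" if len(regions) >= 2 else "branch"] |= comp
    return out
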