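"""Independent brute-force reference implementations used as test oracles."""
from __future__ import annotations

import numpy as np


def brute_force_two_radius_dbscan(coords, r, n_min, r_ref,
                                  strict_core=False):
    """O(n^2) reference for the two-radius DBSCAN contract.

    Core points have >= n_min neighbors within r (self excluded; > when
    strict); cores at distance < r_ref connect; border points attach to
    the cluster of the nearest core within r_ref (ties to the lower
    cluster index).  Clusters are numbered by their smallest member row.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    counts = (dist <= r).sum(axis=1) - 1
    core = counts > n_min if strict_core else counts >= n_min
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels

    # flood fill over cores connected by distance < r_ref
    comp = {}
    next_comp = 0
    for start in core_idx:
        if start in comp:
            continue
        stack = [start]
        comp[start] = next_comp
        while stack:
            i = stack.pop()
            for j in core_idx:
                if j not in comp and dist[i, j] < r_ref:
                    comp[j] = next_comp
                    stack.append(j)
        next_comp += 1
    # canonical numbering by smallest member index
    firsts = {}
    for i, c in comp.items():
        firsts[c] = min(firsts.get(c, i), i)
    order = sorted(firsts, key=lambda c: firsts[c])
    remap = {c: k for k, c in enumerate(order)}
    for i, c in comp.items():
        labels[i] = remap[c]

    for i in range(n):
        if core[i]:
            continue
        d_core = dist[i, core_idx]
        ok = d_core < r_ref
        if not ok.any():
            continue
        dmin = d_core[ok].min()
        tied = core_idx[ok & (d_core <= dmin + 1e-9)]
        labels[i] = min(labels[j] for j in tied)
    return labels
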