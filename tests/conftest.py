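"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by enumeration or
exhaustive search, independent of the library code paths they check.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
import pandas as pd
import pytest


# ----------------------------------------------------------------------
# prominence oracle (widest-path search, independent of the flood filler)
# ----------------------------------------------------------------------

def prominence_maxima_oracle(image, tolerance: float) -> np.ndarray:
    """Brute-force ImageJ-style maxima via widest-path saddle search.

    For each plateau P (8-connected equal-value region) the key saddle is
    the best (highest-bottleneck) path to any dominating plateau (strictly
    higher value, or equal value with an earlier first pixel in row-major
    order).  P is reported iff it has no dominating plateau (global
    maximum of a non-constant image) or value - saddle > tolerance; the
    reported point is P's first pixel.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    if img.min() == img.max():
        return out
    pid = -np.ones((h, w), dtype=int)
    info = []
    for y in range(h):
        for x in range(w):
            if pid[y, x] >= 0:
                continue
            v = img[y, x]
            stack, members = [(y, x)], []
            pid[y, x] = len(info)
            while stack:
                cy, cx = stack.pop()
                members.append((cy, cx))
                for dy, dx in itertools.product((-1, 0, 1), repeat=2):
                    if dy == dx == 0:
                        continue
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and pid[ny, nx] < 0 \
                            and img[ny, nx] == v:
                        pid[ny, nx] = pid[cy, cx]
                        stack.append((ny, nx))
            info.append((float(v), members[0][0] * w + members[0][1], members))

    for i, (v, first, members) in enumerate(info):
        dom = {j for j, (vq, fq, _) in enumerate(info)
               if vq > v or (vq == v and fq < first)}
        if not dom:
            out[first // w, first % w] = 255
            continue
        # widest path (maximize the minimum value en route) to any dominator
        best_at = {}
        hq = []
        for yy, xx in members:
            best_at[(yy, xx)] = v
            heapq.heappush(hq, (-v, yy, xx))
        saddle = None
        while hq:
            nb, cy, cx = heapq.heappop(hq)
            nb = -nb
            if nb < best_at.get((cy, cx), -np.inf):
                continue
            if pid[cy, cx] in dom:
                saddle = nb
                break
            for dy, dx in itertools.product((-1, 0, 1), repeat=2):
                if dy == dx == 0:
                    continue
                ny, nx = cy + dy, cx + dx
                if 0 <= ny < h and 0 <= nx < w:
                    b2 = min(nb, img[ny, nx])
                    if b2 > best_at.get((ny, nx), -np.inf):
                        best_at[(ny, nx)] = b2
                        heapq.heappush(hq, (-b2, ny, nx))
        if saddle is not None and v - saddle > tolerance:
            out[first // w, first % w] = 255
    return out


# ----------------------------------------------------------------------
# CBS arc oracle (exhaustive double loop, no vectorization)
# ----------------------------------------------------------------------

def best_arc_oracle(x, min_width: int = 5):
    """Exhaustive arg-max of the CBS arc statistic; ties -> smallest (i, j)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        return None
    best = None
    for i in range(n + 1):
        if i != 0 and i < min_width:
            continue
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            if j != n and n - j < min_width:
                continue
            mean_in = x[i:j].mean()
            mean_out = (x.sum() - x[i:j].sum()) / (n - k)
            stat = abs(mean_in - mean_out) / (sd * np.sqrt(1 / k + 1 / (n - k)))
            if best is None or stat > best[2] + 1e-12:
                best = (i, j, stat)
    return best


# ----------------------------------------------------------------------
# hotspot oracle (pairwise overlap graph, connected components)
# ----------------------------------------------------------------------

def hotspot_oracle(calls: pd.DataFrame, min_cnv_count: int = 6):
    """Brute-force hotspot filter: build the overlap graph of calls per
    chromosome, take connected components, and drop every call that lies
    entirely inside a component footprint overlapped by >= min_cnv_count
    calls.  Returns the surviving row indexer (boolean array)."""
    n = len(calls)
    keep = np.ones(n, dtype=bool)
    idx = calls.reset_index(drop=True)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = idx.iloc[a], idx.iloc[b]
            if ra["chrom"] == rb["chrom"] and ra["start"] < rb["end"] \
                    and rb["start"] < ra["end"]:
                parent[find(a)] = find(b)
    comps = {}
    for a in range(n):
        comps.setdefault(find(a), []).append(a)
    for members in comps.values():
        if len(members) < min_cnv_count:
            continue
        lo = min(idx.iloc[m]["start"] for m in members)
        hi = max(idx.iloc[m]["end"] for m in members)
        chrom = idx.iloc[members[0]]["chrom"]
        for a in range(n):
            r = idx.iloc[a]
            if r["chrom"] == chrom and r["start"] >= lo and r["end"] <= hi:
                keep[a] = False
    return keep


# ----------------------------------------------------------------------
# Fisher oracle (hypergeometric enumeration)
# ----------------------------------------------------------------------

def fisher_oracle(table) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins
    and summing the probabilities <= that of the observed table."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / denom

    p_obs = prob(a)
    return sum(p for aa in range(0, min(r1, c1) + 1)
               if (p := prob(aa)) <= p_obs * (1 + 1e-9))


@pytest.fixture(scope="session")
def oracles():
    return {
        "prominence": prominence_maxima_oracle,
        "best_arc": best_arc_oracle,
        "hotspot": hotspot_oracle,
        "fisher": fisher_oracle,
    }


@pytest.fixture(scope="session")
def small_sc_adata():
    """A modest synthetic expression dataset shared across tests."""
    from neurogi import synthetic

    cfg = synthetic.SimConfig(seed=11, n_cells_per_class=60)
    return synthetic.generate_sc_dataset(cfg)
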