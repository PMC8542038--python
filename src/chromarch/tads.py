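"""TopDom-style TAD calling and two-condition boundary comparison.

The per-bin statistic (binSignal) is the mean contact frequency between the
``w`` bins upstream and the ``w`` bins downstream of each inter-bin position:
inside a TAD the cross-window is enriched, at a boundary it is depleted, so
TAD boundaries appear as local minima of the (smoothed) binSignal. Boundary
strength is the insulation depth: the mean binSignal of the flanking domain
interiors minus the binSignal at the boundary. Two-condition comparison
matches boundaries by position (greedy nearest within a slack) and classifies
each matched pair as stronger / unchanged / weaker by relative strength
change; unmatched boundaries are reported as gained or lost, the substrate of
TAD merging.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError, StateError
from .matrix import KR, ContactMatrix


@dataclass
class TADSet:
    """TAD call for one chromosome: signals, boundaries, domains, strengths."""

    chrom: str
    bin_size: int
    w: int
    binsignal: np.ndarray
    smoothed: np.ndarray
    boundaries: np.ndarray             # interior boundary bin indices, increasing
    domains: list[tuple[int, int]]     # half-open [start, end) bins tiling the extent
    strength: np.ndarray               # per-boundary insulation depth

    def write_domains_bed(self, path, append: bool = False) -> None:
        with open(path, "a" if append else "w") as fh:
            for k, (s, e) in enumerate(self.domains):
                fh.write(f"{self.chrom}\t{s * self.bin_size}\t{e * self.bin_size}"
                         f"\t{self.chrom}_d{k}\n")

    def write_boundaries_bed(self, path, append: bool = False) -> None:
        with open(path, "a" if append else "w") as fh:
            for b, s in zip(self.boundaries, self.strength):
                fh.write(f"{self.chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}"
                         f"\tboundary\t{s:.6g}\n")


def bin_signal(m: ContactMatrix, w: int) -> np.ndarray:
    """binSignal: mean of m[u, v] over u in (i-w, i], v in (i, i+w].

    Windows are clipped at chromosome ends; masked bins are excluded from the
    mean; positions with no valid cross-window pair are NaN.
    """
    if m.stage != KR:
        raise StateError("bin_signal expects a KR-balanced matrix")
    n = m.n_bins
    if w < 1:
        raise ParameterError("window w must be >= 1")
    if w >= n / 2:
        raise ParameterError(f"window w={w} too large for {n} bins (need w < n/2)")
    keep = m.unmasked
    out = np.full(n, np.nan)
    for i in range(n):
        us = np.arange(max(0, i - w + 1), i + 1)
        vs = np.arange(i + 1, min(n, i + w + 1))
        us = us[keep[us]]
        vs = vs[keep[vs]]
        if us.size == 0 or vs.size == 0:
            continue
        out[i] = m.counts[np.ix_(us, vs)].mean()
    return out


def smooth_signal(binsignal: np.ndarray, span: int) -> np.ndarray:
    """Centered running mean of odd width ``span``, shrunk at the ends.

    NaN positions stay NaN; NaN neighbours are simply dropped from a
    window's mean.
    """
    if span < 1 or span % 2 == 0:
        raise ParameterError(f"span must be odd and >= 1, got {span}")
    x = np.asarray(binsignal, dtype=float)
    if span == 1:
        return x.copy()
    h = span // 2
    n = x.size
    out = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(x[i]):
            continue
        win = x[max(0, i - h): min(n, i + h + 1)]
        out[i] = np.nanmean(win)
    return out


def call_boundaries(binsignal: np.ndarray, smoothed: np.ndarray, w: int,
                    chrom: str, bin_size: int,
                    min_depth: float = 0.1) -> TADSet:
    """Boundaries at prominent local minima of the smoothed binSignal.

    A bin is a boundary iff it is the leftmost bin of a minimal plateau over
    a +/-w neighbourhood and its prominence — min(left max, right max) minus
    the minimum value — is at least ``min_depth`` times that local flanking
    maximum (the local signal scale; a relative criterion, so detection does
    not depend on the compartment context a boundary sits in). Domains are
    the intervals between consecutive boundaries within the unmasked extent.
    """
    s = np.asarray(smoothed, dtype=float)
    n = s.size
    finite = np.isfinite(s)
    if not finite.any():
        return TADSet(chrom, bin_size, w, np.asarray(binsignal, float), s,
                      np.empty(0, int), [], np.empty(0))
    lo, hi = int(np.nonzero(finite)[0][0]), int(np.nonzero(finite)[0][-1])
    bounds: list[int] = []
    for i in range(lo + 1, hi):
        if not finite[i]:
            continue
        left = s[max(lo, i - w): i]
        right = s[i + 1: min(hi, i + w) + 1]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if left.size == 0 or right.size == 0:
            continue
        if s[i] > left.min() or s[i] > right.min():
            continue
        if s[i] == left[-1]:
            continue  # plateau: keep only the leftmost bin (previous bin equal)
        local_scale = min(left.max(), right.max())
        prominence = local_scale - s[i]
        if prominence < min_depth * abs(local_scale):
            continue
        bounds.append(i)
    boundaries = np.asarray(bounds, dtype=int)
    edges = [lo] + [b for b in bounds] + [hi + 1]
    domains = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)
               if edges[k + 1] > edges[k]]
    ts = TADSet(chrom, bin_size, w, np.asarray(binsignal, float), s,
                boundaries, domains, np.empty(0))
    ts.strength = boundary_strength(ts)
    return ts


def call_tads(m: ContactMatrix, w: int = 5, span: int = 3,
              min_depth: float = 0.1) -> TADSet:
    """Full TAD pipeline on one KR-balanced chromosome matrix."""
    bs = bin_signal(m, w)
    sm = smooth_signal(bs, span)
    return call_boundaries(bs, sm, w, m.chrom, m.bin_size, min_depth=min_depth)


def boundary_strength(tads: TADSet) -> np.ndarray:
    """Insulation depth per boundary: mean flanking-domain interior binSignal
    minus the binSignal at the boundary bin (larger = stronger insulation)."""
    bs = tads.binsignal
    bset = set(int(x) for x in tads.boundaries)
    out = np.zeros(tads.boundaries.size)
    for k, b in enumerate(tads.boundaries):
        interiors = []
        for s, e in tads.domains:
            if e == b or s == b:  # flanking domains share an edge with b
                idx = np.array([i for i in range(s, e) if i not in bset])
                if idx.size:
                    interiors.append(bs[idx])
        flank = np.concatenate(interiors) if interiors else np.empty(0)
        flank = flank[np.isfinite(flank)]
        base = float(np.mean(flank)) if flank.size else np.nan
        out[k] = base - bs[b] if np.isfinite(bs[b]) and np.isfinite(base) else np.nan
    return out


def compare_boundaries(t1: TADSet, t2: TADSet, match_slack: int = 2,
                       change_threshold: float = 0.1) -> pd.DataFrame:
    """Match boundaries between conditions and classify strength changes.

    Greedy nearest-position matching within ``match_slack`` bins; a matched
    pair is "weaker" if the relative strength change (s2-s1)/|s1| is below
    -``change_threshold``, "stronger" above +``change_threshold``, else
    "unchanged". Unmatched boundaries are "lost" (condition 1 only) or
    "gained" (condition 2 only). Returns a tidy frame with columns
    position1, position2, s1, s2, class.
    """
    if t1.chrom != t2.chrom or t1.bin_size != t2.bin_size:
        raise AlignmentError("TAD sets are on different chromosome/bin grids")
    if match_slack < 0:
        raise ParameterError("match_slack must be >= 0")
    b1, b2 = t1.boundaries, t2.boundaries
    pairs = []
    for i, p in enumerate(b1):
        for j, q in enumerate(b2):
            d = abs(int(p) - int(q))
            if d <= match_slack:
                pairs.append((d, i, j))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    rows = []
    for d, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        s1, s2 = float(t1.strength[i]), float(t2.strength[j])
        denom = max(abs(s1), 1e-300)
        rel = (s2 - s1) / denom
        if rel < -change_threshold:
            klass = "weaker"
        elif rel > change_threshold:
            klass = "stronger"
        else:
            klass = "unchanged"
        rows.append((int(b1[i]), int(b2[j]), s1, s2, klass))
    for i, p in enumerate(b1):
        if i not in used1:
            rows.append((int(p), -1, float(t1.strength[i]), np.nan, "lost"))
    for j, q in enumerate(b2):
        if j not in used2:
            rows.append((-1, int(q), np.nan, float(t2.strength[j]), "gained"))
    df = pd.DataFrame(rows, columns=["position1", "position2", "s1", "s2", "class"])
    return df.sort_values(["position1", "position2"]).reset_index(drop=True)


def boundary_class_counts(comparison: pd.DataFrame) -> dict[str, int]:
    return {k: int((comparison["class"] == k).sum())
            for k in ("stronger", "unchanged", "weaker", "lost", "gained")}


def tad_stats(tads: TADSet) -> tuple[int, float]:
    """Domain count and mean domain size in megabases."""
    n = len(tads.domains)
    if n == 0:
        return 0, float("nan")
    mean_bins = float(np.mean([e - s for s, e in tads.domains]))
    return n, mean_bins * tads.bin_size / 1e6
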