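"""Donut-enrichment chromatin loop calling and two-condition comparison.

A loop is a focal pixel whose balanced contact count exceeds its local
background: the mean over a square annulus ("donut") around the pixel,
excluding an inner square, the pixel's own row/column stripes, and masked
bins. Each eligible pixel gets a Poisson upper-tail p-value of its (rounded)
observed count given the donut expectation; Benjamini-Hochberg control is
applied per chromosome. Two enrichment guards follow: an observed/expected
floor over the full donut, and a floor over the lower-left quadrant of the
annulus — the region that stays inside a contact domain when the pixel sits
at a domain corner, whose enrichment a full donut averages away. Without the
quadrant guard, corner pixels of strong domains are called at any sequencing
depth. Retained pixels are merged into 8-connected clusters keeping each
cluster's most significant pixel.

This is a deliberately transparent, simplified caller in the spirit of
HiCCUPS; it does not claim pixel-level concordance with it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import AlignmentError, DomainError, ParameterError, StateError
from .matrix import KR, ContactMatrix


@dataclass
class LoopSet:
    """Called loops for one chromosome.

    ``pixels`` columns: i, j (bin indices, i < j), observed, expected, p, q.
    """

    chrom: str
    bin_size: int
    pixels: pd.DataFrame
    fdr: float

    def __len__(self) -> int:
        return len(self.pixels)

    def write_bedpe(self, path, append: bool = False) -> None:
        with open(path, "a" if append else "w") as fh:
            for r in self.pixels.itertuples():
                fh.write(f"{self.chrom}\t{int(r.i) * self.bin_size}\t{(int(r.i) + 1) * self.bin_size}"
                         f"\t{self.chrom}\t{int(r.j) * self.bin_size}\t{(int(r.j) + 1) * self.bin_size}"
                         f"\t{r.observed:.6g}\t{r.expected:.6g}\t{r.q:.3e}\n")


def _donut_kernel(r_inner: int, r_outer: int) -> np.ndarray:
    """Annulus kernel: Chebyshev radius in (r_inner, r_outer], minus the
    centre row and column stripes."""
    size = 2 * r_outer + 1
    du = np.abs(np.arange(size) - r_outer)
    cheb = np.maximum(du[:, None], du[None, :])
    k = (cheb > r_inner) & (cheb <= r_outer)
    k[r_outer, :] = False
    k[:, r_outer] = False
    return k.astype(float)


def _lower_left_kernel(r_inner: int, r_outer: int) -> np.ndarray:
    """Lower-left quadrant of the annulus (toward the diagonal): the region
    that stays inside a contact domain when the pixel sits at a domain
    corner, so comparing against it suppresses corner artifacts."""
    k = _donut_kernel(r_inner, r_outer)
    size = 2 * r_outer + 1
    du = np.arange(size) - r_outer
    quad = (du[:, None] > 0) & (du[None, :] < 0)
    return (k.astype(bool) & quad).astype(float)


def donut_expected(m: ContactMatrix, i: int, j: int,
                   r_inner: int = 2, r_outer: int = 5) -> float:
    """Local background for pixel (i, j): mean over the donut annulus.

    The annulus is the Chebyshev shell ``r_inner < max(|u-i|, |v-j|) <=
    r_outer`` excluding the pixel's row/column stripes and masked bins. The
    pixel must sit at least ``r_outer`` bins from every matrix edge and from
    the diagonal.
    """
    if m.stage != KR:
        raise StateError("donut_expected expects a KR-balanced matrix")
    if not r_outer > r_inner >= 1:
        raise ParameterError("require r_outer > r_inner >= 1")
    n = m.n_bins
    if min(i, j) < r_outer or max(i, j) >= n - r_outer:
        raise DomainError(f"pixel ({i}, {j}) within {r_outer} bins of the matrix edge")
    if abs(i - j) <= r_outer:
        raise DomainError(f"pixel ({i}, {j}) within {r_outer} bins of the diagonal")
    keep = m.unmasked
    vals, wsum = 0.0, 0
    for u in range(i - r_outer, i + r_outer + 1):
        for v in range(j - r_outer, j + r_outer + 1):
            cheb = max(abs(u - i), abs(v - j))
            if cheb <= r_inner or cheb > r_outer or u == i or v == j:
                continue
            if not (keep[u] and keep[v]):
                continue
            vals += m.counts[u, v]
            wsum += 1
    if wsum == 0:
        raise DomainError(f"pixel ({i}, {j}): donut entirely masked")
    return vals / wsum


def call_loops(m: ContactMatrix, fdr: float = 0.1, min_sep: int = 2,
               r_inner: int = 2, r_outer: int = 5,
               oe_threshold: float = 1.75,
               ll_threshold: float = 1.4,
               max_sep: int | None = 100) -> LoopSet:
    """Call loops on one KR-balanced chromosome matrix.

    Eligible pixels lie in the upper triangle at least ``r_outer + 1`` bins
    above the diagonal (and at least ``min_sep``), at most ``max_sep`` bins
    from it (loops beyond ~2.5 Mb are rare, and restricting the band keeps
    the Poisson approximation on balanced counts well calibrated at shallow
    depth), at least ``r_outer`` bins from every edge, with both bins
    unmasked. Retained pixels satisfy BH
    q <= ``fdr``, observed > ``oe_threshold`` x the donut expectation, and
    observed > ``ll_threshold`` x the lower-left-quadrant expectation (the
    domain-corner guard); they are then merged into 8-connected clusters,
    keeping each cluster's most significant pixel.
    """
    if m.stage != KR:
        raise StateError("call_loops expects a KR-balanced matrix")
    if not 0 < fdr < 1:
        raise ParameterError("fdr must be in (0, 1)")
    n = m.n_bins
    keep = m.unmasked
    cols = ["i", "j", "observed", "expected", "p", "q"]
    empty = LoopSet(m.chrom, m.bin_size, pd.DataFrame(columns=cols), fdr)
    lo_sep = max(min_sep, r_outer + 1)
    if n < 2 * r_outer + lo_sep + 2:
        return empty
    kernel = _donut_kernel(r_inner, r_outer)
    ll_kernel = _lower_left_kernel(r_inner, r_outer)
    valid2d = np.outer(keep, keep).astype(float)
    sums = ndimage.correlate(m.counts * valid2d, kernel, mode="constant")
    cnts = ndimage.correlate(valid2d, kernel, mode="constant")
    ll_sums = ndimage.correlate(m.counts * valid2d, ll_kernel, mode="constant")
    ll_cnts = ndimage.correlate(valid2d, ll_kernel, mode="constant")
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    eligible = ((jj - ii >= lo_sep)
                & ((jj - ii <= max_sep) if max_sep is not None else True)
                & (ii >= r_outer) & (jj >= r_outer)
                & (ii < n - r_outer) & (jj < n - r_outer)
                & keep[:, None] & keep[None, :]
                & (cnts > 0))
    if not eligible.any():
        return empty
    ei, ej = np.nonzero(eligible)
    expected = sums[ei, ej] / cnts[ei, ej]
    observed = np.round(m.counts[ei, ej])
    pvals = stats.poisson.sf(observed - 1, expected)
    qvals = stats.false_discovery_control(pvals, method="bh")
    ll_ok = np.ones(ei.size, dtype=bool)
    has_ll = ll_cnts[ei, ej] > 0
    ll_exp = np.divide(ll_sums[ei, ej], ll_cnts[ei, ej],
                       out=np.zeros(ei.size), where=has_ll)
    ll_ok[has_ll] = observed[has_ll] > ll_threshold * ll_exp[has_ll]
    hit = (qvals <= fdr) & (observed > oe_threshold * expected) & ll_ok
    if not hit.any():
        return empty
    # cluster retained pixels (8-connected) and keep the most significant
    mask = np.zeros((n, n), dtype=bool)
    mask[ei[hit], ej[hit]] = True
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    lab_at = labels[ei[hit], ej[hit]]
    sub = pd.DataFrame({"i": ei[hit], "j": ej[hit], "observed": observed[hit],
                        "expected": expected[hit], "p": pvals[hit],
                        "q": qvals[hit], "cluster": lab_at})
    sub = sub.sort_values(["p", "observed", "i", "j"],
                          ascending=[True, False, True, True])
    best = sub.drop_duplicates("cluster", keep="first").drop(columns="cluster")
    best = best.sort_values(["i", "j"]).reset_index(drop=True)
    return LoopSet(m.chrom, m.bin_size, best[cols], fdr)


def compare_loops(l1: LoopSet, l2: LoopSet, slack: int = 1) -> dict:
    """Match loops between conditions within a Chebyshev slack.

    Returns shared / lost (condition 1 only) / gained (condition 2 only)
    pixel lists and counts.
    """
    if l1.chrom != l2.chrom or l1.bin_size != l2.bin_size:
        raise AlignmentError("loop sets are on different chromosome/bin grids")
    if slack < 0:
        raise ParameterError("slack must be >= 0")
    p1 = l1.pixels[["i", "j"]].to_numpy(int)
    p2 = l2.pixels[["i", "j"]].to_numpy(int)
    pairs = []
    for a in range(len(p1)):
        for b in range(len(p2)):
            d = max(abs(p1[a, 0] - p2[b, 0]), abs(p1[a, 1] - p2[b, 1]))
            if d <= slack:
                pairs.append((d, a, b))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    shared = []
    for d, a, b in pairs:
        if a in used1 or b in used2:
            continue
        used1.add(a)
        used2.add(b)
        shared.append((tuple(p1[a]), tuple(p2[b])))
    lost = [tuple(p1[a]) for a in range(len(p1)) if a not in used1]
    gained = [tuple(p2[b]) for b in range(len(p2)) if b not in used2]
    return {"shared": shared, "lost": lost, "gained": gained,
            "n_shared": len(shared), "n_lost": len(lost), "n_gained": len(gained),
            "n_1": len(p1), "n_2": len(p2)}


def write_comparison_json(comparison: dict, path) -> None:
    d = {k: comparison[k] for k in ("n_shared", "n_lost", "n_gained", "n_1", "n_2")}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
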