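"""A/B compartment calling, orientation by histone marks, and switch analysis.

Compartments are called per chromosome from the observed/expected matrix: the
Pearson correlation matrix of O/E rows has a checkerboard block structure
whose leading eigenvector (PC1) separates the two compartments by sign. The
eigenvector's global sign is arbitrary, so it is oriented against histone
marks: PC1 is flipped unless it correlates positively with the active marks
(H3K4me1, H3K27ac) and negatively with the repressive ones (H3K9me3,
H3K27me3), summarized in a single correlation-sum statistic. A bins are those
with oriented PC1 > 0.

The compartment degree rescales the oriented PC1 to [-1, 1] by its maximum
absolute entry; it is the continuous activity index used to place beads
radially in the 3D model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (AlignmentError, AmbiguousOrientationError,
                     DegeneracyError, StateError)
from .matrix import OE, BinTrack, ContactMatrix

SWITCH_CLASSES = ("stable_A", "stable_B", "A->B", "B->A")


@dataclass
class CompartmentProfile:
    """Per-bin compartment call for one chromosome.

    ``pc1`` is the oriented eigenvector (NaN on masked bins), ``labels`` an
    array of "A"/"B"/"NA", ``degree`` the max-abs-normalized oriented PC1 in
    [-1, 1] (NaN on masked bins).
    """

    chrom: str
    bin_size: int
    pc1: np.ndarray
    labels: np.ndarray
    degree: np.ndarray | None = None
    orientation_score: float = float("nan")

    @property
    def unmasked(self) -> np.ndarray:
        return np.isfinite(self.pc1)

    def write_tsv(self, path: str | Path, append: bool = False) -> None:
        """BED-like TSV: chrom, start, end, pc1, label, degree."""
        deg = self.degree if self.degree is not None else np.full(self.pc1.size, np.nan)
        with open(path, "a" if append else "w") as fh:
            for i in range(self.pc1.size):
                p = "NA" if not np.isfinite(self.pc1[i]) else f"{self.pc1[i]:.6g}"
                d = "NA" if not np.isfinite(deg[i]) else f"{deg[i]:.6g}"
                fh.write(f"{self.chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}"
                         f"\t{p}\t{self.labels[i]}\t{d}\n")


@dataclass
class SwitchReport:
    """Per-bin two-condition switch classification for one chromosome."""

    chrom: str
    bin_size: int
    classes: np.ndarray          # "stable_A" | "stable_B" | "A->B" | "B->A" | "masked"
    percentages: dict[str, float] = field(default_factory=dict)

    @property
    def switched_fraction(self) -> float:
        return (self.percentages["A->B"] + self.percentages["B->A"]) / 100.0

    def summary(self) -> dict[str, float]:
        return dict(self.percentages)

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None,
              append: bool = False) -> None:
        with open(tsv_path, "a" if append else "w") as fh:
            for i, k in enumerate(self.classes):
                fh.write(f"{self.chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{k}\n")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.percentages, indent=1))


def correlation_pc1(m: ContactMatrix) -> np.ndarray:
    """Leading eigenvector of the Pearson correlation matrix of an O/E matrix.

    Returned unit-norm with arbitrary sign; masked bins (and bins whose O/E
    row is constant, which have no defined correlation) are NaN. Requires at
    least 10 usable bins.
    """
    if m.stage != OE:
        raise StateError("correlation_pc1 expects an O/E-normalized matrix")
    keep = m.unmasked.copy()
    sub = m.counts[np.ix_(keep, keep)]
    # rows with zero variance have undefined correlations: mask them too
    good = sub.std(axis=1) > 0
    if good.size and not good.all():
        idx = np.nonzero(keep)[0][~good]
        keep[idx] = False
        sub = m.counts[np.ix_(keep, keep)]
    k = int(keep.sum())
    if k < 10:
        raise DegeneracyError(f"only {k} usable bins (need >= 10) for PC1")
    corr = np.corrcoef(sub)
    w, v = np.linalg.eigh(corr)
    vec = v[:, -1]
    vec = vec / np.linalg.norm(vec)
    pc1 = np.full(m.n_bins, np.nan)
    pc1[keep] = vec
    return pc1


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def orient_and_label(pc1: np.ndarray, chrom: str, bin_size: int,
                     active_tracks: list[BinTrack],
                     inactive_tracks: list[BinTrack],
                     ambiguity_threshold: float = 0.05) -> CompartmentProfile:
    """Orient PC1 by histone marks and label bins A/B.

    The orientation statistic is s = sum of Pearson correlations of PC1 with
    active-mark tracks minus the sum with repressive-mark tracks; PC1 is
    negated when s < 0. |s| below ``ambiguity_threshold`` raises
    :class:`AmbiguousOrientationError` rather than guessing. Bins with PC1
    exactly 0 take the label of the nearest nonzero bin (tie -> B).
    """
    pc1 = np.asarray(pc1, dtype=float)
    keep = np.isfinite(pc1)
    for t in active_tracks + inactive_tracks:
        if t.values.size != pc1.size:
            raise AlignmentError(
                f"track {t.mark_name!r} has {t.values.size} bins, PC1 has {pc1.size}")
    s = sum(_pearson(pc1[keep], t.values[keep]) for t in active_tracks) \
        - sum(_pearson(pc1[keep], t.values[keep]) for t in inactive_tracks)
    if abs(s) < ambiguity_threshold:
        raise AmbiguousOrientationError(
            f"orientation statistic |s| = {abs(s):.4f} < {ambiguity_threshold}; "
            "histone marks cannot orient PC1 on this chromosome — set the sign manually")
    oriented = pc1 if s >= 0 else -pc1
    labels = np.full(pc1.size, "NA", dtype=object)
    labels[keep & (oriented > 0)] = "A"
    labels[keep & (oriented < 0)] = "B"
    zero = keep & (oriented == 0)
    if zero.any():
        nz = np.nonzero(keep & (oriented != 0))[0]
        for i in np.nonzero(zero)[0]:
            if nz.size == 0:
                labels[i] = "B"
                continue
            d = np.abs(nz - i)
            near = nz[d == d.min()]
            # tie between equidistant neighbours of opposite sign -> B
            signs = {np.sign(oriented[j]) for j in near}
            labels[i] = "B" if len(signs) > 1 or signs == {-1.0} else "A"
    return CompartmentProfile(chrom, bin_size, oriented, np.asarray(labels, dtype=object),
                              orientation_score=float(s))


def compartment_degree(profile: CompartmentProfile) -> np.ndarray:
    """Max-abs-normalized oriented PC1, in [-1, 1]; stored on the profile."""
    keep = profile.unmasked
    if not keep.any():
        raise DegeneracyError("all bins masked; compartment degree undefined")
    mx = np.max(np.abs(profile.pc1[keep]))
    if mx == 0:
        raise DegeneracyError("PC1 identically zero; compartment degree undefined")
    deg = profile.pc1 / mx
    profile.degree = deg
    return deg


def call_compartments(m_raw: ContactMatrix,
                      active_tracks: list[BinTrack],
                      inactive_tracks: list[BinTrack],
                      kr_tol: float = 1e-8, kr_max_iter: int = 3000,
                      mask_percentile: float = 1.0,
                      ambiguity_threshold: float = 0.05) -> CompartmentProfile:
    """Full per-chromosome compartment pipeline: KR -> O/E -> PC1 -> orient -> degree."""
    from .matrix import distance_normalize, kr_balance
    kr = kr_balance(m_raw, tol=kr_tol, max_iter=kr_max_iter, mask_percentile=mask_percentile)
    oe = distance_normalize(kr)
    pc1 = correlation_pc1(oe)
    prof = orient_and_label(pc1, m_raw.chrom, m_raw.bin_size,
                            active_tracks, inactive_tracks,
                            ambiguity_threshold=ambiguity_threshold)
    compartment_degree(prof)
    return prof


def classify_switches(p1: CompartmentProfile, p2: CompartmentProfile) -> SwitchReport:
    """Per-bin switch classes between two conditions on the same grid.

    Bins masked in either profile are masked in the report; the four class
    percentages are over unmasked bins and sum to 100.
    """
    if (p1.chrom != p2.chrom or p1.bin_size != p2.bin_size
            or p1.pc1.size != p2.pc1.size):
        raise AlignmentError("profiles are on different chromosome/bin grids")
    n = p1.pc1.size
    classes = np.full(n, "masked", dtype=object)
    both = p1.unmasked & p2.unmasked
    for i in np.nonzero(both)[0]:
        a, b = p1.labels[i], p2.labels[i]
        if a == "A" and b == "A":
            classes[i] = "stable_A"
        elif a == "B" and b == "B":
            classes[i] = "stable_B"
        elif a == "A" and b == "B":
            classes[i] = "A->B"
        else:
            classes[i] = "B->A"
    tot = int(both.sum())
    if tot == 0:
        raise DegeneracyError("no bins unmasked in both profiles")
    pct = {k: 100.0 * float(np.sum(classes == k)) / tot for k in SWITCH_CLASSES}
    return SwitchReport(p1.chrom, p1.bin_size, classes, pct)


def combine_reports(reports: dict[str, SwitchReport]) -> dict[str, float]:
    """Genome-wide class percentages pooled over per-chromosome reports."""
    counts = {k: 0 for k in SWITCH_CLASSES}
    tot = 0
    for r in reports.values():
        for k in SWITCH_CLASSES:
            c = int(np.sum(r.classes == k))
            counts[k] += c
            tot += c
    return {k: 100.0 * counts[k] / tot for k in SWITCH_CLASSES}
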