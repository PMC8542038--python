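"""Contact-matrix data model, sparse-triplet I/O, KR balancing and O/E normalization.

The in-memory container is a dense symmetric per-chromosome matrix — desk-scale
chromosomes (a few thousand bins) make dense storage the simplest correct
choice. Balancing follows the matrix-balancing (Knight-Ruiz) objective of
equalizing row sums, implemented as symmetric alternating scaling; the
observed/expected step divides every contact by the mean contact at its
genomic distance, removing the power-law distance decay before compartment
calling.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ConvergenceError, DegeneracyError, FormatError,
                     StateError, ValidationError)
from .genome import GenomeSpec

RAW, KR, OE = "raw", "kr", "oe"


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact matrix.

    ``balancing`` holds the per-bin KR weight vector (NaN on masked bins) and
    is present exactly when ``stage`` is ``"kr"`` or ``"oe"``.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    stage: str = RAW
    balancing: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("counts must be a square matrix")
        if self.stage not in (RAW, KR, OE):
            raise ValidationError(f"unknown stage {self.stage!r}")
        if (self.balancing is None) != (self.stage == RAW):
            raise ValidationError("balancing vector present iff stage is kr/oe")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean per-bin usable mask (True = usable)."""
        if self.balancing is not None:
            return np.isfinite(self.balancing)
        return self.counts.sum(axis=1) > 0

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Sum non-overlapping ``factor x factor`` blocks of a raw matrix."""
        if self.stage != RAW:
            raise StateError("coarsen operates on raw matrices")
        n = self.n_bins
        if factor == 1:
            return ContactMatrix(self.chrom, self.bin_size, self.counts.copy())
        if n % factor:
            raise ValidationError(f"{n} bins not divisible by coarsening factor {factor}")
        m = n // factor
        c = self.counts.reshape(m, factor, m, factor).sum(axis=(1, 3))
        return ContactMatrix(self.chrom, self.bin_size * factor, c)


@dataclass
class BinTrack:
    """Per-bin signal track for one chromosome (e.g. a histone mark)."""

    chrom: str
    bin_size: int
    values: np.ndarray
    mark_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("track values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("track values must be finite")

    def coarsen(self, factor: int) -> "BinTrack":
        n = self.values.size
        if n % factor:
            raise ValidationError(f"{n} bins not divisible by {factor}")
        v = self.values.reshape(n // factor, factor).mean(axis=1)
        return BinTrack(self.chrom, self.bin_size * factor, v, self.mark_name)


# ---------------------------------------------------------------------------
# sparse triplet I/O:  "chrom bin_i bin_j count", 0-based bins, i<=j on disk
# ---------------------------------------------------------------------------

def read_triplets(path: str | Path, genome: GenomeSpec) -> dict[str, ContactMatrix]:
    """Read a sparse triplet file into one raw matrix per chromosome.

    Entries listed once with i<=j are mirrored; duplicate (i, j) lines are
    summed. Out-of-range indices or unknown chromosomes raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "i", "j", "count"],
                         dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"{path}: cannot parse triplet file: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: empty triplet file")
    for col in ("i", "j"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 1 if len(bad) else 1
            raise FormatError(f"{path}:{line}: non-integer bin index")
    mats: dict[str, ContactMatrix] = {
        name: ContactMatrix(name, genome.bin_size, np.zeros((n, n)))
        for name, n in genome.chromosomes
    }
    sizes = dict(genome.chromosomes)
    unknown = ~df["chrom"].isin(sizes)
    if unknown.any():
        line = int(df.index[unknown][0]) + 1
        raise FormatError(f"{path}:{line}: unknown chromosome {df['chrom'][unknown].iloc[0]!r}")
    nmax = df["chrom"].map(sizes).to_numpy()
    bad = (df["i"].to_numpy() < 0) | (df["j"].to_numpy() < 0) | \
          (df["i"].to_numpy() >= nmax) | (df["j"].to_numpy() >= nmax)
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise FormatError(f"{path}:{line}: bin index out of range")
    for chrom, sub in df.groupby("chrom", sort=False):
        c = mats[chrom].counts
        i, j, v = sub["i"].to_numpy(), sub["j"].to_numpy(), sub["count"].to_numpy(float)
        np.add.at(c, (i, j), v)
        off = i != j
        np.add.at(c, (j[off], i[off]), v[off])
    return mats


def write_triplets(mats: dict[str, ContactMatrix] | list[ContactMatrix],
                   path: str | Path) -> None:
    """Write raw matrices as sparse triplet text (upper triangle, i<=j)."""
    if isinstance(mats, dict):
        mats = list(mats.values())
    frames = []
    for m in mats:
        iu, ju = np.triu_indices(m.n_bins)
        v = m.counts[iu, ju]
        nz = v != 0
        frames.append(pd.DataFrame({"chrom": m.chrom, "i": iu[nz], "j": ju[nz],
                                    "count": v[nz]}))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "i", "j", "count"])
    if len(df) and np.all(df["count"] == np.round(df["count"])):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_dense(m: ContactMatrix, path: str | Path) -> None:
    """Dense TSV writer for small matrices (debugging / inspection)."""
    np.savetxt(path, m.counts, delimiter="\t", fmt="%.10g")


def write_balancing(m: ContactMatrix, path: str | Path) -> None:
    """Balancing vector as 2-column TSV (bin, weight; NA for masked bins)."""
    if m.balancing is None:
        raise StateError("matrix has no balancing vector")
    with open(path, "w") as fh:
        for i, w in enumerate(m.balancing):
            fh.write(f"{i}\tNA\n" if not np.isfinite(w) else f"{i}\t{w:.10g}\n")


def read_bedgraph(path: str | Path, genome: GenomeSpec, bin_size: int,
                  mark_name: str = "") -> dict[str, BinTrack]:
    """Read a 4-column bedGraph into per-chromosome tracks at ``bin_size``.

    Intervals are 0-based half-open and must align to the bin grid; bins not
    covered default to 0.
    """
    genome_c = genome if genome.bin_size == bin_size else genome.coarsened(
        bin_size // genome.bin_size)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse bedGraph: {exc}") from exc
    out = {c: BinTrack(c, bin_size, np.zeros(n), mark_name)
           for c, n in genome_c.chromosomes}
    for row in df.itertuples():
        if row.chrom not in out:
            raise FormatError(f"{path}: unknown chromosome {row.chrom!r}")
        b = int(row.start) // bin_size
        if not 0 <= b < out[row.chrom].values.size:
            raise FormatError(f"{path}: interval {row.start}-{row.end} outside {row.chrom}")
        out[row.chrom].values[b] = float(row.value)
    return out


def write_bedgraph(track: BinTrack, path: str | Path, append: bool = False) -> None:
    with open(path, "a" if append else "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# balancing and distance normalization
# ---------------------------------------------------------------------------

def _mask_bins(counts: np.ndarray, mask_percentile: float) -> np.ndarray:
    """Usable-bin mask: drop zero rows, plus rows below the given percentile
    of nonzero row sums (unmappable-bin heuristic; Hi-C practice)."""
    rs = counts.sum(axis=1)
    keep = rs > 0
    if mask_percentile > 0 and keep.any():
        thr = np.percentile(rs[keep], mask_percentile)
        keep &= rs >= thr
    return keep


def kr_balance(m: ContactMatrix, tol: float = 1e-8, max_iter: int = 3000,
               mask_percentile: float = 1.0) -> ContactMatrix:
    """Balance a raw matrix so every unmasked row sums to the mean raw row sum.

    Returns ``B`` with ``B[i,j] = v[i] * v[j] * counts[i,j]``; ``v`` is stored
    as the balancing vector (NaN on masked bins). Masked rows/columns stay
    zero. Raises :class:`ConvergenceError` with the final residual if the
    row-sum residual does not reach ``tol`` within ``max_iter`` sweeps.
    """
    if m.stage != RAW:
        raise StateError("kr_balance expects a raw matrix")
    if tol <= 0 or max_iter < 1:
        raise ValidationError("tol must be > 0 and max_iter >= 1")
    keep = _mask_bins(m.counts, mask_percentile)
    k = int(keep.sum())
    if k < 2:
        raise DegeneracyError(f"only {k} unmasked bins; cannot balance")
    sub = m.counts[np.ix_(keep, keep)]
    target = sub.sum(axis=1).mean()
    v = np.ones(k)
    b = sub.copy()
    resid = np.inf
    for _ in range(max_iter):
        s = b.sum(axis=1)
        resid = float(np.max(np.abs(s - target)) / target)
        if resid < tol:
            break
        d = np.sqrt(target / s)
        b *= d[:, None]
        b *= d[None, :]
        v *= d
    else:
        raise ConvergenceError(
            f"KR balancing: residual {resid:.3e} > tol {tol:.1e} after {max_iter} iterations",
            residual=resid)
    counts = np.zeros_like(m.counts)
    counts[np.ix_(keep, keep)] = b
    vec = np.full(m.n_bins, np.nan)
    vec[keep] = v
    return ContactMatrix(m.chrom, m.bin_size, counts, stage=KR, balancing=vec)


def distance_normalize(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide each entry by the mean unmasked entry at its
    genomic offset |i-j| on this chromosome. Offsets with zero mean yield 0."""
    if m.stage != KR:
        raise StateError("distance_normalize expects a KR-balanced matrix")
    n = m.n_bins
    keep = m.unmasked
    out = np.zeros_like(m.counts)
    for k in range(n):
        diag = np.diagonal(m.counts, k)
        valid = keep[: n - k] & keep[k:]
        if not valid.any():
            continue
        mean = diag[valid].mean()
        if mean == 0:
            continue
        vals = diag / mean
        idx = np.arange(n - k)
        out[idx, idx + k] = np.where(valid, vals, 0.0)
        out[idx + k, idx] = out[idx, idx + k]
    return ContactMatrix(m.chrom, m.bin_size, out, stage=OE, balancing=m.balancing.copy())
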