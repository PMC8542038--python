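"""Two-condition synthetic genomes with planted chromatin architecture.

The generative model produces intra-chromosomal contact matrices whose
marginal behaviours mirror real Hi-C: a power-law distance decay, a
checkerboard of A/B compartment affinity, block-diagonal TAD enrichment, and
focal loop pixels. Architecture is planted once on a multi-resolution grid —
compartment labels on coarse (default 500-kb) bins, TAD boundaries on an
intermediate (50-kb) grid, loops on the finest (25-kb) grid — and a single
fine-resolution library is sampled per condition; coarser analysis matrices
are obtained by block summation, mirroring how one sequencing library serves
all three analysis resolutions.

Condition 2 differs from condition 1 only through recorded truth edits:
a flip set of compartment bins, a weakened set of TAD boundaries (each with
its own merge exponent), and a lost set of loops. Every edit is bookkept so
downstream callers can be scored against exact ground truth.

Expected contact between fine bins i and j (same chromosome):

    E[i, j] = d * max(|i-j|, 1)**(-alpha) * m(i, j)

where m multiplies ``rho`` if the bins share a compartment label, ``tau`` if
they share a TAD (``tau**mu_b`` across a boundary b weakened with exponent
mu_b), and ``loop_boost`` on planted loop pixels. Observed counts are
independent Poisson draws of E on the upper triangle, mirrored.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, ValidationError
from .genome import GenomeSpec
from .matrix import BinTrack, ContactMatrix

ACTIVE_MARKS = ("H3K4me1", "H3K27ac")
INACTIVE_MARKS = ("H3K9me3", "H3K27me3")
MARKS = ACTIVE_MARKS + INACTIVE_MARKS

# marker-track emission levels (arbitrary coverage units)
MU_HIGH, MU_LOW = 2.0, 0.5


def _seed32(*parts: int) -> list[int]:
    """Seed sequence for default_rng, each entry kept below 2**31."""
    return [int(p) & 0x7FFFFFFF for p in parts]


@dataclass
class ArchitectureTruth:
    """Planted architecture for both conditions on one genome.

    ``labels[cond][chrom]`` holds +1 (A) / -1 (B) per compartment bin;
    ``boundaries[chrom]`` interior TAD-boundary indices on the TAD grid
    (positions shared by both conditions; weakening changes contact
    enrichment, not the planted position); ``weaken_mu[chrom]`` the per-
    boundary merge exponent applied in condition 2 (0 = intact, 1 = fully
    merged); ``loops[chrom]`` planted fine-grid pixels with ``lost[chrom]``
    marking those absent from condition 2.
    """

    spec: GenomeSpec                       # fine (loop-resolution) grid
    comp_factor: int
    tad_factor: int
    alpha: float
    rho: float
    tau: float
    loop_boost: float
    depth: float
    labels: dict[int, dict[str, np.ndarray]]
    boundaries: dict[str, np.ndarray]
    weaken_mu: dict[str, np.ndarray]
    loops: dict[str, np.ndarray]
    lost: dict[str, np.ndarray]
    flip_set: dict[str, np.ndarray]
    # condition-2 checkerboard attenuation: the same-compartment affinity in
    # condition 2 is 1 + (rho - 1) * checkerboard_attenuation (the knockout's
    # visibly weakened compartmentalization); 1.0 = no attenuation
    checkerboard_attenuation: float = 1.0

    # -- derived views -----------------------------------------------------
    def labels_fine(self, condition: int, chrom: str) -> np.ndarray:
        return np.repeat(self.labels[condition][chrom], self.comp_factor)

    def boundaries_fine(self, chrom: str) -> np.ndarray:
        return self.boundaries[chrom] * self.tad_factor

    def domain_id_fine(self, chrom: str) -> np.ndarray:
        n = self.spec.n_bins(chrom)
        return np.searchsorted(self.boundaries_fine(chrom), np.arange(n), side="right")

    def loops_active(self, condition: int, chrom: str) -> np.ndarray:
        px = self.loops[chrom]
        if condition == 2:
            return px[~self.lost[chrom]]
        return px

    def weakened_boundaries(self, chrom: str) -> np.ndarray:
        return self.boundaries[chrom][self.weaken_mu[chrom] > 0]

    @property
    def n_compartment_bins(self) -> int:
        return sum(a.size for a in self.labels[1].values())

    # -- expected-contact model -------------------------------------------
    def _check_condition(self, condition: int) -> None:
        if condition not in (1, 2):
            raise ParameterError(f"condition must be 1 or 2, got {condition}")

    def rho_for(self, condition: int) -> float:
        """Same-compartment affinity in the given condition."""
        if condition == 2:
            return 1.0 + (self.rho - 1.0) * self.checkerboard_attenuation
        return self.rho

    def expected_contact(self, i: int, j: int, condition: int = 1) -> float:
        """Expected count for one global fine-bin pair (intra-chromosomal).

        ``i`` and ``j`` are global fine-bin indices; a pair on different
        chromosomes raises :class:`DomainError` (the model is
        intra-chromosomal only).
        """
        self._check_condition(condition)
        ci, li = self.spec.locate(i)
        cj, lj = self.spec.locate(j)
        if ci != cj:
            raise DomainError(f"bins {i} and {j} are on different chromosomes ({ci}, {cj})")
        lab = self.labels[condition][ci]
        dist = max(abs(li - lj), 1)
        e = self.depth * float(dist) ** (-self.alpha)
        if lab[li // self.comp_factor] == lab[lj // self.comp_factor]:
            e *= self.rho_for(condition)
        bf = self.boundaries_fine(ci)
        di = int(np.searchsorted(bf, li, side="right"))
        dj = int(np.searchsorted(bf, lj, side="right"))
        if di == dj:
            e *= self.tau
        elif abs(di - dj) == 1 and condition == 2:
            mu = self.weaken_mu[ci][min(di, dj)]
            if mu > 0:
                e *= self.tau ** mu
        px = self.loops_active(condition, ci)
        if px.size and li != lj:
            a, b = min(li, lj), max(li, lj)
            if np.any((px[:, 0] == a) & (px[:, 1] == b)):
                e *= self.loop_boost
        return e

    def expected_matrix(self, chrom: str, condition: int = 1) -> np.ndarray:
        """Dense expected-count matrix for one chromosome (fine grid)."""
        self._check_condition(condition)
        n = self.spec.n_bins(chrom)
        idx = np.arange(n, dtype=np.int32)
        dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
        np.maximum(dist, 1.0, out=dist)
        e = dist ** (-self.alpha)
        del dist
        e *= self.depth
        lf = self.labels_fine(condition, chrom)
        same = lf[:, None] == lf[None, :]
        e *= np.where(same, self.rho_for(condition), 1.0)
        del same
        did = self.domain_id_fine(chrom)
        e *= np.where(did[:, None] == did[None, :], self.tau, 1.0)
        if condition == 2:
            mus = self.weaken_mu[chrom]
            for k in np.nonzero(mus > 0)[0]:
                left = did == k
                right = did == k + 1
                factor = self.tau ** mus[k]
                e[np.ix_(left, right)] *= factor
                e[np.ix_(right, left)] *= factor
        px = self.loops_active(condition, chrom)
        if px.size:
            e[px[:, 0], px[:, 1]] *= self.loop_boost
            e[px[:, 1], px[:, 0]] *= self.loop_boost
        return e

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "spec": {"chromosomes": list(self.spec.chromosomes),
                     "bin_size": self.spec.bin_size, "seed": self.spec.seed},
            "comp_factor": self.comp_factor, "tad_factor": self.tad_factor,
            "alpha": self.alpha, "rho": self.rho, "tau": self.tau,
            "loop_boost": self.loop_boost, "depth": self.depth,
            "checkerboard_attenuation": self.checkerboard_attenuation,
            "labels": {str(c): {ch: v.tolist() for ch, v in d_.items()}
                       for c, d_ in self.labels.items()},
            "boundaries": {ch: v.tolist() for ch, v in self.boundaries.items()},
            "weaken_mu": {ch: v.tolist() for ch, v in self.weaken_mu.items()},
            "loops": {ch: v.tolist() for ch, v in self.loops.items()},
            "lost": {ch: v.tolist() for ch, v in self.lost.items()},
            "flip_set": {ch: v.tolist() for ch, v in self.flip_set.items()},
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchitectureTruth":
        d = json.loads(Path(path).read_text())
        spec = GenomeSpec(tuple((c, n) for c, n in d["spec"]["chromosomes"]),
                          d["spec"]["bin_size"], d["spec"].get("seed", 0))
        return cls(
            spec=spec, comp_factor=d["comp_factor"], tad_factor=d["tad_factor"],
            alpha=d["alpha"], rho=d["rho"], tau=d["tau"],
            loop_boost=d["loop_boost"], depth=d["depth"],
            checkerboard_attenuation=d.get("checkerboard_attenuation", 1.0),
            labels={int(c): {ch: np.asarray(v, dtype=np.int8) for ch, v in dd.items()}
                    for c, dd in d["labels"].items()},
            boundaries={ch: np.asarray(v, dtype=int) for ch, v in d["boundaries"].items()},
            weaken_mu={ch: np.asarray(v, dtype=float) for ch, v in d["weaken_mu"].items()},
            loops={ch: np.asarray(v, dtype=int).reshape(-1, 2) for ch, v in d["loops"].items()},
            lost={ch: np.asarray(v, dtype=bool) for ch, v in d["lost"].items()},
            flip_set={ch: np.asarray(v, dtype=int) for ch, v in d["flip_set"].items()},
        )


def synthetic_genome(n_chroms: int, comp_bins_per_chrom: int,
                     bin_size: int = 25_000, comp_factor: int = 20,
                     seed: int = 0) -> GenomeSpec:
    """Convenience constructor: ``n_chroms`` chromosomes, each
    ``comp_bins_per_chrom`` compartment-resolution bins on a fine grid of
    ``comp_factor`` fine bins per compartment bin."""
    chroms = tuple((f"chr{i + 1}", comp_bins_per_chrom * comp_factor)
                   for i in range(n_chroms))
    return GenomeSpec(chroms, bin_size, seed)


def plant_architecture(spec: GenomeSpec,
                       flip_fraction: float,
                       weaken_fraction: float,
                       loop_loss_fraction: float,
                       seed: int,
                       *,
                       comp_factor: int = 20,
                       tad_factor: int = 2,
                       alpha: float = 1.0,
                       rho: float = 1.4,
                       tau: float = 2.0,
                       loop_boost: float = 3.0,
                       depth: float = 1e6,
                       a_fraction: float = 0.6,
                       domain_bins: tuple[int, int] = (8, 25),
                       loops_per_bin: float = 1 / 40,
                       weaken_range: tuple[float, float] = (0.3, 0.75),
                       checkerboard_attenuation: float = 1.0,
                       ) -> ArchitectureTruth:
    """Plant two-condition architecture on ``spec``'s fine grid.

    Condition 2 differs from condition 1 in exactly the requested fractions
    (rounded to nearest count): ``flip_fraction`` of compartment bins change
    label, ``weaken_fraction`` of TAD boundaries get a merge exponent drawn
    from ``weaken_range``, ``loop_loss_fraction`` of loops are removed.

    Compartment labels form alternating A/B runs with geometric lengths whose
    means are chosen so the stationary A fraction is ``a_fraction``.
    """
    for name, f in (("flip_fraction", flip_fraction),
                    ("weaken_fraction", weaken_fraction),
                    ("loop_loss_fraction", loop_loss_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {f}")
    # equality (= 1) disables the corresponding feature, e.g. loop_boost=1
    # plants no visible loops (the null used for caller calibration)
    if not (alpha > 0 and rho >= 1 and tau >= 1 and loop_boost >= 1):
        raise ParameterError("require alpha > 0 and rho, tau, loop_boost >= 1")
    if depth < 0:
        raise ParameterError("depth must be non-negative")
    if not 0.0 <= checkerboard_attenuation <= 1.0:
        raise ParameterError("checkerboard_attenuation must be in [0, 1]")
    if comp_factor % tad_factor:
        raise ValidationError("comp_factor must be a multiple of tad_factor")
    for name, n in spec.chromosomes:
        if n % comp_factor:
            raise ValidationError(
                f"chromosome {name!r}: {n} fine bins not divisible by comp_factor {comp_factor}")

    rng = np.random.default_rng(_seed32(seed))
    mean_run = 4.0  # compartment-bin run length (~2 Mb at 500-kb bins)
    mean_a = 2 * mean_run * a_fraction
    mean_b = 2 * mean_run * (1 - a_fraction)

    labels1: dict[str, np.ndarray] = {}
    boundaries: dict[str, np.ndarray] = {}
    loops: dict[str, np.ndarray] = {}
    for chrom, n_fine in spec.chromosomes:
        n_comp = n_fine // comp_factor
        # alternating A/B runs
        lab = np.empty(n_comp, dtype=np.int8)
        pos, cur = 0, (1 if rng.random() < a_fraction else -1)
        while pos < n_comp:
            mean = mean_a if cur == 1 else mean_b
            run = int(rng.geometric(1.0 / mean))
            lab[pos:pos + run] = cur
            pos += run
            cur = -cur
        labels1[chrom] = lab
        # TAD boundaries on the TAD grid
        n_tad = n_fine // tad_factor
        edges, acc = [], 0
        while True:
            acc += int(rng.integers(domain_bins[0], domain_bins[1]))
            if acc >= n_tad - domain_bins[0] // 2:
                break
            edges.append(acc)
        boundaries[chrom] = np.asarray(edges, dtype=int)
        # loop pixels on the fine grid, kept clear of edges and the diagonal
        n_loops = max(3, int(round(n_fine * loops_per_bin)))
        seen: set[tuple[int, int]] = set()
        margin = 6
        attempts = 0
        while len(seen) < n_loops and attempts < 50 * n_loops:
            attempts += 1
            sep = int(rng.integers(12, 81))
            if n_fine - sep - 2 * margin <= 0:
                break
            i = int(rng.integers(margin, n_fine - sep - margin))
            seen.add((i, i + sep))
        loops[chrom] = np.asarray(sorted(seen), dtype=int).reshape(-1, 2)

    # --- condition-2 edits, exact counts genome-wide ----------------------
    chrom_names = list(spec.names)
    comp_sizes = [labels1[c].size for c in chrom_names]
    total_comp = sum(comp_sizes)
    k_flip = int(round(flip_fraction * total_comp))
    # switching happens in contiguous segments (mean ~2.5 compartment bins),
    # truncating the last segment so exactly k_flip bins flip genome-wide
    flipped: set[int] = set()
    guard = 0
    while len(flipped) < k_flip and guard < 100 * max(k_flip, 1):
        guard += 1
        seg = min(int(rng.geometric(1 / 2.5)), k_flip - len(flipped))
        start = int(rng.integers(0, total_comp))
        block = [b for b in range(start, min(start + seg, total_comp))
                 if b not in flipped]
        flipped.update(block)
    flip_global = np.asarray(sorted(flipped), dtype=int)
    flip_set: dict[str, np.ndarray] = {}
    labels2: dict[str, np.ndarray] = {}
    off = 0
    for c, sz in zip(chrom_names, comp_sizes):
        local = flip_global[(flip_global >= off) & (flip_global < off + sz)] - off
        flip_set[c] = local.astype(int)
        lab2 = labels1[c].copy()
        lab2[local] *= -1
        labels2[c] = lab2
        off += sz

    bnd_sizes = [boundaries[c].size for c in chrom_names]
    total_bnd = sum(bnd_sizes)
    k_weak = int(round(weaken_fraction * total_bnd))
    weak_global = rng.choice(total_bnd, size=k_weak, replace=False) if total_bnd else np.empty(0, int)
    weaken_mu: dict[str, np.ndarray] = {}
    off = 0
    for c, sz in zip(chrom_names, bnd_sizes):
        mu = np.zeros(sz)
        local = weak_global[(weak_global >= off) & (weak_global < off + sz)] - off
        mu[local] = rng.uniform(weaken_range[0], weaken_range[1], size=local.size)
        weaken_mu[c] = mu
        off += sz

    loop_sizes = [loops[c].shape[0] for c in chrom_names]
    total_loops = sum(loop_sizes)
    k_lost = int(round(loop_loss_fraction * total_loops))
    lost_global = rng.choice(total_loops, size=k_lost, replace=False) if total_loops else np.empty(0, int)
    lost: dict[str, np.ndarray] = {}
    off = 0
    for c, sz in zip(chrom_names, loop_sizes):
        m = np.zeros(sz, dtype=bool)
        m[lost_global[(lost_global >= off) & (lost_global < off + sz)] - off] = True
        lost[c] = m
        off += sz

    return ArchitectureTruth(
        spec=spec, comp_factor=comp_factor, tad_factor=tad_factor,
        alpha=alpha, rho=rho, tau=tau, loop_boost=loop_boost, depth=depth,
        checkerboard_attenuation=checkerboard_attenuation,
        labels={1: labels1, 2: labels2}, boundaries=boundaries,
        weaken_mu=weaken_mu, loops=loops, lost=lost, flip_set=flip_set)


def sample_contact_matrix(truth: ArchitectureTruth, condition: int,
                          seed: int) -> dict[str, ContactMatrix]:
    """Poisson-sample one fine-resolution library for one condition.

    Upper-triangle entries (including the diagonal) are independent
    Poisson(E[i, j]) draws, mirrored to a symmetric matrix. Reproducible:
    identical (truth, condition, seed) give identical matrices.
    """
    truth._check_condition(condition)
    out: dict[str, ContactMatrix] = {}
    for ci, (chrom, n) in enumerate(truth.spec.chromosomes):
        rng = np.random.default_rng(_seed32(seed, condition, ci))
        lam = truth.expected_matrix(chrom, condition)
        draw = rng.poisson(lam).astype(float)
        del lam
        upper = np.triu(draw)
        counts = upper + upper.T - np.diag(np.diag(upper))
        del draw, upper
        out[chrom] = ContactMatrix(chrom, truth.spec.bin_size, counts)
    return out


def generate_marker_tracks(truth: ArchitectureTruth, snr: float,
                           seed: int, condition: int = 1,
                           ) -> dict[str, dict[str, BinTrack]]:
    """Histone-mark tracks on the fine grid: ``tracks[mark][chrom]``.

    Active marks (H3K4me1, H3K27ac) emit ``MU_HIGH`` over A bins and
    ``MU_LOW`` over B bins; repressive marks (H3K9me3, H3K27me3) the reverse.
    Gaussian noise with sd ``MU_HIGH / snr``; ``snr = inf`` gives noiseless
    indicator-like tracks.
    """
    if not snr > 0:
        raise ParameterError(f"snr must be positive, got {snr}")
    truth._check_condition(condition)
    sd = 0.0 if np.isinf(snr) else MU_HIGH / snr
    out: dict[str, dict[str, BinTrack]] = {m: {} for m in MARKS}
    for mi, mark in enumerate(MARKS):
        active = mark in ACTIVE_MARKS
        for ci, (chrom, n) in enumerate(truth.spec.chromosomes):
            rng = np.random.default_rng(_seed32(seed, condition, mi, ci))
            lf = truth.labels_fine(condition, chrom)
            base = np.where(lf == (1 if active else -1), MU_HIGH, MU_LOW)
            vals = base + (rng.normal(0.0, sd, size=n) if sd else 0.0)
            out[mark][chrom] = BinTrack(chrom, truth.spec.bin_size, vals, mark)
    return out


def generate_gene_table(truth: ArchitectureTruth, n_genes: int,
                        de_effect: float, seed: int,
                        background_de_fraction: float = 0.05,
                        noise_sd_log2: float = 0.25) -> pd.DataFrame:
    """Gene table with expression coupled to planted compartment switching.

    Genes are placed uniformly over the genome; a gene is assigned to the bin
    containing its midpoint. Genes whose compartment bin flips A->B have
    FPKM_KO = FPKM_WT / de_effect in expectation, B->A the reverse, stable
    bins no systematic change; multiplicative log-normal noise throughout.
    A ``background_de_fraction`` of stable-bin genes receive the same effect
    size in a random direction, emulating expression changes unrelated to
    compartment switching. ``de_flag`` is derived from the planted expected
    fold change (|log2 effect| >= 1 -> up/down, else ns).
    """
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    if not de_effect > 1:
        raise ParameterError("de_effect must be > 1")
    rng = np.random.default_rng(_seed32(seed, 977))
    spec = truth.spec
    chrom_bp = {c: n * spec.bin_size for c, n in spec.chromosomes}
    total_bp = sum(chrom_bp.values())
    names = list(spec.names)
    probs = np.array([chrom_bp[c] for c in names], dtype=float) / total_bp
    chroms = rng.choice(len(names), size=n_genes, p=probs)
    rows = []
    comp_bin_size = spec.bin_size * truth.comp_factor
    for g in range(n_genes):
        chrom = names[chroms[g]]
        length = int(10 ** rng.uniform(3.3, 4.9))  # ~2-80 kb
        start = int(rng.integers(0, max(chrom_bp[chrom] - length, 1)))
        end = min(start + length, chrom_bp[chrom])
        mid = (start + end) // 2
        cbin = mid // comp_bin_size
        l1 = truth.labels[1][chrom][cbin]
        l2 = truth.labels[2][chrom][cbin]
        if l1 == 1 and l2 == -1:
            klass, mult = "A->B", 1.0 / de_effect
        elif l1 == -1 and l2 == 1:
            klass, mult = "B->A", de_effect
        else:
            klass, mult = "stable", 1.0
            if rng.random() < background_de_fraction:
                mult = de_effect if rng.random() < 0.5 else 1.0 / de_effect
        fpkm_wt = float(rng.lognormal(np.log(8.0), 1.0))
        fpkm_ko = fpkm_wt * mult * 2.0 ** rng.normal(0.0, noise_sd_log2)
        lfc_true = np.log2(mult)
        flag = "up" if lfc_true >= 1 else ("down" if lfc_true <= -1 else "ns")
        rows.append((f"gene{g:05d}", chrom, start, end, fpkm_wt, fpkm_ko, flag, klass))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "fpkm_wt", "fpkm_ko", "de_flag", "true_class"])


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
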