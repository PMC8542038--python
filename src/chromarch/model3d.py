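"""Coarse-grained bead-on-string 3D genome models with radial compartment bias.

Each chromosome is a chain of beads (one per compartment-resolution bin)
inside a spherical nucleus of radius R. Three potentials act on the beads:

* connectivity — harmonic bonds ``k_b (|x_{i+1} - x_i| - b)**2`` between
  linear neighbours within a chain;
* radial bias — ``k_r (|x_i| - t_i)**2`` pulling each bead toward its target
  radius ``t_i = R (0.5 - 0.35 * degree_i)``, so the most active beads
  (compartment degree +1) sit at 0.15 R near the nucleus centre and the most
  repressed (degree -1) at 0.85 R;
* excluded volume — a soft-core repulsion ``k_rep (sigma - r)**2`` for bead
  pairs closer than ``sigma``.

Starting from seed-reproducible random coordinates, the conformation is
relaxed by damped Langevin descent (gradient steps plus geometrically
decaying noise, simulated-annealing flavour) followed by noiseless descent;
the best-energy configuration visited is returned. Several random restarts
are optimized and the lowest-energy one kept, with all restart energies
reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import IntegrationError, ParameterError

RADIAL_MID, RADIAL_SLOPE = 0.5, 0.35


def radial_targets(degree: np.ndarray, R: float) -> np.ndarray:
    """Map compartment degree in [-1, 1] to a target radius.

    Linear map ``R * (0.5 - 0.35 * degree)``: degree +1 -> 0.15 R (active,
    central), degree -1 -> 0.85 R (repressed, peripheral), masked (NaN)
    beads -> 0.5 R.
    """
    deg = np.asarray(degree, dtype=float)
    finite = deg[np.isfinite(deg)]
    if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
        raise ParameterError("compartment degree must lie in [-1, 1]")
    t = R * (RADIAL_MID - RADIAL_SLOPE * np.where(np.isfinite(deg), deg, 0.0))
    return t


@dataclass
class Conformation3D:
    """Optimized bead coordinates for a set of chains."""

    chains: list[tuple[str, np.ndarray]]    # (chrom, coords (n, 3))
    target_radius: np.ndarray               # concatenated per-bead targets
    R: float
    seed: int
    n_steps: int
    final_energy: float
    energy_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_energies: list[float] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return np.concatenate([c for _, c in self.chains], axis=0)

    def write_xyz(self, path) -> None:
        """Multi-chain text format: chain, bin, x, y, z per bead."""
        with open(path, "w") as fh:
            for chrom, xyz in self.chains:
                for i, (x, y, z) in enumerate(xyz):
                    fh.write(f"{chrom}\t{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")

    def write_pdb(self, path) -> None:
        """Minimal CA-trace PDB, one chain ID per chromosome (viewer aid)."""
        ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
        with open(path, "w") as fh:
            serial = 1
            for k, (chrom, xyz) in enumerate(self.chains):
                cid = ids[k % len(ids)]
                for i, (x, y, z) in enumerate(xyz):
                    fh.write(f"ATOM  {serial % 100000:5d}  CA  GLY {cid}{(i + 1) % 10000:4d}"
                             f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                    serial += 1
                fh.write("TER\n")
            fh.write("END\n")


def _energy_grad(x: np.ndarray, bonds: np.ndarray, targets: np.ndarray,
                 bond_length: float, k_b: float, k_r: float,
                 k_rep: float, sigma: float,
                 want_grad: bool = True) -> tuple[float, np.ndarray | None]:
    """Total potential energy and analytic gradient."""
    grad = np.zeros_like(x) if want_grad else None
    # bonds
    d = x[bonds[:, 1]] - x[bonds[:, 0]]
    r = np.linalg.norm(d, axis=1)
    r_safe = np.maximum(r, 1e-12)
    e = float(np.sum(k_b * (r - bond_length) ** 2))
    if want_grad:
        f = (2.0 * k_b * (r - bond_length) / r_safe)[:, None] * d
        np.add.at(grad, bonds[:, 1], f)
        np.add.at(grad, bonds[:, 0], -f)
    # radial bias
    rad = np.linalg.norm(x, axis=1)
    rad_safe = np.maximum(rad, 1e-12)
    e += float(np.sum(k_r * (rad - targets) ** 2))
    if want_grad:
        grad += (2.0 * k_r * (rad - targets) / rad_safe)[:, None] * x
    # soft-core repulsion
    if k_rep > 0:
        dm = squareform(pdist(x))
        np.fill_diagonal(dm, np.inf)
        close = dm < sigma
        if close.any():
            iu = np.triu(close)
            ci, cj = np.nonzero(iu)
            rr = dm[ci, cj]
            e += float(np.sum(k_rep * (sigma - rr) ** 2))
            if want_grad:
                dd = x[ci] - x[cj]
                f = (-2.0 * k_rep * (sigma - rr) / np.maximum(rr, 1e-12))[:, None] * dd
                np.add.at(grad, ci, f)
                np.add.at(grad, cj, -f)
    return e, grad


def optimize_conformation(chain_lengths: list[tuple[str, int]],
                          target_radius: np.ndarray,
                          R: float = 10.0,
                          bond_length: float = 0.5,
                          n_steps: int = 5000,
                          seed: int = 0,
                          k_b: float = 50.0,
                          k_r: float = 5.0,
                          k_rep: float = 10.0,
                          sigma: float | None = None,
                          n_restarts: int = 5,
                          step_size: float = 2e-3,
                          noise0: float | None = None,
                          n_checkpoints: int = 20) -> Conformation3D:
    """Relax chains under bond + radial-bias + soft-core potentials.

    ``chain_lengths`` lists (chromosome, n_beads); ``target_radius`` is the
    concatenated per-bead target. Deterministic under ``seed``; the reported
    trajectory is the best-so-far energy at checkpoints (non-increasing by
    construction) and the lowest-energy configuration across restarts is
    returned, with every restart's final energy in ``restart_energies``.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if not bond_length < R:
        raise ParameterError("bond_length must be well below R")
    n = sum(k for _, k in chain_lengths)
    targets = np.asarray(target_radius, dtype=float)
    if targets.size != n:
        raise ParameterError(f"target_radius has {targets.size} entries for {n} beads")
    if sigma is None:
        sigma = 0.8 * bond_length
    bonds = []
    off = 0
    for _, k in chain_lengths:
        for i in range(k - 1):
            bonds.append((off + i, off + i + 1))
        off += k
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    if noise0 is None:
        noise0 = 0.1 * bond_length
    decay = (1e-3) ** (1.0 / max(n_steps - 1, 1))  # noise -> noise0/1000 by the end
    anneal_steps = int(0.9 * n_steps)
    check_every = max(n_steps // max(n_checkpoints, 1), 1)
    max_step = 0.5 * bond_length  # per-bead displacement clip

    best_overall: tuple[float, np.ndarray, np.ndarray, int] | None = None
    restart_energies: list[float] = []
    for r_idx in range(max(n_restarts, 1)):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, r_idx])
        # random start inside the sphere
        x = rng.normal(size=(n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        x *= R * rng.random((n, 1)) ** (1 / 3)
        best_e, best_x = np.inf, x.copy()
        traj = []
        noise = noise0
        for step in range(n_steps):
            e, g = _energy_grad(x, bonds, targets, bond_length, k_b, k_r, k_rep, sigma)
            if not np.isfinite(e):
                raise IntegrationError(
                    "non-finite energy during relaxation; reduce step_size")
            if e < best_e:
                best_e, best_x = e, x.copy()
            dx = -step_size * g
            norms = np.linalg.norm(dx, axis=1, keepdims=True)
            np.divide(dx, norms, out=dx, where=norms > max_step)
            dx[np.squeeze(norms > max_step, axis=1)] *= max_step
            x = x + dx
            if step < anneal_steps and noise > 0:
                x = x + rng.normal(scale=noise, size=x.shape)
                noise *= decay
            if (step + 1) % check_every == 0:
                traj.append(best_e)
        e, _ = _energy_grad(x, bonds, targets, bond_length, k_b, k_r, k_rep, sigma,
                            want_grad=False)
        if e < best_e:
            best_e, best_x = e, x.copy()
        restart_energies.append(float(best_e))
        if best_overall is None or best_e < best_overall[0]:
            best_overall = (float(best_e), best_x, np.asarray(traj), r_idx)
    assert best_overall is not None
    final_e, coords, traj, _ = best_overall
    chains = []
    off = 0
    for chrom, k in chain_lengths:
        chains.append((chrom, coords[off:off + k].copy()))
        off += k
    return Conformation3D(chains=chains, target_radius=targets, R=R, seed=seed,
                          n_steps=n_steps, final_energy=final_e,
                          energy_trajectory=traj, restart_energies=restart_energies)


def conformation_energy(conf: Conformation3D, bond_length: float = 0.5,
                        k_b: float = 50.0, k_r: float = 5.0,
                        k_rep: float = 10.0, sigma: float | None = None) -> float:
    """Recompute the potential energy of a conformation (diagnostics)."""
    if sigma is None:
        sigma = 0.8 * bond_length
    bonds = []
    off = 0
    for _, xyz in conf.chains:
        k = len(xyz)
        bonds.extend((off + i, off + i + 1) for i in range(k - 1))
        off += k
    e, _ = _energy_grad(conf.coords, np.asarray(bonds, int).reshape(-1, 2),
                        conf.target_radius, bond_length, k_b, k_r, k_rep, sigma,
                        want_grad=False)
    return e


def radial_profile(conf: Conformation3D,
                   labels_per_chain: dict[str, np.ndarray]) -> dict:
    """Mean and sd of bead radius by compartment label, per chain and global."""
    per_chain = {}
    pooled: dict[str, list[np.ndarray]] = {"A": [], "B": [], "NA": []}
    for chrom, xyz in conf.chains:
        lab = np.asarray(labels_per_chain[chrom], dtype=object)
        rad = np.linalg.norm(xyz, axis=1)
        entry = {}
        for k in ("A", "B", "NA"):
            sel = rad[lab == k]
            pooled[k].append(sel)
            entry[k] = {"n": int(sel.size),
                        "mean": float(sel.mean()) if sel.size else float("nan"),
                        "sd": float(sel.std()) if sel.size else float("nan")}
        per_chain[chrom] = entry
    glob = {}
    for k, parts in pooled.items():
        allv = np.concatenate(parts) if parts else np.empty(0)
        glob[k] = {"n": int(allv.size),
                   "mean": float(allv.mean()) if allv.size else float("nan"),
                   "sd": float(allv.std()) if allv.size else float("nan")}
    return {"global": glob, "per_chain": per_chain}


def compactness_score(conf: Conformation3D, max_pairs: int = 100_000) -> float:
    """Mean within-chain pairwise bead distance (pooled over chains).

    Larger values mean a looser, more expanded genome. Chains with more than
    ``max_pairs`` pairs are deterministically subsampled by stride.
    """
    total, count = 0.0, 0
    for _, xyz in conf.chains:
        if len(xyz) < 2:
            continue
        d = pdist(xyz)
        if d.size > max_pairs:
            stride = int(np.ceil(d.size / max_pairs))
            d = d[::stride]
        total += float(d.sum())
        count += d.size
    if count == 0:
        raise ParameterError("need at least one chain with >= 2 beads")
    return total / count
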