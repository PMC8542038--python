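"""End-to-end pipeline: simulate -> balance -> compartments/TADs/loops -> 3D -> integrate.

A :class:`RunConfig` (JSON file or dict) fixes the resolution ladder, stage
parameters and seeds; :func:`run_pipeline` executes every stage per condition,
runs all cross-condition comparisons, and writes a manifest recording inputs,
a parameter hash, seeds, every decided default, and SHA-256 checksums of all
outputs — identical config and seeds reproduce identical checksums.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from . import integrate as int_mod
from . import loops as loop_mod
from . import model3d as m3d
from . import synthetic as syn
from . import tads as tad_mod
from .errors import ChromarchError, ValidationError
from .genome import GenomeSpec
from .matrix import kr_balance, write_bedgraph, write_triplets

DEFAULTS: dict = {
    "out_dir": "chromarch_run",
    "seed": 0,
    "genome": {"n_chroms": 2, "comp_bins": 40, "bin_size": 25_000,
               "comp_factor": 20, "tad_factor": 2},
    "synthetic": {"flip_fraction": 0.121, "weaken_fraction": 0.5,
                  "loop_loss_fraction": 0.3, "depth": 1e4, "snr": 5.0,
                  "n_genes": 1000, "de_effect": 4.0,
                  "alpha": 1.0, "rho": 1.4, "tau": 2.0, "loop_boost": 3.0},
    "kr": {"tol": 1e-8, "max_iter": 3000, "mask_percentile": 1.0},
    "compartments": {"ambiguity_threshold": 0.05},
    "tads": {"w": 5, "span": 3, "min_depth": 0.1,
             "match_slack": 2, "change_threshold": 0.1},
    "loops": {"fdr": 0.1, "min_sep": 2, "r_inner": 2, "r_outer": 5,
              "oe_threshold": 1.75, "ll_threshold": 1.4, "max_sep": 100,
              "compare_slack": 1},
    "model3d": {"R": 10.0, "bond_length": 0.5, "k_b": 50.0, "k_r": 5.0,
                "k_rep": 10.0, "n_steps": 2000, "n_restarts": 2},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged)."""

    params: dict

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        params = _merge(DEFAULTS, d)
        g = params["genome"]
        cf, tf = int(g["comp_factor"]), int(g["tad_factor"])
        if cf < 1 or tf < 1:
            raise ValidationError("resolution factors must be >= 1")
        if cf < tf:
            raise ValidationError(
                "compartment resolution must be at least TAD resolution "
                f"(comp_factor {cf} < tad_factor {tf})")
        if cf % tf:
            raise ValidationError(
                f"TAD resolution must divide compartment resolution "
                f"(comp_factor {cf} not a multiple of tad_factor {tf})")
        for key in ("flip_fraction", "weaken_fraction", "loop_loss_fraction"):
            f = params["synthetic"][key]
            if not 0 <= f <= 1:
                raise ValidationError(f"synthetic.{key} = {f} outside [0, 1]")
        return cls(params)

    def __getitem__(self, key: str):
        return self.params[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run every stage end-to-end; returns (and writes) the run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    p = config.params
    out_dir = Path(p["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(p["seed"])
    g, s = p["genome"], p["synthetic"]
    manifest: dict = {"config_hash": config.hash(), "seed": seed,
                      "decided_defaults": {
                          "mask_percentile": p["kr"]["mask_percentile"],
                          "tad_min_depth": p["tads"]["min_depth"],
                          "loop_oe_threshold": p["loops"]["oe_threshold"],
                          "degree_formula": "oriented PC1 / max|PC1|",
                          "boundary_strength": "flank-interior mean binSignal minus boundary binSignal",
                      },
                      "stages": [], "outputs": {}}
    stage = "simulate"
    try:
        spec = syn.synthetic_genome(int(g["n_chroms"]), int(g["comp_bins"]),
                                    bin_size=int(g["bin_size"]),
                                    comp_factor=int(g["comp_factor"]), seed=seed)
        truth = syn.plant_architecture(
            spec, s["flip_fraction"], s["weaken_fraction"], s["loop_loss_fraction"],
            seed, comp_factor=int(g["comp_factor"]), tad_factor=int(g["tad_factor"]),
            alpha=s["alpha"], rho=s["rho"], tau=s["tau"],
            loop_boost=s["loop_boost"], depth=s["depth"])
        truth.to_json(out_dir / "truth.json")
        spec.to_json(out_dir / "genome.json")
        mats = {c: syn.sample_contact_matrix(truth, c, seed) for c in (1, 2)}
        tracks = {c: syn.generate_marker_tracks(truth, s["snr"], seed, condition=c)
                  for c in (1, 2)}
        genes = syn.generate_gene_table(truth, int(s["n_genes"]), s["de_effect"], seed)
        for c in (1, 2):
            write_triplets(mats[c], out_dir / f"contacts_cond{c}.txt")
            for mark, per_chrom in tracks[c].items():
                path = out_dir / f"{mark}_cond{c}.bedgraph"
                for k, (chrom, _) in enumerate(spec.chromosomes):
                    write_bedgraph(per_chrom[chrom], path, append=k > 0)
        syn.write_gene_table(genes, out_dir / "genes.tsv")
        manifest["stages"].append(stage)

        # per-condition calls
        profiles: dict[int, dict[str, comp_mod.CompartmentProfile]] = {1: {}, 2: {}}
        tadsets: dict[int, dict[str, tad_mod.TADSet]] = {1: {}, 2: {}}
        loopsets: dict[int, dict[str, loop_mod.LoopSet]] = {1: {}, 2: {}}
        cf, tf = int(g["comp_factor"]), int(g["tad_factor"])
        for c in (1, 2):
            for chrom, n in spec.chromosomes:
                raw = mats[c][chrom]
                stage = f"balance/cond{c}/{chrom}"
                kr_fine = kr_balance(raw, **p["kr"])
                stage = f"compartments/cond{c}/{chrom}"
                raw_comp = raw.coarsen(cf)
                act = [tracks[c][m][chrom].coarsen(cf) for m in syn.ACTIVE_MARKS]
                ina = [tracks[c][m][chrom].coarsen(cf) for m in syn.INACTIVE_MARKS]
                profiles[c][chrom] = comp_mod.call_compartments(
                    raw_comp, act, ina,
                    kr_tol=p["kr"]["tol"], kr_max_iter=p["kr"]["max_iter"],
                    mask_percentile=p["kr"]["mask_percentile"],
                    ambiguity_threshold=p["compartments"]["ambiguity_threshold"])
                stage = f"tads/cond{c}/{chrom}"
                kr_tad = kr_balance(raw.coarsen(tf), **p["kr"])
                tadsets[c][chrom] = tad_mod.call_tads(
                    kr_tad, w=p["tads"]["w"], span=p["tads"]["span"],
                    min_depth=p["tads"]["min_depth"])
                stage = f"loops/cond{c}/{chrom}"
                loopsets[c][chrom] = loop_mod.call_loops(
                    kr_fine, fdr=p["loops"]["fdr"], min_sep=p["loops"]["min_sep"],
                    r_inner=p["loops"]["r_inner"], r_outer=p["loops"]["r_outer"],
                    oe_threshold=p["loops"]["oe_threshold"],
                    ll_threshold=p["loops"]["ll_threshold"],
                    max_sep=p["loops"]["max_sep"])
            # write per-condition outputs
            prof_path = out_dir / f"compartments_cond{c}.tsv"
            dom_path = out_dir / f"tads_cond{c}.bed"
            bnd_path = out_dir / f"boundaries_cond{c}.bed"
            loop_path = out_dir / f"loops_cond{c}.bedpe"
            for k, (chrom, _) in enumerate(spec.chromosomes):
                profiles[c][chrom].write_tsv(prof_path, append=k > 0)
                tadsets[c][chrom].write_domains_bed(dom_path, append=k > 0)
                tadsets[c][chrom].write_boundaries_bed(bnd_path, append=k > 0)
                loopsets[c][chrom].write_bedpe(loop_path, append=k > 0)

        # 3D models at compartment resolution
        stage = "model3d"
        m3p = p["model3d"]
        confs = {}
        for c in (1, 2):
            chain_lengths = [(chrom, n // cf) for chrom, n in spec.chromosomes]
            degree = np.concatenate([profiles[c][chrom].degree
                                     for chrom, _ in spec.chromosomes])
            targets = m3d.radial_targets(degree, m3p["R"])
            conf = m3d.optimize_conformation(
                chain_lengths, targets, R=m3p["R"], bond_length=m3p["bond_length"],
                n_steps=int(m3p["n_steps"]), seed=seed, k_b=m3p["k_b"],
                k_r=m3p["k_r"], k_rep=m3p["k_rep"],
                n_restarts=int(m3p["n_restarts"]))
            conf.write_xyz(out_dir / f"conformation_cond{c}.xyz")
            confs[c] = conf

        # cross-condition comparisons
        stage = "compare"
        reports = {chrom: comp_mod.classify_switches(profiles[1][chrom], profiles[2][chrom])
                   for chrom, _ in spec.chromosomes}
        sw_path = out_dir / "switches.tsv"
        for k, (chrom, _) in enumerate(spec.chromosomes):
            reports[chrom].write(sw_path, append=k > 0)
        genome_pct = comp_mod.combine_reports(reports)
        bcounts = {k: 0 for k in ("stronger", "unchanged", "weaker", "lost", "gained")}
        bframes = []
        for chrom, _ in spec.chromosomes:
            cmp_df = tad_mod.compare_boundaries(
                tadsets[1][chrom], tadsets[2][chrom],
                match_slack=p["tads"]["match_slack"],
                change_threshold=p["tads"]["change_threshold"])
            cmp_df.insert(0, "chrom", chrom)
            bframes.append(cmp_df)
            for k, v in tad_mod.boundary_class_counts(cmp_df).items():
                bcounts[k] += v
        pd.concat(bframes, ignore_index=True).to_csv(
            out_dir / "boundary_comparison.tsv", sep="\t", index=False)
        loop_cmp = {"n_shared": 0, "n_lost": 0, "n_gained": 0, "n_1": 0, "n_2": 0}
        for chrom, _ in spec.chromosomes:
            cc = loop_mod.compare_loops(loopsets[1][chrom], loopsets[2][chrom],
                                        slack=p["loops"]["compare_slack"])
            for k in loop_cmp:
                loop_cmp[k] += cc[k]
        tstats = {c: [tad_mod.tad_stats(tadsets[c][ch]) for ch, _ in spec.chromosomes]
                  for c in (1, 2)}

        # integrate expression with switching
        stage = "integrate"
        annotated = int_mod.annotate_genes(genes, reports)
        fc = int_mod.fold_change_by_class(annotated)
        cands, discord = int_mod.candidate_genes(annotated)
        venn = int_mod.venn_counts(annotated)
        annotated.to_csv(out_dir / "genes_annotated.tsv", sep="\t", index=False)
        cands.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
        discord.to_csv(out_dir / "discordant.tsv", sep="\t", index=False)

        summary = {
            "switch_percent": genome_pct,
            "switched_fraction": (genome_pct["A->B"] + genome_pct["B->A"]) / 100,
            "boundary_classes": bcounts,
            "tad_stats": {str(c): {"n_domains": int(sum(n for n, _ in tstats[c])),
                                   "mean_size_mb": float(np.mean([m for _, m in tstats[c]]))}
                          for c in (1, 2)},
            "loops": loop_cmp,
            "compactness": {str(c): m3d.compactness_score(confs[c]) for c in (1, 2)},
            "fold_change_by_class": fc,
            "venn": venn,
            "n_candidates": int(len(cands)),
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"].append("complete")
    except ChromarchError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
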