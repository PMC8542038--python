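"""Join gene expression with compartment switching.

Genes are assigned to the compartment bin containing their midpoint and
inherit that bin's switch class. The analysis then asks two questions the
switch model makes directional predictions about: (i) do genes in A->B bins
lose expression and B->A bins gain it (fold-change by class, rank test), and
(ii) which differentially expressed genes are candidates for regulation by
compartment switching (DE genes in switched bins whose direction is
concordant with the switch: down with A->B, up with B->A). Discordant DE
genes in switched bins are reported separately so the positional-overlap-only
convention remains recoverable.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ParameterError
from .compartments import SwitchReport

PSEUDOCOUNT = 0.01  # FPKM; avoids infinite fold changes at zero expression


def annotate_genes(genes: pd.DataFrame,
                   reports: dict[str, SwitchReport]) -> pd.DataFrame:
    """Attach bin assignment, log2 fold change and switch class to each gene.

    ``genes`` needs columns gene, chrom, start, end, fpkm_wt, fpkm_ko (plus
    optional de_flag). Returns a copy with added columns ``assigned_bin``
    (midpoint bin on the switch-report grid), ``log2fc`` (pseudocounted) and
    ``switch_class`` ("masked" for genes in masked bins).
    """
    required = {"gene", "chrom", "start", "end", "fpkm_wt", "fpkm_ko"}
    missing = required - set(genes.columns)
    if missing:
        raise ParameterError(f"gene table missing columns: {sorted(missing)}")
    out = genes.copy()
    bins = np.empty(len(out), dtype=int)
    classes = np.empty(len(out), dtype=object)
    for idx, row in enumerate(out.itertuples()):
        rep = reports.get(row.chrom)
        if rep is None:
            raise AlignmentError(f"no switch report for chromosome {row.chrom!r}")
        mid = (int(row.start) + int(row.end)) // 2
        b = mid // rep.bin_size
        if not 0 <= b < rep.classes.size:
            raise AlignmentError(
                f"gene {row.gene}: midpoint bin {b} outside {row.chrom} "
                f"({rep.classes.size} bins)")
        bins[idx] = b
        classes[idx] = rep.classes[b]
    out["assigned_bin"] = bins
    out["switch_class"] = classes
    out["log2fc"] = np.log2((out["fpkm_ko"] + PSEUDOCOUNT)
                            / (out["fpkm_wt"] + PSEUDOCOUNT))
    return out


def fold_change_by_class(genes: pd.DataFrame) -> dict:
    """Per-switch-class log2FC summary plus an A->B vs B->A rank test.

    Classes with no genes are reported with n = 0. The two-sided
    Mann-Whitney U test compares A->B against B->A log2FC distributions; the
    test name is recorded alongside the p-value.
    """
    if "switch_class" not in genes.columns or "log2fc" not in genes.columns:
        raise ParameterError("gene table must be annotated first (annotate_genes)")
    classes = ("stable_A", "stable_B", "A->B", "B->A", "masked")
    summary: dict = {"classes": {}}
    for k in classes:
        v = genes.loc[genes["switch_class"] == k, "log2fc"].to_numpy()
        entry = {"n": int(v.size)}
        if v.size:
            q1, q3 = np.percentile(v, [25, 75])
            entry.update(median=float(np.median(v)), mean=float(v.mean()),
                         iqr=float(q3 - q1))
        summary["classes"][k] = entry
    a2b = genes.loc[genes["switch_class"] == "A->B", "log2fc"].to_numpy()
    b2a = genes.loc[genes["switch_class"] == "B->A", "log2fc"].to_numpy()
    if a2b.size and b2a.size:
        res = stats.mannwhitneyu(a2b, b2a, alternative="two-sided")
        summary["test"] = {"name": "Mann-Whitney U (two-sided)",
                           "statistic": float(res.statistic),
                           "p_value": float(res.pvalue)}
    else:
        summary["test"] = None
    return summary


def candidate_genes(genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Switch-modulated DE candidates and the discordant remainder.

    Candidates: de_flag != ns, switch_class in {A->B, B->A}, and direction
    concordant with the switch (down with A->B, up with B->A). The second
    frame holds DE genes in switched bins whose direction is discordant.
    DE genes in stable or masked bins are excluded from both.
    """
    for col in ("de_flag", "switch_class"):
        if col not in genes.columns:
            raise ParameterError(f"gene table missing column {col!r}")
    de = genes["de_flag"].isin(("up", "down"))
    switched = genes["switch_class"].isin(("A->B", "B->A"))
    concordant = ((genes["de_flag"] == "down") & (genes["switch_class"] == "A->B")) | \
                 ((genes["de_flag"] == "up") & (genes["switch_class"] == "B->A"))
    cands = genes[de & switched & concordant].copy()
    discord = genes[de & switched & ~concordant].copy()
    return cands, discord


def venn_counts(genes: pd.DataFrame) -> dict[str, int]:
    """DE-only / switch-only / overlap gene counts (positional overlap)."""
    de = genes["de_flag"].isin(("up", "down"))
    sw = genes["switch_class"].isin(("A->B", "B->A"))
    return {"de_only": int((de & ~sw).sum()),
            "switch_only": int((~de & sw).sum()),
            "overlap": int((de & sw).sum())}


def degree_change_correlation(genes: pd.DataFrame,
                              degree_wt: dict[str, np.ndarray],
                              degree_ko: dict[str, np.ndarray]) -> dict:
    """Spearman correlation of gene log2FC with its bin's degree change.

    ``degree_wt`` / ``degree_ko`` map chromosome to per-bin compartment
    degree on the same grid genes were annotated on. The switch model
    predicts a positive correlation: bins moving toward A (degree up) carry
    genes whose expression rises.
    """
    dch = []
    lfc = []
    for row in genes.itertuples():
        dw = degree_wt.get(row.chrom)
        dk = degree_ko.get(row.chrom)
        if dw is None or dk is None:
            continue
        b = int(row.assigned_bin)
        if np.isfinite(dw[b]) and np.isfinite(dk[b]):
            dch.append(dk[b] - dw[b])
            lfc.append(row.log2fc)
    if len(dch) < 3:
        raise ParameterError("too few genes with defined degree change")
    rho, p = stats.spearmanr(dch, lfc)
    return {"spearman_rho": float(rho), "p_value": float(p), "n": len(dch)}


def write_class_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
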