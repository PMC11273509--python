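"""Hybrid-generation classification from diagnostic-locus ratios.

Each offspring is summarised over the generation panel by three ratios:
the fraction of genotyped panel loci that are heterozygous (het_ratio),
homozygous for the sire-diagnostic allele (paternal_ratio, PGL), or
homozygous for the dam-diagnostic allele (maternal_ratio, MGL).  An F1
from fully divergent founders is heterozygous everywhere, so het_ratio
near 1 flags F1; F2 offspring (backcross or intercross) drop to ~0.5 and
split into four subclasses by their maternal/paternal balance:

* F1   — het_ratio > 0.5
* MSF2 — F2 with strong paternal character (paternal_ratio > 0.5)
* MDF2 — F2 with strong maternal character (maternal_ratio > 0.5)
* LSF2 — F2 leaning paternal (paternal_ratio >= maternal_ratio)
* LDF2 — F2 leaning maternal (maternal_ratio > paternal_ratio)

An exact maternal/paternal tie goes to LSF2 and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SNPPanel, TruePedigree

__all__ = [
    "OffspringRatios",
    "GENERATION_LABELS",
    "compute_ratios",
    "compute_ratios_table",
    "classify_generation",
    "evaluate_against_truth",
    "ratio_scatter_plot",
]

GENERATION_LABELS = ("F1", "MSF2", "MDF2", "LSF2", "LDF2")


@dataclass
class OffspringRatios:
    """Per-offspring diagnostic-locus summary over a generation panel."""

    sample_id: str
    n_genotyped: int
    het_ratio: float
    maternal_ratio: float
    paternal_ratio: float


class UndefinedRatiosError(ValueError):
    """All panel loci missing for an offspring: ratios are undefined."""


def _panel_counts(matrix: GenotypeMatrix, panel: SNPPanel, offspring_ids: list[str]):
    if panel.kind != "generation":
        raise ValueError("compute_ratios requires a generation panel")
    g = matrix.genotypes[np.ix_(matrix.sample_idx(offspring_ids),
                                matrix.locus_idx(panel.locus_ids))]
    called = g != MISSING
    n_genotyped = called.sum(axis=1)
    het = (g == 1).sum(axis=1)
    pgl = (g == 2 * panel.sire_allele[None, :]).sum(axis=1)
    mgl = (g == 2 * panel.dam_allele[None, :]).sum(axis=1)
    return n_genotyped, het, pgl, mgl


def compute_ratios(matrix: GenotypeMatrix, panel: SNPPanel, offspring_id: str) -> OffspringRatios:
    """Heterozygous / paternal / maternal ratios for one offspring.

    Ratios are counts over the non-missing panel calls; a heterozygous call
    counts toward het, a homozygote matching the sire-diagnostic allele
    toward PGL, one matching the dam-diagnostic allele toward MGL.  For a
    biallelic panel these three classes partition the called loci.
    """
    n_genotyped, het, pgl, mgl = _panel_counts(matrix, panel, [offspring_id])
    n = int(n_genotyped[0])
    if n == 0:
        raise UndefinedRatiosError(f"no genotyped panel loci for {offspring_id}")
    return OffspringRatios(
        sample_id=offspring_id,
        n_genotyped=n,
        het_ratio=float(het[0]) / n,
        paternal_ratio=float(pgl[0]) / n,
        maternal_ratio=float(mgl[0]) / n,
    )


def compute_ratios_table(matrix: GenotypeMatrix, panel: SNPPanel,
                         offspring_ids: list[str]) -> pd.DataFrame:
    """Vectorised ratios for many offspring, with generation labels attached.

    Offspring with zero genotyped panel loci get NaN ratios and label
    ``unclassified``.
    """
    n_genotyped, het, pgl, mgl = _panel_counts(matrix, panel, offspring_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(n_genotyped > 0, n_genotyped, np.nan).astype(float)
        df = pd.DataFrame({
            "sample_id": offspring_ids,
            "n_genotyped": n_genotyped,
            "het_ratio": het / denom,
            "paternal_ratio": pgl / denom,
            "maternal_ratio": mgl / denom,
        })
    labels = []
    for _, row in df.iterrows():
        if row["n_genotyped"] == 0:
            labels.append("unclassified")
        else:
            labels.append(classify_generation(OffspringRatios(
                sample_id=row["sample_id"], n_genotyped=int(row["n_genotyped"]),
                het_ratio=row["het_ratio"], paternal_ratio=row["paternal_ratio"],
                maternal_ratio=row["maternal_ratio"])))
    df["label"] = labels
    return df


def classify_generation(ratios: OffspringRatios) -> str:
    """Assign one of F1 / MSF2 / MDF2 / LSF2 / LDF2 from the ratios.

    het_ratio > 0.5 (strict) → F1; otherwise F2, subdivided by the
    maternal/paternal balance.  A het_ratio of exactly 0.5 is F2; an exact
    maternal/paternal tie within F2 goes to LSF2.
    """
    if ratios.het_ratio > 0.5:
        return "F1"
    if ratios.paternal_ratio > 0.5:
        return "MSF2"
    if ratios.maternal_ratio > 0.5:
        return "MDF2"
    if ratios.paternal_ratio >= ratios.maternal_ratio:  # tie → LSF2 (flagged upstream)
        return "LSF2"
    return "LDF2"


def evaluate_against_truth(labels: pd.DataFrame | dict, truth) -> dict:
    """Compare predicted generation labels with the ground truth.

    ``labels`` maps sample_id → label (or is a DataFrame with sample_id and
    label columns).  ``truth`` is a :class:`TruePedigree` (gives F1-vs-F2
    truth) or a mapping sample_id → label; if the truth labels are already
    5-way subclass names the 5-way accuracy is also computed.  Returns
    collapsed (F1-vs-F2) and, where defined, 5-way accuracy plus confusion
    matrices.
    """
    if isinstance(labels, pd.DataFrame):
        pred = dict(zip(labels["sample_id"], labels["label"]))
    else:
        pred = dict(labels)
    if isinstance(truth, TruePedigree):
        true_raw = {r["id"]: r["generation"] for _, r in truth.df.iterrows()
                    if r["role"] == "offspring"}
    else:
        true_raw = dict(truth)
    common = sorted(set(pred) & set(true_raw))
    if not common:
        raise ValueError("no overlapping sample ids between labels and truth")

    def collapse(lab: str) -> str:
        return "F1" if lab == "F1" else "F2"

    pred_c = [collapse(pred[s]) for s in common]
    true_c = [collapse(true_raw[s]) for s in common]
    collapsed_acc = float(np.mean([p == t for p, t in zip(pred_c, true_c)]))
    confusion_collapsed = pd.crosstab(
        pd.Series(true_c, name="truth"), pd.Series(pred_c, name="predicted"))

    out = {
        "n_evaluated": len(common),
        "accuracy_f1_vs_f2": collapsed_acc,
        "confusion_f1_vs_f2": confusion_collapsed,
        "accuracy_5way": None,
        "confusion_5way": None,
    }
    if all(true_raw[s] in GENERATION_LABELS for s in common):
        pred_5 = [pred[s] for s in common]
        true_5 = [true_raw[s] for s in common]
        out["accuracy_5way"] = float(np.mean([p == t for p, t in zip(pred_5, true_5)]))
        out["confusion_5way"] = pd.crosstab(
            pd.Series(true_5, name="truth"), pd.Series(pred_5, name="predicted"))
    return out


def ratio_scatter_plot(table: pd.DataFrame, path) -> None:
    """Scatter of paternal vs maternal ratio, coloured by assigned label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, sub in table.groupby("label"):
        ax.scatter(sub["paternal_ratio"], sub["maternal_ratio"], s=12, label=label, alpha=0.7)
    ax.set_xlabel("paternal ratio (PGL fraction)")
    ax.set_ylabel("maternal ratio (MGL fraction)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
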