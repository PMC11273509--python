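"""Classify offspring into F1 and the four F2 subclasses; score against truth.

Computes heterozygous/paternal/maternal ratios per offspring over the
generation panel, assigns the five-way label, reports the label counts and
the F1-vs-F2 accuracy against the simulated pedigree, and draws the
paternal-vs-maternal scatter.
"""

from common import HERD_DIR, RESULTS

from crosskin import generations
from crosskin.containers import SNPPanel, TruePedigree
from crosskin.variants import read_vcf


def main() -> None:
    _, matrix = read_vcf(HERD_DIR / "herd.vcf")
    ped = TruePedigree.read_tsv(HERD_DIR / "pedigree_truth.tsv")
    panel = SNPPanel.read_tsv(RESULTS / "generation_panel.tsv")

    table = generations.compute_ratios_table(matrix, panel, ped.offspring_ids)
    table.to_csv(RESULTS / "generation_ratios.tsv", sep="\t", index=False)
    generations.ratio_scatter_plot(table, RESULTS / "generation_scatter.png")

    print("label counts:")
    print(table["label"].value_counts().to_string())
    ev = generations.evaluate_against_truth(table, ped)
    print(f"\nF1-vs-F2 accuracy vs pedigree truth: {ev['accuracy_f1_vs_f2']:.3f} "
          f"({ev['n_evaluated']} offspring)")
    print(ev["confusion_f1_vs_f2"].to_string())
    print("\nnote: backcross/intercross F2 het ratios straddle 0.5, so some F2")
    print("land in the F1 class even without genotyping error.")


if __name__ == "__main__":
    main()
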