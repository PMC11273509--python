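"""Pairwise relatedness on the herd: PI_HAT bands, kinship, NJ tree.

Checks that method-of-moments PI_HAT reproduces the expected bands for
known relationships in the simulated pedigree (parent-offspring ~0.5,
half-sib ~0.25, unrelated founders ~0), writes the doubled centered-IBS
kinship matrix, and builds a neighbor-joining tree from p-distances for
founders plus a subset of offspring.
"""

import itertools

from common import HERD_DIR, RESULTS

from crosskin import relatedness
from crosskin.containers import SNPPanel, TruePedigree
from crosskin.variants import read_vcf


def main() -> None:
    _, matrix = read_vcf(HERD_DIR / "herd.vcf")
    ped = TruePedigree.read_tsv(HERD_DIR / "pedigree_truth.tsv")
    panel = SNPPanel.read_tsv(RESULTS / "parentage_panel.tsv")

    f1 = ped.df.query("generation == 'F1'")["id"].tolist()
    po_pairs = [(oid, ped.parents_of(oid)[0]) for oid in f1[:50]]
    by_sire: dict[str, list[str]] = {}
    for oid in f1:
        by_sire.setdefault(ped.parents_of(oid)[0], []).append(oid)
    hs_pairs = [tuple(kids[:2]) for kids in by_sire.values() if len(kids) >= 2][:50]
    unrel_pairs = list(itertools.islice(
        ((a, b) for a, b in itertools.combinations(ped.sire_ids, 2)), 50))

    for name, pairs in [("parent-offspring", po_pairs),
                        ("half-sib", hs_pairs),
                        ("unrelated sires", unrel_pairs)]:
        df = relatedness.ibd_pihat(matrix, panel=panel, pairs=pairs)
        print(f"mean PI_HAT {name:>17}: {df['PI_HAT'].mean():.3f} "
              f"(n={len(pairs)} pairs)")
        df.to_csv(RESULTS / f"pihat_{name.split()[0].replace('-', '_')}.tsv",
                  sep="\t", index=False)

    subset = ped.sire_ids + ped.dam_ids + f1[:40]
    sub = matrix.subset_samples(subset)
    kin = relatedness.centered_ibs_kinship(sub, times_two=True,
                                           locus_ids=panel.locus_ids)
    kin.write_tsv(RESULTS / "kinship_x2.tsv")
    dist = relatedness.p_distance(sub, locus_ids=panel.locus_ids)
    tree = relatedness.neighbor_joining(dist)
    (RESULTS / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    print(f"\nkinship (x2) and NJ tree written for {len(subset)} samples")


if __name__ == "__main__":
    main()
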