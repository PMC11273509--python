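"""Assign F1 parentage by likelihood, Mendelian transmission, and exclusion.

Runs all three engines on the F1 offspring against the founder sires and
dams, intersects likelihood and transmission calls into the consensus
pedigree, and scores every method against the simulated truth.  The Delta
critical values use 2,000 simulated offspring (a desk-scale choice; the
other simulation conditions follow the documented defaults).
"""

import json

import numpy as np
from common import HERD_DIR, RESULTS, SEED

from crosskin import parentage
from crosskin.containers import SNPPanel, TruePedigree
from crosskin.variants import read_vcf


def main() -> None:
    _, matrix = read_vcf(HERD_DIR / "herd.vcf")
    ped = TruePedigree.read_tsv(HERD_DIR / "pedigree_truth.tsv")
    panel = SNPPanel.read_tsv(RESULTS / "parentage_panel.tsv")
    f1 = ped.df.query("generation == 'F1'")["id"].tolist()
    true_sire = {oid: ped.parents_of(oid)[0] for oid in f1}

    params = parentage.LikelihoodSimulationParams(n_simulated_offspring=2000)
    lik = parentage.assign_likelihood(matrix, panel, f1, ped.sire_ids,
                                      params, seed=SEED)
    apis = parentage.assign_apis(matrix, panel, f1, ped.sire_ids, ped.dam_ids)
    excl = parentage.assign_exclusion(matrix, panel, f1, ped.sire_ids, ped.dam_ids)

    def acc(mapping):
        return float(np.mean([true_sire[o] == s for o, s in mapping.items()]))

    lik_map = {s.offspring_id: s.sire_id for s in lik if s.sire_id}
    apis_map = {a.offspring_id: a.best_pair[0] for a in apis}
    excl_map = {e.offspring_id: e.best["sire_id"] for e in excl}
    agreed, report = parentage.consensus(lik, apis)
    venn = parentage.venn_counts(
        {"likelihood": lik, "apis": apis, "exclusion": excl})

    n_strict = sum(s.confidence == "strict" for s in lik)
    print(f"likelihood: accuracy {acc(lik_map):.3f}, "
          f"{n_strict}/{len(lik)} strict-confidence")
    print(f"apis:       accuracy {acc(apis_map):.3f}, "
          f"{sum(a.accepted for a in apis)}/{len(apis)} accepted")
    print(f"exclusion:  accuracy {acc(excl_map):.3f}")
    print(f"consensus:  {report['n_agree']} agreements "
          f"({report['n_disagree']} disagreements), accuracy {acc(agreed):.3f}")
    print(f"venn: {venn}")

    rows = [{"offspring": o, "sire": s, "true_sire": true_sire[o]}
            for o, s in sorted(agreed.items())]
    import pandas as pd

    pd.DataFrame(rows).to_csv(RESULTS / "consensus_assignments.tsv",
                              sep="\t", index=False)
    (RESULTS / "parentage_venn.json").write_text(json.dumps(venn, indent=2) + "\n")


if __name__ == "__main__":
    main()
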