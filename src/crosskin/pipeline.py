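"""End-to-end pipeline: simulate → filter → panels → classify → relate → assign.

A single config (YAML or constructed in code) drives every stage with the
printed defaults of the study workflow; one global seed propagates to all
stochastic stages.  Each run writes its stage outputs plus a provenance
manifest (parameters and SHA-256 of every output file) so that reruns with
the same config are byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import generations, parentage, relatedness, synth, variants
from .containers import GenotypeMatrix, SNPPanel, TruePedigree

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in args[0]."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(stage, cause)
        self.stage = stage
        self.cause = cause

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"stage {self.stage!r} failed: {self.cause}"


@dataclass
class PipelineConfig:
    """All stage toggles and parameters, with the study defaults."""

    out_dir: str = "crosskin_run"
    seed: int = 0
    # Inputs: either an existing VCF + founder lists, or a simulation.
    vcf: str | None = None
    sires_file: str | None = None
    dams_file: str | None = None
    pedigree_file: str | None = None  # optional truth for evaluation
    # Stage toggles.
    simulate: bool = True
    apply_hard_filter: bool = False  # GATK-style site thresholds suit real call sets
    build_panels: bool = True
    classify: bool = True
    relate: bool = True
    assign: bool = True
    # Stage parameters.
    simulation: dict = field(default_factory=dict)
    hard_filter: dict = field(default_factory=dict)
    generation_panel: dict = field(default_factory=dict)
    parentage_panel: dict = field(default_factory=dict)
    likelihood: dict = field(default_factory=dict)
    apis_accepted_error_rate: float = 0.05
    relate_max_samples: int = 100

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_id_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "metrics": {}}
    rng_seed = int(config.seed)

    # --- inputs ------------------------------------------------------------
    truth_pedigree: TruePedigree | None = None
    try:
        if config.simulate:
            sim_cfg = synth.SimulationConfig(**{"seed": rng_seed, **config.simulation})
            sim = synth.simulate_population(sim_cfg)
            vcf_path = out / "simulated.vcf"
            ped_path = out / "pedigree_truth.tsv"
            synth.write_vcf(sim.observed, vcf_path)
            synth.write_pedigree(sim.pedigree, ped_path)
            truth_pedigree = sim.pedigree
            manifest["stages"]["simulate"] = dataclasses.asdict(
                dataclasses.replace(sim_cfg,
                                    sire_allele_freq_dist=None, dam_allele_freq_dist=None))
            manifest["outputs"]["simulated.vcf"] = _sha256(vcf_path)
            manifest["outputs"]["pedigree_truth.tsv"] = _sha256(ped_path)
        else:
            if config.vcf is None:
                raise ValueError("either enable simulate or provide a VCF path")
            vcf_path = Path(config.vcf)
            if config.pedigree_file:
                truth_pedigree = TruePedigree.read_tsv(config.pedigree_file)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        records, matrix = variants.read_vcf(vcf_path)
        if truth_pedigree is not None:
            sire_ids = truth_pedigree.sire_ids
            dam_ids = truth_pedigree.dam_ids
            offspring_ids = truth_pedigree.offspring_ids
        else:
            if config.sires_file is None or config.dams_file is None:
                raise ValueError("founder id lists required when no pedigree is given")
            sire_ids = _read_id_list(config.sires_file)
            dam_ids = _read_id_list(config.dams_file)
            founders = set(sire_ids) | set(dam_ids)
            offspring_ids = [s for s in matrix.sample_ids if s not in founders]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("read_vcf", exc) from exc

    # --- hard filter -------------------------------------------------------
    if config.apply_hard_filter:
        try:
            th = variants.HardFilterThresholds(**config.hard_filter)
            records, counts = variants.hard_filter(records, th)
            matrix = matrix.subset_loci([r.locus_id for r in records])
            manifest["stages"]["hard_filter"] = {
                "thresholds": dataclasses.asdict(th), "counts": counts}
        except Exception as exc:
            raise StageError("hard_filter", exc) from exc

    biallelic = np.array([r.is_biallelic for r in records], dtype=bool)

    # --- panels ------------------------------------------------------------
    gen_panel: SNPPanel | None = None
    par_panel: SNPPanel | None = None
    if config.build_panels:
        try:
            gen_panel = variants.select_generation_panel(
                matrix, sire_ids, dam_ids, biallelic_mask=biallelic,
                **config.generation_panel)
            par_panel = variants.select_parentage_panel(
                matrix, sire_ids, biallelic_mask=biallelic, **config.parentage_panel)
            gen_panel.write_tsv(out / "generation_panel.tsv")
            par_panel.write_tsv(out / "parentage_panel.tsv")
            manifest["stages"]["panels"] = {
                "generation_loci": gen_panel.n_loci, "parentage_loci": par_panel.n_loci}
            manifest["outputs"]["generation_panel.tsv"] = _sha256(out / "generation_panel.tsv")
            manifest["outputs"]["parentage_panel.tsv"] = _sha256(out / "parentage_panel.tsv")
        except Exception as exc:
            raise StageError("panels", exc) from exc

    # --- classification ----------------------------------------------------
    if config.classify and gen_panel is not None:
        try:
            table = generations.compute_ratios_table(matrix, gen_panel, offspring_ids)
            table.to_csv(out / "generation_ratios.tsv", sep="\t", index=False)
            manifest["outputs"]["generation_ratios.tsv"] = _sha256(out / "generation_ratios.tsv")
            if truth_pedigree is not None:
                ev = generations.evaluate_against_truth(table, truth_pedigree)
                manifest["metrics"]["classification_accuracy_f1_vs_f2"] = ev["accuracy_f1_vs_f2"]
                manifest["metrics"]["classification_n_evaluated"] = ev["n_evaluated"]
        except Exception as exc:
            raise StageError("classify", exc) from exc

    # --- relatedness -------------------------------------------------------
    if config.relate and par_panel is not None:
        try:
            subset_ids = (sire_ids + dam_ids + offspring_ids)[: config.relate_max_samples]
            sub = matrix.subset_samples(subset_ids)
            kin = relatedness.centered_ibs_kinship(sub, times_two=True,
                                                   locus_ids=par_panel.locus_ids)
            kin.write_tsv(out / "kinship.tsv")
            dist = relatedness.p_distance(sub, locus_ids=par_panel.locus_ids)
            dist.write_tsv(out / "p_distance.tsv")
            tree = relatedness.neighbor_joining(dist)
            (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
            for name in ("kinship.tsv", "p_distance.tsv", "nj_tree.nwk"):
                manifest["outputs"][name] = _sha256(out / name)
            manifest["stages"]["relate"] = {"n_samples": len(subset_ids)}
        except Exception as exc:
            raise StageError("relate", exc) from exc

    # --- parentage ---------------------------------------------------------
    if config.assign and par_panel is not None:
        try:
            params = parentage.LikelihoodSimulationParams(**config.likelihood)
            lik = parentage.assign_likelihood(
                matrix, par_panel, offspring_ids, sire_ids, params, seed=rng_seed)
            apis = parentage.assign_apis(
                matrix, par_panel, offspring_ids, sire_ids, dam_ids,
                accepted_error_rate=config.apis_accepted_error_rate)
            excl = parentage.assign_exclusion(
                matrix, par_panel, offspring_ids, sire_ids, dam_ids)
            agreed, report = parentage.consensus(lik, apis)
            venn = parentage.venn_counts(
                {"likelihood": lik, "apis": apis, "exclusion": excl})

            rows = []
            apis_by_id = {a.offspring_id: a for a in apis}
            excl_by_id = {e.offspring_id: e for e in excl}
            for s in lik:
                a = apis_by_id[s.offspring_id]
                e = excl_by_id[s.offspring_id]
                rows.append({
                    "offspring": s.offspring_id,
                    "sire_likelihood": s.sire_id, "LOD": s.lod, "Delta": s.delta,
                    "confidence": s.confidence,
                    "sire_apis": a.best_pair[0], "dam_apis": a.best_pair[1],
                    "mendel1": a.mendel1, "delta1": a.delta1, "apis_accepted": a.accepted,
                    "sire_exclusion": e.best["sire_id"], "mismatches": e.best["mismatches"],
                    "consensus_sire": agreed.get(s.offspring_id, ""),
                })
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
            (out / "venn.json").write_text(json.dumps(venn, indent=2) + "\n")
            manifest["outputs"]["assignments.tsv"] = _sha256(out / "assignments.tsv")
            manifest["outputs"]["venn.json"] = _sha256(out / "venn.json")
            manifest["stages"]["assign"] = {"consensus": report}
            if truth_pedigree is not None:
                true_sires = {oid: truth_pedigree.parents_of(oid)[0] for oid in offspring_ids}
                lik_ok = [s for s in lik if s.sire_id is not None]
                if lik_ok:
                    acc = float(np.mean([true_sires[s.offspring_id] == s.sire_id
                                         for s in lik_ok]))
                    manifest["metrics"]["likelihood_sire_accuracy"] = acc
        except Exception as exc:
            raise StageError("assign", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
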