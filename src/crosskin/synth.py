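"""Simulation of a two-breed crossbreeding herd with RAD-like genotyping noise.

Emulates the study design behind the pipeline: a divergent sire breed
(Angus-like) crossed to a divergent dam breed (Xiangxi-yellow-like),
producing F1 offspring (sire × dam), backcross F2 (F1 dam × founder sire)
and intercross F2 (F1 × F1).  Loci are unlinked autosomal biallelic SNPs.
A fraction of loci is fixed-divergent between breeds (alternative alleles
fixed in sires vs dams); the rest segregate at breed-specific frequencies.

The observation model mimics reduced-representation sequencing: per-call
read depth is Poisson, each read reports the wrong allele with a flip
probability, calls drop out at a missing rate or at zero depth, and the
genotype is the naive call from the sampled reads (both alleles seen →
heterozygous).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import MISSING, GenotypeMatrix, TruePedigree, PEDIGREE_COLUMNS

import pandas as pd

__all__ = [
    "SimulationConfig",
    "CrossPlanEntry",
    "FounderSim",
    "PopulationSim",
    "simulate_founders",
    "simulate_cross",
    "default_cross_plan",
    "simulate_population",
    "apply_observation_model",
    "write_vcf",
    "write_pedigree",
]


def _uniform_dist(lo: float, hi: float):
    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=n)

    return draw


@dataclass
class SimulationConfig:
    """Parameters of the crossbreeding-herd simulation.

    Defaults mirror the study herd: 24 sires, 28 dams, 923 offspring split
    into roughly 615 F1 and 308 F2 (the study's classified counts are used
    as an approximate split; the true herd proportions are unrecorded).
    ``mean_depth`` is mean reads per call; ``genotype_error_rate`` is the
    per-read allele flip probability; ``missing_rate`` is the extra per-call
    dropout probability on top of zero-depth dropout.
    """

    n_sires: int = 24
    n_dams: int = 28
    n_f1: int = 615
    n_f2_backcross: int = 246
    n_f2_intercross: int = 62
    n_loci: int = 7305
    frac_fixed_divergent: float = 0.3
    sire_allele_freq_dist: object = field(default_factory=lambda: _uniform_dist(0.05, 0.95))
    dam_allele_freq_dist: object = field(default_factory=lambda: _uniform_dist(0.05, 0.95))
    mean_depth: float = 12.0
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_sires=self.n_sires,
            n_dams=self.n_dams,
            n_f1=self.n_f1,
            n_f2_backcross=self.n_f2_backcross,
            n_f2_intercross=self.n_f2_intercross,
            n_loci=self.n_loci,
        )
        for name, v in counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        for name in ("frac_fixed_divergent", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if self.n_f1 > 0 and (self.n_sires == 0 or self.n_dams == 0):
            raise ValueError("F1 offspring require at least one sire and one dam")
        if self.n_f2_backcross > 0 and (self.n_f1 == 0 or self.n_sires == 0):
            raise ValueError("backcross F2 require F1 individuals and sires")
        if self.n_f2_intercross > 0 and self.n_f1 < 2:
            raise ValueError("intercross F2 require at least two F1 individuals")

    def scaled_for_tests(self) -> "SimulationConfig":
        """A desk-scale copy of the study design (same structure, small n)."""
        return replace(
            self,
            n_f1=60,
            n_f2_backcross=25,
            n_f2_intercross=6,
            n_loci=600,
        )


@dataclass(frozen=True)
class CrossPlanEntry:
    """One planned mating: offspring id plus its true sire and dam."""

    offspring_id: str
    sire_id: str
    dam_id: str
    generation: str  # "F1" | "F2"
    cross_type: str  # "sire_x_dam" | "backcross" | "intercross"


@dataclass
class FounderSim:
    """Founder genotypes plus the construction truth of the divergent loci."""

    matrix: GenotypeMatrix
    pedigree: TruePedigree
    divergent: np.ndarray  # bool per locus: fixed-divergent between breeds
    sire_fixed_allele: np.ndarray  # per locus, allele (0=ref/1=alt) fixed in sires
    # (only meaningful where divergent; orientation drawn per locus)


def _founder_pedigree(sire_ids: list[str], dam_ids: list[str]) -> TruePedigree:
    rows = [
        {"id": s, "role": "sire", "generation": "P", "sire_id": None, "dam_id": None,
         "cross_type": "none"}
        for s in sire_ids
    ] + [
        {"id": d, "role": "dam", "generation": "P", "sire_id": None, "dam_id": None,
         "cross_type": "none"}
        for d in dam_ids
    ]
    return TruePedigree(pd.DataFrame(rows, columns=PEDIGREE_COLUMNS))


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> FounderSim:
    """Draw founder genotypes for the two divergent breeds.

    At ``frac_fixed_divergent`` of the loci the breeds carry alternative
    fixed alleles (orientation drawn per locus and recorded); elsewhere each
    breed's genotypes are binomial draws from a breed-specific allele
    frequency sampled from its configured distribution.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci
    sire_ids = [f"S{i + 1:03d}" for i in range(config.n_sires)]
    dam_ids = [f"D{i + 1:03d}" for i in range(config.n_dams)]

    n_div = int(round(config.frac_fixed_divergent * n_loci))
    divergent = np.zeros(n_loci, dtype=bool)
    if n_div > 0:
        divergent[rng.choice(n_loci, size=n_div, replace=False)] = True

    # Orientation of fixation per divergent locus: which allele the sires carry.
    sire_fixed_allele = rng.integers(0, 2, size=n_loci).astype(np.int8)

    sire_alt_freq = np.asarray(config.sire_allele_freq_dist(rng, n_loci), dtype=float)
    dam_alt_freq = np.asarray(config.dam_allele_freq_dist(rng, n_loci), dtype=float)

    sires = rng.binomial(2, sire_alt_freq, size=(config.n_sires, n_loci)).astype(np.int8)
    dams = rng.binomial(2, dam_alt_freq, size=(config.n_dams, n_loci)).astype(np.int8)

    # Overwrite divergent loci with fixed alternative homozygotes.
    sires[:, divergent] = np.where(sire_fixed_allele[divergent] == 1, 2, 0)
    dams[:, divergent] = np.where(sire_fixed_allele[divergent] == 1, 0, 2)

    locus_ids = [f"L{i + 1:05d}" for i in range(n_loci)]
    matrix = GenotypeMatrix(
        sample_ids=sire_ids + dam_ids,
        locus_ids=locus_ids,
        genotypes=np.vstack([sires, dams]),
    )
    return FounderSim(
        matrix=matrix,
        pedigree=_founder_pedigree(sire_ids, dam_ids),
        divergent=divergent,
        sire_fixed_allele=sire_fixed_allele,
    )


def simulate_cross(
    founders: GenotypeMatrix,
    pedigree: TruePedigree,
    plan: list[CrossPlanEntry],
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, TruePedigree]:
    """Drop genotypes through a mating plan (gene-dropping, loci unlinked).

    At each locus the offspring receives one allele drawn uniformly from
    each parent's two alleles, independently across loci.  Parents may be
    founders or earlier offspring within the same plan (so F2 crosses that
    reference planned F1 ids are valid).  Returns the offspring matrix plus
    a pedigree covering founders and offspring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci = founders.n_loci
    pool: dict[str, np.ndarray] = {
        s: founders.genotypes[i] for i, s in enumerate(founders.sample_ids)
    }
    rows = []
    out = np.empty((len(plan), n_loci), dtype=np.int8)
    for k, entry in enumerate(plan):
        for pid in (entry.sire_id, entry.dam_id):
            if pid not in pool:
                raise KeyError(f"cross plan references unknown parent {pid!r}")
        g_sire = pool[entry.sire_id]
        g_dam = pool[entry.dam_id]
        if (g_sire == MISSING).any() or (g_dam == MISSING).any():
            raise ValueError("parents must have complete (non-missing) genotypes")
        allele_from_sire = (rng.random(n_loci) < g_sire / 2.0).astype(np.int8)
        allele_from_dam = (rng.random(n_loci) < g_dam / 2.0).astype(np.int8)
        child = allele_from_sire + allele_from_dam
        out[k] = child
        pool[entry.offspring_id] = child
        rows.append(
            {"id": entry.offspring_id, "role": "offspring", "generation": entry.generation,
             "sire_id": entry.sire_id, "dam_id": entry.dam_id, "cross_type": entry.cross_type}
        )
    matrix = GenotypeMatrix(
        sample_ids=[e.offspring_id for e in plan],
        locus_ids=list(founders.locus_ids),
        genotypes=out,
    )
    full_ped = TruePedigree.concat([pedigree, TruePedigree(pd.DataFrame(rows, columns=PEDIGREE_COLUMNS))])
    return matrix, full_ped


def default_cross_plan(config: SimulationConfig, rng: np.random.Generator) -> list[CrossPlanEntry]:
    """Random mating plan following the study design.

    F1 = founder sire × founder dam; backcross F2 = founder sire × F1 dam
    (Angus semen used on F1 cows); intercross F2 = F1 bull × F1 cow.
    """
    sire_ids = [f"S{i + 1:03d}" for i in range(config.n_sires)]
    dam_ids = [f"D{i + 1:03d}" for i in range(config.n_dams)]
    plan: list[CrossPlanEntry] = []
    f1_ids = []
    for i in range(config.n_f1):
        oid = f"F1_{i + 1:04d}"
        plan.append(CrossPlanEntry(oid, rng.choice(sire_ids), rng.choice(dam_ids),
                                   "F1", "sire_x_dam"))
        f1_ids.append(oid)
    for i in range(config.n_f2_backcross):
        oid = f"F2B_{i + 1:04d}"
        plan.append(CrossPlanEntry(oid, rng.choice(sire_ids), rng.choice(f1_ids),
                                   "F2", "backcross"))
    for i in range(config.n_f2_intercross):
        oid = f"F2I_{i + 1:04d}"
        a, b = rng.choice(len(f1_ids), size=2, replace=False)
        plan.append(CrossPlanEntry(oid, f1_ids[a], f1_ids[b], "F2", "intercross"))
    return plan


@dataclass
class PopulationSim:
    """Complete simulated herd: truth, observed calls, and pedigree."""

    config: SimulationConfig
    truth: GenotypeMatrix  # error-free genotypes, founders + offspring
    observed: GenotypeMatrix  # after the observation model, with depths
    pedigree: TruePedigree
    divergent: np.ndarray
    sire_fixed_allele: np.ndarray


def simulate_population(config: SimulationConfig) -> PopulationSim:
    """Founders → mating plan → gene-dropping → observation model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    plan = default_cross_plan(config, rng)
    offspring, pedigree = simulate_cross(founders.matrix, founders.pedigree, plan, rng)
    truth = GenotypeMatrix.vstack([founders.matrix, offspring]) if plan else founders.matrix
    observed = apply_observation_model(truth, config, rng)
    return PopulationSim(
        config=config,
        truth=truth,
        observed=observed,
        pedigree=pedigree,
        divergent=founders.divergent,
        sire_fixed_allele=founders.sire_fixed_allele,
    )


def apply_observation_model(
    truth: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Add RAD-like noise: Poisson depth, per-read allele flips, dropout.

    Per call: depth ~ Poisson(mean_depth); each read drawn from the true
    genotype's allele dosage and flipped with probability
    ``genotype_error_rate``; the call is set MISSING with ``missing_rate``
    or when depth is zero (depths are zeroed for dropouts, so a call is
    MISSING iff it has no reads).  The reported genotype is the naive call:
    reads of both alleles → het, otherwise the homozygote of the observed
    allele.
    """
    if (truth.genotypes == MISSING).any():
        raise ValueError("observation model requires complete truth genotypes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = truth.genotypes.shape
    depth = rng.poisson(config.mean_depth, size=shape)
    p_alt_true = truth.genotypes / 2.0
    e = config.genotype_error_rate
    p_alt_read = p_alt_true * (1 - e) + (1 - p_alt_true) * e
    n_alt = rng.binomial(depth, p_alt_read)
    n_ref = depth - n_alt

    dropout = rng.random(shape) < config.missing_rate
    n_alt = np.where(dropout, 0, n_alt)
    n_ref = np.where(dropout, 0, n_ref)

    called = (n_ref + n_alt) > 0
    geno = np.full(shape, MISSING, dtype=np.int8)
    geno[called & (n_alt == 0)] = 0
    geno[called & (n_ref == 0) & (n_alt > 0)] = 2
    geno[(n_ref > 0) & (n_alt > 0)] = 1

    depths = np.stack([n_ref, n_alt], axis=-1).astype(np.int32)
    return GenotypeMatrix(
        sample_ids=list(truth.sample_ids),
        locus_ids=list(truth.locus_ids),
        genotypes=geno,
        allele_depths=depths,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, contig: str = "chrSim") -> None:
    """Write the matrix as a minimal multi-sample VCF v4.2 (GT:AD:DP).

    One record per locus on a synthetic contig at 1-based positions; REF=A,
    ALT=C.  Missing calls are written ``./.``.  Round-trips losslessly
    through :func:`crosskin.variants.read_vcf`.
    """
    n_samples, n_loci = matrix.genotypes.shape
    has_depth = matrix.allele_depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={max(n_loci, 1) * 100}>\n")
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Called allele number">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j, locus in enumerate(matrix.locus_ids):
            g = matrix.genotypes[:, j]
            an = int(2 * np.count_nonzero(g != MISSING))
            if has_depth:
                ad = matrix.allele_depths[:, j, :]
                site_dp = int(ad.sum())
                info = f"AN={an};DP={site_dp}"
                calls = "\t".join(
                    f"{_GT_STRINGS[int(g[i])]}:{ad[i, 0]},{ad[i, 1]}:{ad[i, 0] + ad[i, 1]}"
                    for i in range(n_samples)
                )
            else:
                info = f"AN={an}"
                calls = "\t".join(f"{_GT_STRINGS[int(g[i])]}:.:." for i in range(n_samples))
            pos = (j + 1) * 100
            fh.write(f"{contig}\t{pos}\t{locus}\tA\tC\t.\tPASS\t{info}\tGT:AD:DP\t{calls}\n")


def write_pedigree(pedigree: TruePedigree, path) -> None:
    """Write the pedigree truth as TSV (id, role, generation, sire, dam, cross)."""
    pedigree.write_tsv(path)


def divergent_truth_panel(sim: "PopulationSim | FounderSim") -> "SNPPanel":
    """Generation panel built from the simulator's construction truth.

    Uses the recorded fixed-divergent loci and per-locus orientation rather
    than re-deriving them from genotypes — the ground-truth counterpart of
    :func:`crosskin.variants.select_generation_panel`.
    """
    from .containers import SNPPanel

    matrix = sim.matrix if isinstance(sim, FounderSim) else sim.truth
    idx = np.flatnonzero(sim.divergent)
    return SNPPanel(
        locus_ids=[matrix.locus_ids[i] for i in idx],
        kind="generation",
        sire_allele=sim.sire_fixed_allele[idx],
        dam_allele=1 - sim.sire_fixed_allele[idx],
    )
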