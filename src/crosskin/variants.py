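"""VCF input, site hard-filtering, and SNP-panel selection.

Two panels are drawn from a filtered multi-sample VCF of the herd:

* a *generation* panel of loci near-fixed for alternative alleles in the
  founder sires vs founder dams (modal-allele counts within a slack window
  of complete homozygosity), used to classify offspring into F1/F2;
* a *parentage* panel of informative biallelic loci selected on the
  paternal samples (minor allele frequency, observed heterozygosity,
  missingness, Hardy–Weinberg exact test), used by the parentage engines.

Hard-filter thresholds follow GATK-style site annotations with strict
inequalities exactly as printed in their usual presentation: a site is
removed when a removal condition (e.g. ``QUAL < 250.0``) holds; a site
lacking an annotation is never removed by that annotation's rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix, SNPPanel

__all__ = [
    "VariantRecord",
    "HardFilterThresholds",
    "read_vcf",
    "hard_filter",
    "select_generation_panel",
    "select_parentage_panel",
    "hwe_exact_test",
]


@dataclass
class VariantRecord:
    """One VCF site: coordinates, alleles, and site-level quality metrics."""

    chrom: str
    pos: int  # 1-based
    locus_id: str
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    metrics: dict  # QD/MQ/FS/SOR/AN/DP/rank-sums/MQ0 where present
    n_samples: int

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


class VcfParseError(ValueError):
    pass


_METRIC_KEYS = (
    "DP", "MQ", "QD", "FS", "SOR", "AN", "MQ0",
    "BaseQRankSum", "ReadPosRankSum", "MQRankSum",
)


def read_vcf(path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a multi-sample VCF into site records plus a genotype matrix.

    Positions stay 1-based; a missing GT becomes :data:`MISSING`; absent AD
    becomes depths (0, 0).  Multiallelic records are retained (coded by
    non-reference allele count in the matrix) and filtered downstream.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    geno_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    for line_no, v in enumerate(vcf, start=1):
        try:
            metrics = {}
            for key in _METRIC_KEYS:
                val = v.INFO.get(key)
                if val is not None:
                    metrics[key] = float(val)
            locus_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    locus_id=locus_id,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    qual=None if v.QUAL is None else float(v.QUAL),
                    metrics=metrics,
                    n_samples=len(samples),
                )
            )
            locus_ids.append(locus_id)

            gt = np.full(len(samples), MISSING, dtype=np.int8)
            for i, g in enumerate(v.genotypes):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    continue
                gt[i] = int(a > 0) + int(b > 0)
            geno_cols.append(gt)

            try:
                ad = v.format("AD")
            except KeyError:  # AD not declared in the header
                ad = None
            if ad is None:
                depth_cols.append(np.zeros((len(samples), 2), dtype=np.int32))
            else:
                ad = np.asarray(ad)
                ref_d = np.clip(ad[:, 0], 0, None)
                alt_d = np.clip(ad[:, 1:], 0, None).sum(axis=1) if ad.shape[1] > 1 else np.zeros(len(samples))
                depth_cols.append(np.stack([ref_d, alt_d], axis=1).astype(np.int32))
        except VcfParseError:
            raise
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{line_no} in {path}: {exc}") from exc

    if not records:
        matrix = GenotypeMatrix(samples, [], np.empty((len(samples), 0), dtype=np.int8),
                                np.empty((len(samples), 0, 2), dtype=np.int32))
        return records, matrix
    matrix = GenotypeMatrix(
        sample_ids=samples,
        locus_ids=locus_ids,
        genotypes=np.stack(geno_cols, axis=1),
        allele_depths=np.stack(depth_cols, axis=1),
    )
    return records, matrix


@dataclass
class HardFilterThresholds:
    """Removal thresholds for site hard-filtering (strict inequalities).

    A site is removed when any of these holds: QUAL < qual_min,
    DP < dp_min, DP > dp_max, (MQ < mq_min or QD < qd_min or FS > fs_max or
    BaseQRankSum < baseq_rs_min or ReadPosRankSum < readpos_rs_min or
    MQRankSum < mq_rs_min), SOR > sor_max, AN < an_min, MQ0 >= mq0_lim.
    ``an_min=None`` defaults to the record's sample count (i.e. at least
    half of all calls present).
    """

    qual_min: float = 250.0
    dp_min: float = 1500.0
    dp_max: float = 6000.0
    mq_min: float = 50.0
    qd_min: float = 4.0
    fs_max: float = 15.0
    baseq_rs_min: float = -4.0
    readpos_rs_min: float = -3.50
    mq_rs_min: float = -10.0
    sor_max: float = 4.0
    an_min: float | None = None
    mq0_lim: float = 30.0

    @staticmethod
    def permissive() -> "HardFilterThresholds":
        inf = math.inf
        return HardFilterThresholds(
            qual_min=-inf, dp_min=-inf, dp_max=inf, mq_min=-inf, qd_min=-inf,
            fs_max=inf, baseq_rs_min=-inf, readpos_rs_min=-inf, mq_rs_min=-inf,
            sor_max=inf, an_min=-inf, mq0_lim=inf,
        )


def _lt(value, bound) -> bool:
    return value is not None and value < bound


def _gt(value, bound) -> bool:
    return value is not None and value > bound


def hard_filter(
    records: list[VariantRecord],
    thresholds: HardFilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the site hard-filter; return retained records + rejection counts.

    The per-rule counts tally every rule a removed record violates (a record
    can hit several), alongside ``removed``/``retained`` totals.
    """
    th = thresholds or HardFilterThresholds()
    counts = {k: 0 for k in
              ("QUAL", "DP_low", "DP_high", "MQ_QD_FS_ranksums", "SOR", "AN", "MQ0")}
    counts["removed"] = 0
    counts["retained"] = 0
    retained = []
    for rec in records:
        m = rec.metrics
        an_min = th.an_min if th.an_min is not None else rec.n_samples
        hits = []
        if _lt(rec.qual, th.qual_min):
            hits.append("QUAL")
        if _lt(m.get("DP"), th.dp_min):
            hits.append("DP_low")
        if _gt(m.get("DP"), th.dp_max):
            hits.append("DP_high")
        if (_lt(m.get("MQ"), th.mq_min) or _lt(m.get("QD"), th.qd_min)
                or _gt(m.get("FS"), th.fs_max)
                or _lt(m.get("BaseQRankSum"), th.baseq_rs_min)
                or _lt(m.get("ReadPosRankSum"), th.readpos_rs_min)
                or _lt(m.get("MQRankSum"), th.mq_rs_min)):
            hits.append("MQ_QD_FS_ranksums")
        if _gt(m.get("SOR"), th.sor_max):
            hits.append("SOR")
        if _lt(m.get("AN"), an_min):
            hits.append("AN")
        mq0 = m.get("MQ0")
        if mq0 is not None and mq0 >= th.mq0_lim:
            hits.append("MQ0")
        if hits:
            counts["removed"] += 1
            for h in hits:
                counts[h] += 1
        else:
            counts["retained"] += 1
            retained.append(rec)
    return retained, counts


def _depth_masked_genotypes(matrix: GenotypeMatrix, min_allele_depth: int) -> np.ndarray:
    """Copy of the genotype array with low-depth calls set MISSING."""
    g = matrix.genotypes.copy()
    if matrix.allele_depths is not None and min_allele_depth > 0:
        low = matrix.allele_depths.sum(axis=2) < min_allele_depth
        g[low] = MISSING
    return g


def _allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (ref_count, alt_count) over called genotypes only."""
    called = geno != MISSING
    g = np.where(called, geno, 0)
    alt = g.sum(axis=0)
    ref = (called * 2).sum(axis=0) - alt
    return ref, alt


def select_generation_panel(
    matrix: GenotypeMatrix,
    sire_ids: list[str],
    dam_ids: list[str],
    slack: int = 5,
    min_allele_depth: int = 6,
    require_complete_founders: bool = True,
    biallelic_mask: np.ndarray | None = None,
) -> SNPPanel:
    """Select near-fixed divergent loci between founder sires and dams.

    A locus is retained iff the modal-allele count among sires falls in
    ``[2*n_sires - slack, 2*n_sires]``, the modal-allele count among dams
    falls in ``[2*n_dams - slack, 2*n_dams]``, and the two modal alleles
    differ (with 24 sires and 28 dams and slack 5 the windows are [43, 48]
    and [51, 56]).  Calls with total allele depth below ``min_allele_depth``
    are treated as missing first; by default any locus with a missing
    founder call is dropped.  A tie for the modal allele disqualifies the
    locus (not diagnostic).
    """
    if not sire_ids or not dam_ids:
        raise ValueError("founder id lists must be non-empty")
    if set(sire_ids) & set(dam_ids):
        raise ValueError("sire and dam id lists must be disjoint")
    geno = _depth_masked_genotypes(matrix, min_allele_depth)
    g_s = geno[matrix.sample_idx(sire_ids)]
    g_d = geno[matrix.sample_idx(dam_ids)]

    ref_s, alt_s = _allele_counts(g_s)
    ref_d, alt_d = _allele_counts(g_d)
    modal_count_s = np.maximum(ref_s, alt_s)
    modal_count_d = np.maximum(ref_d, alt_d)
    modal_s = (alt_s > ref_s).astype(np.int8)
    modal_d = (alt_d > ref_d).astype(np.int8)
    tie = (ref_s == alt_s) | (ref_d == alt_d)

    lo_s, hi_s = 2 * len(sire_ids) - slack, 2 * len(sire_ids)
    lo_d, hi_d = 2 * len(dam_ids) - slack, 2 * len(dam_ids)
    keep = (
        (modal_count_s >= lo_s) & (modal_count_s <= hi_s)
        & (modal_count_d >= lo_d) & (modal_count_d <= hi_d)
        & (modal_s != modal_d) & ~tie
    )
    if require_complete_founders:
        keep &= (g_s != MISSING).all(axis=0) & (g_d != MISSING).all(axis=0)
    if biallelic_mask is not None:
        keep &= np.asarray(biallelic_mask, dtype=bool)

    idx = np.flatnonzero(keep)
    return SNPPanel(
        locus_ids=[matrix.locus_ids[i] for i in idx],
        kind="generation",
        sire_allele=modal_s[idx],
        dam_allele=modal_d[idx],
    )


def select_parentage_panel(
    matrix: GenotypeMatrix,
    sire_ids: list[str],
    maf_min: float = 0.25,
    het_min: float = 0.2,
    miss_max: float = 0.7,
    hwe_p_min: float = 0.01,
    min_allele_depth: int = 6,
    miss_max_final: float = 0.8,
    biallelic_mask: np.ndarray | None = None,
) -> SNPPanel:
    """Select informative biallelic loci for parentage assignment.

    Filters are computed on the paternal samples: minor allele frequency
    > ``maf_min``, observed heterozygosity (het fraction among called
    sires) > ``het_min``, missing-call proportion < ``miss_max``, and
    Hardy–Weinberg exact-test p-value > ``hwe_p_min``.  Low-depth calls
    (total AD < ``min_allele_depth``) are treated as missing first, and a
    final screen drops loci whose missingness across *all* samples exceeds
    ``miss_max_final``.  Reference-allele frequencies are recorded from the
    retained paternal data.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    geno = _depth_masked_genotypes(matrix, min_allele_depth)
    g_s = geno[matrix.sample_idx(sire_ids)]
    n_sires = len(sire_ids)

    called = g_s != MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / n_sires
    with np.errstate(invalid="ignore", divide="ignore"):
        n_het = (g_s == 1).sum(axis=0)
        n_hom_ref = (g_s == 0).sum(axis=0)
        n_hom_alt = (g_s == 2).sum(axis=0)
        alt_freq = np.where(n_called > 0, (n_het + 2 * n_hom_alt) / (2 * np.maximum(n_called, 1)), 0.0)
        maf = np.minimum(alt_freq, 1 - alt_freq)
        het_obs = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)

    hwe_p = np.ones(matrix.n_loci)
    candidate = (n_called > 0) & (maf > maf_min) & (het_obs > het_min) & (miss_frac < miss_max)
    for j in np.flatnonzero(candidate):
        hwe_p[j] = hwe_exact_test(int(n_het[j]), int(n_hom_ref[j]), int(n_hom_alt[j]))

    miss_all = (geno == MISSING).mean(axis=0)
    keep = candidate & (hwe_p > hwe_p_min) & (miss_all <= miss_max_final)
    if biallelic_mask is not None:
        keep &= np.asarray(biallelic_mask, dtype=bool)

    idx = np.flatnonzero(keep)
    return SNPPanel(
        locus_ids=[matrix.locus_ids[i] for i in idx],
        kind="parentage",
        ref_freq=1.0 - alt_freq[idx],
    )


def hwe_exact_test(n_het: int, n_hom_1: int, n_hom_2: int) -> float:
    """Two-sided exact test for Hardy–Weinberg equilibrium at a SNP.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Wigginton-style).  Returns a p-value in (0, 1].
    """
    if min(n_het, n_hom_1, n_hom_2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_1 + n_hom_2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_1, n_hom_2) + n_het  # copies of the rarer allele
    # Heterozygote counts share the parity of the rare-allele count.
    probs = np.zeros(rare + 1)
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # Downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (hr+1) (hc+1))
    h = mid
    while h > 1:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # Upward recurrence: P(h+2)/P(h) = 4 hr hc / ((h+2)(h+1))
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = probs.sum()
    p_obs = probs[n_het] / total
    p = probs[probs / total <= p_obs * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))
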