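"""Pairwise relatedness: method-of-moments IBD, kinship, distances, NJ trees.

PI_HAT (π̂) is the estimated genome fraction shared identical-by-descent,
P(IBD=2) + P(IBD=1)/2, from the classic genome-wide method-of-moments
estimator over identity-by-state counts: observed IBS0/IBS1/IBS2 counts are
matched to their expectations given allele frequencies, solved for the IBD
state probabilities, and projected onto the probability simplex.  Expected
bands: ~1 identical samples, ~0.5 parent–offspring, ~0.25 half-sibs, ~0
unrelated.

The kinship matrix is the centered-IBS (VanRaden-style) cross-product of
mean-centered genotype dosages, normalised to the coancestry scale (self
0.5, parent–offspring 0.25 for non-inbred samples); the ``times_two``
option rescales to expected covariances / numerator-relationship units
(self 1, parent–offspring 0.5).

p-distance between two samples is the mean per-locus allele-sharing
distance (0 identical genotype, 0.5 one shared allele, 1 none) over
pairwise-complete loci; trees are built from it by Saitou–Nei
neighbor-joining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SNPPanel

__all__ = [
    "IbdEstimate",
    "KinshipMatrix",
    "DistanceMatrix",
    "TreeNode",
    "ibd_pihat",
    "centered_ibs_kinship",
    "p_distance",
    "neighbor_joining",
    "tree_distance_matrix",
]


@dataclass
class IbdEstimate:
    """Method-of-moments IBD sharing estimate for one sample pair."""

    id1: str
    id2: str
    p0: float
    p1: float
    p2: float

    @property
    def pi_hat(self) -> float:
        return self.p2 + self.p1 / 2.0


def ibd_pihat(
    matrix: GenotypeMatrix,
    panel: SNPPanel | None = None,
    ref_freq: np.ndarray | None = None,
    pairs: list[tuple[str, str]] | None = None,
    min_informative: int = 50,
) -> pd.DataFrame:
    """Method-of-moments IBD (P0, P1, P2, PI_HAT) per sample pair.

    Allele frequencies come from, in order of preference: the explicit
    ``ref_freq`` array (one reference-allele frequency per matrix locus),
    the parentage ``panel`` (which restricts the loci used), or estimation
    from all samples in the matrix.  Monomorphic loci are skipped; a pair
    with fewer than ``min_informative`` co-called informative loci triggers
    a warning.  Estimates are clamped to the probability simplex before
    PI_HAT = P2 + P1/2 is formed.
    """
    if panel is not None:
        if panel.kind != "parentage":
            raise ValueError("ibd_pihat needs a parentage panel (with frequencies)")
        sub = matrix.subset_loci(panel.locus_ids)
        geno = sub.genotypes
        p = np.asarray(panel.ref_freq, dtype=float)
    else:
        geno = matrix.genotypes
        if ref_freq is not None:
            p = np.asarray(ref_freq, dtype=float)
            if p.shape != (matrix.n_loci,):
                raise ValueError("ref_freq must have one entry per locus")
        else:
            called = geno != MISSING
            with np.errstate(invalid="ignore"):
                alt = np.where(called, geno, 0).sum(axis=0) / np.maximum(
                    2 * called.sum(axis=0), 1)
            p = 1.0 - alt

    q = 1.0 - p
    informative = (p > 0.0) & (p < 1.0)
    # Per-locus expected IBS-category probabilities conditional on IBD state.
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2 * p * q
    e2_ibd1 = 1.0 - e1_ibd1

    ids = matrix.sample_ids
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    lookup = {s: i for i, s in enumerate(ids)}
    rows = []
    for id1, id2 in pairs:
        g1 = geno[lookup[id1]]
        g2 = geno[lookup[id2]]
        use = informative & (g1 != MISSING) & (g2 != MISSING)
        n_use = int(use.sum())
        if n_use < min_informative:
            warnings.warn(
                f"pair ({id1}, {id2}): only {n_use} informative co-called loci",
                stacklevel=2,
            )
        if n_use == 0:
            rows.append((id1, id2, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        diff = np.abs(g1[use] - g2[use])
        n_ibs0 = int((diff == 2).sum())
        n_ibs1 = int((diff == 1).sum())
        n_ibs2 = int((diff == 0).sum())

        s0 = e0_ibd0[use].sum()
        s1_0 = e1_ibd0[use].sum()
        s2_0 = e2_ibd0[use].sum()
        s1_1 = e1_ibd1[use].sum()
        s2_1 = e2_ibd1[use].sum()

        p0 = n_ibs0 / s0 if s0 > 0 else 0.0
        p1 = (n_ibs1 - p0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
        p2 = (n_ibs2 - p0 * s2_0 - p1 * s2_1) / n_use

        est = np.clip(np.array([p0, p1, p2]), 0.0, None)
        total = est.sum()
        est = est / total if total > 0 else np.array([1.0, 0.0, 0.0])
        pi = est[2] + est[1] / 2.0
        rows.append((id1, id2, est[0], est[1], est[2], pi, n_use))

    return pd.DataFrame(rows, columns=["id1", "id2", "P0", "P1", "P2", "PI_HAT", "n_loci"])


@dataclass
class KinshipMatrix:
    """Symmetric centered-IBS kinship matrix with its scaling tag."""

    sample_ids: list[str]
    values: np.ndarray
    method: str = "centered-IBS"
    times_two: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def centered_ibs_kinship(
    matrix: GenotypeMatrix,
    times_two: bool = False,
    locus_ids: list[str] | None = None,
) -> KinshipMatrix:
    """Centered-IBS kinship from genotype dosages.

    Missing calls are mean-imputed per locus; dosages are centered by the
    per-locus mean and the cross-product is normalised by twice the summed
    per-locus binomial variance 2·Σ2p̂q̂ (VanRaden-style), landing on the
    coancestry scale.  ``times_two`` doubles the matrix to the expected
    genotypic covariance scale used for comparing against pedigree
    relationships.  All-missing loci are dropped.
    """
    g = matrix.genotypes if locus_ids is None else matrix.subset_loci(locus_ids).genotypes
    g = g.astype(float)
    called = g != MISSING
    n_called = called.sum(axis=0)
    keep = n_called > 0
    g = g[:, keep]
    called = called[:, keep]
    col_mean = np.where(called, g, 0.0).sum(axis=0) / called.sum(axis=0)
    w = np.where(called, g, col_mean[None, :]) - col_mean[None, :]
    p_hat = col_mean / 2.0
    denom = 2.0 * np.sum(2.0 * p_hat * (1.0 - p_hat))
    if denom <= 0:
        raise ValueError("no polymorphic loci for kinship estimation")
    k = w @ w.T / denom
    if times_two:
        k = 2.0 * k
    k = (k + k.T) / 2.0
    return KinshipMatrix(sample_ids=list(matrix.sample_ids), values=k, times_two=times_two)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ValueError("distance matrix diagonal must be zero")

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def p_distance(matrix: GenotypeMatrix, locus_ids: list[str] | None = None) -> DistanceMatrix:
    """Allele-sharing p-distance between all sample pairs.

    Per co-called locus the distance is |g1 − g2| / 2 ∈ {0, 0.5, 1}
    (identical genotype, one shared allele, none); the pair distance is the
    mean over pairwise-complete loci.  A pair with zero co-called loci is
    an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("p_distance needs at least two samples")
    g = matrix.genotypes if locus_ids is None else matrix.subset_loci(locus_ids).genotypes
    n = g.shape[0]
    out = np.zeros((n, n))
    called = g != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            use = called[i] & called[j]
            if not use.any():
                raise ValueError(
                    f"no co-called loci for pair ({matrix.sample_ids[i]}, {matrix.sample_ids[j]})"
                )
            d = np.abs(g[i, use].astype(float) - g[j, use]) / 2.0
            out[i, j] = out[j, i] = d.mean()
    return DistanceMatrix(ids=list(matrix.sample_ids), values=out)


@dataclass
class TreeNode:
    """Unrooted binary tree node; leaves carry names, edges carry lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for child, _ in self.children for n in child.leaf_names()]

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = [f"{child._newick_inner()}:{length:.10g}" for child, length in self.children]
        return "(" + ",".join(parts) + ")"


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining tree from a distance matrix.

    Ties in the Q criterion are broken toward the lowest pair index in the
    current active-node ordering.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sister branch so the joined
    pair's distance is preserved.  Returns the (arbitrary) trifurcating
    root of the unrooted tree; requires at least three taxa.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dist.ids]

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin over the upper triangle in row-major order = lowest pair index
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])

        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        d_new = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = d_new[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]

    # Three-point resolution of the final trifurcation.
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[(a, la), (b, lb), (c, lc)])


def tree_distance_matrix(tree: TreeNode, leaf_order: list[str] | None = None) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaves of a tree."""
    dists: dict[str, dict[str, float]] = {}

    def below(node: TreeNode) -> dict[str, float]:
        # Distances from `node` to each leaf beneath it; records cross-pair
        # path lengths as a side effect.
        if node.is_leaf:
            return {node.name: 0.0}
        child_maps = []
        for child, length in node.children:
            cm = {leaf: dist + length for leaf, dist in below(child).items()}
            child_maps.append(cm)
        merged: dict[str, float] = {}
        for idx, cm in enumerate(child_maps):
            for other in child_maps[idx + 1:]:
                for la, da in cm.items():
                    for lb, db in other.items():
                        dists.setdefault(la, {})[lb] = da + db
                        dists.setdefault(lb, {})[la] = da + db
            merged.update(cm)
        return merged

    below(tree)
    leaves = leaf_order or tree.leaf_names()
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dists[leaves[i]][leaves[j]]
    return DistanceMatrix(ids=list(leaves), values=out)
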