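"""Shared in-memory containers for the crossbreeding-kinship pipeline.

The lingua franca of every stage is a :class:`GenotypeMatrix` — a dense
samples × loci array of diploid biallelic genotype codes with optional
per-call allele depths — plus a :class:`TruePedigree` giving each sample's
role and (for simulated data) its true parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing (uncalled) genotype.
MISSING: int = -1

#: Valid genotype codes: 0 = ref-hom, 1 = het, 2 = alt-hom, MISSING.
GENOTYPE_CODES = (0, 1, 2, MISSING)

PEDIGREE_COLUMNS = ["id", "role", "generation", "sire_id", "dam_id", "cross_type"]


@dataclass
class GenotypeMatrix:
    """Samples × loci coded genotypes with optional per-call allele depths.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows).
    locus_ids
        Ordered locus identifiers (columns).
    genotypes
        ``(n_samples, n_loci)`` integer array with codes 0 (ref-hom),
        1 (het), 2 (alt-hom), or :data:`MISSING`.
    allele_depths
        Optional ``(n_samples, n_loci, 2)`` array of (ref, alt) read depths.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.genotypes, GENOTYPE_CODES)
        if bad.any():
            raise ValueError("invalid genotype codes present")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
            expected = (len(self.sample_ids), len(self.locus_ids), 2)
            if self.allele_depths.shape != expected:
                raise ValueError(
                    f"allele_depths shape {self.allele_depths.shape} != {expected}"
                )
            if (self.allele_depths < 0).any():
                raise ValueError("negative allele depths")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._locus_index = {l: i for i, l in enumerate(self.locus_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_idx(self, sample_ids) -> np.ndarray:
        """Row indices for the given sample ids (KeyError if absent)."""
        return np.array([self._sample_index[s] for s in sample_ids], dtype=int)

    def locus_idx(self, locus_ids) -> np.ndarray:
        return np.array([self._locus_index[l] for l in locus_ids], dtype=int)

    def row(self, sample_id: str) -> np.ndarray:
        return self.genotypes[self._sample_index[sample_id]]

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_idx(sample_ids)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            locus_ids=list(self.locus_ids),
            genotypes=self.genotypes[idx].copy(),
            allele_depths=None if self.allele_depths is None else self.allele_depths[idx].copy(),
        )

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        idx = self.locus_idx(locus_ids)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=list(locus_ids),
            genotypes=self.genotypes[:, idx].copy(),
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, idx].copy(),
        )

    @staticmethod
    def vstack(matrices: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack matrices over samples; loci must agree in order."""
        first = matrices[0]
        for m in matrices[1:]:
            if m.locus_ids != first.locus_ids:
                raise ValueError("locus ids differ between stacked matrices")
        depths = None
        if all(m.allele_depths is not None for m in matrices):
            depths = np.concatenate([m.allele_depths for m in matrices], axis=0)
        return GenotypeMatrix(
            sample_ids=[s for m in matrices for s in m.sample_ids],
            locus_ids=list(first.locus_ids),
            genotypes=np.concatenate([m.genotypes for m in matrices], axis=0),
            allele_depths=depths,
        )


@dataclass
class TruePedigree:
    """Ground-truth pedigree for simulated (or recorded) samples.

    Backed by a DataFrame with columns ``id, role, generation, sire_id,
    dam_id, cross_type``.  Founders (role sire/dam) have no parents; every
    F1 has one founder sire and one founder dam; backcross F2 have an F1 dam
    and a founder sire; intercross F2 have two F1 parents.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEDIGREE_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(PEDIGREE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        self.df = self.df[PEDIGREE_COLUMNS].reset_index(drop=True)
        founders = self.df["role"].isin(["sire", "dam"])
        if (self.df.loc[founders, ["sire_id", "dam_id"]].notna().to_numpy()).any():
            raise ValueError("founders must have no recorded parents")

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def roles(self, role: str) -> list[str]:
        return self.df.loc[self.df["role"] == role, "id"].tolist()

    @property
    def sire_ids(self) -> list[str]:
        return self.roles("sire")

    @property
    def dam_ids(self) -> list[str]:
        return self.roles("dam")

    @property
    def offspring_ids(self) -> list[str]:
        return self.roles("offspring")

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        row = self.df.loc[self.df["id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        sire = row["sire_id"].iloc[0]
        dam = row["dam_id"].iloc[0]
        return (None if pd.isna(sire) else sire, None if pd.isna(dam) else dam)

    def generation_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["generation"].iloc[0]

    @staticmethod
    def concat(pedigrees: list["TruePedigree"]) -> "TruePedigree":
        return TruePedigree(pd.concat([p.df for p in pedigrees], ignore_index=True))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> "TruePedigree":
        df = pd.read_csv(path, sep="\t", dtype={c: "object" for c in PEDIGREE_COLUMNS})
        return TruePedigree(df)


@dataclass
class SNPPanel:
    """A selected set of loci for either generation classification or parentage.

    A *generation* panel records, per locus, the sire-diagnostic and
    dam-diagnostic allele (0 = ref, 1 = alt; they must differ).  A
    *parentage* panel records the reference-allele frequency estimated from
    the founder data used for selection.
    """

    locus_ids: list[str]
    kind: str  # "generation" | "parentage"
    sire_allele: np.ndarray | None = None  # generation panel: 0/1 per locus
    dam_allele: np.ndarray | None = None
    ref_freq: np.ndarray | None = None  # parentage panel: P(ref allele)

    def __post_init__(self) -> None:
        n = len(self.locus_ids)
        if self.kind == "generation":
            if self.sire_allele is None or self.dam_allele is None:
                raise ValueError("generation panel requires diagnostic alleles")
            self.sire_allele = np.asarray(self.sire_allele, dtype=np.int8)
            self.dam_allele = np.asarray(self.dam_allele, dtype=np.int8)
            if self.sire_allele.shape != (n,) or self.dam_allele.shape != (n,):
                raise ValueError("diagnostic allele arrays must match locus count")
            if (self.sire_allele == self.dam_allele).any():
                raise ValueError("diagnostic sire/dam alleles must differ per locus")
        elif self.kind == "parentage":
            if self.ref_freq is None:
                raise ValueError("parentage panel requires allele frequencies")
            self.ref_freq = np.asarray(self.ref_freq, dtype=float)
            if self.ref_freq.shape != (n,):
                raise ValueError("ref_freq must match locus count")
            if ((self.ref_freq <= 0) | (self.ref_freq >= 1)).any():
                raise ValueError("parentage panel frequencies must lie in (0, 1)")
        else:
            raise ValueError(f"unknown panel kind {self.kind!r}")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"locus_id": self.locus_ids})
        if self.kind == "generation":
            df["sire_allele"] = self.sire_allele
            df["dam_allele"] = self.dam_allele
        else:
            df["ref_freq"] = self.ref_freq
        return df

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(1, "panel_kind", self.kind)
        df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> "SNPPanel":
        df = pd.read_csv(path, sep="\t")
        kind = str(df["panel_kind"].iloc[0])
        if kind == "generation":
            return SNPPanel(
                locus_ids=df["locus_id"].astype(str).tolist(),
                kind=kind,
                sire_allele=df["sire_allele"].to_numpy(),
                dam_allele=df["dam_allele"].to_numpy(),
            )
        return SNPPanel(
            locus_ids=df["locus_id"].astype(str).tolist(),
            kind=kind,
            ref_freq=df["ref_freq"].to_numpy(),
        )
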