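"""Genotype dataset container with EIGENSTRAT semantics.

Genotypes are stored as an ``(n_sites, n_individuals)`` int8 matrix counting
copies of the reference allele (0/1/2), with 9 marking missing data.
Pseudohaploid data contain no heterozygous (1) calls by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 9


@dataclass
class SNPDataset:
    """A genotype matrix plus site and individual metadata.

    Parameters
    ----------
    genotypes
        ``(n_sites, n_ind)`` int8 array; allele counts 0/1/2, missing = 9.
    sites
        DataFrame with columns ``chrom`` (int) and ``pos`` (int), strictly
        increasing within each chromosome.
    individuals
        DataFrame with columns ``id``, ``group`` and optionally ``date``
        (sampling date in generations before present).
    ploidy
        ``"diploid"`` or ``"pseudohaploid"``.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    individuals: pd.DataFrame
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x individuals)")
        if len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("site table length does not match genotype rows")
        if len(self.individuals) != self.genotypes.shape[1]:
            raise ValueError("individual table length does not match columns")
        if self.ploidy not in ("diploid", "pseudohaploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0/1/2/9")
        if self.ploidy == "pseudohaploid" and (self.genotypes == 1).any():
            raise ValueError("pseudohaploid data may not contain heterozygotes")
        for _, sub in self.sites.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must strictly increase per chromosome")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.individuals["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero((self.individuals["group"] == group).to_numpy())
        if cols.size == 0:
            raise KeyError(f"no individuals in group {group!r}")
        return cols

    def group_date(self, group: str) -> float:
        cols = self.group_columns(group)
        return float(self.individuals["date"].iloc[cols[0]])

    # -- derived quantities ----------------------------------------------
    def allele_stats(self, groups: list[str] | None = None):
        """Per-group reference-allele counts and called-allele totals.

        Returns ``(counts, totals)`` of shape ``(n_sites, n_groups)``.
        For pseudohaploid data each individual contributes a single allele.
        """
        groups = groups if groups is not None else self.groups
        per_allele = 1 if self.ploidy == "pseudohaploid" else 2
        counts = np.empty((self.n_sites, len(groups)), dtype=np.float64)
        totals = np.empty_like(counts)
        geno = self.genotypes
        for k, g in enumerate(groups):
            sub = geno[:, self.group_columns(g)]
            called = sub != MISSING
            vals = np.where(called, sub, 0)
            if self.ploidy == "pseudohaploid":
                vals = vals // 2  # 0/2 coding -> one allele per individual
            counts[:, k] = vals.sum(axis=1)
            totals[:, k] = per_allele * called.sum(axis=1)
        return counts, totals

    def subset_individuals(self, mask: np.ndarray) -> "SNPDataset":
        mask = np.asarray(mask)
        return SNPDataset(
            self.genotypes[:, mask],
            self.sites.reset_index(drop=True),
            self.individuals.loc[mask].reset_index(drop=True),
            self.ploidy,
        )

    def subset_sites(self, mask: np.ndarray) -> "SNPDataset":
        mask = np.asarray(mask)
        return SNPDataset(
            self.genotypes[mask],
            self.sites.loc[mask].reset_index(drop=True),
            self.individuals.reset_index(drop=True),
            self.ploidy,
        )

    def polymorphic_mask(self, groups: list[str] | None = None) -> np.ndarray:
        """Sites polymorphic across the pooled set of *groups*."""
        counts, totals = self.allele_stats(groups)
        c = counts.sum(axis=1)
        t = totals.sum(axis=1)
        return (t > 0) & (c > 0) & (c < t)


def from_tree_sequence(ts, individual_table: pd.DataFrame, chrom: int = 1) -> SNPDataset:
    """Build a diploid SNPDataset from a tskit tree sequence.

    Keeps biallelic segregating sites only.  ``individual_table`` rows must
    match the tree sequence's individuals in order.
    """
    gm = ts.genotype_matrix()  # (sites, samples) haploid calls
    keep = np.array(
        [len(v.alleles) - (v.alleles[-1] is None) == 2 for v in ts.variants()],
        dtype=bool,
    )
    gm = gm[keep]
    positions = ts.tables.sites.position[keep].astype(int)
    diploid = gm[:, 0::2] + gm[:, 1::2]
    # collapse duplicate integer positions caused by discretisation
    uniq = np.concatenate(([True], np.diff(positions) > 0))
    sites = pd.DataFrame({"chrom": chrom, "pos": positions[uniq]})
    return SNPDataset(diploid[uniq].astype(np.int8), sites, individual_table)
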