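"""EIGENSTRAT text-format reader and writer.

``.geno``: one row per site, one character per individual (0/1/2 copies of
the reference allele, 9 = missing).  ``.snp``: site ID, chromosome, genetic
position (Morgans), physical position, alleles.  ``.ind``: individual ID,
sex (U here), group label.  The round trip is lossless for genotypes and
the metadata the package tracks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SNPDataset


class EigenstratError(ValueError):
    pass


def write_eigenstrat(data: SNPDataset, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    lookup = np.array([str(d) for d in range(10)])
    with open(f"{prefix}.geno", "w") as fh:
        for row in data.genotypes:
            fh.write("".join(lookup[row]) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for k, (_, site) in enumerate(data.sites.iterrows()):
            chrom, pos = int(site["chrom"]), int(site["pos"])
            fh.write(
                f"rs{chrom}_{pos}\t{chrom}\t{pos / 1e8:.6f}\t{pos}\tA\tG\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for _, ind in data.individuals.iterrows():
            fh.write(f"{ind['id']}\tU\t{ind['group']}\n")


def read_eigenstrat(prefix, ploidy: str | None = None) -> SNPDataset:
    """Read a .geno/.snp/.ind triple; ploidy is inferred (pseudohaploid if
    no heterozygous call) unless given."""
    prefix = Path(prefix)
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", names=["id", "sex", "group"], dtype=str
    )
    snp = pd.read_csv(
        f"{prefix}.snp",
        sep=r"\s+",
        names=["snp_id", "chrom", "gpos", "pos", "ref", "alt"],
    )
    genos = []
    with open(f"{prefix}.geno") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if len(line) != len(ind):
                raise EigenstratError(
                    f"{prefix}.geno line {lineno}: width {len(line)} != "
                    f"{len(ind)} individuals"
                )
            try:
                row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            except Exception as err:  # pragma: no cover
                raise EigenstratError(
                    f"{prefix}.geno line {lineno}: unparseable"
                ) from err
            bad = ~np.isin(row, (0, 1, 2, 9))
            if bad.any():
                raise EigenstratError(
                    f"{prefix}.geno line {lineno}: invalid genotype value "
                    f"{line[int(np.flatnonzero(bad)[0])]}"
                )
            genos.append(row.astype(np.int8))
    if len(genos) != len(snp):
        raise EigenstratError(
            f"{prefix}: {len(genos)} genotype rows but {len(snp)} .snp records"
        )
    geno = np.array(genos, dtype=np.int8) if genos else np.zeros(
        (0, len(ind)), dtype=np.int8
    )
    if ploidy is None:
        ploidy = "diploid" if (geno == 1).any() else "pseudohaploid"
        if geno.size == 0:
            ploidy = "diploid"
    sites = pd.DataFrame(
        {"chrom": snp["chrom"].astype(int), "pos": snp["pos"].astype(int)}
    )
    individuals = ind[["id", "group"]].copy()
    individuals["date"] = 0.0
    return SNPDataset(geno, sites, individuals, ploidy)
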