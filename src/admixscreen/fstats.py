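"""Block-resolved f-statistics, the weighted block jackknife, and Hudson FST.

f2-statistics are computed per 4-Mb genome block with the standard
finite-sample heterozygosity correction; f3 and f4 are linear combinations
of f2.  Standard errors come from a weighted delete-one-block jackknife
(Busing-style, weighted by per-block usable-site counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SNPDataset

DEFAULT_BLGSIZE = 4_000_000


class EmptyBlocksError(ValueError):
    pass


class NoOverlapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def jackknife_estimate(block_values, block_weights) -> tuple[float, float]:
    """Weighted delete-one-block jackknife mean and standard error.

    Blocks are weighted by their usable-site counts.  With equal weights the
    formulas reduce to the ordinary delete-one jackknife.
    """
    theta = np.asarray(block_values, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    keep = w > 0
    theta, w = theta[keep], w[keep]
    g = theta.size
    if g < 2:
        raise EmptyBlocksError("at least 2 non-empty blocks required for an SE")
    n = w.sum()
    est = float(np.sum(w * theta) / n)
    loo = (n * est - w * theta) / (n - w)  # delete-one estimates
    h = n / w
    est_j = float(g * est - np.sum((1.0 - w / n) * loo))
    tau = h * est - (h - 1.0) * loo  # pseudovalues
    var = float(np.sum((tau - est_j) ** 2 / (h - 1.0)) / g)
    return est_j, float(np.sqrt(max(var, 0.0)))


def jackknife_covariance(block_matrix, block_weights) -> np.ndarray:
    """Jackknife covariance of a vector statistic across blocks.

    ``block_matrix`` has shape ``(n_blocks, dim)``; the result is the
    ``(dim, dim)`` covariance of the weighted-mean estimate, generalising the
    weighted jackknife variance formula to vectors.
    """
    theta = np.asarray(block_matrix, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    keep = w > 0
    theta, w = theta[keep], w[keep]
    g = theta.shape[0]
    if g < 2:
        raise EmptyBlocksError("at least 2 non-empty blocks required")
    n = w.sum()
    est = (w[:, None] * theta).sum(axis=0) / n
    loo = (n * est[None, :] - w[:, None] * theta) / (n - w)[:, None]
    h = (n / w)[:, None]
    est_j = g * est - ((1.0 - w / n)[:, None] * loo).sum(axis=0)
    tau = h * est[None, :] - (h - 1.0) * loo
    dev = tau - est_j[None, :]
    scale = 1.0 / (h[:, 0] - 1.0)
    cov = (dev * scale[:, None]).T @ dev / g
    # symmetrise against numerical noise
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# block f2
# ---------------------------------------------------------------------------

@dataclass
class BlockFStats:
    """Per-block pairwise f2 values with jackknife weights.

    ``f2`` has shape ``(n_blocks, n_groups, n_groups)`` and ``weights`` the
    per-block usable-site counts.  ``mode`` records whether downstream f4
    values come from these f2 blocks or are recomputed per quadruplet
    ("allsnps").
    """

    groups: list[str]
    blocks: pd.DataFrame  # chrom, start, end per block
    f2: np.ndarray
    weights: np.ndarray
    mode: str = "from-f2"

    def index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in f2 blocks") from None

    @property
    def n_blocks(self) -> int:
        return len(self.weights)

    def f2_pair(self, a: str, b: str) -> np.ndarray:
        return self.f2[:, self.index(a), self.index(b)]

    def f4_blocks(self, a: str, b: str, c: str, d: str) -> np.ndarray:
        """f4(a, b; c, d) per block as a linear combination of f2 values."""
        return 0.5 * (
            self.f2_pair(a, d) + self.f2_pair(b, c)
            - self.f2_pair(a, c) - self.f2_pair(b, d)
        )

    def f3_blocks(self, target: str, a: str, b: str) -> np.ndarray:
        return 0.5 * (
            self.f2_pair(target, a) + self.f2_pair(target, b) - self.f2_pair(a, b)
        )


@dataclass
class FStatEstimate:
    label: str
    est: float
    se: float
    n_blocks: int
    n_snps: int

    @property
    def z(self) -> float:
        return self.est / self.se if self.se > 0 else np.inf * np.sign(self.est)


def _block_ids(sites: pd.DataFrame, blgsize: int):
    """Assign each site to a physical window of ``blgsize`` nt per chromosome."""
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    win = pos // blgsize
    keys = pd.DataFrame({"chrom": chrom, "win": win})
    uniq, ids = np.unique(keys.to_numpy(), axis=0, return_inverse=True)
    blocks = pd.DataFrame(
        {
            "chrom": uniq[:, 0],
            "start": uniq[:, 1] * blgsize,
            "end": (uniq[:, 1] + 1) * blgsize,
        }
    )
    return blocks, ids


def _freq_and_correction(data: SNPDataset, groups, adjust_pseudohaploid: bool):
    counts, totals = data.allele_stats(groups)
    if data.ploidy == "pseudohaploid" and not adjust_pseudohaploid:
        # treat pseudohaploid calls as diploid genotypes: halves the
        # heterozygosity correction relative to the allele-true counts
        totals = totals * 2.0
        counts = counts * 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
        corr = np.where(totals > 1, p * (1 - p) / np.maximum(totals - 1, 1), 0.0)
    return p, corr, totals


def compute_f2_blocks(
    data: SNPDataset,
    blgsize: int = DEFAULT_BLGSIZE,
    maxmiss: float = 0.0,
    adjust_pseudohaploid: bool = True,
    groups: list[str] | None = None,
) -> BlockFStats:
    """All pairwise f2-statistics per genome block.

    Only sites where the fraction of groups without data is at most
    ``maxmiss`` are used (``maxmiss=0``: complete group-level data).  The
    unbiased estimator subtracts the sampling-variance term
    ``p(1-p)/(n-1)`` per group; with ``adjust_pseudohaploid`` the allele
    total ``n`` counts one allele per pseudohaploid individual.
    """
    groups = groups if groups is not None else data.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for f2")
    p, corr, totals = _freq_and_correction(data, groups, adjust_pseudohaploid)
    has_data = totals > 0
    frac_missing = 1.0 - has_data.mean(axis=1)
    usable = frac_missing <= maxmiss + 1e-12
    if maxmiss == 0:
        usable &= has_data.all(axis=1)
    if not usable.any():
        raise EmptyBlocksError("no usable sites after the missingness filter")
    blocks, ids = _block_ids(data.sites, blgsize)
    nb, ng = len(blocks), len(groups)
    f2 = np.zeros((nb, ng, ng))
    weights = np.bincount(ids[usable], minlength=nb).astype(float)
    pu = p[usable]
    cu = corr[usable]
    idsu = ids[usable]
    for i in range(ng):
        d = pu[:, i, None] - pu[:, i + 1:]
        val = d * d - cu[:, i, None] - cu[:, i + 1:]
        for jo, j in enumerate(range(i + 1, ng)):
            s = np.bincount(idsu, weights=val[:, jo], minlength=nb)
            with np.errstate(invalid="ignore"):
                m = np.where(weights > 0, s / np.maximum(weights, 1), 0.0)
            f2[:, i, j] = m
            f2[:, j, i] = m
    return BlockFStats(groups=list(groups), blocks=blocks, f2=f2, weights=weights)


def f_stat(blocks: BlockFStats, label: tuple) -> FStatEstimate:
    """Estimate f2/f3/f4 with a jackknife SE from precomputed f2 blocks.

    ``label`` is ``("f2", a, b)``, ``("f3", target, a, b)`` or
    ``("f4", a, b, c, d)``.
    """
    kind, *args = label
    if kind == "f2":
        vals = blocks.f2_pair(*args)
    elif kind == "f3":
        vals = blocks.f3_blocks(*args)
    elif kind == "f4":
        vals = blocks.f4_blocks(*args)
    else:
        raise ValueError(f"unknown statistic kind {kind!r}")
    est, se = jackknife_estimate(vals, blocks.weights)
    name = f"{kind}({', '.join(args)})"
    return FStatEstimate(
        label=name,
        est=est,
        se=se,
        n_blocks=int((blocks.weights > 0).sum()),
        n_snps=int(blocks.weights.sum()),
    )


def f4_allsnps(
    data: SNPDataset,
    quadruple: tuple[str, str, str, str],
    blgsize: int = DEFAULT_BLGSIZE,
) -> FStatEstimate:
    """f4 computed directly off the genotypes for one population quadruplet.

    Site selection is per quadruplet: a site is used iff all four groups
    have at least one called allele there (the "allsnps" convention for
    missing-data-rich sets).
    """
    a, b, c, d = quadruple
    groups = list(dict.fromkeys(quadruple))
    counts, totals = data.allele_stats(groups)
    with np.errstate(invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    idx = {g: k for k, g in enumerate(groups)}
    usable = (totals > 0).all(axis=1)
    if not usable.any():
        raise NoOverlapError(f"no sites with data in all of {quadruple}")
    vals = (p[:, idx[a]] - p[:, idx[b]]) * (p[:, idx[c]] - p[:, idx[d]])
    blocks, ids = _block_ids(data.sites, blgsize)
    nb = len(blocks)
    weights = np.bincount(ids[usable], minlength=nb).astype(float)
    sums = np.bincount(ids[usable], weights=vals[usable], minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(weights > 0, sums / np.maximum(weights, 1), 0.0)
    est, se = jackknife_estimate(means, weights)
    return FStatEstimate(
        label=f"f4({a}, {b}; {c}, {d})[allsnps]",
        est=est,
        se=se,
        n_blocks=int((weights > 0).sum()),
        n_snps=int(weights.sum()),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_f2_blocks(blocks: BlockFStats, prefix) -> None:
    """Persist block f2 values as an NPZ container plus a JSON index."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(f"{prefix}.f2.npz", f2=blocks.f2, weights=blocks.weights)
    index = {
        "groups": blocks.groups,
        "mode": blocks.mode,
        "blocks": blocks.blocks.to_dict(orient="list"),
    }
    Path(f"{prefix}.f2.json").write_text(json.dumps(index))


def load_f2_blocks(prefix) -> BlockFStats:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    index = json.loads(Path(f"{prefix}.f2.json").read_text())
    arrays = np.load(f"{prefix}.f2.npz")
    return BlockFStats(
        groups=list(index["groups"]),
        blocks=pd.DataFrame(index["blocks"]),
        f2=arrays["f2"],
        weights=arrays["weights"],
        mode=index["mode"],
    )


def estimates_to_frame(estimates) -> pd.DataFrame:
    """TSV-ready table of FStatEstimates."""
    return pd.DataFrame(
        [
            {
                "statistic": e.label,
                "est": e.est,
                "se": e.se,
                "z": e.z,
                "n_snps": e.n_snps,
                "n_blocks": e.n_blocks,
            }
            for e in estimates
        ]
    )


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def fst_matrix(
    data: SNPDataset,
    groups: list[str] | None = None,
    date: float | None = None,
) -> pd.DataFrame:
    """Pairwise Hudson FST (ratio of averages across sites).

    ``date`` restricts the computation to groups sampled at that time slice.
    A group contributes at a site only when at least two of its chromosomes
    are called there.
    """
    if groups is None:
        groups = data.groups
    if date is not None:
        groups = [g for g in groups if data.group_date(g) == date]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups in the slice")
    counts, totals = data.allele_stats(groups)
    with np.errstate(invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
        corr = np.where(totals > 1, p * (1 - p) / np.maximum(totals - 1, 1), np.nan)
    ok = totals > 1
    ng = len(groups)
    out = np.zeros((ng, ng))
    for i in range(ng):
        pi = p[:, i, None]
        pj = p[:, i + 1:]
        num = (pi - pj) ** 2 - corr[:, i, None] - corr[:, i + 1:]
        den = pi * (1 - pj) + pj * (1 - pi)
        mask = ok[:, i, None] & ok[:, i + 1:]
        num = np.where(mask, num, 0.0)
        den = np.where(mask, den, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = num.sum(axis=0) / den.sum(axis=0)
        out[i, i + 1:] = fst
        out[i + 1:, i] = fst
    return pd.DataFrame(out, index=groups, columns=groups)
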