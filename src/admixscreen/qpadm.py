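"""qpWave rank tests and qpAdm admixture-weight estimation.

qpWave asks how many independent gene-flow streams connect a "left" and a
"right" population set by testing the rank of the f4 matrix
``x[i][j] = f4(left1, left_{i+1}; right1, right_{j+1})``.  qpAdm models a
target as a weighted mixture of proxy sources: the mixture weights are the
normalised left null vector of the best rank-(n-1) approximation of the
target/source f4 matrix, fitted under the block-jackknife covariance of the
f4 estimates by alternating generalised least squares.

Weights are *not* constrained to [0, 1]; the model P-value is the upper
chi-square tail of the minimised quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import SNPDataset
from .fstats import BlockFStats, compute_f2_blocks, jackknife_covariance

#: ridge added to the f4 covariance before inversion, as a fraction of the
#: mean diagonal; applied twice under the compatibility flag emulating the
#: upstream "fudge_twice" behaviour.
RIDGE = 1e-5
MAX_ALS_ITER = 200
ALS_TOL = 1e-10


class DegenerateFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class QpAdmModel:
    """An admixture model: target = mix of sources, given a right set."""

    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]

    @property
    def n_way(self) -> int:
        return len(self.sources)

    @property
    def left(self) -> tuple[str, ...]:
        return (self.target, *self.sources)


@dataclass
class QpWaveResult:
    left: tuple[str, ...]
    right: tuple[str, ...]
    rank: int
    statistic: float
    dof: int
    p_value: float
    n_snps: int


@dataclass
class QpAdmResult:
    target: str
    sources: tuple[str, ...]
    rights: tuple[str, ...]
    weights: np.ndarray
    se: np.ndarray
    p_value: float
    statistic: float
    dof: int
    n_snps: int

    @property
    def n_way(self) -> int:
        return len(self.sources)

    @property
    def max_abs_eaf_minus_ef(self) -> float:
        return float(np.max(np.abs(self.weights - 1.0 / self.n_way)))

    @property
    def max_se(self) -> float:
        return float(np.max(self.se))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _as_blocks(fsource, groups) -> BlockFStats:
    if isinstance(fsource, BlockFStats):
        return fsource
    if isinstance(fsource, SNPDataset):
        return compute_f2_blocks(fsource, groups=list(groups))
    raise TypeError("fsource must be a BlockFStats or an SNPDataset")


def _f4_block_matrix(blocks: BlockFStats, left, right):
    """Per-block f4 matrices: shape (n_blocks, L-1, R-1)."""
    l1, r1 = left[0], right[0]
    cols = []
    for li in left[1:]:
        row = [blocks.f4_blocks(l1, li, r1, rj) for rj in right[1:]]
        cols.append(np.stack(row, axis=-1))
    return np.stack(cols, axis=1)  # (blocks, L-1, R-1)


def _covariance(vec_blocks, weights, fudge_twice: bool):
    q = jackknife_covariance(vec_blocks, weights)
    ridge = RIDGE * float(np.mean(np.diag(q)))
    if ridge <= 0:
        ridge = RIDGE
    reps = 2 if fudge_twice else 1
    for _ in range(reps):
        q = q + ridge * np.eye(q.shape[0])
    return q


def _gls_solve(design, qinv, y):
    a = design.T @ qinv @ design
    b = design.T @ qinv @ y
    return np.linalg.lstsq(a, b, rcond=None)[0]


def _rank_fit(x: np.ndarray, qinv: np.ndarray, rank: int):
    """Best rank-``rank`` approximation of x under the Q-weighted norm.

    Returns ``(fitted, statistic)``.  Uses alternating GLS on the factors
    ``x ~ A @ B`` with an SVD initialisation.
    """
    m, n = x.shape
    y = x.ravel()
    if rank == 0:
        return np.zeros_like(x), float(y @ qinv @ y)
    if rank >= min(m, n):
        return x.copy(), 0.0
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    b = vt[:rank]
    a = u[:, :rank] * s[:rank]
    obj_prev = np.inf
    fitted = a @ b
    for _ in range(MAX_ALS_ITER):
        # solve for A rows given B: vec_C(AB) = (I_m kron B^T) vec_C(A)
        design_a = np.kron(np.eye(m), b.T)
        a = _gls_solve(design_a, qinv, y).reshape(m, rank)
        # solve for B given A: vec_C(AB) = (A kron I_n) vec_C(B)
        design_b = np.kron(a, np.eye(n))
        b = _gls_solve(design_b, qinv, y).reshape(rank, n)
        fitted = a @ b
        resid = y - fitted.ravel()
        obj = float(resid @ qinv @ resid)
        if obj_prev - obj < ALS_TOL * max(obj_prev, 1e-300):
            obj_prev = obj
            break
        obj_prev = obj
    return fitted, max(obj_prev, 0.0)


def _left_null_vector(fitted: np.ndarray, rank: int) -> np.ndarray:
    """Unit-sum left null vector of the fitted rank-deficient matrix."""
    u, s, _vt = np.linalg.svd(fitted)
    m = fitted.shape[0]
    null_dim = m - rank
    if null_dim != 1:
        raise DegenerateFitError(
            f"null space dimension {null_dim} != 1 at the fitted rank"
        )
    vec = u[:, -1]
    total = vec.sum()
    if abs(total) < 1e-12:
        raise DegenerateFitError("left null vector has zero coefficient sum")
    return vec / total


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def qpwave_test(
    left,
    right,
    rank: int,
    fsource,
    fudge_twice: bool = False,
) -> QpWaveResult:
    """Test whether ``rank`` gene-flow streams suffice to connect the sets.

    The chi-square statistic is the Q-weighted misfit of the best rank-r
    approximation of the f4 matrix; dof = (L-1-r)(R-1-r).
    """
    left, right = tuple(left), tuple(right)
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least two groups on each side")
    if set(left) & set(right):
        raise ValueError("left and right sets must be disjoint")
    if not 0 <= rank < min(len(left), len(right)) - 1 + 1:
        raise ValueError("rank must satisfy 0 <= rank <= min(L,R)-1")
    blocks = _as_blocks(fsource, left + right)
    xb = _f4_block_matrix(blocks, left, right)
    g, m, n = xb.shape
    w = blocks.weights
    x = np.einsum("b,bij->ij", w, xb) / w.sum()
    dof = (m - rank) * (n - rank)
    if dof <= 0:
        return QpWaveResult(left, right, rank, 0.0, 0, 1.0, int(w.sum()))
    q = _covariance(xb.reshape(g, m * n), w, fudge_twice)
    qinv = np.linalg.pinv(q)
    _fitted, statistic = _rank_fit(x, qinv, rank)
    p = float(stats.chi2.sf(statistic, dof))
    return QpWaveResult(left, right, rank, statistic, dof, p, int(w.sum()))


def fit_qpadm(
    target: str,
    sources,
    right,
    fsource,
    fudge_twice: bool = False,
) -> QpAdmResult:
    """Fit an n-way qpAdm model and estimate admixture weights.

    Weights sum to 1 exactly and are unconstrained otherwise; their SEs come
    from delete-one-block refits.  The model P-value equals the qpWave rank
    test for left = {target} + sources at rank n-1 (dof = R - n).
    """
    sources, right = tuple(sources), tuple(right)
    n = len(sources)
    if n < 1:
        raise ValueError("need at least one source")
    if target in sources or target in right or set(sources) & set(right):
        raise ValueError("target, sources and rights must be disjoint")
    r_count = len(right)
    dof = r_count - n
    if r_count < n + 2:
        raise ValueError(
            f"need at least n+2 right groups for a testable model "
            f"(got R={r_count}, n={n})"
        )
    left = (target, *sources)
    blocks = _as_blocks(fsource, left + right)
    xb = _f4_block_matrix(blocks, left, right)  # (g, n, R-1)
    g, m, ncol = xb.shape
    w = blocks.weights
    wsum = w.sum()
    x = np.einsum("b,bij->ij", w, xb) / wsum
    q = _covariance(xb.reshape(g, m * ncol), w, fudge_twice)
    qinv = np.linalg.pinv(q)
    rank = n - 1
    fitted, statistic = _rank_fit(x, qinv, rank)
    weights = _left_null_vector(fitted, rank) if n > 1 else np.array([1.0])
    p = float(stats.chi2.sf(statistic, dof))

    # delete-one-block refits for the weight SEs (covariance held fixed)
    if n > 1:
        keep = w > 0
        wk = w[keep]
        xbk = xb[keep]
        gk = wk.size
        loo_w = np.empty((gk, n))
        for bi in range(gk):
            wb = wsum - wk[bi]
            xb_loo = (x * wsum - wk[bi] * xbk[bi]) / wb
            fit_b, _ = _rank_fit(xb_loo, qinv, rank)
            loo_w[bi] = _left_null_vector(fit_b, rank)
        h = wsum / wk
        est_j = gk * weights - ((1.0 - wk / wsum)[:, None] * loo_w).sum(axis=0)
        tau = h[:, None] * weights[None, :] - (h - 1.0)[:, None] * loo_w
        var = ((tau - est_j[None, :]) ** 2 / (h - 1.0)[:, None]).sum(axis=0) / gk
        se = np.sqrt(np.maximum(var, 0.0))
    else:
        se = np.array([0.0])
    return QpAdmResult(
        target=target,
        sources=sources,
        rights=right,
        weights=weights,
        se=se,
        p_value=p,
        statistic=statistic,
        dof=dof,
        n_snps=int(wsum),
    )


def results_to_frame(results) -> "pd.DataFrame":
    """TSV-ready model-result table; weights are written unclamped."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "target": r.target,
            "sources": ",".join(r.sources),
            "rights": ",".join(r.rights),
            "n_way": r.n_way,
            "p_value": r.p_value,
            "max_abs_eaf_minus_ef": r.max_abs_eaf_minus_ef,
            "max_se": r.max_se,
            "n_snps": r.n_snps,
        }
        for k, (w, s) in enumerate(zip(r.weights, r.se), start=1):
            row[f"w{k}"] = float(w)
            row[f"se{k}"] = float(s)
        rows.append(row)
    return pd.DataFrame(rows)


def trailing_models(model: QpAdmModel) -> list[QpAdmModel]:
    """All simpler models over this model's own target and proxy sources.

    Follows the head pattern "target = subset of sources" and
    "source1 = subset of the other sources"; a 1-way model has no trailing
    models (empty list).
    """
    n = model.n_way
    if n < 2:
        return []
    from itertools import combinations

    out: list[QpAdmModel] = []
    for size in range(1, n):
        for combo in combinations(model.sources, size):
            out.append(QpAdmModel(model.target, combo, model.rights))
    head = model.sources[0]
    rest = model.sources[1:]
    for size in range(1, n):
        for combo in combinations(rest, size):
            out.append(QpAdmModel(head, combo, model.rights))
    return out
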