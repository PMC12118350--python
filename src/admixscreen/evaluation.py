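"""Scoring of admixture models and experiments.

Spatial optimality metrics on stepping-stone landscapes (source-target
distances, source-target-source angles, distance to the ideal symmetric
model), prestudy-odds/FDR bookkeeping, the topological true/false-positive
classifier for admixture-graph histories, the misleading-experiment rule,
and the PCA / ancestry-component support rules used to cross-check fitted
models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ags import AdmixtureGraph
from .landscape import HexLandscape
from .qpadm import QpAdmModel

IDEAL_ST = 1.0
ANGLE_NORM_TARGET = 9.0  # the maximal possible ST distance on the landscapes
DISTANCE_TO_IDEAL_THRESHOLD = 5.0


def max_angle(n_way: int) -> float:
    """Largest attainable minimal pairwise angle: 180/120/90 degrees for
    2-/3-/4-way models (360/n in general)."""
    if n_way < 2:
        raise ValueError("angles need at least 2 sources")
    return 360.0 / n_way


@dataclass
class OptimalityMetrics:
    """Geometric optimality of one admixture model."""

    n_way: int
    max_st: float
    avg_st: float
    min_angle: float | None  # degrees; None if undefined (source on target)

    @property
    def normalized_angle(self) -> float | None:
        if self.min_angle is None:
            return None
        return self.min_angle * ANGLE_NORM_TARGET / max_angle(self.n_way)

    def distance_to_ideal(self, use: str = "max") -> float | None:
        """Euclidean distance to the ideal symmetric model at (1, 9) in the
        (ST distance, normalized angle) plane."""
        na = self.normalized_angle
        if na is None:
            return None
        st = self.max_st if use == "max" else self.avg_st
        return math.hypot(st - IDEAL_ST, na - ANGLE_NORM_TARGET)


def st_distance(landscape: HexLandscape, target: int, source: int) -> float:
    """Source-target distance in lattice steps (hops).

    Noncontemporaneous samples of the same deme have distance 0, nearest
    neighbours distance 1, and so on; the maximal possible distance on the
    64-deme landscape is 9.
    """
    if not (0 <= target < landscape.n_demes and 0 <= source < landscape.n_demes):
        raise KeyError("unknown deme index")
    return landscape.hop_distance(target, source)


def min_sts_angle(
    landscape: HexLandscape, target: int, sources
) -> float | None:
    """Smallest angle (degrees) subtended at the target by any source pair;
    undefined (None) when a source coincides with the target deme."""
    sources = list(sources)
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    if any(s == target for s in sources):
        return None
    vecs = [landscape.coords[s] - landscape.coords[target] for s in sources]
    best = 180.0
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cosv = np.dot(vecs[i], vecs[j]) / (
                np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
            )
            ang = math.degrees(math.acos(min(1.0, max(-1.0, cosv))))
            best = min(best, ang)
    return best


def model_metrics(
    landscape: HexLandscape, target_deme: int, source_demes
) -> OptimalityMetrics:
    ds = [st_distance(landscape, target_deme, s) for s in source_demes]
    return OptimalityMetrics(
        n_way=len(ds),
        max_st=max(ds),
        avg_st=float(np.mean(ds)),
        min_angle=min_sts_angle(landscape, target_deme, source_demes),
    )


def classify_optimal(
    metrics: OptimalityMetrics,
    threshold: float = DISTANCE_TO_IDEAL_THRESHOLD,
    rule: str = "distance",
    use: str = "max",
) -> bool | None:
    """Optimal/nonoptimal call; None when the angle is undefined."""
    if rule == "nearest-neighbors":
        return metrics.max_st <= 1.0
    d = metrics.distance_to_ideal(use)
    if d is None:
        return None
    return d <= threshold


# ---------------------------------------------------------------------------
# confusion summaries / Eq.-style FDR
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def prestudy_odds(self) -> float:
        return (self.tp + self.fn) / (self.fp + self.tn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def fnr(self) -> float:
        return self.fn / (self.tp + self.fn)

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp)

    @property
    def ppv(self) -> float:
        return 1.0 - self.fdr

    @property
    def false_omission_rate(self) -> float:
        return self.fn / (self.tn + self.fn)


def fdr_from_rates(r_odds: float, fpr: float, fnr: float) -> float:
    """FDR from the prestudy odds R, the FPR and the FNR:
    ``FDR = FPR / (R - FNR*R + FPR)``."""
    if r_odds <= 0:
        raise ValueError("prestudy odds must be positive")
    den = r_odds - fnr * r_odds + fpr
    if den == 0:
        raise ZeroDivisionError("FDR undefined: zero denominator")
    return fpr / den


# ---------------------------------------------------------------------------
# AGS topological classification into TP and FP
# ---------------------------------------------------------------------------

@dataclass
class AGSLabel:
    label: str  # "TP", "FP" or "no-admixture"
    rule: int | None  # triggering FP rule id (1..5)
    aeh_diff: float  # AEH_T - av.AEH_S


_STRUCT_TOL = 1e-9
_N_RANDOMIZATIONS = 10
_REPRESENT_FRACTION = 0.40


class _GraphAnalyzer:
    """Expected-f4 machinery over virtual lineage anchors.

    An anchor is a (node, time) point; ancestry paths start there.  The
    root anchor carries no drift and serves as the fixed reference.
    """

    def __init__(self, graph: AdmixtureGraph):
        self.graph = graph
        self.segs = graph._segments()
        self.drift = np.array(
            [(b - a) / (2.0 * graph.ne[n]) for n, a, b in self.segs]
        )
        self._cache: dict = {}

    def probs(self, anchor) -> np.ndarray:
        if anchor in self._cache:
            return self._cache[anchor]
        node, time = anchor
        g = self.graph
        out = np.zeros(len(self.segs))
        stack = [(node, time, 1.0)]
        while stack:
            nd, t_enter, mass = stack.pop()
            if mass <= 0:
                continue
            pulses = [p for p in g.pulses_into(nd) if p.time > t_enter]
            remaining = mass
            cursor = t_enter
            for p in pulses:
                self._add(out, nd, cursor, p.time, remaining)
                stack.append((p.donor, p.time, remaining * p.proportion))
                remaining *= 1.0 - p.proportion
                cursor = p.time
            self._add(out, nd, cursor, g.origin_time[nd], remaining)
            if nd in g.parents:
                stack.append((g.parents[nd], g.origin_time[nd], remaining))
        self._cache[anchor] = out
        return out

    def _add(self, out, node, young, old, mass):
        if old <= young or mass <= 0:
            return
        for k, (n, a, b) in enumerate(self.segs):
            if n == node and a >= young - 1e-9 and b <= old + 1e-9:
                out[k] += mass

    def f4(self, a, b, c, d) -> float:
        pa, pb, pc, pd_ = (self.probs(x) for x in (a, b, c, d))
        return float(np.sum(self.drift * (pa - pb) * (pc - pd_)))

    def mass_at(self, leaf_anchor, node, time) -> float:
        """Ancestry mass of an anchor's path occupying *node* at *time*."""
        p = self.probs(leaf_anchor)
        total = 0.0
        for k, (n, a, b) in enumerate(self.segs):
            if n == node and a <= time <= b:
                total += p[k]
        return total


def _leaf_anchor(graph: AdmixtureGraph, leaf: str):
    return (leaf, graph.sample_time[leaf])


def _root_anchor(graph: AdmixtureGraph):
    return (graph.root, graph.origin_time[graph.root])


def _main_path_pulses(graph: AdmixtureGraph, leaf: str):
    """Pulses received by the leaf's scaffold lineage, youngest first."""
    path = set(graph.main_path(leaf))
    pulses = [p for p in graph.pulses if p.recipient in path]
    return sorted(pulses, key=lambda p: p.time)


def _true_source_anchors(graph: AdmixtureGraph, leaf: str):
    """Lineage anchors of the target's true ancestry sources.

    One anchor per scaffold-lineage pulse (the donor at the pulse date)
    plus the backbone lineage just above the oldest such pulse.
    """
    pulses = _main_path_pulses(graph, leaf)
    anchors = [(p.donor, p.time) for p in pulses]
    if pulses:
        oldest = pulses[-1]
        anchors.append((oldest.recipient, oldest.time))
    return anchors


def _anchor_chain(graph: AdmixtureGraph, anchor):
    """Scaffold nodes from the anchor upward to the root."""
    node, _time = anchor
    chain = [node]
    while chain[-1] in graph.parents:
        chain.append(graph.parents[chain[-1]])
    return chain


def _exclusive_top(graph: AdmixtureGraph, anchors, k):
    """Topmost lineage point private to true source *k*.

    Walks the anchor's scaffold chain upward until it meets the chain of
    any other true source; the segment just below that join is the
    source's exclusive drift region.  Ancestry fractions "derived from the
    true source" are measured there.
    """
    chains = [_anchor_chain(graph, a) for a in anchors]
    own = chains[k]
    other_nodes = set()
    for j, ch in enumerate(chains):
        if j != k:
            other_nodes.update(ch)
    if own[0] in other_nodes:
        return anchors[k]
    top = own[0]
    for node in own[1:]:
        if node in other_nodes:
            break
        top = node
    return top, graph.origin_time[top] - 1e-9


def _source_fraction(an: "_GraphAnalyzer", graph, anchors, k, leaf) -> float:
    node, time = _exclusive_top(graph, anchors, k)
    return an.mass_at(_leaf_anchor(graph, leaf), node, time)


def classify_ags_model(graph: AdmixtureGraph, model: QpAdmModel) -> AGSLabel:
    """Label a 2-way model TP or FP from the simulated topology.

    The five FP rules (checked in order, first trigger wins): (1) target
    cladal with a proxy; (2) proxy descends from the target lineage below
    its last admixture event; (3) a proxy is symmetrically related to all
    true sources, or both proxies represent one true source and are
    symmetric to the others; (4) a proxy derives <40% of its ancestry from
    the true source it represents; (5) the target has an ancestry source
    unrepresented by any sampled group and the model includes a proxy that
    represents no true source exclusively.

    Structural predicates (cladality, symmetry) must hold both at the
    simulated branch lengths and across 10 branch-length randomizations.
    """
    if model.n_way != 2:
        raise ValueError("the topological classifier covers 2-way models")
    target = model.target
    proxies = list(model.sources)
    aeh_t = graph.admixture_event_count(target)
    aeh_s = float(
        np.mean([graph.admixture_event_count(s) for s in proxies])
    )
    diff = aeh_t - aeh_s
    if aeh_t == 0:
        return AGSLabel("no-admixture", None, diff)

    variants = [graph] + [
        graph.randomize_branch_lengths(seed=1000 + k)
        for k in range(_N_RANDOMIZATIONS)
    ]
    analyzers = [_GraphAnalyzer(g) for g in variants]

    def structural_zero(values) -> bool:
        return all(abs(v) <= _STRUCT_TOL for v in values)

    others = [lf for lf in graph.leaves if lf not in (target, *proxies)]

    # rule 1: strict cladality of target and a proxy
    for proxy in proxies:
        vals = []
        for an, g in zip(analyzers, variants):
            ta, pa = _leaf_anchor(g, target), _leaf_anchor(g, proxy)
            for x, y in zip(others, others[1:] + others[:1]):
                vals.append(
                    an.f4(ta, pa, _leaf_anchor(g, x), _leaf_anchor(g, y))
                )
            vals.append(an.f4(ta, pa, _leaf_anchor(g, others[0]), _root_anchor(g)))
        if structural_zero(vals):
            return AGSLabel("FP", 1, diff)

    # rule 2: gene flow from the target lineage (below its last admixture
    # event) into a proxy lineage, possibly mediated by other lineages
    pulses_t = _main_path_pulses(graph, target)
    t_last = pulses_t[0].time if pulses_t else math.inf
    mp = set(graph.main_path(target))
    an0 = analyzers[0]
    for proxy in proxies:
        pa = _leaf_anchor(graph, proxy)
        for q in graph.pulses:
            if q.donor in mp and q.time < t_last and q.recipient not in mp:
                # does the proxy carry ancestry that jumped through q?
                mass = _pulse_mass(graph, pa, q)
                if mass > 1e-12:
                    return AGSLabel("FP", 2, diff)

    # representation analysis against the true-source anchors
    ts = _true_source_anchors(graph, target)

    def symmetric(proxy, a, b) -> bool:
        # anchors correspond across variants by construction order
        ia, ib = ts.index(a), ts.index(b)
        vals = []
        for an, g in zip(analyzers, variants):
            anchors = _true_source_anchors(g, target)
            vals.append(
                an.f4(
                    anchors[ia],
                    anchors[ib],
                    _leaf_anchor(g, proxy),
                    _root_anchor(g),
                )
            )
        return structural_zero(vals)

    def represented_source(proxy):
        """The unique true source the proxy is closer to, or None."""
        closer = []
        for k, a in enumerate(ts):
            beats_all = all(
                _consistent_sign(analyzers, variants, target, proxy, k, j, ts)
                for j in range(len(ts))
                if j != k
            )
            if beats_all:
                closer.append(k)
        return closer[0] if len(closer) == 1 else None

    rep = {p: represented_source(p) for p in proxies}

    # rule 3: a proxy symmetric to all true sources, or both proxies
    # representing one true source and symmetric to the others
    if len(ts) >= 2:
        for proxy in proxies:
            if all(
                symmetric(proxy, ts[i], ts[j])
                for i in range(len(ts))
                for j in range(i + 1, len(ts))
            ):
                return AGSLabel("FP", 3, diff)
        if rep[proxies[0]] is not None and rep[proxies[0]] == rep[proxies[1]]:
            return AGSLabel("FP", 3, diff)

    # true sources not represented by any sampled group (ghost lineages)
    unrepresented = {
        k
        for k in range(len(ts))
        if not any(
            _source_fraction(an0, graph, ts, k, lf) >= _REPRESENT_FRACTION
            for lf in graph.leaves
            if lf != target
        )
    }

    # rule 4: a represented *sampled* source contributing <40% of the
    # proxy's ancestry (measured in the source's exclusive drift region);
    # proxies standing in for ghost sources fall under rule 5 instead
    for proxy in proxies:
        k = rep[proxy]
        if k is None or k in unrepresented:
            continue
        frac = _source_fraction(an0, graph, ts, k, proxy)
        if frac < _REPRESENT_FRACTION:
            return AGSLabel("FP", 4, diff)

    # rule 5: unsampled deep-branching true source plus an inappropriate
    # proxy (one representing no true source, or weakly standing in for
    # the ghost)
    if unrepresented and any(
        rep[p] is None or rep[p] in unrepresented for p in proxies
    ):
        return AGSLabel("FP", 5, diff)

    # positive call: proxies must cover at least two distinct true sources
    covered = {rep[p] for p in proxies if rep[p] is not None}
    if len(ts) >= 3 and len(covered) < 2:
        return AGSLabel("FP", 3, diff)
    return AGSLabel("TP", None, diff)


def _consistent_sign(analyzers, variants, target, proxy, k, j, ts_ref) -> bool:
    """True when f4(ts_k, ts_j; proxy, root) > tol on every variant."""
    for an, g in zip(analyzers, variants):
        anchors = _true_source_anchors(g, target)
        v = an.f4(
            anchors[k], anchors[j], _leaf_anchor(g, proxy), _root_anchor(g)
        )
        if v <= _STRUCT_TOL:
            return False
    return True


def _pulse_mass(graph: AdmixtureGraph, leaf_anchor, pulse) -> float:
    """Ancestry mass of the anchor's path that jumps through *pulse*."""
    node0, t0 = leaf_anchor
    total = 0.0
    stack = [(node0, t0, 1.0)]
    while stack:
        nd, t_enter, mass = stack.pop()
        if mass <= 0:
            continue
        pulses = [p for p in graph.pulses_into(nd) if p.time > t_enter]
        remaining = mass
        for p in pulses:
            jump = remaining * p.proportion
            if p is pulse:
                total += jump
            else:
                stack.append((p.donor, p.time, jump))
            remaining -= jump
        if nd in graph.parents:
            stack.append((graph.parents[nd], graph.origin_time[nd], remaining))
    return total


# ---------------------------------------------------------------------------
# misleading experiments
# ---------------------------------------------------------------------------

def classify_experiment_misleading(
    outcome, metrics_fn, distance_gap: float = 8.0
) -> bool:
    """Was the experiment's positive outcome misleading?

    At the stop level, compares minimal distance-to-ideal between the
    nonrejected and the rejected models (gap > 8 means much better models
    were rejected); at a 1-way stop level the minimal ST distances are
    compared instead.  Models with undefined angles are excluded from the
    distance comparison.
    """
    if outcome.stop_level is None:
        raise ValueError("experiment produced no positive result")
    rows = outcome.levels[outcome.stop_level]
    accepted = [m for m, _r, ok in rows if ok]
    rejected = [m for m, _r, ok in rows if not ok]
    if not rejected:
        return False
    if outcome.stop_level == 1:
        def min_st(models):
            vals = [metrics_fn(m).max_st for m in models if metrics_fn(m)]
            return min(vals) if vals else math.inf
        return min_st(accepted) > min_st(rejected)

    def min_dist(models):
        vals = []
        for m in models:
            met = metrics_fn(m)
            if met is None:
                continue
            d = met.distance_to_ideal()
            if d is not None:
                vals.append(d)
        return min(vals) if vals else math.inf
    a, r = min_dist(accepted), min_dist(rejected)
    if math.isinf(a) or math.isinf(r):
        return False
    return a - r > distance_gap


# ---------------------------------------------------------------------------
# PCA / ancestry-component support
# ---------------------------------------------------------------------------

def pca_support(pcs: pd.DataFrame, target: str, s1: str, s2: str) -> bool:
    """Does the 3D PC configuration support "target = s1 + s2"?

    Supported when the target centroid lies on the segment connecting the
    source centroids, or within 3 target-cluster diameters of it.
    """
    cols = ["PC1", "PC2", "PC3"]
    def pts(g):
        sub = pcs[pcs["group"] == g]
        if sub.empty:
            raise KeyError(f"group {g!r} absent from the PC table")
        return sub[cols].to_numpy(float)
    t_pts, a, b = pts(target), pts(s1).mean(0), pts(s2).mean(0)
    t_cent = t_pts.mean(0)
    diam = 0.0
    for i in range(len(t_pts)):
        for j in range(i + 1, len(t_pts)):
            diam = max(diam, float(np.linalg.norm(t_pts[i] - t_pts[j])))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        dist = float(np.linalg.norm(t_cent - a))
        return dist <= 3 * diam
    lam = float((t_cent - a) @ ab) / denom
    lam = min(1.0, max(0.0, lam))
    dist = float(np.linalg.norm(t_cent - (a + lam * ab)))
    return dist <= 3 * diam + 1e-12


def admixture_support(q_matrices: dict, model: QpAdmModel) -> bool:
    """Decision rules over unsupervised ancestry-component tables.

    ``q_matrices`` maps K to a DataFrame with a ``group`` column and one
    column per ancestry component (rows sum to 1).  The model is supported
    if, for at least one K, at least half the target individuals are
    mixtures (minor component >2%) and two distinct components separate the
    two proxy sources.  Components absent from the target, or private to a
    source, are ignored.
    """
    if model.n_way != 2:
        raise ValueError("support rules cover 2-way models")
    s1, s2 = model.sources
    for _k, q in q_matrices.items():
        comp_cols = [c for c in q.columns if c != "group"]
        def grp(g):
            sub = q[q["group"] == g]
            if sub.empty:
                raise KeyError(f"group {g!r} absent from the Q table")
            return sub[comp_cols].to_numpy(float)
        tq, q1, q2 = grp(model.target), grp(s1), grp(s2)
        mixed = ((tq > 0.02).sum(axis=1) >= 2).sum()
        if mixed < max(1, len(tq) // 2 + len(tq) % 2):
            continue
        def present(mat, c):
            col = mat[:, c]
            return (col > 0.02).sum() >= max(1, len(mat) // 2 + len(mat) % 2)
        target_comps = [
            c for c in range(len(comp_cols)) if present(tq, c)
        ]
        shared = [
            c for c in target_comps if present(q1, c) or present(q2, c)
        ]
        if len(shared) < 2:
            continue
        a_comps = [c for c in shared if present(q1, c) and not present(q2, c)]
        b_comps = [c for c in shared if present(q2, c) and not present(q1, c)]
        if a_comps and b_comps:
            return True
    return False


# ---------------------------------------------------------------------------
# LD pruning + PCA
# ---------------------------------------------------------------------------

def ld_prune(
    data, window: int = 2000, step: int = 100, r2_threshold: float = 0.5
) -> np.ndarray:
    """Indices of sites surviving windowed r^2 pruning (later site of each
    correlated pair is removed)."""
    geno = data.genotypes.astype(float)
    geno[data.genotypes == 9] = np.nan
    col_mean = np.nanmean(geno, axis=1, keepdims=True)
    filled = np.where(np.isnan(geno), col_mean, geno)
    centered = filled - filled.mean(axis=1, keepdims=True)
    n_sites = centered.shape[0]
    removed = np.zeros(n_sites, dtype=bool)
    start = 0
    while start < n_sites:
        stop = min(start + window, n_sites)
        idx = np.arange(start, stop)
        alive = idx[~removed[idx]]
        sub = centered[alive]
        norms = np.sqrt((sub**2).sum(axis=1))
        norms[norms == 0] = 1.0
        corr = (sub @ sub.T) / np.outer(norms, norms)
        r2 = corr**2
        for i in range(len(alive)):
            if removed[alive[i]]:
                continue
            hit = np.flatnonzero(r2[i, i + 1:] > r2_threshold) + i + 1
            removed[alive[hit]] = True
        if stop == n_sites:
            break
        start += step
    return np.flatnonzero(~removed)


def ld_prune_and_pca(
    data,
    window: int = 2000,
    step: int = 100,
    r2_threshold: float = 0.5,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """PLINK-style windowed LD pruning followed by PCA (10 PCs).

    Genotypes are mean-centred and variance-standardised per site; missing
    calls are mean-imputed.
    """
    if data.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    keep = ld_prune(data, window, step, r2_threshold)
    if len(keep) < n_pcs:
        raise ValueError("fewer pruned sites than requested components")
    geno = data.genotypes[keep].astype(float)
    geno[data.genotypes[keep] == 9] = np.nan
    mean = np.nanmean(geno, axis=1, keepdims=True)
    filled = np.where(np.isnan(geno), mean, geno)
    sd = filled.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (filled - filled.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    out = pd.DataFrame(
        pcs, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    out.insert(0, "group", data.individuals["group"].to_numpy())
    out.insert(0, "id", data.individuals["id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# prestudy odds of randomized and systematic screens
# ---------------------------------------------------------------------------

def randomized_prestudy_odds(
    landscape: HexLandscape,
    n_per_cell: int = 500,
    seed: int = 0,
    complexities=(2, 3, 4),
    four_way_fraction: float = 0.5,
) -> dict:
    """Pooled optimal/nonoptimal odds over randomized experiments.

    Draws ``n_per_cell`` experiments per protocol x density cell, enumerates
    every n-way source combination, drops models with undefined angles and
    classifies the rest by distance-to-ideal <= 5.  4-way models (the most
    numerous) are enumerated on the leading ``four_way_fraction`` of draws.
    Returns ``{n_way: (odds, n_models)}``.
    """
    from itertools import combinations

    from .protocols import PROTOCOLS, draw_randomized_experiment, ssl_sampling_frame

    frame = ssl_sampling_frame(landscape.n_demes)
    deme_of = dict(zip(frame["group"], frame["deme"]))
    rng = np.random.default_rng(seed)
    hops = landscape.hop_matrix()
    coords = landscape.coords
    counts = {n: [0, 0] for n in complexities}
    for protocol in PROTOCOLS:
        for density in (13, 18):
            for k in range(n_per_cell):
                spec = draw_randomized_experiment(frame, protocol, density, rng)
                t = deme_of[spec.target]
                pool = [deme_of[g] for g in spec.source_pool()]
                for n in complexities:
                    if n == 4 and k >= n_per_cell * four_way_fraction:
                        continue
                    norm = max_angle(n)
                    for combo in combinations(pool, n):
                        if any(s == t for s in combo):
                            continue
                        vecs = [coords[s] - coords[t] for s in combo]
                        best = 180.0
                        for i in range(len(vecs)):
                            ni = np.linalg.norm(vecs[i])
                            for j in range(i + 1, len(vecs)):
                                nj = np.linalg.norm(vecs[j])
                                c = np.dot(vecs[i], vecs[j]) / (ni * nj)
                                ang = math.degrees(
                                    math.acos(min(1.0, max(-1.0, c)))
                                )
                                best = min(best, ang)
                        mx = max(hops[t, s] for s in combo)
                        d = math.hypot(
                            mx - IDEAL_ST,
                            best * ANGLE_NORM_TARGET / norm - ANGLE_NORM_TARGET,
                        )
                        counts[n][0 if d <= DISTANCE_TO_IDEAL_THRESHOLD else 1] += 1
    return {
        n: (opt / non, opt + non) for n, (opt, non) in counts.items()
    }


def systematic_prestudy_odds(
    landscape: HexLandscape, target_deme: int = 0, complexities=(2, 3, 6)
) -> dict:
    """Combinatorial odds in the 16-deme systematic setup.

    The reference set holds the target's 6 nearest neighbours plus 10
    third-circle demes; true models draw all their sources from the nearest
    neighbours.  Returns ``{n_way: (odds, n_models)}``.
    """
    from itertools import combinations

    from .protocols import draw_systematic_experiment

    ring1 = sorted(landscape.hex_ring(target_deme, 1))
    spec = draw_systematic_experiment(landscape, target_deme, tuple(ring1))
    demes = [int(g.split("_")[0][1:]) for g in spec.rotating]
    out = {}
    for n in complexities:
        true = false = 0
        for combo in combinations(demes, n):
            if all(landscape.hop_distance(target_deme, s) <= 1 for s in combo):
                true += 1
            else:
                false += 1
        out[n] = (true / false, true + false)
    return out


# ---------------------------------------------------------------------------
# metric-space summaries
# ---------------------------------------------------------------------------

def summarize_metric_space(
    metrics_list,
    feasible_flags,
    st_bins: int = 9,
    angle_bin_width: float = 10.0,
    use: str = "max",
):
    """Bin models over (ST distance, min STS angle) and correlate counts.

    Returns ``(table, spearman_rho)`` where the table holds per-bin counts
    of all vs feasible models and rho is Spearman's correlation over the
    populated bins (None when undefined, e.g. no feasible models).
    """
    rows = []
    for met, ok in zip(metrics_list, feasible_flags):
        if met is None or met.min_angle is None:
            continue
        st = met.max_st if use == "max" else met.avg_st
        rows.append(
            (
                min(int(st), st_bins - 1),
                min(int(met.min_angle / angle_bin_width), int(180 / angle_bin_width) - 1),
                bool(ok),
            )
        )
    if not rows:
        return pd.DataFrame(columns=["st_bin", "angle_bin", "all", "feasible"]), None
    df = pd.DataFrame(rows, columns=["st_bin", "angle_bin", "ok"])
    table = (
        df.groupby(["st_bin", "angle_bin"])
        .agg(all=("ok", "size"), feasible=("ok", "sum"))
        .reset_index()
    )
    if table["feasible"].sum() == 0 or len(table) < 2:
        return table, None
    rho = stats.spearmanr(table["all"], table["feasible"]).statistic
    return table, float(rho)
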