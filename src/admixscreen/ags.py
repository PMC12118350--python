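"""Random admixture-graph-shaped (AGS) histories.

A history is a dated bifurcating scaffold over 13 sampled leaves plus 10
pulse-like admixture events between contemporaneous lineages.  Demographic
events are tied to integer "levels" (topological depths); consecutive levels
are separated by 20-120 generations, the whole history fits within a maximum
depth of 800 or 3000 generations.  Per-lineage effective sizes lie in
1000-10000 diploids and admixture proportions in 10-50%.

Genotypes are simulated with msprime (discrete-time Wright-Fisher for the
most recent 25 generations), with unlinked 100-Mb chromosomes emulated by a
log(2) per-nt recombination rate at chromosome boundaries.  A degradation
step turns diploid data into pseudohaploid data with archaeogenetic
missingness patterns.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .dataset import MISSING, SNPDataset, from_tree_sequence

GAP_MIN, GAP_MAX = 20, 120
NE_MIN, NE_MAX = 1000, 10000
PROP_MIN, PROP_MAX = 0.10, 0.50
CHROM_LEN = 100_000_000
BOUNDARY_RATE = math.log(2)
RECOMB_RATE = 2e-8
MUT_RATE = 1.25e-8
DTWF_GENERATIONS = 25


class GraphConstructionError(RuntimeError):
    pass


class DegradationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Pulse:
    """A pulse admixture event: *recipient* draws *proportion* of its
    ancestry from *donor* at ``time`` generations before present."""

    time: float
    recipient: str
    donor: str
    proportion: float


@dataclass
class AdmixtureGraph:
    """Dated, Ne-annotated admixture graph.

    ``parents`` maps each non-root node to its scaffold parent;
    ``origin_time`` is the date a lineage is formed (by the split of its
    parent); ``ne`` the diploid effective size along the lineage;
    ``sample_time`` the sampling date for leaves.  ``pulses`` are the
    admixture events.
    """

    leaves: list[str]
    parents: dict[str, str]
    origin_time: dict[str, float]
    ne: dict[str, int]
    sample_time: dict[str, float]
    pulses: list[Pulse]
    max_depth: float

    # -- structure -------------------------------------------------------
    @property
    def root(self) -> str:
        (root,) = [n for n in self.origin_time if n not in self.parents]
        return root

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == node)

    def end_time(self, node: str) -> float:
        """Youngest time of the lineage (split into children or sampling)."""
        kids = self.children(node)
        if kids:
            return self.origin_time[kids[0]]
        # unsampled terminal lineages persist to the present
        return self.sample_time.get(node, 0.0)

    def alive_at(self, node: str, time: float) -> bool:
        return self.end_time(node) < time < self.origin_time[node]

    def n_admixture_events(self) -> int:
        return len(self.pulses)

    # -- ancestry bookkeeping -------------------------------------------
    def main_path(self, leaf: str) -> list[str]:
        """Scaffold lineage chain from a leaf up to the root."""
        chain = [leaf]
        while chain[-1] in self.parents:
            chain.append(self.parents[chain[-1]])
        return chain

    def pulses_into(self, node: str) -> list[Pulse]:
        return sorted(
            (p for p in self.pulses if p.recipient == node), key=lambda p: p.time
        )

    def ancestry_fractions(self, leaf: str) -> dict[tuple[str, float], float]:
        """Probability mass of ancestry paths per (node, entry_time) state.

        Traces a random ancestry path backwards from the sampled leaf; at a
        pulse the path jumps to the donor with the pulse proportion.  Keys
        are the node and the time the path enters that node.
        """
        out: dict[tuple[str, float], float] = {}
        stack = [(leaf, self.sample_time.get(leaf, self.end_time(leaf)), 1.0)]
        while stack:
            node, t_enter, mass = stack.pop()
            if mass <= 0:
                continue
            key = (node, t_enter)
            out[key] = out.get(key, 0.0) + mass
            events = [p for p in self.pulses_into(node) if p.time > t_enter]
            remaining = mass
            for p in events:  # youngest first
                jump = remaining * p.proportion
                stack.append((p.donor, p.time, jump))
                remaining -= jump
            if node in self.parents:
                stack.append((self.parents[node], self.origin_time[node], remaining))
        return out

    def lineage_fraction(self, leaf: str, node: str, after: float = -1.0) -> float:
        """Total ancestry fraction of *leaf* passing through *node* above
        time ``after``."""
        total = 0.0
        for (n, t_enter), mass in self.ancestry_fractions(leaf).items():
            if n == node and self.origin_time[n] > after and t_enter >= after:
                total += mass
        return total

    def admixture_event_count(self, leaf: str) -> int:
        """Number of admixture events in the leaf's history (AEH): pulses
        with positive ancestry mass flowing through their recipient side."""
        count = 0
        frac = self.ancestry_fractions(leaf)
        for p in self.pulses:
            mass = sum(
                m
                for (n, t_enter), m in frac.items()
                if n == p.recipient and t_enter < p.time <= self.origin_time[n]
            )
            if mass > 1e-12:
                count += 1
        return count

    # -- expected f-statistics ------------------------------------------
    def _segments(self):
        """(node, young, old) segments delimited by pulse times.

        Lineages are cut both where they receive a pulse and where they act
        as a donor, so every ancestry-path entry time coincides with a
        segment boundary.
        """
        segs = []
        for node in self.origin_time:
            young = self.end_time(node)
            cuts = sorted(
                {p.time for p in self.pulses if node in (p.recipient, p.donor)}
            )
            times = [young] + [t for t in cuts if young < t < self.origin_time[node]]
            times.append(self.origin_time[node])
            for a, b in zip(times[:-1], times[1:]):
                if b > a:
                    segs.append((node, a, b))
        return segs

    def _segment_probs(self, leaf: str, segs) -> np.ndarray:
        frac = self.ancestry_fractions(leaf)
        probs = np.zeros(len(segs))
        for (node, t_enter), mass in frac.items():
            # the path occupies node from t_enter up to origin (or a pulse
            # jump, which is already accounted by the split masses)
            for k, (n, a, b) in enumerate(segs):
                if n != node:
                    continue
                if a >= t_enter - 1e-12:
                    # mass that survives to the top of this segment: subtract
                    # pulse outflow between t_enter and segment bottom
                    m = mass
                    for p in self.pulses_into(node):
                        if t_enter < p.time <= a + 1e-12:
                            m *= 1.0 - p.proportion
                    probs[k] += m
        return probs

    def expected_f2_matrix(self, groups=None) -> pd.DataFrame:
        """Linear-drift expectation of pairwise f2 between sampled leaves.

        Each segment contributes ``duration/(2*Ne) * (pA - pB)^2`` where p
        is the ancestry-path probability through the segment.
        """
        groups = list(groups) if groups is not None else list(self.leaves)
        segs = self._segments()
        drift = np.array([(b - a) / (2.0 * self.ne[n]) for n, a, b in segs])
        p = np.stack([self._segment_probs(g, segs) for g in groups])
        diff = p[:, None, :] - p[None, :, :]
        f2 = (diff**2 * drift[None, None, :]).sum(axis=-1)
        return pd.DataFrame(f2, index=groups, columns=groups)

    def expected_f4(self, a: str, b: str, c: str, d: str) -> float:
        segs = self._segments()
        drift = np.array([(bb - aa) / (2.0 * self.ne[n]) for n, aa, bb in segs])
        pa, pb, pc, pd_ = (self._segment_probs(x, segs) for x in (a, b, c, d))
        return float(np.sum(drift * (pa - pb) * (pc - pd_)))

    def randomize_branch_lengths(self, seed: int) -> "AdmixtureGraph":
        """Same topology and proportions, redrawn level dates and Ne."""
        rng = np.random.default_rng(seed)
        dates = sorted({self.origin_time[n] for n in self.origin_time}
                       | {p.time for p in self.pulses}
                       | set(self.sample_time.values()), reverse=True)
        gaps = rng.integers(GAP_MIN, GAP_MAX + 1, size=len(dates) - 1)
        new_dates = [float(sum(gaps))]
        for gp in gaps:
            new_dates.append(new_dates[-1] - float(gp))
        mapping = dict(zip(dates, new_dates))
        return AdmixtureGraph(
            leaves=list(self.leaves),
            parents=dict(self.parents),
            origin_time={n: mapping[t] for n, t in self.origin_time.items()},
            ne={n: int(rng.integers(NE_MIN, NE_MAX + 1)) for n in self.ne},
            sample_time={n: mapping[t] for n, t in self.sample_time.items()},
            pulses=[replace(p, time=mapping[p.time]) for p in self.pulses],
            max_depth=self.max_depth,
        )


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

def _leaf_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"P{i}" for i in range(n)]


def _assign_level_dates(n_levels: int, max_depth: float, rng) -> list[float]:
    """Dates per level (level 0 = oldest), gaps drawn from U{20..120}.

    Rejection-samples the gap vector into the depth budget; if that fails,
    the gap upper bound is capped so the chain always fits.
    """
    n_gaps = n_levels - 1
    if n_gaps <= 0:
        return [min(max_depth, float(GAP_MAX))]
    if GAP_MIN * n_gaps > max_depth:
        raise GraphConstructionError(
            f"max_depth {max_depth} too shallow for {n_levels} event levels "
            f"(needs at least {GAP_MIN * n_gaps})"
        )
    for _ in range(200):
        gaps = rng.integers(GAP_MIN, GAP_MAX + 1, size=n_gaps)
        if gaps.sum() <= max_depth:
            break
    else:
        cap = max(GAP_MIN, int(max_depth // n_gaps))
        gaps = rng.integers(GAP_MIN, cap + 1, size=n_gaps)
    depth = float(gaps.sum())
    dates = [depth]
    for gp in gaps:
        dates.append(dates[-1] - float(gp))
    return dates  # dates[level]; youngest >= 0


def generate_random_graph(
    n_leaves: int = 13,
    n_admix: int = 10,
    max_depth: float = 800,
    seed: int = 1,
) -> AdmixtureGraph:
    """Generate a random dated admixture graph.

    Two-phase construction: a random bifurcating scaffold whose split events
    are assigned to integer levels, then ``n_admix`` pulses inserted between
    lineages alive at a common level.  Deterministic under a fixed seed.
    """
    if n_leaves < 2:
        raise GraphConstructionError("need at least 2 leaves")
    if n_admix < 0:
        raise GraphConstructionError("n_admix must be non-negative")
    if max_depth < 200:
        raise GraphConstructionError("max_depth must be at least 200")
    ss = np.random.SeedSequence(seed)
    rng_topo, rng_dates, rng_ne, rng_prop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    leaves = _leaf_names(n_leaves)
    # random scaffold by sequential joins
    lineages = list(leaves)
    parents: dict[str, str] = {}
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng_topo.choice(len(lineages), size=2, replace=False))
        counter += 1
        new = f"n{counter}"
        parents[lineages[i]] = new
        parents[lineages[j]] = new
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [new]
    root = lineages[0]

    # levels for split events: each internal node's split lies 1-2 levels
    # below its parent's split (ties across subtrees arise naturally)
    internal = [root] + [
        n for n in parents if n not in leaves and n != root
    ]
    split_level: dict[str, int] = {}

    def assign(node: str) -> None:
        if node == root:
            split_level[node] = 1
        else:
            split_level[node] = split_level[parents[node]] + int(
                rng_topo.integers(1, 3)
            )
        for child in (c for c, p in parents.items() if p == node):
            if child not in leaves:
                assign(child)

    assign(root)
    max_split = max(split_level.values())
    # leaf sampling levels: strictly below the parent's split level
    sample_level: dict[str, int] = {}
    for leaf in leaves:
        lo = split_level[parents[leaf]] + 1
        hi = max(max_split + 1, lo)
        sample_level[leaf] = int(rng_topo.integers(lo, hi + 1))
    n_levels = max(max(sample_level.values()), max_split) + 1

    # origin level of a node = split level of its parent (root: level 0)
    origin_level = {root: 0}
    for node, par in parents.items():
        origin_level[node] = split_level[par]

    def end_level(node: str) -> int:
        return split_level[node] if node in split_level else sample_level[node]

    # pulses between lineages alive at a common level
    pulses_lv: list[tuple[int, str, str]] = []
    all_nodes = list(origin_level)
    for _ in range(n_admix):
        for _try in range(2000):
            lv = int(rng_topo.integers(1, n_levels))
            alive = [
                n for n in all_nodes if origin_level[n] < lv < end_level(n)
            ]
            if len(alive) >= 2:
                rec, don = rng_topo.choice(len(alive), size=2, replace=False)
                pulses_lv.append((lv, alive[rec], alive[don]))
                break
        else:
            raise GraphConstructionError(
                "could not place an admixture event between concurrent "
                "lineages; graph too shallow for the requested event count"
            )

    # compress levels not used by any event so that adjacent event dates
    # are always separated by a single 20-120 generation gap
    used = sorted(
        {0}
        | set(split_level.values())
        | set(sample_level.values())
        | {lv for lv, _, _ in pulses_lv}
    )
    remap = {lv: k for k, lv in enumerate(used)}
    split_level = {n: remap[lv] for n, lv in split_level.items()}
    sample_level = {n: remap[lv] for n, lv in sample_level.items()}
    pulses_lv = [(remap[lv], rec, don) for lv, rec, don in pulses_lv]
    origin_level = {n: remap[lv] for n, lv in origin_level.items()}
    n_levels = len(used)

    # deeper histories scale all dates up from the 800-generation baseline
    # (e.g. 3.75x for max_depth=3000), leaving the topology untouched
    scale = max(1.0, max_depth / 800.0)
    dates = _assign_level_dates(n_levels, max_depth / scale, rng_dates)
    dates = [d * scale for d in dates]
    graph = AdmixtureGraph(
        leaves=leaves,
        parents=parents,
        origin_time={n: dates[lv] for n, lv in origin_level.items()},
        ne={n: int(rng_ne.integers(NE_MIN, NE_MAX + 1)) for n in origin_level},
        sample_time={lf: dates[sample_level[lf]] for lf in leaves},
        pulses=[
            Pulse(dates[lv], rec, don, float(rng_prop.uniform(PROP_MIN, PROP_MAX)))
            for lv, rec, don in pulses_lv
        ],
        max_depth=float(max_depth),
    )
    return graph


def extend_to_present(graph: AdmixtureGraph) -> AdmixtureGraph:
    """Extend all terminal branches to time 0 and sample there."""
    return AdmixtureGraph(
        leaves=list(graph.leaves),
        parents=dict(graph.parents),
        origin_time=dict(graph.origin_time),
        ne=dict(graph.ne),
        sample_time={lf: 0.0 for lf in graph.leaves},
        pulses=list(graph.pulses),
        max_depth=graph.max_depth,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _graph_demography(graph: AdmixtureGraph) -> msprime.Demography:
    dem = msprime.Demography()
    for node in graph.origin_time:
        dem.add_population(name=node, initial_size=graph.ne[node])
    events = []
    for node in graph.origin_time:
        kids = graph.children(node)
        if kids:
            events.append(("split", graph.origin_time[kids[0]], node, kids))
    for p in graph.pulses:
        events.append(("pulse", p.time, p, None))
    events.sort(key=lambda e: e[1])
    for kind, time, a, b in events:
        if kind == "pulse":
            dem.add_mass_migration(
                time=time, source=a.recipient, dest=a.donor, proportion=a.proportion
            )
        else:
            dem.add_population_split(time=time, derived=b, ancestral=a)
    dem.sort_events()
    return dem


def simulate_ags_genotypes(
    graph: AdmixtureGraph,
    n_chrom: int = 3,
    chrom_len: float = CHROM_LEN,
    seed: int = 1,
    samples_per_leaf: int = 10,
) -> SNPDataset:
    """Simulate diploid genotypes for all sampled leaves.

    Chromosomes are stretches of ``chrom_len`` nt separated by 1-nt
    boundaries with per-nt recombination rate log(2), which makes them
    effectively unlinked; the discrete-time Wright-Fisher model is used for
    the most recent 25 generations.
    """
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    dem = _graph_demography(graph)
    positions = [0.0]
    rates = []
    for k in range(n_chrom):
        positions.append(positions[-1] + chrom_len)
        rates.append(RECOMB_RATE)
        if k < n_chrom - 1:
            positions.append(positions[-1] + 1)
            rates.append(BOUNDARY_RATE)
    rate_map = msprime.RateMap(position=positions, rate=rates)
    samples = [
        msprime.SampleSet(samples_per_leaf, population=lf, time=graph.sample_time[lf])
        for lf in graph.leaves
    ]
    try:
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            recombination_rate=rate_map,
            model=[
                msprime.DiscreteTimeWrightFisher(duration=DTWF_GENERATIONS),
                msprime.StandardCoalescent(),
            ],
            random_seed=(seed % 2**31) or 1,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=MUT_RATE,
            model=msprime.BinaryMutationModel(),
            random_seed=((seed + 1) % 2**31) or 1,
        )
    except Exception as err:  # pragma: no cover
        raise RuntimeError(
            f"coalescent engine failed; offending graph:\n{graph_to_text(graph)}"
        ) from err
    rows = [
        {
            "id": f"{lf}_{k}",
            "group": lf,
            "date": graph.sample_time[lf],
        }
        for lf in graph.leaves
        for k in range(samples_per_leaf)
    ]
    data = from_tree_sequence(ts, pd.DataFrame(rows))
    # split the single coordinate axis into chromosomes
    bounds = np.array([k * (chrom_len + 1) for k in range(1, n_chrom)])
    pos = data.sites["pos"].to_numpy()
    chrom = np.searchsorted(bounds, pos, side="right") + 1
    local = pos - np.concatenate(([0], bounds))[chrom - 1]
    sites = pd.DataFrame({"chrom": chrom, "pos": local})
    keep = np.concatenate(
        ([True], (np.diff(chrom) != 0) | (np.diff(local) > 0))
    )
    return SNPDataset(
        data.genotypes[keep], sites.loc[keep].reset_index(drop=True),
        data.individuals, "diploid",
    )


# ---------------------------------------------------------------------------
# degradation to archaeogenetic data quality
# ---------------------------------------------------------------------------

def degrade_dataset(
    data: SNPDataset,
    min_sites: int = 20000,
    seed: int = 1,
    max_attempts: int = 1000,
) -> SNPDataset:
    """Degrade diploid data to pseudohaploid, missingness-rich data.

    Per attempt: heterozygous calls are replaced by a randomly sampled
    allele; each individual loses sites at a rate drawn from U[0.05, 0.95];
    each group is subsampled to U{1..10} individuals.  Attempts repeat until
    more than ``min_sites`` sites remain polymorphic across the retained
    groups, up to ``max_attempts``.
    """
    if data.ploidy != "diploid":
        raise ValueError("degradation expects diploid input")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_attempts):
        degraded, _rates = degrade_once(data, rng)
        poly = degraded.polymorphic_mask()
        if int(poly.sum()) > min_sites:
            return degraded.subset_sites(poly)
    raise DegradationError(
        f"no degradation replicate with more than {min_sites} polymorphic "
        f"sites found within the {max_attempts}-attempt budget"
    )


def degrade_once(data: SNPDataset, rng) -> tuple[SNPDataset, np.ndarray]:
    """One degradation draw (no polymorphism condition).

    Returns the pseudohaploid dataset over all input sites plus the drawn
    per-individual missing rates (indexed like the input individuals).
    """
    geno = data.genotypes.copy()
    hets = geno == 1
    geno[hets] = rng.choice([0, 2], size=int(hets.sum())).astype(np.int8)
    n_sites, n_ind = geno.shape
    rates = rng.uniform(0.05, 0.95, size=n_ind)
    miss = rng.random((n_sites, n_ind)) < rates[None, :]
    geno[miss] = MISSING
    keep_cols = np.zeros(n_ind, dtype=bool)
    for g in data.groups:
        cols = data.group_columns(g)
        k = int(rng.integers(1, min(10, cols.size) + 1))
        keep_cols[rng.choice(cols, size=k, replace=False)] = True
    degraded = SNPDataset(
        geno[:, keep_cols],
        data.sites.reset_index(drop=True),
        data.individuals.loc[keep_cols].reset_index(drop=True),
        "pseudohaploid",
    )
    return degraded, rates[keep_cols]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def graph_to_text(graph: AdmixtureGraph) -> str:
    """One record per node/pulse; exact round-trip via repr of floats."""
    lines = [f"#max_depth\t{graph.max_depth!r}"]
    for node in sorted(graph.origin_time):
        parent = graph.parents.get(node, "-")
        stime = (
            repr(graph.sample_time[node]) if node in graph.sample_time else "-"
        )
        lines.append(
            f"node\t{node}\t{parent}\t{graph.origin_time[node]!r}"
            f"\t{graph.ne[node]}\t{stime}"
        )
    for p in graph.pulses:
        lines.append(
            f"pulse\t{p.time!r}\t{p.recipient}\t{p.donor}\t{p.proportion!r}"
        )
    return "\n".join(lines) + "\n"


def graph_from_text(text: str) -> AdmixtureGraph:
    parents, origin, ne, sample = {}, {}, {}, {}
    pulses = []
    max_depth = 0.0
    for line in text.strip().splitlines():
        parts = line.split("\t")
        if parts[0] == "#max_depth":
            max_depth = float(parts[1])
        elif parts[0] == "node":
            _, name, parent, otime, n, stime = parts
            if parent != "-":
                parents[name] = parent
            origin[name] = float(otime)
            ne[name] = int(n)
            if stime != "-":
                sample[name] = float(stime)
        elif parts[0] == "pulse":
            _, t, rec, don, prop = parts
            pulses.append(Pulse(float(t), rec, don, float(prop)))
    leaves = sorted(sample)
    return AdmixtureGraph(
        leaves=leaves,
        parents=parents,
        origin_time=origin,
        ne=ne,
        sample_time=sample,
        pulses=pulses,
        max_depth=max_depth,
    )
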