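"""High-throughput qpAdm screening protocols.

Covers model enumeration for rotating and nonrotating screens on
admixture-graph histories, randomized and systematic experiment
construction on stepping-stone landscapes, the 36 composite feasibility
criteria, experiment progression from simple to complex models, and the
model-competition step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .landscape import HexLandscape
from .qpadm import QpAdmModel, QpAdmResult

SLICES = (0, 100, 300)
P_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.5)
EAF_CONDITIONS = ("strict", "plain", "loose")


# ---------------------------------------------------------------------------
# feasibility criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeasibilityCriterion:
    """A composite model feasibility criterion.

    ``eaf_condition``: "strict" (w_i +- 2 SE_i inside (0,1)), "plain"
    (w_i inside (0,1)) or "loose" (w_i inside (-0.3, 1.3)); ``p_main`` the
    P-value threshold for the n-way model; ``trailing_rule``: "none" (do not
    check trailing models), "same" (trailing models rejected at ``p_main``)
    or "fixed-0.001" (trailing models rejected at 0.001).
    """

    eaf_condition: str = "strict"
    p_main: float = 0.01
    trailing_rule: str = "same"

    def __post_init__(self):
        if self.eaf_condition not in EAF_CONDITIONS:
            raise ValueError(f"unknown EAF condition {self.eaf_condition!r}")
        if self.trailing_rule not in ("none", "same", "fixed-0.001"):
            raise ValueError(f"unknown trailing rule {self.trailing_rule!r}")

    @property
    def trailing_threshold(self) -> float | None:
        if self.trailing_rule == "none":
            return None
        if self.trailing_rule == "same":
            return self.p_main
        return 0.001

    def eaf_ok(self, result: QpAdmResult) -> bool:
        if result.n_way == 1:
            return True  # a 1-way model has the trivial weight 1
        w, se = result.weights, result.se
        if self.eaf_condition == "strict":
            return bool(np.all((w - 2 * se > 0) & (w + 2 * se < 1)))
        if self.eaf_condition == "plain":
            return bool(np.all((w > 0) & (w < 1)))
        return bool(np.all((w > -0.3) & (w < 1.3)))

    @classmethod
    def parse(cls, text: str) -> "FeasibilityCriterion":
        eaf, p, trailing = text.split(":")
        return cls(eaf, float(p), trailing)

    def __str__(self) -> str:
        return f"{self.eaf_condition}:{self.p_main:g}:{self.trailing_rule}"


def criterion_grid() -> list[FeasibilityCriterion]:
    """The full grid of 36 composite feasibility criteria.

    Per EAF condition: five "same-threshold" criteria, five without a
    trailing check, and two (p_main 0.05 and 0.5) with trailing models
    rejected at the fixed 0.001 threshold.
    """
    grid = []
    for eaf in EAF_CONDITIONS:
        for p in P_THRESHOLDS:
            grid.append(FeasibilityCriterion(eaf, p, "same"))
        for p in P_THRESHOLDS:
            grid.append(FeasibilityCriterion(eaf, p, "none"))
        for p in (0.05, 0.5):
            grid.append(FeasibilityCriterion(eaf, p, "fixed-0.001"))
    return grid


def apply_feasibility(
    result: QpAdmResult,
    trailing: list | None,
    criterion: FeasibilityCriterion,
) -> bool:
    """Evaluate the composite criterion for one fitted model.

    ``trailing`` holds the fitted results (anything with a ``p_value``) of
    the model's trailing simpler models; it is required unless the
    criterion's trailing rule is "none" or the model is 1-way.
    """
    if result.p_value < criterion.p_main:
        return False
    if not criterion.eaf_ok(result):
        return False
    thr = criterion.trailing_threshold
    if thr is not None and result.n_way > 1:
        if trailing is None:
            raise ValueError(
                "criterion requires trailing-model results but none supplied"
            )
        if any(t.p_value >= thr for t in trailing):
            return False
    return True


# ---------------------------------------------------------------------------
# AGS model enumeration
# ---------------------------------------------------------------------------

def enumerate_ags_rotating(groups) -> list[QpAdmModel]:
    """All 2-way rotating models on a 13-group set: each (target; source
    pair) with the remaining 10 groups as rights -- 13 * C(12,2) models."""
    groups = list(groups)
    if len(set(groups)) != len(groups):
        raise ValueError("groups must be distinct")
    if len(groups) < 4:
        raise ValueError("need at least 4 groups")
    models = []
    for target in groups:
        rest = [g for g in groups if g != target]
        for s1, s2 in combinations(rest, 2):
            rights = tuple(g for g in rest if g not in (s1, s2))
            models.append(QpAdmModel(target, (s1, s2), rights))
    return models


def enumerate_ags_nonrotating(graph) -> list[QpAdmModel]:
    """Nonrotating 2-way models: rights = the 6 oldest sampled groups (ties
    resolved alphabetically), 2-way models for the remaining 7 targets."""
    order = sorted(graph.leaves, key=lambda lf: (-graph.sample_time[lf], lf))
    rights = tuple(sorted(order[:6]))
    rest = [lf for lf in graph.leaves if lf not in rights]
    models = []
    for target in rest:
        pool = [g for g in rest if g != target]
        for s1, s2 in combinations(pool, 2):
            models.append(QpAdmModel(target, (s1, s2), rights))
    return models


def filter_distal(models, dates: dict[str, float]) -> list[QpAdmModel]:
    """Keep models whose target is as old as or older-sampled than no
    source (target date <= all source dates)."""
    return [
        m
        for m in models
        if all(dates[m.target] <= dates[s] for s in m.sources)
    ]


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    """One qpAdm experiment: a target plus its reference demes/groups.

    For rotating protocols ``rotating`` holds the reference pool and each
    n-way model takes its sources from the pool, the rest becoming rights;
    for nonrotating protocols ``proxies`` and ``rights`` are fixed.
    Group labels are opaque strings; on SSL they encode deme and slice.
    """

    protocol: str  # e.g. "distal-rotating"
    target: str
    rotating: tuple[str, ...] = ()
    proxies: tuple[str, ...] = ()
    rights: tuple[str, ...] = ()
    max_complexity: int = 4

    @property
    def is_rotating(self) -> bool:
        return "rotating" in self.protocol and "nonrotating" not in self.protocol

    def source_pool(self) -> tuple[str, ...]:
        return self.rotating if self.is_rotating else self.proxies

    def models(self, n_way: int) -> list[QpAdmModel]:
        pool = self.source_pool()
        out = []
        for combo in combinations(pool, n_way):
            if self.is_rotating:
                rights = tuple(g for g in pool if g not in combo)
            else:
                rights = self.rights
            out.append(QpAdmModel(self.target, tuple(combo), rights))
        return out


@dataclass
class ExperimentOutcome:
    spec: ExperimentSpec
    levels: dict[int, list[tuple[QpAdmModel, QpAdmResult, bool]]]
    stop_level: int | None

    def feasible_at_stop(self) -> list[tuple[QpAdmModel, QpAdmResult]]:
        if self.stop_level is None:
            return []
        return [
            (m, r) for m, r, ok in self.levels[self.stop_level] if ok
        ]


def ssl_sampling_frame(n_demes: int = 64, slices=SLICES) -> pd.DataFrame:
    """All deme x sampling-slice units available on a landscape."""
    rows = [
        {"group": f"d{i}_t{t}", "deme": i, "slice": t}
        for t in slices
        for i in range(n_demes)
    ]
    return pd.DataFrame(rows)


def draw_randomized_experiment(
    frame: pd.DataFrame,
    protocol: str,
    density: int = 13,
    seed: int | np.random.Generator = 0,
) -> ExperimentSpec:
    """Draw one randomized experiment following the protocol rules.

    ``density`` counts rotating demes (13/18); nonrotating protocols use
    ``density - 3`` proxies and rights each (10/15).  Distal targets come
    from the present slice; rotating pools from the two older slices;
    proximal protocols relax the stratification but never allow a target
    from the oldest slice.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_ref = density - 3  # 13 -> 10 proxies/rights, 18 -> 15

    def pick(sub: pd.DataFrame, k: int) -> list[str]:
        idx = rng.choice(len(sub), size=k, replace=False)
        return list(sub["group"].to_numpy()[idx])

    present = frame[frame["slice"] == 0]
    mid = frame[frame["slice"] == 100]
    old = frame[frame["slice"] == 300]
    pooled_old = frame[frame["slice"].isin((100, 300))]

    if protocol == "distal-nonrotating":
        target = pick(present, 1)[0]
        rights = pick(old, n_ref)
        proxies = pick(mid, n_ref)
        return ExperimentSpec(protocol, target, (), tuple(proxies), tuple(rights))
    if protocol == "proximal-nonrotating":
        rights = pick(old, n_ref)
        young = frame[frame["slice"].isin((0, 100))]
        proxies = pick(young, n_ref)
        pool = frame[frame["slice"].isin((100, 300))]
        pool = pool[~pool["group"].isin(proxies + rights)]
        target = pick(pool, 1)[0]
        return ExperimentSpec(protocol, target, (), tuple(proxies), tuple(rights))
    if protocol == "distal-rotating":
        target = pick(present, 1)[0]
        rotating = pick(pooled_old, density)
        return ExperimentSpec(protocol, target, tuple(rotating))
    if protocol == "proximal-rotating":
        drawn = pick(frame, density + 1)
        sub = frame[frame["group"].isin(drawn)]
        candidates = sub[sub["slice"] != 300]
        if candidates.empty:
            raise ValueError("no eligible target in the drawn rotating set")
        target = pick(candidates, 1)[0]
        rotating = tuple(g for g in drawn if g != target)
        return ExperimentSpec(protocol, target, rotating)
    raise ValueError(f"unknown protocol {protocol!r}")


PROTOCOLS = (
    "distal-nonrotating",
    "proximal-nonrotating",
    "distal-rotating",
    "proximal-rotating",
)


def draw_systematic_experiment(
    landscape: HexLandscape,
    target_deme: int,
    first_circle: tuple[int, ...] = (),
    protocol: str = "distal-rotating",
    set_size: int = 16,
    proxy_slice: int = 100,
    right_slice: int = 300,
) -> ExperimentSpec:
    """Build a systematic experiment from the 1st/3rd circles of a target.

    ``first_circle`` lists the nearest-neighbour demes included (a subset of
    the 6); the rotating/proxy set is completed with third-circle demes
    chosen deterministically (sorted by polar angle around the target).
    The nonrotating variant uses 16 third-circle demes at the older slice
    as rights.
    """
    ring1 = set(landscape.hex_ring(target_deme, 1))
    ring3 = landscape.hex_ring(target_deme, 3)
    if len(ring3) < set_size - 6:
        raise ValueError(
            f"target deme {target_deme} lacks a complete 3rd circle "
            f"(found {len(ring3)} demes)"
        )
    if not set(first_circle) <= ring1:
        raise ValueError("first_circle entries must be nearest neighbours")
    k = len(first_circle)
    need = set_size - k
    if need > len(ring3):
        raise ValueError("not enough third-circle demes")
    center = landscape.coords[target_deme]

    def angle(d):
        v = landscape.coords[d] - center
        return np.arctan2(v[1], v[0]) % (2 * np.pi)

    third = sorted(ring3, key=angle)
    stride = len(third) / need if need else 1
    chosen3 = [third[int(i * stride)] for i in range(need)]
    pool = [f"d{d}_t{proxy_slice}" for d in (*sorted(first_circle), *chosen3)]
    target = f"d{target_deme}_t0"
    if "nonrotating" in protocol:
        rights = tuple(f"d{d}_t{right_slice}" for d in third[:set_size])
        return ExperimentSpec(protocol, target, (), tuple(pool), rights)
    return ExperimentSpec(protocol, target, tuple(pool))


def systematic_experiment_grid(
    landscape: HexLandscape, target_deme: int, protocol: str = "distal-rotating"
) -> list[ExperimentSpec]:
    """All 2^6 = 64 first-circle subsets for one target."""
    ring1 = sorted(landscape.hex_ring(target_deme, 1))
    if len(ring1) != 6:
        raise ValueError("target must have 6 nearest neighbours")
    specs = []
    for k in range(7):
        for sub in combinations(ring1, k):
            specs.append(
                draw_systematic_experiment(landscape, target_deme, sub, protocol)
            )
    return specs


def run_experiment(
    spec: ExperimentSpec,
    criterion: FeasibilityCriterion,
    fitter,
    exhaustive: bool = True,
) -> ExperimentOutcome:
    """Run one experiment from 1-way models up to the maximum complexity.

    ``fitter(model) -> QpAdmResult``.  Fit failures count as rejections.
    In exhaustive mode every complexity level is computed and the stop level
    derived afterwards; otherwise the experiment stops at the first level
    with a feasible model.
    """
    from .qpadm import trailing_models

    cache: dict[QpAdmModel, QpAdmResult | None] = {}

    def fit(model):
        if model not in cache:
            try:
                cache[model] = fitter(model)
            except Exception:
                cache[model] = None
        return cache[model]

    levels: dict[int, list] = {}
    stop = None
    for n in range(1, spec.max_complexity + 1):
        rows = []
        for model in spec.models(n):
            res = fit(model)
            if res is None:
                continue
            trailing = None
            if criterion.trailing_threshold is not None and n > 1:
                trailing = [
                    t
                    for t in (fit(tm) for tm in trailing_models(model))
                    if t is not None
                ]
            ok = apply_feasibility(res, trailing, criterion)
            rows.append((model, res, ok))
        levels[n] = rows
        if stop is None and any(ok for _, _, ok in rows):
            stop = n
            if not exhaustive:
                break
    return ExperimentOutcome(spec=spec, levels=levels, stop_level=stop)


def model_competition(
    feasible: list[QpAdmModel],
    criterion: FeasibilityCriterion,
    fitter,
    mode: str = "pool-right",
) -> list[QpAdmModel]:
    """Retest feasible models rotating alternative sources into the rights.

    ``pool-right``: all other models' non-shared sources join the right set
    at once; ``one-by-one``: one alternative source at a time, and a model
    survives only if never rejected.  A single feasible model passes
    automatically.
    """
    if not feasible:
        raise ValueError("need at least one feasible model")
    if len(feasible) == 1:
        return list(feasible)
    if mode not in ("pool-right", "one-by-one"):
        raise ValueError(f"unknown competition mode {mode!r}")
    alternatives = {s for m in feasible for s in m.sources}
    surviving = []
    for model in feasible:
        others = sorted(alternatives - set(model.sources))
        if not others:
            surviving.append(model)
            continue
        if mode == "pool-right":
            retest = QpAdmModel(
                model.target, model.sources, tuple(model.rights) + tuple(others)
            )
            variants = [retest]
        else:
            variants = [
                QpAdmModel(model.target, model.sources, tuple(model.rights) + (o,))
                for o in others
            ]
        ok = True
        for variant in variants:
            try:
                res = fitter(variant)
            except Exception:
                ok = False
                break
            if not apply_feasibility(res, None, FeasibilityCriterion(
                criterion.eaf_condition, criterion.p_main, "none"
            )):
                ok = False
                break
        if ok:
            surviving.append(model)
    return surviving
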