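"""Named reconstitution scenarios for the maturation simulator.

Each scenario encodes one of the characteristic in vitro reconstitution
set-ups: wild-type assembly at 30 C, cold-arrested dimerization at 4 C,
self-dimerization of shortened/extended-loop mutants, region I
truncations (fast dimerization, slow first autocatalysis), mixtures with
catalytically dead (TtoA) subunits, and two-step premixes of preformed
HPs.  Scenarios are qualitative: rate constants are chosen to reproduce
directions of effects, not fitted to gel densitometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .simulate import (
    HPState,
    RateParameters,
    SubunitSpec,
    TrajectorySet,
    simulate,
)
from .synth import gen_mixture_hp_pool

WT = SubunitSpec()
TTOA = SubunitSpec(catalytic=False)
SL1 = SubunitSpec(loop_variant="sl")
EL1 = SubunitSpec(loop_variant="el")
DELTA12 = SubunitSpec(truncation=12)
DELTA23 = SubunitSpec(truncation=23)
DELTA25 = SubunitSpec(truncation=25)
DELTA23_TTOA = SubunitSpec(catalytic=False, truncation=23)


@dataclass
class Scenario:
    name: str
    description: str
    pool_builder: Callable[[int, int], list[HPState]]  # (n_hp, seed) -> pool
    param_overrides: dict = field(default_factory=dict)
    model: str = "cooperative"
    t_end: float = 120.0


def _uniform_pool(spec: SubunitSpec) -> Callable[[int, int], list[HPState]]:
    def build(n_hp: int, seed: int) -> list[HPState]:
        return [HPState.uniform(spec) for _ in range(n_hp)]

    return build


def _mixture_pool(ratio: float, a: SubunitSpec, b: SubunitSpec):
    def build(n_hp: int, seed: int) -> list[HPState]:
        return gen_mixture_hp_pool(ratio, n_hp, a, b, seed=seed)

    return build


def _premix_pool(spec_a: SubunitSpec, spec_b: SubunitSpec):
    """Two preformed homogeneous HP populations mixed 1:1 (two-step assay)."""

    def build(n_hp: int, seed: int) -> list[HPState]:
        half = n_hp // 2
        return [HPState.uniform(spec_a) for _ in range(half)] + [
            HPState.uniform(spec_b) for _ in range(n_hp - half)
        ]

    return build


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            name="wt_30C",
            description="wild-type alpha+beta reconstitution at 30 C",
            pool_builder=_uniform_pool(WT),
        ),
        Scenario(
            name="wt_rt",
            description="wild-type reconstitution at room temperature (slower dimerization)",
            pool_builder=_uniform_pool(WT),
            param_overrides={"temperature_scale": 0.3},
        ),
        Scenario(
            name="wt_4C",
            description="cold reconstitution: dimerization arrested, HPs accumulate",
            pool_builder=_uniform_pool(WT),
            param_overrides={"temperature_scale": 1e-6},
            t_end=10080.0,  # nominal 7 days in minutes
        ),
        Scenario(
            name="sl1_selfdimer",
            description="shortened-loop mutant reconstituted with itself",
            pool_builder=_uniform_pool(SL1),
        ),
        Scenario(
            name="el1_selfdimer",
            description="extended-loop mutant reconstituted with itself",
            pool_builder=_uniform_pool(EL1),
        ),
        Scenario(
            name="delta12",
            description="region I truncation (12 aa): faster dimerization, slower activation",
            pool_builder=_uniform_pool(DELTA12),
        ),
        Scenario(
            name="delta23",
            description="region I truncation (23 aa): pre-holo CP pool becomes visible",
            pool_builder=_uniform_pool(DELTA23),
        ),
        Scenario(
            name="delta25",
            description="region I truncation (25 aa)",
            pool_builder=_uniform_pool(DELTA25),
        ),
        Scenario(
            name="ttoa_1to1",
            description="wild type : catalytically dead TtoA mixed 1:1",
            pool_builder=_mixture_pool(0.5, WT, TTOA),
        ),
        Scenario(
            name="ttoa_1to7",
            description="wild type : TtoA mixed 1:7",
            pool_builder=_mixture_pool(1 / 8, WT, TTOA),
        ),
        Scenario(
            name="el1_ttoa_1to1",
            description="extended loop : TtoA 1:1 (loop clash suppresses dimerization)",
            pool_builder=_mixture_pool(0.5, EL1, TTOA),
        ),
        Scenario(
            name="el1_ttoa_1to7",
            description="extended loop : TtoA 1:7 (dilute loops dimerize better)",
            pool_builder=_mixture_pool(1 / 8, EL1, TTOA),
        ),
        Scenario(
            name="sl1_delta23ttoa_premix",
            description="preformed HP(sl1) + HP(delta23 TtoA) shifted to 30 C: "
            "cross-interface cutting assay",
            pool_builder=_premix_pool(SL1, DELTA23_TTOA),
        ),
        Scenario(
            name="el1_delta23ttoa_premix",
            description="preformed HP(el1) + HP(delta23 TtoA): one-sided extended "
            "loops are accommodated",
            pool_builder=_premix_pool(EL1, DELTA23_TTOA),
        ),
    ]
}


@dataclass
class ScenarioReport:
    name: str
    description: str
    params: RateParameters
    model: str
    timecourse: pd.DataFrame
    trajectories: TrajectorySet


def run_scenario(
    name: str,
    overrides: dict | None = None,
    n_hp: int = 200,
    seed: int = 0,
    params: RateParameters | None = None,
    record_events: bool = False,
) -> ScenarioReport:
    """Run a named scenario and return tidy species time courses.

    ``overrides`` may patch rate parameters (by field name) and the keys
    ``model`` and ``t_end``.  The time course reports, per record time:
    free HPs, total CPs, pre-holo CPs (no subunit processed), active CPs
    (>= 1 processed), fully matured CPs (every catalytic subunit
    processed, at least one catalytic present), mean processed count, and
    population tallies of subunit propeptide states within CPs.  The
    cross-cut tally is reconstructed from the event log, so it requires
    ``record_events=True`` and reads zero otherwise.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    scen = SCENARIOS[name]
    overrides = dict(overrides or {})
    model = overrides.pop("model", scen.model)
    t_end = overrides.pop("t_end", scen.t_end)
    base = params if params is not None else RateParameters()
    patch = {**scen.param_overrides, **overrides}
    if patch:
        base = replace(base, **patch)
    pool = scen.pool_builder(n_hp, seed)
    traj = simulate(
        pool,
        base,
        model=model,
        t_end=t_end,
        seed=seed + 1,
        record_events=record_events,
    )
    rows = []
    for ti, t in enumerate(traj.record_times):
        formed = traj.cp_formation_times <= t
        counts = traj.processed_counts[ti, formed]
        counts = counts[~np.isnan(counts)]
        n_cp = len(counts)
        n_competent = np.array(
            [sum(s.spec.catalytic for s in cp.subunits) for cp in traj.cps]
        )[formed] if n_cp else np.array([])
        fully = int(
            sum((c == nc) and nc > 0 for c, nc in zip(counts, n_competent))
        )
        rows.append(
            {
                "time": float(t),
                "free_hp": int(traj.free_hp[ti]),
                "cp_total": n_cp,
                "cp_preholo": int((counts == 0).sum()) if n_cp else 0,
                "cp_active": int((counts >= 1).sum()) if n_cp else 0,
                "cp_fully_matured": fully,
                "mean_processed": float(counts.mean()) if n_cp else float("nan"),
                "subunits_intact": float(traj.state_tallies[ti, 0]),
                "subunits_cross_cut": float(traj.state_tallies[ti, 1]),
                "subunits_processed": float(traj.state_tallies[ti, 2]),
            }
        )
    return ScenarioReport(
        name=name,
        description=scen.description,
        params=base,
        model=model,
        timecourse=pd.DataFrame(rows),
        trajectories=traj,
    )
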