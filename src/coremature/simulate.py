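"""Stochastic simulator of half-proteasome dimerization and CP activation.

The model follows bacterial core-particle (CP) maturation as a two-stage
process.  Free half-proteasomes (HPs, alpha7-beta7) dimerize by mass
action into CPs; within a CP each of the 14 beta subunits carries a
propeptide that advances through the states::

    intact --(autocatalysis, slow)------------------> processed
    intact --(cross-cut by an active neighbour)-----> cross_cut
    cross_cut --(autocatalysis, fast)---------------> processed

Autocatalysis requires a catalytically competent subunit (a Thr1->Ala
"TtoA" subunit can be cross-cut but never completes processing).
Cross-cutting requires at least one adjacent subunit that is already
processed and competent; adjacency is a configurable topology over the 14
sites (two intra-ring 7-cycles, optionally plus inter-ring edges at the
HP-HP interface).

Two activation hypotheses are contrasted:

* ``independent`` -- every subunit self-processes at a single rate
  ``k_auto`` with no neighbour coupling (``k_cross = 0``); the per-CP
  processed count is then Binomial(14, 1 - exp(-k t)).
* ``cooperative`` -- a slow first autocatalysis is amplified by
  cross-cutting, which unlocks the fast rate on trimmed neighbours,
  concentrating CPs at all-or-none maturation.

Propeptide variants modulate the rates: extended/shortened region III
loops penalise dimerization, and region I truncations accelerate
dimerization while slowing the first autocatalytic step.  Simulation is
exact (Gillespie direct method); dimerization does not depend on internal
CP states, so HP-pool association and per-CP maturation are simulated as
successive exact stages.  Time units are arbitrary (scenario files use
nominal minutes); only rate ratios are meaningful.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

N_PER_RING = 7
N_SITES = 14

INTACT = "intact"
CROSS_CUT = "cross_cut"
PROCESSED = "processed"

LOOP_VARIANTS = ("wt", "sl", "el")


@dataclass(frozen=True)
class SubunitSpec:
    """Genotype of one beta subunit.

    ``catalytic`` is False for the Thr1->Ala active-site substitution;
    ``loop_variant`` describes the region III flexible loop (wild-type,
    shortened, extended); ``truncation`` is the number of region I
    residues deleted from the N terminus (0, 12, 23 or 25 in the
    characterised mutants, but any non-negative count is accepted).
    """

    catalytic: bool = True
    loop_variant: str = "wt"
    truncation: int = 0

    def __post_init__(self) -> None:
        if self.loop_variant not in LOOP_VARIANTS:
            raise ValueError(f"loop_variant must be one of {LOOP_VARIANTS}")
        if self.truncation < 0:
            raise ValueError("truncation must be >= 0")


WT = SubunitSpec()
TTOA = SubunitSpec(catalytic=False)


@dataclass
class SubunitState:
    spec: SubunitSpec
    propeptide: str = INTACT

    def __post_init__(self) -> None:
        if self.propeptide not in (INTACT, CROSS_CUT, PROCESSED):
            raise ValueError(f"bad propeptide state {self.propeptide!r}")
        if self.propeptide == PROCESSED and not self.spec.catalytic:
            raise ValueError("a non-catalytic subunit can never be fully processed")


@dataclass
class HPState:
    """A half proteasome: seven beta subunits on one ring."""

    subunits: list[SubunitState]

    def __post_init__(self) -> None:
        if len(self.subunits) != N_PER_RING:
            raise ValueError(f"an HP carries exactly {N_PER_RING} subunits")

    @classmethod
    def uniform(cls, spec: SubunitSpec) -> "HPState":
        return cls(subunits=[SubunitState(spec=spec) for _ in range(N_PER_RING)])

    def count(self, predicate: Callable[[SubunitSpec], bool]) -> int:
        return sum(predicate(s.spec) for s in self.subunits)

    @property
    def n_extended_loops(self) -> int:
        return self.count(lambda sp: sp.loop_variant == "el")

    @property
    def n_shortened_loops(self) -> int:
        return self.count(lambda sp: sp.loop_variant == "sl")

    def signature(self) -> tuple:
        """Composition key: dimerization kinetics depend only on this."""
        return tuple(
            sorted((s.spec.catalytic, s.spec.loop_variant, s.spec.truncation) for s in self.subunits)
        )


@dataclass
class CPState:
    """A core particle: two rings and an adjacency over the 14 sites."""

    ring_a: HPState
    ring_b: HPState
    topology: nx.Graph
    formation_time: float = 0.0

    def __post_init__(self) -> None:
        if set(self.topology.nodes) != set(range(N_SITES)):
            raise ValueError("topology must cover site ids 0..13")

    @property
    def subunits(self) -> list[SubunitState]:
        return self.ring_a.subunits + self.ring_b.subunits

    def processed_count(self) -> int:
        return sum(s.propeptide == PROCESSED for s in self.subunits)


def build_topology(
    mode: str = "intra_plus_cross",
    cross_pairs: Sequence[tuple[int, int]] | None = None,
) -> nx.Graph:
    """Adjacency over the 14 CP sites (ring A = 0..6, ring B = 7..13).

    ``intra_only`` yields two disjoint 7-cycles.  ``intra_plus_cross``
    additionally wires inter-ring edges: the given ``cross_pairs``, or the
    index-matched pairs ``(i, i+7)`` when none are supplied (the default
    stand-in for geometry-derived feasible pairs across the dimer
    interface).
    """
    if mode not in ("intra_only", "intra_plus_cross"):
        raise ValueError(f"unknown topology mode {mode!r}")
    g = nx.Graph()
    g.add_nodes_from(range(N_SITES))
    for i in range(N_PER_RING):
        g.add_edge(i, (i + 1) % N_PER_RING)
        g.add_edge(N_PER_RING + i, N_PER_RING + (i + 1) % N_PER_RING)
    if mode == "intra_plus_cross":
        if cross_pairs is None:
            cross_pairs = [(i, N_PER_RING + i) for i in range(N_PER_RING)]
        for pair in cross_pairs:
            if len(pair) != 2:
                raise ValueError(f"malformed cross pair {pair!r}")
            a, b = pair
            if not (0 <= a < N_SITES and 0 <= b < N_SITES) or a == b:
                raise ValueError(f"invalid cross pair {pair!r}")
            g.add_edge(a, b)
    return g


@dataclass
class RateParameters:
    """Kinetic constants of the maturation model (arbitrary time units).

    ``k_dimer0`` is the base HP+HP association rate at unit total HP
    concentration; ``el_penalty`` is the two-sided extended-loop clash
    factor (applied as ``el_penalty ** min(nA_el, nB_el)``: the penalty
    engages only when both partners present extended loops at the
    interface); ``sl_penalty`` is the analogous two-sided factor for
    shortened loops (self-dimerization of short-loop HPs is crippled, but
    a normal-loop or loop-free partner rescues association).  ``k_auto_slow`` / ``k_auto_fast`` are the per-subunit
    autocatalysis rates with an intact full-length versus a cross-cut
    propeptide; ``k_cross`` is the cutting rate per processed competent
    neighbour.  ``trunc_factors`` maps a region I truncation length to
    ``(dimer_multiplier, auto_multiplier)``; ``temperature_scale``
    multiplies the dimerization rate only (cold arrests dimerization, not
    processing).  ``loop_interaction`` may replace the default loop
    penalty with any callable ``f(nA_el, nB_el, nA_sl, nB_sl, params) ->
    float``.
    """

    k_dimer0: float = 0.5
    el_penalty: float = 0.01
    sl_penalty: float = 0.2
    k_auto_slow: float = 0.05
    k_auto_fast: float = 5.0
    k_cross: float = 5.0
    trunc_factors: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (1.0, 1.0), 12: (2.0, 0.5), 23: (5.0, 0.1), 25: (5.0, 0.08)}
    )
    temperature_scale: float = 1.0
    loop_interaction: Callable | None = None

    def __post_init__(self) -> None:
        for name in ("k_dimer0", "k_auto_slow", "k_auto_fast", "k_cross", "temperature_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.el_penalty <= 1 and 0 <= self.sl_penalty <= 1):
            raise ValueError("loop penalties must lie in [0, 1]")

    def trunc_dimer(self, truncation: int) -> float:
        return self.trunc_factors.get(truncation, (1.0, 1.0))[0]

    def trunc_auto(self, truncation: int) -> float:
        return self.trunc_factors.get(truncation, (1.0, 1.0))[1]


def dimerization_rate(hp_a: HPState, hp_b: HPState, params: RateParameters) -> float:
    """Association rate for one specific HP pair.

    Base rate times the temperature scale, times each partner's mean
    region I truncation multiplier, times the loop-interaction penalty.
    """
    rate = params.k_dimer0 * params.temperature_scale
    for hp in (hp_a, hp_b):
        rate *= float(np.mean([params.trunc_dimer(s.spec.truncation) for s in hp.subunits]))
    na_el, nb_el = hp_a.n_extended_loops, hp_b.n_extended_loops
    na_sl, nb_sl = hp_a.n_shortened_loops, hp_b.n_shortened_loops
    if params.loop_interaction is not None:
        rate *= float(params.loop_interaction(na_el, nb_el, na_sl, nb_sl, params))
    else:
        if min(na_el, nb_el) > 0:
            rate *= params.el_penalty ** min(na_el, nb_el)
        if min(na_sl, nb_sl) > 0:
            rate *= params.sl_penalty ** min(na_sl, nb_sl)
    return rate


@dataclass(frozen=True)
class Event:
    time: float
    cp_index: int
    site: int
    kind: str  # "autocatalysis_slow" | "autocatalysis_fast" | "cross_cut"
    n_processed_neighbors: int


@dataclass
class TrajectorySet:
    """Snapshots of a simulated population at fixed record times.

    ``processed_counts[t_idx, cp_idx]`` is the processed-subunit count of
    CP ``cp_idx`` at record time ``t_idx`` (NaN before the CP has formed).
    ``state_tallies`` holds population totals of intact / cross_cut /
    processed subunits within formed CPs.
    """

    record_times: np.ndarray
    processed_counts: np.ndarray  # (n_times, n_cps), NaN = not yet formed
    cp_formation_times: np.ndarray
    free_hp: np.ndarray  # (n_times,)
    state_tallies: "np.ndarray"  # (n_times, 3): intact, cross_cut, processed
    n_hp_initial: int
    cps: list[CPState]
    events: list[Event] = field(default_factory=list)

    def n_cps_at(self, t: float) -> int:
        return int((self.cp_formation_times <= t).sum())


@dataclass
class MaturationDistribution:
    """Histogram over processed counts 0..14 across the CP population."""

    time: float
    histogram: np.ndarray  # length 15, sums to 1 (or all zero when empty)
    n_cps: int
    empty: bool

    @property
    def intermediate_fraction(self) -> float:
        """Probability mass on partially matured CPs (1..13 processed)."""
        if self.empty:
            return float("nan")
        return float(self.histogram[1:14].sum())

    @property
    def mean_processed(self) -> float:
        if self.empty:
            return float("nan")
        return float(np.arange(15) @ self.histogram)


def _auto_rate(state: SubunitState, params: RateParameters, model: str) -> float:
    """Propensity of the subunit's own processing step in its current state."""
    if not state.spec.catalytic or state.propeptide == PROCESSED:
        return 0.0
    if model == "independent":
        # single-rate model; cross_cut never arises because k_cross = 0
        return params.k_auto_slow * params.trunc_auto(state.spec.truncation)
    if state.propeptide == INTACT:
        return params.k_auto_slow * params.trunc_auto(state.spec.truncation)
    return params.k_auto_fast


def _simulate_cp(
    cp: CPState,
    params: RateParameters,
    model: str,
    record_times: np.ndarray,
    rng: np.random.Generator,
    cp_index: int,
    events: list[Event] | None,
) -> np.ndarray:
    """Exact per-CP jump process from its formation time to the last record time.

    Returns the processed count at every record time (NaN before formation).
    """
    out = np.full(len(record_times), np.nan)
    states = cp.subunits  # 14 SubunitState, mutated in place
    adj = [list(cp.topology.neighbors(i)) for i in range(N_SITES)]
    t = cp.formation_time
    t_final = float(record_times[-1]) if len(record_times) else cp.formation_time
    next_rec = bisect.bisect_left(record_times, t)
    k_cross = 0.0 if model == "independent" else params.k_cross

    def fill_until(time_limit: float, start: int) -> int:
        i = start
        count = sum(s.propeptide == PROCESSED for s in states)
        while i < len(record_times) and record_times[i] <= time_limit:
            out[i] = count
            i += 1
        return i

    while t <= t_final:
        # propensities
        props: list[tuple[float, int, str, int]] = []
        for i, s in enumerate(states):
            a = _auto_rate(s, params, model)
            if a > 0:
                kind = "autocatalysis_fast" if s.propeptide == CROSS_CUT else "autocatalysis_slow"
                props.append((a, i, kind, 0))
            if k_cross > 0 and s.propeptide == INTACT:
                n_active = sum(
                    states[j].propeptide == PROCESSED and states[j].spec.catalytic
                    for j in adj[i]
                )
                if n_active:
                    props.append((k_cross * n_active, i, "cross_cut", n_active))
        total = sum(p[0] for p in props)
        if total == 0:
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        next_rec = fill_until(min(t_next, t_final), next_rec)
        if t_next > t_final:
            t = t_next
            break
        # pick event
        u = rng.random() * total
        acc = 0.0
        for rate, site, kind, n_active in props:
            acc += rate
            if u <= acc:
                break
        s = states[site]
        if kind == "cross_cut":
            s.propeptide = CROSS_CUT
        else:
            s.propeptide = PROCESSED
        if events is not None:
            events.append(
                Event(time=t_next, cp_index=cp_index, site=site, kind=kind,
                      n_processed_neighbors=n_active)
            )
        t = t_next
    # steady state (or past horizon): fill remaining record times
    fill_until(t_final, next_rec)
    return out


def _simulate_dimerization(
    hps: list[HPState],
    params: RateParameters,
    rng: np.random.Generator,
    t_end: float,
    n_scale: int,
) -> list[tuple[float, HPState, HPState]]:
    """Exact mass-action association of the free HP pool.

    Pair propensity is ``dimerization_rate / n_scale`` (concentration
    units where the initial total HP pool is at unit concentration).
    HPs with identical composition signatures are kinetically
    interchangeable and grouped for efficiency.
    """
    classes: dict[tuple, list[HPState]] = {}
    for hp in hps:
        classes.setdefault(hp.signature(), []).append(hp)
    keys = list(classes)
    reps = {k: classes[k][0] for k in keys}
    pair_rate = {
        (ka, kb): dimerization_rate(reps[ka], reps[kb], params) / max(n_scale, 1)
        for ai, ka in enumerate(keys)
        for kb in keys[ai:]
    }
    t = 0.0
    formed: list[tuple[float, HPState, HPState]] = []
    while True:
        props = []
        for (ka, kb), r in pair_rate.items():
            if r == 0:
                continue
            na, nb = len(classes[ka]), len(classes[kb])
            n_pairs = na * (na - 1) / 2 if ka == kb else na * nb
            if n_pairs > 0:
                props.append((r * n_pairs, ka, kb))
        total = sum(p[0] for p in props)
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        u = rng.random() * total
        acc = 0.0
        for rate, ka, kb in props:
            acc += rate
            if u <= acc:
                break
        pool_a = classes[ka]
        hp_a = pool_a.pop(int(rng.integers(len(pool_a))))
        pool_b = classes[kb]
        hp_b = pool_b.pop(int(rng.integers(len(pool_b))))
        formed.append((t, hp_a, hp_b))
    return formed


def simulate(
    pool: Sequence[HPState | CPState],
    params: RateParameters,
    model: str = "cooperative",
    t_end: float = 120.0,
    n_record_times: int = 50,
    seed: int = 0,
    topology: nx.Graph | None = None,
    record_events: bool = False,
) -> TrajectorySet:
    """Simulate a population of HPs (and/or pre-formed CPs) to ``t_end``.

    The run is an exact stochastic simulation: dimerization events are
    drawn first (they are independent of internal propeptide states),
    then each CP's internal maturation evolves from its formation time.
    Deterministic given ``seed``.
    """
    if model not in ("independent", "cooperative"):
        raise ValueError(f"model must be 'independent' or 'cooperative', got {model!r}")
    if model == "cooperative" and params.k_auto_fast < params.k_auto_slow:
        raise ValueError("cooperative regime requires k_auto_fast >= k_auto_slow")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not pool:
        raise ValueError("pool is empty")
    override_topology = topology is not None
    if topology is None:
        topology = build_topology("intra_plus_cross")

    rng = np.random.default_rng(seed)
    record_times = np.linspace(0.0, t_end, n_record_times)

    def _copy_hp(hp: HPState) -> HPState:
        return HPState(
            subunits=[SubunitState(spec=s.spec, propeptide=s.propeptide) for s in hp.subunits]
        )

    # work on copies so a pool can be reused across runs
    hps = [_copy_hp(p) for p in pool if isinstance(p, HPState)]
    cps: list[CPState] = []
    for p in pool:
        if isinstance(p, CPState):
            cps.append(
                CPState(
                    ring_a=_copy_hp(p.ring_a),
                    ring_b=_copy_hp(p.ring_b),
                    topology=topology if override_topology else p.topology,
                    formation_time=p.formation_time,
                )
            )

    formed = _simulate_dimerization(hps, params, rng, t_end, n_scale=len(hps)) if hps else []
    for t0, hp_a, hp_b in formed:
        cps.append(CPState(ring_a=hp_a, ring_b=hp_b, topology=topology, formation_time=t0))

    events: list[Event] | None = [] if record_events else None
    counts = np.full((len(record_times), len(cps)), np.nan)
    for idx, cp in enumerate(cps):
        counts[:, idx] = _simulate_cp(cp, params, model, record_times, rng, idx, events)

    formation_times = np.array([cp.formation_time for cp in cps])
    n_preformed = sum(1 for p in pool if isinstance(p, CPState))
    free_hp = np.array(
        [len(hps) - 2 * sum(1 for t0, _, _ in formed if t0 <= t) for t in record_times]
    )
    tallies = np.zeros((len(record_times), 3))
    # tallies are reconstructed from counts: processed known exactly; the
    # intact/cross_cut split within CPs is only tracked in final states and
    # the event log, so tally cross_cut from events when recorded.
    for ti, t in enumerate(record_times):
        alive = formation_times <= t
        n_sub = int(alive.sum()) * N_SITES
        n_proc = np.nansum(counts[ti, alive]) if alive.any() else 0.0
        n_cc = 0
        if events is not None:
            per_site: dict[tuple[int, int], str] = {}
            for ev in events:
                if ev.time <= t:
                    per_site[(ev.cp_index, ev.site)] = ev.kind
            n_cc = sum(1 for k in per_site.values() if k == "cross_cut")
        tallies[ti] = (n_sub - n_proc - n_cc, n_cc, n_proc)

    return TrajectorySet(
        record_times=record_times,
        processed_counts=counts,
        cp_formation_times=formation_times,
        free_hp=free_hp,
        state_tallies=tallies,
        n_hp_initial=len(hps) + 2 * n_preformed,
        cps=cps,
        events=events or [],
    )


def preformed_cp_pool(
    n_cp: int,
    spec: SubunitSpec = WT,
    topology: nx.Graph | None = None,
) -> list[CPState]:
    """A population of already-dimerized CPs with all propeptides intact."""
    if topology is None:
        topology = build_topology("intra_plus_cross")
    return [
        CPState(
            ring_a=HPState.uniform(spec),
            ring_b=HPState.uniform(spec),
            topology=topology,
            formation_time=0.0,
        )
        for _ in range(n_cp)
    ]


def processed_count_distribution(traj: TrajectorySet, t: float) -> MaturationDistribution:
    """Normalized histogram of per-CP processed counts at time ``t``.

    Only CPs formed by ``t`` contribute; free HPs are excluded.  With no
    CPs present the distribution is flagged empty rather than erroring.
    """
    times = traj.record_times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside recorded range [{times[0]}, {times[-1]}]")
    ti = int(np.argmin(np.abs(times - t)))
    row = traj.processed_counts[ti]
    vals = row[~np.isnan(row)].astype(int)
    hist = np.zeros(15)
    if len(vals) == 0:
        return MaturationDistribution(time=float(times[ti]), histogram=hist, n_cps=0, empty=True)
    for v in vals:
        hist[v] += 1
    hist /= hist.sum()
    return MaturationDistribution(
        time=float(times[ti]), histogram=hist, n_cps=len(vals), empty=False
    )
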