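"""Exact stochastic simulation (Gillespie direct method) of a compiled network.

One simulation corresponds to one cell.  The state is the vector of free
monomer counts per species plus one occupancy slot per promoter copy (free,
or bound by exactly one activator-oligomer configuration).  Propensities:

* binding of config (X, n):   ``A1 * [promoter free] * C(x, n)``, with x the
  free-monomer count of X and C the binomial coefficient (number of distinct
  oligomers that can assemble);
* unbinding:                  ``A2 * [bound in that config]``;
* production while bound:     ``rate * [bound]``;
* degradation:                ``A4 * x`` (free monomers only — monomers
  sequestered in a bound oligomer are protected and restored exactly on
  unbinding);
* basal production:           ``basal_rate * [promoter free]``.

Event times are sampled from the exponential waiting-time distribution with
the total propensity; the channel is chosen proportionally to its propensity
(direct method).  Counts are right-continuous: a query at an event time
returns the post-event value.  Time is continuous in an arbitrary unit; the
conventional observation horizon is t_end = 100.

The inner loop is compiled with numba; a per-cell integer seed makes every
trajectory bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import CompiledNetwork, NetworkModel, compile_network

__all__ = [
    "SimState",
    "Trajectory",
    "CellSummary",
    "propensities",
    "simulate_cell",
    "simulate_cell_summary",
    "integrate_species",
    "endpoint",
]

_FREE = -1  # occupancy code for an unbound promoter slot


@dataclass
class SimState:
    """Instantaneous simulator state: free-monomer counts + promoter occupancy."""

    time: float
    counts: np.ndarray      # int64[S], free monomers
    occupancy: np.ndarray   # int64[P], _FREE or bound config index


@dataclass
class CellSummary:
    """Endpoint-only view of one cell's simulation (no event path retained)."""

    final_counts: np.ndarray
    final_occupancy: np.ndarray
    integrals: np.ndarray       # one per requested (species, t0, t1) window
    n_events: int
    seed: int
    t_end: float


# ---------------------------------------------------------------------------
# Propensity vector (reference definition; the kernel mirrors it)
# ---------------------------------------------------------------------------

def _comb_float(x: int, n: int) -> float:
    if x < n:
        return 0.0
    r = 1.0
    for i in range(n):
        r *= x - i
    for i in range(2, n + 1):
        r /= i
    return r


def propensities(state: SimState, compiled: CompiledNetwork) -> np.ndarray:
    """Per-channel propensities in the kernel's full channel enumeration.

    Order: [bind_i, unbind_i, produce_i] for each activator config i, then one
    degradation channel per species, then one basal channel per promoter slot.
    An all-zero vector signals an absorbed state.
    """
    C = compiled.n_configs
    S = compiled.n_species
    P = compiled.n_promoters
    a = np.zeros(3 * C + S + P)
    for i in range(C):
        p = compiled.cfg_promoter[i]
        if state.occupancy[p] == _FREE:
            x = state.counts[compiled.cfg_activator[i]]
            a[3 * i] = compiled.cfg_bind[i] * _comb_float(int(x), int(compiled.cfg_order[i]))
        elif state.occupancy[p] == i:
            a[3 * i + 1] = compiled.cfg_unbind[i]
            a[3 * i + 2] = compiled.cfg_rate[i]
    for s in range(S):
        a[3 * C + s] = compiled.deg_rates[s] * state.counts[s]
    for p in range(P):
        if state.occupancy[p] == _FREE:
            a[3 * C + S + p] = compiled.basal_rates[p]
    return a


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _comb_nb(x, n):
    if x < n:
        return 0.0
    r = 1.0
    for i in range(n):
        r *= x - i
    for i in range(2, n + 1):
        r /= i
    return r


@njit(cache=True)
def _ssa_kernel(
    seed,
    counts,          # int64[S], modified in place
    occ,             # int64[P], modified in place
    deg,
    cfg_promoter, cfg_activator, cfg_order, cfg_bind, cfg_unbind, cfg_rate, cfg_product,
    basal_rates, basal_products,
    t_end,
    win_species, win_t0, win_t1,
    integrals,       # float64[W], modified in place
    record,          # bool
    ev_time, ev_code,  # preallocated when recording
):
    """Direct-method loop.  Returns (n_events, status); status 1 = event-log
    overflow (caller enlarges the log and reruns with the same seed)."""
    np.random.seed(seed)
    C = cfg_promoter.shape[0]
    S = counts.shape[0]
    P = occ.shape[0]
    W = win_species.shape[0]
    a = np.zeros(3 * C + S + P)
    t = 0.0
    n_ev = 0
    while True:
        total = 0.0
        for i in range(C):
            p = cfg_promoter[i]
            b = 0.0
            u = 0.0
            pr = 0.0
            if occ[p] == -1:
                b = cfg_bind[i] * _comb_nb(counts[cfg_activator[i]], cfg_order[i])
            elif occ[p] == i:
                u = cfg_unbind[i]
                pr = cfg_rate[i]
            a[3 * i] = b
            a[3 * i + 1] = u
            a[3 * i + 2] = pr
            total += b + u + pr
        for s in range(S):
            v = deg[s] * counts[s]
            a[3 * C + s] = v
            total += v
        for p in range(P):
            v = basal_rates[p] if occ[p] == -1 else 0.0
            a[3 * C + S + p] = v
            total += v

        if total <= 0.0:
            t_next = t_end
        else:
            r1 = np.random.random()
            while r1 <= 0.0:
                r1 = np.random.random()
            t_next = t + (-np.log(r1) / total)
            if t_next > t_end:
                t_next = t_end

        # accumulate window integrals over [t, t_next)
        for w in range(W):
            lo = t if t > win_t0[w] else win_t0[w]
            hi = t_next if t_next < win_t1[w] else win_t1[w]
            if hi > lo:
                integrals[w] += counts[win_species[w]] * (hi - lo)

        if total <= 0.0 or t_next >= t_end:
            return n_ev, 0

        # choose channel proportionally
        u = np.random.random() * total
        acc = 0.0
        chan = 3 * C + S + P - 1
        for k in range(3 * C + S + P):
            acc += a[k]
            if u < acc:
                chan = k
                break

        # apply update
        if chan < 3 * C:
            i = chan // 3
            kind = chan - 3 * i
            p = cfg_promoter[i]
            if kind == 0:      # bind: sequester n monomers
                counts[cfg_activator[i]] -= cfg_order[i]
                occ[p] = i
            elif kind == 1:    # unbind: restore monomers
                counts[cfg_activator[i]] += cfg_order[i]
                occ[p] = -1
            else:              # produce
                counts[cfg_product[i]] += 1
        elif chan < 3 * C + S:
            counts[chan - 3 * C] -= 1
        else:
            counts[basal_products[chan - 3 * C - S]] += 1

        t = t_next
        if record:
            if n_ev >= ev_time.shape[0]:
                return n_ev, 1
            ev_time[n_ev] = t
            ev_code[n_ev] = chan
        n_ev += 1


def _run_kernel(compiled, counts, occ, t_end, seed, win_species, win_t0, win_t1,
                record, max_events):
    ev_time = np.empty(max_events if record else 0, dtype=np.float64)
    ev_code = np.empty(max_events if record else 0, dtype=np.int64)
    while True:
        c = counts.copy()
        o = occ.copy()
        integrals = np.zeros(len(win_species))
        n_ev, status = _ssa_kernel(
            seed, c, o,
            compiled.deg_rates,
            compiled.cfg_promoter, compiled.cfg_activator, compiled.cfg_order,
            compiled.cfg_bind, compiled.cfg_unbind, compiled.cfg_rate, compiled.cfg_product,
            compiled.basal_rates, compiled.basal_products,
            float(t_end),
            win_species, win_t0, win_t1,
            integrals,
            record,
            ev_time, ev_code,
        )
        if status == 0:
            return c, o, integrals, n_ev, ev_time[:n_ev], ev_code[:n_ev]
        # overflow while recording: enlarge log, rerun same seed (identical path)
        ev_time = np.empty(2 * len(ev_time), dtype=np.float64)
        ev_code = np.empty(2 * len(ev_code), dtype=np.int64)


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

class Trajectory:
    """A single cell's piecewise-constant molecule-count path.

    ``times[0] == 0`` holds the initial state; each later row is the state
    immediately after one reaction event.  Queries are right-continuous: the
    state at time t is the state after the latest event with time <= t.
    """

    def __init__(self, times, counts, occupancy, t_end, species_names, event_codes=None):
        self.times = times
        self.counts = counts            # int64[n_points, S]
        self.occupancy = occupancy      # int64[n_points, P]
        self.t_end = float(t_end)
        self.species_names = list(species_names)
        self.event_codes = event_codes

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    def _species_idx(self, species: str) -> int:
        try:
            return self.species_names.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def state_at(self, t: float) -> SimState:
        if t < 0 or t > self.t_end:
            raise ValueError(f"t={t} outside [0, {self.t_end}]")
        i = np.searchsorted(self.times, t, side="right") - 1
        return SimState(time=t, counts=self.counts[i].copy(),
                        occupancy=self.occupancy[i].copy())

    def endpoint(self, species: str, t: float) -> int:
        s = self._species_idx(species)
        if t < 0 or t > self.t_end:
            raise ValueError(f"t={t} outside [0, {self.t_end}]")
        i = np.searchsorted(self.times, t, side="right") - 1
        return int(self.counts[i, s])

    def integrate(self, species: str, t0: float, t1: float) -> float:
        s = self._species_idx(species)
        if not (0 <= t0 < t1 <= self.t_end):
            raise ValueError(f"window [{t0}, {t1}] is not inside [0, {self.t_end}]")
        # piecewise-constant exact integral
        knots = np.concatenate([self.times, [self.t_end]])
        total = 0.0
        for i in range(len(self.times)):
            lo = max(knots[i], t0)
            hi = min(knots[i + 1], t1)
            if hi > lo:
                total += self.counts[i, s] * (hi - lo)
        return float(total)

    def to_frame(self):
        """Tidy event table: one row per state interval, one column per species."""
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df


def integrate_species(trajectory: Trajectory, species: str, t0: float, t1: float) -> float:
    """Exact integral of the piecewise-constant count path over [t0, t1]."""
    return trajectory.integrate(species, t0, t1)


def endpoint(trajectory: Trajectory, species: str, t: float) -> int:
    """Right-continuous count of ``species`` at time t."""
    return trajectory.endpoint(species, t)


# ---------------------------------------------------------------------------
# Public simulation entry points
# ---------------------------------------------------------------------------

def _as_compiled(model) -> CompiledNetwork:
    if isinstance(model, CompiledNetwork):
        return model
    if isinstance(model, NetworkModel):
        return compile_network(model)
    raise TypeError(f"expected NetworkModel or CompiledNetwork, got {type(model)!r}")


def _initial_vector(compiled: CompiledNetwork, initial_counts) -> np.ndarray:
    S = compiled.n_species
    counts = np.zeros(S, dtype=np.int64)
    if initial_counts is None:
        return counts
    if isinstance(initial_counts, dict):
        for name, v in initial_counts.items():
            counts[compiled.species_names.index(name)] = int(v)
    else:
        arr = np.asarray(initial_counts, dtype=np.int64)
        if arr.shape != (S,):
            raise ValueError(f"initial_counts must have shape ({S},)")
        counts[:] = arr
    if (counts < 0).any():
        raise ValueError("initial counts must be nonnegative")
    return counts


def _window_arrays(compiled, windows):
    windows = windows or []
    ws = np.array([compiled.species_names.index(sp) for sp, _, _ in windows], dtype=np.int64)
    w0 = np.array([t0 for _, t0, _ in windows], dtype=np.float64)
    w1 = np.array([t1 for _, _, t1 in windows], dtype=np.float64)
    return ws, w0, w1


def simulate_cell(model, initial_counts, t_end: float, seed: int,
                  windows=None) -> Trajectory:
    """Run one exact SSA realization and return the full event path.

    ``windows`` is an optional list of (species, t0, t1) integration windows;
    their values are recomputed exactly from the returned trajectory, so the
    argument exists only for API symmetry with the summary path.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    compiled = _as_compiled(model)
    counts0 = _initial_vector(compiled, initial_counts)
    ws, w0, w1 = _window_arrays(compiled, windows)
    _, _, _, n_ev, ev_time, ev_code = _run_kernel(
        compiled, counts0, np.full(compiled.n_promoters, _FREE, dtype=np.int64),
        t_end, int(seed), ws, w0, w1, True, max_events=4096,
    )
    # replay the event log into explicit state rows
    S, P, Ccfg = compiled.n_species, compiled.n_promoters, compiled.n_configs
    counts = np.empty((n_ev + 1, S), dtype=np.int64)
    occ = np.empty((n_ev + 1, P), dtype=np.int64)
    counts[0] = counts0
    occ[0] = _FREE
    for k in range(n_ev):
        counts[k + 1] = counts[k]
        occ[k + 1] = occ[k]
        chan = ev_code[k]
        if chan < 3 * Ccfg:
            i, kind = divmod(chan, 3)
            p = compiled.cfg_promoter[i]
            if kind == 0:
                counts[k + 1, compiled.cfg_activator[i]] -= compiled.cfg_order[i]
                occ[k + 1, p] = i
            elif kind == 1:
                counts[k + 1, compiled.cfg_activator[i]] += compiled.cfg_order[i]
                occ[k + 1, p] = _FREE
            else:
                counts[k + 1, compiled.cfg_product[i]] += 1
        elif chan < 3 * Ccfg + S:
            counts[k + 1, chan - 3 * Ccfg] -= 1
        else:
            counts[k + 1, compiled.basal_products[chan - 3 * Ccfg - S]] += 1
    times = np.concatenate([[0.0], ev_time])
    return Trajectory(times, counts, occ, t_end, compiled.species_names,
                      event_codes=ev_code)


def simulate_cell_summary(model, initial_counts, t_end: float, seed: int,
                          windows=None) -> CellSummary:
    """Run one realization keeping only endpoints and window integrals.

    Bit-identical in law and in realization to :func:`simulate_cell` at the
    same seed; used for large ensembles where event paths are not needed.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    compiled = _as_compiled(model)
    counts0 = _initial_vector(compiled, initial_counts)
    ws, w0, w1 = _window_arrays(compiled, windows)
    c, o, integrals, n_ev, _, _ = _run_kernel(
        compiled, counts0, np.full(compiled.n_promoters, _FREE, dtype=np.int64),
        t_end, int(seed), ws, w0, w1, False, max_events=0,
    )
    return CellSummary(final_counts=c, final_occupancy=o, integrals=integrals,
                       n_events=n_ev, seed=int(seed), t_end=float(t_end))
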