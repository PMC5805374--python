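"""Event-driven TASEP simulation of ribosome traffic on one transcript.

The model: an ORF of N codon sites, each occupiable by at most one ribosome
A-site; a ribosome spans L sites, so two A-sites must be >= L apart.  Events
are (1) an initiation attempt at rate λ, succeeding iff no ribosome sits at a
site <= L; (2) a jump attempt of the ribosome at site i at rate λ_i,
succeeding iff no downstream ribosome sits at j <= i+L, and otherwise marking
the ribosome as queued (d_i := 1, cleared on the next successful jump);
(3) the jump out of site N, which is termination at the termination rate.
Waiting times between events are exponential with total rate
μ = λ + Σ_i n_i λ_i; a specific event is an initiation attempt with
probability λ/μ and a jump attempt of the ribosome at i with probability
n_i λ_i / μ.  Blocked ribosomes keep their full rate in μ and generate null
(failed) jump events — this is what sets d_i.

Two interchangeable backends are provided: a numba kernel (default) and a
pure-Python reference built from the elementary operations
:func:`total_event_rate` / :func:`draw_event` / :func:`apply_event`.  An
exact stationary solver for small lattices (:func:`exact_stationary`) serves
as an independent oracle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import SimConfig, Transcript

__all__ = [
    "SimState",
    "SimResult",
    "total_event_rate",
    "draw_event",
    "apply_event",
    "simulate",
    "exact_stationary",
    "gene_seed",
]


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Stable per-gene RNG seed below 2**31."""
    return (zlib.crc32(f"{global_seed}:{gene_id}".encode()) ^ global_seed) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Elementary operations (pure-Python reference semantics)
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Ribosome configuration on one transcript.

    ``positions`` are A-site codon positions (1-based), ascending (index 0 is
    the most upstream ribosome); ``queued[j]`` is the d-flag of ribosome j.
    """

    positions: list[int] = field(default_factory=list)
    queued: list[bool] = field(default_factory=list)
    clock: float = 0.0

    @property
    def queue_flag(self) -> bool:
        """Transcript-level q: 1 while any ribosome is delayed."""
        return any(self.queued)

    def check(self, L: int) -> None:
        for a, b in zip(self.positions, self.positions[1:]):
            assert b - a >= L, f"exclusion violated: {a},{b} with L={L}"


def _out_rate(transcript: Transcript, site: int) -> float:
    """Jump rate out of a 1-based site; site N jumps at the termination rate."""
    if site == transcript.n_codons:
        return float(transcript.termination_rate)
    return float(transcript.site_rates[site - 1])


def total_event_rate(state: SimState, transcript: Transcript, lam: float) -> float:
    """μ = λ + Σ_i n_i λ_i, counting blocked ribosomes' rates."""
    return lam + sum(_out_rate(transcript, p) for p in state.positions)


def draw_event(
    state: SimState, transcript: Transcript, lam: float, rng: np.random.Generator
) -> tuple[tuple, float]:
    """Draw (event, dt): dt ~ Exp(μ); the event is an initiation attempt with
    probability λ/μ, else a jump/termination attempt of ribosome j with
    probability λ_{pos_j}/μ."""
    mu = total_event_rate(state, transcript, lam)
    if not mu > 0:
        raise ValueError("total event rate must be positive")
    dt = rng.exponential(1.0 / mu)
    r = rng.uniform(0.0, mu)
    if r < lam:
        return ("init",), dt
    r -= lam
    for j, p in enumerate(state.positions):
        r -= _out_rate(transcript, p)
        if r < 0:
            return ("jump", j), dt
    return ("jump", len(state.positions) - 1), dt  # float guard


def apply_event(
    state: SimState, event: tuple, transcript: Transcript, L: int
) -> tuple[SimState, bool]:
    """Apply one event in place; returns (state, terminated).

    Initiation succeeds iff no ribosome sits at a site <= L (the entering
    A-site is site 1).  A jump from i succeeds iff the nearest downstream
    neighbour j satisfies j - i > L; a failed jump sets the ribosome's d-flag,
    a successful one clears it.  A jump from site N is termination.
    """
    terminated = False
    if event[0] == "init":
        if not state.positions or state.positions[0] > L:
            state.positions.insert(0, 1)
            state.queued.insert(0, False)
    else:
        j = event[1]
        pos = state.positions[j]
        if pos == transcript.n_codons:
            assert j == len(state.positions) - 1
            state.positions.pop(j)
            state.queued.pop(j)
            terminated = True
        elif j + 1 < len(state.positions) and state.positions[j + 1] - pos <= L:
            state.queued[j] = True
        else:
            state.positions[j] = pos + 1
            state.queued[j] = False
    return state, terminated


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Time-averaged steady-state summaries of one simulated gene."""

    gene_id: str
    initiation_rate: float
    n_codons: int
    translation_rate: float
    mean_ribosomes: float
    density_profile: np.ndarray
    queued_profile: np.ndarray
    footprint_profiles: dict[int, np.ndarray]  # spacing -> (kmax, N) array
    queue_probability: float
    mean_translation_time: float
    mean_delay_time: float
    n_terminations: int
    total_time: float
    seed: int

    @property
    def qfr(self) -> float:
        """Queued fraction of ribosomes: Σ queued density / Σ density."""
        tot = float(self.density_profile.sum())
        return float(self.queued_profile.sum()) / tot if tot > 0 else 0.0

    def regional_qfr(self, start: int, stop: int) -> float:
        """QFR restricted to 1-based codon window [start, stop]."""
        d = self.density_profile[start - 1 : stop]
        q = self.queued_profile[start - 1 : stop]
        tot = float(d.sum())
        return float(q.sum()) / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel(out_rates, lam, L, warmup, monitored, n_spacings, kmax, max_events, seed,
            track_profiles):  # pragma: no cover - exercised via simulate()
    N = out_rates.shape[0]
    np.random.seed(seed)
    max_r = N // L + 2
    pos = np.zeros(max_r, dtype=np.int64)
    dflag = np.zeros(max_r, dtype=np.uint8)
    tstart = np.zeros(max_r, dtype=np.float64)
    dl_acc = np.zeros(max_r, dtype=np.float64)
    R = 0

    density = np.zeros(N)
    queued = np.zeros(N)
    fp = np.zeros((n_spacings, kmax, N))
    q_time = 0.0
    total_time = 0.0
    n_term = 0
    sum_tt = 0.0
    sum_dl = 0.0

    t = 0.0
    events = 0
    target = warmup
    monitoring = False
    status = 1  # 1 = hit event cap without finishing

    while events < max_events:
        events += 1
        mu = lam
        for j in range(R):
            mu += out_rates[pos[j] - 1]
        dt = -np.log(np.random.random()) / mu

        if monitoring:
            total_time += dt
            anyd = False
            for j in range(R):
                density[pos[j] - 1] += dt
                if dflag[j] == 1:
                    queued[pos[j] - 1] += dt
                    anyd = True
            if anyd:
                q_time += dt
            for j in range(R):
                dl_acc[j] += dt if dflag[j] == 1 else 0.0
            if track_profiles and R > 0:
                for s in range(n_spacings):
                    j0 = 0
                    while j0 < R:
                        j1 = j0
                        while j1 + 1 < R and pos[j1 + 1] - pos[j1] - L <= s:
                            j1 += 1
                        k = j1 - j0 + 1
                        if k > kmax:
                            k = kmax
                        fp[s, k - 1, pos[j0] - 1] += dt
                        j0 = j1 + 1
        else:
            for j in range(R):
                dl_acc[j] += dt if dflag[j] == 1 else 0.0

        t += dt

        # event selection
        r = np.random.random() * mu
        if r < lam:
            # initiation attempt
            if R == 0 or pos[0] > L:
                for j in range(R, 0, -1):
                    pos[j] = pos[j - 1]
                    dflag[j] = dflag[j - 1]
                    tstart[j] = tstart[j - 1]
                    dl_acc[j] = dl_acc[j - 1]
                pos[0] = 1
                dflag[0] = 0
                tstart[0] = t
                dl_acc[0] = 0.0
                R += 1
        else:
            r -= lam
            sel = -1
            for j in range(R):
                r -= out_rates[pos[j] - 1]
                if r < 0.0:
                    sel = j
                    break
            if sel >= 0:
                p = pos[sel]
                if p == N:
                    # termination
                    n_term += 1
                    if monitoring:
                        sum_tt += t - tstart[sel]
                        sum_dl += dl_acc[sel]
                    R -= 1
                    if n_term >= target:
                        if monitoring:
                            status = 0
                            break
                        # warm-up complete: reset accumulators, start monitoring
                        monitoring = True
                        n_term = 0
                        target = monitored
                        density[:] = 0.0
                        queued[:] = 0.0
                        fp[:, :, :] = 0.0
                        q_time = 0.0
                        total_time = 0.0
                        sum_tt = 0.0
                        sum_dl = 0.0
                elif sel + 1 < R and pos[sel + 1] - p <= L:
                    dflag[sel] = 1
                else:
                    pos[sel] = p + 1
                    dflag[sel] = 0

    return (density, queued, fp, q_time, total_time, n_term, sum_tt, sum_dl,
            events, status)


# ---------------------------------------------------------------------------
# Python reference backend
# ---------------------------------------------------------------------------

def _simulate_python(transcript, config, spacings, kmax, seed):
    rng = np.random.default_rng(seed)
    N = transcript.n_codons
    L = config.ribosome_size
    lam = config.initiation_rate
    state = SimState()
    density = np.zeros(N)
    queued = np.zeros(N)
    fp = np.zeros((len(spacings), kmax, N))
    q_time = total_time = sum_tt = sum_dl = 0.0
    n_term = 0
    tstart: list[float] = []
    dl: list[float] = []
    monitoring = False
    target = config.warmup_terminations
    events = 0
    while events < config.max_events:
        events += 1
        event, dt = draw_event(state, transcript, lam, rng)
        if monitoring:
            total_time += dt
            anyd = False
            for j, p in enumerate(state.positions):
                density[p - 1] += dt
                if state.queued[j]:
                    queued[p - 1] += dt
                    anyd = True
            if anyd:
                q_time += dt
            for s_idx, s in enumerate(spacings):
                for k, p0 in assign_footprints(state.positions, L, s):
                    fp[s_idx, min(k, kmax) - 1, p0 - 1] += dt
        for j in range(len(state.positions)):
            if state.queued[j]:
                dl[j] += dt
        state.clock += dt
        was_init = event[0] == "init" and (
            not state.positions or state.positions[0] > L
        )
        state, terminated = apply_event(state, event, transcript, L)
        state.check(L)
        if was_init:
            tstart.insert(0, state.clock)
            dl.insert(0, 0.0)
        if terminated:
            n_term += 1
            if monitoring:
                sum_tt += state.clock - tstart.pop()
                sum_dl += dl.pop()
            else:
                tstart.pop()
                dl.pop()
            if n_term >= target:
                if monitoring:
                    return density, queued, fp, q_time, total_time, n_term, sum_tt, sum_dl
                monitoring = True
                n_term = 0
                target = config.monitored_terminations
                density[:] = queued[:] = 0.0
                fp[:] = 0.0
                q_time = total_time = sum_tt = sum_dl = 0.0
    raise RuntimeError(
        f"{transcript.gene_id}: no steady state within {config.max_events} events; "
        "parameters may be infeasible"
    )


# local import placed here to avoid a cycle at module load
from .footprints import assign_footprints  # noqa: E402


# ---------------------------------------------------------------------------
# Public simulate
# ---------------------------------------------------------------------------

def simulate(
    transcript: Transcript,
    config: SimConfig,
    *,
    track_profiles: bool = True,
    backend: str = "numba",
) -> SimResult:
    """Simulate one gene to steady state and time-average its traffic.

    The lattice starts empty, runs until ``warmup_terminations`` terminations,
    then integrates occupancy (n_i), queued state (d_i), footprint states
    (m_i^k for every spacing 0..config.spacing) and the transcript queue flag
    q over ``monitored_terminations`` further terminations.
    """
    if not transcript.has_rates:
        raise ValueError(f"{transcript.gene_id}: transcript has no rates")
    N = transcript.n_codons
    L = config.ribosome_size
    if not N > L // 2:
        raise ValueError(f"{transcript.gene_id}: need N > L/2 (N={N}, L={L})")
    spacings = list(range(config.spacing + 1))
    # exact upper bound on cluster size: no clamping, so the census conserves
    # ribosomes across footprint sizes to float precision
    kmax = N // L + 1
    seed = config.seed % (2**31 - 1)

    out_rates = np.asarray(transcript.site_rates, dtype=np.float64).copy()
    out_rates[N - 1] = transcript.termination_rate

    if backend == "python":
        density, queued, fp, q_time, total_time, n_term, sum_tt, sum_dl = (
            _simulate_python(transcript, config, spacings, kmax, seed)
        )
    elif backend == "numba":
        (density, queued, fp, q_time, total_time, n_term, sum_tt, sum_dl,
         _events, status) = _kernel(
            out_rates, float(config.initiation_rate), L,
            config.warmup_terminations, config.monitored_terminations,
            len(spacings) if track_profiles else 0, kmax,
            config.max_events, seed, track_profiles,
        )
        if status != 0:
            raise RuntimeError(
                f"{transcript.gene_id}: no steady state within "
                f"{config.max_events} events; parameters may be infeasible"
            )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if total_time <= 0:
        raise RuntimeError(f"{transcript.gene_id}: zero monitored time")
    fp_profiles = {
        s: fp[i] / total_time for i, s in enumerate(spacings)
    } if track_profiles else {}
    return SimResult(
        gene_id=transcript.gene_id,
        initiation_rate=config.initiation_rate,
        n_codons=N,
        translation_rate=n_term / total_time,
        mean_ribosomes=float(density.sum()) / total_time,
        density_profile=density / total_time,
        queued_profile=queued / total_time,
        footprint_profiles=fp_profiles,
        queue_probability=q_time / total_time,
        mean_translation_time=sum_tt / n_term if n_term else float("nan"),
        mean_delay_time=sum_dl / n_term if n_term else float("nan"),
        n_terminations=int(n_term),
        total_time=float(total_time),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact stationary oracle (small lattices)
# ---------------------------------------------------------------------------

def exact_stationary(
    transcript: Transcript,
    L: int,
    lam: float,
    *,
    max_states: int = 1_000_000,
) -> tuple[np.ndarray, float, float]:
    """Exact stationary density, translation rate and queue probability.

    Enumerates every reachable (positions, d-flags) configuration of the same
    continuous-time Markov chain as the simulator, solves πQ = 0 by least
    squares, and returns exact expectations.  Intended for N <= ~12.
    """
    if not transcript.has_rates:
        raise ValueError("transcript has no rates")
    N = transcript.n_codons
    if not N > L // 2:
        raise ValueError(f"need N > L/2 (N={N}, L={L})")

    out = np.asarray(transcript.site_rates, dtype=float).copy()
    out[N - 1] = transcript.termination_rate

    def successors(state):
        positions, dflags = state
        res = []
        # initiation
        if not positions or positions[0] > L:
            res.append((lam, ((1,) + positions, (0,) + dflags)))
        for j, p in enumerate(positions):
            rate = out[p - 1]
            if p == N:
                res.append((rate, (positions[:j], dflags[:j])))
            elif j + 1 < len(positions) and positions[j + 1] - p <= L:
                if dflags[j] == 0:
                    nd = dflags[:j] + (1,) + dflags[j + 1 :]
                    res.append((rate, (positions, nd)))
                # already flagged: null event, no state change
            else:
                np_ = positions[:j] + (p + 1,) + positions[j + 1 :]
                nd = dflags[:j] + (0,) + dflags[j + 1 :]
                res.append((rate, (np_, nd)))
        return res

    start = ((), ())
    index = {start: 0}
    order = [start]
    frontier = [start]
    while frontier:
        nxt = []
        for st in frontier:
            for _, s2 in successors(st):
                if s2 not in index:
                    if len(index) >= max_states:
                        raise ValueError("state space too large")
                    index[s2] = len(order)
                    order.append(s2)
                    nxt.append(s2)
        frontier = nxt

    n = len(order)
    Q = np.zeros((n, n))
    for st in order:
        i = index[st]
        for rate, s2 in successors(st):
            j = index[s2]
            if j != i:
                Q[i, j] += rate
                Q[i, i] -= rate
    # solve pi Q = 0, sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    density = np.zeros(N)
    rate_flux = 0.0
    q_prob = 0.0
    for st, p in zip(order, pi):
        positions, dflags = st
        for pos in positions:
            density[pos - 1] += p
        if positions and positions[-1] == N:
            rate_flux += p * out[N - 1]
        if any(dflags):
            q_prob += p
    return density, float(rate_flux), float(q_prob)
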