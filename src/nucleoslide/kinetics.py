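"""Small Markov rate models of nucleosome repositioning routes.

Repositioning from the crystal configuration to the 10-bp-shifted state
can proceed through three alternative intermediates: the 5-bp-shifted
state (rotation-uncoupled jumps), a 5-bp-rotated state (screw-like,
rotation-coupled) or a DNA loop defect (reptation).  Each route is a
3-state continuous-time Markov chain; rates not measurable directly can
be completed from detailed balance against a free-energy difference:

    k_forward = k_reverse * exp(-dF)        (dF in kBT)

Mean first passage times are solved exactly from the first-step linear
equations; a Gillespie stochastic-simulation oracle is provided for
cross-validation.  Times are in MD steps throughout, matching how the
underlying simulations report kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NucleoslideError


class UnreachableStateError(NucleoslideError):
    """No path from the start state to any target (infinite MFPT)."""


def detailed_balance_rate(k_reverse: float, delta_f: float) -> float:
    """Forward rate from the reverse rate and the free-energy cost
    (kBT) of the destination relative to the origin."""
    if k_reverse <= 0:
        raise ValueError("k_reverse must be positive")
    return k_reverse * math.exp(-delta_f)


@dataclass
class RateModel:
    """Labelled-state rate matrix.

    ``rates`` maps ``(from_state, to_state)`` to a rate in 1/MD-steps.
    Self-rates are forbidden; every non-absorbing state must have at
    least one outgoing rate.
    """

    states: list
    rates: dict = field(default_factory=dict)
    absorbing: frozenset = frozenset()

    def __post_init__(self):
        self.states = list(self.states)
        self.absorbing = frozenset(self.absorbing)
        idx = {s: i for i, s in enumerate(self.states)}
        for (a, b), k in self.rates.items():
            if a == b:
                raise ValueError("self-rates are not allowed")
            if a not in idx or b not in idx:
                raise ValueError(f"rate references unknown state ({a!r}, {b!r})")
            if k < 0:
                raise ValueError("rates must be non-negative")
        for s in self.states:
            if s in self.absorbing:
                continue
            if not any(a == s and k > 0 for (a, _), k in self.rates.items()):
                raise ValueError(f"non-absorbing state {s!r} has no outgoing rate")
        self._idx = idx

    def rate_matrix(self) -> np.ndarray:
        """Off-diagonal rate matrix Q[i, j] = k(i -> j)."""
        n = len(self.states)
        q = np.zeros((n, n))
        for (a, b), k in self.rates.items():
            q[self._idx[a], self._idx[b]] = k
        return q


def mfpt(model: RateModel, start, targets) -> float:
    """Exact mean first passage time (MD steps) from ``start`` to the
    target set, via the first-step linear system."""
    if isinstance(targets, (str, int)):
        targets = [targets]
    targets = set(targets)
    idx = model._idx
    if start in targets:
        return 0.0
    q = model.rate_matrix()
    non_t = [i for s, i in idx.items() if s not in targets]
    # reachability check on the embedded graph
    reach = {idx[start]}
    frontier = [idx[start]]
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(q[i] > 0)[0]:
            if j not in reach:
                reach.add(int(j))
                frontier.append(int(j))
    if not reach & {idx[t] for t in targets}:
        raise UnreachableStateError(f"targets {targets} unreachable from {start!r}")
    sub = {i: k for k, i in enumerate(non_t)}
    n = len(non_t)
    a = np.zeros((n, n))
    b = np.ones(n)
    for k, i in enumerate(non_t):
        out = q[i].sum()
        if out == 0:  # absorbing non-target state
            raise UnreachableStateError(
                f"state {model.states[i]!r} is absorbing but not a target")
        a[k, k] = out
        for j in np.nonzero(q[i] > 0)[0]:
            if int(j) in sub:
                a[k, sub[int(j)]] -= q[i, j]
    t = np.linalg.solve(a, b)
    return float(t[sub[idx[start]]])


def gillespie(model: RateModel, start, targets, n_replicates: int,
              seed: int = 0, max_events: int = 10**6):
    """Stochastic first-passage times: mean and standard error.

    Returns ``(mean, sem, samples)``.  A replicate exceeding
    ``max_events`` jumps raises (guards unreachable targets).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(targets, (str, int)):
        targets = [targets]
    targets = {model._idx[t] for t in targets}
    q = model.rate_matrix()
    rng = np.random.default_rng(seed)
    out_rates = q.sum(axis=1)
    samples = np.empty(n_replicates)
    for rep in range(n_replicates):
        i = model._idx[start]
        t = 0.0
        for _ in range(max_events):
            if i in targets:
                break
            k_tot = out_rates[i]
            if k_tot == 0:
                raise UnreachableStateError(
                    f"trapped in absorbing non-target state {model.states[i]!r}")
            t += rng.exponential(1.0 / k_tot)
            i = rng.choice(len(model.states), p=q[i] / k_tot)
        else:
            raise UnreachableStateError("max_events exceeded; target unreachable?")
        samples[rep] = t
    mean = float(samples.mean())
    sem = float(samples.std(ddof=1) / math.sqrt(n_replicates)) \
        if n_replicates > 1 else math.nan
    return mean, sem, samples


# ---------------------------------------------------------------------
# Shipped repositioning-route models
# ---------------------------------------------------------------------

#: Measured inverse rates (MD steps) for the loop-defect route: a
#: pre-formed end loop dissipates on its own end in ~8e4 steps and
#: diffuses across the wrap in ~7e6 steps; forming the loop costs
#: ~15 kBT and its rate follows from detailed balance.
LOOP_DISSIPATION_STEPS = 8e4
LOOP_DIFFUSION_STEPS = 7e6
LOOP_DELTA_F = 15.0


def loop_route_model(delta_f: float = LOOP_DELTA_F,
                     dissipation_steps: float = LOOP_DISSIPATION_STEPS,
                     diffusion_steps: float = LOOP_DIFFUSION_STEPS) -> RateModel:
    """3-state loop-defect (reptation) route: crystal <-> loop -> shifted."""
    k_dissipate = 1.0 / dissipation_steps
    k_diffuse = 1.0 / diffusion_steps
    k_form = detailed_balance_rate(k_dissipate, delta_f)
    return RateModel(
        states=["crystal", "loop", "shifted10"],
        rates={
            ("crystal", "loop"): k_form,
            ("loop", "crystal"): k_dissipate,
            ("loop", "shifted10"): k_diffuse,
        },
        absorbing={"shifted10"},
    )


def uncoupled_route_model(k_entry: float, k_exit: float) -> RateModel:
    """Rotation-uncoupled route through the 5-bp-shifted intermediate
    with symmetric exit rates."""
    return RateModel(
        states=["crystal", "shifted5", "shifted10"],
        rates={
            ("crystal", "shifted5"): k_entry,
            ("shifted5", "crystal"): k_exit,
            ("shifted5", "shifted10"): k_exit,
        },
        absorbing={"shifted10"},
    )


def coupled_route_model(k_rotate_in: float, k_rotate_back: float,
                        k_rotate_on: float) -> RateModel:
    """Rotation-coupled (screw-like) route through a 5-bp-rotated
    intermediate."""
    return RateModel(
        states=["crystal", "rotated5", "shifted10"],
        rates={
            ("crystal", "rotated5"): k_rotate_in,
            ("rotated5", "crystal"): k_rotate_back,
            ("rotated5", "shifted10"): k_rotate_on,
        },
        absorbing={"shifted10"},
    )
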