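"""Kinetic scheme assembly: weighted rate constants, state occupancies,
inter-state free-energy differences and the transmembrane cycling rate.

All quantities derive from uncensored dwell statistics of active
protomers.  The conventions are:

* the weighted rate constant of a transition is the inverse mean dwell
  of the source state times the branching fraction of that exit,
  ``k'(a->b) = n(a->b) / sum_c n(a->c) / <tau_a>``;
* the occupancy of a state is its total observed dwell time normalised
  over states, ``rho_a = n_a <tau_a> / sum_b n_b <tau_b>``;
* the energy difference between two states is
  ``dG(a<->b) = kB T ln(rho_a / rho_b)`` in units of kB T, so the more
  occupied state carries the positive sign;
* the cycling rate counts out<->in membrane crossings through any
  pathway, divided by two (a full cycle is two crossings) and by the
  total active observation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.constants import Avogadro, Boltzmann

from .dwells import DwellRecord
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "DwellSummary",
    "KineticScheme",
    "summarize_dwells",
    "weighted_rates",
    "occupancies",
    "energy_differences",
    "cycle_rate",
    "build_scheme",
]


@dataclass
class DwellSummary:
    """Per-state mean dwells and counts plus per-transition counts.

    ``mean_dwell`` and ``counts`` cover uncensored dwells only; the
    transition counts pool the observed exits of uncensored dwells, so
    the exits from a state never exceed its dwell count.
    ``total_time`` is the full observation time including censored
    dwells (used by the cycling rate).
    """

    mean_dwell: dict
    counts: dict
    transitions: dict
    total_time: Optional[float] = None

    def __post_init__(self):
        for (a, _b), n in self.transitions.items():
            if n < 0:
                raise ConfigurationError("transition counts must be non-negative")
        for a in set(a for a, _ in self.transitions):
            exits = sum(n for (s, _), n in self.transitions.items() if s == a)
            if exits > self.counts.get(a, 0):
                raise ConfigurationError(
                    f"state {a!r}: more exits than uncensored dwells"
                )

    @property
    def states(self) -> list:
        return sorted(self.counts)


def summarize_dwells(
    dwell_sequences: Sequence[Sequence[DwellRecord]],
) -> DwellSummary:
    """Aggregate dwell sequences into the summary the rate equations use."""
    durs: dict = {}
    trans: dict = {}
    total = 0.0
    for seq in dwell_sequences:
        for r in seq:
            total += r.duration
            if r.censored:
                continue
            durs.setdefault(r.state, []).append(r.duration)
            if r.next is not None:
                key = (r.state, r.next)
                trans[key] = trans.get(key, 0) + 1
    if not durs:
        raise InsufficientDataError("no uncensored dwells to summarize")
    return DwellSummary(
        mean_dwell={s: float(np.mean(v)) for s, v in durs.items()},
        counts={s: len(v) for s, v in durs.items()},
        transitions=trans,
        total_time=total,
    )


def weighted_rates(summary: DwellSummary) -> dict:
    """Weighted rate constant per observed transition (1/s).

    ``k'(a->b) = (1 / <tau_a>) * n(a->b) / sum_c n(a->c)``.  States with
    no observed exits have undefined rates and are simply absent from
    the result.
    """
    rates: dict = {}
    for a in summary.states:
        tau = summary.mean_dwell.get(a)
        exits = {b: n for (s, b), n in summary.transitions.items() if s == a}
        total = sum(exits.values())
        if total == 0:
            continue
        if tau is None or tau <= 0:
            raise ConfigurationError(f"state {a!r}: mean dwell must be positive")
        for b, n in exits.items():
            rates[(a, b)] = (n / total) / tau
    return rates


def occupancies(summary: DwellSummary) -> dict:
    """Probability of finding an active protomer in each state.

    ``rho_a = n_a * <tau_a> / sum_b n_b * <tau_b>`` — each state's share
    of the total observed (uncensored) dwell time.
    """
    weights = {
        s: summary.counts[s] * summary.mean_dwell[s] for s in summary.states
    }
    total = sum(weights.values())
    if total <= 0:
        raise InsufficientDataError("no dwell time observed in any state")
    return {s: w / total for s, w in weights.items()}


def energy_differences(rho: dict, temperature: float = 298.0) -> dict:
    """Pairwise free-energy differences from occupancies, in kB T.

    ``dG(a<->b) = ln(rho_a / rho_b)`` (times kB T), antisymmetric by
    construction; the more occupied state carries the positive sign.
    Pairs involving a zero occupancy are reported as NaN rather than
    infinite.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    out: dict = {}
    states = sorted(rho)
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            if rho[a] <= 0 or rho[b] <= 0:
                g = float("nan")
            else:
                g = float(np.log(rho[a] / rho[b]))
            out[(a, b)] = g
            out[(b, a)] = -g  # antisymmetric by construction
    return out


def kbt_to_kj_per_mol(value_kbt: float, temperature: float = 298.0) -> float:
    """Convert an energy from kB T units to kJ/mol."""
    return value_kbt * Boltzmann * temperature * Avogadro / 1000.0


def cycle_rate(
    dwell_sequences: Sequence[Sequence[DwellRecord]],
    out_state: object = None,
    in_state: object = None,
    total_time: Optional[float] = None,
) -> float:
    """Transmembrane cycling rate of active protomers (1/s).

    Counts crossings between the outward- and inward-facing states
    through any pathway (intermediate visits do not interrupt a
    crossing; a failed excursion contributes none), divides by two for
    a full cycle, and by the total active observation time including
    censored dwells.
    """
    if total_time is None:
        total_time = sum(r.duration for seq in dwell_sequences for r in seq)
    if total_time <= 0:
        raise InsufficientDataError("zero active observation time")
    if out_state is None or in_state is None:
        states = sorted({r.state for seq in dwell_sequences for r in seq})
        if len(states) < 2:
            return 0.0
        in_state, out_state = states[0], states[-1]
    crossings = 0
    for seq in dwell_sequences:
        sides = [r.state for r in seq if r.state in (out_state, in_state)]
        crossings += sum(1 for a, b in zip(sides[:-1], sides[1:]) if a != b)
    return crossings / 2.0 / total_time


@dataclass
class KineticScheme:
    """Endpoint summary: rates, occupancies, energies and cycling rate."""

    rates: dict  # (a, b) -> k' in 1/s
    rho: dict  # state -> occupancy
    delta_g: dict  # (a, b) -> energy difference in kB T
    temperature: float
    cycle_rate: float
    condition: Optional[str] = None
    mean_dwell: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rho:
            total = sum(self.rho.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError("occupancies must sum to 1")
        for (a, b), g in self.delta_g.items():
            rev = self.delta_g.get((b, a))
            if rev is not None and np.isfinite(g) and abs(g + rev) > 1e-9:
                raise ConfigurationError("delta G must be antisymmetric")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "temperature_K": self.temperature,
            "cycle_rate_per_s": self.cycle_rate,
            "weighted_rates_per_s": {f"{a}->{b}": v for (a, b), v in self.rates.items()},
            "occupancy": {str(k): v for k, v in self.rho.items()},
            "delta_g_kbt": {f"{a}<->{b}": v for (a, b), v in self.delta_g.items()},
            "mean_dwell_s": {str(k): v for k, v in self.mean_dwell.items()},
            "n_dwells": {str(k): v for k, v in self.counts.items()},
        }


def build_scheme(
    dwell_sequences: Sequence[Sequence[DwellRecord]],
    temperature: float = 298.0,
    condition: Optional[str] = None,
    include_inactive_time: float = 0.0,
) -> KineticScheme:
    """Assemble the full kinetic endpoint summary from dwell sequences.

    Occupancies describe the dynamic (active) protomers only; passing
    ``include_inactive_time`` (seconds of quiescent outward-facing
    observation) folds inactive protomers into the outward state for the
    alternative whole-population landscape.
    """
    summary = summarize_dwells(dwell_sequences)
    rates = weighted_rates(summary)
    if include_inactive_time > 0:
        top = max(summary.states)
        weights = {
            s: summary.counts[s] * summary.mean_dwell[s] for s in summary.states
        }
        weights[top] = weights.get(top, 0.0) + include_inactive_time
        total = sum(weights.values())
        rho = {s: w / total for s, w in weights.items()}
    else:
        rho = occupancies(summary)
    dg = energy_differences(rho, temperature)
    rate = cycle_rate(dwell_sequences, total_time=summary.total_time)
    return KineticScheme(
        rates=rates,
        rho=rho,
        delta_g=dg,
        temperature=temperature,
        cycle_rate=rate,
        condition=condition,
        mean_dwell=summary.mean_dwell,
        counts=summary.counts,
    )
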