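"""Replica exchange with solute tempering (REST2) machinery.

All replicas run at the same bath temperature ``T0`` but on deformed
potential-energy surfaces: with the total energy decomposed into a
solute-solute term Epp, a solute-solvent term Epw and a solvent-solvent term
Eww, replica ``i`` feels

    E_i = lam_i * Epp + lam_i**pw_exponent * Epw + Eww,

where ``lam_i = T0 / T_eff,i`` and the effective temperatures are
geometrically (exponentially) spaced between ``T0`` and ``Tmax``.  The
published form puts ``pw_exponent = 1`` (lambda on both scaled terms); the
canonical REST2 derivation uses ``pw_exponent = 0.5`` (sqrt(lambda) on the
solute-solvent term).  Both are supported; 1 is the default.

Because Eww enters every replica unscaled, it cancels algebraically in the
Metropolis exchange criterion: acceptance depends only on the solute-related
terms of the two configurations.  This cancellation is what makes partial
tempering affordable for large solvated systems, and it is tested exactly.

Exchanges swap rung assignments (lambda values) between neighbouring
replicas, not coordinates; the two conventions are equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

__all__ = [
    "KB_KJ_PER_MOL_K",
    "LadderSpec",
    "EnergyDecomposition",
    "ReplicaState",
    "ExchangeHistory",
    "Diagnostics",
    "LadderSpecError",
    "make_ladder",
    "lambda_for",
    "scaled_energy",
    "exchange_accept_prob",
    "run_replica_exchange",
    "dwell_fractions",
]

#: Boltzmann constant in kJ/mol/K for physical-unit systems.  Reduced-unit
#: systems (the toy Hamiltonians) use kB = 1.
KB_KJ_PER_MOL_K = 0.0083144621


class LadderSpecError(ValueError):
    """Raised for invalid temperature-ladder specifications."""


@dataclass(frozen=True)
class LadderSpec:
    """Effective-temperature ladder specification.

    ``T0`` is the (cold) bath temperature of every replica, ``Tmax`` the
    hottest effective solute temperature, ``n_replicas`` the rung count.
    """

    T0: float
    Tmax: float
    n_replicas: int

    def __post_init__(self):
        if self.n_replicas < 2:
            raise LadderSpecError("need at least 2 replicas")
        if not (0 < self.T0 < self.Tmax):
            raise LadderSpecError("require 0 < T0 < Tmax")


@dataclass(frozen=True)
class EnergyDecomposition:
    """Solute-solute (Epp), solute-solvent (Epw), solvent-solvent (Eww)."""

    Epp: float
    Epw: float
    Eww: float

    def __post_init__(self):
        for name in ("Epp", "Epw", "Eww"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def total(self) -> float:
        return self.Epp + self.Epw + self.Eww


class Configuration(Protocol):
    """Contract the replica-exchange driver needs from a system state."""

    def energy_decomposition(self) -> EnergyDecomposition: ...

    def propagate(self, lam: float, n_sweeps: int,
                  rng: np.random.Generator) -> None: ...


@dataclass
class ReplicaState:
    """One replica: its id, current ladder rung and configuration."""

    replica_id: int
    rung_index: int
    lam: float
    configuration: object = None


def make_ladder(spec: LadderSpec) -> np.ndarray:
    """Geometric (exponentially spaced) effective-temperature ladder.

    ``T_i = T0 * (Tmax/T0)**(i/(n-1))``; endpoints are exact.
    """
    i = np.arange(spec.n_replicas)
    temps = spec.T0 * (spec.Tmax / spec.T0) ** (i / (spec.n_replicas - 1))
    temps[0] = spec.T0
    temps[-1] = spec.Tmax
    return temps


def lambda_for(T_eff: float, T0: float) -> float:
    """Scaling factor ``lam = T0 / T_eff`` for one effective temperature."""
    if T0 <= 0:
        raise LadderSpecError("T0 must be positive")
    if T_eff < T0:
        raise LadderSpecError(
            f"T_eff={T_eff} < T0={T0} would imply lambda > 1"
        )
    return T0 / T_eff


def scaled_energy(lam: float, decomp: EnergyDecomposition,
                  pw_exponent: float = 1.0) -> float:
    """Deformed potential ``lam*Epp + lam**pw_exponent * Epw + Eww``."""
    if not 0 < lam <= 1:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    return lam * decomp.Epp + lam ** pw_exponent * decomp.Epw + decomp.Eww


def exchange_accept_prob(state_i: ReplicaState, state_j: ReplicaState,
                         T0: float, kB: float = 1.0,
                         pw_exponent: float = 1.0,
                         decomp_i: EnergyDecomposition = None,
                         decomp_j: EnergyDecomposition = None) -> float:
    """Metropolis probability of swapping the rungs of two replicas.

    ``p = min(1, exp(-beta0 * Delta))`` with ``beta0 = 1/(kB*T0)`` and
    ``Delta = [E_i(x_j) + E_j(x_i)] - [E_i(x_i) + E_j(x_j)]`` where ``E_k``
    is the deformed potential at ``lam_k``.  The Eww contributions cancel,
    so only Epp and Epw of the two configurations enter.
    """
    if decomp_i is None:
        decomp_i = state_i.configuration.energy_decomposition()
    if decomp_j is None:
        decomp_j = state_j.configuration.energy_decomposition()

    def solute_part(lam, d):
        return lam * d.Epp + lam ** pw_exponent * d.Epw

    delta = (solute_part(state_i.lam, decomp_j)
             + solute_part(state_j.lam, decomp_i)
             - solute_part(state_i.lam, decomp_i)
             - solute_part(state_j.lam, decomp_j))
    if not math.isfinite(delta):
        raise ValueError("non-finite energies in exchange attempt")
    beta0 = 1.0 / (kB * T0)
    if delta <= 0:
        return 1.0
    return math.exp(-beta0 * delta)


@dataclass
class ExchangeHistory:
    """Exchange attempts plus the per-step replica -> rung occupancy map."""

    n_replicas: int
    attempts: list = field(default_factory=list)  # (step, rung_i, rung_j, accepted)
    occupancy: list = field(default_factory=list)  # per step: rung_of_replica array

    def record_occupancy(self, step: int, rung_of_replica) -> None:
        arr = np.asarray(rung_of_replica, dtype=int)
        if sorted(arr.tolist()) != list(range(self.n_replicas)):
            raise ValueError(
                f"occupancy at step {step} is not a permutation of rungs"
            )
        self.occupancy.append(arr.copy())

    @property
    def acceptance_rate(self) -> float:
        if not self.attempts:
            return float("nan")
        return sum(a[3] for a in self.attempts) / len(self.attempts)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.attempts, columns=["step", "rung_i", "rung_j", "accepted"]
        )


@dataclass
class Diagnostics:
    """Convergence diagnostics of one replica-exchange run."""

    mean_acceptance: float
    dwell: np.ndarray          # replica x rung time fractions
    round_trips: int           # completed rung0 -> top -> rung0 excursions
    n_exchange_attempts: int


def dwell_fractions(history: ExchangeHistory) -> np.ndarray:
    """Per-replica fraction of time spent at each rung (rows sum to 1).

    Because rung occupancy is a permutation of the replicas at every step,
    the column mean over replicas is exactly ``1/n_replicas`` -- the value
    replicas are expected to fluctuate around in a well-mixed run (6.25% for
    16 replicas).
    """
    if not history.occupancy:
        raise ValueError("empty exchange history")
    n = history.n_replicas
    counts = np.zeros((n, n), dtype=float)
    for rung_of_replica in history.occupancy:
        counts[np.arange(n), rung_of_replica] += 1.0
    return counts / len(history.occupancy)


def _count_round_trips(occupancy, n_replicas: int) -> int:
    """Completed bottom -> top -> bottom excursions, summed over replicas."""
    occ = np.asarray(occupancy)  # (steps, replicas)
    trips = 0
    for r in range(n_replicas):
        path = occ[:, r]
        state = 0  # 0: waiting at bottom, 1: has touched bottom, seeking top
        for rung in path:
            if state == 0 and rung == 0:
                state = 1
            elif state == 1 and rung == n_replicas - 1:
                state = 2
            elif state == 2 and rung == 0:
                trips += 1
                state = 1
        # replicas that never touch rung 0 contribute nothing
    return trips


def run_replica_exchange(system_factory: Callable[[int, np.random.Generator], object],
                         spec: LadderSpec,
                         n_steps: int,
                         exchange_interval: int = 1,
                         seed: int = 0,
                         kB: float = 1.0,
                         pw_exponent: float = 1.0,
                         record_solute: bool = False):
    """Drive a round-robin replica-exchange simulation.

    Parameters
    ----------
    system_factory
        ``factory(replica_id, rng) -> configuration`` yielding independent
        configurations that satisfy the energy-decomposition contract
        (``energy_decomposition()`` and ``propagate(lam, n_sweeps, rng)``).
    spec
        Ladder specification; ``make_ladder`` supplies the rung temperatures.
    n_steps
        Total number of propagation sweeps per replica.
    exchange_interval
        Sweeps between neighbour-exchange attempts.  Attempts alternate
        between even pairs (0-1, 2-3, ...) and odd pairs (1-2, 3-4, ...).
    record_solute
        If true, solute coordinates are recorded per rung at every exchange
        step (configurations must expose ``solute_coordinates()``).

    Returns
    -------
    (per_rung_solute, history, diagnostics)
        ``per_rung_solute`` is a dict rung -> list of coordinate arrays
        (empty if ``record_solute`` is false).
    """
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    rng = np.random.default_rng(seed)
    temps = make_ladder(spec)
    lambdas = np.array([lambda_for(t, spec.T0) for t in temps])
    n = spec.n_replicas

    replicas = []
    for rid in range(n):
        config = system_factory(rid, rng)
        replicas.append(ReplicaState(replica_id=rid, rung_index=rid,
                                     lam=lambdas[rid], configuration=config))

    history = ExchangeHistory(n_replicas=n)
    per_rung = {r: [] for r in range(n)} if record_solute else {}
    parity = 0
    step = 0
    history.record_occupancy(0, [r.rung_index for r in replicas])
    while step < n_steps:
        sweeps = min(exchange_interval, n_steps - step)
        for rep in replicas:
            rep.configuration.propagate(rep.lam, sweeps, rng)
            d = rep.configuration.energy_decomposition()
            if not (math.isfinite(d.Epp) and math.isfinite(d.Epw)
                    and math.isfinite(d.Eww)):
                raise FloatingPointError(
                    f"non-finite energy in replica {rep.replica_id} "
                    f"at step {step}"
                )
        step += sweeps

        # neighbour exchange attempts, alternating even/odd pairs
        by_rung = sorted(replicas, key=lambda r: r.rung_index)
        for low in range(parity, n - 1, 2):
            ri, rj = by_rung[low], by_rung[low + 1]
            p = exchange_accept_prob(ri, rj, spec.T0, kB=kB,
                                     pw_exponent=pw_exponent)
            accepted = bool(rng.random() < p)
            history.attempts.append((step, low, low + 1, accepted))
            if accepted:
                ri.rung_index, rj.rung_index = rj.rung_index, ri.rung_index
                ri.lam, rj.lam = rj.lam, ri.lam
        parity = 1 - parity

        history.record_occupancy(step, [r.rung_index for r in replicas])
        if record_solute:
            for rep in replicas:
                per_rung[rep.rung_index].append(
                    np.array(rep.configuration.solute_coordinates())
                )

    dwell = dwell_fractions(history)
    diagnostics = Diagnostics(
        mean_acceptance=history.acceptance_rate,
        dwell=dwell,
        round_trips=_count_round_trips(history.occupancy, n),
        n_exchange_attempts=len(history.attempts),
    )
    return per_rung, history, diagnostics
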