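"""Decomposable toy Hamiltonians for exercising the REST2 driver.

The system is a solute bead chain (harmonic bonds between consecutive beads,
Lennard-Jones between non-bonded bead pairs) immersed in a Lennard-Jones
solvent bath, in a periodic cubic box with minimum-image convention.  The
total energy decomposes exactly into Epp (solute-solute), Epw
(solute-solvent) and Eww (solvent-solvent), which is all the replica-exchange
driver requires.

Everything is in reduced units: kB = 1, lengths in sigma, energies in
epsilon.  Propagation is Metropolis Monte Carlo with single-bead displacement
moves on the deformed potential ``lam*Epp + lam**pw * Epw + Eww``: solute
beads therefore sample an effective temperature ``T0/lam`` while solvent
beads stay cold -- the operational content of solute tempering, and the
headline property the tests check (bond-length variance of a harmonic dimer
scales as ``kB*(T0/lam)/k_bond``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rest2 import EnergyDecomposition

__all__ = [
    "ToySystemConfig",
    "ToyConfiguration",
    "energy_decomposition",
    "mc_sweep",
    "make_toy_factory",
    "OverlapError",
]


class OverlapError(FloatingPointError):
    """Raised when beads overlap closely enough for LJ to blow up."""


@dataclass(frozen=True)
class ToySystemConfig:
    """Parameters of the toy solute+solvent system (reduced units).

    ``bond_k`` multiplies ``(r - bond_r0)**2 / 2`` for consecutive solute
    beads.  LJ is truncated (unshifted) at ``lj_cutoff``.
    """

    n_solute: int = 10
    n_solvent: int = 100
    box_length: float = 10.0
    bond_k: float = 100.0
    bond_r0: float = 1.0
    lj_epsilon: float = 1.0
    lj_sigma: float = 1.0
    lj_cutoff: float = 2.5
    move_size: float = 0.1
    temperature: float = 1.0
    n_dim: int = 3

    def __post_init__(self):
        if min(self.n_solute, self.box_length, self.bond_k, self.bond_r0,
               self.lj_epsilon, self.lj_sigma, self.lj_cutoff,
               self.temperature) <= 0:
            raise ValueError("toy-system parameters must be positive")
        if self.n_solvent < 0 or self.move_size < 0:
            raise ValueError("n_solvent and move_size must be >= 0")
        if self.lj_cutoff >= self.box_length / 2:
            raise ValueError("lj_cutoff must be < box_length/2")
        if self.n_dim not in (1, 2, 3):
            raise ValueError("n_dim must be 1, 2 or 3")


def _min_image(dx: np.ndarray, box: float) -> np.ndarray:
    return dx - box * np.round(dx / box)


def _lj_energy(r2: np.ndarray, eps: float, sigma: float,
               cutoff: float) -> float:
    """Truncated (unshifted) LJ over an array of squared distances."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 1e-12):
        raise OverlapError("overlapping beads: LJ energy is not finite")
    mask = r2 <= cutoff * cutoff
    if not np.any(mask):
        return 0.0
    inv6 = (sigma * sigma / r2[mask]) ** 3
    return float(np.sum(4.0 * eps * (inv6 * inv6 - inv6)))


class ToyConfiguration:
    """Coordinates of solute and solvent beads plus a cached decomposition.

    The cached :class:`EnergyDecomposition` is updated incrementally on
    accepted moves and resynchronised against a full recomputation every
    ``resync_every`` sweeps (float drift over long runs stays below 1e-9 in
    practice; the cache-consistency invariant is part of the test suite).
    """

    def __init__(self, config: ToySystemConfig, solute: np.ndarray,
                 solvent: np.ndarray, resync_every: int = 1000):
        self.config = config
        self.solute = np.array(solute, dtype=float).reshape(
            config.n_solute, config.n_dim
        )
        self.solvent = np.array(solvent, dtype=float).reshape(
            config.n_solvent, config.n_dim
        )
        self.resync_every = resync_every
        self._sweeps_since_resync = 0
        self._cached = energy_decomposition(self)

    # -- contract used by the replica-exchange driver ----------------------
    def energy_decomposition(self) -> EnergyDecomposition:
        return self._cached

    def propagate(self, lam: float, n_sweeps: int,
                  rng: np.random.Generator) -> None:
        for _ in range(n_sweeps):
            mc_sweep(self, lam, rng)

    def solute_coordinates(self) -> np.ndarray:
        return self.solute.copy()

    # ----------------------------------------------------------------------
    def _solute_bead_energy(self, i: int, pos: np.ndarray):
        """(Epp, Epw) contributions of solute bead i at position ``pos``."""
        cfg = self.config
        epp = 0.0
        # harmonic bonds to chain neighbours
        for j in (i - 1, i + 1):
            if 0 <= j < cfg.n_solute:
                d = _min_image(pos - self.solute[j], cfg.box_length)
                r = float(np.sqrt(np.dot(d, d)))
                epp += 0.5 * cfg.bond_k * (r - cfg.bond_r0) ** 2
        # LJ to non-bonded solute beads
        others = [j for j in range(cfg.n_solute) if abs(j - i) > 1]
        if others:
            d = _min_image(pos - self.solute[others], cfg.box_length)
            epp += _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon,
                              cfg.lj_sigma, cfg.lj_cutoff)
        epw = 0.0
        if cfg.n_solvent:
            d = _min_image(pos - self.solvent, cfg.box_length)
            epw = _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon,
                             cfg.lj_sigma, cfg.lj_cutoff)
        return epp, epw

    def _solvent_bead_energy(self, i: int, pos: np.ndarray):
        """(Epw, Eww) contributions of solvent bead i at position ``pos``."""
        cfg = self.config
        epw = 0.0
        if cfg.n_solute:
            d = _min_image(pos - self.solute, cfg.box_length)
            epw = _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon,
                             cfg.lj_sigma, cfg.lj_cutoff)
        others = np.arange(cfg.n_solvent) != i
        eww = 0.0
        if np.any(others):
            d = _min_image(pos - self.solvent[others], cfg.box_length)
            eww = _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon,
                             cfg.lj_sigma, cfg.lj_cutoff)
        return epw, eww


def energy_decomposition(config: ToyConfiguration) -> EnergyDecomposition:
    """Full recomputation of (Epp, Epw, Eww) for a toy configuration."""
    cfg = config.config
    box = cfg.box_length
    sol = config.solute
    wat = config.solvent

    epp = 0.0
    # bonds
    d = _min_image(sol[1:] - sol[:-1], box)
    r = np.sqrt((d * d).sum(axis=1))
    epp += float(np.sum(0.5 * cfg.bond_k * (r - cfg.bond_r0) ** 2))
    # LJ over non-bonded solute pairs (|i-j| > 1)
    for i in range(cfg.n_solute - 2):
        d = _min_image(sol[i] - sol[i + 2:], box)
        epp += _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon, cfg.lj_sigma,
                          cfg.lj_cutoff)

    epw = 0.0
    if cfg.n_solvent:
        for i in range(cfg.n_solute):
            d = _min_image(sol[i] - wat, box)
            epw += _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon,
                              cfg.lj_sigma, cfg.lj_cutoff)

    eww = 0.0
    for i in range(cfg.n_solvent - 1):
        d = _min_image(wat[i] - wat[i + 1:], box)
        eww += _lj_energy((d * d).sum(axis=1), cfg.lj_epsilon, cfg.lj_sigma,
                          cfg.lj_cutoff)

    return EnergyDecomposition(Epp=epp, Epw=epw, Eww=eww)


def mc_sweep(config: ToyConfiguration, lam: float, rng: np.random.Generator,
             pw_exponent: float = 1.0) -> float:
    """One Metropolis sweep: a displacement attempt for every bead.

    Solute beads feel ``lam*dEpp + lam**pw * dEpw``; solvent beads feel
    ``lam**pw * dEpw + dEww``.  Acceptance uses ``exp(-dE/T0)`` with the
    bath temperature ``T0`` from the system config (kB = 1).  Returns the
    acceptance fraction of the sweep.
    """
    if not 0 < lam <= 1:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    cfg = config.config
    beta0 = 1.0 / cfg.temperature
    lam_pw = lam ** pw_exponent
    n_acc = 0
    n_total = cfg.n_solute + cfg.n_solvent

    epp, epw, eww = (config._cached.Epp, config._cached.Epw,
                     config._cached.Eww)

    for i in range(cfg.n_solute):
        old = config.solute[i].copy()
        step = rng.uniform(-cfg.move_size, cfg.move_size, size=cfg.n_dim)
        new = old + step
        e_old = config._solute_bead_energy(i, old)
        e_new = config._solute_bead_energy(i, new)
        d_def = lam * (e_new[0] - e_old[0]) + lam_pw * (e_new[1] - e_old[1])
        if d_def <= 0 or rng.random() < np.exp(-beta0 * d_def):
            config.solute[i] = new
            epp += e_new[0] - e_old[0]
            epw += e_new[1] - e_old[1]
            n_acc += 1

    for i in range(cfg.n_solvent):
        old = config.solvent[i].copy()
        step = rng.uniform(-cfg.move_size, cfg.move_size, size=cfg.n_dim)
        new = old + step
        e_old = config._solvent_bead_energy(i, old)
        e_new = config._solvent_bead_energy(i, new)
        d_def = lam_pw * (e_new[0] - e_old[0]) + (e_new[1] - e_old[1])
        if d_def <= 0 or rng.random() < np.exp(-beta0 * d_def):
            config.solvent[i] = new
            epw += e_new[0] - e_old[0]
            eww += e_new[1] - e_old[1]
            n_acc += 1

    config._cached = EnergyDecomposition(Epp=epp, Epw=epw, Eww=eww)
    config._sweeps_since_resync += 1
    if config._sweeps_since_resync >= config.resync_every:
        config._cached = energy_decomposition(config)
        config._sweeps_since_resync = 0
    return n_acc / n_total if n_total else 1.0


def _place_solvent(cfg: ToySystemConfig, rng: np.random.Generator,
                   solute: np.ndarray) -> np.ndarray:
    """Random solvent placement avoiding close overlaps (> 0.85 sigma)."""
    placed = []
    existing = solute.copy()
    min_d2 = (0.85 * cfg.lj_sigma) ** 2
    for _ in range(cfg.n_solvent):
        for _attempt in range(2000):
            pos = rng.uniform(0, cfg.box_length, size=cfg.n_dim)
            d = _min_image(pos - existing, cfg.box_length)
            if np.all((d * d).sum(axis=1) > min_d2):
                break
        else:
            raise OverlapError("could not place solvent without overlap")
        placed.append(pos)
        existing = np.vstack([existing, pos])
    return (np.array(placed).reshape(cfg.n_solvent, cfg.n_dim)
            if placed else np.zeros((0, cfg.n_dim)))


def make_toy_factory(cfg: ToySystemConfig):
    """Factory of independent toy configurations for the exchange driver.

    The solute starts as a straight chain at the bond rest length; solvent
    beads are placed uniformly at random without close overlaps, using the
    driver-supplied generator so runs are reproducible under one seed.
    """
    def factory(replica_id: int, rng: np.random.Generator) -> ToyConfiguration:
        solute = np.zeros((cfg.n_solute, cfg.n_dim))
        solute[:, 0] = np.arange(cfg.n_solute) * cfg.bond_r0
        solute += cfg.box_length / 2.0 - solute.mean(axis=0)
        solvent = _place_solvent(cfg, rng, solute)
        return ToyConfiguration(cfg, solute, solvent)

    return factory
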