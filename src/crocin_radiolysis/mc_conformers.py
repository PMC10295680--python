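"""Metropolis Monte-Carlo sampling of polyene-chain conformations.

The engine mixes two move types — collective Gaussian "multi-stretch"
displacements of all sites (default probability 0.8) and torsional moves
about a uniformly chosen rotatable bond (0.2), the latter proposing either
a small angle perturbation or a cis<->trans flip with equal probability.
Acceptance is standard Metropolis, min(1, exp(-dE/kT)).  The energy surface
is pluggable: a callable mapping a configuration to an energy in eV.  The
quantum-chemical surface used in production conformer searches is external;
a surrogate with per-torsion double wells (trans minimum, cis minimum
offset by a gap) plus harmonic site restraints makes the engine testable
against analytic stationary distributions.

Conformers of a conjugated chain are labeled per isomerizable double bond
(trans/cis); :func:`enumerate_single_cis` lists the all-trans structure and
every single isomerization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .units import KB_EV_PER_K

__all__ = [
    "ChainTopology",
    "ConformerState",
    "MCSettings",
    "ChainConfiguration",
    "SurrogateChainEnergy",
    "TwoStateToyEnergy",
    "MCRecord",
    "Trajectory",
    "me2_crocetin_topology",
    "oxidized_radical_topology",
    "two_state_topology",
    "enumerate_single_cis",
    "run_mc",
    "constrain_conformer",
]

EnergyFunction = Callable[["ChainConfiguration"], float]


@dataclass(frozen=True)
class ChainTopology:
    """Sites, bonds and the isomerizable / rotatable bond subsets.

    Bonds are pairs of site indices; ``bond_labels`` names them in the
    chain-numbering convention (e.g. "(6,7)" for the bond between carbons
    6 and 7, primed labels on the mirror half).  ``isomerizable`` lists the
    labels of double bonds whose cis/trans state defines a conformer;
    ``rotatable`` the labels torsional moves may act on.
    """

    sites: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    bond_labels: tuple[str, ...]
    isomerizable: tuple[str, ...]
    rotatable: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bonds) != len(self.bond_labels):
            raise ValueError("one label per bond required")
        if len(set(self.bond_labels)) != len(self.bond_labels):
            raise ValueError("bond labels must be unique")
        n = len(self.sites)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references unknown sites")
        known = set(self.bond_labels)
        for lab in self.isomerizable:
            if lab not in known:
                raise ValueError(f"isomerizable bond {lab!r} is not a bond")
        for lab in self.rotatable:
            if lab not in known:
                raise ValueError(f"rotatable bond {lab!r} is not a bond")


def _linear_chain(n_sites: int, labels: Sequence[str]) -> ChainTopology:
    sites = tuple(f"C{i}" for i in range(n_sites))
    bonds = tuple((i, i + 1) for i in range(n_sites - 1))
    return ChainTopology(sites, bonds, tuple(labels), tuple(labels), tuple(labels))


def me2_crocetin_topology() -> ChainTopology:
    """Polyene chain of the crocetin dimethyl ester.

    Seven conjugated double bonds can isomerize: three on each half of the
    symmetric chain plus the central (8,8') bond.
    """
    labels = ["(2,3)", "(4,5)", "(6,7)", "(8,8')", "(6',7')", "(4',5')", "(2',3')"]
    return _linear_chain(8, labels)


def oxidized_radical_topology() -> ChainTopology:
    """Chain of the H-abstracted radical: delocalization of the unpaired
    electron gives all 13 chain CC bonds partial double-bond character, so
    every one of them is isomerizable."""
    half = ["(1,2)", "(2,3)", "(3,4)", "(4,5)", "(5,6)", "(6,7)", "(7,8)"]
    labels = half + ["(8,8')"] + [lab.replace(")", "')").replace(",", "',") for lab in half[:5]]
    return _linear_chain(14, labels)


def two_state_topology() -> ChainTopology:
    """Minimal topology for two-state toy tests: one isomerizable bond."""
    return _linear_chain(2, ["(1,2)"])


@dataclass(frozen=True)
class ConformerState:
    """Cis/trans flag per isomerizable bond."""

    flags: tuple[tuple[str, str], ...]  # (bond label, "trans"|"cis")

    def __post_init__(self) -> None:
        for _, state in self.flags:
            if state not in ("trans", "cis"):
                raise ValueError("flags must be 'trans' or 'cis'")

    @classmethod
    def from_mapping(cls, flags: dict[str, str]) -> "ConformerState":
        return cls(tuple(flags.items()))

    @property
    def label(self) -> str:
        cis = [lab for lab, state in self.flags if state == "cis"]
        return "all-trans" if not cis else "cis" + "+cis".join(cis)

    def as_dict(self) -> dict[str, str]:
        return dict(self.flags)


def enumerate_single_cis(topology: ChainTopology) -> list[ConformerState]:
    """All-trans plus every single cis-trans isomerization."""
    base = {lab: "trans" for lab in topology.isomerizable}
    states = [ConformerState.from_mapping(base)]
    for lab in topology.isomerizable:
        flipped = dict(base)
        flipped[lab] = "cis"
        states.append(ConformerState.from_mapping(flipped))
    return states


@dataclass(frozen=True)
class MCSettings:
    """Metropolis run settings.

    Move probabilities default to the production mixture: 0.8 multi-stretch,
    0.2 torsional.  ``stride`` records every stride-th configuration after
    ``burn_in``; ``stretch_amplitude`` is the per-coordinate sigma of the
    collective Gaussian displacement (tuned to ~50% acceptance on the
    default surrogate at room temperature); ``torsion_step_rad`` the
    half-width of the uniform angle perturbation.
    """

    steps: int
    burn_in: int = 0
    p_multi_stretch: float = 0.8
    p_torsional: float = 0.2
    temperature_k: float = 295.0
    seed: int = 0
    stride: int = 100
    stretch_amplitude: float = 0.015
    torsion_step_rad: float = 0.35

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise ValueError("steps must be > 0")
        if not 0 <= self.burn_in < self.steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < steps")
        if self.p_multi_stretch < 0 or self.p_torsional < 0:
            raise ValueError("move probabilities must be >= 0")
        if abs(self.p_multi_stretch + self.p_torsional - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class ChainConfiguration:
    """Site coordinates plus one torsion angle per rotatable bond.

    Torsion angles are radians in (-pi, pi], ordered as
    ``topology.rotatable``; 0 is trans, pi is cis.
    """

    topology: ChainTopology
    coords: np.ndarray
    torsions: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        if self.coords.shape != (len(self.topology.sites), 3):
            raise ValueError("coords must have shape (n_sites, 3)")
        if self.torsions.shape != (len(self.topology.rotatable),):
            raise ValueError("one torsion per rotatable bond required")

    @classmethod
    def all_trans(cls, topology: ChainTopology) -> "ChainConfiguration":
        return cls(
            topology,
            np.zeros((len(topology.sites), 3)),
            np.zeros(len(topology.rotatable)),
        )

    def copy(self) -> "ChainConfiguration":
        return ChainConfiguration(self.topology, self.coords.copy(), self.torsions.copy())

    def conformer_state(self) -> ConformerState:
        """Classify each isomerizable torsion: trans if cos(theta) > 0."""
        rot_index = {lab: k for k, lab in enumerate(self.topology.rotatable)}
        flags = {}
        for lab in self.topology.isomerizable:
            k = rot_index.get(lab)
            theta = 0.0 if k is None else float(self.torsions[k])
            flags[lab] = "trans" if math.cos(theta) > 0 else "cis"
        return ConformerState.from_mapping(flags)


@dataclass
class SurrogateChainEnergy:
    """Testable stand-in energy surface: per-torsion double wells plus
    harmonic site restraints.

    Each rotatable torsion contributes
        E(theta) = barrier/4 * (1 - cos 2 theta) + gap/2 * (1 - cos theta)
    (trans minimum at 0 eV, cis minimum at ``cis_gap_ev``, saddle near
    pi/2); sites feel 0.5 * k * |r|^2 about the reference geometry.
    """

    cis_gap_ev: float = 0.07
    barrier_ev: float = 0.6
    stretch_k_ev: float = 5.0

    def __call__(self, config: ChainConfiguration) -> float:
        torsion = float(
            np.sum(
                0.25 * self.barrier_ev * (1.0 - np.cos(2.0 * config.torsions))
                + 0.5 * self.cis_gap_ev * (1.0 - np.cos(config.torsions))
            )
        )
        stretch = 0.5 * self.stretch_k_ev * float(np.sum(config.coords**2))
        return torsion + stretch


@dataclass
class TwoStateToyEnergy:
    """Step potential depending only on the cis/trans state of one torsion:
    0 in the trans half-circle, ``gap_ev`` in the cis half-circle.  Its
    Boltzmann cis population is exp(-gap/kT) / (1 + exp(-gap/kT)), the
    analytic target for sampler validation."""

    gap_ev: float = 0.05
    bond_index: int = 0

    def __call__(self, config: ChainConfiguration) -> float:
        return self.gap_ev if math.cos(config.torsions[self.bond_index]) <= 0 else 0.0

    def cis_population(self, temperature_k: float) -> float:
        b = math.exp(-self.gap_ev / (KB_EV_PER_K * temperature_k))
        return b / (1.0 + b)


@dataclass
class MCRecord:
    step: int
    energy_ev: float
    config: ChainConfiguration

    @property
    def conformer(self) -> str:
        return self.config.conformer_state().label


@dataclass
class Trajectory:
    """Recorded configurations, energies and acceptance statistics."""

    records: list[MCRecord]
    settings: MCSettings
    attempts: dict[str, int]
    accepted: dict[str, int]
    final_config: ChainConfiguration

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy_ev for r in self.records])

    @property
    def conformer_labels(self) -> list[str]:
        return [r.conformer for r in self.records]

    def acceptance_rate(self, move: str | None = None) -> float:
        if move is None:
            att = sum(self.attempts.values())
            acc = sum(self.accepted.values())
        else:
            att, acc = self.attempts[move], self.accepted[move]
        return acc / att if att else math.nan


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi, pi]."""
    wrapped = math.remainder(theta, 2.0 * math.pi)
    return math.pi if wrapped <= -math.pi else wrapped


def run_mc(
    energy: EnergyFunction,
    settings: MCSettings,
    initial: ChainConfiguration,
    frozen_torsions: Iterable[str] = (),
) -> Trajectory:
    """Metropolis sampling with the configured move mixture.

    The random stream is split from the master seed into per-purpose
    substreams (move selection, stretch proposals, torsion proposals,
    acceptance), so trajectories are reproducible and stable against
    refactors of any single proposal.  ``frozen_torsions`` disables
    torsional moves on those bonds; freezing every rotatable bond leaves a
    multi-stretch-only run.  A non-finite energy aborts with a diagnostic.
    """
    topo = initial.topology
    frozen = set(frozen_torsions)
    unknown = frozen - set(topo.rotatable)
    if unknown:
        raise ValueError(f"frozen torsions {sorted(unknown)} are not rotatable bonds")
    free = [k for k, lab in enumerate(topo.rotatable) if lab not in frozen]

    ss = np.random.SeedSequence(settings.seed)
    move_rng, stretch_rng, torsion_rng, accept_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    kt = KB_EV_PER_K * settings.temperature_k

    config = initial.copy()
    current_e = float(energy(config))
    if not math.isfinite(current_e):
        raise RuntimeError("non-finite energy for the initial configuration")

    records: list[MCRecord] = []
    attempts = {"multi_stretch": 0, "torsional": 0}
    accepted = {"multi_stretch": 0, "torsional": 0}

    for step in range(settings.steps):
        u = move_rng.random()
        torsional = free and u < settings.p_torsional
        trial = config.copy()
        if torsional:
            move = "torsional"
            k = free[int(torsion_rng.integers(len(free)))]
            if torsion_rng.random() < 0.5:
                dtheta = torsion_rng.uniform(
                    -settings.torsion_step_rad, settings.torsion_step_rad
                )
            else:
                dtheta = math.pi  # cis <-> trans flip
            trial.torsions[k] = _wrap_angle(trial.torsions[k] + dtheta)
        else:
            move = "multi_stretch"
            trial.coords = trial.coords + stretch_rng.normal(
                0.0, settings.stretch_amplitude, trial.coords.shape
            )
        trial_e = float(energy(trial))
        if not math.isfinite(trial_e):
            raise RuntimeError(
                f"non-finite energy at step {step} ({move} move); aborting"
            )
        attempts[move] += 1
        de = trial_e - current_e
        u_acc = accept_rng.random()
        if de <= 0.0 or u_acc < math.exp(-de / kt):
            config, current_e = trial, trial_e
            accepted[move] += 1
        if step >= settings.burn_in and (step - settings.burn_in) % settings.stride == 0:
            records.append(MCRecord(step, current_e, config.copy()))

    return Trajectory(records, settings, attempts, accepted, config)


def constrain_conformer(
    energy: EnergyFunction,
    settings: MCSettings,
    initial: ChainConfiguration,
    frozen_torsions: Iterable[str],
) -> Trajectory:
    """Constrained run: torsional moves disabled on ``frozen_torsions``.

    Freezing every rotatable bond samples a fixed conformer with
    multi-stretch moves only; freezing none is byte-for-byte identical to
    :func:`run_mc` at equal seed.
    """
    return run_mc(energy, settings, initial, frozen_torsions=frozen_torsions)
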