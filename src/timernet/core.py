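"""Generic engine for synchronous multi-valued logical network simulation.

The model class implemented here is a small generalisation of Boolean
networks: each factor is an ordinal logical variable taking levels
``0..max_level`` (for the patterning networks in this package, ``max_level``
is 1, read as off/on, or 2, read as off/weak/strong).  Factors are either
*inputs*, whose levels are hard-coded per region and timepoint by a schedule,
or *outputs*, each governed by a single pure update rule that maps the
complete state at timepoint ``t`` to the factor's level at ``t+1``.  Updates
are strictly synchronous and regions are independent: there is no spatial
coupling and no within-step ordering.

Null mutants are simulated by *clamping*: the affected factors are forced to
level 0 at every region and timepoint, after rule evaluation and schedule
lookup (so a clamped factor never shows even its initial condition).

Nothing in this module is specific to the Drosophila terminal network; see
:mod:`timernet.terminal` for the canonical instantiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: A complete assignment of one level per factor, for one region at one
#: timepoint.  Keys are factor names.
State = dict[str, int]

#: Per output factor, a pure total function from the predecessor State to the
#: factor's next level.
RuleSet = Mapping[str, Callable[[State], int]]


class NetworkConfigError(ValueError):
    """A network, state, or schedule is malformed; the message names the factor."""


@dataclass(frozen=True)
class FactorDef:
    """A registered factor: its name, level bound, and input/output role."""

    name: str
    max_level: int = 1
    role: str = "output"  # "input" | "output"

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise NetworkConfigError(f"factor {self.name!r}: max_level must be >= 1")
        if self.role not in ("input", "output"):
            raise NetworkConfigError(f"factor {self.name!r}: role must be input or output")


@dataclass(frozen=True)
class Genotype:
    """A genotype: the set of factors held at level 0 for the whole simulation.

    ``clamped`` empty means wild type.  ``label`` is a display form (e.g.
    ``"tll- opa-"``); ``name`` is the machine identifier.
    """

    name: str
    clamped: frozenset = frozenset()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "clamped", frozenset(self.clamped))
        if not self.label:
            object.__setattr__(self, "label", self.name)


@dataclass
class NetworkSpec:
    """A complete logical network: factors, rules, input schedule, genotypes.

    Attributes
    ----------
    factors
        Ordered factor definitions; names must be unique.
    rules
        One update rule per output factor.
    schedule
        Per input factor, an integer array of shape (n_regions, n_timepoints)
        giving the hard-coded level at every region and timepoint.
    initial
        Level of each output factor at timepoint 0 (factors absent default
        to 0).
    genotypes
        Catalogue of simulatable genotypes, keyed by name.
    interactions
        Optional edge-level metadata (provenance, sign, ...); not consulted
        by the simulator, which reads only ``rules``.
    """

    factors: tuple[FactorDef, ...]
    rules: dict[str, Callable[[State], int]]
    schedule: dict[str, np.ndarray]
    n_regions: int
    n_timepoints: int
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    initial: dict[str, int] = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    name: str = "network"

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.schedule = {k: np.asarray(v, dtype=int) for k, v in self.schedule.items()}

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.role == "input")

    @property
    def output_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.role == "output")

    def factor(self, name: str) -> FactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise NetworkConfigError(f"unknown factor {name!r}")

    def genotype(self, name: str) -> Genotype:
        try:
            return self.genotypes[name]
        except KeyError:
            catalogue = ", ".join(sorted(self.genotypes))
            raise NetworkConfigError(
                f"unknown genotype {name!r}; catalogue: {catalogue}"
            ) from None


def level_label(level: int, max_level: int) -> str:
    """Human-readable level label: off/on for binary, off/weak/strong for ternary."""
    if level == 0:
        return "off"
    if max_level == 1:
        return "on"
    return "weak" if level == 1 else "strong"


@dataclass
class Trajectory:
    """Simulated levels indexed by (region, timepoint, factor) for one genotype.

    ``levels`` has shape (n_regions, n_timepoints, n_factors); regions are
    1-based in the public accessors, matching the field convention.
    """

    levels: np.ndarray
    factor_defs: tuple[FactorDef, ...]
    genotype: Genotype

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factor_defs)

    @property
    def n_regions(self) -> int:
        return self.levels.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.levels.shape[1]

    def _fidx(self, factor: str) -> int:
        try:
            return self.factors.index(factor)
        except ValueError:
            raise NetworkConfigError(f"unknown factor {factor!r}") from None

    def level(self, region: int, timepoint: int, factor: str) -> int:
        """Level of ``factor`` in 1-based ``region`` at ``timepoint``."""
        if not 1 <= region <= self.n_regions:
            raise NetworkConfigError(f"region {region} outside 1..{self.n_regions}")
        return int(self.levels[region - 1, timepoint, self._fidx(factor)])

    def series(self, region: int, factor: str) -> tuple[int, ...]:
        """The level time-series of ``factor`` in 1-based ``region``."""
        if not 1 <= region <= self.n_regions:
            raise NetworkConfigError(f"region {region} outside 1..{self.n_regions}")
        return tuple(int(v) for v in self.levels[region - 1, :, self._fidx(factor)])

    def state(self, region: int, timepoint: int) -> State:
        """The complete State of 1-based ``region`` at ``timepoint``."""
        return {
            f: int(self.levels[region - 1, timepoint, i])
            for i, f in enumerate(self.factors)
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: genotype, region, timepoint, factor, level, label."""
        records = []
        for r in range(self.n_regions):
            for t in range(self.n_timepoints):
                for i, fdef in enumerate(self.factor_defs):
                    lvl = int(self.levels[r, t, i])
                    records.append(
                        {
                            "genotype": self.genotype.name,
                            "region": r + 1,
                            "timepoint": t,
                            "factor": fdef.name,
                            "level": lvl,
                            "label": level_label(lvl, fdef.max_level),
                        }
                    )
        return pd.DataFrame.from_records(records)


def advance_state(
    state: State,
    rules: RuleSet,
    scheduled_inputs: Mapping[str, int],
    genotype: Genotype | None = None,
) -> State:
    """Compute the successor State under synchronous update.

    Output factors are set to ``rules[name](state)``, input factors to their
    scheduled level, and clamped factors are then forced to 0.  ``state`` must
    contain every factor the network registers (all rule keys and all input
    keys); a missing factor raises :class:`NetworkConfigError` naming it.
    """
    for name in list(rules) + list(scheduled_inputs):
        if name not in state:
            raise NetworkConfigError(f"state is missing factor {name!r}")
    nxt: State = {}
    for name, rule in rules.items():
        nxt[name] = int(rule(dict(state)))
    for name, lvl in scheduled_inputs.items():
        nxt[name] = int(lvl)
    if genotype is not None:
        for name in genotype.clamped:
            if name not in nxt:
                raise NetworkConfigError(
                    f"genotype {genotype.name!r} clamps unknown factor {name!r}"
                )
            nxt[name] = 0
    return nxt


def initial_state(network: NetworkSpec, genotype: Genotype, region: int) -> State:
    """State at timepoint 0: outputs at their initial condition, inputs at the
    t0 schedule, clamps applied (a clamped factor never shows its initial
    condition)."""
    state: State = {}
    for f in network.factors:
        if f.role == "input":
            state[f.name] = int(network.schedule[f.name][region - 1, 0])
        else:
            state[f.name] = int(network.initial.get(f.name, 0))
    for name in genotype.clamped:
        state[name] = 0
    return state


def simulate_genotype(network: NetworkSpec, genotype: Genotype | str) -> Trajectory:
    """Simulate every region of ``network`` under ``genotype``.

    Timepoint 0 is the (clamped) initial condition; each later timepoint is
    derived from its predecessor via :func:`advance_state` only.  The
    simulation is deterministic and regions are independent.
    """
    if isinstance(genotype, str):
        genotype = network.genotype(genotype)
    R, T = network.n_regions, network.n_timepoints
    names = network.factor_names
    levels = np.zeros((R, T, len(names)), dtype=np.int8)
    for r in range(1, R + 1):
        state = initial_state(network, genotype, r)
        levels[r - 1, 0] = [state[n] for n in names]
        for t in range(1, T):
            scheduled = {
                n: int(network.schedule[n][r - 1, t]) for n in network.input_names
            }
            state = advance_state(state, network.rules, scheduled, genotype)
            levels[r - 1, t] = [state[n] for n in names]
    return Trajectory(levels=levels, factor_defs=network.factors, genotype=genotype)


def simulate_all(network: NetworkSpec) -> dict[str, Trajectory]:
    """Simulate every genotype in the network's catalogue."""
    return {name: simulate_genotype(network, name) for name in network.genotypes}


@dataclass
class ValidationReport:
    """Findings from :func:`validate_network`; empty findings means valid."""

    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __iter__(self):
        return iter(self.findings)


def validate_network(network: NetworkSpec) -> ValidationReport:
    """Structural validation of a :class:`NetworkSpec`.

    Reports duplicate factor names, missing or surplus rules, rules that
    reference unregistered factors (probed on an all-zero state), schedule
    grids of the wrong shape or with out-of-bounds cells, missing schedules,
    out-of-bounds initial levels, and genotypes clamping unknown factors.
    """
    findings: list[str] = []
    names = [f.name for f in network.factors]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            findings.append(f"duplicate factor name {n!r}")
        seen.add(n)

    outputs = set(network.output_names)
    inputs = set(network.input_names)
    for n in outputs:
        if n not in network.rules:
            findings.append(f"output factor {n!r} has no update rule")
    for n in network.rules:
        if n in inputs:
            findings.append(f"input factor {n!r} must not have an update rule")
        elif n not in outputs:
            findings.append(f"rule for unregistered factor {n!r}")

    probe: State = {n: 0 for n in names}
    for n, rule in network.rules.items():
        try:
            lvl = rule(dict(probe))
        except KeyError as exc:
            findings.append(f"rule for {n!r} references unregistered factor {exc.args[0]!r}")
            continue
        except Exception as exc:  # defensive: report, don't crash validation
            findings.append(f"rule for {n!r} failed on probe state: {exc}")
            continue
        fdef = network.factor(n) if n in names else None
        if fdef is not None and not 0 <= int(lvl) <= fdef.max_level:
            findings.append(f"rule for {n!r} returned out-of-bounds level {lvl}")

    for n in inputs:
        grid = network.schedule.get(n)
        if grid is None:
            findings.append(f"input factor {n!r} has no schedule")
            continue
        if grid.shape != (network.n_regions, network.n_timepoints):
            findings.append(
                f"schedule for {n!r} has shape {grid.shape}, expected "
                f"({network.n_regions}, {network.n_timepoints})"
            )
            continue
        mx = network.factor(n).max_level
        if grid.min() < 0 or grid.max() > mx:
            findings.append(f"schedule for {n!r} has levels outside 0..{mx}")
    for n in network.schedule:
        if n not in inputs:
            findings.append(f"schedule entry for non-input factor {n!r}")

    for n, lvl in network.initial.items():
        if n not in seen:
            findings.append(f"initial level for unknown factor {n!r}")
        elif not 0 <= lvl <= network.factor(n).max_level:
            findings.append(f"initial level {lvl} for {n!r} out of bounds")

    for g in network.genotypes.values():
        for n in g.clamped:
            if n not in seen:
                findings.append(f"genotype {g.name!r} clamps unknown factor {n!r}")

    return ValidationReport(findings)


def write_trajectories_tsv(
    trajectories: Iterable[Trajectory] | Mapping[str, Trajectory],
    path: Any,
    header_lines: Sequence[str] = (),
) -> pd.DataFrame:
    """Write trajectories as one tidy TSV (with optional ``#`` header lines)."""
    if isinstance(trajectories, Mapping):
        trajectories = list(trajectories.values())
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return frame
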