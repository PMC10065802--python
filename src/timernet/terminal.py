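"""The canonical Drosophila posterior-terminal patterning network.

Seven factors are modelled as logical variables.  The terminal-system
repressors Tailless (Tll) and Huckebein (Hkb) are extrinsic inputs with
hard-coded region x timepoint schedules; the timer genes Caudal (Cad),
Dichaete (D) and Odd-paired (Opa) plus the gut-specification genes Forkhead
(Fkh) and Wingless (Wg) are outputs with one update rule each.  Tll, Hkb, D
and Opa are ternary (off/weak/strong); Cad, Fkh and Wg are binary (off/on).

The anteroposterior axis is four discrete regions — 1 trunk, 2 tail, 3
hindgut, 4 posterior midgut — simulated over four timepoints t0..t3
(nuclear cycle 13, early stage 5, mid stage 5, stage 6).  At t0 Cad is on
everywhere (it is maternally deposited, so the Cad rule is default-on absent
repression) and the other outputs are off.

The rule table encodes the strong/weak distinctions inferred from the mutant
series: weak Tll suffices to repress D and opa but not cad; weak Hkb
represses D but not opa, cad or wg; only strong D/Opa-independent inputs
(strong Tll or strong Hkb, together with Cad) activate fkh, which is then
self-maintaining, so hindgut/posterior-midgut identity persists after the
terminal inputs decay.

Update rules, applied to the predecessor state:

=====  ==================================================================
Cad    0 if D>=1 or Opa=2 or Tll=2 or Hkb=2; else 1
D      0 if Tll>=1 or Hkb>=1 or Opa=2; else 2 if Cad=1; else 1
Opa    0 if Tll>=1 or Hkb=2; else min(Opa+1, 2)   (ratchet; no timer input)
Fkh    1 if Fkh=1, or Cad=1 and (Tll=2 or Hkb=2); else 0
Wg     1 if Fkh=1 and Hkb<=1; else 0
=====  ==================================================================

The genotype catalogue holds wild type plus the eight null mutants examined
in the source study; ``tor`` (torso) clamps both tll and hkb, since Torso
signalling is required for all posterior expression of both.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable

import numpy as np
import pandas as pd
import yaml

from .core import (
    FactorDef,
    Genotype,
    NetworkConfigError,
    NetworkSpec,
    State,
    validate_network,
)

N_REGIONS = 4
N_TIMEPOINTS = 4

REGION_NAMES = {1: "trunk", 2: "tail", 3: "hindgut", 4: "posterior midgut"}


@dataclass(frozen=True)
class Interaction:
    """One regulatory edge with provenance metadata.

    ``threshold`` is the minimum source level at which the effect applies
    (1 = weak suffices, 2 = strong required).  ``functional`` marks edges that
    the rule table encodes directly; the rules encode *net* logical effects,
    so indirect chains (e.g. Cad->Wg via Fkh) appear as metadata-only edges.
    """

    source: str
    target: str
    sign: str  # "activation" | "repression"
    directness: str  # "direct" | "indirect"
    provenance: str  # "this_study" | "literature"
    threshold: int = 1
    functional: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


# 18 edges: 11 newly inferred from the mutant analysis, 7 from the prior
# literature on terminal patterning.
INTERACTIONS: tuple[Interaction, ...] = (
    # Timer gene cross-regulation (newly inferred)
    Interaction("Opa", "Cad", "repression", "direct", "this_study", threshold=2),
    Interaction("D", "Cad", "repression", "direct", "this_study", threshold=1),
    Interaction("Cad", "D", "activation", "direct", "this_study", threshold=1),
    Interaction("Opa", "D", "repression", "direct", "this_study", threshold=2),
    # Terminal inputs onto the timer genes (newly inferred)
    Interaction("Tll", "Cad", "repression", "direct", "this_study", threshold=2),
    Interaction("Tll", "D", "repression", "direct", "this_study", threshold=1),
    Interaction("Tll", "Opa", "repression", "direct", "this_study", threshold=1),
    Interaction("Hkb", "Cad", "repression", "direct", "this_study", threshold=2),
    Interaction("Hkb", "D", "repression", "direct", "this_study", threshold=1),
    Interaction("Hkb", "Opa", "repression", "direct", "this_study", threshold=2),
    Interaction("Hkb", "Wg", "repression", "direct", "this_study", threshold=2),
    # Gut specification (previously proposed)
    Interaction("Fkh", "Wg", "activation", "direct", "literature", threshold=1),
    Interaction("Cad", "Fkh", "activation", "direct", "literature", threshold=1),
    Interaction("Tll", "Fkh", "activation", "indirect", "literature", threshold=2),
    Interaction("Hkb", "Fkh", "activation", "indirect", "literature", threshold=2),
    Interaction("Fkh", "Fkh", "activation", "direct", "literature", threshold=1),
    # Net/indirect effects represented in the diagram but not encoded as
    # separate rule terms (the rules encode net logic via Fkh).
    Interaction("Cad", "Wg", "activation", "indirect", "literature", threshold=1, functional=False),
    Interaction("Fkh", "Cad", "repression", "indirect", "literature", threshold=1, functional=False),
)

#: Edges the rule table consults; deleting one changes the dynamics.
FUNCTIONAL_EDGES: tuple[tuple[str, str], ...] = tuple(
    i.key for i in INTERACTIONS if i.functional
)

#: Metadata-only edges (documented exceptions to edge necessity).
METADATA_EDGES: tuple[tuple[str, str], ...] = tuple(
    i.key for i in INTERACTIONS if not i.functional
)


def make_rules(
    removed: Iterable[tuple[str, str]] = (),
) -> dict[str, Callable[[State], int]]:
    """Build the reference rule table, optionally with edges knocked out.

    ``removed`` is an iterable of (source, target) pairs drawn from
    :data:`FUNCTIONAL_EDGES`; the corresponding terms are dropped from the
    rules, which is how the edge-necessity analysis perturbs the network.
    """
    removed = set(removed)
    unknown = removed - set(FUNCTIONAL_EDGES)
    if unknown:
        raise NetworkConfigError(f"cannot remove non-functional edges: {sorted(unknown)}")
    active = set(FUNCTIONAL_EDGES) - removed

    def on(src: str, tgt: str) -> bool:
        return (src, tgt) in active

    def cad(prev: State) -> int:
        repressed = (
            (on("D", "Cad") and prev["D"] >= 1)
            or (on("Opa", "Cad") and prev["Opa"] == 2)
            or (on("Tll", "Cad") and prev["Tll"] == 2)
            or (on("Hkb", "Cad") and prev["Hkb"] == 2)
        )
        return 0 if repressed else 1

    def d(prev: State) -> int:
        repressed = (
            (on("Tll", "D") and prev["Tll"] >= 1)
            or (on("Hkb", "D") and prev["Hkb"] >= 1)
            or (on("Opa", "D") and prev["Opa"] == 2)
        )
        if repressed:
            return 0
        return 2 if (on("Cad", "D") and prev["Cad"] == 1) else 1

    def opa(prev: State) -> int:
        repressed = (on("Tll", "Opa") and prev["Tll"] >= 1) or (
            on("Hkb", "Opa") and prev["Hkb"] == 2
        )
        return 0 if repressed else min(prev["Opa"] + 1, 2)

    def fkh(prev: State) -> int:
        maintained = on("Fkh", "Fkh") and prev["Fkh"] == 1
        activated = (on("Cad", "Fkh") and prev["Cad"] == 1) and (
            (on("Tll", "Fkh") and prev["Tll"] == 2)
            or (on("Hkb", "Fkh") and prev["Hkb"] == 2)
        )
        return 1 if (maintained or activated) else 0

    def wg(prev: State) -> int:
        activated = on("Fkh", "Wg") and prev["Fkh"] == 1
        repressed = on("Hkb", "Wg") and prev["Hkb"] == 2
        return 1 if (activated and not repressed) else 0

    return {"Cad": cad, "D": d, "Opa": opa, "Fkh": fkh, "Wg": wg}


_REFERENCE_RULES = make_rules()

#: Registry mapping the config file's rule identifier to a rule builder.
RULE_REGISTRY: dict[str, Callable[..., dict[str, Callable[[State], int]]]] = {
    "drosophila_terminal_v1": make_rules,
}

DEFAULT_CONFIG_RESOURCE = "terminal_network.yaml"


def evaluate_update(factor: str, prev: State) -> int:
    """Next level of an output ``factor`` given the predecessor State.

    Raises :class:`NetworkConfigError` for input factors (which have no rule).
    """
    if factor in ("Tll", "Hkb"):
        raise NetworkConfigError(f"{factor!r} is an input factor and has no update rule")
    try:
        rule = _REFERENCE_RULES[factor]
    except KeyError:
        raise NetworkConfigError(f"unknown output factor {factor!r}") from None
    return rule(prev)


def reference_schedule() -> dict[str, np.ndarray]:
    """Hard-coded Tll/Hkb input grids, regions 1..4 (rows) x t0..t3 (columns).

    Region 1 (trunk) sees neither input.  Region 2 (tail) sees weak,
    transient Tll.  Region 3 (hindgut) sees strong Tll and weak, transient
    Hkb.  Region 4 (posterior midgut) sees strong Tll and strong Hkb, with
    Hkb persisting weakly at t3 (hkb persists at low levels after
    gastrulation, while tll fades by stage 6).
    """
    return {
        "Tll": np.array(
            [[0, 0, 0, 0], [1, 1, 0, 0], [2, 2, 2, 0], [2, 2, 2, 0]], dtype=int
        ),
        "Hkb": np.array(
            [[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 0, 0], [2, 2, 2, 1]], dtype=int
        ),
    }


def load_network(path=None, removed_edges: Iterable[tuple[str, str]] = ()) -> NetworkSpec:
    """Load a NetworkSpec from a YAML config (default: the shipped canonical one).

    The config carries factors, schedule grids, the initial condition, the
    genotype catalogue and the interaction table; rules are referenced by an
    identifier resolved through :data:`RULE_REGISTRY`.
    """
    if path is None:
        text = (
            resources.files("timernet.data").joinpath(DEFAULT_CONFIG_RESOURCE).read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)

    factors = tuple(
        FactorDef(f["name"], int(f["max_level"]), f["role"]) for f in cfg["factors"]
    )
    schedule = {
        name: np.asarray(grid, dtype=int) for name, grid in cfg["schedule"].items()
    }
    genotypes = {
        g["name"]: Genotype(
            g["name"], frozenset(g.get("clamped", [])), g.get("label", g["name"])
        )
        for g in cfg["genotypes"]
    }
    interactions = [
        Interaction(
            i["source"],
            i["target"],
            i["sign"],
            i["directness"],
            i["provenance"],
            int(i.get("threshold", 1)),
            bool(i.get("functional", True)),
        )
        for i in cfg.get("interactions", [])
    ]
    rule_id = cfg["rules"]
    try:
        builder = RULE_REGISTRY[rule_id]
    except KeyError:
        raise NetworkConfigError(f"unknown rule identifier {rule_id!r}") from None
    return NetworkSpec(
        factors=factors,
        rules=builder(removed_edges),
        schedule=schedule,
        n_regions=int(cfg["n_regions"]),
        n_timepoints=int(cfg["n_timepoints"]),
        genotypes=genotypes,
        initial={k: int(v) for k, v in cfg.get("initial", {}).items()},
        interactions=interactions,
        name=cfg.get("name", "terminal"),
    )


def build_terminal_network(
    removed_edges: Iterable[tuple[str, str]] = (),
) -> NetworkSpec:
    """The canonical terminal network (validated on construction).

    ``removed_edges`` knocks out functional rule terms for the edge-necessity
    analysis; the interaction metadata is left untouched so that structure
    counts always describe the canonical network.
    """
    network = load_network(removed_edges=removed_edges)
    report = validate_network(network)
    if not report.ok:
        raise NetworkConfigError(f"canonical network failed validation: {report.findings}")
    return network


def interactions_frame(network: NetworkSpec | None = None) -> pd.DataFrame:
    """The interaction table as a tidy DataFrame (exportable as TSV)."""
    edges = network.interactions if network is not None else list(INTERACTIONS)
    return pd.DataFrame(
        [
            {
                "source": i.source,
                "target": i.target,
                "sign": i.sign,
                "directness": i.directness,
                "provenance": i.provenance,
                "threshold": i.threshold,
                "functional": i.functional,
            }
            for i in edges
        ]
    )
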