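"""Machine-checkable qualitative phenotype expectations.

Each genotype-by-genotype observation from the mutant analysis is encoded as
an :class:`Expectation` — a small decidable predicate over simulated
trajectories together with the verbatim observation it operationalizes.
Evaluating the shipped suite against simulations of the canonical network is
the model's regression test: 100% of expectations must pass.

Operationalizations (all decidable from trajectories alone):

* "delayed" repression — strictly later first-off time than the reference
  genotype, with a factor that never switches off ordered after every finite
  timepoint;
* "reduced" activation — strictly lower maximum level over the simulation;
* "transformed into" — exact equality of the level time-series over a stated
  factor subset (all factors when unstated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import NetworkConfigError, Trajectory

RELATIONS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


class MissingGenotypeError(KeyError):
    """A suite references a genotype absent from the supplied trajectories."""


def first_off_time(trajectory: Trajectory, region: int, factor: str) -> int | None:
    """Earliest timepoint at which a previously expressed factor is off.

    Returns the smallest ``t`` with level 0 at (region, factor, t) such that
    the factor was >= 1 at some earlier timepoint; ``None`` if the factor is
    never expressed or never switches off.
    """
    series = trajectory.series(region, factor)
    expressed = False
    for t, lvl in enumerate(series):
        if expressed and lvl == 0:
            return t
        if lvl >= 1:
            expressed = True
    return None


def _off_rank(trajectory: Trajectory, region: int, factor: str) -> float:
    """First-off time on an extended scale for delay comparisons.

    Never-off-but-expressed maps to +inf (later than any finite time);
    never-expressed maps to 0 (off from the start)."""
    t = first_off_time(trajectory, region, factor)
    if t is not None:
        return float(t)
    if max(trajectory.series(region, factor)) >= 1:
        return math.inf
    return 0.0


# --------------------------------------------------------------------------
# Predicates


@dataclass(frozen=True)
class LevelAt:
    """``relation`` holds between the factor's level and ``level`` at the
    stated timepoint(s) (``None`` = every timepoint)."""

    region: int
    factor: str
    timepoint: int | tuple[int, ...] | None
    relation: str = "=="
    level: int = 0

    def evaluate(self, traj: Trajectory, _: Mapping[str, Trajectory]) -> tuple[bool, dict]:
        rel = RELATIONS[self.relation]
        series = traj.series(self.region, self.factor)
        if self.timepoint is None:
            times: Sequence[int] = range(len(series))
        elif isinstance(self.timepoint, int):
            times = (self.timepoint,)
        else:
            times = self.timepoint
        observed = {f"t{t}": series[t] for t in times}
        ok = all(rel(series[t], self.level) for t in times)
        return ok, {"series": series, "checked": observed}


@dataclass(frozen=True)
class OffEverywhere:
    """The factor is at level 0 at every timepoint of the region."""

    region: int
    factor: str

    def evaluate(self, traj: Trajectory, _: Mapping[str, Trajectory]) -> tuple[bool, dict]:
        series = traj.series(self.region, self.factor)
        return all(v == 0 for v in series), {"series": series}


@dataclass(frozen=True)
class FirstOffLaterThan:
    """The factor switches off strictly later than in the reference genotype
    (never-off counts as later than any finite time)."""

    region: int
    factor: str
    reference: str

    def evaluate(
        self, traj: Trajectory, all_traj: Mapping[str, Trajectory]
    ) -> tuple[bool, dict]:
        ref = _lookup(all_traj, self.reference)
        mine = _off_rank(traj, self.region, self.factor)
        theirs = _off_rank(ref, self.region, self.factor)
        return mine > theirs, {
            "first_off": first_off_time(traj, self.region, self.factor),
            "reference_first_off": first_off_time(ref, self.region, self.factor),
        }


@dataclass(frozen=True)
class MaxLevelLowerThan:
    """The factor's maximum level is strictly below the reference genotype's."""

    region: int
    factor: str
    reference: str

    def evaluate(
        self, traj: Trajectory, all_traj: Mapping[str, Trajectory]
    ) -> tuple[bool, dict]:
        ref = _lookup(all_traj, self.reference)
        mine = max(traj.series(self.region, self.factor))
        theirs = max(ref.series(self.region, self.factor))
        return mine < theirs, {"max_level": mine, "reference_max_level": theirs}


@dataclass(frozen=True)
class RegionEquals:
    """Two (genotype, region) trajectories agree exactly over a factor subset.

    ``genotype_b=None`` compares within the expectation's own genotype.
    ``factors=None`` compares every factor.
    """

    region_a: int
    region_b: int
    genotype_b: str | None = None
    factors: tuple[str, ...] | None = None

    def evaluate(
        self, traj: Trajectory, all_traj: Mapping[str, Trajectory]
    ) -> tuple[bool, dict]:
        other = traj if self.genotype_b is None else _lookup(all_traj, self.genotype_b)
        names = self.factors if self.factors is not None else traj.factors
        observed = {}
        ok = True
        for f in names:
            a = traj.series(self.region_a, f)
            b = other.series(self.region_b, f)
            observed[f] = {"a": a, "b": b}
            ok = ok and a == b
        return ok, observed


Predicate = LevelAt | OffEverywhere | FirstOffLaterThan | MaxLevelLowerThan | RegionEquals


def _lookup(trajectories: Mapping[str, Trajectory], genotype: str) -> Trajectory:
    try:
        return trajectories[genotype]
    except KeyError:
        raise MissingGenotypeError(
            f"no trajectory supplied for genotype {genotype!r}"
        ) from None


# --------------------------------------------------------------------------
# Expectations and reports


@dataclass(frozen=True)
class Expectation:
    """One machine-checkable qualitative claim about a genotype's trajectory."""

    id: str
    genotype: str
    predicate: Predicate
    source_quote: str

    def __post_init__(self) -> None:
        if not self.source_quote:
            raise NetworkConfigError(f"expectation {self.id!r} has an empty source quote")


@dataclass(frozen=True)
class ExpectationResult:
    id: str
    genotype: str
    passed: bool
    observed: dict
    source_quote: str


@dataclass
class CheckReport:
    """Per-expectation verdicts plus summary counts."""

    results: list[ExpectationResult] = field(default_factory=list)

    @property
    def pass_count(self) -> int:
        return sum(r.passed for r in self.results)

    @property
    def fail_count(self) -> int:
        return len(self.results) - self.pass_count

    @property
    def all_passed(self) -> bool:
        return self.fail_count == 0

    @property
    def failures(self) -> list[ExpectationResult]:
        return [r for r in self.results if not r.passed]

    def to_json(self) -> str:
        payload = {
            "n_expectations": len(self.results),
            "pass_count": self.pass_count,
            "fail_count": self.fail_count,
            "results": [
                {
                    "id": r.id,
                    "genotype": r.genotype,
                    "verdict": "pass" if r.passed else "fail",
                    "observed": r.observed,
                    "quote": r.source_quote,
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=2, default=str)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "genotype": r.genotype,
                    "verdict": "pass" if r.passed else "fail",
                    "quote": r.source_quote,
                }
                for r in self.results
            ]
        )

    def to_table(self) -> str:
        frame = self.to_frame()
        if frame.empty:
            return "(empty suite)\n"
        body = frame.to_string(index=False)
        return f"{body}\n\n{self.pass_count} passed, {self.fail_count} failed\n"


def evaluate_expectations(
    trajectories: Mapping[str, Trajectory], suite: Sequence[Expectation]
) -> CheckReport:
    """Evaluate a suite against per-genotype trajectories.

    Pure and deterministic: the report is a function of its arguments only.
    Raises :class:`MissingGenotypeError` if the suite references a genotype
    absent from ``trajectories``.
    """
    report = CheckReport()
    for exp in suite:
        traj = _lookup(trajectories, exp.genotype)
        passed, observed = exp.predicate.evaluate(traj, trajectories)
        report.results.append(
            ExpectationResult(exp.id, exp.genotype, bool(passed), observed, exp.source_quote)
        )
    return report


# --------------------------------------------------------------------------
# The shipped suite

WT = "wild_type"


def build_expectation_suite() -> list[Expectation]:
    """The canonical expectation suite: the genotype-by-genotype observations
    of the mutant analysis, one decidable claim each, covering all nine
    genotypes."""
    E = Expectation
    suite = [
        # -- wild type, region 1 (trunk): Cad off before D, D pulse, Opa ramp
        E("wt-r1-cad-off-t2", WT, LevelAt(1, "Cad", 2, "==", 0),
          "as D is activated and the level of Opa builds up, first Cad and then D are repressed"),
        E("wt-r1-d-still-on-t2", WT, LevelAt(1, "D", 2, "==", 2),
          "as D is activated and the level of Opa builds up, first Cad and then D are repressed"),
        E("wt-r1-d-off-t3", WT, LevelAt(1, "D", 3, "==", 0),
          "as D is activated and the level of Opa builds up, first Cad and then D are repressed"),
        E("wt-r1-d-activated-strong", WT, LevelAt(1, "D", 1, "==", 2),
          "as D is activated and the level of Opa builds up, first Cad and then D are repressed"),
        E("wt-r1-opa-builds-to-strong", WT, LevelAt(1, "Opa", 3, "==", 2),
          "as D is activated and the level of Opa builds up, first Cad and then D are repressed"),
        # -- wild type, region 2 (tail): prolonged Cad, delayed D and Opa
        E("wt-r2-cad-on-throughout", WT, LevelAt(2, "Cad", None, "==", 1),
          "delays the activation of D and Opa, and thereby prolongs the expression of Cad"),
        E("wt-r2-d-quiet-before-t3", WT, LevelAt(2, "D", (0, 1, 2), "==", 0),
          "delays the activation of D and Opa, and thereby prolongs the expression of Cad"),
        E("wt-r2-d-strong-at-t3", WT, LevelAt(2, "D", 3, "==", 2),
          "delays the activation of D and Opa, and thereby prolongs the expression of Cad"),
        E("wt-r2-opa-delayed", WT, LevelAt(2, "Opa", (0, 1, 2), "==", 0),
          "delays the activation of D and Opa, and thereby prolongs the expression of Cad"),
        E("wt-r2-no-fkh", WT, OffEverywhere(2, "Fkh"),
          "this Tll expression is weaker than in region 3, and so does not activate Fkh"),
        # -- wild type, regions 3/4: gut fates
        E("wt-r3-wg-on", WT, LevelAt(3, "Wg", 3, "==", 1),
          "the nested domains of strong Tll and Hkb expression specify abutting domains of hindgut (Fkh and Wg) and posterior midgut (Fkh only) fates"),
        E("wt-r1-wg-off", WT, OffEverywhere(1, "Wg"),
          "the wg posterior domain neatly demarcates the strip of tll-positive hkb-negative cells"),
        E("wt-r2-wg-off", WT, OffEverywhere(2, "Wg"),
          "the wg posterior domain neatly demarcates the strip of tll-positive hkb-negative cells"),
        E("wt-r4-wg-off", WT, OffEverywhere(4, "Wg"),
          "differentially regulating Wg (repressed by Hkb in region 4)"),
        E("wt-r3-fkh-persists", WT, LevelAt(3, "Fkh", 3, "==", 1),
          "activating Fkh (both regions)"),
        E("wt-r4-fkh-persists", WT, LevelAt(4, "Fkh", 3, "==", 1),
          "activating Fkh (both regions)"),
        E("wt-r3-timer-repressed", WT, LevelAt(3, "Cad", 1, "==", 0),
          "specifically by repressing the timer genes (both regions)"),
        # -- fkh-
        E("fkh-r3-wg-never", "fkh", OffEverywhere(3, "Wg"),
          "In the fkh- mutant, Wg is never activated in region 3."),
        # -- D-
        E("d-r1-cad-delayed", "D", FirstOffLaterThan(1, "Cad", WT),
          "the repression of Cad is delayed in D-"),
        E("d-r1-cad-eventually-off", "D", LevelAt(1, "Cad", 3, "==", 0),
          "the repression of Cad is delayed in D-"),
        # -- opa-
        E("opa-r1-d-delayed", "opa", FirstOffLaterThan(1, "D", WT),
          "the repression of D is delayed in opa-"),
        # -- cad(m-z-)
        E("cad-r3-no-fkh", "cad_mz", OffEverywhere(3, "Fkh"),
          "in regions 3 and 4, Fkh and (therefore) Wg are not expressed"),
        E("cad-r4-no-fkh", "cad_mz", OffEverywhere(4, "Fkh"),
          "in regions 3 and 4, Fkh and (therefore) Wg are not expressed"),
        E("cad-r3-no-wg", "cad_mz", OffEverywhere(3, "Wg"),
          "in regions 3 and 4, Fkh and (therefore) Wg are not expressed"),
        E("cad-r1-d-reduced", "cad_mz", MaxLevelLowerThan(1, "D", WT),
          "in regions 1 and 2 the activation of D is reduced"),
        E("cad-r2-d-reduced", "cad_mz", MaxLevelLowerThan(2, "D", WT),
          "in regions 1 and 2 the activation of D is reduced"),
        # -- tor- (tll- hkb- double clamp): whole axis becomes trunk
        E("tor-r2-is-r1", "tor", RegionEquals(2, 1, genotype_b=WT),
          "transforms regions 2-4 into region 1"),
        E("tor-r3-is-r1", "tor", RegionEquals(3, 1, genotype_b=WT),
          "transforms regions 2-4 into region 1"),
        E("tor-r4-is-r1", "tor", RegionEquals(4, 1, genotype_b=WT),
          "transforms regions 2-4 into region 1"),
        # -- hkb-: posterior midgut becomes hindgut; Fkh/Wg presence only
        # (onset timing is non-normative for this genotype).
        E("hkb-r4-is-r3", "hkb", RegionEquals(4, 3),
          "essentially transforms region 4 (posterior midgut) into region 3 (hindgut)"),
        E("hkb-r4-fkh-eventually", "hkb", LevelAt(4, "Fkh", 3, "==", 1),
          "essentially transforms region 4 (posterior midgut) into region 3 (hindgut)"),
        E("hkb-r4-wg-eventually", "hkb", LevelAt(4, "Wg", 3, "==", 1),
          "essentially transforms region 4 (posterior midgut) into region 3 (hindgut)"),
        # -- tll-
        E("tll-r2-is-r1", "tll", RegionEquals(2, 1),
          "transforms region 2 into region 1"),
        E("tll-r3-d-transient-repression", "tll", OffEverywhere(3, "D"),
          "D expression is transiently repressed (as in wild-type region 2) but Opa is not"),
        E("tll-r3-opa-unrepressed", "tll", LevelAt(3, "Opa", 1, ">=", 1),
          "D expression is transiently repressed (as in wild-type region 2) but Opa is not"),
        E("tll-r3-cad-through-t2", "tll", LevelAt(3, "Cad", (0, 1, 2), "==", 1),
          "producing a posteriorly shifted, transient Cad stripe"),
        E("tll-r3-cad-off-t3", "tll", LevelAt(3, "Cad", 3, "==", 0),
          "producing a posteriorly shifted, transient Cad stripe"),
        E("tll-r3-no-late-d", "tll", LevelAt(3, "D", 3, "==", 0),
          "precluding any late expression of D"),
        E("tll-r4-cad-repressed", "tll", LevelAt(4, "Cad", (1, 2, 3), "==", 0),
          "the posterior borders of cad, D, and opa all abut the hkb expression domain"),
        E("tll-r4-opa-off", "tll", OffEverywhere(4, "Opa"),
          "the posterior borders of cad, D, and opa all abut the hkb expression domain"),
        E("tll-r4-fkh-on", "tll", LevelAt(4, "Fkh", 1, "==", 1),
          "The reduced domain was the same size as the hkb domain"),
        E("tll-r3-wg-absent", "tll", OffEverywhere(3, "Wg"),
          "the posterior wg domain was absent"),
        # -- tll- opa-: hindgut fully transformed into tail (Cad/D subset;
        # Opa is clamped, so whole-state equality is impossible by
        # construction).
        E("tllopa-r3-is-wt-r2", "tll_opa",
          RegionEquals(3, 2, genotype_b=WT, factors=("Cad", "D")),
          "region 3 is fully transformed into region 2"),
    ]
    return suite
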