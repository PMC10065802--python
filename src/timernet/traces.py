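"""Synthetic 1-D expression traces and boundary quantification.

Confocal expression traces along the anteroposterior axis are the
quantitative currency of blastoderm patterning work: per-gene intensity
profiles over % egg length (measured from the anterior pole), windowed to the
posterior of the embryo (67.5-97.5% AP by convention) and individually
min-max normalised per trace.  This module generates such traces with known
ground-truth domain boundaries — each expression domain is a plateau with
logistic edges plus additive Gaussian noise — and quantifies them with the
same conventions (window, per-trace normalisation, half-maximum boundary
calling, mutant-vs-reference boundary shifts).

The generator emulates the *shape* conventions of trace figures only; it
makes no attempt to model optics, nuclear texture, or any real imaging
dataset.  It exists so that the quantification code is testable end to end
with known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import expit

DEFAULT_WINDOW = (67.5, 97.5)  # % egg length, anterior pole = 0
DEFAULT_SEED = 0


class TraceError(ValueError):
    """Invalid trace, domain specification, or quantification request."""


@dataclass(frozen=True)
class DomainSpec:
    """One expression domain: a logistic-edged plateau on the AP axis.

    Positions are % egg length from the anterior pole.  ``edge_sharpness``
    is the logistic width (smaller = sharper edge); the half-maximum of each
    edge sits exactly at the edge parameter.  ``amplitude`` and ``baseline``
    are arbitrary intensity units.
    """

    gene: str
    anterior_edge: float
    posterior_edge: float
    amplitude: float = 1.0
    edge_sharpness: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.anterior_edge < self.posterior_edge <= 100:
            raise TraceError(
                f"domain {self.gene!r}: need 0 <= anterior_edge < posterior_edge "
                f"<= 100, got {self.anterior_edge}..{self.posterior_edge}"
            )
        if self.amplitude <= 0:
            raise TraceError(f"domain {self.gene!r}: amplitude must be > 0")
        if self.edge_sharpness <= 0:
            raise TraceError(f"domain {self.gene!r}: edge_sharpness must be > 0")
        if self.baseline < 0:
            raise TraceError(f"domain {self.gene!r}: baseline must be >= 0")

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Noise-free intensity of this domain at positions ``x``."""
        rising = expit((x - self.anterior_edge) / self.edge_sharpness)
        falling = expit((self.posterior_edge - x) / self.edge_sharpness)
        return self.baseline + self.amplitude * rising * falling


@dataclass(frozen=True)
class ExpressionTrace:
    """Sampled per-gene intensity series over strictly increasing positions."""

    positions: np.ndarray
    intensities: dict[str, np.ndarray]
    normalized: bool = False
    degenerate: frozenset = frozenset()  # genes whose series was constant

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if np.any(np.diff(pos) <= 0):
            raise TraceError("positions must be strictly increasing")
        series = {g: np.asarray(v, dtype=float) for g, v in self.intensities.items()}
        for g, v in series.items():
            if v.shape != pos.shape:
                raise TraceError(f"gene {g!r}: series length differs from positions")
        object.__setattr__(self, "intensities", series)
        object.__setattr__(self, "degenerate", frozenset(self.degenerate))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.intensities)

    def series(self, gene: str) -> np.ndarray:
        try:
            return self.intensities[gene]
        except KeyError:
            raise TraceError(f"unknown gene {gene!r}") from None


def synthesize_trace(
    domains: Sequence[DomainSpec],
    n_points: int = 301,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    lo: float = 0.0,
    hi: float = 100.0,
) -> ExpressionTrace:
    """Generate a multi-gene trace from domain specifications.

    Per gene, intensities are the sum of its domains' logistic-plateau
    profiles, plus Gaussian noise of standard deviation ``noise_sd``, floored
    at 0.  Reproducible per ``seed``.
    """
    if n_points < 10:
        raise TraceError("n_points must be >= 10")
    if noise_sd < 0:
        raise TraceError("noise_sd must be >= 0")
    if not domains:
        raise TraceError("at least one DomainSpec is required")
    x = np.linspace(lo, hi, n_points)
    rng = np.random.default_rng(seed)
    intensities: dict[str, np.ndarray] = {}
    for dom in domains:
        contribution = dom.profile(x)
        if dom.gene in intensities:
            intensities[dom.gene] = intensities[dom.gene] + contribution
        else:
            intensities[dom.gene] = contribution
    for gene in intensities:
        if noise_sd > 0:
            intensities[gene] = intensities[gene] + rng.normal(0.0, noise_sd, n_points)
        intensities[gene] = np.maximum(intensities[gene], 0.0)
    return ExpressionTrace(positions=x, intensities=intensities)


def normalize_trace(trace: ExpressionTrace) -> ExpressionTrace:
    """Min-max scale each gene's series onto [0, 1] (traces are individually
    normalised).  A constant series maps to all zeros and is flagged
    degenerate.  Idempotent."""
    out: dict[str, np.ndarray] = {}
    degenerate = set(trace.degenerate)
    for gene, y in trace.intensities.items():
        span = y.max() - y.min()
        if span == 0:
            out[gene] = np.zeros_like(y)
            degenerate.add(gene)
        else:
            out[gene] = (y - y.min()) / span
    return ExpressionTrace(
        positions=trace.positions.copy(),
        intensities=out,
        normalized=True,
        degenerate=frozenset(degenerate),
    )


def window_trace(
    trace: ExpressionTrace,
    lo: float = DEFAULT_WINDOW[0],
    hi: float = DEFAULT_WINDOW[1],
) -> ExpressionTrace:
    """Restrict a trace to positions in [lo, hi] inclusive (default
    67.5-97.5% AP).  Raises if the window is inverted, outside [0, 100], or
    retains no samples."""
    if not (0 <= lo < hi <= 100):
        raise TraceError(f"invalid window {lo}..{hi}: need 0 <= lo < hi <= 100")
    mask = (trace.positions >= lo) & (trace.positions <= hi)
    if not mask.any():
        raise TraceError(f"window {lo}..{hi} retains no samples")
    return replace(
        trace,
        positions=trace.positions[mask],
        intensities={g: y[mask] for g, y in trace.intensities.items()},
    )


Direction = Literal["rising", "falling"]


def boundary_positions(
    trace: ExpressionTrace, gene: str, threshold: float = 0.5
) -> list[tuple[float, Direction]]:
    """All threshold crossings of a normalized series, by linear interpolation.

    The default threshold 0.5 is the half-maximum convention for calling an
    expression boundary on an individually normalised trace.  Returns
    (position, direction) pairs in order; empty if the series never crosses.
    """
    if not trace.normalized:
        raise TraceError("boundary_positions requires a normalized trace")
    if not 0 < threshold < 1:
        raise TraceError("threshold must lie strictly between 0 and 1")
    y = trace.series(gene)
    x = trace.positions
    s = y - threshold
    crossings: list[tuple[float, Direction]] = []
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a < 0 <= b:
            direction: Direction = "rising"
        elif a > 0 >= b:
            direction = "falling"
        else:
            continue
        pos = x[i] + (0.0 - a) * (x[i + 1] - x[i]) / (b - a)
        crossings.append((float(pos), direction))
    return crossings


def boundary_shift(
    reference: ExpressionTrace,
    test: ExpressionTrace,
    gene: str,
    which: Direction,
    index: int | None = None,
) -> float | None:
    """Signed boundary displacement of ``test`` relative to ``reference``.

    Negative = anterior shift.  Returns ``None`` if either trace lacks a
    crossing in the requested direction.  With multiple crossings, ``index``
    selects which (ambiguity raises otherwise).  Both traces must be
    normalized over the same window.
    """
    for name, tr in (("reference", reference), ("test", test)):
        if not tr.normalized:
            raise TraceError(f"{name} trace must be normalized")
    if not np.isclose(reference.positions[0], test.positions[0]) or not np.isclose(
        reference.positions[-1], test.positions[-1]
    ):
        raise TraceError("traces must share the same window")

    def pick(tr: ExpressionTrace) -> float | None:
        hits = [p for p, d in boundary_positions(tr, gene) if d == which]
        if not hits:
            return None
        if len(hits) > 1 and index is None:
            raise TraceError(
                f"{len(hits)} {which} crossings for {gene!r}; pass index= to select one"
            )
        return hits[index if index is not None else 0]

    ref_pos = pick(reference)
    test_pos = pick(test)
    if ref_pos is None or test_pos is None:
        return None
    return test_pos - ref_pos
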