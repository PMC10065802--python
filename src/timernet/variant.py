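"""Ancestral-style timer gene network on a growing 1-D cell row.

In sequentially segmenting insects, cells leave a posterior segment addition
zone and progress through the caudal -> Dichaete -> odd-paired expression
sequence as they mature.  This module rewires the blastoderm timer-gene
module to emulate that regime: a posterior Wnt source replaces the terminal
inputs, Cad becomes Wnt-dependent (posterior Wnt signalling maintains cad and
the zone), and opa acquires timer-gene cross-regulation (repression by Cad
and by strong D) that the fly blastoderm network lacks.  With posterior
growth, a wavefront of phase transitions then emerges without any positional
input other than the Wnt range.

Update rules, applied to the predecessor state of each cell:

=====  ===============================================================
Cad    1 if the cell saw Wnt at the previous step; else 0
D      0 if Opa=2; else 2 if Cad=1; else 1 if previously expressed
D      (weak decay state); else 0
Opa    0 if Cad>=1 or D=2; else min(Opa+1, 2)
=====  ===============================================================

A cell born into the Wnt zone activates Cad immediately (Wnt acts on the
birth state); without this, the Opa ratchet would fire in newborn cells one
step before Cad could repress it, short-circuiting the phase sequence.

All rule modifications are reconstruction choices and are individually
toggleable on :class:`VariantConfig`; disabling all of them (and growth)
recovers the blastoderm network's trunk dynamics in every cell.

Time and space are dimensionless steps and cells; no claim is made about any
particular species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

#: Phase labels in developmental order, anterior-most (oldest) last.
PHASE_ORDER: tuple[str, ...] = ("naive", "cad", "cad+D", "D", "D+opa", "opa")

PHASE_RANK = {p: i for i, p in enumerate(PHASE_ORDER)}


@dataclass(frozen=True)
class VariantConfig:
    """Geometry and rule toggles for the sequential variant.

    ``wnt_range`` posterior-most cells receive Wnt at every step;
    ``growth_per_step`` naive cells are appended at the posterior per step.
    The rule toggles exist so the variant can be reduced back to the
    blastoderm network (all False, ``initial_cad=True``, no Wnt/growth).
    """

    n_cells: int = 2
    n_steps: int = 20
    wnt_range: int = 2
    growth_per_step: int = 1
    cad_requires_wnt: bool = True
    d_requires_cad: bool = True
    opa_repressed_by_timers: bool = True
    initial_cad: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 <= self.wnt_range <= self.n_cells:
            raise ValueError("wnt_range must satisfy 0 <= wnt_range <= n_cells")
        if self.growth_per_step not in (0, 1):
            raise ValueError("growth_per_step must be 0 or 1")


@dataclass
class CellRow:
    """State of the cell row at one step: per-cell Cad/D/Opa levels, the Wnt
    mask, and each cell's birth step.  Cell 0 is the anterior end."""

    step: int
    cad: np.ndarray
    d: np.ndarray
    opa: np.ndarray
    wnt: np.ndarray
    birth: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cad)

    def levels(self, cell: int) -> dict[str, int]:
        return {
            "Cad": int(self.cad[cell]),
            "D": int(self.d[cell]),
            "Opa": int(self.opa[cell]),
        }

    def phases(self) -> list[str]:
        return [phase_of_cell(self, i) for i in range(self.n_cells)]


def phase_of_cell(row: CellRow, cell: int) -> str:
    """Discrete phase label of one cell from its Cad/D/Opa levels.

    Total and deterministic: any combination maps to exactly one of
    :data:`PHASE_ORDER`.  Opa-bearing states rank last; a cell co-expressing
    Cad and Opa (not produced by the shipped rules) counts as Opa-bearing.
    """
    c = row.cad[cell] >= 1
    d = row.d[cell] >= 1
    o = row.opa[cell] >= 1
    if o:
        return "D+opa" if d else "opa"
    if c:
        return "cad+D" if d else "cad"
    if d:
        return "D"
    return "naive"


def _wnt_mask(n_cells: int, wnt_range: int) -> np.ndarray:
    mask = np.zeros(n_cells, dtype=bool)
    if wnt_range > 0:
        mask[n_cells - wnt_range:] = True
    return mask


def simulate_variant(config: VariantConfig) -> list[CellRow]:
    """Simulate the variant network; returns one :class:`CellRow` per step.

    Synchronous update from the previous step's state (including the
    previous step's Wnt exposure); growth appends all-off naive cells at the
    posterior after the update, so a newborn's first state is naive.
    Deterministic: no randomness anywhere.
    """
    n = config.n_cells
    wnt = _wnt_mask(n, config.wnt_range)
    if config.initial_cad:
        cad = np.ones(n, dtype=int)
    elif config.cad_requires_wnt:
        cad = wnt.astype(int)  # Wnt acts on the birth state
    else:
        cad = np.zeros(n, dtype=int)
    d = np.zeros(n, dtype=int)
    opa = np.zeros(n, dtype=int)
    birth = np.zeros(n, dtype=int)
    rows = [CellRow(0, cad, d, opa, wnt, birth)]

    for step in range(1, config.n_steps):
        prev = rows[-1]
        m = prev.n_cells
        cad = np.zeros(m, dtype=int)
        d = np.zeros(m, dtype=int)
        opa = np.zeros(m, dtype=int)
        for i in range(m):
            pc, pd_, po, pw = prev.cad[i], prev.d[i], prev.opa[i], prev.wnt[i]
            if config.cad_requires_wnt:
                cad[i] = 1 if pw else 0
            else:
                cad[i] = 0 if (pd_ >= 1 or po == 2) else 1
            if po == 2:
                d[i] = 0
            elif pc == 1:
                d[i] = 2
            elif config.d_requires_cad:
                d[i] = 1 if pd_ >= 1 else 0
            else:
                d[i] = 1
            timer_block = config.opa_repressed_by_timers and (pc >= 1 or pd_ == 2)
            opa[i] = 0 if timer_block else min(po + 1, 2)
        birth = prev.birth.copy()
        if config.growth_per_step:
            cad = np.append(cad, 0)
            d = np.append(d, 0)
            opa = np.append(opa, 0)
            birth = np.append(birth, step)
        wnt = _wnt_mask(len(cad), config.wnt_range)
        if config.growth_per_step and config.cad_requires_wnt and wnt[-1]:
            cad[-1] = 1  # newborn posterior cell is born into the Wnt zone
        rows.append(CellRow(step, cad, d, opa, wnt, birth))
    return rows


def cell_phase_history(rows: Iterable[CellRow], cell: int) -> list[str]:
    """Phase label of one cell at every step at which it exists."""
    return [phase_of_cell(r, cell) for r in rows if cell < r.n_cells]


def rows_to_frame(rows: Iterable[CellRow]) -> pd.DataFrame:
    """Tidy long-format table: step, cell, factor, level, phase, wnt."""
    records = []
    for row in rows:
        phases = row.phases()
        for i in range(row.n_cells):
            for factor, arr in (("Cad", row.cad), ("D", row.d), ("Opa", row.opa)):
                records.append(
                    {
                        "step": row.step,
                        "cell": i,
                        "factor": factor,
                        "level": int(arr[i]),
                        "phase": phases[i],
                        "wnt": bool(row.wnt[i]),
                    }
                )
    return pd.DataFrame.from_records(records)


def reduction_config(n_cells: int = 4, n_steps: int = 4) -> VariantConfig:
    """Config that strips every variant-specific feature, recovering the
    blastoderm network's trunk dynamics in each (now independent) cell."""
    return VariantConfig(
        n_cells=n_cells,
        n_steps=n_steps,
        wnt_range=0,
        growth_per_step=0,
        cad_requires_wnt=False,
        d_requires_cad=False,
        opa_repressed_by_timers=False,
        initial_cad=True,
    )
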