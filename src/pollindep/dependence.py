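"""Seed-set means and the insect-pollination dependence index (IPD).

A pollinator-exclusion experiment compares seed set of open-pollinated
flowers (OP) with flowers bagged in fine mesh that admits wind- and
self-pollination but excludes insects (PE).  Mean seed set per treatment is
the pooled ratio: total viable seeds over total marked flower units, with
flower units pooled across individual plants of the species.

IPD is the share of open-pollination seed set attributable to insect
visits::

    IPD = 100 * (SS_OP - SS_PE) / SS_OP

clamped below at 0, so IPD = 100 for plants that set no seed without
insects and 0 for plants that self- or wind-pollinate fully.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pollindep.io import SeedSetRecord


@dataclass(frozen=True)
class TreatmentMeans:
    plant_id: str
    ss_op: float
    ss_pe: float
    n_units_op: int
    n_units_pe: int


@dataclass(frozen=True)
class DependenceScore:
    plant_id: str
    ipd: float


def mean_seed_set(records: list[SeedSetRecord], plant: str, treatment: str) -> float:
    """Pooled mean seeds per flower unit for one plant under one treatment."""
    matching = [r for r in records if r.plant_id == plant and r.treatment == treatment]
    if not matching:
        raise ValueError(f"no seed-set records for plant {plant!r}, treatment {treatment!r}")
    return sum(r.seeds for r in matching) / sum(r.flower_units for r in matching)


def ipd(ss_op: float, ss_pe: float) -> float:
    """Insect-pollination dependence in percent, clamped to [0, 100]."""
    if ss_op < 0 or ss_pe < 0:
        raise ValueError("seed-set means must be non-negative")
    if ss_op == 0:
        raise ValueError(
            "IPD undefined: plant set no seeds under open pollination (SS_OP = 0)"
        )
    return max(0.0, 100.0 * (ss_op - ss_pe) / ss_op)


def dependence_table(records: list[SeedSetRecord]) -> pd.DataFrame:
    """Species-level SS_OP, SS_PE, unit counts and IPD for every plant with both treatments."""
    plants = list(dict.fromkeys(r.plant_id for r in records))
    rows = []
    for plant in plants:
        ss_op = mean_seed_set(records, plant, "OP")
        ss_pe = mean_seed_set(records, plant, "PE")
        rows.append(
            {
                "plant_id": plant,
                "ss_op": ss_op,
                "ss_pe": ss_pe,
                "n_units_op": sum(
                    r.flower_units for r in records if r.plant_id == plant and r.treatment == "OP"
                ),
                "n_units_pe": sum(
                    r.flower_units for r in records if r.plant_id == plant and r.treatment == "PE"
                ),
                "ipd": ipd(ss_op, ss_pe),
            }
        )
    return pd.DataFrame(rows)


def count_zero_dependence(table: pd.DataFrame, site: str) -> int:
    """Number of species at a site whose IPD is exactly zero.

    ``table`` is a study table with ``site`` and ``IPD`` columns (the
    packaged fixture, or any frame shaped like it).
    """
    if len(table) == 0:
        return 0
    return int((table.loc[table["site"] == site, "IPD"] == 0).sum())
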