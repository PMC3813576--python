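"""Readers and writers for the package's delimited-text formats.

Two long-format inputs drive the pipeline:

* pollinator-census records — one row per (plant, pollinator) observation
  with the visit count, the number of flowers watched and the census length
  in minutes;
* seed-set experiment records — one row per batch of marked flower units
  under one of two treatments, open pollination (``OP``) or pollinator
  exclusion with mesh bags (``PE``).

Both formats are UTF-8 delimited text with a header (comma by default, tab
accepted).  Species labels are matched case-sensitively after trimming
surrounding whitespace.

The module also ships a packaged fixture with the published species-level
results for the two Mallorcan study communities: the coastal dune Son Bosc
(``SB``, 27 species) and the mountain shrubland Puig Major (``PM``, 11
species), each row carrying observation time, linkage level L, interaction
diversity H, closeness centrality CC and the insect-pollination dependence
IPD in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import math
import pandas as pd

from pollindep.exceptions import FormatError, ParseError

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = ("plant_id", "pollinator_id", "visits", "flowers_observed", "census_minutes")
SEEDSET_COLUMNS = ("plant_id", "treatment", "flower_units", "seeds")
TREATMENTS = ("OP", "PE")

_FIXTURE = "study_species.csv"


@dataclass(frozen=True)
class CensusRecord:
    """One timed pollinator census on one plant-pollinator pair.

    ``visits`` counts contacts of the insect with flower reproductive parts
    over ``flowers_observed`` flowers watched for ``census_minutes`` minutes.
    Zero-visit rows are legal; they contribute no link.
    """

    plant_id: str
    pollinator_id: str
    visits: int
    flowers_observed: int
    census_minutes: float

    def __post_init__(self) -> None:
        if not self.plant_id or not self.pollinator_id:
            raise FormatError("census record needs non-empty plant and pollinator labels")
        if not math.isfinite(self.census_minutes):
            raise FormatError("census_minutes must be finite")
        if self.visits < 0:
            raise FormatError(f"visits must be >= 0, got {self.visits}")
        if self.flowers_observed < 1:
            raise FormatError(f"flowers_observed must be >= 1, got {self.flowers_observed}")
        if self.census_minutes <= 0:
            raise FormatError(f"census_minutes must be > 0, got {self.census_minutes}")


@dataclass(frozen=True)
class SeedSetRecord:
    """Viable-seed count for a batch of marked flower units under one treatment."""

    plant_id: str
    treatment: str
    flower_units: int
    seeds: int

    def __post_init__(self) -> None:
        if not self.plant_id:
            raise FormatError("seed-set record needs a non-empty plant label")
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.flower_units < 1:
            raise FormatError(f"flower_units must be >= 1, got {self.flower_units}")
        if self.seeds < 0:
            raise FormatError(f"seeds must be >= 0, got {self.seeds}")


def _read_table(path: str | Path, columns: Sequence[str], delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        # comma is the default interchange; fall back to tab when the header
        # has no comma at all
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "," if "," in header else "\t"
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return frame


def _to_int(value: str, column: str, row: int) -> int:
    try:
        out = int(value)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric {column} {value!r}") from exc
    return out


def _to_float(value: str, column: str, row: int) -> float:
    try:
        out = float(value)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric {column} {value!r}") from exc
    return out


def read_census(path: str | Path, delimiter: str | None = None) -> list[CensusRecord]:
    """Read pollinator-census records from a delimited text file.

    Rows with zero visits are retained (they document sampling effort but
    add no link).  Duplicate (plant, pollinator) rows are kept as separate
    records — pooling across censuses happens in
    :func:`pollindep.network.build_network`.
    """
    frame = _read_table(path, CENSUS_COLUMNS, delimiter)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                CensusRecord(
                    plant_id=str(row.plant_id).strip(),
                    pollinator_id=str(row.pollinator_id).strip(),
                    visits=_to_int(row.visits, "visits", i),
                    flowers_observed=_to_int(row.flowers_observed, "flowers_observed", i),
                    census_minutes=_to_float(row.census_minutes, "census_minutes", i),
                )
            )
        except FormatError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    if not records:
        logger.warning("%s: no census rows (header only)", path)
    return records


def read_seedset(path: str | Path, delimiter: str | None = None) -> list[SeedSetRecord]:
    """Read seed-set experiment records, preserving file order."""
    frame = _read_table(path, SEEDSET_COLUMNS, delimiter)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                SeedSetRecord(
                    plant_id=str(row.plant_id).strip(),
                    treatment=str(row.treatment).strip(),
                    flower_units=_to_int(row.flower_units, "flower_units", i),
                    seeds=_to_int(row.seeds, "seeds", i),
                )
            )
        except FormatError as exc:
            if "treatment" in str(exc):
                raise FormatError(f"row {i}: {exc}") from exc
            raise ParseError(f"row {i}: {exc}") from exc
    if not records:
        logger.warning("%s: no seed-set rows (header only)", path)
    return records


def write_census(records: Iterable[CensusRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=CENSUS_COLUMNS).to_csv(
        path, index=False
    )


def write_seedset(records: Iterable[SeedSetRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=SEEDSET_COLUMNS).to_csv(
        path, index=False
    )


def fixture_path() -> Path:
    """Path of the packaged study-species fixture CSV."""
    return Path(resources.files("pollindep.data") / _FIXTURE)


def load_study_table(site: str = "both") -> pd.DataFrame:
    """Load the packaged per-species results of the two study communities.

    Parameters
    ----------
    site
        ``"SB"`` (coastal dune, 27 species), ``"PM"`` (mountain, 11 species)
        or ``"both"`` (38 rows).

    Returns
    -------
    DataFrame with columns site, family, species, obs_minutes, L, H, CC, IPD.
    L is an integer count; H is in nats; CC in [0, 1]; IPD in percent.
    """
    if site not in ("SB", "PM", "both"):
        raise ValueError(f"site must be 'SB', 'PM' or 'both', got {site!r}")
    frame = pd.read_csv(fixture_path())
    frame = frame.astype(
        {"obs_minutes": int, "L": int, "H": float, "CC": float, "IPD": float}
    )
    if site != "both":
        frame = frame[frame["site"] == site].reset_index(drop=True)
    return frame
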