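"""Canal-diameter measurement tables and harmonic mean canal diameter (HMC).

The harmonic mean of the minimum diameters of the primary vascular canals in
a bone thin section is the histological proxy driving the whole pipeline:
small canals imply small erythrocytes and hence a high aerobic capacity.
This module reads per-canal measurement tables and reduces them to one HMC
value per thin section.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CanalMeasurementSet",
    "SpecimenRecord",
    "harmonic_mean",
    "read_measurements",
    "write_specimen_table",
    "read_specimen_table",
]

#: Column layout of the raw measurement table (one row per traced canal).
MEASUREMENT_COLUMNS = ("specimen_id", "taxon", "diameter_um")

#: Column layout of the per-specimen output table.
SPECIMEN_COLUMNS = ("taxon", "specimen_id", "hmc_um", "p_end", "status")


@dataclass(frozen=True)
class CanalMeasurementSet:
    """All minimum canal diameters traced on one thin section.

    Parameters
    ----------
    specimen_id
        Collection identifier of the thin section.
    taxon
        Taxon the section belongs to (may contain non-ASCII daggers).
    diameters
        Minimum vascular canal diameters in micrometres, one per traced
        canal, in file order. Must be strictly positive and non-empty.
    """

    specimen_id: str
    taxon: str
    diameters: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.diameters) == 0:
            raise ValueError(
                f"specimen {self.specimen_id!r}: no measurements"
            )
        for k, d in enumerate(self.diameters):
            if not np.isfinite(d) or d <= 0:
                raise ValueError(
                    f"specimen {self.specimen_id!r}: diameter #{k + 1} is "
                    f"{d!r}; all canal diameters must be positive"
                )

    @property
    def n(self) -> int:
        """Number of quantified canals."""
        return len(self.diameters)

    @property
    def hmc(self) -> float:
        """Harmonic mean canal diameter (µm)."""
        return harmonic_mean(self.diameters)


@dataclass(frozen=True)
class SpecimenRecord:
    """One classified thin section: HMC, probability of endothermy, status."""

    specimen_id: str
    taxon: str
    hmc: float
    p_end: float
    status: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_end <= 1.0:
            raise ValueError(f"p_end={self.p_end} outside [0, 1]")
        if self.status not in ("ectothermy", "endothermy"):
            raise ValueError(f"unknown status {self.status!r}")


def harmonic_mean(diameters: Sequence[float] | np.ndarray) -> float:
    """Harmonic mean ``n / sum(1/x_i)`` of positive canal diameters.

    Raises
    ------
    ValueError
        If the collection is empty or contains a non-positive value.
    """
    x = np.asarray(diameters, dtype=float)
    if x.size == 0:
        raise ValueError("no measurements")
    bad = np.flatnonzero(~(x > 0) | ~np.isfinite(x))
    if bad.size:
        k = int(bad[0])
        raise ValueError(
            f"diameter #{k + 1} is {x[k]!r}; harmonic mean requires "
            "strictly positive values"
        )
    return float(x.size / np.sum(1.0 / x))


def _read_delimited(path: str | Path | io.TextIOBase, columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV/TSV with a required header; delimiter is sniffed."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skip_blank_lines=True, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {list(df.columns)}"
        )
    return df


def read_measurements(path: str | Path | io.TextIOBase) -> list[CanalMeasurementSet]:
    """Read a per-canal measurement table into per-specimen sets.

    The file is delimited text (comma or tab, sniffed) with header columns
    ``specimen_id``, ``taxon``, ``diameter_um`` and one row per traced
    canal. One :class:`CanalMeasurementSet` is returned per distinct
    ``specimen_id``, diameters kept in file order.
    """
    df = _read_delimited(path, MEASUREMENT_COLUMNS)
    diam = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df["diameter_um"]):
        try:
            diam[i] = float(raw)
        except (TypeError, ValueError):
            # +2: one for the header line, one for 0- vs 1-based rows
            raise ValueError(
                f"{path}: row {i + 2}: unparseable diameter {raw!r}"
            ) from None
        if not diam[i] > 0:
            raise ValueError(
                f"{path}: row {i + 2}: non-positive diameter {raw!r} "
                f"(specimen {df['specimen_id'].iloc[i]!r})"
            )
    sets: list[CanalMeasurementSet] = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        taxa = grp["taxon"].unique()
        if len(taxa) > 1:
            raise ValueError(
                f"{path}: specimen {spec_id!r} mapped to multiple taxa: "
                f"{list(taxa)}"
            )
        sets.append(
            CanalMeasurementSet(
                specimen_id=str(spec_id),
                taxon=str(taxa[0]),
                diameters=tuple(diam[grp.index]),
            )
        )
    return sets


def write_specimen_table(records: Iterable[SpecimenRecord],
                         path: str | Path) -> None:
    """Write classified specimens as a TSV.

    ``p_end`` is written with full double precision (``repr`` round-trip)
    plus a 3-significant-figure display column ``p_end_3sf``.
    """
    rows = [
        {
            "taxon": r.taxon,
            "specimen_id": r.specimen_id,
            "hmc_um": repr(r.hmc),
            "p_end": repr(r.p_end),
            "p_end_3sf": f"{r.p_end:.2e}",
            "status": r.status,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Inverse of :func:`write_specimen_table` (bit-exact round trip)."""
    df = _read_delimited(path, SPECIMEN_COLUMNS)
    return [
        SpecimenRecord(
            specimen_id=str(row.specimen_id),
            taxon=str(row.taxon),
            hmc=float(row.hmc_um),
            p_end=float(row.p_end),
            status=str(row.status),
        )
        for row in df.itertuples()
    ]
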