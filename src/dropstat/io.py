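"""Reading droplet amplitude exports and plate configuration; writing reports.

Two amplitude dialects are supported:

* ``plain-column`` — one fluorescence value per line, no header.
* ``vendor-export`` — a delimited file with a header row in which every
  column whose name contains ``Amplitude`` is read as one fluorescence
  channel (the QuantaSoft "amplitude and cluster data" export has columns
  like ``Ch1 Amplitude``, ``Ch2 Amplitude``, ``Cluster``).  A ``Cluster``
  column, when present, is retained as the instrument's own droplet category
  but is never used by the classifier.

Plate configuration is a flat ``key = value`` text file.  Decimal commas are
accepted and normalized to points.  All volumes are stored internally in µl;
the partition volume is given in nl in the file and converted on read.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplitudeTable",
    "WellConfig",
    "PlateConfig",
    "DropletFileFormatError",
    "read_amplitudes",
    "read_plate_config",
    "write_report",
    "write_amplitudes",
]

#: platform defaults (Biorad QX200: 23530 droplets of 0.85 nl from 20 µl)
DEFAULT_PARTITION_VOLUME_NL = 0.85
DEFAULT_MAX_PARTITIONS = 23530
NL_PER_UL = 1000.0


class DropletFileFormatError(ValueError):
    """An input file does not parse under the requested dialect."""


@dataclass
class AmplitudeTable:
    """Raw per-droplet end-point fluorescence for one well/channel.

    Attributes
    ----------
    well_id : str
        Well identifier (for file input, derived from the file name).
    channel : str
        Fluorescence channel name (e.g. ``"Ch1"``).
    amplitudes : numpy.ndarray
        End-point fluorescence readings in file order (arbitrary units).
    vendor_labels : numpy.ndarray or None
        Per-droplet category assigned by the instrument software, if the
        export contained one.  Retained for comparison only.
    """

    well_id: str
    channel: str
    amplitudes: np.ndarray
    vendor_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise ValueError("amplitudes must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.vendor_labels is not None:
            self.vendor_labels = np.asarray(self.vendor_labels)
            if self.vendor_labels.shape != self.amplitudes.shape:
                raise ValueError("vendor_labels must match amplitudes in length")

    @property
    def n_droplets(self) -> int:
        return int(self.amplitudes.size)


@dataclass
class WellConfig:
    """Per-well metadata: target, role, and replicate grouping."""

    well_id: str
    target: str = ""
    role: Literal["transgene", "endogene", "control"] = "control"
    replicate_group: str = ""


@dataclass
class PlateConfig:
    """Plate/run configuration.

    Volumes are in µl (``partition_volume_ul`` is converted from the nl
    value in the config file).  ``quantification_level`` is the lowest
    analyte fraction the run is meant to quantify (e.g. 0.01 for 1%); it
    selects the compartmentalization limit in QC.
    """

    loaded_volume_ul: float = 20.0
    partition_volume_ul: float = DEFAULT_PARTITION_VOLUME_NL / NL_PER_UL
    max_partitions: int = DEFAULT_MAX_PARTITIONS
    quantification_level: float = 0.01
    wells: dict[str, WellConfig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loaded_volume_ul <= 0:
            raise ValueError("loaded_volume must be positive")
        if self.partition_volume_ul <= 0:
            raise ValueError("partition_volume must be positive")
        if self.max_partitions < 1:
            raise ValueError("max_partitions must be >= 1")
        if not 0 < self.quantification_level <= 1:
            raise ValueError("quantification_level must be in (0, 1]")

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map replicate-group id -> list of well ids (insertion order)."""
        groups: dict[str, list[str]] = {}
        for well in self.wells.values():
            groups.setdefault(well.replicate_group or well.well_id, []).append(
                well.well_id
            )
        return groups


def _normalize_decimal(text: str) -> str:
    """Turn a continental decimal comma into a point (``0,85`` -> ``0.85``)."""
    return re.sub(r"(?<=\d),(?=\d)", ".", text.strip())


def _sniff_dialect(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "vendor-export" if re.search(r"[A-Za-z]", first) else "plain-column"


def read_amplitudes(
    path: str | Path,
    dialect: Literal["vendor-export", "plain-column", "auto"] = "auto",
) -> list[AmplitudeTable]:
    """Read a droplet amplitude export into one table per channel.

    Parameters
    ----------
    path : path-like
        Amplitude file.  The well id is the file stem.
    dialect : {"vendor-export", "plain-column", "auto"}
        ``plain-column`` is one numeric value per line.  ``vendor-export``
        is a delimited file with a header naming at least one
        ``*Amplitude*`` column.  ``auto`` sniffs: a header row containing
        letters selects the vendor dialect.

    Returns
    -------
    list of AmplitudeTable
        One entry per amplitude column, droplet order preserved.

    Raises
    ------
    DropletFileFormatError
        On a non-numeric amplitude (the message names the offending line),
        a missing amplitude column, or an empty file.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    well_id = path.stem

    if dialect == "plain-column":
        values: list[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text:
                    continue
                try:
                    values.append(float(_normalize_decimal(text)))
                except ValueError:
                    raise DropletFileFormatError(
                        f"{path}: non-numeric amplitude on line {lineno}: {text!r}"
                    ) from None
        if not values:
            raise DropletFileFormatError(f"{path}: no droplets found (empty well)")
        return [AmplitudeTable(well_id=well_id, channel="Ch1", amplitudes=np.array(values))]

    if dialect != "vendor-export":
        raise ValueError(f"unknown dialect: {dialect!r}")

    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            sniffed = csv.Sniffer().sniff(sample, delimiters=",;\t")
            delim = sniffed.delimiter
        except csv.Error:
            delim = ","
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise DropletFileFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        amp_cols = [i for i, h in enumerate(header) if "amplitude" in h.lower()]
        if not amp_cols:
            raise DropletFileFormatError(
                f"{path}: vendor export must contain an 'Amplitude' column; "
                f"header was {header}"
            )
        cluster_col = next(
            (i for i, h in enumerate(header) if "cluster" in h.lower()), None
        )
        columns: dict[int, list[float]] = {i: [] for i in amp_cols}
        clusters: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            for i in amp_cols:
                try:
                    columns[i].append(float(_normalize_decimal(row[i])))
                except (ValueError, IndexError):
                    raise DropletFileFormatError(
                        f"{path}: non-numeric amplitude in column "
                        f"{header[i]!r} on line {lineno}"
                    ) from None
            if cluster_col is not None:
                clusters.append(row[cluster_col].strip())

    if not next(iter(columns.values())):
        raise DropletFileFormatError(f"{path}: no droplets found (empty well)")
    labels = np.array(clusters) if cluster_col is not None else None
    tables = []
    for i in amp_cols:
        name = header[i]
        channel = re.sub(r"(?i)amplitude", "", name).strip(" _-") or "Ch1"
        tables.append(
            AmplitudeTable(
                well_id=well_id,
                channel=channel,
                amplitudes=np.array(columns[i]),
                vendor_labels=labels,
            )
        )
    return tables


def write_amplitudes(table: AmplitudeTable, path: str | Path) -> None:
    """Write a plain one-column amplitude file (full float precision)."""
    with open(path, "w") as fh:
        for value in table.amplitudes:
            fh.write(f"{float(value)!r}\n")


def read_plate_config(path: str | Path) -> PlateConfig:
    """Read a flat ``key = value`` plate configuration file.

    Recognized global keys: ``loaded_volume_ul``, ``partition_volume_nl``,
    ``max_partitions``, ``quantification_level``.  Per-well keys use dotted
    names: ``well.<id>.target``, ``well.<id>.role``,
    ``well.<id>.replicate_group``.  Omitted globals fall back to the QX200
    defaults (0.85 nl partitions, 23530 maximum).  ``#`` starts a comment.
    """
    path = Path(path)
    globals_: dict[str, float] = {}
    wells: dict[str, WellConfig] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DropletFileFormatError(
                    f"{path}: expected 'key = value' on line {lineno}: {raw!r}"
                )
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("well."):
                parts = key.split(".")
                if len(parts) != 3:
                    raise DropletFileFormatError(
                        f"{path}: malformed well key on line {lineno}: {key!r}"
                    )
                _, well_id, attr = parts
                well = wells.setdefault(well_id, WellConfig(well_id=well_id))
                if attr not in ("target", "role", "replicate_group"):
                    raise DropletFileFormatError(
                        f"{path}: unknown well attribute {attr!r} on line {lineno}"
                    )
                if attr == "role" and value not in ("transgene", "endogene", "control"):
                    raise DropletFileFormatError(
                        f"{path}: invalid role {value!r} on line {lineno}"
                    )
                setattr(well, attr, value)
            else:
                try:
                    globals_[key] = float(_normalize_decimal(value))
                except ValueError:
                    raise DropletFileFormatError(
                        f"{path}: non-numeric value for {key!r} on line {lineno}"
                    ) from None
    known = {
        "loaded_volume_ul",
        "partition_volume_nl",
        "max_partitions",
        "quantification_level",
    }
    unknown = set(globals_) - known
    if unknown:
        raise DropletFileFormatError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs: dict = {"wells": wells}
    if "loaded_volume_ul" in globals_:
        kwargs["loaded_volume_ul"] = globals_["loaded_volume_ul"]
    if "partition_volume_nl" in globals_:
        kwargs["partition_volume_ul"] = globals_["partition_volume_nl"] / NL_PER_UL
    if "max_partitions" in globals_:
        kwargs["max_partitions"] = int(globals_["max_partitions"])
    if "quantification_level" in globals_:
        kwargs["quantification_level"] = globals_["quantification_level"]
    return PlateConfig(**kwargs)


def _to_record(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        record = dataclasses.asdict(obj)
    elif isinstance(obj, dict):
        record = dict(obj)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    clean = {}
    for key, value in record.items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, (np.floating, np.integer)):
            value = value.item()
        clean[key] = value
    return clean


def write_report(
    report,
    path: str | Path,
    format: Literal["json", "csv"] = "json",
) -> None:
    """Write one report object or a sequence of them to JSON or CSV.

    Round-trip stable: numeric fields are written at full precision, so a
    read-back compares equal.  CSV output flattens each record into one row.
    """
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        records = [_to_record(report)]
    elif isinstance(report, dict):
        records = [_to_record(report)]
    else:
        records = [_to_record(item) for item in report]
    path = Path(path)
    if format == "json":
        payload = records[0] if len(records) == 1 and not isinstance(report, Sequence) else records
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
    elif format == "csv":
        frame = pd.DataFrame.from_records(records)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format: {format!r}")
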