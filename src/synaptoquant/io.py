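"""Event-table I/O and compensation.

Flow-cytometry events are held in :class:`EventTable`, a thin wrapper around a
pandas DataFrame that distinguishes fluorescence channels from scatter
parameters and carries acquisition metadata.  Two on-disk formats are
supported: FCS 3.0/3.1 list-mode float files (written as 3.1) and plain
delimited tables with a header row.  Spectral-overlap compensation is the
exact linear inverse of a user-supplied spillover matrix.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "AntibodyPanel",
    "read_events",
    "write_events",
    "apply_compensation",
    "estimate_spillover",
]


class EventTable:
    """Per-event channel intensities plus scatter and optional population labels.

    Parameters
    ----------
    data
        One column per parameter (fluorescence channels and scatter), one row
        per event.  Values are arbitrary fluorescence units.
    channels
        Names of the fluorescence channels (columns of ``data``).
    scatter
        Names of the scatter parameters (e.g. ``["FSC", "SSC"]``).
    labels
        Optional per-event population tag (cells, BSLBs, doublets, debris,
        calibration beads...).
    metadata
        Instrument / acquisition metadata (FCS keywords survive a round trip).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        channels: Sequence[str],
        scatter: Sequence[str] = (),
        labels: pd.Series | Sequence[str] | None = None,
        metadata: Mapping[str, str] | None = None,
    ):
        channels = list(channels)
        scatter = list(scatter)
        names = channels + scatter
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {sorted(names)}")
        missing = [c for c in names if c not in data.columns]
        if missing:
            raise ValueError(f"columns absent from data: {missing}")
        self.data = data.reset_index(drop=True)
        self.channels = channels
        self.scatter = scatter
        if labels is not None:
            labels = pd.Series(list(labels), name="population")
            if len(labels) != len(self.data):
                raise ValueError("labels length does not match event count")
            labels = labels.reset_index(drop=True)
        self.labels = labels
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.data)

    def intensity(self, channel: str) -> np.ndarray:
        """Per-event intensities of one channel as a float array."""
        return self.data[channel].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Events selected by a boolean mask, labels and metadata preserved."""
        labels = self.labels[mask].reset_index(drop=True) if self.labels is not None else None
        return EventTable(
            self.data.loc[mask].reset_index(drop=True),
            self.channels,
            self.scatter,
            labels,
            self.metadata,
        )

    def with_channels(self, new: pd.DataFrame) -> "EventTable":
        """Copy of the table with fluorescence columns replaced."""
        data = self.data.copy()
        for c in self.channels:
            data[c] = new[c].to_numpy()
        return EventTable(data, self.channels, self.scatter, self.labels, self.metadata)


@dataclass(frozen=True)
class PanelEntry:
    """One detection antibody: channel it is read on, F/P ratio, control id."""

    channel: str
    f_over_p: float
    isotype_acquisition: str | None = None

    def __post_init__(self):
        if self.f_over_p <= 0:
            raise ValueError(f"F/P ratio must be positive, got {self.f_over_p}")


@dataclass
class AntibodyPanel:
    """Marker name -> (detection channel, fluorophore-to-protein ratio, control).

    The F/P ratio divides calibrated fluorochrome counts to give bound
    antibodies (and hence molecules) per event.
    """

    markers: dict[str, PanelEntry] = field(default_factory=dict)

    def add(self, marker: str, channel: str, f_over_p: float,
            isotype_acquisition: str | None = None) -> None:
        self.markers[marker] = PanelEntry(channel, f_over_p, isotype_acquisition)

    def validate_against(self, events: EventTable) -> None:
        for name, entry in self.markers.items():
            if entry.channel not in events.channels:
                raise ValueError(
                    f"marker {name!r} maps to channel {entry.channel!r} "
                    f"which is not in the event table"
                )

    def __getitem__(self, marker: str) -> PanelEntry:
        return self.markers[marker]


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode float I/O
# ---------------------------------------------------------------------------

_DELIM = "/"


def _write_fcs(path: Path, table: EventTable) -> None:
    """Write an FCS 3.1 file: list mode, float32, little endian."""
    names = table.channels + table.scatter
    arr = table.data[names].to_numpy(dtype=np.float32)
    n_events, n_par = arr.shape
    data_bytes = arr.tobytes()

    text: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i, name in enumerate(names, start=1):
        text[f"$P{i}N"] = name
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(arr[:, i - 1], initial=0.0))
        text[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)
    # user metadata: keywords must not start with '$' unless standard
    for k, v in table.metadata.items():
        if not k.startswith("$"):
            text[k] = str(v)

    def render(begin_data: int, end_data: int) -> bytes:
        text["$BEGINDATA"] = str(begin_data)
        text["$ENDDATA"] = str(end_data)
        parts = [_DELIM]
        for k, v in text.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("utf-8")

    # two-pass: text length depends on the data offsets it embeds
    header_len = 58
    text_start = header_len
    begin = end = 0
    for _ in range(3):
        body = render(begin, end)
        new_begin = text_start + len(body)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin, end):
            break
        begin, end = new_begin, new_end
    body = render(begin, end)
    text_end = text_start + len(body) - 1

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin if begin <= 99999999 else 0:>8d}".encode()
        + f"{end if end <= 99999999 else 0:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)
        fh.write(data_bytes)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty FCS TEXT segment")
    delim = raw[:1].decode("latin-1")
    fields = raw.decode("latin-1").split(delim)[1:]
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2) if fields[i]}


def _read_fcs(path: Path, scatter_names: Sequence[str] = ("FSC", "SSC")) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode float/double file."""
    blob = Path(path).read_bytes()
    if len(blob) < 58:
        raise ValueError(f"{path}: too short to be an FCS file")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r} (need 3.0/3.1)")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FCS header offsets") from exc
    text = _parse_text_segment(blob[text_start:text_end + 1])

    if text.get("$MODE", "L") != "L":
        raise ValueError(f"{path}: only list-mode FCS is supported")
    dtype_code = text.get("$DATATYPE", "F")
    if dtype_code == "F":
        itemsize, fmt = 4, "f"
    elif dtype_code == "D":
        itemsize, fmt = 8, "d"
    else:
        raise ValueError(f"{path}: only float FCS data supported, got $DATATYPE={dtype_code}")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    begin = int(text.get("$BEGINDATA") or blob[26:34])
    data = blob[begin:begin + n_par * n_tot * itemsize]
    arr = np.array(struct.unpack(f"{endian}{n_par * n_tot}{fmt}", data), dtype=float)
    arr = arr.reshape(n_tot, n_par)

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate channel names {names}")
    df = pd.DataFrame(arr, columns=names)
    scatter = [n for n in names if n in scatter_names or n.startswith(("FSC", "SSC"))]
    channels = [n for n in names if n not in scatter]
    meta = {k: v for k, v in text.items() if not k.startswith("$")}
    meta["fcs_version"] = version.strip()
    return EventTable(df, channels, scatter, metadata=meta)


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

# columns that describe the condition rather than a detector
_SPECIAL_COLUMNS = ("population", "event_id", "dose", "acquisition", "tcell_population")


def _write_delimited(path: Path, table: EventTable, sep: str) -> None:
    df = table.data.copy()
    df.insert(0, "event_id", np.arange(len(df)))
    if table.labels is not None:
        df["population"] = table.labels.to_numpy()
    df.to_csv(path, sep=sep, index=False)


def _read_delimited(path: Path, sep: str, scatter_names=("FSC", "SSC")) -> EventTable:
    df = pd.read_csv(path, sep=sep)
    labels = df["population"] if "population" in df.columns else None
    data = df.drop(columns=[c for c in ("event_id", "population") if c in df.columns])
    value_cols = [c for c in data.columns
                  if c not in _SPECIAL_COLUMNS and pd.api.types.is_numeric_dtype(data[c])]
    scatter = [c for c in value_cols if c in scatter_names or c.startswith(("FSC", "SSC"))]
    channels = [c for c in value_cols if c not in scatter]
    return EventTable(data, channels, scatter, labels)


def read_events(path: str | Path, format: str = "auto") -> EventTable:
    """Read events from an FCS 3.0/3.1 file or a delimited table.

    ``format`` is one of ``"fcs"``, ``"csv"``, ``"tsv"`` or ``"auto"``
    (sniffed from the extension, falling back to the FCS magic bytes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix == ".fcs":
            fmt = "fcs"
        elif suffix in (".tsv", ".tab", ".txt"):
            fmt = "tsv"
        elif suffix == ".csv":
            fmt = "csv"
        else:
            fmt = "fcs" if path.read_bytes()[:3] == b"FCS" else "csv"
    if fmt == "fcs":
        return _read_fcs(path)
    if fmt in ("csv", "delimited"):
        return _read_delimited(path, ",")
    if fmt == "tsv":
        return _read_delimited(path, "\t")
    raise ValueError(f"unknown event format {format!r}")


def write_events(path: str | Path, table: EventTable, format: str = "auto") -> None:
    """Write events as FCS 3.1 or a delimited table (by ``format`` or extension)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = {".fcs": "fcs", ".tsv": "tsv"}.get(path.suffix.lower(), "csv")
    if fmt == "fcs":
        _write_fcs(path, table)
    elif fmt in ("csv", "delimited"):
        _write_delimited(path, table, ",")
    elif fmt == "tsv":
        _write_delimited(path, table, "\t")
    else:
        raise ValueError(f"unknown event format {format!r}")


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------


def apply_compensation(events: EventTable, spillover: np.ndarray | pd.DataFrame) -> EventTable:
    """Unmix fluorescence channels with the inverse of a spillover matrix.

    ``spillover[i, j]`` is the fraction of channel ``j``'s true signal that
    is read on detector ``i`` (diagonal 1), so an observed event vector is
    ``spillover @ true`` and compensation solves that linear system per
    event.  Negative compensated values are kept; the original table is
    untouched.
    """
    names = events.channels
    if isinstance(spillover, pd.DataFrame):
        spillover = spillover.loc[names, names].to_numpy(dtype=float)
    else:
        spillover = np.asarray(spillover, dtype=float)
    n = len(names)
    if spillover.shape != (n, n):
        raise ValueError(
            f"spillover matrix shape {spillover.shape} does not match "
            f"{n} fluorescence channels {names}"
        )
    if abs(np.linalg.det(spillover)) < 1e-12:
        raise ValueError(f"singular spillover matrix over channels {names}")
    observed = events.data[names].to_numpy(dtype=float)
    compensated = np.linalg.solve(spillover, observed.T).T
    return events.with_channels(pd.DataFrame(compensated, columns=names))


def estimate_spillover(single_stains: Mapping[str, EventTable]) -> pd.DataFrame:
    """Approximate spillover matrix from single-stain controls.

    For each control (keyed by its primary channel) the spill into every other
    channel is estimated as the ratio of median off-channel to median
    on-channel intensity.  This per-channel slope estimate is a simple
    approximation, not a full unmixing model.
    """
    channels = None
    for table in single_stains.values():
        if channels is None:
            channels = table.channels
        elif table.channels != channels:
            raise ValueError("single-stain controls must share the same channels")
    if channels is None:
        raise ValueError("no single-stain controls given")
    mat = pd.DataFrame(np.eye(len(channels)), index=channels, columns=channels)
    for primary, table in single_stains.items():
        if primary not in channels:
            raise ValueError(f"control channel {primary!r} not in panel channels")
        on = np.median(table.intensity(primary))
        if on <= 0:
            raise ValueError(f"non-positive on-channel median for {primary!r}")
        for other in channels:
            if other != primary:
                mat.loc[primary, other] = max(np.median(table.intensity(other)), 0.0) / on
    return mat
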