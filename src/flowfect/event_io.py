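"""Cytometry event I/O and per-channel transforms.

Event data are held in an :class:`EventTable`, an events x channels matrix of
acquisition-scale (linear) values with role-annotated channels.  Roles attach
the assay semantics to detectors: forward/side scatter pulse parameters for
gating (``fsc_a``, ``fsc_h``, ``ssc_a``), the labeled-plasmid channel
(``dna_label``, e.g. FITC), the expressed-protein channel (``protein``, e.g.
mCherry or an antibody conjugate) and an optional dead-cell dye channel
(``viability``).

Files are read and written as FCS 3.1 list-mode float or as plain CSV with a
header row of channel names.  All summary statistics elsewhere in the package
are computed on the untransformed linear values; :func:`transform_channel`
exists for gate geometry and display only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

ROLES = ("fsc_a", "fsc_h", "ssc_a", "dna_label", "protein", "viability", "other")
MANDATORY_ROLES = ("fsc_a", "fsc_h", "ssc_a")


@dataclass(frozen=True)
class Channel:
    """A detector column: short name, assay role and acquisition scale."""

    name: str
    role: str = "other"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown channel role {self.role!r}")
        if self.scale not in ("linear", "log_acquired"):
            raise ConfigurationError(f"unknown channel scale {self.scale!r}")


@dataclass
class EventTable:
    """Events x channels matrix with channel metadata.

    ``values`` is float64, shape ``(n_events, n_channels)``; rows containing
    non-finite values are dropped at load time and counted in ``n_dropped``.
    """

    values: np.ndarray
    channels: list[Channel]
    sample_id: str = ""
    timepoint_h: float | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values.reshape(0, len(self.channels))
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ConfigurationError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate channel names: {names}")
        assigned = [c.role for c in self.channels if c.role != "other"]
        if len(set(assigned)) != len(assigned):
            raise ConfigurationError(f"duplicate channel roles: {assigned}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def has_role(self, role: str) -> bool:
        return any(c.role == role for c in self.channels)

    def role_index(self, role: str) -> int:
        for i, c in enumerate(self.channels):
            if c.role == role:
                return i
        raise ConfigurationError(f"no channel with role {role!r}")

    def column(self, role: str) -> np.ndarray:
        """Values of the channel assigned to ``role`` (view, do not mutate)."""
        return self.values[:, self.role_index(role)]

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row-subset sharing channel metadata."""
        return replace(self, values=self.values[np.asarray(mask)], n_dropped=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


def _apply_role_map(names: Sequence[str], role_map: Mapping[str, str] | None,
                    require_scatter: bool) -> list[Channel]:
    role_map = dict(role_map or {})
    lower = {}
    for k, v in role_map.items():
        if v not in ROLES:
            raise ConfigurationError(f"unknown role {v!r} for channel {k!r}")
        lower[k.lower()] = v
    channels = []
    seen = set()
    for name in names:
        role = lower.pop(name.lower(), "other")
        if role != "other" and role in seen:
            raise ConfigurationError(f"role {role!r} assigned twice")
        seen.add(role)
        channels.append(Channel(name=name, role=role))
    if lower:
        raise ConfigurationError(
            f"role map names channels absent from file: {sorted(lower)}"
        )
    if require_scatter:
        missing = [r for r in MANDATORY_ROLES if r not in seen]
        if missing:
            raise ConfigurationError(f"mandatory roles not mapped: {missing}")
    return channels


def _drop_nonfinite(values: np.ndarray) -> tuple[np.ndarray, int]:
    finite = np.isfinite(values).all(axis=1)
    return values[finite], int((~finite).sum())


# ---------------------------------------------------------------------------
# FCS 3.0/3.1 list-mode
# ---------------------------------------------------------------------------

def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are rare; handle by split-and-rejoin.
    parts = body.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"" and i + 2 < len(parts):
            tok = tok + delim + parts[i + 2]
            i += 2
        tokens.append(tok.decode("utf-8", "replace"))
        i += 1
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[j].strip().upper(): tokens[j + 1] for j in range(0, len(tokens), 2)}


def _read_fcs(path: Path, role_map, require_scatter) -> EventTable:
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError(f"{path}: truncated FCS header")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _off(lo: int, hi: int) -> int:
        s = blob[lo:hi].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    try:
        text = _parse_fcs_text(blob[text_begin:text_end + 1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: unparsable TEXT segment: {exc}") from exc

    if int(text.get("$BEGINDATA", 0) or 0) > 0:
        data_begin = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").strip().upper()
    byteord = text.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_bytes = n_tot * n_par * dtype.itemsize
    raw = blob[data_begin:data_begin + n_bytes]
    if len(raw) < n_bytes:
        raise FormatError(f"{path}: DATA segment shorter than $TOT*$PAR")
    values = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    values = values.reshape(n_tot, n_par) if n_tot else values.reshape(0, n_par)
    values = values.copy()

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
        names.append(name)
        # Log-amplified parameters: x -> f2 * 10^(f1*x/range); gains divide.
        pne = text.get(f"$P{i}E", "0,0").split(",")
        f1 = float(pne[0]) if pne[0] else 0.0
        f2 = float(pne[1]) if len(pne) > 1 and pne[1] else 0.0
        if f1 > 0:
            rng = float(text.get(f"$P{i}R", 1024) or 1024)
            values[:, i - 1] = (f2 or 1.0) * 10.0 ** (f1 * values[:, i - 1] / rng)
        else:
            gain = float(text.get(f"$P{i}G", 1) or 1)
            if gain not in (0.0, 1.0):
                values[:, i - 1] /= gain

    # Match role map case-insensitively against $PnN and $PnS.
    alias = {}
    for i in range(1, n_par + 1):
        for key in (f"$P{i}N", f"$P{i}S"):
            if key in text and text[key]:
                alias[text[key].lower()] = names[i - 1]
    resolved = {alias.get(k.lower(), k): v for k, v in (role_map or {}).items()}
    channels = _apply_role_map(names, resolved, require_scatter)
    values, n_dropped = _drop_nonfinite(values)

    timepoint = text.get("TIMEPOINT_H")
    return EventTable(
        values=values,
        channels=channels,
        sample_id=text.get("SAMPLE_ID", text.get("$FIL", path.stem)),
        timepoint_h=float(timepoint) if timepoint not in (None, "") else None,
        n_dropped=n_dropped,
    )


def _write_fcs(table: EventTable, path: Path) -> None:
    n, p = table.values.shape
    data = table.values.astype("<f4").tobytes()
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{begindata:>10d}"), ("$ENDDATA", "{enddata:>10d}"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"), ("$TOT", str(n)), ("$PAR", str(p)),
        ("SAMPLE_ID", table.sample_id or path.stem),
    ]
    if table.timepoint_h is not None:
        keywords.append(("TIMEPOINT_H", repr(float(table.timepoint_h))))
    for i, ch in enumerate(table.channels, start=1):
        col = table.values[:, i - 1]
        rng = float(np.max(col)) if n else 1.0
        keywords += [
            (f"$P{i}N", ch.name), (f"$P{i}S", ch.name),
            (f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(max(int(np.ceil(rng)) + 1, 1024))),
        ]
    template = "/" + "".join(f"{k}/{v}/" for k, v in keywords)
    text_begin = 58
    text_len = len(template.format(begindata=0, enddata=0))
    data_begin = text_begin + text_len
    data_end = data_begin + len(data) - 1 if data else 0
    text = template.format(begindata=data_begin, enddata=data_end).encode("ascii")
    assert len(text) == text_len

    header = b"FCS3.1    "
    header += f"{text_begin:>8d}".encode()
    header += f"{text_begin + text_len - 1:>8d}".encode()
    if data and data_end <= 99_999_999:
        header += f"{data_begin:>8d}".encode() + f"{data_end:>8d}".encode()
    else:
        header += f"{0:>8d}".encode() * 2
    header += f"{0:>8d}".encode() * 2
    assert len(header) == 58
    path.write_bytes(header + text + data)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, role_map, require_scatter) -> EventTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unparsable CSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: CSV has no columns")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    values, n_dropped = _drop_nonfinite(values)
    channels = _apply_role_map([str(c) for c in df.columns], role_map, require_scatter)
    return EventTable(values=values, channels=channels,
                      sample_id=path.stem, n_dropped=n_dropped)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".fcs":
        return "fcs"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ConfigurationError(f"cannot infer format from {path.name!r}")


def read_events(path, format: str | None = None,
                role_map: Mapping[str, str] | None = None,
                require_scatter: bool = True) -> EventTable:
    """Read an event file into an :class:`EventTable`.

    Parameters
    ----------
    path : path-like
        FCS 3.0/3.1 or CSV file.
    format : {"fcs", "csv"}, optional
        Inferred from the suffix when omitted.
    role_map : mapping, optional
        Channel name -> role, e.g. ``{"FSC-A": "fsc_a"}``. Matching is
        case-insensitive against the CSV header or the FCS $PnN/$PnS keywords.
    require_scatter : bool
        Require the three scatter roles needed for gating. Disable for
        single-channel files such as MESF bead acquisitions.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        return _read_fcs(path, role_map, require_scatter)
    if fmt == "csv":
        return _read_csv(path, role_map, require_scatter)
    raise ConfigurationError(f"unknown format {fmt!r}")


def write_events(table: EventTable, path, format: str | None = None) -> None:
    """Write ``table`` as FCS 3.1 (list-mode float) or CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "fcs":
            _write_fcs(table, path)
        elif fmt == "csv":
            table.to_dataframe().to_csv(path, index=False)
        else:
            raise ConfigurationError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Transforms (gate geometry / display only; statistics stay on linear scale)
# ---------------------------------------------------------------------------

def transform_channel(table: EventTable, role: str, transform: str,
                      cofactor: float = 150.0, floor: float = 1.0) -> EventTable:
    """Return a new table with one channel transformed.

    ``linear`` is the identity; ``log10_floor`` maps values <= ``floor`` to
    ``log10(floor)``; ``asinh`` applies ``asinh(x / cofactor)``.  The input
    table is never modified.
    """
    idx = table.role_index(role)
    x = table.values[:, idx]
    if transform == "linear":
        y = x.copy()
    elif transform == "log10_floor":
        if floor <= 0:
            raise ConfigurationError("log10_floor requires floor > 0")
        y = np.log10(np.maximum(x, floor))
    elif transform == "asinh":
        if cofactor <= 0:
            raise ConfigurationError("asinh requires cofactor > 0")
        y = np.arcsinh(x / cofactor)
    else:
        raise ConfigurationError(f"unknown transform {transform!r}")
    values = table.values.copy()
    values[:, idx] = y
    return replace(table, values=values)
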