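"""Reading and writing event-level data.

Two on-disk forms are supported:

* **FCS 3.0/3.1** — list-mode, floating-point data.  The implementation here
  is intentionally minimal: it reads the HEADER/TEXT/DATA segments of
  single-dataset files with ``$DATATYPE`` F or D and a uniform ``$PnB``, and
  writes FCS 3.1 with float32 little-endian data.  Channel roles and marker
  names are carried in vendor keywords (``CYTOSCREENnROLE`` /
  ``CYTOSCREENnMARKER``) and can be overridden by a user-supplied channel
  map, since ``$PnS`` conventions vary by instrument.
* **plain-matrix TSV** — a tab-separated text table with a small comment
  header; convenient for fixtures and diffable artifacts.

Raw FCS files hold linear-scale values; if an :class:`EventMatrix` is
arcsinh-transformed, :func:`write_fcs` writes the inverse-transformed
(linear) values and records the cofactors so a round trip is lossless up to
float32 precision.
"""

from __future__ import annotations

import io as _io
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .events import (
    MARKER,
    METADATA_COLUMNS,
    Channel,
    EventMatrix,
    inverse_transform,
    transform as _transform,
)

_DELIM = "/"


# ---------------------------------------------------------------------------
# FCS writing
# ---------------------------------------------------------------------------

def write_fcs(events: EventMatrix, path: str | Path) -> None:
    """Write an EventMatrix as a single-dataset FCS 3.1 file.

    Data are stored as linear-scale float32, list mode, little-endian.
    """
    em = inverse_transform(events) if events.transform == "arcsinh" else events
    n_events, n_par = em.values.shape
    data = em.values.astype("<f4").tobytes()

    kw: dict[str, str] = {
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
        "$FIL": em.sample_id,
    }
    for j, ch in enumerate(em.channels, start=1):
        rng = float(np.max(em.values[:, j - 1], initial=0.0))
        kw[f"$P{j}B"] = "32"
        kw[f"$P{j}E"] = "0,0"
        kw[f"$P{j}N"] = ch.name
        kw[f"$P{j}R"] = str(int(rng) + 1)
        if ch.marker:
            kw[f"$P{j}S"] = ch.marker
        kw[f"CYTOSCREEN{j}ROLE"] = ch.role
        if ch.marker:
            kw[f"CYTOSCREEN{j}MARKER"] = ch.marker
        if ch.name in events.cofactors:
            kw[f"CYTOSCREEN{j}COFACTOR"] = repr(events.cofactors[ch.name])

    # TEXT with fixed-width (10-digit) offsets so its length is known before
    # the offsets themselves are.
    header_len = 58  # "FCS3.1" + 4 spaces + 6 x 8-char offsets
    placeholder = {"$BEGINDATA": "0" * 10, "$ENDDATA": "0" * 10}
    text_len = _text_length({**kw, **placeholder})
    begin_data = header_len + text_len
    end_data = begin_data + len(data) - 1 if data else 0
    kw["$BEGINDATA"] = str(begin_data).zfill(10)
    kw["$ENDDATA"] = str(end_data).zfill(10)
    text = _serialize_text(kw)
    assert len(text) == text_len

    begin_text = header_len
    end_text = begin_text + text_len - 1

    def _off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT offsets remain valid
        return s.rjust(8).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(b"FCS3.1    ")
        fh.write(_off(begin_text) + _off(end_text))
        fh.write(_off(begin_data if data else 0) + _off(end_data))
        fh.write(_off(0) + _off(0))
        fh.write(text)
        fh.write(data)


def _serialize_text(kw: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key in sorted(kw):
        val = kw[key] if kw[key] != "" else " "
        if _DELIM in key or _DELIM in val:
            raise ValueError(f"delimiter {_DELIM!r} inside keyword {key!r}")
        parts.append(f"{key}{_DELIM}{val}{_DELIM}")
    return "".join(parts).encode("utf-8")


def _text_length(kw: dict[str, str]) -> int:
    return len(_serialize_text(kw))


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

def read_fcs(
    path: str | Path,
    channel_map: dict[str, dict] | None = None,
) -> EventMatrix:
    """Read a single-dataset FCS 3.0/3.1 file with float data.

    ``channel_map`` maps channel ($PnN) names to ``{"role": ..., "marker":
    ...}`` and takes precedence over keywords embedded in the file.  Channels
    matched by neither are retained with ``mapped=False``.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58 or raw[:3] != b"FCS":
        raise ValueError(f"{path}: not an FCS file")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _hoff(i: int) -> int:
        field = raw[10 + 8 * i : 18 + 8 * i].decode("ascii").strip()
        return int(field) if field else 0

    begin_text, end_text = _hoff(0), _hoff(1)
    kw = _parse_text(raw[begin_text : end_text + 1])

    begin_data = int(kw.get("$BEGINDATA") or _hoff(2))
    end_data = int(kw.get("$ENDDATA") or _hoff(3))

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    if datatype not in ("F", "D"):
        raise ValueError(f"{path}: only float FCS data supported, got {datatype}")
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError(f"{path}: only list-mode FCS supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    width = 4 if datatype == "F" else 8
    for j in range(1, n_par + 1):
        if int(kw.get(f"$P{j}B", width * 8)) != width * 8:
            raise ValueError(f"{path}: $P{j}B inconsistent with $DATATYPE")

    n_bytes = n_par * n_tot * width
    buf = raw[begin_data : begin_data + n_bytes]
    if len(buf) != n_bytes:
        raise ValueError(f"{path}: DATA segment truncated")
    dt = np.dtype(f"{endian}f{width}")
    values = np.frombuffer(buf, dtype=dt).reshape(n_tot, n_par).astype(float)

    channels = []
    cofactors: dict[str, float] = {}
    for j in range(1, n_par + 1):
        name = kw.get(f"$P{j}N", f"P{j}")
        role = kw.get(f"CYTOSCREEN{j}ROLE")
        marker = kw.get(f"CYTOSCREEN{j}MARKER") or kw.get(f"$P{j}S")
        mapped = role is not None
        if channel_map and name in channel_map:
            entry = channel_map[name]
            role = entry.get("role", MARKER)
            marker = entry.get("marker", marker)
            mapped = True
        if role is None:
            role = MARKER
        channels.append(
            Channel(name=name, role=role,
                    marker=marker if role == MARKER else None, mapped=mapped)
        )
        cf = kw.get(f"CYTOSCREEN{j}COFACTOR")
        if cf is not None:
            cofactors[name] = float(cf)

    sample_id = kw.get("$FIL") or Path(path).stem
    em = EventMatrix(sample_id=sample_id, channels=channels, values=values)
    if cofactors:
        # file was written from an arcsinh-transformed matrix; restore it
        em = _transform(em, cofactors)
    return em


def _parse_text(seg: bytes) -> dict[str, str]:
    text = seg.decode("utf-8", "replace")
    if not text:
        raise ValueError("empty TEXT segment")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise ValueError("malformed FCS TEXT segment (odd token count)")
    kw = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        key = k.strip().upper() if k.startswith("$") else k.strip()
        if key in kw:
            raise ValueError(f"duplicate FCS keyword {key!r}")
        kw[key] = v
    return kw


# ---------------------------------------------------------------------------
# plain-matrix TSV
# ---------------------------------------------------------------------------

def write_plain(events: EventMatrix, path: str | Path) -> None:
    """Write the package's plain-matrix TSV format (values as analysed)."""
    with open(path, "w") as fh:
        fh.write("#cytoscreen-events\tv1\n")
        fh.write(f"#sample_id\t{events.sample_id}\n")
        fh.write(f"#transform\t{events.transform}\n")
        for ch in events.channels:
            cf = events.cofactors.get(ch.name, "")
            fh.write(
                f"#channel\t{ch.name}\t{ch.role}\t{ch.marker or ''}\t{cf}\n"
            )
        fh.write("\t".join(events.channel_names) + "\n")
        np.savetxt(fh, events.values, delimiter="\t", fmt="%.10g")


def read_plain(path: str | Path) -> EventMatrix:
    sample_id = Path(path).stem
    tf = "none"
    channels: list[Channel] = []
    cofactors: dict[str, float] = {}
    header_lines = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#cytoscreen-events"):
            raise ValueError(f"{path}: not a cytoscreen plain-matrix file")
        header_lines += 1
        for line in fh:
            header_lines += 1
            if not line.startswith("#"):
                break
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#sample_id":
                sample_id = parts[1]
            elif parts[0] == "#transform":
                tf = parts[1]
            elif parts[0] == "#channel":
                name, role, marker, cf = parts[1], parts[2], parts[3], parts[4]
                channels.append(
                    Channel(name=name, role=role, marker=marker or None)
                )
                if cf:
                    cofactors[name] = float(cf)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no data.*")
        values = np.loadtxt(path, delimiter="\t", skiprows=header_lines,
                            ndmin=2)
    if values.size == 0:
        values = np.empty((0, len(channels)))
    if values.shape[1] != len(channels):
        raise ValueError(f"{path}: column count does not match channel header")
    return EventMatrix(
        sample_id=sample_id, channels=channels, values=values,
        transform=tf, cofactors=cofactors,
    )


def read_events(
    path: str | Path, channel_map: dict[str, dict] | None = None
) -> EventMatrix:
    """Read either an FCS file or a plain-matrix TSV, sniffing the format."""
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic == b"FCS":
        return read_fcs(path, channel_map=channel_map)
    return read_plain(path)


def write_events(events: EventMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        write_fcs(events, path)
    else:
        write_plain(events, path)


# ---------------------------------------------------------------------------
# metadata CSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path,
                   provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        df.to_csv(fh, index=False)
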