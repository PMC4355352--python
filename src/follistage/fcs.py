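"""Minimal FCS 3.0/3.1 list-mode reader and float writer.

Covers the subset of the flow-cytometry standard the pipeline needs:
single-dataset files, list-mode ($MODE L) data in float ($DATATYPE F/D)
or unsigned integer ($DATATYPE I) with byte order $BYTEORD 1,2,3,4 or
4,3,2,1. Parameter short names ($PnN) become column names. The writer
emits FCS 3.1 float32 little-endian, enough for lossless round-trips of
event tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class FcsParseError(ValueError):
    pass


def _read_text_segment(raw: bytes, start: int, end: int) -> dict:
    text = raw[start : end + 1]
    if not text:
        raise FcsParseError("empty TEXT segment")
    delim = text[0:1]
    parts = text[1:].split(delim)
    # trailing delimiter produces one empty tail element
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsParseError("TEXT segment has an odd number of tokens")
    out = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        out[key] = parts[i + 1].decode("utf-8", "replace").strip()
    return out


def read_fcs(path) -> pd.DataFrame:
    """Read an FCS 3.x file into an events x parameters table."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FcsParseError("file too short to hold an FCS header")
    version = raw[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FcsParseError(f"unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FcsParseError(f"malformed header offsets: {exc}") from exc

    keys = _read_text_segment(raw, text_start, text_end)
    if data_start == 0 and data_end == 0:
        data_start = int(keys.get("$BEGINDATA", 0))
        data_end = int(keys.get("$ENDDATA", 0))
    if data_end <= data_start:
        raise FcsParseError("DATA segment offsets are invalid")

    mode = keys.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsParseError(f"only list mode is supported, got $MODE={mode}")
    n_par = int(keys["$PAR"])
    n_events = int(keys["$TOT"])
    dtype_code = keys.get("$DATATYPE", "F").upper()
    byteord = keys.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(keys.get(f"$P{i + 1}B", 32)) for i in range(n_par)]
    names = [keys.get(f"$P{i + 1}N", f"P{i + 1}") for i in range(n_par)]
    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise FcsParseError("$DATATYPE F requires 32-bit parameters")
        np_dtype = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        if any(b != 64 for b in bits):
            raise FcsParseError("$DATATYPE D requires 64-bit parameters")
        np_dtype = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FcsParseError("$DATATYPE I supported only for uniform 16/32-bit parameters")
        np_dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FcsParseError(f"unsupported $DATATYPE {dtype_code!r}")

    need = n_par * n_events * np_dtype.itemsize
    data = raw[data_start : data_start + need]
    if len(data) < need:
        raise FcsParseError("DATA segment shorter than $PAR * $TOT events")
    arr = np.frombuffer(data, dtype=np_dtype).reshape(n_events, n_par)
    return pd.DataFrame(arr.astype(float), columns=names)


def write_fcs(path, table: pd.DataFrame) -> None:
    """Write an events table as FCS 3.1 (float32, little-endian)."""
    cols = list(table.columns)
    arr = table.to_numpy(dtype="<f4")
    n_events, n_par = arr.shape

    pairs = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, c in enumerate(cols):
        pairs[f"$P{i + 1}N"] = str(c)
        pairs[f"$P{i + 1}B"] = "32"
        pairs[f"$P{i + 1}E"] = "0,0"
        pairs[f"$P{i + 1}R"] = str(int(np.ceil(max(float(np.nanmax(arr[:, i])), 1.0))) + 1)

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
    text_bytes = text.encode("ascii")
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + arr.nbytes - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(arr.tobytes())
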