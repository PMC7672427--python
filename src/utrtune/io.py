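"""File I/O for event tables and assay CSVs.

Event tables are read from CSV (columns ``fsc_a,ssc_a,ssc_h,bfp,rfp``)
or from FCS 3.0/3.1 list-mode files via a small built-in reader (only
the TEXT segment and uncompressed float/integer DATA are supported,
which covers ordinary cytometer exports).  Channel names are mapped to
roles through a configurable ``channel_map``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_events", "read_fcs", "write_fcs", "DEFAULT_CHANNEL_MAP"]

#: $PnN channel name -> analysis role.
DEFAULT_CHANNEL_MAP = {
    "FSC-A": "fsc_a",
    "SSC-A": "ssc_a",
    "SSC-H": "ssc_h",
    "BFP-A": "bfp",
    "RFP-A": "rfp",
}


def read_events(path, channel_map: dict = None) -> pd.DataFrame:
    """Read a cell-event table from CSV or FCS, mapping channels to roles."""
    path = str(path)
    if path.lower().endswith(".fcs"):
        return read_fcs(path, channel_map)
    df = pd.read_csv(path)
    if channel_map:
        df = df.rename(columns=channel_map)
    return df


def _parse_text_segment(raw: bytes) -> dict:
    delim = raw[:1].decode("latin-1")
    fields = raw.decode("latin-1").strip(delim).split(delim)
    return {fields[i]: fields[i + 1] for i in range(0, len(fields) - 1, 2)}


def read_fcs(path, channel_map: dict = None) -> pd.DataFrame:
    """Minimal FCS 3.0/3.1 list-mode reader."""
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    with open(path, "rb") as fh:
        header = fh.read(58)
        version = header[:6].decode("latin-1")
        if not version.startswith("FCS3"):
            raise ValueError(f"unsupported FCS version {version!r}")
        text_start, text_end = int(header[10:18]), int(header[18:26])
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))
        data_start = int(text.get("$BEGINDATA", header[26:34] or 0))
        data_end = int(text.get("$ENDDATA", header[34:42] or 0))
        n_par = int(text["$PAR"])
        n_events = int(text["$TOT"])
        dtype_code = text["$DATATYPE"].upper()
        byteorder = text.get("$BYTEORD", "1,2,3,4")
        little = byteorder.startswith("1")
        if text.get("$MODE", "L").upper() != "L":
            raise ValueError("only list-mode FCS data is supported")
        fh.seek(data_start)
        raw = fh.read(data_end - data_start + 1)
    if dtype_code == "F":
        fmt = ("<" if little else ">") + "f"
        arr = np.frombuffer(raw[:n_events * n_par * 4], dtype=fmt).astype(float)
    elif dtype_code == "D":
        fmt = ("<" if little else ">") + "d"
        arr = np.frombuffer(raw[:n_events * n_par * 8], dtype=fmt).astype(float)
    elif dtype_code == "I":
        bits = {int(text[f"$P{i+1}B"]) for i in range(n_par)}
        if bits != {32}:
            raise ValueError("only 32-bit integer FCS data is supported")
        fmt = ("<" if little else ">") + "u4"
        arr = np.frombuffer(raw[:n_events * n_par * 4], dtype=fmt).astype(float)
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    arr = arr.reshape(n_events, n_par)
    names = [text.get(f"$P{i+1}N", f"P{i+1}") for i in range(n_par)]
    df = pd.DataFrame(arr, columns=names)
    return df.rename(columns=channel_map)


def write_fcs(df: pd.DataFrame, path, channel_names: list = None) -> None:
    """Write a float32 FCS 3.1 file (used for round-trip testing)."""
    channels = channel_names or list(df.columns)
    data = df[channels].to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    kv = {"$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
          "$PAR": str(n_par), "$TOT": str(n_events), "$NEXTDATA": "0"}
    for i, name in enumerate(channels, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(np.max(data[:, i - 1]), 1)) + 1)
    # two-pass sizing: BEGINDATA/ENDDATA appear inside TEXT
    for _ in range(3):
        text = "|" + "|".join(f"{k}|{v}" for k, v in kv.items()) + "|"
        text_start = 58
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + data.nbytes - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
    header = (f"FCS3.1    {text_start:8d}{text_end:8d}"
              f"{data_start:8d}{data_end:8d}{0:8d}{0:8d}")
    with open(path, "wb") as fh:
        fh.write(header.encode("latin-1"))
        fh.write(text.encode("latin-1"))
        fh.write(data.tobytes())
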