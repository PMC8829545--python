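"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Covers the subset of the standard that list-mode cytometry event data
actually use: a fixed 58-byte header with segment offsets, a
delimiter-separated TEXT segment of keyword/value pairs, and a DATA
segment in list mode (``$MODE L``) holding float32/float64 (``$DATATYPE
F``/``D``) values. No compensation is applied and the ANALYSIS segment
is ignored. Written files are FCS 3.1, little-endian float32.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"  # TEXT keyword delimiter used when writing


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # First character is the delimiter; a trailing delimiter is required.
    parts = body.split(delim)
    # parts[0] is empty (leading delim); drop trailing empty from final delim
    fields = parts[1:]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2 == 1:
        raise ValueError("malformed TEXT segment: odd number of fields")
    return {
        fields[i].strip().upper(): fields[i + 1]
        for i in range(0, len(fields), 2)
    }


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS 3.0/3.1 file.

    Returns ``(data, channel_names, keywords)`` where ``data`` is an
    (events x parameters) float array and ``channel_names`` are the
    ``$PnN`` short names in file order.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise OSError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("latin-1")
    if not version.startswith("FCS3"):
        raise OSError(f"{path}: unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text_segment(raw[text_start : text_end + 1])

    data_start = int(text.get("$BEGINDATA") or raw[26:34])
    data_end = int(text.get("$ENDDATA") or raw[34:42])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text["$DATATYPE"].strip().upper()
    if dtype_code not in ("F", "D"):
        raise OSError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    if text.get("$MODE", "L").strip().upper() != "L":
        raise OSError(f"{path}: only list mode ($MODE L) is supported")
    byteord = text["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    np_dtype = np.dtype(f"{endian}f4" if dtype_code == "F" else f"{endian}f8")

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}").strip())

    buf = raw[data_start : data_end + 1]
    expected = n_tot * n_par * np_dtype.itemsize
    if len(buf) < expected:
        raise OSError(f"{path}: DATA segment truncated")
    data = np.frombuffer(buf[:expected], dtype=np_dtype).reshape(n_tot, n_par)
    return data.astype(float), names, text


def write_fcs(path: str | Path, data: np.ndarray, channel_names: list[str],
              extra_keywords: dict[str, str] | None = None) -> None:
    """Write events as FCS 3.1 (list mode, little-endian float32)."""
    data = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    n_tot, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length does not match data columns")

    payload = data.tobytes()
    keywords: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        if _DELIM in name:
            raise ValueError(f"channel name {name!r} contains the TEXT delimiter")
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "262144"
    if extra_keywords:
        keywords.update(extra_keywords)

    def render_text(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        kw["$BEGINANALYSIS"] = "0"
        kw["$ENDANALYSIS"] = "0"
        kw["$BEGINSTEXT"] = "0"
        kw["$ENDSTEXT"] = "0"
        out = io.StringIO()
        out.write(_DELIM)
        for k, v in kw.items():
            out.write(f"{k}{_DELIM}{v}{_DELIM}")
        return out.getvalue().encode("latin-1")

    # Offsets depend on TEXT length, which depends on the offsets; the
    # digit count stabilizes after a couple of passes.
    text_start = 58
    begin_data, end_data = 0, 0
    for _ in range(8):
        text = render_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + len(payload) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    header = (
        f"FCS3.1    "
        f"{text_start:>8d}{text_end:>8d}"
        f"{begin_data:>8d}{end_data:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("latin-1")
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
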