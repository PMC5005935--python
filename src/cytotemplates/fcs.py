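"""Minimal reader for FCS 3.0 / 3.1 list-mode files.

Supports the common case emitted by modern instruments: a single dataset,
``$MODE L`` (list mode), ``$DATATYPE`` F (float32), D (float64) or I
(unsigned integer with uniform ``$PnB``), either byte order. Anything else
is rejected with an explicit message rather than guessed at.
"""

from __future__ import annotations

import numpy as np

from .model import EventMatrix

__all__ = ["read_fcs"]

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")


class FCSFormatError(ValueError):
    pass


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FCSFormatError("TEXT segment too short")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Delimiter escaping (doubled delimiters) is rare; split-and-rejoin
    # handles the plain case, which is all we accept.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of delimited fields")
    out: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        out[key.decode("ascii", "replace").strip().upper()] = value.decode(
            "ascii", "replace"
        ).strip()
    return out


def read_fcs(path: str) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventMatrix`.

    Channels are returned in file order, named by ``$PnN`` (falling back to
    ``$PnS``, then ``Pn``); values are the stored raw values, untransformed.
    """
    with open(path, "rb") as fh:
        raw = fh.read()

    if len(raw) < 58:
        raise FCSFormatError(f"{path}: file too short to hold an FCS header")
    version = raw[0:6]
    if version not in _SUPPORTED_VERSIONS:
        raise FCSFormatError(
            f"{path}: unsupported FCS version {version!r}; only FCS 3.0/3.1 "
            "list-mode files are readable"
        )

    def _offset(a: int, b: int, what: str) -> int:
        field = raw[a:b].decode("ascii", "replace").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FCSFormatError(
                f"{path}: bad {what} offset at bytes {a}-{b}: {field!r}"
            ) from None

    text_start = _offset(10, 18, "TEXT start")
    text_end = _offset(18, 26, "TEXT end")
    data_start = _offset(26, 34, "DATA start")
    data_end = _offset(34, 42, "DATA end")

    text = _parse_text_segment(raw[text_start : text_end + 1])

    if text.get("$MODE", "L").upper() != "L":
        raise FCSFormatError(f"{path}: only list-mode ($MODE L) data is supported")
    datatype = text.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D", "I"):
        raise FCSFormatError(
            f"{path}: $DATATYPE {datatype!r} unsupported (need F, D or I)"
        )

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FCSFormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FCSFormatError(f"{path}: $DATATYPE D requires 64-bit parameters")
        dtype = np.dtype(f"{order}f8")
    else:
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FCSFormatError(
                f"{path}: integer data needs uniform $PnB of 8/16/32 (got {bits})"
            )
        dtype = np.dtype(f"{order}u{bits[0] // 8}")

    n_values = n_par * n_tot
    buf = raw[data_start : data_start + n_values * dtype.itemsize]
    if len(buf) < n_values * dtype.itemsize:
        raise FCSFormatError(
            f"{path}: DATA segment truncated at byte {data_start + len(buf)}"
        )
    values = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
        names.append(name)
    # De-duplicate (some instruments reuse $PnN for scatter channels)
    seen: dict[str, int] = {}
    unique_names = []
    for name in names:
        if name in seen:
            seen[name] += 1
            unique_names.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            unique_names.append(name)

    import os

    sample_id = os.path.splitext(os.path.basename(path))[0]
    return EventMatrix(values=values, channel_names=unique_names, sample_id=sample_id)
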