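"""Minimal FCS 3.0 list-mode file writer/reader.

Stores events as little-endian float32 ($DATATYPE F, $MODE L), with
detector ids in $PnN and marker names in $PnS. Ground-truth population
labels of synthetic samples are carried as an extra integer-coded
parameter (``TRUTH-IDX``) plus a custom keyword holding the label
dictionary, so that write -> read round-trips preserve them. Sample
metadata travels in a custom JSON keyword (``DCFMETA``).
"""

from __future__ import annotations

import json
import struct

import numpy as np

from .events import EventMatrix

_DELIM = "\x0c"           # TEXT-segment delimiter
_TEXT_START = 256         # TEXT offset leaves room for the 58-byte header
_TRUTH_PARAM = "TRUTH-IDX"


def _build_text(keywords: dict) -> bytes:
    parts = [_DELIM]
    for key, val in keywords.items():
        sval = str(val)
        if _DELIM in key or _DELIM in sval:
            raise ValueError("keyword content may not contain the delimiter")
        parts.append(f"{key}{_DELIM}{sval}{_DELIM}")
    return "".join(parts).encode("latin-1")


def write_fcs(events: EventMatrix, path) -> None:
    """Write an :class:`EventMatrix` as an FCS 3.0 file."""
    values = np.asarray(events.values, dtype="<f4")
    channels = list(events.channels)
    markers = list(events.markers)

    if events.truth_labels is not None:
        names = sorted(set(map(str, events.truth_labels)))
        code = {n: i for i, n in enumerate(names)}
        idx = np.array([code[str(x)] for x in events.truth_labels],
                       dtype="<f4")
        values = np.column_stack([values, idx]).astype("<f4")
        channels.append(_TRUTH_PARAM)
        markers.append(_TRUTH_PARAM)
        truth_names = ",".join(names)
    else:
        truth_names = None

    n_events, n_par = values.shape
    keywords = {
        "$BEGINANALYSIS": 0, "$ENDANALYSIS": 0,
        "$BEGINSTEXT": 0, "$ENDSTEXT": 0,
        # placeholders; fixed width keeps the TEXT length stable when filled
        "$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12,
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": 0, "$PAR": n_par, "$TOT": n_events,
    }
    for i, (det, mark) in enumerate(zip(channels, markers), start=1):
        keywords[f"$P{i}B"] = 32
        keywords[f"$P{i}E"] = "0,0"
        rng = float(values[:, i - 1].max()) if n_events else 262144
        keywords[f"$P{i}R"] = int(max(rng, 1)) + 1
        keywords[f"$P{i}N"] = det
        keywords[f"$P{i}S"] = mark
    if truth_names is not None:
        keywords["DCFTRUTH"] = truth_names
    keywords["DCFMETA"] = json.dumps(events.metadata, sort_keys=True)

    text = _build_text(keywords)
    data_begin = _TEXT_START + len(text)
    data_end = data_begin + values.nbytes - 1
    keywords["$BEGINDATA"] = f"{data_begin:012d}"
    keywords["$ENDDATA"] = f"{data_end:012d}"
    text = _build_text(keywords)

    def _off(x):  # header offsets must fit 8 chars, else 0 per FCS 3.0
        return f"{x:8d}" if x <= 99_999_999 else f"{0:8d}"

    header = (b"FCS3.0    "
              + _off(_TEXT_START).encode()
              + _off(_TEXT_START + len(text) - 1).encode()
              + _off(data_begin if data_end <= 99_999_999 else 0).encode()
              + _off(data_end if data_end <= 99_999_999 else 0).encode()
              + _off(0).encode() + _off(0).encode())

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (_TEXT_START - len(header)))
        fh.write(text)
        fh.write(values.tobytes())


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0 file written by :func:`write_fcs` (or any
    single-dataset float32 list-mode FCS 3.0 file with $PnN keywords)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:6] == b"FCS3.0":
        raise ValueError("not an FCS 3.0 file")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError("malformed FCS header offsets") from exc

    text = raw[text_begin:text_end + 1].decode("latin-1")
    delim, body = text[0], text[1:]
    fields = body.split(delim)
    if len(fields) < 2:
        raise ValueError("empty TEXT segment")
    kw = {fields[i]: fields[i + 1]
          for i in range(0, len(fields) - 1, 2) if fields[i]}

    for required in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD"):
        if required not in kw:
            raise ValueError(f"missing required keyword {required}")
    if kw["$DATATYPE"] != "F":
        raise ValueError("only $DATATYPE F (float32) is supported")
    endian = "<" if kw["$BYTEORD"].startswith("1") else ">"

    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    channels, markers = [], []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N")
        if name is None:
            raise ValueError(f"file lacking $P{i}N keyword")
        channels.append(name)
        markers.append(kw.get(f"$P{i}S", name))

    data_begin = int(kw.get("$BEGINDATA", 0)) or int(raw[26:34])
    data_end = int(kw.get("$ENDDATA", 0)) or int(raw[34:42])
    nbytes = n_par * n_tot * 4
    if data_end - data_begin + 1 < nbytes:
        raise ValueError("DATA segment shorter than $PAR x $TOT events")
    values = np.frombuffer(raw[data_begin:data_begin + nbytes],
                           dtype=f"{endian}f4").reshape(n_tot, n_par)
    values = values.astype(np.float64)

    metadata = json.loads(kw["DCFMETA"]) if "DCFMETA" in kw else {}
    truth = None
    if _TRUTH_PARAM in channels:
        col = channels.index(_TRUTH_PARAM)
        names = kw.get("DCFTRUTH", "").split(",")
        idx = values[:, col].astype(int)
        truth = np.array([names[i] for i in idx])
        keep = [i for i in range(n_par) if i != col]
        values = values[:, keep]
        channels = [channels[i] for i in keep]
        markers = [markers[i] for i in keep]

    return EventMatrix(values=values, channels=channels, markers=markers,
                       truth_labels=truth, metadata=metadata)
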