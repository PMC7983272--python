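"""FCS reading/writing and event-matrix preprocessing.

Supports single-dataset FCS 3.0 / 3.1 files in list mode with float
(DATATYPE F/D) or integer (DATATYPE I) storage; log-stored integer
parameters are linearized on read via $PnE.  The spillover matrix is
taken from $SPILLOVER (FCS 3.1) or the older SPILL / $SPILL keywords,
with rows = detector channels and columns = fluorochromes.

Preprocessing follows the usual cytometry order: compensation (solve
X' . S = X for the spilled channels), axis-aligned interval gating,
an intensity transform (arcsinh with a cofactor by default), and
merging of per-sample matrices with fixed-size uniform downsampling
so that every time point contributes equally.
"""

from __future__ import annotations

import math
import os
import struct
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from cytotrail.model import EventMatrix


class FCSParseError(ValueError):
    """Raised for malformed or truncated FCS files."""


class UnsupportedFCSVersionError(FCSParseError):
    """Raised for FCS versions other than 3.0 / 3.1."""


@dataclass
class RawSample:
    """Events and metadata from one FCS file (pre-compensation)."""

    events: np.ndarray                    # events x channels, linearized
    channel_names: list[str]              # $PnN
    marker_names: list[str]               # $PnS, '' where absent
    spillover: Optional[pd.DataFrame]     # square, labelled by channel
    source_id: str

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2 or self.events.shape[0] < 1 or self.events.shape[1] < 1:
            raise ValueError("events must be a non-empty 2-D matrix")
        if len(self.channel_names) != self.events.shape[1]:
            raise ValueError("channel_names length must equal the column count")
        if self.spillover is not None:
            s = self.spillover
            if s.shape[0] != s.shape[1]:
                raise ValueError("spillover must be square")
            if not np.allclose(np.diag(s.to_numpy()), 1.0):
                raise ValueError("spillover diagonal must be 1")
            unknown = [c for c in s.columns if c not in self.channel_names]
            if unknown:
                raise ValueError(f"spillover names not among channels: {unknown}")


# -- FCS parsing -----------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Parse a TEXT segment; doubled delimiters escape a literal delimiter."""
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Split on the delimiter; an empty token means a doubled (escaped)
    # delimiter, whose two neighbours belong to the same field.
    parts = [p.decode("utf-8", errors="replace") for p in body.split(delim)]
    d = delim.decode("utf-8", errors="replace")
    repaired: list[str] = []
    pending_join = False
    for tok in parts:
        if tok == "":
            if repaired:
                repaired[-1] += d
                pending_join = True
            continue
        if pending_join:
            repaired[-1] += tok
            pending_join = False
        else:
            repaired.append(tok)
    if len(repaired) % 2 == 1:
        repaired.append("")
    return {repaired[i].strip().upper(): repaired[i + 1] for i in range(0, len(repaired), 2)}


def _parse_spillover(value: str) -> pd.DataFrame:
    fields = [f.strip() for f in value.split(",")]
    try:
        n = int(fields[0])
    except ValueError as exc:
        raise FCSParseError(f"bad spillover keyword: {value[:40]!r}") from exc
    names = fields[1 : 1 + n]
    numbers = [float(x) for x in fields[1 + n :]]
    if len(numbers) != n * n:
        raise FCSParseError(f"spillover expects {n * n} values, got {len(numbers)}")
    mat = np.array(numbers).reshape(n, n)
    return pd.DataFrame(mat, index=names, columns=names)


def read_fcs(path: Union[str, os.PathLike]) -> RawSample:
    """Read a single-dataset FCS 3.0/3.1 file into a :class:`RawSample`.

    Integer parameters stored on a log scale ($PnE = "f1,f2" with f1 > 0)
    are linearized to ``f2 * 10**(f1 * x / $PnR)``.

    Raises
    ------
    UnsupportedFCSVersionError
        For any version other than FCS 3.0 / 3.1.
    FCSParseError
        For truncated or malformed files, naming the failing byte offset.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 58:
        raise FCSParseError(f"file truncated at offset {len(data)}: no FCS header")
    version = data[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FCSParseError("not an FCS file: missing 'FCS' magic at offset 0")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFCSVersionError(f"unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(data[lo:hi].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise FCSParseError(f"bad header offset field at bytes {lo}-{hi}") from exc

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(data):
        raise FCSParseError(f"file truncated at offset {len(data)}: TEXT ends at {text_end}")
    keywords = _parse_text_segment(data[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(keywords.get("$BEGINDATA", "0"))
        data_end = int(keywords.get("$ENDDATA", "0"))
    if int(keywords.get("$NEXTDATA", "0")) != 0:
        raise FCSParseError("multi-dataset FCS files are not supported")
    mode = keywords.get("$MODE", "L")
    if mode != "L":
        raise FCSParseError(f"only list mode ($MODE=L) is supported, got {mode!r}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"

    if data_end < data_begin or data_end >= len(data):
        raise FCSParseError(
            f"file truncated at offset {len(data)}: DATA segment claims {data_begin}-{data_end}"
        )
    payload = data[data_begin : data_end + 1]

    if datatype == "F":
        arr = np.frombuffer(payload[: 4 * n_par * n_tot], dtype=f"{endian}f4")
    elif datatype == "D":
        arr = np.frombuffer(payload[: 8 * n_par * n_tot], dtype=f"{endian}f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FCSParseError("integer data requires a uniform $PnB of 16 or 32")
        width = int(keywords["$P1B"]) // 8
        arr = np.frombuffer(payload[: width * n_par * n_tot], dtype=f"{endian}u{width}")
    else:
        raise FCSParseError(f"unsupported $DATATYPE {datatype!r}")
    if arr.size < n_par * n_tot:
        raise FCSParseError(
            f"file truncated at offset {data_begin + arr.nbytes}: "
            f"expected {n_par * n_tot} values, got {arr.size}"
        )
    events = arr.reshape(n_tot, n_par).astype(float)

    channel_names, marker_names = [], []
    for i in range(1, n_par + 1):
        channel_names.append(keywords.get(f"$P{i}N", f"P{i}"))
        marker_names.append(keywords.get(f"$P{i}S", ""))
        pne = keywords.get(f"$P{i}E", "0,0")
        try:
            f1, f2 = (float(x) for x in pne.split(","))
        except ValueError as exc:
            raise FCSParseError(f"bad $P{i}E value {pne!r}") from exc
        if f1 > 0 and datatype == "I":
            # log-amplified storage; f2 == 0 is a common writer bug meaning 1
            f2 = f2 if f2 > 0 else 1.0
            pnr = float(keywords.get(f"$P{i}R", "1024"))
            events[:, i - 1] = f2 * 10.0 ** (f1 * events[:, i - 1] / pnr)

    spill_value = None
    for key in ("$SPILLOVER", "SPILL", "$SPILL"):
        if key in keywords:
            spill_value = keywords[key]
            break
    spillover = _parse_spillover(spill_value) if spill_value else None

    return RawSample(
        events=events,
        channel_names=channel_names,
        marker_names=marker_names,
        spillover=spillover,
        source_id=os.path.splitext(os.path.basename(str(path)))[0],
    )


def write_fcs(
    path: Union[str, os.PathLike],
    events: np.ndarray,
    channel_names: Sequence[str],
    marker_names: Optional[Sequence[str]] = None,
    spillover: Optional[pd.DataFrame] = None,
) -> None:
    """Write a minimal FCS 3.1 file (list mode, float32, little-endian)."""
    events = np.asarray(events, dtype=np.float32)
    n_tot, n_par = events.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match the column count")
    marker_names = list(marker_names) if marker_names is not None else [""] * n_par

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i in range(n_par):
        kw[f"$P{i + 1}N"] = str(channel_names[i])
        if marker_names[i]:
            kw[f"$P{i + 1}S"] = str(marker_names[i])
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        rng = float(np.max(np.abs(events[:, i]))) if n_tot else 1.0
        kw[f"$P{i + 1}R"] = str(int(max(1, math.ceil(rng + 1))))
    if spillover is not None:
        names = list(spillover.columns)
        flat = ",".join(repr(float(v)) for v in spillover.to_numpy().ravel())
        kw["$SPILLOVER"] = f"{len(names)}," + ",".join(names) + "," + flat

    payload = events.astype("<f4").tobytes()
    delim = "/"
    # Data offsets appear inside TEXT, so the layout is solved iteratively.
    data_begin = 256
    for _ in range(8):
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_begin + len(payload) - 1)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
        text_begin = 58
        text_end = text_begin + len(text) - 1
        if text_end + 1 == data_begin:
            break
        data_begin = text_end + 1
    header = (
        b"FCS3.1    "
        + f"{text_begin:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_begin + len(payload) - 1:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(payload)


def read_matrix(
    path: Union[str, os.PathLike],
    sep: Optional[str] = None,
    id_column: Optional[str] = None,
    sample_label: Optional[str] = None,
) -> EventMatrix:
    """Read a delimited cells x markers matrix (header row = marker names)."""
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if id_column is not None:
        df = df.set_index(id_column)
        ids = [str(i) for i in df.index]
    else:
        ids = [f"cell_{i}" for i in range(len(df))]
    label = sample_label or os.path.splitext(os.path.basename(path))[0]
    return EventMatrix(df.to_numpy(float), list(df.columns), ids, [label] * len(df))


# -- compensation / transform / gating ------------------------------------


def compensate(
    events: np.ndarray,
    spillover: Union[np.ndarray, pd.DataFrame],
    channel_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Remove fluorescence spillover: solve ``X' . S = X`` (``X' = X S^-1``).

    With a labelled spillover (DataFrame) and ``channel_names``, only the
    named channels are compensated; the rest pass through unchanged.
    """
    events = np.asarray(events, dtype=float)
    if isinstance(spillover, pd.DataFrame):
        s_names = list(spillover.columns)
        s = spillover.to_numpy(float)
        if channel_names is None:
            if events.shape[1] != s.shape[0]:
                raise ValueError("event columns do not match spillover size; pass channel_names")
            cols = np.arange(events.shape[1])
        else:
            missing = [c for c in s_names if c not in channel_names]
            if missing:
                raise KeyError(f"spillover channels missing from events: {missing}")
            cols = np.array([list(channel_names).index(c) for c in s_names])
    else:
        s = np.asarray(spillover, dtype=float)
        if events.shape[1] != s.shape[0]:
            raise ValueError(
                f"spillover is {s.shape[0]}x{s.shape[1]} but events have "
                f"{events.shape[1]} channels"
            )
        cols = np.arange(events.shape[1])
    if s.shape[0] != s.shape[1]:
        raise ValueError("spillover must be square")
    if np.linalg.matrix_rank(s) < s.shape[0]:
        raise np.linalg.LinAlgError("spillover matrix is singular")
    out = events.copy()
    # X' = X S^-1  <=>  S^T X'^T = X^T
    out[:, cols] = np.linalg.solve(s.T, events[:, cols].T).T
    return out


def transform(events: np.ndarray, method: str = "arcsinh", cofactor: float = 5.0) -> np.ndarray:
    """Intensity transform: ``arcsinh(x / cofactor)``, ``log10(x + 1)`` or none.

    arcsinh with cofactor 5 is the mass-cytometry convention (150-ish for
    conventional flow); log10 clips at zero so negative compensated values
    do not produce NaN.
    """
    events = np.asarray(events, dtype=float)
    if method == "arcsinh":
        if cofactor <= 0:
            raise ValueError("cofactor must be positive")
        return np.arcsinh(events / cofactor)
    if method == "log10":
        return np.log10(np.maximum(events + 1.0, 1.0))
    if method == "none":
        return events
    raise ValueError(f"unknown transform {method!r}; use arcsinh, log10 or none")


@dataclass(frozen=True)
class GateSpec:
    """Closed-interval gate on one channel: keep ``lower <= x <= upper``."""

    channel: str
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"gate on {self.channel}: lower must be < upper")


def apply_gates(
    events: np.ndarray, channel_names: Sequence[str], gates: Sequence[GateSpec]
) -> np.ndarray:
    """Boolean mask of events inside ALL gates (intersection of intervals)."""
    events = np.asarray(events, dtype=float)
    mask = np.ones(events.shape[0], dtype=bool)
    names = list(channel_names)
    for gate in gates:
        if gate.channel not in names:
            raise KeyError(f"gate channel {gate.channel!r} not among {names}")
        col = events[:, names.index(gate.channel)]
        mask &= (col >= gate.lower) & (col <= gate.upper)
    return mask


# -- merging ---------------------------------------------------------------


def _sample_stream(seed: int, label: str) -> np.random.Generator:
    # substream keyed by the sample label so input order never changes draws
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def merge_samples(
    samples: Sequence[EventMatrix], n_per_sample: int, seed: int = 0
) -> EventMatrix:
    """Concatenate samples after drawing ``min(n_per_sample, n_i)`` cells each.

    Cells are drawn uniformly without replacement; the per-sample random
    substream is derived from ``seed`` and the sample's label, so reordering
    the input list does not change which cells are selected.  Only markers
    shared by every sample are retained, in the order of the first sample.
    """
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be positive")
    if not samples:
        raise ValueError("no samples to merge")
    shared = [m for m in samples[0].markers if all(m in s.markers for s in samples[1:])]
    if not shared:
        raise ValueError("samples share no markers")
    pieces = []
    for k, sample in enumerate(samples):
        label = sample.sample_labels[0] if sample.sample_labels else str(k)
        rng = _sample_stream(seed, label)
        n_take = min(n_per_sample, sample.n_cells)
        rows = np.sort(rng.choice(sample.n_cells, size=n_take, replace=False))
        pieces.append(sample.select_markers(shared).subset_cells(rows))
    values = np.vstack([p.values for p in pieces])
    ids: list[str] = []
    labels: list[str] = []
    for k, p in enumerate(pieces):
        for cid in p.cell_ids:
            ids.append(f"s{k}_{cid}")
        labels.extend(p.sample_labels)
    return EventMatrix(values, shared, ids, labels)


def preprocess_fcs(
    paths: Sequence[Union[str, os.PathLike]],
    compensate_mode: str = "auto",
    gates: Sequence[GateSpec] = (),
    method: str = "arcsinh",
    cofactor: float = 5.0,
    n_per_sample: int = 2000,
    seed: int = 0,
) -> EventMatrix:
    """Full preprocessing: read, compensate, gate, transform, merge.

    Order is compensate -> gate -> transform, the common manual-analysis
    convention (gates are specified on compensated linear intensities).
    ``compensate_mode`` is ``auto`` (use each file's stored spillover when
    present), ``none``, or a path to a CSV spillover matrix applied to all.
    """
    samples = []
    external = None
    if compensate_mode not in ("auto", "none"):
        external = pd.read_csv(compensate_mode, index_col=0)
    for path in paths:
        raw = read_fcs(path)
        events = raw.events
        if compensate_mode == "auto" and raw.spillover is not None:
            events = compensate(events, raw.spillover, raw.channel_names)
        elif external is not None:
            events = compensate(events, external, raw.channel_names)
        if gates:
            events = events[apply_gates(events, raw.channel_names, gates)]
        events = transform(events, method=method, cofactor=cofactor)
        names = [m or c for c, m in zip(raw.channel_names, raw.marker_names)]
        samples.append(
            EventMatrix(
                events,
                names,
                [f"{raw.source_id}_{i}" for i in range(events.shape[0])],
                [raw.source_id] * events.shape[0],
            )
        )
    return merge_samples(samples, n_per_sample=n_per_sample, seed=seed)
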