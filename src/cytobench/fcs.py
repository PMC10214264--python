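"""FCS file I/O, sample metadata, merging, downsampling and marker selection.

Cytometry acquisitions are deposited as FCS files: a text segment of
keyword/value pairs describing the panel plus a list-mode data segment
holding the events x channels intensity matrix.  This module reads FCS
2.0/3.0/3.1 (integer and float list mode), writes FCS 3.1 (float32), and
implements the front half of the evaluation pipeline: metadata validation,
per-file downsampling, merging across samples with imbalance correction,
and marker selection.

The analysis-facing container is :class:`MergedData`: a single events x
channels matrix with a per-event sample index (``origin``), the acquisition
Time values kept aside for signal cleaning, and the sample annotation.
"""

from __future__ import annotations

import enum
import math
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ArgumentError,
    EmptyDataError,
    FCSParseError,
    MetadataError,
    TechniqueMismatchError,
)

__all__ = [
    "Technique",
    "StudyKind",
    "ExpressionFrame",
    "SampleAnnotation",
    "MergedData",
    "read_fcs",
    "write_fcs",
    "read_metadata",
    "downsample",
    "merge_samples",
    "select_markers",
]


class Technique(str, enum.Enum):
    """Acquisition technique: conventional flow (FC) or mass cytometry (MC)."""

    FC = "FC"
    MC = "MC"


class StudyKind(str, enum.Enum):
    """Downstream study the data supports: subpopulation identification or
    pseudotime trajectory inference."""

    CSI = "CSI"
    PTI = "PTI"


def _is_time_channel(name: str) -> bool:
    return name.strip().lower() == "time"


@dataclass
class ExpressionFrame:
    """One sample: an events x channels matrix with channel/marker names.

    ``markers`` holds the stain names ($PnS, falling back to $PnN) and is
    always the same length as ``channels``.  ``time_channel`` names the
    acquisition-time column when one exists.
    """

    sample_id: str
    technique: Technique
    channels: list[str]
    markers: list[str]
    values: np.ndarray
    time_channel: str | None = None
    keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ArgumentError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.channels):
            raise ArgumentError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.channels)} channels are named"
            )
        if len(self.markers) != len(self.channels):
            raise ArgumentError("one marker name is required per channel")
        if self.time_channel is None:
            for name in self.channels:
                if _is_time_channel(name):
                    self.time_channel = name
                    break

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_index(self, channel: str) -> int:
        return self.channels.index(channel)

    def time_values(self) -> np.ndarray | None:
        if self.time_channel is None:
            return None
        return self.values[:, self.channel_index(self.time_channel)]

    def take(self, idx: np.ndarray) -> "ExpressionFrame":
        """Row subset (pure: event values are untouched)."""
        return replace(self, values=self.values[idx])


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty text segment")
    delim = raw[0:1]
    body = raw[1:]
    # trailing delimiter is required but be lenient
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiters escape a literal delimiter inside a value
    parts = body.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        # empty part means two delimiters in a row -> escaped delimiter
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            tok = tok + delim.decode("latin-1") + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2 == 1:
        tokens = tokens[:-1]
    out: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        out[k.decode("latin-1").strip().upper() if isinstance(k, bytes) else k] = v
    return out


def _decode(b):
    if isinstance(b, str):
        return b
    try:
        return b.decode("utf-8")
    except UnicodeDecodeError:
        return b.decode("latin-1")


def _decode_tokens(raw: bytes) -> dict[str, str]:
    text = _parse_text_segment(raw)
    return {_decode(k).strip().upper(): _decode(v) for k, v in text.items()}


def infer_technique(keywords: dict[str, str]) -> Technique | None:
    """Guess FC vs MC from the $CYT instrument keyword, if present."""
    cyt = keywords.get("$CYT", "")
    if not cyt:
        return None
    if re.search(r"tof|cytof|helios|hyperion|mass", cyt, re.IGNORECASE):
        return Technique.MC
    return Technique.FC


def read_fcs(path: str | os.PathLike, technique: Technique | None = None) -> ExpressionFrame:
    """Read an FCS 2.0/3.0/3.1 list-mode file into an :class:`ExpressionFrame`.

    Markers come from $PnS with $PnN as the fallback; the technique is
    inferred from $CYT when possible, otherwise ``technique`` must be given.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER_LEN:
        raise FCSParseError(f"{path}: file shorter than an FCS header")
    version = blob[0:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"{path}: not an FCS file (version field {version!r})")

    def _offset(a: int, b: int, name: str) -> int:
        fieldtxt = blob[a:b].decode("latin-1").strip()
        if fieldtxt == "":
            return 0
        try:
            return int(fieldtxt)
        except ValueError as exc:
            raise FCSParseError(f"{path}: bad header offset for {name}: {fieldtxt!r}") from exc

    text_begin = _offset(10, 18, "text begin")
    text_end = _offset(18, 26, "text end")
    data_begin = _offset(26, 34, "data begin")
    data_end = _offset(34, 42, "data end")
    if text_begin <= 0 or text_end <= text_begin or text_end >= len(blob):
        raise FCSParseError(f"{path}: invalid text segment offsets {text_begin}..{text_end}")
    kw = _decode_tokens(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FCSParseError(f"{path}: invalid data segment offsets ($BEGINDATA/$ENDDATA)")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except KeyError as exc:
        raise FCSParseError(f"{path}: missing required keyword {exc.args[0]}") from exc
    if n_tot == 0:
        raise EmptyDataError(f"{path}: $TOT is 0 (no events)")
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSParseError(f"{path}: only list mode is supported ($MODE={mode})")

    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"
    dtype_code = kw.get("$DATATYPE", "F").upper()

    if dtype_code == "F":
        dtype = np.dtype(endian + "f4")
        counts = [32] * n_par
    elif dtype_code == "D":
        dtype = np.dtype(endian + "f8")
        counts = [64] * n_par
    elif dtype_code == "I":
        counts = []
        for i in range(1, n_par + 1):
            bits = int(kw.get(f"$P{i}B", "32"))
            if bits not in (8, 16, 32, 64):
                raise FCSParseError(f"{path}: unsupported $P{i}B={bits}")
            counts.append(bits)
        dtype = None
    else:
        raise FCSParseError(f"{path}: unsupported $DATATYPE={dtype_code}")

    nbytes_expected = n_tot * sum(counts) // 8
    data = blob[data_begin : data_end + 1]
    if len(data) < nbytes_expected:
        raise FCSParseError(
            f"{path}: data segment truncated "
            f"({len(data)} bytes, expected {nbytes_expected})"
        )
    data = data[:nbytes_expected]

    if dtype is not None:
        values = np.frombuffer(data, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    elif len(set(counts)) == 1:
        idt = np.dtype(endian + f"u{counts[0] // 8}")
        values = np.frombuffer(data, dtype=idt).reshape(n_tot, n_par).astype(np.float64)
    else:  # mixed integer widths: build a structured dtype row-wise
        fields = [(f"c{i}", endian + f"u{b // 8}") for i, b in enumerate(counts)]
        rec = np.frombuffer(data, dtype=np.dtype(fields))
        values = np.column_stack([rec[f"c{i}"].astype(np.float64) for i in range(n_par)])

    channels, markers = [], []
    for i in range(1, n_par + 1):
        short = kw.get(f"$P{i}N", f"P{i}").strip()
        stain = kw.get(f"$P{i}S", "").strip()
        channels.append(short)
        markers.append(stain if stain else short)

    tech = infer_technique(kw) or technique
    if tech is None:
        raise ArgumentError(
            f"{path}: technique not inferable from $CYT; pass technique=FC or MC"
        )
    sample_id = os.path.splitext(os.path.basename(path))[0]
    return ExpressionFrame(
        sample_id=sample_id,
        technique=Technique(tech),
        channels=channels,
        markers=markers,
        values=values,
        keywords=kw,
    )


# ---------------------------------------------------------------------------
# FCS writing (3.1, float32)
# ---------------------------------------------------------------------------

def _escape(value: str, delim: str) -> str:
    return value.replace(delim, delim * 2) if value else " "


def write_fcs(frame: ExpressionFrame, path: str | os.PathLike) -> str:
    """Write ``frame`` as an FCS 3.1 float list-mode file; returns the path."""
    if frame.n_events == 0:
        raise EmptyDataError("refusing to write an FCS file with zero events")
    path = os.fspath(path)
    n_tot, n_par = frame.values.shape
    delim = "/"
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    cyt = frame.keywords.get("$CYT")
    if not cyt:
        cyt = "CyTOF" if frame.technique == Technique.MC else "FlowCytometer"
    kw["$CYT"] = cyt
    data = frame.values.astype("<f4")
    for i in range(n_par):
        kw[f"$P{i + 1}N"] = frame.channels[i]
        kw[f"$P{i + 1}S"] = frame.markers[i]
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        top = float(np.nanmax(data[:, i])) if n_tot else 1.0
        kw[f"$P{i + 1}R"] = str(int(max(1.0, math.ceil(abs(top)) + 1)))
    # carry through any user keywords that are not structural
    for k, v in frame.keywords.items():
        if k.startswith("$P") or k in kw or k in (
            "$BEGINDATA", "$ENDDATA", "$BEGINANALYSIS", "$ENDANALYSIS",
        ):
            continue
        kw[k] = v

    text_begin = 64
    data_begin = 0
    data_end = 0
    # text length depends on the printed data offsets: iterate to fixpoint
    for _ in range(8):
        pairs = dict(kw)
        pairs["$BEGINDATA"] = str(data_begin)
        pairs["$ENDDATA"] = str(data_end)
        body = delim + delim.join(
            _escape(str(k), delim) + delim + _escape(str(v), delim)
            for k, v in sorted(pairs.items())
        ) + delim
        text = body.encode("utf-8")
        new_begin = text_begin + len(text)
        new_end = new_begin + data.nbytes - 1
        if new_begin == data_begin and new_end == data_end:
            break
        data_begin, data_end = new_begin, new_end
    text_end = text_begin + len(text) - 1

    def _hdr(n: int) -> bytes:
        s = str(n)
        return (" " * (8 - len(s)) + s).encode("ascii") if len(s) <= 8 else b"       0"

    header = b"FCS3.1    " + _hdr(text_begin) + _hdr(text_end) + _hdr(data_begin) + _hdr(data_end) + _hdr(0) + _hdr(0)
    header = header + b" " * (text_begin - len(header))
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(text)
            fh.write(data.tobytes())
    except OSError as exc:
        raise OSError(f"cannot write FCS file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """Maps FCS base filenames to condition labels (CSI) or time points (PTI)."""

    study_kind: StudyKind
    entries: list[tuple[str, str]]
    label_order: dict[str, int] = field(default_factory=dict)

    @property
    def filenames(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.entries]

    def label_of(self, filename: str) -> str:
        for f, l in self.entries:
            if f == filename:
                return l
        raise MetadataError(f"filename {filename!r} not annotated")

    def ordinal_of(self, label: str) -> int:
        if not self.label_order:
            raise MetadataError("no time-point ordering (CSI annotation?)")
        return self.label_order[label]


def _expected_columns(study_kind: StudyKind) -> list[str]:
    return ["filename", "condition" if study_kind == StudyKind.CSI else "timepoint"]


def read_metadata(path: str | os.PathLike, study_kind: StudyKind | str) -> SampleAnnotation:
    """Read and validate the two-column annotation CSV.

    The header must be exactly ``filename,condition`` (CSI) or
    ``filename,timepoint`` (PTI).  CSI requires at least two samples per
    condition; PTI requires at least two distinct time points, ordered by
    numeric value when all labels parse as numbers, else by file order.
    """
    study_kind = StudyKind(study_kind)
    df = pd.read_csv(path, dtype=str).fillna("")
    expected = _expected_columns(study_kind)
    if list(df.columns) != expected:
        raise MetadataError(
            f"metadata columns must be exactly {expected!r}, got {list(df.columns)!r}"
        )
    entries = [(str(r[expected[0]]).strip(), str(r[expected[1]]).strip()) for _, r in df.iterrows()]
    names = [f for f, _ in entries]
    if len(set(names)) != len(names):
        raise MetadataError("duplicate filenames in metadata")
    labels = [l for _, l in entries]
    order: dict[str, int] = {}
    if study_kind == StudyKind.CSI:
        counts = pd.Series(labels).value_counts()
        bad = counts[counts < 2]
        if len(bad):
            raise MetadataError(
                "at least two samples are required for each condition; "
                f"single-sample condition(s): {sorted(bad.index)}"
            )
    else:
        uniq = list(dict.fromkeys(labels))
        if len(uniq) < 2:
            raise MetadataError("PTI metadata must contain at least two time points")
        try:
            uniq_sorted = sorted(uniq, key=lambda s: float(s))
        except ValueError:
            uniq_sorted = uniq  # labels are ordinals already, keep stated order
        order = {lab: i + 1 for i, lab in enumerate(uniq_sorted)}
    return SampleAnnotation(study_kind=study_kind, entries=entries, label_order=order)


# ---------------------------------------------------------------------------
# Downsampling / merging / marker selection
# ---------------------------------------------------------------------------

def downsample(
    frame: ExpressionFrame,
    n: int,
    strategy: str = "uniform_random",
    seed: int = 0,
) -> ExpressionFrame:
    """Sample ``min(n, available)`` events without replacement.

    ``uniform_random`` draws uniformly; ``density_preserving`` weights events
    by inverse local density (per-channel histogram estimate) so sparse
    regions survive; ``take_first`` keeps the earliest stored rows.  Event
    values are never modified; a fixed seed and strategy give an identical
    selection.
    """
    if n < 1:
        raise ArgumentError(f"downsample n must be >= 1, got {n}")
    m = frame.n_events
    if n >= m:
        return frame.take(np.arange(m))
    if strategy == "take_first":
        idx = np.arange(n)
    elif strategy == "uniform_random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(m, size=n, replace=False))
    elif strategy == "density_preserving":
        rng = np.random.default_rng(seed)
        logdens = np.zeros(m)
        for j in range(frame.n_channels):
            col = frame.values[:, j]
            if _is_time_channel(frame.channels[j]):
                continue
            hist, edges = np.histogram(col, bins=64)
            which = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, 63)
            logdens += np.log(hist[which] + 1.0)
        w = np.exp(-(logdens - logdens.max()) / max(1, frame.n_channels))
        w = w / w.sum()
        idx = np.sort(rng.choice(m, size=n, replace=False, p=w))
    else:
        raise ArgumentError(f"unknown downsampling strategy {strategy!r}")
    return frame.take(idx)


@dataclass
class MergedData:
    """Merged multi-sample matrix restricted to the shared analysis channels.

    ``values`` excludes the Time channel, which is carried in ``time`` so
    signal cleaning can use it regardless of marker selection.  ``origin``
    gives each event's index into ``sample_ids``.
    """

    sample_ids: list[str]
    technique: Technique
    channels: list[str]
    markers: list[str]
    values: np.ndarray
    origin: np.ndarray
    annotation: SampleAnnotation
    time: np.ndarray | None = None
    selected_markers: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.int64)
        if self.values.shape[0] != self.origin.shape[0]:
            raise ArgumentError("origin length must equal the merged event count")
        if self.values.shape[1] != len(self.channels) or len(self.markers) != len(self.channels):
            raise ArgumentError("channel/marker naming mismatch")

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise ArgumentError(f"unknown marker {marker!r}") from None

    def labels_per_event(self) -> np.ndarray:
        """Condition / time-point label of every event (via its sample)."""
        per_sample = np.array(
            [self.annotation.label_of(sid) for sid in self.sample_ids], dtype=object
        )
        return per_sample[self.origin]

    def copy(self, **updates) -> "MergedData":
        base = dict(
            sample_ids=list(self.sample_ids),
            technique=self.technique,
            channels=list(self.channels),
            markers=list(self.markers),
            values=self.values.copy(),
            origin=self.origin.copy(),
            annotation=self.annotation,
            time=None if self.time is None else self.time.copy(),
            selected_markers=None if self.selected_markers is None else list(self.selected_markers),
        )
        base.update(updates)
        return MergedData(**base)

    def take(self, idx: np.ndarray) -> "MergedData":
        return self.copy(
            values=self.values[idx],
            origin=self.origin[idx],
            time=None if self.time is None else self.time[idx],
        )


def merge_samples(
    frames: list[ExpressionFrame],
    annotation: SampleAnnotation,
    per_file_n: int,
    strategy: str = "uniform_random",
    seed: int = 0,
) -> MergedData:
    """Downsample every annotated frame to ``per_file_n`` events and stack.

    Equal per-file counts correct for imbalance in cell numbers across
    samples.  All frames must share the acquisition technique; the merged
    channel set is the first frame's analysis channels intersected with all
    others, in first-frame order.
    """
    by_id = {f.sample_id: f for f in frames}
    missing = [name for name in annotation.filenames if name not in by_id]
    if missing:
        raise MetadataError(f"no FCS frame for annotated filename(s): {missing}")
    ordered = [by_id[name] for name in annotation.filenames]
    techniques = {f.technique for f in ordered}
    if len(techniques) > 1:
        raise TechniqueMismatchError(f"mixed techniques in one merge: {sorted(t.value for t in techniques)}")
    technique = ordered[0].technique

    first = ordered[0]
    shared = [
        ch for ch in first.channels
        if not _is_time_channel(ch) and all(ch in f.channels for f in ordered)
    ]
    if not shared:
        raise ArgumentError("no shared analysis channels across frames")
    marker_of = {ch: first.markers[first.channel_index(ch)] for ch in shared}

    blocks, times, origin = [], [], []
    has_time = all(f.time_channel is not None for f in ordered)
    for si, f in enumerate(ordered):
        sub = downsample(f, per_file_n, strategy=strategy, seed=seed + si)
        cols = [sub.channel_index(ch) for ch in shared]
        blocks.append(sub.values[:, cols])
        if has_time:
            times.append(sub.time_values())
        origin.append(np.full(sub.n_events, si, dtype=np.int64))
    return MergedData(
        sample_ids=[f.sample_id for f in ordered],
        technique=technique,
        channels=shared,
        markers=[marker_of[ch] for ch in shared],
        values=np.vstack(blocks),
        origin=np.concatenate(origin),
        annotation=annotation,
        time=np.concatenate(times) if has_time else None,
    )


def select_markers(data: MergedData, markers: list[str]) -> MergedData:
    """Column-filter to the requested markers (Time is carried regardless)."""
    idx = [data.marker_index(m) for m in markers]
    return data.copy(
        channels=[data.channels[i] for i in idx],
        markers=[data.markers[i] for i in idx],
        values=data.values[:, idx],
        selected_markers=list(markers),
    )
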