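"""Readers and writers for the standard formats the pipeline touches.

Supported formats:

* delimited UTF-8 time-series tables (tab or comma, auto-detected from the
  header line) — the export schema used in place of vendor EMA tooling;
* WAV audio (PCM16/PCM32/float32), used only for the clapperboard
  synchronization impulse and acoustic segmentation;
* Praat TextGrid interval tiers, long and short text dialects;
* CSV per-cycle parameter reports.

Integer WAV samples are normalized by ``2**(bits-1)`` so full-scale maps to
±1; stereo files collapse to channel 0.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import Interval, IntervalTier, TimeSeries
from .errors import FormatError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "read_timeseries_table",
    "write_timeseries_table",
    "read_wav",
    "write_wav",
    "read_textgrid",
    "write_textgrid",
    "write_cycle_report",
    "read_cycle_report",
    "CYCLE_REPORT_COLUMNS",
]


# ---------------------------------------------------------------------------
# delimited time-series tables
# ---------------------------------------------------------------------------

def _detect_delimiter(header_line: str) -> str:
    # Tab wins if present; otherwise comma.  Decimal separator is always '.'.
    return "\t" if "\t" in header_line else ","


def read_timeseries_table(
    stream: IO[str] | str,
    column_map: Mapping[str, str] | None = None,
    rate_hz: float | None = None,
    units: str = "au",
) -> list[TimeSeries]:
    """Read a delimited table into one :class:`TimeSeries` per data column.

    Parameters
    ----------
    stream : text stream or path
    column_map : mapping column-name -> role label, optional
        Columns not listed are skipped.  A column named ``t`` (or mapped to
        role ``"time"``) provides the time base; otherwise ``rate_hz`` must
        be given.
    rate_hz : float, optional
        Sampling rate when no time column is present.  When a time column
        exists the rate is inferred from its median spacing and checked for
        uniformity.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, "r", encoding="utf-8")
        close = True
    try:
        header_line = stream.readline()
        if not header_line.strip():
            raise FormatError("empty table: no header row")
        delim = _detect_delimiter(header_line)
        names = [c.strip() for c in header_line.rstrip("\n").split(delim)]
        rows: list[list[float]] = []
        for lineno, line in enumerate(stream, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(delim)
            if len(cells) != len(names):
                raise ParseError(
                    f"expected {len(names)} cells, found {len(cells)}", line=lineno
                )
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise ParseError(f"malformed numeric cell ({exc})", line=lineno) from None
            if not all(np.isfinite(v) for v in row):
                raise ParseError("non-finite value (NaN/inf) in body", line=lineno)
            rows.append(row)
    finally:
        if close:
            stream.close()

    if not rows:
        raise FormatError("table has a header but no data rows")
    data = np.asarray(rows, dtype=float)

    time_col = None
    if column_map is not None:
        for col, role in column_map.items():
            if role == "time" and col in names:
                time_col = col
    if time_col is None and "t" in names:
        time_col = "t"

    if time_col is not None:
        t = data[:, names.index(time_col)]
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0)):
            raise FormatError(f"time column {time_col!r} is not strictly increasing")
        if len(dt):
            med = float(np.median(dt))
            if np.max(np.abs(dt - med)) > 1e-6 * max(med, 1.0) + 1e-9:
                raise FormatError(f"time column {time_col!r} is not uniformly sampled")
            rate_hz = 1.0 / med
        elif rate_hz is None:
            raise FormatError("single-row table without rate_hz")
        start_s = float(t[0])
    else:
        if rate_hz is None or rate_hz <= 0:
            raise FormatError("no time column present and no positive rate_hz given")
        start_s = 0.0

    out: list[TimeSeries] = []
    for j, name in enumerate(names):
        if name == time_col:
            continue
        if column_map is not None and name not in column_map:
            continue
        label = column_map[name] if column_map is not None else name
        if label == "time":
            continue
        out.append(
            TimeSeries(data[:, j], rate_hz=float(rate_hz), start_s=start_s,
                       label=label, units=units)
        )
    return out


def write_timeseries_table(
    stream: IO[str] | str, series: Iterable[TimeSeries], delimiter: str = "\t"
) -> None:
    """Write equal-length series to a delimited table with a ``t`` column."""
    series = list(series)
    if not series:
        raise ValueError("nothing to write")
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise ValueError("all series must have equal length")
    if any(abs(s.rate_hz - series[0].rate_hz) > 1e-9 for s in series):
        raise ValueError("all series must share one sampling rate")
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w", encoding="utf-8", newline="")
        close = True
    try:
        names = ["t"] + [s.label or f"ch{i}" for i, s in enumerate(series)]
        stream.write(delimiter.join(names) + "\n")
        t = series[0].times()
        cols = [t] + [s.values for s in series]
        for row in zip(*cols):
            stream.write(delimiter.join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_wav(stream: IO[bytes] | str, label: str = "audio") -> TimeSeries:
    """Read a WAV file as a :class:`TimeSeries` scaled to [-1, 1].

    Integer PCM is normalized by ``2**(bits-1)``; float data passes through.
    Multichannel audio collapses to channel 0 (audio is used only for the
    synchronization impulse and segmentation, not acoustic analysis).
    """
    try:
        rate, data = wavfile.read(stream)
    except Exception as exc:
        raise FormatError(f"unreadable WAV: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype.kind == "i":
        scale = float(2 ** (8 * data.dtype.itemsize - 1))
        values = data.astype(float) / scale
    elif data.dtype.kind == "u":  # 8-bit unsigned
        values = (data.astype(float) - 128.0) / 128.0
    else:
        values = data.astype(float)
    return TimeSeries(values, rate_hz=float(rate), start_s=0.0, label=label, units="au")


def write_wav(stream: IO[bytes] | str, ts: TimeSeries) -> None:
    """Write a signal as float32 WAV."""
    wavfile.write(stream, int(round(ts.rate_hz)), ts.values.astype(np.float32))


# ---------------------------------------------------------------------------
# Praat TextGrid (long and short text dialects)
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def _tg_tokens(text: str) -> list[str]:
    """Tokenize a TextGrid body into numbers and quoted strings, in order.

    Both Praat dialects carry the same token sequence once keywords and
    punctuation are stripped, so one tokenizer serves long and short formats.
    """
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == '"':
            j = i + 1
            buf = []
            while j < n:
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':  # escaped quote
                        buf.append('"')
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            else:
                raise FormatError("unterminated string in TextGrid")
            tokens.append('"' + "".join(buf))
            i = j + 1
        elif ch == "[":  # structural index in the long dialect, e.g. "item [3]:"
            j = text.find("]", i)
            i = n if j < 0 else j + 1
        elif ch.isdigit() or (ch == "-" and i + 1 < n and text[i + 1].isdigit()):
            m = _NUM_RE.match(text, i)
            assert m is not None
            tokens.append(m.group(0))
            i = m.end()
        else:
            i += 1
    return tokens


def read_textgrid(stream: IO[str] | str) -> list[IntervalTier]:
    """Read interval tiers from a Praat TextGrid (long or short text format).

    Point (TextTier) tiers are skipped with a logged warning.  Raises
    :class:`FormatError` when any interval has xmin >= xmax (zero-length
    intervals are rejected) or the token stream is malformed.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, "r", encoding="utf-8")
        close = True
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    if "TextGrid" not in text:
        raise FormatError("not a Praat TextGrid file")

    toks = _tg_tokens(text)
    # global xmin, xmax, [exists flag in long format is the word <exists>], size
    pos = 0

    def take_num() -> float:
        nonlocal pos
        while pos < len(toks) and toks[pos].startswith('"'):
            pos += 1
        if pos >= len(toks):
            raise FormatError("truncated TextGrid: expected a number")
        v = float(toks[pos])
        pos += 1
        return v

    def take_str() -> str:
        nonlocal pos
        if pos >= len(toks) or not toks[pos].startswith('"'):
            raise FormatError("truncated TextGrid: expected a string")
        s = toks[pos][1:]
        pos += 1
        return s

    take_num()  # global xmin
    take_num()  # global xmax
    n_tiers = int(take_num())
    tiers: list[IntervalTier] = []
    for _ in range(n_tiers):
        klass = take_str()
        name = take_str()
        t_min = take_num()
        t_max = take_num()
        if t_min > t_max:
            raise FormatError(f"tier {name!r}: xmin {t_min} > xmax {t_max}")
        n_items = int(take_num())
        if klass == "IntervalTier":
            intervals: list[Interval] = []
            for _ in range(n_items):
                x0 = take_num()
                x1 = take_num()
                lab = take_str()
                if x0 > x1:
                    raise FormatError(f"tier {name!r}: interval xmin {x0} > xmax {x1}")
                if x1 > x0:  # Praat pads with zero-length guards only in theory
                    intervals.append(Interval(x0, x1, lab))
            tiers.append(IntervalTier(name, intervals))
        elif klass == "TextTier":
            log.warning("skipping point tier %r (only interval tiers are used)", name)
            for _ in range(n_items):
                take_num()
                take_str()
        else:
            raise FormatError(f"unknown tier class {klass!r}")
    return tiers


def _tg_quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid(
    stream: IO[str] | str,
    tiers: list[IntervalTier],
    xmin: float | None = None,
    xmax: float | None = None,
    short: bool = False,
) -> None:
    """Write interval tiers as a Praat TextGrid.

    Gaps between labelled intervals are filled with empty-label intervals so
    Praat accepts the file.  ``short=True`` emits the short text dialect.
    """
    all_edges = [iv for tier in tiers for iv in tier.intervals]
    lo = 0.0 if xmin is None else xmin
    hi = (max((iv.end_s for iv in all_edges), default=lo + 1.0) if xmax is None else xmax)

    def filled(tier: IntervalTier) -> list[Interval]:
        out: list[Interval] = []
        cursor = lo
        for iv in tier.intervals:
            if iv.start_s > cursor + 1e-9:
                out.append(Interval(cursor, iv.start_s, ""))
            out.append(iv)
            cursor = iv.end_s
        if hi > cursor + 1e-9:
            out.append(Interval(cursor, hi, ""))
        return out

    close = False
    if isinstance(stream, str):
        stream = open(stream, "w", encoding="utf-8", newline="")
        close = True
    try:
        w = stream.write
        w('File type = "ooTextFile"\n')
        w('Object class = "TextGrid"\n\n')
        if short:
            w(f"{lo}\n{hi}\n<exists>\n{len(tiers)}\n")
            for tier in tiers:
                ivs = filled(tier)
                w('"IntervalTier"\n')
                w(f"{_tg_quote(tier.name)}\n{lo}\n{hi}\n{len(ivs)}\n")
                for iv in ivs:
                    w(f"{iv.start_s}\n{iv.end_s}\n{_tg_quote(iv.label)}\n")
        else:
            w(f"xmin = {lo}\nxmax = {hi}\ntiers? <exists>\nsize = {len(tiers)}\n")
            w("item []:\n")
            for ti, tier in enumerate(tiers, start=1):
                ivs = filled(tier)
                w(f"    item [{ti}]:\n")
                w('        class = "IntervalTier"\n')
                w(f"        name = {_tg_quote(tier.name)}\n")
                w(f"        xmin = {lo}\n        xmax = {hi}\n")
                w(f"        intervals: size = {len(ivs)}\n")
                for k, iv in enumerate(ivs, start=1):
                    w(f"        intervals [{k}]:\n")
                    w(f"            xmin = {iv.start_s}\n")
                    w(f"            xmax = {iv.end_s}\n")
                    w(f"            text = {_tg_quote(iv.label)}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# cycle-parameter CSV reports
# ---------------------------------------------------------------------------

CYCLE_REPORT_COLUMNS = [
    "speaker",
    "sentence_type",
    "repetition",
    "dimension",
    "inhalation_duration_ms",
    "exhalation_duration_ms",
    "delta_sonja_ms",
    "inhalation_amplitude_sd",
]


def write_cycle_report(records: Iterable[Mapping[str, object]],
                       stream: IO[str] | str | None = None) -> str:
    """Write per-cycle parameters to CSV with a fixed, documented header.

    One row per (utterance x signal dimension); rows are sorted by
    (speaker, sentence_type, repetition, dimension) so output is
    deterministic.  Returns the CSV text (and writes it if a stream/path is
    given).  An empty record list yields a header-only file.
    """
    rows = [dict(r) for r in records]
    for r in rows:
        missing = [c for c in CYCLE_REPORT_COLUMNS if c not in r]
        if missing:
            raise ValueError(f"record missing fields {missing}")
    rows.sort(key=lambda r: (str(r["speaker"]), str(r["sentence_type"]),
                             int(r["repetition"]), str(r["dimension"])))
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=CYCLE_REPORT_COLUMNS, extrasaction="ignore",
                            lineterminator="\n")
    writer.writeheader()
    for r in rows:
        writer.writerow({k: (repr(float(v)) if isinstance(v, float) else v)
                         for k, v in r.items() if k in CYCLE_REPORT_COLUMNS})
    text = buf.getvalue()
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_cycle_report(stream: IO[str] | str) -> pd.DataFrame:
    df = pd.read_csv(stream)
    missing = [c for c in CYCLE_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cycle report missing columns {missing}")
    return df
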