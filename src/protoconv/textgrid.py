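"""Minimal Praat TextGrid reader/writer.

Supports the two *text* dialects Praat emits ("long" with ``key = value``
lines and "short" with bare values), interval tiers and point tiers, and the
UTF-8 / UTF-16 encodings Praat uses.  Binary TextGrids are rejected with a
clear message.  Only what interval-annotation work needs is implemented:
there is no support for multi-line labels.

Times are kept at full double precision; the writer emits 17 significant
digits so a write/read round trip reproduces boundaries exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

__all__ = [
    "Interval",
    "Point",
    "IntervalTier",
    "PointTier",
    "TextGrid",
    "TextGridError",
    "read",
    "write",
]


class TextGridError(ValueError):
    """Raised for malformed or unsupported TextGrid input."""


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass(frozen=True)
class Point:
    number: float
    mark: str


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval] = field(default_factory=list)


@dataclass
class PointTier:
    name: str
    xmin: float
    xmax: float
    points: list[Point] = field(default_factory=list)


Tier = Union[IntervalTier, PointTier]


@dataclass
class TextGrid:
    xmin: float
    xmax: float
    tiers: list[Tier] = field(default_factory=list)

    def tier_names(self) -> list[str]:
        return [t.name for t in self.tiers]

    def get_tier(self, name: str) -> Tier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise TextGridError(
            f"tier {name!r} not found; available tiers: {self.tier_names()!r}"
        )


# ---------------------------------------------------------------------------
# reading

_INDEX_LINE = re.compile(r"^(item|intervals|points)\s*\[\d*\]\s*:?\s*$")


def _decode(raw: bytes) -> str:
    if raw.startswith(b"ooBinaryFile"):
        raise TextGridError(
            "binary TextGrid files are not supported; re-save as a text "
            "TextGrid from Praat"
        )
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    if raw.startswith(b"\xef\xbb\xbf"):
        return raw.decode("utf-8-sig")
    return raw.decode("utf-8")


def _parse_quoted(value: str, where: str) -> str:
    # Praat escapes embedded double quotes by doubling them.
    if not value.endswith('"') or len(value) < 2:
        raise TextGridError(f"unterminated string {value!r} {where}")
    return value[1:-1].replace('""', '"')


def _tokens(text: str) -> Iterator[object]:
    """Yield values (floats / strings / the ``'exists'`` flag) in file order.

    Long- and short-format files differ only in decoration (``xmin = 0`` vs
    a bare ``0``; ``item [1]:`` headers), so after stripping decoration both
    dialects yield the same token stream.
    """
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or _INDEX_LINE.match(line):
            continue
        if "=" in line and not line.startswith('"'):
            line = line.split("=", 1)[1].strip()
        if "<exists>" in line:
            yield "exists"
            continue
        if "<absent>" in line:
            yield "absent"
            continue
        if line.startswith('"'):
            yield _parse_quoted(line, f"on line {lineno}")
            continue
        try:
            yield float(line)
        except ValueError:
            # decorative long-format residue such as "item []:"
            continue


class _TokenStream:
    def __init__(self, tokens: Iterator[object]):
        self._tokens = list(tokens)
        self._pos = 0

    def peek(self) -> object | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def next_number(self, what: str) -> float:
        tok = self.peek()
        if not isinstance(tok, float):
            raise TextGridError(f"expected a number for {what}, got {tok!r}")
        self._pos += 1
        return tok

    def next_string(self, what: str) -> str:
        tok = self.peek()
        if not isinstance(tok, str) or tok in ("exists", "absent"):
            raise TextGridError(f"expected a string for {what}, got {tok!r}")
        self._pos += 1
        return tok

    def pop_flag(self) -> str | None:
        tok = self.peek()
        if tok in ("exists", "absent"):
            self._pos += 1
            return tok  # type: ignore[return-value]
        return None


def read(path: str | Path) -> TextGrid:
    """Parse a Praat text TextGrid (long or short format)."""
    raw = Path(path).read_bytes()
    text = _decode(raw)
    stream = _TokenStream(_tokens(text))
    # Both dialects open with the same two header strings.
    if stream.peek() != "ooTextFile":
        raise TextGridError(f"{path}: not a Praat text file (bad header)")
    stream.next_string("file type header")
    if stream.peek() != "TextGrid":
        raise TextGridError(f"{path}: not a TextGrid object")
    stream.next_string("object class header")

    xmin = stream.next_number("global xmin")
    xmax = stream.next_number("global xmax")
    flag = stream.pop_flag()
    grid = TextGrid(xmin=xmin, xmax=xmax)
    if flag == "absent":
        return grid
    n_tiers = int(stream.next_number("tier count"))
    for i in range(n_tiers):
        klass = stream.next_string(f"class of tier {i + 1}")
        name = stream.next_string(f"name of tier {i + 1}")
        t_xmin = stream.next_number(f"xmin of tier {name!r}")
        t_xmax = stream.next_number(f"xmax of tier {name!r}")
        n_items = int(stream.next_number(f"size of tier {name!r}"))
        if klass == "IntervalTier":
            tier: Tier = IntervalTier(name, t_xmin, t_xmax)
            for j in range(n_items):
                a = stream.next_number(f"interval {j + 1} xmin in {name!r}")
                b = stream.next_number(f"interval {j + 1} xmax in {name!r}")
                lab = stream.next_string(f"interval {j + 1} text in {name!r}")
                tier.intervals.append(Interval(a, b, lab))
        elif klass == "TextTier":
            tier = PointTier(name, t_xmin, t_xmax)
            for j in range(n_items):
                num = stream.next_number(f"point {j + 1} number in {name!r}")
                mark = stream.next_string(f"point {j + 1} mark in {name!r}")
                tier.points.append(Point(num, mark))
        else:
            raise TextGridError(f"unsupported tier class {klass!r}")
        grid.tiers.append(tier)
    return grid


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write(grid: TextGrid, path: str | Path) -> None:
    """Write a long-format, UTF-8 TextGrid that :func:`read` inverts exactly."""
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {_fmt(grid.xmin)}",
        f"xmax = {_fmt(grid.xmax)}",
        "tiers? <exists>",
        f"size = {len(grid.tiers)}",
        "item []:",
    ]
    for i, tier in enumerate(grid.tiers, start=1):
        lines.append(f"    item [{i}]:")
        if isinstance(tier, IntervalTier):
            lines.append('        class = "IntervalTier"')
            lines.append(f"        name = {_quote(tier.name)}")
            lines.append(f"        xmin = {_fmt(tier.xmin)}")
            lines.append(f"        xmax = {_fmt(tier.xmax)}")
            lines.append(f"        intervals: size = {len(tier.intervals)}")
            for j, iv in enumerate(tier.intervals, start=1):
                lines.append(f"        intervals [{j}]:")
                lines.append(f"            xmin = {_fmt(iv.xmin)}")
                lines.append(f"            xmax = {_fmt(iv.xmax)}")
                lines.append(f"            text = {_quote(iv.text)}")
        else:
            lines.append('        class = "TextTier"')
            lines.append(f"        name = {_quote(tier.name)}")
            lines.append(f"        xmin = {_fmt(tier.xmin)}")
            lines.append(f"        xmax = {_fmt(tier.xmax)}")
            lines.append(f"        points: size = {len(tier.points)}")
            for j, pt in enumerate(tier.points, start=1):
                lines.append(f"        points [{j}]:")
                lines.append(f"            number = {_fmt(pt.number)}")
                lines.append(f"            mark = {_quote(pt.mark)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
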