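"""Minimal Praat TextGrid interval-tier reader/writer.

Handles the "long" (ooTextFile with labelled fields) and "short" dialects,
which is what behaviour-annotation exports use.  Only interval tiers are
supported; point tiers are skipped.
"""

from __future__ import annotations

import re
from pathlib import Path

Interval = tuple[float, float, str]


def read_textgrid(path: str | Path) -> dict[str, list[Interval]]:
    """Parse a TextGrid into ``{tier_name: [(xmin, xmax, text), ...]}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TextGrid not found: {path}")
    text = path.read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text.splitlines()[0]:
        raise ValueError(f"{path}: not a TextGrid (missing ooTextFile header)")
    if re.search(r"^\s*item\s*\[", text, flags=re.M):
        return _read_long(text, path)
    return _read_short(text, path)


def _read_long(text: str, path: Path) -> dict[str, list[Interval]]:
    tiers: dict[str, list[Interval]] = {}
    blocks = re.split(r"^\s*item\s*\[\d+\]\s*:?\s*$", text, flags=re.M)[1:]
    for block in blocks:
        cls = re.search(r'class\s*=\s*"([^"]*)"', block)
        name = re.search(r'name\s*=\s*"([^"]*)"', block)
        if cls is None or cls.group(1) != "IntervalTier":
            continue
        tier_name = name.group(1) if name else f"tier{len(tiers)}"
        intervals: list[Interval] = []
        for m in re.finditer(
                r"intervals\s*\[\d+\]\s*:?\s*\n"
                r"\s*xmin\s*=\s*([\d.eE+-]+)\s*\n"
                r"\s*xmax\s*=\s*([\d.eE+-]+)\s*\n"
                r'\s*text\s*=\s*"((?:[^"]|"")*)"', block):
            xmin, xmax = float(m.group(1)), float(m.group(2))
            label = m.group(3).replace('""', '"')
            intervals.append((xmin, xmax, label))
        if not intervals:
            raise ValueError(f"{path}: interval tier '{tier_name}' parsed no intervals")
        tiers[tier_name] = intervals
    if not tiers:
        raise ValueError(f"{path}: no interval tiers found")
    return tiers


def _read_short(text: str, path: Path) -> dict[str, list[Interval]]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    # short format: header (6 lines incl. tier count) then per tier:
    # "IntervalTier", name, xmin, xmax, n, then n * (xmin, xmax, text)
    tiers: dict[str, list[Interval]] = {}
    i = 0
    while i < len(lines):
        if lines[i].strip('"') == "IntervalTier":
            try:
                name = lines[i + 1].strip('"')
                n = int(lines[i + 4])
                intervals: list[Interval] = []
                j = i + 5
                for k in range(n):
                    xmin = float(lines[j + 3 * k])
                    xmax = float(lines[j + 3 * k + 1])
                    label = lines[j + 3 * k + 2].strip('"')
                    intervals.append((xmin, xmax, label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed short TextGrid near line {i}: {exc}")
            tiers[name] = intervals
            i = j + 3 * n
        else:
            i += 1
    if not tiers:
        raise ValueError(f"{path}: no interval tiers found")
    return tiers


def write_textgrid(path: str | Path, tiers: dict[str, list[Interval]],
                   xmin: float = 0.0, xmax: float | None = None) -> None:
    """Write interval tiers as a long-format TextGrid.

    Gaps between annotated intervals are filled with empty-text intervals so
    the file is a valid, contiguous Praat tier.
    """
    if xmax is None:
        xmax = max((iv[1] for ivs in tiers.values() for iv in ivs), default=1.0)
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t_idx, (name, intervals) in enumerate(tiers.items(), start=1):
        filled: list[Interval] = []
        cursor = xmin
        for a, b, text in sorted(intervals):
            if a > cursor:
                filled.append((cursor, a, ""))
            filled.append((a, b, text))
            cursor = b
        if cursor < xmax:
            filled.append((cursor, xmax, ""))
        lines += [
            f"    item [{t_idx}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin}",
            f"        xmax = {xmax}",
            f"        intervals: size = {len(filled)}",
        ]
        for i_idx, (a, b, text) in enumerate(filled, start=1):
            esc = text.replace('"', '""')
            lines += [
                f"        intervals [{i_idx}]:",
                f"            xmin = {a}",
                f"            xmax = {b}",
                f'            text = "{esc}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
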