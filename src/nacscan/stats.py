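"""Trajectory-level persistence statistics of W1/W2 detections.

Counts are frame-level: a frame counts once as a W1 frame however many
attacking waters it contains, and once as a W1+W2 frame if any assisting
water is present.  Pair occupancy measures how persistently one specific
(W1, W2) water pair co-qualifies; its denominator is ambiguous in common
usage, so it is a mandatory explicit parameter — either all frames of the
trajectory or only the W1 frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .detector import FrameReport, WaterId

__all__ = [
    "DenominatorMode",
    "PairKey",
    "Summary",
    "summarize",
    "pair_occupancy",
    "format_percent",
]


class DenominatorMode(str, Enum):
    W1_FRAMES = "w1_frames"
    ALL_FRAMES = "all_frames"


@dataclass(frozen=True, order=True)
class PairKey:
    """An ordered (attacking, assisting) water pair."""

    w1: WaterId
    w2: WaterId

    def __post_init__(self) -> None:
        if self.w1 == self.w2:
            raise ValueError("W1 and W2 of a pair must be distinct waters")


@dataclass(frozen=True)
class Summary:
    """Trajectory-level W1/W2 statistics.

    Percentages are retained at full precision; ``None`` marks an undefined
    percentage (zero denominator), which is deliberately distinct from 0.
    """

    n_frames_total: int
    n_w1_frames: int
    n_w1w2_frames: int
    pct_w2_of_w1: float | None
    n_distinct_pairs: int
    pair_occupancy: dict[PairKey, float | None]
    top_pair: PairKey | None
    top_pair_occupancy: float | None
    denominator_mode: DenominatorMode


def format_percent(value: float | None, threshold_2dp: float = 95.0) -> str:
    """Display rounding: one decimal place, two once the value reaches
    ``threshold_2dp`` (so 61.3 and 9.5 but 95.37).  ``None`` renders ``n/a``."""
    if value is None:
        return "n/a"
    if value >= threshold_2dp:
        return f"{value:.2f}"
    return f"{value:.1f}"


def _check_reports(reports: Sequence[FrameReport]) -> None:
    if not reports:
        raise ValueError("reports must be non-empty")
    indices = [r.frame_index for r in reports]
    if len(set(indices)) != len(indices):
        raise ValueError("frame indices must be unique")


def _denominator(reports: Sequence[FrameReport], mode: DenominatorMode) -> int:
    if mode == DenominatorMode.ALL_FRAMES:
        return len(reports)
    return sum(1 for r in reports if r.has_w1)


def pair_occupancy(
    reports: Sequence[FrameReport],
    pair: PairKey,
    denominator_mode: DenominatorMode | str,
) -> float | None:
    """Percent of frames (per the chosen denominator) in which this exact
    W1+W2 pair co-qualifies.  ``None`` when the denominator is empty."""
    _check_reports(reports)
    mode = DenominatorMode(denominator_mode)
    denom = _denominator(reports, mode)
    if denom == 0:
        return None
    n = sum(
        1
        for r in reports
        if any(h.w1_water == pair.w1 and h.w2_water == pair.w2 for h in r.w2_hits)
    )
    return 100.0 * n / denom


def summarize(
    reports: Sequence[FrameReport],
    denominator_mode: DenominatorMode | str,
) -> Summary:
    """Frame-level counts, the W2-of-W1 percentage, and per-pair occupancies."""
    _check_reports(reports)
    mode = DenominatorMode(denominator_mode)
    ordered = sorted(reports, key=lambda r: r.frame_index)

    n_total = len(ordered)
    n_w1 = sum(1 for r in ordered if r.has_w1)
    n_w1w2 = sum(1 for r in ordered if r.has_w1w2)
    pct = 100.0 * n_w1w2 / n_w1 if n_w1 > 0 else None

    pair_frames: dict[PairKey, int] = {}
    for rep in ordered:
        seen = {PairKey(h.w1_water, h.w2_water) for h in rep.w2_hits}
        for key in seen:
            pair_frames[key] = pair_frames.get(key, 0) + 1

    denom = _denominator(ordered, mode)
    occupancies: dict[PairKey, float | None] = {
        key: (100.0 * n / denom if denom > 0 else None) for key, n in pair_frames.items()
    }
    top_pair = None
    top_occ = None
    if pair_frames and denom > 0:
        top_pair = max(pair_frames, key=lambda k: (pair_frames[k], k))
        top_occ = occupancies[top_pair]

    return Summary(
        n_frames_total=n_total,
        n_w1_frames=n_w1,
        n_w1w2_frames=n_w1w2,
        pct_w2_of_w1=pct,
        n_distinct_pairs=len(pair_frames),
        pair_occupancy=occupancies,
        top_pair=top_pair,
        top_pair_occupancy=top_occ,
        denominator_mode=mode,
    )


def summary_to_json(summary: Summary, path: str | Path) -> None:
    def pair_str(key: PairKey) -> str:
        def w(ident: WaterId) -> str:
            name, seq, chain = ident
            return f"{name}{seq}" + (f":{chain}" if chain else "")

        return f"{w(key.w1)}+{w(key.w2)}"

    payload = {
        "n_frames_total": summary.n_frames_total,
        "n_w1_frames": summary.n_w1_frames,
        "n_w1w2_frames": summary.n_w1w2_frames,
        "pct_w2_of_w1": summary.pct_w2_of_w1,
        "pct_w2_of_w1_display": format_percent(summary.pct_w2_of_w1),
        "n_distinct_pairs": summary.n_distinct_pairs,
        "denominator_mode": summary.denominator_mode.value,
        "pair_occupancy": {
            pair_str(k): {"percent": v, "display": format_percent(v)}
            for k, v in sorted(summary.pair_occupancy.items())
        },
        "top_pair": pair_str(summary.top_pair) if summary.top_pair else None,
        "top_pair_occupancy": summary.top_pair_occupancy,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
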