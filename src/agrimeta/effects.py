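"""Log response-ratio effect sizes and their diagnostics.

The effect size is y = ln(mean_org / mean_conv) with sampling variance
v = sd_org^2 / (n_org * mean_org^2) + sd_conv^2 / (n_conv * mean_conv^2).
A positive y means the organic arm is richer.  The normal approximation to
the log ratio is considered adequate when sqrt(n) * mean / sd exceeds ~3 in
both arms; the score is diagnostic only and never used to exclude data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import StudyRecord

__all__ = [
    "EffectSize",
    "log_response_ratio",
    "effects_from_records",
    "adequacy_score",
    "adequacy_summary",
    "percent_change",
    "write_effect_table",
]


@dataclass
class EffectSize:
    y: float
    v: float
    publication_id: str
    observation_id: str = ""
    adequacy_org: float = math.inf
    adequacy_conv: float = math.inf
    record: StudyRecord | None = None

    @property
    def adequacy_min(self) -> float:
        return min(self.adequacy_org, self.adequacy_conv)


def log_response_ratio(
    mean_org: float,
    sd_org: float,
    n_org: int,
    mean_conv: float,
    sd_conv: float,
    n_conv: int,
    *,
    publication_id: str = "",
    observation_id: str = "",
    record: StudyRecord | None = None,
) -> EffectSize:
    """Compute one log response-ratio effect size from arm summaries."""
    if mean_org <= 0 or mean_conv <= 0:
        raise ValueError("undefined log ratio: arm means must be > 0")
    if n_org <= 1 or n_conv <= 1:
        raise ValueError("arm sample sizes must exceed 1")
    if sd_org < 0 or sd_conv < 0:
        raise ValueError("arm SDs must be >= 0")
    y = math.log(mean_org) - math.log(mean_conv)
    v = sd_org**2 / (n_org * mean_org**2) + sd_conv**2 / (n_conv * mean_conv**2)
    if v <= 0:
        raise ValueError("degenerate variance: both arm SDs are zero")
    return EffectSize(
        y=y,
        v=v,
        publication_id=publication_id,
        observation_id=observation_id,
        adequacy_org=adequacy_score(mean_org, sd_org, n_org),
        adequacy_conv=adequacy_score(mean_conv, sd_conv, n_conv),
        record=record,
    )


def effects_from_records(records: Iterable[StudyRecord]) -> list[EffectSize]:
    return [
        log_response_ratio(
            r.mean_org, r.sd_org, r.n_org, r.mean_conv, r.sd_conv, r.n_conv,
            publication_id=r.publication_id,
            observation_id=r.observation_id,
            record=r,
        )
        for r in records
    ]


def adequacy_score(mean: float, sd: float, n: int) -> float:
    """sqrt(n) * mean / sd; +inf when sd = 0."""
    if mean <= 0:
        raise ValueError("adequacy score undefined for nonpositive mean")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd == 0:
        return math.inf
    return math.sqrt(n) * mean / sd


def adequacy_summary(
    effects: Sequence[EffectSize], thresholds: Sequence[float] = (3.0, 6.0)
) -> dict:
    """Fractions of effects whose minimum arm score falls below / above each
    threshold; per-arm fractions are reported alongside (the source material
    is ambiguous about which was summarised, so both are emitted).
    """
    if not effects:
        raise ValueError("adequacy_summary requires a nonempty list")
    minima = [e.adequacy_min for e in effects]
    per_arm = [s for e in effects for s in (e.adequacy_org, e.adequacy_conv)]
    out: dict = {"n_effects": len(effects)}
    for t in thresholds:
        # boundary counted as "not below"
        out[f"min_below_{t:g}"] = sum(m < t for m in minima) / len(minima)
        out[f"min_above_{t:g}"] = sum(m > t for m in minima) / len(minima)
        out[f"arm_below_{t:g}"] = sum(s < t for s in per_arm) / len(per_arm)
        out[f"arm_above_{t:g}"] = sum(s > t for s in per_arm) / len(per_arm)
    return out


def percent_change(y: float) -> float:
    """Percent difference in richness, organic relative to conventional.

    Rounding to an integer happens only at the presentation layer.
    """
    if not math.isfinite(y):
        raise ValueError("y must be finite")
    return 100.0 * (math.exp(y) - 1.0)


def write_effect_table(effects: Iterable[EffectSize], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["publication_id", "observation_id", "y", "v", "adequacy_min"])
        for e in effects:
            writer.writerow([e.publication_id, e.observation_id, e.y, e.v, e.adequacy_min])
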