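"""Stepwise perfusion flow protocol.

The default protocol mirrors the dual-perfusion experiment: a 30-min
baseline at maternal/fetal flows of 14/6 ml/min, then three 60-min maternal
blocks at 10, 14 and 18 ml/min, each subdivided into three 20-min fetal
sub-blocks at 3, 6 and 9 ml/min (9 flow combinations in total), with venous
samples drawn 5, 10, 15 and 18 min into every sub-block.  The 15- and
18-min samples are treated as the quasi-steady-state measurements from
which uptake and transfer are computed.  An optional 15-min tracer-free
wash closes the protocol and is excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["FlowSegment", "FlowProtocol", "build_protocol"]

BASELINE_F_M = 14e-3   # l/min
BASELINE_F_F = 6e-3
MATERNAL_FLOWS = (10e-3, 14e-3, 18e-3)
FETAL_FLOWS = (3e-3, 6e-3, 9e-3)
SAMPLE_OFFSETS = (5.0, 10.0, 15.0, 18.0)        # min into each sub-block
STEADY_SAMPLE_OFFSETS = (15.0, 18.0)


@dataclass(frozen=True)
class FlowSegment:
    """One constant-flow stretch of the protocol."""

    duration: float          # min
    f_m: float               # maternal flow, l/min
    f_f: float               # fetal flow, l/min
    label: str = "experimental"   # baseline | experimental | wash
    sample_offsets: tuple = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be positive: {self!r}")
        if self.f_m < 0 or self.f_f < 0:
            raise ValueError(f"flows must be nonnegative: {self!r}")
        for s in self.sample_offsets:
            if not 0 < s <= self.duration:
                raise ValueError(
                    f"sample offset {s} outside segment of {self.duration} min"
                )


@dataclass(frozen=True)
class FlowProtocol:
    """Ordered piecewise-constant maternal/fetal flow schedule."""

    segments: tuple

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")

    @property
    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    @property
    def experimental_segments(self) -> tuple:
        return tuple(s for s in self.segments if s.label == "experimental")

    def segment_starts(self) -> list:
        starts, t = [], 0.0
        for seg in self.segments:
            starts.append(t)
            t += seg.duration
        return starts


def build_protocol(
    baseline_duration: float = 30.0,
    maternal_flows: Sequence[float] = MATERNAL_FLOWS,
    fetal_flows: Sequence[float] = FETAL_FLOWS,
    maternal_block_duration: float = 60.0,
    sample_offsets: Sequence[float] = SAMPLE_OFFSETS,
    include_wash: bool = False,
    wash_duration: float = 15.0,
    baseline_f_m: float = BASELINE_F_M,
    baseline_f_f: float = BASELINE_F_F,
) -> FlowProtocol:
    """Assemble the stepwise flow protocol.

    With defaults: 1 baseline segment + 9 experimental sub-blocks covering
    the full 3 maternal x 3 fetal flow design over 180 min.  Raises
    ``ValueError`` listing the offending inputs on a malformed configuration.
    """
    problems = []
    if baseline_duration <= 0:
        problems.append("baseline_duration must be positive")
    if not maternal_flows or not fetal_flows:
        problems.append("maternal_flows and fetal_flows must be non-empty")
    if any(f <= 0 for f in maternal_flows):
        problems.append("maternal_flows must be positive")
    if any(f <= 0 for f in fetal_flows):
        problems.append("fetal_flows must be positive")
    if maternal_block_duration <= 0:
        problems.append("maternal_block_duration must be positive")
    if problems:
        raise ValueError("invalid protocol config: " + "; ".join(problems))

    sub_duration = maternal_block_duration / len(fetal_flows)
    offsets = tuple(sorted(sample_offsets))
    if offsets and offsets[-1] > sub_duration:
        raise ValueError(
            f"invalid protocol config: sample offset {offsets[-1]} exceeds "
            f"sub-block duration {sub_duration}"
        )

    segments = [
        FlowSegment(baseline_duration, baseline_f_m, baseline_f_f,
                    label="baseline")
    ]
    for f_m in maternal_flows:
        for f_f in fetal_flows:
            segments.append(
                FlowSegment(sub_duration, f_m, f_f, sample_offsets=offsets)
            )
    if include_wash:
        segments.append(
            FlowSegment(wash_duration, baseline_f_m, baseline_f_f, label="wash")
        )
    return FlowProtocol(tuple(segments))
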