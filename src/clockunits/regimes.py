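"""Light regimes: piecewise-constant light/dark schedules on a ZT axis.

A regime is an ordered list of contiguous segments ``(start_h, end_h, light)``.
ZT0 is lights-on of the first cycle.  Regimes drive both the simple protein
model (light-switched degradation) and the clock circuit models (light input).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LightRegime:
    """Ordered, contiguous light/dark segments covering [t0, t1]."""

    segments: tuple[tuple[float, float, bool], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty regime")
        prev_end = None
        for start, end, _light in self.segments:
            if end <= start:
                raise ValueError(f"segment ({start}, {end}) has non-positive length")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")
            prev_end = end
        if self.duration <= 0:
            raise ValueError("regime duration must be positive")

    @property
    def t0(self) -> float:
        return self.segments[0][0]

    @property
    def t1(self) -> float:
        return self.segments[-1][1]

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def light_at(self, t: float) -> bool:
        """Light state at time t; boundaries belong to the later segment."""
        if t < self.t0 or t > self.t1:
            raise ValueError(f"time {t} outside regime [{self.t0}, {self.t1}]")
        for start, end, light in self.segments:
            if start <= t < end:
                return light
        return self.segments[-1][2]

    def switch_times(self) -> list[float]:
        """Interior segment boundaries (dawn/dusk transitions)."""
        return [seg[0] for seg in self.segments[1:]]

    def ll_start(self) -> float | None:
        """Start of the trailing constant-light span, or None if the regime
        ends in darkness / has no light-only tail longer than one segment."""
        last_dark_end = None
        for start, end, light in self.segments:
            if not light:
                last_dark_end = end
        if last_dark_end is None:
            return self.t0
        if last_dark_end >= self.t1:
            return None
        return last_dark_end


def ld_cycles(n_cycles: int, light_h: float = 12.0, dark_h: float = 12.0,
              start: float = 0.0) -> LightRegime:
    """n light:dark cycles, e.g. ``ld_cycles(10)`` = ten 12L:12D cycles."""
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    segs = []
    t = start
    for _ in range(n_cycles):
        segs.append((t, t + light_h, True))
        segs.append((t + light_h, t + light_h + dark_h, False))
        t += light_h + dark_h
    return LightRegime(tuple(segs), f"{light_h:g}L:{dark_h:g}D x{n_cycles}")


def constant_light(hours: float, start: float = 0.0) -> LightRegime:
    return LightRegime(((start, start + hours, True),), f"LL {hours:g}h")


def followed_by(a: LightRegime, b: LightRegime) -> LightRegime:
    """Concatenate two regimes; b is shifted to start where a ends."""
    shift = a.t1 - b.t0
    segs = a.segments + tuple((s + shift, e + shift, l) for s, e, l in b.segments)
    desc = f"{a.description} then {b.description}".strip()
    return LightRegime(segs, desc)


def ld_then_ll(n_ld: int, ll_hours: float, light_h: float = 12.0,
               dark_h: float = 12.0) -> LightRegime:
    """The study's standard protocol: LD entrainment then release into LL."""
    return followed_by(ld_cycles(n_ld, light_h, dark_h), constant_light(ll_hours))
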