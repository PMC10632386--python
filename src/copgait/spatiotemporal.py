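"""Spatiotemporal gait parameters from footfall-level COP recordings.

An instrumented pressure walkway exports one COP/pressure time series per
footfall (foot contact).  This module segments those footfalls into strides
and computes the stride-level parameters used in gait analysis:

* stride length — Euclidean distance between two successive ipsilateral
  heel strikes (cm),
* stride velocity — stride length over stride duration (cm/s),
* single support time — time within a stride during which exactly one foot
  is in contact with the ground (s),
* integrated pressure — area under a footfall's pressure-versus-time curve
  (instrument units x s).

Conventions: lengths in cm, times in s.  The heel-strike position of a
footfall is taken to be its first COP sample (walkway exports carry no
anatomical landmarks).  Strides never span walkway passes; the pass
boundary comes from the file, never from inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FootfallRecord:
    """One foot contact with its COP/pressure time series.

    Samples are stored as parallel arrays (``t``, ``x``, ``y``,
    ``pressure``): time in s, mediolateral position in cm (+ = subject's
    right after pass normalization), anteroposterior position in cm along
    the direction of progression, and instrument pressure (>= 0).
    """

    footfall_id: str
    subject_id: str
    trial_label: str
    pass_id: int
    foot: str  # 'L' or 'R'
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)

    @property
    def heel_strike_t(self) -> float:
        return float(self.t[0])

    @property
    def toe_off_t(self) -> float:
        return float(self.t[-1])

    @property
    def heel_position(self) -> tuple[float, float]:
        """(x, y) of the first COP sample — the heel-strike position."""
        return float(self.x[0]), float(self.y[0])

    @property
    def contact_interval(self) -> tuple[float, float]:
        return self.heel_strike_t, self.toe_off_t

    def validate(self) -> None:
        n = self.t.size
        if n < 1:
            raise ValidationError(f"footfall {self.footfall_id}: no samples")
        if not (self.x.size == n and self.y.size == n and self.pressure.size == n):
            raise ValidationError(
                f"footfall {self.footfall_id}: sample arrays have unequal length"
            )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError(
                f"footfall {self.footfall_id}: sample times not strictly increasing"
            )
        if np.any(self.pressure < 0):
            raise ValidationError(
                f"footfall {self.footfall_id}: negative pressure sample"
            )
        if self.foot not in ("L", "R"):
            raise ValidationError(
                f"footfall {self.footfall_id}: foot must be 'L' or 'R', got {self.foot!r}"
            )


@dataclass
class Stride:
    """Two successive ipsilateral heel strikes and the derived parameters.

    ``single_support_time`` is ``None`` when the contralateral contact
    history at the stride start is unknown (first stride of a pass); such
    strides are flagged and excluded from single-support summaries.
    """

    lead: FootfallRecord
    next_ipsilateral: FootfallRecord
    stride_length: float
    stride_duration: float
    stride_velocity: float
    single_support_time: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def foot(self) -> str:
        return self.lead.foot

    @property
    def span(self) -> tuple[float, float]:
        return self.lead.heel_strike_t, self.next_ipsilateral.heel_strike_t


def stride_length_cm(lead: FootfallRecord, nxt: FootfallRecord) -> float:
    """Euclidean distance between the two heel-strike positions (cm)."""
    x0, y0 = lead.heel_position
    x1, y1 = nxt.heel_position
    return float(np.hypot(x1 - x0, y1 - y0))


def stride_velocity(length_cm: float, duration_s: float) -> float:
    """Average stride velocity (cm/s): stride length over stride duration."""
    if duration_s <= 0:
        raise ValidationError(f"stride duration must be positive, got {duration_s}")
    return length_cm / duration_s


def single_support_time(
    span: tuple[float, float], contact_intervals: Iterable[tuple[float, float]]
) -> float:
    """Total time within ``span`` during which exactly one foot is down.

    ``contact_intervals`` are the (heel-strike, toe-off) intervals of every
    footfall — both feet — overlapping the stride span.  Pure interval
    arithmetic: the span is partitioned at interval endpoints and pieces
    with contact multiplicity exactly 1 are summed.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValidationError(f"stride span must have positive length: {span}")
    edges = {t0, t1}
    intervals = []
    for a, b in contact_intervals:
        if b <= t0 or a >= t1:
            continue
        a, b = max(a, t0), min(b, t1)
        intervals.append((a, b))
        edges.add(a)
        edges.add(b)
    cuts = np.array(sorted(edges))
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (lo + hi)
        cover = sum(1 for a, b in intervals if a <= mid < b)
        if cover == 1:
            total += hi - lo
    return float(total)


def integrated_pressure(footfall: FootfallRecord) -> float:
    """Area under the footfall's pressure curve (trapezoidal rule)."""
    if footfall.t.size < 2:
        raise ValidationError(
            f"footfall {footfall.footfall_id}: need >= 2 samples to integrate"
        )
    if np.any(footfall.pressure < 0):
        raise ValidationError(
            f"footfall {footfall.footfall_id}: negative pressure sample"
        )
    return float(np.trapezoid(footfall.pressure, footfall.t))


def _group_passes(
    footfalls: Sequence[FootfallRecord],
) -> dict[int, list[FootfallRecord]]:
    passes: dict[int, list[FootfallRecord]] = {}
    for ff in footfalls:
        passes.setdefault(ff.pass_id, []).append(ff)
    for pid in passes:
        passes[pid].sort(key=lambda f: f.heel_strike_t)
    return passes


def detect_strides(footfalls: Sequence[FootfallRecord]) -> list[Stride]:
    """Segment one subject-trial's footfalls into strides.

    One :class:`Stride` per consecutive ipsilateral footfall pair within a
    walkway pass (never across passes).  Feet must alternate within a pass;
    a violation is a hard validation error.  A pass with fewer than two
    ipsilateral footfalls yields no strides (logged).

    Single support is computed per stride from both feet's contact
    intervals; it is flagged missing when no contralateral footfall has
    begun by the stride's start (contact history unknown at a pass edge).
    """
    strides: list[Stride] = []
    for pass_id, ffs in sorted(_group_passes(footfalls).items()):
        for ff in ffs:
            ff.validate()
        for prev, cur in zip(ffs[:-1], ffs[1:]):
            if prev.foot == cur.foot:
                raise ValidationError(
                    f"pass {pass_id}: feet do not alternate "
                    f"({prev.footfall_id} and {cur.footfall_id} both {cur.foot})"
                )
        by_foot = {"L": [f for f in ffs if f.foot == "L"],
                   "R": [f for f in ffs if f.foot == "R"]}
        contacts = [f.contact_interval for f in ffs]
        made_any = False
        for foot, same in by_foot.items():
            if len(same) < 2:
                continue
            contra = by_foot["R" if foot == "L" else "L"]
            for lead, nxt in zip(same[:-1], same[1:]):
                length = stride_length_cm(lead, nxt)
                duration = nxt.heel_strike_t - lead.heel_strike_t
                if duration <= 0:
                    raise ValidationError(
                        f"pass {pass_id}: non-positive stride duration between "
                        f"{lead.footfall_id} and {nxt.footfall_id}"
                    )
                span = (lead.heel_strike_t, nxt.heel_strike_t)
                history_known = any(
                    c.heel_strike_t <= lead.heel_strike_t for c in contra
                )
                if history_known:
                    ss: float | None = single_support_time(span, contacts)
                    flags: tuple[str, ...] = ()
                else:
                    ss, flags = None, ("missing_single_support",)
                strides.append(
                    Stride(
                        lead=lead,
                        next_ipsilateral=nxt,
                        stride_length=length,
                        stride_duration=duration,
                        stride_velocity=stride_velocity(length, duration),
                        single_support_time=ss,
                        flags=flags,
                    )
                )
                made_any = True
        if not made_any:
            logger.info("pass %s: fewer than 2 ipsilateral footfalls, no strides",
                        pass_id)
    strides.sort(key=lambda s: s.span[0])
    return strides


def normalize_passes(footfalls: Sequence[FootfallRecord]) -> None:
    """Rotate backward walkway passes onto the common forward axis, in place.

    Subjects walk back and forth; passes whose net anteroposterior heel
    progression is negative are rotated by 180 degrees (x -> -x, y -> -y) so
    that +y is always the direction of progression and +x the subject's
    right.  Stride and cyclogram metrics are invariant to this rigid
    motion; normalization only fixes the sign conventions.
    """
    for _pid, ffs in _group_passes(footfalls).items():
        if len(ffs) >= 2:
            dy = ffs[-1].heel_position[1] - ffs[0].heel_position[1]
        else:
            yy = ffs[0].y
            dy = float(yy[-1] - yy[0]) if yy.size >= 2 else 0.0
        if dy < 0:
            for ff in ffs:
                ff.x = -ff.x
                ff.y = -ff.y
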