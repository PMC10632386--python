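"""COP butterfly cyclograms, the cyclogram intersection point, and
single-stance COP path efficiency.

The cyclogram plots the center of pressure's mediolateral displacement
(x) against its anteroposterior displacement (y) over one gait cycle, with
the forward-progression trend removed.  Both feet's COP streams are merged
(pressure-weighted during double support), so the trajectory traces the
familiar butterfly: two single-stance strokes joined by two double-support
transitions that cross near the middle.  The self-intersection of that
path is the cyclogram intersection point (CISP); its anteroposterior and
mediolateral position, expressed as percentages of the cyclogram's extent,
index gait symmetry.

Single-stance COP path efficiency is the length of the straight chord from
the start to the end of a foot's single-stance COP trajectory divided by
the actual path length, times 100.  COP samples exactly on the chord give
100%; lateral meander lowers it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spatiotemporal import FootfallRecord, Stride, detect_strides

logger = logging.getLogger(__name__)

PHASE_SS_L = "single_stance_L"
PHASE_SS_R = "single_stance_R"
PHASE_DS = "double_support"


@dataclass
class CyclogramTrajectory:
    """Merged COP trajectory for one gait cycle, in the cycle frame.

    The frame is anchored at the cycle's leading heel strike, rotated so
    the mean progression velocity points along +y, and the linear forward
    trend (speed x time) is removed from y.  ``phase`` labels each sample
    as single stance (per foot) or double support.
    """

    t: np.ndarray      # s, from cycle start
    x: np.ndarray      # cm, mediolateral after trend removal
    y: np.ndarray      # cm, anteroposterior after trend removal
    phase: np.ndarray  # object array of phase labels

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CyclogramMetrics:
    """Per-cycle CISP position and single-stance COP efficiencies.

    CISP AP is a percentage of the cyclogram's anteroposterior extent
    (0 = posterior edge, 100 = anterior edge); CISP ML is a signed
    percentage of half the mediolateral extent about the midline.
    """

    cisp_ap_pct: float | None
    cisp_ml_pct: float | None
    ss_cop_efficiency_L: float | None
    ss_cop_efficiency_R: float | None
    flags: tuple[str, ...] = ()


def ss_cop_efficiency(x: np.ndarray, y: np.ndarray) -> float:
    """Single-stance COP path efficiency in percent.

    100 x ||end - start|| / (sum of consecutive sample distances), in the
    horizontal plane.  By the triangle inequality the value lies in
    (0, 100], with 100 attained iff the samples are collinear along the
    chord and monotone.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValidationError("efficiency needs >= 2 COP samples")
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    if path <= 0:
        raise ValidationError("zero COP path length")
    chord = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return 100.0 * chord / path


def merge_cycle_cop(
    footfalls: list[FootfallRecord], t0: float, t1: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Merge both feet's COP into one global COP sequence over [t0, t1).

    At each sample time the global COP is the pressure-weighted mean of
    the feet in contact (a single foot's COP during single stance).  The
    time grid is the union of the involved footfalls' sample times.
    Returns (t, x, y, phase).
    """
    involved = [
        ff for ff in footfalls
        if ff.toe_off_t > t0 and ff.heel_strike_t < t1
    ]
    if not involved:
        raise ValidationError("no footfalls overlap the requested cycle")
    times = np.unique(np.concatenate([
        ff.t[(ff.t >= t0) & (ff.t < t1)] for ff in involved
    ]))
    if times.size < 4:
        raise ValidationError("cycle has too few COP samples")
    num_x = np.zeros_like(times)
    num_y = np.zeros_like(times)
    den = np.zeros_like(times)
    sum_x = np.zeros_like(times)
    sum_y = np.zeros_like(times)
    count = np.zeros_like(times)
    feet_down = {"L": np.zeros(times.size, dtype=bool),
                 "R": np.zeros(times.size, dtype=bool)}
    for ff in involved:
        mask = (times >= ff.heel_strike_t) & (times <= ff.toe_off_t)
        if not mask.any():
            continue
        xi = np.interp(times[mask], ff.t, ff.x)
        yi = np.interp(times[mask], ff.t, ff.y)
        pi = np.clip(np.interp(times[mask], ff.t, ff.pressure), 0.0, None)
        num_x[mask] += pi * xi
        num_y[mask] += pi * yi
        den[mask] += pi
        sum_x[mask] += xi
        sum_y[mask] += yi
        count[mask] += 1
        feet_down[ff.foot][mask] = True
    ok = count > 0
    times, num_x, num_y, den = times[ok], num_x[ok], num_y[ok], den[ok]
    sum_x, sum_y, count = sum_x[ok], sum_y[ok], count[ok]
    l_down = feet_down["L"][ok]
    r_down = feet_down["R"][ok]
    # Pressure weighting; fall back to the unweighted mean where total
    # pressure vanishes (contact edges).
    weighted = den > 1e-12
    gx = np.where(weighted, num_x / np.where(weighted, den, 1.0), sum_x / count)
    gy = np.where(weighted, num_y / np.where(weighted, den, 1.0), sum_y / count)
    phase = np.full(times.size, PHASE_DS, dtype=object)
    phase[l_down & ~r_down] = PHASE_SS_L
    phase[r_down & ~l_down] = PHASE_SS_R
    return times, gx, gy, phase


def build_cyclogram(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, phase: np.ndarray
) -> CyclogramTrajectory:
    """Re-express a merged cycle COP sequence in the cyclogram frame.

    Anchors the frame at the first sample (the leading heel strike),
    rotates so the least-squares progression velocity points along +y, and
    subtracts the linear forward trend (speed x time) from y.  After the
    rotation the mediolateral coordinate has exactly zero linear trend.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise ValidationError("cyclogram needs >= 4 samples")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("cycle samples not strictly increasing in time")
    tr = t - t[0]
    xa = x - x[0]
    ya = y - y[0]
    vx = np.polyfit(tr, xa, 1)[0]
    vy = np.polyfit(tr, ya, 1)[0]
    speed = float(np.hypot(vx, vy))
    if speed <= 1e-9:
        raise ValidationError("cycle has no forward progression")
    ux, uy = vx / speed, vy / speed
    # Rotate (ux, uy) -> (0, 1).
    x_rot = uy * xa - ux * ya
    y_rot = ux * xa + uy * ya
    y_detr = y_rot - speed * tr
    return CyclogramTrajectory(t=tr, x=x_rot, y=y_detr, phase=np.asarray(phase))


def _segment_intersections(px, py, qx0, qy0, qx1, qy1):
    """Vectorized proper intersection of one segment with many segments.

    Returns (mask, ix, iy, t_param, u_param) where mask marks genuine
    crossings with parameters in [0, 1] on both segments.
    """
    rx, ry = px[1] - px[0], py[1] - py[0]
    sx, sy = qx1 - qx0, qy1 - qy0
    denom = rx * sy - ry * sx
    wx, wy = qx0 - px[0], qy0 - py[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = (wx * sy - wy * sx) / denom
        uu = (wx * ry - wy * rx) / denom
    mask = (np.abs(denom) > 1e-14) & (tt >= 0) & (tt <= 1) & (uu >= 0) & (uu <= 1)
    ix = px[0] + tt * rx
    iy = py[0] + tt * ry
    return mask, ix, iy, tt, uu


def find_cisp(traj: CyclogramTrajectory) -> tuple[tuple[float, float] | None, CyclogramMetrics]:
    """Locate the cyclogram's self-intersection point.

    Tests every non-adjacent segment pair of the piecewise-linear
    trajectory.  If several crossings exist, returns the one nearest the
    cyclogram's anteroposterior midpoint, breaking ties by the earliest
    position along the path.  Returns ``(None, metrics-with-flag)`` when
    the path never crosses itself.
    """
    x, y = traj.x, traj.y
    n = x.size - 1  # number of segments
    if n < 3:
        return None, CyclogramMetrics(None, None, None, None, ("no_crossing",))
    y_min, y_max = float(y.min()), float(y.max())
    x_min, x_max = float(x.min()), float(x.max())
    y_mid = 0.5 * (y_min + y_max)
    best = None  # (dist_to_mid, seg_i, t_param, ix, iy)
    for i in range(n - 2):
        j0 = i + 2
        mask, ix, iy, tt, _ = _segment_intersections(
            x[i:i + 2], y[i:i + 2],
            x[j0:n], y[j0:n], x[j0 + 1:n + 1], y[j0 + 1:n + 1],
        )
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        for k in idx:
            cand = (abs(iy[k] - y_mid), i, float(tt[k]), float(ix[k]), float(iy[k]))
            if best is None:
                best = cand
            else:
                # nearest AP midpoint; tie -> earliest along the path
                if cand[0] < best[0] - 1e-12:
                    best = cand
                elif abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2]) < (best[1], best[2]):
                    best = cand
    if best is None:
        return None, CyclogramMetrics(None, None, None, None, ("no_crossing",))
    _, _, _, cx, cy = best
    ap_extent = y_max - y_min
    ml_half = 0.5 * (x_max - x_min)
    x_mid = 0.5 * (x_min + x_max)
    ap_pct = 100.0 * (cy - y_min) / ap_extent if ap_extent > 0 else float("nan")
    ml_pct = 100.0 * (cx - x_mid) / ml_half if ml_half > 0 else float("nan")
    return (cx, cy), CyclogramMetrics(ap_pct, ml_pct, None, None, ())


def _single_stance_segment(
    ff: FootfallRecord, contra: list[FootfallRecord]
) -> tuple[np.ndarray, np.ndarray] | None:
    """COP samples of ``ff`` during which the contralateral foot is off."""
    covered = np.zeros(ff.t.size, dtype=bool)
    for c in contra:
        covered |= (ff.t >= c.heel_strike_t) & (ff.t <= c.toe_off_t)
    free = ~covered
    if free.sum() < 2:
        return None
    # use the longest contiguous free run (the mid-stance single-support phase)
    runs = []
    start = None
    for i, f in enumerate(free):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, free.size))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    if e - s < 2:
        return None
    return ff.x[s:e], ff.y[s:e]


def cycle_metrics(
    footfalls: list[FootfallRecord],
    subject_id: str | None = None,
    group: str | None = None,
    trial_label: str | None = None,
) -> pd.DataFrame:
    """Per-cycle cyclogram metrics for one subject-trial recording.

    Cycles are anchored on successive ipsilateral heel strikes of each
    pass's leading foot.  Cycles whose trajectory never self-intersects
    (e.g. the first cycle of a pass, which lacks the preceding
    double-support transition) yield flagged rows that summaries exclude.
    Efficiency is computed per foot from each foot's single-stance COP
    segment within the cycle.

    Returns a tidy frame: subject_id, group, trial, cycle_index, metric,
    foot, value, flag.
    """
    if subject_id is None and footfalls:
        subject_id = footfalls[0].subject_id
    if trial_label is None and footfalls:
        trial_label = footfalls[0].trial_label
    strides = detect_strides(footfalls)
    by_pass: dict[int, list[FootfallRecord]] = {}
    for ff in footfalls:
        by_pass.setdefault(ff.pass_id, []).append(ff)
    rows = []
    n_no_crossing = 0
    cycle_index = 0
    for st in strides:
        pass_ffs = by_pass[st.lead.pass_id]
        # anchor cycles on the pass's leading foot only (avoid double counting)
        lead_foot = min(pass_ffs, key=lambda f: f.heel_strike_t).foot
        if st.foot != lead_foot:
            continue
        t0, t1 = st.span
        try:
            tm, xm, ym, ph = merge_cycle_cop(pass_ffs, t0, t1)
            traj = build_cyclogram(tm, xm, ym, ph)
            _, cm = find_cisp(traj)
        except ValidationError:
            cm = CyclogramMetrics(None, None, None, None, ("degenerate_cycle",))
        if "no_crossing" in cm.flags or "degenerate_cycle" in cm.flags:
            n_no_crossing += 1
            flag = cm.flags[0]
            for metric in ("cisp_ap_pct", "cisp_ml_pct"):
                rows.append((subject_id, group, trial_label, cycle_index,
                             metric, "", np.nan, flag))
        else:
            rows.append((subject_id, group, trial_label, cycle_index,
                         "cisp_ap_pct", "", cm.cisp_ap_pct, ""))
            rows.append((subject_id, group, trial_label, cycle_index,
                         "cisp_ml_pct", "", cm.cisp_ml_pct, ""))
        # per-foot single-stance efficiency within the cycle
        in_cycle = [
            ff for ff in pass_ffs
            if ff.heel_strike_t < t1 and ff.toe_off_t > t0
        ]
        for ff in in_cycle:
            if ff.heel_strike_t < t0:  # belongs to the previous cycle
                continue
            contra = [c for c in pass_ffs if c.foot != ff.foot]
            seg = _single_stance_segment(ff, contra)
            if seg is None:
                rows.append((subject_id, group, trial_label, cycle_index,
                             "ss_cop_efficiency", ff.foot, np.nan,
                             "missing_single_stance"))
                continue
            try:
                eff = ss_cop_efficiency(*seg)
            except ValidationError:
                rows.append((subject_id, group, trial_label, cycle_index,
                             "ss_cop_efficiency", ff.foot, np.nan,
                             "degenerate_segment"))
                continue
            rows.append((subject_id, group, trial_label, cycle_index,
                         "ss_cop_efficiency", ff.foot, eff, ""))
        cycle_index += 1
    if n_no_crossing:
        logger.info("%s/%s: %d cycles without a cyclogram crossing",
                    subject_id, trial_label, n_no_crossing)
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "trial", "cycle_index",
                 "metric", "foot", "value", "flag"],
    )


def plot_cyclogram(traj: CyclogramTrajectory, ax=None):
    """Diagnostic butterfly plot of one cycle (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {PHASE_SS_L: "tab:blue", PHASE_SS_R: "tab:orange",
              PHASE_DS: "tab:gray"}
    for ph, c in colors.items():
        m = traj.phase == ph
        ax.plot(traj.x[m], traj.y[m], ".", ms=3, color=c, label=ph)
    ax.plot(traj.x, traj.y, "-", lw=0.5, color="k", alpha=0.3)
    pt, _ = find_cisp(traj)
    if pt is not None:
        ax.plot(*pt, "r*", ms=12, label="CISP")
    ax.set_xlabel("mediolateral (cm)")
    ax.set_ylabel("anteroposterior, detrended (cm)")
    ax.legend(fontsize=7)
    return ax
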