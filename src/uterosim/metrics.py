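"""Summary metrics: action-potential waveform features, wavefront speed,
refractory period and the contracting-volume fraction.

Conventions (documented in the methods note):
- "contracting" means v_m at or above the excitation threshold, default
  -40 mV (the v2 parameter of the ionic model);
- upstroke arrival times are crossings of the same -40 mV level;
- the action-potential duration runs from the upward to the subsequent
  downward crossing of the resting level, i.e. ends where the
  hyperpolarized undershoot begins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fhn import Trajectory, integrate_space_clamped, resting_state
from .geometry import Compartment
from .meshing import Mesh
from .monodomain import FieldSeries
from .params import IonicParams

__all__ = [
    "WaveformMetrics",
    "waveform_metrics",
    "contracting_fraction",
    "refractory_period",
    "front_speed",
    "front_speed_1d",
    "CONTRACT_THRESHOLD",
    "UPSTROKE_LEVEL",
]

CONTRACT_THRESHOLD = -0.040  # V
UPSTROKE_LEVEL = -0.040  # V


@dataclass
class WaveformMetrics:
    peak_vm: float
    plateau_mean: float
    duration_s: float
    resting_vm: float

    def __post_init__(self) -> None:
        if not (self.peak_vm >= self.plateau_mean >= self.resting_vm):
            raise ValueError("expect peak >= plateau mean >= resting level")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def _cross_time(t: np.ndarray, v: np.ndarray, level: float, i: int) -> float:
    """Linear-interpolated crossing time between samples i and i+1."""
    f = (level - v[i]) / (v[i + 1] - v[i])
    return t[i] + f * (t[i + 1] - t[i])


def waveform_metrics(
    t: np.ndarray,
    v: np.ndarray,
    resting: float = -0.056,
    band: float = 0.005,
    lookback: float = 2.0,
) -> WaveformMetrics | None:
    """Extract plateau action-potential features from a probe trace.

    Returns None (no-AP signal) if the trace never exceeds resting + 10 mV.
    The plateau window runs from the first post-peak sample to the onset of
    rapid repolarization, detected as the first instant the trace falls
    more than ``band`` below its own value ``lookback`` seconds earlier
    (the slowly declining plateau stays inside the band; the abrupt
    repolarization leaves it).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.max() < resting + 0.010:
        return None
    ip = int(np.argmax(v))
    peak = float(v[ip])

    # duration: upward crossing of resting before the peak, downward after
    up = None
    for i in range(ip - 1, -1, -1):
        if v[i] <= resting < v[i + 1]:
            up = _cross_time(t, v, resting, i)
            break
    down = None
    for i in range(ip, len(v) - 1):
        if v[i] >= resting > v[i + 1]:
            down = _cross_time(t, v, resting, i)
            break
    if up is None or down is None:
        return None

    # repolarization onset via the lookback band
    onset_idx = len(v) - 1
    for i in range(ip + 1, len(v)):
        j = int(np.searchsorted(t, t[i] - lookback))
        j = min(max(j, 0), i - 1)
        if v[i] < v[j] - band:
            onset_idx = i
            break
    sel = slice(ip, max(onset_idx, ip + 1))
    plateau = float(np.mean(v[sel]))
    return WaveformMetrics(
        peak_vm=peak,
        plateau_mean=plateau,
        duration_s=float(down - up),
        resting_vm=resting,
    )


def contracting_fraction(
    series: FieldSeries,
    mesh: Mesh | None = None,
    threshold: float = CONTRACT_THRESHOLD,
    resting: float = -0.056,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of myometrial volume with v_m >= threshold, per time.

    Element-wise: an element counts as contracting when its nodal mean is
    at or above the threshold; the percentage is volume-weighted.
    """
    mesh = mesh or series.mesh
    if threshold < resting:
        warnings.warn(
            "contracting threshold below the resting level: the fraction "
            "would be 100% at rest",
            stacklevel=2,
        )
    mask = mesh.cell_labels == Compartment.M
    vols = mesh.cell_volumes()[mask]
    total = vols.sum()
    cells = mesh.cells[mask]
    pct = np.empty(series.times.size)
    for i, snap in enumerate(series.values):
        elem_v = snap[cells].mean(axis=1)
        pct[i] = 100.0 * vols[elem_v >= threshold].sum() / total
    return series.times.copy(), pct


def _post_offset_peak(traj: Trajectory, t_after: float) -> float:
    m = traj.t >= t_after
    return float(traj.v_m[m].max())


def refractory_period(
    params: IonicParams,
    nu: float = 2.0,
    stim_dur: float = 0.1,
    tol_s: float = 1.0,
    tol_mv: float = 5.0,
    t_max: float = 600.0,
    settle: float = 1.0,
) -> float:
    """Minimal inter-stimulus interval re-eliciting a full action potential.

    Space-clamped (0D) protocol: two identical pulses (amplitude ``nu`` V,
    duration ``stim_dur`` s) separated by a variable interval, from the
    resting initial state.  The second response counts as a full AP when
    (a) v_m has returned below the resting level before the second pulse
    and (b) its post-offset peak (measured ``settle`` s after stimulus
    offset, to exclude the stimulus-driven transient) lies within
    ``tol_mv`` mV of the unconditioned AP's post-offset peak.  Bisection to
    ``tol_s``; returns ``math.inf`` if no interval up to ``t_max`` succeeds.
    """
    p = params

    def drive(stims):
        def f(t):
            for t0 in stims:
                if t0 <= t <= t0 + stim_dur:
                    return nu / p.eps1
            return 0.0

        return f

    margin = 120.0
    ref = integrate_space_clamped(
        p, drive([0.0]), (0.0, margin + stim_dur), dt=0.02
    )
    peak0 = _post_offset_peak(ref, stim_dur + settle)

    def full_ap(interval: float) -> bool:
        t1 = interval
        traj = integrate_space_clamped(
            p, drive([0.0, t1]), (0.0, t1 + margin), dt=0.02
        )
        before = (traj.t > stim_dur) & (traj.t < t1)
        if not np.any(traj.v_m[before] < p.v_mr):
            return False
        peak = _post_offset_peak(traj, t1 + stim_dur + settle)
        return peak >= peak0 - tol_mv * 1e-3

    lo = stim_dur
    hi = t_max
    if not full_ap(hi):
        return math.inf
    # grow lo to the largest known failure via coarse scan for robustness
    for cand in np.linspace(stim_dur, t_max, 9)[1:-1]:
        if full_ap(cand):
            hi = cand
            break
        lo = cand
    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        if full_ap(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def front_speed(
    series: FieldSeries,
    probe_points: Sequence | None = None,
    level: float = UPSTROKE_LEVEL,
) -> tuple[float, float]:
    """Front speed from upstroke arrival times along a probe path.

    Fits arrival time against arc distance along the probe path (ordered
    points); the speed is the inverse slope.  Returns ``(speed_m_per_s,
    r_squared)`` and warns if R² < 0.95.
    """
    if probe_points is None:
        return front_speed_1d(series, level=level)
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    arrivals = []
    for p in pts:
        trace = series.probe(p)
        arrivals.append(_arrival_time(series.times, trace, level))
    return _fit_speed(np.asarray(arc), np.asarray(arrivals))


def front_speed_1d(
    series: FieldSeries,
    central_frac: float = 0.5,
    level: float = UPSTROKE_LEVEL,
    n_probes: int = 9,
) -> tuple[float, float]:
    """Front speed on a 1D cable from probes over its central portion."""
    x = series.mesh.points[:, 0]
    L = x.max() - x.min()
    lo = x.min() + (0.5 - central_frac / 2) * L
    hi = x.min() + (0.5 + central_frac / 2) * L
    probes = np.linspace(lo, hi, n_probes)
    arrivals, dists = [], []
    for xp in probes:
        i = int(np.argmin(np.abs(x - xp)))
        arrivals.append(_arrival_time(series.times, series.values[:, i], level))
        dists.append(x[i])
    return _fit_speed(np.asarray(dists), np.asarray(arrivals))


def _arrival_time(t: np.ndarray, v: np.ndarray, level: float) -> float:
    idx = np.where((v[:-1] < level) & (v[1:] >= level))[0]
    if idx.size == 0:
        raise ValueError("front never crossed the upstroke level at a probe")
    return _cross_time(t, v, level, int(idx[0]))


def _fit_speed(dist: np.ndarray, arrival: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([dist, np.ones_like(dist)])
    coef, *_ = np.linalg.lstsq(A, arrival, rcond=None)
    slope = coef[0]
    pred = A @ coef
    ss_res = float(((arrival - pred) ** 2).sum())
    ss_tot = float(((arrival - arrival.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.95:
        warnings.warn(f"unreliable front-speed fit (R^2 = {r2:.3f})", stacklevel=2)
    if slope <= 0:
        raise ValueError("non-positive arrival-time slope; no coherent front")
    return 1.0 / slope, r2
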