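"""Post-processing: conduction velocity, spiral-tip tracking, inter-beat
intervals, power spectra, rotation periods and inhomogeneity classification.

The primary tip tracker follows the sodium current: during propagation,
|I_Na| is large only on the thin depolarization front, so the front appears
as a fine line in the I_Na field; the line terminates at the spiral tip
(where wave front and wave back meet).  The reference threshold is taken
operationally as the peak |I_Na| of a just-supra-threshold single-cell AP -
the weakest sodium-current surge that still regenerates an AP.  An
independent cross-check tracker intersects the V = -35 mV isoline with the
dV/dt = 0 contour (the classical isopotential method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .composite import ACTIVATION_THRESHOLD, UPSTROKE_SLOPE, CompositeConfig, run_single_cell
from .params import FibroblastParams, MyocyteParams

__all__ = [
    "CVResult", "TipTrajectory", "BeatSeries",
    "measure_cv", "measure_cv_probes", "sodium_threshold", "track_tip",
    "track_tip_isopotential", "beat_statistics", "rotation_period",
    "classify_inhomogeneity_dynamics",
]


# ---------------------------------------------------------------- conduction

@dataclass
class CVResult:
    cv: float          # cm/s (nan on failure)
    t_first: float     # ms, activation time at the first probe
    t_second: float    # ms, at the second probe
    failed: bool


def _upcross_time(t, v, level):
    idx = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    if len(idx) == 0:
        return math.nan
    k = idx[0]
    f = (level - v[k]) / (v[k + 1] - v[k])
    return t[k] + f * (t[k + 1] - t[k])


def measure_cv_probes(t: np.ndarray, v1: np.ndarray, v2: np.ndarray,
                      distance_mm: float,
                      threshold: float = ACTIVATION_THRESHOLD,
                      cv_bounds=(3.0, 200.0)) -> CVResult:
    """CV from two probe traces separated by distance_mm along the wave.

    Failure covers both a front that never reaches the far probe and
    threshold crossings that do not correspond to a propagating front (a
    tonically depolarizing substrate crosses the threshold near-
    simultaneously everywhere, implying an unphysiological velocity);
    cv_bounds are the plausibility limits in cm/s.
    """
    t1 = _upcross_time(t, v1, threshold)
    t2 = _upcross_time(t, v2, threshold)
    if math.isnan(t1) or math.isnan(t2) or t2 <= t1:
        return CVResult(math.nan, t1, t2, True)
    cv = distance_mm / (t2 - t1) * 100.0
    if not cv_bounds[0] <= cv <= cv_bounds[1]:
        return CVResult(cv, t1, t2, True)
    return CVResult(cv, t1, t2, False)


def measure_cv(t_snap: np.ndarray, vm_stack: np.ndarray, dx: float,
               row: int | None = None, fractions=(0.25, 0.75),
               threshold: float = ACTIVATION_THRESHOLD) -> CVResult:
    """CV of a planar wave travelling along +x, from field snapshots.

    Activation times are the threshold upward-crossing times (linear
    interpolation between frames) at two midline probes placed at the given
    fractions of the domain length.
    """
    n, ny, nx = vm_stack.shape
    row = ny // 2 if row is None else row
    j1, j2 = (int(f * nx) for f in fractions)
    v1 = vm_stack[:, row, j1].astype(float)
    v2 = vm_stack[:, row, j2].astype(float)
    return measure_cv_probes(np.asarray(t_snap, float), v1, v2,
                             (j2 - j1) * dx, threshold)


# ------------------------------------------------------------- tip tracking

_THRESH_CACHE: dict = {}


def sodium_threshold_single_cell(myo: MyocyteParams | None = None,
                                 stim_duration: float = 3.0) -> float:
    """Peak |I_Na| (pA/pF) of the weakest single-cell stimulus (bisected to
    1%) that still elicits an AP - the weakest regenerative sodium surge."""
    myo = myo or MyocyteParams()
    key = ("cell", myo, stim_duration)
    if key in _THRESH_CACHE:
        return _THRESH_CACHE[key]

    def fires(amp):
        cfg = CompositeConfig(N_f=0, stimulus=((50.0, stim_duration, -amp),),
                              myo=myo)
        r = run_single_cell(cfg, t_end=250.0, record_every=5)
        return r.V_m.max() > 0.0

    lo, hi = 0.5, 64.0
    while not fires(hi):
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("no stimulus elicits an AP")
    while hi / lo > 1.01:
        mid = math.sqrt(lo * hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    cfg = CompositeConfig(N_f=0, stimulus=((50.0, stim_duration, -hi),), myo=myo)
    r = run_single_cell(cfg, t_end=250.0, record_currents=True)
    thr = float(np.abs(r.current("I_Na")).max())
    _THRESH_CACHE[key] = thr
    return thr


def sodium_threshold(myo: MyocyteParams | None = None,
                     fraction: float = 0.25) -> float:
    """Reference |I_Na| (pA/pF) for tip tracking.

    Based on the weakest regenerative single-cell sodium surge
    (:func:`sodium_threshold_single_cell`).  Fronts propagating through
    partially recovered tissue - the regime around a reentrant core - peak
    at roughly half the fully recovered value, so the mask threshold is a
    quarter of the reference by default; this keeps the swept front band
    connected while still excluding sub-regenerative sodium activity.
    """
    return fraction * sodium_threshold_single_cell(myo)


@dataclass
class TipTrajectory:
    t: np.ndarray              # ms, one entry per frame
    x: np.ndarray              # mm (nan where no tip)
    y: np.ndarray              # mm
    counts: np.ndarray         # tips found per frame

    def valid(self):
        m = ~np.isnan(self.x)
        return self.t[m], self.x[m], self.y[m]


def _is_free_end(sk: np.ndarray, mask: np.ndarray, i: int, j: int,
                 walk: int = 5, probe: int = 6) -> bool:
    """True if the skeleton endpoint (i, j) is a genuine free end of the
    locus: the mask must be empty ahead of the terminal skeleton direction.
    (The medial axis of a wide band ends inside the band even though the
    band itself continues - e.g. a full-height plane-wave front - and such
    interior endpoints must not be reported as tips.)"""
    ny, nx = sk.shape
    path = [(i, j)]
    seen = {(i, j)}
    ci, cj = i, j
    for _ in range(walk):
        nxt = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = ci + di, cj + dj
                if (di or dj) and 0 <= ii < ny and 0 <= jj < nx \
                        and sk[ii, jj] and (ii, jj) not in seen:
                    nxt = (ii, jj)
                    break
            if nxt:
                break
        if nxt is None:
            break
        seen.add(nxt)
        path.append(nxt)
        ci, cj = nxt
    if len(path) < 3:
        return True  # too short to orient; keep
    vi = i - path[-1][0]
    vj = j - path[-1][1]
    norm = math.hypot(vi, vj)
    if norm == 0:
        return True
    vi, vj = vi / norm, vj / norm
    ahead = 0
    hits = 0
    for s in range(2, 2 + probe):
        ii, jj = int(round(i + vi * s)), int(round(j + vj * s))
        if 0 <= ii < ny and 0 <= jj < nx:
            ahead += 1
            hits += bool(mask[ii, jj])
    return ahead == 0 or hits <= ahead // 3


def _frame_tips(mask: np.ndarray, weight: np.ndarray, dx: float,
                border: int = 3):
    """Endpoints of the thin active locus: skeleton pixels with exactly one
    skeleton neighbor, away from the domain border, refined by a local
    weighted centroid.  Small gaps in the locus are closed and speckle
    components removed before skeletonizing; endpoints closer than 2 nodes
    are merged."""
    from scipy import ndimage as ndi
    from skimage.morphology import skeletonize
    if not mask.any():
        return []
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3), bool))
    lab, nlab = ndi.label(mask)
    if nlab == 0:
        return []
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = sizes[lab] >= 6  # drop speckle components
    if not mask.any():
        return []
    sk = skeletonize(mask)
    nb = np.zeros_like(sk, dtype=np.int16)
    s = sk.astype(np.int16)
    nb[1:-1, 1:-1] = (s[:-2, :-2] + s[:-2, 1:-1] + s[:-2, 2:]
                      + s[1:-1, :-2] + s[1:-1, 2:]
                      + s[2:, :-2] + s[2:, 1:-1] + s[2:, 2:])
    ends = np.argwhere(sk & (nb == 1))
    ny, nx = mask.shape
    tips = []
    for i, j in ends:
        if i < border or j < border or i >= ny - border or j >= nx - border:
            continue
        if not _is_free_end(sk, mask, int(i), int(j)):
            continue
        sl = (slice(max(i - 1, 0), i + 2), slice(max(j - 1, 0), j + 2))
        w = weight[sl]
        tot = w.sum()
        if tot > 0:
            ii, jj = np.mgrid[sl]
            i_c = (ii * w).sum() / tot
            j_c = (jj * w).sum() / tot
        else:
            i_c, j_c = float(i), float(j)
        tips.append((j_c * dx, i_c * dx))  # (x, y) in mm
    # merge near-duplicate endpoints (skeleton spurs)
    merged: list = []
    for p in tips:
        for q in merged:
            if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < (2.0 * dx) ** 2:
                break
        else:
            merged.append(p)
    return merged


def track_tip(t_snap: np.ndarray, ina_stack: np.ndarray, dx: float,
              threshold: float | None = None,
              myo: MyocyteParams | None = None) -> TipTrajectory:
    """Track the spiral tip as the interior endpoint of the |I_Na| locus.

    A plane wave's locus spans the domain (both endpoints on the border), so
    it yields no tip; a quiescent frame yields none either.  When several
    tips are present the one closest to the previous position is reported.
    """
    thr = sodium_threshold(myo) if threshold is None else threshold
    n = len(t_snap)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    ny, nx = np.asarray(ina_stack[0]).shape
    w, h = (nx - 1) * dx, (ny - 1) * dx
    prev = None
    for k in range(n):
        ina = np.abs(np.asarray(ina_stack[k], float))
        tips = _frame_tips(ina >= thr, ina, dx)
        counts[k] = len(tips)
        if not tips:
            continue
        if len(tips) == 1:
            tip = tips[0]
        elif prev is None:
            # no history yet: the genuine tip is the interior-most endpoint
            tip = max(tips, key=lambda p: min(p[0], w - p[0], p[1],
                                              h - p[1]))
        else:
            tip = min(tips, key=lambda p: (p[0] - prev[0]) ** 2
                      + (p[1] - prev[1]) ** 2)
        x[k], y[k] = tip
        prev = tip
    return TipTrajectory(np.asarray(t_snap, float), x, y, counts)


def track_tip_isopotential(t_snap: np.ndarray, vm_stack: np.ndarray,
                           dx: float, v_iso: float = -35.0) -> TipTrajectory:
    """Cross-check tracker: tip = intersection of the V = v_iso isoline with
    the dV/dt = 0 contour (estimated from consecutive frames)."""
    from skimage import measure as _meas
    n = len(t_snap)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    prev = None
    for k in range(n - 1):
        a = np.asarray(vm_stack[k], float)
        b = np.asarray(vm_stack[k + 1], float)
        c1 = _meas.find_contours(a, v_iso)
        c2 = _meas.find_contours(b - a, 0.0)
        if not c1 or not c2:
            continue
        p1 = np.vstack(c1)
        p2 = np.vstack(c2)
        # nearest approach of the two contour sets
        d2 = ((p1[:, None, :] - p2[None, :, :]) ** 2).sum(-1)
        i1, i2 = np.unravel_index(np.argmin(d2), d2.shape)
        if d2[i1, i2] > 4.0:  # no genuine intersection (> 2 nodes apart)
            continue
        pt = 0.5 * (p1[i1] + p2[i2])  # (row, col)
        counts[k] = 1
        x[k], y[k] = pt[1] * dx, pt[0] * dx
        prev = (x[k], y[k])
    return TipTrajectory(np.asarray(t_snap, float), x, y, counts)


# ------------------------------------------------------- beats and spectra

@dataclass
class BeatSeries:
    upstrokes: np.ndarray      # ms
    ibi: np.ndarray            # ms
    freq: np.ndarray           # Hz
    power: np.ndarray          # periodogram of the mean-removed series

    @property
    def peak_frequency(self) -> float:
        """Frequency (Hz) of the dominant non-zero spectral line."""
        if len(self.freq) < 2:
            return math.nan
        k = 1 + int(np.argmax(self.power[1:]))
        return float(self.freq[k])

    @property
    def mean_ibi(self) -> float:
        return float(np.mean(self.ibi)) if len(self.ibi) else math.nan

    @property
    def ibi_cov(self) -> float:
        """Coefficient of variation of the inter-beat intervals."""
        if len(self.ibi) < 2:
            return math.nan
        return float(np.std(self.ibi) / np.mean(self.ibi))


def beat_statistics(v: np.ndarray, dt_sample: float,
                    threshold: float = ACTIVATION_THRESHOLD,
                    min_slope: float = UPSTROKE_SLOPE) -> BeatSeries:
    """Upstroke times, inter-beat intervals and the plain periodogram.

    Upstrokes are upward crossings of `threshold` with dV/dt > `min_slope`;
    the spectrum is the magnitude-squared DFT of the mean-removed series
    (frequency resolution 1 / (N dt_sample)).
    """
    v = np.asarray(v, float)
    dvdt = np.diff(v) / dt_sample
    idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold)
                     & (dvdt > min_slope))[0]
    ups = idx * dt_sample
    ibi = np.diff(ups)
    n = v.size
    spec = np.abs(np.fft.rfft(v - v.mean())) ** 2
    freq = np.fft.rfftfreq(n, d=dt_sample * 1e-3)  # Hz
    return BeatSeries(ups, ibi, freq, spec)


def rotation_period(source, dt_sample: float | None = None) -> tuple:
    """Spiral rotation period, ms: (mean, spread).

    From a BeatSeries (probe far from the core): mean and std of the ibi.
    From a TipTrajectory: per-revolution times of the unwrapped tip angle
    about the trajectory centroid.
    """
    if isinstance(source, BeatSeries):
        if len(source.ibi) == 0:
            return math.nan, math.nan
        return float(np.mean(source.ibi)), float(np.std(source.ibi))
    if isinstance(source, TipTrajectory):
        t, x, y = source.valid()
        if len(t) < 8:
            return math.nan, math.nan
        ang = np.unwrap(np.arctan2(y - y.mean(), x - x.mean()))
        total = abs(ang[-1] - ang[0]) / (2.0 * math.pi)
        if total < 1.0:
            return math.nan, math.nan
        period = (t[-1] - t[0]) / total
        # spread: std of per-revolution durations (monotonized angle)
        a = ang if ang[-1] > ang[0] else -ang
        a = np.maximum.accumulate(a)
        revs = np.arange(math.ceil(a[0] / (2 * math.pi)),
                         a[-1] / (2 * math.pi)) * 2 * math.pi
        if len(revs) >= 3:
            tr = np.interp(revs, a, t)
            spread = float(np.std(np.diff(tr)))
        else:
            spread = math.nan
        return float(period), spread
    raise TypeError("source must be a BeatSeries or TipTrajectory")


def classify_inhomogeneity_dynamics(probe_inside: BeatSeries,
                                    probe_outside: BeatSeries,
                                    tip: TipTrajectory | None = None,
                                    patch_bbox: tuple | None = None,
                                    cov_limit: float = 0.05) -> dict:
    """Periodicity inside/outside an inhomogeneity, plus anchoring.

    A probe is periodic when its ibi coefficient of variation is below
    cov_limit and its spectrum is dominated by a single line (the peak bin
    and its immediate neighbors hold most of the non-DC power).  The spiral
    is anchored when the tip-trajectory centroid lies within the patch
    bounding box (x0, y0, x1, y1 in mm).
    """
    def periodic(bs: BeatSeries) -> bool:
        if len(bs.ibi) < 2 or bs.ibi_cov >= cov_limit:
            return False
        p = bs.power[1:]
        if p.sum() <= 0:
            return False
        k = int(np.argmax(p))
        window = p[max(k - 2, 0):k + 3].sum()
        return bool(window / p.sum() > 0.3)

    out = {
        "inside": "periodic" if periodic(probe_inside) else "nonperiodic",
        "outside": "periodic" if periodic(probe_outside) else "nonperiodic",
        "anchored": False,
    }
    if tip is not None and patch_bbox is not None:
        t, x, y = tip.valid()
        if len(x):
            x0, y0, x1, y1 = patch_bbox
            out["anchored"] = bool(x0 <= x.mean() <= x1
                                   and y0 <= y.mean() <= y1)
    return out
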