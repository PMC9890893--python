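"""Field-potential feature extraction for hippocampal slice recordings.

Evoked field excitatory post-synaptic potentials (fEPSPs) recorded in CA1
stratum radiatum are reduced to the standard quantities: the initial slope
of the fEPSP (measured over the first 1 ms of its descending domain), the
fiber-volley amplitude, input-output (I/O) curves of slope versus fiber
volley, paired-pulse facilitation (PPF) ratios over a 20-400 ms interval
schedule, and the minute-binned long-term potentiation (LTP) profile
normalized to the pre-tetanus baseline.

Slope convention: fEPSP slopes are stored signed (negative for the usual
downward deflection); every ratio, I/O point and LTP normalization uses the
magnitude.

Descending-domain detection
---------------------------
The descending domain runs from the local maximum preceding the fEPSP
trough down to the trough. On noisy traces the raw local maximum is a
fragile landmark, so the onset is located on a Savitzky-Golay-smoothed
copy of the trace: the trough is the smoothed minimum inside the search
window, the steepest descent is the minimum of the smoothed derivative
before the trough, and the domain start is the last point before the
steepest descent at which the decline first reaches a fraction
(``onset_frac``, default 0.6) of that steepest rate. The slope itself is
the least-squares line over the first 1 ms of raw samples from that start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.signal import savgol_filter

from . import groupstats

__all__ = [
    "Sweep",
    "SweepFeatures",
    "IOCurve",
    "PPFProfile",
    "LTPProfile",
    "EphysSession",
    "StimulusChoice",
    "NoResponseError",
    "extract_sweep_features",
    "build_io_curve",
    "select_test_stimulus",
    "ppf_profile",
    "ltp_profile",
    "read_sweep_csv",
    "load_session",
]

PPF_SCHEDULE_MS = tuple(range(20, 401, 20))


class NoResponseError(ValueError):
    """The trace contains no measurable descending fEPSP."""


@dataclass
class Sweep:
    """One evoked trace on a uniform time grid (ms / mV)."""

    time_ms: np.ndarray
    voltage_mV: np.ndarray
    stim_onset_ms: float
    stim_level: float = np.nan
    epoch: str = ""  # io | baseline | ppf | post_tbs
    slice_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.voltage_mV.shape:
            raise ValueError("time and voltage must be 1-D arrays of equal length")
        steps = np.diff(self.time_ms)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.voltage_mV)):
            raise ValueError("voltage must be finite")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class SweepFeatures:
    fv_amplitude_mV: float
    fepsp_slope_mV_per_ms: float  # signed; negative for downward fEPSP
    slope_window: tuple  # (start_ms, end_ms), end - start = 1 ms
    fepsp_amplitude_mV: float = np.nan  # trough depth below pre-stim baseline

    @property
    def slope_magnitude(self) -> float:
        return abs(self.fepsp_slope_mV_per_ms)


@dataclass
class IOCurve:
    fv_amplitude: np.ndarray  # sorted ascending
    slope_magnitude: np.ndarray
    fit_slope: float
    fit_intercept: float
    r2: float

    @property
    def points(self):
        return list(zip(self.fv_amplitude, self.slope_magnitude))


@dataclass
class PPFProfile:
    intervals_ms: np.ndarray  # ascending
    ratios: np.ndarray  # |slope2| / |slope1|


@dataclass
class LTPProfile:
    minutes: np.ndarray  # [-n_baseline .. -1, 1 .. n_post]
    percent_of_baseline: np.ndarray
    last5_mean: float


@dataclass
class EphysSession:
    """Sweeps with session timestamps in minutes relative to the TBS at 0."""

    sweeps: list
    minutes: np.ndarray  # session time of each sweep, minutes; <0 baseline
    tbs_minute: float = 0.0

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if len(self.sweeps) != self.minutes.size:
            raise ValueError("one timestamp per sweep required")


@dataclass
class StimulusChoice:
    stim_level: float
    amplitude_mV: float
    flagged: bool
    reason: str = ""


def _smooth(v: np.ndarray, dt_ms: float, smooth_ms: float) -> np.ndarray:
    win = max(5, int(round(smooth_ms / dt_ms)) | 1)
    if win >= v.size:
        win = (v.size - 1) | 1
    if win < 5:
        return v.copy()
    return savgol_filter(v, win, polyorder=2)


def extract_sweep_features(
    sweep: Sweep,
    fv_window_ms: tuple = (0.8, 3.2),
    fepsp_search_window_ms: tuple | None = None,
    *,
    blank_ms: float = 1.0,
    smooth_ms: float = 0.3,
    deriv_smooth_ms: float = 0.5,
    onset_frac: float = 0.6,
    slope_span_ms: float = 1.0,
) -> SweepFeatures:
    """Measure fiber-volley amplitude and initial fEPSP slope of one sweep.

    Windows are in ms relative to the stimulus onset. ``fv_window_ms``
    brackets the fiber volley; ``fepsp_search_window_ms`` brackets the
    fEPSP trough search (default: from the end of the fiber-volley window
    to the end of the trace). The first ``blank_ms`` after the stimulus is
    blanked as artifact.
    """
    t, v = sweep.time_ms, sweep.voltage_mV
    dt = sweep.dt_ms
    on = sweep.stim_onset_ms
    if fepsp_search_window_ms is None:
        fepsp_search_window_ms = (fv_window_ms[1], t[-1] - on)
    lo, hi = (on + w for w in fepsp_search_window_ms)
    lo = max(lo, on + blank_ms)
    if not (t[0] <= lo < hi <= t[-1] + dt / 2):
        raise ValueError("fEPSP search window must lie within the trace, after blanking")

    base_mask = t < on
    baseline = float(v[base_mask].mean()) if base_mask.any() else 0.0

    vs = _smooth(v, dt, smooth_ms)
    search = (t >= lo) & (t <= hi)
    idx_search = np.nonzero(search)[0]
    trough = idx_search[np.argmin(vs[idx_search])]

    # steepest descent from a wider Savitzky-Golay derivative (landmark only)
    dwin = max(7, int(round(deriv_smooth_ms / dt)) | 1)
    if dwin >= v.size:
        dwin = (v.size - 1) | 1
    dvs = savgol_filter(v, dwin, polyorder=2, deriv=1, delta=dt)
    pre = idx_search[idx_search <= trough]
    if pre.size < 3:
        raise NoResponseError("search window holds too few points before the trough")
    steep = pre[np.argmin(dvs[pre])]
    d_steep = dvs[steep]
    depth = baseline - vs[trough]
    if d_steep >= 0 or depth < max(1e-9, 4.0 * _noise_scale(v, base_mask)):
        raise NoResponseError("no descending fEPSP found in the search window")

    # domain start: last point before the steepest descent where the decline
    # first reaches onset_frac of the steepest rate
    i = steep
    lo_i = idx_search[0]
    while i > lo_i and dvs[i - 1] <= onset_frac * d_steep:
        i -= 1
    start = i

    n_span = int(round(slope_span_ms / dt))
    if n_span < 2:
        raise ValueError("slope window shorter than 2 samples; decrease dt")
    if trough - start < n_span:
        raise NoResponseError(
            f"descending segment shorter than {slope_span_ms} ms "
            f"({(trough - start) * dt:.3g} ms from domain start to trough)"
        )
    seg_t = t[start:start + n_span + 1]
    seg_v = v[start:start + n_span + 1]
    slope = float(stats.linregress(seg_t, seg_v).slope)

    # fiber volley: smoothed trough depth inside the FV window
    fv_lo, fv_hi = (on + w for w in fv_window_ms)
    fv_mask = (t >= fv_lo) & (t <= fv_hi)
    if fv_mask.any():
        fv_amp = max(0.0, baseline - float(vs[fv_mask].min()))
    else:
        fv_amp = np.nan
    return SweepFeatures(
        fv_amplitude_mV=fv_amp,
        fepsp_slope_mV_per_ms=slope,
        slope_window=(float(seg_t[0]), float(seg_t[0] + slope_span_ms)),
        fepsp_amplitude_mV=float(depth),
    )


def _noise_scale(v: np.ndarray, base_mask: np.ndarray) -> float:
    """Robust noise scale from the pre-stimulus segment (0 if unavailable)."""
    if base_mask.sum() < 4:
        return 0.0
    d = np.diff(v[base_mask])
    return float(np.median(np.abs(d)) / 0.6745 / np.sqrt(2)) if d.size else 0.0


def build_io_curve(features) -> IOCurve:
    """I/O curve: |fEPSP slope| versus fiber-volley amplitude with a line fit."""
    feats = list(features)
    if len(feats) < 3:
        raise ValueError("an I/O curve needs at least 3 valid sweeps")
    fv = np.array([f.fv_amplitude_mV for f in feats])
    sl = np.array([f.slope_magnitude for f in feats])
    order = np.argsort(fv, kind="stable")
    fv, sl = fv[order], sl[order]
    res = stats.linregress(fv, sl)
    r2 = float(res.rvalue**2) if np.ptp(sl) > 0 else 1.0
    return IOCurve(fv, sl, float(res.slope), float(res.intercept), r2)


def select_test_stimulus(
    io_sweeps,
    frac_lo: float = 0.50,
    frac_hi: float = 0.60,
    **feature_kwargs,
) -> StimulusChoice:
    """Pick the stimulus producing 50-60% of the maximal fEPSP amplitude.

    Returns the smallest stimulus level whose amplitude falls inside
    ``[frac_lo, frac_hi]`` of the maximum; if none does, the level whose
    amplitude is closest to the band midpoint, flagged.
    """
    levels, amps = [], []
    for sw in io_sweeps:
        try:
            f = extract_sweep_features(sw, **feature_kwargs)
        except NoResponseError:
            continue
        levels.append(sw.stim_level)
        amps.append(f.fepsp_amplitude_mV)
    if not levels:
        raise NoResponseError("all I/O sweeps are no-response")
    levels = np.asarray(levels, float)
    amps = np.asarray(amps, float)
    amax = amps.max()
    tol = 1e-9 * amax  # keep exact band-edge amplitudes inside (float safety)
    in_band = (amps >= frac_lo * amax - tol) & (amps <= frac_hi * amax + tol)
    if in_band.any():
        k = np.nonzero(in_band)[0][np.argmin(levels[in_band])]
        flagged = len(levels) == 1
        return StimulusChoice(float(levels[k]), float(amps[k]), flagged,
                              "single sweep" if flagged else "")
    mid = (frac_lo + frac_hi) / 2.0
    k = int(np.argmin(np.abs(amps - mid * amax)))
    return StimulusChoice(float(levels[k]), float(amps[k]), True,
                          f"no amplitude inside [{frac_lo}, {frac_hi}] x max; "
                          "closest to band midpoint chosen")


def ppf_profile(pairs, **feature_kwargs) -> PPFProfile:
    """Paired-pulse facilitation: |slope2|/|slope1| per inter-pulse interval.

    ``pairs`` is an iterable of ``(sweep1, sweep2, interval_ms)``.
    """
    intervals, ratios = [], []
    for sw1, sw2, interval in pairs:
        f1 = extract_sweep_features(sw1, **feature_kwargs)
        f2 = extract_sweep_features(sw2, **feature_kwargs)
        if f1.slope_magnitude == 0:
            raise ZeroDivisionError(
                f"first fEPSP slope is zero at interval {interval} ms; PPF undefined"
            )
        intervals.append(float(interval))
        ratios.append(f2.slope_magnitude / f1.slope_magnitude)
    if not intervals:
        raise ValueError("no sweep pairs supplied")
    order = np.argsort(intervals)
    return PPFProfile(np.asarray(intervals)[order], np.asarray(ratios)[order])


def ltp_profile(session: EphysSession, **feature_kwargs) -> LTPProfile:
    """Minute-binned LTP profile normalized to the baseline mean (=100%).

    Each sweep is assigned to the minute bin ending at the next integer
    minute relative to the TBS marker (t in (m-1, m] -> minute m for post,
    t in [m, m+1) -> minute m for baseline). The per-minute mean |slope| is
    divided by the mean over baseline minutes; ``last5_mean`` averages the
    last five post-TBS minutes present.
    """
    rel = session.minutes - session.tbs_minute
    slopes = np.array([
        extract_sweep_features(sw, **feature_kwargs).slope_magnitude
        for sw in session.sweeps
    ])
    minute_label = np.where(rel > 0, np.floor(rel) + 1, np.floor(rel)).astype(int)
    labels = np.unique(minute_label)
    labels = labels[labels != 0]
    base_labels = labels[labels < 0]
    post_labels = labels[labels > 0]
    if base_labels.size < 1 or post_labels.size < 5:
        raise ValueError("need at least 1 baseline minute and 5 post-TBS minutes")
    per_minute = np.array([slopes[minute_label == m].mean() for m in labels])
    base_mean = per_minute[np.isin(labels, base_labels)].mean()
    if base_mean == 0:
        raise ZeroDivisionError("baseline mean slope is zero; cannot normalize")
    pct = per_minute / base_mean * 100.0
    last5 = float(pct[np.isin(labels, post_labels[-5:])].mean())
    return LTPProfile(labels, pct, last5)


def compare_io_slopes(curve_a: IOCurve, curve_b: IOCurve):
    """ANCOVA slope comparison of two I/O curves (group-by-x interaction F)."""
    pa = np.column_stack([curve_a.fv_amplitude, curve_a.slope_magnitude])
    pb = np.column_stack([curve_b.fv_amplitude, curve_b.slope_magnitude])
    return groupstats.ancova_slopes(pa, pb)


# ---------------------------------------------------------------------------
# file readers


def read_sweep_csv(path, *, stim_onset_ms, **meta) -> Sweep:
    """Read one sweep from a two-column CSV (time_ms, voltage_mV)."""
    df = pd.read_csv(path)
    if not {"time_ms", "voltage_mV"}.issubset(df.columns):
        raise ValueError("sweep CSV must have columns time_ms, voltage_mV")
    return Sweep(df["time_ms"].to_numpy(), df["voltage_mV"].to_numpy(),
                 stim_onset_ms=stim_onset_ms, **meta)


def load_session(manifest_path):
    """Load sweeps listed in a session manifest (YAML).

    The manifest maps sweep files to their role::

        stim_onset_ms: 2.0
        sweeps:
          - {file: sw_001.csv, epoch: baseline, minute: -20.5, stim_level: 4.0}
          - {file: sw_200.csv, epoch: post_tbs, minute: 12.5, stim_level: 4.0}

    Paths are relative to the manifest. Returns a dict with ``sweeps`` (all
    sweeps, each annotated), and ``session`` (an :class:`EphysSession` over
    the baseline/post_tbs sweeps) when LTP epochs are present.
    """
    import pathlib

    mpath = pathlib.Path(manifest_path)
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    onset = float(manifest["stim_onset_ms"])
    records = []
    for entry in manifest["sweeps"]:
        sw = read_sweep_csv(mpath.parent / entry["file"], stim_onset_ms=onset,
                            epoch=entry.get("epoch", ""),
                            stim_level=float(entry.get("stim_level", np.nan)))
        records.append((sw, entry))
    out = {"sweeps": [sw for sw, _ in records]}
    ltp = [(sw, float(e["minute"])) for sw, e in records
           if e.get("epoch") in ("baseline", "post_tbs")]
    if ltp:
        out["session"] = EphysSession([sw for sw, _ in ltp],
                                      np.array([m for _, m in ltp]))
    return out
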