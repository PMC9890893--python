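"""Synthetic data with planted ground truth for every analysis modality.

Each generator emulates one input modality of the study — evoked field
potentials, hourly microdialysis fractions, stained-section image planes,
PRM peak-area manifests, and RNA-seq count matrices — with the parameters
of interest planted exactly, so the downstream analysis modules can be
validated against known truth without any recorded data.

Every generator returns ``(data, GroundTruth)``; identical seed and
parameters give byte-identical output (all randomness flows through one
``numpy.random.default_rng(seed)``).

fEPSP waveform parameterization
-------------------------------
A sweep is baseline + stimulus artifact (a short biphasic deflection at
the stimulus onset) + fiber volley (a narrow Gaussian trough) + synaptic
fEPSP + optional Gaussian sensor noise. The synaptic component descends
linearly at exactly the planted slope for 1.6 ms, rounds into the trough
over a half-cosine, and recovers exponentially; the linear segment is
deliberately longer than the 1 ms measurement window so the planted slope
is the exact steepest-1-ms regression slope of the noise-free trace.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ephys import PPF_SCHEDULE_MS, EphysSession, Sweep
from .clearance import DialysateSeries
from .assayquant import DEFAULT_SPIKE_FMOL, PeptideMeasurement
from .histoquant import ImagePlane, RoiMask
from .transcript import CountMatrix

__all__ = [
    "GroundTruth",
    "gen_fepsp_sweep",
    "gen_ltp_session",
    "gen_ppf_session",
    "gen_dialysis_series",
    "gen_scene",
    "gen_prm_run",
    "gen_counts",
    "write_sweep_csv",
    "write_dialysis_csv",
    "write_scene",
    "write_prm_csv",
    "write_counts",
    "write_ground_truth",
]

# fEPSP geometry (ms, relative to the stimulus onset unless noted)
STIM_ONSET_MS = 2.0
ARTIFACT_SPAN_MS = 0.2
ARTIFACT_AMP_MV = 1.0
FV_DELAY_MS = 2.0
FV_SD_MS = 0.35
SYN_DELAY_MS = 4.0
SYN_LINEAR_MS = 1.6
SYN_ROUND_MS = 1.0
SYN_RECOVERY_TAU_MS = 3.0
SWEEP_DURATION_MS = 18.0


@dataclass
class GroundTruth:
    """The planted parameters behind one generated dataset."""

    modality: str
    params: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# electrophysiology


def _fepsp_component(u: np.ndarray, slope_mag: float) -> np.ndarray:
    """Synaptic deflection: linear descent at ``slope_mag``, half-cosine
    rounding into the trough, exponential recovery. ``u`` is time since
    fEPSP onset (ms)."""
    v = np.zeros_like(u)
    lin = (u >= 0) & (u < SYN_LINEAR_MS)
    v[lin] = -slope_mag * u[lin]
    w = u - SYN_LINEAR_MS
    rnd = (w >= 0) & (w < SYN_ROUND_MS)
    v[rnd] = -slope_mag * SYN_LINEAR_MS - slope_mag * 0.5 * (
        w[rnd] + np.sin(np.pi * w[rnd] / SYN_ROUND_MS) * SYN_ROUND_MS / np.pi
    )
    depth = slope_mag * (SYN_LINEAR_MS + 0.5 * SYN_ROUND_MS)
    rec = w >= SYN_ROUND_MS
    v[rec] = -depth * np.exp(-(w[rec] - SYN_ROUND_MS) / SYN_RECOVERY_TAU_MS)
    return v


def _sweep_voltage(t: np.ndarray, slope_mag: float, fv_amplitude_mV: float) -> np.ndarray:
    u = t - STIM_ONSET_MS
    v = np.zeros_like(t)
    art = (u >= 0) & (u < ARTIFACT_SPAN_MS)
    v[art] = ARTIFACT_AMP_MV * np.sin(2 * np.pi * u[art] / ARTIFACT_SPAN_MS)
    v -= fv_amplitude_mV * np.exp(-0.5 * ((u - FV_DELAY_MS) / FV_SD_MS) ** 2)
    v += _fepsp_component(u - SYN_DELAY_MS, slope_mag)
    return v


def gen_fepsp_sweep(
    slope_mV_per_ms: float,
    fv_amplitude_mV: float = 0.3,
    noise_sd_mV: float = 0.0,
    dt_ms: float = 0.05,
    seed: int = 0,
    *,
    duration_ms: float = SWEEP_DURATION_MS,
    stim_level: float = np.nan,
    epoch: str = "",
    rng=None,
) -> tuple:
    """One evoked sweep whose steepest 1 ms descent has the planted slope.

    ``slope_mV_per_ms`` is the signed planted slope (negative = downward
    fEPSP, the usual case; the magnitude is planted either way).
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if noise_sd_mV < 0:
        raise ValueError("noise_sd_mV must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    v = _sweep_voltage(t, abs(slope_mV_per_ms), fv_amplitude_mV)
    if noise_sd_mV > 0:
        v = v + rng.normal(0.0, noise_sd_mV, size=t.size)
    sweep = Sweep(t, v, stim_onset_ms=STIM_ONSET_MS, stim_level=stim_level, epoch=epoch)
    gt = GroundTruth("fepsp_sweep", {
        "slope_mV_per_ms": -abs(slope_mV_per_ms),
        "fv_amplitude_mV": fv_amplitude_mV,
        "noise_sd_mV": noise_sd_mV,
        "dt_ms": dt_ms,
        "geometry": {
            "stim_onset_ms": STIM_ONSET_MS, "fv_delay_ms": FV_DELAY_MS,
            "syn_delay_ms": SYN_DELAY_MS, "linear_ms": SYN_LINEAR_MS,
        },
    }, seed)
    return sweep, gt


def gen_ltp_session(
    baseline_slope: float,
    potentiation_factor: float,
    n_baseline_min: int = 20,
    n_post_min: int = 60,
    sweeps_per_min: int = 3,
    noise: float = 0.0,
    seed: int = 0,
    *,
    trace_noise_mV: float = 0.0,
    dt_ms: float = 0.05,
) -> tuple:
    """A baseline + post-TBS session; post slopes = baseline x factor.

    ``noise`` is the fractional sweep-to-sweep variability of the planted
    slope (multiplicative Gaussian); the TBS marker sits at minute 0.
    """
    if potentiation_factor <= 0:
        raise ValueError("potentiation_factor must be positive")
    if min(n_baseline_min, n_post_min, sweeps_per_min) < 1:
        raise ValueError("minute and sweep counts must be positive")
    rng = np.random.default_rng(seed)
    sweeps, minutes, true_slopes = [], [], []
    offsets = (np.arange(sweeps_per_min) + 0.5) / sweeps_per_min
    for m in list(range(-n_baseline_min, 0)) + list(range(1, n_post_min + 1)):
        target = abs(baseline_slope) * (potentiation_factor if m > 0 else 1.0)
        for off in offsets:
            s = target * max(0.1, 1.0 + rng.normal(0.0, noise)) if noise > 0 else target
            sw, _ = gen_fepsp_sweep(-s, noise_sd_mV=trace_noise_mV, dt_ms=dt_ms,
                                    epoch="post_tbs" if m > 0 else "baseline", rng=rng)
            sweeps.append(sw)
            minutes.append((m - 1) + off if m > 0 else m + off)
            true_slopes.append(-s)
    session = EphysSession(sweeps, np.array(minutes))
    gt = GroundTruth("ltp_session", {
        "baseline_slope": -abs(baseline_slope),
        "potentiation_factor": potentiation_factor,
        "n_baseline_min": n_baseline_min, "n_post_min": n_post_min,
        "sweeps_per_min": sweeps_per_min, "noise": noise,
        "true_slopes": np.array(true_slopes),
    }, seed)
    return session, gt


def gen_ppf_session(
    first_slope: float,
    facilitation_curve,
    intervals_ms=None,
    noise: float = 0.0,
    seed: int = 0,
    *,
    trace_noise_mV: float = 0.0,
    dt_ms: float = 0.05,
) -> tuple:
    """Paired sweeps per inter-pulse interval; second slope = first x curve.

    ``facilitation_curve`` is a callable interval -> factor or a mapping.
    """
    if intervals_ms is None:
        intervals_ms = PPF_SCHEDULE_MS
    intervals_ms = list(intervals_ms)
    if not intervals_ms:
        raise ValueError("interval list is empty")
    fac = (facilitation_curve if callable(facilitation_curve)
           else lambda i: facilitation_curve[i])
    rng = np.random.default_rng(seed)
    pairs, truth = [], []
    for interval in intervals_ms:
        f = float(fac(interval))
        s1 = abs(first_slope) * (max(0.1, 1.0 + rng.normal(0.0, noise)) if noise > 0 else 1.0)
        s2 = abs(first_slope) * f * (max(0.1, 1.0 + rng.normal(0.0, noise)) if noise > 0 else 1.0)
        sw1, _ = gen_fepsp_sweep(-s1, noise_sd_mV=trace_noise_mV, dt_ms=dt_ms,
                                 epoch="ppf", rng=rng)
        sw2, _ = gen_fepsp_sweep(-s2, noise_sd_mV=trace_noise_mV, dt_ms=dt_ms,
                                 epoch="ppf", rng=rng)
        pairs.append((sw1, sw2, interval))
        truth.append(f)
    gt = GroundTruth("ppf_session", {
        "first_slope": -abs(first_slope),
        "facilitation": dict(zip(intervals_ms, truth)),
        "noise": noise,
    }, seed)
    return pairs, gt


# ---------------------------------------------------------------------------
# microdialysis


def gen_dialysis_series(
    baseline_conc: float,
    Ke_per_h: float,
    n_baseline_h: int = 10,
    n_post_h: int = 4,
    noise_cv: float = 0.0,
    seed: int = 0,
    animal_id: str = "",
) -> tuple:
    """Hourly dialysate fractions: flat baseline, then first-order decay.

    Post-dose concentration at t hours is ``baseline * exp(-Ke * t)``
    (equivalently ``baseline * 10**(-Ke*t/ln 10)``). Noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``
    and mean 1, so concentrations stay positive for the semi-log fit.
    """
    if baseline_conc <= 0 or Ke_per_h <= 0:
        raise ValueError("baseline_conc and Ke_per_h must be positive")
    rng = np.random.default_rng(seed)
    t = np.concatenate([np.arange(-n_baseline_h, 0), np.arange(1, n_post_h + 1)]).astype(float)
    conc = np.where(t < 0, baseline_conc, baseline_conc * np.exp(-Ke_per_h * np.maximum(t, 0)))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        conc = conc * np.exp(rng.normal(-sigma**2 / 2, sigma, size=t.size))
    series = DialysateSeries(t, conc, animal_id=animal_id)
    gt = GroundTruth("dialysis_series", {
        "baseline_conc": baseline_conc, "Ke_per_h": Ke_per_h,
        "half_life_h": np.log(2) / Ke_per_h,
        "n_baseline_h": n_baseline_h, "n_post_h": n_post_h,
        "noise_cv": noise_cv, "noise_model": "lognormal, mean 1",
    }, seed)
    return series, gt


# ---------------------------------------------------------------------------
# imaging


def _draw_disk(img: np.ndarray, cx_px: float, cy_px: float, r_px: float,
               intensity: float) -> None:
    """Anti-aliased disk: edge coverage ramps linearly over one pixel."""
    y0 = max(0, int(np.floor(cy_px - r_px - 2)))
    y1 = min(img.shape[0], int(np.ceil(cy_px + r_px + 2)) + 1)
    x0 = max(0, int(np.floor(cx_px - r_px - 2)))
    x1 = min(img.shape[1], int(np.ceil(cx_px + r_px + 2)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx_px, yy - cy_px)
    cov = np.clip(0.5 + (r_px - d), 0.0, 1.0)
    np.maximum(img[y0:y1, x0:x1], intensity * cov, out=img[y0:y1, x0:x1])


def _draw_segment(img: np.ndarray, p0_px, p1_px, half_width_px: float,
                  intensity: float) -> None:
    """Anti-aliased capsule (thick segment)."""
    (x0, y0), (x1, y1) = p0_px, p1_px
    pad = half_width_px + 2
    ya = max(0, int(np.floor(min(y0, y1) - pad)))
    yb = min(img.shape[0], int(np.ceil(max(y0, y1) + pad)) + 1)
    xa = max(0, int(np.floor(min(x0, x1) - pad)))
    xb = min(img.shape[1], int(np.ceil(max(x0, x1) + pad)) + 1)
    if ya >= yb or xa >= xb:
        return
    yy, xx = np.mgrid[ya:yb, xa:xb]
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / L2, 0.0, 1.0)
    d = np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy))
    cov = np.clip(0.5 + (half_width_px - d), 0.0, 1.0)
    np.maximum(img[ya:yb, xa:xb], intensity * cov, out=img[ya:yb, xa:xb])


def gen_scene(
    roi_size_um: float,
    pixel_size_um: float,
    plaques=(),
    microglia=(),
    background: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    *,
    soma_intensity: float = 1.0,
    branch_intensity: float = 0.4,
    branch_half_width_um: float = 0.8,
) -> tuple:
    """Render a multi-channel scene with planted plaques and microglia.

    ``plaques``: dicts with ``center_um`` (x, y), ``diameter_um`` and
    optional ``intensity`` (default 1). ``microglia``: dicts with
    ``soma_center_um``, ``soma_diameter_um`` and ``branches`` (list of
    polylines, each a list of (x, y) um points; by convention branches
    start at the soma center). Objects are drawn as anti-aliased intensity
    profiles on a ``plaque`` and a ``microglia`` channel; Gaussian noise of
    standard deviation ``noise`` is added on top of ``background``.

    Ground truth records per-object geometry in physical um: plaque
    centers/diameters/areas, per-cell branch count, junction count (branch
    endpoints shared by 3+ branches) and total branch length, pairwise
    plaque-soma centroid distances, and overlap flags.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    n_px = int(round(roi_size_um / pixel_size_um))
    shape = (n_px, n_px)
    for obj in list(plaques):
        cx, cy = obj["center_um"]
        r = obj["diameter_um"] / 2
        if not (0 <= cx - r and cx + r <= roi_size_um and 0 <= cy - r and cy + r <= roi_size_um):
            raise ValueError(f"plaque at ({cx}, {cy}) um extends outside the ROI")
    for mg in list(microglia):
        cx, cy = mg["soma_center_um"]
        if not (0 <= cx <= roi_size_um and 0 <= cy <= roi_size_um):
            raise ValueError(f"microglion soma at ({cx}, {cy}) um lies outside the ROI")

    rng = np.random.default_rng(seed)
    px = pixel_size_um
    plaque_img = np.zeros(shape)
    mg_img = np.zeros(shape)
    plaque_rows = []
    for obj in plaques:
        cx, cy = obj["center_um"]
        d = obj["diameter_um"]
        inten = obj.get("intensity", 1.0)
        _draw_disk(plaque_img, cx / px, cy / px, d / 2 / px, inten)
        plaque_rows.append({"center_x_um": cx, "center_y_um": cy,
                            "diameter_um": d, "intensity": inten,
                            "area_um2": np.pi * (d / 2) ** 2})
    mg_rows = []
    for mg in microglia:
        cx, cy = mg["soma_center_um"]
        d = mg["soma_diameter_um"]
        branches = [np.asarray(b, dtype=float) for b in mg.get("branches", [])]
        for poly in branches:
            for k in range(len(poly) - 1):
                _draw_segment(mg_img, poly[k] / px, poly[k + 1] / px,
                              branch_half_width_um / px, branch_intensity)
        _draw_disk(mg_img, cx / px, cy / px, d / 2 / px, soma_intensity)
        lengths = [float(np.sum(np.hypot(*np.diff(poly, axis=0).T))) for poly in branches]
        mg_rows.append({
            "soma_x_um": cx, "soma_y_um": cy, "soma_diameter_um": d,
            "soma_area_um2": np.pi * (d / 2) ** 2,
            "branch_count": len(branches),
            "junction_count": _count_junctions(branches),
            "total_branch_length_um": float(sum(lengths)),
        })

    channels = {}
    for name, img in (("plaque", plaque_img), ("microglia", mg_img)):
        out = img + background
        if noise > 0:
            out = np.clip(out + rng.normal(0.0, noise, size=shape), 0.0, None)
        channels[name] = ImagePlane(out, px, channel=name)
    roi = RoiMask(np.ones(shape, dtype=bool), px)

    plaque_df = pd.DataFrame(plaque_rows)
    mg_df = pd.DataFrame(mg_rows)
    dist = {}
    if len(plaque_df) and len(mg_df):
        pc = plaque_df[["center_x_um", "center_y_um"]].to_numpy()
        sc = mg_df[["soma_x_um", "soma_y_um"]].to_numpy()
        dist = {"plaque_soma_dist_um":
                np.hypot(pc[:, None, 0] - sc[None, :, 0],
                         pc[:, None, 1] - sc[None, :, 1])}
    gt = GroundTruth("scene", {
        "roi_size_um": roi_size_um, "pixel_size_um": px,
        "plaques": plaque_df, "microglia": mg_df,
        "overlapping_plaques": _overlap_flags(plaque_df),
        "background": background, "noise": noise,
        **dist,
    }, seed)
    return {"channels": channels, "roi": roi}, gt


def _count_junctions(branches, tol_um: float = 0.5) -> int:
    """Branch endpoints shared by 3+ branches count as one junction each."""
    ends = []
    for poly in branches:
        if len(poly) >= 2:
            ends.append(tuple(np.round(poly[0] / tol_um).astype(int)))
            ends.append(tuple(np.round(poly[-1] / tol_um).astype(int)))
    from collections import Counter

    return sum(1 for _, c in Counter(ends).items() if c >= 3)


def _overlap_flags(plaque_df: pd.DataFrame) -> list:
    flagged = []
    if len(plaque_df) < 2:
        return flagged
    c = plaque_df[["center_x_um", "center_y_um"]].to_numpy()
    r = plaque_df["diameter_um"].to_numpy() / 2
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            if np.hypot(*(c[i] - c[j])) < r[i] + r[j]:
                flagged.append((i, j))
    return flagged


# ---------------------------------------------------------------------------
# targeted proteomics


def gen_prm_run(
    true_fmol: dict,
    spike_fmol: float = DEFAULT_SPIKE_FMOL,
    area_per_fmol: float = 1e4,
    noise_cv: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
    genotype: str = "",
) -> tuple:
    """PRM peak areas for the planted molar amounts.

    ``true_fmol`` maps TREM2 species to the planted native amount; both the
    native and internal-standard areas get independent multiplicative
    log-normal noise of coefficient of variation ``noise_cv`` (mean 1).
    """
    if spike_fmol <= 0:
        raise ValueError("spike_fmol must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def jitter():
        return np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0

    out = []
    for species, fmol in true_fmol.items():
        out.append(PeptideMeasurement(
            species=species,
            native_area=fmol * area_per_fmol * jitter(),
            sil_area=spike_fmol * area_per_fmol * jitter(),
            spike_fmol=spike_fmol,
            sample_id=sample_id,
            genotype=genotype,
        ))
    gt = GroundTruth("prm_run", {
        "true_fmol": dict(true_fmol), "spike_fmol": spike_fmol,
        "area_per_fmol": area_per_fmol, "noise_cv": noise_cv,
    }, seed)
    return out, gt


# ---------------------------------------------------------------------------
# RNA-seq counts


def gen_counts(
    n_genes: int,
    groups,
    lib_sizes=None,
    nb_dispersion: float = 0.05,
    de_genes: dict | None = None,
    module_genes: dict | None = None,
    seed: int = 0,
    *,
    module_group_effect: float = 1.0,
    module_scale: float = 0.4,
    dispersion_sdlog: float = 0.3,
) -> tuple:
    """Negative-binomial count matrix with planted DE genes and one module.

    ``groups`` is a label per sample (the first distinct label codes 0,
    the second 1). ``de_genes`` maps gene index -> log2 fold change applied
    to group 1. ``module_genes`` maps gene index -> loading on a latent
    factor ``f = module_group_effect * (code - mean) + N(0, 0.5)`` shared
    by module members (log2 mean shift ``loading * f * module_scale``),
    the simplest structure producing a co-expression module correlated
    with group membership. Gene-wise dispersions are log-normal around
    ``nb_dispersion``.
    """
    labels = list(groups)
    uniq = list(dict.fromkeys(labels))
    code = np.array([uniq.index(g) for g in labels], dtype=float)
    for u in uniq:
        if labels.count(u) < 2:
            raise ValueError(f"group {u!r} has fewer than 2 samples")
    n_samples = len(labels)
    if lib_sizes is None:
        lib_sizes = np.full(n_samples, 1e6)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    de_genes = de_genes or {}
    module_genes = module_genes or {}

    rng = np.random.default_rng(seed)
    rel = rng.lognormal(0.0, 1.0, size=n_genes)
    p = rel / rel.sum()
    phi = rng.lognormal(np.log(nb_dispersion), dispersion_sdlog, size=n_genes)

    log2shift = np.zeros((n_genes, n_samples))
    for g, lfc in de_genes.items():
        log2shift[g] += lfc * code
    f = module_group_effect * (code - code.mean()) + rng.normal(0.0, 0.5, n_samples)
    for g, loading in module_genes.items():
        log2shift[g] += loading * f * module_scale
    mu = np.outer(p, lib_sizes) * 2.0**log2shift

    n_param = 1.0 / phi[:, None]
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    sample_names = [f"S{i + 1:02d}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, columns=sample_names,
                             index=[f"g{i + 1:04d}" for i in range(n_genes)])
    meta = pd.DataFrame({
        "genotype": labels,
        "sex": ["F" if i % 2 else "M" for i in range(n_samples)],
        "gene_count_pct": rng.uniform(70, 90, n_samples),
        "strandness": rng.uniform(0.93, 1.0, n_samples),
        "exonic_rate": rng.uniform(0.65, 0.8, n_samples),
    }, index=sample_names)
    cm = CountMatrix(counts_df, meta)
    gt = GroundTruth("counts", {
        "n_genes": n_genes, "groups": labels,
        "lib_sizes": lib_sizes, "nb_dispersion": nb_dispersion,
        "de_genes": {int(k): float(v) for k, v in de_genes.items()},
        "module_genes": {int(k): float(v) for k, v in module_genes.items()},
        "module_gene_names": [f"g{int(k) + 1:04d}" for k in module_genes],
        "de_gene_names": [f"g{int(k) + 1:04d}" for k in de_genes],
        "latent_factor": f,
        "module_scale": module_scale,
    }, seed)
    return cm, gt


# ---------------------------------------------------------------------------
# writers (plain-text outputs + ground-truth JSON)


def write_sweep_csv(sweep: Sweep, path) -> None:
    pd.DataFrame({"time_ms": sweep.time_ms, "voltage_mV": sweep.voltage_mV}
                 ).to_csv(path, index=False)


def write_dialysis_csv(series_list, path) -> None:
    rows = []
    for s in series_list:
        for t, c in zip(s.t_h, s.conc):
            rows.append({"animal_id": s.animal_id, "t_h": t, "conc": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scene(scene: dict, outdir) -> None:
    """Write each channel as single-plane TIFF + YAML calibration sidecar,
    plus the ROI mask as TIFF."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, plane in scene["channels"].items():
        tifffile.imwrite(outdir / f"{name}.tiff", plane.data.astype(np.float32))
        with open(outdir / f"{name}.yaml", "w") as fh:
            yaml.safe_dump({"pixel_size_um": plane.pixel_size_um,
                            "channel": plane.channel}, fh)
    tifffile.imwrite(outdir / "roi.tiff",
                     scene["roi"].mask.astype(np.uint8))


def write_prm_csv(measurements, path) -> None:
    pd.DataFrame([{
        "sample_id": m.sample_id, "genotype": m.genotype, "species": m.species,
        "native_area": m.native_area, "sil_area": m.sil_area,
        "spike_fmol": m.spike_fmol,
    } for m in measurements]).to_csv(path, index=False)


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.meta.to_csv(meta_path)


def write_ground_truth(gt: GroundTruth, path) -> None:
    gt.to_json(path)
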