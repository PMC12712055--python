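"""Quantification of patch-clamp sweeps and calcium-imaging time courses.

Covers the functional-assay readouts used to characterize PIEZO1 variants:

* mechanical activation threshold (first stimulus whose peak current exceeds
  six baseline standard deviations);
* inactivation time constant tau from a single-exponential fit
  ``C1 + C2 * exp(-(t - t0) / tau)`` with t0 fixed at the fit-window start;
* pressure-response normalization and Boltzmann fit for P50;
* peak/sustained current ratio;
* single-channel amplitude from a two-component Gaussian-mixture fit of the
  trace histogram and unitary conductance from the I/V regression;
* F/F0 calcium time courses and the four-parameter logistic EC50 fit.

Units: currents in pA, pressures in mmHg, displacements in um, voltages in
mV, conductance in pS, time in s (tau is reported in ms), concentrations in
uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture


class NoResponseError(ValueError):
    """Raised when a cell shows no current to normalize against."""


# ---------------------------------------------------------------------------
# sweep container


@dataclass
class SweepSeries:
    """A family of current traces evoked by a monotone stimulus series.

    ``currents`` has one row per stimulus; all sweeps share the time base.
    The stimulus (pressure step or indenter displacement) is applied from
    ``stim_onset_s`` for ``stim_duration_s``.
    """

    stimuli: np.ndarray  # mmHg (negative-going) or um (positive-going)
    time_s: np.ndarray
    currents: np.ndarray  # (n_sweeps, n_samples) pA
    stim_onset_s: float
    stim_duration_s: float
    sample_rate_hz: float
    stimulus_unit: str = "mmHg"

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, float)
        self.time_s = np.asarray(self.time_s, float)
        self.currents = np.atleast_2d(np.asarray(self.currents, float))
        d = np.diff(self.stimuli)
        if len(self.stimuli) == 0:
            raise ValueError("empty stimulus list")
        if len(d) and not ((d > 0).all() or (d < 0).all()):
            raise ValueError("stimuli must be strictly monotone")
        if self.currents.shape != (len(self.stimuli), len(self.time_s)):
            raise ValueError("currents must be (n_stimuli, n_samples)")

    @property
    def baseline_slice(self) -> np.ndarray:
        return self.time_s < self.stim_onset_s

    @property
    def stim_slice(self) -> np.ndarray:
        return (self.time_s >= self.stim_onset_s) & (
            self.time_s < self.stim_onset_s + self.stim_duration_s
        )


def _signed_peak(dev: np.ndarray) -> float:
    """Extremum (largest |value|, sign kept) of a baseline-subtracted segment."""
    return float(dev[np.argmax(np.abs(dev))])


# ---------------------------------------------------------------------------
# mechanical threshold


@dataclass
class ThresholdResult:
    reached: bool
    threshold: float | None  # stimulus value, or None if not reached
    index: int | None  # index of first supra-threshold sweep
    baseline_mean: float
    baseline_sd: float
    k_sd: float
    used_sd_floor: bool


def detect_threshold(
    series: SweepSeries,
    k_sd: float = 6.0,
    sd_floor: float = 1.0,
) -> ThresholdResult:
    """First stimulus whose peak deviation exceeds ``k_sd`` baseline SDs.

    The baseline is the pre-stimulus segment of each sweep; mean and SD are
    pooled over sweeps.  A zero baseline SD (noiseless synthetic data) falls
    back to the absolute floor ``sd_floor`` (pA), flagged in the result.
    """
    base = series.currents[:, series.baseline_slice]
    mu = float(base.mean())
    sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    used_floor = False
    if sd == 0.0 or not np.isfinite(sd):
        sd = float(sd_floor)
        used_floor = True
    window = series.stim_slice
    for idx, sweep in enumerate(series.currents):
        peak = np.abs(sweep[window] - mu).max()
        if peak > k_sd * sd:
            return ThresholdResult(
                True, float(series.stimuli[idx]), idx, mu, sd, k_sd, used_floor
            )
    return ThresholdResult(False, None, None, mu, sd, k_sd, used_floor)


# ---------------------------------------------------------------------------
# inactivation kinetics


@dataclass
class InactivationFit:
    c1: float  # pA, steady-state offset
    c2: float  # pA, decaying amplitude
    t0: float  # s, fixed at the fit-window start
    tau_inact_ms: float
    peak: float  # pA, current at/near the window start (gate quantity)
    converged: bool
    degenerate: bool = False


def fit_inactivation(
    t_s: np.ndarray,
    i_pa: np.ndarray,
    window: tuple[float, float] | None = None,
    peak: float | None = None,
) -> InactivationFit:
    """Single-exponential decay fit ``C1 + C2 * exp(-(t - t0) / tau)``.

    ``t0`` is fixed at the window start, leaving three free parameters
    (C1, C2, tau) and removing the t0/C2 degeneracy.  A flat trace (or a fit
    collapsing to C2 ~ 0) is flagged degenerate and excluded from cell-level
    averaging.
    """
    t_s = np.asarray(t_s, float)
    i_pa = np.asarray(i_pa, float)
    if window is None:
        window = (float(t_s[0]), float(t_s[-1]))
    sel = (t_s >= window[0]) & (t_s <= window[1])
    t = t_s[sel]
    y = i_pa[sel]
    t0 = float(window[0])
    if peak is None:
        peak = _signed_peak(y) if len(y) else 0.0
    span = float(np.ptp(y)) if len(y) else 0.0
    scale = max(np.abs(y).max() if len(y) else 0.0, 1.0)
    if len(y) < 4 or span < 1e-12 * scale:
        return InactivationFit(
            c1=float(y.mean()) if len(y) else np.nan,
            c2=0.0, t0=t0, tau_inact_ms=np.nan,
            peak=float(peak), converged=False, degenerate=True,
        )

    def model(tt, c1, c2, tau):
        return c1 + c2 * np.exp(-(tt - t0) / tau)

    p0 = (float(y[-1]), float(y[0] - y[-1]), max((window[1] - window[0]) / 5.0, 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return InactivationFit(np.nan, np.nan, t0, np.nan, float(peak), False)
    c1, c2, tau = (float(v) for v in popt)
    degenerate = abs(c2) < 1e-9 * max(abs(c1), 1.0)
    return InactivationFit(
        c1=c1, c2=c2, t0=t0, tau_inact_ms=tau * 1e3,
        peak=float(peak), converged=not degenerate, degenerate=degenerate,
    )


def cell_mean_tau(
    fits: list[InactivationFit], peak_range: tuple[float, float] = (100.0, 1500.0)
) -> tuple[float, int]:
    """Cell-level tau: equal-weight mean over converged sweeps passing the peak gate.

    Only sweeps whose |peak| lies in ``peak_range`` (pA) contribute.  Returns
    (mean tau in ms, number of sweeps used); NaN mean if none qualify.
    """
    lo, hi = peak_range
    taus = [
        f.tau_inact_ms
        for f in fits
        if f.converged and not f.degenerate and lo <= abs(f.peak) <= hi
    ]
    if not taus:
        return float("nan"), 0
    return float(np.mean(taus)), len(taus)


# ---------------------------------------------------------------------------
# pressure-response / Boltzmann


def normalize_pressure_response(series: SweepSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-pressure peak current normalized to the cell's maximal response.

    Peaks are baseline-subtracted magnitudes over the stimulus window; the
    divisor is the global maximum over all pressures (I/Imax in [0, 1]).
    """
    base = series.currents[:, series.baseline_slice]
    mu = float(base.mean()) if base.size else 0.0
    window = series.stim_slice
    peaks = np.abs(series.currents[:, window] - mu).max(axis=1)
    imax = peaks.max()
    if imax == 0.0:
        raise NoResponseError("all sweeps are flat; no maximal response")
    return series.stimuli.copy(), peaks / imax


@dataclass
class BoltzmannFit:
    p50_mmhg: float  # on the sampled (negative) pressure axis
    slope_mmhg: float  # k > 0 so response grows with more-negative pressure
    imax_norm: float  # free saturating amplitude on the normalized scale
    residuals: np.ndarray
    converged: bool
    in_range: bool  # P50 within sampled range +- one step

    @property
    def p50_magnitude(self) -> float:
        return abs(self.p50_mmhg)


def boltzmann(p, p50, k):
    """Pressure-response sigmoid ``1 / (1 + exp((P - P50)/k))``, k > 0."""
    return 1.0 / (1.0 + np.exp((p - p50) / k))


def fit_boltzmann(pressures: np.ndarray, responses: np.ndarray) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to a normalized pressure-response curve.

    The model is ``Imax / (1 + exp((P - P50)/k))`` with the saturating
    amplitude free: normalization divides by the largest *sampled* response,
    which sits slightly below the true saturating current whenever the curve
    is not fully saturated in range, and a free amplitude absorbs that.
    P50 is reported on the pressure axis as sampled (negative mmHg for
    suction protocols); ``p50_magnitude`` gives the unsigned value.
    """
    p = np.asarray(pressures, float)
    r = np.asarray(responses, float)
    if len(p) < 3:
        raise ValueError("need >= 3 pressures")

    def model(pp, p50, k, top):
        return top * boltzmann(pp, p50, k)

    # initial P50: pressure whose response is closest to one half
    p0_guess = float(p[np.argmin(np.abs(r - 0.5))])
    step = float(np.abs(np.diff(p)).mean()) if len(p) > 1 else 5.0
    try:
        popt, _ = optimize.curve_fit(
            model, p, r, p0=(p0_guess, max(step, 1.0), 1.0),
            bounds=([-np.inf, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except (RuntimeError, ValueError):
        return BoltzmannFit(
            np.nan, np.nan, np.nan, np.full_like(r, np.nan), False, False
        )
    p50, k, top = (float(v) for v in popt)
    lo, hi = min(p.min(), p.max()) - step, max(p.min(), p.max()) + step
    return BoltzmannFit(
        p50_mmhg=p50,
        slope_mmhg=k,
        imax_norm=top,
        residuals=r - model(p, p50, k, top),
        converged=converged,
        in_range=lo <= p50 <= hi,
    )


# ---------------------------------------------------------------------------
# peak / sustained ratio


@dataclass
class PeakSustainedResult:
    ratio: float
    peak: float  # baseline-subtracted extremum, sign kept
    sustained: float  # baseline-subtracted mean over the final window fraction
    capped: bool


def peak_sustained_ratio(
    t_s: np.ndarray,
    i_pa: np.ndarray,
    stim_window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
    sustained_fraction: float = 0.1,
    cap: float = 1000.0,
) -> PeakSustainedResult:
    """Peak current over mean current in the final fraction of the stimulus.

    Both quantities are baseline-subtracted.  A near-zero sustained component
    (fully inactivating trace) yields a capped, flagged ratio.
    """
    t_s = np.asarray(t_s, float)
    i_pa = np.asarray(i_pa, float)
    if baseline_window is None:
        base = i_pa[t_s < stim_window[0]]
    else:
        base = i_pa[(t_s >= baseline_window[0]) & (t_s < baseline_window[1])]
    mu = float(base.mean()) if base.size else 0.0
    # half-open stimulus window: the sample at offset belongs to the recovery
    in_stim = (t_s >= stim_window[0]) & (t_s < stim_window[1])
    dev = i_pa[in_stim] - mu
    peak = _signed_peak(dev)
    t_stim = t_s[in_stim]
    tail_start = stim_window[1] - sustained_fraction * (stim_window[1] - stim_window[0])
    sustained = float(dev[t_stim >= tail_start].mean())
    if abs(sustained) < 1e-6 * max(abs(peak), 1.0):
        return PeakSustainedResult(ratio=cap, peak=peak, sustained=sustained, capped=True)
    return PeakSustainedResult(
        ratio=peak / sustained, peak=peak, sustained=sustained, capped=False
    )


# ---------------------------------------------------------------------------
# single-channel amplitude and I/V conductance


@dataclass
class AmplitudeResult:
    amplitude_pa: float  # |difference of Gaussian component means|
    signed_amplitude_pa: float  # open minus closed (closed = heavier component)
    means: np.ndarray
    weights: np.ndarray
    no_event: bool


def _histogram_mode_init(samples: np.ndarray) -> np.ndarray:
    """Initial mixture means: the two highest local maxima of the FD histogram."""
    counts, edges = np.histogram(samples, bins="fd")
    mids = 0.5 * (edges[:-1] + edges[1:])
    if len(counts) < 3:
        return np.percentile(samples, [10, 90]).reshape(-1, 1)
    interior = (counts[1:-1] >= counts[:-2]) & (counts[1:-1] >= counts[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) < 2:
        return np.percentile(samples, [10, 90]).reshape(-1, 1)
    top2 = peaks[np.argsort(counts[peaks])[-2:]]
    return mids[np.sort(top2)].reshape(-1, 1)


def single_channel_amplitude(
    segment: np.ndarray,
    min_weight: float = 0.02,
    min_separation_sds: float = 2.0,
) -> AmplitudeResult:
    """Unitary current amplitude of one 1 s two-level trace segment.

    The sample histogram is modelled as a two-component Gaussian mixture
    (initialized at the two histogram modes, Freedman-Diaconis binning); the
    amplitude is the absolute difference of the component means.  The segment
    is flagged ``no_event`` when the components are not separable: minor
    weight below ``min_weight`` or mean separation below
    ``min_separation_sds`` pooled SDs (a unimodal, no-openings histogram).
    """
    x = np.asarray(segment, float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, means_init=_histogram_mode_init(x.ravel()), random_state=0
    ).fit(x)
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    sep = abs(means[0] - means[1])
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    no_event = weights.min() < min_weight or sep < min_separation_sds * pooled_sd
    closed = int(np.argmax(weights))  # channel is closed most of the time
    open_ = 1 - closed
    return AmplitudeResult(
        amplitude_pa=float(sep),
        signed_amplitude_pa=float(means[open_] - means[closed]),
        means=means,
        weights=weights,
        no_event=bool(no_event),
    )


def voltage_amplitudes(
    traces: dict[float, np.ndarray], sample_rate_hz: float, segment_s: float = 1.0
) -> pd.DataFrame:
    """Per-voltage mean signed amplitude over 1 s segments with openings."""
    seg_len = int(round(segment_s * sample_rate_hz))
    rows = []
    for v, trace in traces.items():
        amps = []
        for start in range(0, len(trace) - seg_len + 1, seg_len):
            res = single_channel_amplitude(trace[start : start + seg_len])
            if not res.no_event:
                amps.append(res.signed_amplitude_pa)
        rows.append(
            {
                "voltage_mv": float(v),
                "amplitude_pa": float(np.mean(amps)) if amps else np.nan,
                "n_segments": len(amps),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IVFit:
    conductance_ps: float
    reversal_mv: float
    slope_pa_per_mv: float
    intercept_pa: float
    r_value: float


def fit_iv(voltages: np.ndarray, amplitudes: np.ndarray) -> IVFit:
    """Unitary conductance from the OLS slope of the I/V plot.

    ``amplitudes`` are signed unitary currents (pA); the slope in pA/mV
    converts to pS by a factor of 1000 (i = g * (V - Vrev), g in pS, V in mV).
    """
    v = np.asarray(voltages, float)
    i = np.asarray(amplitudes, float)
    ok = np.isfinite(i)
    v, i = v[ok], i[ok]
    if len(v) < 2:
        raise ValueError("need >= 2 voltages with measurable amplitudes")
    res = stats.linregress(v, i)
    slope = float(res.slope)
    return IVFit(
        conductance_ps=slope * 1e3,
        reversal_mv=float(-res.intercept / slope) if slope != 0 else np.nan,
        slope_pa_per_mv=slope,
        intercept_pa=float(res.intercept),
        r_value=float(res.rvalue),
    )


# ---------------------------------------------------------------------------
# calcium imaging


@dataclass
class CalciumTimecourse:
    time_s: np.ndarray
    f_au: np.ndarray
    f0: float  # mean fluorescence over the control window
    f_over_f0: np.ndarray

    def max_response(self, window: tuple[float, float] | None = None) -> float:
        """Maximal F/F0, optionally restricted to the drug-perfusion window."""
        if window is None:
            return float(self.f_over_f0.max())
        sel = (self.time_s >= window[0]) & (self.time_s <= window[1])
        return float(self.f_over_f0[sel].max())


def compute_f_over_f0(
    time_s: np.ndarray,
    f_au: np.ndarray,
    control_window: tuple[float, float] = (0.0, 10.0),
) -> CalciumTimecourse:
    """Normalize a fluorescence series to its 10 s control-window mean (F0)."""
    time_s = np.asarray(time_s, float)
    f_au = np.asarray(f_au, float)
    sel = (time_s >= control_window[0]) & (time_s <= control_window[1])
    if not sel.any():
        raise ValueError("control window contains no frames")
    f0 = float(f_au[sel].mean())
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    return CalciumTimecourse(time_s=time_s, f_au=f_au, f0=f0, f_over_f0=f_au / f0)


# ---------------------------------------------------------------------------
# dose-response EC50


@dataclass
class DoseResponseFit:
    ec50_um: float
    hill: float
    top: float
    bottom: float
    summary: pd.DataFrame  # per-concentration mean +- SEM of max F/F0
    converged: bool
    extrapolated: bool  # EC50 outside the sampled concentration range


def logistic4(logc, bottom, top, logec50, hill):
    """Four-parameter logistic in log10 concentration."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def fit_ec50(per_cell: pd.DataFrame) -> DoseResponseFit:
    """EC50 from per-cell maximal F/F0 responses.

    Per-cell maxima are averaged per concentration and the per-concentration
    means are fitted with a four-parameter logistic in log10 concentration.

    Parameters
    ----------
    per_cell:
        DataFrame with columns ``conc_um`` and ``max_f_over_f0`` (one row per
        cell and concentration).
    """
    grp = per_cell.groupby("conc_um")["max_f_over_f0"]
    summary = grp.agg(["mean", "sem", "count"]).reset_index()
    if len(summary) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    logc = np.log10(summary["conc_um"].to_numpy(float))
    y = summary["mean"].to_numpy(float)
    p0 = (float(y.min()), float(y.max()), float(logc.mean()), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            logistic4, logc, y, p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf, 100.0]),
            maxfev=20000,
        )
        converged = True
    except (RuntimeError, ValueError):
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, summary, False, False)
    bottom, top, logec50, hill = (float(v) for v in popt)
    return DoseResponseFit(
        ec50_um=10.0**logec50,
        hill=hill,
        top=top,
        bottom=bottom,
        summary=summary,
        converged=converged,
        extrapolated=not (logc.min() <= logec50 <= logc.max()),
    )
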