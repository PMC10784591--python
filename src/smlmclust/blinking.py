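"""Blink calibration: from localization tables of immobilized emitters to
the localizations-per-molecule correction factor.

A photoconvertible fluorophore visits a reversible dark state ``N_blink``
times before photobleaching.  With dark-branch probability
``h = k_d/(k_d + k_b)`` the blink count is geometric,

    P(N_blink = n) = h^n (1 - h),        <N_blink> = h/(1 - h) = k_d/k_b,

so one molecule yields ``1 + <N_blink>`` localizations on average; cluster
localization counts divided by this multiplicity give molecule counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import LocalizationTable


@dataclass
class EmissionTrace:
    """On/off interval structure of one reconstructed molecule."""

    molecule_id: str
    on_intervals: list[tuple[int, int]]  # (first_frame, last_frame), inclusive
    frame_interval_ms: float
    mean_intensity: float = float("nan")
    n_localizations: int = 0

    @property
    def n_blink(self) -> int:
        return len(self.on_intervals) - 1

    @property
    def t_on_list_s(self) -> np.ndarray:
        dt = self.frame_interval_ms / 1000.0
        return np.array([(f1 - f0 + 1) * dt for f0, f1 in self.on_intervals])

    @property
    def t_off_list_s(self) -> np.ndarray:
        dt = self.frame_interval_ms / 1000.0
        pairs = zip(self.on_intervals[:-1], self.on_intervals[1:])
        return np.array([(b[0] - a[1] - 1) * dt for a, b in pairs])


@dataclass
class BlinkCalibration:
    """Fitted blinking statistics of a fluorophore."""

    h: float
    n_traces: int = 0
    k_on_decay: float = float("nan")  # fitted k_b + k_d, 1/s
    k_on_decay_se: float = float("nan")
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h < 1.0:
            raise ValueError("h must lie in [0, 1)")

    @property
    def mean_nblink(self) -> float:
        return self.h / (1.0 - self.h)

    @property
    def multiplicity(self) -> float:
        """Expected localizations per molecule, 1 + <N_blink>."""
        return 1.0 + self.mean_nblink

    @classmethod
    def from_rates(cls, k_d: float, k_b: float) -> "BlinkCalibration":
        """Calibration implied by the dark and bleach rates directly."""
        if k_b <= 0 or k_d < 0:
            raise ValueError("require k_b > 0 and k_d >= 0")
        return cls(h=k_d / (k_d + k_b), k_on_decay=k_b + k_d)

    @classmethod
    def from_mean_nblink(cls, mean_nblink: float) -> "BlinkCalibration":
        if mean_nblink < 0:
            raise ValueError("mean_nblink must be >= 0")
        return cls(h=mean_nblink / (1.0 + mean_nblink))


def multiplicity(calibration: BlinkCalibration) -> float:
    """Localizations-per-molecule factor 1 + <N_blink>."""
    return calibration.multiplicity


def group_localizations_into_traces(
    table: LocalizationTable,
    dark_time_threshold_s: float = 2.5,
    link_radius_nm: float | None = None,
) -> list[EmissionTrace]:
    """Reconstruct per-molecule traces from an immobilized-emitter table.

    Localizations within ``link_radius_nm`` of a trace's running centroid
    and within ``dark_time_threshold_s`` of its last frame are merged into
    that trace; runs of consecutive frames inside a trace form its
    on-intervals.  Every localization is assigned to exactly one trace.

    ``link_radius_nm`` defaults to 4x the median uncertainty.  The gate is
    widened by sqrt(1 + 1/n) for a trace of n localizations: the running
    centroid of a young trace is itself noisy, so the distance between a
    re-blink and a single-point trace is Rayleigh with scale sqrt(2) times
    the precision, and a plain 3-sigma point gate would split about 1% of
    re-blinks off into spurious traces.
    """
    if table.frame_interval_ms is None or table.frame_interval_ms <= 0:
        raise ValueError("table must carry a positive frame_interval_ms")
    if link_radius_nm is None:
        link_radius_nm = 4.0 * float(np.median(table.uncertainty)) if len(table) else 80.0
    max_gap_frames = int(np.floor(dark_time_threshold_s * 1000.0 / table.frame_interval_ms))

    df = table.df.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(int)
    xs = df["x"].to_numpy(float)
    ys = df["y"].to_numpy(float)
    inten = df["intensity"].to_numpy(float)

    # open traces: (cx, cy, n, last_frame, frame_list, intensity_sum)
    open_traces: list[dict] = []
    closed: list[dict] = []
    # spatial hash for candidate lookup; cell size covers the widest gate
    cell = 2.0 * link_radius_nm
    grid: dict[tuple[int, int], list[int]] = {}

    def keys_around(x: float, y: float):
        ci, cj = int(x // cell), int(y // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                yield (ci + di, cj + dj)

    for k in range(len(frames)):
        f, x, y = frames[k], xs[k], ys[k]
        best = None
        best_d = np.inf
        for key in keys_around(x, y):
            for ti in grid.get(key, ()):
                tr = open_traces[ti]
                if tr is None or f - tr["last_frame"] > max_gap_frames:
                    continue
                gate = link_radius_nm * np.sqrt(1.0 + 1.0 / tr["n"])
                d = np.hypot(x - tr["cx"], y - tr["cy"])
                if d <= gate and d < best_d:
                    best, best_d = ti, d
        if best is None:
            tr = {
                "cx": x, "cy": y, "n": 1, "last_frame": f,
                "frames": [f], "isum": inten[k],
            }
            open_traces.append(tr)
            key = (int(x // cell), int(y // cell))
            grid.setdefault(key, []).append(len(open_traces) - 1)
        else:
            tr = open_traces[best]
            n = tr["n"]
            tr["cx"] = (tr["cx"] * n + x) / (n + 1)
            tr["cy"] = (tr["cy"] * n + y) / (n + 1)
            tr["n"] = n + 1
            tr["last_frame"] = f
            tr["frames"].append(f)
            tr["isum"] += inten[k]

    traces: list[EmissionTrace] = []
    for i, tr in enumerate(open_traces):
        fr = np.asarray(tr["frames"])
        breaks = np.where(np.diff(fr) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(fr) - 1]])
        intervals = [(int(fr[s]), int(fr[e])) for s, e in zip(starts, ends)]
        traces.append(
            EmissionTrace(
                molecule_id=f"trace{i:06d}",
                on_intervals=intervals,
                frame_interval_ms=table.frame_interval_ms,
                mean_intensity=tr["isum"] / tr["n"],
                n_localizations=tr["n"],
            )
        )
    return traces


def fit_geometric_nblink(traces) -> BlinkCalibration:
    """Maximum-likelihood fit of the geometric blink-count law.

    For P(N = n) = h^n (1 - h) the MLE is closed-form, h = m/(1 + m) with
    m the sample mean blink count.  A fitted-vs-empirical histogram is kept
    in ``fit_diagnostics`` as the conventional visual check.
    """
    nblinks = np.asarray(
        [t.n_blink if hasattr(t, "n_blink") else int(t) for t in traces], dtype=float
    )
    n = len(nblinks)
    if n < 50:
        raise ValueError(f"need >= 50 traces for a geometric fit, got {n}")
    m = float(nblinks.mean())
    h = m / (1.0 + m)
    if m == 0:
        warnings.warn("all blink counts are zero: degenerate fit h = 0")
    # standard error of m (hence of the derived h) for diagnostics
    se_m = float(nblinks.std(ddof=1)) / np.sqrt(n) if n > 1 else float("nan")
    kmax = int(nblinks.max()) + 1
    emp, _ = np.histogram(nblinks, bins=np.arange(kmax + 1) - 0.5)
    fitted = n * (h ** np.arange(kmax)) * (1 - h)
    return BlinkCalibration(
        h=h,
        n_traces=n,
        fit_diagnostics={
            "mean_nblink_se": se_m,
            "empirical_hist": emp,
            "fitted_hist": fitted,
        },
    )


def fit_ton_exponential(traces) -> tuple[float, float]:
    """Fit a single-exponential decay to the on-time density.

    Returns ``(rate, se)``: the decay rate ``k_b + k_d`` (1/s) and its
    1-sigma (68.3%) confidence limit.  Continuous on-times are fitted by
    the exponential MLE (rate = 1/mean).  Frame-quantized on-times (all
    values multiples of the exposure) are handled through the geometric
    law they follow — the per-frame survival ratio ``q`` satisfies
    ``rate = -ln(q)/exposure`` — which removes the first-bin censoring and
    discretization bias of a naive mean.
    """
    seq = list(traces)
    if seq and hasattr(seq[0], "t_on_list_s"):
        t_on = np.concatenate([np.atleast_1d(t.t_on_list_s) for t in seq])
    elif seq and hasattr(seq[0], "on_times_s"):
        t_on = np.concatenate([np.atleast_1d(t.on_times_s) for t in seq])
    else:
        t_on = np.asarray(seq, dtype=float)
    t_on = t_on[np.isfinite(t_on) & (t_on > 0)]
    n = len(t_on)
    if n < 50:
        raise ValueError(f"need >= 50 on-times, got {n}")
    if len(np.unique(t_on)) < 2:
        raise ValueError("on-times are all equal: cannot fit a decay")
    # detect frame quantization: values sit on a common small grid
    dt = float(np.min(t_on))
    quantized = np.allclose(t_on / dt, np.round(t_on / dt), atol=1e-9) and dt > 0
    if quantized and len(np.unique(np.round(t_on / dt))) >= 2:
        k = np.round(t_on / dt)  # frames spanned per burst, support k >= 1
        # The single-frame bin is censored by the random phase of the burst
        # against the frame grid; beyond the first boundary crossing the
        # remaining on-time is memoryless, so (k - 2 | k >= 2) is geometric
        # with ratio exp(-rate * dt).  Fit from the second bin on.
        k2 = k[k >= 2] - 1.0
        n2 = len(k2)
        if n2 < 10:
            raise ValueError("too few multi-frame on-times for a discretized fit")
        mk = float(k2.mean())
        q = (mk - 1.0) / mk  # truncated-geometric MLE of the frame survival
        if not 0 < q < 1:
            raise ValueError("degenerate discretized on-time distribution")
        rate = -np.log(q) / dt
        se_q = np.sqrt(q * (1 - q) ** 2 / n2)  # delta method on q-hat
        se = se_q / (q * dt)
        return float(rate), float(se)
    rate = 1.0 / float(t_on.mean())
    return float(rate), float(rate / np.sqrt(n))


def fit_intensity_lognormal(
    intensities: np.ndarray, max_components: int = 3, seed: int = 0
) -> dict:
    """Select a lognormal mixture for emission intensities by AIC and BIC.

    Fits Gaussian mixtures with 1..max_components components to the log
    intensities (a lognormal mixture in the original scale) and reports
    the component count minimizing each criterion; if they disagree both
    are reported and the result is flagged.
    """
    from sklearn.mixture import GaussianMixture

    from .stats import information_criteria

    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities <= 0):
        raise ValueError("intensities must be positive")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n = len(intensities)
    logi = np.log(intensities).reshape(-1, 1)
    aics, bics, params = [], [], []
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(logi)
        loglik = float(gm.score(logi)) * n
        n_par = 3 * k - 1  # k means, k variances, k-1 weights
        aic, bic = information_criteria(loglik, n_par, n)
        aics.append(aic)
        bics.append(bic)
        params.append(
            {
                "weights": gm.weights_.ravel().tolist(),
                "log_means": gm.means_.ravel().tolist(),
                "log_sds": np.sqrt(gm.covariances_.ravel()).tolist(),
            }
        )
    best_aic = int(np.argmin(aics)) + 1
    best_bic = int(np.argmin(bics)) + 1
    agreed = best_aic == best_bic
    result = {
        "n_components_aic": best_aic,
        "n_components_bic": best_bic,
        "selected": best_aic if agreed else None,
        "criteria_agree": agreed,
        "aic": aics,
        "bic": bics,
        "parameters": params[best_bic - 1],
        "underpowered": n < 50,
    }
    if n < 50:
        warnings.warn(f"only {n} intensities: model selection is underpowered")
    return result
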