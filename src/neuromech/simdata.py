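"""Synthetic isometric-contraction trials with known ground truth.

Generates complete desk-scale experiments with the statistical structure the
analysis pipeline assumes: a Fuglevand-style motoneuron pool driven by a
ramp-hold (or sinusoidally modulated) excitation, muscle mechanics in which
the neural-to-fascicle and fascicle-to-torque latencies are injected as pure
time shifts (so ground-truth delays are exact), a 32-channel surface-EMG
synthesis by template superposition, and a speckle B-mode-like image renderer
whose frames encode the commanded fascicle geometry exactly, together with the
80-Hz frame trigger used to synchronize imaging with the EMG timeline.

Every stochastic component draws from named sub-streams fanned out from one
master seed, so identical configuration + seed reproduces a bit-identical
trial.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import butter, fftconvolve, filtfilt, get_window

from .fastrack import FascicleGeometry, FascicleTrace
from .spiketools import SpikeTrain, SpikeTrainSet, cumulative_spike_train

logger = logging.getLogger(__name__)

#: EMG/torque sampling rate (Hz) and imaging frame rate (Hz) of the emulated
#: acquisition chain.
FS_EMG = 2048.0
FRAME_RATE = 80.0

# Sub-stream order for seed fan-out; changing it changes every simulation.
_STREAMS = ("isi", "emg_noise", "torque_noise", "fascicle_noise", "speckle", "templates")


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Fan one master seed out into named independent generators."""
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# motoneuron pool
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolConfig:
    """Motoneuron pool parameters.

    The pool size matches the typical decomposition yield of the emulated
    recordings (about seven detectable units) and the rate gain is calibrated
    so the pooled mean discharge rate on a 20 %MVC plateau lands near 15 Hz.
    Recruitment thresholds span ``recruitment_range`` (ratio of highest to
    lowest threshold excitation) from ``min_threshold`` %MVC upward on an
    exponential grid, the classic many-low/few-high arrangement.
    """

    n_units: int = 7
    recruitment_range: float = 30.0
    min_threshold: float = 0.5  # %MVC excitation of the most excitable unit
    min_rate: float = 8.0  # Hz at recruitment
    rate_gain: float = 0.5  # Hz per %MVC excitation above threshold
    peak_rate: float = 35.0  # Hz saturation
    isi_cv: float = 0.15  # multiplicative ISI jitter coefficient of variation
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be >= 0")
        if self.recruitment_range <= 1:
            raise ValueError("recruitment_range must exceed 1")


@dataclass(frozen=True)
class MotorPool:
    """Realized pool: per-unit recruitment thresholds and rate coding."""

    config: PoolConfig
    thresholds: np.ndarray  # %MVC excitation, strictly increasing

    def rate(self, unit: int, excitation) -> np.ndarray:
        """Discharge rate (Hz) of ``unit`` at the given excitation (%MVC).

        Zero below the unit's recruitment threshold, ``min_rate`` exactly at
        threshold, then linear with ``rate_gain`` up to ``peak_rate``.
        """
        e = np.asarray(excitation, dtype=float)
        cfg = self.config
        r = cfg.min_rate + cfg.rate_gain * (e - self.thresholds[unit])
        r = np.clip(r, cfg.min_rate, cfg.peak_rate)
        return np.where(e < self.thresholds[unit], 0.0, r)


def build_pool(cfg: PoolConfig) -> MotorPool:
    """Construct the pool's recruitment-threshold ladder and rate functions.

    Thresholds follow ``t_i = min_threshold * R**((i-1)/(n-1))`` so the ratio of
    the highest to the lowest threshold equals ``recruitment_range`` exactly
    and the ladder is strictly increasing.
    """
    n = cfg.n_units
    if n == 1:
        thr = np.array([cfg.min_threshold])
    else:
        expo = np.arange(n) / (n - 1)
        thr = cfg.min_threshold * cfg.recruitment_range**expo
    return MotorPool(config=cfg, thresholds=thr)


# ---------------------------------------------------------------------------
# contraction protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolConfig:
    """Ramp-hold contraction protocol.

    Torque rises at ``ramp_rate`` %MVC/s to ``target_level``, holds for
    ``plateau_s`` seconds (optionally tracking a sinusoidal target of
    ``sin_amp`` %MVC about the level at ``sin_freq`` Hz), then falls
    symmetrically.  ``rest_s`` seconds of silence can pad either side.
    """

    target_level: float = 20.0  # %MVC
    ramp_rate: float = 10.0  # %MVC/s
    plateau_s: float = 30.0
    mode: str = "sustained"  # or "sinusoidal"
    sin_freq: float = 0.5  # Hz
    sin_amp: float = 2.5  # %MVC half-amplitude (5 %MVC peak-to-peak)
    fs: float = FS_EMG
    frame_rate: float = FRAME_RATE
    rest_s: float = 0.0

    def __post_init__(self):
        if self.plateau_s <= 0:
            raise ValueError("plateau duration must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mode not in ("sustained", "sinusoidal"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def ramp_samples(self) -> int:
        return int(round(self.fs * self.target_level / self.ramp_rate))

    @property
    def rest_samples(self) -> int:
        return int(round(self.fs * self.rest_s))

    @property
    def plateau_samples(self) -> int:
        return int(round(self.fs * self.plateau_s))

    @property
    def n_samples(self) -> int:
        return 2 * self.rest_samples + 2 * self.ramp_samples + self.plateau_samples

    def segments(self) -> dict[str, tuple[int, int]]:
        """Ground-truth sample ranges of the protocol phases."""
        r, u, p = self.rest_samples, self.ramp_samples, self.plateau_samples
        return {
            "ramp_up": (r, r + u),
            "plateau": (r + u, r + u + p),
            "ramp_down": (r + u + p, r + 2 * u + p),
        }


def generate_excitation(protocol: ProtocolConfig) -> np.ndarray:
    """Common drive to the pool, in %MVC-equivalent units at ``fs``."""
    p = protocol
    up = np.linspace(0.0, p.target_level, p.ramp_samples, endpoint=False)
    if p.mode == "sinusoidal":
        t = np.arange(p.plateau_samples) / p.fs
        plateau = p.target_level + p.sin_amp * np.sin(2 * np.pi * p.sin_freq * t)
    else:
        plateau = np.full(p.plateau_samples, p.target_level)
    down = np.linspace(p.target_level, 0.0, p.ramp_samples, endpoint=False)
    rest = np.zeros(p.rest_samples)
    return np.concatenate([rest, up, plateau, down, rest])


# ---------------------------------------------------------------------------
# spike sampling
# ---------------------------------------------------------------------------

def sample_spikes(
    pool: MotorPool,
    excitation: np.ndarray,
    fs: float,
    rng: np.random.Generator | int,
) -> SpikeTrainSet:
    """Renewal-process discharges for every unit under a common drive.

    Each unit fires its first discharge at the sample where the excitation
    first reaches its recruitment threshold, then sequentially with
    ``ISI = 1/rate(E(t))`` jittered multiplicatively by
    ``max(0.1, 1 + isi_cv * z)``, ``z`` standard normal (the 0.1 floor forbids
    non-physiological short intervals).  No discharges occur while the drive
    is sub-threshold; a unit silenced by a drive dip resumes at the next
    threshold crossing.  Empty trains are allowed.
    """
    if np.any(excitation < 0) or np.any(excitation > 100):
        raise ValueError("excitation must lie in [0, 100] %MVC")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = excitation.size
    cv = pool.config.isi_cv
    trains = []
    for u in range(pool.config.n_units):
        thr = pool.thresholds[u]
        supra = excitation >= thr
        spikes: list[int] = []
        idx = int(np.argmax(supra)) if supra.any() else n
        t = float(idx)
        while idx < n:
            if not supra[idx]:
                nxt = np.flatnonzero(supra[idx:])
                if nxt.size == 0:
                    break
                idx = idx + int(nxt[0])
                t = float(idx)
            spikes.append(idx)
            r = float(pool.rate(u, excitation[idx]))
            jitter = max(0.1, 1.0 + cv * rng.standard_normal()) if cv > 0 else 1.0
            t = t + fs / r * jitter
            if t >= n:
                break
            idx = int(round(t))
        trains.append(SpikeTrain(u, np.asarray(spikes, dtype=np.int64), fs))
    return SpikeTrainSet(tuple(trains), fs)


# ---------------------------------------------------------------------------
# muscle mechanics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanicsConfig:
    """Muscle geometry, torque scaling, injected delays and noise.

    Delays are injected as *pure time shifts* by default so the ground-truth
    lags between neural drive, fascicle shortening and torque are exact to
    sample resolution; ``mode="causal-kernel"`` instead convolves with a
    critically damped kernel ``(t/tau^2) exp(-t/tau)`` for realism, at the
    price of a band-dependent (not nominal) effective group delay.

    Geometry anchors are typical tibialis anterior values for the two ankle
    positions: short muscle (rest 60.2 mm, 15.2 deg) shortens 7.5 mm at a
    20 %MVC plateau; the long-muscle preset is provided as ``LONG_TA``.
    """

    delay_drive_to_fascicle_ms: float = 75.0
    delay_fascicle_to_torque_ms: float = 75.0
    smoothing_tau_ms: float = 400.0  # zero-phase Hann width for the CST drive
    rest_length_mm: float = 60.2
    shortening_at_20pct_mm: float = 7.5
    shortening_at_40pct_mm: float = 9.4
    rest_pennation_deg: float = 15.2
    pennation_at_20pct_deg: float = 19.2
    torque_mvc_nm: float = 25.2
    torque_noise_pct: float = 0.25  # %MVC, band-limited additive noise
    fascicle_noise_mm: float = 0.15  # per-frame length-measurement noise
    emg_noise_sd: float = 0.05  # white noise per EMG channel, a.u.
    mode: str = "pure-shift"  # or "causal-kernel"
    kernel_tau_ms: float = 40.0

    def __post_init__(self):
        if self.delay_drive_to_fascicle_ms < 0 or self.delay_fascicle_to_torque_ms < 0:
            raise ValueError("delays must be non-negative")
        if self.shortening_at_20pct_mm <= 0:
            raise ValueError("shortening amplitude must be positive")
        if self.mode not in ("pure-shift", "causal-kernel"):
            raise ValueError(f"unknown mechanics mode {self.mode!r}")

    def shortening_at(self, level: float) -> float:
        """Configured plateau shortening (mm) for a %MVC target level."""
        if abs(level - 40.0) < 1e-9:
            return self.shortening_at_40pct_mm
        return self.shortening_at_20pct_mm * level / 20.0


#: Tibialis anterior presets for the two ankle positions.
SHORT_TA = MechanicsConfig()
LONG_TA = MechanicsConfig(
    rest_length_mm=74.5,
    shortening_at_20pct_mm=8.2,
    shortening_at_40pct_mm=12.6,
    rest_pennation_deg=12.0,
    pennation_at_20pct_deg=16.9,
    torque_mvc_nm=51.8,
)


def _shift_pure(x: np.ndarray, n: int) -> np.ndarray:
    if n >= x.size:
        raise ValueError(f"delay shift of {n} samples exceeds trace length {x.size}")
    if n == 0:
        return x.copy()
    out = np.empty_like(x)
    out[:n] = x[0]
    out[n:] = x[:-n]
    return out


def _causal_kernel(tau_ms: float, fs: float) -> np.ndarray:
    tau = tau_ms / 1000.0
    t = np.arange(0.0, 8.0 * tau, 1.0 / fs)
    k = (t / tau**2) * np.exp(-t / tau)
    return k / k.sum()


def _band_noise(rng: np.random.Generator, n: int, sd: float, fs: float,
                cutoff_hz: float = 5.0) -> np.ndarray:
    """Low-frequency additive noise, scaled to the requested sd.

    White sensor noise at 2048 Hz carries almost no power in the 0.75-2 Hz
    analysis band, so disturbance noise is generated band-limited (lowpassed
    white noise) to actually compete with the signal fluctuations.
    """
    if sd == 0.0:
        return np.zeros(n)
    b, a = butter(2, cutoff_hz / (fs / 2.0), "low")
    w = filtfilt(b, a, rng.standard_normal(n))
    s = w.std()
    return w / s * sd if s > 0 else w


def smooth_cst(counts: np.ndarray, fs: float, tau_ms: float = 400.0) -> np.ndarray:
    """Zero-phase Hann smoothing of the CST into a rate-like drive (Hz)."""
    m = max(int(round(tau_ms / 1000.0 * fs)), 1) | 1
    k = get_window("hann", m, fftbins=False)
    k /= k.sum()
    return fftconvolve(counts.astype(float), k, mode="same") * fs


@dataclass
class MechanicsResult:
    """Simulated mechanical output of one contraction.

    ``drive_pct`` is the noiseless normalized drive (%MVC scale) from which
    fascicle and torque are derived; ``torque_pct``/``fascicle`` carry the
    measurement-like noise, with noiseless copies alongside for oracles.
    ``applied_delays_ms`` are the exact (sample-quantized) shifts injected.
    """

    drive_pct: np.ndarray  # at fs
    torque_pct: np.ndarray  # at fs, noisy
    torque_pct_clean: np.ndarray
    torque_nm: np.ndarray
    delta_mm_fs: np.ndarray  # noiseless shortening at fs (ground truth)
    fascicle: FascicleTrace  # at frame_rate, with per-frame noise
    fascicle_clean: FascicleTrace
    applied_delays_ms: tuple[float, float]
    frame_samples: np.ndarray  # sample index of each imaging frame


def synthesize_mechanics(
    source,
    mech: MechanicsConfig,
    protocol: ProtocolConfig,
    rng: np.random.Generator | dict | int | None = None,
) -> MechanicsResult:
    """Fascicle-length and torque traces driven by spikes or excitation.

    ``source`` is either a :class:`~neuromech.spiketools.SpikeTrainSet` (the
    drive is the zero-phase-smoothed CST, so plateau fluctuations carry the
    units' common firing variability) or an excitation trace in %MVC (fully
    deterministic mechanics).  The drive is normalized so its plateau mean
    equals the protocol target level, then

        shortening(t) = k_f * drive(t - Df),   torque(t) = drive(t - Df - Dt)

    with ``k_f`` calibrated so the plateau shortening equals the configured
    value for the target level, and ``Df``/``Dt`` the configured delays as
    pure shifts (default) or causal kernels.
    """
    p = protocol
    fs = p.fs
    if rng is None:
        streams = seed_streams(0)
    elif isinstance(rng, dict):
        streams = rng
    elif isinstance(rng, (int, np.integer)):
        streams = seed_streams(int(rng))
    else:
        streams = {"torque_noise": rng, "fascicle_noise": rng}

    if isinstance(source, SpikeTrainSet):
        cst = cumulative_spike_train(source, p.n_samples)
        drive = smooth_cst(cst.counts, fs, mech.smoothing_tau_ms)
    else:
        drive = np.asarray(source, dtype=float)
        if drive.size != p.n_samples:
            raise ValueError("excitation length does not match the protocol")

    lo, hi = p.segments()["plateau"]
    plateau_mean = float(drive[lo:hi].mean())
    if plateau_mean <= 0:
        raise ValueError("drive has no activity on the plateau; cannot calibrate")
    drive_pct = drive * (p.target_level / plateau_mean)

    nf = int(round(mech.delay_drive_to_fascicle_ms / 1000.0 * fs))
    nt = int(round(mech.delay_fascicle_to_torque_ms / 1000.0 * fs))
    if mech.mode == "pure-shift":
        drive_f = _shift_pure(drive_pct, nf)
        drive_t = _shift_pure(drive_f, nt)
        applied = (nf / fs * 1000.0, nt / fs * 1000.0)
    else:
        k = _causal_kernel(mech.kernel_tau_ms, fs)
        drive_f = fftconvolve(_shift_pure(drive_pct, nf), k)[: drive_pct.size]
        drive_t = fftconvolve(_shift_pure(drive_f, nt), k)[: drive_pct.size]
        applied = (nf / fs * 1000.0, nt / fs * 1000.0)  # nominal; kernel adds group delay

    k_f = mech.shortening_at(p.target_level) / p.target_level  # mm per %MVC
    delta_fs = k_f * drive_f
    torque_clean = drive_t
    torque = torque_clean + _band_noise(streams["torque_noise"], torque_clean.size,
                                        mech.torque_noise_pct, fs)
    torque_nm = torque / 100.0 * mech.torque_mvc_nm

    # imaging frames subsample the fascicle trace at the trigger instants
    n_frames = int(np.floor(p.n_samples * p.frame_rate / fs))
    frame_samples = np.round(np.arange(n_frames) * fs / p.frame_rate).astype(np.int64)
    delta_frames = delta_fs[frame_samples]
    length_clean = mech.rest_length_mm - delta_frames
    noise = streams["fascicle_noise"].standard_normal(n_frames) * mech.fascicle_noise_mm
    length_noisy = length_clean + noise

    pen_slope = (mech.pennation_at_20pct_deg - mech.rest_pennation_deg) / mech.shortening_at_20pct_mm
    penn_clean = mech.rest_pennation_deg + pen_slope * delta_frames
    penn_noisy = mech.rest_pennation_deg + pen_slope * (mech.rest_length_mm - length_noisy)

    fascicle = FascicleTrace(length_noisy, penn_noisy, p.frame_rate, mech.rest_length_mm)
    fascicle_clean = FascicleTrace(length_clean, penn_clean, p.frame_rate, mech.rest_length_mm)
    return MechanicsResult(
        drive_pct=drive_pct,
        torque_pct=torque,
        torque_pct_clean=torque_clean,
        torque_nm=torque_nm,
        delta_mm_fs=delta_fs,
        fascicle=fascicle,
        fascicle_clean=fascicle_clean,
        applied_delays_ms=applied,
        frame_samples=frame_samples,
    )


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

N_CHANNELS = 32  # 8 x 4 grid, 10-mm interelectrode distance
GRID_ROWS, GRID_COLS = 8, 4


def make_template_library(
    n_units: int,
    fs: float = FS_EMG,
    rng: np.random.Generator | int = 0,
    duration_ms: float = 25.0,
) -> list[np.ndarray]:
    """Random 32-channel MUAP templates, one per unit.

    Each template is a Gaussian-windowed (slightly skewed) oscillation whose
    amplitude decays with grid distance from a random centre electrode, whose
    onset shifts along grid rows (propagation along the fibre direction) and
    whose phase drifts across the grid (tissue filtering differs per
    electrode).  The spatial phase/lag gradients give every unit a distinct
    2-D signature, so independently seeded templates are mutually dissimilar
    under global-shift cross-correlation.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = int(round(duration_ms / 1000.0 * fs))
    t = (np.arange(n) - n / 2) / fs * 1000.0  # ms, centred
    rows, cols = np.divmod(np.arange(N_CHANNELS), GRID_COLS)
    lib = []
    for _ in range(n_units):
        f0 = rng.uniform(50.0, 220.0)  # Hz
        width = rng.uniform(1.5, 4.0)  # ms
        phase = rng.uniform(0, 2 * np.pi)
        r0, c0 = rng.uniform(0, GRID_ROWS - 1), rng.uniform(0, GRID_COLS - 1)
        dist = np.sqrt((rows - r0) ** 2 + (cols - c0) ** 2)
        amp = np.exp(-dist / rng.uniform(1.0, 2.5))
        row_lag_ms = rng.uniform(-1.0, 1.0)  # per-row propagation lag
        phase_grad_row = rng.uniform(-1.8, 1.8)  # rad per grid row
        phase_grad_col = rng.uniform(-1.8, 1.8)  # rad per grid column
        skew = rng.uniform(-0.5, 0.5)
        w = np.empty((N_CHANNELS, n))
        for ch in range(N_CHANNELS):
            tc = t - rows[ch] * row_lag_ms
            ph = phase + phase_grad_row * rows[ch] + phase_grad_col * cols[ch]
            env = np.exp(-(tc**2) / (2 * width**2)) * (1 + skew * tc / width)
            w[ch] = amp[ch] * env * np.sin(2 * np.pi * f0 * tc / 1000.0 + ph)
        lib.append(w / np.abs(w).max())
    return lib


def synthesize_emg(
    spikes: SpikeTrainSet,
    templates: list[np.ndarray],
    n_samples: int,
    noise_sd: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Superpose MUAP templates at the discharge times plus white noise.

    The model is additive and linear: overlapping discharges simply sum.
    Returns an (n_samples, 32) matrix.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    emg = np.zeros((int(n_samples), N_CHANNELS))
    for train, tpl in zip(spikes, templates):
        w = np.asarray(tpl)
        ln = w.shape[1]
        if ln > n_samples:
            raise ValueError("template longer than the recording")
        half = ln // 2
        for s in train.discharges:
            lo = int(s) - half
            hi = lo + ln
            wlo = max(0, -lo)
            whi = ln - max(0, hi - n_samples)
            emg[max(0, lo) : min(n_samples, hi), :] += w[:, wlo:whi].T
    if noise_sd > 0:
        emg += rng.standard_normal(emg.shape) * noise_sd
    return emg


# ---------------------------------------------------------------------------
# ultrasound rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Speckle-image renderer settings.

    The synthetic field of view is wider than the 60-mm probe so the whole
    fascicle (rest lengths up to ~75 mm) stays inside the image; ``mm_per_px``
    is configurable and defaults to 0.25 mm (a 100 x 40 mm field at the
    default pixel size).
    """

    width: int = 400
    height: int = 160
    mm_per_px: float = 0.25
    insertion_frac: tuple[float, float] = (0.94, 0.75)  # (x, y) of P0 in image
    speckle_sigma: float = 1.2
    speckle_amp: float = 0.08
    line_amp: float = 0.5
    line_sigma_px: float = 1.5
    n_parallel: int = 2  # fainter parallel fascicles for texture
    parallel_spacing_px: float = 14.0
    frame_noise_sd: float = 0.0  # per-frame additive noise (0 keeps statics bit-identical)


def _segment_distance(xs, ys, p0, p1):
    """Distance of each grid point to segment p0-p1 (vectorized)."""
    v = np.asarray(p1, float) - np.asarray(p0, float)
    L2 = float(v @ v)
    wx = xs - p0[0]
    wy = ys - p0[1]
    tt = np.clip((wx * v[0] + wy * v[1]) / L2, 0.0, 1.0)
    return np.hypot(wx - tt * v[0], wy - tt * v[1])


def _geometry_at(cfg: ImagingConfig, length_mm: float, pennation_deg: float) -> FascicleGeometry:
    x0 = cfg.insertion_frac[0] * cfg.width
    y0 = cfg.insertion_frac[1] * cfg.height
    L = length_mm / cfg.mm_per_px
    th = np.radians(pennation_deg)
    p1 = np.array([x0 - L * np.cos(th), y0 - L * np.sin(th)])
    return FascicleGeometry(
        endpoints=np.array([[x0, y0], p1]),
        apo_point=np.array([x0, y0]),
        apo_direction=np.array([-1.0, 0.0]),
        mm_per_px=cfg.mm_per_px,
    )


def render_ultrasound(
    truth: FascicleTrace,
    cfg: ImagingConfig = ImagingConfig(),
    fs: float = FS_EMG,
    rng: np.random.Generator | int = 0,
    n_trigger_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray, FascicleGeometry]:
    """Render a speckle image sequence encoding the commanded geometry.

    A static speckle background with the fascicle (plus faint parallel
    neighbours) and the central aponeurosis drawn at the rest geometry is
    rendered once; each frame then warps it with the affine that fixes the
    aponeurosis line pointwise and maps the rest fascicle endpoint onto the
    commanded frame-k endpoint, so frame k encodes ``length_mm[k]`` and
    ``pennation_deg[k]`` exactly in the drawn endpoint coordinates and the
    optical flow has a recoverable affine ground truth.

    Returns ``(frames, trigger, rest_geometry)`` where ``trigger`` is a binary
    trace at ``fs`` with one rising edge per frame.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rest_geom = _geometry_at(cfg, truth.rest_length_mm, truth.pennation_deg[0])
    h, w = cfg.height, cfg.width
    ys, xs = np.mgrid[0:h, 0:w].astype(float)

    base = 0.25 + ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.speckle_sigma)
    base = 0.25 + (base - base.mean()) / base.std() * cfg.speckle_amp

    p0, p1 = rest_geom.endpoints
    fasc_dir = (p1 - p0) / np.linalg.norm(p1 - p0)
    normal = np.array([-fasc_dir[1], fasc_dir[0]])
    for k in range(-cfg.n_parallel, cfg.n_parallel + 1):
        off = normal * k * cfg.parallel_spacing_px
        amp = cfg.line_amp if k == 0 else cfg.line_amp * 0.4
        d = _segment_distance(xs, ys, p0 + off, p1 + off)
        base += amp * np.exp(-(d**2) / (2 * cfg.line_sigma_px**2))
    d_apo = np.abs(ys - p0[1])
    base += cfg.line_amp * 0.8 * np.exp(-(d_apo**2) / (2 * (cfg.line_sigma_px * 1.5) ** 2))
    base = np.clip(base, 0.0, 1.0)

    u0 = p1 - p0
    if abs(u0[1]) < 1e-9:
        raise ValueError("rest fascicle parallel to the aponeurosis; degenerate geometry")
    n_frames = truth.n_frames
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for k in range(n_frames):
        gk = _geometry_at(cfg, truth.length_mm[k], truth.pennation_deg[k])
        if not (
            0 <= gk.endpoints[1, 0] < w and 0 <= gk.endpoints[1, 1] < h
            and 0 <= gk.endpoints[0, 0] < w and 0 <= gk.endpoints[0, 1] < h
        ):
            raise ValueError(f"commanded geometry leaves the image at frame {k}")
        uk = gk.endpoints[1] - p0
        beta = uk[1] / u0[1]
        alpha = (uk[0] - u0[0]) / u0[1]
        # inverse map in (y, x) order for affine_transform
        inv = np.array([[1.0 / beta, 0.0], [-alpha / beta, 1.0]])
        off_yx = np.array([p0[1], p0[0]]) - inv @ np.array([p0[1], p0[0]])
        frame = ndimage.affine_transform(base, inv, offset=off_yx, order=3, mode="nearest")
        if cfg.frame_noise_sd > 0:
            frame = frame + rng.standard_normal((h, w)) * cfg.frame_noise_sd
        frames[k] = frame

    n_total = (
        int(round(n_frames * fs / truth.frame_rate))
        if n_trigger_samples is None
        else int(n_trigger_samples)
    )
    trigger = np.zeros(n_total, dtype=np.int8)
    edges = np.round(np.arange(n_frames) * fs / truth.frame_rate).astype(np.int64)
    pulse = max(int(fs / truth.frame_rate / 2), 1)
    for e in edges:
        trigger[e : e + pulse] = 1
    return frames, trigger, rest_geom


# ---------------------------------------------------------------------------
# trial assembly and persistence
# ---------------------------------------------------------------------------

@dataclass
class TrialRecording:
    """One complete simulated contraction, with its ground truth."""

    emg: np.ndarray | None  # (n_samples, 32)
    torque_pct: np.ndarray
    torque_nm: np.ndarray
    trigger: np.ndarray
    spikes: SpikeTrainSet
    truth_fascicle: FascicleTrace
    truth_delta_fs: np.ndarray
    drive_pct: np.ndarray
    truth_delays_ms: tuple[float, float]
    frame_samples: np.ndarray
    frames: np.ndarray | None
    protocol: ProtocolConfig
    mechanics: MechanicsConfig
    pool: PoolConfig
    seed: int
    mechanics_result: MechanicsResult | None = None

    @property
    def fs(self) -> float:
        return self.protocol.fs

    @property
    def n_samples(self) -> int:
        return int(self.torque_pct.size)

    # -- persistence -------------------------------------------------------

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("torque_pct", "torque_nm", "trigger", "truth_delta_fs",
                         "drive_pct", "frame_samples"):
                f.create_dataset(name, data=getattr(self, name))
            if self.emg is not None:
                f.create_dataset("emg", data=self.emg)
            f.create_dataset("fascicle_length_mm", data=self.truth_fascicle.length_mm)
            f.create_dataset("fascicle_pennation_deg", data=self.truth_fascicle.pennation_deg)
            sp = self.spikes.to_frame()
            f.create_dataset("spike_unit_id", data=sp["unit_id"].to_numpy())
            f.create_dataset("spike_sample_index", data=sp["sample_index"].to_numpy())
            f.attrs["fs"] = self.fs
            f.attrs["frame_rate"] = self.protocol.frame_rate
            f.attrs["rest_length_mm"] = self.truth_fascicle.rest_length_mm
            f.attrs["truth_delays_ms"] = list(self.truth_delays_ms)
            f.attrs["seed"] = self.seed
            f.attrs["protocol_json"] = json.dumps(dataclasses.asdict(self.protocol))
            f.attrs["mechanics_json"] = json.dumps(dataclasses.asdict(self.mechanics))
            f.attrs["pool_json"] = json.dumps(dataclasses.asdict(self.pool))

    @classmethod
    def load_h5(cls, path) -> "TrialRecording":
        import h5py

        with h5py.File(path, "r") as f:
            protocol = ProtocolConfig(**json.loads(f.attrs["protocol_json"]))
            mech = MechanicsConfig(**json.loads(f.attrs["mechanics_json"]))
            pool = PoolConfig(**json.loads(f.attrs["pool_json"]))
            fs = float(f.attrs["fs"])
            import pandas as pd

            spikes = SpikeTrainSet.from_frame(
                pd.DataFrame(
                    {
                        "unit_id": f["spike_unit_id"][()],
                        "sample_index": f["spike_sample_index"][()],
                    }
                ),
                fs,
            )
            trace = FascicleTrace(
                f["fascicle_length_mm"][()],
                f["fascicle_pennation_deg"][()],
                float(f.attrs["frame_rate"]),
                float(f.attrs["rest_length_mm"]),
            )
            return cls(
                emg=f["emg"][()] if "emg" in f else None,
                torque_pct=f["torque_pct"][()],
                torque_nm=f["torque_nm"][()],
                trigger=f["trigger"][()],
                spikes=spikes,
                truth_fascicle=trace,
                truth_delta_fs=f["truth_delta_fs"][()],
                drive_pct=f["drive_pct"][()],
                truth_delays_ms=tuple(f.attrs["truth_delays_ms"]),
                frame_samples=f["frame_samples"][()],
                frames=None,
                protocol=protocol,
                mechanics=mech,
                pool=pool,
                seed=int(f.attrs["seed"]),
            )

    def save_frames_tiff(self, path) -> None:
        import tifffile

        if self.frames is None:
            raise ValueError("trial was simulated without rendered frames")
        tifffile.imwrite(path, self.frames)


def simulate_trial(
    protocol: ProtocolConfig = ProtocolConfig(),
    mechanics: MechanicsConfig = SHORT_TA,
    pool_cfg: PoolConfig = PoolConfig(),
    seed: int = 0,
    with_emg: bool = False,
    with_frames: bool = False,
    imaging: ImagingConfig = ImagingConfig(),
    drive_from: str = "cst",
) -> TrialRecording:
    """Simulate one contraction end to end.

    ``drive_from`` selects whether mechanics are driven by the smoothed CST
    (default; plateau fluctuations then share the units' firing variability,
    which is what the cross-correlation analysis exploits) or by the noiseless
    excitation (``"excitation"``; deterministic mechanics, used for delay-free
    threshold constructions).
    """
    streams = seed_streams(seed)
    pool = build_pool(pool_cfg)
    exc = generate_excitation(protocol)
    spikes = sample_spikes(pool, exc, protocol.fs, streams["isi"])
    source = spikes if drive_from == "cst" else exc
    mres = synthesize_mechanics(source, mechanics, protocol, streams)

    emg = None
    if with_emg:
        lib = make_template_library(pool_cfg.n_units, protocol.fs, streams["templates"])
        emg = synthesize_emg(spikes, lib, protocol.n_samples,
                             mechanics.emg_noise_sd, streams["emg_noise"])

    frames = None
    if with_frames:
        frames, trigger, _ = render_ultrasound(mres.fascicle, imaging, protocol.fs,
                                               streams["speckle"],
                                               n_trigger_samples=protocol.n_samples)
    else:
        n_frames = mres.fascicle.n_frames
        trigger = np.zeros(protocol.n_samples, dtype=np.int8)
        pulse = max(int(protocol.fs / protocol.frame_rate / 2), 1)
        for e in mres.frame_samples:
            trigger[e : e + pulse] = 1

    return TrialRecording(
        emg=emg,
        torque_pct=mres.torque_pct,
        torque_nm=mres.torque_nm,
        trigger=trigger,
        spikes=spikes,
        truth_fascicle=mres.fascicle,
        truth_delta_fs=mres.delta_mm_fs,
        drive_pct=mres.drive_pct,
        truth_delays_ms=mres.applied_delays_ms,
        frame_samples=mres.frame_samples,
        frames=frames,
        protocol=protocol,
        mechanics=mechanics,
        pool=pool_cfg,
        seed=seed,
        mechanics_result=mres,
    )
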