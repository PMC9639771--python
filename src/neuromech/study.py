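"""Study-level orchestration: synchronization, per-trial pipeline, statistics.

Runs the full analysis across a balanced condition grid (muscle length x
torque level x contraction mode), with simulation seeds standing in for
subjects, and aggregates trial results into group tables with paired
contrasts and 95 % confidence intervals.  Also houses the reference
group-mean tables used for worked-example arithmetic (fascicle architecture
and cross-correlation coefficients of a 10-subject tibialis anterior cohort).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import fastrack, simdata, spiketools, thresholds, xcorrlag

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trigger alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriggerMap:
    """Rising-edge sample indices mapping imaging frames onto the EMG clock."""

    edges: np.ndarray  # sample index of frame k's trigger edge
    fs: float
    frame_rate: float
    gap_frames: tuple[int, ...] = ()  # frames preceded by a dropped-pulse gap

    @property
    def n_frames(self) -> int:
        return int(self.edges.size)

    def frame_to_sample(self, k: int) -> int:
        return int(self.edges[k])

    def sample_to_frame(self, s: int) -> int:
        """Index of the frame whose edge is nearest at or before ``s``."""
        return int(np.searchsorted(self.edges, s, side="right") - 1)


def align_trigger(trigger: np.ndarray, fs: float, frame_rate: float) -> TriggerMap:
    """Detect rising edges by half-maximum crossing and map frames to samples.

    Edge spacings larger than 1.5x the nominal frame interval are reported as
    dropped-pulse gaps.
    """
    x = np.asarray(trigger, dtype=float)
    if x.size < 2 or x.max() <= x.min():
        raise ValueError("trigger trace carries no edges")
    thr = (x.max() + x.min()) / 2.0
    above = x >= thr
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    if edges.size < 2:
        raise ValueError("fewer than two trigger edges detected")
    spacing = np.diff(edges)
    nominal = fs / frame_rate
    gaps = tuple(int(i) + 1 for i in np.flatnonzero(spacing > 1.5 * nominal))
    if gaps:
        logger.warning("trigger: %d dropped-pulse gap(s) before frames %s", len(gaps), gaps)
    return TriggerMap(edges=edges.astype(np.int64), fs=fs, frame_rate=frame_rate,
                      gap_frames=gaps)


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """Paired mean difference with its 95 % CI and two-sided paired-t p."""

    mean_diff: float
    ci95: tuple[float, float]
    p: float
    n: int

    def __post_init__(self):
        lo, hi = self.ci95
        if np.isfinite(lo) and not (lo <= self.mean_diff <= hi):
            raise ValueError("CI must bracket the mean difference")


def paired_contrast(x: np.ndarray, y: np.ndarray) -> ContrastResult:
    """Paired t contrast of two equally long per-subject value vectors.

    ``mean_diff = mean(x - y)``; the CI uses the t(0.975, n-1) quantile on the
    paired differences.  Identical vectors take the exact-equality branch
    (zero-width CI, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired_contrast needs two equal-length vectors with n >= 2")
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return ContrastResult(mean, (mean, mean), 1.0 if mean == 0.0 else 0.0, n)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    p = float(stats.ttest_rel(x, y).pvalue)
    return ContrastResult(mean, (mean - half, mean + half), p, n)


def marginal_effect(
    table: pd.DataFrame,
    metric: str,
    factor: str,
    levels: tuple | None = None,
    subject: str = "subject",
) -> ContrastResult:
    """Main effect of a two-level factor, collapsing the other factors.

    Within each subject the metric is averaged over all rows at each level of
    ``factor`` (the design must be balanced: every subject carries the same
    number of rows at both levels), then a paired contrast is taken across
    subjects in ``levels`` order (first minus second).  With a single subject
    row set (e.g. a table of printed condition means) only the collapsed mean
    difference is defined and the CI/p are NaN.
    """
    if factor not in table or metric not in table:
        raise KeyError(f"table must contain columns {factor!r} and {metric!r}")
    if subject not in table:
        table = table.assign(**{subject: 0})
    if levels is None:
        levels = tuple(pd.unique(table[factor]))
    if len(levels) != 2:
        raise ValueError("marginal_effect needs exactly two factor levels")
    sub = table[table[factor].isin(levels)]
    counts = sub.groupby([subject, factor], sort=False)[metric].count().unstack(factor)
    if counts.isna().any().any() or np.unique(counts.to_numpy()).size != 1:
        raise ValueError("unbalanced design: unequal cell counts across subjects/levels")
    collapsed = sub.groupby([subject, factor], sort=False)[metric].mean().unstack(factor)
    a = collapsed[levels[0]].to_numpy()
    b = collapsed[levels[1]].to_numpy()
    if a.size == 1:
        return ContrastResult(float(a[0] - b[0]), (np.nan, np.nan), np.nan, 1)
    return paired_contrast(a, b)


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values for one contrast family."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# reference group-mean tables (worked-example inputs)
# ---------------------------------------------------------------------------

#: Group-mean tibialis anterior architecture (n = 10 cohort): fascicle length
#: (mm) and pennation angle (deg) at rest and on 20/40 %MVC plateaus, for the
#: short (0 deg plantar flexion) and long (30 deg) muscle lengths.
TA_ARCHITECTURE_MEANS = pd.DataFrame(
    [
        ("rest", "short", 60.2, 15.2),
        ("rest", "long", 74.5, 12.0),
        ("20", "short", 52.7, 19.2),
        ("20", "long", 66.3, 16.9),
        ("40", "short", 50.8, 20.8),
        ("40", "long", 61.9, 17.4),
    ],
    columns=["state", "length", "fascicle_mm", "pennation_deg"],
)

#: Group-mean cross-correlation coefficients for the three signal pairings in
#: each of the four conditions (length x level), separately for steady and
#: sinusoidal contraction types.
XCORR_COEFFICIENT_MEANS = pd.DataFrame(
    [
        ("steady", "torque-cst", "short", 20, 0.74),
        ("steady", "torque-cst", "long", 20, 0.74),
        ("steady", "torque-cst", "short", 40, 0.74),
        ("steady", "torque-cst", "long", 40, 0.61),
        ("steady", "fascicle-cst", "short", 20, 0.64),
        ("steady", "fascicle-cst", "long", 20, 0.57),
        ("steady", "fascicle-cst", "short", 40, 0.63),
        ("steady", "fascicle-cst", "long", 40, 0.50),
        ("steady", "torque-fascicle", "short", 20, 0.71),
        ("steady", "torque-fascicle", "long", 20, 0.67),
        ("steady", "torque-fascicle", "short", 40, 0.78),
        ("steady", "torque-fascicle", "long", 40, 0.72),
        ("sinusoidal", "torque-cst", "short", 20, 0.78),
        ("sinusoidal", "torque-cst", "long", 20, 0.77),
        ("sinusoidal", "torque-cst", "short", 40, 0.77),
        ("sinusoidal", "torque-cst", "long", 40, 0.66),
        ("sinusoidal", "fascicle-cst", "short", 20, 0.71),
        ("sinusoidal", "fascicle-cst", "long", 20, 0.73),
        ("sinusoidal", "fascicle-cst", "short", 40, 0.74),
        ("sinusoidal", "fascicle-cst", "long", 40, 0.62),
        ("sinusoidal", "torque-fascicle", "short", 20, 0.87),
        ("sinusoidal", "torque-fascicle", "long", 20, 0.89),
        ("sinusoidal", "torque-fascicle", "short", 40, 0.91),
        ("sinusoidal", "torque-fascicle", "long", 40, 0.89),
    ],
    columns=["contraction", "pairing", "length", "level", "coefficient"],
)


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------

@dataclass
class TrialAnalysis:
    """Everything the pipeline extracts from one trial."""

    xcorr: dict[str, xcorrlag.XcorrSummary]
    threshold_records: list[thresholds.ThresholdRecord]
    segments: thresholds.ContractionSegments
    mean_rates_hz: dict[int, float]
    cleaning: dict[int, spiketools.CleaningFlags]


def delta_on_emg_timeline(
    trace: fastrack.FascicleTrace,
    trigger_map: TriggerMap,
    n_samples: int,
) -> np.ndarray:
    """Fascicle shortening interpolated to the EMG rate, edge-padded.

    Outside [first edge, last edge] the nearest frame value is held so the
    array aligns sample-for-sample with the torque trace.
    """
    vals, start = fastrack.resample_to_emg(trace.delta_mm, trigger_map.edges)
    out = np.empty(n_samples)
    out[:start] = vals[0]
    out[start : start + vals.size] = vals
    out[start + vals.size :] = vals[-1]
    return out


def analyze_trial(
    trial: simdata.TrialRecording,
    win_s: float = 5.0,
    overlap: float = 0.5,
    lag_max_ms: float = 1000.0,
    seg_opts: thresholds.SegmentationOptions = thresholds.SegmentationOptions(),
) -> TrialAnalysis:
    """Run the full single-trial pipeline.

    Cleans the spike trains, builds the CST, puts the (measured) fascicle
    trace on the EMG timeline through the trigger, conditions all three
    signals into the fluctuation band, segments the contraction on the torque
    trace, windows the plateau for the three cross-correlation pairings, and
    reads the dual-coordinate thresholds on the ramps.
    """
    fs = trial.fs
    cleaned = []
    cleaning = {}
    for t in trial.spikes:
        ct, fl = spiketools.clean_discharges(t)
        cleaned.append(ct)
        cleaning[t.unit_id] = fl
    spikeset = spiketools.SpikeTrainSet(tuple(cleaned), fs)
    cst = spiketools.cumulative_spike_train(spikeset, trial.n_samples)

    tmap = align_trigger(trial.trigger, fs, trial.protocol.frame_rate)
    delta_fs = delta_on_emg_timeline(trial.truth_fascicle, tmap, trial.n_samples)

    segments = thresholds.segment_contraction(
        trial.torque_pct, trial.protocol.target_level, fs, seg_opts
    )

    c_cst = xcorrlag.condition_signal(cst.counts, fs, "cst")
    c_torque = xcorrlag.condition_signal(trial.torque_pct, fs, "torque")
    c_fasc = xcorrlag.condition_signal(delta_fs, fs, "fascicle")
    lo, hi = segments.plateau
    xc = xcorrlag.delay_matrix(
        c_cst.crop(lo, hi), c_torque.crop(lo, hi), c_fasc.crop(lo, hi),
        win_s=win_s, overlap=overlap, lag_max_ms=lag_max_ms,
    )

    recs = thresholds.threshold_records(spikeset, trial.torque_pct, delta_fs, segments)
    rates = {
        t.unit_id: spiketools.discharge_rate_stats(t, segments.plateau)[0]
        for t in spikeset
    }
    return TrialAnalysis(
        xcorr=xc,
        threshold_records=recs,
        segments=segments,
        mean_rates_hz=rates,
        cleaning=cleaning,
    )


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Simulated-cohort configuration.

    Subjects are simulation seeds with +/-``subject_jitter`` uniform parameter
    scatter on rest length, delays and MVC torque so group dispersion is
    nonzero; n defaults to 10.
    """

    n_subjects: int = 10
    levels: tuple = (20.0, 40.0)
    lengths: tuple = ("short", "long")
    modes: tuple = ("sustained", "sinusoidal")
    plateau_s: float = 30.0
    subject_jitter: float = 0.10
    master_seed: int = 0
    win_s: float = 5.0
    overlap: float = 0.5
    lag_max_ms: float = 1000.0


def _subject_mechanics(base: simdata.MechanicsConfig, rng: np.random.Generator,
                       jitter: float) -> simdata.MechanicsConfig:
    j = lambda: 1.0 + rng.uniform(-jitter, jitter)
    return dataclasses.replace(
        base,
        rest_length_mm=base.rest_length_mm * j(),
        delay_drive_to_fascicle_ms=base.delay_drive_to_fascicle_ms * j(),
        delay_fascicle_to_torque_ms=base.delay_fascicle_to_torque_ms * j(),
        torque_mvc_nm=base.torque_mvc_nm * j(),
    )


@dataclass
class StudyReport:
    windows: pd.DataFrame  # per-window xcorr results
    summaries: pd.DataFrame  # per-trial pairing means
    thresholds: pd.DataFrame  # per-unit threshold records
    contrasts: pd.DataFrame  # group-level marginal effects
    config: StudyConfig

    def write(self, outdir) -> None:
        """Write the report as deterministic CSV/JSON files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.6f"
        self.windows.to_csv(out / "windows.csv", index=False, float_format=fmt)
        self.summaries.to_csv(out / "summaries.csv", index=False, float_format=fmt)
        self.thresholds.to_csv(out / "thresholds.csv", index=False, float_format=fmt)
        self.contrasts.to_csv(out / "contrasts.csv", index=False, float_format=fmt)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2, default=str) + "\n"
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        fmt = "%.6f"
        for df in (self.windows, self.summaries, self.thresholds, self.contrasts):
            h.update(df.to_csv(index=False, float_format=fmt).encode())
        return h.hexdigest()


def run_pipeline(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Simulate and analyze a full condition grid of trials.

    Any per-trial failure aborts that trial with a logged reason, not the
    run.  Fully reproducible from the master seed.
    """
    base = {"short": simdata.SHORT_TA, "long": simdata.LONG_TA}
    rows_w, rows_s, rows_t = [], [], []
    subj_ss = np.random.SeedSequence(config.master_seed).spawn(config.n_subjects)
    for s_idx, ss in enumerate(subj_ss):
        jit_rng = np.random.default_rng(ss)
        trial_seed_base = int(jit_rng.integers(0, 2**31 - 10000))
        mech_by_len = {
            ln: _subject_mechanics(base[ln], jit_rng, config.subject_jitter)
            for ln in config.lengths
        }
        for li, length in enumerate(config.lengths):
            for vi, level in enumerate(config.levels):
                for mi, mode in enumerate(config.modes):
                    seed = trial_seed_base + li * 100 + vi * 10 + mi
                    try:
                        trial = simdata.simulate_trial(
                            protocol=simdata.ProtocolConfig(
                                target_level=level, mode=mode,
                                plateau_s=config.plateau_s,
                            ),
                            mechanics=mech_by_len[length],
                            seed=seed,
                        )
                        ana = analyze_trial(
                            trial, win_s=config.win_s, overlap=config.overlap,
                            lag_max_ms=config.lag_max_ms,
                        )
                    except Exception:
                        logger.exception(
                            "trial failed (subject %d, %s, %g%%, %s); skipped",
                            s_idx, length, level, mode,
                        )
                        continue
                    key = dict(subject=s_idx, length=length, level=level, mode=mode)
                    for pairing, summ in ana.xcorr.items():
                        df = summ.to_frame()
                        for col, val in key.items():
                            df[col] = val
                        rows_w.append(df)
                        rows_s.append(
                            {**key, "pairing": pairing,
                             "mean_coefficient": summ.mean_coefficient,
                             "mean_lag_ms": summ.mean_lag_ms,
                             "n_windows": summ.n_windows}
                        )
                    tdf = thresholds.records_to_frame(ana.threshold_records)
                    for col, val in key.items():
                        tdf[col] = val
                    tdf["mean_rate_hz"] = tdf["unit_id"].map(ana.mean_rates_hz)
                    rows_t.append(tdf)

    windows = pd.concat(rows_w, ignore_index=True)
    summaries = pd.DataFrame(rows_s)
    thr = pd.concat(rows_t, ignore_index=True)

    contrasts = []
    fam = []
    for pairing in summaries["pairing"].unique():
        sub = summaries[summaries["pairing"] == pairing]
        for metric in ("mean_coefficient", "mean_lag_ms"):
            for factor, levels in (("level", tuple(config.levels)),
                                   ("length", tuple(config.lengths)),
                                   ("mode", tuple(config.modes))):
                if len(levels) != 2:
                    continue
                try:
                    c = marginal_effect(sub, metric, factor, levels)
                except ValueError:
                    continue
                fam.append(c.p)
                contrasts.append(
                    {"family": f"{pairing}:{metric}", "factor": factor,
                     "mean_diff": c.mean_diff, "ci_lo": c.ci95[0],
                     "ci_hi": c.ci95[1], "p": c.p, "n": c.n}
                )
    cdf = pd.DataFrame(contrasts)
    if not cdf.empty:
        cdf["p_bonferroni"] = cdf.groupby("family")["p"].transform(
            lambda p: np.minimum(1.0, p * p.size)
        )
    return StudyReport(windows=windows, summaries=summaries, thresholds=thr,
                       contrasts=cdf, config=config)
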