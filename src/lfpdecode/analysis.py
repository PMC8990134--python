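"""Descriptive analyses: gait-locked ERD/ERS maps, mutual information,
group statistics and cadence effects.

Mutual information is estimated by adaptive partitioning of the
rank-transformed observation space (recursive quadrant splits accepted while
a chi-square test rejects uniformity) and reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .bands import CANONICAL_BANDS, FEATURE_NAMES
from .preprocess import (
    EnvelopeSeries,
    align_targets,
    bandpass_bank,
    compute_alfp,
    compute_envelopes,
    remove_line_noise,
)
from .session import JOINT_NAMES, Session
from .synth import cadence_group

__all__ = [
    "GaitCycleSet",
    "TFMap",
    "MIMatrix",
    "StatsResult",
    "CadenceComparison",
    "segment_gait_cycles",
    "cycle_average",
    "mutual_information",
    "mi_analysis",
    "compare_groups",
    "cadence_analysis",
    "session_envelopes",
]


# ---------------------------------------------------------------------------
# gait cycles
# ---------------------------------------------------------------------------


@dataclass
class GaitCycleSet:
    """Cycle onset times; normalized phase is interpolated between onsets."""

    boundaries: np.ndarray  # strictly increasing onset times, seconds

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.boundaries) < 3:
            raise ValueError("need at least 2 full cycles")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        """Normalized phase in [0, 1) for each time; NaN outside the cycles."""
        t = np.asarray(times, dtype=float)
        cyc = np.searchsorted(self.boundaries, t, side="right") - 1
        phase = np.full(t.shape, np.nan)
        ok = (cyc >= 0) & (cyc < self.n_cycles)
        b0 = self.boundaries[cyc[ok]]
        b1 = self.boundaries[cyc[ok] + 1]
        phase[ok] = (t[ok] - b0) / (b1 - b0)
        return phase


def segment_gait_cycles(
    session: Session | None = None,
    kinematics: np.ndarray | None = None,
    fs: float | None = None,
) -> GaitCycleSet:
    """Detect gait-cycle onsets.

    Synthetic sessions carry the ground-truth phase (cadence and phase
    origin), so onsets fall at exact multiples of the cycle period.  For
    generic kinematics, onsets are the peaks of the hip angle (low-passed at
    twice the dominant stepping frequency).
    """
    if session is not None and session.meta.get("synthetic"):
        cadence = session.meta["cadence"]
        duration = session.kinematics.shape[1] / session.kinematic_fs
        n_cycles = int(np.floor(duration * cadence))
        if n_cycles < 2:
            raise ValueError("fewer than 2 full cycles in the session")
        return GaitCycleSet(boundaries=np.arange(n_cycles + 1) / cadence)
    if session is not None:
        kinematics, fs = session.kinematics, session.kinematic_fs
    if kinematics is None or fs is None:
        raise ValueError("need a session or (kinematics, fs)")
    hip = np.atleast_2d(np.asarray(kinematics, dtype=float))[0]
    if np.ptp(hip) < 1e-9:
        raise ValueError("kinematics are constant; no detectable gait")
    # dominant stepping frequency from the periodogram
    f, p = sps.periodogram(hip - hip.mean(), fs=fs)
    valid = f > 0.1
    if not valid.any() or p[valid].max() <= 0:
        raise ValueError("no detectable periodicity in the hip angle")
    f0 = f[valid][np.argmax(p[valid])]
    total_power = p.sum()
    if p[valid].max() < 0.05 * total_power:
        raise ValueError("no detectable periodicity in the hip angle")
    sos = sps.butter(4, min(2 * f0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, hip)
    peaks, _ = sps.find_peaks(smooth, distance=max(1, int(0.5 * fs / f0)))
    if len(peaks) < 3:
        raise ValueError("fewer than 2 full cycles detected")
    return GaitCycleSet(boundaries=peaks / fs)


# ---------------------------------------------------------------------------
# gait-locked time-frequency maps (ERD/ERS)
# ---------------------------------------------------------------------------


@dataclass
class TFMap:
    """Cycle-averaged envelope per channel x band x phase bin.

    ``percent_change`` is the deviation of each bin from the cycle mean in
    percent: positive values are event-related synchronization (ERS),
    negative values desynchronization (ERD).
    """

    mean_envelope: np.ndarray  # (channel, band, bins)
    percent_change: np.ndarray  # (channel, band, bins)
    n_bins: int
    band_names: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

    def peak_bin(self, channel: int, band: int, smooth: int = 5) -> int:
        """Phase bin of the ERS peak.

        ``smooth`` applies a circular moving average over that many bins
        before the argmax, suppressing single-bin sampling noise (1 keeps
        the raw profile).
        """
        prof = self.percent_change[channel, band]
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            circ = np.real(
                np.fft.ifft(np.fft.fft(prof) * np.fft.fft(kernel, len(prof)))
            )
            prof = np.roll(circ, -(smooth // 2))  # re-centre the average
        return int(np.argmax(prof))


def cycle_average(
    envelopes: EnvelopeSeries, cycles: GaitCycleSet, bins: int = 100
) -> TFMap:
    """Average the band envelopes over gait cycles into phase bins."""
    if cycles.n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    phase = cycles.phase_of(envelopes.times)
    ok = np.isfinite(phase)
    if ok.sum() < bins:
        raise ValueError("too few envelope samples inside the cycles")
    bin_idx = np.minimum((phase[ok] * bins).astype(int), bins - 1)
    vals = envelopes.values[ok]  # (time, channel, band)
    n_ch, n_band = vals.shape[1], vals.shape[2]
    sums = np.zeros((bins, n_ch, n_band))
    counts = np.bincount(bin_idx, minlength=bins).astype(float)
    for b in range(bins):
        sel = bin_idx == b
        if sel.any():
            sums[b] = vals[sel].mean(axis=0)
    if np.any(counts == 0):
        raise ValueError("empty phase bins; use fewer bins or more cycles")
    mean_env = np.moveaxis(sums, 0, 2)  # (channel, band, bins)
    cycle_mean = mean_env.mean(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (mean_env - cycle_mean) / cycle_mean * 100.0
    pct = np.where(cycle_mean > 0, pct, 0.0)
    return TFMap(mean_envelope=mean_env, percent_change=pct, n_bins=bins)


def phase_shuffled_excursion(
    envelopes: EnvelopeSeries,
    cycles: GaitCycleSet,
    channel: int,
    band: int,
    bins: int = 100,
    n_shuffles: int = 200,
    seed: int = 0,
    quantile: float = 0.95,
) -> float:
    """Surrogate threshold for ERD/ERS excursions of one channel/band.

    Circularly shifts the envelope relative to the gait phase and returns
    the requested quantile of the surrogate max |percent change|.
    """
    rng = np.random.default_rng(seed)
    vals = envelopes.values[:, channel : channel + 1, band : band + 1]
    maxima = np.empty(n_shuffles)
    n = len(envelopes.times)
    for s in range(n_shuffles):
        shift = int(rng.integers(1, n - 1))
        rolled = EnvelopeSeries(
            values=np.roll(vals, shift, axis=0),
            times=envelopes.times,
            bands=envelopes.bands,
        )
        tf = cycle_average(rolled, cycles, bins=bins)
        maxima[s] = np.abs(tf.percent_change[0, 0]).max()
    return float(np.quantile(maxima, quantile))


# ---------------------------------------------------------------------------
# mutual information (adaptive partitioning)
# ---------------------------------------------------------------------------

_CHI2_DOF = 3


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    min_cell: int = 8,
) -> float:
    """Mutual information in bits by adaptive partitioning.

    Both variables are rank-transformed (uniform marginals); the rank plane
    is then partitioned recursively: a cell is split into its four quadrants
    (at the midpoints of its rank extents) while a chi-square test at level
    ``alpha`` rejects uniformity of the four counts and the cell holds at
    least ``4 * min_cell`` points.  MI is summed over the final cells and
    floored at zero.  Constant inputs give 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    n = x.size
    if n < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    crit = stats.chi2.isf(alpha, _CHI2_DOF)

    mi = 0.0
    # stack of (x_lo, x_hi, y_lo, y_hi, point index array); bounds are open
    # at the low edge, closed at the high edge, in rank coordinates (0, n].
    stack = [(0.0, float(n), 0.0, float(n), np.arange(n))]
    log2n = np.log2(n)
    while stack:
        x_lo, x_hi, y_lo, y_hi, idx = stack.pop()
        cnt = idx.size
        if cnt == 0:
            continue
        xm = (x_lo + x_hi) / 2.0
        ym = (y_lo + y_hi) / 2.0
        split = False
        if cnt >= 4 * min_cell:
            right = rx[idx] > xm
            top = ry[idx] > ym
            quads = [
                idx[~right & ~top],
                idx[right & ~top],
                idx[~right & top],
                idx[right & top],
            ]
            e = cnt / 4.0
            chi2 = sum((q.size - e) ** 2 for q in quads) / e
            if chi2 > crit:
                split = True
        if split:
            stack.append((x_lo, xm, y_lo, ym, quads[0]))
            stack.append((xm, x_hi, y_lo, ym, quads[1]))
            stack.append((x_lo, xm, ym, y_hi, quads[2]))
            stack.append((xm, x_hi, ym, y_hi, quads[3]))
        else:
            p = cnt / n
            px = (x_hi - x_lo) / n
            py = (y_hi - y_lo) / n
            mi += p * (np.log2(p) - np.log2(px) - np.log2(py))
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# MI analysis across sessions
# ---------------------------------------------------------------------------


@dataclass
class MIMatrix:
    """MI (bits) per channel x feature type (6 bands + ALFP) x joint."""

    values: np.ndarray  # (n_channels, 7, 6)
    session_id: str = ""
    feature_names: tuple[str, ...] = FEATURE_NAMES
    joint_names: tuple[str, ...] = JOINT_NAMES

    def band_average(self) -> np.ndarray:
        """Mean MI per feature type, averaged over channels and joints."""
        return self.values.mean(axis=(0, 2))

    def channel_average(self) -> np.ndarray:
        """Mean MI per channel, averaged over feature types and joints."""
        return self.values.mean(axis=(1, 2))

    def per_leg(self) -> dict[str, np.ndarray]:
        """Mean over the three joints of each leg: feature x channel views."""
        return {
            "left": self.values[:, :, :3].mean(axis=2),
            "right": self.values[:, :, 3:].mean(axis=2),
        }


def session_envelopes(session: Session):
    """Preprocess a session to (EnvelopeSeries, ALFPSeries, targets).

    Targets are the six joint angles aligned to the shared 10 Hz grid.
    """
    clean = remove_line_noise(session.neural, session.neural_fs)
    band_sig = bandpass_bank(clean, CANONICAL_BANDS, session.neural_fs)
    envs = compute_envelopes(band_sig, session.neural_fs)
    alfp = compute_alfp(clean, session.neural_fs)
    targets = align_targets(session.kinematics, session.kinematic_fs, envs.times)
    return envs, alfp, targets


def mi_matrix(session: Session) -> MIMatrix:
    """MI between every feature series and every joint angle of a session."""
    envs, alfp, targets = session_envelopes(session)
    n_ch = envs.values.shape[1]
    out = np.zeros((n_ch, len(FEATURE_NAMES), len(JOINT_NAMES)))
    for c in range(n_ch):
        feats = [envs.values[:, c, b] for b in range(len(CANONICAL_BANDS))]
        feats.append(alfp.values[:, c])
        for fi, fv in enumerate(feats):
            for j in range(len(JOINT_NAMES)):
                out[c, fi, j] = mutual_information(fv, targets[j])
    return MIMatrix(values=out, session_id=str(session.meta.get("seed", "")))


def mi_analysis(sessions: list[Session]) -> tuple[list[MIMatrix], MIMatrix]:
    """Per-session MI matrices and their average over sessions."""
    if not sessions:
        raise ValueError("need at least one session")
    mats = [mi_matrix(s) for s in sessions]
    avg = MIMatrix(
        values=np.mean([m.values for m in mats], axis=0), session_id="average"
    )
    return mats, avg


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass
class StatsResult:
    """ANOVA table plus Tukey HSD pairwise comparisons at alpha."""

    anova: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    alpha: float = 0.05

    def significant_pairs(self, factor: str) -> list[tuple[str, str]]:
        t = self.tukey[factor]
        return [
            (row["group1"], row["group2"])
            for _, row in t.iterrows()
            if row["reject"]
        ]


def compare_groups(
    data: pd.DataFrame,
    value: str,
    factors: list[str] | str,
    alpha: float = 0.05,
) -> StatsResult:
    """One- or two-way ANOVA followed by Tukey HSD post hoc comparisons."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor '{f}' needs at least 2 levels")
    counts = data.groupby(factors, observed=True)[value].count()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 observations")
    df = data.rename(columns={value: "_value"})
    rhs = " + ".join(f"C({f})" for f in factors)
    model = ols(f"_value ~ {rhs}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    tukey = {}
    for f in factors:
        res = pairwise_tukeyhsd(df["_value"], df[f].astype(str), alpha=alpha)
        tukey[f] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return StatsResult(anova=anova, tukey=tukey, alpha=alpha)


# ---------------------------------------------------------------------------
# cadence effects
# ---------------------------------------------------------------------------


@dataclass
class CadenceComparison:
    """Per-band envelope comparison between lower- and higher-cadence groups."""

    table: pd.DataFrame  # band, mean_lower, mean_higher, t, p, significant
    alpha: float = 0.05

    @property
    def significant_bands(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "band"])


def _session_band_means(session: Session) -> np.ndarray:
    """Mean envelope per band during movement (samples inside gait cycles)."""
    envs, _, _ = session_envelopes(session)
    cycles = segment_gait_cycles(session=session)
    phase = cycles.phase_of(envs.times)
    ok = np.isfinite(phase)
    if not ok.any():
        raise ValueError("no envelope samples inside the gait cycles")
    return envs.values[ok].mean(axis=(0, 1))  # (band,)


def cadence_analysis(sessions: list[Session], alpha: float = 0.05) -> CadenceComparison:
    """Per-band mean envelope by cadence group with Welch t-tests.

    Sessions are grouped by their cadence against the 0.67 / 0.73 steps/s
    thresholds; sessions between the thresholds are excluded.
    """
    lower, higher = [], []
    for s in sessions:
        cad = s.meta.get("cadence")
        if cad is None:
            raise ValueError("session lacks cadence metadata")
        grp = cadence_group(cad)
        if grp == "lower":
            lower.append(_session_band_means(s))
        elif grp == "higher":
            higher.append(_session_band_means(s))
    if not lower or not higher:
        raise ValueError("need at least one session in each cadence group")
    lo = np.vstack(lower)
    hi = np.vstack(higher)
    rows = []
    for b, band in enumerate(CANONICAL_BANDS):
        t, p = stats.ttest_ind(lo[:, b], hi[:, b], equal_var=False)
        rows.append(
            {
                "band": band.name,
                "mean_lower": lo[:, b].mean(),
                "mean_higher": hi[:, b].mean(),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return CadenceComparison(table=pd.DataFrame(rows), alpha=alpha)
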