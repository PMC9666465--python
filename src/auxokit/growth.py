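"""Growth-curve analysis: rate fitting, doubling accounting, auxotrophy calls.

The experimental design this module analyses is a semi-continuous batch
culture: a strain grows exponentially in a plate reader, is diluted with
fresh medium after every ~2 doublings to stay inside the detector's linear
range, and is monitored in two arms — a vitamin-supplemented control and a
vitamin-depleted condition. An auxotroph with an intracellular coenzyme
reserve keeps doubling after vitamin withdrawal until the reserve is diluted
out by growth, then arrests. The number of doublings performed without the
vitamin quantifies the storage (a reserve of d doublings is a 2**d fold
excess coenzyme pool).

Growth rates are slopes of ordinary least squares fits on ln-transformed,
dilution-corrected OD. A strain is called auxotrophic ("deviating") for a
vitamin when the depleted cultures fall >= 0.25 doublings behind the mean
supplemented control AND the post-separation growth rate is reduced by
>= 25% in at least two of three replicates and >= 10% in the remaining one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

__all__ = [
    "ODTimeSeries",
    "GrowthFit",
    "DeviationThresholds",
    "DeviationCall",
    "AuxotrophyMatrix",
    "blank_normalize",
    "fit_growth_rate",
    "cumulative_doublings",
    "detect_deviation",
    "storage_fold_excess",
    "build_auxotrophy_matrix",
]


@dataclass
class ODTimeSeries:
    """A blank-normalized optical density trajectory for one well.

    Parameters
    ----------
    time_h : array of strictly increasing sampling times in hours.
    od : optical density readings (dimensionless, blank subtracted).
    strain, replicate : identifiers.
    condition : ``"supplemented"`` or ``"depleted:<vitamin>"``.
    dilution_events : list of ``(time_h, factor)`` with factor > 1. A reading
        at exactly the event time is post-dilution.
    flags : per-point quality marks; the empty string means usable. Flagged
        points are retained but excluded from all fits and doubling sums.
    """

    time_h: np.ndarray
    od: np.ndarray
    strain: str = "strain"
    replicate: str = "1"
    condition: str = "supplemented"
    dilution_events: list[tuple[float, float]] = field(default_factory=list)
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.od.shape:
            raise ValueError("time_h and od must be 1-D arrays of equal length")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be strictly increasing")
        for t, f in self.dilution_events:
            if f <= 1:
                raise ValueError(f"dilution factor must exceed 1, got {f}")
        if self.flags is None:
            self.flags = np.full(self.time_h.shape, "", dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.time_h.shape:
                raise ValueError("flags must align with time_h")

    @property
    def ok(self) -> np.ndarray:
        """Boolean mask of usable (unflagged) readings."""
        return np.asarray([f == "" for f in self.flags], dtype=bool)

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True)
class GrowthFit:
    """An OLS exponential-phase fit on (time, ln OD)."""

    rate: float  # per hour
    intercept: float  # ln OD at window start
    r_squared: float
    window: tuple[float, float]
    n_points: int
    doublings_in_window: float
    rate_stderr: float = float("nan")  # OLS standard error of the slope


@dataclass(frozen=True)
class DeviationThresholds:
    """Criteria for calling a depleted culture deviating from its control."""

    doubling_gap: float = 0.25
    rate_drop_major: float = 0.25
    rate_drop_minor: float = 0.10
    majority: int = 2  # replicates that must satisfy the major reduction

    def __post_init__(self) -> None:
        if not (0 < self.rate_drop_minor <= self.rate_drop_major < 1):
            raise ValueError("need 0 < minor <= major < 1")
        if self.doubling_gap <= 0:
            raise ValueError("doubling_gap must be positive")


@dataclass(frozen=True)
class DeviationCall:
    """Auxotrophy verdict for one strain x vitamin."""

    strain: str
    vitamin: str
    deviated: bool
    deviation_time_h: float | None
    storage_doublings: float | None
    per_replicate_rate_reduction: tuple[float, ...]
    thresholds: DeviationThresholds


class AuxotrophyMatrix(NamedTuple):
    deviated: pd.DataFrame  # strain x vitamin booleans
    storage: pd.DataFrame  # strain x vitamin storage doublings (NaN if none)


def blank_normalize(
    raw_plate: pd.DataFrame, blank_wells: Sequence[str]
) -> list[ODTimeSeries]:
    """Subtract the per-timepoint mean of blank (cell-free) wells.

    ``raw_plate`` is long format with columns ``time_h``, ``well``, ``od`` and
    optional ``strain``, ``replicate``, ``condition``. Returns one series per
    non-blank well; blank-corrected values <= 0 are flagged ``nonpositive``.
    """
    required = {"time_h", "well", "od"}
    missing = required - set(raw_plate.columns)
    if missing:
        raise ValueError(f"raw_plate missing columns: {sorted(missing)}")
    blank_wells = list(blank_wells)
    blanks = raw_plate[raw_plate["well"].isin(blank_wells)]
    if blanks.empty:
        raise ValueError("no blank wells present in the plate table")
    blank_mean = blanks.groupby("time_h")["od"].mean()
    times_needed = set(raw_plate["time_h"].unique())
    if not times_needed <= set(blank_mean.index):
        raise ValueError("blank wells missing at some time points")

    out: list[ODTimeSeries] = []
    samples = raw_plate[~raw_plate["well"].isin(blank_wells)]
    for well, grp in samples.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        corrected = grp["od"].to_numpy() - blank_mean.loc[grp["time_h"]].to_numpy()
        flags = np.where(corrected <= 0, "nonpositive", "").astype(object)
        series = ODTimeSeries(
            time_h=grp["time_h"].to_numpy(),
            od=corrected,
            strain=str(grp["strain"].iloc[0]) if "strain" in grp else str(well),
            replicate=str(grp["replicate"].iloc[0]) if "replicate" in grp else "1",
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else "supplemented",
            flags=flags,
        )
        if not series.ok.any():
            warnings.warn(f"well {well}: blank exceeds sample OD everywhere")
        out.append(series)
    return out


def _corrected_log2(series: ODTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Unflagged times and dilution-corrected log2 OD (not yet zeroed)."""
    ok = series.ok
    t = series.time_h[ok]
    od = series.od[ok]
    if np.any(od <= 0):
        raise ValueError("nonpositive OD in an unflagged point")
    corr = np.zeros_like(t)
    for te, f in series.dilution_events:
        corr += np.where(t >= te, math.log2(f), 0.0)
    return t, np.log2(od) + corr


def cumulative_doublings(series: ODTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-corrected cumulative doublings at each unflagged reading.

    doublings(t_k) = sum over consecutive readings of log2(od_{k+1}/od_k),
    with log2(factor) added back for each dilution event, so transfers to
    fresh medium do not reduce the count. The first unflagged reading is the
    zero point. Noise may cause small non-monotonic dips; none are enforced
    away.
    """
    t, y = _corrected_log2(series)
    if t.size == 0:
        raise ValueError("series has no usable points")
    return t, y - y[0]


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept at t[0], and r^2 of a least-squares line."""
    slope, icept = np.polyfit(t, y, 1)
    resid = y - (slope * t + icept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(slope * t[0] + icept), r2


def _window_rate(
    series: ODTimeSeries, t_start: float, t_end: float, min_points: int = 3
) -> tuple[float, float, int]:
    """Plain OLS rate (1/h) on corrected ln OD inside [t_start, t_end]."""
    t, y2 = _corrected_log2(series)
    m = (t >= t_start) & (t <= t_end)
    if int(m.sum()) < min_points:
        raise ValueError(
            f"window [{t_start:.2f}, {t_end:.2f}] h has fewer than {min_points} usable points"
        )
    slope, _, r2 = _ols(t[m], y2[m] * LN2)
    return slope, r2, int(m.sum())


def fit_growth_rate(
    series: ODTimeSeries,
    min_doublings: float = 2.0,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> GrowthFit | None:
    """Best exponential-phase OLS fit on ln-transformed, dilution-corrected OD.

    Searches all contiguous windows of >= ``min_points`` unflagged readings
    (optionally restricted to ``window``), keeps those spanning at least
    ``min_doublings`` doublings, and returns the one maximising r^2 (ties
    broken toward the earliest, then shortest window). Returns ``None`` — a
    no-rate outcome, not an error — when no window qualifies. Raises if every
    point is flagged.
    """
    if not series.ok.any():
        raise ValueError("all points flagged; nothing to fit")
    t, y2 = _corrected_log2(series)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y2 = t[m], y2[m]
    n = t.size
    if n < min_points:
        return None
    y = y2 * LN2  # natural log of corrected OD

    best: tuple[float, int, int] | None = None  # (-r2, i, j)
    # prefix sums give O(1) OLS per window
    one = np.ones(n)
    St = np.concatenate(([0.0], np.cumsum(t)))
    Sy = np.concatenate(([0.0], np.cumsum(y)))
    Stt = np.concatenate(([0.0], np.cumsum(t * t)))
    Sty = np.concatenate(([0.0], np.cumsum(t * y)))
    Syy = np.concatenate(([0.0], np.cumsum(y * y)))
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            k = j - i + 1
            st = St[j + 1] - St[i]
            sy = Sy[j + 1] - Sy[i]
            stt = Stt[j + 1] - Stt[i]
            sty = Sty[j + 1] - Sty[i]
            syy = Syy[j + 1] - Syy[i]
            denom = k * stt - st * st
            if denom <= 0:
                continue
            slope = (k * sty - st * sy) / denom
            doublings = slope * (t[j] - t[i]) / LN2
            if doublings < min_doublings:
                continue
            ss_tot = syy - sy * sy / k
            ss_res = max(0.0, ss_tot - slope * slope * denom / k)
            r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
            key = (-round(r2, 12), i, j)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    _, i, j = best
    tw, yw = t[i : j + 1], y[i : j + 1]
    slope, icept, r2 = _ols(tw, yw)
    k = tw.size
    resid = yw - (slope * (tw - tw[0]) + icept)
    sxx = float(np.sum((tw - tw.mean()) ** 2))
    stderr = math.sqrt(float(np.sum(resid**2)) / (k - 2) / sxx) if k > 2 and sxx > 0 else float("nan")
    return GrowthFit(
        rate=slope,
        intercept=icept,
        r_squared=r2,
        window=(float(tw[0]), float(tw[-1])),
        n_points=k,
        doublings_in_window=slope * (tw[-1] - tw[0]) / LN2,
        rate_stderr=stderr,
    )


def detect_deviation(
    depleted_reps: Sequence[ODTimeSeries],
    control_reps: Sequence[ODTimeSeries],
    thresholds: DeviationThresholds = DeviationThresholds(),
    post_window_h: float = 2.0,
    post_window_points: int = 6,
    allow_fewer_replicates: bool = False,
) -> DeviationCall:
    """Apply the deviation criteria to paired depleted/control replicates.

    Procedure: (1) average the control replicates' cumulative-doubling curves;
    (2) per depleted replicate, find the earliest time at which the mean
    control leads by >= ``doubling_gap`` doublings; (3) fit that replicate's
    growth rate over a post-separation window of max(``post_window_h`` hours,
    ``post_window_points`` readings) and express it as a reduction relative to
    the same replicate's pre-separation rate; (4) the strain deviates if the
    reduction reaches ``rate_drop_major`` in at least ``majority`` replicates
    and ``rate_drop_minor`` in every replicate (no-separation replicates count
    as reduction 0); (5) the storage is the median across replicates of the
    depleted cumulative doublings at their separation times.
    """
    if not allow_fewer_replicates and (len(depleted_reps) != 3 or len(control_reps) != 3):
        raise ValueError("expected 3 replicates per arm (set allow_fewer_replicates to relax)")
    if not depleted_reps or not control_reps:
        raise ValueError("need at least one replicate in each arm")

    ctrl_curves = [cumulative_doublings(s) for s in control_reps]

    def mean_control(at: np.ndarray) -> np.ndarray:
        return np.mean([np.interp(at, t, d) for t, d in ctrl_curves], axis=0)

    sep_times: list[float] = []
    sep_doublings: list[float] = []
    reductions: list[float] = []
    for rep in depleted_reps:
        t, d = cumulative_doublings(rep)
        t_max_ctrl = min(tc[-1] for tc, _ in ctrl_curves)
        in_range = t <= t_max_ctrl
        gap = mean_control(t[in_range]) - d[in_range]
        idx = np.nonzero(gap >= thresholds.doubling_gap)[0]
        if idx.size == 0:
            reductions.append(0.0)
            continue
        k = int(idx[0])
        t_sep = float(t[in_range][k])
        sep_times.append(t_sep)
        sep_doublings.append(float(d[in_range][k]))
        interval = float(np.median(np.diff(t))) if t.size > 1 else post_window_h
        t_post_end = t_sep + max(post_window_h, post_window_points * interval)
        # baseline = the replicate's own exponential-phase rate before the
        # separation: best >=2-doubling window if one exists (immune to the
        # already-arrested tail just before the gap crossing), else plain OLS
        pre_fit = fit_growth_rate(rep, window=(float(t[0]), t_sep))
        if pre_fit is not None:
            pre_rate = pre_fit.rate
        else:
            pre_rate, _, _ = _window_rate(rep, t[0], t_sep)
        post_rate, _, _ = _window_rate(rep, t_sep, t_post_end)
        reductions.append(0.0 if pre_rate <= 0 else 1.0 - post_rate / pre_rate)

    red = np.asarray(reductions)
    deviated = bool(
        sep_times
        and int(np.sum(red >= thresholds.rate_drop_major)) >= thresholds.majority
        and bool(np.all(red >= thresholds.rate_drop_minor))
    )
    first = depleted_reps[0]
    vitamin = first.condition.split(":", 1)[1] if ":" in first.condition else first.condition
    return DeviationCall(
        strain=first.strain,
        vitamin=vitamin,
        deviated=deviated,
        deviation_time_h=float(np.median(sep_times)) if deviated else None,
        storage_doublings=float(np.median(sep_doublings)) if deviated else None,
        per_replicate_rate_reduction=tuple(float(r) for r in reductions),
        thresholds=thresholds,
    )


def storage_fold_excess(doublings: float) -> float:
    """Fold excess of the coenzyme pool: 2**doublings (9 doublings = 512x)."""
    if doublings < 0:
        raise ValueError("doublings must be non-negative")
    return float(2.0**doublings)


def build_auxotrophy_matrix(calls: Sequence[DeviationCall]) -> AuxotrophyMatrix:
    """Assemble deviation calls into strain x vitamin tables.

    Strains with zero deviations are retained as all-False rows (prototrophic
    for the tested vitamin set). Duplicate strain x vitamin calls raise.
    """
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.strain, c.vitamin)
        if key in seen:
            raise ValueError(f"duplicate call for strain {c.strain!r}, vitamin {c.vitamin!r}")
        seen.add(key)
    strains = sorted({c.strain for c in calls})
    vitamins = sorted({c.vitamin for c in calls})
    dev = pd.DataFrame(False, index=strains, columns=vitamins, dtype=bool)
    sto = pd.DataFrame(np.nan, index=strains, columns=vitamins, dtype=float)
    for c in calls:
        dev.loc[c.strain, c.vitamin] = c.deviated
        if c.deviated:
            sto.loc[c.strain, c.vitamin] = c.storage_doublings
    return AuxotrophyMatrix(deviated=dev, storage=sto)
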