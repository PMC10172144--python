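"""Infra-slow time-delay (lag) estimation from lagged cross-covariance.

For a pair of standardized time courses the lagged cross-covariance
function (CCF) at integer frame offset k is (1/n) * sum_t x(t) y(t+k)
over the valid overlap.  The delay is refined to sub-frame precision by
three-point parabolic interpolation around the CCF extremum, and pairwise
delays are assembled into an antisymmetric time-delay (TD) matrix.

Sign convention (fixed throughout the package): td[i, j] > 0 means
element i's signal occurs *later* than element j's.  Because the CCF of
(x_i, x_j) as defined above peaks at k = tau_j - tau_i when j is delayed
by tau_j - tau_i relative to i, the TD entry is the *negated* location of
the interpolated CCF extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BoldRun, CorticalStrip, EFFECTOR_REGIONS, INTER_REGIONS

__all__ = [
    "CCFProfile",
    "LagEstimate",
    "TDMatrix",
    "lagged_ccf",
    "parabolic_extremum",
    "td_matrix",
    "mean_lag_projection",
    "motor_lag_groups",
    "DEFAULT_MAX_LAG_FRAMES",
    "DEFAULT_MIN_PEAK",
]

#: default CCF half-window, in frames
DEFAULT_MAX_LAG_FRAMES = 8
#: pairs whose peak |CCF| falls below this are marked invalid (noise guard)
DEFAULT_MIN_PEAK = 0.3


@dataclass
class CCFProfile:
    """Normalized lagged cross-covariance over symmetric integer offsets."""

    lags: np.ndarray  # integer frame offsets, -L..L
    values: np.ndarray
    tr: float


@dataclass
class LagEstimate:
    lag_s: float
    valid: bool
    peak_value: float
    reason: str = ""


@dataclass
class TDMatrix:
    """Antisymmetric pairwise delay matrix (seconds) with validity mask."""

    td: np.ndarray
    valid: np.ndarray
    labels: list[str] | None = None

    def check(self) -> None:
        asym = self.td + self.td.T
        if not np.allclose(asym[self.valid & self.valid.T], 0.0, atol=1e-12):
            raise AssertionError("TD matrix is not antisymmetric on valid pairs")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant time course")
    return (x - x.mean()) / sd


def lagged_ccf(x: np.ndarray, y: np.ndarray, max_lag_frames: int, tr: float = 1.0) -> CCFProfile:
    """Lagged cross-covariance of standardized x, y at offsets -L..+L.

    value[k] = (1/n) sum over the valid overlap of x(t) * y(t+k); both
    inputs are standardized internally, so values are bounded by ~1.
    """
    x = _standardize(x)
    y = _standardize(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    if max_lag_frames >= n / 2:
        raise ValueError("max_lag_frames must be < length / 2")
    if n < 4 * max_lag_frames:
        raise ValueError("need length >= 4 * max_lag_frames")
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    vals = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            vals[i] = np.dot(x[: n - k], y[k:]) / n
        else:
            vals[i] = np.dot(x[-k:], y[: n + k]) / n
    return CCFProfile(lags=lags, values=vals, tr=tr)


def parabolic_extremum(ccf: CCFProfile, min_peak: float = DEFAULT_MIN_PEAK) -> LagEstimate:
    """Sub-frame CCF extremum location by three-point parabolic fit.

    With c-, c0, c+ the CCF values at the integer maximum and its
    neighbours, the refined location is
    k0 + 0.5 * (c- - c+) / (c- - 2 c0 + c+), converted to seconds via tr.
    The extremum is the CCF *maximum* (in-scope signals are positively
    correlated).  Invalid when the peak sits at the window edge, the
    curvature vanishes, or peak |CCF| < min_peak.
    """
    v = ccf.values
    i0 = int(np.argmax(v))
    peak = float(v[i0])
    if abs(peak) < min_peak:
        return LagEstimate(np.nan, False, peak, "peak below threshold")
    if i0 == 0 or i0 == v.size - 1:
        return LagEstimate(np.nan, False, peak, "extremum at window edge")
    cm, c0, cp = v[i0 - 1], v[i0], v[i0 + 1]
    denom = cm - 2.0 * c0 + cp
    if denom == 0.0:
        return LagEstimate(np.nan, False, peak, "zero curvature")
    offset = 0.5 * (cm - cp) / denom
    lag = (ccf.lags[i0] + offset) * ccf.tr
    return LagEstimate(float(lag), True, peak)


def _element_timecourses(
    run: BoldRun, strip: CorticalStrip | None, elements: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    if strip is None:
        labels = [str(i) for i in range(run.n_vertices)]
        return run.data.astype(float), labels
    if elements is None:
        elements = [r for r in strip.regions if r != "background"]
    tcs = np.stack([run.data[strip.vertices_of(r)].mean(axis=0) for r in elements])
    return tcs, list(elements)


def td_matrix(
    runs: BoldRun | list[BoldRun],
    strip: CorticalStrip | None = None,
    elements: list[str] | None = None,
    max_lag_frames: int = DEFAULT_MAX_LAG_FRAMES,
    min_peak: float = DEFAULT_MIN_PEAK,
) -> TDMatrix:
    """Pairwise antisymmetric time-delay matrix over regions or vertices.

    With a strip, elements are region-mean time courses (default: all
    labelled regions except background); without one, raw vertex rows.
    One triangle is estimated and mirrored with opposite sign, so
    antisymmetry is exact by construction.  When several runs (sessions)
    are given, a TD matrix is computed per session and entries averaged
    over the sessions in which they are valid.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    if not runs:
        raise ValueError("no runs given")
    per_session = []
    labels = None
    for run in runs:
        tcs, labels = _element_timecourses(run, strip, elements)
        m = tcs.shape[0]
        if m < 2:
            raise ValueError("need at least 2 elements")
        td = np.zeros((m, m))
        valid = np.zeros((m, m), dtype=bool)
        np.fill_diagonal(valid, True)
        for i in range(m):
            for j in range(i + 1, m):
                est = parabolic_extremum(
                    lagged_ccf(tcs[i], tcs[j], max_lag_frames, tr=run.tr),
                    min_peak=min_peak,
                )
                if est.valid:
                    td[i, j] = -est.lag_s  # positive when i is later
                    td[j, i] = est.lag_s
                    valid[i, j] = valid[j, i] = True
        per_session.append(TDMatrix(td=td, valid=valid, labels=labels))
    if len(per_session) == 1:
        return per_session[0]
    stack = np.stack([s.td for s in per_session])
    vstack = np.stack([s.valid for s in per_session])
    counts = vstack.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(counts > 0, (stack * vstack).sum(axis=0) / np.maximum(counts, 1), 0.0)
    return TDMatrix(td=avg, valid=counts > 0, labels=labels)


def mean_lag_projection(
    td: TDMatrix,
    groups: dict[str, list[str]] | None = None,
) -> pd.Series:
    """Mean row delay per element, optionally averaged within groups.

    Row i's mean over valid off-diagonal entries summarizes element i's
    average shift relative to everything else (positive = later,
    lagging).  With ``groups`` (name -> element labels), projections are
    further averaged within each group.
    """
    m = td.td.shape[0]
    off = ~np.eye(m, dtype=bool)
    use = td.valid & off
    counts = use.sum(axis=1)
    if (counts == 0).all():
        raise ValueError("TD matrix has no valid off-diagonal entries")
    row_means = np.where(counts > 0, (td.td * use).sum(axis=1) / np.maximum(counts, 1), np.nan)
    if td.labels is not None:
        proj = pd.Series(row_means, index=td.labels, name="mean_lag_s")
    else:
        proj = pd.Series(row_means, name="mean_lag_s")
    if groups is None:
        return proj
    out = {}
    for name, members in groups.items():
        missing = [mb for mb in members if mb not in proj.index]
        if missing:
            raise ValueError(f"group {name!r}: unknown elements {missing}")
        vals = proj[members].dropna()
        if vals.empty:
            raise ValueError(f"group {name!r} has no valid lag projections")
        out[name] = float(vals.mean())
    return pd.Series(out, name="mean_lag_s")


def motor_lag_groups() -> dict[str, list[str]]:
    """Default grouping for the lag projection summary."""
    return {
        "CON": ["CON"],
        "inter_effector": list(INTER_REGIONS),
        **{r: [r] for r in EFFECTOR_REGIONS},
    }
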