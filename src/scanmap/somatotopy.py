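"""Somatotopy statistics along the dorsal->ventral cortical axis.

Covers the concentric-zone analyses: projection of vertices onto the
axis line, winner-take-all preferred-movement maps, one- vs two-peak
Gaussian fits to activation profiles with a nested extra-sum-of-squares
F-test, movement selectivity (best minus second-best activation),
region coactivation profiles, and LOWESS profile smoothing.

The spatial models are
    Activation = a1 * exp(-((position - b1) / c1)^2)                (one peak)
    Activation = one-peak + a2 * exp(-((position - b2) / c2)^2)     (two peaks)
with amplitudes constrained non-negative, centers inside the fitted
range and widths bounded below (0.5 axis units) to prevent delta-spike
overfits.  The model comparison statistic is
    F = ((SSE_1 - SSE_2) / (df_1 - df_2)) / (SSE_2 / df_2)
with df = n_fitted_points - n_params, and the p-value is the upper tail
of the F distribution with (df_1 - df_2, df_2) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "AxisProfile",
    "PeakFit",
    "ModelComparison",
    "WTAMap",
    "project_to_axis",
    "axis_profile",
    "fit_mask_for_class",
    "winner_take_all",
    "fit_peak_models",
    "compare_models_f",
    "movement_selectivity",
    "coactivation_profiles",
    "lowess_profile",
]

#: lower bound on Gaussian widths (axis units)
MIN_WIDTH = 0.5
#: two-peak fits with |b2 - b1| below this are flagged collapsed
COLLAPSE_SEPARATION = 1.0
# multi-start budget: starts are ranked by initial SSE and only the best
# few are polished, keeping fits deterministic and fast
_N_POLISH_1PEAK = 8
_N_POLISH_2PEAK = 10


@dataclass
class AxisProfile:
    """Activation (Z) per ordered axis position for one movement."""

    positions: np.ndarray  # strictly increasing integer axis coordinates
    activation: np.ndarray
    fit_mask: np.ndarray  # bool, positions eligible for curve fitting
    movement: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions.shape != self.activation.shape or self.positions.shape != self.fit_mask.shape:
            raise ValueError("positions/activation/fit_mask shape mismatch")


@dataclass
class PeakFit:
    """Constrained Gaussian fit: params (a1,b1,c1[,a2,b2,c2]), SSE, df."""

    n_peaks: int
    params: np.ndarray
    sse: float
    df: int
    converged: bool
    collapsed: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        out = p[0] * np.exp(-(((x - p[1]) / p[2]) ** 2))
        if self.n_peaks == 2:
            out = out + p[3] * np.exp(-(((x - p[4]) / p[5]) ** 2))
        return out


@dataclass
class ModelComparison:
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    preferred: int
    collapsed: bool = False


@dataclass
class WTAMap:
    """Per-vertex winning movement with tie flags and selectivity."""

    winner: np.ndarray  # str labels
    tie: np.ndarray  # bool
    selectivity: np.ndarray  # best - second best activation
    display_mask: np.ndarray | None = None


def project_to_axis(vertex_coords: np.ndarray, axis_coords: np.ndarray) -> np.ndarray:
    """Ordered index of the Euclidean-nearest axis point for each vertex.

    Ties go to the lower index (np.argmin convention), matching the
    minimal-distance assignment used for stimulation-site mapping.
    """
    axis_coords = np.atleast_2d(np.asarray(axis_coords, dtype=float))
    if axis_coords.shape[0] == 0:
        raise ValueError("empty axis")
    vertex_coords = np.atleast_2d(np.asarray(vertex_coords, dtype=float))
    d = cdist(vertex_coords, axis_coords)
    return d.argmin(axis=1)


def fit_mask_for_class(n_positions: int, movement_class: str) -> np.ndarray:
    """Axis-fraction fit masks per movement class.

    Lower-extremity and upper-extremity movements exclude the bottom
    (ventral) third of the axis; face movements exclude the top (dorsal)
    third; trunk/axial movements use the full axis.
    """
    mask = np.ones(n_positions, dtype=bool)
    third = n_positions // 3
    if movement_class in ("lower", "upper"):
        mask[n_positions - third :] = False
    elif movement_class == "face":
        mask[:third] = False
    elif movement_class not in ("trunk", "none", ""):
        raise ValueError(f"unknown movement class {movement_class!r}")
    return mask


def axis_profile(
    z_values: np.ndarray,
    vertex_positions: np.ndarray,
    n_positions: int,
    fit_mask: np.ndarray | None = None,
    movement: str = "",
) -> AxisProfile:
    """Aggregate per-vertex Z to unweighted per-position means."""
    z_values = np.asarray(z_values, dtype=float)
    vertex_positions = np.asarray(vertex_positions)
    ok = np.isfinite(z_values) & np.isfinite(vertex_positions.astype(float))
    sums = np.bincount(
        vertex_positions[ok].astype(int), weights=z_values[ok], minlength=n_positions
    )
    counts = np.bincount(vertex_positions[ok].astype(int), minlength=n_positions)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    positions = np.arange(n_positions)
    if fit_mask is None:
        fit_mask = np.ones(n_positions, dtype=bool)
    fit_mask = fit_mask & (counts > 0) & np.isfinite(means)
    return AxisProfile(
        positions=positions, activation=means, fit_mask=fit_mask, movement=movement
    )


def winner_take_all(
    activation_maps: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    top_percent: float | None = None,
) -> WTAMap:
    """Per-vertex argmax of activation across movement conditions.

    Exact ties are resolved to the earliest condition (insertion order)
    and flagged.  ``top_percent`` adds a display mask keeping only the
    most strongly activated fraction of in-mask vertices (e.g. 1.0 for
    the top 1%).
    """
    if len(activation_maps) < 2:
        raise ValueError("winner-take-all needs at least 2 conditions")
    names = list(activation_maps)
    stack = np.stack([np.asarray(activation_maps[n], dtype=float) for n in names])
    n_vertices = stack.shape[1]
    if mask is None:
        mask = np.ones(n_vertices, dtype=bool)
    win_idx = np.argmax(stack, axis=0)
    best = stack[win_idx, np.arange(n_vertices)]
    tie = (stack == best[None, :]).sum(axis=0) > 1
    sorted_desc = np.sort(stack, axis=0)[::-1]
    selectivity = sorted_desc[0] - sorted_desc[1]
    winner = np.asarray([names[i] for i in win_idx], dtype=object)
    display_mask = None
    if top_percent is not None:
        if not (0.0 < top_percent <= 100.0):
            raise ValueError("top_percent must be in (0, 100]")
        thr = np.percentile(best[mask], 100.0 - top_percent)
        display_mask = mask & (best >= thr)
    winner[~mask] = ""
    return WTAMap(winner=winner, tie=tie & mask, selectivity=selectivity, display_mask=display_mask)


# ---------------------------------------------------------------------------
# Gaussian peak fitting


def _residual_fn(x, y, n_peaks):
    def fun(p):
        pred = p[0] * np.exp(-(((x - p[1]) / p[2]) ** 2))
        if n_peaks == 2:
            pred = pred + p[3] * np.exp(-(((x - p[4]) / p[5]) ** 2))
        return pred - y

    def jac(p):
        cols = []
        for k in range(n_peaks):
            a, b, c = p[3 * k], p[3 * k + 1], p[3 * k + 2]
            u = (x - b) / c
            e = np.exp(-(u**2))
            cols.append(e)
            cols.append(a * e * 2.0 * u / c)
            cols.append(a * e * 2.0 * u**2 / c)
        return np.column_stack(cols)

    return fun, jac


def _sse(x, y, p, n_peaks):
    fun, _ = _residual_fn(x, y, n_peaks)
    return float(np.sum(fun(p) ** 2))


def _polish_starts(x, y, n_peaks, starts, bounds, n_polish):
    fun, jac = _residual_fn(x, y, n_peaks)
    ranked = sorted(range(len(starts)), key=lambda i: (_sse(x, y, starts[i], n_peaks), i))
    best_p, best_sse, converged = None, np.inf, False
    for i in ranked[:n_polish]:
        try:
            res = least_squares(
                fun, starts[i], jac=jac, bounds=bounds, method="trf", max_nfev=200
            )
        except ValueError:
            continue
        sse = 2.0 * res.cost
        if res.status > 0:
            converged = True
        if sse < best_sse - 1e-12:
            best_sse, best_p = sse, res.x
    if best_p is None:  # pragma: no cover - every start failed
        best_p, best_sse = starts[ranked[0]], _sse(x, y, starts[ranked[0]], n_peaks)
    return np.asarray(best_p), best_sse, converged


def fit_peak_models(profile: AxisProfile) -> tuple[PeakFit, PeakFit]:
    """Fit the one- and two-peak Gaussian models to a masked profile.

    Constrained nonlinear least squares (a >= 0, b inside the masked
    range, c in (0.5, range]) with a deterministic multi-start: center
    candidates at the masked-range deciles, width starts {2, 5, 10} axis
    units, ranked by initial SSE and the best few polished.  The
    two-peak starts include the best one-peak solution with a vanishing
    second amplitude, so SSE_2 <= SSE_1 always.  Two-peak parameters are
    reported in canonical order b1 <= b2; fits whose centers collapse to
    within one axis unit are flagged.
    """
    x = profile.positions[profile.fit_mask].astype(float)
    y = profile.activation[profile.fit_mask].astype(float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 masked points for the one-peak fit")
    if n < 10:
        raise ValueError("need at least 10 masked points for the two-peak fit")
    lo, hi = x.min(), x.max()
    span = max(hi - lo, MIN_WIDTH + 1e-6)
    a0 = max(float(y.max()), 1e-3)
    b_cands = np.percentile(x, np.arange(10, 100, 10))
    c_cands = [c for c in (2.0, 5.0, 10.0) if MIN_WIDTH < c <= span] or [span / 4.0]

    bounds1 = ([0.0, lo, MIN_WIDTH], [np.inf, hi, span])
    starts1 = [np.array([a0, b, c]) for b in b_cands for c in c_cands]
    p1, sse1, conv1 = _polish_starts(x, y, 1, starts1, bounds1, _N_POLISH_1PEAK)
    fit1 = PeakFit(n_peaks=1, params=p1, sse=sse1, df=n - 3, converged=conv1)

    bounds2 = (
        [0.0, lo, MIN_WIDTH, 0.0, lo, MIN_WIDTH],
        [np.inf, hi, span, np.inf, hi, span],
    )
    c_mid = c_cands[min(1, len(c_cands) - 1)]
    starts2 = [
        np.array([a0, bi, c_mid, a0, bj, c_mid])
        for ii, bi in enumerate(b_cands)
        for bj in b_cands[ii + 1 :]
    ]
    # seed from the one-peak optimum: second peak at the largest residual
    resid = y - fit1.predict(x)
    b_res = x[int(np.argmax(resid))]
    a_res = max(float(resid.max()), 0.0)
    starts2.append(np.array([p1[0], p1[1], p1[2], a_res, b_res, c_mid]))
    # exact nesting guarantee: start at the one-peak optimum with a2 = 0
    b_far = hi if p1[1] < (lo + hi) / 2.0 else lo
    starts2.append(np.array([p1[0], p1[1], p1[2], 0.0, b_far, c_mid]))
    p2, sse2, conv2 = _polish_starts(x, y, 2, starts2, bounds2, _N_POLISH_2PEAK)
    if sse2 > sse1:  # numerical safety: the nested start bounds SSE_2 above
        p2 = np.array([p1[0], p1[1], p1[2], 0.0, b_far, c_mid])
        sse2 = _sse(x, y, p2, 2)
    if p2[1] > p2[4]:  # canonical ordering b1 <= b2
        p2 = np.concatenate([p2[3:], p2[:3]])
    collapsed = abs(p2[4] - p2[1]) < COLLAPSE_SEPARATION
    fit2 = PeakFit(
        n_peaks=2, params=p2, sse=sse2, df=n - 6, converged=conv2, collapsed=collapsed
    )
    return fit1, fit2


def compare_models_f(
    fit1: PeakFit, fit2: PeakFit, alpha: float = 0.05
) -> ModelComparison:
    """Extra-sum-of-squares F-test between the nested peak models.

    F = ((SSE_1 - SSE_2) / (df_1 - df_2)) / (SSE_2 / df_2), upper-tail p
    with (df_1 - df_2, df_2) degrees of freedom; the two-peak model is
    preferred when p < alpha.  SSE_2 = 0 yields F = inf, p = 0.
    """
    if not (fit1.df > fit2.df > 0):
        raise ValueError("need df_1peak > df_2peaks > 0")
    df_num = fit1.df - fit2.df
    df_den = fit2.df
    if fit2.sse == 0.0:
        return ModelComparison(np.inf, 0.0, df_num, df_den, preferred=2, collapsed=fit2.collapsed)
    f = ((fit1.sse - fit2.sse) / df_num) / (fit2.sse / df_den)
    p = float(stats.f.sf(f, df_num, df_den)) if f >= 0 else 1.0
    return ModelComparison(
        f_stat=float(f),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
        preferred=2 if p < alpha else 1,
        collapsed=fit2.collapsed,
    )


def movement_selectivity(activation_maps: dict[str, np.ndarray]) -> np.ndarray:
    """Best minus second-best activation per vertex across movements."""
    if len(activation_maps) < 2:
        raise ValueError("selectivity needs at least 2 conditions")
    stack = np.stack([np.asarray(v, dtype=float) for v in activation_maps.values()])
    sorted_desc = np.sort(stack, axis=0)[::-1]
    return sorted_desc[0] - sorted_desc[1]


def coactivation_profiles(
    activation_maps: dict[str, np.ndarray],
    region_labels: np.ndarray,
    regions: list[str],
    exclude_movements: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Correlation of regions' movement-activation profiles.

    Each region's profile is its mean activation per movement (after
    dropping excluded, e.g. motion-distorted, conditions); the result is
    the region x region Pearson correlation matrix of these profiles.
    Constant profiles yield NaN correlations.
    """
    movements = [m for m in activation_maps if m not in exclude_movements]
    if len(movements) < 3:
        raise ValueError("need at least 3 movements after exclusions")
    region_labels = np.asarray(region_labels)
    profiles = np.empty((len(regions), len(movements)))
    for i, region in enumerate(regions):
        verts = np.flatnonzero(region_labels == region)
        if verts.size == 0:
            raise ValueError(f"region {region!r} is empty")
        for j, mv in enumerate(movements):
            profiles[i, j] = np.asarray(activation_maps[mv], dtype=float)[verts].mean()
    sd = profiles.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=regions, columns=regions)


def lowess_profile(
    activation: np.ndarray,
    positions: np.ndarray | None = None,
    span: float = 0.3,
) -> np.ndarray:
    """LOWESS-smoothed activation profile evaluated at each position.

    Locally weighted linear regression with tricube weights and one
    robustness iteration.  ``span`` is the fraction of points in each
    local fit; it must give at least 3 points per window.
    """
    activation = np.asarray(activation, dtype=float)
    n = activation.size
    if positions is None:
        positions = np.arange(n, dtype=float)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if span * n < 3:
        raise ValueError("span too small: local fits need at least 3 points")
    return _sm_lowess(
        activation, np.asarray(positions, dtype=float), frac=span, it=1, return_sorted=False
    )
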