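"""Fisher-z functional connectivity and region comparison statistics.

Vertexwise connectivity is the Fisher-transformed (atanh) pairwise
Pearson correlation of BOLD time series; region connectivity is the
Fisher-z correlation of region-mean time courses (mean-then-correlate).
Also provides the seed sweep down the cortical axis, percentile
thresholding of seed maps, the conservative "target minus best
competitor" contrast, the per-network smallest inter-effector-minus-
effector difference, and paired t-tests with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import BoldRun, CorticalStrip, EFFECTOR_REGIONS

__all__ = [
    "R_CLIP",
    "ConnectivityMatrix",
    "SeedMap",
    "fisher_z",
    "fisher_connectivity",
    "seed_sweep",
    "percentile_threshold",
    "region_mean_connectivity",
    "conservative_contrast",
    "network_min_difference",
    "paired_ttest_fdr",
    "region_scalar_compare",
]

#: correlations are clipped to +/- (1 - R_CLIP_EPS) before atanh
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with r clipped to +/-(1 - 1e-7) so z stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


@dataclass
class ConnectivityMatrix:
    """Vertex x vertex Fisher-z matrix with a valid-pair mask.

    Symmetric; the diagonal and pairs involving zero-variance vertices
    are masked out of all statistics.
    """

    z: np.ndarray
    mask: np.ndarray  # bool, True = valid pair

    @property
    def n_vertices(self) -> int:
        return self.z.shape[0]


@dataclass
class SeedMap:
    """Per-vertex Fisher-z map for one seed vertex (or region)."""

    seed_id: int | str
    z: np.ndarray
    mask: np.ndarray


def _standardized_concat(runs: BoldRun | list[BoldRun]) -> tuple[np.ndarray, np.ndarray]:
    """Per-run standardized time courses, concatenated across runs.

    Returns (data, valid) where valid marks vertices with positive
    variance in every run.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    if not runs:
        raise ValueError("no runs given")
    pieces = []
    valid = np.ones(runs[0].n_vertices, dtype=bool)
    for run in runs:
        if run.n_vertices != runs[0].n_vertices:
            raise ValueError("runs have mismatched vertex counts")
        if run.n_frames < 3:
            raise ValueError("need at least 3 frames")
        x = run.data.astype(float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        valid &= ok
        sd[~ok] = 1.0
        pieces.append((x - mu) / sd)
    return np.concatenate(pieces, axis=1), valid


def fisher_connectivity(runs: BoldRun | list[BoldRun]) -> ConnectivityMatrix:
    """Fisher-transformed pairwise correlation matrix of vertex time series.

    Runs are standardized per run and concatenated before correlation.
    Zero-variance vertices are masked; all-constant input yields an
    all-masked matrix with a warning.
    """
    data, valid = _standardized_concat(runs)
    n = data.shape[0]
    if not valid.any():
        warnings.warn("all vertices are constant; connectivity is undefined", stacklevel=2)
        return ConnectivityMatrix(z=np.zeros((n, n)), mask=np.zeros((n, n), dtype=bool))
    r = (data @ data.T) / data.shape[1]
    z = fisher_z(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    mask = np.outer(valid, valid)
    np.fill_diagonal(mask, False)
    z[~mask] = 0.0
    return ConnectivityMatrix(z=z, mask=mask)


def seed_sweep(conn: ConnectivityMatrix, strip: CorticalStrip) -> list[SeedMap]:
    """One SeedMap per axis vertex, ordered dorsal -> ventral.

    Each map is the seed's row of the connectivity matrix; the seed's own
    vertex is excluded from the map's valid mask (so thresholding
    statistics never count the trivial self-connection).
    """
    if strip.axis_line.size == 0:
        raise ValueError("empty axis line")
    if conn.n_vertices != strip.n_vertices:
        raise ValueError("connectivity matrix does not match strip")
    maps = []
    for v in strip.axis_line:
        mask = conn.mask[v].copy()
        mask[v] = False
        maps.append(SeedMap(seed_id=int(v), z=conn.z[v].copy(), mask=mask))
    return maps


def percentile_threshold(seed_map: SeedMap, q_percent: float) -> SeedMap:
    """Keep values at or above the q-th percentile of in-mask values.

    Ties at the threshold are kept, so survivor sets are nested across
    increasing q.  Sub-threshold vertices get z = NaN and mask False.
    """
    if not (0.0 < q_percent < 100.0):
        raise ValueError("q_percent must be in (0, 100)")
    vals = seed_map.z[seed_map.mask]
    if vals.size == 0:
        raise ValueError("seed map has no valid values")
    thr = np.percentile(vals, q_percent)
    keep = seed_map.mask & (seed_map.z >= thr)
    z = np.where(keep, seed_map.z, np.nan)
    return SeedMap(seed_id=seed_map.seed_id, z=z, mask=keep)


def region_mean_connectivity(
    runs: BoldRun | list[BoldRun],
    strip_or_labels: CorticalStrip | np.ndarray,
    region_a: str,
    region_b: str,
) -> float:
    """Fisher-z correlation of two regions' mean time courses.

    The average time course across all vertices of each region is formed
    per run (mean-then-correlate), standardized per run, concatenated,
    then correlated.
    """
    labels = (
        strip_or_labels.region_labels
        if isinstance(strip_or_labels, CorticalStrip)
        else np.asarray(strip_or_labels)
    )
    if isinstance(runs, BoldRun):
        runs = [runs]
    idx_a = np.flatnonzero(labels == region_a)
    idx_b = np.flatnonzero(labels == region_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"empty region in pair ({region_a!r}, {region_b!r})")
    xs, ys = [], []
    for run in runs:
        a = run.data[idx_a].mean(axis=0)
        b = run.data[idx_b].mean(axis=0)
        for tc, out in ((a, xs), (b, ys)):
            sd = tc.std()
            out.append((tc - tc.mean()) / (sd if sd > 0 else 1.0))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    r = float(x @ y) / x.size
    return float(fisher_z(r))


def conservative_contrast(
    target: SeedMap | np.ndarray, competitors: list[SeedMap | np.ndarray]
) -> np.ndarray:
    """Target z minus the elementwise max over competitor z maps.

    Positive values mark vertices more strongly connected to the target
    (inter-effector) seed than to *any* competitor (foot/hand/mouth).
    """
    if len(competitors) == 0:
        raise ValueError("need at least one competitor map")
    tz = target.z if isinstance(target, SeedMap) else np.asarray(target, dtype=float)
    comp = []
    for c in competitors:
        cz = c.z if isinstance(c, SeedMap) else np.asarray(c, dtype=float)
        if cz.shape != tz.shape:
            raise ValueError("misaligned maps in conservative contrast")
        comp.append(cz)
    return tz - np.max(comp, axis=0)


def paired_ttest_fdr(
    comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed paired t-tests with BH-FDR over the declared family.

    ``comparisons`` maps a label to paired samples (a, b); the test is on
    d = a - b with df = n - 1.  All-zero differences give t = 0, p = 1;
    zero-variance nonzero differences are flagged degenerate (p = NaN,
    excluded from FDR).  Returns a table with columns
    {comparison, n, mean_diff, t, df, p, q, sig, degenerate}.
    """
    rows = []
    for label, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{label}: unpaired samples")
        n = a.size
        if n < 2:
            raise ValueError(f"{label}: need at least 2 subjects")
        d = a - b
        sd = d.std(ddof=1)
        degenerate = False
        if sd == 0.0:
            if np.all(d == 0.0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = np.nan, np.nan, True
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), n - 1)
        rows.append(
            {
                "comparison": label,
                "n": n,
                "mean_diff": d.mean(),
                "t": t,
                "df": n - 1,
                "p": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    ok = ~table["degenerate"]
    if ok.any():
        _, q, _, _ = multipletests(table.loc[ok, "p"], method="fdr_bh")
        table.loc[ok, "q"] = q
    table["sig"] = table["q"] < alpha
    return table


def network_min_difference(
    region_fc: pd.DataFrame,
    inter_label: str = "inter_effector",
    effector_labels: tuple[str, ...] = EFFECTOR_REGIONS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Smallest inter-effector-minus-effector connectivity per network.

    ``region_fc`` is long form with columns {subject, network, region, z}
    where region includes the inter-effector label and each effector.
    For each subject and network the statistic is
    min over effectors of (z_inter,net - z_effector,net); the table
    reports the across-subject mean plus a two-tailed one-sample t-test
    against zero per network, BH-FDR corrected across networks.
    """
    required = {"subject", "network", "region", "z"}
    if not required.issubset(region_fc.columns):
        raise ValueError(f"region_fc must have columns {sorted(required)}")
    per_subject: dict[str, list[float]] = {}
    for (network, subject), grp in region_fc.groupby(["network", "subject"]):
        vals = grp.set_index("region")["z"]
        needed = [inter_label, *effector_labels]
        if any(r not in vals.index for r in needed):
            raise ValueError(f"missing region cell for network {network!r}, subject {subject!r}")
        diff = min(vals[inter_label] - vals[e] for e in effector_labels)
        per_subject.setdefault(network, []).append(float(diff))
    comparisons = {
        net: (np.asarray(vals), np.zeros(len(vals))) for net, vals in per_subject.items()
    }
    table = paired_ttest_fdr(comparisons, alpha=alpha)
    table = table.rename(columns={"comparison": "network", "mean_diff": "min_difference"})
    return table.sort_values("min_difference", ascending=False).reset_index(drop=True)


def region_scalar_compare(
    scalar_maps: np.ndarray,
    strip: CorticalStrip,
    inter_regions: tuple[str, ...] = ("inter_superior", "inter_middle", "inter_inferior"),
    effector_regions: tuple[str, ...] = EFFECTOR_REGIONS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region means of a structural scalar plus inter-vs-effector t-tests.

    ``scalar_maps`` is (n_subjects, n_vertices).  The pooled
    inter-effector mean (across the three inter regions) is compared with
    each effector region by paired t-test across subjects, FDR over the
    three tests.  Returns (means_table, stats_table).
    """
    scalar_maps = np.atleast_2d(np.asarray(scalar_maps, dtype=float))
    regions = list(inter_regions) + list(effector_regions)
    means = {}
    for region in regions:
        verts = strip.vertices_of(region)
        means[region] = scalar_maps[:, verts].mean(axis=1)
    inter_mean = np.mean([means[r] for r in inter_regions], axis=0)
    means_table = pd.DataFrame({"inter_effector": inter_mean, **{r: means[r] for r in effector_regions}})
    comparisons = {
        f"inter_vs_{e}": (inter_mean, means[e]) for e in effector_regions
    }
    stats_table = paired_ttest_fdr(comparisons, alpha=alpha)
    return means_table, stats_table
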