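"""Synthetic cortical-strip datasets with known ground truth.

The generator emulates the data structure of a precision-fMRI motor-cortex
study on a 1-D dorsal->ventral cortical axis: six motor regions laid out
in interdigitated order (foot, superior inter-effector, hand, middle
inter-effector, mouth, inferior inter-effector), plus off-axis
cingulo-opercular (CON), adjacent-S1 and background territories.

Resting-state BOLD is built from infra-slow (< 0.1 Hz) latent signals --
Gaussian white noise brick-wall low-pass filtered in the frequency
domain -- mixed per region as a shared "global" component plus a
network-specific component, time-shifted by a per-region lag via a
band-limited (frequency-domain phase) shift, and corrupted with white
vertex noise.  Task runs place haemodynamic responses with one- or
two-peak Gaussian spatial profiles along the axis (or region-wise effect
sizes for event designs).  Structural scalar maps (thickness, FA,
myelin) are drawn per region from configurable normal distributions.

Every generator is deterministic given its seed, and the zero-noise
limit reproduces the analytic signal model exactly, so all downstream
estimators can be tested against injected truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import TaskDesign, build_design_matrix

__all__ = [
    "MOTOR_AXIS_ORDER",
    "EFFECTOR_REGIONS",
    "INTER_REGIONS",
    "CorticalStrip",
    "SyntheticTruth",
    "BoldRun",
    "StructuralMaps",
    "generate_strip",
    "default_truth",
    "generate_rest_run",
    "generate_task_run",
    "generate_structural_maps",
    "gaussian_profile",
    "sample_profile",
    "infra_slow_signal",
    "band_limited_shift",
]

#: Interdigitated dorsal->ventral ordering of the six motor-strip regions.
MOTOR_AXIS_ORDER = (
    "foot",
    "inter_superior",
    "hand",
    "inter_middle",
    "mouth",
    "inter_inferior",
)
EFFECTOR_REGIONS = ("foot", "hand", "mouth")
INTER_REGIONS = ("inter_superior", "inter_middle", "inter_inferior")
OFF_AXIS_REGIONS = ("CON", "S1_adjacent", "background")

#: Infra-slow cutoff (Hz) for the latent resting-state signals.
INFRA_SLOW_CUTOFF_HZ = 0.1


def _rng(seed, stream: int) -> np.random.Generator:
    """Derive a per-stream generator from a root seed by fixed offsets."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class CorticalStrip:
    """Synthetic surface geometry: vertex coordinates, ordered axis, labels.

    The axis line runs dorsal (index 0) to ventral (index L-1); axis
    positions are consecutive integers.  Off-axis territories sit at a
    lateral offset so Euclidean nearest-axis projection is well defined.
    """

    coords: np.ndarray  # (n_vertices, 2), mm-like units
    axis_line: np.ndarray  # ordered vertex indices, dorsal->ventral
    region_labels: np.ndarray  # (n_vertices,) str
    hemisphere: str = "L"

    def __post_init__(self):
        ax = np.asarray(self.axis_line)
        if len(np.unique(ax)) != len(ax):
            raise ValueError("axis_line indices must be unique")
        if ax.size and (ax.min() < 0 or ax.max() >= self.n_vertices):
            raise ValueError("axis_line contains invalid vertex index")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def axis_length(self) -> int:
        return int(self.axis_line.size)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.region_labels.tolist()))

    def vertices_of(self, region: str) -> np.ndarray:
        idx = np.flatnonzero(self.region_labels == region)
        if idx.size == 0:
            raise ValueError(f"region {region!r} is empty")
        return idx

    def axis_position(self) -> np.ndarray:
        """Axis position (0..L-1) of each axis vertex, NaN for off-axis."""
        pos = np.full(self.n_vertices, np.nan)
        pos[self.axis_line] = np.arange(self.axis_length)
        return pos

    def region_center(self, region: str) -> float:
        """Mean axis position of an on-axis region."""
        pos = self.axis_position()[self.vertices_of(region)]
        if np.isnan(pos).any():
            raise ValueError(f"region {region!r} is not on the axis")
        return float(pos.mean())

    def to_dict(self) -> dict:
        return {
            "coords": self.coords.tolist(),
            "axis_line": self.axis_line.tolist(),
            "region_labels": self.region_labels.tolist(),
            "hemisphere": self.hemisphere,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorticalStrip":
        return cls(
            coords=np.asarray(d["coords"], dtype=float),
            axis_line=np.asarray(d["axis_line"], dtype=int),
            region_labels=np.asarray(d["region_labels"], dtype=object),
            hemisphere=d.get("hemisphere", "L"),
        )


def generate_strip(layout: dict | None = None) -> CorticalStrip:
    """Build the interdigitated strip geometry from a layout config.

    ``layout`` maps region name to vertex count.  Motor regions (in
    MOTOR_AXIS_ORDER) are placed consecutively along the axis at integer
    positions 0..L-1; CON / S1_adjacent / background vertices sit at
    lateral x offsets.  Default: 20 vertices per region everywhere.
    """
    sizes = {r: 20 for r in MOTOR_AXIS_ORDER + OFF_AXIS_REGIONS}
    if layout:
        unknown = set(layout) - set(sizes)
        if unknown:
            raise ValueError(f"unknown regions in layout: {sorted(unknown)}")
        sizes.update(layout)
    for r, n in sizes.items():
        if n <= 0:
            raise ValueError(f"region {r!r} must have a positive vertex count")

    coords: list[tuple[float, float]] = []
    labels: list[str] = []
    axis_line: list[int] = []
    y = 0
    for region in MOTOR_AXIS_ORDER:
        for _ in range(sizes[region]):
            axis_line.append(len(coords))
            coords.append((0.0, float(y)))
            labels.append(region)
            y += 1
    axis_len = y
    for k, region in enumerate(OFF_AXIS_REGIONS):
        n = sizes[region]
        xs = 4.0 + 3.0 * k
        ys = np.linspace(0.0, axis_len - 1.0, n)
        for yy in ys:
            coords.append((xs, float(yy)))
            labels.append(region)
    return CorticalStrip(
        coords=np.asarray(coords, dtype=float),
        axis_line=np.asarray(axis_line, dtype=int),
        region_labels=np.asarray(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Ground-truth parameters shared by all generators.

    signal_assignments maps each region to the index of its
    network-specific latent signal; regions sharing an index are mutually
    correlated.  region_lags_s gives each region's temporal offset:
    positive means the region's signal occurs *later*.  peak_params maps
    movement name to one or two (a, b, c) Gaussian peaks on the axis
    (amplitudes a >= 0, centers b in axis units, widths c > 0);
    region_effects maps event-task conditions to region -> beta
    amplitude.  Pairwise lags are antisymmetric by construction:
    lag(i, j) = lag_i - lag_j.
    """

    signal_assignments: dict[str, int]
    region_lags_s: dict[str, float]
    peak_params: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=dict
    )
    movement_class: dict[str, str] = field(default_factory=dict)
    region_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    structural_effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    noise_sd: float = 1.0
    task_noise_sd: float = 2.0
    global_weight: float = 0.6
    network_weight: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for mv, peaks in self.peak_params.items():
            for (a, b, c) in peaks:
                if a < 0:
                    raise ValueError(f"{mv}: amplitude a must be >= 0")
                if c <= 0:
                    raise ValueError(f"{mv}: width c must be > 0")
        if self.noise_sd < 0 or self.task_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def pairwise_lag(self, region_i: str, region_j: str) -> float:
        """Antisymmetric truth lag: positive if region_i is later."""
        return self.region_lags_s.get(region_i, 0.0) - self.region_lags_s.get(
            region_j, 0.0
        )

    @property
    def n_latents(self) -> int:
        return max(self.signal_assignments.values()) + 1


def default_truth(strip: CorticalStrip, seed: int = 0) -> SyntheticTruth:
    """Study-condition defaults for the synthetic ground truth.

    Latent structure: one latent per effector (foot/hand/mouth); the
    three inter-effector regions and CON share a fourth latent (their
    injected coupling); S1_adjacent shares the hand latent; background
    has its own.  Lags: effectors 0 s, inter-effector regions +0.4 s,
    CON +0.8 s (inter-effector and CON signals arrive later).  Movement
    battery: single peaks at the foot/hand/mouth centers (a = 3) and
    two-peak profiles over inter-effector centers (a ~ 1.5), giving the
    interdigitated winner bands, weak inter-effector selectivity and
    inter-effector/CON coactivation structure.  The planning/execution
    event task activates inter-effector regions more during planning and
    effector regions more during execution.  Thickness is lower (2.3 vs
    2.7 mm), FA higher, in inter-effector than effector regions.
    """
    assignments = {
        "foot": 0,
        "hand": 1,
        "mouth": 2,
        "inter_superior": 3,
        "inter_middle": 3,
        "inter_inferior": 3,
        "CON": 3,
        "S1_adjacent": 1,
        "background": 4,
    }
    lags = {r: 0.0 for r in assignments}
    for r in INTER_REGIONS:
        lags[r] = 0.4
    lags["CON"] = 0.8

    c_foot = strip.region_center("foot")
    c_hand = strip.region_center("hand")
    c_mouth = strip.region_center("mouth")
    c_is = strip.region_center("inter_superior")
    c_im = strip.region_center("inter_middle")
    c_ii = strip.region_center("inter_inferior")
    peaks = {
        "toes": ((3.0, c_foot, 6.0),),
        "abdominal": ((1.6, c_is, 6.0), (1.3, c_im, 6.0)),
        "hand": ((3.0, c_hand, 6.0),),
        "eyelid": ((1.5, c_im, 6.0), (1.2, c_ii, 6.0)),
        "tongue": ((3.0, c_mouth, 6.0),),
        "swallowing": ((1.2, c_is, 6.0), (1.5, c_ii, 6.0)),
    }
    movement_class = {
        "toes": "lower",
        "abdominal": "trunk",
        "hand": "upper",
        "eyelid": "face",
        "tongue": "face",
        "swallowing": "trunk",
    }
    region_effects = {
        # CON co-activates with the axial / inter-effector-preferring
        # movements but barely with isolated effector movements
        "abdominal": {"CON": 1.2},
        "eyelid": {"CON": 1.0},
        "swallowing": {"CON": 1.1},
        "toes": {"CON": 0.1},
        "hand": {"CON": 0.1},
        "tongue": {"CON": 0.1},
        "planning": {
            **{r: 1.2 for r in INTER_REGIONS},
            **{r: 0.3 for r in EFFECTOR_REGIONS},
        },
        "execution": {
            **{r: 0.6 for r in INTER_REGIONS},
            **{r: 1.2 for r in EFFECTOR_REGIONS},
        },
    }
    structural = {}
    for r in assignments:
        inter = r in INTER_REGIONS
        eff = r in EFFECTOR_REGIONS
        structural[r] = {
            "thickness": (2.3 if inter else 2.7 if eff else 2.5, 0.15),
            "fa": (0.45 if inter else 0.40 if eff else 0.42, 0.03),
            "myelin": (
                {"foot": 0.95, "hand": 1.10, "mouth": 1.00}.get(
                    r, 1.02 if inter else 1.0
                ),
                0.05,
            ),
        }
    return SyntheticTruth(
        signal_assignments=assignments,
        region_lags_s=lags,
        peak_params=peaks,
        movement_class=movement_class,
        region_effects=region_effects,
        structural_effects=structural,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# BOLD containers and signal primitives


@dataclass
class BoldRun:
    """Vertex x frame BOLD matrix with repetition time and run metadata."""

    data: np.ndarray  # (n_vertices, n_frames)
    tr: float
    run_type: str = "rest"  # rest | block_task | event_task
    design: TaskDesign | None = None

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[1] < 2:
            raise ValueError("a run needs at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data must be finite")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class StructuralMaps:
    """Per-vertex structural scalars; myelin is precentral-mean normalized."""

    thickness: np.ndarray
    fa: np.ndarray
    myelin: np.ndarray
    myelin_raw: np.ndarray

    def __post_init__(self):
        for name in ("thickness", "fa", "myelin"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} map must be finite")
        if (self.thickness <= 0).any():
            raise ValueError("thickness must be positive")


def infra_slow_signal(
    n_frames: int, tr: float, rng: np.random.Generator, cutoff_hz: float = INFRA_SLOW_CUTOFF_HZ
) -> np.ndarray:
    """Unit-variance infra-slow latent: white noise, FFT brick-wall < cutoff."""
    white = rng.standard_normal(n_frames)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    spec[freqs > cutoff_hz] = 0.0
    sig = np.fft.irfft(spec, n=n_frames)
    sig -= sig.mean()
    sd = sig.std()
    if sd == 0:
        raise ValueError("degenerate latent signal (no passband content)")
    return sig / sd


def band_limited_shift(x: np.ndarray, shift_s: float, tr: float) -> np.ndarray:
    """Delay ``x`` by shift_s seconds via a frequency-domain phase ramp.

    Returns y with y(t) = x(t - shift_s) under the band-limited, circular
    extension of x; supports fractional (sub-frame) shifts exactly, which
    is what sub-TR parabolic lag interpolation is tested against.
    """
    n = x.size
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * shift_s)
    return np.fft.irfft(spec, n=n)


# ---------------------------------------------------------------------------
# generators


def generate_rest_run(
    strip: CorticalStrip,
    truth: SyntheticTruth,
    n_frames: int = 600,
    tr: float = 1.1,
    seed: int | None = None,
) -> BoldRun:
    """Resting-state run with injected network covariance and lags.

    Each vertex time course is ``global_weight * g(t - lag) +
    network_weight * s_k(t - lag) + noise`` where g is a global latent
    shared by all labelled regions, s_k the region's network latent and
    lag the region's truth lag.  Regions sharing a latent (the three
    inter-effector regions and CON) are therefore mutually correlated
    beyond the global component.
    """
    if n_frames < 64:
        raise ValueError("n_frames must be >= 64")
    max_lag = max(abs(v) for v in truth.region_lags_s.values()) if truth.region_lags_s else 0.0
    if max_lag >= tr * n_frames / 4.0:
        raise ValueError("truth lag exceeds representable range (tr * n_frames / 4)")
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 1)

    global_latent = infra_slow_signal(n_frames, tr, rng)
    latents = np.stack(
        [infra_slow_signal(n_frames, tr, rng) for _ in range(truth.n_latents)]
    )
    data = np.zeros((strip.n_vertices, n_frames))
    for region, k in truth.signal_assignments.items():
        try:
            verts = strip.vertices_of(region)
        except ValueError:
            continue
        lag = truth.region_lags_s.get(region, 0.0)
        base = (
            truth.global_weight * band_limited_shift(global_latent, lag, tr)
            + truth.network_weight * band_limited_shift(latents[k], lag, tr)
        )
        data[verts] = base
    if truth.noise_sd > 0:
        data += truth.noise_sd * rng.standard_normal(data.shape)
    return BoldRun(data=data, tr=tr, run_type="rest")


def gaussian_profile(
    positions: np.ndarray, peaks: tuple[tuple[float, float, float], ...]
) -> np.ndarray:
    """Sum of Gaussian peaks a * exp(-((x - b) / c)^2) along the axis."""
    x = np.asarray(positions, dtype=float)
    out = np.zeros_like(x)
    for (a, b, c) in peaks:
        out += a * np.exp(-(((x - b) / c) ** 2))
    return out


def sample_profile(
    peaks: tuple[tuple[float, float, float], ...],
    n_positions: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy activation profile on positions 0..n-1 (for fit calibration)."""
    x = np.arange(n_positions, dtype=float)
    y = gaussian_profile(x, peaks)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n_positions)
    return x, y


def generate_task_run(
    strip: CorticalStrip,
    truth: SyntheticTruth,
    design: TaskDesign,
    tr: float = 1.1,
    seed: int | None = None,
    run_type: str = "block_task",
) -> BoldRun:
    """Task run: per-vertex amplitudes times HRF-convolved regressors.

    Conditions found in ``truth.peak_params`` activate axis vertices with
    the Gaussian spatial profile evaluated at the vertex axis position;
    conditions found in ``truth.region_effects`` activate whole regions
    at the stated beta.  White noise at task_noise_sd is added.
    """
    n_frames = int(np.ceil(design.run_length_s / tr - 1e-9))
    X = build_design_matrix(design, tr, n_frames)  # validates the design
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 2)

    axis_pos = strip.axis_position()
    amplitudes = np.zeros((strip.n_vertices, len(design.conditions)))
    for j, cond in enumerate(design.conditions):
        if cond.name in truth.peak_params:
            on_axis = ~np.isnan(axis_pos)
            amplitudes[on_axis, j] += gaussian_profile(
                axis_pos[on_axis], truth.peak_params[cond.name]
            )
        if cond.name in truth.region_effects:
            for region, beta in truth.region_effects[cond.name].items():
                try:
                    verts = strip.vertices_of(region)
                except ValueError:
                    continue
                amplitudes[verts, j] += beta
    regressors = X[[c.name for c in design.conditions]].to_numpy()
    data = amplitudes @ regressors.T
    if truth.task_noise_sd > 0:
        data += truth.task_noise_sd * rng.standard_normal(data.shape)
    return BoldRun(data=data, tr=tr, run_type=run_type, design=design)


def generate_structural_maps(
    strip: CorticalStrip,
    region_effects: dict[str, dict[str, tuple[float, float]]],
    seed: int = 0,
) -> StructuralMaps:
    """Region-structured structural scalar maps.

    ``region_effects[region][metric] = (mean, sd)`` for metrics
    thickness / fa / myelin; per-vertex values are normal draws.  The
    returned myelin map is additionally normalized by its mean over the
    precentral gyrus (all motor-strip regions), so that mean is exactly 1.
    """
    rng = _rng(seed, 3)
    maps = {}
    for metric in ("thickness", "fa", "myelin"):
        vals = np.full(strip.n_vertices, np.nan)
        for region, effects in region_effects.items():
            if metric not in effects:
                continue
            mean, sd = effects[metric]
            if sd < 0:
                raise ValueError(f"{region}/{metric}: negative sd")
            verts = strip.vertices_of(region)
            vals[verts] = mean + sd * rng.standard_normal(verts.size)
        vals = np.where(np.isnan(vals), {"thickness": 2.5, "fa": 0.4, "myelin": 1.0}[metric], vals)
        maps[metric] = vals
    motor = np.isin(strip.region_labels, MOTOR_AXIS_ORDER)
    precentral_mean = maps["myelin"][motor].mean()
    if precentral_mean == 0:
        raise ValueError("cannot normalize myelin: precentral mean is zero")
    return StructuralMaps(
        thickness=maps["thickness"],
        fa=maps["fa"],
        myelin=maps["myelin"] / precentral_mean,
        myelin_raw=maps["myelin"],
    )
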