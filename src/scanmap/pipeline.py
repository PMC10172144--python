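"""End-to-end orchestration: simulate -> connectivity -> lags -> GLM ->
somatotopy -> structural -> report, with a validated config and fixed
seeds.

The pipeline simulates a cohort of subjects from the synthetic ground
truth, runs every analysis stage on each subject, and assembles group
tables analogous to the study's headline figures: the per-network
smallest inter-effector-minus-effector connectivity difference, the lag
ordering of effector / inter-effector / CON signals, winner-take-all
movement bands and Gaussian peak fits along the axis, movement
selectivity, the planning-vs-execution contrast, and structural region
comparisons, plus recovery metrics against the injected truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import glm as tg
from . import lags as lg
from . import somatotopy as st
from . import synthetic as syn
from .io import write_table

__all__ = ["PipelineConfig", "RunReport", "ConfigError", "run_pipeline", "export_edge_list"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Analysis thresholds default to the study's printed choices:
    alpha = 0.05, edge threshold Z(r) > 0.2, seed-map percentiles
    80-97, top-1% winner-take-all display, smoothing sigma 2.55.
    """

    seed: int = 0
    n_subjects: int = 20
    layout: dict | None = None
    tr: float = 1.1
    n_rest_runs: int = 4
    rest_frames: int = 600
    n_battery_runs: int = 8
    n_event_runs: int = 8
    n_event_trials: int = 24
    alpha: float = 0.05
    edge_threshold_z: float = 0.2
    smoothing_sigma: float = 2.55
    percentile_low: float = 80.0
    percentile_high: float = 97.0
    top_percent_display: float = 1.0
    max_lag_frames: int = 8
    min_ccf_peak: float = 0.3
    inter_con_coupling: bool = True
    subject_jitter_sd: float = 0.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.n_subjects >= 2, "n_subjects must be >= 2"),
            (self.tr > 0, "tr must be positive"),
            (self.n_rest_runs >= 1, "n_rest_runs must be >= 1"),
            (self.rest_frames >= 64, "rest_frames must be >= 64"),
            (self.n_battery_runs >= 2, "n_battery_runs must be >= 2"),
            (self.n_event_runs >= 2, "n_event_runs must be >= 2"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.percentile_low < self.percentile_high < 100, "percentiles must satisfy 0 < low < high < 100"),
            (0 < self.top_percent_display <= 100, "top_percent_display must be in (0, 100]"),
            (self.smoothing_sigma >= 0, "smoothing_sigma must be >= 0"),
            (self.max_lag_frames >= 1, "max_lag_frames must be >= 1"),
            (self.subject_jitter_sd >= 0, "subject_jitter_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Stage outcomes, group tables and truth-recovery metrics."""

    config_hash: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    stage_status: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.stage_status.values())

    def write(self, out_dir: str | Path, figures: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            write_table(table.reset_index() if table.index.name else table, out / f"{name}.tsv")
        summary = {
            "config_hash": self.config_hash,
            "stage_status": self.stage_status,
            "metrics": self.metrics,
            "timings_s": self.timings_s,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1, default=float))
        if figures:
            _write_figures(self, out)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.metrics, sort_keys=True, default=float).encode())
        for name in sorted(self.tables):
            h.update(self.tables[name].to_csv().encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# subject simulation


def _event_design(config: PipelineConfig, rng: np.random.Generator) -> tg.TaskDesign:
    """Planning/execution event design: jittered zero-duration event pairs."""
    trial_spacing = 12.0
    plan_onsets, exec_onsets = [], []
    t = 2.0
    for _ in range(config.n_event_trials):
        plan_onsets.append(t)
        exec_onsets.append(t + float(rng.uniform(3.5, 6.5)))
        t += trial_spacing
    run_length = t + 20.0
    return tg.TaskDesign(
        conditions=(
            tg.Condition("planning", tuple(plan_onsets), (0.0,) * len(plan_onsets), phase="planning"),
            tg.Condition("execution", tuple(exec_onsets), (0.0,) * len(exec_onsets), phase="execution"),
        ),
        run_length_s=run_length,
    )


def _subject_truth(
    strip: syn.CorticalStrip, config: PipelineConfig, subject: int
) -> syn.SyntheticTruth:
    seed = np.random.SeedSequence([config.seed, 100 + subject]).generate_state(1)[0] % (2**31)
    truth = syn.default_truth(strip, seed=int(seed))
    if not config.inter_con_coupling:
        # negative control: CON gets its own latent, uncoupled from the
        # inter-effector network
        truth.signal_assignments = dict(truth.signal_assignments)
        truth.signal_assignments["CON"] = truth.n_latents
    if config.subject_jitter_sd > 0:
        rng = syn._rng(seed, 9)
        jittered = {}
        for region, effects in truth.structural_effects.items():
            jittered[region] = {
                metric: (mean + float(rng.normal(0.0, config.subject_jitter_sd)), sd)
                for metric, (mean, sd) in effects.items()
            }
        truth.structural_effects = jittered
    return truth


@dataclass
class SubjectData:
    subject: int
    truth: syn.SyntheticTruth
    rest_runs: list[syn.BoldRun]
    battery_runs: list[syn.BoldRun]
    event_runs: list[syn.BoldRun]
    structural: syn.StructuralMaps


def simulate_subject(
    strip: syn.CorticalStrip, config: PipelineConfig, subject: int
) -> SubjectData:
    truth = _subject_truth(strip, config, subject)
    movements = list(truth.peak_params)
    battery_design = tg.make_block_design(movements)
    rest = [
        syn.generate_rest_run(
            strip, truth, config.rest_frames, config.tr, seed=truth.seed + 10 + r
        )
        for r in range(config.n_rest_runs)
    ]
    battery = [
        syn.generate_task_run(
            strip, truth, battery_design, config.tr, seed=truth.seed + 40 + r
        )
        for r in range(config.n_battery_runs)
    ]
    events = []
    for r in range(config.n_event_runs):
        rng = syn._rng(truth.seed, 70 + r)
        design = _event_design(config, rng)
        events.append(
            syn.generate_task_run(
                strip, truth, design, config.tr, seed=truth.seed + 70 + r, run_type="event_task"
            )
        )
    structural = syn.generate_structural_maps(strip, truth.structural_effects, seed=truth.seed + 5)
    return SubjectData(subject, truth, rest, battery, events, structural)


# ---------------------------------------------------------------------------
# per-subject analyses


def _merged_labels(strip: syn.CorticalStrip) -> np.ndarray:
    labels = strip.region_labels.copy()
    labels[np.isin(labels, syn.INTER_REGIONS)] = "inter_effector"
    return labels


_NETWORKS = ("CON", "S1_adjacent", "background")
_FC_REGIONS = ("inter_effector", "foot", "hand", "mouth")


def subject_network_fc(data: SubjectData, strip: syn.CorticalStrip) -> pd.DataFrame:
    labels = _merged_labels(strip)
    rows = []
    for network in _NETWORKS:
        for region in _FC_REGIONS:
            z = conn.region_mean_connectivity(data.rest_runs, labels, region, network)
            rows.append({"subject": data.subject, "network": network, "region": region, "z": z})
    return pd.DataFrame(rows)


def subject_region_fc_matrix(data: SubjectData, strip: syn.CorticalStrip) -> pd.DataFrame:
    regions = list(syn.MOTOR_AXIS_ORDER) + ["CON"]
    m = np.zeros((len(regions), len(regions)))
    for i, a in enumerate(regions):
        for j in range(i + 1, len(regions)):
            z = conn.region_mean_connectivity(data.rest_runs, strip, a, regions[j])
            m[i, j] = m[j, i] = z
    return pd.DataFrame(m, index=regions, columns=regions)


def subject_lag_projection(
    data: SubjectData, strip: syn.CorticalStrip, config: PipelineConfig
) -> pd.Series:
    elements = list(syn.MOTOR_AXIS_ORDER) + ["CON"]
    td = lg.td_matrix(
        data.rest_runs,
        strip,
        elements=elements,
        max_lag_frames=config.max_lag_frames,
        min_peak=config.min_ccf_peak,
    )
    td.check()
    return lg.mean_lag_projection(td, groups=lg.motor_lag_groups())


def subject_battery_maps(
    data: SubjectData, strip: syn.CorticalStrip, config: PipelineConfig
) -> dict[str, np.ndarray]:
    """Subject-level smoothed Z map per movement (axis-ordered smoothing)."""
    run_maps = []
    for run in data.battery_runs:
        X = tg.build_design_matrix(run.design, run.tr, run.n_frames)
        run_maps.append(tg.fit_glm(run.data, X))
    subject_map = tg.second_level(run_maps)
    z_maps = {}
    for cond in subject_map.conditions:
        z = subject_map.condition_z(cond).copy()
        z[np.isnan(z)] = 0.0
        z_axis = z[strip.axis_line]
        z[strip.axis_line] = tg.smooth_map(z_axis, config.smoothing_sigma)
        z_maps[cond] = z
    return z_maps


def subject_peak_fits(
    z_maps: dict[str, np.ndarray],
    strip: syn.CorticalStrip,
    truth: syn.SyntheticTruth,
    alpha: float,
) -> pd.DataFrame:
    axis_pos = strip.axis_position()
    on_axis = ~np.isnan(axis_pos)
    rows = []
    for movement, z in z_maps.items():
        mask = st.fit_mask_for_class(
            strip.axis_length, truth.movement_class.get(movement, "trunk")
        )
        profile = st.axis_profile(
            z[on_axis], axis_pos[on_axis].astype(int), strip.axis_length, fit_mask=mask, movement=movement
        )
        fit1, fit2 = st.fit_peak_models(profile)
        comp = st.compare_models_f(fit1, fit2, alpha=alpha)
        rows.append(
            {
                "movement": movement,
                "a1": fit2.params[0],
                "b1": fit2.params[1],
                "c1": fit2.params[2],
                "a2": fit2.params[3],
                "b2": fit2.params[4],
                "c2": fit2.params[5],
                "sse1": fit1.sse,
                "sse2": fit2.sse,
                "F": comp.f_stat,
                "p": comp.p_value,
                "preferred": comp.preferred,
                "collapsed": comp.collapsed,
            }
        )
    return pd.DataFrame(rows)


def subject_planning_contrast(data: SubjectData) -> tg.ActivationMap:
    plan, execu = [], []
    for run in data.event_runs:
        X = tg.build_design_matrix(run.design, run.tr, run.n_frames)
        m = tg.fit_glm(run.data, X)
        plan.append(m.condition_beta("planning"))
        execu.append(m.condition_beta("execution"))
    return tg.planning_vs_execution(np.stack(plan), np.stack(execu))


def export_edge_list(
    region_fc: pd.DataFrame, threshold_z: float = 0.2
) -> pd.DataFrame:
    """Edges with Fisher z above threshold from a square region FC table."""
    if region_fc.shape[0] != region_fc.shape[1]:
        raise ValueError("region FC table must be square")
    rows = []
    labels = list(region_fc.index)
    vals = region_fc.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if vals[i, j] > threshold_z:
                rows.append({"node_a": labels[i], "node_b": labels[j], "z": vals[i, j]})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "z"])


# ---------------------------------------------------------------------------
# group pipeline


def _expected_band_order(truth: syn.SyntheticTruth) -> list[str]:
    """Movements ordered by the axis position of their dominant peak."""
    def dominant_center(peaks):
        return max(peaks, key=lambda p: p[0])[1]
    return sorted(truth.peak_params, key=lambda m: dominant_center(truth.peak_params[m]))


def _wta_band_order_ok(
    wta: st.WTAMap, strip: syn.CorticalStrip, truth: syn.SyntheticTruth
) -> bool:
    """Modal winner in each motor region must match the injected layout."""
    expected = {
        "foot": "toes",
        "inter_superior": "abdominal",
        "hand": "hand",
        "inter_middle": "eyelid",
        "mouth": "tongue",
        "inter_inferior": "swallowing",
    }
    for region, movement in expected.items():
        winners = wta.winner[strip.vertices_of(region)]
        winners = winners[winners != ""]
        if winners.size == 0:
            return False
        vals, counts = np.unique(winners, return_counts=True)
        if vals[np.argmax(counts)] != movement:
            return False
    return True


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on a simulated cohort; deterministic given the seed."""
    report = RunReport(config_hash=config.hash())
    strip = syn.generate_strip(config.layout)
    subjects = [simulate_subject(strip, config, s) for s in range(config.n_subjects)]
    truth0 = subjects[0].truth

    # --- connectivity -----------------------------------------------------
    t0 = time.time()
    try:
        fc_long = pd.concat(
            [subject_network_fc(s, strip) for s in subjects], ignore_index=True
        )
        report.tables["network_fc"] = fc_long
        report.tables["network_min_difference"] = conn.network_min_difference(
            fc_long, alpha=config.alpha
        )
        region_fc = sum(subject_region_fc_matrix(s, strip) for s in subjects) / len(subjects)
        report.tables["region_fc_matrix"] = region_fc.reset_index(names="region")
        report.tables["edge_list"] = export_edge_list(region_fc, config.edge_threshold_z)

        # seed-sweep demonstration on the first subject
        cmat = conn.fisher_connectivity(subjects[0].rest_runs)
        maps = conn.seed_sweep(cmat, strip)
        center = {r: int(round(strip.region_center(r))) for r in syn.MOTOR_AXIS_ORDER}
        target = maps[center["inter_superior"]]
        competitors = [maps[center[r]] for r in syn.EFFECTOR_REGIONS]
        contrast = conn.conservative_contrast(target, competitors)
        inter_verts = np.concatenate([strip.vertices_of(r) for r in syn.INTER_REGIONS])
        eff_verts = np.concatenate([strip.vertices_of(r) for r in syn.EFFECTOR_REGIONS])
        report.metrics["contrast_mean_inter"] = float(contrast[inter_verts].mean())
        report.metrics["contrast_mean_effector"] = float(contrast[eff_verts].mean())
        surv_low = int(conn.percentile_threshold(target, config.percentile_low).mask.sum())
        surv_high = int(conn.percentile_threshold(target, config.percentile_high).mask.sum())
        report.metrics["survivors_low_percentile"] = surv_low
        report.metrics["survivors_high_percentile"] = surv_high
        nmd = report.tables["network_min_difference"]
        con_row = nmd[nmd["network"] == "CON"].iloc[0]
        report.metrics["con_min_difference_z"] = float(con_row["min_difference"])
        report.metrics["con_min_difference_q"] = float(con_row["q"])
        report.metrics["con_min_difference_is_largest"] = float(
            nmd["min_difference"].idxmax() == con_row.name
        )
        report.stage_status["connectivity"] = "ok"
    except Exception as exc:  # pragma: no cover - partial-report path
        report.stage_status["connectivity"] = f"failed: {exc}"
    report.timings_s["connectivity"] = round(time.time() - t0, 2)

    # --- lag structure ----------------------------------------------------
    t0 = time.time()
    try:
        projections = pd.DataFrame(
            [subject_lag_projection(s, strip, config) for s in subjects]
        )
        projections.insert(0, "subject", range(len(subjects)))
        report.tables["lag_projection"] = projections
        grp = projections.drop(columns="subject").mean()
        report.metrics["mean_lag_CON_s"] = float(grp["CON"])
        report.metrics["mean_lag_inter_s"] = float(grp["inter_effector"])
        report.metrics["mean_lag_effector_s"] = float(grp[["foot", "hand", "mouth"]].mean())
        eff_max = projections[["foot", "hand", "mouth"]].max(axis=1)
        ordering = (
            (eff_max < projections["inter_effector"])
            & (projections["inter_effector"] <= projections["CON"] + 1e-9)
        )
        report.metrics["lag_ordering_fraction"] = float(ordering.mean())
        lag_tests = conn.paired_ttest_fdr(
            {
                f"inter_vs_{e}": (
                    projections["inter_effector"].to_numpy(),
                    projections[e].to_numpy(),
                )
                for e in syn.EFFECTOR_REGIONS
            },
            alpha=config.alpha,
        )
        report.tables["lag_tests"] = lag_tests
        report.stage_status["lags"] = "ok"
    except Exception as exc:  # pragma: no cover
        report.stage_status["lags"] = f"failed: {exc}"
    report.timings_s["lags"] = round(time.time() - t0, 2)

    # --- task GLM + somatotopy --------------------------------------------
    t0 = time.time()
    try:
        band_ok, sel_lower, fit_rows = [], [], []
        plan_inter, plan_eff = [], []
        coact_first = None
        group_z_sum: dict[str, np.ndarray] | None = None
        inter_verts = np.concatenate([strip.vertices_of(r) for r in syn.INTER_REGIONS])
        eff_verts = np.concatenate([strip.vertices_of(r) for r in syn.EFFECTOR_REGIONS])
        for s in subjects:
            z_maps = subject_battery_maps(s, strip, config)
            wta = st.winner_take_all(
                z_maps,
                mask=np.isin(np.arange(strip.n_vertices), strip.axis_line),
                top_percent=config.top_percent_display,
            )
            band_ok.append(_wta_band_order_ok(wta, strip, s.truth))
            if group_z_sum is None:
                group_z_sum = {c: z.copy() for c, z in z_maps.items()}
            else:
                for c, z in z_maps.items():
                    group_z_sum[c] += z
            sel = st.movement_selectivity(z_maps)
            sel_lower.append(sel[inter_verts].mean() < sel[eff_verts].mean())
            fits = subject_peak_fits(z_maps, strip, s.truth, config.alpha)
            fits.insert(0, "subject", s.subject)
            fit_rows.append(fits)
            if coact_first is None:
                coact_first = st.coactivation_profiles(
                    z_maps,
                    strip.region_labels,
                    list(syn.MOTOR_AXIS_ORDER) + ["CON"],
                )
            pve = subject_planning_contrast(s)
            zc = pve.z[0]
            plan_inter.append(np.nanmean(zc[inter_verts]))
            plan_eff.append(np.nanmean(zc[eff_verts]))
        fit_table = pd.concat(fit_rows, ignore_index=True)
        report.tables["peak_fits"] = fit_table
        report.tables["coactivation_first_subject"] = coact_first.reset_index(names="region")
        report.metrics["wta_band_order_fraction"] = float(np.mean(band_ok))
        group_wta = st.winner_take_all(
            {c: z / len(subjects) for c, z in group_z_sum.items()},
            mask=np.isin(np.arange(strip.n_vertices), strip.axis_line),
        )
        report.metrics["wta_band_order_group"] = float(
            _wta_band_order_ok(group_wta, strip, truth0)
        )
        report.metrics["selectivity_inter_lower_fraction"] = float(np.mean(sel_lower))
        report.metrics["planning_contrast_inter_mean_z"] = float(np.mean(plan_inter))
        report.metrics["planning_contrast_effector_mean_z"] = float(np.mean(plan_eff))
        # recovery of injected peak centers for the single-peak movements
        errs = []
        grid = np.linspace(0, strip.axis_length - 1, 1200)
        for mv in ("toes", "hand", "tongue"):
            b_true = truth0.peak_params[mv][0][1]
            sub = fit_table[fit_table["movement"] == mv]
            for _, r in sub.iterrows():
                curve = r["a1"] * np.exp(-(((grid - r["b1"]) / r["c1"]) ** 2)) + r[
                    "a2"
                ] * np.exp(-(((grid - r["b2"]) / r["c2"]) ** 2))
                errs.append(abs(grid[int(np.argmax(curve))] - b_true))
        report.metrics["single_peak_center_median_abs_error"] = float(np.median(errs))
        two_peak = fit_table[fit_table["movement"].isin(["abdominal", "eyelid", "swallowing"])]
        report.metrics["two_peak_preferred_fraction"] = float(
            (two_peak["preferred"] == 2).mean()
        )
        report.stage_status["task_glm_somatotopy"] = "ok"
    except Exception as exc:  # pragma: no cover
        report.stage_status["task_glm_somatotopy"] = f"failed: {exc}"
    report.timings_s["task_glm_somatotopy"] = round(time.time() - t0, 2)

    # --- structural -------------------------------------------------------
    t0 = time.time()
    try:
        thick = np.stack([s.structural.thickness for s in subjects])
        means, stats_table = conn.region_scalar_compare(thick, strip, alpha=config.alpha)
        report.tables["thickness_region_means"] = means
        report.tables["thickness_tests"] = stats_table
        report.metrics["thickness_inter_minus_effector_mm"] = float(
            stats_table["mean_diff"].mean()
        )
        report.metrics["thickness_max_q"] = float(stats_table["q"].max())
        report.stage_status["structural"] = "ok"
    except Exception as exc:  # pragma: no cover
        report.stage_status["structural"] = f"failed: {exc}"
    report.timings_s["structural"] = round(time.time() - t0, 2)

    return report


def _write_figures(report: RunReport, out: Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "peak_fits" in report.tables:
        fits = report.tables["peak_fits"]
        first = fits[fits["subject"] == fits["subject"].min()]
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.linspace(0, 120, 400)
        for _, row in first.iterrows():
            y = row["a1"] * np.exp(-(((x - row["b1"]) / row["c1"]) ** 2)) + row[
                "a2"
            ] * np.exp(-(((x - row["b2"]) / row["c2"]) ** 2))
            ax.plot(x, y, label=row["movement"])
        ax.set_xlabel("dorsal-ventral axis position")
        ax.set_ylabel("fitted activation (Z)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "peak_fits.png", dpi=120)
        plt.close(fig)
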