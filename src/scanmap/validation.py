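"""Simulation studies validating estimator calibration and recovery.

Each study regenerates synthetic data with known truth and measures the
behaviour of one estimator chain: type-I error and p-value uniformity of
the one- vs two-peak F-test, its power and peak-center recovery under a
genuine two-peak truth, lag-estimation error for injected band-limited
shifts, null calibration of GLM Z maps and of the paired t-test, and the
full end-to-end figure-analogue pattern recovery.  The studies are what
the acceptance checks and the pipeline report run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity as conn
from . import glm as tg
from . import lags as lg
from . import somatotopy as st
from . import synthetic as syn
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "ftest_null_calibration",
    "ftest_power_recovery",
    "lag_recovery",
    "glm_null_calibration",
    "paired_t_type1",
    "end_to_end_recovery",
]


def _fit_and_compare(y: np.ndarray, alpha: float = 0.05):
    n = y.size
    profile = st.AxisProfile(
        positions=np.arange(n), activation=y, fit_mask=np.ones(n, dtype=bool)
    )
    fit1, fit2 = st.fit_peak_models(profile)
    return fit1, fit2, st.compare_models_f(fit1, fit2, alpha=alpha)


def ftest_null_calibration(
    n_profiles: int = 500,
    n_positions: int = 60,
    peak: tuple[float, float, float] = (3.0, 30.0, 8.0),
    noise_ratio: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I behaviour of the model-comparison F-test.

    Profiles are drawn from a one-peak truth with noise sd =
    noise_ratio * a1; both models are fitted and the two-peak rejection
    rate at ``alpha`` plus a KS test of p-value uniformity are reported.
    """
    rng = np.random.default_rng([seed, 11])
    noise_sd = noise_ratio * peak[0]
    pvals = np.empty(n_profiles)
    for i in range(n_profiles):
        _, y = syn.sample_profile((peak,), n_positions, noise_sd, rng)
        _, _, comp = _fit_and_compare(y, alpha)
        pvals[i] = comp.p_value
    ks = stats.kstest(pvals, "uniform")
    return {
        "n": n_profiles,
        "rejection_rate": float((pvals < alpha).mean()),
        "ks_p": float(ks.pvalue),
        "pvalues": pvals,
    }


def ftest_power_recovery(
    n_profiles: int = 200,
    n_positions: int = 60,
    peaks: tuple = ((3.0, 18.0, 5.0), (3.0, 46.0, 5.0)),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Power of the F-test and peak-center recovery under a two-peak truth.

    The default truth has peak separation 28 >= 3 * max(c) and
    amplitude-to-noise ratio 3.  Reports the fraction of replicates in
    which the two-peak model is preferred at p < 0.001 and the median
    absolute error of the fitted centers.
    """
    rng = np.random.default_rng([seed, 12])
    b_true = np.sort([p[1] for p in peaks])
    n_detect = 0
    b_errors = []
    for _ in range(n_profiles):
        _, y = syn.sample_profile(peaks, n_positions, noise_sd, rng)
        _, fit2, comp = _fit_and_compare(y)
        if comp.p_value < 1e-3:
            n_detect += 1
        b_hat = np.sort([fit2.params[1], fit2.params[4]])
        b_errors.extend(np.abs(b_hat - b_true).tolist())
    return {
        "n": n_profiles,
        "detect_fraction": n_detect / n_profiles,
        "median_b_abs_error": float(np.median(b_errors)),
    }


def lag_recovery(
    shifts_s: tuple[float, ...] = (0.5, 1.0, 1.5),
    tr: float = 1.1,
    n_frames: int = 800,
    snr: float = 2.0,
    n_seeds: int = 100,
    max_lag_frames: int = 8,
    seed: int = 0,
) -> dict:
    """Lag-estimation error for injected band-limited fractional shifts.

    For each replicate, an infra-slow latent is shifted by the stated
    amount, both copies are corrupted with white noise at the stated
    SNR, and the parabolic-interpolated CCF extremum is compared with
    the injected shift.  Also asserts exact TD antisymmetry on the
    valid mask for every replicate pair.
    """
    rng_root = np.random.default_rng([seed, 13])
    errors = []
    n_invalid = 0
    noise_sd = 1.0 / snr
    for rep in range(n_seeds):
        rng = np.random.default_rng(rng_root.integers(2**31, size=2))
        latent = syn.infra_slow_signal(n_frames, tr, rng)
        for shift in shifts_s:
            x = latent + noise_sd * rng.standard_normal(n_frames)
            y = syn.band_limited_shift(latent, shift, tr) + noise_sd * rng.standard_normal(n_frames)
            run = syn.BoldRun(data=np.stack([x, y]), tr=tr, run_type="rest")
            td = lg.td_matrix(run, max_lag_frames=max_lag_frames)
            td.check()
            if not td.valid[0, 1]:
                n_invalid += 1
                continue
            # td[1, 0] > 0 means y is later; the injected delay of y is +shift
            errors.append(abs(td.td[1, 0] - shift))
    return {
        "n": n_seeds * len(shifts_s),
        "median_abs_error_s": float(np.median(errors)),
        "invalid_fraction": n_invalid / (n_seeds * len(shifts_s)),
    }


def glm_null_calibration(
    n_vertices: int = 10_000,
    tr: float = 1.1,
    seed: int = 0,
) -> dict:
    """Run-level GLM Z maps under the null are standard normal.

    Pure white-noise data are fitted with a standard two-condition block
    design; the Z values of the first condition across vertices should
    have mean ~0 and sd ~1.
    """
    rng = np.random.default_rng([seed, 14])
    design = tg.make_block_design(["a", "b"], n_blocks=3)
    n_frames = int(round(design.run_length_s / tr))
    X = tg.build_design_matrix(design, tr, n_frames)
    data = rng.standard_normal((n_vertices, n_frames))
    m = tg.fit_glm(data, X)
    z = m.condition_z("a")
    ks = stats.kstest(z, "norm")
    return {
        "n": n_vertices,
        "z_mean": float(z.mean()),
        "z_sd": float(z.std(ddof=1)),
        "ks_p": float(ks.pvalue),
    }


def paired_t_type1(
    n_reps: int = 10_000,
    n_subjects: int = 7,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical size of the paired t-test under a true null.

    Runs the package's paired-test routine on ``n_reps`` null samples of
    ``n_subjects`` paired observations and reports the uncorrected
    rejection rate at ``alpha``.
    """
    rng = np.random.default_rng([seed, 15])
    a = rng.standard_normal((n_reps, n_subjects))
    b = rng.standard_normal((n_reps, n_subjects))
    comparisons = {f"rep{i}": (a[i], b[i]) for i in range(n_reps)}
    table = conn.paired_ttest_fdr(comparisons, alpha=alpha)
    return {
        "n": n_reps,
        "rejection_rate": float((table["p"] < alpha).mean()),
    }


def end_to_end_recovery(
    n_subjects: int = 20, seed: int = 0, config: PipelineConfig | None = None
) -> dict:
    """Full pipeline on a simulated cohort; figure-analogue recovery metrics."""
    if config is None:
        config = PipelineConfig(seed=seed, n_subjects=n_subjects)
    report = run_pipeline(config)
    out = {"n": config.n_subjects, "ok": report.ok}
    out.update(report.metrics)
    out["report"] = report
    return out
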