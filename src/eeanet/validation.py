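"""End-to-end validation studies with known ground truth.

Each function runs one self-contained simulation study — density/simulator
agreement, EEA recovery, cross-validation calibration and signal recovery,
bootstrap coverage, and qualitative pattern reproduction on the default
cohort preset — and returns plain dictionaries of summary numbers.  The test
suite asserts on these outputs and the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import quad

from . import _wfpt
from .bayes import DriftDiffusionModel
from .cohort import (
    CohortSpec,
    build_task_schedule,
    confounded_null_cohort,
    generate_clustered_xy,
    generate_cohort,
    table1_preset,
    true_parameters_for_subject,
)
from .ddm import TrialSet, apply_quality_exclusions, simulate_trials
from .networks import (
    clustered_bootstrap_ci,
    decile_bin_summary,
    extract_network_means,
    network_regression_compare,
    quadrant_summary,
    residualize_on_covariates,
)
from .prediction import CrossValidatedPCR
from .priors import load_default_priors

__all__ = [
    "density_simulator_ks",
    "eea_recovery_study",
    "null_calibration_study",
    "signal_recovery_study",
    "bootstrap_coverage_study",
    "pattern_reproduction_study",
]

#: (drift, boundary, start) regimes for the density-simulator comparison,
#: spanning the parameter range seen in n-back fits.  Each set keeps both
#: boundary masses above ~0.2 so that a million simulated passages leave
#: enough samples per boundary for the KS comparison to be decisive.
KS_PARAMETER_SETS = (
    (1.0, 0.9, 0.5),
    (0.8, 0.8, 0.4),
    (1.5, 0.9, 0.5),
    (-1.2, 0.9, 0.6),
    (2.0, 0.8, 0.45),
)


def density_simulator_ks(v: float, a: float, w: float, n: int = 1_000_000,
                         dt: float = 1e-4, seed: int = 0) -> dict:
    """KS distance between simulated passage times and the series density.

    Compares, per boundary, the empirical CDF of bridge-corrected Euler
    passage times against the analytic CDF (adaptive integration of the
    series density, conditioned on the boundary).
    """
    rts, up = _wfpt.euler_fpt_sample(n, v, a, w, dt=dt, seed=seed)
    out = {}
    for boundary, args in (("upper", (-v, a, 1 - w)), ("lower", (v, a, w))):
        mask = (up == 1) if boundary == "upper" else (up == 0)
        r = np.sort(rts[mask & (rts > 0)])
        mass = quad(lambda t: float(_wfpt.pdf_lower(t, *args)), 0, 60, limit=200)[0]
        grid = np.linspace(1e-6, max(4.0, r[-1]), 8000)
        pdf = _wfpt.pdf_lower(grid, *args)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        F = np.interp(r, grid, cdf / mass)
        emp = np.arange(1, len(r) + 1) / len(r)
        out[boundary] = float(max(np.abs(F - emp).max(),
                                  np.abs(F - emp + 1 / len(r)).max()))
        out[f"n_{boundary}"] = int(len(r))
    return out


def eea_recovery_study(n_subjects: int = 50, seed: int = 0, priors=None,
                       dt: float = 1e-4, progress: bool = False) -> dict:
    """Simulate subjects, fit each under informative priors, score recovery.

    Returns the Pearson correlation between true and estimated overall EEA,
    the fraction of fits reaching convergence, and the per-subject table.
    """
    if priors is None:
        priors = load_default_priors()
    spec = CohortSpec(n_subjects=n_subjects)
    cohort = generate_cohort(spec, seed=seed)
    rng = np.random.default_rng(seed + 500)

    frames = []
    for _, row in cohort.truth.iterrows():
        sid = row["subject_id"]
        sched = build_task_schedule(sid, seed=int(rng.integers(2**31 - 1)))
        params = true_parameters_for_subject(row)
        ts = simulate_trials(params, sched, seed=int(rng.integers(2**31 - 1)), dt=dt)
        frames.append(ts.trials)
    trials = pd.concat(frames, ignore_index=True)
    retained, report, filtered = apply_quality_exclusions(trials)

    rows = []
    truth = cohort.truth.set_index("subject_id")
    for i, sid in enumerate(retained):
        sub = filtered[filtered.subject_id == sid].reset_index(drop=True)
        res = DriftDiffusionModel(TrialSet(trials=sub), priors).fit(
            seed=int(rng.integers(2**31 - 1))
        )
        med = res.summary()["median"]
        est_0 = np.mean([med[f"0-back.v_{c}"] for c in ("target", "novel", "lure")])
        est_2 = np.mean([med[f"2-back.v_{c}"] for c in ("target", "novel", "lure")])
        rows.append({
            "subject_id": sid,
            "true_eea_mean": truth.loc[sid, "eea_mean"],
            "est_eea_mean": (est_0 + est_2) / 2.0,
            "converged": res.converged,
            "max_rhat": float(np.nanmax(res.rhat)),
            "n_rounds": res.n_rounds,
        })
        if progress and (i + 1) % 10 == 0:
            print(f"  fitted {i + 1}/{len(retained)} subjects", flush=True)
    table = pd.DataFrame(rows)
    r = float(np.corrcoef(table.true_eea_mean, table.est_eea_mean)[0, 1])
    return {
        "recovery_r": r,
        "frac_converged": float(table.converged.mean()),
        "n_retained": len(retained),
        "n_excluded": int(cohort.truth.shape[0] - len(retained)),
        "table": table,
    }


def null_calibration_study(n_cohorts: int = 100, n: int = 500,
                           n_features: int = 100, seed: int = 0,
                           candidate_ks=(5, 10, 25)) -> dict:
    """Mean out-of-fold partial correlation on covariate-confounded null data."""
    rs = []
    for c in range(n_cohorts):
        X, y, cov = confounded_null_cohort(n, n_features, seed=seed + c)
        model = CrossValidatedPCR(y, X, cov, scheme="kfold", k=5, seed=seed + c)
        rs.append(model.fit(candidate_ks=candidate_ks, seed=seed + c).mean_r)
    rs = np.asarray(rs)
    return {"mean_r": float(rs.mean()), "sd_r": float(rs.std(ddof=1)),
            "n_cohorts": n_cohorts}


def signal_recovery_study(n: int = 2000, seed: int = 0) -> dict:
    """Cross-validated prediction on the default preset with planted signal.

    The preset's parcel-level loading pattern is calibrated so the population
    R^2 of overall EEA given the 2-0 map is 0.36; the out-of-fold partial
    correlation should approach sqrt(0.36) = 0.6 less estimation noise.
    """
    cohort = generate_cohort(table1_preset(n_subjects=n), seed=seed)
    y = pd.Series(cohort.truth.eea_mean.to_numpy(),
                  index=cohort.truth.subject_id.to_numpy(), name="eea")
    X = cohort.activation["2-0"].copy()
    X.index = cohort.truth.subject_id.to_numpy()
    model = CrossValidatedPCR(y, X, cohort.covariates, scheme="loso")
    res = model.fit(seed=seed)
    return {"mean_r": res.mean_r, "fold_rs": res.fold_rs, "fold_ks": res.fold_ks,
            "n": n, "planted_r2": 0.36}


def bootstrap_coverage_study(n_datasets: int = 300, population_r: float = 0.3,
                             n_sites: int = 30, families_per_site: int = 7,
                             subjects_per_family: int = 2, n_boot: int = 500,
                             site_share: float = 0.05, family_share: float = 0.1,
                             seed: int = 0) -> dict:
    """Coverage of the nominal 95% clustered-bootstrap CI for Pearson r.

    The cluster design mirrors large multi-site developmental studies: many
    sites, sibling pairs nested in families, and modest intraclass
    correlations at both levels.
    """
    covered = 0
    for d in range(n_datasets):
        x, y, si, fa = generate_clustered_xy(
            n_sites, families_per_site, subjects_per_family, population_r,
            seed=seed + d, site_share=site_share, family_share=family_share,
        )
        ci = clustered_bootstrap_ci(x, y, si, fa, n_boot=n_boot, seed=seed + d)
        covered += int(ci.contains(population_r))
    return {"coverage": covered / n_datasets, "n_datasets": n_datasets,
            "population_r": population_r}


def pattern_reproduction_study(n: int = 4000, seed: int = 0) -> dict:
    """Qualitative sign pattern of network-EEA relations on the preset cohort.

    Checks the divergent task-positive pattern (FPN/DAN positive in the
    2-back, negative in the 0-back, SMN negative in the 2-back), the decile
    slopes of FPN activation against EEA rank per condition, and the quadrant
    ordering of mean EEA.
    """
    cohort = generate_cohort(table1_preset(n_subjects=n), seed=seed)
    nm = {c: extract_network_means(cohort.activation[c], cohort.labels)
          for c in ("0", "2", "2-0")}
    ids = cohort.truth.subject_id.to_numpy()
    resid = {c: residualize_on_covariates(df.set_index(ids), cohort.covariates)
             for c, df in nm.items()}
    eea = pd.DataFrame({"eea": cohort.truth.eea_mean.to_numpy()}, index=ids)
    eea_r = residualize_on_covariates(eea, cohort.covariates)["eea"]

    corr = {}
    for c in ("0", "2", "2-0"):
        for net in resid[c].columns:
            corr[(net, c)] = float(np.corrcoef(resid[c][net], eea_r)[0, 1])

    bins = decile_bin_summary(eea_r.to_numpy(), {
        "0": resid["0"]["FPN"].to_numpy(), "2": resid["2"]["FPN"].to_numpy()})
    slopes = bins.groupby("condition")["slope"].first().to_dict()

    quad = quadrant_summary(resid["0"]["FPN"], resid["2"]["FPN"], eea_r)
    quad = quad.set_index("quadrant")

    compare = network_regression_compare(
        resid["2-0"], eea_r, True,
        cohort.covariates["site"].to_numpy(), cohort.covariates["family"].to_numpy(),
        n_boot=300, seed=seed,
    )

    return {
        "correlations": corr,
        "three_network_r": compare["subset"].estimate,
        "seven_network_r": compare["full"].estimate,
        "regression_cis_overlap": compare["subset"].overlaps(compare["full"]),
        "fpn_slope_0back": slopes["0"],
        "fpn_slope_2back": slopes["2"],
        "quadrant_upper_left": float(quad.loc["upper_left", "mean_eea_z"]),
        "quadrant_lower_right": float(quad.loc["lower_right", "mean_eea_z"]),
        "n": n,
    }
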