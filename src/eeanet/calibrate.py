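"""Informative-prior calibration.

The informative priors shipped with the package are produced by an emulation
of the prior-generation procedure used with developmental n-back data: fit
the diffusion model to every subject of an independent calibration cohort
under weakly informative priors, pool the posterior draws across subjects for
each parameter, and fit a truncated normal to each pooled distribution.
(The original procedure fits a hierarchical model to the independent sample;
here the hierarchy is replaced by pooled individual-level fits, since
group-level estimation is out of scope.)
"""

from __future__ import annotations

import numpy as np

from .bayes import DriftDiffusionModel, PARAM_LABELS
from .cohort import (
    CohortSpec,
    build_task_schedule,
    generate_cohort,
    true_parameters_for_subject,
)
from .ddm import CONDITIONS, PARAM_NAMES, TrialSet, apply_quality_exclusions, simulate_trials
from .priors import DEFAULT_BOUNDS, PriorSpec, fit_truncated_normal_prior, vague_priors

__all__ = ["emulate_prior_calibration"]


def emulate_prior_calibration(n_subjects: int = 300, seed: int = 0,
                              thin: int = 10, dt: float = 1e-4,
                              progress: bool = False) -> tuple[PriorSpec, dict]:
    """Build informative priors from a synthetic calibration cohort.

    Returns ``(priors, info)`` where ``info`` holds per-subject convergence
    flags and the pooled draw counts.  Deterministic under ``seed``.
    """
    spec = CohortSpec(n_subjects=n_subjects)
    cohort = generate_cohort(spec, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    base_priors = vague_priors()

    pooled = {(c, n): [] for c in CONDITIONS for n in PARAM_NAMES}
    flags = []
    for i, row in cohort.truth.iterrows():
        sid = row["subject_id"]
        sched = build_task_schedule(sid, seed=int(rng.integers(2**31 - 1)))
        params = true_parameters_for_subject(row)
        ts = simulate_trials(params, sched, seed=int(rng.integers(2**31 - 1)), dt=dt)
        retained, _report, filtered = apply_quality_exclusions(ts.trials)
        if sid not in retained:
            flags.append((sid, "excluded"))
            continue
        model = DriftDiffusionModel(TrialSet(trials=filtered), base_priors)
        res = model.fit(seed=int(rng.integers(2**31 - 1)))
        flags.append((sid, "converged" if res.converged else "non-converged"))
        flat = res.draws.reshape(-1, 16)[::thin]
        for j, lab in enumerate(PARAM_LABELS):
            cond = int(lab.split("-")[0])
            name = lab.split(".")[1]
            pooled[(cond, name)].append(flat[:, j])
        if progress and (i + 1) % 10 == 0:
            print(f"  calibrated {i + 1}/{n_subjects} subjects", flush=True)

    priors = PriorSpec()
    counts = {}
    for key, chunks in pooled.items():
        pool = np.concatenate(chunks)
        counts[key] = len(pool)
        priors[key] = fit_truncated_normal_prior(pool, DEFAULT_BOUNDS[key[1]])
    info = {
        "n_subjects": n_subjects,
        "flags": flags,
        "pool_counts": counts,
        "n_converged": sum(1 for _, f in flags if f == "converged"),
        "n_excluded": sum(1 for _, f in flags if f == "excluded"),
    }
    return priors, info
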