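"""Diffusion decision model for the n-back task: densities, likelihoods,
trial simulation, and behavioral quality exclusions.

The task has two load conditions (0-back, 2-back) and three stimulus classes
(target, novel, lure).  The model is accuracy coded: the upper boundary is the
correct response for every stimulus class (``match`` for targets, ``nonmatch``
for novels and lures), so each class's drift rate measures the quality of
evidence toward the correct response.  Eight free parameters per condition:
three class drifts, boundary separation ``a``, non-decision time ``t0`` with
uniform between-trial variability of width ``st0``, relative start point
``z``, and a contaminant-omission probability ``p_contam``.  Between-trial
drift and start-point variability (sv, sz) are deliberately not modeled.

Omissions are a mixture: with probability ``p_contam`` the trial is a
contaminant non-response generated outside the diffusion process; otherwise
the diffusion runs and the response is censored whenever the decision plus
non-decision time exceeds the response window (2 s in the canonical design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from . import _wfpt
from ._wfpt import gauss_legendre_01

CONDITIONS = (0, 2)
STIMULUS_CLASSES = ("target", "novel", "lure")
RESPONSES = ("match", "nonmatch", "none")
RESPONSE_WINDOW = 2.0
MIN_RT = 0.200            # trial-wise fast-guess cutoff, seconds
ACCURACY_FLOOR = 0.55     # subject-level exclusion threshold
OMISSION_CEILING = 0.25   # subject-level exclusion threshold

#: correct response per stimulus class under accuracy coding
CORRECT_RESPONSE = {"target": "match", "novel": "nonmatch", "lure": "nonmatch"}

PARAM_NAMES = ("v_target", "v_novel", "v_lure", "a", "t0", "st0", "z", "p_contam")

TRIAL_COLUMNS = ["subject_id", "condition", "stimulus_class", "response", "rt_s", "block_index"]

_ST0_NODES = 10  # Gauss-Legendre nodes over the non-decision-time interval


@dataclass(frozen=True)
class ConditionParameters:
    """The eight free parameters for one load condition."""

    v_target: float
    v_novel: float
    v_lure: float
    a: float
    t0: float
    st0: float
    z: float
    p_contam: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0.0 < self.z < 1.0:
            raise ValueError(f"relative start point must lie in (0, 1), got z={self.z}")
        if self.t0 < 0 or self.st0 < 0:
            raise ValueError("non-decision time parameters must be non-negative")
        if not 0.0 <= self.p_contam <= 1.0:
            raise ValueError("p_contam must lie in [0, 1]")

    def drift(self, stimulus_class: str) -> float:
        return getattr(self, f"v_{stimulus_class}")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in PARAM_NAMES)


@dataclass(frozen=True)
class DDMParameters:
    """Per-condition parameter sets plus the fixed diffusion coefficient.

    ``sigma`` is a scaling convention (fixed at 1, never estimated); estimates
    are comparable only across fits that share it.
    """

    conditions: dict = field(default_factory=dict)
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for cond, p in self.conditions.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if not isinstance(p, ConditionParameters):
                raise TypeError("condition entries must be ConditionParameters")

    def __getitem__(self, condition) -> ConditionParameters:
        return self.conditions[condition]

    def to_vector(self) -> np.ndarray:
        """Flatten to a 16-vector ordered (0-back params, 2-back params)."""
        return np.array(
            [getattr(self.conditions[c], n) for c in CONDITIONS for n in PARAM_NAMES]
        )

    @classmethod
    def from_vector(cls, vec, sigma: float = 1.0) -> "DDMParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (16,):
            raise ValueError("expected a 16-element parameter vector")
        conds = {}
        for i, c in enumerate(CONDITIONS):
            vals = vec[8 * i: 8 * (i + 1)]
            conds[c] = ConditionParameters(**dict(zip(PARAM_NAMES, vals)))
        return cls(conditions=conds, sigma=sigma)


@dataclass
class TrialSet:
    """Per-trial observations for a single subject.

    ``trials`` is a DataFrame with columns ``subject_id, condition,
    stimulus_class, response, rt_s, block_index``; ``rt_s`` is NaN exactly
    when ``response == 'none'``.
    """

    trials: pd.DataFrame
    response_window: float = RESPONSE_WINDOW

    def __post_init__(self):
        df = self.trials
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns {missing}")
        omitted = df["response"].eq("none")
        if not (df.loc[omitted, "rt_s"].isna().all() and df.loc[~omitted, "rt_s"].notna().all()):
            raise ValueError("rt_s must be absent exactly when response is 'none'")
        rts = df.loc[~omitted, "rt_s"]
        if len(rts) and not ((rts > 0) & (rts <= self.response_window)).all():
            raise ValueError("observed RTs must lie in (0, response_window]")
        bad = set(df["stimulus_class"]) - set(STIMULUS_CLASSES)
        if bad:
            raise ValueError(f"unknown stimulus classes {bad}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def subject_id(self):
        return self.trials["subject_id"].iloc[0]


def wiener_fpt_density(t, v, a, z, boundary="upper", sigma=1.0):
    """First-passage-time density of the diffusion at the named boundary.

    ``z`` is the relative start point (fraction of ``a``).  A diffusion
    coefficient other than 1 rescales drift and boundary: the density with
    coefficient ``sigma`` equals the unit-coefficient density at
    ``(v/sigma, a/sigma, z)``.
    """
    a_arr = np.asarray(a, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    if np.any(a_arr <= 0):
        raise ValueError("boundary separation a must be positive")
    if np.any((z_arr <= 0) | (z_arr >= 1)):
        raise ValueError("relative start point z must lie in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v_eff = np.asarray(v, dtype=float) / sigma
    a_eff = a_arr / sigma
    if boundary == "lower":
        return _wfpt.pdf_lower(t, v_eff, a_eff, z_arr)
    if boundary == "upper":
        return _wfpt.pdf_lower(t, -v_eff, a_eff, 1.0 - z_arr)
    raise ValueError("boundary must be 'upper' or 'lower'")


def _boundary_args(p: ConditionParameters, stimulus_class: str, correct: bool, sigma: float):
    """(v, a, w) for the lower-boundary density of the requested outcome."""
    v = p.drift(stimulus_class) / sigma
    a = p.a / sigma
    if correct:      # upper boundary via reflection
        return -v, a, 1.0 - p.z
    return v, a, p.z


def _mass_within_window(p, stimulus_class, correct, window, sigma, adaptive=False):
    """P(reach the given boundary with decision+non-decision time <= window).

    Integrates the first-passage density over decision time and the uniform
    non-decision-time distribution on [t0, t0 + st0].
    """
    v, a, w = _boundary_args(p, stimulus_class, correct, sigma)
    if p.st0 == 0:
        uppers = np.array([window - p.t0])
        wts = np.array([1.0])
    else:
        nodes, wts = gauss_legendre_01(_ST0_NODES)
        uppers = window - (p.t0 + p.st0 * nodes)
    uppers = np.maximum(uppers, 0.0)
    if adaptive:
        vals = np.array(
            [
                quad(lambda s: float(_wfpt.pdf_lower(s, v, a, w)), 0.0, u, limit=200)[0]
                if u > 0 else 0.0
                for u in uppers
            ]
        )
    else:
        vals = _wfpt.cdf_lower_quadrature(uppers, v, a, w)
    return float(np.clip(vals @ wts, 0.0, 1.0))


def response_probability(params: DDMParameters, condition, stimulus_class, outcome,
                         response_window: float = RESPONSE_WINDOW, adaptive: bool = False):
    """Probability of a correct response, an error, or an omission.

    The three outcomes partition the trial:  ``P(omission)`` is defined as the
    complement of the within-window response masses scaled by the contaminant
    mixture, so the three probabilities sum to one by construction.
    """
    if outcome not in ("correct", "error", "omission"):
        raise ValueError("outcome must be 'correct', 'error' or 'omission'")
    if stimulus_class not in STIMULUS_CLASSES:
        raise ValueError(f"unknown stimulus class {stimulus_class!r}")
    p = params[condition]
    if response_window <= p.t0 and p.st0 == 0:
        warnings.warn("response window does not exceed non-decision time; P(response)=0")
    pc = p.p_contam
    m_corr = _mass_within_window(p, stimulus_class, True, response_window, params.sigma, adaptive)
    m_err = _mass_within_window(p, stimulus_class, False, response_window, params.sigma, adaptive)
    if outcome == "correct":
        return (1.0 - pc) * m_corr
    if outcome == "error":
        return (1.0 - pc) * m_err
    return 1.0 - (1.0 - pc) * (m_corr + m_err)


def trial_log_likelihood(trial, params: DDMParameters,
                         response_window: float = RESPONSE_WINDOW) -> float:
    """Log-likelihood of one trial (a mapping or namedtuple-like row).

    For an observed response the contribution is
    ``(1 - p_contam) * mean_{t0'} f_boundary(rt - t0')`` with the mean taken
    over the uniform non-decision-time distribution by Gauss-Legendre
    quadrature; for an omission it is the contaminant/censoring mixture mass.
    Returns -inf for observations that are impossible under the parameters.
    """
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    condition = get("condition")
    stimulus_class = get("stimulus_class")
    response = get("response")
    p = params[condition]
    pc = p.p_contam

    if response == "none":
        m = sum(
            _mass_within_window(p, stimulus_class, corr, response_window, params.sigma)
            for corr in (True, False)
        )
        prob = pc + (1.0 - pc) * (1.0 - m)
        return float(np.log(prob)) if prob > 0 else -np.inf

    if pc >= 1.0:
        return -np.inf
    rt = float(get("rt_s"))
    correct = response == CORRECT_RESPONSE[stimulus_class]
    v, a, w = _boundary_args(p, stimulus_class, correct, params.sigma)
    if p.st0 == 0:
        dens = float(_wfpt.pdf_lower(rt - p.t0, v, a, w))
    else:
        nodes, wts = gauss_legendre_01(_ST0_NODES)
        dts = rt - (p.t0 + p.st0 * nodes)
        dens = float(_wfpt.pdf_lower(dts, v, a, w) @ wts)
    if dens <= 0:
        return -np.inf
    return float(np.log1p(-pc) + np.log(dens))


def subject_log_likelihood(trials: TrialSet, params: DDMParameters) -> float:
    """Sum of per-trial log-likelihoods; -inf propagates."""
    if len(trials) == 0:
        raise ValueError("empty trial set")
    total = 0.0
    for row in trials.trials.itertuples(index=False):
        ll = trial_log_likelihood(row._asdict(), params, trials.response_window)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def simulate_trials(params: DDMParameters, schedule: pd.DataFrame, seed: int,
                    response_window: float = RESPONSE_WINDOW, dt: float = 1e-4) -> TrialSet:
    """Simulate choices, RTs and omissions for a trial schedule.

    ``schedule`` needs columns ``subject_id, condition, stimulus_class,
    block_index``.  Decision times come from the bridge-corrected Euler
    simulation of the diffusion; uniform non-decision time is added, responses
    slower than the window are censored into omissions, and contaminant
    omissions are injected with probability ``p_contam``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDITIONS:
        sub = schedule[schedule["condition"] == cond]
        if sub.empty:
            continue
        p = params[cond]
        for cls in STIMULUS_CLASSES:
            cls_rows = sub[sub["stimulus_class"] == cls]
            n = len(cls_rows)
            if n == 0:
                continue
            v = p.drift(cls) / params.sigma
            dec, up = _wfpt.euler_fpt_sample(
                n, v, p.a / params.sigma, p.z, dt=dt,
                t_max=response_window + 1.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            ndt = p.t0 + p.st0 * rng.random(n)
            rt = np.where(dec > 0, dec + ndt, np.inf)
            omitted = (rt > response_window) | (rng.random(n) < p.p_contam)
            correct_resp = CORRECT_RESPONSE[cls]
            wrong_resp = "nonmatch" if correct_resp == "match" else "match"
            resp = np.where(up == 1, correct_resp, wrong_resp)
            for (idx, sched_row), r, t_obs, om in zip(
                cls_rows.iterrows(), resp, rt, omitted
            ):
                rows.append(
                    {
                        "subject_id": sched_row["subject_id"],
                        "condition": cond,
                        "stimulus_class": cls,
                        "response": "none" if om else r,
                        "rt_s": np.nan if om else float(t_obs),
                        "block_index": sched_row["block_index"],
                    }
                )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    # restore schedule order within subject
    df = df.sort_values(["condition", "block_index"], kind="stable").reset_index(drop=True)
    return TrialSet(trials=df, response_window=response_window)


def apply_quality_exclusions(trials: pd.DataFrame,
                             response_window: float = RESPONSE_WINDOW):
    """Behavioral quality filter.

    Fast guesses (RT < 200 ms) are removed trial-wise first.  A subject is
    then excluded when, in either load condition, accuracy over non-omitted
    trials falls below 55% or the omission rate over all trials exceeds 25%.
    Returns ``(retained_ids, report, filtered)`` where ``report`` is a
    per-subject-condition table of accuracy, omission rate and exclusion
    reason and ``filtered`` is the RT-filtered trial table restricted to
    retained subjects.
    """
    df = trials.copy()
    fast = df["rt_s"].notna() & (df["rt_s"] < MIN_RT)
    df = df[~fast]

    records = []
    excluded_ids = set()
    for sid, sub in df.groupby("subject_id", sort=True):
        for cond in CONDITIONS:
            cond_df = sub[sub["condition"] == cond]
            n = len(cond_df)
            if n == 0:
                records.append((sid, cond, np.nan, np.nan, 1, "no data"))
                excluded_ids.add(sid)
                continue
            omitted = cond_df["response"].eq("none")
            omission_rate = float(omitted.mean())
            scored = cond_df[~omitted]
            if len(scored) == 0:
                records.append((sid, cond, np.nan, omission_rate, 1, "no data"))
                excluded_ids.add(sid)
                continue
            correct = scored.apply(
                lambda r: r["response"] == CORRECT_RESPONSE[r["stimulus_class"]], axis=1
            )
            accuracy = float(correct.mean())
            reasons = []
            if accuracy < ACCURACY_FLOOR:
                reasons.append("accuracy<55%")
            if omission_rate > OMISSION_CEILING:
                reasons.append("omissions>25%")
            excluded = bool(reasons)
            if excluded:
                excluded_ids.add(sid)
            records.append(
                (sid, cond, accuracy, omission_rate, int(excluded), ";".join(reasons))
            )

    report = pd.DataFrame(
        records,
        columns=["subject_id", "condition", "accuracy", "omission_rate", "excluded", "reason"],
    )
    all_ids = list(pd.unique(trials["subject_id"]))
    retained = [sid for sid in all_ids if sid not in excluded_ids]
    filtered = df[df["subject_id"].isin(retained)].reset_index(drop=True)
    return retained, report, filtered


def read_trial_table(path) -> pd.DataFrame:
    """Read the tab-separated trial-table format."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    df["rt_s"] = pd.to_numeric(df["rt_s"], errors="coerce")
    return df[TRIAL_COLUMNS]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")
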