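"""Bayesian estimation of the diffusion model and extraction of the
efficiency of evidence accumulation (EEA).

One model is fitted per subject (16 free parameters: 8 per load condition)
under truncated-normal priors using differential-evolution MCMC — an ensemble
sampler whose proposals are scaled difference vectors between randomly chosen
chains, well suited to the correlated, bounded posteriors of sequential
sampling models.  Because the two load conditions share no parameters, the
posterior factorizes into two 8-dimensional blocks which the sampler updates
alternately within each sweep; this is exact and mixes far better than joint
16-dimensional proposals.  Sampling is repeated in rounds until the
split-chain potential-scale-reduction statistic (rhat) drops below 1.1 for
every parameter, up to a round cap; fits that never converge are retained but
flagged.

EEA per condition is the mean of the posterior medians of the three class
drift rates; the headline index averages the two conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr

from . import _wfpt
from ._wfpt import gauss_legendre_01, pdf_scalar
from .ddm import (
    CONDITIONS,
    CORRECT_RESPONSE,
    PARAM_NAMES,
    STIMULUS_CLASSES,
    DDMParameters,
    TrialSet,
    simulate_trials,
)
from .priors import PriorSpec

__all__ = [
    "DriftDiffusionModel",
    "DDMResults",
    "EEARecord",
    "gelman_rubin_rhat",
    "compute_eea",
    "write_eea_table",
]

_ST0_NODES = 10   # Gauss-Legendre nodes over the non-decision-time interval
_CDF_NODES = 32   # quadrature nodes for within-window absorption masses
_PC_BLOCK_INDEX = 7   # p_contam position within an 8-parameter block
_LIK_EPS = 1e-7   # series truncation inside the sampler's likelihood

PARAM_LABELS = [f"{c}-back.{n}" for c in CONDITIONS for n in PARAM_NAMES]


def gelman_rubin_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction per parameter.

    ``draws`` has shape (n_chains, n_draws, n_params); each chain is split in
    half so stationarity within chains is also penalized.  Constant parameters
    return 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (n_chains >= 2, n_draws, n_params)")
    n_draws = draws.shape[1]
    half = n_draws // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    split = np.concatenate([draws[:, :half, :], draws[:, half: 2 * half, :]], axis=0)
    n = split.shape[1]
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w <= 1e-300, 1.0, rhat)


@dataclass(frozen=True)
class EEARecord:
    subject_id: str
    eea_0back: float
    eea_2back: float
    eea_mean: float
    converged: bool = True


def compute_eea(results: "DDMResults") -> EEARecord:
    """EEA per condition = mean of posterior-median class drift rates."""
    med = results.posterior_median
    idx = {lab: i for i, lab in enumerate(PARAM_LABELS)}
    vals = {}
    for cond in CONDITIONS:
        vals[cond] = float(
            np.mean([med[idx[f"{cond}-back.v_{cls}"]] for cls in STIMULUS_CLASSES])
        )
    if not results.converged:
        warnings.warn(
            f"subject {results.subject_id}: EEA extracted from a non-converged fit"
        )
    return EEARecord(
        subject_id=results.subject_id,
        eea_0back=vals[0],
        eea_2back=vals[2],
        eea_mean=(vals[0] + vals[2]) / 2.0,
        converged=results.converged,
    )


def write_eea_table(records, path) -> None:
    """Write a cohort-level tab-separated table of EEA records."""
    df = pd.DataFrame([
        {"subject_id": r.subject_id, "eea_0back": r.eea_0back,
         "eea_2back": r.eea_2back, "eea_mean": r.eea_mean,
         "converged": int(r.converged)}
        for r in records
    ])
    df.to_csv(path, sep="\t", index=False)


class _SubjectData:
    """Trial data reorganized for vectorized likelihood evaluation."""

    def __init__(self, trials: TrialSet):
        self.response_window = trials.response_window
        df = trials.trials
        self.per_condition = {}
        n_resp_total = 0
        for cond in CONDITIONS:
            sub = df[df["condition"] == cond]
            resp = sub[sub["response"] != "none"]
            om = sub[sub["response"] == "none"]
            cls_idx = np.array(
                [STIMULUS_CLASSES.index(c) for c in resp["stimulus_class"]], dtype=int
            )
            correct = np.array(
                [r == CORRECT_RESPONSE[c] for r, c in zip(resp["response"], resp["stimulus_class"])],
                dtype=bool,
            )
            om_counts = np.array(
                [int((om["stimulus_class"] == c).sum()) for c in STIMULUS_CLASSES]
            )
            self.per_condition[cond] = {
                "rt": resp["rt_s"].to_numpy(dtype=float),
                "cls": cls_idx,
                "correct": correct,
                "om_counts": om_counts,
            }
            n_resp_total += len(resp)
        if n_resp_total == 0:
            raise ValueError(
                "all trials are omissions; the diffusion parameters are not "
                "identifiable from omission counts alone"
            )


@njit(cache=True, fastmath=True)
def _block_loglik_kernel(blk, rt, cls, correct, om_counts, window,
                         st0_nodes, st0_wts, cdf_nodes, cdf_wts):  # pragma: no cover - numba
    n_sets = blk.shape[0]
    n_trials = rt.shape[0]
    n_q = st0_nodes.shape[0]
    n_c = cdf_nodes.shape[0]
    out = np.empty(n_sets)
    for s in range(n_sets):
        a = blk[s, 3]
        t0 = blk[s, 4]
        st0 = blk[s, 5]
        z = blk[s, 6]
        pc = blk[s, 7]
        total = 0.0
        bad = False
        if n_trials > 0:
            if pc >= 1.0:
                out[s] = -np.inf
                continue
            log_resp = np.log1p(-pc)
            for i in range(n_trials):
                v = blk[s, cls[i]]
                if correct[i]:
                    ve = -v
                    we = 1.0 - z
                else:
                    ve = v
                    we = z
                fbar = 0.0
                for q in range(n_q):
                    dt_ = rt[i] - (t0 + st0 * st0_nodes[q])
                    fbar += st0_wts[q] * pdf_scalar(dt_, ve, a, we, _LIK_EPS)
                if fbar <= 0.0:
                    bad = True
                    break
                total += log_resp + np.log(fbar)
        if bad:
            out[s] = -np.inf
            continue
        cch = a * a  # rational-map time constant for the mass quadrature
        for c in range(3):
            count = om_counts[c]
            if count == 0:
                continue
            v = blk[s, c]
            mass = 0.0
            for q in range(n_q):
                horizon = window - (t0 + st0 * st0_nodes[q])
                if horizon <= 0.0:
                    continue
                smax = horizon / (horizon + cch)
                acc = 0.0
                for j in range(n_c):
                    sj = smax * cdf_nodes[j]
                    tj = cch * sj / (1.0 - sj)
                    jac = cch / ((1.0 - sj) * (1.0 - sj))
                    acc += cdf_wts[j] * jac * (
                        pdf_scalar(tj, -v, a, 1.0 - z, _LIK_EPS)
                        + pdf_scalar(tj, v, a, z, _LIK_EPS)
                    )
                m = acc * smax
                if m < 0.0:
                    m = 0.0
                elif m > 1.0:
                    m = 1.0
                mass += st0_wts[q] * m
            if mass > 1.0:
                mass = 1.0
            p_om = pc + (1.0 - pc) * (1.0 - mass)
            if p_om <= 0.0:
                bad = True
                break
            total += count * np.log(p_om)
        out[s] = -np.inf if bad else total
    return out


def _loglik_block(blk: np.ndarray, d: dict, window: float) -> np.ndarray:
    """Log-likelihood of one condition's trials for (n_sets, 8) parameters.

    Thin wrapper over the compiled kernel; :func:`_loglik_block_numpy` keeps
    the original vectorized-numpy computation as an independent cross-check.
    """
    blk = np.ascontiguousarray(np.atleast_2d(np.asarray(blk, dtype=float)))
    st0_nodes, st0_wts = gauss_legendre_01(_ST0_NODES)
    cdf_nodes, cdf_wts = gauss_legendre_01(_CDF_NODES)
    return _block_loglik_kernel(
        blk, d["rt"], d["cls"].astype(np.int64), d["correct"],
        d["om_counts"].astype(np.int64), float(window),
        st0_nodes, st0_wts, cdf_nodes, cdf_wts,
    )


def _loglik_block_numpy(blk: np.ndarray, d: dict, window: float) -> np.ndarray:
    """Vectorized-numpy implementation of the block log-likelihood."""
    blk = np.atleast_2d(np.asarray(blk, dtype=float))
    n_sets = blk.shape[0]
    total = np.zeros(n_sets)
    nodes01, wts = gauss_legendre_01(_ST0_NODES)
    drifts, a, t0, st0, z, pc = (
        blk[:, 0:3], blk[:, 3], blk[:, 4], blk[:, 5], blk[:, 6], blk[:, 7]
    )
    t0_nodes = t0[:, None] + st0[:, None] * nodes01[None, :]         # (S, Q)

    if len(d["rt"]):
        v_tr = drifts[:, d["cls"]]                                   # (S, T)
        w_tr = np.where(d["correct"][None, :], 1.0 - z[:, None], z[:, None])
        v_eff = np.where(d["correct"][None, :], -v_tr, v_tr)
        dts = d["rt"][None, :, None] - t0_nodes[:, None, :]          # (S, T, Q)
        dens = _wfpt.pdf_lower(
            dts, v_eff[:, :, None], a[:, None, None], w_tr[:, :, None]
        )
        fbar = dens @ wts
        with np.errstate(divide="ignore"):
            ll = np.where(fbar > 0, np.log(fbar), -np.inf)
        with np.errstate(divide="ignore"):
            log_resp_scale = np.where(pc < 1.0, np.log1p(-np.minimum(pc, 1 - 1e-300)), -np.inf)
        total += log_resp_scale * len(d["rt"]) + ll.sum(axis=1)

    active = np.nonzero(d["om_counts"])[0]
    if len(active):
        uppers = np.maximum(window - t0_nodes, 0.0)
        for k in active:
            v = drifts[:, k]
            m_up = _wfpt.cdf_lower_quadrature(
                uppers, -v[:, None], a[:, None], 1.0 - z[:, None], n_nodes=_CDF_NODES
            )
            m_lo = _wfpt.cdf_lower_quadrature(
                uppers, v[:, None], a[:, None], z[:, None], n_nodes=_CDF_NODES
            )
            mass = np.clip((m_up + m_lo) @ wts, 0.0, 1.0)
            p_om = pc + (1.0 - pc) * (1.0 - mass)
            with np.errstate(divide="ignore"):
                total += d["om_counts"][k] * np.where(p_om > 0, np.log(p_om), -np.inf)
    return total


def _loglik_matrix(theta: np.ndarray, data: _SubjectData) -> np.ndarray:
    """Joint log-likelihood for each row of a (n_sets, 16) parameter matrix."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    total = np.zeros(theta.shape[0])
    for ci, cond in enumerate(CONDITIONS):
        total += _loglik_block(
            theta[:, 8 * ci: 8 * ci + 8], data.per_condition[cond], data.response_window
        )
    return total


class _BlockPrior:
    """Truncated-normal prior over one 8-parameter block, with the
    contaminant probability mapped to a logit sampling scale."""

    def __init__(self, priors):
        self.priors = list(priors)
        self.loc = np.array([p.location for p in self.priors])
        self.scale = np.array([p.scale for p in self.priors])
        self.lo = np.array([p.lower for p in self.priors])
        self.hi = np.array([p.upper for p in self.priors])
        self.pinned = np.array([p.pinned for p in self.priors])
        with np.errstate(all="ignore"):
            za = (self.lo - self.loc) / self.scale
            zb = (self.hi - self.loc) / self.scale
            self.log_z = np.log(ndtr(zb) - ndtr(za))
        self.j = _PC_BLOCK_INDEX
        self.pc_free = not self.pinned[self.j]

    def natural(self, state: np.ndarray) -> np.ndarray:
        nat = state.copy()
        if self.pc_free:
            j = self.j
            nat[..., j] = self.lo[j] + (self.hi[j] - self.lo[j]) / (
                1.0 + np.exp(-state[..., j])
            )
        return nat

    def state(self, nat: np.ndarray) -> np.ndarray:
        st = nat.copy()
        if self.pc_free:
            j = self.j
            frac = np.clip((nat[..., j] - self.lo[j]) / (self.hi[j] - self.lo[j]),
                           1e-9, 1.0 - 1e-9)
            st[..., j] = np.log(frac / (1.0 - frac))
        return st

    def logpdf(self, nat: np.ndarray, state: np.ndarray) -> np.ndarray:
        nat = np.atleast_2d(nat)
        state = np.atleast_2d(state)
        free = ~self.pinned
        x = nat[:, free]
        inside = np.all((x >= self.lo[free]) & (x <= self.hi[free]), axis=1)
        zsc = (x - self.loc[free]) / self.scale[free]
        lp = (-0.5 * zsc**2 - np.log(self.scale[free])
              - 0.5 * np.log(2.0 * np.pi) - self.log_z[free]).sum(axis=1)
        if self.pc_free:
            s = 1.0 / (1.0 + np.exp(-state[:, self.j]))
            lp += np.log(self.hi[self.j] - self.lo[self.j]) + np.log(s) + np.log1p(-s)
        return np.where(inside, lp, -np.inf)

    def rvs(self, rng) -> np.ndarray:
        return np.array([p.rvs(rng=rng) for p in self.priors])


class DriftDiffusionModel:
    """Per-subject Bayesian diffusion model for n-back trial data.

    Parameters
    ----------
    trials:
        The subject's :class:`~eeanet.ddm.TrialSet` (after quality exclusions).
    priors:
        :class:`~eeanet.priors.PriorSpec` of truncated-normal priors over the
        16 free parameters.
    """

    def __init__(self, trials: TrialSet, priors: PriorSpec):
        self.trials = trials
        self.priors = priors
        self._data = _SubjectData(trials)
        self._blocks = [
            _BlockPrior([priors[(c, n)] for n in PARAM_NAMES]) for c in CONDITIONS
        ]

    def log_likelihood(self, params: DDMParameters) -> float:
        """Vectorized-path log-likelihood for one parameter set."""
        return float(_loglik_matrix(params.to_vector()[None, :], self._data)[0])

    def log_posterior(self, vec: np.ndarray) -> float:
        """Log posterior density (natural scale, up to a constant)."""
        vec = np.asarray(vec, dtype=float)
        total = 0.0
        for ci, cond in enumerate(CONDITIONS):
            bp = self._blocks[ci]
            nat = vec[8 * ci: 8 * ci + 8][None, :]
            st = bp.state(nat)
            lp = float(bp.logpdf(nat, st)[0])
            if not np.isfinite(lp):
                return -np.inf
            total += lp + float(
                _loglik_block(nat, self._data.per_condition[cond], self._data.response_window)[0]
            )
        return total

    def fit(self, seed: int = 0, n_chains: int | None = None, n_burn: int = 300,
            n_keep: int = 500, max_rounds: int = 5, rhat_threshold: float = 1.1,
            migration_prob: float = 0.15) -> "DDMResults":
        """Sample the posterior by blockwise differential-evolution MCMC.

        Because the posterior factorizes into two 8-parameter condition
        blocks, proposals act blockwise and ``n_chains`` defaults to three
        times the dimension of the largest block (24 for the canonical
        design).  Each sweep updates the two blocks in turn with DE proposals
        built from the other chains' states; a migration move that lets stuck
        chains adopt better states runs with small probability during burn-in
        only.  Blocks of ``n_keep`` post-burn-in sweeps are drawn repeatedly
        until every parameter's split-rhat over the latest block is below
        ``rhat_threshold`` (at most ``max_rounds`` blocks); the latest block
        is the reported posterior sample.
        """
        rng = np.random.default_rng(seed)
        if n_chains is None:
            n_chains = 3 * int(max((~b.pinned).sum() for b in self._blocks))
        if n_chains < 8:
            raise ValueError("need at least 8 chains for DE-MCMC")

        data_blocks = [self._data.per_condition[c] for c in CONDITIONS]
        window = self._data.response_window

        # initialize from the priors, redrawing until the posterior is finite
        states = []       # per block: (n_chains, 8) on the sampling scale
        lls = []
        lps = []
        for bi, bp in enumerate(self._blocks):
            st = np.empty((n_chains, 8))
            for i in range(n_chains):
                for _attempt in range(200):
                    nat = bp.rvs(rng)[None, :]
                    cand = bp.state(nat)[0]
                    lp = float(bp.logpdf(nat, cand[None, :])[0])
                    ll = float(_loglik_block(nat, data_blocks[bi], window)[0])
                    if np.isfinite(lp + ll):
                        st[i] = cand
                        break
                else:
                    raise RuntimeError(
                        "could not find a finite-posterior starting point; "
                        "check the data against the priors"
                    )
            states.append(st)
            nat = bp.natural(st)
            lps.append(bp.logpdf(nat, st))
            lls.append(_loglik_block(nat, data_blocks[bi], window))

        d_block = 8
        gamma0 = 2.38 / np.sqrt(2.0 * d_block)

        def sweep(migrate_ok: bool):
            for bi, bp in enumerate(self._blocks):
                st = states[bi]
                n = n_chains
                r1 = rng.integers(0, n - 1, size=n)
                r1 = r1 + (r1 >= np.arange(n))
                r2 = rng.integers(0, n - 2, size=n)
                lo_ = np.minimum(np.arange(n), r1)
                hi_ = np.maximum(np.arange(n), r1)
                r2 = r2 + (r2 >= lo_)
                r2 = r2 + (r2 >= hi_)
                gamma = np.where(rng.random(n) < 0.1, 0.98, gamma0)[:, None]
                prop = st + gamma * (st[r1] - st[r2]) + rng.uniform(-1e-3, 1e-3, st.shape)
                prop[:, bp.pinned] = st[:, bp.pinned]
                nat = bp.natural(prop)
                lp_prop = bp.logpdf(nat, prop)
                ll_prop = np.full(n, -np.inf)
                ok = np.isfinite(lp_prop)
                if ok.any():
                    ll_prop[ok] = _loglik_block(nat[ok], data_blocks[bi], window)
                accept = np.log(rng.random(n)) < (lp_prop + ll_prop - lps[bi] - lls[bi])
                st[accept] = prop[accept]
                lps[bi] = np.where(accept, lp_prop, lps[bi])
                lls[bi] = np.where(accept, ll_prop, lls[bi])
                if migrate_ok and rng.random() < migration_prob:
                    k = int(rng.integers(2, max(3, n // 4)))
                    idx = rng.choice(n, size=k, replace=False)
                    src = np.roll(idx, 1)
                    cur = lps[bi][idx] + lls[bi][idx]
                    new = lps[bi][src] + lls[bi][src]
                    acc = np.log(rng.random(k)) < (new - cur)
                    st[idx[acc]] = st[src[acc]]
                    lps[bi][idx[acc]] = lps[bi][src[acc]]
                    lls[bi][idx[acc]] = lls[bi][src[acc]]

        for _ in range(n_burn):
            sweep(migrate_ok=True)

        rounds = 0
        rhat = None
        kept = None
        while rounds < max_rounds:
            block_draws = np.empty((n_chains, n_keep, 16))
            for it in range(n_keep):
                sweep(migrate_ok=False)
                for bi, bp in enumerate(self._blocks):
                    block_draws[:, it, 8 * bi: 8 * bi + 8] = bp.natural(states[bi])
            rounds += 1
            kept = block_draws
            rhat = gelman_rubin_rhat(kept)
            if np.nanmax(rhat) < rhat_threshold:
                break

        converged = bool(np.nanmax(rhat) < rhat_threshold)
        return DDMResults(
            subject_id=str(self.trials.subject_id),
            draws=kept,
            rhat=rhat,
            converged=converged,
            n_rounds=rounds,
            model=self,
        )


class DDMResults:
    """Posterior sample and diagnostics for one subject's diffusion-model fit."""

    def __init__(self, subject_id, draws, rhat, converged, n_rounds, model=None):
        self.subject_id = subject_id
        self.draws = draws                      # (n_chains, n_draws, 16), natural scale
        self.rhat = np.asarray(rhat, dtype=float)
        self.converged = bool(converged)
        self.n_rounds = int(n_rounds)
        self.model = model
        flat = draws.reshape(-1, draws.shape[-1])
        self.posterior_median = np.median(flat, axis=0)
        self.posterior_sd = flat.std(axis=0, ddof=1)

    @property
    def param_labels(self):
        return list(PARAM_LABELS)

    def median_parameters(self) -> DDMParameters:
        return DDMParameters.from_vector(self.posterior_median)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median": self.posterior_median,
                "sd": self.posterior_sd,
                "rhat": self.rhat,
            },
            index=self.param_labels,
        )

    def eea(self) -> EEARecord:
        return compute_eea(self)

    def to_json(self, path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "converged": self.converged,
            "n_rounds": self.n_rounds,
            "parameters": {
                lab: {"median": float(m), "sd": float(s), "rhat": float(r)}
                for lab, m, s, r in zip(
                    self.param_labels, self.posterior_median, self.posterior_sd, self.rhat
                )
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    # ---- posterior predictive ---------------------------------------------
    def posterior_predictive_check(self, n_rep: int = 100, seed: int = 0,
                                   dt: float = 1e-3) -> pd.DataFrame:
        """Observed vs replicated behavioral statistics.

        Simulates ``n_rep`` datasets from randomly drawn posterior parameter
        vectors on the observed trial schedule and summarizes accuracy,
        omission rate and RT deciles per condition with 2.5/97.5% predictive
        intervals.
        """
        if self.model is None:
            raise ValueError("results were created without the fitted model attached")
        rng = np.random.default_rng(seed)
        obs = self.model.trials.trials
        window = self.model.trials.response_window
        schedule = obs[["subject_id", "condition", "stimulus_class", "block_index"]]
        flat = self.draws.reshape(-1, 16)

        def stats(df):
            out = {}
            for cond in CONDITIONS:
                sub = df[df["condition"] == cond]
                if len(sub) == 0:
                    continue
                om = sub["response"].eq("none")
                out[(cond, "omission_rate")] = float(om.mean())
                scored = sub[~om]
                if len(scored):
                    corr = [
                        r == CORRECT_RESPONSE[c]
                        for r, c in zip(scored["response"], scored["stimulus_class"])
                    ]
                    out[(cond, "accuracy")] = float(np.mean(corr))
                    for q in range(1, 10):
                        out[(cond, f"rt_q{q * 10}")] = float(
                            np.quantile(scored["rt_s"], q / 10.0)
                        )
            return out

        obs_stats = stats(obs)
        reps = []
        for _ in range(int(n_rep)):
            vec = flat[rng.integers(len(flat))]
            sim = simulate_trials(
                DDMParameters.from_vector(vec), schedule,
                seed=int(rng.integers(2**31 - 1)), response_window=window, dt=dt,
            )
            reps.append(stats(sim.trials))

        rows = []
        for key, obs_val in obs_stats.items():
            vals = np.array([r[key] for r in reps if key in r])
            lo, hi = (np.quantile(vals, [0.025, 0.975]) if len(vals) else (np.nan, np.nan))
            rows.append(
                {
                    "condition": key[0],
                    "statistic": key[1],
                    "observed": obs_val,
                    "rep_mean": float(vals.mean()) if len(vals) else np.nan,
                    "rep_lo": float(lo),
                    "rep_hi": float(hi),
                    "inside": bool(lo <= obs_val <= hi) if len(vals) else False,
                }
            )
        return pd.DataFrame(rows)
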