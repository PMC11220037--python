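"""Truncated-normal priors for the diffusion-model parameters.

Informative priors are built by pooling posterior draws across an independent
calibration cohort and fitting a truncated normal per parameter by maximum
likelihood; the package ships a default prior file produced by that procedure
on a synthetic calibration cohort (see ``build_informative_priors``).  Priors
can be widened by a scalar factor on their scales to make them less
informative for a population that differs from the calibration sample.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.stats import truncnorm

from .ddm import CONDITIONS, PARAM_NAMES

__all__ = [
    "TruncatedNormalPrior",
    "PriorSpec",
    "fit_truncated_normal_prior",
    "scale_priors",
    "default_bounds",
    "vague_priors",
    "load_default_priors",
]

#: domain bounds per free parameter, chosen to cover plausible human RT
#: regimes under the unit-diffusion scaling convention
DEFAULT_BOUNDS = {
    "v_target": (-10.0, 10.0),
    "v_novel": (-10.0, 10.0),
    "v_lure": (-10.0, 10.0),
    "a": (1e-3, 10.0),
    "t0": (0.05, 1.0),
    "st0": (0.0, 1.0),
    "z": (0.1, 0.9),
    "p_contam": (0.0, 0.5),
}


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """location/scale of the untruncated normal plus truncation bounds."""

    location: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower <= self.upper:
            raise ValueError("lower bound must not exceed upper bound")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def pinned(self) -> bool:
        """Zero-width bounds pin the parameter to a point mass."""
        return self.lower == self.upper

    def _ab(self):
        return (self.lower - self.location) / self.scale, (self.upper - self.location) / self.scale

    def logpdf(self, x):
        if self.pinned:
            x = np.asarray(x, dtype=float)
            return np.where(x == self.lower, 0.0, -np.inf)
        a, b = self._ab()
        return truncnorm.logpdf(x, a, b, loc=self.location, scale=self.scale)

    def rvs(self, size=None, rng=None):
        if self.pinned:
            return np.full(size, self.lower) if size is not None else self.lower
        # inverse-CDF draw; avoids scipy's per-call distribution overhead
        from scipy.special import ndtr, ndtri
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        a, b = self._ab()
        fa, fb = ndtr(a), ndtr(b)
        u = rng.uniform(fa, fb, size=size)
        return self.location + self.scale * ndtri(u)


class PriorSpec(dict):
    """Mapping ``(condition, parameter_name) -> TruncatedNormalPrior``.

    Key order follows the 16-vector layout used by the sampler.
    """

    @classmethod
    def from_flat(cls, entries: dict) -> "PriorSpec":
        spec = cls()
        for cond in CONDITIONS:
            for name in PARAM_NAMES:
                spec[(cond, name)] = entries[(cond, name)]
        return spec

    def logpdf_vector(self, vec: np.ndarray) -> float:
        keys = [(c, n) for c in CONDITIONS for n in PARAM_NAMES]
        total = 0.0
        for x, k in zip(vec, keys):
            total += float(self[k].logpdf(x))
        return total

    def to_yaml(self, path) -> None:
        payload = {}
        for (cond, name), prior in self.items():
            payload.setdefault(f"{cond}-back", {})[name] = {
                "location": float(prior.location),
                "scale": float(prior.scale),
                "lower": float(prior.lower),
                "upper": float(prior.upper),
            }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, source) -> "PriorSpec":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        spec = cls()
        for cond in CONDITIONS:
            block = payload[f"{cond}-back"]
            for name in PARAM_NAMES:
                e = block[name]
                spec[(cond, name)] = TruncatedNormalPrior(
                    e["location"], e["scale"], e["lower"], e["upper"]
                )
        return spec


def default_bounds(name: str) -> tuple[float, float]:
    return DEFAULT_BOUNDS[name]


def vague_priors(scale_factor: float = 1.0) -> PriorSpec:
    """Weakly informative priors spanning the plausible parameter ranges.

    Used for the calibration cohort whose pooled posteriors generate the
    shipped informative priors.
    """
    centers = {
        "v_target": (1.5, 3.0), "v_novel": (1.5, 3.0), "v_lure": (1.0, 3.0),
        "a": (1.2, 1.0), "t0": (0.35, 0.25), "st0": (0.2, 0.25),
        "z": (0.5, 0.2), "p_contam": (0.1, 0.15),
    }
    spec = PriorSpec()
    for cond in CONDITIONS:
        for name in PARAM_NAMES:
            loc, sc = centers[name]
            lo, hi = DEFAULT_BOUNDS[name]
            spec[(cond, name)] = TruncatedNormalPrior(loc, sc * scale_factor, lo, hi)
    return spec


def fit_truncated_normal_prior(pool, bounds) -> TruncatedNormalPrior:
    """Maximum-likelihood truncated normal fitted to pooled posterior draws.

    ``bounds`` fixes the truncation interval; location and scale of the
    underlying normal are estimated by minimizing the negative log-likelihood
    over (location, log scale).
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size < 100:
        raise ValueError("need at least 100 pooled draws to fit a prior")
    lo, hi = bounds
    if not (np.all(pool >= lo - 1e-9) and np.all(pool <= hi + 1e-9)):
        raise ValueError("pooled draws fall outside the truncation bounds")
    sd = float(np.std(pool))
    if sd == 0:
        raise ValueError("degenerate pool: zero variance")
    mean = float(np.mean(pool))
    pool = np.clip(pool, lo, hi)

    # Identifiability box: as location and scale diverge together the family
    # degenerates into pure exponential tilts on [lo, hi] with unidentifiable
    # parameters, so the search is confined to a generous neighbourhood of
    # the truncation interval.
    width = hi - lo
    loc_box = (lo - 2 * width, hi + 2 * width)
    max_scale = 10 * width

    def nll(theta):
        loc, log_scale = theta
        scale = np.exp(log_scale)
        if not (loc_box[0] <= loc <= loc_box[1]) or not (0 < scale <= max_scale):
            return 1e12
        a, b = (lo - loc) / scale, (hi - loc) / scale
        with np.errstate(all="ignore"):
            ll = truncnorm.logpdf(pool, a, b, loc=loc, scale=scale)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(np.sum(ll))

    best = None
    for x0 in ([mean, np.log(sd)], [mean, np.log(2 * sd)], [(lo + hi) / 2, np.log(hi - lo)]):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    loc, log_scale = best.x
    return TruncatedNormalPrior(float(loc), float(np.exp(log_scale)), lo, hi)


def scale_priors(priors: PriorSpec, factor: float) -> PriorSpec:
    """Multiply every prior scale by ``factor``; locations and bounds unchanged."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = PriorSpec()
    for key, p in priors.items():
        out[key] = TruncatedNormalPrior(p.location, p.scale * factor, p.lower, p.upper)
    return out


def load_default_priors() -> PriorSpec:
    """Informative priors shipped with the package.

    Generated by pooling individual-level posterior draws from a 300-subject
    synthetic calibration cohort fitted under vague priors, then fitting a
    truncated normal per parameter (``build_informative_priors``).
    """
    ref = importlib.resources.files("eeanet.data").joinpath("default_priors.yaml")
    with ref.open() as fh:
        return PriorSpec.from_yaml(fh)


def build_informative_priors(pooled_draws: dict, bounds: dict | None = None) -> PriorSpec:
    """Fit per-parameter truncated normals to pooled posterior draws.

    ``pooled_draws`` maps ``(condition, parameter_name)`` to a 1-D array of
    draws pooled across calibration subjects.
    """
    spec = PriorSpec()
    for cond in CONDITIONS:
        for name in PARAM_NAMES:
            b = (bounds or DEFAULT_BOUNDS)[name] if not isinstance(
                (bounds or DEFAULT_BOUNDS).get(name, None), dict
            ) else bounds[name]
            spec[(cond, name)] = fit_truncated_normal_prior(pooled_draws[(cond, name)], b)
    return spec
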