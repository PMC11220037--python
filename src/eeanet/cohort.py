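"""Synthetic cohort generation with known ground truth.

Emulates the statistical structure of a large developmental neuroimaging
study of the n-back task: per-subject diffusion-model parameters drawn from a
population model (with correlated evidence-accumulation efficiency across
load conditions and covariate effects), behavioral trial tables simulated
from those parameters, parcel-level activation maps for the 0-back and 2-back
contrasts over a 7-network cortical parcellation, nuisance covariates (age,
sex, race/ethnicity, head motion), and two-level cluster structure (families
nested in acquisition sites).

The activation model is linear-Gaussian and is written directly in terms of
*residualized, standardized* quantities, so every planted correlation refers
to the partial correlation that remains after regressing out the nuisance
covariates — which is what the downstream analyses estimate.  For subject
``i``, network ``n``, condition ``c`` the network-mean signal is

    act = baseline(n, c) + r(n, c) * E_i + q(n) * G_i + site + family + u

with ``E`` the standardized covariate-free part of overall EEA, ``G`` a
shared "general activation" factor inducing the positive cross-condition
correlation, and the variance components chosen so the network mean has unit
residual variance — hence ``corr(network mean, E) = r(n, c)`` exactly in the
population.  A zero-mean per-parcel loading pattern adds sub-network
predictive signal; its scale is calibrated at construction so the population
R-squared of E given the full 2-0 parcel map equals a target (default 0.36).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ddm import CONDITIONS, PARAM_NAMES, DDMParameters, TrialSet, simulate_trials
from .priors import DEFAULT_BOUNDS

__all__ = [
    "NetworkSpec",
    "ActivationSpec",
    "BehaviorSpec",
    "ClusterSpec",
    "CovariateSpec",
    "CohortSpec",
    "Cohort",
    "table1_preset",
    "build_task_schedule",
    "generate_cohort",
    "generate_cohort_behavior",
    "generate_clustered_xy",
    "confounded_null_cohort",
]

NETWORK_NAMES = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

_PARCEL_PATTERN_SEED = 1915  # fixed: the per-parcel loading pattern is part of the preset


@dataclass(frozen=True)
class NetworkSpec:
    """One network's size, condition baselines, and planted EEA correlations."""

    name: str
    n_parcels: int
    baseline_0: float
    baseline_2: float
    r0: float          # partial corr(0-back network mean, overall EEA)
    r2: float          # partial corr(2-back network mean, overall EEA)

    def __post_init__(self):
        if not (-1 < self.r0 < 1 and -1 < self.r2 < 1):
            raise ValueError("planted correlations must lie in (-1, 1)")
        if self.n_parcels < 1:
            raise ValueError("network needs at least one parcel")


@dataclass
class ActivationSpec:
    """Generative model for parcel-level activation maps."""

    networks: list
    rho_cross: float = 0.35       # cross-condition network-mean correlation
    site_var: float = 0.04        # variance share of the site random effect
    family_var: float = 0.06      # variance share of the family random effect
    parcel_noise_sd: float = 0.8  # independent per-parcel noise SD
    target_r2: float | None = 0.36  # population R^2 of EEA given the 2-0 map
    # nuisance effects (standardized covariate -> activation shift) applied to
    # every parcel of the named network; removed downstream by residualization
    age_effect: dict = field(default_factory=lambda: {"FPN": 0.15, "DAN": 0.15})
    fd_effect: dict = field(default_factory=lambda: {"SMN": 0.25, "VIS": 0.2})
    sex_effect: dict = field(default_factory=lambda: {"DMN": 0.1})

    def __post_init__(self):
        self.networks = list(self.networks)
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate network names")
        for n in self.networks:
            if self.general_var(n) < 0:
                raise ValueError(
                    f"network {n.name}: rho_cross too small for the planted "
                    "correlations and cluster variances (implied covariance "
                    "not positive definite)"
                )
            for cond in (0, 2):
                if self.idio_var(n, cond) <= 0:
                    raise ValueError(
                        f"network {n.name}, {cond}-back: planted variance "
                        "components exceed the unit residual variance"
                    )

    def general_var(self, net: NetworkSpec) -> float:
        """q^2 for the shared general-activation factor."""
        return self.rho_cross - net.r0 * net.r2 - self.site_var - self.family_var

    def idio_var(self, net: NetworkSpec, cond: int) -> float:
        """Variance of the network-condition noise keeping unit total."""
        r = net.r0 if cond == 0 else net.r2
        return (
            1.0 - r**2 - self.general_var(net) - self.site_var - self.family_var
            - self.parcel_noise_sd**2 / net.n_parcels
        )

    @property
    def n_parcels(self) -> int:
        return sum(n.n_parcels for n in self.networks)

    def labels(self) -> pd.DataFrame:
        rows = []
        pid = 0
        for net in self.networks:
            for _ in range(net.n_parcels):
                rows.append({"parcel_id": f"p{pid:04d}", "network": net.name})
                pid += 1
        return pd.DataFrame(rows)


@dataclass
class BehaviorSpec:
    """Population distribution of the diffusion-model parameters.

    Class drifts decompose into a condition-level latent (shared across the
    three stimulus classes, correlated across conditions) plus class-specific
    noise, covariate effects, and family/site effects, so that overall EEA has
    a controlled cross-condition correlation and known covariate structure.
    """

    # per condition: means of the 8 parameters
    means: dict = field(default_factory=lambda: {
        0: {"v_target": 2.5, "v_novel": 3.0, "v_lure": 1.8, "a": 1.1,
            "t0": 0.35, "st0": 0.15, "z": 0.5, "p_contam": 0.03},
        2: {"v_target": 1.6, "v_novel": 2.2, "v_lure": 1.0, "a": 1.2,
            "t0": 0.40, "st0": 0.18, "z": 0.5, "p_contam": 0.05},
    })
    # between-subject SDs of the non-drift parameters
    sds: dict = field(default_factory=lambda: {
        "a": 0.18, "t0": 0.05, "st0": 0.05, "z": 0.05, "p_contam": 0.03,
    })
    sigma_common: float = 0.6     # SD of the condition-level drift latent
    sigma_class: float = 0.45     # SD of class-specific drift noise
    eea_cross_corr: float = 0.45  # target corr(EEA 0-back, EEA 2-back)
    site_sd: float = 0.10         # drift shift shared within a site
    family_sd: float = 0.15       # drift shift shared within a family
    beta_age: float = 0.15        # drift shift per SD of age
    beta_fd: float = -0.10        # drift shift per SD of motion
    beta_sex: float = 0.05        # drift shift for the +0.5 coded sex

    def latent_corr(self) -> float:
        """Correlation of the condition latents implied by the EEA target."""
        var_eea = (self.sigma_common**2 + self.sigma_class**2 / 3
                   + self.site_sd**2 + self.family_sd**2)
        cov_needed = self.eea_cross_corr * var_eea - self.site_sd**2 - self.family_sd**2
        rho = cov_needed / self.sigma_common**2
        if not -1 < rho < 1:
            raise ValueError("eea_cross_corr infeasible for the variance components")
        return rho

    def resid_eea_sd(self) -> float:
        """SD of the covariate-free part of overall (mean) EEA."""
        rho = self.latent_corr()
        return float(np.sqrt(
            self.sigma_common**2 * (1 + rho) / 2.0
            + self.sigma_class**2 / 6.0
            + self.site_sd**2 + self.family_sd**2
        ))


@dataclass
class ClusterSpec:
    n_sites: int = 20
    family_size_probs: dict = field(default_factory=lambda: {1: 0.8, 2: 0.2})


@dataclass
class CovariateSpec:
    age_range: tuple = (9.0, 11.0)        # years
    fd_log_mean: float = np.log(0.18)     # framewise displacement, mm
    fd_log_sd: float = 0.5
    raceeth_probs: tuple = (0.5, 0.2, 0.2, 0.1)


@dataclass
class CohortSpec:
    n_subjects: int = 1000
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    activation: ActivationSpec = None
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)

    def __post_init__(self):
        if self.activation is None:
            self.activation = _default_activation()


def _default_networks():
    # sizes roughly proportional to a 400-parcel 7-network cortical parcellation
    return [
        NetworkSpec("VIS", 58, 0.30, 0.35, 0.02, -0.08),
        NetworkSpec("SMN", 58, -0.10, -0.40, 0.02, -0.29),
        NetworkSpec("DAN", 57, 0.05, 0.45, -0.07, 0.17),
        NetworkSpec("VAN", 57, 0.05, 0.15, 0.03, -0.05),
        NetworkSpec("LIM", 28, -0.05, -0.15, 0.05, -0.14),
        NetworkSpec("FPN", 71, 0.10, 0.50, -0.27, 0.17),
        NetworkSpec("DMN", 71, -0.20, -0.50, 0.00, 0.01),
    ]


def _default_activation():
    return ActivationSpec(networks=_default_networks())


def table1_preset(n_subjects: int = 4000) -> CohortSpec:
    """The default cohort preset.

    Plants the qualitative (and approximate quantitative) pattern of
    network-EEA partial correlations observed in large n-back samples:
    task-positive networks (FPN, DAN) positively related to EEA in the
    2-back and negatively in the 0-back, the somatomotor network reversed,
    a positive cross-condition activation correlation, and sub-network
    predictive heterogeneity scaled so the full-map population R-squared for
    overall EEA is 0.36.  These are targets of the generator, not results.
    """
    return CohortSpec(n_subjects=n_subjects)


# --------------------------------------------------------------------------
# task schedule
# --------------------------------------------------------------------------

def build_task_schedule(subject_id: str, seed: int, n_blocks: int = 8,
                        trials_per_block: int = 10, n_targets: int = 2,
                        lure_choices=(2, 3)) -> pd.DataFrame:
    """Blocked n-back trial schedule for one subject.

    Per condition: ``n_blocks`` blocks of ``trials_per_block`` trials, each
    with exactly ``n_targets`` targets and a uniformly chosen number of lures
    from ``lure_choices``; the remainder are novel stimuli, order randomized
    within block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDITIONS:
        for b in range(n_blocks):
            n_lures = int(rng.choice(lure_choices))
            classes = (["target"] * n_targets + ["lure"] * n_lures
                       + ["novel"] * (trials_per_block - n_targets - n_lures))
            rng.shuffle(classes)
            for cls in classes:
                rows.append({
                    "subject_id": subject_id, "condition": cond,
                    "stimulus_class": cls, "block_index": b,
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: ground truth, covariates, and activation maps."""

    spec: CohortSpec
    truth: pd.DataFrame          # per subject: true parameters and EEA
    covariates: pd.DataFrame     # subject_id, site, family, age, age2, sex, raceeth, fd, fd2
    activation: dict             # {"0": df, "2": df, "2-0": df}, subjects x parcels
    labels: pd.DataFrame         # parcel_id, network

    def network_names(self):
        return [n.name for n in self.spec.activation.networks]

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
        self.labels.to_csv(out / "parcel_labels.tsv", sep="\t", index=False)
        for contrast, df in self.activation.items():
            name = contrast.replace("-", "minus")
            df.to_csv(out / f"activation_{name}.tsv", sep="\t")
        payload = self.truth.to_dict(orient="list")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(payload, fh)


def generate_covariates_and_clusters(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Assign sites/families and draw nuisance covariates."""
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    cl, cov = spec.clusters, spec.covariates

    sizes = np.array(list(cl.family_size_probs.keys()))
    probs = np.array(list(cl.family_size_probs.values()), dtype=float)
    probs = probs / probs.sum()

    subj, fam, site = [], [], []
    fam_id = 0
    while len(subj) < n:
        fsize = int(rng.choice(sizes, p=probs))
        fsite = int(rng.integers(cl.n_sites))
        for _ in range(min(fsize, n - len(subj))):
            subj.append(f"sub{len(subj):05d}")
            fam.append(f"fam{fam_id:05d}")
            site.append(f"site{fsite:02d}")
        fam_id += 1

    age = rng.uniform(*cov.age_range, size=n)
    sex = rng.integers(0, 2, size=n)           # 0 = F, 1 = M
    raceeth = rng.choice(len(cov.raceeth_probs), size=n, p=cov.raceeth_probs)
    fd = np.exp(rng.normal(cov.fd_log_mean, cov.fd_log_sd, size=n))
    return pd.DataFrame({
        "subject_id": subj, "site": site, "family": fam,
        "age": age, "age2": age**2, "sex": sex,
        "raceeth": raceeth, "fd": fd, "fd2": fd**2,
    })


def _standardize(x):
    return (x - np.mean(x)) / np.std(x)


def sample_population_parameters(spec: CohortSpec, covariates: pd.DataFrame,
                                 seed: int) -> pd.DataFrame:
    """Draw per-subject true diffusion parameters and EEA.

    Returns the ground-truth table with one row per subject: the 16 true
    parameters, true EEA per condition and overall, and the standardized
    covariate-free EEA component ``eea_resid_z`` used to plant activation
    correlations.
    """
    rng = np.random.default_rng(seed)
    b = spec.behavior
    n = spec.n_subjects
    rho = b.latent_corr()

    z_age = _standardize(covariates["age"].to_numpy())
    z_fd = _standardize(covariates["fd"].to_numpy())
    sex_c = covariates["sex"].to_numpy() - 0.5

    site_codes, site_idx = np.unique(covariates["site"], return_inverse=True)
    fam_codes, fam_idx = np.unique(covariates["family"], return_inverse=True)
    site_b = rng.normal(0, b.site_sd, len(site_codes))[site_idx]
    fam_b = rng.normal(0, b.family_sd, len(fam_codes))[fam_idx]

    cov_part = b.beta_age * z_age + b.beta_fd * z_fd + b.beta_sex * sex_c

    u = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    cols = {}
    resid_eea = np.zeros(n)
    for ci, cond in enumerate(CONDITIONS):
        mu = b.means[cond]
        class_noise = rng.normal(0, b.sigma_class, size=(n, 3))
        drift_shift = b.sigma_common * u[:, ci] + site_b + fam_b + cov_part
        for k, cls in enumerate(("target", "novel", "lure")):
            name = f"v_{cls}"
            lo, hi = DEFAULT_BOUNDS[name]
            cols[f"{cond}.{name}"] = np.clip(
                mu[name] + drift_shift + class_noise[:, k], lo, hi
            )
        for name in ("a", "t0", "st0", "z", "p_contam"):
            lo, hi = DEFAULT_BOUNDS[name]
            lo = max(lo, 1e-6) if name == "a" else lo
            cols[f"{cond}.{name}"] = np.clip(
                rng.normal(mu[name], b.sds[name], size=n), lo, hi
            )
        eea_c = np.mean(
            [cols[f"{cond}.v_{cls}"] for cls in ("target", "novel", "lure")], axis=0
        )
        cols[f"eea_{cond}back"] = eea_c
        resid_eea += (b.sigma_common * u[:, ci] + site_b + fam_b
                      + class_noise.mean(axis=1)) / 2.0

    truth = pd.DataFrame(cols)
    truth.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    truth["eea_mean"] = (truth["eea_0back"] + truth["eea_2back"]) / 2.0
    truth["eea_resid_z"] = resid_eea / b.resid_eea_sd()
    return truth


def _parcel_pattern(act: ActivationSpec) -> np.ndarray:
    """Fixed zero-mean (within network) per-parcel loading pattern, unit scale."""
    rng = np.random.default_rng(_PARCEL_PATTERN_SEED)
    h = rng.normal(0.0, 1.0, act.n_parcels)
    start = 0
    for net in act.networks:
        sl = slice(start, start + net.n_parcels)
        h[sl] -= h[sl].mean()
        h[sl] /= h[sl].std()
        start += net.n_parcels
    return h


def implied_population_r2(act: ActivationSpec, h_scale: float) -> float:
    """Population R^2 of standardized EEA given the full 2-0 parcel map.

    Built from the exact generative covariance: the shared factor, site and
    family effects cancel in the 2-0 difference, leaving the EEA channel
    (network loading Delta-r plus the parcel pattern), network-condition
    noise, and independent parcel noise.
    """
    h = h_scale * _parcel_pattern(act)
    p = act.n_parcels
    c = np.empty(p)
    start = 0
    blocks = []
    for net in act.networks:
        sl = slice(start, start + net.n_parcels)
        c[sl] = (net.r2 - net.r0) + h[sl]
        blocks.append((sl, act.idio_var(net, 0) + act.idio_var(net, 2)))
        start += net.n_parcels
    sigma = np.outer(c, c)
    for sl, var in blocks:
        sigma[sl, sl] += var
    sigma[np.diag_indices(p)] += 2.0 * act.parcel_noise_sd**2
    sol = np.linalg.solve(sigma, c)
    return float(c @ sol)


def _calibrate_h_scale(act: ActivationSpec) -> float:
    if act.target_r2 is None:
        return 0.0
    base = implied_population_r2(act, 0.0)
    if base >= act.target_r2:
        return 0.0
    f = lambda s: implied_population_r2(act, s) - act.target_r2
    return float(brentq(f, 0.0, 5.0, xtol=1e-6))


def generate_activation_maps(truth: pd.DataFrame, spec: CohortSpec,
                             covariates: pd.DataFrame, seed: int) -> dict:
    """Generate subjects-by-parcels activation for both conditions.

    Returns ``{"0": df, "2": df, "2-0": df}`` with parcel IDs as columns and
    subject IDs as index; the 2-0 matrix is the elementwise difference.
    """
    rng = np.random.default_rng(seed)
    act = spec.activation
    n = len(truth)
    p = act.n_parcels
    labels = act.labels()
    e = truth["eea_resid_z"].to_numpy()

    z_age = _standardize(covariates["age"].to_numpy())
    z_fd = _standardize(covariates["fd"].to_numpy())
    sex_c = covariates["sex"].to_numpy() - 0.5

    site_codes, site_idx = np.unique(covariates["site"], return_inverse=True)
    fam_codes, fam_idx = np.unique(covariates["family"], return_inverse=True)
    site_e = rng.normal(0, np.sqrt(act.site_var), len(site_codes))[site_idx]
    fam_e = rng.normal(0, np.sqrt(act.family_var), len(fam_codes))[fam_idx]
    g = rng.normal(0, 1, n)

    h = _calibrate_h_scale(act) * _parcel_pattern(act)

    mats = {}
    for cond in (0, 2):
        out = np.empty((n, p))
        start = 0
        for net in act.networks:
            sl = slice(start, start + net.n_parcels)
            r = net.r0 if cond == 0 else net.r2
            q = np.sqrt(act.general_var(net))
            u = rng.normal(0, np.sqrt(act.idio_var(net, cond)), n)
            base = net.baseline_0 if cond == 0 else net.baseline_2
            net_mean = base + r * e + q * g + site_e + fam_e + u
            net_mean = net_mean + (
                act.age_effect.get(net.name, 0.0) * z_age * (cond == 2)
                + act.fd_effect.get(net.name, 0.0) * z_fd
                + act.sex_effect.get(net.name, 0.0) * sex_c
            )
            sign = 0.5 if cond == 2 else -0.5
            parcel_sig = sign * h[sl][None, :] * e[:, None]
            noise = rng.normal(0, act.parcel_noise_sd, (n, net.n_parcels))
            out[:, sl] = net_mean[:, None] + parcel_sig + noise
            start += net.n_parcels
        mats[str(cond)] = pd.DataFrame(
            out, index=truth["subject_id"].to_numpy(), columns=labels["parcel_id"]
        )
    mats["2-0"] = mats["2"] - mats["0"]
    for df in mats.values():
        df.index.name = "subject_id"
    return mats


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Full cohort: clusters, covariates, true parameters, activation maps."""
    covariates = generate_covariates_and_clusters(spec, seed)
    truth = sample_population_parameters(spec, covariates, seed + 1)
    activation = generate_activation_maps(truth, spec, covariates, seed + 2)
    return Cohort(
        spec=spec, truth=truth, covariates=covariates,
        activation=activation, labels=spec.activation.labels(),
    )


def true_parameters_for_subject(truth_row) -> DDMParameters:
    conds = {}
    for cond in CONDITIONS:
        vals = {name: float(truth_row[f"{cond}.{name}"]) for name in PARAM_NAMES}
        from .ddm import ConditionParameters
        conds[cond] = ConditionParameters(**vals)
    return DDMParameters(conditions=conds)


def generate_cohort_behavior(truth: pd.DataFrame, seed: int,
                             schedule_seed: int | None = None,
                             dt: float = 1e-4) -> pd.DataFrame:
    """Simulate trial tables for every subject in the ground-truth table."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, row in truth.iterrows():
        sid = row["subject_id"]
        sched = build_task_schedule(
            sid, seed=int(rng.integers(2**31 - 1)) if schedule_seed is None
            else schedule_seed + i,
        )
        params = true_parameters_for_subject(row)
        ts = simulate_trials(params, sched, seed=int(rng.integers(2**31 - 1)), dt=dt)
        frames.append(ts.trials)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# auxiliary simulators for calibration studies
# --------------------------------------------------------------------------

def generate_clustered_xy(n_sites: int, families_per_site: int,
                          subjects_per_family: int, r: float, seed: int,
                          site_share: float = 0.15, family_share: float = 0.2):
    """Bivariate clustered data with exact population correlation ``r``.

    Site, family and individual components are each bivariate normal with
    correlation ``r``, so the marginal correlation equals ``r`` at every
    level while observations within a cluster are dependent.  Returns
    ``(x, y, site_ids, family_ids)``.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    ind_share = 1.0 - site_share - family_share
    if ind_share <= 0:
        raise ValueError("variance shares must leave room for individual noise")
    n_fam = n_sites * families_per_site
    n = n_fam * subjects_per_family
    site_eff = rng.multivariate_normal([0, 0], cov * site_share, n_sites)
    fam_eff = rng.multivariate_normal([0, 0], cov * family_share, n_fam)
    ind_eff = rng.multivariate_normal([0, 0], cov * ind_share, n)
    fam_site = np.repeat(np.arange(n_sites), families_per_site)
    subj_fam = np.repeat(np.arange(n_fam), subjects_per_family)
    total = site_eff[fam_site][subj_fam] + fam_eff[subj_fam] + ind_eff
    return (total[:, 0], total[:, 1], fam_site[subj_fam].astype(str),
            subj_fam.astype(str))


def confounded_null_cohort(n: int, n_features: int, seed: int,
                           confound_strength: float = 0.5):
    """A cohort where outcome and features share covariate-driven variance only.

    Conditional on the nuisance covariates the outcome is independent of the
    features, so any out-of-sample *partial* correlation is null-calibrated
    while the raw correlation is not.  Returns ``(X, y, covariates)``.
    """
    rng = np.random.default_rng(seed)
    covariates = pd.DataFrame({
        "subject_id": [f"sub{i:05d}" for i in range(n)],
        "site": "site00",
        "family": [f"fam{i:05d}" for i in range(n)],
        "age": rng.uniform(9, 11, n),
        "sex": rng.integers(0, 2, n),
        "raceeth": rng.integers(0, 4, n),
        "fd": np.exp(rng.normal(np.log(0.18), 0.5, n)),
    })
    covariates["age2"] = covariates["age"] ** 2
    covariates["fd2"] = covariates["fd"] ** 2
    z_age = _standardize(covariates["age"].to_numpy())
    z_fd = _standardize(covariates["fd"].to_numpy())
    sex_c = covariates["sex"].to_numpy() - 0.5
    conf = confound_strength * (z_age - z_fd + sex_c)
    y = conf + rng.normal(0, 1, n)
    loadings = rng.normal(0, 1, n_features)
    X = np.outer(conf, loadings) + rng.normal(0, 1, (n, n_features))
    X = pd.DataFrame(X, index=covariates["subject_id"],
                     columns=[f"p{j:04d}" for j in range(n_features)])
    return X, pd.Series(y, index=covariates["subject_id"], name="y"), covariates
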