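"""Cross-validated principal-components regression (PCR) linking activation
maps to behavior, scored as an out-of-sample partial correlation.

The estimand is the correlation between brain-predicted and observed outcome
*after* both have been residualized on nuisance covariates, estimated without
leakage: each training fold centers the features, computes principal
components, regresses component expressions and the outcome on the covariate
design, and fits OLS of the residualized outcome on residualized expressions;
the test fold is projected, residualized and scored with training-fold
parameters only.  The number of retained components K is chosen per outer
fold by a nested 5-fold cross-validation within the training rows, scored by
the same partial-correlation metric.

Fold schemes: leave-one-site-out (one fold per acquisition site) or k-fold
with whole families always assigned to a single fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "build_covariate_design",
    "make_folds",
    "select_num_components",
    "fit_pcr_fold",
    "predict_and_correlate",
    "run_cv_pipeline",
    "consensus_feature_map",
    "CrossValidatedPCR",
    "PCRResults",
    "PCRFoldModel",
]

DEFAULT_K_GRID = (5, 10, 25, 50, 100, 250)

NUISANCE_NUMERIC = ("age", "age2", "sex", "fd", "fd2")


def build_covariate_design(covariates: pd.DataFrame, raceeth_levels=None,
                           drop_collinear: bool = True):
    """Covariate design matrix: intercept, numeric nuisances, race dummies.

    Race/ethnicity is reference-level dummy coded against a fixed level set
    (``raceeth_levels``; defaults to the levels present), so train and test
    splits of one dataset produce aligned columns.  Collinear columns are
    dropped with a warning.  Returns ``(matrix, column_names)``.
    """
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in NUISANCE_NUMERIC:
        if c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    if "raceeth" in covariates.columns:
        levels = (np.unique(covariates["raceeth"]) if raceeth_levels is None
                  else np.asarray(raceeth_levels))
        for lv in levels[1:]:
            cols.append((covariates["raceeth"] == lv).to_numpy(dtype=float))
            names.append(f"raceeth_{lv}")
    design = np.column_stack(cols)
    # drop collinear columns (keep earliest)
    rank = np.linalg.matrix_rank(design)
    if drop_collinear and rank < design.shape[1]:
        keep = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear covariate columns: {dropped}")
        design = design[:, keep]
        names = [names[j] for j in keep]
    return design, names


def make_folds(covariates: pd.DataFrame, scheme: str = "kfold", k: int = 10,
               seed: int = 0, respect_family: bool = True) -> pd.Series:
    """Fold labels per subject.

    ``loso``: one fold per site (labelled by site).  ``kfold``: whole
    families are dealt to the ``k`` folds in random order onto the currently
    smallest fold, keeping sizes balanced; deterministic under ``seed``.
    """
    idx = covariates["subject_id"]
    if scheme == "loso":
        labels = covariates["site"].astype(str)
        counts = labels.value_counts()
        small = counts[counts < 10]
        if len(small):
            warnings.warn(f"sites with fewer than 10 subjects kept as folds: "
                          f"{list(small.index)}")
        return pd.Series(labels.to_numpy(), index=idx.to_numpy(), name="fold")
    if scheme != "kfold":
        raise ValueError("scheme must be 'loso' or 'kfold'")
    rng = np.random.default_rng(seed)
    if respect_family:
        groups = covariates.groupby("family")["subject_id"].apply(list)
    else:
        groups = pd.Series({i: [s] for i, s in enumerate(idx)})
    order = rng.permutation(len(groups))
    sizes = np.zeros(k, dtype=int)
    assign = {}
    for gi in order:
        members = groups.iloc[gi]
        f = int(np.argmin(sizes))
        for s in members:
            assign[s] = f"fold{f:02d}"
        sizes[f] += len(members)
    return pd.Series([assign[s] for s in idx], index=idx.to_numpy(), name="fold")


# --------------------------------------------------------------------------
# core fold machinery
# --------------------------------------------------------------------------

@dataclass
class PCRFoldModel:
    """Training-fold artifacts needed to score a test fold."""

    feature_mean: np.ndarray       # (p,) training centering vector
    loadings: np.ndarray           # (p, K) orthonormal components
    k: int
    cov_names: list
    score_betas: np.ndarray        # (q, K) nuisance betas per component
    y_beta: np.ndarray             # (q,) nuisance betas for the outcome
    weights: np.ndarray            # (K,) OLS weights on residualized scores
    raceeth_levels: tuple | None = None

    def __post_init__(self):
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("component loadings are not orthonormal")


def _pca_train(X: np.ndarray, k_max: int):
    mean = X.mean(axis=0)
    Xc = X - mean
    # economical SVD; components ordered by explained variance
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    k_max = min(k_max, rank)
    v = vt[:k_max].T
    return mean, v, Xc @ v, rank


def _residualize(design: np.ndarray, values: np.ndarray):
    """OLS betas and residuals of ``values`` (column-wise) on ``design``."""
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return beta, values - design @ beta


def fit_pcr_fold(train_x, train_y, train_cov: pd.DataFrame, k: int,
                 raceeth_levels=None) -> PCRFoldModel:
    """Fit the PCR fold model with ``k`` components on training rows only."""
    X = np.asarray(train_x, dtype=float)
    y = np.asarray(train_y, dtype=float)
    if raceeth_levels is None and "raceeth" in train_cov.columns:
        raceeth_levels = tuple(np.unique(train_cov["raceeth"]))
    design, names = build_covariate_design(train_cov, raceeth_levels)
    if k > min(X.shape):
        raise ValueError(f"K={k} exceeds the rank bound of the training matrix")
    mean, v, scores, rank = _pca_train(X, k)
    if v.shape[1] < k:
        raise ValueError(f"K={k} exceeds the numerical rank {rank}")
    score_betas, score_resid = _residualize(design, scores)
    y_beta, y_resid = _residualize(design, y)
    weights, *_ = np.linalg.lstsq(score_resid, y_resid, rcond=None)
    return PCRFoldModel(
        feature_mean=mean, loadings=v, k=k, cov_names=names,
        score_betas=score_betas, y_beta=y_beta, weights=weights,
        raceeth_levels=raceeth_levels,
    )


def predict_and_correlate(model: PCRFoldModel, test_x, test_y,
                          test_cov: pd.DataFrame):
    """Score a test fold with training-fold parameters.

    Returns ``(r, y_pred, y_resid)``; ``r`` is NaN (fold skipped upstream)
    when the test fold has fewer than 3 subjects.
    """
    X = np.asarray(test_x, dtype=float)
    y = np.asarray(test_y, dtype=float)
    design, names = build_covariate_design(test_cov, model.raceeth_levels,
                                           drop_collinear=False)
    if names != model.cov_names:
        # training may have dropped collinear columns; align by name
        try:
            keep = [names.index(n) for n in model.cov_names]
        except ValueError as exc:
            raise ValueError(
                "test covariate design does not match training design"
            ) from exc
        design = design[:, keep]
    scores = (X - model.feature_mean) @ model.loadings
    score_resid = scores - design @ model.score_betas
    y_resid = y - design @ model.y_beta
    y_pred = score_resid @ model.weights
    if len(y) < 3:
        warnings.warn("test fold with fewer than 3 subjects: correlation undefined")
        return np.nan, y_pred, y_resid
    r = float(np.corrcoef(y_pred, y_resid)[0, 1])
    return r, y_pred, y_resid


def _inner_cv_scores(X, y, cov, candidate_ks, n_inner, rng, families=None,
                     raceeth_levels=None):
    """Mean inner-fold partial correlation per candidate K (one PCA per split)."""
    n = len(y)
    if families is not None:
        groups = pd.Series(range(n)).groupby(np.asarray(families)).apply(list)
        order = rng.permutation(len(groups))
        fold_of = np.empty(n, dtype=int)
        sizes = np.zeros(n_inner, dtype=int)
        for gi in order:
            members = groups.iloc[gi]
            f = int(np.argmin(sizes))
            fold_of[members] = f
            sizes[f] += len(members)
    else:
        fold_of = rng.permutation(n) % n_inner
    scores = {k: [] for k in candidate_ks}
    for f in range(n_inner):
        tr = fold_of != f
        te = ~tr
        if te.sum() < 3 or tr.sum() <= max(candidate_ks[0], 3):
            continue
        k_max = min(max(candidate_ks), tr.sum() - 1)
        mean, v, sc, rank = _pca_train(X[tr], k_max)
        design_tr, names_tr = build_covariate_design(cov[tr], raceeth_levels)
        design_te, names_te = build_covariate_design(cov[te], raceeth_levels,
                                                     drop_collinear=False)
        design_te = design_te[:, [names_te.index(nm) for nm in names_tr]]
        sb, sc_resid = _residualize(design_tr, sc)
        yb, y_resid = _residualize(design_tr, y[tr])
        sc_te = (X[te] - mean) @ v
        sc_te_resid = sc_te - design_te @ sb
        y_te_resid = y[te] - design_te @ yb
        for k in candidate_ks:
            if k > v.shape[1]:
                continue
            w, *_ = np.linalg.lstsq(sc_resid[:, :k], y_resid, rcond=None)
            pred = sc_te_resid[:, :k] @ w
            if np.std(pred) == 0 or np.std(y_te_resid) == 0:
                continue
            scores[k].append(float(np.corrcoef(pred, y_te_resid)[0, 1]))
    return {k: (float(np.mean(v_)) if v_ else -np.inf) for k, v_ in scores.items()}


def select_num_components(train_x, train_y, train_cov: pd.DataFrame,
                          candidate_ks=DEFAULT_K_GRID, seed: int = 0,
                          n_inner: int = 5, families=None,
                          raceeth_levels=None) -> int:
    """Pick K by nested inner cross-validation on training rows only.

    Candidates exceeding the feasible rank are dropped with a warning; ties
    break toward the smaller K.
    """
    X = np.asarray(train_x, dtype=float)
    y = np.asarray(train_y, dtype=float)
    if raceeth_levels is None and "raceeth" in train_cov.columns:
        raceeth_levels = tuple(np.unique(train_cov["raceeth"]))
    design, _ = build_covariate_design(train_cov, raceeth_levels)
    q = design.shape[1]
    bound = min(X.shape[0] - q - 2, X.shape[1])
    ks = sorted(k for k in candidate_ks if k >= 1)
    feasible = [k for k in ks if k <= bound]
    dropped = [k for k in ks if k > bound]
    if dropped:
        warnings.warn(f"candidate K values beyond the rank bound dropped: {dropped}")
    if not feasible:
        raise ValueError("no feasible candidate K")
    rng = np.random.default_rng(seed)
    scores = _inner_cv_scores(X, y, train_cov.reset_index(drop=True), feasible,
                              n_inner, rng, families=families,
                              raceeth_levels=raceeth_levels)
    best = feasible[0]
    for k in feasible:
        if scores[k] > scores[best]:
            best = k
    return best


# --------------------------------------------------------------------------
# outer loop
# --------------------------------------------------------------------------

@dataclass
class PredictionResult:
    fold_rs: dict                    # fold label -> out-of-sample partial r
    fold_ks: dict                    # fold label -> selected K
    mean_r: float
    predictions: pd.DataFrame        # subject_id, fold, y_resid, y_pred
    fold_models: dict                # fold label -> PCRFoldModel
    skipped: list = field(default_factory=list)


def run_cv_pipeline(X: pd.DataFrame, y: pd.Series, covariates: pd.DataFrame,
                    folds: pd.Series, candidate_ks=DEFAULT_K_GRID,
                    seed: int = 0) -> PredictionResult:
    """Nested-CV PCR over the outer folds; every subject is scored exactly
    once out of fold and per-fold correlations are averaged unweighted."""
    subjects = list(X.index)
    if not (list(y.index) == subjects and list(covariates["subject_id"]) == subjects
            and list(folds.index) == subjects):
        raise ValueError("X, y, covariates and folds must share subject order")
    rng = np.random.default_rng(seed)
    labels = pd.unique(folds)
    levels = (tuple(np.unique(covariates["raceeth"]))
              if "raceeth" in covariates.columns else None)
    fold_rs, fold_ks, fold_models = {}, {}, {}
    rows = []
    skipped = []
    for lab in labels:
        te = (folds == lab).to_numpy()
        tr = ~te
        if te.sum() < 3:
            warnings.warn(f"fold {lab} has fewer than 3 subjects; skipped")
            skipped.append(lab)
            continue
        cov_tr = covariates[tr].reset_index(drop=True)
        cov_te = covariates[te].reset_index(drop=True)
        fams = covariates["family"].to_numpy()[tr] if "family" in covariates else None
        k = select_num_components(
            X.to_numpy()[tr], y.to_numpy()[tr], cov_tr, candidate_ks,
            seed=int(rng.integers(2**31 - 1)), families=fams,
            raceeth_levels=levels,
        )
        model = fit_pcr_fold(X.to_numpy()[tr], y.to_numpy()[tr], cov_tr, k,
                             raceeth_levels=levels)
        r, y_pred, y_resid = predict_and_correlate(
            model, X.to_numpy()[te], y.to_numpy()[te], cov_te
        )
        fold_rs[lab] = r
        fold_ks[lab] = k
        fold_models[lab] = model
        for sid, yp, yr in zip(np.asarray(subjects)[te], y_pred, y_resid):
            rows.append({"subject_id": sid, "fold": lab,
                         "y_resid": yr, "y_pred": yp})
    if len(skipped) > 0.2 * len(labels):
        raise RuntimeError(f"more than 20% of folds skipped: {skipped}")
    mean_r = float(np.mean(list(fold_rs.values()))) if fold_rs else np.nan
    return PredictionResult(
        fold_rs=fold_rs, fold_ks=fold_ks, mean_r=mean_r,
        predictions=pd.DataFrame(rows), fold_models=fold_models, skipped=skipped,
    )


def consensus_feature_map(models, feature_ids=None, zscore: bool = True):
    """Feature-space weight map: sum over components of loading times beta.

    ``models`` may be a single :class:`PCRFoldModel` or an iterable of fold
    models; fold maps are computed first and then averaged.  The map is
    z-scored for reporting unless it is constant, in which case the raw map
    is returned with a warning.
    """
    if isinstance(models, PCRFoldModel):
        models = [models]
    maps = [m.loadings @ m.weights for m in models]
    raw = np.mean(maps, axis=0)
    sd = raw.std()
    if zscore:
        if sd == 0:
            warnings.warn("constant consensus map; returning raw weights")
            out = raw
        else:
            out = (raw - raw.mean()) / sd
    else:
        out = raw
    if feature_ids is not None:
        return pd.Series(out, index=feature_ids, name="weight")
    return out


# --------------------------------------------------------------------------
# model-object facade
# --------------------------------------------------------------------------

class CrossValidatedPCR:
    """Cross-validated PCR prediction model.

    Parameters
    ----------
    y:
        Outcome series indexed by subject (e.g. overall EEA).
    X:
        Subjects-by-features activation DataFrame, same index.
    covariates:
        Nuisance table with ``subject_id`` plus the covariate columns.
    folds:
        Fold labels per subject (see :func:`make_folds`); built automatically
        with ``scheme``/``k`` when omitted.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, covariates: pd.DataFrame,
                 folds: pd.Series | None = None, scheme: str = "kfold",
                 k: int = 10, seed: int = 0):
        y = y.loc[X.index]
        covariates = (covariates.set_index("subject_id").loc[X.index]
                      .rename_axis("subject_id").reset_index())
        if folds is None:
            folds = make_folds(covariates, scheme=scheme, k=k, seed=seed)
        self.y, self.X, self.covariates = y, X, covariates
        self.folds = folds.loc[X.index]

    def fit(self, candidate_ks=DEFAULT_K_GRID, seed: int = 0) -> "PCRResults":
        res = run_cv_pipeline(self.X, self.y, self.covariates, self.folds,
                              candidate_ks, seed=seed)
        return PCRResults(self, res)


class PCRResults:
    """Results of the cross-validated PCR fit."""

    def __init__(self, model: CrossValidatedPCR, result: PredictionResult):
        self.model = model
        self._result = result
        self.fold_rs = result.fold_rs
        self.fold_ks = result.fold_ks
        self.mean_r = result.mean_r
        self.predictions = result.predictions

    def summary(self) -> pd.DataFrame:
        rows = [
            {"fold": lab, "r": self.fold_rs[lab], "K": self.fold_ks[lab],
             "n_test": int((self.model.folds == lab).sum())}
            for lab in self.fold_rs
        ]
        df = pd.DataFrame(rows)
        df.loc[len(df)] = {"fold": "mean", "r": self.mean_r, "K": np.nan,
                           "n_test": int(len(self.model.y))}
        return df

    def consensus_map(self, mode: str = "folds", candidate_ks=DEFAULT_K_GRID,
                      seed: int = 0) -> pd.Series:
        """Consensus feature weights, z-scored.

        ``folds`` averages the per-fold feature maps; ``full`` refits one
        model on the complete sample (K selected by inner CV) and maps it.
        """
        if mode == "folds":
            return consensus_feature_map(
                list(self._result.fold_models.values()),
                feature_ids=self.model.X.columns,
            )
        if mode == "full":
            cov = self.model.covariates
            fams = cov["family"].to_numpy() if "family" in cov else None
            k = select_num_components(
                self.model.X.to_numpy(), self.model.y.to_numpy(), cov,
                candidate_ks, seed=seed, families=fams,
            )
            m = fit_pcr_fold(self.model.X.to_numpy(), self.model.y.to_numpy(), cov, k)
            return consensus_feature_map(m, feature_ids=self.model.X.columns)
        raise ValueError("mode must be 'folds' or 'full'")
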