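"""Skill-evaluation models: random-intercept regression, forward-selection
cross-validation, learning-rate regression, and the associated statistics.

The performance model is a linear mixed model with a per-subject random
intercept, fitted by maximum likelihood. ML estimation profiles the variance
ratio lambda = sigma_u^2 / sigma_e^2: for fixed lambda the GLS estimates and
the residual variance have closed forms, so the fit reduces to a
one-dimensional likelihood maximization. Fixed effects get Wald z-tests; the
random effect is tested by a likelihood-ratio test against the plain linear
model using the 50:50 chi2_0/chi2_1 mixture. This fitter reproduces
statsmodels' MixedLM (ML) to optimizer tolerance while being fast enough for
the forward-selection cross-validation loop, which refits the model thousands
of times.

Predictor screening follows the study protocol: folds partition subjects;
within each fold's training set forward selection adds, at each step, the
feature minimizing in-sample RMSE among candidates whose Wald p-value is
below alpha, stopping when none qualifies (model size capped); features
chosen in at least ``min_selections`` folds form the final model.

Learning rate is the OLS slope of score on 1-based attempt index; the
learning-rate model is an OLS regression of the slope on forward-selected
first-attempt features with the baseline (first-attempt) score always
included and age as a candidate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def learning_rate(scores, attempts=None) -> float:
    """OLS slope of performance score on 1-based attempt index."""
    y = np.asarray(scores, dtype=float)
    if len(y) < 2:
        raise ValueError("learning rate needs at least 2 attempts")
    x = (np.arange(1, len(y) + 1, dtype=float) if attempts is None
         else np.asarray(attempts, dtype=float))
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def surg_tlx_total(domains) -> int:
    """Total workload: sum of the six SURG-TLX domains (range 6..120)."""
    domains = list(domains)
    if len(domains) != 6:
        raise ValueError("SURG-TLX has six domains")
    if any(not 1 <= d <= 20 for d in domains):
        raise ValueError("each SURG-TLX domain must lie in [1, 20]")
    return int(sum(domains))


def efron_pseudo_r2(y, y_hat) -> float:
    """1 - SS_res / SS_tot computed on model predictions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("lengths differ")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        warnings.warn("constant outcome: pseudo-R^2 undefined")
        return np.nan
    return float(1.0 - ((y - y_hat) ** 2).sum() / ss_tot)


def error_metrics(y, y_hat):
    """(MAE, RMSE) of predictions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) == 0:
        raise ValueError("need equal-length, nonempty arrays")
    r = y - y_hat
    return float(np.abs(r).mean()), float(np.sqrt((r ** 2).mean()))


def pearson(x, y):
    """Pearson r and two-sided p-value; NaN (with a warning) on zero
    variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return np.nan, np.nan
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# random-intercept model (profiled ML)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """Coefficient table and fit statistics of a random-intercept model."""

    params: pd.DataFrame            # estimate, se, p per fixed effect
    sigma2_u: float
    sigma2_e: float
    random_effect_pvalue: float
    loglik: float
    pseudo_r2: float
    mae: float
    rmse: float
    n: int

    def to_table(self) -> pd.DataFrame:
        return self.params.reset_index(names="predictor")


def _group_codes(groups):
    codes, uniques = pd.factorize(np.asarray(groups))
    counts = np.bincount(codes).astype(float)
    return codes, uniques, counts


def _profiled_quantities(lam, XtX, Xty, yty, GX, gy, counts, n):
    w = lam / (1.0 + lam * counts)
    A = XtX - GX.T @ (w[:, None] * GX)
    b = Xty - GX.T @ (w * gy)
    yyw = yty - (w * gy * gy).sum()
    beta = np.linalg.solve(A, b)
    q = max(yyw - beta @ b, 1e-300)
    sigma2 = q / n
    ll = (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
          - 0.5 * np.log1p(lam * counts).sum())
    return ll, beta, A, sigma2


def _ri_ml_fit(X, y, codes, counts):
    n, p = X.shape
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y
    G = len(counts)
    GX = np.zeros((G, p))
    np.add.at(GX, codes, X)
    gy = np.bincount(codes, weights=y, minlength=G)

    def neg_ll(t):
        return -_profiled_quantities(np.exp(t), XtX, Xty, yty, GX, gy,
                                     counts, n)[0]

    res = scipy.optimize.minimize_scalar(neg_ll, bounds=(-15.0, 15.0),
                                         method="bounded",
                                         options={"xatol": 1e-10})
    ll0, beta0, A0, s20 = _profiled_quantities(
        0.0, XtX, Xty, yty, GX, gy, counts, n)
    lam = float(np.exp(res.x))
    ll, beta, A, sigma2 = _profiled_quantities(
        lam, XtX, Xty, yty, GX, gy, counts, n)
    if ll0 >= ll:                     # boundary solution: no random effect
        lam, ll, beta, A, sigma2 = 0.0, ll0, beta0, A0, s20
    cov = sigma2 * np.linalg.inv(A)
    resid = y - X @ beta
    gs = np.bincount(codes, weights=resid, minlength=G)
    u_hat = lam * gs / (1.0 + lam * counts)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p_re = 0.5 * scipy.stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
    return {"beta": beta, "cov": cov, "lam": lam, "sigma2_e": sigma2,
            "sigma2_u": lam * sigma2, "loglik": ll, "loglik0": ll0,
            "u_hat": u_hat, "random_effect_pvalue": float(p_re)}


class RandomInterceptRegressor(BaseEstimator, RegressorMixin):
    """Linear mixed model with a per-subject random intercept (ML).

    ``fit`` takes the design matrix (an intercept column is added), the
    outcome, and the grouping labels. ``predict`` returns population-level
    predictions, or subject-specific (BLUP-shifted) predictions when the
    fitted groups are passed.
    """

    def __init__(self, cond_threshold: float = 1e10):
        self.cond_threshold = cond_threshold

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in X.columns]
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        y = np.asarray(y, dtype=float)
        codes, uniques, counts = _group_codes(groups)
        if len(counts) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        if np.linalg.cond(Xd) > self.cond_threshold:
            raise ValueError("design matrix is (near-)collinear; "
                             f"condition number > {self.cond_threshold:g}")
        fit = _ri_ml_fit(Xd, y, codes, counts)
        if not np.all(np.isfinite(fit["cov"])) or np.any(
                np.diag(fit["cov"]) <= 0):
            raise ValueError(
                "singular fit: sigma2_e="
                f"{fit['sigma2_e']:.3g}, sigma2_u={fit['sigma2_u']:.3g}")
        self.coef_ = fit["beta"][1:]
        self.intercept_ = float(fit["beta"][0])
        self.se_ = np.sqrt(np.diag(fit["cov"]))
        z = fit["beta"] / self.se_
        self.pvalues_ = 2 * scipy.stats.norm.sf(np.abs(z))
        self.sigma2_u_ = fit["sigma2_u"]
        self.sigma2_e_ = fit["sigma2_e"]
        self.loglik_ = fit["loglik"]
        self.random_effect_pvalue_ = fit["random_effect_pvalue"]
        self.group_effects_ = dict(zip(uniques, fit["u_hat"]))
        self.groups_ = uniques
        self.n_ = len(y)
        self._train_pred_blup = (Xd @ fit["beta"] + fit["u_hat"][codes])
        self._train_y = y
        return self

    def predict(self, X, groups=None):
        X = pd.DataFrame(X)
        pred = self.intercept_ + X.to_numpy(float) @ self.coef_
        if groups is not None:
            shift = np.array([self.group_effects_.get(g, 0.0)
                              for g in np.asarray(groups)])
            pred = pred + shift
        return pred

    def summary(self) -> MixedModelFit:
        names = ["intercept"] + self.feature_names_
        params = pd.DataFrame(
            {"estimate": np.concatenate([[self.intercept_], self.coef_]),
             "se": self.se_, "p": self.pvalues_}, index=names)
        mae, rmse = error_metrics(self._train_y, self._train_pred_blup)
        return MixedModelFit(
            params=params, sigma2_u=float(self.sigma2_u_),
            sigma2_e=float(self.sigma2_e_),
            random_effect_pvalue=float(self.random_effect_pvalue_),
            loglik=float(self.loglik_),
            pseudo_r2=efron_pseudo_r2(self._train_y, self._train_pred_blup),
            mae=mae, rmse=rmse, n=int(self.n_))


def fit_random_intercept(y, X, groups) -> MixedModelFit:
    """Functional wrapper: fit the random-intercept model and summarize."""
    return RandomInterceptRegressor().fit(X, y, groups).summary()


# ---------------------------------------------------------------------------
# forward selection with grouped cross-validation
# ---------------------------------------------------------------------------

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-4.0, 4.0, 49)])


def _forward_select_single(F, y, codes, counts, names, alpha, max_features,
                           grid=_LAMBDA_GRID, entry_adjust="bonferroni"):
    """Forward selection on one training set.

    Candidate models are profiled over a fixed lambda grid with all
    candidates evaluated simultaneously (Schur-complement update of the GLS
    normal equations); the entry criterion is the Wald p-value of the new
    coefficient at the profile-optimal lambda, and among qualifying
    candidates the one with the smallest in-sample (BLUP) RMSE enters.

    Because each step effectively tests the best of K candidates, the entry
    threshold is Bonferroni-adjusted (alpha / K remaining candidates) by
    default; otherwise pure-noise feature pools would essentially always
    contribute a spuriously significant predictor. ``entry_adjust="none"``
    restores the unadjusted threshold.
    """
    n, K = F.shape
    G = len(counts)
    Xs = np.ones((n, 1))
    FtF = np.einsum("ij,ij->j", F, F)
    Fty = F.T @ y
    yty = y @ y
    GF = np.zeros((G, K))
    np.add.at(GF, codes, F)
    gy = np.bincount(codes, weights=y, minlength=G)
    selected = []
    active = np.ones(K, dtype=bool)
    while len(selected) < max_features:
        p_s = Xs.shape[1]
        XtXs, Xsy = Xs.T @ Xs, Xs.T @ y
        XsF = Xs.T @ F
        GXs = np.zeros((G, p_s))
        np.add.at(GXs, codes, Xs)
        nl = len(grid)
        ll = np.full((nl, K), -np.inf)
        beta_f = np.zeros((nl, K))
        schur = np.zeros((nl, K))
        sigma2 = np.ones((nl, K))
        rf = np.zeros((nl, K))
        ainvbs_all = np.zeros((nl, p_s))
        ainvB_all = np.zeros((nl, p_s, K))
        for li, lam in enumerate(grid):
            w = lam / (1.0 + lam * counts)
            A_ss = XtXs - GXs.T @ (w[:, None] * GXs)
            A_sf = XsF - GXs.T @ (w[:, None] * GF)
            a_ff = FtF - (w[:, None] * GF * GF).sum(axis=0)
            b_s = Xsy - GXs.T @ (w * gy)
            b_f = Fty - (GF * (w * gy)[:, None]).sum(axis=0)
            yyw = yty - (w * gy * gy).sum()
            Ainv = np.linalg.inv(A_ss)
            AinvB = Ainv @ A_sf
            Ainvbs = Ainv @ b_s
            s = a_ff - np.einsum("pk,pk->k", A_sf, AinvB)
            r = b_f - A_sf.T @ Ainvbs
            ok = active & (s > 1e-10 * np.maximum(a_ff, 1e-30))
            bf = np.where(ok, r / np.where(ok, s, 1.0), 0.0)
            q = np.maximum(yyw - b_s @ Ainvbs - bf * r, 1e-300)
            s2 = q / n
            ll_l = (-0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
                    - 0.5 * np.log1p(lam * counts).sum())
            ll[li] = np.where(ok, ll_l, -np.inf)
            beta_f[li], schur[li], sigma2[li], rf[li] = bf, s, s2, r
            ainvbs_all[li], ainvB_all[li] = Ainvbs, AinvB
        best_li = ll.argmax(axis=0)
        cols = np.arange(K)
        bf = beta_f[best_li, cols]
        s2 = sigma2[best_li, cols]
        sch = np.where(schur[best_li, cols] > 0, schur[best_li, cols], np.inf)
        # small-sample entry test: df-corrected residual variance and a
        # t reference (the normal/ML-variance Wald test is anticonservative
        # at these sample sizes and inflates best-of-K false entries)
        df = max(n - p_s - 1, 1)
        se = np.sqrt(s2 * n / df / sch)
        tstat = np.abs(bf) / np.where(se > 0, se, 1.0)
        pvals = 2 * scipy.stats.t.sf(tstat, df)
        threshold = alpha
        if entry_adjust == "bonferroni":
            threshold = alpha / max(int(active.sum()), 1)
        qualifies = active & (pvals < threshold) & np.isfinite(ll[best_li, cols])
        if not qualifies.any():
            break
        # in-sample BLUP RMSE for qualifying candidates at their optimal lam
        rmse = np.full(K, np.inf)
        for li in np.unique(best_li[qualifies]):
            kk = np.flatnonzero(qualifies & (best_li == li))
            lam = grid[li]
            b_sl = ainvbs_all[li][:, None] - ainvB_all[li][:, kk] * bf[kk]
            resid = y[:, None] - Xs @ b_sl - F[:, kk] * bf[kk]
            gs = np.zeros((G, len(kk)))
            np.add.at(gs, codes, resid)
            u = (lam / (1.0 + lam * counts))[:, None] * gs
            rmse[kk] = np.sqrt(((resid - u[codes]) ** 2).mean(axis=0))
        order = sorted(np.flatnonzero(qualifies),
                       key=lambda k: (rmse[k], str(names[k])))
        pick = order[0]
        selected.append(pick)
        active[pick] = False
        Xs = np.column_stack([Xs, F[:, pick]])
    return [names[k] for k in selected]


class ForwardSelectCV(BaseEstimator):
    """Subject-grouped k-fold forward selection of skill predictors.

    Folds partition subjects (all attempts of a subject share a fold) so
    feature detection is not driven by individual subjects. Features selected
    in at least ``min_selections`` folds are kept and used to fit the final
    random-intercept model on all data (``estimator_``).
    """

    def __init__(self, k: int = 7, min_selections: int = 2,
                 alpha: float = 0.05, max_features: int = 5,
                 random_state: int = 0):
        self.k = k
        self.min_selections = min_selections
        self.alpha = alpha
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, groups):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("feature table contains missing values; "
                             "resolve flagged columns before selection")
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        subjects = np.unique(groups)
        if self.k > len(subjects):
            raise ValueError(f"k={self.k} folds but only {len(subjects)} "
                             "subjects")
        rng = np.random.default_rng(self.random_state)
        order = subjects[rng.permutation(len(subjects))]
        folds = np.array_split(order, self.k)
        self.fold_assignments_ = {s: fi for fi, fold in enumerate(folds)
                                  for s in fold}
        names = [str(c) for c in X.columns]
        F = X.to_numpy(float)
        self.fold_selections_ = {}
        counts_by_name = {}
        for fi, fold in enumerate(folds):
            train = ~np.isin(groups, fold)
            codes, _, counts = _group_codes(groups[train])
            sel = _forward_select_single(
                F[train], y[train], codes, counts, names,
                self.alpha, self.max_features)
            self.fold_selections_[fi] = sel
            for name in sel:
                counts_by_name[name] = counts_by_name.get(name, 0) + 1
        self.selection_counts_ = counts_by_name
        self.selected_features_ = sorted(
            n for n, c in counts_by_name.items()
            if c >= self.min_selections)
        if self.selected_features_:
            self.estimator_ = RandomInterceptRegressor().fit(
                X[self.selected_features_], y, groups)
        else:
            self.estimator_ = None
        return self


def forward_select_cv(table: pd.DataFrame, y, groups, k: int = 7,
                      min_selections: int = 2, alpha: float = 0.05,
                      max_features: int = 5, random_state: int = 0) -> list:
    """Functional wrapper returning the selected feature names."""
    sel = ForwardSelectCV(k, min_selections, alpha, max_features,
                          random_state).fit(table, y, groups)
    return sel.selected_features_


# ---------------------------------------------------------------------------
# learning-rate model
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    """Coefficient table and fit statistics of the learning-rate model."""

    params: pd.DataFrame
    r2: float
    mae: float
    rmse: float
    n: int

    def to_table(self) -> pd.DataFrame:
        return self.params.reset_index(names="predictor")


class LearningRateModel(BaseEstimator, RegressorMixin):
    """OLS model of per-subject learning-rate slope.

    The column named by ``baseline_col`` (first-attempt score, unstandardized)
    is always included; remaining columns of X -- first-attempt features and
    age -- are forward-selection candidates with a Wald p < alpha entry rule.
    """

    def __init__(self, alpha: float = 0.05, max_features: int = 5,
                 baseline_col: str = "baseline_score"):
        self.alpha = alpha
        self.max_features = max_features
        self.baseline_col = baseline_col

    def _ols(self, X: pd.DataFrame, y):
        return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        if self.baseline_col not in X.columns:
            raise ValueError(f"X must contain {self.baseline_col!r}")
        y = np.asarray(y, dtype=float)
        if len(y) < X.shape[1] and len(y) < 4:
            raise ValueError("too few records")
        selected = [self.baseline_col]
        candidates = [c for c in X.columns if c != self.baseline_col]
        while len(selected) - 1 < self.max_features:
            best = None
            for c in sorted(candidates):
                res = self._ols(X[selected + [c]], y)
                if np.linalg.matrix_rank(res.model.exog) \
                        < res.model.exog.shape[1]:
                    continue
                p = res.pvalues[c]
                rmse = np.sqrt((res.resid ** 2).mean())
                if p < self.alpha and (best is None or rmse < best[0]):
                    best = (rmse, c)
            if best is None:
                break
            selected.append(best[1])
            candidates.remove(best[1])
        self.selected_features_ = [c for c in selected
                                   if c != self.baseline_col]
        self.results_ = self._ols(X[selected], y)
        if np.linalg.matrix_rank(self.results_.model.exog) \
                < self.results_.model.exog.shape[1]:
            raise ValueError("rank-deficient final design")
        self.columns_ = selected
        self.n_ = len(y)
        self._train_y = y
        return self

    def predict(self, X: pd.DataFrame):
        X = sm.add_constant(pd.DataFrame(X)[self.columns_],
                            has_constant="add")
        return np.asarray(self.results_.predict(X))

    def summary(self) -> LinearModelFit:
        res = self.results_
        params = pd.DataFrame({"estimate": res.params, "se": res.bse,
                               "p": res.pvalues})
        mae, rmse = error_metrics(self._train_y, res.fittedvalues)
        return LinearModelFit(params=params, r2=float(res.rsquared),
                              mae=mae, rmse=rmse, n=int(self.n_))


def build_learning_rate_records(table: pd.DataFrame,
                                feature_cols) -> pd.DataFrame:
    """Per-(subject, task) learning-rate records from an attempt-level table.

    Needs columns subject, task, attempt, score, age plus the feature
    columns; returns one row per subject and task with the OLS slope, the
    first-attempt feature values, the baseline score and age.
    """
    rows = []
    for (s, task), sub in table.groupby(["subject", "task"]):
        sub = sub.sort_values("attempt")
        if len(sub) < 2:
            warnings.warn(f"subject {s}, task {task}: fewer than 2 attempts;"
                          " learning rate undefined")
            continue
        first = sub.iloc[0]
        row = {"subject": s, "task": task,
               "slope": learning_rate(sub["score"].to_numpy(),
                                      sub["attempt"].to_numpy()),
               "baseline_score": float(first["score"]),
               "age": float(first["age"])}
        for c in feature_cols:
            row[c] = float(first[c])
        rows.append(row)
    return pd.DataFrame(rows)


def fit_learning_rate_model(records: pd.DataFrame, feature_cols,
                            alpha: float = 0.05,
                            max_features: int = 5) -> LinearModelFit:
    """Forward-selected OLS of slope on first-attempt features + baseline."""
    X = records[[*feature_cols, "age", "baseline_score"]]
    model = LearningRateModel(alpha=alpha, max_features=max_features)
    model.fit(X, records["slope"].to_numpy())
    return model.summary()


# ---------------------------------------------------------------------------
# residual summaries
# ---------------------------------------------------------------------------

def prediction_residual_summary(predicted, actual, tasks) -> pd.DataFrame:
    """Per-task box-plot summary of (predicted - actual) residuals.

    Whiskers are the most extreme residuals within 1.5 x IQR of the
    quartiles; residuals beyond them are listed as outliers.
    """
    df = pd.DataFrame({"predicted": np.asarray(predicted, float),
                       "actual": np.asarray(actual, float),
                       "task": np.asarray(tasks)})
    df["residual"] = df["predicted"] - df["actual"]
    rows = []
    for task, sub in df.groupby("task"):
        r = sub["residual"].to_numpy()
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = r[(r >= lo_fence) & (r <= hi_fence)]
        rows.append({
            "task": task, "n": len(r), "median": med, "mean": r.mean(),
            "q1": q1, "q3": q3, "iqr": iqr,
            "whisker_low": inside.min(), "whisker_high": inside.max(),
            "outliers": sorted(r[(r < lo_fence) | (r > hi_fence)].tolist()),
        })
    return pd.DataFrame(rows).set_index("task")
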