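"""Per-species candidate niche models: fitting, evaluation, importance.

Ten statistical methods are fitted to each species' presence/absence
design matrix — GLM, GBM, GAM, CTA, ANN, SRE, FDA, MARS, RF and MAXENT —
each repeated over three random 80/20 calibration/evaluation splits,
giving 30 candidate models per species.  Records are weighted so
presences and absences contribute equally (prevalence 0.5).  Each model
is scored on its held-out split by ROC (area under the ROC curve, i.e.
the probability a random presence outranks a random absence, ties ½) and
TSS (sensitivity + specificity − 1, maximised over all cutoffs); the
TSS-maximising cutoff is stored for later binarisation.  Variable
importance is estimated by permutation: 1 − Pearson correlation between
predictions on the original and column-shuffled data, averaged over
three permutations.

The GLM (weighted logistic regression via IRLS) and SRE (rectilinear
presence-quantile envelope) learners are implemented here directly; the
remaining methods delegate to scikit-learn estimators through a uniform
adapter registry, at the backends' documented defaults, wrapped to honour
record weights where the backend supports them and to emit suitability
probabilities in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

METHODS = ["GLM", "GBM", "GAM", "CTA", "ANN", "SRE", "FDA", "MARS", "RF", "MAXENT"]


class EvaluationError(ValueError):
    """Evaluation impossible (single-class labels)."""


class WeightingError(ValueError):
    """Prevalence weighting impossible (single-class labels)."""


class ModelFitError(RuntimeError):
    """A learner failed to fit; recorded, never fatal to the pipeline."""


@dataclass(frozen=True)
class ModelSpec:
    method: str
    run: int = 1
    calibration_fraction: float = 0.8
    prevalence: float = 0.5
    n_importance_permutations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration fraction must lie in (0, 1)")


@dataclass
class EvalScores:
    roc: float
    tss: float
    cutoff: float
    sensitivity: float  # percent correctly predicted presences at cutoff
    specificity: float  # percent correctly predicted absences at cutoff


@dataclass
class FittedModel:
    spec: ModelSpec
    learner: "Learner"
    roc: float
    tss: float
    cutoff: float
    sensitivity: float
    specificity: float
    importance: pd.Series

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.learner.predict(X)


# ---------------------------------------------------------------------------
# Feature encoding shared by all delegated learners


class FeatureEncoder:
    """Indicator-code categorical columns with levels fixed at fit time.

    Unseen levels at prediction time map to the all-zero indicator block,
    the standard reference treatment for out-of-sample categories.
    """

    def __init__(self, categorical: Sequence[str]):
        self.categorical = list(categorical)
        self.levels_: dict[str, np.ndarray] = {}
        self.columns_: list[str] = []

    def fit(self, X: pd.DataFrame) -> "FeatureEncoder":
        self.levels_ = {
            c: np.unique(X[c].to_numpy()) for c in self.categorical if c in X
        }
        self.columns_ = [c for c in X.columns if c not in self.levels_]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        blocks = [X[self.columns_].to_numpy(dtype=float)]
        for c, levels in self.levels_.items():
            col = X[c].to_numpy()
            blocks.append((col[:, None] == levels[None, :]).astype(float))
        return np.column_stack(blocks)

    @property
    def n_continuous(self) -> int:
        return len(self.columns_)


# ---------------------------------------------------------------------------
# Native learners


class GlmLearner:
    """Weighted logistic regression (logit link) fitted by IRLS.

    Continuous predictors enter linearly; categorical predictors as
    indicator terms.  A tiny ridge (1e-8) stabilises the normal equations
    under separation, where coefficients diverge but predictions converge
    to 0/1.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, Z: np.ndarray, y: np.ndarray, w: np.ndarray) -> "GlmLearner":
        n, p = Z.shape
        A = np.column_stack([np.ones(n), Z])
        beta = np.zeros(p + 1)
        for _ in range(self.max_iter):
            eta = np.clip(A @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = np.clip(w * mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)
            AtW = A.T * W
            H = AtW @ A + 1e-8 * np.eye(p + 1)
            new_beta = np.linalg.solve(H, AtW @ z)
            if np.max(np.abs(new_beta - beta)) < self.tol:
                beta = new_beta
                break
            beta = new_beta
        self.coef_ = beta
        return self

    def predict_proba_1(self, Z: np.ndarray) -> np.ndarray:
        eta = np.clip(np.column_stack([np.ones(len(Z)), Z]) @ self.coef_, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


class SreLearner:
    """Surface range envelope: rectilinear presence-quantile box classifier.

    For each continuous predictor the envelope spans the q and 1−q
    quantiles (default q = 0.025) of the *presence* values; a point is
    suitable (1) iff every continuous value lies inside its interval and
    every categorical value is a level observed among training presences.
    """

    def __init__(self, q: float = 0.025):
        self.q = q
        self.lower_: dict[str, float] = {}
        self.upper_: dict[str, float] = {}
        self.allowed_levels_: dict[str, set] = {}

    def fit(self, X: pd.DataFrame, y: np.ndarray, categorical: Sequence[str]
            ) -> "SreLearner":
        pres = X[np.asarray(y) == 1]
        if len(pres) == 0:
            raise ModelFitError("SRE needs at least one presence")
        cat = set(categorical)
        for c in X.columns:
            vals = pres[c].to_numpy(dtype=float)
            if c in cat:
                self.allowed_levels_[c] = set(np.unique(vals).tolist())
            else:
                self.lower_[c] = float(np.quantile(vals, self.q))
                self.upper_[c] = float(np.quantile(vals, 1.0 - self.q))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(X), dtype=bool)
        for c, lo in self.lower_.items():
            v = X[c].to_numpy(dtype=float)
            ok &= (v >= lo) & (v <= self.upper_[c])
        for c, levels in self.allowed_levels_.items():
            ok &= np.isin(X[c].to_numpy(dtype=float), list(levels))
        return ok.astype(float)


# ---------------------------------------------------------------------------
# Basis expansions for the spline-flavoured delegated methods


def _hinge_basis(Z: np.ndarray, knots: list[np.ndarray]) -> np.ndarray:
    """Paired hinge features max(x−k, 0), max(k−x, 0) per knot per column."""
    feats = [Z]
    for j in range(Z.shape[1]):
        for k in knots[j]:
            feats.append(np.maximum(Z[:, j : j + 1] - k, 0.0))
            feats.append(np.maximum(k - Z[:, j : j + 1], 0.0))
    return np.column_stack(feats)


def _quantile_knots(Z: np.ndarray, n_knots: int = 5) -> list[np.ndarray]:
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    return [np.unique(np.quantile(Z[:, j], qs)) for j in range(Z.shape[1])]


class Learner:
    """Uniform adapter: fit on a DataFrame + labels + weights, predict [0,1]."""

    def __init__(self, method: str, seed: int, categorical: Sequence[str]):
        self.method = method
        self.seed = seed
        self.categorical = list(categorical)
        self.encoder = FeatureEncoder(categorical)
        self.scaler: StandardScaler | None = None
        self.spline: SplineTransformer | None = None
        self.knots_: list[np.ndarray] | None = None
        self.inner = None
        self.sre: SreLearner | None = None

    # -- feature pipeline ------------------------------------------------
    def _features(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        Z = self.encoder.fit(X).transform(X) if fitting else self.encoder.transform(X)
        ncont = self.encoder.n_continuous
        if self.method in ("ANN", "MAXENT", "GAM", "MARS", "GLM"):
            if fitting:
                self.scaler = StandardScaler().fit(Z[:, :ncont]) if ncont else None
            if self.scaler is not None:
                Z = np.column_stack([self.scaler.transform(Z[:, :ncont]), Z[:, ncont:]])
        cont, cat = Z[:, :ncont], Z[:, ncont:]
        if self.method == "GAM" and ncont:
            if fitting:
                self.spline = SplineTransformer(degree=3, n_knots=5).fit(cont)
            Z = np.column_stack([self.spline.transform(cont), cat])
        elif self.method in ("MARS", "FDA") and ncont:
            if fitting:
                self.knots_ = _quantile_knots(cont)
            Z = np.column_stack([_hinge_basis(cont, self.knots_), cat])
        elif self.method == "MAXENT" and ncont:
            Z = np.column_stack([cont, cont**2, cat])
        return Z

    def fit(self, X: pd.DataFrame, y: np.ndarray, weights: np.ndarray) -> "Learner":
        y = np.asarray(y, dtype=int)
        weights = np.asarray(weights, dtype=float)
        if self.method == "SRE":
            self.sre = SreLearner().fit(X, y, self.categorical)
            self.encoder.fit(X)
            return self
        Z = self._features(X, fitting=True)
        seed = self.seed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.method == "GLM":
                self.inner = GlmLearner().fit(Z, y, weights)
            elif self.method == "GBM":
                self.inner = GradientBoostingClassifier(random_state=seed)
                self.inner.fit(Z, y, sample_weight=weights)
            elif self.method == "GAM":
                self.inner = LogisticRegression(C=100.0, max_iter=2000)
                self.inner.fit(Z, y, sample_weight=weights)
            elif self.method == "CTA":
                self.inner = DecisionTreeClassifier(random_state=seed)
                self.inner.fit(Z, y, sample_weight=weights)
            elif self.method == "ANN":
                # MLP has no per-record weights; prevalence handled upstream
                self.inner = MLPClassifier(max_iter=500, random_state=seed)
                self.inner.fit(Z, y)
            elif self.method == "FDA":
                self.inner = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
                self.inner.fit(Z, y)
            elif self.method == "MARS":
                self.inner = LogisticRegression(C=10.0, max_iter=2000)
                self.inner.fit(Z, y, sample_weight=weights)
            elif self.method == "RF":
                self.inner = RandomForestClassifier(random_state=seed)
                self.inner.fit(Z, y, sample_weight=weights)
            elif self.method == "MAXENT":
                # L1-regularised logistic on linear+quadratic features: the
                # maxnet formulation of maximum entropy for presence/absence
                self.inner = LogisticRegression(
                    penalty="l1", solver="liblinear", C=1.0, max_iter=2000,
                    random_state=seed)
                self.inner.fit(Z, y, sample_weight=weights)
            else:  # pragma: no cover - guarded by ModelSpec
                raise ValueError(self.method)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.method == "SRE":
            return self.sre.predict(X)
        Z = self._features(X, fitting=False)
        if self.method == "GLM":
            return self.inner.predict_proba_1(Z)
        proba = self.inner.predict_proba(Z)
        classes = list(self.inner.classes_)
        if 1 not in classes:
            return np.zeros(len(Z))
        return np.clip(proba[:, classes.index(1)], 0.0, 1.0)


# ---------------------------------------------------------------------------
# Splitting, weighting, evaluation


def split_calibration(y: np.ndarray, fraction: float = 0.8, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random calibration/evaluation split (default 80/20).

    Each class with at least two members appears in both parts; a class
    with a single member is forced into the calibration set with a
    warning.  Deterministic given the seed.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            warnings.warn(
                f"class {cls} has a single record; forced into calibration set")
            continue
        n_test = int(round(len(idx) * (1.0 - fraction)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_parts.append(rng.choice(idx, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def class_weights(y: np.ndarray, prevalence: float = 0.5) -> np.ndarray:
    """Record weights giving presences total weight n·prevalence.

    With the default prevalence 0.5, presences and absences carry equal
    total weight regardless of sample imbalance, and weights sum to n.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    n1 = int((y == 1).sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise WeightingError("both classes required for prevalence weighting")
    w1 = n * prevalence / n1
    w0 = n * (1.0 - prevalence) / n0
    return np.where(y == 1, w1, w0)


def auc_roc(pred: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUC: P(random presence outranks random absence), ties ½."""
    y = np.asarray(y, dtype=int)
    pred = np.asarray(pred, dtype=float)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes required for ROC")
    ranks = rankdata(pred)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _cutoff_candidates(pred: np.ndarray) -> np.ndarray:
    u = np.unique(pred)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.array([])
    return np.concatenate([[u[0] - 1.0], mids, [u[-1]]])


def evaluate(pred: np.ndarray, y: np.ndarray) -> EvalScores:
    """ROC plus the cutoff-maximised true skill statistic.

    The cutoff scan covers every midpoint between distinct predicted
    values (plus the all-present and all-absent extremes); classification
    is presence iff prediction > cutoff, strictly.  Sensitivity and
    specificity are reported in percent at the chosen cutoff, so
    TSS = sens/100 + spec/100 − 1.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=int)
    roc = auc_roc(pred, y)
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best = (-np.inf, 0.0, 0.0, 0.0)
    for c in _cutoff_candidates(pred):
        pos = pred > c
        sens = (pos & (y == 1)).sum() / n1
        spec = (~pos & (y == 0)).sum() / n0
        tss = sens + spec - 1.0
        if tss > best[0] + 1e-12:
            best = (tss, c, sens, spec)
    tss, cutoff, sens, spec = best
    return EvalScores(roc=roc, tss=float(tss), cutoff=float(cutoff),
                      sensitivity=float(100 * sens), specificity=float(100 * spec))


def permutation_importance(learner: Learner, X: pd.DataFrame, n_perm: int = 3,
                           seed: int = 0) -> pd.Series:
    """Shuffle-one-column importance in [0, 1] per predictor.

    importance_v = mean over permutations of 1 − max(r, 0), where r is the
    Pearson correlation between predictions on the intact data and on data
    with column v shuffled.  A variable the model ignores scores 0; a
    variable that fully drives predictions scores ≈ 1.  Degenerate
    (zero-variance) predictions define importance 0 for every variable.
    """
    rng = np.random.default_rng(seed)
    base = learner.predict(X)
    out = {}
    if np.std(base) == 0.0:
        return pd.Series({c: 0.0 for c in X.columns})
    for col in X.columns:
        vals = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            shuffled = learner.predict(Xp)
            if np.std(shuffled) == 0.0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, shuffled)[0, 1])
            vals.append(1.0 - max(r, 0.0))
        out[col] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class FailedModel:
    spec: ModelSpec
    reason: str


def fit_model(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray,
              weights: np.ndarray, categorical: Sequence[str] = ()) -> Learner:
    """Fit one learner; raises :class:`ModelFitError` on backend failure."""
    try:
        return Learner(spec.method, spec.seed, categorical).fit(X, y, weights)
    except ModelFitError:
        raise
    except Exception as exc:  # backend failures become recordable events
        raise ModelFitError(f"{spec.method} run {spec.run}: {exc}") from exc


def fit_all(X: pd.DataFrame, y: np.ndarray, categorical: Sequence[str] = (),
            methods: Sequence[str] = METHODS, n_runs: int = 3, seed: int = 0,
            calibration_fraction: float = 0.8, prevalence: float = 0.5,
            n_importance_permutations: int = 3,
            ) -> tuple[list[FittedModel], list[FailedModel]]:
    """Fit |methods| × n_runs candidate models with per-run 80/20 splits.

    With the default ten methods and three repetitions this yields the
    30-candidate-model set per species.  Failures (fit errors, single-class
    evaluation splits) are logged and excluded, never fatal.  Fewer than 30
    presences triggers a small-sample warning.
    """
    y = np.asarray(y, dtype=int)
    if (y == 1).sum() < 30:
        warnings.warn("fewer than 30 presences; model accuracy may be unstable")
    fitted: list[FittedModel] = []
    failures: list[FailedModel] = []
    for run in range(1, n_runs + 1):
        run_seed = int((seed * 1009 + run * 7919) % (2**31 - 1))
        train, test = split_calibration(y, calibration_fraction, seed=run_seed)
        for mi, method in enumerate(methods):
            spec = ModelSpec(method=method, run=run,
                             calibration_fraction=calibration_fraction,
                             prevalence=prevalence,
                             n_importance_permutations=n_importance_permutations,
                             seed=int((run_seed + 31 * mi) % (2**31 - 1)))
            try:
                w = class_weights(y[train], prevalence)
                learner = fit_model(spec, X.iloc[train], y[train], w, categorical)
                scores = evaluate(learner.predict(X.iloc[test]), y[test])
                imp = permutation_importance(
                    learner, X.iloc[train], n_perm=n_importance_permutations,
                    seed=spec.seed)
            except (ModelFitError, EvaluationError, WeightingError) as exc:
                failures.append(FailedModel(spec=spec, reason=str(exc)))
                continue
            fitted.append(FittedModel(
                spec=spec, learner=learner, roc=scores.roc, tss=scores.tss,
                cutoff=scores.cutoff, sensitivity=scores.sensitivity,
                specificity=scores.specificity, importance=imp))
    return fitted, failures


def evaluation_table(models: Sequence[FittedModel], species: str = "") -> pd.DataFrame:
    rows = [{
        "species": species, "method": m.spec.method, "run": m.spec.run,
        "roc": m.roc, "tss": m.tss, "cutoff": m.cutoff,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
    } for m in models]
    return pd.DataFrame(rows)


def importance_table(models: Sequence[FittedModel], species: str = "") -> pd.DataFrame:
    rows = []
    for m in models:
        for var, v in m.importance.items():
            rows.append({"species": species, "method": m.spec.method,
                         "run": m.spec.run, "variable": var, "importance": v})
    return pd.DataFrame(rows)
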