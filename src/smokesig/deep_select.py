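"""Deep selecting: iterative PLS-DA feature elimination for signature probes.

The idea borrows the layer-by-layer notion of feature extraction: fit a
PLS discriminant model on all surviving probes, rank probes by their
contribution (VIP), discard the least important fraction, refit, and
repeat while cross-validated accuracy keeps improving. The probe set at
the best-accuracy iteration is the methylation signature.

`DeepSelectPLS` is the model object (built from a sample x probe matrix
and ±1 smoking labels); its :meth:`~DeepSelectPLS.fit` returns a
:class:`DeepSelectResults` carrying the signature, the per-iteration
trace, cross-validated metrics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierMetrics",
    "PLSModel",
    "fit_plsda",
    "contribution_scores",
    "cross_validate",
    "DeepSelectConfig",
    "DeepSelectPLS",
    "DeepSelectResults",
    "deep_select",
    "evaluate_external",
]


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts with sensitivity / specificity / accuracy.

    The positive class is the smoker (+1) label.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sn(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def sp(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def acc(self) -> float:
        d = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / d if d else float("nan")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ClassifierMetrics":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == -1) & (yp == 1))),
            tn=int(np.sum((yt == -1) & (yp == -1))),
            fn=int(np.sum((yt == 1) & (yp == -1))),
        )


@dataclass
class PLSModel:
    """A fitted PLS1 discriminant model (NIPALS) on centred/scaled probes."""

    n_components: int
    feature_names: list
    x_weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    x_scores: np.ndarray  # (n, a), mutually orthogonal columns
    coef: np.ndarray  # (p,), on the original X scale
    _estimator: PLSRegression = field(repr=False, default=None)

    def predict_scores(self, X) -> np.ndarray:
        """Continuous PLS prediction of the ±1-coded label."""
        Xa = _extract(X, self.feature_names)
        return np.asarray(self._estimator.predict(Xa)).ravel()

    def predict_classes(self, X) -> np.ndarray:
        """Classify by the sign of the prediction; an exact 0 is called +1."""
        s = self.predict_scores(X)
        return np.where(s >= 0, 1, -1)


def _extract(X, feature_names) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"matrix is missing probes: {missing[:10]}")
        return X[feature_names].to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _as_xy(X, y):
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = np.asarray(y, dtype=float).ravel()
    if set(np.unique(yv)) - {-1.0, 1.0}:
        raise ValueError("labels must be coded +1 (smoker) / -1 (never)")
    if Xv.shape[0] != yv.size:
        raise ValueError("X and y disagree on sample count")
    return Xv, yv, names


def fit_plsda(X, y, n_components: int, scale: bool = True) -> PLSModel:
    """Fit a PLS discriminant model of the ±1 label on probe beta-values.

    Columns with zero variance are dropped with a warning when scaling is
    on (their scaled values are undefined); ``n_components`` may not
    exceed min(n_samples - 1, n_probes).
    """
    Xv, yv, names = _as_xy(X, y)
    if scale:
        sd = Xv.std(axis=0)
        dead = sd == 0
        if dead.any():
            warnings.warn(f"dropping {int(dead.sum())} zero-variance probe(s)")
            keep = ~dead
            Xv = Xv[:, keep]
            names = [n for n, k in zip(names, keep) if k]
    if Xv.shape[1] == 0:
        raise ValueError("no usable probes (all zero variance)")
    cap = min(Xv.shape[0] - 1, Xv.shape[1])
    if not 1 <= n_components <= cap:
        raise ValueError(f"n_components must be in [1, {cap}]")
    est = PLSRegression(n_components=n_components, scale=scale)
    est.fit(Xv, yv)
    return PLSModel(
        n_components=n_components,
        feature_names=names,
        x_weights=np.asarray(est.x_weights_),
        x_loadings=np.asarray(est.x_loadings_),
        y_loadings=np.asarray(est.y_loadings_).ravel(),
        x_scores=np.asarray(est.x_scores_),
        coef=np.asarray(est.coef_).ravel(),
        _estimator=est,
    )


def contribution_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection (VIP) for every probe in the model.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ),
    with SSY_a the y-variance captured by component a. The squares
    average to one: sum_j VIP_j^2 = p, for any fit.
    """
    if model._estimator is None:
        raise ValueError("model is not fitted")
    W = model.x_weights  # (p, a)
    p, a = W.shape
    t_ss = np.sum(model.x_scores**2, axis=0)  # (a,)
    ssy = (model.y_loadings**2) * t_ss
    wnorm2 = np.sum(W**2, axis=0)
    frac = (W**2) / wnorm2  # (p, a)
    vip2 = p * (frac @ ssy) / ssy.sum()
    return np.sqrt(vip2)


def cross_validate(
    X,
    y,
    k: int = 5,
    component_grid=None,
    scale: bool = True,
    random_state: int = 0,
) -> tuple[int, ClassifierMetrics]:
    """Stratified k-fold CV over a component grid.

    Predictions from held-out folds are pooled; the component count with
    the highest pooled accuracy wins (smallest count on ties). Returns
    that count and the pooled confusion metrics.
    """
    Xv, yv, _ = _as_xy(X, y)
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for cross-validation")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    folds = list(skf.split(Xv, yv))
    max_train = min(len(tr) for tr, _ in folds)
    cap = min(max_train - 1, Xv.shape[1])
    grid = component_grid if component_grid is not None else range(1, min(5, cap) + 1)
    grid = [c for c in grid if 1 <= c <= cap]
    if not grid:
        raise ValueError("component grid is empty after capping")

    best = None
    for ncomp in grid:
        pred = np.empty_like(yv)
        for tr, te in folds:
            m = fit_plsda(Xv[tr], yv[tr], ncomp, scale=scale)
            pred[te] = m.predict_classes(Xv[te])
        metrics = ClassifierMetrics.from_predictions(yv, pred)
        if best is None or metrics.acc > best[1].acc:
            best = (ncomp, metrics)
    return best


@dataclass(frozen=True)
class DeepSelectConfig:
    """Knobs of the elimination loop.

    drop_fraction: share of surviving probes removed per round (floor 1).
    patience: rounds without a new best CV accuracy before stopping.
    min_probes: stop rather than shrink below this many probes.
    importance: 'vip' (default) or 'coef' (absolute regression weight).
    """

    drop_fraction: float = 0.1
    patience: int = 5
    min_probes: int = 10
    k_folds: int = 5
    max_components: int = 5
    scale: bool = True
    importance: str = "vip"
    random_state: int = 0

    def __post_init__(self):
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.importance not in ("vip", "coef"):
            raise ValueError("importance must be 'vip' or 'coef'")


@dataclass
class _Iteration:
    index: int
    probes: list
    n_components: int
    metrics: ClassifierMetrics


class DeepSelectPLS:
    """Deep-selecting PLS-DA model of tobacco exposure from methylation.

    Parameters
    ----------
    X : sample x probe matrix (DataFrame or array) of beta-values.
    y : ±1 labels (+1 current-smoker, -1 never-smoker).
    """

    def __init__(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.exog = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            self.exog = pd.DataFrame(
                X, columns=[f"p{j}" for j in range(X.shape[1])]
            )
        self.endog = np.asarray(y).astype(int)
        _as_xy(self.exog, self.endog)  # validate

    @classmethod
    def from_dataframes(cls, methylation: pd.DataFrame, metadata: pd.DataFrame):
        """Build from a probe x sample matrix and sample metadata.

        Keeps current/never samples only (+1 / -1); 'ever'-only records
        are excluded as in the prescreen contrast.
        """
        from .prescreen import split_groups

        current, never = split_groups(metadata, methylation.columns)
        samples = current + never
        X = methylation[samples].T
        y = np.concatenate([np.ones(len(current), int), -np.ones(len(never), int)])
        return cls(X, y)

    def fit(self, config: DeepSelectConfig | None = None, **overrides) -> "DeepSelectResults":
        """Run the elimination loop and return the results object."""
        cfg = config or DeepSelectConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        X, y = self.exog, self.endog
        active = [c for c in X.columns if X[c].std() > 0]
        if len(active) < 2:
            raise ValueError("fewer than 2 non-degenerate probes to select from")

        trace: list[_Iteration] = []
        best_acc = -np.inf
        best_iter = 0
        stall = 0
        reason = ""
        it = 0
        while True:
            Xa = X[active]
            ncomp, metrics = cross_validate(
                Xa,
                y,
                k=cfg.k_folds,
                component_grid=range(1, cfg.max_components + 1),
                scale=cfg.scale,
                random_state=cfg.random_state,
            )
            trace.append(_Iteration(it, list(active), ncomp, metrics))
            if metrics.acc > best_acc:
                best_acc = metrics.acc
                best_iter = it
                stall = 0
            else:
                stall += 1
            if stall >= cfg.patience:
                reason = "patience"
                break
            n_drop = max(1, int(cfg.drop_fraction * len(active)))
            if len(active) - n_drop < cfg.min_probes:
                reason = "min_probes"
                break
            model = fit_plsda(Xa, y, ncomp, scale=cfg.scale)
            if cfg.importance == "vip":
                imp = contribution_scores(model)
            else:
                imp = np.abs(model.coef)
            order = np.argsort(imp, kind="stable")  # ascending importance
            doomed = {model.feature_names[j] for j in order[:n_drop]}
            active = [a for a in active if a not in doomed]
            it += 1

        best = trace[best_iter]
        final_model = fit_plsda(X[best.probes], y, best.n_components, scale=cfg.scale)
        return DeepSelectResults(
            model=self,
            config=cfg,
            trace=trace,
            best_iteration=best_iter,
            signature=list(best.probes),
            stopping_reason=reason,
            final_model=final_model,
        )


@dataclass
class DeepSelectResults:
    """Fitted signature with its selection trace and diagnostics."""

    model: DeepSelectPLS
    config: DeepSelectConfig
    trace: list
    best_iteration: int
    signature: list
    stopping_reason: str
    final_model: PLSModel

    @property
    def cv_metrics(self) -> ClassifierMetrics:
        return self.trace[self.best_iteration].metrics

    @property
    def trace_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": t.index,
                "n_probes": len(t.probes),
                "n_components": t.n_components,
                "tp": t.metrics.tp,
                "fp": t.metrics.fp,
                "tn": t.metrics.tn,
                "fn": t.metrics.fn,
                "sn": t.metrics.sn,
                "sp": t.metrics.sp,
                "acc": t.metrics.acc,
            }
            for t in self.trace
        ]
        return pd.DataFrame(rows).set_index("iteration")

    def predict(self, X) -> np.ndarray:
        """±1 class predictions for a sample x probe matrix."""
        return self.final_model.predict_classes(X)

    def evaluate(self, X_val, y_val) -> ClassifierMetrics:
        """Score the refit signature model on an external cohort."""
        return evaluate_external(
            self.signature,
            self.model.exog,
            self.model.endog,
            X_val,
            y_val,
            n_components=self.final_model.n_components,
            scale=self.config.scale,
        )

    def summary(self) -> str:
        m = self.cv_metrics
        lines = [
            "Deep-selecting PLS-DA signature",
            "=" * 38,
            f"iterations run        : {len(self.trace)}",
            f"stopping reason       : {self.stopping_reason}",
            f"best iteration        : {self.best_iteration}",
            f"signature size        : {len(self.signature)}",
            f"PLS components        : {self.final_model.n_components}",
            f"CV sensitivity (SN)   : {m.sn:.4f}",
            f"CV specificity (SP)   : {m.sp:.4f}",
            f"CV accuracy (ACC)     : {m.acc:.4f}",
        ]
        return "\n".join(lines)


def deep_select(X, y, config: DeepSelectConfig | None = None) -> DeepSelectResults:
    """Functional wrapper: build :class:`DeepSelectPLS` and fit it."""
    return DeepSelectPLS(X, y).fit(config)


def evaluate_external(
    signature,
    X_train,
    y_train,
    X_val,
    y_val,
    n_components: int | None = None,
    scale: bool = True,
) -> ClassifierMetrics:
    """Refit on the training cohort restricted to the signature, score a validation cohort.

    The validation matrix must contain every signature probe; if either
    class is absent from the validation labels the corresponding SN or SP
    is NaN and a warning is raised.
    """
    signature = list(signature)
    if isinstance(X_val, pd.DataFrame):
        missing = [p for p in signature if p not in X_val.columns]
        if missing:
            raise ValueError(f"validation matrix is missing probes: {missing[:10]}")
    Xt = X_train[signature] if isinstance(X_train, pd.DataFrame) else np.asarray(X_train)
    ncomp = n_components or min(5, len(signature), np.shape(Xt)[0] - 1)
    model = fit_plsda(Xt, y_train, ncomp, scale=scale)
    y_pred = model.predict_classes(X_val)
    yv = np.asarray(y_val)
    metrics = ClassifierMetrics.from_predictions(yv, y_pred)
    if (yv == 1).sum() == 0 or (yv == -1).sum() == 0:
        warnings.warn("a class is absent from validation labels; SN or SP is NaN")
    return metrics
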