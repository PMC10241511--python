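"""Brain-age prediction from latent functional connectivity.

Features are the covariances (or correlations) between every pair of latent
timecourses — the upper triangle of the k x k FC matrix, 32,640 edges for
k = 256.  Three protocols are implemented:

* ``crossval_predict`` — tenfold cross-validation with feature selection
  (age-correlation + Benjamini-Hochberg FDR) inside the training fold, a
  linear epsilon-insensitive support-vector regressor, and affine bias
  adjustment fit on a held-out validation split.  Within each fold the data
  split is 76.5% train / 13.5% validation / 10% test.
* ``cross_center_predict`` — transfer between acquisitions: the training
  cohort's significant, positively age-correlated edges are summed into a
  single global-network-strength feature, an ordinary linear regression maps
  strength to age, bias adjustment uses a held-out slice of the training
  cohort, and the model is evaluated on the full second cohort.
* single-feature within-cohort prediction via ``global_network_strength``
  with an uncorrected p < 0.01 selection variant.

Bias adjustment regresses actual on predicted age in the validation set and
applies the resulting affine map to test predictions, removing the
regression-to-the-mean bias typical of brain-age models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .vae import LatentTimeseries

logger = logging.getLogger("latentcortex")

__all__ = [
    "LatentFC",
    "PredictionReport",
    "latent_fc",
    "fc_feature_matrix",
    "select_features",
    "fit_rsvm",
    "bias_adjust",
    "BiasAdjuster",
    "crossval_predict",
    "global_network_strength",
    "cross_center_predict",
    "prediction_metrics",
]


@dataclass
class LatentFC:
    """Functional connectivity over latent variables for one scan."""

    matrix: np.ndarray  # (k, k) symmetric
    vector: np.ndarray  # upper triangle excluding the diagonal
    mode: str  # 'covariance' | 'correlation'
    subject_id: str = "sub-0"
    session_id: str = "ses-0"
    age_weeks: float = float("nan")

    @property
    def n_latent(self) -> int:
        return self.matrix.shape[0]


def latent_fc(Z, mode: str = "covariance", **metadata) -> LatentFC:
    """FC matrix of the latent timecourses: sample covariance or Pearson
    correlation between every pair of latent variables.

    ``Z`` is a :class:`LatentTimeseries` (its posterior means are used) or a
    plain (k, T) array.  Constant series in correlation mode yield undefined
    entries, recorded as NaN with a warning.
    """
    if isinstance(Z, LatentTimeseries):
        metadata.setdefault("subject_id", Z.subject_id)
        metadata.setdefault("session_id", Z.session_id)
        metadata.setdefault("age_weeks", Z.age_weeks)
        data = Z.mu
    else:
        data = np.asarray(Z, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need a (k, T) matrix with T >= 3")
    if mode == "covariance":
        mat = np.cov(data)
    elif mode == "correlation":
        sd = data.std(axis=1)
        if np.any(sd == 0):
            warnings.warn(
                f"{int((sd == 0).sum())} constant latent series: correlation "
                "entries undefined (NaN)"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.corrcoef(data)
        np.fill_diagonal(mat, np.where(sd > 0, 1.0, np.nan))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mat = np.atleast_2d(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return LatentFC(matrix=mat, vector=mat[iu], mode=mode, **metadata)


def fc_feature_matrix(fcs) -> tuple:
    """Stack per-scan FC vectors into (n_scans, n_edges) plus the age vector."""
    F = np.stack([fc.vector for fc in fcs])
    ages = np.array([fc.age_weeks for fc in fcs], dtype=np.float64)
    return F, ages


def _feature_age_correlations(F: np.ndarray, ages: np.ndarray):
    """Vectorized Pearson r and two-sided p of each feature against age."""
    n = len(ages)
    Fc = F - F.mean(axis=0)
    ac = ages - ages.mean()
    sf = np.sqrt((Fc**2).sum(axis=0))
    sa = np.sqrt((ac**2).sum())
    ok = np.ptp(F, axis=0) > 0  # exact constant-column detection
    r = np.full(F.shape[1], np.nan)
    r[ok] = (Fc[:, ok] * ac[:, None]).sum(axis=0) / (sf[ok] * sa)
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, p, ok


def select_features(F: np.ndarray, ages, method: str = "fdr", alpha: float = 0.05):
    """Age-informative FC edges: per-feature Pearson r with age, thresholded.

    ``method='fdr'`` applies Benjamini-Hochberg at ``alpha`` (the multi-scan
    default, alpha = 0.05); ``method='uncorrected'`` thresholds raw p-values
    (the single-group variant uses alpha = 0.01).  Zero-variance features are
    excluded with a warning.  Selection must be computed on training scans
    only — callers are responsible for passing the training fold.

    Returns ``(mask, r, p)``.
    """
    F = np.asarray(F, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if F.shape[0] != len(ages):
        raise ValueError("feature matrix and ages disagree on n")
    if len(ages) < 4:
        raise ValueError("need at least 4 subjects for feature selection")
    r, p, ok = _feature_age_correlations(F, ages)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance feature(s) excluded")
    mask = np.zeros(F.shape[1], dtype=bool)
    if method == "fdr":
        rejected = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
        mask[np.flatnonzero(ok)[rejected]] = True
    elif method == "uncorrected":
        mask[ok] = p[ok] < alpha
    else:
        raise ValueError(f"unknown method {method!r}")
    return mask, r, p


@dataclass
class _SVRModel:
    scaler: StandardScaler
    svr: SVR
    feature_mask: np.ndarray | None = None

    def predict(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=np.float64)
        if self.feature_mask is not None:
            F = F[:, self.feature_mask]
        return self.svr.predict(self.scaler.transform(F))


def fit_rsvm(F_selected: np.ndarray, ages, C: float = 1.0,
             epsilon: float = 0.1) -> _SVRModel:
    """Linear epsilon-insensitive support-vector regressor on selected edges.

    Features are standardized with training statistics.  Deterministic given
    the inputs and C.
    """
    F_selected = np.asarray(F_selected, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if F_selected.ndim != 2 or F_selected.shape[1] == 0:
        raise ValueError("empty feature set")
    if F_selected.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    scaler = StandardScaler().fit(F_selected)
    svr = SVR(kernel="linear", C=C, epsilon=epsilon)
    svr.fit(scaler.transform(F_selected), ages)
    return _SVRModel(scaler=scaler, svr=svr)


@dataclass
class BiasAdjuster:
    """Affine map p -> a*p + b fitted as actual ~ predicted on validation."""

    a: float
    b: float

    def __call__(self, predictions) -> np.ndarray:
        return self.a * np.asarray(predictions, dtype=np.float64) + self.b


def bias_adjust(predictions_val, ages_val) -> BiasAdjuster:
    """Least-squares fit of actual age on predicted age in the validation set.

    If predictions are exactly an affine distortion of the truth, the
    adjuster inverts it exactly; for unbiased predictions it is close to the
    identity.
    """
    p = np.asarray(predictions_val, dtype=np.float64)
    a = np.asarray(ages_val, dtype=np.float64)
    if len(p) < 3:
        raise ValueError("need at least 3 validation subjects")
    if np.ptp(p) == 0:
        raise ValueError("constant validation predictions: bias fit undefined")
    slope, intercept = np.polyfit(p, a, 1)
    return BiasAdjuster(a=float(slope), b=float(intercept))


def prediction_metrics(y, y_hat):
    """RMSE, MAE, r^2 (squared Pearson), and Pearson correlation.

    Constant predictions have undefined correlation; r2 and correlation are
    returned as NaN in that case.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must have equal length >= 2")
    err = y_hat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(y_hat) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: correlation undefined")
        corr = float("nan")
    else:
        corr = float(np.corrcoef(y, y_hat)[0, 1])
    return {"rmse": rmse, "mae": mae, "r2": corr**2, "correlation": corr}


@dataclass
class PredictionReport:
    """Per-fold metrics aggregated over repeats."""

    rmse: np.ndarray
    mae: np.ndarray
    r2: np.ndarray
    correlation: np.ndarray
    pooled_correlation: float
    selected_feature_fraction: float  # percent of FC edges passing selection
    n_repeats: int
    seed: int
    split_sizes: tuple  # (train, validation, test) of a representative fold
    pooled_ages: np.ndarray = None  # test-set ages pooled over folds/repeats
    pooled_predictions: np.ndarray = None  # matching adjusted predictions

    def summary(self) -> dict:
        def ms(x):
            x = x[~np.isnan(x)]
            return {"mean": float(x.mean()), "sd": float(x.std(ddof=1))} if x.size > 1 \
                else {"mean": float(x.mean()) if x.size else float("nan"), "sd": float("nan")}

        return {
            "rmse": ms(self.rmse),
            "mae": ms(self.mae),
            "r2": ms(self.r2),
            "correlation": ms(self.correlation),
            "pooled_correlation": self.pooled_correlation,
            "selected_feature_fraction_pct": self.selected_feature_fraction,
            "n_repeats": self.n_repeats,
            "split_sizes": list(self.split_sizes),
        }


def chance_mae(ages) -> float:
    """MAE of the predictor that always outputs the mean age."""
    ages = np.asarray(ages, dtype=np.float64)
    return float(np.mean(np.abs(ages - ages.mean())))


def crossval_predict(F, ages, k: int = 10, repeats: int = 100, seed: int = 0,
                     selection: str = "fdr", alpha: float = 0.05,
                     C: float = 1.0) -> PredictionReport:
    """Repeated k-fold cross-validated age prediction.

    Per repeat, scans are randomly partitioned into ``k`` folds.  Each fold
    serves once as the 10% test set; 15% of the remainder (13.5% overall)
    becomes the bias-adjustment validation set and the rest (76.5%) the
    training set.  Feature selection and regressor fitting see the training
    set only.  Folds whose selection comes back empty are skipped and
    logged.
    """
    F = np.asarray(F, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    n = len(ages)
    if n < 20:
        raise ValueError("need at least 20 scans for the tenfold protocol")
    rng = np.random.default_rng(seed)
    rmses, maes, r2s, corrs, fracs = [], [], [], [], []
    pooled_y, pooled_p = [], []
    split_sizes = None
    for _rep in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        for fold in folds:
            test = fold
            rest = np.setdiff1d(order, test, assume_unique=False)
            rest = rng.permutation(rest)
            n_val = max(3, int(round(0.15 * len(rest))))
            val, train = rest[:n_val], rest[n_val:]
            if split_sizes is None:
                split_sizes = (len(train), len(val), len(test))
            mask, _, _ = select_features(F[train], ages[train],
                                         method=selection, alpha=alpha)
            if not mask.any():
                logger.info("fold skipped: empty feature selection")
                continue
            model = fit_rsvm(F[train][:, mask], ages[train], C=C)
            adjuster = bias_adjust(model.predict(F[val][:, mask]), ages[val])
            pred = adjuster(model.predict(F[test][:, mask]))
            m = prediction_metrics(ages[test], pred)
            rmses.append(m["rmse"])
            maes.append(m["mae"])
            r2s.append(m["r2"])
            corrs.append(m["correlation"])
            fracs.append(100.0 * mask.mean())
            pooled_y.append(ages[test])
            pooled_p.append(pred)
    if not maes:
        raise ValueError("no fold produced a non-empty feature selection")
    yy = np.concatenate(pooled_y)
    pp = np.concatenate(pooled_p)
    pooled = float(np.corrcoef(yy, pp)[0, 1]) if np.ptp(pp) > 0 else float("nan")
    return PredictionReport(
        rmse=np.array(rmses), mae=np.array(maes), r2=np.array(r2s),
        correlation=np.array(corrs), pooled_correlation=pooled,
        selected_feature_fraction=float(np.mean(fracs)),
        n_repeats=repeats, seed=seed, split_sizes=split_sizes,
        pooled_ages=yy, pooled_predictions=pp,
    )


def global_network_strength(F_vector, selected_positive_mask) -> float:
    """Sum of a subject's FC values over significant, positively
    age-correlated edges — the single-feature summary used for transfer
    between acquisitions."""
    mask = np.asarray(selected_positive_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no positively age-correlated significant edges")
    return float(np.asarray(F_vector, dtype=np.float64)[mask].sum())


def cross_center_predict(F_train, ages_train, F_test, ages_test,
                         repeats: int = 100, seed: int = 0,
                         selection: str = "fdr", alpha: float = 0.05,
                         subsample: float = 0.5) -> PredictionReport:
    """Cross-acquisition transfer with the global-network-strength model.

    Per repeat: draw ``subsample`` (default half) of the training cohort;
    split it 85% fit / 15% validation; select significant positively
    age-correlated edges on the fit part; regress age on the summed strength
    (ordinary least squares); bias-adjust on the validation part; evaluate
    on the complete test cohort.
    """
    F_train = np.asarray(F_train, dtype=np.float64)
    F_test = np.asarray(F_test, dtype=np.float64)
    ages_train = np.asarray(ages_train, dtype=np.float64)
    ages_test = np.asarray(ages_test, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = len(ages_train)
    rmses, maes, r2s, corrs, fracs = [], [], [], [], []
    pooled_y, pooled_p = [], []
    split_sizes = None
    for _rep in range(repeats):
        sub = rng.permutation(n)[: max(8, int(round(subsample * n)))]
        n_val = max(3, int(round(0.15 * len(sub))))
        val, fit = sub[:n_val], sub[n_val:]
        if split_sizes is None:
            split_sizes = (len(fit), len(val), len(ages_test))
        mask, r, _ = select_features(F_train[fit], ages_train[fit],
                                     method=selection, alpha=alpha)
        mask = mask & (r > 0)
        if not mask.any():
            logger.info("repeat skipped: no positive significant edges")
            continue
        s_fit = F_train[fit][:, mask].sum(axis=1)
        if np.ptp(s_fit) == 0:
            continue
        slope, intercept = np.polyfit(s_fit, ages_train[fit], 1)
        predict = lambda F: slope * F[:, mask].sum(axis=1) + intercept
        adjuster = bias_adjust(predict(F_train[val]), ages_train[val])
        pred = adjuster(predict(F_test))
        m = prediction_metrics(ages_test, pred)
        rmses.append(m["rmse"])
        maes.append(m["mae"])
        r2s.append(m["r2"])
        corrs.append(m["correlation"])
        fracs.append(100.0 * mask.mean())
        pooled_y.append(ages_test)
        pooled_p.append(pred)
    if not maes:
        raise ValueError("no repeat produced a usable strength model")
    yy = np.concatenate(pooled_y)
    pp = np.concatenate(pooled_p)
    pooled = float(np.corrcoef(yy, pp)[0, 1]) if np.ptp(pp) > 0 else float("nan")
    return PredictionReport(
        rmse=np.array(rmses), mae=np.array(maes), r2=np.array(r2s),
        correlation=np.array(corrs), pooled_correlation=pooled,
        selected_feature_fraction=float(np.mean(fracs)),
        n_repeats=repeats, seed=seed, split_sizes=split_sizes,
        pooled_ages=yy, pooled_predictions=pp,
    )
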