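"""Feature extraction (time, nonlinear, statistical, frequency and
model-based families) and the two-step feature selection.

All features are causal: the value at sample k uses only samples <= k.
Rows whose contributing windows touch a missing sample are flagged
invalid and excluded downstream (never zero-filled).

Selection is two-step: a per-feature deviance (likelihood-ratio) test
of a single-feature multinomial logistic model against the
intercept-only model drops insignificant features, then sequential
floating forward selection (SFFS) scored by stratified cross-validated
accuracy of a small random forest (30 trees, depth 6) ranks the
survivors and keeps the top 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from scipy.stats import chi2
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .io_grid import GriddedSeries
from .impute import total_insulin_per_sample

log = logging.getLogger("glyco")

# fourth-order-accurate backward difference stencils (unit step h = 1 sample)
D1_STENCIL = np.array([25.0, -48.0, 36.0, -16.0, 3.0]) / 12.0
D2_STENCIL = np.array([45.0, -154.0, 214.0, -156.0, 61.0, -10.0]) / 12.0

STAT_WINDOW = 24
SPECTRAL_WINDOW = 288


def _backward_apply(x: np.ndarray, stencil: np.ndarray) -> np.ndarray:
    """y_k = sum_i stencil[i] * x[k-i]; NaN where the window is incomplete."""
    n, w = len(x), len(stencil)
    out = np.full(n, np.nan)
    if n < w:
        return out
    wins = sliding_window_view(x, w)  # wins[j] = x[j..j+w-1]
    vals = wins @ stencil[::-1]
    out[w - 1:] = vals
    out[np.isnan(out)] = np.nan
    return out


def backward_derivatives(cgm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives per sample by 4th-order backward
    differences (NaN where any window sample is missing)."""
    return _backward_apply(cgm, D1_STENCIL), _backward_apply(cgm, D2_STENCIL)


def qualitative_products(d1: np.ndarray, d2: np.ndarray):
    """sign(d1)*sign(d2) in {-1,0,1} and |d1|*|d2|."""
    return np.sign(d1) * np.sign(d2), np.abs(d1) * np.abs(d2)


def _gauss_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> float:
    return float(np.exp(-np.sum((a - b) ** 2) / (2.0 * gamma ** 2)))


def window_statistics(cgm, d1, d2, window: int = STAT_WINDOW,
                      gamma: float | None = None):
    """Per-sample statistics of the trailing ``window`` CGM samples plus
    pairwise covariance / Pearson correlation / Gaussian-kernel
    similarity for (CGM,d1), (CGM,d2), (d1,d2).

    Correlation of a zero-variance window is defined as 0.  Returns
    (names, N x F block); rows with incomplete windows are NaN.
    """
    n = len(cgm)
    names = ["win_mean", "win_var", "win_std", "win_median", "win_skew",
             "win_min", "win_max", "win_range"]
    for pa, pb in (("cgm", "d1"), ("cgm", "d2"), ("d1", "d2")):
        names += [f"cov_{pa}_{pb}", f"corr_{pa}_{pb}", f"ksim_{pa}_{pb}"]
    out = np.full((n, len(names)), np.nan)
    series = {"cgm": cgm, "d1": d1, "d2": d2}
    if gamma is None:
        gamma = _median_heuristic(cgm, d1, d2, window)
    for k in range(window - 1, n):
        wins = {nm: s[k - window + 1: k + 1] for nm, s in series.items()}
        if any(np.isnan(w).any() for w in wins.values()):
            continue
        c = wins["cgm"]
        row = [c.mean(), c.var(), c.std(), np.median(c),
               stats.skew(c, bias=True) if c.std() > 0 else 0.0,
               c.min(), c.max(), c.max() - c.min()]
        for pa, pb in (("cgm", "d1"), ("cgm", "d2"), ("d1", "d2")):
            a, b = wins[pa], wins[pb]
            cov = float(np.cov(a, b, bias=True)[0, 1])
            if a.std() > 0 and b.std() > 0:
                corr = float(np.corrcoef(a, b)[0, 1])
            else:
                corr = 0.0
            row += [cov, corr, _gauss_kernel(a, b, gamma)]
        out[k] = row
    return names, out


def _median_heuristic(cgm, d1, d2, window, max_pairs: int = 200) -> float:
    """Median pairwise distance between trailing windows (kernel bandwidth)."""
    n = len(cgm)
    valid = [k for k in range(window - 1, n)
             if not (np.isnan(cgm[k - window + 1:k + 1]).any())]
    if len(valid) < 2:
        return 1.0
    rng = np.random.default_rng(0)
    ks = rng.choice(valid, size=min(len(valid), max_pairs), replace=False)
    wins = np.stack([cgm[k - window + 1:k + 1] for k in ks])
    d = np.sqrt(((wins[:, None] - wins[None]) ** 2).sum(-1))
    med = float(np.median(d[np.triu_indices(len(ks), 1)]))
    return med if med > 0 else 1.0


def spectral_peaks(cgm: np.ndarray, window: int = SPECTRAL_WINDOW):
    """Magnitudes and frequencies (cycles/day) of the three dominant
    power-spectrum peaks of the trailing 24-h window.

    The window is mean-removed; peaks are local maxima of the
    periodogram excluding the zero bin, sorted by power descending and
    padded with (0, 0) when fewer than three exist.
    """
    n = len(cgm)
    names = []
    for i in (1, 2, 3):
        names += [f"spec_mag{i}", f"spec_freq{i}"]
    out = np.full((n, 6), np.nan)
    freqs_per_day = np.arange(window // 2 + 1) * (86400.0 / (window * 300.0))
    for k in range(window - 1, n):
        w = cgm[k - window + 1: k + 1]
        if np.isnan(w).any():
            continue
        power = np.abs(np.fft.rfft(w - w.mean())) ** 2 / window
        # local maxima over bins 1..end (zero bin excluded by mean removal)
        gt_left = power[1:] > power[:-1]
        ge_right = np.append(power[1:-1] >= power[2:], True)
        loc = np.flatnonzero(gt_left & ge_right) + 1
        loc = loc[np.argsort(-power[loc], kind="stable")][:3]
        peaks = [(power[j], freqs_per_day[j]) for j in loc]
        peaks = (peaks + [(0.0, 0.0)] * 3)[:3]
        out[k] = [v for pk in peaks for v in pk]
    return names, out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    names: list
    values: np.ndarray      # N x F
    valid_mask: np.ndarray  # True where every contributing window was complete
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    @property
    def F(self) -> int:
        return self.values.shape[1]

    def standardize(self, train_rows: np.ndarray) -> "FeatureTable":
        """Fit zero-mean/unit-variance scaling on ``train_rows`` only and
        apply it everywhere (test rows use the training statistics)."""
        sel = train_rows & self.valid_mask
        mu = np.nanmean(self.values[sel], axis=0)
        sd = np.nanstd(self.values[sel], axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        vals = (self.values - mu) / sd
        return FeatureTable(names=list(self.names), values=vals,
                            valid_mask=self.valid_mask.copy(),
                            scaler_mean=mu, scaler_std=sd)

    def select(self, names) -> "FeatureTable":
        idx = [self.names.index(nm) for nm in names]
        return FeatureTable(names=list(names), values=self.values[:, idx],
                            valid_mask=self.valid_mask.copy(),
                            scaler_mean=None if self.scaler_mean is None
                            else self.scaler_mean[idx],
                            scaler_std=None if self.scaler_std is None
                            else self.scaler_std[idx])


def assemble_features(series: GriddedSeries, pic: np.ndarray,
                      ug: np.ndarray) -> FeatureTable:
    """Column-bind all feature families plus raw CGM and insulin."""
    cgm = series.channels["cgm"]
    ins = total_insulin_per_sample(series)
    d1, d2 = backward_derivatives(cgm)
    sgn, mag = qualitative_products(d1, d2)
    stat_names, stat_vals = window_statistics(cgm, d1, d2)
    spec_names, spec_vals = spectral_peaks(cgm)

    names = (["cgm", "insulin", "d1", "d2", "sign_prod", "mag_prod"]
             + stat_names + spec_names + ["pic", "ug"])
    cols = [cgm, ins, d1, d2, sgn, mag]
    values = np.column_stack(cols + [stat_vals, spec_vals,
                                     np.asarray(pic), np.asarray(ug)])
    valid = ~np.isnan(values).any(axis=1)
    return FeatureTable(names=names, values=values, valid_mask=valid)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _multinomial_loglik_null(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(counts * np.log(p)))


def deviance_filter(table: FeatureTable, labels: np.ndarray,
                    alpha: float = 0.05) -> list:
    """Marginal deviance screen: keep features whose single-feature
    multinomial logistic model beats the intercept-only model in a
    likelihood-ratio test at level ``alpha``.  Constant features drop."""
    rows = table.valid_mask
    y = labels[rows]
    classes = np.unique(y)
    ll0 = _multinomial_loglik_null(y)
    df = len(classes) - 1
    kept = []
    for f, name in enumerate(table.names):
        x = table.values[rows, f:f + 1]
        if np.std(x) == 0:
            log.info("deviance_filter: %s constant -> dropped", name)
            continue
        xs = (x - x.mean()) / x.std()
        model = LogisticRegression(C=np.inf, max_iter=200)  # unpenalized
        model.fit(xs, y)
        proba = model.predict_proba(xs)
        idx = np.searchsorted(classes, y)
        ll1 = float(np.sum(np.log(proba[np.arange(len(y)), idx] + 1e-300)))
        dev = 2.0 * (ll1 - ll0)
        p = float(chi2.sf(max(dev, 0.0), df))
        if p <= alpha:
            kept.append(name)
    return kept


def _cv_score(X, y, estimator_cfg, folds, seed) -> float:
    rf = RandomForestClassifier(
        n_estimators=estimator_cfg.get("trees", 30),
        max_depth=estimator_cfg.get("max_depth", 6),
        random_state=seed, n_jobs=1)
    counts = np.bincount(y)
    n_splits = int(min(folds, counts[counts > 0].min()))
    if n_splits < 2:
        return float(np.mean(cross_val_score(rf, X, y, cv=2)))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(rf, X, y, cv=cv, n_jobs=1)))


def sffs_select(table: FeatureTable, labels: np.ndarray, k_out: int = 20,
                estimator_cfg: dict | None = None, seed: int = 0,
                folds: int = 3, max_rows: int = 4000) -> tuple[list, list]:
    """Sequential floating forward selection of exactly ``k_out`` features.

    Greedy forward inclusion scored by stratified CV accuracy of the
    configured random forest, with conditional backward exclusion when
    removing a feature improves the best score recorded for that subset
    size.  Returns (selected names in inclusion order, score trace).
    """
    estimator_cfg = estimator_cfg or {"trees": 30, "max_depth": 6}
    rows = np.flatnonzero(table.valid_mask)
    if len(rows) > max_rows:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(rows, size=max_rows, replace=False))
    X_all = table.values[rows]
    y = labels[rows]
    names = list(table.names)
    if len(names) <= k_out:
        if len(names) < k_out:
            log.warning("sffs_select: only %d features available (< %d)",
                        len(names), k_out)
        return names, []

    selected: list[int] = []
    best_at_size: dict[int, float] = {}
    trace = []

    def score(subset) -> float:
        return _cv_score(X_all[:, subset], y, estimator_cfg, folds, seed)

    while len(selected) < k_out:
        # forward: add the best remaining feature (ties -> lowest index)
        cand_scores = [(score(selected + [j]), j)
                       for j in range(len(names)) if j not in selected]
        s_best, j_best = max(cand_scores, key=lambda t: (t[0], -t[1]))
        selected.append(j_best)
        best_at_size[len(selected)] = max(best_at_size.get(len(selected), -np.inf), s_best)
        trace.append((names[j_best], s_best))
        # floating backward: drop a feature if that beats the recorded best
        while len(selected) > 2:
            rem_scores = [(score([i for i in selected if i != j]), j)
                          for j in selected[:-1]]
            s_rem, j_rem = max(rem_scores, key=lambda t: (t[0], -t[1]))
            size = len(selected) - 1
            if s_rem > best_at_size.get(size, -np.inf) + 1e-12:
                selected.remove(j_rem)
                best_at_size[size] = s_rem
            else:
                break
    return [names[j] for j in selected[:k_out]], trace
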