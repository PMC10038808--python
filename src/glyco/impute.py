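"""Missing-sample imputation.

Three strategies, matched to the physiology of each channel:

* basal insulin is piecewise constant and follows a daily schedule, so
  short gaps (<= 2 h) are forward/backward filled and longer gaps copy
  the previous day's value at the same time of day;
* sparse diary channels (bolus, carbohydrate, fingerstick glucose,
  durations, distance) receive median imputation;
* CGM is imputed multivariately with probabilistic PCA (PPCA) on lagged
  matrices built from CGM, total delivered insulin, carbohydrate,
  energy expenditure and activity duration, using the EM algorithm for
  factor models with missing entries.  Each column of the lagged matrix
  stacks the past two hours (25 samples) of the five variables, so a
  single missing CGM grid sample appears in up to 25 columns; its final
  estimate is the diagonal average of all reconstructed occurrences.

Gaps of more than 25 consecutive missing CGM samples (~2 h) are left
missing: extrapolating across them is unreliable and the detectors
exclude them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_grid import GriddedSeries, PROV_IMPUTED

log = logging.getLogger("glyco")

#: variables entering the lagged matrix, in row-block order
LAG_VARS = ("cgm", "insulin", "carbohydrate", "energy_value", "activity_duration")
N_LAGS = 25  # lags 0..24 = two hours of 5-min samples
MAX_CGM_GAP = 25  # longest consecutive-missing CGM run that is imputed

SPARSE_CHANNELS = ("bolus", "carbohydrate", "smbg", "duration",
                   "activity_duration", "distance_value")


def total_insulin_per_sample(series: GriddedSeries) -> np.ndarray:
    """Total delivered insulin per 5-min sample (U): basal_rate/12 + bolus."""
    basal = series.channels["basal_rate"] / 12.0
    bolus = np.nan_to_num(series.channels["bolus"], nan=0.0)
    return basal + bolus


# ---------------------------------------------------------------------------
# rule-based imputation
# ---------------------------------------------------------------------------

def _missing_runs(mask: np.ndarray):
    """(start, stop) of maximal runs of True, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def impute_basal(series: GriddedSeries, short_gap: int = 24,
                 day_offset: int = 288) -> GriddedSeries:
    """Fill basal-rate gaps: ffill/bfill up to ``short_gap`` samples, else
    copy the previous day's sample at the same time of day."""
    out = series.copy()
    b = out.channels["basal_rate"]
    prov = out.provenance["basal_rate"]
    for start, stop in _missing_runs(np.isnan(b)):
        length = stop - start
        if length <= short_gap:
            if start > 0:
                b[start:stop] = b[start - 1]
            elif stop < len(b):
                b[start:stop] = b[stop]  # head gap: backward fill
            else:
                continue
            prov[start:stop] = PROV_IMPUTED
        else:
            for k in range(start, stop):
                if k - day_offset >= 0 and not np.isnan(b[k - day_offset]):
                    b[k] = b[k - day_offset]
                    prov[k] = PROV_IMPUTED
    return out


def impute_sparse_median(series: GriddedSeries, channel: str) -> GriddedSeries:
    """Replace missing samples with the channel's observed median (0 if no
    observations exist)."""
    out = series.copy()
    x = out.channels[channel]
    miss = np.isnan(x)
    obs = x[~miss]
    fill = float(np.median(obs)) if obs.size else 0.0
    x[miss] = fill
    out.provenance[channel][miss] = PROV_IMPUTED
    return out


def impute_rule_based(series: GriddedSeries) -> GriddedSeries:
    """Basal fill plus median fill of every sparse channel."""
    out = impute_basal(series)
    for ch in SPARSE_CHANNELS:
        if ch in out.channels:
            out = impute_sparse_median(out, ch)
    return out


# ---------------------------------------------------------------------------
# lagged matrix
# ---------------------------------------------------------------------------

@dataclass
class LaggedMatrix:
    """M x N matrix of lagged multichannel histories (NaN = unobserved).

    Row ``k * 25 + l`` holds variable ``LAG_VARS[k]`` at lag ``l``; column
    ``c`` corresponds to grid index ``c + 24``.
    """

    X: np.ndarray
    col_offset: int = N_LAGS - 1

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def obs_mask(self) -> np.ndarray:
        return ~np.isnan(self.X)


def build_lagged_matrix(series: GriddedSeries) -> LaggedMatrix:
    """Stack 25-lag histories of the five imputation variables."""
    n = series.n
    if n < N_LAGS:
        raise ValueError(f"series of length {n} < {N_LAGS}: no complete lag window")
    chans = {v: (total_insulin_per_sample(series) if v == "insulin"
                 else series.channels[v]) for v in LAG_VARS}
    ncols = n - (N_LAGS - 1)
    X = np.empty((len(LAG_VARS) * N_LAGS, ncols))
    for k, v in enumerate(LAG_VARS):
        x = chans[v]
        for lag in range(N_LAGS):
            X[k * N_LAGS + lag] = x[N_LAGS - 1 - lag: n - lag]
    return LaggedMatrix(X=X)


# ---------------------------------------------------------------------------
# PPCA via EM with missing entries
# ---------------------------------------------------------------------------

@dataclass
class PPCAModel:
    """Gaussian latent-factor model x_j = W t_j + mu + eps, eps ~ N(0, s2 I).

    Fitted by EM over the observed cells only.  ``latent_mean`` holds the
    per-column posterior mean of t_j; ``loglik_trace`` the observed-data
    log-likelihood after every EM iteration.
    """

    W: np.ndarray
    mu: np.ndarray
    sigma2: float
    q: int
    latent_mean: np.ndarray  # q x N
    n_iter: int = 0
    converged: bool = True
    loglik_trace: list = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.latent_mean + self.mu[:, None]


def _pattern_groups(obs: np.ndarray):
    """Group columns sharing a missing pattern; yields (row-idx, col-idx)."""
    keys = np.ascontiguousarray(obs.T).view(
        np.dtype((np.void, obs.shape[0] * obs.dtype.itemsize))).ravel()
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    starts = np.flatnonzero(np.concatenate(([True], sorted_keys[1:] != sorted_keys[:-1])))
    bounds = np.append(starts, len(order))
    for a, b in zip(bounds[:-1], bounds[1:]):
        cols = order[a:b]
        rows = np.flatnonzero(obs[:, cols[0]])
        if rows.size:
            yield rows, cols


def _observed_loglik(X, obs, W, mu, sigma2) -> float:
    """Marginal log-likelihood of the observed cells, via Woodbury."""
    q = W.shape[1]
    total = 0.0
    for rows, cols in _pattern_groups(obs):
        Wp = W[rows]
        m = rows.size
        G = Wp.T @ Wp
        A = np.eye(q) + G / sigma2
        sign, logdet_A = np.linalg.slogdet(A)
        logdet = m * np.log(sigma2) + logdet_A
        D = X[np.ix_(rows, cols)] - mu[rows, None]  # m x nc
        # quadratic form via Woodbury: S^-1 = I/s2 - W A^-1 W^T / s2^2
        WtD = Wp.T @ D
        quad = (D * D).sum(axis=0) / sigma2 - np.einsum(
            "qn,qn->n", WtD, np.linalg.solve(A, WtD)) / sigma2 ** 2
        total += float(-(0.5 * (m * np.log(2 * np.pi) + logdet) * cols.size
                         + 0.5 * quad.sum()))
    return total


def fit_ppca(L: LaggedMatrix, q: int = 10, tol: float = 1e-6,
             max_iter: int = 500, seed: int = 0,
             track_loglik: bool = True) -> PPCAModel:
    """EM fit of the PPCA model to the observed cells of a lagged matrix.

    E-step (per column j, observed rows eta_j):
        Cvar_j = s2 (s2 I_q + sum_i W_i W_i^T)^-1
        m_j    = Cvar_j / s2 * sum_i W_i^T (X_ij - mu_i)
    M-step (per row i, observed columns eta_i):
        mu_i = mean_j (X_ij - W_i m_j)
        W_i  = [sum_j m_j m_j^T + Cvar_j]^-1 sum_j m_j (X_ij - mu_i)
        s2   = mean over eta of (X_ij - W_i m_j - mu_i)^2 + W_i Cvar_j W_i^T

    Iterates until the relative changes of both sigma^2 and ||W||_F fall
    below ``tol``.  Deterministic given ``seed``.
    """
    X = L.X
    M, N = X.shape
    if q > M:
        raise ValueError(f"q={q} exceeds M={M}")
    obs = ~np.isnan(X)
    if not obs.any():
        raise ValueError("no observed cells")
    rng = np.random.default_rng(seed)

    Xz = np.where(obs, X, 0.0)
    counts_row = obs.sum(axis=1)
    mu = np.where(counts_row > 0, Xz.sum(axis=1) / np.maximum(counts_row, 1), 0.0)
    resid = np.where(obs, X - mu[:, None], 0.0)
    sigma2 = float((resid ** 2).sum() / obs.sum())
    sigma2 = max(sigma2, 1e-12)
    W = 0.01 * np.sqrt(max(sigma2, 1e-6)) * rng.standard_normal((M, q))

    model = PPCAModel(W=W, mu=mu, sigma2=sigma2, q=q,
                      latent_mean=np.zeros((q, N)))
    Tm = np.zeros((q, N))
    TT = np.zeros((N, q, q))  # m_j m_j^T + Cvar_j per column

    def e_step():
        for rows, cols in _pattern_groups(obs):
            Wp = W[rows]
            A = sigma2 * np.eye(q) + Wp.T @ Wp
            A_inv = np.linalg.inv(A)
            Cvar = sigma2 * A_inv
            D = X[np.ix_(rows, cols)] - mu[rows, None]
            Tm[:, cols] = A_inv @ (Wp.T @ D)
            TT[cols] = Cvar + np.einsum("qn,rn->nqr", Tm[:, cols], Tm[:, cols])

    for it in range(max_iter):
        W_old, s2_old = W, sigma2
        e_step()
        # ---- M-step (conditional maximizations under the fixed posterior)
        recon_T = W @ Tm
        mu = np.where(counts_row > 0,
                      np.where(obs, X - recon_T, 0.0).sum(axis=1)
                      / np.maximum(counts_row, 1), mu)
        B = obs.astype(float) @ TT.reshape(N, q * q)  # M x q^2
        C = np.where(obs, X - mu[:, None], 0.0) @ Tm.T  # M x q
        W = np.array([np.linalg.solve(B[i].reshape(q, q) + 1e-10 * np.eye(q), C[i])
                      if counts_row[i] else W[i] for i in range(M)])
        # expected complete-data residual with the updated W and mu:
        # sum_eta (X-mu)^2 - 2 W_i . C_i + W_i B_i W_i^T
        sq = float((np.where(obs, X - mu[:, None], 0.0) ** 2).sum())
        term2 = -2.0 * float(np.einsum("iq,iq->", W, C))
        term3 = float(np.einsum("iq,iqr,ir->", W, B.reshape(M, q, q), W))
        sigma2 = max((sq + term2 + term3) / obs.sum(), 1e-12)
        if track_loglik:
            model.loglik_trace.append(_observed_loglik(X, obs, W, mu, sigma2))
        dW = np.linalg.norm(W - W_old) / max(np.linalg.norm(W_old), 1e-12)
        ds = abs(sigma2 - s2_old) / max(s2_old, 1e-12)
        if dW < tol and ds < tol:
            model.n_iter = it + 1
            break
    else:
        model.n_iter = max_iter
        model.converged = False
        log.warning("fit_ppca: EM did not converge in %d iterations", max_iter)

    e_step()  # posterior consistent with the final parameters
    model.W, model.mu, model.sigma2, model.latent_mean = W, mu, sigma2, Tm.copy()
    return model


def impute_cgm_ppca(series: GriddedSeries, q: int = 10, tol: float = 1e-6,
                    max_iter: int = 500, seed: int = 0,
                    max_gap: int = MAX_CGM_GAP) -> tuple[GriddedSeries, PPCAModel]:
    """Impute missing CGM samples by PPCA reconstruction of lagged matrices.

    Every missing CGM grid sample that lies in a run of at most ``max_gap``
    consecutive missing samples receives the mean of its reconstructed
    occurrences over all (lag, column) positions (diagonal averaging).
    Observed samples are never altered.
    """
    out = series.copy()
    cgm = out.channels["cgm"]
    miss = np.isnan(cgm)
    if not miss.any():
        return out, None
    L = build_lagged_matrix(out)
    # per-variable standardization: the model has one isotropic noise
    # variance, so rows must share a scale (activity is in ms, CGM in mg/dL)
    scales = np.ones(L.M)
    for k in range(len(LAG_VARS)):
        block = L.X[k * N_LAGS:(k + 1) * N_LAGS]
        sd = np.nanstd(block)
        scales[k * N_LAGS:(k + 1) * N_LAGS] = sd if sd > 1e-9 else 1.0
    Ls = LaggedMatrix(X=L.X / scales[:, None], col_offset=L.col_offset)
    model = fit_ppca(Ls, q=q, tol=tol, max_iter=max_iter, seed=seed,
                     track_loglik=False)
    Xhat = model.reconstruct() * scales[:, None]
    fillable = np.zeros_like(miss)
    for start, stop in _missing_runs(miss):
        if stop - start <= max_gap:
            fillable[start:stop] = True
    ncols = L.N
    for g in np.flatnonzero(fillable):
        vals = []
        for lag in range(N_LAGS):
            c = g + lag - (N_LAGS - 1)
            if 0 <= c < ncols:
                vals.append(Xhat[lag, c])  # CGM block is rows 0..24
        if vals:
            cgm[g] = float(np.mean(vals))
            out.provenance["cgm"][g] = PROV_IMPUTED
    return out, model
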