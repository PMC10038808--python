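"""Glucose--insulin physiology: Hovorka compartment model, body-weight
estimation from insulin totals, and particle-filter estimation of plasma
insulin concentration (PIC) and gut glucose absorption rate (U_G).

The Hovorka model tracks subcutaneous insulin absorption (S1, S2),
plasma insulin I, three remote insulin actions (x1 distribution, x2
disposal, x3 endogenous glucose production), glucose masses in the
accessible/non-accessible compartments (Q1, Q2), and the subcutaneous
glucose concentration Gsub that a CGM sensor measures.  For state
estimation the state is extended with t_maxI, k_e and U_G as bounded
random walks, so the filter can infer unannounced carbohydrate intake
from the CGM trace alone: a meal appears as a rising U_G estimate.

Units follow the standard parameterization: insulin in mU, glucose
masses in mmol, concentrations in mmol/L (glucose) and mU/L (insulin),
time in minutes; EGP_0 and F_01 are per kg body weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io_grid import GriddedSeries, MGDL_PER_MMOLL
from .impute import total_insulin_per_sample

log = logging.getLogger("glyco")

MMOL_PER_GRAM = 1000.0 / 180.16  # mmol glucose per gram of carbohydrate
PARAM_REVERT_MIN = 360.0  # min; mean-reversion time of augmented parameters

# extended state vector layout
S1, S2, I, X1, X2, X3, Q1, Q2, GSUB, TMAXI, KE, UG = range(12)
NX = 12
STATE_NAMES = ("S1", "S2", "I", "x1", "x2", "x3", "Q1", "Q2", "Gsub",
               "tmaxI", "ke", "UG")


@dataclass
class HovorkaParams:
    """Nominal parameter set (per-kg fluxes scaled by ``body_weight``)."""

    body_weight: float = 70.0   # kg
    ke: float = 0.138           # 1/min, fractional PIC elimination
    ka1: float = 0.006          # 1/min
    ka2: float = 0.06
    ka3: float = 0.03
    sit: float = 0.00512        # L/min/mU, insulin sensitivity of distribution
    sid: float = 0.00082        # L/min/mU, insulin sensitivity of disposal
    sie: float = 0.052          # L/mU, insulin sensitivity of EGP
    egp0: float = 0.0161        # mmol/kg/min, EGP at zero insulin
    k12: float = 0.066          # 1/min
    f01: float = 0.0097         # mmol/kg/min, non-insulin-dependent flux
    tau: float = 15.0           # min, subcutaneous glucose sensor lag
    tmax_i: float = 55.0        # min, insulin absorption time-to-maximum
    # forward meal (gut absorption) model used by the simulator
    ag: float = 0.8             # carbohydrate bioavailability
    tmax_g: float = 40.0        # min, time-to-maximum of gut absorption
    exercise_intensity: float = 1.0  # extra fractional glucose uptake

    @property
    def kb1(self) -> float:
        return self.ka1 * self.sit

    @property
    def kb2(self) -> float:
        return self.ka2 * self.sid

    @property
    def kb3(self) -> float:
        return self.ka3 * self.sie

    @property
    def vg(self) -> float:
        return 0.16 * self.body_weight

    @property
    def vi(self) -> float:
        return 0.12 * self.body_weight


#: physiological bounds for the extended state (state estimation clips here)
DEFAULT_BOUNDS = np.array([
    [0.0, 1e5],     # S1 (mU)
    [0.0, 1e5],     # S2
    [0.0, 300.0],   # I (mU/L)
    [0.0, 1.0],     # x1 (1/min)
    [0.0, 1.0],     # x2
    [0.0, 2.0],     # x3
    [0.0, 1e4],     # Q1 (mmol)
    [0.0, 1e4],     # Q2
    [0.0, 33.3],    # Gsub (mmol/L)
    [20.0, 120.0],  # tmaxI (min)
    [0.05, 0.30],   # ke (1/min)
    [0.0, 8.0],     # UG (mmol/min)
])


def estimate_body_weight(series: GriddedSeries, factor: float = 0.5) -> float:
    """Body weight (kg) = modal daily insulin total (U/day) / 0.5 U/kg/day.

    Daily totals are computed over complete days (288 samples with basal
    defined throughout), rounded to the nearest unit; the mode (smallest
    on ties) is divided by the conversion factor.
    """
    days = series.day_index()
    basal = series.channels["basal_rate"]
    bolus = np.nan_to_num(series.channels["bolus"], nan=0.0)
    totals = []
    for d in np.unique(days):
        sel = days == d
        if sel.sum() != 288 or np.isnan(basal[sel]).any():
            continue
        totals.append(float(np.sum(basal[sel]) / 12.0 + np.sum(bolus[sel])))
    if not totals:
        raise ValueError("no complete day of insulin data")
    rounded = np.round(totals)
    vals, counts = np.unique(rounded, return_counts=True)
    mode = float(vals[np.argmax(counts)])  # np.unique sorts: ties -> smallest
    if mode <= 0:
        raise ValueError("modal daily insulin total is zero; cannot estimate weight")
    return mode / factor


# ---------------------------------------------------------------------------
# model dynamics
# ---------------------------------------------------------------------------

def hovorka_rhs(state: np.ndarray, insulin: float, params: HovorkaParams,
                exercise: float = 0.0) -> np.ndarray:
    """Right-hand side of the extended ODE system.

    ``state`` has shape (..., 12); ``insulin`` is the subcutaneous
    infusion in mU/min.  U_G, t_maxI and k_e are read from the state
    (zero dynamics; they move only under process noise).  During
    exercise the insulin-dependent flux x1*Q1 out of the accessible
    compartment is amplified by (1 + exercise), representing increased
    glucose uptake.
    """
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state")
    s = np.asarray(state, dtype=float)
    d = np.zeros_like(s)
    p = params
    bw = p.body_weight
    tmaxi = s[..., TMAXI]
    ke = s[..., KE]
    gsub = s[..., GSUB]

    d[..., S1] = insulin - s[..., S1] / tmaxi
    d[..., S2] = s[..., S1] / tmaxi - s[..., S2] / tmaxi
    d[..., I] = s[..., S2] / (tmaxi * p.vi) - ke * s[..., I]
    d[..., X1] = p.kb1 * s[..., I] - p.ka1 * s[..., X1]
    d[..., X2] = p.kb2 * s[..., I] - p.ka2 * s[..., X2]
    d[..., X3] = p.kb3 * s[..., I] - p.ka3 * s[..., X3]

    f01c = np.where(gsub >= 4.5, p.f01 * bw, p.f01 * bw * gsub / 4.5)
    fr = np.where(gsub >= 9.0, 0.003 * (gsub - 9.0) * p.vg, 0.0)
    egp = p.egp0 * bw * np.maximum(1.0 - s[..., X3], 0.0)
    uptake = s[..., X1] * s[..., Q1] * (1.0 + exercise)
    d[..., Q1] = s[..., UG] - f01c - fr - uptake + p.k12 * s[..., Q2] + egp
    d[..., Q2] = s[..., X1] * s[..., Q1] - (p.k12 + s[..., X2]) * s[..., Q2]
    d[..., GSUB] = (s[..., Q1] / p.vg - gsub) / p.tau
    # augmented parameter states revert gently to nominal: they adapt
    # through process noise but cannot drift away unidentifiably
    d[..., TMAXI] = (p.tmax_i - tmaxi) / PARAM_REVERT_MIN
    d[..., KE] = (p.ke - ke) / PARAM_REVERT_MIN
    return d


def rk4_step(state, insulin, params, dt, exercise=0.0):
    k1 = hovorka_rhs(state, insulin, params, exercise)
    k2 = hovorka_rhs(state + 0.5 * dt * k1, insulin, params, exercise)
    k3 = hovorka_rhs(state + 0.5 * dt * k2, insulin, params, exercise)
    k4 = hovorka_rhs(state + dt * k3, insulin, params, exercise)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def propagate(state, insulin, params, total_min=5.0, dt_min=1.0, exercise=0.0):
    """Advance the state over one grid interval with fixed-step RK4."""
    nsub = max(1, int(round(total_min / dt_min)))
    h = total_min / nsub
    for _ in range(nsub):
        state = rk4_step(state, insulin, params, h, exercise)
    return state


def meal_ug_profile(n: int, meal_samples, meal_grams, params: HovorkaParams,
                    step_min: float = 5.0) -> np.ndarray:
    """Gut absorption input U_G (mmol/min) per grid sample from a meal list.

    Two-compartment gut model: U_G(t) = D A_G t exp(-t/t_maxG) / t_maxG^2
    with D in mmol, evaluated at each sample midpoint and superposed.
    """
    ug = np.zeros(n)
    t = (np.arange(n) + 0.5) * step_min
    for k, grams in zip(meal_samples, meal_grams):
        d_mmol = grams * MMOL_PER_GRAM
        rel = t - k * step_min
        active = rel > 0
        ug[active] += (d_mmol * params.ag * rel[active]
                       * np.exp(-rel[active] / params.tmax_g) / params.tmax_g ** 2)
    return ug


def basal_steady_state(params: HovorkaParams, basal_u_per_h: float) -> np.ndarray:
    """Equilibrium extended state under constant basal infusion."""
    p = params
    u = basal_u_per_h * 1000.0 / 60.0  # mU/min
    s1 = s2 = u * p.tmax_i
    i_eq = u / (p.ke * p.vi)
    x1 = p.kb1 * i_eq / p.ka1
    x2 = p.kb2 * i_eq / p.ka2
    x3 = p.kb3 * i_eq / p.ka3
    egp = p.egp0 * p.body_weight * max(1.0 - x3, 0.0)

    def balance(q1):
        g = q1 / p.vg
        f01c = p.f01 * p.body_weight * (1.0 if g >= 4.5 else g / 4.5)
        fr = 0.003 * (g - 9.0) * p.vg if g >= 9.0 else 0.0
        q2 = x1 * q1 / (p.k12 + x2) if (p.k12 + x2) > 0 else 0.0
        return egp - f01c - fr - x1 * q1 + p.k12 * q2

    lo_q1, hi_q1 = 1e-9, 40.0 * p.vg
    if balance(lo_q1) <= 0:
        q1 = lo_q1   # EGP fully suppressed: glucose equilibrium at ~0
    elif balance(hi_q1) >= 0:
        q1 = hi_q1   # sinks never catch production within the bracket
    else:
        q1 = brentq(balance, lo_q1, hi_q1)
    q2 = x1 * q1 / (p.k12 + x2) if (p.k12 + x2) > 0 else 0.0
    state = np.zeros(NX)
    state[[S1, S2, I, X1, X2, X3, Q1, Q2, GSUB]] = [s1, s2, i_eq, x1, x2, x3,
                                                    q1, q2, q1 / p.vg]
    state[TMAXI], state[KE], state[UG] = p.tmax_i, p.ke, 0.0
    return state


def simulate_hovorka(params: HovorkaParams, insulin_mu_min: np.ndarray,
                     ug_input: np.ndarray, exercise_mask: np.ndarray | None = None,
                     x0: np.ndarray | None = None, dt_min: float = 1.0,
                     process_noise: np.ndarray | None = None,
                     seed: int = 0) -> np.ndarray:
    """Forward-simulate the model on the 5-minute grid.

    Inputs are held constant within each grid interval.  Returns the
    state trajectory (n x 12) *at* the grid samples; row k is the state
    at the start of interval k (so row 0 is the initial state).
    Optional zero-mean Gaussian process noise (per-state SD vector) is
    added after every grid step, seeded for determinism.
    """
    n = len(insulin_mu_min)
    if exercise_mask is None:
        exercise_mask = np.zeros(n, dtype=bool)
    if x0 is None:
        x0 = basal_steady_state(params, float(np.median(insulin_mu_min)) * 60 / 1000)
    rng = np.random.default_rng(seed)
    traj = np.empty((n, NX))
    state = x0.copy()
    state[UG] = ug_input[0]
    traj[0] = state
    clip_count = 0
    for k in range(n - 1):
        state[UG] = ug_input[k]
        ex = params.exercise_intensity if exercise_mask[k] else 0.0
        state = propagate(state, insulin_mu_min[k], params, 5.0, dt_min, ex)
        if process_noise is not None:
            state = state + rng.standard_normal(NX) * process_noise
        lo, hi = DEFAULT_BOUNDS[:, 0], DEFAULT_BOUNDS[:, 1]
        clipped = np.clip(state, lo, hi)
        clip_count += int(np.sum(clipped != state))
        state = clipped
        state[UG] = ug_input[k + 1]
        traj[k + 1] = state
    if clip_count:
        log.info("simulate_hovorka: %d state components clipped to bounds", clip_count)
    return traj


# ---------------------------------------------------------------------------
# particle filter
# ---------------------------------------------------------------------------

@dataclass
class PFConfig:
    n_particles: int = 500
    resample_frac: float = 0.5   # resample when N_eff < frac * N_s
    r_var: float = 0.04          # measurement variance, (mmol/L)^2
    q_scale: np.ndarray | None = None  # per-state process-noise SD
    dt_min: float = 1.0
    seed: int = 0
    init_spread: float = 0.10    # initial ensemble SD as fraction of the mean
    smooth_lag: int = 8          # fixed-lag smoothing horizon for U_G (samples)


def default_q_scale(params: HovorkaParams) -> np.ndarray:
    """Per-state process-noise SDs: ~1% of nominal magnitudes for the
    physical states; random-walk scales for the augmented states."""
    eq = basal_steady_state(params, 0.5)
    q = 0.01 * np.maximum(np.abs(eq), 1e-3)
    q[TMAXI] = 0.1    # min per step
    q[KE] = 2e-4      # 1/min per step
    q[UG] = 0.5       # mmol/min per step: lets the filter track meals
    return q


@dataclass
class PFResult:
    pic: np.ndarray          # weighted-mean plasma insulin, mU/L
    ug: np.ndarray           # weighted-mean gut absorption, mmol/min (filtered)
    gsub: np.ndarray         # weighted-mean model glucose, mmol/L
    n_eff: np.ndarray
    ug_smoothed: np.ndarray | None = None  # fixed-lag smoothed U_G
    n_resample: int = 0
    n_weight_resets: int = 0
    states_mean: np.ndarray | None = None


def ug_peak_times(ug_est: np.ndarray, smooth_window: int = 9,
                  prominence_frac: float = 0.25,
                  min_distance: int = 18) -> np.ndarray:
    """Sample indices of gut-absorption peaks in a U_G estimate.

    The estimate is smoothed with a short centered moving average (the
    bump tops are flat, so raw argmax wanders on noise wiggles) and
    peaks are local maxima with prominence above ``prominence_frac`` of
    the global maximum, at least ``min_distance`` samples apart.  A
    meal's absorption peaks about t_maxG after intake, so subtracting
    t_maxG from a peak time gives the implied meal start.
    """
    from scipy.signal import find_peaks

    sm = np.convolve(ug_est, np.ones(smooth_window) / smooth_window, mode="same")
    if sm.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(sm, prominence=prominence_frac * sm.max(),
                          distance=min_distance)
    return peaks


def systematic_resample(weights: np.ndarray, rng) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def pf_estimate(series: GriddedSeries, params: HovorkaParams,
                cfg: PFConfig | None = None,
                exercise_mask: np.ndarray | None = None) -> PFResult:
    """Bootstrap particle filter over the extended Hovorka model.

    CGM (mg/dL) is the measurement of Gsub (converted to mmol/L); total
    delivered insulin is the known input.  Missing CGM samples trigger
    prediction-only steps.  Particles are clipped to physiological
    bounds after every propagation; systematic resampling fires when
    N_eff drops below ``resample_frac * N_s``.
    """
    cfg = cfg or PFConfig()
    rng = np.random.default_rng(cfg.seed)
    n = series.n
    y = series.channels["cgm"] / MGDL_PER_MMOLL  # mmol/L
    u = total_insulin_per_sample(series)
    u = np.nan_to_num(u, nan=float(np.nanmedian(u))) * 1000.0 / 5.0  # mU/min
    if exercise_mask is None:
        exercise_mask = np.zeros(n, dtype=bool)
    q_scale = cfg.q_scale if cfg.q_scale is not None else default_q_scale(params)

    basal = series.channels["basal_rate"]
    basal_med = float(np.nanmedian(basal)) if np.isfinite(basal).any() else 0.5
    eta = basal_steady_state(params, max(basal_med, 1e-3))
    ns = cfg.n_particles
    particles = eta + rng.standard_normal((ns, NX)) * (cfg.init_spread * np.abs(eta))
    lo, hi = DEFAULT_BOUNDS[:, 0], DEFAULT_BOUNDS[:, 1]
    particles = np.clip(particles, lo, hi)
    weights = np.full(ns, 1.0 / ns)

    lag = max(0, int(cfg.smooth_lag))
    ug_hist: list[np.ndarray] = []  # particle U_G over the last `lag` steps
    res = PFResult(pic=np.empty(n), ug=np.empty(n), gsub=np.empty(n),
                   n_eff=np.empty(n), ug_smoothed=np.empty(n))
    for k in range(n):
        if k > 0:
            ex = params.exercise_intensity if exercise_mask[k - 1] else 0.0
            particles = propagate(particles, u[k - 1], params, 5.0, cfg.dt_min, ex)
            particles = particles + rng.standard_normal((ns, NX)) * q_scale
            particles = np.clip(particles, lo, hi)
        if not np.isnan(y[k]):
            logw = np.log(weights + 1e-300) - 0.5 * (y[k] - particles[:, GSUB]) ** 2 / cfg.r_var
            logw -= logw.max()
            w = np.exp(logw)
            tot = w.sum()
            if tot <= 0 or not np.isfinite(tot):
                log.warning("pf_estimate: weight underflow at step %d; reset to uniform", k)
                weights = np.full(ns, 1.0 / ns)
                res.n_weight_resets += 1
            else:
                weights = w / tot
        n_eff = 1.0 / np.sum(weights ** 2)
        res.n_eff[k] = n_eff
        ug_hist.append(particles[:, UG].copy())
        if n_eff < cfg.resample_frac * ns:
            idx = systematic_resample(weights, rng)
            particles = particles[idx]
            # carry the ancestry through the smoothing buffer
            ug_hist = [h[idx] for h in ug_hist]
            weights = np.full(ns, 1.0 / ns)
            res.n_resample += 1
        res.pic[k] = float(weights @ particles[:, I])
        res.ug[k] = float(weights @ particles[:, UG])
        res.gsub[k] = float(weights @ particles[:, GSUB])
        if len(ug_hist) > lag:
            res.ug_smoothed[k - lag] = float(weights @ ug_hist.pop(0))
    # flush the tail with the final weights
    for j, h in enumerate(ug_hist):
        res.ug_smoothed[n - len(ug_hist) + j] = float(weights @ h)
    return res
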