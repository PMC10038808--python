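"""Synthetic free-living T1D datasets with known ground truth.

The generator draws a behavioral scenario (meal and exercise times from
time-of-day probability profiles, meal sizes, boluses from a carb
ratio, a daily basal profile), renders it through the Hovorka model to
a clean CGM trace plus pump/diary channels, and then corrupts the
result with the defect types real pump--sensor exports exhibit:
sensor drop-out gaps (including gaps too long to impute), spikes that
violate the physiological outlier rules, stuck-sensor duplicates, and
scheduled fingerstick calibrations with bias.  Ground truth (clean CGM,
true labels, and a ledger of every injected defect) is always returned
alongside, so every cleaning stage can be scored exactly.

Scenario defaults emulate a free-living adult: 60 days, three meals a
day with ~45 min timing jitter, log-normal carbohydrate sizes around
45 g, exercise on about 40% of days (30-60 min, late afternoon), and a
5% chance that an event goes unlogged (and, for meals, unbolused) --
the unannounced events the detectors are for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_grid import (CHANNELS, GriddedSeries, MGDL_PER_MMOLL, PROV_OBSERVED,
                      empty_series)
from .label import EventLabels, label_events
from .physio import (HovorkaParams, basal_steady_state, meal_ug_profile,
                     simulate_hovorka, GSUB, I as STATE_I, UG as STATE_UG)

log = logging.getLogger("glyco")

SAMPLES_PER_DAY = 288
BIN_MINUTES = 30
N_BINS = 48


def _profile_from_modes(modes_min, sds_min, per_day) -> np.ndarray:
    """Per-bin Bernoulli probabilities as a Gaussian mixture over the day,
    scaled so the expected number of events per day is ``per_day``."""
    centers = (np.arange(N_BINS) + 0.5) * BIN_MINUTES
    p = np.zeros(N_BINS)
    for m, s in zip(modes_min, sds_min):
        p += np.exp(-0.5 * ((centers - m) / s) ** 2)
    p *= per_day / p.sum()
    return np.clip(p, 0.0, 1.0)


@dataclass
class Scenario:
    days: int = 60
    meal_profile: np.ndarray = field(default_factory=lambda: _profile_from_modes(
        [8 * 60, 12.5 * 60, 18.5 * 60], [45, 45, 45], per_day=3.0))
    exercise_profile: np.ndarray = field(default_factory=lambda: _profile_from_modes(
        [17.5 * 60], [90], per_day=0.4))
    meal_log_median: float = 45.0   # g CHO, log-normal median
    meal_log_sigma: float = 0.35
    activity_min_minutes: float = 30.0
    activity_max_minutes: float = 60.0
    # dosing chosen consistent with the compartment model's high insulin
    # sensitivity so the rendered glucose stays in a realistic band
    carb_ratio: float = 30.0        # g per U bolus
    basal_day: float = 0.33         # U/h, 06:00-22:00
    basal_night: float = 0.30       # U/h
    reporting_rate: float = 0.95


@dataclass
class CorruptionSpec:
    missing_rate: float = 0.08      # target missing fraction of CGM
    gap_mean: float = 6.0           # mean gap length (geometric), samples
    long_gap_prob: float = 0.08     # chance a gap is drawn long (> 25)
    long_gap_range: tuple = (30, 60)
    spike_rate: float = 0.01        # per-sample probability of a spike
    spike_magnitude: tuple = (40.0, 120.0)  # mg/dL, added or subtracted
    duplicate_rate: float = 0.005   # stuck-sensor repeats
    smbg_per_day: float = 2.0
    smbg_bias_sd: float = 4.0       # mg/dL
    smbg_outlier_prob: float = 0.05  # discrepant fingerstick (> 18 mg/dL off)


@dataclass
class Schedule:
    n: int
    meal_samples: np.ndarray
    meal_grams: np.ndarray
    meal_reported: np.ndarray
    activity_samples: np.ndarray
    activity_ms: np.ndarray
    activity_reported: np.ndarray
    bolus_samples: np.ndarray
    bolus_units: np.ndarray
    basal_u_per_h: np.ndarray


def sample_scenario(spec: Scenario, seed: int = 0) -> Schedule:
    """Draw a concrete event schedule from the scenario probabilities."""
    rng = np.random.default_rng(seed)
    n = spec.days * SAMPLES_PER_DAY
    meals, grams = [], []
    acts, durs = [], []
    bins_per_day = N_BINS
    for d in range(spec.days):
        for b in range(bins_per_day):
            if rng.random() < spec.meal_profile[b]:
                offset = rng.random() * BIN_MINUTES
                k = d * SAMPLES_PER_DAY + int((b * BIN_MINUTES + offset) // 5)
                meals.append(min(k, n - 1))
                grams.append(spec.meal_log_median
                             * np.exp(rng.normal(0.0, spec.meal_log_sigma)))
            if rng.random() < spec.exercise_profile[b]:
                offset = rng.random() * BIN_MINUTES
                k = d * SAMPLES_PER_DAY + int((b * BIN_MINUTES + offset) // 5)
                minutes = rng.uniform(spec.activity_min_minutes,
                                      spec.activity_max_minutes)
                acts.append(min(k, n - 1))
                durs.append(minutes * 60_000.0)
    meals = np.asarray(meals, dtype=int)
    grams = np.asarray(grams)
    acts = np.asarray(acts, dtype=int)
    durs = np.asarray(durs)
    meal_rep = rng.random(len(meals)) < spec.reporting_rate
    act_rep = rng.random(len(acts)) < spec.reporting_rate

    # an unreported (unannounced) meal receives no bolus either
    bolus_samples = meals[meal_rep]
    bolus_units = grams[meal_rep] / spec.carb_ratio

    sod_min = (np.arange(n) % SAMPLES_PER_DAY) * 5
    basal = np.where((sod_min >= 6 * 60) & (sod_min < 22 * 60),
                     spec.basal_day, spec.basal_night)
    return Schedule(n=n, meal_samples=meals, meal_grams=grams,
                    meal_reported=meal_rep, activity_samples=acts,
                    activity_ms=durs, activity_reported=act_rep,
                    bolus_samples=bolus_samples, bolus_units=bolus_units,
                    basal_u_per_h=basal)


@dataclass
class RenderedDataset:
    series: GriddedSeries          # clean channels (diary = reported events)
    truth: EventLabels             # labels from the full schedule
    true_cgm: np.ndarray           # noiseless CGM, mg/dL
    true_ug: np.ndarray            # mmol/min
    true_pic: np.ndarray           # mU/L
    exercise_mask: np.ndarray


def render_dataset(schedule: Schedule, params: HovorkaParams | None = None,
                   cgm_noise_sd: float = 7.0, ar_rho: float = 0.7,
                   seed: int = 0, t0: int = 0) -> RenderedDataset:
    """Forward-simulate the schedule into a clean gridded dataset.

    CGM = Gsub x 18.0182 + AR(1) Gaussian noise (SD in mg/dL).  Diary
    channels carry only *reported* events; the returned truth labels are
    computed from the complete schedule.
    """
    params = params or HovorkaParams()
    rng = np.random.default_rng(seed)
    n = schedule.n
    ug = meal_ug_profile(n, schedule.meal_samples, schedule.meal_grams, params)
    insulin = schedule.basal_u_per_h * 1000.0 / 60.0  # mU/min
    for k, units in zip(schedule.bolus_samples, schedule.bolus_units):
        insulin[k] += units * 1000.0 / 5.0
    exercise = np.zeros(n, dtype=bool)
    for k, ms in zip(schedule.activity_samples, schedule.activity_ms):
        exercise[k: k + max(1, int(np.ceil(ms / 3e5)))] = True
    x0 = basal_steady_state(params, float(np.median(schedule.basal_u_per_h)))
    traj = simulate_hovorka(params, insulin, ug, exercise, x0=x0)
    gsub = traj[:, GSUB]
    true_cgm = gsub * MGDL_PER_MMOLL

    noise = np.zeros(n)
    eps = rng.standard_normal(n) * cgm_noise_sd * np.sqrt(1 - ar_rho ** 2)
    for k in range(1, n):
        noise[k] = ar_rho * noise[k - 1] + eps[k]
    cgm = true_cgm + noise

    series = empty_series(t0, n)
    ch, prov = series.channels, series.provenance
    ch["cgm"][:] = cgm
    ch["basal_rate"][:] = schedule.basal_u_per_h
    ch["bolus"][:] = 0.0
    ch["bolus"][schedule.bolus_samples] = 0.0  # ensure indices valid
    np.add.at(ch["bolus"], schedule.bolus_samples, schedule.bolus_units)
    ch["carbohydrate"][:] = 0.0
    np.add.at(ch["carbohydrate"], schedule.meal_samples[schedule.meal_reported],
              schedule.meal_grams[schedule.meal_reported])
    ch["activity_duration"][:] = 0.0
    rep = schedule.activity_reported
    np.add.at(ch["activity_duration"], schedule.activity_samples[rep],
              schedule.activity_ms[rep])
    ch["duration"][:] = 0.0
    ch["distance_value"][:] = 0.0
    np.add.at(ch["distance_value"], schedule.activity_samples[rep],
              schedule.activity_ms[rep] / 60_000.0 * 0.05)  # ~3 mph walk
    ch["energy_value"][:] = 0.0
    np.add.at(ch["energy_value"], schedule.activity_samples[rep],
              schedule.activity_ms[rep] / 60_000.0 * 5.0)   # ~5 kcal/min
    # smbg left missing in the clean rendering (added by corruption)
    for c in CHANNELS:
        if c != "smbg":
            prov[c][:] = PROV_OBSERVED

    # truth labels come from the FULL schedule, reported or not
    truth_series = series.copy()
    np.add.at(truth_series.channels["carbohydrate"],
              schedule.meal_samples[~schedule.meal_reported],
              schedule.meal_grams[~schedule.meal_reported])
    np.add.at(truth_series.channels["activity_duration"],
              schedule.activity_samples[~rep], schedule.activity_ms[~rep])
    truth = label_events(truth_series)

    return RenderedDataset(series=series, truth=truth, true_cgm=true_cgm,
                           true_ug=ug, true_pic=traj[:, STATE_I],
                           exercise_mask=exercise)


def corrupt_dataset(series: GriddedSeries, spec: CorruptionSpec | None = None,
                    seed: int = 0) -> tuple[GriddedSeries, dict]:
    """Inject realistic defects; every defect is recorded in the ledger."""
    spec = spec or CorruptionSpec()
    rng = np.random.default_rng(seed)
    out = series.copy()
    cgm = out.channels["cgm"]
    n = out.n
    ledger = {"gaps": [], "spikes": [], "duplicates": [], "smbg": []}

    # --- missing gaps until the target missing fraction is reached
    target_missing = int(spec.missing_rate * n)
    n_missing = 0
    guard = 0
    while n_missing < target_missing and guard < 10 * n:
        guard += 1
        start = int(rng.integers(0, n))
        if rng.random() < spec.long_gap_prob:
            length = int(rng.integers(*spec.long_gap_range))
        else:
            length = 1 + int(rng.geometric(1.0 / spec.gap_mean))
        stop = min(start + length, n)
        newly = np.sum(~np.isnan(cgm[start:stop]))
        if newly == 0:
            continue
        cgm[start:stop] = np.nan
        out.provenance["cgm"][start:stop] = 0
        n_missing += int(newly)
        ledger["gaps"].append({"start": start, "stop": int(stop)})

    # --- spikes violating the unexplained rise/drop rules
    cho = out.channels["carbohydrate"]
    bolus = out.channels["bolus"]
    ad = out.channels["activity_duration"]
    touched = set()
    for k in np.flatnonzero(rng.random(n) < spec.spike_rate):
        k = int(k)
        if k < 10 or np.isnan(cgm[k]) or np.isnan(cgm[k - 1]):
            continue
        if touched & {k - 1, k, k + 1}:
            continue  # keep defects isolated so each is attributable
        sign = 1 if rng.random() < 0.5 else -1
        mag = rng.uniform(*spec.spike_magnitude)
        new_val = cgm[k] + sign * mag
        d = new_val - cgm[k - 1]
        if d > 30.0:
            rejectable = bool(np.all(np.nan_to_num(cho[k - 9:k + 1], nan=0) == 0))
        elif d < -30.0:
            rejectable = bool(
                np.all(np.nan_to_num(bolus[k - 6:k + 1], nan=0) == 0)
                and np.all(np.nan_to_num(ad[k - 6:k + 1], nan=0) == 0))
        else:
            rejectable = False
        if new_val > 400.0 or new_val < 0.0:
            rejectable = True  # calibration-range rule
        cgm[k] = new_val
        touched.add(k)
        ledger["spikes"].append({"index": k, "delta": float(sign * mag),
                                 "rule_rejectable": rejectable})

    # --- stuck-sensor duplicates
    for k in np.flatnonzero(rng.random(n) < spec.duplicate_rate):
        k = int(k)
        if k == 0 or np.isnan(cgm[k]) or np.isnan(cgm[k - 1]) or k in touched:
            continue
        ledger["duplicates"].append({"index": k, "orig": float(cgm[k])})
        cgm[k] = cgm[k - 1]

    # --- scheduled fingersticks with bias; occasional discrepant ones
    smbg = out.channels["smbg"]
    per_sample = spec.smbg_per_day / SAMPLES_PER_DAY
    for k in np.flatnonzero(rng.random(n) < per_sample):
        if np.isnan(cgm[k]):
            continue
        if rng.random() < spec.smbg_outlier_prob:
            off = rng.uniform(25.0, 60.0) * (1 if rng.random() < 0.5 else -1)
        else:
            off = rng.normal(0.0, spec.smbg_bias_sd)
        smbg[k] = max(cgm[k] + off, 1.0)
        out.provenance["smbg"][k] = PROV_OBSERVED
        ledger["smbg"].append({"index": int(k), "offset": float(off)})

    return out, ledger


def generate_dataset(scenario: Scenario | None = None,
                     corruption: CorruptionSpec | None = None,
                     params: HovorkaParams | None = None, seed: int = 0):
    """Scenario -> rendering -> corruption; the standard entry point.

    Returns (corrupted series, rendered truth bundle, corruption ledger).
    """
    scenario = scenario or Scenario()
    sched = sample_scenario(scenario, seed=seed)
    rendered = render_dataset(sched, params=params, seed=seed + 1)
    corrupted, ledger = corrupt_dataset(rendered.series, corruption,
                                        seed=seed + 2)
    return corrupted, rendered, ledger
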