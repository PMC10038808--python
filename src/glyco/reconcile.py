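"""CGM signal reconciliation: rule-based outlier rejection and
singular-spectrum (Hankel/SVD) denoising.

Outlier rejection uses physiological prior knowledge instead of purely
statistical fences: a CGM sample is implausible when it leaves the
sensor calibration range, when it jumps more than 30 mg/dL in 5 minutes
with no recent carbohydrate intake to explain a rise (or no recent
bolus/activity to explain a drop), or when it disagrees with a
concurrent fingerstick measurement by more than 18 mg/dL.  A plain
Tukey-fence count (|z| > 2.72 SD) is reported as a diagnostic but never
used to delete samples: CGM is heavily skewed and fences would discard
genuine hypo-/hyperglycemia.

Denoising embeds each maximal run of consecutive CGM samples into a
Hankel matrix, truncates its SVD at 95% cumulative singular-value
energy (always retaining the leading component), and maps back by
anti-diagonal averaging (singular-spectrum analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hankel

from .io_grid import GriddedSeries, PROV_REJECTED

log = logging.getLogger("glyco")


@dataclass
class OutlierRules:
    """Thresholds of the rule-based CGM outlier rejection (mg/dL units)."""

    cal_max: float = 400.0
    cal_min: float = 0.0
    jump: float = 30.0
    smbg_tol: float = 18.0
    cho_window: int = 10      # samples k..k-9
    bolus_window: int = 7     # samples k..k-6
    activity_window: int = 7  # samples k..k-6


def _window_all_zero(x: np.ndarray, k: int, width: int) -> bool:
    """True when x is zero (or unrecorded) over samples k .. k-width+1."""
    lo = max(0, k - width + 1)
    w = x[lo: k + 1]
    return bool(np.all(np.nan_to_num(w, nan=0.0) == 0.0))


def reject_outliers(series: GriddedSeries,
                    rules: OutlierRules | None = None) -> tuple[GriddedSeries, dict]:
    """Set physiologically implausible CGM samples to missing.

    Rules (applied in-place, sequentially, as a single forward pass):
      (a) calibration range: CGM > 400 or CGM < 0 mg/dL;
      (b) unexplained rise: dCGM > 30 mg/dL per sample with no
          carbohydrate entry over the last 10 samples;
      (c) unexplained drop: dCGM < -30 mg/dL per sample with neither a
          bolus nor activity over the last 7 samples;
      (d) concurrent Smbg disagreement: |Smbg - CGM| > 18 mg/dL.
    dCGM is only evaluated where both operands are non-missing.  Sparse
    diary channels treat unrecorded (NaN) as zero.  Returns the cleaned
    series and a per-rule rejection report including the Tukey-fence
    diagnostic count (reported, never applied).
    """
    rules = rules or OutlierRules()
    out = series.copy()
    cgm = out.channels["cgm"]
    prov = out.provenance["cgm"]
    smbg = out.channels.get("smbg")
    cho = out.channels.get("carbohydrate")
    bolus = out.channels.get("bolus")
    ad = out.channels.get("activity_duration")
    n = out.n
    counts = {"calibration": 0, "rise": 0, "drop": 0, "smbg": 0}

    obs = ~np.isnan(cgm)
    mu = float(np.mean(cgm[obs])) if obs.any() else 0.0
    sd = float(np.std(cgm[obs])) if obs.any() else 0.0
    tukey = int(np.sum(np.abs(cgm[obs] - mu) > 2.72 * sd)) if sd > 0 else 0

    def reject(k: int, rule: str) -> None:
        cgm[k] = np.nan
        prov[k] = PROV_REJECTED
        counts[rule] += 1

    for k in range(n):
        if not np.isnan(cgm[k]) and (cgm[k] > rules.cal_max or cgm[k] < rules.cal_min):
            reject(k, "calibration")
    for k in range(1, n):
        if np.isnan(cgm[k]):
            continue
        if not np.isnan(cgm[k - 1]):
            d = cgm[k] - cgm[k - 1]
            if d > rules.jump and cho is not None and \
                    _window_all_zero(cho, k, rules.cho_window):
                reject(k, "rise")
                continue
            if d < -rules.jump and bolus is not None and ad is not None and \
                    _window_all_zero(bolus, k, rules.bolus_window) and \
                    _window_all_zero(ad, k, rules.activity_window):
                reject(k, "drop")
                continue
        if smbg is not None and not np.isnan(smbg[k]) and \
                abs(smbg[k] - cgm[k]) > rules.smbg_tol:
            reject(k, "smbg")

    report = {"rejected": counts, "tukey_fence_diagnostic": tukey,
              "n_samples": int(obs.sum())}
    return out, report


# ---------------------------------------------------------------------------
# Hankel / SSA denoising
# ---------------------------------------------------------------------------

@dataclass
class HankelSegment:
    """A maximal run of consecutive non-missing CGM samples with its
    Hankel embedding shape: p = floor(q/2) columns, w = q - p + 1 rows."""

    start: int
    values: np.ndarray

    @property
    def q(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.q // 2

    @property
    def w(self) -> int:
        return self.q - self.p + 1

    def matrix(self) -> np.ndarray:
        return hankel(self.values[: self.w], self.values[self.w - 1:])


def split_runs(series: GriddedSeries, channel: str = "cgm") -> list[HankelSegment]:
    """Maximal runs of consecutive non-missing samples of a channel."""
    x = series.channels[channel]
    ok = ~np.isnan(x)
    segs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(int)))
    for a, b in zip(idx[::2], idx[1::2]):
        segs.append(HankelSegment(start=int(a), values=x[a:b].copy()))
    return segs


def hankel_to_series(A: np.ndarray, q: int) -> np.ndarray:
    """Anti-diagonal averaging: invert the Hankel embedding."""
    w, p = A.shape
    out = np.zeros(q)
    cnt = np.zeros(q)
    for c in range(p):
        out[c: c + w] += A[:, c]
        cnt[c: c + w] += 1.0
    return out / cnt


def smooth_segment(seg: HankelSegment, energy_cut: float = 0.95) -> np.ndarray:
    """Truncated-SVD reconstruction of one run.

    Components are retained while the cumulative normalized singular-value
    spectrum stays <= ``energy_cut``; the leading component is always
    retained.  Runs shorter than 4 samples pass through unsmoothed.
    """
    if seg.q < 4:
        return seg.values.copy()
    A = seg.matrix()
    try:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError:
        log.warning("smooth_segment: SVD failed on run at %d; passed through", seg.start)
        return seg.values.copy()
    total = s.sum()
    if total <= 0:
        return seg.values.copy()
    eta = np.cumsum(s) / total
    # retain components until the cumulative spectrum reaches the cut,
    # including the component that crosses it (and always the first), so
    # exactly low-rank signals are reconstructed exactly
    keep = min(len(s), int(np.searchsorted(eta, energy_cut)) + 1)
    A_hat = (U[:, :keep] * s[:keep]) @ Vt[:keep]
    return hankel_to_series(A_hat, seg.q)


def denoise_cgm(series: GriddedSeries, energy_cut: float = 0.95) -> tuple[GriddedSeries, dict]:
    """SSA-denoise every CGM run; missing samples untouched."""
    out = series.copy()
    cgm = out.channels["cgm"]
    n_smoothed = 0
    var_removed = 0.0
    for seg in split_runs(out):
        sm = smooth_segment(seg, energy_cut=energy_cut)
        var_removed += float(np.sum((seg.values - sm) ** 2))
        if seg.q >= 4:
            n_smoothed += 1
        cgm[seg.start: seg.start + seg.q] = sm
    report = {"segments_smoothed": n_smoothed, "sum_sq_change": var_removed}
    return out, report
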