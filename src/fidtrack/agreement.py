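"""Agreement statistics between tracker output and human-coded behaviour.

Validation compares two aligned binary time series — e.g. detector presence
in the food ROI versus a human coder's frame-by-frame "eating" labels —
with two chance-aware statistics:

* **Intraclass correlation coefficient (ICC)**, computed from two-way ANOVA
  mean squares via the classical Shrout–Fleiss estimators.  Forms (1,1),
  (2,1) and (3,1) treat each time unit as a target rated by two "raters"
  (tracker and human); the (·,k) average-measure forms are also provided.
  The default is ICC(2,1): two-way random effects, absolute agreement,
  single measurement — the standard choice when a method is compared
  against a human rater drawn from a population of possible raters.
* **Cohen's kappa**, chance-corrected categorical agreement from the 2x2
  contingency table, with a large-sample z test of kappa = 0.

Degenerate inputs (both series constant, expected agreement 1) yield
reports flagged ``undefined`` rather than silent numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .analytics import PresenceSeries, frame_to_second

__all__ = [
    "AgreementReport",
    "align_series",
    "anova_mean_squares",
    "icc",
    "cohen_kappa",
    "table1_analysis",
    "load_coder_csv",
    "ICC_FORMS",
]

ICC_FORMS = ("1,1", "2,1", "3,1", "1,k", "2,k", "3,k")


@dataclass
class AgreementReport:
    """One agreement estimate with its test statistic and interval."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    stat_value: float
    p_value: float
    n: int
    series_a: str = "a"
    series_b: str = "b"
    defined: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "stat": self.stat_value, "p": self.p_value, "n": self.n,
            "a": self.series_a, "b": self.series_b, "defined": self.defined,
            "note": self.note,
        }


def _as_series(x) -> PresenceSeries:
    if isinstance(x, PresenceSeries):
        return x
    return PresenceSeries(subject=-1, roi=-1, resolution="frame",
                          values=np.asarray(x), start=0)


def align_series(a, b, resolution: str = "second") -> tuple[np.ndarray, np.ndarray, int]:
    """Resample two binary series to a common resolution and trim to overlap.

    Frame series are downsampled to seconds by the any-presence rule when
    the target resolution is "second".  Returns the paired equal-length
    arrays plus the common start offset.  Raises ``ValueError`` when the
    series do not overlap in time.
    """
    sa, sb = _as_series(a), _as_series(b)
    if resolution == "second":
        sa, sb = frame_to_second(sa), frame_to_second(sb)
    elif resolution == "frame":
        if sa.resolution != "frame" or sb.resolution != "frame":
            raise ValueError("cannot upsample a second series to frames")
    start = max(sa.start, sb.start)
    end = min(sa.start + len(sa.values), sb.start + len(sb.values))
    if end <= start:
        raise ValueError("series do not overlap in time")
    va = sa.values[start - sa.start:end - sa.start]
    vb = sb.values[start - sb.start:end - sb.start]
    return va, vb, start


def anova_mean_squares(ratings: np.ndarray) -> dict:
    """Two-way ANOVA mean squares for an n-targets x k-raters table.

    Returns MSR (between targets), MSC (between raters), MSE (residual) and
    MSW (within targets, for the one-way model), with n and k.
    """
    y = np.asarray(ratings, dtype=np.float64)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ((y - row_means[:, None]) ** 2).sum()
    return {
        "MSR": ss_rows / (n - 1),
        "MSC": ss_cols / (k - 1) if k > 1 else np.nan,
        "MSE": ss_err / ((n - 1) * (k - 1)) if k > 1 else np.nan,
        "MSW": ss_within / (n * (k - 1)) if k > 1 else np.nan,
        "n": n, "k": k,
    }


def icc(a, b=None, form: str = "2,1", alpha: float = 0.05,
        labels: tuple[str, str] = ("a", "b")) -> AgreementReport:
    """Intraclass correlation between paired ratings (Shrout–Fleiss).

    Accepts two equal-length 1-D series, or a single (n, k) ratings matrix
    as ``a``.  ``form`` is one of "1,1", "2,1", "3,1", "1,k", "2,k", "3,k".
    The p value comes from the corresponding F test; the confidence
    interval follows the classical F-based formulas.
    """
    if b is not None:
        va = np.asarray(a, dtype=float).ravel()
        vb = np.asarray(b, dtype=float).ravel()
        if len(va) != len(vb):
            raise ValueError("series must have equal length")
        y = np.column_stack([va, vb])
    else:
        y = np.asarray(a, dtype=float)
    n, k = y.shape
    if n < 2:
        raise ValueError("need at least 2 rated targets")
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; use one of {ICC_FORMS}")

    ms = anova_mean_squares(y)
    msr, msc, mse, msw = ms["MSR"], ms["MSC"], ms["MSE"], ms["MSW"]

    if np.allclose(y.std(axis=0), 0):
        return AgreementReport(statistic=f"ICC({form})", estimate=np.nan,
                               ci_low=np.nan, ci_high=np.nan,
                               stat_value=np.nan, p_value=np.nan, n=n,
                               series_a=labels[0], series_b=labels[1],
                               defined=False, note="both series constant")

    model, unit = form.split(",")
    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "1":
            est_single = (msr - msw) / (msr + (k - 1) * msw)
            f = msr / msw
            df1, df2 = n - 1, n * (k - 1)
        elif model == "2":
            est_single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            f = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
        else:  # consistency, mixed effects
            est_single = (msr - mse) / (msr + (k - 1) * mse)
            f = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)

        if unit == "1":
            est = est_single
        else:  # average of the k measurements
            if model == "1":
                est = (msr - msw) / msr
            elif model == "2":
                est = (msr - mse) / (msr + (msc - mse) / n)
            else:
                est = (msr - mse) / msr

    p = float(stats.f.sf(f, df1, df2))

    # F-based confidence bounds (exact for models 1 and 3; Shrout–Fleiss
    # approximation for model 2)
    if model in ("1", "3"):
        with np.errstate(invalid="ignore", divide="ignore"):
            fl = f / stats.f.isf(alpha / 2, df1, df2)
            fu = f * stats.f.isf(alpha / 2, df2, df1)
            if unit == "1":
                lo = (fl - 1) / (fl + (k - 1))
                hi = (fu - 1) / (fu + (k - 1))
            else:
                lo = 1 - 1 / fl
                hi = 1 - 1 / fu
        if not np.isfinite(lo):
            lo = 1.0 if not np.isfinite(f) else np.nan
        if not np.isfinite(hi):
            hi = 1.0 if not np.isfinite(f) else np.nan
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            fj = msc / mse
            vn = ((k - 1) * (n - 1) * (k * est_single * fj + n * (1 + (k - 1) * est_single)
                                      - k * est_single) ** 2)
            vd = ((n - 1) * k ** 2 * est_single ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * est_single) - k * est_single) ** 2)
            v = vn / vd if vd > 0 else np.nan
            f_star = stats.f.isf(alpha / 2, n - 1, v) if np.isfinite(v) else np.nan
            f_star2 = stats.f.isf(alpha / 2, v, n - 1) if np.isfinite(v) else np.nan
            fstat2 = msr / mse
            lo = (n * (msr - f_star * mse)
                  / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
                  ) if np.isfinite(f_star) else np.nan
            hi = (n * (f_star2 * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_star2 * msr)
                  ) if np.isfinite(f_star2) else np.nan
        if unit == "k":
            lo = k * lo / (1 + (k - 1) * lo) if np.isfinite(lo) else np.nan
            hi = k * hi / (1 + (k - 1) * hi) if np.isfinite(hi) else np.nan

    return AgreementReport(statistic=f"ICC({form})", estimate=float(est),
                           ci_low=float(lo), ci_high=float(hi),
                           stat_value=float(f), p_value=p, n=n,
                           series_a=labels[0], series_b=labels[1])


def cohen_kappa(a, b, alpha: float = 0.05,
                labels: tuple[str, str] = ("a", "b")) -> AgreementReport:
    """Cohen's kappa for two paired binary series, with a z test of zero.

    kappa = (p_o - p_e) / (1 - p_e) from the 2x2 contingency table; the
    null-hypothesis standard error follows Fleiss, Cohen & Everitt, giving
    z = kappa / se0.  Expected agreement of 1 (a degenerate table) yields an
    undefined, flagged report.
    """
    va = np.asarray(a).ravel().astype(int)
    vb = np.asarray(b).ravel().astype(int)
    if len(va) != len(vb):
        raise ValueError("series must have equal length")
    n = len(va)
    if n == 0:
        raise ValueError("empty input")
    cats = sorted(set(va) | set(vb))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k), dtype=float)
    for x, y in zip(va, vb):
        table[idx[x], idx[y]] += 1
    p = table / n
    p_o = float(np.trace(p))
    prow, pcol = p.sum(axis=1), p.sum(axis=0)
    p_e = float(prow @ pcol)
    if np.isclose(p_e, 1.0):
        return AgreementReport(statistic="kappa", estimate=np.nan,
                               ci_low=np.nan, ci_high=np.nan,
                               stat_value=np.nan, p_value=np.nan, n=n,
                               series_a=labels[0], series_b=labels[1],
                               defined=False,
                               note="expected agreement 1; kappa undefined")
    kap = (p_o - p_e) / (1 - p_e)
    # null-hypothesis SE for the z test of kappa = 0
    var0 = (p_e + p_e ** 2 - float(np.sum(prow * pcol * (prow + pcol)))) \
        / (n * (1 - p_e) ** 2)
    se0 = np.sqrt(max(var0, 0.0))
    z = kap / se0 if se0 > 0 else np.inf
    p_val = float(2 * stats.norm.sf(abs(z)))
    # large-sample SE for the confidence interval (Fleiss et al.)
    sum_term = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 if i == j else 0.0
            sum_term += p[i, j] * (w - (prow[i] + pcol[j]) * (1 - kap)) ** 2
    var_k = (sum_term - (kap - p_e * (1 - kap)) ** 2) / (n * (1 - p_e) ** 2)
    se = np.sqrt(max(var_k, 0.0))
    zc = stats.norm.isf(alpha / 2)
    return AgreementReport(statistic="kappa", estimate=float(kap),
                           ci_low=float(max(-1.0, kap - zc * se)),
                           ci_high=float(min(1.0, kap + zc * se)),
                           stat_value=float(z), p_value=p_val, n=n,
                           series_a=labels[0], series_b=labels[1])


# ---------------------------------------------------------------------------
# study-table analysis
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_MAP = {
    "unit": ("unit", "frame", "second", "index", "t"),
    "eating": ("eating", "eat"),
    "drinking": ("drinking", "drink"),
    "food_roi": ("food_roi", "food", "roi_food", "food_presence"),
    "water_roi": ("water_roi", "water", "roi_water", "water_presence"),
    "sniffing": ("sniffing", "sniff"),
}


def load_coder_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a human-coder CSV with tolerant column naming.

    The reader lower-cases headers and maps synonyms onto the canonical
    label set (unit, eating, drinking, food_roi, water_roi, sniffing); an
    explicit ``column_map`` of {canonical: actual} overrides the heuristics.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    out = {}
    cmap = column_map or {}
    for canon, synonyms in _DEFAULT_COLUMN_MAP.items():
        if canon in cmap:
            if cmap[canon] in df.columns:
                out[canon] = df[cmap[canon]]
            continue
        for s in synonyms:
            if s in df.columns:
                out[canon] = df[s]
                break
    if "unit" not in out:
        out["unit"] = pd.Series(np.arange(len(df)))
    return pd.DataFrame(out)


def _presence_from_log(log: pd.DataFrame, roi: int, subject: int | None,
                       resolution: str, n_frames: int | None,
                       rate: float) -> PresenceSeries:
    from .analytics import presence_series

    if subject is None:
        subjects = sorted(set(int(s) for s in log["id"])) if len(log) else []
        acc = None
        for s in subjects:
            ser = presence_series(log, s, roi, resolution="frame",
                                  rate=rate, n_frames=n_frames)
            acc = ser.values if acc is None else np.maximum(acc, ser.values)
        if acc is None:
            acc = np.zeros(n_frames or 0, dtype=np.uint8)
        ser = PresenceSeries(subject=-1, roi=roi, resolution="frame",
                             values=acc, start=0, rate=rate)
    else:
        ser = presence_series(log, subject, roi, resolution="frame",
                              rate=rate, n_frames=n_frames)
    return frame_to_second(ser) if resolution == "second" else ser


def table1_analysis(log: pd.DataFrame, coding: pd.DataFrame, arm: str,
                    food_roi: int = 1, water_roi: int = 2,
                    subject: int | None = None, rate: float = 30.0,
                    icc_form: str = "2,1",
                    corrected_interval: tuple[int, int] | None = None
                    ) -> pd.DataFrame:
    """Agreement table between a tracker log and human-coded behaviour.

    ``arm`` selects the study design: ``post_event`` (frame resolution;
    behaviour-vs-detection and ROI-presence-vs-detection comparisons),
    ``post_event_corrected`` (same, with the drinking/water comparisons
    restricted to ``corrected_interval`` — the span with proper resource
    placement), or ``real_time`` (second resolution; behaviour only).
    Each comparison is reported with both the requested ICC form and
    Cohen's kappa.
    """
    if arm not in ("post_event", "post_event_corrected", "real_time"):
        raise ValueError(f"unknown arm {arm!r}")
    resolution = "second" if arm == "real_time" else "frame"
    n_units = len(coding)
    n_frames = n_units if resolution == "frame" else None

    def coder(label):
        if label not in coding.columns:
            raise ValueError(f"coding lacks required label {label!r}")
        return np.asarray(coding[label], dtype=int)

    comparisons: list[tuple[str, np.ndarray, np.ndarray]] = []
    det_food = _presence_from_log(log, food_roi, subject, resolution,
                                  n_frames, rate).values
    det_water = _presence_from_log(log, water_roi, subject, resolution,
                                   n_frames, rate).values

    def paired(det, lab):
        hv = coder(lab)
        m = min(len(det), len(hv))
        return det[:m].astype(int), hv[:m]

    d, h = paired(det_food, "eating")
    comparisons.append(("eating_vs_food_detection", d, h))
    d, h = paired(det_water, "drinking")
    if arm == "post_event_corrected" and corrected_interval is not None:
        lo, hi = corrected_interval
        d, h = d[lo:hi], h[lo:hi]
    comparisons.append(("drinking_vs_water_detection", d, h))
    if arm in ("post_event", "post_event_corrected"):
        if "food_roi" in coding.columns:
            d, h = paired(det_food, "food_roi")
            comparisons.append(("food_roi_presence_vs_detection", d, h))
        if "water_roi" in coding.columns:
            d, h = paired(det_water, "water_roi")
            if arm == "post_event_corrected" and corrected_interval is not None:
                lo, hi = corrected_interval
                d, h = d[lo:hi], h[lo:hi]
            comparisons.append(("water_roi_presence_vs_detection", d, h))

    rows = []
    for name, det, human in comparisons:
        try:
            r_icc = icc(det, human, form=icc_form,
                        labels=("tracker", "human"))
        except ValueError as exc:
            r_icc = AgreementReport(statistic=f"ICC({icc_form})",
                                    estimate=np.nan, ci_low=np.nan,
                                    ci_high=np.nan, stat_value=np.nan,
                                    p_value=np.nan, n=len(det),
                                    defined=False, note=str(exc))
        r_kap = cohen_kappa(det, human, labels=("tracker", "human"))
        rows.append({"comparison": name, "n": len(det),
                     "icc_form": icc_form, "icc": r_icc.estimate,
                     "icc_p": r_icc.p_value, "kappa": r_kap.estimate,
                     "kappa_p": r_kap.p_value,
                     "defined": r_icc.defined and r_kap.defined})
    return pd.DataFrame(rows)
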