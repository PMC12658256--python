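"""Stress-challenge analyses: speed bins, fits, contrasts, welfare states.

This module assembles the derived biologger channels into the two
challenge analyses:

* the swimming challenge — records binned by the incremental flow-speed
  ladder (0.2-1.0 m/s, one hour per speed), speed-response fits
  (polynomial or exponential), and a signed correlation matrix across
  respirometry, kinematic and cardiac variables;
* the crowding challenge — phase labelling (basal, stress 1-4, recovery
  1-4, final recovery), per-phase summaries with mixed-model pairwise
  contrasts (individual as random intercept, family-wise adjustment via
  the studentized range, compact-letter grouping), and a four-state
  welfare classifier on baseline-relative heart rate, external
  acceleration and QRS amplitude.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import studentized_range
import statsmodels.api as sm

from .errors import ChannelMissing
from .specs import CrowdingSchedule
from .synthetic import crowding_phase_for_time

DEFAULT_SPEEDS = (0.2, 0.4, 0.6, 0.8, 1.0)


# ---------------------------------------------------------------------------
# swimming challenge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedSchedule:
    """The incremental-speed ladder: one step per speed, fixed duration."""

    speeds: tuple[float, ...] = DEFAULT_SPEEDS
    step_min: float = 60.0
    start_min: float = 0.0
    exclusion_min: float = 20.0  # flush + acclimation at each step's start

    def __post_init__(self) -> None:
        if self.step_min <= 0:
            raise ValueError("step_min must be > 0")


def aggregate_speed_bins(records: pd.DataFrame, schedule: SpeedSchedule
                         ) -> pd.DataFrame:
    """Assign each measurement to its flow-speed bin.

    ``records`` must have a ``time_min`` column.  Adds ``speed_mps``
    (NaN for records outside the schedule, returned but flagged via
    ``assigned``) and ``in_respiro_window`` (False during the flush +
    acclimation minutes at the start of each step; those records remain
    available for HR/ACC analyses but are excluded when aligning with
    respirometry).
    """
    out = records.copy()
    rel = (out["time_min"] - schedule.start_min) / schedule.step_min
    idx = np.floor(rel).astype(int)
    in_range = (rel >= 0) & (idx < len(schedule.speeds))
    speeds = np.full(len(out), np.nan)
    speeds[in_range] = np.asarray(schedule.speeds)[idx[in_range]]
    offset_min = (out["time_min"] - schedule.start_min
                  - idx * schedule.step_min)
    out["speed_mps"] = speeds
    out["assigned"] = in_range
    out["in_respiro_window"] = in_range & (offset_min >= schedule.exclusion_min)
    return out


@dataclass
class FitResult:
    """A speed-response fit with a signed coefficient of determination."""

    model: str  # "polynomial" | "exponential"
    coeffs: np.ndarray
    r_squared: float  # signed: sign of the speed trend
    p_value: float


def _signed_r2(x, y, fitted, n_params: int) -> tuple[float, float]:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = max(r2, 0.0)
    with np.errstate(invalid="ignore"):
        trend = np.corrcoef(x, fitted)[0, 1]
    sign = -1.0 if np.isfinite(trend) and trend < 0 else 1.0
    n = len(y)
    df_num = n_params - 1
    df_den = n - n_params
    if df_den <= 0 or ss_res <= 0 or r2 >= 1.0:
        p = 0.0 if r2 >= 1.0 else 1.0
    else:
        f = (r2 / df_num) / ((1 - r2) / df_den)
        p = float(stats.f.sf(f, df_num, df_den))
    return sign * r2, p


def fit_speed_response(x, y, model: str = "polynomial", degree: int = 1
                       ) -> FitResult:
    """Least-squares fit of a channel against flow speed.

    ``model`` is ``"polynomial"`` (with ``degree``) or ``"exponential"``
    (y = a * exp(b * x)).  The reported R^2 carries the sign of the
    fitted trend; the p-value is an F-test against the constant model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct speeds")
    if model == "polynomial":
        coeffs = np.polyfit(x, y, degree)
        fitted = np.polyval(coeffs, x)
        r2, p = _signed_r2(x, y, fitted, degree + 1)
        return FitResult("polynomial", coeffs, r2, p)
    if model == "exponential":
        # log-linear initial guess where possible
        if np.all(y > 0):
            b0, loga0 = np.polyfit(x, np.log(y), 1)
            p0 = (np.exp(loga0), b0)
        else:
            p0 = (max(np.mean(y), 1.0), 0.1)
        popt, _ = optimize.curve_fit(lambda u, a, b: a * np.exp(b * u),
                                     x, y, p0=p0, maxfev=20000)
        fitted = popt[0] * np.exp(popt[1] * x)
        r2, p = _signed_r2(x, y, fitted, 2)
        return FitResult("exponential", np.asarray(popt), r2, p)
    raise ValueError(f"unknown model family: {model!r}")


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with signed R^2 and p-values."""

    r: pd.DataFrame
    r2_signed: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # p < alpha; False where undefined
    constant_columns: list[str] = field(default_factory=list)


def correlation_matrix(df: pd.DataFrame, alpha: float = 0.05
                       ) -> CorrelationMatrix:
    """Pairwise Pearson r (sign retained), signed r^2 and p across columns.

    Constant columns yield undefined (NaN) correlations and are listed
    in ``constant_columns``; their pairs are marked non-significant.
    """
    cols = list(df.columns)
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    constant = [c for c in cols if np.nanstd(df[c].to_numpy(dtype=float)) == 0]
    for i, j in itertools.combinations(range(n), 2):
        xi = df[cols[i]].to_numpy(dtype=float)
        xj = df[cols[j]].to_numpy(dtype=float)
        ok = np.isfinite(xi) & np.isfinite(xj)
        if ok.sum() < 3 or cols[i] in constant or cols[j] in constant:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        rr, pp = stats.pearsonr(xi[ok], xj[ok])
        r[i, j] = r[j, i] = rr
        p[i, j] = p[j, i] = pp
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationMatrix(
        r=r_df,
        r2_signed=np.sign(r_df) * r_df ** 2,
        p=p_df,
        significant=(p_df < alpha).fillna(False),
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# mixed-model pairwise contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """All pairwise group contrasts with family-wise-adjusted p-values."""

    table: pd.DataFrame  # group_a, group_b, estimate, se, q, p_adj
    group_means: pd.Series
    model_kind: str  # "mixed" | "fixed"
    df_resid: float

    def p_matrix(self) -> pd.DataFrame:
        groups = list(self.group_means.index)
        m = pd.DataFrame(np.ones((len(groups), len(groups))),
                         index=groups, columns=groups)
        for _, row in self.table.iterrows():
            m.loc[row["group_a"], row["group_b"]] = row["p_adj"]
            m.loc[row["group_b"], row["group_a"]] = row["p_adj"]
        return m


def pairwise_contrasts(values, groups, individuals) -> ContrastResult:
    """Mixed-model pairwise group contrasts with Tukey-style adjustment.

    Fits ``value ~ group`` with a random intercept per individual
    (REML); every pairwise group difference is tested with the
    studentized-range distribution for family-wise error control.  When
    the random intercept is unidentifiable (fewer than two individuals,
    one observation per individual, or a singular fit) the model falls
    back to fixed effects with a warning — on a balanced one-way design
    this path reproduces the classical Tukey HSD exactly.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(groups),
        "individual": np.asarray(individuals),
    })
    levels = sorted(df["group"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    X = pd.get_dummies(df["group"], dtype=float)[levels]  # cell-means coding
    n = len(df)
    n_ind = df["individual"].nunique()

    use_mixed = n_ind >= 2 and n_ind < n
    result = None
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(df["value"], X, groups=df["individual"])
                result = model.fit(reml=True)
            if not np.all(np.isfinite(result.bse_fe)):
                result = None
        except Exception:
            result = None
    if result is not None:
        means = pd.Series(np.asarray(result.fe_params), index=levels)
        cov = np.asarray(result.cov_params())[:k, :k]
        df_resid = max(n - k - (n_ind - 1), 1)
        kind = "mixed"
    else:
        warnings.warn("random intercept unidentifiable or fit singular; "
                      "falling back to fixed effects", stacklevel=2)
        ols = sm.OLS(df["value"], X).fit()
        means = pd.Series(np.asarray(ols.params), index=levels)
        cov = np.asarray(ols.cov_params())
        df_resid = n - k
        kind = "fixed"

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means.iloc[i] - means.iloc[j]
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        q = abs(diff) / se * np.sqrt(2.0) if se > 0 else np.inf
        p_adj = float(studentized_range.sf(q, k, df_resid)) if np.isfinite(q) \
            else 0.0
        rows.append({"group_a": levels[i], "group_b": levels[j],
                     "estimate": diff, "se": se, "q": q,
                     "p_adj": min(p_adj, 1.0)})
    return ContrastResult(table=pd.DataFrame(rows), group_means=means,
                          model_kind=kind, df_resid=df_resid)


def compact_letters(p_matrix: pd.DataFrame, alpha: float = 0.05
                    ) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different.
    """
    groups = list(p_matrix.index)
    columns: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if p_matrix.loc[a, b] >= alpha:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb columns contained in others
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
        # drop duplicates
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: sorted(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


# ---------------------------------------------------------------------------
# crowding phases
# ---------------------------------------------------------------------------

def label_crowding_phases(timestamps, schedule: CrowdingSchedule | None = None
                          ) -> np.ndarray:
    """Phase label for each measurement time (minutes from midnight).

    Each measurement receives exactly one label among basal, stress_k,
    recovery_k, final_rec and uncategorized (the 0-2 h gap after the
    last event, which belongs to no named phase).  An empty schedule
    labels everything basal.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if schedule is None or len(schedule.stress_times) == 0:
        return np.full(timestamps.shape, "basal", dtype=object)
    return np.array([crowding_phase_for_time(t, schedule) for t in timestamps],
                    dtype=object)


def phase_summaries(records: pd.DataFrame, schedule: CrowdingSchedule,
                    alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-phase mean +/- SE and letter groups for each channel.

    ``records`` is the tidy crowding table (time_min, individual,
    channel, value).  Empty phases are omitted; ``uncategorized``
    measurements are excluded from the summaries.  Letters come from
    mixed-model pairwise contrasts; phases sharing a letter do not
    differ significantly.
    """
    labelled = records.copy()
    labelled["phase"] = label_crowding_phases(labelled["time_min"], schedule)
    labelled = labelled[labelled["phase"] != "uncategorized"]
    out = {}
    for channel, sub in labelled.groupby("channel"):
        summary = (sub.groupby("phase")["value"]
                   .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                        n="count")
                   .reset_index())
        contrasts = pairwise_contrasts(sub["value"], sub["phase"],
                                       sub["individual"])
        letters = compact_letters(contrasts.p_matrix(), alpha)
        summary["letters"] = summary["phase"].map(letters)
        out[channel] = summary
    return out


# ---------------------------------------------------------------------------
# welfare states
# ---------------------------------------------------------------------------

class WelfareState(str, Enum):
    RESTING = "resting"
    REGULAR_ACTIVITY = "regular_activity"
    REACTIVE_RESPONSE = "reactive_response"
    PROACTIVE_RESPONSE = "proactive_response"


@dataclass(frozen=True)
class WelfareThresholds:
    """Cutoffs separating low from high baseline-relative channels.

    Heart rate is expressed as a z-score against its baseline (high
    above 1.5 baseline SDs); acceleration and QRS amplitude as ratios to
    their baseline means (high above 2x).  All overridable.
    """

    hr_z_high: float = 1.5
    acc_ratio_high: float = 2.0
    amp_ratio_high: float = 2.0


@dataclass
class WelfareClassification:
    state: WelfareState
    score: float  # continuum score in (0, 1]; 1 = deep inside the state
    hr_high: bool
    acc_high: bool
    amp_high: bool


# state prototypes in (hr, acc, amp) high/low corner coordinates
_PROTOTYPES = {
    WelfareState.RESTING: (-1.0, -1.0, -1.0),
    WelfareState.REGULAR_ACTIVITY: (-1.0, 1.0, -1.0),
    WelfareState.REACTIVE_RESPONSE: (1.0, -1.0, -1.0),
    WelfareState.PROACTIVE_RESPONSE: (1.0, 1.0, 1.0),
}
_PRIORITY = list(_PROTOTYPES)  # deterministic tie-break order


def classify_welfare_state(
    hr_rel: float,
    acc_rel: float,
    amp_rel: float,
    thresholds: WelfareThresholds | None = None,
) -> WelfareClassification:
    """Map baseline-relative channels onto the four welfare states.

    Rules: low HR with low ACC is resting; low HR with high ACC is
    regular activity; high HR with low ACC and low AMP is a reactive
    (freezing-type) response; high HR with high AMP is a proactive
    response.  The remaining corner (high HR, high ACC, low AMP) and
    borderline values resolve to the nearest prototype in a normalized
    margin space, with a continuum score attached to every output.
    """
    thresholds = thresholds or WelfareThresholds()
    for name, v in (("hr_rel", hr_rel), ("acc_rel", acc_rel),
                    ("amp_rel", amp_rel)):
        if v is None or not np.isfinite(v):
            raise ChannelMissing(f"channel {name} is missing or not finite")
    hr_high = hr_rel > thresholds.hr_z_high
    acc_high = acc_rel > thresholds.acc_ratio_high
    amp_high = amp_rel > thresholds.amp_ratio_high

    if not hr_high:
        state = WelfareState.REGULAR_ACTIVITY if acc_high else WelfareState.RESTING
    elif amp_high:
        state = WelfareState.PROACTIVE_RESPONSE
    elif not acc_high:
        state = WelfareState.REACTIVE_RESPONSE
    else:
        state = None  # high HR, high ACC, low AMP -> nearest prototype

    # continuum coordinates: signed margins squashed to (-1, 1)
    coords = (
        float(np.tanh(hr_rel - thresholds.hr_z_high)),
        float(np.tanh(acc_rel - thresholds.acc_ratio_high)),
        float(np.tanh(amp_rel - thresholds.amp_ratio_high)),
    )
    dists = {
        s: float(np.linalg.norm(np.subtract(coords, proto)))
        for s, proto in _PROTOTYPES.items()
    }
    if state is None:
        best = min(dists.values())
        state = next(s for s in _PRIORITY if dists[s] == best)
    score = 1.0 / (1.0 + dists[state])
    return WelfareClassification(state=state, score=score, hr_high=hr_high,
                                 acc_high=acc_high, amp_high=amp_high)


def classify_welfare_timeline(df: pd.DataFrame,
                              thresholds: WelfareThresholds | None = None
                              ) -> pd.DataFrame:
    """Classify every row of a frame with hr_rel/acc_rel/amp_rel columns."""
    for col in ("hr_rel", "acc_rel", "amp_rel"):
        if col not in df.columns:
            raise ChannelMissing(f"channel {col} is missing from the input")
    out = df.copy()
    results = [classify_welfare_state(r.hr_rel, r.acc_rel, r.amp_rel, thresholds)
               for r in df.itertuples()]
    out["state"] = [r.state.value for r in results]
    out["score"] = [r.score for r in results]
    return out
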