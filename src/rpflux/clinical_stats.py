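"""Cohort-level clinical and dosimetric statistics.

Covers the association analysis between clinical/dosimetric covariates and
pneumonitis outcome (control-mean dichotomization, Pearson chi-square
without continuity correction), the rank statistics used to compare
predicted and observed outcomes (Mann-Whitney U, Spearman rho, rank AUC,
exact-binomial agreement), Cox proportional-hazards fits (lifelines, Efron
ties) and cumulative incidence curves (1 - Kaplan-Meier).

Clinical tables are plain CSV with one row per patient; see
``read_clinical_csv`` for the column contract.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DegenerateInputError, DomainError

try:  # lifelines pulls in matplotlib; keep import cost at module load
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.exceptions import ConvergenceError
except Exception as _exc:  # pragma: no cover
    CoxPHFitter = None
    _LIFELINES_ERR = _exc

__all__ = [
    "CohortTable",
    "ContingencyTable",
    "ChiSquareResult",
    "read_clinical_csv",
    "write_clinical_csv",
    "dichotomize_at_control_mean",
    "pearson_chi_square",
    "chi_square_pvalue",
    "mann_whitney_u",
    "spearman_rho",
    "roc_auc",
    "agreement",
    "fit_cox_ph",
    "cumulative_incidence",
    "build_association_tables",
    "evaluate_predictions",
    "EVENT_DEFINITIONS",
    "AGE_BANDS",
]

logger = logging.getLogger(__name__)

#: outcome splits mirroring the three association tables
EVENT_DEFINITIONS = {"rp_ge1": 1, "rp_ge2": 2, "rp_ge3": 3}

SEX_LEVELS = ("male", "female")
PATHOLOGY_LEVELS = ("SCLC", "adeno", "squamous", "other")
STAGE_LEVELS = ("I", "II", "III", "IV")
AGE_BANDS = ("<50", "50-59", "60-69", "70-79", ">=80")

CLINICAL_COLUMNS = [
    "sample_id", "sex", "age", "smoking", "chemotherapy", "pathology",
    "stage", "dose_gy", "v5", "v10", "v20", "v30", "rp_grade",
    "time_to_rp_days", "followup_days",
]
DOSIMETRIC_COLUMNS = ["dose_gy", "v5", "v10", "v20", "v30"]


def age_band(age: float) -> str:
    """Decade band used by the association tables."""
    if age < 50:
        return "<50"
    if age >= 80:
        return ">=80"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


@dataclass
class CohortTable:
    """Validated per-patient clinical table.

    ``df`` holds one row per patient with the columns of
    ``CLINICAL_COLUMNS``; dosimetric columns may be entirely absent (NaN)
    when only categorical covariates are known.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ContractError(f"clinical table lacks column(s): {missing}")
        if df["sample_id"].duplicated().any():
            raise ContractError("duplicate sample ids in clinical table")
        if not df["sex"].isin(SEX_LEVELS).all():
            raise ContractError(f"sex must be one of {SEX_LEVELS}")
        if not df["pathology"].isin(PATHOLOGY_LEVELS).all():
            raise ContractError(f"pathology must be one of {PATHOLOGY_LEVELS}")
        if not df["stage"].isin(STAGE_LEVELS).all():
            raise ContractError(f"stage must be one of {STAGE_LEVELS}")
        grades = df["rp_grade"]
        if not grades.between(0, 4).all():
            raise ContractError("rp_grade outside 0-4")
        has_time = df["time_to_rp_days"].notna()
        if not (has_time == (grades >= 1)).all():
            raise ContractError(
                "time_to_rp_days must be present exactly for patients with "
                "rp_grade >= 1"
            )
        both = has_time & df["followup_days"].notna()
        if (df.loc[both, "followup_days"] < df.loc[both, "time_to_rp_days"]).any():
            raise ContractError("followup_days < time_to_rp_days")

    def __len__(self) -> int:
        return len(self.df)

    def event_indicator(self, event: str) -> pd.Series:
        """Boolean per patient for an event definition (rp_ge1/2/3)."""
        if event not in EVENT_DEFINITIONS:
            raise DomainError(f"unknown event definition {event!r}")
        return self.df["rp_grade"] >= EVENT_DEFINITIONS[event]

    def survival_frame(self, event: str) -> pd.DataFrame:
        """duration/event columns: time-to-RP for events, follow-up otherwise."""
        ev = self.event_indicator(event)
        duration = self.df["time_to_rp_days"].where(ev, self.df["followup_days"])
        return pd.DataFrame(
            {"duration": duration.astype(float), "event": ev.astype(int)},
            index=self.df.index,
        )


def read_clinical_csv(path) -> CohortTable:
    df = pd.read_csv(path)
    if df.empty:
        raise ContractError(f"{path}: empty clinical table")
    for col in ("smoking", "chemotherapy"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
        df[col] = df[col].astype(bool)
    return CohortTable(df)


def write_clinical_csv(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# dichotomization and chi-square

def dichotomize_at_control_mean(
    values, control_mask, round_dp: int = 2
) -> tuple[float, np.ndarray]:
    """Split a continuous covariate at the control-group mean.

    The threshold is the mean over the control patients, rounded to
    ``round_dp`` decimals; patients at or above the threshold form the upper
    group (labels ``at_or_above`` / ``below``), matching the inclusive
    ">= threshold" convention of the association tables.
    """
    values = np.asarray(values, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if values.shape != control_mask.shape:
        raise ContractError("values and control_mask differ in length")
    if not control_mask.any():
        raise DegenerateInputError("empty control group")
    threshold = round(float(values[control_mask].mean()), round_dp)
    groups = np.where(values >= threshold, "at_or_above", "below")
    return threshold, groups


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ContractError("counts shape does not match labels")
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ContractError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        counts = np.asarray(counts, dtype=float)
        rl = tuple(row_labels) if row_labels is not None else tuple(
            f"r{i}" for i in range(counts.shape[0])
        )
        cl = tuple(col_labels) if col_labels is not None else tuple(
            f"c{j}" for j in range(counts.shape[1])
        )
        return cls(rl, cl, counts)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    Rows whose total is zero are dropped before computing (rows that are
    zero in one column only are retained); df = (r-1)(c-1) on the retained
    rows.  An expected count of exactly zero after row-dropping (an all-zero
    column) is a degenerate input.
    """
    counts = np.asarray(table.counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateInputError(
            "contingency table needs >=2 non-empty rows and >=2 columns"
        )
    total = counts.sum()
    if total < 1:
        raise DegenerateInputError("empty contingency table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    if (expected == 0).any():
        raise DegenerateInputError("expected count of exactly 0 (all-zero column)")
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return ChiSquareResult(statistic=statistic, df=df,
                           p_value=chi_square_pvalue(statistic, df))


def chi_square_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    if statistic < 0:
        raise DomainError(f"chi-square statistic must be >= 0, got {statistic}")
    return float(sps.chi2.sf(statistic, df))


# ---------------------------------------------------------------------------
# rank statistics

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #(a < b) + 0.5 * #(a == b) over all cross pairs."""
    a = a[:, None]
    return float((a < b).sum() + 0.5 * (a == b).sum())


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (pairs favoring ``group_b``) and two-sided p.

    ``exact`` enumerates every split of the pooled sample (tie-safe);
    ``normal_approx`` uses the tie-corrected normal approximation with
    continuity correction; ``auto`` picks exact when n_a + n_b <= 12.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise DomainError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if a.size + b.size <= 12 else "normal_approx"
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    mean_u = n1 * n2 / 2.0

    if mode == "exact":
        pooled = np.concatenate([a, b])
        idx = range(pooled.size)
        deviations = []
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            deviations.append(abs(_u_statistic(pooled[mask], pooled[~mask]) - mean_u))
        deviations = np.asarray(deviations)
        p = float((deviations >= abs(u - mean_u) - 1e-12).mean())
        return u, p

    pooled = np.concatenate([a, b])
    n = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:  # all observations identical
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return u, float(2 * sps.norm.sf(z))


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Pearson correlation of mid-ranks (tie-aware Spearman rho)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ContractError("x and y differ in length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + half-ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise ContractError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present")
    return _u_statistic(scores[~labels], scores[labels]) / (n_pos * n_neg)


def agreement(predicted, observed) -> tuple[float, tuple[float, float]]:
    """Proportion of exact class matches with Clopper-Pearson 95% CI."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.size != observed.size:
        raise ContractError("predicted and observed differ in length")
    if predicted.size == 0:
        raise DegenerateInputError("empty class vectors")
    n = predicted.size
    k = int((predicted == observed).sum())
    lo = 0.0 if k == 0 else float(sps.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(0.975, k + 1, n - k))
    return k / n, (lo, hi)


# ---------------------------------------------------------------------------
# survival analysis

def fit_cox_ph(
    cohort: CohortTable,
    covariates: list[str],
    event: str = "rp_ge1",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Time is time-to-RP for events and follow-up time for censored patients.
    Returns one row per covariate: coef, hazard_ratio, p, flag.  Constant
    covariates are flagged ``non_identifiable`` (coef 0) without fitting;
    separation / non-convergence is flagged, never silently returned.
    """
    if CoxPHFitter is None:  # pragma: no cover
        raise ImportError(f"lifelines unavailable: {_LIFELINES_ERR}")
    surv = cohort.survival_frame(event)
    if surv["event"].sum() == 0:
        raise DegenerateInputError(f"no events under definition {event!r}")
    missing = [c for c in covariates if c not in cohort.df.columns]
    if missing:
        raise ContractError(f"unknown covariate(s): {missing}")

    rows = []
    fit_cols = []
    for cov in covariates:
        x = pd.to_numeric(cohort.df[cov], errors="raise").astype(float)
        if x.nunique() <= 1:
            rows.append({"covariate": cov, "coef": 0.0, "hazard_ratio": 1.0,
                         "p": float("nan"), "flag": "non_identifiable"})
        else:
            fit_cols.append(cov)
    if fit_cols:
        data = pd.concat(
            [surv.reset_index(drop=True),
             cohort.df[fit_cols].astype(float).reset_index(drop=True)],
            axis=1,
        )
        cph = CoxPHFitter()
        flag = ""
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cph.fit(data, duration_col="duration", event_col="event")
            except ConvergenceError:
                flag = "non_converged"
            if any("convergence" in str(w.message).lower()
                   or "complete separation" in str(w.message).lower()
                   for w in caught):
                flag = flag or "separation_suspect"
        if flag == "non_converged":
            for cov in fit_cols:
                rows.append({"covariate": cov, "coef": float("nan"),
                             "hazard_ratio": float("nan"), "p": float("nan"),
                             "flag": flag})
        else:
            summary = cph.summary
            for cov in fit_cols:
                coef = float(summary.loc[cov, "coef"])
                cov_flag = flag
                if abs(coef) > 10:  # monotone likelihood escape
                    cov_flag = "separation_suspect"
                rows.append({"covariate": cov, "coef": coef,
                             "hazard_ratio": float(summary.loc[cov, "exp(coef)"]),
                             "p": float(summary.loc[cov, "p"]), "flag": cov_flag})
    out = pd.DataFrame(rows, columns=["covariate", "coef", "hazard_ratio", "p", "flag"])
    return out.set_index("covariate").loc[covariates].reset_index()


def cumulative_incidence(
    cohort: CohortTable,
    strata,
    event: str = "rp_ge1",
    horizon_days: float = 90.0,
) -> dict[str, pd.DataFrame]:
    """Per-stratum cumulative incidence, 1 - Kaplan-Meier survival.

    ``strata`` is a per-patient label vector aligned with the cohort.
    Curves are step functions on the pooled event-time grid up to the
    horizon, starting at 0; empty strata are omitted with a warning.
    """
    strata = pd.Series(np.asarray(strata), index=cohort.df.index)
    surv = cohort.survival_frame(event)
    event_times = np.unique(
        surv.loc[(surv["event"] == 1) & (surv["duration"] <= horizon_days), "duration"]
    )
    grid = np.concatenate([[0.0], event_times])
    out: dict[str, pd.DataFrame] = {}
    for label in sorted(pd.unique(strata).astype(str)):
        mask = strata.astype(str) == label
        if not mask.any():
            logger.warning("stratum %r is empty; omitted", label)
            continue
        km = KaplanMeierFitter()
        km.fit(surv.loc[mask, "duration"], surv.loc[mask, "event"], timeline=grid)
        inc = 1.0 - km.survival_function_.iloc[:, 0].to_numpy()
        out[label] = pd.DataFrame({"time": grid, "incidence": inc})
    return out


# ---------------------------------------------------------------------------
# association tables

_CATEGORICAL_SPECS = [
    ("sex", SEX_LEVELS, lambda df: df["sex"]),
    ("age", AGE_BANDS, lambda df: df["age"].map(age_band)),
    ("smoking", ("yes", "no"), lambda df: df["smoking"].map({True: "yes", False: "no"})),
    ("chemotherapy", ("yes", "no"),
     lambda df: df["chemotherapy"].map({True: "yes", False: "no"})),
    ("pathology", PATHOLOGY_LEVELS, lambda df: df["pathology"]),
    ("stage", STAGE_LEVELS, lambda df: df["stage"]),
]


def _crosstab(levels, values, case_mask) -> ContingencyTable:
    values = pd.Series(np.asarray(values))
    counts = []
    kept_levels = []
    for lev in levels:
        in_level = (values == lev).to_numpy()
        row = [int((in_level & case_mask).sum()), int((in_level & ~case_mask).sum())]
        if sum(row) > 0:
            counts.append(row)
            kept_levels.append(lev)
    return ContingencyTable.from_counts(
        counts, row_labels=kept_levels, col_labels=("case", "control")
    )


def build_association_tables(cohort: CohortTable) -> dict[str, pd.DataFrame]:
    """Chi-square association tables for the three outcome splits.

    For each split (grade >=1 / >=2 / >=3 versus below), categorical
    covariates are cross-tabulated directly and dosimetric covariates are
    first dichotomized at that split's control-group mean.  Dosimetric
    covariates that are entirely absent (NaN) are skipped.  Output: one
    DataFrame per split with covariate, level, n_case, n_control, chi2, df, p.
    """
    if len(cohort) == 0:
        raise DegenerateInputError("empty cohort")
    out: dict[str, pd.DataFrame] = {}
    for event in EVENT_DEFINITIONS:
        case = cohort.event_indicator(event).to_numpy()
        if case.all() or not case.any():
            raise DegenerateInputError(
                f"degenerate split for {event!r}: one outcome group is empty"
            )
        rows = []

        def add(covariate: str, table: ContingencyTable, level_suffix=None):
            res = pearson_chi_square(table)
            for i, lev in enumerate(table.row_labels):
                rows.append({
                    "covariate": covariate,
                    "level": lev if level_suffix is None else level_suffix[i],
                    "n_case": int(table.counts[i, 0]),
                    "n_control": int(table.counts[i, 1]),
                    "chi2": res.statistic, "df": res.df, "p": res.p_value,
                })

        for name, levels, getter in _CATEGORICAL_SPECS:
            add(name, _crosstab(levels, getter(cohort.df), case))

        for col in DOSIMETRIC_COLUMNS:
            values = cohort.df[col]
            if values.isna().all():
                continue
            if values.isna().any():
                raise ContractError(f"column {col!r} has partial missingness")
            threshold, groups = dichotomize_at_control_mean(
                values.to_numpy(), ~case
            )
            table = _crosstab(("below", "at_or_above"), groups, case)
            add(col, table,
                level_suffix=[f"<{threshold:g}" if l == "below" else f">={threshold:g}"
                              for l in table.row_labels])
        out[event] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# predicted-vs-observed evaluation

def evaluate_predictions(scores: pd.DataFrame, cohort: CohortTable) -> dict:
    """Juxtapose predicted severity classes with observed RP outcomes.

    Returns agreement proportion with exact 95% CI, Spearman rho between the
    predicted class ordinal and the observed grade, a two-sided Mann-Whitney
    p between the predicted and observed severity distributions, and the
    rank AUC of the continuous score against RP occurrence (grade >= 1).
    """
    from .rp_scoring import CLASS_ORDER, observed_class

    s_ids = set(scores["sample_id"].astype(str))
    c_ids = set(cohort.df["sample_id"].astype(str))
    if s_ids != c_ids:
        raise ContractError(
            f"sample id mismatch; only in scores: {sorted(s_ids - c_ids)}, "
            f"only in clinical: {sorted(c_ids - s_ids)}"
        )
    sc = scores.copy()
    sc["sample_id"] = sc["sample_id"].astype(str)
    cl = cohort.df.copy()
    cl["sample_id"] = cl["sample_id"].astype(str)
    merged = sc.merge(cl, on="sample_id").sort_values("sample_id")

    ordinal = {c: i for i, c in enumerate(CLASS_ORDER)}
    pred_class = merged["predicted_class"].to_numpy()
    obs_class = merged["rp_grade"].map(observed_class).to_numpy()
    pred_ord = np.array([ordinal[c] for c in pred_class], dtype=float)
    obs_ord = np.array([ordinal[c] for c in obs_class], dtype=float)

    prop, ci = agreement(pred_class, obs_class)
    occurred = (merged["rp_grade"] >= 1).to_numpy()
    result = {
        "n": int(len(merged)),
        "agreement": prop,
        "agreement_ci95": list(ci),
        "spearman_rho": (
            spearman_rho(pred_ord, merged["rp_grade"].to_numpy())
            if np.ptp(pred_ord) > 0 and merged["rp_grade"].nunique() > 1
            else float("nan")
        ),
        "spearman_rho_s_grade": (
            spearman_rho(merged["s_value"].to_numpy(), merged["rp_grade"].to_numpy())
            if merged["rp_grade"].nunique() > 1 and merged["s_value"].nunique() > 1
            else float("nan")
        ),
        "mann_whitney_p": mann_whitney_u(pred_ord, obs_ord, mode="normal_approx")[1],
        "auc_s_vs_rp": (
            roc_auc(merged["s_value"].to_numpy(), occurred)
            if 0 < occurred.sum() < len(merged) else float("nan")
        ),
    }
    return result
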