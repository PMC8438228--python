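"""RP score S and severity classification.

For each pathway, S = log2(F_treat / F_control), where both fluxes are
floored at a small epsilon so the ratio is defined for non-positive fluxes
(both floored means S = 0).  The patient-level score is the arithmetic mean
of S over the RP-relevant pathways (all pathways when none is flagged).

Classification: S <= 0 predicts no pneumonitis; 0 < S < theta predicts a
low-grade event (grade <= 2); S >= theta predicts a severe event
(grade >= 3).  theta is a configurable cutoff, default 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ContractError, DomainError
from .flux_engine import (
    ExpressionProfile,
    PathwayFluxResult,
    all_pathway_fluxes,
    normalize_expression,
    simulate_irradiation_state,
)
from .signaling_map import SignalingMap

__all__ = [
    "CLASS_NONE",
    "CLASS_LE2",
    "CLASS_GE3",
    "CLASS_ORDER",
    "RPScore",
    "pathway_s",
    "patient_score",
    "classify_rp",
    "cohort_scores",
    "observed_class",
    "write_scores_tsv",
    "read_scores_tsv",
]

CLASS_NONE = "none"
CLASS_LE2 = "grade_le2"
CLASS_GE3 = "grade_ge3"
#: severity-ordered classes; index = ordinal used in rank statistics
CLASS_ORDER = (CLASS_NONE, CLASS_LE2, CLASS_GE3)

DEFAULT_EPSILON = 1e-6
DEFAULT_THETA = 0.8
DEFAULT_D0 = 50.0


@dataclass(frozen=True)
class RPScore:
    sample_id: str
    per_pathway_s: dict[str, float]
    s_value: float
    predicted_class: str | None = None


def pathway_s(f_treat: float, f_control: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2 ratio of treat to control flux, floored at epsilon.

    Total on all real inputs: non-positive fluxes are floored, so e.g.
    both-negative fluxes give S = 0.
    """
    if epsilon <= 0:
        raise DomainError(f"epsilon must be positive, got {epsilon}")
    return math.log2(max(f_treat, epsilon) / max(f_control, epsilon))


def patient_score(
    treat_fluxes: dict[str, PathwayFluxResult],
    control_fluxes: dict[str, PathwayFluxResult],
    smap: SignalingMap,
    epsilon: float = DEFAULT_EPSILON,
    sample_id: str = "",
) -> RPScore:
    """Aggregate per-pathway S into one patient-level score (class unset).

    Uses net fluxes of the RP-relevant pathways; falls back to all pathways
    when the map flags none as RP-relevant.
    """
    if set(treat_fluxes) != set(control_fluxes):
        raise ContractError(
            "treat/control flux sets cover different pathways: "
            f"{sorted(set(treat_fluxes) ^ set(control_fluxes))}"
        )
    relevant = [p.pathway_id for p in smap.pathways if p.rp_relevant]
    if not relevant:
        relevant = [p.pathway_id for p in smap.pathways]
    per = {
        pid: pathway_s(treat_fluxes[pid].net_flux, control_fluxes[pid].net_flux, epsilon)
        for pid in relevant
    }
    s = sum(per.values()) / len(per)
    return RPScore(sample_id=sample_id, per_pathway_s=per, s_value=s)


def classify_rp(s_value: float, theta: float = DEFAULT_THETA) -> str:
    """Severity class from the patient score: none / grade_le2 / grade_ge3."""
    if not math.isfinite(s_value):
        raise DomainError(f"non-finite score {s_value}")
    if theta <= 0:
        raise DomainError(f"theta must be positive, got {theta}")
    if s_value <= 0:
        return CLASS_NONE
    if s_value >= theta:
        return CLASS_GE3
    return CLASS_LE2


def observed_class(rp_grade: int) -> str:
    """Map an observed RTOG grade (0-4) onto the predicted-class vocabulary."""
    if rp_grade <= 0:
        return CLASS_NONE
    return CLASS_GE3 if rp_grade >= 3 else CLASS_LE2


def cohort_scores(
    expression: pd.DataFrame,
    smap: SignalingMap,
    doses: dict[str, float],
    *,
    epsilon: float = DEFAULT_EPSILON,
    theta: float = DEFAULT_THETA,
    d0: float = DEFAULT_D0,
    normalization: str = "none",
) -> pd.DataFrame:
    """Score every sample of a genes x samples matrix.

    The measured profile is the control state; the treat state is the
    deterministic irradiation surrogate at the patient's own dose.  Output
    rows are sorted by sample id; columns are sample_id, s_value,
    predicted_class, then one ``s_<pathway>`` column per scored pathway.
    """
    samples = [str(c) for c in expression.columns]
    missing = sorted(set(samples) - set(doses))
    if missing:
        raise ContractError(f"no dose entry for sample(s): {', '.join(missing)}")

    rows = []
    for sample in sorted(samples):
        profile = ExpressionProfile(
            sample_id=sample, values=expression[sample].to_dict()
        )
        profile = normalize_expression(profile, normalization)
        control = all_pathway_fluxes(profile, smap)
        treated = simulate_irradiation_state(profile, smap, doses[sample], d0)
        treat = all_pathway_fluxes(treated, smap)
        score = patient_score(treat, control, smap, epsilon, sample_id=sample)
        row = {"sample_id": sample, "s_value": score.s_value,
               "predicted_class": classify_rp(score.s_value, theta)}
        row.update({f"s_{pid}": v for pid, v in score.per_pathway_s.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
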