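"""Survival stratification of bulk cohorts by signature score.

Bulk samples are scored for a metaprogram's top-30 gene signature with the
same control-gene-matched SC formula used for single cells (the bulk matrix is
log-transformed and gene-centered across samples, with aggregate expression
computed from the bulk TPM).  Scores are dichotomized into high/low groups —
by 1-D Ward clustering by default, or a median split — and the groups are
compared with Kaplan-Meier estimates and a two-sample log-rank test.

Multivariable Cox modelling is out of scope; :func:`covariate_table` formats a
cohort for external Cox tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

from .matrix import ExpressionMatrix, require_scale
from .preprocess import aggregate_expression, center_expression, log_transform
from .scoring import build_control_sets, score_cells


@dataclass
class KMResult:
    """Two-group Kaplan-Meier curves with the log-rank comparison.

    ``curves`` maps group name -> DataFrame(time, at_risk, events, survival);
    ``statistic`` is the log-rank chi-square (1 df), ``p_value`` its p.
    """

    curves: dict[str, pd.DataFrame]
    statistic: float
    p_value: float


def score_bulk(
    bulk: ExpressionMatrix, signature: list[str], n_control: int = 100
) -> pd.Series:
    """Per-sample SC score of a signature on a bulk TPM matrix.

    Requires at least half the signature genes to be present.  Samples are
    treated exactly as cells are in single-cell scoring, so the code path is
    shared.
    """
    require_scale(bulk, "tpm")
    present = [g for g in signature if g in bulk.gene_ids]
    if len(present) < 0.5 * len(signature):
        raise ValueError(
            f"only {len(present)}/{len(signature)} signature genes present in bulk matrix"
        )
    ea = aggregate_expression(bulk)
    er = center_expression(log_transform(bulk), by_group=False)
    ctrl = build_control_sets(ea, present, n_control=n_control)
    return score_cells(er, present, ctrl).rename("score")


def dichotomize(scores: pd.Series, method: str = "two_cluster") -> pd.Series:
    """Split samples into 'high' and 'low' score groups.

    ``two_cluster``: Ward linkage on the 1-D scores cut into two clusters, the
    cluster with the larger mean labeled high.  ``median``: samples strictly
    above the median are high.  Labels are invariant to adding a constant.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    if scores.nunique() == 1:
        raise ValueError("all scores identical")
    if method == "two_cluster":
        lab = fcluster(
            linkage(scores.to_numpy()[:, None], method="ward"), t=2, criterion="maxclust"
        )
        lab = pd.Series(lab, index=scores.index)
        means = scores.groupby(lab).mean()
        high_cluster = means.idxmax()
        out = lab.map(lambda c: "high" if c == high_cluster else "low")
    elif method == "median":
        out = pd.Series(
            np.where(scores > scores.median(), "high", "low"), index=scores.index
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return out.rename("group")


def km_logrank(
    time: pd.Series, event: pd.Series, group: pd.Series
) -> KMResult:
    """Kaplan-Meier curves per group and the two-sample log-rank test."""
    groups = sorted(group.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if event.sum() < 1:
        raise ValueError("need at least one event")

    curves = {}
    for g in groups:
        mask = group == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
                "events": tab["observed"].to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy(),
            }
        )

    m0, m1 = (group == groups[0]), (group == groups[1])
    res = logrank_test(time[m0], time[m1], event_observed_A=event[m0], event_observed_B=event[m1])
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def stratify_cohort(
    bulk: ExpressionMatrix,
    signature: list[str],
    time: pd.Series,
    event: pd.Series,
    method: str = "two_cluster",
) -> tuple[pd.DataFrame, KMResult]:
    """Score -> dichotomize -> log-rank, returning the cohort table and test."""
    scores = score_bulk(bulk, signature)
    group = dichotomize(scores, method=method)
    cohort = pd.DataFrame(
        {"score": scores, "group": group, "time": time, "event": event}
    )
    return cohort, km_logrank(cohort["time"], cohort["event"], cohort["group"])


def covariate_table(
    cohort: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort formatted for external Cox tooling (sample, time, event, group, ...)."""
    out = cohort[["time", "event", "group", "score"]].copy()
    if covariates is not None:
        out = out.join(covariates)
    return out
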