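"""Group comparison and motor-score correlation of efficiency measures.

Whole-brain global and local efficiency are compared between patients and
controls with a classical (pooled-variance) Student t-test, and related to
the UPDRS part-3 motor score within the patient group with Pearson's
correlation; the same tests run per node, with Benjamini-Hochberg false
discovery rate control applied separately to each family of nodal tests
(one family per measure, weighting and test type).  Whole-brain tests are
reported uncorrected.  All tests are two-sided; correlation signs are
reported so directional claims can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectome import CohortStudy
from .core import EfficiencyResult, Group, Measure, StatResult, Weighting

__all__ = [
    "AnalysisConfig",
    "group_ttest",
    "updrs_correlation",
    "fdr_adjust",
    "run_analysis",
]


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    fdr_q: float = 0.05
    weightings: tuple[Weighting, ...] = (Weighting.FA, Weighting.NOS, Weighting.BINARY)
    measures: tuple[Measure, ...] = (Measure.EGLOB, Measure.ELOC)
    welch: bool = False  # Welch's unequal-variance t-test instead of pooled

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.fdr_q < 1:
            raise ValueError("alpha and fdr_q must lie in (0, 1)")


def group_ttest(
    pd_values: np.ndarray, hc_values: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample Student t-test (pooled variance by default).

    Returns ``(t, p)``.  With zero pooled variance, equal means give
    ``(0, 1)``; unequal means are an error (the statistic is undefined).
    """
    x = np.asarray(pd_values, dtype=float)
    y = np.asarray(hc_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def updrs_correlation(values: np.ndarray, updrs: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t-distribution, n-2 df)."""
    x = np.asarray(values, dtype=float)
    u = np.asarray(updrs, dtype=float)
    if len(x) != len(u) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or u.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    res = sps.pearsonr(x, u)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean significance mask in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def run_analysis(
    study: CohortStudy,
    efficiencies: dict[str, dict[Weighting, EfficiencyResult]],
    cfg: AnalysisConfig | None = None,
) -> list[StatResult]:
    """All group and correlation tests for one study.

    ``efficiencies`` maps subject_id -> weighting -> EfficiencyResult.
    For each weighting x measure this produces one whole-brain StatResult
    (t-test plus patient-group Pearson, uncorrected) and one nodal
    StatResult (per-node tests with BH-FDR masks per family).
    """
    cfg = cfg or AnalysisConfig()
    pd_ids = [s.subject_id for s in study.subjects if s.group is Group.PD]
    hc_ids = [s.subject_id for s in study.subjects if s.group is Group.HC]
    updrs = {}
    for s in study.subjects:
        if s.group is Group.PD:
            if s.updrs_motor is None:
                raise ValueError(f"PD subject {s.subject_id} is missing a UPDRS score")
            updrs[s.subject_id] = s.updrs_motor
    u = np.array([updrs[i] for i in pd_ids])

    def values(ids, w, measure, nodal):
        attr = ("nodal_" if nodal else "wholebrain_") + (
            "eglob" if measure is Measure.EGLOB else "eloc"
        )
        return np.array([getattr(efficiencies[i][w], attr) for i in ids])

    results: list[StatResult] = []
    for w in cfg.weightings:
        for measure in cfg.measures:
            # whole-brain; degenerate (zero-variance) measures report nan
            try:
                t, p = group_ttest(values(pd_ids, w, measure, False),
                                   values(hc_ids, w, measure, False), welch=cfg.welch)
            except ValueError:
                t, p = float("nan"), 1.0
            try:
                r, pc = updrs_correlation(values(pd_ids, w, measure, False), u)
            except ValueError:
                r, pc = float("nan"), 1.0
            results.append(StatResult(measure, w, "wholebrain",
                                      t_stat=t, p_group=p, r=r, p_corr=pc))
            # nodal
            Xpd = values(pd_ids, w, measure, True)   # (n_pd, n_nodes)
            Xhc = values(hc_ids, w, measure, True)
            n_nodes = Xpd.shape[1]
            tv = np.zeros(n_nodes)
            pg = np.ones(n_nodes)
            rv = np.zeros(n_nodes)
            pr = np.ones(n_nodes)
            for k in range(n_nodes):
                try:
                    tv[k], pg[k] = group_ttest(Xpd[:, k], Xhc[:, k], welch=cfg.welch)
                except ValueError:
                    tv[k], pg[k] = np.nan, 1.0
                try:
                    rv[k], pr[k] = updrs_correlation(Xpd[:, k], u)
                except ValueError:
                    rv[k], pr[k] = np.nan, 1.0
            results.append(StatResult(
                measure, w, "nodal",
                t_stat=tv, p_group=pg, r=rv, p_corr=pr,
                fdr_mask_group=fdr_adjust(pg, cfg.fdr_q),
                fdr_mask_corr=fdr_adjust(pr, cfg.fdr_q),
            ))
    return results
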