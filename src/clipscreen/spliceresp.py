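"""PSI quantification, knockdown-response testing and paralog-compensation calls.

PSI = 100 * included / (included + skipped) per sample; per-exon condition
means are contrasted against control with an equal-variance two-sample
t-test (df = n1 + n2 - 2, two-sided).  Response classes follow the
screen's thresholds: responsive if |dPSI(double KD)| > 15 points with
p < alpha, strong if > 40 points, constitutive-like if control PSI >= 95,
fully constitutive at 100.  The compensation test flags exons whose joint-
depletion effect exceeds both single-depletion effects by a buffering
margin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)

KNOCKDOWN_CONDITIONS = ("kd_alpha", "kd_beta", "kd_double")


def compute_psi(included: float, skipped: float) -> float:
    """Percent spliced in: 100 * included / (included + skipped)."""
    if included < 0 or skipped < 0:
        raise DataError("isoform quantities must be >= 0")
    total = included + skipped
    if total == 0:
        raise DataError("included + skipped must be > 0")
    return 100.0 * included / total


@dataclass
class SplicingResponse:
    """Per-exon condition means, contrasts against control and class labels."""

    exon_id: str
    mean_psi: Dict[str, float]
    n_reps: Dict[str, int]
    delta_psi: Dict[str, float] = field(default_factory=dict)
    t_stat: Dict[str, float] = field(default_factory=dict)
    p_value: Dict[str, float] = field(default_factory=dict)
    classes: List[str] = field(default_factory=list)
    compensated: Optional[bool] = None
    buffering_score: Optional[float] = None


def delta_psi(measurements: pd.DataFrame, equal_var: bool = True,
              bh_correct: bool = False) -> List[SplicingResponse]:
    """Condition means, dPSI vs control, and per-contrast t-tests.

    ``measurements`` columns: exon_id, sample_id, condition, included,
    skipped.  Contrasts with fewer than two replicates on either side are
    skipped with a warning.  ``bh_correct`` applies Benjamini-Hochberg
    across exons within each contrast (off by default; per-exon p values
    are reported as-is).
    """
    df = measurements.copy()
    df["psi"] = [compute_psi(i, s) for i, s in zip(df["included"], df["skipped"])]
    out: List[SplicingResponse] = []
    for exon_id, grp in df.groupby("exon_id", sort=True):
        by_cond = {c: g["psi"].to_numpy() for c, g in grp.groupby("condition")}
        if "control" not in by_cond:
            log.warning("exon %s has no control samples; skipped", exon_id)
            continue
        ctrl = by_cond["control"]
        resp = SplicingResponse(
            exon_id=exon_id,
            mean_psi={c: float(v.mean()) for c, v in by_cond.items()},
            n_reps={c: int(v.size) for c, v in by_cond.items()},
        )
        for cond in KNOCKDOWN_CONDITIONS:
            if cond not in by_cond:
                continue
            kd = by_cond[cond]
            resp.delta_psi[cond] = float(kd.mean() - ctrl.mean())
            if kd.size < 2 or ctrl.size < 2:
                log.warning("exon %s %s: < 2 replicates, test skipped", exon_id, cond)
                continue
            if kd.std() == 0 and ctrl.std() == 0:
                t, p = (0.0, 1.0) if kd.mean() == ctrl.mean() else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(kd, ctrl, equal_var=equal_var)
            resp.t_stat[cond] = float(t)
            resp.p_value[cond] = float(p)
        out.append(resp)
    if bh_correct:
        _bh_adjust(out)
    return out


def _bh_adjust(responses: List[SplicingResponse]) -> None:
    for cond in KNOCKDOWN_CONDITIONS:
        with_p = [r for r in responses if cond in r.p_value]
        if not with_p:
            continue
        ps = np.array([r.p_value[cond] for r in with_p])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        for r, q in zip(with_p, adj):
            r.p_value[cond] = float(q)


def classify_response(response: SplicingResponse,
                      responsive_threshold: float = 15.0,
                      strong_threshold: float = 40.0,
                      constitutive_psi: float = 95.0,
                      alpha: float = 0.05) -> List[str]:
    """Assign response-class labels from the double-knockdown contrast.

    A missing p value (e.g. a fixture carrying only dPSI) is treated as
    significant.  ``strong`` implies ``responsive``; ``non-responder``
    means the joint-depletion shift is below the responsive threshold or
    not significant.
    """
    if "kd_double" not in response.delta_psi:
        raise DataError(f"exon {response.exon_id}: no double-knockdown contrast")
    d = abs(response.delta_psi["kd_double"])
    p = response.p_value.get("kd_double", 0.0)
    labels: List[str] = []
    ctrl = response.mean_psi.get("control")
    if ctrl is not None:
        if ctrl == 100.0:
            labels.append("fully-constitutive")
        if ctrl >= constitutive_psi:
            labels.append("constitutive-like")
    if d > responsive_threshold and p < alpha:
        labels.append("responsive")
        if d > strong_threshold:
            labels.append("strong")
    else:
        labels.append("non-responder")
    response.classes = labels
    return labels


def compensation_test(response: SplicingResponse,
                      min_gain: float = 15.0,
                      max_single: float = 10.0) -> SplicingResponse:
    """Buffering score and paralog-compensation flag.

    S = |dPSI(double)| - max(|dPSI(alpha)|, |dPSI(beta)|); the exon is
    flagged compensated iff S > ``min_gain`` and both single-knockdown
    effects stay below ``max_single`` points — the single-vs-joint
    depletion signature of paralog buffering.
    """
    needed = {"kd_alpha", "kd_beta", "kd_double"}
    if not needed <= set(response.delta_psi):
        log.warning("exon %s: missing conditions for compensation test", response.exon_id)
        return response
    da = abs(response.delta_psi["kd_alpha"])
    db = abs(response.delta_psi["kd_beta"])
    dd = abs(response.delta_psi["kd_double"])
    s = dd - max(da, db)
    response.buffering_score = float(s)
    response.compensated = bool(s > min_gain and da < max_single and db < max_single)
    return response


def responses_table(responses: Sequence[SplicingResponse]) -> pd.DataFrame:
    rows = []
    for r in responses:
        row = {"exon_id": r.exon_id}
        for c, v in r.mean_psi.items():
            row[f"psi_{c}"] = v
        for c in KNOCKDOWN_CONDITIONS:
            row[f"dpsi_{c}"] = r.delta_psi.get(c)
            row[f"t_{c}"] = r.t_stat.get(c)
            row[f"p_{c}"] = r.p_value.get(c)
        row["classes"] = ";".join(r.classes)
        row["buffering_score"] = r.buffering_score
        row["compensated"] = r.compensated
        rows.append(row)
    return pd.DataFrame(rows)
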