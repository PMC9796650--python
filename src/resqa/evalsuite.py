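"""CASP-style local-accuracy evaluation of per-residue deviation predictions.

Given predicted and true per-residue deviations the suite computes, per
model: ASE (averaged S-score error, on a 0-100 scale), ROC AUC of the
accurate/inaccurate classification at 3.8 A, precision/recall/F1 of
unreliable-local-region (ULR) detection under two merging rules, and
segment-overlap scores of the binary accuracy strings.  Model scores are
averaged within each evaluation unit (EU) and then across EUs; predictor
groups are ranked by summed standardised metrics (Z-1, Z-2).

Residues with a missing value on either side ('X' placeholders, residues
absent from the reference) are dropped from a model's evaluation rather
than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from . import sovscore
from .nets import D0_EVAL, deviation_to_s

__all__ = [
    "Ulr", "ase", "classify_accurate", "auc", "ulr_detect", "ulr_match",
    "sov_string_eval", "evaluate_model", "aggregate", "filter_models",
    "z_rank", "ACCURATE_THRESHOLD",
]

ACCURATE_THRESHOLD = 3.8   # Angstrom; strict less-than = accurately modelled
ULR_MIN_LEN = 3
MATCH_TOL = 2


@dataclass
class Ulr:
    """Sorted, non-overlapping closed intervals of unreliable residues
    (1-based coordinates), each at least ULR_MIN_LEN long."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -10
        for s, e in self.intervals:
            if e - s + 1 < ULR_MIN_LEN:
                raise ValueError(f"interval ({s},{e}) shorter than "
                                 f"{ULR_MIN_LEN}")
            if s <= prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)

    def coverage(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.intervals:
            out.update(range(s, e + 1))
        return out

    def to_string(self, length: int) -> str:
        chars = ["0"] * length
        for pos in self.coverage():
            chars[pos - 1] = "1"
        return "".join(chars)


def ase(pred_dev: np.ndarray, true_dev: np.ndarray,
        d0: float = D0_EVAL) -> Optional[float]:
    """Averaged S-score error: (1 - mean |S(pred) - S(true)|) * 100.

    Residues with NaN on either side are dropped; returns None when nothing
    remains.
    """
    pred_dev = np.asarray(pred_dev, dtype=float)
    true_dev = np.asarray(true_dev, dtype=float)
    if pred_dev.shape != true_dev.shape:
        raise ValueError("prediction and truth must align")
    ok = np.isfinite(pred_dev) & np.isfinite(true_dev)
    if not np.any(ok):
        return None
    se = deviation_to_s(pred_dev[ok], d0)
    sd = deviation_to_s(true_dev[ok], d0)
    return float((1.0 - np.abs(se - sd).mean()) * 100.0)


def classify_accurate(true_dev: np.ndarray,
                      threshold: float = ACCURATE_THRESHOLD) -> str:
    """Binary accuracy string: '0' where deviation < threshold (accurately
    modelled), '1' otherwise (strict less-than)."""
    true_dev = np.asarray(true_dev, dtype=float)
    if np.any(~np.isfinite(true_dev)):
        raise ValueError("classification requires finite deviations")
    return "".join("0" if d < threshold else "1" for d in true_dev)


def auc(pred_scores: np.ndarray, true_labels: str) -> Optional[float]:
    """ROC area of scores against binary labels, mid-rank tie handling.

    ``pred_scores`` must be oriented so that larger means more accurate;
    '0' labels are the positive (accurate) class.  Returns None when only
    one class is present.  Equivalent to the normalised Mann-Whitney U
    statistic.
    """
    scores = np.asarray(pred_scores, dtype=float)
    if len(scores) != len(true_labels):
        raise ValueError("scores and labels must align")
    pos = np.array([c == "0" for c in true_labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _runs_of_ones(labels: str) -> list[tuple[int, int]]:
    """Maximal runs of '1' as closed 1-based intervals."""
    out = []
    start = None
    for i, c in enumerate(labels, start=1):
        if c == "1" and start is None:
            start = i
        elif c != "1" and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(labels)))
    return out


def ulr_detect(labels: str, mode: str = "ULR1") -> Ulr:
    """Detect unreliable local regions in a binary accuracy string.

    Runs of at least three consecutive '1's seed the regions.  Merging,
    repeated to a fixed point and bridging the single '0' in between:

    * ULR1 — two regions separated by exactly one accurate residue merge;
    * ULR2 — additionally, a region merges with any adjacent run of
      inaccurate residues (length >= 1) one accurate residue away.
    """
    if len(labels) == 0:
        raise ValueError("empty label string")
    if set(labels) - {"0", "1"}:
        raise ValueError("labels must be 0/1")
    mode = mode.upper()
    if mode not in ("ULR1", "ULR2"):
        raise ValueError("mode must be ULR1 or ULR2")
    # (start, end, is_region) over the maximal runs of 1s; seed regions are
    # runs of length >= 3.  Adjacent runs are separated by >= 1 zero; a gap
    # of exactly one zero (s2 == e1 + 2) is bridgeable.
    items = [(s, e, e - s + 1 >= ULR_MIN_LEN) for s, e in
             _runs_of_ones(labels)]
    changed = True
    while changed:
        changed = False
        merged: list[list] = []
        for s, e, reg in items:
            if merged and s == merged[-1][1] + 2:
                ps, pe, preg = merged[-1]
                allow = (preg and reg) if mode == "ULR1" else (preg or reg)
                if allow:
                    merged[-1] = [ps, e, True]
                    changed = True
                    continue
            merged.append([s, e, reg])
        items = [tuple(t) for t in merged]
    return Ulr(intervals=[(s, e) for s, e, reg in items if reg])


def ulr_match(pred: Ulr, true: Ulr) -> tuple[Optional[float], Optional[float],
                                             Optional[float]]:
    """Greedy one-to-one interval matching with a +/-2-residue tolerance.

    A predicted interval matches a true interval when both |start - start'|
    and |end - end'| are at most 2; each true interval can be matched once,
    scanning predictions left to right.  Returns (precision, recall, F1);
    all three are None when both sets are empty (such models are excluded
    from averages), and F1 is 0 when precision + recall is 0.
    """
    if len(pred) == 0 and len(true) == 0:
        return None, None, None
    used = [False] * len(true)
    matched = 0
    for ps, pe in pred.intervals:
        for k, (ts, te) in enumerate(true.intervals):
            if used[k]:
                continue
            if abs(ps - ts) <= MATCH_TOL and abs(pe - te) <= MATCH_TOL:
                used[k] = True
                matched += 1
                break
    precision = matched / len(pred) if len(pred) else 0.0
    recall = matched / len(true) if len(true) else 0.0
    if precision + recall == 0.0:
        return precision, recall, 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def sov_string_eval(pred_dev: np.ndarray,
                    true_dev: np.ndarray) -> tuple[float, float]:
    """(SOV'99, SOV_refine) of the two binary accuracy strings."""
    pred_dev = np.asarray(pred_dev, dtype=float)
    true_dev = np.asarray(true_dev, dtype=float)
    ok = np.isfinite(pred_dev) & np.isfinite(true_dev)
    true_s = classify_accurate(true_dev[ok])
    pred_s = classify_accurate(pred_dev[ok])
    return (sovscore.sov99(true_s, pred_s),
            sovscore.sov_refine(true_s, pred_s))


def evaluate_model(pred_dev: np.ndarray, true_dev: np.ndarray) -> dict:
    """All per-model local metrics as a dict (None where undefined)."""
    pred_dev = np.asarray(pred_dev, dtype=float)
    true_dev = np.asarray(true_dev, dtype=float)
    ok = np.isfinite(pred_dev) & np.isfinite(true_dev)
    out = {"ASE": ase(pred_dev, true_dev)}
    if not np.any(ok):
        return {**out, "AUC": None, "ULR1_F1": None, "ULR2_F1": None,
                "SOV99": None, "SOV_refine": None}
    p, t = pred_dev[ok], true_dev[ok]
    true_labels = classify_accurate(t)
    out["AUC"] = auc(deviation_to_s(p, D0_EVAL), true_labels)
    pred_labels = classify_accurate(p)
    for mode, key in (("ULR1", "ULR1_F1"), ("ULR2", "ULR2_F1")):
        _, _, f1 = ulr_match(ulr_detect(pred_labels, mode),
                             ulr_detect(true_labels, mode))
        out[key] = f1
    out["SOV99"], out["SOV_refine"] = sov_string_eval(p, t)
    return out


def aggregate(per_model: Sequence[dict],
              eu_of_model: Sequence[str]) -> tuple[dict, dict]:
    """Average metrics over models within each EU, then over EUs.

    ``per_model`` holds metric dicts; ``eu_of_model`` the parallel EU ids.
    None values are excluded at each level.  Returns (per-EU means,
    overall means); metrics with no defined value anywhere are None.
    """
    if len(per_model) != len(eu_of_model):
        raise ValueError("per_model and eu_of_model must align")
    metrics = ["ASE", "AUC", "ULR1_F1", "ULR2_F1", "SOV99", "SOV_refine"]
    by_eu: dict[str, list[dict]] = {}
    for rep, eu in zip(per_model, eu_of_model):
        by_eu.setdefault(eu, []).append(rep)
    eu_means: dict[str, dict] = {}
    for eu, reps in by_eu.items():
        eu_means[eu] = {}
        for m in metrics:
            vals = [r[m] for r in reps if r.get(m) is not None]
            eu_means[eu][m] = float(np.mean(vals)) if vals else None
    overall = {}
    for m in metrics:
        vals = [d[m] for d in eu_means.values() if d[m] is not None]
        overall[m] = float(np.mean(vals)) if vals else None
    return eu_means, overall


def filter_models(gdt_scores: Sequence[float],
                  regime: str = "gt40") -> np.ndarray:
    """Boolean mask selecting models by GDT_TS regime.

    ``gt40``: GDT_TS > 40 (the official filtering); ``between40and60``:
    40 < GDT_TS < 60; ``gt90``: GDT_TS > 90; ``all``: everything.
    """
    g = np.asarray(gdt_scores, dtype=float)
    if regime == "gt40":
        return g > 40.0
    if regime == "between40and60":
        return (g > 40.0) & (g < 60.0)
    if regime == "gt90":
        return g > 90.0
    if regime == "all":
        return np.ones_like(g, dtype=bool)
    raise ValueError(f"unknown regime: {regime}")


def z_rank(group_eu_scores: dict[str, dict[str, dict[str, float]]],
           flavor: str = "Z1") -> list[tuple[str, float]]:
    """Rank predictor groups by summed standardised metrics.

    ``group_eu_scores[group][eu]`` is a metric dict of that group's mean
    scores on that EU.  Per EU and metric, scores are standardised across
    groups (population sd; z = 0 when the sd vanishes), each metric's z is
    averaged over the EUs where it is defined, and the flavour's metrics
    are summed: Z1 over {ASE/100, AUC, ULR1_F1}; Z2 over {ASE/100, AUC,
    ULR2_F1, SOV_refine}.  Returns (group, Z) pairs sorted descending.
    """
    groups = sorted(group_eu_scores)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to standardise")
    flavor = flavor.upper()
    if flavor == "Z1":
        metrics = ["ASE", "AUC", "ULR1_F1"]
    elif flavor == "Z2":
        metrics = ["ASE", "AUC", "ULR2_F1", "SOV_refine"]
    else:
        raise ValueError("flavor must be Z1 or Z2")
    eus = sorted({eu for g in groups for eu in group_eu_scores[g]})
    z_by_group = {g: {m: [] for m in metrics} for g in groups}
    for eu in eus:
        for m in metrics:
            vals = {}
            for g in groups:
                v = group_eu_scores[g].get(eu, {}).get(m)
                if v is not None:
                    vals[g] = v / 100.0 if m == "ASE" else v
            if len(vals) < 2:
                continue
            arr = np.array(list(vals.values()))
            mu, sd = arr.mean(), arr.std()
            for g, v in vals.items():
                z_by_group[g][m].append(
                    0.0 if sd < 1e-15 else (v - mu) / sd)
    totals = []
    for g in groups:
        total = 0.0
        for m in metrics:
            zs = z_by_group[g][m]
            if zs:
                total += float(np.mean(zs))
        totals.append((g, total))
    totals.sort(key=lambda t: (-t[1], t[0]))
    return totals
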