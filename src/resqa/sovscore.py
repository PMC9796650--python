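"""Segment-overlap and per-residue agreement scores between label strings.

These scores compare two equal-length strings over a small alphabet —
three-state secondary structure {H, E, C}, binarised relative solvent
accessibility {b, e}, or accurate/inaccurate residue classes {0, 1}.  Q3 is
plain positional identity; the SOV family scores overlap at the level of
contiguous same-label segments, which tolerates small boundary shifts that
per-residue accuracy punishes.

SOV'99 follows the published segment-overlap definition: for each label
class, every overlapping (reference, observed) segment pair contributes

    len(s_ref) * (minov + delta) / maxov

where minov/maxov are the intersection/union extents of the pair and delta
is an allowance capped by min(maxov - minov, minov, len(s_ref)//2,
len(s_obs)//2).  Reference segments with no same-class overlap contribute
only to the normalisation.  The refined variant used here scales the
allowance by the overlap agreement instead of segment halves:

    delta_refine = min(maxov - minov, lambda * (minov / maxov) * (maxov - minov))

which keeps every pair ratio <= 1 (so the score is exactly 1 only for
identical strings), vanishes as segments disagree, and reduces the reward
for sprawling, loosely-overlapping segments.  ``lam`` defaults to 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["q3", "sov99", "sov_refine", "local_sov_features",
           "global_sov_features", "segments"]


def _check(reference: str, observed: str) -> None:
    if len(reference) == 0:
        raise ValueError("label strings must be non-empty")
    if len(reference) != len(observed):
        raise ValueError(
            f"label strings differ in length: {len(reference)} vs "
            f"{len(observed)}")


def segments(labels: str) -> list[tuple[int, int, str]]:
    """Maximal runs of one label as (start, end, label), 0-based inclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i - 1, labels[start]))
            start = i
    return out


def q3(reference: str, observed: str) -> float:
    """Fraction of positions with identical labels."""
    _check(reference, observed)
    same = sum(a == b for a, b in zip(reference, observed))
    return same / len(reference)


def _sov(reference: str, observed: str, refine: bool, lam: float) -> float:
    _check(reference, observed)
    ref_segs = segments(reference)
    obs_segs = segments(observed)
    numer = 0.0
    norm = 0
    for rs, re, rlab in ref_segs:
        rlen = re - rs + 1
        overlapped = False
        for os_, oe, olab in obs_segs:
            if olab != rlab:
                continue
            minov_start, minov_end = max(rs, os_), min(re, oe)
            if minov_end < minov_start:
                continue
            overlapped = True
            minov = minov_end - minov_start + 1
            maxov = max(re, oe) - min(rs, os_) + 1
            olen = oe - os_ + 1
            if refine:
                delta = min(maxov - minov,
                            lam * (minov / maxov) * (maxov - minov))
            else:
                delta = min(maxov - minov, minov, rlen // 2, olen // 2)
            numer += rlen * (minov + delta) / maxov
            norm += rlen
        if not overlapped:
            norm += rlen
    if norm == 0:
        return 0.0
    return min(1.0, numer / norm)


def sov99(reference: str, observed: str) -> float:
    """Segment-overlap score with the classic half-segment allowance."""
    return _sov(reference, observed, refine=False, lam=1.0)


def sov_refine(reference: str, observed: str, lam: float = 1.0) -> float:
    """Segment-overlap score with the agreement-scaled allowance.

    Equals 1.0 iff the strings are identical; 0.0 when no same-class
    segments overlap.
    """
    return _sov(reference, observed, refine=True, lam=lam)


def local_sov_features(reference: str, observed: str,
                       window_halfwidth: int = 6) -> np.ndarray:
    """Windowed (Q3, SOV'99, SOV_refine) rows, one per residue.

    Residue i (0-based) is scored on the substring
    [max(0, i - w) .. min(L - 1, i + w)] of both strings — a 13-residue
    window at default halfwidth, truncated at the termini.
    """
    _check(reference, observed)
    L = len(reference)
    out = np.empty((L, 3))
    for i in range(L):
        lo = max(0, i - window_halfwidth)
        hi = min(L, i + window_halfwidth + 1)
        r, o = reference[lo:hi], observed[lo:hi]
        out[i] = (q3(r, o), sov99(r, o), sov_refine(r, o))
    return out


def global_sov_features(ss_ref: str, ss_obs: str,
                        rsa_ref: str, rsa_obs: str) -> np.ndarray:
    """(Q3, SOV'99, SOV_refine) for SS followed by the same triple for RSA."""
    return np.array([
        q3(ss_ref, ss_obs), sov99(ss_ref, ss_obs), sov_refine(ss_ref, ss_obs),
        q3(rsa_ref, rsa_obs), sov99(rsa_ref, rsa_obs),
        sov_refine(rsa_ref, rsa_obs),
    ])
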