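"""Independent brute-force reference implementations used only by tests.

Each function re-derives its quantity directly from the written definition,
with no shared code with the package, so agreement is a genuine cross-check.
"""

import numpy as np

WINDOW = 0.5
TOL = 1e-9


def isolation_oracle(times):
    """O(n^2) isolation classes from the plain-language rules, applied in
    order: isolated, then pairs, then triplets, then other."""
    times = list(map(float, times))
    n = len(times)
    labels = ["other"] * n

    def far(i, j):
        return abs(times[i] - times[j]) >= WINDOW - TOL

    def near(i, j):
        return abs(times[i] - times[j]) < WINDOW - TOL

    for i in range(n):
        if all(far(i, j) for j in range(n) if j != i):
            labels[i] = "isolated"
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] != "other" or labels[j] != "other":
                continue
            others = [k for k in range(n) if k not in (i, j)]
            if near(i, j) and all(far(i, k) and far(j, k) for k in others):
                labels[i] = labels[j] = "pair"
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                trio = (i, j, k)
                if any(labels[m] != "other" for m in trio):
                    continue
                span = max(times[m] for m in trio) - min(times[m] for m in trio)
                others = [m for m in range(n) if m not in trio]
                if span <= 2 * WINDOW + TOL and all(
                    far(m, o) for m in trio for o in others
                ):
                    for m in trio:
                        labels[m] = "triplet"
    return labels


def overlapping_pairs_oracle(times, lo=0.15, hi=0.20):
    times = list(map(float, times))
    out = []
    for i in range(len(times) - 1):
        gap = times[i + 1] - times[i]
        if lo - TOL <= gap <= hi + TOL:
            out.append((i, i + 1))
    return out


def lick_rate_oracle(licks):
    licks = list(map(float, licks))
    intervals = [b - a for a, b in zip(licks, licks[1:])]
    return len(intervals) / sum(intervals)


def epoch_oracle(t, licks):
    if len(licks) == 0:
        return "non-licking"
    d = min(abs(t - el) for el in licks)
    if d <= 0.25 + TOL:
        return "licking"
    if d > 0.75 + TOL:
        return "non-licking"
    return "unclassified"


def tone_response_oracle(cue_offsets, licks, cue_onsets):
    out = []
    for i, off in enumerate(cue_offsets):
        bound = cue_onsets[i + 1] if i + 1 < len(cue_onsets) else np.inf
        later = [el for el in licks if off < el < bound]
        out.append(min(later) - off if later else np.nan)
    return out


def mdm_oracle(cm, tm, cr, tr):
    return (cm / tm) / (cr / tr)


def branch_variability_oracle(a1, a2):
    return 2.0 * abs(a1 - a2) / (a1 + a2)
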