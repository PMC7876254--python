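"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive every quantity with naive per-sample /
per-pair loops, sharing no code with the library implementations.
"""

import math


def naive_rate_score(samples, aoi, window_ms, duration_ms):
    """Per-sample loop: dwell(20 ms per in-AOI valid sample) / window."""
    w = duration_ms if window_ms is None else window_ms
    hits = 0
    for t, x, y, valid in samples:
        if t >= w or not valid:
            continue
        if _inside(aoi, x, y):
            hits += 1
    return hits * 20.0 / w


def naive_count_score(samples, aoi, min_run=1):
    run = 0
    for _, x, y, valid in samples:
        if valid and _inside(aoi, x, y):
            run += 1
            if run >= min_run:
                return 1
        else:
            run = 0
    return 0


def naive_fixation_pct(all_samples, expected_total):
    valid = sum(1 for (_, _, _, v) in all_samples if v)
    return 100.0 * valid / expected_total


def _inside(aoi, x, y):
    if x is None or y is None or (isinstance(x, float) and math.isnan(x)):
        return False
    if aoi.shape == "circle":
        return (x - aoi.cx) ** 2 + (y - aoi.cy) ** 2 <= aoi.r**2
    return aoi.x <= x <= aoi.x + aoi.w and aoi.y <= y <= aoi.y + aoi.h


def naive_auc(scores, labels):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_youden(scores, labels):
    """Scan every candidate threshold; ties toward higher sensitivity."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    best = None
    thresholds = sorted(set(scores)) + [max(scores) + 1.0]
    for thr in thresholds:
        sens = sum(1 for s in pos if s >= thr) / len(pos)
        spec = sum(1 for s in neg if s < thr) / len(neg)
        key = (round(sens + spec - 1.0, 9), sens)
        if best is None or key > best[0]:
            best = (key, (sens, spec))
    return best[1]


def naive_cohens_d(a, b):
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(pooled)
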