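"""Independent brute-force oracles, written before the operations they check.

Nothing here imports the package's scanning, folding or metric code: each
oracle is a direct transcription of the rule it verifies, implemented with
plain loops so disagreements point at the optimized path.
"""

from __future__ import annotations

import numpy as np

_COL = {"A": 0, "C": 1, "G": 2, "U": 3}


# --- matching score --------------------------------------------------------


def naive_matching_scores(bases: str, freq: np.ndarray) -> list[float]:
    """Per-start frequency sum, one explicit loop per motif position."""
    k = freq.shape[0]
    scores = []
    for i in range(len(bases) - k + 1):
        total = 0.0
        for j in range(k):
            c = bases[i + j]
            total += freq[j][_COL[c]] if c in _COL else 0.25
        scores.append(total)
    return scores


def naive_top_sites(scores, n):
    """Full stable sort on (-score, start)."""
    pairs = sorted(enumerate(scores), key=lambda p: (-p[1], p[0]))
    return pairs[:n]


# --- clustering ------------------------------------------------------------


def naive_local_maxima(values) -> list[tuple[int, float]]:
    """Plateau maxima by explicit neighbor comparison at every index."""
    out = []
    n = len(values)
    for i in range(n):
        if i > 0 and values[i - 1] == values[i]:
            continue  # not leftmost of its plateau
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if (i == 0 or values[i - 1] < values[i]) and (
            j == n - 1 or values[j + 1] < values[i]
        ):
            out.append((i, float(values[i])))
    return out


def naive_clustering_score(scores, start, k, window_nt=50, n_peaks=5) -> float:
    center = start + k // 2
    L = len(scores) + k - 1
    win_lo = max(0, center - window_nt // 2)
    win_hi = min(L, center + window_nt // 2)
    cand = [s for s in range(len(scores)) if s >= win_lo and s + k <= win_hi]
    if not cand:
        return 0.0
    sub = [scores[s] for s in cand]
    peaks = sorted(naive_local_maxima(sub), key=lambda p: (-p[1], p[0]))[:n_peaks]
    return sum(0.5 ** (r + 1) * v for r, (_, v) in enumerate(peaks))


# --- folding ---------------------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_max_pairs(bases: str, mask=None, min_loop: int = 3) -> int:
    """Maximum nested pair count by explicit recursion over all structures.

    Branches on every legal partner of position ``i`` (or none), so it
    walks the full structure space; exponential, for short strings only.
    """
    n = len(bases)
    if mask is None:
        mask = [False] * n

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        if not mask[i] and bases[i] != "N":
            for p in range(i + min_loop + 1, j + 1):
                if mask[p] or bases[p] == "N":
                    continue
                if (bases[i], bases[p]) in _PAIRS:
                    cand = 1 + rec(i + 1, p - 1) + rec(p + 1, j)
                    if cand > best:
                        best = cand
        return best

    return rec(0, n - 1)


# --- metrics ---------------------------------------------------------------


def naive_roc_auc(labels, scores) -> float:
    """All-pairs Mann-Whitney counting with 0.5 tie credit."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_pr_auc(labels, scores) -> float:
    """Step-rule AP by descending threshold sweep with ties grouped."""
    labels = list(labels)
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for l, s in zip(labels, scores) if s >= t and l == 1)
        fp = sum(1 for l, s in zip(labels, scores) if s >= t and l == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# --- statistics ------------------------------------------------------------


def two_pass_mean_sd(column) -> tuple[float, float]:
    """Textbook two-pass sample mean / sd (n-1)."""
    n = len(column)
    mean = sum(column) / n
    var = sum((x - mean) ** 2 for x in column) / (n - 1)
    return mean, var**0.5


# --- full featurization ----------------------------------------------------


def naive_featurize(bases: str, freq: np.ndarray, track=None, n_sites: int = 10):
    """Direct-loop reimplementation of the 40-feature vector.

    Uses the recursive structure-enumeration folder, so it is only viable
    for short sequences; shares no code with the package.
    """
    k = freq.shape[0]
    L = len(bases)
    scores = naive_matching_scores(bases, freq)
    top = naive_top_sites(scores, n_sites)
    ms, cs, gacc, csrv = [], [], [], []
    for start, score in top:
        ms.append(score)
        cs.append(naive_clustering_score(scores, start, k))
        core_lo, core_hi = max(0, start - 15), min(L, start + 25)
        seg_lo, seg_hi = max(0, start - 85), min(L, start + 95)
        seg = bases[seg_lo:seg_hi]
        m = [core_lo - seg_lo <= p < core_hi - seg_lo for p in range(len(seg))]
        gacc.append(
            float(enumerate_max_pairs(seg)) - float(enumerate_max_pairs(seg, m))
        )
        if track is None:
            csrv.append(0.0)
        else:
            vals = list(track[start : start + 10])
            csrv.append(sum(vals) / len(vals) if vals else 0.0)
    pad = n_sites - len(top)
    return ms + [0.0] * pad + cs + [0.0] * pad + gacc + [0.0] * pad + csrv + [0.0] * pad
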