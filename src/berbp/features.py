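"""Per-sequence feature computation: matching, clustering, accessibility
and conservation scores for the ten best PWM matches.

The matching score of a window is the plain sum of PWM frequencies of the
observed bases (an N contributes 0.25, the expectation of a renormalized
column).  The ten top-scoring starts — ties broken leftmost, short
sequences padded with zero-score sites — define the putative binding
sites; each contributes one value per feature type, giving a 40-entry
vector in fixed block order MS1..MS10, CS1..CS10, Gacc1..Gacc10,
Csrv1..Csrv10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from berbp.folding import FoldBackend, accessibility_score
from berbp.io_formats import ALPHABET, CandidateSequence, PWM

N_SITES = 10
CLUSTER_WINDOW_NT = 50
CLUSTER_N_PEAKS = 5
CONSERVATION_SPAN = 10

FEATURE_BLOCKS = ("MS", "CS", "Gacc", "Csrv")
#: Fixed column order of every feature vector / matrix.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{block}{i}" for block in FEATURE_BLOCKS for i in range(1, N_SITES + 1)
)

_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class PutativeSite:
    """One ranked PWM match.  Padded sites fill ranks beyond L-k+1."""

    start: int
    ms: float
    rank: int
    padded: bool = False


@dataclass
class FeatureVector:
    """The 40 features of one (sequence, PWM) pair plus best-site context."""

    seq_id: str
    pwm_id: str
    values: np.ndarray
    best_site_start: int
    best_site_score: float
    standardized: bool = False
    stats_fingerprint: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} entries")
        if not np.isfinite(values).all():
            raise ValueError("feature vector contains non-finite entries")
        self.values = values


def scan_matching_scores(seq: CandidateSequence, pwm: PWM) -> np.ndarray:
    """Matching score at every start: sum of per-position PWM frequencies.

    Returns L-k+1 scores, each in [0, k].  An N base contributes 0.25 at
    any motif position.
    """
    L, k = seq.L, pwm.k
    if L < k:
        raise ValueError(f"sequence {seq.id!r} shorter than motif ({L} < {k})")
    idx = np.fromiter((_CODE.get(c, -1) for c in seq.bases), dtype=np.int64, count=L)
    n_starts = L - k + 1
    scores = np.zeros(n_starts)
    for j in range(k):
        col = idx[j : j + n_starts]
        vals = np.where(col >= 0, pwm.freq[j, np.clip(col, 0, 3)], 0.25)
        scores += vals
    return scores


def select_top_sites(scores: np.ndarray, n: int = N_SITES) -> list[PutativeSite]:
    """Pick the ``n`` best starts, ties leftmost, padding with zero sites."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("score vector is empty")
    starts = np.arange(scores.size)
    order = np.lexsort((starts, -scores))[:n]
    sites = [
        PutativeSite(start=int(s), ms=float(scores[s]), rank=r + 1)
        for r, s in enumerate(order)
    ]
    for r in range(len(sites), n):
        sites.append(PutativeSite(start=-1, ms=0.0, rank=r + 1, padded=True))
    return sites


def _plateau_maxima(values: np.ndarray) -> list[tuple[int, float]]:
    """Local maxima of a vector, one per plateau at its leftmost index.

    A maximal run of equal values is a local maximum when both flanking
    values (where they exist) are strictly smaller; a constant vector
    yields exactly one maximum at index 0.
    """
    n = values.size
    out: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            out.append((i, float(values[i])))
        i = j + 1
    return out


def clustering_score(
    scores: np.ndarray,
    site: PutativeSite,
    k: int,
    window_nt: int = CLUSTER_WINDOW_NT,
    n_peaks: int = CLUSTER_N_PEAKS,
) -> float:
    """Rank-weighted sum of the best local matching-score maxima near a site.

    Local maxima are taken over starts whose k-mer lies inside the
    ``window_nt`` window centered on the site midpoint (clamped to the
    sequence); the ``n_peaks`` largest get geometric weights 2^-r by
    descending rank.  Padded sites score 0.
    """
    if site.padded:
        return 0.0
    scores = np.asarray(scores, dtype=float)
    center = site.start + k // 2
    half = window_nt // 2
    win_lo = max(0, center - half)
    win_hi = min(scores.size + k - 1, center + half)  # nt coords, exclusive
    s_lo = win_lo
    s_hi = min(scores.size, win_hi - k + 1)  # starts whose k-mer fits
    if s_hi <= s_lo:
        return 0.0
    peaks = _plateau_maxima(scores[s_lo:s_hi])
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return float(sum(2.0 ** -(r + 1) * v for r, (_, v) in enumerate(peaks[:n_peaks])))


def conservation_score(
    seq: CandidateSequence, site: PutativeSite, span: int = CONSERVATION_SPAN
) -> float:
    """Mean conservation over ``span`` positions from the site start.

    Clamped at the sequence end (mean over available positions); 0 when
    the sequence has no track or the site is padded.
    """
    if site.padded or seq.track is None:
        return 0.0
    vals = seq.track[site.start : site.start + span]
    if vals.size == 0:
        return 0.0
    return float(vals.mean())


def featurize(
    seq: CandidateSequence,
    pwm: PWM,
    fold_backend: FoldBackend,
    n_sites: int = N_SITES,
) -> FeatureVector:
    """Assemble the full feature vector for one (sequence, PWM) pair."""
    scores = scan_matching_scores(seq, pwm)
    sites = select_top_sites(scores, n=n_sites)
    ms = [s.ms for s in sites]
    cs = [clustering_score(scores, s, pwm.k) for s in sites]
    gacc = [accessibility_score(seq, s, fold_backend) for s in sites]
    csrv = [conservation_score(seq, s) for s in sites]
    return FeatureVector(
        seq_id=seq.id,
        pwm_id=pwm.id,
        values=np.concatenate([ms, cs, gacc, csrv]),
        best_site_start=sites[0].start,
        best_site_score=sites[0].ms,
    )


def feature_matrix(
    seqs: Sequence[CandidateSequence], pwm: PWM, fold_backend: FoldBackend
) -> tuple[np.ndarray, list[str], list[FeatureVector]]:
    """Featurize many sequences; rows follow input order."""
    fvs = [featurize(s, pwm, fold_backend) for s in seqs]
    X = np.stack([fv.values for fv in fvs]) if fvs else np.empty((0, len(FEATURE_NAMES)))
    return X, [fv.seq_id for fv in fvs], fvs
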