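"""Seeded generators for PWMs, planted-motif positives, background
negatives and conservation tracks.

These stand in for curated UTR target/background corpora so that every
pipeline stage is exercisable offline: positives carry motif instances
sampled column-wise from the PWM at annotated, non-overlapping positions;
negatives are background-composition sequences; conservation tracks are
Gaussian noise elevated over the planted intervals.  Every generator is
a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from berbp.io_formats import ALPHABET, CandidateSequence, PWM

logger = logging.getLogger(__name__)

MIN_TRAINING_LENGTH = 150

#: Uniform background composition (A, C, G, U).
UNIFORM_COMPOSITION = (0.25, 0.25, 0.25, 0.25)
#: AU-rich 3'-UTR-like preset for realism tests.
UTR_COMPOSITION = (0.3, 0.2, 0.2, 0.3)


@dataclass(frozen=True)
class PlantedSite:
    """One planted motif instance, 0-based half-open."""

    seq_id: str
    start: int
    end: int


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    k: int = 7
    concentration: float = 0.5
    n_pos: int = 100
    n_neg: int = 100
    seq_length: int = 300
    sites_per_positive: tuple[int, int] = (1, 1)  # inclusive range
    composition: tuple[float, float, float, float] = UNIFORM_COMPOSITION
    cons_baseline: tuple[float, float] = (0.0, 1.0)  # mean, sd
    cons_planted: tuple[float, float] = (2.0, 1.0)
    pwm: PWM | None = None

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.seq_length, self.k) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.sites_per_positive
        if not 1 <= lo <= hi:
            raise ValueError("sites_per_positive must be an increasing range >= 1")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or comp.sum() <= 0:
            raise ValueError("composition must be 4 non-negative weights")
        self.composition = tuple(comp / comp.sum())

    def resolve_pwm(self) -> PWM:
        if self.pwm is not None:
            return self.pwm
        return generate_pwm(self.k, self.concentration, self.seed)


def generate_pwm(
    k: int, concentration: float, seed: int, pwm_id: str | None = None
) -> PWM:
    """Draw each PWM row from a symmetric Dirichlet.

    Low concentration gives peaked (informative) columns; high
    concentration approaches the uniform matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    freq = rng.dirichlet([concentration] * 4, size=k)
    return PWM(id=pwm_id or f"synthetic_k{k}_c{concentration}_s{seed}", freq=freq)


def _random_bases(rng: np.random.Generator, length: int, composition) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(composition))


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _sample_motif(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in pwm.freq])


def _place_sites(
    rng: np.random.Generator, L: int, k: int, n_sites: int, max_tries: int = 1000
) -> list[int]:
    """Non-overlapping uniform start positions, by rejection."""
    for _ in range(max_tries):
        starts = sorted(int(s) for s in rng.integers(0, L - k + 1, size=n_sites))
        if all(b - a >= k for a, b in zip(starts, starts[1:])):
            return starts
    raise ValueError(
        f"could not place {n_sites} non-overlapping {k}-mers in {L} nt "
        f"after {max_tries} tries"
    )


def generate_positive_set(
    spec: SyntheticSpec,
) -> tuple[list[CandidateSequence], list[PlantedSite]]:
    """Background sequences with PWM-sampled motif instances planted in.

    Each positive gets a per-sequence count drawn uniformly from
    ``sites_per_positive``; every planted interval is annotated.
    """
    pwm = spec.resolve_pwm()
    if spec.seq_length < pwm.k:
        raise ValueError("seq_length must be >= motif length")
    rng = np.random.default_rng((spec.seed, 1))
    seqs: list[CandidateSequence] = []
    sites: list[PlantedSite] = []
    lo, hi = spec.sites_per_positive
    for i in range(spec.n_pos):
        codes = _random_bases(rng, spec.seq_length, spec.composition)
        n_sites = int(rng.integers(lo, hi + 1))
        seq_id = f"pos_{i}"
        for start in _place_sites(rng, spec.seq_length, pwm.k, n_sites):
            codes[start : start + pwm.k] = _sample_motif(rng, pwm)
            sites.append(PlantedSite(seq_id=seq_id, start=start, end=start + pwm.k))
        seqs.append(CandidateSequence(id=seq_id, bases=_codes_to_str(codes)))
    return seqs, sites


def generate_negative_set(
    spec: SyntheticSpec,
    screen_consensus: bool = False,
    screen_threshold: float | None = None,
    max_resamples: int = 100,
) -> list[CandidateSequence]:
    """Background-only sequences (pseudo-negatives).

    With ``screen_consensus`` on, any sequence whose best match to the
    PWM reaches ``screen_threshold`` (default 0.9*k) is re-drawn — off by
    default, matching the pseudo-negative argument that random sequences
    approximate true negatives.
    """
    from berbp.features import scan_matching_scores  # local: avoid import cycle

    pwm = spec.resolve_pwm()
    threshold = screen_threshold if screen_threshold is not None else 0.9 * pwm.k
    rng = np.random.default_rng((spec.seed, 2))
    seqs: list[CandidateSequence] = []
    for i in range(spec.n_neg):
        for _ in range(max_resamples):
            codes = _random_bases(rng, spec.seq_length, spec.composition)
            seq = CandidateSequence(id=f"neg_{i}", bases=_codes_to_str(codes))
            if not screen_consensus:
                break
            if scan_matching_scores(seq, pwm).max() < threshold:
                break
        else:
            raise ValueError(
                f"could not draw a screened negative below threshold {threshold}"
            )
        seqs.append(seq)
    return seqs


def generate_conservation_tracks(
    seqs: Sequence[CandidateSequence],
    annotations: Sequence[PlantedSite],
    spec: SyntheticSpec,
) -> list[CandidateSequence]:
    """Attach Gaussian tracks, elevated over planted intervals (in place)."""
    rng = np.random.default_rng((spec.seed, 3))
    by_id: dict[str, list[PlantedSite]] = {}
    for a in annotations:
        by_id.setdefault(a.seq_id, []).append(a)
    b_mean, b_sd = spec.cons_baseline
    e_mean, e_sd = spec.cons_planted
    for seq in seqs:
        track = rng.normal(b_mean, b_sd, seq.L)
        for a in by_id.get(seq.id, ()):
            track[a.start : a.end] = rng.normal(e_mean, e_sd, a.end - a.start)
        seq.track = track
    return list(seqs)


def apply_length_filter(
    seqs: Sequence[CandidateSequence], min_len: int = MIN_TRAINING_LENGTH
) -> list[CandidateSequence]:
    """Drop sequences strictly shorter than ``min_len`` (default keeps 150)."""
    kept = [s for s in seqs if s.L >= min_len]
    removed = len(seqs) - len(kept)
    if removed:
        logger.info("length filter (< %d nt) removed %d of %d sequences",
                    min_len, removed, len(seqs))
    if not kept:
        logger.warning("length filter removed every sequence")
    return kept
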