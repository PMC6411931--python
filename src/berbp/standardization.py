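"""Z-standardization of features against a background sequence set.

Raw features depend strongly on the PWM; standardizing each feature
column by its mean and standard deviation over a background set puts
features from different PWMs on a common scale, which is what makes
pooled (cross-PWM) training possible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from berbp.features import FEATURE_NAMES, FeatureVector, feature_matrix
from berbp.folding import FoldBackend
from berbp.io_formats import CandidateSequence, PWM


@dataclass(frozen=True)
class BackgroundStats:
    """Per-feature mean/sd of one PWM on a background set, plus provenance."""

    pwm_id: str
    n_background: int
    mean: np.ndarray
    sd: np.ndarray
    backend_mode: str = "mfe"
    seed: int | None = None

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (len(FEATURE_NAMES),) or sd.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"mean/sd must have {len(FEATURE_NAMES)} entries")
        if self.n_background < 2:
            raise ValueError("background stats require >= 2 sequences")
        if (sd < 0).any():
            raise ValueError("standard deviations must be >= 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    @property
    def fingerprint(self) -> str:
        """Stable digest identifying these exact stats (for pooling checks)."""
        h = hashlib.sha256()
        h.update(self.pwm_id.encode())
        h.update(np.round(self.mean, 12).tobytes())
        h.update(np.round(self.sd, 12).tobytes())
        return h.hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pwm_id": self.pwm_id,
            "n_background": self.n_background,
            "backend_mode": self.backend_mode,
            "seed": self.seed,
            "feature_names": list(FEATURE_NAMES),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            pwm_id=payload["pwm_id"],
            n_background=payload["n_background"],
            mean=np.array(payload["mean"], dtype=float),
            sd=np.array(payload["sd"], dtype=float),
            backend_mode=payload.get("backend_mode", "mfe"),
            seed=payload.get("seed"),
        )


def compute_background_stats(
    background: Sequence[CandidateSequence],
    pwm: PWM,
    backend: FoldBackend,
    seed: int | None = None,
) -> BackgroundStats:
    """Featurize a background set and take per-column mean and sample sd.

    The sample (n-1 denominator) standard deviation is used.  Sequences
    shorter than the motif are unusable; fewer than two usable sequences
    is an error.
    """
    usable = [s for s in background if s.L >= pwm.k]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 background sequences with L >= k={pwm.k}, got {len(usable)}"
        )
    X, _, _ = feature_matrix(usable, pwm, backend)
    return BackgroundStats(
        pwm_id=pwm.id,
        n_background=len(usable),
        mean=X.mean(axis=0),
        sd=X.std(axis=0, ddof=1),
        backend_mode=backend.mode,
        seed=seed,
    )


def z_transform(fv: FeatureVector, stats: BackgroundStats) -> FeatureVector:
    """Standardize one feature vector; degenerate columns (sd=0) map to 0."""
    if fv.pwm_id != stats.pwm_id:
        raise ValueError(
            f"PWM mismatch: features for {fv.pwm_id!r}, stats for {stats.pwm_id!r}"
        )
    if fv.standardized:
        raise ValueError(f"feature vector for {fv.seq_id!r} is already standardized")
    z = np.where(stats.sd > 0, (fv.values - stats.mean) / np.where(stats.sd > 0, stats.sd, 1.0), 0.0)
    return FeatureVector(
        seq_id=fv.seq_id,
        pwm_id=fv.pwm_id,
        values=z,
        best_site_start=fv.best_site_start,
        best_site_score=fv.best_site_score,
        standardized=True,
        stats_fingerprint=stats.fingerprint,
    )


def z_transform_matrix(X: np.ndarray, stats: BackgroundStats) -> np.ndarray:
    """Column-wise z-transform of a feature matrix (sd=0 columns map to 0)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected an (n, {len(FEATURE_NAMES)}) matrix")
    safe_sd = np.where(stats.sd > 0, stats.sd, 1.0)
    return np.where(stats.sd > 0, (X - stats.mean) / safe_sd, 0.0)
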