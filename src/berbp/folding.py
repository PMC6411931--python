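"""Folding-accessibility scoring via unconstrained vs. constrained folds.

A 180-nt segment is cut around each putative site (10-nt site extent,
15-nt immediate flanks, 70-nt far flanks on each side) and folded twice:
once freely and once with the 40-nt core (site plus immediate flanks)
forced single-stranded.  The accessibility score is the energy difference
constrained minus unconstrained, which is always >= 0 because constrained
structures are a subset of unconstrained ones.

Two backends implement the energy call: a self-contained base-pair
maximization dynamic program (default, MFE-flavored, unitless) and an
adapter around an external folding executable.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass
from typing import TYPE_CHECKING, Protocol, runtime_checkable

import numpy as np
from numba import njit

if TYPE_CHECKING:  # pragma: no cover
    from berbp.io_formats import CandidateSequence
    from berbp.features import PutativeSite

# Printed segment arithmetic: 180 = 10 + 2*15 + 2*70, core = 10 + 2*15 = 40.
SITE_EXTENT = 10
IMMEDIATE_FLANK = 15
FAR_FLANK = 70
SEGMENT_LENGTH = SITE_EXTENT + 2 * IMMEDIATE_FLANK + 2 * FAR_FLANK
CORE_LENGTH = SITE_EXTENT + 2 * IMMEDIATE_FLANK

MIN_HAIRPIN_LOOP = 3

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


class FoldingError(RuntimeError):
    """The folding backend failed; never silently fall back."""


@dataclass(frozen=True)
class AccessibilitySegment:
    """Folding substrate for one putative site."""

    segment: str
    core_mask: np.ndarray  # True = must stay unpaired
    seg_start: int  # 0-based offset of the segment in the parent sequence

    def __post_init__(self) -> None:
        if len(self.segment) != len(self.core_mask):
            raise ValueError("core_mask length must equal segment length")


@runtime_checkable
class FoldBackend(Protocol):
    name: str
    mode: str

    def fold(self, segment: str, unpaired_mask: np.ndarray) -> float:
        """Free energy of ``segment`` with masked positions forced unpaired."""
        ...


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------


def extract_segment(seq: "CandidateSequence", site: "PutativeSite") -> AccessibilitySegment:
    """Cut the folding segment and core mask around a putative site.

    The site extent is fixed at 10 nt from the match start regardless of
    motif length; intervals are clamped at the sequence bounds.
    """
    if site.padded:
        raise ValueError("cannot extract a segment for a padded site")
    L = seq.L
    start = site.start
    core_lo = max(0, start - IMMEDIATE_FLANK)
    core_hi = min(L, start + SITE_EXTENT + IMMEDIATE_FLANK)
    seg_lo = max(0, start - IMMEDIATE_FLANK - FAR_FLANK)
    seg_hi = min(L, start + SITE_EXTENT + IMMEDIATE_FLANK + FAR_FLANK)
    mask = np.zeros(seg_hi - seg_lo, dtype=bool)
    mask[core_lo - seg_lo : core_hi - seg_lo] = True
    return AccessibilitySegment(
        segment=seq.bases[seg_lo:seg_hi], core_mask=mask, seg_start=seg_lo
    )


# ---------------------------------------------------------------------------
# internal backend: base-pair maximization DP
# ---------------------------------------------------------------------------


@njit(cache=True)
def _max_pairs(codes, pairable):  # pragma: no cover - compiled
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if pairable[i] and pairable[j]:
                a, b = codes[i], codes[j]
                ok = (
                    (a == 0 and b == 3)
                    or (a == 3 and b == 0)
                    or (a == 1 and b == 2)
                    or (a == 2 and b == 1)
                    or (a == 2 and b == 3)
                    or (a == 3 and b == 2)
                )
                if ok and dp[i + 1, j - 1] + 1 > best:
                    best = dp[i + 1, j - 1] + 1
            for m in range(i, j):
                v = dp[i, m] + dp[m + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp[0, n - 1]


class NussinovBackend:
    """Base-pair maximization fold: energy = -(max nested canonical pairs).

    Canonical pairs are AU, GC and GU; hairpin loops span at least three
    unpaired bases; N never pairs; masked positions never pair.  The model
    is deliberately minimal but preserves the two properties the feature
    relies on: constrained energy >= unconstrained energy, and monotone
    energy under a growing mask.
    """

    name = "internal"
    mode = "mfe"

    def fold(self, segment: str, unpaired_mask: np.ndarray) -> float:
        n = len(segment)
        mask = np.asarray(unpaired_mask, dtype=bool)
        if mask.shape != (n,):
            raise ValueError("unpaired_mask length must equal segment length")
        if n < MIN_HAIRPIN_LOOP + 2:
            return 0.0
        codes = np.empty(n, dtype=np.int8)
        for i, c in enumerate(segment):
            try:
                codes[i] = _BASE_CODE[c]
            except KeyError:
                raise FoldingError(f"invalid base {c!r} in folding segment") from None
        pairable = (~mask) & (codes != 4)
        return -float(_max_pairs(codes, pairable))


# ---------------------------------------------------------------------------
# external backend adapter
# ---------------------------------------------------------------------------

_ENSEMBLE_RE = re.compile(r"free energy of ensemble\s*=\s*(-?\d+\.?\d*)")
_MFE_RE = re.compile(r"\(\s*(-?\d+\.\d+)\s*\)\s*$")


class ExternalFoldBackend:
    """Adapter around an external folding executable (RNAfold dialect).

    The mask is rendered as a dot-bracket constraint string ('.' free,
    'x' forced unpaired).  ``mode='ensemble'`` parses the ensemble free
    energy; ``mode='mfe'`` parses the minimum free energy.  Any failure
    raises :class:`FoldingError` with the captured stderr.
    """

    name = "external"

    def __init__(
        self,
        executable: str = "RNAfold",
        mode: str = "ensemble",
        temperature: float | None = None,
    ) -> None:
        if mode not in ("ensemble", "mfe"):
            raise ValueError(f"mode must be 'ensemble' or 'mfe', got {mode!r}")
        self.executable = executable
        self.mode = mode
        self.temperature = temperature

    def fold(self, segment: str, unpaired_mask: np.ndarray) -> float:
        mask = np.asarray(unpaired_mask, dtype=bool)
        if mask.shape != (len(segment),):
            raise ValueError("unpaired_mask length must equal segment length")
        constraint = "".join("x" if m else "." for m in mask)
        cmd = [self.executable, "-C", "--noPS"]
        if self.mode == "ensemble":
            cmd.append("-p0")
        if self.temperature is not None:
            cmd += ["-T", str(self.temperature)]
        try:
            proc = subprocess.run(
                cmd,
                input=f"{segment}\n{constraint}\n",
                capture_output=True,
                text=True,
                check=False,
            )
        except FileNotFoundError as exc:
            raise FoldingError(f"folding executable {self.executable!r} not found") from exc
        if proc.returncode != 0:
            raise FoldingError(
                f"{self.executable} exited {proc.returncode}: {proc.stderr.strip()}"
            )
        if self.mode == "ensemble":
            m = _ENSEMBLE_RE.search(proc.stdout)
            if not m:
                raise FoldingError(
                    f"no ensemble free energy in {self.executable} output:\n{proc.stdout}"
                )
            return float(m.group(1))
        for line in proc.stdout.splitlines():
            m = _MFE_RE.search(line)
            if m:
                return float(m.group(1))
        raise FoldingError(f"no MFE line in {self.executable} output:\n{proc.stdout}")


def get_backend(name: str = "internal", **kwargs) -> FoldBackend:
    """Backend factory: ``internal`` (default) or ``external``."""
    if name == "internal":
        return NussinovBackend()
    if name == "external":
        return ExternalFoldBackend(**kwargs)
    raise ValueError(f"unknown folding backend {name!r}")


# ---------------------------------------------------------------------------
# accessibility score
# ---------------------------------------------------------------------------


def accessibility_score(
    seq: "CandidateSequence", site: "PutativeSite", backend: FoldBackend
) -> float:
    """Energy cost of keeping the site core unpaired; 0 for padded sites."""
    if site.padded:
        return 0.0
    seg = extract_segment(seq, site)
    g_con = backend.fold(seg.segment, seg.core_mask)
    g_unc = backend.fold(seg.segment, np.zeros(len(seg.segment), dtype=bool))
    return g_con - g_unc
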