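"""Readers and writers for sequences, PWMs, conservation tracks, models
and prediction tables.

Coordinates are 0-based half-open internally; every emitted file is
1-based inclusive.  Sequence alphabets are normalized on input: T becomes
U, lowercase is uppercased, and anything outside {A, C, G, U} becomes N.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from berbp.models import BindingModel

logger = logging.getLogger(__name__)

#: Column order of every PWM frequency matrix.
ALPHABET = ("A", "C", "G", "U")

_BASE_SET = frozenset("ACGUN")

#: On-disk model bundle format; bumped on any incompatible layout change.
MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """A file violated the expected layout or content rules."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Position-by-nucleotide frequency matrix of a binding preference.

    ``freq`` has one row per motif position and columns ordered A, C, G, U.
    Rows are renormalized to sum to one at construction time.
    """

    id: str
    freq: np.ndarray
    rbp_name: str = ""

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise FormatError(
                f"PWM {self.id!r}: expected a k x 4 matrix, got shape {freq.shape}"
            )
        if not np.isfinite(freq).all() or (freq < 0).any():
            raise FormatError(f"PWM {self.id!r}: entries must be finite and >= 0")
        sums = freq.sum(axis=1)
        zero = np.flatnonzero(sums <= 0)
        if zero.size:
            raise FormatError(
                f"PWM {self.id!r}: row {zero[0] + 1} sums to zero and cannot be renormalized"
            )
        freq = freq / sums[:, None]
        freq.flags.writeable = False
        object.__setattr__(self, "freq", freq)

    @property
    def k(self) -> int:
        """Motif length (number of positions)."""
        return self.freq.shape[0]

    def consensus(self) -> str:
        """Most frequent base at each position (ties broken A<C<G<U)."""
        return "".join(ALPHABET[i] for i in self.freq.argmax(axis=1))


@dataclass
class CandidateSequence:
    """One RNA sequence with an optional per-position conservation track."""

    id: str
    bases: str
    track: np.ndarray | None = None

    def __post_init__(self) -> None:
        bases = normalize_bases(self.bases)
        if not bases:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.bases = bases
        if self.track is not None:
            track = np.asarray(self.track, dtype=float)
            if track.shape != (len(bases),):
                raise FormatError(
                    f"sequence {self.id!r}: track length {track.shape} != L={len(bases)}"
                )
            self.track = track

    @property
    def L(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PredictionRecord:
    """One model verdict for one (sequence, PWM) pair."""

    seq_id: str
    pwm_id: str
    model_id: str
    vote_fraction: float
    binding_call: bool
    best_site_start: int  # 0-based internally; written 1-based
    best_site_score: float


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def normalize_bases(raw: str) -> str:
    """Uppercase, map T to U, and collapse ambiguity codes to N."""
    out = raw.upper().replace("T", "U")
    if not _BASE_SET.issuperset(out):
        out = "".join(c if c in _BASE_SET else "N" for c in out)
    return out


def read_fasta(path: str | Path) -> list[CandidateSequence]:
    """Read a FASTA file into normalized candidate sequences.

    Record order is preserved.  Duplicate ids and empty records are
    rejected outright rather than silently patched.
    """
    seqs: list[CandidateSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        seqs.append(CandidateSequence(id=rec.id, bases=str(rec.seq)))
    return seqs


def write_fasta(seqs: Iterable[CandidateSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------


def read_pwm_cisbp(path: str | Path, pwm_id: str | None = None, rbp_name: str = "") -> PWM:
    """Read a tab-separated position-by-nucleotide frequency table.

    The header must name the four nucleotide columns A, C, G and U (a T
    column is accepted and relabeled U); any leading position column is
    ignored.  Rows are renormalized to sum to one.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse PWM table {path}: {exc}") from exc
    cols = {str(c).strip().upper(): c for c in table.columns}
    if "T" in cols and "U" not in cols:
        cols["U"] = cols.pop("T")
    missing = [b for b in ALPHABET if b not in cols]
    if missing:
        raise FormatError(f"PWM table {path} lacks nucleotide column(s) {missing}")
    sub = table[[cols[b] for b in ALPHABET]]
    try:
        freq = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in PWM table {path}: {exc}") from exc
    if freq.shape[0] == 0:
        raise FormatError(f"PWM table {path} has no positions")
    return PWM(id=pwm_id or path.stem, freq=freq, rbp_name=rbp_name)


def read_pwm_meme(path: str | Path, motif_index: int = 0) -> PWM:
    """Minimal MEME motif reader: the letter-probability matrix block only."""
    lines = Path(path).read_text().splitlines()
    motifs: list[tuple[str, list[list[float]]]] = []
    name = ""
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(motifs)}"
        elif line.startswith("letter-probability matrix"):
            rows: list[list[float]] = []
            i += 1
            while i < len(lines):
                cells = lines[i].split()
                if len(cells) != 4:
                    break
                try:
                    rows.append([float(c) for c in cells])
                except ValueError as exc:
                    raise FormatError(f"bad matrix row in {path}: {lines[i]!r}") from exc
                i += 1
            if not rows:
                raise FormatError(f"empty letter-probability matrix in {path}")
            motifs.append((name or f"motif{len(motifs)}", rows))
            continue
        i += 1
    if not motifs:
        raise FormatError(f"no letter-probability matrix found in {path}")
    if motif_index >= len(motifs):
        raise FormatError(
            f"{path} holds {len(motifs)} motif(s); index {motif_index} out of range"
        )
    name, rows = motifs[motif_index]
    return PWM(id=name, freq=np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------


def read_conservation_tsv(
    path: str | Path, seqs: Sequence[CandidateSequence]
) -> list[CandidateSequence]:
    """Attach per-position conservation scores to ``seqs`` (in place).

    The file holds columns seq_id, pos (1-based), score.  Positions absent
    from the file default to 0.0; rows naming unknown sequences are logged
    and skipped; out-of-range positions are an error.  Returns ``seqs``.
    """
    by_id = {s.id: s for s in seqs}
    for s in seqs:
        s.track = np.zeros(s.L)
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["seq_id", "pos", "score"],
            comment="#",
            skip_blank_lines=True,
            dtype={"seq_id": str},
        )
    except pd.errors.EmptyDataError:
        return list(seqs)
    if len(table) and table.iloc[0]["seq_id"] == "seq_id":
        table = table.iloc[1:]
    for row in table.itertuples(index=False):
        try:
            pos = int(row.pos)
            score = float(row.score)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"malformed conservation row {tuple(row)!r} in {path}") from exc
        seq = by_id.get(str(row.seq_id))
        if seq is None:
            logger.warning("conservation track: unknown seq_id %r skipped", row.seq_id)
            continue
        if not 1 <= pos <= seq.L:
            raise FormatError(
                f"conservation position {pos} outside [1, {seq.L}] for {seq.id!r}"
            )
        seq.track[pos - 1] = score
    return list(seqs)


def write_conservation_tsv(seqs: Iterable[CandidateSequence], path: str | Path) -> None:
    """Write non-zero track entries as a (seq_id, pos, score) TSV."""
    with open(path, "w") as fh:
        fh.write("seq_id\tpos\tscore\n")
        for s in seqs:
            if s.track is None:
                continue
            for i, v in enumerate(s.track):
                if v != 0.0:
                    fh.write(f"{s.id}\t{i + 1}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------


def save_model(model: "BindingModel", path: str | Path) -> None:
    """Serialize a trained model plus a JSON metadata sidecar.

    The bundle is ``<path>`` (joblib) and ``<path>.json`` (provenance:
    format version, seed, hyperparameters, PWM ids, standardized flag).
    """
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "model_id": model.model_id,
        "kind": model.kind,
        "pwm_ids": list(model.pwm_ids),
        "standardized": model.standardized,
        "backend_mode": model.backend_mode,
        "n_trees": model.n_trees,
        "mtry": model.mtry,
        "seed": model.seed,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "tool_version": _tool_version(),
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path: str | Path) -> "BindingModel":
    """Load a model bundle, refusing version mismatches and corrupt files."""
    from berbp.models import BindingModel  # deferred: avoids an import cycle

    path = Path(path)
    meta_path = path.with_name(path.name + ".json")
    if not meta_path.exists():
        raise FormatError(f"model bundle {path} lacks its metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"model bundle {path} has format version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION} only"
        )
    try:
        model = joblib.load(path)
    except Exception as exc:
        raise FormatError(f"cannot deserialize model bundle {path}: {exc}") from exc
    if not isinstance(model, BindingModel):
        raise FormatError(f"model bundle {path} does not contain a BindingModel")
    return model


def _tool_version() -> str:
    from berbp import __version__

    return __version__


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

_PRED_HEADER = (
    "seq_id\tpwm_id\tmodel_id\tvote_fraction\tbinding_call\t"
    "best_site_start\tbest_site_score\n"
)


def write_predictions_tsv(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write prediction records as a deterministic TSV.

    Rows are ordered by first appearance of the sequence id, then PWM id,
    then model id; starts are emitted 1-based.
    """
    order: dict[str, int] = {}
    for r in records:
        order.setdefault(r.seq_id, len(order))
    rows = sorted(records, key=lambda r: (order[r.seq_id], r.pwm_id, r.model_id))
    with open(path, "w") as fh:
        fh.write(_PRED_HEADER)
        for r in rows:
            fh.write(
                f"{r.seq_id}\t{r.pwm_id}\t{r.model_id}\t{r.vote_fraction:.6f}\t"
                f"{int(r.binding_call)}\t{r.best_site_start + 1}\t{r.best_site_score:.6f}\n"
            )
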