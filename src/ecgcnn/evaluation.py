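"""Confusion-matrix evaluation and the optional WFDB beat extractor."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ecgcnn import model, wfdb_io
from ecgcnn.model import BeatClass

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "per_class_recall",
    "percent_recall",
    "overall_accuracy",
    "evaluate",
    "extract_mitbih_beats",
]

N = model.N_CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 integer counts; rows = labeled class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N, N):
            raise ValueError(f"confusion matrix must be {N}x{N}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion_matrix(labels, predictions) -> ConfusionMatrix:
    """counts[i, j] = number of beats labeled i and predicted j."""
    y = np.asarray([int(v) for v in labels], dtype=np.int64)
    p = np.asarray([int(v) for v in predictions], dtype=np.int64)
    if y.shape != p.shape:
        raise ValueError(f"labels ({y.shape}) and predictions ({p.shape}) differ in length")
    if y.size and (y.min() < 0 or y.max() >= N or p.min() < 0 or p.max() >= N):
        raise ValueError("class indices must be in 0..5")
    counts = np.zeros((N, N), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    return ConfusionMatrix(counts)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalized diagonal: recall[i] = counts[i, i] / row_total[i]."""
    rows = cm.row_sums
    if np.any(rows == 0):
        missing = [BeatClass(i).code for i in np.flatnonzero(rows == 0)]
        raise ValueError(f"recall undefined for classes with no test beats: {missing}")
    return np.diag(cm.counts) / rows


def percent_recall(cm: ConfusionMatrix) -> list[int]:
    """Per-class recall as whole percents, rounded half-up."""
    return [int(np.floor(r * 100.0 + 0.5)) for r in per_class_recall(cm)]


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """trace / total count."""
    if cm.total == 0:
        raise ValueError("overall accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class EvalReport:
    matrix: ConfusionMatrix
    recalls: np.ndarray
    percent_recalls: list[int]
    accuracy: float

    def to_tsv(self, path) -> None:
        codes = [BeatClass(i).code for i in range(N)]
        lines = ["label\\predict\t" + "\t".join(codes)]
        for i, row in enumerate(self.matrix.counts):
            lines.append(codes[i] + "\t" + "\t".join(str(int(v)) for v in row))
        lines.append("recall%\t" + "\t".join(str(p) for p in self.percent_recalls))
        lines.append(f"# overall_accuracy\t{self.accuracy:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(labels, predictions) -> EvalReport:
    cm = confusion_matrix(labels, predictions)
    return EvalReport(
        matrix=cm,
        recalls=per_class_recall(cm),
        percent_recalls=percent_recall(cm),
        accuracy=overall_accuracy(cm),
    )


# ---------------------------------------------------------------------------
# Optional: beat extraction from WFDB-format records
# ---------------------------------------------------------------------------

#: Annotation symbols kept for classification; everything else is skipped.
SYMBOL_TO_CLASS = {c.code: c for c in BeatClass}


@dataclass
class ExtractedBeats:
    tensors: np.ndarray        # (n, 2, 24)
    waveforms: np.ndarray      # (n, 48) raw windows
    labels: np.ndarray         # (n,)
    skipped_bounds: int        # annotations whose window left the record
    skipped_symbols: int       # annotations with unmapped symbols


def extract_mitbih_beats(record_path: str | Path, channel: int = 0) -> ExtractedBeats:
    """Extract labeled 48-sample beat windows from a WFDB record.

    ``record_path`` is the record name without extension (``.hea``/``.dat``
    and ``.atr`` must exist beside it).  A window covers samples R-23 ..
    R+24 around each annotated beat; windows exceeding the record bounds
    are skipped and counted, as are annotations whose symbol is not one of
    N, L, R, V, A, /.
    """
    record_path = Path(record_path)
    try:
        signal, _fs = wfdb_io.read_record(record_path)
        annotations = wfdb_io.read_annotations(record_path.with_suffix(".atr"))
    except OSError as exc:
        raise OSError(f"cannot read WFDB record {record_path.name!r}: {exc}") from exc
    trace = signal[:, channel].astype(np.float64)
    before = model.SAMPLES_BEFORE_R
    after = model.WINDOW_SAMPLES - before
    waves, labels = [], []
    skipped_bounds = skipped_symbols = 0
    for sample, symbol in annotations:
        cls = SYMBOL_TO_CLASS.get(symbol)
        if cls is None:
            skipped_symbols += 1
            continue
        lo, hi = sample - before, sample + after
        if lo < 0 or hi > len(trace):
            skipped_bounds += 1
            continue
        waves.append(trace[lo:hi])
        labels.append(int(cls))
    waveforms = np.asarray(waves, dtype=np.float64).reshape(-1, model.WINDOW_SAMPLES)
    tensors = (
        np.stack([model.preprocess_beat(wv) for wv in waveforms])
        if len(waveforms)
        else np.empty((0, 2, 24))
    )
    return ExtractedBeats(
        tensors=tensors,
        waveforms=waveforms,
        labels=np.asarray(labels, dtype=np.int64),
        skipped_bounds=skipped_bounds,
        skipped_symbols=skipped_symbols,
    )
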