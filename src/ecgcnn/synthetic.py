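"""Seeded synthetic six-class ECG beat generator.

Each beat is a sum of Gaussian bumps (one per characteristic wave: P, Q, R,
S, T, plus class-specific extras such as a pacing spike or a QRS notch)
sampled at 360 Hz over a 48-sample window centered on the R peak, with
per-beat parameter jitter and additive white Gaussian noise.

The six morphologies are caricatures — mutually distinguishable waveforms
sufficient to exercise a classifier — NOT clinical simulations.  All
parameters are plain data and can be edited or loaded from a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ecgcnn import model
from ecgcnn.model import BeatClass

__all__ = [
    "WaveComponent",
    "ClassMorphology",
    "GeneratorConfig",
    "LabeledDataset",
    "render_beat",
    "default_morphologies",
    "generate_dataset",
]


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: amplitude (normalized), center and sigma in ms
    relative to the R peak."""

    name: str
    amplitude: float
    center_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"component {self.name!r}: width must be positive")


@dataclass(frozen=True)
class ClassMorphology:
    beat_class: BeatClass
    components: tuple[WaveComponent, ...]
    jitter: float = 0.05          # relative spread applied per parameter
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if not any(c.name == "R" for c in self.components):
            raise ValueError("every morphology must contain an R component")


@dataclass(frozen=True)
class GeneratorConfig:
    sampling_rate: int = 360      # fixed by the source database convention
    window: int = 48
    noise_sigma: float = 0.02     # additive white noise, normalized units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate != 360:
            raise ValueError("sampling_rate is fixed at 360 Hz")
        if self.window % 2 != 0 or self.window <= 0:
            raise ValueError("window must be a positive even sample count")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _window_times_ms(cfg: GeneratorConfig) -> np.ndarray:
    # Sample i sits at (i - (window/2 - 1)) / fs seconds from the R peak,
    # i.e. the window covers R-23 .. R+24 for the default 48 samples.
    before = cfg.window // 2 - 1
    idx = np.arange(cfg.window) - before
    return idx * 1000.0 / cfg.sampling_rate


def render_beat(
    m: ClassMorphology,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one jittered, noisy 48-sample beat. Deterministic given seed.

    When ``rng`` is omitted a fresh generator is built from ``cfg.seed``,
    so repeated calls return the identical waveform; pass a shared ``rng``
    to draw a stream of distinct beats.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = _window_times_ms(cfg)
    signal = np.zeros(cfg.window)
    for comp in m.components:
        a = comp.amplitude * (1.0 + m.jitter * rng.standard_normal())
        mu = comp.center_ms * (1.0 + m.jitter * rng.standard_normal())
        sigma = max(comp.width_ms * (1.0 + m.jitter * rng.standard_normal()), 0.25)
        signal += a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))
    if cfg.noise_sigma > 0:
        signal += cfg.noise_sigma * rng.standard_normal(cfg.window)
    return signal


def default_morphologies() -> tuple[ClassMorphology, ...]:
    """One morphology per class, in class order N, L, R, V, A, /.

    All features live inside the ±65 ms half-window around R (at 360 Hz a
    48-sample window only spans R-64 ms .. R+67 ms), so the discriminative
    structure is QRS-and-near-field shape: widened/notched QRS for the
    bundle-branch blocks, a broad ectopic complex with discordant T for
    PVC, an early prominent P for APB, and a narrow stimulus spike for
    paced beats.
    """
    W = WaveComponent
    return (
        ClassMorphology(BeatClass.NORMAL, (
            W("P", 0.20, -50.0, 8.0),
            W("Q", -0.15, -16.0, 5.0),
            W("R", 1.00, 0.0, 6.0),
            W("S", -0.25, 16.0, 5.0),
            W("T", 0.35, 45.0, 12.0),
        )),
        ClassMorphology(BeatClass.LBBB, (
            W("P", 0.10, -52.0, 8.0),
            W("R", 0.85, -8.0, 14.0),
            W("R_notch", 0.50, 14.0, 10.0),
            W("T", -0.30, 48.0, 14.0),
        ), extras={"feature": "wide notched QRS, discordant T"}),
        ClassMorphology(BeatClass.RBBB, (
            W("P", 0.20, -50.0, 8.0),
            W("R", 0.75, -6.0, 6.0),
            W("R_prime", 0.65, 18.0, 8.0),
            W("S", -0.45, 38.0, 10.0),
            W("T", 0.15, 55.0, 9.0),
        ), extras={"feature": "rsR' pattern with deep slurred S"}),
        ClassMorphology(BeatClass.PVC, (
            W("R", 0.95, 2.0, 16.0),
            W("S", -0.55, 28.0, 12.0),
            W("T", -0.45, 52.0, 14.0),
        ), extras={"feature": "no P, broad complex, inverted T"}),
        ClassMorphology(BeatClass.APB, (
            W("P", 0.38, -38.0, 6.0),
            W("Q", -0.10, -15.0, 5.0),
            W("R", 0.90, 0.0, 6.0),
            W("S", -0.20, 15.0, 5.0),
            W("T", 0.30, 44.0, 12.0),
        ), extras={"feature": "early, prominent ectopic P"}),
        ClassMorphology(BeatClass.PACED, (
            W("spike", 0.90, -30.0, 1.5),
            W("R", 0.65, 8.0, 12.0),
            W("T", -0.35, 48.0, 13.0),
        ), extras={"feature": "narrow pacing stimulus before a wide QRS"}),
    )


def class_mean_waveforms(
    morphologies: tuple[ClassMorphology, ...] | None = None,
    cfg: GeneratorConfig | None = None,
) -> np.ndarray:
    """Noiseless, jitter-free mean waveform per class, shape (6, window)."""
    morphologies = morphologies or default_morphologies()
    cfg = cfg or GeneratorConfig()
    clean = replace(cfg, noise_sigma=0.0)
    means = []
    for m in sorted(morphologies, key=lambda m: m.beat_class):
        means.append(render_beat(replace(m, jitter=0.0), clean))
    return np.stack(means)


@dataclass
class LabeledDataset:
    """Beat tensors with labels and a disjoint train/test split.

    ``waveforms`` keeps the raw 48-sample windows; ``tensors`` the
    preprocessed 2x24 network inputs.
    """

    waveforms: np.ndarray          # (n, 48)
    tensors: np.ndarray            # (n, 2, 24)
    labels: np.ndarray             # (n,) int class indices
    split: np.ndarray              # (n,) "train" | "test"

    def _mask(self, tag: str) -> np.ndarray:
        return self.split == tag

    @property
    def train_x(self) -> np.ndarray:
        return self.tensors[self._mask("train")]

    @property
    def train_y(self) -> np.ndarray:
        return self.labels[self._mask("train")]

    @property
    def test_x(self) -> np.ndarray:
        return self.tensors[self._mask("test")]

    @property
    def test_y(self) -> np.ndarray:
        return self.labels[self._mask("test")]

    def __len__(self) -> int:
        return len(self.labels)

    def save_tsv(self, path) -> None:
        """One row per beat: 48 raw samples, class code, split tag."""
        from pathlib import Path

        lines = []
        for wave, lab, tag in zip(self.waveforms, self.labels, self.split):
            samples = "\t".join(f"{v:.6g}" for v in wave)
            lines.append(f"{samples}\t{BeatClass(int(lab)).code}\t{tag}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_tsv(cls, path) -> "LabeledDataset":
        from pathlib import Path

        waves, labels, tags = [], [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            waves.append([float(v) for v in parts[:-2]])
            labels.append(int(BeatClass.from_code(parts[-2])))
            tags.append(parts[-1])
        waveforms = np.asarray(waves, dtype=np.float64)
        tensors = np.stack([model.preprocess_beat(wv) for wv in waveforms])
        return cls(
            waveforms=waveforms,
            tensors=tensors,
            labels=np.asarray(labels, dtype=np.int64),
            split=np.asarray(tags),
        )


def generate_dataset(
    n_train_per_class: int = 2000,
    n_test_per_class: int = 500,
    cfg: GeneratorConfig | None = None,
    morphologies: tuple[ClassMorphology, ...] | None = None,
) -> LabeledDataset:
    """Render a labeled six-class dataset with disjoint train/test splits.

    Defaults follow the published evaluation sizes: 2000 train + 500 test
    beats per class (12,000 + 3,000 = 15,000 total).
    """
    if n_train_per_class < 1 or n_test_per_class < 1:
        raise ValueError("per-class counts must be >= 1")
    cfg = cfg or GeneratorConfig()
    morphologies = morphologies or default_morphologies()
    rng = np.random.default_rng(cfg.seed)
    waves, labels, tags = [], [], []
    per_class = n_train_per_class + n_test_per_class
    for m in sorted(morphologies, key=lambda m: m.beat_class):
        for i in range(per_class):
            waves.append(render_beat(m, cfg, rng))
            labels.append(int(m.beat_class))
            tags.append("train" if i < n_train_per_class else "test")
    waveforms = np.stack(waves)
    tensors = np.stack([model.preprocess_beat(wv) for wv in waveforms])
    return LabeledDataset(
        waveforms=waveforms,
        tensors=tensors,
        labels=np.asarray(labels, dtype=np.int64),
        split=np.asarray(tags),
    )
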