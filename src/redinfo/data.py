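"""Sample containers shared by the samplers, decoders and benchmarks.

A :class:`LabeledDataset` holds one observation matrix per source (rows are
aligned across sources) together with a single discrete label vector -- the
unit of training and evaluation throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Row-aligned observation matrices for n sources plus a discrete target.

    Parameters
    ----------
    sources
        One 2-D float array per source; all must share the same row count.
    labels
        Integer class vector in ``{0, ..., n_classes - 1}``.
    n_classes
        Number of target classes ``K``.
    """

    sources: list[np.ndarray] = field()
    labels: np.ndarray = field()
    n_classes: int = field()

    def __post_init__(self) -> None:
        self.sources = [np.asarray(s, dtype=np.float64) for s in self.sources]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.sources:
            raise ValueError("at least one source matrix is required")
        for i, s in enumerate(self.sources):
            if s.ndim != 2:
                raise ValueError(f"source {i} must be 2-D, got shape {s.shape}")
            if s.shape[0] != self.labels.shape[0]:
                raise ValueError(
                    f"source {i} has {s.shape[0]} rows but there are "
                    f"{self.labels.shape[0]} labels"
                )
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}); "
                f"observed range [{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_samples(self) -> int:
        return int(self.labels.shape[0])

    def label_entropy_bits(self) -> float:
        """Plug-in Shannon entropy of the empirical label frequencies, in bits."""
        if self.n_samples == 0:
            raise ValueError("empty dataset has no label entropy")
        counts = np.bincount(self.labels, minlength=self.n_classes)
        p = counts[counts > 0] / self.n_samples
        return float(-(p * np.log2(p)).sum())

    def split(self, fraction: float, rng: np.random.Generator) -> tuple[
        "LabeledDataset", "LabeledDataset"
    ]:
        """Shuffle rows and split into two datasets (``fraction`` goes first)."""
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        perm = rng.permutation(self.n_samples)
        k = int(round(fraction * self.n_samples))
        a, b = perm[:k], perm[k:]
        return (
            LabeledDataset([s[a] for s in self.sources], self.labels[a], self.n_classes),
            LabeledDataset([s[b] for s in self.sources], self.labels[b], self.n_classes),
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, directory: str | Path, prefix: str = "dataset") -> list[Path]:
        """Write one ``<prefix>_source<i>.csv`` per source plus ``<prefix>_labels.csv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for i, s in enumerate(self.sources):
            path = directory / f"{prefix}_source{i}.csv"
            cols = [f"f{j}" for j in range(s.shape[1])]
            pd.DataFrame(s, columns=cols).to_csv(path, index=False)
            written.append(path)
        lpath = directory / f"{prefix}_labels.csv"
        pd.DataFrame({"label": self.labels}).to_csv(lpath, index=False)
        written.append(lpath)
        return written

    @classmethod
    def from_csv(
        cls,
        source_paths: Sequence[str | Path],
        labels_path: str | Path,
        n_classes: int | None = None,
    ) -> "LabeledDataset":
        """Load source matrices and labels written by :meth:`to_csv`."""
        sources = [pd.read_csv(p).to_numpy(dtype=np.float64) for p in source_paths]
        ldf = pd.read_csv(labels_path)
        if "label" not in ldf.columns:
            raise ValueError(f"{labels_path} must contain a 'label' column")
        labels = ldf["label"].to_numpy(dtype=np.int64)
        if n_classes is None:
            n_classes = int(labels.max()) + 1 if labels.size else 1
        return cls(sources, labels, n_classes)
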