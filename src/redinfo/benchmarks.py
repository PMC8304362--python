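"""Packaged experiments.

Two families of experiments ship with the package:

* the canonical-distribution suite: sample each benchmark distribution
  (UNQ, AND, RDNXOR, IMPERFECTRDN), run the constrained redundancy estimator,
  and tabulate the estimates next to the exact common-variable oracle and the
  literature reference values;

* a synthetic "class overlap" task emulating paired population recordings:
  two sources of class-selective units observe overlapping subsets of 8
  classes, optionally padded with per-source noise units and with shared
  label-independent units.  The sweep over overlap / noise / shared-unit
  counts contrasts redundant information (which ignores label-independent
  structure) with raw cosine similarity between the observation vectors
  (which does not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .estimator import RedundancyEstimate, RedundancyEstimator
from .pmf import CANONICAL_TASKS, entropy_bits, i_cap_wedge_bits, make_canonical, sample_dataset

__all__ = [
    "BenchmarkReport",
    "OverlapTaskSpec",
    "run_canonical_suite",
    "make_overlap_task",
    "cosine_similarity_mean",
    "overlap_ground_truth_pmf",
    "run_overlap_sweep",
    "CANONICAL_REFERENCE",
]

logger = logging.getLogger("redinfo")

MAX_SEED = 2**31 - 1

# literature ground truth per canonical task: (true redundancy, wedge oracle)
CANONICAL_REFERENCE: dict[str, dict] = {
    "UNQ": {"true": "0", "wedge_bits": 0.0},
    "AND": {"true": "[0, 0.311]", "wedge_bits": 0.0},
    "RDNXOR": {"true": "1", "wedge_bits": 1.0},
    "IMPERFECTRDN": {"true": "0.99", "wedge_bits": 0.0},
}


@dataclass
class BenchmarkReport:
    """Per-task rows of the canonical suite plus the full estimates."""

    rows: list[dict] = field(default_factory=list)
    estimates: dict[str, RedundancyEstimate] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        """Pretty table of estimates (all quantities in bits)."""
        lines = [
            f"{'task':<14}{'true':>12}{'I_wedge [bits]':>16}"
            f"{'estimate [bits]':>18}{'sd [bits]':>12}"
        ]
        for row in self.rows:
            if row.get("error"):
                lines.append(f"{row['task']:<14}  FAILED: {row['error']}")
                continue
            sd = "-" if row["sd_bits"] is None else f"{row['sd_bits']:.4f}"
            lines.append(
                f"{row['task']:<14}{row['true_value']:>12}"
                f"{row['oracle_wedge_bits']:>16.3f}"
                f"{row['mean_bits']:>18.4f}{sd:>12}"
            )
        return "\n".join(lines)


def run_canonical_suite(
    beta_final: float = 15.0,
    n_seeds: int = 5,
    base_seed: int = 0,
    *,
    n_train: int = 10_000,
    n_test: int = 10_000,
    epochs: int = 150,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    hidden_layer_sizes: tuple[int, ...] = (64, 64),
    tasks: Sequence[str] = CANONICAL_TASKS,
) -> BenchmarkReport:
    """Estimate redundancy on each canonical task and tabulate against oracles.

    Deterministic given ``base_seed``: sampling seeds and per-run training
    seeds are all derived from it.  A failing task is recorded in its row and
    the suite continues.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    report = BenchmarkReport()
    ss = np.random.SeedSequence(base_seed)
    for task, task_ss in zip(tasks, ss.spawn(len(tasks))):
        pmf = make_canonical(task)
        wedge = i_cap_wedge_bits(pmf)
        h_y = entropy_bits(pmf, "y")
        sample_seed, test_seed, run_ss = task_ss.spawn(3)
        run_seeds = [
            int(s.generate_state(1)[0] % MAX_SEED) for s in run_ss.spawn(n_seeds)
        ]
        row = {
            "task": task,
            "beta_final": beta_final,
            "true_value": CANONICAL_REFERENCE[task]["true"],
            "oracle_wedge_bits": wedge,
            "n_seeds": n_seeds,
            "mean_bits": np.nan,
            "sd_bits": None,
            "error": "",
        }
        try:
            train = sample_dataset(pmf, n_train, int(sample_seed.generate_state(1)[0] % MAX_SEED))
            test = sample_dataset(pmf, n_test, int(test_seed.generate_state(1)[0] % MAX_SEED))
            est = RedundancyEstimator(
                hidden_layer_sizes=hidden_layer_sizes,
                epochs=epochs,
                batch_size=batch_size,
                learning_rate=learning_rate,
                beta_final=beta_final,
                seeds=run_seeds,
            )
            est.fit(train, train.labels, X_eval=test, y_eval=test.labels, h_y_bits=h_y)
            result = est.result()
            report.estimates[task] = result
            row["mean_bits"] = result.mean_bits
            row["sd_bits"] = result.sd_bits
            logger.info(
                "%s: estimate %.4f bits (sd %s), wedge oracle %.3f bits",
                task, result.mean_bits,
                "n/a" if result.sd_bits is None else f"{result.sd_bits:.4f}",
                wedge,
            )
        except Exception as err:  # keep the suite alive past one bad task
            logger.exception("task %s failed", task)
            row["error"] = str(err)
        report.rows.append(row)
    return report


# ---------------------------------------------------------------------------
# synthetic class-overlap task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTaskSpec:
    """Generative settings for the two-source class-overlap task.

    Eight balanced classes; source 1 encodes the first ``n_encoded_per_source``
    classes and source 2 the last ``n_encoded_per_source``, so
    ``2 * n_encoded_per_source - 8`` classes are encoded by both.  Each source
    observes class-selective informative units driven by its *effective*
    class ``g_s(Y)``: encoded classes map to themselves, while every
    non-encoded class is aliased onto an encoded one through a cyclic shift.
    The aliasing hides set membership (otherwise "is the class in my encoded
    set" would itself be a redundant bit shared by both sources) and is
    chosen so the co-occurrence graph of ``(g_1(Y), g_2(Y))`` links all
    non-overlap classes into a single block: the exact common-variable
    redundancy is then 0 bits at minimum overlap (n=4) and the full
    H(Y) = 3 bits at n=8 (see :func:`overlap_ground_truth_pmf`).

    Informative units have mean ``selective_mean`` when the unit's class
    equals ``g_s(Y)`` and 0 otherwise, with Gaussian noise of scale
    ``noise_scale``.  Noise units are independent standard normal draws per
    source; shared non-task units are label-independent standard normal
    draws appended identically to both sources.
    """

    n_encoded_per_source: int = 6
    n_informative_units: int = 10
    n_noise_units: int = 0
    n_shared_nontask_units: int = 0
    noise_scale: float = 1.0
    selective_mean: float = 4.0
    samples_per_class: int = 100
    seed: int = 0
    n_classes_total: int = 8

    def __post_init__(self):
        if self.n_classes_total != 8:
            raise ValueError("the overlap task is defined over 8 classes")
        if not 4 <= self.n_encoded_per_source <= 8:
            raise ValueError(
                "n_encoded_per_source must be in [4, 8] so that the class "
                "overlap 2*n - 8 is non-negative"
            )
        if self.n_informative_units < self.n_encoded_per_source:
            raise ValueError("need at least one informative unit per encoded class")
        if min(self.n_noise_units, self.n_shared_nontask_units) < 0:
            raise ValueError("unit counts must be non-negative")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")

    @property
    def overlap(self) -> int:
        """Number of classes encoded by both sources."""
        return 2 * self.n_encoded_per_source - self.n_classes_total

    def encoded_classes(self, source: int) -> tuple[int, ...]:
        k, total = self.n_encoded_per_source, self.n_classes_total
        if source == 0:
            return tuple(range(k))
        if source == 1:
            return tuple(range(total - k, total))
        raise ValueError("source must be 0 or 1")

    def effective_class_map(self, source: int) -> np.ndarray:
        """``g_s``: class -> the encoded class whose pattern the source observes.

        Encoded classes map to themselves.  The ``m = 8 - n`` classes each
        source does not encode are aliased onto encoded classes: source 1
        maps class ``n + i`` to ``i``, source 2 maps class ``i`` to
        ``n + (i + 1) mod m``; the off-by-one shift makes the bipartite
        co-occurrence graph of ``(g_1(Y), g_2(Y))`` a single cycle over the
        non-overlap classes, so they contribute no common variable.
        """
        n, total = self.n_encoded_per_source, self.n_classes_total
        m = total - n
        g = np.arange(total)
        if m == 0:
            return g
        if source == 0:
            for i in range(m):
                g[n + i] = i
        else:
            for i in range(m):
                g[i] = n + (i + 1) % m
        return g


def _overlap_split(spec: OverlapTaskSpec, ss: np.random.SeedSequence) -> LabeledDataset:
    # separate substreams per component so that adding noise or shared units
    # leaves the labels and informative activations bitwise unchanged
    lab_ss, inf0_ss, inf1_ss, noise0_ss, noise1_ss, shared_ss = ss.spawn(6)
    n = spec.samples_per_class * spec.n_classes_total
    labels = np.random.default_rng(lab_ss).permutation(
        np.repeat(np.arange(spec.n_classes_total), spec.samples_per_class)
    )
    shared = np.random.default_rng(shared_ss).standard_normal(
        (n, spec.n_shared_nontask_units)
    )
    sources = []
    for s, inf_ss, noise_ss in ((0, inf0_ss, noise0_ss), (1, inf1_ss, noise1_ss)):
        enc = spec.encoded_classes(s)
        effective = spec.effective_class_map(s)[labels]
        # unit u is selective for enc[u % len(enc)]
        unit_class = np.array([enc[u % len(enc)] for u in range(spec.n_informative_units)])
        means = spec.selective_mean * (effective[:, None] == unit_class[None, :])
        informative = means + spec.noise_scale * np.random.default_rng(
            inf_ss
        ).standard_normal((n, spec.n_informative_units))
        noise = np.random.default_rng(noise_ss).standard_normal((n, spec.n_noise_units))
        sources.append(np.hstack([informative, noise, shared]))
    return LabeledDataset(sources, labels, n_classes=spec.n_classes_total)


def make_overlap_task(spec: OverlapTaskSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Generate train and test splits (independent draws) of the overlap task."""
    ss = np.random.SeedSequence(spec.seed)
    train_ss, test_ss = ss.spawn(2)
    return _overlap_split(spec, train_ss), _overlap_split(spec, test_ss)


def overlap_ground_truth_pmf(spec: OverlapTaskSpec):
    """Discrete skeleton of the overlap task: p(g1(Y), g2(Y), Y), Y uniform.

    In the noiseless limit each source observes exactly its effective class,
    so the common-variable redundancy of this pmf (``i_cap_wedge_bits``) is
    the ground-truth redundancy of the overlap task.
    """
    from .pmf import JointPMF

    total = spec.n_classes_total
    g1 = spec.effective_class_map(0)
    g2 = spec.effective_class_map(1)
    table = {
        (int(g1[c]), int(g2[c]), c): 1.0 / total for c in range(total)
    }
    return JointPMF(
        (tuple(sorted(set(map(int, g1)))), tuple(sorted(set(map(int, g2))))),
        tuple(range(total)),
        table,
    )


def cosine_similarity_mean(d1: np.ndarray, d2: np.ndarray) -> float:
    """Mean over paired rows of the cosine of the angle between observations."""
    d1 = np.asarray(d1, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    if d1.shape != d2.shape:
        raise ValueError(f"matrices must share shape, got {d1.shape} vs {d2.shape}")
    n1 = np.linalg.norm(d1, axis=1)
    n2 = np.linalg.norm(d2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-norm rows have no direction")
    return float(((d1 * d2).sum(axis=1) / (n1 * n2)).mean())


def run_overlap_sweep(
    n_encoded_values: Sequence[int],
    noise_unit_counts: Sequence[int],
    shared_unit_counts: Sequence[int],
    seeds: Sequence[int],
    *,
    samples_per_class: int = 100,
    epochs: int = 100,
    beta_final: float = 50.0,
    hidden_layer_sizes: tuple[int, ...] = (64, 64),
    activation: str = "tanh",
    batch_size: int = 64,
    learning_rate: float = 1e-3,
) -> pd.DataFrame:
    """Factorial sweep over overlap / noise / shared-unit counts.

    For every grid cell and seed, generates the overlap task, computes the
    constrained redundancy estimate (one training run per seed) and the mean
    cosine similarity between the paired source observations.  Returns a
    long-format table with columns ``n_encoded, n_noise_units,
    n_shared_units, seed, metric, value``; redundancy values are in bits.
    """
    for grid, name in (
        (n_encoded_values, "n_encoded_values"),
        (noise_unit_counts, "noise_unit_counts"),
        (shared_unit_counts, "shared_unit_counts"),
        (seeds, "seeds"),
    ):
        if not len(grid):
            raise ValueError(f"{name} must be non-empty")
    records: list[dict] = []
    for n_enc in n_encoded_values:
        for n_noise in noise_unit_counts:
            for n_shared in shared_unit_counts:
                for seed in seeds:
                    cell = dict(
                        n_encoded=n_enc,
                        n_noise_units=n_noise,
                        n_shared_units=n_shared,
                        seed=seed,
                    )
                    spec = OverlapTaskSpec(
                        n_encoded_per_source=n_enc,
                        n_noise_units=n_noise,
                        n_shared_nontask_units=n_shared,
                        samples_per_class=samples_per_class,
                        seed=int(seed),
                    )
                    try:
                        train, test = make_overlap_task(spec)
                        est = RedundancyEstimator(
                            hidden_layer_sizes=hidden_layer_sizes,
                            activation=activation,
                            epochs=epochs,
                            batch_size=batch_size,
                            learning_rate=learning_rate,
                            beta_final=beta_final,
                            seeds=[int(seed)],
                        )
                        est.fit(
                            train, train.labels,
                            X_eval=test, y_eval=test.labels,
                            h_y_bits=float(np.log2(spec.n_classes_total)),
                        )
                        records.append(
                            {**cell, "metric": "redundancy_bits",
                             "value": est.redundancy_bits_}
                        )
                        records.append(
                            {**cell, "metric": "cosine_similarity",
                             "value": cosine_similarity_mean(*train.sources)}
                        )
                    except Exception as err:
                        logger.exception("sweep cell %s failed", cell)
                        records.append({**cell, "metric": "error", "value": str(err)})
    return pd.DataFrame.from_records(records)
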