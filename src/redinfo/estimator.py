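"""Agreement-constrained neural estimation of redundant information.

The redundancy of sources ``X1, ..., Xn`` about a discrete target ``Y``,
relative to a decoder family ``V``, is defined through a constrained
minimisation: fit one probabilistic decoder per source, require their
predicted distributions over ``Y`` to agree (expected L1 distance zero), and
report

    I_V = H(Y) - min (1/n) * sum_i H_fi(Y | Xi)   s.t.  D(fi, fj) = 0,

where ``H_fi`` is the test cross-entropy of decoder ``i`` in bits.  The
constrained problem is solved by minimising the Lagrangian

    (1/n) * sum_i H_fi(Y | Xi) + beta * sum_{i<j} D(fi, fj)

with the penalty coefficient ``beta`` reverse-annealed from a small value up
to its final value during training: starting with a large ``beta`` tends to
collapse both decoders onto a constant prediction (which satisfies the
constraint trivially but carries no information).

With a single source the constrained problem degenerates to ordinary
cross-entropy minimisation and the estimate becomes the "usable information"
H(Y) - H_V(Y|X), the decoder-limited analogue of mutual information.

The decoder family here is fully-connected softmax networks trained with
Adam or SGD (see ``_mlp``); the main entry point is the scikit-learn style
:class:`RedundancyEstimator`, with thin functional wrappers below it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._mlp import MLP, PROB_FLOOR, cross_entropy_grad_logits, l1_distance_grad_logits, make_optimizer
from .data import LabeledDataset

__all__ = [
    "BetaSchedule",
    "DecoderFamilySpec",
    "TrainConfig",
    "RedundancyEstimate",
    "SingleRunResult",
    "TrainingError",
    "ConstantPredictionWarning",
    "MLPSoftmaxDecoder",
    "RedundancyEstimator",
    "beta_at",
    "cross_entropy_bits",
    "prediction_distance",
    "lagrangian_bits",
    "train_rine",
    "usable_information_bits",
    "estimate_redundancy",
    "estimate_redundancy_multisource",
]

logger = logging.getLogger("redinfo")

MAX_SEED = 2**31 - 1


class TrainingError(RuntimeError):
    """Raised when optimisation produces non-finite losses or gradients."""


class ConstantPredictionWarning(UserWarning):
    """A decoder's predictions are (near-)constant across inputs.

    The agreement constraint is satisfied trivially by constant decoders; for
    genuinely redundancy-free tasks this is the correct optimum, but on tasks
    with known redundancy it signals a collapsed (too aggressive beta)
    optimisation.
    """


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaSchedule:
    """Reverse-annealing profile for the agreement penalty coefficient.

    ``beta`` ramps linearly from ``beta_start`` to ``beta_final`` over the
    first ``ramp_fraction`` of training and stays at ``beta_final`` after.
    """

    beta_start: float = 0.0
    beta_final: float = 50.0
    ramp_fraction: float = 0.8

    def __post_init__(self):
        if self.beta_start < 0 or self.beta_final < 0:
            raise ValueError("beta values must be non-negative")
        if self.beta_start > self.beta_final:
            raise ValueError("beta_start must not exceed beta_final")
        if not 0.0 < self.ramp_fraction <= 1.0:
            raise ValueError("ramp_fraction must be in (0, 1]")

    def beta_at(self, progress: float) -> float:
        """Penalty coefficient at training progress ``progress`` in [0, 1]."""
        if not 0.0 <= progress <= 1.0:
            raise ValueError(f"progress must be in [0, 1], got {progress}")
        if progress >= self.ramp_fraction:
            return self.beta_final
        t = progress / self.ramp_fraction
        return self.beta_start + t * (self.beta_final - self.beta_start)


def beta_at(schedule: BetaSchedule, progress: float) -> float:
    """Functional alias for :meth:`BetaSchedule.beta_at`."""
    return schedule.beta_at(progress)


@dataclass(frozen=True)
class DecoderFamilySpec:
    """Declarative description of the decoder function family for one source.

    Only the fully-connected family is implemented (hidden widths + pointwise
    nonlinearity, softmax output over ``n_classes``).  Input dimensionality
    and class count may be left ``None`` to be inferred from data.
    """

    kind: str = "fully_connected"
    hidden: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    n_inputs: int | None = None
    n_classes: int | None = None

    def __post_init__(self):
        if self.kind != "fully_connected":
            raise NotImplementedError(
                f"decoder family {self.kind!r} is not implemented; "
                "only 'fully_connected' is available"
            )
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by all decoders of a run."""

    epochs: int = 150
    batch_size: int = 256
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    beta: BetaSchedule = field(default_factory=BetaSchedule)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SingleRunResult:
    """Outcome of one seeded constrained-training run."""

    redundancy_bits: float
    cross_entropies_bits: tuple[float, ...]
    final_distance: float
    h_y_bits: float
    seed: int
    decoders: list["MLPSoftmaxDecoder"] = field(repr=False, default_factory=list)


@dataclass
class RedundancyEstimate:
    """Multi-seed aggregate of the constrained redundancy estimate."""

    per_seed_bits: list[float]
    mean_bits: float
    sd_bits: float | None
    h_y_bits: float
    per_seed_cross_entropies: list[tuple[float, ...]]
    final_distances: list[float]
    beta_final: float
    seeds: list[int]
    n_sources: int
    failures: dict[int, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["units"] = "bits"
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def _proba(decoder, X: np.ndarray) -> np.ndarray:
    p = decoder.predict_proba(X)
    return np.asarray(p, dtype=np.float64)


def cross_entropy_bits(decoder, data: LabeledDataset, source_index: int) -> float:
    """Empirical mean of ``-log2 f(y | x)`` over the indexed source, in bits."""
    X = data.sources[source_index]
    n_in = getattr(decoder, "n_features_in_", None)
    if n_in is not None and n_in != X.shape[1]:
        raise ValueError(
            f"decoder expects {n_in} features but source {source_index} has {X.shape[1]}"
        )
    p = _proba(decoder, X)
    picked = np.clip(p[np.arange(data.n_samples), data.labels], PROB_FLOOR, None)
    return float(-np.log2(picked).mean())


def prediction_distance(f1, f2, data: LabeledDataset) -> float:
    """Expected L1 distance between the two decoders' predicted distributions.

    Estimated over jointly observed rows (x1 and x2 from the same
    observation); lies in [0, 2].
    """
    if data.n_sources < 2:
        raise ValueError("prediction distance needs two sources")
    X1, X2 = data.sources[0], data.sources[1]
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("source matrices must share the row count")
    p1, p2 = _proba(f1, X1), _proba(f2, X2)
    if p1.shape != p2.shape:
        raise ValueError("decoders must predict over the same class set")
    return float(np.abs(p1 - p2).sum(axis=1).mean())


def lagrangian_bits(f1, f2, data: LabeledDataset, beta: float) -> float:
    """Penalised objective: mean cross-entropy (bits) + beta * L1 agreement."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    ce1 = cross_entropy_bits(f1, data, 0)
    ce2 = cross_entropy_bits(f2, data, 1)
    return 0.5 * (ce1 + ce2) + beta * prediction_distance(f1, f2, data)


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

class MLPSoftmaxDecoder(BaseEstimator, ClassifierMixin):
    """Fully-connected softmax classifier trained by cross-entropy (bits).

    A scikit-learn-compatible probabilistic decoder; also the per-source
    building block of :class:`RedundancyEstimator`, which trains several of
    these jointly under the agreement penalty.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden layer widths.
    activation : {"relu", "tanh"}
    epochs, batch_size, learning_rate, optimizer
        Mini-batch optimisation settings ("adam" or "sgd").
    n_classes : int or None
        Number of target classes; inferred as ``max(y) + 1`` when ``None``.
    random_state : int or None
        Seed for weight initialisation and batch shuffling.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 64),
        activation: str = "relu",
        epochs: int = 150,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        weight_decay: float = 0.0,
        n_classes: int | None = None,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.weight_decay = weight_decay
        self.n_classes = n_classes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        k = self.n_classes if self.n_classes is not None else int(y.max()) + 1
        data = LabeledDataset([X], y, n_classes=k)
        rng = np.random.default_rng(self.random_state)
        net = MLP(
            X.shape[1], k, tuple(self.hidden_layer_sizes), self.activation, rng
        )
        _joint_train(
            [net],
            data,
            BetaSchedule(0.0, 0.0, 1.0),
            epochs=self.epochs,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            rng=rng,
            weight_decay=self.weight_decay,
        )
        self.net_ = net
        self.classes_ = np.arange(k)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.net_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # ------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Write weights to ``<path>.npz`` and metadata to ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.state_dict())
        meta = {
            "hidden_layer_sizes": list(self.net_.hidden),
            "activation": self.net_.activation,
            "n_features_in": int(self.n_features_in_),
            "n_classes": int(self.net_.n_classes),
            "params": {
                k: v for k, v in self.get_params().items()
                if k != "hidden_layer_sizes"
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "MLPSoftmaxDecoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        dec = cls(
            hidden_layer_sizes=tuple(meta["hidden_layer_sizes"]),
            activation=meta["activation"],
            n_classes=meta["n_classes"],
        )
        net = MLP(
            meta["n_features_in"],
            meta["n_classes"],
            tuple(meta["hidden_layer_sizes"]),
            meta["activation"],
            np.random.default_rng(0),
        )
        with np.load(path.with_suffix(".npz")) as d:
            net.load_state_dict({k: d[k] for k in d.files})
        dec.net_ = net
        dec.classes_ = np.arange(meta["n_classes"])
        dec.n_features_in_ = meta["n_features_in"]
        return dec

    @classmethod
    def _from_net(cls, net: MLP, params: dict) -> "MLPSoftmaxDecoder":
        dec = cls(**params)
        dec.net_ = net
        dec.classes_ = np.arange(net.n_classes)
        dec.n_features_in_ = net.n_in
        return dec


# ---------------------------------------------------------------------------
# joint constrained training
# ---------------------------------------------------------------------------

def _joint_train(
    nets: list[MLP],
    data: LabeledDataset,
    schedule: BetaSchedule,
    *,
    epochs: int,
    batch_size: int,
    optimizer: str,
    learning_rate: float,
    rng: np.random.Generator,
    weight_decay: float = 0.0,
) -> None:
    """Minimise (1/n) sum_i CE_i(bits) + beta(t) * sum_{i<j} L1(p_i, p_j) in place."""
    n = data.n_samples
    if n == 0:
        raise ValueError("cannot train on an empty dataset")
    m = len(nets)
    params = [p for net in nets for p in net.parameters()]
    opt = make_optimizer(optimizer, params, learning_rate, weight_decay)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    total_steps = epochs * n_batches
    step = 0
    for epoch in range(epochs):
        perm = rng.permutation(n)
        ep_loss = ep_dist = 0.0
        beta = 0.0
        for b in range(n_batches):
            idx = perm[b * batch_size : (b + 1) * batch_size]
            yb = data.labels[idx]
            progress = step / max(total_steps - 1, 1)
            beta = schedule.beta_at(progress)
            # linear decay to 10% of the base rate lets the constrained pair
            # settle instead of orbiting the penalised optimum
            opt.lr = learning_rate * (1.0 - 0.9 * progress)
            probs, caches = [], []
            for i, net in enumerate(nets):
                p, c = net.forward(data.sources[i][idx])
                probs.append(p)
                caches.append(c)
            grads: list[np.ndarray] = []
            batch_ce = 0.0
            batch_d = 0.0
            for i, net in enumerate(nets):
                g = cross_entropy_grad_logits(probs[i], yb, 1.0 / m)
                for j in range(m):
                    if j != i:
                        g = g + l1_distance_grad_logits(probs[i], probs[j], beta)
                grads.extend(net.backward(caches[i], g))
                picked = np.clip(probs[i][np.arange(len(yb)), yb], PROB_FLOOR, None)
                batch_ce += float(-np.log2(picked).mean()) / m
            for i in range(m):
                for j in range(i + 1, m):
                    batch_d += float(np.abs(probs[i] - probs[j]).sum(axis=1).mean())
            if not all(np.all(np.isfinite(g)) for g in grads) or not np.isfinite(batch_ce):
                raise TrainingError(
                    f"non-finite loss/gradient at epoch {epoch}, batch {b} "
                    f"(beta={beta:.3g}, ce={batch_ce:.3g}, D={batch_d:.3g})"
                )
            opt.step(grads)
            ep_loss += batch_ce + beta * batch_d
            ep_dist += batch_d
            step += 1
        logger.info(
            "epoch %3d/%d  beta=%6.3f  loss=%8.4f bits  D=%7.4f",
            epoch + 1, epochs, beta, ep_loss / n_batches, ep_dist / n_batches,
        )


def _check_constant_predictions(
    decoders: Sequence[MLPSoftmaxDecoder], data: LabeledDataset, tol: float = 1e-6
) -> None:
    for i, dec in enumerate(decoders):
        p = dec.predict_proba(data.sources[i])
        if p.shape[0] > 1 and float(p.var(axis=0).max()) < tol:
            warnings.warn(
                f"decoder {i} predicts a near-constant distribution "
                "(possible collapse to the trivial agreeing solution)",
                ConstantPredictionWarning,
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class RedundancyEstimator(BaseEstimator):
    """Constrained multi-decoder estimator of redundant information (bits).

    Fits one softmax decoder per source on ``fit(Xs, y)`` where ``Xs`` is a
    sequence of row-aligned observation matrices, penalising disagreement
    between the decoders' predicted distributions with a reverse-annealed
    coefficient, and reports

        ``redundancy_bits_ = H(Y) - mean_i H_fi(Y | Xi)``

    with cross-entropies and the residual agreement distance evaluated on
    held-out data.  Training is repeated over ``n_runs`` seeds; the mean and
    sample standard deviation across seeds are exposed as fitted attributes.

    Parameters
    ----------
    hidden_layer_sizes, activation
        Shared decoder architecture (fully-connected family).
    epochs, batch_size, learning_rate, optimizer
        Mini-batch optimisation settings.
    beta_start, beta_final, ramp_fraction
        Agreement-penalty schedule: linear ramp from ``beta_start`` to
        ``beta_final`` over the first ``ramp_fraction`` of training.
    n_runs : int
        Number of independent initialisations to aggregate over.
    seeds : sequence of int or None
        Explicit per-run seeds; derived from ``random_state`` when ``None``.
    eval_fraction : float
        Held-out fraction used when no explicit evaluation set is passed to
        :meth:`fit`.
    n_classes : int or None
        Number of target classes (inferred when ``None``).
    random_state : int or None
        Master seed for the train/eval split and per-run seed derivation.

    Attributes
    ----------
    redundancy_bits_ : float
        Mean estimate over runs.
    sd_bits_ : float or None
        Sample standard deviation over runs (``None`` for a single run).
    per_run_bits_, cross_entropies_bits_, final_distances_, seeds_ : lists
        Per-run diagnostics.
    h_y_bits_ : float
        Target entropy used in the estimate.
    decoders_ : list of list of MLPSoftmaxDecoder
        Fitted decoders per run (one per source).
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 64),
        activation: str = "relu",
        epochs: int = 150,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        weight_decay: float = 0.0,
        beta_start: float = 0.0,
        beta_final: float = 50.0,
        ramp_fraction: float = 0.8,
        n_runs: int = 5,
        seeds: Sequence[int] | None = None,
        eval_fraction: float = 0.5,
        n_classes: int | None = None,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.weight_decay = weight_decay
        self.beta_start = beta_start
        self.beta_final = beta_final
        self.ramp_fraction = ramp_fraction
        self.n_runs = n_runs
        self.seeds = seeds
        self.eval_fraction = eval_fraction
        self.n_classes = n_classes
        self.random_state = random_state

    # ------------------------------------------------------------- fitting
    def _schedule(self) -> BetaSchedule:
        return BetaSchedule(self.beta_start, self.beta_final, self.ramp_fraction)

    def _run_seeds(self) -> list[int]:
        if self.seeds is not None:
            if not len(self.seeds):
                raise ValueError("seeds must be non-empty when given")
            return [int(s) for s in self.seeds]
        rng = np.random.default_rng(self.random_state)
        return [int(s) for s in rng.integers(0, MAX_SEED, size=self.n_runs)]

    def fit(self, X, y, X_eval=None, y_eval=None, h_y_bits: float | None = None):
        """Fit on row-aligned source matrices ``X`` (a sequence) and labels ``y``.

        When no evaluation set is given, ``eval_fraction`` of the rows is
        held out for the reported cross-entropies and distances.
        """
        train, evald = self._build_datasets(X, y, X_eval, y_eval)
        if train.n_sources < 2:
            raise ValueError(
                "redundancy needs >= 2 sources; for a single source use "
                "usable_information_bits (self-redundancy)"
            )
        if h_y_bits is None:
            pooled = np.concatenate([train.labels, evald.labels])
            counts = np.bincount(pooled, minlength=train.n_classes)
            p = counts[counts > 0] / counts.sum()
            h_y_bits = float(-(p * np.log2(p)).sum())
        schedule = self._schedule()
        seeds = self._run_seeds()

        per_bits: list[float] = []
        per_ce: list[tuple[float, ...]] = []
        per_d: list[float] = []
        ok_seeds: list[int] = []
        decoders_all: list[list[MLPSoftmaxDecoder]] = []
        failures: dict[int, str] = {}
        for seed in seeds:
            try:
                res = _single_run(
                    train, evald, self, schedule, seed, h_y_bits
                )
            except TrainingError as err:
                logger.error("seed %d failed: %s", seed, err)
                failures[seed] = str(err)
                continue
            per_bits.append(res.redundancy_bits)
            per_ce.append(res.cross_entropies_bits)
            per_d.append(res.final_distance)
            ok_seeds.append(seed)
            decoders_all.append(res.decoders)
        if not per_bits:
            raise TrainingError(
                f"all {len(seeds)} runs failed: {failures}"
            )
        self.per_run_bits_ = per_bits
        self.redundancy_bits_ = float(np.mean(per_bits))
        self.sd_bits_ = float(np.std(per_bits, ddof=1)) if len(per_bits) > 1 else None
        self.cross_entropies_bits_ = per_ce
        self.final_distances_ = per_d
        self.h_y_bits_ = h_y_bits
        self.seeds_ = ok_seeds
        self.failures_ = failures
        self.decoders_ = decoders_all
        self.n_sources_ = train.n_sources
        return self

    def _build_datasets(
        self, X, y, X_eval, y_eval
    ) -> tuple[LabeledDataset, LabeledDataset]:
        def as_dataset(Xs, ys) -> LabeledDataset:
            if isinstance(Xs, LabeledDataset):
                return Xs
            if isinstance(Xs, np.ndarray) and Xs.ndim == 2:
                Xs = [Xs]
            k = self.n_classes
            if k is None:
                k = int(np.max(ys)) + 1
            return LabeledDataset(list(Xs), ys, n_classes=k)

        full = as_dataset(X, y)
        if X_eval is None:
            if not 0.0 < self.eval_fraction < 1.0:
                raise ValueError("eval_fraction must be in (0, 1)")
            rng = np.random.default_rng(self.random_state)
            evald, train = full.split(self.eval_fraction, rng)
            return train, evald
        evald = as_dataset(X_eval, y_eval)
        if evald.n_sources != full.n_sources:
            raise ValueError("train and eval must have the same number of sources")
        return full, evald

    # -------------------------------------------------------------- output
    def result(self) -> RedundancyEstimate:
        """Aggregate the fitted state into a serialisable estimate."""
        return RedundancyEstimate(
            per_seed_bits=list(self.per_run_bits_),
            mean_bits=self.redundancy_bits_,
            sd_bits=self.sd_bits_,
            h_y_bits=self.h_y_bits_,
            per_seed_cross_entropies=list(self.cross_entropies_bits_),
            final_distances=list(self.final_distances_),
            beta_final=float(self.beta_final),
            seeds=list(self.seeds_),
            n_sources=self.n_sources_,
            failures=dict(self.failures_),
            config=self.get_params(),
        )


def _single_run(
    train: LabeledDataset,
    evald: LabeledDataset,
    est: RedundancyEstimator,
    schedule: BetaSchedule,
    seed: int,
    h_y_bits: float,
) -> SingleRunResult:
    rng = np.random.default_rng(seed)
    nets = [
        MLP(
            train.sources[i].shape[1],
            train.n_classes,
            tuple(est.hidden_layer_sizes),
            est.activation,
            rng,
        )
        for i in range(train.n_sources)
    ]
    _joint_train(
        nets,
        train,
        schedule,
        epochs=est.epochs,
        batch_size=est.batch_size,
        optimizer=est.optimizer,
        learning_rate=est.learning_rate,
        rng=rng,
        weight_decay=est.weight_decay,
    )
    dec_params = dict(
        hidden_layer_sizes=tuple(est.hidden_layer_sizes),
        activation=est.activation,
        epochs=est.epochs,
        batch_size=est.batch_size,
        learning_rate=est.learning_rate,
        optimizer=est.optimizer,
        weight_decay=est.weight_decay,
        n_classes=train.n_classes,
        random_state=seed,
    )
    decoders = [MLPSoftmaxDecoder._from_net(net, dec_params) for net in nets]
    ces = tuple(
        cross_entropy_bits(dec, evald, i) for i, dec in enumerate(decoders)
    )
    # mean pairwise residual agreement distance on held-out rows
    m = len(decoders)
    dists = [
        float(
            np.abs(
                decoders[i].predict_proba(evald.sources[i])
                - decoders[j].predict_proba(evald.sources[j])
            ).sum(axis=1).mean()
        )
        for i in range(m)
        for j in range(i + 1, m)
    ]
    _check_constant_predictions(decoders, evald)
    return SingleRunResult(
        redundancy_bits=float(h_y_bits - np.mean(ces)),
        cross_entropies_bits=ces,
        final_distance=float(np.mean(dists)),
        h_y_bits=h_y_bits,
        seed=seed,
        decoders=decoders,
    )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _estimator_from(
    families: Sequence[DecoderFamilySpec], config: TrainConfig, n_classes: int | None
) -> RedundancyEstimator:
    fams = list(families)
    first = fams[0]
    for f in fams[1:]:
        if (f.hidden, f.activation) != (first.hidden, first.activation):
            raise ValueError(
                "per-source decoder families must share architecture "
                "(a single family V is optimised over)"
            )
    return RedundancyEstimator(
        hidden_layer_sizes=first.hidden,
        activation=first.activation,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        optimizer=config.optimizer,
        weight_decay=config.weight_decay,
        beta_start=config.beta.beta_start,
        beta_final=config.beta.beta_final,
        ramp_fraction=config.beta.ramp_fraction,
        seeds=config.seeds,
        n_classes=n_classes,
    )


def train_rine(
    train: LabeledDataset,
    test: LabeledDataset,
    families: Sequence[DecoderFamilySpec],
    config: TrainConfig,
    seed: int,
    h_y_bits: float | None = None,
) -> SingleRunResult:
    """One seeded constrained-training run; metrics evaluated on ``test``."""
    if train.n_sources < 2:
        raise ValueError("use usable_information_bits for a single source")
    est = _estimator_from(families, config, train.n_classes)
    if h_y_bits is None:
        pooled = np.concatenate([train.labels, test.labels])
        p = np.bincount(pooled, minlength=train.n_classes) / pooled.size
        p = p[p > 0]
        h_y_bits = float(-(p * np.log2(p)).sum())
    return _single_run(train, test, est, est._schedule(), seed, h_y_bits)


def usable_information_bits(
    train: LabeledDataset,
    test: LabeledDataset,
    family: DecoderFamilySpec,
    config: TrainConfig,
    source_index: int = 0,
    seed: int = 0,
    h_y_bits: float | None = None,
) -> float:
    """Decoder-limited information H(Y) - H_V(Y|X) of one source, in bits.

    This is also the redundancy of a single source with itself
    (self-redundancy), so the constrained estimator degenerates to it.
    """
    if not 0 <= source_index < train.n_sources:
        raise ValueError(f"source_index {source_index} out of range")
    dec = MLPSoftmaxDecoder(
        hidden_layer_sizes=family.hidden,
        activation=family.activation,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        optimizer=config.optimizer,
        weight_decay=config.weight_decay,
        n_classes=train.n_classes,
        random_state=seed,
    )
    dec.fit(train.sources[source_index], train.labels)
    if h_y_bits is None:
        pooled = np.concatenate([train.labels, test.labels])
        p = np.bincount(pooled, minlength=train.n_classes) / pooled.size
        p = p[p > 0]
        h_y_bits = float(-(p * np.log2(p)).sum())
    return h_y_bits - cross_entropy_bits(dec, test, source_index)


def estimate_redundancy(
    train: LabeledDataset,
    test: LabeledDataset,
    families: Sequence[DecoderFamilySpec],
    config: TrainConfig,
    h_y_bits: float | None = None,
) -> RedundancyEstimate:
    """Multi-seed constrained redundancy estimate (any number of sources >= 2)."""
    est = _estimator_from(families, config, train.n_classes)
    est.fit(train, train.labels, X_eval=test, y_eval=test.labels, h_y_bits=h_y_bits)
    return est.result()


# n >= 2 sources share one code path; the two-source contract is the special case
estimate_redundancy_multisource = estimate_redundancy
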