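"""The three engram-dropout experiments.

Experiment 1 (placement): train a digit classifier with no dropout, with
50% dropout of the fully connected layer during training, or with 50%
dropout applied only at evaluation, and compare learning curves.  This
is the model of stimulation applied around encoding (enhancement) versus
during recall (disruption).

Experiment 2 (dose): sweep training-phase dropout rates 20/40/60/80%
against a 0% baseline.

Experiment 3 (chronic stimulation / new task): take digit networks
pretrained with and without training dropout, replace the output layer
with a 26-class letter head, retrain on letters, and compare against a
letters-from-scratch baseline.

All runs are seeded and multi-replicate.  Within a replicate every
condition shares the data, the initialization and the shuffling seeds,
so curve differences are attributable to the dropout policy alone; the
dropout RNG is a separate stream.  Per-epoch records (mean training
loss, test accuracy, test loss) mirror the evaluation protocol of
training in batches of 10 with end-of-epoch evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("engramsim")

from .engram_dropout import DropoutPolicy, policy_multipliers
from .nn_core import (
    ConfigurationError,
    LayerShapes,
    LossSpec,
    NetworkParams,
    backward_pass,
    batch_loss,
    forward_pass,
    init_network,
    sgd_update,
)
from .synthetic_data import DIGITS, UPPERCASE, GlyphDataset, GlyphGenParams, generate_dataset

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "ExperimentResult",
    "train_epoch",
    "evaluate",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
    "transfer_network",
    "summarize",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = ("exp1", "exp2", "exp3")

# paper-protocol dataset sizes; scaled profiles override them
PAPER_DIGITS = dict(n_train=1000, n_test=1000)
PAPER_LETTERS = dict(n_train=5000, n_test=1000)


@dataclass(frozen=True)
class TrainingConfig:
    """Shared configuration for all experiment runs.

    The protocol defaults are 500 epochs in batches of 10; the smaller
    profile used by the test-suite and acceptance runs overrides
    ``epochs`` and the dataset sizes (see :func:`scaled_config`).
    ``dtype`` selects the engine precision; float32 is the default for
    experiment work, float64 for numerical verification.
    """

    epochs: int = 500
    batch_size: int = 10
    learning_rate: float = 0.3
    loss: LossSpec = field(default_factory=LossSpec)
    master_seed: int = 0
    n_replicates: int = 5
    n_train: int | None = None
    n_test: int | None = None
    pretrain_epochs: int | None = None  # exp3; defaults to ``epochs``
    n_pretrain: int | None = None  # exp3 digit pretraining set size
    retrain_dropout: bool = False  # exp3: 50% train dropout while retraining
    gen_params: GlyphGenParams = field(default_factory=GlyphGenParams)
    eval_batch_size: int = 50
    dtype: str = "float32"
    single_run: bool = False  # protocol-faithful single-curve mode

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.n_replicates < 1:
            raise ConfigurationError(
                "epochs, batch_size and n_replicates must all be >= 1"
            )

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def replicates(self) -> int:
        return 1 if self.single_run else self.n_replicates


def scaled_config(master_seed: int = 0, **overrides) -> TrainingConfig:
    """The reduced profile used for routine runs: 100 epochs, 250/250
    digit images (letters are sized separately), 3 replicates."""
    base = dict(epochs=100, n_replicates=3, n_train=250, n_test=250,
                master_seed=master_seed)
    base.update(overrides)
    return TrainingConfig(**base)


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    test_accuracy: float
    test_loss: float


@dataclass
class ExperimentResult:
    """Per-condition, per-replicate epoch records for one experiment."""

    experiment_id: str
    conditions: dict[str, list[list[EpochRecord]]]
    config: TrainingConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cond, reps in self.conditions.items():
            for r, records in enumerate(reps):
                for rec in records:
                    rows.append((cond, r, rec.epoch, rec.train_loss,
                                 rec.test_loss, rec.test_accuracy))
        return pd.DataFrame(rows, columns=[
            "condition", "replicate", "epoch",
            "train_loss", "test_loss", "test_accuracy"])

    def to_csv(self, path: str) -> None:
        # fixed float formatting so identical runs give identical bytes
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    def final_metric(self, condition: str, metric: str) -> np.ndarray:
        """Final-epoch values of a metric across replicates."""
        return np.array([
            getattr(records[-1], metric)
            for records in self.conditions[condition]
        ])

    def epoch_matrix(self, condition: str, metric: str) -> np.ndarray:
        """(n_replicates, n_epochs) array of a metric."""
        return np.array([
            [getattr(rec, metric) for rec in records]
            for records in self.conditions[condition]
        ])


# ---------------------------------------------------------------------------
# training / evaluation primitives


def train_epoch(params: NetworkParams, data: GlyphDataset,
                config: TrainingConfig, policy: DropoutPolicy,
                shuffle_rng: np.random.Generator,
                dropout_rng: np.random.Generator,
                ) -> tuple[NetworkParams, float]:
    """One pass over the training data.

    Seeded shuffle, sequential batches (final short batch included), a
    fresh dropout mask per batch when the policy is active in the train
    phase, backprop and a plain SGD step per batch.  Returns the updated
    parameters and the mean per-batch loss weighted by batch size.
    """
    n = len(data)
    if n == 0:
        raise ConfigurationError("empty training data")
    order = shuffle_rng.permutation(n)
    total = 0.0
    use_dropout = policy.active_in("train")
    for start in range(0, n, config.batch_size):
        idx = order[start:start + config.batch_size]
        x, y = data.images[idx], data.labels[idx]
        mult = out_mult = None
        if use_dropout:
            mult, out_mult = policy_multipliers(
                policy, params.shapes.fc_units, params.n_classes,
                dropout_rng, len(idx))
        cache = forward_pass(params, x, mult)
        logits = cache.logits if out_mult is None else cache.logits * out_mult
        loss, _, d_logits = batch_loss(logits, y, config.loss)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss in batch starting at {start}"
            )
        if out_mult is not None:
            d_logits = d_logits * out_mult
        grads = backward_pass(params, cache, d_logits)
        params = sgd_update(params, grads, config.learning_rate)
        total += loss * len(idx)
    return params, total / n


def evaluate(params: NetworkParams, data: GlyphDataset,
             policy: DropoutPolicy, loss_spec: LossSpec,
             dropout_rng: np.random.Generator | None = None,
             batch_size: int = 50) -> tuple[float, float]:
    """Accuracy and mean loss on a dataset.

    Test-phase dropout (a fresh mask per evaluation batch) is applied
    only when ``policy.phase == "test"``; a train-phase policy is inert
    here, matching standard inference of a dropout-trained network.
    """
    n = len(data)
    if n == 0:
        raise ConfigurationError("empty evaluation data")
    use_dropout = policy.active_in("test")
    if use_dropout and dropout_rng is None:
        dropout_rng = np.random.default_rng(policy.mask_seed)
    correct = 0
    total_loss = 0.0
    for start in range(0, n, batch_size):
        x = data.images[start:start + batch_size]
        y = data.labels[start:start + batch_size]
        mult = out_mult = None
        if use_dropout:
            mult, out_mult = policy_multipliers(
                policy, params.shapes.fc_units, params.n_classes,
                dropout_rng, len(y))
        cache = forward_pass(params, x, mult)
        logits = cache.logits if out_mult is None else cache.logits * out_mult
        loss, probs, _ = batch_loss(logits, y, loss_spec)
        correct += int((probs.argmax(axis=1) == y).sum())
        total_loss += loss * len(y)
    return correct / n, total_loss / n


# ---------------------------------------------------------------------------
# seeds: every stream is derived from (master_seed, replicate, role) so
# conditions within a replicate share data/init/shuffle and differ only
# in what the policy does with the dropout stream


def _seed(master: int, replicate: int, role: int) -> int:
    return int(np.random.SeedSequence([master, replicate, role])
               .generate_state(1)[0] % (2 ** 31))


_ROLE_TRAIN_DATA, _ROLE_TEST_DATA, _ROLE_INIT, _ROLE_SHUFFLE, \
    _ROLE_DROPOUT, _ROLE_HEAD, _ROLE_LETTER_TRAIN, _ROLE_LETTER_TEST, \
    _ROLE_SCRATCH_INIT = range(9)


def _train_condition(params: NetworkParams, train: GlyphDataset,
                     test: GlyphDataset, config: TrainingConfig,
                     policy: DropoutPolicy, shuffle_seed: int,
                     dropout_seed: int, epochs: int,
                     ) -> tuple[NetworkParams, list[EpochRecord]]:
    shuffle_rng = np.random.default_rng(shuffle_seed)
    train_drop_rng = np.random.default_rng(dropout_seed)
    test_drop_rng = np.random.default_rng(dropout_seed + 1)
    records = []
    for epoch in range(epochs):
        params, train_loss = train_epoch(params, train, config, policy,
                                         shuffle_rng, train_drop_rng)
        acc, test_loss = evaluate(params, test, policy, config.loss,
                                  test_drop_rng, config.eval_batch_size)
        records.append(EpochRecord(epoch=epoch, train_loss=float(train_loss),
                                   test_accuracy=float(acc),
                                   test_loss=float(test_loss)))
        level = logging.INFO if (epoch + 1) % 10 == 0 else logging.DEBUG
        logger.log(level, "epoch %d: train_loss=%.4f test_acc=%.3f",
                   epoch, train_loss, acc)
    return params, records


def _digit_data(config: TrainingConfig, replicate: int,
                ) -> tuple[GlyphDataset, GlyphDataset]:
    n_train = config.n_train or PAPER_DIGITS["n_train"]
    n_test = config.n_test or PAPER_DIGITS["n_test"]
    train = generate_dataset(DIGITS, n_train, config.gen_params,
                             _seed(config.master_seed, replicate, _ROLE_TRAIN_DATA))
    test = generate_dataset(DIGITS, n_test, config.gen_params,
                            _seed(config.master_seed, replicate, _ROLE_TEST_DATA))
    return train, test


def run_experiment1(config: TrainingConfig) -> ExperimentResult:
    """Dropout placement: control vs. 50% train-phase vs. 50% test-phase."""
    policies = {
        "control": DropoutPolicy(phase="none"),
        "dropout-train-50": DropoutPolicy(phase="train", rate=0.5),
        "dropout-test-50": DropoutPolicy(phase="test", rate=0.5),
    }
    conditions: dict[str, list[list[EpochRecord]]] = {c: [] for c in policies}
    for r in range(config.replicates()):
        train, test = _digit_data(config, r)
        init_seed = _seed(config.master_seed, r, _ROLE_INIT)
        shuffle_seed = _seed(config.master_seed, r, _ROLE_SHUFFLE)
        dropout_seed = _seed(config.master_seed, r, _ROLE_DROPOUT)
        for name, policy in policies.items():
            params = init_network(LayerShapes(), len(DIGITS), init_seed,
                                  dtype=config.np_dtype)
            _, records = _train_condition(params, train, test, config, policy,
                                          shuffle_seed, dropout_seed,
                                          config.epochs)
            conditions[name].append(records)
    return ExperimentResult("exp1", conditions, config)


def run_experiment2(config: TrainingConfig,
                    rates: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
                    ) -> ExperimentResult:
    """Dose sweep of training-phase dropout, with a 0% baseline."""
    policies = {"baseline-0": DropoutPolicy(phase="none")}
    for rate in rates:
        policies[f"rate-{int(round(rate * 100))}"] = DropoutPolicy(
            phase="train", rate=rate)
    conditions: dict[str, list[list[EpochRecord]]] = {c: [] for c in policies}
    for r in range(config.replicates()):
        train, test = _digit_data(config, r)
        init_seed = _seed(config.master_seed, r, _ROLE_INIT)
        shuffle_seed = _seed(config.master_seed, r, _ROLE_SHUFFLE)
        dropout_seed = _seed(config.master_seed, r, _ROLE_DROPOUT)
        for name, policy in policies.items():
            params = init_network(LayerShapes(), len(DIGITS), init_seed,
                                  dtype=config.np_dtype)
            _, records = _train_condition(params, train, test, config, policy,
                                          shuffle_seed, dropout_seed,
                                          config.epochs)
            conditions[name].append(records)
    return ExperimentResult("exp2", conditions, config)


def transfer_network(source: NetworkParams, n_new_classes: int,
                     head_seed: int) -> NetworkParams:
    """Replace the output layer for a new task, keeping all other weights.

    Convolutional and fully connected parameters are copied bit-exactly;
    only the class-score head is re-initialized.  Nothing is frozen: all
    layers stay trainable during retraining.
    """
    if n_new_classes < 2:
        raise ConfigurationError("n_new_classes must be >= 2")
    fresh = init_network(source.shapes, n_new_classes, head_seed,
                         dtype=source.out_w.dtype)
    out = source.copy()
    return replace(out, n_classes=n_new_classes,
                   out_w=fresh.out_w, out_b=fresh.out_b)


def run_experiment3(config: TrainingConfig,
                    sources: dict[str, list[NetworkParams]] | None = None,
                    ) -> ExperimentResult:
    """Transfer to letters from dropout/control digit networks vs. scratch.

    ``sources`` may supply pretrained digit networks per replicate under
    keys "control" and "dropout-train-50" (e.g. the end state of an
    Experiment-1-style run); otherwise they are pretrained here with the
    same seed discipline (no evaluation during pretraining).

    The condition labels refer to the *pretraining* history: by default
    all three conditions retrain on letters without dropout, modelling
    stimulation that ended before the new task began.  Setting
    ``config.retrain_dropout`` lets the dropout-pretrained network keep
    its 50% training dropout during retraining instead.
    """
    n_train = config.n_train or PAPER_LETTERS["n_train"]
    n_test = config.n_test or PAPER_LETTERS["n_test"]
    pretrain_epochs = config.pretrain_epochs or config.epochs
    retrain_policies = {
        "transfer-with-dropout": (
            DropoutPolicy(phase="train", rate=0.5)
            if config.retrain_dropout else DropoutPolicy(phase="none")),
        "transfer-no-dropout": DropoutPolicy(phase="none"),
        "scratch": DropoutPolicy(phase="none"),
    }
    source_key = {"transfer-with-dropout": "dropout-train-50",
                  "transfer-no-dropout": "control"}
    conditions: dict[str, list[list[EpochRecord]]] = {
        c: [] for c in retrain_policies}
    for r in range(config.replicates()):
        letters_train = generate_dataset(
            UPPERCASE, n_train, config.gen_params,
            _seed(config.master_seed, r, _ROLE_LETTER_TRAIN))
        letters_test = generate_dataset(
            UPPERCASE, n_test, config.gen_params,
            _seed(config.master_seed, r, _ROLE_LETTER_TEST))
        if sources is None:
            digit_train = generate_dataset(
                DIGITS, config.n_pretrain or PAPER_DIGITS["n_train"],
                config.gen_params,
                _seed(config.master_seed, r, _ROLE_TRAIN_DATA))
            init_seed = _seed(config.master_seed, r, _ROLE_INIT)
            shuffle_seed = _seed(config.master_seed, r, _ROLE_SHUFFLE)
            dropout_seed = _seed(config.master_seed, r, _ROLE_DROPOUT)
            rep_sources = {}
            for key, policy in (("control", DropoutPolicy(phase="none")),
                                ("dropout-train-50",
                                 DropoutPolicy(phase="train", rate=0.5))):
                params = init_network(LayerShapes(), len(DIGITS), init_seed,
                                      dtype=config.np_dtype)
                shuffle_rng = np.random.default_rng(shuffle_seed)
                drop_rng = np.random.default_rng(dropout_seed)
                for _ in range(pretrain_epochs):
                    params, _loss = train_epoch(params, digit_train, config,
                                                policy, shuffle_rng, drop_rng)
                rep_sources[key] = params
        else:
            rep_sources = {k: v[r] for k, v in sources.items()}
        head_seed = _seed(config.master_seed, r, _ROLE_HEAD)
        shuffle_seed = _seed(config.master_seed, r, _ROLE_SHUFFLE) + 1
        dropout_seed = _seed(config.master_seed, r, _ROLE_DROPOUT) + 1
        for name, policy in retrain_policies.items():
            if name == "scratch":
                params = init_network(
                    LayerShapes(), len(UPPERCASE),
                    _seed(config.master_seed, r, _ROLE_SCRATCH_INIT),
                    dtype=config.np_dtype)
            else:
                params = transfer_network(rep_sources[source_key[name]],
                                          len(UPPERCASE), head_seed)
            _, records = _train_condition(params, letters_train, letters_test,
                                          config, policy, shuffle_seed,
                                          dropout_seed, config.epochs)
            conditions[name].append(records)
    return ExperimentResult("exp3", conditions, config)


# ---------------------------------------------------------------------------
# summaries


def summarize(result: ExperimentResult, n_boot: int = 2000,
              seed: int = 0) -> dict:
    """Final-epoch summary per condition with bootstrap intervals.

    Percentile bootstrap over replicates (95%), plus, for every ordered
    condition pair, the bootstrap frequency with which the first
    condition's mean final accuracy exceeds the second's.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict = {"experiment": result.experiment_id, "conditions": {},
                 "orderings": {}}
    finals = {}
    for cond in result.conditions:
        entry = {}
        for metric in ("test_accuracy", "train_loss", "test_loss"):
            vals = result.final_metric(cond, metric)
            boots = rng.choice(vals, size=(n_boot, len(vals))).mean(axis=1)
            entry[metric] = {
                "mean": float(vals.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "n_replicates": int(len(vals)),
            }
        finals[cond] = result.final_metric(cond, "test_accuracy")
        out["conditions"][cond] = entry
    names = list(result.conditions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = finals[a], finals[b]
            ba = rng.choice(va, size=(n_boot, len(va))).mean(axis=1)
            bb = rng.choice(vb, size=(n_boot, len(vb))).mean(axis=1)
            out["orderings"][f"{a}>{b}"] = float((ba > bb).mean())
    return out


def run_experiment(experiment_id: str, config: TrainingConfig,
                   ) -> ExperimentResult:
    """Dispatch by experiment id ("exp1", "exp2", "exp3")."""
    runners = {"exp1": run_experiment1, "exp2": run_experiment2,
               "exp3": run_experiment3}
    if experiment_id not in runners:
        raise ConfigurationError(
            f"unknown experiment {experiment_id!r}; valid ids: "
            f"{', '.join(EXPERIMENT_IDS)}"
        )
    return runners[experiment_id](config)
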