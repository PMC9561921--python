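"""Training protocol, two-stage decoding rules, and evaluation.

The estimation surface follows the familiar model/results split:
:class:`SingleTrialERPModel` wraps the epochs to learn from, its
``fit()`` runs the seeded training loop (Adam, categorical
cross-entropy, validation checkpointing: the returned weights are those
of the pass with minimum validation loss) and returns a
:class:`SingleTrialERPResults` carrying the trained network, the loss
history, attention summaries and ``summary()``.  A
:class:`TwoStageSpeller` combines a stage-1 and a stage-2 results
object with the codebook to spell characters.

Decoding rules: stage 1 picks the group whose 3-bit code has maximal
Bernoulli log-likelihood given the three sub-trial target
probabilities; stage 2 picks the slot with the highest target
probability.  A character is spelled correctly iff both stages are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score

from . import nn
from .model import STACNN, ModelConfig
from .paradigm import CodeBook, chance_level
from .preprocess import EpochSet

_EPS = 1e-9
_PREDICT_BATCH = 256


class DataError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    """A test statistic has no defined value (e.g. zero-variance t)."""


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol knobs.

    max_iterations: full passes over the training set (upper bound; the
    checkpoint with minimum validation loss is returned).
    oversample_extra_copies: extra duplicates of each stage-2 training
    target epoch, balancing the 1:4 class ratio at the default 3.
    """

    max_iterations: int = 300
    val_fraction: float = 0.10
    oversample_extra_copies: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.oversample_extra_copies < 0:
            raise ValueError("oversample_extra_copies must be >= 0")


# ---------------------------------------------------------------------------
# splitting


def split_and_oversample(
    epochs: EpochSet,
    cfg: TrainConfig | None = None,
    n_train_chars: int = 300,
) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Character-block split plus stage-2 target oversampling.

    The first ``n_train_chars`` spelled characters supply train+val
    epochs (validation = a seeded stratified ``val_fraction``); the
    remaining characters form the test set.  For stage-2 sets, each
    training target epoch is duplicated ``oversample_extra_copies``
    times so the classes balance.  Splitting by character block keeps
    whole spelled characters on one side of the split.
    """
    cfg = cfg or TrainConfig()
    chars = epochs.info["char_index"].to_numpy()
    n_chars = chars.max() + 1 if len(chars) else 0
    if n_chars <= n_train_chars:
        raise DataError(
            f"need more than {n_train_chars} spelled characters, "
            f"have {n_chars}"
        )
    trainval = epochs.select(chars < n_train_chars)
    test = epochs.select(chars >= n_train_chars)

    rng = np.random.default_rng(cfg.seed)
    y = trainval.labels
    val_mask = np.zeros(len(trainval), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(cfg.val_fraction * len(idx))))
        val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    train = trainval.select(~val_mask)
    val = trainval.select(val_mask)

    stage = int(epochs.info["stage"].iloc[0]) if len(epochs) else 0
    if stage == 2 and cfg.oversample_extra_copies > 0:
        tgt = np.flatnonzero(train.labels == 1)
        extra = np.tile(tgt, cfg.oversample_extra_copies)
        keep = np.concatenate([np.arange(len(train)), extra])
        train = train.select(keep)
    return train, val, test


# ---------------------------------------------------------------------------
# model / results


class SingleTrialERPModel:
    """Binary target/nontarget classifier over 62x100 epochs.

    Parameters
    ----------
    train, val : EpochSet
        Disjoint training and validation epochs (same stage).
    config : ModelConfig, optional
        Architecture; defaults to the full attention model.
    """

    def __init__(self, train: EpochSet, val: EpochSet,
                 config: ModelConfig | None = None):
        if len(train) == 0 or len(val) == 0:
            raise DataError("train and validation sets must be non-empty")
        self.train_set = train
        self.val_set = val
        self.config = config or ModelConfig()

    @classmethod
    def from_epochs(cls, epochs: EpochSet, cfg: TrainConfig | None = None,
                    config: ModelConfig | None = None,
                    n_train_chars: int = 300):
        """Build model and test set from a full session's epochs."""
        train, val, test = split_and_oversample(epochs, cfg, n_train_chars)
        return cls(train, val, config=config), test

    def fit(self, cfg: TrainConfig | None = None) -> "SingleTrialERPResults":
        """Run the training loop; return the best-validation checkpoint."""
        cfg = cfg or TrainConfig()
        net = STACNN(replace(self.config, init_seed=cfg.seed))
        rng = np.random.default_rng(cfg.seed + 1)
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)

        Xtr = self.train_set.data.astype(np.float32)
        ytr = self.train_set.labels
        Xval = self.val_set.data.astype(np.float32)
        yval = self.val_set.labels

        history = []
        best = (np.inf, None, -1)
        for it in range(cfg.max_iterations):
            order = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = net.forward(Xtr[idx], train=True, rng=rng)
                loss, dlogits = nn.cross_entropy(logits, ytr[idx])
                net.backward(dlogits)
                opt.step()
                opt.zero_grad()
                losses.append(loss)
            val_logits = _forward_batched(net, Xval)
            val_loss, _ = nn.cross_entropy(val_logits, yval)
            val_acc = float((val_logits.argmax(axis=1) == yval).mean())
            history.append(
                {"iteration": it, "train_loss": float(np.mean(losses)),
                 "val_loss": val_loss, "val_acc": val_acc}
            )
            if val_loss < best[0]:
                best = (val_loss, net.state_dict(), it)
        net.load_state_dict(best[1])
        return SingleTrialERPResults(
            model=self, net=net, history=pd.DataFrame(history),
            best_iteration=best[2], train_config=cfg,
        )


def _forward_batched(net: STACNN, X: np.ndarray) -> np.ndarray:
    outs = [
        net.forward(X[i : i + _PREDICT_BATCH])
        for i in range(0, len(X), _PREDICT_BATCH)
    ]
    return np.concatenate(outs, axis=0)


@dataclass
class SingleTrialERPResults:
    """Fitted classifier: weights, history, attention, diagnostics."""

    model: SingleTrialERPModel
    net: STACNN
    history: pd.DataFrame
    best_iteration: int
    train_config: TrainConfig

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities (n, 2); column 1 is the target class."""
        if isinstance(X, EpochSet):
            X = X.data
        logits = _forward_batched(self.net, np.asarray(X, dtype=np.float32))
        return nn.softmax(logits, axis=-1)

    def score_epochs(self, X) -> np.ndarray:
        """Per-epoch target probability p_target in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def attention_report(self, epochs: EpochSet) -> dict:
        return attention_report(self.net, epochs)

    def evaluate_epochs(self, epochs: EpochSet) -> dict:
        """Epoch-level accuracy and F1 (target = positive class)."""
        p = self.score_epochs(epochs)
        pred = (p >= 0.5).astype(int)
        y = epochs.labels
        return {
            "accuracy": float(accuracy_score(y, pred)),
            "f1": float(f1_score(y, pred, zero_division=0)),
            "n": len(y),
        }

    def summary(self) -> str:
        cfg = self.net.config
        h = self.history
        lines = [
            "Single-trial ERP classifier",
            "=" * 44,
            f"variant:              {cfg.variant}",
            f"input:                ({cfg.n_channels} channels, "
            f"{cfg.n_times} samples)",
            f"parameters:           {self.net.n_params}",
            f"training epochs run:  {len(h)}",
            f"best iteration:       {self.best_iteration}",
            f"best val loss:        {h['val_loss'].min():.4f}",
            f"val accuracy at best: "
            f"{h.loc[h['val_loss'].idxmin(), 'val_acc']:.3f}",
            f"train size / val size: {len(self.model.train_set)} / "
            f"{len(self.model.val_set)}",
            f"seed: {self.train_config.seed}",
        ]
        return "\n".join(lines)


def score_epoch(net: STACNN, epoch: np.ndarray) -> float:
    """Target probability of one (62, 100) epoch under a trained net."""
    return float(nn.softmax(net.forward(epoch[None]), axis=-1)[0, 1])


# ---------------------------------------------------------------------------
# two-stage decoding


def decode_stage1(scores, cb: CodeBook, method: str = "likelihood") -> int:
    """Pick the group whose 3-bit code best explains the sub-trial scores.

    ``likelihood``: argmax over groups of the Bernoulli log-likelihood
    sum_k [bit_k log p_k + (1 - bit_k) log(1 - p_k)]; ``hamming``:
    threshold scores at 0.5 and pick the code with minimum Hamming
    distance.  Ties break to the lowest group index.
    """
    p = np.clip(np.asarray(scores, dtype=float), _EPS, 1 - _EPS)
    if p.shape != (len(cb.codes[0]),):
        raise ValueError(f"need {len(cb.codes[0])} sub-trial scores")
    bits = np.array([[int(b) for b in code] for code in cb.codes])
    if method == "likelihood":
        ll = bits @ np.log(p) + (1 - bits) @ np.log(1 - p)
        # lowest index among exact ties (matmul rounding must not break them)
        return int(np.flatnonzero(ll >= ll.max() - 1e-9)[0])
    if method == "hamming":
        hard = (p >= 0.5).astype(int)
        dist = np.abs(bits - hard).sum(axis=1)
        return int(np.argmin(dist))
    raise ValueError(f"unknown method {method!r}")


def decode_stage2(scores) -> int:
    """Slot with the highest target probability; ties to the lowest index."""
    return int(np.argmax(np.asarray(scores, dtype=float)))


class TwoStageSpeller:
    """Character decoder from fitted stage-1 and stage-2 classifiers."""

    def __init__(self, stage1: SingleTrialERPResults,
                 stage2: SingleTrialERPResults, codebook: CodeBook,
                 stage1_method: str = "likelihood"):
        self.stage1 = stage1
        self.stage2 = stage2
        self.codebook = codebook
        self.stage1_method = stage1_method

    def decode_session(self, epochs1: EpochSet, epochs2: EpochSet
                       ) -> pd.DataFrame:
        """Per-character two-stage decisions for aligned epoch sets.

        Stage 2 is scored against the true group's five slots (offline
        copy-spelling convention), so both stage decisions are always
        attempted; a character counts as correct iff both are right.
        """
        p1 = self.stage1.score_epochs(epochs1)
        p2 = self.stage2.score_epochs(epochs2)
        rows = []
        for ci in np.unique(epochs1.info["char_index"]):
            m1 = epochs1.info["char_index"] == ci
            m2 = epochs2.info["char_index"] == ci
            sub = epochs1.info[m1].sort_values("index")
            truth_char = sub["character"].iloc[0]
            true_group = int(sub["group"].iloc[0])
            s1 = p1[m1.to_numpy()][np.argsort(sub["index"].to_numpy(),
                                              kind="stable")]
            chosen_group = decode_stage1(s1, self.codebook,
                                         self.stage1_method)
            slots = epochs2.info[m2].sort_values("index")
            s2 = p2[m2.to_numpy()][np.argsort(slots["index"].to_numpy(),
                                              kind="stable")]
            chosen_slot = decode_stage2(s2)
            chosen_char = slots["shown"].iloc[chosen_slot]
            rows.append(
                {
                    "char_index": int(ci),
                    "truth": truth_char,
                    "true_group": true_group,
                    "chosen_group": chosen_group,
                    "group_correct": chosen_group == true_group,
                    "chosen_char": chosen_char,
                    "char_stage2_correct": chosen_char == truth_char,
                    "correct": (chosen_group == true_group)
                    and (chosen_char == truth_char),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Aggregate spelling metrics; target is the positive class for F1."""

    stage1_epoch: dict
    stage2_epoch: dict
    stage1_char_accuracy: float
    stage2_char_accuracy: float
    total_accuracy: float
    n_characters: int
    chance: float

    def summary(self) -> str:
        lines = [
            "Two-stage spelling evaluation",
            "=" * 44,
            f"characters scored:        {self.n_characters}",
            f"stage-1 epoch acc / F1:   {self.stage1_epoch['accuracy']:.3f}"
            f" / {self.stage1_epoch['f1']:.3f}",
            f"stage-2 epoch acc / F1:   {self.stage2_epoch['accuracy']:.3f}"
            f" / {self.stage2_epoch['f1']:.3f}",
            f"stage-1 group accuracy:   {self.stage1_char_accuracy:.3f}",
            f"stage-2 char accuracy:    {self.stage2_char_accuracy:.3f}",
            f"total accuracy:           {self.total_accuracy:.3f}"
            f"   (chance {self.chance:.3f})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stage1_epoch": self.stage1_epoch,
            "stage2_epoch": self.stage2_epoch,
            "stage1_char_accuracy": self.stage1_char_accuracy,
            "stage2_char_accuracy": self.stage2_char_accuracy,
            "total_accuracy": self.total_accuracy,
            "n_characters": self.n_characters,
            "chance": self.chance,
        }


def evaluate(speller: TwoStageSpeller, epochs1: EpochSet,
             epochs2: EpochSet) -> EvalReport:
    """Score a speller on held-out epochs of both stages."""
    decisions = speller.decode_session(epochs1, epochs2)
    if decisions.empty:
        raise DataError("no characters to evaluate")
    return EvalReport(
        stage1_epoch=speller.stage1.evaluate_epochs(epochs1),
        stage2_epoch=speller.stage2.evaluate_epochs(epochs2),
        stage1_char_accuracy=float(decisions["group_correct"].mean()),
        stage2_char_accuracy=float(decisions["char_stage2_correct"].mean()),
        total_accuracy=float(decisions["correct"].mean()),
        n_characters=len(decisions),
        chance=chance_level(speller.codebook),
    )


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; raises if the differences have no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise UndefinedStatisticError(
            "paired differences have zero variance; t is undefined"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def sign_test(x, y) -> tuple[int, int, float]:
    """One-sided sign test for median(x) > median(y); ties discarded.

    Returns (wins, losses, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wins = int(np.sum(x > y))
    losses = int(np.sum(x < y))
    n = wins + losses
    if n == 0:
        return wins, losses, 1.0
    p = stats.binomtest(wins, n, 0.5, alternative="greater").pvalue
    return wins, losses, float(p)


# ---------------------------------------------------------------------------
# descriptive reports


def attention_report(net: STACNN, epochs: EpochSet) -> dict:
    """Average attention probability weights over test samples and filters.

    Returns the temporal curve (length n_times, mapped to 0–500 ms) and
    the per-channel spatial vector (length 62), whichever the variant
    provides (absent ones are None).
    """
    if len(epochs) == 0:
        raise DataError("cannot summarize attention over an empty set")
    sum_t = sum_s = None
    n = 0
    X = epochs.data.astype(np.float32)
    for i in range(0, len(X), _PREDICT_BATCH):
        batch = X[i : i + _PREDICT_BATCH]
        net.forward(batch)
        att = net.last_attention
        n += len(batch)
        if att["A_t"] is not None:
            t = att["A_t"].mean(axis=1).sum(axis=0)
            sum_t = t if sum_t is None else sum_t + t
        if att["A_s"] is not None:
            s = att["A_s"].mean(axis=1).sum(axis=0)
            sum_s = s if sum_s is None else sum_s + s
    return {
        "a_t": None if sum_t is None else sum_t / n,
        "times_ms": epochs.times_ms,
        "a_s": None if sum_s is None else sum_s / n,
        "channels": epochs.montage.labels,
    }


def grand_average(epochs: EpochSet, label: str | None = None,
                  stage: int | None = None) -> np.ndarray:
    """Mean (62, 100) waveform over epochs matching label/stage filters."""
    mask = np.ones(len(epochs), dtype=bool)
    if label is not None:
        mask &= epochs.labels == (1 if label == "target" else 0)
    if stage is not None:
        mask &= (epochs.info["stage"] == stage).to_numpy()
    if not mask.any():
        raise DataError("no epochs match the requested filters")
    return epochs.data[mask].mean(axis=0)


def topography_at(avg: np.ndarray, latency_ms: float,
                  fs: float = 200.0) -> np.ndarray:
    """Per-channel amplitude of an average waveform at one latency."""
    idx = int(round(latency_ms / 1000.0 * fs))
    return avg[:, idx]
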