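import numpy as np
import pytest

from shiftbench.tables import PredictionTable


def random_table(
    rng: np.random.Generator,
    n: int = 20,
    k: int = 4,
    force_most_certain_correct: bool = False,
) -> PredictionTable:
    """Random prediction table with Dirichlet probability rows."""
    probs = rng.dirichlet(np.ones(k), size=n)
    classes = [f"C{j}" for j in range(k)]
    pred_idx = probs.argmax(axis=1)
    true_idx = np.where(rng.random(n) < 0.6, pred_idx, rng.integers(0, k, size=n))
    if force_most_certain_correct:
        entropy = -np.sum(np.where(probs > 0, probs * np.log(probs), 0.0), axis=1)
        i = int(np.argmin(entropy))
        true_idx[i] = pred_idx[i]
    return PredictionTable(
        sample_id=[f"s{i}" for i in range(n)],
        true_label=[classes[i] for i in true_idx],
        probs=probs,
        classes=classes,
    )


def table_from_correctness(correct, uncertainty=None) -> PredictionTable:
    """Two-class table realising a given correctness pattern.

    When `uncertainty` is given, row probabilities are shaped so the table's
    own entropy ranks samples exactly in that uncertainty order.
    """
    correct = np.asarray(correct, dtype=bool)
    n = correct.size
    if uncertainty is None:
        uncertainty = np.arange(n, dtype=float)
    ranks = np.argsort(np.argsort(uncertainty))  # 0 = least uncertain
    # map rank to a max-probability in (0.5, 1): higher rank -> closer to 0.5
    p_max = 0.99 - 0.4 * (ranks / max(n - 1, 1))
    probs = np.column_stack([p_max, 1.0 - p_max])
    true = np.where(correct, "A", "B")
    return PredictionTable(
        sample_id=[f"s{i}" for i in range(n)],
        true_label=list(true),
        probs=probs,
        classes=["A", "B"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
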