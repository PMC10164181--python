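"""Strata-structured synthetic data emulating a development→production shift.

The generator produces a multiclass "expression-like" dataset in a continuous
feature space: each class has a fixed signature vector, samples are the
signature plus isotropic Gaussian noise, and four strata proxy distinct
distribution shifts:

* ``(batch A, Primary, seen)`` — the IID development stratum (training and
  validation are both drawn from here);
* ``(batch B, Primary, seen)`` — covariate shift via a per-batch additive
  offset vector (a batch effect);
* ``(batch A, Metastatic, seen)`` — each class's signature blended toward its
  nearest other seen class signature with weight ``blend_alpha`` (a
  metastasis-like signature drift);
* ``(batch B, Metastatic, unseen)`` — classes absent from training, each
  placed between a fresh random signature and a designated "related" seen
  class signature, so some unseen classes sit close to the decision regions
  of seen classes and others far away.

Everything is driven by one seed, so a configuration generates bit-identical
datasets across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import StrataDataset

__all__ = ["SyntheticConfig", "generate", "split_development", "Subset"]

BATCH_DEV = "A"
BATCH_SHIFTED = "B"
IID_KEY = (BATCH_DEV, "Primary", True)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic shift benchmark.

    `signature_scale` sets inter-class mean separation (per-dimension sd of
    the class signature vectors); `noise_sd` the within-class spread;
    `batch_shift_sd` the per-dimension sd of batch B's additive offset;
    `blend_alpha` the interpolation weight pulling metastatic samples toward
    the nearest other seen class. Unseen classes get evenly spaced blend
    weights toward their related seen class (`unseen_blend_range`), creating
    both near and far unseen classes. Defaults are desk scale: 8 seen + 3
    unseen classes, 64 features, 400 samples per seen OOD stratum, a smaller
    unseen stratum (`n_unseen_stratum`) so unseen classes are a minor fraction
    of production data, and a development stratum (`n_iid_stratum`) several
    times larger than any single test stratum — both mirroring the relative
    cohort sizes of real tumour compendia.
    """

    k_seen: int = 8
    k_unseen: int = 3
    n_features: int = 64
    n_per_stratum: int = 400
    n_iid_stratum: int = 1200
    n_unseen_stratum: int = 100
    signature_scale: float = 0.55
    noise_sd: float = 1.0
    batch_shift_sd: float = 0.5
    blend_alpha: float = 0.35
    unseen_blend_range: tuple[float, float] = (0.25, 0.85)
    related_map: dict[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_seen < 2:
            raise ValueError("need at least two seen classes")
        if self.k_unseen < 0:
            raise ValueError("k_unseen must be non-negative")
        if self.n_features < 2:
            raise ValueError("need at least two features")
        if not (0.0 <= self.blend_alpha <= 1.0):
            raise ValueError("blend_alpha must be in [0, 1]")

    def seen_classes(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.k_seen)]

    def unseen_classes(self) -> list[str]:
        return [f"U{i + 1:02d}" for i in range(self.k_unseen)]


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Class index per sample, as balanced as n allows, in shuffled order."""
    idx = np.arange(n) % k
    rng.shuffle(idx)
    return idx


def generate(config: SyntheticConfig) -> StrataDataset:
    """Draw a full strata dataset from the configuration.

    Class signatures are drawn once from a zero-mean spherical Gaussian scaled
    by `signature_scale`; each sample is its (possibly blended) class
    signature plus Gaussian noise plus its batch offset. Batch A is the
    reference batch (zero offset), so with ``batch_shift_sd = 0`` and
    ``blend_alpha = 0`` every seen OOD stratum is distributionally identical
    to the IID stratum (the null-shift control).
    """
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    sig_seen = rng.normal(0.0, config.signature_scale, size=(config.k_seen, d))
    sig_fresh = rng.normal(0.0, config.signature_scale, size=(config.k_unseen, d))
    offset_b = rng.normal(0.0, config.batch_shift_sd, size=d) if config.batch_shift_sd > 0 else np.zeros(d)

    # nearest *other* seen signature, for metastatic blending
    d2 = ((sig_seen[:, None, :] - sig_seen[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest_seen = d2.argmin(axis=1)

    if config.related_map is not None:
        related = dict(config.related_map)
        if sorted(related) != list(range(config.k_unseen)):
            raise ValueError("related_map must cover every unseen class index")
    else:
        # each unseen class is related to its nearest seen signature
        du = ((sig_fresh[:, None, :] - sig_seen[None, :, :]) ** 2).sum(axis=2)
        related = {u: int(du[u].argmin()) for u in range(config.k_unseen)}
    if config.k_unseen > 1:
        lo, hi = config.unseen_blend_range
        unseen_blend = np.linspace(lo, hi, config.k_unseen)
    else:
        unseen_blend = np.full(config.k_unseen, float(np.mean(config.unseen_blend_range)))

    seen_names = config.seen_classes()
    unseen_names = config.unseen_classes()
    n = config.n_per_stratum

    ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[str] = []
    batches: list[str] = []
    states: list[str] = []
    seen_flags: list[bool] = []

    def add_stratum(tag, batch, state, seen, means, names, class_idx):
        offset = offset_b if batch == BATCH_SHIFTED else 0.0
        noise = rng.normal(0.0, config.noise_sd, size=(class_idx.size, d))
        x = means[class_idx] + noise + offset
        for j in range(class_idx.size):
            ids.append(f"{tag}-{j:04d}")
        rows.append(x)
        labels.extend(names[c] for c in class_idx)
        batches.extend([batch] * class_idx.size)
        states.extend([state] * class_idx.size)
        seen_flags.extend([seen] * class_idx.size)

    # IID development stratum
    add_stratum("IID", BATCH_DEV, "Primary", True, sig_seen, seen_names,
                _balanced_labels(config.n_iid_stratum, config.k_seen, rng))
    # batch-shifted primaries
    add_stratum("OODB", BATCH_SHIFTED, "Primary", True, sig_seen, seen_names,
                _balanced_labels(n, config.k_seen, rng))
    # metastatic blend within the development batch
    sig_met = (1.0 - config.blend_alpha) * sig_seen + config.blend_alpha * sig_seen[nearest_seen]
    add_stratum("OODM", BATCH_DEV, "Metastatic", True, sig_met, seen_names,
                _balanced_labels(n, config.k_seen, rng))
    # unseen classes in the shifted batch
    if config.k_unseen > 0:
        w = unseen_blend[:, None]
        sig_unseen = (1.0 - w) * sig_fresh + w * sig_seen[[related[u] for u in range(config.k_unseen)]]
        add_stratum("OODU", BATCH_SHIFTED, "Metastatic", False, sig_unseen, unseen_names,
                    _balanced_labels(config.n_unseen_stratum, config.k_unseen, rng))

    return StrataDataset(
        sample_id=ids,
        X=np.vstack(rows),
        y=np.asarray(labels, dtype=object),
        batch=np.asarray(batches, dtype=object),
        state=np.asarray(states, dtype=object),
        seen=np.asarray(seen_flags, dtype=bool),
        iid_key=IID_KEY,
    )


@dataclass
class Subset:
    """A plain (ids, X, y) view used for the train/validation split."""

    sample_id: list[str]
    X: np.ndarray
    y: np.ndarray


def split_development(
    dataset: StrataDataset, val_fraction: float = 0.25, seed: int = 0
) -> tuple[Subset, Subset]:
    """Stratified-by-class split of the IID stratum into train and validation.

    Only the designated IID stratum is split; OOD samples never enter either
    side. Per class, ``round(n_c · val_fraction)`` samples (at least one, and
    at least one left for training) go to validation.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    iid = np.flatnonzero(dataset.iid_mask())
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in sorted(set(dataset.y[iid])):
        members = iid[dataset.y[iid] == cls]
        if members.size < 2:
            raise ValueError(f"class {cls!r} has fewer than two IID samples")
        members = members[rng.permutation(members.size)]
        n_val = int(round(members.size * val_fraction))
        n_val = min(max(n_val, 1), members.size - 1)
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    train_idx = np.asarray(sorted(train_idx))
    val_idx = np.asarray(sorted(val_idx))

    def take(idx: np.ndarray) -> Subset:
        return Subset(
            sample_id=[dataset.sample_id[i] for i in idx],
            X=dataset.X[idx],
            y=dataset.y[idx],
        )

    return take(train_idx), take(val_idx)
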