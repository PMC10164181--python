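"""Controlled four-model benchmark over IID and OOD strata.

One shared :class:`~shiftbench.models.ModelSpec` parameterises all four
variants (the controlled-benchmark design: identical architecture and
optimisation settings), each seed generates a fresh strata dataset, trains the
variants on the IID split, predicts on the validation (development) and pooled
OOD (production) data, and computes the full metric stack — micro-F1, entropy
distributions, ECE, per-sample calibration error, F1-AUC and ADP with optional
bootstrap CI — plus Wilcoxon rank-sum comparisons against the pointwise
baseline with the conventional star codes.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from . import metrics as M
from .models import (
    ModelSpec,
    build_network,
    predict_ensemble,
    predict_mcd,
    predict_pointwise,
    train,
)
from .synthetic import SyntheticConfig, generate, split_development
from .tables import BenchmarkReport, PredictionTable, StrataDataset, config_hash

__all__ = [
    "BenchmarkConfig",
    "MODEL_NAMES",
    "run_benchmark",
    "compare_uncertainties",
    "adp_range_checks",
    "stars",
    "fit_variants",
]

MODEL_NAMES = ("resnet", "mcd", "bilipschitz", "ensemble")


@dataclass
class BenchmarkConfig:
    """Everything needed to reproduce one benchmark run."""

    model: ModelSpec = field(default_factory=ModelSpec)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    val_fraction: float = 0.25
    m_bins: int = 10
    uncertainty: str = "entropy"
    f1_min: float = M.DEFAULT_F1_MIN
    f1_max: float = M.DEFAULT_F1_MAX
    grid_step: float = M.DEFAULT_GRID_STEP
    bootstrap: int = 0
    alpha: float = 0.05
    min_support: int = 30
    production_floor: float = 0.9
    # stop every Bayesian variant at the baseline's best validation NLL, so
    # IID accuracy differences cannot confound the uncertainty comparison
    loss_controlled: bool = True

    def __post_init__(self) -> None:
        if len(self.seeds) == 0:
            raise ValueError("seeds list must be nonempty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        return d


def stars(p_value: float) -> str:
    """Significance star code: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_uncertainties(
    a: np.ndarray, b: np.ndarray, sidedness: str = "greater"
) -> tuple[float, float, str]:
    """Wilcoxon rank-sum test between two per-sample uncertainty samples.

    `sidedness` is 'greater' (a tends larger than b), 'less', or 'two-sided'.
    All-tied degenerate inputs return (0, 1, 'ns') with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if sidedness not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all-tied rank-sum inputs; reporting ns", stacklevel=2)
        return 0.0, 1.0, "ns"
    stat, p = stats.ranksums(a, b, alternative=sidedness)
    return float(stat), float(p), stars(float(p))


def _holm(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def adp_range_checks(
    dev_curve: M.F1UncertaintyCurve,
    f1_min: float = M.DEFAULT_F1_MIN,
    f1_max: float = M.DEFAULT_F1_MAX,
    min_support: int = 30,
    production_floor: float = 0.9,
) -> list[str]:
    """The two sanity checks on the nominal F1 range, as warnings.

    First check: the retained-sample count where the development curve first
    attains ``f1_max`` must be large enough for the top of the range to be
    trustworthy. Second check: ``f1_min`` must sit above the minimally
    acceptable production accuracy floor.
    """
    out: list[str] = []
    meets = np.flatnonzero(dev_curve.f1 >= f1_max)
    if meets.size == 0:
        out.append(
            f"development curve never attains F1 >= {f1_max}; ADP is undefined "
            "on this range"
        )
    else:
        support = int(dev_curve.n_retained[meets].max())
        if support < min_support:
            out.append(
                f"only {support} retained development samples at F1 >= {f1_max} "
                f"(< {min_support}); the top of the nominal range is unstable"
            )
    if f1_min < production_floor:
        out.append(
            f"f1_min={f1_min} is below the production accuracy floor "
            f"{production_floor}; decreases may understate deployment risk"
        )
    return out


# ---------------------------------------------------------------------------
# model fitting


def _variant_seed(seed: int, offset: int) -> int:
    return (seed * 1000003 + offset * 7919 + 17) % (2**31 - 1)


def fit_variants(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train_idx: np.ndarray,
    X_val: np.ndarray,
    y_val_idx: np.ndarray,
    seed: int,
    loss_controlled: bool = True,
) -> dict:
    """Train the four variants from one shared spec; returns name -> predictor.

    Each predictor maps an (n, D) matrix to MC-averaged probabilities. The
    histories and the trained networks are attached for inspection. With
    `loss_controlled` the Bayesian variants stop at the first epoch whose
    validation NLL reaches the baseline's best, keeping IID performance
    comparable across variants so it cannot confound the uncertainty metrics.
    """
    d = X_train.shape[1]
    k = int(max(y_train_idx.max(), y_val_idx.max())) + 1
    out: dict = {"networks": {}, "histories": {}, "predictors": {}, "failures": {}}

    def make(offset):
        s = ModelSpec(**{**asdict(spec), "seed": _variant_seed(seed, offset)})
        return build_network(s, d, k)

    target_nll = None

    # pointwise baseline: plain cross-entropy, nothing stochastic at inference
    try:
        net = make(0)
        hist = train(net, X_train, y_train_idx, X_val, y_val_idx, heteroscedastic=False)
        out["networks"]["resnet"] = net
        out["histories"]["resnet"] = hist
        out["predictors"]["resnet"] = lambda X, n=net: predict_pointwise(n, X).mean_probs
        if loss_controlled:
            target_nll = hist.val_nll[hist.best_epoch]
    except FloatingPointError as err:  # pragma: no cover - divergence guard
        out["failures"]["resnet"] = str(err)

    # MC dropout with the heteroscedastic Gaussian head
    try:
        net = make(1)
        hist = train(net, X_train, y_train_idx, X_val, y_val_idx,
                     heteroscedastic=True, target_val_nll=target_nll)
        out["networks"]["mcd"] = net
        out["histories"]["mcd"] = hist
        out["predictors"]["mcd"] = lambda X, n=net: predict_mcd(
            n, X, seed=_variant_seed(seed, 11)
        ).mean_probs
    except FloatingPointError as err:  # pragma: no cover
        out["failures"]["mcd"] = str(err)

    # bi-Lipschitz: MCD plus spectral normalisation after every step
    try:
        net = make(2)
        hist = train(
            net, X_train, y_train_idx, X_val, y_val_idx,
            heteroscedastic=True, spectral_bound=spec.spectral_bound,
            target_val_nll=target_nll,
        )
        out["networks"]["bilipschitz"] = net
        out["histories"]["bilipschitz"] = hist
        out["predictors"]["bilipschitz"] = lambda X, n=net: predict_mcd(
            n, X, seed=_variant_seed(seed, 12)
        ).mean_probs
    except FloatingPointError as err:  # pragma: no cover
        out["failures"]["bilipschitz"] = str(err)

    # deep ensemble of independently initialised bi-Lipschitz members
    members = []
    try:
        for j in range(spec.ensemble_size):
            net = make(100 + j)
            train(
                net, X_train, y_train_idx, X_val, y_val_idx,
                heteroscedastic=True, spectral_bound=spec.spectral_bound,
                target_val_nll=target_nll,
            )
            members.append(net)
        out["networks"]["ensemble"] = members
        out["predictors"]["ensemble"] = lambda X, ms=members: predict_ensemble(
            ms, X, seed=_variant_seed(seed, 13)
        ).mean_probs
    except FloatingPointError as err:  # pragma: no cover
        out["failures"]["ensemble"] = str(err)
    return out


# ---------------------------------------------------------------------------
# per-seed evaluation


def _table(ids, y, probs, classes) -> PredictionTable:
    return PredictionTable(sample_id=ids, true_label=list(y), probs=probs, classes=classes)


def _evaluate_model(
    dev_table: PredictionTable,
    prod_table: PredictionTable,
    ood_masks: dict[str, np.ndarray],
    config: BenchmarkConfig,
    seed: int,
) -> dict:
    """All metrics for one model on one seed; arrays kept under '_arrays'."""
    rec: dict = {}
    dev_u = M.uncertainty_scores(dev_table, config.uncertainty)
    prod_u = M.uncertainty_scores(prod_table, config.uncertainty)
    rec["iid_f1"] = M.micro_f1(dev_table.predicted_label, dev_table.true_label)
    rec["ood_f1"] = M.micro_f1(prod_table.predicted_label, prod_table.true_label)
    rec["iid_mean_entropy"] = float(np.mean(dev_table.entropy))
    rec["ood_mean_entropy"] = float(np.mean(prod_table.entropy))
    rec["iid_ece"] = M.ece(dev_table.confidence, dev_table.correct, config.m_bins).ece
    rec["ood_ece"] = M.ece(prod_table.confidence, prod_table.correct, config.m_bins).ece
    rec["iid_calibration_error"] = float(
        np.mean(M.samplewise_calibration_error(dev_table, config.m_bins))
    )
    rec["ood_calibration_error"] = float(
        np.mean(M.samplewise_calibration_error(prod_table, config.m_bins))
    )
    for name, mask in ood_masks.items():
        sub = prod_table.subset(np.flatnonzero(mask))
        rec[f"f1[{name}]"] = M.micro_f1(sub.predicted_label, sub.true_label)
        rec[f"mean_entropy[{name}]"] = float(np.mean(sub.entropy))
        rec[f"ece[{name}]"] = M.ece(sub.confidence, sub.correct, config.m_bins).ece
    rec["f1_auc"] = M.f1_retention_curve(prod_table, prod_u).auc
    dev_curve = M.f1_uncertainty_curve(dev_table, dev_u, flavour="development")
    prod_curve = M.f1_uncertainty_curve(prod_table, prod_u, flavour="production")
    rec["range_warnings"] = adp_range_checks(
        dev_curve, config.f1_min, config.f1_max, config.min_support,
        config.production_floor,
    )
    try:
        result = M.adp(
            dev_curve, prod_curve, config.f1_min, config.f1_max, config.grid_step
        )
        rec["adp"] = result.adp
        if config.bootstrap:
            rec["adp_ci"] = list(
                M.adp_bootstrap_ci(
                    dev_table, prod_table,
                    n_boot=config.bootstrap, alpha=config.alpha,
                    seed=_variant_seed(seed, 999),
                    uncertainty=config.uncertainty,
                    f1_min=config.f1_min, f1_max=config.f1_max,
                    step=config.grid_step,
                )
            )
    except ValueError as err:
        rec["adp"] = None
        rec["adp_error"] = str(err)
    rec["_arrays"] = {
        "dev_entropy": np.asarray(dev_table.entropy),
        "prod_entropy": np.asarray(prod_table.entropy),
        "prod_calibration": M.samplewise_calibration_error(prod_table, config.m_bins),
        "unseen_entropy": np.asarray(prod_table.entropy)[ood_masks["unseen"]]
        if "unseen" in ood_masks
        else None,
    }
    return rec


def run_seed(config: BenchmarkConfig, seed: int) -> tuple[dict, list]:
    """Run the full four-model benchmark for one seed."""
    synth = SyntheticConfig(**{**asdict(config.synthetic), "seed": seed})
    dataset = generate(synth)
    train_set, val_set = split_development(dataset, config.val_fraction, seed)
    classes = dataset.iid_classes()
    cls_index = {c: i for i, c in enumerate(classes)}
    y_train = np.asarray([cls_index[c] for c in train_set.y])
    y_val = np.asarray([cls_index[c] for c in val_set.y])

    fitted = fit_variants(
        config.model, train_set.X, y_train, val_set.X, y_val, seed,
        loss_controlled=config.loss_controlled,
    )

    ood = np.flatnonzero(dataset.ood_mask())
    ood_ids = [dataset.sample_id[i] for i in ood]
    ood_y = dataset.y[ood]
    ood_masks = {
        "seen": dataset.seen[ood],
        "unseen": ~dataset.seen[ood],
    }
    if not ood_masks["unseen"].any():
        del ood_masks["unseen"]
    for key in dataset.ood_keys():
        label = f"{key[0]}/{key[1]}/{'seen' if key[2] else 'unseen'}"
        ood_masks[label] = dataset.mask(key)[ood]

    per_model: dict = {}
    for name in MODEL_NAMES:
        if name in fitted["failures"]:
            per_model[name] = {"failure": fitted["failures"][name]}
            continue
        probs_dev = fitted["predictors"][name](val_set.X)
        probs_prod = fitted["predictors"][name](dataset.X[ood])
        dev_table = _table(val_set.sample_id, val_set.y, probs_dev, classes)
        prod_table = _table(ood_ids, ood_y, probs_prod, classes)
        per_model[name] = _evaluate_model(dev_table, prod_table, ood_masks, config, seed)

    comparisons: list = []
    baseline = per_model.get("resnet", {})
    if "_arrays" in baseline:
        for name in ("mcd", "bilipschitz", "ensemble"):
            if "_arrays" not in per_model.get(name, {}):
                continue
            pairs = [
                ("ood_entropy", "prod_entropy", "greater"),
                ("ood_calibration_error", "prod_calibration", "less"),
            ]
            if baseline["_arrays"]["unseen_entropy"] is not None:
                pairs.append(("unseen_entropy", "unseen_entropy", "two-sided"))
            for metric, key, side in pairs:
                stat, p, code = compare_uncertainties(
                    per_model[name]["_arrays"][key], baseline["_arrays"][key], side
                )
                comparisons.append(
                    {
                        "seed": seed,
                        "metric": metric,
                        "model": name,
                        "baseline": "resnet",
                        "sidedness": side,
                        "statistic": stat,
                        "p": p,
                        "stars": code,
                    }
                )
    if comparisons:
        adj = _holm([c["p"] for c in comparisons])
        for c, pa in zip(comparisons, adj):
            c["p_holm"] = pa
            c["stars_holm"] = stars(pa)
    return per_model, comparisons


def _aggregate(per_seed: dict) -> dict:
    agg: dict = {}
    keys = set()
    for rec in per_seed.values():
        keys |= {k for k, v in rec.items() if isinstance(v, (int, float)) and v is not None}
    for key in sorted(keys):
        vals = [
            rec[key]
            for rec in per_seed.values()
            if isinstance(rec.get(key), (int, float))
        ]
        if vals:
            agg[key] = {
                "mean": float(np.mean(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "n_seeds": len(vals),
            }
    return agg


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run every seed, aggregate, and assemble the report.

    A variant whose training diverges on some seed is recorded as an explicit
    failure for that seed, never silently skipped.
    """
    models: dict = {name: {"per_seed": {}} for name in MODEL_NAMES}
    comparisons: list = []
    for seed in config.seeds:
        per_model, comps = run_seed(config, seed)
        comparisons.extend(comps)
        for name, rec in per_model.items():
            rec = {k: v for k, v in rec.items() if k != "_arrays"}
            models[name]["per_seed"][str(seed)] = rec
    for name in MODEL_NAMES:
        models[name]["aggregate"] = _aggregate(models[name]["per_seed"])
    provenance = {
        "seeds": list(config.seeds),
        "config_hash": config_hash(config.to_dict()),
        "config": config.to_dict(),
        "uncertainty": config.uncertainty,
    }
    return BenchmarkReport(models=models, comparisons=comparisons, provenance=provenance)
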