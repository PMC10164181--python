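"""Data model and IO for prediction tables, strata datasets and benchmark reports.

A *prediction table* is the universal metric input: one row per sample with its
true label and a row-stochastic class-probability vector. Derived per-sample
quantities (predicted label, confidence = max probability, Shannon entropy in
nats) are recomputed on construction and, when present in a file, checked
against the stored values.

A *strata dataset* is a feature matrix plus labels, partitioned by the triple
(batch, state-of-metastases, seen-in-training) into exactly one IID
development stratum and one or more OOD production strata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PredictionTable",
    "StrataDataset",
    "BenchmarkReport",
    "read_prediction_table",
    "write_prediction_table",
    "read_strata_dataset",
    "write_strata_dataset",
    "read_report",
    "write_report",
]

# Tolerance for accepting a probability row as stochastic (IO contract);
# stored derived columns must agree with recomputed ones to _DERIVED_ATOL.
_ROW_SUM_ATOL = 1e-6
_DERIVED_ATOL = 1e-9

_PROB_PREFIX = "p_"
_VALID_STATES = ("Primary", "Metastatic")


def _entropy_rows(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(probs > 0.0, probs * np.log(probs), 0.0)
    return -t.sum(axis=1)


@dataclass
class PredictionTable:
    """Per-sample class-probability vectors with labels and derived uncertainties.

    Parameters
    ----------
    sample_id
        Opaque, unique string identifiers (duplicates rejected).
    true_label
        Ground-truth class per sample. May contain labels outside `classes`
        (samples from classes unseen during training; such samples can never
        be predicted correctly).
    probs
        ``(n, K)`` row-stochastic matrix; column order given by `classes`.
    classes
        Class labels naming the probability columns, order preserved.
    """

    sample_id: list[str]
    true_label: list[str]
    probs: np.ndarray
    classes: list[str]
    predicted_label: np.ndarray = field(init=False, repr=False)
    confidence: np.ndarray = field(init=False, repr=False)
    entropy: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.sample_id = [str(s) for s in self.sample_id]
        self.true_label = [str(s) for s in self.true_label]
        n, k = self.probs.shape if self.probs.ndim == 2 else (0, 0)
        if n < 1 or k < 2:
            raise ValueError("prediction table needs n >= 1 samples and K >= 2 classes")
        if len(self.sample_id) != n or len(self.true_label) != n:
            raise ValueError("sample_id/true_label length does not match probs rows")
        if len(self.classes) != k:
            raise ValueError("classes length does not match probability columns")
        if len(set(self.classes)) != k:
            raise ValueError("duplicate class labels")
        if len(set(self.sample_id)) != n:
            raise ValueError("duplicate sample ids")
        if np.any(self.probs < 0):
            raise ValueError("negative probabilities")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_ATOL)
        if bad.size:
            raise ValueError(
                f"probability rows do not sum to 1 within {_ROW_SUM_ATOL}: "
                f"first offending sample {self.sample_id[bad[0]]!r} (sum={sums[bad[0]]!r})"
            )
        idx = self.probs.argmax(axis=1)
        self.predicted_label = np.asarray([self.classes[i] for i in idx], dtype=object)
        self.confidence = self.probs.max(axis=1)
        self.entropy = _entropy_rows(self.probs)

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    @property
    def correct(self) -> np.ndarray:
        """Boolean per-sample correctness (unseen-class samples always False)."""
        return np.asarray(
            [p == t for p, t in zip(self.predicted_label, self.true_label)], dtype=bool
        )

    def subset(self, index: np.ndarray) -> "PredictionTable":
        index = np.asarray(index)
        return PredictionTable(
            sample_id=[self.sample_id[i] for i in index],
            true_label=[self.true_label[i] for i in index],
            probs=self.probs[index],
            classes=list(self.classes),
        )

    def resample(self, index: np.ndarray, suffix: str = "_bs") -> "PredictionTable":
        """Row resample (with repeats allowed); ids are disambiguated."""
        index = np.asarray(index)
        ids = [f"{self.sample_id[i]}{suffix}{j}" for j, i in enumerate(index)]
        return PredictionTable(
            sample_id=ids,
            true_label=[self.true_label[i] for i in index],
            probs=self.probs[index],
            classes=list(self.classes),
        )


def _dialect_sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if dialect == "csv" else "\t"


def read_prediction_table(
    path: str | Path, dialect: str | None = None, renormalise: bool = False
) -> PredictionTable:
    """Read a prediction table from TSV/CSV.

    Expected header: ``sample_id, label, p_<class1>, ..., p_<classK>`` with
    optional stored ``predicted_label``, ``confidence``, ``entropy`` columns,
    which are recomputed and must agree within 1e-9.

    Rows whose probabilities sum outside ``1 ± 1e-6`` are a validation error
    unless ``renormalise=True``, in which case rows are rescaled to sum to 1.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "label": str})
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    prob_cols = [c for c in df.columns if c.startswith(_PROB_PREFIX)]
    if len(prob_cols) < 2:
        raise ValueError(f"{path}: needs at least two {_PROB_PREFIX}<class> columns")
    classes = [c[len(_PROB_PREFIX):] for c in prob_cols]
    probs = df[prob_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(probs).all(axis=1) | df["sample_id"].isna().to_numpy())
    if bad.size:
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    sums = probs.sum(axis=1)
    out_of_tol = np.abs(sums - 1.0) > _ROW_SUM_ATOL
    if np.any(out_of_tol):
        if not renormalise:
            line = int(np.flatnonzero(out_of_tol)[0]) + 2
            raise ValueError(
                f"{path}: probability row at line {line} sums to {sums[line - 2]:.8g}; "
                "pass renormalise=True to rescale"
            )
        probs = probs / sums[:, None]
    table = PredictionTable(
        sample_id=df["sample_id"].tolist(),
        true_label=df["label"].tolist(),
        probs=probs,
        classes=classes,
    )
    checks = {
        "confidence": table.confidence,
        "entropy": table.entropy,
    }
    for col, expected in checks.items():
        if col in df.columns:
            stored = df[col].to_numpy(dtype=float)
            if np.max(np.abs(stored - expected)) > _DERIVED_ATOL:
                raise ValueError(f"{path}: stored {col} disagrees with recomputed values")
    if "predicted_label" in df.columns:
        stored_lab = df["predicted_label"].astype(str).to_numpy()
        if not np.array_equal(stored_lab, table.predicted_label.astype(str)):
            raise ValueError(f"{path}: stored predicted_label disagrees with argmax")
    return table


def write_prediction_table(
    table: PredictionTable, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.DataFrame({"sample_id": table.sample_id, "label": table.true_label})
    for j, cls in enumerate(table.classes):
        df[f"{_PROB_PREFIX}{cls}"] = table.probs[:, j]
    df["predicted_label"] = table.predicted_label
    df["confidence"] = table.confidence
    df["entropy"] = table.entropy
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Strata datasets


def _normalise_state(value: str) -> str:
    v = str(value).strip().capitalize()
    if v not in _VALID_STATES:
        raise ValueError(f"unknown state_of_metastases value {value!r}")
    return v


def _normalise_seen(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    v = str(value).strip().casefold()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(f"unknown seen value {value!r}")


@dataclass
class StrataDataset:
    """Feature matrix + labels partitioned into one IID and several OOD strata.

    Each sample carries a strata key ``(batch, state_of_metastases, seen)``.
    Exactly one key — `iid_key` — designates the development (training +
    validation) pool; all other strata are out-of-distribution test sets.
    """

    sample_id: list[str]
    X: np.ndarray
    y: np.ndarray
    batch: np.ndarray
    state: np.ndarray
    seen: np.ndarray
    iid_key: tuple[str, str, bool]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.state = np.asarray([_normalise_state(s) for s in self.state], dtype=object)
        self.seen = np.asarray([_normalise_seen(s) for s in self.seen], dtype=bool)
        n = self.X.shape[0]
        if len(set(self.sample_id)) != n:
            raise ValueError("duplicate sample ids")
        for arr in (self.y, self.batch, self.state, self.seen):
            if arr.shape[0] != n:
                raise ValueError("metadata length does not match feature rows")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        iid = self.iid_mask()
        if not iid.any():
            raise ValueError(f"no samples in designated IID stratum {self.iid_key!r}")
        iid_labels = set(self.y[iid])
        seen_labels = set(self.y[self.seen])
        unseen_labels = set(self.y[~self.seen])
        missing = seen_labels - iid_labels
        if missing:
            raise ValueError(
                f"seen=true samples carry labels absent from the IID stratum: {sorted(missing)}"
            )
        overlap = unseen_labels & iid_labels
        if overlap:
            raise ValueError(
                f"seen=false samples carry labels present in the IID stratum: {sorted(overlap)}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def keys(self) -> list[tuple[str, str, bool]]:
        seen_keys: list[tuple[str, str, bool]] = []
        for b, s, f in zip(self.batch, self.state, self.seen):
            key = (b, s, bool(f))
            if key not in seen_keys:
                seen_keys.append(key)
        return seen_keys

    def mask(self, key: tuple[str, str, bool]) -> np.ndarray:
        b, s, f = key
        return (
            (self.batch == b)
            & (self.state == _normalise_state(s))
            & (self.seen == _normalise_seen(f))
        )

    def iid_mask(self) -> np.ndarray:
        return self.mask(self.iid_key)

    def ood_keys(self) -> list[tuple[str, str, bool]]:
        return [k for k in self.keys() if k != self.iid_key]

    def ood_mask(self) -> np.ndarray:
        return ~self.iid_mask()

    def counts(self) -> dict[tuple[str, str, bool], int]:
        return {k: int(self.mask(k).sum()) for k in self.keys()}

    def iid_classes(self) -> list[str]:
        return sorted(set(self.y[self.iid_mask()]))


def read_strata_dataset(
    features_path: str | Path,
    labels_path: str | Path,
    strata_path: str | Path,
    iid_key: tuple[str, str, bool] | None = None,
) -> StrataDataset:
    """Assemble a StrataDataset from three TSV files sharing sample ids.

    ``features``: ``sample_id`` + one column per feature.
    ``labels``: ``sample_id, label``.
    ``strata``: ``sample_id, batch, state_of_metastases, seen`` (keys are
    case-normalised on read).

    When `iid_key` is omitted, the unique ``(*, Primary, seen=True)`` stratum
    is taken as the development pool; ambiguity is an error.
    """
    feats = pd.read_csv(features_path, sep="\t", dtype={"sample_id": str})
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    strata = pd.read_csv(strata_path, sep="\t", dtype=str)
    for df, name, cols in (
        (feats, "features", ["sample_id"]),
        (labels, "labels", ["sample_id", "label"]),
        (strata, "strata", ["sample_id", "batch", "state_of_metastases", "seen"]),
    ):
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"{name} file missing column {c!r}")
    ids = feats["sample_id"].tolist()
    if set(ids) != set(labels["sample_id"]) or set(ids) != set(strata["sample_id"]):
        raise ValueError("sample ids do not match across features/labels/strata files")
    labels = labels.set_index("sample_id").loc[ids].reset_index()
    strata = strata.set_index("sample_id").loc[ids].reset_index()
    feature_names = [c for c in feats.columns if c != "sample_id"]
    X = feats[feature_names].to_numpy(dtype=float)
    state = [_normalise_state(s) for s in strata["state_of_metastases"]]
    seen = [_normalise_seen(s) for s in strata["seen"]]
    batch = strata["batch"].astype(str).str.strip().tolist()
    if iid_key is None:
        cands = sorted(
            {(b, s, f) for b, s, f in zip(batch, state, seen) if s == "Primary" and f}
        )
        if len(cands) != 1:
            raise ValueError(
                "cannot infer the IID stratum: pass iid_key explicitly "
                f"(candidates: {cands})"
            )
        iid_key = cands[0]
    else:
        iid_key = (str(iid_key[0]), _normalise_state(iid_key[1]), _normalise_seen(iid_key[2]))
    return StrataDataset(
        sample_id=ids,
        X=X,
        y=labels["label"].to_numpy(dtype=object),
        batch=np.asarray(batch, dtype=object),
        state=np.asarray(state, dtype=object),
        seen=np.asarray(seen, dtype=bool),
        iid_key=iid_key,
        feature_names=feature_names,
    )


def write_strata_dataset(ds: StrataDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write features/labels/strata TSVs; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.tsv",
        "labels": out / "labels.tsv",
        "strata": out / "strata.tsv",
    }
    feats = pd.DataFrame(ds.X, columns=ds.feature_names)
    feats.insert(0, "sample_id", ds.sample_id)
    feats.to_csv(paths["features"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame({"sample_id": ds.sample_id, "label": ds.y}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    pd.DataFrame(
        {
            "sample_id": ds.sample_id,
            "batch": ds.batch,
            "state_of_metastases": ds.state,
            "seen": ds.seen,
        }
    ).to_csv(paths["strata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Benchmark reports

_STAR_CODES = ("ns", "*", "**", "***")


@dataclass
class BenchmarkReport:
    """Per-model, per-stratum metric values plus pairwise tests and provenance.

    `models` maps model name -> {"per_seed": {seed: {...}}, "aggregate": {...}};
    `comparisons` is a flat list of test records with star codes in
    {ns, *, **, ***}; `provenance` records seeds and a config hash.
    """

    models: dict
    comparisons: list
    provenance: dict

    def __post_init__(self) -> None:
        for rec in self.comparisons:
            if rec.get("stars") not in _STAR_CODES:
                raise ValueError(f"invalid star code {rec.get('stars')!r}")

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "comparisons": self.comparisons,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        return cls(
            models=d.get("models", {}),
            comparisons=d.get("comparisons", []),
            provenance=d.get("provenance", {}),
        )


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)) and obj and all(
        isinstance(v, (int, float)) for v in obj
    ):
        rows.append((prefix, ";".join(repr(float(v)) for v in obj)))
    elif isinstance(obj, (int, float, str, bool)) or obj is None:
        rows.append((prefix, obj))
    else:
        rows.append((prefix, json.dumps(obj, default=str)))


def write_report(
    report: BenchmarkReport, path: str | Path, tsv_decimals: int = 4
) -> tuple[Path, Path]:
    """Write the canonical JSON rendering plus a flat TSV summary.

    JSON keeps full precision; the TSV rounds floats to `tsv_decimals`.
    Returns (json_path, tsv_path).
    """
    path = Path(path)
    json_path = path if path.suffix == ".json" else path.with_suffix(".json")
    tsv_path = json_path.with_suffix(".tsv")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)
    rows: list = []
    _flatten("", report.to_dict(), rows)
    with open(tsv_path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, val in rows:
            if isinstance(val, float):
                val = round(val, tsv_decimals)
            fh.write(f"{key}\t{val}\n")
    return json_path, tsv_path


def read_report(path: str | Path) -> BenchmarkReport:
    with open(path) as fh:
        return BenchmarkReport.from_dict(json.load(fh))
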