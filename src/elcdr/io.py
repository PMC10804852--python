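"""Table readers/writers and the model-adapter file contract.

Any external system — a training pipeline for convolutional networks, an
R script, a spreadsheet — participates in an ensemble run by exporting
two delimited-text tables per model:

feature table
    header ``sample_id,label,f1..fd`` — one row per training sample with
    its class label and the d components of its embedding vector;
softmax table
    header ``sample_id,<class_id_1>..<class_id_k>`` — one row per
    evaluation sample with the model's class probabilities.

A truth table (``sample_id,label``) scores predictions.  Delimiter is
inferred from the extension (.csv comma, .tsv tab); encoding is UTF-8
with '.' decimals.  Floats are written with repr-level precision so a
write/read round trip is exact and repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .evaluation import ConfusionMatrix
from .fusion import EnsembleResult, SoftmaxTable
from .separation import FeatureVectorSet, SeparationStats, WeightVector

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_softmax_table",
    "write_softmax_table",
    "read_truth_table",
    "write_truth_table",
    "read_predictions",
    "write_predictions",
    "write_weights_report",
    "write_confusion_matrix",
    "write_ensemble_fixture",
]

_FLOAT_FMT = "%.17g"


def _delimiter(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix == ".tsv":
        return "\t"
    raise InvalidInputError(
        f"cannot infer delimiter from extension {suffix!r} of {path} (use .csv or .tsv)"
    )


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _delimiter(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: missing cell on line {row + 2}")
    return df


def _numeric_block(df: pd.DataFrame, cols: list[str], path: Path) -> np.ndarray:
    block = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        col = block.columns[block.iloc[row].isna().argmax()]
        raise ParseError(
            f"{path}: non-numeric value {df.at[row, col]!r} in column {col!r} on line {row + 2}"
        )
    return block.to_numpy(dtype=float)


def _check_unique_samples(ids: Iterable[str], path: Path) -> None:
    seen: set[str] = set()
    for i, sid in enumerate(ids):
        if sid in seen:
            raise ParseError(f"{path}: duplicate sample id {sid!r} on line {i + 2}")
        seen.add(sid)


def read_feature_table(path: str | Path, model_id: str | None = None) -> FeatureVectorSet:
    """Parse a labeled feature-vector table into a :class:`FeatureVectorSet`."""
    path = Path(path)
    df = _read_frame(path)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ParseError(
            f"{path}: feature table must start with columns sample_id,label, "
            f"got {list(df.columns[:3])}"
        )
    feat_cols = list(df.columns[2:])
    if not feat_cols:
        raise ParseError(f"{path}: feature table has no feature columns")
    _check_unique_samples(df["sample_id"], path)
    vectors = _numeric_block(df, feat_cols, path)
    return FeatureVectorSet(
        vectors,
        df["label"].to_numpy(dtype=object),
        model_id=model_id if model_id is not None else path.stem,
        sample_ids=tuple(df["sample_id"]),
    )


def write_feature_table(fvs: FeatureVectorSet, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(fvs.vectors, columns=[f"f{j + 1}" for j in range(fvs.d)])
    df.insert(0, "label", list(fvs.labels))
    df.insert(0, "sample_id", list(fvs.sample_ids))
    df.to_csv(path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT)


def read_softmax_table(
    path: str | Path, model_id: str | None = None, renormalize: bool = False
) -> SoftmaxTable:
    """Parse a per-model softmax table; rows must sum to 1 unless ``renormalize``."""
    path = Path(path)
    df = _read_frame(path)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be sample_id, got {df.columns[0]!r}")
    class_ids = tuple(df.columns[1:])
    if len(class_ids) < 2:
        raise ParseError(f"{path}: softmax table needs at least 2 class columns")
    _check_unique_samples(df["sample_id"], path)
    probs = _numeric_block(df, list(class_ids), path)
    if renormalize:
        sums = probs.sum(axis=1)
        if (sums <= 0).any():
            row = int(np.argmax(sums <= 0))
            raise ParseError(f"{path}: row on line {row + 2} sums to {sums[row]:g}, cannot renormalize")
        probs = probs / sums[:, None]
    return SoftmaxTable(
        probs,
        sample_ids=tuple(df["sample_id"]),
        class_ids=class_ids,
        model_id=model_id if model_id is not None else path.stem,
    )


def write_softmax_table(table: SoftmaxTable, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.probs, columns=list(table.class_ids))
    df.insert(0, "sample_id", list(table.sample_ids))
    df.to_csv(path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT)


def read_truth_table(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read a ``sample_id,label`` table; returns (sample_ids, labels)."""
    path = Path(path)
    df = _read_frame(path)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ParseError(
            f"{path}: truth table must have columns sample_id,label, got {list(df.columns)}"
        )
    _check_unique_samples(df["sample_id"], path)
    return tuple(df["sample_id"]), tuple(df["label"])


def write_truth_table(
    sample_ids: Iterable[str], labels: Iterable[str], path: str | Path
) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)}).to_csv(
        path, sep=_delimiter(path), index=False
    )


def read_predictions(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read a predictions table; returns (sample_ids, predicted labels)."""
    path = Path(path)
    df = _read_frame(path)
    if list(df.columns[:2]) != ["sample_id", "predicted"]:
        raise ParseError(
            f"{path}: predictions table must start with sample_id,predicted, "
            f"got {list(df.columns[:2])}"
        )
    _check_unique_samples(df["sample_id"], path)
    return tuple(df["sample_id"]), tuple(df["predicted"])


def write_predictions(result: EnsembleResult, path: str | Path) -> None:
    """Write ``sample_id,predicted,<class probabilities>`` for a fused run."""
    path = Path(path)
    df = pd.DataFrame(result.fused, columns=list(result.class_ids))
    df.insert(0, "predicted", list(result.predicted))
    df.insert(0, "sample_id", list(result.sample_ids))
    df.to_csv(path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT)


def write_weights_report(
    stats: Mapping[str, SeparationStats], weights: WeightVector, path: str | Path
) -> None:
    """JSON report ``{model_id: {icD, bcD, FEP, weight}}`` in model order."""
    if tuple(stats) != weights.model_ids:
        raise InvalidInputError("stats keys must match weight model ids in order")
    report = {
        m: {
            "icD": stats[m].icd,
            "bcD": stats[m].bcd,
            "FEP": stats[m].fep,
            "weight": float(w),
        }
        for m, w in zip(weights.model_ids, weights.weights)
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")


def write_confusion_matrix(cm: ConfusionMatrix, path: str | Path) -> None:
    """Delimited confusion matrix with class identifiers on both margins."""
    path = Path(path)
    cols = list(cm.class_ids) + ["INVALID"]
    df = pd.DataFrame(cm.counts, columns=cols)
    df.insert(0, "true_class", list(cm.class_ids))
    df.to_csv(path, sep=_delimiter(path), index=False)


def write_ensemble_fixture(data, out_dir: str | Path) -> dict[str, dict[str, str]]:
    """Write one synthetic run as the standard file set, plus a manifest.

    Per model: ``<id>_features.csv`` (train split) and ``<id>_softmax.csv``
    (test split); shared: ``truth.csv``; ``manifest.json`` records the
    generating configuration and seed.  Returns the per-model file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}
    for model_id, fvs in data.train_features.items():
        fpath = out / f"{model_id}_features.csv"
        spath = out / f"{model_id}_softmax.csv"
        write_feature_table(fvs, fpath)
        write_softmax_table(data.softmax_tables[model_id], spath)
        files[model_id] = {"features": fpath.name, "softmax": spath.name}
    write_truth_table(data.truth_sample_ids, data.truth_labels, out / "truth.csv")
    cfg = data.config
    manifest = {
        "k": cfg.k,
        "per_class_train": cfg.per_class_train,
        "per_class_test": cfg.per_class_test,
        "d": cfg.d,
        "seed": cfg.seed,
        "models": [
            {
                "model_id": m.model_id,
                "separation": m.separation,
                "spread": m.spread,
                "temperature": m.temperature,
            }
            for m in cfg.model_specs
        ],
        "files": files,
        "truth": "truth.csv",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return files
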