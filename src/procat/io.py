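"""File formats: item-bank JSON, response CSV, results CSV, report JSON.

Bank JSON schema::

    {
      "metadata": {"instrument": ..., "version": ...,
                   "transform": {"slope": 12.5, "offset": 50.0}},
      "items": [{"id": "Q1", "label": "...", "n_categories": 7,
                 "discrimination": 2.1, "thresholds": [-1.2, ...]}]
    }

Two parameter dialects are supported on read: the native slope-threshold
form (``a``, ``b_k``) and a slope-intercept form (``a``, ``c_k`` with
``c_k = -a b_k``), converted on load via ``b_k = -c_k / a``.

Responses travel as wide CSV: a ``person_id`` column plus one column per
item; cells are 1-based categories, empty = missing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibrate import MISSING, ResponseMatrix
from .grm import ItemBank, ItemParameters
from .scale import ScaleTransform

PathLike = Union[str, Path]

DIALECT_SLOPE_THRESHOLD = "slope_threshold"
DIALECT_SLOPE_INTERCEPT = "slope_intercept"


class SchemaError(ValueError):
    """A file violated the bank or responses schema; the message addresses
    the offending item / row / column."""


def read_item_bank(path: PathLike, dialect: str = DIALECT_SLOPE_THRESHOLD) -> ItemBank:
    if dialect not in (DIALECT_SLOPE_THRESHOLD, DIALECT_SLOPE_INTERCEPT):
        raise ValueError(f"unknown parameter dialect {dialect!r}")
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(doc, dict) or "items" not in doc:
        raise SchemaError(f"{path}: bank document must be an object with an 'items' array")

    meta = dict(doc.get("metadata", {}))
    tr = meta.pop("transform", None)
    transform = (
        ScaleTransform(slope=float(tr["slope"]), offset=float(tr["offset"]))
        if tr
        else ScaleTransform()
    )

    items = []
    for entry in doc["items"]:
        item_id = entry.get("id", "<missing id>")
        try:
            a = float(entry["discrimination"])
            raw = [float(v) for v in entry["thresholds"]]
            if dialect == DIALECT_SLOPE_INTERCEPT:
                # c_k = -a b_k, intercepts arrive descending; convert and sort check
                raw = [-c / a for c in raw]
            item = ItemParameters(
                item_id=str(item_id),
                label=str(entry.get("label", "")),
                discrimination=a,
                thresholds=tuple(raw),
            )
            declared_k = entry.get("n_categories")
            if declared_k is not None and int(declared_k) != item.n_categories:
                raise ValueError(
                    f"declared n_categories {declared_k} but "
                    f"{len(raw)} thresholds imply {item.n_categories}"
                )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: item {item_id!r}: missing/invalid field ({exc})") from exc
        except ValueError as exc:
            raise SchemaError(f"{path}: item {item_id!r}: {exc}") from exc
        items.append(item)
    try:
        return ItemBank(items=tuple(items), scale_transform=transform, metadata=meta)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_item_bank(bank: ItemBank, path: PathLike) -> None:
    """Serialize losslessly (full float precision via repr round-trip)."""
    doc = {
        "metadata": {
            **dict(bank.metadata),
            "transform": {
                "slope": bank.scale_transform.slope,
                "offset": bank.scale_transform.offset,
            },
        },
        "items": [
            {
                "id": it.item_id,
                "label": it.label,
                "n_categories": it.n_categories,
                "discrimination": it.discrimination,
                "thresholds": list(it.thresholds),
            }
            for it in bank
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_responses(
    path: PathLike, bank: ItemBank, complete_case: bool = False
) -> ResponseMatrix:
    """Wide response CSV -> ResponseMatrix, validated against the bank.

    ``complete_case=True`` drops every person with any missing cell (the
    filter used when an analysis requires complete response sets).
    """
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise SchemaError(f"{path}: missing required 'person_id' column")
    item_cols = [c for c in df.columns if c != "person_id"]
    unknown = [c for c in item_cols if c not in bank.item_ids]
    if unknown:
        raise SchemaError(f"{path}: columns {unknown} not in bank {bank.item_ids}")
    missing_cols = [i for i in bank.item_ids if i not in item_cols]
    if missing_cols:
        raise SchemaError(f"{path}: bank items {missing_cols} absent from header")

    ordered = df[list(bank.item_ids)].to_numpy(dtype=float)
    values = np.where(np.isnan(ordered), MISSING, ordered)
    if np.any(values != np.round(values)):
        r, c = np.argwhere(values != np.round(values))[0]
        raise SchemaError(
            f"{path}: row {r + 2}, column {bank.item_ids[c]!r}: "
            f"non-integer category {ordered[r, c]}"
        )
    values = values.astype(int)
    for c, item in enumerate(bank):
        col = values[:, c]
        bad = np.nonzero((col != MISSING) & ((col < 1) | (col > item.n_categories)))[0]
        if len(bad):
            r = int(bad[0])
            raise SchemaError(
                f"{path}: row {r + 2}, column {item.item_id!r}: category "
                f"{col[r]} outside 1..{item.n_categories}"
            )
    matrix = ResponseMatrix(
        person_ids=tuple(str(p) for p in df["person_id"]),
        item_ids=tuple(bank.item_ids),
        values=values,
    )
    return matrix.complete_cases() if complete_case else matrix


def write_responses(matrix: ResponseMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        matrix.values.astype(float), columns=list(matrix.item_ids)
    ).replace(float(MISSING), np.nan)
    df.insert(0, "person_id", list(matrix.person_ids))
    df.to_csv(path, index=False)


def write_results(records_or_frame, path: PathLike) -> None:
    """Simulation records -> one-row-per-respondent CSV."""
    from .simulate import records_frame

    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
    else:
        df = records_frame(records_or_frame)
    df.to_csv(path, index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report_dict: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
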