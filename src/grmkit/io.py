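"""File formats: item-bank JSON, response-matrix CSV, scores CSV.

CSV dialect is comma-separated UTF-8 with a required header row; an empty
cell is a missing response.  JSON numbers round-trip at full double
precision (``repr`` of Python floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import MISSING, AbilityEstimate, ItemBank, ItemParameters, ResponseMatrix

__all__ = [
    "read_bank",
    "write_bank",
    "read_responses",
    "write_responses",
    "read_scores",
    "write_scores",
]

_BANK_KEYS = {"domain", "items"}
_ITEM_KEYS = {"id", "n_categories", "discrimination", "thresholds"}


def read_bank(path: str | Path) -> ItemBank:
    """Read an item bank from JSON with strict schema validation."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or not _BANK_KEYS.issubset(raw):
        raise ValueError(f"{path}: bank JSON must have keys {sorted(_BANK_KEYS)}")
    items = []
    for k, rec in enumerate(raw["items"]):
        if not isinstance(rec, dict) or not _ITEM_KEYS.issubset(rec):
            raise ValueError(
                f"{path}: item record {k} must have keys {sorted(_ITEM_KEYS)}"
            )
        items.append(
            ItemParameters(
                item_id=str(rec["id"]),
                n_categories=int(rec["n_categories"]),
                discrimination=float(rec["discrimination"]),
                thresholds=tuple(float(t) for t in rec["thresholds"]),
            )
        )
    return ItemBank(domain=str(raw["domain"]), items=tuple(items))


def write_bank(bank: ItemBank, path: str | Path, *, meta: dict | None = None) -> None:
    """Write an item bank to JSON at full double precision."""
    payload: dict = {
        "domain": bank.domain,
        "items": [
            {
                "id": it.item_id,
                "n_categories": it.n_categories,
                "discrimination": it.discrimination,
                "thresholds": list(it.thresholds),
            }
            for it in bank.items
        ],
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a response matrix CSV: ``person_id`` column then item columns.

    Empty cells are missing; everything else must be a non-negative integer
    code.  Errors name the offending cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "person_id":
        raise ValueError(f"{path}: first column must be 'person_id'")
    person_ids = df["person_id"].tolist()
    dupes = df["person_id"][df["person_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate person_id {dupes[0]!r}")
    item_ids = list(df.columns[1:])
    resp = np.full((len(person_ids), len(item_ids)), MISSING, dtype=np.int64)
    for i, col in enumerate(item_ids):
        for p, cell in enumerate(df[col].tolist()):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                code = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer cell {cell!r} at person "
                    f"{person_ids[p]!r}, item {col!r}"
                ) from None
            if code < 1:
                raise ValueError(
                    f"{path}: invalid code {code} at person {person_ids[p]!r}, "
                    f"item {col!r} (codes are 1-based; blank = missing)"
                )
            resp[p, i] = code
    return ResponseMatrix(
        person_ids=tuple(person_ids), item_ids=tuple(item_ids), responses=resp
    )


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix CSV (inverse of :func:`read_responses`)."""
    cells = matrix.responses.astype(object)
    cells[matrix.responses == MISSING] = ""
    df = pd.DataFrame(cells, columns=list(matrix.item_ids))
    df.insert(0, "person_id", list(matrix.person_ids))
    df.to_csv(path, index=False)


def write_scores(
    person_ids,
    estimates: list[AbilityEstimate],
    path: str | Path,
) -> None:
    """Write a scores CSV: ``person_id, theta, se, method, flagged``."""
    df = pd.DataFrame(
        {
            "person_id": list(person_ids),
            "theta": [e.theta for e in estimates],
            "se": [e.se for e in estimates],
            "method": [e.method for e in estimates],
            "flagged": [e.flagged for e in estimates],
        }
    )
    df.to_csv(path, index=False)


def read_scores(path: str | Path) -> tuple[list[str], list[AbilityEstimate]]:
    df = pd.read_csv(path, dtype={"person_id": str})
    estimates = [
        AbilityEstimate(
            theta=float(r.theta),
            se=float(r.se),
            method=str(r.method),
            flagged=bool(r.flagged),
        )
        for r in df.itertuples()
    ]
    return df["person_id"].tolist(), estimates
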