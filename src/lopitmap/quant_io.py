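"""Readers for protein quantitation tables and categorized marker lists.

Quantitation tables are label-free MS exports: one row per protein, one
abundance column per fraction (precursor-intensity scale, arbitrary
units).  Blank, NA and zero cells are all treated as "not quantified in
this fraction": a label-free zero almost always means not detected, and
the downstream ratio logic presumes detection.

Marker lists mirror the MISEV2018 recommendation: five disjoint
categories of proteins for evaluating extracellular-vesicle sample
preparations, with a role derived from the category (1, 2, 5 are EV
markers, 3 contaminant markers, 4 EV-subtype markers).

All tables are keyed by UniProt accession.  Accessions are uppercased,
stripped and isoform-collapsed (``Q96NT5-2`` -> ``Q96NT5``) before any
join; gene-symbol fallback matching is deliberately not offered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ISOFORM_SUFFIX = re.compile(r"-\d+$")

#: role implied by each marker category
CATEGORY_ROLES: dict[int, str] = {
    1: "ev-marker",
    2: "ev-marker",
    3: "contaminant",
    4: "subtype",
    5: "ev-marker",
}

VALID_ROLES = frozenset(CATEGORY_ROLES.values())


def normalize_accession(raw: str, collapse_isoform: bool = True) -> str:
    """Canonicalize a UniProt-style accession.

    Uppercases, strips surrounding whitespace and (by default) removes a
    trailing ``-N`` isoform suffix.  Idempotent.

    >>> normalize_accession(" q96nt5-2 ")
    'Q96NT5'
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty accession")
    acc = str(raw).strip().upper()
    if collapse_isoform:
        acc = _ISOFORM_SUFFIX.sub("", acc)
    return acc


class QuantTable:
    """Accession x fraction abundance matrix with missing values.

    The underlying frame is indexed by normalized accession; columns are
    fraction identifiers in their original order; cells are positive
    floats or NaN (missing = not quantified in that fraction).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 1:
            raise ValueError("quant table needs at least one fraction column")
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate accession {dup!r} in quant table")
        values = frame.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative abundance {values[r, c]} for accession "
                    f"{frame.index[r]!r} fraction {frame.columns[c]!r}"
                )
        frame = frame.astype(float).copy()
        frame[frame == 0] = np.nan  # zero intensity == not detected
        self._frame = frame
        self._frame.index.name = "accession"

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def fraction_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def accessions(self) -> pd.Index:
        return self._frame.index

    def abundances(self, fraction_id: str) -> pd.Series:
        if fraction_id not in self._frame.columns:
            raise KeyError(
                f"unknown fraction {fraction_id!r}; available: {self.fraction_ids}"
            )
        return self._frame[fraction_id].copy()

    def detected(self, fraction_id: str) -> pd.Index:
        """Accessions with a quantified (non-missing) abundance in a fraction."""
        col = self.abundances(fraction_id)
        return col.index[col.notna()]

    def detected_any(self) -> pd.Index:
        """Accessions quantified in at least one fraction."""
        return self._frame.index[self._frame.notna().any(axis=1)]


def load_quant_table(
    path: str | Path,
    column_spec: Mapping[str, object] | None = None,
    duplicate_policy: str = "error",
    collapse_isoforms: bool = True,
) -> QuantTable:
    """Load a quantitation table from CSV or TSV (sniffed by extension).

    Parameters
    ----------
    column_spec
        ``{"accession": <column name>, "fractions": [<columns>...]}``.
        Defaults: accession column named ``accession``; every other
        column is a fraction.
    duplicate_policy
        ``"error"`` (default), ``"max"`` or ``"sum"`` — how rows that
        collapse to the same normalized accession are combined.
    """
    path = Path(path)
    if duplicate_policy not in ("error", "max", "sum"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)

    acc_col = "accession"
    fraction_cols: Sequence[str] | None = None
    if column_spec:
        acc_col = str(column_spec.get("accession", acc_col))
        if "fractions" in column_spec:
            fraction_cols = list(column_spec["fractions"])  # type: ignore[arg-type]
    if acc_col not in raw.columns:
        raise ValueError(f"{path.name}: accession column {acc_col!r} not found")
    if fraction_cols is None:
        fraction_cols = [c for c in raw.columns if c != acc_col]
    missing = [c for c in fraction_cols if c not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: fraction columns {missing} not found")

    accs = [
        normalize_accession(a, collapse_isoform=collapse_isoforms)
        for a in raw[acc_col]
    ]
    data = raw[list(fraction_cols)].apply(pd.to_numeric, errors="coerce")
    data.index = pd.Index(accs, name="accession")

    with np.errstate(invalid="ignore"):
        neg = data.lt(0)
    if neg.any().any():
        acc = data.index[neg.any(axis=1)][0]
        raise ValueError(f"{path.name}: negative abundance for accession {acc!r}")

    if data.index.has_duplicates:
        if duplicate_policy == "error":
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(
                f"{path.name}: duplicate accession {dup!r} "
                "(use duplicate_policy='max' or 'sum' to aggregate)"
            )
        agg = data.groupby(level=0, sort=False)
        data = agg.max() if duplicate_policy == "max" else agg.sum(min_count=1)
        logger.info(
            "%s: aggregated duplicate accessions with policy %s",
            path.name,
            duplicate_policy,
        )

    table = QuantTable(data)
    logger.info(
        "loaded quant table %s: %d proteins x %d fractions",
        path.name,
        len(table),
        len(table.fraction_ids),
    )
    return table


@dataclass(frozen=True)
class MarkerSet:
    """Categorized marker list: accession -> (category 1-5, role).

    Categories are disjoint by construction (loading a list that assigns
    one accession to two categories is an error), so the five category
    totals sum to the number of entries.
    """

    entries: pd.DataFrame  # index accession; columns category (int), role (str)

    def __post_init__(self):
        if len(self.entries) and self.entries.index.has_duplicates:
            dup = self.entries.index[self.entries.index.duplicated()][0]
            raise ValueError(f"accession {dup!r} appears in more than one category")
        for acc, row in self.entries.iterrows():
            cat = int(row["category"])
            if cat not in CATEGORY_ROLES:
                raise ValueError(f"accession {acc!r}: category {cat} outside 1-5")
            if row["role"] != CATEGORY_ROLES[cat]:
                raise ValueError(
                    f"accession {acc!r}: role {row['role']!r} inconsistent with "
                    f"category {cat} (expected {CATEGORY_ROLES[cat]!r})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def category_totals(self) -> dict[int, int]:
        counts = self.entries.groupby("category").size() if len(self.entries) else {}
        return {cat: int(counts.get(cat, 0)) for cat in sorted(CATEGORY_ROLES)}

    @property
    def accessions(self) -> pd.Index:
        return self.entries.index

    def of_category(self, category: int) -> pd.Index:
        return self.entries.index[self.entries["category"] == category]

    def of_role(self, role: str) -> pd.Index:
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}; valid: {sorted(VALID_ROLES)}")
        return self.entries.index[self.entries["role"] == role]


def load_marker_set(path: str | Path, collapse_isoforms: bool = True) -> MarkerSet:
    """Load a marker list (TSV: accession, category, optional role).

    If the role column is absent it is derived from the category.  A
    role that contradicts its category, or an accession assigned to two
    categories, is an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        empty = pd.DataFrame(columns=["category", "role"])
        empty.index.name = "accession"
        return MarkerSet(empty)
    for col in ("accession", "category"):
        if col not in raw.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    accs = [
        normalize_accession(a, collapse_isoform=collapse_isoforms)
        for a in raw["accession"]
    ]
    cats = pd.to_numeric(raw["category"], errors="raise").astype(int)
    roles = (
        raw["role"].astype(str).str.strip().str.lower()
        if "role" in raw.columns
        else pd.Series([CATEGORY_ROLES.get(int(c), "?") for c in cats])
    )
    entries = pd.DataFrame(
        {"category": cats.to_numpy(), "role": roles.to_numpy()},
        index=pd.Index(accs, name="accession"),
    )
    marker_set = MarkerSet(entries)
    logger.info(
        "loaded marker set %s: %d entries, totals %s",
        path.name,
        len(marker_set),
        marker_set.category_totals,
    )
    return marker_set


def normalize_accessions(raw: Iterable[str], collapse_isoform: bool = True) -> set[str]:
    """Normalize an iterable of accessions to a set."""
    return {normalize_accession(a, collapse_isoform=collapse_isoform) for a in raw}
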