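"""The fixed organellar reference map.

A reference map assigns each protein (keyed by UniProt accession) a pair
of 2-D coordinates from a t-SNE embedding of LOPIT density-gradient
profiles, plus one of 13 compartment labels.  The map is consumed as
published — coordinates are never recomputed or refined here — so every
downstream statistic is reproducible from the same frozen space.

The compartment vocabulary is closed.  "unknown" is a real assignment
(proteins whose gradient profile matches no organelle marker set) and is
distinct from a protein being absent from the map altogether.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from lopitmap.quant_io import normalize_accession

logger = logging.getLogger(__name__)

#: The 13 compartment labels of the organellar map, in canonical
#: (tally/report) order.
COMPARTMENTS: tuple[str, ...] = (
    "cytosol",
    "endoplasmic reticulum",
    "golgi",
    "lysosome",
    "mitochondria",
    "nucleus",
    "nucleus-chromatin",
    "peroxisome",
    "plasma membrane",
    "proteasome",
    "ribosome 40S",
    "ribosome 60S",
    "unknown",
)

_COMPARTMENT_SET = frozenset(COMPARTMENTS)

#: Default alias table for compartment spellings seen in exported tables.
#: Aliasing is explicit — unknown spellings are errors, never fuzzy-matched.
DEFAULT_COMPARTMENT_ALIASES: dict[str, str] = {
    "er": "endoplasmic reticulum",
    "pm": "plasma membrane",
    "mitochondrion": "mitochondria",
    "40s ribosome": "ribosome 40S",
    "60s ribosome": "ribosome 60S",
}


class _NotInMap:
    """Sentinel for accessions absent from the reference map."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return "NOT_IN_MAP"

    def __bool__(self) -> bool:
        return False


#: Returned by :meth:`ReferenceMap.compartment_of` for proteins with no
#: map entry.  Falsy, and never equal to any compartment label.
NOT_IN_MAP = _NotInMap()


def _canonical_compartment(raw: str, aliases: Mapping[str, str]) -> str:
    label = raw.strip()
    if label in _COMPARTMENT_SET:
        return label
    aliased = aliases.get(label.lower())
    if aliased is not None:
        return aliased
    raise ValueError(
        f"unknown compartment label {label!r}; allowed labels are "
        f"{sorted(_COMPARTMENT_SET)} (aliases: {sorted(aliases)})"
    )


@dataclass(frozen=True)
class RegionAnnotation:
    """An annotated map region (e.g. P, U, N, R, M) drawn as an ellipse.

    The ellipse is derived deterministically from the coordinates of the
    proteins assigned to the member compartments: centred on their mean,
    with the sample covariance scaled to ``k_sigma`` standard deviations.
    The role (enriched-marker / background-contaminant / neutral) is
    configuration, not computed.
    """

    region_id: str
    compartments: tuple[str, ...]
    center: tuple[float, float]
    covariance: np.ndarray  # 2x2, already scaled by k_sigma**2
    k_sigma: float
    role: str = "neutral"


class ReferenceMap:
    """Immutable accession -> (x, y, compartment) lookup.

    Parameters
    ----------
    table
        DataFrame indexed by normalized accession with columns
        ``x``, ``y`` (finite floats) and ``compartment`` (one of the 13
        canonical labels).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"x", "y", "compartment"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference map table missing columns {sorted(missing)}")
        if table.index.has_duplicates:
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate accession in reference map: {dup!r}")
        coords = table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            bad = table.index[~np.isfinite(coords).all(axis=1)][0]
            raise ValueError(f"non-finite coordinate for accession {bad!r}")
        bad_labels = set(table["compartment"]) - _COMPARTMENT_SET
        if bad_labels:
            raise ValueError(
                f"unknown compartment labels {sorted(bad_labels)}; "
                f"allowed: {sorted(_COMPARTMENT_SET)}"
            )
        self._table = table.copy()
        self._table.index.name = "accession"

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, accession: str) -> bool:
        return normalize_accession(accession) in self._table.index

    @property
    def table(self) -> pd.DataFrame:
        """Copy of the underlying (accession, x, y, compartment) table."""
        return self._table.copy()

    @property
    def accessions(self) -> pd.Index:
        return self._table.index

    def compartment_of(self, accession: str):
        """Compartment label for ``accession``, or :data:`NOT_IN_MAP`.

        The accession is normalized (case, whitespace, isoform suffix)
        before lookup.  Absence from the map is reported distinctly and
        never conflated with the "unknown" compartment assignment.
        """
        acc = normalize_accession(accession)
        try:
            return self._table.at[acc, "compartment"]
        except KeyError:
            return NOT_IN_MAP

    def coordinates_of(self, accessions: Iterable[str]) -> pd.DataFrame:
        """Subset of the map table for the given (normalized) accessions."""
        accs = [normalize_accession(a) for a in accessions]
        present = [a for a in accs if a in self._table.index]
        return self._table.loc[present]

    def members_of(self, compartments: Sequence[str]) -> pd.DataFrame:
        """Map rows whose compartment is in ``compartments``."""
        unknown = set(compartments) - _COMPARTMENT_SET
        if unknown:
            raise ValueError(f"unknown compartment labels {sorted(unknown)}")
        return self._table[self._table["compartment"].isin(compartments)]

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of all map coordinates."""
        x = self._table["x"]
        y = self._table["y"]
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())


def load_reference_map(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
    collapse_isoforms: bool = True,
) -> ReferenceMap:
    """Load a reference map from a tab- or comma-separated text file.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row.
    column_spec
        Mapping with keys ``accession``, ``x``, ``y``, ``compartment``
        giving the column names in the file.  Defaults to those names.
    aliases
        Compartment spelling aliases (lower-cased input -> canonical
        label), merged over :data:`DEFAULT_COMPARTMENT_ALIASES`.
    collapse_isoforms
        Strip ``-N`` isoform suffixes during accession normalization.

    Raises
    ------
    ValueError
        On duplicate accessions (named), non-numeric coordinates (with
        row number) or compartment labels outside the closed vocabulary.
    """
    path = Path(path)
    spec = {"accession": "accession", "x": "x", "y": "y", "compartment": "compartment"}
    if column_spec:
        spec.update(column_spec)
    alias_table = dict(DEFAULT_COMPARTMENT_ALIASES)
    if aliases:
        alias_table.update({k.lower(): v for k, v in aliases.items()})

    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in spec.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}; found {list(raw.columns)}")

    accs = [
        normalize_accession(a, collapse_isoform=collapse_isoforms)
        for a in raw[spec["accession"]]
    ]
    coords = {}
    for axis in ("x", "y"):
        col = raw[spec[axis]]
        parsed = pd.to_numeric(col, errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            # header is line 1, data starts at line 2
            raise ValueError(
                f"{path.name}: non-numeric {axis} coordinate "
                f"{col.iloc[bad[0]]!r} at line {bad[0] + 2}"
            )
        coords[axis] = parsed.to_numpy(dtype=float)

    compartments = [_canonical_compartment(c, alias_table) for c in raw[spec["compartment"]]]

    seen: set[str] = set()
    for acc in accs:
        if acc in seen:
            raise ValueError(f"{path.name}: duplicate accession {acc!r}")
        seen.add(acc)

    table = pd.DataFrame(
        {"x": coords["x"], "y": coords["y"], "compartment": compartments},
        index=pd.Index(accs, name="accession"),
    )
    refmap = ReferenceMap(table)
    logger.info("loaded reference map %s: %d entries", path.name, len(refmap))
    return refmap


def write_reference_map(refmap: ReferenceMap, path: str | Path) -> None:
    """Write a reference map back to TSV (round-trips with the loader)."""
    refmap.table.to_csv(path, sep="\t", index=True)


def region_ellipse(
    refmap: ReferenceMap,
    compartments: Sequence[str],
    k_sigma: float = 2.0,
    region_id: str | None = None,
    role: str = "neutral",
) -> RegionAnnotation:
    """Fit a k-sigma ellipse to the proteins of one or more compartments.

    The centre is the arithmetic mean of the member coordinates and the
    covariance is the sample covariance scaled by ``k_sigma**2``, so the
    ellipse axes scale linearly with ``k_sigma``.  With the default
    ``k_sigma=2`` the ellipse covers the bulk of a Gaussian cluster.

    Identical member points yield a zero-covariance ellipse with a
    warning rather than an error, so that collapsed synthetic clusters
    remain drawable.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    members = refmap.members_of(compartments)
    if len(members) < 3:
        raise ValueError(
            f"region over {list(compartments)} has only {len(members)} member "
            "proteins; need at least 3 for an ellipse"
        )
    pts = members[["x", "y"]].to_numpy(dtype=float)
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.any(cov):
        warnings.warn(
            f"region {region_id or compartments}: member coordinates are "
            "identical; returning a zero-covariance (degenerate) ellipse",
            stacklevel=2,
        )
    return RegionAnnotation(
        region_id=region_id or "+".join(compartments),
        compartments=tuple(compartments),
        center=(float(center[0]), float(center[1])),
        covariance=cov * k_sigma**2,
        k_sigma=float(k_sigma),
        role=role,
    )
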