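"""Overlay detected proteomes on the reference map.

Joins a quantitation table (or a plain accession set) onto the fixed
organellar map, bins abundances or fold changes for size-coded display,
and produces the two summary statistics used throughout: per-fraction
mapping statistics (how much of the detected proteome has map
coordinates) and per-compartment tallies of the mapped proteins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lopitmap.quant_io import QuantTable, normalize_accession
from lopitmap.reference_map import COMPARTMENTS, ReferenceMap

logger = logging.getLogger(__name__)

BINNING_SCHEMES = ("quantile-log10", "equal-width-log10")

#: bin value used for points whose value is missing (presence-only overlays)
UNBINNED = 0


def bin_values(
    values: Sequence[float] | np.ndarray,
    n_bins: int = 5,
    scheme: str = "quantile-log10",
) -> np.ndarray:
    """Assign positive values to ordered bins 1..n_bins on a log10 scale.

    MS intensities are approximately log-distributed, so binning happens
    after a log10 transform.  ``quantile-log10`` (default) gives
    equal-frequency bins; ``equal-width-log10`` splits the log-range into
    equal intervals.  Ties at a bin edge fall to the lower bin; an
    all-equal input collapses to bin 1.  Binning is monotone: a larger
    value never lands in a smaller bin.

    Parameters
    ----------
    values
        Positive numbers (missing/zero values must be excluded upstream).
    n_bins
        Number of bins (>= 1).

    Returns
    -------
    numpy.ndarray of int, same length as ``values``, entries in 1..n_bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scheme not in BINNING_SCHEMES:
        raise ValueError(f"unknown binning scheme {scheme!r}; use one of {BINNING_SCHEMES}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.zeros(0, dtype=int)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("bin_values requires finite positive values")
    logv = np.log10(arr)
    if scheme == "quantile-log10":
        # edges are order statistics (method "lower"), not interpolated:
        # exact data values, so edge ties are well defined bit-for-bit
        qs = np.arange(1, n_bins) / n_bins
        edges = np.quantile(logv, qs, method="lower")
    else:
        edges = np.linspace(logv.min(), logv.max(), n_bins + 1)[1:-1]
    # count of interior edges strictly below each value -> edge ties go low
    bins = np.searchsorted(edges, logv, side="left") + 1
    return bins.astype(int)


@dataclass
class OverlayResult:
    """Join of a detected proteome onto the reference map.

    ``points`` holds the mapped proteins (accession index; x, y,
    compartment, value, bin columns); ``unmapped`` lists detected
    accessions absent from the map.  Together they partition the
    detected input set.
    """

    points: pd.DataFrame
    unmapped: list[str]

    @property
    def n_mapped(self) -> int:
        return len(self.points)

    @property
    def n_input(self) -> int:
        return len(self.points) + len(self.unmapped)


@dataclass
class MappingStats:
    """Per-fraction identified/mapped counts and percentages.

    ``table`` has one row per fraction (or one row named ``set`` for a
    plain accession-set overlay): total_ids, mapped, percent_mapped.
    """

    table: pd.DataFrame


def _detected_accessions(source, fraction: str | None) -> list[str]:
    if isinstance(source, QuantTable):
        if fraction is None:
            idx = source.detected_any()
        else:
            idx = source.detected(fraction)
        return list(idx)
    return [normalize_accession(a) for a in source]


def map_to_reference(
    quant_or_set,
    refmap: ReferenceMap,
    value_fraction: str | None = None,
    n_bins: int = 5,
    scheme: str = "quantile-log10",
) -> tuple[OverlayResult, MappingStats]:
    """Map a detected proteome onto the reference map.

    A protein counts as detected in a fraction iff its abundance is
    quantified (non-missing) there.  Proteins absent from the map are
    data, not errors: they are returned in ``unmapped`` and excluded
    from all compartment tallies.

    Parameters
    ----------
    quant_or_set
        A :class:`~lopitmap.quant_io.QuantTable`, or any iterable of
        accessions (presence-only overlay, no values or bins).
    value_fraction
        For a QuantTable: the fraction whose abundances become point
        values (binned for size-coded display).  If None the overlay is
        presence-based over proteins detected in any fraction.

    Returns
    -------
    (OverlayResult, MappingStats)
        MappingStats covers every fraction of a QuantTable regardless of
        ``value_fraction``; for a plain set it has a single ``set`` row.
    """
    is_quant = isinstance(quant_or_set, QuantTable)
    detected = _detected_accessions(quant_or_set, value_fraction)

    values: pd.Series | None = None
    if is_quant and value_fraction is not None:
        values = quant_or_set.abundances(value_fraction).dropna()

    in_map = [a for a in detected if a in refmap.accessions]
    unmapped = [a for a in detected if a not in refmap.accessions]
    points = refmap.coordinates_of(in_map)

    if values is not None and len(points):
        vals = values.reindex(points.index)
        bins = np.full(len(points), UNBINNED, dtype=int)
        ok = vals.notna().to_numpy()
        if ok.any():
            bins[ok] = bin_values(vals[ok].to_numpy(), n_bins=n_bins, scheme=scheme)
        points = points.assign(value=vals.to_numpy(), bin=bins)
    else:
        points = points.assign(value=np.nan, bin=UNBINNED)

    # mapping statistics per fraction
    rows = {}
    if is_quant:
        for frac in quant_or_set.fraction_ids:
            det = quant_or_set.detected(frac)
            mapped = sum(1 for a in det if a in refmap.accessions)
            rows[frac] = (len(det), mapped)
    else:
        rows["set"] = (len(detected), len(in_map))

    stats = []
    for name, (total, mapped) in rows.items():
        if total == 0:
            warnings.warn(
                f"fraction {name!r}: no detected proteins; percent_mapped reported as 0",
                stacklevel=2,
            )
            pct = 0.0
        else:
            pct = 100.0 * mapped / total
        stats.append({"fraction": name, "total_ids": total, "mapped": mapped,
                      "percent_mapped": pct})
    stats_table = pd.DataFrame(stats).set_index("fraction")

    logger.info(
        "overlay: %d detected, %d mapped, %d not in map",
        len(detected), len(in_map), len(unmapped),
    )
    return OverlayResult(points=points, unmapped=unmapped), MappingStats(stats_table)


def tally_compartments(overlay: OverlayResult) -> pd.Series:
    """Count mapped proteins per compartment (all 13 labels, zeros kept).

    "unknown" is a genuine map assignment and gets its own row; proteins
    absent from the map never enter the tally (they live in
    ``overlay.unmapped``).  The counts always sum to the number of
    mapped points.
    """
    counts = overlay.points["compartment"].value_counts() if len(overlay.points) else {}
    tally = pd.Series(
        [int(counts.get(c, 0)) for c in COMPARTMENTS],
        index=pd.Index(COMPARTMENTS, name="compartment"),
        name="count",
        dtype=int,
    )
    return tally


def mapped_fraction(detected_total: int, mapped_count: int) -> float:
    """Share (%) of a detected proteome that has reference-map coordinates.

    Returns the exact percentage; use ``round(x)`` for the integer
    display convention and ``round(x, 1)`` for the 1-decimal one.
    """
    if detected_total == 0:
        raise ValueError("detected_total must be positive")
    if not (0 <= mapped_count <= detected_total):
        raise ValueError(
            f"mapped_count {mapped_count} outside [0, detected_total={detected_total}]"
        )
    return 100.0 * mapped_count / detected_total


def compare_tallies(a: pd.Series, b: pd.Series) -> tuple[pd.Series, str]:
    """Signed per-compartment difference (a - b) between two tallies.

    Returns the difference series plus a one-line-per-compartment text
    summary of the non-zero differences ("N fewer/more proteins in
    <compartment>"), the phrasing used when comparing preparations.
    """
    if list(a.index) != list(b.index):
        raise ValueError("tallies use different compartment vocabularies")
    diff = (a - b).astype(int)
    lines = []
    for comp, d in diff.items():
        if d == 0:
            continue
        word = "more" if d > 0 else "fewer"
        lines.append(f"{abs(int(d))} {word} proteins in {comp}")
    return diff, "; ".join(lines) if lines else "no per-compartment differences"


# -- writers -------------------------------------------------------------

def write_tally(tally: pd.Series, path: str | Path) -> None:
    """Write a compartment tally as TSV in canonical compartment order."""
    tally.rename("mapped_proteins").to_csv(path, sep="\t")


def write_mapping_stats(stats: MappingStats, path: str | Path) -> None:
    out = stats.table.copy()
    out["percent_mapped"] = out["percent_mapped"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t")


def write_overlay(overlay: OverlayResult, path: str | Path) -> None:
    """Write overlay points as TSV; not-in-map accessions go to a
    sibling ``<name>.unmapped.txt`` ledger so the points table stays
    rectangular."""
    path = Path(path)
    overlay.points.to_csv(path, sep="\t")
    if overlay.unmapped:
        side = path.with_suffix(path.suffix + ".unmapped.txt")
        side.write_text("\n".join(overlay.unmapped) + "\n", encoding="utf-8")
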