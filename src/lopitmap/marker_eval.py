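"""Score a detected proteome against a categorized marker list.

The MISEV2018 recommendation defines five categories of proteins for
evaluating extracellular-vesicle preparations: transmembrane/GPI
proteins of the plasma membrane or endosomes (1), cytosolic proteins
recovered inside EVs (2), co-isolated non-EV structures i.e.
contaminants (3), EV-subtype markers (4) and functional EV components
(5).  Per-category recovery — the share of each category's accessions
present in a detected proteome — together with where the recovered
markers fall on the organellar map summarizes how vesicle-enriched a
preparation is: EV markers concentrate in the plasma-membrane /
lysosome / ER / cytosol regions, contaminants in the mitochondrial,
ribosomal and nuclear regions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from lopitmap.overlay import OverlayResult, map_to_reference, tally_compartments, mapped_fraction
from lopitmap.quant_io import MarkerSet, VALID_ROLES, normalize_accessions
from lopitmap.reference_map import COMPARTMENTS, ReferenceMap

logger = logging.getLogger(__name__)

#: Compartments where EV-marker proteins concentrate on the map.
MARKER_REGION: tuple[str, ...] = (
    "plasma membrane",
    "lysosome",
    "endoplasmic reticulum",
    "cytosol",
)

#: Compartments whose proteins indicate carry-over of non-vesicular
#: material into an EV preparation.
CONTAMINANT_REGION: tuple[str, ...] = (
    "mitochondria",
    "nucleus",
    "nucleus-chromatin",
    "ribosome 40S",
    "ribosome 60S",
)


def category_recovery(detected: Iterable[str], markers: MarkerSet) -> pd.DataFrame:
    """Per-category detection counts and percentages.

    Returns a frame indexed by category (1..5) with columns ``total``,
    ``detected`` and ``percent`` (1-decimal convention applies at
    display; the stored percent is exact).  A category with no members
    gets percent NaN (not applicable), never a division by zero.
    """
    det = normalize_accessions(detected)
    rows = []
    for cat, total in markers.category_totals.items():
        members = set(markers.of_category(cat))
        n_det = len(det & members)
        pct = 100.0 * n_det / total if total else np.nan
        rows.append({"category": cat, "total": total, "detected": n_det, "percent": pct})
    table = pd.DataFrame(rows).set_index("category")
    return table


def role_summary(
    detected: Iterable[str],
    markers: MarkerSet,
    refmap: ReferenceMap,
) -> dict[str, pd.Series]:
    """Compartment tallies of detected markers, split by role.

    Each detected marker is counted once, under the role its category
    implies (ev-marker / contaminant / subtype).  Markers without map
    coordinates are excluded, exactly as in the overlay tallies.
    """
    det = normalize_accessions(detected)
    summary: dict[str, pd.Series] = {}
    for role in sorted(VALID_ROLES):
        role_detected = det & set(markers.of_role(role))
        if role_detected:
            overlay, _ = map_to_reference(role_detected, refmap)
            summary[role] = tally_compartments(overlay)
        else:  # an empty role subset is normal, not a degenerate overlay
            summary[role] = pd.Series(
                0, index=pd.Index(COMPARTMENTS, name="compartment"),
                name="count", dtype=int,
            )
    return summary


def preparation_report(
    detected: Iterable[str],
    markers: MarkerSet,
    refmap: ReferenceMap,
    marker_region: tuple[str, ...] = MARKER_REGION,
    contaminant_region: tuple[str, ...] = CONTAMINANT_REGION,
) -> dict:
    """Descriptive evaluation of one preparation's detected proteome.

    Bundles category recovery, role-split tallies, the mapped fraction
    of the detected set, the overall compartment tally, and the shares
    of mapped proteins falling in the marker vs contaminant regions.
    Purely descriptive — no good/poor verdict is issued; interpreting
    the region shares is left to the analyst (or a configured threshold
    downstream).
    """
    det = normalize_accessions(detected)
    overlay, stats = map_to_reference(det, refmap)
    tally = tally_compartments(overlay)
    n_mapped = overlay.n_mapped

    def region_share(region: tuple[str, ...]) -> float:
        if n_mapped == 0:
            return float("nan")
        return float(tally.loc[list(region)].sum()) / n_mapped

    report = {
        "n_detected": len(det),
        "n_mapped": n_mapped,
        "mapped_percent": mapped_fraction(len(det), n_mapped) if det else float("nan"),
        "category_recovery": category_recovery(det, markers),
        "role_summary": role_summary(det, markers, refmap),
        "compartment_tally": tally,
        "marker_region_share": region_share(marker_region),
        "contaminant_region_share": region_share(contaminant_region),
    }
    return report


def write_report(report: Mapping, path) -> None:
    """Write a preparation report as sectioned TSV-ish text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# preparation report\n")
        fh.write(f"n_detected\t{report['n_detected']}\n")
        fh.write(f"n_mapped\t{report['n_mapped']}\n")
        fh.write(f"mapped_percent\t{report['mapped_percent']:.1f}\n")
        fh.write(f"marker_region_share\t{report['marker_region_share']:.4f}\n")
        fh.write(f"contaminant_region_share\t{report['contaminant_region_share']:.4f}\n")
        fh.write("\n# category recovery\ncategory\ttotal\tdetected\tpercent\n")
        for cat, row in report["category_recovery"].iterrows():
            pct = "NA" if np.isnan(row["percent"]) else f"{row['percent']:.1f}"
            fh.write(f"{cat}\t{int(row['total'])}\t{int(row['detected'])}\t{pct}\n")
        for role, tally in report["role_summary"].items():
            fh.write(f"\n# role tally: {role}\ncompartment\tcount\n")
            for comp, n in tally.items():
                fh.write(f"{comp}\t{int(n)}\n")
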