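"""Fold-change enrichment filtering for proximity-labeling data.

In a BioID/streptavidin experiment the elution fraction contains the
biotinylated (bait-proximal) proteins plus carry-over background, while
the final wash contains mostly background.  The per-protein ratio of
Elute over final-wash abundance is therefore the enrichment statistic,
and the four endogenously biotinylated carboxylases — the natural
substrates of mammalian biotin ligases, hence guaranteed true positives
of the streptavidin selection — calibrate what ratio a genuinely
biotinylated protein achieves.

A protein detected in the elution but absent from the wash cannot be
ratioed.  Absence from the wash is the strongest possible enrichment
signal, so such "elute-only" proteins pass the cutoff by default,
flagged distinctly; no pseudo-count is imputed unless an abundance
floor is configured explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lopitmap.quant_io import QuantTable, normalize_accession
from lopitmap.reference_map import ReferenceMap

logger = logging.getLogger(__name__)

#: Endogenously biotinylated carboxylases used as positive controls for
#: streptavidin selection: pyruvate carboxylase (P11498), propionyl-CoA
#: carboxylase alpha (P05165), methylcrotonoyl-CoA carboxylase alpha
#: (Q96RQ3), acetyl-CoA carboxylase 1 (Q13085).  All mitochondrial
#: except ACC1; overridable for other organisms.
CARBOXYLASE_CONTROLS: tuple[str, ...] = ("P11498", "P05165", "Q96RQ3", "Q13085")

STATUS_BOTH = "both"
STATUS_NUMERATOR_ONLY = "numerator_only"
STATUS_DENOMINATOR_ONLY = "denominator_only"
STATUS_NEITHER = "neither"


@dataclass
class FoldChangeTable:
    """Per-protein fold change between two fractions.

    ``table`` is indexed by accession with columns:

    ratio
        numerator/denominator abundance; finite only for status "both".
    status
        both / numerator_only / denominator_only / neither, partitioning
        the proteins by where they were quantified.
    passes_cutoff
        Set by :func:`apply_cutoff`; False until then.
    """

    table: pd.DataFrame
    numerator_fraction: str
    denominator_fraction: str

    def of_status(self, status: str) -> pd.DataFrame:
        return self.table[self.table["status"] == status]


def compute_fold_change(
    quant: QuantTable,
    numerator_fraction: str,
    denominator_fraction: str,
    abundance_floor: float | None = None,
) -> FoldChangeTable:
    """Ratio of abundances between two fractions for every protein.

    Parameters
    ----------
    abundance_floor
        Optional positive value substituted for *missing* abundances
        before ratioing, turning single-fraction proteins into finite
        ratios.  Off by default: presence status is the primary signal.
    """
    num = quant.abundances(numerator_fraction)
    den = quant.abundances(denominator_fraction)
    if abundance_floor is not None:
        if abundance_floor <= 0:
            raise ValueError("abundance_floor must be positive")
        num = num.fillna(abundance_floor)
        den = den.fillna(abundance_floor)

    has_num = num.notna()
    has_den = den.notna()
    status = np.select(
        [has_num & has_den, has_num & ~has_den, ~has_num & has_den],
        [STATUS_BOTH, STATUS_NUMERATOR_ONLY, STATUS_DENOMINATOR_ONLY],
        default=STATUS_NEITHER,
    )
    ratio = np.where(has_num & has_den, num / den, np.nan)
    table = pd.DataFrame(
        {"ratio": ratio, "status": status, "passes_cutoff": False},
        index=quant.accessions,
    )
    return FoldChangeTable(
        table=table,
        numerator_fraction=numerator_fraction,
        denominator_fraction=denominator_fraction,
    )


@dataclass
class CarboxylaseBenchmark:
    """Elute/wash ratios of the carboxylase positive controls.

    ``total_ratio`` is the ratio of summed numerator abundance over
    summed denominator abundance across the controls detected in both
    fractions — the aggregate recovery of known-biotinylated protein.
    Controls missing from either fraction are excluded (listed in
    ``missing``), never imputed.
    """

    control_accessions: tuple[str, ...]
    per_protein_ratio: dict[str, float]
    min_ratio: float
    max_ratio: float
    total_ratio: float
    missing: tuple[str, ...]


def carboxylase_benchmark(
    quant: QuantTable,
    numerator_fraction: str,
    denominator_fraction: str,
    control_accessions: Sequence[str] = CARBOXYLASE_CONTROLS,
) -> CarboxylaseBenchmark:
    """Benchmark the streptavidin selection on the carboxylase controls.

    Raises
    ------
    ValueError
        If no control is quantified in both fractions — the benchmark
        is undefined without at least one two-fraction control.
    """
    controls = tuple(normalize_accession(a) for a in control_accessions)
    num = quant.abundances(numerator_fraction)
    den = quant.abundances(denominator_fraction)

    ratios: dict[str, float] = {}
    missing: list[str] = []
    num_sum = den_sum = 0.0
    for acc in controls:
        a = num.get(acc, np.nan)
        b = den.get(acc, np.nan)
        if np.isfinite(a) and np.isfinite(b):
            ratios[acc] = float(a / b)
            num_sum += float(a)
            den_sum += float(b)
        else:
            missing.append(acc)
    if not ratios:
        raise ValueError(
            "no carboxylase control detected in both fractions; benchmark undefined"
        )
    if missing:
        logger.warning(
            "controls %s not quantified in both fractions; excluded from benchmark",
            missing,
        )
    values = list(ratios.values())
    return CarboxylaseBenchmark(
        control_accessions=controls,
        per_protein_ratio=ratios,
        min_ratio=min(values),
        max_ratio=max(values),
        total_ratio=num_sum / den_sum,
        missing=tuple(missing),
    )


def apply_cutoff(
    fc: FoldChangeTable,
    cutoff: float,
    include_numerator_only: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Filter to proteins enriched at least ``cutoff``-fold.

    A protein passes iff its ratio is defined and >= cutoff (inclusive
    boundary: "at least N-fold"), or it is numerator-only and
    ``include_numerator_only`` is set.  Mutates ``fc.table``'s
    ``passes_cutoff`` column and returns (passing rows, count).
    """
    if not np.isfinite(cutoff) or cutoff < 0:
        raise ValueError("cutoff must be a finite non-negative number")
    table = fc.table
    passes = (table["status"] == STATUS_BOTH) & (table["ratio"] >= cutoff)
    if include_numerator_only:
        passes |= table["status"] == STATUS_NUMERATOR_ONLY
    table["passes_cutoff"] = passes
    passing = table[passes].copy()
    logger.info(
        "cutoff %.3g: %d of %d proteins pass (%d elute-only included)",
        cutoff,
        len(passing),
        len(table),
        int((passing["status"] == STATUS_NUMERATOR_ONLY).sum()),
    )
    return passing, int(passes.sum())


def suggest_cutoff(
    benchmark: CarboxylaseBenchmark,
    policy: str = "fixed",
    fixed_value: float = 3.0,
) -> float:
    """Derive an enrichment cutoff from the carboxylase benchmark.

    Policies: ``min_control`` (the smallest control ratio — the minimum
    enrichment a known-biotinylated protein achieved), ``total`` (the
    aggregate-abundance ratio), ``fixed`` (an explicit value; the
    conventional choice is 3).
    """
    if policy == "min_control":
        return benchmark.min_ratio
    if policy == "total":
        return benchmark.total_ratio
    if policy == "fixed":
        return float(fixed_value)
    raise ValueError(f"unknown cutoff policy {policy!r}")


def write_candidates(
    passing: pd.DataFrame,
    path: str | Path,
    refmap: ReferenceMap | None = None,
) -> None:
    """Write filtered candidates as TSV (accession, ratio, status,
    pass flag, and compartment when a reference map is supplied)."""
    out = passing.copy()
    if refmap is not None:
        from lopitmap.reference_map import NOT_IN_MAP

        comp = [
            (c if (c := refmap.compartment_of(acc)) is not NOT_IN_MAP else "not-in-map")
            for acc in out.index
        ]
        out["compartment"] = comp
    out.index.name = "accession"
    out.to_csv(path, sep="\t")
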