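"""Synthetic data generators with known ground truth.

Every stage of the pipeline is testable without downloading the real
reference map or the public proteome tables: this module generates

* a reference map of 2-D Gaussian compartment clusters (plus a broad
  central "unknown" cloud, mimicking proteins with ambiguous gradient
  profiles),
* a proximity-labeling experiment — wash/elute fractions for a bait
  (test) and an unfused-ligase (control) group, with planted
  bait-proximal interactors, carboxylase positive controls at
  configured recovery ratios, and log-normal multiplicative intensity
  noise,
* an extracellular-vesicle experiment — a five-category marker list
  with configurable category sizes and two preparations differing in
  how much non-vesicular (contaminant-region) material they carry.

All generators are fully deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lopitmap.enrichment import CARBOXYLASE_CONTROLS
from lopitmap.marker_eval import CONTAMINANT_REGION, MARKER_REGION
from lopitmap.quant_io import CATEGORY_ROLES, MarkerSet, QuantTable
from lopitmap.reference_map import COMPARTMENTS, ReferenceMap

logger = logging.getLogger(__name__)

GROUPS = ("GR", "PCFT")
FRACTIONS = ("W-1", "W-2", "Elute")


def fraction_id(group: str, fraction: str) -> str:
    """Column name for a group/fraction pair, e.g. ``PCFT Elute``."""
    return f"{group} {fraction}"


@dataclass(frozen=True)
class CompartmentSpec:
    """One Gaussian cluster of the synthetic map."""

    label: str
    center: tuple[float, float]
    spread: float
    n_proteins: int


def default_compartment_layout(
    n_per_compartment: int = 150,
    n_unknown: int = 600,
    radius: float = 30.0,
    spread: float = 2.5,
    unknown_spread: float = 12.0,
) -> tuple[CompartmentSpec, ...]:
    """Twelve labeled clusters on a circle plus a broad central
    "unknown" cloud, the qualitative geometry of published organellar
    t-SNE maps."""
    labeled = [c for c in COMPARTMENTS if c != "unknown"]
    specs = []
    for i, label in enumerate(labeled):
        theta = 2 * math.pi * i / len(labeled)
        specs.append(
            CompartmentSpec(
                label=label,
                center=(radius * math.cos(theta), radius * math.sin(theta)),
                spread=spread,
                n_proteins=n_per_compartment,
            )
        )
    specs.append(
        CompartmentSpec("unknown", (0.0, 0.0), unknown_spread, n_unknown)
    )
    return tuple(specs)


@dataclass(frozen=True)
class BioidConfig:
    """Study conditions for the synthetic proximity-labeling experiment.

    Defaults: planted interactors are 10x enriched in the bait group's
    eluate over the final wash while background is unenriched (1x),
    under multiplicative log-normal noise of sigma 0.2 log10 units per
    measurement; the four carboxylase controls recover at ratios
    spanning 2.1-68.8, the observed range for a bait-group selection.
    """

    n_background: int = 400
    n_interactors: int = 60
    bait_compartment: str = "plasma membrane"
    interactor_effect: float = 10.0
    background_effect: float = 1.0
    noise_sigma_log10: float = 0.2
    carboxylase_ratios: tuple[float, ...] = (2.1, 10.0, 30.0, 68.8)
    carboxylase_accessions: tuple[str, ...] = CARBOXYLASE_CONTROLS
    dropout_floor: float | None = None


@dataclass(frozen=True)
class EvConfig:
    """Study conditions for the synthetic EV-preparation experiment.

    Category sizes default to the five-category marker list used for
    EV-preparation evaluation (110, 55, 195, 41, 160 proteins).
    ``contamination_level`` scales how strongly preparation B detects
    contaminant-region proteins; at 0 it detects none.
    """

    marker_category_sizes: tuple[int, ...] = (110, 55, 195, 41, 160)
    contamination_level: float = 0.5
    p_detect_marker_region: float = 0.8
    p_detect_other: float = 0.3
    p_detect_contaminant_a: float = 0.15
    p_detect_contaminant_b_max: float = 0.7
    #: proteins detected per preparation that have no map coordinates,
    #: emulating the sizeable share of any real proteome absent from
    #: the reference embedding
    n_offmap: int = 300


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    compartments: tuple[CompartmentSpec, ...] = field(
        default_factory=default_compartment_layout
    )
    bioid: BioidConfig = field(default_factory=BioidConfig)
    ev: EvConfig = field(default_factory=EvConfig)


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator; stream key must be
    # stable across processes, so avoid Python's randomized str hash
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(key,))
    )


def generate_reference_map(cfg: SynthConfig) -> ReferenceMap:
    """Draw a synthetic organellar map from the configured clusters.

    Compartment labels in the layout must be unique.  The four
    carboxylase control accessions are planted in their physiological
    compartments (three mitochondrial, acetyl-CoA carboxylase cytosolic)
    so that proximity-labeling fixtures can reference them; all other
    accessions are synthetic ``SYNnnnnn`` identifiers.
    """
    labels = [spec.label for spec in cfg.compartments]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate compartment labels in synthetic layout")
    bad = set(labels) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"labels outside the map vocabulary: {sorted(bad)}")

    rng = _rng(cfg, "reference_map")
    rows = []
    counter = 0
    for spec in cfg.compartments:
        pts = rng.normal(
            loc=spec.center, scale=spec.spread, size=(spec.n_proteins, 2)
        )
        for x, y in pts:
            counter += 1
            rows.append((f"SYN{counter:05d}", float(x), float(y), spec.label))

    frame = pd.DataFrame(rows, columns=["accession", "x", "y", "compartment"])
    # plant carboxylase accessions in their physiological compartments
    carb_home = {
        "P11498": "mitochondria",
        "P05165": "mitochondria",
        "Q96RQ3": "mitochondria",
        "Q13085": "cytosol",
    }
    taken: set[int] = set()
    for acc, comp in carb_home.items():
        idx = [i for i in frame.index[frame["compartment"] == comp] if i not in taken]
        if not idx:
            continue
        frame.loc[idx[0], "accession"] = acc
        taken.add(idx[0])
    frame = frame.set_index("accession")
    return ReferenceMap(frame)


def _lognormal_base(rng: np.random.Generator, n: int, mean_log10: float = 7.0,
                    sd_log10: float = 0.6) -> np.ndarray:
    return 10.0 ** rng.normal(mean_log10, sd_log10, size=n)


def generate_bioid_experiment(
    cfg: SynthConfig, refmap: ReferenceMap
) -> tuple[QuantTable, pd.DataFrame]:
    """Simulate wash/elute quantitation for control and bait groups.

    Returns the quantitation table (six fraction columns: W-1, W-2 and
    Elute for the GR control and the bait group) and a truth table
    flagging the planted interactors.

    Background proteins have elute/wash ratios around
    ``background_effect`` in both groups; interactors, drawn from the
    bait compartment, are enriched by ``interactor_effect`` in the bait
    group's eluate only.  Carboxylase controls recover at the configured
    per-protein ratios in both groups.  Every measured abundance is
    multiplied by independent log-normal noise.
    """
    b = cfg.bioid
    rng = _rng(cfg, "bioid")
    carbs = [a for a in b.carboxylase_accessions if a in refmap.accessions]
    if len(carbs) != len(b.carboxylase_accessions):
        raise ValueError("carboxylase controls missing from the reference map")
    if len(b.carboxylase_ratios) != len(carbs):
        raise ValueError("need one carboxylase ratio per control accession")

    bait_members = refmap.members_of([b.bait_compartment]).index.difference(carbs)
    if b.n_interactors > len(bait_members):
        raise ValueError(
            f"n_interactors={b.n_interactors} exceeds the {len(bait_members)} "
            f"proteins in compartment {b.bait_compartment!r}"
        )
    interactors = pd.Index(
        rng.choice(bait_members, size=b.n_interactors, replace=False)
    )
    pool = refmap.accessions.difference(interactors).difference(carbs)
    if b.n_background > len(pool):
        raise ValueError("n_background exceeds the available map proteins")
    background = pd.Index(rng.choice(pool, size=b.n_background, replace=False))

    accs = list(background) + list(interactors) + list(carbs)
    n = len(accs)
    is_interactor = np.r_[
        np.zeros(len(background), bool), np.ones(len(interactors), bool),
        np.zeros(len(carbs), bool),
    ]
    is_carb = np.r_[np.zeros(len(background) + len(interactors), bool),
                    np.ones(len(carbs), bool)]

    def noise(size):
        return 10.0 ** rng.normal(0.0, b.noise_sigma_log10, size=size)

    data = {}
    for group in GROUPS:
        base = _lognormal_base(rng, n)  # true W-2-level abundance per protein
        effect = np.ones(n)
        if group == "PCFT":
            effect[is_interactor] = b.interactor_effect
            effect[~is_interactor & ~is_carb] = b.background_effect
        else:
            effect[~is_carb] = b.background_effect
        effect[is_carb] = np.asarray(b.carboxylase_ratios, dtype=float)
        data[fraction_id(group, "W-1")] = base * 2.0 * noise(n)
        data[fraction_id(group, "W-2")] = base * noise(n)
        data[fraction_id(group, "Elute")] = base * effect * noise(n)

    frame = pd.DataFrame(data, index=pd.Index(accs, name="accession"))
    if b.dropout_floor is not None:
        frame = frame.mask(frame < b.dropout_floor)
    truth = pd.DataFrame(
        {
            "is_interactor": is_interactor,
            "is_carboxylase": is_carb,
            "compartment": [refmap.compartment_of(a) for a in accs],
        },
        index=pd.Index(accs, name="accession"),
    )
    logger.info(
        "synthetic proximity-labeling experiment: %d background, %d interactors, "
        "%d controls", len(background), len(interactors), len(carbs),
    )
    return QuantTable(frame), truth


def generate_ev_experiment(
    cfg: SynthConfig, refmap: ReferenceMap
) -> tuple[QuantTable, MarkerSet]:
    """Simulate two EV preparations plus a categorized marker list.

    The marker list draws its categories from compartments consistent
    with their biology: plasma membrane (category 1), cytosol (2), the
    contaminant-region compartments (3), and the marker-region
    compartments (4 and 5).  Preparation A detects marker-region
    proteins preferentially; preparation B additionally detects
    contaminant-region proteins with probability proportional to
    ``contamination_level`` (none at level 0).
    """
    e = cfg.ev
    if len(e.marker_category_sizes) != 5:
        raise ValueError("marker_category_sizes must have exactly 5 entries")
    if not (0.0 <= e.contamination_level <= 1.0):
        raise ValueError("contamination_level must be in [0, 1]")
    rng = _rng(cfg, "ev")

    category_pools = {
        1: ["plasma membrane"],
        2: ["cytosol"],
        3: list(CONTAMINANT_REGION),
        4: list(MARKER_REGION),
        5: list(MARKER_REGION),
    }
    used: set[str] = set()
    entries = []
    for cat, size in zip(sorted(category_pools), e.marker_category_sizes):
        pool = refmap.members_of(category_pools[cat]).index.difference(sorted(used))
        if size > len(pool):
            raise ValueError(
                f"category {cat} size {size} exceeds the {len(pool)} available "
                f"proteins in {category_pools[cat]}"
            )
        chosen = rng.choice(pool, size=size, replace=False)
        used.update(chosen)
        entries.extend((a, cat, CATEGORY_ROLES[cat]) for a in chosen)
    marker_frame = pd.DataFrame(
        entries, columns=["accession", "category", "role"]
    ).set_index("accession")
    markers = MarkerSet(marker_frame)

    table = refmap.table
    comp = table["compartment"]
    in_marker = comp.isin(MARKER_REGION).to_numpy()
    in_contam = comp.isin(CONTAMINANT_REGION).to_numpy()

    def detect(p_marker, p_contam, p_other):
        p = np.where(in_marker, p_marker, np.where(in_contam, p_contam, p_other))
        return rng.random(len(table)) < p

    det_a = detect(e.p_detect_marker_region, e.p_detect_contaminant_a, e.p_detect_other)
    det_b = detect(
        e.p_detect_marker_region * 0.8,
        e.p_detect_contaminant_b_max * e.contamination_level,
        e.p_detect_other,
    )
    base = _lognormal_base(rng, len(table))
    frame = pd.DataFrame(
        {
            "prep-A": np.where(det_a, base * 10.0 ** rng.normal(0, 0.3, len(table)), np.nan),
            "prep-B": np.where(det_b, base * 10.0 ** rng.normal(0, 0.3, len(table)), np.nan),
        },
        index=table.index,
    )
    # drop proteins detected in neither preparation
    frame = frame[frame.notna().any(axis=1)]

    if e.n_offmap:
        off_accs = [f"EXT{i:05d}" for i in range(1, e.n_offmap + 1)]
        off_base = _lognormal_base(rng, e.n_offmap)
        off_a = rng.random(e.n_offmap) < 0.5
        off = pd.DataFrame(
            {
                "prep-A": np.where(off_a, off_base, np.nan),
                "prep-B": np.where(~off_a, off_base, np.nan),
            },
            index=pd.Index(off_accs, name="accession"),
        )
        frame = pd.concat([frame, off])
    return QuantTable(frame), markers


# -- writers for the synth CLI subcommand --------------------------------

def write_experiment(
    outdir: str | Path,
    cfg: SynthConfig,
) -> dict[str, Path]:
    """Generate and write the full synthetic bundle as plain-text tables.

    Writes reference map TSV, proximity-labeling quant CSV plus truth
    TSV, EV quant CSV plus marker TSV; returns the path of each file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refmap = generate_reference_map(cfg)
    bioid_quant, truth = generate_bioid_experiment(cfg, refmap)
    ev_quant, markers = generate_ev_experiment(cfg, refmap)

    paths = {
        "reference_map": outdir / "reference_map.tsv",
        "bioid_quant": outdir / "bioid_quant.csv",
        "bioid_truth": outdir / "bioid_truth.tsv",
        "ev_quant": outdir / "ev_quant.csv",
        "markers": outdir / "markers.tsv",
    }
    from lopitmap.reference_map import write_reference_map

    write_reference_map(refmap, paths["reference_map"])
    bioid_quant.frame.to_csv(paths["bioid_quant"])
    truth.to_csv(paths["bioid_truth"], sep="\t")
    ev_quant.frame.to_csv(paths["ev_quant"])
    markers.entries.to_csv(paths["markers"], sep="\t")
    return paths
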