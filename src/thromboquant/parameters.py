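"""Assembly of the eight thrombus parameters per image, experiment and strain.

The assay yields up to eight parameters per image:

======  =============================================  =========  ======
 P      meaning                                        image      range
======  =============================================  =========  ======
 P1     platelet surface area coverage (%SAC)          BF         0-93.67
 P2     platelet aggregate coverage (%SAC)             BF         0-49.17
 P3     thrombus morphology score                      BF         0-5
 P4     thrombus multilayer score                      BF         0-3
 P5     thrombus contraction score                     BF         0-3
 P6     PS exposure, annexin A5 (%SAC)                 FL         0-12.23
 P7     P-selectin expression, CD62P (%SAC)            FL         0-29.70
 P8     integrin aIIbb3 activation, JON/A (%SAC)       FL         0-28.25
======  =============================================  =========  ======

P3-P5 are manual visual scores against standard images, accepted in 0.5
increments; they are ingested, never computed from pixels. Three images per
experiment are averaged into one value per parameter, and experiments are
summarized per strain and surface with the inclusion rule of at least three
animals per modified group and four per wild-type group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("thromboquant")

PARAMETERS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")
SURFACES = ("M1", "M2", "M3")
SHEAR_RATES = (1000, 1700)

#: hard validity ranges per parameter (%SAC for P1/P2/P6-8, scores for P3-5)
PARAMETER_RANGES: Dict[str, tuple] = {
    "P1": (0.0, 100.0),
    "P2": (0.0, 100.0),
    "P3": (0.0, 5.0),
    "P4": (0.0, 3.0),
    "P5": (0.0, 3.0),
    "P6": (0.0, 100.0),
    "P7": (0.0, 100.0),
    "P8": (0.0, 100.0),
}

VISUAL_SCORES = ("P3", "P4", "P5")


class InvalidInputError(ValueError):
    pass


class ExclusionError(ValueError):
    """A strain fails the animal-number inclusion rule."""


@dataclass
class ImageParameters:
    """Parameter values for one image (or one experiment after averaging)."""

    surface: str
    image_id: str = ""
    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise InvalidInputError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        for p, v in list(self.values.items()):
            if p not in PARAMETERS:
                raise InvalidInputError(f"unknown parameter {p!r}")
            if v is None or (isinstance(v, float) and math.isnan(v)):
                del self.values[p]
                continue
            lo, hi = PARAMETER_RANGES[p]
            if not (lo <= v <= hi):
                raise InvalidInputError(
                    f"{p}={v} outside valid range [{lo}, {hi}] for image {self.image_id!r}"
                )
            if p in VISUAL_SCORES and (round(v * 2) - v * 2) > 1e-9:
                raise InvalidInputError(
                    f"visual score {p}={v} must be in 0.5 increments"
                )
        p1, p2 = self.values.get("P1"), self.values.get("P2")
        if p1 is not None and p2 is not None and p2 > p1 + 1e-9:
            raise InvalidInputError(
                f"aggregate coverage P2={p2} exceeds platelet coverage P1={p1}"
            )

    def get(self, p: str) -> Optional[float]:
        return self.values.get(p)


@dataclass
class ExperimentRecord:
    """One blood-perfusion experiment, parameters averaged over its images."""

    strain_id: str
    database_id: str
    genotype_class: str  # "modified" or "wildtype"
    surface: str
    shear_rate_per_s: int
    parameters: ImageParameters
    n_images: int = 1

    def __post_init__(self) -> None:
        if self.genotype_class not in ("modified", "wildtype"):
            raise InvalidInputError(
                f"genotype_class must be 'modified' or 'wildtype', got {self.genotype_class!r}"
            )
        if self.shear_rate_per_s not in SHEAR_RATES:
            raise InvalidInputError(
                f"shear rate must be one of {SHEAR_RATES}, got {self.shear_rate_per_s}"
            )
        if self.n_images < 1:
            raise InvalidInputError("n_images must be >= 1")


@dataclass
class StrainSummary:
    """Per-strain, per-surface mean/SD/n for each parameter."""

    strain_id: str
    database_id: str
    genotype_class: str
    surface: str
    mean: Dict[str, float]
    sd: Dict[str, float]
    n: Dict[str, int]
    n_experiments: int


def average_experiment(images: Sequence[ImageParameters]) -> ImageParameters:
    """Average parameter values across the (typically three) images of one
    experiment.

    A parameter present in only a subset of the images is averaged over the
    available images with a warning; it is absent from the result only if
    absent everywhere. Mixing surfaces is an error.
    """
    if not images:
        raise InvalidInputError("no images to average")
    surfaces = {im.surface for im in images}
    if len(surfaces) != 1:
        raise InvalidInputError(f"images mix surfaces {sorted(surfaces)}")
    out: Dict[str, float] = {}
    for p in PARAMETERS:
        vals = [im.values[p] for im in images if p in im.values]
        if not vals:
            continue
        if 0 < len(vals) < len(images):
            logger.warning(
                "parameter %s present in %d of %d images; averaging available values",
                p, len(vals), len(images),
            )
        out[p] = float(np.mean(vals))
    avg = ImageParameters(surface=images[0].surface,
                          image_id="+".join(im.image_id for im in images))
    avg.values = out  # already validated per image; mean stays in range
    return avg


def summarize_strain(
    records: Sequence[ExperimentRecord], enforce_inclusion: bool = True
) -> StrainSummary:
    """Mean, sample SD (n-1 denominator) and n per parameter for one strain.

    With ``enforce_inclusion`` on, modified strains need >= 3 experiments and
    wild-types >= 4, mirroring the animal-number criterion of the assay.
    """
    if not records:
        raise InvalidInputError("no experiment records")
    strains = {r.strain_id for r in records}
    surfaces = {r.surface for r in records}
    if len(strains) != 1 or len(surfaces) != 1:
        raise InvalidInputError(
            f"records must share strain and surface, got {sorted(strains)} / {sorted(surfaces)}"
        )
    rec0 = records[0]
    n_exp = len(records)
    if enforce_inclusion:
        minimum = 3 if rec0.genotype_class == "modified" else 4
        if n_exp < minimum:
            raise ExclusionError(
                f"strain {rec0.strain_id!r} ({rec0.genotype_class}) has only "
                f"{n_exp} experiments; inclusion requires >= {minimum}"
            )
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    n: Dict[str, int] = {}
    for p in PARAMETERS:
        vals = [r.parameters.values[p] for r in records if p in r.parameters.values]
        if not vals:
            continue
        mean[p] = float(np.mean(vals))
        sd[p] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        n[p] = len(vals)
    return StrainSummary(
        strain_id=rec0.strain_id,
        database_id=rec0.database_id,
        genotype_class=rec0.genotype_class,
        surface=rec0.surface,
        mean=mean,
        sd=sd,
        n=n,
        n_experiments=n_exp,
    )


def thrombus_signature(scaled: Dict[str, float], normalized: bool = False):
    """Thrombus signature: the sum of scaled P2-P5 (each 0-10, sum 0-40).

    Returns ``None`` when any of P2-P5 is missing — an undefined signature is
    an explicit marker, never silently zero. ``normalized=True`` divides the
    sum by 4; the plain sum is the canonical form.
    """
    needed = ("P2", "P3", "P4", "P5")
    vals = []
    for p in needed:
        v = scaled.get(p)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        vals.append(float(v))
    total = float(sum(vals))
    return total / 4.0 if normalized else total


# ---------------------------------------------------------------------------
# tabular ingest / emit
# ---------------------------------------------------------------------------

#: canonical column names of the per-image quantification CSV
IMAGE_CSV_COLUMNS = ("image_id", "experiment_id", "surface", "channel",
                     "threshold", "sac_percent", "aggregate_percent")
#: canonical column names of the manual scores CSV
SCORES_CSV_COLUMNS = ("image_id", "P3", "P4", "P5", "observer_id")

_CHANNEL_TO_PARAM = {"annexinA5": "P6", "CD62P": "P7", "JONA": "P8"}


def assemble_image_parameters(
    quant: pd.DataFrame, scores: Optional[pd.DataFrame] = None
) -> List[ImageParameters]:
    """Join per-image quantification rows with manual visual scores.

    ``quant`` holds one row per image and channel (brightfield rows carry
    P1 in ``sac_percent`` and P2 in ``aggregate_percent``; fluorescence rows
    carry their marker's %SAC in ``sac_percent``). ``scores`` holds P3-P5 per
    image; multiple observers of the same image are averaged.
    """
    out: List[ImageParameters] = []
    score_map: Dict[str, Dict[str, float]] = {}
    if scores is not None and len(scores):
        grouped = scores.groupby("image_id")[["P3", "P4", "P5"]].mean()
        score_map = grouped.to_dict("index")  # type: ignore[assignment]
    for image_id, group in quant.groupby("image_id"):
        values: Dict[str, float] = {}
        surface = str(group.iloc[0]["surface"])
        for _, row in group.iterrows():
            ch = row["channel"]
            if ch == "brightfield":
                values["P1"] = float(row["sac_percent"])
                if not pd.isna(row.get("aggregate_percent")):
                    values["P2"] = float(row["aggregate_percent"])
            elif ch in _CHANNEL_TO_PARAM:
                values[_CHANNEL_TO_PARAM[ch]] = float(row["sac_percent"])
            else:
                raise InvalidInputError(f"unknown channel {ch!r} for image {image_id!r}")
        if image_id in score_map:
            for p, v in score_map[image_id].items():
                if not pd.isna(v):
                    values[p] = float(v)
        out.append(ImageParameters(surface=surface, image_id=str(image_id), values=values))
    return out


def records_to_frame(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Tidy per-experiment table: one row per experiment, P1-P8 columns."""
    rows = []
    for r in records:
        row = {
            "strain_id": r.strain_id,
            "database_id": r.database_id,
            "genotype_class": r.genotype_class,
            "surface": r.surface,
            "shear_rate_per_s": r.shear_rate_per_s,
            "n_images": r.n_images,
        }
        for p in PARAMETERS:
            row[p] = r.parameters.values.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_summaries(df: pd.DataFrame) -> List[StrainSummary]:
    """Read a per-strain CSV (as written by ``summaries_to_frame``) back
    into typed summaries without loss."""
    out: List[StrainSummary] = []
    for _, row in df.iterrows():
        mean: Dict[str, float] = {}
        sd: Dict[str, float] = {}
        n: Dict[str, int] = {}
        for p in PARAMETERS:
            if f"{p}_mean" in row and not pd.isna(row[f"{p}_mean"]):
                mean[p] = float(row[f"{p}_mean"])
                sd[p] = float(row[f"{p}_sd"])
                n[p] = int(row[f"{p}_n"])
        out.append(StrainSummary(
            strain_id=str(row["strain_id"]),
            database_id=str(row["database_id"]),
            genotype_class=str(row["genotype_class"]),
            surface=str(row["surface"]),
            mean=mean, sd=sd, n=n,
            n_experiments=int(row["n_experiments"]),
        ))
    return out


def summaries_to_frame(summaries: Sequence[StrainSummary]) -> pd.DataFrame:
    """Tidy per-strain table with mean/sd/n columns per parameter."""
    rows = []
    for s in summaries:
        row = {
            "strain_id": s.strain_id,
            "database_id": s.database_id,
            "genotype_class": s.genotype_class,
            "surface": s.surface,
            "n_experiments": s.n_experiments,
        }
        for p in PARAMETERS:
            row[f"{p}_mean"] = s.mean.get(p, float("nan"))
            row[f"{p}_sd"] = s.sd.get(p, float("nan"))
            row[f"{p}_n"] = s.n.get(p, 0)
        rows.append(row)
    return pd.DataFrame(rows)
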