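"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the data the flow-chamber assay produces:

* **Brightfield images** — bright platelet discs (radius 2-4 px) and larger
  multi-intensity aggregate blobs on a darker background, corrupted by the
  artifacts the clean-up operators target: periodic vertical striping
  (sensor readout), a linear illumination gradient, and additive Gaussian
  noise. Truth masks and coverage percentages are exact by construction.
* **Strain parameter tables** — replicate experiment values drawn from
  normal distributions truncated to each parameter's valid range, with
  per-strain effects planted on the 0-10 scaled axis. Visual scores (P3-P5)
  are rounded to the half-step granularity of manual scoring.
* **Planted-cluster graphs** — planted-partition random graphs with uniform
  random edge confidences in the medium-to-highest band [0.40, 0.99].

All generators are seed-deterministic. No flow physics or platelet biology
is simulated; the images exercise the measurement chain, not the assay.
"""

from __future__ import annotations

import logging
from pathlib import Path
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from skimage.draw import disk as draw_disk

from .imaging import BinaryMask, GrayImage
from .parameters import (
    ExclusionError,
    ExperimentRecord,
    ImageParameters,
    InvalidInputError,
    records_to_frame,
)
from .pipeline import load_parameter_ranges

logger = logging.getLogger("thromboquant")


class PlacementError(RuntimeError):
    """Requested objects cannot be placed without overlap."""


@dataclass
class ImageTruth:
    """A synthetic image with its exact ground truth."""

    image: GrayImage
    platelet_mask: BinaryMask
    aggregate_mask: BinaryMask
    true_sac_percent: float
    true_aggregate_percent: float
    params: Dict[str, float] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# brightfield images
# ---------------------------------------------------------------------------

def _place_discs(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    radii: Sequence[int],
    occupied: List[Tuple[int, int, int]],
    margin: int,
    max_retries_per_object: int = 5000,
) -> List[Tuple[int, int, int]]:
    """Place discs without overlap (centre distance > sum of radii + margin).

    Larger discs are placed first — rejection sampling packs far more
    reliably when the big objects claim space before the small ones.
    """
    placed: List[Tuple[int, int, int]] = []
    h, w = shape
    for rad in sorted(radii, reverse=True):
        ok = False
        for _ in range(max_retries_per_object):
            r = int(rng.integers(rad + 1, h - rad - 1))
            c = int(rng.integers(rad + 1, w - rad - 1))
            if all(
                (r - r0) ** 2 + (c - c0) ** 2 > (rad + rad0 + margin) ** 2
                for r0, c0, rad0 in occupied + placed
            ):
                placed.append((r, c, rad))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a disc of radius {rad} after "
                f"{max_retries_per_object} retries"
            )
    return placed


def generate_brightfield(
    n_platelets: int = 120,
    aggregate_count: int = 4,
    aggregate_radius_px: int = 14,
    stripe_amplitude: float = 0.10,
    illumination_amplitude: float = 0.15,
    noise_sd: float = 0.03,
    seed: int = 0,
    shape: Tuple[int, int] = (256, 256),
    stripe_period_px: int = 8,
    bit_depth: int = 8,
) -> ImageTruth:
    """Synthesize a brightfield thrombus image with exact ground truth.

    Platelets are bright discs of radius 2-4 px; aggregates are larger blobs
    with an even brighter multilayered core. ``stripe_amplitude``,
    ``illumination_amplitude`` and ``noise_sd`` are fractions of the dynamic
    range. Objects never overlap; a separation margin keeps distinct objects
    from merging under the morphological clean-up so the truth masks stay
    meaningful at the component level.
    """
    if min(shape) < 256:
        raise InvalidInputError("image must be at least 256 x 256")
    for name, v in [("n_platelets", n_platelets), ("aggregate_count", aggregate_count),
                    ("stripe_amplitude", stripe_amplitude),
                    ("illumination_amplitude", illumination_amplitude),
                    ("noise_sd", noise_sd)]:
        if v < 0:
            raise InvalidInputError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    max_i = float(2 ** bit_depth - 1)
    background = 0.40 * max_i
    platelet_level = 0.65 * max_i
    aggregate_level = 0.70 * max_i
    core_level = 0.85 * max_i

    img = np.full(shape, background, dtype=float)
    platelet_mask = np.zeros(shape, dtype=bool)
    aggregate_mask = np.zeros(shape, dtype=bool)

    agg_radii = [aggregate_radius_px] * aggregate_count
    agg_pos = _place_discs(rng, shape, agg_radii, [], margin=12)
    for r, c, rad in agg_pos:
        rr, cc = draw_disk((r, c), rad, shape=shape)
        img[rr, cc] = aggregate_level
        aggregate_mask[rr, cc] = True
        rr, cc = draw_disk((r, c), max(2, int(0.6 * rad)), shape=shape)
        img[rr, cc] = core_level
    platelet_mask |= aggregate_mask

    pl_radii = rng.integers(2, 5, size=n_platelets)
    pl_pos = _place_discs(rng, shape, list(pl_radii), agg_pos, margin=10)
    for r, c, rad in pl_pos:
        rr, cc = draw_disk((r, c), rad, shape=shape)
        img[rr, cc] = platelet_level
        platelet_mask[rr, cc] = True

    cols = np.arange(shape[1])[None, :]
    img = img + stripe_amplitude * max_i * np.sin(2 * np.pi * cols / stripe_period_px)
    rows = np.arange(shape[0])[:, None]
    img = img + illumination_amplitude * max_i * (rows / (shape[0] - 1) - 0.5)
    img = img + rng.normal(0.0, noise_sd * max_i, size=shape)
    img = np.clip(img, 0.0, max_i)

    true_sac = 100.0 * platelet_mask.mean()
    true_agg = 100.0 * aggregate_mask.mean()
    gray = GrayImage(pixels=img, bit_depth=bit_depth, channel_label="brightfield")
    return ImageTruth(
        image=gray,
        platelet_mask=BinaryMask(platelet_mask, source_threshold=float("nan")),
        aggregate_mask=BinaryMask(aggregate_mask, source_threshold=float("nan")),
        true_sac_percent=true_sac,
        true_aggregate_percent=true_agg,
        params={
            "stripe_amplitude": stripe_amplitude,
            "stripe_period_px": stripe_period_px,
            "illumination_amplitude": illumination_amplitude,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fluorescence images
# ---------------------------------------------------------------------------

def generate_fluorescence(
    platelet_mask: BinaryMask,
    positive_fraction: float,
    noise_sd: float = 0.02,
    seed: int = 0,
    channel_label: str = "annexinA5",
    bit_depth: int = 8,
) -> ImageTruth:
    """Mark a fraction of platelet-mask pixels as stained, in contiguous
    patches, emulating an activation-marker channel.

    The positive pixel count is ``round(positive_fraction * mask pixels)``;
    the truth %SAC is computed from the resulting mask so truth and mask
    agree exactly.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise InvalidInputError("positive_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    mask = platelet_mask.pixels
    max_i = float(2 ** bit_depth - 1)
    n_mask = int(mask.sum())
    target = int(round(positive_fraction * n_mask))
    pos = np.zeros_like(mask)
    if target > 0:
        coords = np.argwhere(mask)
        order = rng.permutation(len(coords))
        chosen = np.zeros(len(coords), dtype=bool)
        index = {tuple(c): i for i, c in enumerate(coords)}
        n_chosen = 0
        ptr = 0
        while n_chosen < target and ptr < len(order):
            start = order[ptr]
            ptr += 1
            if chosen[start]:
                continue
            # breadth-first growth of a contiguous patch inside the mask
            queue = [start]
            chosen[start] = True
            n_chosen += 1
            while queue and n_chosen < target:
                i = queue.pop(0)
                r, c = coords[i]
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    j = index.get((r + dr, c + dc))
                    if j is not None and not chosen[j]:
                        chosen[j] = True
                        n_chosen += 1
                        queue.append(j)
                        if n_chosen >= target:
                            break
        pos[tuple(coords[chosen].T)] = True
    img = np.full(mask.shape, 0.05 * max_i, dtype=float)
    img[pos] = 0.70 * max_i
    img = np.clip(img + rng.normal(0.0, noise_sd * max_i, size=mask.shape), 0.0, max_i)
    true_sac = 100.0 * pos.mean()
    return ImageTruth(
        image=GrayImage(pixels=img, bit_depth=bit_depth, channel_label=channel_label),
        platelet_mask=platelet_mask,
        aggregate_mask=BinaryMask(pos, source_threshold=float("nan")),
        true_sac_percent=true_sac,
        true_aggregate_percent=true_sac,
        params={"positive_fraction": positive_fraction, "noise_sd": noise_sd},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# strain parameter tables
# ---------------------------------------------------------------------------

@dataclass
class StrainTableTruth:
    """Synthetic multi-strain experiment table with planted effects."""

    records: List[ExperimentRecord]
    planted_effects: Dict[str, Dict[str, float]]
    anchors: Dict[Tuple[str, str], Tuple[float, float]]
    group_sd: float
    seed: int

    def frame(self):
        return records_to_frame(self.records)

    def wildtype_records(self) -> List[ExperimentRecord]:
        return [r for r in self.records if r.genotype_class == "wildtype"]

    def modified_records(self) -> List[ExperimentRecord]:
        return [r for r in self.records if r.genotype_class == "modified"]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    from scipy.stats import truncnorm

    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_strain_table(
    n_wildtype_sets: int = 3,
    n_modified: int = 5,
    planted_effects: Optional[Dict[str, Dict[str, float]]] = None,
    group_sd: float = 0.5,
    n_per_group: int = 4,
    seed: int = 0,
    parameters: Sequence[str] = ("P1", "P2", "P3", "P4", "P5"),
    surface: str = "M1",
    baseline_scaled: float = 5.0,
    wildtype_baseline_cv: float = 0.0,
    enforce_inclusion: bool = True,
) -> StrainTableTruth:
    """Generate per-experiment parameter values for wild-type and modified
    strains with effects planted on the 0-10 scaled axis.

    The nominal scaling anchor of each parameter is the top of its valid
    range (so scaled 10 corresponds to the range maximum); wild-type group
    means sit at ``baseline_scaled`` and modified groups at baseline plus
    the planted effect. Replicate values are drawn from normal distributions
    truncated to the valid range; ``group_sd`` is in scaled units. Visual
    scores P3-P5 are rounded to 0.5 steps. ``wildtype_baseline_cv`` spreads
    the wild-type dataset means (percent CV) to emulate inter-cohort drift.
    """
    if n_per_group < 1 or n_wildtype_sets < 1:
        raise InvalidInputError("group sizes must be positive")
    if enforce_inclusion:
        if n_per_group < 3:
            raise ExclusionError(
                f"n_per_group={n_per_group} violates the inclusion rule "
                "(>= 3 modified animals); pass enforce_inclusion=False to override"
            )
        wt_n = max(4, n_per_group)
    else:
        wt_n = n_per_group
    rng = np.random.default_rng(seed)
    ranges = load_parameter_ranges()
    range_max = {p: float(ranges.loc[p, "range_max"]) for p in parameters}
    mod_names = [f"mod{i + 1:02d}" for i in range(n_modified)]
    planted: Dict[str, Dict[str, float]] = {
        s: {p: 0.0 for p in parameters} for s in mod_names
    }
    for s, effs in (planted_effects or {}).items():
        if s not in planted:
            raise InvalidInputError(f"unknown strain {s!r} in planted_effects")
        for p, d in effs.items():
            if p not in range_max:
                raise InvalidInputError(f"unknown parameter {p!r} in planted_effects")
            if not (0.0 <= baseline_scaled + d <= 10.0):
                raise InvalidInputError(
                    f"planted mean {baseline_scaled + d} for {s}/{p} outside the "
                    "0-10 scaled range"
                )
            planted[s][p] = float(d)

    db_ids = [f"{i + 1:02d}" for i in range(n_wildtype_sets)]
    # per-dataset wild-type baselines (scaled units), optionally spread
    wt_base = {
        db: {
            p: float(np.clip(
                baseline_scaled * (1.0 + wildtype_baseline_cv / 100.0 * rng.standard_normal()),
                0.05, 10.0,
            ))
            for p in parameters
        }
        for db in db_ids
    }

    records: List[ExperimentRecord] = []

    def _make_records(strain, db, genotype, means_scaled, n_rep):
        draws = {}
        for p in parameters:
            mean_raw = means_scaled[p] / 10.0 * range_max[p]
            sd_raw = group_sd / 10.0 * range_max[p]
            vals = _truncated_normal(rng, mean_raw, sd_raw, 0.0, range_max[p], n_rep)
            if p in ("P3", "P4", "P5"):
                vals = np.round(np.asarray(vals) * 2.0) / 2.0
            draws[p] = np.asarray(vals, dtype=float)
        for i in range(n_rep):
            values = {p: float(draws[p][i]) for p in parameters}
            if "P1" in values and "P2" in values and values["P2"] > values["P1"]:
                values["P2"] = values["P1"]  # aggregate cannot exceed adhesion
            ip = ImageParameters(surface=surface, image_id=f"{strain}_e{i + 1}",
                                 values=values)
            records.append(
                ExperimentRecord(
                    strain_id=strain, database_id=db, genotype_class=genotype,
                    surface=surface, shear_rate_per_s=1000, parameters=ip,
                    n_images=3,
                )
            )

    for db in db_ids:
        _make_records(f"WT{db}", db, "wildtype", wt_base[db], wt_n)
    for i, strain in enumerate(mod_names):
        db = db_ids[i % len(db_ids)]
        means = {p: float(np.clip(wt_base[db][p] + planted[strain][p], 0.0, 10.0))
                 for p in parameters}
        _make_records(strain, db, "modified", means, n_per_group)

    anchors = {(surface, p): (0.0, range_max[p]) for p in parameters}
    return StrainTableTruth(
        records=records, planted_effects=planted, anchors=anchors,
        group_sd=group_sd, seed=seed,
    )


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def write_demo_inputs(out_dir, seed: int = 0):
    """Write a small, fully synthetic demo dataset and return its RunConfig.

    One wild-type cohort (4 experiments) and two modified strains named
    after receptor-pathway knockouts with strongly reduced thrombus
    formation ("Gp6", "Syk"; 3 experiments each), three brightfield images
    per experiment, visual scores derived deterministically from the planted
    platelet counts, and a small interaction edge list over the strain genes
    plus calcium-signaling partners.
    """
    import tifffile

    from .pipeline import RunConfig

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    # planted per-strain image-content settings: platelet count, aggregates,
    # and visual scores tied to thrombus size
    strains = {
        "WT01": dict(genotype="wildtype", n_exp=4, n_platelets=120,
                     aggregates=4, scores=(3.5, 2.0, 2.0)),
        "Gp6": dict(genotype="modified", n_exp=3, n_platelets=60,
                    aggregates=1, scores=(2.0, 1.0, 1.0)),
        "Syk": dict(genotype="modified", n_exp=3, n_platelets=30,
                    aggregates=0, scores=(1.0, 0.5, 0.0)),
    }
    image_rows, score_rows, meta_rows = [], [], []
    k = 0
    for strain, spec in strains.items():
        for e in range(spec["n_exp"]):
            exp_id = f"{strain}_e{e + 1}"
            meta_rows.append({
                "experiment_id": exp_id, "strain_id": strain,
                "database_id": "01", "genotype_class": spec["genotype"],
                "surface": "M1", "shear_rate_per_s": 1000,
            })
            for i in range(3):
                truth = generate_brightfield(
                    n_platelets=spec["n_platelets"],
                    aggregate_count=spec["aggregates"],
                    seed=seed * 10007 + k,
                )
                k += 1
                image_id = f"{exp_id}_i{i + 1}"
                rel = f"images/{image_id}.tif"
                tifffile.imwrite(out / rel,
                                 truth.image.pixels.round().astype("uint8"))
                image_rows.append({
                    "image_id": image_id, "path": rel, "channel": "brightfield",
                    "surface": "M1", "experiment_id": exp_id,
                })
                score_rows.append({
                    "image_id": image_id, "P3": spec["scores"][0],
                    "P4": spec["scores"][1], "P5": spec["scores"][2],
                    "observer_id": "obs1",
                })
    import pandas as pd

    pd.DataFrame(image_rows).to_csv(out / "images.csv", index=False,
                                    lineterminator="\n")
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False,
                                    lineterminator="\n")
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False,
                                   lineterminator="\n")
    genes = ["Gp6", "Syk", "Fcer1g", "Lat", "Lcp2", "Vav1",
             "Stim1", "Stim2", "Orai1", "Itga2", "Itgb1", "Rac1"]
    g, _ = generate_planted_cluster_graph((6, 6), p_in=0.9, p_out=0.1,
                                          seed=seed + 17)
    mapping = {old: genes[i] for i, old in enumerate(sorted(g.nodes))}
    with open(out / "edges.tsv", "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{mapping[a]}\t{mapping[b]}\t{d['confidence']:.3f}\n")
    return RunConfig(
        out_dir=str(out / "results"), seed=seed,
        images_csv=str(out / "images.csv"), scores_csv=str(out / "scores.csv"),
        metadata_csv=str(out / "metadata.csv"),
        edges_file=str(out / "edges.tsv"),
    )


# ---------------------------------------------------------------------------
# planted-cluster graphs
# ---------------------------------------------------------------------------

def generate_planted_cluster_graph(
    block_sizes: Sequence[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> Tuple[nx.Graph, Dict[str, int]]:
    """Planted-partition random graph with STRING-band edge confidences.

    Within-block edges appear with probability ``p_in``, between-block edges
    with ``p_out`` (require ``0 <= p_out < p_in <= 1``); kept edges get a
    uniform random confidence in [0.40, 0.99]. Returns the graph and the
    true block membership of every node.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise InvalidInputError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    nodes: List[str] = []
    membership: Dict[str, int] = {}
    for b, size in enumerate(block_sizes):
        for i in range(size):
            name = f"G{len(nodes):03d}"
            nodes.append(name)
            membership[name] = b
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            same = membership[nodes[i]] == membership[nodes[j]]
            p = p_in if same else p_out
            if rng.random() < p:
                conf = float(rng.uniform(0.40, 0.99))
                g.add_edge(nodes[i], nodes[j], confidence=conf)
    for n in g.nodes:
        g.nodes[n]["class"] = "core"
    return g, membership
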