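"""Run configuration, packaged reference tables, and the end-to-end pipeline.

The pipeline ties the stages together: quantify (images to %SAC), ingest
visual scores, parameterize (per-experiment, per-strain summaries), compare
(scaling, subtraction heatmap, correlation, concordance) and, when an edge
list is supplied, network clustering. Every run writes a manifest listing
its output files with content hashes, so that identical configuration and
inputs are verifiably reproducible. Every resolved threshold and scaling
anchor is logged — the manual choices are the assay's main reproducibility
hazard.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from .comparison import (
    DeltaMatrix,
    PhenotypeAnnotation,
    build_delta_matrix,
    compute_anchors,
    concordance_table,
    correlation_matrix,
    rank_and_cluster,
    scale_summary,
)
from .imaging import MorphologyConfig, quantify_brightfield, quantify_fluorescence, read_image
from .parameters import (
    PARAMETERS,
    ExperimentRecord,
    assemble_image_parameters,
    average_experiment,
    records_to_frame,
    summaries_to_frame,
    summarize_strain,
)

logger = logging.getLogger("thromboquant")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

_THROMBOSIS_TOKENS = {"down": "decreased", "o": "unchanged", "up": "increased",
                      "nd": "nd"}
# a compound "o-up" token (unchanged-to-prolonged) maps to the flagged direction
_BLEEDING_TOKENS = {"up": "prolonged", "o": "unchanged", "down": "shortened",
                    "nd": "nd", "o-up": "prolonged"}


def _data_path(name: str):
    return resources.files("thromboquant").joinpath("data", name)


def load_parameter_ranges() -> pd.DataFrame:
    """Valid range and 0-10 scaling band of each parameter P1-P8."""
    with resources.as_file(_data_path("parameter_ranges.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"parameter": str})
    return df.set_index("parameter")


def load_strain_registry() -> Tuple[pd.DataFrame, List[PhenotypeAnnotation]]:
    """Strain metadata with in vivo thrombosis/bleeding phenotype labels.

    Returns the metadata table (one row per re-analyzed strain: gene(s),
    genetic modification, background, wild-type database id, flow-chamber
    coverage-change token, in vivo phenotype tokens) and the parsed
    phenotype annotations. Unknown tokens raise a parse error naming the row.
    """
    with resources.as_file(_data_path("strain_registry.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    annotations: List[PhenotypeAnnotation] = []
    for i, row in df.iterrows():
        t, b = row["thrombosis"], row["bleeding"]
        if t not in _THROMBOSIS_TOKENS:
            raise ConfigError(f"row {i} ({row['strain_id']}): unknown thrombosis token {t!r}")
        if b not in _BLEEDING_TOKENS:
            raise ConfigError(f"row {i} ({row['strain_id']}): unknown bleeding token {b!r}")
        annotations.append(
            PhenotypeAnnotation(
                strain_id=row["strain_id"],
                thrombosis=_THROMBOSIS_TOKENS[t],
                bleeding=_BLEEDING_TOKENS[b],
            )
        )
    return df, annotations


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class McodeOptions:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = True
    fluff_density_cutoff: float = 0.1


@dataclass
class RunConfig:
    """Complete, file-round-trippable configuration of one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    # inputs
    images_csv: Optional[str] = None       # image_id, path, channel, surface, experiment_id
    scores_csv: Optional[str] = None       # image_id, P3, P4, P5, observer_id
    metadata_csv: Optional[str] = None     # experiment_id, strain_id, database_id, ...
    annotations: str = "packaged"          # "packaged", "none", or a CSV path
    edges_file: Optional[str] = None
    # stage options
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    brightfield_threshold: Union[float, str] = "auto"
    fluorescence_threshold: Union[float, str] = "auto"
    polarity: str = "auto"
    min_aggregate_area_px: int = 80
    enforce_inclusion: bool = True
    sd_mode: str = "rms"
    rank_by: str = "signature"
    min_confidence: float = 0.40
    mcode: McodeOptions = field(default_factory=McodeOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "morphology" in data and isinstance(data["morphology"], dict):
            mknown = {f.name for f in dataclasses.fields(MorphologyConfig)}
            munknown = set(data["morphology"]) - mknown
            if munknown:
                raise ConfigError(f"unknown morphology keys: {sorted(munknown)}")
            data["morphology"] = MorphologyConfig(**data["morphology"])
        if "mcode" in data and isinstance(data["mcode"], dict):
            mknown = {f.name for f in dataclasses.fields(McodeOptions)}
            munknown = set(data["mcode"]) - mknown
            if munknown:
                raise ConfigError(f"unknown mcode keys: {sorted(munknown)}")
            data["mcode"] = McodeOptions(**data["mcode"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: Optional[Union[str, Path]] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def _stage_quantify(cfg: RunConfig, out: Path) -> Path:
    listing = pd.read_csv(cfg.images_csv, dtype=str)
    required = {"image_id", "path", "channel", "surface", "experiment_id"}
    missing = required - set(listing.columns)
    if missing:
        raise StageError("quantify", f"images CSV lacks columns {sorted(missing)}")
    rows = []
    base = Path(cfg.images_csv).parent
    for _, r in listing.iterrows():
        path = Path(r["path"])
        if not path.is_absolute():
            path = base / path
        img = read_image(path, channel_label=r["channel"])
        if r["channel"] == "brightfield":
            res = quantify_brightfield(
                img, cfg.morphology, threshold=cfg.brightfield_threshold,
                polarity=cfg.polarity,
                min_aggregate_area_px=cfg.min_aggregate_area_px,
            )
            agg = res["aggregate_percent"]
        else:
            fcfg = dataclasses.replace(cfg.morphology, bandpass_large_px=65)
            res = quantify_fluorescence(img, fcfg,
                                        threshold=cfg.fluorescence_threshold)
            agg = float("nan")
        rows.append({
            "image_id": r["image_id"], "experiment_id": r["experiment_id"],
            "surface": r["surface"], "channel": r["channel"],
            "threshold": res["threshold"], "sac_percent": res["sac_percent"],
            "aggregate_percent": agg, "image_path": str(path),
        })
        logger.info("quantified %s (%s): threshold %.2f, %%SAC %.2f",
                    r["image_id"], r["channel"], res["threshold"], res["sac_percent"])
    per_image = out / "per_image.csv"
    _write_csv(pd.DataFrame(rows), per_image)
    return per_image


def _stage_parameterize(cfg: RunConfig, out: Path, per_image: Path):
    quant = pd.read_csv(per_image)
    if (quant["channel"] == "brightfield").any() and cfg.scores_csv is None:
        raise StageError(
            "parameterization",
            "scores CSV with visual parameters P3-P5 is required for "
            "brightfield analysis but none was configured",
        )
    scores = pd.read_csv(cfg.scores_csv) if cfg.scores_csv else None
    if cfg.metadata_csv is None:
        raise StageError("parameterization", "metadata CSV is required")
    meta = pd.read_csv(cfg.metadata_csv, dtype=str).set_index("experiment_id")
    images = assemble_image_parameters(quant, scores)
    by_exp: Dict[Tuple[str, str], list] = {}
    exp_of_image = dict(zip(quant["image_id"].astype(str), quant["experiment_id"].astype(str)))
    for ip in images:
        key = (exp_of_image[ip.image_id], ip.surface)
        by_exp.setdefault(key, []).append(ip)
    records: List[ExperimentRecord] = []
    for (exp_id, surface), ims in sorted(by_exp.items()):
        if exp_id not in meta.index:
            raise StageError("parameterization", f"experiment {exp_id!r} missing from metadata")
        m = meta.loc[exp_id]
        avg = average_experiment(ims)
        records.append(ExperimentRecord(
            strain_id=m["strain_id"], database_id=m["database_id"],
            genotype_class=m["genotype_class"], surface=surface,
            shear_rate_per_s=int(m.get("shear_rate_per_s", 1000)),
            parameters=avg, n_images=len(ims),
        ))
    _write_csv(records_to_frame(records), out / "per_experiment.csv")
    groups: Dict[Tuple[str, str], list] = {}
    for r in records:
        groups.setdefault((r.strain_id, r.surface), []).append(r)
    summaries = [
        summarize_strain(rs, enforce_inclusion=cfg.enforce_inclusion)
        for _, rs in sorted(groups.items())
    ]
    _write_csv(summaries_to_frame(summaries), out / "per_strain.csv")
    return records, summaries


def _stage_compare(cfg: RunConfig, out: Path, records, summaries) -> Optional[DeltaMatrix]:
    anchors = compute_anchors(summaries)
    for key, anc in sorted(anchors.items()):
        logger.info("scaling anchor %s:%s -> max %.4f", key[0], key[1], anc.max_anchor)
    scaled_rows = []
    for s in summaries:
        mean_s, _ = scale_summary(s, anchors)
        row = {"strain_id": s.strain_id, "surface": s.surface,
               "genotype_class": s.genotype_class}
        row.update({p: mean_s.get(p, float("nan")) for p in PARAMETERS})
        scaled_rows.append(row)
    _write_csv(pd.DataFrame(scaled_rows), out / "scaled_matrix.csv")

    wt = [s for s in summaries if s.genotype_class == "wildtype"]
    mod = [s for s in summaries if s.genotype_class == "modified"]
    dm: Optional[DeltaMatrix] = None
    if wt and mod:
        dm = build_delta_matrix(mod, wt, anchors=anchors, sd_mode=cfg.sd_mode)
        _write_csv(dm.delta, out / "delta_matrix.csv", index=True)
        _write_csv(dm.relevant, out / "delta_relevance.csv", index=True)
        _write_csv(dm.composite_sd, out / "delta_composite_sd.csv", index=True)
        _write_csv(dm.filtered(), out / "delta_filtered.csv", index=True)
        order = rank_and_cluster(dm.filtered(), rank_by=cfg.rank_by)
        (out / "strain_ranking.txt").write_text("\n".join(order) + "\n")
    raw = records_to_frame(records)
    strain_means = raw.groupby("strain_id")[["P1", "P2", "P3", "P4", "P5"]].mean()
    complete = strain_means.dropna()
    if len(complete) >= 3:
        tau, pval = correlation_matrix(strain_means)
        _write_csv(tau, out / "correlation_tau.csv", index=True)
        _write_csv(pval, out / "correlation_p.csv", index=True)
    else:
        logger.info("skipping correlation matrix: fewer than 3 complete strains")
    if dm is not None and cfg.annotations != "none":
        if cfg.annotations == "packaged":
            _, annotations = load_strain_registry()
        else:
            ann_df = pd.read_csv(cfg.annotations, dtype=str)
            annotations = [
                PhenotypeAnnotation(r["strain_id"], r["thrombosis"], r["bleeding"])
                for _, r in ann_df.iterrows()
            ]
        conc = concordance_table(dm, annotations)
        conc.in_vitro_class.rename_axis("strain_id").to_frame().to_csv(
            out / "in_vitro_classes.csv", lineterminator="\n")
        _write_csv(conc.thrombosis, out / "concordance_thrombosis.csv", index=True)
        _write_csv(conc.bleeding, out / "concordance_bleeding.csv", index=True)
    return dm


def _stage_network(cfg: RunConfig, out: Path, dm: Optional[DeltaMatrix]) -> None:
    from .network import (annotate_effects, clusters_to_frame, load_edges,
                          mcode, write_graphml, write_sif)

    core = set()
    if dm is not None:
        for strain in dm.delta.index:
            core.update(g.strip() for g in str(strain).split("/"))
    g = load_edges(cfg.edges_file, min_confidence=cfg.min_confidence,
                   core_nodes=core)
    opts = cfg.mcode
    clusters = mcode(
        g, degree_cutoff=opts.degree_cutoff,
        node_score_cutoff=opts.node_score_cutoff, k_core=opts.k_core,
        max_depth=opts.max_depth, haircut=opts.haircut, fluff=opts.fluff,
        fluff_density_cutoff=opts.fluff_density_cutoff,
    )
    for i, c in enumerate(clusters):
        for n in c.members:
            g.nodes[n]["cluster_id"] = i + 1
    _write_csv(clusters_to_frame(clusters), out / "clusters.csv")
    if dm is not None:
        table, unmatched = annotate_effects(g, dm, mode="signature")
        _write_csv(table, out / "node_effects.csv")
        (out / "unmatched_core_nodes.txt").write_text(
            "\n".join(unmatched) + ("\n" if unmatched else ""))
    write_graphml(g, out / "network.graphml")
    write_sif(g, out / "network.sif")


def run_pipeline(config: RunConfig) -> dict:
    """Execute quantify -> parameterize -> compare (-> network) and write a
    manifest of every output file with its SHA-256 content hash.

    Identical configuration and inputs yield identical manifest hashes.
    Stage failures raise :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages_run: List[str] = []
    try:
        if config.images_csv is None:
            raise StageError("quantify", "no images CSV configured")
        per_image = _stage_quantify(config, out)
        stages_run.append("quantify")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    try:
        records, summaries = _stage_parameterize(config, out, per_image)
        stages_run.append("parameterization")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("parameterization", str(exc)) from exc
    try:
        dm = _stage_compare(config, out, records, summaries)
        stages_run.append("compare")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("compare", str(exc)) from exc
    if config.edges_file:
        try:
            _stage_network(config, out, dm)
            stages_run.append("network")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("network", str(exc)) from exc

    config.to_yaml(out / "run_config.yaml")
    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stages": stages_run,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
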