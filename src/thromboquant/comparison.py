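"""Cross-strain statistics: scaling, subtraction heatmaps, correlation,
consistency, ranking/clustering and in vitro / in vivo concordance.

Strain mean parameters are univariate scaled to 0-10 per (surface, parameter)
column, anchored at zero (every parameter's natural range starts at 0) with
the observed column maximum mapping to 10. Gene-effect ("subtraction")
heatmaps are scaled modified-strain means minus paired wild-type means; a
difference counts as relevant only when it falls outside the composite
mean +/- SD band, with the composite SD taken as the root-mean-square of the
two group SDs on the scaled axis (configurable to the more conservative
max of the two).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .parameters import PARAMETERS, StrainSummary

logger = logging.getLogger("thromboquant")


class InvalidInputError(ValueError):
    pass


class PairingError(ValueError):
    """Modified strain and wild-type summary do not share a database id."""


class InsufficientDataError(ValueError):
    pass


THROMBOSIS_CATEGORIES = ("decreased", "unchanged", "increased", "nd")
BLEEDING_CATEGORIES = ("prolonged", "unchanged", "shortened", "nd")


@dataclass
class PhenotypeAnnotation:
    """Literature-derived in vivo phenotype labels for one strain."""

    strain_id: str
    thrombosis: str
    bleeding: str

    def __post_init__(self) -> None:
        if self.thrombosis not in THROMBOSIS_CATEGORIES:
            raise InvalidInputError(
                f"thrombosis category {self.thrombosis!r} not in {THROMBOSIS_CATEGORIES}"
            )
        if self.bleeding not in BLEEDING_CATEGORIES:
            raise InvalidInputError(
                f"bleeding category {self.bleeding!r} not in {BLEEDING_CATEGORIES}"
            )


# ---------------------------------------------------------------------------
# univariate 0-10 scaling
# ---------------------------------------------------------------------------

class ScaleAnchors(NamedTuple):
    """Anchors of a scaled column: raw 0 maps to 0, raw ``max_anchor`` to 10."""

    min_anchor: float
    max_anchor: float


def scale_univariate(
    values, anchors: Optional[ScaleAnchors] = None
) -> Tuple[np.ndarray, ScaleAnchors]:
    """Scale one column of per-strain means to 0-10.

    ``scaled = 10 * value / max(values)``; the observed maximum maps to 10
    and zero maps to 0. Missing values (NaN) stay missing. Passing recorded
    ``anchors`` scales new data consistently with an earlier run (values
    above the anchor are clipped to 10 with a warning).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise InvalidInputError("no non-missing values to scale")
    if np.any(finite < 0):
        raise InvalidInputError("negative values cannot be univariate scaled")
    if anchors is None:
        vmax = float(finite.max())
        anchors = ScaleAnchors(0.0, vmax)
    if anchors.max_anchor == 0:
        warnings.warn("degenerate column: all values zero; scaled to all-zero")
        return np.where(np.isnan(arr), np.nan, 0.0), anchors
    scaled = 10.0 * arr / anchors.max_anchor
    if np.nanmax(scaled) > 10.0 + 1e-9:
        warnings.warn("values above the recorded anchor were clipped to 10")
    scaled = np.clip(scaled, 0.0, 10.0)
    return scaled, anchors


def compute_anchors(
    summaries: Sequence[StrainSummary], parameters: Sequence[str] = PARAMETERS
) -> Dict[Tuple[str, str], ScaleAnchors]:
    """Per-(surface, parameter) anchors over all strains in the run.

    Anchors are computed jointly across wild-type and modified strains so
    that one common 0-10 axis underlies both the consistency heatmap and the
    subtraction heatmap.
    """
    anchors: Dict[Tuple[str, str], ScaleAnchors] = {}
    keys = sorted({(s.surface, p) for s in summaries for p in parameters if p in s.mean})
    for surface, p in keys:
        vals = [s.mean[p] for s in summaries if s.surface == surface and p in s.mean]
        _, anc = scale_univariate(np.asarray(vals, dtype=float))
        anchors[(surface, p)] = anc
    return anchors


def scale_summary(
    summary: StrainSummary, anchors: Dict[Tuple[str, str], ScaleAnchors]
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Scaled means and scaled SDs of one strain summary (per parameter)."""
    mean_s: Dict[str, float] = {}
    sd_s: Dict[str, float] = {}
    for p, m in summary.mean.items():
        key = (summary.surface, p)
        if key not in anchors:
            continue
        anc = anchors[key]
        if anc.max_anchor == 0:
            mean_s[p] = 0.0
            sd_s[p] = 0.0
            continue
        mean_s[p] = min(10.0, 10.0 * m / anc.max_anchor)
        sd = summary.sd.get(p, float("nan"))
        sd_s[p] = 10.0 * sd / anc.max_anchor
    return mean_s, sd_s


# ---------------------------------------------------------------------------
# subtraction heatmap with relevance filter
# ---------------------------------------------------------------------------

@dataclass
class DeltaMatrix:
    """Scaled modified-minus-wildtype differences with a relevance mask.

    ``delta`` holds the raw scaled differences in [-10, 10]; ``relevant`` is
    True where ``|delta| > composite SD``; ``filtered()`` reports irrelevant
    cells as 0 (unchanged), the form rendered in subtraction heatmaps.
    Columns are labelled ``"<surface>:<parameter>"``.
    """

    delta: pd.DataFrame
    composite_sd: pd.DataFrame
    relevant: pd.DataFrame

    def filtered(self) -> pd.DataFrame:
        return self.delta.where(self.relevant, 0.0)

    def columns_for(self, surface: str, parameters: Sequence[str]) -> List[str]:
        return [
            c for c in self.delta.columns
            if c.split(":")[0] == surface and c.split(":")[1] in parameters
        ]


def delta_heatmap_row(
    modified: StrainSummary,
    wildtype: StrainSummary,
    anchors: Dict[Tuple[str, str], ScaleAnchors],
    sd_mode: str = "rms",
) -> Tuple[Dict[str, float], Dict[str, float], Dict[str, bool]]:
    """One subtraction-heatmap row: scaled modified minus paired wild-type.

    The pairing unit is the wild-type database id; an unmatched id is an
    error. ``sd_mode="rms"`` (default) uses
    ``sqrt((sd_mod^2 + sd_wt^2) / 2)`` as the composite SD;
    ``sd_mode="max"`` uses ``max(sd_mod, sd_wt)``.
    """
    if modified.database_id != wildtype.database_id:
        raise PairingError(
            f"modified strain {modified.strain_id!r} (db {modified.database_id}) is "
            f"not paired with wild-type db {wildtype.database_id}"
        )
    if modified.surface != wildtype.surface:
        raise PairingError("modified and wild-type summaries are from different surfaces")
    if sd_mode not in ("rms", "max"):
        raise InvalidInputError(f"sd_mode must be 'rms' or 'max', got {sd_mode!r}")
    mod_m, mod_s = scale_summary(modified, anchors)
    wt_m, wt_s = scale_summary(wildtype, anchors)
    delta: Dict[str, float] = {}
    comp: Dict[str, float] = {}
    rel: Dict[str, bool] = {}
    for p in mod_m:
        if p not in wt_m:
            continue
        d = mod_m[p] - wt_m[p]
        s1, s2 = mod_s.get(p, float("nan")), wt_s.get(p, float("nan"))
        if sd_mode == "rms":
            c = math.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
        else:
            c = max(s1, s2)
        delta[p] = d
        comp[p] = c
        rel[p] = bool(abs(d) > c) if not math.isnan(c) else False
    return delta, comp, rel


def build_delta_matrix(
    modified: Sequence[StrainSummary],
    wildtypes: Sequence[StrainSummary],
    anchors: Optional[Dict[Tuple[str, str], ScaleAnchors]] = None,
    sd_mode: str = "rms",
) -> DeltaMatrix:
    """Assemble the full subtraction heatmap over all modified strains.

    Each modified summary is paired with the wild-type summary sharing its
    database id and surface. Anchors default to the joint anchors over all
    summaries passed in (wild-type and modified together).
    """
    if anchors is None:
        anchors = compute_anchors(list(modified) + list(wildtypes))
    wt_index = {(w.database_id, w.surface): w for w in wildtypes}
    deltas: Dict[str, Dict[str, float]] = {}
    comps: Dict[str, Dict[str, float]] = {}
    rels: Dict[str, Dict[str, bool]] = {}
    for m in modified:
        key = (m.database_id, m.surface)
        if key not in wt_index:
            raise PairingError(
                f"no wild-type summary for database id {m.database_id!r} on {m.surface}"
            )
        d, c, r = delta_heatmap_row(m, wt_index[key], anchors, sd_mode=sd_mode)
        row_d = deltas.setdefault(m.strain_id, {})
        row_c = comps.setdefault(m.strain_id, {})
        row_r = rels.setdefault(m.strain_id, {})
        for p in d:
            col = f"{m.surface}:{p}"
            row_d[col] = d[p]
            row_c[col] = c[p]
            row_r[col] = r[p]
    strains = sorted(deltas)
    cols = sorted({c for row in deltas.values() for c in row},
                  key=lambda c: (c.split(":")[0], c.split(":")[1]))
    delta_df = pd.DataFrame(index=strains, columns=cols, dtype=float)
    comp_df = pd.DataFrame(index=strains, columns=cols, dtype=float)
    rel_df = pd.DataFrame(False, index=strains, columns=cols)
    for s in strains:
        for c in cols:
            if c in deltas[s]:
                delta_df.loc[s, c] = deltas[s][c]
                comp_df.loc[s, c] = comps[s][c]
                rel_df.loc[s, c] = rels[s][c]
    return DeltaMatrix(delta=delta_df, composite_sd=comp_df, relevant=rel_df)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TauResult(NamedTuple):
    tau: float
    p_value: float


def kendall_tau_b(x, y) -> TauResult:
    """Kendall's tau-b with tie correction.

    ``tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))`` with the standard tie
    terms; the p-value uses exact enumeration for small untied samples and
    the tie-corrected normal approximation otherwise. An all-tied input has
    a zero denominator: the result is returned as NaN (undefined marker).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise InvalidInputError("need at least two observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TauResult(float("nan"), float("nan"))
    res = scipy.stats.kendalltau(x, y, variant="b", method="auto")
    return TauResult(float(res.statistic), float(res.pvalue))


def correlation_matrix(
    table: pd.DataFrame, parameters: Sequence[str] = ("P1", "P2", "P3", "P4", "P5")
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Kendall tau-b matrix (and p-values) over raw parameters.

    Observations are pairwise complete; the diagonal is 1 by definition.
    At least three rows complete in some pair are required.
    """
    sub = table[list(parameters)].astype(float)
    if (sub.notna().all(axis=1)).sum() < 3 and len(sub.dropna(how="all")) < 3:
        raise InsufficientDataError("fewer than 3 complete rows")
    k = len(parameters)
    tau = pd.DataFrame(np.eye(k), index=parameters, columns=parameters)
    pval = pd.DataFrame(np.zeros((k, k)), index=parameters, columns=parameters)
    ok = False
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                t, p = float("nan"), float("nan")
            else:
                t, p = kendall_tau_b(pair.iloc[:, 0].values, pair.iloc[:, 1].values)
                ok = True
            tau.iloc[i, j] = tau.iloc[j, i] = t
            pval.iloc[i, j] = pval.iloc[j, i] = p
    if not ok:
        raise InsufficientDataError("no parameter pair has 3 complete rows")
    return tau, pval


def wildtype_cv(means: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (%) of strain means across wild-type datasets.

    ``means`` has one row per wild-type dataset and one column per parameter;
    ``CV% = 100 * SD(means) / mean(means)``. A zero mean yields NaN
    (undefined marker).
    """
    if len(means) < 2:
        raise InsufficientDataError("need at least two wild-type datasets")
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mu
    cv[mu == 0] = float("nan")
    return cv


# ---------------------------------------------------------------------------
# ranking and clustering
# ---------------------------------------------------------------------------

def _nan_euclidean_condensed(mat: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances with missing cells pairwise-excluded,
    rescaled by sqrt(n_columns / n_valid) so rows with gaps stay comparable."""
    n, k = mat.shape
    out = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(np.isnan(mat[i]) | np.isnan(mat[j]))
            nv = valid.sum()
            if nv == 0:
                d = 0.0
            else:
                diff = mat[i, valid] - mat[j, valid]
                d = math.sqrt(float(diff @ diff) * k / nv)
            out[idx] = d
            idx += 1
    return out


def rank_and_cluster(
    matrix: pd.DataFrame,
    rank_by: str = "signature",
    relevant: Optional[pd.DataFrame] = None,
    surface: Optional[str] = None,
) -> List[str]:
    """Row ordering of a (delta) matrix for heatmap display.

    ``rank_by="signature"`` sorts ascending by the summed P2-P5 delta (the
    thrombus-signature change), ``"adhesion"`` by the P1 delta, both with
    alphabetical tie-break on strain id. ``rank_by="none"`` orders rows by
    unsupervised agglomerative hierarchical clustering (Euclidean distance,
    complete linkage, missing cells pairwise-excluded) and returns the
    dendrogram leaf order.
    """
    if matrix.empty:
        return []
    if rank_by not in ("signature", "adhesion", "none"):
        raise InvalidInputError(f"unknown rank_by {rank_by!r}")
    if rank_by in ("signature", "adhesion"):
        params = ("P2", "P3", "P4", "P5") if rank_by == "signature" else ("P1",)
        cols = [
            c for c in matrix.columns
            if c.split(":")[-1] in params
            and (surface is None or c.split(":")[0] == surface)
        ]
        if not cols:
            raise InvalidInputError(f"no {params} columns present")
        key = matrix[cols].sum(axis=1, min_count=1)
        order = sorted(matrix.index, key=lambda s: (float(key[s]), s))
        return order
    values = matrix.to_numpy(dtype=float)
    if len(matrix) == 1:
        return list(matrix.index)
    dist = _nan_euclidean_condensed(values)
    link = linkage(dist, method="complete")
    leaves = leaves_list(link)
    return [matrix.index[i] for i in leaves]


# ---------------------------------------------------------------------------
# in vitro / in vivo concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTable:
    """Per-strain in vitro classes and cross-tabulations against in vivo
    thrombosis and bleeding phenotype categories."""

    in_vitro_class: pd.Series
    thrombosis: pd.DataFrame
    bleeding: pd.DataFrame


def concordance_table(
    deltas: DeltaMatrix,
    annotations: Iterable[PhenotypeAnnotation],
    surface: str = "M1",
) -> ConcordanceTable:
    """Cross-tabulate in vitro flow-chamber effects against in vivo phenotypes.

    The in vitro class per strain is the sign of the summed relevant P1-P5
    change at the given surface: negative sums are "decreased", positive
    "increased" and an all-irrelevant row "unchanged". Strains lacking
    in vivo data ("nd") are tabulated separately, not dropped.
    """
    anns = list(annotations)
    cols = deltas.columns_for(surface, ("P1", "P2", "P3", "P4", "P5"))
    filt = deltas.filtered()
    classes = {}
    for strain in deltas.delta.index:
        total = float(filt.loc[strain, cols].sum()) if cols else 0.0
        if total < 0:
            classes[strain] = "decreased"
        elif total > 0:
            classes[strain] = "increased"
        else:
            classes[strain] = "unchanged"
    in_vitro = pd.Series(classes, name="in_vitro_class")
    ann_map = {a.strain_id: a for a in anns}
    rows = []
    for strain, cls in in_vitro.items():
        a = ann_map.get(strain)
        rows.append({
            "strain_id": strain,
            "in_vitro": cls,
            "thrombosis": a.thrombosis if a else "nd",
            "bleeding": a.bleeding if a else "nd",
        })
    df = pd.DataFrame(rows)
    if df.empty:
        empty = pd.DataFrame()
        return ConcordanceTable(in_vitro, empty, empty)
    thrombosis = pd.crosstab(df["in_vitro"], df["thrombosis"])
    bleeding = pd.crosstab(df["in_vitro"], df["bleeding"])
    return ConcordanceTable(in_vitro, thrombosis, bleeding)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Render a delta matrix as a green/black/red heatmap image.

    Green encodes decreased, black unchanged and red increased parameters,
    the convention of gene-effect subtraction heatmaps in this assay.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("gbr", ["#00a000", "#000000", "#d00000"])
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(matrix.columns)), max(3, 0.25 * len(matrix)))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap, vmin=-10, vmax=10,
                   aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="scaled difference vs wild-type")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
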