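"""Stress-subtype clustering, drug-repurposing signature export, and the
telomere-length T/S ratio.

Subtype clustering follows the exploratory high-stress-visit analysis:
visits are clustered hierarchically (Ward linkage on per-scale
standardized anxiety/mood/psychosis ratings) and the tree is cut at k=3;
clusters are labelled post hoc from their centroids as predominantly
anxious, predominantly psychotic, or non-comorbid.

Signature export writes the up/down probeset tag lists (GRP format, one
id per line) used to query the Connectivity Map for compounds with
opposite expression effects; the query itself is external and out of
scope here.

The T/S ratio is the qPCR relative quantity telomere/single-copy-gene,
computed from triplicate cycle thresholds at assumed 100% efficiency:
T/S = 2 ** (mean Ct of the albumin assay - mean Ct of the telomere assay).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("stressmark")

SUBTYPE_LABELS = ("anxious", "psychotic", "non_comorbid")
CT_SPREAD_LIMIT = 0.5


def subtype_cluster(
    scale_matrix: pd.DataFrame,
    k: int = 3,
    method: str = "ward",
    metric: str = "euclidean",
) -> pd.Series:
    """Cluster high-stress visits on anxiety/mood/psychosis ratings.

    ``scale_matrix`` has one row per visit and columns ``anxiety``,
    ``mood``, ``psychosis``.  Each scale is standardized, visits are
    clustered agglomeratively and the tree is cut at ``k``.  For k=3 the
    clusters are labelled from their centroid profiles: highest anxiety
    -> ``anxious``, highest psychosis (among the rest) -> ``psychotic``,
    remaining -> ``non_comorbid``.  For other k the raw cluster numbers
    are returned as strings.
    """
    if len(scale_matrix) < k:
        raise ValueError(f"{len(scale_matrix)} visits < k={k}")
    X = scale_matrix[["anxiety", "mood", "psychosis"]].astype(float).copy()
    for col in X.columns:
        sd = X[col].std(ddof=1)
        X[col] = (X[col] - X[col].mean()) / sd if sd > 0 else 0.0
    if k == 1:
        return pd.Series("non_comorbid", index=scale_matrix.index)
    Z = linkage(X.to_numpy(), method=method, metric=metric)
    numbers = fcluster(Z, t=k, criterion="maxclust")
    if len(set(numbers)) < k:
        logger.warning(
            "tree cut yielded %d < k=%d distinct clusters (degenerate data)",
            len(set(numbers)), k,
        )
    if k != 3:
        return pd.Series(
            [str(c) for c in numbers], index=scale_matrix.index
        )
    centroids = X.groupby(numbers).mean()
    names: dict[int, str] = {}
    anxious = centroids["anxiety"].idxmax()
    names[anxious] = "anxious"
    rest = centroids.drop(index=anxious)
    if len(rest):
        psychotic = rest["psychosis"].idxmax()
        names[psychotic] = "psychotic"
        for c in rest.index:
            if c not in names:
                names[c] = "non_comorbid"
    return pd.Series(
        [names[c] for c in numbers], index=scale_matrix.index
    )


def export_signature(
    markers: pd.DataFrame,
    platform_universe,
    out_dir,
    prefix: str = "signature",
) -> tuple[Path, Path]:
    """Write up/down GRP tag files for the given markers.

    ``markers`` has a ``direction`` column ({increased, decreased}) indexed
    by probeset id.  Probesets outside ``platform_universe`` are dropped;
    duplicates are removed.  Empty files are still written (with a
    warning) so downstream tooling sees a consistent layout.
    """
    universe = set(platform_universe)
    up, down = [], []
    seen = set()
    for probeset, row in markers.iterrows():
        if probeset in seen or probeset not in universe:
            continue
        seen.add(probeset)
        if row["direction"] == "increased":
            up.append(probeset)
        elif row["direction"] == "decreased":
            down.append(probeset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    up_path = out / f"{prefix}_up.grp"
    down_path = out / f"{prefix}_down.grp"
    up_path.write_text("".join(f"{p}\n" for p in up))
    down_path.write_text("".join(f"{p}\n" for p in down))
    if not up and not down:
        logger.warning("signature %s is empty after platform filtering", prefix)
    return up_path, down_path


def ts_ratio(
    tel_cts, alb_cts, spread_limit: float = CT_SPREAD_LIMIT
) -> float:
    """Telomere/single-copy T/S ratio from triplicate cycle thresholds.

    T/S = 2 ** (mean(ALB Ct) - mean(TEL Ct)), i.e. one cycle fewer for
    the telomere assay means twice the relative quantity.  Missing
    replicates are tolerated (computed on the available ones, logged);
    replicate spreads beyond ``spread_limit`` cycles are flagged.
    """
    tel = np.asarray([c for c in tel_cts if c is not None and not np.isnan(c)])
    alb = np.asarray([c for c in alb_cts if c is not None and not np.isnan(c)])
    if len(tel) == 0 or len(alb) == 0:
        raise ValueError("no usable replicates for T/S ratio")
    if len(tel) < 3 or len(alb) < 3:
        logger.warning(
            "T/S computed on %d/%d replicates", len(tel), len(alb)
        )
    for name, cts in (("TEL", tel), ("ALB", alb)):
        if cts.max() - cts.min() > spread_limit:
            logger.warning(
                "%s triplicate spread %.2f Ct exceeds %.2f",
                name, cts.max() - cts.min(), spread_limit,
            )
    return float(2.0 ** (alb.mean() - tel.mean()))
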