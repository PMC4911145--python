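"""Correlation screening: cluster redundant features, keep one per cluster.

Features are summarized to one value per region (mean over windows),
pairwise Spearman rank correlations are computed, and complete-linkage
hierarchical clustering on distance = 1 - |rho| is cut so that features
inside a cluster correlate at least at the threshold in absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .curves import CurveMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    retained: list[str]
    clusters: dict[int, list[str]]
    report: pd.DataFrame  # feature, cluster, retained
    correlation: pd.DataFrame


def correlation_matrix(curves: dict[str, CurveMatrix]) -> pd.DataFrame:
    """Pairwise Spearman correlation of region-mean summaries.

    Constant features (undefined correlation) get rho = 0 against every
    other feature, which isolates them into singleton clusters.
    """
    names = sorted(curves)
    if len(names) < 2:
        raise ValueError("need at least 2 features to screen")
    ref_ids = curves[names[0]].region_ids
    summaries = {}
    constant = []
    for name in names:
        cm = curves[name]
        if cm.region_ids != ref_ids:
            raise ValueError(f"{name}: region ids differ from {names[0]}")
        s = cm.values.mean(axis=1)
        if np.ptp(s) == 0:
            constant.append(name)
        summaries[name] = s
    if constant:
        logger.warning("constant feature(s) %s treated as their own clusters", constant)
    mat = np.column_stack([summaries[n] for n in names])
    with np.errstate(invalid="ignore"):
        rho = spearmanr(mat).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the two-feature case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


def screen_features(
    curves: dict[str, CurveMatrix],
    threshold_corr: float = 0.8,
    representatives: dict[int, str] | list[str] | None = None,
) -> ScreenResult:
    """Cut the complete-linkage dendrogram at distance 1 - threshold_corr.

    One feature is retained per cluster: the lexicographically first, unless
    a preferred representative list is given (first listed member of a
    cluster wins).
    """
    corr = correlation_matrix(curves)
    names = list(corr.index)
    dist = 1.0 - np.abs(corr.to_numpy())
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    assignment = fcluster(z, t=1.0 - threshold_corr, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for name, cid in zip(names, assignment):
        clusters.setdefault(int(cid), []).append(name)
    for members in clusters.values():
        members.sort()

    preferred = list(representatives) if isinstance(representatives, list) else []
    retained = []
    rows = []
    for cid in sorted(clusters):
        members = clusters[cid]
        rep = members[0]
        for cand in preferred:
            if cand in members:
                rep = cand
                break
        retained.append(rep)
        for m in members:
            rows.append({"feature": m, "cluster": cid, "retained": m == rep})
    retained.sort()
    report = pd.DataFrame(rows, columns=["feature", "cluster", "retained"])
    return ScreenResult(
        retained=retained, clusters=clusters, report=report, correlation=corr
    )
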