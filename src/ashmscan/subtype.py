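"""Expression-based two-group subtype calls and the mutated-group rule.

Within the focal lymphoma cohort two molecular subtypes are distinguished
from a marker gene signature: the classical subtype (cMCL, e.g. SOX11
positive) and the non-nodal subtype (nnMCL).  Samples are clustered on the
signature-gene submatrix (1 - Pearson correlation distance, average
linkage, cut into two groups) and the group with the higher signed marker
score receives the positive label.  Non-nodal samples are then split into a
mutated group when they carry at least ``min_cluster_muts`` mutations in
focal-specific binding-site clusters AND at least ``min_noncoding``
non-coding mutations in the regulatory region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str  # positive label (cMCL) or negative label (nnMCL)
    mut_group: str = "not-applicable"  # nnMCL_MUT | nnMCL_WT | not-applicable


def cluster_subtypes(
    expr: pd.DataFrame,
    signature_genes: Mapping[str, int],
    positive_label: str = "cMCL",
    negative_label: str = "nnMCL",
    linkage_method: str = "average",
) -> list[SubtypeCall]:
    """Two-group hierarchical clustering of samples on signature genes.

    ``expr`` is genes x samples (normalized values); ``signature_genes`` maps
    gene id to direction (+1 = high in the positive subtype, -1 = high in
    the negative one).  Missing genes are logged; all-missing is an error.
    The cluster with the higher mean signed marker score gets
    ``positive_label``.
    """
    present = {g: d for g, d in signature_genes.items() if g in expr.index}
    missing = sorted(set(signature_genes) - set(present))
    if missing:
        logger.warning("signature genes absent from expression matrix: %s", missing)
    if len(present) < 2:
        raise ValueError(f"need >= 2 signature genes in the matrix; missing: {missing}")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")

    sub = expr.loc[list(present)]  # genes x samples
    X = sub.to_numpy(dtype=float).T  # samples x genes
    dist = pdist(X, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)  # constant profiles: treat as identical
    groups = fcluster(linkage(dist, method=linkage_method), t=2, criterion="maxclust")

    directions = np.array([present[g] for g in sub.index], dtype=float)
    score = (X * directions[None, :]).mean(axis=1)
    labels = {}
    if len(np.unique(groups)) == 1:
        # degenerate cut (e.g. identical samples): single cluster, label by score sign
        labels[1] = positive_label if score.mean() >= 0 else negative_label
    else:
        mean1 = score[groups == 1].mean()
        mean2 = score[groups == 2].mean()
        labels = {1: positive_label, 2: negative_label} if mean1 >= mean2 else {
            1: negative_label,
            2: positive_label,
        }
    return [
        SubtypeCall(sample_id=s, subtype=labels.get(g, negative_label))
        for s, g in zip(expr.columns, groups)
    ]


def assign_mut_group(
    calls: Sequence[SubtypeCall],
    cluster_mut_count: Mapping[str, int],
    regulatory_noncoding_count: Mapping[str, int],
    min_cluster_muts: int = 2,
    min_noncoding: int = 10,
    nn_label: str = "nnMCL",
) -> list[SubtypeCall]:
    """Split non-nodal samples into mutated / wild-type groups.

    A non-nodal sample is assigned ``nnMCL_MUT`` iff it has at least
    ``min_cluster_muts`` mutations inside focal-specific binding-site
    clusters and at least ``min_noncoding`` non-coding mutations in the
    regulatory region; otherwise ``nnMCL_WT``.  Other subtypes stay
    ``not-applicable``.
    """
    out = []
    for c in calls:
        if c.subtype != nn_label:
            out.append(SubtypeCall(c.sample_id, c.subtype, "not-applicable"))
            continue
        if c.sample_id not in cluster_mut_count or c.sample_id not in regulatory_noncoding_count:
            raise ValueError(f"missing mutation counts for {nn_label} sample {c.sample_id}")
        mut = (
            cluster_mut_count[c.sample_id] >= min_cluster_muts
            and regulatory_noncoding_count[c.sample_id] >= min_noncoding
        )
        out.append(SubtypeCall(c.sample_id, c.subtype, f"{nn_label}_MUT" if mut else f"{nn_label}_WT"))
    return out


def rank_by_gene(expr: pd.DataFrame, gene: str) -> list[str]:
    """Sample ids ranked by a named gene's expression, descending."""
    if gene not in expr.index:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    return list(expr.loc[gene].sort_values(ascending=False).index)


def subtype_calls_to_frame(calls: Sequence[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": c.sample_id, "subtype": c.subtype, "mut_group": c.mut_group}
            for c in calls
        ]
    )
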