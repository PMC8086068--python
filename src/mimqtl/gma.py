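"""Global Methylation Alteration (GMA) score.

For tumor i the score is the sum of absolute deviations of its CpG beta
values from the per-CpG median of a normal-tissue reference panel::

    GMA_i = sum_j | beta[j, i] - median_j(normals) |

It is non-negative, zero iff the tumor matches the reference median at every
evaluated CpG, and additive over any partition of the CpG set. Missing tumor
betas are skipped (pairwise-complete sum) and the number of CpGs actually
summed is reported per tumor; an optional mean-normalized variant
(score / n_cpgs_used) is available for tumors with unequal missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import EnrichmentResult, flag_correlated, hypergeom_enrichment, covariate_correlations
from .containers import OmicsMatrix

log = logging.getLogger("mimqtl")

__all__ = ["GMAResult", "normal_reference", "gma_scores", "gma_mirna_enrichment"]


@dataclass
class GMAResult:
    scores: pd.DataFrame  # index sample_id; columns gma_score, n_cpgs_used[, gma_mean]
    reference: pd.Series  # per-CpG normal medians actually used

    @property
    def gma(self) -> pd.Series:
        return self.scores["gma_score"]


def normal_reference(normals: OmicsMatrix) -> pd.Series:
    """Per-CpG median beta over the normal panel (non-missing values; an
    even count averages the two central values). CpGs with all normals
    missing are excluded with a log entry."""
    if normals.shape[1] < 2:
        raise ValueError("need at least 2 normal samples for a median reference")
    med = normals.values.median(axis=1, skipna=True)
    dropped = med.isna()
    if dropped.any():
        log.warning("normal_reference: %d CpGs with no normal values excluded",
                    int(dropped.sum()))
    return med[~dropped].rename("reference_median")


def gma_scores(tumors: OmicsMatrix, reference: pd.Series,
               normalize: bool = False) -> GMAResult:
    """Per-tumor sum of |beta - reference median| over the CpGs shared by
    the tumor matrix and the reference (non-missing in both)."""
    shared = tumors.feature_ids.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("tumor matrix and reference share no CpGs")
    vals = tumors.values.loc[shared]
    ref = reference.loc[shared]
    dev = (vals.sub(ref, axis=0)).abs()
    n_used = dev.notna().sum(axis=0)
    if (n_used == 0).any():
        bad = list(n_used.index[n_used == 0])[:5]
        raise ValueError(f"tumor(s) share zero evaluated CpGs with reference: {bad}")
    scores = pd.DataFrame({
        "gma_score": dev.sum(axis=0, skipna=True),
        "n_cpgs_used": n_used,
    })
    if normalize:
        scores["gma_mean"] = scores["gma_score"] / scores["n_cpgs_used"]
    log.info("gma_scores: %d tumors over %d CpGs (median score %.2f)",
             scores.shape[0], len(shared), float(scores["gma_score"].median()))
    return GMAResult(scores, ref)


def gma_mirna_enrichment(expr: OmicsMatrix, gma: GMAResult,
                         cluster_members: dict[str, set],
                         background: set | None = None) -> tuple[pd.DataFrame, dict]:
    """Correlate every mimQTL miRNA with the GMA score and test each miRNA
    cluster for enrichment of positively (and negatively) correlated
    members, with the mimQTL miRNA universe as background."""
    g = gma.gma.reindex(expr.sample_ids)
    if g.nunique(dropna=True) <= 1:
        raise ValueError("constant GMA vector: correlations undefined")
    background = set(background) if background is not None else set(expr.feature_ids)
    sub = expr.subset_features(sorted(background))
    corr = covariate_correlations(sub, g)
    pos = flag_correlated(corr, "positive")
    neg = flag_correlated(corr, "negative")
    enrich: dict[str, dict[str, EnrichmentResult]] = {}
    for name, members in cluster_members.items():
        enrich[name] = {
            "positive": hypergeom_enrichment(members, pos, background,
                                             name=f"gma_pos_{name}"),
            "negative": hypergeom_enrichment(members, neg, background,
                                             name=f"gma_neg_{name}"),
        }
    return corr, enrich
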