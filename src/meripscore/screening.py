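"""Two-replicate screening, group comparison and the differential gene set.

Screening admits a gene to a group's m6A-modified set when it is scored
(i.e. methylated) in both biological replicates, its score clears the
minimum in both replicates (or either, under the looser rule), and the
between-replicate fold change max/min stays strictly below the cap —
the random-error filter applied before any group-level analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "screen_genes",
    "rep_scores_from_table",
    "wilcoxon_compare",
    "differential_exon_genes",
    "differential_table",
]

EXACT_N_MAX = 25  # exact enumeration below this per-sample size (untied data)


def screen_genes(
    rep_scores: Mapping[str, tuple[Optional[float], Optional[float]]],
    score_min: float = 1.0,
    fc_max: float = 2.0,
    score_rule: str = "both",
) -> pd.DataFrame:
    """Apply the two-replicate screening criteria to one group.

    ``rep_scores`` maps gene_id to its two replicate scores (None =
    unmethylated in that replicate).  A gene is retained iff it is present
    in both replicates, its score exceeds ``score_min`` (strictly) in both
    replicates (``score_rule="both"``) or in at least one (``"either"``),
    and the replicate fold change max/min is strictly below ``fc_max``.

    Returns a DataFrame (gene_id, score_rep1, score_rep2, group_score,
    fold_change) where group_score is the replicate mean.
    """
    if score_rule not in ("both", "either"):
        raise ValueError(f"unknown score_rule {score_rule!r}")
    if fc_max <= 1:
        raise ValueError(f"fc_max must exceed 1, got {fc_max}")
    if score_min < 0:
        raise ValueError(f"score_min must be non-negative, got {score_min}")
    rows = []
    for gene_id in sorted(rep_scores):
        s1, s2 = rep_scores[gene_id]
        if s1 is None or s2 is None:
            continue
        if s1 < 0 or s2 < 0:
            raise ValueError(f"gene {gene_id}: negative score")
        lo, hi = min(s1, s2), max(s1, s2)
        passes_score = lo > score_min if score_rule == "both" else hi > score_min
        if not passes_score:
            continue
        fc = np.inf if lo == 0 else hi / lo
        if not fc < fc_max:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "score_rep1": s1,
                "score_rep2": s2,
                "group_score": (s1 + s2) / 2,
                "fold_change": fc,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "score_rep1", "score_rep2", "group_score", "fold_change"])


def rep_scores_from_table(
    scores: pd.DataFrame,
    group: str,
    value: str = "score",
    replicates: Optional[Sequence[str]] = None,
) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Extract gene -> (rep1, rep2) scores for one group from a score table.

    ``value`` selects the score column ("score" or "exon_score").  With
    more than two replicates present, the first two (sorted) are used and
    a warning is logged.
    """
    sub = scores[scores["group"] == group]
    reps = list(replicates) if replicates is not None else sorted(sub["replicate"].unique())
    if len(reps) < 2:
        raise ValueError(f"group {group!r}: screening needs two replicates, found {reps}")
    if len(reps) > 2:
        logger.warning("group %s: %d replicates; screening uses the first two (%s, %s)", group, len(reps), reps[0], reps[1])
        reps = reps[:2]
    out: dict[str, tuple[Optional[float], Optional[float]]] = {}
    maps = [
        sub[sub["replicate"] == r].set_index("gene_id")[value].to_dict() for r in reps
    ]
    for gene_id in sorted(set(maps[0]) | set(maps[1])):
        out[gene_id] = (maps[0].get(gene_id), maps[1].get(gene_id))
    return out


@dataclass(frozen=True)
class DifferentialResult:
    """Outcome of the two-group Wilcoxon comparison."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    variant: str
    method: str  # "exact" or "asymptotic"


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wilcoxon_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    variant: str = "rank_sum",
) -> DifferentialResult:
    """Two-sided Wilcoxon comparison of two score samples.

    ``rank_sum`` is the unpaired Mann-Whitney/Wilcoxon rank-sum test over
    two (possibly different-sized) gene sets; ``signed_rank`` is the
    paired test on equal-length lists (gene intersection), dropping zero
    differences.  Exact enumeration is used when both sample sizes are at
    most 25 and the data are untied; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if variant == "rank_sum":
        if a.size == 0 or b.size == 0:
            raise ValueError("rank_sum requires two non-empty samples")
        exact = a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX and not _has_ties(np.concatenate([a, b]))
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        return DifferentialResult(float(res.statistic), float(res.pvalue), a.size, b.size, variant, method)
    if variant == "signed_rank":
        if a.size != b.size or a.size == 0:
            raise ValueError("signed_rank requires two equal-length non-empty samples")
        d = a - b
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("no informative pairs: all paired differences are zero")
        exact = d.size <= EXACT_N_MAX and not _has_ties(np.abs(d))
        method = "exact" if exact else "asymptotic"
        res = stats.wilcoxon(d, alternative="two-sided", method="exact" if exact else "approx", correction=True)
        return DifferentialResult(float(res.statistic), float(res.pvalue), a.size, b.size, variant, method)
    raise ValueError(f"unknown test variant {variant!r}")


def differential_table(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    include_ko_only: bool = False,
) -> pd.DataFrame:
    """Gene-wise KO vs WT comparison of screened group scores.

    Both inputs are screened tables (from :func:`screen_genes`, typically
    built from exon scores).  Returns one row per gene in the screened
    intersection — plus KO-only genes when ``include_ko_only`` — with
    wt_score, ko_score, ratio and the ``increased`` flag
    (ko_score > wt_score, strictly; KO-only genes count as increased).
    """
    wt_map = wt.set_index("gene_id")["group_score"].to_dict()
    ko_map = ko.set_index("gene_id")["group_score"].to_dict()
    rows = []
    for gene_id in sorted(set(wt_map) & set(ko_map)):
        w, k = wt_map[gene_id], ko_map[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "wt_score": w,
                "ko_score": k,
                "ratio": np.inf if w == 0 else k / w,
                "increased": k > w,
            }
        )
    if include_ko_only:
        for gene_id in sorted(set(ko_map) - set(wt_map)):
            rows.append(
                {
                    "gene_id": gene_id,
                    "wt_score": np.nan,
                    "ko_score": ko_map[gene_id],
                    "ratio": np.inf,
                    "increased": True,
                }
            )
    if not rows:
        logger.warning("differential_table: empty screened intersection")
        return pd.DataFrame(columns=["gene_id", "wt_score", "ko_score", "ratio", "increased"])
    return pd.DataFrame(rows)


def differential_exon_genes(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    include_ko_only: bool = False,
) -> set[str]:
    """Genes whose screened KO group score strictly exceeds the WT one.

    Applied to exon-score screened tables this yields the
    "m6A increased within exons in KO" gene set.
    """
    table = differential_table(wt, ko, include_ko_only=include_ko_only)
    if table.empty:
        return set()
    return set(table.loc[table["increased"], "gene_id"])
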