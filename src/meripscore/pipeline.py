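"""End-to-end orchestration: annotation + peaks in, tables out.

A single config (YAML file or :class:`PipelineConfig`) drives every
stage; all thresholds are echoed to the run log and outputs are
deterministic for identical config and inputs.  A ``SUCCESS`` sentinel
marks completed output directories; re-running on a complete directory
without ``force`` is a no-op.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as mio
from .assign import DEFAULT_PRECEDENCE, AnnotationIndex, metagene_table, region_proportions
from .enrichment import hypergeom_enrich
from .screening import (
    differential_exon_genes,
    differential_table,
    rep_scores_from_table,
    screen_genes,
    wilcoxon_compare,
)
from .scoring import score_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

SENTINEL = "SUCCESS"


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run.

    ``peaks`` maps group -> replicate -> narrowPeak path; exactly two
    groups with at least two replicates each are required for the
    screening stage.  ``wt_group``/``ko_group`` name the comparison
    direction (defaults: the two groups in order).
    """

    gtf: str
    peaks: dict[str, dict[str, str]]
    gmt: Optional[str] = None
    wt_group: Optional[str] = None
    ko_group: Optional[str] = None
    min_fraction: float = 0.5
    use_exon_union: bool = False
    score_mode: str = "length_weighted"
    score_min: float = 1.0
    fc_max: float = 2.0
    score_rule: str = "both"
    test_variant: str = "rank_sum"
    include_ko_only: bool = False
    promoter_window: int = 2000
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    universe: str = "assigned"  # assigned | screened | annotation
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.peaks) != 2:
            raise ValueError(f"exactly two groups required, got {sorted(self.peaks)}")
        for group, reps in self.peaks.items():
            if len(reps) < 2:
                raise ValueError(f"group {group!r} needs >= 2 replicates, got {sorted(reps)}")
        groups = list(self.peaks)
        if self.wt_group is None:
            self.wt_group = groups[0]
        if self.ko_group is None:
            self.ko_group = groups[1] if groups[1] != self.wt_group else groups[0]
        if {self.wt_group, self.ko_group} != set(groups):
            raise ValueError(
                f"wt_group/ko_group ({self.wt_group}, {self.ko_group}) must name the two groups {groups}"
            )
        if self.universe not in ("assigned", "screened", "annotation"):
            raise ValueError(f"unknown universe choice {self.universe!r}")
        self.precedence = tuple(self.precedence)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = raw.pop("params", {})
        return cls(**{**raw, **params})


def run_pipeline(config: PipelineConfig, output: str | Path, force: bool = False) -> Path:
    """Run every stage and write the fixed output layout.

    Outputs: assignments-implied score table, per-group screened tables
    (whole-gene and exon scores), the differential exon-increased gene
    set, the Wilcoxon report, per-group region proportions, the metagene
    density table and (when a GMT is configured) the enrichment table,
    plus run.log and the SUCCESS sentinel.
    """
    outdir = Path(output)
    if (outdir / SENTINEL).exists() and not force:
        logger.info("output directory %s already complete; skipping (use force to re-run)", outdir)
        return outdir
    outdir.mkdir(parents=True, exist_ok=True)
    sentinel = outdir / SENTINEL
    if sentinel.exists():
        sentinel.unlink()
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log("pipeline parameters: " + json.dumps(dataclasses.asdict(config), sort_keys=True, default=str))

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                (outdir / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at stage {name}: {exc}\n")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- load ---------------------------------------------------------
    def _load():
        genes = mio.read_gtf(config.gtf)
        index = AnnotationIndex(genes, promoter_window=config.promoter_window)
        peaks = {
            (group, rep): mio.read_narrowpeak(path, group=group, replicate=rep)
            for group in sorted(config.peaks)
            for rep, path in sorted(config.peaks[group].items())
        }
        return genes, index, peaks

    genes, index, peaks = stage("load")(_load)
    log(f"stage load: {len(genes)} genes; " + ", ".join(f"{g}/{r}: {len(p)} peaks" for (g, r), p in peaks.items()))

    # --- score --------------------------------------------------------
    def _score():
        df = score_table(
            peaks, index,
            min_fraction=config.min_fraction, mode=config.score_mode,
            use_exon_union=config.use_exon_union,
        )
        df.to_csv(outdir / "scores.tsv", sep="\t", index=False, float_format="%.6g")
        return df

    scores = stage("score")(_score)
    log(f"stage score: {len(scores)} (gene, sample) rows over {scores['gene_id'].nunique() if len(scores) else 0} genes")

    # --- screen (whole-gene and exon scores, per group) ----------------
    def _screen():
        screened, screened_exon = {}, {}
        for group in sorted(config.peaks):
            for value, target in (("score", screened), ("exon_score", screened_exon)):
                tbl = screen_genes(
                    rep_scores_from_table(scores, group, value=value),
                    score_min=config.score_min, fc_max=config.fc_max, score_rule=config.score_rule,
                )
                target[group] = tbl
                suffix = "" if value == "score" else "_exon"
                tbl.to_csv(outdir / f"screened_{group}{suffix}.tsv", sep="\t", index=False, float_format="%.6g")
        return screened, screened_exon

    screened, screened_exon = stage("screen")(_screen)
    for group in sorted(screened):
        log(f"stage screen: group {group}: {len(screened[group])} genes (whole), {len(screened_exon[group])} genes (exon)")

    # --- compare ------------------------------------------------------
    def _compare():
        wt, ko = config.wt_group, config.ko_group
        a = screened[ko]["group_score"].to_numpy()
        b = screened[wt]["group_score"].to_numpy()
        if config.test_variant == "signed_rank":
            merged = screened[ko].merge(screened[wt], on="gene_id", suffixes=("_ko", "_wt"))
            result = wilcoxon_compare(
                merged["group_score_ko"], merged["group_score_wt"], variant="signed_rank"
            )
        else:
            result = wilcoxon_compare(a, b, variant=config.test_variant)
        report = {
            "statistic": result.statistic, "p_value": result.p_value,
            "n_ko": result.n_a, "n_wt": result.n_b,
            "variant": result.variant, "method": result.method,
        }
        (outdir / "wilcoxon.json").write_text(json.dumps(report, sort_keys=True) + "\n")

        diff = differential_table(screened_exon[wt], screened_exon[ko], include_ko_only=config.include_ko_only)
        diff.to_csv(outdir / "differential_exon.tsv", sep="\t", index=False, float_format="%.6g")
        genes_up = sorted(differential_exon_genes(screened_exon[wt], screened_exon[ko], config.include_ko_only))
        (outdir / "exon_increased_genes.txt").write_text("".join(g + "\n" for g in genes_up))
        return report, genes_up

    report, genes_up = stage("compare")(_compare)
    log(f"stage compare: {config.test_variant} p={report['p_value']:.4g} "
        f"(n_ko={report['n_ko']}, n_wt={report['n_wt']}); {len(genes_up)} exon-increased genes")

    # --- annotate: region proportions + metagene ----------------------
    def _annotate():
        rows = []
        for group in sorted(config.peaks):
            gp = [p for (g, _), ps in peaks.items() if g == group for p in ps]
            props = region_proportions(gp, index, precedence=config.precedence, promoter_window=config.promoter_window)
            rows.append({"group": group, **props})
        props_df = pd.DataFrame(rows)
        props_df.to_csv(outdir / "region_proportions.tsv", sep="\t", index=False, float_format="%.6g")
        all_peaks = [p for ps in peaks.values() for p in ps]
        _, hist = metagene_table(all_peaks, index, min_fraction=config.min_fraction)
        mg = pd.DataFrame({
            "bin_start": [i * 0.1 for i in range(len(hist))],
            "density": hist,
        })
        mg.to_csv(outdir / "metagene_density.tsv", sep="\t", index=False, float_format="%.6g")
        return props_df

    props_df = stage("annotate")(_annotate)
    for _, row in props_df.iterrows():
        log(f"stage annotate: group {row['group']}: exon proportion {row['exon']:.3f}")

    # --- enrich (optional) --------------------------------------------
    if config.gmt is not None:
        def _enrich():
            collections = mio.read_gmt(config.gmt)
            if config.universe == "annotation":
                universe = {g.gene_id for g in genes}
            elif config.universe == "screened":
                universe = set().union(*(set(t["gene_id"]) for t in screened.values()))
            else:  # assigned: any gene with a peak in any sample
                universe = set(scores["gene_id"])
            query = set(genes_up) & universe
            if not query:
                log("stage enrich: empty query after universe intersection; skipped")
                return None
            enr = hypergeom_enrich(query, collections, universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            return enr

        enr = stage("enrich")(_enrich)
        if enr is not None:
            log(f"stage enrich: {len(enr)} gene sets tested against universe '{config.universe}'")
    else:
        log("stage enrich: no GMT configured; skipped")

    (outdir / "run.log").write_text("".join(line + "\n" for line in log_lines))
    sentinel.write_text("ok\n")
    return outdir
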