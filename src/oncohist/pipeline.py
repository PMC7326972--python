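"""End-to-end orchestration of the integrative analysis.

Stages run in dependency order, each persisting its outputs as flat
files in the run directory so any stage can be re-run (or run alone)
from the persisted outputs of its prerequisites:

1. ``diff``     — differential RNA-seq and PRO-seq calls,
2. ``peaks``    — mutant-specific occupancy peaks from FLAG/H2A tracks,
3. ``annotate`` — genomic distribution vs shuffled null, ATAC
   co-localization, promoter/expression crosstab,
4. ``concord``  — RNA/PRO fold-change correlation and quadrant sets,
5. ``gsea``     — locus-wide FLAG scores, enriched genes, and the
   running-sum permutation test of the concordantly-up set,

followed by the intersection of concordantly-up and FLAG-enriched
genes and a machine-readable run summary.  The whole pipeline is a
pure function of (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    AnnotationIndex,
    atac_colocalization,
    peak_distribution_enrichment,
    promoter_expression_crosstab,
)
from .concordance import intersect_with_flag, quadrant_classify
from .differential import run_differential, up_down_sets
from .genomic_io import (
    Interval,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_counts,
    read_gene_table,
    write_bed,
)
from .locuswide import gsea_test, locus_score_table, locuswide_enriched_genes
from .occupancy import call_occupancy_peaks

__all__ = ["PipelineConfig", "run_all", "load_inputs"]


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run."""

    fixture_dir: str
    out_dir: str
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5
    bin_size: int = 100
    pc: float = 1.0
    max_gap: int = 1
    min_bins: int = 2
    promoter_up: int = 1000
    promoter_down: int = 1000
    upstream_bp: int = 1000
    n_shuffles: int = 1000
    n_perm: int = 10_000
    weight_exponent: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def load_inputs(config: PipelineConfig) -> dict:
    """Load every pipeline input from the fixture directory."""
    fx = Path(config.fixture_dir)
    required = ["chrom.sizes", "genes.tsv", "rna_counts.tsv", "pro_counts.tsv",
                "groups.json", "atac_peaks.bed"]
    for name in required:
        if not (fx / name).exists():
            raise FileNotFoundError(f"missing pipeline input: {fx / name}")
    chrom_sizes = read_chrom_sizes(fx / "chrom.sizes")
    annotation = read_gene_table(fx / "genes.tsv", chrom_sizes)
    groups = json.loads((fx / "groups.json").read_text())
    rna = read_counts(fx / "rna_counts.tsv", groups["rna"])
    pro = read_counts(fx / "pro_counts.tsv", groups["pro"])
    clones = groups["clones"]
    flag_tracks = {}
    h2a_tracks = {}
    for clone in clones:
        for role, store in (("flag", flag_tracks), ("h2a", h2a_tracks)):
            path = fx / f"{role}_{clone}.bedgraph"
            if not path.exists():
                raise FileNotFoundError(f"missing pipeline input: {path}")
            store[clone] = read_bedgraph(
                path, chrom_sizes, config.bin_size, sample_id=clone, role=role
            )
    atac = read_bed(fx / "atac_peaks.bed", chrom_sizes)
    return {
        "annotation": annotation,
        "rna": rna,
        "pro": pro,
        "clone_groups": clones,
        "flag": flag_tracks,
        "h2a": h2a_tracks,
        "atac": atac,
    }


def _write_diff(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def _peaks_to_files(peaks, out_dir: Path) -> None:
    rows = []
    intervals = []
    for i, p in enumerate(peaks):
        name = f"peak{i + 1:05d}"
        score = -10.0 * math.log10(max(p.q, 1e-300)) if np.isfinite(p.q) else 0.0
        intervals.append(
            Interval(p.interval.chrom, p.interval.start, p.interval.end,
                     name=name, score=round(score, 3))
        )
        rows.append(
            (name, p.interval.chrom, p.interval.start, p.interval.end,
             p.delta_r, p.p, p.q)
        )
    write_bed(intervals, out_dir / "g53d_peaks.bed")
    pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "delta_r", "p", "q"]
    ).to_csv(out_dir / "g53d_peaks.tsv", sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return (and persist) the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)
    annotation = inputs["annotation"]

    # 1. differential counts, both assays
    rna_res = run_differential(
        inputs["rna"], alpha=config.alpha,
        min_abs_log2fc=config.min_abs_log2fc, pseudocount=config.pseudocount,
    )
    pro_res = run_differential(
        inputs["pro"], alpha=config.alpha,
        min_abs_log2fc=config.min_abs_log2fc, pseudocount=config.pseudocount,
    )
    _write_diff(rna_res, out / "rna_diff.tsv")
    _write_diff(pro_res, out / "pro_diff.tsv")
    rna_up, rna_down = up_down_sets(rna_res)
    pro_up, pro_down = up_down_sets(pro_res)

    # 2. occupancy peaks
    peaks, windows, ratio = call_occupancy_peaks(
        inputs["flag"], inputs["h2a"], inputs["clone_groups"],
        pc=config.pc, alpha=config.alpha,
        max_gap=config.max_gap, min_bins=config.min_bins,
    )
    _peaks_to_files(peaks, out)

    # 3. genomic distribution + ATAC co-localization + crosstab
    peak_ivs = peaks.intervals()
    index = AnnotationIndex.build(annotation, config.promoter_up, config.promoter_down)
    enrich = None
    coloc = None
    if len(peak_ivs) > 0:
        enrich = peak_distribution_enrichment(
            peak_ivs, annotation,
            n_shuffles=config.n_shuffles, seed=config.seed,
            promoter_up=config.promoter_up, promoter_down=config.promoter_down,
        )
        coloc = atac_colocalization(peak_ivs, inputs["atac"], index=index)
    crosstab = promoter_expression_crosstab(
        peak_ivs, annotation, rna_up,
        promoter_up=config.promoter_up, promoter_down=config.promoter_down,
    )
    annotation_report = {
        "enrichment": None if enrich is None else {
            "categories": list(enrich.categories),
            "observed": [int(x) for x in enrich.observed],
            "expected": [float(x) for x in enrich.expected],
            "chi2": enrich.chi2,
            "df": enrich.df,
            "p": enrich.p,
            "n_shuffles": enrich.n_shuffles,
        },
        "colocalization": None if coloc is None else {
            "n_peaks": coloc.n_peaks,
            "n_colocalized": coloc.n_colocalized,
            "fraction": coloc.fraction,
            "by_category": {k: list(v) for k, v in coloc.by_category.items()},
        },
        "promoter_crosstab": crosstab,
    }
    (out / "annotation.json").write_text(json.dumps(annotation_report, indent=2))

    # 4. concordance quadrants
    conc = quadrant_classify(rna_res, pro_res)
    for name, genes in conc.quadrants.items():
        (out / f"quadrant_{name}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(genes))
        )

    # 5. locus-wide scores, enriched genes, GSEA on the concordantly-up set
    mut = [t for t in ratio.values() if t.group == "MUT"]
    wt = [t for t in ratio.values() if t.group == "WT"]
    scores = locus_score_table(annotation, mut, wt, upstream=config.upstream_bp)
    scores.to_csv(out / "locus_scores.tsv", sep="\t")
    flag_enriched, flag_table = locuswide_enriched_genes(
        annotation, mut, wt, alpha=config.alpha, upstream=config.upstream_bp
    )
    flag_table.to_csv(out / "flag_enriched.tsv", sep="\t")
    (out / "flag_enriched_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(flag_enriched))
    )
    gsea = None
    both_up = conc.quadrants["both_up"]
    if 0 < len(both_up) < len(scores):
        gsea = gsea_test(
            scores, both_up,
            n_perm=config.n_perm, seed=config.seed, weight=config.weight_exponent,
        )
        pd.DataFrame(
            {"rank": np.arange(1, len(gsea.running_sum) + 1),
             "running_sum": gsea.running_sum}
        ).to_csv(out / "gsea_running_sum.tsv", sep="\t", index=False)

    # 6. intersection of concordantly-up and FLAG-enriched genes
    inter = intersect_with_flag(
        both_up, flag_enriched, rna=rna_res, pro=pro_res, locus_scores=scores
    )
    inter.to_csv(out / "intersection.tsv", sep="\t")

    fixture = Path(config.fixture_dir)
    checksums = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(fixture.iterdir())
        if f.is_file() and f.suffix in (".tsv", ".bed", ".bedgraph", ".sizes", ".json")
    }
    summary = {
        "version": __version__,
        "config": asdict(config),
        "input_checksums": checksums,
        "rna": {"n_up": len(rna_up), "n_down": len(rna_down)},
        "pro": {"n_up": len(pro_up), "n_down": len(pro_down)},
        "peaks": {"n_specific": len(peaks)},
        "annotation": annotation_report,
        "concordance": {
            "pearson_r": conc.pearson_r,
            "p_r": conc.p_r,
            "n_shared": conc.n_shared,
            "quadrant_sizes": {k: len(v) for k, v in conc.quadrants.items()},
        },
        "locuswide": {
            "n_flag_enriched": len(flag_enriched),
            "es": None if gsea is None else gsea.es,
            "p_perm": None if gsea is None else gsea.p_perm,
            "n_perm": None if gsea is None else gsea.n_perm,
        },
        "intersection": {"n": len(inter), "genes": list(inter.index)},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
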