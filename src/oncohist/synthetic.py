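"""Synthetic study generator with planted ground truth.

Emulates the experimental design the pipeline targets: two wild-type and
two mutant-histone knock-in clones, RNA-seq in duplicate per clone,
PRO-seq one library per clone, and per-clone FLAG / H2A CUT&RUN coverage
tracks plus ATAC open-chromatin peaks.  A configurable fraction of genes
is planted as transcriptionally up- or downregulated in the mutant, and
a subset of the up-genes additionally receives locus-wide FLAG
enrichment (mutant clones only) over the window from 1 kb upstream of
the TSS to the TES — the ground truth every downstream stage is tested
against.

Counts follow a negative binomial with a single shared dispersion
(gamma–Poisson sampling, so the Poisson limit is exact as the dispersion
approaches zero).  Clone-to-clone biological variability is a per-clone
log-normal scale factor.  Tracks are emitted pre-binned: the pipeline's
unit of computation is the bin, so read-level simulation is deliberately
out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    BinnedTrack,
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    Interval,
    n_bins,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_counts,
    write_gene_table,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlacementError",
    "generate_genome",
    "plant_truth",
    "simulate_counts",
    "simulate_tracks",
    "write_fixture",
]


class PlacementError(RuntimeError):
    """Non-overlapping gene placement failed within the retry budget."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (1000, 5000)
    n_samples_per_group: int = 2  # clones per genotype
    rna_repeats: int = 2  # RNA-seq libraries per clone
    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.05
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_log2fc: float = 2.0
    frac_flag_enriched_of_up: float = 0.4
    flag_enrichment_log2: float = 3.0
    bin_size: int = 100
    h2a_mean_per_bin: float = 20.0
    flag_mean_per_bin: float = 20.0
    clone_sigma: float = 0.1
    n_background_atac: int = 200
    atac_halfwidth: int = 250
    upstream_bp: int = 1000
    depth_factors: tuple[float, ...] | None = None  # per clone, default all 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_genes, self.n_samples_per_group) < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if not (0 <= self.frac_flag_enriched_of_up <= 1):
            raise ValueError("frac_flag_enriched_of_up must lie in [0, 1]")
        if self.gene_length_range[1] >= self.chromosome_length:
            raise ValueError("max gene length must be < chromosome length")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def clone_names(self) -> dict[str, list[str]]:
        n = self.n_samples_per_group
        return {
            "WT": [f"WT{i + 1}" for i in range(n)],
            "MUT": [f"G53D{i + 1}" for i in range(n)],
        }


@dataclass
class GroundTruth:
    """Planted truth: which genes move, and where the mutant histone sits."""

    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)
    flag_genes: set[str] = field(default_factory=set)
    planted_peak_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")
        if not self.flag_genes <= self.up_genes:
            raise ValueError("flag_genes must be a subset of up_genes")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    mix = hashlib.sha256(f"{config.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(mix[:8], "little"))


def generate_genome(config: SimConfig) -> GenomeAnnotation:
    """Place non-overlapping, strand-assigned genes uniformly on the genome."""
    rng = _rng(config, "genome")
    chrom_sizes = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    chroms = sorted(chrom_sizes)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    max_retries = 200
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        placed = False
        for _ in range(max_retries):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            end = start + length
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    interval=Interval(chrom, start, end),
                    strand=strand,
                    gene_id=f"gene{i + 1:05d}",
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place gene {i + 1} of {config.n_genes} "
                f"after {max_retries} retries; genome too crowded"
            )
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def _isolated_gene_ids(annotation: GenomeAnnotation, upstream: int) -> set[str]:
    """Genes whose locus window overlaps no other gene's locus window.

    Planting locus-wide FLAG enrichment at a non-isolated gene would
    spill signal into a neighbor's window and make the planted truth
    ambiguous, so only isolated genes are eligible as FLAG targets.
    """
    windows = sorted(
        (
            g.locus_window(upstream, annotation.chrom_sizes[g.chrom])
            for g in annotation.genes
        ),
        key=lambda iv: (iv.chrom, iv.start),
    )
    isolated: set[str] = set()
    for i, w in enumerate(windows):
        prev_ok = (
            i == 0
            or windows[i - 1].chrom != w.chrom
            or windows[i - 1].end <= w.start
        )
        next_ok = (
            i == len(windows) - 1
            or windows[i + 1].chrom != w.chrom
            or w.end <= windows[i + 1].start
        )
        if prev_ok and next_ok:
            isolated.add(w.name)
    return isolated


def plant_truth(annotation: GenomeAnnotation, config: SimConfig) -> GroundTruth:
    """Draw disjoint planted up/down gene sets and the FLAG-enriched subset.

    FLAG targets are sampled from the up-genes whose locus windows are
    isolated from every other gene's window, so each planted enrichment
    interval is attributable to exactly one gene.
    """
    rng = _rng(config, "truth")
    ids = np.array(annotation.gene_ids)
    n_up = int(round(config.frac_up * len(ids)))
    n_down = int(round(config.frac_down * len(ids)))
    chosen = rng.choice(len(ids), size=n_up + n_down, replace=False)
    up = set(ids[chosen[:n_up]])
    down = set(ids[chosen[n_up:]])
    n_flag = int(round(config.frac_flag_enriched_of_up * n_up))
    flag: set[str] = set()
    if n_flag:
        eligible = sorted(up & _isolated_gene_ids(annotation, config.upstream_bp))
        if len(eligible) < n_flag:
            raise PlacementError(
                f"only {len(eligible)} isolated up-genes available for "
                f"{n_flag} FLAG targets; lower gene density or frac_flag_enriched_of_up"
            )
        flag = set(
            np.array(eligible)[rng.choice(len(eligible), size=n_flag, replace=False)]
        )
    windows = [
        g.locus_window(config.upstream_bp, annotation.chrom_sizes[g.chrom])
        for g in annotation.genes
        if g.gene_id in flag
    ]
    windows.sort(key=lambda iv: (iv.chrom, iv.start))
    return GroundTruth(
        up_genes=up,
        down_genes=down,
        flag_genes=flag,
        planted_peak_intervals=windows,
    )


def _gamma_poisson(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, alpha) draws via gamma-Poisson mixing; exact Poisson limit."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimConfig,
    assay: str,
) -> CountMatrix:
    """Negative-binomial count matrix for one assay.

    ``assay='rna'`` yields ``rna_repeats`` columns per clone;
    ``assay='pro'`` yields one column per clone.  Planted genes have
    their mean multiplied by ``2**(+-effect_log2fc)`` in mutant samples.
    """
    if assay not in ("rna", "pro"):
        raise ValueError(f"unknown assay {assay!r}; expected 'rna' or 'pro'")
    known = set(annotation.gene_ids)
    for s in (truth.up_genes, truth.down_genes, truth.flag_genes):
        if not s <= known:
            raise ValueError("ground-truth gene ids not all present in annotation")
    rng = _rng(config, f"counts:{assay}")
    ids = annotation.gene_ids
    n_genes = len(ids)
    base = np.exp(
        rng.uniform(
            np.log(config.nb_mean_range[0]),
            np.log(config.nb_mean_range[1]),
            size=n_genes,
        )
    )
    effect = np.ones(n_genes)
    up_mask = np.isin(ids, sorted(truth.up_genes))
    down_mask = np.isin(ids, sorted(truth.down_genes))
    effect[up_mask] = 2.0**config.effect_log2fc
    effect[down_mask] = 2.0**-config.effect_log2fc

    clone_names = config.clone_names
    n_clones_total = 2 * config.n_samples_per_group
    clone_factors = np.exp(
        rng.normal(0.0, config.clone_sigma, size=n_clones_total)
    )
    depth = (
        np.asarray(config.depth_factors, dtype=float)
        if config.depth_factors is not None
        else np.ones(n_clones_total)
    )
    repeats = config.rna_repeats if assay == "rna" else 1

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    clone_idx = 0
    for group in ("WT", "MUT"):
        for clone in clone_names[group]:
            mu_clone = base * clone_factors[clone_idx] * depth[clone_idx]
            if group == "MUT":
                mu_clone = mu_clone * effect
            for rep in range(repeats):
                label = f"{clone}_rep{rep + 1}" if assay == "rna" else clone
                cols[label] = _gamma_poisson(rng, mu_clone, config.nb_dispersion)
                groups[label] = group
            clone_idx += 1
    df = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    return CountMatrix(counts=df, groups=groups)


def simulate_tracks(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimConfig,
) -> dict:
    """Per-clone FLAG and H2A binned tracks plus ATAC peaks.

    H2A is Poisson baseline everywhere.  FLAG is Poisson baseline
    multiplied by ``2**flag_enrichment_log2`` over the locus window of
    each planted FLAG gene — in mutant clones only.  ATAC peaks sit at
    every promoter plus a background set of random open regions.
    """
    rng = _rng(config, "tracks")
    bs = config.bin_size
    chroms = sorted(annotation.chrom_sizes)
    clone_names = config.clone_names
    n_clones_total = 2 * config.n_samples_per_group
    clone_factors = np.exp(rng.normal(0.0, config.clone_sigma, size=n_clones_total))
    depth = (
        np.asarray(config.depth_factors, dtype=float)
        if config.depth_factors is not None
        else np.ones(n_clones_total)
    )

    # per-bin FLAG enrichment multiplier for mutant clones
    enrich: dict[str, np.ndarray] = {
        c: np.ones(n_bins(annotation.chrom_sizes[c], bs)) for c in chroms
    }
    for iv in truth.planted_peak_intervals:
        first = iv.start // bs
        last = (iv.end - 1) // bs
        enrich[iv.chrom][first : last + 1] = 2.0**config.flag_enrichment_log2

    flag: dict[str, BinnedTrack] = {}
    h2a: dict[str, BinnedTrack] = {}
    clone_idx = 0
    for group in ("WT", "MUT"):
        for clone in clone_names[group]:
            scale = clone_factors[clone_idx] * depth[clone_idx]
            h2a_vals = {}
            flag_vals = {}
            for c in chroms:
                nb = n_bins(annotation.chrom_sizes[c], bs)
                widths = np.full(nb, bs, dtype=float)
                widths[-1] = annotation.chrom_sizes[c] - (nb - 1) * bs
                wfrac = widths / bs
                h2a_vals[c] = rng.poisson(
                    config.h2a_mean_per_bin * scale * wfrac
                ).astype(float)
                mult = enrich[c] if group == "MUT" else 1.0
                flag_vals[c] = rng.poisson(
                    config.flag_mean_per_bin * scale * wfrac * mult
                ).astype(float)
            h2a[clone] = BinnedTrack(
                bin_size=bs,
                chrom_sizes=dict(annotation.chrom_sizes),
                values=h2a_vals,
                sample_id=clone,
                role="h2a",
            )
            flag[clone] = BinnedTrack(
                bin_size=bs,
                chrom_sizes=dict(annotation.chrom_sizes),
                values=flag_vals,
                sample_id=clone,
                role="flag",
            )
            clone_idx += 1

    atac: list[Interval] = []
    for g in annotation.genes:
        win = g.promoter_window(
            config.atac_halfwidth,
            config.atac_halfwidth,
            annotation.chrom_sizes[g.chrom],
        )
        atac.append(Interval(win.chrom, win.start, win.end, name=f"atac_{g.gene_id}"))
    for i in range(config.n_background_atac):
        c = chroms[rng.integers(len(chroms))]
        width = 2 * config.atac_halfwidth
        s = int(rng.integers(0, annotation.chrom_sizes[c] - width))
        atac.append(Interval(c, s, s + width, name=f"atac_bg{i + 1}"))
    atac.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return {"flag": flag, "h2a": h2a, "atac": atac}


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate a complete study and write it to disk with a manifest.

    Emits the gene table, chrom sizes, RNA and PRO count tables, one
    FLAG and one H2A bedGraph per clone, the ATAC BED, a ground-truth
    TSV, sample group labels, and a JSON manifest with SHA-256 checksums
    of every file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_genome(config)
    truth = plant_truth(annotation, config)
    rna = simulate_counts(annotation, truth, config, "rna")
    pro = simulate_counts(annotation, truth, config, "pro")
    tracks = simulate_tracks(annotation, truth, config)

    files: dict[str, Path] = {}
    files["genes"] = out / "genes.tsv"
    write_gene_table(annotation, files["genes"])
    files["chrom_sizes"] = out / "chrom.sizes"
    write_chrom_sizes(annotation.chrom_sizes, files["chrom_sizes"])
    files["rna_counts"] = out / "rna_counts.tsv"
    write_counts(rna, files["rna_counts"])
    files["pro_counts"] = out / "pro_counts.tsv"
    write_counts(pro, files["pro_counts"])
    for role, per_clone in (("flag", tracks["flag"]), ("h2a", tracks["h2a"])):
        for clone, track in per_clone.items():
            key = f"{role}_{clone}"
            files[key] = out / f"{role}_{clone}.bedgraph"
            write_bedgraph(track, files[key])
    files["atac"] = out / "atac_peaks.bed"
    write_bed(tracks["atac"], files["atac"])

    files["truth"] = out / "ground_truth.tsv"
    rows = (
        [("up", g) for g in sorted(truth.up_genes)]
        + [("down", g) for g in sorted(truth.down_genes)]
        + [("flag", g) for g in sorted(truth.flag_genes)]
    )
    pd.DataFrame(rows, columns=["role", "gene_id"]).to_csv(
        files["truth"], sep="\t", index=False
    )
    files["planted_peaks"] = out / "planted_peaks.bed"
    write_bed(truth.planted_peak_intervals, files["planted_peaks"])

    groups = {s: rna.groups[s] for s in rna.sample_ids}
    groups.update({s: pro.groups[s] for s in pro.sample_ids})
    clone_groups = {
        clone: grp for grp, names in config.clone_names.items() for clone in names
    }
    files["groups"] = out / "groups.json"
    files["groups"].write_text(
        json.dumps(
            {"rna": rna.groups, "pro": pro.groups, "clones": clone_groups}, indent=2
        )
    )

    manifest = {
        "config": asdict(config),
        "files": {
            key: {
                "path": path.name,
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for key, path in sorted(files.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        up_genes=set(df.loc[df["role"] == "up", "gene_id"]),
        down_genes=set(df.loc[df["role"] == "down", "gene_id"]),
        flag_genes=set(df.loc[df["role"] == "flag", "gene_id"]),
    )
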