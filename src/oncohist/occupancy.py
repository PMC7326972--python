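"""Mutant-histone occupancy mapping from FLAG CUT&RUN with an H2A internal control.

The FLAG track reports where the tagged mutant histone sits; the H2A
track from the same cells controls for chromatin accessibility,
nucleosome density and library depth.  Each sample is reduced to a
per-bin normalized log-ratio

    r = log2( (flag_c / F + pc / n) / (h2a_c / H + pc / n) )

where ``flag_c``/``h2a_c`` are bin counts, ``F``/``H`` the sample's
library totals, ``n`` the genome-wide bin count and ``pc`` a pseudocount
expressed in units of the sample's mean bin count (default 1).  Writing
the pseudocount on the depth-normalized scale makes ``r`` exactly
invariant to rescaling a sample's tracks by any constant.

Mutant-specific peaks are called by a per-bin two-sample comparison of
``r`` between mutant and wild-type clones.  With two clones per group a
raw per-bin variance is hopeless, so the pooled within-group variance is
moderated by averaging over all bins in the same coverage decile before
forming a z statistic; significant bins are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_io import BinnedTrack, Interval
from .differential import bh_adjust

__all__ = [
    "NormalizedRatioTrack",
    "Peak",
    "PeakSet",
    "normalize_internal_control",
    "differential_windows",
    "merge_windows",
    "g53d_specific_peaks",
    "call_occupancy_peaks",
]


@dataclass
class NormalizedRatioTrack:
    """Per-bin log2 FLAG/H2A ratio for one sample, plus a coverage track.

    ``coverage`` holds the mean depth-normalized FLAG+H2A signal per bin
    (library-fraction scale); it drives the variance-moderation deciles.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    r: dict[str, np.ndarray]
    coverage: dict[str, np.ndarray]
    sample_id: str = ""
    group: str = ""

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_sizes)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.r[c] for c in self.chroms])

    def concat_coverage(self) -> np.ndarray:
        return np.concatenate([self.coverage[c] for c in self.chroms])


@dataclass(frozen=True)
class Peak:
    interval: Interval
    delta_r: float
    p: float
    q: float = float("nan")


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.interval.chrom, p.interval.start))
        )


def normalize_internal_control(
    flag: BinnedTrack,
    h2a: BinnedTrack,
    pc: float = 1.0,
    group: str = "",
) -> NormalizedRatioTrack:
    """Depth-normalized log2 FLAG/H2A ratio per bin.

    Library totals are computed from the tracks themselves.  ``pc`` is
    the pseudocount in mean-bin-count units (``pc=1`` behaves like adding
    one average-coverage count to both tracks).
    """
    if flag.bin_size != h2a.bin_size or flag.chrom_sizes != h2a.chrom_sizes:
        raise ValueError("FLAG and H2A tracks must share bin grid and chromosomes")
    if pc <= 0:
        raise ValueError("pseudocount must be > 0")
    total_bins = sum(len(v) for v in flag.values.values())
    F = flag.total()
    H = h2a.total()
    if F <= 0 or H <= 0:
        raise ValueError("track with zero total signal cannot be normalized")
    eps = pc / total_bins
    r: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    for c in flag.chrom_sizes:
        fmass = flag.values[c] / F
        hmass = h2a.values[c] / H
        r[c] = np.log2((fmass + eps) / (hmass + eps))
        cov[c] = 0.5 * (fmass + hmass)
    return NormalizedRatioTrack(
        bin_size=flag.bin_size,
        chrom_sizes=dict(flag.chrom_sizes),
        r=r,
        coverage=cov,
        sample_id=flag.sample_id,
        group=group,
    )


def _check_grids(tracks: list[NormalizedRatioTrack]) -> None:
    ref = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != ref.bin_size or t.chrom_sizes != ref.chrom_sizes:
            raise ValueError("ratio tracks must share bin grid and chromosomes")


def differential_windows(
    mut: list[NormalizedRatioTrack],
    wt: list[NormalizedRatioTrack],
    n_deciles: int = 10,
) -> dict[str, np.ndarray]:
    """Per-bin mutant-minus-WT ratio difference with a moderated z test.

    Returns arrays over the concatenated bin axis (chromosomes in sorted
    order): ``delta_r``, ``p``, ``q``, plus bookkeeping ``chrom_index``
    and ``bin_index`` to map back to coordinates.
    """
    if len(mut) < 2 or len(wt) < 2:
        raise ValueError("need >= 2 samples per group")
    _check_grids(mut + wt)
    M = np.stack([t.concat() for t in mut])
    W = np.stack([t.concat() for t in wt])
    cov = np.mean([t.concat_coverage() for t in mut + wt], axis=0)

    delta = M.mean(axis=0) - W.mean(axis=0)
    n1, n2 = M.shape[0], W.shape[0]
    ss = ((M - M.mean(axis=0)) ** 2).sum(axis=0) + ((W - W.mean(axis=0)) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    s2 = ss / df

    # moderate: replace per-bin s2 by its mean within the bin's coverage decile
    order = np.argsort(cov, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(cov))
    decile = np.minimum((ranks * n_deciles) // len(cov), n_deciles - 1)
    s2_mod = np.empty_like(s2)
    for d in range(n_deciles):
        mask = decile == d
        if mask.any():
            s2_mod[mask] = s2[mask].mean()
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)

    ref = mut[0]
    chrom_index = np.concatenate(
        [np.full(len(ref.r[c]), i) for i, c in enumerate(ref.chroms)]
    )
    bin_index = np.concatenate([np.arange(len(ref.r[c])) for c in ref.chroms])
    return {
        "chroms": ref.chroms,
        "bin_size": ref.bin_size,
        "chrom_sizes": ref.chrom_sizes,
        "chrom_index": chrom_index,
        "bin_index": bin_index,
        "delta_r": delta,
        "p": p,
        "q": q,
    }


def merge_windows(
    windows: dict,
    significant: np.ndarray,
    max_gap: int = 1,
    min_bins: int = 2,
) -> PeakSet:
    """Merge runs of significant bins into peaks.

    Consecutive significant bins separated by at most ``max_gap``
    non-significant bins are merged; merged runs spanning fewer than
    ``min_bins`` significant bins are dropped.  Per-peak ``delta_r`` is
    the width-weighted mean over member bins, per-peak p the Fisher
    combination of member-bin p-values.  Peak q-values are BH across the
    returned peaks.
    """
    chroms = windows["chroms"]
    bs = windows["bin_size"]
    sizes = windows["chrom_sizes"]
    significant = np.asarray(significant, dtype=bool)
    peaks: list[Peak] = []
    for ci, chrom in enumerate(chroms):
        sel = windows["chrom_index"] == ci
        sig = significant[sel]
        delta = windows["delta_r"][sel]
        pvals = windows["p"][sel]
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for b in idx[1:]:
            if b - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(b)
            else:
                runs.append([b])
        for run in runs:
            if len(run) < min_bins:
                continue
            first, last = run[0], run[-1]
            member = np.arange(first, last + 1)
            start = int(first * bs)
            end = int(min((last + 1) * bs, sizes[chrom]))
            widths = np.minimum((member + 1) * bs, sizes[chrom]) - member * bs
            dr = float(np.average(delta[member], weights=widths))
            pm = np.clip(pvals[member], 1e-300, 1.0)
            x = -2.0 * np.log(pm).sum()
            p_comb = float(stats.chi2.sf(x, 2 * len(member)))
            peaks.append(Peak(Interval(chrom, start, end), delta_r=dr, p=p_comb))
    if peaks:
        qs = bh_adjust([p.p for p in peaks])
        peaks = [
            Peak(p.interval, p.delta_r, p.p, q=float(q)) for p, q in zip(peaks, qs)
        ]
    return PeakSet(peaks).sorted()


def g53d_specific_peaks(peaks: PeakSet, alpha: float = 0.05) -> PeakSet:
    """Retain mutant-elevated significant peaks (delta_r > 0, q < alpha)."""
    kept = [p for p in peaks if p.delta_r > 0 and (p.q < alpha or alpha >= 1.0)]
    return PeakSet(kept).sorted()


def call_occupancy_peaks(
    flag_tracks: dict[str, BinnedTrack],
    h2a_tracks: dict[str, BinnedTrack],
    clone_groups: dict[str, str],
    pc: float = 1.0,
    alpha: float = 0.05,
    max_gap: int = 1,
    min_bins: int = 2,
) -> tuple[PeakSet, dict, dict[str, NormalizedRatioTrack]]:
    """End-to-end occupancy stage: normalize, test bins, merge, filter.

    Returns the mutant-specific peak set, the per-bin differential
    arrays, and the per-sample normalized ratio tracks.
    """
    ratio: dict[str, NormalizedRatioTrack] = {}
    for clone, flag in flag_tracks.items():
        ratio[clone] = normalize_internal_control(
            flag, h2a_tracks[clone], pc=pc, group=clone_groups[clone]
        )
    mut = [t for t in ratio.values() if t.group == "MUT"]
    wt = [t for t in ratio.values() if t.group == "WT"]
    windows = differential_windows(mut, wt)
    merged = merge_windows(
        windows, windows["q"] < alpha, max_gap=max_gap, min_bins=min_bins
    )
    specific = g53d_specific_peaks(merged, alpha=alpha)
    return specific, windows, ratio
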