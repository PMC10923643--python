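"""Metagene methylation profiles and DMR density around genes.

Metagene profiles pool weighted methylation over a 2-kb upstream flank,
the proportionally scaled feature body (TSS..TES), and a 2-kb downstream
flank.  Minus-strand features are reversed so bin 0 is always the 5'-most
position; bin levels pool read counts across all contributing features, so
the profile of a pooled feature set is exactly the count-weighted
combination of subset profiles.

DMR density profiles count DMR midpoints per position bin around TSS and
TES and compare the total against a permutation background of
length-matched regions placed uniformly on the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome_io import GeneModel

__all__ = ["MetaProfile", "DensityProfile", "compute_metaprofile", "dmr_density_vs_random"]


@dataclass
class MetaProfile:
    """Binned weighted-methylation curve: upstream flank, body, downstream flank."""

    context: str
    n_bins_flank: int
    n_bins_body: int
    bin_levels: np.ndarray   # NaN where a bin has zero read coverage
    bin_c: np.ndarray        # pooled methylated reads per bin
    bin_n: np.ndarray        # pooled covering reads per bin
    n_features: int
    n_skipped: int           # features shorter than n_bins_body bp

    @property
    def n_bins(self) -> int:
        return 2 * self.n_bins_flank + self.n_bins_body

    def to_frame(self) -> pd.DataFrame:
        nf, nb = self.n_bins_flank, self.n_bins_body
        segment = (["upstream"] * nf) + (["body"] * nb) + (["downstream"] * nf)
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "segment": segment,
                "level": self.bin_levels,
                "c_count": self.bin_c,
                "total_count": self.bin_n,
            }
        )


def _feature_bins(
    pos0: np.ndarray, feat: GeneModel, flank: int, nf: int, nb: int
) -> tuple[np.ndarray, np.ndarray]:
    """Map 0-based positions on the feature's chromosome to profile bins.

    Returns (selector mask, bin index) computed in plus-strand geometry and
    reflected for minus-strand features.
    """
    start, end = feat.start, feat.end
    total = 2 * nf + nb
    bins = np.full(pos0.shape, -1, dtype=np.int64)

    up = (pos0 >= start - flank) & (pos0 < start)
    bins[up] = (pos0[up] - (start - flank)) * nf // flank
    body = (pos0 >= start) & (pos0 < end)
    bins[body] = nf + (pos0[body] - start) * nb // (end - start)
    down = (pos0 >= end) & (pos0 < end + flank)
    bins[down] = nf + nb + (pos0[down] - end) * nf // flank

    sel = bins >= 0
    if feat.strand == "-":
        bins[sel] = total - 1 - bins[sel]
    return sel, bins


def compute_metaprofile(
    features: Sequence[GeneModel],
    records: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_bins_flank: int = 20,
    n_bins_body: int = 40,
) -> MetaProfile:
    """Pooled metagene profile of one context over gene/TE features.

    Each feature's upstream 2 kb, body, and downstream 2 kb are divided into
    ``n_bins_flank``/``n_bins_body``/``n_bins_flank`` bins (body bins scale
    with feature length); cytosine read counts are pooled per bin across all
    features.  Features shorter than ``n_bins_body`` bp are skipped and
    counted in ``n_skipped``.
    """
    if len(features) == 0:
        raise ValueError("no features supplied")
    total = 2 * n_bins_flank + n_bins_body
    bin_c = np.zeros(total, dtype=np.int64)
    bin_n = np.zeros(total, dtype=np.int64)

    sub = records[records["context"] == context]
    by_chrom = {
        chrom: (
            grp["pos"].to_numpy() - 1,
            grp["c_count"].to_numpy(),
            grp["total_count"].to_numpy(),
        )
        for chrom, grp in sub.groupby("chrom")
    }
    n_used = n_skipped = 0
    for feat in features:
        if feat.end - feat.start < n_bins_body:
            n_skipped += 1
            continue
        n_used += 1
        if feat.chrom not in by_chrom:
            continue
        pos0, c, n = by_chrom[feat.chrom]
        lo = np.searchsorted(pos0, feat.start - flank, side="left")
        hi = np.searchsorted(pos0, feat.end + flank, side="left")
        if hi <= lo:
            continue
        sel, bins = _feature_bins(pos0[lo:hi], feat, flank, n_bins_flank, n_bins_body)
        np.add.at(bin_c, bins[sel], c[lo:hi][sel])
        np.add.at(bin_n, bins[sel], n[lo:hi][sel])

    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(bin_n > 0, bin_c / np.where(bin_n > 0, bin_n, 1), np.nan)
    return MetaProfile(
        context=context, n_bins_flank=n_bins_flank, n_bins_body=n_bins_body,
        bin_levels=levels, bin_c=bin_c, bin_n=bin_n,
        n_features=n_used, n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# DMR density vs random background
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """DMR midpoint density around TSS/TES against a permutation background.

    ``observed_density`` holds DMRs per feature per kb in position bins
    spanning TSS-flank..TSS+flank followed by TES-flank..TES+flank (5'->3'
    in feature orientation).  ``empirical_p`` is the one-sided enrichment
    p of the total anchored DMR count, (1 + #{perm >= observed})/(1 + n_perm).
    """

    observed_density: np.ndarray
    background_mean: np.ndarray
    background_sd: np.ndarray
    observed_total: int
    empirical_p: float
    n_permutations: int
    seed: int
    bin_width: int
    flank: int
    bin_offsets: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        nb = len(self.observed_density) // 2
        anchor = ["TSS"] * nb + ["TES"] * nb
        return pd.DataFrame(
            {
                "anchor": anchor,
                "offset_bp": np.concatenate([self.bin_offsets, self.bin_offsets]),
                "density": self.observed_density,
                "background_mean": self.background_mean,
                "background_sd": self.background_sd,
            }
        )


def _anchored_counts(
    mids_by_chrom: dict[str, np.ndarray],
    features: Sequence[GeneModel],
    flank: int,
    bin_width: int,
) -> tuple[np.ndarray, int]:
    """Histogram of midpoints in TSS+-flank and TES+-flank, 5'-oriented."""
    nb = (2 * flank) // bin_width
    counts = np.zeros(2 * nb, dtype=np.int64)
    total = 0
    for feat in features:
        mids = mids_by_chrom.get(feat.chrom)
        if mids is None or mids.size == 0:
            continue
        if feat.strand == "+":
            anchors = ((feat.start, 0), (feat.end, nb))
            sign = 1
        else:
            anchors = ((feat.end, 0), (feat.start, nb))
            sign = -1
        for anchor, base in anchors:
            lo = np.searchsorted(mids, anchor - flank, side="left")
            hi = np.searchsorted(mids, anchor + flank, side="left")
            if hi <= lo:
                continue
            d = (mids[lo:hi] - anchor) * sign
            b = (d + flank) // bin_width
            b = b[(b >= 0) & (b < nb)]
            np.add.at(counts, base + b, 1)
            total += b.size
    return counts, total


def dmr_density_vs_random(
    dmrs: pd.DataFrame,
    features: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    flank: int = 2000,
    bin_width: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
    exclude=(),
) -> DensityProfile:
    """Observed DMR density around TSS/TES vs uniformly placed random regions.

    Each permutation places one length-matched region per DMR uniformly at
    random on the genome (chromosomes in ``exclude``, e.g. the spike-in
    control, are never used) and recomputes the same anchored midpoint
    counts.  Densities are normalized per feature per kb.
    """
    if len(features) == 0:
        raise ValueError("no features supplied")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100 gives a coarse empirical p",
            stacklevel=2,
        )
    chroms = [c for c in sorted(chrom_sizes) if c not in exclude]
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if len(chroms) == 0:
        raise ValueError("no chromosomes left after exclusion")

    norm = len(features) * (bin_width / 1000.0)
    nb = (2 * flank) // bin_width

    if len(dmrs):
        mids = ((dmrs["start"].to_numpy() + dmrs["end"].to_numpy()) // 2).astype(np.int64)
        dmr_chroms = dmrs["chrom"].to_numpy()
        mids_by_chrom = {
            c: np.sort(mids[dmr_chroms == c]) for c in np.unique(dmr_chroms)
        }
        dmr_lengths = (dmrs["end"].to_numpy() - dmrs["start"].to_numpy()).astype(np.int64)
    else:
        mids_by_chrom = {}
        dmr_lengths = np.array([], dtype=np.int64)

    obs_counts, obs_total = _anchored_counts(mids_by_chrom, features, flank, bin_width)

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((n_permutations, 2 * nb), dtype=np.int64)
    perm_totals = np.zeros(n_permutations, dtype=np.int64)
    if len(dmr_lengths):
        probs = lengths / lengths.sum()
        for k in range(n_permutations):
            ci = rng.choice(len(chroms), size=len(dmr_lengths), p=probs)
            span = np.maximum(lengths[ci] - dmr_lengths, 1)
            starts = (rng.random(len(dmr_lengths)) * span).astype(np.int64)
            pm = starts + dmr_lengths // 2
            pm_by_chrom = {
                chroms[j]: np.sort(pm[ci == j]) for j in np.unique(ci)
            }
            perm_counts[k], perm_totals[k] = _anchored_counts(
                pm_by_chrom, features, flank, bin_width
            )
    empirical_p = (1 + int((perm_totals >= obs_total).sum())) / (1 + n_permutations)
    if len(dmr_lengths) == 0:
        empirical_p = 1.0

    offsets = -flank + bin_width * np.arange(nb) + bin_width // 2
    return DensityProfile(
        observed_density=obs_counts / norm,
        background_mean=perm_counts.mean(axis=0) / norm,
        background_sd=perm_counts.std(axis=0) / norm,
        observed_total=int(obs_total),
        empirical_p=float(empirical_p),
        n_permutations=n_permutations,
        seed=seed,
        bin_width=bin_width,
        flank=flank,
        bin_offsets=offsets,
    )
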