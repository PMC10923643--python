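"""Linking differential methylation to differential expression.

DEGs are thresholded from supplied per-gene statistics (|log2FC| > 2 and
adjusted p < 0.05, strict inequalities); the differential-expression model
itself is fit upstream.  A DMG (differentially methylated gene) is a gene
whose body or +-2 kb flanks intersect at least one DMR by any base-pair
overlap.  DEG-DMG enrichment uses the one-sided upper-tail hypergeometric
test: draw the DEGs from a universe of all annotated genes in which the
DMGs are the successes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .methylome_io import GeneModel

LOG2FC_THRESHOLD = 2.0
ADJ_P_THRESHOLD = 0.05

REGIONS = ("promoter_flank", "body", "downstream_flank")


def classify_degs(
    stats_table: pd.DataFrame,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    adj_p_threshold: float = ADJ_P_THRESHOLD,
) -> pd.DataFrame:
    """Label each gene up/down/ns from supplied expression statistics.

    Expects columns ``gene_id``, ``log2_fc``, ``adj_p`` (plus an optional
    ``comparison`` column; gene ids must be unique within a comparison).
    Boundary values (|log2FC| exactly at the threshold, adj_p exactly at
    alpha) are ``ns``: the inequalities are strict.
    """
    df = stats_table.copy()
    for col in ("gene_id", "log2_fc", "adj_p"):
        if col not in df.columns:
            raise ValueError(f"statistics table missing column {col!r}")
    if not np.isfinite(df["log2_fc"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite log2_fc")
    p = df["adj_p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("adj_p must lie in [0,1]")
    keys = ["comparison", "gene_id"] if "comparison" in df.columns else ["gene_id"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate gene ids: {sorted(df.loc[dup, 'gene_id'].unique())[:5]}")

    fc = df["log2_fc"].to_numpy(dtype=float)
    sig = p < adj_p_threshold
    df["direction"] = np.select(
        [sig & (fc > log2fc_threshold), sig & (fc < -log2fc_threshold)],
        ["up", "down"],
        default="ns",
    )
    return df


@dataclass
class DmgAnnotationResult:
    """Per-gene DMG status plus the long (gene x DMR) overlap detail."""

    per_gene: pd.DataFrame  # gene_id, is_dmg, n_dmrs, regions_hit
    detail: pd.DataFrame    # gene_id, dmr index columns, context, direction, delta, region
    flank: int

    @property
    def dmg_ids(self) -> list[str]:
        return self.per_gene.loc[self.per_gene["is_dmg"], "gene_id"].tolist()


def _gene_regions(gene: GeneModel, flank: int, chrom_len: int | None):
    """Strand-aware promoter/body/downstream intervals, clipped to bounds."""
    if gene.strand == "+":
        regions = {
            "promoter_flank": (gene.start - flank, gene.start),
            "body": (gene.start, gene.end),
            "downstream_flank": (gene.end, gene.end + flank),
        }
    else:
        regions = {
            "promoter_flank": (gene.end, gene.end + flank),
            "body": (gene.start, gene.end),
            "downstream_flank": (gene.start - flank, gene.start),
        }
    out = {}
    for name, (s, e) in regions.items():
        s = max(s, 0)
        if chrom_len is not None:
            e = min(e, chrom_len)
        if s < e:
            out[name] = (s, e)
    return out


def annotate_dmgs(
    genes: Sequence[GeneModel],
    dmrs: pd.DataFrame,
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> DmgAnnotationResult:
    """Intersect gene +-flank intervals with DMRs (any-bp overlap rule).

    ``regions_hit`` records which of promoter flank (2 kb 5' of the TSS,
    strand-aware), body, and downstream flank each overlapping DMR touches;
    a DMR crossing a boundary counts for every region it overlaps.
    """
    trees: dict[str, IntervalTree] = {}
    for i in range(len(dmrs)):
        row = dmrs.iloc[i]
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]), i
        )

    gene_rows, detail_rows = [], []
    for gene in genes:
        chrom_len = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        tree = trees.get(gene.chrom)
        hit_dmrs: set[int] = set()
        regions_hit: set[str] = set()
        if tree is not None:
            for name, (s, e) in _gene_regions(gene, flank, chrom_len).items():
                for iv in tree.overlap(s, e):
                    hit_dmrs.add(iv.data)
                    regions_hit.add(name)
                    detail_rows.append(
                        {
                            "gene_id": gene.id,
                            "region": name,
                            "chrom": gene.chrom,
                            "dmr_start": iv.begin,
                            "dmr_end": iv.end,
                            "context": dmrs.iloc[iv.data]["context"],
                            "direction": dmrs.iloc[iv.data].get("direction", ""),
                            "delta": dmrs.iloc[iv.data].get("delta", np.nan),
                        }
                    )
        gene_rows.append(
            {
                "gene_id": gene.id,
                "is_dmg": bool(hit_dmrs),
                "n_dmrs": len(hit_dmrs),
                "regions_hit": ";".join(r for r in REGIONS if r in regions_hit),
            }
        )
    detail = pd.DataFrame(
        detail_rows,
        columns=["gene_id", "region", "chrom", "dmr_start", "dmr_end",
                 "context", "direction", "delta"],
    )
    return DmgAnnotationResult(per_gene=pd.DataFrame(gene_rows), detail=detail, flank=flank)


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    overlap_percent: float
    n_universe: int
    n_dmg: int
    n_deg: int
    n_overlap: int


def overlap_percentage(n_overlap: int, n_deg: int) -> float:
    """Percentage of DEGs that are DMGs, rounded half-up to one decimal."""
    if n_deg <= 0:
        raise ValueError("n_deg must be positive")
    pct = Decimal(100 * n_overlap) / Decimal(n_deg)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def deg_dmg_enrichment(
    n_universe: int, n_dmg: int, n_deg: int, n_overlap: int
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of DEGs among DMGs.

    p = P(X >= n_overlap) with X ~ Hypergeom(universe=n_universe,
    successes=n_dmg, draws=n_deg).
    """
    if not (0 <= n_overlap <= min(n_dmg, n_deg) <= n_universe):
        raise ValueError(
            f"inconsistent counts: universe={n_universe}, dmg={n_dmg}, "
            f"deg={n_deg}, overlap={n_overlap}"
        )
    if max(n_dmg, n_deg) > n_universe:
        raise ValueError("set sizes exceed the universe")
    p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_dmg, n_deg))
    return EnrichmentResult(
        p_value=p,
        overlap_percent=overlap_percentage(n_overlap, n_deg),
        n_universe=n_universe, n_dmg=n_dmg, n_deg=n_deg, n_overlap=n_overlap,
    )


def shared_deg_fraction(n_shared: int, n_total: int) -> float:
    """Percentage of DEGs shared between comparisons, half-up to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_shared <= n_total:
        raise ValueError("n_shared must lie in [0, n_total]")
    pct = Decimal(100 * n_shared) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def promoter_dmr_report(
    gene_ids: Iterable[str],
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Candidate-gene summary of DMRs per context per region.

    Returns (table, missing_ids); rows cover every requested known gene x
    context x region with the DMR count, mean delta, and the direction
    ('hyper', 'hypo', 'mixed', or '' when no DMR).  Unknown ids are listed
    in ``missing_ids`` rather than failing.
    """
    wanted = list(gene_ids)
    known = {g.id: g for g in genes}
    missing = [g for g in wanted if g not in known]
    present = [known[g] for g in wanted if g in known]
    ann = annotate_dmgs(present, dmrs, flank=flank, chrom_sizes=chrom_sizes)

    contexts = sorted(dmrs["context"].unique()) if len(dmrs) else ["CG", "CHG", "CHH"]
    rows = []
    det = ann.detail
    for gene in present:
        sub = det[det["gene_id"] == gene.id]
        for ctx in contexts:
            for region in REGIONS:
                hits = sub[(sub["context"] == ctx) & (sub["region"] == region)]
                if len(hits):
                    dirs = set(hits["direction"])
                    direction = dirs.pop() if len(dirs) == 1 else "mixed"
                    mean_delta = float(hits["delta"].mean())
                else:
                    direction, mean_delta = "", np.nan
                rows.append(
                    {
                        "gene_id": gene.id, "context": ctx, "region": region,
                        "n_dmrs": len(hits), "mean_delta": mean_delta,
                        "direction": direction,
                    }
                )
    cols = ["gene_id", "context", "region", "n_dmrs", "mean_delta", "direction"]
    return pd.DataFrame(rows, columns=cols), missing
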