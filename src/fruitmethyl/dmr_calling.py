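"""Windowed differential-methylation calling between two samples.

The genome is tiled into fixed non-overlapping windows (200 bp by default;
the final window of each chromosome is retained truncated and flagged).
Within a window, read counts of all strand-specific cytosines of one context
are pooled per sample.  A window is a DMR when all three hold:

* |level_B - level_A| exceeds the context threshold (CG > 0.4, CHG > 0.2,
  CHH > 0.1 by default; strict inequality),
* two-sided Fisher's exact p on the pooled 2x2 count table is < 0.05,
* Benjamini-Hochberg q, computed per context over all testable windows,
  is < 0.05.

Direction is *hyper* when sample B is more methylated than sample A.
Windows below the per-sample coverage or cytosine-count floor in either
sample are untestable and excluded from testing and FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome_io import CONTEXTS

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context",
    "c_a", "n_a", "c_b", "n_b", "sites_a", "sites_b",
    "level_a", "level_b", "testable", "truncated",
]


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the windowed DMR definition."""

    window_size: int = 200
    delta_thresholds: dict = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
    )
    p_alpha: float = 0.05
    q_alpha: float = 0.05
    min_coverage_per_sample: int = 10
    min_sites: int = 3

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for ctx, thr in self.delta_thresholds.items():
            if not 0 < thr <= 1:
                raise ValueError(f"delta threshold for {ctx} must be in (0,1]")
        for a in (self.p_alpha, self.q_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0,1)")


@dataclass
class DmrResult:
    """All tested windows with statistics, and the DMR subset."""

    tested: pd.DataFrame  # testable windows + delta, p_value, q_value, is_dmr
    dmrs: pd.DataFrame    # rows of `tested` passing the full DMR definition
    params: DmrParams


def _aggregate(records: pd.DataFrame, w: int, tag: str) -> pd.DataFrame:
    df = records.copy()
    df["widx"] = (df["pos"].to_numpy() - 1) // w
    g = df.groupby(["chrom", "widx", "context"], observed=True).agg(
        c=("c_count", "sum"), n=("total_count", "sum"), sites=("pos", "size")
    )
    return g.rename(columns={"c": f"c_{tag}", "n": f"n_{tag}", "sites": f"sites_{tag}"})


def bin_windows(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    chrom_sizes: dict[str, int],
    params: DmrParams | None = None,
    contexts=CONTEXTS,
) -> pd.DataFrame:
    """Tile chromosomes and pool per-context counts of both samples.

    Both methylomes must cover the same chromosome set (a subset of
    ``chrom_sizes``); a mismatch raises with the differing names.
    """
    params = params or DmrParams()
    w = params.window_size
    set_a = set(records_a["chrom"].unique())
    set_b = set(records_b["chrom"].unique())
    if set_a != set_b:
        raise ValueError(
            "mismatched chromosome sets between samples: "
            f"only in A: {sorted(set_a - set_b)}, only in B: {sorted(set_b - set_a)}"
        )
    unknown = set_a - set(chrom_sizes)
    if unknown:
        raise ValueError(f"records on chromosomes absent from the reference: {sorted(unknown)}")

    frames = []
    for chrom in sorted(set_a):
        L = chrom_sizes[chrom]
        n_win = int(np.ceil(L / w))
        widx = np.arange(n_win)
        for ctx in contexts:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "widx": widx,
                        "context": ctx,
                        "start": widx * w,
                        "end": np.minimum((widx + 1) * w, L),
                    }
                )
            )
    grid = pd.concat(frames, ignore_index=True)
    agg_a = _aggregate(records_a[records_a["context"].isin(contexts)], w, "a")
    agg_b = _aggregate(records_b[records_b["context"].isin(contexts)], w, "b")
    out = grid.join(agg_a, on=["chrom", "widx", "context"]).join(
        agg_b, on=["chrom", "widx", "context"]
    )
    for col in ("c_a", "n_a", "sites_a", "c_b", "n_b", "sites_b"):
        out[col] = out[col].fillna(0).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level_a"] = np.where(out["n_a"] > 0, out["c_a"] / out["n_a"].replace(0, 1), np.nan)
        out["level_b"] = np.where(out["n_b"] > 0, out["c_b"] / out["n_b"].replace(0, 1), np.nan)
    out["testable"] = (
        (out["n_a"] >= params.min_coverage_per_sample)
        & (out["n_b"] >= params.min_coverage_per_sample)
        & (out["sites_a"] >= params.min_sites)
        & (out["sites_b"] >= params.min_sites)
    )
    out["truncated"] = (out["end"] - out["start"]) < w
    return out.drop(columns="widx")[WINDOW_COLUMNS]


def fisher_window_test(c_a: int, n_a: int, c_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for a window's pooled 2x2 count table.

    The table is [[methylated_A, unmethylated_A], [methylated_B,
    unmethylated_B]]; two-sidedness sums all tables with point probability
    at most that of the observed table.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both samples need positive read totals")
    if not (0 <= c_a <= n_a and 0 <= c_b <= n_b):
        raise ValueError("counts must satisfy 0 <= c <= n")
    table = [[c_a, n_a - c_a], [c_b, n_b - c_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def call_dmrs(windows: pd.DataFrame, params: DmrParams | None = None) -> DmrResult:
    """Test all testable windows and apply the full DMR definition.

    BH q-values are computed separately per context over that context's
    testable windows (thresholds and biology are context-specific).
    """
    params = params or DmrParams()
    tested = windows[windows["testable"]].copy()
    if len(tested) == 0:
        warnings.warn("no testable windows; empty DMR set", stacklevel=2)
        for col in ("delta", "p_value", "q_value"):
            tested[col] = pd.Series(dtype=float)
        tested["is_dmr"] = pd.Series(dtype=bool)
        tested["direction"] = pd.Series(dtype=str)
        return DmrResult(tested=tested, dmrs=tested.copy(), params=params)

    tested["delta"] = tested["level_b"] - tested["level_a"]
    p = np.empty(len(tested))
    cols = tested[["c_a", "n_a", "c_b", "n_b"]].to_numpy()
    for i, (c_a, n_a, c_b, n_b) in enumerate(cols):
        p[i] = fisher_window_test(int(c_a), int(n_a), int(c_b), int(n_b))
    tested["p_value"] = p
    tested["q_value"] = np.nan
    for ctx, idx in tested.groupby("context", observed=True).groups.items():
        q = multipletests(tested.loc[idx, "p_value"].to_numpy(), method="fdr_bh")[1]
        tested.loc[idx, "q_value"] = q
    thr = tested["context"].map(params.delta_thresholds).to_numpy(dtype=float)
    tested["is_dmr"] = (
        (tested["delta"].abs().to_numpy() > thr)
        & (tested["p_value"].to_numpy() < params.p_alpha)
        & (tested["q_value"].to_numpy() < params.q_alpha)
    )
    tested["direction"] = np.where(tested["delta"] > 0, "hyper", "hypo")
    dmrs = tested[tested["is_dmr"]].reset_index(drop=True)
    logger.info("call_dmrs: %d DMRs among %d testable windows", len(dmrs), len(tested))
    return DmrResult(tested=tested, dmrs=dmrs, params=params)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (cumulative-minimum form)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def shared_dmrs(dmrs_1: pd.DataFrame, dmrs_2: pd.DataFrame) -> pd.DataFrame:
    """Compare two DMR sets on the same window tiling, per context.

    Shared DMRs are coordinate-identical windows of the same context present
    in both sets; concordance is the fraction of shared DMRs whose direction
    agrees (NaN when nothing is shared).
    """
    for df in (dmrs_1, dmrs_2):
        for col in ("chrom", "start", "end", "context", "direction"):
            if col not in df.columns:
                raise ValueError(f"DMR table missing column {col!r}")
    w1 = _modal_window(dmrs_1)
    w2 = _modal_window(dmrs_2)
    if w1 is not None and w2 is not None and w1 != w2:
        raise ValueError(f"window sizes differ between DMR sets: {w1} vs {w2}")

    key = ["chrom", "start", "end", "context"]
    merged = dmrs_1[key + ["direction"]].merge(
        dmrs_2[key + ["direction"]], on=key, suffixes=("_1", "_2")
    )
    rows = []
    for ctx in CONTEXTS:
        n1 = int((dmrs_1["context"] == ctx).sum())
        n2 = int((dmrs_2["context"] == ctx).sum())
        sub = merged[merged["context"] == ctx]
        n_shared = len(sub)
        conc = float((sub["direction_1"] == sub["direction_2"]).mean()) if n_shared else np.nan
        rows.append(
            {
                "context": ctx, "n_1": n1, "n_2": n2, "n_shared": n_shared,
                "n_unique_1": n1 - n_shared, "n_unique_2": n2 - n_shared,
                "concordance": conc,
            }
        )
    return pd.DataFrame(rows)


def _modal_window(dmrs: pd.DataFrame) -> int | None:
    if len(dmrs) == 0:
        return None
    sizes = (dmrs["end"] - dmrs["start"]).value_counts()
    return int(sizes.idxmax())


def genome_dmr_coverage(
    dmrs: pd.DataFrame, chrom_sizes: dict[str, int], exclude=()
) -> float:
    """Fraction of the genome covered by the union of DMR windows.

    The denominator is the total length of all chromosomes in
    ``chrom_sizes`` except ``exclude`` (e.g. the spike-in control).
    """
    total = sum(L for name, L in chrom_sizes.items() if name not in exclude)
    if total == 0:
        raise ValueError("empty genome")
    covered = 0
    sub = dmrs[~dmrs["chrom"].isin(exclude)] if len(dmrs) else dmrs
    for chrom, grp in sub.groupby("chrom") if len(sub) else []:
        ivals = grp[["start", "end"]].sort_values("start").to_numpy()
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            covered += cur_e - cur_s
    return covered / total


# ---------------------------------------------------------------------------
# DMR BED6+ I/O
# ---------------------------------------------------------------------------

_BED_EXTRA = ["delta", "p_value", "q_value", "direction"]


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+4: chrom start end context -log10(q) . delta p q direction."""
    with np.errstate(divide="ignore"):
        score = np.where(
            dmrs["q_value"] > 0, -np.log10(dmrs["q_value"].astype(float)), 999.0
        ) if len(dmrs) else np.array([])
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"], "start": dmrs["start"], "end": dmrs["end"],
            "name": dmrs["context"], "score": np.round(score, 4), "strand": ".",
            "delta": dmrs["delta"], "p_value": dmrs["p_value"],
            "q_value": dmrs["q_value"], "direction": dmrs["direction"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_dmr_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "context", "score", "strand"] + _BED_EXTRA
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "context"] + _BED_EXTRA)
    return df.drop(columns=["score", "strand"])
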