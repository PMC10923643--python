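"""Synthetic bisulfite-sequencing data with known ground truth.

Generates a toy genome (plus an unmethylated spike-in control sequence in
the same FASTA, mirroring lambda-phage practice), non-overlapping gene
models, TE intervals, per-stage per-cytosine methylation count tables, and
per-gene expression statistics — with the differential windows and the
DMG/DEG coupling recorded as ground truth.

Generative model
----------------
Each cytosine carries a latent quantile u ~ Uniform(0,1) shared across
developmental stages; its true methylation level at a stage is the Beta
quantile ``Beta.ppf(u; mean*kappa, (1-mean)*kappa)`` at that stage's
context mean (kappa = 20 reproduces the overdispersion of real methylomes
with two parameters).  Sharing u across stages makes a site's level
positionally stable between stages, as in real methylomes, and makes null
windows (equal stage means) exactly null.  A chosen fraction of 200-bp
windows receives a context-specific mean shift in every stage after the
first — identically in all later stages, so shared-DMR behaviour between
stage comparisons is emulated.  Read coverage is Poisson (minimum 1) and
the observed methylated count is Binomial(coverage, level + (1-level) *
non_conversion_rate); control cytosines have true level 0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_io import (
    GeneModel,
    extract_contexts,
    write_bed,
    write_fasta,
    write_gff3,
    write_methylome,
)

MIN_GENE_LENGTH = 1000
MAX_GENE_LENGTH = 3000

# named substreams so each simulation stage draws from its own stream
_STREAMS = {"genome": 1, "genes": 2, "tes": 3, "windows": 4, "levels": 5,
            "counts": 6, "expression": 7}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _default_means() -> dict:
    # stage trends mirror a developing fruit methylome: CG/CHG decline,
    # CHH rises sharply then eases off
    return {
        "YF": {"CG": 0.60, "CHG": 0.40, "CHH": 0.066},
        "EF": {"CG": 0.55, "CHG": 0.36, "CHH": 0.153},
        "MF": {"CG": 0.52, "CHG": 0.34, "CHH": 0.145},
    }


def _default_effects() -> dict:
    return {"CG": -0.45, "CHG": -0.25, "CHH": 0.15}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic WGBS study.

    Defaults emulate the study conditions: three stages (young, expanding,
    mature fruit), ~40x coverage, ~1% bisulfite non-conversion, CHH stage
    means 0.066/0.153/0.145 with CG/CHG declining, and 10% of windows given
    a true context-specific shift from the first stage onward.
    """

    genome_length: int = 400_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.35
    n_genes: int = 80
    n_tes: int = 40
    stage_names: tuple = ("YF", "EF", "MF")
    context_level_means: dict = field(default_factory=_default_means)
    diff_window_fraction: float = 0.10
    diff_effect: dict = field(default_factory=_default_effects)
    coverage_mean: float = 40.0
    non_conversion_rate: float = 0.01
    control_length: int = 20_000
    control_name: str = "lambda_control"
    window_size: int = 200
    beta_concentration: float = 20.0
    expression_coupling: float = 0.9
    expression_effect_log2fc: float = 4.0
    background_deg_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name, v in (
            ("gc_fraction", self.gc_fraction),
            ("diff_window_fraction", self.diff_window_fraction),
            ("non_conversion_rate", self.non_conversion_rate),
            ("expression_coupling", self.expression_coupling),
            ("background_deg_rate", self.background_deg_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if len(self.stage_names) < 2:
            raise ValueError("need at least two stages")
        for stage in self.stage_names:
            means = self.context_level_means.get(stage)
            if means is None:
                raise ValueError(f"no context means for stage {stage!r}")
            for ctx, m in means.items():
                if not 0.0 <= m <= 1.0:
                    raise ValueError(f"mean for {stage}/{ctx} must lie in [0,1]")
        if self.genome_length < self.n_genes * MIN_GENE_LENGTH:
            raise ValueError(
                f"genome_length {self.genome_length} cannot hold {self.n_genes} genes "
                f"of minimum footprint {MIN_GENE_LENGTH} bp"
            )

    # -- named study conditions ---------------------------------------------

    @classmethod
    def flat(cls, chh_mean: float = 0.066, **kw) -> "SimulationSpec":
        """Identical context means in every stage (no genome-wide drift)."""
        means = {"CG": 0.60, "CHG": 0.40, "CHH": chh_mean}
        kw.setdefault("context_level_means", {s: dict(means) for s in ("YF", "EF", "MF")})
        return cls(**kw)

    @classmethod
    def null(cls, **kw) -> "SimulationSpec":
        """Flat means and no shifted windows: every window is truly null."""
        kw.setdefault("diff_window_fraction", 0.0)
        return cls.flat(**kw)

    @classmethod
    def recovery(cls, **kw) -> "SimulationSpec":
        """Flat means with a +0.15 CHH shift in 10% of windows at 40x."""
        kw.setdefault("diff_effect", {"CG": 0.0, "CHG": 0.0, "CHH": 0.15})
        kw.setdefault("diff_window_fraction", 0.10)
        kw.setdefault("coverage_mean", 40.0)
        return cls.flat(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_names"] = list(self.stage_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "stage_names" in d:
            d["stage_names"] = tuple(d["stage_names"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the simulator actually planted, for scoring recovered calls."""

    true_diff_windows: pd.DataFrame  # chrom, start, end, context, direction
    true_dmg_ids: list
    true_deg_ids: list

    def windows_for_context(self, context: str) -> pd.DataFrame:
        return self.true_diff_windows[self.true_diff_windows["context"] == context]


# ---------------------------------------------------------------------------
# genome + annotations
# ---------------------------------------------------------------------------


def generate_genome(
    spec: SimulationSpec, outdir: str | Path | None = None
) -> tuple[dict, list[GeneModel], list[GeneModel]]:
    """Random genome at the requested GC plus the unmethylated control.

    Returns (sequences, genes, tes); ``sequences`` maps name to sequence and
    includes the control under ``spec.control_name``.  With ``outdir`` set,
    writes genome.fa, genes.gff3 and tes.bed there.
    """
    rng = _rng(spec.seed, "genome")
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)

    base = spec.genome_length // spec.n_chromosomes
    lengths = [base] * spec.n_chromosomes
    lengths[-1] += spec.genome_length - base * spec.n_chromosomes
    sequences: dict[str, str] = {}
    for i, L in enumerate(lengths, start=1):
        draw = rng.choice(alphabet, size=L, p=p)
        sequences[f"chr{i}"] = draw.tobytes().decode("ascii")
    draw = rng.choice(alphabet, size=spec.control_length, p=p)
    sequences[spec.control_name] = draw.tobytes().decode("ascii")

    genes = _place_genes(spec, lengths)
    tes = _place_tes(spec, lengths)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, outdir / "genome.fa")
        write_gff3(genes, outdir / "genes.gff3")
        write_bed(tes, outdir / "tes.bed")
    return sequences, genes, tes


def _split_counts(n_items: int, weights: list[int]) -> list[int]:
    total = sum(weights)
    counts = [n_items * w // total for w in weights]
    for i in range(n_items - sum(counts)):
        counts[i % len(counts)] += 1
    return counts


def _place_genes(spec: SimulationSpec, chrom_lengths: list[int]) -> list[GeneModel]:
    rng = _rng(spec.seed, "genes")
    per_chrom = _split_counts(spec.n_genes, chrom_lengths)
    genes: list[GeneModel] = []
    gid = 0
    for ci, (L, k) in enumerate(zip(chrom_lengths, per_chrom), start=1):
        if k == 0:
            continue
        lens = rng.integers(MIN_GENE_LENGTH, MAX_GENE_LENGTH + 1, size=k)
        if int(lens.sum()) > L:
            raise ValueError(
                f"cannot pack {k} genes totalling {int(lens.sum())} bp into "
                f"chr{ci} of length {L} bp"
            )
        leftover = L - int(lens.sum())
        cuts = np.sort(rng.integers(0, leftover + 1, size=k))
        starts = cuts + np.concatenate([[0], np.cumsum(lens[:-1])])
        strands = rng.choice(np.array(["+", "-"]), size=k)
        for s, ln, st in zip(starts, lens, strands):
            gid += 1
            genes.append(
                GeneModel(
                    id=f"gene{gid:04d}", chrom=f"chr{ci}",
                    start=int(s), end=int(s + ln), strand=str(st),
                    feature_class="gene",
                )
            )
    return genes


def _place_tes(spec: SimulationSpec, chrom_lengths: list[int]) -> list[GeneModel]:
    rng = _rng(spec.seed, "tes")
    per_chrom = _split_counts(spec.n_tes, chrom_lengths)
    tes: list[GeneModel] = []
    tid = 0
    for ci, (L, k) in enumerate(zip(chrom_lengths, per_chrom), start=1):
        for _ in range(k):
            ln = int(rng.integers(300, 2001))
            ln = min(ln, L - 1)
            start = int(rng.integers(0, L - ln))
            tid += 1
            tes.append(
                GeneModel(
                    id=f"te{tid:04d}", chrom=f"chr{ci}",
                    start=start, end=start + ln, strand="+",
                    feature_class="TE",
                )
            )
    return tes


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def simulate_methylomes(
    spec: SimulationSpec,
    sequences: dict,
    genes: list[GeneModel] | None = None,
    dmg_flank: int = 2000,
) -> tuple[dict, GroundTruth]:
    """Per-stage per-cytosine count tables plus the planted ground truth.

    Returns ({stage: records DataFrame}, GroundTruth); each table covers
    every context-classifiable cytosine of the genome and the control.
    ``true_dmg_ids`` are the genes whose +-``dmg_flank`` span intersects a
    planted window of any context (``true_deg_ids`` is filled later by
    :func:`simulate_expression`).
    """
    ctx_all = extract_contexts(sequences)
    is_control = ctx_all["chrom"] == spec.control_name
    ref = ctx_all[~is_control].reset_index(drop=True)
    ctrl = ctx_all[is_control].reset_index(drop=True)

    chrom_lengths = {
        name: len(seq) for name, seq in sequences.items() if name != spec.control_name
    }
    truth_windows = _choose_diff_windows(spec, chrom_lengths)

    # per-site shift mask by context membership of its window
    w = spec.window_size
    widx = (ref["pos"].to_numpy() - 1) // w
    shifted = np.zeros(len(ref), dtype=bool)
    if len(truth_windows):
        key_site = pd.MultiIndex.from_arrays(
            [ref["chrom"].to_numpy(), widx, ref["context"].to_numpy()]
        )
        key_truth = pd.MultiIndex.from_arrays(
            [
                truth_windows["chrom"].to_numpy(),
                truth_windows["start"].to_numpy() // w,
                truth_windows["context"].to_numpy(),
            ]
        )
        shifted = key_site.isin(key_truth)

    u = _rng(spec.seed, "levels").random(len(ref))
    rng_counts = _rng(spec.seed, "counts")
    kappa = spec.beta_concentration
    r = spec.non_conversion_rate
    ctx_codes = ref["context"].to_numpy()

    tables: dict[str, pd.DataFrame] = {}
    for si, stage in enumerate(spec.stage_names):
        means = np.array(
            [spec.context_level_means[stage][c] for c in ctx_codes], dtype=float
        )
        if si > 0 and shifted.any():
            effect = np.array(
                [spec.diff_effect.get(c, 0.0) for c in ctx_codes], dtype=float
            )
            means = means + np.where(shifted, effect, 0.0)
        means = np.clip(means, 0.0, 1.0)

        levels = np.empty(len(ref))
        for m in np.unique(means):
            mask = means == m
            if m <= 0.0:
                levels[mask] = 0.0  # degenerate: truly unmethylated
            elif m >= 1.0:
                levels[mask] = 1.0
            else:
                levels[mask] = stats.beta.ppf(u[mask], m * kappa, (1 - m) * kappa)

        n = np.maximum(rng_counts.poisson(spec.coverage_mean, size=len(ref)), 1)
        p_obs = np.clip(levels + (1 - levels) * r, 0.0, 1.0)
        c = rng_counts.binomial(n, p_obs)

        n_ctrl = np.maximum(rng_counts.poisson(spec.coverage_mean, size=len(ctrl)), 1)
        c_ctrl = rng_counts.binomial(n_ctrl, r)

        table = pd.concat(
            [
                pd.DataFrame(
                    {
                        "chrom": ref["chrom"], "pos": ref["pos"],
                        "strand": ref["strand"], "context": ref["context"],
                        "c_count": c, "total_count": n,
                    }
                ),
                pd.DataFrame(
                    {
                        "chrom": ctrl["chrom"], "pos": ctrl["pos"],
                        "strand": ctrl["strand"], "context": ctrl["context"],
                        "c_count": c_ctrl, "total_count": n_ctrl,
                    }
                ),
            ],
            ignore_index=True,
        )
        tables[stage] = table

    true_dmg = _true_dmgs(genes or [], truth_windows, dmg_flank)
    truth = GroundTruth(
        true_diff_windows=truth_windows, true_dmg_ids=true_dmg, true_deg_ids=[]
    )
    return tables, truth


def _choose_diff_windows(
    spec: SimulationSpec, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "context", "direction"]
    rows = []
    if spec.diff_window_fraction > 0:
        rng = _rng(spec.seed, "windows")
        w = spec.window_size
        all_windows = []
        for chrom in sorted(chrom_lengths):
            L = chrom_lengths[chrom]
            for k in range(int(np.ceil(L / w))):
                all_windows.append((chrom, k * w, min((k + 1) * w, L)))
        n_pick = int(round(spec.diff_window_fraction * len(all_windows)))
        for ctx in ("CG", "CHG", "CHH"):
            effect = spec.diff_effect.get(ctx, 0.0)
            if effect == 0.0 or n_pick == 0:
                continue
            idx = rng.choice(len(all_windows), size=n_pick, replace=False)
            direction = "hyper" if effect > 0 else "hypo"
            for i in np.sort(idx):
                chrom, s, e = all_windows[i]
                rows.append(
                    {"chrom": chrom, "start": s, "end": e,
                     "context": ctx, "direction": direction}
                )
    return pd.DataFrame(rows, columns=cols)


def _true_dmgs(
    genes: list[GeneModel], truth_windows: pd.DataFrame, flank: int
) -> list:
    if not genes or not len(truth_windows):
        return []
    out = []
    by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in truth_windows.groupby("chrom")
    }
    for g in genes:
        ivals = by_chrom.get(g.chrom)
        if ivals is None:
            continue
        lo, hi = g.start - flank, g.end + flank
        if ((ivals[:, 0] < hi) & (ivals[:, 1] > lo)).any():
            out.append(g.id)
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    spec: SimulationSpec,
    genes: list[GeneModel],
    ground_truth: GroundTruth,
) -> pd.DataFrame:
    """Per-gene expression statistics coupled to the planted DMGs.

    For each later-stage comparison against the first stage, every gene gets
    a log2 fold change and adjusted p.  True DMGs receive a large effect
    (|log2FC| >= ``expression_effect_log2fc``, adjusted p in [1e-8, 1e-3])
    with probability ``expression_coupling``, drawn once so coupled DEGs are
    shared across comparisons; a ``background_deg_rate`` fraction of the
    remaining genes are DEGs for methylation-unrelated reasons (real
    transcriptomes always have these); everything else draws null values.
    Fills ``ground_truth.true_deg_ids``.
    """
    rng = _rng(spec.seed, "expression")
    gene_ids = [g.id for g in genes]
    n = len(gene_ids)
    dmg_set = set(ground_truth.true_dmg_ids)

    is_dmg = np.array([g in dmg_set for g in gene_ids])
    coupled = is_dmg & (rng.random(n) < spec.expression_coupling)
    coupled_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    coupled_mag = spec.expression_effect_log2fc + np.abs(rng.normal(0, 0.5, size=n))
    coupled_p = 10.0 ** rng.uniform(-8, -3, size=n)

    comparisons = [f"{s}_vs_{spec.stage_names[0]}" for s in spec.stage_names[1:]]
    frames = []
    deg_ids: set = set()
    for comp in comparisons:
        bg = (~coupled) & (rng.random(n) < spec.background_deg_rate)
        log2fc = rng.normal(0.0, 0.7, size=n)
        adj_p = rng.uniform(0.0, 1.0, size=n)

        bg_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        bg_mag = 2.5 + np.abs(rng.normal(0, 1.0, size=n))
        bg_p = rng.uniform(0.0, 0.05, size=n)
        log2fc = np.where(bg, bg_sign * bg_mag, log2fc)
        adj_p = np.where(bg, bg_p, adj_p)

        log2fc = np.where(coupled, coupled_sign * coupled_mag, log2fc)
        adj_p = np.where(coupled, coupled_p, adj_p)

        deg_ids.update(np.array(gene_ids)[coupled | bg].tolist())
        frames.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "comparison": comp,
                 "log2_fc": log2fc, "adj_p": adj_p}
            )
        )
    ground_truth.true_deg_ids = sorted(deg_ids)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# file-level simulation run
# ---------------------------------------------------------------------------


def run_simulation(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Generate and write the full synthetic study; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, genes, tes = generate_genome(spec, outdir=outdir)
    tables, truth = simulate_methylomes(spec, sequences, genes=genes)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "tes": outdir / "tes.bed",
        "ground_truth": outdir / "ground_truth.tsv",
        "expression": outdir / "expression.tsv",
    }
    for stage, table in tables.items():
        p = outdir / f"methylome_{stage}.tsv"
        write_methylome(table, p)
        paths[f"methylome_{stage}"] = p
    expr = simulate_expression(spec, genes, truth)
    expr.to_csv(paths["expression"], sep="\t", index=False)
    truth.true_diff_windows.to_csv(paths["ground_truth"], sep="\t", index=False)
    (outdir / "true_dmg_ids.txt").write_text("\n".join(truth.true_dmg_ids) + "\n")
    (outdir / "true_deg_ids.txt").write_text("\n".join(truth.true_deg_ids) + "\n")
    return paths


def score_dmr_calls(
    dmrs: pd.DataFrame, truth: GroundTruth, context: str
) -> dict:
    """Recall and false-discovery proportion of called DMRs vs ground truth.

    Matching is exact window identity (same tiling as the simulator).  The
    recall denominator is every planted window of the context; windows the
    caller deemed untestable therefore count against recall.
    """
    true_w = truth.windows_for_context(context)
    called = dmrs[dmrs["context"] == context] if len(dmrs) else dmrs
    key = ["chrom", "start", "end"]
    n_true, n_called = len(true_w), len(called)
    if n_called and n_true:
        hit = called[key].merge(true_w[key], on=key)
        n_hit = len(hit)
    else:
        n_hit = 0
    return {
        "n_true": n_true,
        "n_called": n_called,
        "n_hit": n_hit,
        "recall": n_hit / n_true if n_true else np.nan,
        "fdp": (n_called - n_hit) / n_called if n_called else 0.0,
    }


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for determinism checks and run logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
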