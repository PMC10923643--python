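"""Readers/writers for the standard formats and cytosine-context extraction.

Per-cytosine methylation data are carried as pandas DataFrames with the
columns of :data:`METHYLOME_COLUMNS` — one row per strand-specific cytosine
holding its sequence context (CG, CHG or CHH; H is A, T or C) and bisulfite
read counts (``c_count`` methylated reads out of ``total_count`` covering
reads).  Symmetric CG/CHG sites are *not* merged across strands: each
strand's cytosine is an independent record, matching per-strand methylation
extractor output and keeping weighted levels well defined.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only at file boundaries (methratio TSV positions and
GFF3 are 1-based, BED is 0-based half-open).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

#: canonical column order of the in-memory per-cytosine table
METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "c_count", "total_count"]

#: header of the methratio-style TSV dialect (pos is 1-based)
METHRATIO_HEADER = ["chrom", "pos", "strand", "context", "ratio", "eff_CT_count", "C_count"]


class MethylomeFormatError(ValueError):
    """A methylome/annotation file violates its dialect or an invariant."""


class NoDataError(ValueError):
    """An operation that needs covered cytosines received none."""


@dataclass(frozen=True)
class GeneModel:
    """A gene or TE interval; start/end are 0-based half-open."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str = "gene"  # "gene" or "TE"

    def __post_init__(self):
        if self.start >= self.end:
            raise MethylomeFormatError(
                f"feature {self.id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise MethylomeFormatError(f"feature {self.id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


def _contexts_one_seq(chrom: str, seq: str) -> pd.DataFrame:
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(b, (_A, _C, _G, _T, _N))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise MethylomeFormatError(
            f"{chrom}: invalid base {chr(b[i])!r} at position {i + 1}"
        )
    L = b.size
    out = []

    # plus strand: C at i classified by bases i+1, i+2
    idx = np.flatnonzero(b == _C)
    idx = idx[idx + 2 < L]
    if idx.size:
        n1, n2 = b[idx + 1], b[idx + 2]
        ok = (n1 != _N) & (n2 != _N)
        idx, n1, n2 = idx[ok], n1[ok], n2[ok]
        ctx = np.where(n1 == _G, "CG", np.where(n2 == _G, "CHG", "CHH"))
        out.append((idx, "+", ctx))

    # minus strand: G at i; minus-strand 3' neighbours are the complements of
    # plus-strand bases i-1, i-2 (complement of C is G)
    idx = np.flatnonzero(b == _G)
    idx = idx[idx >= 2]
    if idx.size:
        n1, n2 = b[idx - 1], b[idx - 2]
        ok = (n1 != _N) & (n2 != _N)
        idx, n1, n2 = idx[ok], n1[ok], n2[ok]
        ctx = np.where(n1 == _C, "CG", np.where(n2 == _C, "CHG", "CHH"))
        out.append((idx, "-", ctx))

    if not out:
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
             "strand": pd.Series(dtype=str), "context": pd.Series(dtype=str)}
        )
    frames = [
        pd.DataFrame({"chrom": chrom, "pos": i + 1, "strand": s, "context": c})
        for i, s, c in out
    ]
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def extract_contexts(reference) -> pd.DataFrame:
    """Classify every cytosine of both strands into CG/CHG/CHH.

    Parameters
    ----------
    reference
        A FASTA path or a mapping of sequence name to sequence string.

    Returns
    -------
    DataFrame with columns chrom, pos (1-based), strand, context.  Cytosines
    whose two 3' neighbours run off the sequence end or contain N are omitted
    (their context is undefined).
    """
    seqs = _as_sequences(reference)
    frames = [_contexts_one_seq(name, seq) for name, seq in seqs.items()]
    if not frames:
        return _contexts_one_seq("", "")
    return pd.concat(frames, ignore_index=True)


def _as_sequences(reference) -> Mapping[str, str]:
    if isinstance(reference, Mapping):
        return reference
    import pyfaidx

    fa = pyfaidx.Fasta(str(reference), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_fasta_lengths(reference) -> dict[str, int]:
    """Sequence name -> length, from a FASTA path or name->sequence mapping."""
    return {name: len(seq) for name, seq in _as_sequences(reference).items()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# methratio-style TSV
# ---------------------------------------------------------------------------


def read_methylome(path) -> pd.DataFrame:
    """Read a methratio-style TSV into the canonical per-cytosine table.

    The dialect is tab-separated with header
    ``chrom pos strand context ratio eff_CT_count C_count``; ``pos`` is
    1-based and ``C_count`` (methylated reads) must not exceed
    ``eff_CT_count`` (covering reads).  Gzip-compressed input is accepted.
    Malformed rows raise :class:`MethylomeFormatError` naming the line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, compression="infer")
    missing = [c for c in METHRATIO_HEADER if c not in df.columns]
    if missing:
        raise MethylomeFormatError(f"{path}: missing columns {missing}")
    # +2: header line plus 1-based numbering
    lines = df.index.to_numpy() + 2

    def _fail(mask: np.ndarray, msg: str):
        if mask.any():
            first = int(lines[np.flatnonzero(mask)[0]])
            raise MethylomeFormatError(f"{path}, line {first}: {msg}")

    _fail(~df["context"].isin(CONTEXTS).to_numpy(), "unknown context")
    _fail(~df["strand"].isin(("+", "-")).to_numpy(), "strand must be + or -")
    pos = df["pos"].to_numpy()
    _fail(pos < 1, "pos must be >= 1")
    c = df["C_count"].to_numpy()
    n = df["eff_CT_count"].to_numpy()
    _fail((c < 0) | (n < 0), "negative count")
    _fail(c > n, "C_count exceeds eff_CT_count")

    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64),
            "strand": df["strand"],
            "context": df["context"],
            "c_count": df["C_count"].astype(np.int64),
            "total_count": df["eff_CT_count"].astype(np.int64),
        }
    )
    return out


def write_methylome(records: pd.DataFrame, path) -> None:
    """Write the canonical table in the methratio-style dialect."""
    n = records["total_count"].to_numpy(dtype=float)
    c = records["c_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n > 0, c / np.where(n > 0, n, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "pos": records["pos"],
            "strand": records["strand"],
            "context": records["context"],
            "ratio": np.round(ratio, 6),
            "eff_CT_count": records["total_count"],
            "C_count": records["c_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False, compression="infer")


def validate_records(records: pd.DataFrame) -> None:
    """Raise if the canonical table violates its invariants."""
    if (records["c_count"] > records["total_count"]).any():
        raise MethylomeFormatError("c_count exceeds total_count")
    if (records["c_count"] < 0).any() or (records["pos"] < 1).any():
        raise MethylomeFormatError("negative count or non-positive pos")
    if not records["context"].isin(CONTEXTS).all():
        raise MethylomeFormatError("unknown context value")


# ---------------------------------------------------------------------------
# annotations (GFF3 / BED)
# ---------------------------------------------------------------------------

_GFF_EXT = (".gff", ".gff3")
_BED_EXT = (".bed",)
_TE_TYPES = {
    "transposable_element", "transposon", "repeat_region", "TE",
    "transposable_element_gene", "mobile_genetic_element",
}


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
    return open(p, "r", encoding="utf-8")


def read_annotations(path, feature_class: str | None = None) -> list[GeneModel]:
    """Read gene/TE models from GFF3 (1-based inclusive) or BED (0-based).

    The dialect is chosen by file extension (``.gff``/``.gff3`` vs ``.bed``,
    optionally ``.gz``); internal coordinates are normalized to 0-based
    half-open.  ``feature_class`` labels every returned feature ("gene" or
    "TE"); for GFF3 the default is taken per feature type instead.
    """
    p = str(path)
    stem = p[:-3] if p.endswith(".gz") else p
    ext = os.path.splitext(stem)[1].lower()
    if ext in _GFF_EXT:
        return _read_gff3(path, feature_class)
    if ext in _BED_EXT:
        return _read_bed(path, feature_class or "TE")
    raise MethylomeFormatError(f"{path}: unrecognized annotation extension {ext!r}")


def _read_gff3(path, feature_class: str | None) -> list[GeneModel]:
    # validate line shape first so a mixed-dialect file fails with a line number
    n_feature_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_feature_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: expected 9 tab-separated GFF3 fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: non-integer start/end"
                ) from None
            if start > end or start < 1:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: invalid interval {start}..{end}"
                )
    if n_feature_lines == 0:  # header-only GFF3 is a valid empty annotation
        return []
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype == "gene":
            klass = "gene"
        elif feat.featuretype in _TE_TYPES:
            klass = "TE"
        else:
            continue
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        models.append(
            GeneModel(
                id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=strand,
                feature_class=feature_class or klass,
            )
        )
    return models


def _read_bed(path, feature_class: str) -> list[GeneModel]:
    models: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: BED needs >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: non-integer start/end"
                ) from None
            if start >= end or start < 0:
                raise MethylomeFormatError(
                    f"{path}, line {lineno}: invalid interval [{start},{end})"
                )
            name = fields[3] if len(fields) > 3 else f"{feature_class}_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            models.append(
                GeneModel(
                    id=name, chrom=fields[0], start=start, end=end,
                    strand=strand, feature_class=feature_class,
                )
            )
    return models


def write_gff3(features: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tfruitmethyl\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.id}\n"
            )


def write_bed(features: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")
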