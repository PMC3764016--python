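"""Readers, writers and peak-to-gene assignment.

All coordinates are BED-style 0-based half-open internally; GTF input is
converted on read.  Tabular outputs are tab-separated UTF-8 with a header
row, floats serialized to 12 significant digits so that read(write(x))
round-trips.  Readers are gzip-transparent (by file extension, via pandas).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tfsig")

#: half-width of the TSS-centred assignment window, in bp
DEFAULT_WINDOW_HALF_WIDTH = 1_000_000

PEAK_COLUMNS = ["chrom", "start", "end", "intensity", "summit_offset"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss"]
LINK_COLUMNS = ["gene_id", "peak_index", "a", "intensity", "gamma"]

_TABLE_SCHEMAS = {
    "binding_profile": ["gene_id", "S", "p", "n"],
    "signature": ["gene_id", "e", "p_e", "t"],
}


def read_peaks(path, intensity_column: int = 6) -> pd.DataFrame:
    """Read ChIP-seq peak calls from a narrowPeak / BED6+ file.

    Parameters
    ----------
    path
        Path to a tab-separated BED-like file (gzip-transparent).  Needs at
        least 3 BED fields plus an intensity column.
    intensity_column
        0-based index of the column holding the peak intensity (the maximum
        read depth within the peak).  Defaults to 6, the narrowPeak
        ``signalValue`` field.

    Returns
    -------
    DataFrame with columns chrom, start, end, intensity, summit_offset;
    summit_offset is NaN where the file carries the -1 sentinel (narrowPeak
    column 10) or has fewer than 10 columns.  Rows with start >= end or an
    unparseable intensity are dropped with a logged warning.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=PEAK_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "intensity": float, "summit_offset": float}
        )
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 BED fields, found {raw.shape[1]}")
    if raw.shape[1] <= intensity_column:
        raise ValueError(
            f"{path}: intensity column {intensity_column} out of range "
            f"(file has {raw.shape[1]} columns)"
        )
    peaks = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start": pd.to_numeric(raw[1], errors="coerce"),
            "end": pd.to_numeric(raw[2], errors="coerce"),
            "intensity": pd.to_numeric(raw[intensity_column], errors="coerce"),
        }
    )
    if raw.shape[1] >= 10:
        summit = pd.to_numeric(raw[9], errors="coerce")
        peaks["summit_offset"] = summit.where(summit >= 0)
    else:
        peaks["summit_offset"] = np.nan

    bad = (
        peaks["start"].isna()
        | peaks["end"].isna()
        | peaks["intensity"].isna()
        | (peaks["start"] >= peaks["end"])
        | (peaks["intensity"] < 0)
    )
    # summit must fall inside the interval when present
    with np.errstate(invalid="ignore"):
        bad |= peaks["summit_offset"].notna() & (
            peaks["start"] + peaks["summit_offset"] >= peaks["end"]
        )
    if bad.any():
        logger.warning("read_peaks: rejected %d malformed row(s) in %s", int(bad.sum()), path)
        peaks = peaks[~bad]
    peaks = peaks.reset_index(drop=True)
    peaks["start"] = peaks["start"].astype(np.int64)
    peaks["end"] = peaks["end"].astype(np.int64)
    return peaks


def read_gene_annotation(path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene annotation with one TSS per gene.

    ``tsv`` expects a header ``gene_id  chrom  strand  tss`` (tab-separated,
    0-based tss).  ``gtf`` collapses transcript records per gene to the
    5'-most transcript start: min(start-1) on the + strand, max(end-1) on
    the - strand (GTF is 1-based inclusive).
    """
    if format == "tsv":
        genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"{path}: annotation is missing column(s) {missing}")
        if genes["gene_id"].duplicated().any():
            dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
            raise ValueError(f"{path}: duplicate gene_id(s): {list(dups[:5])}")
        ok = genes["strand"].isin(["+", "-"])
        if not ok.all():
            logger.warning(
                "read_gene_annotation: rejected %d row(s) with unknown strand", int((~ok).sum())
            )
            genes = genes[ok]
        genes = genes[GENE_COLUMNS].reset_index(drop=True)
        genes["tss"] = genes["tss"].astype(np.int64)
        return genes
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_gtf(path) -> pd.DataFrame:
    from gffutils.iterators import DataIterator

    records = []
    n_bad_strand = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype not in ("transcript", "mRNA"):
            continue
        if feat.strand not in ("+", "-"):
            n_bad_strand += 1
            continue
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            n_bad_strand += 1
            continue
        # GTF is 1-based inclusive; 5' end is start on +, end on -
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        records.append((gene_id, feat.seqid, feat.strand, tss))
    if n_bad_strand:
        logger.warning("read_gene_annotation: rejected %d gtf record(s)", n_bad_strand)
    if not records:
        return pd.DataFrame(columns=GENE_COLUMNS).astype({"tss": np.int64})
    df = pd.DataFrame(records, columns=GENE_COLUMNS)

    def _five_prime(group: pd.DataFrame) -> pd.Series:
        strand = group["strand"].iloc[0]
        tss = group["tss"].min() if strand == "+" else group["tss"].max()
        return pd.Series(
            {"chrom": group["chrom"].iloc[0], "strand": strand, "tss": tss}
        )

    out = df.groupby("gene_id", sort=True).apply(_five_prime, include_groups=False)
    out = out.reset_index()
    out["tss"] = out["tss"].astype(np.int64)
    return out[GENE_COLUMNS]


def read_expression_profile(path, tail_mode: str = "two") -> pd.DataFrame:
    """Read a differential-expression profile (gene_id, p[, effect]).

    ``tail_mode`` controls conversion of two-tailed p-values into one-tailed
    ones using the sign of the effect column: for ``up``, p_up = p/2 when
    the effect is positive and 1 - p/2 when negative (mirrored for
    ``down``).  p = 0 is clamped to 1e-300 with a warning; any other p
    outside (0, 1] is a fatal error.
    """
    if tail_mode not in ("two", "up", "down"):
        raise ValueError(f"unknown tail_mode: {tail_mode!r}")
    expr = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "p"):
        if col not in expr.columns:
            raise ValueError(f"{path}: expression profile is missing column '{col}'")
    if expr["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id in expression profile")
    p = expr["p"].astype(float).to_numpy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"{path}: p-values must lie in (0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("read_expression_profile: clamped %d zero p-value(s) to 1e-300", n_zero)
        p = np.where(p == 0, 1e-300, p)
    expr["p"] = p
    if tail_mode != "two":
        if "effect" not in expr.columns:
            raise ValueError(
                f"{path}: tail_mode={tail_mode!r} requires an 'effect' column"
            )
        effect = expr["effect"].astype(float).to_numpy()
        concordant = effect > 0 if tail_mode == "up" else effect < 0
        expr["p"] = np.where(concordant, p / 2.0, 1.0 - p / 2.0)
    expr.attrs["tail_mode"] = tail_mode
    return expr


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    L: int = DEFAULT_WINDOW_HALF_WIDTH,
) -> pd.DataFrame:
    """Link every peak to every gene whose TSS lies within ``L`` bp of it.

    The peak's representative position is its summit (start + summit_offset)
    when called, else the interval midpoint floor((start+end)/2).  The signed
    distance ``a`` is strand-oriented: a = position - tss on the + strand and
    tss - position on the - strand, so negative a always means upstream of
    the TSS.  A peak may link to many genes and a gene to many peaks; genes
    without any link simply have no rows here (they re-enter downstream with
    a peak count of zero).
    """
    if peaks.empty or genes.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)
    pos = np.where(
        peaks["summit_offset"].notna(),
        peaks["start"] + peaks["summit_offset"].fillna(0),
        (peaks["start"] + peaks["end"]) // 2,
    ).astype(np.int64)

    out_gene, out_peak, out_a, out_h = [], [], [], []
    gene_chroms = set(genes["chrom"])
    missing = set(peaks["chrom"]) - gene_chroms
    if missing:
        logger.info(
            "assign_peaks_to_genes: %d chromosome(s) in peaks absent from annotation", len(missing)
        )
    for chrom, gsub in genes.groupby("chrom", sort=False):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        p_idx = np.flatnonzero(mask)
        p_pos = pos[p_idx]
        order = np.argsort(p_pos, kind="stable")
        p_idx, p_pos = p_idx[order], p_pos[order]
        h = peaks["intensity"].to_numpy()[p_idx]
        tss = gsub["tss"].to_numpy()
        lo = np.searchsorted(p_pos, tss - L, side="left")
        hi = np.searchsorted(p_pos, tss + L, side="right")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        take = np.concatenate([np.arange(l, h_) for l, h_ in zip(lo[keep], hi[keep])])
        rep_gene = np.repeat(gsub["gene_id"].to_numpy()[keep], counts[keep])
        rep_tss = np.repeat(tss[keep], counts[keep])
        rep_strand = np.repeat(gsub["strand"].to_numpy()[keep], counts[keep])
        a = p_pos[take] - rep_tss
        a = np.where(rep_strand == "+", a, -a)
        out_gene.append(rep_gene)
        out_peak.append(p_idx[take])
        out_a.append(a)
        out_h.append(h[take])
    if not out_gene:
        return pd.DataFrame(columns=LINK_COLUMNS)
    links = pd.DataFrame(
        {
            "gene_id": np.concatenate(out_gene),
            "peak_index": np.concatenate(out_peak).astype(np.int64),
            "a": np.concatenate(out_a).astype(np.int64),
            "intensity": np.concatenate(out_h).astype(float),
            "gamma": np.nan,
        }
    )
    return links.reset_index(drop=True)


def read_gene_sets(path) -> pd.DataFrame:
    """Read gene sets from a two-column TSV (set_id, gene_id) or a GMT file.

    GMT is detected by the ``.gmt`` extension: one set per line,
    tab-separated, ``name  description  gene1  gene2 ...``.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        rows = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                rows.extend((fields[0], g) for g in fields[2:] if g)
        return pd.DataFrame(rows, columns=["set_id", "gene_id"])
    sets = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set_id", "gene_id"):
        if col not in sets.columns:
            raise ValueError(f"{path}: gene-set table is missing column '{col}'")
    return sets[["set_id", "gene_id"]]


# ---------------------------------------------------------------------------
# generic table / parameter-document round trips


def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "nan"
        return f"{x:.12g}"
    return str(x)


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a tabular result as tab-separated text (12 significant digits)."""
    if kind is not None and kind in _TABLE_SCHEMAS:
        missing = [c for c in _TABLE_SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise ValueError(f"table of kind {kind!r} is missing column(s) {missing}")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, validating its schema."""
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind: {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in _TABLE_SCHEMAS[kind]:
        if col not in df.columns:
            raise ValueError(f"{path}: table of kind {kind!r} is missing column '{col}'")
    return df


def write_params(params: dict, path) -> None:
    """Write model parameters as a flat key/value document."""
    with open(path, "w") as fh:
        for key, value in params.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                value = ",".join(_format_float(v) for v in value)
            else:
                value = _format_float(value)
            fh.write(f"{key}\t{value}\n")


def read_params(path) -> dict:
    """Read a flat key/value parameter document, recovering numeric types."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = _parse_scalar(value)
    return out


def _parse_scalar(value: str):
    if "," in value:
        return [_parse_scalar(v) for v in value.split(",")]
    for caster in (int, float):
        try:
            return caster(value)
        except ValueError:
            continue
    if value in ("True", "False"):
        return value == "True"
    return value
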