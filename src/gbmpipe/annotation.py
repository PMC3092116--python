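"""Transcript annotation handling and exon-transcript incidence matrices.

A gene with *m* measured exons and *n* annotated transcripts is represented
by a binary incidence matrix ``A`` (m x n) whose entry ``A[j, k]`` is 1 iff
exon *j* is part of transcript *k*.  These matrices drive the least-squares
transcript deconvolution in :mod:`gbmpipe.expression`.

Coordinates are 0-based half-open internally; GTF input (1-based closed) is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of a transcript-model table.
MODEL_COLUMNS = ["gene_id", "transcript_id", "exon_id", "chrom", "start", "end", "strand"]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class ExonTranscriptIncidence:
    """Per-gene binary exon x transcript membership matrix."""

    gene_id: str
    exon_ids: list[str]
    transcript_ids: list[str]
    matrix: np.ndarray  # (m, n) of 0/1 floats

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m, n = self.matrix.shape
        if m != len(self.exon_ids) or n != len(self.transcript_ids):
            raise AnnotationError(f"{self.gene_id}: incidence shape does not match labels")
        if m < 1 or n < 1:
            raise AnnotationError(f"{self.gene_id}: empty incidence matrix")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise AnnotationError(f"{self.gene_id}: incidence entries must be 0/1")
        if (self.matrix.sum(axis=1) == 0).any():
            raise AnnotationError(f"{self.gene_id}: exon row with no transcript membership")

    @property
    def rank_deficient(self) -> bool:
        """True when the matrix has column rank < n (transcripts not identifiable)."""
        return int(np.linalg.matrix_rank(self.matrix)) < self.matrix.shape[1]


def _validate_models(models: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MODEL_COLUMNS if c not in models.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    models = models.loc[:, MODEL_COLUMNS].copy()
    models["start"] = models["start"].astype(int)
    models["end"] = models["end"].astype(int)
    if (models["start"] < 0).any() or (models["end"] <= models["start"]).any():
        raise AnnotationError("invalid exon coordinates (need 0 <= start < end)")
    # exons within one transcript must not overlap
    for (g, t), grp in models.groupby(["gene_id", "transcript_id"], sort=False):
        grp = grp.sort_values("start")
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise AnnotationError(f"overlapping exons within transcript {t} of gene {g}")
    return models


def read_annotation(path, fmt: str = "gtf") -> pd.DataFrame:
    """Read transcript models from a GTF-like file or a 4-column TSV.

    Parameters
    ----------
    path : str or Path
        Input file.
    fmt : {"gtf", "tsv"}
        ``gtf``: standard 9-column GTF with ``gene_id``/``transcript_id``/
        ``exon_id`` attributes on ``exon`` features (1-based closed
        coordinates, converted here).  ``tsv``: columns ``gene_id``,
        ``transcript_id``, ``exon_id``, ``coordinates`` where coordinates are
        ``chrom:start-end:strand`` in 0-based half-open convention.

    Returns
    -------
    pandas.DataFrame
        One row per (transcript, exon) with columns :data:`MODEL_COLUMNS`.
    """
    if fmt == "gtf":
        import pyranges as pr

        try:
            gr = pr.read_gtf(str(path))
        except Exception as exc:  # pragma: no cover - parser detail
            raise AnnotationError(f"malformed GTF {path}: {exc}") from exc
        df = gr.df if len(gr) else pd.DataFrame()
        if df.empty:
            logger.warning("annotation file %s contains no exon features", path)
            return pd.DataFrame(columns=MODEL_COLUMNS)
        df = df[df["Feature"] == "exon"]
        for col in ("gene_id", "transcript_id", "exon_id"):
            if col not in df.columns:
                raise AnnotationError(f"GTF {path} lacks required attribute {col}")
        out = pd.DataFrame(
            {
                "gene_id": df["gene_id"].values,
                "transcript_id": df["transcript_id"].values,
                "exon_id": df["exon_id"].values,
                "chrom": df["Chromosome"].astype(str).values,
                "start": df["Start"].values,  # pyranges is already 0-based half-open
                "end": df["End"].values,
                "strand": df["Strand"].astype(str).values if "Strand" in df else "+",
            }
        )
        return _validate_models(out)
    if fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        if raw.empty:
            logger.warning("annotation file %s is empty", path)
            return pd.DataFrame(columns=MODEL_COLUMNS)
        needed = ["gene_id", "transcript_id", "exon_id", "coordinates"]
        if list(raw.columns[:4]) != needed:
            raise AnnotationError(f"TSV annotation must have columns {needed}")
        parts = []
        for lineno, coord in enumerate(raw["coordinates"], start=2):
            try:
                chrom, span, strand = coord.rsplit(":", 2)
                start, end = span.split("-")
                parts.append((chrom, int(start), int(end), strand))
            except Exception as exc:
                raise AnnotationError(f"{path}: malformed coordinates at line {lineno}: {coord!r}") from exc
        coords = pd.DataFrame(parts, columns=["chrom", "start", "end", "strand"])
        out = pd.concat([raw[["gene_id", "transcript_id", "exon_id"]], coords], axis=1)
        return _validate_models(out)
    raise ValueError(f"unknown annotation format: {fmt!r}")


def write_annotation(models: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write transcript models; inverse of :func:`read_annotation`."""
    models = _validate_models(models)
    if fmt == "tsv":
        out = models[["gene_id", "transcript_id", "exon_id"]].copy()
        out["coordinates"] = (
            models["chrom"].astype(str)
            + ":"
            + models["start"].astype(str)
            + "-"
            + models["end"].astype(str)
            + ":"
            + models["strand"].astype(str)
        )
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "gtf":
        with open(path, "w") as fh:
            for row in models.itertuples(index=False):
                attrs = (
                    f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                    f'exon_id "{row.exon_id}";'
                )
                fh.write(
                    f"{row.chrom}\tgbmpipe\texon\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")


def gene_spans(models: pd.DataFrame) -> pd.DataFrame:
    """Genomic span of each gene (union of its exons).

    Returns a frame indexed by gene_id with columns chrom/start/end.
    """
    models = _validate_models(models)
    agg = models.groupby("gene_id").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    multi = models.groupby("gene_id")["chrom"].nunique()
    bad = multi[multi > 1].index.tolist()
    if bad:
        raise AnnotationError(f"genes span multiple chromosomes: {bad}")
    return agg


def exon_gene_map(models: pd.DataFrame) -> pd.Series:
    """Series mapping exon_id -> gene_id (unique exon ids assumed genome-wide)."""
    pairs = models[["exon_id", "gene_id"]].drop_duplicates()
    dup = pairs["exon_id"][pairs["exon_id"].duplicated()]
    if not dup.empty:
        raise AnnotationError(f"exon ids shared across genes: {sorted(set(dup))[:5]}")
    return pairs.set_index("exon_id")["gene_id"]


def build_incidence(
    models: pd.DataFrame, measured_exon_ids=None
) -> dict[str, ExonTranscriptIncidence]:
    """Build one exon x transcript incidence matrix per gene.

    Rows are restricted to exons in ``measured_exon_ids`` (when given);
    measured ids absent from the annotation are dropped with a logged count.
    An exon id occurring within one gene at two different genomic coordinates
    is ambiguous and raises :class:`AnnotationError`.
    """
    models = _validate_models(models)
    measured = None if measured_exon_ids is None else set(measured_exon_ids)
    if measured is not None:
        known = set(models["exon_id"])
        unmapped = measured - known
        if unmapped:
            logger.info("%d measured exon ids not in annotation; dropped", len(unmapped))
    result: dict[str, ExonTranscriptIncidence] = {}
    for gene, grp in models.groupby("gene_id", sort=True):
        coords = grp.groupby("exon_id")[["chrom", "start", "end"]].nunique()
        ambiguous = coords[(coords > 1).any(axis=1)].index.tolist()
        if ambiguous:
            raise AnnotationError(f"duplicate exon id with conflicting coordinates in {gene}: {ambiguous}")
        dup = grp.duplicated(subset=["transcript_id", "exon_id"])
        if dup.any():
            raise AnnotationError(f"duplicate exon id within a transcript of {gene}")
        # stable row order: genomic position, then id
        exons = (
            grp[["exon_id", "start"]]
            .drop_duplicates("exon_id")
            .sort_values(["start", "exon_id"])["exon_id"]
            .tolist()
        )
        if measured is not None:
            exons = [e for e in exons if e in measured]
        transcripts = sorted(grp["transcript_id"].unique())
        if not exons:
            logger.warning("gene %s has no measured exons; skipped", gene)
            continue
        a = np.zeros((len(exons), len(transcripts)))
        e_idx = {e: j for j, e in enumerate(exons)}
        t_idx = {t: k for k, t in enumerate(transcripts)}
        for row in grp.itertuples(index=False):
            if row.exon_id in e_idx:
                a[e_idx[row.exon_id], t_idx[row.transcript_id]] = 1.0
        keep = a.sum(axis=1) > 0
        if not keep.all():  # cannot happen for exons drawn from the annotation itself
            exons = [e for e, k in zip(exons, keep) if k]
            a = a[keep]
        result[gene] = ExonTranscriptIncidence(gene, exons, transcripts, a)
        if result[gene].rank_deficient:
            logger.warning("gene %s incidence matrix is rank-deficient", gene)
    return result
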