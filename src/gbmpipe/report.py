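"""Per-gene result fusion and static browsable report site.

Fuses the stage outputs (differential expression on the gene and exon
platforms, transcript-level deconvolution fold changes, survival screens,
copy-number gain/loss frequencies, methylation betas and the
amplification-expression integration) into one row per gene, and renders a
self-contained static HTML site: a sortable index colored by fold change
(red = up, green = down) and P-value strength, plus per-gene subpages with
per-transcript rows, Kaplan-Meier curves for features with survival P < 0.01
and external database link templates.  Rendering never recomputes: every
number on the site equals the corresponding table value.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column schema of the fused gene table (the "13 fields")
REPORT_COLUMNS = [
    "gene_name",
    "gene_fc",
    "exon_gene_fc",
    "transcript_fc_min",
    "transcript_fc_max",
    "transcript_survival_p",
    "gene_survival_p",
    "snp_survival_p",
    "gain_freq",
    "loss_freq",
    "methylation_beta",
    "integration_p",
    "n_transcripts",
]

KM_GATE_P = 0.01

URL_TEMPLATES = {
    "GeneCards": "https://www.genecards.org/cgi-bin/carddisp.pl?gene={gene}",
    "Ensembl": "https://www.ensembl.org/Homo_sapiens/Gene/Summary?g={gene}",
    "KEGG": "https://www.genome.jp/dbget-bin/www_bget?hsa:{gene}",
    "PINA": "https://omics.bjcancer.org/pina/interactome.do?gene={gene}",
}


def _canonical_index(df: pd.DataFrame | pd.Series, stage: str):
    """Upper-case gene ids; error on duplicates after canonicalization."""
    idx = df.index.astype(str)
    upper = idx.str.upper()
    if (upper != idx).any():
        logger.info("%s: %d gene ids canonicalized to upper case", stage, int((upper != idx).sum()))
    out = df.copy()
    out.index = upper
    dup = out.index[out.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{stage}: conflicting duplicate gene ids after canonicalization: {dup}")
    return out


def build_gene_table(
    gene_de: pd.DataFrame | None = None,
    exon_gene_de: pd.DataFrame | None = None,
    transcript_de: pd.DataFrame | None = None,
    transcript_genes: pd.Series | None = None,
    transcript_survival: pd.DataFrame | None = None,
    gene_survival: pd.DataFrame | None = None,
    snp_results: pd.DataFrame | None = None,
    marker_genes: pd.Series | None = None,
    cn_frequencies: pd.DataFrame | None = None,
    methylation_beta: pd.Series | None = None,
    integration_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outer-join all stage outputs into one row per gene.

    Missing fields stay missing (rendered blank, never 0).  The field ->
    source-stage provenance map is stored in ``table.attrs["provenance"]``.
    """
    pieces: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}

    def add(column: str, series: pd.Series, stage: str) -> None:
        pieces[column] = _canonical_index(series, stage)
        provenance[column] = stage

    if gene_de is not None:
        add("gene_fc", gene_de["fc"], "gene_expression_de")
    if exon_gene_de is not None:
        add("exon_gene_fc", exon_gene_de["fc"], "exon_platform_de")
    if transcript_de is not None:
        if transcript_genes is None:
            raise ValueError("transcript_de requires a transcript -> gene map")
        tg = transcript_genes.reindex(transcript_de.index)
        grouped = transcript_de["fc"].groupby(tg.str.upper())
        add("transcript_fc_min", grouped.min(), "transcript_deconvolution")
        add("transcript_fc_max", grouped.max(), "transcript_deconvolution")
        add("n_transcripts", grouped.size(), "transcript_deconvolution")
    if transcript_survival is not None:
        if transcript_genes is None:
            raise ValueError("transcript_survival requires a transcript -> gene map")
        tg = transcript_genes.reindex(transcript_survival.index)
        add("transcript_survival_p", transcript_survival["p"].groupby(tg.str.upper()).min(), "transcript_survival")
    if gene_survival is not None:
        add("gene_survival_p", gene_survival["p"], "gene_survival")
    if snp_results is not None:
        if marker_genes is None:
            raise ValueError("snp_results requires a marker -> gene map")
        mg = marker_genes.reindex(snp_results.index)
        add("snp_survival_p", snp_results["p"].groupby(mg.str.upper()).min(), "snp_survival")
    if cn_frequencies is not None:
        add("gain_freq", cn_frequencies["gain_freq"], "copy_number")
        pieces["loss_freq"] = _canonical_index(cn_frequencies["loss_freq"], "copy_number")
        provenance["loss_freq"] = "copy_number"
    if methylation_beta is not None:
        add("methylation_beta", methylation_beta, "methylation")
    if integration_results is not None:
        add("integration_p", integration_results["p_perm"], "integration")

    if not pieces:
        raise ValueError("no stage outputs supplied")
    table = pd.DataFrame(pieces)
    table.index.name = "gene_id"
    table["gene_name"] = table.index
    provenance["gene_name"] = "identifier"
    table = table.reindex(columns=REPORT_COLUMNS)
    table.attrs["provenance"] = provenance
    return table


def _fc_color(fc) -> str:
    """Two-color log-ratio ramp saturating at |log2 FC| = 3 (red up, green down)."""
    if fc is None or not np.isfinite(fc) or fc <= 0:
        return "#ffffff"
    lf = math.log2(fc)
    i = min(abs(lf) / 3.0, 1.0)
    fade = int(round(255 * (1 - i)))
    return f"#ff{fade:02x}{fade:02x}" if lf > 0 else f"#{fade:02x}ff{fade:02x}"


def _p_color(p) -> str:
    if p is None or not np.isfinite(p):
        return "#ffffff"
    if p < 0.001:
        return "#ff6666"
    if p < 0.01:
        return "#ff9999"
    if p < 0.05:
        return "#ffcccc"
    return "#ffffff"


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return ""
    if isinstance(value, float):
        return f"{value:.3g}"
    return str(value)


_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<link rel="stylesheet" href="$css"></head>
<body><h1>$title</h1>
$body
$script
</body></html>
"""
)

_SORT_JS = """<script>
function sortTable(col) {
  var table = document.getElementById('genes');
  var rows = Array.from(table.tBodies[0].rows);
  var asc = table.dataset.sortcol == col ? table.dataset.asc != '1' : true;
  rows.sort(function(a, b) {
    var x = a.cells[col].dataset.v, y = b.cells[col].dataset.v;
    if (x === '' || x === undefined) return 1;
    if (y === '' || y === undefined) return -1;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return asc ? nx - ny : ny - nx;
    return asc ? x.localeCompare(y) : y.localeCompare(x);
  });
  rows.forEach(function(r) { table.tBodies[0].appendChild(r); });
  table.dataset.sortcol = col; table.dataset.asc = asc ? '1' : '0';
}
</script>"""

_CSS = """body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 2px 6px; font-size: 13px; }
th { cursor: pointer; background: #eee; }
img { max-width: 480px; }
"""


def render_website(
    table: pd.DataFrame,
    out_dir,
    transcript_table: pd.DataFrame | None = None,
    km_plots: dict | None = None,
    sort_key: str = "transcript_survival_p",
) -> Path:
    """Render the fused gene table as a static, self-contained site.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`build_gene_table`.
    transcript_table : DataFrame, optional
        Per-transcript rows (columns ``gene_id``, ``fc``, ``p``) shown on
        gene subpages.
    km_plots : dict, optional
        Feature id -> path of a pre-rendered Kaplan-Meier SVG.  A plot is
        embedded only when the feature's survival P is below 0.01.
    sort_key : str
        Initial sort column (ascending); default best transcript survival P.

    Returns the path of the written index page.
    """
    if table.empty:
        raise ValueError("gene table is empty")
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "km").mkdir(exist_ok=True)
    (out / "style.css").write_text(_CSS)

    ordered = table.sort_values(sort_key, na_position="last") if sort_key in table.columns else table
    ordered.to_csv(out / "gene_report.tsv", sep="\t")
    (out / "gene_report.json").write_text(
        json.dumps(json.loads(ordered.to_json(orient="index")), indent=1)
    )

    km_plots = km_plots or {}
    header = "".join(
        f'<th onclick="sortTable({i})">{c}</th>' for i, c in enumerate(["gene_id", *REPORT_COLUMNS])
    )
    body_rows = []
    for gene, row in ordered.iterrows():
        cells = [f'<td data-v="{gene}"><a href="genes/{gene}.html">{gene}</a></td>']
        for col in REPORT_COLUMNS:
            v = row[col]
            if col.endswith("_fc") or col.startswith("transcript_fc"):
                style = f' style="background:{_fc_color(v)}"'
            elif col.endswith("_p"):
                style = f' style="background:{_p_color(v)}"'
            elif col in ("gain_freq", "loss_freq") and np.isfinite(v) and v > 0:
                style = f' style="background:{_fc_color(2 ** (v * 3) if col == "gain_freq" else 2 ** (-v * 3))}"'
            else:
                style = ""
            cells.append(f'<td data-v="{_fmt(v)}"{style}>{_fmt(v)}</td>')
        body_rows.append("<tr>" + "".join(cells) + "</tr>")
    index_body = (
        f'<table id="genes" data-sortcol="" data-asc=""><thead><tr>{header}</tr></thead>'
        f'<tbody>{"".join(body_rows)}</tbody></table>'
        f"<p>{len(ordered)} genes; initial sort: {sort_key} ascending. Click a header to re-sort.</p>"
    )
    index_path = out / "index.html"
    index_path.write_text(_PAGE.substitute(title="Gene report", css="style.css", body=index_body, script=_SORT_JS))

    for gene, row in ordered.iterrows():
        parts = ["<table><tbody>"]
        for col in REPORT_COLUMNS:
            parts.append(f"<tr><th>{col}</th><td>{_fmt(row[col])}</td></tr>")
        parts.append("</tbody></table>")
        parts.append("<h2>External links</h2><ul>")
        for name, tpl in URL_TEMPLATES.items():
            parts.append(f'<li><a href="{tpl.format(gene=gene)}">{name}</a></li>')
        parts.append("</ul>")
        if transcript_table is not None:
            sub = transcript_table[transcript_table["gene_id"].str.upper() == gene]
            if not sub.empty:
                parts.append("<h2>Transcripts</h2><table><thead><tr><th>transcript</th><th>FC</th><th>survival P</th></tr></thead><tbody>")
                for tid, trow in sub.iterrows():
                    parts.append(
                        f"<tr><td>{tid}</td><td style=\"background:{_fc_color(trow.get('fc'))}\">{_fmt(trow.get('fc'))}</td>"
                        f"<td style=\"background:{_p_color(trow.get('p'))}\">{_fmt(trow.get('p'))}</td></tr>"
                    )
                parts.append("</tbody></table>")
                for tid, trow in sub.iterrows():
                    p = trow.get("p")
                    if tid in km_plots and p is not None and np.isfinite(p) and p < KM_GATE_P:
                        src = Path(km_plots[tid])
                        dest = out / "km" / src.name
                        if src.resolve() != dest.resolve():
                            dest.write_bytes(src.read_bytes())
                        parts.append(f"<h3>Kaplan-Meier: {tid} (P = {_fmt(p)})</h3>")
                        parts.append(f'<img src="../km/{src.name}" alt="KM {tid}">')
        (out / "genes" / f"{gene}.html").write_text(
            _PAGE.substitute(title=f"Gene {gene}", css="../style.css", body="".join(parts), script="")
        )
    return index_path
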