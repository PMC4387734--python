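"""Render comparison views to files.

Three renderers mirror the three comparison views:

* :func:`render_pairwise` — scatter-matrix image of all method pairs
  (-log10 scale by default) plus the correlation coefficients as TSV;
* :func:`render_detail` — two-method scatter colored by Venn class
  (red = A only, blue = B only, purple = both, grey = neither), a
  two-set Venn diagram, the threshold-sweep TSV, and the four marker
  lists as TSV;
* :func:`render_multi` — color-coded HTML significance table with a
  plain TSV twin.

Rendering is a pure function of its inputs: identical inputs produce
byte-identical TSV and HTML.  Images are written as PNG and SVG with a
fixed hash salt so their content is stable too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from jinja2 import Environment
from matplotlib.patches import Circle

from .core_model import ResultMatrix
from .multi_compare import INDEPENDENCE_CAUTION, MultiTable
from .pair_compare import CorrelationMatrix, PairClassification, SweepTable, neglog10

__all__ = ["ReportBundle", "render_pairwise", "render_detail", "render_multi"]

matplotlib.rcParams["svg.hashsalt"] = "pvcomp"

#: Venn-class colors: A only, B only, both, neither.
CLASS_COLORS = {"only_a": "#d62728", "only_b": "#1f77b4", "both": "#7d3c98", "neither": "#bbbbbb"}


@dataclass(frozen=True)
class ReportBundle:
    """Manifest of files produced by one render call."""

    output_dir: Path
    files: tuple[tuple[str, str], ...]  # (file name, kind in {image, tsv, html})

    def paths(self) -> list[Path]:
        return [self.output_dir / name for name, _ in self.files]


def _ensure_dir(out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _fmt(v: float, digits: int = 6) -> str:
    return "NA" if np.isnan(v) else f"{v:.{digits}g}"


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _save_figure(fig: plt.Figure, out: Path, stem: str) -> list[tuple[str, str]]:
    produced = []
    for ext in ("png", "svg"):
        name = f"{stem}.{ext}"
        fig.savefig(out / name, metadata={"Date": None} if ext == "svg" else None)
        produced.append((name, "image"))
    plt.close(fig)
    return produced


def render_pairwise(
    c: CorrelationMatrix, m: ResultMatrix, out_dir: str | Path
) -> ReportBundle:
    """Scatter-matrix image (one panel per method pair, annotated with r)
    plus the K x K correlation table as TSV."""
    if m.n_markers == 0:
        raise ValueError("cannot render pairwise view of an empty marker set")
    if m.n_methods < 2:
        raise ValueError("pairwise view requires at least 2 methods")
    out = _ensure_dir(out_dir)
    K = m.n_methods
    values = m.pvalues
    if c.transform == "neglog10":
        with np.errstate(divide="ignore"):
            values = neglog10(values)
        axis_label = "-log10 p"
    else:
        axis_label = "p"

    fig, axes = plt.subplots(K, K, figsize=(2.2 * K, 2.2 * K), squeeze=False)
    for i in range(K):
        for j in range(K):
            ax = axes[i][j]
            if i == j:
                ax.text(0.5, 0.5, c.method_names[i], ha="center", va="center", fontsize=10)
                ax.set_xticks([])
                ax.set_yticks([])
                continue
            ok = ~np.isnan(values[:, j]) & ~np.isnan(values[:, i])
            ax.scatter(values[ok, j], values[ok, i], s=4, alpha=0.5, color="#1f77b4")
            r = c.r[i, j]
            ax.set_title("r = " + ("NA" if np.isnan(r) else f"{r:.3f}"), fontsize=8)
            ax.tick_params(labelsize=6)
    fig.suptitle(f"Pairwise comparison ({axis_label}, {c.method})", fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.96))
    files = _save_figure(fig, out, "pairwise_scatter")

    rows = []
    for i, name in enumerate(c.method_names):
        rows.append([name] + [_fmt(c.r[i, j]) for j in range(K)])
    _write_tsv(out / "correlation.tsv", ["method", *c.method_names], rows)
    files.append(("correlation.tsv", "tsv"))
    return ReportBundle(out, tuple(files))


def _draw_venn(ax: plt.Axes, pc: PairClassification) -> None:
    # two-set Venn drawn directly; region labels are the partition counts
    ax.add_patch(Circle((-0.35, 0), 0.72, alpha=0.45, color=CLASS_COLORS["only_a"]))
    ax.add_patch(Circle((0.35, 0), 0.72, alpha=0.45, color=CLASS_COLORS["only_b"]))
    ax.text(-0.66, 0, str(len(pc.only_a)), ha="center", va="center", fontsize=12)
    ax.text(0.66, 0, str(len(pc.only_b)), ha="center", va="center", fontsize=12)
    ax.text(0, 0, str(len(pc.both)), ha="center", va="center", fontsize=12)
    ax.text(-0.55, 0.82, pc.method_a, ha="center", fontsize=10)
    ax.text(0.55, 0.82, pc.method_b, ha="center", fontsize=10)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.0, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")


def render_detail(
    pc: PairClassification,
    sweep: SweepTable,
    m: ResultMatrix,
    out_dir: str | Path,
    transform: str = "neglog10",
) -> ReportBundle:
    """Two-method detail view: classified scatter, Venn, sweep, marker lists."""
    out = _ensure_dir(out_dir)
    m.require_methods([pc.method_a, pc.method_b])
    pa = m.data[pc.method_a].to_numpy(dtype=float)
    pb = m.data[pc.method_b].to_numpy(dtype=float)
    if transform == "neglog10":
        with np.errstate(divide="ignore"):
            pa, pb = neglog10(pa), neglog10(pb)
        axis_label = "-log10 p"
    else:
        axis_label = "p"
    index = {marker: pos for pos, marker in enumerate(m.marker_ids)}

    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, label in [
        ("neither", "neither"),
        ("only_a", f"{pc.method_a} only"),
        ("only_b", f"{pc.method_b} only"),
        ("both", "both"),
    ]:
        ids = getattr(pc, cls)
        pos = [index[i] for i in ids]
        ax.scatter(pa[pos], pb[pos], s=6, alpha=0.6, color=CLASS_COLORS[cls], label=label)
    ax.set_xlabel(f"{pc.method_a} ({axis_label})")
    ax.set_ylabel(f"{pc.method_b} ({axis_label})")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    files = _save_figure(fig, out, "detail_scatter")

    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    _draw_venn(ax, pc)
    files.extend(_save_figure(fig, out, "venn"))

    _write_tsv(
        out / "sweep.tsv",
        ["cutoff", "n_both", "n_only_a", "n_only_b", "n_neither"],
        [
            [_fmt(r.cutoff), str(r.n_both), str(r.n_only_a), str(r.n_only_b), str(r.n_neither)]
            for r in sweep.rows
        ],
    )
    files.append(("sweep.tsv", "tsv"))

    raw_a = m.data[pc.method_a]
    raw_b = m.data[pc.method_b]
    for cls in ("both", "only_a", "only_b", "neither"):
        ids = getattr(pc, cls)
        name = f"markers_{cls}.tsv"
        _write_tsv(
            out / name,
            ["marker", f"p_{pc.method_a}", f"p_{pc.method_b}"],
            [[i, _fmt(float(raw_a.loc[i]), 12), _fmt(float(raw_b.loc[i]), 12)] for i in ids],
        )
        files.append((name, "tsv"))
    return ReportBundle(out, tuple(files))


_MULTI_TEMPLATE = Environment(autoescape=True).from_string(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Multi-method significance table</title>
<style>
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 3px 8px; font-size: 12px; text-align: right; }
th { background: #eee; }
td.marker { text-align: left; font-weight: bold; }
p.caution { color: #8a6d3b; background: #fcf8e3; padding: 8px; max-width: 60em; }
</style>
</head>
<body>
<h1>Multi-method significance table</h1>
<p>Methods: {{ methods | join(', ') }}. Red = significant at the method's
threshold, green = not; deeper color means a smaller p-value.</p>
<table>
<tr><th>marker</th><th>average p</th>{% for name in methods %}<th>{{ name }}
(&alpha;={{ alphas[name] }})</th>{% endfor %}{% if has_combined %}<th>combined p</th>{% endif %}</tr>
{% for row in rows %}<tr><td class="marker">{{ row.marker }}</td><td>{{ row.avg }}</td>
{%- for cell in row.cells %}<td style="background-color: {{ cell.css }}">{{ cell.text }}</td>{% endfor %}
{%- if has_combined %}<td>{{ row.combined }}</td>{% endif %}</tr>
{% endfor %}</table>
{% if has_combined %}<p class="caution">{{ caution }}</p>{% endif %}
</body>
</html>
"""
)


def render_multi(t: MultiTable, out_dir: str | Path) -> ReportBundle:
    """HTML heat table (inline styles, no external assets) + TSV twin.

    The TSV carries the p-values, significance flags, average p and —
    when combination is on — the combined p per marker; the HTML footer
    then carries the independence caution.
    """
    out = _ensure_dir(out_dir)
    methods = t.selected_methods
    has_combined = t.combined_p is not None

    html_rows = []
    for marker in t.marker_ids:
        cells = []
        for name in methods:
            p = float(t.pvalues.loc[marker, name])
            color = t.colors.loc[marker, name]
            cells.append(
                {
                    "css": "#ffffff" if color is None else color.css(),
                    "text": _fmt(p, 4),
                }
            )
        html_rows.append(
            {
                "marker": marker,
                "avg": _fmt(float(t.average_p.loc[marker]), 4),
                "cells": cells,
                "combined": _fmt(float(t.combined_p.loc[marker]), 4) if has_combined else "",
            }
        )
    html = _MULTI_TEMPLATE.render(
        methods=methods,
        alphas={name: _fmt(t.thresholds.alpha_for(name)) for name in methods},
        rows=html_rows,
        has_combined=has_combined,
        caution=INDEPENDENCE_CAUTION,
    )
    (out / "multi_table.html").write_text(html, encoding="utf-8")
    files = [("multi_table.html", "html")]

    header = ["marker", "average_p"]
    for name in methods:
        header += [f"p_{name}", f"sig_{name}"]
    if has_combined:
        header.append("combined_p")
    rows = []
    for marker in t.marker_ids:
        row = [marker, _fmt(float(t.average_p.loc[marker]), 12)]
        for name in methods:
            row.append(_fmt(float(t.pvalues.loc[marker, name]), 12))
            row.append(str(int(bool(t.significant.loc[marker, name]))))
        if has_combined:
            row.append(_fmt(float(t.combined_p.loc[marker]), 12))
        rows.append(row)
    _write_tsv(out / "multi_table.tsv", header, rows)
    files.append(("multi_table.tsv", "tsv"))
    return ReportBundle(out, tuple(files))
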