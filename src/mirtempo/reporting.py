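"""Rendering of the diagnostic plot, clustered heatmaps and the HTML index.

Heatmap rows are ordered by agglomerative hierarchical clustering on the
Euclidean distance matrix of the NQT profiles.  The clusterer is a small
naive implementation so that tie-breaking is fully deterministic: at each
step the pair of clusters with the smallest linkage distance merges, ties
resolved by the smallest (older) cluster ids, and the displayed leaf order
is the preorder traversal of the merge tree visiting the older child
first.

Rendering never aborts the statistical pipeline; failures are collected
into the bundle and surfaced at exit.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DimensionMismatchError, UnwritablePathError
from .matrix_io import write_heatmap_text
from .normalization import NormalizedMatrix
from .replicate_qc import CollapsedMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Paths of every artifact a run emitted."""

    output_dir: Path
    html_index: Path | None = None
    pngs: list[Path] = field(default_factory=list)
    tsvs: list[Path] = field(default_factory=list)
    cluster_orders: dict[str, list[int]] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


def euclidean_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise L2 distances between row vectors."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(rows, metric="euclidean"))


def hierarchical_cluster(
    d: np.ndarray, linkage: str = "complete"
) -> tuple[list[int], list[tuple[int, int, float]]]:
    """Agglomerative clustering of a distance matrix.

    Returns ``(leaf_order, merges)``: the display order of the original
    row indices and the merge list ``(id_a, id_b, height)`` where leaves
    are ids ``0..n-1`` and each merge creates id ``n, n+1, ...``.
    Deterministic: ties in the minimum linkage distance are broken by the
    lexicographically smallest (id_a, id_b) pair.  Inter-cluster distances
    are maintained with Lance-Williams updates, so each merge costs O(n).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 1:
        raise ValueError("distance matrix must be square and non-empty")
    if n == 1:
        return [0], []

    # working matrix indexed by active slot; slot -> current cluster id
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    slot_id = list(range(n))
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    next_id = n

    for _ in range(n - 1):
        # find minimum distance among active pairs; tie-break on smallest
        # (id_a, id_b) with ids ordered so id_a < id_b
        sub = np.where(active[:, None] & active[None, :], work, np.inf)
        dist = float(sub.min())
        cand = np.argwhere(sub == dist)
        pairs = []
        for i, j in cand:
            if i < j:
                a, b = sorted((slot_id[i], slot_id[j]))
                pairs.append((a, b, i, j))
        a, b, i, j = min(pairs)

        # Lance-Williams update into slot i; retire slot j
        other = active.copy()
        other[[i, j]] = False
        if linkage == "complete":
            new_row = np.maximum(work[i], work[j])
        elif linkage == "single":
            new_row = np.minimum(work[i], work[j])
        elif linkage == "average":
            new_row = (sizes[i] * work[i] + sizes[j] * work[j]) / (
                sizes[i] + sizes[j]
            )
        else:
            raise ValueError(f"unknown linkage {linkage!r}")
        work[i, other] = new_row[other]
        work[other, i] = new_row[other]
        work[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        children[next_id] = (a, b)
        merges.append((a, b, dist))
        slot_id[i] = next_id
        next_id += 1

    def preorder(node: int) -> list[int]:
        stack, order = [node], []
        while stack:
            cur = stack.pop()
            if cur < n:
                order.append(cur)
            else:
                ca, cb = children[cur]
                stack.append(cb)
                stack.append(ca)
        return order

    return preorder(next_id - 1), merges


def render_heatmap(
    feature_names: list[str],
    values: np.ndarray,
    title: str,
    path: str | Path,
    linkage: str = "complete",
    column_labels: list[str] | None = None,
) -> tuple[Path, Path | None, list[int]]:
    """Clustered heatmap PNG plus its companion TSV.

    Rows are reordered by :func:`hierarchical_cluster` leaf order; an empty
    subset renders a placeholder image and writes no TSV.  Returns
    ``(png_path, tsv_path_or_None, leaf_order)``.
    """
    path = Path(path)
    values = np.asarray(values, dtype=float)
    tsv_path = path.with_suffix(".tsv")

    if len(feature_names) == 0:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.text(0.5, 0.5, "no significant features", ha="center", va="center",
                fontsize=14)
        ax.set_axis_off()
        ax.set_title(title)
        _save_fig(fig, path)
        write_heatmap_text([], np.empty((0, 0)), tsv_path)  # logs the warning
        return path, None, []

    if values.ndim != 2 or values.shape[0] != len(feature_names):
        raise DimensionMismatchError(
            f"heatmap values shape {values.shape} vs {len(feature_names)} names"
        )
    order, _ = hierarchical_cluster(euclidean_distance_matrix(values), linkage)
    ordered = values[order]
    ordered_names = [feature_names[i] for i in order]
    if column_labels is None:
        column_labels = [f"t{j + 1}" for j in range(values.shape[1])]

    height = max(2.5, 0.22 * len(ordered_names) + 1.5)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(column_labels) + 2), height))
    vmax = float(np.max(np.abs(ordered))) or 1.0
    im = ax.imshow(ordered, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(column_labels)), column_labels)
    if len(ordered_names) <= 60:
        ax.set_yticks(range(len(ordered_names)), ordered_names, fontsize=6)
    else:
        ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="NQT score")
    _save_fig(fig, path)

    write_heatmap_text(ordered_names, ordered, tsv_path, column_labels)
    return path, tsv_path, order


def render_raw_vs_nqt(
    raw: CollapsedMatrix, nm: NormalizedMatrix, path: str | Path
) -> Path:
    """Side-by-side distribution plot: collapsed raw counts vs NQT scores."""
    path = Path(path)
    if raw.values.shape != nm.nqt.shape:
        raise DimensionMismatchError(
            f"raw {raw.values.shape} vs normalized {nm.nqt.shape}"
        )
    T = raw.n_timepoints
    labels = [f"t{j + 1}" for j in range(T)]
    fig, (ax_raw, ax_nqt) = plt.subplots(1, 2, figsize=(10, 4))
    ax_raw.boxplot([raw.values[:, j] for j in range(T)], tick_labels=labels)
    ax_raw.set_title("raw counts (collapsed)")
    ax_raw.set_ylabel("count")
    ax_nqt.boxplot([nm.nqt[:, j] for j in range(T)], tick_labels=labels)
    ax_nqt.set_title("NQT scores")
    ax_nqt.set_ylabel("NQT score")
    fig.suptitle("Before vs after normal quantile transformation")
    _save_fig(fig, path)
    return path


def _save_fig(fig, path: Path) -> None:
    try:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {path}: {exc}") from exc
    finally:
        plt.close(fig)


_HTML_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>miRNA temporal differential expression report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
h1 {{ border-bottom: 2px solid #444; }}
table.params td {{ padding: 0.15em 0.8em; }}
img {{ max-width: 100%; border: 1px solid #ccc; margin: 0.5em 0; }}
.missing {{ color: #888; font-style: italic; }}
</style>
</head>
<body>
<h1>miRNA temporal differential expression report</h1>
<h2>Run parameters</h2>
<table class="params">
{params}
</table>
<h2>Raw vs normalized distributions</h2>
{raw_vs_nqt}
<h2>Linearly differentially expressed miRNAs (P &lt; {alpha})</h2>
{linear_heatmap}
<h2>Non-linearly differentially expressed miRNAs (P &lt; {alpha})</h2>
{nonlinear_heatmap}
<h2>Tables</h2>
<ul>
{tables}
</ul>
{warnings}
</body>
</html>
"""


def render_html(
    bundle: ReportBundle,
    config_echo: dict,
    sections: dict[str, Path | None],
    tables: list[Path],
    warnings: list[str] | None = None,
) -> Path:
    """Write the single-page HTML index ``mirnata.html``.

    Every image and table is referenced by a path relative to the output
    directory; missing artifacts render as placeholder notes rather than
    broken links.
    """
    out = bundle.output_dir / "mirnata.html"

    def img_or_note(p: Path | None, note: str) -> str:
        if p is not None and p.exists():
            rel = p.relative_to(bundle.output_dir)
            return f'<img src="{html.escape(str(rel))}" alt="{html.escape(note)}">'
        return f'<p class="missing">{html.escape(note)}: not available</p>'

    params = "\n".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in config_echo.items()
    )
    table_items = []
    for t in tables:
        if t is not None and t.exists():
            rel = t.relative_to(bundle.output_dir)
            table_items.append(
                f'<li><a href="{html.escape(str(rel))}">{html.escape(t.name)}</a></li>'
            )
    warn_html = ""
    if warnings:
        items = "\n".join(f"<li>{html.escape(w)}</li>" for w in warnings)
        warn_html = f"<h2>Warnings</h2>\n<ul>\n{items}\n</ul>"

    page = _HTML_PAGE.format(
        params=params,
        alpha=html.escape(str(config_echo.get("alpha", ""))),
        raw_vs_nqt=img_or_note(sections.get("raw_vs_nqt"), "raw vs NQT plot"),
        linear_heatmap=img_or_note(sections.get("linear_heatmap"),
                                   "linear heatmap"),
        nonlinear_heatmap=img_or_note(sections.get("nonlinear_heatmap"),
                                      "non-linear heatmap"),
        tables="\n".join(table_items) or '<li class="missing">none</li>',
        warnings=warn_html,
    )
    try:
        out.write_text(page, encoding="utf-8")
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {out}: {exc}") from exc
    bundle.html_index = out
    return out
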