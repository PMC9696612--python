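"""Family-level statistics and motif-pattern grouping.

Covers the descriptive layer of an R-gene survey: agglomerative clustering
of the motif presence/absence matrix (Jaccard distance, average linkage by
default, cut at k = 8 groups to mirror the conventional eight-pattern
report), Pearson correlations between per-genome counts (clusters vs
paralogs, orthogroups vs family size), and per-family count summaries
formatted as "mean (min–max)".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

__all__ = [
    "Dendrogram",
    "hier_cluster",
    "pearson",
    "family_stats",
    "render_report",
    "plot_presence_heatmap",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree over presence-matrix rows."""

    labels: list[str]
    linkage_matrix: np.ndarray
    distance: str
    linkage_method: str

    def cut(self, k: int | None = None, h: float | None = None) -> dict[str, int]:
        """Group assignment at k groups or at merge height h."""
        if (k is None) == (h is None):
            raise ValueError("specify exactly one of k or h")
        if k is not None:
            if k > len(self.labels):
                raise ValueError(f"k={k} exceeds {len(self.labels)} rows")
            assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        else:
            assign = fcluster(self.linkage_matrix, t=h, criterion="distance")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hier_cluster(
    matrix: pd.DataFrame,
    distance: str = "jaccard",
    linkage_method: str = "average",
    k: int | None = None,
    h: float | None = None,
) -> tuple[Dendrogram, dict[str, int] | None]:
    """Agglomerative clustering of binary presence rows.

    Rows are sorted by label before distance computation so tie-breaking is
    deterministic.  Returns the dendrogram plus group labels when a cut
    (``k`` or ``h``) is requested.
    """
    if distance not in ("jaccard", "hamming"):
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    matrix = matrix.sort_index()
    data = matrix.to_numpy(dtype=bool)
    dists = pdist(data, metric=distance)
    Z = linkage(dists, method=linkage_method)
    dend = Dendrogram(
        labels=list(matrix.index),
        linkage_matrix=Z,
        distance=distance,
        linkage_method=linkage_method,
    )
    groups = dend.cut(k=k, h=h) if (k is not None or h is not None) else None
    return dend, groups


def pearson(x, y) -> float:
    """Product-moment correlation, computed from the closed form.

    Requires equal lengths >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float((dx * dy).sum() / (sx * sy))


def _format_summary(mean: float, lo: float, hi: float) -> str:
    def fmt(v: float) -> str:
        return f"{v:g}" if abs(v - round(v)) > 1e-9 else f"{int(round(v))}"

    return f"{fmt(mean)} ({fmt(lo)}–{fmt(hi)})"


def family_stats(
    counts: pd.DataFrame,
    grouping: dict[str, str],
) -> pd.DataFrame:
    """Per-family summaries of per-genome counts.

    ``counts`` is indexed by genome/species with numeric columns (e.g.
    orthogroups, paralogs, clusters); ``grouping`` maps genome → family.
    Each cell of the result reports the arithmetic mean with the min–max
    range, formatted "mean (min–max)"; numeric columns are kept alongside.
    """
    missing = [sp for sp in counts.index if sp not in grouping]
    if missing:
        raise ValueError(f"species without family assignment: {missing}")
    fam = counts.copy()
    fam["__family"] = [grouping[sp] for sp in counts.index]
    rows = []
    for family, sub in fam.groupby("__family", sort=True):
        row: dict[str, object] = {"family": family, "n_genomes": len(sub)}
        for col in counts.columns:
            v = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(v.mean())
            row[f"{col}_min"] = float(v.min())
            row[f"{col}_max"] = float(v.max())
            row[col] = _format_summary(v.mean(), v.min(), v.max())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("family")
    for col in counts.columns:
        bad = out[f"{col}_mean"] < out[f"{col}_min"] - 1e-12
        bad |= out[f"{col}_mean"] > out[f"{col}_max"] + 1e-12
        assert not bad.any()
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_report(
    outdir: str | Path,
    summary: dict,
    input_paths: Iterable[str | Path] = (),
    tables: dict[str, pd.DataFrame] | None = None,
    newick: str | None = None,
) -> Path:
    """Assemble a run report: summary JSON (+ referenced input checksums),
    optional TSV tables and a newick dendrogram.

    Sections absent from ``summary``/``tables`` are listed under
    ``missing_sections`` rather than silently dropped.  Output is
    deterministic for identical inputs (sorted keys, no timestamps).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expected = ["cohort", "classification", "clusters", "orthology", "motifs",
                "profiles"]
    report = {
        "summary": summary,
        "missing_sections": [s for s in expected if s not in summary],
        "inputs": {
            str(p): _sha256(Path(p)) for p in sorted(map(str, input_paths))
        },
        "artifacts": {},
    }
    if tables:
        for name in sorted(tables):
            path = outdir / f"{name}.tsv"
            tables[name].to_csv(path, sep="\t")
            report["artifacts"][name] = _sha256(path)
    if newick is not None:
        path = outdir / "dendrogram.nwk"
        path.write_text(newick + "\n")
        report["artifacts"]["dendrogram"] = _sha256(path)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report_path


def plot_presence_heatmap(matrix: pd.DataFrame, path: str | Path,
                          distance: str = "jaccard",
                          linkage_method: str = "average") -> None:
    """Optional clustered heatmap of the presence matrix (never load-bearing)."""
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns

    g = sns.clustermap(
        matrix, metric=distance, method=linkage_method, col_cluster=False,
        cmap="Greys", figsize=(max(6, matrix.shape[1] / 4),
                               max(6, matrix.shape[0] / 6)),
    )
    g.savefig(path, dpi=120)
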