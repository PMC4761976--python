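"""25-ROI connectivity matrices and edge-wise group difference testing.

Each subject contributes a K x K Pearson correlation matrix over ROI-mean
time courses; group differences per unordered ROI pair are tested on the
Fisher-z transformed subject correlations with a Welch two-sample t-test
(two-sided — an edge is drawn whichever group is stronger) at a
Bonferroni-corrected level.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import fisher_z
from .core import BrainMask, Image4D, ROIAtlas
from .group import bonferroni_alpha
from .preprocess import preprocess_subject

__all__ = [
    "ConnMatrix",
    "EdgeDiffGraph",
    "subject_conn_matrix",
    "edge_group_diff",
    "export_graph",
    "EdgeNetwork",
    "EdgeNetworkResults",
]


@dataclass
class ConnMatrix:
    """Per-subject ROI-by-ROI Pearson correlation matrix."""

    values: np.ndarray
    roi_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=np.float64)
        K = len(self.roi_names)
        if V.shape != (K, K):
            raise ValueError(f"matrix shape {V.shape} does not match {K} ROI names")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.any(np.abs(V) > 1 + 1e-9):
            raise ValueError("correlations must satisfy |r| <= 1")
        self.values = V

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names, columns=self.roi_names)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path, subject_id: str = "") -> "ConnMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(c) for c in df.columns], subject_id)


def subject_conn_matrix(
    img: Image4D,
    atlas: ROIAtlas,
    mask: BrainMask | None = None,
    subject_id: str = "",
    preprocessed: bool = True,
    preproc=None,
) -> ConnMatrix:
    """K x K matrix of Pearson correlations between ROI-mean time courses.

    With ``preprocessed=False`` the standard preprocessing chain is run
    first. The diagonal is exactly 1; a zero-variance ROI series raises an
    error naming the ROI.
    """
    if not preprocessed:
        img, mask = preprocess_subject(img, preproc)
    series = []
    for name in atlas.names:
        roi = atlas.roi_mask(name)
        if mask is not None:
            roi = roi & mask.data
        if not roi.any():
            raise ValueError(f"ROI {name!r} has no voxels inside the brain mask")
        series.append(img.data[roi].mean(axis=0, dtype=np.float64))
    series = np.asarray(series)
    sds = series.std(axis=1)
    if np.any(sds == 0):
        bad = atlas.names[int(np.argmin(sds))]
        raise ValueError(f"ROI {bad!r} has a zero-variance time course")
    V = np.corrcoef(series)
    np.clip(V, -1.0, 1.0, out=V)
    np.fill_diagonal(V, 1.0)
    return ConnMatrix(values=(V + V.T) / 2.0, roi_names=list(atlas.names),
                      subject_id=subject_id)


@dataclass
class EdgeDiffGraph:
    """Edge-wise two-group test results over all unordered ROI pairs."""

    edges: pd.DataFrame  # roi_a, roi_b, mean_z_a, mean_z_b, t_stat, p_value, direction, significant
    roi_names: list[str]
    alpha: float
    family_size: int
    group_a: str = "A"
    group_b: str = "B"

    @property
    def per_test_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, self.family_size)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]].reset_index(drop=True)

    def edge(self, roi_a: str, roi_b: str) -> pd.Series:
        e = self.edges
        hit = e[((e.roi_a == roi_a) & (e.roi_b == roi_b))
                | ((e.roi_a == roi_b) & (e.roi_b == roi_a))]
        if hit.empty:
            raise KeyError(f"no edge ({roi_a}, {roi_b})")
        return hit.iloc[0]


def edge_group_diff(
    mats_a: list[ConnMatrix],
    mats_b: list[ConnMatrix],
    alpha: float = 0.05,
    family_size: int | str | None = None,
    group_a: str = "A",
    group_b: str = "B",
) -> EdgeDiffGraph:
    """Welch two-sample t-test per ROI pair on Fisher-z correlations.

    ``family_size`` defaults to the group size (the convention matching a
    per-test level of 0.0056 for n = 9); pass ``"edges"`` for the
    conventional K(K-1)/2 family. Direction is the group whose mean z is
    larger. Swapping the groups flips every direction and negates t.
    """
    if len(mats_a) < 2 or len(mats_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    names = mats_a[0].roi_names
    for m in (*mats_a, *mats_b):
        if m.roi_names != names:
            raise ValueError("ROI name sets differ between matrices")
    K = len(names)
    iu = np.triu_indices(K, k=1)
    za = np.stack([fisher_z(m.values[iu]) for m in mats_a])  # (na, E)
    zb = np.stack([fisher_z(m.values[iu]) for m in mats_b])
    na, nb = za.shape[0], zb.shape[0]
    if family_size is None:
        family = na
    elif family_size == "edges":
        family = iu[0].size
    else:
        family = int(family_size)
    per_test = bonferroni_alpha(alpha, family)

    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    va, vb = za.var(axis=0, ddof=1), zb.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    t = np.zeros(iu[0].size)
    p = np.ones_like(t)
    nz = se2 > 0
    t[nz] = (ma[nz] - mb[nz]) / np.sqrt(se2[nz])
    with np.errstate(invalid="ignore", divide="ignore"):
        df = np.where(
            nz,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            na + nb - 2,
        )
    p[nz] = np.minimum(2.0 * stats.t.sf(np.abs(t[nz]), df=df[nz]), 1.0)

    direction = np.where(ma >= mb, group_a, group_b).astype(object)
    direction[ma == mb] = "tie"
    edges = pd.DataFrame(
        {
            "roi_a": [names[i] for i in iu[0]],
            "roi_b": [names[j] for j in iu[1]],
            "mean_z_a": ma,
            "mean_z_b": mb,
            "t_stat": t,
            "p_value": p,
            "df": df,
            "direction": direction,
            "significant": p < per_test,
        }
    )
    return EdgeDiffGraph(
        edges=edges, roi_names=list(names), alpha=alpha, family_size=family,
        group_a=group_a, group_b=group_b,
    )


_EXPORT_COLS = ["roi_a", "roi_b", "t_stat", "p_value", "direction", "significant"]


def export_graph(graph: EdgeDiffGraph, out_dir: str | Path, prefix: str = "edges"):
    """Write the significant-edge list and the full pair table as TSV.

    Returns (significant_path, full_path). The significant-edge file has a
    header even when no edge crosses the threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{prefix}_significant.tsv"
    full_path = out_dir / f"{prefix}_all.tsv"
    graph.significant_edges[_EXPORT_COLS].to_csv(sig_path, sep="\t", index=False)
    graph.edges[_EXPORT_COLS].to_csv(full_path, sep="\t", index=False)
    return sig_path, full_path


class EdgeNetwork:
    """Two-group edge-difference model over subject connectivity matrices."""

    def __init__(
        self,
        mats_a: list[ConnMatrix],
        mats_b: list[ConnMatrix],
        alpha: float = 0.05,
        family_size: int | str | None = None,
        group_a: str = "A",
        group_b: str = "B",
    ):
        self.mats_a = list(mats_a)
        self.mats_b = list(mats_b)
        self.alpha = alpha
        self.family_size = family_size
        self.group_a = group_a
        self.group_b = group_b

    @classmethod
    def from_images(
        cls, images_a, images_b, atlas: ROIAtlas, preproc=None, **kwargs
    ) -> "EdgeNetwork":
        mats_a = [
            subject_conn_matrix(img, atlas, preprocessed=False, preproc=preproc,
                                subject_id=f"a{i:02d}")
            for i, img in enumerate(images_a)
        ]
        mats_b = [
            subject_conn_matrix(img, atlas, preprocessed=False, preproc=preproc,
                                subject_id=f"b{i:02d}")
            for i, img in enumerate(images_b)
        ]
        return cls(mats_a, mats_b, **kwargs)

    def fit(self) -> "EdgeNetworkResults":
        graph = edge_group_diff(
            self.mats_a, self.mats_b, self.alpha, self.family_size,
            self.group_a, self.group_b,
        )
        return EdgeNetworkResults(self, graph)


class EdgeNetworkResults:
    """Fitted edge-difference network with summary and export helpers."""

    def __init__(self, model: EdgeNetwork, graph: EdgeDiffGraph):
        self.model = model
        self.graph = graph

    @property
    def edges(self) -> pd.DataFrame:
        return self.graph.edges

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.graph.significant_edges

    def summary(self) -> str:
        g = self.graph
        sig = g.significant_edges
        n_a = int((sig["direction"] == g.group_a).sum())
        n_b = int((sig["direction"] == g.group_b).sum())
        lines = [
            "Edge-wise group difference (Welch t on Fisher-z correlations)",
            "=" * 62,
            f"groups:              {g.group_a} (n={len(self.model.mats_a)}) vs "
            f"{g.group_b} (n={len(self.model.mats_b)})",
            f"ROI pairs tested:    {g.n_edges}",
            f"alpha / family:      {g.alpha} / {g.family_size}"
            f"  (per-test {g.per_test_alpha:.6g})",
            f"significant edges:   {len(sig)}"
            f"  ({n_a} stronger in {g.group_a}, {n_b} stronger in {g.group_b})",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row.roi_a:>20s} -- {row.roi_b:<20s} t={row.t_stat:+.2f} "
                f"p={row.p_value:.2e} stronger in {row.direction}"
            )
        return "\n".join(lines)

    def export(self, out_dir, prefix="edges"):
        return export_graph(self.graph, out_dir, prefix)
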