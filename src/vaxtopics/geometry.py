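"""Intratopic consistency and intertopic distinctiveness statistics.

A topic cluster's *radius* is the mean Euclidean distance from its member
points to its centroid — larger radius, less internally consistent topic.
The *distinctiveness* of a pair of clusters is their centroid distance
normalized by the sum of the two radii, so a score below 1 means the
clusters overlap substantially and a score of 1 or more means they are
distinct.  Stance groups are compared by two-sample t-tests on the
prominent-versus-rest distinctiveness scores (and on radii), and the
geometry is rendered as the familiar circles-and-edges chart: prominent
topics as central circles whose radius encodes intratopic consistency,
edges to the remaining topics labelled by distinctiveness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics.pairwise import euclidean_distances

from .clusters import ClusterAssignment

__all__ = [
    "ClusterGeometry",
    "GroupComparison",
    "radius",
    "distinctiveness",
    "compute_geometry",
    "prominent_vs_rest",
    "two_sample_t",
    "plot_geometry",
]


def radius(features, members: Sequence[int], centroid: np.ndarray) -> float:
    """Mean Euclidean member-to-centroid distance (intratopic radius)."""
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("cluster is empty")
    d = euclidean_distances(features[members], np.asarray(centroid).reshape(1, -1))
    return float(d.mean())


def distinctiveness(
    features,
    members_x: Sequence[int],
    centroid_x: np.ndarray,
    members_y: Sequence[int],
    centroid_y: np.ndarray,
) -> float:
    """Centroid distance over the sum of the two cluster radii.

    0 when the centroids coincide (complete overlap); +inf when both radii
    are 0 but the centroids differ (two distinct point masses).
    """
    cx = np.asarray(centroid_x, dtype=float).ravel()
    cy = np.asarray(centroid_y, dtype=float).ravel()
    d = float(np.linalg.norm(cx - cy))
    if d == 0.0:
        return 0.0
    rsum = radius(features, members_x, cx) + radius(features, members_y, cy)
    if rsum == 0.0:
        return math.inf
    return d / rsum


@dataclass
class ClusterGeometry:
    """Radii and pairwise distinctiveness scores of one stance group."""

    stance: str | None
    cluster_ids: tuple[int, ...]
    radii: dict[int, float]
    sizes: dict[int, int]
    scores: dict[tuple[int, int], float]

    def score(self, a: int, b: int) -> float:
        if a == b:
            return 0.0
        return self.scores[(a, b) if (a, b) in self.scores else (b, a)]


def compute_geometry(
    features, assignment: ClusterAssignment, stance: str | None = None
) -> ClusterGeometry:
    """Radii of every cluster and distinctiveness of every unordered pair."""
    ids = tuple(sorted(assignment.sizes))
    radii = {
        c: radius(features, assignment.members(c), assignment.centroids[c]) for c in ids
    }
    sizes = assignment.sizes
    scores: dict[tuple[int, int], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = float(np.linalg.norm(assignment.centroids[a] - assignment.centroids[b]))
            rsum = radii[a] + radii[b]
            scores[(a, b)] = 0.0 if d == 0.0 else (math.inf if rsum == 0.0 else d / rsum)
    return ClusterGeometry(
        stance=stance, cluster_ids=ids, radii=radii, sizes=sizes, scores=scores
    )


def geometry_from_labels(features, labels: Sequence[int], stance: str | None = None) -> ClusterGeometry:
    """Geometry of a labelled partition, centroids taken as member means.

    Useful for planted (ground-truth) topic assignments, where no K-means
    fit is involved.  Labels must be 0..k-1.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError("labels must be contiguous integers 0..k-1")
    centroids = np.vstack(
        [np.asarray(features[np.flatnonzero(labels == c)].mean(axis=0)).ravel() for c in ids]
    )
    assign = ClusterAssignment(
        k=len(ids), labels=labels, centroids=centroids, inertia=float("nan")
    )
    return compute_geometry(features, assign, stance=stance)


def prominent_vs_rest(
    geometry: ClusterGeometry,
    prominent_ids: Sequence[int],
    rest_ids: Sequence[int],
) -> list[float]:
    """Distinctiveness scores of every (prominent, rest) ordered pair.

    Returns |prominent| x |rest| scores; summarize with mean and SD.
    """
    prominent_ids = list(prominent_ids)
    rest_ids = list(rest_ids)
    if not prominent_ids or not rest_ids:
        raise ValueError("both prominent and rest cluster sets must be non-empty")
    if set(prominent_ids) & set(rest_ids):
        raise ValueError("prominent and rest cluster sets must be disjoint")
    return [geometry.score(p, r) for p in prominent_ids for r in rest_ids]


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test summary."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p_value: float
    tail: str
    variance: str


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    tail: str = "two",
    variance: str = "pooled",
) -> GroupComparison:
    """Two-sample t-test between score lists a and b.

    ``variance="pooled"`` is the classical equal-variance test with
    df = n_a + n_b - 2; ``"unequal"`` is Welch's test with
    Welch-Satterthwaite df.  The one-tailed p tests mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if variance not in ("pooled", "unequal"):
        raise ValueError("variance must be 'pooled' or 'unequal'")
    equal_var = variance == "pooled"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    if equal_var:
        df = len(a) + len(b) - 2.0
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    if tail == "two":
        p = float(res.pvalue)
    else:
        p = float(stats.t.sf(t, df))
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
        t=t,
        df=float(df),
        p_value=p,
        tail=tail,
        variance=variance,
    )


def plot_geometry(
    geometry: ClusterGeometry,
    prominent_ids: Sequence[int],
    rest_ids: Sequence[int],
    out: str | Path,
    seed: int = 0,
) -> Path:
    """Render prominent clusters as central circles with edges to the rest.

    Circle radius is proportional to the intratopic radius (zero-radius
    clusters get a minimum visible marker with an annotation); edge length
    and label are proportional to distinctiveness.  The layout is
    deterministic per seed and the written file is byte-reproducible.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prominent_ids = list(prominent_ids)
    rest_ids = list(rest_ids)
    if not prominent_ids:
        raise ValueError("need at least one prominent cluster to plot")
    rng = np.random.default_rng(seed)

    rmax = max(geometry.radii.values()) or 1.0
    vis = {c: 0.25 * geometry.radii[c] / rmax for c in geometry.cluster_ids}

    # prominent clusters on a small inner ring; rest on an outer ring at
    # range scaled by their mean distinctiveness from the prominent set
    pos: dict[int, tuple[float, float]] = {}
    for i, c in enumerate(prominent_ids):
        ang = 2 * math.pi * i / len(prominent_ids) + rng.uniform(0, 0.1)
        r0 = 0.0 if len(prominent_ids) == 1 else 0.9
        pos[c] = (r0 * math.cos(ang), r0 * math.sin(ang))
    finite = [
        geometry.score(p, r)
        for p in prominent_ids
        for r in rest_ids
        if math.isfinite(geometry.score(p, r))
    ]
    dmax = max(finite) if finite else 1.0
    for i, c in enumerate(rest_ids):
        ang = 2 * math.pi * i / max(len(rest_ids), 1) + math.pi / max(len(rest_ids), 1)
        mean_d = (
            float(np.mean([geometry.score(p, c) for p in prominent_ids]))
            if prominent_ids
            else 1.0
        )
        rr = 2.0 + 2.0 * (mean_d / dmax if math.isfinite(mean_d) and dmax else 1.0)
        pos[c] = (rr * math.cos(ang), rr * math.sin(ang))

    fig, ax = plt.subplots(figsize=(8, 8))
    for p in prominent_ids:
        for r in rest_ids:
            x0, y0 = pos[p]
            x1, y1 = pos[r]
            (line,) = ax.plot([x0, x1], [y0, y1], color="0.8", lw=0.6, zorder=1)
            line.set_gid(f"edge-{p}-{r}")
            s = geometry.score(p, r)
            label = "inf" if not math.isfinite(s) else f"{s:.2f}"
            ax.annotate(
                label, ((x0 + x1) / 2, (y0 + y1) / 2), fontsize=6, color="0.4"
            )
    for c in geometry.cluster_ids:
        if c not in pos:
            continue
        rad = vis[c]
        face = "tab:blue" if c in prominent_ids else "tab:gray"
        if rad == 0.0:
            rad = 0.04  # minimum visible marker
            ax.annotate("r=0", pos[c], fontsize=6, color="tab:red")
        circle = plt.Circle(pos[c], rad, facecolor=face, alpha=0.55, edgecolor="k", lw=0.5)
        circle.set_gid(f"cluster-circle-{c}")
        ax.add_patch(circle)
        ax.annotate(f"C{c}", pos[c], ha="center", va="center", fontsize=8)
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.relim()
    ax.set_axis_off()
    title = "Cluster geometry" + (f" ({geometry.stance})" if geometry.stance else "")
    ax.set_title(title)

    out = Path(out)
    with plt.rc_context({"svg.hashsalt": str(seed)}):
        fig.savefig(out, metadata=_stable_metadata(out))
    plt.close(fig)
    return out


def _stable_metadata(out: Path) -> dict | None:
    # strip volatile timestamps so identical renders are byte-identical
    suffix = out.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix in (".pdf", ".ps", ".eps"):
        return {"CreationDate": None}
    return None
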