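"""Pathway tracing and linguistics-style clustering of reaction mechanisms.

Continuous reactants -> products pathways are reconstructed from the run
record by following walker lineages backwards from every recycling event to
the trajectory's last departure from the unassociated state.  Each pathway
is discretized into a string of symmetry-adapted site labels (which carbon
of the cation the anion is nearest after each resampling interval), pairwise
string distances are computed with a length-corrected Gestalt
(Ratcliff--Obershelp) measure, and pathways are grouped by Ward-linkage
agglomerative clustering with the dendrogram cut placed in the largest gap
between merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import surrogate as sg
from .engine import RunRecord

__all__ = [
    "Pathway",
    "ClusterTree",
    "trace_pathways",
    "discretize",
    "gestalt_similarity",
    "pathway_distance",
    "distance_matrix",
    "cluster",
    "cut_tree",
    "class_probabilities",
    "contact_distribution",
    "label_entropy",
    "addition_site",
]


@dataclass
class Pathway:
    """A continuous reactants -> products trajectory with its weight.

    ``frames`` holds configurations at tau resolution (iteration-end
    frames); ``frames_all`` additionally interleaves the tau/2 frames used
    for contact analysis.  Pathways reconstructed from the same WE run may
    share ancestral frames by design.
    """

    frames: np.ndarray
    frames_all: np.ndarray
    weight: float
    start_iteration: int
    end_iteration: int
    labels: str = ""
    class_id: "int | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("pathway weight must be positive")


def trace_pathways(record: RunRecord) -> list[Pathway]:
    """One pathway per recycling event, traced through walker lineages.

    Frames run from the last iteration the lineage was in the unassociated
    state (or from its spawn, whichever is later) to product entry; the
    pathway weight is the recycled weight.  A lineage split after frame k
    yields pathways sharing frames up to k.
    """
    paths: list[Pathway] = []
    iters = record.iterations
    u_code = record.state_index("unassociated")
    for ti in range(len(iters)):
        it = iters[ti]
        for k in np.flatnonzero(it.recycled):
            chain: list[tuple[int, int]] = []
            t, j = ti, int(k)
            while True:
                chain.append((t, j))
                seg = iters[t]
                r_end = np.hypot(seg.x_end[j, 0], seg.x_end[j, 1]) \
                    if seg.x_end.shape[1] == 2 else np.inf
                if seg.x_end.shape[1] == 2 and sg.classify_r(r_end) == u_code \
                        and t != ti:
                    break  # reached the last unassociated frame
                if seg.spawn[j] or t == 0:
                    break
                j = int(seg.parent[j])
                t -= 1
                if j < 0:
                    raise ValueError("broken lineage chain in run record")
            chain.reverse()
            frames = np.array([iters[t].x_end[j] for t, j in chain])
            frames_all = []
            for idx, (t, j) in enumerate(chain):
                if idx > 0:
                    frames_all.append(iters[t].x_mid[j])
                frames_all.append(iters[t].x_end[j])
            paths.append(Pathway(
                frames=frames, frames_all=np.array(frames_all),
                weight=float(it.weights[k]),
                start_iteration=chain[0][0] + 1,
                end_iteration=ti + 1))
    return paths


def discretize(pathway: Pathway, params: sg.SurrogateParams) -> str:
    """Site-label string of a pathway at tau resolution.

    The alphabet is {T, O, P} for the unsubstituted system and
    {T, O, P, X, S} for substituted ones; the final character of a
    productive pathway is always T (the central carbon).
    """
    labels = sg.site_labels_xy(params, pathway.frames)
    s = "".join(labels)
    pathway.labels = s
    return s


# ---------------------------------------------------------------------------
# Gestalt (Ratcliff--Obershelp) pattern matching

def _longest_match(a: str, b: str, alo: int, ahi: int, blo: int, bhi: int
                   ) -> tuple[int, int, int]:
    """Longest common substring within the given slices.

    Ties are broken toward the earliest start in ``a``, then in ``b``,
    making the decomposition deterministic.
    """
    besti, bestj, bestsize = alo, blo, 0
    prev = np.zeros(bhi - blo + 1, dtype=np.int64)
    for i in range(alo, ahi):
        cur = np.zeros(bhi - blo + 1, dtype=np.int64)
        ai = a[i]
        for j in range(blo, bhi):
            if ai == b[j]:
                v = prev[j - blo] + 1
                cur[j - blo + 1] = v
                if v > bestsize:
                    besti, bestj, bestsize = i - v + 1, j - v + 1, int(v)
        prev = cur
    return besti, bestj, bestsize


def _matched(a: str, b: str, alo: int, ahi: int, blo: int, bhi: int) -> int:
    if alo >= ahi or blo >= bhi:
        return 0
    i, j, size = _longest_match(a, b, alo, ahi, blo, bhi)
    if size == 0:
        return 0
    return (size
            + _matched(a, b, alo, i, blo, j)
            + _matched(a, b, i + size, ahi, j + size, bhi))


def gestalt_similarity(s1: str, s2: str) -> float:
    """Ratcliff--Obershelp similarity 2M / (L1 + L2) in [0, 1].

    M is the total number of matched characters from the recursive
    longest-common-substring decomposition (longest block first, then
    recurse on the flanks).
    """
    if not s1 or not s2:
        raise ValueError("pathway strings must be nonempty")
    m = _matched(s1, s2, 0, len(s1), 0, len(s2))
    return 2.0 * m / (len(s1) + len(s2))


def length_correction(l1: int, l2: int) -> float:
    """Default length-correction factor c = min(L)/max(L) (<= 1)."""
    return min(l1, l2) / max(l1, l2)


def pathway_distance(s1: str, s2: str, correction=length_correction) -> float:
    """Length-corrected Gestalt distance (1 - similarity) / c(L1, L2).

    The correction divisor c = min/max inflates distances between pathways
    of unequal length; it is pluggable for alternative corrections.
    The raw Ratcliff--Obershelp decomposition depends on argument order, so
    the pair is put in canonical (lexicographic) order first: d(s, s) = 0
    and the distance is exactly symmetric.
    """
    a, b = sorted((s1, s2))
    sim = gestalt_similarity(a, b)
    return (1.0 - sim) / correction(len(s1), len(s2))


def distance_matrix(strings: list[str], correction=length_correction) -> np.ndarray:
    n = len(strings)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pathway_distance(strings[i], strings[j],
                                                   correction)
    return dm


# ---------------------------------------------------------------------------
# Hierarchical clustering

@dataclass
class ClusterTree:
    """Agglomerative merge tree (scipy linkage encoding) for n pathways."""

    linkage: np.ndarray
    n_items: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster(dm: np.ndarray) -> ClusterTree:
    """Ward-linkage agglomerative clustering of a pathway distance matrix."""
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12) or np.any(dm < 0) \
            or np.any(np.abs(np.diag(dm)) > 1e-12):
        raise ValueError("distance matrix must be symmetric, non-negative, "
                         "with zero diagonal")
    if dm.shape[0] < 2:
        raise ValueError("need at least two pathways to cluster")
    Z = hierarchy.linkage(squareform(dm, checks=False), method="ward")
    return ClusterTree(Z, dm.shape[0])


def cut_tree(tree: ClusterTree, n_classes: "int | None" = None
             ) -> tuple[np.ndarray, int, bool]:
    """Class assignments from the dendrogram's largest-gap cut.

    The horizontal cut is placed in the largest gap between consecutive
    merge heights (ties broken toward the later gap, i.e. fewer classes).
    Returns (labels starting at 1, n_classes, degenerate_flag); the flag is
    set when all merge heights coincide, in which case everything is one
    class by convention.  ``n_classes`` forces the number of classes.
    """
    Z, n = tree.linkage, tree.n_items
    if n_classes is not None:
        labels = hierarchy.fcluster(Z, t=n_classes, criterion="maxclust")
        return labels, int(labels.max()), False
    h = tree.heights
    if len(h) < 2 or np.ptp(h) < 1e-12:
        return np.ones(n, dtype=np.int64), 1, True
    gaps = np.diff(h)
    idx = len(gaps) - 1 - int(np.argmax(gaps[::-1]))  # later tie -> fewer classes
    thr = 0.5 * (h[idx] + h[idx + 1])
    labels = hierarchy.fcluster(Z, t=thr, criterion="distance")
    return labels, int(labels.max()), False


def class_probabilities(pathways: list[Pathway]) -> dict[int, float]:
    """Weight-normalized probability of each pathway class."""
    if any(p.class_id is None for p in pathways):
        raise ValueError("all pathways must carry a class id")
    total = sum(p.weight for p in pathways)
    out: dict[int, float] = {}
    for p in pathways:
        out[p.class_id] = out.get(p.class_id, 0.0) + p.weight / total
    return out


# ---------------------------------------------------------------------------
# On-disk artefacts

def save_pathway_strings(path: str, strings: list[str], weights) -> None:
    """Plain text, one discretized pathway per line with its weight."""
    with open(path, "w") as f:
        for s, w in zip(strings, weights):
            f.write(f"{s},{float(w)!r}\n")


def save_distance_matrix(path: str, dm: np.ndarray) -> None:
    np.savetxt(path, np.asarray(dm), delimiter=",")


def load_distance_matrix(path: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def tree_to_dict(tree: ClusterTree) -> dict:
    """Nested-JSON form of the merge tree (leaves carry item indices)."""
    root = hierarchy.to_tree(tree.linkage)

    def walk(node):
        if node.is_leaf():
            return {"item": int(node.id)}
        return {"height": float(node.dist),
                "children": [walk(node.left), walk(node.right)]}

    return walk(root)


# ---------------------------------------------------------------------------
# Contact analysis over the activation step

def _activation_slice(pathway: Pathway) -> np.ndarray:
    r = np.hypot(pathway.frames_all[:, 0], pathway.frames_all[:, 1])
    inside = np.flatnonzero(r < sg.R_ION_PAIR_OUTER)
    if inside.size == 0:
        raise ValueError("pathway never enters the ion-pair shell")
    return pathway.frames_all[inside[0]:]

def contact_distribution(pathways: list[Pathway], params: sg.SurrogateParams
                         ) -> dict[str, float]:
    """Probability of each site label being contacted during activation.

    The activation segment runs from the first crossing below the 5 A
    contact threshold to product entry; frames are sampled at tau/2
    resolution and label occurrences are weighted by pathway probability,
    then normalized over the label alphabet.
    """
    alphabet = params.label_alphabet
    counts = dict.fromkeys(alphabet, 0.0)
    for p in pathways:
        seg = _activation_slice(p)
        labs = sg.site_labels_xy(params, seg)
        for lab in labs:
            counts[str(lab)] += p.weight / len(labs)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty activation segments")
    return {k: v / total for k, v in counts.items()}


def label_entropy(distribution: dict[str, float]) -> float:
    """Shannon entropy (nats) of a contact-label distribution."""
    p = np.array([v for v in distribution.values() if v > 0])
    return float(-(p * np.log(p)).sum())


def addition_site(pathway: Pathway, params: sg.SurrogateParams) -> str:
    """Surrogate addition-site label: the ring site nearest in angle at
    product entry (the direction of the final approach)."""
    x, y = pathway.frames[-1]
    theta = np.arctan2(y, x)
    d = np.abs(np.angle(np.exp(1j * (np.asarray(params.site_angles) - theta))))
    return params.site_labels[int(np.argmin(d))]
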