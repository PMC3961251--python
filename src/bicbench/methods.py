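"""Reference biclustering methods and the result-filtering rules.

Implements the concretely specified criteria:

* Cheng–Church delta-biclustering: greedy node deletion/addition under a
  mean-squared-residue ceiling, with random masking of discovered cells.
* Bimax-style enumeration of inclusion-maximal all-ones submatrices of a
  binarized matrix.
* An xMOTIF-flavoured constant-row search: genes whose values fall within a
  small interval across a sample set.
* One-way clustering adapters (k-means with Euclidean distance; hierarchical
  with Pearson distance and complete linkage) that lift each cluster to a
  bicluster spanning the full other axis.

Methods with published reference implementations that are not re-derived
here (Plaid, SAMBA, FABIA, ISA, OPSM, QUBIC, ...) are evaluated through the
bicluster exchange format instead.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .datamodel import Bicluster, BiclusterSet, ExpressionMatrix

logger = logging.getLogger("bicbench")


# ---------------------------------------------------------------------------
# Binarization + Bimax
# ---------------------------------------------------------------------------


class BinaryMatrix:
    """0/1 matrix on the same axes as an ExpressionMatrix."""

    def __init__(self, gene_ids, sample_ids, values: np.ndarray):
        values = np.asarray(values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = values.astype(np.int8)


def binarize_matrix(m: ExpressionMatrix, z_threshold: float = 1.0) -> BinaryMatrix:
    """Per-gene z-score discretization: entry = 1 iff z > z_threshold.

    Each gene is standardized by its own across-sample mean and SD; a
    zero-SD gene yields an all-zero row (a warning is logged).
    """
    if m.n_missing:
        raise ValueError("binarize_matrix requires a matrix without missing entries")
    x = m.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("binarize_matrix: %d zero-SD genes set to all-zero rows",
                       int(flat.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, -np.inf)
    return BinaryMatrix(m.gene_ids, m.sample_ids, (z > z_threshold).astype(np.int8))


def bimax_enumerate(
    b: BinaryMatrix,
    min_genes: int = 2,
    min_samples: int = 2,
    max_results: int = 100,
) -> BiclusterSet:
    """Enumerate inclusion-maximal all-ones submatrices meeting size minima.

    A maximal all-ones submatrix is a pair (rows, cols) where cols is the
    intersection of the rows' supports and rows is every row whose support
    covers cols — a maximal biclique of the gene/sample bipartite graph.
    Enumeration walks the lattice of row-support intersections, pruning
    column sets below ``min_samples`` (intersections only shrink), and caps
    the number of explored column sets to bound worst-case blow-up.
    """
    supports = [frozenset(np.flatnonzero(row)) for row in b.values]
    explored: set[frozenset] = set()
    frontier = {s for s in supports if len(s) >= min_samples}
    cap = max(max_results * 50, 5000)
    while frontier and len(explored) < cap:
        nxt: set[frozenset] = set()
        for cols in frontier:
            if cols in explored:
                continue
            explored.add(cols)
            if len(explored) >= cap:
                break
            for s in supports:
                inter = cols & s
                if (
                    len(inter) >= min_samples
                    and inter != cols
                    and inter not in explored
                ):
                    nxt.add(inter)
        frontier = nxt - explored

    results: list[tuple[frozenset, frozenset]] = []
    for cols in explored:
        rows = frozenset(
            i for i, s in enumerate(supports) if cols <= s
        )
        if len(rows) < min_genes:
            continue
        closure = frozenset.intersection(*(supports[i] for i in rows))
        if closure != cols:  # not closed -> not maximal
            continue
        results.append((rows, cols))

    # deterministic order: biggest area first, then lexicographic
    results.sort(key=lambda rc: (-len(rc[0]) * len(rc[1]),
                                 sorted(rc[0]), sorted(rc[1])))
    results = results[:max_results]
    bics = [
        Bicluster(
            frozenset(b.gene_ids[i] for i in rows),
            frozenset(b.sample_ids[j] for j in cols),
        )
        for rows, cols in results
    ]
    return BiclusterSet(
        method_name="bimax",
        parameters={"min_genes": min_genes, "min_samples": min_samples,
                    "max_results": max_results},
        biclusters=bics,
    )


# ---------------------------------------------------------------------------
# Cheng–Church
# ---------------------------------------------------------------------------


class CCParams:
    """Cheng–Church settings: MSR ceiling delta, deletion rate, count, seed."""

    def __init__(
        self,
        delta: float = 50.0,
        alpha_rate: float = 1.5,
        n_biclusters: int = 40,
        seed: int = 0,
    ):
        if delta < 0:
            raise ValueError("delta must be >= 0")
        if alpha_rate <= 1:
            raise ValueError("alpha_rate must be > 1")
        self.delta = float(delta)
        self.alpha_rate = float(alpha_rate)
        self.n_biclusters = int(n_biclusters)
        self.seed = int(seed)


def mean_squared_residue(sub: np.ndarray) -> float:
    """MSR: mean of squared entries after removing row/column/overall means."""
    res = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float((res**2).mean())


def _residues(sub: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    rm = sub.mean(axis=1, keepdims=True)
    cm = sub.mean(axis=0, keepdims=True)
    res = sub - rm - cm + sub.mean()
    sq = res**2
    return float(sq.mean()), sq.mean(axis=1), sq.mean(axis=0)


def _cc_single(x: np.ndarray, delta: float, alpha_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One Cheng–Church round: deletion to MSR <= delta, then node addition."""
    rows = np.arange(x.shape[0])
    cols = np.arange(x.shape[1])

    # Phase 1+2: multiple node deletion (threshold alpha_rate * MSR), falling
    # back to single deletion of the worst row/column when nothing exceeds it.
    while True:
        sub = x[np.ix_(rows, cols)]
        msr, dr, dc = _residues(sub)
        if msr <= delta or (len(rows) <= 2 and len(cols) <= 2):
            break
        thr = alpha_rate * msr
        keep_r = dr <= thr
        keep_c = dc <= thr
        if keep_r.sum() >= 2 and keep_c.sum() >= 2 and (
            not keep_r.all() or not keep_c.all()
        ):
            rows = rows[keep_r]
            cols = cols[keep_c]
            continue
        # single node deletion: drop the row or column of largest residue
        if len(rows) > 2 and (len(cols) <= 2 or dr.max() >= dc.max()):
            rows = np.delete(rows, int(np.argmax(dr)))
        else:
            cols = np.delete(cols, int(np.argmax(dc)))

    # Phase 3: node addition — add columns/rows whose residue w.r.t. the
    # current bicluster does not increase the MSR.
    changed = True
    while changed:
        changed = False
        sub = x[np.ix_(rows, cols)]
        msr = mean_squared_residue(sub)
        out_c = np.setdiff1d(np.arange(x.shape[1]), cols)
        if out_c.size:
            cand = x[np.ix_(rows, out_c)]
            rm = sub.mean(axis=1, keepdims=True)
            am = sub.mean()
            cm = cand.mean(axis=0, keepdims=True)
            d = ((cand - rm - cm + am) ** 2).mean(axis=0)
            add = out_c[d <= msr]
            if add.size:
                cols = np.sort(np.concatenate([cols, add]))
                changed = True
                sub = x[np.ix_(rows, cols)]
                msr = mean_squared_residue(sub)
        out_r = np.setdiff1d(np.arange(x.shape[0]), rows)
        if out_r.size:
            cand = x[np.ix_(out_r, cols)]
            cm = sub.mean(axis=0, keepdims=True)
            am = sub.mean()
            rm = cand.mean(axis=1, keepdims=True)
            d = ((cand - rm - cm + am) ** 2).mean(axis=1)
            add = out_r[d <= msr]
            if add.size:
                rows = np.sort(np.concatenate([rows, add]))
                changed = True
    return rows, cols


def cc_biclusters(m: ExpressionMatrix, p: CCParams) -> BiclusterSet:
    """Iterative delta-biclustering with masking of discovered cells.

    After each discovery the covered cells are replaced with values drawn
    uniformly over the observed data range before the next round, so
    subsequent biclusters explore different regions.  A discovery whose MSR
    on the ORIGINAL (unmasked) values exceeds delta — possible once masking
    noise leaks into later rounds — is suppressed rather than returned, so
    every emitted bicluster honours the delta contract on the input matrix.
    """
    if m.n_missing:
        raise ValueError("cc_biclusters requires a matrix without missing entries")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be at least 2 x 2")
    rng = np.random.default_rng(p.seed)
    orig = m.values.copy()
    x = m.values.copy()
    lo, hi = float(x.min()), float(x.max())
    gene_ids = np.array(m.gene_ids)
    sample_ids = np.array(m.sample_ids)
    bics: list[Bicluster] = []
    delta_eff = p.delta + 1e-12  # guard against float noise at delta = 0
    for _ in range(p.n_biclusters):
        rows, cols = _cc_single(x, delta_eff, p.alpha_rate)
        if len(rows) == 0 or len(cols) == 0:
            break
        if mean_squared_residue(orig[np.ix_(rows, cols)]) <= delta_eff:
            bics.append(
                Bicluster(frozenset(gene_ids[rows]), frozenset(sample_ids[cols]))
            )
        x[np.ix_(rows, cols)] = rng.uniform(lo, hi, size=(len(rows), len(cols)))
    return BiclusterSet(
        method_name="cc",
        parameters={"delta": p.delta, "alpha_rate": p.alpha_rate,
                    "n_biclusters": p.n_biclusters, "seed": p.seed},
        biclusters=bics,
    )


# ---------------------------------------------------------------------------
# Constant-interval (xMOTIF-style) search
# ---------------------------------------------------------------------------


def constant_interval_biclusters(
    m: ExpressionMatrix,
    interval_width: float,
    n_seeds: int = 200,
    min_genes: int = 2,
    min_samples: int = 2,
    seed: int = 0,
) -> BiclusterSet:
    """Randomized search for near-constant gene rows over sample subsets.

    Each trial draws a small discriminating sample set, keeps the genes whose
    value range over it is within ``interval_width``, then greedily extends
    the sample set with samples that keep every selected gene inside its
    window.  Results meeting both size minima are kept (de-duplicated);
    every returned pair satisfies the window condition by construction.
    """
    if m.n_missing:
        raise ValueError("requires a matrix without missing entries")
    rng = np.random.default_rng(seed)
    x = m.values
    n_g, n_s = x.shape
    gene_ids = np.array(m.gene_ids)
    sample_ids = np.array(m.sample_ids)
    d_size = min(max(min_samples, 2), n_s)
    found: dict[tuple, Bicluster] = {}
    for _ in range(n_seeds):
        cand = rng.choice(n_s, size=d_size, replace=False)
        sub = x[:, cand]
        lo = sub.min(axis=1)
        hi = sub.max(axis=1)
        genes = np.flatnonzero(hi - lo <= interval_width)
        if len(genes) < min_genes:
            continue
        lo_g = lo[genes].copy()
        hi_g = hi[genes].copy()
        members = set(cand.tolist())
        for s in rng.permutation(np.setdiff1d(np.arange(n_s), cand)):
            v = x[genes, s]
            new_lo = np.minimum(lo_g, v)
            new_hi = np.maximum(hi_g, v)
            if (new_hi - new_lo <= interval_width).all():
                members.add(int(s))
                lo_g, hi_g = new_lo, new_hi
        if len(members) < min_samples:
            continue
        key = (tuple(sorted(genes.tolist())), tuple(sorted(members)))
        if key not in found:
            found[key] = Bicluster(
                frozenset(gene_ids[genes]),
                frozenset(sample_ids[sorted(members)]),
            )
    bics = sorted(
        found.values(),
        key=lambda b: (-b.n_genes * b.n_samples, sorted(b.genes), sorted(b.samples)),
    )
    return BiclusterSet(
        method_name="xmotif",
        parameters={"interval_width": interval_width, "n_seeds": n_seeds,
                    "min_genes": min_genes, "min_samples": min_samples,
                    "seed": seed},
        biclusters=bics,
    )


# ---------------------------------------------------------------------------
# One-way clustering adapters
# ---------------------------------------------------------------------------


def one_way_cluster_adapter(
    m: ExpressionMatrix,
    axis: str,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
    n_init: int = 10,
) -> BiclusterSet:
    """Partition one axis into k clusters, each lifted to a full-axis bicluster.

    ``kmeans`` uses Euclidean distance on the profile vectors; ``hierarchical``
    uses Pearson-correlation distance (1 - r) with complete linkage, cut at k
    clusters.  The output is a partition of the clustered axis: mutually
    exclusive, exhaustive clusters, each spanning the entire other axis.
    """
    if m.n_missing:
        raise ValueError("clustering requires a matrix without missing entries")
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    if method not in ("kmeans", "hierarchical"):
        raise ValueError("method must be 'kmeans' or 'hierarchical'")
    if k < 2:
        raise ValueError("k must be >= 2")
    x = m.values if axis == "genes" else m.values.T
    n_items = x.shape[0]
    if k > n_items:
        raise ValueError(f"k={k} exceeds number of {axis} ({n_items})")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
    else:
        z = linkage(x, method="complete", metric="correlation")
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    item_ids = np.array(m.gene_ids if axis == "genes" else m.sample_ids)
    other = (
        frozenset(m.sample_ids) if axis == "genes" else frozenset(m.gene_ids)
    )
    bics = []
    for c in sorted(set(labels.tolist())):
        ids = frozenset(item_ids[labels == c])
        if axis == "genes":
            bics.append(Bicluster(ids, other))
        else:
            bics.append(Bicluster(other, ids))
    return BiclusterSet(
        method_name=method,
        parameters={"axis": axis, "k": k, "seed": seed},
        biclusters=bics,
    )


# ---------------------------------------------------------------------------
# Result filtering
# ---------------------------------------------------------------------------


def filter_bicluster_set(
    bs: BiclusterSet,
    min_genes: int = 10,
    min_samples: int = 10,
    top_n: int = 40,
) -> BiclusterSet:
    """Drop undersized biclusters, rank by sample count, keep the top_n.

    Biclusters with fewer than ``min_genes`` genes OR fewer than
    ``min_samples`` samples are removed; survivors are sorted in decreasing
    order of sample count (stable, so original order breaks ties) and
    truncated to ``top_n``.
    """
    survivors = [
        b for b in bs.biclusters
        if b.n_genes >= min_genes and b.n_samples >= min_samples
    ]
    # stable sort keeps original rank among equal sample counts
    ordered = sorted(survivors, key=lambda b: -b.n_samples)
    params = dict(bs.parameters)
    params.update(
        {"filter_min_genes": min_genes, "filter_min_samples": min_samples,
         "filter_top_n": top_n}
    )
    return BiclusterSet(
        method_name=bs.method_name,
        parameters=params,
        biclusters=ordered[: max(top_n, 0)],
    )
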