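"""Evaluation statistics for biclustering results.

Four benchmark families:

* **Sample differentiation (SampleDif).**  The Dice/Sørensen overlap
  s(A, B) = 2|A ∩ B| / (|A| + |B|) between each bicluster's sample set and
  each sample type's column set fills a k x t overlap matrix D; a greedy
  matching repeatedly extracts the global maximum of D and deletes its row
  and column, yielding a vector V of length min(k, t).  SampleDif is the
  mean of V: 1.0 means each sample type is recovered exactly by a distinct
  bicluster.

* **Tissue-specificity significance (TiGER-Sig role).**  The same Dice
  overlap applied to gene sets measures how well a bicluster covers the
  genes specific to the studied sample types (their union).  An empirical
  p-value compares the observed overlap with overlaps of random gene sets
  of the same size drawn from the expression universe; TiGER-Sig is the
  fraction of biclusters with p below alpha.

* **Annotation enrichment significance (GO-Sig role).**  Fisher's exact
  test (upper-tail hypergeometric) per annotation category, adjusted for
  multiplicity with the Westfall–Young minP resampling procedure; GO-Sig is
  the fraction of biclusters with at least one adjusted p below alpha.

* **Gene-overlap diagnostic.**  Mean pairwise Dice overlap of the
  biclusters' gene sets — high values flag methods whose apparent
  enrichment is driven by returning near-copies of one gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .datamodel import (
    BenchmarkConfig,
    BiclusterSet,
    GeneSetCollection,
    SampleTypeLabels,
)

logger = logging.getLogger("bicbench")


# ---------------------------------------------------------------------------
# Dice / Sørensen overlap and the sample-based benchmark
# ---------------------------------------------------------------------------


def dice_overlap(a, b) -> float:
    """Dice/Sørensen coefficient 2|a ∩ b| / (|a| + |b|), in [0, 1].

    Symmetric; 1 iff the sets are equal, 0 iff disjoint.  Undefined (error)
    when both sets are empty.
    """
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ValueError("dice_overlap undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass
class OverlapMatrix:
    """k x t grid of Dice overlaps: rows = biclusters, columns = types."""

    scores: np.ndarray
    type_labels: list[str]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and (
            self.scores.min() < 0 or self.scores.max() > 1
        ):
            raise ValueError("overlap scores must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.scores.shape[0]

    @property
    def t(self) -> int:
        return self.scores.shape[1]


@dataclass
class MatchResult:
    """Greedy matching trace: matched scores v (extraction order) + pairing."""

    v: np.ndarray
    pairing: list[tuple[int, str]]


def overlap_matrix(bs: BiclusterSet, labels: SampleTypeLabels) -> OverlapMatrix:
    """Entry (j, i): Dice overlap of bicluster j's samples with type i's samples."""
    known = set(labels.assignment)
    types = labels.types
    type_sets = [labels.samples_of_type(lab) for lab in types]
    scores = np.zeros((bs.k, len(types)))
    for j, b in enumerate(bs):
        unknown = b.samples - known
        if unknown:
            raise ValueError(
                f"bicluster {j} contains unlabeled sample id {sorted(unknown)[0]!r}"
            )
        for i, cols in enumerate(type_sets):
            scores[j, i] = dice_overlap(b.samples, cols)
    return OverlapMatrix(scores, types)


def greedy_match(d: OverlapMatrix) -> MatchResult:
    """Iteratively extract the global maximum of D, deleting its row and column.

    Repeats until one dimension is exhausted; the extracted values, in
    order, form v (necessarily non-increasing).  Ties break on the lowest
    row index, then the lowest column index.
    """
    if d.k < 1 or d.t < 1:
        raise ValueError("greedy_match needs at least one row and one column")
    scores = d.scores.copy()
    rows = list(range(d.k))
    cols = list(range(d.t))
    v: list[float] = []
    pairing: list[tuple[int, str]] = []
    while rows and cols:
        sub = scores[np.ix_(rows, cols)]
        flat = int(np.argmax(sub))  # argmax scans row-major: lowest row, then col
        ri, ci = divmod(flat, len(cols))
        v.append(float(sub[ri, ci]))
        pairing.append((rows[ri], d.type_labels[cols[ci]]))
        del rows[ri]
        del cols[ci]
    return MatchResult(np.array(v), pairing)


def sample_dif(bs: BiclusterSet, labels: SampleTypeLabels) -> float:
    """Mean of the greedily matched overlap scores; the sample differentiation score."""
    if bs.k == 0:
        logger.warning("sample_dif: empty bicluster set scored as 0.0")
        return 0.0
    return float(greedy_match(overlap_matrix(bs, labels)).v.mean())


# ---------------------------------------------------------------------------
# Resampling significance of gene-set overlap
# ---------------------------------------------------------------------------


@dataclass
class SignificanceResult:
    per_bicluster_p: np.ndarray
    significant_fraction: float
    alpha: float
    n_resamples: int
    seed: int


def _resample_index_matrix(
    rng: np.random.Generator, n_resamples: int, n_universe: int, size: int
) -> np.ndarray:
    """(n_resamples, size) indices of uniform draws without replacement."""
    keys = rng.random((n_resamples, n_universe))
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def resampling_overlap_pvalue(
    bicluster_genes,
    special_genes,
    universe,
    n_resamples: int = 1000,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """Empirical p-value of a gene-set Dice overlap under uniform resampling.

    Draws ``n_resamples`` gene sets of the bicluster's size from the
    universe, computes each draw's Dice overlap with ``special_genes``, and
    returns (1 + #{draws with overlap >= observed}) / (n_resamples + 1).
    With ``strict=True`` the comparison is ">" (only strictly higher
    overlaps count), the literal reading of "higher overlaps"; the default
    ">=" with the add-one correction is conservative and never returns 0.
    """
    bic = frozenset(bicluster_genes)
    spec = frozenset(special_genes)
    uni = sorted(set(universe))
    if not bic <= set(uni):
        raise ValueError("bicluster genes must be a subset of the universe")
    if not spec <= set(uni):
        raise ValueError("special genes must be a subset of the universe")
    m = len(bic)
    if m > len(uni):
        raise ValueError("bicluster larger than universe")
    observed = dice_overlap(bic, spec)
    rng = np.random.default_rng(seed)
    mask = np.array([g in spec for g in uni])
    idx = _resample_index_matrix(rng, n_resamples, len(uni), m)
    counts = mask[idx].sum(axis=1)
    overlaps = 2.0 * counts / (m + len(spec))
    hits = (overlaps > observed) if strict else (overlaps >= observed)
    return (1 + int(hits.sum())) / (n_resamples + 1)


def tiger_sig(
    bs: BiclusterSet,
    special: GeneSetCollection,
    universe,
    cfg: BenchmarkConfig,
    strict: bool = False,
) -> SignificanceResult:
    """Fraction of biclusters whose gene overlap with the pooled
    tissue-specific genes beats the resampling null at ``cfg.alpha``.

    The target set is the union of all type-specific lists in ``special``.
    """
    target = special.union()
    if not target:
        raise ValueError("union of tissue-specific sets is empty")
    uni = sorted(set(universe))
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(bs.k, 1))]
    target_in_universe = frozenset(target) & set(uni)
    pvals = np.array([
        resampling_overlap_pvalue(
            b.genes & set(uni), target_in_universe, uni,
            n_resamples=cfg.n_resamples, seed=seeds[j], strict=strict,
        )
        for j, b in enumerate(bs)
    ]) if bs.k else np.array([])
    frac = float((pvals < cfg.alpha).mean()) if bs.k else 0.0
    return SignificanceResult(pvals, frac, cfg.alpha, cfg.n_resamples, cfg.seed)


# ---------------------------------------------------------------------------
# Fisher's exact enrichment + Westfall–Young minP adjustment
# ---------------------------------------------------------------------------


def fisher_enrichment_pvalue(bicluster_genes, category_genes, universe) -> float:
    """One-sided over-representation p-value (upper hypergeometric tail).

    Probability of observing at least the actual intersection count when
    |bicluster_genes| genes are drawn at random from the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    bic = frozenset(bicluster_genes) & uni
    cat = frozenset(category_genes) & uni
    x = len(bic & cat)
    # P(X >= x) for X ~ Hypergeom(N=|uni|, K=|cat|, n=|bic|)
    return float(hypergeom.sf(x - 1, len(uni), len(cat), len(bic)))


def westfall_young_adjust(
    bicluster_genes,
    categories: GeneSetCollection,
    universe,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Westfall–Young minP adjusted p-values for every category.

    For each resample a random gene set of the bicluster's size is drawn
    from the universe and the minimum Fisher p over all categories is
    recorded; the adjusted p of category c is
    (1 + #{resamples with min-p <= raw p(c)}) / (n_resamples + 1), followed
    by step-down monotonicity enforcement in raw-p order.  Controls the
    family-wise error rate under the complete null.
    """
    uni = sorted(set(universe))
    n = len(uni)
    bic = frozenset(bicluster_genes) & set(uni)
    m = len(bic)
    names = categories.names
    raw = np.array([
        fisher_enrichment_pvalue(bic, categories[c].genes, uni) for c in names
    ])

    member = np.zeros((len(names), n), dtype=np.int32)
    pos = {g: i for i, g in enumerate(uni)}
    sizes = np.zeros(len(names), dtype=np.int64)
    for ci, c in enumerate(names):
        genes = frozenset(categories[c].genes) & set(uni)
        sizes[ci] = len(genes)
        for g in genes:
            member[ci, pos[g]] = 1

    rng = np.random.default_rng(seed)
    idx = _resample_index_matrix(rng, n_resamples, n, m)
    indicator = np.zeros((n, n_resamples), dtype=np.int32)
    indicator[idx.T, np.arange(n_resamples)[None, :]] = 1
    counts = member @ indicator  # categories x resamples intersection counts
    pmat = hypergeom.sf(counts - 1, n, sizes[:, None], m)
    minp = pmat.min(axis=0)

    adj = np.array([
        (1 + int((minp <= p).sum())) / (n_resamples + 1) for p in raw
    ])
    order = np.argsort(raw, kind="stable")
    adj_sorted = np.maximum.accumulate(adj[order])
    out = np.empty_like(adj)
    out[order] = adj_sorted
    return {c: float(out[i]) for i, c in enumerate(names)}


def go_sig(
    bs: BiclusterSet,
    categories: GeneSetCollection,
    universe,
    cfg: BenchmarkConfig,
) -> SignificanceResult:
    """Fraction of biclusters with some adjusted enrichment p below alpha.

    Per bicluster, the reported p is the minimum Westfall–Young-adjusted
    Fisher p over all categories.
    """
    uni = sorted(set(universe))
    ss = np.random.SeedSequence(cfg.seed + 1)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(bs.k, 1))]
    pvals = []
    for j, b in enumerate(bs):
        adj = westfall_young_adjust(
            b.genes, categories, uni, n_resamples=cfg.n_resamples, seed=seeds[j]
        )
        pvals.append(min(adj.values()) if adj else 1.0)
    pvals = np.array(pvals) if pvals else np.array([])
    frac = float((pvals < cfg.alpha).mean()) if bs.k else 0.0
    return SignificanceResult(pvals, frac, cfg.alpha, cfg.n_resamples, cfg.seed)


# ---------------------------------------------------------------------------
# Gene-overlap bias diagnostic
# ---------------------------------------------------------------------------


def mean_pairwise_gene_overlap(bs: BiclusterSet) -> float:
    """Mean Dice overlap of gene sets over all unordered bicluster pairs.

    A high value indicates the method returned near-duplicate gene sets,
    which inflates enrichment-based benchmarks; reported alongside GO-Sig
    as a bias diagnostic.
    """
    if bs.k < 2:
        raise ValueError("need at least two biclusters")
    vals = [
        dice_overlap(bs.biclusters[i].genes, bs.biclusters[j].genes)
        for i in range(bs.k)
        for j in range(i + 1, bs.k)
    ]
    return float(np.mean(vals))
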