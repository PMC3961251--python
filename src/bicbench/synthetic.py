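"""Synthetic multi-tissue expression data with planted, recoverable structure.

The generator emulates the shape of a multi-tissue bulk expression study:
five sample types with group sizes 59/95/13/41/20, each type carrying a
module of signature genes expressed with a type-specific pattern on top of
Gaussian background noise.  Two planted-pattern archetypes are supported:

``constant_shift``
    signature genes are uniformly up-shifted in their type's samples
    (a limited-variance, near-constant block);
``correlated``
    signature genes share a latent per-sample profile: entry =
    a_g * (effect * p_s) + b_g + noise with gene loadings a_g > 0, so the
    genes co-vary across the block's samples.

Ground truth (which genes/samples form which planted bicluster) is recorded
before any missing values are injected, so recovery and significance
statistics can be calibrated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    Bicluster,
    BiclusterSet,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleTypeLabels,
)

#: Sample-type group sizes of the multi-tissue design being emulated.
DEFAULT_TYPE_SIZES: dict[str, int] = {
    "blood_tcell": 59,
    "cerebral_cortex": 95,
    "liver": 13,
    "striated_muscle": 41,
    "testis": 20,
}


@dataclass(frozen=True)
class PlantedBicluster:
    """Ground-truth record of one planted gene x sample block."""

    genes: frozenset[str]
    samples: frozenset[str]
    pattern_kind: str  # "correlated" | "constant_shift"
    effect_size: float

    def __post_init__(self):
        if self.pattern_kind not in ("correlated", "constant_shift"):
            raise ValueError(f"unknown pattern kind {self.pattern_kind!r}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


@dataclass
class GroundTruth:
    planted: list[PlantedBicluster]
    type_signatures: dict[str, frozenset[str]]
    noise_sd: float
    seed: int


@dataclass
class SimulationConfig:
    """Design of one simulated dataset.

    Defaults mirror the emulated study: 5 tissue types, 228 samples.  The
    gene pool defaults to 2000 genes with 100 signature genes per type —
    large enough that random gene sets are overwhelmingly non-signature,
    small enough to keep resampling benchmarks quick.
    """

    n_genes: int = 2000
    type_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_SIZES)
    )
    signature_size: int = 100
    n_extra_biclusters: int = 0
    overlap_fraction: float = 0.0
    noise_sd: float = 1.0
    effect_size: float = 2.0
    missing_rate: float = 0.0
    correlated_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not self.type_sizes:
            raise ValueError("type_sizes must be non-empty")
        if any(n < 1 for n in self.type_sizes.values()):
            raise ValueError("each type needs at least one sample")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.correlated_fraction <= 1.0:
            raise ValueError("correlated_fraction must be in [0, 1]")
        t = len(self.type_sizes)
        need = self.signature_size * t
        if self.overlap_fraction == 0.0 and need > self.n_genes:
            raise ValueError(
                f"signature_size * t = {need} exceeds gene pool of {self.n_genes}"
            )

    @property
    def t(self) -> int:
        return len(self.type_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.type_sizes.values())


def _scaled(sizes: dict[str, int], factor: float) -> dict[str, int]:
    return {k: max(1, round(v * factor)) for k, v in sizes.items()}


def desk_config(**overrides) -> SimulationConfig:
    """A small configuration: group sizes scaled to ~1/4, 1000 genes.

    Proportions of the five groups are preserved (15/24/3/10/5 samples).
    """
    defaults = dict(
        n_genes=1000,
        type_sizes=_scaled(DEFAULT_TYPE_SIZES, 0.25),
        signature_size=50,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _apply_pattern(
    values: np.ndarray,
    gene_idx: np.ndarray,
    sample_idx: np.ndarray,
    kind: str,
    effect: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> None:
    """Overwrite the block in-place with the chosen planted pattern."""
    g, s = len(gene_idx), len(sample_idx)
    if kind == "constant_shift":
        values[np.ix_(gene_idx, sample_idx)] += effect
    else:  # correlated: shared latent profile with positive gene loadings
        p = rng.normal(0.0, 1.0, size=s)
        a = rng.uniform(0.5, 2.0, size=g)
        b = rng.normal(0.0, 1.0, size=g)
        block = (
            effect * np.outer(a, p)
            + b[:, None]
            + rng.normal(0.0, noise_sd, size=(g, s))
        )
        values[np.ix_(gene_idx, sample_idx)] = block


def generate_multitissue_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTypeLabels, GroundTruth]:
    """Simulate a matrix with planted per-type signature modules.

    Background entries are Normal(0, noise_sd^2).  Types are assigned a
    pattern kind deterministically: the first round(correlated_fraction * t)
    types (in declaration order) get the correlated archetype, the rest the
    constant shift.  Extra biclusters are planted over random gene/sample
    subsets, optionally reusing a fraction of an earlier block's genes and
    samples (``overlap_fraction``).  Missing values are injected uniformly
    at random only after ground truth is fixed.
    """
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.type_sizes)
    t = cfg.t

    width = max(4, len(str(cfg.n_genes)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(cfg.n_genes)])
    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    col_of_type: dict[str, np.ndarray] = {}
    col = 0
    for lab in types:
        n = cfg.type_sizes[lab]
        ids = [f"{lab}_{i:03d}" for i in range(n)]
        sample_ids.extend(ids)
        for sid in ids:
            assignment[sid] = lab
        col_of_type[lab] = np.arange(col, col + n)
        col += n
    n_samples = col

    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    # signature gene indices: disjoint draw, then optional reuse for overlap
    n_corr = round(cfg.correlated_fraction * t)
    pool = rng.permutation(cfg.n_genes)
    planted: list[PlantedBicluster] = []
    type_signatures: dict[str, frozenset[str]] = {}
    sig_idx: list[np.ndarray] = []
    pos = 0
    n_reuse = (
        math.floor(cfg.overlap_fraction * cfg.signature_size)
        if cfg.overlap_fraction > 0
        else 0
    )
    for i, lab in enumerate(types):
        if i > 0 and n_reuse > 0:
            reused = rng.choice(sig_idx[i - 1], size=n_reuse, replace=False)
            fresh = pool[pos : pos + cfg.signature_size - n_reuse]
            pos += cfg.signature_size - n_reuse
            idx = np.concatenate([reused, fresh])
        else:
            idx = pool[pos : pos + cfg.signature_size]
            pos += cfg.signature_size
        if len(idx) < cfg.signature_size:
            raise ValueError("gene pool exhausted while placing signatures")
        sig_idx.append(np.sort(idx))
        kind = "correlated" if i < n_corr else "constant_shift"
        _apply_pattern(
            values, sig_idx[i], col_of_type[lab], kind, cfg.effect_size,
            cfg.noise_sd, rng,
        )
        genes = frozenset(gene_ids[sig_idx[i]])
        samples = frozenset(sample_ids[j] for j in col_of_type[lab])
        type_signatures[lab] = genes
        planted.append(
            PlantedBicluster(genes, samples, kind, cfg.effect_size)
        )

    # extra planted biclusters beyond the per-type signatures
    mean_type = max(2, round(n_samples / t))
    for e in range(cfg.n_extra_biclusters):
        gsize = cfg.signature_size
        ssize = min(mean_type, n_samples)
        if cfg.overlap_fraction > 0 and planted:
            src = planted[int(rng.integers(len(planted)))]
            g_re = min(n_reuse, len(src.genes))
            s_re = min(math.floor(cfg.overlap_fraction * ssize), len(src.samples))
            g_reused = rng.choice(sorted(src.genes), size=g_re, replace=False)
            s_reused = rng.choice(sorted(src.samples), size=s_re, replace=False)
            g_rest = rng.choice(
                np.setdiff1d(gene_ids, g_reused), size=gsize - g_re, replace=False
            )
            s_rest = rng.choice(
                np.setdiff1d(np.array(sample_ids), s_reused),
                size=ssize - s_re, replace=False,
            )
            genes = frozenset(g_reused) | frozenset(g_rest)
            samples = frozenset(s_reused) | frozenset(s_rest)
        else:
            remaining = pool[pos:]
            if len(remaining) >= gsize:
                idx = remaining[:gsize]
                pos += gsize
            else:
                idx = rng.choice(cfg.n_genes, size=gsize, replace=False)
            genes = frozenset(gene_ids[idx])
            samples = frozenset(
                np.array(sample_ids)[
                    rng.choice(n_samples, size=ssize, replace=False)
                ]
            )
        kind = "correlated" if (e % 2 == 0) else "constant_shift"
        g_pos = np.sort([np.searchsorted(gene_ids, g) for g in sorted(genes)])
        s_pos = np.sort([sample_ids.index(s) for s in sorted(samples)])
        _apply_pattern(
            values, np.asarray(g_pos), np.asarray(s_pos), kind,
            cfg.effect_size, cfg.noise_sd, rng,
        )
        planted.append(PlantedBicluster(genes, samples, kind, cfg.effect_size))

    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    matrix = ExpressionMatrix.from_arrays(list(gene_ids), sample_ids, values)
    labels = SampleTypeLabels(assignment)
    truth = GroundTruth(planted, type_signatures, cfg.noise_sd, cfg.seed)
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Annotation sets derived from the ground truth
# ---------------------------------------------------------------------------


def tissue_gene_sets(
    truth: GroundTruth,
    cfg: SimulationConfig,
    dropout: float = 0.0,
    spurious: float = 0.0,
) -> GeneSetCollection:
    """Tissue-specific gene lists, one per type, from the planted signatures.

    ``dropout`` removes a fraction of true members (the list keeps
    ceil((1 - dropout) * size) of them); ``spurious`` adds that fraction of
    random non-signature genes.  Both mimic database incompleteness.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    width = max(4, len(str(cfg.n_genes)))
    universe = np.array([f"g{i:0{width}d}" for i in range(cfg.n_genes)])
    sets = []
    for lab, genes in truth.type_signatures.items():
        members = np.array(sorted(genes))
        if dropout > 0:
            n_keep = math.ceil((1.0 - dropout) * len(members))
            members = rng.choice(members, size=n_keep, replace=False)
        if spurious > 0:
            n_add = round(spurious * len(genes))
            candidates = np.setdiff1d(universe, np.array(sorted(genes)))
            members = np.concatenate(
                [members, rng.choice(candidates, size=n_add, replace=False)]
            )
        sets.append(GeneSet(lab, f"tissue-specific genes ({lab})", frozenset(members)))
    return GeneSetCollection(sets)


def go_like_categories(
    truth: GroundTruth,
    cfg: SimulationConfig,
    n_background: int = 20,
    background_size: int = 50,
) -> GeneSetCollection:
    """Annotation categories: one per planted module plus random background.

    Background categories are drawn uniformly from the gene universe and
    play the role of unenriched annotation terms.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    width = max(4, len(str(cfg.n_genes)))
    universe = np.array([f"g{i:0{width}d}" for i in range(cfg.n_genes)])
    sets = []
    for i, pb in enumerate(truth.planted):
        sets.append(
            GeneSet(f"module_{i:02d}", f"planted {pb.pattern_kind} module", pb.genes)
        )
    for j in range(n_background):
        members = rng.choice(universe, size=background_size, replace=False)
        sets.append(GeneSet(f"background_{j:02d}", "random category", frozenset(members)))
    return GeneSetCollection(sets)


def generate_annotation_sets(
    truth: GroundTruth,
    cfg: SimulationConfig,
    dropout: float = 0.0,
    spurious: float = 0.0,
    n_background: int = 20,
    background_size: int = 50,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Convenience wrapper: (tissue-specific sets, GO-like categories)."""
    return (
        tissue_gene_sets(truth, cfg, dropout=dropout, spurious=spurious),
        go_like_categories(
            truth, cfg, n_background=n_background, background_size=background_size
        ),
    )


def oracle_bicluster_set(
    truth: GroundTruth, labels: SampleTypeLabels
) -> BiclusterSet:
    """Perfect-recovery control: one bicluster per planted block.

    Type-signature blocks come first, in label order, each spanning exactly
    that type's samples; extra planted blocks follow.
    """
    bics = []
    seen: set[tuple[frozenset, frozenset]] = set()
    for lab, genes in truth.type_signatures.items():
        b = Bicluster(genes, labels.samples_of_type(lab))
        bics.append(b)
        seen.add((b.genes, b.samples))
    for pb in truth.planted:
        key = (frozenset(pb.genes), frozenset(pb.samples))
        if key not in seen:
            bics.append(Bicluster(pb.genes, pb.samples))
            seen.add(key)
    return BiclusterSet(method_name="oracle", parameters={}, biclusters=bics)
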