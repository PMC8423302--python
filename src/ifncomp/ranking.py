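"""Gene-set selection from DE tables and nonparametric group comparisons.

Interferome gene classes are selected from a differential-expression table:
ISGs are the most upregulated significantly DE genes (FDR < 0.05, largest
mean log2 fold change) and IRGs the most downregulated; random control sets
are drawn from non-DE genes with expression evidence in every sample.
Group comparisons use the Wilcoxon rank sum test with continuity correction
(two groups) or the Kruskal–Wallis test followed by Dunn's post hoc test
with Benjamini–Hochberg correction (more than two groups); CpG frequency
distributions are non-normal, so tests are nonparametric throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import composition
from .sequence_io import DERecord, GeneRecord

FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeneSet:
    label: str  # ISG | IRG | RANDOM | custom
    gene_ids: tuple[str, ...]
    species: str = "unknown"

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.label}: duplicate gene ids")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.label} ({self.species}), n={len(self.gene_ids)}\n")
            for gid in self.gene_ids:
                fh.write(gid + "\n")


def rank_top_de(
    de_table: Sequence[DERecord],
    direction: Literal["up", "down"],
    n: int,
    species: str = "unknown",
) -> GeneSet:
    """The n most up- or downregulated significantly DE genes, by mean log2FC.

    Only genes with FDR < 0.05 are ranked; ties are broken by gene id. When
    fewer than n genes are significant in the requested direction all of
    them are returned.
    """
    if not de_table:
        raise ValueError("empty DE table")
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    sig = [r for r in de_table if r.fdr < FDR_THRESHOLD]
    if direction == "up":
        sig = [r for r in sig if r.log2fc >= 0]
        sig.sort(key=lambda r: (-r.log2fc, r.gene_id))
    else:
        sig = [r for r in sig if r.log2fc < 0]
        sig.sort(key=lambda r: (r.log2fc, r.gene_id))
    chosen = sig[:n]
    return GeneSet(
        label="ISG" if direction == "up" else "IRG",
        gene_ids=tuple(r.gene_id for r in chosen),
        species=species,
    )


def select_random_genes(
    de_table: Sequence[DERecord],
    n: int,
    seed: int,
    species: str = "unknown",
) -> GeneSet:
    """Uniform sample of n non-DE genes expressed in every sample.

    Candidates are the genes with FDR >= 0.05 and expression evidence in all
    samples; the draw is without replacement and reproducible under seed.
    """
    pool = sorted(
        r.gene_id
        for r in de_table
        if r.fdr >= FDR_THRESHOLD and r.expressed_all_samples
    )
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} eligible non-DE genes for a random set of {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return GeneSet(
        label="RANDOM",
        gene_ids=tuple(pool[i] for i in sorted(chosen)),
        species=species,
    )


def select_most_suppressed(
    records: Iterable[GeneRecord],
    metric: Literal["cpg_frequency", "normalised"] = "cpg_frequency",
    n: int = 1000,
    min_len: int = 100,
    species: str = "unknown",
) -> GeneSet:
    """The n transcripts with the lowest CpG content, after a length filter.

    Transcripts must be strictly longer than min_len nucleotides; ties in
    the metric are broken by gene id. If fewer than n candidates remain all
    are returned with a warning.
    """
    metric_fn: Callable[[str], float]
    if metric == "cpg_frequency":
        metric_fn = composition.cpg_frequency
    elif metric == "normalised":
        metric_fn = composition.cpg_frequency_normalised
    else:
        raise ValueError(f"unknown metric {metric!r}")
    scored = []
    for r in records:
        if len(r.cdna) <= min_len:
            continue
        try:
            scored.append((metric_fn(r.cdna), r.gene_id))
        except composition.UndefinedCompositionError:
            continue
    scored.sort()
    if len(scored) < n:
        warnings.warn(
            f"only {len(scored)} candidates for the {n} most CpG-suppressed; "
            "returning all", stacklevel=2,
        )
    return GeneSet(
        label="custom",
        gene_ids=tuple(gid for _, gid in scored[:n]),
        species=species,
    )


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank sum p-value, normal approximation with
    continuity and tie correction."""
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 observations")
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all observations identical: no evidence either way
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class KruskalDunnResult:
    """Omnibus Kruskal–Wallis p plus pairwise Dunn tests, BH-adjusted."""

    omnibus_p: float
    pairs: tuple[tuple[int, int], ...]
    z: tuple[float, ...]
    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    group_labels: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        labels = self.group_labels or tuple(
            str(i) for i in range(max(j for _, j in self.pairs) + 1)
        )
        return pd.DataFrame(
            {
                "group_a": [labels[i] for i, _ in self.pairs],
                "group_b": [labels[j] for _, j in self.pairs],
                "z": self.z,
                "p": self.raw_p,
                "p_adjusted": self.adjusted_p,
            }
        )


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> KruskalDunnResult:
    """Kruskal–Wallis omnibus test with Dunn's post hoc z-tests.

    All pairwise Dunn p-values are Benjamini–Hochberg adjusted across the
    pair set. Degenerate input (every observation identical) yields p = 1
    throughout.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    labels = tuple(labels) if labels is not None else tuple(
        f"group{i+1}" for i in range(len(arrays))
    )
    pooled = np.concatenate(arrays)
    pairs = tuple(itertools.combinations(range(len(arrays)), 2))

    if np.ptp(pooled) == 0:
        ones = tuple(1.0 for _ in pairs)
        return KruskalDunnResult(1.0, pairs, tuple(0.0 for _ in pairs),
                                 ones, ones, labels)

    omnibus = float(stats.kruskal(*arrays).pvalue)

    # Dunn's test: pairwise z on mean ranks with tie correction
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrays))
    ]
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_total - 1))

    z_list, p_list = [], []
    for i, j in pairs:
        sigma = np.sqrt(
            (n_total * (n_total + 1) / 12 - tie_term)
            * (1 / sizes[i] + 1 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / sigma if sigma > 0 else 0.0
        z_list.append(float(z))
        p_list.append(float(2 * stats.norm.sf(abs(z))))

    adjusted = multipletests(p_list, method="fdr_bh")[1]
    return KruskalDunnResult(
        omnibus_p=omnibus,
        pairs=pairs,
        z=tuple(z_list),
        raw_p=tuple(p_list),
        adjusted_p=tuple(float(p) for p in adjusted),
        group_labels=labels,
    )
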