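"""Synthetic inputs with known compositional structure.

Every stage of the pipeline can be exercised without downloads: this module
generates (a) transcript sequences from a first-order Markov chain whose
stationary base composition and CpG odds ratio are set exactly, (b) valid
ORFs whose CpG content is steered through synonymous-codon choice, (c) DE
tables with configurable ISG/IRG effect and FDR structure, and (d)
multi-species alignments with a planted CpG conservation spectrum.

The first-order Markov model is the minimal generative model with a
controllable dinucleotide odds ratio; it exists to test the pipeline, not
to model transcript biology. Every generator is a pure function of its seed
and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .composition import AA_FAMILIES, _CODON_TO_AA
from .sequence_io import AlignmentBlock, DERecord, GeneRecord
from .conservation import ConservationProfile

BASES = "ACGT"

#: default stationary base composition, loosely mammalian-transcript-like
DEFAULT_BASE_COMPOSITION: dict[str, float] = {
    "A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26,
}

SENSE_CODONS = tuple(c for c, aa in _CODON_TO_AA.items() if aa != "*")
STOP_CODONS = tuple(AA_FAMILIES["*"])


def markov_transition_matrix(
    base_composition: Mapping[str, float],
    target_cpg_odds: float,
) -> np.ndarray:
    """Transition matrix with stationary composition pi and CG odds ratio t.

    Row C is set so that P(C->G) = t * pi_G (giving stationary CG frequency
    pi_C * t * pi_G, i.e. odds ratio exactly t), with the remaining mass
    distributed over A/C/T proportionally to pi. All other rows share a
    common distribution q solved so that pi stays the stationary law.
    Raises for targets that would force a negative probability, naming the
    feasible bound.
    """
    pi = np.array([base_composition[b] for b in BASES], float)
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("base composition must sum to 1")
    if np.any(pi <= 0):
        raise ValueError("base composition must be strictly positive")
    t = float(target_cpg_odds)
    if t <= 0:
        raise ValueError("target CpG odds must be > 0")
    pi_c, pi_g = pi[BASES.index("C")], pi[BASES.index("G")]
    if t * pi_g >= 1:
        raise ValueError(
            f"target odds {t} infeasible: requires P(C->G) = {t * pi_g:.3f} "
            f">= 1; bound is t < {1 / pi_g:.3f}"
        )
    row_c = pi * (1 - t * pi_g) / (1 - pi_g)
    row_c[BASES.index("G")] = t * pi_g
    # q shared by rows A, G, T keeps pi stationary: pi = pi_C row_C + (1-pi_C) q
    q = (pi - pi_c * row_c) / (1 - pi_c)
    if np.any(q < 0):
        raise ValueError(
            f"target odds {t} infeasible with this composition: compensating "
            f"row would need a negative probability; bound is t <= {1 / pi_c:.3f}"
        )
    P = np.tile(q, (4, 1))
    P[BASES.index("C")] = row_c
    return P


def generate_sequence(
    length: int,
    target_cpg_odds: float = 1.0,
    base_composition: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """A first-order Markov sequence with designed composition and CpG odds."""
    if length < 2:
        raise ValueError("length must be >= 2")
    comp = dict(base_composition or DEFAULT_BASE_COMPOSITION)
    P = markov_transition_matrix(comp, target_cpg_odds)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.array([comp[b] for b in BASES])
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    state = out[0]
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = state
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def _codon_weights(
    prev_last: str,
    codons: Sequence[str],
    base_p: Mapping[str, float],
    t: float,
) -> np.ndarray:
    """Sampling weights: base-composition product times t per CG formed."""
    w = np.empty(len(codons))
    for k, c in enumerate(codons):
        n_cg = (prev_last == "C" and c[0] == "G") + (c[0] == "C" and c[1] == "G") \
            + (c[1] == "C" and c[2] == "G")
        w[k] = base_p[c[0]] * base_p[c[1]] * base_p[c[2]] * (t ** n_cg)
    return w / w.sum()


def generate_cds(
    n_codons: int,
    target_cpg_odds: float = 1.0,
    seed: int | np.random.Generator = 0,
    base_composition: Mapping[str, float] | None = None,
) -> str:
    """A valid ORF (ATG ... stop, no internal stops) of 3*n_codons nt.

    CpG content is steered toward the target odds ratio by weighting each
    candidate codon with t per CG dinucleotide it would create (within the
    codon or bridging from the previous codon). The realised odds is
    nearest-feasible under the ORF constraints rather than exact.
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2 (start + stop)")
    comp = dict(base_composition or DEFAULT_BASE_COMPOSITION)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = float(target_cpg_odds)
    if t <= 0:
        raise ValueError("target CpG odds must be > 0")
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        w = _codon_weights(codons[-1][2], SENSE_CODONS, comp, t)
        codons.append(SENSE_CODONS[int(rng.choice(len(SENSE_CODONS), p=w))])
    w = _codon_weights(codons[-1][2], STOP_CODONS, comp, t)
    codons.append(STOP_CODONS[int(rng.choice(len(STOP_CODONS), p=w))])
    return "".join(codons)


# --------------------------------------------------------------------------
# Gene sets: sequences + DE table + labels


@dataclass(frozen=True)
class GeneSetDesign:
    """Study conditions for a synthetic interferome gene set.

    Per-class normalised-CpG targets bracket the suppression visible in the
    real interferome (strongly suppressed ISGs, near-genome-average random
    genes, CpG-rich IRGs); log2FC distributions give ISGs positive and IRGs
    negative mean fold changes with significant FDRs, while random genes are
    centred at zero and non-significant.
    """

    n_isg: int = 50
    n_irg: int = 50
    n_random: int = 50
    cpg_odds: Mapping[str, float] = field(
        default_factory=lambda: {"ISG": 0.4, "RANDOM": 0.8, "IRG": 1.2}
    )
    length_median: float = 1500.0  # nt, log-normal
    length_sigma: float = 0.4  # dispersion of log length
    cds_fraction: float = 0.5  # share of the transcript that is ORF
    log2fc_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ISG": 4.0, "RANDOM": 0.0, "IRG": -4.0}
    )
    log2fc_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ISG": 1.0, "RANDOM": 0.25, "IRG": 1.0}
    )
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COMPOSITION)
    )
    species: str = "synthetic"
    seed: int = 0

    def manifest(self) -> dict:
        d = asdict(self)
        d["cpg_odds"] = dict(self.cpg_odds)
        d["log2fc_mean"] = dict(self.log2fc_mean)
        d["log2fc_sd"] = dict(self.log2fc_sd)
        d["base_composition"] = dict(self.base_composition)
        return d


def _one_gene(
    gene_id: str,
    cls: str,
    design: GeneSetDesign,
    rng: np.random.Generator,
) -> tuple[GeneRecord, DERecord]:
    t = design.cpg_odds[cls]
    length = int(round(design.length_median
                       * math.exp(rng.normal(0.0, design.length_sigma))))
    length = max(length, 90)
    n_codons = max(8, int(length * design.cds_fraction // 3))
    cds = generate_cds(n_codons, t, rng, design.base_composition)
    utr_total = max(length - 3 * n_codons, 2)
    utr5_len = max(utr_total // 3, 1)
    utr3_len = max(utr_total - utr5_len, 1)
    utr5 = generate_sequence(utr5_len + 1, t, design.base_composition, rng)[1:] \
        if utr5_len >= 1 else ""
    utr3 = generate_sequence(utr3_len + 1, t, design.base_composition, rng)[1:] \
        if utr3_len >= 1 else ""
    record = GeneRecord(
        gene_id=gene_id, cdna=utr5 + cds + utr3, cds=cds, species=design.species
    )
    lfc = rng.normal(design.log2fc_mean[cls], design.log2fc_sd[cls])
    if cls == "ISG":
        lfc = max(lfc, 0.2)
        fdr = rng.uniform(1e-6, 0.049)
    elif cls == "IRG":
        lfc = min(lfc, -0.2)
        fdr = rng.uniform(1e-6, 0.049)
    else:
        fdr = rng.uniform(0.05, 1.0)
    de = DERecord(gene_id=gene_id, log2fc=float(lfc), fdr=float(fdr),
                  expressed_all_samples=True)
    return record, de


def generate_gene_set(
    design: GeneSetDesign,
) -> tuple[list[GeneRecord], list[DERecord], dict[str, str], dict]:
    """Records, DE table, true class labels and a manifest, from one design."""
    rng = np.random.default_rng(design.seed)
    records: list[GeneRecord] = []
    de_table: list[DERecord] = []
    labels: dict[str, str] = {}
    plan = [("ISG", design.n_isg), ("IRG", design.n_irg), ("RANDOM", design.n_random)]
    for cls, count in plan:
        for i in range(count):
            gid = f"{cls}{i + 1:04d}"
            rec, de = _one_gene(gid, cls, design, rng)
            records.append(rec)
            de_table.append(de)
            labels[gid] = cls
    return records, de_table, labels, design.manifest()


# --------------------------------------------------------------------------
# Alignments with a planted conservation spectrum


def _cpg_free_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence (byte array) guaranteed to contain no CG dinucleotide."""
    arr = np.frombuffer(
        "".join(rng.choice(list(BASES), size=length)).encode(), dtype=np.uint8
    ).copy()
    c, g = ord("C"), ord("G")
    for i in range(1, length):  # G after C -> replace the G
        if arr[i - 1] == c and arr[i] == g:
            arr[i] = ord("A")
    return arr


def generate_alignment_set(
    n_genes: int,
    n_species: int,
    lengths: int | Sequence[int],
    conservation_spectrum: Mapping[int, int],
    seed: int = 0,
) -> tuple[list[AlignmentBlock], ConservationProfile]:
    """Gapless alignments with CpG sites planted at specified degrees.

    ``conservation_spectrum`` maps degree d (number of species carrying the
    CpG) to the total number of CpG *instances* at that degree; instances
    must be a multiple of d (each planted site contributes d instances).
    Which rows carry each planted CpG is chosen uniformly at random.
    Background sequence is CpG-free, so the returned ground-truth profile is
    exact.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if isinstance(lengths, int):
        lengths = [lengths] * n_genes
    lengths = list(lengths)
    if len(lengths) != n_genes:
        raise ValueError("lengths must match n_genes")

    sites: list[int] = []
    for d, instances in sorted(conservation_spectrum.items()):
        if not 1 <= d <= n_species:
            raise ValueError(f"degree {d} outside 1..{n_species}")
        if instances % d != 0:
            raise ValueError(
                f"degree {d}: {instances} instances is not a multiple of {d}"
            )
        sites += [d] * (instances // d)

    # non-overlapping column pairs, one per 3 columns
    capacity_per_gene = [max((L - 1) // 3, 0) for L in lengths]
    if len(sites) > sum(capacity_per_gene):
        raise ValueError(
            f"spectrum needs {len(sites)} sites but alignments only fit "
            f"{sum(capacity_per_gene)}"
        )

    rng = np.random.default_rng(seed)
    rng.shuffle(sites)
    blocks: list[AlignmentBlock] = []
    site_iter = iter(sites)
    remaining = len(sites)
    for gi, L in enumerate(lengths):
        mat = np.vstack([_cpg_free_background(L, rng) for _ in range(n_species)])
        for slot in range(capacity_per_gene[gi]):
            if remaining == 0:
                break
            d = next(site_iter)
            remaining -= 1
            col = 3 * slot
            carriers = rng.choice(n_species, size=d, replace=False)
            mat[:, col] = ord("A")
            mat[:, col + 1] = ord("T")
            mat[carriers, col] = ord("C")
            mat[carriers, col + 1] = ord("G")
        rows = tuple(mat[i].tobytes().decode("ascii") for i in range(n_species))
        blocks.append(
            AlignmentBlock(
                gene_id=f"aln{gi + 1:03d}",
                rows=rows,
                species_labels=tuple(f"species{k + 1}" for k in range(n_species)),
            )
        )
    if remaining:
        raise ValueError("internal error: unplaced CpG sites")

    total_kb = n_species * sum(lengths) / 1000.0
    instances_by_degree = [int(conservation_spectrum.get(d, 0))
                           for d in range(1, n_species + 1)]
    profile = ConservationProfile(
        species_count=n_species,
        cpg_instance_count=tuple(instances_by_degree),
        cpg_per_kb=tuple(x / total_kb for x in instances_by_degree),
        total_ungapped_kb=total_kb,
    )
    return blocks, profile
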