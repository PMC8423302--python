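"""Codon Adaptation Index.

The relative adaptiveness weight of codon ``c`` is ``w_c = f_c / max(f_c')``
where the maximum runs over the synonymous codons of the same amino acid and
``f`` are codon frequencies pooled over a reference CDS collection
(typically all CDSs of a genome). The CAI of a CDS is the geometric mean of
the weights of its codons over its codon length L, computed in the log
domain for numerical stability. Stop codons are excluded both from the
weight table and from L; single-codon families (Met, Trp) always have
weight 1. Codons never observed in the reference receive a 0.5 pseudo-count
before weights are formed, so no weight is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .composition import AA_FAMILIES, CODONS, _CODON_TO_AA

SENSE_CODONS = tuple(c for c in CODONS if _CODON_TO_AA[c] != "*")


@dataclass(frozen=True)
class CodonWeightTable:
    """Genome-wide codon frequencies and relative adaptiveness weights."""

    f: Mapping[str, float]  # frequency (count) per sense codon
    w: Mapping[str, float]  # relative adaptiveness in (0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": list(SENSE_CODONS),
             "frequency": [self.f[c] for c in SENSE_CODONS],
             "weight": [self.w[c] for c in SENSE_CODONS]}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CodonWeightTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            f=dict(zip(df["codon"], df["frequency"].astype(float))),
            w=dict(zip(df["codon"], df["weight"].astype(float))),
        )


@dataclass(frozen=True)
class CaiResult:
    gene_id: str
    cai: float


def codon_weights(reference_cds: Iterable[str]) -> CodonWeightTable:
    """Relative adaptiveness weights from a pooled reference CDS collection."""
    counts = {c: 0.0 for c in SENSE_CODONS}
    n_seqs = 0
    for cds in reference_cds:
        n_seqs += 1
        if len(cds) % 3 != 0:
            raise ValueError("reference CDS length not a multiple of 3")
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i:i + 3].upper()
            if codon in counts:
                counts[codon] += 1
    if n_seqs == 0:
        raise ValueError("empty reference CDS collection")
    # pseudo-count for unobserved codons keeps every weight positive
    for c in counts:
        if counts[c] == 0:
            counts[c] = 0.5
    weights = {}
    for aa, family in AA_FAMILIES.items():
        if aa == "*":
            continue
        fam_max = max(counts[c] for c in family)
        for c in family:
            weights[c] = counts[c] / fam_max
    return CodonWeightTable(f=counts, w=weights)


def compute_cai(cds: str, weights: CodonWeightTable, gene_id: str = "") -> CaiResult:
    """Geometric mean of codon weights over the CDS's non-stop codons."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3].upper()
        if codon in weights.w:  # skips stops and N-containing codons
            log_sum += math.log(weights.w[codon])
            n += 1
    if n == 0:
        raise ValueError(f"{gene_id or 'CDS'}: no scoreable (non-stop) codons")
    return CaiResult(gene_id=gene_id, cai=math.exp(log_sum / n))


def cai_table(
    cds_by_gene: Mapping[str, str], weights: CodonWeightTable
) -> pd.DataFrame:
    """CAI for many genes as a two-column DataFrame (gene_id, cai)."""
    rows = [(gid, compute_cai(s, weights, gid).cai) for gid, s in cds_by_gene.items()]
    return pd.DataFrame(rows, columns=["gene_id", "cai"])
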