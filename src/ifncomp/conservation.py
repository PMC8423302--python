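"""CpG conservation across multi-species alignments.

For every aligned column pair (j, j+1) the number of rows carrying a CpG
(C immediately followed by G, neither a gap nor N) is the site's degree of
conservation d. Each carrying row contributes one CpG *instance* to bin d,
so with S species the bins run 1..S (d = S means the CpG is conserved in
every species). Bins are normalised to CpG/kb by the total ungapped length
of all rows across all genes, which keeps cross-degree comparisons
length-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sequence_io import AlignmentBlock


@dataclass(frozen=True)
class ConservationProfile:
    """CpG instances and CpG/kb binned by conservation degree 1..S."""

    species_count: int
    cpg_instance_count: tuple[int, ...]  # index d-1 -> instances at degree d
    cpg_per_kb: tuple[float, ...]
    total_ungapped_kb: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": np.arange(1, self.species_count + 1),
                "instances": self.cpg_instance_count,
                "cpg_per_kb": self.cpg_per_kb,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def cpg_conservation_profile(
    alignments: Iterable[AlignmentBlock],
) -> ConservationProfile:
    """Bin the CpG instances of an alignment set by conservation degree.

    All blocks must have the same number of rows (species). A row carries a
    CpG at column pair (j, j+1) only if it has literal C then G there; a gap
    or N in either column means that row lacks a CpG at that site, but the
    site is still evaluated for the other rows. Overlapping CpGs (CGCG) are
    counted at every column pair independently.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("empty alignment collection")
    s = alignments[0].n_species
    if any(b.n_species != s for b in alignments):
        counts = sorted({b.n_species for b in alignments})
        raise ValueError(f"alignments disagree on species count: {counts}")

    instances = np.zeros(s + 1, dtype=int)  # index = degree
    total_ungapped = 0
    for block in alignments:
        mat = np.frombuffer("".join(block.rows).encode("ascii"),
                            dtype=np.uint8).reshape(s, block.aligned_length)
        cg = (mat[:, :-1] == ord("C")) & (mat[:, 1:] == ord("G"))
        degree = cg.sum(axis=0)  # per column pair
        present = degree[degree > 0]
        if present.size:
            # each of the d carrying rows contributes one instance to bin d
            instances += np.bincount(present, weights=present,
                                     minlength=s + 1).astype(int)
        total_ungapped += sum(block.ungapped_lengths())

    total_kb = total_ungapped / 1000.0
    per_kb = instances[1:] / total_kb if total_kb > 0 else np.zeros(s)
    return ConservationProfile(
        species_count=s,
        cpg_instance_count=tuple(int(x) for x in instances[1:]),
        cpg_per_kb=tuple(float(x) for x in per_kb),
        total_ungapped_kb=total_kb,
    )
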