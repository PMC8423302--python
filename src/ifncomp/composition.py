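"""Per-sequence compositional statistics.

CpG metrics central to the analysis:

* ``CpG frequency`` = #CG dinucleotides / (L - 1), with L the full transcript
  length,
* ``normalised CpG frequency`` = CpG frequency / (Prop(C) * Prop(G)) — the
  observed/expected odds ratio; values below 1 indicate CpG suppression,
* ``expected CpG`` = Prop(C) * Prop(G) * (L - 1).

On top of these, the module computes the full 185-feature compositional
vector used by the expression-class classifiers: a 34-entry whole-transcript
block (GC, AT, 16 dinucleotide biases, 16 dinucleotide proportions) and a
151-entry ORF block (GC, AT, 16 dinucleotide biases and proportions, 64
codon usage biases, 21 amino-acid proportions including stop, and 16 + 16
dinucleotide biases at codon bridge / non-bridge positions).

N handling: dinucleotide positions containing N are excluded from both the
numerator and the valid-position denominator; mononucleotide proportions are
computed over non-N bases; the L in the printed CpG formulas remains the
total sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import GeneRecord

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)  # AA..TT lexicographic
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"
AMINO_ACIDS = tuple(sorted(set(_CODON_TO_AA.values()) - {"*"})) + ("*",)  # 20 + stop

#: codons grouped by the amino acid (or stop) they encode
AA_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in CODONS if _CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}

FEATURE_SCHEME_VERSION = "1.0"


class UndefinedCompositionError(ValueError):
    """A compositional ratio is undefined (zero expectation) for this sequence."""


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, N=-1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        codes[arr == ord(b)] = i
    return codes


def base_proportions(seq: str) -> dict[str, float]:
    """Proportion of each of A, C, G, T among non-N bases."""
    codes = _encode(seq)
    valid = codes[codes >= 0]
    if valid.size == 0:
        raise UndefinedCompositionError("sequence has no unambiguous bases")
    counts = np.bincount(valid, minlength=4)
    props = counts / valid.size
    return dict(zip(BASES, props.tolist()))


def count_dinucleotides(seq: str) -> dict[str, int]:
    """Counts of the 16 ordered dinucleotides over all overlapping positions.

    Positions where either base is N are excluded from the counts (and from
    the valid-position denominator used for proportions).
    """
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 nt")
    codes = _encode(seq)
    a, b = codes[:-1], codes[1:]
    ok = (a >= 0) & (b >= 0)
    idx = a[ok] * 4 + b[ok]
    counts = np.bincount(idx, minlength=16)
    return dict(zip(DINUCLEOTIDES, counts.tolist()))


def valid_dinucleotide_positions(seq: str) -> int:
    """Number of overlapping positions whose two bases are both unambiguous."""
    codes = _encode(seq)
    return int(((codes[:-1] >= 0) & (codes[1:] >= 0)).sum())


def cpg_frequency(seq: str) -> float:
    """#CG dinucleotides / (length - 1); L is the full sequence length."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 nt")
    return count_dinucleotides(seq)["CG"] / (len(seq) - 1)


def cpg_frequency_normalised(seq: str) -> float:
    """CpG frequency / (Prop(C) * Prop(G)) — the observed/expected odds ratio."""
    props = base_proportions(seq)
    denom = props["C"] * props["G"]
    if denom == 0:
        raise UndefinedCompositionError("sequence lacks C or G; normalised CpG undefined")
    return cpg_frequency(seq) / denom


def expected_cpg(seq: str) -> float:
    """Prop(C) * Prop(G) * (L - 1): the CG count expected under independence."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 nt")
    props = base_proportions(seq)
    return props["C"] * props["G"] * (len(seq) - 1)


def dinucleotide_bias(seq: str, xy: str) -> float:
    """Observed/expected ratio for one ordered dinucleotide.

    Observed frequency is over valid overlapping positions; the expectation
    is the product of the mononucleotide proportions of its two bases.
    """
    if xy not in DINUCLEOTIDES:
        raise ValueError(f"unknown dinucleotide {xy!r}")
    props = base_proportions(seq)
    denom = props[xy[0]] * props[xy[1]]
    if denom == 0:
        raise UndefinedCompositionError(f"base {xy[0]} or {xy[1]} absent; bias undefined")
    n_valid = valid_dinucleotide_positions(seq)
    if n_valid == 0:
        raise UndefinedCompositionError("no valid dinucleotide positions")
    obs = count_dinucleotides(seq)[xy] / n_valid
    return obs / denom


def dinucleotide_proportion(seq: str, xy: str) -> float:
    """count(xy) / number of valid overlapping positions."""
    n_valid = valid_dinucleotide_positions(seq)
    if n_valid == 0:
        raise UndefinedCompositionError("no valid dinucleotide positions")
    return count_dinucleotides(seq)[xy] / n_valid


@dataclass(frozen=True)
class CompositionMetrics:
    """The CpG summary statistics for one sequence."""

    length: int
    prop_base: dict[str, float]
    dinuc_count: dict[str, int]
    cpg_frequency: float
    cpg_frequency_normalised: float | None
    expected_cpg: float

    @classmethod
    def from_sequence(cls, seq: str) -> "CompositionMetrics":
        props = base_proportions(seq)
        try:
            norm = cpg_frequency_normalised(seq)
        except UndefinedCompositionError:
            norm = None
        return cls(
            length=len(seq),
            prop_base=props,
            dinuc_count=count_dinucleotides(seq),
            cpg_frequency=cpg_frequency(seq),
            cpg_frequency_normalised=norm,
            expected_cpg=expected_cpg(seq),
        )


# --------------------------------------------------------------------------
# ORF-specific features


def _codon_list(cds: str) -> list[str]:
    if len(cds) < 6 or len(cds) % 3 != 0:
        raise ValueError("CDS must be >= 6 nt and a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def codon_amino_features(cds: str) -> dict[str, float]:
    """Codon usage, amino-acid and position-specific dinucleotide biases of an ORF.

    Returns a flat dict with:

    * ``codon:XYZ`` — RSCU-style usage bias: observed codon count divided by
      (its amino-acid family count / family size); 0 for empty families,
    * ``aa:X`` — proportion of each of the 21 translated symbols (stop = ``*``),
    * ``bridge:XY`` — dinucleotide bias at codon bridge positions (codon
      position 3 -> next codon position 1), expected term from
      position-specific mononucleotide frequencies,
    * ``nonbridge:XY`` — bias pooled over within-codon positions 1-2 and 2-3.

    Biases with a zero expected term are reported as 0. Codons containing N
    are excluded from codon/amino-acid tallies; dinucleotide positions with
    N are excluded as elsewhere.
    """
    codons = _codon_list(cds)
    n_codons = len(codons)

    clean = [c for c in codons if "N" not in c]
    codon_counts = {c: 0 for c in CODONS}
    for c in clean:
        codon_counts[c] += 1

    out: dict[str, float] = {}

    # RSCU-style codon usage bias
    for aa, family in AA_FAMILIES.items():
        fam_total = sum(codon_counts[c] for c in family)
        for c in family:
            if fam_total == 0:
                out[f"codon:{c}"] = 0.0
            else:
                out[f"codon:{c}"] = codon_counts[c] / (fam_total / len(family))

    # amino-acid proportions over the 21 translated symbols
    aa_counts = {aa: 0 for aa in AMINO_ACIDS}
    for c in clean:
        aa_counts[_CODON_TO_AA[c]] += 1
    n_trans = sum(aa_counts.values())
    for aa in AMINO_ACIDS:
        out[f"aa:{aa}"] = aa_counts[aa] / n_trans if n_trans else 0.0

    # position-specific mononucleotide frequencies (codon positions 1..3)
    codes = _encode(cds).reshape(n_codons, 3)
    pos_freq = np.zeros((3, 4))
    for p in range(3):
        col = codes[:, p]
        valid = col[col >= 0]
        if valid.size:
            pos_freq[p] = np.bincount(valid, minlength=4) / valid.size

    def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
        ok = (a >= 0) & (b >= 0)
        idx = a[ok] * 4 + b[ok]
        return np.bincount(idx, minlength=16), int(ok.sum())

    # bridge: codon position 3 of codon i -> position 1 of codon i+1
    bridge_counts, bridge_n = _pair_counts(codes[:-1, 2], codes[1:, 0])
    # non-bridge: within-codon positions 1-2 and 2-3, pooled
    nb12, n12 = _pair_counts(codes[:, 0], codes[:, 1])
    nb23, n23 = _pair_counts(codes[:, 1], codes[:, 2])
    nonbridge_counts = nb12 + nb23
    nonbridge_n = n12 + n23

    for k, xy in enumerate(DINUCLEOTIDES):
        i, j = BASES.index(xy[0]), BASES.index(xy[1])
        exp_bridge = pos_freq[2, i] * pos_freq[0, j]
        obs = bridge_counts[k] / bridge_n if bridge_n else 0.0
        out[f"bridge:{xy}"] = obs / exp_bridge if exp_bridge > 0 else 0.0

        exp_nb = (pos_freq[0, i] * pos_freq[1, j] + pos_freq[1, i] * pos_freq[2, j]) / 2
        obs = nonbridge_counts[k] / nonbridge_n if nonbridge_n else 0.0
        out[f"nonbridge:{xy}"] = obs / exp_nb if exp_nb > 0 else 0.0

    return out


# --------------------------------------------------------------------------
# The 185-feature vector


def _sequence_block(seq: str, prefix: str) -> dict[str, float]:
    """GC, AT, 16 dinucleotide biases and 16 proportions for one sequence."""
    props = base_proportions(seq)
    counts = count_dinucleotides(seq)
    n_valid = valid_dinucleotide_positions(seq)
    out = {
        f"{prefix}:GC": props["G"] + props["C"],
        f"{prefix}:AT": props["A"] + props["T"],
    }
    for xy in DINUCLEOTIDES:
        denom = props[xy[0]] * props[xy[1]]
        obs = counts[xy] / n_valid if n_valid else 0.0
        out[f"{prefix}:{xy}-bias"] = obs / denom if denom > 0 else 0.0
    for xy in DINUCLEOTIDES:
        out[f"{prefix}:{xy}-prop"] = counts[xy] / n_valid if n_valid else 0.0
    return out


def _canonical_feature_names() -> tuple[str, ...]:
    names = ["cdna:GC", "cdna:AT"]
    names += [f"cdna:{xy}-bias" for xy in DINUCLEOTIDES]
    names += [f"cdna:{xy}-prop" for xy in DINUCLEOTIDES]
    names += ["cds:GC", "cds:AT"]
    names += [f"cds:{xy}-bias" for xy in DINUCLEOTIDES]
    names += [f"cds:{xy}-prop" for xy in DINUCLEOTIDES]
    names += [f"cds:codon:{c}" for c in CODONS]
    names += [f"cds:aa:{aa}" for aa in AMINO_ACIDS]
    names += [f"cds:bridge:{xy}" for xy in DINUCLEOTIDES]
    names += [f"cds:nonbridge:{xy}" for xy in DINUCLEOTIDES]
    return tuple(names)


#: canonical, versioned order of the 185 features
FEATURE_NAMES: tuple[str, ...] = _canonical_feature_names()
assert len(FEATURE_NAMES) == 185


def feature_vector(record: GeneRecord) -> np.ndarray:
    """The 185 compositional features of one gene, in canonical order.

    Whole-transcript entries are the standalone composition operations
    applied to the cDNA; ORF entries are applied to the CDS. Biases that are
    undefined for a sequence (an absent base) are encoded as 0.
    """
    if record.cds is None:
        raise ValueError(f"{record.gene_id}: feature extraction requires a CDS")
    values = _sequence_block(record.cdna, "cdna")
    values.update(_sequence_block(record.cds, "cds"))
    values.update({f"cds:{k}": v for k, v in codon_amino_features(record.cds).items()})
    return np.array([values[name] for name in FEATURE_NAMES])


def feature_table(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Feature vectors for many genes as a DataFrame indexed by gene id."""
    records = list(records)
    data = np.vstack([feature_vector(r) for r in records]) if records else \
        np.empty((0, len(FEATURE_NAMES)))
    return pd.DataFrame(data, index=[r.gene_id for r in records],
                        columns=list(FEATURE_NAMES))


def feature_classes() -> dict[str, tuple[str, ...]]:
    """Group the 185 features into broad feature classes for importance reports.

    Each dinucleotide XY gets one class (named XpY) pooling its
    whole-transcript bias and proportion, ORF bias and proportion, and its
    bridge and non-bridge biases. Each codon and amino acid is its own
    class; GC and AT pool their whole-transcript and ORF versions.
    """
    classes: dict[str, tuple[str, ...]] = {
        "GC": ("cdna:GC", "cds:GC"),
        "AT": ("cdna:AT", "cds:AT"),
    }
    for xy in DINUCLEOTIDES:
        classes[f"{xy[0]}p{xy[1]}"] = (
            f"cdna:{xy}-bias", f"cdna:{xy}-prop",
            f"cds:{xy}-bias", f"cds:{xy}-prop",
            f"cds:bridge:{xy}", f"cds:nonbridge:{xy}",
        )
    for c in CODONS:
        classes[f"{c}-codon-bias"] = (f"cds:codon:{c}",)
    for aa in AMINO_ACIDS:
        classes[f"{aa}-aa-bias"] = (f"cds:aa:{aa}",)
    return classes


class CompositionFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: GeneRecords -> 185-column feature frame.

    Stateless; ``fit`` only records the canonical feature names so the
    transformer composes with sklearn pipelines.
    """

    def fit(self, X: Sequence[GeneRecord], y=None) -> "CompositionFeaturizer":
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence[GeneRecord]) -> pd.DataFrame:
        return feature_table(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def dinucleotide_fold_change(
    group_a: Iterable[GeneRecord | str],
    group_b: Iterable[GeneRecord | str],
) -> dict[str, float]:
    """Per-dinucleotide fold change in median normalised frequency, a over b.

    Per-gene values are the observed/expected dinucleotide odds ratios of the
    cDNA. A zero median in the denominator yields NaN for that dinucleotide.
    """
    def _seqs(group) -> list[str]:
        return [g.cdna if isinstance(g, GeneRecord) else g for g in group]

    seqs_a, seqs_b = _seqs(group_a), _seqs(group_b)
    if not seqs_a or not seqs_b:
        raise ValueError("both groups must be non-empty")

    def _bias_matrix(seqs: list[str]) -> np.ndarray:
        rows = []
        for s in seqs:
            row = []
            for xy in DINUCLEOTIDES:
                try:
                    row.append(dinucleotide_bias(s, xy))
                except UndefinedCompositionError:
                    row.append(np.nan)
            rows.append(row)
        return np.array(rows)

    med_a = np.nanmedian(_bias_matrix(seqs_a), axis=0)
    med_b = np.nanmedian(_bias_matrix(seqs_b), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(med_b != 0, med_a / med_b, np.nan)
    return dict(zip(DINUCLEOTIDES, fc.tolist()))
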