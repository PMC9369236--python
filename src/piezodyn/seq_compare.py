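"""Pairwise comparison of ortholog sequences: substitutions and their classes.

Globally aligns two amino-acid sequences (BLOSUM62, affine gaps), enumerates
the aligned mismatches as substitution records labelled like ``I35V``
(first letter = residue in the first ortholog, 1-based position on its
numbering) and classifies residues by polarity: acidic, basic, polar or
hydrophobic.  Glycine and histidine assignments vary between conventions;
the default mapping (G polar, H basic) can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .data_model import SubstitutionRecord, ValidationError, _POLARITY_DEFAULT

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class OrthologPair:
    """Two aligned ortholog sequences with their paired index map."""

    seq_a: str
    seq_b: str
    labels: tuple = ("seq_a", "seq_b")
    indices: np.ndarray = None  # type: ignore[assignment]  # (2, n_cols), -1 = gap
    score: float = np.nan

    @property
    def n_columns(self) -> int:
        return self.indices.shape[1]

    @property
    def gap_columns(self) -> int:
        return int(np.sum((self.indices < 0).any(axis=0)))


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper().strip()
    if not seq:
        raise ValidationError(f"{name} is empty")
    for i, ch in enumerate(seq, start=1):
        if ch not in AA_ALPHABET:
            raise ValidationError(
                f"invalid residue '{ch}' at position {i} of {name}"
            )
    return seq


def align_pair(seq_a: str, seq_b: str, labels=("seq_a", "seq_b")) -> OrthologPair:
    """Global alignment with BLOSUM62 scoring and affine gap penalties.

    The highest-scoring alignment is taken; Biopython enumerates co-optimal
    alignments in a deterministic order, so ties resolve reproducibly.
    """
    seq_a = _validate_sequence(seq_a, labels[0])
    seq_b = _validate_sequence(seq_b, labels[1])
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    return OrthologPair(
        seq_a=seq_a, seq_b=seq_b, labels=tuple(labels),
        indices=np.asarray(best.indices), score=float(best.score),
    )


def classify_residue(code: str, mapping: dict | None = None) -> str:
    """Polarity class of a one-letter residue code."""
    mapping = mapping or _POLARITY_DEFAULT
    code = code.upper()
    if code not in mapping:
        raise ValidationError(f"nonstandard residue code '{code}'")
    return mapping[code]


def enumerate_substitutions(
    pair: OrthologPair, mapping: dict | None = None
) -> list[SubstitutionRecord]:
    """One record per aligned mismatch, numbered on the first sequence.

    Gap columns are not substitutions; count them via ``pair.gap_columns``.
    Swapping the input order reverses every record's from/to.
    """
    records = []
    ia, ib = pair.indices
    for col in range(pair.n_columns):
        if ia[col] < 0 or ib[col] < 0:
            continue
        ra, rb = pair.seq_a[ia[col]], pair.seq_b[ib[col]]
        if ra != rb:
            records.append(
                SubstitutionRecord(
                    position=int(ia[col]) + 1, from_res=ra, to_res=rb,
                    class_from=classify_residue(ra, mapping),
                    class_to=classify_residue(rb, mapping),
                )
            )
    return records


def alignment_summary(pair: OrthologPair) -> dict:
    """Column bookkeeping: matches + substitutions + gap columns = length."""
    subs = enumerate_substitutions(pair)
    n_gap = pair.gap_columns
    n_sub = len(subs)
    return {
        "columns": pair.n_columns,
        "matches": pair.n_columns - n_gap - n_sub,
        "substitutions": n_sub,
        "gap_columns": n_gap,
    }


def read_fasta_sequence(path) -> str:
    """First record of a FASTA file as a plain string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return str(records[0].seq)


# ---------------------------------------------------------------------------
# synthetic ortholog pair (stand-in for the deposited structures' sequences)
# ---------------------------------------------------------------------------

#: The 16 ortholog substitutions, first letter = first ortholog.
PMI_SUBSTITUTIONS = (
    "E7N", "F8L", "A17L", "I35V", "P42K", "K48R", "Q59E", "K61R",
    "E65G", "E66D", "R67T", "D70Q", "K90E", "E92D", "I100V", "F105H",
)

#: Conserved active-site residues (position, residue).
_ACTIVE_SITE = ((44, "H"), (46, "H"), (51, "E"), (85, "H"))


def parse_substitution_label(label: str) -> tuple[str, int, str]:
    return label[0], int(label[1:-1]), label[-1]


def synthetic_ortholog_pair(length: int = 161, seed: int = 7) -> tuple[str, str]:
    """Synthetic near-identical ortholog pair with planted point substitutions.

    A deterministic pseudo-random backbone sequence of the given length with
    the 16 documented substitutions planted at their printed positions and
    the conserved active-site residues fixed in both sequences.  This is a
    synthetic stand-in for the real deposited sequences (which require a
    download), built to exercise alignment and substitution enumeration
    against a known planted truth.
    """
    rng = np.random.default_rng(seed)
    aas = sorted(AA_ALPHABET)
    backbone = [aas[i] for i in rng.integers(0, len(aas), size=length)]
    seq_a, seq_b = backbone.copy(), backbone.copy()
    for pos, res in _ACTIVE_SITE:
        seq_a[pos - 1] = res
        seq_b[pos - 1] = res
    for label in PMI_SUBSTITUTIONS:
        fr, pos, to = parse_substitution_label(label)
        seq_a[pos - 1] = fr
        seq_b[pos - 1] = to
    return "".join(seq_a), "".join(seq_b)
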