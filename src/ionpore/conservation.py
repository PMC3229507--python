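"""Multiple-sequence-alignment conservation scoring and net-charge model.

Columns are scored against a reference sequence (channel numbering): the
identical fraction and the fractions exchanged into four physicochemical
classes that partition the 20 standard amino acids —

* negative: D, E
* positive: R, K
* polar: T, W, S, N, Q, Y, C, H
* other: A, G, I, L, M, P, V, F

Gaps are excluded from the class fractions and reported separately, so
class fractions + gap fraction sum to one. A column is *conserved* when
the reference residue itself occurs in over ``threshold`` (default 90%) of
sequences, *functionally conserved* when its physicochemical class does.

The net-charge model is the standard-protonation pH-7 count: -1 for Asp
and Glu, +1 for Arg and Lys, 0 for everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

AA_CLASSES: dict[str, frozenset] = {
    "negative": frozenset("DE"),
    "positive": frozenset("RK"),
    "polar": frozenset("TWSNQYCH"),
    "other": frozenset("AGILMPVF"),
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# the four classes must partition the 20 standard amino acids exactly once
assert frozenset().union(*AA_CLASSES.values()) == STANDARD_AA
assert sum(len(v) for v in AA_CLASSES.values()) == 20

GAP_CHARS = frozenset("-.")

RESIDUE_CHARGE = {aa: 0 for aa in STANDARD_AA}
RESIDUE_CHARGE.update({"D": -1, "E": -1, "R": 1, "K": 1})


def residue_class(aa: str) -> str | None:
    """Physicochemical class name of one residue letter (None for gaps/unknowns)."""
    aa = aa.upper()
    for name, members in AA_CLASSES.items():
        if aa in members:
            return name
    return None


@dataclass
class Alignment:
    """A validated MSA with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ConfigurationError("ids and rows length mismatch")
        if len(self.rows) == 0:
            raise ConfigurationError("alignment is empty")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ConfigurationError(
                    f"record {self.ids[i]!r} has length {len(row)}, expected {width}"
                )
        if self.reference_id not in self.ids:
            raise ConfigurationError(f"reference {self.reference_id!r} not in alignment")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def reference_column(self, position: int) -> int:
        """Alignment column (0-based) of a 1-based reference residue number.

        Reference numbering skips the gaps of the reference row.
        """
        if position < 1:
            raise InvalidParameterError("reference positions are 1-based")
        count = 0
        for col, aa in enumerate(self.reference_row):
            if aa not in GAP_CHARS:
                count += 1
                if count == position:
                    return col
        raise InvalidParameterError(
            f"reference position {position} beyond the reference sequence"
        )

    def numbering_map(self) -> dict[int, int]:
        """1-based reference position -> 0-based alignment column (audit table)."""
        out = {}
        count = 0
        for col, aa in enumerate(self.reference_row):
            if aa not in GAP_CHARS:
                count += 1
                out[count] = col
        return out


def read_alignment(path, format: str = "fasta", reference_id: str | None = None) -> Alignment:
    """Read a FASTA or Clustal MSA; the reference defaults to the first record."""
    from Bio import AlignIO

    fmt = {"fasta": "fasta", "clustal": "clustal"}.get(format.lower())
    if fmt is None:
        raise ConfigurationError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    return Alignment(ids=ids, rows=rows, reference_id=reference_id or ids[0])


@dataclass
class ColumnStats:
    """Composition of one alignment column in reference numbering."""

    reference_residue: str
    reference_position: int
    fraction_identical: float
    class_fractions: dict = field(default_factory=dict)
    gap_fraction: float = 0.0
    n_sequences: int = 0

    def own_class_fraction(self) -> float:
        cls = residue_class(self.reference_residue)
        return self.class_fractions.get(cls, 0.0) if cls else 0.0


def column_stats(aln: Alignment, reference_position: int) -> ColumnStats:
    """Identical/class/gap fractions of the column at a reference position."""
    col = aln.reference_column(reference_position)
    ref_aa = aln.reference_row[col]
    if ref_aa in GAP_CHARS:
        raise InvalidParameterError("reference position maps to a gap column")
    letters = [row[col] for row in aln.rows]
    n = len(letters)
    gaps = sum(1 for c in letters if c in GAP_CHARS)
    counts = {name: 0 for name in AA_CLASSES}
    identical = 0
    for c in letters:
        if c in GAP_CHARS:
            continue
        if c == ref_aa:
            identical += 1
        cls = residue_class(c)
        if cls:
            counts[cls] += 1
    fractions = {name: k / n for name, k in counts.items()}
    return ColumnStats(
        reference_residue=ref_aa,
        reference_position=reference_position,
        fraction_identical=identical / n,
        class_fractions=fractions,
        gap_fraction=gaps / n,
        n_sequences=n,
    )


def is_conserved(stats: ColumnStats, threshold: float = 0.90) -> str:
    """Category: ``conserved`` | ``functionally conserved`` | ``not conserved``.

    Strictly-over comparisons: exactly the threshold does not qualify.
    """
    if stats.fraction_identical > threshold:
        return "conserved"
    if stats.own_class_fraction() > threshold:
        return "functionally conserved"
    return "not conserved"


def net_charge(sequence: str) -> int:
    """Sequence net charge at pH 7 (D/E -1, R/K +1, others 0), gaps ignored."""
    seq = [c for c in sequence.upper() if c not in GAP_CHARS]
    if not seq:
        warnings.warn("empty sequence: net charge reported as 0")
        return 0
    unknown = [c for c in seq if c not in STANDARD_AA]
    if unknown:
        warnings.warn(
            f"non-standard letters {sorted(set(unknown))} counted as charge 0"
        )
    return sum(RESIDUE_CHARGE.get(c, 0) for c in seq)


def charge_distribution(aln: Alignment) -> tuple[float, float]:
    """(mean, sample std) of per-sequence net charge over ungapped sequences."""
    if aln.n_sequences < 2:
        raise ConfigurationError("charge distribution needs at least 2 sequences")
    charges = np.asarray([net_charge(row) for row in aln.rows], dtype=float)
    return float(charges.mean()), float(charges.std(ddof=1))
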