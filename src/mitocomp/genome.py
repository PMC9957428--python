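"""Annotated circular mitogenomes and circular-coordinate arithmetic.

Coordinates follow the GenBank convention: 1-based, inclusive on both ends.
A feature that spans the origin of the circle is stored with ``end < start``
and ``wraps_origin=True`` (serialized as ``join(start..L,1..end)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tokens import classify_token

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")
WHOLE = "WHOLE"


class CoordinateError(ValueError):
    """A feature coordinate is outside the genome or otherwise invalid."""


class DuplicateTokenError(ValueError):
    """Two features carry the same token within one genome."""


@dataclass(frozen=True)
class Feature:
    """One annotated gene or region on a circular genome.

    ``start``/``end`` are 1-based inclusive; ``wraps_origin`` is true iff the
    feature runs across position 1 of the circle (``end < start``).  Start and
    stop codons are recorded only for protein-coding genes; incomplete stops
    truncated at the gene boundary (completed by polyadenylation of the mRNA)
    are written literally as ``"T--"`` or ``"TA-"``.  Anticodons are recorded
    only for tRNAs, in the DNA alphabet.
    """

    token: str
    start: int
    end: int
    strand: str = "+"
    feature_class: str = ""
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.feature_class:
            object.__setattr__(self, "feature_class", classify_token(self.token))
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.token}: coordinates must be >= 1 ({self.start}..{self.end})")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotatedGenome:
    """A circular genome's identity, length, optional sequence and features."""

    genome_id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}")
        self.validate()
        self.features.sort(key=lambda f: f.start)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise CoordinateError(
                    f"{f.token}: {f.start}..{f.end} outside genome of length {self.length}")
            if f.wraps_origin and not self.circular:
                raise CoordinateError(
                    f"{f.token}: wraps the origin of a non-circular genome")
            if f.token in seen:
                raise DuplicateTokenError(
                    f"duplicate token {f.token!r} in genome {self.genome_id}")
            seen.add(f.token)

    def feature(self, token: str) -> Feature:
        for f in self.features:
            if f.token == token:
                return f
        raise KeyError(f"no feature {token!r} in genome {self.genome_id}")

    def features_of_class(self, cls: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == cls]

    def with_sequence(self, sequence: str) -> "AnnotatedGenome":
        return AnnotatedGenome(self.genome_id, self.length, self.circular,
                               sequence, list(self.features))


def feature_length(f: Feature, genome_length: int) -> int:
    """Length in bp of a feature, honouring origin wrap-around."""
    if f.wraps_origin:
        return genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


def spacer_length(f1: Feature, f2: Feature, genome_length: int) -> int:
    """Signed gap between a feature and the next one clockwise.

    Positive values are intergenic spacers, negative values are overlaps,
    zero means the genes abut.  ``f2`` is taken to be the next feature on the
    circle after ``f1``; for the pair that spans the origin the gap is
    computed circularly.
    """
    if f1 is f2 or (f1.token == f2.token and f1.start == f2.start):
        raise ValueError("spacer_length requires two distinct features")
    gap = f2.start - f1.end - 1
    if f2.start <= f1.start and not f1.wraps_origin:
        gap += genome_length  # f2 is past the origin
    return gap


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(g: AnnotatedGenome, f: Feature) -> str:
    """Subsequence of a feature, wrap-aware, reverse-complemented on '-'."""
    if g.sequence is None:
        raise ValueError(
            f"genome {g.genome_id} carries no sequence; cannot extract {f.token}")
    if f.wraps_origin:
        sub = g.sequence[f.start - 1:] + g.sequence[:f.end]
    else:
        sub = g.sequence[f.start - 1:f.end]
    if f.strand == "-":
        sub = reverse_complement(sub)
    return sub


def genome_order_features(g: AnnotatedGenome) -> list[Feature]:
    """Features in clockwise genome order (ascending start)."""
    return sorted(g.features, key=lambda f: f.start)


__all__ = [
    "Feature", "AnnotatedGenome", "feature_length", "spacer_length",
    "extract_sequence", "reverse_complement", "genome_order_features",
    "CoordinateError", "DuplicateTokenError", "FEATURE_CLASSES", "WHOLE",
]
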