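"""Nucleotide composition, A+T content, and strand-asymmetry skews.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C) summarize the
compositional asymmetry between the two strands of a mitogenome; both lie in
[−1, 1] and are 0 for a strand with equal counts of the paired bases.  Skews
can be computed from raw base counts or from published percentages (the two
can differ in the third decimal because percentages are rounded).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome import AnnotatedGenome, WHOLE, extract_sequence, genome_order_features


@dataclass(frozen=True)
class BaseCounts:
    nA: int
    nC: int
    nG: int
    nT: int
    n_other: int = 0

    @property
    def total(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.n_other


@dataclass(frozen=True)
class CompositionStats:
    """Percent composition plus AT/GC skew for one sequence region."""

    counts: BaseCounts | None
    pA: float
    pC: float
    pG: float
    pT: float
    at_content: float
    at_skew: float
    gc_skew: float


def round_display(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, as printed tables do (0.0985 -> 0.099)."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def base_counts(seq: str) -> BaseCounts:
    """Case-insensitive base tally; non-ACGT symbols land in ``n_other``."""
    if not seq:
        raise ValueError("cannot count bases of an empty sequence")
    s = seq.upper()
    nA, nC, nG, nT = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return BaseCounts(nA, nC, nG, nT, len(s) - nA - nC - nG - nT)


def skews(c: BaseCounts) -> tuple[float, float]:
    """(AT skew, GC skew) from raw counts, unrounded; NaN when undefined."""
    at = (c.nA - c.nT) / (c.nA + c.nT) if c.nA + c.nT else float("nan")
    gc = (c.nG - c.nC) / (c.nG + c.nC) if c.nG + c.nC else float("nan")
    return at, gc


def skews_from_percent(pT: float, pC: float, pA: float, pG: float,
                       tol: float = 0.5) -> tuple[float, float]:
    """Skews recomputed from published percentages (argument order follows
    the usual table layout T, C, A, G).

    Because published percentages are rounded (typically to 1 decimal), the
    result can differ from count-based skews in the third decimal.
    """
    for p in (pT, pC, pA, pG):
        if p < 0:
            raise ValueError("percentages must be non-negative")
    total = pT + pC + pA + pG
    if abs(total - 100.0) > tol:
        raise ValueError(f"percentages sum to {total}, outside 100 ± {tol}")
    at = (pA - pT) / (pA + pT) if pA + pT else float("nan")
    gc = (pG - pC) / (pG + pC) if pG + pC else float("nan")
    return at, gc


def stats_from_counts(c: BaseCounts) -> CompositionStats:
    denom = c.total - c.n_other
    if denom == 0:
        raise ValueError("no unambiguous bases in region")
    at, gc = skews(c)
    pA, pC, pG, pT = (100.0 * n / denom for n in (c.nA, c.nC, c.nG, c.nT))
    return CompositionStats(c, pA, pC, pG, pT, pA + pT, at, gc)


def sequence_stats(seq: str) -> CompositionStats:
    return stats_from_counts(base_counts(seq))


def region_stats(g: AnnotatedGenome, cls: str = WHOLE) -> CompositionStats:
    """Composition of a feature class (PCG / tRNA / rRNA / CR) or the whole
    genome.

    Each feature of the class is extracted independently and the extracts
    concatenated in genome order, so bases shared by overlapping genes are
    counted once per gene — matching how printed per-region totals (e.g. the
    protein-coding region length) sum the individual gene lengths.
    """
    if g.sequence is None:
        raise ValueError(f"genome {g.genome_id} carries no sequence")
    if cls == WHOLE:
        return sequence_stats(g.sequence)
    parts = [extract_sequence(g, f) for f in genome_order_features(g)
             if f.feature_class == cls]
    if not parts:
        raise ValueError(f"genome {g.genome_id} has no features of class {cls}")
    return sequence_stats("".join(parts))


def region_length(g: AnnotatedGenome, cls: str) -> int:
    """Summed length (bp) of all features of a class (overlaps counted per gene)."""
    from .genome import feature_length
    return sum(feature_length(f, g.length) for f in g.features
               if f.feature_class == cls)


_T1_COLUMNS = ["species", "accession", "size_bp", "pT", "pC", "pA", "pG",
               "at_pct", "at_skew", "gc_skew"]


def composition_report(genomes=None, table=None) -> pd.DataFrame:
    """Per-genome composition table (one row per genome, display-rounded).

    ``genomes`` is an iterable of :class:`AnnotatedGenome` with sequences;
    ``table`` is a TSV of published percentages (columns species, accession,
    size_bp, pT, pC, pA, pG, ...).  Rows whose percentages cannot be parsed
    or validated are emitted with NaN skews and a note in the ``error``
    column rather than aborting the report.
    """
    rows = []
    if genomes:
        for g in genomes:
            st = region_stats(g, WHOLE)
            rows.append(_row(g.genome_id, g.genome_id, g.length,
                             st.pT, st.pC, st.pA, st.pG, st.at_skew, st.gc_skew))
    if table is not None:
        df = pd.read_csv(table, sep="\t", comment="#", dtype=str)
        for _, r in df.iterrows():
            try:
                pT, pC, pA, pG = (float(r[k]) for k in ("pT", "pC", "pA", "pG"))
                at, gc = skews_from_percent(pT, pC, pA, pG)
                rows.append(_row(r["species"], r.get("accession", ""),
                                 float(r["size_bp"]), pT, pC, pA, pG, at, gc))
            except (ValueError, KeyError) as exc:
                rows.append({"species": r.get("species", "?"),
                             "accession": r.get("accession", ""),
                             "error": str(exc)})
    out = pd.DataFrame(rows)
    return out


def _row(species, accession, size, pT, pC, pA, pG, at, gc):
    return {
        "species": species, "accession": accession, "size_bp": int(size),
        "pT": round_display(pT, 1), "pC": round_display(pC, 1),
        "pA": round_display(pA, 1), "pG": round_display(pG, 1),
        "at_pct": round_display(pA + pT, 1),
        "at_skew": round_display(at, 3), "gc_skew": round_display(gc, 3),
        "error": "",
    }
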