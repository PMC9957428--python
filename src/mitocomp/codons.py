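"""Codon extraction, start/stop identification, and RSCU.

Relative synonymous codon usage (RSCU) for codon *j* of a synonymous family
*i* with *k_i* members is ``n_ij * k_i / sum_j n_ij``: the observed count
divided by the count expected if all synonyms were used equally.  RSCU is 1
under uniform usage and >1 for preferred codons.

The default genetic code is the invertebrate mitochondrial code (NCBI
translation table 5: AGA/AGG = Ser, TGA = Trp, ATA = Met), the code used by
annelid mitogenomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_FAMILY = "*"


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: codon→amino-acid map plus start/stop sets."""

    table_id: int
    codon_to_aa: dict
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id, dict(t.forward_table),
                   frozenset(t.start_codons), frozenset(t.stop_codons))

    def family(self, aa: str) -> tuple[str, ...]:
        """All codons of one synonymous family ('*' = stop codons)."""
        if aa == STOP_FAMILY:
            return tuple(sorted(self.stop_codons))
        return tuple(c for c in ALL_CODONS if self.codon_to_aa.get(c) == aa)

    def families(self, include_stops: bool = False) -> dict:
        fams = {}
        for aa in sorted(set(self.codon_to_aa.values())):
            fams[aa] = self.family(aa)
        if include_stops:
            fams[STOP_FAMILY] = self.family(STOP_FAMILY)
        return fams


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)

INCOMPLETE_STOPS = ("T--", "TA-")


def split_codons(cds: str) -> tuple[list[str], str]:
    """Split a CDS into consecutive triplets from position 1 plus a 0-2 nt
    remainder (the incomplete terminal codon of many mitochondrial genes)."""
    if not cds:
        raise ValueError("empty CDS")
    s = cds.upper()
    n3 = len(s) // 3 * 3
    return [s[i:i + 3] for i in range(0, n3, 3)], s[n3:]


def detect_start_stop(cds: str, code: GeneticCode = INVERTEBRATE_MITO):
    """(start_codon, stop_codon, flags) for a CDS in frame 0.

    The stop is the final complete triplet when it is in the code's stop set;
    otherwise a 1-2 nt remainder of T / TA is reported as the incomplete form
    "T--" / "TA-" (completed to TAA by mRNA polyadenylation).  Flags note a
    non-canonical start or a missing stop; neither is an error.
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than 6 nt")
    codons, rest = split_codons(cds)
    start = codons[0]
    flags = []
    if start not in code.start_codons:
        flags.append("noncanonical_start")
    if rest == "T":
        stop = "T--"
    elif rest == "TA":
        stop = "TA-"
    elif not rest and codons[-1] in code.stop_codons:
        stop = codons[-1]
    else:
        stop = None
        flags.append("no_stop")
    return start, stop, flags


@dataclass
class CodonCounts:
    counts: Counter = field(default_factory=Counter)
    n_ambiguous: int = 0
    genes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_list, code: GeneticCode = INVERTEBRATE_MITO,
                 include_stops: bool = False, gene_names=None) -> CodonCounts:
    """Pool codon counts across genes.

    Terminal incomplete codons (the 1-2 nt remainder) are never counted;
    stop codons are counted only when ``include_stops``.  Codons containing
    non-ACGT symbols are skipped and tallied as ambiguous.
    """
    cc = CodonCounts(genes=list(gene_names or []))
    for cds in cds_list:
        codons, _ = split_codons(cds)
        for codon in codons:
            if any(b not in "ACGT" for b in codon):
                cc.n_ambiguous += 1
                continue
            if codon in code.stop_codons and not include_stops:
                continue
            cc.counts[codon] += 1
    return cc


def rscu(c: CodonCounts, code: GeneticCode = INVERTEBRATE_MITO,
         include_stops: bool | None = None) -> pd.DataFrame:
    """RSCU table: one row per codon with columns ``aa, count, rscu,
    degenerate_family``.

    A family with zero total keeps RSCU 0 for all members and is flagged
    degenerate.  Stop codons form their own family when they were counted.
    """
    if include_stops is None:
        include_stops = any(codon in code.stop_codons for codon in c.counts)
    rows = []
    for aa, fam in code.families(include_stops=include_stops).items():
        k = len(fam)
        fam_total = sum(c.counts.get(codon, 0) for codon in fam)
        for codon in fam:
            n = c.counts.get(codon, 0)
            val = n * k / fam_total if fam_total else 0.0
            rows.append({"codon": codon, "aa": aa, "count": n, "rscu": val,
                         "degenerate_family": fam_total == 0})
    return pd.DataFrame(rows).set_index("codon")


def pcg_rscu(genome, code: GeneticCode = INVERTEBRATE_MITO,
             include_stops: bool = False) -> pd.DataFrame:
    """RSCU over all protein-coding genes of an annotated genome with
    sequence."""
    from .genome import extract_sequence
    pcgs = genome.features_of_class("PCG")
    seqs = [extract_sequence(genome, f) for f in pcgs]
    counts = count_codons(seqs, code, include_stops=include_stops,
                          gene_names=[f.token for f in pcgs])
    return rscu(counts, code, include_stops=include_stops)
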