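"""Standardized gene tokens for metazoan mitogenomes and name normalization.

The 37-gene convention: 13 protein-coding genes (cox1-3, cob, atp6, atp8,
nad1-6, nad4l), 22 tRNAs (trnX, with the leucine and serine isoacceptors
disambiguated as trnL1/trnL2 and trnS1/trnS2), two rRNAs (rrnS, rrnL) and
the control region (CR).  GenBank records use many dialects for the same
genes (COI, COX1, cytb, 12S ribosomal RNA, D-loop ...); :func:`normalize_token`
maps them onto the standard tokens.
"""

from __future__ import annotations

import re
import warnings

PCG_TOKENS = (
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

TRNA_TOKENS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_TOKENS = ("rrnS", "rrnL")

CR_TOKEN = "CR"

ALL_TOKENS = PCG_TOKENS + TRNA_TOKENS + RRNA_TOKENS + (CR_TOKEN,)

#: Anticodons that disambiguate the leucine and serine isoacceptor tRNAs
#: (DNA alphabet).  trnL1 reads CUN codons, trnL2 reads UUR; trnS1 reads
#: AGN, trnS2 reads UCN.
ISOACCEPTOR_BY_ANTICODON = {
    ("L", "TAG"): "trnL1",
    ("L", "TAA"): "trnL2",
    ("S", "TCT"): "trnS1",
    ("S", "TGA"): "trnS2",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Direct synonym map (lower-cased, stripped of spaces/hyphens/underscores).
_SYNONYMS = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "cytochromecoxidasesubuniti": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3",
    "cob": "cob", "cytb": "cob", "cytochromeb": "cob", "cob1": "cob",
    "atp6": "atp6", "atpase6": "atp6",
    "atp8": "atp8", "atpase8": "atp8",
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l", "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "12sribosomalrna": "rrnS",
    "srrna": "rrnS", "smallsubunitribosomalrna": "rrnS",
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "16sribosomalrna": "rrnL",
    "lrrna": "rrnL", "largesubunitribosomalrna": "rrnL",
    "cr": "CR", "dloop": "CR", "controlregion": "CR", "atrichregion": "CR",
}


class UnknownGeneNameWarning(UserWarning):
    """A gene name could not be normalized; it is kept verbatim."""


def _squash(name: str) -> str:
    return re.sub(r"[\s\-_()]+", "", name).lower()


def normalize_token(name: str, anticodon: str | None = None) -> str:
    """Map a GenBank-style gene/product name onto a standard token.

    ``anticodon`` (DNA, 3 nt) disambiguates the leucine/serine isoacceptors;
    without it an undecorated "trnL"/"trnS" is returned as-is with a warning.
    Unknown names pass through verbatim with an :class:`UnknownGeneNameWarning`.
    """
    raw = name.strip()
    # already a standard token (including _2 duplicates)
    base = raw[:-2] if raw.endswith("_2") else raw
    if base in ALL_TOKENS:
        return raw

    squashed = _squash(raw)
    if squashed in _SYNONYMS:
        return _SYNONYMS[squashed]

    # tRNA dialects: "trnW", "trnS1", "tRNA-Ser", "tRNA-Leu(UUR)", "trnL(tag)"
    m = re.match(r"(?:trn|trna)[\s\-_]*([A-Za-z]{1,3})([12]?)"
                 r"(?:[\s\-_(]*([A-Za-z]{3}))?\)?$",
                 raw.replace("tRNA", "trn"), flags=re.IGNORECASE)
    if m:
        aa, iso, paren = m.group(1), m.group(2), m.group(3)
        paren = paren.upper().replace("U", "T") if paren else None
        one = _AA3_TO_1.get(aa.lower(), aa.upper() if len(aa) == 1 else None)
        if one is not None:
            if one in ("L", "S"):
                if iso:
                    return f"trn{one}{iso}"
                # codon-family notation: L(UUR)/L(CUN), S(AGN)/S(UCN)
                family = {("L", "TTR"): "trnL2", ("L", "CTN"): "trnL1",
                          ("S", "AGN"): "trnS1", ("S", "TCN"): "trnS2"}
                if paren and (one, paren) in family:
                    return family[(one, paren)]
                anti = anticodon or paren
                if anti and (one, anti) in ISOACCEPTOR_BY_ANTICODON:
                    return ISOACCEPTOR_BY_ANTICODON[(one, anti)]
                warnings.warn(
                    f"ambiguous isoacceptor tRNA name {raw!r}; kept verbatim",
                    UnknownGeneNameWarning, stacklevel=2)
                return raw
            return f"trn{one}"

    warnings.warn(f"unknown gene name {raw!r}; kept verbatim",
                  UnknownGeneNameWarning, stacklevel=2)
    return raw


def classify_token(token: str) -> str:
    """Return the feature class ('PCG', 'tRNA', 'rRNA' or 'CR') of a token."""
    base = token[:-2] if token.endswith("_2") else token
    if base in PCG_TOKENS:
        return "PCG"
    if base in TRNA_TOKENS or base.startswith("trn"):
        return "tRNA"
    if base in RRNA_TOKENS:
        return "rRNA"
    if base == CR_TOKEN:
        return "CR"
    raise ValueError(f"cannot classify token {token!r}")
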