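"""Reading and writing annotated mitogenomes.

Three formats are supported:

* GenBank flat files (via Biopython); circular topology from the LOCUS line,
  origin-spanning features as ``join(a..L,1..b)``.
* A sequence-free feature-table TSV mirroring a printed annotation table:
  two header lines ``#genome_id=<id>`` and ``#length=<bp>``, then columns
  ``token  start  end  strand  start_codon  stop_codon  anticodon``.
* FASTA (via Biopython), records keyed ``genome_id|token``.
"""

from __future__ import annotations

import importlib.resources
import os
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, CoordinateError, Feature
from .tokens import classify_token, normalize_token


class GenBankParseError(ValueError):
    pass


_GB_KEY_TO_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                    "D-loop": "CR", "misc_feature": "CR"}
_CLASS_TO_GB_KEY = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def _location_to_coords(loc, length: int, token: str):
    """GenBank location -> (start, end) 1-based inclusive, wrap-aware."""
    if isinstance(loc, CompoundLocation):
        parts = loc.parts
        if len(parts) == 2 and int(parts[0].end) == length and int(parts[1].start) == 0:
            return int(parts[0].start) + 1, int(parts[1].end)
        raise GenBankParseError(
            f"feature {token!r}: unsupported compound location {loc}")
    return int(loc.start) + 1, int(loc.end)


def read_genbank(path: str | os.PathLike) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`."""
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    length = len(record.seq)
    circular = record.annotations.get("topology", "circular") == "circular"
    try:
        sequence = str(record.seq).upper()
    except Exception:  # contig/CONS records without ORIGIN
        sequence = None

    features: list[Feature] = []
    for sf in record.features:
        if sf.type == "source":
            continue
        cls = _GB_KEY_TO_CLASS.get(sf.type)
        if cls is None:
            continue
        quals = sf.qualifiers
        name = (quals.get("gene") or quals.get("product") or [None])[0]
        anticodon_q = (quals.get("anticodon_seq") or [None])[0]
        if name is None:
            if cls == "CR":
                name = "CR"
            else:
                raise GenBankParseError(
                    f"{path}: {sf.type} feature without /gene or /product at {sf.location}")
        token = normalize_token(name, anticodon=anticodon_q)
        try:
            cls = classify_token(token)
        except ValueError:
            pass  # unknown token: keep the class guessed from the feature key
        start, end = _location_to_coords(sf.location, length, token)
        strand = "-" if sf.location.strand == -1 else "+"
        kwargs = {}
        if cls == "PCG":
            kwargs["start_codon"] = (quals.get("start_codon") or [None])[0]
            kwargs["stop_codon"] = (quals.get("stop_codon") or [None])[0]
        if cls == "tRNA":
            kwargs["anticodon"] = anticodon_q
        features.append(Feature(token, start, end, strand, cls, **kwargs))

    return AnnotatedGenome(record.id or record.name, length, circular,
                           sequence, features)


def write_genbank(g: AnnotatedGenome, path: str | os.PathLike) -> None:
    """Serialize an annotated genome (sequence required) as GenBank."""
    if g.sequence is None:
        raise ValueError("write_genbank requires a sequence (GenBank ORIGIN)")
    record = SeqRecord(Seq(g.sequence), id=g.genome_id, name=g.genome_id[:16],
                       description=f"{g.genome_id} mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if g.circular else "linear"
    for f in g.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, g.length, strand),
                FeatureLocation(0, f.end, strand),
            ])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.token]}
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        if f.anticodon:
            quals["anticodon_seq"] = [f.anticodon]
        record.features.append(
            SeqFeature(loc, type=_CLASS_TO_GB_KEY[f.feature_class], qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


_TABLE_COLUMNS = ("token", "start", "end", "strand",
                  "start_codon", "stop_codon", "anticodon")


def read_feature_table(path: str | os.PathLike) -> AnnotatedGenome:
    """Read a sequence-free feature-table TSV (printed-table transcript)."""
    path = Path(path)
    genome_id = None
    length = None
    features: list[Feature] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#genome_id="):
                genome_id = line.split("=", 1)[1].strip()
                continue
            if line.startswith("#length="):
                length = int(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            cells = line.split("\t")
            if not header_seen:
                if cells[0] != "token":
                    raise ValueError(f"{path}:{lineno}: expected header row, got {line!r}")
                header_seen = True
                continue
            cells += [""] * (len(_TABLE_COLUMNS) - len(cells))
            token, start, end, strand, start_codon, stop_codon, anticodon = \
                cells[:len(_TABLE_COLUMNS)]
            features.append(Feature(
                token=token,
                start=int(start.replace(",", "")),
                end=int(end.replace(",", "")),
                strand=strand or "+",
                start_codon=start_codon or None,
                stop_codon=stop_codon or None,
                anticodon=anticodon or None,
            ))
    if genome_id is None or length is None:
        raise ValueError(f"{path}: missing #genome_id= / #length= header lines")
    return AnnotatedGenome(genome_id, length, circular=True,
                           sequence=None, features=features)


def write_feature_table(g: AnnotatedGenome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_id={g.genome_id}\n")
        fh.write(f"#length={g.length}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in g.features:
            fh.write("\t".join([
                f.token, str(f.start), str(f.end), f.strand,
                f.start_codon or "", f.stop_codon or "", f.anticodon or "",
            ]).rstrip("\t") + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA -> {record id: sequence}; any line wrap is accepted."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | os.PathLike,
                width: int = 70) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def packaged_fixture(name: str) -> Path:
    """Path of a data table shipped with the package (e.g. the printed
    annotation table ``tukubana_table2.tsv``)."""
    return Path(importlib.resources.files("mitocomp") / "data" / name)


def load_tukubana_annotation() -> AnnotatedGenome:
    """The transcribed printed annotation of the T. tukubana mitogenome."""
    return read_feature_table(packaged_fixture("tukubana_table2.tsv"))
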