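"""Core data types, GenBank/FASTA input and GFF3/TSV/JSON report output.

Everything downstream consumes :class:`MitoGenome`: a circular nucleotide
sequence plus strand-aware gene features whose labels come from a controlled
vocabulary (13 protein-coding genes, two rRNAs, 22 tRNAs with the Leu/Ser
isoacceptors disambiguated by codon class, the light-strand replication
origin ``OL`` and the control region ``CR``).

Coordinates are 0-based half-open on the linearized heavy strand throughout
the package; GenBank records (1-based inclusive) are converted on read and
GFF3 output is converted back on write.  A feature that spans the circular
origin is kept as a single interval whose ``end`` exceeds the genome length
and is interpreted modulo the length.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

UNKNOWN = "unknown"


class GenBankParseError(ValueError):
    """Raised when a GenBank record lacks a sequence or any usable feature."""


def reverse_complement(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """An uppercase DNA sequence over the IUPAC alphabet.

    ``circular`` marks a closed molecule; :meth:`rotated` exposes rotation
    without mutating the original.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        res = self.residues.upper()
        bad = set(res) - set(IUPAC_CODES) - {"-"}
        if bad:
            raise ValueError(f"invalid nucleotide codes: {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def rotated(self, offset: int) -> "NucSequence":
        """Return the sequence re-linearized to start at ``offset`` (circular only)."""
        if not self.circular:
            raise ValueError("rotation requires a circular sequence")
        k = offset % len(self)
        return replace(self, residues=self.residues[k:] + self.residues[:k])

    def slice_circular(self, start: int, end: int) -> str:
        """Subsequence ``[start, end)``; for circular molecules the interval may wrap."""
        n = len(self)
        if self.circular:
            start %= n
            if end < start:
                end += n
            if end <= n:
                return self.residues[start:end]
            return self.residues[start:] + self.residues[: end - n]
        return self.residues[start:end]

    def reverse_complement(self) -> "NucSequence":
        return replace(self, residues=reverse_complement(self.residues))


@dataclass(frozen=True)
class GeneFeature:
    """A labelled interval on the linearized H-strand.

    ``strand`` is ``"H"`` (heavy, majority-coding) or ``"L"`` (light).  For a
    feature spanning the circular origin ``end`` may exceed the genome length;
    positions are then read modulo the length.
    """

    label: str
    start: int
    end: int
    strand: str = "H"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A mitogenome: circular sequence plus ordered gene features."""

    sequence: NucSequence
    features: list[GeneFeature]
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            limit = 2 * n if self.sequence.circular else n
            if f.end > limit:
                raise ValueError(f"feature {f.label} [{f.start},{f.end}) outside sequence")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if sum(1 for f in self.features if f.label == "CR") > 1:
            raise ValueError("more than one CR feature")

    def get(self, label: str) -> GeneFeature | None:
        for f in self.features:
            if f.label == label:
                return f
        return None

    def rotated(self, offset: int) -> "MitoGenome":
        """Re-linearize the circle to start at ``offset`` (features remapped)."""
        n = len(self.sequence)
        k = offset % n
        feats = []
        for f in self.features:
            s = (f.start - k) % n
            feats.append(replace(f, start=s, end=s + len(f)))
        return MitoGenome(self.sequence.rotated(k), feats, self.source_id)


# ---------------------------------------------------------------------------
# Controlled vocabulary

_AMINO = [
    ("trnF", "Phe"), ("trnV", "Val"), ("trnI", "Ile"), ("trnQ", "Gln"),
    ("trnM", "Met"), ("trnW", "Trp"), ("trnA", "Ala"), ("trnN", "Asn"),
    ("trnC", "Cys"), ("trnY", "Tyr"), ("trnD", "Asp"), ("trnK", "Lys"),
    ("trnG", "Gly"), ("trnR", "Arg"), ("trnH", "His"), ("trnE", "Glu"),
    ("trnT", "Thr"), ("trnP", "Pro"),
]

_CODON_CLASS = {"trnL(UUR)": ("Leu", "UUR"), "trnL(CUN)": ("Leu", "CUN"),
                "trnS(UCN)": ("Ser", "UCN"), "trnS(AGY)": ("Ser", "AGY")}


def _canon(raw: str) -> str:
    """Lowercase and strip everything but letters and digits."""
    return re.sub(r"[^a-z0-9]", "", raw.lower())


def _builtin_vocabulary() -> dict[str, str]:
    table: dict[str, str] = {}

    def add(token: str, *aliases: str) -> None:
        table.setdefault(_canon(token), token)
        for a in aliases:
            table.setdefault(_canon(a), token)

    # aliases shipped as a data table so submitters' naming drift is editable
    with resources.files("mitocr").joinpath("vocabulary.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token, _, aliases = line.partition("\t")
            add(token, *aliases.split(",") if aliases else ())

    for token, three in _AMINO:
        one = token[3]
        add(token, f"tRNA-{three}", f"trn{three}", f"trna{one}", f"t{three}")
    for token, (three, codons) in _CODON_CLASS.items():
        one = token[3]
        add(token, f"tRNA-{three}({codons})", f"trn{one}{codons}",
            f"trn{three}{codons}", f"trna{three}{codons}")
    return table


_VOCAB: dict[str, str] | None = None


def _vocab() -> dict[str, str]:
    global _VOCAB
    if _VOCAB is None:
        _VOCAB = _builtin_vocabulary()
    return _VOCAB


def vocabulary_tokens() -> set[str]:
    return set(_vocab().values())


def normalize_label(raw: str, extra: Mapping[str, str] | None = None) -> str:
    """Map a raw gene name to its controlled-vocabulary token.

    Case- and punctuation-insensitive (``"COX1"``, ``"co1"``, ``"COI"`` all map
    to ``COI``; ``"D-loop"`` to ``CR``).  Unrecognized names, including bare
    ``tRNA-Leu``/``tRNA-Ser`` without a codon class, map to ``"unknown"``.
    Idempotent: tokens normalize to themselves.
    """
    key = _canon(raw)
    if extra:
        for k, v in extra.items():
            if _canon(k) == key:
                return v
    return _vocab().get(key, UNKNOWN)


# ---------------------------------------------------------------------------
# GenBank reading

_FEATURE_TYPES = {"gene", "CDS", "tRNA", "rRNA", "D-loop", "rep_origin",
                  "misc_feature", "misc_RNA"}

_CODON_HINTS = [("UUR", "trnL(UUR)"), ("CUN", "trnL(CUN)"),
                ("UCN", "trnS(UCN)"), ("AGY", "trnS(AGY)")]


def _label_from_qualifiers(feat: SeqFeature, extra: Mapping[str, str] | None) -> str:
    names: list[str] = []
    for q in ("product", "gene", "note", "standard_name"):
        names.extend(feat.qualifiers.get(q, []))
    if feat.type == "D-loop":
        names.append("D-loop")
    if feat.type == "rep_origin":
        names.append("OL")
    for name in names:
        token = normalize_label(name, extra)
        if token != UNKNOWN:
            return token
    # Leu/Ser isoacceptors: codon class may sit in a separate qualifier
    joined = " ".join(names).upper()
    if "LEU" in joined or "SER" in joined or "TRNL" in joined or "TRNS" in joined:
        for hint, token in _CODON_HINTS:
            if hint in joined:
                return token
    return UNKNOWN


def read_genbank(path: str | Path, extra_vocab: Mapping[str, str] | None = None) -> MitoGenome:
    """Read a GenBank flat file into a :class:`MitoGenome`.

    Feature labels are normalized into the controlled vocabulary; unmapped
    labels are kept with the ``"unknown"`` token.  GenBank's 1-based inclusive
    coordinates become 0-based half-open.  A compound location that wraps the
    circular origin becomes one interval with ``end > genome length``.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"cannot parse {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise GenBankParseError(f"{path}: record has no sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    seq = NucSequence(record.id or record.name, str(record.seq), circular=circular)

    n = len(seq)
    feats: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _label_from_qualifiers(feat, extra_vocab)
        if feat.type in ("gene", "misc_feature") and label == UNKNOWN:
            continue  # unnamed container features carry no information
        strand = "L" if feat.location.strand == -1 else "H"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        start, end = int(parts[0].start), int(parts[-1].end)
        if len(parts) > 1 and int(parts[-1].end) == n and int(parts[0].start) == 0:
            # wraps the origin: [s, n) + [0, e) -> [s, s + span)
            start = int(parts[-1].start)
            end = start + sum(len(p) for p in parts)
        key = (label, start % n, end)
        if key in seen:
            continue  # gene + CDS/tRNA pairs annotate the same span twice
        seen.add(key)
        feats.append(GeneFeature(label, start, end, strand))
    if not feats:
        raise GenBankParseError(f"{path}: no recognizable gene features")
    return MitoGenome(seq, feats, source_id=record.id or record.name)


def read_fasta(path: str | Path) -> list[NucSequence]:
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Report output (GFF3 + TSV/JSON)

def _gff3_row(seqid: str, source: str, ftype: str, start0: int, end0: int,
              strand: str = "+", attrs: str = ".") -> str:
    # GFF3 is 1-based inclusive
    return "\t".join([seqid, source, ftype, str(start0 + 1), str(end0), ".", strand, ".", attrs])


def write_report(partition, arrays: Sequence, call, path: str | Path,
                 seqid: str = "CR") -> None:
    """Write a GFF3 of CR domain/array intervals plus a JSON summary.

    ``path`` is the GFF3 file; a sibling ``<path>.json`` carries the
    rearrangement call and tandem-array table.  Field order is deterministic
    and re-reading the GFF3 reproduces the intervals exactly.
    """
    path = Path(path)
    rows = ["##gff-version 3"]
    if partition is not None:
        for name, (s, e) in (("ETAS", partition.etas), ("CCR", partition.ccr),
                             ("CSB", partition.csb)):
            rows.append(_gff3_row(seqid, "mitocr", "domain", s, e, "+", f"Name={name}"))
        for h in partition.hits:
            rows.append(_gff3_row(seqid, "mitocr", "motif", h.start, h.end,
                                  "+" if h.strand == "H" else "-",
                                  f"Name={h.motif};mismatches={h.mismatches}"))
    for i, arr in enumerate(arrays):
        rows.append(_gff3_row(seqid, "mitocr", "tandem_array", arr.start, arr.end, "+",
                              f"ID=array{i};unit_length={arr.unit_length};copies={arr.copy_number}"))
    path.write_text("\n".join(rows) + "\n")

    summary: dict = {"rearrangement": None, "arrays": []}
    if call is not None:
        summary["rearrangement"] = {
            "type": call.type,
            "events": [{"kind": k, "labels": list(labels)} for k, labels in call.events],
        }
    for arr in arrays:
        summary["arrays"].append({
            "start": arr.start, "end": arr.end, "unit_length": arr.unit_length,
            "copy_number": arr.copy_number, "consensus": arr.consensus,
        })
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=1))


def read_gff3_intervals(path: str | Path) -> list[tuple[str, str, int, int, str]]:
    """Read back (type, name, start0, end0, strand) rows written by :func:`write_report`."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        name = ""
        for kv in cols[8].split(";"):
            if kv.startswith("Name=") or kv.startswith("ID="):
                name = kv.split("=", 1)[1]
                break
        out.append((cols[2], name, int(cols[3]) - 1, int(cols[4]), cols[6]))
    return out


def to_seqrecord(g: MitoGenome) -> SeqRecord:
    """Render a MitoGenome as a Biopython SeqRecord (for GenBank output)."""
    rec = SeqRecord(Seq(g.sequence.residues), id=g.source_id or g.sequence.id,
                    name=(g.source_id or g.sequence.id)[:16], description="synthetic mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if g.sequence.circular else "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed so output is byte-stable
    n = len(g.sequence)
    for f in g.features:
        strand = -1 if f.strand == "L" else 1
        if f.end <= n:
            loc = FeatureLocation(f.start, f.end, strand=strand)
        else:
            loc = FeatureLocation(f.start, n, strand=strand) + FeatureLocation(0, f.end - n, strand=strand)
        ftype = "D-loop" if f.label == "CR" else ("rep_origin" if f.label == "OL" else
                                                  ("tRNA" if f.label.startswith("trn") else
                                                   ("rRNA" if f.label.startswith("rrn") else "gene")))
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.label]}))
    return rec


def write_genbank(g: MitoGenome, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(g), str(path), "genbank")
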