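"""Annotated mitochondrial genome records: GenBank/FASTA I/O, annotation
projection and gene extraction.

A complete avian mitogenome is a circular molecule of roughly 17 kb carrying
13 protein-coding genes, two rRNAs, 22 tRNAs and the non-coding control
region (CR), in a conserved order. Internally all coordinates are 0-based
half-open on the forward strand; the 1-based inclusive GenBank convention is
converted at the I/O boundary. A feature whose ``start > end`` spans the
circular origin.

Congeneric mitogenomes are typically >85% identical, so annotations can be
transferred from one fully annotated reference onto an unannotated assembly
through a single global pairwise alignment (:func:`project_annotations`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import edlib
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "CANONICAL_ELEMENTS",
    "canonical_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "project_annotations",
    "extract_gene",
    "reverse_complement",
]

#: Canonical non-tRNA element labels in the standard avian mitogenome order.
CANONICAL_ELEMENTS = (
    "12S", "16S", "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3",
    "ND3", "ND4L", "ND4", "ND5", "CytB", "ND6", "CR",
)

PROTEIN_ELEMENTS = frozenset(
    {"ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4L",
     "ND4", "ND5", "CytB", "ND6"}
)

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
VERTEBRATE_MITO_CODE = 2

# Synonyms seen in GenBank annotations, folded to canonical labels.
_SYNONYMS = {
    "12S": "12S", "12S RRNA": "12S", "12S RIBOSOMAL RNA": "12S",
    "S-RRNA": "12S", "RRNS": "12S", "SMALL SUBUNIT RIBOSOMAL RNA": "12S",
    "16S": "16S", "16S RRNA": "16S", "16S RIBOSOMAL RNA": "16S",
    "L-RRNA": "16S", "RRNL": "16S", "LARGE SUBUNIT RIBOSOMAL RNA": "16S",
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1",
    "NADH DEHYDROGENASE SUBUNIT 1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2",
    "NADH DEHYDROGENASE SUBUNIT 2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3",
    "NADH DEHYDROGENASE SUBUNIT 3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4",
    "NADH DEHYDROGENASE SUBUNIT 4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L",
    "NADH DEHYDROGENASE SUBUNIT 4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5",
    "NADH DEHYDROGENASE SUBUNIT 5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6",
    "NADH DEHYDROGENASE SUBUNIT 6": "ND6",
    "CO1": "CO1", "COI": "CO1", "COX1": "CO1", "COXI": "CO1",
    "CYTOCHROME C OXIDASE SUBUNIT 1": "CO1",
    "CYTOCHROME C OXIDASE SUBUNIT I": "CO1",
    "CO2": "CO2", "COII": "CO2", "COX2": "CO2", "COXII": "CO2",
    "CYTOCHROME C OXIDASE SUBUNIT 2": "CO2",
    "CYTOCHROME C OXIDASE SUBUNIT II": "CO2",
    "CO3": "CO3", "COIII": "CO3", "COX3": "CO3", "COXIII": "CO3",
    "CYTOCHROME C OXIDASE SUBUNIT 3": "CO3",
    "CYTOCHROME C OXIDASE SUBUNIT III": "CO3",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6",
    "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8",
    "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "CYTB": "CytB", "COB": "CytB", "CYB": "CytB", "CYT B": "CytB",
    "CYTOCHROME B": "CytB",
    "CR": "CR", "D-LOOP": "CR", "CONTROL REGION": "CR", "DLOOP": "CR",
    "MITOCHONDRIAL CONTROL REGION": "CR",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Sanity window for a complete avian mitogenome, in bp.
LENGTH_WINDOW = (15_000, 18_000)


def canonical_name(raw: str) -> str | None:
    """Map a raw GenBank feature name to its canonical element label.

    Returns ``None`` when the name is not a recognized synonym (the caller
    keeps such features verbatim, with ``kind='spacer'``).
    """
    key = raw.strip().upper()
    if key.startswith("TRNA") or key.startswith("TRN-") or key.startswith("TRN "):
        return None
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    return None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element on a mitogenome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``start > end`` denotes a feature spanning the circular origin.
    """

    name: str
    kind: str  # protein | rRNA | tRNA | control_region | spacer
    start: int
    end: int
    strand: str = "+"
    code_id: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in ("protein", "rRNA", "tRNA", "control_region", "spacer"):
            raise ValueError(f"bad feature kind {self.kind!r}")

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start
        return genome_length - self.start + self.end


@dataclass
class MitogenomeRecord:
    """One (possibly annotated) mitochondrial genome."""

    record_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    taxon: str = ""
    individual: str = ""
    circular: bool = True

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if not (0 <= f.start <= n and 0 <= f.end <= n):
                raise ValueError(
                    f"{self.record_id}: feature {f.name} [{f.start},{f.end}) "
                    f"outside sequence of length {n}"
                )
            if f.start > f.end and not self.circular:
                raise ValueError(
                    f"{self.record_id}: origin-spanning feature {f.name} on "
                    "a linear record"
                )
            if f.name in seen:
                raise ValueError(f"{self.record_id}: duplicate feature {f.name}")
            seen.add(f.name)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.record_id}: no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _classify(name: str, ftype: str) -> str:
    if name in PROTEIN_ELEMENTS:
        return "protein"
    if name in ("12S", "16S"):
        return "rRNA"
    if name == "CR":
        return "control_region"
    if ftype == "tRNA" or name.upper().startswith("TRNA"):
        return "tRNA"
    return "spacer"


def _feature_name(feat: SeqFeature) -> str:
    q = feat.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return str(q[key][0])
    return feat.type


def read_genbank(path) -> list[MitogenomeRecord]:
    """Read a (possibly multi-record) GenBank flat file of mitogenomes.

    CDS/rRNA/tRNA/D-loop features are mapped to :class:`GeneFeature` with
    canonical names; unrecognized names are retained verbatim with
    ``kind='spacer'``. Sequences are upper-cased.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not parsed:
        raise ValueError(f"malformed GenBank file {path}: no records found")
    if any(len(rec.seq) == 0 for rec in parsed):
        raise ValueError(f"malformed GenBank file {path}: record without sequence")
    for rec in parsed:
        feats: list[GeneFeature] = []
        seen: set[str] = set()
        for feat in rec.features:
            if feat.type not in ("CDS", "rRNA", "tRNA", "D-loop", "misc_feature"):
                continue
            raw = _feature_name(feat)
            if feat.type == "D-loop":
                name = "CR"
            else:
                name = canonical_name(raw)
                if name is None:
                    is_trna = feat.type == "tRNA" or raw.upper().startswith("TRNA")
                    name = raw if not is_trna else raw.replace(" ", "")
            if name in seen:
                continue
            seen.add(name)
            start = int(feat.location.start)
            end = int(feat.location.end)
            if not (0 <= start <= len(rec.seq) and 0 <= end <= len(rec.seq)):
                raise ValueError(
                    f"record {rec.id}: feature {name} beyond sequence bounds"
                )
            kind = _classify(name, feat.type)
            feats.append(GeneFeature(
                name=name,
                kind=kind,
                start=start,
                end=end,
                strand="-" if feat.location.strand == -1 else "+",
                code_id=VERTEBRATE_MITO_CODE if kind == "protein" else None,
            ))
        topology = rec.annotations.get("topology", "circular")
        organism = rec.annotations.get("organism", "")
        records.append(MitogenomeRecord(
            record_id=rec.id,
            sequence=str(rec.seq),
            features=feats,
            taxon=organism,
            circular=topology == "circular",
        ))
    return records


def write_genbank(records: list[MitogenomeRecord], path) -> None:
    """Write records back to GenBank; inverse of :func:`read_genbank`."""
    out = []
    _types = {"protein": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
              "control_region": "D-loop", "spacer": "misc_feature"}
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence), id=rec.record_id, name=rec.record_id[:16],
            description=rec.taxon or "mitochondrion",
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        if rec.taxon:
            sr.annotations["organism"] = rec.taxon
        for f in rec.features:
            loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
            sf = SeqFeature(loc, type=_types[f.kind])
            sf.qualifiers["gene"] = [f.name]
            if f.kind == "protein":
                sf.qualifiers["transl_table"] = [str(f.code_id or VERTEBRATE_MITO_CODE)]
            sr.features.append(sf)
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def extract_gene(record: MitogenomeRecord, name: str) -> str:
    """Extract one element's nucleotide sequence in feature orientation.

    Minus-strand features (e.g. ND6) are reverse-complemented;
    origin-spanning features on circular records are concatenated across
    the origin.
    """
    f = record.feature(name)
    if f.start <= f.end:
        sub = record.sequence[f.start:f.end]
    else:
        sub = record.sequence[f.start:] + record.sequence[:f.end]
    return reverse_complement(sub) if f.strand == "-" else sub


# ---------------------------------------------------------------------------
# Annotation projection


def _alignment_maps(target: str, reference: str) -> list[int]:
    """Map every reference coordinate (0..len(ref), inclusive ends) to the
    corresponding target coordinate through a global pairwise alignment."""
    res = edlib.align(reference, target, mode="NW", task="path")
    ref_to_tgt = [0] * (len(reference) + 1)
    r = t = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            for _ in range(n):
                ref_to_tgt[r] = t
                r += 1
                t += 1
        elif ch == "I":  # present in reference, absent in target
            for _ in range(n):
                ref_to_tgt[r] = t
                r += 1
        elif ch == "D":  # present in target only
            t += n
    ref_to_tgt[len(reference)] = len(target)
    return ref_to_tgt


def _feature_aligner() -> "Align.PairwiseAligner":
    # query (reference feature) global, target end gaps free; affine
    # internal gaps dearer than mismatches so boundaries are not shaved
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # unaligned target flanks appear as end gaps in the query row; free
    for new, old in (("open_left_deletion_score", "query_left_open_gap_score"),
                     ("extend_left_deletion_score", "query_left_extend_gap_score"),
                     ("open_right_deletion_score", "query_right_open_gap_score"),
                     ("extend_right_deletion_score", "query_right_extend_gap_score")):
        try:
            setattr(aligner, new, 0)
        except AttributeError:  # pragma: no cover - older Bio.Align naming
            setattr(aligner, old, 0)
    return aligner


def _refine_boundaries(target: str, ref_feature_seq: str, s: int, e: int,
                       window: int = 30) -> tuple[int, int]:
    """Sharpen projected feature boundaries by re-locating the reference
    feature sequence within a window around the globally mapped interval
    (semi-global affine alignment). The whole-genome pass places gaps at
    feature boundaries arbitrarily when flanks tie; this search is
    anchored by the feature itself.
    """
    if len(ref_feature_seq) < 30:
        return s, e
    pad = window + abs((e - s) - len(ref_feature_seq))
    lo = max(0, s - pad)
    hi = min(len(target), e + pad)
    aln = _feature_aligner().align(target[lo:hi], ref_feature_seq)[0]
    blocks = aln.aligned[0]
    if len(blocks) == 0:
        return s, e
    return lo + int(blocks[0][0]), lo + int(blocks[-1][1])


def _adjust_frame(start: int, end: int, ref_len: int, max_shift: int = 6) -> tuple[int, int]:
    """Nudge a projected protein feature's end so its length is congruent
    mod 3 with the reference feature's length (tolerating 1–2 nt partial
    stop codons), moving at most ``max_shift`` nt."""
    want = ref_len % 3
    have = (end - start) % 3
    if have == want:
        return start, end
    for shift in range(1, max_shift + 1):
        for cand in (end + shift, end - shift):
            if cand > start and (cand - start) % 3 == want:
                return start, cand
    return start, end


def project_annotations(
    target: MitogenomeRecord,
    reference: MitogenomeRecord,
    max_unaligned: int = 2000,
) -> MitogenomeRecord:
    """Transfer the reference's feature set onto an unannotated target.

    The target and reference genomes are globally aligned once; every
    reference feature's boundaries are carried through the alignment onto
    target coordinates. Protein features are nudged (≤6 nt) to preserve the
    reference reading-frame length mod 3.

    Assumes both genomes are rotated to the same origin; origin-spanning
    reference features are projected per arm.
    """
    lo, hi = LENGTH_WINDOW
    if not (lo <= target.length <= hi):
        raise ValueError(
            f"{target.record_id}: length {target.length} outside sanity "
            f"window [{lo}, {hi}]"
        )
    if not reference.features:
        raise ValueError(f"reference {reference.record_id} has no annotations")
    if abs(target.length - reference.length) > max_unaligned:
        raise ValueError(
            f"{target.record_id}: length differs from reference by more than "
            f"{max_unaligned} nt; genomes may not be alignable in one pass"
        )
    ref_to_tgt = _alignment_maps(target.sequence, reference.sequence)
    feats: list[GeneFeature] = []
    prev: GeneFeature | None = None
    prev_ref_end: int | None = None
    for f in reference.features:
        s, e = ref_to_tgt[f.start], ref_to_tgt[f.end]
        if f.start <= f.end and e <= s:
            warnings.warn(
                f"{target.record_id}: feature {f.name} collapsed during "
                "projection; dropped"
            )
            continue
        if f.start <= f.end:
            ref_seq = reference.sequence[f.start:f.end]
        else:
            ref_seq = reference.sequence[f.start:] + reference.sequence[:f.end]
        s, e = _refine_boundaries(target.sequence, ref_seq, s, e)
        # boundary gaps between abutting features are placed arbitrarily by
        # tied optimal alignments; snap non-coding boundaries to abutting
        # conserved neighbors, never the other way round
        abuts = prev is not None and prev_ref_end == f.start and feats
        reliable = ("protein", "rRNA", "tRNA")
        if abuts and f.kind not in reliable and \
                0 < abs(s - feats[-1].end) <= 10 and feats[-1].end < e:
            s = feats[-1].end
        elif abuts and f.kind in reliable and feats[-1].kind not in reliable \
                and 0 < abs(feats[-1].end - s) <= 10 and feats[-1].start < s:
            feats[-1] = replace(feats[-1], end=s)
        if f.kind == "protein":
            s, e = _adjust_frame(s, e, f.length(reference.length))
        feats.append(replace(f, start=s, end=e))
        prev, prev_ref_end = f, f.end
    return MitogenomeRecord(
        record_id=target.record_id,
        sequence=target.sequence,
        features=feats,
        taxon=target.taxon,
        individual=target.individual,
        circular=target.circular,
    )
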