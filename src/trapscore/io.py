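"""Reading and writing the formats the scorer consumes and produces.

Genomes (FASTA), transcript models (GTF/GFF3 exon features), SNVs (VCF),
per-position conservation tracks (chrom/pos/score TSV) and splicing-regulatory
motif sets (k-mer/weight text files). All coordinates are 1-based inclusive,
matching GTF and VCF; every sequence-window helper takes (contig, start, end,
strand) and reverse-complements for the minus strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed annotation, variant or track input."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """In-memory nucleotide sequences keyed by contig name.

    Sequences are stored uppercase over {A,C,G,T,N}. ``fetch`` is 1-based
    inclusive and reverse-complements when ``strand == '-'``.
    """

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"empty sequence for contig {name!r}")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def contig_length(self, contig: str) -> int:
        return len(self._get(contig))

    def _get(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise AnnotationError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence on [start, end] (1-based inclusive)."""
        seq = self._get(contig)
        if start < 1 or end > len(seq) or start > end:
            raise AnnotationError(
                f"window {contig}:{start}-{end} outside contig bounds (1-{len(seq)})"
            )
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub

    def fetch_padded(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Like ``fetch`` but pads out-of-bounds flanks with ``N``."""
        seq = self._get(contig)
        left = max(start, 1)
        right = min(end, len(seq))
        if left > right:
            sub = "N" * (end - start + 1)
        else:
            sub = "N" * (left - start) + seq[left - 1 : right] + "N" * (end - right)
        return reverse_complement(sub) if strand == "-" else sub

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos)

    def with_substitution(self, contig: str, pos: int, alt: str) -> "Genome":
        """A copy of this genome with a single-base substitution applied."""
        seq = self._get(contig)
        if not 1 <= pos <= len(seq):
            raise AnnotationError(f"substitution position {pos} outside {contig}")
        new = seq[: pos - 1] + alt.upper() + seq[pos:]
        out = object.__new__(Genome)
        out.contigs = {**self.contigs, contig: new}
        return out


def load_genome(path) -> Genome:
    """Load a FASTA file into memory (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    names = list(fa.keys())
    if len(set(names)) != len(names):  # pragma: no cover - pyfaidx raises first
        raise AnnotationError("duplicate contig names in FASTA")
    contigs = {name: str(fa[name][:]) for name in names}
    fa.close()
    return Genome(contigs)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One transcript model: exons in transcription order, 1-based inclusive.

    For minus-strand transcripts the exon list is ordered by descending
    genomic start, so index 0 is always the 5'-most exon of the mRNA.
    """

    id: str
    gene_id: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r} for {self.id}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise AnnotationError(f"overlapping exons in transcript {self.id}")
            if s2 - e1 - 1 < 4:
                raise AnnotationError(
                    f"intron shorter than 4 nt in transcript {self.id}"
                )
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic (start, end) of the whole gene body."""
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)

    def introns(self) -> List[Tuple[int, int]]:
        """Genomic (start, end) of each intron, in transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(text: str) -> Dict[str, str]:
    if "=" in text and '"' not in text:
        return dict(_GFF3_ATTR.findall(text))
    return dict(_GTF_ATTR.findall(text))


def load_annotation(path) -> List[Transcript]:
    """Parse exon features from a GTF or GFF3 file into Transcript models."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    exons: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab fields")
            contig, _, feature, start, end, _, strand, _, attrs = fields
            if feature.lower() != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id") or attr.get("Parent")
            if not tid:
                raise AnnotationError(f"{path}:{lineno}: exon without transcript id")
            gid = attr.get("gene_id") or attr.get("gene") or tid
            rec = exons.setdefault(
                tid, {"gene_id": gid, "contig": contig, "strand": strand, "exons": []}
            )
            if rec["contig"] != contig or rec["strand"] != strand:
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid} spans contigs/strands"
                )
            rec["exons"].append((start_i, end_i))
    return [
        Transcript(id=tid, gene_id=r["gene_id"], contig=r["contig"],
                   strand=r["strand"], exons=r["exons"])
        for tid, r in exons.items()
    ]


def write_annotation(transcripts: Sequence[Transcript], path) -> None:
    """Emit transcripts as GTF exon features (genomic coordinate order)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, (s, e) in enumerate(sorted(t.exons), 1):
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.contig}\ttrapscore\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution, genomic plus-strand alleles."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise AnnotationError(f"not an SNV: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise AnnotationError("ref and alt alleles identical")

    def check_reference(self, genome: Genome) -> None:
        obs = genome.base(self.contig, self.pos)
        if obs != self.ref:
            raise AnnotationError(
                f"reference mismatch at {self.contig}:{self.pos}: "
                f"VCF says {self.ref}, genome has {obs}"
            )


def load_variants(path, genome: Optional[Genome] = None) -> List[Variant]:
    """Read SNVs from a VCF; multi-allelic rows are split, non-SNVs skipped."""
    from cyvcf2 import VCF

    out: List[Variant] = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
                logger.warning(
                    "skipping non-SNV allele %s>%s at %s:%d",
                    rec.REF, alt, rec.CHROM, rec.POS,
                )
                continue
            v = Variant(rec.CHROM, rec.POS, rec.REF.upper(), alt.upper())
            if genome is not None:
                v.check_reference(genome)
            out.append(v)
    return out


def write_vcf(variants: Sequence[Variant], path, contig_lengths=None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=trapscore\n')
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(variants):
            fh.write(f"{v.contig}\t{v.pos}\tv{i}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Variant-in-transcript context
# ---------------------------------------------------------------------------


@dataclass
class VariantContext:
    """A variant's placement within one transcript.

    ``exon_index`` is the 1-based ordinal (transcription order) of the
    harboring exon, or of the nearest exon for intronic variants. Distances
    are strand-oriented and signed: 0 at the boundary base, positive inside
    the exon, negative on the intronic side. ``dist_to_acceptor`` refers to
    the 3'ss at the exon's upstream junction (None for the first exon);
    ``dist_to_donor`` to the 5'ss at its downstream junction (None for the
    last exon).
    """

    variant: Variant
    transcript: Transcript
    region: str  # "exonic" | "intronic"
    exon_index: int
    dist_to_acceptor: Optional[int]
    dist_to_donor: Optional[int]


def _oriented(pos: int, strand: str) -> int:
    return pos if strand == "+" else -pos


def _context_for(variant: Variant, t: Transcript) -> Optional[VariantContext]:
    lo, hi = t.span
    if variant.contig != t.contig or not lo <= variant.pos <= hi:
        return None
    u = _oriented(variant.pos, t.strand)
    # harboring exon, else nearest exon (ties -> upstream, i.e. earlier in
    # transcription order)
    region = "intronic"
    best_i, best_gap = None, None
    for i, (gs, ge) in enumerate(t.exons):
        if gs <= variant.pos <= ge:
            region, best_i = "exonic", i
            break
        gap = min(abs(variant.pos - gs), abs(variant.pos - ge))
        if best_gap is None or gap < best_gap:
            best_i, best_gap = i, gap
    assert best_i is not None
    gs, ge = t.exons[best_i]
    if t.strand == "+":
        acc_base, don_base = gs, ge
    else:
        acc_base, don_base = ge, gs
    dist_acc = u - _oriented(acc_base, t.strand) if best_i > 0 else None
    dist_don = _oriented(don_base, t.strand) - u if best_i < t.n_exons - 1 else None
    return VariantContext(
        variant=variant,
        transcript=t,
        region=region,
        exon_index=best_i + 1,
        dist_to_acceptor=dist_acc,
        dist_to_donor=dist_don,
    )


def locate_variant(
    variant: Variant, transcripts: Iterable[Transcript]
) -> List[VariantContext]:
    """One context per transcript whose gene span contains the variant."""
    out = []
    for t in transcripts:
        ctx = _context_for(variant, t)
        if ctx is not None:
            out.append(ctx)
    return out


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Sparse per-position conservation scores (rejected-substitutions style).

    ``get`` returns None for positions absent from the track; downstream
    feature assembly imputes 0 with an explicit missing flag.
    """

    def __init__(self, scores: Dict[Tuple[str, int], float]):
        self._scores = scores

    def __len__(self) -> int:
        return len(self._scores)

    def get(self, contig: str, pos: int) -> Optional[float]:
        return self._scores.get((contig, pos))


def load_conservation(path) -> ConservationTrack:
    """Read a chrom<TAB>pos<TAB>score track; duplicate positions: last wins."""
    scores: Dict[Tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected 3 columns")
            contig, pos_s, score_s = parts[0], parts[1], parts[2]
            if lineno == 1 and not _is_number(score_s):
                continue  # header row
            if not _is_number(score_s):
                raise AnnotationError(f"{path}:{lineno}: non-numeric score {score_s!r}")
            key = (contig, int(pos_s))
            if key in scores:
                logger.warning("duplicate conservation entry %s:%s, last wins", *key)
            scores[key] = float(score_s)
    return ConservationTrack(scores)


def write_conservation(track_rows: Iterable[Tuple[str, int, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tscore\n")
        for contig, pos, score in track_rows:
            fh.write(f"{contig}\t{pos}\t{score:.4f}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Splicing-regulatory motif sets
# ---------------------------------------------------------------------------


@dataclass
class MotifSet:
    """A named set of equal-length k-mers with weights (e.g. SRSF1 hexamers)."""

    name: str
    kmers: Dict[str, float]
    role: str = "enhancer"  # "enhancer" | "silencer"
    k: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.kmers:
            raise AnnotationError(f"motif set {self.name!r} is empty")
        lengths = {len(m) for m in self.kmers}
        if len(lengths) != 1:
            raise AnnotationError(f"motif set {self.name!r} mixes k-mer lengths")
        bad = [m for m in self.kmers if set(m) - set("ACGT")]
        if bad:
            raise AnnotationError(f"invalid characters in motif {bad[0]!r}")
        for w in self.kmers.values():
            if not _finite(w):
                raise AnnotationError(f"non-finite motif weight in {self.name!r}")
        self.k = lengths.pop()

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def load_motif_set(path, name: str, role: str = "enhancer") -> MotifSet:
    """Load a two-column k-mer/weight text file (weight optional, default 1)."""
    kmers: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            kmer = parts[0].upper()
            weight = float(parts[1]) if len(parts) > 1 else 1.0
            kmers[kmer] = weight
    return MotifSet(name=name, kmers=kmers, role=role)


def write_motif_set(motifs: MotifSet, path) -> None:
    with open(path, "w") as fh:
        for kmer, w in motifs.kmers.items():
            fh.write(f"{kmer}\t{w:g}\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

SCORE_KEY_COLUMNS = ["contig", "pos", "ref", "alt", "transcript", "trap", "tier"]


def write_scores(records, path, header_lines: Sequence[str] = ()) -> None:
    """Write (Variant, transcript id, TrapScore, FeatureVector) rows as TSV.

    Column order is fixed: the seven key columns followed by the 20 registry
    features. TraP values are vote fractions out of 1000 trees, so 3 decimals
    are exact.
    """
    from .features import FEATURE_NAMES

    rows = []
    for variant, tid, score, fv in records:
        row = {
            "contig": variant.contig,
            "pos": variant.pos,
            "ref": variant.ref,
            "alt": variant.alt,
            "transcript": tid,
            "trap": round(score.value, 3),
            "tier": score.tier,
        }
        for name in FEATURE_NAMES:
            row[name] = fv[name]
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCORE_KEY_COLUMNS + list(FEATURE_NAMES))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
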