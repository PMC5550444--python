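"""Splice-site position-specific scoring matrices (PSSMs).

Matrices are tallied from annotated introns whose cores obey the G[T/C]–AG
rule. The acceptor (3'ss) motif is the last 20 intronic nucleotides plus the
first 3 exonic nucleotides (K=23); the donor (5'ss) motif is the last 3
exonic nucleotides plus the first 6 intronic nucleotides (K=9). A motif A of
length K is scored as

    raw(A) = sum_{i=1..K} log2 f(i, A_i)

where f(i, b) is the pseudocounted base frequency at motif position i, and
normalized to the 0–100 scale as

    score = 100 * (raw - Min) / (Max - Min)

with Min and Max the extreme raw scores over motifs (see ``bounds``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import Genome, Transcript, VariantContext

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

ACCEPTOR_K = 23
ACCEPTOR_INTRON_NT = 20  # intronic part of the 3'ss window
ACCEPTOR_EXON_NT = 3
DONOR_K = 9
DONOR_EXON_NT = 3
DONOR_INTRON_NT = 6

DONOR_CORES = ("GT", "GC")  # G[T/C] rule at the intron 5' end
ACCEPTOR_CORE = "AG"

# offset of the 2-nt core within each window
DONOR_CORE_OFFSET = DONOR_EXON_NT  # positions 4-5 of the 9-mer
ACCEPTOR_CORE_OFFSET = ACCEPTOR_INTRON_NT - 2  # positions 19-20 of the 23-mer


class PssmError(ValueError):
    pass


class DegenerateWindow(ValueError):
    """Window contains non-ACGT characters and cannot be scored."""


@dataclass
class PSSM:
    """Per-position base frequencies for one splice-site class."""

    site_class: str  # "acceptor_3ss" | "donor_5ss"
    freq: np.ndarray  # K x 4, rows sum to 1
    pseudocount: float
    n_sites: int
    min_raw: float
    max_raw: float
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.K = self.freq.shape[0]
        expected = {"acceptor_3ss": ACCEPTOR_K, "donor_5ss": DONOR_K}.get(self.site_class)
        if expected is not None and self.K != expected:
            raise PssmError(f"{self.site_class} PSSM must have K={expected}")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise PssmError("PSSM rows must sum to 1")
        if (self.freq <= 0).any():
            raise PssmError("PSSM frequencies must be strictly positive")
        if self.min_raw > self.max_raw:
            raise PssmError("min_raw exceeds max_raw")
        self._log2 = np.log2(self.freq)

    # -- scoring ----------------------------------------------------------

    def raw_score(self, seq: str) -> float:
        """Sum of per-position log2 frequencies of ``seq``."""
        if len(seq) != self.K:
            raise PssmError(f"motif length {len(seq)} != K={self.K}")
        total = 0.0
        for i, b in enumerate(seq.upper()):
            j = _BASE_INDEX.get(b)
            if j is None:
                raise DegenerateWindow(f"non-ACGT base {b!r} at motif position {i+1}")
            total += self._log2[i, j]
        return total

    def normalized_score(self, seq: str) -> float:
        """0–100 score; argmax motif maps to 100, argmin to 0 exactly."""
        if self.max_raw == self.min_raw:
            raise PssmError("degenerate PSSM: min_raw == max_raw")
        raw = self.raw_score(seq)
        score = 100.0 * (raw - self.min_raw) / (self.max_raw - self.min_raw)
        return min(100.0, max(0.0, score))

    # -- convenience ------------------------------------------------------

    def argmax_motif(self) -> str:
        return "".join(BASES[j] for j in self.freq.argmax(axis=1))

    def argmin_motif(self) -> str:
        return "".join(BASES[j] for j in self.freq.argmin(axis=1))


def _analytic_bounds(freq: np.ndarray) -> Tuple[float, float]:
    # accumulate in the same order as raw_score so the argmin/argmax motifs
    # reproduce the bounds bit-exactly (normalized scores of exactly 0/100)
    lg = np.log2(freq)
    mn = mx = 0.0
    for i in range(lg.shape[0]):
        mn += float(lg[i].min())
        mx += float(lg[i].max())
    return mn, mx


def intron_windows(
    t: Transcript, intron: Tuple[int, int], genome: Genome
) -> Tuple[str, str]:
    """Strand-oriented (donor 9-mer, acceptor 23-mer) windows of one intron.

    ``intron`` is the genomic (start, end) interval. Windows reaching past
    the contig are padded with N and will raise ``DegenerateWindow`` when
    scored.
    """
    a, b = intron
    c = t.contig
    if t.strand == "+":
        donor = genome.fetch_padded(c, a - DONOR_EXON_NT, a + DONOR_INTRON_NT - 1, "+")
        acceptor = genome.fetch_padded(
            c, b - ACCEPTOR_INTRON_NT + 1, b + ACCEPTOR_EXON_NT, "+"
        )
    else:
        donor = genome.fetch_padded(c, b - DONOR_INTRON_NT + 1, b + DONOR_EXON_NT, "-")
        acceptor = genome.fetch_padded(
            c, a - ACCEPTOR_EXON_NT, a + ACCEPTOR_INTRON_NT - 1, "-"
        )
    return donor, acceptor


def _qualifies(donor_window: str, acceptor_window: str) -> bool:
    """G[T/C]..AG rule on the strand-oriented intron ends."""
    core5 = donor_window[DONOR_CORE_OFFSET : DONOR_CORE_OFFSET + 2]
    core3 = acceptor_window[ACCEPTOR_CORE_OFFSET : ACCEPTOR_CORE_OFFSET + 2]
    return core5 in DONOR_CORES and core3 == ACCEPTOR_CORE


def build_pssms(
    transcripts: Iterable[Transcript],
    genome: Genome,
    pseudocount: float = 1.0,
    bounds: str = "analytic",
) -> Tuple[PSSM, PSSM]:
    """Tally acceptor and donor PSSMs from all qualifying annotated introns.

    Only introns whose strand-oriented ends read G[T/C]..AG contribute; both
    matrices come from the same intron set. ``bounds`` selects how Min/Max
    are computed: "analytic" takes the extreme raw score over all possible
    K-mers (sum of per-position min/max log-frequencies), "annotated" takes
    the extremes over the training windows themselves.

    Returns (acceptor PSSM, donor PSSM).
    """
    if bounds not in ("analytic", "annotated"):
        raise PssmError(f"unknown bounds mode {bounds!r}")
    acc_counts = np.zeros((ACCEPTOR_K, 4))
    don_counts = np.zeros((DONOR_K, 4))
    don_windows: List[str] = []
    acc_windows: List[str] = []
    for t in transcripts:
        for intron in t.introns():
            donor, acceptor = intron_windows(t, intron, genome)
            if "N" in donor or "N" in acceptor:
                logger.warning(
                    "skipping intron %s:%d-%d of %s: window truncated/ambiguous",
                    t.contig, intron[0], intron[1], t.id,
                )
                continue
            if not _qualifies(donor, acceptor):
                continue
            for i, b in enumerate(donor):
                don_counts[i, _BASE_INDEX[b]] += 1
            for i, b in enumerate(acceptor):
                acc_counts[i, _BASE_INDEX[b]] += 1
            don_windows.append(donor)
            acc_windows.append(acceptor)
    n = len(don_windows)
    if n == 0:
        raise PssmError("no introns satisfy the G[T/C]-AG rule")

    def _finish(counts: np.ndarray, site_class: str, windows: List[str]) -> PSSM:
        freq = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        mn, mx = _analytic_bounds(freq)
        p = PSSM(site_class=site_class, freq=freq, pseudocount=pseudocount,
                 n_sites=n, min_raw=mn, max_raw=mx)
        if bounds == "annotated":
            raws = [p.raw_score(w) for w in windows]
            p.min_raw, p.max_raw = min(raws), max(raws)
        return p

    return (
        _finish(acc_counts, "acceptor_3ss", acc_windows),
        _finish(don_counts, "donor_5ss", don_windows),
    )


@dataclass
class SiteWindows:
    """Acceptor/donor windows flanking one exon (None where absent)."""

    acceptor: Optional[str]
    donor: Optional[str]


def site_windows(context: VariantContext, genome: Genome) -> SiteWindows:
    """Splice-site windows of the context's harboring/nearest exon.

    The first exon has no acceptor and the last exon no donor; those slots
    are None. Windows are strand-oriented; extracting from a genome with the
    variant substituted yields the post-variant windows.
    """
    t = context.transcript
    i = context.exon_index - 1
    introns = t.introns()
    acceptor = donor = None
    if i > 0:  # acceptor window comes from the upstream intron
        _, acceptor = intron_windows(t, introns[i - 1], genome)
    if i < t.n_exons - 1:  # donor window from the downstream intron
        donor, _ = intron_windows(t, introns[i], genome)
    return SiteWindows(acceptor=acceptor, donor=donor)


# ---------------------------------------------------------------------------
# Serialization: TSV with a header line per matrix followed by K rows of 4
# frequencies.
# ---------------------------------------------------------------------------


def save_pssms(pssms: Sequence[PSSM], path) -> None:
    with open(path, "w") as fh:
        fh.write("# trapscore splice-site PSSMs\n")
        for p in pssms:
            fh.write(
                f">{p.site_class}\tK={p.K}\tpseudocount={p.pseudocount:g}"
                f"\tn_sites={p.n_sites}\tmin_raw={p.min_raw!r}\tmax_raw={p.max_raw!r}\n"
            )
            fh.write("pos\t" + "\t".join(BASES) + "\n")
            for i in range(p.K):
                row = "\t".join(repr(float(x)) for x in p.freq[i])
                fh.write(f"{i + 1}\t{row}\n")


def load_pssms(path) -> Tuple[PSSM, PSSM]:
    """Load (acceptor, donor) PSSMs from the TSV produced by ``save_pssms``."""
    out = {}
    header = None
    rows: List[List[float]] = []

    def _flush():
        if header is None:
            return
        meta = dict(kv.split("=", 1) for kv in header[1:])
        p = PSSM(
            site_class=header[0],
            freq=np.array(rows),
            pseudocount=float(meta["pseudocount"]),
            n_sites=int(meta["n_sites"]),
            min_raw=float(meta["min_raw"]),
            max_raw=float(meta["max_raw"]),
        )
        out[p.site_class] = p

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split("\t")
                header = [parts[0]] + parts[1:]
                rows = []
            elif line.startswith("pos\t"):
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    _flush()
    try:
        return out["acceptor_3ss"], out["donor_5ss"]
    except KeyError as e:
        raise PssmError(f"PSSM file {path} missing matrix {e}") from None
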