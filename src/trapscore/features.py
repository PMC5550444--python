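"""Per variant-in-transcript feature extraction.

The 20-feature registry covers splice-site strength before/after the
substitution, cryptic splice-site creation and disruption, interaction
summaries, exonic splicing regulatory (ESR) element gains and losses,
conservation and distance to the nearest splice site. The splice-interaction
summaries follow the weak-site logic: an exon with a weak splice site is
highly affected by a variant creating a strong competing site, while a
strong existing site nullifies the effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    ConservationTrack,
    Genome,
    MotifSet,
    Variant,
    VariantContext,
    reverse_complement,
)
from .pssm import (
    ACCEPTOR_EXON_NT,
    ACCEPTOR_INTRON_NT,
    DONOR_EXON_NT,
    DONOR_INTRON_NT,
    PSSM,
    DegenerateWindow,
    site_windows,
)

logger = logging.getLogger(__name__)

#: The model's feature registry: name -> position in the feature matrix.
FEATURE_NAMES: Tuple[str, ...] = (
    "acc_score_ref",
    "acc_score_alt",
    "don_score_ref",
    "don_score_alt",
    "acc_delta",
    "don_delta",
    "cryptic5_score",
    "cryptic3_score",
    "cryptic5_lost",
    "cryptic3_lost",
    "splice_site_overall",
    "variant_splice_score",
    "esr_created",
    "esr_disrupted",
    "silencer_created",
    "silencer_disrupted",
    "combined_esr_score",
    "negated_esr_score",
    "gerp_rs",
    "dist_nearest_ss",
)

#: radius of strand-oriented local sequence kept around the variant for the
#: cryptic-site scan (enough for a 23-nt acceptor window in either frame)
CRYPTIC_FLANK = 25

STRONG_CRYPTIC_5SS = 84.0  # normalized score above which a cryptic 5'ss is "strong"


@dataclass
class FeatureVector:
    """The 20 registry features for one variant-in-transcript, plus flags."""

    values: Dict[str, float]
    gerp_missing: bool = False
    cpg: str = "none"  # "creates_cpg" | "destroys_cpg" | "none"

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature registry mismatch: -{missing} +{extra}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite feature {name}={v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


def _safe_norm(pssm: PSSM, seq: Optional[str], what: str) -> Optional[float]:
    if seq is None:
        return None
    try:
        return pssm.normalized_score(seq)
    except DegenerateWindow:
        logger.warning("%s window contains ambiguous bases; treated as missing", what)
        return None


# ---------------------------------------------------------------------------
# Splice-site before/after scores
# ---------------------------------------------------------------------------


def splice_site_delta(
    context: VariantContext,
    genome: Genome,
    pssms: Tuple[PSSM, PSSM],
) -> Dict[str, float]:
    """Acceptor/donor strengths of the harboring (or nearest) exon before and
    after the substitution, plus alt-ref deltas.

    The post-variant score differs from the pre-variant score only when the
    variant lies inside the corresponding splice-site window; a missing
    window (first/last exon, or ambiguous bases) contributes 0.
    """
    acc_pssm, don_pssm = pssms
    v = context.variant
    ref_w = site_windows(context, genome)
    alt_w = site_windows(context, genome.with_substitution(v.contig, v.pos, v.alt))

    acc_ref = _safe_norm(acc_pssm, ref_w.acceptor, "acceptor")
    don_ref = _safe_norm(don_pssm, ref_w.donor, "donor")
    acc_alt = _safe_norm(acc_pssm, alt_w.acceptor, "acceptor")
    don_alt = _safe_norm(don_pssm, alt_w.donor, "donor")

    def _val(x: Optional[float], fallback: Optional[float] = None) -> float:
        if x is None:
            x = fallback
        return 0.0 if x is None else x

    out = {
        "acc_score_ref": _val(acc_ref),
        "acc_score_alt": _val(acc_alt, acc_ref),
        "don_score_ref": _val(don_ref),
        "don_score_alt": _val(don_alt, don_ref),
    }
    out["acc_delta"] = out["acc_score_alt"] - out["acc_score_ref"]
    out["don_delta"] = out["don_score_alt"] - out["don_score_ref"]
    return out


# ---------------------------------------------------------------------------
# Cryptic splice sites
# ---------------------------------------------------------------------------


def _local_sequences(
    variant: Variant, strand: str, genome: Genome, flank: int = CRYPTIC_FLANK
) -> Tuple[str, str, int]:
    """Strand-oriented (ref_local, alt_local, variant_index) around the SNV."""
    ref_local = genome.fetch_padded(
        variant.contig, variant.pos - flank, variant.pos + flank, strand
    )
    alt_base = variant.alt if strand == "+" else reverse_complement(variant.alt)
    idx = flank  # centre position in either orientation
    alt_local = ref_local[:idx] + alt_base + ref_local[idx + 1 :]
    return ref_local, alt_local, idx


def _core_window(seq: str, core_start: int, site: str) -> Optional[str]:
    """Full splice window implied by a 2-nt core starting at ``core_start``."""
    if site == "donor":
        lo = core_start - DONOR_EXON_NT
        hi = core_start + DONOR_INTRON_NT
    else:  # acceptor: 18 intronic nt precede the AG, 3 exonic nt follow it
        lo = core_start - (ACCEPTOR_INTRON_NT - 2)
        hi = core_start + 2 + ACCEPTOR_EXON_NT
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    return None if "N" in window else window


def cryptic_site_scan(
    context: VariantContext,
    genome: Genome,
    pssms: Tuple[PSSM, PSSM],
) -> Dict[str, float]:
    """Score cryptic splice cores created or destroyed by the variant.

    Both dinucleotide frames overlapping the variant base are examined on
    the transcript strand. A GT (donor core) or AG (acceptor core) present
    in the alt allele but not the ref is a creation: the implied full splice
    window is scored on the alt sequence. A core present in ref but lost in
    alt is a disruption, scored on the ref sequence. The best normalized
    score per class is kept; no core change leaves all four features at 0.
    """
    acc_pssm, don_pssm = pssms
    v = context.variant
    ref_local, alt_local, idx = _local_sequences(v, context.transcript.strand, genome)

    created5: List[float] = []
    created3: List[float] = []
    lost5: List[float] = []
    lost3: List[float] = []
    for f0 in (idx - 1, idx):
        if f0 < 0 or f0 + 2 > len(ref_local):
            continue
        ref_di = ref_local[f0 : f0 + 2]
        alt_di = alt_local[f0 : f0 + 2]
        if ref_di == alt_di:
            continue
        for core, site, pssm, created, lost in (
            ("GT", "donor", don_pssm, created5, lost5),
            ("AG", "acceptor", acc_pssm, created3, lost3),
        ):
            if alt_di == core and ref_di != core:
                w = _core_window(alt_local, f0, site)
                if w is None:
                    logger.warning("cryptic %s candidate window truncated; skipped", site)
                else:
                    created.append(pssm.normalized_score(w))
            elif ref_di == core and alt_di != core:
                w = _core_window(ref_local, f0, site)
                if w is None:
                    logger.warning("cryptic %s candidate window truncated; skipped", site)
                else:
                    lost.append(pssm.normalized_score(w))
    return {
        "cryptic5_score": max(created5, default=0.0),
        "cryptic3_score": max(created3, default=0.0),
        "cryptic5_lost": max(lost5, default=0.0),
        "cryptic3_lost": max(lost3, default=0.0),
    }


# ---------------------------------------------------------------------------
# Interaction summaries
# ---------------------------------------------------------------------------


def interaction_scores(f: Dict[str, float]) -> Dict[str, float]:
    """Splice Site Overall Score and Variant Splice Score.

    The overall score is the advantage of the best newly created cryptic
    site over the existing site of the same class (floored at 0): a strong
    existing site nullifies a competing cryptic site. The variant splice
    score is a single worst-damage summary across weakened sites, destroyed
    cryptic cores and the overall score.
    """
    overall = max(
        0.0,
        f["cryptic5_score"] - f["don_score_ref"],
        f["cryptic3_score"] - f["acc_score_ref"],
    )
    variant_splice = max(
        overall,
        -f["acc_delta"],
        -f["don_delta"],
        f["cryptic5_lost"],
        f["cryptic3_lost"],
        0.0,
    )
    return {"splice_site_overall": overall, "variant_splice_score": variant_splice}


# ---------------------------------------------------------------------------
# Exonic splicing regulatory elements
# ---------------------------------------------------------------------------


def esr_scan(
    context: VariantContext,
    genome: Genome,
    motif_sets: Sequence[MotifSet],
) -> Dict[str, float]:
    """Count regulatory k-mers gained/lost by the substitution.

    Only exonic variants are scanned (the elements are exonic by
    definition); for each motif set of length k the 2k-1-nt windows centred
    on the variant — truncated to the exon bounds — are compared between the
    ref and alt alleles on the transcript strand. A k-mer offset whose alt
    k-mer belongs to the set while the ref k-mer does not is a creation; the
    reverse is a disruption.
    """
    zeros = {
        "esr_created": 0.0,
        "esr_disrupted": 0.0,
        "silencer_created": 0.0,
        "silencer_disrupted": 0.0,
    }
    if context.region != "exonic" or not motif_sets:
        out = dict(zeros)
        out["combined_esr_score"] = 0.0
        out["negated_esr_score"] = 0.0
        return out

    v = context.variant
    t = context.transcript
    gs, ge = t.exons[context.exon_index - 1]
    counts = dict(zeros)
    for ms in motif_sets:
        k = ms.k
        lo = max(gs, v.pos - (k - 1))
        hi = min(ge, v.pos + (k - 1))
        if hi - lo + 1 < k:
            logger.warning(
                "exon too short around %s:%d for %d-mer scan; truncated window",
                v.contig, v.pos, k,
            )
            continue
        ref_win = genome.fetch(v.contig, lo, hi, t.strand)
        alt_win = genome.with_substitution(v.contig, v.pos, v.alt).fetch(
            v.contig, lo, hi, t.strand
        )
        prefix = "esr" if ms.role == "enhancer" else "silencer"
        for off in range(len(ref_win) - k + 1):
            in_ref = ref_win[off : off + k] in ms
            in_alt = alt_win[off : off + k] in ms
            if in_alt and not in_ref:
                counts[f"{prefix}_created"] += 1
            elif in_ref and not in_alt:
                counts[f"{prefix}_disrupted"] += 1
    counts["combined_esr_score"] = (
        counts["esr_created"]
        - counts["esr_disrupted"]
        - counts["silencer_created"]
        + counts["silencer_disrupted"]
    )
    counts["negated_esr_score"] = -(counts["esr_created"] + counts["esr_disrupted"])
    return counts


# ---------------------------------------------------------------------------
# CpG (computed and exported, but outside the 20-feature registry)
# ---------------------------------------------------------------------------


def cpg_feature(variant: Variant, genome: Genome) -> str:
    """Classify CpG dinucleotide gain/loss across both overlapping frames.

    CpG is strand-symmetric, so frames are examined on the plus strand. A
    variant that simultaneously creates one CpG and destroys another is
    classified "none".
    """
    created = destroyed = False
    alt_genome = genome.with_substitution(variant.contig, variant.pos, variant.alt)
    for start in (variant.pos - 1, variant.pos):
        ref_di = genome.fetch_padded(variant.contig, start, start + 1)
        alt_di = alt_genome.fetch_padded(variant.contig, start, start + 1)
        if alt_di == "CG" and ref_di != "CG":
            created = True
        if ref_di == "CG" and alt_di != "CG":
            destroyed = True
    if created and not destroyed:
        return "creates_cpg"
    if destroyed and not created:
        return "destroys_cpg"
    return "none"


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _distance_feature(context: VariantContext) -> float:
    dists = [
        abs(d)
        for d in (context.dist_to_acceptor, context.dist_to_donor)
        if d is not None
    ]
    return float(min(dists)) if dists else 0.0


def compute_features(
    context: VariantContext,
    genome: Genome,
    pssms: Tuple[PSSM, PSSM],
    motif_sets: Sequence[MotifSet] = (),
    conservation: Optional[ConservationTrack] = None,
) -> FeatureVector:
    """The full 20-feature vector for one variant-in-transcript."""
    v = context.variant
    v.check_reference(genome)
    values: Dict[str, float] = {}
    values.update(splice_site_delta(context, genome, pssms))
    values.update(cryptic_site_scan(context, genome, pssms))
    values.update(interaction_scores(values))
    values.update(esr_scan(context, genome, motif_sets))
    gerp = conservation.get(v.contig, v.pos) if conservation is not None else None
    values["gerp_rs"] = gerp if gerp is not None else 0.0
    values["dist_nearest_ss"] = _distance_feature(context)
    return FeatureVector(
        values=values,
        gerp_missing=gerp is None,
        cpg=cpg_feature(v, genome),
    )


def assemble_features(
    variant: Variant,
    contexts: Sequence[VariantContext],
    genome: Genome,
    pssms: Tuple[PSSM, PSSM],
    motif_sets: Sequence[MotifSet] = (),
    conservation: Optional[ConservationTrack] = None,
) -> List[FeatureVector]:
    """One FeatureVector per transcript context of ``variant``."""
    return [
        compute_features(ctx, genome, pssms, motif_sets, conservation)
        for ctx in contexts
    ]


def feature_frame(
    rows: Iterable[Tuple[Variant, VariantContext, FeatureVector]]
) -> pd.DataFrame:
    """Tabulate (variant, context, vector) triples into a feature matrix."""
    records = []
    for v, ctx, fv in rows:
        rec = {
            "contig": v.contig,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "transcript": ctx.transcript.id,
            "region": ctx.region,
        }
        rec.update({n: fv[n] for n in FEATURE_NAMES})
        rec["gerp_missing"] = int(fv.gerp_missing)
        rec["cpg"] = fv.cpg
        records.append(rec)
    cols = ["contig", "pos", "ref", "alt", "transcript", "region"]
    return pd.DataFrame(records, columns=cols + list(FEATURE_NAMES) + ["gerp_missing", "cpg"])


class TrapAnnotator:
    """Convenience wrapper tying annotation resources to feature extraction.

    ``fit`` builds the splice-site PSSMs from the provided transcript models
    and genome; ``annotate`` maps each SNV into every harboring transcript
    and returns the feature matrix (one row per variant x transcript).
    """

    def __init__(self, motif_sets: Sequence[MotifSet] = (),
                 conservation: Optional[ConservationTrack] = None,
                 pseudocount: float = 1.0, bounds: str = "analytic"):
        self.motif_sets = list(motif_sets)
        self.conservation = conservation
        self.pseudocount = pseudocount
        self.bounds = bounds

    def fit(self, transcripts: Sequence["Transcript"], genome: Genome) -> "TrapAnnotator":
        from .pssm import build_pssms

        self.transcripts_ = list(transcripts)
        self.genome_ = genome
        self.pssms_ = build_pssms(
            self.transcripts_, genome, pseudocount=self.pseudocount, bounds=self.bounds
        )
        return self

    def annotate(self, variants: Sequence[Variant]) -> pd.DataFrame:
        from .io import locate_variant

        rows = []
        for v in variants:
            for ctx in locate_variant(v, self.transcripts_):
                fv = compute_features(
                    ctx, self.genome_, self.pssms_, self.motif_sets, self.conservation
                )
                rows.append((v, ctx, fv))
        return feature_frame(rows)
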