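"""Self-contained synthetic fixtures: mini-genomes with engineered splicing.

Generates multi-exon genes with G[T/C]–AG introns whose splice-site
strengths are tuned to target normalized scores, plants pre-formed cryptic
donor loci and regulatory-motif loci inside exon bodies, and emits labeled
variant sets in five classes:

* ``donor_disrupt`` / ``acceptor_disrupt`` — intronic window substitutions
  that weaken the annotated site by a graded, discrete magnitude;
* ``cryptic_create`` — exonic substitutions completing a GT donor core with
  consensus flanks (a strong cryptic 5'ss, normalized score > 84);
* ``esr_hit`` — exonic substitutions creating or destroying a planted
  regulatory hexamer;
* ``neutral`` — substitutions verified to change no splice window, core
  dinucleotide or motif membership.

A conservation track is elevated at functional elements except for a
configurable fraction left unelevated, emulating pathogenic variation at
non-conserved positions. Everything is deterministic per seed.

Toy motif hexamers are drawn over the {A,C} alphabet: they can never
contain a GT/AG core nor overlap splice-site consensus, keeping the feature
blocks of the variant classes orthogonal by construction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    Genome,
    MotifSet,
    Transcript,
    Variant,
    reverse_complement,
    write_annotation,
    write_conservation,
    write_fasta,
    write_motif_set,
    write_vcf,
)
from .pssm import (
    ACCEPTOR_K,
    DONOR_K,
    PSSM,
    build_pssms,
)

logger = logging.getLogger(__name__)

VARIANT_CLASSES = (
    "donor_disrupt",
    "acceptor_disrupt",
    "cryptic_create",
    "esr_hit",
    "neutral",
)

#: feature-block membership used by fixture manifests
FEATURE_BLOCKS = {
    "splice_delta": ("acc_delta", "don_delta"),
    "cryptic": ("cryptic5_score", "cryptic3_score", "cryptic5_lost", "cryptic3_lost"),
    "esr": ("esr_created", "esr_disrupted", "silencer_created", "silencer_disrupted"),
}

# donor window consensus (3 exonic + GT + 4 intronic) and per-position
# consensus probabilities loosely shaped like the human 5'ss
DONOR_CONSENSUS = "CAGGTAAGT"
DONOR_CORE_IDX = (3, 4)
# acceptor window consensus: 17-nt pyrimidine tract + C + AG + 3 exonic nt
ACCEPTOR_CONSENSUS = "T" * 17 + "CAG" + "GCT"
ACCEPTOR_CORE_IDX = (18, 19)

# pre-formed cryptic donor: consensus window with the core T knocked out;
# the A->T variant at window index 4 restores CAGGTAAGT exactly
CRYPTIC_PLANT = "CAGGAAAGT"
CRYPTIC_VARIANT_OFFSET = 4

SIGNAL_CLASS_BLOCKS = {
    "donor_disrupt": {"nonzero": ["don_delta"], "zero_blocks": ["cryptic", "esr"]},
    "acceptor_disrupt": {"nonzero": ["acc_delta"], "zero_blocks": ["cryptic", "esr"]},
    "cryptic_create": {"nonzero": ["cryptic5_score"], "zero_blocks": ["esr"]},
    "esr_hit": {"nonzero": [], "zero_blocks": ["splice_delta", "cryptic"]},
    "neutral": {"nonzero": [], "zero_blocks": ["splice_delta", "cryptic", "esr"]},
}

#: discrete target magnitudes (normalized score units) for graded
#: splice-site disruption levels
DISRUPT_DELTA_LEVELS = (2.0, 4.0, 6.0, 8.0, 10.0)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give 30 three-exon genes (alternating strand), 500 variants
    with a ~1:4 pathogenic:benign imbalance echoing a curated training set
    of 75 pathogenic vs 402 control variants, splice sites tuned to strong
    (85) or weak (60) normalized strengths, and a conservation track
    elevated by 3 score units at functional elements except for 20% of
    them, emulating pathogenic variation at non-conserved positions.
    """

    n_genes: int = 40
    exons_per_gene: int = 3
    exon_len: Tuple[int, int] = (60, 90)
    intron_len: Tuple[int, int] = (40, 70)
    flank_len: int = 30
    strong_site_score: float = 85.0
    weak_site_score: float = 60.0
    weak_site_fraction: float = 0.2
    gc_donor_fraction: float = 0.1
    n_variants: int = 500
    class_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "donor_disrupt": 0.06,
            "acceptor_disrupt": 0.05,
            "cryptic_create": 0.05,
            "esr_hit": 0.04,
            "neutral": 0.80,
        }
    )
    conservation_elevation: float = 3.0
    nonconserved_fraction: float = 0.2
    noise_sd: float = 1.0
    motif_set_size: int = 6
    site_tolerance: float = 4.0  # repair-loop convergence band, inside the
    # generator's +/-5 unit contract on site strengths
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class mix proportions must sum to 1")
        unknown = set(self.class_mix) - set(VARIANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown variant classes {sorted(unknown)}")
        if self.intron_len[0] < 26:
            raise ValueError("introns must be >= 26 nt so site windows never overlap")
        if self.exon_len[0] < 40:
            raise ValueError("exons must be >= 40 nt to host planted elements")
        if self.exons_per_gene < 2:
            raise ValueError("genes need >= 2 exons to have splice sites")


def _rng(seed: Optional[int], cfg: SimConfig, stream: int) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), stream])


# ---------------------------------------------------------------------------
# Motif sets
# ---------------------------------------------------------------------------


def generate_motif_sets(cfg: SimConfig, seed: Optional[int] = None) -> List[MotifSet]:
    """Four enhancer sets (SRSF1/2/5/6 stand-ins) + one silencer set.

    Hexamers are pairwise disjoint across sets and drawn over {A,C}, so they
    are disjoint from splice-site consensus sequences by construction.
    """
    rng = _rng(seed, cfg, 1)
    k = 6
    pool = ["".join(p) for p in itertools.product("AC", repeat=k)]
    # require both letters so a single substitution can toggle membership
    pool = [m for m in pool if "A" in m and "C" in m]
    need = 5 * cfg.motif_set_size
    if need > len(pool):
        raise SimulationError("motif_set_size too large for the {A,C} hexamer pool")
    chosen = rng.choice(len(pool), size=need, replace=False)
    names = ["SRSF1", "SRSF2", "SRSF5", "SRSF6", "silencer"]
    sets = []
    for i, name in enumerate(names):
        kmers = {
            pool[j]: round(float(rng.uniform(0.5, 2.0)), 3)
            for j in chosen[i * cfg.motif_set_size : (i + 1) * cfg.motif_set_size]
        }
        role = "silencer" if name == "silencer" else "enhancer"
        sets.append(MotifSet(name=name, kmers=kmers, role=role))
    return sets


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


@dataclass
class Plant:
    """A pre-placed functional element inside an exon body (t-coords)."""

    kind: str  # "cryptic" | "esr_create" | "esr_destroy"
    gene: int
    tstart: int
    tend: int  # inclusive
    variant_tpos: int
    ref_t: str
    alt_t: str
    motif: Optional[str] = None
    used: bool = False


@dataclass
class SiteSpec:
    """One annotated splice site with its target normalized strength.

    ``pref`` is a per-site shuffled (position, base) candidate order used by
    the strength-tuning loop, so sites weaken along different positions.
    """

    gene: int
    kind: str  # "donor" | "acceptor"
    window_tstart: int  # t-coord of window position 0
    target: float
    core: str
    pref: List[Tuple[int, str]] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    """A generated mini-genome plus the bookkeeping needed downstream."""

    cfg: SimConfig
    genome: Genome
    transcripts: List[Transcript]
    motif_sets: List[MotifSet]
    tseqs: List[List[str]]  # transcript-oriented per-gene sequence buffers
    strands: List[str]
    exon_tcoords: List[List[Tuple[int, int]]]  # per gene, 0-based inclusive
    sites: List[SiteSpec]
    plants: List[Plant]
    splice_window_tcoords: List[set]  # per gene

    def t_to_genomic(self, gene: int, tpos: int) -> int:
        L = len(self.tseqs[gene])
        return tpos + 1 if self.strands[gene] == "+" else L - tpos

    def contig(self, gene: int) -> str:
        return f"ctg{gene + 1}"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _sample_window(
    consensus: str, probs: Sequence[float], core_idx: Tuple[int, int],
    core: str, q_scale: float, rng: np.random.Generator,
) -> str:
    out = []
    for i, b in enumerate(consensus):
        if i in core_idx:
            out.append(core[i - core_idx[0]])
        elif rng.random() < min(0.98, probs[i] * q_scale):
            out.append(b)
        else:
            out.append(rng.choice([x for x in "ACGT" if x != b]))
    return "".join(out)


DONOR_PROBS = (0.35, 0.60, 0.80, 1.0, 1.0, 0.60, 0.72, 0.84, 0.50)
ACCEPTOR_PROBS = tuple([0.65] * 17 + [0.75, 1.0, 1.0, 0.50, 0.45, 0.45])


def generate_genome(cfg: SimConfig, seed: Optional[int] = None) -> SyntheticGenome:
    """Generate contigs, transcripts and planted elements; tune site strengths.

    Each gene occupies its own contig; strands alternate. After assembly a
    bounded repair loop rebuilds the PSSMs from the generated annotation and
    greedily edits non-core window bases until every annotated site scores
    within ``cfg.site_tolerance`` of its target.
    """
    rng = _rng(seed, cfg, 2)
    motif_sets = generate_motif_sets(cfg, seed)

    tseqs: List[List[str]] = []
    strands: List[str] = []
    exon_tcoords: List[List[Tuple[int, int]]] = []
    sites: List[SiteSpec] = []
    plants: List[Plant] = []
    window_sets: List[set] = []

    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1,
                                 size=cfg.exons_per_gene)
        intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1,
                                   size=cfg.exons_per_gene - 1)
        L = 2 * cfg.flank_len + int(exon_lens.sum()) + int(intron_lens.sum())
        seq = list(rng.choice(list("ACGT"), size=L))
        # exon layout in transcript orientation
        exons = []
        cur = cfg.flank_len
        for i, el in enumerate(exon_lens):
            exons.append((cur, cur + int(el) - 1))
            cur += int(el)
            if i < len(intron_lens):
                cur += int(intron_lens[i])
        # splice-site windows
        windows: set = set()
        for i in range(len(exons) - 1):
            ee = exons[i][1]
            es = exons[i + 1][0]
            weak = rng.random() < cfg.weak_site_fraction
            target = cfg.weak_site_score if weak else cfg.strong_site_score
            q = 0.7 if weak else 1.15
            don_core = "GC" if rng.random() < cfg.gc_donor_fraction else "GT"
            donor = _sample_window(DONOR_CONSENSUS, DONOR_PROBS, DONOR_CORE_IDX,
                                   don_core, q, rng)
            acceptor = _sample_window(ACCEPTOR_CONSENSUS, ACCEPTOR_PROBS,
                                      ACCEPTOR_CORE_IDX, "AG", q, rng)
            don_start = ee - 2
            acc_start = es - 20
            seq[don_start : don_start + DONOR_K] = list(donor)
            seq[acc_start : acc_start + ACCEPTOR_K] = list(acceptor)
            windows.update(range(don_start, don_start + DONOR_K))
            windows.update(range(acc_start, acc_start + ACCEPTOR_K))
            sites.append(SiteSpec(g, "donor", don_start, target, don_core,
                                  _candidate_order(DONOR_K, DONOR_CORE_IDX, rng)))
            sites.append(SiteSpec(g, "acceptor", acc_start, target, "AG",
                                  _candidate_order(ACCEPTOR_K, ACCEPTOR_CORE_IDX, rng)))
        # planted elements: cryptic donor in the middle exon, ESR loci in the
        # first and last exons
        mid = len(exons) // 2
        plants.append(_plant_cryptic(g, exons[mid], seq, rng))
        plants.append(_plant_esr(g, exons[0], seq, rng, motif_sets, create=True))
        plants.append(_plant_esr(g, exons[-1], seq, rng, motif_sets, create=False))

        tseqs.append(seq)
        strands.append(strand)
        exon_tcoords.append(exons)
        window_sets.append(windows)

    syn = SyntheticGenome(
        cfg=cfg, genome=None, transcripts=[], motif_sets=motif_sets,  # type: ignore[arg-type]
        tseqs=tseqs, strands=strands, exon_tcoords=exon_tcoords,
        sites=sites, plants=plants, splice_window_tcoords=window_sets,
    )
    _materialize(syn)
    _tune_site_strengths(syn)
    return syn


def _plant_cryptic(gene: int, exon: Tuple[int, int], seq: List[str],
                   rng: np.random.Generator) -> Plant:
    es, ee = exon
    lo, hi = es + 4, ee - 4 - len(CRYPTIC_PLANT) + 1
    start = int(rng.integers(lo, hi))
    seq[start : start + len(CRYPTIC_PLANT)] = list(CRYPTIC_PLANT)
    tpos = start + CRYPTIC_VARIANT_OFFSET
    return Plant(kind="cryptic", gene=gene, tstart=start,
                 tend=start + len(CRYPTIC_PLANT) - 1,
                 variant_tpos=tpos, ref_t="A", alt_t="T")


def _plant_esr(gene: int, exon: Tuple[int, int], seq: List[str],
               rng: np.random.Generator, motif_sets: List[MotifSet],
               create: bool) -> Plant:
    es, ee = exon
    enhancers = [m for m in motif_sets if m.role == "enhancer"]
    all_kmers = {k for m in motif_sets for k in m.kmers}
    k = enhancers[0].k
    for _ in range(200):
        ms = enhancers[int(rng.integers(len(enhancers)))]
        motif = list(ms.kmers)[int(rng.integers(len(ms.kmers)))]
        flip = int(rng.integers(k))
        other = "C" if motif[flip] == "A" else "A"
        near_miss = motif[:flip] + other + motif[flip + 1 :]
        if near_miss in all_kmers:
            continue
        planted = near_miss if create else motif
        # 1-nt {A,C} margins keep variant frames free of G/T
        block = "A" + planted + "A"
        lo, hi = es + 4, ee - 4 - len(block) + 1
        start = int(rng.integers(lo, hi))
        seq[start : start + len(block)] = list(block)
        tpos = start + 1 + flip
        ref_t = planted[flip]
        alt_t = motif[flip] if create else other
        return Plant(kind="esr_create" if create else "esr_destroy", gene=gene,
                     tstart=start, tend=start + len(block) - 1,
                     variant_tpos=tpos, ref_t=ref_t, alt_t=alt_t, motif=motif)
    raise SimulationError("could not place an ESR plant")  # pragma: no cover


def _materialize(syn: SyntheticGenome) -> None:
    """Rebuild the Genome and Transcript objects from the t-oriented buffers."""
    contigs = {}
    transcripts = []
    for g, seq in enumerate(syn.tseqs):
        t_oriented = "".join(seq)
        strand = syn.strands[g]
        contig_seq = t_oriented if strand == "+" else reverse_complement(t_oriented)
        name = syn.contig(g)
        contigs[name] = contig_seq
        exons_genomic = []
        for (ts, te) in syn.exon_tcoords[g]:
            gs, ge = syn.t_to_genomic(g, ts), syn.t_to_genomic(g, te)
            exons_genomic.append((min(gs, ge), max(gs, ge)))
        transcripts.append(
            Transcript(id=f"tx{g + 1}", gene_id=f"gene{g + 1}", contig=name,
                       strand=strand, exons=exons_genomic)
        )
    syn.genome = Genome(contigs)
    syn.transcripts = transcripts


def _window_len(kind: str) -> int:
    return DONOR_K if kind == "donor" else ACCEPTOR_K


def _core_range(kind: str) -> Tuple[int, int]:
    return DONOR_CORE_IDX if kind == "donor" else ACCEPTOR_CORE_IDX


def _candidate_order(K: int, core_idx: Tuple[int, int],
                     rng: np.random.Generator) -> List[Tuple[int, str]]:
    cands = [(pos, base) for pos in range(K) if pos not in core_idx
             for base in "ACGT"]
    order = rng.permutation(len(cands))
    return [cands[i] for i in order]


def _derive_window(pssm: PSSM, site: SiteSpec, band: float) -> str:
    """Deterministic window for one site under a frozen matrix.

    Anchors at the fixed design consensus (a stable anchor, unlike the
    matrix argmax, whose low-information positions flip between rebuilds)
    with the site's core dinucleotide in place, then walks the site's
    candidate order, accepting substitutions that lower the score without
    undershooting, until the normalized score sits within ``band`` of the
    target. Re-deriving from the anchor keeps windows canonical — exactly
    the deviations the target needs — so the tuning loop is a damped
    fixed-point iteration instead of an accumulating random walk.
    """
    c0, c1 = _core_range(site.kind)
    consensus = DONOR_CONSENSUS if site.kind == "donor" else ACCEPTOR_CONSENSUS
    motif = list(consensus)
    motif[c0], motif[c1] = site.core[0], site.core[1]
    window = "".join(motif)
    score = pssm.normalized_score(window)
    site.target = min(site.target, score - 0.25)
    for _ in range(2):  # two passes give fine-grained steps a second chance
        for pos, base in site.pref:
            if score <= site.target + band:
                return window
            if base == window[pos]:
                continue
            cand = window[:pos] + base + window[pos + 1 :]
            s2 = pssm.normalized_score(cand)
            if site.target - band <= s2 < score:
                window, score = cand, s2
    # granularity fallback: accept the error-minimizing edit even if it
    # lands slightly below the target band
    for _ in range(3):
        if abs(score - site.target) <= band:
            break
        best = None
        for pos, base in site.pref:
            if base == window[pos]:
                continue
            cand = window[:pos] + base + window[pos + 1 :]
            err = abs(pssm.normalized_score(cand) - site.target)
            if err < abs(score - site.target) - 1e-12 and (
                best is None or err < best[0]
            ):
                best = (err, cand)
        if best is None:
            break
        window = best[1]
        score = pssm.normalized_score(window)
    return window


def _exhaustive_donor_window(pssm: PSSM, site: SiteSpec) -> str:
    """Optimal donor window by enumerating all 4^7 non-core base choices.

    The donor motif is short enough to search outright; ties prefer fewer
    deviations from the design consensus, then alphabetical order, keeping
    the result deterministic.
    """
    c0, c1 = _core_range("donor")
    free = [i for i in range(DONOR_K) if i not in (c0, c1)]
    anchor = list(DONOR_CONSENSUS)
    anchor[c0], anchor[c1] = site.core[0], site.core[1]
    core_raw = pssm._log2[c0, "ACGT".index(site.core[0])] + pssm._log2[
        c1, "ACGT".index(site.core[1])
    ]
    span = pssm.max_raw - pssm.min_raw
    best = None
    for combo in itertools.product(range(4), repeat=len(free)):
        raw = core_raw + sum(pssm._log2[p, b] for p, b in zip(free, combo))
        score = min(100.0, max(0.0, 100.0 * (raw - pssm.min_raw) / span))
        err = abs(score - site.target)
        ndev = sum(1 for p, b in zip(free, combo) if "ACGT"[b] != anchor[p])
        key = (err, ndev, combo)
        if best is None or key < best[0]:
            best = (key, combo)
    window = anchor[:]
    for p, b in zip(free, best[1]):
        window[p] = "ACGT"[b]
    return "".join(window)


def _tune_site_strengths(syn: SyntheticGenome, max_rounds: int = 100) -> None:
    """Closed-loop tuning of site strengths against rebuilt PSSMs.

    Every edit shifts the matrices, which shifts every other site's
    normalized score, so the loop damps itself: the first rounds re-derive
    every off-target window, later rounds touch only the few worst sites so
    the count matrices can settle. The loop exits only from a verification
    pass in which the freshly rebuilt matrices score every in-place window
    within tolerance of its target — the same check the closed-loop tests
    repeat downstream.
    """
    tol = syn.cfg.site_tolerance
    for round_no in range(max_rounds):
        acc_pssm, don_pssm = build_pssms(syn.transcripts, syn.genome)
        residuals = []
        for site in syn.sites:
            pssm = don_pssm if site.kind == "donor" else acc_pssm
            seq = syn.tseqs[site.gene]
            w0 = site.window_tstart
            window = "".join(seq[w0 : w0 + _window_len(site.kind)])
            residuals.append(abs(pssm.normalized_score(window) - site.target))
        off = [i for i, r in enumerate(residuals) if r > tol]
        if round_no > 0 and not off:
            return  # verified against the matrices this very state induces
        off.sort(key=lambda i: residuals[i], reverse=True)
        if round_no >= 3:  # damp: touch only the worst offenders
            off = off[: max(1, len(off) // 4)]
        if round_no == 0:
            off = list(range(len(syn.sites)))
        for i in off:
            site = syn.sites[i]
            pssm = don_pssm if site.kind == "donor" else acc_pssm
            seq = syn.tseqs[site.gene]
            w0 = site.window_tstart
            current = "".join(seq[w0 : w0 + _window_len(site.kind)])
            derived = _derive_window(pssm, site, band=0.6 * tol)
            err = abs(pssm.normalized_score(derived) - site.target)
            if err > 0.6 * tol:
                if site.kind == "donor":
                    # short motif: solve the placement exactly
                    cand = _exhaustive_donor_window(pssm, site)
                    if abs(pssm.normalized_score(cand) - site.target) < err:
                        derived = cand
                elif derived == current:
                    # rotate the candidate order to leave the local optimum
                    for _ in range(len(site.pref) - 1):
                        site.pref = site.pref[1:] + site.pref[:1]
                        cand = _derive_window(pssm, site, band=0.6 * tol)
                        e2 = abs(pssm.normalized_score(cand) - site.target)
                        if e2 < err - 1e-9:
                            derived, err = cand, e2
                            if err <= 0.6 * tol:
                                break
            seq[w0 : w0 + len(derived)] = list(derived)
        _materialize(syn)
    raise SimulationError(
        f"site strength targets infeasible after {max_rounds} repair rounds"
    )


# ---------------------------------------------------------------------------
# Variant generation
# ---------------------------------------------------------------------------


def _frames_core_change(ref_local: str, alt_local: str, idx: int) -> bool:
    for f0 in (idx - 1, idx):
        if f0 < 0 or f0 + 2 > len(ref_local):
            continue
        rd, ad = ref_local[f0 : f0 + 2], alt_local[f0 : f0 + 2]
        if rd == ad:
            continue
        for core in ("GT", "AG"):
            if (rd == core) != (ad == core):
                return True
    return False


def _esr_membership_change(
    syn: SyntheticGenome, gene: int, tpos: int, alt_t: str
) -> bool:
    """Does the substitution toggle any motif k-mer inside its exon?"""
    exon = _containing_exon(syn, gene, tpos)
    if exon is None:
        return False
    es, ee = exon
    seq = syn.tseqs[gene]
    for ms in syn.motif_sets:
        k = ms.k
        lo = max(es, tpos - k + 1)
        hi = min(ee, tpos + k - 1)
        ref_win = "".join(seq[lo : hi + 1])
        rel = tpos - lo
        alt_win = ref_win[:rel] + alt_t + ref_win[rel + 1 :]
        for off in range(len(ref_win) - k + 1):
            if (ref_win[off : off + k] in ms) != (alt_win[off : off + k] in ms):
                return True
    return False


def _containing_exon(syn: SyntheticGenome, gene: int, tpos: int):
    for es, ee in syn.exon_tcoords[gene]:
        if es <= tpos <= ee:
            return es, ee
    return None


def _local(syn: SyntheticGenome, gene: int, tpos: int, alt_t: str,
           flank: int = 2) -> Tuple[str, str, int]:
    seq = syn.tseqs[gene]
    lo = max(0, tpos - flank)
    hi = min(len(seq) - 1, tpos + flank)
    ref_local = "".join(seq[lo : hi + 1])
    idx = tpos - lo
    alt_local = ref_local[:idx] + alt_t + ref_local[idx + 1 :]
    return ref_local, alt_local, idx


def _to_variant(syn: SyntheticGenome, gene: int, tpos: int, alt_t: str) -> Variant:
    seq = syn.tseqs[gene]
    strand = syn.strands[gene]
    pos = syn.t_to_genomic(gene, tpos)
    ref_t = seq[tpos]
    if strand == "+":
        return Variant(syn.contig(gene), pos, ref_t, alt_t)
    return Variant(syn.contig(gene), pos, _COMP[ref_t], _COMP[alt_t])


@dataclass
class TruthRecord:
    id: str
    variant: Variant
    cls: str
    magnitude: float
    pathogenic: int


def generate_variants(
    cfg: SimConfig, syn: SyntheticGenome, seed: Optional[int] = None
) -> Tuple[List[Variant], pd.DataFrame, Dict[str, dict]]:
    """Engineered variant set with truth table and expected-feature manifest.

    Returns (variants, truth table, manifest). The truth table has one row
    per variant (id, coordinates, class, engineered magnitude, pathogenic
    label); the manifest records which feature blocks each variant must and
    must not activate.
    """
    rng = _rng(seed, cfg, 3)
    acc_pssm, don_pssm = build_pssms(syn.transcripts, syn.genome)
    counts = _class_counts(cfg)
    used: set = set()
    records: List[TruthRecord] = []

    for cls in VARIANT_CLASSES:
        for j in range(counts[cls]):
            if cls == "donor_disrupt":
                rec = _make_disrupt(syn, rng, don_pssm, "donor", j, used)
            elif cls == "acceptor_disrupt":
                rec = _make_disrupt(syn, rng, acc_pssm, "acceptor", j, used)
            elif cls == "cryptic_create":
                rec = _make_cryptic(syn, rng, don_pssm, used)
            elif cls == "esr_hit":
                rec = _make_esr(syn, rng, j, used)
            else:
                rec = _make_neutral(syn, rng, used)
            records.append(rec)

    for i, r in enumerate(records):
        r.id = f"v{i}"
    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "contig": [r.variant.contig for r in records],
            "pos": [r.variant.pos for r in records],
            "ref": [r.variant.ref for r in records],
            "alt": [r.variant.alt for r in records],
            "class": [r.cls for r in records],
            "magnitude": [r.magnitude for r in records],
            "pathogenic": [r.pathogenic for r in records],
        }
    )
    manifest = {
        r.id: {
            "class": r.cls,
            "expected_nonzero": SIGNAL_CLASS_BLOCKS[r.cls]["nonzero"]
            + (["esr_created"] if r.cls == "esr_hit" and r.magnitude > 0 else [])
            + (["esr_disrupted"] if r.cls == "esr_hit" and r.magnitude < 0 else []),
            "expected_zero_blocks": SIGNAL_CLASS_BLOCKS[r.cls]["zero_blocks"],
        }
        for r in records
    }
    return [r.variant for r in records], truth, manifest


def _class_counts(cfg: SimConfig) -> Dict[str, int]:
    counts = {
        cls: int(round(cfg.class_mix.get(cls, 0.0) * cfg.n_variants))
        for cls in VARIANT_CLASSES
    }
    counts["neutral"] += cfg.n_variants - sum(counts.values())
    if counts["neutral"] < 0:
        raise SimulationError("class mix rounding produced a negative count")
    return counts


def _make_disrupt(syn, rng, pssm, kind, level_cycle, used) -> TruthRecord:
    """Weaken an annotated site by a graded discrete magnitude."""
    target = DISRUPT_DELTA_LEVELS[level_cycle % len(DISRUPT_DELTA_LEVELS)]
    span = pssm.max_raw - pssm.min_raw
    c0, c1 = _core_range(kind)
    candidates = [s for s in syn.sites if s.kind == kind]
    order = rng.permutation(len(candidates))
    # non-core window offsets; exonic ones additionally pass an
    # ESR-membership guard below so the splice block stays orthogonal
    offsets = [i for i in range(_window_len(kind)) if i not in (c0, c1)]
    exonic_offsets = set(range(3)) if kind == "donor" else set(range(20, 23))
    for si in order:
        site = candidates[si]
        seq = syn.tseqs[site.gene]
        w0 = site.window_tstart
        window = "".join(seq[w0 : w0 + _window_len(kind)])
        best = None
        for off in offsets:
            tpos = w0 + off
            key = (site.gene, tpos)
            ref_t = window[off]
            for alt_t in "ACGT":
                if alt_t == ref_t or key in used:
                    continue
                delta = (
                    100.0
                    * (pssm._log2[off, "ACGT".index(alt_t)]
                       - pssm._log2[off, "ACGT".index(ref_t)])
                    / span
                )
                if delta >= -0.5:  # must weaken the site
                    continue
                ref_local, alt_local, idx = _local(syn, site.gene, tpos, alt_t)
                if _frames_core_change(ref_local, alt_local, idx):
                    continue
                if off in exonic_offsets and _esr_membership_change(
                    syn, site.gene, tpos, alt_t
                ):
                    continue
                err = abs(-delta - target)
                if best is None or err < best[0]:
                    best = (err, tpos, alt_t, delta)
        if best is not None:
            _, tpos, alt_t, delta = best
            used.add((site.gene, tpos))
            v = _to_variant(syn, site.gene, tpos, alt_t)
            return TruthRecord("", v, f"{kind}_disrupt", float(-delta), 1)
    raise SimulationError(f"no placement left for a {kind}_disrupt variant")


def _make_cryptic(syn, rng, don_pssm, used) -> TruthRecord:
    plants = [p for p in syn.plants if p.kind == "cryptic" and not p.used]
    if not plants:
        raise SimulationError("ran out of cryptic plants; increase n_genes")
    p = plants[int(rng.integers(len(plants)))]
    p.used = True
    used.add((p.gene, p.variant_tpos))
    seq = syn.tseqs[p.gene]
    alt_window = "".join(seq[p.tstart : p.tend + 1])
    alt_window = (
        alt_window[: CRYPTIC_VARIANT_OFFSET] + p.alt_t
        + alt_window[CRYPTIC_VARIANT_OFFSET + 1 :]
    )
    magnitude = don_pssm.normalized_score(alt_window)
    v = _to_variant(syn, p.gene, p.variant_tpos, p.alt_t)
    return TruthRecord("", v, "cryptic_create", float(magnitude), 1)


def _make_esr(syn, rng, j, used) -> TruthRecord:
    want = "esr_create" if j % 2 == 0 else "esr_destroy"
    plants = [p for p in syn.plants if p.kind == want and not p.used]
    if not plants:  # fall back to the other subtype before giving up
        plants = [
            p for p in syn.plants
            if p.kind in ("esr_create", "esr_destroy") and not p.used
        ]
    if not plants:
        raise SimulationError("ran out of ESR plants; increase n_genes")
    p = plants[int(rng.integers(len(plants)))]
    p.used = True
    used.add((p.gene, p.variant_tpos))
    v = _to_variant(syn, p.gene, p.variant_tpos, p.alt_t)
    magnitude = 1.0 if p.kind == "esr_create" else -1.0
    return TruthRecord("", v, "esr_hit", magnitude, 1)


def _make_neutral(syn, rng, used) -> TruthRecord:
    plant_spans = {
        (p.gene, t) for p in syn.plants for t in range(p.tstart, p.tend + 1)
    }
    for _ in range(3000):
        gene = int(rng.integers(syn.cfg.n_genes))
        exons = syn.exon_tcoords[gene]
        span_lo, span_hi = exons[0][0], exons[-1][1]
        tpos = int(rng.integers(span_lo, span_hi + 1))
        key = (gene, tpos)
        if key in used or key in plant_spans:
            continue
        if tpos in syn.splice_window_tcoords[gene]:
            continue
        ref_t = syn.tseqs[gene][tpos]
        alt_t = str(rng.choice([b for b in "ACGT" if b != ref_t]))
        ref_local, alt_local, idx = _local(syn, gene, tpos, alt_t)
        if _frames_core_change(ref_local, alt_local, idx):
            continue
        if _esr_membership_change(syn, gene, tpos, alt_t):
            continue
        used.add(key)
        v = _to_variant(syn, gene, tpos, alt_t)
        return TruthRecord("", v, "neutral", 0.0, 0)
    raise SimulationError("could not place a neutral variant")  # pragma: no cover


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


def generate_conservation(
    cfg: SimConfig, syn: SyntheticGenome, seed: Optional[int] = None
) -> List[Tuple[str, int, float]]:
    """Per-position track: Normal(0, sd) noise, mean-shifted at functional
    elements except a ``nonconserved_fraction`` of them."""
    rng = _rng(seed, cfg, 4)
    elements: List[Tuple[int, range]] = []
    for site in syn.sites:
        elements.append(
            (site.gene, range(site.window_tstart,
                              site.window_tstart + _window_len(site.kind)))
        )
    for p in syn.plants:
        elements.append((p.gene, range(p.tstart, p.tend + 1)))
    elevated: set = set()
    for gene, rng_t in elements:
        if rng.random() < cfg.nonconserved_fraction:
            continue
        for t in rng_t:
            elevated.add((gene, syn.t_to_genomic(gene, t)))
    rows = []
    for g in range(cfg.n_genes):
        contig = syn.contig(g)
        L = len(syn.tseqs[g])
        noise = rng.normal(0.0, cfg.noise_sd, size=L)
        for pos in range(1, L + 1):
            score = noise[pos - 1]
            if (g, pos) in elevated:
                score += cfg.conservation_elevation
            rows.append((contig, pos, float(score)))
    return rows


def linked_maf(
    scores: Sequence[float], seed: int = 0, base: float = 0.05,
    slope: float = 0.045, noise_sd: float = 0.002,
) -> np.ndarray:
    """Minor allele frequencies linearly (negatively) linked to a score."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    maf = base - slope * scores + rng.normal(0.0, noise_sd, size=len(scores))
    return np.clip(maf, 1e-5, None)


# ---------------------------------------------------------------------------
# End-to-end fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    cfg: SimConfig
    outdir: Path
    fasta: Path
    gtf: Path
    vcf: Path
    conservation: Path
    motif_paths: Dict[str, Path]
    truth: Path
    manifest: Path
    syn: SyntheticGenome
    variants: List[Variant]
    truth_table: pd.DataFrame
    manifest_data: Dict[str, dict]


def end_to_end_fixture(
    cfg: SimConfig, outdir, seed: Optional[int] = None
) -> FixtureBundle:
    """Generate and write every file the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = generate_genome(cfg, seed)
    variants, truth, manifest = generate_variants(cfg, syn, seed)
    cons_rows = generate_conservation(cfg, syn, seed)

    fasta = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    vcf = outdir / "variants.vcf"
    cons = outdir / "conservation.tsv"
    truth_path = outdir / "truth.tsv"
    manifest_path = outdir / "manifest.json"
    write_fasta(syn.genome, fasta)
    write_annotation(syn.transcripts, gtf)
    write_vcf(variants, vcf,
              {n: len(s) for n, s in syn.genome.contigs.items()})
    write_conservation(cons_rows, cons)
    truth.to_csv(truth_path, sep="\t", index=False)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    motif_dir = outdir / "motifs"
    motif_dir.mkdir(exist_ok=True)
    motif_paths = {}
    for ms in syn.motif_sets:
        path = motif_dir / f"{ms.name}.txt"
        write_motif_set(ms, path)
        motif_paths[ms.name] = path
    return FixtureBundle(
        cfg=cfg, outdir=outdir, fasta=fasta, gtf=gtf, vcf=vcf,
        conservation=cons, motif_paths=motif_paths, truth=truth_path,
        manifest=manifest_path, syn=syn, variants=variants,
        truth_table=truth, manifest_data=manifest,
    )
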