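"""Shared fixtures: hand-built toy genes and the default synthetic bundle."""

import numpy as np
import pytest

from trapscore.features import FEATURE_NAMES, TrapAnnotator
from trapscore.io import ConservationTrack, Genome, MotifSet, Transcript
from trapscore.model import TrapClassifier
from trapscore.pssm import build_pssms
from trapscore.synthetic import (
    SimConfig,
    end_to_end_fixture,
    generate_conservation,
    generate_genome,
    generate_variants,
)

# ---------------------------------------------------------------------------
# Tiny training annotation with hand-specified splice windows
# ---------------------------------------------------------------------------

# (donor 9-mer: 3 exonic + GT/GC + 4 intronic, acceptor 23-mer: 18 + AG + 3)
TRAINING_WINDOWS = [
    ("CAGGTAAGT", "TTTTTTTTTTTTTTTTTCAGGCT"),
    ("CAGGTAAGT", "TTTTTTTTTTTTTTTTTCAGGCT"),
    ("AAGGTAAGT", "TTTTTTTTTCTTTTTTTCAGGCT"),
    ("CAGGTGAGT", "TTTTTCTTTTTTTTTTTCAGGTT"),
    ("CTGGTAAGT", "TTTTTTTTTTTTCTTTTCAGGCT"),
    ("CAGGTAAGA", "TCTTTTTTTTTTTTTTTCAGACT"),
    ("CAGGCAAGT", "TTTTTTTTTTTTTTTTCCAGGCT"),
    ("GAGGTAAGT", "TTTTTTTTTTTTTTTTTAAGGCT"),
    ("CAGGTACGT", "TTTTCTTTTTTTTTTTTCAGGCG"),
    ("CAAGTAAGT", "TTTTTTTTCTTTTTTTTCAGGCC"),
    ("CAGGTAAGT", "TTTTTTTTTTTTTTTTTCAGGCT"),
    ("CAGGTATGT", "TTTTTTTTTTTTTTGTTCAGGCT"),
]

FILLER = "ACGTTGCAACGTTGCAACGT"  # fixed background, no role in the tallies


def make_training_gene(idx, donor, acceptor):
    """Two-exon gene on its own contig embedding one intron's windows."""
    exon1 = FILLER[:17] + donor[:3]
    intron = donor[3:] + FILLER[:10] + acceptor[:20]
    exon2 = acceptor[20:] + FILLER[:17]
    contig = FILLER[:10] + exon1 + intron + exon2 + FILLER[:10]
    e1 = (11, 30)
    e2 = (11 + 20 + len(intron), 10 + 20 + len(intron) + 20)
    t = Transcript(id=f"train{idx}", gene_id=f"g{idx}", contig=f"train_ctg{idx}",
                   strand="+", exons=[e1, e2])
    return f"train_ctg{idx}", contig, t


@pytest.fixture(scope="session")
def toy_training():
    contigs, transcripts = {}, []
    for i, (don, acc) in enumerate(TRAINING_WINDOWS):
        name, seq, t = make_training_gene(i, don, acc)
        contigs[name] = seq
        transcripts.append(t)
    return Genome(contigs), transcripts


@pytest.fixture(scope="session")
def toy_pssms(toy_training):
    genome, transcripts = toy_training
    return build_pssms(transcripts, genome)


# ---------------------------------------------------------------------------
# A 3-exon toy gene (gene span 88 nt) for exhaustive feature checks
# ---------------------------------------------------------------------------

TOY_EXONS = [(31, 42), (69, 80), (107, 118)]  # 12-nt exons, 26-nt introns


def _toy_contig(seed=5):
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=150))
    for pos, base in ((43, "G"), (44, "T"), (67, "A"), (68, "G"),
                      (81, "G"), (82, "T"), (105, "A"), (106, "G")):
        seq[pos - 1] = base
    return "".join(str(b) for b in seq)


@pytest.fixture(scope="session")
def toy_gene():
    contig = _toy_contig()
    genome = Genome({"toy": contig})
    t = Transcript(id="toy_tx", gene_id="toy_gene", contig="toy",
                   strand="+", exons=list(TOY_EXONS))
    return genome, t


@pytest.fixture(scope="session")
def toy_motifs(toy_gene):
    """Motif sets seeded from the toy gene's own exon hexamers, so that many
    substitutions genuinely toggle membership."""
    genome, t = toy_gene
    hexamers = []
    for gs, ge in t.exons:
        exon = genome.fetch("toy", gs, ge)
        hexamers += [exon[i : i + 6] for i in range(0, len(exon) - 5, 3)]
    hexamers = list(dict.fromkeys(hexamers))
    # one-off variants of exon hexamers are reachable by a single SNV
    variants = [h[:2] + ("A" if h[2] != "A" else "C") + h[3:] for h in hexamers]
    enh1 = MotifSet("ENH1", {m: 1.0 for m in hexamers[:4]})
    enh2 = MotifSet("ENH2", {m: 1.0 for m in variants[:3]})
    sil = MotifSet("SIL", {m: 1.0 for m in (hexamers[4:6] + variants[3:5])},
                   role="silencer")
    return [enh1, enh2, sil]


@pytest.fixture(scope="session")
def toy_conservation(toy_gene):
    genome, _ = toy_gene
    rng = np.random.default_rng(11)
    n = len(genome.contigs["toy"])
    # every third position is absent, exercising the missing marker
    return ConservationTrack(
        {("toy", p): float(rng.normal(1.0, 2.0)) for p in range(1, n + 1) if p % 3}
    )


def mirror_gene(genome, t, variants=()):
    """Reverse-complement the contig and flip annotation/variants."""
    from trapscore.io import Variant, reverse_complement

    seq = genome.contigs[t.contig]
    L = len(seq)
    mirrored = Genome({t.contig: reverse_complement(seq)})
    flipped_exons = [(L + 1 - e, L + 1 - s) for s, e in t.exons]
    mt = Transcript(id=t.id, gene_id=t.gene_id, contig=t.contig,
                    strand="-" if t.strand == "+" else "+", exons=flipped_exons)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mvars = [
        Variant(v.contig, L + 1 - v.pos, comp[v.ref], comp[v.alt]) for v in variants
    ]
    return mirrored, mt, mvars


# ---------------------------------------------------------------------------
# Default synthetic bundle, annotated and modeled once per session
# ---------------------------------------------------------------------------

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return end_to_end_fixture(SimConfig(), outdir, seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def annotated_bundle(default_bundle):
    b = default_bundle
    rows = generate_conservation(b.cfg, b.syn, seed=BUNDLE_SEED)
    track = ConservationTrack({(c, p): s for c, p, s in rows})
    ann = TrapAnnotator(motif_sets=b.syn.motif_sets, conservation=track)
    ann.fit(b.syn.transcripts, b.syn.genome)
    table = ann.annotate(b.variants)
    merged = table.merge(b.truth_table, on=["contig", "pos", "ref", "alt"])
    assert len(merged) == len(table)
    return b, ann, merged


@pytest.fixture(scope="session")
def trained_model(annotated_bundle):
    _, _, merged = annotated_bundle
    X = merged[list(FEATURE_NAMES)]
    y = merged["pathogenic"].to_numpy(int)
    return TrapClassifier(random_state=BUNDLE_SEED).fit(X, y)
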