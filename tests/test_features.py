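"""Feature extraction: splice deltas, cryptic sites, ESR turnover, assembly."""

import pytest

from trapscore.features import (
    FEATURE_NAMES,
    STRONG_CRYPTIC_5SS,
    compute_features,
    cpg_feature,
    interaction_scores,
)
from trapscore.io import Genome, Transcript, Variant, locate_variant

from conftest import TOY_EXONS, mirror_gene
from feature_oracle import brute_force_features


def _matrix(pssm):
    return ([list(row) for row in pssm.freq], pssm.min_raw, pssm.max_raw)


def _all_snvs(genome, t):
    lo, hi = t.span
    seq = genome.contigs[t.contig]
    for pos in range(lo, hi + 1):
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                yield Variant(t.contig, pos, ref, alt)


def _oracle_kwargs(toy_pssms, toy_motifs, cons):
    acc, don = toy_pssms
    return dict(
        acc_matrix=_matrix(acc),
        don_matrix=_matrix(don),
        enhancer_sets=[set(m.kmers) for m in toy_motifs if m.role == "enhancer"],
        silencer_sets=[set(m.kmers) for m in toy_motifs if m.role == "silencer"],
        conservation=cons,
    )


class TestExhaustiveOracle:
    def test_every_snv_matches_brute_force(
        self, toy_gene, toy_pssms, toy_motifs, toy_conservation
    ):
        """All features of every possible SNV on the toy gene equal an
        independent full-rescan implementation."""
        genome, t = toy_gene
        cons = {p: toy_conservation.get("toy", p)
                for p in range(1, 151)
                if toy_conservation.get("toy", p) is not None}
        kwargs = _oracle_kwargs(toy_pssms, toy_motifs, cons)
        n_checked = 0
        for v in _all_snvs(genome, t):
            (ctx,) = locate_variant(v, [t])
            fv = compute_features(ctx, genome, toy_pssms, toy_motifs,
                                  toy_conservation)
            expected = brute_force_features(
                genome.contigs["toy"], sorted(t.exons), "+",
                v.pos, v.ref, v.alt, **kwargs,
            )
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(expected[name], abs=1e-9), (
                    f"{name} mismatch for {v}"
                )
            n_checked += 1
        assert n_checked == (TOY_EXONS[-1][1] - TOY_EXONS[0][0] + 1) * 3

    def test_strand_invariance(self, toy_gene, toy_pssms, toy_motifs):
        """A variant and its reverse-complement twin on the mirrored gene
        produce identical feature vectors."""
        genome, t = toy_gene
        variants = list(_all_snvs(genome, t))[::7]
        mg, mt, mvars = mirror_gene(genome, t, variants)
        for v, mv in zip(variants, mvars):
            (ctx,) = locate_variant(v, [t])
            (mctx,) = locate_variant(mv, [mt])
            fv = compute_features(ctx, genome, toy_pssms, toy_motifs)
            mfv = compute_features(mctx, mg, toy_pssms, toy_motifs)
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(mfv[name], abs=1e-9), name

    def test_allele_symmetry(self, toy_gene, toy_pssms, toy_motifs):
        """Swapping ref and alt swaps created/disrupted counts, lost/created
        cryptic scores and negates the splice deltas."""
        genome, t = toy_gene
        for v in list(_all_snvs(genome, t))[::5]:
            swapped_genome = genome.with_substitution(t.contig, v.pos, v.alt)
            vs = Variant(v.contig, v.pos, v.alt, v.ref)
            (ctx,) = locate_variant(v, [t])
            (ctx_s,) = locate_variant(vs, [t])
            a = compute_features(ctx, genome, toy_pssms, toy_motifs)
            b = compute_features(ctx_s, swapped_genome, toy_pssms, toy_motifs)
            assert a["esr_created"] == b["esr_disrupted"]
            assert a["esr_disrupted"] == b["esr_created"]
            assert a["silencer_created"] == b["silencer_disrupted"]
            assert a["acc_delta"] == pytest.approx(-b["acc_delta"], abs=1e-9)
            assert a["don_delta"] == pytest.approx(-b["don_delta"], abs=1e-9)
            assert a["cryptic5_score"] == pytest.approx(b["cryptic5_lost"], abs=1e-9)
            assert a["cryptic3_score"] == pytest.approx(b["cryptic3_lost"], abs=1e-9)


class TestSpliceBlocks:
    def test_donor_core_disruption_lowers_score(self, toy_gene, toy_pssms):
        genome, t = toy_gene
        v = Variant("toy", 44, "T", "A")  # intron 1 donor core GT -> GA
        (ctx,) = locate_variant(v, [t])
        fv = compute_features(ctx, genome, toy_pssms)
        assert fv["don_score_alt"] < fv["don_score_ref"]
        assert fv["don_delta"] < 0

    def test_mid_exon_variant_outside_windows_has_zero_deltas(
        self, toy_gene, toy_pssms
    ):
        genome, t = toy_gene
        pos = 74  # exon 2 interior: outside the 3-nt exonic window margins
        ref = genome.base("toy", pos)
        for alt in (b for b in "ACGT" if b != ref):
            v = Variant("toy", pos, ref, alt)
            (ctx,) = locate_variant(v, [t])
            assert ctx.region == "exonic"
            fv = compute_features(ctx, genome, toy_pssms)
            assert fv["acc_delta"] == 0 and fv["don_delta"] == 0

    def test_gating_no_core_change_means_zero_cryptic(self, toy_gene, toy_pssms):
        genome, t = toy_gene
        found = 0
        for v in _all_snvs(genome, t):
            (ctx,) = locate_variant(v, [t])
            fv = compute_features(ctx, genome, toy_pssms)
            seq = genome.contigs["toy"]
            alt_seq = seq[: v.pos - 1] + v.alt + seq[v.pos :]
            core_change = any(
                (seq[i : i + 2] in ("GT", "AG")) != (alt_seq[i : i + 2] in ("GT", "AG"))
                for i in (v.pos - 2, v.pos - 1)
            )
            if not core_change:
                found += 1
                for name in ("cryptic5_score", "cryptic3_score",
                             "cryptic5_lost", "cryptic3_lost"):
                    assert fv[name] == 0.0
        assert found > 50

    def test_interaction_score_definitions(self):
        base = {n: 0.0 for n in FEATURE_NAMES}
        # strong existing donor nullifies a cryptic competitor
        f = dict(base, cryptic5_score=90.0, don_score_ref=95.0)
        assert interaction_scores(f)["splice_site_overall"] == 0.0
        # weak existing donor exposes it
        f = dict(base, cryptic5_score=90.0, don_score_ref=60.0)
        assert interaction_scores(f)["splice_site_overall"] == 30.0
        # engineered weak donor at 55 with a cryptic at 88
        f = dict(base, cryptic5_score=88.0, don_score_ref=55.0)
        out = interaction_scores(f)
        assert out["splice_site_overall"] == 33.0
        assert out["variant_splice_score"] == 33.0

    def test_engineered_strong_cryptic_exceeds_threshold(self, default_bundle,
                                                         annotated_bundle):
        _, _, merged = annotated_bundle
        cc = merged[merged["class"] == "cryptic_create"]
        assert (cc["cryptic5_score"] > STRONG_CRYPTIC_5SS).all()


class TestEsrAndAssembly:
    def test_esr_counts_on_engineered_bundle(self, annotated_bundle):
        _, _, merged = annotated_bundle
        esr = merged[merged["class"] == "esr_hit"]
        assert ((esr["esr_created"] + esr["esr_disrupted"]) >= 1).all()
        created = esr[esr["magnitude"] > 0]
        assert (created["esr_created"] >= 1).all()
        assert (esr["combined_esr_score"]
                == esr["esr_created"] - esr["esr_disrupted"]
                - esr["silencer_created"] + esr["silencer_disrupted"]).all()
        assert (esr["negated_esr_score"]
                == -(esr["esr_created"] + esr["esr_disrupted"])).all()

    def test_intronic_variants_have_zero_esr_block(self, toy_gene, toy_pssms,
                                                   toy_motifs):
        genome, t = toy_gene
        pos = 90  # intron 2 interior
        ref = genome.base("toy", pos)
        v = Variant("toy", pos, ref, "A" if ref != "A" else "C")
        (ctx,) = locate_variant(v, [t])
        assert ctx.region == "intronic"
        fv = compute_features(ctx, genome, toy_pssms, toy_motifs)
        for n in ("esr_created", "esr_disrupted", "silencer_created",
                  "silencer_disrupted", "combined_esr_score",
                  "negated_esr_score"):
            assert fv[n] == 0.0

    def test_cpg_classification(self):
        g = Genome({"c": "ATCGAA"})
        assert cpg_feature(Variant("c", 4, "G", "T"), g) == "destroys_cpg"
        g2 = Genome({"c": "ATTGAA"})
        assert cpg_feature(Variant("c", 3, "T", "C"), g2) == "creates_cpg"
        g3 = Genome({"c": "TTATT"})
        assert cpg_feature(Variant("c", 3, "A", "T"), g3) == "none"

    def test_missing_conservation_imputed_with_flag(self, toy_gene, toy_pssms,
                                                    toy_conservation):
        genome, t = toy_gene
        pos = 72  # 72 % 3 == 0: absent from the toy track
        ref = genome.base("toy", pos)
        v = Variant("toy", pos, ref, "A" if ref != "A" else "C")
        (ctx,) = locate_variant(v, [t])
        fv = compute_features(ctx, genome, toy_pssms,
                              conservation=toy_conservation)
        assert fv["gerp_rs"] == 0.0 and fv.gerp_missing
        v2 = Variant("toy", 71, genome.base("toy", 71),
                     "A" if genome.base("toy", 71) != "A" else "C")
        (ctx2,) = locate_variant(v2, [t])
        fv2 = compute_features(ctx2, genome, toy_pssms,
                               conservation=toy_conservation)
        assert not fv2.gerp_missing
        assert fv2["gerp_rs"] == toy_conservation.get("toy", 71)
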