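"""Independent brute-force feature oracle used by the test suite.

Recomputes every feature for a variant-in-transcript from scratch, working
in transcript-oriented sequence space with plain string slicing and full
rescans of both alleles — no incremental logic, no imports from the package
under test. PSSMs enter as plain frequency matrices with their
normalization bounds.
"""

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = "ACGT"


def rc(s):
    return "".join(COMP[c] for c in reversed(s))


def _norm(freq, mn, mx, motif):
    raw = 0.0
    for i, b in enumerate(motif):
        raw += math.log2(freq[i][BASES.index(b)])
    return min(100.0, max(0.0, 100.0 * (raw - mn) / (mx - mn)))


def brute_force_features(
    contig_seq,
    exons,  # genomic (start, end), ascending, 1-based inclusive
    strand,
    pos,
    ref,
    alt,
    acc_matrix,  # (freq rows, min_raw, max_raw), K=23
    don_matrix,  # (freq rows, min_raw, max_raw), K=9
    enhancer_sets,  # list of sets of k-mers
    silencer_sets,
    conservation,  # dict (pos -> score), single contig
):
    assert contig_seq[pos - 1] == ref
    L = len(contig_seq)
    alt_seq = contig_seq[: pos - 1] + alt + contig_seq[pos:]

    # oriented space: index 0 is the transcript 5' end
    if strand == "+":
        T, Ta = contig_seq, alt_seq
        o = pos - 1
        oexons = [(s - 1, e - 1) for s, e in exons]
    else:
        T, Ta = rc(contig_seq), rc(alt_seq)
        o = L - pos
        oexons = [(L - e, L - s) for s, e in reversed(exons)]

    # harboring exon, else nearest (ties -> earlier in transcription order)
    exon_i, region = None, "intronic"
    for i, (s, e) in enumerate(oexons):
        if s <= o <= e:
            exon_i, region = i, "exonic"
            break
    if exon_i is None:
        best = None
        for i, (s, e) in enumerate(oexons):
            gap = min(abs(o - s), abs(o - e))
            if best is None or gap < best[0]:
                best = (gap, i)
        exon_i = best[1]
    es, ee = oexons[exon_i]

    dist_acc = o - es if exon_i > 0 else None
    dist_don = ee - o if exon_i < len(oexons) - 1 else None

    acc_freq, acc_mn, acc_mx = acc_matrix
    don_freq, don_mn, don_mx = don_matrix

    def window_scores(seq):
        accw = seq[es - 20 : es + 3] if exon_i > 0 else None
        donw = seq[ee - 2 : ee + 7] if exon_i < len(oexons) - 1 else None
        acc = _norm(acc_freq, acc_mn, acc_mx, accw) if accw and "N" not in accw else None
        don = _norm(don_freq, don_mn, don_mx, donw) if donw and "N" not in donw else None
        return acc, don

    acc_ref, don_ref = window_scores(T)
    acc_alt, don_alt = window_scores(Ta)
    f = {}
    f["acc_score_ref"] = acc_ref if acc_ref is not None else 0.0
    f["acc_score_alt"] = acc_alt if acc_alt is not None else f["acc_score_ref"]
    f["don_score_ref"] = don_ref if don_ref is not None else 0.0
    f["don_score_alt"] = don_alt if don_alt is not None else f["don_score_ref"]
    f["acc_delta"] = f["acc_score_alt"] - f["acc_score_ref"]
    f["don_delta"] = f["don_score_alt"] - f["don_score_ref"]

    # cryptic cores: full scan of both oriented alleles
    created5, created3, lost5, lost3 = [], [], [], []
    for i in range(len(T) - 1):
        rd, ad = T[i : i + 2], Ta[i : i + 2]
        if rd == ad:
            continue
        for core, windows, created, lost in (
            ("GT", (i - 3, i + 6), created5, lost5),
            ("AG", (i - 18, i + 5), created3, lost3),
        ):
            lo, hi = windows
            if lo < 0 or hi > len(T):
                continue
            if ad == core and rd != core:
                w = Ta[lo:hi]
                if "N" not in w:
                    m = (don_freq, don_mn, don_mx) if core == "GT" else (acc_freq, acc_mn, acc_mx)
                    created.append(_norm(*m, w))
            elif rd == core and ad != core:
                w = T[lo:hi]
                if "N" not in w:
                    m = (don_freq, don_mn, don_mx) if core == "GT" else (acc_freq, acc_mn, acc_mx)
                    lost.append(_norm(*m, w))
    f["cryptic5_score"] = max(created5, default=0.0)
    f["cryptic3_score"] = max(created3, default=0.0)
    f["cryptic5_lost"] = max(lost5, default=0.0)
    f["cryptic3_lost"] = max(lost3, default=0.0)

    f["splice_site_overall"] = max(
        0.0,
        f["cryptic5_score"] - f["don_score_ref"],
        f["cryptic3_score"] - f["acc_score_ref"],
    )
    f["variant_splice_score"] = max(
        f["splice_site_overall"],
        -f["acc_delta"],
        -f["don_delta"],
        f["cryptic5_lost"],
        f["cryptic3_lost"],
        0.0,
    )

    # ESR turnover: full-exon rescans of both alleles
    ec = ed = sc = sd = 0
    if region == "exonic":
        for sets, bucket in ((enhancer_sets, "e"), (silencer_sets, "s")):
            for kmers in sets:
                k = len(next(iter(kmers)))
                exon_ref = T[es : ee + 1]
                exon_alt = Ta[es : ee + 1]
                for off in range(len(exon_ref) - k + 1):
                    in_r = exon_ref[off : off + k] in kmers
                    in_a = exon_alt[off : off + k] in kmers
                    if in_a and not in_r:
                        if bucket == "e":
                            ec += 1
                        else:
                            sc += 1
                    elif in_r and not in_a:
                        if bucket == "e":
                            ed += 1
                        else:
                            sd += 1
    f["esr_created"] = float(ec)
    f["esr_disrupted"] = float(ed)
    f["silencer_created"] = float(sc)
    f["silencer_disrupted"] = float(sd)
    f["combined_esr_score"] = float(ec - ed - sc + sd)
    f["negated_esr_score"] = float(-(ec + ed))

    g = conservation.get(pos)
    f["gerp_rs"] = g if g is not None else 0.0
    dists = [abs(d) for d in (dist_acc, dist_don) if d is not None]
    f["dist_nearest_ss"] = float(min(dists)) if dists else 0.0
    return f
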