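"""Hand-built annotation helpers shared across test modules."""

from chromcycle import Gene, GenomeAnnotation, Interval


def mk_gene(gid, scaf, start, end, strand="+", exons=None,
            biotype="protein_coding"):
    iv = Interval(scaf, start, end, strand)
    if exons is None:
        exon_ivs = (iv,)
    else:
        exon_ivs = tuple(Interval(scaf, s, e, strand) for s, e in exons)
        if strand == "-":
            exon_ivs = exon_ivs[::-1]
    return Gene(gid, iv, strand, exon_ivs, biotype)


def mk_ann(scaffolds, genes=(), tes=()):
    return GenomeAnnotation(
        dict(scaffolds), list(genes),
        [Interval(s, a, b) for s, a, b in tes],
    )
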