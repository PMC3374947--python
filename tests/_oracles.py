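"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the implementation's coordinate machinery: the
consequence oracle rebuilds the full spliced CDS from the genome, applies
the variant, translates both alleles and compares the proteins.
"""

from Bio.Seq import Seq


def oracle_classify(variant, model, genome):
    """Classify an SNV by full-transcript reconstruction and translation."""
    g0 = variant.pos - 1
    if not (model.tx_start <= g0 < model.tx_end):
        return "intergenic"
    exonic = [(s, e) for s, e in zip(model.exon_starts, model.exon_ends) if s <= g0 < e]
    if not exonic:
        near = any(
            (0 < g0 - e + 1 <= 2) or (0 < s - g0 <= 2)
            for s, e in zip(model.exon_starts, model.exon_ends)
        )
        return "canonical_splice" if near else "intronic"
    chrom_seq = genome[model.chrom]
    spliced = "".join(chrom_seq[s:e] for s, e in zip(model.exon_starts, model.exon_ends))
    offsets = [p for s, e in zip(model.exon_starts, model.exon_ends) for p in range(s, e)]
    i = offsets.index(g0)
    alt_spliced = spliced[:i] + variant.alt + spliced[i + 1 :]
    cds_idx = [j for j, p in enumerate(offsets) if model.cds_start <= p < model.cds_end]
    lo, hi = cds_idx[0], cds_idx[-1] + 1
    if not (lo <= i < hi):
        before_cds = i < lo
        if model.strand == "+":
            return "utr5" if before_cds else "utr3"
        return "utr3" if before_cds else "utr5"
    cds_ref, cds_alt = spliced[lo:hi], alt_spliced[lo:hi]
    if model.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_alt = str(Seq(cds_alt).reverse_complement())
    prot_ref = str(Seq(cds_ref).translate())
    prot_alt = str(Seq(cds_alt).translate())
    if prot_ref == prot_alt:
        return "synonymous"
    diffs = [k for k, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if diffs and prot_alt[diffs[0]] == "*":
        return "stopgain"
    return "nonsynonymous"
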