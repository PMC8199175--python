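"""Published reference panel: the 13 lung oncofetal miRNAs.

The published study of fetal lung / LUAD small RNA transcriptomes reported
a 13-miRNA lung oncofetal panel together with each mature sequence's genomic
locus and a linear SVM score over the panel's log2(RPM) values. Both are
shipped here verbatim as reference artifacts: the locus strings in the
printed dialect (note the minus strand appears both as an ASCII hyphen and
as a Unicode minus sign, exactly as published), and the score's weight per
panel member.

Five of the 13 loci fall in the imprinted C14MC miRNA cluster at
chromosome band 14q32 (the DLK1-DIO3 locus); :data:`C14MC_REGION` is this
package's default boundary for that cluster, chosen to cover all five
chr14 panel loci.
"""

from __future__ import annotations

from .io_matrix import GenomicLocus, parse_locus

#: Genomic locus of each panel member, in the published string dialect.
PUBLISHED_PANEL_LOCI: dict[str, str] = {
    "hsa-miR-1290": "chr1−:18897078-18897096",
    "hsa-miR-1343": "chr11+:34941851-34941872",
    "hsa-miR-301b": "chr22+:21652990-21653011",
    "hsa-miR-3170": "chr13+:98208533-98208554",
    "hsa-miR-323b": "chr14+:101056233-101056255",
    "hsa-miR-329": "chr14+:101026797-101026819",
    "hsa-miR-380": "chr14+:101025021-101025042",
    "hsa-miR-433": "chr14+:100881897-100881918",
    "hsa-miR-4787": "chr3+:50675093-50675114",
    "hsa-miR-543": "chr14+:101032033-101032054",
    "hsa-miR-5684": "chr19+:12787132-12787151",
    "hsa-miR-627": "chr15-:42199630-42199651",
    "hsa-miR-6516": "chr17+:77089428-77089449",
}

#: Linear SVM score weights of the published panel classifier, in the
#: published panel order; features are log2(RPM) values (this package uses
#: log2(RPM+1) so that an absent miRNA contributes 0). No intercept was
#: published.
PUBLISHED_PANEL_WEIGHTS: dict[str, float] = {
    "hsa-miR-301b": 1.24,
    "hsa-miR-323b": 0.86,
    "hsa-miR-329": -0.47,
    "hsa-miR-380": -0.24,
    "hsa-miR-433": -0.42,
    "hsa-miR-543": -0.26,
    "hsa-miR-627": 0.01,
    "hsa-miR-6516": 1.12,
    "hsa-miR-1290": 0.44,
    "hsa-miR-1343": 0.34,
    "hsa-miR-3170": 1.01,
    "hsa-miR-4787": 0.97,
    "hsa-miR-5684": 0.02,
}

#: Default boundary of the C14MC imprinted miRNA cluster (hg38, band 14q32).
#: A config value, not hard-coded truth: the cluster has no single canonical
#: printed boundary.
C14MC_REGION = GenomicLocus("chr14", "+", 100_800_000, 101_100_000)


def published_panel_annotation() -> dict[str, GenomicLocus]:
    """Parsed loci of the published 13-miRNA panel."""
    return {m: parse_locus(s) for m, s in PUBLISHED_PANEL_LOCI.items()}
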