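"""Small curated C. elegans phenotype gene sets used in docs and tests.

These are complete published small gene sets from the WormBase-derived
phenotype annotations (locus tags with official symbols in parentheses
where available). They are tiny, fully enumerated, and convenient for
worked examples: e.g. ``neuron_morphology_variant`` (8 genes) and
``ectopic_neurite_outgrowth`` (6 genes) share exactly one gene,
C35C5.4(mig-2), so their overlap distance is 1 - 1/6.
"""

from __future__ import annotations

import io

from .genesets import GeneSetCollection, read_gmt

WORM_EXAMPLES_GMT = """\
neuron_function_reduced\tcurated\tF36F2.5(tax-2)\tF55A8.2(egl-4)\tK03A11.3(ceh-28)\tK03A11.8\tZC416.8(unc-17)\tZC84.2(tax-4)\tZK1290.18\tZK1290.2(tph-1)
neuron_morphology_variant\tcurated\tC10A4.8(mnm-2)\tC35C5.4(mig-2)\tC44B11.3(mec-12)\tF28D1.10(gex-3)\tK10G9.3(pad-2)\tT01E8.4\tY51H4A.3\tZK154.3(mec-7)
pheromone_induced_dauer_form._enhan\tcurated\tC38C3.5(unc-60)\tF02E8.6(ncr-1)\tF02E8.9\tF55A8.2(egl-4)\tT20B5.3(oga-1)\tY44A6D.4(sdf-9)\tY6B3B.11(hsd-1)
programmed_cell_death_variant\tcurated\tC07H6.7(lin-39)\tC09G4.1(hyl-1)\tF31E3.1(ceh-20)\tT07C4.8(ced-9)\tT12F5.4(lin-59)\tT28F12.2(unc-62)\tY6B3B.10(lag-1)
cell_division_slow\tcurated\tC26D10.1(ran-3)\tC29E4.3(ran-2)\tF26B1.3(ima-2)\tF28B3.8(imb-1)\tK01G5.4(ran-1)\tZK328.5(npp-10)
ectopic_neurite_outgrowth\tcurated\tB0285.5(hse-5)\tC35C5.4(mig-2)\tC39F7.2\tF41C6.1(unc-6)\tT19B4.7(unc-40)\tT24B8.6(hlh-3)
dauer_cuticle_variant\tcurated\tC47G2.1(cut-1)\tC47G2.15\tF22B5.3(cut-3)\tM142.2(cut-6)\tZC328.1
endosome_biogenesis_variant\tcurated\tF49E7.1(rme-6)\tF58G6.1(amph-1)\tW06B4.3(vps-18)\tY39A1A.5(rabx-5)\tY49E10.11(tat-1)
"""


def worm_example_collection() -> GeneSetCollection:
    """The curated small worm gene sets as a ready-made collection."""
    return read_gmt(io.StringIO(WORM_EXAMPLES_GMT), label="worm-examples")
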