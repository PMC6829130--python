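"""Published summary values for the Metrosideros polymorpha v2.0 genome.

These are the printed per-pseudomolecule sizes/gap fractions and the
repeat-space accounting of the public M. polymorpha assembly.  They are
inputs for re-totalling with the package's report operations (e.g. in
regression checks), not outputs of this package.

Note: the published RepeatMasker per-category rows sum to 8,156,877 bp,
which is the figure consistent with the published 2.88% of the assembly;
the separately printed RepeatMasker grand-total bp cell is not, so the
category sum is what is recorded here.
"""

from __future__ import annotations

import pandas as pd

# per-pseudomolecule size (bp) and gap percentage
MPOLYMORPHA_V2_MOLECULES: list[tuple[str, int, float]] = [
    ("Mpol_Chr01", 26_760_463, 2.5),
    ("Mpol_Chr02", 25_476_500, 2.9),
    ("Mpol_Chr03", 27_763_088, 3.8),
    ("Mpol_Chr04", 21_740_955, 2.7),
    ("Mpol_Chr05", 19_091_012, 4.9),
    ("Mpol_Chr06", 32_945_760, 2.8),
    ("Mpol_Chr07", 14_555_926, 3.4),
    ("Mpol_Chr08", 40_261_496, 3.4),
    ("Mpol_Chr09", 21_463_900, 2.8),
    ("Mpol_Chr10", 27_804_677, 2.4),
    ("Mpol_Chr11", 25_789_789, 3.5),
]

MPOLYMORPHA_V2_ASSEMBLY_BP = 283_653_566

# manual TE library: superfamily -> (n_families, n_elements, te_space_bp)
MPOLYMORPHA_MANUAL_TE_BP: dict[str, tuple[int, int, int]] = {
    "Gypsy": (19, 15_563, 6_978_439),
    "Copia": (24, 8_733, 6_258_363),
    "LTR_other": (2, 6_220, 2_659_321),      # LTR total minus Gypsy+Copia
    "Mutator": (4, 22_608, 3_564_813),
    "CACTA": (1, 348, 369_394),
    "hAT": (2, 1_396, 370_560),
    "unknown_TIR": (9, 16_461, 2_338_440),   # TIR total minus named rows
    "Helitron": (3, 2_344, 238_737),
}

MPOLYMORPHA_MANUAL_TE_TOTAL_BP = 22_778_067          # -> 8.03 %
MPOLYMORPHA_REPEATMASKER_TE_BP = 8_156_877           # category sum -> 2.88 %
MPOLYMORPHA_REPEATRUNNER_TE_PCT = 0.28
MPOLYMORPHA_TE_GENE_PCT = 0.20
MPOLYMORPHA_MULTI_SOURCE_OVERLAP_PCT = 0.09


def molecule_table() -> pd.DataFrame:
    return pd.DataFrame(MPOLYMORPHA_V2_MOLECULES,
                        columns=["molecule_id", "size_bp", "gap_pct"])
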