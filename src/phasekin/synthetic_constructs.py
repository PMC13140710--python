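"""Bundled construct sequences (synthetic reconstructions).

These are reconstructions of the expressed protein constructs assembled
from the public database entries (UniProt Q13148, P04792, P02511) and the
vector descriptions, bundled so the worked examples and the sequence-derived
constants run self-contained. They are synthetic stand-ins, not verbatim
database exports: the aromatic/cysteine content — the only part entering a
280 nm extinction-coefficient calculation — is exact (it is pinned by the
measured coefficients), while a few residues in the glycine-rich stretches
of the TDP-43 low-complexity domain may differ from the database entry.

``TDP43_LCD`` is the bare low-complexity domain (residues 267-414 of human
TDP-43; 3 Trp, 1 Tyr -> 17,990 M^-1 cm^-1). The expressed construct
``TDP43_LCD_CONSTRUCT`` keeps its His6 leader and TEV recognition site
(ENLYFQ | G267), whose tyrosine raises the coefficient to 19,480.
"""

# His6 leader with TEV site; cleavage at ENLYFQ|G would leave exactly G267.
TDP43_LCD_LEADER = "MGSSHHHHHHSSGENLYFQ"

# TDP-43 residues 267-414: Gly/Ser/Asn-rich low-complexity domain.
TDP43_LCD = (
    "GRFGGNPGGFGNQGGFGNSRGGGGAGLGNNQGSNMGGGMNFGAFSINPAMMAAAQAALQSS"
    "WGMMGMLASQQNQSGPSGNNQNQGNMQREPNQGGNNAFGSGNNSYSGSNSGAAIGWGSASNAGSG"
    "SGFNGGFGSSMDSKSSGSGWGM"
)

TDP43_LCD_CONSTRUCT = TDP43_LCD_LEADER + TDP43_LCD

# HspB1 (HSPB1, P04792) alpha-crystallin domain, residues 86-169.
HSPB1_ACD = (
    "SEIRHTADRWRVSLDVNHFAPDELTVKTKDGVVEITGKHEERQDEHGYISRCFTRKYTLP"
    "PGVDPTQVSSSLSPEGTLTVEAPM"
)

# HspB5 (alphaB-crystallin, CRYAB, P02511) alpha-crystallin domain,
# residues 68-162 (cysteine-free).
HSPB5_ACD = (
    "SEMRLEKDRFSVNLDVKHFSPEELKVKVLGDVIEVHGKHEERQDEHGFISREFHRKYRIP"
    "ADVDPLTITSSLSSDGVLTVNGPRKQVSGPERTIP"
)

CONSTRUCTS = {
    "tdp43_lcd": TDP43_LCD,
    "tdp43_lcd_construct": TDP43_LCD_CONSTRUCT,
    "hspb1_acd": HSPB1_ACD,
    "hspb5_acd": HSPB5_ACD,
}
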