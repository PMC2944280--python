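"""Published cross-database agreement cells used as arithmetic ground truth.

Each cell is (label, count_a, count_b, overlap, printed_pct): the two
per-database set sizes (genes or interacting gene pairs) for one pathway
compared across 2010-era snapshots of KEGG, Ingenuity and WikiPathways,
the overlap count, and the integer percentage printed alongside it. The
percentage convention is overlap divided by the smaller count, rounded
half-up. One printed gene cell (Complement and coagulation cascades,
KEGG x Wiki) is internally inconsistent — its overlap exceeds the
smaller set size, which no agreement arithmetic can produce — and is
kept separately as a corrupt-input case.
"""

# Apoptosis, manual extraction (three database pairings)
APOPTOSIS_MANUAL = [
    ("apoptosis KxI genes", 89, 169, 33, 37),
    ("apoptosis KxW genes", 89, 82, 38, 46),
    ("apoptosis IxW genes", 169, 82, 26, 32),
    ("apoptosis KxI pairs", 151, 3374, 21, 14),
    ("apoptosis KxW pairs", 151, 133, 21, 16),
    ("apoptosis IxW pairs", 3374, 133, 15, 11),
]

# Apoptosis, automated extraction
APOPTOSIS_AUTOMATED = [
    ("apoptosis-auto KxI genes", 84, 185, 28, 33),
    ("apoptosis-auto KxW genes", 84, 79, 36, 46),
    ("apoptosis-auto IxW genes", 185, 79, 24, 30),
    ("apoptosis-auto KxI pairs", 182, 3486, 22, 12),
    ("apoptosis-auto KxW pairs", 182, 155, 22, 14),
    ("apoptosis-auto IxW pairs", 3486, 155, 18, 12),
]

# KEGG x Ingenuity: (pathway, genes_a, genes_b, pairs_a, pairs_b,
#                    gene_overlap, gene_pct, pair_overlap, pair_pct)
KEGG_INGENUITY = [
    ("Apoptosis Signaling", 89, 169, 151, 3374, 33, 37, 21, 14),
    ("Axonal Guidance", 129, 213, 308, 1843, 85, 66, 159, 52),
    ("Calcium Signaling", 179, 51, 582, 202, 18, 35, 0, 0),
    ("Cell Cycle-G2M", 119, 13, 78, 18, 11, 85, 11, 61),
    ("Cell cycle", 119, 31, 78, 59, 26, 84, 6, 10),
    ("Fc epsilon RI signaling", 78, 75, 184, 225, 61, 81, 108, 59),
    ("JAK/Stat Signaling", 155, 144, 868, 3192, 42, 29, 88, 10),
    ("Actin Cytoskeleton Signaling", 217, 213, 672, 2297, 137, 64, 230, 34),
    ("T cell receptor Signaling", 94, 63, 175, 133, 41, 65, 39, 29),
    ("TGF-Beta Signaling", 87, 84, 155, 113, 12, 14, 5, 4),
    ("VEGF Signaling", 74, 69, 240, 167, 29, 42, 27, 16),
    ("Wnt Signaling", 152, 76, 778, 134, 33, 43, 11, 8),
]

# KEGG x Wiki (without the corrupt Complement gene cell; its pair cell
# is arithmetically fine and is retained)
KEGG_WIKI = [
    ("Apoptosis", 89, 82, 151, 133, 38, 46, 21, 16),
    ("Apoptosis Modulation by HSP70", 89, 18, 151, 33, 14, 78, 5, 15),
    ("Cell cycle", 119, 91, 78, 147, 76, 84, 35, 45),
    ("G1 to S cell cycle control", 119, 67, 78, 25, 45, 67, 1, 4),
    ("Focal Adhesion", 203, 188, 706, 288, 154, 82, 110, 38),
    ("Insulin Signaling", 138, 159, 412, 255, 66, 48, 13, 5),
    ("MAPK Cascade", 269, 31, 819, 55, 23, 74, 24, 44),
    ("Notch Signaling", 46, 46, 90, 98, 39, 85, 32, 36),
    ("Regulation of actin cytoskeleton", 217, 151, 672, 244, 133, 88, 113, 46),
    ("T Cell Receptor Signaling", 94, 135, 175, 261, 37, 39, 6, 3),
    ("TGF Beta Signaling", 87, 52, 155, 80, 23, 44, 6, 8),
    ("Tryptophan metabolism", 51, 94, 233, 33, 29, 57, 2, 6),
    ("Urea cycle", 28, 66, 69, 14, 13, 46, 1, 7),
    ("Wnt signaling", 152, 61, 778, 184, 49, 80, 34, 18),
]

# the valid pair cell of the Complement and coagulation cascades row
COMPLEMENT_PAIR_CELL = ("Complement pairs", 69, 107, 24, 35)

# the corrupt gene cell of the same row: overlap 52 > min(69, 31)
COMPLEMENT_INVALID_GENE_CELL = ("Complement genes", 69, 31, 52, 80)

# Ingenuity x Wiki
INGENUITY_WIKI = [
    ("Apoptosis", 169, 82, 3374, 133, 26, 32, 15, 11),
    ("Calcium Signaling", 51, 152, 202, 111, 14, 27, 0, 0),
    ("Cell Cycle", 13, 91, 18, 147, 7, 54, 5, 28),
    ("G1/S Check point Regulation", 31, 91, 59, 147, 24, 77, 10, 17),
    ("IL-4 Signaling", 21, 62, 21, 47, 8, 38, 1, 5),
    ("IL6 Signaling", 67, 100, 148, 121, 21, 31, 4, 3),
    ("Insulin Recpetor Signaling", 66, 159, 148, 255, 40, 61, 12, 8),
    ("TGF-Beta Signaling", 84, 52, 113, 80, 13, 25, 0, 0),
    ("p38 MAPK Signaling", 53, 34, 88, 35, 13, 38, 4, 11),
    ("T cell receptor Signaling", 63, 135, 133, 261, 25, 40, 3, 2),
    ("Wnt Signaling", 76, 61, 134, 184, 17, 28, 0, 0),
]


def iter_cells():
    """Every arithmetically valid (label, count_a, count_b, overlap, pct) cell."""
    yield from APOPTOSIS_MANUAL
    yield from APOPTOSIS_AUTOMATED
    for name, ga, gb, pa, pb, gov, gpct, pov, ppct in (
            KEGG_INGENUITY + KEGG_WIKI + INGENUITY_WIKI):
        yield (f"{name} genes", ga, gb, gov, gpct)
        yield (f"{name} pairs", pa, pb, pov, ppct)
    yield COMPLEMENT_PAIR_CELL


def iter_pairwise_rows():
    """Rows of the three pairwise tables (valid gene cells only)."""
    yield from KEGG_INGENUITY
    yield from KEGG_WIKI
    yield from INGENUITY_WIKI
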