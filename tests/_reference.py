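"""Frozen reference values from a published TCGA colon-adenocarcinoma cohort
analysis (471 tumors vs 41 normal controls), used as fixed inputs and
expected outputs for ranking, filtering, and set-algebra tests."""

# Top 20 upregulated genes: (symbol, log2 fold change, p-value)
TOP20_UP = [
    ("MAGEA3", 11.81, 0.0),
    ("MAGEA6", 10.71, 0.0),
    ("IGFL1", 10.60, 0.0),
    ("PRSS56", 10.55, 0.0),
    ("MAGEA12", 10.16, 0.0),
    ("KLK6", 9.74, 0.0),
    ("PAEP", 9.67, 0.0),
    ("NOTUM", 9.65, 0.0),
    ("PRR9", 9.51, 0.0),
    ("KLK8", 9.28, 0.0),
    ("SPRR2E", 9.21, 0.0),
    ("PPBP", 9.21, 0.0),
    ("SPRR1A", 9.10, 0.0),
    ("MAGEA1", 9.07, 1.58e-10),
    ("FEZF1", 8.99, 0.0),
    ("DKK4", 8.93, 0.0),
    ("ZIC5", 8.91, 3.71e-13),
    ("KLK7", 8.87, 0.0),
    ("CST1", 8.58, 0.0),
    ("SPRR2D", 8.52, 0.0),
]

# Top 20 downregulated genes: (symbol, log2 fold change, p-value)
TOP20_DOWN = [
    ("APOA4", -8.12, 0.0),
    ("OTOP2", -7.95, 0.0),
    ("APOC3", -7.84, 0.0),
    ("SLC10A2", -7.16, 0.0),
    ("APOA1", -7.10, 0.0),
    ("MS4A10", -7.07, 0.0),
    ("AQP8", -6.86, 0.0),
    ("CA1", -6.58, 0.0),
    ("APOB", -6.41, 0.0),
    ("INSL5", -6.14, 0.0),
    ("TMIGD1", -6.07, 0.0),
    ("GUCA2B", -6.06, 0.0),
    ("G6PC", -6.02, 0.0),
    ("CPO", -5.83, 0.0),
    ("KRTAP13-2", -5.75, 0.0),
    ("PYY", -5.74, 0.0),
    ("OTOP3", -5.73, 0.0),
    ("BEST4", -5.70, 0.0),
    ("SLC30A10", -5.57, 0.0),
    ("CLDN8", -5.55, 0.0),
]

# Top 10 perturbed KEGG pathways: (name, DEG overlap count, pathway size)
PATHWAY_TABLE = [
    ("Neuroactive ligand-receptor interaction", 29, 275),
    ("Systemic lupus erythematosus", 28, 126),
    ("Cytokine-cytokine receptor interaction", 27, 258),
    ("Pathways in cancer", 19, 329),
    ("Bile secretion", 18, 72),
    ("Wnt signaling pathway", 17, 140),
    ("Cell adhesion molecules", 17, 144),
    ("Metabolism of xenobiotics by cytochrome P450", 16, 73),
    ("Drug metabolism", 14, 67),
    ("Tight junction", 14, 135),
]

# Correlation-shifted pairs in the xenobiotic-metabolism pathway:
# (gene_a, gene_b, delta_cc)
XENOBIOTIC_PAIRS = [
    ("AKR1C4", "CYP3A4", -0.97),
    ("AKR1C4", "GSTA1", -0.95),
    ("AKR1C4", "GSTA2", -0.93),
    ("AKR1C4", "SULT2A1", -0.87),
    ("AKR1C4", "UGT1A1", -0.72),
    ("CYP3A4", "GSTA2", -0.99),
    ("CYP3A4", "SULT2A1", -0.96),
    ("GSTA1", "UGT1A1", -0.80),
    ("GSTA2", "UGT1A1", -0.80),
    ("GSTA2", "SULT2A1", -0.99),
    ("SULT2A1", "UGT1A1", -0.78),
]

XENOBIOTIC_PAIR_GENES = {"AKR1C4", "CYP3A4", "GSTA1", "GSTA2", "SULT2A1", "UGT1A1"}

# The 17 DEGs of the Wnt signaling pathway in the reference cohort
WNT_DEGS = [
    "AXIN2", "DKK1", "DKK4", "FOSL1", "FZD10", "MMP7", "NKD1", "NKD2",
    "PRKCG", "SFRP1", "SFRP4", "SFRP5", "WIF1", "WNT11", "WNT2", "WNT3", "WNT7B",
]
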