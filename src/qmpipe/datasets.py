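"""Bundled reference inputs: cohort intake records, taxon panel, copy numbers.

The delivery-record table reproduces the intake of a 144-infant Finnish birth
cohort (two merged sub-cohorts, HELMi and Jorvi) in which intrapartum
antibiotic use and birth mode were recorded per infant; a 92-infant subset
additionally has qPCR-quantified samples ("absolute data").  The taxon panel
is a genus-level summary of the dominant infant-gut lineages with mean 16S
rRNA gene copy numbers in the style of rrnDB.
"""

from __future__ import annotations

import pandas as pd

# (birth_mode, antibiotic, n_infants_relative_data, n_infants_absolute_data)
_DELIVERY_RECORDS = [
    ("VD", "none", 58, 26),
    ("VD", "penicillin", 25, 13),
    ("VD", "cefuroxime", 13, 7),
    ("elective CS", "cefuroxime", 13, 12),
    ("elective CS", "cephalexin", 7, 7),
    ("elective CS", "clindamycin", 1, 1),
    ("elective CS", "metronidazole", 1, 1),
    ("elective CS", "not_reported", 1, 1),
    ("emergency CS", "cefuroxime", 11, 11),
    ("emergency CS", "cephalexin", 3, 3),
    ("emergency CS", "clindamycin", 4, 4),
    ("emergency CS", "penicillin", 2, 1),
    ("emergency CS", "combination", 5, 5),
]


def delivery_record_counts() -> pd.DataFrame:
    """Intake table: infants per (birth mode, intrapartum antibiotic).

    Returns a frame with columns ``birth_mode``, ``antibiotic``, ``n`` (full
    cohort) and ``n_absolute`` (subset with qPCR-quantified samples).
    """
    return pd.DataFrame(
        _DELIVERY_RECORDS,
        columns=["birth_mode", "antibiotic", "n", "n_absolute"],
    )


def exposure_records(subset: str = "full") -> pd.DataFrame:
    """Expand the intake table into one row per infant.

    Parameters
    ----------
    subset:
        ``"full"`` for all 144 infants, ``"absolute"`` for the 92-infant
        qPCR-quantified subset.

    Returns a frame with columns ``infant_id``, ``birth_mode``,
    ``antibiotic``.
    """
    col = {"full": "n", "absolute": "n_absolute"}[subset]
    counts = delivery_record_counts()
    rows = []
    i = 0
    for _, rec in counts.iterrows():
        for _ in range(int(rec[col])):
            i += 1
            rows.append((f"I{i:03d}", rec["birth_mode"], rec["antibiotic"]))
    return pd.DataFrame(rows, columns=["infant_id", "birth_mode", "antibiotic"])


# Genus-level panel of dominant infant-gut taxa.
# columns: genus, family, order, class
_TAXON_PANEL = [
    ("Bifidobacterium", "Bifidobacteriaceae", "Bifidobacteriales", "Actinobacteria"),
    ("Collinsella", "Coriobacteriaceae", "Coriobacteriales", "Actinobacteria"),
    ("Actinomyces", "Actinomycetaceae", "Actinomycetales", "Actinobacteria"),
    ("Rothia", "Micrococcaceae", "Actinomycetales", "Actinobacteria"),
    ("Bacteroides", "Bacteroidaceae", "Bacteroidales", "Bacteroidia"),
    ("Parabacteroides", "Porphyromonadaceae", "Bacteroidales", "Bacteroidia"),
    ("Alistipes", "Rikenellaceae", "Bacteroidales", "Bacteroidia"),
    ("Paludibacter", "Porphyromonadaceae", "Bacteroidales", "Bacteroidia"),
    ("Staphylococcus", "Staphylococcaceae", "Bacillales", "Bacilli"),
    ("Streptococcus", "Streptococcaceae", "Lactobacillales", "Bacilli"),
    ("Enterococcus", "Enterococcaceae", "Lactobacillales", "Bacilli"),
    ("Lactobacillus", "Lactobacillaceae", "Lactobacillales", "Bacilli"),
    ("Blautia", "Lachnospiraceae", "Clostridiales", "Clostridia"),
    ("Roseburia", "Lachnospiraceae", "Clostridiales", "Clostridia"),
    ("Faecalibacterium", "Ruminococcaceae", "Clostridiales", "Clostridia"),
    ("Clostridium", "Clostridiaceae", "Clostridiales", "Clostridia"),
    ("Finegoldia", "Peptostreptococcaceae", "Clostridiales", "Clostridia"),
    ("Christensenella", "Christensenellaceae", "Clostridiales", "Clostridia"),
    ("Veillonella", "Veillonellaceae", "Selenomonadales", "Negativicutes"),
    ("Phascolarctobacterium", "Acidaminococcaceae", "Selenomonadales", "Negativicutes"),
    ("Escherichia", "Enterobacteriaceae", "Enterobacteriales", "Gammaproteobacteria"),
    ("Klebsiella", "Enterobacteriaceae", "Enterobacteriales", "Gammaproteobacteria"),
    ("Haemophilus", "Pasteurellaceae", "Pasteurellales", "Gammaproteobacteria"),
    ("Akkermansia", "Verrucomicrobiaceae", "Verrucomicrobiales", "Verrucomicrobiae"),
    # common reagent / low-biomass contaminant lineage
    ("Achromobacter", "Alcaligenaceae", "Burkholderiales", "Betaproteobacteria"),
]


def default_taxonomy() -> pd.DataFrame:
    """Genus-indexed lineage table with columns family/order/class."""
    df = pd.DataFrame(
        _TAXON_PANEL, columns=["genus", "family", "order", "class"]
    ).set_index("genus")
    return df


# rrnDB-style mean 16S copy numbers; order-level anchors 3.5 and 5.5 for
# Bifidobacteriales and Clostridiales, genus/family refinements elsewhere.
_COPY_NUMBERS = [
    ("Bifidobacteriales", "order", 3.5),
    ("Clostridiales", "order", 5.5),
    ("Coriobacteriales", "order", 2.5),
    ("Actinomycetales", "order", 3.0),
    ("Bacteroidales", "order", 4.5),
    ("Bacteroides", "genus", 5.0),
    ("Bacillales", "order", 5.5),
    ("Lactobacillales", "order", 5.0),
    ("Selenomonadales", "order", 5.5),
    ("Enterobacteriaceae", "family", 7.0),
    ("Pasteurellales", "order", 6.0),
    ("Verrucomicrobiales", "order", 2.5),
    ("Burkholderiales", "order", 4.0),
]


def default_copy_numbers() -> pd.DataFrame:
    """Copy-number table with columns ``name``, ``rank``, ``mean16S``."""
    return pd.DataFrame(_COPY_NUMBERS, columns=["name", "rank", "mean16S"])
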