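"""Small bundled example data: the Bahia dung-beetle habitat-use table.

A published survey of ten Atlantic Forest landscapes in Bahia (Brazil)
recorded 7,673 dung-beetle individuals of 42 species along a 5-55% forest
cover gradient; 20 of the 42 species could not be assigned a habitat-use
category and were excluded from the response analysis.  The table below
lists the classified species with their capture totals, their
literature-derived label, their empirical (IndVal-based) label, and the
reconciled final category — the canonical worked example for the
classification logic in :mod:`ecothresh.classification`.
"""

from __future__ import annotations

import pandas as pd

#: (species, N individuals, literature label, empirical label, final label)
BAHIA_HABITAT_USE = [
    ("Ateuchus oblongus", 2553, "FS", "FS", "FS"),
    ("Canthidium punctatostriatum", 30, "II", "FS", "FS"),
    ("Canthidium sp. 7", 28, "II", "G", "G"),
    ("Canthon curvodilatatus", 56, "OS", "OS", "OS"),
    ("Canthon nigripennis", 7, "G", "II", "G"),
    ("Canthon septemmaculatus histrio", 4, "G", "II", "G"),
    ("Canthon staigi", 36, "G", "G", "G"),
    ("Canthonella barrerai", 43, "FS", "FS", "FS"),
    ("Coprophanaeus acrisius", 13, "G", "II", "G"),
    ("Coprophanaeus dardanus", 11, "FS", "II", "FS"),
    ("Deltochilum brasiliense", 12, "FS", "II", "FS"),
    ("Deltochilum calcaratum", 48, "FS", "FS", "FS"),
    ("Dichotomius ascanius", 2, "G", "II", "G"),
    ("Dichotomius bos", 2, "G", "II", "G"),
    ("Dichotomius nisus", 11, "G", "II", "G"),
    ("Dichotomius semisquamosus", 10, "G", "II", "G"),
    ("Dichotomius sp. aff. fissus", 355, "II", "FS", "FS"),
    ("Dichotomius sp. aff. sericeus", 4357, "II", "FS", "FS"),
    ("Digitonthophagus gazella", 7, "OS", "II", "OS"),
    ("Ontherus appendiculatus", 21, "G", "G", "G"),
    ("Trichillum externepunctatum", 4, "G", "II", "G"),
]

#: survey-wide totals as published
BAHIA_TOTAL_INDIVIDUALS = 7673
BAHIA_TOTAL_SPECIES = 42
BAHIA_EXCLUDED_SPECIES = 20


def load_bahia_habitat_use() -> pd.DataFrame:
    """The Bahia habitat-use classification table as a DataFrame."""
    return pd.DataFrame(
        BAHIA_HABITAT_USE,
        columns=["species", "N", "literature", "empirical", "final"],
    )
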