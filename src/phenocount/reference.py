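"""Published flight-period parameter estimates for a montane butterfly community.

Selected-model estimates for the 10 univoltine butterfly species of a
10-year (2004–2013) transect study at 20 sites spanning 930–2,050 m in
the Sierra de Guadarrama (central Spain): peak day-of-year at the mean
site elevation (``d_star``), the Gaussian flight-period standard
deviation in days (``s_d``), the selected elevation form for the peak day
with its coefficients (``h1``, ``h2``; NaN when inactive), and whether
each yearly effect group was supported.  These values serve as realistic
defaults for the synthetic-data generator and as inputs to in-table
arithmetic (e.g. flight-window widths).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["species_parameters"]

_ROWS = [
    # species, d_star, s_d, elevation_form, h1, h2, year_peak, year_duration, year_abundance
    ("Fabriciana niobe",      185.2, 14.2, "quadratic", 0.0287,  0.0130, True, False, True),
    ("Hesperia comma",        224.6, 12.3, "linear",    0.0254,  None,   True, True,  True),
    ("Hipparchia hermione",   221.8, 16.4, "constant",  None,    None,   True, True,  False),
    ("Hipparchia statilinus", 241.4, 17.2, "linear",    0.0163,  None,   True, True,  True),
    ("Hyponephele lycaon",    219.7, 13.1, "quadratic", 0.0315, -0.0158, True, True,  True),
    ("Lycaena alciphron",     199.8, 17.1, "quadratic", 0.0368, -0.0247, True, False, True),
    ("Lycaena virgaureae",    214.5, 14.0, "quadratic", 0.0371, -0.0237, True, False, True),
    ("Melanargia lachesis",   201.5, 11.9, "linear",    0.0363,  None,   True, True,  True),
    ("Pyronia tithonus",      223.4, 12.9, "linear",    0.0352,  None,   True, False, True),
    ("Speyeria aglaja",       195.4, 12.4, "linear",    0.0535,  None,   True, False, True),
]


def species_parameters() -> pd.DataFrame:
    """Reference parameter table, one row per species."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "species",
            "d_star",
            "s_d",
            "elevation_form",
            "h1",
            "h2",
            "year_peak",
            "year_duration",
            "year_abundance",
        ],
    )
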