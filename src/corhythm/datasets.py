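"""Small built-in reference tables used in worked examples and tests.

``conserved_clock_peaks`` is a reported peak-time table for six
canonical clock transcripts in the mouse medial prefrontal cortex and
two human prefrontal subregions (DLPFC, ACC), stratified by sex. Units
are hours after the species' circadian reference: lights-on (ZT0) for
mouse, sunrise for human. It is the standard worked input for the
phase-difference machinery: human peak minus mouse peak, per gene, sex
and subregion.
"""

from __future__ import annotations

import pandas as pd

CLOCK_PANEL = ("PER1", "PER2", "PER3", "DBP", "CIART", "NR1D1")

_MOUSE_PEAKS = {
    #        M      F
    "PER1": (14.5, 15.2),
    "PER2": (18.5, 17.1),
    "PER3": (17.9, 17.8),
    "DBP": (15.0, 13.5),
    "CIART": (13.6, 12.5),
    "NR1D1": (11.0, 12.5),
}

_HUMAN_PEAKS = {
    #        DLPFC M  ACC M  DLPFC F  ACC F
    "PER1": (3.8, 5.0, 5.8, 6.5),
    "PER2": (6.6, 6.1, 9.0, 7.9),
    "PER3": (5.6, 5.4, 6.2, 5.5),
    "DBP": (3.5, 2.9, 4.1, 4.9),
    "CIART": (3.0, 2.2, 2.9, 3.8),
    "NR1D1": (3.9, 3.6, 2.8, 4.3),
}


def conserved_clock_peaks() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference peak times for the six-gene conserved clock panel.

    Returns
    -------
    mouse : DataFrame indexed by gene with columns ``M``, ``F`` —
        mPFC peak times (h after ZT0).
    human : DataFrame indexed by gene with MultiIndex columns
        (region, sex) for regions DLPFC/ACC — peak times (h after
        sunrise).
    """
    mouse = pd.DataFrame(_MOUSE_PEAKS, index=["M", "F"]).T
    mouse.index.name = "gene_id"
    cols = pd.MultiIndex.from_tuples(
        [("DLPFC", "M"), ("ACC", "M"), ("DLPFC", "F"), ("ACC", "F")],
        names=["region", "sex"],
    )
    human = pd.DataFrame(_HUMAN_PEAKS, index=cols).T
    human.index.name = "gene_id"
    return mouse, human
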