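"""Published reference values from the Chlamydomonas *lpa2* complexome study.

The *lpa2* complexome-profiling dataset (ProteomeXchange accession
PXD023443) compared thylakoid membrane complexes of a *Chlamydomonas
reinhardtii* *lpa2* mutant against wild type on 36-slice BN-PAGE lanes,
three biological replicates each.  The study's published per-subunit
abundance ratios (mutant/wild-type, from summed ion intensities pooled
over replicates) are embedded here as reference data so that the reported
per-complex medians can be recomputed and checked without downloading the
raw deposit.

``WHOLE_LANE_RATIOS`` holds the whole-lane ratios per complex/subunit
family; ``PSII_BAND_RATIOS`` holds the PSII-core ratios resolved by
assembly-state band (supercomplexes = band 4, dimers = 10, monomers = 15,
RC47 = 17), with ``None`` marking subunits not detected in a band.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["WHOLE_LANE_RATIOS", "PSII_BAND_RATIOS", "STUDY_BANDS",
           "whole_lane_frame", "psii_band_frame"]

# mutant/wild-type whole-lane abundance ratios, one entry per subunit
WHOLE_LANE_RATIOS: dict[str, dict[str, float]] = {
    "ATP synthase": {
        "AtpA": 1.27, "AtpB": 1.30, "ATPC": 1.28, "ATPD": 1.08,
        "AtpE": 1.52, "AtpF": 1.52, "ATPG": 1.28, "AtpI": 1.72,
    },
    "Cytochrome b6f": {
        "PetA": 1.01, "PetB": 0.93, "PETC": 1.09, "PetD": 0.68,
        "PETM": 1.52, "PETO": 0.96,
    },
    "PSII core": {
        "PsbA": 0.29, "PsbB": 0.29, "PsbC": 0.23, "PsbD": 0.30,
        "PsbE": 0.49, "PsbF": 0.55, "PsbH": 0.67, "PsbJ": 2.17,
        "PsbL": 0.84, "PBA1": 0.94,
    },
    "OEC": {
        "PSBO": 0.55, "PSBP1": 0.61, "PSBP2": 0.46, "PSBP3": 1.08,
        "PSBP4": 0.81, "PSBP6": 0.61, "PSBQ": 0.54, "PSBR": 0.50,
    },
    "LHCII": {
        "LHCB4": 1.20, "LHCB5": 1.45, "LHCB7": 1.79, "LHCBM1": 1.41,
        "LHCBM3": 1.25, "LHCBM5": 1.27, "LHCBM6": 1.27, "LHCBM8": 1.20,
        "LHCBM9": 0.94,
    },
    "PSI core": {
        "PsaA": 0.93, "PsaB": 0.71, "PsaC": 0.88, "PSAD": 1.06,
        "PSAE": 1.15, "PSAF": 1.03, "PSAG": 0.70, "PSAH": 1.04,
        "PsaJ": 0.92, "PSAK": 1.35, "PSAL": 0.82, "PSAN": 1.25,
    },
    "LHCA": {
        "LHCA1": 1.10, "LHCA2": 1.19, "LHCA3": 0.88, "LHCA4": 0.96,
        "LHCA5": 1.04, "LHCA6": 1.16, "LHCA7": 1.03, "LHCA8": 1.10,
        "LHCA9": 1.25,
    },
}

# PSII-core ratios per assembly-state band; None = not detected in band
PSII_BAND_RATIOS: dict[str, dict[str, float | None]] = {
    "SC": {
        "PsbA": 0.06, "PsbB": 0.07, "PsbC": 0.07, "PsbD": 0.07, "PsbE": 0.09,
        "PsbF": 0.07, "PsbJ": 0.11, "PsbL": 0.05, "PBA1": 0.10,
    },
    "dimer": {
        "PsbA": 0.27, "PsbB": 0.25, "PsbC": 0.29, "PsbD": 0.32, "PsbE": 0.27,
        "PsbF": 0.19, "PsbJ": 0.15, "PsbL": 0.37, "PBA1": 0.14,
    },
    "monomer": {
        "PsbA": 0.54, "PsbB": 0.67, "PsbC": 0.60, "PsbD": 0.54, "PsbE": 0.64,
        "PsbF": 0.78, "PsbJ": 0.48, "PsbL": 1.46, "PBA1": 0.30,
    },
    "RC47": {
        "PsbA": 4.84, "PsbB": 4.81, "PsbC": None, "PsbD": 5.60, "PsbE": 6.05,
        "PsbF": 6.55, "PsbJ": None, "PsbL": 9.67, "PBA1": 6.28,
    },
}

# band label -> gel slice index in the study's 36-slice lane
STUDY_BANDS: dict[str, int] = {"SC": 4, "dimer": 10, "monomer": 15, "RC47": 17}


def whole_lane_frame() -> pd.DataFrame:
    """Whole-lane ratios as a tidy frame: complex, protein, ratio."""
    rows = [{"complex": cx, "protein": p, "ratio": r}
            for cx, members in WHOLE_LANE_RATIOS.items()
            for p, r in members.items()]
    return pd.DataFrame(rows)


def psii_band_frame() -> pd.DataFrame:
    """Band-resolved PSII ratios as a tidy frame: band, protein, ratio
    (NaN where not detected)."""
    rows = [{"band": band, "protein": p,
             "ratio": float("nan") if r is None else r}
            for band, members in PSII_BAND_RATIOS.items()
            for p, r in members.items()]
    return pd.DataFrame(rows)
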