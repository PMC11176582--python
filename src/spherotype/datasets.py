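"""Bundled reference datasets.

``reference_response_distances`` is the published distance-from-control
table of a four-line, two-day, five-concentration 5-FU spheroid screen
(one mean PC-space distance per cell line, viability day and
concentration).  It is used to calibrate and regression-test the quartile
classification convention: under linear-interpolation quantiles its pooled
25th/75th percentiles are 0.432 and 1.365, splitting the 40 values
10 low / 20 intermediate / 10 high.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_response_distances"]

_CONCENTRATIONS = (0.25, 0.5, 1.0, 4.0, 16.0)

_DISTANCES = {
    ("HCT116", 4): (0.122, 0.725, 1.007, 1.464, 2.137),
    ("HCT116", 18): (0.724, 0.747, 0.598, 1.465, 4.222),
    ("SW948", 4): (0.312, 0.903, 0.592, 0.265, 1.539),
    ("SW948", 18): (0.812, 1.560, 1.317, 1.516, 3.440),
    ("Panc1", 4): (0.401, 0.630, 0.433, 0.863, 1.957),
    ("Panc1", 18): (0.430, 0.630, 0.574, 1.880, 1.332),
    ("MIA-Pa-Ca-2", 4): (0.263, 0.191, 0.419, 0.415, 1.065),
    ("MIA-Pa-Ca-2", 18): (0.787, 1.056, 0.705, 1.134, 0.268),
}

# Expected classes under the bundled table's own typographic key.
_EXPECTED_CLASSES = {
    ("HCT116", 4): ("low", "intermediate", "intermediate", "high", "high"),
    ("HCT116", 18): ("intermediate", "intermediate", "intermediate", "high", "high"),
    ("SW948", 4): ("low", "intermediate", "intermediate", "low", "high"),
    ("SW948", 18): ("intermediate", "high", "intermediate", "high", "high"),
    ("Panc1", 4): ("low", "intermediate", "intermediate", "intermediate", "high"),
    ("Panc1", 18): ("low", "intermediate", "intermediate", "high", "intermediate"),
    ("MIA-Pa-Ca-2", 4): ("low", "low", "low", "low", "intermediate"),
    ("MIA-Pa-Ca-2", 18): ("intermediate", "intermediate", "intermediate",
                          "intermediate", "low"),
}


def reference_response_distances(with_expected_classes: bool = False
                                 ) -> pd.DataFrame:
    """Tidy table: cell_line, day, concentration_ug_ml, distance
    (optionally the published class per row)."""
    rows = []
    for (line, day), values in _DISTANCES.items():
        for conc, d in zip(_CONCENTRATIONS, values):
            row = {"cell_line": line, "day": day,
                   "concentration_ug_ml": conc, "distance": d}
            if with_expected_classes:
                row["expected_class"] = _EXPECTED_CLASSES[(line, day)][
                    _CONCENTRATIONS.index(conc)
                ]
            rows.append(row)
    return pd.DataFrame(rows)
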