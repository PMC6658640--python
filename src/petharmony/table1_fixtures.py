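"""Published 4x4 Deauville cross-tabulations of the three-reconstruction
lymphoma study (54 examinations), embedded as reference fixtures.

Six panels: SUVmax-based scores (A: QC vs EARL_lower, B: QC vs
EARL_upper, C: EARL_lower vs EARL_upper) and the same three pairings for
SUVpeak (D, E, F). Rows are the first method's scores, columns the
second's, over DS levels 2..5 (no examination scored DS 1).
"""

from __future__ import annotations

from .stats import ContingencyTable

DS_LEVELS = (2, 3, 4, 5)

_PANELS = {
    # panel: (row_method, col_method, metric, counts rows DS2..DS5 x cols DS2..DS5)
    "A": ("qclear", "earl_lower", "suv_max",
          [[14, 0, 0, 0],
           [8, 5, 0, 0],
           [1, 2, 3, 0],
           [0, 1, 6, 14]]),
    "B": ("qclear", "earl_upper", "suv_max",
          [[13, 1, 0, 0],
           [6, 7, 0, 0],
           [1, 3, 2, 0],
           [0, 0, 6, 15]]),
    "C": ("earl_lower", "earl_upper", "suv_max",
          [[20, 3, 0, 0],
           [0, 7, 1, 0],
           [0, 1, 7, 1],
           [0, 0, 0, 14]]),
    "D": ("qclear", "earl_lower", "suv_peak",
          [[20, 0, 0, 0],
           [3, 4, 0, 0],
           [0, 3, 6, 0],
           [0, 0, 5, 13]]),
    "E": ("qclear", "earl_upper", "suv_peak",
          [[18, 2, 0, 0],
           [2, 4, 1, 0],
           [0, 4, 4, 1],
           [0, 0, 5, 13]]),
    "F": ("earl_lower", "earl_upper", "suv_peak",
          [[20, 3, 0, 0],
           [0, 6, 1, 0],
           [0, 1, 9, 1],
           [0, 0, 0, 13]]),
}


def load_table1() -> dict[str, ContingencyTable]:
    """All six published cross-tabulations as ContingencyTable objects."""
    return {
        panel: ContingencyTable(
            counts=counts,
            row_levels=DS_LEVELS,
            col_levels=DS_LEVELS,
            row_method=row,
            col_method=col,
            metric=metric,
        )
        for panel, (row, col, metric, counts) in _PANELS.items()
    }
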