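"""Published reference values used as inputs by examples and reproduction scripts.

``MI_MODULE_TABLE`` is the printed module/cluster composition table from the
staged-MI co-expression study this pipeline models: per disease-associated
module or trend cluster, the lncRNA and coding-gene counts, the printed
depletion p-value and the printed adjusted p-value.  The royalblue module has
no lncRNAs and its test is not defined (printed NA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["MI_MODULE_TABLE", "EXACT_ADJUSTED_ROWS"]

_ROWS = [
    # tag, lnc_count, pcg_count, p_printed, p_adjusted_printed
    ("brown", 31, 1211, 7.40e-16, 6.66e-15),
    ("darkred", 57, 1974, 2.69e-22, 2.69e-21),
    ("greenyellow", 5, 248, 2.31e-05, 0.000162),
    ("grey60", 7, 104, 0.268219, 0.536437),
    ("lightgreen", 4, 145, 0.003388, 0.016941),
    ("pink", 4, 154, 0.00197, 0.011819),
    ("royalblue", 0, 76, np.nan, np.nan),
    ("saddlebrown", 4, 41, 0.563794, 0.563794),
    ("white", 1, 56, 0.011879, 0.047516),
    ("Cluster4", 86, 1264, 0.04585, 0.13755),
    ("Cluster10", 46, 1170, 1.02e-08, 8.14e-08),
]

MI_MODULE_TABLE = pd.DataFrame(
    _ROWS,
    columns=["tag", "lnc_count", "pcg_count", "p_printed", "p_adjusted_printed"],
)

# rows whose printed p-value carries enough digits for the adjusted value to be
# reproduced exactly; the rest are limited by the rounding of the printed p
EXACT_ADJUSTED_ROWS = ("darkred", "brown", "white", "Cluster4", "saddlebrown")
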