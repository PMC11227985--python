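"""Nitrogen-to-protein conversion for rice grain.

Grain protein content is assayed as Kjeldahl total nitrogen and converted
to protein with the rice-specific factor 5.82 (protein % = 5.82 x N %).
"""

from __future__ import annotations

import numpy as np

#: rice grain nitrogen-to-protein conversion factor
N_TO_PROTEIN_FACTOR = 5.82


def nitrogen_to_gpc(total_n_percent, factor: float = N_TO_PROTEIN_FACTOR):
    """Convert total grain N (%) to grain protein content (%).

    Accepts scalars or arrays; negative nitrogen values are rejected.
    """
    n = np.asarray(total_n_percent, dtype=float)
    if np.any(n < 0):
        raise ValueError("total nitrogen cannot be negative")
    out = factor * n
    return float(out) if np.isscalar(total_n_percent) or out.ndim == 0 else out
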