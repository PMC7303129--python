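"""Allele-fraction model shared by the simulator and the inference code.

A somatic mutation carried on ``m`` chromosomal copies by a fraction ``phi``
(the cancer cell fraction, CCF) of tumor cells, in a sample of purity ``rho``
whose locus has total copy number ``CN``, is expected at variant allele
fraction

    VAF = m * phi * rho / (rho * CN + 2 * (1 - rho))

The simulator draws reads forward through this equation; CCF estimation
inverts it.
"""

from __future__ import annotations

import numpy as np


def vaf_coefficient(rho, total_cn, multiplicity=1.0):
    """Coefficient ``c`` such that expected VAF = ``c * CCF``.

    Parameters may be scalars or broadcastable arrays.
    """
    rho = np.asarray(rho, dtype=float)
    total_cn = np.asarray(total_cn, dtype=float)
    mult = np.asarray(multiplicity, dtype=float)
    denom = rho * total_cn + 2.0 * (1.0 - rho)
    return mult * rho / denom


def expected_vaf(ccf, rho, total_cn, multiplicity=1.0):
    """Expected variant allele fraction for a mutation at CCF ``ccf``."""
    return vaf_coefficient(rho, total_cn, multiplicity) * np.asarray(ccf, dtype=float)


def round_half_up(x):
    """Round with .5 always rounding up (deterministic multiplicity calls)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)
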