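"""Unit conversions for glucose and glycated hemoglobin.

Glucose is held internally in mg/dL and HbA1c in % (NGSP); conversion to
SI-style units (mmol/L, IFCC mmol/mol) happens only at I/O edges and in
reports. The NGSP<->IFCC link is the master equation
``IFCC = 10.929 x (NGSP - 2.15)``.
"""

from __future__ import annotations

import numpy as np

#: grams per mole of glucose divided by 10 (mg/dL per mmol/L)
MGDL_PER_MMOLL = 18.016

#: master-equation slope and intercept (NGSP % -> IFCC mmol/mol)
IFCC_SLOPE = 10.929
IFCC_OFFSET = 2.15


def ngsp_to_ifcc(ngsp_percent):
    """Convert HbA1c from % (NGSP) to mmol/mol (IFCC).

    Parameters
    ----------
    ngsp_percent : float or array-like
        HbA1c in % NGSP; must be strictly positive.

    Returns
    -------
    float or ndarray
        HbA1c in mmol/mol: ``10.929 * (ngsp - 2.15)``.
    """
    x = np.asarray(ngsp_percent, dtype=float)
    if np.any(x <= 0):
        raise ValueError("HbA1c (% NGSP) must be positive")
    out = IFCC_SLOPE * (x - IFCC_OFFSET)
    return out.item() if np.isscalar(ngsp_percent) else out


def ifcc_to_ngsp(ifcc_mmolmol):
    """Inverse of :func:`ngsp_to_ifcc`."""
    x = np.asarray(ifcc_mmolmol, dtype=float)
    out = x / IFCC_SLOPE + IFCC_OFFSET
    return out.item() if np.isscalar(ifcc_mmolmol) else out


def mgdl_to_mmoll(mgdl):
    """Convert glucose from mg/dL to mmol/L (divide by 18.016)."""
    x = np.asarray(mgdl, dtype=float)
    if np.any(x < 0):
        raise ValueError("glucose (mg/dL) must be non-negative")
    out = x / MGDL_PER_MMOLL
    return out.item() if np.isscalar(mgdl) else out


def mmoll_to_mgdl(mmoll):
    """Convert glucose from mmol/L to mg/dL (multiply by 18.016)."""
    x = np.asarray(mmoll, dtype=float)
    if np.any(x < 0):
        raise ValueError("glucose (mmol/L) must be non-negative")
    out = x * MGDL_PER_MMOLL
    return out.item() if np.isscalar(mmoll) else out
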