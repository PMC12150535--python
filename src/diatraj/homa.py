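"""Homeostasis-model-assessment (HOMA) indices of beta-cell function and
insulin resistance.

The pipeline works from fasting plasma glucose in mg/dL (the unit the cohort
records use) and fasting insulin in mIE/L, which is numerically identical to
µU/mL.  Internally glucose is converted to mmol/L with the fixed factor
18.016 mg/dL per mmol/L.

Two computation routes exist:

``homa1``
    The original closed forms:

    .. math::

        \\mathrm{HOMA\\text{-}IR} = \\frac{G \\cdot I}{22.5}, \\qquad
        \\mathrm{HOMA\\text{-}B} = \\frac{20 \\cdot I}{G - 3.5}

    with :math:`G` in mmol/L and :math:`I` in µU/mL.  HOMA-B is undefined at
    or below 3.5 mmol/L.

``homa2_model``
    A hook for the iterative HOMA2 structural model (the Oxford calculator).
    That program is closed-source, so no solver ships with the package;
    callers may register one with :func:`register_homa2_solver`, and cohort
    files with precomputed HOMA2-B / HOMA2-IR columns are accepted as
    first-class inputs throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._errors import ConfigurationError, DomainError

#: mg/dL per mmol/L for glucose (molar mass basis).
MGDL_PER_MMOL = 18.016

#: Glucose floor (mmol/L) below which the HOMA1 beta-cell index is undefined.
HOMA_B_GLUCOSE_FLOOR = 3.5


@dataclass(frozen=True)
class HomaResult:
    """HOMA indices for one fasting glucose/insulin pair.

    Attributes
    ----------
    homa_b : float
        Beta-cell function index, percent.
    homa_ir : float
        Insulin-resistance index, dimensionless (a.u.).
    method : str
        ``"homa1"`` or ``"homa2_model"``.
    glucose_mmol : float
        Glucose converted to mmol/L.
    insulin_uUml : float
        Fasting insulin in µU/mL (== mIE/L).
    """

    homa_b: float
    homa_ir: float
    method: str
    glucose_mmol: float
    insulin_uUml: float


def mgdl_to_mmol(glucose_mgdl):
    """Convert glucose from mg/dL to mmol/L.

    Accepts scalars or arrays; raises :class:`DomainError` on any
    non-positive value.
    """
    g = np.asarray(glucose_mgdl, dtype=float)
    if np.any(g <= 0) or np.any(~np.isfinite(g)):
        raise DomainError("glucose must be positive and finite (mg/dL)")
    out = g / MGDL_PER_MMOL
    return float(out) if np.isscalar(glucose_mgdl) else out


_HOMA2_SOLVER: Callable[[float, float], tuple[float, float]] | None = None


def register_homa2_solver(solver: Callable[[float, float], tuple[float, float]]) -> None:
    """Register a HOMA2 structural-model solver.

    ``solver(glucose_mmol, insulin_uUml)`` must return ``(homa_b, homa_ir)``.
    """
    global _HOMA2_SOLVER
    _HOMA2_SOLVER = solver


def compute_homa(fpg_mgdl: float, insulin_miel: float, method: str = "homa1") -> HomaResult:
    """Compute HOMA-B (%) and HOMA-IR (a.u.) from fasting measurements.

    Parameters
    ----------
    fpg_mgdl : float
        Fasting plasma glucose in mg/dL; must exceed 63.056 mg/dL
        (3.5 mmol/L) for the HOMA1 beta-cell index to be defined.
    insulin_miel : float
        Fasting insulin in mIE/L (numerically µU/mL); must be positive.
    method : {"homa1", "homa2_model"}
        ``homa1`` uses the closed forms; ``homa2_model`` dispatches to a
        registered solver and raises :class:`ConfigurationError` when none
        is registered.
    """
    if not np.isfinite(insulin_miel) or insulin_miel <= 0:
        raise DomainError("fasting insulin must be positive (mIE/L)")
    g_mmol = mgdl_to_mmol(fpg_mgdl)
    if method == "homa1":
        denom = g_mmol - HOMA_B_GLUCOSE_FLOOR
        if denom <= 0:
            raise DomainError(
                f"HOMA1 beta-cell index undefined for glucose <= 3.5 mmol/L "
                f"(got {g_mmol:.4f} mmol/L)"
            )
        homa_ir = g_mmol * insulin_miel / 22.5
        homa_b = 20.0 * insulin_miel / denom
    elif method == "homa2_model":
        if _HOMA2_SOLVER is None:
            raise ConfigurationError(
                "method='homa2_model' requires a registered solver; "
                "use register_homa2_solver() or supply precomputed HOMA2 columns"
            )
        homa_b, homa_ir = _HOMA2_SOLVER(g_mmol, insulin_miel)
    else:
        raise ConfigurationError(f"unknown HOMA method {method!r}; use 'homa1' or 'homa2_model'")
    return HomaResult(
        homa_b=float(homa_b),
        homa_ir=float(homa_ir),
        method=method,
        glucose_mmol=float(g_mmol),
        insulin_uUml=float(insulin_miel),
    )


def homa_columns(fpg_mgdl, insulin_miel):
    """Vectorised HOMA1 indices for cohort tables.

    Returns ``(homa_b, homa_ir)`` arrays; entries with glucose at or below
    3.5 mmol/L or non-positive insulin are NaN (flagged, not clamped).
    """
    g = np.asarray(fpg_mgdl, dtype=float) / MGDL_PER_MMOL
    i = np.asarray(insulin_miel, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = g - HOMA_B_GLUCOSE_FLOOR
        homa_b = np.where((denom > 0) & (i > 0), 20.0 * i / denom, np.nan)
        homa_ir = np.where((g > 0) & (i > 0), g * i / 22.5, np.nan)
    return homa_b, homa_ir
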