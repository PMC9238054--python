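"""Systemic and ocular perfusion metrics.

Ocular perfusion pressure (OPP) is the effective driving pressure for blood
flow through the eye: two thirds of the mean arterial pressure (MAP, the
seated brachial estimate) minus the intraocular pressure (IOP) opposing it.
"""

from __future__ import annotations

import warnings

__all__ = ["mean_arterial_pressure", "ocular_perfusion_pressure"]


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = DBP + (SBP - DBP)/3, in mmHg.

    The diastolic-weighted estimate reflects that the heart spends roughly
    two thirds of the cardiac cycle in diastole at resting heart rates.
    """
    if not (sbp >= dbp > 0):
        raise ValueError(f"require sbp >= dbp > 0, got sbp={sbp}, dbp={dbp}")
    return dbp + (sbp - dbp) / 3.0


def ocular_perfusion_pressure(map_mmHg: float, iop: float) -> float:
    """OPP = (2/3) MAP - IOP, in mmHg (sitting position).

    A non-positive result is physiologically extreme but not impossible to
    enter (e.g. severe hypotension with ocular hypertension); it is returned
    with a warning rather than rejected.
    """
    if iop < 0:
        raise ValueError(f"IOP must be non-negative, got {iop}")
    opp = (2.0 / 3.0) * map_mmHg - iop
    if opp <= 0:
        warnings.warn(
            f"ocular perfusion pressure {opp:.2f} mmHg is non-positive", stacklevel=2
        )
    return opp
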