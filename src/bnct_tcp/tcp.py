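"""gEUD reduction of non-uniform dose and the logistic TCP dose-response model.

A non-uniform tumor dose distribution is reduced to a single generalized
equivalent uniform dose (power mean with tissue exponent ``a``)::

    gEUD = ( sum_i v_i * D_i**a ) ** (1/a)

For tumors ``a`` is large and negative (-13 for squamous cell carcinoma),
which makes gEUD track the cold end of the distribution.  Tumor control
probability follows the logistic dose-response

    TCP(D) = 1 / (1 + (TCD50/D)**(4*gamma50))

with TCD50 the dose giving 50% control and gamma50 the normalized slope at
TCD50; plugging gEUD in for D gives the EUD-based TCP of a non-uniform
distribution.  Default parameters are the photon-derived SCC values
TCD50 = 46.8 Gy (reported uncertainty +/-6.4 Gy, recorded but not
propagated) and gamma50 = 2.0, so gEUD must be supplied in photon-equivalent
dose (EQD2, Gy), not raw weighted dose.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .dvh import DVH, to_differential

__all__ = [
    "TCPParams",
    "ResponseClass",
    "SCC_TCP_PARAMS",
    "geud",
    "tcp_uniform",
    "tcp_from_geud",
    "classify_response",
]

#: doses at or below this are rejected for negative a (diverging power term)
_MIN_DOSE_FOR_NEGATIVE_A = 1e-6

#: TCP thresholds (%) mapping model output onto RECIST-like response levels
CR_THRESHOLD = 60.0
PR_THRESHOLD = 25.0


@dataclass(frozen=True)
class TCPParams:
    """Logistic TCP parameters plus the gEUD tissue exponent."""

    tcd50: float = 46.8
    gamma50: float = 2.0
    a: float = -13.0
    tcd50_uncertainty: float = 6.4  # recorded only, not propagated

    def __post_init__(self):
        if self.tcd50 <= 0:
            raise ValueError("tcd50 must be positive")
        if self.gamma50 <= 0:
            raise ValueError("gamma50 must be positive")
        if self.a == 0:
            raise ValueError("a must be nonzero")


SCC_TCP_PARAMS = TCPParams()


class ResponseClass(enum.Enum):
    """TCP bands mapped onto clinical response levels: TCP >= 60% tracks
    complete response, >= 25% partial response (boundaries inclusive)."""

    CR_LEVEL = "CR-level"
    PR_LEVEL = "PR-level"
    SUB_PR = "sub-PR"


def geud(dvh: DVH, a: float) -> float:
    """Generalized equivalent uniform dose, ``(sum v_i D_i^a)^(1/a)``.

    Computed in log space (logsumexp over ``ln v_i + a ln D_i``) so that
    strongly negative exponents do not underflow.  Zero-volume bins are
    ignored; for a < 0 any contributing dose <= 1e-6 is an error rather
    than a silently clamped diverging term.
    """
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    d = to_differential(dvh)
    mask = d.volumes > 0
    doses = d.doses[mask]
    vols = d.volumes[mask]
    if a < 0 and np.any(doses <= _MIN_DOSE_FOR_NEGATIVE_A):
        raise ValueError(
            "gEUD with negative exponent requires strictly positive doses "
            f"(> {_MIN_DOSE_FOR_NEGATIVE_A:g})"
        )
    if np.any(doses <= 0):
        raise ValueError("gEUD requires positive doses")
    log_sum = logsumexp(a * np.log(doses), b=vols)
    return float(np.exp(log_sum / a))


def tcp_uniform(dose: float, p: TCPParams = SCC_TCP_PARAMS) -> float:
    """Logistic TCP (%) of a uniform dose: 100/(1 + (TCD50/D)^(4*gamma50))."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive")
    out = 100.0 / (1.0 + (p.tcd50 / dose) ** (4.0 * p.gamma50))
    return out if out.ndim else float(out)


def tcp_from_geud(geud_gy: float, p: TCPParams = SCC_TCP_PARAMS) -> float:
    """EUD-based TCP (%): the uniform-dose logistic model evaluated at gEUD."""
    return tcp_uniform(geud_gy, p)


def classify_response(tcp_percent: float) -> ResponseClass:
    """Map a TCP (%) onto a response level: >=60 CR-level, >=25 PR-level,
    otherwise sub-PR.  Boundaries are inclusive."""
    if not (0 <= tcp_percent <= 100):
        raise ValueError("tcp_percent must lie in [0, 100]")
    if tcp_percent >= CR_THRESHOLD:
        return ResponseClass.CR_LEVEL
    if tcp_percent >= PR_THRESHOLD:
        return ResponseClass.PR_LEVEL
    return ResponseClass.SUB_PR
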