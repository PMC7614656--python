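"""Logistic response models imposing MCAR/MAR missingness on components.

The incomplete components z2 and z3 each get an independent binary response
indicator r_l drawn from

    logit P(r_l = 1 | x, z1) = a0 + ax*x + az1*z1 + axz1*x*z1,

so missingness can depend on randomized treatment and the fully observed
component z1 but never on the component's own value (the mechanisms are at
worst MAR at component level — the induced missingness of a *derived
composite* can still be MNAR).  Three named presets are provided:

* ``MCAR``: a0 = 0.7, others 0 — every component observed with probability
  expit(0.7) ~ 0.668 regardless of data;
* ``MAR1``: a0 = 1.05, ax = -0.75, az1 = 0.25 — response depends on
  treatment and z1, no interaction;
* ``MAR2``: as MAR1 plus interaction axz1 = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DomainError

__all__ = ["MissingnessParams", "PRESETS", "response_prob", "apply_missingness"]


@dataclass(frozen=True)
class MissingnessParams:
    """Coefficients of one component's logistic response-probability model."""

    alpha0: float = 0.0
    alpha_x: float = 0.0
    alpha_z1: float = 0.0
    alpha_xz1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha_x", "alpha_z1", "alpha_xz1"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"{name} is not finite")


PRESETS: dict[str, MissingnessParams] = {
    "MCAR": MissingnessParams(alpha0=0.7),
    "MAR1": MissingnessParams(alpha0=1.05, alpha_x=-0.75, alpha_z1=0.25),
    "MAR2": MissingnessParams(alpha0=1.05, alpha_x=-0.75, alpha_z1=0.25, alpha_xz1=0.25),
}


def response_prob(params: MissingnessParams, x: int, z1: int) -> float:
    """P(component observed | x, z1) under the logistic response model."""
    if x not in (0, 1) or z1 not in (0, 1):
        raise DomainError(f"(x, z1) = {(x, z1)!r} must be binary")
    return float(
        expit(
            params.alpha0
            + params.alpha_x * x
            + params.alpha_z1 * z1
            + params.alpha_xz1 * x * z1
        )
    )


def _response_probs_vec(params: MissingnessParams, x: np.ndarray, z1: np.ndarray) -> np.ndarray:
    return expit(
        params.alpha0
        + params.alpha_x * x
        + params.alpha_z1 * z1
        + params.alpha_xz1 * x * z1
    )


def apply_missingness(
    data: pd.DataFrame,
    params_z2: MissingnessParams,
    params_z3: MissingnessParams,
    seed=None,
) -> pd.DataFrame:
    """Mask z2 and z3 by independent draws from their response models.

    The input must have z1, z2, z3 fully observed.  Each component gets its
    own random stream spawned from the master seed, so switching one
    component's mechanism leaves the other's mask unchanged.  x and z1 are
    never touched.
    """
    for col in ("x", "z1", "z2", "z3"):
        if col not in data.columns:
            raise DomainError(f"dataset lacks column {col!r}")
    for col in ("z1", "z2", "z3"):
        if data[col].isna().any():
            raise DomainError(
                f"column {col!r} already contains missing values; "
                "apply_missingness expects a fully observed input"
            )
    x = data["x"].to_numpy(dtype=np.int8)
    z1 = data["z1"].to_numpy(dtype=np.int8)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(2)]
    out = data.copy()
    for col, params, rng in (("z2", params_z2, streams[0]), ("z3", params_z3, streams[1])):
        p_obs = _response_probs_vec(params, x, z1)
        observed = rng.random(len(data)) < p_obs
        masked = out[col].copy()
        masked[~observed] = pd.NA
        out[col] = masked
    return out
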