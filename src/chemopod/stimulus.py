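"""Chemoattractant fields, receptor occupancy, and the noisy signal term.

The chemistry on the perimeter is driven by a per-node signal

    s_i = k_a (1 + eta_a U1_i)  +  k_s Y_i (1 + eta_s U2_i),   s_i >= 0,

with ``Y_i`` the fractional receptor occupancy at node ``i``.  The first
term is the baseline drive sustaining the activator's autocatalysis, the
second couples the local occupancy into the positive feedback; each carries
its own multiplicative noise (``U`` uniform on [-1, 1] by default, drawn
independently per node per step).  There is no signal processing: every
membrane point only ever sees its own local concentration.

Occupancy is hyperbolic in concentration, ``Y = C / (C + Kd)``, with the
default ``Kd`` chosen so nanomolar gradients sit in the sensitive low-
occupancy regime.  An optional exponential decay of the occupancy models
receptor adaptation after a sudden uniform stimulus.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np

logger = logging.getLogger("chemopod")

KINDS = ("none", "linear", "point_source", "uniform_step", "scheduled")


class ConfigurationError(ValueError):
    """Raised for invalid stimulus or run configuration."""


@dataclasses.dataclass
class StimulusSpec:
    """Declarative chemoattractant protocol.

    kind : one of ``none``, ``linear``, ``point_source``, ``uniform_step``,
        ``scheduled`` (a linear gradient that is re-aimed relative to the
        cell's heading every ``reorientation_interval`` frames).
    reference_concentration : nM; concentration at ``reference_point``
        (linear/scheduled), at unit distance from the source
        (point_source), or the plateau level (uniform_step).
    gradient_vector : nM per length unit, the spatial gradient direction and
        magnitude for linear/scheduled kinds.
    reference_point : where the linear field equals the reference value.
    source_position : 2-D location of the point source.
    onset_time : model time at which the stimulus switches on (0 before).
    adaptation_timescale : if > 0, occupancy decays as exp(-(t-onset)/tau)
        after onset (receptor adaptation; used by the uniform_step cringe
        protocol).
    reorientation_interval : frames between re-aims (scheduled kind).
    reorientation_offset : degrees added to the cell heading at each re-aim.
    """

    kind: str = "none"
    reference_concentration: float = 0.0
    gradient_vector: tuple = (0.0, 0.0)
    reference_point: tuple = (0.0, 0.0)
    source_position: tuple = (0.0, 0.0)
    onset_time: float = 0.0
    adaptation_timescale: float = 0.0
    reorientation_interval: int = 0
    reorientation_offset: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}; valid: {KINDS}")
        if self.reference_concentration < 0:
            raise ConfigurationError("reference_concentration must be >= 0")
        if self.kind == "scheduled" and self.reorientation_interval <= 0:
            raise ConfigurationError("scheduled stimulus needs a positive reorientation_interval")

    @property
    def gradient_direction(self) -> float:
        """Direction of the gradient vector, degrees CCW from +x."""
        g = self.gradient_vector
        return math.degrees(math.atan2(g[1], g[0]))

    @property
    def gradient_magnitude(self) -> float:
        return float(np.hypot(*self.gradient_vector))


@dataclasses.dataclass
class SignalParameters:
    """Couplings and noise of the signal term (see module docstring)."""

    autocatalysis_coupling: float = 0.02   # k_a
    occupancy_coupling: float = 0.05       # k_s
    autocatalysis_noise_amplitude: float = 0.3   # eta_a
    receptor_noise_amplitude: float = 0.3        # eta_s
    occupancy_Kd: float = 30.0             # nM, half-saturation
    rng_seed: int = 0
    noise_distribution: str = "uniform"    # or "gaussian"

    def __post_init__(self) -> None:
        if self.autocatalysis_noise_amplitude < 0 or self.receptor_noise_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.occupancy_Kd <= 0:
            raise ValueError("occupancy_Kd must be positive")
        if self.noise_distribution not in ("uniform", "gaussian"):
            raise ValueError("noise_distribution must be 'uniform' or 'gaussian'")


def concentration_at(position, time: float, spec: StimulusSpec):
    """Chemoattractant concentration (nM) at one or many positions.

    Linear fields are clipped at zero rather than erroring when the cell
    wanders past the zero isoline; the point source decays as 1/r with the
    reference concentration read at unit distance.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    scalar = np.ndim(position) == 1
    if time < spec.onset_time or spec.kind == "none":
        out = np.zeros(len(pos))
        return float(out[0]) if scalar else out
    if spec.kind in ("linear", "scheduled"):
        g = np.asarray(spec.gradient_vector, dtype=float)
        ref = np.asarray(spec.reference_point, dtype=float)
        out = spec.reference_concentration + (pos - ref) @ g
    elif spec.kind == "point_source":
        r = np.linalg.norm(pos - np.asarray(spec.source_position, dtype=float), axis=1)
        out = spec.reference_concentration / np.maximum(r, 1e-6)
    elif spec.kind == "uniform_step":
        out = np.full(len(pos), spec.reference_concentration)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"unknown stimulus kind {spec.kind!r}")
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def receptor_occupancy(concentration, Kd: float):
    """Fractional receptor occupancy ``Y = C / (C + Kd)``."""
    C = np.asarray(concentration, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be nonnegative")
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    out = C / (C + Kd)
    return float(out) if out.ndim == 0 else out


def adapted_occupancy(occupancy, time: float, onset_time: float, tau: float):
    """Occupancy after exponential receptor adaptation.

    Returns ``occupancy * exp(-(time - onset_time)/tau)``; before onset the
    pre-stimulus value 0 is returned.  ``tau <= 0`` disables adaptation.
    """
    occ = np.asarray(occupancy, dtype=float)
    if time < onset_time:
        out = np.zeros_like(occ)
    elif tau <= 0:
        out = occ
    else:
        out = occ * math.exp(-(time - onset_time) / tau)
    return float(out) if out.ndim == 0 else out


def occupancy_at(position, time: float, spec: StimulusSpec, Kd: float):
    """Occupancy at positions, including onset gating and adaptation."""
    C = concentration_at(position, time, spec)
    Y = receptor_occupancy(C, Kd)
    if spec.adaptation_timescale > 0 and time >= spec.onset_time:
        Y = adapted_occupancy(Y, time, spec.onset_time, spec.adaptation_timescale)
    return Y


def reorient_gradient(spec: StimulusSpec, cell_heading: float,
                      offset: Optional[float] = None) -> StimulusSpec:
    """Re-aim the gradient to ``cell_heading + offset`` (magnitude unchanged).

    The offset is relative to the *current* heading, not cumulative.  For a
    point source the source is re-positioned on the new bearing at its
    current distance from the reference point.  ``kind='none'`` is a warned
    no-op.
    """
    if offset is None:
        offset = spec.reorientation_offset
    if spec.kind == "none":
        logger.warning("reorient_gradient called on kind='none'; no-op")
        return spec
    theta = math.radians((cell_heading + offset) % 360.0)
    u = np.array([math.cos(theta), math.sin(theta)])
    if spec.kind == "point_source":
        ref = np.asarray(spec.reference_point, dtype=float)
        d = np.linalg.norm(np.asarray(spec.source_position, dtype=float) - ref)
        return dataclasses.replace(spec, source_position=tuple(ref + d * u))
    mag = spec.gradient_magnitude
    return dataclasses.replace(spec, gradient_vector=tuple(mag * u))


def signal_field(occupancy: np.ndarray, activator: np.ndarray,
                 params: SignalParameters, rng: np.random.Generator) -> np.ndarray:
    """Per-node signal ``s`` combining baseline autocatalytic drive and occupancy.

    Node noise draws are mutually independent and consumed from ``rng`` in
    node order (first the autocatalysis noise vector, then the receptor
    noise vector), so identical seeds and inputs give bit-identical output.
    The result is clipped at zero.
    """
    Y = np.asarray(occupancy, dtype=float)
    a = np.asarray(activator, dtype=float)
    if Y.shape != a.shape:
        raise ValueError("occupancy and activator must share the node set")
    n = len(Y)
    if params.noise_distribution == "gaussian":
        u1 = rng.standard_normal(n)
        u2 = rng.standard_normal(n)
    else:
        u1 = rng.uniform(-1.0, 1.0, n)
        u2 = rng.uniform(-1.0, 1.0, n)
    s = (params.autocatalysis_coupling * (1.0 + params.autocatalysis_noise_amplitude * u1)
         + params.occupancy_coupling * Y * (1.0 + params.receptor_noise_amplitude * u2))
    return np.maximum(s, 0.0)
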