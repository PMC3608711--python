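"""Fourier retrieval of transmission, differential phase and dark-field.

Each pixel of a phase-stepping scan traces a sinusoid over one grating
period,

    I_k = a0 * (1 + v * cos(2 pi f_k + phi)),

whose mean ``a0``, first-harmonic amplitude ``a1 = a0 * v`` and phase
``phi`` are read off the discrete Fourier components of the stepping
curve.  For frames sampled uniformly over exactly one period the DFT
estimator is exact on a single-harmonic curve, which is why it is the
standard retrieval for Talbot interferometry.  Comparing the sample
against the sample-free reference scan gives the three contrast
channels:

    T   = a0_sample / a0_reference          (transmission)
    V   = (a1/a0)_sample / (a1/a0)_ref      (dark-field, rel. visibility)
    dphi = wrap(phi_sample - phi_reference)  (differential phase)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .phantom import StepScan

__all__ = ["ProjectionTriplet", "retrieve_signals", "normalize_to_water"]


class RetrievalError(ValueError):
    """Structural problem with a stepping-scan pair."""


@dataclass
class ProjectionTriplet:
    """Co-registered transmission / differential-phase / dark-field maps."""

    T_map: np.ndarray
    dphi_map: np.ndarray
    V_map: np.ndarray
    valid_mask: np.ndarray
    metadata: Dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.T_map.shape


def _fourier_components(scan: StepScan) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(a0, a1, phi) per pixel from the stepping curve."""
    frames = scan.frames
    n = scan.n_steps
    phase = np.exp(-2j * np.pi * scan.step_fractions)
    a0 = frames.mean(axis=0)
    X1 = np.tensordot(phase, frames, axes=(0, 0))
    a1 = 2.0 * np.abs(X1) / n
    phi = np.angle(X1)
    return a0, a1, phi


def retrieve_signals(
    sample: StepScan,
    reference: StepScan,
    validity_floor: float = 0.01,
) -> ProjectionTriplet:
    """Extract the three contrast channels from a sample/reference pair.

    Pixels whose reference mean or modulation amplitude falls below
    ``validity_floor`` times the frame-wide median (dead or unmodulated
    pixels) are flagged invalid; their channel values are NaN.

    A completely dark reference yields an all-invalid triplet with a
    warning rather than an exception, so batch processing can continue.
    """
    if sample.frames.shape != reference.frames.shape:
        raise RetrievalError(
            f"sample frames {sample.frames.shape} and reference frames "
            f"{reference.frames.shape} do not match"
        )
    if not np.allclose(sample.step_fractions, reference.step_fractions):
        raise RetrievalError("sample and reference step fractions differ")
    if (sample.frames < 0).any() or (reference.frames < 0).any():
        raise RetrievalError("stepping frames must be non-negative")

    a0_s, a1_s, phi_s = _fourier_components(sample)
    a0_r, a1_r, phi_r = _fourier_components(reference)

    med_a0 = np.median(a0_r)
    med_a1 = np.median(a1_r)
    valid = (a0_r > validity_floor * med_a0) & (a1_r > validity_floor * med_a1)
    valid &= a0_s > 0
    if not valid.any():
        warnings.warn(
            "reference scan carries no usable signal; all pixels flagged "
            "invalid",
            stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        T = a0_s / a0_r
        V = (a1_s / a0_s) / (a1_r / a0_r)
    dphi = np.angle(np.exp(1j * (phi_s - phi_r)))  # wrapped to (-pi, pi]
    valid &= np.isfinite(T) & np.isfinite(V)
    T = np.where(valid, T, np.nan)
    V = np.where(valid, V, np.nan)
    dphi = np.where(valid, dphi, np.nan)
    return ProjectionTriplet(
        T_map=T,
        dphi_map=dphi,
        V_map=V,
        valid_mask=valid,
        metadata={
            "specimen_id": sample.specimen_id,
            "projection_index": sample.projection_index,
            "n_steps": sample.n_steps,
            "validity_floor": validity_floor,
        },
    )


def normalize_to_water(
    triplet: ProjectionTriplet, water_roi: np.ndarray
) -> ProjectionTriplet:
    """Divide T and V by their medians over the water-bath ROI.

    After normalization the median of both channels over the water ROI
    is exactly 1, anchoring transmission "relative to water".  The
    normalizers are recorded in the metadata; re-normalizing an already
    normalized triplet is a no-op (normalizers 1).
    """
    roi = np.asarray(water_roi, dtype=bool) & triplet.valid_mask
    if not roi.any():
        raise RetrievalError(
            "water ROI is empty or fully invalid; cannot normalize"
        )
    t_norm = float(np.median(triplet.T_map[roi]))
    v_norm = float(np.median(triplet.V_map[roi]))
    if t_norm <= 0 or v_norm <= 0:
        raise RetrievalError("non-positive water-ROI median")
    meta = dict(triplet.metadata)
    meta["water_T_normalizer"] = t_norm
    meta["water_V_normalizer"] = v_norm
    return ProjectionTriplet(
        T_map=triplet.T_map / t_norm,
        dphi_map=triplet.dphi_map,
        V_map=triplet.V_map / v_norm,
        valid_mask=triplet.valid_mask,
        metadata=meta,
    )
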