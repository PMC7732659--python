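"""Accelerometer-to-angle transforms for the Physical Analogue Scale.

The PAS encodes a continuous rating in the elevation of the forearm: flat
(0°) is the scale minimum, fully upright (90°) the maximum.  A wrist-worn
accelerometer reads the gravity vector at the moment of a button press; with
``y`` the along-forearm axis and ``x``/``z`` the two perpendicular device
axes, the elevation is

    angle = arctan(|y| / sqrt(x**2 + z**2)) * 180 / pi

The transform is a ratio of accelerations, so it is unit-free (g or m/s^2
both work) and invariant under sign flips of any axis.  A flat forearm gives
``y ~ 0`` hence 0°; an upright forearm puts gravity entirely on ``y`` hence
90°.  No calibration or gravity/linear-acceleration separation is attempted:
the device is read while the arm is held still.

An *extended* variant keeps the signs of ``y`` and of the horizontal
component, decoding with ``atan2`` instead of folding everything into
[0, 90].  On [0, 90] it agrees exactly with the device transform; outside it
represents virtual angles (used by the study simulator when scale clipping
is disabled, so that a linear latent variable survives the log round trip).
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "GRAVITY",
    "accel_to_angle",
    "angle_to_accel",
    "angle_to_scale",
]

#: Standard gravity in m/s^2; default magnitude for synthesised triplets.
GRAVITY = 9.81


def accel_to_angle(x, y, z, *, extended: bool = False):
    """Convert accelerometer triplet(s) to PAS elevation angle(s) in degrees.

    Parameters
    ----------
    x, y, z
        Acceleration components (scalars or broadcastable arrays) in any
        consistent unit; ``y`` is the along-forearm axis.
    extended
        If False (device behaviour), return ``arctan(|y|/hypot(x, z))`` in
        [0, 90].  If True, return ``atan2(y, sign(x)*hypot(x, z))`` in
        (-180, 180], which equals the device angle whenever the true
        elevation lies in [0, 90].

    Raises
    ------
    InputError
        If any component is non-finite.
    DomainError
        If a triplet is the zero vector (free fall / no signal carries no
        orientation information and must not be silently recorded as 0°).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise InputError("accelerometer components must be finite")
    horiz = np.hypot(x, z)
    if np.any((horiz == 0) & (y == 0)):
        raise DomainError("zero acceleration vector: no orientation information")
    if extended:
        # copysign keeps x's sign on the horizontal magnitude; x == +0.0 maps
        # to the forward half-plane, matching the device convention.
        ang = np.degrees(np.arctan2(y, np.copysign(horiz, x)))
    else:
        ang = np.degrees(np.arctan2(np.abs(y), horiz))
    return float(ang) if ang.ndim == 0 else ang


def angle_to_accel(
    angle,
    noise_sd: float = 0.0,
    rng=None,
    *,
    magnitude: float = GRAVITY,
    extended: bool = False,
):
    """Synthesise an accelerometer triplet that decodes to ``angle``.

    Inverse of :func:`accel_to_angle`, used by the study simulator.  With
    ``noise_sd > 0`` a Gaussian perturbation is applied *on the angle scale*
    (the literature reports dispersion as angle SDs, not per-axis sensor
    noise) and, in device mode, truncated to [0, 90] before inversion.

    In device mode a random azimuth distributes the horizontal component
    between ``x`` and ``z`` (the device transform is insensitive to it).  In
    extended mode the horizontal component is kept entirely on ``x`` so its
    sign survives the round trip.

    Returns ``(x, y, z)`` with Euclidean norm ``magnitude``.
    """
    a = float(angle)
    if not np.isfinite(a):
        raise InputError("angle must be finite")
    if not extended and not (0.0 <= a <= 90.0):
        raise InputError(f"angle {a!r} outside [0, 90]")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    if noise_sd > 0:
        if rng is None:
            raise InputError("noise_sd > 0 requires an rng")
        a = a + noise_sd * float(rng.standard_normal())
        if not extended:
            a = min(max(a, 0.0), 90.0)
    rad = np.radians(a)
    y = magnitude * np.sin(rad)
    horiz = magnitude * np.cos(rad)
    if extended:
        return float(horiz), float(y), 0.0
    if rng is not None:
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
    else:
        azimuth = 0.0
    return (
        float(abs(horiz) * np.cos(azimuth)),
        float(y),
        float(abs(horiz) * np.sin(azimuth)),
    )


def angle_to_scale(angle, scale_min: float, scale_max: float):
    """Map PAS angle(s) in [0, 90] linearly onto a response scale.

    0° maps to ``scale_min`` ("does not apply at all") and 90° to
    ``scale_max`` ("applies very well"); validation against VAS ratings found
    no material departure from linearity, so no curvature correction is
    applied.
    """
    if not scale_max > scale_min:
        raise InputError("scale_max must exceed scale_min")
    a = np.asarray(angle, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a > 90):
        raise InputError("angle must lie in [0, 90]")
    out = scale_min + (a / 90.0) * (scale_max - scale_min)
    return float(out) if out.ndim == 0 else out
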