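"""Small vector-geometry helpers shared by the builder and the validator."""

from __future__ import annotations

import math

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    k = normalize(np.asarray(axis, dtype=float))
    a = math.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(a) * kx + (1 - math.cos(a)) * (kx @ kx)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, normalize(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def exo_directions(p, nbr_a, nbr_b, tilt_deg=54.75):
    """The two exocyclic substituent directions at a ring atom.

    ``p`` is the ring atom, ``nbr_a``/``nbr_b`` its two ring neighbours.  The
    directions are symmetric about the plane of the exterior bisector and the
    local ring normal; the first returned direction is the one on the +normal
    side (where the normal is cross(a-p, b-p)).
    """
    na = normalize(np.asarray(nbr_a) - p)
    nb = normalize(np.asarray(nbr_b) - p)
    bis = normalize(na + nb)
    perp = normalize(np.cross(na, nb))
    t = math.radians(tilt_deg)
    d1 = normalize(-bis * math.cos(t) + perp * math.sin(t))
    d2 = normalize(-bis * math.cos(t) - perp * math.sin(t))
    return d1, d2
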