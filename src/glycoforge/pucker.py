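"""Cremer-Pople ring puckering analysis and conformer classification.

For an N-membered ring the atoms are projected onto their mean plane (defined
so that the out-of-plane displacements ``z_j`` satisfy the two Cremer-Pople
orthogonality conditions) and the displacements are decomposed into Fourier
puckering modes::

    q_m cos(phi_m) =  sqrt(2/N) * sum_j z_j cos(2 pi m j / N)
    q_m sin(phi_m) = -sqrt(2/N) * sum_j z_j sin(2 pi m j / N)
    q_{N/2}        =  sqrt(1/N) * sum_j z_j (-1)^j          (N even)

with total amplitude ``Q = sqrt(sum q_m^2)``.  For six-membered rings the
spherical coordinates are ``cos(theta) = q_3 / Q`` and ``phi = phi_2``; for
five-membered rings there is a single mode (``Q = q_2``, pseudorotation phase
``phi_2``).

Atom-ordering convention: the ring oxygen first, then the anomeric carbon,
then the remaining carbons in ascending order (O5, C1, C2, ... for
aldopyranoses).  With this convention the 4C1 chair of a D-pyranose sits at
theta ~ 0 and the 1C4 chair at theta ~ 180.

Conformer labels are plain ASCII: ``4C1``, ``1C4``, ``3,OB`` (the 3,O-boat),
``B1,4``, ``3S1``, ``OH1``, ``3H4``, ``OE``, ``E1`` ... Superscript atoms of
the printed form precede the letter, subscript atoms follow it.  The vertex
table is generated from the same displacement synthesis used by the ring
builder, so each label is tied to which ring atoms lie above/below the
reference plane rather than to a transcribed lookup table.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError

#: Canonical polar angle of the envelope/half-chair tropics, arccos(1/sqrt(3)).
TROPIC_THETA = math.degrees(math.acos(1.0 / math.sqrt(3.0)))

#: Rings with total amplitude below this (Angstrom) are reported planar.
FLATNESS_Q = 0.10


# ---------------------------------------------------------------------------
# forward analysis
# ---------------------------------------------------------------------------

def ring_displacements(coords: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j relative to the Cremer-Pople mean plane.

    The returned vector sums to zero and is orthogonal to the m=1 Fourier
    mode (the defining conditions of the mean plane).
    """
    r = np.asarray(coords, dtype=float)
    n_atoms = len(r)
    r = r - r.mean(axis=0)
    j = np.arange(n_atoms)
    rp = (r * np.sin(2 * np.pi * j / n_atoms)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / n_atoms)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-12:
        raise GeometryError("degenerate (collinear) ring coordinates")
    return r @ (normal / nrm)


def cremer_pople(coords: np.ndarray) -> tuple:
    """Puckering parameters of a 5- or 6-membered ring.

    Parameters
    ----------
    coords : (N, 3) array
        Ring atom positions in CP order (ring O first, then anomeric C, ...).

    Returns
    -------
    (Q, theta, phi)
        ``Q`` in Angstrom; ``theta`` in degrees [0, 180] (``None`` for
        5-rings, which have no polar angle); ``phi`` in degrees [0, 360).
        Invariant to rigid-body motion of the inputs.
    """
    z = ring_displacements(coords)
    n_atoms = len(z)
    if n_atoms not in (5, 6):
        raise GeometryError(f"ring size {n_atoms} not supported")
    j = np.arange(n_atoms)
    ang = 2 * np.pi * 2 * j / n_atoms
    qc = math.sqrt(2.0 / n_atoms) * float(z @ np.cos(ang))
    qs = -math.sqrt(2.0 / n_atoms) * float(z @ np.sin(ang))
    q2 = math.hypot(qc, qs)
    phi = math.degrees(math.atan2(qs, qc)) % 360.0 if q2 > 1e-12 else 0.0
    if n_atoms == 5:
        return q2, None, phi
    q3 = math.sqrt(1.0 / n_atoms) * float(z @ ((-1.0) ** j))
    big_q = math.hypot(q2, q3)
    if big_q < 1e-12:
        return 0.0, 0.0, 0.0
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / big_q))))
    return big_q, theta, phi


# ---------------------------------------------------------------------------
# displacement synthesis (shared with the synthetic ring builder)
# ---------------------------------------------------------------------------

def synthesize_displacements(n_atoms: int, q_total: float,
                             theta: Optional[float], phi: float) -> np.ndarray:
    """Inverse Cremer-Pople: z_j for a target (Q, theta, phi)."""
    j = np.arange(n_atoms)
    phi_r = math.radians(phi)
    if n_atoms == 5:
        return math.sqrt(2.0 / 5.0) * q_total * np.cos(phi_r + 4 * np.pi * j / 5)
    if n_atoms == 6:
        th = math.radians(theta)
        q2 = q_total * math.sin(th)
        q3 = q_total * math.cos(th)
        return (math.sqrt(2.0 / 6.0) * q2 * np.cos(phi_r + 4 * np.pi * j / 6)
                + math.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j)
    raise GeometryError(f"ring size {n_atoms} not supported")


# ---------------------------------------------------------------------------
# canonical conformer vertices
# ---------------------------------------------------------------------------

def _token(atom_name: str) -> str:
    """Label token for a ring atom: 'O5' -> 'O', 'C3' -> '3'."""
    return "O" if atom_name[0] == "O" else atom_name[1:]

def _order_tokens(names: Sequence[str]) -> list:
    carbons = sorted(_token(n) for n in names if n[0] != "O")
    oxygens = ["O"] * sum(1 for n in names if n[0] == "O")
    return carbons + oxygens


def _label_from_pattern(z: np.ndarray, ring_atoms: Sequence[str],
                        kind: str) -> str:
    """Derive the conformer label at a canonical vertex from its z-pattern."""
    n_atoms = len(z)
    up = [i for i in range(n_atoms) if z[i] > 1e-9]
    order = np.argsort(-np.abs(z))
    if kind == "chair":
        # reference plane excludes the para pair containing the lowest carbon
        # (ring index 1 = anomeric C) -> named atoms are ring indices 1 and 4
        lo, hi = 1, 1 + n_atoms // 2
        above = hi if z[hi] > 0 else lo
        below = lo if above == hi else hi
        return f"{_token(ring_atoms[above])}C{_token(ring_atoms[below])}"
    if kind == "equator":
        big = np.abs(z).max()
        extremes = [i for i in range(n_atoms) if abs(z[i]) > big - 1e-6]
        if len(extremes) == 2:  # boat: one para pair displaced together
            toks = ",".join(_order_tokens([ring_atoms[i] for i in extremes]))
            return f"{toks}B" if z[extremes[0]] > 0 else f"B{toks}"
        # skew-boat: of the two meta opposite-sign pairs, name the one that
        # contains the lowest-numbered carbon
        pairs = []
        for i in range(n_atoms):
            for k in range(n_atoms):
                if min((i - k) % n_atoms, (k - i) % n_atoms) != 2:
                    continue
                if z[i] > 1e-9 and z[k] < -1e-9 and abs(abs(z[i]) - abs(z[k])) < 1e-6:
                    pairs.append((i, k))
        def lowest_carbon(pair):
            nums = [int(_token(ring_atoms[i])) for i in pair
                    if ring_atoms[i][0] != "O"]
            return min(nums) if nums else 99
        i_up, i_dn = min(pairs, key=lowest_carbon)
        return f"{_token(ring_atoms[i_up])}S{_token(ring_atoms[i_dn])}"
    # tropic (6-ring E/H) or 5-ring E/T vertex
    letter = "H" if n_atoms == 6 else "T"
    a, b = int(order[0]), int(order[1])
    near_equal = abs(z[b]) / abs(z[a]) > 0.9
    adjacent = (a - b) % n_atoms in (1, n_atoms - 1)
    if near_equal and adjacent and (z[a] > 0) != (z[b] > 0):
        i_up, i_dn = (a, b) if z[a] > 0 else (b, a)
        return f"{_token(ring_atoms[i_up])}{letter}{_token(ring_atoms[i_dn])}"
    return f"{_token(ring_atoms[a])}E" if z[a] > 0 else f"E{_token(ring_atoms[a])}"


def canonical_vertices(ring_atoms: Sequence[str]) -> list:
    """All canonical conformer vertices for a ring.

    Returns a list of ``(theta, phi, label)`` for 6-rings (38 entries: 2
    chairs, 6 boats, 6 twist-boats, 12 half-chairs, 12 envelopes) or
    ``(None, phi, label)`` for 5-rings (10 envelopes + 10 twists).
    """
    n_atoms = len(ring_atoms)
    out = []
    if n_atoms == 6:
        for theta in (0.0, 180.0):
            z = synthesize_displacements(6, 1.0, theta, 0.0)
            out.append((theta, 0.0, _label_from_pattern(z, ring_atoms, "chair")))
        for k in range(12):
            phi = 30.0 * k
            z = synthesize_displacements(6, 1.0, 90.0, phi)
            out.append((90.0, phi, _label_from_pattern(z, ring_atoms, "equator")))
        for theta in (TROPIC_THETA, 180.0 - TROPIC_THETA):
            for k in range(12):
                phi = 30.0 * k
                z = synthesize_displacements(6, 1.0, theta, phi)
                out.append((theta, phi, _label_from_pattern(z, ring_atoms, "tropic")))
    elif n_atoms == 5:
        for k in range(20):
            phi = 18.0 * k
            z = synthesize_displacements(5, 1.0, None, phi)
            out.append((None, phi, _label_from_pattern(z, ring_atoms, "tropic")))
    else:
        raise GeometryError(f"ring size {n_atoms} not supported")
    return out


def classify_pucker(q_total: float, theta: Optional[float], phi: float,
                    ring_atoms: Sequence[str]) -> str:
    """Nearest canonical conformer label for measured (Q, theta, phi)."""
    label, _margin = classify_pucker_detail(q_total, theta, phi, ring_atoms)
    return label


def classify_pucker_detail(q_total: float, theta: Optional[float], phi: float,
                           ring_atoms: Sequence[str]) -> tuple:
    """As :func:`classify_pucker` but also return the angular margin (degrees)
    between the nearest and second-nearest canonical vertex; small margins
    (< 10 deg) indicate a borderline assignment."""
    if q_total < FLATNESS_Q:
        return "planar", float("inf")
    verts = canonical_vertices(ring_atoms)
    if theta is None:
        dists = [(min(abs(phi - pv) % 360, 360 - abs(phi - pv) % 360), lab)
                 for _tv, pv, lab in verts]
    else:
        th = math.radians(theta)
        dists = []
        for tv, pv, lab in verts:
            tvr = math.radians(tv)
            cosd = (math.cos(th) * math.cos(tvr)
                    + math.sin(th) * math.sin(tvr) * math.cos(math.radians(phi - pv)))
            dists.append((math.degrees(math.acos(max(-1.0, min(1.0, cosd)))), lab))
    dists.sort(key=lambda t: t[0])
    best_d, best_lab = dists[0]
    runner = next((d for d, lab in dists[1:] if lab != best_lab), best_d)
    return best_lab, runner - best_d
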